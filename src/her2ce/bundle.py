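"""Structured parameter bundle: model settings, transition inputs,
utilities, regimens, costs, and the fitted survival specification.

The bundle is the single input object the decision model consumes. It
round-trips through YAML, every leaf carries a provenance tag
(``paper`` / ``assumption`` / ``calibrated``), and parameters are
addressable by dotted paths (used by the sensitivity analyses), e.g.
``utilities.met_2l`` or ``costs.tdm1.monthly.met_1l.supportive``.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .economics import CostSet, DoseRegimen, UtilitySet
from .survival import FAMILY_PARAM_NAMES, ParametricFamily, WaningSchedule

__all__ = ["ModelSettings", "ArmTransitions", "SurvivalSpec", "InputBundle",
           "ARMS", "PROVENANCE_TAGS"]

ARMS = ("tdm1", "tras")
PROVENANCE_TAGS = ("paper", "assumption", "calibrated")

SCHEMA_VERSION = 1


@dataclass
class ModelSettings:
    """Global analysis settings (defaults are the base case)."""

    horizon_years: int = 48
    discount_rate: float = 0.05
    baseline_age: float = 52.0
    weight_kg: float = 67.0
    wtp: float = 6831.0
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        if self.weight_kg <= 0:
            raise ValueError("body weight must be positive")

    @property
    def n_cycles(self) -> int:
        return self.horizon_years * 12


@dataclass
class ArmTransitions:
    """Arm-specific metastatic-line monthly probabilities."""

    p_1l_to_2l: float
    p_2l_death: float


@dataclass
class CurveSpec:
    """Serializable mixture-cure curve (one arm)."""

    family: str
    cure_fraction: float
    params: dict[str, float]

    def latent(self) -> ParametricFamily:
        names = FAMILY_PARAM_NAMES[self.family]
        return ParametricFamily(self.family, tuple(self.params[p] for p in names))


@dataclass
class SurvivalSpec:
    """Disease-free survival specification for both arms.

    ``mode``: 'per-arm' uses each arm's own fitted curve, with the
    cycle-specific arm hazard contrast waned toward 1; 'ph' derives the
    treated curve from the control curve and a single hazard ratio.
    """

    control: CurveSpec
    treated: CurveSpec | None
    hr: float = 0.54
    mode: str = "per-arm"
    waning: WaningSchedule = field(default_factory=WaningSchedule)
    #: reference value of ``hr`` at bundle build; in per-arm mode a
    #: sensitivity draw of ``hr`` scales the fitted cycle contrast by
    #: hr / hr_ref (1 at base case)
    hr_ref: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("per-arm", "ph"):
            raise ValueError("survival mode must be 'per-arm' or 'ph'")
        if self.mode == "per-arm" and self.treated is None:
            raise ValueError("per-arm mode requires a treated curve")
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")


@dataclass
class InputBundle:
    """All parameters the decision model needs for both arms."""

    settings: ModelSettings
    survival: SurvivalSpec
    utilities: UtilitySet
    remission_to_1l: float
    arm_transitions: dict[str, ArmTransitions]
    event_shares: dict[str, float]  # locoregional / metastatic / death
    regimens: dict[str, DoseRegimen]
    costs: dict[str, CostSet]
    treatment_cycles: int = 10
    cost_targets: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        for arm in ARMS:
            if arm not in self.arm_transitions or arm not in self.costs:
                raise ValueError(f"bundle missing arm {arm!r}")
        if abs(sum(self.event_shares.values()) - 1.0) > 1e-9:
            raise ValueError("event destination shares must sum to 1")
        for tag in self.provenance.values():
            if tag not in PROVENANCE_TAGS:
                raise ValueError(f"unknown provenance tag {tag!r}")

    # ---- dotted-path parameter access (used by PSA / DSA) ------------

    def get_path(self, path: str):
        obj = self
        for part in path.split("."):
            if isinstance(obj, dict):
                obj = obj[part]
            else:
                obj = getattr(obj, part)
        return obj

    def set_path(self, path: str, value) -> None:
        parts = path.split(".")
        obj = self
        for part in parts[:-1]:
            if isinstance(obj, dict):
                obj = obj[part]
            else:
                obj = getattr(obj, part)
        last = parts[-1]
        if isinstance(obj, dict):
            obj[last] = value
        else:
            if not hasattr(obj, last):
                raise AttributeError(f"no parameter at path {path!r}")
            object.__setattr__(obj, last, value) if _frozen_dc(obj) else \
                setattr(obj, last, value)

    def copy(self) -> "InputBundle":
        return copy.deepcopy(self)

    # ---- serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "schema_version": self.schema_version,
            "settings": asdict(self.settings),
            "survival": {
                "mode": self.survival.mode,
                "hr": self.survival.hr,
                "hr_ref": self.survival.hr_ref,
                "waning": asdict(self.survival.waning),
                "control": asdict(self.survival.control),
                "treated": (asdict(self.survival.treated)
                            if self.survival.treated else None),
            },
            "utilities": self.utilities.as_dict(),
            "remission_to_1l": self.remission_to_1l,
            "arm_transitions": {a: asdict(t) for a, t in self.arm_transitions.items()},
            "event_shares": dict(self.event_shares),
            "regimens": {a: asdict(r) for a, r in self.regimens.items()},
            "costs": {a: {"monthly": c.monthly,
                          "treatment_cycles": c.treatment_cycles}
                      for a, c in self.costs.items()},
            "treatment_cycles": self.treatment_cycles,
            "cost_targets": self.cost_targets,
            "provenance": dict(self.provenance),
        }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "InputBundle":
        known = {"schema_version", "settings", "survival", "utilities",
                 "remission_to_1l", "arm_transitions", "event_shares",
                 "regimens", "costs", "treatment_cycles", "cost_targets",
                 "provenance"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown bundle keys: {sorted(unknown)}")
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported bundle schema version {d.get('schema_version')!r}"
            )
        surv = d["survival"]
        spec = SurvivalSpec(
            control=CurveSpec(**surv["control"]),
            treated=CurveSpec(**surv["treated"]) if surv.get("treated") else None,
            hr=surv["hr"],
            mode=surv["mode"],
            waning=WaningSchedule(**surv["waning"]),
            hr_ref=surv.get("hr_ref"),
        )
        return cls(
            settings=ModelSettings(**d["settings"]),
            survival=spec,
            utilities=UtilitySet(**d["utilities"]),
            remission_to_1l=d["remission_to_1l"],
            arm_transitions={a: ArmTransitions(**t)
                             for a, t in d["arm_transitions"].items()},
            event_shares=d["event_shares"],
            regimens={a: DoseRegimen(**r) for a, r in d["regimens"].items()},
            costs={a: CostSet(c["monthly"], c["treatment_cycles"])
                   for a, c in d["costs"].items()},
            treatment_cycles=d["treatment_cycles"],
            cost_targets=d.get("cost_targets", {}),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_yaml(cls, path) -> "InputBundle":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable short hash of the bundle contents (report provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _frozen_dc(obj) -> bool:
    params = getattr(type(obj), "__dataclass_params__", None)
    return bool(params and params.frozen)
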