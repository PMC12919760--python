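"""Micro-costing, utility accumulation and incremental summaries.

Costs are accumulated per health state and per component (acquisition,
diagnostic tests, drug administration, adverse events, supportive care),
in 2024 US dollars, over the half-cycle-corrected occupancy of the
cohort trace. Utilities are per-state weights in [0, 1]; QALYs discount
and sum them per cycle (divided by 12, the cycles per year).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import StateSpace, discount_factors

__all__ = [
    "COST_COMPONENTS",
    "DoseRegimen",
    "CostSet",
    "UtilitySet",
    "ArmResult",
    "CEComparison",
    "per_administration_mg",
    "per_cycle_drug_cost",
    "weighted_average_price",
    "adverse_event_cost",
    "accumulate_costs",
    "accumulate_qalys",
    "incremental_summary",
]

COST_COMPONENTS = (
    "acquisition",
    "diagnostic",
    "administration",
    "adverse_events",
    "supportive",
)

#: components incurred only while on adjuvant treatment (residual_on)
TREATMENT_PHASE_COMPONENTS = ("acquisition", "administration", "adverse_events")


@dataclass(frozen=True)
class DoseRegimen:
    """Weight-based IV dosing regimen priced per mg.

    ``loading_dose_per_kg`` (if given) replaces the maintenance dose for
    the first administration only. Costs are linear in milligrams: the
    price applies per minimum concentration unit, so no vial wastage.
    """

    drug: str
    dose_per_kg: float
    n_administrations: int = 14
    interval_days: int = 21
    loading_dose_per_kg: float | None = None
    price_per_mg: float | None = None

    def __post_init__(self) -> None:
        if self.dose_per_kg <= 0:
            raise ValueError("dose must be > 0")
        if self.loading_dose_per_kg is not None and self.loading_dose_per_kg <= 0:
            raise ValueError("loading dose must be > 0")
        if self.n_administrations < 1:
            raise ValueError("need at least one administration")

    @property
    def duration_months(self) -> int:
        """Treatment span in whole monthly cycles (ceiling of days/30.44
        replaced by exact 21-day spacing mapped onto months: the k-th
        administration occurs on day 21(k-1))."""
        span_days = self.interval_days * (self.n_administrations - 1) + self.interval_days
        return math.ceil(span_days / 30.0)

    def mg(self, weight_kg: float, administration: int = 1) -> float:
        """Milligrams for one administration (1-based index)."""
        if weight_kg <= 0:
            raise ValueError("body weight must be > 0")
        if administration == 1 and self.loading_dose_per_kg is not None:
            return self.loading_dose_per_kg * weight_kg
        return self.dose_per_kg * weight_kg

    def total_mg(self, weight_kg: float) -> float:
        return sum(self.mg(weight_kg, i + 1) for i in range(self.n_administrations))


def per_administration_mg(regimen: DoseRegimen, weight_kg: float,
                          administration: int = 1) -> float:
    return regimen.mg(weight_kg, administration)


def per_cycle_drug_cost(regimen: DoseRegimen, weight_kg: float,
                        administration: int = 1) -> float:
    """Acquisition cost of one administration: mg x price per mg."""
    if regimen.price_per_mg is None:
        raise ValueError(f"no price per mg set for {regimen.drug}")
    return regimen.mg(weight_kg, administration) * regimen.price_per_mg


def weighted_average_price(presentations: list[tuple[float, float]]) -> float:
    """Market-share-weighted mean price per mg.

    ``presentations`` is a list of (price_per_mg, market_share); shares are
    renormalised to sum to one.
    """
    if not presentations:
        raise ValueError("no presentations supplied")
    prices = np.array([p for p, _ in presentations], dtype=float)
    shares = np.array([s for _, s in presentations], dtype=float)
    if np.any(shares < 0):
        raise ValueError("market shares must be non-negative")
    total = shares.sum()
    if total <= 0:
        raise ValueError("market shares must sum to a positive value")
    return float(np.dot(prices, shares / total))


def adverse_event_cost(arm: str, cbc_unit_cost: float,
                       counts_per_cycle: float = 1.0) -> float:
    """Monthly adverse-event monitoring cost during treatment.

    Only the additional complete blood count in the T-DM1-treated
    population carries a cost; the comparator arm incurs none.
    """
    if cbc_unit_cost < 0:
        raise ValueError("unit cost must be non-negative")
    if arm == "tdm1":
        return cbc_unit_cost * counts_per_cycle
    return 0.0


@dataclass
class CostSet:
    """Monthly per-state, per-component costs (2024 US$) for one arm.

    ``monthly[state][component]`` is a non-negative monthly cost.
    Treatment-phase components (acquisition, administration, adverse
    events) accrue only in ``residual_on`` during the treatment cycles;
    all other components accrue whenever the state is occupied.
    """

    monthly: dict[str, dict[str, float]]
    treatment_cycles: int = 10

    def __post_init__(self) -> None:
        for state, comps in self.monthly.items():
            for comp, v in comps.items():
                if comp not in COST_COMPONENTS:
                    raise ValueError(f"unknown cost component {comp!r} in {state!r}")
                if v < 0:
                    raise ValueError(f"negative cost for {state}/{comp}")
            for comp in TREATMENT_PHASE_COMPONENTS:
                if state != "residual_on" and comps.get(comp, 0.0) != 0.0:
                    raise ValueError(
                        f"treatment-phase component {comp!r} must be zero "
                        f"outside residual_on (state {state!r})"
                    )

    def rate(self, state: str, component: str, cycle: int) -> float:
        v = self.monthly.get(state, {}).get(component, 0.0)
        if component in TREATMENT_PHASE_COMPONENTS and cycle >= self.treatment_cycles:
            return 0.0
        return v

    def scaled(self, factor: float) -> "CostSet":
        return CostSet(
            {s: {c: v * factor for c, v in comps.items()}
             for s, comps in self.monthly.items()},
            self.treatment_cycles,
        )


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights in [0, 1]; death is 0."""

    residual_on: float = 0.77
    residual_off: float = 0.78
    recurrence: float = 0.77
    remission: float = 0.78
    met_1l: float = 0.77
    met_2l: float = 0.52

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"utility {name} must lie in [0, 1], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "residual_on": self.residual_on,
            "residual_off": self.residual_off,
            "recurrence": self.recurrence,
            "remission": self.remission,
            "met_1l": self.met_1l,
            "met_2l": self.met_2l,
        }

    def vector(self, space: StateSpace) -> np.ndarray:
        u = np.zeros(len(space))
        u[space.residual_on] = self.residual_on
        u[space.residual_off] = self.residual_off
        for j in space.tunnel_states:
            u[j] = self.recurrence
        u[space.remission] = self.remission
        u[space.met_1l] = self.met_1l
        u[space.met_2l] = self.met_2l
        return u


# state-space index groups -> reporting states used by CostSet keys
def _state_groups(space: StateSpace) -> dict[str, list[int]]:
    return {
        "residual_on": [space.residual_on],
        "residual_off": [space.residual_off],
        "recurrence": list(space.tunnel_states),
        "remission": [space.remission],
        "met_1l": [space.met_1l],
        "met_2l": [space.met_2l],
    }


def accumulate_costs(eff_occ: np.ndarray, costs: CostSet, annual_rate: float,
                     space: StateSpace | None = None) -> pd.DataFrame:
    """Discounted cost by reporting state and component.

    ``eff_occ`` is the half-cycle-corrected occupancy (H x n_states).
    Returns a DataFrame indexed by reporting state with one column per
    component plus a ``total``; the grand total equals the sum of all
    components exactly (no leakage).
    """
    space = space or StateSpace()
    eff_occ = np.asarray(eff_occ, dtype=float)
    if eff_occ.shape[1] != len(space):
        raise ValueError("occupancy and state space do not match")
    H = eff_occ.shape[0]
    df = discount_factors(H, annual_rate)
    groups = _state_groups(space)
    out = pd.DataFrame(0.0, index=list(groups), columns=list(COST_COMPONENTS))
    for state, idxs in groups.items():
        occ = eff_occ[:, idxs].sum(axis=1)
        comps = costs.monthly.get(state, {})
        for comp, value in comps.items():
            if value == 0.0:
                continue
            if comp in TREATMENT_PHASE_COMPONENTS:
                mask = np.arange(H) < costs.treatment_cycles
                out.loc[state, comp] = float(np.sum(occ * df * value * mask))
            else:
                out.loc[state, comp] = float(np.sum(occ * df * value))
    out["total"] = out[list(COST_COMPONENTS)].sum(axis=1)
    return out


def accumulate_qalys(eff_occ: np.ndarray, utilities: UtilitySet,
                     annual_rate: float,
                     space: StateSpace | None = None) -> tuple[float, float]:
    """Discounted (QALYs, life-years) over the trace.

    QALY = sum_k sum_s occ_eff(k, s) u(s) df(k) / 12; life-years use a
    unit utility for every alive state, so QALYs <= life-years always.
    """
    space = space or StateSpace()
    eff_occ = np.asarray(eff_occ, dtype=float)
    H = eff_occ.shape[0]
    df = discount_factors(H, annual_rate)
    u = utilities.vector(space)
    qalys = float(np.sum((eff_occ @ u) * df) / 12.0)
    alive = space.alive.astype(float)
    lys = float(np.sum((eff_occ @ alive) * df) / 12.0)
    return qalys, lys


@dataclass
class ArmResult:
    """Discounted totals for one strategy arm."""

    arm: str
    cost_components: pd.DataFrame
    qalys: float
    life_years: float

    @property
    def total_cost(self) -> float:
        return float(self.cost_components["total"].sum())


@dataclass
class CEComparison:
    """Incremental comparison of a new strategy vs a comparator."""

    delta_cost: float
    delta_qalys: float
    wtp: float
    icer: float | None
    label: str

    @property
    def nmb(self) -> float:
        """Net monetary benefit at the willingness-to-pay threshold."""
        return self.delta_qalys * self.wtp - self.delta_cost


def incremental_summary(new: ArmResult | tuple[float, float],
                        comparator: ArmResult | tuple[float, float],
                        wtp: float) -> CEComparison:
    """Classify the incremental result and compute ICER/NMB.

    Labels: ``Dominant`` (cheaper and more effective), ``Dominated``
    (dearer and less effective), ``Equivalent`` (no difference), else the
    ICER is reported and compared with the threshold
    (``Cost-effective`` / ``Not cost-effective``).
    """
    def unpack(x):
        if isinstance(x, ArmResult):
            return x.total_cost, x.qalys
        return float(x[0]), float(x[1])

    c_new, e_new = unpack(new)
    c_cmp, e_cmp = unpack(comparator)
    dc, de = c_new - c_cmp, e_new - e_cmp
    icer: float | None = None
    if dc == 0.0 and de == 0.0:
        label = "Equivalent"
    elif dc < 0 and de > 0:
        label = "Dominant"
    elif dc > 0 and de < 0:
        label = "Dominated"
    elif de == 0.0:
        # same effect, different cost: cheaper wins without a finite ICER
        label = "Dominant" if dc < 0 else "Dominated"
    else:
        icer = dc / de
        if de > 0:
            label = "Cost-effective" if icer <= wtp else "Not cost-effective"
        else:
            # cheaper and less effective: cost saved per QALY forgone
            label = "Cost-effective" if icer >= wtp else "Not cost-effective"
    return CEComparison(delta_cost=dc, delta_qalys=de, wtp=wtp,
                        icer=icer, label=label)


def state_component_summary(new_means: dict, cmp_means: dict) -> pd.DataFrame:
    """Reporting-layer arithmetic over per-arm state/component cost means.

    ``new_means`` / ``cmp_means`` map state -> component -> mean cost.
    Returns a frame indexed by (state, component) — with a ``total`` row
    per state — and columns ``new``, ``comparator``, ``incremental``
    (new minus comparator). Totals are sums of the listed components.
    """
    rows = []
    states = list(new_means)
    for state in states:
        comps = sorted(set(new_means[state]) | set(cmp_means.get(state, {})),
                       key=list(COST_COMPONENTS).index)
        for comp in comps:
            a = float(new_means[state].get(comp, 0.0))
            b = float(cmp_means.get(state, {}).get(comp, 0.0))
            rows.append((state, comp, a, b, a - b))
        tot_a = sum(float(v) for v in new_means[state].values())
        tot_b = sum(float(v) for v in cmp_means.get(state, {}).values())
        rows.append((state, "total", tot_a, tot_b, tot_a - tot_b))
    out = pd.DataFrame(rows, columns=["state", "component", "new",
                                      "comparator", "incremental"])
    return out.set_index(["state", "component"])


def component_increment_table(new: pd.DataFrame,
                              comparator: pd.DataFrame) -> pd.DataFrame:
    """Per-state, per-component incremental cost table (new - comparator),
    shaped like a published component breakdown with per-state totals."""
    inc = new[list(COST_COMPONENTS)] - comparator[list(COST_COMPONENTS)]
    inc["total"] = inc.sum(axis=1)
    return inc
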