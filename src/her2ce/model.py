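"""Cohort decision model: assembles survival, Markov and costing layers.

:class:`DecisionModel` is built from an :class:`~her2ce.bundle.InputBundle`
and a background-mortality life table; ``run()`` returns a
:class:`DecisionResults` carrying per-arm discounted costs, life-years and
QALYs, the incremental comparison (ICER / dominance / NMB), the cohort
traces, and tabular summaries shaped like published base-case and cost-
component tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import ARMS, InputBundle
from .economics import (ArmResult, CEComparison, CostSet, accumulate_costs,
                        accumulate_qalys, component_increment_table,
                        incremental_summary)
from .markov import (ArmTransitionInputs, StateSpace,
                     build_matrix_sequence, half_cycle_effective_occupancy,
                     run_cohort)
from .survival import LifeTable, effective_hazard_ratio

__all__ = ["DecisionModel", "DecisionResults"]

_EPS = 1e-300


@dataclass
class DecisionResults:
    """Results object for a two-arm cost-effectiveness run."""

    arms: dict[str, ArmResult]
    comparison: CEComparison
    traces: dict[str, np.ndarray]
    incidence: dict[str, pd.DataFrame]
    space: StateSpace
    config_hash: str

    def summary(self) -> pd.DataFrame:
        """Base-case table: per-arm cost/QALYs plus incrementals."""
        t, c = self.arms["tdm1"], self.arms["tras"]
        cmp_ = self.comparison
        return pd.DataFrame(
            {
                "cost": [t.total_cost, c.total_cost],
                "qalys": [t.qalys, c.qalys],
                "life_years": [t.life_years, c.life_years],
                "delta_cost": [np.nan, cmp_.delta_cost],
                "delta_qalys": [np.nan, cmp_.delta_qalys],
                "icer_or_label": [
                    "-", cmp_.label if cmp_.icer is None else f"{cmp_.icer:.1f}"
                ],
                "nmb": [np.nan, cmp_.nmb],
            },
            index=["tdm1", "tras"],
        )

    def state_cost_table(self, aggregate_residual: bool = True) -> pd.DataFrame:
        """Per-state component costs by arm with the incremental column,
        shaped like a published cost-component breakdown. By default the
        on-/off-treatment residual split is aggregated into a single
        residual-state row."""
        t = self.arms["tdm1"].cost_components
        c = self.arms["tras"].cost_components
        if aggregate_residual:
            t, c = (_merge_residual(x) for x in (t, c))
        inc = component_increment_table(t, c)
        out = pd.concat({"tdm1": t, "tras": c, "incremental": inc}, axis=1)
        return out

    def event_reduction(self, month: int) -> dict[str, float]:
        """Relative reduction (T-DM1 vs control) in cumulative
        locoregional events, metastatic events and deaths at ``month``."""
        out = {}
        for kind in ("locoregional", "metastatic", "death"):
            ct = float(self.incidence["tdm1"][kind].iloc[month])
            cc = float(self.incidence["tras"][kind].iloc[month])
            out[kind] = 1.0 - ct / cc if cc > 0 else 0.0
        return out


def _merge_residual(components: pd.DataFrame) -> pd.DataFrame:
    out = components.drop(index=["residual_on", "residual_off"])
    residual = components.loc[["residual_on", "residual_off"]].sum(axis=0)
    residual.name = "residual"
    return pd.concat([residual.to_frame().T, out])


class DecisionModel:
    """Markov cohort cost-effectiveness model over two strategy arms.

    Parameters
    ----------
    bundle : InputBundle
        Full parameter set (settings, curves, transitions, costs,
        utilities, regimens).
    life_table : LifeTable
        Background all-cause annual mortality by age.
    """

    def __init__(self, bundle: InputBundle, life_table: LifeTable):
        self.bundle = bundle
        self.life_table = life_table
        self.space = StateSpace()
        end_age = bundle.settings.baseline_age + bundle.settings.horizon_years
        if end_age > life_table.max_age + 1:
            raise ValueError(
                f"horizon reaches age {end_age:g}, beyond the life table "
                f"(max age {life_table.max_age})"
            )

    # ---- survival layer ---------------------------------------------

    def _background_q(self) -> np.ndarray:
        s = self.bundle.settings
        return np.array(
            [self.life_table.monthly(min(s.baseline_age + k / 12.0,
                                         self.life_table.max_age))
             for k in range(s.n_cycles)]
        )

    def disease_free_exit_probs(self, arm: str) -> np.ndarray:
        """Per-cycle probability of a first invasive-disease event.

        The control arm uses its fitted mixture-cure curve directly. The
        treated arm's per-cycle log-hazard contrast against control is
        multiplied by the waning weight w(t) (1 up to t_full, 0 from
        t_none): in 'per-arm' mode the contrast is the ratio of the two
        fitted cycle hazards, in 'ph' mode it is the single hazard ratio.
        Beyond t_none both arms share the control hazard exactly.
        """
        spec = self.bundle.survival
        H = self.bundle.settings.n_cycles
        t = np.arange(H + 1, dtype=float)
        ctrl = spec.control
        s_ctrl = np.maximum(
            ctrl.cure_fraction + (1 - ctrl.cure_fraction) * ctrl.latent().sf(t),
            _EPS,
        )
        dH_ctrl = np.diff(-np.log(s_ctrl))
        if arm == "tras":
            return 1.0 - np.exp(-dH_ctrl)
        # treated arm: cycle hazard contrast vs control, waned toward 1
        if spec.mode == "ph":
            ratio = np.full(H, spec.hr)
        else:
            tr = spec.treated
            s_tr = np.maximum(
                tr.cure_fraction + (1 - tr.cure_fraction) * tr.latent().sf(t),
                _EPS,
            )
            dH_tr = np.maximum(np.diff(-np.log(s_tr)), _EPS)
            ratio = dH_tr / np.maximum(dH_ctrl, _EPS)
            if spec.hr_ref:
                # sensitivity draw of the overall HR scales the fitted
                # cycle contrast relative to its build-time reference
                ratio = ratio * (spec.hr / spec.hr_ref)
        eff = np.array(
            [effective_hazard_ratio(max(float(r), _EPS), float(k), spec.waning)
             for k, r in enumerate(ratio)]
        )
        dH = dH_ctrl * eff
        return 1.0 - np.exp(-dH)

    # ---- assembly ----------------------------------------------------

    def _arm_inputs(self, arm: str) -> ArmTransitionInputs:
        b = self.bundle
        at = b.arm_transitions[arm]
        return ArmTransitionInputs(
            df_exit_prob=self.disease_free_exit_probs(arm),
            share_locoregional=b.event_shares["locoregional"],
            share_metastatic=b.event_shares["metastatic"],
            share_death=b.event_shares["death"],
            remission_to_1l=b.remission_to_1l,
            p_1l_to_2l=at.p_1l_to_2l,
            p_2l_death=at.p_2l_death,
            background_q=self._background_q(),
            treatment_cycles=b.treatment_cycles,
        )

    def _arm_costs(self, arm: str) -> CostSet:
        """Cost set with the acquisition component derived from the
        arm's dosing regimen, price per mg and patient weight."""
        b = self.bundle
        base = b.costs[arm]
        regimen = b.regimens.get(arm)
        monthly = {s: dict(c) for s, c in base.monthly.items()}
        if regimen is not None and regimen.price_per_mg is not None:
            total_cost = regimen.total_mg(b.settings.weight_kg) * regimen.price_per_mg
            monthly.setdefault("residual_on", {})
            monthly["residual_on"]["acquisition"] = total_cost / b.treatment_cycles
        return CostSet(monthly, treatment_cycles=base.treatment_cycles)

    def run_arm(self, arm: str) -> tuple[ArmResult, np.ndarray, pd.DataFrame]:
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}")
        b = self.bundle
        inputs = self._arm_inputs(arm)
        matrices = build_matrix_sequence(inputs, self.space)
        init = np.zeros(len(self.space))
        init[self.space.residual_on] = 1.0
        trace = run_cohort(init, matrices)
        eff = half_cycle_effective_occupancy(
            trace, enabled=b.settings.half_cycle_correction
        )
        cost_components = accumulate_costs(
            eff, self._arm_costs(arm), b.settings.discount_rate, self.space
        )
        qalys, lys = accumulate_qalys(
            eff, b.utilities, b.settings.discount_rate, self.space
        )
        incidence = _cumulative_incidence(trace, matrices, self.space)
        return (ArmResult(arm, cost_components, qalys, lys), trace, incidence)

    def run(self) -> DecisionResults:
        arms, traces, incidence = {}, {}, {}
        for arm in ARMS:
            arms[arm], traces[arm], incidence[arm] = self.run_arm(arm)
        comparison = incremental_summary(
            arms["tdm1"], arms["tras"], self.bundle.settings.wtp
        )
        return DecisionResults(
            arms=arms, comparison=comparison, traces=traces,
            incidence=incidence, space=self.space,
            config_hash=self.bundle.config_hash(),
        )


def _cumulative_incidence(trace: np.ndarray, matrices: np.ndarray,
                          space: StateSpace) -> pd.DataFrame:
    """Cumulative first locoregional events (inflow to tunnel 1),
    metastatic events (inflow to 1L mBC) and deaths, per cycle."""
    H = matrices.shape[0]
    loco = np.einsum("ks,ks->k", trace[:-1], matrices[:, :, space.tunnel(1)])
    met = np.einsum("ks,ks->k", trace[:-1], matrices[:, :, space.met_1l])
    out = pd.DataFrame(
        {
            "locoregional": np.concatenate(([0.0], np.cumsum(loco))),
            "metastatic": np.concatenate(([0.0], np.cumsum(met))),
            "death": trace[:, space.death],
        }
    )
    return out
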