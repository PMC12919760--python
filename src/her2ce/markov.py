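"""Monthly Markov cohort engine over the expanded six-state space.

Base health states: residual invasive disease (split into on- and
off-treatment), non-metastatic recurrence (a 12-month tunnel of monthly
compartments enforcing automatic remission after 12 months if alive),
remission, first-line metastatic disease (1L mBC), later-line metastatic
disease (2L+ mBC), and death (absorbing).

The engine builds one row-stochastic transition matrix per monthly cycle
(transition probabilities are time-dependent through the fitted
disease-free curve and the age-dependent background mortality) and
propagates the cohort with an optional trapezoidal half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StateSpace",
    "ArmTransitionInputs",
    "build_matrix",
    "build_matrix_sequence",
    "run_cohort",
    "half_cycle_effective_occupancy",
    "discount_factor",
    "discount_factors",
    "combine_competing",
    "microsim_oracle",
]

N_TUNNEL = 12


@dataclass(frozen=True)
class StateSpace:
    """Index map over the expanded state space.

    Order: residual_on, residual_off, recurrence_1..recurrence_12,
    remission, met_1l, met_2l, death.
    """

    names: tuple[str, ...] = field(
        default=tuple(
            ["residual_on", "residual_off"]
            + [f"recurrence_{j}" for j in range(1, N_TUNNEL + 1)]
            + ["remission", "met_1l", "met_2l", "death"]
        )
    )

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def residual_on(self) -> int:
        return 0

    @property
    def residual_off(self) -> int:
        return 1

    def tunnel(self, j: int) -> int:
        """Index of recurrence tunnel compartment j (1-based, 1..12)."""
        if not 1 <= j <= N_TUNNEL:
            raise ValueError(f"tunnel compartment must be 1..{N_TUNNEL}")
        return 1 + j

    @property
    def remission(self) -> int:
        return 2 + N_TUNNEL

    @property
    def met_1l(self) -> int:
        return 3 + N_TUNNEL

    @property
    def met_2l(self) -> int:
        return 4 + N_TUNNEL

    @property
    def death(self) -> int:
        return 5 + N_TUNNEL

    @property
    def alive(self) -> np.ndarray:
        mask = np.ones(len(self), dtype=bool)
        mask[self.death] = False
        return mask

    @property
    def residual_states(self) -> tuple[int, int]:
        return (self.residual_on, self.residual_off)

    @property
    def tunnel_states(self) -> tuple[int, ...]:
        return tuple(self.tunnel(j) for j in range(1, N_TUNNEL + 1))


@dataclass
class ArmTransitionInputs:
    """Per-cycle transition inputs for one treatment arm.

    df_exit_prob[k]   probability of a first invasive-disease event during
                      cycle k, from the (possibly waned) disease-free curve
    share_locoregional/metastatic/death
                      destination split of that first event (sums to 1)
    remission_to_1l   monthly probability of metastatic progression from
                      remission after a non-metastatic recurrence
    p_1l_to_2l        monthly 1L mBC -> 2L+ mBC progression probability
    p_2l_death        monthly 2L+ mBC -> death probability
    background_q[k]   monthly background all-cause death probability at the
                      age attained in cycle k
    treatment_cycles  number of initial cycles spent in residual_on before
                      survivors switch to the off-treatment profile
    """

    df_exit_prob: np.ndarray
    share_locoregional: float
    share_metastatic: float
    share_death: float
    remission_to_1l: float
    p_1l_to_2l: float
    p_2l_death: float
    background_q: np.ndarray
    treatment_cycles: int

    def __post_init__(self) -> None:
        self.df_exit_prob = np.asarray(self.df_exit_prob, dtype=float)
        self.background_q = np.asarray(self.background_q, dtype=float)
        if self.df_exit_prob.shape != self.background_q.shape:
            raise ValueError("df_exit_prob and background_q must align")
        shares = (self.share_locoregional, self.share_metastatic, self.share_death)
        if any(s < 0 for s in shares) or abs(sum(shares) - 1.0) > 1e-9:
            raise ValueError("destination shares must be >= 0 and sum to 1")
        for nm in ("remission_to_1l", "p_1l_to_2l", "p_2l_death"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be a probability, got {v}")
        if np.any((self.df_exit_prob < 0) | (self.df_exit_prob > 1)):
            raise ValueError("df_exit_prob entries must be in [0, 1]")
        if np.any((self.background_q < 0) | (self.background_q > 1)):
            raise ValueError("background_q entries must be in [0, 1]")

    @property
    def n_cycles(self) -> int:
        return self.df_exit_prob.shape[0]


def combine_competing(probs) -> float:
    """Combine independent competing risks: 1 - prod(1 - p_i).

    If the plain sum exceeds 1 by more than 1e-9 after combination the
    caller should treat the row as malformed; this helper only validates
    the inputs.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("competing probabilities must be in [0, 1]")
    return float(1.0 - np.prod(1.0 - probs))


def build_matrix(k: int, inputs: ArmTransitionInputs,
                 space: StateSpace | None = None) -> np.ndarray:
    """Transition matrix for cycle ``k``.

    Background mortality competes independently with the disease event:
    in the residual states a fraction q dies of background causes, and the
    survivors experience the first invasive-disease event with probability
    e_k, split across the locoregional tunnel, 1L mBC and death. The
    recurrence tunnel advances deterministically (death risk = background
    only; no excess mortality for non-metastatic recurrence) and compartment
    12 moves to remission. No edge exists from any tunnel compartment to
    1L mBC.
    """
    space = space or StateSpace()
    n = len(space)
    if not 0 <= k < inputs.n_cycles:
        raise ValueError(f"cycle {k} outside inputs range 0..{inputs.n_cycles - 1}")
    q = float(inputs.background_q[k])
    e = float(inputs.df_exit_prob[k])
    M = np.zeros((n, n))

    # residual states: stay / recurrence tunnel / 1L mBC / death
    p_rec = (1 - q) * e * inputs.share_locoregional
    p_met = (1 - q) * e * inputs.share_metastatic
    p_die = q + (1 - q) * e * inputs.share_death
    p_stay = (1 - q) * (1 - e)
    for src in space.residual_states:
        # survivors remaining disease-free move off treatment once the
        # adjuvant course is complete
        if src == space.residual_on and k + 1 < inputs.treatment_cycles:
            stay_dst = space.residual_on
        else:
            stay_dst = space.residual_off
        if src == space.residual_off:
            stay_dst = space.residual_off
        M[src, stay_dst] = p_stay
        M[src, space.tunnel(1)] = p_rec
        M[src, space.met_1l] = p_met
        M[src, space.death] = p_die

    # recurrence tunnel: advance or die of background causes
    for j in range(1, N_TUNNEL + 1):
        src = space.tunnel(j)
        dst = space.remission if j == N_TUNNEL else space.tunnel(j + 1)
        M[src, dst] = 1 - q
        M[src, space.death] = q

    # remission: metastatic progression competes with background death
    r = inputs.remission_to_1l
    M[space.remission, space.met_1l] = (1 - q) * r
    M[space.remission, space.death] = q
    M[space.remission, space.remission] = (1 - q) * (1 - r)

    # 1L mBC: progression to 2L+ competes with background death
    p12 = inputs.p_1l_to_2l
    M[space.met_1l, space.met_2l] = (1 - q) * p12
    M[space.met_1l, space.death] = q
    M[space.met_1l, space.met_1l] = (1 - q) * (1 - p12)

    # 2L+ mBC: death hazard combines disease progression and background
    p2d = combine_competing([inputs.p_2l_death, q])
    M[space.met_2l, space.death] = p2d
    M[space.met_2l, space.met_2l] = 1 - p2d

    M[space.death, space.death] = 1.0

    rows = M.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-12):
        bad = int(np.argmax(np.abs(rows - 1.0)))
        raise ValueError(
            f"row for state {space.names[bad]!r} sums to {rows[bad]!r} at cycle {k}"
        )
    if np.any((M < 0) | (M > 1)):
        raise ValueError(f"transition entries outside [0, 1] at cycle {k}")
    return M


def build_matrix_sequence(inputs: ArmTransitionInputs,
                          space: StateSpace | None = None) -> np.ndarray:
    """Stack of per-cycle matrices, shape (H, n_states, n_states).

    Vectorised over cycles; cycle-by-cycle output is identical to
    :func:`build_matrix`.
    """
    space = space or StateSpace()
    n = len(space)
    H = inputs.n_cycles
    q = inputs.background_q
    e = inputs.df_exit_prob
    M = np.zeros((H, n, n))
    ks = np.arange(H)

    p_rec = (1 - q) * e * inputs.share_locoregional
    p_met = (1 - q) * e * inputs.share_metastatic
    p_die = q + (1 - q) * e * inputs.share_death
    p_stay = (1 - q) * (1 - e)
    on_treat = ks + 1 < inputs.treatment_cycles
    M[on_treat, space.residual_on, space.residual_on] = p_stay[on_treat]
    M[~on_treat, space.residual_on, space.residual_off] = p_stay[~on_treat]
    for src in space.residual_states:
        M[:, src, space.tunnel(1)] = p_rec
        M[:, src, space.met_1l] = p_met
        M[:, src, space.death] = p_die
    M[:, space.residual_off, space.residual_off] = p_stay

    for j in range(1, N_TUNNEL + 1):
        src = space.tunnel(j)
        dst = space.remission if j == N_TUNNEL else space.tunnel(j + 1)
        M[:, src, dst] = 1 - q
        M[:, src, space.death] = q

    r = inputs.remission_to_1l
    M[:, space.remission, space.met_1l] = (1 - q) * r
    M[:, space.remission, space.death] = q
    M[:, space.remission, space.remission] = (1 - q) * (1 - r)

    p12 = inputs.p_1l_to_2l
    M[:, space.met_1l, space.met_2l] = (1 - q) * p12
    M[:, space.met_1l, space.death] = q
    M[:, space.met_1l, space.met_1l] = (1 - q) * (1 - p12)

    p2d = 1 - (1 - inputs.p_2l_death) * (1 - q)
    M[:, space.met_2l, space.death] = p2d
    M[:, space.met_2l, space.met_2l] = 1 - p2d

    M[:, space.death, space.death] = 1.0

    rows = M.sum(axis=2)
    if np.any(np.abs(rows - 1.0) > 1e-12):
        k_bad, s_bad = np.unravel_index(np.argmax(np.abs(rows - 1.0)), rows.shape)
        raise ValueError(
            f"row for state {space.names[s_bad]!r} does not sum to 1 "
            f"at cycle {k_bad}"
        )
    return M


def run_cohort(initial: np.ndarray, matrices: np.ndarray) -> np.ndarray:
    """Propagate the cohort: row k+1 = row k @ M_k.

    Returns the occupancy trace of shape (H+1, n_states). Probability
    conservation is asserted to 1e-10 at every cycle.
    """
    initial = np.asarray(initial, dtype=float)
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim != 3 or matrices.shape[1] != matrices.shape[2]:
        raise ValueError("matrices must have shape (H, n, n)")
    n = matrices.shape[1]
    if initial.shape != (n,):
        raise ValueError(f"initial distribution must have length {n}")
    if abs(initial.sum() - 1.0) > 1e-10:
        raise ValueError("initial distribution must sum to 1")
    H = matrices.shape[0]
    trace = np.empty((H + 1, n))
    trace[0] = initial
    for k in range(H):
        trace[k + 1] = trace[k] @ matrices[k]
        if abs(trace[k + 1].sum() - 1.0) > 1e-10:
            raise ValueError(f"probability mass not conserved at cycle {k + 1}")
    return trace


def half_cycle_effective_occupancy(trace: np.ndarray,
                                   enabled: bool = True) -> np.ndarray:
    """Per-cycle occupancy used for payoffs.

    With the half-cycle correction on, cycle k uses the trapezoidal
    average of the occupancy at its start and end; off, it uses the
    start-of-cycle occupancy. Shape (H, n_states); rows still sum to 1.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[0] < 2:
        raise ValueError("trace must have at least two rows")
    if enabled:
        return 0.5 * (trace[:-1] + trace[1:])
    return trace[:-1].copy()


def discount_factor(k: int, annual_rate: float) -> float:
    """Monthly-cycle discount factor (1 + r)^(-k/12)."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    if k < 0:
        raise ValueError("cycle index must be non-negative")
    return float((1.0 + annual_rate) ** (-k / 12.0))


def discount_factors(n_cycles: int, annual_rate: float) -> np.ndarray:
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    k = np.arange(n_cycles, dtype=float)
    return (1.0 + annual_rate) ** (-k / 12.0)


def microsim_oracle(initial: np.ndarray, matrices: np.ndarray,
                    n_individuals: int, seed: int) -> np.ndarray:
    """Individual-level Monte-Carlo occupancy (validation oracle).

    Simulates ``n_individuals`` independent trajectories through the
    per-cycle matrices and returns the empirical occupancy trace with the
    same shape as :func:`run_cohort`. Intended for small instances in
    tests only.
    """
    initial = np.asarray(initial, dtype=float)
    matrices = np.asarray(matrices, dtype=float)
    rng = np.random.default_rng(seed)
    H, n, _ = matrices.shape
    cum = np.cumsum(matrices, axis=2)
    state = rng.choice(n, size=n_individuals, p=initial)
    trace = np.empty((H + 1, n))
    trace[0] = np.bincount(state, minlength=n) / n_individuals
    for k in range(H):
        u = rng.random(n_individuals)
        state = (cum[k][state] < u[:, None]).sum(axis=1)
        trace[k + 1] = np.bincount(state, minlength=n) / n_individuals
    return trace


def trace_to_frame(trace: np.ndarray, space: StateSpace | None = None) -> pd.DataFrame:
    space = space or StateSpace()
    return pd.DataFrame(trace, columns=list(space.names))
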