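"""Mixture-cure parametric survival models and extrapolation utilities.

The disease-free survival of a cohort with a cured fraction is modelled as

    S(t) = pi + (1 - pi) * S_latent(t)

where ``pi`` is the cure fraction (patients immune to the disease event,
though still subject to background mortality, which is handled at the
model-assembly layer) and ``S_latent`` is a standard parametric survival
distribution for the uncured. Four latent families are supported:
exponential, Weibull, log-normal and log-logistic.

Fitted curves are converted to per-cycle transition probabilities, the
relative treatment effect can be waned between two timepoints, and a
life table supplies the background all-cause mortality floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ParametricFamily",
    "MixtureCureModel",
    "MixtureCureResults",
    "WaningSchedule",
    "LifeTable",
    "FAMILY_PARAM_NAMES",
    "mixture_cure_survival",
    "negative_log_likelihood",
    "fit_mixture_cure",
    "rank_by_information_criteria",
    "survival_to_cycle_prob",
    "effective_hazard_ratio",
    "blend_background_mortality",
]

# canonical family order; also the documented final tie-break in ranking
FAMILY_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "lognormal": ("meanlog", "sdlog"),
    "loglogistic": ("shape", "scale"),
}


def _frozen(name: str, params: Sequence[float]):
    """scipy frozen distribution for a latent family."""
    p = tuple(float(v) for v in params)
    if name == "exponential":
        (rate,) = p
        return stats.expon(scale=1.0 / rate)
    if name == "weibull":
        shape, scale = p
        return stats.weibull_min(c=shape, scale=scale)
    if name == "lognormal":
        meanlog, sdlog = p
        return stats.lognorm(s=sdlog, scale=math.exp(meanlog))
    if name == "loglogistic":
        shape, scale = p
        return stats.fisk(c=shape, scale=scale)
    raise ValueError(f"unknown parametric family {name!r}")


@dataclass(frozen=True)
class ParametricFamily:
    """A named parametric survival distribution with positive support.

    ``params`` follow the field conventions: exponential ``(rate,)``,
    Weibull ``(shape, scale)``, log-normal ``(meanlog, sdlog)``,
    log-logistic ``(shape, scale)``. ``meanlog`` may be any real; every
    other parameter must be strictly positive.
    """

    name: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.name not in FAMILY_PARAM_NAMES:
            raise ValueError(f"unknown parametric family {self.name!r}")
        expected = FAMILY_PARAM_NAMES[self.name]
        if len(self.params) != len(expected):
            raise ValueError(
                f"{self.name} expects {len(expected)} parameters "
                f"{expected}, got {len(self.params)}"
            )
        for pname, value in zip(expected, self.params):
            if pname != "meanlog" and value <= 0:
                raise ValueError(f"{self.name} parameter {pname} must be > 0")
            if not np.isfinite(value):
                raise ValueError(f"{self.name} parameter {pname} not finite")

    @property
    def n_params(self) -> int:
        return len(self.params)

    def sf(self, t):
        return _frozen(self.name, self.params).sf(t)

    def logpdf(self, t):
        return _frozen(self.name, self.params).logpdf(t)


def mixture_cure_survival(t, cure_fraction: float, latent: ParametricFamily):
    """S(t) = pi + (1 - pi) * S_latent(t); vectorised over ``t``.

    Bounded in [pi, 1], equal to 1 at t = 0, with plateau pi as t -> inf.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival time must be non-negative")
    if not 0.0 <= cure_fraction <= 1.0:
        raise ValueError("cure fraction must lie in [0, 1]")
    out = cure_fraction + (1.0 - cure_fraction) * latent.sf(t)
    return float(out) if out.ndim == 0 else out


def negative_log_likelihood(
    time: np.ndarray,
    event: np.ndarray,
    cure_fraction: float,
    latent: ParametricFamily,
) -> float:
    """Mixture-cure negative log-likelihood.

    An observed event at ``t`` contributes ``-log[(1-pi) f_latent(t)]``
    (a cured subject can never experience the event); a censored record
    contributes ``-log[pi + (1-pi) S_latent(t)]``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        return 0.0
    if np.any(time <= 0):
        raise ValueError("event/censoring times must be strictly positive")
    nll = 0.0
    ev = event == 1
    if ev.any():
        if cure_fraction >= 1.0:
            return math.inf  # events are impossible in a fully cured cohort
        logf = latent.logpdf(time[ev])
        if not np.all(np.isfinite(logf)):
            bad = int(np.flatnonzero(~np.isfinite(logf))[0])
            raise ValueError(
                f"latent density not finite at event time {time[ev][bad]:g}"
            )
        nll -= float(np.sum(math.log(1.0 - cure_fraction) + logf))
    if (~ev).any():
        s = cure_fraction + (1.0 - cure_fraction) * latent.sf(time[~ev])
        nll -= float(np.sum(np.log(s)))
    return nll


@dataclass
class MixtureCureResults:
    """MLE of a mixture-cure model, statsmodels-results style."""

    family: str
    cure_fraction: float
    latent: ParametricFamily
    loglik: float
    n: int
    converged: bool
    boundary: bool  # cure fraction at 0 or 1

    @property
    def k(self) -> int:
        """Number of free parameters: cure fraction + latent parameters."""
        return 1 + self.latent.n_params

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2 * self.loglik

    def sf(self, t):
        """Fitted mixture survival function."""
        return mixture_cure_survival(t, self.cure_fraction, self.latent)

    def summary(self) -> pd.DataFrame:
        rows = {"cure_fraction": self.cure_fraction}
        for pname, v in zip(FAMILY_PARAM_NAMES[self.family], self.latent.params):
            rows[pname] = v
        rows.update(
            loglik=self.loglik, aic=self.aic, bic=self.bic,
            n=self.n, converged=self.converged, boundary=self.boundary,
        )
        return pd.DataFrame({"value": rows})

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "cure_fraction": float(self.cure_fraction),
            "params": {
                p: float(v)
                for p, v in zip(FAMILY_PARAM_NAMES[self.family], self.latent.params)
            },
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "n": int(self.n),
        }


class MixtureCureModel:
    """Maximum-likelihood mixture-cure model for right-censored times.

    Parameters
    ----------
    time : array of strictly positive event/censoring times (months)
    event : array of {0, 1}; 1 = invasive-disease event or death observed

    ``fit(family=...)`` maximises the mixture likelihood with a bounded
    multistart over the cure fraction (starts 0.1 / 0.5 / 0.9, fixed) so
    that refitting identical data reproduces identical estimates.
    """

    #: multistart grid for the cure fraction (fixed for determinism)
    PI_STARTS = (0.1, 0.5, 0.9)
    #: convergence tolerance on the objective
    FTOL = 1e-8

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if time.size and np.any(time <= 0):
            raise ValueError("times must be strictly positive")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        self.time = time
        self.event = event

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, arm: str | None = None,
                       time_col: str = "time", event_col: str = "event",
                       arm_col: str = "arm") -> "MixtureCureModel":
        if arm is not None:
            df = df[df[arm_col] == arm]
            if df.empty:
                raise ValueError(f"no records for arm {arm!r}")
        return cls(df[time_col].to_numpy(), df[event_col].to_numpy())

    # ---- internal parametrisation: theta = (pi, log-params...) -------

    def _latent_starts(self, family: str) -> list[np.ndarray]:
        """Data-driven starting values on the log scale (meanlog raw)."""
        t_ev = self.time[self.event == 1]
        ref = t_ev if t_ev.size >= 2 else self.time
        m = float(np.mean(np.log(ref)))
        s = float(np.std(np.log(ref)))
        s = max(s, 0.1)
        if family == "exponential":
            rate = max(len(t_ev), 1) / float(np.sum(self.time))
            return [np.array([math.log(rate)])]
        if family == "lognormal":
            return [np.array([m, math.log(s)])]
        # weibull / loglogistic: shape ~ 1/s (log-scale spread), scale ~ exp(m)
        return [np.array([math.log(max(1.0 / s, 0.2)), m])]

    def _unpack(self, family: str, theta: np.ndarray) -> tuple[float, ParametricFamily]:
        pi = float(theta[0])
        raw = theta[1:]
        if family == "exponential":
            params = (math.exp(raw[0]),)
        elif family == "lognormal":
            params = (raw[0], math.exp(raw[1]))
        else:
            params = (math.exp(raw[0]), math.exp(raw[1]))
        return pi, ParametricFamily(family, params)

    def _objective(self, family: str):
        def fun(theta: np.ndarray) -> float:
            pi = min(max(float(theta[0]), 0.0), 1.0)
            try:
                # extreme trial parameters overflow harmlessly to -inf
                # log-densities; the guard below rejects them
                with np.errstate(over="ignore", invalid="ignore",
                                 divide="ignore"):
                    _, latent = self._unpack(
                        family, np.concatenate(([pi], theta[1:]))
                    )
                    val = negative_log_likelihood(
                        self.time, self.event, pi, latent
                    )
            except (ValueError, OverflowError):
                return 1e12
            return val if np.isfinite(val) else 1e12
        return fun

    def fit(self, family: str = "lognormal") -> MixtureCureResults:
        if family not in FAMILY_PARAM_NAMES:
            raise ValueError(f"unknown parametric family {family!r}")
        n_events = int(self.event.sum())
        if n_events == 0:
            # no events: likelihood is maximised at the pi = 1 boundary
            latent = ParametricFamily(family, self._default_latent(family))
            ll = -negative_log_likelihood(self.time, self.event, 1.0, latent)
            return MixtureCureResults(family, 1.0, latent, ll, self.time.size,
                                      converged=True, boundary=True)
        if len(np.unique(self.time[self.event == 1])) < 2 and \
                len(FAMILY_PARAM_NAMES[family]) > 1:
            raise ValueError(
                f"need >= 2 distinct event times to identify a "
                f"{family} latent distribution"
            )
        fun = self._objective(family)
        # events observed => pi strictly below 1; keep a hair inside the box
        eps = 1e-9
        n_latent = len(FAMILY_PARAM_NAMES[family])
        bounds = [(eps, 1.0 - eps)] + [(-20.0, 20.0)] * n_latent
        best = None
        for pi0 in self.PI_STARTS:
            for lat0 in self._latent_starts(family):
                theta0 = np.concatenate(([pi0], lat0))
                res = optimize.minimize(
                    fun, theta0, method="L-BFGS-B", bounds=bounds,
                    options={"ftol": self.FTOL, "maxiter": 500},
                )
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"mixture-cure fit failed for family {family!r}")
        if not best.success and best.fun >= 1e12:
            raise RuntimeError(
                f"optimizer did not converge for {family}: {best.message}"
            )
        pi_hat, latent = self._unpack(family, best.x)
        boundary = pi_hat <= 1e-6 or pi_hat >= 1.0 - 1e-6
        return MixtureCureResults(
            family=family, cure_fraction=pi_hat, latent=latent,
            loglik=-float(best.fun), n=self.time.size,
            converged=bool(best.success), boundary=boundary,
        )

    def fit_all(self) -> list[MixtureCureResults]:
        """Fit all four latent families to the same data."""
        return [self.fit(f) for f in FAMILY_PARAM_NAMES]

    @staticmethod
    def _default_latent(family: str) -> tuple[float, ...]:
        return {"exponential": (0.05,), "weibull": (1.0, 20.0),
                "lognormal": (3.0, 1.0), "loglogistic": (1.0, 20.0)}[family]


def fit_mixture_cure(time, event, family: str = "lognormal") -> MixtureCureResults:
    """Functional wrapper around :class:`MixtureCureModel`."""
    return MixtureCureModel(time, event).fit(family)


def rank_by_information_criteria(
    fits: Sequence[MixtureCureResults],
) -> tuple[list[MixtureCureResults], MixtureCureResults, pd.DataFrame]:
    """Rank candidate fits by AIC (BIC reported alongside).

    All fits must be on the same data (same n). Ties in AIC are broken by
    fewer parameters, then by the canonical family order
    exponential < weibull < lognormal < loglogistic.

    Returns (ranked fits, selected fit, comparison table).
    """
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits computed on different sample sizes: {sorted(ns)}")
    order = list(FAMILY_PARAM_NAMES)

    def key(f: MixtureCureResults):
        return (f.aic, f.k, order.index(f.family))

    ranked = sorted(fits, key=key)
    table = pd.DataFrame(
        {
            "family": [f.family for f in ranked],
            "k": [f.k for f in ranked],
            "loglik": [f.loglik for f in ranked],
            "aic": [f.aic for f in ranked],
            "bic": [f.bic for f in ranked],
        }
    )
    table["bic_rank"] = table["bic"].rank(method="first").astype(int)
    return ranked, ranked[0], table


def survival_to_cycle_prob(sf, k: int, delta: float = 1.0) -> float:
    """Per-cycle event probability ``1 - S((k+1)d) / S(kd)``.

    ``sf`` is a survival callable (months -> probability). Raises when the
    curve has already hit zero at the cycle start (cohort exhausted).
    """
    if k < 0:
        raise ValueError("cycle index must be non-negative")
    s0 = float(sf(k * delta))
    if s0 <= 0.0:
        raise ValueError(f"survival is zero at cycle {k}; cohort exhausted")
    p = 1.0 - float(sf((k + 1) * delta)) / s0
    return min(max(p, 0.0), 1.0)


@dataclass(frozen=True)
class WaningSchedule:
    """Treatment-effect waning window.

    The full relative effect (hazard ratio) applies up to ``t_full``
    months, no effect remains from ``t_none`` months, and in between the
    hazard ratio is interpolated toward 1 — log-linearly by default
    (``shape='log-linear'``), or linearly in the HR (``shape='linear'``).
    """

    t_full: float = 84.0
    t_none: float = 120.0
    shape: str = "log-linear"

    def __post_init__(self) -> None:
        if not self.t_full < self.t_none:
            raise ValueError("t_full must be < t_none")
        if self.shape not in ("log-linear", "linear"):
            raise ValueError("waning shape must be 'log-linear' or 'linear'")


def effective_hazard_ratio(hr: float, t: float, schedule: WaningSchedule) -> float:
    """Hazard ratio in force at time ``t`` months under a waning schedule.

    Continuous in ``t``, equal to ``hr`` for t <= t_full and exactly 1 for
    t >= t_none.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be strictly positive")
    if t <= schedule.t_full:
        return float(hr)
    if t >= schedule.t_none:
        return 1.0
    w = (schedule.t_none - t) / (schedule.t_none - schedule.t_full)
    if schedule.shape == "log-linear":
        return float(math.exp(w * math.log(hr)))
    return float(1.0 + w * (hr - 1.0))


class LifeTable:
    """Annual all-cause mortality probabilities by integer age (0..100)."""

    def __init__(self, ages, annual_q):
        ages = np.asarray(ages, dtype=int)
        annual_q = np.asarray(annual_q, dtype=float)
        if ages.shape != annual_q.shape or ages.ndim != 1:
            raise ValueError("ages and annual_q must be 1-d and equal length")
        if np.any((annual_q < 0) | (annual_q > 1)):
            raise ValueError("annual mortality probabilities must be in [0, 1]")
        order = np.argsort(ages)
        self.ages = ages[order]
        self.annual_q = annual_q[order]
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("ages must be consecutive integers")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual(self, age: float) -> float:
        """Annual probability for the attained (floored) age."""
        a = int(math.floor(age))
        if a < self.ages[0] or a > self.max_age:
            raise ValueError(f"age {age:g} outside life table range "
                             f"[{self.ages[0]}, {self.max_age}]")
        return float(self.annual_q[a - self.ages[0]])

    def monthly(self, age: float) -> float:
        """Monthly probability via 1 - (1 - q)^(1/12)."""
        return 1.0 - (1.0 - self.annual(age)) ** (1.0 / 12.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "annual_q": self.annual_q})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["annual_q"].to_numpy())


def blend_background_mortality(
    disease_probs: np.ndarray,
    life_table: LifeTable,
    baseline_age: float = 52.0,
) -> np.ndarray:
    """Combine per-cycle disease event probabilities with background death.

    Independent competing-risks combination 1 - (1-p_disease)(1-q_month),
    where q_month is the monthly background probability at the age
    attained in cycle k (baseline_age + k/12). Result is elementwise at
    least the background probability.
    """
    disease_probs = np.asarray(disease_probs, dtype=float)
    out = np.empty_like(disease_probs)
    for k, p in enumerate(disease_probs):
        q = life_table.monthly(baseline_age + k / 12.0)
        out[k] = 1.0 - (1.0 - p) * (1.0 - q)
    return out
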