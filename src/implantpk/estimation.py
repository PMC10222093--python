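"""Nonlinear least-squares fitting of release models to implant data.

Observations come in two flavours: *amount* observations (mean cumulative
released amount in mg, derived from residual drug assayed in explanted
devices) and *rate* observations (release rates in mg/day, e.g. from a
product label).  Both are fitted jointly; the objective is

    SSE = Σ (q_i − Q(t_i))² + w · Σ (r_j − dQ/dt(t_j))²

where ``w`` (``rate_weight``) rescales the rate residuals.  The default
``w = (mean amount / mean rate)²`` makes one rate point contribute
comparably to one amount point after scale normalisation.

Goodness of fit is summarised by the adjusted coefficient of determination

    R²    = 1 − SSE/SST
    R²adj = 1 − (1 − R²)(n − 1)/(n − p − 1)

with SST computed from deviations of the *amount* observations about their
mean only (rate observations are auxiliary: they enter SSE but not SST).

Parameter uncertainty is linearised (Wald): cov = σ̂²(JᵀJ)⁻¹ with
σ̂² = SSE/(n − p) and J the residual Jacobian at the optimum, intervals
using Student-t quantiles.  Poorly identified parameters (as is typical for
biexponential fits to sparse implant data) legitimately produce intervals
spanning negative values; these are flagged, not suppressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .release_models import (
    FamilyLike,
    ImplantSpec,
    ModelFamily,
    ParameterSet,
    cumulative_release,
    get_family,
    release_rate,
)

__all__ = [
    "ObservationSet",
    "FitOptions",
    "FitResult",
    "objective_sse",
    "fit_release_model",
    "adjusted_r_squared",
    "parameter_cis",
    "prediction_band",
    "compare_models",
]

_PENALTY = 1e8  # residual magnitude substituted for non-finite model output


@dataclass(frozen=True)
class ObservationSet:
    """Released-amount and release-rate observations on a day time base."""

    implant: ImplantSpec
    amount_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    amount_q: np.ndarray = field(default_factory=lambda: np.empty(0))
    amount_se: Optional[np.ndarray] = None
    amount_n: Optional[np.ndarray] = None
    rate_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    rate_r: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        for name in ("amount_t", "amount_q", "rate_t", "rate_r"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("amount_se", "amount_n"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        if self.amount_t.shape != self.amount_q.shape:
            raise ValueError("amount_t and amount_q must have equal length")
        if self.rate_t.shape != self.rate_r.shape:
            raise ValueError("rate_t and rate_r must have equal length")
        if (self.amount_t < 0).any() or (self.rate_t < 0).any():
            raise ValueError("observation times must be non-negative")
        if (self.amount_q < 0).any() or (self.amount_q > self.implant.dose_loaded).any():
            raise ValueError("amounts must lie in [0, dose_loaded]")
        if (self.rate_r < 0).any():
            raise ValueError("rates must be non-negative")

    @property
    def n_amount(self) -> int:
        return self.amount_t.size

    @property
    def n_rate(self) -> int:
        return self.rate_t.size

    @property
    def n_obs(self) -> int:
        return self.n_amount + self.n_rate

    @property
    def t_max(self) -> float:
        times = np.concatenate([self.amount_t, self.rate_t])
        return float(times.max()) if times.size else 0.0

    def fingerprint(self) -> int:
        """Stable identity of the numeric content, for cross-fit checks."""
        payload = np.concatenate(
            [self.amount_t, self.amount_q, self.rate_t, self.rate_r]
        ).tobytes()
        return hash((payload, self.implant.dose_loaded))


@dataclass(frozen=True)
class FitOptions:
    """Options controlling :func:`fit_release_model`.

    ``starting_values``/``bounds`` map parameter names to overrides of the
    automatic, data-scaled defaults.  ``fixed`` pins parameters at given
    values and removes them from the free set (e.g. Dose = 150 for the
    biexponential family).  ``rate_weight`` is the relative weight of rate
    observations; ``"auto"`` matches scales as described in the module
    docstring.
    """

    starting_values: Union[str, Mapping[str, float]] = "auto"
    bounds: Optional[Mapping[str, tuple[float, float]]] = None
    fixed: Mapping[str, float] = field(default_factory=dict)
    rate_weight: Union[str, float] = "auto"
    max_evaluations: int = 20000
    tol: float = 1e-10
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if not isinstance(self.rate_weight, str) and self.rate_weight < 0:
            raise ValueError("rate_weight must be >= 0")
        object.__setattr__(self, "fixed", dict(self.fixed))


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit."""

    family_id: str
    estimates: ParameterSet
    free_names: tuple[str, ...]
    se: dict[str, float]
    ci: dict[str, tuple[float, float]]
    sse: float
    sst: float
    r2: float
    adjusted_r2: float
    n_obs: int
    n_params: int
    covariance: np.ndarray
    sigma2: float
    converged: bool
    message: str
    rate_weight_used: float
    options: FitOptions
    obs_fingerprint: int
    covariance_singular: bool = False

    @property
    def df(self) -> int:
        return self.n_obs - self.n_params

    def to_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "estimates": self.estimates.to_dict(),
            "free_parameters": list(self.free_names),
            "se": self.se,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "sse": self.sse,
            "sst": self.sst,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "message": self.message,
            "rate_weight_used": self.rate_weight_used,
            "covariance": np.asarray(self.covariance).tolist(),
            "covariance_singular": self.covariance_singular,
            "options": {
                "starting_values": self.options.starting_values
                if isinstance(self.options.starting_values, str)
                else dict(self.options.starting_values),
                "bounds": None
                if self.options.bounds is None
                else {k: list(v) for k, v in self.options.bounds.items()},
                "fixed": dict(self.options.fixed),
                "rate_weight": self.options.rate_weight,
                "max_evaluations": self.options.max_evaluations,
                "tol": self.options.tol,
                "ci_level": self.options.ci_level,
            },
        }


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _resolve_rate_weight(obs: ObservationSet, rate_weight) -> float:
    if isinstance(rate_weight, str):
        if rate_weight != "auto":
            raise ValueError("rate_weight must be a number or 'auto'")
        if obs.n_rate == 0 or obs.n_amount == 0:
            return 1.0
        mean_q = float(np.mean(np.abs(obs.amount_q)))
        mean_r = float(np.mean(np.abs(obs.rate_r)))
        if mean_q == 0 or mean_r == 0:
            return 1.0
        return (mean_q / mean_r) ** 2
    return float(rate_weight)


def objective_sse(
    family: FamilyLike,
    params: Union[ParameterSet, Mapping[str, float]],
    obs: ObservationSet,
    rate_weight: Union[str, float] = "auto",
) -> float:
    """Weighted sum of squared residuals over amount and rate observations.

    Invalid parameter values (outside the family's domain, non-finite model
    output) yield +inf so the objective is safe inside an optimizer.
    """
    if obs.n_obs == 0:
        raise ValueError("observation set is empty")
    fam = get_family(family)
    w = _resolve_rate_weight(obs, rate_weight)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sse = 0.0
            if obs.n_amount:
                q = cumulative_release(fam, params, obs.amount_t)
                sse += float(np.sum((obs.amount_q - q) ** 2))
            if obs.n_rate and w > 0:
                r = release_rate(fam, params, obs.rate_t)
                sse += w * float(np.sum((obs.rate_r - r) ** 2))
    except (ValueError, FloatingPointError):
        return np.inf
    return sse if np.isfinite(sse) else np.inf


# ---------------------------------------------------------------------------
# automatic starts and bounds
# ---------------------------------------------------------------------------

def _auto_start(fam: ModelFamily, obs: ObservationSet, name: str, kind: str) -> float:
    dose = obs.implant.dose_loaded
    t_max = obs.t_max or 1.0
    if kind == "amount":
        return 0.5 * dose
    if kind == "rate":
        return 1.0 / t_max
    if kind == "exponent":
        return 0.5
    if kind == "inv_amount_rate":  # second-order k2, units 1/(mg·day)
        return 1.0 / (t_max * 0.5 * dose)
    if kind == "cuberoot_rate":  # Hixson-Crowell khc: depletion near t_max
        return (0.5 * dose) ** (1.0 / 3.0) / t_max
    # coeff: scale so the power law reaches half the dose at t_max
    expo = {"k": 1.0, "kh": 0.45, "kkp": 0.5, "kps1": 0.5, "kps2": 1.0}.get(name, 0.5)
    return 0.5 * dose / t_max**expo


def _auto_bounds(fam: ModelFamily, obs: ObservationSet, kind: str) -> tuple[float, float]:
    dose = obs.implant.dose_loaded
    if kind == "amount":
        return (1e-9, dose)
    if kind == "rate":
        return (1e-7, 1.0)
    if kind == "exponent":
        return (1e-2, 5.0)
    if kind == "inv_amount_rate":
        return (1e-10, 1.0)
    if kind == "cuberoot_rate":
        return (1e-7, 10.0)
    return (1e-12, 10.0 * dose)


def _stagger_rate_starts(fam: ModelFamily, start: dict[str, float]) -> None:
    # two identical exponential rate constants start indistinguishable; spread
    # them a factor of 3 either side so the optimizer can separate the phases
    rate_names = [
        n for n, k in zip(fam.parameter_names, fam.parameter_kinds) if k == "rate"
    ]
    if len(rate_names) == 2:
        start[rate_names[0]] *= 3.0
        start[rate_names[1]] /= 3.0


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_release_model(
    obs: ObservationSet,
    family: FamilyLike,
    options: Optional[FitOptions] = None,
) -> FitResult:
    """Fit one model family to an observation set by bounded least squares.

    Uses a trust-region-reflective solver within data-scaled bounds; the
    result is deterministic for identical inputs and options.
    Non-convergence is reported through ``FitResult.converged`` rather than
    an exception.
    """
    fam = get_family(family)
    options = options or FitOptions()
    unknown = set(options.fixed) - set(fam.parameter_names)
    if unknown:
        raise ValueError(f"fixed parameters {sorted(unknown)} not in family {fam.family_id}")
    free = tuple(n for n in fam.parameter_names if n not in options.fixed)
    n_free = len(free)
    if n_free == 0:
        raise ValueError("no free parameters to fit")
    if obs.n_obs - n_free < 1:
        raise ValueError(
            f"need at least {n_free + 1} observations to fit {fam.family_id}, "
            f"got {obs.n_obs}"
        )
    w = _resolve_rate_weight(obs, options.rate_weight)
    sqrt_w = np.sqrt(w)

    kinds = dict(zip(fam.parameter_names, fam.parameter_kinds))
    start = {n: _auto_start(fam, obs, n, kinds[n]) for n in free}
    if isinstance(options.starting_values, Mapping):
        start.update({k: float(v) for k, v in options.starting_values.items() if k in start})
    else:
        _stagger_rate_starts(fam, start)
    bounds = {n: _auto_bounds(fam, obs, kinds[n]) for n in free}
    if options.bounds:
        bounds.update({k: tuple(v) for k, v in options.bounds.items() if k in bounds})

    lower = np.array([bounds[n][0] for n in free])
    upper = np.array([bounds[n][1] for n in free])
    p0 = np.clip(np.array([start[n] for n in free]), lower, upper)

    def assemble(theta: np.ndarray) -> dict[str, float]:
        vals = dict(options.fixed)
        vals.update(zip(free, theta))
        return vals

    def residuals(theta: np.ndarray) -> np.ndarray:
        vals = assemble(theta)
        out = np.empty(obs.n_obs)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if obs.n_amount:
                    q = fam._cumulative(obs.amount_t, *(vals[n] for n in fam.parameter_names))
                    out[: obs.n_amount] = q - obs.amount_q
                if obs.n_rate:
                    r = fam._rate(obs.rate_t, *(vals[n] for n in fam.parameter_names))
                    out[obs.n_amount :] = sqrt_w * (r - obs.rate_r)
        except (ValueError, FloatingPointError):
            return np.full(obs.n_obs, _PENALTY)
        return np.nan_to_num(out, nan=_PENALTY, posinf=_PENALTY, neginf=-_PENALTY)

    res = optimize.least_squares(
        residuals,
        p0,
        bounds=(lower, upper),
        method="trf",
        ftol=options.tol,
        xtol=options.tol,
        gtol=options.tol,
        max_nfev=options.max_evaluations,
    )
    converged = bool(res.status > 0)
    estimates = ParameterSet(fam.family_id, assemble(res.x))
    sse = float(2.0 * res.cost)

    # goodness of fit: SST about the mean of the amount observations
    if obs.n_amount >= 2:
        sst = float(np.sum((obs.amount_q - obs.amount_q.mean()) ** 2))
    else:
        sst = np.nan
    r2 = 1.0 - sse / sst if sst and np.isfinite(sst) and sst > 0 else np.nan
    if np.isfinite(r2) and obs.n_obs - n_free - 1 >= 1:
        adj = adjusted_r_squared(sse, sst, obs.n_obs, n_free)
    else:
        adj = np.nan

    # linearised covariance
    dof = obs.n_obs - n_free
    sigma2 = sse / dof
    J = res.jac
    JtJ = J.T @ J
    singular = False
    try:
        cov_unit = np.linalg.inv(JtJ)
        if not np.all(np.isfinite(cov_unit)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov_unit = np.linalg.pinv(JtJ)
        singular = True
    cov = sigma2 * cov_unit
    se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    tq = stats.t.ppf(0.5 + options.ci_level / 2.0, dof)
    se = dict(zip(free, se_vec))
    ci = {
        n: (float(estimates[n] - tq * se[n]), float(estimates[n] + tq * se[n]))
        for n in free
    }

    return FitResult(
        family_id=fam.family_id,
        estimates=estimates,
        free_names=free,
        se={k: float(v) for k, v in se.items()},
        ci=ci,
        sse=sse,
        sst=sst,
        r2=float(r2) if np.isfinite(r2) else np.nan,
        adjusted_r2=float(adj) if np.isfinite(adj) else np.nan,
        n_obs=obs.n_obs,
        n_params=n_free,
        covariance=cov,
        sigma2=sigma2,
        converged=converged,
        message=res.message,
        rate_weight_used=w,
        options=options,
        obs_fingerprint=obs.fingerprint(),
        covariance_singular=singular,
    )


def adjusted_r_squared(sse: float, sst: float, n_obs: int, n_params: int) -> float:
    """Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    if sst <= 0:
        raise ValueError("sst must be positive")
    if n_params > 0 and n_obs - n_params - 1 < 1:
        raise ValueError("need n_obs - n_params - 1 >= 1 for the adjustment")
    r2 = 1.0 - sse / sst
    if n_params == 0:
        return r2
    return 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - n_params - 1)


def parameter_cis(
    fit: FitResult, level: float = 0.95
) -> dict[str, tuple[float, float]]:
    """Wald-type confidence intervals at ``level`` from the fit covariance."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    tq = stats.t.ppf(0.5 + level / 2.0, fit.df)
    return {
        n: (
            float(fit.estimates[n] - tq * fit.se[n]),
            float(fit.estimates[n] + tq * fit.se[n]),
        )
        for n in fit.free_names
    }


def _gradient(fit: FitResult, times: np.ndarray) -> np.ndarray:
    """Finite-difference gradient of Q(t) w.r.t. the free parameters."""
    fam = get_family(fit.family_id)
    base = dict(fit.estimates.values)
    g = np.empty((times.size, len(fit.free_names)))
    for j, name in enumerate(fit.free_names):
        h = max(abs(base[name]) * 1e-6, 1e-10)
        hi = dict(base)
        lo = dict(base)
        hi[name] = base[name] + h
        lo[name] = max(base[name] - h, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            qh = fam._cumulative(times, *(hi[n] for n in fam.parameter_names))
            ql = fam._cumulative(times, *(lo[n] for n in fam.parameter_names))
        g[:, j] = (qh - ql) / (hi[name] - lo[name])
    return g


def prediction_band(
    fit: FitResult, times: Sequence[float], level: float = 0.95
) -> pd.DataFrame:
    """Delta-method 95% (by default) prediction band for future amounts.

    Half-width at time t is t-quantile × sqrt(σ̂² + gᵀ C g), the residual
    variance plus the parameter-uncertainty contribution; the band widens
    outside the fitted time range as the gradient grows.
    """
    t = np.asarray(times, dtype=float)
    fam = get_family(fit.family_id)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qhat = fam._cumulative(
            t, *(fit.estimates[n] for n in fam.parameter_names)
        )
    g = _gradient(fit, t)
    var = fit.sigma2 + np.einsum("ij,jk,ik->i", g, fit.covariance, g)
    tq = stats.t.ppf(0.5 + level / 2.0, fit.df)
    half = tq * np.sqrt(np.clip(var, 0.0, None))
    return pd.DataFrame(
        {"time": t, "predicted": qhat, "lower": qhat - half, "upper": qhat + half}
    )


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits of the same dataset by adjusted R².

    Descending adjusted R²; ties broken in favour of fewer parameters;
    non-converged fits sink to the bottom and are flagged.
    """
    if not fits:
        raise ValueError("no fits to compare")
    fps = {f.obs_fingerprint for f in fits}
    if len(fps) > 1:
        raise ValueError("fits were made on different observation sets")
    rows = pd.DataFrame(
        {
            "family_id": [f.family_id for f in fits],
            "adjusted_r2": [f.adjusted_r2 for f in fits],
            "r2": [f.r2 for f in fits],
            "sse": [f.sse for f in fits],
            "n_params": [f.n_params for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    rows["_adj"] = rows["adjusted_r2"].fillna(-np.inf)
    rows = rows.sort_values(
        by=["converged", "_adj", "n_params"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_adj")
    rows.insert(0, "rank", np.arange(1, len(rows) + 1))
    return rows.reset_index(drop=True)
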