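"""Seeded synthetic datasets emulating implant release studies.

Three kinds of observations feed the analysis, and each has a generator:

* device-removal ("ex vivo") studies: implants are explanted from a few
  subjects at scheduled visits and the residual drug assayed, giving a
  mean released amount, SE and device count per time point;
* label release rates: piecewise rates stated at a few months of wear
  (e.g. 0.1 mg/day at month 1, 0.04 at month 12, 0.03 from month 24);
* sparse plasma concentration points with proportional assay error.

The default sampling design — 13 visits (quarterly through year 1, then
semi-annual) over 1825 days with 5 devices per visit and 2 mg additive
noise on the residual amount — mimics the sparse multi-year designs of
published device-removal studies; it is an assumption of this package, not
a reproduction of any specific trial, and every element is configurable.

All randomness flows from a single integer seed through per-stream
``numpy`` generators, so identical configurations give identical data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .data_io import RateRecord
from .estimation import ObservationSet
from .pk import DispositionParams, simulate_concentration
from .release_models import (
    DAYS_PER_MONTH,
    FamilyLike,
    ImplantSpec,
    ParameterSet,
    cumulative_release,
    get_family,
    release_rate,
)

__all__ = [
    "DEFAULT_AMOUNT_TIMES",
    "DEFAULT_RATE_MONTHS",
    "SyntheticConfig",
    "generate_ex_vivo",
    "generate_label_rates",
    "generate_plasma_observations",
]

#: 13 visits over five years: quarterly through year 1, semi-annual after.
DEFAULT_AMOUNT_TIMES: tuple[float, ...] = (
    0.0, 91.0, 182.0, 274.0, 365.0, 548.0, 730.0,
    912.0, 1095.0, 1277.0, 1460.0, 1642.0, 1825.0,
)

#: Months at which label release rates are stated.
DEFAULT_RATE_MONTHS: tuple[float, ...] = (1.0, 12.0, 24.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """A complete description of one synthetic study.

    ``additive_sd`` (mg, on the residual amount per device) and
    ``proportional_cv`` (fraction of the remaining amount) are alternative
    noise models; set the unused one to 0/None.  ``rate_sd`` perturbs the
    label rates (mg/day).  The plasma block drives
    :func:`generate_plasma_observations`.
    """

    family: FamilyLike
    params: Union[ParameterSet, Mapping[str, float]]
    implant: ImplantSpec
    amount_times: Sequence[float] = DEFAULT_AMOUNT_TIMES
    n_implants_per_time: int = 5
    additive_sd: float = 2.0
    proportional_cv: Optional[float] = None
    rate_months: Sequence[float] = DEFAULT_RATE_MONTHS
    rate_sd: float = 0.0
    disposition: DispositionParams = field(default_factory=DispositionParams)
    plasma_times: Sequence[float] = tuple(np.arange(30.0, 1830.0, 90.0))
    plasma_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fam = get_family(self.family)
        if not isinstance(self.params, ParameterSet):
            object.__setattr__(self, "params", ParameterSet(fam.family_id, self.params))
        if self.n_implants_per_time < 1:
            raise ValueError("n_implants_per_time must be >= 1")
        if self.additive_sd < 0 or (self.proportional_cv or 0) < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.rate_sd < 0 or self.plasma_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        horizon = 2 * 1825.0
        if any(t < 0 or t > horizon for t in self.amount_times):
            raise ValueError(f"amount_times must lie in [0, {horizon}] days")

    @property
    def rate_times(self) -> np.ndarray:
        return np.asarray(self.rate_months, dtype=float) * DAYS_PER_MONTH


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator function
    return np.random.default_rng([config.seed, stream])


def generate_ex_vivo(config: SyntheticConfig) -> ObservationSet:
    """Simulate a device-removal study and summarise it per time point.

    At each visit, ``n_implants_per_time`` residual amounts are drawn as
    dose − Q_true(t) plus noise, truncated to [0, dose]; the reported
    observation is the mean *released* amount with SE = sd/√n.  With zero
    noise the means equal Q_true exactly.  If truncation affects more than
    half of all draws the noise model is inconsistent with the truth and a
    warning is issued.
    """
    rng = _rng(config, 1)
    dose = config.implant.dose_loaded
    times = np.asarray(config.amount_times, dtype=float)
    q_true = np.atleast_1d(cumulative_release(config.family, config.params, times))
    n = config.n_implants_per_time

    means = np.empty_like(times)
    ses = np.empty_like(times)
    n_truncated = 0
    for i, (t, q) in enumerate(zip(times, q_true)):
        remaining_true = dose - q
        if config.proportional_cv:
            noise = rng.normal(0.0, config.proportional_cv * remaining_true, size=n)
        else:
            noise = rng.normal(0.0, config.additive_sd, size=n) if config.additive_sd else np.zeros(n)
        draws = remaining_true + noise
        clipped = np.clip(draws, 0.0, dose)
        n_truncated += int(np.sum(clipped != draws))
        released = dose - clipped
        means[i] = released.mean()
        ses[i] = released.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    if n_truncated > 0.5 * times.size * n:
        warnings.warn(
            f"{n_truncated}/{times.size * n} draws truncated at [0, dose]: "
            "noise scale is inconsistent with the release curve",
            UserWarning,
            stacklevel=2,
        )
    return ObservationSet(
        implant=config.implant,
        amount_t=times,
        amount_q=means,
        amount_se=ses,
        amount_n=np.full(times.size, float(n)),
    )


def generate_label_rates(config: SyntheticConfig) -> list[RateRecord]:
    """Release rates at the configured label months (plus optional noise)."""
    rng = _rng(config, 2)
    times = config.rate_times
    rates = np.atleast_1d(release_rate(config.family, config.params, times))
    if config.rate_sd:
        rates = np.clip(rates + rng.normal(0.0, config.rate_sd, rates.size), 0.0, None)
    return [RateRecord(float(t), float(r)) for t, r in zip(times, rates)]


def generate_plasma_observations(
    config: SyntheticConfig,
) -> list[tuple[float, float, float]]:
    """Sparse plasma observations (t, conc, error) with proportional error.

    Concentrations are simulated at the true release parameters, then
    perturbed multiplicatively with CV ``plasma_cv``; the reported per-point
    error is CV × true concentration.  CV = 0 returns the profile exactly.
    """
    rng = _rng(config, 3)
    times = np.asarray(config.plasma_times, dtype=float)
    grid = np.union1d([0.0], times)
    profile = simulate_concentration(
        config.implant, config.family, config.params, config.disposition, grid
    )
    true_c = np.interp(times, profile.times, profile.conc)
    if config.plasma_cv:
        obs_c = np.clip(true_c * (1.0 + rng.normal(0.0, config.plasma_cv, times.size)), 0.0, None)
    else:
        obs_c = true_c.copy()
    errors = config.plasma_cv * true_c
    return [(float(t), float(c), float(e)) for t, c, e in zip(times, obs_c, errors)]
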