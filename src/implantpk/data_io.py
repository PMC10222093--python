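"""Readers, writers and conversions for implant release datasets.

Three observed representations of the same release process circulate in
this field and all are supported:

* *remaining* — residual drug assayed in an explanted device (mg);
* *amount*    — cumulative released amount (mg), i.e. loaded − remaining;
* *rate*      — instantaneous release rate (mg/day), e.g. label values
  such as 0.1 mg/day at month 1.

The on-disk format is a plain CSV with header
``time,time_unit,observation_type,value,se,n`` where ``time_unit`` is
``day`` or ``month`` (months convert at 30.44 days/month) and
``observation_type`` is ``amount``, ``rate`` or ``remaining``.  ``se`` and
``n`` may be empty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .estimation import FitResult, ObservationSet, compare_models
from .release_models import DAYS_PER_MONTH, ImplantSpec

__all__ = [
    "ExVivoRecord",
    "RateRecord",
    "residual_to_released",
    "released_to_residual",
    "rates_to_cumulative",
    "read_release_dataset",
    "write_observation_set",
    "write_fit_report",
    "read_fit_report",
]

_COLUMNS = ["time", "time_unit", "observation_type", "value", "se", "n"]
_UNIT_FACTORS = {"day": 1.0, "month": DAYS_PER_MONTH}
_OBS_TYPES = {"amount", "rate", "remaining"}


@dataclass(frozen=True)
class ExVivoRecord:
    """Residual drug measured in devices explanted at one time point."""

    t: float  # days since insertion
    remaining: float  # mg left in the device (mean over devices)
    n_implants: Optional[int] = None
    se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("time must be non-negative")
        if self.remaining < 0:
            raise ValueError("remaining amount must be non-negative")


@dataclass(frozen=True)
class RateRecord:
    """A stated release rate at one time point (e.g. a label value)."""

    t: float  # days
    rate: float  # mg/day

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.t < 0:
            raise ValueError("time must be non-negative")


def residual_to_released(implant: ImplantSpec, remaining: float) -> float:
    """Released amount = loaded dose − residual drug in the device."""
    if not 0.0 <= remaining <= implant.dose_loaded:
        raise ValueError(
            f"remaining amount {remaining} mg outside [0, {implant.dose_loaded}] mg "
            f"for implant {implant.name!r}"
        )
    return implant.dose_loaded - remaining


def released_to_residual(implant: ImplantSpec, released: float) -> float:
    """Inverse of :func:`residual_to_released`."""
    if not 0.0 <= released <= implant.dose_loaded:
        raise ValueError(
            f"released amount {released} mg outside [0, {implant.dose_loaded}] mg "
            f"for implant {implant.name!r}"
        )
    return implant.dose_loaded - released


def rates_to_cumulative(
    records: Sequence[RateRecord],
    t_grid: Sequence[float],
    interpolation: str = "linear",
) -> pd.DataFrame:
    """Cumulative released amount implied by piecewise release rates.

    The rate curve is interpolated between the stated points (``"linear"``
    default, ``"constant"`` for a step function holding each rate until the
    next record) with constant extrapolation before the first and after the
    last record, then integrated from t = 0.  The result is exact for the
    interpolated rate curve, not a quadrature approximation.
    """
    if interpolation not in ("linear", "constant"):
        raise ValueError("interpolation must be 'linear' or 'constant'")
    t_grid = np.asarray(t_grid, dtype=float)
    if len(records) == 0:
        return pd.DataFrame({"time": [], "cumulative": []})
    ts = np.array([r.t for r in records], dtype=float)
    rs = np.array([r.rate for r in records], dtype=float)
    if np.any(np.diff(ts) <= 0):
        raise ValueError("rate records must be sorted by strictly increasing time")
    if np.any(t_grid < 0):
        raise ValueError("t_grid times must be non-negative")

    # integrate on the union of breakpoints and grid points: the rate is
    # linear (or constant) between consecutive breakpoints, so the
    # trapezoid (resp. left-rectangle) rule is exact there.
    knots = np.union1d(np.union1d(ts, t_grid), [0.0])
    if interpolation == "linear":
        vals = np.interp(knots, ts, rs)
        seg = 0.5 * (vals[1:] + vals[:-1]) * np.diff(knots)
    else:
        idx = np.searchsorted(ts, knots[:-1], side="right") - 1
        left = rs[np.clip(idx, 0, len(rs) - 1)]
        seg = left * np.diff(knots)
    cum_at_knot = np.concatenate([[0.0], np.cumsum(seg)])
    cumulative = cum_at_knot[np.searchsorted(knots, t_grid)]
    return pd.DataFrame({"time": t_grid, "cumulative": cumulative})


def read_release_dataset(
    path: Union[str, Path], implant: ImplantSpec
) -> ObservationSet:
    """Read a release dataset CSV into a validated :class:`ObservationSet`.

    ``remaining`` rows are converted to released amounts against the
    implant's loaded dose; ``month`` times convert at 30.44 days/month.
    Schema violations raise with the offending row number (1-based, header
    excluded).
    """
    df = pd.read_csv(path)
    missing = [c for c in ("time", "time_unit", "observation_type", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("se", "n"):
        if col not in df.columns:
            df[col] = np.nan

    amount_rows: list[tuple[float, float, float, float]] = []
    rate_rows: list[tuple[float, float]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        unit = str(row.time_unit).strip().lower()
        if unit not in _UNIT_FACTORS:
            raise ValueError(f"{path} row {i}: unknown time_unit {row.time_unit!r}")
        t = float(row.time) * _UNIT_FACTORS[unit]
        if t < 0:
            raise ValueError(f"{path} row {i}: negative time")
        kind = str(row.observation_type).strip().lower()
        value = float(row.value)
        if kind not in _OBS_TYPES:
            raise ValueError(
                f"{path} row {i}: unknown observation_type {row.observation_type!r}"
            )
        if value < 0:
            raise ValueError(f"{path} row {i}: negative value")
        if kind == "rate":
            rate_rows.append((t, value))
            continue
        if kind == "remaining":
            try:
                value = residual_to_released(implant, value)
            except ValueError as exc:
                raise ValueError(f"{path} row {i}: {exc}") from None
        elif value > implant.dose_loaded:
            raise ValueError(
                f"{path} row {i}: amount {value} mg exceeds loaded dose "
                f"{implant.dose_loaded} mg"
            )
        se = float(row.se) if np.isfinite(row.se) else np.nan
        n = float(row.n) if np.isfinite(row.n) else np.nan
        amount_rows.append((t, value, se, n))

    amount_rows.sort(key=lambda r: r[0])
    rate_rows.sort(key=lambda r: r[0])
    a = np.array(amount_rows, dtype=float).reshape(-1, 4)
    r = np.array(rate_rows, dtype=float).reshape(-1, 2)
    return ObservationSet(
        implant=implant,
        amount_t=a[:, 0],
        amount_q=a[:, 1],
        amount_se=a[:, 2],
        amount_n=a[:, 3],
        rate_t=r[:, 0],
        rate_r=r[:, 1],
    )


def write_observation_set(obs: ObservationSet, path: Union[str, Path]) -> None:
    """Write an observation set back to the CSV schema (times in days)."""
    se = obs.amount_se if obs.amount_se is not None else np.full(obs.n_amount, np.nan)
    n = obs.amount_n if obs.amount_n is not None else np.full(obs.n_amount, np.nan)
    rows = pd.DataFrame(
        {
            "time": np.concatenate([obs.amount_t, obs.rate_t]),
            "time_unit": "day",
            "observation_type": ["amount"] * obs.n_amount + ["rate"] * obs.n_rate,
            "value": np.concatenate([obs.amount_q, obs.rate_r]),
            "se": np.concatenate([se, np.full(obs.n_rate, np.nan)]),
            "n": np.concatenate([n, np.full(obs.n_rate, np.nan)]),
        },
        columns=_COLUMNS,
    )
    rows.to_csv(path, index=False)


def write_fit_report(fits: Sequence[FitResult], path: Union[str, Path]) -> None:
    """Write a JSON report of one or more fits, ranked by adjusted R²."""
    if not fits:
        raise ValueError("no fits to report")
    ranking = compare_models(list(fits))
    doc = {
        "ranking": ranking["family_id"].tolist(),
        "fits": {f.family_id: f.to_dict() for f in fits},
    }
    Path(path).write_text(json.dumps(doc, indent=2, allow_nan=True))


def read_fit_report(path: Union[str, Path]) -> dict:
    """Load a fit report written by :func:`write_fit_report`."""
    return json.loads(Path(path).read_text())
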