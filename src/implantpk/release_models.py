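"""Closed-form release-kinetics models for long-acting drug implants.

Ten model families describe the cumulative amount ``Q(t)`` of drug released
from a subcutaneous implant as a function of time since insertion (days),
together with the analytic release rate ``dQ/dt`` (mg/day):

========================  =============================================  ==========
family_id                 Q(t)                                           parameters
========================  =============================================  ==========
zero_order                k·t                                            k
first_order               Qmax·(1 − e^{−k1·t})                           Qmax, k1
second_order              Qmax·(1 − 1/(1 + Qmax·k2·t))                   Qmax, k2
higuchi                   kh·t^0.45                                      kh
korsmeyer_peppas          kkp·t^n                                        kkp, n
hixson_crowell            Qhc − (Qhc^{1/3} − khc·t)^3                    Qhc, khc
weibull                   Qmax·(1 − e^{−(kw·t)^l})                       Qmax, kw, l
biexponential             Dose − Qb1·e^{−kb1·t} − (Dose−Qb1)·e^{−kb2·t}  Dose, Qb1, kb1, kb2
peppas_sahlin             kps1·t^m + kps2·t^{2m}                         kps1, kps2, m
population_council        kps1·√t + kps2·t                               kps1, kps2
========================  =============================================  ==========

Notes on conventions:

* The second-order family is the solution of dQ/dt = k2·(Qmax − Q)², which
  is bounded, non-negative and singularity-free for k2 > 0.
* The "higuchi" family here uses exponent 0.45, the power-law exponent at
  which the Korsmeyer–Peppas family is conventionally identified with
  Higuchi-type diffusion for these devices (the classical square-root law
  is recovered by Korsmeyer–Peppas with n = 0.5).
* Hixson–Crowell (a shrinking-cube model) is clamped at Q = Qhc for times
  past the depletion time Qhc^{1/3}/khc, with a :class:`DepletionWarning`.

Exponent-bearing families reduce to simpler ones at special exponent
values (Weibull l=1 → first-order; Korsmeyer–Peppas n=1 → zero-order,
n=0.45 → higuchi; Peppas–Sahlin m=0.5 → Population Council); see
:func:`reduce_special_case`.

Beyond the fitted release curves, the module provides the implant *input*
functions that drive plasma-exposure simulation: only a fraction (1−f) of
the loaded dose is available for release (f estimated from ex vivo
residual-drug data, typically 0.50), so the releasable amount remaining in
the device is

    first-order:    Li(t) = (1−f)·Dose·e^{−k1·t}
    biexponential:  Li(t) = (1−f)·(Qb1·e^{−kb1·t} + (Dose−Qb1)·e^{−kb2·t})

and the rate entering the subcutaneous depot is −dLi/dt.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Union

import numpy as np

__all__ = [
    "DAYS_PER_MONTH",
    "DepletionWarning",
    "ImplantSpec",
    "ModelFamily",
    "ParameterSet",
    "FAMILIES",
    "get_family",
    "cumulative_release",
    "release_rate",
    "remaining_releasable",
    "implant_input_rate",
    "reduce_special_case",
]

#: Fixed month→day conversion (365.25 / 12), used wherever label data are
#: stated in months ("0.04 mg/day at 12 months").
DAYS_PER_MONTH = 30.44

#: Units of each named parameter, used in JSON serialization.
PARAMETER_UNITS: dict[str, str] = {
    "k": "mg/day",
    "Qmax": "mg",
    "k1": "1/day",
    "k2": "1/(mg*day)",
    "kh": "mg/day^0.45",
    "kkp": "mg/day^n",
    "n": "dimensionless",
    "Qhc": "mg",
    "khc": "mg^(1/3)/day",
    "kw": "1/day",
    "l": "dimensionless",
    "Dose": "mg",
    "Qb1": "mg",
    "kb1": "1/day",
    "kb2": "1/day",
    "kps1": "mg/day^m",
    "kps2": "mg/day^(2m)",
    "m": "dimensionless",
}


class DepletionWarning(UserWarning):
    """Raised when a model is evaluated past its physical depletion time."""


@dataclass(frozen=True)
class ImplantSpec:
    """A contraceptive implant product.

    Parameters
    ----------
    name:
        Product identifier (e.g. ``"Jadelle"``).
    dose_loaded:
        Total drug loaded into the device, mg (150 mg for a two-rod
        levonorgestrel implant).
    n_rods:
        Number of rods making up the device.
    f:
        Complement of the releasable fraction: (1−f) of the loaded dose is
        available for release.  Estimated at 0.50 from residual drug in
        devices explanted at the end of five-year use.  f = 1 is the
        degenerate no-release case.
    """

    name: str
    dose_loaded: float
    n_rods: int = 2
    f: float = 0.5

    def __post_init__(self) -> None:
        if self.dose_loaded <= 0:
            raise ValueError("dose_loaded must be positive")
        if self.n_rods < 1:
            raise ValueError("n_rods must be a positive integer")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")

    @property
    def per_rod_load(self) -> float:
        return self.dose_loaded / self.n_rods

    @property
    def releasable_dose(self) -> float:
        """(1−f)·Dose, the asymptotically releasable amount in mg."""
        return (1.0 - self.f) * self.dose_loaded


@dataclass(frozen=True)
class ModelFamily:
    """One release-model family: its parameters and closed forms."""

    family_id: str
    parameter_names: tuple[str, ...]
    #: per-parameter kind, one of {amount, rate, exponent, coeff, inv_amount_rate,
    #: cuberoot_rate}; drives default bounds and starting values in estimation.
    parameter_kinds: tuple[str, ...]
    _cumulative: Callable[..., np.ndarray]
    _rate: Callable[..., np.ndarray]
    #: parameter name of the asymptote for bounded families, else None
    asymptote: Union[str, None] = None

    def __post_init__(self) -> None:
        if len(set(self.parameter_names)) != len(self.parameter_names):
            raise ValueError("parameter names must be unique")

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ModelFamily({self.family_id!r})"


@dataclass(frozen=True)
class ParameterSet:
    """Named parameter values of one model family."""

    family_id: str
    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fam = get_family(self.family_id)
        object.__setattr__(self, "values", dict(self.values))
        missing = set(fam.parameter_names) - set(self.values)
        extra = set(self.values) - set(fam.parameter_names)
        if missing:
            raise ValueError(f"{self.family_id}: missing parameters {sorted(missing)}")
        if extra:
            raise ValueError(f"{self.family_id}: unknown parameters {sorted(extra)}")
        for name, kind in zip(fam.parameter_names, fam.parameter_kinds):
            v = self.values[name]
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if kind == "amount" and v < 0:
                raise ValueError(f"amount parameter {name} must be >= 0, got {v}")
            if kind == "exponent" and v <= 0:
                raise ValueError(f"exponent {name} must be > 0, got {v}")
            if kind in ("rate", "inv_amount_rate", "cuberoot_rate") and v < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {v}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    # -- JSON round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "parameters": {k: self.values[k] for k in get_family(self.family_id).parameter_names},
            "units": {k: PARAMETER_UNITS[k] for k in get_family(self.family_id).parameter_names},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ParameterSet":
        return cls(doc["family_id"], dict(doc["parameters"]))

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# closed forms (all operate on non-negative numpy arrays)
# ---------------------------------------------------------------------------

def _zero_order_q(t, k):
    return k * t


def _zero_order_r(t, k):
    return np.full_like(t, k, dtype=float)


def _first_order_q(t, Qmax, k1):
    return Qmax * -np.expm1(-k1 * t)


def _first_order_r(t, Qmax, k1):
    return Qmax * k1 * np.exp(-k1 * t)


def _second_order_q(t, Qmax, k2):
    # solution of dQ/dt = k2 (Qmax - Q)^2
    x = Qmax * k2 * t
    return Qmax * x / (1.0 + x)


def _second_order_r(t, Qmax, k2):
    return Qmax**2 * k2 / (1.0 + Qmax * k2 * t) ** 2


def _powerlaw_q(t, coef, expo):
    with np.errstate(divide="ignore"):
        return coef * np.power(t, expo)


def _powerlaw_r(t, coef, expo):
    # d/dt coef t^expo, with the t=0 limit: 0 for expo>1, coef for expo=1, inf below
    out = np.empty_like(t, dtype=float)
    pos = t > 0
    with np.errstate(divide="ignore"):
        out[pos] = coef * expo * np.power(t[pos], expo - 1.0)
    if np.any(~pos):
        if expo > 1.0:
            limit = 0.0
        elif expo == 1.0:
            limit = coef
        else:
            limit = np.inf if coef > 0 else 0.0
        out[~pos] = limit
    return out


def _higuchi_q(t, kh):
    return _powerlaw_q(t, kh, 0.45)


def _higuchi_r(t, kh):
    return _powerlaw_r(t, kh, 0.45)


def _kp_q(t, kkp, n):
    return _powerlaw_q(t, kkp, n)


def _kp_r(t, kkp, n):
    return _powerlaw_r(t, kkp, n)


def _hc_depletion_time(Qhc, khc):
    return np.cbrt(Qhc) / khc if khc > 0 else np.inf


def _hixson_crowell_q(t, Qhc, khc):
    td = _hc_depletion_time(Qhc, khc)
    past = t > td
    if np.any(past):
        warnings.warn(
            f"Hixson-Crowell evaluated past depletion time {td:.6g} d; clamped at Qhc",
            DepletionWarning,
            stacklevel=3,
        )
    core = np.cbrt(Qhc) - khc * np.minimum(t, td)
    # Qhc - cbrt(Qhc)^3 can round to ~-1e-14 at t = 0
    return np.maximum(Qhc - core**3, 0.0)


def _hixson_crowell_r(t, Qhc, khc):
    td = _hc_depletion_time(Qhc, khc)
    core = np.cbrt(Qhc) - khc * np.minimum(t, td)
    out = 3.0 * khc * core**2
    out[t > td] = 0.0
    return out


def _weibull_q(t, Qmax, kw, l):
    return Qmax * -np.expm1(-np.power(kw * t, l))


def _weibull_r(t, Qmax, kw, l):
    out = np.empty_like(t, dtype=float)
    pos = t > 0
    x = kw * t[pos]
    out[pos] = Qmax * kw * l * np.power(x, l - 1.0) * np.exp(-np.power(x, l))
    if np.any(~pos):
        if l > 1.0:
            limit = 0.0
        elif l == 1.0:
            limit = Qmax * kw
        else:
            limit = np.inf if Qmax * kw > 0 else 0.0
        out[~pos] = limit
    return out


def _biexp_q(t, Dose, Qb1, kb1, kb2):
    return Dose - Qb1 * np.exp(-kb1 * t) - (Dose - Qb1) * np.exp(-kb2 * t)


def _biexp_r(t, Dose, Qb1, kb1, kb2):
    return kb1 * Qb1 * np.exp(-kb1 * t) + kb2 * (Dose - Qb1) * np.exp(-kb2 * t)


def _ps_q(t, kps1, kps2, m):
    return _powerlaw_q(t, kps1, m) + _powerlaw_q(t, kps2, 2.0 * m)


def _ps_r(t, kps1, kps2, m):
    return _powerlaw_r(t, kps1, m) + _powerlaw_r(t, kps2, 2.0 * m)


def _pc_q(t, kps1, kps2):
    return kps1 * np.sqrt(t) + kps2 * t


def _pc_r(t, kps1, kps2):
    return _powerlaw_r(t, kps1, 0.5) + kps2


FAMILIES: dict[str, ModelFamily] = {
    f.family_id: f
    for f in [
        ModelFamily("zero_order", ("k",), ("coeff",), _zero_order_q, _zero_order_r),
        ModelFamily(
            "first_order", ("Qmax", "k1"), ("amount", "rate"),
            _first_order_q, _first_order_r, asymptote="Qmax",
        ),
        ModelFamily(
            "second_order", ("Qmax", "k2"), ("amount", "inv_amount_rate"),
            _second_order_q, _second_order_r, asymptote="Qmax",
        ),
        ModelFamily("higuchi", ("kh",), ("coeff",), _higuchi_q, _higuchi_r),
        ModelFamily(
            "korsmeyer_peppas", ("kkp", "n"), ("coeff", "exponent"), _kp_q, _kp_r
        ),
        ModelFamily(
            "hixson_crowell", ("Qhc", "khc"), ("amount", "cuberoot_rate"),
            _hixson_crowell_q, _hixson_crowell_r,
        ),
        ModelFamily(
            "weibull", ("Qmax", "kw", "l"), ("amount", "rate", "exponent"),
            _weibull_q, _weibull_r, asymptote="Qmax",
        ),
        ModelFamily(
            "biexponential", ("Dose", "Qb1", "kb1", "kb2"),
            ("amount", "amount", "rate", "rate"),
            _biexp_q, _biexp_r, asymptote="Dose",
        ),
        ModelFamily(
            "peppas_sahlin", ("kps1", "kps2", "m"), ("coeff", "coeff", "exponent"),
            _ps_q, _ps_r,
        ),
        ModelFamily(
            "population_council", ("kps1", "kps2"), ("coeff", "coeff"), _pc_q, _pc_r
        ),
    ]
}

FamilyLike = Union[str, ModelFamily]
ParamsLike = Union[ParameterSet, Mapping[str, float]]


def get_family(family: FamilyLike) -> ModelFamily:
    """Resolve a family id or instance to the registered :class:`ModelFamily`."""
    if isinstance(family, ModelFamily):
        return family
    try:
        return FAMILIES[family]
    except KeyError:
        raise KeyError(
            f"unknown model family {family!r}; known: {sorted(FAMILIES)}"
        ) from None


def _coerce(family: ModelFamily, params: ParamsLike) -> ParameterSet:
    if isinstance(params, ParameterSet):
        if params.family_id != family.family_id:
            raise ValueError(
                f"parameter set is for {params.family_id!r}, not {family.family_id!r}"
            )
        return params
    return ParameterSet(family.family_id, params)


def _prep_t(t) -> tuple[np.ndarray, bool]:
    arr = np.asarray(t, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr < 0):
        raise ValueError("time must be non-negative")
    return arr, scalar


def cumulative_release(family: FamilyLike, params: ParamsLike, t) -> Union[float, np.ndarray]:
    """Cumulative released amount Q(t) in mg at time(s) ``t`` (days)."""
    fam = get_family(family)
    ps = _coerce(fam, params)
    arr, scalar = _prep_t(t)
    out = fam._cumulative(arr, *(ps[name] for name in fam.parameter_names))
    return float(out[0]) if scalar else out


def release_rate(family: FamilyLike, params: ParamsLike, t) -> Union[float, np.ndarray]:
    """Analytic release rate dQ/dt in mg/day at time(s) ``t`` (days)."""
    fam = get_family(family)
    ps = _coerce(fam, params)
    arr, scalar = _prep_t(t)
    out = fam._rate(arr, *(ps[name] for name in fam.parameter_names))
    return float(out[0]) if scalar else out


_INPUT_FAMILIES = ("first_order", "biexponential")


def _input_scale(implant: ImplantSpec, convention: str) -> float:
    if convention == "corrected":
        return 1.0 - implant.f
    if convention == "fitted":
        return 1.0
    raise ValueError("convention must be 'corrected' or 'fitted'")


def remaining_releasable(
    implant: ImplantSpec,
    family: FamilyLike,
    params: ParamsLike,
    t,
    convention: str = "corrected",
) -> Union[float, np.ndarray]:
    """Releasable drug Li(t) still in the device, mg.

    Under the default ``"corrected"`` convention the (1−f) factor multiplies
    the full exponential expression, so Li(0) = (1−f)·Dose regardless of the
    fitted amplitudes.  The ``"fitted"`` convention drops the prefactor and
    uses the fitted amplitudes as-is (the convention under which the
    biexponential asymptote is the full loaded dose).

    Only the first-order and biexponential families are supported: these are
    the bounded, mechanistically interpretable forms used as implant input
    functions.
    """
    fam = get_family(family)
    if fam.family_id not in _INPUT_FAMILIES:
        raise ValueError(
            f"input functions are defined for families {_INPUT_FAMILIES}, "
            f"not {fam.family_id!r}"
        )
    ps = _coerce(fam, params)
    arr, scalar = _prep_t(t)
    s = _input_scale(implant, convention)
    dose = implant.dose_loaded
    if fam.family_id == "first_order":
        out = s * dose * np.exp(-ps["k1"] * arr)
    else:
        out = s * (
            ps["Qb1"] * np.exp(-ps["kb1"] * arr)
            + (dose - ps["Qb1"]) * np.exp(-ps["kb2"] * arr)
        )
    return float(out[0]) if scalar else out


def implant_input_rate(
    implant: ImplantSpec,
    family: FamilyLike,
    params: ParamsLike,
    t,
    convention: str = "corrected",
) -> Union[float, np.ndarray]:
    """Rate −dLi/dt (mg/day) at which drug leaves the device.

    Integrates to (1−f)·Dose over [0, ∞) under the default convention.
    """
    fam = get_family(family)
    if fam.family_id not in _INPUT_FAMILIES:
        raise ValueError(
            f"input functions are defined for families {_INPUT_FAMILIES}, "
            f"not {fam.family_id!r}"
        )
    ps = _coerce(fam, params)
    arr, scalar = _prep_t(t)
    s = _input_scale(implant, convention)
    dose = implant.dose_loaded
    if fam.family_id == "first_order":
        out = s * dose * ps["k1"] * np.exp(-ps["k1"] * arr)
    else:
        out = s * (
            ps["kb1"] * ps["Qb1"] * np.exp(-ps["kb1"] * arr)
            + ps["kb2"] * (dose - ps["Qb1"]) * np.exp(-ps["kb2"] * arr)
        )
    return float(out[0]) if scalar else out


def reduce_special_case(
    family: FamilyLike, params: ParamsLike, tol: float = 1e-12
) -> tuple[ModelFamily, ParameterSet]:
    """Collapse an exponent-bearing family to its special case.

    Weibull with l = 1 is first-order; Korsmeyer–Peppas with n = 1 is
    zero-order and with n = 0.45 is the Higuchi-type power law;
    Peppas–Sahlin with m = 0.5 is the Population Council model.  Exponents
    are compared within ``tol``.  Anything else is returned unchanged.
    """
    fam = get_family(family)
    ps = _coerce(fam, params)
    if fam.family_id == "weibull" and math.isclose(ps["l"], 1.0, abs_tol=tol):
        return (
            FAMILIES["first_order"],
            ParameterSet("first_order", {"Qmax": ps["Qmax"], "k1": ps["kw"]}),
        )
    if fam.family_id == "korsmeyer_peppas":
        if math.isclose(ps["n"], 1.0, abs_tol=tol):
            return FAMILIES["zero_order"], ParameterSet("zero_order", {"k": ps["kkp"]})
        if math.isclose(ps["n"], 0.45, abs_tol=tol):
            return FAMILIES["higuchi"], ParameterSet("higuchi", {"kh": ps["kkp"]})
    if fam.family_id == "peppas_sahlin" and math.isclose(ps["m"], 0.5, abs_tol=tol):
        return (
            FAMILIES["population_council"],
            ParameterSet(
                "population_council", {"kps1": ps["kps1"], "kps2": ps["kps2"]}
            ),
        )
    return fam, ps
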