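import numpy as np
import pytest

from implantpk import (
    DispositionParams,
    ImplantSpec,
    ParameterSet,
)

#: published point estimates of the two release models fitted to the
#: two-rod 150 mg levonorgestrel implant, used as generating truths
FIRST_ORDER_TRUTH = {"Qmax": 67.86, "k1": 0.0009}
BIEXP_TRUTH = {"Dose": 150.0, "Qb1": 44.64, "kb1": 0.00127, "kb2": 8.985e-5}

#: realistic generating truths for the remaining families, scaled so that
#: roughly a third to half the load releases over five years
FAMILY_TRUTHS = {
    "zero_order": {"k": 0.033},
    "first_order": FIRST_ORDER_TRUTH,
    "second_order": {"Qmax": 80.0, "k2": 2e-5},
    "higuchi": {"kh": 2.3},
    "korsmeyer_peppas": {"kkp": 2.0, "n": 0.5},
    "hixson_crowell": {"Qhc": 150.0, "khc": 5e-4},
    "weibull": {"Qmax": 67.86, "kw": 0.0009, "l": 0.9},
    "biexponential": BIEXP_TRUTH,
    "peppas_sahlin": {"kps1": 1.5, "kps2": 0.02, "m": 0.5},
    "population_council": {"kps1": 1.0, "kps2": 0.02},
}


@pytest.fixture
def jadelle() -> ImplantSpec:
    return ImplantSpec("Jadelle", dose_loaded=150.0, n_rods=2, f=0.5)


@pytest.fixture
def first_order_params() -> ParameterSet:
    return ParameterSet("first_order", FIRST_ORDER_TRUTH)


@pytest.fixture
def biexp_params() -> ParameterSet:
    return ParameterSet("biexponential", BIEXP_TRUTH)


@pytest.fixture
def disposition() -> DispositionParams:
    return DispositionParams()


@pytest.fixture
def day_grid() -> np.ndarray:
    return np.arange(0.0, 1826.0)
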