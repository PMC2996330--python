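import numpy as np
import pytest

from liabpred import DiseaseModel


def last_digit_unit(printed: str) -> float:
    """Size of one unit in the last printed digit of a formatted number."""
    s = printed.upper()
    if "E" in s:
        mantissa, exponent = s.split("E")
        decimals = len(mantissa.split(".")[1]) if "." in mantissa else 0
        return 10.0 ** (int(exponent) - decimals)
    decimals = len(s.split(".")[1]) if "." in s else 0
    return 10.0 ** (-decimals)


def assert_printed(value: float, printed: str, n_units: float = 1.5) -> None:
    """Assert agreement with a printed value to ±1 in its last digit
    (1.5 units absorbs the rounding of the printed figure itself)."""
    target = float(printed)
    tol = n_units * last_digit_unit(printed)
    assert abs(value - target) <= tol, (
        f"{value!r} differs from printed {printed} by "
        f"{abs(value - target):.2e} > {tol:.2e}")


@pytest.fixture
def model_grid():
    """The 12 (K, Vm) combinations used throughout the reference tables."""
    return [
        DiseaseModel(k, vm)
        for k in (0.005, 0.01, 0.05, 0.1)
        for vm in (0.05, 0.1, 0.2)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)
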