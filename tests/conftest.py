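import numpy as np
import pytest

from twometal import ModelSpec, ModelVariant, RateConstants


@pytest.fixture
def example_rates() -> RateConstants:
    """Rounded fitted constants used across worked examples."""
    return RateConstants(k_B_off=18.0, k_B_b=25.35, k_A_off=0.1, k_A_b=0.333)


@pytest.fixture
def concluded_rates() -> RateConstants:
    """Constants implied exactly by the printed fit (K_B = 0.71, K_A = 0.30)."""
    return RateConstants(k_B_off=18.0, k_B_b=18.0 / 0.71, k_A_off=0.1, k_A_b=0.1 / 0.30)


@pytest.fixture
def spec1(example_rates) -> ModelSpec:
    return ModelSpec(ModelVariant.MODEL1, example_rates, 20)


@pytest.fixture
def spec2(example_rates) -> ModelSpec:
    return ModelSpec(ModelVariant.MODEL2, example_rates, 20)


def random_rates(rng: np.random.Generator) -> RateConstants:
    """Log-uniform random rate constants for property tests."""
    lo, hi = np.log(0.01), np.log(100.0)
    k = np.exp(rng.uniform(lo, hi, size=4))
    return RateConstants(k_B_off=k[0], k_B_b=k[1], k_A_off=k[2], k_A_b=k[3])
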