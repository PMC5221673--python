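import numpy as np
import pytest

from csfkit import CSFParams


@pytest.fixture
def running_params() -> CSFParams:
    """Reference parameter set used throughout the model tests."""
    return CSFParams(peak_logcs=2.0, peak_sf=3.0, bandwidth_oct=4.0, truncation=0.5)


@pytest.fixture
def plateau_params() -> CSFParams:
    """Parameter set whose low-frequency plateau covers 1.5 c/deg."""
    return CSFParams(peak_logcs=2.0, peak_sf=6.0, bandwidth_oct=3.0, truncation=0.4)


def random_params(rng: np.random.Generator, size: int) -> list[CSFParams]:
    """Draw plausible clinical parameter sets for property tests."""
    return [
        CSFParams(
            peak_logcs=float(rng.uniform(0.5, 2.5)),
            peak_sf=float(10 ** rng.uniform(-0.3, 1.2)),
            bandwidth_oct=float(rng.uniform(1.0, 6.0)),
            truncation=float(rng.uniform(0.0, 1.5)),
        )
        for _ in range(size)
    ]
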