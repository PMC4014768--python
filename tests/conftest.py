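import numpy as np
import pytest

from bmdbatch import DoseResponseDataset, RunConfig


@pytest.fixture
def dich_dataset():
    """Well-behaved dichotomous dataset: monotone response, 5 groups."""
    return DoseResponseDataset(
        "dich-1", "dichotomous",
        doses=[0, 5, 15, 50, 150],
        n=[50, 50, 50, 50, 50],
        incidence=[2, 5, 12, 25, 41],
        chemical_id="chem-A",
    )


@pytest.fixture
def cont_dataset():
    """Well-behaved continuous dataset: increasing means, 5 groups."""
    return DoseResponseDataset(
        "cont-1", "continuous",
        doses=[0, 10, 30, 100, 300],
        n=[20, 20, 20, 20, 20],
        mean=[100.0, 106.0, 118.0, 142.0, 165.0],
        sd=[12.0, 11.0, 13.0, 12.5, 14.0],
        chemical_id="chem-B",
    )


@pytest.fixture
def cancer_dataset():
    return DoseResponseDataset(
        "canc-1", "dichotomous_cancer",
        doses=[0, 10, 30, 100],
        n=[50, 50, 50, 50],
        incidence=[1, 6, 14, 35],
        chemical_id="chem-C",
    )


@pytest.fixture
def config():
    return RunConfig()


def make_linear_fit(slope=2.0, intercept=100.0, sigma=10.0, doses=(0, 5, 10, 20)):
    """A hand-built linear continuous fit (no optimization involved)."""
    from bmdbatch.fitting import DoseResponseResults
    from bmdbatch.models import Polynomial

    doses = np.asarray(doses, float)
    mean = intercept + slope * doses
    ds = DoseResponseDataset(
        "lin", "continuous", doses=doses, n=[10] * len(doses),
        mean=mean, sd=[sigma] * len(doses),
    )
    spec = Polynomial(1, variance_mode="constant")
    spec.direction = 1 if slope >= 0 else -1
    params = np.array([intercept, slope, np.log(sigma**2)])
    from bmdbatch.fitting import _loglik_full

    return DoseResponseResults(spec, ds, params, _loglik_full(spec, params, ds), True)
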