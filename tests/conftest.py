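import numpy as np
import pandas as pd
import pytest

from tracerfuse import (BioTracerTable, CohortSpec, RegionSpec, center_scale,
                        generate_cohort, sockeye_like)


def make_table(values, regions, tracer_names=None):
    values = np.asarray(values, dtype=float)
    if tracer_names is None:
        tracer_names = [f"t{j + 1}" for j in range(values.shape[1])]
    idx = [f"s{i + 1}" for i in range(values.shape[0])]
    return BioTracerTable(
        values=pd.DataFrame(values, index=idx, columns=tracer_names),
        region=pd.Series(list(regions), index=idx),
    )


def two_gaussian_spec(mu_a=0.0, mu_b=2.0, sd=1.0, d=1, n=200, seed=0):
    """Two-region cohort spec with d independent copies of a 1-D separation."""
    cov = (sd**2) * np.eye(d)
    return CohortSpec(
        regions=[
            RegionSpec(name="A", mean=np.full(d, mu_a), covariance=cov),
            RegionSpec(name="B", mean=np.full(d, mu_b), covariance=cov),
        ],
        n_per_region=n,
        seed=seed,
    )


@pytest.fixture(scope="session")
def sockeye_spec():
    return sockeye_like(seed=0)


@pytest.fixture(scope="session")
def sockeye_table(sockeye_spec):
    """The scaled study-shaped cohort: 3 regions × 30 samples × 17 tracers."""
    return center_scale(generate_cohort(sockeye_spec))


@pytest.fixture(scope="session")
def identical_regions_table():
    """Two regions drawn from the same distribution: chance-level problem."""
    spec = two_gaussian_spec(mu_a=0.0, mu_b=0.0, d=2, n=100, seed=7)
    return center_scale(generate_cohort(spec))
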