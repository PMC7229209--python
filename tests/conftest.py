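import numpy as np
import pandas as pd
import pytest

from umwgs.cohort_sim import SimConfig, simulate_cohort
from umwgs.resources import load_signature_matrix


@pytest.fixture(scope="session")
def sbs_signatures() -> pd.DataFrame:
    return load_signature_matrix(kind="sbs")


@pytest.fixture(scope="session")
def dbs_signatures() -> pd.DataFrame:
    return load_signature_matrix(kind="dbs")


@pytest.fixture(scope="session")
def cohort200():
    """A 200-sample cohort with ~10% iris primaries, shared across tests."""
    cfg = SimConfig(
        n_samples=200,
        site_probs={"choroid": 0.86, "iris": 0.10, "ciliary_body": 0.04},
        seed=7,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_samples=30, seed=3)
    return cfg, simulate_cohort(cfg)


def two_sided_fisher_enumeration(table) -> float:
    """Independent oracle: sum hypergeometric probabilities <= P(observed)."""
    from scipy.stats import hypergeom

    (a, b), (c, d) = table
    n1, n2, m = a + b, c + d, a + c
    lo, hi = max(0, m - n2), min(m, n1)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, n1 + n2, m, n1)
    p_obs = hypergeom.pmf(a, n1 + n2, m, n1)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())
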