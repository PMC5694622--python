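import numpy as np
import pandas as pd
import pytest

from trivus.data_prep import PreparedDataset, RawDataset, prepare
from trivus.simulation import SimulationConfig, simulate


def brute_force_vus(dhat: np.ndarray, t: np.ndarray) -> float:
    """Independent O(n^3) oracle: tie-weighted sum over all ordered triples."""
    a = t[:, None, None]
    b = t[None, :, None]
    c = t[None, None, :]
    w = ((a < b) & (b < c)).astype(float)
    w += 0.5 * (((a == b) & (b < c)) | ((a < b) & (b == c)))
    w += (1.0 / 6.0) * ((a == b) & (b == c))
    num = np.einsum("i,j,k,ijk->", dhat[:, 0], dhat[:, 1], dhat[:, 2], w)
    col = dhat.sum(axis=0)
    return float(num / (col[0] * col[1] * col[2]))


def make_prepared(t, codes, verified=None, covariates=None) -> PreparedDataset:
    """Assemble a PreparedDataset directly from arrays (test helper)."""
    t = np.asarray(t, dtype=float)
    codes = np.asarray(codes, dtype=float)
    n = t.size
    verified = np.ones(n, dtype=int) if verified is None else np.asarray(verified)
    code = np.where(verified == 1, codes, np.nan)
    dmat = np.full((n, 3), np.nan)
    for k in (1, 2, 3):
        dmat[verified == 1, k - 1] = (code[verified == 1] == k).astype(float)
    cov = pd.DataFrame(index=range(n)) if covariates is None else pd.DataFrame(covariates)
    return PreparedDataset(
        test=t, verified=verified, covariates=cov, disease_code=code,
        disease_matrix=dmat, class_mapping={1: 1, 2: 2, 3: 3},
    )


def bayes_rho(config: SimulationConfig, t: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Closed-form class posterior of the generating Gaussian mixture."""
    from scipy.stats import multivariate_normal

    x = np.column_stack([t, a])
    base = np.asarray(config.class_mean_base)
    cov = np.asarray(config.cov)
    dens = np.column_stack(
        [multivariate_normal.pdf(x, mean=k * base, cov=cov) for k in (1, 2, 3)]
    )
    post = dens * np.asarray(config.theta)
    return post / post.sum(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def sim_cfg() -> SimulationConfig:
    return SimulationConfig(n=1000, seed=7)


@pytest.fixture(scope="session")
def sim_data(sim_cfg):
    """One simulated verification-biased dataset at n=1000, prepared."""
    return prepare(simulate(sim_cfg))


@pytest.fixture(scope="session")
def full_data():
    """Fully verified dataset (near-certain verification), n=200."""
    cfg = SimulationConfig(n=200, seed=2, verif_coef=(50.0, 0.0, 0.0))
    raw = simulate(cfg)
    assert (raw.verified == 1).all()
    return prepare(raw)
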