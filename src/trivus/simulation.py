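"""Synthetic three-class verification-biased data and truth oracles.

The generator draws, per subject,

* a disease class k in {1, 2, 3} with probabilities theta = (0.40, 0.35,
  0.25) by default;
* a test value T and one auxiliary covariate A from the class-conditional
  bivariate normal with mean k * (2, 1)' and covariance
  [[1.75, 0.1], [0.1, 2.5]] — so class-conditional test means 2, 4, 6
  satisfy monotone ordering by construction;
* a verification indicator V ~ Bernoulli(expit(1 - 2.2 T + 4 A)).

Missingness of the disease status is exactly the verification draw:
unverified subjects have their label hidden, which makes the mechanism
missing at random given (T, A). The hidden truth is retained on a side
channel (``RawDataset.true_label``) for oracle evaluation only.

Truth oracles: ``true_vus`` Monte-Carlo-averages the tie-weighted
concordance kernel over independent class-conditional test draws;
``true_tcf`` evaluates the class-conditional normal CDFs in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .data_prep import RawDataset

__all__ = ["SimulationConfig", "simulate", "true_vus", "true_tcf"]


@dataclass
class SimulationConfig:
    """Parameters of the trinomial / bivariate-normal generating model."""

    n: int = 500
    theta: tuple[float, float, float] = (0.40, 0.35, 0.25)
    class_mean_base: tuple[float, float] = (2.0, 1.0)
    cov: tuple[tuple[float, float], tuple[float, float]] = (
        (1.75, 0.1),
        (0.1, 2.5),
    )
    verif_coef: tuple[float, float, float] = (1.0, -2.2, 4.0)  # intercept, T, A
    seed: int = 0

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.shape != (3,) or (th <= 0).any() or abs(th.sum() - 1.0) > 1e-12:
            raise ValueError("theta must be three positive values summing to 1")
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (2, 2) or not np.allclose(c, c.T):
            raise ValueError("cov must be symmetric 2x2")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("cov must be positive definite")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def test_sd(self) -> float:
        return float(np.sqrt(np.asarray(self.cov)[0, 0]))

    def class_test_mean(self, k: int) -> float:
        return float(k * self.class_mean_base[0])


def simulate(config: SimulationConfig) -> RawDataset:
    """Draw one dataset from the generating model.

    Returns a :class:`~trivus.data_prep.RawDataset` whose ``disease_label``
    is hidden (None) for unverified subjects; the complete labels are kept
    in ``true_label`` for oracle use only.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    klass = rng.choice([1, 2, 3], size=n, p=np.asarray(config.theta))
    base = np.asarray(config.class_mean_base)
    chol = np.linalg.cholesky(np.asarray(config.cov))
    z = rng.standard_normal((n, 2))
    ta = klass[:, None] * base[None, :] + z @ chol.T
    t, a = ta[:, 0], ta[:, 1]
    b0, b1, b2 = config.verif_coef
    v = (rng.random(n) < expit(b0 + b1 * t + b2 * a)).astype(int)
    labels = np.array([int(k) for k in klass], dtype=object)
    hidden = labels.copy()
    hidden[v == 0] = None
    return RawDataset(
        test=t,
        disease_label=hidden,
        verified=v,
        covariates=pd.DataFrame({"A": a}),
        true_label=labels,
    )


def _tie_kernel(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    w = np.zeros(a.shape)
    w[(a < b) & (b < c)] = 1.0
    w[((a == b) & (b < c)) | ((a < b) & (b == c))] = 0.5
    w[(a == b) & (b == c)] = 1.0 / 6.0
    return w


def true_vus(
    config: SimulationConfig, m: int = 1_000_000, seed: int = 12345
) -> tuple[float, float]:
    """Monte-Carlo ground-truth VUS under the generating model.

    Draws ``m`` independent triples (T1, T2, T3), one test value from each
    class-conditional marginal, and averages the tie-weighted concordance
    kernel. Returns ``(value, standard_error)``.
    """
    if m < 1000:
        raise ValueError("m must be >= 1000 for a meaningful oracle")
    rng = np.random.default_rng(seed)
    sd = config.test_sd
    draws = [
        config.class_test_mean(k) + sd * rng.standard_normal(m) for k in (1, 2, 3)
    ]
    w = _tie_kernel(*draws)
    return float(w.mean()), float(w.std(ddof=1) / np.sqrt(m))


def true_tcf(
    config: SimulationConfig, c1: float, c2: float
) -> tuple[float, float, float]:
    """Exact true class fractions at (c1, c2) under the generating model."""
    if c1 > c2:
        raise ValueError("cut-points must satisfy c1 <= c2")
    sd = config.test_sd
    m1, m2, m3 = (config.class_test_mean(k) for k in (1, 2, 3))
    tcf1 = stats.norm.cdf(c1, loc=m1, scale=sd)
    tcf2 = stats.norm.cdf(c2, loc=m2, scale=sd) - stats.norm.cdf(c1, loc=m2, scale=sd)
    tcf3 = stats.norm.sf(c2, loc=m3, scale=sd)
    return float(tcf1), float(tcf2), float(tcf3)
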