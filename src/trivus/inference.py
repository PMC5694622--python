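"""VUS point estimation, variance, confidence intervals and the useless-test test.

The volume under the three-class ROC surface (VUS) is the probability that
test values drawn from classes 1, 2 and 3 are correctly ordered,
P(T1 < T2 < T3). Given a corrected disease matrix D_hat, the estimator is
the ratio-form trivariate U-statistic

    VUS_hat = sum_{i,j,l} w(T_i, T_j, T_l) D1_i D2_j D3_l
              ---------------------------------------------
              (sum_i D1_i) (sum_j D2_j) (sum_l D3_l)

with tie-handling kernel w(a,b,c) = 1 if a < b < c, 1/2 if exactly one
adjacent pair ties (a = b < c or a < b = c), 1/6 if a = b = c, else 0. The
triple-tie weight 1/6 makes a completely uninformative test (all values
equal) score exactly the useless-test value 1/6.

The normative definition is the full triple sum over all n^3 ordered index
triples; the implementation groups subjects by unique test value and uses
cumulative sums, which is algebraically identical and O(n log n).

Variance comes from a leave-one-out jackknife (fitted nuisance predictions
reused, not refitted) or a nonparametric bootstrap that refits the nuisance
models inside each replicate. Confidence intervals are built on the natural
scale and, when the estimate lies in (0, 1), on the logit scale. The test
of H0: VUS = 1/6 against H1: VUS > 1/6 uses
t = (VUS_hat - 1/6) / se ~ N(0, 1), one-sided upper tail.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy import stats

from .data_prep import PreparedDataset
from .estimators import CorrectedDisease, corrected_disease
from .models import (
    DiseaseProbabilityFit,
    VerificationFit,
    fit_disease_knn,
    fit_disease_mlogit,
    fit_verification_model,
)

__all__ = [
    "ModelSpec",
    "VUSResult",
    "vus_point",
    "asymptotic_variance",
    "bootstrap_variance",
    "confidence_interval",
    "test_vus",
    "vus_analyze",
]

logger = logging.getLogger(__name__)

USELESS_VUS = 1.0 / 6.0


@dataclass
class ModelSpec:
    """Which predictors feed the nuisance models.

    ``disease_predictors`` drive the disease-probability model (multinomial
    logit, or KNN for method ``knn``); ``verification_predictors`` drive the
    binary verification model. ``"T"`` denotes the diagnostic test itself.
    """

    disease_predictors: tuple[str, ...] = ("T",)
    verification_predictors: tuple[str, ...] = ("T",)
    link: str = "logit"
    knn_k: int | None = None
    pi_floor: float = 1e-6


@dataclass
class VUSResult:
    """Point estimate, uncertainty and test for one estimation method."""

    estimate: float
    variance: float
    se: float
    ci_normal: tuple[float, float]
    ci_logit: tuple[float, float] | None
    level: float
    t_stat: float
    p_value: float
    method: str
    variance_method: str
    model_spec: ModelSpec | None = field(default=None, repr=False)

    def format_p(self) -> str:
        return "< 0.0001" if self.p_value < 1e-4 else f"{self.p_value:.4f}"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "variance": self.variance,
            "se": self.se,
            "level": self.level,
            "ci_normal": list(self.ci_normal),
            "ci_logit": None if self.ci_logit is None else list(self.ci_logit),
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "p_display": self.format_p(),
            "variance_method": self.variance_method,
        }


def _as_dhat(dhat) -> np.ndarray:
    if isinstance(dhat, CorrectedDisease):
        return dhat.dhat
    return np.asarray(dhat, dtype=float)


def _grouped_sums(dhat: np.ndarray, t: np.ndarray):
    """Per-unique-test-value column sums of dhat (values ascending)."""
    values, inv = np.unique(t, return_inverse=True)
    m = values.size
    s1 = np.bincount(inv, weights=dhat[:, 0], minlength=m)
    s2 = np.bincount(inv, weights=dhat[:, 1], minlength=m)
    s3 = np.bincount(inv, weights=dhat[:, 2], minlength=m)
    return inv, s1, s2, s3


def _numerator(s1: np.ndarray, s2: np.ndarray, s3: np.ndarray) -> float:
    """Tie-weighted triple sum from per-value mass vectors.

    Splitting the triple sum by the unique values (a, b, c) taken by the
    three slots gives four cumulative-sum terms: strict a < b < c, the two
    single-adjacent-tie terms at weight 1/2, and the triple tie at 1/6.
    """
    below1 = np.concatenate(([0.0], np.cumsum(s1)[:-1]))  # mass of s1 strictly below
    above3 = np.concatenate((np.cumsum(s3[::-1])[::-1][1:], [0.0]))  # strictly above
    strict = float(np.sum(s2 * below1 * above3))
    tie_ab = 0.5 * float(np.sum(s1 * s2 * above3))
    tie_bc = 0.5 * float(np.sum(below1 * s2 * s3))
    tie_abc = float(np.sum(s1 * s2 * s3)) / 6.0
    return strict + tie_ab + tie_bc + tie_abc


def vus_point(dhat, test_values: np.ndarray) -> float:
    """VUS point estimate from a corrected disease matrix.

    Accepts a :class:`~trivus.estimators.CorrectedDisease` or a bare n x 3
    array. Depends on the test values only through their ordering and ties,
    so it is invariant under strictly increasing transformations.
    """
    d = _as_dhat(dhat)
    t = np.asarray(test_values, dtype=float)
    if d.shape != (t.size, 3):
        raise ValueError("dhat must be n x 3 aligned with test_values")
    col = d.sum(axis=0)
    if np.any(col <= 0):
        raise ValueError(f"each corrected-disease column needs positive sum, got {col}")
    _, s1, s2, s3 = _grouped_sums(d, t)
    return _numerator(s1, s2, s3) / float(col[0] * col[1] * col[2])


def asymptotic_variance(
    dhat,
    test_values: np.ndarray,
    rho: DiseaseProbabilityFit | None = None,
    verif: VerificationFit | None = None,
) -> float:
    """Leave-one-out jackknife variance of the VUS estimate.

    Each subject is removed in turn and the ratio-form VUS recomputed with
    the fitted nuisance predictions kept fixed (the corrected matrix row is
    simply dropped); the variance is ((n-1)/n) * sum (v_i - v_bar)^2. The
    ``rho``/``verif`` fits are accepted for provenance only — their
    predictions are already embedded in ``dhat``.
    """
    d = _as_dhat(dhat)
    t = np.asarray(test_values, dtype=float)
    n = t.size
    if n < 10:
        raise ValueError("jackknife variance needs n >= 10")
    inv, s1, s2, s3 = _grouped_sums(d, t)
    col = d.sum(axis=0)
    loo = np.empty(n)
    for i in range(n):
        j = inv[i]
        d1, d2, d3 = d[i]
        s1[j] -= d1
        s2[j] -= d2
        s3[j] -= d3
        num = _numerator(s1, s2, s3)
        den = (col[0] - d1) * (col[1] - d2) * (col[2] - d3)
        s1[j] += d1
        s2[j] += d2
        s3[j] += d3
        if den <= 0:
            raise ValueError("leave-one-out estimate undefined: empty class")
        loo[i] = num / den
    return float((n - 1) / n * np.sum((loo - loo.mean()) ** 2))


def _fit_and_estimate(data: PreparedDataset, method: str, spec: ModelSpec):
    """Fit required nuisance models and return (CorrectedDisease, fits)."""
    rho = verif = None
    if method in ("fi", "msi", "spe"):
        rho = fit_disease_mlogit(data, spec.disease_predictors)
    elif method == "knn":
        if spec.knn_k is None:
            raise ValueError("method 'knn' requires ModelSpec.knn_k")
        rho = fit_disease_knn(data, spec.disease_predictors, k=spec.knn_k)
    if method in ("ipw", "spe"):
        verif = fit_verification_model(
            data, spec.verification_predictors, link=spec.link, pi_floor=spec.pi_floor
        )
    return corrected_disease(method, data, rho=rho, verif=verif)


def _resample(data: PreparedDataset, idx: np.ndarray) -> PreparedDataset:
    return PreparedDataset(
        test=data.test[idx],
        verified=data.verified[idx],
        covariates=data.covariates.iloc[idx].reset_index(drop=True),
        disease_code=data.disease_code[idx],
        disease_matrix=data.disease_matrix[idx],
        class_mapping=data.class_mapping,
    )


def _one_bootstrap(data: PreparedDataset, method: str, spec: ModelSpec,
                   seed: int, max_tries: int = 100):
    """One bootstrap replicate of (VUS, TCF machinery inputs).

    Resamples subjects with replacement; a replicate that loses an entire
    class among verified subjects is redrawn (fresh child seed) up to
    ``max_tries`` times.
    """
    rng = np.random.default_rng(seed)
    n = data.n
    for _ in range(max_tries):
        idx = rng.integers(0, n, size=n)
        boot = _resample(data, idx)
        codes = boot.disease_code[boot.verified == 1]
        if all((codes == k).any() for k in (1, 2, 3)):
            try:
                dh = _fit_and_estimate(boot, method, spec)
                return vus_point(dh, boot.test), dh, boot
            except (ValueError, RuntimeError) as exc:  # refit failure -> redraw
                logger.debug("bootstrap replicate redrawn: %s", exc)
                continue
    raise RuntimeError(f"no valid bootstrap replicate after {max_tries} redraws")


def bootstrap_variance(
    data: PreparedDataset,
    method: str,
    model_spec: ModelSpec | None = None,
    B: int = 250,
    seed: int = 0,
    workers: int = 1,
) -> float:
    """Nonparametric bootstrap variance of the VUS estimate.

    Subjects are resampled with replacement and the verification and
    disease models are refitted inside each replicate. Replicate ``r`` uses
    seed ``seed + 1 + r``, so the result is identical for any worker count.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    spec = model_spec or ModelSpec()
    seeds = [seed + 1 + r for r in range(B)]
    if workers == 1:
        values = [_one_bootstrap(data, method, spec, s)[0] for s in seeds]
    else:
        values = Parallel(n_jobs=workers)(
            delayed(_one_bootstrap)(data, method, spec, s) for s in seeds
        )
        values = [v[0] for v in values]
    return float(np.var(values, ddof=1))


def confidence_interval(
    estimate: float,
    se: float,
    level: float = 0.95,
    scale: str = "normal",
) -> tuple[float, float]:
    """Normal-approximation confidence interval on the natural or logit scale.

    Logit-scale intervals use the delta method,
    se(logit(p)) = se / (p (1 - p)), and map the endpoints back through the
    inverse logit, guaranteeing bounds inside (0, 1).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if se < 0:
        raise ValueError("se must be nonnegative")
    z = stats.norm.ppf((1 + level) / 2)
    if scale == "normal":
        return (estimate - z * se, estimate + z * se)
    if scale == "logit":
        if not 0 < estimate < 1:
            raise ValueError("logit-scale interval requires estimate in (0, 1)")
        center = np.log(estimate / (1 - estimate))
        half = z * se / (estimate * (1 - estimate))
        lo, hi = center - half, center + half
        expit = lambda x: 1.0 / (1.0 + np.exp(-x))
        # keep the bounds strictly inside (0, 1) even when the transformed
        # half-width saturates floating point
        eps_lo = np.nextafter(0.0, 1.0)
        eps_hi = np.nextafter(1.0, 0.0)
        return (
            float(min(max(expit(lo), eps_lo), eps_hi)),
            float(min(max(expit(hi), eps_lo), eps_hi)),
        )
    raise ValueError(f"unknown scale {scale!r}")


def test_vus(estimate: float, variance: float) -> tuple[float, float]:
    """Test H0: VUS = 1/6 against H1: VUS > 1/6.

    Returns ``(t, p)`` with t = (estimate - 1/6)/sqrt(variance) and p the
    upper-tail standard-normal probability.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    t = (estimate - USELESS_VUS) / np.sqrt(variance)
    return float(t), float(stats.norm.sf(t))


def vus_analyze(
    data: PreparedDataset,
    method: str,
    model_spec: ModelSpec | None = None,
    variance_method: str = "jackknife",
    B: int = 250,
    seed: int = 0,
    level: float = 0.95,
    workers: int = 1,
) -> VUSResult:
    """End-to-end VUS analysis: fit models, correct, estimate, infer.

    ``variance_method`` is ``"jackknife"`` (leave-one-out, reusing fitted
    nuisance predictions) or ``"bootstrap"`` (refitting models per
    replicate, ``B`` replicates).
    """
    spec = model_spec or ModelSpec()
    dh = _fit_and_estimate(data, method, spec)
    est = vus_point(dh, data.test)
    if variance_method == "jackknife":
        var = asymptotic_variance(dh, data.test)
    elif variance_method == "bootstrap":
        var = bootstrap_variance(data, method, spec, B=B, seed=seed, workers=workers)
    else:
        raise ValueError(f"unknown variance_method {variance_method!r}")
    se = float(np.sqrt(var))
    ci_n = confidence_interval(est, se, level, "normal")
    if 0 < est < 1:
        ci_l = confidence_interval(est, se, level, "logit")
    else:
        ci_l = None
        warnings.warn(
            f"estimate {est:.4f} outside (0,1); logit-scale CI unavailable",
            stacklevel=2,
        )
    t, p = test_vus(est, var)
    return VUSResult(
        estimate=float(est),
        variance=float(var),
        se=se,
        ci_normal=ci_n,
        ci_logit=ci_l,
        level=level,
        t_stat=t,
        p_value=p,
        method=method,
        variance_method=variance_method,
        model_spec=spec,
    )
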