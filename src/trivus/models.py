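"""Nuisance-model fitting: verification probabilities and disease probabilities.

Bias correction under missing-at-random verification needs two working
models:

* a binary regression of the verification indicator V on observed
  predictors (typically the test T and auxiliary covariates), yielding
  fitted verification probabilities pi_i = Pr(V_i = 1 | predictors); and
* a model for the conditional disease-class probabilities
  rho_k(T, A) = Pr(class k | T, A), fitted on verified subjects only and
  predicted for everyone — either a multinomial logistic regression or a
  K-nearest-neighbour average of observed disease indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
import statsmodels.api as sm

from .data_prep import PreparedDataset

__all__ = [
    "VerificationFit",
    "DiseaseProbabilityFit",
    "fit_verification_model",
    "fit_disease_mlogit",
    "fit_disease_knn",
    "select_k",
]

logger = logging.getLogger(__name__)

# "threshold" is accepted as a third link option alongside logit/probit and
# is mapped to the complementary log-log link; see docs/methods.md for the
# rationale behind this interpretation.
_LINKS = {
    "logit": sm.families.links.Logit,
    "probit": sm.families.links.Probit,
    "threshold": sm.families.links.CLogLog,
}

DEFAULT_PI_FLOOR = 1e-6


@dataclass
class VerificationFit:
    """Fitted binary regression for the verification mechanism."""

    link: str
    coefficients: np.ndarray  # intercept first
    pi: np.ndarray  # floored fitted probabilities, length n
    pi_raw: np.ndarray  # unfloored fitted probabilities
    predictor_names: tuple[str, ...]
    floor: float
    n_floored: int

    def summary_dict(self) -> dict:
        names = ("intercept", *self.predictor_names)
        return {
            "model": "verification",
            "link": self.link,
            "coefficients": dict(zip(names, map(float, self.coefficients))),
            "floor": self.floor,
            "n_floored": self.n_floored,
        }


@dataclass
class DiseaseProbabilityFit:
    """Fitted disease-class probabilities rho (n x 3, rows sum to 1)."""

    method: str  # "mlogit" or "knn"
    rho: np.ndarray
    predictor_names: tuple[str, ...]
    coefficients: np.ndarray | None = None  # (2, p+1) for mlogit, class-1 baseline
    k: int | None = None
    distance_metric: str | None = None
    converged: bool = True
    n_iter: int | None = field(default=None, repr=False)

    def summary_dict(self) -> dict:
        out = {"model": "disease", "method": self.method,
               "predictors": list(self.predictor_names)}
        if self.method == "mlogit":
            names = ("intercept", *self.predictor_names)
            out["coefficients"] = {
                f"class{k + 2}_vs_1": dict(zip(names, map(float, row)))
                for k, row in enumerate(self.coefficients)
            }
            out["converged"] = self.converged
        else:
            out["K"] = self.k
            out["distance"] = self.distance_metric
        return out


def _check_separation(x: np.ndarray, y: np.ndarray, names: Sequence[str]) -> None:
    for j, name in enumerate(names):
        lo, hi = x[y == 0, j], x[y == 1, j]
        if lo.size and hi.size and (lo.max() < hi.min() or hi.max() < lo.min()):
            raise ValueError(
                f"perfect separation of verification status by predictor {name!r}"
            )


def fit_verification_model(
    data: PreparedDataset,
    predictors: Sequence[str] = ("T",),
    link: str = "logit",
    pi_floor: float = DEFAULT_PI_FLOOR,
) -> VerificationFit:
    """Fit Pr(V = 1 | predictors) by maximum-likelihood binary regression.

    Fitted probabilities are produced for every subject and floored at
    ``pi_floor`` before use as inverse weights; flooring events are logged.
    """
    if link not in _LINKS:
        raise ValueError(f"unknown link {link!r}; choose from {sorted(_LINKS)}")
    v = data.verified
    if v.min() == v.max():
        raise ValueError("verification status must contain both 0s and 1s")
    x = data.predictor_matrix(predictors)
    _check_separation(x, v, predictors)
    design = sm.add_constant(x, has_constant="add")
    fam = sm.families.Binomial(link=_LINKS[link]())
    res = sm.GLM(v, design, family=fam).fit()
    pi_raw = np.asarray(res.predict(design))
    pi = np.clip(pi_raw, pi_floor, 1.0)
    n_floored = int((pi_raw < pi_floor).sum())
    if n_floored:
        logger.warning(
            "floored %d fitted verification probabilities at %g", n_floored, pi_floor
        )
    return VerificationFit(
        link=link,
        coefficients=np.asarray(res.params),
        pi=pi,
        pi_raw=pi_raw,
        predictor_names=tuple(predictors),
        floor=pi_floor,
        n_floored=n_floored,
    )


def fit_disease_mlogit(
    data: PreparedDataset,
    predictors: Sequence[str] = ("T",),
    maxiter: int = 100,
) -> DiseaseProbabilityFit:
    """Multinomial logistic regression of disease class on predictors.

    Fitted on verified subjects (class 1 is the baseline category) and
    predicted for all subjects, verified or not.
    """
    mask = data.verified == 1
    codes = data.disease_code[mask]
    counts = [(codes == k).sum() for k in (1, 2, 3)]
    if min(counts) == 0:
        raise ValueError(f"each class needs >=1 verified subject, counts={counts}")
    x = data.predictor_matrix(predictors)
    design = sm.add_constant(x, has_constant="add")
    model = sm.MNLogit(codes - 1, design[mask])
    res = model.fit(method="newton", maxiter=maxiter, disp=False)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(
            f"multinomial logit did not converge in {maxiter} iterations"
        )
    rho = np.asarray(res.predict(design))
    return DiseaseProbabilityFit(
        method="mlogit",
        rho=rho,
        predictor_names=tuple(predictors),
        coefficients=np.asarray(res.params).T,  # rows: class 2 vs 1, class 3 vs 1
        converged=True,
        n_iter=res.mle_retvals.get("iterations"),
    )


def _standardize(x: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd, (ref - mu) / sd


def fit_disease_knn(
    data: PreparedDataset,
    predictors: Sequence[str] = ("T",),
    k: int = 1,
    distance: str = "euclidean",
    leave_one_out: bool = False,
) -> DiseaseProbabilityFit:
    """K-nearest-neighbour disease-probability estimate.

    For each subject, rho is the average of the disease indicator rows of
    the K verified subjects nearest in predictor space. Predictors are
    standardized by the verified-subject mean and standard deviation, so the
    fit is exactly invariant to affine rescaling; ties at the K-th distance
    are broken by lowest subject index (stable sort). With
    ``leave_one_out=True`` a verified subject is excluded from its own
    neighbour set.
    """
    mask = data.verified == 1
    n_ver = int(mask.sum())
    if not 1 <= k <= n_ver:
        raise ValueError(f"K must be in [1, {n_ver}], got {k}")
    x = data.predictor_matrix(predictors)
    q, ref = _standardize(x, x[mask])
    dist = cdist(q, ref, metric=distance)
    dmat = data.disease_matrix[mask]
    rho = np.empty((data.n, 3))
    ver_pos = np.flatnonzero(mask)  # query row index of each reference subject
    for i in range(data.n):
        row = dist[i]
        if leave_one_out and mask[i]:
            row = row.copy()
            row[np.searchsorted(ver_pos, i)] = np.inf
        idx = np.argsort(row, kind="stable")[:k]
        rho[i] = dmat[idx].mean(axis=0)
    return DiseaseProbabilityFit(
        method="knn",
        rho=rho,
        predictor_names=tuple(predictors),
        k=k,
        distance_metric=distance,
    )


def default_k_grid(n_verified: int) -> list[int]:
    """Odd values 1, 3, 5, ... up to ceil(sqrt(n_verified)) rounded up to odd."""
    top = int(np.ceil(np.sqrt(n_verified)))
    if top % 2 == 0:
        top += 1
    return list(range(1, top + 1, 2))


def select_k(
    data: PreparedDataset,
    predictors: Sequence[str] = ("T",),
    k_grid: Sequence[int] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose K for the KNN disease model by cross-validation.

    Verified subjects are split into ``folds`` folds (seeded, shuffled);
    the score for each K is the mean squared error between held-out
    disease-indicator rows and the KNN probabilities predicted from the
    remaining verified subjects. Ties are broken by the smaller K.
    """
    mask = data.verified == 1
    n_ver = int(mask.sum())
    if k_grid is None:
        k_grid = default_k_grid(n_ver)
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    if folds < 2 or folds > n_ver:
        raise ValueError(f"folds must be in [2, {n_ver}]")
    if max(k_grid) > n_ver - int(np.ceil(n_ver / folds)):
        raise ValueError("largest K exceeds the training size of a fold")

    x = data.predictor_matrix(predictors)[mask]
    dmat = data.disease_matrix[mask]
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(np.arange(n_ver) % folds)

    scores = np.zeros(len(k_grid))
    for f in range(folds):
        test_sel = fold_of == f
        train_sel = ~test_sel
        xq, xr = _standardize(x[test_sel], x[train_sel])
        dist = cdist(xq, xr)
        order = np.argsort(dist, axis=1, kind="stable")
        for ki, k in enumerate(k_grid):
            pred = dmat[train_sel][order[:, :k]].mean(axis=1)
            scores[ki] += ((pred - dmat[test_sel]) ** 2).sum()
    scores /= n_ver * 3
    table = pd.DataFrame({"K": k_grid, "cv_mse": scores})
    best = int(table.loc[table["cv_mse"].idxmin(), "K"])  # idxmin: first minimum
    return best, table
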