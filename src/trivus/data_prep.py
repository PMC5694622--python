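"""Input validation and disease-status encoding for three-class verification-bias studies.

A study record consists of a continuous diagnostic test value ``T``, a binary
verification indicator ``V`` (1 = the gold-standard disease status was
obtained), a three-class disease label (observed only when ``V = 1``), and
zero or more fully observed numeric auxiliary covariates.

The preparation step maps the three observed disease labels onto ordered
numeric codes 1/2/3 (1 = least severe), builds the n x 3 disease indicator
matrix used by every downstream estimator, and checks the monotone-ordering
condition: test values should increase, on average, with disease severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawDataset",
    "PreparedDataset",
    "OrderingReport",
    "read_table",
    "prepare",
    "check_monotone_ordering",
]

TEST_COLUMN = "T"


@dataclass
class RawDataset:
    """Subject-level input before encoding.

    Parameters
    ----------
    test
        Continuous diagnostic test values, no missing entries.
    disease_label
        Disease label per subject; may be missing (``None``/NaN) for
        unverified subjects and must be present for verified ones.
    verified
        Verification status, 0 or 1 per subject.
    covariates
        Numeric auxiliary covariates, fully observed. A DataFrame (possibly
        with zero columns) aligned with ``test``.
    """

    test: np.ndarray
    disease_label: np.ndarray
    verified: np.ndarray
    covariates: pd.DataFrame
    # Oracle-only ground truth (e.g. from a simulator); never consumed by
    # estimators and absent for real data.
    true_label: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.test = np.asarray(self.test, dtype=float)
        self.verified = np.asarray(self.verified)
        self.disease_label = np.asarray(self.disease_label, dtype=object)
        if self.test.ndim != 1 or self.test.size < 1:
            raise ValueError("test must be a non-empty 1-D array")
        n = self.test.size
        if self.disease_label.shape != (n,) or self.verified.shape != (n,):
            raise ValueError("test, disease_label and verified must share length")
        if np.isnan(self.test).any():
            raise ValueError("missing test values are not allowed")
        v = np.unique(self.verified)
        if not np.isin(v, [0, 1]).all():
            raise ValueError("verified must contain only 0/1 values")
        self.verified = self.verified.astype(int)
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(self.covariates)
        if len(self.covariates) != n:
            raise ValueError("covariates must align with test values")
        if self.covariates.shape[1] and self.covariates.isna().any().any():
            raise ValueError("missing covariate values are not allowed")
        miss = _is_missing(self.disease_label)
        if (miss & (self.verified == 1)).any():
            raise ValueError("disease_label missing for a verified subject")

    @property
    def n(self) -> int:
        return self.test.size


@dataclass
class PreparedDataset:
    """Validated dataset with numeric disease coding and indicator matrix.

    ``disease_code`` holds 1/2/3 for verified subjects and NaN otherwise;
    ``disease_matrix`` is n x 3 with one-hot rows for verified subjects and
    all-NaN rows for unverified ones, so a naive sum over everyone fails
    loudly rather than silently ignoring the missing statuses.
    """

    test: np.ndarray
    verified: np.ndarray
    covariates: pd.DataFrame
    disease_code: np.ndarray
    disease_matrix: np.ndarray
    class_mapping: Mapping[object, int]
    true_label: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.test.size

    @property
    def n_verified(self) -> int:
        return int(self.verified.sum())

    def predictor_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Column-stack the named predictors; ``"T"`` denotes the test.

        An empty name list yields an (n, 0) matrix (intercept-only models).
        """
        if not names:
            return np.empty((self.n, 0))
        cols = []
        for name in names:
            if name == TEST_COLUMN:
                cols.append(self.test)
            elif name in self.covariates.columns:
                cols.append(self.covariates[name].to_numpy(dtype=float))
            else:
                raise KeyError(f"unknown predictor {name!r}")
        return np.column_stack(cols)

    def decode_labels(self) -> np.ndarray:
        """Map disease codes back to the original labels (verified rows)."""
        inverse = {v: k for k, v in self.class_mapping.items()}
        out = np.full(self.n, None, dtype=object)
        ok = ~np.isnan(self.disease_code)
        out[ok] = [inverse[int(c)] for c in self.disease_code[ok]]
        return out


@dataclass
class OrderingReport:
    """Result of the monotone-ordering diagnostic."""

    class_means: tuple[float, float, float]
    satisfied: bool
    message: str


def _is_missing(labels: np.ndarray) -> np.ndarray:
    out = np.zeros(labels.shape, dtype=bool)
    for i, x in enumerate(labels):
        out[i] = x is None or (isinstance(x, float) and np.isnan(x))
    return out


def read_table(
    path,
    *,
    test: str,
    disease: str,
    verified: str,
    covariates: Sequence[str] = (),
    sep: str = ",",
    quotechar: str = '"',
) -> RawDataset:
    """Read a delimited text file into a :class:`RawDataset`.

    Column roles are given by name; ``sep`` and ``quotechar`` mirror the
    usual spreadsheet-export options.
    """
    df = pd.read_csv(path, sep=sep, quotechar=quotechar)
    for col in (test, disease, verified, *covariates):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path}")
    labels = df[disease].to_numpy(dtype=object)
    labels[pd.isna(df[disease]).to_numpy()] = None
    return RawDataset(
        test=df[test].to_numpy(dtype=float),
        disease_label=labels,
        verified=df[verified].to_numpy(),
        covariates=df[list(covariates)].astype(float),
    )


def prepare(raw: RawDataset, class_order: Sequence | None = None) -> PreparedDataset:
    """Encode disease labels as ordered codes 1/2/3 and build the indicator matrix.

    Exactly three distinct labels must occur among verified subjects. If
    ``class_order`` is given, it fixes the label -> 1/2/3 mapping explicitly;
    otherwise labels are ordered by ascending class-conditional mean of the
    test among verified subjects, matching the monotone-ordering assumption
    (higher test values indicate more severe disease).
    """
    mask = raw.verified == 1
    observed = raw.disease_label[mask]
    classes = sorted(set(observed), key=lambda x: str(x))
    if len(classes) != 3:
        raise ValueError(
            f"expected exactly 3 disease classes among verified subjects, "
            f"found {len(classes)}: {classes}"
        )
    if class_order is not None:
        if sorted(map(str, class_order)) != sorted(map(str, classes)):
            raise ValueError("class_order must list the three observed labels")
        ordered = list(class_order)
    else:
        means = {
            c: raw.test[mask & (raw.disease_label == c)].mean() for c in classes
        }
        ordered = sorted(classes, key=lambda c: means[c])
    mapping = {label: k + 1 for k, label in enumerate(ordered)}

    code = np.full(raw.n, np.nan)
    for label, k in mapping.items():
        code[mask & (raw.disease_label == label)] = k
    dmat = np.full((raw.n, 3), np.nan)
    for k in (1, 2, 3):
        dmat[mask, k - 1] = (code[mask] == k).astype(float)
    return PreparedDataset(
        test=raw.test.copy(),
        verified=raw.verified.copy(),
        covariates=raw.covariates.copy(),
        disease_code=code,
        disease_matrix=dmat,
        class_mapping=mapping,
        true_label=None if raw.true_label is None else raw.true_label.copy(),
    )


def check_monotone_ordering(data: PreparedDataset) -> OrderingReport:
    """Check that class-conditional mean test values strictly increase with code.

    The check uses sample means of ``T`` among verified subjects per class.
    A failed check is reported, never raised: downstream analyses remain
    callable, but their monotone-ordering premise is then unsupported.

    Raises
    ------
    ValueError
        If some class has no verified subject (its mean is undefined).
    """
    means = []
    for k in (1, 2, 3):
        sel = (data.verified == 1) & (data.disease_code == k)
        if not sel.any():
            raise ValueError(f"class {k} has no verified subjects; ordering undefined")
        means.append(float(data.test[sel].mean()))
    satisfied = means[0] < means[1] < means[2]
    if satisfied:
        msg = (
            "monotone ordering satisfied: class-conditional mean test values "
            f"{means[0]:.4g} < {means[1]:.4g} < {means[2]:.4g}"
        )
    else:
        msg = (
            "monotone ordering NOT satisfied: class-conditional mean test values "
            f"are {means[0]:.4g}, {means[1]:.4g}, {means[2]:.4g}; consider "
            "relabeling the classes (e.g. via class_order) so that mean test "
            "values increase with severity"
        )
    return OrderingReport(class_means=tuple(means), satisfied=satisfied, message=msg)
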