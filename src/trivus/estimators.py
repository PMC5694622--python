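"""Bias-corrected disease matrices.

Every estimator of the ROC surface and its volume consumes the same object:
an n x 3 matrix ``D_hat`` of corrected disease values, one column per class.
With D the observed indicator matrix, V the verification indicator,
rho_k the fitted disease probabilities and pi the fitted verification
probabilities, the corrections are

* ``full``  D_hat = D                  (requires complete verification)
* ``fi``    D_hat_ki = rho_ki          (full imputation)
* ``msi``   D_hat_ki = V_i D_ki + (1 - V_i) rho_ki   (mean score imputation)
* ``ipw``   D_hat_ki = V_i D_ki / pi_i (inverse probability weighting)
* ``spe``   D_hat_ki = V_i D_ki / pi_i - (V_i - pi_i) rho_ki / pi_i
* ``knn``   as ``msi`` with rho from the K-nearest-neighbour fit

The SPE (semiparametric efficient) rows are doubly robust — consistent if
either the disease model or the verification model is correct — and may lie
outside [0, 1]; they are deliberately not clipped, since clipping would
destroy the unbiasedness that defines the estimator. IPW rows for
unverified subjects are exact zeros so that downstream sums need no special
casing; the VUS and TCF estimators normalize by column sums (ratio form),
which makes the zero convention harmless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_prep import PreparedDataset
from .models import DiseaseProbabilityFit, VerificationFit

__all__ = ["CorrectedDisease", "corrected_disease", "METHODS"]

METHODS = ("full", "fi", "msi", "ipw", "spe", "knn")


@dataclass
class CorrectedDisease:
    """n x 3 corrected disease matrix plus provenance."""

    dhat: np.ndarray
    method: str
    rho_fit: DiseaseProbabilityFit | None = field(default=None, repr=False)
    verif_fit: VerificationFit | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.dhat.shape[0]


def corrected_disease(
    method: str,
    data: PreparedDataset,
    rho: DiseaseProbabilityFit | None = None,
    verif: VerificationFit | None = None,
) -> CorrectedDisease:
    """Build the corrected disease matrix for one estimation method.

    Parameters
    ----------
    method
        One of ``full``, ``fi``, ``msi``, ``ipw``, ``spe``, ``knn``.
    rho
        Disease-probability fit; required for fi/msi/spe (multinomial
        logistic) and knn (K-nearest-neighbour).
    verif
        Verification-probability fit; required for ipw/spe.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    v = data.verified.astype(float)[:, None]
    if method == "full":
        if (data.verified == 0).any():
            raise ValueError("method 'full' requires every subject to be verified")
        return CorrectedDisease(dhat=data.disease_matrix.copy(), method=method)

    if method in ("fi", "msi", "spe") and (rho is None or rho.method != "mlogit"):
        raise ValueError(f"method {method!r} requires a multinomial-logit rho fit")
    if method == "knn" and (rho is None or rho.method != "knn"):
        raise ValueError("method 'knn' requires a K-nearest-neighbour rho fit")
    if method in ("ipw", "spe") and verif is None:
        raise ValueError(f"method {method!r} requires a verification fit")

    # Observed indicators with unverified rows zeroed: they only ever enter
    # multiplied by V, so the NaN placeholders must not propagate.
    d_obs = np.nan_to_num(data.disease_matrix, nan=0.0)

    if method == "fi":
        dhat = rho.rho.copy()
    elif method in ("msi", "knn"):
        dhat = v * d_obs + (1.0 - v) * rho.rho
    elif method == "ipw":
        dhat = v * d_obs / verif.pi[:, None]
    else:  # spe
        pi = verif.pi[:, None]
        dhat = v * d_obs / pi - (v - pi) * rho.rho / pi
    return CorrectedDisease(dhat=dhat, method=method, rho_fit=rho, verif_fit=verif)
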