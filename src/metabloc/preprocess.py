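"""Dilution normalization (PQN) and feature autoscaling.

Probabilistic quotient normalization divides each sample by the median
ratio of its intensities to a reference spectrum (the per-metabolite
median across samples), removing per-sample dilution differences that
dominate raw urine intensities.  Autoscaling then centers each
metabolite to mean 0 and unit sample variance.  The contract is PQN
first, autoscaling second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

__all__ = ["PqnResult", "pqn_normalize", "Autoscaler", "autoscale"]


@dataclass
class PqnResult:
    normalized: FeatureMatrix
    reference_spectrum: pd.Series
    dilution_coefficients: pd.Series


def pqn_normalize(matrix: FeatureMatrix) -> PqnResult:
    """Probabilistic quotient normalization against the pooled median spectrum.

    For sample i: quotients q_ij = x_ij / ref_j over metabolites with a
    positive reference; the dilution coefficient c_i is the median
    quotient; the normalized row is x_i / c_i.  Re-application is the
    identity (all coefficients 1).
    """
    if matrix.state == "autoscaled":
        raise ValueError("PQN must run on raw (or pqn) intensities, not autoscaled data")
    x = matrix.values
    if np.isnan(x).any():
        raise ValueError(
            "missing intensities present; impute or filter metabolites upstream before PQN"
        )
    if (x <= 0).any():
        raise ValueError(
            "non-positive intensities present; filter or re-process upstream before PQN"
        )
    # single-sample degenerate case: the reference is the sample itself
    ref = np.median(x, axis=0)
    usable = ref > 0
    if not usable.any():
        raise ValueError("reference spectrum is identically zero")
    quotients = x[:, usable] / ref[usable]
    coeff = np.median(quotients, axis=1)
    normalized = x / coeff[:, None]
    return PqnResult(
        normalized=FeatureMatrix(
            pd.DataFrame(normalized, index=matrix.data.index, columns=matrix.data.columns),
            state="pqn",
        ),
        reference_spectrum=pd.Series(ref, index=matrix.data.columns, name="reference"),
        dilution_coefficients=pd.Series(coeff, index=matrix.data.index, name="coefficient"),
    )


class Autoscaler:
    """Column-wise center/unit-variance scaler with reusable parameters.

    Parameters estimated by :meth:`fit` can be re-applied to held-out
    samples (e.g. test folds during cross-validation) so no information
    leaks from validation rows into the scaling.
    Constant columns (sd == 0) are dropped with a warning.
    """

    def __init__(self) -> None:
        self.means_: pd.Series | None = None
        self.scales_: pd.Series | None = None
        self.dropped_: list[str] = []

    def fit(self, data: pd.DataFrame) -> "Autoscaler":
        if len(data) < 2:
            raise ValueError("autoscaling needs at least 2 samples (sd undefined)")
        means = data.mean(axis=0)
        sds = data.std(axis=0, ddof=1)
        # numerically-constant columns (sd at rounding level of the mean)
        constant = sds <= 1e-12 * (1.0 + means.abs())
        self.dropped_ = list(data.columns[constant])
        if self.dropped_:
            warnings.warn(
                f"dropping {len(self.dropped_)} constant column(s): {self.dropped_[:5]}...",
                UserWarning,
                stacklevel=2,
            )
        keep = ~constant
        self.means_ = means[keep]
        self.scales_ = sds[keep]
        return self

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        if self.means_ is None or self.scales_ is None:
            raise ValueError("Autoscaler is not fitted")
        return (data[self.means_.index] - self.means_) / self.scales_

    def fit_transform(self, data: pd.DataFrame) -> pd.DataFrame:
        return self.fit(data).transform(data)


def autoscale(matrix: FeatureMatrix) -> tuple[FeatureMatrix, Autoscaler]:
    """Autoscale a feature matrix; returns the scaled matrix and the scaler."""
    scaler = Autoscaler()
    scaled = scaler.fit_transform(matrix.data)
    return FeatureMatrix(scaled, state="autoscaled"), scaler
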