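"""Per-gene feature matrix combining mean and variability signals.

For a gene with n CpGs measured on 2N samples, the mean block X^m holds the
raw beta values and the variability block X^v holds squared deviations of
each sample from its own group's CpG mean. The concatenation [X^m, X^v] is
column-standardized so that mean differences and variance differences enter
the distance on a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class FeatureMatrix:
    """Standardized [X^m, X^v] block matrix for one gene.

    ``values`` has shape (2N, 2n): the first ``n_cpg`` columns are the
    standardized methylation values, the last ``n_cpg`` the standardized
    variability scores. Constant columns standardize to all-zero.
    """

    values: np.ndarray
    n_cpg: int
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=int)
        if self.values.shape[1] != 2 * self.n_cpg:
            raise ValueError("feature matrix must have 2 * n_cpg columns")
        if self.values.shape[0] != self.group_labels.size:
            raise ValueError("row count must match number of labels")

    @property
    def mean_block(self) -> np.ndarray:
        return self.values[:, : self.n_cpg]

    @property
    def var_block(self) -> np.ndarray:
        return self.values[:, self.n_cpg:]


def group_means(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample matrix of the CpG means of each sample's own group."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    out = np.empty_like(x)
    for g in (0, 1):
        rows = labels == g
        if not rows.any():
            raise ValueError(f"group {g} is empty")
        out[rows] = x[rows].mean(axis=0)
    return out


def variability_scores(xm: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Squared deviation of each value from its group's CpG mean.

    Encodes a variance difference between groups as a mean difference of the
    scores, which is what lets a distance on means pick up differential
    variability.
    """
    xm = np.asarray(xm, dtype=float)
    return (xm - group_means(xm, labels)) ** 2


def standardize_columns(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Column z-scores over all samples; constant columns become zero."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    # exact max == min: robust to rounding in the mean of identical values
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s) standardized to zero",
            stacklevel=2,
        )
    sd = np.where(constant | (sd == 0), 1.0, sd)
    z = (x - mu) / sd
    z[:, constant] = 0.0
    return z


def assemble_xmv(x: np.ndarray, labels: np.ndarray) -> FeatureMatrix:
    """Build the standardized 2N x 2n feature matrix for one gene.

    ``x`` is the (2N, n) beta-value block of the gene in canonical sample
    order; ``labels`` the matching 0/1 group vector. The variability block
    depends on the labels and is recomputed under every label permutation.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if x.shape[0] != labels.size:
        raise ValueError("sample count mismatch between x and labels")
    xv = variability_scores(x, labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = standardize_columns(np.hstack([x, xv]))
    return FeatureMatrix(values, n_cpg=x.shape[1], group_labels=labels)
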