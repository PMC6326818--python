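"""Pairwise epigenetic distance matrices.

Every variant is a weighted Euclidean distance on the standardized feature
matrix: d_st^2 = sum_j c_j^m (x_sj^m - x_tj^m)^2 + c_j^v (x_sj^v - x_tj^v)^2.
The coefficients select the variant:

=========  ==============  ==============
variant    c_j^m           c_j^v
=========  ==============  ==============
DM-DV      1 / (2n)        1 / (2n)
w-DM-DV    w_j^m / 2       w_j^v / 2
DM         1 / n           0
w-DM       w_j^m           0
DV         0               1 / n
w-DV       0               w_j^v
=========  ==============  ==============

Single-block variants renormalize so the coefficients still sum to one;
pseudo-F and permutation p-values are invariant to that overall scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .features import FeatureMatrix
from .weights import SiteWeights

VARIANTS = ("w-DM-DV", "w-DM", "w-DV", "DM-DV", "DM", "DV")
WEIGHTED_VARIANTS = ("w-DM-DV", "w-DM", "w-DV")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative dissimilarity matrix for one gene."""

    d: np.ndarray
    variant: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any() or not np.isfinite(self.d).all():
            raise ValueError("distances must be finite and nonnegative")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must have zero diagonal")


def variant_coefficients(variant: str, n_cpg: int,
                         weights: SiteWeights | None):
    """Return the (c^m, c^v) coefficient vectors of a distance variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    weighted = variant in WEIGHTED_VARIANTS
    if weighted and weights is None:
        raise ValueError(f"variant {variant!r} requires site weights")
    if not weighted and weights is not None:
        raise ValueError(f"variant {variant!r} takes no weights")
    n = n_cpg
    if variant == "DM-DV":
        return np.full(n, 1 / (2 * n)), np.full(n, 1 / (2 * n))
    if variant == "w-DM-DV":
        return weights.w_m / 2, weights.w_v / 2
    if variant == "DM":
        return np.full(n, 1 / n), np.zeros(n)
    if variant == "w-DM":
        return weights.w_m.copy(), np.zeros(n)
    if variant == "DV":
        return np.zeros(n), np.full(n, 1 / n)
    return np.zeros(n), weights.w_v.copy()  # w-DV


def rescaled_features(fm: FeatureMatrix, variant: str,
                      weights: SiteWeights | None) -> np.ndarray:
    """Column-rescale the feature matrix so plain Euclidean distance on the
    result equals the variant's weighted distance."""
    c_m, c_v = variant_coefficients(variant, fm.n_cpg, weights)
    scale = np.sqrt(np.concatenate([c_m, c_v]))
    return fm.values * scale


def distance_matrix(fm: FeatureMatrix, weights: SiteWeights | None = None,
                    variant: str = "w-DM-DV") -> DistanceMatrix:
    """Compute one gene's 2N x 2N distance matrix for the given variant.

    Computed in pairwise-difference form (no Gram-matrix shortcut), so the
    entries are exactly nonnegative.
    """
    z = rescaled_features(fm, variant, weights)
    d = squareform(pdist(z, metric="euclidean"))
    return DistanceMatrix(d, variant)
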