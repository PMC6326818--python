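"""Distance-based regression: Gower centering and the pseudo-F statistic.

Association between a gene's distance matrix and the binary phenotype is
summarized by F = tr(HGH) / tr[(I-H) G (I-H)], where G is the Gower-centered
matrix of -d^2/2 and H the projection onto the raw 0/1 label vector. The
statistic has no known null distribution here; significance comes from
label permutations only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix


@dataclass
class GowerMatrix:
    """Double-centered inner-product matrix of a distance matrix."""

    g: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)


@dataclass
class PseudoF:
    """Pseudo-F value; ``undefined`` flags a nonpositive denominator
    (no dispersion), treated downstream as non-significant."""

    value: float
    undefined: bool = False


def gower_center(d: DistanceMatrix | np.ndarray) -> GowerMatrix:
    """G = C A C with A = -d^2/2 and C = I - 11^T/(2N).

    Row and column sums of G vanish; for Euclidean d, G is the Gram matrix
    of the column-centered embedding.
    """
    dm = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    a = -0.5 * dm**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    return GowerMatrix(g)


def pseudo_f(g: GowerMatrix | np.ndarray, y: np.ndarray,
             convention: str = "raw") -> PseudoF:
    """Pseudo-F from a Gower matrix and 0/1 labels.

    Uses the closed forms tr(HGH) = tr(HG) = y^T G y / (y^T y) for the
    idempotent projection H = y (y^T y)^{-1} y^T on the raw 0/1 labels
    (``convention='raw'``), or on the centered labels with the classical
    PERMANOVA degrees-of-freedom scaling (``convention='permanova'``).
    """
    gm = g.g if isinstance(g, GowerMatrix) else np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    trg = float(np.trace(gm))
    quad = float(y @ gm @ y)
    n = y.size
    if convention == "raw":
        t = quad / float(y @ y)
        num, den = t, trg - t
    elif convention == "permanova":
        yc = y - y.mean()
        t = float(yc @ gm @ yc) / float(yc @ yc)
        num, den = t, (trg - t) / (n - 2)
    else:
        raise ValueError(f"unknown pseudo-F convention {convention!r}")
    if den <= 0:
        return PseudoF(np.nan, undefined=True)
    return PseudoF(num / den)


def feature_space_pseudo_f(z: np.ndarray, y: np.ndarray,
                           convention: str = "raw") -> PseudoF:
    """Pseudo-F computed entirely in (rescaled) feature space.

    For Euclidean distances on ``z`` this equals :func:`pseudo_f` on the
    Gower matrix: with column-centered Zc, tr(G) = ||Zc||_F^2 and
    y^T G y = ||Zc^T y||^2. O(N n) instead of O(N^2), used by the
    permutation engine.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    zc = z - z.mean(axis=0)
    trg = float((zc**2).sum())
    quad = float(((zc.T @ y) ** 2).sum())
    n = y.size
    if convention == "raw":
        t = quad / float(y @ y)
        num, den = t, trg - t
    elif convention == "permanova":
        yc = y - y.mean()
        t = float(((zc.T @ yc) ** 2).sum()) / float(yc @ yc)
        num, den = t, (trg - t) / (n - 2)
    else:
        raise ValueError(f"unknown pseudo-F convention {convention!r}")
    if den <= 0:
        return PseudoF(np.nan, undefined=True)
    return PseudoF(num / den)
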