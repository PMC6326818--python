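"""CpG site-level tests and -log10(p) weights.

Each CpG gets a mean weight from a two-sided two-sample t-test on the beta
values and a variance weight from a one-sided Levene test (cases more
variable). Weights are -log10(p) normalized to sum to one per signal type,
so strong site signals dominate the weighted distance and flat p-value
profiles reduce it to the unweighted one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: floor applied to p-values before taking -log10, keeps weights finite
P_FLOOR = 1e-300


@dataclass
class SiteWeights:
    """Per-CpG weights and the p-values they came from."""

    w_m: np.ndarray
    w_v: np.ndarray
    p_m: np.ndarray
    p_v: np.ndarray

    def __post_init__(self) -> None:
        for name in ("w_m", "w_v", "p_m", "p_v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.w_m.size
        if not (self.w_v.size == self.p_m.size == self.p_v.size == n):
            raise ValueError("weight/p-value vectors must share one length")
        if (self.w_m < 0).any() or (self.w_v < 0).any():
            raise ValueError("weights must be nonnegative")


def _split(x: np.ndarray, labels: np.ndarray):
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=int)
    x = x[:, None] if x.ndim == 1 else x
    x0, x1 = x[labels == 0], x[labels == 1]
    if x0.shape[0] < 2 or x1.shape[0] < 2:
        raise ValueError("need at least 2 samples per group")
    return x0, x1


def pooled_t_pvalues(x0: np.ndarray, x1: np.ndarray,
                     alternative: str = "two-sided") -> np.ndarray:
    """Pooled-variance two-sample t-test p-values, columnwise.

    ``alternative='greater'`` tests group-1 mean > group-0 mean. Degenerate
    columns (zero pooled variance) give p = 1 when the means agree and the
    p-value floor otherwise.
    """
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    n0, n1 = x0.shape[0], x1.shape[0]
    df = n0 + n1 - 2
    diff = x1.mean(axis=0) - x0.mean(axis=0)
    ss = x0.var(axis=0, ddof=0) * n0 + x1.var(axis=0, ddof=0) * n1
    se = np.sqrt(ss / df * (1.0 / n0 + 1.0 / n1))
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.where(degenerate, 1.0, se)
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = np.where(degenerate, np.where(diff == 0, 1.0, P_FLOOR), p)
    return np.minimum(p, 1.0)


def site_mean_pvalue(x: np.ndarray, labels: np.ndarray,
                     welch: bool = False) -> np.ndarray:
    """Two-sided t-test p-value per CpG for a case/control mean difference.

    Pooled-variance Student test by default; ``welch=True`` switches to the
    unequal-variance form.
    """
    x0, x1 = _split(x, labels)
    if welch:
        res = stats.ttest_ind(x1, x0, axis=0, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        return p if np.asarray(x).ndim > 1 else float(p[0])
    p = pooled_t_pvalues(x0, x1, "two-sided")
    return p if np.asarray(x).ndim > 1 else float(p[0])


def site_variance_pvalue(x: np.ndarray, labels: np.ndarray,
                         center: str = "mean") -> np.ndarray:
    """One-sided Levene p-value per CpG: variance greater in cases.

    Two-group Levene reduces to a t-test on absolute deviations from the
    group center; the one-sided alternative is case deviations larger.
    ``center='median'`` gives the Brown-Forsythe variant.
    """
    if center not in ("mean", "median"):
        raise ValueError(f"unknown Levene center {center!r}")
    x0, x1 = _split(x, labels)
    loc = np.median if center == "median" else np.mean
    d0 = np.abs(x0 - loc(x0, axis=0))
    d1 = np.abs(x1 - loc(x1, axis=0))
    p = pooled_t_pvalues(d0, d1, "greater")
    return p if np.asarray(x).ndim > 1 else float(p[0])


def neglog10_weights(p: np.ndarray) -> np.ndarray:
    """Normalize -log10(p) to sum to one; equal weights if all p = 1."""
    p = np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0)
    logs = -np.log10(p)
    total = logs.sum()
    if total <= 0:
        return np.full(p.size, 1.0 / p.size)
    return logs / total


def compute_weights(p_m: np.ndarray, p_v: np.ndarray) -> SiteWeights:
    """Build normalized mean and variance weights from site p-values."""
    p_m = np.asarray(p_m, dtype=float)
    p_v = np.asarray(p_v, dtype=float)
    return SiteWeights(neglog10_weights(p_m), neglog10_weights(p_v), p_m, p_v)


def site_weights(x: np.ndarray, labels: np.ndarray, welch: bool = False,
                 levene_center: str = "mean") -> SiteWeights:
    """Convenience: run both site tests on a gene block and form weights."""
    p_m = site_mean_pvalue(x, labels, welch=welch)
    p_v = site_variance_pvalue(x, labels, center=levene_center)
    return compute_weights(np.atleast_1d(p_m), np.atleast_1d(p_v))
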