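"""Site-level EWAS baselines and the gene-level min-P comparator.

The baselines test every CpG separately (two-sided t-test for mean signals,
one-sided Levene for variance signals) and adjust for the number of CpGs in
the gene by Bonferroni multiplication. The min-P comparator takes the
minimum adjusted p-value over both signal types; it is the site-level
counterpart of the distance test and pays a multiplicity penalty that grows
with gene size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .weights import site_mean_pvalue, site_variance_pvalue


@dataclass
class EwasGeneResult:
    """Gene-level min-P summary: the best Bonferroni-adjusted site p-value
    and which CpG/test produced it."""

    gene: str
    n_cpg: int
    p_gene: float
    top_cpg: str
    top_signal: str


def ewas_site_scan(x: np.ndarray, labels: np.ndarray, mode: str = "both"):
    """Per-CpG p-values on a (samples x CpGs) gene block.

    ``mode='DM'`` returns mean-test p-values, ``'DV'`` variance-test
    p-values, ``'both'`` the pair (p_m, p_v). Shares the test
    implementations of the weights module.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if mode == "DM":
        return np.atleast_1d(site_mean_pvalue(x, labels))
    if mode == "DV":
        return np.atleast_1d(site_variance_pvalue(x, labels))
    if mode == "both":
        return (np.atleast_1d(site_mean_pvalue(x, labels)),
                np.atleast_1d(site_variance_pvalue(x, labels)))
    raise ValueError(f"unknown mode {mode!r}")


def bonferroni_min_p(p: np.ndarray, n: int) -> float:
    """min over sites of min(1, n * p) -- the gene-level p of one mode."""
    p = np.asarray(p, dtype=float)
    return float(np.minimum(n * p, 1.0).min())


def ewas_min_p(p_m: np.ndarray, p_v: np.ndarray, n: int | None = None,
               gene: str = "", cpg_ids=None) -> EwasGeneResult:
    """Gene-level min-P over both signal types.

    Each site p-value is multiplied by the gene's CpG count ``n`` and capped
    at 1; the gene p-value is the minimum over all 2n adjusted values. Ties
    resolve to the first index, mean before variance.
    """
    p_m = np.asarray(p_m, dtype=float)
    p_v = np.asarray(p_v, dtype=float)
    if p_m.size != p_v.size or p_m.size == 0:
        raise ValueError("p_m and p_v must be nonempty and equally long")
    if n is None:
        n = p_m.size
    adj = np.minimum(n * np.concatenate([p_m, p_v]), 1.0)
    k = int(np.argmin(adj))
    site = k % p_m.size
    signal = "mean" if k < p_m.size else "variance"
    top = cpg_ids[site] if cpg_ids is not None else f"cpg_{site + 1}"
    return EwasGeneResult(gene=gene, n_cpg=int(n), p_gene=float(adj[k]),
                          top_cpg=str(top), top_signal=signal)
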