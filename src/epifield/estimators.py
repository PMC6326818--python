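"""scikit-learn style estimator facades.

``DistanceAssociationTest`` runs the permutation-based distance test on a
(samples x CpGs) matrix with binary labels; ``EwasTest`` runs the
site-level baselines. Both follow the sklearn contract (``get_params`` /
``set_params``, ``fit`` returning self, fitted attributes with trailing
underscores) and compose with ``sklearn.base.clone``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, check_X_y

from .distances import VARIANTS
from .ewas import ewas_min_p, ewas_site_scan
from .inference import (call_significant, permutation_test_arrays,
                        pooled_empirical_pvalues, results_table)


def _normalize_gene_map(gene_map, n_features):
    if gene_map is None:
        return {"gene_1": list(range(n_features))}
    gm = {str(g): list(map(int, ix)) for g, ix in dict(gene_map).items()}
    for g, ix in gm.items():
        if not ix or min(ix) < 0 or max(ix) >= n_features:
            raise ValueError(f"gene {g!r} has invalid CpG indices")
    return gm


def _check_inputs(X, y):
    X, y = check_X_y(X, y, dtype=float, ensure_min_samples=4)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("y must contain both labels 0 (control) and 1 (case)")
    return X, y.astype(int)


class DistanceAssociationTest(BaseEstimator):
    """Gene-level weighted epigenetic distance association test.

    Parameters
    ----------
    variant : one of {"w-DM-DV", "w-DM", "w-DV", "DM-DV", "DM", "DV"}
        Which distance matrix to test. Weighted variants recompute site
        weights under every permutation.
    n_permutations : int
        Number of global label shuffles (999 reproduces the reference
        protocol).
    alpha, correction : significance threshold on the pooled empirical
        p-values and the across-gene adjustment ("none" or "bonferroni").
    f_convention : "raw" builds the pseudo-F projection from the raw 0/1
        label vector; "permanova" uses the centered-label form with
        degrees-of-freedom scaling.
    random_state : seed for the permutation stream.

    Attributes
    ----------
    genes_, f_statistic_, p_values_, significant_ : per-gene outputs.
    results_ : ranked :class:`pandas.DataFrame` of the same.
    """

    def __init__(self, variant: str = "w-DM-DV", n_permutations: int = 999,
                 alpha: float = 0.05, correction: str = "none",
                 pooling: str = "plus-one", f_convention: str = "raw",
                 engine: str = "fast", random_state: int | None = 0):
        self.variant = variant
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.correction = correction
        self.pooling = pooling
        self.f_convention = f_convention
        self.engine = engine
        self.random_state = random_state

    def fit(self, X, y, gene_map=None):
        """Run the test.

        ``gene_map`` maps gene name -> column indices of its CpGs; by
        default all columns form a single gene.
        """
        X, y = _check_inputs(X, y)
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        gm = _normalize_gene_map(gene_map, X.shape[1])
        pr = permutation_test_arrays(
            X, y, gm, variant=self.variant, n_perm=self.n_permutations,
            seed=self.random_state, f_convention=self.f_convention,
            engine=self.engine)
        self.permutation_result_ = pr
        self.genes_ = list(pr.genes)
        self.f_statistic_ = pr.observed_f.copy()
        self.p_values_ = pooled_empirical_pvalues(pr, self.pooling)
        self.significant_ = call_significant(self.p_values_, self.alpha,
                                             self.correction)
        rows = results_table(pr, self.pooling)
        self.results_ = pd.DataFrame([vars(r) for r in rows])
        return self

    def predict(self, X=None):
        """Boolean significance call per gene (X is ignored; the test is
        fit on the full design)."""
        check_is_fitted(self, "p_values_")
        return self.significant_.copy()


class EwasTest(BaseEstimator):
    """Site-level EWAS baseline with per-gene Bonferroni min-P summary.

    ``mode`` selects the signal tested per CpG: "DM" (two-sided t-test),
    "DV" (one-sided Levene) or "min-P" (minimum over both).
    """

    def __init__(self, mode: str = "min-P", alpha: float = 0.05,
                 correction: str = "none"):
        self.mode = mode
        self.alpha = alpha
        self.correction = correction

    def fit(self, X, y, gene_map=None, cpg_ids=None):
        X, y = _check_inputs(X, y)
        if self.mode not in ("DM", "DV", "min-P"):
            raise ValueError(f"unknown mode {self.mode!r}")
        gm = _normalize_gene_map(gene_map, X.shape[1])
        rows = []
        for gene, ix in gm.items():
            xg = X[:, ix]
            n = len(ix)
            ids = ([cpg_ids[i] for i in ix] if cpg_ids is not None
                   else [f"cpg_{i + 1}" for i in ix])
            p_m, p_v = ewas_site_scan(xg, y, "both")
            if self.mode == "DM":
                res = ewas_min_p(p_m, np.ones(n), n, gene, ids)
            elif self.mode == "DV":
                res = ewas_min_p(np.ones(n), p_v, n, gene, ids)
            else:
                res = ewas_min_p(p_m, p_v, n, gene, ids)
            rows.append(vars(res))
        self.results_ = pd.DataFrame(rows)
        self.genes_ = list(self.results_["gene"])
        self.p_values_ = self.results_["p_gene"].to_numpy()
        self.significant_ = call_significant(self.p_values_, self.alpha,
                                             self.correction)
        return self

    def predict(self, X=None):
        check_is_fitted(self, "p_values_")
        return self.significant_.copy()
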