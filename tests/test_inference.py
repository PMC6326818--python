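"""Permutation engine, pooled empirical p-values, significance calls."""

import numpy as np
import pytest

from epifield.data import CpGAnnotation, MethylationDataset, PhenotypeVector
from epifield.inference import (PermutationResult, batch_pseudo_f,
                                call_significant, label_configurations,
                                permutation_test_arrays,
                                pooled_empirical_pvalues, reference_pseudo_f,
                                results_table, run_permutations)
from epifield.simulate import null_scenario, simulate_dataset


def make_pr(observed, perm, n_perm=None):
    observed = np.asarray(observed, dtype=float)
    perm = np.asarray(perm, dtype=float)
    return PermutationResult(
        genes=[f"g{i}" for i in range(observed.size)],
        n_cpg=np.ones(observed.size, dtype=int),
        observed_f=observed, perm_f=perm,
        n_perm=n_perm or perm.shape[1], seed=0, variant="w-DM-DV")


class TestPooledPvalues:
    def test_top_ranked_boundary(self):
        """Observed F above all 999 permuted values: p = 1/1000."""
        pr = make_pr([10.0], np.linspace(0, 1, 999)[None, :])
        assert pooled_empirical_pvalues(pr)[0] == pytest.approx(0.001)

    def test_bottom_ranked_boundary(self):
        pr = make_pr([-1.0], np.linspace(0, 1, 999)[None, :])
        assert pooled_empirical_pvalues(pr)[0] == pytest.approx(1.0)

    def test_two_gene_pooling(self):
        """Gene pools are shared: the minimum attainable p is 1/(n_perm+1)."""
        perm = np.vstack([np.linspace(0, 1, 999), np.linspace(0, 2, 999)])
        pr = make_pr([10.0, 0.0], perm)
        p = pooled_empirical_pvalues(pr)
        assert p[0] == pytest.approx(2 / 2000)
        assert p.min() >= 2 / 2000

    def test_ties_count_against_significance(self):
        pr = make_pr([1.0], np.array([[1.0, 0.5, 0.2]]))
        # one tie + the formula's +1 over 4 configurations
        assert pooled_empirical_pvalues(pr)[0] == pytest.approx(2 / 4)

    def test_undefined_permuted_never_exceed(self):
        pr = make_pr([1.0], np.array([[np.nan, 0.5, np.nan]]))
        assert pooled_empirical_pvalues(pr)[0] == pytest.approx(1 / 4)

    def test_undefined_observed_is_nonsignificant(self):
        pr = make_pr([np.nan], np.array([[0.1, 0.2, 0.3]]))
        assert pooled_empirical_pvalues(pr)[0] == 1.0

    def test_monotone_in_observed_f(self, rng):
        perm = rng.random((1, 99))
        p_lo = pooled_empirical_pvalues(make_pr([0.3], perm))[0]
        p_hi = pooled_empirical_pvalues(make_pr([0.7], perm))[0]
        assert p_hi <= p_lo

    def test_pooled_observed_alternative(self):
        pr = make_pr([10.0, 0.0], np.vstack([np.linspace(0, 1, 9),
                                             np.linspace(0, 2, 9)]))
        p = pooled_empirical_pvalues(pr, pooling="pooled-observed")
        # top gene: only itself among the 2 observed + 18 permuted >= 10
        assert p[0] == pytest.approx(1 / 20)


class TestCallSignificant:
    def test_plain_threshold(self):
        calls = call_significant(np.array([0.0004, 0.02]), 0.0005, "none")
        assert list(calls) == [True, False]

    def test_bonferroni_ten_genes(self):
        p = np.full(10, 0.004)
        assert call_significant(p, 0.05, "bonferroni").all()
        p[0] = 0.006
        assert not call_significant(p, 0.05, "bonferroni")[0]

    def test_bonferroni_genomewide_cutoff(self):
        cutoff = 0.05 / 19271
        p = np.full(19271, 1.0)
        p[0] = cutoff * 0.9
        assert call_significant(p, 0.05, "bonferroni")[0]
        assert call_significant(p, 0.05, "bonferroni").sum() == 1


class TestEngine:
    def test_fast_equals_reference_engine(self, rng):
        """The vectorized engine reproduces the naive per-permutation walk
        through features/weights/distances/Gower, for every variant."""
        x = rng.beta(5, 5, size=(16, 4))
        y = np.array([0] * 8 + [1] * 8)
        gm = {"g1": [0, 1, 2], "g2": [3]}
        from epifield.distances import VARIANTS
        for variant in VARIANTS:
            fast = permutation_test_arrays(x, y, gm, variant, n_perm=8,
                                           seed=7, engine="fast")
            ref = permutation_test_arrays(x, y, gm, variant, n_perm=8,
                                          seed=7, engine="reference")
            assert np.allclose(fast.observed_f, ref.observed_f,
                               atol=1e-10, equal_nan=True)
            assert np.allclose(fast.perm_f, ref.perm_f, atol=1e-10,
                               equal_nan=True)

    def test_identity_shuffle_reproduces_observed(self, rng):
        x = rng.beta(5, 5, size=(12, 3))
        y = np.array([0] * 6 + [1] * 6)
        f = batch_pseudo_f(x, np.vstack([y, y]), ["w-DM-DV"])["w-DM-DV"]
        assert f[0] == pytest.approx(f[1], rel=1e-12)
        assert f[0] == pytest.approx(reference_pseudo_f(x, y, "w-DM-DV"),
                                     rel=1e-10)

    def test_same_seed_bit_identical(self, rng):
        x = rng.beta(5, 5, size=(12, 3))
        y = np.array([0] * 6 + [1] * 6)
        a = permutation_test_arrays(x, y, {"g": [0, 1, 2]}, n_perm=20, seed=5)
        b = permutation_test_arrays(x, y, {"g": [0, 1, 2]}, n_perm=20, seed=5)
        assert np.array_equal(a.observed_f, b.observed_f)
        assert np.array_equal(a.perm_f, b.perm_f)

    def test_different_seeds_differ(self, rng):
        x = rng.beta(5, 5, size=(12, 3))
        y = np.array([0] * 6 + [1] * 6)
        a = permutation_test_arrays(x, y, {"g": [0, 1, 2]}, n_perm=20, seed=5)
        b = permutation_test_arrays(x, y, {"g": [0, 1, 2]}, n_perm=20, seed=6)
        assert not np.array_equal(a.perm_f, b.perm_f)

    def test_run_permutations_canonicalizes(self, rng):
        """Scrambled sample order gives the same result as controls-first."""
        sim = simulate_dataset(null_scenario(1, 3, n_cases=6, n_controls=6),
                               rng)
        ds, pheno, ann = sim.dataset, sim.phenotype, sim.annotation
        pr1 = run_permutations(ds, pheno, ann, n_perm=10, seed=3)
        order = np.random.default_rng(0).permutation(ds.n_samples)
        ds2 = ds.subset(sample_idx=order)
        pr2 = run_permutations(ds2, pheno, ann, n_perm=10, seed=3)
        # observed statistic is invariant to the sample order on disk
        assert np.allclose(pr1.observed_f, pr2.observed_f)
        assert pr2.perm_f.shape == pr1.perm_f.shape

    def test_null_calibration_superuniform(self):
        """Pooled empirical p-values of a single null gene are (super-)
        uniform up to Monte-Carlo error."""
        n_rep, n_perm, alpha = 500, 199, 0.05
        master = np.random.default_rng(12345)
        hits = 0
        for _ in range(n_rep):
            x = master.beta(46.36, 52.28, size=(20, 5))
            y = np.array([0] * 10 + [1] * 10)
            lab = label_configurations(y, n_perm, master)
            f = batch_pseudo_f(x, lab, ["w-DM-DV"])["w-DM-DV"]
            pr = make_pr([f[0]], f[None, 1:], n_perm)
            hits += pooled_empirical_pvalues(pr)[0] <= alpha
        rate = hits / n_rep
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= 4 * se

    def test_results_table_ranks(self):
        pr = make_pr([5.0, 1.0, 3.0], np.tile(np.linspace(0, 2, 99), (3, 1)))
        rows = results_table(pr)
        ranks = {r.gene: r.rank for r in rows}
        assert ranks == {"g0": 1, "g2": 2, "g1": 3}
        assert sorted(r.rank for r in rows) == [1, 2, 3]
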