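"""Containers, tabular I/O, grouping, coverage filtering, imputation."""

import numpy as np
import pandas as pd
import pytest

from epifield.data import (CpGAnnotation, GeneResult, MethylationDataset,
                           PhenotypeVector, ValidationError,
                           apply_coverage_filters, canonicalize,
                           group_cpgs_by_gene, impute_missing,
                           read_annotation, read_beta_matrix, read_phenotype,
                           read_results, write_results)


def write_beta_tsv(path, values, cpgs, samples):
    pd.DataFrame(values, index=cpgs, columns=samples).to_csv(path, sep="\t")


class TestBetaMatrixIO:
    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "beta.tsv"
        write_beta_tsv(path, np.full((3, 4), 0.5), ["c1", "c2", "c3"],
                       ["s1", "s2", "s3", "s4"])
        ds = read_beta_matrix(path)
        assert ds.beta.shape == (3, 4)
        assert ds.n_missing == 0
        assert np.all(ds.beta == 0.5)
        assert ds.cpg_ids == ["c1", "c2", "c3"]

    def test_transposed_dialect(self, tmp_path):
        path = tmp_path / "beta.tsv"
        write_beta_tsv(path, [[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]],
                       ["s1", "s2", "s3"], ["c1", "c2"])
        ds = read_beta_matrix(path, dialect="samples_in_rows")
        assert ds.cpg_ids == ["c1", "c2"]
        assert np.allclose(ds.beta[:, 0], [0.1, 0.2])

    @pytest.mark.parametrize("token", ["NA", "na", "NaN", "nan", ""])
    def test_na_tokens_become_missing(self, tmp_path, token):
        path = tmp_path / "beta.tsv"
        path.write_text(f"\ts1\ts2\nc1\t0.5\t{token}\nc2\t0.1\t0.2\n")
        ds = read_beta_matrix(path)
        assert ds.n_missing == 1
        assert np.isnan(ds.beta[0, 1])

    def test_out_of_range_value_names_the_cell(self, tmp_path):
        path = tmp_path / "beta.tsv"
        write_beta_tsv(path, [[0.5, 1.3]], ["c1"], ["s1", "s2"])
        with pytest.raises(ValidationError, match=r"c1.*s2"):
            read_beta_matrix(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            MethylationDataset(np.full((2, 2), 0.5), ["c1", "c1"], ["s1", "s2"])

    def test_unparseable_token_rejected(self, tmp_path):
        path = tmp_path / "beta.tsv"
        path.write_text("\ts1\nc1\tzero\n")
        with pytest.raises(ValidationError, match="zero"):
            read_beta_matrix(path)


class TestPhenotypeAndAnnotation:
    def test_phenotype_round_trip(self, tmp_path):
        path = tmp_path / "pheno.tsv"
        path.write_text("sample_id\tlabel\ns1\t0\ns2\t1\n")
        pv = read_phenotype(path)
        assert pv.labels == {"s1": 0, "s2": 1}

    def test_nonbinary_label_rejected(self):
        with pytest.raises(ValidationError):
            PhenotypeVector({"s1": 2})

    def test_missing_label_raises(self):
        pv = PhenotypeVector({"s1": 0})
        with pytest.raises(ValidationError, match="without phenotype"):
            pv.labels_for(["s1", "s2"])

    def test_annotation_multi_gene(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("cpg_id\tgene\nc1\tA\nc1\tB\nc2\tB\n")
        ann = read_annotation(path)
        assert ann.genes["c1"] == frozenset({"A", "B"})
        assert ann.genes["c2"] == frozenset({"B"})


class TestGrouping:
    def make_ds(self, n_cpg=2, n_samples=4):
        return MethylationDataset(np.full((n_cpg, n_samples), 0.5),
                                  [f"c{i}" for i in range(n_cpg)],
                                  [f"s{j}" for j in range(n_samples)])

    def test_single_gene(self):
        gm = group_cpgs_by_gene(self.make_ds(),
                                CpGAnnotation({"c0": {"A"}, "c1": {"A"}}))
        assert gm == {"A": [0, 1]}

    def test_multi_mapping_cpg_appears_in_every_gene(self):
        gm = group_cpgs_by_gene(self.make_ds(),
                                CpGAnnotation({"c0": {"A", "B"}, "c1": {"B"}}))
        assert gm == {"A": [0], "B": [0, 1]}

    def test_disjoint_annotation_errors(self):
        with pytest.raises(ValidationError, match="no annotated"):
            group_cpgs_by_gene(self.make_ds(), CpGAnnotation({"cX": {"A"}}))


class TestCoverageFilter:
    def make_ds(self, beta):
        beta = np.asarray(beta, dtype=float)
        return MethylationDataset(beta,
                                  [f"c{i}" for i in range(beta.shape[0])],
                                  [f"s{j}" for j in range(beta.shape[1])])

    def test_complete_matrix_unchanged(self):
        ds = self.make_ds(np.full((4, 10), 0.5))
        out = apply_coverage_filters(ds, 0.95, 0.70)
        assert out.beta.shape == (4, 10)

    def test_low_coverage_sample_removed(self):
        beta = np.full((10, 10), 0.5)
        beta[:5, 0] = np.nan  # sample s0 at 50% coverage
        out = apply_coverage_filters(self.make_ds(beta), 0.95, 0.70)
        assert "s0" not in out.sample_ids
        assert out.beta.shape == (10, 9)

    def test_cpg_filter_runs_after_sample_filter(self):
        # c0 passes the 0.70 threshold on the full data (7/10) but not after
        # the badly covered sample s0 -- which held a c0 value -- is dropped
        beta = np.full((10, 10), 0.5)
        beta[1:7, 0] = np.nan           # s0 at 40% CpG coverage -> dropped
        beta[0, 1:4] = np.nan           # c0 then covered 6/9 < 0.70
        out = apply_coverage_filters(self.make_ds(beta), 0.80, 0.70)
        assert "s0" not in out.sample_ids
        assert "c0" not in out.cpg_ids
        assert "c1" in out.cpg_ids

    def test_idempotent(self):
        beta = np.full((10, 10), 0.5)
        beta[:5, 0] = np.nan
        beta[0, :4] = np.nan
        once = apply_coverage_filters(self.make_ds(beta), 0.8, 0.7)
        twice = apply_coverage_filters(once, 0.8, 0.7)
        assert once.cpg_ids == twice.cpg_ids
        assert once.sample_ids == twice.sample_ids

    def test_everything_removed_errors(self):
        beta = np.full((2, 2), np.nan)
        beta[0, 0] = 0.5
        with pytest.raises(ValidationError):
            apply_coverage_filters(self.make_ds(beta), 1.0, 1.0)


class TestImputationAndCanonicalOrder:
    def test_group_mean_imputation(self):
        beta = np.array([[0.2, 0.4, np.nan, 0.8]])
        ds = MethylationDataset(beta, ["c1"], ["s1", "s2", "s3", "s4"])
        pheno = PhenotypeVector({"s1": 0, "s2": 0, "s3": 1, "s4": 1})
        out = impute_missing(ds, pheno)
        assert out.beta[0, 2] == pytest.approx(0.8)  # case-group mean

    def test_error_policy(self):
        ds = MethylationDataset(np.array([[np.nan, 0.5, 0.5, 0.5]]), ["c1"],
                                ["s1", "s2", "s3", "s4"])
        pheno = PhenotypeVector({"s1": 0, "s2": 0, "s3": 1, "s4": 1})
        with pytest.raises(ValidationError):
            impute_missing(ds, pheno, policy="error")

    def test_canonicalize_controls_first(self):
        beta = np.array([[0.1, 0.2, 0.3, 0.4]])
        ds = MethylationDataset(beta, ["c1"], ["a", "b", "c", "d"])
        pheno = PhenotypeVector({"a": 1, "b": 0, "c": 1, "d": 0})
        ds2, y = canonicalize(ds, pheno)
        assert ds2.sample_ids == ["b", "d", "a", "c"]
        assert list(y) == [0, 0, 1, 1]


class TestResultsIO:
    def test_round_trip(self, tmp_path):
        res = [GeneResult("A", 5, "w-DM-DV", 1.234567890123, 0.001, 1),
               GeneResult("B", 2, "w-DM-DV", 0.5, 0.25, 2)]
        path = tmp_path / "res.tsv"
        write_results(res, path)
        back = read_results(path)
        assert [r.gene for r in back] == ["A", "B"]
        assert back[0].pseudo_F == pytest.approx(1.234567890123, rel=1e-12)

    def test_single_row_file(self, tmp_path):
        path = tmp_path / "res.tsv"
        write_results([GeneResult("A", 1, "DM", 1.0, 0.5, 1)], path)
        assert len(path.read_text().strip().splitlines()) == 2

    def test_empty_list_errors(self, tmp_path):
        with pytest.raises(ValueError):
            write_results([], tmp_path / "res.tsv")
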