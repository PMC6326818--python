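"""Core data containers and tabular I/O.

The universal input is a methylation beta-value matrix (CpG sites x samples,
values in [0, 1]), a binary phenotype (0 = normal/control, 1 = normal-adjacent
/case) and a CpG -> gene annotation. All downstream matrices use a canonical
sample order of controls first, then cases, which makes permutation streams
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: tokens parsed as missing values (matched case-insensitively)
NA_TOKENS = ("", "na", "nan")


class ValidationError(ValueError):
    """Raised when an input table violates a dataset invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()][0]
        raise ValidationError(f"duplicate {what} {dup!r}")


@dataclass
class MethylationDataset:
    """Beta-value matrix with row (CpG) and column (sample) identifiers.

    ``beta`` is a float array of shape (n_cpgs, n_samples); missing entries
    are NaN, all other entries must lie in [0, 1].
    """

    beta: np.ndarray
    cpg_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.cpg_ids = list(self.cpg_ids)
        self.sample_ids = list(self.sample_ids)
        if self.beta.ndim != 2 or self.beta.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta shape {self.beta.shape} does not match "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        _check_unique(self.cpg_ids, "CpG id")
        _check_unique(self.sample_ids, "sample id")
        bad = (self.beta < 0) | (self.beta > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {self.beta[i, j]!r} outside [0, 1] at "
                f"CpG {self.cpg_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_cpgs(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.beta).sum())

    def subset(self, cpg_idx=None, sample_idx=None) -> "MethylationDataset":
        cpg_idx = np.arange(self.n_cpgs) if cpg_idx is None else np.asarray(cpg_idx)
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        return MethylationDataset(
            self.beta[np.ix_(cpg_idx, sample_idx)],
            [self.cpg_ids[i] for i in cpg_idx],
            [self.sample_ids[j] for j in sample_idx],
        )


@dataclass
class PhenotypeVector:
    """Binary case/control labels keyed by sample id (0 control, 1 case)."""

    labels: dict[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for sid, lab in dict(self.labels).items():
            lab = int(lab)
            if lab not in (0, 1):
                raise ValidationError(f"label for sample {sid!r} must be 0 or 1, got {lab}")
            clean[str(sid)] = lab
        self.labels = clean

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise ValidationError(f"samples without phenotype label: {missing[:5]}")
        return np.array([self.labels[s] for s in sample_ids], dtype=int)

    def validate_against(self, ds: MethylationDataset) -> None:
        y = self.labels_for(ds.sample_ids)
        if (y == 0).sum() < 2 or (y == 1).sum() < 2:
            raise ValidationError("need at least 2 samples per group")


@dataclass
class CpGAnnotation:
    """CpG id -> set of gene symbols (a CpG may belong to several genes)."""

    genes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean = {}
        for cpg, gs in dict(self.genes).items():
            gs = frozenset(str(g) for g in gs)
            if not gs or any(g == "" for g in gs):
                raise ValidationError(f"empty gene symbol for CpG {cpg!r}")
            clean[str(cpg)] = gs
        self.genes = clean


@dataclass
class GeneResult:
    """Per-gene outcome of one association method."""

    gene: str
    n_cpg: int
    method: str
    pseudo_F: float
    p_empirical: float
    rank: int = 0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path, delimiter=None) -> pd.DataFrame:
    if delimiter is None:
        return pd.read_csv(path, sep=None, engine="python", dtype=str,
                           keep_default_na=False, index_col=0)
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                       index_col=0)


def read_beta_matrix(path, dialect: str = "cpgs_in_rows",
                     delimiter: str | None = None) -> MethylationDataset:
    """Read a beta-value TSV/CSV (delimiter sniffed unless given).

    ``dialect`` says whether rows are CpGs (default) or samples. Blank cells
    and the tokens "NA"/"NaN" (any case) parse as missing.
    """
    if dialect not in ("cpgs_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_table(path, delimiter)
    if dialect == "samples_in_rows":
        df = df.T
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(raw):
        token = str(cell).strip()
        if token.lower() in NA_TOKENS:
            values[i, j] = np.nan
            continue
        try:
            values[i, j] = float(token)
        except ValueError:
            raise ValidationError(
                f"unparseable value {token!r} at CpG {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            ) from None
    return MethylationDataset(values, list(df.index), list(df.columns))


def read_phenotype(path, delimiter: str | None = None) -> PhenotypeVector:
    """Read a phenotype TSV with columns sample_id, label."""
    sep = delimiter if delimiter is not None else None
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.shape[1] < 2:
        raise ValidationError("phenotype file needs columns sample_id, label")
    return PhenotypeVector(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1])))


def read_annotation(path, delimiter: str | None = None) -> CpGAnnotation:
    """Read an annotation TSV with columns cpg_id, gene (one row per pair)."""
    sep = delimiter if delimiter is not None else None
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.shape[1] < 2:
        raise ValidationError("annotation file needs columns cpg_id, gene")
    genes: dict[str, set[str]] = {}
    for cpg, gene in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        genes.setdefault(cpg, set()).add(gene)
    return CpGAnnotation({c: frozenset(g) for c, g in genes.items()})


def write_results(results: Sequence[GeneResult], path) -> None:
    """Write gene results as TSV ordered by rank."""
    if not results:
        raise ValueError("no results to write")
    df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "n_cpg": r.n_cpg,
                "method": r.method,
                "pseudo_F": r.pseudo_F,
                "p_empirical": r.p_empirical,
                "rank": r.rank,
            }
            for r in sorted(results, key=lambda r: (r.method, r.rank))
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> list[GeneResult]:
    df = pd.read_csv(path, sep="\t")
    return [GeneResult(**row) for row in df.to_dict("records")]


# ---------------------------------------------------------------------------
# grouping / filtering / imputation
# ---------------------------------------------------------------------------

def group_cpgs_by_gene(ds: MethylationDataset, ann: CpGAnnotation) -> dict[str, list[int]]:
    """Map each annotated gene to the ordered row indices of its CpGs.

    CpGs without annotation are dropped; a CpG annotated to k genes appears
    in all k groups. Gene order follows first appearance along the CpG axis.
    """
    gene_map: dict[str, list[int]] = {}
    for idx, cpg in enumerate(ds.cpg_ids):
        for gene in sorted(ann.genes.get(cpg, ())):
            gene_map.setdefault(gene, []).append(idx)
    if not gene_map:
        raise ValidationError("no annotated CpGs in the dataset")
    return gene_map


def apply_coverage_filters(ds: MethylationDataset, min_sample_cov: float = 0.95,
                           min_cpg_cov: float = 0.70) -> MethylationDataset:
    """Drop poorly covered samples, then poorly covered CpGs.

    A sample must have at least ``min_sample_cov`` of its CpGs observed; a
    CpG must then have at least ``min_cpg_cov`` of the remaining samples
    observed. The two passes run in that order and the result is a fixed
    point of the filter.
    """
    for frac in (min_sample_cov, min_cpg_cov):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("coverage fractions must lie in [0, 1]")
    obs = ~np.isnan(ds.beta)
    keep_samples = np.flatnonzero(obs.mean(axis=0) >= min_sample_cov)
    if keep_samples.size == 0:
        raise ValidationError("coverage filter removed every sample")
    obs = obs[:, keep_samples]
    keep_cpgs = np.flatnonzero(obs.mean(axis=1) >= min_cpg_cov)
    if keep_cpgs.size == 0:
        raise ValidationError("coverage filter removed every CpG")
    return ds.subset(keep_cpgs, keep_samples)


def impute_missing(ds: MethylationDataset, pheno: PhenotypeVector,
                   policy: str = "group_mean") -> MethylationDataset:
    """Fill remaining missing entries per CpG with that CpG's group mean.

    ``policy='error'`` refuses missing data instead. A CpG entirely missing
    within one group falls back to the overall CpG mean.
    """
    if policy not in ("group_mean", "error"):
        raise ValueError(f"unknown imputation policy {policy!r}")
    if ds.n_missing == 0:
        return ds
    if policy == "error":
        raise ValidationError(f"{ds.n_missing} missing entries after filtering")
    beta = ds.beta.copy()
    y = pheno.labels_for(ds.sample_ids)
    for g in (0, 1):
        cols = y == g
        block = beta[:, cols]
        with np.errstate(invalid="ignore"):
            mean_g = np.nanmean(block, axis=1)
        overall = np.nanmean(beta, axis=1)
        mean_g = np.where(np.isnan(mean_g), overall, mean_g)
        miss = np.isnan(block)
        block[miss] = np.broadcast_to(mean_g[:, None], block.shape)[miss]
        beta[:, cols] = block
    return MethylationDataset(beta, ds.cpg_ids, ds.sample_ids)


def canonicalize(ds: MethylationDataset, pheno: PhenotypeVector):
    """Reorder samples to controls-first-then-cases; return (dataset, y).

    Ties keep the original file order inside each group, so the order (and
    with it every permutation stream) is fully determined by the input.
    """
    pheno.validate_against(ds)
    y = pheno.labels_for(ds.sample_ids)
    order = np.concatenate([np.flatnonzero(y == 0), np.flatnonzero(y == 1)])
    return ds.subset(sample_idx=order), y[order]
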