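"""Synthetic case-control 450K-style methylation data.

Beta values are drawn from beta distributions. Noise CpGs use the baseline
Beta(46.36, 52.28) in both groups -- mean 0.47, SD 0.05, matching average
moments of normal breast tissue on the 450K array. Signal CpGs shift the
case distribution: a mean signal adds ``mean_diff`` to the mean at fixed
SD, a variance signal multiplies the SD by ``sd_ratio`` at fixed mean, both
via method-of-moments re-solving of the shape parameters.

Field-defect-like scenarios draw each case at each signal CpG from a
Bernoulli(p) mixture: with probability p the case is an outlier whose value
comes from a shifted beta (default mean +0.2 at baseline SD), otherwise
from the baseline -- different cases can be outliers at different CpGs.
An optional AR(1) dependence among the CpGs of a gene is induced by a
Gaussian copula that preserves every CpG's beta marginal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data import CpGAnnotation, MethylationDataset, PhenotypeVector

#: baseline shape parameters (mean 0.47, SD 0.05)
BASELINE = None  # set below once BetaParams exists


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a beta distribution."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)
                and self.a > 0 and self.b > 0):
            raise ValueError("beta shape parameters must be positive and finite")


BASELINE = BetaParams(46.36, 52.28)
#: default mean shift of the outlier mixture component
DEFAULT_OUTLIER_SHIFT = 0.2


def beta_moments(params: BetaParams) -> tuple[float, float]:
    """(mean, SD) of Beta(a, b)."""
    a, b = params.a, params.b
    mean = a / (a + b)
    sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    return float(mean), float(sd)


def solve_beta_params(mean: float, sd: float) -> BetaParams:
    """Method-of-moments inversion: shapes with the given mean and SD."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly in (0, 1)")
    if not 0.0 < sd**2 < mean * (1.0 - mean):
        raise ValueError(f"sd {sd} infeasible for mean {mean}")
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return BetaParams(mean * nu, (1.0 - mean) * nu)


def signal_params(baseline: BetaParams, signal_type: str,
                  mean_diff: float = 0.0, sd_ratio: float = 1.0) -> BetaParams:
    """Case-group beta parameters realizing a mean and/or variance effect."""
    mean, sd = beta_moments(baseline)
    if signal_type == "none":
        return baseline
    if signal_type == "mean":
        return solve_beta_params(mean + mean_diff, sd)
    if signal_type == "variance":
        return solve_beta_params(mean, sd * sd_ratio)
    if signal_type == "both":
        return solve_beta_params(mean + mean_diff, sd * sd_ratio)
    raise ValueError(f"unknown signal type {signal_type!r}")


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: CpG count, which CpGs carry signal, and how."""

    n_cpg: int
    signal_cpgs: tuple[int, ...] = ()
    signal_type: str = "none"
    mean_diff: float = 0.0
    sd_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cpg < 1:
            raise ValueError("a gene needs at least one CpG")
        if any(not 0 <= i < self.n_cpg for i in self.signal_cpgs):
            raise ValueError("signal CpG index outside gene")
        if self.signal_cpgs and self.signal_type == "none":
            raise ValueError("signal CpGs given but signal_type is 'none'")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one simulation condition.

    Defaults mirror the study design the simulator emulates: 40 cases vs
    40 controls with baseline Beta(46.36, 52.28) noise. ``outlier_prob``
    switches signal CpGs to the Bernoulli outlier mixture; ``ar1_rho``
    adds AR(1) dependence among each gene's CpGs via a Gaussian copula.
    """

    genes: tuple[GeneSpec, ...]
    n_cases: int = 40
    n_controls: int = 40
    baseline: BetaParams = BASELINE
    outlier_prob: float | None = None
    outlier_mean_shift: float = DEFAULT_OUTLIER_SHIFT
    ar1_rho: float | None = None

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 samples per group")
        if self.outlier_prob is not None and not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier_prob must lie in [0, 1]")
        if self.ar1_rho is not None and not abs(self.ar1_rho) < 1.0:
            raise ValueError("ar1_rho must satisfy |rho| < 1")
        if self.outlier_prob is not None and self.ar1_rho is not None:
            raise ValueError("outlier mixture and AR(1) copula cannot be combined")

    @property
    def has_signal(self) -> bool:
        return any(g.signal_cpgs for g in self.genes)


@dataclass
class SimulatedData:
    """Dataset bundle plus ground truth of the generating scenario."""

    dataset: MethylationDataset
    phenotype: PhenotypeVector
    annotation: CpGAnnotation
    truth: dict


# -- convenience constructors for the standard study conditions -------------

def null_scenario(n_genes: int = 1, n_cpg: int = 25, **kw) -> ScenarioSpec:
    """All-noise scenario used for type-I error evaluation."""
    return ScenarioSpec(tuple(GeneSpec(n_cpg) for _ in range(n_genes)), **kw)


def single_gene_scenario(n_signal: int, n_noise: int, signal_type: str,
                         mean_diff: float = 0.0, sd_ratio: float = 1.0,
                         **kw) -> ScenarioSpec:
    """One gene with the given signal-to-noise CpG split (e.g. 1:24, 5:45)."""
    gene = GeneSpec(n_signal + n_noise, tuple(range(n_signal)), signal_type,
                    mean_diff, sd_ratio)
    return ScenarioSpec((gene,), **kw)


def ten_gene_scenario(signal_type: str, mean_diff: float = 0.0,
                      sd_ratio: float = 1.0, n_cpg: int = 25,
                      n_signal: int = 1, **kw) -> ScenarioSpec:
    """Ten genes, the first carrying signal CpGs, the rest pure noise."""
    sig = GeneSpec(n_cpg, tuple(range(n_signal)), signal_type, mean_diff, sd_ratio)
    return ScenarioSpec((sig,) + tuple(GeneSpec(n_cpg) for _ in range(9)), **kw)


def outlier_scenario(n_signal: int = 5, n_noise: int = 45,
                     outlier_prob: float = 0.10,
                     outlier_mean_shift: float = DEFAULT_OUTLIER_SHIFT,
                     **kw) -> ScenarioSpec:
    """One 50-CpG gene whose signal CpGs carry Bernoulli outlier cases."""
    gene = GeneSpec(n_signal + n_noise, tuple(range(n_signal)), "mean",
                    mean_diff=0.0)
    return ScenarioSpec((gene,), outlier_prob=outlier_prob,
                        outlier_mean_shift=outlier_mean_shift, **kw)


# -- generation --------------------------------------------------------------

def _gene_case_params(spec: ScenarioSpec, gene: GeneSpec) -> list[BetaParams]:
    """Per-CpG case-group parameters for one gene."""
    out = []
    for j in range(gene.n_cpg):
        if j in gene.signal_cpgs:
            out.append(signal_params(spec.baseline, gene.signal_type,
                                     gene.mean_diff, gene.sd_ratio))
        else:
            out.append(spec.baseline)
    return out


def _draw_iid(rng, params: BetaParams, size) -> np.ndarray:
    return rng.beta(params.a, params.b, size=size)


def _draw_copula_gene(rng, param_list: list[BetaParams], n_samples: int,
                      rho: float) -> np.ndarray:
    """(n_samples, n_cpg) draws with AR(1) latent correlation and the given
    beta marginals (Gaussian copula)."""
    n_cpg = len(param_list)
    z = np.empty((n_samples, n_cpg))
    z[:, 0] = rng.standard_normal(n_samples)
    innov = rng.standard_normal((n_samples, max(n_cpg - 1, 0)))
    for j in range(1, n_cpg):
        z[:, j] = rho * z[:, j - 1] + np.sqrt(1.0 - rho**2) * innov[:, j - 1]
    u = stats.norm.cdf(z)
    x = np.empty_like(u)
    for j, p in enumerate(param_list):
        x[:, j] = stats.beta.ppf(u[:, j], p.a, p.b)
    return x


def simulate_dataset(spec: ScenarioSpec,
                     rng: np.random.Generator | int | None = None) -> SimulatedData:
    """Draw one dataset under a scenario.

    Samples are emitted in canonical order (controls first); CpGs are named
    ``<gene>_cpg_<j>`` and annotated one row per (CpG, gene) pair. The
    truth dict records the scenario, the signal CpGs per gene, and -- for
    outlier scenarios -- the realized outlier indicators.
    """
    rng = np.random.default_rng(rng)
    n0, n1 = spec.n_controls, spec.n_cases
    blocks, cpg_ids, ann, truth_genes = [], [], {}, {}
    outlier_draws = {}
    for k, gene in enumerate(spec.genes):
        gname = f"gene_{k + 1}"
        case_params = _gene_case_params(spec, gene)
        if spec.ar1_rho is not None:
            ctrl = _draw_copula_gene(rng, [spec.baseline] * gene.n_cpg, n0,
                                     spec.ar1_rho)
            case = _draw_copula_gene(rng, case_params, n1, spec.ar1_rho)
        else:
            ctrl = _draw_iid(rng, spec.baseline, (n0, gene.n_cpg))
            case = np.empty((n1, gene.n_cpg))
            for j, p in enumerate(case_params):
                case[:, j] = _draw_iid(rng, p, n1)
        if spec.outlier_prob is not None and gene.signal_cpgs:
            mean0, sd0 = beta_moments(spec.baseline)
            out_params = solve_beta_params(mean0 + spec.outlier_mean_shift, sd0)
            sig = list(gene.signal_cpgs)
            # non-outlier cases revert to baseline at the signal CpGs
            case[:, sig] = _draw_iid(rng, spec.baseline, (n1, len(sig)))
            z = rng.random((n1, len(sig))) < spec.outlier_prob
            case[:, sig] = np.where(
                z, _draw_iid(rng, out_params, (n1, len(sig))), case[:, sig])
            outlier_draws[gname] = z.astype(int).tolist()
        blocks.append(np.vstack([ctrl, case]).T)      # CpGs x samples
        ids = [f"{gname}_cpg_{j + 1}" for j in range(gene.n_cpg)]
        cpg_ids.extend(ids)
        for cid in ids:
            ann[cid] = frozenset({gname})
        truth_genes[gname] = {
            "n_cpg": gene.n_cpg,
            "signal_cpgs": list(gene.signal_cpgs),
            "signal_type": gene.signal_type,
            "mean_diff": gene.mean_diff,
            "sd_ratio": gene.sd_ratio,
        }
    sample_ids = ([f"ctrl_{i + 1}" for i in range(n0)]
                  + [f"case_{i + 1}" for i in range(n1)])
    ds = MethylationDataset(np.vstack(blocks), cpg_ids, sample_ids)
    pheno = PhenotypeVector({s: 0 for s in sample_ids[:n0]}
                            | {s: 1 for s in sample_ids[n0:]})
    truth = {
        "n_cases": n1, "n_controls": n0,
        "baseline": {"a": spec.baseline.a, "b": spec.baseline.b},
        "outlier_prob": spec.outlier_prob,
        "ar1_rho": spec.ar1_rho,
        "genes": truth_genes,
    }
    if outlier_draws:
        truth["outlier_indicators"] = outlier_draws
    return SimulatedData(ds, pheno, CpGAnnotation(ann), truth)


def simulate_outlier_dataset(spec: ScenarioSpec,
                             rng=None) -> SimulatedData:
    """Outlier-mixture scenario (requires ``outlier_prob`` set)."""
    if spec.outlier_prob is None:
        raise ValueError("scenario has no outlier_prob")
    return simulate_dataset(spec, rng)


def simulate_ar1_dataset(spec: ScenarioSpec, rng=None) -> SimulatedData:
    """AR(1)-correlated scenario (requires ``ar1_rho`` set)."""
    if spec.ar1_rho is None:
        raise ValueError("scenario has no ar1_rho")
    return simulate_dataset(spec, rng)
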