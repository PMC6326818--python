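"""Monte-Carlo experiments: type-I error and power of all methods.

Each simulation draws one dataset under a scenario, runs every requested
method on the same data (distance variants share one set of label shuffles,
so method comparisons are paired), and records whether the method rejects.
With one gene a method rejects when the pooled empirical p-value is at most
alpha; with several genes when any gene passes the Bonferroni-adjusted
threshold alpha/G (for the EWAS baselines, when any gene-level
min-adjusted-p passes it). The rejection proportion over simulations is the
type-I error rate under a null scenario and the power under a signal one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .distances import VARIANTS
from .ewas import bonferroni_min_p, ewas_site_scan
from .inference import (PermutationResult, batch_pseudo_f,
                        label_configurations, pooled_empirical_pvalues)
from .simulate import ScenarioSpec, SimulatedData, simulate_dataset

EWAS_METHODS = ("EWAS-DM", "EWAS-DV")
ALL_METHODS = VARIANTS + EWAS_METHODS


@dataclass
class ExperimentReport:
    """Rejection rate of one method under one scenario."""

    scenario: dict
    method: str
    n_sim: int
    n_perm: int
    alpha: float
    rejection_rate: float
    mc_se: float
    n_reject: int


def _gene_blocks(sim: SimulatedData):
    """(samples x CpGs) blocks per gene, in gene order."""
    x = sim.dataset.beta.T
    blocks, start = [], 0
    for gname, info in sim.truth["genes"].items():
        n = info["n_cpg"]
        blocks.append((gname, x[:, start:start + n]))
        start += n
    return blocks


def _distance_rejects(blocks, lab, methods, n_perm, alpha, pooling,
                      f_convention) -> dict[str, bool]:
    g = len(blocks)
    obs = {m: np.empty(g) for m in methods}
    perm = {m: np.empty((g, n_perm)) for m in methods}
    for gi, (_, xg) in enumerate(blocks):
        f = batch_pseudo_f(xg, lab, methods, f_convention)
        for m in methods:
            obs[m][gi], perm[m][gi] = f[m][0], f[m][1:]
    out = {}
    for m in methods:
        pr = PermutationResult([b[0] for b in blocks],
                               np.array([b[1].shape[1] for b in blocks]),
                               obs[m], perm[m], n_perm, None, m)
        p = pooled_empirical_pvalues(pr, pooling)
        cutoff = alpha if g == 1 else alpha / g
        out[m] = bool((p <= cutoff).any())
    return out


def _ewas_rejects(blocks, y, methods, alpha) -> dict[str, bool]:
    g = len(blocks)
    cutoff = alpha if g == 1 else alpha / g
    out = {m: False for m in methods}
    for _, xg in blocks:
        for m in methods:
            mode = "DM" if m == "EWAS-DM" else "DV"
            p = ewas_site_scan(xg, y, mode)
            if bonferroni_min_p(p, xg.shape[1]) <= cutoff:
                out[m] = True
    return out


def simulate_rejections(spec: ScenarioSpec,
                        methods: Sequence[str] = ALL_METHODS,
                        n_sim: int = 200, n_perm: int = 199,
                        alpha: float = 0.05, seed: int = 0,
                        pooling: str = "plus-one",
                        f_convention: str = "raw") -> dict[str, np.ndarray]:
    """Boolean rejection indicators per method over ``n_sim`` simulations.

    All methods see the same simulated datasets and the distance variants
    additionally share label shuffles within each simulation, so
    between-method differences are not inflated by Monte-Carlo noise.
    """
    unknown = [m for m in methods if m not in ALL_METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}")
    dist_methods = [m for m in methods if m in VARIANTS]
    ewas_methods = [m for m in methods if m in EWAS_METHODS]
    rejects = {m: np.zeros(n_sim, dtype=bool) for m in methods}
    children = np.random.SeedSequence(seed).spawn(n_sim)
    for i in range(n_sim):
        rng = np.random.default_rng(children[i])
        sim = simulate_dataset(spec, rng)
        blocks = _gene_blocks(sim)
        y = np.array([0] * spec.n_controls + [1] * spec.n_cases)
        if dist_methods:
            lab = label_configurations(y, n_perm, rng)
            for m, r in _distance_rejects(blocks, lab, dist_methods, n_perm,
                                          alpha, pooling, f_convention).items():
                rejects[m][i] = r
        if ewas_methods:
            for m, r in _ewas_rejects(blocks, y, ewas_methods, alpha).items():
                rejects[m][i] = r
    return rejects


def _reports(spec, rejects, n_sim, n_perm, alpha) -> list[ExperimentReport]:
    scen = {
        "n_genes": len(spec.genes),
        "n_cpg": [g.n_cpg for g in spec.genes],
        "n_cases": spec.n_cases,
        "n_controls": spec.n_controls,
        "has_signal": spec.has_signal,
        "outlier_prob": spec.outlier_prob,
        "ar1_rho": spec.ar1_rho,
    }
    out = []
    for m, r in rejects.items():
        rate = float(r.mean())
        out.append(ExperimentReport(
            scenario=scen, method=m, n_sim=n_sim, n_perm=n_perm, alpha=alpha,
            rejection_rate=rate,
            mc_se=float(np.sqrt(rate * (1 - rate) / n_sim)),
            n_reject=int(r.sum())))
    return out


def run_type1_experiment(spec: ScenarioSpec,
                         methods: Sequence[str] = ALL_METHODS,
                         n_sim: int = 200, n_perm: int = 199,
                         alpha: float = 0.05, seed: int = 0,
                         **kw) -> list[ExperimentReport]:
    """Rejection rates under a null scenario (no signal CpGs)."""
    if spec.has_signal:
        raise ValueError("type-I experiment requires a null scenario")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 0.0:
        return _reports(spec, {m: np.zeros(n_sim, dtype=bool) for m in methods},
                        n_sim, n_perm, alpha)
    rejects = simulate_rejections(spec, methods, n_sim, n_perm, alpha, seed, **kw)
    return _reports(spec, rejects, n_sim, n_perm, alpha)


def run_power_experiment(spec: ScenarioSpec,
                         methods: Sequence[str] = ALL_METHODS,
                         n_sim: int = 200, n_perm: int = 199,
                         alpha: float = 0.05, seed: int = 0,
                         **kw) -> list[ExperimentReport]:
    """Rejection rates under a signal scenario (power)."""
    if not spec.has_signal:
        raise ValueError("power experiment requires a signal scenario")
    rejects = simulate_rejections(spec, methods, n_sim, n_perm, alpha, seed, **kw)
    return _reports(spec, rejects, n_sim, n_perm, alpha)
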