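"""Synthetic regulatory networks and steady-state expression ensembles.

The generator emulates the characteristics of transcriptional-network
simulators of the SynTReN family: a scale-free directed acyclic topology
sampled by preferential attachment, nonlinear Hill-type transfer of
regulator activity, additive biological noise at each regulated gene and
multiplicative log-normal technical noise on every measurement.  Datasets
within an ensemble differ in their noise levels (biological replicate
heterogeneity), mimicking a series of microarray experiments on the same
underlying network.

All randomness flows from a single master seed through numpy's
SeedSequence spawning (PCG64 generators), so any ensemble is bit-for-bit
reproducible from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datatypes import (
    DataError,
    DatasetEnsemble,
    Edge,
    ExpressionDataset,
    GeneNetwork,
)

__all__ = [
    "SimulationDefaults",
    "DEFAULTS",
    "sample_topology",
    "simulate_dataset",
    "generate_ensemble",
]


@dataclass(frozen=True)
class SimulationDefaults:
    """Default study conditions for the simulated benchmark.

    Topology: 15 genes, 17 edges, activating edges with probability 0.7.
    Ensemble: Z = 24 datasets of 1000 samples each.  Noise: biological
    standard deviation sigma_bio added to each regulated gene, technical
    log-normal sigma applied multiplicatively; per-dataset noise levels are
    scaled by independent Uniform(1 - heterogeneity, 1 + heterogeneity)
    factors.  Hill transfer uses exponent 2 and half-saturation 0.5.  The
    noise levels are calibration constants chosen so that a single-dataset
    relevance network reaches a median AUC near 0.73 on the default
    topology.
    """

    n_genes: int = 15
    n_edges: int = 17
    activation_prob: float = 0.7
    ensemble_size: int = 24
    n_samples: int = 1000
    sigma_bio: float = 0.15
    sigma_tech: float = 1.0
    heterogeneity: float = 0.3
    hill_exponent: float = 2.0
    hill_k: float = 0.5


DEFAULTS = SimulationDefaults()


def sample_topology(
    n_genes: int = DEFAULTS.n_genes,
    n_edges: int = DEFAULTS.n_edges,
    seed: int | np.random.SeedSequence = 0,
    activation_prob: float = DEFAULTS.activation_prob,
) -> GeneNetwork:
    """Sample a scale-free directed acyclic network by preferential attachment.

    Genes g01..gNN are created in topological order; each new gene attaches
    to one earlier gene chosen with probability proportional to degree + 1,
    and the remaining edge budget is spent on extra parent edges with the
    same degree bias, keeping the graph acyclic (edges always point from
    earlier to later genes).  Each edge activates with probability
    ``activation_prob``, otherwise represses.  Deterministic given the seed.
    """
    if n_genes < 2:
        raise DataError("need at least 2 genes")
    max_edges = n_genes * (n_genes - 1) // 2  # DAG bound: one edge per pair
    if n_edges < 0 or n_edges > max_edges:
        raise DataError(
            f"{n_edges} edges infeasible for an acyclic {n_genes}-gene network "
            f"(max {max_edges})"
        )
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    degree = np.zeros(n_genes)
    edge_set: set[tuple[int, int]] = set()

    # backbone: each non-root gene gets one parent while budget remains
    backbone = list(range(1, n_genes))
    if n_edges < n_genes - 1:
        backbone = sorted(rng.choice(backbone, size=n_edges, replace=False))
    for child in backbone:
        weights = degree[:child] + 1.0
        parent = int(rng.choice(child, p=weights / weights.sum()))
        edge_set.add((parent, child))
        degree[parent] += 1
        degree[child] += 1

    # extra edges with the same preferential bias, child chosen by in-degree
    while len(edge_set) < n_edges:
        weights = degree + 1.0
        child = int(rng.choice(n_genes, p=weights / weights.sum()))
        if child == 0:
            continue
        open_parents = [p for p in range(child) if (p, child) not in edge_set]
        if not open_parents:
            continue
        w = degree[open_parents] + 1.0
        parent = int(rng.choice(open_parents, p=w / w.sum()))
        edge_set.add((parent, child))
        degree[parent] += 1
        degree[child] += 1

    edges = [
        Edge(
            genes[p],
            genes[c],
            sign=1 if rng.random() < activation_prob else -1,
            weight=1.0,
        )
        for p, c in sorted(edge_set)
    ]
    return GeneNetwork(genes, edges)


def _hill(x: np.ndarray, m: float, k: float) -> np.ndarray:
    xm = np.power(np.maximum(x, 0.0), m)
    return xm / (k**m + xm)


def simulate_dataset(
    net: GeneNetwork,
    n_samples: int = DEFAULTS.n_samples,
    noise: tuple[float, float] = (DEFAULTS.sigma_bio, DEFAULTS.sigma_tech),
    seed: int | np.random.SeedSequence = 0,
    dataset_id: str = "sim",
    hill_exponent: float = DEFAULTS.hill_exponent,
    hill_k: float = DEFAULTS.hill_k,
) -> ExpressionDataset:
    """Draw steady-state expression samples from an acyclic network.

    Genes are evaluated in topological order.  Root genes are Uniform(0.1,
    1); a regulated gene multiplies Hill activations h(x) of its activators
    and complements 1 - h(x) of its repressors, then receives additive
    Gaussian biological noise (clipped at zero).  Finally every value is
    multiplied by exp(Normal(0, sigma_tech)) technical noise.  Samples are
    independent draws.
    """
    sigma_bio, sigma_tech = noise
    if sigma_bio < 0 or sigma_tech < 0:
        raise DataError("noise levels must be non-negative")
    g = net.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        raise DataError("steady-state simulation requires an acyclic network")
    rng = np.random.default_rng(seed)
    order = list(nx.topological_sort(g))
    idx = {gene: i for i, gene in enumerate(net.genes)}
    values = np.empty((net.n_genes, n_samples))
    parents: dict[str, list[tuple[int, int]]] = {
        gene: [(idx[r], g.edges[r, gene]["sign"]) for r in g.predecessors(gene)]
        for gene in order
    }
    for gene in order:
        i = idx[gene]
        regs = parents[gene]
        if not regs:
            values[i] = rng.uniform(0.1, 1.0, size=n_samples)
            continue
        x = np.ones(n_samples)
        for j, sign in regs:
            h = _hill(values[j], hill_exponent, hill_k)
            x = x * (h if sign > 0 else 1.0 - h)
        if sigma_bio > 0:
            x = x + rng.normal(0.0, sigma_bio, size=n_samples)
        values[i] = np.maximum(x, 0.0)
    if sigma_tech > 0:
        values = values * np.exp(rng.normal(0.0, sigma_tech, size=values.shape))
    return ExpressionDataset(dataset_id, net.genes, values)


def generate_ensemble(
    net: GeneNetwork | None = None,
    ensemble_size: int = DEFAULTS.ensemble_size,
    n_samples: int = DEFAULTS.n_samples,
    noise: tuple[float, float] = (DEFAULTS.sigma_bio, DEFAULTS.sigma_tech),
    heterogeneity: float = DEFAULTS.heterogeneity,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[GeneNetwork, DatasetEnsemble]:
    """Generate Z heterogeneous datasets from one network.

    Dataset k draws its own noise multipliers u_k, v_k ~ Uniform(1 - eta,
    1 + eta) applied to the biological and technical noise levels, plus a
    fresh child seed, so datasets emulate independent experiments of
    varying quality.  When ``net`` is None a fresh default topology is
    sampled from the same master seed.  Returns (network, ensemble).
    """
    if ensemble_size < 1:
        raise DataError("ensemble size must be at least 1")
    if heterogeneity < 0:
        raise DataError("heterogeneity must be non-negative")
    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    topo_seq, noise_seq, *child_seqs = master.spawn(2 + ensemble_size)
    if net is None:
        net = sample_topology(seed=topo_seq)
    noise_rng = np.random.default_rng(noise_seq)
    lo, hi = 1.0 - heterogeneity, 1.0 + heterogeneity
    datasets = []
    width = len(str(ensemble_size))
    for k in range(ensemble_size):
        u, v = noise_rng.uniform(lo, hi, size=2)
        datasets.append(
            simulate_dataset(
                net,
                n_samples=n_samples,
                noise=(noise[0] * u, noise[1] * v),
                seed=child_seqs[k],
                dataset_id=f"data_{k + 1:0{width}d}",
            )
        )
    return net, DatasetEnsemble(datasets)
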