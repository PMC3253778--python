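"""Domain types for gene-network meta-analysis.

A regulatory network is a directed, signed, weighted graph over a fixed
gene universe; expression evidence arrives as one or more genes x samples
matrices; pairwise association evidence is held in symmetric matrices and,
once scored, in per-pair score tables.  All types validate their invariants
at construction and never repair bad input silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Edge",
    "GeneNetwork",
    "ExpressionDataset",
    "DatasetEnsemble",
    "AssociationMatrix",
    "EdgeScoreTable",
    "InferredEnsemble",
    "AnalysisConfig",
    "DataError",
    "pair_key",
    "all_pairs",
]


class DataError(ValueError):
    """Raised when input data violates a structural invariant."""


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered-pair key: lexicographically sorted gene ids."""
    if a == b:
        raise DataError(f"gene pair must involve two distinct genes, got {a!r} twice")
    return (a, b) if a < b else (b, a)


def all_pairs(genes: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs of a gene universe, in canonical order."""
    ordered = sorted(genes)
    return [(a, b) for i, a in enumerate(ordered) for b in ordered[i + 1 :]]


@dataclass(frozen=True)
class Edge:
    """Directed regulatory edge: regulator -> target with sign and strength."""

    regulator: str
    target: str
    sign: int = 1
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.regulator == self.target:
            raise DataError(f"self-loop edge on gene {self.regulator!r} is not allowed")
        if self.sign not in (1, -1):
            raise DataError(f"edge sign must be +1 or -1, got {self.sign}")
        if not math.isfinite(self.weight):
            raise DataError(f"edge weight must be finite, got {self.weight}")


class GeneNetwork:
    """Directed signed weighted gene network (the true weight matrix B).

    Entry ``b_ij`` gives the signed strength of the effect of regulator *j*
    on target *i*.  At most one edge per ordered gene pair; self-loops are
    rejected.
    """

    def __init__(self, genes: Sequence[str], edges: Iterable[Edge | tuple]) -> None:
        genes = list(genes)
        if len(set(genes)) != len(genes):
            raise DataError("gene identifiers must be unique")
        self.genes: list[str] = genes
        gene_set = set(genes)
        self._edges: dict[tuple[str, str], Edge] = {}
        for e in edges:
            if not isinstance(e, Edge):
                e = Edge(*e)
            if e.regulator not in gene_set or e.target not in gene_set:
                raise DataError(
                    f"edge {e.regulator}->{e.target} references a gene outside the universe"
                )
            key = (e.regulator, e.target)
            if key in self._edges:
                raise DataError(f"duplicate edge {e.regulator}->{e.target}")
            self._edges[key] = e

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, regulator: str, target: str) -> bool:
        return (regulator, target) in self._edges

    def skeleton(self) -> set[tuple[str, str]]:
        """Undirected edge set as canonical unordered pairs."""
        return {pair_key(r, t) for (r, t) in self._edges}

    def in_degree(self, gene: str) -> int:
        return sum(1 for (_, t) in self._edges if t == gene)

    def out_degree(self, gene: str) -> int:
        return sum(1 for (r, _) in self._edges if r == gene)

    def leaves(self) -> list[str]:
        """Terminal genes with exactly one incoming and no outgoing edge."""
        return [
            g for g in self.genes if self.out_degree(g) == 0 and self.in_degree(g) == 1
        ]

    def in_hubs(self) -> list[str]:
        """Genes with more than two incoming edges (in-degree >= 3)."""
        return [g for g in self.genes if self.in_degree(g) >= 3]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for e in self.edges:
            g.add_edge(e.regulator, e.target, sign=e.sign, weight=e.weight)
        return g

    def weight_matrix(self) -> pd.DataFrame:
        """N x N matrix B with B[target, regulator] = sign * weight."""
        b = pd.DataFrame(0.0, index=self.genes, columns=self.genes)
        for e in self.edges:
            b.loc[e.target, e.regulator] = e.sign * e.weight
        return b

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.genes == other.genes and self._edges == other._edges

    def __repr__(self) -> str:
        return f"GeneNetwork({self.n_genes} genes, {self.n_edges} edges)"


class ExpressionDataset:
    """One expression matrix, genes x samples, with N_k = sample count."""

    def __init__(
        self,
        dataset_id: str,
        gene_ids: Sequence[str],
        values: np.ndarray | pd.DataFrame,
        sample_ids: Sequence[str] | None = None,
    ) -> None:
        if isinstance(values, pd.DataFrame):
            if sample_ids is None:
                sample_ids = [str(c) for c in values.columns]
            values = values.to_numpy(dtype=float)
        values = np.asarray(values, dtype=float)
        gene_ids = [str(g) for g in gene_ids]
        if len(set(gene_ids)) != len(gene_ids):
            dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
            raise DataError(f"duplicate gene identifiers: {dupes}")
        if values.ndim != 2 or values.shape[0] != len(gene_ids):
            raise DataError(
                f"expression matrix shape {values.shape} does not match "
                f"{len(gene_ids)} gene ids"
            )
        if not np.isfinite(values).all():
            raise DataError("expression values must all be finite")
        if values.shape[1] < 4:
            raise DataError(
                f"dataset {dataset_id!r} has {values.shape[1]} samples; at least 4 "
                "are required (correlation variance 1/(N_k - 3) must be defined)"
            )
        if sample_ids is None:
            sample_ids = [f"s{i + 1}" for i in range(values.shape[1])]
        sample_ids = [str(s) for s in sample_ids]
        if len(sample_ids) != values.shape[1]:
            raise DataError("sample id count does not match matrix width")
        self.dataset_id = dataset_id
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.values = values

    @property
    def n_samples(self) -> int:
        """Profile length N_k."""
        return self.values.shape[1]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def __repr__(self) -> str:
        return (
            f"ExpressionDataset({self.dataset_id!r}, {self.n_genes} genes x "
            f"{self.n_samples} samples)"
        )


class DatasetEnsemble:
    """A series of Z expression datasets over an identical gene universe."""

    def __init__(self, datasets: Sequence[ExpressionDataset]) -> None:
        datasets = list(datasets)
        if not datasets:
            raise DataError("an ensemble needs at least one dataset")
        ref = datasets[0].gene_ids
        for d in datasets[1:]:
            if d.gene_ids != ref:
                raise DataError(
                    f"dataset {d.dataset_id!r} has a different gene-id list than "
                    f"{datasets[0].dataset_id!r}; ensembles require identical ordering"
                )
        self.datasets = datasets

    @property
    def size(self) -> int:
        return len(self.datasets)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.datasets[0].gene_ids)

    def __iter__(self) -> Iterator[ExpressionDataset]:
        return iter(self.datasets)

    def __len__(self) -> int:
        return self.size

    def __repr__(self) -> str:
        return f"DatasetEnsemble(Z={self.size}, {len(self.gene_ids)} genes)"


_ASSOC_KINDS = ("pearson", "partial", "mi")


class AssociationMatrix:
    """Symmetric pairwise association statistic for one dataset.

    ``order`` records how many variables each entry was conditioned on
    (0 = marginal, 1 = first order, n_genes - 2 = full order) so that
    downstream significance tests can adjust degrees of freedom.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        stat: np.ndarray,
        kind: str,
        n_samples: int,
        order: int = 0,
    ) -> None:
        if kind not in _ASSOC_KINDS:
            raise DataError(f"kind must be one of {_ASSOC_KINDS}, got {kind!r}")
        stat = np.asarray(stat, dtype=float)
        gene_ids = [str(g) for g in gene_ids]
        n = len(gene_ids)
        if stat.shape != (n, n):
            raise DataError(f"stat shape {stat.shape} does not match {n} genes")
        if not np.allclose(stat, stat.T, atol=1e-10, equal_nan=True):
            raise DataError("association matrix must be symmetric")
        off = stat[~np.eye(n, dtype=bool)]
        if kind in ("pearson", "partial") and np.any(np.abs(off) > 1 + 1e-12):
            raise DataError("correlation entries must lie in [-1, 1]")
        if kind == "mi" and np.any(off < -1e-12):
            raise DataError("mutual information entries must be non-negative")
        self.gene_ids = gene_ids
        self.stat = stat
        self.kind = kind
        self.n_samples = int(n_samples)
        self.order = int(order)

    def value(self, a: str, b: str) -> float:
        i, j = self.gene_ids.index(a), self.gene_ids.index(b)
        return float(self.stat[i, j])

    def __repr__(self) -> str:
        return (
            f"AssociationMatrix({self.kind}, order={self.order}, "
            f"{len(self.gene_ids)} genes, N_k={self.n_samples})"
        )


_METHOD_TAGS = ("ftcct", "ficpt", "rn", "clr", "aracne", "mrnet")

#: Columns every score table carries; method-specific extras may follow.
SCORE_COLUMNS = ("gene_a", "gene_b", "effect", "score", "statistic", "p_value")


class EdgeScoreTable:
    """Per-pair scores for one inferred network.

    One row per unordered gene pair with canonical ordering
    ``gene_a < gene_b``.  ``score`` is the ranking score (larger = stronger
    evidence); ``effect`` is the signed effect size where the method has one
    (e.g. the combined correlation r-bar); ``p_value`` may be NaN for
    methods without a significance test (MI-based baselines).
    """

    def __init__(self, table: pd.DataFrame, method: str) -> None:
        if method not in _METHOD_TAGS:
            raise DataError(f"method must be one of {_METHOD_TAGS}, got {method!r}")
        table = table.copy()
        missing = [c for c in SCORE_COLUMNS if c not in table.columns]
        if missing:
            raise DataError(f"score table is missing columns {missing}")
        keys = [pair_key(a, b) for a, b in zip(table["gene_a"], table["gene_b"])]
        table["gene_a"] = [k[0] for k in keys]
        table["gene_b"] = [k[1] for k in keys]
        if len(set(keys)) != len(keys):
            raise DataError("score table must have exactly one row per gene pair")
        p = table["p_value"].to_numpy(dtype=float)
        valid = ~np.isnan(p)
        if np.any((p[valid] < 0) | (p[valid] > 1)):
            raise DataError("p-values must lie in [0, 1]")
        table = table.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(
            drop=True
        )
        self.table = table
        self.method = method

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.table["gene_a"]) | set(self.table["gene_b"]))

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.table["gene_a"], self.table["gene_b"]))

    def scores(self) -> pd.Series:
        idx = pd.MultiIndex.from_arrays([self.table["gene_a"], self.table["gene_b"]])
        return pd.Series(self.table["score"].to_numpy(), index=idx, name="score")

    def p_values(self) -> pd.Series:
        idx = pd.MultiIndex.from_arrays([self.table["gene_a"], self.table["gene_b"]])
        return pd.Series(self.table["p_value"].to_numpy(), index=idx, name="p_value")

    def significant_pairs(self, alpha: float) -> set[tuple[str, str]]:
        """Pairs declared correlated at level alpha (p < alpha)."""
        p = self.table["p_value"].to_numpy(dtype=float)
        mask = ~np.isnan(p) & (p < alpha)
        return {
            (a, b)
            for a, b, m in zip(self.table["gene_a"], self.table["gene_b"], mask)
            if m
        }

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:
        return f"EdgeScoreTable({self.method}, {len(self)} pairs)"


class InferredEnsemble:
    """Collection C = {(B_k, s_k)} of inferred networks with fit scores.

    Fit scores are carried for completeness but not used by the combination
    statistics.
    """

    def __init__(
        self,
        networks: Sequence[EdgeScoreTable],
        fit_scores: Sequence[float] | None = None,
    ) -> None:
        networks = list(networks)
        if not networks:
            raise DataError("an inferred ensemble needs at least one network")
        universe = networks[0].genes
        for t in networks[1:]:
            if t.genes != universe:
                raise DataError("all ensemble members must share the gene universe")
        if fit_scores is not None:
            fit_scores = [float(s) for s in fit_scores]
            if len(fit_scores) != len(networks):
                raise DataError("one fit score per network is required")
        self.networks = networks
        self.fit_scores = fit_scores

    @property
    def genes(self) -> list[str]:
        return self.networks[0].genes

    def __iter__(self) -> Iterator[EdgeScoreTable]:
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)


@dataclass
class AnalysisConfig:
    """Knobs shared across the inference and evaluation pipeline.

    alpha_edge is the hard significance threshold used to binarise score
    tables for tIDR/tIRR and the ensemble statistics; comparison_alphas are
    the levels at which method-vs-method AUC differences are declared
    significant; significance_test picks the test applied to combined
    correlation coefficients ('z' on the weighted z-average, or 't' with an
    effective sample size).
    """

    alpha_edge: float = 1e-12
    comparison_alphas: tuple[float, ...] = (1e-5, 1e-3)
    significance_test: str = "z"
    partial_order: str = "full"  # 'full' or 'first'
    cat_n_max: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.alpha_edge, *self.comparison_alphas):
            if not (0.0 < a < 1.0):
                raise DataError(f"significance threshold must be in (0,1), got {a}")
        if self.significance_test not in ("t", "z"):
            raise DataError("significance_test must be 't' or 'z'")
        if self.partial_order not in ("full", "first"):
            raise DataError("partial_order must be 'full' or 'first'")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise DataError("seed must be a non-negative integer")
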