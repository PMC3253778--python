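"""Benchmarking of inferred networks against a known truth.

Covers four evaluation families:

* ROC AUC of a score table's pair ranking against the true undirected
  skeleton (correlation-style inferrers are undirected, so all accuracy
  measures use the skeleton; motif typing below still uses directions);
* tIDR / tIRR — the fraction of true edges recovered only by the
  meta-analysis, respectively only by the individual studies, at a hard
  significance threshold;
* ensemble statistics on three-gene motifs (chain, collider, fork,
  triangle) and on individual true edges (mean TPR colour classes, with
  leaf and in-hub breakdowns);
* CAT (correspondence-at-the-top) curves of agreement between ranked gene
  lists around a hub gene, plus a rank-sum test for comparing AUC samples
  between methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .datatypes import (
    DataError,
    EdgeScoreTable,
    GeneNetwork,
    InferredEnsemble,
    pair_key,
)

__all__ = [
    "MotifReport",
    "EdgeEnsembleReport",
    "CATCurve",
    "roc_auc",
    "tidr",
    "tirr",
    "enumerate_motifs",
    "motif_reconstruction_rate",
    "edge_ensemble_report",
    "hub_ranked_list",
    "cat_curve",
    "compare_auc_samples",
]

MOTIF_TYPES = {1: "chain", 2: "collider", 3: "fork", 4: "triangle"}

#: Mean-TPR colour bins: red [0, 0.25], green (0.25, 0.5], blue (0.5, 0.75],
#: black (0.75, 1].
COLOUR_BINS = (("red", 0.25), ("green", 0.5), ("blue", 0.75), ("black", 1.0))


def colour_of(tpr: float) -> str:
    if not 0.0 <= tpr <= 1.0:
        raise DataError(f"mean TPR must lie in [0, 1], got {tpr}")
    for name, upper in COLOUR_BINS:
        if tpr <= upper:
            return name
    return "black"


@dataclass
class MotifReport:
    """Counts and mean true reconstruction rates per three-gene motif type."""

    counts: dict[int, int]
    rates: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif_type": list(MOTIF_TYPES),
                "name": [MOTIF_TYPES[t] for t in MOTIF_TYPES],
                "count": [self.counts.get(t, 0) for t in MOTIF_TYPES],
                "rate": [self.rates.get(t, 0.0) for t in MOTIF_TYPES],
            }
        )


@dataclass
class EdgeEnsembleReport:
    """Per-true-edge mean TPR, colour class and leaf / in-hub breakdown."""

    edges: pd.DataFrame  # regulator, target, mean_tpr, colour, is_leaf_edge, is_inhub_edge

    def tally(self) -> pd.DataFrame:
        """Colour tallies for the whole network, leaf edges and in-hub edges.

        Per scope: counts, the within-scope percentage (%E_L) and the
        percentage of all true edges (%N_et).
        """
        total = len(self.edges)
        scopes = {
            "network": np.ones(total, dtype=bool),
            "leaves": self.edges["is_leaf_edge"].to_numpy(),
            "in_hubs": self.edges["is_inhub_edge"].to_numpy(),
        }
        rows = []
        for scope, mask in scopes.items():
            scoped = self.edges.loc[mask, "colour"]
            size = int(mask.sum())
            for colour, _ in COLOUR_BINS:
                count = int((scoped == colour).sum())
                rows.append(
                    {
                        "scope": scope,
                        "colour": colour,
                        "count": count,
                        "pct_scope": 100.0 * count / size if size else 0.0,
                        "pct_network": 100.0 * count / total if total else 0.0,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CATCurve:
    """Top-n agreement between ranked gene lists."""

    n: np.ndarray
    agreement: np.ndarray
    mode: str  # 'meta' or 'individual'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n, "agreement": self.agreement})


def _truth_labels(scores: EdgeScoreTable, truth: GeneNetwork):
    skeleton = truth.skeleton()
    table = scores.table
    pair_set = set(zip(table["gene_a"], table["gene_b"]))
    needed = {pair_key(a, b) for a, b in combinations(truth.genes, 2)}
    if not needed <= pair_set:
        raise DataError("score table does not cover all gene pairs of the truth")
    keep = [(a, b) in needed for a, b in zip(table["gene_a"], table["gene_b"])]
    table = table.loc[keep]
    y = np.array(
        [(a, b) in skeleton for a, b in zip(table["gene_a"], table["gene_b"])],
        dtype=int,
    )
    return y, table["score"].to_numpy(dtype=float)


def roc_auc(scores: EdgeScoreTable, truth: GeneNetwork) -> float:
    """AUC of the pair ranking against the true undirected skeleton.

    Scores rank pairs directly (larger = stronger evidence); ties receive
    the average rank, matching the Mann-Whitney formulation of the AUC.
    """
    y, s = _truth_labels(scores, truth)
    if y.sum() == 0 or y.sum() == len(y):
        raise DataError("AUC undefined: truth has no edges or only edges")
    return float(roc_auc_score(y, s))


def _union_significant(singles: InferredEnsemble, alpha: float) -> set:
    out: set = set()
    for t in singles:
        out |= t.significant_pairs(alpha)
    return out


def tidr(
    meta: EdgeScoreTable,
    singles: InferredEnsemble,
    truth: GeneNetwork,
    alpha_edge: float = 1e-12,
) -> float:
    """True integration discovery rate.

    Fraction of true skeleton edges declared significant by the
    meta-analysis but by none of the individual studies:
    |T intersect M minus union I_k| / |T|.
    """
    t_set = truth.skeleton()
    if not t_set:
        raise DataError("tIDR undefined for an edgeless truth")
    m = meta.significant_pairs(alpha_edge)
    union_i = _union_significant(singles, alpha_edge)
    return len((t_set & m) - union_i) / len(t_set)


def tirr(
    meta: EdgeScoreTable,
    singles: InferredEnsemble,
    truth: GeneNetwork,
    alpha_edge: float = 1e-12,
) -> float:
    """True integration reversion rate.

    Fraction of true skeleton edges declared significant in at least one
    individual study but missed by the meta-analysis:
    |T intersect union I_k minus M| / |T|.
    """
    t_set = truth.skeleton()
    if not t_set:
        raise DataError("tIRR undefined for an edgeless truth")
    m = meta.significant_pairs(alpha_edge)
    union_i = _union_significant(singles, alpha_edge)
    return len((t_set & union_i) - m) / len(t_set)


def _classify_triple(edges_present: set[tuple[str, str]], triple) -> tuple[int, tuple] | None:
    """Classify one gene triple by its induced directed subgraph.

    Returns (motif_type, (true_pairs, absent_pairs)) or None if the triple
    is not one of the four counted motifs.  Directed patterns with exactly
    two edges split into chain / collider / fork; three edges must form the
    feed-forward triangle i->j, j->k, i->k.
    """
    a, b, c = triple
    within = [
        (x, y)
        for x, y in ((a, b), (b, a), (a, c), (c, a), (b, c), (c, b))
        if (x, y) in edges_present
    ]
    n = len(within)
    if n == 2:
        (r1, t1), (r2, t2) = within
        pairs = {pair_key(r1, t1), pair_key(r2, t2)}
        if len(pairs) != 2:
            return None  # a 2-cycle, not a motif
        absent = {pair_key(*p) for p in combinations(triple, 2)} - pairs
        if t1 == t2:
            mtype = 2  # collider: two edges into the same gene
        elif r1 == r2:
            mtype = 3  # fork: two edges out of the same gene
        elif t1 == r2 or t2 == r1:
            mtype = 1  # chain
        else:
            return None
        return mtype, (tuple(sorted(pairs)), tuple(sorted(absent)))
    if n == 3:
        regs = {r for r, _ in within}
        tgts = {t for _, t in within}
        pairs = {pair_key(r, t) for r, t in within}
        # feed-forward: one pure source, one pure sink, one middle gene
        if len(pairs) == 3 and len(regs) == 2 and len(tgts) == 2:
            return 4, (tuple(sorted(pairs)), ())
    return None


def enumerate_motifs(net: GeneNetwork) -> MotifReport:
    """Count the four three-gene motif types over all gene triples."""
    edges_present = {(e.regulator, e.target) for e in net.edges}
    counts = {t: 0 for t in MOTIF_TYPES}
    for triple in combinations(net.genes, 3):
        hit = _classify_triple(edges_present, triple)
        if hit is not None:
            counts[hit[0]] += 1
    return MotifReport(counts=counts, rates={t: 0.0 for t in MOTIF_TYPES})


def motif_reconstruction_rate(
    ens: InferredEnsemble,
    truth: GeneNetwork,
    alpha_edge: float = 1e-12,
) -> MotifReport:
    """Mean true reconstruction rate per motif type across the ensemble.

    Each inferred table is binarised at alpha_edge (undirected).  For motif
    types 1-3 the per-motif rate is (TPR + TNR)/2: half the fraction of the
    motif's two true pairs predicted plus half the indicator that its
    absent pair is not predicted.  Type 4 has no absent pair, so the rate
    is the fraction of its three pairs predicted.  Types with no motifs in
    the truth report rate 0 by convention.
    """
    if len(ens) == 0:
        raise DataError("motif evaluation needs a non-empty ensemble")
    edges_present = {(e.regulator, e.target) for e in truth.edges}
    motifs: dict[int, list[tuple]] = {t: [] for t in MOTIF_TYPES}
    for triple in combinations(truth.genes, 3):
        hit = _classify_triple(edges_present, triple)
        if hit is not None:
            motifs[hit[0]].append(hit[1])
    counts = {t: len(motifs[t]) for t in MOTIF_TYPES}
    predicted_sets = [t.significant_pairs(alpha_edge) for t in ens]
    rates = {}
    for mtype in MOTIF_TYPES:
        if counts[mtype] == 0:
            rates[mtype] = 0.0
            continue
        vals = []
        for true_pairs, absent_pairs in motifs[mtype]:
            for predicted in predicted_sets:
                tpr = np.mean([p in predicted for p in true_pairs])
                if mtype == 4:
                    vals.append(tpr)
                else:
                    tnr = float(absent_pairs[0] not in predicted)
                    vals.append(0.5 * (tpr + tnr))
        rates[mtype] = float(np.mean(vals))
    return MotifReport(counts=counts, rates=rates)


def edge_ensemble_report(
    ens: InferredEnsemble,
    truth: GeneNetwork,
    alpha_edge: float = 1e-12,
) -> EdgeEnsembleReport:
    """Mean recovery rate and colour class of every true edge.

    The mean TPR of an edge is the fraction of ensemble members whose
    binarised network contains the edge's unordered pair.  An edge is a
    leaf edge if its target is a terminal gene with exactly one incoming
    edge, and an in-hub edge if its target has more than two incoming
    edges.
    """
    if len(ens) == 0:
        raise DataError("edge evaluation needs a non-empty ensemble")
    predicted_sets = [t.significant_pairs(alpha_edge) for t in ens]
    leaves = set(truth.leaves())
    in_hubs = set(truth.in_hubs())
    rows = []
    for e in truth.edges:
        pair = pair_key(e.regulator, e.target)
        mean_tpr = float(np.mean([pair in p for p in predicted_sets]))
        rows.append(
            {
                "regulator": e.regulator,
                "target": e.target,
                "mean_tpr": mean_tpr,
                "colour": colour_of(mean_tpr),
                "is_leaf_edge": e.target in leaves,
                "is_inhub_edge": e.target in in_hubs,
            }
        )
    return EdgeEnsembleReport(edges=pd.DataFrame(rows))


def hub_ranked_list(scores: EdgeScoreTable, master: str) -> list[str]:
    """Genes ranked by the significance of their association with a master gene.

    All genes other than the master, ordered by ascending p-value of their
    pair with the master; ties broken by descending |effect|, then by
    gene id.
    """
    genes = scores.genes
    if master not in genes:
        raise DataError(f"master gene {master!r} not in the score table")
    records = []
    table = scores.table
    mask = (table["gene_a"] == master) | (table["gene_b"] == master)
    for _, row in table.loc[mask].iterrows():
        partner = row["gene_b"] if row["gene_a"] == master else row["gene_a"]
        p = row["p_value"]
        records.append((1.0 if np.isnan(p) else p, -abs(row["effect"]), partner))
    records.sort()
    return [partner for _, _, partner in records]


def cat_curve(
    list_a: list[str],
    list_b: list[str],
    reference: list[str] | None = None,
    n_max: int = 500,
) -> CATCurve:
    """Correspondence-at-the-top curve for two ranked gene lists.

    Without a reference (meta mode) the agreement at n is the overlap of
    the two top-n lists divided by n; with a reference (individual mode) it
    is the mean of each list's top-n overlap with the reference's top n.
    Lists shorter than n_max truncate the curve with a warning.
    """
    limit = min(n_max, len(list_a), len(list_b))
    if reference is not None:
        limit = min(limit, len(reference))
    if limit < n_max:
        warnings.warn(
            f"ranked lists support only n <= {limit}; CAT curve truncated",
            stacklevel=2,
        )
    if limit < 1:
        raise DataError("CAT curve needs non-empty ranked lists")
    ns = np.arange(1, limit + 1)
    agreement = np.empty(limit)
    top_a: set[str] = set()
    top_b: set[str] = set()
    top_r: set[str] = set()
    for n in ns:
        top_a.add(list_a[n - 1])
        top_b.add(list_b[n - 1])
        if reference is None:
            agreement[n - 1] = len(top_a & top_b) / n
        else:
            top_r.add(reference[n - 1])
            agreement[n - 1] = 0.5 * (len(top_a & top_r) + len(top_b & top_r)) / n
    mode = "meta" if reference is None else "individual"
    return CATCurve(n=ns, agreement=agreement, mode=mode)


def compare_auc_samples(auc_a, auc_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing two AUC samples."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise DataError("need at least 3 AUC values per group")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
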