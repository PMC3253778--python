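"""Single-dataset reverse-engineering baselines.

Relevance network (RN) scores each pair by the magnitude of its partial
correlation with a t-test p-value.  CLR, ARACNe and MRNET operate on a
mutual-information matrix: CLR contrasts each MI value against its row
backgrounds, ARACNe prunes the weakest edge of every triangle via the
data-processing inequality, and MRNET performs per-target greedy
max-relevance min-redundancy forward selection.  Copula concatenation pools
heterogeneous datasets into one by mapping each gene to in-dataset ranks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import partial_correlation_matrix
from .datatypes import (
    AnalysisConfig,
    AssociationMatrix,
    DataError,
    DatasetEnsemble,
    EdgeScoreTable,
    ExpressionDataset,
)

__all__ = [
    "relevance_network",
    "copula_concatenate",
    "clr",
    "aracne",
    "mrnet",
]


def _pairs_of(gene_ids) -> tuple[list[tuple[int, int]], list[tuple[str, str]]]:
    order = sorted(range(len(gene_ids)), key=lambda i: gene_ids[i])
    idx_pairs, name_pairs = [], []
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            i, j = order[a], order[b]
            idx_pairs.append((i, j))
            name_pairs.append((gene_ids[i], gene_ids[j]))
    return idx_pairs, name_pairs


def _mi_table(mi: AssociationMatrix, scores: np.ndarray, method: str) -> EdgeScoreTable:
    idx_pairs, name_pairs = _pairs_of(mi.gene_ids)
    rows = {
        "gene_a": [a for a, _ in name_pairs],
        "gene_b": [b for _, b in name_pairs],
        "effect": [scores[i, j] for i, j in idx_pairs],
        "score": [scores[i, j] for i, j in idx_pairs],
        "statistic": [mi.stat[i, j] for i, j in idx_pairs],
        "p_value": np.nan,
    }
    return EdgeScoreTable(pd.DataFrame(rows), method=method)


def relevance_network(
    d: ExpressionDataset, cfg: AnalysisConfig | None = None
) -> EdgeScoreTable:
    """Rank pairs by |partial correlation| with a per-pair t-test p-value."""
    cfg = cfg or AnalysisConfig()
    am = partial_correlation_matrix(d, order=cfg.partial_order)
    idx_pairs, name_pairs = _pairs_of(am.gene_ids)
    r = np.array([am.stat[i, j] for i, j in idx_pairs])
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    df = am.n_samples - 2 - am.order
    if df < 1:
        raise DataError(f"t-test needs N_k - 2 - g >= 1, got {df}")
    t = r * np.sqrt(df / (1.0 - r * r))
    p = np.minimum(2.0 * stats.t.sf(np.abs(t), df), 1.0)
    table = pd.DataFrame(
        {
            "gene_a": [a for a, _ in name_pairs],
            "gene_b": [b for _, b in name_pairs],
            "effect": r,
            "score": np.abs(r),
            "statistic": t,
            "p_value": p,
        }
    )
    return EdgeScoreTable(table, method="rn")


def copula_concatenate(ens: DatasetEnsemble) -> ExpressionDataset:
    """Pool an ensemble into one dataset via the within-dataset rank copula.

    Each gene's profile in dataset k is replaced by rank/(N_k + 1) with
    average ranks for ties, mapping every dataset onto a common (0, 1)
    scale; the transformed sample columns are then concatenated, so the
    output has sum(N_k) samples.
    """
    blocks, samples = [], []
    for d in ens:
        u = np.apply_along_axis(stats.rankdata, 1, d.values) / (d.n_samples + 1.0)
        blocks.append(u)
        samples.extend(f"{d.dataset_id}:{s}" for s in d.sample_ids)
    return ExpressionDataset(
        dataset_id="copula_pool",
        gene_ids=ens.gene_ids,
        values=np.hstack(blocks),
        sample_ids=samples,
    )


def clr(mi: AssociationMatrix) -> EdgeScoreTable:
    """Context-likelihood-of-relatedness scores from an MI matrix.

    Per row i, each MI_ij is standardised against the row's off-diagonal
    mean and standard deviation, clipped at zero; the edge score is the
    Euclidean combination sqrt(z_i(j)^2 + z_j(i)^2).  A constant row
    (zero standard deviation) contributes z = 0.
    """
    if mi.kind != "mi":
        raise DataError("clr expects a mutual-information matrix")
    m = mi.stat.copy()
    n = m.shape[0]
    mask = ~np.eye(n, dtype=bool)
    off = np.where(mask, m, np.nan)
    mean = np.nanmean(off, axis=1, keepdims=True)
    sd = np.nanstd(off, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, np.maximum(0.0, (m - mean) / sd), 0.0)
    scores = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(scores, 0.0)
    return _mi_table(mi, scores, "clr")


def aracne(mi: AssociationMatrix, dpi_tolerance: float = 0.0) -> EdgeScoreTable:
    """ARACNe: MI network pruned by the data-processing inequality.

    For every gene triple (i, j, k) the edge (i, j) is removed when
    MI_ij < min(MI_ik, MI_jk) * (1 - eps); surviving edges keep their MI as
    score, pruned edges score 0.
    """
    if mi.kind != "mi":
        raise DataError("aracne expects a mutual-information matrix")
    if dpi_tolerance < 0:
        raise DataError("DPI tolerance must be non-negative")
    m = mi.stat.copy()
    np.fill_diagonal(m, 0.0)
    n = m.shape[0]
    keep = np.ones((n, n), dtype=bool)
    factor = 1.0 - dpi_tolerance
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(n):
                if k in (i, j):
                    continue
                if m[i, j] < min(m[i, k], m[j, k]) * factor:
                    keep[i, j] = keep[j, i] = False
                    break
    scores = np.where(keep, m, 0.0)
    return _mi_table(mi, scores, "aracne")


def mrnet(mi: AssociationMatrix) -> EdgeScoreTable:
    """MRNET: greedy max-relevance min-redundancy regulator selection.

    For each target, candidate regulators are added one at a time, each
    chosen to maximise MI(target, candidate) minus the mean MI between the
    candidate and the already-selected regulators; selection stops once the
    best mRMR score drops to <= 0.  The undirected pair score is the larger
    of the two directed selection scores, floored at zero.
    """
    if mi.kind != "mi":
        raise DataError("mrnet expects a mutual-information matrix")
    m = mi.stat.copy()
    np.fill_diagonal(m, 0.0)
    n = m.shape[0]
    directed = np.zeros((n, n))
    for target in range(n):
        selected: list[int] = []
        remaining = [g for g in range(n) if g != target]
        while remaining:
            best_gene, best_score = None, 0.0
            for cand in remaining:
                redundancy = np.mean([m[cand, s] for s in selected]) if selected else 0.0
                score = m[target, cand] - redundancy
                if best_gene is None or score > best_score:
                    best_gene, best_score = cand, score
            if best_score <= 0.0:
                break
            directed[best_gene, target] = best_score
            selected.append(best_gene)
            remaining.remove(best_gene)
    scores = np.maximum(np.maximum(directed, directed.T), 0.0)
    return _mi_table(mi, scores, "mrnet")
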