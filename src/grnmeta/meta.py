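"""Meta-analysis of pairwise gene association across a dataset ensemble.

Two combination statistics are provided, applied per unordered gene pair
across the Z datasets of an ensemble:

FTCCT (Fisher-transformation combined correlation test) treats the
per-dataset partial correlation r_k as the effect size.  Each r_k is mapped
to z-space with Fisher's transform z_k = arctanh(r_k), whose sampling
variance is 1/(N_k - 3 - g) for a correlation conditioned on g variables.
Between-dataset heterogeneity tau^2 is estimated from Cochran's Q with the
DerSimonian-Laird moment estimator, the z_k are averaged with
random-effects weights w_k = 1/(var_k + tau^2), and the average is mapped
back to a combined correlation r-bar = tanh(z-bar).  Significance comes
either from the z-statistic z-bar/se(z-bar) against the standard normal, or
from a t-test on r-bar with an effective sample size 3 + 1/se^2.

FICPT (Fisher's inverse combined probability test) treats the per-dataset
two-sided p-value p_k of the partial correlation as the effect size and
combines them with Fisher's statistic S = -2 sum ln p_k, referred to a
chi-squared distribution with 2Z degrees of freedom.

Both reduce sensibly at Z = 1: FTCCT returns the single dataset's partial
correlation, and FICPT's chi-squared survival at 2 df recovers the input
p-value exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import partial_correlation_matrix
from .datatypes import (
    AnalysisConfig,
    DataError,
    DatasetEnsemble,
    EdgeScoreTable,
)

__all__ = [
    "fisher_r_to_z",
    "fisher_z_to_r",
    "z_variance",
    "cochran_q_tau2",
    "combine_z",
    "ftcct",
    "ficpt",
]

#: Correlations are clipped to this magnitude before arctanh so the
#: transform stays finite under floating-point arithmetic.
R_CLIP = 1.0 - 1e-15

#: Per-dataset p-values are floored here before taking logs in FICPT.
P_FLOOR = 1e-300


def fisher_r_to_z(r):
    """Fisher's r-to-z transform, z = 1/2 ln((1+r)/(1-r)) = arctanh(r).

    Raises for |r| >= 1 (infinite z); callers that may see boundary values
    clip to ``R_CLIP`` first.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise DataError("fisher_r_to_z requires |r| < 1; clip boundary values first")
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def fisher_z_to_r(z):
    """Inverse transform r = tanh(z); maps any finite z into (-1, 1)."""
    z = np.asarray(z, dtype=float)
    r = np.tanh(z)
    return float(r) if r.ndim == 0 else r


def z_variance(n: int, n_conditioned: int = 0) -> float:
    """Sampling variance of arctanh(r): 1/(n - 3) for a marginal correlation,
    1/(n - 3 - g) when the correlation was conditioned on g variables."""
    df = n - 3 - n_conditioned
    if df < 1:
        raise DataError(f"z variance needs n - 3 - g >= 1, got {df}")
    return 1.0 / df


def cochran_q_tau2(z_list, var_list) -> tuple[float, float]:
    """Cochran's Q heterogeneity statistic and the DerSimonian-Laird
    between-study variance tau^2 (truncated at zero).

    Q = sum w_k (z_k - z_FE)^2 with fixed-effect weights w_k = 1/var_k and
    z_FE the fixed-effect average; tau^2 = max(0, (Q - (Z-1)) / (sum w -
    sum w^2 / sum w)).  A single study yields Q = tau^2 = 0.
    """
    z = np.asarray(z_list, dtype=float)
    v = np.asarray(var_list, dtype=float)
    if z.shape != v.shape or z.size == 0:
        raise DataError("z values and variances must be non-empty and equal length")
    if np.any(v <= 0):
        raise DataError("variances must be positive")
    if z.size == 1:
        return 0.0, 0.0
    w = 1.0 / v
    sw = w.sum()
    z_fe = float((w * z).sum() / sw)
    q = float((w * (z - z_fe) ** 2).sum())
    denom = sw - (w * w).sum() / sw
    tau2 = max(0.0, (q - (z.size - 1)) / denom) if denom > 0 else 0.0
    return q, float(tau2)


def combine_z(z_list, var_list, tau2: float = 0.0) -> tuple[float, float]:
    """Random-effects weighted average of z-values.

    Weights w_k = 1/(var_k + tau^2); returns (z-bar, se) with
    se = 1/sqrt(sum w_k).
    """
    z = np.asarray(z_list, dtype=float)
    v = np.asarray(var_list, dtype=float)
    if z.size == 0:
        raise DataError("cannot combine an empty list of effects")
    if z.shape != v.shape:
        raise DataError("z values and variances must have equal length")
    if tau2 < 0:
        raise DataError("tau^2 must be non-negative")
    w = 1.0 / (v + tau2)
    sw = w.sum()
    return float((w * z).sum() / sw), float(1.0 / np.sqrt(sw))


def _pair_effects(ens: DatasetEnsemble, cfg: AnalysisConfig):
    """Per-dataset partial correlations for every pair.

    Returns (pairs, r: Z x P array, var: Z x P array, g per dataset).
    """
    gene_ids = ens.gene_ids
    n = len(gene_ids)
    iu = np.triu_indices(n, k=1)
    # canonical unordered pairs need sorted ids; reindex the matrices
    order = np.argsort(np.asarray(gene_ids, dtype=object))
    sorted_ids = [gene_ids[i] for i in order]
    pairs = [(sorted_ids[i], sorted_ids[j]) for i, j in zip(*iu)]
    r_rows, var_rows, gs, ns = [], [], [], []
    for d in ens:
        try:
            am = partial_correlation_matrix(d, order=cfg.partial_order)
        except DataError as exc:
            raise DataError(f"dataset {d.dataset_id!r}: {exc}") from exc
        stat = am.stat[np.ix_(order, order)]
        r_rows.append(stat[iu])
        var_rows.append(np.full(len(pairs), z_variance(am.n_samples, am.order)))
        gs.append(am.order)
        ns.append(am.n_samples)
    return pairs, np.vstack(r_rows), np.vstack(var_rows), gs, ns


def _dl_tau2_vec(z: np.ndarray, var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Cochran Q / DerSimonian-Laird tau^2 over columns (pairs)."""
    w = 1.0 / var
    sw = w.sum(axis=0)
    z_fe = (w * z).sum(axis=0) / sw
    q = (w * (z - z_fe) ** 2).sum(axis=0)
    denom = sw - (w * w).sum(axis=0) / sw
    zsize = z.shape[0]
    if zsize == 1:
        return np.zeros_like(q), np.zeros_like(q)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.where(denom > 0, np.maximum(0.0, (q - (zsize - 1)) / denom), 0.0)
    return q, tau2


def ftcct(ens: DatasetEnsemble, cfg: AnalysisConfig | None = None) -> EdgeScoreTable:
    """Combine per-dataset partial correlations across the ensemble.

    Returns a score table with the combined correlation r-bar as effect,
    |r-bar| as ranking score, and per-pair heterogeneity diagnostics Q and
    tau^2; the combined p-value follows cfg.significance_test.
    """
    cfg = cfg or AnalysisConfig()
    pairs, r, var, gs, ns = _pair_effects(ens, cfg)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    q, tau2 = _dl_tau2_vec(z, var)
    w = 1.0 / (var + tau2[None, :])
    sw = w.sum(axis=0)
    z_bar = (w * z).sum(axis=0) / sw
    se = 1.0 / np.sqrt(sw)
    r_bar = np.tanh(z_bar)
    if cfg.significance_test == "z":
        stat = z_bar / se
        p = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        # t-test on the combined coefficient with effective sample size
        # derived from the combined variance: se^2 = 1/(n_eff - 3)
        n_eff = 3.0 + 1.0 / se**2
        df = n_eff - 2.0
        stat = r_bar * np.sqrt(df / (1.0 - r_bar**2))
        p = 2.0 * stats.t.sf(np.abs(stat), df)
    p = np.minimum(p, 1.0)
    table = pd.DataFrame(
        {
            "gene_a": [a for a, _ in pairs],
            "gene_b": [b for _, b in pairs],
            "effect": r_bar,
            "score": np.abs(r_bar),
            "statistic": stat,
            "p_value": p,
            "z_bar": z_bar,
            "se": se,
            "Q": q,
            "tau2": tau2,
        }
    )
    for k, d in enumerate(ens):
        table[f"r_{d.dataset_id}"] = r[k]
    return EdgeScoreTable(table, method="ftcct")


def ficpt(ens: DatasetEnsemble, cfg: AnalysisConfig | None = None) -> EdgeScoreTable:
    """Fisher's combined probability test across the ensemble.

    Per pair, per-dataset two-sided p-values of the partial correlation
    (t-test with df = N_k - 2 - g) are combined as S = -2 sum ln p_k; the
    combined p is the chi-squared survival at S with 2Z degrees of freedom.
    S doubles as the ranking score.
    """
    cfg = cfg or AnalysisConfig()
    pairs, r, _, gs, ns = _pair_effects(ens, cfg)
    r = np.clip(r, -R_CLIP, R_CLIP)
    p_k = np.empty_like(r)
    for k in range(r.shape[0]):
        df = ns[k] - 2 - gs[k]
        if df < 1:
            raise DataError(
                f"dataset {ens.datasets[k].dataset_id!r}: t-test needs "
                f"N_k - 2 - g >= 1, got {df}"
            )
        t = r[k] * np.sqrt(df / (1.0 - r[k] ** 2))
        p_k[k] = np.minimum(2.0 * stats.t.sf(np.abs(t), df), 1.0)
    if np.any((p_k < 0) | (p_k > 1)):
        raise DataError("per-dataset p-values must lie in [0, 1]")
    s = -2.0 * np.log(np.maximum(p_k, P_FLOOR)).sum(axis=0)
    z_count = r.shape[0]
    p_comb = stats.chi2.sf(s, 2 * z_count)
    mean_r = r.mean(axis=0)
    table = pd.DataFrame(
        {
            "gene_a": [a for a, _ in pairs],
            "gene_b": [b for _, b in pairs],
            "effect": mean_r,
            "score": s,
            "statistic": s,
            "p_value": p_comb,
        }
    )
    for k, d in enumerate(ens):
        table[f"p_{d.dataset_id}"] = p_k[k]
    return EdgeScoreTable(table, method="ficpt")
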