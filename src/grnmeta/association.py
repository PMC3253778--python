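"""Per-dataset pairwise effect sizes.

Pearson and partial correlation (first order or full order via the inverse
correlation matrix), their significance tests, and a mutual-information
matrix used by the information-theoretic baselines.

The full-order partial correlation between genes i and j given all other
genes is read off the precision matrix Omega = R^-1 of the gene-gene
correlation matrix R:

    r_ij.rest = -omega_ij / sqrt(omega_ii * omega_jj)

and is identical to the correlation of the residuals of i and j after
regressing each on the remaining genes.  Significance tests account for the
number of conditioned variables g through the degrees of freedom n - 2 - g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import AssociationMatrix, DataError, ExpressionDataset

__all__ = [
    "pearson_matrix",
    "partial_correlation_matrix",
    "correlation_to_pvalue",
    "correlation_test",
    "CorrelationTest",
    "mutual_information_matrix",
]

#: Condition number above which the correlation matrix is ridge-shrunk
#: before inversion, and the shrinkage intensity applied then.
CONDITION_LIMIT = 1e8
RIDGE_LAMBDA = 0.05


def _check_variance(d: ExpressionDataset) -> None:
    sd = d.values.std(axis=1)
    flat = [g for g, s in zip(d.gene_ids, sd) if s == 0.0]
    if flat:
        raise DataError(
            f"zero-variance gene(s) {flat} in dataset {d.dataset_id!r}; "
            "correlation is undefined"
        )


def pearson_matrix(d: ExpressionDataset) -> AssociationMatrix:
    """Pairwise Pearson correlation of all gene profiles."""
    _check_variance(d)
    r = np.corrcoef(d.values)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return AssociationMatrix(d.gene_ids, r, kind="pearson", n_samples=d.n_samples)


def partial_correlation_matrix(
    d: ExpressionDataset, order: str = "full", shrink: bool = True
) -> AssociationMatrix:
    """Partial correlation between every gene pair.

    order='full' conditions each pair on all remaining genes via the
    precision matrix; order='first' conditions on the single strongest
    confounder k, the gene maximising |r_ik * r_jk|, using

        r_ij.k = (r_ij - r_ik r_jk) / sqrt((1 - r_ik^2)(1 - r_jk^2))

    With exactly three genes both orders coincide.  Near-singular
    correlation matrices are ridge-shrunk towards the identity when
    ``shrink`` is enabled, otherwise inversion failure raises.
    """
    if order not in ("full", "first"):
        raise DataError(f"order must be 'full' or 'first', got {order!r}")
    _check_variance(d)
    n_genes = d.n_genes
    if n_genes < 3:
        raise DataError("partial correlation needs at least 3 genes")
    r = np.corrcoef(d.values)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)

    if order == "full":
        if d.n_samples <= n_genes and not shrink:
            raise DataError(
                f"full-order partial correlation needs more samples "
                f"({d.n_samples}) than genes ({n_genes}) unless shrinkage is enabled"
            )
        if np.linalg.cond(r) > CONDITION_LIMIT:
            if not shrink:
                raise DataError(
                    "correlation matrix is numerically singular; enable "
                    "shrinkage or drop collinear genes"
                )
            r = (1.0 - RIDGE_LAMBDA) * r + RIDGE_LAMBDA * np.eye(n_genes)
        try:
            omega = np.linalg.inv(r)
        except np.linalg.LinAlgError as exc:
            raise DataError(
                "correlation matrix is singular; enable shrinkage or drop genes"
            ) from exc
        denom = np.sqrt(np.outer(np.diag(omega), np.diag(omega)))
        pc = -omega / denom
        np.fill_diagonal(pc, 1.0)
        pc = (pc + pc.T) / 2.0
        pc = np.clip(pc, -1.0, 1.0)
        return AssociationMatrix(
            d.gene_ids, pc, kind="partial", n_samples=d.n_samples, order=n_genes - 2
        )

    # first order: condition on the strongest confounder per pair
    pc = np.eye(n_genes)
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            others = [k for k in range(n_genes) if k not in (i, j)]
            prod = np.abs(r[i, others] * r[j, others])
            k = others[int(np.argmax(prod))]
            denom = np.sqrt((1.0 - r[i, k] ** 2) * (1.0 - r[j, k] ** 2))
            if denom == 0.0:
                raise DataError(
                    f"first-order partial correlation undefined: conditioning gene "
                    f"{d.gene_ids[k]!r} is perfectly correlated with the pair"
                )
            val = (r[i, j] - r[i, k] * r[j, k]) / denom
            pc[i, j] = pc[j, i] = np.clip(val, -1.0, 1.0)
    return AssociationMatrix(
        d.gene_ids, pc, kind="partial", n_samples=d.n_samples, order=1
    )


@dataclass(frozen=True)
class CorrelationTest:
    """Result of a correlation significance test."""

    p_value: float
    statistic: float
    df: float
    degenerate: bool = False


def correlation_test(
    r: float, n: int, n_conditioned: int = 0, test: str = "t"
) -> CorrelationTest:
    """Two-sided significance test for a (partial) correlation coefficient.

    test='t' uses t = r * sqrt((n - 2 - g) / (1 - r^2)) with df = n - 2 - g;
    test='z' uses the Fisher transform z = arctanh(r) * sqrt(n - 3 - g)
    against the standard normal.  g = ``n_conditioned`` is the number of
    conditioned variables.  |r| = 1 yields p = 0 with the degenerate flag
    set rather than an exception.
    """
    if test not in ("t", "z"):
        raise DataError(f"test must be 't' or 'z', got {test!r}")
    if abs(r) > 1.0:
        raise DataError(f"correlation must lie in [-1, 1], got {r}")
    g = int(n_conditioned)
    if test == "t":
        df = n - 2 - g
        if df < 1:
            raise DataError(f"t-test needs n - 2 - g >= 1, got df={df}")
        if abs(r) == 1.0:
            return CorrelationTest(0.0, np.inf if r > 0 else -np.inf, df, True)
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
        return CorrelationTest(float(min(p, 1.0)), float(t), float(df))
    df = n - 3 - g
    if df < 1:
        raise DataError(f"z-test needs n - 3 - g >= 1, got {df}")
    if abs(r) == 1.0:
        return CorrelationTest(0.0, np.inf if r > 0 else -np.inf, df, True)
    z = np.arctanh(r) * np.sqrt(df)
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationTest(float(min(p, 1.0)), float(z), float(df))


def correlation_to_pvalue(
    r: float, n: int, n_conditioned: int = 0, test: str = "t"
) -> float:
    """Two-sided p-value for a (partial) correlation; see correlation_test."""
    return correlation_test(r, n, n_conditioned, test).p_value


def mutual_information_matrix(
    d: ExpressionDataset, estimator: str = "gaussian", n_bins: int = 10
) -> AssociationMatrix:
    """Pairwise mutual information in nats.

    estimator='gaussian' uses the closed form MI = -1/2 ln(1 - r^2) implied
    by a bivariate normal; estimator='bins' is the plug-in estimate on an
    equal-width discretisation with ``n_bins`` bins per gene.
    """
    if estimator not in ("gaussian", "bins"):
        raise DataError(f"estimator must be 'gaussian' or 'bins', got {estimator!r}")
    _check_variance(d)
    n_genes = d.n_genes
    if estimator == "gaussian":
        r = np.corrcoef(d.values)
        r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
        mi = -0.5 * np.log1p(-(r * r))
        np.fill_diagonal(mi, -0.5 * np.log1p(-(1.0 - 1e-15) ** 2))
    else:
        if n_bins < 1:
            raise DataError(f"bin count must be positive, got {n_bins}")
        discrete = np.empty_like(d.values, dtype=np.intp)
        for i in range(n_genes):
            x = d.values[i]
            edges = np.linspace(x.min(), x.max(), n_bins + 1)
            discrete[i] = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
        n = d.n_samples
        mi = np.zeros((n_genes, n_genes))
        for i in range(n_genes):
            for j in range(i, n_genes):
                joint = np.zeros((n_bins, n_bins))
                np.add.at(joint, (discrete[i], discrete[j]), 1.0)
                joint /= n
                px = joint.sum(axis=1, keepdims=True)
                py = joint.sum(axis=0, keepdims=True)
                with np.errstate(divide="ignore", invalid="ignore"):
                    terms = joint * np.log(joint / (px * py))
                mi[i, j] = mi[j, i] = np.nansum(terms)
        mi = np.maximum(mi, 0.0)
    return AssociationMatrix(d.gene_ids, mi, kind="mi", n_samples=d.n_samples)
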