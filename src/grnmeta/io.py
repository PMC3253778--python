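"""Readers and writers for the package's plain-text formats.

Three tab-separated formats are supported, all deterministic and diff-able
(tab delimiter, '.' decimal, no quoting, case-sensitive gene ids):

* expression matrix — genes x samples, first column gene ids, first row
  sample ids;
* edge list — regulator, target, sign (+/-), optional weight; a
  SIF-compatible three-column variant is accepted;
* score table — one row per unordered gene pair with the standard columns
  gene_a, gene_b, effect, score, statistic, p_value plus method extras.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DataError,
    Edge,
    EdgeScoreTable,
    ExpressionDataset,
    GeneNetwork,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_scores",
    "write_scores",
]

_FLOAT_FMT = "%.17g"  # shortest-exact round trip for doubles


def read_expression(path: str | Path, dataset_id: str | None = None) -> ExpressionDataset:
    """Read a genes x samples expression matrix from tab-separated text."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # noqa: BLE001 - rewrap as a data error
        raise DataError(f"cannot parse expression file {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise DataError(f"duplicate gene ids in {path}: {dupes}")
    non_numeric = frame.columns[
        [not np.issubdtype(dt, np.number) for dt in frame.dtypes]
    ]
    if len(non_numeric):
        raise DataError(
            f"non-numeric expression values in {path}, columns {list(non_numeric)}"
        )
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem,
        gene_ids=[str(g) for g in frame.index],
        values=frame.to_numpy(dtype=float),
        sample_ids=[str(c) for c in frame.columns],
    )


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(
        path, sep="\t", float_format=_FLOAT_FMT, quoting=csv.QUOTE_NONE
    )


def _parse_sign(token: str) -> int:
    token = token.strip()
    if token in ("+", "+1", "1", "activation"):
        return 1
    if token in ("-", "-1", "repression"):
        return -1
    return 1  # documented default: unknown sign treated as activation


def read_network(path: str | Path, genes: Sequence[str] | None = None) -> GeneNetwork:
    """Read an edge list (regulator, target[, sign[, weight]]) into a network.

    The gene universe defaults to the genes appearing in the file, in order
    of first appearance; pass ``genes`` to fix a larger universe (needed for
    isolated genes).
    """
    path = Path(path)
    edges: list[Edge] = []
    seen_genes: list[str] = []
    seen_set: set[str] = set()
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2:
                raise DataError(f"{path}:{line_no}: expected at least 2 columns")
            reg, tgt = fields[0].strip(), fields[1].strip()
            sign = _parse_sign(fields[2]) if len(fields) >= 3 else 1
            try:
                weight = float(fields[3]) if len(fields) >= 4 else 1.0
            except ValueError as exc:
                raise DataError(f"{path}:{line_no}: bad weight {fields[3]!r}") from exc
            if reg == tgt:
                raise DataError(f"{path}:{line_no}: self-loop on gene {reg!r}")
            for g in (reg, tgt):
                if g not in seen_set:
                    seen_set.add(g)
                    seen_genes.append(g)
            edges.append(Edge(reg, tgt, sign, weight))
    universe = list(genes) if genes is not None else seen_genes
    return GeneNetwork(universe, edges)


def write_network(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in net.edges:
            sign = "+" if e.sign > 0 else "-"
            fh.write(f"{e.regulator}\t{e.target}\t{sign}\t{_FLOAT_FMT % e.weight}\n")


def read_scores(path: str | Path, method: str | None = None) -> EdgeScoreTable:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", header=0)
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"cannot parse score table {path}: {exc}") from exc
    if method is None:
        if "method" not in table.columns:
            raise DataError(f"{path}: no 'method' column and no method given")
        tags = set(table["method"])
        if len(tags) != 1:
            raise DataError(f"{path}: mixed method tags {sorted(tags)}")
        method = tags.pop()
    return EdgeScoreTable(table.drop(columns=["method"], errors="ignore"), method)


def write_scores(scores: EdgeScoreTable, path: str | Path) -> None:
    out = scores.table.copy()
    out.insert(len(out.columns), "method", scores.method)
    out.to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT, quoting=csv.QUOTE_NONE
    )
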