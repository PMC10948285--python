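"""Reading and writing the plain-text formats of the pipeline.

Expression matrices are tab-separated: first column gene identifiers,
header row sample identifiers.  Regulator lists are one identifier per
line.  Edge lists and metric tables are TSV with fixed column sets.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .evaluate import EvalResult
from .network import EdgeRecord

__all__ = [
    "ExpressionFormatError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_regulators",
    "read_edges",
    "write_edges",
    "read_truth_edges",
    "write_truth_edges",
    "write_metrics",
]

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["regulator", "target", "weight", "subanalysis"]


class ExpressionFormatError(ValueError):
    """Malformed expression matrix file."""


def read_expression_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Load a genes x samples expression matrix from TSV.

    Rejects duplicate gene identifiers, missing entries and non-numeric
    cells, naming the offending gene and 1-based file line.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ExpressionFormatError(f"{path}: ragged or malformed table: {exc}") from exc
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        line = int(np.flatnonzero(raw.index == dup)[-1]) + 2  # +1 header, +1 1-based
        raise ExpressionFormatError(f"{path}: duplicate gene id {dup!r} (line {line})")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.to_numpy().any():
        gene = raw.index[bad.any(axis=1)][0]
        line = int(raw.index.get_loc(gene)) + 2
        col = bad.columns[bad.loc[gene]][0]
        cell = raw.loc[gene, col]
        kind = "missing value" if pd.isna(cell) else f"non-numeric cell {cell!r}"
        raise ExpressionFormatError(
            f"{path}: {kind} for gene {gene!r}, sample {col!r} (line {line})"
        )
    values = values.astype(np.float64)
    values.index.name = None  # matrix contract: unnamed gene index
    logger.info("read %s: %d genes x %d samples", path, *values.shape)
    return values


def write_expression_tsv(path: Union[str, Path], expr: pd.DataFrame) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_regulators(path: Union[str, Path]) -> List[str]:
    """One regulator identifier per line; blank lines ignored."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    regs = [ln for ln in lines if ln]
    if not regs:
        raise ValueError(f"{path}: empty regulator list — no candidate features")
    return regs


def write_edges(path: Union[str, Path], edges: Sequence[EdgeRecord]) -> None:
    df = pd.DataFrame(
        [(e.regulator, e.target, e.weight, e.subanalysis) for e in edges],
        columns=EDGE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_edges(path: Union[str, Path]) -> List[EdgeRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing edge columns {sorted(missing)}")
    return [
        EdgeRecord(str(r.regulator), str(r.target), float(r.weight), str(r.subanalysis))
        for r in df.itertuples(index=False)
    ]


def write_truth_edges(path: Union[str, Path], edges: Iterable[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\n")
        for r, t in sorted(edges):
            fh.write(f"{r}\t{t}\n")


def read_truth_edges(path: Union[str, Path]) -> Set[Tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return {(str(r.regulator), str(r.target)) for r in df.itertuples(index=False)}


def write_metrics(path: Union[str, Path], results: Sequence[EvalResult]) -> None:
    df = pd.DataFrame(
        [(r.k, r.precision, r.recall, r.f1, r.n_truth) for r in results],
        columns=["k", "precision", "recall", "f1", "n_truth"],
    )
    df.to_csv(path, sep="\t", index=False)
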