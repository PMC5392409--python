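"""Readers and writers for labelled expression matrices and run outputs.

File orientation is always genes x samples: the first column holds gene
identifiers and the header row holds sample identifiers.  Gene ranks in
user-facing files are 1-based; everything in memory is 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .exceptions import ParseError

__all__ = ["ExpressionMatrix", "read_matrix", "write_results"]


@dataclass
class ExpressionMatrix:
    """m x n numeric matrix with gene and sample identifiers."""

    values: np.ndarray
    gene_ids: List[str] = field(default=None)
    sample_ids: List[str] = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParseError("expression matrix must be 2-D")
        m, n = self.values.shape
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{i + 1}" for i in range(m)]
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{j + 1}" for j in range(n)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != m or len(self.sample_ids) != n:
            raise ParseError("label counts do not match the matrix shape")
        if len(set(self.gene_ids)) != m:
            raise ParseError("gene identifiers are not unique")
        if len(set(self.sample_ids)) != n:
            raise ParseError("sample identifiers are not unique")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"non-finite value for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self):
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)


def _infer_delimiter(path):
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".tab", ".txt"):
        return "\t"
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(path, delimiter=None, center=False):
    """Parse a TSV/CSV file into an :class:`ExpressionMatrix`.

    The delimiter is inferred from the extension (or the header line)
    unless forced.  Non-numeric cells and ragged rows raise
    :class:`~l12glpca.exceptions.ParseError` naming the offending cell.
    """
    sep = delimiter or _infer_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} for gene "
            f"{df.index[i]!r}, sample {df.columns[j]!r} (line {i + 2})"
        )
    values = numeric.to_numpy(dtype=float)
    if center:
        values = values - values.mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        values=values,
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
    )


def write_matrix(expr, path, delimiter="\t"):
    """Write an :class:`ExpressionMatrix` back to TSV/CSV."""
    expr.to_frame().to_csv(path, sep=delimiter)


def write_results(decomp, expr, prefix, report_extra=None):
    """Write a solver run: ``U.tsv``, ``V.tsv``, ``S.tsv``, ``ranking.tsv``
    and ``report.json`` under the given path prefix.

    The ranking file lists every gene with its loading-norm score and
    1-based rank; the report echoes the configuration and traces so a run
    can be repeated bit-identically.
    """
    from dataclasses import asdict

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    k = decomp.U.shape[1]
    comp_ids = [f"PC{i + 1}" for i in range(k)]
    pd.DataFrame(decomp.U, index=expr.gene_ids, columns=comp_ids).to_csv(
        f"{prefix}.U.tsv", sep="\t")
    pd.DataFrame(decomp.V, index=expr.sample_ids, columns=comp_ids).to_csv(
        f"{prefix}.V.tsv", sep="\t")
    pd.DataFrame(decomp.S, index=expr.gene_ids, columns=expr.sample_ids).to_csv(
        f"{prefix}.S.tsv", sep="\t")

    scores = decomp.feature_scores
    order = np.lexsort((np.arange(len(scores)), -scores))
    ranking = pd.DataFrame({
        "gene_id": [expr.gene_ids[i] for i in order],
        "score": scores[order],
        "rank": np.arange(1, len(order) + 1),
    })
    ranking.to_csv(f"{prefix}.ranking.tsv", sep="\t", index=False)

    report = {
        "config": asdict(decomp.config),
        "iterations": int(decomp.iterations),
        "converged": bool(decomp.converged),
        "final_objective": float(decomp.objective_trace[-1]),
        "objective_is_penalty_only": bool(decomp.objective_is_penalty_only),
        "objective_trace": [float(x) for x in decomp.objective_trace],
        "residual_trace": [float(x) for x in decomp.residual_trace],
    }
    if report_extra:
        report.update(report_extra)
    with open(f"{prefix}.report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return {
        "U": f"{prefix}.U.tsv",
        "V": f"{prefix}.V.tsv",
        "S": f"{prefix}.S.tsv",
        "ranking": f"{prefix}.ranking.tsv",
        "report": f"{prefix}.report.json",
    }
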