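"""Reading and writing the pipeline's file formats.

Matrices travel as TSV/CSV with a header row and an identifier first
column (delimiter sniffed from the extension); trees as Newick with
`[&pi=..,p=..]` node comments plus a YAML sidecar of node probabilities.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import BulkMatrix, Covariate, DesignSpec, ProportionMatrix
from .tree import CellTypeTree

__all__ = [
    "read_table",
    "read_bulk",
    "read_proportions",
    "read_design",
    "write_table",
    "read_tree",
    "write_tree",
]


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line."""


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path) -> pd.DataFrame:
    """Numeric table with id first column; validates ids and every cell.

    Raises :class:`ParseError` naming the 1-based file line of the first
    non-numeric or missing cell, and on duplicated identifiers.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_delimiter(path), index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated identifier {dup!r}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicated column {dup!r}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.to_numpy().any():
        row = int(np.argmax(bad.any(axis=1).to_numpy()))
        col = bad.columns[int(np.argmax(bad.iloc[row].to_numpy()))]
        cell = raw.iloc[row][col]
        kind = "missing value" if pd.isna(cell) else f"non-numeric value {cell!r}"
        raise ParseError(
            f"{path}, line {row + 2}: {kind} in column {col!r} "
            f"(feature/sample {raw.index[row]!r})"
        )
    values.index = raw.index.astype(str)
    values.columns = raw.columns.astype(str)
    return values


def write_table(frame: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    path = Path(path)
    frame.to_csv(path, sep=_delimiter(path), index_label=index_label)


def read_bulk(path: str | Path) -> BulkMatrix:
    """Features x samples bulk matrix (log expression or beta values)."""
    table = read_table(path)
    return BulkMatrix(
        values=table.to_numpy(dtype=float),
        feature_ids=list(table.index),
        sample_ids=list(table.columns),
    )


def read_proportions(path: str | Path) -> ProportionMatrix:
    """Samples x cell-types composition matrix; rows renormalized if needed."""
    table = read_table(path)
    return ProportionMatrix(
        values=table.to_numpy(dtype=float),
        cell_types=list(table.columns),
        sample_ids=list(table.index),
    )


def read_design(
    path: str | Path,
    tested: str | None = None,
    cell_type_specific: tuple[str, ...] | list[str] = (),
    sample_ids: list[str] | None = None,
) -> DesignSpec:
    """Samples x covariates design table.

    ``tested`` names the covariate of interest (default: the first
    column); every other column is a confounder, flagged cell-type-
    specific when listed in ``cell_type_specific``, shared otherwise.
    """
    table = read_table(path)
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in table.index]
        if missing:
            raise ParseError(f"{path}: design is missing samples {missing[:5]}")
        table = table.loc[sample_ids]
    if tested is None:
        tested = table.columns[0]
    if tested not in table.columns:
        raise ParseError(f"{path}: no tested covariate column {tested!r}")
    unknown = [c for c in cell_type_specific if c not in table.columns]
    if unknown:
        raise ParseError(f"{path}: unknown confounder column(s) {unknown}")
    confounders = [
        Covariate(
            name=c,
            values=table[c].to_numpy(dtype=float),
            cell_type_specific=c in cell_type_specific,
        )
        for c in table.columns
        if c != tested
    ]
    return DesignSpec(
        tested=table[tested].to_numpy(dtype=float),
        confounders=confounders,
        tested_name=tested,
    )


def write_tree(tree: CellTypeTree, newick_path: str | Path, yaml_path: str | Path | None = None) -> None:
    Path(newick_path).write_text(tree.to_newick() + "\n")
    if yaml_path is not None:
        Path(yaml_path).write_text(tree.priors_to_yaml())


def read_tree(newick_path: str | Path, yaml_path: str | Path | None = None) -> CellTypeTree:
    newick = Path(newick_path).read_text()
    if yaml_path is not None:
        doc = yaml.safe_load(Path(yaml_path).read_text())
        return CellTypeTree.from_newick(newick, priors=doc["nodes"])
    return CellTypeTree.from_newick(newick)
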