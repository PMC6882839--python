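"""Readers and writers for the tabular formats the pipeline touches.

TSV is the canonical matrix format (mirroring the genomicMatrix /
cBioPortal export layouts); gene sets use the standard GMT interchange
format. The internal convention is samples-in-rows everywhere; readers
normalize orientation at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from paretotasks.preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its expected tabular format."""


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways), keyed by unique set name."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def read_expression_matrix(
    path: str | Path,
    orientation: str = "samples_in_rows",
    metadata: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix, normalizing to samples-in-rows.

    The first row and first column are identifiers; the body must be
    complete and numeric. ``orientation`` is ``samples_in_rows`` or
    ``genes_in_rows`` (the genomicMatrix layout).
    """
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for name in header:  # pandas silently mangles duplicate columns
        if name in seen:
            raise FormatError(f"duplicate column identifier in {path}: {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate row identifier in {path}: {dup[0]!r}")
    try:
        numeric = df.astype(float)
    except ValueError:
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy() & df.notna().to_numpy())
        if len(bad):
            r, c = bad[0]
            raise FormatError(
                f"non-numeric cell in {path} at row {df.index[r]!r}, "
                f"column {df.columns[c]!r}: {df.iat[r, c]!r}"
            ) from None
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"missing value in expression matrix {path} at row "
            f"{numeric.index[r]!r}, column {numeric.columns[c]!r}"
        )
    if orientation == "genes_in_rows":
        numeric = numeric.T
    return ExpressionMatrix(numeric, metadata)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path,
                            orientation: str = "samples_in_rows") -> None:
    """Write a TSV expression matrix with full double precision."""
    df = expr.values if orientation == "samples_in_rows" else expr.values.T
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV metadata / clinical / response table (missing values allowed)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, members per tab-separated line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description, *genes = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = [g for g in genes if g]
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
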