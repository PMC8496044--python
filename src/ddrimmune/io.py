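"""Readers and writers for the delimited formats the pipeline touches.

Gene sets travel as GMT (tab-separated: name, description, member genes),
expression and signature matrices as TSV/CSV with a header row of sample or
cell-type identifiers and a first column of gene symbols, and immune gene
lists as plain text with one symbol per line.

Gene symbols are matched case-insensitively and stored upper-case throughout,
because symbol case is inconsistent across KEGG/Reactome exports and
literature-derived lists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_expression",
    "write_expression",
    "read_signature",
    "filter_gene_sets",
    "validate_expression",
    "validate_signature",
]


class GmtParseError(ValueError):
    """Raised when a GMT line cannot be parsed."""


def _normalize_symbols(symbols: Iterable[str]) -> tuple[str, ...]:
    """Upper-case, strip, and de-duplicate symbols preserving first occurrence."""
    seen: dict[str, None] = {}
    for s in symbols:
        s = s.strip().upper()
        if s:
            seen.setdefault(s, None)
    return tuple(seen)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: unique upper-cased member symbols in a stable order."""

    name: str
    description: str = ""
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        normalized = _normalize_symbols(self.members)
        if not normalized:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(normalized) != len(tuple(self.members)):
            logger.warning(
                "gene set %s: %d duplicate/blank member symbols removed",
                self.name,
                len(tuple(self.members)) - len(normalized),
            )
        object.__setattr__(self, "members", normalized)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.members

    def intersect(self, universe: Iterable[str]) -> "GeneSet | None":
        """Members restricted to `universe` (upper-cased); None if empty."""
        allowed = {g.upper() for g in universe}
        kept = tuple(g for g in self.members if g in allowed)
        if not kept:
            return None
        return GeneSet(self.name, self.description, kept)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of gene sets with unique names."""

    sets: tuple[GeneSet, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", tuple(self.sets))
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(tuple(self[n] for n in names), self.source_label)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a GeneSetCollection.

    Each non-blank line must have at least three tab-separated fields:
    name, description, and one or more gene symbols.  Duplicate member
    symbols within a line are dropped with a warning; a duplicate set
    name is an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description, *genes = fields
            sets.append(GeneSet(name=name, description=description, members=tuple(genes)))
    return GeneSetCollection(tuple(sets), source_label=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; tabs in descriptions are replaced by spaces."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in collection:
            desc = s.description
            if "\t" in desc:
                logger.warning("gene set %s: tab in description replaced by space", s.name)
                desc = desc.replace("\t", " ")
            fh.write("\t".join([s.name, desc, *s.members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; '#' comments and blank lines are skipped."""
    path = Path(path)
    symbols: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.append(line)
    out = list(_normalize_symbols(symbols))
    if not out:
        raise ValueError(f"{path}: no gene symbols found")
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n", encoding="utf-8")


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the genes x samples contract: unique labels, finite numeric body."""
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("expression matrix has zero genes or zero samples")
    if expr.index.has_duplicates:
        raise ValueError("expression matrix has duplicate gene symbols")
    if expr.columns.has_duplicates:
        raise ValueError("expression matrix has duplicate sample identifiers")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression matrix body is not numeric")
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite expression value at gene {expr.index[bad[0]]!r}, "
            f"sample {expr.columns[bad[1]]!r}"
        )
    return expr


def read_expression(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a genes x samples expression matrix from delimited text.

    Returns a DataFrame indexed by upper-cased gene symbols with sample
    identifiers as columns.  Duplicate gene symbols are collapsed by keeping
    the row with the highest mean (logged).  Non-numeric or missing cells
    raise a ValueError naming the offending gene and sample.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: expression matrix has zero genes or zero samples")
    df.index = df.index.astype(str).str.strip().str.upper()
    df.columns = df.columns.astype(str)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna().to_numpy()
    missing = df.isna()
    problems = bad | missing
    if problems.to_numpy().any():
        gi, si = np.argwhere(problems.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r}"
        )
    numeric = numeric.astype(float)

    if numeric.index.has_duplicates:
        means = numeric.mean(axis=1).to_numpy()
        keep_mask = np.zeros(len(numeric), dtype=bool)
        for sym in numeric.index.unique():
            idx = np.flatnonzero(numeric.index.to_numpy() == sym)
            if len(idx) > 1:
                logger.info(
                    "gene %s appears %d times; keeping the highest-mean row", sym, len(idx)
                )
            keep_mask[idx[np.argmax(means[idx])]] = True
        numeric = numeric.loc[keep_mask]
    return validate_expression(numeric)


def write_expression(expr: pd.DataFrame, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    expr.to_csv(path, sep=sep, index_label="gene")


def validate_signature(signature: pd.DataFrame) -> pd.DataFrame:
    """Check the genes x cell-types contract: non-negative, >=2 informative columns."""
    if signature.shape[1] < 2:
        raise ValueError("signature matrix needs at least 2 cell types")
    values = signature.to_numpy()
    if (values < 0).any():
        raise ValueError("signature matrix contains negative values")
    zero_cols = signature.columns[(values == 0).all(axis=0)]
    if len(zero_cols):
        raise ValueError(f"signature columns are all zero: {list(zero_cols)}")
    if signature.index.has_duplicates or signature.columns.has_duplicates:
        raise ValueError("signature matrix has duplicate gene or cell-type labels")
    return signature


def read_signature(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a genes x cell-types signature matrix (same layout as expression)."""
    sig = read_expression(path, delimiter)
    return validate_signature(sig)


def filter_gene_sets(
    collection: GeneSetCollection,
    expr: pd.DataFrame,
    min_size: int = 5,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect each set with the measured genes and apply size bounds.

    Sets whose intersected size falls outside [min_size, max_size] are
    dropped, each with a log entry.  Raises if every set is dropped.
    Idempotent for fixed arguments.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if not (max_size is None or math.isinf(max_size)) and max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    upper = math.inf if max_size is None else max_size
    universe = set(expr.index)
    kept: list[GeneSet] = []
    for s in collection:
        inter = s.intersect(universe)
        n = 0 if inter is None else len(inter)
        if n < min_size or n > upper:
            logger.info(
                "dropping gene set %s: %d of %d members measured (bounds [%s, %s])",
                s.name, n, len(s), min_size, upper,
            )
            continue
        kept.append(inter)
    if not kept:
        raise ValueError(
            "all gene sets dropped after intersection with the expression matrix; "
            "relax min_size/max_size or check gene symbol conventions"
        )
    return GeneSetCollection(tuple(kept), collection.source_label)
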