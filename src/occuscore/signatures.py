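"""Derivation of cell-type-specific marker gene sets from a reference
expression-profile table, plus GMT read/write.

The reference table has gene rows and ``<celltype>|<timepoint>`` columns.
A gene is assigned to the single cell type whose aggregated expression
(mean or max over timepoints) is at least ``min_expr`` and exceeds every
other cell type's aggregated expression by a factor of ``fold_margin``.
Genes qualifying for no cell type (or, degenerately, for more than one,
which can only happen when all aggregated values are zero) are dropped.
The margin rule guarantees disjointness of the resulting sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CELL_TYPES",
    "ReferenceProfileTable",
    "SignatureSet",
    "SpecificityParams",
    "load_reference_profiles",
    "derive_signatures",
    "read_gmt",
    "write_gmt",
]

#: Cell-type vocabulary used by the default simulation and scoring configs.
DEFAULT_CELL_TYPES = [
    "basal", "club", "ciliated", "goblet", "AT1", "AT2",
    "lipofibroblast", "matrix_fibroblast", "myofibroblast",
    "epithelial", "myeloid",
]


class SignatureError(ValueError):
    """Raised for invalid reference tables or signature sets."""


@dataclass(frozen=True)
class ReferenceProfileTable:
    """Gene x (cell type, timepoint) non-negative expression profiles.

    ``expr`` is a 3-D array indexed ``[gene, cell_type, timepoint]``; a NaN
    entry means the (cell type, timepoint) column was absent from the input
    table (ragged timepoint coverage is allowed).
    """

    genes: tuple[str, ...]
    cell_types: tuple[str, ...]
    timepoints: tuple[str, ...]
    expr: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise SignatureError(f"duplicate gene identifiers: {dupes}")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise SignatureError("duplicate cell-type names")
        if len(self.timepoints) < 1:
            raise SignatureError("at least one timepoint required")
        expected = (len(self.genes), len(self.cell_types), len(self.timepoints))
        if self.expr.shape != expected:
            raise SignatureError(
                f"expr shape {self.expr.shape} != expected {expected}"
            )
        if np.nanmin(self.expr) < 0:
            raise SignatureError("negative expression values in reference table")

    def aggregate(self, how: Literal["mean", "max"] = "mean") -> pd.DataFrame:
        """Collapse timepoints to a gene x cell-type matrix."""
        if how == "mean":
            agg = np.nanmean(self.expr, axis=2)
        elif how == "max":
            agg = np.nanmax(self.expr, axis=2)
        else:
            raise SignatureError(f"unknown aggregation {how!r}")
        return pd.DataFrame(agg, index=list(self.genes), columns=list(self.cell_types))

    def to_frame(self) -> pd.DataFrame:
        """Flat frame with ``<celltype>|<timepoint>`` columns (NaN columns omitted)."""
        cols = {}
        for ci, ct in enumerate(self.cell_types):
            for ti, tp in enumerate(self.timepoints):
                col = self.expr[:, ci, ti]
                if not np.all(np.isnan(col)):
                    cols[f"{ct}|{tp}"] = col
        return pd.DataFrame(cols, index=list(self.genes)).rename_axis("gene")


@dataclass(frozen=True)
class SpecificityParams:
    """Parameters of the margin-over-second-best specificity rule."""

    fold_margin: float = 5.0
    min_expr: float = 1.0
    aggregation: Literal["mean", "max"] = "mean"

    def __post_init__(self) -> None:
        if not self.fold_margin > 1:
            raise SignatureError(f"fold_margin must be > 1, got {self.fold_margin}")
        if self.min_expr < 0:
            raise SignatureError(f"min_expr must be >= 0, got {self.min_expr}")
        if self.aggregation not in ("mean", "max"):
            raise SignatureError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class SignatureSet:
    """Disjoint assignment of marker genes to named cell types."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, genes in self.sets.items():
            if not genes:
                raise SignatureError(f"empty gene set {name!r}")
            for g in genes:
                if g in seen:
                    raise SignatureError(
                        f"gene {g!r} appears in both {seen[g]!r} and {name!r}"
                    )
                seen[g] = name

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignatureSet):
            return NotImplemented
        return {k: list(v) for k, v in self.sets.items()} == {
            k: list(v) for k, v in other.sets.items()
        }

    @property
    def cell_types(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> set[str]:
        return {g for genes in self.sets.values() for g in genes}


def load_reference_profiles(path: str | Path) -> ReferenceProfileTable:
    """Read a TSV with gene rows and ``<celltype>|<timepoint>`` columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.shape[1] == 0:
        raise SignatureError(f"{path}: no profile columns found")
    pairs = []
    for col in df.columns:
        if "|" not in col:
            raise SignatureError(
                f"{path}: malformed column header {col!r} "
                "(expected '<celltype>|<timepoint>')"
            )
        ct, tp = col.split("|", 1)
        if not ct or not tp:
            raise SignatureError(f"{path}: empty cell type or timepoint in {col!r}")
        pairs.append((ct, tp))
    if len(set(pairs)) != len(pairs):
        raise SignatureError(f"{path}: duplicate (cell type, timepoint) columns")
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise SignatureError(f"{path}: duplicate gene rows: {dupes}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise SignatureError(f"{path}: missing or non-numeric expression values")
    if (values < 0).any():
        bad = df.index[(values < 0).any(axis=1)][0]
        raise SignatureError(f"{path}: negative expression value for gene {bad!r}")

    cell_types = list(dict.fromkeys(ct for ct, _ in pairs))
    timepoints = list(dict.fromkeys(tp for _, tp in pairs))
    expr = np.full((df.shape[0], len(cell_types), len(timepoints)), np.nan)
    for j, (ct, tp) in enumerate(pairs):
        expr[:, cell_types.index(ct), timepoints.index(tp)] = values[:, j]
    return ReferenceProfileTable(
        genes=tuple(str(g) for g in df.index),
        cell_types=tuple(cell_types),
        timepoints=tuple(timepoints),
        expr=expr,
    )


def write_reference_profiles(ref: ReferenceProfileTable, path: str | Path) -> None:
    """Write a reference table in the TSV layout read by :func:`load_reference_profiles`."""
    ref.to_frame().to_csv(path, sep="\t")


def derive_signatures(
    ref: ReferenceProfileTable, params: SpecificityParams | None = None
) -> SignatureSet:
    """Assign each gene to at most one cell type by the margin rule.

    Gene ``g`` is assigned to cell type ``c`` iff its aggregated expression
    in ``c`` is >= ``min_expr`` and >= ``fold_margin`` times its aggregated
    expression in every other cell type.  At most one cell type can satisfy
    the margin for a gene with any nonzero expression; the all-zero ties
    case is left unassigned.
    """
    params = params or SpecificityParams()
    agg = ref.aggregate(params.aggregation)
    mat = agg.to_numpy()
    n_ct = mat.shape[1]
    sets: dict[str, list[str]] = {ct: [] for ct in ref.cell_types}
    n_unassigned = 0
    for gi, gene in enumerate(ref.genes):
        row = mat[gi]
        qualifying = [
            ci
            for ci in range(n_ct)
            if row[ci] >= params.min_expr
            and all(
                row[ci] >= params.fold_margin * row[cj]
                for cj in range(n_ct)
                if cj != ci
            )
        ]
        if len(qualifying) == 1:
            sets[ref.cell_types[qualifying[0]]].append(gene)
        else:
            n_unassigned += 1
            logger.debug("gene %s unassigned (%d qualifying types)",
                         gene, len(qualifying))
    sets = {ct: genes for ct, genes in sets.items() if genes}
    if not sets:
        raise SignatureError(
            "no gene qualified for any cell type with "
            f"fold_margin={params.fold_margin}, min_expr={params.min_expr}, "
            f"aggregation={params.aggregation!r}"
        )
    logger.debug("derive_signatures: %d genes unassigned", n_unassigned)
    prov = (
        f"fold_margin={params.fold_margin};min_expr={params.min_expr};"
        f"aggregation={params.aggregation}"
    )
    return SignatureSet(sets=sets, provenance=prov)


def write_gmt(sigs: SignatureSet, path: str | Path, description: str = "derived") -> None:
    """Write one ``name TAB description TAB gene...`` line per set."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name, genes in sigs.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path: str | Path) -> SignatureSet:
    """Parse a GMT file into a :class:`SignatureSet` (disjointness enforced)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SignatureError(
                    f"{path}:{lineno}: expected 'name<TAB>description<TAB>genes...'"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise SignatureError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                raise SignatureError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    if not sets:
        raise SignatureError(f"{path}: no gene sets found")
    return SignatureSet(sets=sets, provenance=f"read from {path.name}")
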