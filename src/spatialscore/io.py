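"""Shared data model and file I/O for single-cell tables, expression matrices
and gene signatures.

The pipeline's universal input is a :class:`CellTable`: one row per segmented
cell from a multiplexed tissue image (CODEX, Vectra/Opal + HALO, ...), carrying
the tissue-microarray spot it came from, the patient / response group /
timepoint, planar centroid coordinates, a curated cell-type label, marker
intensities and cell area. Bulk expression arrives as a genes x spots TPM
matrix (:class:`ExpressionMatrix`), gene signatures as plain-text symbol
lists (:class:`GeneSignature`).

Coordinates are abstract planar units (pixels); every statistic downstream is
either a ratio or unit-free, so no micron conversion is attempted. Platform
exports differ in column naming, hence ``read_cell_table`` takes a column
mapping onto the canonical names below.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical column names, in canonical order
CELL_COLUMNS = (
    "cell_id",
    "spot_id",
    "patient_id",
    "group",
    "timepoint",
    "x",
    "y",
    "cell_type",
    "size",
)

GROUPS = ("responder", "nonresponder")
TIMEPOINTS = ("pre", "post")


class SchemaError(ValueError):
    """A required column is missing or mis-mapped."""


class ValidationError(ValueError):
    """Rows or values violate a CellTable/ExpressionMatrix invariant."""


class TransformStateError(ValueError):
    """An expression transform was requested in the wrong state."""


@dataclass
class CellTable:
    """Validated per-cell table plus the names of its marker columns.

    ``df`` holds the canonical columns (:data:`CELL_COLUMNS`) followed by one
    column per marker. ``cell_types`` is the declared vocabulary; rows must
    draw their labels from it.
    """

    df: pd.DataFrame
    markers: tuple[str, ...] = ()
    cell_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        if not self.cell_types:
            self.cell_types = tuple(sorted(self.df["cell_type"].unique()))
        else:
            self.cell_types = tuple(self.cell_types)
        self.validate()

    # -- container sugar ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def spots(self) -> list[str]:
        return list(pd.unique(self.df["spot_id"]))

    def spot(self, spot_id: str) -> pd.DataFrame:
        return self.df[self.df["spot_id"] == spot_id]

    def spot_metadata(self) -> pd.DataFrame:
        """One row per spot: patient_id, group, timepoint."""
        meta = self.df[["spot_id", "patient_id", "group", "timepoint"]]
        return meta.drop_duplicates("spot_id").set_index("spot_id")

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in CELL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        for m in self.markers:
            if m not in df.columns:
                raise SchemaError(f"missing marker column: {m!r}")

        problems: list[str] = []

        dup = df["cell_id"][df["cell_id"].duplicated()]
        if len(dup):
            problems.append(f"duplicate cell_id values: {sorted(set(dup))[:5]}")

        xy = df[["x", "y"]].to_numpy(dtype=float)
        bad = ~np.isfinite(xy).all(axis=1)
        if bad.any():
            rows = list(np.flatnonzero(bad)[:10])
            problems.append(f"non-finite coordinates in rows {rows}")

        unknown = set(df["cell_type"]) - set(self.cell_types)
        if unknown:
            problems.append(f"cell_type labels outside vocabulary: {sorted(unknown)}")

        if (df["size"].to_numpy(dtype=float) <= 0).any():
            rows = list(np.flatnonzero(df["size"].to_numpy(dtype=float) <= 0)[:10])
            problems.append(f"non-positive cell size in rows {rows}")

        for m in self.markers:
            vals = df[m].to_numpy(dtype=float)
            if (vals < 0).any() or not np.isfinite(vals).all():
                rows = list(np.flatnonzero((vals < 0) | ~np.isfinite(vals))[:10])
                problems.append(f"invalid intensities for marker {m!r} in rows {rows}")

        # each spot belongs to exactly one (patient, group, timepoint)
        meta = df[["spot_id", "patient_id", "group", "timepoint"]].drop_duplicates()
        clash = meta["spot_id"][meta["spot_id"].duplicated()]
        if len(clash):
            problems.append(
                f"spot_id mapped to multiple (patient, group, timepoint): {sorted(set(clash))}"
            )

        if problems:
            raise ValidationError("; ".join(problems))

    def subset(self, mask: pd.Series | np.ndarray) -> "CellTable":
        return CellTable(
            self.df[mask].reset_index(drop=True),
            markers=self.markers,
            cell_types=self.cell_types,
        )


@dataclass
class ExpressionMatrix:
    """Genes x spots expression values with an explicit transform state."""

    values: pd.DataFrame  # index: gene symbols, columns: spot_ids
    transform_state: str = "raw_TPM"  # or "log2_TPM"

    def __post_init__(self) -> None:
        if self.transform_state not in ("raw_TPM", "log2_TPM"):
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        idx = self.values.index
        if idx.duplicated().any():
            dup = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate gene symbol(s): {dup}")
        if self.transform_state == "raw_TPM":
            arr = self.values.to_numpy(dtype=float)
            if (arr < 0).any():
                raise ValidationError("negative values in raw_TPM matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def spots(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSignature:
    """Named list of gene symbols used for PCA signature scoring."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate symbols")


# ---------------------------------------------------------------------------
# readers / writers


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    markers: Sequence[str] | None = None,
    cell_types: Sequence[str] | None = None,
) -> CellTable:
    """Read a TSV/CSV cell table.

    Parameters
    ----------
    schema
        Mapping from file column names to canonical names
        (e.g. ``{"X_position": "x"}``). Unmapped canonical columns must
        already be present under their canonical name.
    markers
        Marker column names (post-mapping). Default: every numeric column
        that is not canonical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) after mapping: {missing}")
    if markers is None:
        markers = [
            c
            for c in df.columns
            if c not in CELL_COLUMNS and pd.api.types.is_numeric_dtype(df[c])
        ]
    cols = list(CELL_COLUMNS) + list(markers)
    return CellTable(
        df[cols].reset_index(drop=True),
        markers=tuple(markers),
        cell_types=tuple(cell_types) if cell_types else (),
    )


def write_cell_table(table: CellTable, path: str | Path) -> None:
    path = Path(path)
    table.df.to_csv(path, sep=_sep_for(path), index=False)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene symbols, remaining
    columns spot ids) in raw TPM state."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, transform_state="raw_TPM")


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(Path(path), sep="\t", index_label="gene")


def read_gene_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """One gene symbol per line; name defaults to the file stem."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return GeneSignature(name or path.stem, tuple(genes))


# ---------------------------------------------------------------------------
# normalisation


def tpm_log2_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each spot to one million transcripts, then log2(x + 1).

    The +1 pseudo-count handles zero counts; applying the transform twice is
    refused via ``transform_state``.
    """
    if expr.transform_state != "raw_TPM":
        raise TransformStateError("matrix is already log2-transformed")
    vals = expr.values.to_numpy(dtype=float)
    sums = vals.sum(axis=0)
    scale = np.divide(1e6, sums, out=np.ones_like(sums), where=sums > 0)
    out = np.log2(vals * scale + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        transform_state="log2_TPM",
    )
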