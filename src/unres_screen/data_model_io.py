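"""Core data types and readers/writers for all tabular inputs and result reports.

All readers accept CSV or TSV with a header row; the delimiter is sniffed
unless forced with ``sep=``.  Identifiers are matched case-sensitively after
whitespace trimming.  Drug-response statistics operate on natural-log IC50
values throughout; nothing in the package ever exponentiates them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "DrugResponseTable",
    "CFEMatrix",
    "CellAnnotation",
    "EssentialityMatrix",
    "GeneList",
    "read_drug_response",
    "read_cfe_matrix",
    "read_annotations",
    "read_essentiality",
    "read_gene_list",
    "write_table",
    "read_table",
    "write_manifest",
]

#: float formatting used for every result table (12 significant digits)
FLOAT_FORMAT = "%.12g"

ALTERATION_CLASSES = frozenset({"mutation", "cna", "methylation"})


def _read_raw(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited text file with header, sniffing the delimiter."""
    return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugResponseTable:
    """Per-(cell line, drug) natural-log IC50 measurements.

    ``df`` has columns ``cell_line_id``, ``drug_id``, ``ln_ic50`` (ln µM),
    ``extrapolated`` (bool) and, when available, ``max_screened_conc`` (µM).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        validate_drug_response_frame(self.df)

    @property
    def cell_lines(self) -> pd.Index:
        return pd.Index(self.df["cell_line_id"].unique())

    @property
    def drugs(self) -> pd.Index:
        return pd.Index(self.df["drug_id"].unique())

    def subset_cells(self, cells: Sequence[str]) -> "DrugResponseTable":
        keep = self.df["cell_line_id"].isin(set(cells))
        return DrugResponseTable(self.df.loc[keep].reset_index(drop=True))


def validate_drug_response_frame(df: pd.DataFrame) -> None:
    for col in ("cell_line_id", "drug_id", "ln_ic50", "extrapolated"):
        if col not in df.columns:
            raise SchemaError(f"drug-response table is missing column {col!r}")
    if not np.isfinite(df["ln_ic50"].to_numpy(dtype=float)).all():
        bad = df.loc[~np.isfinite(df["ln_ic50"].to_numpy(dtype=float))]
        raise IntegrityError(
            f"non-finite ln_ic50 values for {bad['cell_line_id'].tolist()[:5]}"
        )
    dup = df.duplicated(subset=["cell_line_id", "drug_id"])
    if dup.any():
        offenders = (
            df.loc[dup, ["cell_line_id", "drug_id"]]
            .apply(tuple, axis=1)
            .unique()
            .tolist()
        )
        raise IntegrityError(f"duplicate (cell_line, drug) pairs: {offenders[:10]}")


@dataclass(frozen=True)
class CFEMatrix:
    """Binary cancer-functional-event matrix plus per-CFE metadata.

    ``matrix``: DataFrame indexed by cell_line_id with one {0,1} column per
    cfe_id.  ``metadata``: DataFrame indexed by cfe_id with columns
    ``alteration_class`` (mutation | cna | methylation), ``genes`` (list of
    symbols) and ``has_driver_gene`` (bool).
    """

    matrix: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise IntegrityError(
                "non-binary CFE value "
                f"{vals[r, c]!r} at (cell={self.matrix.index[r]!r}, "
                f"cfe={self.matrix.columns[c]!r})"
            )
        missing = self.matrix.columns.difference(self.metadata.index)
        if len(missing):
            raise SchemaError(f"CFEs without metadata: {sorted(missing)[:10]}")
        for col in ("alteration_class", "genes", "has_driver_gene"):
            if col not in self.metadata.columns:
                raise SchemaError(f"CFE metadata is missing column {col!r}")
        unknown = set(self.metadata["alteration_class"]) - ALTERATION_CLASSES
        if unknown:
            raise IntegrityError(f"unknown alteration classes: {sorted(unknown)}")
        for cfe_id, row in self.metadata.iterrows():
            if row["has_driver_gene"] and not row["genes"]:
                raise IntegrityError(
                    f"CFE {cfe_id!r} flagged has_driver_gene but lists no genes"
                )

    @property
    def cell_lines(self) -> pd.Index:
        return self.matrix.index

    @property
    def cfe_ids(self) -> pd.Index:
        return self.matrix.columns

    def carriers(self, cfe_id: str) -> list[str]:
        """Cell lines with the CFE present."""
        col = self.matrix[cfe_id]
        return col.index[col == 1].tolist()

    def genes_of(self, cfe_id: str) -> list[str]:
        return list(self.metadata.at[cfe_id, "genes"])


@dataclass(frozen=True)
class CellAnnotation:
    """Per-cell-line annotations: tissue, MSI status, medium, growth property."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("cell_line_id", "tissue", "msi_status", "medium", "growth_property"):
            if col not in self.df.columns:
                raise SchemaError(f"annotation table is missing column {col!r}")
        dup = self.df["cell_line_id"].duplicated()
        if dup.any():
            raise IntegrityError(
                f"duplicated cell_line_id: {self.df.loc[dup, 'cell_line_id'].tolist()}"
            )
        tissues = self.df["tissue"].astype(str).str.strip()
        if (tissues == "").any() or self.df["tissue"].isna().any():
            bad = self.df.loc[(tissues == "") | self.df["tissue"].isna(), "cell_line_id"]
            raise IntegrityError(f"empty tissue for cell lines: {bad.tolist()}")

    def tissue_of(self) -> pd.Series:
        return self.df.set_index("cell_line_id")["tissue"]

    def cells_in_tissue(self, tissue: str) -> list[str]:
        return self.df.loc[self.df["tissue"] == tissue, "cell_line_id"].tolist()

    def covariates(self) -> pd.DataFrame:
        return self.df.set_index("cell_line_id")[
            ["msi_status", "medium", "growth_property"]
        ]


@dataclass(frozen=True)
class EssentialityMatrix:
    """CRISPR gene-effect scores, genes in rows, cell lines in columns.

    Lower (more negative) values mean the gene is more essential.  Missing
    measurements are NaN, never zero-filled.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate gene symbols: {dups[:10]}")
        vals = self.df.to_numpy(dtype=float)
        if np.isinf(vals).any():
            r, c = np.argwhere(np.isinf(vals))[0]
            raise IntegrityError(
                f"infinite gene effect at (gene={self.df.index[r]!r}, "
                f"cell={self.df.columns[c]!r})"
            )

    @property
    def genes(self) -> pd.Index:
        return self.df.index

    @property
    def cell_lines(self) -> pd.Index:
        return self.df.columns

    def profile(self, cell_line: str) -> pd.Series:
        """Gene-effect vector for one cell line (NaN for missing genes)."""
        return self.df[cell_line]


class GeneList(frozenset):
    """Case-normalized (upper-case) set of gene symbols."""

    def __new__(cls, symbols):
        cleaned = {str(s).strip().upper() for s in symbols if str(s).strip()}
        if not cleaned:
            raise IntegrityError("gene list is empty")
        return super().__new__(cls, cleaned)

    def __contains__(self, item) -> bool:  # case-insensitive membership
        return super().__contains__(str(item).strip().upper())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_DEFAULT_RESPONSE_DIALECT = {
    "cell_line_id": "cell_line_id",
    "drug_id": "drug_id",
    "ln_ic50": "ln_ic50",
    "max_screened_conc": "max_screened_conc",
    "extrapolated": "extrapolated",
}


def read_drug_response(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> DrugResponseTable:
    """Read a drug-response table.

    ``dialect`` maps canonical column names (``cell_line_id``, ``drug_id``,
    ``ln_ic50``, and optionally ``max_screened_conc`` or ``extrapolated``)
    onto the column names present in the file.  The ``extrapolated`` flag is
    computed as ``ln_ic50 > ln(max_screened_conc)`` (strict) when absent; if
    neither the flag nor a concentration column exists, every row is treated
    as non-extrapolated and a warning is logged.
    """
    names = dict(_DEFAULT_RESPONSE_DIALECT)
    if dialect:
        names.update(dialect)
    raw = _read_raw(path, sep=sep)
    for canonical in ("cell_line_id", "drug_id", "ln_ic50"):
        if names[canonical] not in raw.columns:
            raise SchemaError(
                f"drug-response file {path} is missing required column "
                f"{names[canonical]!r} (for {canonical})"
            )
    df = pd.DataFrame(
        {
            "cell_line_id": raw[names["cell_line_id"]].astype(str).str.strip(),
            "drug_id": raw[names["drug_id"]].astype(str).str.strip(),
            "ln_ic50": pd.to_numeric(raw[names["ln_ic50"]]),
        }
    )
    if names["max_screened_conc"] in raw.columns:
        conc = pd.to_numeric(raw[names["max_screened_conc"]])
        if (conc <= 0).any():
            raise IntegrityError("max_screened_conc must be positive")
        df["max_screened_conc"] = conc
    if names["extrapolated"] in raw.columns:
        df["extrapolated"] = raw[names["extrapolated"]].astype(bool)
    elif "max_screened_conc" in df.columns:
        df["extrapolated"] = df["ln_ic50"] > np.log(df["max_screened_conc"])
    else:
        logger.warning(
            "%s: no extrapolated flag or max_screened_conc column; "
            "treating all rows as non-extrapolated",
            path,
        )
        df["extrapolated"] = False
    return DrugResponseTable(df)


def read_cfe_matrix(
    matrix_path: str | Path,
    metadata_path: str | Path,
    sep: str | None = None,
) -> CFEMatrix:
    """Read the binary CFE matrix (cells in rows) and its metadata table.

    The metadata file needs columns ``cfe_id``, ``alteration_class``,
    ``genes`` (comma- or semicolon-separated symbols, may be empty) and
    ``has_driver_gene``.
    """
    raw = _read_raw(matrix_path, sep=sep)
    matrix = raw.set_index(raw.columns[0])
    matrix.index = matrix.index.astype(str).str.strip()
    matrix.index.name = "cell_line_id"
    vals = matrix.to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise IntegrityError(
            f"non-binary value {vals[r, c]!r} in {matrix_path} at "
            f"(cell={matrix.index[r]!r}, cfe={matrix.columns[c]!r})"
        )
    matrix = matrix.astype(np.int8)

    meta_raw = _read_raw(metadata_path, sep=sep)
    for col in ("cfe_id", "alteration_class", "genes", "has_driver_gene"):
        if col not in meta_raw.columns:
            raise SchemaError(f"CFE metadata {metadata_path} is missing column {col!r}")
    meta = meta_raw.set_index(meta_raw["cfe_id"].astype(str).str.strip())
    genes = meta["genes"].fillna("").astype(str)
    meta = pd.DataFrame(
        {
            "alteration_class": meta["alteration_class"].astype(str).str.strip(),
            "genes": [
                [g.strip() for g in gs.replace(";", ",").split(",") if g.strip()]
                for gs in genes
            ],
            "has_driver_gene": meta["has_driver_gene"]
            .map(_parse_bool)
            .astype(bool),
        },
        index=meta.index,
    )
    return CFEMatrix(matrix=matrix, metadata=meta)


def _parse_bool(x) -> bool:
    if isinstance(x, str):
        s = x.strip().lower()
        if s in {"true", "1", "yes"}:
            return True
        if s in {"false", "0", "no"}:
            return False
        raise IntegrityError(f"cannot parse boolean value {x!r}")
    return bool(x)


def read_annotations(path: str | Path, sep: str | None = None) -> CellAnnotation:
    raw = _read_raw(path, sep=sep)
    if "cell_line_id" not in raw.columns:
        raise SchemaError(f"annotation file {path} is missing column 'cell_line_id'")
    df = raw.copy()
    df["cell_line_id"] = df["cell_line_id"].astype(str).str.strip()
    return CellAnnotation(df)


def read_essentiality(
    path: str | Path,
    orientation: str = "genes_in_rows",
    sep: str | None = None,
) -> EssentialityMatrix:
    """Read a gene-effect matrix, normalizing to gene x cell orientation.

    ``orientation`` is ``"genes_in_rows"`` or ``"cells_in_rows"`` and refers
    to the layout of the *file*; DepMap ``gene_effect.csv`` exports use
    cells in rows.
    """
    if orientation not in {"genes_in_rows", "cells_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_raw(path, sep=sep)
    body = raw.set_index(raw.columns[0])
    body.index = body.index.astype(str).str.strip()
    try:
        body = body.astype(float)
    except (TypeError, ValueError):
        for col in body.columns:
            coerced = pd.to_numeric(body[col], errors="coerce")
            bad = coerced.isna() & body[col].notna()
            if bad.any():
                row = body.index[bad][0]
                raise SchemaError(
                    f"non-numeric gene effect {body.at[row, col]!r} at "
                    f"(row={row!r}, column={col!r}) in {path}"
                ) from None
        raise
    if orientation == "cells_in_rows":
        body = body.T
    body.index.name = "gene_symbol"
    body.columns = body.columns.astype(str).str.strip()
    return EssentialityMatrix(body)


def read_gene_list(path: str | Path) -> GeneList:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    return GeneList(symbols)


# ---------------------------------------------------------------------------
# Result-report writers
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as TSV with 12-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(manifest: dict, path: str | Path) -> Path:
    """Write the JSON run-manifest (inputs, parameters, seed, versions)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, Path):
            return str(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_default))
    return path
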