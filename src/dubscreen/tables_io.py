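"""Readers and writers for MaxQuant-dialect protein-group and GlyGly-site tables.

The pipeline consumes the tab-separated output of a MaxQuant/MaxLFQ search:
a ``proteinGroups``-style table (one row per protein group, one
``LFQ intensity <label>`` column per sample, ``+``-encoded decoy/contaminant
flags) and a GlyGly(K)-sites-style table (diGly remnant sites with a
localization probability).  Parsed rows are held in pandas DataFrames with
canonical column names; LFQ value 0 encodes "not quantified".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import ExperimentDesign

__all__ = [
    "SchemaError",
    "TableParseError",
    "ProteinGroupTable",
    "GlyGlySiteRow",
    "read_protein_groups",
    "write_protein_groups",
    "read_glygly_sites",
    "write_glygly_sites",
    "write_results_csv",
    "DEFAULT_PG_COLUMNS",
    "DEFAULT_SITE_COLUMNS",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class TableParseError(ValueError):
    """A cell could not be parsed; the message carries the 1-based line number."""


# MaxQuant column names; overridable via a column-mapping dict (config file).
DEFAULT_PG_COLUMNS: dict[str, str] = {
    "protein_ids": "Protein IDs",
    "gene_names": "Gene names",
    "description": "Protein names",
    "unique_peptides": "Unique peptides",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
    "lfq_prefix": "LFQ intensity ",
}

DEFAULT_SITE_COLUMNS: dict[str, str] = {
    "protein_id": "Protein",
    "gene_names": "Gene names",
    "position": "Position",
    "localization_probability": "Localization prob",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "intensity_prefix": "Intensity ",
}


def _first_gene(raw: Any) -> str:
    """First symbol of a semicolon-separated gene-name list; '' if absent."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ""
    return str(raw).split(";")[0].strip()


def _flag(raw: Any) -> bool:
    # MaxQuant convention: only the literal "+" marks a row.
    return str(raw).strip() == "+" if raw is not None else False


def _numeric(raw: Any, *, line: int, column: str) -> float:
    """Parse an LFQ/intensity cell; blank/NaN means 0 (not quantified)."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return 0.0
    text = str(raw).strip()
    if text == "" or text.lower() == "nan":
        return 0.0
    try:
        value = float(text)
    except ValueError:
        raise TableParseError(
            f"non-numeric value {text!r} in column {column!r} at line {line}"
        ) from None
    if not np.isfinite(value) or value < 0:
        raise TableParseError(
            f"intensity must be finite and >= 0, got {text!r} in column "
            f"{column!r} at line {line}"
        )
    return value


@dataclass
class ProteinGroupTable:
    """Parsed protein-group table.

    ``df`` uses canonical columns: ``protein_ids`` (semicolon-joined
    accessions), ``gene_name`` (first symbol), ``description``,
    ``unique_peptides`` (int), boolean ``reverse``/``contaminant``/
    ``only_by_site`` flags, and one float LFQ column per sample label.
    """

    df: pd.DataFrame
    sample_labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lfq(self) -> pd.DataFrame:
        """Proteins x samples LFQ sub-matrix (0 = not quantified)."""
        return self.df[self.sample_labels]

    def copy(self) -> "ProteinGroupTable":
        return ProteinGroupTable(self.df.copy(), list(self.sample_labels))


@dataclass(frozen=True)
class GlyGlySiteRow:
    """One diGly-remnant (GlyGly) site on a modified lysine (1-based position)."""

    protein_id: str
    gene_name: str
    position: int
    localization_probability: float
    intensity: dict[str, float]
    reverse_flag: bool = False
    contaminant_flag: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValueError(
                "localization probability must be in [0, 1], got "
                f"{self.localization_probability}"
            )


def _read_tsv(path: str | Path) -> pd.DataFrame:
    # Everything read as text so that cell-level parse errors can cite lines.
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require(columns: Iterable[str], required: Iterable[str]) -> None:
    have = set(columns)
    for col in required:
        if col not in have:
            raise SchemaError(f"required column {col!r} missing from table")


def read_protein_groups(
    path: str | Path,
    design: ExperimentDesign,
    columns: Mapping[str, str] | None = None,
) -> ProteinGroupTable:
    """Read a MaxQuant-dialect proteinGroups table for the given design.

    Flag columns parse the literal ``"+"`` as true and anything else as
    false; blank or missing numeric cells parse as 0 ("not quantified").

    Raises
    ------
    SchemaError
        If a required column (including any ``LFQ intensity <label>`` named
        by the design) is absent.
    TableParseError
        If an intensity cell is non-numeric, with the offending line number.
    """
    cols = dict(DEFAULT_PG_COLUMNS)
    if columns:
        cols.update(columns)
    raw = _read_tsv(path)
    lfq_cols = {lab: f"{cols['lfq_prefix']}{lab}" for lab in design.sample_labels}
    _require(
        raw.columns,
        [
            cols["protein_ids"],
            cols["gene_names"],
            cols["unique_peptides"],
            cols["reverse"],
            cols["contaminant"],
            cols["only_by_site"],
            *lfq_cols.values(),
        ],
    )
    has_desc = cols["description"] in raw.columns

    records: list[dict[str, Any]] = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):  # line 1 = header
        row_map = dict(zip(raw.columns, row))
        rec: dict[str, Any] = {
            "protein_ids": str(row_map[cols["protein_ids"]]).strip(),
            "gene_name": _first_gene(row_map[cols["gene_names"]]),
            "description": str(row_map[cols["description"]]).strip() if has_desc else "",
            "unique_peptides": int(
                _numeric(row_map[cols["unique_peptides"]], line=i, column=cols["unique_peptides"])
            ),
            "reverse": _flag(row_map[cols["reverse"]]),
            "contaminant": _flag(row_map[cols["contaminant"]]),
            "only_by_site": _flag(row_map[cols["only_by_site"]]),
        }
        for lab, col in lfq_cols.items():
            rec[lab] = _numeric(row_map[col], line=i, column=col)
        records.append(rec)

    base_cols = [
        "protein_ids",
        "gene_name",
        "description",
        "unique_peptides",
        "reverse",
        "contaminant",
        "only_by_site",
        *design.sample_labels,
    ]
    df = pd.DataFrame.from_records(records, columns=base_cols) if records else pd.DataFrame(
        columns=base_cols
    )
    return ProteinGroupTable(df, list(design.sample_labels))


def write_protein_groups(
    table: ProteinGroupTable,
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> None:
    """Write a :class:`ProteinGroupTable` back to the MaxQuant dialect (TSV)."""
    cols = dict(DEFAULT_PG_COLUMNS)
    if columns:
        cols.update(columns)
    out = pd.DataFrame(
        {
            cols["protein_ids"]: table.df["protein_ids"],
            cols["gene_names"]: table.df["gene_name"],
            cols["description"]: table.df["description"],
            cols["unique_peptides"]: table.df["unique_peptides"],
        }
    )
    for lab in table.sample_labels:
        out[f"{cols['lfq_prefix']}{lab}"] = table.df[lab]
    for key in ("reverse", "contaminant", "only_by_site"):
        out[cols[key]] = np.where(table.df[key], "+", "")
    out.to_csv(path, sep="\t", index=False)


def read_glygly_sites(
    path: str | Path,
    design: ExperimentDesign,
    columns: Mapping[str, str] | None = None,
) -> list[GlyGlySiteRow]:
    """Read a MaxQuant-dialect GlyGly(K) site table.

    Same parsing conventions as :func:`read_protein_groups`; the site
    localization-probability column is additionally required and must lie in
    [0, 1].
    """
    cols = dict(DEFAULT_SITE_COLUMNS)
    if columns:
        cols.update(columns)
    raw = _read_tsv(path)
    int_cols = {lab: f"{cols['intensity_prefix']}{lab}" for lab in design.sample_labels}
    _require(
        raw.columns,
        [
            cols["protein_id"],
            cols["gene_names"],
            cols["position"],
            cols["localization_probability"],
            cols["reverse"],
            cols["contaminant"],
            *int_cols.values(),
        ],
    )

    rows: list[GlyGlySiteRow] = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):
        row_map = dict(zip(raw.columns, row))
        prob = _numeric(
            row_map[cols["localization_probability"]],
            line=i,
            column=cols["localization_probability"],
        )
        if prob > 1.0:
            raise TableParseError(
                f"localization probability {prob} outside [0, 1] at line {i}"
            )
        rows.append(
            GlyGlySiteRow(
                protein_id=str(row_map[cols["protein_id"]]).strip(),
                gene_name=_first_gene(row_map[cols["gene_names"]]),
                position=int(_numeric(row_map[cols["position"]], line=i, column=cols["position"])),
                localization_probability=prob,
                intensity={
                    lab: _numeric(row_map[col], line=i, column=col)
                    for lab, col in int_cols.items()
                },
                reverse_flag=_flag(row_map[cols["reverse"]]),
                contaminant_flag=_flag(row_map[cols["contaminant"]]),
            )
        )
    return rows


def write_glygly_sites(
    rows: Sequence[GlyGlySiteRow],
    path: str | Path,
    sample_labels: Sequence[str],
    columns: Mapping[str, str] | None = None,
) -> None:
    """Write GlyGly site rows in the MaxQuant dialect (TSV)."""
    cols = dict(DEFAULT_SITE_COLUMNS)
    if columns:
        cols.update(columns)
    out = pd.DataFrame(
        {
            cols["protein_id"]: [r.protein_id for r in rows],
            cols["gene_names"]: [r.gene_name for r in rows],
            cols["position"]: [r.position for r in rows],
            cols["localization_probability"]: [r.localization_probability for r in rows],
        }
    )
    for lab in sample_labels:
        out[f"{cols['intensity_prefix']}{lab}"] = [r.intensity.get(lab, 0.0) for r in rows]
    out[cols["reverse"]] = ["+" if r.reverse_flag else "" for r in rows]
    out[cols["contaminant"]] = ["+" if r.contaminant_flag else "" for r in rows]
    out.to_csv(path, sep="\t", index=False)


def write_results_csv(results: Any, path: str | Path) -> None:
    """Write any tabular result as RFC-4180 CSV with a header row.

    Accepts a DataFrame, a sequence of dataclass instances, a sequence of
    mappings, or a sequence of (named)tuples.  Floats are written at full
    round-trip precision; row order is the input order.
    """
    df = _as_dataframe(results)
    df.to_csv(path, index=False, lineterminator="\r\n")


def _as_dataframe(results: Any) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    results = list(results)
    if not results:
        return pd.DataFrame()
    first = results[0]
    if dataclasses.is_dataclass(first):
        return pd.DataFrame([dataclasses.asdict(r) for r in results])
    if isinstance(first, Mapping):
        return pd.DataFrame(list(results))
    if hasattr(first, "_fields"):  # namedtuple
        return pd.DataFrame(results, columns=list(first._fields))
    return pd.DataFrame(results)
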