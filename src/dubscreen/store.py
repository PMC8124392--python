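"""A queryable, file-backed store of DUB-substrate evidence.

Mirrors the behaviour of an interactive DUB-substrate database: differential
results are ingested *unfiltered*, and user-adjustable thresholds (fold
change, p-value, minimum unique peptides, direction) are applied only at
query time, so the same evidence can be re-screened under different
criteria.  Two logical tables — ``experiment`` and ``evidence`` — live in a
single SQLite file (or in memory).  Queries run in both directions: all
substrates of one DUB, or all DUBs affecting one protein.

A curated example dataset ships with the package: the published putative
substrates of a five-DUB silencing screen (USP1, USP7, USP9X, USP11,
USP42), transcribed with their log2 fold changes.  Those records carry
``provenance="published_table"`` and no p-values or peptide counts; they
pass the corresponding query filters vacuously, with a notice.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .differential import DifferentialResult, Thresholds, volcano_dataset

__all__ = ["SubstrateRecord", "SubstrateStore", "load_published_screen", "records_from_results"]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS experiment (
    experiment_id TEXT PRIMARY KEY,
    dub_name      TEXT NOT NULL,
    meta          TEXT NOT NULL DEFAULT '{}'
);
CREATE TABLE IF NOT EXISTS evidence (
    experiment_id     TEXT NOT NULL REFERENCES experiment(experiment_id),
    dub_name          TEXT NOT NULL,
    gene_name         TEXT NOT NULL,
    description       TEXT NOT NULL DEFAULT '',
    log2_fc           REAL NOT NULL,
    p_value           REAL,
    unique_peptides   INTEGER,
    protein_id        TEXT,
    all_peptides      INTEGER,
    sequence_coverage REAL,
    glygly_positions  TEXT,
    provenance        TEXT NOT NULL DEFAULT 'pipeline',
    UNIQUE (experiment_id, dub_name, gene_name)
);
CREATE TABLE IF NOT EXISTS settings (
    key   TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
"""


@dataclass(frozen=True)
class SubstrateRecord:
    """One (DUB, protein) evidence row of the store.

    ``p_value`` and ``unique_peptides`` may be ``None`` for records ingested
    from a published summary table; such records pass the corresponding
    query filters vacuously.
    """

    dub_name: str
    gene_name: str
    description: str = ""
    log2_fc: float = 0.0
    p_value: float | None = None
    unique_peptides: int | None = None
    protein_id: str | None = None
    all_peptides: int | None = None
    sequence_coverage: float | None = None
    glygly_positions: tuple[int, ...] | None = None
    provenance: str = "pipeline"


def load_published_screen() -> list[SubstrateRecord]:
    """The bundled five-DUB screen (56 putative substrate records)."""
    with resources.files("dubscreen.data").joinpath("usp_screen_substrates.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        SubstrateRecord(
            dub_name=row.dub,
            gene_name=row.gene,
            description=row.description,
            log2_fc=float(row.log2_fc),
            provenance="published_table",
        )
        for row in df.itertuples(index=False)
    ]


def records_from_results(
    results: Sequence[DifferentialResult],
    dub_name: str,
    glygly_sites: Mapping[str, Sequence[int]] | None = None,
) -> list[SubstrateRecord]:
    """Convert pipeline differential results into store records (unfiltered)."""
    sites = glygly_sites or {}
    records = []
    for r in results:
        positions = sites.get(r.row_key) or sites.get(r.gene_name)
        records.append(
            SubstrateRecord(
                dub_name=dub_name,
                gene_name=r.gene_name,
                description=r.description,
                log2_fc=r.log2_fc,
                p_value=r.p_value,
                unique_peptides=r.unique_peptides,
                protein_id=r.row_key,
                glygly_positions=tuple(positions) if positions else None,
            )
        )
    return records


class SubstrateStore:
    """SQLite-backed store with threshold-at-query-time semantics.

    Parameters
    ----------
    path : str or Path, default ":memory:"
        Database file; ``":memory:"`` gives an ephemeral store.

    Notes
    -----
    Thresholds set with :meth:`set_thresholds` persist (in the ``settings``
    table for file-backed stores) and apply to every subsequent query until
    changed or :meth:`reset_thresholds` is called.  Gene and DUB matching is
    case-insensitive exact match.  After each query, :attr:`last_notices`
    holds human-readable notes (e.g. filters passed vacuously by records
    without p-values).
    """

    def __init__(self, path: str | Path = ":memory:") -> None:
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self.last_notices: list[str] = []

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "SubstrateStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- ingest ------------------------------------------------------------
    def ingest(
        self,
        records: Iterable[SubstrateRecord],
        experiment_id: str,
        experiment_meta: Mapping[str, str] | None = None,
    ) -> int:
        """Store ALL records of one experiment, unfiltered.

        Raises on a duplicate experiment id or a duplicate (DUB, gene) pair
        within the experiment, naming the offender.
        """
        records = list(records)
        cur = self._conn.cursor()
        if cur.execute(
            "SELECT 1 FROM experiment WHERE experiment_id = ?", (experiment_id,)
        ).fetchone():
            raise ValueError(f"experiment {experiment_id!r} already ingested")
        seen: set[tuple[str, str]] = set()
        for r in records:
            key = (r.dub_name.upper(), r.gene_name.upper())
            if key in seen:
                raise ValueError(
                    f"duplicate (DUB, gene) pair {r.dub_name}/{r.gene_name} in "
                    f"experiment {experiment_id!r}"
                )
            seen.add(key)
        dub = records[0].dub_name if records else ""
        cur.execute(
            "INSERT INTO experiment (experiment_id, dub_name, meta) VALUES (?, ?, ?)",
            (experiment_id, dub, json.dumps(dict(experiment_meta or {}))),
        )
        cur.executemany(
            """INSERT INTO evidence (experiment_id, dub_name, gene_name, description,
                   log2_fc, p_value, unique_peptides, protein_id, all_peptides,
                   sequence_coverage, glygly_positions, provenance)
               VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)""",
            [
                (
                    experiment_id,
                    r.dub_name,
                    r.gene_name,
                    r.description,
                    r.log2_fc,
                    r.p_value,
                    r.unique_peptides,
                    r.protein_id,
                    r.all_peptides,
                    r.sequence_coverage,
                    json.dumps(list(r.glygly_positions)) if r.glygly_positions else None,
                    r.provenance,
                )
                for r in records
            ],
        )
        self._conn.commit()
        return len(records)

    def __len__(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM evidence").fetchone()[0]

    # -- thresholds ----------------------------------------------------------
    def set_thresholds(self, thresholds: Thresholds) -> None:
        """Persist thresholds for all subsequent queries in this store."""
        payload = json.dumps(
            {
                "min_abs_log2_fc": thresholds.min_abs_log2_fc,
                "max_p": thresholds.max_p,
                "min_unique_peptides": thresholds.min_unique_peptides,
                "direction": thresholds.direction,
            }
        )
        self._conn.execute(
            "INSERT INTO settings (key, value) VALUES ('thresholds', ?) "
            "ON CONFLICT(key) DO UPDATE SET value = excluded.value",
            (payload,),
        )
        self._conn.commit()

    def reset_thresholds(self) -> None:
        self._conn.execute("DELETE FROM settings WHERE key = 'thresholds'")
        self._conn.commit()

    @property
    def thresholds(self) -> Thresholds:
        row = self._conn.execute(
            "SELECT value FROM settings WHERE key = 'thresholds'"
        ).fetchone()
        return Thresholds(**json.loads(row[0])) if row else Thresholds()

    # -- queries -------------------------------------------------------------
    def _fetch(self, where: str, args: tuple) -> list[SubstrateRecord]:
        rows = self._conn.execute(
            f"""SELECT dub_name, gene_name, description, log2_fc, p_value,
                       unique_peptides, protein_id, all_peptides,
                       sequence_coverage, glygly_positions, provenance
                FROM evidence WHERE {where}""",
            args,
        ).fetchall()
        return [
            SubstrateRecord(
                dub_name=r[0],
                gene_name=r[1],
                description=r[2],
                log2_fc=r[3],
                p_value=r[4],
                unique_peptides=r[5],
                protein_id=r[6],
                all_peptides=r[7],
                sequence_coverage=r[8],
                glygly_positions=tuple(json.loads(r[9])) if r[9] else None,
                provenance=r[10],
            )
            for r in rows
        ]

    def _passes(self, r: SubstrateRecord, t: Thresholds) -> bool:
        if t.direction == "up":
            if r.log2_fc < t.min_abs_log2_fc:
                return False
        elif t.direction == "down":
            if r.log2_fc > -t.min_abs_log2_fc:
                return False
        elif abs(r.log2_fc) < t.min_abs_log2_fc:
            return False
        if r.p_value is None:
            self._vacuous.add("p_value")
        elif not r.p_value < t.max_p:
            return False
        if r.unique_peptides is None:
            self._vacuous.add("unique_peptides")
        elif r.unique_peptides < t.min_unique_peptides:
            return False
        return True

    def _apply(self, records: list[SubstrateRecord], thresholds: Thresholds | None) -> list[SubstrateRecord]:
        t = thresholds if thresholds is not None else self.thresholds
        self._vacuous: set[str] = set()
        kept = [r for r in records if self._passes(r, t)]
        self.last_notices = [
            f"records without {fieldname} pass that filter vacuously"
            for fieldname in sorted(self._vacuous)
        ]
        return sorted(kept, key=lambda r: (-r.log2_fc, r.gene_name))

    def query_by_dub(
        self, dub_name: str, thresholds: Thresholds | None = None
    ) -> list[SubstrateRecord]:
        """Substrates of one DUB passing the (session or given) thresholds,
        sorted by descending log2 fold change."""
        records = self._fetch("UPPER(dub_name) = UPPER(?)", (dub_name,))
        if not records:
            self.last_notices = [f"no records for DUB {dub_name!r}"]
            return []
        return self._apply(records, thresholds)

    def query_by_substrate(
        self, gene_name: str, thresholds: Thresholds | None = None
    ) -> list[tuple[str, SubstrateRecord]]:
        """DUBs with evidence on one protein, as (dub_name, record) pairs."""
        records = self._fetch("UPPER(gene_name) = UPPER(?)", (gene_name,))
        if not records:
            self.last_notices = [f"no records for gene {gene_name!r}"]
            return []
        return [(r.dub_name, r) for r in self._apply(records, thresholds)]

    def dubs(self) -> list[str]:
        return [
            r[0]
            for r in self._conn.execute(
                "SELECT DISTINCT dub_name FROM evidence ORDER BY dub_name"
            )
        ]

    # -- export / volcano ----------------------------------------------------
    def export_csv(self, records: Sequence[SubstrateRecord], path: str | Path) -> None:
        """RFC-4180 CSV of a query result (header-only when empty)."""
        from .tables_io import write_results_csv

        columns = [
            "dub_name",
            "gene_name",
            "description",
            "log2_fc",
            "p_value",
            "unique_peptides",
            "protein_id",
            "all_peptides",
            "sequence_coverage",
            "glygly_positions",
            "provenance",
        ]
        df = pd.DataFrame(
            [
                {
                    **{c: getattr(r, c) for c in columns if c != "glygly_positions"},
                    "glygly_positions": (
                        ";".join(map(str, r.glygly_positions)) if r.glygly_positions else ""
                    ),
                }
                for r in records
            ],
            columns=columns,
        )
        write_results_csv(df, path)

    def import_csv(self, path: str | Path, experiment_id: str) -> int:
        """Re-ingest a previously exported CSV (round-trip counterpart)."""
        df = pd.read_csv(path, float_precision="round_trip")
        records = [
            SubstrateRecord(
                dub_name=row["dub_name"],
                gene_name=row["gene_name"],
                description="" if pd.isna(row["description"]) else str(row["description"]),
                log2_fc=float(row["log2_fc"]),
                p_value=None if pd.isna(row["p_value"]) else float(row["p_value"]),
                unique_peptides=(
                    None if pd.isna(row["unique_peptides"]) else int(row["unique_peptides"])
                ),
                protein_id=None if pd.isna(row["protein_id"]) else str(row["protein_id"]),
                all_peptides=None if pd.isna(row["all_peptides"]) else int(row["all_peptides"]),
                sequence_coverage=(
                    None if pd.isna(row["sequence_coverage"]) else float(row["sequence_coverage"])
                ),
                glygly_positions=(
                    tuple(int(x) for x in str(row["glygly_positions"]).split(";"))
                    if isinstance(row["glygly_positions"], str) and row["glygly_positions"]
                    else None
                ),
                provenance=str(row["provenance"]),
            )
            for _, row in df.iterrows()
        ]
        return self.ingest(records, experiment_id)

    def volcano_for_dub(self, dub_name: str, thresholds: Thresholds | None = None):
        """Volcano dataset over ALL ingested records of the DUB (including
        sub-threshold ones), with a boolean passing flag per point."""
        import numpy as np

        t = thresholds if thresholds is not None else self.thresholds
        records = self._fetch("UPPER(dub_name) = UPPER(?)", (dub_name,))
        passing = {
            (r.dub_name, r.gene_name) for r in self._apply(list(records), t)
        }
        points = []
        for r in records:
            p = r.p_value
            neg_log10_p = float(-np.log10(p)) if p and p > 0 else None
            points.append(
                {
                    "gene_name": r.gene_name,
                    "description": r.description,
                    "log2_fc": r.log2_fc,
                    "neg_log10_p": neg_log10_p,
                    "passes_thresholds": (r.dub_name, r.gene_name) in passing,
                }
            )
        points.sort(key=lambda d: (-d["log2_fc"], d["gene_name"]))
        return points
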