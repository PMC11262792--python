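"""Embedded SQLite store of validated / predicted miRNA-target interactions.

Mirrors the lookup layer a screen needs over miRTarBase/TarBase-style
dumps: a single flat interaction table, TSV import with deduplication,
queries per miRNA, and verification of stored pairs against 3'-UTR
sequences with the seed scanner.
"""

from __future__ import annotations

import csv
import sqlite3
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError
from .seedsites import SeedSite, scan_utr
from .seqio import MatureMiRNA, UTRRecord

VALIDATED = "validated-db"
PREDICTED = "predicted-seedscan"

_REQUIRED_COLUMNS = ("mirna_id", "gene_symbol", "evidence", "db_origin")


@dataclass(frozen=True)
class InteractionRecord:
    mirna_id: str
    gene_symbol: str
    source: str = VALIDATED
    evidence: str = ""
    db_origin: str = ""


class InteractionStore:
    """Single-file (or in-memory) relational store of interaction records."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._con = sqlite3.connect(path)
        self._con.execute(
            """
            CREATE TABLE IF NOT EXISTS interactions (
                mirna_id TEXT NOT NULL,
                gene_symbol TEXT NOT NULL,
                source TEXT NOT NULL,
                evidence TEXT NOT NULL DEFAULT '',
                db_origin TEXT NOT NULL DEFAULT '',
                UNIQUE (mirna_id, gene_symbol, source, evidence, db_origin)
            )
            """
        )
        self._con.commit()

    def close(self) -> None:
        self._con.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def add(self, records: Iterable[InteractionRecord]) -> int:
        """Insert records, deduplicating on the full key; returns rows added."""
        before = self.count()
        self._con.executemany(
            "INSERT OR IGNORE INTO interactions VALUES (?,?,?,?,?)",
            [
                (r.mirna_id, r.gene_symbol.upper(), r.source, r.evidence, r.db_origin)
                for r in records
            ],
        )
        self._con.commit()
        return self.count() - before

    def import_interactions(self, tsv_path, source: str = VALIDATED) -> int:
        """Load a TSV dump with header (mirna_id, gene_symbol, evidence, db_origin).

        Gene symbols are upper-cased on import; re-import is idempotent
        (adds 0). An empty file loads 0 records with a warning.
        """
        with open(tsv_path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                warnings.warn(f"{tsv_path}: empty interaction file, 0 records loaded")
                return 0
            missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise SchemaError(f"{tsv_path}: missing columns {missing}")
            records = [
                InteractionRecord(
                    mirna_id=row["mirna_id"],
                    gene_symbol=row["gene_symbol"],
                    source=source,
                    evidence=row["evidence"] or "",
                    db_origin=row["db_origin"] or "",
                )
                for row in reader
            ]
        if not records:
            warnings.warn(f"{tsv_path}: empty interaction file, 0 records loaded")
            return 0
        return self.add(records)

    def count(self) -> int:
        return self._con.execute("SELECT COUNT(*) FROM interactions").fetchone()[0]

    def query_targets(self, mirna_id: str) -> list[InteractionRecord]:
        """All records for a miRNA, stable-ordered; unknown ids give []."""
        rows = self._con.execute(
            "SELECT mirna_id, gene_symbol, source, evidence, db_origin "
            "FROM interactions WHERE mirna_id = ? "
            "ORDER BY gene_symbol, source, db_origin, evidence",
            (mirna_id,),
        ).fetchall()
        return [InteractionRecord(*row) for row in rows]

    def export_tsv(self, path) -> None:
        df = pd.read_sql_query(
            "SELECT * FROM interactions ORDER BY mirna_id, gene_symbol, source",
            self._con,
        )
        df.to_csv(path, sep="\t", index=False)


def verify_against_utrs(
    records: Sequence[InteractionRecord],
    mirnas: Sequence[MatureMiRNA],
    utrs: Sequence[UTRRecord],
) -> pd.DataFrame:
    """Check each stored interaction for a canonical seed site in its UTR.

    UTRs are matched to gene symbols case-insensitively by record id. A
    record without a UTR is flagged 'no-utr' rather than dropped; otherwise
    the flag is 'ok' and ``best_site_type`` is the highest-priority mode
    found (empty when no site exists).
    """
    mirna_by_id = {m.id: m for m in mirnas}
    utr_by_gene = {u.id.upper(): u for u in utrs}
    rows = []
    for rec in records:
        row = {
            "mirna_id": rec.mirna_id,
            "gene_symbol": rec.gene_symbol,
            "source": rec.source,
            "has_canonical_site": False,
            "best_site_type": "",
            "flag": "ok",
        }
        utr = utr_by_gene.get(rec.gene_symbol.upper())
        mirna = mirna_by_id.get(rec.mirna_id)
        if utr is None:
            row["flag"] = "no-utr"
        elif mirna is None:
            row["flag"] = "no-mirna"
        else:
            sites: list[SeedSite] = scan_utr(mirna, utr)
            if sites:
                best = max(sites, key=lambda s: s.site_type.priority)
                row["has_canonical_site"] = True
                row["best_site_type"] = best.site_type.label
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "gene_symbol", "source", "has_canonical_site", "best_site_type", "flag"],
    )
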