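"""The reverse structural-homology index.

A conventional profile-vs-structure search asks "which templates does this
protein resemble?".  Inverting it — parse every per-protein ranked hit list
once, store every hit keyed by template — yields an index that answers the
far more useful discovery question: "which proteins, in any proteome,
resemble this solved structure?".  The index is queryable by template id
and by keyword over template descriptions, and persists to a single SQLite
file.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence as TSequence

from .hhr_io import HitRecord, QueryMeta

__all__ = ["Index", "IndexRow", "build_index", "load_index"]

# an IndexRow is a HitRecord re-keyed by template; same field set
IndexRow = HitRecord

_COLUMNS = (
    "query_protein_id",
    "species",
    "template_id",
    "template_description",
    "rank",
    "probability",
    "e_value",
    "q_start",
    "q_end",
    "t_start",
    "t_end",
)


@dataclass
class Index:
    """Template→proteins lookup built from per-protein hhr documents."""

    rows: list[IndexRow] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    # -- queries ---------------------------------------------------------
    def query_template(self, template_id: str) -> list[IndexRow]:
        """All rows hitting ``template_id``, best (lowest) rank first."""
        rows = [r for r in self.rows if r.template_id == template_id]
        rows.sort(key=lambda r: (r.rank, -r.probability, r.species, r.query_protein_id))
        return rows

    def query_keyword(self, keywords: TSequence[str]) -> list[IndexRow]:
        """Rows whose template description contains ANY keyword.

        Matching is case-insensitive substring over the description only;
        the union over keywords is deduplicated per (protein, template).
        """
        terms = [k.lower() for k in keywords if k and k.strip()]
        if not terms:
            raise ValueError("at least one non-empty keyword is required")
        seen: set[tuple[str, str]] = set()
        out: list[IndexRow] = []
        for r in self.rows:
            desc = r.template_description.lower()
            if any(t in desc for t in terms):
                key = (r.query_protein_id, r.template_id)
                if key not in seen:
                    seen.add(key)
                    out.append(r)
        out.sort(key=lambda r: (r.rank, -r.probability, r.species, r.query_protein_id))
        return out

    def species(self) -> list[str]:
        return sorted({r.species for r in self.rows})

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Persist to a single SQLite file (reload-stable)."""
        path = Path(path)
        if path.exists():
            path.unlink()
        con = sqlite3.connect(path)
        try:
            con.execute(
                "CREATE TABLE hits (query_protein_id TEXT, species TEXT, "
                "template_id TEXT, template_description TEXT, rank INTEGER, "
                "probability REAL, e_value REAL, q_start INTEGER, q_end INTEGER, "
                "t_start INTEGER, t_end INTEGER, "
                "PRIMARY KEY (query_protein_id, template_id))"
            )
            con.execute("CREATE INDEX ix_template ON hits (template_id)")
            con.execute("CREATE TABLE provenance (source TEXT)")
            con.executemany(
                f"INSERT INTO hits ({', '.join(_COLUMNS)}) VALUES ({', '.join('?' * len(_COLUMNS))})",
                [tuple(getattr(r, c) for c in _COLUMNS) for r in self.rows],
            )
            con.executemany("INSERT INTO provenance VALUES (?)", [(p,) for p in self.provenance])
            con.commit()
        finally:
            con.close()


def load_index(path: str | Path) -> Index:
    """Load an index persisted by :meth:`Index.save`."""
    con = sqlite3.connect(path)
    try:
        rows = [
            IndexRow(**dict(zip(_COLUMNS, rec)))
            for rec in con.execute(f"SELECT {', '.join(_COLUMNS)} FROM hits")
        ]
        provenance = [p for (p,) in con.execute("SELECT source FROM provenance")]
    finally:
        con.close()
    idx = Index(rows=rows, provenance=provenance)
    idx.rows.sort(key=lambda r: (r.species, r.query_protein_id, r.rank))
    return idx


def build_index(
    documents: Iterable[tuple[QueryMeta, list[HitRecord]]],
    species: str | None = None,
) -> Index:
    """Assemble an Index from parsed hhr documents.

    Each document must carry a species label, either in its metadata or via
    the ``species`` override (the corpus convention is one directory per
    species, so the label often arrives from the path, not the file).

    Raises
    ------
    ValueError
        If a (protein, template) pair occurs twice with conflicting fields,
        or a document has no species label.
    """
    rows: dict[tuple[str, str], IndexRow] = {}
    provenance: list[str] = []
    for meta, hits in documents:
        sp = species or meta.species
        if not sp:
            raise ValueError(f"document for {meta.query_protein_id!r} has no species label")
        provenance.append(f"{sp}/{meta.query_protein_id}")
        for h in hits:
            row = replace(h, species=sp, query_protein_id=meta.query_protein_id)
            key = (row.query_protein_id, row.template_id)
            if key in rows:
                if rows[key] != row:
                    raise ValueError(
                        f"conflicting duplicate hit for protein {key[0]!r} vs template {key[1]!r}"
                    )
                continue
            rows[key] = row
    idx = Index(rows=list(rows.values()), provenance=provenance)
    idx.rows.sort(key=lambda r: (r.species, r.query_protein_id, r.rank))
    return idx
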