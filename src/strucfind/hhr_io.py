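"""Readers/writers for the two hit-table formats the pipeline exchanges.

* **hhr** — the per-query report of an HHsearch-style profile–profile
  search: a small header naming the query, then a ranked summary table of
  template hits.  Only the summary table feeds the reverse index, so the
  pairwise alignment blocks of the full format are out of contract; the
  writer emits exactly the dialect the parser accepts.
* **BLAST tabular** — the standard 12-column ``-outfmt 6`` layout used to
  exchange hits with the orthology stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "HitRecord",
    "QueryMeta",
    "BlastHit",
    "parse_hhr",
    "write_hhr",
    "parse_blast_tab",
    "write_blast_tab",
]


@dataclass(frozen=True)
class QueryMeta:
    """Identity of the proteome protein one hhr document reports on."""

    query_protein_id: str
    species: str = ""
    match_columns: int = 0


@dataclass(frozen=True)
class HitRecord:
    """One template hit for one proteome protein.

    ``rank`` is the "result number": the position of this template in the
    protein's best-first hit list.  Rank 1 means no structure in the
    template library resembles this protein more.  Coordinates are 1-based
    inclusive; ``q_*`` index the proteome protein, ``t_*`` the template.
    """

    query_protein_id: str
    template_id: str
    rank: int
    probability: float
    e_value: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    template_description: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if not (0.0 <= self.probability <= 100.0):
            raise ValueError(f"probability must be in [0, 100], got {self.probability}")
        if self.e_value < 0:
            raise ValueError("e-value must be non-negative")
        if self.q_start > self.q_end or self.q_start < 1:
            raise ValueError(f"bad query span {self.q_start}-{self.q_end}")
        if self.t_start > self.t_end or self.t_start < 1:
            raise ValueError(f"bad template span {self.t_start}-{self.t_end}")

    @property
    def q_span(self) -> int:
        """Aligned extent on the proteome protein, in residues."""
        return self.q_end - self.q_start + 1


_HHR_TABLE_HEADER = " No Hit                Prob  E-value  Query       Template    Description"


def write_hhr(meta: QueryMeta, hits: Iterable[HitRecord]) -> str:
    """Serialise one query's ranked hit list as an hhr document.

    Byte-deterministic for identical input; reals carry 6 significant
    digits so a write→parse→write cycle is stable.
    """
    hits = list(hits)
    ranks = [h.rank for h in hits]
    if ranks != list(range(1, len(hits) + 1)):
        raise ValueError("hit ranks must be unique and consecutive from 1")
    lines = [f"Query         {meta.query_protein_id}"]
    if meta.species:
        lines.append(f"Species       {meta.species}")
    if meta.match_columns:
        lines.append(f"Match_columns {meta.match_columns}")
    lines.append("")
    lines.append(_HHR_TABLE_HEADER)
    for h in hits:
        lines.append(
            f"{h.rank:>3d} {h.template_id:<18s} {h.probability:>5.6g} "
            f"{h.e_value:>8.6g} {h.q_start}-{h.q_end} {h.t_start}-{h.t_end} "
            f"{h.template_description}".rstrip()
        )
    return "\n".join(lines) + "\n"


def _parse_span(token: str, lineno: int) -> tuple[int, int]:
    try:
        lo, hi = token.split("-", 1)
        return int(lo), int(hi)
    except ValueError:
        raise ValueError(f"line {lineno}: malformed coordinate span {token!r}") from None


def parse_hhr(text: str) -> tuple[QueryMeta, list[HitRecord]]:
    """Parse one hhr document into query metadata and its ranked hits.

    Raises
    ------
    ValueError
        If the ``Query`` header is missing, a table row is malformed (the
        line number is named), or ranks are not consecutive from 1.
    """
    query_id = ""
    species = ""
    match_columns = 0
    hits: list[HitRecord] = []
    in_table = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not in_table:
            if line.startswith("Query"):
                query_id = line.split(None, 1)[1].strip() if len(line.split(None, 1)) > 1 else ""
            elif line.startswith("Species"):
                species = line.split(None, 1)[1].strip()
            elif line.startswith("Match_columns"):
                match_columns = int(line.split(None, 1)[1])
            elif line.lstrip().startswith("No Hit"):
                in_table = True
            continue
        if not line.strip():
            continue
        parts = line.split(None, 6)
        if len(parts) < 6:
            raise ValueError(f"line {lineno}: malformed hhr summary row: {line!r}")
        try:
            rank = int(parts[0])
            probability = float(parts[2])
            e_value = float(parts[3])
        except ValueError:
            raise ValueError(f"line {lineno}: malformed numeric field in: {line!r}") from None
        q_start, q_end = _parse_span(parts[4], lineno)
        t_start, t_end = _parse_span(parts[5], lineno)
        hits.append(
            HitRecord(
                query_protein_id=query_id,
                species=species,
                template_id=parts[1],
                rank=rank,
                probability=probability,
                e_value=e_value,
                q_start=q_start,
                q_end=q_end,
                t_start=t_start,
                t_end=t_end,
                template_description=parts[6] if len(parts) > 6 else "",
            )
        )
    if not query_id:
        raise ValueError("hhr document has no Query header")
    ranks = [h.rank for h in hits]
    if ranks != list(range(1, len(hits) + 1)):
        raise ValueError(f"hit ranks are not consecutive from 1: {ranks}")
    return QueryMeta(query_id, species, match_columns), hits


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column BLAST tabular output (``-outfmt 6``)."""

    query_id: str
    subject_id: str
    percent_id: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0 or not math.isfinite(self.e_value):
            raise ValueError("e-value must be finite and non-negative")


def parse_blast_tab(text: str) -> list[BlastHit]:
    """Parse 12-column tab-separated BLAST output, preserving row order."""
    hits: list[BlastHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 12:
            raise ValueError(f"line {lineno}: expected 12 tab-separated columns, got {len(cols)}")
        try:
            hits.append(
                BlastHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_id=float(cols[2]),
                    align_len=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    e_value=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    return hits


def write_blast_tab(hits: Iterable[BlastHit]) -> str:
    """Serialise hits as 12-column tab-separated text (round-trips)."""
    lines = []
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.percent_id:.6g}",
                    str(h.align_len),
                    str(h.mismatches),
                    str(h.gap_opens),
                    str(h.q_start),
                    str(h.q_end),
                    str(h.s_start),
                    str(h.s_end),
                    f"{h.e_value:.6g}",
                    f"{h.bit_score:.6g}",
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
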