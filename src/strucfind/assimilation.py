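"""Multi-structure hit assimilation.

A reverse-index query with one template structure yields one ranked list
of candidate proteins.  Because several solved structures exist for each
subunit family, the same protein is typically returned by several of those
searches; this module merges the per-structure result lists into one
candidate table and applies the four-criterion rule that separates real
structural homologues from noise:

* result number (rank) strictly below 10,
* hit probability strictly above 50%,
* at least 100 residues of homology on the candidate protein,
* recovered by at least two distinct query structures ("repeats").

Hits ranked worse than 50 are discarded before merging: fifty templates
resembling a protein more than the query does is taken as decisive
evidence against homology.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .reverse_index import IndexRow

__all__ = [
    "CandidateRow",
    "CallCriteria",
    "merge_searches",
    "rank_candidates",
    "call_hits",
    "display_filter",
    "candidates_to_tsv",
]

#: hits ranked worse than this are discarded before any merging
PRECLUSION_RANK = 50


@dataclass(frozen=True)
class CallCriteria:
    """Thresholds of the hit-call rule.

    ``max_rank`` and ``min_probability`` are exclusive bounds (rank < 10,
    probability > 50); ``min_span`` and ``min_repeats`` are inclusive.
    """

    max_rank: int = 10
    min_probability: float = 50.0
    min_span: int = 100
    min_repeats: int = 2

    def __post_init__(self) -> None:
        if min(self.max_rank, self.min_probability, self.min_span, self.min_repeats) <= 0:
            raise ValueError("all call criteria must be positive")


@dataclass(frozen=True)
class CandidateRow:
    """One protein after multi-structure merging.

    ``best_rank``/``best_probability``/``span`` come from the single kept
    hit (lowest rank; ties broken by higher probability, then template id);
    ``repeats`` counts the distinct query structures that returned the
    protein at rank <= 50.
    """

    protein_id: str
    species: str
    best_rank: int
    best_probability: float
    span: int
    repeats: int
    supporting_templates: tuple[str, ...]
    called: bool = False

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.best_rank > PRECLUSION_RANK:
            raise ValueError(f"best_rank {self.best_rank} exceeds the preclusion bound")
        if self.span < 1:
            raise ValueError("span must be >= 1")


def merge_searches(per_structure_results: Mapping[str, Iterable[IndexRow]]) -> list[CandidateRow]:
    """Merge per-structure result lists into one row per protein.

    Parameters
    ----------
    per_structure_results
        Map from query structure (template id) to the rows returned for it.

    Rows ranked worse than 50 are precluded before merging, so they count
    neither toward the kept hit nor toward repeats.  The merge is invariant
    to the mapping's iteration order and idempotent.
    """
    best: dict[tuple[str, str], tuple[tuple[int, float, str], IndexRow]] = {}
    supporters: dict[tuple[str, str], set[str]] = {}
    for structure in sorted(per_structure_results):
        for row in per_structure_results[structure]:
            if row.rank > PRECLUSION_RANK:
                continue
            key = (row.species, row.query_protein_id)
            sort_key = (row.rank, -row.probability, row.template_id)
            supporters.setdefault(key, set()).add(structure)
            if key not in best or sort_key < best[key][0]:
                best[key] = (sort_key, row)
    out = []
    for key in sorted(best):
        _, row = best[key]
        out.append(
            CandidateRow(
                protein_id=row.query_protein_id,
                species=row.species,
                best_rank=row.rank,
                best_probability=row.probability,
                span=row.q_span,
                repeats=len(supporters[key]),
                supporting_templates=tuple(sorted(supporters[key])),
            )
        )
    return out


def rank_candidates(rows: Iterable[CandidateRow]) -> list[CandidateRow]:
    """Order candidates: lowest rank first, then highest probability.

    Residual ties fall back to protein id, making the order fully
    deterministic.
    """
    return sorted(rows, key=lambda r: (r.best_rank, -r.best_probability, r.protein_id))


def call_hits(rows: Iterable[CandidateRow], criteria: CallCriteria = CallCriteria()) -> list[CandidateRow]:
    """Set the ``called`` flag by the four-criterion rule; order preserved."""
    out = []
    for r in rows:
        called = (
            r.best_rank < criteria.max_rank
            and r.best_probability > criteria.min_probability
            and r.span >= criteria.min_span
            and r.repeats >= criteria.min_repeats
        )
        out.append(replace(r, called=called))
    return out


def display_filter(rows: Iterable[CandidateRow], max_rank: int = 10, min_repeats_exclusive: int = 2) -> list[CandidateRow]:
    """The looser report filter (rank < 10 OR repeats > 2), kept distinct
    from calling: it selects what is worth showing, not what is real."""
    return [r for r in rows if r.best_rank < max_rank or r.repeats > min_repeats_exclusive]


_TSV_HEADER = "protein_id\tspecies\tbest_rank\tbest_probability\tspan\trepeats\tsupporting_templates\tcalled"


def candidates_to_tsv(rows: Iterable[CandidateRow]) -> str:
    """Serialise candidate rows as TSV with a header, called flag last."""
    lines = [_TSV_HEADER]
    for r in rows:
        lines.append(
            f"{r.protein_id}\t{r.species}\t{r.best_rank}\t{r.best_probability:.6g}\t"
            f"{r.span}\t{r.repeats}\t{','.join(r.supporting_templates)}\t{int(r.called)}"
        )
    return "\n".join(lines) + "\n"
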