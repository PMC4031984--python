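"""Reciprocal-best-hit orthology with iterative seed growth.

Candidate homologues surfaced by a sensitive forward search are only
accepted as orthologues if the reciprocal search confirms them: searching
the candidate back into at least one reference genome must (a) retrieve
the known orthologue as the best hit and (b) do so with an e-value at
least two orders of magnitude better than the next best hit.  Accepted
members are folded into the seed set before the next genome is searched,
so the model's sensitivity grows as the taxon sampling broadens.

Verdicts across a (family × taxon) grid assemble into a presence/absence
matrix, the data behind a Coulson plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as TSequence

from .backends import SearchBackend
from .hhr_io import BlastHit
from .seqkit import Sequence

__all__ = [
    "OrthologyCall",
    "PresenceMatrix",
    "rbh_validate",
    "iterative_search",
    "run_orthology",
    "presence_matrix",
    "EVALUE_FLOOR",
]

#: e-values of exactly 0 (numerical underflow) are floored here before log10
EVALUE_FLOOR = 1e-180


def _log10e(e: float) -> tuple[float, bool]:
    if e <= EVALUE_FLOOR:
        return math.log10(EVALUE_FLOOR), e < EVALUE_FLOOR or e == 0.0
    return math.log10(e), False


@dataclass(frozen=True)
class OrthologyCall:
    """Verdict for one (gene family, taxon) pair."""

    family: str
    taxon: str
    status: str  # "found" | "not_found"
    candidate_id: str | None = None
    rbh_reference: str | None = None
    margin: float | None = None
    flags: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("found", "not_found"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "found":
            if self.candidate_id is None or self.rbh_reference is None:
                raise ValueError("a found call must carry candidate and reference")
            if "single_hit" not in self.flags and (self.margin is None or self.margin < 0):
                raise ValueError("a found call must carry a non-negative margin")

    @property
    def found(self) -> bool:
        return self.status == "found"


def rbh_validate(
    candidate: Sequence | str,
    reference_hits: Mapping[str, TSequence[BlastHit]],
    expected: Mapping[str, str],
    margin_orders: float = 2.0,
    *,
    family: str = "",
    taxon: str = "",
    strict_single_hit: bool = False,
) -> OrthologyCall:
    """Reciprocal-best-hit test against one or more reference genomes.

    Parameters
    ----------
    candidate
        The candidate sequence (or its accession) being validated.
    reference_hits
        Per reference taxon, the candidate's hit list into that reference
        proteome, already sorted best-first by e-value.
    expected
        Per reference taxon, the accession of the known orthologue the
        reciprocal search must retrieve.
    margin_orders
        Required log10 e-value gap between best and next-best hit
        (default two orders of magnitude).
    strict_single_hit
        A one-hit reference list has no "next best hit"; by default it
        passes the margin vacuously (flagged ``single_hit``); set True to
        reject instead.

    The verdict depends only on the top two hits of each reference list,
    and is invariant under multiplying all e-values in a list by a
    positive constant.
    """
    if not reference_hits:
        raise ValueError("at least one reference taxon is required")
    missing = sorted(set(reference_hits) - set(expected))
    if missing:
        raise ValueError(f"no expected orthologue given for reference taxa: {missing}")
    candidate_id = candidate.id if isinstance(candidate, Sequence) else candidate

    best_pass: tuple[float, str, tuple[str, ...]] | None = None
    for ref in sorted(reference_hits):
        hits = reference_hits[ref]
        if not hits:
            continue
        if hits[0].subject_id != expected[ref]:
            continue
        flags: list[str] = []
        if len(hits) == 1:
            if strict_single_hit:
                continue
            margin = math.inf
            flags.append("single_hit")
        else:
            l1, f1 = _log10e(hits[0].e_value)
            l2, f2 = _log10e(hits[1].e_value)
            if f1 or f2:
                flags.append("evalue_floored")
            margin = l2 - l1
            if margin < margin_orders:
                continue
        if best_pass is None or margin > best_pass[0]:
            best_pass = (margin, ref, tuple(flags))
    if best_pass is None:
        return OrthologyCall(family=family, taxon=taxon, status="not_found", candidate_id=candidate_id)
    margin, ref, flags = best_pass
    return OrthologyCall(
        family=family,
        taxon=taxon,
        status="found",
        candidate_id=candidate_id,
        rbh_reference=ref,
        margin=None if math.isinf(margin) else margin,
        flags=flags,
    )


def iterative_search(
    seed_set: TSequence[Sequence],
    genome_queue: TSequence[tuple[str, TSequence[Sequence]]],
    backend: SearchBackend,
    references: Mapping[str, TSequence[Sequence]],
    expected: Mapping[str, str],
    *,
    family: str = "",
    margin_orders: float = 2.0,
    top_n: int = 5,
    incorporate: bool = True,
) -> list[OrthologyCall]:
    """Search genomes in order, growing the seed set with validated finds.

    For each genome: the current seed set is searched against the
    proteome; the ``top_n`` best-scoring candidates are validated by
    :func:`rbh_validate` (reciprocal search into every reference
    proteome); the first candidate to pass is the family's member in that
    genome and — when ``incorporate`` is set — joins the seed set before
    the next genome is searched.  ``incorporate=False`` gives the static
    baseline.  A backend failure on one genome is recorded as a
    ``not_found`` call with an error note; the queue continues.
    """
    if not seed_set:
        raise ValueError("seed set must be non-empty")
    seeds = list(seed_set)
    calls: list[OrthologyCall] = []
    for taxon, proteome in genome_queue:
        try:
            forward = backend.search(seeds, proteome)
        except Exception as exc:  # noqa: BLE001 - backend is pluggable
            calls.append(
                OrthologyCall(family=family, taxon=taxon, status="not_found", note=f"backend error: {exc}")
            )
            continue
        by_id = {s.id: s for s in proteome}
        verdict: OrthologyCall | None = None
        for hit in forward[:top_n]:
            cand = by_id[hit.subject_id]
            try:
                reference_hits = {ref: backend.search([cand], prot) for ref, prot in references.items()}
            except Exception as exc:  # noqa: BLE001
                verdict = OrthologyCall(
                    family=family, taxon=taxon, status="not_found", note=f"backend error: {exc}"
                )
                break
            call = rbh_validate(
                cand, reference_hits, expected, margin_orders, family=family, taxon=taxon
            )
            if call.found:
                verdict = call
                if incorporate:
                    seeds.append(cand)
                break
        if verdict is None:
            verdict = OrthologyCall(family=family, taxon=taxon, status="not_found")
        calls.append(verdict)
    return calls


def run_orthology(
    seed_sets: Mapping[str, TSequence[Sequence]],
    genome_queue: TSequence[tuple[str, TSequence[Sequence]]],
    backend: SearchBackend,
    references: Mapping[str, TSequence[Sequence]],
    expected: Mapping[str, Mapping[str, str]],
    **kwargs,
) -> list[OrthologyCall]:
    """Run :func:`iterative_search` for every family; one call per cell."""
    calls: list[OrthologyCall] = []
    for family in seed_sets:
        calls.extend(
            iterative_search(
                seed_sets[family],
                genome_queue,
                backend,
                references,
                expected[family],
                family=family,
                **kwargs,
            )
        )
    return calls


@dataclass(frozen=True)
class PresenceMatrix:
    """Taxa × families presence/absence grid (Coulson-plot data)."""

    taxa: tuple[str, ...]
    families: tuple[str, ...]
    cells: Mapping[tuple[str, str], bool] = field(hash=False)

    @property
    def complete_taxa(self) -> tuple[str, ...]:
        """Taxa in which every family was found (bold names in a plot)."""
        return tuple(t for t in self.taxa if all(self.cells[(t, f)] for f in self.families))

    def to_csv(self) -> str:
        """CSV consumable as Coulson-plot input: taxa rows, cells 1/0."""
        lines = ["taxon," + ",".join(self.families)]
        for t in self.taxa:
            lines.append(t + "," + ",".join("1" if self.cells[(t, f)] else "0" for f in self.families))
        return "\n".join(lines) + "\n"

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [[int(self.cells[(t, f)]) for f in self.families] for t in self.taxa],
            index=list(self.taxa),
            columns=list(self.families),
        )

    def plot(self, ax=None):
        """Coulson-style glyph grid: one pie per taxon, one sector per
        family, filled where the family was found.  Taxa with the full
        complement are labelled bold.  Requires matplotlib."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Wedge

        if ax is None:
            _, ax = plt.subplots(figsize=(2 + 0.5 * len(self.families), 0.5 * len(self.taxa) + 1))
        n = len(self.families)
        complete = set(self.complete_taxa)
        for row, taxon in enumerate(self.taxa):
            y = len(self.taxa) - row
            for k, family in enumerate(self.families):
                theta1, theta2 = 90 - 360 * (k + 1) / n, 90 - 360 * k / n
                filled = self.cells[(taxon, family)]
                ax.add_patch(
                    Wedge((1.0, y), 0.42, theta1, theta2,
                          facecolor="#3b6ea5" if filled else "white",
                          edgecolor="black", linewidth=0.6)
                )
            ax.text(1.6, y, taxon, va="center",
                    fontweight="bold" if taxon in complete else "normal")
        ax.set_xlim(0.4, 4)
        ax.set_ylim(0.3, len(self.taxa) + 0.9)
        ax.set_aspect("equal")
        ax.axis("off")
        ax.set_title(" / ".join(self.families), fontsize=8)
        return ax


def presence_matrix(calls: Iterable[OrthologyCall]) -> PresenceMatrix:
    """Assemble calls into a complete grid; missing cells are an error."""
    calls = list(calls)
    taxa = tuple(dict.fromkeys(c.taxon for c in calls))
    families = tuple(dict.fromkeys(c.family for c in calls))
    cells: dict[tuple[str, str], bool] = {}
    for c in calls:
        cells[(c.taxon, c.family)] = c.found
    missing = [(t, f) for t in taxa for f in families if (t, f) not in cells]
    if missing:
        raise ValueError(f"presence grid incomplete; missing (taxon, family) pairs: {missing}")
    return PresenceMatrix(taxa=taxa, families=families, cells=cells)
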