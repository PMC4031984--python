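"""Sequence I/O plus the two small sequence computations the pipeline needs.

The toolkit works from proteome FASTA files.  Two bespoke statistics are
computed directly from raw sequence:

* **global percent identity** between two proteins, from a Needleman–Wunsch
  global alignment (used to quantify divergence between distant family
  members, e.g. beta-like large subunits across supergroups);
* **theoretical tryptic peptide counts**, the per-protein normaliser the
  iBAQ abundance estimate divides by.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Sequence",
    "IdentityResult",
    "read_fasta",
    "write_fasta",
    "global_identity",
    "digest",
    "count_theoretical_peptides",
]

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXBZ*")


@dataclass(frozen=True)
class Sequence:
    """One protein: an accession, free-text description and residue string."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class IdentityResult:
    """Identity statistics of one global alignment.

    ``percent_identity`` uses the full alignment length (gap columns
    included) as denominator, so highly divergent pairs with long
    unalignable stretches score low rather than being flattered by a
    matched-columns-only denominator.
    """

    percent_identity: float
    aligned_length: int
    identities: int
    score: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.identities <= self.aligned_length):
            raise ValueError("identities must lie within [0, aligned_length]")


def read_fasta(source: str | TextIO) -> list[Sequence]:
    """Read a (possibly line-wrapped) FASTA document into Sequence records.

    Parameters
    ----------
    source : str or file-like
        FASTA text, a path is *not* accepted; pass text or a handle.

    Raises
    ------
    ValueError
        If a record has an empty residue string (the record id is named).
    """
    handle = io.StringIO(source) if isinstance(source, str) else source
    out: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        residues = str(rec.seq).upper()
        if not residues:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        out.append(Sequence(id=rec.id, residues=residues, description=desc))
    return out


def write_fasta(seqs: Iterable[Sequence], handle: TextIO | None = None, width: int = 60) -> str:
    """Write records as multi-FASTA, wrapping residue lines at ``width``.

    Round-trips through :func:`read_fasta` up to line wrapping.
    """
    buf = io.StringIO()
    for s in seqs:
        header = f">{s.id} {s.description}".rstrip()
        buf.write(header + "\n")
        for i in range(0, len(s.residues), width):
            buf.write(s.residues[i:i + width] + "\n")
    text = buf.getvalue()
    if handle is not None:
        handle.write(text)
    return text


def _default_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_identity(
    a: Sequence,
    b: Sequence,
    *,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> IdentityResult:
    """Percent identity from a Needleman–Wunsch global alignment.

    Identity is counted as exact residue matches over the full alignment
    length, gap columns included.  Defaults are BLOSUM62 with affine gap
    penalties 10 (open) / 0.5 (extend), the common protein global-alignment
    default.  Symmetric in its arguments.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    aligner = _default_aligner(gap_open, gap_extend)
    if matrix != "BLOSUM62":
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    alignment = aligner.align(a.residues, b.residues)[0]
    counts = alignment.counts()
    length = alignment.length
    identities = counts.identities
    return IdentityResult(
        percent_identity=100.0 * identities / length,
        aligned_length=length,
        identities=identities,
        score=alignment.score,
    )


def digest(residues: str) -> list[str]:
    """In-silico tryptic digest with zero missed cleavages.

    Trypsin cleaves C-terminal to K or R, except when the next residue is
    proline.  The returned peptides concatenate back to the input.
    """
    peptides: list[str] = []
    start = 0
    for i, aa in enumerate(residues):
        if aa in "KR" and (i + 1 == len(residues) or residues[i + 1] != "P"):
            peptides.append(residues[start:i + 1])
            start = i + 1
    if start < len(residues):
        peptides.append(residues[start:])
    return peptides


def count_theoretical_peptides(seq: Sequence | str, min_len: int = 6, max_len: int = 30) -> int:
    """Count tryptic peptides whose length falls in ``[min_len, max_len]``.

    This is the observable-peptide normaliser of the iBAQ abundance
    estimate; the default 6–30 residue window is the convention of that
    method.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    residues = seq.residues if isinstance(seq, Sequence) else seq
    return sum(1 for p in digest(residues) if min_len <= len(p) <= max_len)
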