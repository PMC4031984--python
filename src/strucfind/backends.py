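"""Homology-search backends behind the orthology stage.

The orthology stage only needs a contract: (query sequences or profile,
target proteome) -> scored hits, best-first by e-value.  Anything honouring
it plugs in — externally produced BLAST tabular files, a profile-HMM
search, or the bundled score backend.

Two backends ship here:

* :class:`NaiveBackend` — a self-contained ungapped best-segment scorer.
  Each target is scored by its best ungapped diagonal segment against the
  query set (or, when the queries are aligned to equal length, against
  their position-specific average-score profile, so sensitivity grows as
  members are incorporated).  The raw score is mapped to a surrogate
  e-value through a Karlin–Altschul-shaped tail, ``E = K·m·n·exp(-λS)``,
  which is monotone decreasing in score — all the downstream logic
  (best-first order, log-ratio margins) needs.  It is deterministic and
  runs with no external program.
* :class:`PyhmmerBackend` — a real profile-HMM search via pyhmmer
  (HMMER3), available when that optional dependency is installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence as TSequence, runtime_checkable

import numpy as np
from Bio.Align import substitution_matrices

from .hhr_io import BlastHit
from .seqkit import Sequence

__all__ = ["SearchBackend", "NaiveBackend", "PyhmmerBackend"]

# ungapped BLOSUM62 Karlin-Altschul parameters (natural-log units)
_LAMBDA = 0.3176
_K = 0.134

_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"


def _blosum62_matrix() -> tuple[np.ndarray, dict[str, int]]:
    m = substitution_matrices.load("BLOSUM62")
    idx = {aa: i for i, aa in enumerate(_ALPHABET)}
    arr = np.zeros((len(_ALPHABET), len(_ALPHABET)), dtype=np.float64)
    for a in _ALPHABET:
        for b in _ALPHABET:
            try:
                arr[idx[a], idx[b]] = m[a, b]
            except KeyError:
                arr[idx[a], idx[b]] = -1.0
    return arr, idx


_BLOSUM, _AA_INDEX = _blosum62_matrix()


def _encode(residues: str) -> np.ndarray:
    x = _AA_INDEX.get("X")
    return np.array([_AA_INDEX.get(aa, x) for aa in residues], dtype=np.intp)


def _best_segment(score_matrix: np.ndarray) -> float:
    """Best ungapped (diagonal) segment sum of a position-score matrix."""
    m, n = score_matrix.shape
    best = 0.0
    for k in range(-(m - 1), n):
        d = np.diagonal(score_matrix, offset=k)
        cs = np.cumsum(d)
        prefix_min = np.minimum.accumulate(np.concatenate(([0.0], cs[:-1])))
        best = max(best, float((cs - prefix_min).max()))
    return best


@runtime_checkable
class SearchBackend(Protocol):
    """Contract: score a query set against a proteome, best hits first."""

    def search(self, queries: TSequence[Sequence], proteome: TSequence[Sequence]) -> list[BlastHit]:
        ...


class NaiveBackend:
    """Ungapped best-segment scorer with a surrogate e-value.

    Parameters
    ----------
    lambda_, k
        Shape parameters of the score→e-value map.  Their exact values are
        immaterial to the downstream logic (order and log-ratios are
        preserved under any monotone map); the defaults are the classical
        ungapped BLOSUM62 constants so the surrogate e-values look
        familiar.
    """

    def __init__(self, lambda_: float = _LAMBDA, k: float = _K) -> None:
        self.lambda_ = lambda_
        self.k = k

    def _surrogate_evalue(self, score: float, m: int, n: int) -> float:
        log_e = np.log(self.k * m * n) - self.lambda_ * score
        if log_e < -745.0:  # below double underflow; report 0 like BLAST does
            return 0.0
        return float(np.exp(log_e))

    def _score_one(self, queries: TSequence[Sequence], target: Sequence) -> tuple[float, int]:
        t = _encode(target.residues)
        lengths = {len(q.residues) for q in queries}
        if len(lengths) == 1 and len(queries) > 1:
            # aligned query set: score against the average-score profile
            q_stack = np.stack([_encode(q.residues) for q in queries])
            profile = _BLOSUM[q_stack].mean(axis=0)  # L x alphabet
            score = _best_segment(profile[:, t])
            return score, next(iter(lengths))
        best = -np.inf
        best_m = len(queries[0].residues)
        for q in queries:
            qi = _encode(q.residues)
            s = _best_segment(_BLOSUM[qi][:, t])
            if s > best:
                best, best_m = s, len(qi)
        return float(best), best_m

    def search(self, queries: TSequence[Sequence], proteome: TSequence[Sequence]) -> list[BlastHit]:
        if not queries:
            raise ValueError("empty query set")
        query_label = queries[0].id if len(queries) == 1 else f"profile({len(queries)})"
        hits = []
        for target in proteome:
            score, m = self._score_one(queries, target)
            n = len(target.residues)
            e = self._surrogate_evalue(score, m, n)
            bit = (self.lambda_ * score - np.log(self.k)) / np.log(2.0)
            hits.append(
                BlastHit(
                    query_id=query_label,
                    subject_id=target.id,
                    percent_id=0.0,
                    align_len=min(m, n),
                    mismatches=0,
                    gap_opens=0,
                    q_start=1,
                    q_end=m,
                    s_start=1,
                    s_end=n,
                    e_value=e,
                    bit_score=float(bit),
                )
            )
        hits.sort(key=lambda h: (h.e_value, -h.bit_score, h.subject_id))
        return hits


class PyhmmerBackend:
    """Profile-HMM search via pyhmmer (HMMER3); queries must be aligned.

    Builds an HMM from the (equal-length, gap-free or pre-aligned) query
    set and searches the target proteome with it, reporting real HMMER
    e-values.  Requires the optional ``pyhmmer`` dependency.
    """

    def __init__(self) -> None:
        import pyhmmer  # deferred: optional dependency

        self._pyhmmer = pyhmmer
        self._alphabet = pyhmmer.easel.Alphabet.amino()

    def _build_hmm(self, queries: TSequence[Sequence]):
        pyhmmer = self._pyhmmer
        if len({len(q.residues) for q in queries}) != 1:
            raise ValueError("PyhmmerBackend requires an aligned (equal-length) query set")
        seqs = [
            pyhmmer.easel.TextSequence(name=q.id.encode(), sequence=q.residues)
            for q in queries
        ]
        msa = pyhmmer.easel.TextMSA(name=b"seed", sequences=seqs).digitize(self._alphabet)
        builder = pyhmmer.plan7.Builder(self._alphabet)
        background = pyhmmer.plan7.Background(self._alphabet)
        hmm, _, _ = builder.build_msa(msa, background)
        return hmm

    def search(self, queries: TSequence[Sequence], proteome: TSequence[Sequence]) -> list[BlastHit]:
        if not queries:
            raise ValueError("empty query set")
        pyhmmer = self._pyhmmer
        hmm = self._build_hmm(queries)
        targets = pyhmmer.easel.DigitalSequenceBlock(
            self._alphabet,
            [
                pyhmmer.easel.TextSequence(name=s.id.encode(), sequence=s.residues).digitize(self._alphabet)
                for s in proteome
            ],
        )
        pipeline = pyhmmer.plan7.Pipeline(self._alphabet)
        top_hits = pipeline.search_hmm(hmm, targets)
        hits = []
        for h in top_hits:
            name = h.name.decode() if isinstance(h.name, bytes) else h.name
            hits.append(
                BlastHit(
                    query_id="hmm:seed",
                    subject_id=name,
                    percent_id=0.0,
                    align_len=hmm.M,
                    mismatches=0,
                    gap_opens=0,
                    q_start=1,
                    q_end=hmm.M,
                    s_start=1,
                    s_end=h.length,
                    e_value=float(h.evalue),
                    bit_score=float(h.score),
                )
            )
        hits.sort(key=lambda x: (x.e_value, -x.bit_score, x.subject_id))
        return hits
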