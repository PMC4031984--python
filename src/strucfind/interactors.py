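"""AP-MS interactor calling from peptide-intensity tables.

Given replicate bait pulldowns plus non-transformed controls, the stage:

1. estimates molar abundance per (protein, experiment) by iBAQ — summed
   peptide intensity divided by the protein's count of theoretically
   observable tryptic peptides;
2. normalises each experiment so the median abundance of all proteins is
   exactly 1.0 (the bait, grossly overrepresented by overexpression, is
   excluded from the median by default);
3. applies the specificity filters: any detection in a control eliminates
   a protein, as do fewer than 5 identified peptides in total, failure to
   coprecipitate in at least 3 independent experiments, or a median molar
   ratio to the bait below 0.002.

Every excluded protein carries the exhaustive list of filters it failed.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as TSequence

import pandas as pd

from .seqkit import Sequence, count_theoretical_peptides

__all__ = [
    "PulldownTable",
    "InteractorCriteria",
    "InteractorCall",
    "compute_ibaq",
    "normalize_median",
    "call_interactors",
    "calls_to_tsv",
]


@dataclass
class PulldownTable:
    """Per-protein peptide counts and intensities across experiments.

    ``counts`` and ``intensities`` are protein × experiment DataFrames
    with identical shape; ``sequences`` maps each protein id to its
    Sequence (needed for the iBAQ digest normaliser).
    """

    counts: pd.DataFrame
    intensities: pd.DataFrame
    sequences: Mapping[str, Sequence]

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.intensities.index) or not self.counts.columns.equals(
            self.intensities.columns
        ):
            raise ValueError("counts and intensities must share index and columns")
        bad = (self.intensities == 0) & (self.counts > 0)
        if bad.any().any():
            raise ValueError("peptide_count > 0 requires intensity_sum > 0")

    @property
    def experiments(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self) -> str:
        """Rows = proteins; per experiment a ``<label>.peptides`` and a
        ``<label>.intensity`` column pair."""
        cols: dict[str, pd.Series] = {}
        for e in self.experiments:
            cols[f"{e}.peptides"] = self.counts[e]
            cols[f"{e}.intensity"] = self.intensities[e]
        df = pd.DataFrame(cols, index=self.counts.index)
        df.index.name = "protein_id"
        return df.to_csv(sep="\t")

    @classmethod
    def from_tsv(cls, text: str, sequences: Mapping[str, Sequence]) -> "PulldownTable":
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col="protein_id")
        labels = []
        for c in df.columns:
            if c.endswith(".peptides"):
                labels.append(c[: -len(".peptides")])
        counts = df[[f"{e}.peptides" for e in labels]].astype(int)
        counts.columns = labels
        intensities = df[[f"{e}.intensity" for e in labels]].astype(float)
        intensities.columns = labels
        return cls(counts=counts, intensities=intensities, sequences=sequences)


@dataclass(frozen=True)
class InteractorCriteria:
    """Specificity thresholds; defaults follow the standard filter set."""

    min_peptides: int = 5        # summed across bait experiments, inclusive lower bound
    min_ratio: float = 0.002     # median molar ratio to bait, inclusive lower bound
    min_experiments: int = 3     # bait experiments with >=1 peptide, inclusive
    digest_min: int = 6
    digest_max: int = 30


@dataclass(frozen=True)
class InteractorCall:
    """Verdict for one protein, with every failed filter listed."""

    protein_id: str
    called: bool
    reasons: tuple[str, ...]
    median_ratio_to_bait: float
    total_peptides: int
    n_experiments_detected: int
    normalized_abundance: Mapping[str, float] = field(default_factory=dict, compare=False)
    is_bait: bool = False

    def __post_init__(self) -> None:
        if self.called != (len(self.reasons) == 0):
            raise ValueError("called must hold exactly when no filter failed")


def compute_ibaq(
    table: PulldownTable,
    digest_min: int = 6,
    digest_max: int = 30,
) -> pd.DataFrame:
    """iBAQ abundance per (protein, experiment).

    abundance = intensity_sum / count of theoretical tryptic peptides in
    the digest window.  A protein with zero theoretical peptides but
    non-zero intensity cannot be normalised; it is dropped with a warning
    rather than failing the run.
    """
    n_pep = {}
    dropped = []
    for pid in table.proteins:
        if pid not in table.sequences:
            raise KeyError(f"no sequence provided for protein {pid!r}")
        n = count_theoretical_peptides(table.sequences[pid], digest_min, digest_max)
        if n == 0:
            dropped.append(pid)
        else:
            n_pep[pid] = n
    if dropped:
        warnings.warn(
            f"{len(dropped)} protein(s) with zero theoretical peptides excluded from iBAQ: {dropped}",
            stacklevel=2,
        )
    kept = table.intensities.drop(index=dropped)
    return kept.div(pd.Series(n_pep), axis=0)


def normalize_median(abundances: pd.Series | pd.DataFrame, exclude: Iterable[str] = ()) -> pd.Series | pd.DataFrame:
    """Scale one experiment (Series) or all (DataFrame) so the median of
    positive abundances is exactly 1.0.

    ``exclude`` lists proteins (typically the overexpressed bait and its
    tag) left out of the median computation but still rescaled.
    """
    if isinstance(abundances, pd.DataFrame):
        return abundances.apply(lambda col: normalize_median(col, exclude))
    pool = abundances.drop(index=[p for p in exclude if p in abundances.index])
    positive = pool[pool > 0]
    if positive.empty:
        raise ValueError("experiment has no positive abundances to normalise against")
    return abundances / positive.median()


def call_interactors(
    table: PulldownTable,
    bait_id: str,
    control_labels: TSequence[str],
    criteria: InteractorCriteria = InteractorCriteria(),
    tag_id: str | None = None,
    exclude_bait_from_median: bool = True,
) -> list[InteractorCall]:
    """Apply the specificity filters and report every protein's verdict.

    A protein is called a specific interactor iff it is (a) undetected in
    every control, (b) supported by at least ``min_peptides`` peptides
    summed over bait experiments, (c) detected in at least
    ``min_experiments`` bait experiments, and (d) at a median molar ratio
    to the bait of at least ``min_ratio``.  The bait (and its tag, if
    named) runs through the same filters but is flagged.
    """
    controls = list(control_labels)
    unknown = sorted(set(controls) - set(table.experiments))
    if unknown:
        raise ValueError(f"control labels not in table: {unknown}")
    bait_experiments = [e for e in table.experiments if e not in controls]
    if len(bait_experiments) < criteria.min_experiments:
        raise ValueError(
            f"need at least {criteria.min_experiments} bait experiments, got {len(bait_experiments)}"
        )
    if bait_id not in table.proteins:
        raise ValueError(f"bait {bait_id!r} absent from the table")
    if (table.counts.loc[bait_id, bait_experiments] == 0).any():
        missing = [e for e in bait_experiments if table.counts.loc[bait_id, e] == 0]
        raise ValueError(f"bait {bait_id!r} undetected in bait experiment(s): {missing}")

    ibaq = compute_ibaq(table, criteria.digest_min, criteria.digest_max)
    exclude = {bait_id} | ({tag_id} if tag_id else set()) if exclude_bait_from_median else set()
    norm = normalize_median(ibaq[bait_experiments], exclude=exclude)
    ratios = norm.div(norm.loc[bait_id], axis=1)

    calls: list[InteractorCall] = []
    for pid in table.proteins:
        if pid not in ibaq.index:
            continue  # zero theoretical peptides; warned in compute_ibaq
        reasons: list[str] = []
        if (table.counts.loc[pid, controls] > 0).any():
            reasons.append("control_present")
        total = int(table.counts.loc[pid, bait_experiments].sum())
        if total < criteria.min_peptides:
            reasons.append("low_peptides")
        detected = int((table.counts.loc[pid, bait_experiments] > 0).sum())
        if detected < criteria.min_experiments:
            reasons.append("inconsistent")
        # ratio over experiments where the protein was detected; undetected
        # replicates ("ND") do not drag the median down
        det_exps = [e for e in bait_experiments if table.counts.loc[pid, e] > 0]
        ratio = float(ratios.loc[pid, det_exps].median()) if det_exps else 0.0
        if ratio < criteria.min_ratio:
            reasons.append("low_ratio")
        calls.append(
            InteractorCall(
                protein_id=pid,
                called=not reasons,
                reasons=tuple(reasons),
                median_ratio_to_bait=ratio,
                total_peptides=total,
                n_experiments_detected=detected,
                normalized_abundance={e: float(norm.loc[pid, e]) for e in bait_experiments},
                is_bait=pid == bait_id or (tag_id is not None and pid == tag_id),
            )
        )
    return calls


def calls_to_tsv(calls: Iterable[InteractorCall]) -> str:
    """Serialise interactor calls as TSV with a header."""
    lines = ["protein_id\tcalled\tis_bait\ttotal_peptides\tn_experiments\tmedian_ratio_to_bait\treasons"]
    for c in calls:
        ratio = "nan" if math.isnan(c.median_ratio_to_bait) else f"{c.median_ratio_to_bait:.6g}"
        lines.append(
            f"{c.protein_id}\t{int(c.called)}\t{int(c.is_bait)}\t{c.total_peptides}\t"
            f"{c.n_experiments_detected}\t{ratio}\t{','.join(c.reasons)}"
        )
    return "\n".join(lines) + "\n"
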