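"""Deterministic synthetic fixtures with emitted ground truth.

The discovery pipeline was designed around cluster-scale inputs (a full
proteome × template-library search, dozens of genomes, an Orbitrap run).
None of that is needed to test the *logic*: each generator here emits a
small corpus with the same structure — planted signal separated from
decoys by construction — plus the truth table the tests score against.

Every generator is a pure function of (params, seed): the same seed
yields byte-identical output.

* :func:`simulate_reverse_db` — per-protein ranked template-hit documents
  with planted homologue families among decoys that each violate exactly
  one call criterion;
* :func:`simulate_genomes` — pseudo-proteomes carrying mutated copies of
  family seeds along a divergence gradient, with lineage-specific losses;
* :func:`simulate_pulldown` — replicate pulldown intensity tables with an
  overexpressed bait + tag, an equimolar planted complex, control-shared
  contaminants and sub-ratio specks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence as TSequence

import numpy as np
import pandas as pd

from .hhr_io import HitRecord, QueryMeta
from .interactors import PulldownTable
from .seqkit import Sequence, count_theoretical_peptides

__all__ = [
    "ReverseDbFixture",
    "GenomeFixture",
    "PulldownFixture",
    "simulate_reverse_db",
    "simulate_genomes",
    "simulate_pulldown",
    "SUBUNIT_FAMILIES",
]

#: the six-subunit membrane-coat complex the discovery pipeline targets
SUBUNIT_FAMILIES = ("TPLATE", "TSAUCER", "TCUP", "TSPOON", "TTRAY1", "TTRAY2")

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_DECOY_MODES = ("bad_rank", "low_prob", "short_span", "single_template", "precluded")


def _round6(x: float) -> float:
    # keep reals at the writer's printed precision so round-trips are exact
    return float(f"{x:.6g}")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _random_digestible(rng: np.random.Generator, length: int) -> str:
    """Random protein guaranteed >=1 theoretical tryptic peptide (6-30 aa)."""
    while True:
        s = _random_protein(rng, length)
        if count_theoretical_peptides(s, 6, 30) >= 1:
            return s


# ---------------------------------------------------------------------------
# reverse-db fixture
# ---------------------------------------------------------------------------

@dataclass
class ReverseDbFixture:
    """hhr corpus plus the truth needed to score recovery."""

    documents: list[tuple[QueryMeta, list[HitRecord]]]
    family_templates: Mapping[str, tuple[str, ...]]
    planted: Mapping[str, set[tuple[str, str]]]  # family -> {(species, protein_id)}
    decoy_modes: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def truth_json(self) -> dict:
        return {
            "family_templates": {f: list(t) for f, t in self.family_templates.items()},
            "planted": {f: sorted(map(list, s)) for f, s in self.planted.items()},
            "decoy_modes": {f"{sp}/{pid}": m for (sp, pid), m in self.decoy_modes.items()},
        }


def _filler_hits(
    rng: np.random.Generator,
    protein_id: str,
    species: str,
    start_rank: int,
    n: int,
    prefix: str,
) -> list[HitRecord]:
    hits = []
    for i in range(n):
        rank = start_rank + i
        hits.append(
            HitRecord(
                query_protein_id=protein_id,
                species=species,
                template_id=f"{prefix}{rank:02d}{rng.integers(0, 99):02d}_A",
                template_description=f"unrelated fold {rng.integers(0, 999)}",
                rank=rank,
                probability=_round6(float(rng.uniform(1.0, 40.0))),
                e_value=_round6(float(10.0 ** rng.uniform(-2, 2))),
                q_start=1,
                q_end=int(rng.integers(40, 90)),
                t_start=1,
                t_end=int(rng.integers(40, 90)),
            )
        )
    return hits


def simulate_reverse_db(
    n_species: int = 12,
    n_families: int = 4,
    templates_per_family: int = 3,
    n_decoys_per_species: int = 10,
    seed: int = 0,
) -> ReverseDbFixture:
    """Plant one homologue per (species, family) among criterion-violating decoys.

    Planted proteins hit >=2 of their family's query templates at rank 1-5
    with probability in (60, 99] and >=100 aligned residues, so the call
    rule (rank<10, probability>50, span>=100, repeats>=2) recovers exactly
    the planted set.  Each decoy violates exactly one criterion: rank >=10,
    probability <=50, span <100, a single supporting template, or rank >50
    (precluded before merging).
    """
    if min(n_species, templates_per_family, n_decoys_per_species) <= 0 or n_families < 0:
        raise ValueError("inconsistent generator parameters")
    if n_families > len(SUBUNIT_FAMILIES):
        raise ValueError(f"at most {len(SUBUNIT_FAMILIES)} families supported")
    rng = np.random.default_rng(seed)
    families = SUBUNIT_FAMILIES[:n_families]
    family_templates = {
        f: tuple(f"{1000 + 17 * i + j:04d}_{chr(ord('A') + j)}" for j in range(templates_per_family))
        for i, f in enumerate(families)
    }
    template_desc = {
        t: f"{f.lower()} adaptor-like subunit structure {k}"
        for f, ts in family_templates.items()
        for k, t in enumerate(ts)
    }

    documents: list[tuple[QueryMeta, list[HitRecord]]] = []
    planted: dict[str, set[tuple[str, str]]] = {f: set() for f in families}
    decoy_modes: dict[tuple[str, str], str] = {}

    for s in range(n_species):
        species = f"sp{s + 1:02d}"
        for f in families:
            pid = f"{species}_{f}_planted"
            n_support = int(rng.integers(2, templates_per_family + 1))
            hits = []
            for r, t in enumerate(family_templates[f][:n_support], start=1):
                span = int(rng.integers(100, 400))
                q_start = int(rng.integers(1, 50))
                hits.append(
                    HitRecord(
                        query_protein_id=pid,
                        species=species,
                        template_id=t,
                        template_description=template_desc[t],
                        rank=r,
                        probability=_round6(float(rng.uniform(60.01, 99.0))),
                        e_value=_round6(float(10.0 ** rng.uniform(-30, -8))),
                        q_start=q_start,
                        q_end=q_start + span - 1,
                        t_start=1,
                        t_end=span,
                    )
                )
            hits += _filler_hits(rng, pid, species, n_support + 1, 4, "7f")
            documents.append((QueryMeta(pid, species), hits))
            planted[f].add((species, pid))

        for d in range(n_decoys_per_species):
            pid = f"{species}_decoy{d:02d}"
            if not families:  # no planted signal at all: pure-noise documents
                documents.append((QueryMeta(pid, species), _filler_hits(rng, pid, species, 1, 6, "8f")))
                continue
            mode = _DECOY_MODES[d % len(_DECOY_MODES)]
            f = families[int(rng.integers(0, n_families))]
            t1, t2 = family_templates[f][0], family_templates[f][1]
            good_prob = lambda: _round6(float(rng.uniform(60.01, 99.0)))
            bad_prob = lambda: _round6(float(rng.uniform(5.0, 50.0)))
            good_span = lambda: int(rng.integers(100, 300))
            short_span = lambda: int(rng.integers(20, 100))

            def planted_hit(rank: int, t: str, prob: float, span: int) -> HitRecord:
                return HitRecord(
                    query_protein_id=pid,
                    species=species,
                    template_id=t,
                    template_description=template_desc[t],
                    rank=rank,
                    probability=prob,
                    e_value=_round6(float(10.0 ** rng.uniform(-12, -2))),
                    q_start=1,
                    q_end=span,
                    t_start=1,
                    t_end=span,
                )

            if mode == "bad_rank":
                hits = _filler_hits(rng, pid, species, 1, 10, "8f")
                hits.append(planted_hit(11, t1, good_prob(), good_span()))
                hits.append(planted_hit(12, t2, good_prob(), good_span()))
            elif mode == "low_prob":
                hits = [planted_hit(1, t1, bad_prob(), good_span()),
                        planted_hit(2, t2, bad_prob(), good_span())]
            elif mode == "short_span":
                hits = [planted_hit(1, t1, good_prob(), short_span()),
                        planted_hit(2, t2, good_prob(), short_span())]
            elif mode == "single_template":
                hits = [planted_hit(1, t1, good_prob(), good_span())]
                hits += _filler_hits(rng, pid, species, 2, 3, "8f")
            else:  # precluded: family hits only past the rank-50 bound
                hits = _filler_hits(rng, pid, species, 1, 50, "8f")
                hits.append(planted_hit(51, t1, good_prob(), good_span()))
                hits.append(planted_hit(52, t2, good_prob(), good_span()))
            documents.append((QueryMeta(pid, species), hits))
            decoy_modes[(species, pid)] = mode

    return ReverseDbFixture(
        documents=documents,
        family_templates=family_templates,
        planted=planted,
        decoy_modes=decoy_modes,
    )


# ---------------------------------------------------------------------------
# genome fixture
# ---------------------------------------------------------------------------

@dataclass
class GenomeFixture:
    """Pseudo-proteomes with planted orthologue families and losses."""

    references: Mapping[str, list[Sequence]]          # ref taxon -> proteome
    genomes: list[tuple[str, list[Sequence]]]         # queue order preserved
    seed_sets: Mapping[str, list[Sequence]]           # family -> reference members
    expected: Mapping[str, Mapping[str, str]]         # family -> ref taxon -> accession
    loss_pattern: set[tuple[str, str]]                # (taxon, family) cells with no member
    planted_ids: Mapping[tuple[str, str], str]        # (taxon, family) -> accession

    @property
    def taxa(self) -> list[str]:
        return [t for t, _ in self.genomes]

    def truth_json(self) -> dict:
        return {
            "taxa": self.taxa,
            "families": sorted(self.seed_sets),
            "loss_pattern": sorted(map(list, self.loss_pattern)),
            "planted": {f"{t}/{f}": pid for (t, f), pid in self.planted_ids.items()},
        }


def _mutate(rng: np.random.Generator, residues: str, fraction: float) -> str:
    arr = np.array(list(residues))
    n_mut = int(round(fraction * len(arr)))
    if n_mut == 0:
        return residues
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    for p in pos:
        choices = _AA[_AA != arr[p]]
        arr[p] = rng.choice(choices)
    return "".join(arr)


def simulate_genomes(
    n_taxa: int = 8,
    families: TSequence[str] = SUBUNIT_FAMILIES,
    member_length: int = 150,
    n_background: int = 12,
    step_divergence: float = 0.05,
    loss_pattern: set[tuple[str, str]] | None = None,
    reference_taxa: TSequence[str] = ("refA", "refB", "refC"),
    seed: int = 0,
) -> GenomeFixture:
    """Generate reference proteomes, seeds, and a divergence-gradient queue.

    Family members evolve along a chain: the member in genome *i+1* is a
    further-mutated copy of the member in genome *i* (``step_divergence``
    substitutions per step), so later genomes in the queue are
    progressively harder for the original seeds — the regime iterative
    seed incorporation is meant for.  Cells in ``loss_pattern`` receive no
    member at all.  By default a deterministic ~15% of cells are lost,
    sparing the first taxon (so at least one taxon keeps the full
    complement).
    """
    rng = np.random.default_rng(seed)
    families = tuple(families)
    taxa = [f"tx{i + 1:02d}" for i in range(n_taxa)]
    if loss_pattern is None:
        loss_pattern = set()
        for t in taxa[1:]:
            for f in families:
                if rng.random() < 0.15:
                    loss_pattern.add((t, f))
    bad = loss_pattern - {(t, f) for t in taxa for f in families}
    if bad:
        raise ValueError(f"loss pattern outside the taxa x families grid: {sorted(bad)}")

    ancestors = {f: _random_protein(rng, member_length) for f in families}

    references: dict[str, list[Sequence]] = {}
    seed_sets: dict[str, list[Sequence]] = {f: [] for f in families}
    expected: dict[str, dict[str, str]] = {f: {} for f in families}
    for k, ref in enumerate(reference_taxa):
        proteome = []
        for f in families:
            acc = f"{ref}_{f}"
            seq = Sequence(acc, _mutate(rng, ancestors[f], 0.05 * (k + 1)), f"{f} reference member")
            proteome.append(seq)
            seed_sets[f].append(seq)
            expected[f][ref] = acc
        for b in range(n_background):
            proteome.append(
                Sequence(f"{ref}_bg{b:02d}", _random_protein(rng, int(rng.integers(100, 200))))
            )
        references[ref] = proteome

    genomes: list[tuple[str, list[Sequence]]] = []
    planted_ids: dict[tuple[str, str], str] = {}
    current = dict(ancestors)
    for t in taxa:
        current = {f: _mutate(rng, current[f], step_divergence) for f in families}
        proteome = []
        for f in families:
            if (t, f) in loss_pattern:
                continue
            acc = f"{t}_{f}"
            proteome.append(Sequence(acc, current[f], f"{f} planted member"))
            planted_ids[(t, f)] = acc
        for b in range(n_background):
            proteome.append(
                Sequence(f"{t}_bg{b:02d}", _random_protein(rng, int(rng.integers(100, 200))))
            )
        genomes.append((t, proteome))

    return GenomeFixture(
        references=references,
        genomes=genomes,
        seed_sets=seed_sets,
        expected=expected,
        loss_pattern=loss_pattern,
        planted_ids=planted_ids,
    )


# ---------------------------------------------------------------------------
# pulldown fixture
# ---------------------------------------------------------------------------

_PARTNER_NAMES = ("TPLATE", "TSAUCER", "TCUP", "TTRAY1", "TTRAY2", "SECG", "VACA", "VACB")


@dataclass
class PulldownFixture:
    """Replicate pulldown tables with a planted specific-interactor set."""

    table: PulldownTable
    bait_id: str
    tag_id: str
    control_labels: list[str]
    planted_called: set[str]       # bait + tag + equimolar partners
    molar: Mapping[str, float]     # planted molar amount per protein (bait experiments)
    contaminants: set[str]
    specks: set[str]

    def truth_json(self) -> dict:
        return {
            "bait": self.bait_id,
            "tag": self.tag_id,
            "controls": self.control_labels,
            "called": sorted(self.planted_called),
            "molar": dict(sorted(self.molar.items())),
            "contaminants": sorted(self.contaminants),
            "specks": sorted(self.specks),
        }


def simulate_pulldown(
    n_partners: int = 8,
    bait_fold: float = 15.0,
    n_contaminants: int = 50,
    n_specks: int = 20,
    cv: float = 0.2,
    replicates: int = 5,
    n_controls: int = 2,
    intensity_scale: float = 1e9,
    seed: int = 0,
) -> PulldownFixture:
    """Emulate the AP-MS experiment the interactor caller is built for.

    Planted composition: a bait and its tag at ``bait_fold`` molar excess
    (overexpression), ``n_partners`` complex members log-normal around
    molar 1.0 with coefficient of variation ``cv``, contaminants present
    in the non-transformed controls as well, and "specks" at molar ratios
    to bait below 0.002 — so the default filter set calls exactly
    bait + tag + partners.
    """
    if replicates < 3:
        raise ValueError("need at least 3 replicate pulldowns")
    if n_partners < 1 or n_controls < 1:
        raise ValueError("need at least one partner and one control")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))

    bait_id, tag_id = "TSPOON", "GFP_tag"
    partners = [
        _PARTNER_NAMES[i] if i < len(_PARTNER_NAMES) else f"PARTNER_{i + 1:02d}"
        for i in range(n_partners)
    ]
    contaminants = [f"contam_{i + 1:03d}" for i in range(n_contaminants)]
    specks = [f"speck_{i + 1:03d}" for i in range(n_specks)]
    proteins = [bait_id, tag_id] + partners + contaminants + specks

    sequences = {
        pid: Sequence(pid, _random_digestible(rng, int(rng.integers(120, 300))))
        for pid in proteins
    }

    molar: dict[str, float] = {bait_id: bait_fold, tag_id: bait_fold}
    for p in partners:
        molar[p] = 1.0
    for c in contaminants:
        molar[c] = float(10.0 ** rng.uniform(-1.0, 0.7))
    for s in specks:
        # median ratio to bait in [1e-4, 1e-3], clear of the 0.002 cutoff
        molar[s] = bait_fold * float(10.0 ** rng.uniform(-4.0, -3.0))

    bait_experiments = [f"IP{r + 1}" for r in range(replicates)]
    control_labels = [f"ctrl{c + 1}" for c in range(n_controls)]
    columns = bait_experiments + control_labels
    counts = pd.DataFrame(0, index=proteins, columns=columns, dtype=int)
    intensities = pd.DataFrame(0.0, index=proteins, columns=columns)

    def detect(pid: str, exp: str, molar_amount: float, base_count: int) -> None:
        n_pep = count_theoretical_peptides(sequences[pid], 6, 30)
        noise = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
        intensities.loc[pid, exp] = molar_amount * n_pep * intensity_scale * noise
        counts.loc[pid, exp] = max(1, base_count + int(rng.integers(-2, 3)))

    for exp in bait_experiments:
        detect(bait_id, exp, molar[bait_id], 40)
        detect(tag_id, exp, molar[tag_id], 25)
        for p in partners:
            detect(p, exp, molar[p], 15)
        for c in contaminants:
            detect(c, exp, molar[c], 8)
        for s in specks:
            detect(s, exp, molar[s], 6)
    for exp in control_labels:
        for c in contaminants:
            detect(c, exp, molar[c], 8)

    table = PulldownTable(counts=counts, intensities=intensities, sequences=sequences)
    return PulldownFixture(
        table=table,
        bait_id=bait_id,
        tag_id=tag_id,
        control_labels=control_labels,
        planted_called={bait_id, tag_id, *partners},
        molar=molar,
        contaminants=set(contaminants),
        specks=set(specks),
    )
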