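# Methods

This note documents the procedures implemented in `strucfind`, the
reasoning behind the defaults, and what the synthetic fixtures do and do
not establish.

## Reverse structural-homology index

A profile-vs-structure search produces, per proteome protein, a ranked
list of template hits. The index inverts the direction of the question:
every hit of every per-protein report is stored as a row keyed by
template, so one can ask "which proteins, in which species, resemble this
solved structure?" The semantic core is the **result number** (rank): a
protein whose hit to template *T* has rank 1 resembles *T* more than any
other structure in the template library, which is strong evidence even
when the probability score alone is ambiguous.

Parsing keeps only the summary-table fields that feed the index (rank,
template id and description, probability, e-value, query and template
spans); pairwise alignment blocks are out of contract. Persistence is a
single SQLite file — the storage engine is incidental, the contract is
only that save → load reproduces the rows. Keyword queries are
case-insensitive substring matches over the template description only;
template-id lookup is a separate operation.

## Hit assimilation

Several solved structures exist per subunit family, so per-structure
result lists are merged:

1. rows with rank > 50 are discarded first (50 structures more similar
   than the query is treated as decisive evidence against homology);
2. duplicates are collapsed keeping the best-ranked hit — ties on rank are
   broken by higher probability, then lexicographic template id, making
   the merge fully deterministic and order-invariant;
3. `repeats` counts the distinct query structures contributing at least
   one surviving hit;
4. candidates are ordered by ascending best rank, then descending
   probability, then protein id.

A candidate is **called** iff best rank < 10 (strict), probability > 50%
(strict), aligned span ≥ 100 residues (inclusive), and repeats ≥ 2
(inclusive). The span is measured on the candidate-protein side of the
alignment (q_end − q_start + 1): the biological argument is about how much
of the *candidate* is covered by the fold, and the template-side extent
can differ when the template is a fragment. A looser display filter
(rank < 10 OR repeats > 2) is available separately; it selects what is
worth inspecting, not what is called real, and the two are deliberately
distinct operations.

All four thresholds are parameters (`CallCriteria`); the defaults are the
working values above and every CLI exposes overrides, with effective
values echoed into the run manifest.

## Orthology by reciprocal best hit, with iterative seed growth

For each gene family a seed set of known members (from reference genomes)
is searched against each target proteome in a user-defined queue order.
The top `top_n` (default 5) forward candidates are validated by the
reciprocal criterion: searching the candidate back into a reference
proteome must retrieve the known orthologue as the best hit, with

    margin = log10(E_next) − log10(E_best) ≥ 2

i.e. at least two orders of magnitude separation from the next best hit,
in at least one reference genome. The first candidate to pass is the
family's member in that genome and is appended to the seed set before the
next genome is searched (`incorporate=False` gives the static baseline).
Only RBH-validated sequences are ever incorporated; forward-search hits
that fail validation never contaminate the model.

Numerical choices:

- e-values of exactly 0 (numerical underflow in the backend) are floored
  at 1e-180 before taking log10, and the verdict is flagged
  `evalue_floored`; this keeps margin arithmetic finite without inventing
  precision.
- a single-hit reference list has no "next best hit"; the margin is
  treated as vacuously satisfied and flagged `single_hit`. The
  conservative alternative (`strict_single_hit=True`) rejects instead.
- the verdict provably depends only on the top two hits per reference
  list, and is invariant under multiplying a list's e-values by any
  positive constant (only the log-ratio enters). Both properties are
  tested against a brute-force reference.

### Search backends

The stage is written against a minimal contract — (queries, proteome) →
best-first scored hits — so externally produced BLAST tabular files, a
profile-HMM search, or the bundled scorer all plug in.

The bundled `NaiveBackend` scores each target by its best ungapped
diagonal segment (BLOSUM62) against the query set; when the queries are
aligned to equal length it scores against their position-averaged profile
instead, so sensitivity genuinely grows as members are incorporated. Raw
scores map to surrogate e-values through a Karlin–Altschul-shaped tail,
E = K·m·n·exp(−λS) with the classical ungapped BLOSUM62 constants
(λ = 0.3176, K = 0.134). The map is monotone in score, which is all the
downstream logic uses; the surrogate is *not* a calibrated significance
estimate and is documented as such. `PyhmmerBackend` provides a real
HMMER3 profile search when pyhmmer is installed.

Presence/absence verdicts across the full (family × taxon) grid assemble
into a `PresenceMatrix`; an incomplete grid is an error that lists the
missing cells. Taxa with the full complement are flagged (bold in the
Coulson-style plot).

## Interactor calling from AP-MS pulldowns

Per (protein, experiment), abundance is estimated by iBAQ: summed peptide
intensity divided by the protein's count of theoretical tryptic peptides.
The digest cleaves after K or R except before proline, with zero missed
cleavages, and counts peptides of 6–30 residues — the observable window of
the quantification method. Each experiment is then rescaled so the median
abundance of positive proteins is 1.0; the bait and its tag are excluded
from the median pool by default (their overexpression would otherwise
drag the reference level), but are still rescaled and reported. With an
even number of proteins the median is interpolated, so "median = 1.0"
holds to a unit in the last place rather than bit-exactly; tests compare
at machine precision.

A protein is called a specific interactor iff all four filters pass:

- **control_present** — any detection (≥ 1 peptide) in any control
  eliminates; the pipeline treats control contamination as disqualifying,
  not down-weighted. A fold-enrichment alternative is not provided.
- **low_peptides** — fewer than 5 peptides summed across bait
  experiments. Totals (rather than per-experiment uniques) were chosen
  because the detection-consistency clause below already handles
  per-experiment support; the threshold is configurable.
- **inconsistent** — detected in fewer than 3 independent bait
  experiments.
- **low_ratio** — median molar ratio to bait below 0.002. The median is
  taken over the experiments where the protein was detected, so a single
  dropout replicate (a "not detected" cell) does not halve the statistic.

Every uncalled protein carries the exhaustive list of filters it failed.
Calling is invariant to uniform per-experiment intensity rescaling
(normalisation and ratios are scale-free), and tightening any threshold
can only shrink the called set; both are tested.

## Synthetic fixtures: what they emulate, and what they do not

All three generators are pure functions of (params, seed) at the byte
level, and every generated file parses through the package's own I/O.

**Reverse-db fixture** (default 12 pseudo-species, 4 planted families,
3 query templates per family, 10 decoys per species): planted homologues
hit ≥ 2 of their family's templates at rank 1–5, probability in (60, 99],
span ≥ 100; each decoy violates exactly one criterion (rank ≥ 10,
probability ≤ 50, span < 100, single supporting template, or rank > 50 and
hence precluded). Separation is built in by construction, so
precision = recall = 1.0 at the default thresholds is a *logic* check —
it shows the criteria are implemented exactly, not that they would
separate hits this cleanly on a real proteome, where the rank and
probability distributions of true and false hits overlap.

**Genome fixture** (default 8 taxa, the six subunit families, 150-residue
members, 12 background proteins per proteome, 5% substitutions per step):
members evolve along a chain, so divergence from the reference seeds grows
down the queue (~34% substituted by the last taxon); ~15% of cells are
lost at random (first taxon spared). Substitution-only evolution (no
indels) keeps the seed set trivially aligned, which both backends exploit;
real families have indels, domain gains/losses and compositional biases
that this fixture does not model. At these divergences the static seed set
also recovers every surviving member, so the iterative-vs-static
comparison asserts "at least as many", the property the incorporation
step guarantees, rather than a strict improvement.

**Pulldown fixture** (default 8 partners at molar 1.0, bait + tag at
15-fold excess, 50 control-shared contaminants, 20 specks at molar ratios
1e-4–1e-3, CV 0.2 log-normal intensity noise, 5 replicate pulldowns,
2 controls): intensities are molar × theoretical-peptide-count × scale ×
noise, so iBAQ recovers molar ratios up to noise. The called set is
exactly the 10 planted proteins (bait, tag, 8 partners) — the same
cardinality structure as the motivating experiment. Peptide counts are
drawn independently of intensity rather than through a spectral model,
and replicate dropouts are not simulated by default.

Problem sizes were chosen so the full suite and the acceptance script
each run in well under a minute of CPU (the orthology stage, the most
expensive, is ~25 s for iterative + static across 48 cells); the
generators scale up by parameter if heavier stress runs are wanted.

## Global identity and the divergent-pair check

`global_identity` is a Needleman–Wunsch global alignment (Biopython's
`PairwiseAligner`) under BLOSUM62 with gap open 10 / extend 0.5 — a
conventional protein default, since the original comparison's parameters
are not recorded. Identity is identical residue pairs over the *full*
alignment length including gap columns: for highly divergent pairs the
gap-inclusive denominator is what yields the characteristically low
percentages (a matched-columns denominator would flatter them). The
implementation is checked against exhaustive enumeration of all global
alignments for short sequences. The check against the two real divergent
β-like subunits needs their sequences fetched from NCBI
(`scripts/fetch_reference_pair.py`) and allows ±1.5 percentage points for
the unrecorded alignment parameters.

## Known limitations

- The naive backend's e-values are surrogates: ordering and margins are
  meaningful, absolute significance is not. Real analyses should plug in
  BLAST tabular output or the pyhmmer backend.
- The hhr parser reads the dialect its writer emits (header + summary
  table); full HHsearch reports with alignment blocks are not in
  contract.
- tblastn-style searches of unannotated nucleotide scaffolds are out of
  scope; the orthology stage accepts externally produced tabular hits for
  such cases.
- Phylogenetic confirmation of orthology (tree building, model testing)
  is intentionally outside the package.
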