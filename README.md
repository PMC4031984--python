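# strucfind

Reverse structural-homology discovery for comparative genomics and
interaction proteomics.

Sequence-based searches routinely miss ancient protein families: after two
billion years of divergence, membrane-coat subunits in different eukaryotic
supergroups can share well under 20% sequence identity while keeping the
same fold. `strucfind` implements the desk side of a discovery pipeline
built around that problem, for researchers hunting distant members of known
complexes (adaptor/COPI-like coats being the motivating case):

1. **Reverse index** (`reverse_index`, `hhr_io`) — parse the per-protein
   ranked template-hit reports of a profile-vs-structure search (hhr
   dialect) for whole proteomes, and invert them into a template → proteins
   lookup, queryable by PDB template id or by keyword over template
   descriptions. Persisted as a single SQLite file.
2. **Hit assimilation** (`assimilation`) — merge the result lists obtained
   from several solved structures of the same family, discard anything with
   result number > 50, deduplicate keeping the best-ranked hit, count
   `repeats` (how many query structures recovered each protein), and call
   real hits by the four-criterion rule: result number < 10, probability
   > 50%, ≥ 100 aligned residues, repeats ≥ 2.
3. **Orthology validation** (`orthology`, `backends`) — confirm candidates
   by reciprocal best hit: a candidate is an orthologue if, searched back
   into at least one reference genome, it retrieves the known orthologue as
   the best hit with an e-value at least two orders of magnitude better
   than the next best hit (margin = log₁₀ E₂ − log₁₀ E₁ ≥ 2). Validated
   members are incorporated into the seed model before the next genome is
   searched. Verdicts assemble into a taxa × subunits presence/absence
   matrix (Coulson-plot input).
4. **Interactor calling** (`interactors`, `seqkit`) — score AP-MS pulldowns
   by iBAQ (summed peptide intensity / count of theoretical tryptic
   peptides of 6–30 residues), normalise each experiment to median 1.0, and
   call specific interactors: absent from every control, ≥ 5 peptides,
   detected in ≥ 3 independent experiments, median molar ratio to bait
   ≥ 0.002.

A deterministic fixture generator (`fixtures`) emulates all three input
regimes with planted ground truth, so the entire pipeline runs and is
tested without any external search program or download. `seqkit` also
provides Needleman–Wunsch global percent identity (BLOSUM62, gap open
10 / extend 0.5, gap-inclusive denominator) for quantifying divergence
between family members.

## Worked example

Simulate a reverse-search corpus (12 pseudo-species, 4 planted subunit
families among decoys), index it, and assimilate hits for the planted
families' query structures:

```sh
$ strucfind simulate reverse-db --seed 1 --out rdb
$ strucfind build-index --hhr-dir rdb/hhr --out idx.sqlite
2037 rows from 168 documents
$ python -c "import json; t=json.load(open('rdb/truth.json')); \
  print('\n'.join(t for ts in t['family_templates'].values() for t in ts))" > structures.txt
$ strucfind assimilate --index idx.sqlite --structures structures.txt --out candidates.tsv
48/144 candidates called
$ head -3 candidates.tsv
protein_id	species	best_rank	best_probability	span	repeats	supporting_templates	called
sp01_decoy03	sp01	1	97.6341	198	1	1034_A	0
sp01_TSAUCER_planted	sp01	1	97.505	135	2	1017_A,1018_B	1
```

144 merged candidates survive the rank-50 preclusion; exactly the 48
planted homologues (12 species × 4 families) pass the four-criterion rule.
Note the top decoy: rank 1 and 97.6% probability, but supported by a
single structure (`repeats` 1), so it is not called — the repeats
criterion is what separates it from the planted hit below it.

The index is also queryable directly:

```sh
$ strucfind query --index idx.sqlite --keyword tsaucer | head -2
species	protein_id	template_id	rank	probability	e_value	q_start	q_end	description
sp01	sp01_TSAUCER_planted	1017_A	1	97.505	8.81817e-15	49	183	tsaucer adaptor-like subunit structure 0
```

The orthology and interactor stages run the same way (`strucfind orthology`,
`strucfind interactors`), or all together on fixtures via
`strucfind run --out outdir --seed 1`, which writes `candidates.tsv`,
`presence.csv`, `interactors.tsv` and a run manifest. In the default
pulldown fixture the interactor caller reports exactly 10 specific
proteins: the bait and its tag (at ~15-fold molar excess, mirroring
overexpression) plus the 8 equimolar planted partners.

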