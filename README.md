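# methylgate

A toolkit for annotating eukaryotic cytosine methylomes and relating
methylation to gene ancestry and gene-family evolution. It covers the
full analysis path from per-cytosine methylation calls to:

- **Context-aware methylation arithmetic** — CGmap ingestion, weighted
  (read-count pooled) levels per dinucleotide/trinucleotide context,
  spike-in conversion QC (unmethylated lambda-like and methylated
  pUC19-like controls), CpG-dyad symmetry, and deepTools-style
  metaprofiles over scaled feature bodies.
- **Gene/TE methylation classification** — per-feature weighted levels,
  automatic threshold selection from the bimodal level distribution
  (histogram valley cross-validated by deterministic 1-D k-means, k = 2),
  and methylated/unmethylated/undetermined calls.
- **Hypermethylated-region calling** — 500 bp sliding windows with 250 bp
  step, >10% level filter, merge into maximal regions.
- **TE age profiling** — Kimura 2-parameter divergence from family
  consensus with a CpG-modified transition weighting (divCpGMod-style),
  and methylation-by-age-bin tables.
- **Lateral-gene-transfer enrichment** — superkingdom-level ancestry
  categories from best-hit tables (self-genus hits discarded, 10 best
  kept), two-sided Fisher exact tests of category enrichment in the
  methylated fraction, and greedy chaining of viral-ancestry genes into
  candidate endogenized-virus neighborhoods.
- **Dollo parsimony** — single-gain/minimum-loss ancestral gene-family
  repertoires from a species tree plus presence/absence matrix
  (three-state input with a "potential presence" toggle).
- **Synthetic data** — a fully ground-truthed methylome bundle generator
  (genome, GFF3, CGmap, hit tables, TE alignments, spike-ins, truth
  tables) and random gain/loss phyletic profiles, so every stage is
  testable offline with known answers.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks the
implementation against independent oracles: a quadratic brute-force
region caller, exact-integer hypergeometric enumeration for Fisher
p-values, exhaustive ancestral-state minimisation for Dollo, closed-form
K2P evaluation, and parameter recovery on seeded synthetic bundles.

## CLI

Every stage is exposed under one entry point:

```sh
methylgate simulate --seed 1 --out bundle/
methylgate qc --cgmap bundle/calls.cgmap
methylgate levels --cgmap bundle/calls.cgmap --exclude-contig lambda --exclude-contig pUC19
methylgate classify --cgmap bundle/calls.cgmap --features bundle/features.gff3 \
    --context-mode cg --threshold auto --out classes.tsv --report threshold.json
methylgate hmr --cgmap bundle/calls.cgmap --genome-lengths lengths.tsv \
    --out-bed hmr.bed --out-tsv hmr.tsv
methylgate metaprofile --cgmap bundle/calls.cgmap --features bundle/features.gff3 --out profile.tsv
methylgate teage --align bundle/te_alignments.align --out ages.tsv
methylgate lgt --hits bundle/hits.tsv --classification classes.tsv \
    --features bundle/features.gff3 --self-genus Selfia \
    --out-calls calls.tsv --out-enrichment enrichment.tsv --out-neighborhoods geve.bed
methylgate dollo --tree species.nwk --matrix presence.tsv --out dollo.tsv
methylgate convert --cgmap bundle/calls.cgmap --to bedgraph --out track.bedgraph
```

## Conventions

- All coordinates are 0-based half-open internally; CGmap (1-based) and
  GFF3 (1-based closed) are converted at the I/O boundary.
- Methylation levels are always read-count-weighted (sum methylated /
  sum total), never means of per-site fractions.
- The CGmap level column is never trusted; levels are recomputed from
  counts.
- Hit-table taxonomy strings are ordered rank labels, superkingdom
  first, genus last, separated by semicolons.
- TE alignments use a plain-text pairwise dialect documented in
  `methylgate/te_age.py`.
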