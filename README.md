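# pparpipe

Analysis pipeline for recurrent somatic mutations of the PPARγ/RXRα axis
in bladder cancer cohorts: cross-cohort mutation harmonization and
recurrence (hotspot) calling, a gene-expression–based PPARγ activation
score, exact-test enrichment statistics, and mapping of mutated residues
onto heterodimer structures. A seeded synthetic-data layer emulates the
tumor cohorts so every stage runs and is tested without any external
download.

## The problem

Luminal bladder tumors depend on an activated PPARγ/RXRα transcriptional
program. Alongside *PPARG* amplification and the RXRα S427F/Y hotspot,
rare activating point mutations of PPARγ itself (e.g. T475M in the
ligand-binding domain) recur across cohorts at a rate of a few percent.
Detecting them requires care on three fronts that this package automates:

1. **Numbering frames.** PPARγ2 is 28 residues longer than PPARγ1 at the
   N terminus, so the same physical substitution carries two labels
   (T447M in γ1 = T475M in γ2). All mutations are renumbered into one
   frame before aggregation; changes lying in the γ2-specific extension
   (E3K, D7N) are flagged isoform-specific rather than silently shifted.
2. **Recurrence across sources.** A change is *recurrent* when seen ≥ 2
   times — within the sequenced cohorts alone, or pooling occurrences
   reported in public databases (COSMIC/cBioPortal-style tables), which
   is what promotes singleton cohort observations to hotspots.
3. **Subgroup statistics.** Associations (mutation vs activation-high
   subgroup, mutation vs amplification) are tested with a self-contained
   two-sided Fisher exact test: exhaustive hypergeometric enumeration in
   exact integer arithmetic, summing all tables with the observed margins
   whose point probability does not exceed the observed one.

The **PPARγ activation score** of a tumor is the mean of the centered
(per gene, across samples) log expression of a refined signature gene
set. The seed signature is refined by a quartile contrast: genes must be
significantly more expressed in the 25% of tumors with the highest
*PPARG* expression than in the bottom 25% (one-sided Wilcoxon rank-sum,
Benjamini–Hochberg FDR ≤ 0.05).

Structural queries use minimum heavy-atom distances: a residue sits at
the dimer interface when it comes within 5 Å of the partner chain, and
intra-chain contact partners are residues within 4.5 Å at sequence
separation ≥ 3.

## Worked example

The numbered scripts under `analysis/` run the chain on synthetic data:

```bash
python analysis/01_simulate_cohort.py --seed 1   # cohort + expression + structure
python analysis/02_call_recurrence.py            # narrative fixture recurrence
python analysis/03_score_activation.py           # refine + score + classify
python analysis/04_test_enrichment.py            # Fisher exact tests
python analysis/05_map_structure.py              # interface mapping
```

Output of steps 2–4 (seed 1):

```
21 unique PPARG changes
recurrent within cohorts: 6
recurrent with database pooling: 8 (E3K, P113S, R164W, R168K, S249L, M280I, I290M, T475M)
retained 10 of 20 seed genes (10/10 planted genes recovered)
184 of 359 samples classified activation-high
mutation vs activation-high: OR=17.7 p=0.00011 (co_occurrence)
amplification vs activation-high: OR=1.09 p=0.878 (co_occurrence)
mutation vs amplification: OR=0.782 p=1 (exclusivity)
```

Reading: the miniature narrative cohort holds 21 distinct PPARγ changes
of which six are recurrent on cohort evidence alone; pooling database
occurrences promotes E3K and M280I, giving eight hotspots. On the
simulated 359-tumor cohort the signature refinement recovers all ten
planted signature genes and rejects all decoys, and mutations — planted
with an alteration–subgroup odds ratio of 8 — come out strongly enriched
in activation-high tumors, while amplifications (planted independently)
do not, and mutations and amplifications are not mutually exclusive.

The same chain is available as one orchestrated command with provenance
(config hash, per-stage log, byte-reproducible outputs):

```bash
pparpipe run --config run.yaml --seed 7 --out out/
```

plus `pparpipe recur|score|enrich|interface|simdata` for the individual
stages (see `--help`).

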