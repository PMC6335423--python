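# Methods

This note documents the models, conventions, and design choices behind
each stage of the pipeline, what the synthetic-data layer does and does
not emulate, and the numerical details a user changing defaults should
know.

## Mutation catalog

**Coordinates.** All positions are 1-based inclusive protein residue
indices, matching mutation labels such as `T475M`. No 0-based indexing is
exposed anywhere.

**Isoform harmonization.** Renumbering between isoform frames is an
affine map (`IsoformMap`): PPARγ1 → PPARγ2 adds +28, the length of the
γ2-specific N-terminal extension. A position that would land below the
first residue of the target frame is returned as an explicit
`UnmappableChange` marker, never clamped: E3K and D7N exist only in the
γ2 frame. Harmonizing with offset +k then −k is the identity wherever
both directions are defined (property-tested).

**Deduplication and counting.** Repeated reports of the same
(sample, gene, change) count once. External-database occurrences are
counted per reported entry because database records lack stable sample
identity; this is why pooling is a separate, explicit switch
(`pool_external`) whose effect on each record is recorded in
`recurrence_basis` (`cohort_only` vs `pooled`).

**Recurrence threshold.** `min_count = 2` by default: a change is
recurrent when observed at least twice. Whether the two observations
must come from distinct cohorts is deliberately not required — two
samples anywhere suffice — and the threshold is configurable.

**Domain boundaries.** The ligand-binding domain is fixed to residues
231–505 (γ2 frame), the span of the bacterially expressed LBD construct.
The A/B (N-terminal) domain (1–136) and DNA-binding domain (137–206)
boundaries follow standard nuclear-receptor annotation renumbered into
the γ2 frame; they live in configuration and can be overridden. Positions
between domains annotate as `linker`. Landmarks (S112, S273 phosphosites)
are carried for plotting.

**Multi-allele labels.** `S427F/Y` expands into two `ProteinChange`
records that aggregate separately. The RXRα hotspot appears in the
literature under two numbering frames (S242 and S427); the package never
reconciles such labels silently — supply an `IsoformMap` if both occur.

## Exact association tests

The two-sided Fisher exact p-value is computed by full hypergeometric
enumeration in exact integer arithmetic: every admissible table with the
observed margins has unnormalized weight C(r1, k)·C(r2, c1−k); the
p-value sums the weights not exceeding the observed one (point-probability
two-sided convention, the one used by standard implementations), over the
common normalizer C(n, c1). A relative tie tolerance of 1e−7 is applied
in integer form, so results are deterministic and free of float
round-off. The test suite checks this implementation against an
independent rational-arithmetic oracle exhaustively for n ≤ 14 and
against `scipy.stats.fisher_exact` for every table with n ≤ 40.

Degenerate tables (an all-zero row or column) return p = 1 with a flag.
Odds ratios are the raw cross-product (a·d)/(b·c); zero cells produce 0
or an infinity flag, never a Haldane-style continuity correction, because
the associations of interest are reported as raw exact-test results.

**Type-I-error calibration.** Fisher's exact test is conservative for
sparse tables, so its rejection rate approaches the nominal level only
when cell counts are large. The calibration simulation therefore uses a
balanced design — 400 samples, both margins at rate 0.5, odds ratio 1,
1000 replicates — where the empirical rate at α = 0.05 lands near 0.045.
With a rare alteration (a few percent, as in the cohorts) the same test
rejects at well under the nominal rate; that conservatism is a property
of the exact test, not an implementation artifact.

**Percent rounding.** Frequencies print as percentages rounded half-up
to one decimal (14/359 → 3.9, 14/455 → 3.1). Published reports sometimes
round inconsistently (6/338 appearing as 1.7 rather than 1.8); a single
fixed rule is used here and regression-tested.

## Activation score

**Refinement.** Samples are ranked by the anchor gene's expression
(*PPARG*), ties broken by sample identifier; the top and bottom
⌈q·n⌉ samples (q = 0.25 by default) are contrasted per seed gene with a
one-sided Wilcoxon rank-sum test (greater in the anchor-high bin) under
Benjamini–Hochberg FDR at α = 0.05. The choice of a rank test is
deliberate — it is robust to the expression scale — and a Welch t
alternative is selectable for sensitivity analysis (`test="welch"`).
Seed genes missing from the matrix are excluded and recorded in the
returned `SignatureDefinition`; every refinement parameter travels with
the result as provenance.

**Scoring.** Per gene, the across-sample center (mean by default, median
optional) is subtracted; a sample's score is the mean of the centered
values over the refined genes. With gene-mean centering the scores sum
to zero exactly (up to accumulation error), and the score is invariant
to adding any per-gene constant — both property-tested.

**Classification.** The activation-high threshold is not a published
constant; the default rule is score > 0, with top-quartile and fixed
cutoff rules selectable, and the rule used recorded in output.

**Scope.** The literal published 77-gene signature cannot be reproduced
here: it requires the TCGA expression matrix and the prior 148-gene list,
neither of which ships with the package. The refinement procedure is the
deliverable; on synthetic data it attains ≥95% sensitivity and ≤5% FDR
at a +2 SD planted effect (n = 200, 20 seeds), degrading smoothly to the
α-level false-positive rate at zero effect.

## Structure mapping

PDB files are parsed with Bio.PDB into a minimal coordinate container
(chains → residues → heavy atoms). Hydrogens and waters are dropped at
load; HETATM ligands are kept in a separate namespace excluded from
residue distance queries; disordered atoms resolve to the highest
occupancy altloc (tie → 'A'); insertion codes are appended to residue
keys. NMR-style multi-model files are addressed by model index.

Distance conventions: residue–residue distance is the minimum over heavy
atom pairs; interface membership at cutoff 5.0 Å; intra-chain contacts at
4.5 Å with sequence separation ≥ 3 to suppress backbone neighbors. The
published co-localization claims are qualitative, so these cutoffs are
explicit configuration with standard defaults, not inferred values. All
operations are checked against a brute-force all-pairs oracle and are
invariant under rigid-body transforms to 1e−6 Å.

Mutations mapped onto a structure whose construct does not cover their
position (e.g. anything outside an LBD-only 231–505 construct) are
flagged `unresolved`, never dropped.

## Synthetic data

The generators reproduce the *statistical structure* the analysis
assumes, not the biology of real cohorts:

- **Cohorts** (`CohortSimSpec`): default 359 samples with the observed
  NMIBC/MIBC split, mutation rate 14/359 ≈ 3.9%, amplification rate 12%,
  and an alteration–subgroup odds ratio of 8 concentrating mutations in
  the activation-high (luminal-like) half. The two Bernoulli rates
  inside/outside the subgroup are solved from (overall rate, odds ratio,
  subgroup fraction): with subgroup fraction f, f·p1 + (1−f)·p0 = overall
  and odds(p1)/odds(p0) = OR, a monotone one-dimensional root problem.
  Recurrent changes receive exactly their target counts among altered
  samples; remaining altered samples get unique background changes.
- **Expression** (`ExpressionSimSpec`): i.i.d. normal log-scale baseline
  (σ = 1), +2 σ added to 10 signature genes in the activation-high 25%
  of 200 samples, anchor gene coupled at +3 σ. No library-size,
  count-distribution, or gene–gene correlation structure is simulated —
  so passing tests demonstrate correctness of the procedure under its
  own model, not performance on RNA-seq data.
- **Toy structures**: two ideal poly-alanine helices (rise 1.5 Å, twist
  100°/residue, 5 heavy atoms per residue), the second translated so the
  minimum inter-chain distance equals the requested gap (solved by root
  finding); the truth interface is computed by brute force at
  construction. Real packing, side-chain diversity, and disorder are not
  modeled.

Every generator is deterministic given (spec, seed) and returns a truth
record sufficient to score recovery, power, and type-I error downstream.

A deterministic miniature fixture (`bladder_narrative_variants`) encodes
the published mutation narrative exactly: 21 unique changes, six
recurrent on cohort evidence (T475M most frequent at 4), E3K and M280I
promoted to recurrent only by external-database pooling — eight hotspots
in total.

## Orchestration and reproducibility

`pparpipe run` executes cohort → recurrence → score → oncoprint →
enrichment → structure in order from one YAML config; a single master
seed drives all randomness (stage-specific seeds are derived as seed+1,
seed+2 to decouple streams). The summary JSON carries a SHA-256 hash of
the canonical config serialization; wall-times are excluded from
persisted outputs so identical configs give byte-identical output trees.
Stages without inputs (no expression matrix configured) are reported
`skipped` rather than failing, mirroring cohorts without transcriptomic
data. Single-command CLI entry points wrap each stage; the `analysis/`
scripts are the same calls in narrative order.

## Problem sizes

Defaults were chosen at desk scale: cohorts of a few hundred samples,
expression matrices of ~500 × 200, 1000-replicate null calibrations, and
toy structures of ≤ 200 atoms. These sizes put Monte-Carlo error well
inside the asserted tolerances while keeping any full run in seconds.

## Known limitations

- Protein-level substitutions only: no DNA-level calls, VCF ingestion,
  HGVS cDNA parsing, indels, or fusions.
- External-database occurrences arrive as user-supplied tables; there is
  no live COSMIC/cBioPortal querying.
- No multiple-testing correction across association tests (raw exact
  p-values, as in the motivating analyses) and no logistic modeling.
- Expression input is assumed already log-scale and normalized.
- The wet-lab arms of the underlying biology (reporter assays, binding
  constants, crystallographic refinement, molecular dynamics) are out of
  scope; structural statements here are purely geometric.
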