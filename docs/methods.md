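# Methods

This note records the models, conventions and numerical choices behind
`panelclassify`, and what the synthetic validation does and does not show.

## Variant representation

All comparisons key on the minimal anchored representation of
`(chrom, pos, ref, alt)`: shared trailing bases are trimmed first, then
shared leading bases with the position advanced, always keeping one anchor
base when either allele would become empty. Trailing-before-leading
matters: for `CTT→CT` both orders terminate, but only trailing-first yields
the conventional left-anchored deletion `(pos, CT, C)`; the property tests
therefore check membership in the set of reachable fully-trimmed forms and
pin the discipline on explicit examples. Normalization is idempotent.
Multi-allelic records are split into one call per ALT allele *before*
normalization, with per-allele alt depths taken from the ordered AD field —
callers disagree on multi-allelic encoding, and splitting makes keys
comparable across callers. Positions are 1-based internally; BED input is
converted from 0-based half-open.

## Consensus model

The ensemble vote is a pure counting rule: a variant is reported iff
supported by at least `min_support` callers of its class (default 3 of the
5 SNV callers; 3 of the 6 indel-capable callers, treating Scalpel as an
equal member of the indel set). Only calls passing each caller's own FILTER
column count as support by default (`count_nonpass_calls` relaxes this).
No machine-learning re-scoring of the ensemble is attempted; the vote is
the model.

The consensus VAF/depths are the per-field **median** across supporting
callers — robust to one outlier caller — with even counts averaging the two
middle values and depths rounded half-up back to integers. A
`primary_caller` mode returns one caller's fields verbatim instead. The
aggregated VAF always lies within the supporters' range.

## Filtering and classification

Thresholds (all configurable, defaults in parentheses): limit of detection
VAF (0.05, inclusive), minimum alt reads (12, inclusive), maximum
population AF (0.01, strict — an AF of exactly 0.01 is kept). The
population maximum ranges over every (database, subpopulation) entry
present plus the local population database; absence is represented as
missing, never zero, so "not in gnomAD" can never masquerade as "AF 0".
Whether the local database participates in the population filter as well as
in classification is a switch (`local_db_in_pop_filter`, default on); the
two roles are conceptually distinct and laboratories differ here.

Classification is a **decision list**: rules state minimal positive
conditions and rely on order for exclusions, so the order is a real degree
of freedom (configurable via `rule_order`; e.g. swapping R4/R5 flips the
label of a dbSNP-known variant inside a germline band). The default order
encodes an evidence hierarchy:

| rule | condition | category |
|---|---|---|
| R1 | ClinVar germline assertion or local-database presence | germline |
| R2 | COSMIC-recurrent, absent from dbSNP and all population DBs | somatic |
| R3 | COSMIC-recurrent, VAF outside the germline bands | putative somatic |
| R4 | dbSNP/population-DB presence, VAF inside a band | putative germline |
| R5 | dbSNP/population-DB presence (VAF off-band after R4) | putative somatic |
| R6 | no database evidence: split on VAF band | putative novel germline / somatic |

A ClinVar label asserts a germline condition when it contains any of the
configured marker substrings (default: `"germline"`). COSMIC recurrence
requires `cosmic_count ≥ 1` by default. The germline VAF bands
[0.40, 0.60] and [0.90, 1.00] are the heterozygous/homozygous expectations
for tumor-only data; they are a package choice — copy-number change and
tumor purity shift real germline VAFs, which is why the band-dependent
categories are "putative". Filtering precedes classification; every
assignment records the ordered trail of rules consulted.

The germline arm applies site-level hard filters per class (SNP: QD < 2,
FS > 60, MQ < 40, MQRankSum < −12.5, ReadPosRankSum < −8; indel: QD < 2,
FS > 200, ReadPosRankSum < −20; both: QUAL < 30), with absent metrics never
counting as violations.

## QC definitions

Region coverage fractions use the **mean depth per target region**; the
pass rules are ≥ 300× in ≥ 80% of regions (somatic) and ≥ 200× in ≥ 80%
(germline), boundaries inclusive. Uniformity is the fraction of target
bases at or above 0.2× the mean target depth — a widespread panel
convention chosen here because the metric's exact formula varies between
vendors; the 0.2 factor is configurable, the value is scale-invariant and
defined as 0 for an all-zero profile. Read-level metrics (raw reads,
filtered fraction, duplication rate, on-target reads) are ingested from
upstream tool summaries, not recomputed from alignments, which are out of
scope.

## Biomarker matching

The knowledge base is a static TSV; duplicate (gene, protein-change, drug)
rows collapse to the highest evidence tier on load. Exact protein-change
rules are tried first; gene-level rules apply to any protein-affecting
consequence (everything except `synonymous`/`other`). At most one hit per
(variant occurrence, drug) survives, at the highest supporting tier. Only
somatic-family variants are eligible by default. A rule's tumor types are
reported with the hit but never suppress it — indication filtering is the
consumer's decision. Percentages in reports use half-up rounding to match
clinical-report formatting conventions.

The packaged knowledge-base fixtures transcribe published panel tables with
two conventions: per-drug evidence tiers follow the printed row order where
a row block lists several drugs and tiers, and the guideline-level table is
encoded entirely at the `fda_guidelines` tier because the source does not
distinguish its FDA from its NCCN rows; letter grades in the gene-level
table map A→fda_guidelines, B→clinical_guidelines, C→late_trials. TP53 is
absent from the gene-level KB (its association is prognostic, not a drug).

## Synthetic cohort model

The generator starts at caller-output level — no reads or alignments. Per
truth variant: sequencing depth ~ Poisson(mean depth, default 500), alt
count ~ Binomial(depth, true VAF), one realization shared by all callers
(they see the same library). Each caller then detects the variant
independently with probability `logistic(slope·(VAF − midpoint))`
(midpoints 0.015–0.03, slope 200 — synthetic knobs, not estimates of any
real caller), or a flat `detect_prob` override.

Default study conditions: 8 samples × (10 germline het + 3 germline hom +
12 somatic + 4 FFPE artifacts) = 232 truth variants; somatic VAFs cycle the
grid {0.01, 0.02, 0.05, 0.10, 0.25, 0.50}; ~20% of somatic variants are
single-base indels; germline het/hom VAFs are uniform in their bands.
FFPE artifacts are C>T or G>A with true VAF uniform in [0.005, 0.025] —
the deamination regime, kept well below the 0.05 LOD so that at 500× depth
the binomial tail above the LOD is negligible (~3 × 10⁻⁴ per variant) and
the "no artifact survives" property holds across seeds. Database profiles
default to the unambiguous mapping somatic→COSMIC-only,
germline→local-database (with a ClinVar germline label), artifact→novel,
making classification of detected variants exact by construction;
`pvd_rare`/`pvd_common` profiles exercise the band-dependent and
filtered-out paths.

What passing these tests shows — and does not. The synthetic model
validates the *logic*: voting thresholds, boundary semantics, rule order,
category bookkeeping, determinism. It does not emulate caller-correlated
errors, strand bias, mapping artifacts, tumor purity or copy number, so
perfect recovery here is a statement about the implementation, not about
clinical sensitivity. The expected-vs-observed VAF correlation of the
13-variant reference-standard-like ladder (r > 0.95 at 500×) follows from
binomial counting noise shrinking with depth.

`recovery_metrics` defines sensitivities conditionally on detectability:
the denominator is the set of truth variants of that family that survived
consensus and filtering (appear in the classified output). The realized —
not the true — VAF decides survival, so the metric measures the classifier
rather than sampling noise; unconditional recovery is readable off the
confusion table, whose rows include an `absent` column and sum to the
truth counts.

## Numerical and interface choices

* VAFs written to VCF are formatted at 6 significant digits and re-read at
  the same precision (htslib stores Float fields in single precision);
  TSV output uses full `repr` precision and round-trips exactly.
* Consensus output order is deterministic (sample, chrom, pos, ref, alt);
  pipeline outputs contain no timestamps, and the run manifest lists
  SHA-256 checksums so replicate runs can be compared byte-for-byte.
* The BED reader merges overlapping or touching intervals with a
  sort-and-sweep, verified against a per-base set oracle.
* Degenerate inputs are errors, not silent defaults: empty depth vectors,
  empty aggregation sets, zero-variance correlation inputs, unknown tiers,
  effects, modes and rule ids all raise.
* A sample failing QC is reported in the QC table but excluded from
  classification; the cohort run continues (per-sample, not per-cohort,
  gating).

## Problem sizes

The default test-suite and acceptance problem sizes — 8-sample cohorts
(~230 truth variants), 100 target regions, 13-variant VAF ladders, and
exhaustive 2⁵/2⁶ voting patterns — were chosen as the smallest sizes at
which every rule, boundary and family is exercised with comfortable
statistical margins; everything runs in seconds on one CPU.

## Known limitations

* The classifier consumes annotation as given; it does not re-annotate,
  and CADD-style pathogenicity scores are carried but unused by the
  default rules.
* Tumor mutational burden, fusions and copy-number events are out of
  scope.
* The decision list treats database evidence as boolean presence plus a
  COSMIC count threshold; it does not weigh allele-frequency magnitude
  below the polymorphism cutoff.
* Caller detection in the simulator is independent across callers;
  correlated failure modes (shared alignment artifacts) are not modelled.
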