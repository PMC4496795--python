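# Methods

This note documents the statistical model behind `regrewire`, the choices
made where the design was genuinely open, and what the synthetic data do and
do not establish about real cohorts.

## The analysis model

**Network model.** A gene regulatory network (GRN) is a directed graph whose
regulators are transcription factors (TFs) or miRNAs and whose targets are
TFs, miRNAs or genes. Self-loops are removed at load time. Each directed
edge carries one of four classes: `TFout` (unidirectional TF → target),
`miRout` (unidirectional miRNA → target), `BiTT` (mutual TF–TF regulation)
and `BiTM` (mutual TF–miRNA regulation, i.e. a feedback loop). Both directed
edges of a reciprocal pair share the bidirectional class and are represented
by a canonical pair key (lexicographically smaller id first) wherever
pair-level statistics are computed. A reciprocal miRNA–miRNA pair falls
outside this taxonomy (both bidirectional classes require a TF); each of its
directed edges is kept as `miRout` with a warning. An unreciprocated
TF → miRNA or TF → TF edge is `TFout`: "unidirectional TF to target" is read
as covering every non-reciprocal TF edge regardless of target kind.

**Co-expression score.** For each regulation, Spearman's ρ (average ranks
for ties) is computed over the samples of one cohort and condition present
in both relevant expression matrices, matched by exact sample id. Because
cohorts differ in depth, ρ is variance-stabilized and standardized:

    z = arctanh(ρ) · sqrt(n − 3)

with n the matched-sample count. |ρ| is clamped to 1 − 1e−7 before
`arctanh` so perfect correlations stay finite (ranking is preserved; clamped
records are flagged). Edges with n < 4 are excluded (the minimal requirement
for the transform), as are edges with a constant value vector. A regulation
with |z| ≥ 2.5 (boundary inclusive) is *significantly correlated*; "top k%"
networks retain the ⌈kN⌉ records with largest |z|, ranking by |z| rather
than |ρ| because standardization is precisely the correction for unequal
sample counts (with constant n the orders coincide). Ties at the cut are
broken by (|z| descending, pair key ascending) so selection is
deterministic. Reciprocal pairs are scored once — Spearman correlation is
symmetric — so one feedback loop contributes one record.

**Sign activity.** A positive correlation is read as evidence of activation,
a negative one of repression (z = 0 counts as positive; this occurs with
probability zero for continuous data and the convention is stated rather
than load-bearing). Per class, the counts of positive and negative records
in a top-k network are tested for over-representation of each sign against
the 100% network of the same scoring run, by one-sided Fisher's exact tests
at α = 0.05 with no multiplicity correction (each bar is reported on its
own).

**Rewiring.** Two condition-specific networks built under the same selection
rule are compared by (i) Jaccard overlap of interactors (nodes touching a
retained regulation) and of interactions (retained regulations) — Jaccard is
used because it is symmetric and bounded, and the qualitative contrast
(interactor overlap exceeding interaction overlap) does not depend on the
denominator convention; (ii) a two-sided Wilcoxon rank-sum test comparing
the per-cohort interactor and interaction fractions (exact enumeration for
combined sample size ≤ 12, normal approximation with tie correction above);
and (iii) per-edge rewiring classes: every regulation in the symmetric
difference is typed by how many of its endpoints remain interactors in the
other condition's network — 2 → type I, 1 → type II, 0 → type III — with
direction *lost* (normal-only) or *gained* (tumor-only). Types partition
the symmetric difference by construction. Gained and lost edges are pooled
in summary tables and the split is also reported.

**Differential co-expression.** For every regulation scored in both
conditions, D = |z_N − z_T|. Absolute difference makes D a nonnegative
ranking score invariant under exchanging conditions. Eligibility requires
significance (|z| ≥ 2.5) in *at least one* condition: requiring both would
discard exactly the gained/lost regulations the analysis is after. The top
10% of D values (ceiling rule, deterministic tie-break) are flagged DC
(differentially co-expressed). Feedback (BiTM) pairs with a D value in
every cohort are ranked by mean D across cohorts; pairs covered in only
some cohorts are reported separately but not ranked, mirroring the
requirement of consistency across all studied cancer types.

**Cancer association.** A regulation is cancer-associated when at least one
endpoint appears in the supplied cancer-gene or cancer-miRNA list. BiTM
pairs additionally carry a category — CN (only the TF annotated), NC (only
the miRNA), CC (both), NN (neither). Enrichment of cancer-associated
regulations among DC regulations versus the rest of the background, and of
each category among DC BiTM pairs versus background BiTM pairs, is assessed
by one-sided Fisher's exact tests (over- and under-representation reported
separately). The per-category background is the category's share among
non-DC BiTM pairs of the same scoring run; this construction is the
implemented choice where a convention had to be fixed.

**Target modules.** The activated target-gene set of a regulator consists of
tumor-condition targets with z > 2.5 (one-sided, positive) that are also
up-regulated in tumors. Up-regulation is decided by a deliberately
self-contained substitute for count-model DE callers: log2(x+1) mean fold
change combined with an exact/asymptotic Wilcoxon rank-sum p (α = 0.05,
direction by fold-change sign). Being rank-based, the p-value is invariant
under monotone transforms, so the test is insensitive to the abundance
scale; it does not model count dispersion, which is out of scope here.
Gene-set enrichment of the module is a one-sided hypergeometric test per
GMT set (sets intersected with the universe first), with Benjamini–Hochberg
q-values reported alongside raw p; decisions mirror raw p at α = 0.05.
Per-cohort p-values are combined with Fisher's method, −2·Σ ln p ~ χ² with
2k degrees of freedom.

**Drug signatures.** The amplitude of a treatment/control signature is
a = 2(t − c)/(|t| + |c|), bounded in [−2, 2], antisymmetric and scale
invariant; t = 2c > 0 gives a = 2/3 ≈ 0.67, the two-fold point. The
classification cutoff is applied literally and strictly: a > 0.67 → up,
a < −0.67 → down, otherwise neutral; a is undefined at t = c = 0 and such
signatures are dropped with a log record. Each input row is one signature;
an optional per-drug collapse keeps the row of largest |a| for data sets
with several instances per drug. The subnetwork is the bipartite graph of
up/down drugs and their deduplicated gene interactions, annotated with
regulation class, target status and ATC class, exported as GraphML or SIF.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `z_thresh` | 2.5 | significance cutoff on the standardized score (≈ one-sided normal P < 0.01); the score itself is used, never converted to a p-value |
| `top_ks` | 0.05, 0.10, 0.15, 0.20 | fractions defining the top correlated networks compared between conditions |
| `dc_fraction` | 0.10 | share of D(z) values flagged differentially co-expressed |
| `amplitude_cutoff` | 0.67 | two-fold amplitude threshold for up/down drug signatures (strict) |
| `de_alpha` | 0.05 | significance level of the differential-expression substitute |

All randomness in a pipeline run flows from a single seed through named
substreams per stage, so stochastic outputs are reproducible
byte-for-byte.

## The synthetic-data generator

The generator emulates a matched tumor/normal multi-cohort study: seven
cohorts of 60 normal + 60 tumor samples by default, a typed network of
about 250 directed edges (15 TFs, 15 miRNAs, 150 genes; 120 TFout, 100
miRout, 8 BiTT and 7 BiTM pairs), miRNA sample ids overlapping mRNA sample
ids at fraction 0.8 per condition, and per-class planted Spearman
correlations (TFout 0.4, miRout −0.3, BiTT 0.5, BiTM 0.4, equal in both
conditions unless an effect is planted). These defaults are the desk-scale
study conditions: large enough for the selection and ranking rules to have
realistic granularity, small enough that a full run takes seconds.
Regulator out-degrees follow preferential attachment (weight = out-degree
+ 1), giving the heavy-tailed degree distributions regulatory networks
show.

Correlations are planted on latent Gaussians with Pearson parameter
2·sin(π·ρ_S/6), so the planted *Spearman* value equals the requested one;
values are exp(7 + latent), a monotone map that preserves ranks and puts
values on a positive abundance-like scale (log-normal, median ≈ 1100).
Tumor shifts are added on the latent scale in log2 units. Targets of a
shared regulator share one latent factor, so sibling targets carry residual
correlation r₁·r₂; a feature targeted by several planted edges keeps its
first planting and later plantings are recorded as conflicts in the truth
record (conflicted edges end up approximately uncorrelated). Every edge,
shift, planted loop and module has a truth entry.

The planted feedback loop (the analysis's positive control) sets one BiTM
pair to ρ_N = 0, ρ_T = 0.8 in every cohort, shifts the TF up by 1 log2 unit
in tumors, and gives the TF a block of 12 module targets with ρ_T = 0.7 and
a 1 log2-unit tumor shift, collected in a `planted_module` gene set among
random decoys. Annotation fixtures label nodes cancer-associated at a
configurable fraction (default 0.2), force the planted-loop endpoints when
requested, and include drug signatures covering up, down, neutral, exact
two-fold boundary and undefined cases plus an interaction list with a
planted duplicate.

**What passing on synthetic data does and does not show.** The generator
uses clean log-normal values with exact planted rank correlations; it has
no count noise (negative-binomial dispersion), batch effects, missing
values or identifier ambiguity. Recovery of the planted loop therefore
demonstrates the correctness and calibration of the scoring, selection and
ranking machinery under the stated effect sizes — not robustness to
real-data artifacts, which upstream normalization and harmonization must
handle.

## Numerical choices and degenerate inputs

- |ρ| = 1 → clamped before `arctanh` (flagged); n < 4 → excluded with
  reason `n_lt_4`; constant vectors → excluded with `constant_values`;
  features absent from their modality's matrix → `feature_missing` (edges
  are skipped and logged, never a hard error; an empty cohort/condition is
  a hard error).
- All top-k and DC selections use the ceiling rule with deterministic
  tie-breaks; `k = 1` retains everything and equals a zero threshold.
- The exact Wilcoxon branch enumerates all label assignments of the pooled
  average ranks (valid with ties) for combined n ≤ 12; above that, the
  normal approximation with tie correction is used.
- Empty networks report overlap 0 with a warning; a class absent from a top
  network yields a zero-count row with p = 1; a BiTM ranking with no fully
  covered pair is empty with a warning.
- Fisher's combined method requires p ∈ (0, 1]; zero or empty inputs are
  errors rather than silently clipped.

## Known limitations

- Sample matching is by exact sample id; patient-level matching across
  modalities is left to upstream sample-sheet preparation.
- Expression values are used as given (no internal normalization); only the
  DE substitute applies a log2(x+1) transform internally.
- The DE substitute is rank-based and will be conservative relative to
  count-model callers at very small n.
- Class proportions and pair-level statistics count each feedback loop
  once (pair-level convention, documented here); directed-edge counts are
  recoverable from the network tables.
- Multi-condition (> 2) designs, partial correlation and other
  co-expression measures, GO DAG logic and ATC ontology logic are out of
  scope.
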