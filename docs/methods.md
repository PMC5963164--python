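# Methods

## Model and rationale

The analysis treats post-transcriptional regulation as a directed bipartite
graph from microRNAs to target genes and asks which microRNAs control the
network's *vulnerable* structure. A gene of in-degree 1 (a "single-line
regulation") has no compensating co-regulator, so alterations of its one
incoming edge propagate unbuffered; transcription-factor (TF) genes amplify
such perturbations downstream. Three per-microRNA measurements capture
this: NSR (count of in-degree-1 targets), TFP (fraction of targets that are
TFs) and UTP (fraction of in-degree-1 targets that are TFs; defined as 0
when there is no in-degree-1 target, so the step-3 condition "UTP > 0"
cleanly excludes microRNAs without unique targets). A microRNA passes the
screen when its NSR is significantly high in the network (step 1), its TFP
is significantly high (step 2, evaluated among step-1 survivors but against
the full network population — step 1 only restricts who may advance), and
it uniquely regulates at least one TF (step 3).

Key assumptions: the input interaction corpus is trustworthy at the level
of its evidence tags; expression matrices are already normalized and on
log2 scale; the two sample groups are independent (no pairing, no
covariates); and the condition-specific network is simply the induced
subgraph of the reference on the differentially expressed features.

## Differential expression

The moderated two-sample t shrinks each feature's pooled variance s²_g
(d_g = n_A + n_B − 2 residual df) toward a prior s₀² with weight d₀:
s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g); t_g = Δmean / (s̃_g √(1/n_A + 1/n_B))
is referred to a t distribution on d₀ + d_g df. When not supplied, (d₀, s₀²)
are estimated by the method of moments on z_g = log s²_g under the scaled-F
hierarchical model: the empirical variance of z in excess of the mean of
trigamma(d_g/2) determines d₀ through a Newton inversion of the trigamma
function (asymptotic starting point 0.5 + 1/x, relative tolerance 1e-10);
non-positive excess yields d₀ = ∞, i.e. one shared variance. d₀ = 0
recovers the ordinary pooled t (`--stat plain`). The test suite verifies
agreement with the Bioconductor reference implementation of this estimator
to ~1e-8 relative on a shared fixture.

Conventions: group A is the reference condition and group B the contrast
(in the motivating prostate-cancer design, A = primary, B = metastatic);
log₂FC = mean_B − mean_A, so positive values mean up-regulation in B. DE
calls use strict inequalities (adj.p < α, |log₂FC| > lfc_cut; defaults
α = 0.05, lfc_cut = 1.0 log2 units). Missing values: a feature is tested on
its non-missing samples and excluded (logged) when fewer than 2 remain in
either group — exclusion is the conservative reading. Probe sets are
collapsed to genes before FDR adjustment by keeping each gene's smallest
raw p (ties: larger |t|, then lexicographically smaller probe id).

## Network integration

A (microRNA, gene) pair enters the reference network iff it has at least
one low-throughput experimental record, or predictions from at least
`min_predicted_support` (default 2) *distinct* prediction databases.
High-throughput experimental evidence alone never qualifies a pair — such
screens carry a high false-positive rate — but is retained as annotation.
MicroRNA names are normalized against an alias table (canonical names must
be fixed points; unmappable records are dropped with a report) before
integration, so records from corpora using different nomenclature releases
merge correctly. Gene symbols are upper-cased at ingest. Node sets are
derived from edges, so no isolated nodes can exist by construction. An
experimental pair contradicted by predictions receives no special
treatment.

## Significance of "high" scores

The source method names a one-sided Wilcoxon signed-rank test (p < 0.05)
without stating what is paired against what; this is genuinely
underdetermined, so the package implements two constructions behind one
`method` switch:

* **`empirical` (default)** — the empirical tail p-value
  p_i = #{j : score_j ≥ score_i}/n. p < α selects scores above the
  network's own (1 − α) quantile; identical scores share one p, so a
  constant score vector yields nothing.
* **`signed_rank`** — for each microRNA the differences
  {score_i − score_j : j ≠ i}, zeros removed (Wilcoxon's original zero
  treatment, matching mainstream libraries), enter a one-sample signed-rank
  test of "median > 0". For n ≤ 25 the null is computed *exactly* by a
  dynamic program over doubled (hence integral) average ranks — equivalent
  to enumerating all 2ⁿ sign vectors, ties handled exactly; beyond that a
  normal approximation with tie-corrected variance
  (−Σ(t³ − t)/48) and a 0.5 continuity correction is used. All differences
  zero is signalled as a distinct error.

The signed-rank construction is the literal reading but behaves like an
above-the-bulk detector in large populations: with hundreds of microRNAs,
beating the low-score mass dominates the rank sum and roughly two-fifths of
the network tests "significantly high", which is inconsistent with the
selectivity the three-step screen is meant to have. The tail rule gives the
filter its intended sharpness and is therefore the default; the signed-rank
route remains available and fully tested (including exact-enumeration
oracles) for users who want the literal pairing.

## Evaluation

Per-candidate AUC is computed through the Mann–Whitney identity
U/(n_pos·n_neg) with midrank tie handling; the ROC curve itself is the
standard grouped-threshold step construction, and its trapezoidal area
equals the Mann–Whitney AUC to ~1e-12 (asserted in tests). Because
down-regulated markers separate groups with *low* expression, each
candidate's score is oriented by the sign of its discovery-set log₂FC
before the sweep, and the flip is recorded — no validation labels are
consulted. Prediction precision is |candidates ∩ reported| / |candidates|;
it is undefined (distinct error) for an empty candidate set.

## Synthetic data

`simulate_network` emulates the gross topology of curated microRNA-target
corpora: microRNA out-degree propensities follow a truncated power law
(exponent 2.0, cap n_gene/8) rescaled to a requested mean (default 79
targets per microRNA — the scale of a ~600-microRNA × ~9,500-gene corpus
with ~49,000 pairs); a requested fraction of genes (default 0.25) receives
in-degree exactly 1 and the rest in-degree ≥ 2 (gene-side regulator draws
without replacement, so the realized single-line fraction tracks the
request within ±2% for n_gene ≥ 1,000); TF labels (default 10% of genes,
roughly the human TF share) are assigned uniformly. Planted microRNAs are
drawn from the 60th–92nd degree percentile band and rewired — never given
new nodes, so their degrees stay comparable to the background — to carry
min(deg, max(25, deg/3)) single-line targets of which 40% are TFs, and a
35% TF share over all targets; TF relabelling is compensated elsewhere so
the global TF fraction is preserved. These magnitudes place plants an order
of magnitude above the background NSR median and ~3.5× the background TF
fraction — the separation regime in which published candidates sit —
and, importantly, above the NSR range that high-degree hubs reach by
topology alone. All randomness flows from one integer seed; a seed
reproduces the dataset bit-exactly.

`simulate_expression` draws i.i.d. Normal(μ₀ = 8, σ²) log2 values with
additive group-B shifts for a chosen effect map. What the generator does
*not* emulate: platform-specific noise, probe-level artifacts,
normalization residue, correlated expression between co-regulated genes,
non-uniform TF placement, and evidence heterogeneity (synthetic edges carry
a single low-throughput tag). Passing tests therefore demonstrate
correctness of the algorithms and calibration under the stated model, not
robustness to real-data pathologies.

## Problem sizes and numerical choices

The recovery study runs 100 replicates at 600 × 9,000 with 3 planted
microRNAs (~10 s per 30 replicates on one CPU); calibration uses 10,000
null features and a 200-sample null AUC. Score invariants (tfp·n_targets
and utp·nsr integral) are enforced at 1e-9; round-trip IO is bit-exact for
strings/integers and 1e-12 relative for floats (17-significant-digit
serialization). Degenerate inputs are first-class: all-zero variances,
empty networks, empty candidate sets and all-zero rank differences raise
typed errors rather than returning numbers.

## Limitations

Gene importance is binary (TF / non-TF); no weighting by pathway position
or essentiality. No multi-factor or paired designs. The reference-corpus
integration consumes pre-exported TSV tables — no live database access —
and published corpus-level counts are version-dependent and not
reproduced here. The choice of significance construction materially changes
the screen's selectivity (see above); both options are exposed precisely
because the original pairing is not recoverable from its description.
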