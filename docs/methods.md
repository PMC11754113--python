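# Methods

This note documents the statistical models, default parameters and design
choices behind `tcellcircuits`, and what the synthetic-data generators do
and do not emulate.

## Coordinates and formats

All genomic coordinates are 0-based half-open throughout (BED/bedGraph
native); any 1-based input must be converted at the boundary.  Gene models
are accepted as BED12 only — the pausing computation needs only the TSS,
exon structure and strand.  Count tables are strictly integer; normalized
matrices are separate in-memory objects and are never written back as
"counts".

## Sorted-bin screen model

A sort-and-sequence screen compares sgRNA abundance between FACS bins
(top/bottom 20% of cells by surface marker, the `sort_fraction` default).
Guide effect: per (condition, donor),
`lfc = log2((low_cpm + α)/(high_cpm + α))` with per-million normalization
within each sample and pseudocount α = 0.5 inside the ratio.  The sign
convention is fixed by the sorting: a knockout that lowers the marker sends
cells to the low bin, so positive `lfc` marks a positive regulator.  A
guide absent from both bins scores exactly log2(α/α) = 0.

Gene test: the statistic is the median of a gene's guide lfc values pooled
across donors.  The null re-assigns guide identities at random with control
guides in the pool; for a gene with k guides the null is the median over k
randomly drawn guides.  Two-sided Monte-Carlo p-values use the add-one
correction (1 + hits)/(1 + n_perm) so p is never 0; when C(n, k) is small
(≤ 50,000 by default) every subset is enumerated and p is the exact null
fraction — the observed assignment is always among the enumerated ones, so
exact p-values are also never 0.  BH correction runs across genes within
each condition; hits are FDR < 0.05.  Donors are pooled for the statistic
(the screens are analysed jointly across donors); per-donor columns remain
available in `GuideEffects`.

Cross-condition classification: *consistent* = significant everywhere with
one direction; *differential* = significant in ≥ 2 conditions with opposing
directions (this takes precedence even when a gene is significant in all
conditions with a 2-vs-1 direction split); *context_specific* = significant
somewhere but not everywhere, never opposing; *non_hit* otherwise.  The
context-dependent percentage is 100·(hits − consistent)/hits.

## Activation signature and score

The signature comes from non-targeting (NT) control cells of one cell
type.  Normalization is depth scaling to 10,000 counts per cell followed by
log1p — deterministic and dependency-light; the score is a ratio statistic
and robust to this choice.  The stim-vs-rest log2FC is computed from
exponentiated means, log2((mean expm1 + 1)stim / (mean expm1 + 1)rest).
Genes enter the signature when |log2FC| is strictly greater than 0.25 and
the gene is detected (raw count > 0) in at least 10% of stimulated or
resting NT cells.  Per-gene rank-sum p-values are reported in the signature
table for reference but are not an additional filter.  GM is the mean
normalized expression over all NT cells of the cell type; genes with
GM ≤ 10⁻⁸ are dropped and logged.  The per-cell score is
S = Σ_g GE·GW/GM; an all-zero cell scores 0, and scaling GE and GM by a
common constant leaves S unchanged.

Per-target testing uses the two-sided Wilcoxon rank-sum test with
continuity-corrected normal approximation against NT cells within each
condition, Bonferroni-corrected across targets within the condition, with
significance at adjusted P < 0.01 (the adjusted threshold interpretation).
The default floor is 10 cells per target per condition.

## Pseudobulk NB differential expression

Cells are summed to raw counts per (target, donor, condition) unit, with
units under 10 cells dropped and reported.  Size factors are
median-of-ratios over genes positive in every sample.  Each gene gets a
negative-binomial log-linear model with intercept, group and donor terms
fitted by IRLS (log link, size-factor offsets, small ridge for stability).
Dispersion: a first pass at fixed moderate dispersion yields fitted means;
the per-gene method-of-moments estimate from those residuals is shrunk
toward a lowess mean–dispersion trend with four pseudo-degrees of freedom
of prior weight and floored at a tenth of the trend.  The shrinkage matters:
small designs (two groups × three donors leaves two residual degrees of
freedom) make unshrunk moment estimates so noisy that the Wald test becomes
anticonservative.  The group coefficient is tested with a normal Wald
statistic, BH-corrected across tested genes; all-zero genes are excluded
and reported.  No log-fold-change shrinkage is applied, and exact parity
with external DE packages is not claimed (one test cross-checks estimates
against an independent NB GLM implementation).

The NB maximum-likelihood fit is not exactly invariant to rescaling the
counts of a single sample — a deeper sample legitimately carries more
likelihood weight — so "size factors absorb depth" holds exactly only in
the Poisson limit (`dispersion=0`) and approximately otherwise.

Network construction: with per-target DE tables restricted to the perturbed
regulator set, an edge A → B exists when B's adjusted p < 0.05 in the DE of
perturbation A.  The stored regulation sign is the negation of the DE sign:
B falling upon knockdown of A means A promotes B.  Self-edges are allowed
and flagged.  Node roles come from the activation tests: knockdown raising
the activation score at rest marks a rest-maintenance factor; lowering it
when stimulated marks an activation-promoting factor.

## Bulk stimulation-response statistics

The response catalog uses strict thresholds (adj P < 0.05 and
|log2FC| > 1); boundary values are `ns`.  Category comparisons are Welch
t-tests of each responsive group's knockout log2FCs against the
non-responsive group, Bonferroni-corrected over the comparisons performed
(two per condition).  The binomial aberrance test is one-sided (excess) by
default with the null proportion p₀ equal to the fraction of
stimulation-responsive genes among all catalogued genes; the sidedness flag
is exposed because the choice is a judgment call.  Regulator enrichment is
a one-sided Fisher exact test within the universe of screen-library genes
detected in bulk RNA-seq.  The CAR activation signature filter applies
three strict inequalities: adj P < 0.01, log2FC > 2, baseMean > 10.
"Expressed" is base mean > 10 throughout, shared with the pausing filter.

## Chromatin analyses

Spike-in scaling divides track values by
s = (ChIP_primary/ChIP_spike)/(input_primary/input_spike): a sample whose
primary-genome ChIP signal exceeds what its input predicts is down-scaled.
The direction (divide rather than multiply) is a package choice, recorded
in output metadata and trivially invertible.

The peak caller is a simplified Poisson local-λ model standing in for a
full fragment-based caller.  Window signal is converted to a read-like
count by depth-matching both tracks to a common effective total
(200,000 reads by default; the read length cancels), so uniform rescaling
of both tracks leaves calls unchanged — the cost is that absolute
significance depends on the effective depth, which is therefore a stated
parameter.  λ is the maximum of the background count in the window itself,
local background means over 1/5/10 kb, and the genome-wide rate; the
window-level term implements the knockout-background "high-confidence"
logic (signal retained in the background masks the call, and a treatment
track tested against itself yields nothing).  Windows are BH-corrected and
adjacent significant windows merged.

Region segmentation takes the union of all input peaks and splits each
merged interval left-to-right into chunks of ≤ 5,000 bp; the output covers
exactly the union.  Differential regions reuse the NB Wald model on
region × sample counts, and each region is annotated with the gene whose
TSS is nearest its midpoint; equidistant ties resolve to the
lexicographically first symbol and are flagged.  An optional BED blacklist
mask can be applied before matrix construction.

Pausing index: PI = (TSS cov/TSS len)/(body cov/body len) from base-pair
coverage (Σ value × overlap).  Plus strand: TSS window [tss−200, tss+200),
body [tss+400, final_exon_end+400); minus strand is the mirror with the
terminal exon boundary on the left.  Genes with zero body coverage or
non-positive window lengths are flagged as undefined, never reported as 0.
PI is invariant to uniform track rescaling.

## Assays

Absolute proliferating responder counts are bead-normalized:
count × beads_input/beads_observed.  Percent suppression is
(1 − count/responder_only) × 100, the conventional 0–100% form; the
dimensionally inconsistent variant (100 − ratio) × 100 sometimes seen in
print is available behind `literal_formula=True` for auditability only.
MFI effects are log2(knockout/control).

## Synthetic data: what it emulates, what it does not

The screen generator works at the cell level: each cell draws a latent
phenotype Normal(β_gene, 1), bins are rank cutoffs at the sort fraction,
and per-bin guide compositions are sequenced to depth with gamma-weighted
multinomial (NB-like) noise.  Sorting is simulated rather than injecting
fold changes directly so the bin-ratio estimator is exercised end-to-end.
Defaults mirror the study design: 20% bins, 4 guides per gene, donors 3/3/2
across the T_eff-rest, T_eff-stim and T_reg-rest conditions.

The perturbation generator emits an AnnData of NB counts with per-donor
library-size effects; stimulated cells express program genes at
2^stim_lfc × baseline, and each target applies a per-condition multiplier
to program-gene expression.  The bulk generator uses the study's 3-donor
knockout design with planted stimulation-responsive genes and knockout
effects.  The coverage generator places reads so each gene's TSS/body
density ratio hits the configured pausing index in expectation and routes
2.5% of reads to a separate spike-in contig, matching dual-genome
alignment semantics by contig membership.

Not emulated: ambient RNA, doublets, UMI collisions, cell-cycle structure,
guide-efficiency variation, chromatin fragment-size distributions, or
mapping artifacts.  Passing tests therefore demonstrate correctness of the
estimators under the stated stochastic models, not robustness to every
artifact of real data.

A single global seed expands into named substreams via
`SeedSequence(seed, spawn_key=crc32(component))`, so each component's
stream is reproducible independently of call order.

## Problem sizes and numerical choices

The test and acceptance runs use deliberately compact designs chosen to
exercise every code path with stable statistics: screens of 40–80 genes ×
4 guides (100–500 cells per guide), perturbation pools of ~60 genes and a
few hundred cells per condition, bulk designs of 100 genes × 3 donors, and
coverage tracks of ~10⁵ reads over 6–8 toy genes.  Monte-Carlo permutation
counts are 1,000–5,000 with exact enumeration on small instances.
Convergence: IRLS runs to a 10⁻¹⁰ step tolerance with a 10⁻⁸ ridge;
coefficients are clipped at ±30 on the natural-log scale; Poisson tails use
the regularized incomplete gamma so non-integer depth-matched counts are
handled continuously.  Ties in the permutation test use ≥ comparisons with
a 10⁻¹² tolerance.

## Known limitations

- The permutation gene test is exchangeable across guides; guide-quality
  structure (some guides systematically inert) is not modelled.
- The NB Wald test relies on asymptotic normality; with two residual
  degrees of freedom its raw p-values are approximate even after dispersion
  shrinkage (calibration is verified on the adjusted scale).
- The peak caller scores fixed windows, so peak boundaries are quantized to
  the window size.
- Activation-signature derivation assumes NT cells are a clean baseline;
  contamination of the NT pool is not modelled.
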