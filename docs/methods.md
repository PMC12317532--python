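# Methods

This note documents the models implemented in `epimark`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## Data model and preprocessing

Inputs are a probe manifest (CSV; 1-based Illumina coordinates), a
normalized β matrix with optional detection-P matrix (probes ×
samples), a sample sheet, and optionally an expression matrix and a
clock-coefficient CSV. IDAT parsing and within-array normalization
(functional normalization, background/dye-bias correction) are out of
scope: the pipeline starts from normalized β.

β ↔ M conversion is the logit2 transform with β clipped to
[ε, 1−ε], ε = 10⁻⁶ (configurable), keeping M finite at the extremes.
M values are used for testing (variance-stabilized); β for effect
sizes and all sample-level indices, as is conventional for arrays.

Probe filtering applies five criteria in a fixed order, attributing
each removed probe to the first criterion it fails: (1) detection
P ≥ 0.01 in at least one sample, (2) cross-reactive flag, (3) sex
chromosomes, (4) non-CpG probes, (5) SNP-masked flag. Manifest flag
columns default to absent-flag (False) when missing, with one
exception: `is_cpg` defaults to True, since a manifest that does not
annotate probe type is in practice all-CpG and a False default would
empty the array.

Quantile normalization is the plain across-sample variant: each
column is mapped onto the mean of the per-column order statistics,
ties receiving the mean of their target quantiles via mid-rank
interpolation. The probe-type-stratified variant used by array
packages is deliberately not reproduced; this is documented as a
simplification appropriate for normal–normal comparisons.

## Differential methylation

Per probe, ordinary least squares of M on a design with intercept,
tumor/normal indicator, centered age, and a binary colon-location
indicator (proximal/distal; for FAP-style cohorts the analogous
rectum vs descending/sigmoid split). Covariates that are constant in
the analyzed samples are dropped with a warning. The model is
unpaired (age and location as covariates); tumor–normal pairing
exists in the sample sheet but is not used as a blocking factor,
matching the covariate model the study describes.

Variance moderation follows the standard empirical-Bayes scheme: the
residual variances s² are modeled as scaled inverse-χ² draws around a
prior (d₀, s₀²) estimated by moment matching of log s² — the excess of
var(log s²) over trigamma(d/2) is inverted through the trigamma
function (Newton iteration, relative tolerance 1e-8, ≤ 50 steps).
When the excess is non-positive or d₀ exceeds 10⁶, the prior df is
reported as infinite and s₀² is the arithmetic mean of the variances
(the fully pooled limit, matching the convention of the established
R implementation, against which the whole path is frozen-oracle
tested to 1e-9). The moderated t uses s̃² = (d₀s₀² + d s²)/(d₀+d)
with d₀+d degrees of freedom (normal reference when infinite); d₀ = 0
reproduces the ordinary t exactly. Probes with zero residual variance
take s₀² and are flagged.

DMPs require BH-adjusted P < 0.01 (computed from M values over all
tested probes) **and** |Δβ| > threshold, where Δβ is the
covariate-unadjusted difference of group mean β (tumor − normal).
The threshold is 0.10 for low-grade and normal–normal contrasts and
0.15 for high-grade/carcinoma contrasts. A raw-P option mirrors
low-power sensitivity analyses. Stratification counts DMPs by CGI
relation (a partition) and by gene region, where a probe annotated to
k regions contributes to each (documented multi-counting);
unannotated probes count as intergenic.

## Regions and promoter enrichment

DMR calling is a transparent seed-and-merge scheme, not a port of the
kernel-smoothing region caller: probes with raw p < 0.01 are
clustered per chromosome while consecutive seeds lie ≤ λ = 1000 bp
apart; clusters with ≥ 2 CpGs are scored by the signed Stouffer sum
of member p-values (sign from Δβ), BH-adjusted over candidates, and
kept when adjusted p < 0.05 and |mean Δβ| > 0.10/0.15 (0.08 for
sensitive runs). The kernel scale parameter C = 2 of the reference
tool has no analogue in this scheme and is recorded but unused; exact
boundary parity with that tool is a non-goal — the validated property
is recovery of planted clusters (probe-set Jaccard ≥ 0.8).

Promoter enrichment is rank-list GSEA: probes ranked by descending
M-value log2 fold change (ties by probe id), weighted KS running sum
with weight |score| (exponent 1), ES at the extremum, leading edge =
member probes at or before a positive extremum (at or after a
negative one). The null permutes set membership (random same-size
probe sets), not phenotypes, with an independent substream per gene
(derived from the seed and a CRC-32 of the gene name), so results are
invariant to evaluation order. NES divides ES by the mean |null ES|
of matching sign; p = (1 + #{as-or-more-extreme same-sign nulls}) /
(1 + #same-sign nulls); BH across genes; sets with < 5 CpGs present
in the list (3 for sensitive runs) are excluded before testing.

## Biomarker scores

LINE-1 index: mean β over probes flagged as mapping to evolutionarily
young LINE-1 elements. The flag is a manifest input; the genomic
intersection with repeat annotations is out of scope, so values are
relative to the supplied list. Hypermethylation index: mean β over
probes hypermethylated in *every* supplied tumor contrast that lie in
a CGI and in ≥ 1 promoter region (5′UTR/TSS200/TSS1500/1stExon).
CIMP: positive iff ≥ 3 of 5 panel-gene statuses are hypermethylated
(any five supplied statuses; the panel identity is the caller's).
MSI: MSI iff ≥ 1 of BAT25/BAT26 unstable. TMB: mutation count /
6.4 Mb; hypermutated strictly above 10/Mb — a count of exactly 64 on
the default panel is **not** hypermutated. Group analyses:
Kruskal–Wallis per score, all pairwise Wilcoxon BH-adjusted within
the pair family, and Spearman correlations for (LINE-1, hypermeth),
(TMB, LINE-1), (TMB, hypermeth).

## DNAm age

The clock is linear in β with the adult-calibrated transform
(adult age 20 by default): F(age) = log((age+1)/21) for age ≤ 20,
(age−20)/21 above; its inverse maps the predictor back to years.
Published clock coefficients are **not** bundled (they load from a
user CSV with an `(Intercept)` row); all tests use synthetic clocks so
the package builds offline. Missing clock probes are handled per
policy: `strict` errors, `warn` (default) drops terms and requires
≥ 50% present, `impute` substitutes β = 0.5. Delta analyses report
per-group Spearman of DNAm vs chronological age, mean ± sd of delta
split at 50 years with a two-sided Wilcoxon, and the same stratified
by colon location.

## Integration and overlap

Feature methylation is the per-sample mean β over a probe group (DMR
members or leading-edge probes); expression coupling is Spearman over
shared samples, pooled across sample groups (as the study's 36-sample
overlap analysis pooled tissue types), BH across features, and
"significant negative" means r < 0 with adjusted p < 0.05. Spearman
p-values use the t approximation at n ≥ 10 and exact permutation
below. Overlap utilities report intersections with direction
concordance, full Venn partitions, and a database-agnostic
hypergeometric over-representation test (no annotation databases
ship with the package; gene-length/probe-number bias correction is a
non-goal).

## Statistics conventions

Two-sided Fisher tests use the probability-mass definition with a
1e-7 relative tolerance on the "no more probable" comparison to avoid
floating-point cliffs; r×c tables are fully enumerated over the
margins up to a total of 200 (beyond that, a seeded Monte-Carlo
estimate must be requested explicitly and is labelled approximate).
The 2×2 chi-square applies the Yates correction by default (the
convention consistent with the published value recomputed in the
acceptance checks). Wilcoxon rank-sum is exact (enumeration) when
both n ≤ 8 without ties, otherwise normal approximation with tie and
continuity correction capped at 1. Kruskal–Wallis applies the tie
correction, returning H = 0, p = 1 for all-tied data. All p-values
are floored at 1e-300.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the conditions
under which every recovery claim is measured. Defaults mirror the
emulated study design: group sizes LS_normal 33, LS unaffected normal
14, low-grade adenoma 21, high-grade adenoma 7, carcinoma 5,
FAP_normal 24, FAP_adenoma 12 (the FAP split is a realistic choice;
the source design does not print it); 20,000 probes as a scaled-down
array; expression for a 36-sample overlap subset (14/10/4/4/4).
Tests and the acceptance script use smaller instances (typically
2,000 probes, 15 vs 15) chosen as the package's own problem sizes.

Baselines are bimodal (island probes low, open-sea high, Beta-
distributed); planted effects are applied on the logit2 scale and
back-transformed, so the planted Δβ (default 0.2) is exact at the
baseline and β never leaves [0,1]. Within-group noise is
Beta(μc, (1−μ)c) with concentration c = 50 (≈ sd 0.05 near β = 0.5).
Hypermethylation is planted in promoter-island blocks of 5 probes
spaced 50–150 bp (doubling as ground-truth DMRs and as the genes for
expression coupling); hypomethylation in scattered open-sea body
probes — hypo-dominant, as in the emulated cohorts. Each tumor draws
a severity multiplier (uniform 0.8–1.2, ×1.35 for CIMP-positive
tumors) that jointly scales its hyper-, hypo- and LINE-1 shifts, so
biomarker scores co-vary across tumors the way the study reports
(LINE-1 ↓ with hypermethylation ↑, TMB ↑ with hypermethylation).
LINE-1 probes start near β 0.73 and shift by −0.35 logit2 units in
tumors (≈ 0.68), matching the printed group means. Clock probes carry
the age signal through small mixed-sign weights (the signal spread
over many CpGs, as in real clocks) with predictor noise sd 0.3 —
chosen to reproduce correlations near the reported R ≈ 0.94; at
predictor noise 0.5 the attainable Spearman is ≈ 0.85 by
construction, which the test suite asserts as such. Mutation counts
are round(−280 + 1000·hypermeth index + N(0, 20)) clipped at 0,
calibrated so tumor TMB spans roughly 0–40/Mb with a mix of
hypermutated and non-hypermutated tumors. Detection failures occur at
rate 0.002 per probe×sample (planted probes exempt, so truth
bookkeeping survives filtering).

One global seed feeds a fixed ordered list of substreams; identical
seeds give byte-identical outputs.

What the generator does **not** emulate: raw fluorescence, batch and
chip effects, cell-type composition, SNP artefacts, spatially
realistic CGI architecture, linkage between MSI status and TMB beyond
the shared hypermethylation coupling, and grade-dependent effect
sizes (all tumor groups share one planted effect set). Passing
recovery tests therefore demonstrate correctness of the analysis
machinery under a clean, known-truth model — not performance on real
arrays with correlated technical noise.

## Degenerate inputs and tie-breaks

Duplicate probe or sample ids, out-of-range β, inconsistent
detection-P layout, and empty post-filter probe sets are hard errors.
Most-variable-probe selection breaks variance ties by manifest order;
probe ranking breaks score ties lexicographically; unsorted manifest
positions are sorted internally with a warning. Rank-deficient
designs drop constant covariates with a warning but error if the
group indicator itself is degenerate.

## Known limitations

- DMR boundaries are merge-based; they will not match kernel-smoothed
  region callers probe-for-probe.
- The moderated model assumes homoscedastic residuals within probe
  and no correlation between paired samples; strong pairing structure
  would make the unpaired covariate model conservative.
- The hypermethylation index depends on the supplied contrast family
  and thresholds; it is a relative, not absolute, score.
- Exact r×c Fisher is exponential in table size; totals above 200
  require the Monte-Carlo mode.
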