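# Methods

## Scope and data model

The package analyzes per-gene, per-timepoint, per-replicate signal from an
acute activation time course: transcription-factor ChIP-seq in promoter
windows, RNAPII ChIP-seq in promoter / gene-body / TES windows, and
exonic/intronic quantifications of total and nascent (metabolically
labeled) RNA-seq.  All tables share one `TimeGrid`; the default grid is
{0, 10 min, 30 min, 1 h, 2 h, 4 h} with a 10-minute labeling pulse, both
configurable.  Coordinates are 0-based half-open (BED convention); GTF
input is converted on load and the longest transcript represents a gene
(ties broken by coordinate).  Default windows are promoter = TSS ± 500 bp,
gene body = promoter end to TES, TES window = TES + 1 kb; genes too short
for a positive-length body are flagged and excluded from RNAPII modeling
rather than dropped.

Normalization is counts-per-million per library.  Replicates are averaged
after normalization; per-replicate values are retained for variance
estimation.  Log2 responses use a pseudocount (default 1 CPM-equivalent)
applied symmetrically at both timepoints, which keeps the share identities
below exact.

## Binding share

With binding `b_i` and pseudocount `c`, the share of gene `i` is
`(b_i + c) / Σ_j (b_j + c)`.  Writing `δ_i` for the pseudocounted log2
binding change and `δ*` for the log2 change of the cohort total, the
share change of every gene equals `δ_i − δ*` exactly; a gene gains share
iff `δ_i > δ*`.  `δ*` is the *share-neutral threshold*.  ROC analysis of
any per-gene score sweeps all distinct observed values as thresholds, so
the trapezoidal AUC equals the Mann–Whitney pair statistic with ties
counted half.  Trend curves use a tricube-weighted local *quadratic*
regression (span 0.5) after trimming the 2nd/98th percentiles of the
x-variable; Spearman correlations are computed on the trimmed set, with an
exact permutation p-value below n = 9 and the large-sample approximation
otherwise.  Regulation classes default to |log2FC| ≥ 1 at any
post-activation timepoint, with ties in excursion resolved to
"unresponsive".

## RNA kinetic rates

Pre-mRNA is read out as intronic total signal, mature mRNA as the exonic
excess (clamped at zero, with clamping flagged); genes with no intronic
signal are flagged intronless.  Synthesis is the pooled nascent signal
divided by the labeling duration — a short-pulse approximation whose
relative error is below `k3·τ/2` (≈ 4% at k3 = 1/h, τ = 10 min).  The
nascent-to-total scale is 1 when the generator emits both on a common
scale; `scale="auto"` estimates it from total-RNA mass balance (interval
changes in P+M regressed on integrated synthesis with per-gene degradation
profiled out, monotone interpolants for the integrals).  With 6 coarse
timepoints this recovers a deliberate 4× mis-scaling to roughly ±20%; the
residual reflects unobserved sub-interval transient structure and is the
main reason to calibrate scales experimentally when possible.

Rates follow a nested functional family: constant, sigmoid, and the
product-of-sigmoids impulse.  By convention rates are held at their t = 0
value before treatment, and every gene starts at the steady state
P = k1(0)/k2(0), M = k1(0)/k3(0).  k1 is fit directly to the
window-averaged synthesis observations; k2 and k3 are then estimated by
weighted least squares between the ODE solution and observed P and M, with
every form pair screened (a pair whose AIC penalty alone cannot beat the
current best is skipped), seeded multistart for impulse surfaces, and a
final higher-budget polish of the selected model.  Model selection is AIC
subject to a chi-square goodness-of-fit gate at p ≥ 0.05.  Weights come
from replicate variances with cohort-level moderation: a single median
replicate CV is estimated per table and applied per value (floor 0.5% of
the median signal), which keeps chi-square statistics calibrated with few
replicates.  Temporal variability per rate is a likelihood-ratio chi-square
test of the constant fit against the best variable form (the other rate
held at its selected form), Benjamini–Hochberg corrected across genes.

The fitting backend integrates the linear ODE cascade with an exponential
midpoint scheme on a fine grid (default 121 points plus the sampling
times): each step applies the exact constant-coefficient propagator with
midpoint rates, so steady states are exact fixed points and the scheme is
second-order for varying rates.  The public `solve_rna_ode` uses an
adaptive LSODA solver at rtol 1e-8.

Identifiability: with 6 timepoints, mid-transient values of k2 are only
softly constrained when k1 itself is changing (the k1 path between
labeling windows is not observed); recovery claims are therefore stated as
medians over genes and timepoints.

## RNAPII compartment model

Densities follow the promoter → gene body → TES chain with promoter flux
p1 (unconstrained in sign; negative values mean nonproductive loss of
polymerase from promoters), pause-release p2, elongation p3 = k1/Gb, and
TES release p4 (p2–p4 floored at 1e-6/h).  Parameters are piecewise in
time over the sampling grid: piecewise-linear by default, with a
piecewise-constant mode whose inference is an exact sequential inversion —
p3 from k1/Gb (right-continuous), (p1, p2) from a 2×2 root-solve matching
the promoter and gene-body increments with the closed-form
constant-coefficient solution, p4 from a bracketed scalar solve.  Stage 1
of every inference is the interval-midpoint finite-difference closed form,
which initializes the refinement and serves as an independent oracle: on
densely sampled noiseless data the two routes agree to a small fraction of
a percent.

The untreated state is anchored at steady state (p1 = k1, p2 = k1/Pr,
p3 = k1/Gb, p4 = k1/Te at t = 0): the t = 0 observations alone cannot
separate loading from pause-release, and the anchor both resolves that
degeneracy and defines the "untreated level" used when freezing a
parameter in silico.  Joint refinement is least squares over the
post-activation knots of all four parameters against the Pr/Gb/Te/k1
streams, each stream standardized to comparable scale.  Explained variance
is 1 − SS_res/SS_tot over the concatenated standardized streams;
single-parameter models refit only one parameter's time course with the
others fixed at the untreated anchor.  Fitting is per cluster on
cluster-mean trajectories — a per-gene mode exists but is noise-sensitive.
Densities are relative (reads per region per library); absolute polymerase
counts are not identifiable, so p1 carries density/h units unless a
calibration constant is supplied.

## Response clustering

Feature matrices concatenate log2-response blocks, each block scaled to
unit overall variance; optional baseline-intensity columns are appended but
excluded from distances by default.  Clustering is agglomerative (Ward,
Euclidean by default — declared choices) cut at k = 14 with
min_cluster_size = 30; undersized clusters are labeled "removed" but kept
in outputs for auditability, and surviving clusters are renumbered by
decreasing size with deterministic tie-breaks.  PCA is centered, with
fractions summing to one over all components.

## Synthetic cohorts

The generator draws per-gene baselines (k1 ~ lognormal around 10
units/h, k2 around 4/h, k3 around 0.5/h; p2, p3, p4 around 2, 3, 6/h with
p1(0) = k1(0)), assigns induced / repressed / unresponsive classes
(default 20/20/60%), and gives responsive genes impulse-family rate
changes: synthesis folds of 2–5.7× (log2 effects 1–2.5) with mild
overshoot, immediate promoter-flux responses (onset within ~6–8 min),
pause-release shifts of ±0.3–0.8 log2, and transient processing- and
elongation-rate decreases in ~45% of induced genes (mirrored with opposite
sign in 30% of repressed genes) — processing/elongation effects peaking
between 30 min and 1.5 h.  Strongly repressed genes get transiently
negative promoter flux.  Degradation changes affect ~15% of responsive
genes, the least prevalent effect.  Onset×slope products are kept large
enough that the leading tail of each response is negligible at t = 0, so
"untreated" values match the nominal baselines closely.

Two cohort-level budgets are built in.  Promoter-flux gains of induced
genes are scaled by a single factor so that (weighted by per-gene pool
size) they offset repressed genes' losses: total chromatin-bound RNAPII
then drifts by well under 10% across the course, reflecting a limiting
polymerase pool.  An optional competition mode redistributes lost flux
per timepoint instead (off by default).  Binding fold-changes are
constructed so the binding-weighted cohort mean equals the global gain
(default 3×) exactly: induced genes sit 0.5–2.0 log2 above the
share-neutral threshold, repressed genes the same below, and the passive
unresponsive pool absorbs the (induced-heavy) share imbalance through a
common dilution factor computed in closed form.  If a cohort has no
unresponsive pool to absorb it, the generator falls back to margins
relative to the unresponsive level and warns.

Noise is multiplicative lognormal at a given CV per replicate, optionally
Poisson-resampled at a stated depth.  Library sizes are held constant
across the course (quantitative, spike-in-like scaling), so genome-wide
binding gains survive CPM normalization — the regime in which the share
analysis is meaningful.  The generator does not emulate read-level
artifacts (mappability, GC, peak shape), the shared-count structure of
exonic/intronic quantification, or biological covariance between noise and
expression level; passing recovery tests therefore demonstrates
correctness of the inference machinery under the stated noise model, not
robustness to all real-data pathologies.

## Problem sizes and numerical defaults

Unit and acceptance tests run the stages at: 1,000 random binding tables
for the threshold identity; 50 score/label sets (n ≤ 200) for the AUC
oracle; 200 genes × 6 timepoints × 3 replicates at CV 5% (and noiseless)
for rate recovery; 500 constant genes at CV 10% for null calibration and
150 four-fold impulse alternatives for power; 6-interval piecewise
compartment courses (one with negative p1) plus a Δt = 0.02 h dense course
for the inference round trip; and a 1,500-gene cohort at CV 20% for the
end-to-end share analysis.  `scripts/acceptance.py` uses 80/120/60-gene
cohorts for the rate-fitting stages to keep a full run at a few minutes on
one CPU; the statistics it reports are medians/fractions that are stable
at these sizes.

Key numerical defaults: solver rtol 1e-8 (adaptive paths); fitting grid
121 points; rate value bounds (1e-6, 60)/h for k2/k3 and data-scaled for
k1; slope bounds (0.5, 60)/h; positivity floor 1e-6/h for p2–p4; nearly
equal compartment rates nudged by a relative 1e-9 in the closed-form
propagator; BH correction at alpha 0.05.

## Known limitations

- Share accounting is promoter-window based over the supplied gene
  universe; an external background-total column can widen the denominator
  to all genomic binding, but no peak-level accounting is provided.
- `scale="auto"` for nascent/total calibration is coarse (see above).
- Per-gene RNAPII inference is exposed but noise-sensitive; cluster-mean
  profiles are the intended granularity.
- The variability test's LRT selects among alternative forms, which is
  mildly anti-conservative before correction; BH across genes leaves the
  realized false-call fraction far below alpha in calibration runs.
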