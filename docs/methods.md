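# Methods

`dosetrend` implements the statistical machinery of a translational screen
for chemotherapy-induced endothelial damage: an in-vitro dose–time
expression screen on micro-vascular endothelial cells (HMEC-1) exposed to
bleomycin or cisplatin, candidate selection by overlap across exposure
settings, gene-set enrichment, qRT-PCR validation math, and the
longitudinal statistics for a plasma-biomarker panel collected from
testicular-cancer patients over a BEP (bleomycin–etoposide–cisplatin)
course. Because the raw arrays and the patient-level data behind such a
study are not bundled, a synthetic-data module generates datasets with the
same statistical structure, and two printed result tables (the four top-50
lists and the enrichment report) are shipped for the worked examples.

## Array preprocessing

Raw intensities are log2-transformed (non-positive values floored at a
configurable epsilon with a warning; strict mode aborts naming probe and
sample). Quantile normalization maps every sample column onto the common
reference profile — the vector of row-wise means of column-sorted values —
by rank; tied values receive the mean of the reference values their tie
group spans (mean-of-ranks), so within-column rank order is preserved
exactly and the identical-sorted-multiset post-condition holds for
tie-free columns. Each channel of a two-channel array is treated as an
independent sample column and all columns are normalized jointly; ratio
formation and dye-bias modelling are out of scope. Probes mapping to the
same HUGO symbol are averaged (unmapped probes dropped and counted in the
run log), and repeated hybridizations of one specimen are averaged into a
single column.

## Trend screening

The acute screen tests each gene for a monotone expression trend over the
ordered dose ladder (untreated control, IC50, IC90) with the Cuzick rank
test: with midranks `r_j`, per-observation group scores `l_j` and `N`
observations,

    T = Σ l_j r_j,   E[T] = (N+1)/2 · Σ l_j,
    Var[T] = (N+1)/12 · (N·Σ l_j² − (Σ l_j)²) · [1 − Σ(t³−t)/(N³−N)],
    Z = (T − E[T]) / √Var[T],

with a two-sided normal p-value. Group scores default to the dose rank
(1, 2, 3) rather than concentrations, keeping the statistic comparable
across drugs; they are configurable. The composite score is the sum of the
per-time-point Z values at 6, 24 and 48 h; genes are ranked by it, so only
genes whose dose response points the same way at every time point reach
the extremes. Under the null the composite is approximately the sum of
three independent standard normals (variance 3), which the calibration
tests verify. Zero-variance genes receive Z = 0, p = 1 and a flag rather
than aborting a genome-wide run. The chronic screen (day-30 IC10 vs
control) uses a per-gene two-sample t-test — Welch by default, pooled
variance by flag — ranked by ascending p. Neither ranking applies a
multiple-testing correction (a Benjamini–Hochberg column is emitted for
reference only), matching how such screens feed a fixed-size top list.

The normal approximation of the trend p is accurate where it matters:
against exhaustive permutation enumeration at N ≤ 8 the moments agree to
1e-12 and the p-value agrees within 0.05 (in practice ≤ 0.02) throughout
the rejection region (exact p ≤ 0.1). Mid-distribution p-values of so
discrete a null deviate more; no selection decision depends on them.
`max_sigma_z` returns the largest attainable composite for a design (three
times the perfectly ordered arrangement's Z) — a useful plausibility bound:
published composite magnitudes near 9.6 exceed the bound for one or two
observations per group (4.24 and 6.41), implying more effective replication
than the documented hybridization averaging alone provides. For that reason
the package does not promise to reproduce any published per-gene composite
value, only the machinery.

## Candidate selection

Each setting's ranked table is reduced to a top-k list (k = 50): the k/2
largest-composite genes as up-regulated plus the k/2 smallest as
down-regulated for acute settings, the k smallest-p genes for chronic
ones; boundary ties break by statistic then symbol so lists are
deterministic. Genes present in at least m of the settings' lists (m = 3
of 4 by default) form the candidate set; the threshold is
greater-or-equal, so a gene in all four lists still qualifies. A
direction-concordance flag records whether a candidate moves the same way
in all its member settings — on the published lists all three candidates
(GDF-15, ATF3, AREG) are discordant, rising acutely and falling
chronically.

## Gene-set enrichment

The enrichment score walks the metric-ranked gene list, incrementing by a
hit's normalized weight `|metric|^p` (p = 1 by default; p = 0 gives the
unweighted Kolmogorov–Smirnov-style variant) and decrementing by
`1/(N − N_hit)` per miss; ES is the signed maximum deviation, with exact
magnitude ties resolved to the first-attained extreme. The ranking metric
is the trend composite for acute settings and `sign(t)·(−log10 p)` for
chronic ones (configurable). The null permutes gene labels — one shared
permutation of the gene-to-position assignment per round for all sets —
with 1000 rounds by default. Nominal p is the add-one-smoothed fraction of
same-sign null scores at least as extreme; NES divides ES by the mean
magnitude of same-sign null scores; the FDR q compares null and observed
NES tail fractions, clipped to [0, 1]. Reporting keeps sets with
FDR ≤ 0.10 and p ≤ 0.025. Sets are restricted to genes present in the
ranking, and restricted sizes outside [5, 500] are skipped. The FDR
estimator is tested for calibration (null flag rate, planted-set
detection), not against any published per-set FDR value, which would
require the original arrays and era-specific catalog.

## qPCR quantification

The default relative quantity is the CT-ratio: mean target CT divided by
mean GAPDH CT for the same condition × time cell, with baseline-relative
differences as the ratio of quantities at a time point versus the 6 h
baseline. Because CT falls as transcript rises, this quantity is
direction-inverted; the conventional `2^−ΔΔCT` fold change is provided
side by side as an explicitly labelled alternative, and both are reported.
Condition comparisons use a two-sided Welch t-test on replicate-level
quantities (each replicate's target CT over the cell's mean housekeeping
CT), flagged at 0.05. No outlier handling is applied to triplicates.

## Clinical statistics

Plasma panels are long-format patient × timepoint × marker tables over a
declared ordered schedule (baseline = first label). Summaries are median
(range) per timepoint; values are treated as non-normal throughout. Paired
changes versus baseline use the Wilcoxon signed-rank test with zeros
dropped and pairwise-complete filtering: exhaustive sign-flip enumeration
(exact even under tied magnitudes) up to 14 nonzero differences, the exact
distribution up to 25 without ties, and the tie-corrected normal
approximation beyond. Group contrasts use the two-sided Mann–Whitney U
(exact for small untied samples) with "median (range; n)" summaries; the
prognosis grouping merges intermediate and poor. Marker correlations are
Spearman on pairwise-complete pairs (≥ 4 required), with exact permutation
p for n ≤ 8 and the t-approximation otherwise; the per-timepoint
correlation track adds a Holm-adjusted column for reference while flags
use the unadjusted 0.05 rule, matching per-timepoint reporting. All-zero
difference vectors yield p = 1 in the course summary (no evidence of
change) but are a hard error when the test is called directly.

## Synthetic data

The generators are pure functions of their design objects (seed included).

* **Acute**: one column per (dose, time, replicate, hybridization); trend
  genes shift mean log2 expression by `effect_size_log2` per dose step in a
  fixed per-gene direction at every time point; Gaussian noise on the log2
  scale at both the specimen and the hybridization level (sd
  `noise_sd_log2`, default 0.5, typical of array log-intensity residuals);
  gene baselines N(8, 1.5). Defaults mirror the modelled study: dose
  scores 1/2/3 for control/IC50/IC90, time points 6/24/48 h, 2 replicate
  specimens per cell (two independent experiments) and 4 hybridizations
  per specimen. A separate `spike_seed` lets several settings share
  planted genes while their noise differs.
* **Chronic**: two arms (control, IC10) at day 30; affected genes differ in
  arm means by the effect size; at least 2 replicates per arm.
* **Plasma**: lognormal values, `log v = log(baseline median) +
  log(multiplier) + patient effect + correlated noise`, with the noise
  vector across markers following a Gaussian copula (pairwise latent
  correlation `cross_marker_rho`, default 0.35) so the Spearman correlation
  between markers is a tunable target. Default course multipliers shape a
  strong within-course GDF-15 spike, a sustained vWF rise and an
  oscillating hsCRP response around baseline medians 383 pg/mL, 100 % and
  2 mg/L; log-scale noise sd 0.5. The patient random intercept defaults to
  0 so the copula target is exact; missingness is completely at random per
  patient × timepoint.
* **Catalogs**: random gene sets in GMT form (169 sets of size 10–60 by
  default, the size of a KEGG-era catalog), optionally planting one
  supplied set.

What the generators do **not** emulate: spot-level image artifacts,
dye-swap bias, probe-specific effects, pharmacokinetics behind the IC
doses, informative missingness, or patient covariate structure beyond the
prognosis label. Passing tests therefore demonstrate the statistics are
implemented and calibrated correctly — not that the pipeline would
reproduce any particular biological finding on real arrays.

## Problem sizes and numerical choices

Calibration and recovery studies are sized so their conclusions are
stable: null uniformity of the trend p uses 5,000 genes with 20 replicates
per group (N = 60 observations per time point — small-N rank statistics
are too discrete for a Kolmogorov–Smirnov uniformity check, which resolves
CDF deviations of ~0.02 at this gene count); the enrichment null
calibration uses 169 random sets × 1000 permutations over 1000 genes,
repeated 20–50 times; spiked recovery uses 500 genes with 25 planted trend
genes at effect 1.0 log2, noise 0.5, 2 replicates per group. The pipeline
demo powers its chronic arm with 6 replicates, since a single-gene t-test
competing against a top-50-of-1000 cut is underpowered at 2–3. Seeds flow
from the design objects or a run config; nothing reads global random
state.

## Known limitations

* Published per-gene composite values, per-set FDR values and
  patient-level summaries are not reproducible from shipped inputs (raw
  data, era-specific catalogs and individual patient data are not public);
  the worked examples operate on the printed result tables instead.
* The enrichment FDR uses the standard NES-ratio estimator; other
  implementations differ in normalization details, so q-values are
  comparable in calibration, not digit-for-digit.
* The CT-ratio quantification is nonstandard (direction-inverted); users
  wanting conventional fold changes should read the `2^−ΔΔCT` column.
* Exact Spearman p-values are enumerated only for n ≤ 8.
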