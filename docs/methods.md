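# Methods

This note documents the models, conventions and numerical choices in
`microflux`, in the order the pipeline runs them.

## Quantification and depth normalization

Gene counts are assumed to arrive already mapped and multi-mapper
normalized. All tables are plain TSV (tab-separated, header row of
sample ids, first column the row id, UTF-8, no quoting); minimal
examples of each dialect live in `docs/examples/`. Two rules are applied before any modeling:

- **Downsizing.** Each sample's gene counts are subsampled *without
  replacement* (multivariate hypergeometric) to a fixed target
  (default 10 million reads); samples below the target cannot be
  downsized and are dropped with a report. A retained column sums
  exactly to the target and every output count is bounded by its input
  count.
- **Marker-gene quantification.** A species' abundance is the
  arithmetic mean over *all* of its marker genes, zeros included — not
  only detected markers; this literal convention is what makes the
  detection rule meaningful. If strictly fewer than 10% of a species'
  markers have nonzero counts in a sample, the species is set to 0
  there (a tie at exactly 10% is retained). Species tables are then
  per-million scaled per sample.

## Detection model

Presence cannot be read off abundance > 0 at finite sequencing depth.
All nonzero abundances in the cohort are pooled (across species and
samples — per-species fits would be data-starved), log2-transformed on
the per-million scale, and fitted by maximum likelihood with a gamma
distribution (scipy's MLE with location fixed at 0). The presence
threshold is the fitted distribution's lower quantile, default the 1st
percentile; the percentile is configurable because "the 1% detection
tail" is a convention, not a law. Presence requires the log2
per-million abundance to *strictly exceed* the threshold; zeros are
always absent. Values ≤ 0 after log2 fall outside the gamma support and
are excluded from the fit — they can never exceed a positive threshold,
so calling stays conservative. The fit refuses degenerate inputs
(< 100 pooled values, or all values identical).

## Markov flux model

Each species' presence sequence over a subject's visits is a two-state
Markov chain. Transition pairs are *adjacent observed visits of the
same subject*; a skipped visit does not break adjacency (cohorts have
missing visits; the alternative — breaking the chain at gaps — is a
one-line change in `consecutive_pairs` if a stricter design is wanted).
Pairs pool across subjects into one chain per species, matching the
single inflow/outflow pair reported per species. Estimates are the
row-normalized maximum-likelihood transition frequencies. A row with no
observations (a species never absent, or never present, within pairs)
is left NaN and flagged — never imputed. Species at 0% or 100%
prevalence carry no transition information and are excluded.

Classification uses strict inequalities at t_in = t_out = 0.3:
PCS ⇔ inflow > 0.3 and outflow < 0.3; TCS ⇔ outflow > 0.3 and
inflow < 0.3; anything else (including undefined probabilities) is
UNCLASSIFIED. Cross-cohort or cross-depth agreement is summarized by
Spearman rank correlation of inflow and outflow on shared species
(requiring ≥ 10 shared species).

## Retention

A (subject, species) survival record starts at the first observed
presence; the event is the first subsequent absence; a species still
present at the subject's last visit is censored. Time is counted in
visit intervals — the only clock the design provides (one interval ≈ 3
months in a quarterly design). By default only the *first* episode per
subject × species is used, because a second colonization episode of the
same species in the same subject is not an independent record;
`first_episode_only=False` emits every episode. Species first seen at a
subject's last visit yield zero-length (uninformative) records and are
dropped. Curves come from the product-limit estimator
(`lifelines.KaplanMeierFitter`); no per-species Cox regression is
offered — curves and horizon summaries only.

One property worth stating precisely: *adding* a new censored record —
even one censored after the last event — changes earlier survival
estimates, because it enlarges every earlier risk set. What leaves the
curve unchanged is *extending an existing censored record* past the
last event; the test suite asserts the correct version.

## Scores and destabilization

Standardization uses all cohort samples, zeros included, with the n−1
standard-deviation denominator; zero-variance species are dropped with
a warning. The class score divides the member-z sum by √n so its null
distribution is standard normal for any class size. μ/Δ pair statistics
are computed per adjacent same-subject visit pair. The Eq.-style sum
runs over *all* class species (zeros standardized), not only species
detected in that sample; restricting to detected species would couple
the score to richness.

Community turnover is the Jaccard similarity of present-species sets at
adjacent visits (NaN when both sets are empty). Comparing similarity
between TCS-enriched (μ_TCS > 2) and TCS-depleted (μ_TCS < −2) pairs
offers both a one-sided rank-sum test (default) and a one-sided Welch
t-test, because both appear in practice; the direction tested is
"enriched less similar than depleted". Richness dynamics correlate
Δ_class with the per-pair richness change (Spearman); richness defaults
to species richness, with gene richness available when gene counts are
supplied.

## Associations

- **Co-abundance network**: pairwise Spearman correlations among
  classified (PCS ∪ TCS) species, Benjamini–Hochberg adjusted, signed
  edges below the adjusted-p threshold. The p-value uses the
  t-approximation on the rank correlation.
- **Function enrichment**: per binary annotation, a simple linear
  regression of the species' inflow (or outflow) score on the
  annotation — the coefficient is exactly the annotated-vs-unannotated
  mean difference; enriched means coefficient > 0 and BH-adjusted
  p < 10⁻³. Functions with no contrast (present in none or all species)
  are skipped.
- **Differential abundance**: per-species two-sided Wilcoxon rank-sum
  between the two metadata groups; direction is the case-group median
  shift (mean as tie-break); species all-zero in both groups are
  skipped. No covariate adjustment is applied.
- **Overlap enrichment**: 2×2 hit × class contingency within a stated
  universe; chi-square (without continuity correction) and the exact
  hypergeometric upper tail P(overlap ≥ observed).
- **Mixed models**: random-intercept-only (no random slopes),
  REML-fitted via statsmodels MixedLM. The class-score model uses
  Z_PCS and Z_TCS jointly; the per-species model uses one abundance
  fixed effect. With one sample per subject the random intercept is
  inestimable and the fit falls back to OLS with a note. The
  fixed-effect explained-variance fraction follows the marginal-R²
  decomposition var(fixed) / (var(fixed) + var(intercept) +
  var(residual)); per-species associations are retained above 10%.
  Multiple testing is Benjamini–Hochberg wherever adjustment is
  reported.

## Synthetic cohorts

The generator exists to give every stage a ground truth; it is
deliberately not a mechanistic model of gut ecology. Defaults emulate a
wellness-cohort design: 86 subjects × 4 visits × 300 species, read
depth 10⁷, 100 markers per species. Per-species inflow/outflow default
to U(0.05, 0.95) — spanning both classes and the unclassified middle —
and abundance-when-present is log-normal with per-species log-mean
drawn N(0, 2) (a few orders of magnitude of spread) and log-sd 1, a
simple heavy-tailed positive model consistent with fitting the
detection limit on the log scale.

Presence chains start from the stationary occupancy
π = inflow/(inflow + outflow), which keeps per-visit prevalence
time-homogeneous and makes recovery tests well-posed; a frozen chain
(inflow = outflow = 0) defaults to always-absent and records that
policy in the truth object. Optional sequencing noise splits a species'
mass uniformly over its markers and draws reads multinomially at the
configured depth, so each gene-count column sums exactly to the depth.
Phenotypes follow Y = Z_PCS·β_PCS + Z_TCS·β_TCS + u_subject + ε with
u ~ N(0, σ_u²), ε ~ N(0, σ_ε²). Case-control cohorts are
cross-sectional; a designated species subset (default: the true TCS)
receives an additive shift on both the logit of occupancy and the log
abundance mean in cases, so effect 0 is an exact null.

One global seed expands into fixed per-stage substreams (parameters,
presence, abundance, genes, phenotype, case-control), so a stage
reproduces bit-identically regardless of which other stages run.

What the generator does **not** emulate — compositional interactions
between taxa, phylogenetic correlation, strain structure, visit-time
irregularity, covariate-linked confounding — bounds what green tests
mean: they demonstrate estimator correctness and calibration under the
stated model, not robustness to every feature of real cohorts.

## Problem sizes and tolerances

Recovery checks run at 150 subjects × 6 visits × 200 species (noiseless
MAE < 0.03; with multinomial read noise at depth 10⁶ and re-detection,
MAE < 0.08 and Spearman ρ > 0.9 against truth). The detection fit is
checked on 10⁵ known-gamma draws (threshold within 2% of the closed
form). Exactness checks (hypergeometric vs full enumeration up to
universe size 15, flux estimator vs brute-force pair counting, KM hand
examples, downsizing totals, pipeline bit-identity) have no tolerance
at all. Mixed-model recovery uses 86 subjects × 4 visits; the
OLS-reduction check constructs residuals demeaned within subject so the
between-subject variance is exactly zero and the REML fit sits on the
boundary, where the GLS and OLS solutions coincide.
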