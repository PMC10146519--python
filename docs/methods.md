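# Methods

This note documents the models, rules and numerical choices implemented in
`gcvolatiles`, the defaults of the synthetic-study generator, and what the
simulation-based checks do and do not establish.

## Data model

A peak table is a samples × peaks matrix of non-negative areas with 0
meaning "not detected" (detection censoring, not missingness). Sample
metadata carries the design factors: line, locality, generation, replicate
cage, sex, mating-history category (virgin vs mixed-sex cohort) and
analytical batch. Peak columns are labelled by retention time (minutes,
2 d.p.) for FID data or integer Kovats index for MS data and are kept
strictly increasing.

### Batch normalisation

Batches are corrected multiplicatively so every batch's total peak area
equals the grand mean of the batch totals. The target is a design choice
(only the fact of normalisation is given upstream); the grand mean is
scale-preserving and symmetric in the batches. The operation is idempotent,
keeps zeros at zero, and preserves within-sample peak proportions, hence
detection patterns and rank orders. A batch with zero total area is an
error rather than a silent skip.

## Classification rules

* **Inclusion filter.** A peak is retained iff its detection proportion is
  ≥ 0.5 in at least one (line × sex/mating-category) cell; the comparison
  is inclusive ("at least 50 %"), so 2 of 4 samples in a single cell
  suffices. The threshold and the by-line grouping are configurable. The
  filter is monotone in the threshold.
* **Abundance classes.** Per category, a peak's share is its summed area
  over the summed area of all peaks in that category (not a mean of
  per-sample shares). The class comes from the maximum share across
  categories: ≥ 1 % major, ≥ 0.1 % intermediate, < 0.1 % minor — boundary
  values fall in the upper class.
* **Sex bias.** Within one mating-history category: detected in exactly one
  sex → sex-specific; detected in both with |log10 mean ratio| strictly
  greater than 1 → sex-selective; otherwise no bias. Means include
  non-detected (zero) samples, because zeros are true non-detections in
  this data model; an option excludes them. A tie at exactly 10-fold is
  "none" (the rule is strict).
* **Retention ranges.** Short/mid/long windows: Rt 4.60–10.39, 10.40–13.59,
  13.60–21 min; KI 840–1095, 1096–1240, 1241–2175. Labels ≥ 600 are read
  on the KI axis. Out-of-window labels are errors, not a fourth class.
* **Ratio (enrichment) test.** Goodness-of-fit χ² of observed category
  counts against expectations in the reference proportions, df = k − 1.
  A 2 × k contingency variant is provided for the reading where the
  reference is itself a counted sample disjoint from the observed one.
  For the published abundance-class counts, (3, 13, 10) against
  (21, 75, 105), the goodness-of-fit gives 2.10 and the disjoint
  contingency 2.41; the printed companion value 2.36 is reproduced by
  neither formulation and is documented here rather than targeted. The
  per-range test, (11, 3, 12) against (31, 23, 147), reproduces the
  printed 14.77 on 2 df exactly.

## Rt → KI calibration

The Rt–KI relationship is close to linear at both ends of the temperature
programme with a curved transition in between. `KovatsCalibrator` fits:

* piecewise-linear interpolation through the calibrators with Rt ≤ 13.59
  min and, separately, Rt ≥ 17.37 min (exact at those calibrators before
  rounding; linear extrapolation from the end segments within a ±1 min
  margin, beyond which prediction errors unless extrapolation is enabled);
* a least-squares polynomial (degree 3 by default — the lowest degree that
  expresses the visible curvature; configurable) over the calibrators
  spanning the mid region, boundary calibrators included with heavy weight
  so the piecewise map stays continuous. Continuity is enforced softly: a
  fit whose polynomial misses a boundary calibrator by more than 1 KI unit
  is rejected, as is any fit that is non-monotone on a 2001-point grid over
  the span.

Imputed KIs are reported as integers (as such tables print them). The
degree default, the boundary tolerance, and the off-by-default
extrapolation are design choices; the region boundaries are data-derived
constants of the instrument programme and are constructor parameters.

## Cross-platform matching

Candidates are mutually-nearest (FID, MS) KI pairs. A candidate is accepted
when its |ΔKI| ≤ 4 and Δ is strictly smaller than the distance from either
member to the adjacent alternative peaks on both sides; equality rejects.
Requiring mutual nearest-neighbourship plus two-sided adjacency is the
conservative reading of "best match, clearly more similar than the next
before and next after" — one-directional adjacency would accept chains of
ambiguous assignments. The rule set makes matching symmetric in the
platforms and the accepted set a partial injection, and raising the
tolerance never removes an accepted pair.

Note a consequence: when two peaks sit closer together than the KI noise
scale on both platforms (e.g. published pairs 1185/1187 and 1186/1188), the
strict rule declines both rather than guessing; such chains need the joint
context of the full profiles, which is why the published-pair check in the
tests applies the tolerance filter to the printed pairs rather than
re-deriving the pairing from the bare 19-row lists.

Compatibility ratings compare detection codes (all / some / none / not
assayed, per sex per sample type) between platforms: YY when every
comparable state agrees with all-vs-some collapsed or one side was not
assayed; Y when the only disagreements are presences that are partial in a
minor-abundance peak, or presences retaining a strictly >10-fold mean bias
toward the sex in question; N otherwise. The ≥10-fold reading defines the
code flag and the strict >10-fold reading the Y rule, each following its own
defining sentence; both thresholds are configurable. Final assignment drops
already-identified peaks (reported separately) and N-rated pairs, and
enforces one-to-one pairing.

## Line-effect screen

OrderNorm maps training values to normal quantiles of p = (rank − ½)/n with
average ranks for ties; transform and inverse are monotone linear
interpolations of the fitted map, clamped at the extremes, so
inverse∘transform restores training values (tie groups share a score). The
training scores have mean 0 exactly and variance 1 up to the n/(n − 1)
correction. This is a standard rank-to-normal mapping implemented here
directly (no Python equivalent of the R implementation is available);
constant input is an error. Zeros enter as smallest-rank ties by default.

The model is one-way fixed effects with line as the only factor:
generation, cage and batch variation deliberately enter the residual, so a
significant F ratio means line differences exceed replicate variation both
within and between generations — the isofemale-line criterion for inherited
variation. A degenerate fit (zero within-line variance) is flagged rather
than hidden. FDR families are the peaks of one dataset (each of the five
sex/mating datasets is adjusted separately). Marginal means per line are
the transformed-scale group means with CI = mean ± t(0.975, df_within) ·
√(MS_within/n_line), back-transformed through the OrderNorm inverse for
display. Pairwise contrasts use the Tukey studentized-range adjustment by
default (configurable to none/BH); significance decisions use the exact
studentized-range critical value, reported p values the standard fast
approximation, and letters come from insert-and-absorb so two lines share a
letter iff their contrast is non-significant. Spearman screens correlate
per-line mean areas across peaks, BH-adjusted over pairs, with optional
exclusion of a named line (the domesticated line, in the motivating
design).

## Multivariate analyses

Distances default to Bray–Curtis (the convention of the PERMANOVA
implementation the field uses when nothing else is stated; Euclidean and a
log1p option are provided). PERMANOVA Gower-centres −½D², projects the
sequential design (Analysis I: line; Analysis II: locality, then
line-within-locality) via SVD-based hat matrices — robust to the redundant
dummy coding — and takes pseudo-F per term against the residual. P values
come from free permutation of sample rows with the +1 correction, so
p ∈ [1/(n_perm+1), 1] and results are bit-reproducible given the seed.
Sequential sums of squares plus the residual reconstruct the total within
1e−9. PCA is centred, unscaled, via SVD; the LDA of localities runs on the
leading components (default: smallest locality sample size − 1, keeping the
feature count below every group's n) and reports group centroids ± per-axis
within-group SD/√n and the eigenvalue shares of between-group variance.

## Synthetic-study generator

The generator emulates the motivating design: 23 isofemale lines across 7
localities (3–4 lines each) plus one domesticated line, screened over
generations 6–12 with 1–2 replicate cages per generation (unbalanced, as
in the real screens), four sex/mating categories, and 150 peaks on a
uniform Rt grid over 4.6–21 min (an explicit grid can be supplied).
Areas follow log10(area) = baseline + sex effect + line effect + locality
effect + generation jitter + batch log-factor + N(0, 0.3), censored to 0
below 300 area units; baselines are uniform on [2.5, 6] log10 units so a
realistic minority of peaks sits near the detection limit. Peak areas are
positive and heavy-tailed and the sex-selectivity rule is a log10
comparison, so a log-normal abundance model with additive log-scale
effects is the natural choice. About 45 % of peaks are sex-specific (75 %
of those male-biased) and 20 % sex-selective with a 1.5 log10 shift,
mirroring the predominance of male-biased volatiles in this system; 10 %
of peaks carry line effects drawn per line from N(0, 2·residual SD), with
the domesticated line shifted up by twice that scale (it shows the highest
abundances for most varying peaks in the real data). Locality effects are
off by default and, when enabled, rank-one: one shared direction across the
affected peaks with a scalar per locality — the structure under which LD1
dominance is the expected outcome. Batches coincide with generations, as
in the assay design, with 0.05 log10 SD scale factors; KI truth follows a
fixed piecewise map (linear–curved–linear, continuous and increasing) and
the MS side observes a configurable subset of peaks with N(0, 1.5) KI noise
plus platform-specific extras.

What the generator does not emulate: correlated residuals between
co-eluting peaks, drift within batches, non-multiplicative batch effects,
peak-area integration error, and compound identity. Passing tests
therefore establish the statistical machinery's operating characteristics
under the stated model, not robustness to those real-data features.

## Validation benchmarks and problem sizes

The package validates itself by simulation (`gcvolatiles.benchmarks`),
with these default problem sizes:

* **Type-I error of the screen:** 30 null datasets (~125 peaks each, one
  male category), batch-normalised and screened; the pooled raw rejection
  rate at α = 0.05 sits in [0.03, 0.07]. Peaks near the detection limit
  carry heavy zero-ties and make the rank-based F test mildly
  conservative, which is visible as a rate slightly below 0.05.
* **Power:** 10 datasets, 24 lines × 5 replicates, 2-residual-SD line
  effects on ~10 % of 100 peaks; the FDR-significant fraction of affected
  peaks exceeds 0.8 (in practice ≈ 1 at this effect size).
* **Matching:** 50 simulations of a 30-peak evenly spaced panel (all peaks
  shared, 20 % platform-specific extras, KI noise SD 1.5): candidate
  generation, compatibility rating and assignment recover ≥ 95 % of shared
  pairs with ≤ 1 % false pairs at the 4-unit tolerance. The evenly spaced
  panel represents the resolvable-peak scenario this property is about;
  on dense panels (~150 peaks, mean KI gap ≈ 9) the adjacency rule
  correctly declines ambiguous chains and recovery is necessarily lower —
  the behaviour seen in the real profiles, where only 35 of 105 peaks in
  the shared interval could be provisionally matched.
* **PERMANOVA null:** 500 runs × 199 permutations on 12-sample null
  tables; the p values pass a Kolmogorov–Smirnov uniformity test at 0.01.
* **Calibration:** with 15 calibrators and 1-KI-unit noise the fitted map
  stays within ~2 KI of truth at the calibrators; noise-free fits are
  exact up to integer rounding.

The real-data multivariate F values are not recomputable from the material
deposited with the motivating study alone (the major-set raw data live
with a prior publication and the distance metric is unstated); the
structural form of the output tables and the synthetic-data behaviour
stand in for them, and the corresponding check on the deposited minor-set
table runs only when the user supplies that CSV.
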