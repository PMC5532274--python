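# Methods

This note records the models, estimators, numerical choices and known
limitations of the `podomot` pipeline, in the order the stages run.

## Track statistics

A track is a time-ordered sequence of positions `x₀ … x_N` (µm) with
timestamps. Mean speed is path length over duration, `v = Σ‖Δxᵢ‖ / (t_N −
t₀)`, and persistence is `P = ‖x_N − x₀‖ / Σ‖Δxᵢ‖`. Both are computed per
cell; cohort values are **unweighted means across cells** with SEM
(`sd/√n`, `ddof = 1`), matching error bars drawn across cells rather than
pooled steps. A cell that never moves has `P = 0/0`; it is flagged
undefined, excluded from the persistence mean, and counted
(`n_excluded_persistence`) rather than imputed. A single-cell cohort
reports SEM 0 with a `degenerate_sem` flag.

Both statistics are invariant under global translation and rotation, and
subsampling frames can only shorten the measured path (triangle
inequality) — these are enforced as property tests.

Instantaneous speed at frame *i* is the step from the cell's previous
recorded frame divided by the actual elapsed time, assigned to the later
frame; gaps are skipped, never interpolated. Cohorts are compared per
timepoint with Welch's two-sample t on the per-cell speeds, and the family
of timepoints is controlled with the Šídák adjustment `p' = 1 − (1−p)^m`.
This replaces a repeated-measures ANOVA + Šídák post-hoc chain: the
omnibus step of that chain is under-specified for reimplementation, while
the per-timepoint comparisons with Šídák control are exactly what the
time-to-effect readout consumes. Timepoints where either cohort has fewer
than two cells, or where all speeds are identical, keep p = 1.

MDF track files carry frame indices but no clock, so a configurable
`frame_interval_s` (default 600 s) supplies timestamps; the pixel→µm scale
is likewise a config input (default 1.0) since calibrations vary per
microscope.

## ECIS and scratch wounds

Traces are resistance time series on a regular 30 s grid. Baseline
normalization divides a well by its own resistance at the treatment time
(nearest sample), making 1.0 the value at treatment and the operation
idempotent; vehicle normalization divides pointwise by the vehicle
condition's across-well mean trace. The endpoint statistic is each well's
mean over the final 30 minutes of its trace (window inclusive of the last
sample; traces shorter than the window are rejected). Conditions are
compared on **per-well endpoint means** — one number per well, avoiding
pseudo-replication from the thousands of autocorrelated samples inside the
window — by one-way ANOVA followed by Tukey's HSD
(`scipy.stats.tukey_hsd`, which takes its studentized-range quantiles from
scipy's implementation). If every well in every condition is constant the
comparison is degenerate and p-values of 0/1 are assigned by exact
equality.

Wound closure efficiency is `(A(0) − A(t))/A(0)` at the sample nearest to
the query time (tolerance 0.25 h); it is unit-free, may be negative if a
wound expands, and requires `A(0) > 0`. Mask-based areas count foreground
pixels (foreground = open wound) and reject non-binary images.

## Peak annotation

All internal coordinates are 0-based half-open; GTF gene records (1-based
inclusive) are converted on load, and the TSS is the strand-aware 5′ end
(`start` on +, `end − 1` on −). A peak is represented by its **midpoint**
for TSS distance and promoter membership — input peak lists report one
distance per peak without stating a convention, and the midpoint is the
deterministic choice. Location classes form a partition with precedence:
overlap of the peak interval with any gene span → intragenic; else
midpoint within 2,500 bp strictly upstream of a TSS (TSS excluded,
strand-aware) → promoter; else distal. Distance categories use the gap
between the peak interval and the gene **coding span** (0 when
overlapping): > 50 kb from every gene is its own category, otherwise the
nearest gene's responsive flag decides, and an exact distance tie goes to
the responsive gene (deterministic and documented; ties are measure-zero
in real data). Promoter enrichment merges the per-gene 2.5 kb upstream
windows (clipping at chromosome ends) before measuring, so duplicated gene
records cannot inflate the background.

The vectorized per-chromosome implementation is checked exactly against a
pure-Python all-pairs oracle on random small genomes in the test suite.

## Expression filter

The differential table uses Welch's t on log2 intensities with
`log2FC = mean(treated) − mean(vehicle)` and the signed fold-change
convention `FC = 2^lfc` for up, `−2^(−lfc)` for down. Welch replaces a
moderated-t (empirical-Bayes) fit: the headline filter is the FC/q gate,
and a precomputed differential table (`probeset, log2fc, p`) can be
supplied to use any external test instead. Probesets with zero variance in
both groups get p = 1 (flagged) when the means agree and p = 0 when they
differ.

Storey q-values use the fixed-λ estimator `π̂₀ = min(1, #{p > λ}/(m(1−λ)))`
with λ = 0.5 (configurable; no spline smoothing — deterministic and
transparent), then the step-down minimum `q₍ᵢ₎ = min_{j≥i} π̂₀·m·p₍ⱼ₎/j`
clipped to [0, 1]. With π̂₀ = 1 this is exactly Benjamini–Hochberg. Note
that for very small m the estimator can return π̂₀ = 0 (all p ≤ λ), making
all q-values 0; the estimator is intended for genome-scale m.

The significance gate is |FC| ≥ 1.5 **inclusive** (reconciling "±1.5" and
">1.5-fold" phrasings) and q < 0.05 strict. Gene collapse keeps the
probeset with the largest |log2FC| per gene; a `conflict` flag marks genes
whose probesets disagree in sign. Unmapped probesets are excluded and
reported, never silently dropped.

## Exact Mann–Whitney

For group sizes ≤ 10 the two-sided p-value is exact: all C(n_x+n_y, n_x)
assignments of the pooled mid-ranks to the first group are enumerated and
the p-value is the fraction with `|U − n_x n_y/2|` at least the observed
deviation (two-sided definitions vary; this symmetric-deviation form is
the one implemented, and it conditions on the observed tie pattern).
Larger samples use the tie-corrected normal approximation with continuity
correction. Two-sided is the default sidedness for the activation-ratio
comparisons. Activation ratios are active/total band intensity, normalized
per timepoint to the mean vehicle ratio so the vehicle group's mean
normalized ratio is 1 by construction.

## Synthetic data

The generators define the conditions under which the pipeline is
validated; they are deliberately simple and their defaults are fixed.

*Tracks* are correlated random walks: step lengths ~ Gamma with mean
`v·dt` and CV 0.5 (within-cohort speed dispersion is not published; CV 0.5
is a realistic spread for cultured epithelial cells and the tests tolerate
it), heading increments ~ von Mises(0, κ). The turning model was chosen
over an OU-velocity model because it has one shape parameter with a
monotone link to the persistence ratio. κ was calibrated by grid search
(`scripts/calibrate_kappa.py`) at the default geometry — 145 frames at
dt = 600 s, i.e. 24 h at one frame per 10 min, a typical live-imaging
cadence since the true interval is not published — giving κ = 13.4 for
cohort persistence ≈ 0.50 (vehicle) and κ = 17.8 for ≈ 0.57 (Gc). Cohort
speeds default to 0.0053/0.0034 µm/s. PAN-injured cells, when simulated,
default to the vehicle κ since only their speed ordering is ever asserted.

*Toy genomes* place non-overlapping stranded genes with ≥120 kb gaps (so
every location class and distance category is realizable), then plant each
peak to realize its class exactly under the midpoint rules: intragenic
peaks inside a span, promoter peaks offset 1–2.5 kb upstream of a TSS
(biased 80:20 toward responsive genes, which is what makes
responsive-promoter enrichment exceed unresponsive in end-to-end runs),
distal peaks by rejection sampling away from spans and TSS windows. The
default class mix (0.412/0.022/0.566) and peak count (1,130) mirror the
reported cistrome composition. The truth table's distance categories are
computed by an independent double loop, not by the classifier under test.

*Expression* matrices spike a DE fraction at gene level (so redundant
probesets shift together) with ±effect on a Normal(8, 1.5) log2 baseline
and Normal(0, 0.3) replicate noise, 3v3. At the default planted effect
(3.0 log2) the Welch-based filter's power is ~0.90 on average over 20
simulation replicates at m = 2000 — individual replicates range roughly
0.82–0.95 because a 3v3 Welch test has only ~4 df; a moderated-t would sit
higher. Null calibration (no planted effects) selects essentially nothing.

*ECIS* traces are a logistic rise (500→2000 Ω, midpoint 6 h) times a
condition multiplier that ramps in after treatment (τ = 6 h), plus AR(1)
noise (φ = 0.9, σ = 15 Ω). Default multipliers PAN 0.55 < PAN+Gc 0.80 <
vehicle 1.00 < Gc 1.25 encode: injury collapses the barrier, Gc protects,
and Gc partially rescues injury without restoring it past vehicle (the
orderings asserted downstream are only the ones with direct support:
PAN lowest, Gc > vehicle, PAN+Gc > PAN).

*Wounds* are centred rectangles whose width shrinks linearly at a
per-condition fraction of the initial area per hour; defaults 0.17/0.08
h⁻¹ reproduce closure efficiencies 0.34 (vehicle) and 0.16 (Gc) at 2 h
exactly at zero noise. The area table keeps the continuous width; masks
quantize to whole pixels.

All generators are deterministic under a fixed seed.

### What synthetic validation does and does not show

Passing tests demonstrate that the estimators recover the parameters of
the generating models (speeds, persistence, planted peak classes, planted
fold changes, configured barrier orderings) at the study's sample sizes.
They do not validate against real measurement artifacts: tracking errors
and cell collisions, non-stationary cell speeds, ECIS electrode drift,
segmentation error in wound masks, probe-level array effects, or peak
callers' boundary noise. Absolute agreement with any real dataset's
values is outside what these tests can certify.

## Numerical conventions and edge cases

- SEM uses `ddof = 1`; n = 1 groups report SEM 0 with a flag.
- Collinearity/persistence comparisons use a 1e-9 float tolerance.
- Welch tests fall back to p = 1 when a timepoint or probeset is
  degenerate (fewer than 2 values per group, or zero spread).
- Duplicate (cell, frame) records and non-monotone timestamps are hard
  errors naming the offender, not warnings.
- All file formats are plain text (CSV/TSV/BED/GTF, PNG/TIFF masks);
  outputs carry a comment header with version, seed and config hash, and
  readers skip `#` comment lines.

## Limitations

- The exact Mann–Whitney enumerates up to C(20,10) ≈ 1.8×10⁵ splits;
  beyond n = 10 per group it switches to the normal approximation.
- Tukey HSD assumes balanced-ish, homoscedastic well groups; with 2–3
  wells per condition this is a convention, not a guarantee.
- The promoter definition is a fixed 2.5 kb strictly-upstream window;
  bidirectional promoters and UTR-proximal binding are not modelled.
- Gene models are coding-sequence spans; UTR-extended transcript models
  would shift intragenic/promoter fractions.
- The pipeline starts from processed inputs (linked tracks, normalized
  expression, called peaks); upstream preprocessing quality is out of
  scope.
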