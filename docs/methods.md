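# Methods

This note documents the models, parameter choices and numerical decisions
behind `esokin`, and what the synthetic-data experiments do and do not
establish about real recordings.

## Signal model and preprocessing

A recording is modelled as uniformly sampled tri-axial acceleration
`y(t) = g + a(t) + ε(t) + s(t)` in mG at 500 Hz per limb segment: a static
gravity projection `g`, band-limited voluntary motion `a(t)`, white sensor
noise `ε`, and rare spike artefacts `s`. The conditioning chain addresses
each term in a fixed order:

1. **Spike replacement.** Samples with `|y − mean| > k·SD` (default
   `k = 3`; mean and *population* SD computed once over the whole trace,
   not iteratively) are replaced by linear interpolation between the
   nearest retained neighbours; flagged edge samples take the nearest
   retained value. The comparison is strict, so a constant trace (SD = 0)
   flags nothing. The threshold is deliberately single-shot: an iterated
   rule would keep shrinking the SD on heavy-tailed movement data.
   Note that genuinely ballistic movement is itself heavy-tailed, so on
   movement-rich signals a percent or so of *real* motion peaks is clipped
   along with the artefacts — the same behaviour visible in human data,
   where ~98.9% of samples survive this rule. Consequently the
   injected-versus-detected artefact accounting is validated on
   motion-free fixtures, which isolate the stage.
2. **Gravity zeroing** by whole-session mean subtraction. This assumes the
   sensor orientation is static over the session; no attitude tracking is
   attempted.
3. **Unit conversion** at standard gravity, 9.80665 m·s⁻² per 1000 mG.
4. **Band-pass filtering**: Butterworth, design order 2, passband
   0.5–11 Hz, covering voluntary mouse movement while rejecting residual
   gravity drift and high-frequency noise. Default application is
   forward–backward (zero-phase), which preserves the phase relation
   between acceleration and the doubly integrated displacement; a causal
   single pass is available (`zero_phase=False`). Zero-phase filtering is
   run with a pad of `3/band_low_hz` seconds so the slow high-pass edge
   mode does not leak transients into the analysis window.
5. **Integration** by cumulative trapezoid (initial value 0), twice.
   Double integration turns band-limited noise into a low-frequency random
   walk that would dominate every displacement-derived metric, so by
   default each integration is followed by the same 0.5 Hz high-pass plus
   mean removal (`drift_correction=True`). A strict mode disables both
   (`--strict-paper`): displacement metrics in that mode are dominated by
   drift on noisy input and are reported for fidelity only.

## Global magnitude: L1 versus L2

The per-frame combination of axes is `|x| + |y| + |z|` by default
(`as_printed`), with `euclidean` (`√(x²+y²+z²)`) as an option. The L1 form
dominates the L2 form frame-wise and, for isotropically oriented movement,
overstates geometric path length by `E[|cosθ| + |sinθ|] ≈ 4/π` (measured
+22–30% on synthetic sessions). Cumulative distance is therefore a
norm-dependent quantity; parameter-recovery experiments against planned
path length run in `euclidean` mode, while the default honours the
published form.

Cumulative distance itself is `Σ|D_{i+1} − D_i|` — the sum of absolute
changes. (The alternative reading `Σ(|D_{i+1}| − |D_i|)` telescopes to
`D_n − D_0` and measures nothing; it is not implemented.)

## Confidence ellipse

The displacement footprint is the *population-coverage* ellipse of the x–y
displacement cloud: sample covariance, eigen-decomposition, semi-axes
`√(q λ₁) ≥ √(q λ₂)` with `q = χ²₂(coverage)` (5.9915 at the 0.95 default),
area `πab`, reported in cm/cm². A coverage ellipse (not a standard-error
ellipse of the mean) is used because the object of interest is the area of
mousepad the hand sweeps. Clouds with `λ₂ ≤ 10⁻¹² λ₁` raise a degenerate-
geometry error; in session summaries this is caught and surfaced as a
`degenerate-ellipse` flag so motionless sessions still produce a row. The
fitted axis ratio is ≥ 1 by construction and carries an upward
small-sample fluctuation of a few percent per 10-minute session
(displacement samples are strongly autocorrelated, so the effective sample
size is the number of movements, not of frames); shape conclusions should
be drawn at the group level.

## Direction changes

Zero crossings are counted per velocity axis as consecutive effective
samples whose signs multiply negative, summing the three axes. Exact zeros
carry the previous sign forward (touching zero is not a crossing). A
`deadband` (m·s⁻¹, default 0) treats `|v| ≤ deadband` as zero. With
deadband 0 the count on noisy data includes a noise-floor term whose rate
depends only on the noise *bandwidth*, not its amplitude (both the level
and its derivative scale together), so experiments that relate the count
to movement rate use a deadband of ~3× the noise-velocity SD
(5×10⁻⁴ m·s⁻¹ for the synthetic presets). The paper-faithful default
remains 0.

## Cohort statistics

* Natural log for the transform; the base only shifts log-means additively
  and cannot change F, p or η².
* The bootstrap (simple resampling, B = 1000, percentile 95% CI, seeded)
  provides CIs of the transformed group means; the ANOVA itself runs on
  the transformed values and is not bootstrapped.
* η² = SS_between/SS_total, which for a one-way design equals
  `df₁F / (df₁F + df₂)` — the identity used to recover effect sizes from
  printed summaries.
* Fisher LSD is by definition unadjusted: pairwise t statistics on the
  pooled within-group mean square with the ANOVA's df₂.
* The DPI analysis tests the genre × DPI count table (levels nobody chose
  are dropped from the omnibus table as uninformative), with pairwise 2×2
  follow-ups (genre pair × chose-this-level vs not) at each level — nine
  comparisons for three genres and three levels — flagged at the Šidák
  threshold `1 − 0.95^{1/9} ≈ 0.006`.
* The one-sample t of the ellipse long:short ratio against 1 runs on raw
  (untransformed) ratios, since the reference value 1 is meaningful on the
  ratio scale.
* Degenerate inputs are legitimate: identical groups give F = 0 (not an
  error); a zero-spread Levene statistic reports homogeneity p = 1.

## Synthetic sessions

The generator emulates the study conditions — 10-minute, 500 Hz, 3-sensor
× 3-axis recordings in mG with gravity offset, genre-dependent ballistic
movement, sensor noise (1.5 mG per axis, typical of wearable
accelerometers) and 1% spike artefacts at 12× the clean signal SD.

Hand motion is a thinned Poisson stream of **out-and-back minimum-jerk
flicks** from a home position: each event draws a target direction from
the genre's 2×2 spatial covariance (which sets the footprint shape), an
amplitude from a log-normal (which sets the scale), and a one-way stroke
duration from a uniform range; the flick runs home → target → home with
fifth-order minimum-jerk strokes, plus a vertical residual of 5% of the
amplitude. Acceleration is synthesized analytically and attenuated copies
form the forearm and arm channels. Returning home makes the planned path
length (twice the summed target distances) recoverable from high-pass-
filtered displacement without a drift ambiguity, and it is a fair cartoon
of aiming (flick and re-center) and click-to-move control. Randomness is
split into independent substreams (events / noise / spikes / metadata) so
toggling artefacts never perturbs the planned path.

Preset parameters (chosen once for regime ordering and plausibility, not
to reproduce any cohort's means):

| preset    | events/s | amp mean±SD (cm) | stroke (s) | cov diag (cm²) | attenuation (forearm, arm) |
|-----------|----------|------------------|------------|----------------|----------------------------|
| FPS       | 0.9      | 4.0 ± 1.4        | 0.25–0.40  | (9.0, 2.25)    | (0.55, 0.35)               |
| MOBA      | 1.5      | 1.8 ± 0.6        | 0.20–0.30  | (4.0, 3.3)     | (0.75, 0.55)               |
| Adventure | 0.5      | 3.5 ± 1.2        | 0.30–0.50  | (7.5, 2.5)     | (0.65, 0.45)               |

These give FPS > MOBA > Adventure on RMS acceleration and distance, MOBA
the highest movement rate, and oblong footprints for FPS/Adventure versus
a near-circular MOBA footprint. DPI choice is drawn from genre-conditioned
probabilities (FPS favouring 400, MOBA favouring 1600).

**What passing tests show — and don't.** The generator validates the
pipeline's arithmetic and its parameter recovery (path length within a few
percent in euclidean mode; segment ratios exactly in the noiseless limit;
footprint shape at the group level). It does *not* reproduce several
features of human data: sustained postural wander (hands do not snap back
to a home position), so synthetic ellipse areas are much smaller than
human ones; inter-segment dynamics richer than scalar attenuation; skin-
artefact and orientation drift; or any DPI-dependent movement scaling.
Agreement on synthetic data therefore certifies the computation, not the
human-cohort values.

## Problem sizes and tolerances

Experiments use session lengths matched to what each quantity needs:
one-minute sessions for path-length recovery (100 seeds, median error,
observed ~2%), ten-minute sessions for ellipse shape (50 seeds, median
error, observed ~5%), 63-session cohorts (32/16/15) for the end-to-end
analysis, and 2000 replicates for the type-I-error check of the
log-transform → ANOVA ladder (observed 0.0495 at nominal 0.05). Bootstrap
and simulation seeds all derive from a single user-supplied seed; reports
are byte-identical across reruns at a fixed seed. Floating-point identities
(brute-force metric references, F = t², the η² summary identity) are held
to 1e-9 relative; filter oracles to their physical tolerances (DC
rejection below 1e-3, mid-band gain within 5%).
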