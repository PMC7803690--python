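# Methods

This note documents the models, conventions and design choices behind
`erpstates`, in the spirit of the methods appendices of statistical
simulation packages: what is computed, under which assumptions, and what
the synthetic benchmarks do and do not demonstrate.

## Topographic measures

All measures operate on average-referenced maps; every public function
re-references defensively, so the choice of acquisition reference does
not affect results.  Units are microvolts throughout; file readers
convert at the I/O boundary.

* GFP is the spatial standard deviation (population normalization,
  `1/N`).  DISS between two maps is the RMS difference of the
  GFP-normalized maps; the identity `DISS² = 2(1 − r)` with the
  inter-map Pearson correlation `r` holds to numerical precision and is
  enforced by tests.
* Flat (zero-GFP) maps raise an error in correlation/DISS rather than
  producing NaN: inside a permutation test a silent NaN would corrupt
  exceedance counts.  In back-fitting, a zero-GFP frame instead inherits
  the previous frame's label and is logged — there a hard error would
  discard an entire trial for one degenerate sample.
* GEV weights each frame's squared template correlation by its squared
  GFP.  Note that GEV squares the correlation, so it is blind to
  polarity even when the assignment is polarity-sensitive.

### Time conventions

Frame indices are 0-based with half-open windows.  A response-locked
epoch of `n` frames covers the interval `[−n, 0)` in frames relative to
the vocal onset; the last sample is the final frame before acoustic
energy.  `tf_to_ms` rounds to a granularity of 1 ms (or 10 ms for
quoting approximate windows); duration *criteria* use the ceiling
instead (10 ms at 512 Hz → 6 frames), because "present at least 10 ms"
is a lower bound, not a nearest-value conversion.

## Synthetic data generator

The generator emulates a delayed pseudoword-production EEG study: 22
participants, 128 scalp electrodes, 512 Hz, 150-frame (~293 ms) epochs
aligned backward from the vocal onset, 88 trials per condition per
participant, and two onset conditions (voiceless stops /p,t,k/ vs
/s/-initial clusters).

* **Montage** — a Fibonacci lattice on the upper head sphere
  (quasi-uniform, deterministic); any montage file can be substituted.
  Topographies are phenomenological: there is no dipole source or head
  conductor model.
* **Templates** — four smooth fields built from axis projections of the
  electrode positions plus a weaker quadrupolar term, spatially smoothed
  and partially decorrelated so all pairwise |r| ≤ 0.4.  Purely dipolar
  (linear) fields span only three dimensions, which makes four mutually
  dissimilar maps a measure-zero event; the quadrupolar term and the
  controlled decorrelation make generation reliable on any montage while
  keeping the maps realistically non-orthogonal.
* **Schedule** — maps tile each epoch in the order D → B → C → A with
  stop-condition durations 74/8/12/56 frames (matching the observed
  individual-ERP duration profile over a 150-frame window).  The
  fricative condition delays map A's onset by `shift_tf` frames
  (default 46 ≈ 90 ms), map D absorbing the freed frames; B and C are
  identical across conditions.  This is the planted
  articulatory-to-acoustic interval (AAI) effect.
* **Amplitude envelope** — a raised-cosine bump per segment, peaking
  mid-segment and decaying to a 0.3 floor at the edges, so GFP waxes and
  wanes as in real ERPs but never vanishes.  Short segments peak
  proportionally lower (a microstate shorter than ~30 frames does not
  reach full field strength), which also keeps the GFP free of
  sample-to-sample discontinuities.  A flat envelope is available for
  analytic tests.
* **Subject variability** — each subject's templates are a mildly mixed
  copy of the group templates (mixing coefficients N(0, 0.1)),
  renormalized; this makes subject-level random effects non-degenerate
  without breaking group-level recovery.
* **Noise** — single-trial background activity is spatially smooth
  (Gaussian kernel over inter-electrode chord distance, width 0.5 head
  radii) and temporally autocorrelated (AR(1), coefficient 0.9 ≈ 20 ms
  time constant), scaled to `noise_sd` × the mean signal GFP per
  channel.  White sensor noise is a special case
  (`noise_spatial_sigma=0, noise_ar=0`) but is *not* the default:
  spatially white noise averages out in a 128-electrode spatial
  correlation and leaves single-trial label recovery essentially
  perfect at any plausible amplitude, which real single trials are not.
  The default level (3.0) was calibrated once so that the planted
  46-frame grand-average shift survives intact while the single-trial
  estimate attenuates to roughly 20 frames — the qualitative
  grand-average vs single-trial gap a realistic generator must show.
* **Vocal RTs** — Gaussian per phoneme with the empirical means and SDs
  of the delayed-production task (e.g. /k/ 610.88 (151.94) ms, /sk/
  529.76 (149.32) ms), truncated at a 150 ms floor.  Each phoneme's SD
  is decomposed into a subject intercept (50 ms), an item intercept
  (20 ms) and a residual, so the marginal distribution keeps the
  tabulated mean/SD while the crossed random effects of the mixed model
  are estimable.  The implied stop-minus-fricative difference is
  ≈ 90 ms.

What passing tests on these data do **not** show: robustness to muscle
and ocular artifacts, electrode drift, non-stationary noise spectra,
inter-subject montage digitization error, or map topographies that
change gradually rather than switching — none of which the generator
emulates.

## Preprocessing

Order is fixed: filter → epoch → reject → interpolate → re-reference →
average.  The band-pass is a zero-phase (forward-backward) 2nd-order
Butterworth, 0.1–30 Hz, plus a 50 Hz notch (Q = 30); zero-phase
filtering preserves pass-band amplitude within 5% and removes DC by
more than 40 dB.  Already-epoched data are reflection-padded up to one
epoch length.  Artifact rejection is a deterministic ±100 µV amplitude
threshold — reproducibility over fidelity to visual inspection.  Bad
channels are rebuilt by spherical-spline interpolation (stiffness m = 4,
Legendre truncation degree 7, solved with a constant term so constant
fields are reproduced exactly); at most 16% of channels may be
interpolated (20 of 128).  Averaging is the arithmetic mean over
accepted trials per subject × condition; grand averages weight subjects
equally.

## TANOVA

The observed statistic at each frame is the DISS between the two
condition grand averages (maps GFP-normalized, hence strength-
independent).  The null distribution flips each subject's condition
assignment independently per permutation — the correct exchangeability
for a paired within-subject design — and
`p = (#{permuted ≥ observed} + 1)/(n_permutations + 1)`, which cannot
reach zero.  With 200 permutations the exact pre-criterion rate of
`p < 0.01` under the null is 2/201 ≈ 0.00995; the calibration test and
the acceptance script verify this empirically.  Significant runs
shorter than the 10 ms criterion (6 frames at 512 Hz) are cleared.
Default 1000 permutations, seeded.  Frames with a zero-GFP grand
average are excluded with a warning rather than tested.

## Segmentation

Polarity-sensitive modified k-means: frames are assigned by *signed*
spatial correlation and templates updated as the GFP-weighted mean of
their assigned frames, renormalized; empty clusters are reseeded from
the worst-fit frame.  Polarity sensitivity is the ERP convention —
evoked components of opposite polarity are distinct states, unlike in
resting-state analysis.  The two condition grand averages are
concatenated and share one template set, which is what makes
cross-condition duration comparisons meaningful.  Each run tracks the
best labelling encountered (ties resolved toward later, more converged
iterates); the best of 50 restarts by GEV wins.  Smoothing reassigns
every frame of a run shorter than the duration criterion to the
better-correlating adjacent segment's template, iterating until no
short run remains (the run count strictly decreases, so this
terminates).  Template letters are assigned by mean occurrence time,
latest first, so the map bordering the vocal onset is always "A";
letters are names, not identities, and tests match recovered to planted
maps by correlation, not by letter.

`choose_k` scores each candidate K by the elbow ratio
`gain(K)/gain(K+1)` of successive GEV gains, warm-starting each K from
the best K−1 solution (guaranteeing GEV is non-decreasing in K).  A
candidate wins only if its ratio reaches 2; on structureless data every
gain sits near the chance level (roughly one part in the channel count)
and the smallest candidate is returned.

## Back-fitting and durations

Each frame of a target ERP or single trial gets the template with the
highest signed spatial correlation; ties break toward the previous
frame's label (lowest index at the first frame) to avoid spurious
segment boundaries.  Durations are counts of labelled frames within the
fixed fitting window (the full −150..0 frame epoch by default), *not*
onset-to-offset spans, so they always sum to the window length per
fitted epoch.  Single-trial fitting applies the same ≥ 10 ms smoothing
as the segmentation by default (raw argmax labels flicker under noise);
both modes are exposed because either choice is defensible for
trial-level duration tables.

## Statistical models

RTs and map durations are modelled with REML linear mixed models:
mode × place fixed effects and crossed random intercepts for subjects
and items, implemented as variance components over a single trivial
group.  Random slopes are deliberately omitted.  Term tests are Wald
chi-square tests on the fixed effects; the degrees-of-freedom
convention therefore differs from Satterthwaite-style F tests and exact
replication of any particular software's F/df values is out of scope.
If the optimizer fails or all variance components collapse to ~0, the
model falls back to OLS on subject-cell means with subject fixed
effects (the classical aggregated within-subject analysis) and the
result is flagged.  Planned place contrasts refit within one mode and
report uncorrected pairwise differences.

## Problem sizes

The test suite and the acceptance script run scaled-down versions of
the full study so the whole pipeline stays desk-sized: typically 8–12
subjects × 16–30 trials per condition at 128 electrodes for recovery
benchmarks, 32 electrodes × 10 subjects × 500 null datasets × 200
permutations for the TANOVA calibration.  These sizes were chosen as
the smallest at which the quantities of interest are stable; the
generator's defaults retain the full study dimensions.

## Known limitations

* The smoothing rule (short-run reassignment) honours the ≥ 10 ms
  criterion but is not identical to window-based smoothing schemes used
  by some microstate software; results can differ in edge cases.
* Wald chi-square p-values are anti-conservative for very few subjects;
  the type-I calibration test bounds the damage at the simulated sizes
  but small-sample inference should use the aggregated fallback.
* The TANOVA is two-condition and point-by-point only; no omnibus or
  multi-condition variant is provided.
* Source localization is out of scope; topographies are treated as
  phenomenological signatures.
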