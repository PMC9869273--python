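# Methods

This note records the models, defaults and numerical choices behind
`olfactomap`, and what the synthetic-data tests do and do not demonstrate.

## Paradigm model

A *run* is the fixed 70 s block sequence 5 s PEA → 5 s rest → 5 s amyl
acetate → 5 s rest → 5 s PEA → 5 s rest → 10 s amyl acetate → 10 s rest →
10 s PEA → 10 s rest; a session concatenates four runs (280 s).  Epochs are
aligned to block onsets, never span blocks, and tails shorter than the
epoch length are dropped: each block contributes `floor(duration /
epoch_length)` epochs.  With 1 s epochs this yields exactly 80 PEA, 60
amyl-acetate and 140 rest epochs.  The study that motivated this package
reported 126 rest epochs against the same schedule; the deficit is not
explained there, so the package makes no silent correction — amplitude
based epoch rejection exists (`preprocess.reject_epochs`) but is disabled
by default, and the discrepancy is simply documented.  Time is kept in
seconds as floats; sample indices are `round(onset × rate)`.

The 5-minute post-run untasked rest block is representable (a REST segment
with `run_index ≥ n_runs`) and selectable as the contrast baseline
(`baseline="post_run_rest"`); the default baseline is the within-run rest.

## Spectral analysis

Per epoch and channel the power spectrum is `|DFT(w ⊙ x)|² / Σw²` with a
periodic Hann taper `w(k) = 0.5·(1 − cos 2πk/N)`.  The `Σw²` normalization
makes the expected per-bin power of white noise equal its variance,
independent of the taper.  Epoch spectra are arithmetically averaged per
condition.  Frequency resolution is `1/epoch_length` (1 Hz by default).

Band power sums bins half-open: delta [1, 4), theta [4, 8), alpha [8, 13),
beta [13, 31), gamma [31, 81).  The printed classical edges overlap (8 Hz
is both a theta and an alpha edge; 30 Hz both beta and gamma) and leave a
12–13 Hz gap; this partition keeps the alpha sum over exactly the integer
frequencies 8–12 Hz, resolves shared edges consistently, and makes the five
bands an exact partition of the 1–80 Hz total, so band fractions sum to 1
to 1e-10.  The DC bin and frequencies above 80 Hz are excluded from the
broadband total.

## Contrast

The outcome is `100·(P_cond − P_rest)/P_rest` per location and band, with
the significance mask `|Δ| ≥ threshold` (default 20 %, boundary inclusive
within 1e-9 numerical slack, two-sided because decreases are reported
outcomes too).  The contrast is computed on **absolute band power** by
default: the source description of the analysis sums oscillatory power over
the band and compares *that* quantity across conditions via relative
change, so "relative" refers to change-versus-rest, not to band/broadband
normalization.  The normalized variant (band power divided by the 1–80 Hz
total at the same location) is implemented and selectable
(`normalization="relative"`); note that under it a +40 % band-power effect
structurally appears as only ≈ +33 %, because the broadband denominator
grows with the band.  A pooled "olfactory stimulation" condition is the
epoch-weighted mean of the PEA and amyl-acetate condition spectra (80:60).

## Forward model and simulator

The head is a single-sphere homogeneous conductor (radius 0.09 m, centred
at the origin); sensors sit on a 0.12 m helmet cap covering polar angles up
to 125°, radially oriented magnetometers by default (planar gradiometers
are available as a 17 mm two-point finite difference).  Dipole fields use
the closed-form spherical-conductor solution; central and radial dipoles
are silent to machine precision, and the leadfield is linear in the moment.

Each ROI is a patch of 9 dipoles on a 2 cm golden-angle disc tangential to
the centroid's radius, with orientations rotating through the tangential
plane (a stand-in for cortical folding).  Patch granularity matters for
statistics, not just realism: the band power of a single Gaussian
narrowband process over time `T` has only ≈ `2·B·T` degrees of freedom, so
a ROI must contain several *resolvable* incoherent sources for its mean
band power to be stable at this paradigm's epoch counts.  Nine points per
ROI also keeps the total source count (63) below the default channel count
(64), which makes the matched minimum-norm resolution matrix close to the
identity.  ROI centroids are nominal schematic coordinates (deep inferior
frontal "olfactory", superficial "somatosensory", etc.), not subject
anatomy; co-registration is out of scope.

Each patch point emits five independent band-limited components (white
noise through a 4th-order zero-phase Butterworth band-pass), RMS dipole
moments 35/25/15/16/15 nAm for delta/theta/alpha/beta/gamma — a 1/f-like
profile in which alpha carries ≈ 9 % of broadband source variance.
Component passbands are inset from the analysis-band bin edges (delta
1.5–3.5, theta 4.6–6.9, alpha 8–12, beta 14–30, gamma 32–79 Hz) because the
Butterworth response is only −3 dB at its edge; without the inset ≈ 11 % of
theta power lands in the alpha bins and an injected "alpha modulation" no
longer measures as itself.  Alpha spans its full 8–12 Hz band since those
bins all belong to the alpha analysis band.

A condition modulation multiplies a component's variance by
`1 + percent/100` inside that condition's blocks, as an amplitude step at
block boundaries (no ramp).  The default scene injects the reported
pattern: +40 % bilateral olfactory and −30 % bilateral somatosensory alpha
for both odorants, and PEA-only +27.5 % orbitofrontal, +7.5 % medial
frontal, +27.5 % precentral.  Sensor noise is white, 8e-14 T per sample at
500 Hz (≈ 5 fT/√Hz), independent across channels; an optional empty-room
segment contains noise only.  All randomness flows from one integer seed
through `numpy` seed sequences; outputs are bit-reproducible.

## Inverse and ROI mapping

The inverse is Tikhonov minimum-norm, `Lᵀ(LLᵀ + λ·tr(LLᵀ)/n·I)⁻¹`, with
dimensionless λ defaulting to 3e-4.  The default was set by a
predicted-bias analysis of the matched overdetermined system: the recovered
percent change is a within-source power *ratio*, so the fixed minimum-norm
gain cancels, and the residual bias has two parts — cross-ROI leakage
(grows with λ) and projected sensor-noise power (grows as λ shrinks).
Small λ plus empty-room PSD subtraction removes both: the subject-absent
recording is tiled into epochs, passed through the same inverse, and its
mean source-space spectrum subtracted (floored at zero) from every
condition before band aggregation.  The subtraction stage is enabled by
default whenever an empty-room recording is supplied.  ROI band power is
the arithmetic mean over the ROI's points (stable under atlas resolution
changes); the contrast is computed after source projection, per condition.

External interference suppression (the vendor's temporal signal-space
separation) is *not* re-implemented; the `passthrough_tsss_settings` hook
records the published settings (correlation threshold 0.9, 10 s window) in
provenance and returns the data unchanged.

## What the synthetic tests show — and what they don't

Recovery tests demonstrate that the pipeline faithfully measures known
band-power modulations through a *matched* forward model with Gaussian
sources and white sensor noise.  Real data differ in ways the generator
does not emulate: forward-model mismatch (real heads are not spheres, and
the analysis atlas never equals the true source configuration),
non-Gaussian and non-stationary rhythms, physiological artifacts (cardiac,
ocular, muscle), head movement, and correlated environmental noise.
Passing these tests therefore validates the *analysis machinery*, not the
anatomical accuracy of any real-data result.  Voxel-wise map extents in
particular depend on the (here, unstated) inverse method and are only
reproduced qualitatively.

At the study's own epoch counts the percent-change estimator for a
narrow band has a per-ROI standard error of a few percentage points even
in the best case, which is why the recovery tolerance is ±10 points and
why the headline acceptance quantity averages the bilateral ROI pair, the
pooled odorant condition, and three replicate simulations.

## Problem sizes and defaults

Desk-scale analyses and all tests run four runs (280 s) at 64 channels /
500 Hz with 63 sources — a few seconds per simulate-and-analyze cycle.
The study-scale settings (306 channels, 5,000 Hz, 0–1,000 Hz online
band-pass) are configuration defaults of `PipelineConfig` and remain fully
supported; they change cost, not code paths.  Key defaults: epoch length
1 s; threshold 20 %; normalization absolute; baseline within-run rest;
λ = 3e-4; rejection disabled; empty-room subtraction on when available.

## Degenerate inputs and tie-breaks

Zero total power makes relative band power undefined (error, not NaN);
a non-positive rest baseline makes percent change undefined (error).
Empty condition spectra, mismatched frequency grids, channel/source count
mismatches, dipoles on or outside the conductor, and schedules extending
past the recording all raise descriptive `ValueError`s.  Epoch counts use
`floor` with a 1e-9 guard against float rounding; sample indices round to
nearest.  The five-band partition resolves edge ownership downward
(8 Hz → alpha's lower edge is inclusive, 4 Hz → theta, 13 Hz → beta,
31 Hz → gamma).
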