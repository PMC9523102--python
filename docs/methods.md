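# Methods

`nirswave` quantifies cortical hemodynamics from multichannel fNIRS
concentration series in three wavelet-domain measures — band wavelet
amplitude (WA), lateralization index (LI) and wavelet phase coherence
(WPCO) — and compares resting vs. motor-training states within
impairment groups. This note records the model, its assumptions, the
numerical choices, and what the synthetic validation does and does not
show.

## Measurement model and montage

Recordings are ΔO2Hb/ΔHHb concentration-change series (µM) sampled at
10 Hz over 38 channels formed by 18 sources and 16 detectors at 30 mm
separation, seven regions per hemisphere (PFC, DLPFC, SFC, PMC, M1,
S1, OC). The channel→region table is a declarative TSV fixture: the
true assignment depends on optode placement, which only the user can
know, so every downstream computation reads the fixture and users can
substitute their own. Because lesion side varies across subjects, all
group-level quantities live in the ipsilesional (I) / contralesional
(C) frame; `remap_hemispheres` relabels hemispheres per subject and is
an involution under lesion-side flip.

Subjects are grouped by manual muscle test grade: 0–1 severe, 2–3
moderate, ≥4 mild. Applying this rule to the packaged 33-subject
demographics table yields group sizes 10/15/8; the table stores the
grades verbatim and the rule is applied mechanically. The demographics
table records hemiplegia side and lesion site; lesion side is stored
as the side opposite the hemiplegia (contralateral motor
organization), while the two fields remain independent in the data
model.

## Preprocessing

1. **MBLL (optional).** Dual-wavelength (740/850 nm) optical-density
   changes are converted to concentrations by solving the 2×2
   extinction system. Extinction coefficients default to the
   Gratzer/Cope tabulation and the differential pathlength factor to
   6.0 at both wavelengths; both are config keys, because published
   tabulations differ and the analysis proper starts at
   concentrations. Conversion precedes filtering by default; the
   reverse ordering is a config switch since either is defensible.
2. **Bandpass.** Zero-phase Butterworth, 0.0095–2 Hz, overall order 6
   (applied as a cascaded second-order-section forward–backward
   filter). Series must comfortably exceed the filter's padding length
   or a preprocessing error is raised.
3. **PCA+ICA denoising.** Channels are reduced to the PCA rank
   retaining 99% variance and unmixed with FastICA (seeded; on
   non-convergence the selection falls back to the PCA basis and the
   report records it). Where an operator would visually inspect
   component spectra, the package applies an automated criterion: a
   component is retained iff the fraction of its Welch-spectrum power
   inside 0.01–0.08 Hz is ≥ 0.5 (configurable), with a manual-override
   list for forced rejections. Every decision (band-power fraction,
   retained flag, auto/manual reason) is logged in a
   `ComponentReport` so selections stay auditable.
4. **Despike + repair.** Samples deviating from a centered 3-s moving
   average by more than k = 5 robust standard deviations (1.4826×MAD
   of the residual, so a spike does not inflate its own threshold) are
   flagged, the mask dilated by 2 samples to cover spike shoulders,
   and interior flagged spans replaced by a cubic spline through the
   valid samples. Spans touching an edge cannot be bracketed and are
   held at the nearest valid value. A mask covering more than 50% of a
   series raises a quality error. k is deliberately conservative; it
   is a config key.

On an already-clean in-band signal the full chain changes band WA by
less than 5% (tested), so the cleaning does not manufacture effects.

## Wavelet amplitude

The continuous wavelet transform uses an analytic Morlet with central
frequency parameter ω0 = 6 (admissibility-safe standard choice) on a
logarithmic grid of 16 voices per octave spanning 0.0095–2 Hz; only
0.01–0.08 Hz — the band attributed to neurally driven hemodynamic
oscillations — feeds the measures. The transform is evaluated in the
Fourier domain (one FFT of the zero-padded, demeaned signal, then one
inverse FFT per scale), with the window matrix cached across calls
because surrogate ensembles evaluate thousands of transforms on one
grid.

Normalization is amplitude-preserving: a unit-amplitude in-band tone
has unit coefficient modulus at its ridge, independent of the sampling
rate, so WA reads in the signal's concentration units and WA computed
at 10 Hz and at 5 Hz on the same waveform agrees within 5% (tested).

WA per channel = mean of |coefficients| over time, then over the band
frequencies, in that order (the alternative ordering differs only in
how frequencies with unequal valid-sample counts are weighted and is
exposed as the `average` argument). Samples inside the cone of
influence — closer to an edge than the e-folding time √2·s of the
scale-s wavelet — are excluded by default. A 600-s state keeps ≈330 s
of valid samples at 0.01 Hz; states must span at least five 0.01-Hz
cycles (≥500 s) to be analyzed at all, an overridable validity gate.

Regional WA is the mean over the region's channels for activation
reporting and the sum for the LI; the two satisfy sum = mean × n.

## Lateralization index

LI = (ΣWA_C − ΣWA_I)/(ΣWA_C + ΣWA_I) per homologous region pair,
bounded in [−1, +1], antisymmetric under C↔I exchange and invariant to
common rescaling. When both sums are zero the LI is undefined and is
reported as missing rather than 0, so downstream statistics exclude it
explicitly instead of averaging in a fabricated balance value.

## Wavelet phase coherence and surrogates

At each band frequency the coherence is the resultant length of the
wavelet phase difference over valid time samples,
R(f) = √(⟨cos Δφ⟩² + ⟨sin Δφ⟩²); WPCO is R(f) averaged over the band.
Identical inputs give exactly 1; the estimator ignores amplitudes
entirely, so it is invariant to rescaling of either series.

Slow narrowband signals have few independent phase patches in 600 s,
so the no-coupling null of WPCO is far from zero (≈0.3 at these
durations). Significance therefore uses amplitude-adjusted Fourier
transform (AAFT) surrogates: 50 per pair, built for one member while
the other stays original (both-sided surrogacy is a config option),
threshold = surrogate mean + 2 SD. AAFT reassigns the original sorted
values by the ranks of a phase-randomized gaussianized copy, so the
surrogate's value distribution is exactly the original's and its
spectrum approximately so. Degenerate cases (constant series, zero
surrogate spread) are reported as inapplicable, not as a flag.

Region-level connectivity uses channel-mean region signals computed
before the transform (per-channel-pair averaging is available behind
a flag); all 91 unordered pairs of the 14 effective regions are
evaluated, and a region failing the quality checks has its row/column
marked missing. Per-pair surrogate transforms are computed once per
"first" region and reused across its partners, which cuts the
surrogate cost by an order of magnitude without changing any value.
Significance is per-pair with no correction across the 91 pairs
(mirroring the mean+2SD convention); a family-wise option exists but
is off by default.

## Group statistics

Within each group, rest vs. training is compared per region (WA, LI)
or region pair (WPCO) with a one-way ANOVA treating the two states as
independent groups — the literal design this pipeline reproduces, even
though the states come from the same subjects. A paired alternative
(squared paired-t, equivalent F) sits behind the `paired` flag with
this caveat documented. Kolmogorov–Smirnov normality (against a fitted
normal) and Levene homogeneity checks are computed and reported per
comparison but advisory only: they never gate the ANOVA, because no
fallback rule is part of the design. Significance uses α/m with
α = 0.05 and m = 3 metric families, reported at 4 decimals (0.0167)
while comparisons use the raw quotient. Under the null the
per-comparison rejection rate matches that threshold (tested at 2000
simulated comparisons).

## Synthetic data: what it emulates, and what it does not

Each synthetic subject has a 600-s rest and a 600-s training state at
10 Hz. Per effective region, the "neural" signal is a 0.01–0.08 Hz
band-limited Gaussian process — a random-phase oscillator rather than
a fixed sinusoid, so AAFT surrogates and the WPCO null behave as with
real data. The realized RMS is normalized within each state so planted
amplitudes and training gains are exact per realization, not just in
expectation. Defaults (µM): neural 0.3 with 20% between-subject
lognormal spread, Mayer wave 0.15 at 0.1 Hz, respiratory 0.1 at
0.25 Hz, cardiac 0.2 at 1 Hz (all with slow Brownian phase wander),
1/f background 0.05, channel white noise 0.03, drift 0.2, motion
spikes of ~1.5 µM at 0.5/min. ΔHHb = −1/3 × ΔO2Hb lagged 1 s plus
independent noise, the usual anti-correlated convention; all of these
are config fields.

Ground-truth handles: `training_gain` multiplies a region's
neural-band amplitude during training (smooth 5-s ramp at the state
boundary); `coupling` (a, b, κ) gives region b region a's narrowband
phase plus a slowly varying (15-s knots) von-Mises(0, κ) jitter —
WPCO rises monotonically with κ, and κ = 0 is indistinguishable from
no coupling. MMT grades cycle through each group's admissible values
and lesion sides alternate so both remapping branches are exercised.
Everything is a deterministic function of (seed, subject index).

The generator does not model: biophysical hemodynamics
(balloon/Windkessel), superficial/scalp contamination or
short-channel physiology, optode-coupling drift, inter-regional
anatomical distance effects, or realistic spatial noise correlation
beyond shared systemic components. Passing recovery tests therefore
demonstrates estimator correctness under the assumed signal structure,
not clinical validity on patient recordings.

## Problem sizes and numerical choices

Validation suites use 600-s states at 10 Hz (the study duration),
50-surrogate ensembles, 100-repetition error-rate runs, and 20-cohort
replicates of 10 subjects for the planted-activation check; cohort
replicate runs use the ΔO2Hb chromophore, 8 voices per octave, and
skip ICA and the WPCO stage, since the quantity under test is the WA
comparison. Recovery of a planted WA gain is assessed as the mean
training/rest ratio over independent region realizations because a
single 600-s realization of a 0.01–0.08 Hz process carries ≈9%
intrinsic estimator spread. The per-region false-flag rate of
unmodulated regions is compared with the nominal per-comparison level
(13 null regions at 0.0167 imply ≈20% of replicates show some chance
flag family-wise, which is the expected behavior of per-comparison
thresholds, not a defect).

Seeds: every stochastic stage (ICA, surrogates, generation) draws from
a generator derived from the run seed and stable stage labels, so
reruns are byte-identical and no stage consumes another's stream.

## Known limitations

- The ANOVA treats repeated-measures states as independent groups by
  design fidelity; statistical power and error rates inherit that
  choice unless `paired` is enabled.
- The automated ICA retention criterion is a proxy for expert visual
  inspection; on real data the 0.5 band-power threshold may retain
  mixed components and should be reviewed via the `ComponentReport`.
- WPCO is undirected and time-averaged; no directionality, lag, or
  dynamic connectivity is estimated.
- The channel→region fixture is a plausible 10/10-based assignment
  with the declared counts, not digitized coordinates.
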