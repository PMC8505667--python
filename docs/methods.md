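# Methods

## Signal model and preprocessing

A continuous-wave fNIRS channel measures light attenuation at 760 and
850 nm between one source and one detector 3 cm apart. The modified
Beer–Lambert law links the optical-density change at wavelength λ to the
chromophore concentration changes:

    ΔOD_λ(t) = (ε_λ,HbO2 ΔHbO2(t) + ε_λ,HHb ΔHHb(t)) · d · DPF_λ

with d the optode distance (cm) and DPF the differential pathlength factor
(5.286 at 760 nm, 4.2238 at 850 nm — age-appropriate values for neonates).
Optical density is referenced to the channel's mean intensity,
OD(t) = −log10(I(t)/mean(I)). Because intensities only determine
concentration *changes* relative to an arbitrary baseline, the inversion
recovers each channel's time course up to an additive constant; round-trip
validation therefore compares mean-removed signals. Extinction
coefficients default to the widely used compiled values at 760/850 nm in
1/(mM·cm); concentrations are reported in µM.

Band-pass filtering (0.01–0.3 Hz) removes slow drift and cardiac
(~2.5 Hz in neonates) and respiratory (~0.7 Hz) oscillations while keeping
the Mayer-wave band (~0.1 Hz) and the stimulus-driven hemodynamics. The
filter is a 3rd-order Butterworth applied forward–backward (zero phase), so
filtering does not shift the signal against stimulus regressors. The
0.01 Hz corner has a very long impulse response; reflection padding of
3/low seconds suppresses edge transients. Filtering is idempotent in the
flat interior of the passband; at the band edges each pass re-applies the
rolloff, which is inherent to any finite-order realization.

Motion artifacts are detected per channel with a centred moving standard
deviation (window 1 s): samples whose moving SD exceeds 3× the channel's
median moving-SD level, padded by 0.5 s of context, are flagged and
replaced by a cubic spline anchored on the surrounding clean samples;
flagged stretches touching the recording edge are held at the nearest
clean value instead of extrapolating. Unflagged samples are never
modified. Motion repair runs after filtering, matching the stated
processing order of the acquisition protocol this reproduces; the original
description does not fix filter family, order, or the order of the two
steps, so these are package choices.

## Musical features and regressors

Twenty-four features summarise the excerpt: 19 short-term series (25 ms
Hann windows, 50% hop) — zero-crossing rate, spectral centroid / spread /
roll-off (85%) / entropy / flatness, Sethares roughness over the 15
strongest spectral peaks, half-wave-rectified spectral flux (full band and
in 10 octave-spaced sub-bands ending at Nyquist), and frame RMS — and 5
long-term series (1 s windows, 50% hop): mode and key clarity from
Krumhansl–Kessler profile correlations on a 12-bin chromagram (key clarity
= best-key correlation; mode = best-major − best-minor), pulse clarity
(strongest normalised autocorrelation peak of the onset envelope in the
0.125–0.75 s lag range), event density (detected onsets per second), and
the metrical centroid (centroid of the onset-envelope periodicity spectrum
over 0.5–10 Hz, in Hz). Spectral flatness is computed on the magnitude
spectrum, for which white noise sits near 0.85 and a pure tone near 0.
The hop is 50% for both window lengths.

A regressor is built per feature by linear-interpolation resampling onto
the fNIRS clock, z-scoring, causal convolution with a peak-normalised
double-gamma HRF (peak delay 6 s, undershoot delay 16 s, dispersions 1 s,
undershoot ratio 1/6, kernel 32 s), and z-scoring again. Pearson
correlation is scale-invariant, so the z-score convention only fixes
numerics; constant features yield a flagged degenerate regressor that
downstream stages mark invalid rather than correlate.

## Activation inference

For each subject, Pearson r between every regressor and every channel
forms a 24 × 19 map. Fisher's z = atanh(r) has null variance 1/(df − 3);
because both regressor (HRF smoothing) and signal (band-pass, physiology)
are serially correlated, df is the Bartlett effective sample size

    df_eff = N / (1 + 2 Σ_{l=1..N/4} ρx(l) ρy(l)),

floored at 5 and capped at N (a nominal-df mode is selectable). The
normalised statistic z·√(df−3) is standard normal under the null and gives
a two-tailed p. Subject p maps combine per cell via Fisher's method,
T = −2 Σ ln pᵢ ~ χ²(2k); the activation mask applies the upper-α quantile
(α = 0.01 by default, critical value 37.57 at k = 10). No further
multiple-testing correction is applied by default, matching the original
design; Bonferroni over cells is available in the stats module.

Known limitation: regressors with very long plateaus (event density is the
extreme case — integer counts per second, constant for seconds at a time)
have autocorrelation extending beyond the N/4 lag cap, so their effective
df is slightly optimistic and they sit closest to the false-positive
budget. The cohort-level false-positive rate over non-planted channels
still calibrates below 3% at α = 0.01 in the validation suite.

## Connectivity

Homotopic (left–right) connectivity per region: each symmetric channel
pair's Pearson r is Fisher z-transformed (|r| clamped to 1 − 1e−7 so
degenerate perfect correlations stay finite), averaged over the region's
pairs (4 frontal, 3 temporal) within subject, averaged across subjects,
and back-transformed to the group r.

Edge-count networks: pair categories are IntraC-I (within-ROI pairs pooled
per hemisphere, C(4,2)+C(3,2) = 9 per side), IntraC-II (frontal × temporal
within a hemisphere, 12 per side), InterC-III (all pairs between symmetric
ROIs — symmetric and asymmetric alike — 16 frontal, 9 temporal), and
InterC-IV (asymmetric ROI pairs across hemispheres, 12 each). The
correlation matrix is binarised at each threshold of the inclusive grid
0.40…0.90 step 0.05 (11 levels) with strict inequality r > t; negative
correlations never form edges. Counts are therefore non-increasing in the
threshold for every subject, a property the test suite asserts wholesale.
Whether within-ROI pairs should be pooled per hemisphere or analysed per
ROI is not fixed by the source design; pooling is the default here because
the category scheme distinguishes within-ROI from cross-ROI connectivity.

## Group statistics

Implemented from their standard formulas so branch behaviour is explicit:
Kruskal–Wallis H with tie correction (p from χ²(g−1)); Wilcoxon
signed-rank with the exact conditional null distribution of W+ (dynamic
programming over the observed, possibly tied, ranks) for n ≤ 25 and a
continuity- and tie-corrected normal approximation above, reporting
W = min(W+, W−); and a split-plot repeated-measures ANOVA with the
threshold levels as the within factor and group as the between factor.
Sphericity is assessed with Mauchly's test on the orthonormal-contrast
covariance pooled within groups (error df N − g); when rejected at 0.05 —
or untestable because subjects ≤ levels — the Greenhouse–Geisser epsilon
(eigenvalue form) deflates both within-factor dfs. Bonferroni-adjusted
pairwise group comparisons on subject means run when the omnibus
between-group F is significant and there are at least three groups. The
between-group F equals the squared two-sample t on subject means, an
identity the tests exploit as an oracle. F statistics, df pairs and
epsilons agree with pingouin's mixed ANOVA to machine precision on shared
fixtures; Mauchly's W and χ² agree exactly (the p-value uses the standard
first-order χ² approximation).

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for all validation: a
19-channel montage at 8.9286 Hz, 3-minute segments, cohorts of 10 per
group.

*Audio* is a stream of harmonic tone events (diatonic pitches over three
octaves, 5 partials with 1/h^1.3 rolloff, 10 ms attack and exponential
decay, inter-onset intervals 0.15–0.5 s), which makes all 24 features
non-constant. It emulates note-level structure, not real instrumentation,
reverberation or expressive timing.

*Noise* per channel combines white noise (SD 1), cardiac (2.5 Hz, amp
0.5), respiration (0.7 Hz, amp 0.8) and Mayer-wave (0.1 Hz, amp 0.6)
oscillations with ±5% frequency jitter and random phase, linear drift
(0.02/s scale, random sign), and Poisson motion spikes (0.5/min, half-sine,
8× the clean SD, 0.2–0.5 s). Frequencies follow neonatal physiology; the
amplitudes are fixed package choices.

*Stimulus recordings* add a·regressor to the noise on target channels,
with a solved per channel from the realised sample moments of the
band-passed regressor and noise so the in-band Pearson correlation equals
the target exactly on that realisation (an empirical calibration —
band-pass filtering alters any analytic SNR-to-r mapping).

*Resting recordings* impose ROI-block structure (within-ROI,
within-hemisphere, symmetric- and asymmetric-interhemispheric targets) on
the in-band correlation matrix. Three design points matter. First, a
3-minute record holds so few independent low-frequency cycles that a
population-correlated latent process would realise correlations scattered
±0.2 around target; the structure is therefore imposed on the *realised*
series (whiten the sample covariance, re-colour with the target matrix).
Second, the latent lives on Fourier bins in 0.03–0.15 Hz — the flat
interior of the analysis band — so downstream zero-phase filtering is
near-identity on it and preserves the imposed covariance (the support
widens automatically for recordings shorter than ~3 min so it still spans
the channel count, and generation refuses records too short to do so).
Third, the quasi-periodic Mayer component of the independent noise is
residualised against the latent basis, because its realised correlation
with any narrowband series would not average out. The independent noise
dilutes the imposed correlation by c²/(1+c²) with c = 5 (targets are
pre-divided by this factor), and target matrices that are not positive
semidefinite after that adjustment are rejected. Correlation targets are
therefore statements about the band-passed signals — which is where the
analysis operates — not about raw samples. The generator does not model
scalp/skull partial-volume effects, optode-coupling physics, or spatially
continuous correlation falloff.

*Dual-wavelength synthesis* pushes HbO2/HHb through the forward
Beer–Lambert system to strictly positive intensities around a baseline
count level, enabling end-to-end validation of the preprocessing chain.

All generators are pure functions of their arguments and an integer seed.

## Validation problem sizes

The validation suite uses cohorts of 10 subjects and 3-minute segments for
the planted-activation study (50 replicate cohorts; planted r = 0.5 at
channel 13), 20 seeds for block-covariance recovery, and 100 replicate
null cohorts with a 5-level threshold grid (0.4…0.8 step 0.1) for the
type-I-error check of the connectivity + ANOVA chain; these sizes give
stable pass/fail margins while keeping the whole suite under a few
minutes. Because features from a single excerpt are mutually correlated,
planting one feature's regressor on a channel genuinely activates
correlated features there; the false-positive budget is therefore assessed
over cells on non-planted channels.
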