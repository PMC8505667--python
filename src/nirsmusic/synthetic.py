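"""Synthetic audio and fNIRS recordings with known embedded structure.

Every downstream stage of the pipeline is exercised against recordings whose
ground truth is planted here:

* :func:`gen_audio` builds a stream of harmonic tone events (randomised
  diatonic pitch, amplitude and inter-onset interval) so that all 24 musical
  features vary over time.
* :func:`gen_stimulus_recording` plants an HRF-convolved feature regressor
  at chosen channels at a chosen in-band Pearson correlation, on top of
  physiological noise (cardiac ~2.5 Hz, respiration ~0.7 Hz, Mayer wave
  ~0.1 Hz -- neonatal rates), slow drift, motion spikes, and white noise.
  The regressor gain is calibrated on the realised noise so the band-passed
  (0.01-0.3 Hz) correlation matches the target.
* :func:`gen_resting_recording` imposes ROI-block structure on the in-band
  inter-channel correlation matrix (within-ROI, within-hemisphere,
  symmetric-ROI and asymmetric-ROI targets).
* :func:`gen_dual_wavelength` pushes HbO2/HHb concentration changes through
  the forward Beer-Lambert model to raw dual-wavelength intensities, so the
  preprocessing chain can be validated by round-trip.

All generators are pure functions of their arguments and an integer seed.
Correlation targets refer to the band-passed signals: connectivity and
activation always operate on filtered data, so the ground truth is stated
where it is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    Condition,
    DEFAULT_SAMPLING_RATE,
    Montage,
    Recording,
    RoiSet,
    SignalKind,
)
from .features import AudioClip
from .preprocess import MbllParams, bandpass_array, mbll_forward

__all__ = [
    "NoiseSpec",
    "StimulusSpec",
    "RestingSpec",
    "gen_audio",
    "gen_stimulus_recording",
    "gen_resting_recording",
    "gen_dual_wavelength",
]

_BAND = (0.01, 0.3)  # Hz, the analysis band the correlation targets refer to


@dataclass
class NoiseSpec:
    """Physiological + instrumental noise model (neonatal defaults)."""

    cardiac: tuple[float, float] = (2.5, 0.5)       # (Hz, amplitude)
    respiration: tuple[float, float] = (0.7, 0.8)
    mayer: tuple[float, float] = (0.1, 0.6)
    drift_slope: float = 0.02                        # amplitude per second
    spike_rate: float = 0.5                          # events per minute
    spike_amplitude: float = 8.0                     # multiples of clean SD
    white_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cardiac", "respiration", "mayer"):
            f, a = getattr(self, name)
            if f <= 0:
                raise ValueError(f"{name} frequency must be positive")
            if a < 0:
                raise ValueError(f"{name} amplitude must be non-negative")
        if min(self.spike_rate, self.spike_amplitude, self.white_sd) < 0:
            raise ValueError("rates, amplitudes and SDs must be non-negative")


@dataclass
class StimulusSpec:
    """Ground truth for a stimulus recording: where and how strongly the
    music regressor is planted."""

    target_channels: list[int] = field(default_factory=list)
    feature_name: str = ""
    target_correlation: float = 0.5
    noise_model: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if not -1 < self.target_correlation < 1:
            raise ValueError("|target_correlation| must be below 1")
        if not self.target_channels and self.target_correlation != 0:
            raise ValueError("nonzero target_correlation needs target channels")


@dataclass
class RestingSpec:
    """Block-correlation targets for a resting recording.

    ``roi_block_correlation`` keys: 'within_roi', 'intra_hemisphere',
    'inter_symmetric', 'inter_asymmetric'; missing keys default to 0.
    """

    roi_block_correlation: dict = field(default_factory=dict)
    duration: float = 180.0  # s
    noise_model: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        for k, v in self.roi_block_correlation.items():
            if not 0 <= v < 1:
                raise ValueError(f"block target {k}={v} must lie in [0, 1)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _sine(n: int, fs: float, freq: float, amp: float, rng: np.random.Generator,
          jitter: float = 0.05) -> np.ndarray:
    f = freq * (1.0 + jitter * rng.uniform(-1, 1))
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * f * t + phase)


def _noise_channel(n: int, fs: float, spec: NoiseSpec,
                   rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    x = rng.normal(0.0, spec.white_sd, size=n)
    x += _sine(n, fs, *spec.cardiac, rng)
    x += _sine(n, fs, *spec.respiration, rng)
    x += _sine(n, fs, *spec.mayer, rng)
    x += spec.drift_slope * rng.uniform(-1, 1) * t
    clean_sd = max(x.std(), 1e-12)
    n_spikes = rng.poisson(spec.spike_rate * (n / fs) / 60.0)
    for _ in range(n_spikes):
        width = int(rng.uniform(0.2, 0.5) * fs)
        start = rng.integers(0, max(1, n - width))
        bump = np.sin(np.pi * np.arange(width) / width)  # half-sine spike
        sign = rng.choice([-1.0, 1.0])
        x[start:start + width] += sign * spec.spike_amplitude * clean_sd * bump
    return x


def gen_audio(duration: float, sample_rate: int = 22050, seed: int = 0) -> AudioClip:
    """A stream of harmonic tone events with randomised pitch, envelope and
    inter-onset interval; deterministic given the seed."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate < 8000:
        raise ValueError("sample_rate must be at least 8000 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    out = np.zeros(n)
    # C major diatonic pitches over three octaves
    scale_midi = [m for octave in (48, 60, 72) for m in
                  (octave, octave + 2, octave + 4, octave + 5,
                   octave + 7, octave + 9, octave + 11)]
    t_onset = 0.05
    while t_onset < duration - 0.05:
        midi = int(rng.choice(scale_midi))
        f0 = 440.0 * 2 ** ((midi - 69) / 12.0)
        note_dur = rng.uniform(0.15, 0.6)
        amp = rng.uniform(0.3, 1.0)
        n_note = int(note_dur * sample_rate)
        start = int(t_onset * sample_rate)
        n_note = min(n_note, n - start)
        if n_note <= 0:
            break
        tt = np.arange(n_note) / sample_rate
        env = np.minimum(tt / 0.01, 1.0) * np.exp(-tt / (note_dur / 3.0))
        tone = np.zeros(n_note)
        for h in range(1, 6):
            if h * f0 < sample_rate / 2:
                tone += (h ** -1.3) * np.sin(2 * np.pi * h * f0 * tt
                                             + rng.uniform(0, 2 * np.pi))
        out[start:start + n_note] += amp * env * tone
        t_onset += rng.uniform(0.15, 0.5)
    peak = np.max(np.abs(out)) or 1.0
    out = 0.5 * out / peak
    out += rng.normal(0.0, 1e-4, size=n)  # low noise floor keeps spectra finite
    return AudioClip(samples=out, sample_rate=sample_rate)


def _calibrated_gain(x_band: np.ndarray, n_band: np.ndarray, rho: float) -> float:
    """Gain a with corr(a * x_band + n_band, x_band) equal to rho on the
    realised series (exact solution of the sample-moment quadratic)."""
    if rho == 0:
        return 0.0
    x = x_band - x_band.mean()
    m = n_band - n_band.mean()
    cxx = float(x @ x)
    cxn = float(x @ m)
    cnn = float(m @ m)
    q = 1.0 - rho ** 2
    a_coef = cxx ** 2 * q
    b_coef = 2.0 * cxx * cxn * q
    c_coef = cxn ** 2 - rho ** 2 * cxx * cnn
    disc = max(b_coef ** 2 - 4 * a_coef * c_coef, 0.0)
    roots = [(-b_coef + math.sqrt(disc)) / (2 * a_coef),
             (-b_coef - math.sqrt(disc)) / (2 * a_coef)]

    def realised(a: float) -> float:
        num = a * cxx + cxn
        den = math.sqrt(max(a * a * cxx + 2 * a * cxn + cnn, 1e-300) * cxx)
        return num / den

    return min(roots, key=lambda a: abs(realised(a) - rho))


def gen_stimulus_recording(regressor, spec: StimulusSpec, montage: Montage,
                           duration: float, seed: int = 0,
                           sampling_rate: float | None = None) -> Recording:
    """HbO2 recording whose target channels carry the regressor at the
    requested in-band correlation; other channels carry noise only."""
    fs = sampling_rate or getattr(regressor, "sampling_rate", DEFAULT_SAMPLING_RATE)
    n = int(round(duration * fs))
    x = np.asarray(regressor.values, float)
    if len(x) != n:
        raise ValueError(f"regressor length {len(x)} != duration * rate = {n}")
    bad = [c for c in spec.target_channels if c not in montage.channel_ids]
    if bad:
        raise ValueError(f"target channels {bad} not in montage")
    rng = np.random.default_rng(seed)
    x_band = bandpass_array(x, fs, *_BAND)
    data = np.empty((n, montage.n_channels))
    targets = set(spec.target_channels)
    for idx, cid in enumerate(montage.channel_ids):
        noise = _noise_channel(n, fs, spec.noise_model, rng)
        if cid in targets and spec.target_correlation != 0:
            n_band = bandpass_array(noise, fs, *_BAND)
            gain = _calibrated_gain(x_band, n_band, spec.target_correlation)
            data[:, idx] = gain * x + noise
        else:
            data[:, idx] = noise
    return Recording(data=data, sampling_rate=fs, kind=SignalKind.hbo2,
                     condition=Condition.stimulus)


_BLOCK_KEYS = ("within_roi", "intra_hemisphere", "inter_symmetric", "inter_asymmetric")


def _target_matrix(spec: RestingSpec, montage: Montage, roiset: RoiSet) -> np.ndarray:
    targets = {k: float(spec.roi_block_correlation.get(k, 0.0)) for k in _BLOCK_KEYS}
    unknown = set(spec.roi_block_correlation) - set(_BLOCK_KEYS)
    if unknown:
        raise ValueError(f"unknown block keys: {sorted(unknown)}")
    ids = montage.channel_ids
    pos = {cid: i for i, cid in enumerate(ids)}
    r = np.eye(len(ids))
    roi_of = {}
    for name, chans in roiset.rois.items():
        for c in chans:
            roi_of[c] = name
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if j <= i:
                continue
            ra, rb = roi_of.get(a), roi_of.get(b)
            if ra is None or rb is None:
                continue
            if ra == rb:
                key = "within_roi"
            else:
                hemi_a, hemi_b = ra[0], rb[0]
                region_a, region_b = ra[2], rb[2]
                if hemi_a == hemi_b:
                    key = "intra_hemisphere"
                elif region_a == region_b:
                    key = "inter_symmetric"
                else:
                    key = "inter_asymmetric"
            r[i, j] = r[j, i] = targets[key]
    return r


def gen_resting_recording(spec: RestingSpec, montage: Montage,
                          roiset: RoiSet | None = None, seed: int = 0,
                          sampling_rate: float = DEFAULT_SAMPLING_RATE) -> Recording:
    """HbO2 resting recording whose band-passed inter-channel correlations
    follow the ROI block targets."""
    if roiset is None:
        from .core import default_roiset
        roiset = default_roiset(montage)
    if spec.duration < 60:
        raise ValueError("duration must be at least 60 s")
    fs = sampling_rate
    n = int(round(spec.duration * fs))
    rng = np.random.default_rng(seed)
    # dilution by independent in-band noise: latent in-band SD is scaled to
    # c times the noise in-band SD, so targets are divided by c^2/(1+c^2)
    c_ratio = 5.0
    dilution = c_ratio ** 2 / (1.0 + c_ratio ** 2)
    r_target = _target_matrix(spec, montage, roiset)
    r_latent = r_target / dilution
    np.fill_diagonal(r_latent, 1.0)
    eig = np.linalg.eigvalsh(r_latent)
    if eig.min() < -1e-10:
        raise ValueError("correlation targets imply a non-positive-semidefinite structure")
    # Band-limiting to 0.01-0.3 Hz leaves few independent low-frequency
    # cycles in a 3-min record, so the realised correlation of a merely
    # population-correlated latent would scatter widely around its target.
    # The block structure is therefore imposed on the realised series:
    # whiten their sample covariance, then re-colour with the target matrix
    # (the empirical calibration the generator promises).  The latent lives
    # on Fourier bins in 0.03-0.15 Hz, the flat interior of the analysis
    # band, so downstream zero-phase filtering is near-identity on it and
    # does not disturb the imposed covariance.
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    # widen the support for short records so the latent spans at least the
    # channel count (each retained bin contributes two degrees of freedom)
    df_bin = fs / n
    hi = min(max(0.15, 0.03 + (montage.n_channels // 2 + 6) * df_bin), 0.27)
    support = (freqs >= 0.03) & (freqs <= hi)
    if 2 * int(support.sum()) <= montage.n_channels:
        raise ValueError("recording too short to span the montage channel count")
    spectrum = np.fft.rfft(rng.standard_normal((n, montage.n_channels)), axis=0)
    spectrum[~support, :] = 0.0
    latent_band = np.fft.irfft(spectrum, n=n, axis=0)
    latent_band = latent_band - latent_band.mean(axis=0, keepdims=True)
    cov = np.cov(latent_band, rowvar=False)
    cov += 1e-10 * np.trace(cov) / len(cov) * np.eye(len(cov))
    white = latent_band @ np.linalg.inv(np.linalg.cholesky(cov)).T
    chol = np.linalg.cholesky(r_latent + 1e-10 * np.eye(len(r_latent)))
    colored = white @ chol.T
    noise = np.column_stack([
        _noise_channel(n, fs, spec.noise_model, rng)
        for _ in range(montage.n_channels)])
    # The quasi-periodic in-band noise (Mayer wave) has so few independent
    # cycles in 3 min that its realised correlation with the latent signals
    # would not average out; project the noise's in-band part off the
    # whitened latent basis so the planted structure is not contaminated.
    nb = bandpass_array(noise, fs, *_BAND)
    nb = nb - nb.mean(axis=0, keepdims=True)
    noise = noise - white @ (white.T @ nb) / (n - 1)
    noise_band_sd = bandpass_array(noise, fs, *_BAND).std(axis=0)
    data = colored * (c_ratio * noise_band_sd) + noise
    return Recording(data=data, sampling_rate=fs, kind=SignalKind.hbo2,
                     condition=Condition.pre_rest)


def gen_dual_wavelength(hbo2: Recording, hhb: Recording,
                        baseline_intensity: float = 1e6,
                        params: MbllParams | None = None
                        ) -> tuple[Recording, Recording]:
    """Forward Beer-Lambert model: concentration changes (uM) to raw
    dual-wavelength intensities around a baseline count level."""
    if baseline_intensity <= 0:
        raise ValueError("baseline intensity must be positive")
    if hbo2.data.shape != hhb.data.shape:
        raise ValueError("HbO2 and HHb recordings must be aligned")
    od760, od850 = mbll_forward(hbo2.data, hhb.data, params)
    i760 = baseline_intensity * 10.0 ** (-od760)
    i850 = baseline_intensity * 10.0 ** (-od850)
    rec760 = hbo2.copy_with(data=i760, kind=SignalKind.intensity_760)
    rec850 = hbo2.copy_with(data=i850, kind=SignalKind.intensity_850)
    return rec760, rec850
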