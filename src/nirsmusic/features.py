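"""Musical feature extraction and hemodynamic regressor construction.

Twenty-four features describe the timbral, dynamic, tonal and rhythmic
content of an audio excerpt.  Short-term features are framed with 25 ms
windows, long-term features with 1 s windows (50% overlap in both cases):

short-term (timbre / other / dynamic)
    zero_crossing, spectral_centroid, spectral_spread, spectral_rolloff,
    spectral_entropy, spectral_flatness, roughness, subband_flux_1..10,
    spectral_flux, rms

long-term (tonal / rhythm)
    mode, key_clarity, pulse_clarity, event_density, metrical_centroid

Tonal features correlate a 12-bin chromagram with the Krumhansl-Kessler key
profiles: key clarity is the best-key correlation and mode is the best-major
minus best-minor correlation.  Rhythm features are read off a spectral-flux
onset envelope: event density counts detected onsets per second, pulse
clarity is the strongest normalised autocorrelation peak of the envelope in
the beat-period range, and the metrical centroid is the centroid of the
envelope's periodicity (fluctuation) spectrum in Hz.

A feature series becomes an fNIRS regressor by linear-interpolation
resampling onto the recording clock, convolution with a canonical
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6, 32 s kernel), and
z-scoring; Pearson correlation downstream is scale-free, so the z-score
convention only stabilises numerics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile
from scipy.stats import gamma as gamma_dist

from .core import DEFAULT_SAMPLING_RATE, Recording

__all__ = [
    "AudioClip",
    "FeatureSeries",
    "HrfParams",
    "Regressor",
    "Term",
    "FeatureCategory",
    "CANONICAL_FEATURES",
    "FEATURE_TERM",
    "FEATURE_CATEGORY",
    "extract_features",
    "resample_series",
    "double_gamma_hrf",
    "make_regressor",
    "load_wav",
    "save_wav",
]


class Term(str, Enum):
    short = "short"
    long = "long"


class FeatureCategory(str, Enum):
    timbre = "timbre"
    other = "other"
    dynamic = "dynamic"
    tonal = "tonal"
    rhythm = "rhythm"


_SHORT = [
    "zero_crossing", "spectral_centroid", "spectral_spread", "spectral_rolloff",
    "spectral_entropy", "spectral_flatness", "roughness",
    *[f"subband_flux_{i}" for i in range(1, 11)],
    "spectral_flux", "rms",
]
_LONG = ["mode", "key_clarity", "pulse_clarity", "event_density", "metrical_centroid"]

CANONICAL_FEATURES: tuple[str, ...] = tuple(_SHORT + _LONG)

FEATURE_TERM = {**{n: Term.short for n in _SHORT}, **{n: Term.long for n in _LONG}}
FEATURE_CATEGORY = {n: FeatureCategory.timbre for n in _SHORT}
FEATURE_CATEGORY["spectral_flux"] = FeatureCategory.other
FEATURE_CATEGORY["rms"] = FeatureCategory.dynamic
FEATURE_CATEGORY.update({"mode": FeatureCategory.tonal, "key_clarity": FeatureCategory.tonal})
FEATURE_CATEGORY.update({n: FeatureCategory.rhythm
                         for n in ("pulse_clarity", "event_density", "metrical_centroid")})

SHORT_WINDOW = 0.025  # s
LONG_WINDOW = 1.0     # s


@dataclass
class AudioClip:
    """A mono audio excerpt."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sample_rate < 8000:
            raise ValueError("sample_rate must be at least 8000 Hz")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class FeatureSeries:
    name: str
    values: np.ndarray
    frame_rate: float
    term: Term
    category: FeatureCategory

    def __post_init__(self) -> None:
        if self.name not in CANONICAL_FEATURES:
            raise ValueError(f"{self.name!r} is not a canonical feature name")
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class HrfParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        for f in ("peak_delay", "undershoot_delay", "peak_dispersion",
                  "undershoot_dispersion", "kernel_length"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be non-negative")


@dataclass
class Regressor:
    """A feature series on the fNIRS clock after HRF convolution (z-scored)."""

    feature_name: str
    values: np.ndarray
    sampling_rate: float
    valid: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


# ---------------------------------------------------------------------------
# audio I/O
# ---------------------------------------------------------------------------

def load_wav(path: str | Path) -> AudioClip:
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioClip(samples=data.astype(float), sample_rate=int(rate))


def save_wav(clip: AudioClip, path: str | Path) -> None:
    peak = np.max(np.abs(clip.samples)) or 1.0
    pcm = np.clip(clip.samples / peak, -1, 1)
    wavfile.write(str(path), clip.sample_rate, (pcm * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# framing helpers
# ---------------------------------------------------------------------------

def _frame(x: np.ndarray, n: int, hop: int) -> np.ndarray:
    """Overlapping frames (n_frames x n); drops the trailing partial frame."""
    if len(x) < n:
        return np.empty((0, n))
    n_frames = 1 + (len(x) - n) // hop
    strides = (x.strides[0] * hop, x.strides[0])
    return np.lib.stride_tricks.as_strided(x, shape=(n_frames, n), strides=strides).copy()


def _magnitude_spectra(frames: np.ndarray, nfft: int) -> np.ndarray:
    win = sps.get_window("hann", frames.shape[1], fftbins=True)
    return np.abs(np.fft.rfft(frames * win, n=nfft, axis=1))


_KK_MAJOR = np.array([6.35, 2.23, 3.48, 2.33, 4.38, 4.09,
                      2.52, 5.19, 2.39, 3.66, 2.29, 2.88])
_KK_MINOR = np.array([6.33, 2.68, 3.52, 5.38, 2.60, 3.53,
                      2.54, 4.75, 3.98, 2.69, 3.34, 3.17])


def _key_correlations(chroma: np.ndarray) -> tuple[float, float]:
    """(best major r, best minor r) over the 12 rotations of the KK profiles."""
    if chroma.std() <= 0:
        return 0.0, 0.0
    c = (chroma - chroma.mean()) / chroma.std()
    best = []
    for profile in (_KK_MAJOR, _KK_MINOR):
        p = (profile - profile.mean()) / profile.std()
        rs = [float(np.dot(c, np.roll(p, k)) / 12.0) for k in range(12)]
        best.append(max(rs))
    return best[0], best[1]


def _sethares_roughness(freqs: np.ndarray, amps: np.ndarray) -> float:
    """Summed pairwise partial dissonance (Plomp-Levelt / Sethares model)."""
    if len(freqs) < 2:
        return 0.0
    order = np.argsort(freqs)
    f, a = freqs[order], amps[order]
    fi, fj = np.meshgrid(f, f, indexing="ij")
    ai, aj = np.meshgrid(a, a, indexing="ij")
    upper = np.triu_indices(len(f), k=1)
    fmin = np.minimum(fi, fj)[upper]
    df = np.abs(fi - fj)[upper]
    s = 0.24 / (0.0207 * fmin + 18.96)
    d = np.exp(-3.5 * s * df) - np.exp(-5.75 * s * df)
    return float(np.sum((ai * aj)[upper] * d))


def _octave_band_edges(nyquist: float, n_bands: int = 10) -> np.ndarray:
    """Octave-spaced band edges ending at Nyquist; lowest band starts at 0."""
    edges = nyquist / (2.0 ** np.arange(n_bands, -1, -1))
    edges[0] = 0.0
    return edges


# ---------------------------------------------------------------------------
# the extractor
# ---------------------------------------------------------------------------

def extract_features(audio: AudioClip) -> list[FeatureSeries]:
    """Extract the 24 canonical feature series from a mono clip (>= 2 s)."""
    if audio.duration < 2 * LONG_WINDOW:
        raise ValueError("audio must be at least 2 s long")
    x = audio.samples.astype(float)
    sr = audio.sample_rate
    eps = 1e-12

    # ---- short-term frames ------------------------------------------------
    n_s = int(round(SHORT_WINDOW * sr))
    hop_s = max(1, n_s // 2)
    frames = _frame(x, n_s, hop_s)
    frame_rate_s = sr / hop_s
    nfft = int(2 ** np.ceil(np.log2(n_s)))
    mag = _magnitude_spectra(frames, nfft)                     # frames x bins
    freqs = np.fft.rfftfreq(nfft, 1.0 / sr)
    power = mag ** 2
    mag_sum = mag.sum(axis=1)
    pow_sum = power.sum(axis=1)
    nz = mag_sum > eps

    centroid = np.zeros(len(frames))
    centroid[nz] = (mag[nz] * freqs).sum(axis=1) / mag_sum[nz]
    spread = np.zeros(len(frames))
    spread[nz] = np.sqrt(
        (mag[nz] * (freqs - centroid[nz, None]) ** 2).sum(axis=1) / mag_sum[nz])

    rolloff = np.zeros(len(frames))
    if nz.any():
        cum = np.cumsum(power[nz], axis=1)
        target = 0.85 * cum[:, -1:]
        rolloff[nz] = freqs[np.argmax(cum >= target, axis=1)]

    entropy = np.zeros(len(frames))
    if nz.any():
        p = power[nz] / pow_sum[nz, None]
        entropy[nz] = -(p * np.log(p + eps)).sum(axis=1) / np.log(mag.shape[1])

    flatness = np.ones(len(frames))
    if nz.any():
        logm = np.log(mag[nz] + eps)
        flatness[nz] = np.exp(logm.mean(axis=1)) / (mag[nz].mean(axis=1) + eps)

    signs = np.signbit(frames)
    zc = np.sum(signs[:, 1:] != signs[:, :-1], axis=1) / (n_s / sr)  # crossings/s

    rms = np.sqrt(np.mean(frames ** 2, axis=1))

    # roughness from the strongest spectral peaks of each frame
    roughness = np.zeros(len(frames))
    for i in np.where(nz)[0]:
        m = mag[i]
        peaks, props = sps.find_peaks(m, height=0.01 * m.max())
        if len(peaks) > 15:
            peaks = peaks[np.argsort(props["peak_heights"])[-15:]]
        roughness[i] = _sethares_roughness(freqs[peaks], m[peaks])

    # spectral flux, full band and in 10 octave-spaced sub-bands
    diff = np.diff(mag, axis=0, prepend=mag[:1])
    rect = np.clip(diff, 0.0, None)
    spectral_flux = rect.sum(axis=1)
    edges = _octave_band_edges(sr / 2.0)
    subband_flux = []
    for b in range(10):
        sel = (freqs >= edges[b]) & (freqs < edges[b + 1] if b < 9 else freqs <= edges[b + 1])
        subband_flux.append(rect[:, sel].sum(axis=1))

    # ---- long-term frames -------------------------------------------------
    n_l = int(round(LONG_WINDOW * sr))
    hop_l = max(1, n_l // 2)
    frames_l = _frame(x, n_l, hop_l)
    frame_rate_l = sr / hop_l
    nfft_l = int(2 ** np.ceil(np.log2(n_l)))
    mag_l = _magnitude_spectra(frames_l, nfft_l)
    freqs_l = np.fft.rfftfreq(nfft_l, 1.0 / sr)

    # chromagram -> key profile correlations
    mode = np.zeros(len(frames_l))
    key_clarity = np.zeros(len(frames_l))
    pitched = (freqs_l >= 55.0) & (freqs_l <= 2093.0)
    pc_of_bin = np.mod(np.round(12 * np.log2(freqs_l[pitched] / 440.0)), 12).astype(int)
    for i in range(len(frames_l)):
        chroma = np.bincount(pc_of_bin, weights=mag_l[i, pitched] ** 2, minlength=12)
        r_maj, r_min = _key_correlations(chroma)
        key_clarity[i] = max(r_maj, r_min)
        mode[i] = r_maj - r_min

    # onset envelope at the short-term frame rate drives the rhythm features
    env = spectral_flux - np.median(spectral_flux)
    env = np.clip(env, 0.0, None)
    min_sep = max(1, int(round(0.05 * frame_rate_s)))
    height = np.mean(env) + np.std(env)
    onset_idx, _ = sps.find_peaks(env, height=height, distance=min_sep)
    onset_times = onset_idx / frame_rate_s

    pulse_clarity = np.zeros(len(frames_l))
    event_density = np.zeros(len(frames_l))
    metrical_centroid = np.zeros(len(frames_l))
    env_per_long = int(round(LONG_WINDOW * frame_rate_s))
    hop_env = env_per_long // 2
    lag_lo = max(1, int(round(0.125 * frame_rate_s)))
    lag_hi = max(lag_lo + 1, int(round(0.75 * frame_rate_s)))
    fluct_freqs = np.fft.rfftfreq(env_per_long, 1.0 / frame_rate_s)
    fluct_sel = (fluct_freqs >= 0.5) & (fluct_freqs <= 10.0)
    for i in range(len(frames_l)):
        t0 = i * hop_env
        seg = env[t0:t0 + env_per_long]
        if len(seg) < lag_hi + 1:
            continue
        t_start, t_end = t0 / frame_rate_s, (t0 + env_per_long) / frame_rate_s
        event_density[i] = np.sum((onset_times >= t_start) & (onset_times < t_end)) / LONG_WINDOW
        segc = seg - seg.mean()
        denom = float(np.dot(segc, segc))
        if denom > eps:
            ac = np.correlate(segc, segc, mode="full")[len(segc) - 1:]
            ac = ac / denom
            pulse_clarity[i] = float(np.clip(ac[lag_lo:lag_hi + 1].max(), 0.0, 1.0))
            spec = np.abs(np.fft.rfft(segc, n=env_per_long))
            num = float((spec[fluct_sel] * fluct_freqs[fluct_sel]).sum())
            den = float(spec[fluct_sel].sum())
            if den > eps:
                metrical_centroid[i] = num / den

    def _fs(name: str, values: np.ndarray, rate: float) -> FeatureSeries:
        return FeatureSeries(name=name, values=values, frame_rate=rate,
                             term=FEATURE_TERM[name], category=FEATURE_CATEGORY[name])

    out = [
        _fs("zero_crossing", zc, frame_rate_s),
        _fs("spectral_centroid", centroid, frame_rate_s),
        _fs("spectral_spread", spread, frame_rate_s),
        _fs("spectral_rolloff", rolloff, frame_rate_s),
        _fs("spectral_entropy", entropy, frame_rate_s),
        _fs("spectral_flatness", flatness, frame_rate_s),
        _fs("roughness", roughness, frame_rate_s),
    ]
    out += [_fs(f"subband_flux_{b + 1}", subband_flux[b], frame_rate_s) for b in range(10)]
    out += [
        _fs("spectral_flux", spectral_flux, frame_rate_s),
        _fs("rms", rms, frame_rate_s),
        _fs("mode", mode, frame_rate_l),
        _fs("key_clarity", key_clarity, frame_rate_l),
        _fs("pulse_clarity", pulse_clarity, frame_rate_l),
        _fs("event_density", event_density, frame_rate_l),
        _fs("metrical_centroid", metrical_centroid, frame_rate_l),
    ]
    assert [f.name for f in out] == list(CANONICAL_FEATURES)
    return out


# ---------------------------------------------------------------------------
# regressors
# ---------------------------------------------------------------------------

def resample_series(fs: FeatureSeries, n_target: int,
                    rate_target: float) -> FeatureSeries:
    """Linear-interpolation resampling onto n_target uniform points,
    preserving the endpoints."""
    if n_target < 2:
        raise ValueError("n_target must be at least 2")
    if len(fs.values) == 0:
        raise ValueError("cannot resample an empty series")
    src = np.linspace(0.0, 1.0, len(fs.values))
    dst = np.linspace(0.0, 1.0, n_target)
    vals = np.interp(dst, src, fs.values)
    return FeatureSeries(name=fs.name, values=vals, frame_rate=rate_target,
                         term=fs.term, category=fs.category)


def double_gamma_hrf(params: HrfParams | None = None,
                     rate: float = DEFAULT_SAMPLING_RATE) -> np.ndarray:
    """Peak-normalised double-gamma HRF kernel sampled at ``rate`` Hz."""
    params = params or HrfParams()
    if rate <= 0:
        raise ValueError("rate must be positive")
    t = np.arange(0.0, params.kernel_length, 1.0 / rate)
    peak = gamma_dist.pdf(t, a=params.peak_delay / params.peak_dispersion,
                          scale=params.peak_dispersion)
    under = gamma_dist.pdf(t, a=params.undershoot_delay / params.undershoot_dispersion,
                           scale=params.undershoot_dispersion)
    h = peak - params.undershoot_ratio * under
    return h / np.max(h)


def _zscore(x: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = x.std()
    if sd <= 0:
        return np.zeros_like(x), False
    return (x - x.mean()) / sd, True


def make_regressor(fs: FeatureSeries, rec: Recording,
                   hrf: HrfParams | None = None) -> Regressor:
    """Resample a feature to the recording clock, convolve with the HRF and
    z-score.  Constant (degenerate) features yield a flagged all-zero
    regressor that downstream correlation treats as invalid."""
    resampled = resample_series(fs, rec.n_samples, rec.sampling_rate)
    vals, ok = _zscore(resampled.values)
    if not ok:
        warnings.warn(f"feature {fs.name!r} is constant; regressor marked invalid")
        return Regressor(fs.name, np.zeros(rec.n_samples), rec.sampling_rate, valid=False)
    kernel = double_gamma_hrf(hrf, rec.sampling_rate)
    conv = np.convolve(vals, kernel)[: rec.n_samples]
    conv, ok = _zscore(conv)
    return Regressor(fs.name, conv, rec.sampling_rate, valid=ok)
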