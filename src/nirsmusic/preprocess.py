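"""fNIRS preprocessing: modified Beer-Lambert conversion, band-pass filtering,
and moving-SD + spline motion-artifact repair.

The conversion chain is raw dual-wavelength intensity -> optical density (OD)
-> HbO2 / HHb concentration change.  The modified Beer-Lambert law relates the
OD change at wavelength lambda to the chromophore concentration changes:

    dOD_lambda = (eps_lambda,HbO2 * dHbO2 + eps_lambda,HHb * dHHb) * d * DPF_lambda

with d the source-detector distance (cm) and DPF the differential pathlength
factor.  Inverting the 2x2 extinction system per sample and channel yields the
concentration changes, reported here in micromolar (uM).

Band-pass filtering (default 0.01-0.3 Hz) removes slow drift and the cardiac /
respiratory oscillations; it is realised as a 3rd-order Butterworth applied
forward-backward so the filter is zero phase and does not shift the signal
relative to stimulus regressors.  Motion spikes are detected with a moving
standard deviation and repaired by cubic-spline interpolation anchored on the
surrounding clean samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .core import (
    ConfigurationError,
    DataError,
    Recording,
    SignalKind,
)

__all__ = [
    "MbllParams",
    "MotionRepairParams",
    "intensity_to_od",
    "mbll_convert",
    "mbll_forward",
    "bandpass",
    "bandpass_array",
    "repair_motion",
]

# Compiled molar extinction coefficients at 760 / 850 nm, 1/(mM*cm).
DEFAULT_EXTINCTION = {
    (760, "hbo2"): 0.5958,
    (760, "hhb"): 1.6745,
    (850, "hbo2"): 1.0507,
    (850, "hhb"): 0.7804,
}


@dataclass
class MbllParams:
    """Extinction coefficients, DPFs and optode distance for the MBLL system."""

    extinction: dict = field(default_factory=lambda: dict(DEFAULT_EXTINCTION))
    dpf: dict = field(default_factory=lambda: {760: 5.286, 850: 4.2238})
    distance: float = 3.0  # cm

    def matrix(self) -> np.ndarray:
        """The 2x2 pathlength-scaled extinction matrix A with
        [dOD760, dOD850]^T = A @ [dHbO2_mM, dHHb_mM]^T."""
        a = np.array([
            [self.extinction[(760, "hbo2")], self.extinction[(760, "hhb")]],
            [self.extinction[(850, "hbo2")], self.extinction[(850, "hhb")]],
        ], dtype=float)
        a[0] *= self.distance * self.dpf[760]
        a[1] *= self.distance * self.dpf[850]
        if abs(np.linalg.det(a)) < 1e-12:
            raise ConfigurationError("extinction matrix is singular")
        return a


@dataclass
class MotionRepairParams:
    window: float = 1.0        # s, moving-SD window
    sd_threshold: float = 3.0  # multiples of the channel's median moving SD
    pad: float = 0.5           # s of context flagged around each detection

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.sd_threshold <= 1:
            raise ValueError("sd_threshold must exceed 1")


_OD_KIND = {SignalKind.intensity_760: SignalKind.od_760,
            SignalKind.intensity_850: SignalKind.od_850}


def intensity_to_od(rec: Recording) -> Recording:
    """Optical density relative to the channel-mean intensity:
    OD(t) = -log10(I(t) / mean(I))."""
    if rec.kind not in _OD_KIND:
        raise ValueError(f"expected a raw intensity recording, got kind={rec.kind.value}")
    bad = rec.data <= 0
    if bad.any():
        t, c = map(int, np.argwhere(bad)[0])
        raise DataError(f"non-positive intensity at sample {t}, channel column {c}")
    od = -np.log10(rec.data / rec.data.mean(axis=0, keepdims=True))
    return rec.copy_with(data=od, kind=_OD_KIND[rec.kind])


def mbll_convert(od_760: Recording, od_850: Recording,
                 params: MbllParams | None = None) -> tuple[Recording, Recording]:
    """Invert the modified Beer-Lambert system per sample and channel.

    Returns (HbO2, HHb) concentration-change recordings in uM.
    """
    params = params or MbllParams()
    if od_760.data.shape != od_850.data.shape:
        raise ValueError("OD recordings must share one shape")
    if od_760.kind != SignalKind.od_760 or od_850.kind != SignalKind.od_850:
        raise ValueError("inputs must be od_760 and od_850 recordings")
    a_inv = np.linalg.inv(params.matrix())
    od = np.stack([od_760.data, od_850.data])          # 2 x T x C
    conc_mM = np.einsum("ij,jtc->itc", a_inv, od)      # 2 x T x C
    conc_uM = conc_mM * 1e3
    hbo2 = od_760.copy_with(data=conc_uM[0], kind=SignalKind.hbo2)
    hhb = od_760.copy_with(data=conc_uM[1], kind=SignalKind.hhb)
    return hbo2, hhb


def mbll_forward(hbo2_uM: np.ndarray, hhb_uM: np.ndarray,
                 params: MbllParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Forward MBLL model: concentration changes (uM) -> (dOD760, dOD850)."""
    params = params or MbllParams()
    a = params.matrix()
    conc_mM = np.stack([np.asarray(hbo2_uM, float), np.asarray(hhb_uM, float)]) * 1e-3
    od = np.einsum("ij,jtc->itc", a, np.atleast_3d(conc_mM))
    return od[0], od[1]


def bandpass_array(data: np.ndarray, fs: float, low: float = 0.01,
                   high: float = 0.3, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0."""
    nyq = fs / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz must lie below Nyquist {nyq:.3f} Hz")
    sos = sps.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    x = np.asarray(data, float)
    # generous odd-reflection padding: the 0.01 Hz corner has a long impulse
    # response and the default padlen leaves visible edge transients
    padlen = int(min(x.shape[0] - 1, round(3.0 * fs / low)))
    return sps.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def bandpass(rec: Recording, low: float = 0.01, high: float = 0.3,
             order: int = 3) -> Recording:
    """Band-pass a recording (default 0.01-0.3 Hz), preserving its length."""
    return rec.copy_with(data=bandpass_array(rec.data, rec.sampling_rate, low, high, order))


def _moving_sd(x: np.ndarray, w: int) -> np.ndarray:
    """Centred moving standard deviation with edge-shrinking windows."""
    n = len(x)
    kernel = np.ones(w)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    s1 = np.convolve(x, kernel, mode="same")
    s2 = np.convolve(x * x, kernel, mode="same")
    var = s2 / counts - (s1 / counts) ** 2
    return np.sqrt(np.clip(var, 0.0, None))


def repair_motion(rec: Recording, params: MotionRepairParams | None = None
                  ) -> tuple[Recording, np.ndarray]:
    """Flag motion spikes by moving SD and repair them by cubic-spline
    interpolation anchored on surrounding clean samples.

    Returns the repaired recording and the boolean artifact mask
    (samples x channels).  Unflagged samples are passed through unchanged.
    """
    params = params or MotionRepairParams()
    fs = rec.sampling_rate
    w = max(3, int(round(params.window * fs)))
    if rec.n_samples <= 3 * w:
        raise ValueError("recording must be longer than 3 x window")
    pad = int(round(params.pad * fs))
    out = rec.data.copy()
    mask = np.zeros(rec.data.shape, dtype=bool)
    idx = np.arange(rec.n_samples)
    for c in range(rec.n_channels):
        x = rec.data[:, c]
        msd = _moving_sd(x, w)
        level = np.median(msd)
        if level <= 0:
            continue
        flagged = msd > params.sd_threshold * level
        if pad > 0 and flagged.any():
            kernel = np.ones(2 * pad + 1)
            flagged = np.convolve(flagged.astype(float), kernel, mode="same") > 0
        if not flagged.any():
            continue
        clean = ~flagged
        if clean.sum() < 4:
            continue  # cannot anchor a cubic spline; leave channel untouched
        spline = CubicSpline(idx[clean], x[clean])
        interior = flagged & (idx > idx[clean][0]) & (idx < idx[clean][-1])
        out[interior, c] = spline(idx[interior])
        # hold nearest clean value at flagged edges instead of extrapolating
        lead = flagged & (idx < idx[clean][0])
        trail = flagged & (idx > idx[clean][-1])
        out[lead, c] = x[clean][0]
        out[trail, c] = x[clean][-1]
        mask[:, c] = flagged
    return rec.copy_with(data=out), mask
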