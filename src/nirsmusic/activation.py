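"""Music-to-hemodynamics activation mapping.

For each subject, every music-feature regressor is Pearson-correlated with
every fNIRS channel, giving a feature x channel r map.  Each r is Fisher
z-transformed, z = atanh(r), whose null sampling variance is 1/(df - 3); the
normalised statistic z * sqrt(df - 3) is standard normal under the null and
is converted to a two-tailed p-value.  Because both the regressor (HRF
smoothing) and the hemodynamic signal are serially correlated, ``df`` is an
effective sample size following the Bartlett correction

    df_eff = N / (1 + 2 * sum_{l=1..L} rho_x(l) * rho_y(l)),   L = N // 4,

floored at 5 and capped at N.  Subject p maps are combined per cell with
Fisher's method, T = -2 * sum_i ln p_i, which under the null follows a
chi-square distribution with 2k degrees of freedom for k subjects; cells
with T above the upper-alpha quantile (37.57 for k = 10, alpha = 0.01) are
declared active.

:class:`GroupActivation` bundles the per-subject stages into a model object
whose :meth:`~GroupActivation.fit` returns a :class:`GroupActivationResults`
with the group T map, activation mask and per-subject maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import Recording
from .features import Regressor

__all__ = [
    "SubjectMaps",
    "GroupTMap",
    "correlate",
    "effective_df",
    "effective_df_map",
    "z_transform",
    "fisher_combine",
    "threshold_activation",
    "subject_maps",
    "GroupActivation",
    "GroupActivationResults",
]

_MIN_DF = 5.0


def correlate(rec: Recording, regressors: list[Regressor]) -> np.ndarray:
    """Pearson r between every regressor and every channel (features x channels).

    Zero-variance channels or invalid regressors yield NaN cells rather than
    raising.
    """
    n = rec.n_samples
    for reg in regressors:
        if len(reg.values) != n:
            raise ValueError(
                f"regressor {reg.feature_name!r} has {len(reg.values)} samples, "
                f"recording has {n}")
    x = np.stack([r.values for r in regressors])              # F x N
    y = rec.data.T                                            # C x N
    xv = x.std(axis=1) > 0
    yv = y.std(axis=1) > 0
    for i, reg in enumerate(regressors):
        xv[i] &= reg.valid
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    yn = np.linalg.norm(yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc.T) / np.outer(xn, yn)
    r[~xv, :] = np.nan
    r[:, ~yv] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def _autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation at lags 0..max_lag via FFT."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(f * np.conj(f))[: max_lag + 1]
    if ac[0] <= 0:
        return np.full(max_lag + 1, np.nan)
    return ac / ac[0]


def effective_df(x: np.ndarray, y: np.ndarray, method: str = "bartlett") -> float:
    """Effective degrees of freedom of the correlation between two serially
    correlated series (Bartlett correction); ``method='nominal'`` returns N."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples")
    if x.std() <= 0 or y.std() <= 0:
        return np.nan
    if method == "nominal":
        return float(n)
    if method != "bartlett":
        raise ValueError(f"unknown method {method!r}")
    lag = n // 4
    rx = _autocorr(x, lag)[1:]
    ry = _autocorr(y, lag)[1:]
    denom = 1.0 + 2.0 * float(np.dot(rx, ry))
    df = float(n) if denom <= 0 else n / denom
    return float(np.clip(df, _MIN_DF, n))


def effective_df_map(rec: Recording, regressors: list[Regressor],
                     method: str = "bartlett") -> np.ndarray:
    """Vectorised effective-df for every feature x channel cell."""
    n = rec.n_samples
    if method == "nominal":
        return np.full((len(regressors), rec.n_channels), float(n))
    lag = n // 4
    px = np.stack([_autocorr(r.values, lag)[1:] if r.valid and r.values.std() > 0
                   else np.full(lag, np.nan) for r in regressors])
    py = np.stack([_autocorr(rec.data[:, c], lag)[1:] if rec.data[:, c].std() > 0
                   else np.full(lag, np.nan) for c in range(rec.n_channels)])
    denom = 1.0 + 2.0 * (px @ py.T)
    df = np.where(denom <= 0, float(n), n / denom)
    df = np.clip(df, _MIN_DF, n)
    df[np.isnan(px).any(axis=1), :] = np.nan
    df[:, np.isnan(py).any(axis=1)] = np.nan
    return df


def z_transform(r_map: np.ndarray, df_map: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fisher z, df-normalised z, and two-tailed p maps.

    z = atanh(r); z_norm = z * sqrt(df - 3) (unit-variance under the null);
    p = two-tailed standard-normal tail probability of z_norm.  Cells with
    df <= 3 or NaN inputs stay NaN.
    """
    r = np.asarray(r_map, float)
    df = np.asarray(df_map, float)
    valid = np.isfinite(r) & np.isfinite(df) & (df > 3)
    z = np.full(r.shape, np.nan)
    z_norm = np.full(r.shape, np.nan)
    p = np.full(r.shape, np.nan)
    rc = np.clip(r[valid], -1 + 1e-15, 1 - 1e-15)
    z[valid] = np.arctanh(rc)
    z_norm[valid] = z[valid] * np.sqrt(df[valid] - 3.0)
    p[valid] = np.clip(2.0 * sstats.norm.sf(np.abs(z_norm[valid])), 1e-300, 1.0)
    return z, z_norm, p


def fisher_combine(p_values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Fisher's combined probability statistic T = -2 * sum ln p.

    Zero p-values are clamped to the smallest positive float (counted on the
    function attribute ``fisher_combine.n_clamped``).
    """
    p = np.asarray(p_values, float)
    n_zero = int(np.sum(p == 0))
    fisher_combine.n_clamped += n_zero
    if n_zero:
        import warnings
        warnings.warn(f"{n_zero} zero p-values clamped before Fisher combination")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return -2.0 * np.sum(np.log(p), axis=axis)


fisher_combine.n_clamped = 0


def threshold_activation(t_map: np.ndarray, k: int, alpha: float = 0.01):
    """Threshold a Fisher T map at the chi-square(2k) upper-alpha quantile."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if k < 2:
        raise ValueError("need at least 2 subjects")
    critical = float(sstats.chi2.ppf(1.0 - alpha, df=2 * k))
    t = np.asarray(t_map, float)
    active = np.zeros(t.shape, dtype=bool)
    finite = np.isfinite(t)
    active[finite] = t[finite] > critical
    return GroupTMap(T=t, k=k, critical_value=critical, active=active, alpha=alpha)


@dataclass
class SubjectMaps:
    """Per-subject feature x channel correlation statistics."""

    subject_id: str
    r_map: np.ndarray
    z_map: np.ndarray
    z_norm_map: np.ndarray
    p_map: np.ndarray
    df_map: np.ndarray


@dataclass
class GroupTMap:
    """Group Fisher-combined T map with its chi-square activation mask."""

    T: np.ndarray
    k: int
    critical_value: float
    active: np.ndarray
    alpha: float = 0.01

    @property
    def df_chi2(self) -> int:
        return 2 * self.k


def subject_maps(rec: Recording, regressors: list[Regressor],
                 df_method: str = "bartlett") -> SubjectMaps:
    """Compute one subject's r/z/p maps against a regressor set."""
    r_map = correlate(rec, regressors)
    df_map = effective_df_map(rec, regressors, method=df_method)
    z, z_norm, p = z_transform(r_map, df_map)
    return SubjectMaps(subject_id=rec.subject_id, r_map=r_map, z_map=z,
                       z_norm_map=z_norm, p_map=p, df_map=df_map)


class GroupActivation:
    """Group activation model: k subjects' stimulus recordings against one
    regressor set.

    Parameters
    ----------
    recordings : per-subject HbO2 recordings (band-passed), equal lengths.
    regressors : music-feature regressors on the recording clock.
    alpha : chi-square activation level (default 0.01).
    df_method : 'bartlett' (autocorrelation-corrected df) or 'nominal'.
    """

    def __init__(self, recordings: list[Recording], regressors: list[Regressor],
                 alpha: float = 0.01, df_method: str = "bartlett"):
        if len(recordings) < 2:
            raise ValueError("need at least 2 subjects")
        n = recordings[0].n_samples
        if any(r.n_samples != n for r in recordings):
            raise ValueError("all recordings must have equal length")
        self.recordings = recordings
        self.regressors = regressors
        self.alpha = alpha
        self.df_method = df_method

    def fit(self) -> "GroupActivationResults":
        maps = [subject_maps(rec, self.regressors, self.df_method)
                for rec in self.recordings]
        p_stack = np.stack([m.p_map for m in maps])           # k x F x C
        t_map = np.where(np.isnan(p_stack).any(axis=0), np.nan,
                         fisher_combine(np.where(np.isnan(p_stack), 1.0, p_stack),
                                        axis=0))
        group = threshold_activation(t_map, k=len(maps), alpha=self.alpha)
        return GroupActivationResults(
            model=self, subject_maps=maps, group=group,
            feature_names=[r.feature_name for r in self.regressors])


@dataclass
class GroupActivationResults:
    """Fitted group activation map."""

    model: GroupActivation
    subject_maps: list[SubjectMaps]
    group: GroupTMap
    feature_names: list[str]
    channel_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.channel_ids:
            self.channel_ids = list(range(1, self.group.T.shape[1] + 1))

    @property
    def t_map(self) -> np.ndarray:
        return self.group.T

    @property
    def active(self) -> np.ndarray:
        return self.group.active

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of T values and activation flags."""
        rows = []
        for i, f in enumerate(self.feature_names):
            for j, c in enumerate(self.channel_ids):
                rows.append({"feature": f, "channel": c,
                             "T": self.group.T[i, j],
                             "active": bool(self.group.active[i, j])})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        act = df[df["active"]].sort_values("T", ascending=False)
        lines = [
            "Group activation (Fisher combined probability)",
            f"  subjects (k):       {self.group.k}",
            f"  chi2 df (2k):       {self.group.df_chi2}",
            f"  alpha:              {self.group.alpha}",
            f"  critical value:     {self.group.critical_value:.2f}",
            f"  active cells:       {len(act)} / {df['T'].notna().sum()}",
        ]
        for _, row in act.head(20).iterrows():
            lines.append(f"    {row['feature']:<20s} ch {int(row['channel']):>2d}  "
                         f"T = {row['T']:.2f}")
        return "\n".join(lines)

    def plot_tmap(self, ax=None):
        """Heat map of the group T matrix with active cells outlined."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 6))
        im = ax.imshow(self.group.T, aspect="auto", cmap="magma")
        ax.set_xlabel("channel")
        ax.set_ylabel("feature")
        ax.set_xticks(range(len(self.channel_ids)), self.channel_ids)
        ax.set_yticks(range(len(self.feature_names)), self.feature_names, fontsize=7)
        ys, xs = np.where(self.group.active)
        ax.scatter(xs, ys, marker="s", s=60, facecolors="none", edgecolors="cyan")
        ax.figure.colorbar(im, ax=ax, label="Fisher T")
        return ax
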