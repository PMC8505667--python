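"""Resting-state functional connectivity over frontal/temporal ROIs.

Two complementary summaries of inter-channel Pearson correlation:

* Left-right (homotopic) correlations: per subject, the correlation of each
  symmetric channel pair in a region is Fisher z-transformed and averaged
  over pairs; per-subject z values are averaged over subjects and
  back-transformed to a group r.

* Edge-count networks: the correlation matrix restricted to a category of
  channel pairs is binarised at each threshold of an inclusive grid
  (default 0.40..0.90 in steps of 0.05, 11 levels; strict inequality
  r > t creates an edge), and edges are counted per subject and threshold.

Pair categories (per hemisphere/side where applicable):

* IntraC-I: pairs within a single ROI, pooled over the hemisphere's two
  ROIs (C(4,2) + C(3,2) = 9 pairs per side).
* IntraC-II: frontal x temporal pairs within one hemisphere (12 per side).
* InterC-III: all pairs between symmetric ROIs of the two hemispheres,
  symmetric and asymmetric alike (frontal 16, temporal 9).
* InterC-IV: pairs between asymmetric ROIs across hemispheres
  (L-F x R-T and L-T x R-F, 12 each).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd

from .core import ConfigurationError, Montage, Recording, Region, RoiSet

__all__ = [
    "CATEGORIES",
    "CategoryPairSet",
    "LeftRightResult",
    "EdgeCountTable",
    "threshold_grid",
    "category_pairs",
    "edge_counts",
    "left_right_correlation",
    "RestingConnectivity",
    "RestingConnectivityResults",
]

# (category, side) keys in canonical order
CATEGORIES: tuple[tuple[str, str], ...] = (
    ("IntraC-I", "left"),
    ("IntraC-I", "right"),
    ("IntraC-II", "left"),
    ("IntraC-II", "right"),
    ("InterC-III", "frontal"),
    ("InterC-III", "temporal"),
    ("InterC-IV", "LF-RT"),
    ("InterC-IV", "LT-RF"),
)

_Z_CLAMP = 1.0 - 1e-7  # |r| clamp before atanh on degenerate inputs


@dataclass
class CategoryPairSet:
    category: str
    side: str
    channel_pairs: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.channel_pairs)


@dataclass
class LeftRightResult:
    """Homotopic correlation of one region, Fisher-averaged over pairs and
    subjects."""

    roi_region: Region
    per_subject_z: np.ndarray
    group_r: float


@dataclass
class EdgeCountTable:
    category: str
    side: str
    thresholds: np.ndarray
    counts: np.ndarray       # subjects x thresholds
    subject_ids: list[str] = field(default_factory=list)
    n_pairs: int = 0


def threshold_grid(start: float = 0.4, stop: float = 0.9,
                   step: float = 0.05) -> np.ndarray:
    """Inclusive arithmetic threshold grid; defaults give the 11-level sweep."""
    if not (start < stop and step > 0):
        raise ValueError("need start < stop and step > 0")
    n_steps = (stop - start) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("step must divide the range exactly")
    n = int(round(n_steps)) + 1
    return np.round(start + step * np.arange(n), 10)


def _roi_pairs(ids: list[int]) -> list[tuple[int, int]]:
    return [tuple(sorted(p)) for p in combinations(sorted(ids), 2)]


def category_pairs(roiset: RoiSet, montage: Montage, category: str,
                   side: str | None = None) -> CategoryPairSet:
    """Enumerate the channel pairs of one connectivity category."""
    lf, rf, lt, rt = roiset["L-F"], roiset["R-F"], roiset["L-T"], roiset["R-T"]
    if category == "IntraC-I":
        if side not in ("left", "right"):
            raise ValueError("IntraC-I needs side 'left' or 'right'")
        f, t = (lf, lt) if side == "left" else (rf, rt)
        pairs = _roi_pairs(f) + _roi_pairs(t)
    elif category == "IntraC-II":
        if side not in ("left", "right"):
            raise ValueError("IntraC-II needs side 'left' or 'right'")
        f, t = (lf, lt) if side == "left" else (rf, rt)
        pairs = [tuple(sorted(p)) for p in product(f, t)]
    elif category == "InterC-III":
        if side not in ("frontal", "temporal"):
            raise ValueError("InterC-III needs side 'frontal' or 'temporal'")
        a, b = (lf, rf) if side == "frontal" else (lt, rt)
        pairs = [tuple(sorted(p)) for p in product(a, b)]
    elif category == "InterC-IV":
        if side not in ("LF-RT", "LT-RF"):
            raise ValueError("InterC-IV needs side 'LF-RT' or 'LT-RF'")
        a, b = (lf, rt) if side == "LF-RT" else (lt, rf)
        pairs = [tuple(sorted(p)) for p in product(a, b)]
    else:
        raise ValueError(f"unknown category {category!r}")
    for a, b in pairs:
        montage.channel(a), montage.channel(b)
    return CategoryPairSet(category=category, side=side, channel_pairs=sorted(pairs))


def _pair_correlations(rec: Recording, pairs: list[tuple[int, int]]) -> np.ndarray:
    data = rec.data
    sd = data.std(axis=0)
    # tolerance absorbs rounding noise on numerically constant channels
    dead = np.where(sd <= 1e-10 * (np.abs(data).mean(axis=0) + 1.0))[0]
    if dead.size:
        warnings.warn(f"zero-variance channel column(s) {dead.tolist()}; "
                      "their pairs contribute no edges")
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = np.corrcoef(data.T)
    dead_ids = {int(d) + 1 for d in dead}
    out = np.array([np.nan if (a in dead_ids or b in dead_ids)
                    else cm[a - 1, b - 1] for a, b in pairs], dtype=float)
    return out


def edge_counts(rec: Recording, pairs: CategoryPairSet,
                thresholds: np.ndarray) -> np.ndarray:
    """Edges (pair correlations strictly above threshold) per threshold."""
    if rec.duration < 60:
        raise ValueError("need at least 60 s of data")
    r = _pair_correlations(rec, pairs.channel_pairs)
    r = r[np.isfinite(r)]
    return np.array([int(np.sum(r > t)) for t in np.asarray(thresholds)])


def left_right_correlation(recs: list[Recording], roiset: RoiSet,
                           montage: Montage, region: Region | str) -> LeftRightResult:
    """Group homotopic correlation of one region (frontal or temporal)."""
    region = Region(region)
    if len(recs) < 2:
        raise ValueError("need at least 2 subjects")
    pairs = montage.pairs_in_region(region)
    expect = {Region.frontal: 4, Region.temporal: 3}.get(region)
    if expect is not None and len(pairs) != expect:
        raise ConfigurationError(
            f"montage has {len(pairs)} symmetric {region.value} pairs, expected {expect}")
    roi_channels = set(roiset.channels())
    for a, b in pairs:
        if not {a, b} <= roi_channels:
            raise ConfigurationError(f"symmetric pair ({a},{b}) outside the ROI set")
    zs = []
    for rec in recs:
        r = _pair_correlations(rec, pairs)
        r = r[np.isfinite(r)]
        if r.size == 0:
            raise ValueError("no usable symmetric-pair correlations for a subject")
        r = np.clip(r, -_Z_CLAMP, _Z_CLAMP)
        zs.append(float(np.mean(np.arctanh(r))))
    per_subject_z = np.array(zs)
    group_r = float(np.tanh(per_subject_z.mean()))
    return LeftRightResult(roi_region=region, per_subject_z=per_subject_z,
                           group_r=group_r)


class RestingConnectivity:
    """Resting-state connectivity model over one cohort of recordings.

    Parameters
    ----------
    recordings : per-subject (band-passed HbO2) resting recordings.
    montage, roiset : channel geometry and ROI membership.
    thresholds : binarisation grid (default the 11-level sweep).
    """

    def __init__(self, recordings: list[Recording], montage: Montage | None = None,
                 roiset: RoiSet | None = None, thresholds: np.ndarray | None = None):
        from .core import default_montage, default_roiset
        self.montage = montage or default_montage()
        self.roiset = roiset or default_roiset(self.montage)
        self.recordings = recordings
        self.thresholds = thresholds if thresholds is not None else threshold_grid()

    def fit(self) -> "RestingConnectivityResults":
        tables = []
        for category, side in CATEGORIES:
            pairs = category_pairs(self.roiset, self.montage, category, side)
            counts = np.stack([edge_counts(rec, pairs, self.thresholds)
                               for rec in self.recordings])
            tables.append(EdgeCountTable(
                category=category, side=side, thresholds=self.thresholds,
                counts=counts, n_pairs=len(pairs),
                subject_ids=[r.subject_id for r in self.recordings]))
        left_right = {
            region: left_right_correlation(self.recordings, self.roiset,
                                           self.montage, region)
            for region in (Region.frontal, Region.temporal)
        } if len(self.recordings) >= 2 else {}
        return RestingConnectivityResults(model=self, edge_tables=tables,
                                          left_right=left_right)


@dataclass
class RestingConnectivityResults:
    model: RestingConnectivity
    edge_tables: list[EdgeCountTable]
    left_right: dict

    def table(self, category: str, side: str) -> EdgeCountTable:
        for t in self.edge_tables:
            if t.category == category and t.side == side:
                return t
        raise KeyError((category, side))

    def to_frame(self) -> pd.DataFrame:
        """Long-format edge counts: subject, category, side, threshold, count."""
        rows = []
        for t in self.edge_tables:
            subjects = t.subject_ids or [str(i) for i in range(t.counts.shape[0])]
            for i, sid in enumerate(subjects):
                for j, thr in enumerate(t.thresholds):
                    rows.append({"subject": sid, "category": t.category,
                                 "side": t.side, "threshold": float(thr),
                                 "count": int(t.counts[i, j])})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Resting-state connectivity",
                 f"  subjects:   {len(self.model.recordings)}",
                 f"  thresholds: {len(self.model.thresholds)} levels "
                 f"[{self.model.thresholds[0]:.2f} .. {self.model.thresholds[-1]:.2f}]"]
        for region, res in self.left_right.items():
            lines.append(f"  left-right r ({region.value}): {res.group_r:+.3f}")
        for t in self.edge_tables:
            mean_lo = t.counts[:, 0].mean()
            lines.append(f"  {t.category:<10s} {t.side:<9s} pairs={t.n_pairs:>2d}  "
                         f"mean edges @ {t.thresholds[0]:.2f}: {mean_lo:.1f}")
        return "\n".join(lines)

    def plot_edge_curves(self, ax=None):
        """Mean edge count vs threshold, one curve per category/side."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        for t in self.edge_tables:
            ax.plot(t.thresholds, t.counts.mean(axis=0), marker="o", ms=3,
                    label=f"{t.category} {t.side}")
        ax.set_xlabel("correlation threshold")
        ax.set_ylabel("mean edge count")
        ax.legend(fontsize=7)
        return ax
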