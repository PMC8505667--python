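"""Core domain types and I/O for infant fNIRS music-therapy analysis.

The package analyses continuous-wave fNIRS recordings taken while preterm
infants listen to music.  This module holds the shared vocabulary: the optode
montage (19 channels over frontal, temporal and parietal cortex, 3 cm
source-detector separation), regions of interest, the :class:`Recording`
container for channel x time matrices, and the pipeline configuration with
the study defaults (8.9286 Hz sampling, 0.01-0.3 Hz pass band, differential
pathlength factors 5.286 / 4.2238 at 760 / 850 nm).

Recordings are plain delimited text (comma or tab), one row per sample and
one column per channel; montage and ROI descriptions are JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "Hemisphere",
    "SignalKind",
    "StudyGroup",
    "Condition",
    "MontageError",
    "ConfigurationError",
    "DataError",
    "ChannelInfo",
    "Montage",
    "RoiSet",
    "Recording",
    "PipelineConfig",
    "ROI_NAMES",
    "default_montage",
    "default_roiset",
    "load_recording",
    "save_recording",
]

DEFAULT_SAMPLING_RATE = 8.9286  # Hz, the instrument's automatic rate


class Region(str, Enum):
    frontal = "frontal"
    temporal = "temporal"
    parietal = "parietal"


class Hemisphere(str, Enum):
    left = "left"
    right = "right"
    midline = "midline"


class SignalKind(str, Enum):
    intensity_760 = "intensity_760"
    intensity_850 = "intensity_850"
    od_760 = "od_760"
    od_850 = "od_850"
    hbo2 = "hbo2"
    hhb = "hhb"


class StudyGroup(str, Enum):
    MTG = "MTG"  # music therapy group
    CG = "CG"    # control group


class Condition(str, Enum):
    pre_rest = "pre_rest"
    stimulus = "stimulus"
    post_rest = "post_rest"


class MontageError(ValueError):
    """Recording geometry does not match the montage."""


class ConfigurationError(ValueError):
    """Inconsistent montage / ROI / parameter configuration."""


class DataError(ValueError):
    """Malformed numeric data in a recording file."""


@dataclass(frozen=True)
class ChannelInfo:
    id: int
    source: int
    detector: int
    region: Region
    hemisphere: Hemisphere

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", Region(self.region))
        object.__setattr__(self, "hemisphere", Hemisphere(self.hemisphere))


@dataclass
class Montage:
    """Channel geometry: source/detector pairing, region and hemisphere labels.

    ``symmetric_pairs`` holds (left_channel_id, right_channel_id) tuples
    joining homotopic channels of the same region; pair membership queries
    are order-insensitive (see :meth:`has_pair`).
    """

    channels: list[ChannelInfo]
    symmetric_pairs: list[tuple[int, int]]
    source_detector_distance: float = 3.0  # cm

    def __post_init__(self) -> None:
        self.channels = [c if isinstance(c, ChannelInfo) else ChannelInfo(**c) for c in self.channels]
        self.symmetric_pairs = [tuple(int(x) for x in p) for p in self.symmetric_pairs]
        ids = [c.id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise MontageError("channel ids must be unique")
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise MontageError("channel ids must be 1-based and contiguous")
        by_id = {c.id: c for c in self.channels}
        for a, b in self.symmetric_pairs:
            ca, cb = by_id.get(a), by_id.get(b)
            if ca is None or cb is None:
                raise MontageError(f"symmetric pair ({a},{b}) references unknown channel")
            if {ca.hemisphere, cb.hemisphere} != {Hemisphere.left, Hemisphere.right}:
                raise MontageError(f"symmetric pair ({a},{b}) must join a left and a right channel")
            if ca.region != cb.region:
                raise MontageError(f"symmetric pair ({a},{b}) must join channels of one region")
        if self.source_detector_distance <= 0:
            raise MontageError("source_detector_distance must be positive")
        self._by_id = by_id

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> list[int]:
        return sorted(c.id for c in self.channels)

    def channel(self, cid: int) -> ChannelInfo:
        try:
            return self._by_id[cid]
        except KeyError:
            raise MontageError(f"no channel with id {cid}") from None

    def ids_where(self, region: Region | str | None = None,
                  hemisphere: Hemisphere | str | None = None) -> list[int]:
        region = Region(region) if region is not None else None
        hemisphere = Hemisphere(hemisphere) if hemisphere is not None else None
        out = [c.id for c in self.channels
               if (region is None or c.region == region)
               and (hemisphere is None or c.hemisphere == hemisphere)]
        return sorted(out)

    def has_pair(self, a: int, b: int) -> bool:
        """True if (a, b) is a symmetric pair in either order."""
        want = frozenset((a, b))
        return any(frozenset(p) == want for p in self.symmetric_pairs)

    def pairs_in_region(self, region: Region | str) -> list[tuple[int, int]]:
        region = Region(region)
        return [p for p in self.symmetric_pairs if self.channel(p[0]).region == region]

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "source_detector_distance": self.source_detector_distance,
            "channels": [
                {"id": c.id, "source": c.source, "detector": c.detector,
                 "region": c.region.value, "hemisphere": c.hemisphere.value}
                for c in self.channels
            ],
            "symmetric_pairs": [list(p) for p in self.symmetric_pairs],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: Mapping) -> "Montage":
        return cls(
            channels=[ChannelInfo(**c) for c in d["channels"]],
            symmetric_pairs=[tuple(p) for p in d["symmetric_pairs"]],
            source_detector_distance=float(d.get("source_detector_distance", 3.0)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        return cls.from_dict(json.loads(Path(path).read_text()))


@lru_cache(maxsize=1)
def _default_montage_dict() -> dict:
    with resources.files("nirsmusic.data").joinpath("default_montage.json").open() as fh:
        return json.load(fh)


def default_montage() -> Montage:
    """The packaged 19-channel montage (7 sources, 7 detectors, 3 cm)."""
    return Montage.from_dict(_default_montage_dict())


ROI_NAMES = ("L-F", "R-F", "L-T", "R-T")


@dataclass
class RoiSet:
    """Regions of interest: left/right frontal and temporal channel groups."""

    rois: dict[str, list[int]]

    def __post_init__(self) -> None:
        unknown = set(self.rois) - set(ROI_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown ROI names: {sorted(unknown)}")
        missing = set(ROI_NAMES) - set(self.rois)
        if missing:
            raise ConfigurationError(f"missing ROI names: {sorted(missing)}")
        self.rois = {k: sorted(int(c) for c in v) for k, v in self.rois.items()}

    def __getitem__(self, name: str) -> list[int]:
        return self.rois[name]

    def channels(self) -> list[int]:
        out: set[int] = set()
        for v in self.rois.values():
            out.update(v)
        return sorted(out)


_ROI_SPEC = {
    "L-F": (Region.frontal, Hemisphere.left),
    "R-F": (Region.frontal, Hemisphere.right),
    "L-T": (Region.temporal, Hemisphere.left),
    "R-T": (Region.temporal, Hemisphere.right),
}


def default_roiset(montage: Montage) -> RoiSet:
    """ROIs derived from montage labels: 4 frontal + 3 temporal channels per side."""
    rois = {}
    for name, (region, hemi) in _ROI_SPEC.items():
        ids = montage.ids_where(region=region, hemisphere=hemi)
        if not ids:
            raise ConfigurationError(
                f"montage has no {hemi.value} {region.value} channels for ROI {name}")
        rois[name] = ids
    return RoiSet(rois)


@dataclass
class Recording:
    """One subject/condition channel-time matrix.

    ``data`` is samples x channels; columns follow montage channel-id order.
    """

    data: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    kind: SignalKind = SignalKind.hbo2
    subject_id: str = ""
    group: StudyGroup | None = None
    day: int = 1
    condition: Condition | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.kind = SignalKind(self.kind)
        if self.group is not None:
            self.group = StudyGroup(self.group)
        if self.condition is not None:
            self.condition = Condition(self.condition)
        if not 1 <= int(self.day) <= 3:
            raise ValueError("day must be in 1..3")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise DataError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, **kw) -> "Recording":
        base = dict(data=self.data.copy(), sampling_rate=self.sampling_rate,
                    kind=self.kind, subject_id=self.subject_id, group=self.group,
                    day=self.day, condition=self.condition)
        base.update(kw)
        return Recording(**base)


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def load_recording(path: str | Path, montage: Montage,
                   kind: SignalKind | str = SignalKind.hbo2,
                   sampling_rate: float = DEFAULT_SAMPLING_RATE,
                   **meta) -> Recording:
    """Read a delimited channel-time matrix and attach montage-ordered columns.

    The header row (channel ids) is optional.  NaN rows at the file edges are
    trimmed (incomplete first/last samples from acquisition); interior NaN is
    rejected.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    sep = _sniff_delimiter(first)
    tokens = [t for t in first.strip().split(sep) if t != ""]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if tokens and not all(_numeric(t) for t in tokens) else None
    try:
        df = pd.read_csv(path, sep=sep, header=header)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"could not parse {path}: {exc}") from exc
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise DataError(
                    f"non-numeric cell in column {col!r} at row {int(np.where(bad)[0][0])}")
            df[col] = coerced
    if df.shape[1] != montage.n_channels:
        raise MontageError(
            f"file has {df.shape[1]} columns but montage has {montage.n_channels} channels")
    values = df.to_numpy(dtype=float)
    # trim all-NaN / partially-NaN rows at edges only
    row_bad = ~np.all(np.isfinite(values), axis=1)
    lo, hi = 0, len(values)
    while lo < hi and row_bad[lo]:
        lo += 1
    while hi > lo and row_bad[hi - 1]:
        hi -= 1
    values = values[lo:hi]
    if values.size == 0:
        raise DataError(f"{path} contains no complete samples")
    if not np.all(np.isfinite(values)):
        raise DataError(f"{path} has non-finite samples in the interior of the recording")
    if header is not None:
        # reorder columns by channel id when the header carries ids
        try:
            ids = [int(float(str(c).lstrip("chCH"))) for c in df.columns]
        except ValueError:
            ids = None
        if ids is not None and sorted(ids) == montage.channel_ids:
            order = np.argsort(ids)
            values = values[:, order]
    return Recording(data=values, sampling_rate=sampling_rate, kind=kind, **meta)


def save_recording(rec: Recording, path: str | Path, header: bool = True) -> None:
    """Write a recording as comma-delimited text (17 significant digits)."""
    path = Path(path)
    cols = [f"ch{i + 1}" for i in range(rec.n_channels)]
    df = pd.DataFrame(rec.data, columns=cols)
    df.to_csv(path, index=False, header=header, float_format="%.17g")


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters with the study defaults."""

    band_pass: tuple[float, float] = (0.01, 0.3)  # Hz
    dpf_760: float = 5.286
    dpf_850: float = 4.2238
    hrf: dict = field(default_factory=dict)  # overrides for features.HrfParams
    threshold_grid: tuple[float, float, float] = (0.4, 0.9, 0.05)
    alpha_activation: float = 0.01
    alpha_stats: float = 0.05
    motion_window: float = 1.0       # s
    motion_sd_threshold: float = 3.0
    motion_pad: float = 0.5          # s
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.band_pass
        if not 0 < low < high:
            raise ConfigurationError("band_pass must satisfy 0 < low < high")
        if not (0 < self.alpha_activation < 1 and 0 < self.alpha_stats < 1):
            raise ConfigurationError("alpha levels must lie in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        d["band_pass"] = tuple(d.get("band_pass", (0.01, 0.3)))
        d["threshold_grid"] = tuple(d.get("threshold_grid", (0.4, 0.9, 0.05)))
        return cls(**d)
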