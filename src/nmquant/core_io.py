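"""Imaging-stack and table I/O plus acquisition metadata.

Conventions used throughout the package:

* movie axes are ``[t, z, y, x]`` with an optional trailing channel axis,
  0-based everywhere;
* on disk a movie is a multi-page grayscale TIFF whose pages enumerate, by
  default, z fastest, then time, then channel (a config switch selects the
  channel-fastest dialect instead);
* intensities are held as floats in memory regardless of the on-disk integer
  type, because baseline subtraction needs signed arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "AcquisitionMeta",
    "MovieStack",
    "RunConfig",
    "read_movie",
    "write_movie",
    "volume_rate",
    "write_table",
    "read_table",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition parameters of a time-lapse z-stack recording.

    Defaults mirror a swept-field confocal acquiring rapid five-plane
    z-stacks at a 50 Hz frame rate (10 Hz volume rate) with 268 nm pixels.
    """

    pixel_size_nm: float = 268.0
    frame_rate_hz: float = 50.0
    n_planes: int = 5
    z_step_um: float = 1.0
    channels: tuple[str, ...] = ("green-indicator",)
    t0_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if self.frame_rate_hz <= 0:
            raise ValueError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if self.n_planes < 1:
            raise ValueError(f"n_planes must be >= 1, got {self.n_planes}")
        if not self.channels:
            raise ValueError("channels must be a non-empty sequence of role labels")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def volume_rate_hz(self) -> float:
        return self.frame_rate_hz / self.n_planes

    @property
    def volume_period_s(self) -> float:
        return 1.0 / self.volume_rate_hz


def volume_rate(meta: AcquisitionMeta) -> float:
    """Volumes per second: frame rate divided by the number of z planes."""
    return meta.frame_rate_hz / meta.n_planes


@dataclass
class MovieStack:
    """A fluorescence movie with axes ``[t, z, y, x]`` (+ optional channel).

    ``data`` is kept as float64; intensities must be non-negative on
    construction (ΔF images live in :class:`~nmquant.movie_prep.DeltaFSeries`,
    not here).
    """

    data: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (4, 5):
            raise ValueError(
                f"movie data must be [t, z, y, x] or [t, z, y, x, c], "
                f"got {self.data.ndim} axes"
            )
        if self.data.shape[0] < 1:
            raise ValueError("movie must contain at least one volume")
        if self.data.shape[1] != self.meta.n_planes:
            raise ValueError(
                f"z axis has {self.data.shape[1]} planes but metadata declares "
                f"{self.meta.n_planes}"
            )
        if self.data.ndim == 5 and self.data.shape[4] != self.meta.n_channels:
            raise ValueError(
                f"channel axis has {self.data.shape[4]} channels but metadata "
                f"declares {self.meta.n_channels}"
            )
        if np.any(self.data < 0):
            raise ValueError("movie intensities must be non-negative")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def has_channels(self) -> bool:
        return self.data.ndim == 5

    def channel(self, role: str) -> "MovieStack":
        """Single-channel view selected by its role label."""
        if not self.has_channels:
            raise ValueError("movie has no channel axis")
        try:
            idx = self.meta.channels.index(role)
        except ValueError:
            raise KeyError(
                f"channel {role!r} not among {self.meta.channels}"
            ) from None
        meta = replace(self.meta, channels=(role,))
        return MovieStack(self.data[..., idx], meta)

    def times_s(self) -> np.ndarray:
        """Volume timestamps (s), offset by the metadata's t0."""
        return self.meta.t0_offset_s + np.arange(self.n_volumes) * self.meta.volume_period_s


# ---------------------------------------------------------------------------
# TIFF round trip


def write_movie(
    movie: MovieStack,
    path: str | Path,
    dtype: np.dtype | str | None = None,
    page_order: str = "z-fastest",
) -> None:
    """Write a movie as a multi-page grayscale TIFF.

    Unless ``dtype`` is given, integer-valued data are written as 16-bit
    unsigned and anything else as 32-bit float. ``page_order`` selects the
    page dialect; the default enumerates z fastest, then t, then channel.
    """
    if movie.n_volumes < 1:
        raise ValueError("refusing to write a movie with an empty time axis")
    data = movie.data
    if dtype is None:
        integral = np.all(data == np.round(data)) and np.all(data <= np.iinfo(np.uint16).max)
        dtype = np.uint16 if integral else np.float32
    dtype = np.dtype(dtype)

    pages = _to_pages(data, page_order)
    tifffile.imwrite(str(path), pages.astype(dtype), photometric="minisblack")


def read_movie(
    path: str | Path,
    meta: AcquisitionMeta,
    page_order: str = "z-fastest",
) -> MovieStack:
    """Read a multi-page TIFF into a :class:`MovieStack`.

    The page count must be divisible by ``n_planes × n_channels``; the
    quotient becomes the number of volumes.
    """
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    denom = meta.n_planes * meta.n_channels
    if n_pages % denom != 0:
        raise ValueError(
            f"{n_pages} TIFF pages are not divisible by n_planes × n_channels "
            f"= {meta.n_planes} × {meta.n_channels} = {denom}"
        )
    n_t = n_pages // denom
    data = _from_pages(pages, n_t, meta.n_planes, meta.n_channels, page_order)
    return MovieStack(data, meta)


def _to_pages(data: np.ndarray, page_order: str) -> np.ndarray:
    if data.ndim == 4:
        data = data[..., None]
    n_t, n_z, n_y, n_x, n_c = data.shape
    if page_order == "z-fastest":
        # page index = c*(T*Z) + t*Z + z
        arr = np.moveaxis(data, 4, 0)  # [c, t, z, y, x]
        return arr.reshape(n_c * n_t * n_z, n_y, n_x)
    if page_order == "channel-fastest":
        # page index = t*(Z*C) + z*C + c
        arr = np.moveaxis(data, 4, 2)  # [t, z, c, y, x]
        return arr.reshape(n_t * n_z * n_c, n_y, n_x)
    raise ValueError(f"unknown page_order {page_order!r}")


def _from_pages(
    pages: np.ndarray, n_t: int, n_z: int, n_c: int, page_order: str
) -> np.ndarray:
    n_y, n_x = pages.shape[1:]
    if page_order == "z-fastest":
        arr = pages.reshape(n_c, n_t, n_z, n_y, n_x)
        data = np.moveaxis(arr, 0, 4)
    elif page_order == "channel-fastest":
        arr = pages.reshape(n_t, n_z, n_c, n_y, n_x)
        data = np.moveaxis(arr, 2, 4)
    else:
        raise ValueError(f"unknown page_order {page_order!r}")
    if n_c == 1:
        data = data[..., 0]
    return np.ascontiguousarray(data.astype(np.float64))


# ---------------------------------------------------------------------------
# Tables


def write_table(records: Sequence[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write homogeneous records as a CSV with a header row.

    Decimal points are locale-independent ('.'); an empty record list still
    produces a header-only file when a DataFrame (which carries columns) is
    passed, or an empty file for a bare empty sequence.
    """
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    frame.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


# ---------------------------------------------------------------------------
# Run configuration

#: Default parameters for every pipeline stage. Values with a stated origin
#: in the acquisition/analysis protocol keep that value as the default.
DEFAULT_CONFIG: dict[str, dict[str, object]] = {
    "io": {
        "page_order": "z-fastest",  # or "channel-fastest"
        "write_dtype": "uint16",
    },
    "prep": {
        "trim_volumes": 10,        # initial volumes dropped (photobleaching)
        "bin_s": 0.5,              # temporal bin width
        "projection": "average",   # z projection for functional movies
        "register": True,
        "prestim_s": 2.0,          # F0 / resting-intensity window
    },
    "kinetics": {
        "presynaptic_roi_um": 3.3,
        "bundle_roi_um": 1.7,
        "activity_k": 3.0,         # peak must exceed k·σ(prestim ΔF/F0)
    },
    "dye": {
        "bg_radius_px": 50,        # rolling-ball radius
        "n_central_slices": 2,
        "threshold_method": "mean",
    },
    "assays": {
        "spike_threshold_mads": 5.0,
        "spike_refractory_ms": 1.0,
        "spike_window_s": 300.0,
        "post_window_s": 600.0,
        "age_threshold_um": 20.0,
    },
    "stats": {
        "alpha": 0.05,
        "all_groups_must_pass_normality": True,
        "welch_on_unequal_variance": False,
    },
    "simulate": {
        "seed": 0,
        "noise_gaussian_sd": 5.0,
        "noise_poisson_scale": 0.5,
        "bleach_amplitude": 0.15,
        "bleach_tau_s": 0.3,
    },
}

_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    ("prep", "trim_volumes"): (0, 10_000),
    ("prep", "bin_s"): (1e-6, 3600.0),
    ("prep", "prestim_s"): (1e-6, 3600.0),
    ("kinetics", "presynaptic_roi_um"): (1e-3, 100.0),
    ("kinetics", "bundle_roi_um"): (1e-3, 100.0),
    ("kinetics", "activity_k"): (0.0, 100.0),
    ("dye", "bg_radius_px"): (1, 10_000),
    ("dye", "n_central_slices"): (1, 1000),
    ("assays", "spike_threshold_mads"): (0.0, 1000.0),
    ("assays", "spike_refractory_ms"): (0.0, 1000.0),
    ("assays", "age_threshold_um"): (0.0, 1000.0),
    ("stats", "alpha"): (0.0, 1.0),
}

_CHOICES: dict[tuple[str, str], tuple[str, ...]] = {
    ("io", "page_order"): ("z-fastest", "channel-fastest"),
    ("prep", "projection"): ("average", "max"),
    ("dye", "threshold_method"): ("mean",),
}


@dataclass
class RunConfig:
    """Validated, nested run parameters for every pipeline stage.

    Unknown groups or keys are rejected; values outside their documented
    range are rejected. Construct with :meth:`from_dict` / :meth:`from_yaml`
    to merge user overrides onto the defaults.
    """

    params: dict[str, dict[str, object]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CONFIG.items()}
    )

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        for group, values in self.params.items():
            if group not in DEFAULT_CONFIG:
                raise KeyError(f"unknown config group {group!r}")
            for key, value in values.items():
                if key not in DEFAULT_CONFIG[group]:
                    raise KeyError(f"unknown key {group}.{key}")
                rng = _RANGES.get((group, key))
                if rng is not None:
                    lo, hi = rng
                    if not (lo <= float(value) <= hi):  # type: ignore[arg-type]
                        raise ValueError(
                            f"{group}.{key} = {value!r} outside [{lo}, {hi}]"
                        )
                choices = _CHOICES.get((group, key))
                if choices is not None and value not in choices:
                    raise ValueError(
                        f"{group}.{key} = {value!r} not among {choices}"
                    )

    def __getitem__(self, group: str) -> dict[str, object]:
        return self.params[group]

    @classmethod
    def from_dict(cls, overrides: Mapping[str, Mapping[str, object]]) -> "RunConfig":
        params = {g: dict(v) for g, v in DEFAULT_CONFIG.items()}
        for group, values in overrides.items():
            if group not in params:
                raise KeyError(f"unknown config group {group!r}")
            for key, value in values.items():
                if key not in params[group]:
                    raise KeyError(f"unknown key {group}.{key}")
                params[group][key] = value
        return cls(params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        return cls.from_dict(loaded)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.params, fh, sort_keys=True)
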