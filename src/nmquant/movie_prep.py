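"""Preprocessing chain for functional acquisitions.

The order used on every evoked recording is: drop the initial volumes that
carry the photobleaching transient, register each volume in x-y against a
reference (translation only, phase cross-correlation, 0.1 px subpixel),
project across z, compute the pre-stimulus baseline image F0, subtract it to
get the ΔF series, then temporally bin for display/overlay rendering.
ΔF/F0 itself is evaluated per ROI downstream, never per pixel, so the F0
image only needs to be positive where ROIs will land.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from matplotlib import colormaps
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core_io import AcquisitionMeta, MovieStack
from .synthetic import StimulusWindow

__all__ = [
    "DeltaFSeries",
    "trim_initial",
    "register_xy",
    "project_z",
    "compute_baseline",
    "delta_f",
    "temporal_bin",
    "render_overlay",
    "prep_pipeline",
]


@dataclass
class DeltaFSeries:
    """Baseline-subtracted image series: ``dF[t] = movie[t] - F0``."""

    dF: np.ndarray                     # [t, y, x], signed
    F0: np.ndarray                     # [y, x]
    meta: AcquisitionMeta
    stimulus: StimulusWindow | None = None

    def __post_init__(self) -> None:
        self.dF = np.asarray(self.dF, dtype=np.float64)
        self.F0 = np.asarray(self.F0, dtype=np.float64)
        if self.dF.ndim != 3:
            raise ValueError("dF must be [t, y, x]")
        if self.F0.shape != self.dF.shape[1:]:
            raise ValueError("F0 shape must match the dF frame shape")

    @property
    def n_frames(self) -> int:
        return self.dF.shape[0]

    def times_s(self) -> np.ndarray:
        return self.meta.t0_offset_s + np.arange(self.n_frames) * self.meta.volume_period_s


def trim_initial(movie: MovieStack, n: int = 10) -> MovieStack:
    """Drop the first ``n`` volumes (initial photobleaching transient).

    The metadata t0 offset advances by ``n`` volume periods so downstream
    timestamps stay on the acquisition clock.
    """
    if n < 0:
        raise ValueError("trim count must be >= 0")
    if movie.n_volumes <= n:
        raise ValueError(
            f"cannot trim {n} volumes from a movie with only {movie.n_volumes}"
        )
    if n == 0:
        return movie
    meta = replace(
        movie.meta, t0_offset_s=movie.meta.t0_offset_s + n * movie.meta.volume_period_s
    )
    return MovieStack(movie.data[n:], meta)


def register_xy(
    movie: MovieStack,
    reference: int = 0,
    upsample_factor: int = 10,
) -> tuple[MovieStack, np.ndarray]:
    """Translation-only x-y registration against one reference volume.

    Shifts are estimated on the z-mean projection of each volume by phase
    cross-correlation (subpixel to ``1/upsample_factor`` px) and applied
    identically to every z plane; out-of-frame pixels are filled by edge
    replication. Returns the registered movie and the applied (dy, dx) per
    volume.
    """
    if movie.n_volumes < 2:
        raise ValueError("registration needs at least two volumes")
    if movie.has_channels:
        raise ValueError("register single-channel movies (select a channel first)")
    if not 0 <= reference < movie.n_volumes:
        raise ValueError("reference volume index out of range")

    projections = movie.data.mean(axis=1)
    ref = projections[reference]
    shifts = np.zeros((movie.n_volumes, 2))
    out = movie.data.copy()
    degenerate_ref = np.ptp(ref) == 0
    for t in range(movie.n_volumes):
        if t == reference:
            continue
        if degenerate_ref or np.ptp(projections[t]) == 0:
            warnings.warn(
                f"volume {t}: constant frame, registration shift set to zero",
                stacklevel=2,
            )
            continue
        shift, _, _ = phase_cross_correlation(
            ref, projections[t], upsample_factor=upsample_factor, normalization=None
        )
        shifts[t] = shift
        if np.any(shift != 0):
            for z in range(movie.data.shape[1]):
                out[t, z] = ndimage.shift(
                    movie.data[t, z], shift, order=1, mode="nearest"
                )
    return MovieStack(out, movie.meta), shifts


def project_z(movie: MovieStack, method: str = "average") -> MovieStack:
    """Collapse the z axis to a single plane by per-pixel mean or max."""
    if method == "average":
        projected = movie.data.mean(axis=1, keepdims=True)
    elif method == "max":
        projected = movie.data.max(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    # preserve the volume clock: one remaining plane per volume period
    meta = replace(movie.meta, n_planes=1, frame_rate_hz=movie.meta.volume_rate_hz)
    return MovieStack(projected, meta)


def compute_baseline(
    movie: MovieStack,
    prestim: tuple[float, float] | None = None,
    stimulus: StimulusWindow | None = None,
) -> np.ndarray:
    """Per-pixel mean baseline image F0 over a pre-stimulus window.

    ``prestim`` is a (start_s, end_s) window on the movie's own clock
    (i.e. including the metadata t0 offset). When omitted it defaults to
    everything from the movie start up to the stimulus onset. The window
    must contain at least one volume and must not reach past the stimulus
    onset.
    """
    if movie.has_channels:
        raise ValueError("compute F0 on a single channel")
    times = movie.times_s()
    if prestim is None:
        if stimulus is None:
            raise ValueError("provide either a prestim window or a stimulus")
        prestim = (float(times[0]), stimulus.onset_s)
    start, end = prestim
    if stimulus is not None and end > stimulus.onset_s + 1e-12:
        raise ValueError(
            f"prestim window end {end} s overlaps the stimulus onset at "
            f"{stimulus.onset_s} s"
        )
    selector = (times >= start - 1e-12) & (times < end - 1e-12)
    if not np.any(selector):
        raise ValueError(f"prestim window [{start}, {end}) s contains no volumes")
    if movie.data.shape[1] != 1:
        raise ValueError("project across z before computing F0")
    return movie.data[selector, 0].mean(axis=0)


def delta_f(
    movie: MovieStack,
    F0: np.ndarray,
    stimulus: StimulusWindow | None = None,
) -> DeltaFSeries:
    """Subtract the baseline image from every frame: ``dF[t] = F[t] - F0``."""
    if movie.has_channels:
        raise ValueError("compute dF on a single channel")
    if movie.data.shape[1] != 1:
        raise ValueError("project across z before computing dF")
    frames = movie.data[:, 0]
    F0 = np.asarray(F0, dtype=np.float64)
    if F0.shape != frames.shape[1:]:
        raise ValueError(
            f"F0 shape {F0.shape} does not match frame shape {frames.shape[1:]}"
        )
    return DeltaFSeries(frames - F0, F0, movie.meta, stimulus)


def temporal_bin(series: DeltaFSeries, bin_s: float = 0.5) -> DeltaFSeries:
    """Average non-overlapping groups of volumes into ``bin_s`` bins.

    The group size is ``round(bin_s * volume_rate)``; a trailing partial
    group is dropped rather than padded so every bin mean is unbiased.
    """
    rate = series.meta.volume_rate_hz
    if bin_s < 1.0 / rate - 1e-12:
        raise ValueError(
            f"bin of {bin_s} s is shorter than one volume period ({1.0 / rate} s)"
        )
    group = int(round(bin_s * rate))
    n_bins = series.n_frames // group
    if n_bins == 0:
        raise ValueError("series shorter than one bin")
    trimmed = series.dF[: n_bins * group]
    binned = trimmed.reshape(n_bins, group, *series.dF.shape[1:]).mean(axis=1)
    meta = replace(
        series.meta,
        frame_rate_hz=series.meta.frame_rate_hz / group,
    )
    return DeltaFSeries(binned, series.F0, meta, series.stimulus)


def render_overlay(binned: DeltaFSeries, colormap: str = "hot") -> np.ndarray:
    """RGB frames of color-mapped ΔF superimposed on the grayscale F0.

    ΔF is min-max scaled to [0, 1] over the whole series (negative values
    clip to 0) and used both to look up the colormap and as the blend
    weight, so zero ΔF leaves pure grayscale and the series maximum shows
    the colormap's top color.
    """
    cmap = colormaps[colormap]
    f0 = binned.F0
    f0_span = np.ptp(f0)
    gray = (f0 - f0.min()) / f0_span if f0_span > 0 else np.zeros_like(f0)
    gray_rgb = np.repeat(gray[..., None], 3, axis=-1)

    peak = binned.dF.max()
    frames = np.empty((binned.n_frames, *f0.shape, 3))
    for t in range(binned.n_frames):
        w = np.clip(binned.dF[t], 0, None)
        w = w / peak if peak > 0 else np.zeros_like(w)
        color = cmap(w)[..., :3]
        frames[t] = gray_rgb * (1.0 - w[..., None]) + color * w[..., None]
    return frames


def prep_pipeline(
    movie: MovieStack,
    stimulus: StimulusWindow,
    trim: int = 10,
    register: bool = True,
    projection: str = "average",
    prestim: tuple[float, float] | None = None,
) -> tuple[DeltaFSeries, MovieStack, np.ndarray]:
    """Full preprocessing chain: trim → register → project → F0 → ΔF.

    Returns the ΔF series, the registered projected movie (for raw-trace
    extraction), and the per-volume registration shifts.
    """
    trimmed = trim_initial(movie, trim)
    if register:
        registered, shifts = register_xy(trimmed)
    else:
        registered, shifts = trimmed, np.zeros((trimmed.n_volumes, 2))
    projected = project_z(registered, projection)
    F0 = compute_baseline(projected, prestim=prestim, stimulus=stimulus)
    series = delta_f(projected, F0, stimulus)
    return series, projected, shifts
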