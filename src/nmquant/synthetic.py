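"""Ground-truthed synthetic inputs emulating the acquisitions the pipeline
expects: evoked-transient functional movies, dye uptake/clearance stacks,
loose-patch current traces, survival scenarios and age cohorts.

Every simulator is deterministic given its seed, returns its generating
truth alongside the data, and reproduces the statistical structure the
downstream stages assume (five-plane z-stacks, early photobleaching
transient, rigid x-y drift, mixed Gaussian/Poisson-like noise, saturating
dye uptake, biphasic extracellular spikes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .assays import CellRecord
from .core_io import AcquisitionMeta, MovieStack

__all__ = [
    "StimulusWindow",
    "CellSpec",
    "SimMovieTruth",
    "UptakeTruth",
    "make_movie_truth",
    "simulate_functional_movie",
    "simulate_uptake_series",
    "simulate_spike_train",
    "simulate_survival_scenario",
    "simulate_age_cohort",
    "default_bleach",
]


@dataclass(frozen=True)
class StimulusWindow:
    """A fluid-jet stimulus epoch.

    ``pattern`` is ``"step"`` for the 200 ms / 500 ms / 4 s step stimuli or
    ``"alternating"`` with a frequency for the 2 s alternating stimulus.
    """

    onset_s: float
    duration_s: float
    pattern: Literal["step", "alternating"] = "step"
    frequency_hz: float = 5.0

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("stimulus onset must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("stimulus duration must be positive")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class CellSpec:
    """Ground truth for one simulated hair cell."""

    center: tuple[float, float]            # (y, x) pixels
    radius_px: float
    baseline_F0: float
    is_active: bool = False
    peak_dff: float = 0.0
    rise_s: float = 0.5
    decay_halflife_s: float = 1.0
    age_class: Literal["young", "mature"] = "mature"
    dapi_positive: bool = False
    kinocilium_um: float = 21.0
    survives: bool = True

    def __post_init__(self) -> None:
        if self.baseline_F0 <= 0:
            raise ValueError("baseline_F0 must be positive")
        if self.peak_dff < 0:
            raise ValueError("peak_dff must be >= 0")
        if self.decay_halflife_s <= 0:
            raise ValueError("decay_halflife_s must be positive")
        if self.kinocilium_um < 0:
            raise ValueError("kinocilium_um must be >= 0")


@dataclass
class SimMovieTruth:
    """Complete generating state of one functional movie."""

    cells: list[CellSpec]
    stimulus: StimulusWindow
    shape: tuple[int, int]                 # (y, x)
    drift: np.ndarray                      # (T, 2) per-volume (dy, dx)
    bleach: np.ndarray                     # (T,) multiplicative factors
    seed: int = 0
    noise: tuple[float, float] = (0.0, 0.0)  # (gaussian_sd, poisson_scale)
    background: float = 20.0

    def __post_init__(self) -> None:
        self.drift = np.atleast_2d(np.asarray(self.drift, dtype=float))
        self.bleach = np.asarray(self.bleach, dtype=float)
        if self.drift.shape[0] != self.bleach.shape[0]:
            raise ValueError("drift and bleach must cover the same volume count")
        if np.any(self.bleach <= 0) or np.any(self.bleach > 1):
            raise ValueError("bleach factors must lie in (0, 1]")

    @property
    def n_volumes(self) -> int:
        return self.bleach.shape[0]


def default_bleach(
    n_volumes: int, volume_rate_hz: float, amplitude: float = 0.15, tau_s: float = 0.3
) -> np.ndarray:
    """Early photobleaching transient ``1 - a*exp(-t/tau)``.

    With the defaults the factor recovers to within ~0.5% of unity by one
    second, which is what the initial-volume trim is there to discard.
    """
    t = np.arange(n_volumes) / volume_rate_hz
    return 1.0 - amplitude * np.exp(-t / tau_s)


def make_movie_truth(
    n_cells: int = 8,
    n_active: int = 3,
    n_volumes: int = 100,
    shape: tuple[int, int] = (96, 96),
    seed: int = 0,
    meta: AcquisitionMeta | None = None,
    stimulus: StimulusWindow | None = None,
    peak_dff: float | tuple[float, float] = 1.0,
    rise_s: float = 0.5,
    decay_halflife_s: float = 1.0,
    radius_px: float = 6.0,
    baseline_F0: float = 200.0,
    noise: tuple[float, float] = (0.0, 0.0),
    drift: np.ndarray | None = None,
    bleach: np.ndarray | None = None,
) -> SimMovieTruth:
    """Lay out ``n_cells`` non-overlapping cells on a grid and draw truth.

    The first ``n_active`` cells respond to the stimulus; ``peak_dff`` may be
    a scalar (all identical) or a ``(low, high)`` range sampled uniformly.
    """
    if meta is None:
        meta = AcquisitionMeta()
    if stimulus is None:
        # default: 1 s for the trim + 2 s prestim baseline, then a 500 ms step
        stimulus = StimulusWindow(onset_s=3.0, duration_s=0.5)
    rng = np.random.default_rng(seed)
    n_y, n_x = shape
    margin = int(np.ceil(radius_px)) + 4
    grid = int(np.ceil(np.sqrt(n_cells)))
    ys = np.linspace(margin, n_y - margin, grid)
    xs = np.linspace(margin, n_x - margin, grid)
    centers = [(float(y), float(x)) for y in ys for x in xs][:n_cells]
    cells = []
    for i, center in enumerate(centers):
        active = i < n_active
        if isinstance(peak_dff, tuple):
            peak = float(rng.uniform(*peak_dff))
        else:
            peak = float(peak_dff)
        cells.append(
            CellSpec(
                center=center,
                radius_px=radius_px,
                baseline_F0=baseline_F0,
                is_active=active,
                peak_dff=peak if active else 0.0,
                rise_s=rise_s,
                decay_halflife_s=decay_halflife_s,
            )
        )
    if drift is None:
        drift = np.zeros((n_volumes, 2))
    if bleach is None:
        bleach = np.ones(n_volumes)
    return SimMovieTruth(
        cells=cells,
        stimulus=stimulus,
        shape=shape,
        drift=drift,
        bleach=bleach,
        seed=seed,
        noise=noise,
    )


def _dff_profile(cell: CellSpec, times: np.ndarray, stim: StimulusWindow) -> np.ndarray:
    """Piecewise transient: linear rise over ``rise_s`` from stimulus onset
    to ``peak_dff``, then exponential decay with the stated half-life."""
    dff = np.zeros_like(times)
    if not cell.is_active or cell.peak_dff == 0:
        return dff
    t_peak = stim.onset_s + cell.rise_s
    rising = (times >= stim.onset_s) & (times <= t_peak)
    if cell.rise_s > 0:
        dff[rising] = cell.peak_dff * (times[rising] - stim.onset_s) / cell.rise_s
    else:
        dff[times >= t_peak] = cell.peak_dff
    decay = times > t_peak
    dff[decay] = cell.peak_dff * np.exp2(-(times[decay] - t_peak) / cell.decay_halflife_s)
    return dff


def simulate_functional_movie(
    truth: SimMovieTruth, meta: AcquisitionMeta | None = None
) -> tuple[MovieStack, SimMovieTruth]:
    """Render a functional movie from its generating truth.

    Each cell is a hard disk whose fluorescence follows
    ``bleach(t) * F0 * (1 + dff(t))``; the whole frame is rigidly shifted by
    the per-volume drift (first-order interpolation, edge replication) and
    replicated across the z planes with independent noise per plane. Noise is
    Gaussian plus a signal-proportional-variance term standing in for shot
    noise.
    """
    if meta is None:
        meta = AcquisitionMeta()
    n_y, n_x = truth.shape
    n_t = truth.n_volumes
    times = np.arange(n_t) / meta.volume_rate_hz

    max_dy = float(np.max(np.abs(truth.drift[:, 0]), initial=0.0))
    max_dx = float(np.max(np.abs(truth.drift[:, 1]), initial=0.0))
    for cell in truth.cells:
        cy, cx = cell.center
        r = cell.radius_px
        if cy - r < 0 or cx - r < 0 or cy + r > n_y - 1 or cx + r > n_x - 1:
            raise ValueError(f"cell at {cell.center} overlaps the image border")
        if (
            cy - r - max_dy < 0
            or cx - r - max_dx < 0
            or cy + r + max_dy > n_y - 1
            or cx + r + max_dx > n_x - 1
        ):
            raise ValueError(f"drift pushes cell at {cell.center} out of frame")

    yy, xx = np.mgrid[0:n_y, 0:n_x]
    masks = [
        (yy - c.center[0]) ** 2 + (xx - c.center[1]) ** 2 <= c.radius_px**2
        for c in truth.cells
    ]
    profiles = [_dff_profile(c, times, truth.stimulus) for c in truth.cells]

    rng = np.random.default_rng(truth.seed)
    gauss_sd, poisson_scale = truth.noise
    data = np.empty((n_t, meta.n_planes, n_y, n_x))
    for t in range(n_t):
        frame = np.full((n_y, n_x), truth.background, dtype=float)
        for cell, mask, dff in zip(truth.cells, masks, profiles):
            frame[mask] = cell.baseline_F0 * (1.0 + dff[t])
        frame *= truth.bleach[t]
        dy, dx = truth.drift[t]
        if dy != 0 or dx != 0:
            frame = ndimage.shift(frame, (dy, dx), order=1, mode="nearest")
        for z in range(meta.n_planes):
            plane = frame
            if gauss_sd > 0 or poisson_scale > 0:
                sd = np.sqrt(gauss_sd**2 + poisson_scale * np.clip(frame, 0, None))
                plane = frame + rng.standard_normal((n_y, n_x)) * sd
            data[t, z] = np.clip(plane, 0, None)
    return MovieStack(data, meta), truth


# ---------------------------------------------------------------------------
# Dye uptake / clearance


@dataclass(frozen=True)
class UptakeTruth:
    """Generating parameters of a dye uptake or clearance series."""

    Imax: float
    tau_s: float
    t_points_s: tuple[float, ...]
    phase: Literal["uptake", "clearance"]
    retained_fraction: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    cell_radius_px: float = 18.0

    def expected_intensity(self) -> np.ndarray:
        t = np.asarray(self.t_points_s, dtype=float)
        if self.phase == "uptake":
            return self.Imax * (1.0 - np.exp(-t / self.tau_s))
        f = self.retained_fraction
        return self.Imax * (f + (1.0 - f) * np.exp(-t / self.tau_s))


def simulate_uptake_series(
    Imax: float,
    tau_s: float,
    t_points: Sequence[float],
    retained_fraction: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    n_planes: int = 3,
    drift: np.ndarray | None = None,
) -> tuple[MovieStack, UptakeTruth]:
    """Two-channel dye stacks: a constant reference channel that carries the
    cell-region footprint used for masking, and a dye channel following
    saturating uptake ``Imax*(1-exp(-t/tau))`` or, when ``retained_fraction``
    is given, washout clearance ``Imax*(f + (1-f)*exp(-t/tau))``.

    One volume per time point; ``drift`` optionally injects per-timepoint
    rigid (dy, dx) offsets for the registration step to undo.
    """
    if Imax <= 0 or tau_s <= 0:
        raise ValueError("Imax and tau_s must be positive")
    if len(t_points) == 0:
        raise ValueError("t_points must be non-empty")
    if retained_fraction is not None and not (0.0 <= retained_fraction <= 1.0):
        raise ValueError("retained_fraction must lie in [0, 1]")
    phase: Literal["uptake", "clearance"]
    phase = "uptake" if retained_fraction is None else "clearance"
    truth = UptakeTruth(
        Imax=Imax,
        tau_s=tau_s,
        t_points_s=tuple(float(t) for t in t_points),
        phase=phase,
        retained_fraction=0.0 if retained_fraction is None else retained_fraction,
        noise_sd=noise_sd,
        seed=seed,
    )
    n_y, n_x = shape
    yy, xx = np.mgrid[0:n_y, 0:n_x]
    mask = (yy - n_y / 2) ** 2 + (xx - n_x / 2) ** 2 <= truth.cell_radius_px**2
    reference = np.where(mask, 150.0, 10.0)
    intensities = truth.expected_intensity()
    if drift is None:
        drift = np.zeros((len(t_points), 2))
    rng = np.random.default_rng(seed)
    data = np.empty((len(t_points), n_planes, n_y, n_x, 2))
    for i, level in enumerate(intensities):
        dye = np.where(mask, level, 0.0)
        ref = reference
        dy, dx = np.asarray(drift, dtype=float)[i]
        if dy != 0 or dx != 0:
            dye = ndimage.shift(dye, (dy, dx), order=1, mode="nearest")
            ref = ndimage.shift(ref, (dy, dx), order=1, mode="nearest")
        for z in range(n_planes):
            d, r = dye, ref
            if noise_sd > 0:
                d = d + rng.standard_normal((n_y, n_x)) * noise_sd
                r = r + rng.standard_normal((n_y, n_x)) * noise_sd
            data[i, z, ..., 0] = np.clip(r, 0, None)
            data[i, z, ..., 1] = np.clip(d, 0, None)
    meta = AcquisitionMeta(
        frame_rate_hz=1.0,
        n_planes=n_planes,
        channels=("reference", "dye"),
    )
    return MovieStack(data, meta), truth


# ---------------------------------------------------------------------------
# Extracellular spikes


def _biphasic_template(fs_hz: float, width_s: float = 1e-3) -> np.ndarray:
    """One sine period: a positive then a negative lobe of equal area."""
    n = int(round(width_s * fs_hz))
    if n < 4:
        raise ValueError(
            f"sampling rate {fs_hz} Hz too low for a {width_s * 1e3:.2f} ms "
            "biphasic template (need >= 4 samples)"
        )
    t = np.arange(n) / n
    return np.sin(2 * np.pi * t)


def simulate_spike_train(
    rate_per_min: float,
    duration_s: float,
    fs_hz: float = 20_000.0,
    amplitude: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    template_width_s: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous-Poisson biphasic events on white noise.

    Returns the sampled trace and the true event onset times (s). Events are
    thinned so that consecutive onsets are at least one template width
    apart. The 20 kHz default matches a 50 µs/pt acquisition.
    """
    if rate_per_min < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    template = _biphasic_template(fs_hz, template_width_s) * amplitude
    n = int(round(duration_s * fs_hz))
    trace = rng.standard_normal(n) * noise_sd if noise_sd > 0 else np.zeros(n)

    events: list[float] = []
    rate_hz = rate_per_min / 60.0
    if rate_hz > 0:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / rate_hz)
            if t >= duration_s - template_width_s:
                break
            if not events or t - events[-1] >= template_width_s:
                events.append(t)
    for t0 in events:
        i0 = int(round(t0 * fs_hz))
        trace[i0 : i0 + template.size] += template[: n - i0]
    return trace, np.asarray(events)


# ---------------------------------------------------------------------------
# Survival scenarios and age cohorts


def simulate_survival_scenario(
    n_per_class: Mapping[str, int] | int,
    survive_prob: Mapping[str, float] | float,
    seed: int = 0,
    immature_fraction: float = 0.0,
) -> tuple[list[CellRecord], list[CellRecord]]:
    """Bernoulli survival per cell, grouped by class (e.g. genotype).

    Pre-treatment cells are reporter-positive; post-treatment cells keep the
    reporter and gain the vital-dye label iff they survive (the dye
    disappears on membrane fragmentation, so dead cells show neither).
    A configurable fraction of pre cells is flagged immature and thereby
    excluded from the eligible denominator.
    """
    if isinstance(n_per_class, int):
        n_per_class = {"all": n_per_class}
    rng = np.random.default_rng(seed)
    pre: list[CellRecord] = []
    post: list[CellRecord] = []
    for group, n in n_per_class.items():
        p = survive_prob[group] if isinstance(survive_prob, Mapping) else survive_prob
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"survival probability for {group!r} outside [0, 1]")
        for i in range(n):
            cell_id = f"{group}-{i}"
            immature = bool(rng.random() < immature_fraction)
            survives = bool(rng.random() < p)
            pre.append(
                CellRecord(
                    id=cell_id,
                    group=group,
                    reporter_positive=True,
                    fm_positive=False,
                    immature=immature,
                )
            )
            post.append(
                CellRecord(
                    id=cell_id,
                    group=group,
                    reporter_positive=survives,
                    fm_positive=survives,
                    immature=immature,
                )
            )
    return pre, post


def simulate_age_cohort(
    n_young: int, n_mature: int, seed: int = 0
) -> list[CellRecord]:
    """Cells with kinocilial heights drawn per age class.

    Young heights are uniform on [2.5, 20) µm and mature heights uniform on
    [20, 23.5] µm, reproducing the observed overall spread of 2.5–23.5 µm
    with the 20 µm boundary separating the classes. Nuclear-dye positivity
    (an early-born-cell label) is set for mature cells only.
    """
    if n_young < 0 or n_mature < 0:
        raise ValueError("cohort counts must be >= 0")
    rng = np.random.default_rng(seed)
    cells: list[CellRecord] = []
    heights_young = rng.uniform(2.5, np.nextafter(20.0, 0.0), size=n_young)
    heights_mature = rng.uniform(20.0, 23.5, size=n_mature)
    for i, h in enumerate(heights_young):
        cells.append(
            CellRecord(
                id=f"young-{i}",
                reporter_positive=True,
                dapi_positive=False,
                kinocilium_um=float(h),
                age_class="young",
            )
        )
    for i, h in enumerate(heights_mature):
        cells.append(
            CellRecord(
                id=f"mature-{i}",
                reporter_positive=True,
                dapi_positive=True,
                kinocilium_um=float(h),
                age_class="mature",
            )
        )
    return cells
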