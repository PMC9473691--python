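"""Survival quantification, spontaneous spike rates, age classification and
indel genotyping.

Survival is counted two ways, matching the two assay designs: a paired
within-neuromast percentage (surviving cells / cells present before
treatment, for the fast-acting ototoxin where the same neuromast is imaged
before and after) and a group-normalized percentage (treated count /
untreated-group mean, for the slow-acting ototoxin where pre-treatment
imaging is impossible). A surviving cell must carry both the genetic
reporter and the vital-dye label; immature cells without visible bundles
are excluded from the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CellRecord",
    "SpikeTrain",
    "percent_survival_paired",
    "percent_survival_normalized",
    "detect_spikes",
    "spikes_per_minute",
    "pre_post_rate",
    "classify_age_by_height",
    "indel_length",
]


@dataclass
class CellRecord:
    """Per-cell identity and label flags."""

    id: str
    reporter_positive: bool = True
    fm_positive: bool = False
    immature: bool = False
    dapi_positive: bool = False
    kinocilium_um: float | None = None
    age_class: Literal["young", "mature"] | None = None
    group: str = ""

    @property
    def surviving(self) -> bool:
        return self.reporter_positive and self.fm_positive

    @property
    def eligible(self) -> bool:
        return not self.immature


@dataclass
class SpikeTrain:
    """Detected event times within a recording."""

    event_times_s: np.ndarray
    duration_s: float
    fs_hz: float

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=np.float64)
        if self.event_times_s.size:
            if np.any(np.diff(self.event_times_s) <= 0):
                raise ValueError("event times must be strictly increasing")
            if self.event_times_s[0] < 0 or self.event_times_s[-1] >= self.duration_s:
                raise ValueError("event times must lie in [0, duration)")

    @property
    def n_events(self) -> int:
        return int(self.event_times_s.size)


# ---------------------------------------------------------------------------
# Survival


def percent_survival_paired(
    pre: Sequence[CellRecord], post: Sequence[CellRecord]
) -> float:
    """Paired within-neuromast survival percentage.

    ``100 × (post cells with reporter AND vital dye) / (eligible pre
    cells)``, where eligible excludes immature cells. Raises when no pre
    cell is eligible or survivors outnumber the pre-treatment population
    (an impossible pairing).
    """
    n_pre = sum(1 for c in pre if c.eligible)
    if n_pre == 0:
        raise ValueError("no eligible pre-treatment cells")
    n_surv = sum(1 for c in post if c.eligible and c.surviving)
    if n_surv > n_pre:
        raise ValueError(
            f"{n_surv} survivors exceed the {n_pre} eligible pre-treatment cells"
        )
    return 100.0 * n_surv / n_pre


def percent_survival_normalized(
    treated_counts: Sequence[int], untreated_counts: Sequence[int]
) -> np.ndarray:
    """Group-normalized survival: each treated neuromast's surviving-cell
    count as a percentage of the untreated group's mean count."""
    untreated = np.asarray(list(untreated_counts), dtype=float)
    if untreated.size == 0:
        raise ValueError("untreated group is empty")
    denom = untreated.mean()
    if denom == 0:
        raise ZeroDivisionError("untreated group mean count is zero")
    treated = np.asarray(list(treated_counts), dtype=float)
    return 100.0 * treated / denom


# ---------------------------------------------------------------------------
# Spontaneous spikes


def detect_spikes(
    trace: np.ndarray,
    fs_hz: float,
    threshold_mads: float = 5.0,
    refractory_ms: float = 1.0,
    min_crossings: int = 2,
) -> SpikeTrain:
    """Threshold-crossing event detection on an extracellular trace.

    The noise scale is the MAD-based robust σ of the median-subtracted
    trace; samples whose absolute deviation exceeds ``threshold_mads·σ``
    are grouped into events, events closer than the refractory window are
    merged, and each event is timestamped at its extremum. Deviations are
    two-sided, so detection is invariant to offset and polarity.

    An event must comprise at least ``min_crossings`` supra-threshold
    samples: a biphasic spike always contributes several (both lobes cross
    the two-sided threshold within the refractory window), whereas an
    isolated single-sample excursion is indistinguishable from noise and is
    discarded.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size < fs_hz:
        raise ValueError("need at least one second of samples")
    if fs_hz < 1000.0:
        warnings.warn(
            f"sampling rate {fs_hz} Hz is below the 1 kHz recording bandwidth",
            stacklevel=2,
        )
    dev = trace - np.median(trace)
    mad = np.median(np.abs(dev))
    sigma = 1.4826 * mad
    duration = trace.size / fs_hz
    if sigma == 0:
        return SpikeTrain(np.empty(0), duration, fs_hz)

    above = np.abs(dev) > threshold_mads * sigma
    if not above.any():
        return SpikeTrain(np.empty(0), duration, fs_hz)

    idx = np.flatnonzero(above)
    gap = int(round(refractory_ms * 1e-3 * fs_hz))
    # split supra-threshold samples into events separated by > refractory
    breaks = np.flatnonzero(np.diff(idx) > max(gap, 1))
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [idx.size]))
    times = []
    for s, e in zip(starts, ends):
        cluster = idx[s:e]
        if cluster.size < min_crossings:
            continue
        peak = cluster[int(np.argmax(np.abs(dev[cluster])))]
        times.append(peak / fs_hz)
    return SpikeTrain(np.asarray(times), duration, fs_hz)


def spikes_per_minute(train: SpikeTrain, window_s: float = 300.0) -> float:
    """Events per minute within the first ``window_s`` of the recording
    (5 min by default)."""
    if window_s <= 0:
        raise ValueError("window must be positive")
    if window_s > train.duration_s + 1e-9:
        raise ValueError(
            f"window of {window_s} s exceeds the {train.duration_s} s recording"
        )
    n = int(np.count_nonzero(train.event_times_s < window_s))
    return 60.0 * n / window_s


def pre_post_rate(
    train: SpikeTrain,
    treatment_time_s: float,
    pre_window_s: float = 300.0,
    post_window_s: float = 600.0,
) -> tuple[float, float]:
    """Per-minute rates in the pre-treatment window (5 min before the
    treatment) and the post-treatment window (10 min after)."""
    if treatment_time_s - pre_window_s < -1e-9:
        raise ValueError("pre-treatment window extends before the recording")
    if treatment_time_s + post_window_s > train.duration_s + 1e-9:
        raise ValueError("post-treatment window extends past the recording")
    t = train.event_times_s
    n_pre = int(
        np.count_nonzero((t >= treatment_time_s - pre_window_s) & (t < treatment_time_s))
    )
    n_post = int(
        np.count_nonzero((t >= treatment_time_s) & (t < treatment_time_s + post_window_s))
    )
    return 60.0 * n_pre / pre_window_s, 60.0 * n_post / post_window_s


# ---------------------------------------------------------------------------
# Age classification


def classify_age_by_height(
    kinocilium_um: float, threshold_um: float = 20.0
) -> Literal["young", "mature"]:
    """Split cells by kinocilial height: young below the threshold, mature
    at or above it (boundary inclusive on the mature side)."""
    if kinocilium_um < 0:
        raise ValueError("kinocilial height must be >= 0")
    return "young" if kinocilium_um < threshold_um else "mature"


# ---------------------------------------------------------------------------
# Indel genotyping

_VALID_BASES = frozenset("ACGT")


def indel_length(ref_seq: str, mut_seq: str) -> int:
    """Length (bp) of the single contiguous indel between two sequences.

    The matching flanks are located as the longest common prefix and
    suffix; together they must account for every base of the shorter
    sequence, otherwise the difference is not a single contiguous indel and
    an error is raised. Symmetric in its arguments.
    """
    ref = ref_seq.upper()
    mut = mut_seq.upper()
    for name, seq in (("ref_seq", ref), ("mut_seq", mut)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    if ref == mut:
        return 0

    short, long = (ref, mut) if len(ref) <= len(mut) else (mut, ref)
    prefix = 0
    while prefix < len(short) and short[prefix] == long[prefix]:
        prefix += 1
    suffix = 0
    while (
        suffix < len(short) - prefix
        and short[len(short) - 1 - suffix] == long[len(long) - 1 - suffix]
    ):
        suffix += 1
    if prefix + suffix < len(short):
        raise ValueError(
            "sequences differ by more than a single contiguous indel"
        )
    return len(long) - len(short)
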