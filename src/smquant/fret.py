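"""Single-molecule FRET efficiency traces, histograms and two-state dwells.

Efficiency is computed from integrated donor and acceptor intensities as
E = I_A / (I_D + I_A).  Population histograms are built from the mean of the
first 10 frames of each trajectory with bins of 0.1.  Two-state segmentation
thresholds E into free (high FRET) and bound (low FRET) intervals whose
durations feed exponential dwell fits (t_on / t_off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kinetics import DwellSet

logger = logging.getLogger(__name__)

__all__ = [
    "FretTrace",
    "StateInterval",
    "StateSegmentation",
    "compute_fret",
    "fret_histogram",
    "default_threshold",
    "segment_states",
    "dwells_from_segmentation",
]

#: Default camera exposure, seconds (30 ms EM-CCD acquisition).
DEFAULT_EXPOSURE = 0.030


def compute_fret(I_D, I_A) -> np.ndarray:
    """Per-frame FRET efficiency E = I_A / (I_D + I_A).

    Frames with zero total intensity are returned as NaN (missing).  E is
    invariant under any common rescaling of the two channels.
    """
    d = np.asarray(I_D, dtype=float)
    a = np.asarray(I_A, dtype=float)
    if d.shape != a.shape:
        raise ValueError("donor and acceptor series must have equal length")
    if np.any(d < 0) or np.any(a < 0):
        raise ValueError("intensities must be non-negative")
    total = d + a
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(total > 0, a / total, np.nan)
    return e


@dataclass
class FretTrace:
    """Donor/acceptor intensity trace of one molecule."""

    I_D: np.ndarray
    I_A: np.ndarray
    exposure: float = DEFAULT_EXPOSURE

    def __post_init__(self) -> None:
        self.I_D = np.asarray(self.I_D, dtype=float)
        self.I_A = np.asarray(self.I_A, dtype=float)
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        # validates shapes/signs
        self._E = compute_fret(self.I_D, self.I_A)

    @property
    def E(self) -> np.ndarray:
        return self._E

    def __len__(self) -> int:
        return self.I_D.size


def fret_histogram(
    traces: list[FretTrace], n_first_frames: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Population FRET histogram from per-trace initial means.

    Each trajectory contributes one value, the mean E of its first
    ``n_first_frames`` frames; values are binned on [0, 1] with width 0.1,
    left-closed (E = 0.1 falls in [0.1, 0.2); the last bin is [0.9, 1.0]).
    Traces shorter than ``n_first_frames`` are excluded with a log message.

    Returns (counts, bin_edges).
    """
    values = []
    for i, tr in enumerate(traces):
        if len(tr) < n_first_frames:
            logger.info("trace %d shorter than %d frames; excluded", i, n_first_frames)
            continue
        e0 = tr.E[:n_first_frames]
        e0 = e0[np.isfinite(e0)]
        if e0.size:
            values.append(float(np.mean(e0)))
    edges = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    counts, _ = np.histogram(values, bins=edges)
    return counts, edges


def default_threshold(traces: list[FretTrace]) -> float:
    """Midpoint of the two modes of the population histogram (fallback 0.5)."""
    counts, edges = fret_histogram(traces)
    centers = 0.5 * (edges[:-1] + edges[1:])
    order = np.argsort(counts)[::-1]
    if counts[order[1]] == 0:
        return 0.5
    m1, m2 = centers[order[0]], centers[order[1]]
    if abs(m1 - m2) < 0.15:  # modes not separated
        return 0.5
    return float(0.5 * (m1 + m2))


@dataclass(frozen=True)
class StateInterval:
    """One contiguous interval in a single state."""

    state: str  # "free" (high FRET) | "bound" (low FRET)
    start: int  # frame index, inclusive
    stop: int  # frame index, exclusive
    duration: float  # s
    censored: bool  # touches the start or end of the trace


@dataclass
class StateSegmentation:
    """Alternating free/bound intervals partitioning a trace."""

    intervals: list[StateInterval]
    threshold: float
    exposure: float


def segment_states(
    E: np.ndarray,
    threshold: float,
    exposure: float = DEFAULT_EXPOSURE,
    min_dwell_frames: int = 2,
) -> StateSegmentation:
    """Threshold a FRET trace into free (E >= threshold) and bound intervals.

    Consecutive same-state frames merge into intervals; runs shorter than
    ``min_dwell_frames`` are absorbed into the preceding state to suppress
    single-frame noise crossings (set to 1 to disable).  Interval durations
    are frames * exposure; the first and last intervals are flagged censored
    because their true start/end lie outside the recording.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    e = np.asarray(E, dtype=float)
    valid = np.isfinite(e)
    if not valid.any():
        raise ValueError("trace has no valid FRET values")
    # missing frames inherit the previous state; leading NaNs take the first
    # valid frame's state
    states = (e >= threshold).astype(int)  # 1 = free
    first = int(np.flatnonzero(valid)[0])
    states[:first] = states[first]
    for i in range(first + 1, e.size):
        if not valid[i]:
            states[i] = states[i - 1]

    # run-length encode
    runs: list[list[int]] = []  # [state, length]
    for s in states:
        if runs and runs[-1][0] == s:
            runs[-1][1] += 1
        else:
            runs.append([int(s), 1])

    # absorb short runs into predecessor (first run exempt: no predecessor)
    if min_dwell_frames > 1:
        merged: list[list[int]] = []
        for st, ln in runs:
            if merged and ln < min_dwell_frames:
                merged[-1][1] += ln
            elif merged and merged[-1][0] == st:
                merged[-1][1] += ln
            else:
                merged.append([st, ln])
        runs = merged

    intervals: list[StateInterval] = []
    pos = 0
    for idx, (st, ln) in enumerate(runs):
        intervals.append(
            StateInterval(
                state="free" if st == 1 else "bound",
                start=pos,
                stop=pos + ln,
                duration=ln * exposure,
                censored=(idx == 0 or idx == len(runs) - 1),
            )
        )
        pos += ln
    return StateSegmentation(intervals=intervals, threshold=threshold, exposure=exposure)


def dwells_from_segmentation(
    seg: StateSegmentation, state: str, include_censored: bool = False
) -> DwellSet:
    """Collect dwell durations of one state ("free" -> t_on, "bound" -> t_off).

    Censored first/last intervals are excluded by default so the downstream
    exponential fit sees complete dwells only (set ``include_censored`` to
    keep them with their censoring flags for the censored MLE).
    """
    ivs = [iv for iv in seg.intervals if iv.state == state]
    if not include_censored:
        ivs = [iv for iv in ivs if not iv.censored]
    return DwellSet(
        durations=np.array([iv.duration for iv in ivs]),
        censored=np.array([iv.censored for iv in ivs]),
        condition=state,
    )
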