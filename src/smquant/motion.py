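"""Motion analysis: MSD power-law classification, velocity, stroke rates.

The mean squared displacement of a tracked particle over lag n of N frames is

    MSD(n, N) = sum_{i=1}^{N-n} (X_{i+n} - X_i)^2 / (N - n) = D dt^alpha

and the power-law exponent alpha separates free or constrained diffusion
(alpha <= 1) from superdiffusive, directed motion (alpha > 1), e.g. a
unidirectionally translocating helicase-recombinase complex.  Average
translocation velocity is the total route (sum of frame-to-frame displacements
of the Savitzky-Golay-smoothed track) divided by the trajectory duration.
Unwinding stroke rates are extracted from bead-distance traces by smoothing
and differentiation, segmenting bursts from pauses, and fitting the rate
distribution with a one- or two-component Gaussian mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.mixture import GaussianMixture

from .tracking import Trajectory

__all__ = [
    "MSDCurve",
    "MotionFit",
    "DistanceTrace",
    "StrokeFit",
    "compute_msd",
    "fit_msd",
    "classify_motion",
    "estimate_velocity",
    "extract_stroke_rates",
]


@dataclass
class MSDCurve:
    """MSD versus lag time for one trajectory."""

    lag: np.ndarray  # lag index n = 1..N-1
    lag_time: np.ndarray  # n * dt, s
    msd: np.ndarray  # nm^2
    n_frames: int

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=int)
        self.lag_time = np.asarray(self.lag_time, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)


@dataclass(frozen=True)
class MotionFit:
    """Power-law fit MSD = D * dt^alpha and the derived motion class."""

    D: float  # nm^2 / s^alpha
    alpha: float
    n_lags: int
    label: str  # diffusive | superdiffusive | static
    static: bool = False


@dataclass
class DistanceTrace:
    """Bead-centre distance between the traps as a function of time."""

    time: np.ndarray  # s
    distance: np.ndarray  # nm
    force: float | None = None  # constant clamp force, pN

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        if self.time.size != self.distance.size:
            raise ValueError("time and distance must have equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("distance trace must be uniformly sampled")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.distance))):
            raise ValueError("trace values must be finite")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class StrokeFit:
    """Segmented stroke rates and their Gaussian-mixture summary."""

    segment_rates: np.ndarray  # nm/s, one per contiguous segment
    segment_labels: list[str]  # "burst" | "pause"
    means: np.ndarray  # mixture component means
    sds: np.ndarray
    weights: np.ndarray
    n_components: int
    bic: dict[int, float] = field(default_factory=dict)

    @property
    def burst_rates(self) -> np.ndarray:
        mask = np.array([l == "burst" for l in self.segment_labels])
        return self.segment_rates[mask]

    @property
    def mean_burst_rate(self) -> float:
        r = self.burst_rates
        return float(np.mean(r)) if r.size else np.nan


def compute_msd(traj: Trajectory) -> MSDCurve:
    """Evaluate the MSD sum exactly for lags n = 1..N-1.

    Requires a uniformly sampled trajectory of length >= 2 (resample upstream
    if linking left gaps).
    """
    n = len(traj)
    if n < 2:
        raise ValueError("trajectory must have at least 2 points")
    dt_all = np.diff(traj.time)
    if not np.allclose(dt_all, dt_all[0], rtol=1e-6):
        raise ValueError("trajectory must be uniformly sampled (resample upstream)")
    dt = dt_all[0]
    x = traj.position
    lags = np.arange(1, n)
    msd = np.array([np.mean((x[k:] - x[:-k]) ** 2) for k in lags])
    return MSDCurve(lag=lags, lag_time=lags * dt, msd=msd, n_frames=n)


def fit_msd(msd: MSDCurve, lag_fraction: float = 0.25) -> MotionFit:
    """Fit MSD = D * dt^alpha over the short-lag range.

    Linear least squares on the log-log transformed curve over lags
    1..ceil(lag_fraction * N); at least 4 lags are required.  A trajectory
    with zero MSD everywhere has an undefined exponent and is flagged static.
    """
    n_fit = int(np.ceil(lag_fraction * msd.n_frames))
    n_fit = min(max(n_fit, 4), msd.lag.size)
    if msd.lag.size < 4:
        raise ValueError("need at least 4 lags to fit the MSD power law")
    y = msd.msd[:n_fit]
    t = msd.lag_time[:n_fit]
    if np.all(y == 0):
        return MotionFit(D=0.0, alpha=np.nan, n_lags=n_fit, label="static", static=True)
    pos = y > 0
    if pos.sum() < 4:
        return MotionFit(D=0.0, alpha=np.nan, n_lags=n_fit, label="static", static=True)
    slope, intercept = np.polyfit(np.log(t[pos]), np.log(y[pos]), 1)
    return MotionFit(
        D=float(np.exp(intercept)),
        alpha=float(slope),
        n_lags=n_fit,
        label=classify_motion(float(slope)),
    )


def classify_motion(alpha: float) -> str:
    """Motion class from the MSD exponent: alpha <= 1 diffusive, > 1 superdiffusive."""
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    return "superdiffusive" if alpha > 1.0 else "diffusive"


def estimate_velocity(
    traj: Trajectory, window: int = 51, polyorder: int = 3
) -> float:
    """Average translocation velocity in nm/s.

    The trajectory is smoothed with a Savitzky-Golay filter (default window 51
    frames, cubic) to suppress localization error and thermal fluctuations;
    the velocity is the sum of absolute frame-to-frame displacements of the
    smoothed track divided by the total trajectory time.  For unidirectional
    motion this equals net displacement over time.
    """
    n = len(traj)
    if n < 5:
        raise ValueError("trajectory too short for velocity estimation (need >= 5)")
    w = min(window, n if n % 2 == 1 else n - 1)
    if w % 2 == 0:
        w -= 1
    w = max(w, polyorder + 2 if (polyorder + 2) % 2 == 1 else polyorder + 3)
    smoothed = signal.savgol_filter(traj.position, window_length=w, polyorder=polyorder)
    total_route = float(np.sum(np.abs(np.diff(smoothed))))
    total_time = float(traj.time[-1] - traj.time[0])
    return total_route / total_time


def extract_stroke_rates(
    trace: DistanceTrace,
    smooth_window: int = 11,
    polyorder: int = 2,
    pause_threshold: float = 0.5,
    max_components: int = 2,
    random_state: int = 0,
) -> StrokeFit:
    """Extract unwinding stroke rates from a bead-distance trace.

    The trace is smoothed (Savitzky-Golay) and differentiated; contiguous runs
    of the derivative above/below ``pause_threshold`` (nm/s) are segmented
    into bursts and pauses.  Each segment's rate is the slope of a straight
    line fitted to the *raw* trace over the segment interior (trimmed by half
    the smoothing window at each end) -- averaging the smoothed derivative
    instead would dilute burst rates into the flanking pauses.  The pooled
    per-segment rates are then summarised by a one- or two-component Gaussian
    mixture, selected by BIC (a double-Gaussian resolves the pause peak near
    0 nm/s from the burst peak).
    """
    x = trace.distance
    n = x.size
    if n <= smooth_window:
        raise ValueError("trace shorter than the smoothing window")
    w = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
    dt = trace.dt
    rate = signal.savgol_filter(x, window_length=w, polyorder=polyorder, deriv=1, delta=dt)

    is_burst = np.abs(rate) > pause_threshold
    # run-length encode; runs shorter than the smoothing window are below the
    # derivative filter's resolution (noise crossings) and are absorbed into
    # the preceding segment
    runs: list[list[int]] = []
    for flag in is_burst:
        if runs and runs[-1][0] == int(flag):
            runs[-1][1] += 1
        else:
            runs.append([int(flag), 1])
    merged: list[list[int]] = []
    for st, ln in runs:
        if merged and ln < w:
            merged[-1][1] += ln
        elif merged and merged[-1][0] == st:
            merged[-1][1] += ln
        else:
            merged.append([st, ln])
    starts_l, flags = [], []
    pos = 0
    for st, ln in merged:
        starts_l.append(pos)
        flags.append(bool(st))
        pos += ln
    starts = np.asarray(starts_l)
    ends = np.append(starts[1:], n)
    is_burst = np.zeros(n, dtype=bool)
    for a, b, fl in zip(starts, ends, flags):
        is_burst[a:b] = fl

    trim = w // 2
    seg_rates: list[float] = []
    seg_labels: list[str] = []
    for a, b in zip(starts, ends):
        label = "burst" if is_burst[a] else "pause"
        # trim as much of the smoothing ramp as the segment affords while
        # keeping at least 5 interior points for the slope fit
        t_eff = min(trim, max((b - a - 5) // 2, 0))
        ai, bi = a + t_eff, b - t_eff
        if bi - ai >= 2:
            slope = np.polyfit(trace.time[ai:bi], x[ai:bi], 1)[0]
        else:
            slope = float(np.mean(rate[a:b]))
        seg_rates.append(float(slope))
        seg_labels.append(label)

    rates = np.asarray(seg_rates)
    if rates.size == 1:  # a single segment needs no mixture
        return StrokeFit(
            segment_rates=rates,
            segment_labels=seg_labels,
            means=rates.copy(),
            sds=np.zeros(1),
            weights=np.ones(1),
            n_components=1,
            bic={1: np.nan},
        )
    bic: dict[int, float] = {}
    best: GaussianMixture | None = None
    ncomp_max = min(max_components, max(1, rates.size))
    for k in range(1, ncomp_max + 1):
        gm = GaussianMixture(n_components=k, random_state=random_state, n_init=3)
        gm.fit(rates.reshape(-1, 1))
        bic[k] = float(gm.bic(rates.reshape(-1, 1)))
        if best is None or bic[k] < bic[best.n_components]:
            best = gm
    assert best is not None
    order = np.argsort(best.means_.ravel())
    return StrokeFit(
        segment_rates=rates,
        segment_labels=seg_labels,
        means=best.means_.ravel()[order],
        sds=np.sqrt(best.covariances_.ravel()[order]),
        weights=best.weights_.ravel()[order],
        n_components=best.n_components,
        bic=bic,
    )
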