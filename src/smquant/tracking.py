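"""Sub-pixel particle localization in kymographs and trajectory linking.

A kymograph is a 2D image of fluorescence intensity along a tethered DNA
molecule (spatial pixels) versus time (scan lines).  Particles are localized
per frame by averaging a three-frame moving window and fitting candidate peaks
with a 1D Gaussian plus offset, which yields sub-pixel positions; localizations
are then linked frame-to-frame into trajectories by greedy nearest-neighbour
assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

logger = logging.getLogger(__name__)

__all__ = [
    "Kymograph",
    "Localization",
    "Trajectory",
    "DetectionParams",
    "localize_frame",
    "localize_all",
    "link_trajectories",
]


@dataclass
class Kymograph:
    """2D intensity array [spatial pixel, frame] with scan calibration.

    ``pixel_size`` is nm per pixel and ``line_time`` seconds per scan line;
    the instrument defaults are 100 nm/px and 0.997 s/line.
    """

    intensity: np.ndarray
    pixel_size: float = 100.0
    line_time: float = 0.997
    channel: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph intensity must be 2D [pixel, frame]")
        if self.pixel_size <= 0 or self.line_time <= 0:
            raise ValueError("pixel_size and line_time must be positive")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("kymograph intensity must be finite and non-negative")

    @property
    def n_pixels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]


@dataclass(frozen=True)
class Localization:
    """One sub-pixel particle localization in one frame."""

    frame: int
    position: float  # nm
    amplitude: float  # counts above offset
    width: float  # nm (Gaussian sigma)
    residual: float  # RMS fit residual, counts


@dataclass
class Trajectory:
    """Positions of one particle over time.

    ``time`` in seconds (frame * line_time), ``position`` in nm; uniform
    spacing equal to the line time, with any linking gaps filled by the
    ``gap_frames`` annotation rather than resampling.
    """

    time: np.ndarray
    position: np.ndarray
    particle_id: int = 0
    channel: str = ""
    gap_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.time.size != self.position.size:
            raise ValueError("time and position must have equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time))) if len(self) > 1 else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": self.particle_id,
                "time_s": self.time,
                "position_nm": self.position,
            }
        )


@dataclass(frozen=True)
class DetectionParams:
    """Peak detection and fitting configuration.

    ``threshold_sigmas`` sets the candidate threshold at
    median + threshold_sigmas * robust sigma (1.4826*MAD) of the averaged
    profile; ``fit_halfwidth`` is the half-width of the fit window in pixels.
    """

    threshold_sigmas: float = 3.0
    fit_halfwidth: int = 5
    min_separation: int = 3  # px between candidate maxima
    dedup_distance: float = 1.0  # px; converged fits closer than this merge


def _gauss_offset(p, offset, amplitude, mu, sigma):
    return offset + amplitude * np.exp(-((p - mu) ** 2) / (2.0 * sigma**2))


def localize_frame(
    kymo: Kymograph, frame: int, params: DetectionParams | None = None
) -> list[Localization]:
    """Localize particles in one frame of a kymograph.

    Averages the intensity of frames {frame-1, frame, frame+1} (truncated at
    the sequence edges), thresholds candidate peaks at median + 3 robust sigma,
    and fits each candidate with offset + A*exp(-(p-mu)^2 / (2 s^2)) over a
    +/-5 px window.  Only converged fits inside the field of view are
    returned; an empty frame yields an empty list.
    """
    params = params or DetectionParams()
    if not 0 <= frame < kymo.n_frames:
        raise IndexError(f"frame {frame} outside kymograph with {kymo.n_frames} frames")

    lo, hi = max(0, frame - 1), min(kymo.n_frames, frame + 2)
    profile = kymo.intensity[:, lo:hi].mean(axis=1)

    med = np.median(profile)
    mad = np.median(np.abs(profile - med))
    robust_sigma = 1.4826 * mad
    threshold = med + params.threshold_sigmas * robust_sigma
    if robust_sigma == 0 and np.ptp(profile) == 0:
        return []

    peaks, _ = signal.find_peaks(
        profile, height=threshold, distance=params.min_separation
    )
    # a peak at the very edge has no turning point; include edge maxima
    for edge in (0, profile.size - 1):
        inner = 1 if edge == 0 else profile.size - 2
        if profile[edge] > threshold and profile[edge] >= profile[inner]:
            peaks = np.append(peaks, edge)

    out: list[Localization] = []
    for pk in np.unique(peaks):
        a = max(0, pk - params.fit_halfwidth)
        b = min(profile.size, pk + params.fit_halfwidth + 1)
        px = np.arange(a, b, dtype=float)
        y = profile[a:b]
        p0 = [float(y.min()), float(y[pk - a] - y.min()), float(pk), 1.5]
        try:
            popt, _ = optimize.curve_fit(
                _gauss_offset,
                px,
                y,
                p0=p0,
                bounds=([0, 0, a - 1, 0.3], [np.inf, np.inf, b, params.fit_halfwidth * 2.0]),
                maxfev=2000,
            )
        except RuntimeError:
            logger.debug("fit did not converge for candidate at px %d, frame %d", pk, frame)
            continue
        offset, amp, mu, sigma = popt
        pos_nm = mu * kymo.pixel_size
        if not 0 <= pos_nm < kymo.n_pixels * kymo.pixel_size:
            continue
        # the fitted peak must itself clear the detection threshold,
        # otherwise a noise blip that crossed it at a single pixel survives
        if amp < params.threshold_sigmas * robust_sigma:
            continue
        rms = float(np.sqrt(np.mean((_gauss_offset(px, *popt) - y) ** 2)))
        out.append(
            Localization(
                frame=frame,
                position=float(pos_nm),
                amplitude=float(amp),
                width=float(sigma * kymo.pixel_size),
                residual=rms,
            )
        )
    # neighbouring candidate pixels can converge onto the same peak; keep the
    # brighter of any pair of fits closer than dedup_distance
    out.sort(key=lambda l: -l.amplitude)
    kept: list[Localization] = []
    for loc in out:
        if all(
            abs(loc.position - k.position) > params.dedup_distance * kymo.pixel_size
            for k in kept
        ):
            kept.append(loc)
    kept.sort(key=lambda l: l.position)
    return kept


def localize_all(
    kymo: Kymograph, params: DetectionParams | None = None
) -> list[Localization]:
    """Localize every frame; returns localizations sorted by frame."""
    locs: list[Localization] = []
    for f in range(kymo.n_frames):
        locs.extend(localize_frame(kymo, f, params))
    return locs


def link_trajectories(
    locs: list[Localization],
    line_time: float,
    max_step: float = 300.0,
    max_gap: int = 2,
    min_length: int = 2,
) -> list[Trajectory]:
    """Link localizations into trajectories by greedy nearest-neighbour.

    A link requires displacement <= ``max_step`` nm and a frame gap <=
    ``max_gap``; among competing candidates the smallest displacement wins and
    each localization joins at most one trajectory.  Tracks shorter than
    ``min_length`` (unlinked singletons) are discarded.  The assignment is
    independent of the within-frame ordering of the input.
    """
    if not locs:
        return []
    by_frame: dict[int, list[Localization]] = {}
    for loc in locs:
        by_frame.setdefault(loc.frame, []).append(loc)
    # canonical within-frame order -> permutation invariance
    for f in by_frame:
        by_frame[f].sort(key=lambda l: (l.position, -l.amplitude))

    tracks: list[list[Localization]] = []
    active: list[int] = []  # indices into tracks

    for frame in sorted(by_frame):
        frame_locs = by_frame[frame]
        # candidate (displacement, track_idx, loc_idx) links
        cands = []
        for ti in active:
            last = tracks[ti][-1]
            if frame - last.frame > max_gap:
                continue
            for li, loc in enumerate(frame_locs):
                d = abs(loc.position - last.position)
                if d <= max_step:
                    cands.append((d, ti, li))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_locs: set[int] = set()
        for d, ti, li in cands:
            if ti in used_tracks or li in used_locs:
                continue
            tracks[ti].append(frame_locs[li])
            used_tracks.add(ti)
            used_locs.add(li)
        for li, loc in enumerate(frame_locs):
            if li not in used_locs:
                tracks.append([loc])
        active = [ti for ti in range(len(tracks)) if frame - tracks[ti][-1].frame <= max_gap]

    out: list[Trajectory] = []
    tid = 0
    for track in tracks:
        if len(track) < min_length:
            continue
        frames = np.array([l.frame for l in track])
        gaps = [int(f) for f in frames[:-1][np.diff(frames) > 1]]
        out.append(
            Trajectory(
                time=frames * line_time,
                position=np.array([l.position for l in track]),
                particle_id=tid,
                gap_frames=gaps,
            )
        )
        tid += 1
    return out
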