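"""Synthetic single-molecule data with stored ground truth.

Every input type of the analysis stages can be generated here with known
truth, so the whole pipeline is testable without instrument data: kymographs
of static, diffusing or unidirectionally translocating fluorophores on a 1D
DNA axis (Gaussian line-scan PSF, Poisson shot noise plus optional Gaussian
read noise); burst-pause unwinding traces; exponential fluorescence-loss
traces; two-state telegraph smFRET traces; multi-branch worm-like-chain
force-distance curves with unfolding events; and amplicon reads carrying
deletion / substitution repair outcomes.

All generators are driven by an explicit integer seed and are bit-identical
for identical (seed, config).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .fret import DEFAULT_EXPOSURE, FretTrace
from .kinetics import DecayTrace
from .motion import DistanceTrace
from .polymer import ForceExtensionCurve, PolymerParams, wlc_force
from .tracking import Kymograph

__all__ = [
    "SimConfig",
    "ParticleSpec",
    "KymographTruth",
    "simulate_kymograph",
    "DistanceTraceTruth",
    "simulate_distance_trace",
    "simulate_decay_trace",
    "FretTruth",
    "simulate_fret_trace",
    "FdTruth",
    "simulate_fd_curve",
    "ReadTruth",
    "simulate_repair_reads",
    "find_microhomology_sites",
]


# --------------------------------------------------------------------------
# kymographs


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry and noise model for kymograph simulation.

    Defaults match the confocal line-scan acquisition of the analysed
    experiments: 100 nm pixels, 0.997 s line time.  ``noise_model`` is
    "poisson" (shot noise on photon counts), "gaussian" (additive, with
    ``noise_sigma``), "both", or "none".  ``bleach_rate`` (1/s) truncates a
    particle's emission after an exponentially distributed lifetime; 0
    disables bleaching.
    """

    seed: int = 0
    pixel_size: float = 100.0  # nm / px
    line_time: float = 0.997  # s / line
    n_frames: int = 300
    n_pixels: int = 64
    psf_sigma: float = 1.5  # px
    amplitude: float = 200.0  # photon counts at peak
    background: float = 20.0  # counts
    noise_model: str = "poisson"
    noise_sigma: float = 0.0  # counts, gaussian read noise
    bleach_rate: float = 0.0  # 1/s

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.line_time <= 0:
            raise ValueError("pixel_size and line_time must be positive")
        if self.n_frames <= 0 or self.n_pixels <= 0:
            raise ValueError("kymograph dimensions must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.noise_model not in ("poisson", "gaussian", "both", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        data = json.loads(text)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class ParticleSpec:
    """Motion specification of one simulated particle.

    kind: "static", "diffusive" (``D`` in nm^2/s) or "directed" (``v`` in
    nm/s).  ``x0`` is the start position in nm; frames outside
    [start_frame, end_frame) contribute no emission.
    """

    kind: str
    x0: float
    D: float = 0.0
    v: float = 0.0
    start_frame: int = 0
    end_frame: int | None = None
    amplitude: float | None = None  # overrides SimConfig.amplitude

    def __post_init__(self) -> None:
        if self.kind not in ("static", "diffusive", "directed"):
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.D < 0:
            raise ValueError("diffusion coefficient must be non-negative")


@dataclass
class KymographTruth:
    """Ground truth for one simulated kymograph."""

    particles: list[ParticleSpec]
    paths: list[np.ndarray]  # nm, one per particle, length n_frames (NaN = absent)
    config: SimConfig


def _particle_path(spec: ParticleSpec, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """True position per frame in nm; NaN while the particle is absent."""
    n = cfg.n_frames
    length = cfg.n_pixels * cfg.pixel_size
    end = spec.end_frame if spec.end_frame is not None else n
    path = np.full(n, np.nan)
    t_active = np.arange(spec.start_frame, min(end, n))
    if t_active.size == 0:
        return path
    if spec.kind == "static":
        x = np.full(t_active.size, spec.x0)
    elif spec.kind == "directed":
        x = spec.x0 + spec.v * (t_active - spec.start_frame) * cfg.line_time
        # a directed particle that runs off the DNA end leaves the field
        x[(x < 0) | (x >= length)] = np.nan
    else:  # diffusive: Brownian increments, reflecting at the DNA ends
        steps = rng.normal(0.0, np.sqrt(2.0 * spec.D * cfg.line_time), t_active.size - 1)
        x = np.empty(t_active.size)
        x[0] = spec.x0
        for i, s in enumerate(steps):
            xi = x[i] + s
            # reflect at [0, length)
            while xi < 0 or xi >= length:
                if xi < 0:
                    xi = -xi
                else:
                    xi = 2 * (length - 1e-9) - xi
            x[i + 1] = xi
    if cfg.bleach_rate > 0:
        lifetime = rng.exponential(1.0 / cfg.bleach_rate)
        alive = (t_active - spec.start_frame) * cfg.line_time < lifetime
        x = np.where(alive, x, np.nan)
    path[t_active] = x
    return path


def simulate_kymograph(
    config: SimConfig, particles: list[ParticleSpec]
) -> tuple[Kymograph, KymographTruth]:
    """Render a kymograph of the given particles with stored ground truth.

    Per frame t and pixel p the noiseless intensity is

        background + sum_i A_i exp(-(p - x_i(t)/px)^2 / (2 psf_sigma^2))

    over particles currently inside the field; Poisson and/or Gaussian noise
    is then applied per the config.
    """
    for spec in particles:
        length = config.n_pixels * config.pixel_size
        if not 0 <= spec.x0 < length:
            raise ValueError(
                f"particle start {spec.x0} nm outside field [0, {length}) nm"
            )
    rng = np.random.default_rng(config.seed)
    paths = [_particle_path(spec, config, rng) for spec in particles]

    px = np.arange(config.n_pixels, dtype=float)[:, None]  # [pixel, 1]
    img = np.full((config.n_pixels, config.n_frames), float(config.background))
    for spec, path in zip(particles, paths):
        amp = spec.amplitude if spec.amplitude is not None else config.amplitude
        pos_px = path / config.pixel_size  # [frame]
        with np.errstate(invalid="ignore"):
            contrib = amp * np.exp(
                -((px - pos_px[None, :]) ** 2) / (2.0 * config.psf_sigma**2)
            )
        img += np.nan_to_num(contrib)

    if config.noise_model in ("poisson", "both"):
        img = rng.poisson(img).astype(float)
    if config.noise_model in ("gaussian", "both") and config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, img.shape)
    img = np.clip(img, 0.0, None)

    kymo = Kymograph(
        intensity=img, pixel_size=config.pixel_size, line_time=config.line_time
    )
    return kymo, KymographTruth(particles=list(particles), paths=paths, config=config)


# --------------------------------------------------------------------------
# bead-distance unwinding traces


@dataclass
class DistanceTraceTruth:
    """Per-segment ground truth of a burst-pause trace."""

    burst_rates: np.ndarray  # nm/s, drawn per burst
    segment_starts: np.ndarray  # s
    segment_labels: list[str]  # "burst" | "pause"


def simulate_distance_trace(
    burst_rate_mean: float = 3.3,
    burst_rate_rel_sd: float = 0.2,
    burst_dur: float = 30.0,
    pause_dur: float = 20.0,
    total_dur: float = 300.0,
    dt: float = 1.0,
    noise_sigma: float = 2.0,
    seed: int = 0,
) -> tuple[DistanceTrace, DistanceTraceTruth]:
    """Simulate a bead-distance trace of unwinding bursts separated by pauses.

    The mean path is piecewise linear and monotone non-decreasing: during a
    burst the distance grows at a rate drawn from
    N(burst_rate_mean, rel_sd * mean) (clipped at 0), during a pause it is
    flat; additive Gaussian noise models bead fluctuation.  Defaults are the
    published HELQ-alone regime: 3.3 nm/s mean burst rate, 1 s sampling.
    """
    if dt <= 0 or burst_dur <= 0 or pause_dur <= 0 or total_dur <= 0:
        raise ValueError("durations and dt must be positive")
    if burst_rate_mean < 0:
        raise ValueError("burst rate must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, total_dur, dt)
    d = np.zeros_like(t)

    rates: list[float] = []
    seg_starts: list[float] = []
    seg_labels: list[str] = []
    pos = 0.0
    t0 = 0.0
    bursting = True
    while t0 < total_dur:
        dur = burst_dur if bursting else pause_dur
        rate = 0.0
        if bursting:
            rate = max(
                0.0, rng.normal(burst_rate_mean, burst_rate_rel_sd * burst_rate_mean)
            )
            rates.append(rate)
        seg_starts.append(t0)
        seg_labels.append("burst" if bursting else "pause")
        mask = (t >= t0) & (t < t0 + dur)
        d[mask] = pos + rate * (t[mask] - t0)
        pos += rate * min(dur, total_dur - t0)
        t0 += dur
        bursting = not bursting

    if noise_sigma > 0:
        d = d + rng.normal(0.0, noise_sigma, d.size)
    trace = DistanceTrace(time=t, distance=d)
    truth = DistanceTraceTruth(
        burst_rates=np.asarray(rates),
        segment_starts=np.asarray(seg_starts),
        segment_labels=seg_labels,
    )
    return trace, truth


# --------------------------------------------------------------------------
# fluorescence-loss decays


def simulate_decay_trace(
    k: float = 0.136,
    A: float = 1.0,
    C: float = 0.0,
    total_dur: float = 30.0,
    dt: float = 0.1,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DecayTrace:
    """Exponential fluorescence-loss trace I(t) = A exp(-k t) + C + noise.

    ``k`` in 1/min, time axis in minutes.  Default k is the published
    wild-type stripping rate.
    """
    if k < 0:
        raise ValueError("decay rate k must be non-negative")
    if dt <= 0 or total_dur <= 0:
        raise ValueError("dt and total_dur must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, total_dur, dt)
    y = A * np.exp(-k * t) + C
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, y.size)
    return DecayTrace(time=t, intensity=y)


# --------------------------------------------------------------------------
# smFRET telegraph traces


@dataclass
class FretTruth:
    """Continuous-time two-state path underlying a simulated FRET trace."""

    state_path: np.ndarray  # per-frame state, 1 = free (high FRET)
    dwell_states: list[str]  # continuous-time dwell sequence
    dwell_durations: np.ndarray  # s, matching dwell_states
    E_frames: np.ndarray  # exposure-averaged noiseless E per frame


def simulate_fret_trace(
    E_low: float = 0.2,
    E_high: float = 0.8,
    k_bind: float = 0.5,
    k_release: float = 0.5,
    n_frames: int = 1000,
    exposure: float = DEFAULT_EXPOSURE,
    noise_sigma: float = 0.0,
    total_intensity: float = 1000.0,
    start_state: str | None = None,
    seed: int = 0,
) -> tuple[FretTrace, FretTruth]:
    """Two-state telegraph smFRET trace with stored state path.

    The molecule alternates between free (high FRET, leaves at rate
    ``k_bind``) and bound (low FRET, leaves at rate ``k_release``) with
    exponential holding times; each frame's noiseless E is the
    exposure-time-weighted average of the state efficiencies, and donor /
    acceptor intensities are I_A = E * total, I_D = (1 - E) * total plus
    Gaussian noise.
    """
    if not 0 <= E_low < E_high <= 1:
        raise ValueError("need 0 <= E_low < E_high <= 1")
    if k_bind < 0 or k_release < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    total_t = n_frames * exposure

    if start_state is None:
        # stationary start (uniform if both rates vanish)
        p_free = 0.5 if (k_bind + k_release) == 0 else k_release / (k_bind + k_release)
        state = 1 if rng.random() < p_free else 0
    else:
        state = 1 if start_state == "free" else 0

    # continuous-time jump sequence
    times = [0.0]
    states = [state]
    t = 0.0
    while t < total_t:
        rate = k_bind if state == 1 else k_release
        if rate == 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= total_t:
            break
        state = 1 - state
        times.append(t)
        states.append(state)
    times.append(total_t)

    dwell_states = ["free" if s == 1 else "bound" for s in states]
    dwell_durations = np.diff(times)

    # exposure-averaged E per frame
    e_of = {1: E_high, 0: E_low}
    edges = np.array(times)
    frame_E = np.empty(n_frames)
    frame_state = np.empty(n_frames, dtype=int)
    for f in range(n_frames):
        a, b = f * exposure, (f + 1) * exposure
        # overlap of [a,b) with each dwell [edges[j], edges[j+1])
        j0 = np.searchsorted(edges, a, side="right") - 1
        e_acc = 0.0
        occ = {0: 0.0, 1: 0.0}
        j = max(j0, 0)
        while j < len(states) and edges[j] < b:
            lo = max(edges[j], a)
            hi = min(edges[j + 1], b)
            if hi > lo:
                e_acc += e_of[states[j]] * (hi - lo)
                occ[states[j]] += hi - lo
            j += 1
        frame_E[f] = e_acc / exposure
        frame_state[f] = 1 if occ[1] >= occ[0] else 0

    e_obs = frame_E
    if noise_sigma > 0:
        e_obs = np.clip(frame_E + rng.normal(0.0, noise_sigma, n_frames), 0.0, 1.0)
    I_A = e_obs * total_intensity
    I_D = (1.0 - e_obs) * total_intensity
    trace = FretTrace(I_D=I_D, I_A=I_A, exposure=exposure)
    truth = FretTruth(
        state_path=frame_state,
        dwell_states=dwell_states,
        dwell_durations=dwell_durations,
        E_frames=frame_E,
    )
    return trace, truth


# --------------------------------------------------------------------------
# force-distance curves


@dataclass
class FdTruth:
    """Ground truth of a simulated force-distance curve."""

    contour_lengths: np.ndarray  # nm, one per branch
    loop_sizes: np.ndarray  # nm, successive differences
    event_indices: np.ndarray  # sample index where each branch starts


def simulate_fd_curve(
    polymer: PolymerParams,
    events: list[tuple[float, float]] | None = None,
    extension_range: tuple[float, float] = (0.3, 0.98),
    n_points: int = 400,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[ForceExtensionCurve, FdTruth]:
    """Concatenated WLC branches with loop-release unfolding events.

    ``events`` is a list of (trigger force pN, released contour length nm)
    with strictly increasing trigger forces; when the running branch force
    reaches a trigger the contour length grows by the released length and the
    force drops onto the new branch.  ``extension_range`` is in fractions of
    the initial contour length.
    """
    events = list(events or [])
    if any(dlc <= 0 for _, dlc in events):
        raise ValueError("released contour length must be positive")
    trig = [f for f, _ in events]
    if any(b <= a for a, b in zip(trig, trig[1:])):
        raise ValueError("trigger forces must be strictly increasing")
    lo, hi = extension_range
    if not 0 <= lo < hi:
        raise ValueError("invalid extension range")
    # sweep far enough to sample the final branch after all loop releases
    lc_final = polymer.Lc + sum(dlc for _, dlc in events)
    x = np.linspace(lo * polymer.Lc, hi * lc_final, n_points)
    if x[-1] >= lc_final and polymer.S is None:
        raise ValueError("requested extension reaches the contour length")

    rng = np.random.default_rng(seed)
    lc = polymer.Lc
    lcs = [lc]
    event_idx: list[int] = []
    f = np.empty(n_points)
    pending = list(events)
    for i, xi in enumerate(x):
        fi = wlc_force(min(xi, 0.999 * lc), replace(polymer, Lc=lc))
        if pending and fi >= pending[0][0]:
            lc = lc + pending.pop(0)[1]
            lcs.append(lc)
            event_idx.append(i)
            fi = wlc_force(min(xi, 0.999 * lc), replace(polymer, Lc=lc))
        f[i] = fi
    if noise_sigma > 0:
        f = f + rng.normal(0.0, noise_sigma, n_points)

    curve = ForceExtensionCurve(extension=x, force=f)
    lcs_arr = np.asarray(lcs)
    truth = FdTruth(
        contour_lengths=lcs_arr,
        loop_sizes=np.diff(lcs_arr),
        event_indices=np.asarray(event_idx, dtype=int),
    )
    return curve, truth


# --------------------------------------------------------------------------
# amplicon repair reads


@dataclass
class ReadTruth:
    """Per-read ground truth labels for a simulated amplicon read set."""

    labels: list[str]  # intact | NHEJ | MMEJ | SSTR
    deletions: list[tuple[int, int] | None]  # reference interval, or None
    mh_lengths: list[int]


def find_microhomology_sites(
    reference: str, min_del: int = 6, max_del: int = 30, min_mh: int = 2
) -> list[tuple[int, int, int]]:
    """All deletions (start, length, mh) with length >= min_del and junction
    microhomology >= min_mh in the reference.

    The microhomology of deletion [s, s+L) is the longest m with
    ref[s:s+m] == ref[s+L:s+L+m] (capped at L).
    """
    sites = []
    n = len(reference)
    for L in range(min_del, min(max_del, n - 2) + 1):
        for s in range(0, n - L):
            m = _mh_len(reference, s, L)
            if m >= min_mh:
                sites.append((s, L, m))
    return sites


def _mh_len(ref: str, start: int, length: int) -> int:
    m = 0
    n = len(ref)
    while (
        m < length
        and start + length + m < n
        and ref[start + m] == ref[start + length + m]
    ):
        m += 1
    return m


_BASES = "ACGT"


def simulate_repair_reads(
    reference: str,
    mix: dict[str, float],
    donor_subs: list[tuple[int, str]] | None = None,
    n_reads: int = 1000,
    cut_site: int | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], ReadTruth]:
    """Simulate amplicon reads carrying repair outcomes with known labels.

    ``mix`` gives class proportions over {"intact", "NHEJ", "MMEJ", "SSTR"}.
    NHEJ reads carry a single 1-5 bp deletion near the cut site; MMEJ reads a
    single >5 bp deletion placed at a site with >= 2 bp junction
    microhomology (searched in the reference); SSTR reads carry exactly the
    three donor substitutions.  Returns (list of (read_id, sequence), truth).
    """
    reference = reference.upper()
    if len(reference) < 50:
        raise ValueError("reference must be at least 50 bp")
    if set(reference) - set(_BASES):
        raise ValueError("reference must contain only A/C/G/T")
    classes = list(mix)
    unknown = set(classes) - {"intact", "NHEJ", "MMEJ", "SSTR"}
    if unknown:
        raise ValueError(f"unknown repair classes: {sorted(unknown)}")
    probs = np.array([mix[c] for c in classes], dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("mix proportions must be non-negative with positive sum")
    probs = probs / probs.sum()
    cut = cut_site if cut_site is not None else len(reference) // 2

    mmej_sites = None
    if mix.get("MMEJ", 0) > 0:
        mmej_sites = find_microhomology_sites(reference)
        if not mmej_sites:
            raise ValueError(
                "reference has no >5 bp deletion with >= 2 bp microhomology; "
                "cannot generate MMEJ reads"
            )
    if mix.get("SSTR", 0) > 0:
        if not donor_subs or len(donor_subs) != 3:
            raise ValueError("SSTR generation requires exactly 3 donor substitutions")
        for pos, base in donor_subs:
            if not 0 <= pos < len(reference):
                raise ValueError(f"donor substitution position {pos} outside reference")
            if base not in _BASES:
                raise ValueError(f"invalid donor base {base!r}")
            if reference[pos] == base:
                raise ValueError(
                    f"donor base at {pos} equals the reference base; not a substitution"
                )

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    labels: list[str] = []
    deletions: list[tuple[int, int] | None] = []
    mh_lengths: list[int] = []
    for i in range(n_reads):
        cls = classes[rng.choice(len(classes), p=probs)]
        if cls == "intact":
            seq = reference
            dele, mh = None, 0
        elif cls == "NHEJ":
            L = int(rng.integers(1, 6))
            # place the deletion spanning the cut site where possible
            s_lo = max(0, cut - L)
            s_hi = min(len(reference) - L, cut)
            s = int(rng.integers(s_lo, s_hi + 1))
            seq = reference[:s] + reference[s + L:]
            dele, mh = (s, L), _mh_len(reference, s, L)
        elif cls == "MMEJ":
            assert mmej_sites
            s, L, m = mmej_sites[rng.choice(len(mmej_sites))]
            seq = reference[:s] + reference[s + L:]
            dele, mh = (s, L), m
        else:  # SSTR
            assert donor_subs
            seq_l = list(reference)
            for pos, base in donor_subs:
                seq_l[pos] = base
            seq = "".join(seq_l)
            dele, mh = None, 0
        reads.append((f"read_{i:05d}_{cls}", seq))
        labels.append(cls)
        deletions.append(dele)
        mh_lengths.append(mh)
    return reads, ReadTruth(labels=labels, deletions=deletions, mh_lengths=mh_lengths)
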