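"""Polymer elasticity models and contour-length fitting for force-extension data.

Implements the Marko-Siggia worm-like chain (WLC) interpolation formula, an
extensible variant for dsDNA above ~10 pN, and a freely-jointed chain (FJC)
used as the ssDNA reference, plus unfolding-event detection and per-branch
contour-length fits.  A protein-mediated DNA loop releases contour length when
disrupted, so the loop size is the difference between contour lengths fitted to
neighbouring branches of the force-distance curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

__all__ = [
    "PolymerParams",
    "ForceExtensionCurve",
    "ContourFit",
    "wlc_force",
    "fjc_extension",
    "detect_events",
    "fit_contour_length",
    "loop_sizes",
]

#: Thermal energy at 25 degC in pN*nm.
KT_ROOM = 4.114


@dataclass(frozen=True)
class PolymerParams:
    """Mechanical parameters of a polymer chain.

    Parameters
    ----------
    Lp : float
        Persistence length in nm (50 nm for dsDNA).
    Lc : float
        Contour length in nm.
    kT : float
        Thermal energy in pN*nm; default 4.114 (room temperature).
    S : float or None
        Stretch modulus in pN for the extensible WLC; ``None`` selects the
        inextensible interpolation formula.
    kuhn : float
        Kuhn length in nm for the FJC (1.5 nm, standard for lambda-ssDNA).
    S_fjc : float
        FJC stretch modulus in pN (800 pN for ssDNA).
    """

    Lp: float = 50.0
    Lc: float = 16_000.0
    kT: float = KT_ROOM
    S: float | None = None
    kuhn: float = 1.5
    S_fjc: float = 800.0

    def __post_init__(self) -> None:
        if self.Lp <= 0 or self.Lc <= 0 or self.kT <= 0:
            raise ValueError("Lp, Lc and kT must all be positive")
        if self.S is not None and self.S <= 0:
            raise ValueError("stretch modulus S must be positive")


@dataclass
class ForceExtensionCurve:
    """A force-distance curve with optional event annotation.

    ``boundaries`` are indices into ``extension`` where a new branch starts
    (an unfolding event increased the contour length); branch ``i`` spans
    ``boundaries[i-1]:boundaries[i]`` with implicit 0 and ``len`` at the ends.
    """

    extension: np.ndarray  # nm, sorted ascending
    force: np.ndarray  # pN
    boundaries: list[int] = field(default_factory=list)
    contour_lengths: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.extension.shape != self.force.shape:
            raise ValueError("extension and force must have equal length")
        if np.any(np.diff(self.extension) < 0):
            raise ValueError("extension must be sorted ascending")

    def branches(self) -> list[slice]:
        edges = [0, *self.boundaries, len(self.extension)]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


@dataclass(frozen=True)
class ContourFit:
    """Result of a single-branch contour-length fit."""

    Lc: float  # nm
    stderr: float  # nm
    residual_rms: float  # pN
    n_points: int


def wlc_force(extension, params: PolymerParams):
    """Worm-like-chain force at the given extension(s).

    Inextensible Marko-Siggia interpolation

        F = (kT/Lp) * [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ]

    When ``params.S`` is set, the fractional extension is corrected by the
    enthalpic stretch ``F/S`` and the equation is solved self-consistently.

    Parameters
    ----------
    extension : float or array
        Extension x in nm.  The inextensible variant requires 0 <= x < Lc.
    params : PolymerParams

    Returns
    -------
    float or ndarray
        Force in pN, same shape as ``extension``.
    """
    x = np.asarray(extension, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0):
        raise ValueError("extension must be non-negative")
    if params.S is None:
        if np.any(x >= params.Lc):
            raise ValueError(
                "extension >= contour length is outside the inextensible WLC domain"
            )
        f = _ms_force(x / params.Lc, params)
    else:
        f = np.array([_extensible_wlc_force(xi, params) for xi in x])
    return float(f[0]) if scalar else f


def _ms_force(frac: np.ndarray, params: PolymerParams) -> np.ndarray:
    return (params.kT / params.Lp) * (0.25 / (1.0 - frac) ** 2 - 0.25 + frac)


def _extensible_wlc_force(x: float, params: PolymerParams) -> float:
    """Solve F = MS(x/Lc - F/S) for one extension by bracketed root finding."""
    S = params.S
    assert S is not None

    def g(f):
        frac = x / params.Lc - f / S
        if frac >= 1.0:
            return np.inf
        return (params.kT / params.Lp) * (0.25 / (1 - frac) ** 2 - 0.25 + frac) - f

    # F is bracketed between 0 and the force that cancels the enthalpic term.
    lo, hi = 0.0, max(1.0, S * (x / params.Lc))
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e7:  # pragma: no cover - pathological parameters
            raise RuntimeError("extensible WLC root bracketing failed")
    if g(lo) <= 0:
        return 0.0
    return float(optimize.brentq(g, lo, hi, xtol=1e-10))


def fjc_extension(force, params: PolymerParams):
    """Freely-jointed-chain extension at the given force(s).

    x = Lc * [coth(F b / kT) - kT/(F b)] * (1 + F/S_fjc), with Kuhn length b.
    Used as the ssDNA reference model; returns nm.
    """
    f = np.asarray(force, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    u = f * params.kuhn / params.kT
    with np.errstate(divide="ignore", invalid="ignore"):
        langevin = 1.0 / np.tanh(u) - 1.0 / u
    langevin[u == 0] = 0.0
    x = params.Lc * langevin * (1.0 + f / params.S_fjc)
    return float(x[0]) if scalar else x


def fit_contour_length(
    extension: np.ndarray,
    force: np.ndarray,
    params: PolymerParams,
    min_points: int = 20,
) -> ContourFit:
    """Fit the contour length of one WLC branch, all other parameters fixed.

    Least squares in force with ``Lc`` the single free parameter; the standard
    error comes from the Jacobian of the converged fit.  Branches sampled only
    at low force constrain ``Lc`` poorly and return a correspondingly wide
    standard error.
    """
    x = np.asarray(extension, dtype=float)
    f = np.asarray(force, dtype=float)
    if x.size != f.size:
        raise ValueError("extension and force must have equal length")
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} points per branch, got {x.size}")

    xmax = float(np.max(x))

    def resid(lc):
        return wlc_force(x, replace(params, Lc=float(lc[0]))) - f

    lc0 = max(params.Lc, 1.05 * xmax)
    sol = optimize.least_squares(
        resid, x0=[lc0], bounds=([xmax * (1 + 1e-9)], [np.inf])
    )
    if not sol.success:
        raise RuntimeError(
            f"contour-length fit did not converge (residual {np.abs(sol.fun).max():.3g} pN)"
        )
    dof = max(x.size - 1, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    jtj = float(np.squeeze(sol.jac.T @ sol.jac))
    stderr = np.sqrt(s2 / jtj) if jtj > 0 else np.inf
    return ContourFit(
        Lc=float(sol.x[0]),
        stderr=float(stderr),
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
        n_points=x.size,
    )


def detect_events(
    curve: ForceExtensionCurve,
    params: PolymerParams,
    residual_threshold: float = 2.0,
    min_branch_points: int = 20,
) -> list[int]:
    """Locate unfolding events in a force-distance curve.

    Scans the curve in extension order maintaining a running contour-length
    fit; a point whose force deviates from the running WLC prediction by more
    than ``residual_threshold`` (pN) -- persistently, i.e. the next point
    deviates too -- opens a new branch: at an unfolding event the released
    contour length makes the observed force drop below the branch prediction
    and stay low.  Branches ending up shorter than ``min_branch_points`` are
    merged into their predecessor (with a warning).

    Returns the list of branch start indices and annotates ``curve``.
    """
    x, f = curve.extension, curve.force
    n = x.size
    if n < min_branch_points:
        raise ValueError("curve too short for event detection")

    boundaries: list[int] = []
    start = 0
    i = min_branch_points
    fit = fit_contour_length(x[start:i], f[start:i], params, min_points=2)
    lc = fit.Lc
    while i < n:
        pred = wlc_force(min(x[i], 0.999 * lc), replace(params, Lc=lc))
        hit = abs(f[i] - pred) > residual_threshold
        if hit and i + 1 < n:
            pred_next = wlc_force(min(x[i + 1], 0.999 * lc), replace(params, Lc=lc))
            hit = abs(f[i + 1] - pred_next) > residual_threshold
        if hit:
            boundaries.append(i)
            start = i
            # seed the new branch with a short window so a second event close
            # behind the first is not overrun
            stop = min(start + 6, n)
            if stop - start >= 3:
                fit = fit_contour_length(
                    x[start:stop], f[start:stop], params, min_points=2
                )
                lc = fit.Lc
            i = stop
            continue
        # refit periodically so the running estimate tightens
        if (i - start) % 25 == 0:
            fit = fit_contour_length(x[start:i], f[start:i], params, min_points=2)
            lc = fit.Lc
        i += 1

    # merge undersized branches
    merged: list[int] = []
    edges = [0, *boundaries, n]
    for a, b in zip(edges[1:-1], edges[2:]):
        if b - a < min_branch_points:
            warnings.warn(
                f"branch of {b - a} points below minimum {min_branch_points}; merged",
                stacklevel=2,
            )
        else:
            merged.append(a)

    # refine each boundary: the scan detects a shallow force drop a few
    # samples late, so refit the clean interiors on both sides and hand the
    # points in a window around the boundary to whichever branch predicts
    # them better
    refined: list[int] = []
    edges = [0, *merged, n]
    for k in range(1, len(edges) - 1):
        b = edges[k]
        lo = max(edges[k - 1], b - 10)
        hi = min(edges[k + 1], b + 6)
        prev_int = slice(edges[k - 1], lo)
        next_int = slice(hi, edges[k + 1])
        if lo - edges[k - 1] < 5 or edges[k + 1] - hi < 5:
            refined.append(b)
            continue
        lc_prev = fit_contour_length(x[prev_int], f[prev_int], params, min_points=2).Lc
        lc_next = fit_contour_length(x[next_int], f[next_int], params, min_points=2).Lc
        idx = np.arange(lo, hi)
        rp = np.array(
            [f[i] - wlc_force(min(x[i], 0.999 * lc_prev), replace(params, Lc=lc_prev)) for i in idx]
        )
        rn = np.array(
            [f[i] - wlc_force(min(x[i], 0.999 * lc_next), replace(params, Lc=lc_next)) for i in idx]
        )
        # change point minimizing the total squared residual when points
        # before it belong to the previous branch and from it on to the next
        costs = [
            float(np.sum(rp[:j] ** 2) + np.sum(rn[j:] ** 2))
            for j in range(idx.size + 1)
        ]
        refined.append(int(lo + int(np.argmin(costs))))

    curve.boundaries = refined
    return refined


def loop_sizes(contour_lengths) -> list[float]:
    """Loop sizes as successive contour-length differences.

    ``loop_i = Lc_{i+1} - Lc_i``.  A negative difference is non-physical for a
    loop-release event; it is retained in the output but triggers a warning.
    """
    lc = list(contour_lengths)
    if len(lc) < 2:
        return []
    loops = [b - a for a, b in zip(lc[:-1], lc[1:])]
    if any(l < 0 for l in loops):
        warnings.warn("negative contour-length difference (non-physical loop)", stacklevel=2)
    return loops
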