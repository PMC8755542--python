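# Methods

This note documents the models implemented in `smquant`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the underlying analysis
protocol left the design open.

## Kymograph simulation and tracking

A kymograph is the intensity along a line-scanned, bead-tethered DNA
molecule versus time. The generator renders each particle as a 1D Gaussian
point-spread function,

    I(p, t) = background + Σᵢ Aᵢ exp(−(p − xᵢ(t)/px)² / (2 σ_psf²)),

with Poisson shot noise on the photon counts (optionally plus Gaussian read
noise), matching EM-CCD/confocal acquisition. Defaults: 100 nm/pixel,
0.997 s/line (the instrument settings of the experiments analysed),
σ_psf = 1.5 px and 200 counts peak amplitude over a 20-count background —
the acquisition reports neither PSF width nor photon budget, so these are
free parameters chosen to give a realistic ~10 nm localization precision.
Motion models: static; Brownian with Gaussian increments of variance 2 D Δt,
reflecting at the DNA ends (tethered geometry); directed at constant
velocity, leaving the field (and contributing nothing) if it runs off the
end. Photobleaching, off by default, truncates emission after an
exponential lifetime.

Localization averages the three frames centred on the target (two at the
sequence edges — this keeps the first/last frames usable at the cost of a
v·Δt/2 lag for moving particles), thresholds candidates at median + 3 robust
σ (1.4826·MAD) of the averaged profile, and fits offset + Gaussian over a
±5 px window by least squares. Two robustness guards were added after
testing: a converged fit must itself exceed the candidate threshold
(otherwise single-pixel noise blips survive as spurious localizations), and
fits converging within 1 px of one another are deduplicated keeping the
brighter (neighbouring candidate pixels can fit the same peak). Linking is
greedy nearest-neighbour (smallest displacement first, each localization in
at most one track, gaps up to 2 frames, 300 nm maximum step) and is
invariant to the within-frame ordering of its input.

## MSD, classification, velocity

The MSD is evaluated exactly as the time-averaged sum over lags
n = 1..N−1; a brute-force double loop serves as the test oracle. The
power law MSD = D Δtᵅ is fitted by linear least squares on log–log axes
over lags 1..⌈N/4⌉ (the fit range is unspecified in the protocol;
short lags carry the most statistics, and a quarter of the trajectory is a
common compromise). α ≤ 1 is labelled diffusive, α > 1 superdiffusive; an
all-zero MSD returns a static flag rather than an undefined exponent. Note
that single-trajectory α estimates scatter substantially around 1 for pure
diffusion; classification is reliable per ensemble, not per trace.

Velocity is Σ|smoothed frame-to-frame displacement| / total time with a
Savitzky–Golay filter, window 51 frames (stated), polynomial order 3
(unstated; cubic is the filter's common default). "Sum of frame-to-frame
displacements" is read as the sum of absolute smoothed displacements: for
unidirectional motion this equals the net displacement over time, and it
remains meaningful for back-and-forth traces. The estimator is invariant
under position offset and axis sign-flip.

## Stroke rates from bead-distance traces

Traces are smoothed (Savitzky–Golay, window 11 samples, order 2) and
differentiated; samples with |rate| above a 0.5 nm/s pause threshold are
bursts. Runs shorter than the smoothing window are below the derivative
filter's temporal resolution and are absorbed into the preceding segment —
without this, threshold-crossing noise fragments pauses into spurious short
"bursts" whose near-zero rates drag the burst mean down by ~10%.

Each segment's rate is the slope of a straight line fitted to the **raw**
trace over the segment interior, trimmed by half the smoothing window at
each end (adaptively, keeping at least 5 points). Averaging the smoothed
derivative over the segment instead would dilute burst rates into the
flanking pauses by roughly window/burst-duration (~25% at the defaults) —
far outside the published uncertainty of the mean rate. The pooled
segment-rate distribution is summarised by a Gaussian mixture with 1 or 2
components chosen by BIC (the protocol says "single or double Gaussian"
without a criterion; BIC is the standard choice).

Generator defaults describe the enzyme-alone unwinding regime: bursts drawn
from N(3.3, 0.2·3.3) nm/s, 30 s bursts alternating with 20 s pauses over
300 s at 1 s sampling with 2 nm Gaussian bead noise. Burst and pause
durations are not reported; these values reproduce the look of the published
traces (a handful of bursts per trace) and are *not* tuned thereafter.

## Dwell and decay kinetics

Right-censored exponential MLE: τ̂ = (Σ all durations)/(#uncensored), with
s.e. τ̂/√n_unc; with no censoring this is exactly the sample mean (tested as
an identity). The histogram method (Freedman–Diaconis bins, least squares
on counts) is retained for fidelity to figure-style fits and agrees with
the MLE within 10% at n ≥ 500. Decay fits use
I(t) = A e^{−kt} + C via Levenberg–Marquardt with data-driven start values;
a trace with no net loss returns k = 0 with a warning flag rather than an
error. k is reported in min⁻¹ and τ in s, following the conventions of the
original figures.

## smFRET

E = I_A/(I_D + I_A); frames with zero total intensity are missing (NaN) and
inherit the previous state during segmentation. The population histogram
takes one value per trace — the mean of its first 10 frames — in left-closed
0.1-wide bins on [0, 1]. Segmentation thresholds E at the midpoint of the
two histogram modes (fallback 0.5; the original threshold is unstated), and
a 2-frame minimum dwell suppresses single-frame noise crossings (a
deliberate knob, default on; it biases dwell means upward by a few per cent
when true dwells approach the 30 ms exposure — at the rates studied here,
dwells are tens of frames and the effect is ≪10%). First and last intervals
are censored and excluded from dwell fits by default. The telegraph
generator draws exponential holding times in continuous time and
exposure-averages E within each frame, so brief state excursions produce
intermediate E values exactly as camera integration does.

## Polymer elasticity and loop sizes

Worm-like chain, Marko–Siggia interpolation (the analysis names only the
model family):

    F(x) = (kT/Lp) [ 1/(4(1 − x/Lc)²) − 1/4 + x/Lc ],

with Lp = 50 nm and kT = 4.114 pN·nm (room temperature) as dsDNA defaults —
the original fits state neither. An extensible variant (x/Lc → x/Lc − F/S,
S = 1200 pN, solved by bracketed root finding) is available for forces above
~10 pN, and a freely-jointed chain (Kuhn length 1.5 nm, S = 800 pN) serves
as the ssDNA reference. The low-force limit F → (3kT/2Lp)(x/Lc) is exact to
first order; the interpolation's relative deviation from the Hooke line is
(x/Lc)/2 + O((x/Lc)²), i.e. ~2% is reached near x/Lc ≈ 0.04.

Event detection scans the curve in extension order with a running
contour-length fit and opens a new branch where the observed force deviates
from the running WLC prediction by more than 2 pN at two consecutive points
(persistence suppresses single-point noise; an unfolding event makes the
force drop and stay low). Each boundary is then refined by a change-point
step: the clean interiors on both sides are refitted and the boundary is
placed to minimise the total squared residual of the two-branch assignment.
Branches with fewer than 20 points are merged with a warning. Contour
lengths are fitted per branch with Lc the only free parameter; branches
sampled only at low force are weakly identifying and report a
correspondingly wide standard error. Loop sizes are successive Lc
differences; negative differences are non-physical for loop release and are
flagged but retained.

## Repair-outcome classification

Reads are aligned globally with affine gaps (match +2, mismatch −3, open
−5, extend −2). The upstream tooling note names a protein substitution
matrix, which is inapplicable to nucleotide reads; the DNA scoring above is
a deliberate replacement. Both orientations are scored and the better kept.
Deletions are left-aligned to a canonical placement before microhomology
calling; the microhomology of a deletion [s, e) is the longest m with
ref[s:s+m] = ref[e:e+m], capped at the deletion length (exhaustive prefix
search is the test oracle). Classes: intact (no edits); NHEJ (single
deletion of 1–5 bp); MMEJ (single deletion >5 bp with microhomology ≥2 bp);
SSTR (exactly the three donor substitutions, no indel). Deletions >5 bp
with <2 bp microhomology, insertions, and compound edits are not defined by
the stated rules and are routed to "other" without guessing intent. The
read generator emulates outcome mixtures with substitution-free sequencing;
it does not model sequencing error, read stitching, or UMI structure, so a
green classifier test establishes rule correctness, not robustness to
noisy base calls.

## What the generators do not emulate

Blinking and other photophysics beyond single-step bleaching; 2D
camera-frame imaging (kymographs only); force-dependent unwinding rates;
instrument drift; FRET gamma/crosstalk corrections; sequencing error models
beyond the simulated substitutions. Green tests therefore establish that
the estimators recover known parameters under the stated noise models, not
that they are robust to every instrumental artefact of real data.

## Numerical notes

All generators are driven by `numpy.random.default_rng(seed)` and are
bit-reproducible for identical (seed, config). CSV output uses 6
significant digits; TIFFs are written uncompressed as float32. Nonlinear
fits use scipy.optimize (`curve_fit` / `least_squares` / `brentq`) with
bounds keeping amplitudes and rates non-negative and Lc above the largest
observed extension.
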