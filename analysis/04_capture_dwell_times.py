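"""Capture dwell-time analysis: censored-MLE exponential taus.

Draws dwell-time samples at the two published oligo-capture lifetimes
(tau = 134 s wild type, tau = 179 s for the tighter-binding mutant), with a
fraction right-censored at a 600 s recording limit, and fits each set with
the censored MLE and with the histogram method for comparison.
Writes results/capture_dwells.json.
"""

import json
from pathlib import Path

import numpy as np

from smquant import kinetics
from smquant.kinetics import DwellSet

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

RECORD_LIMIT = 600.0  # s

results = {}
for name, tau_true, seed in (("wild_type", 134.0, 4134), ("mutant", 179.0, 4179)):
    rng = np.random.default_rng(seed)
    d = rng.exponential(tau_true, 500)
    censored = d > RECORD_LIMIT
    d[censored] = RECORD_LIMIT
    dwells = DwellSet(durations=d, censored=censored)
    mle = kinetics.fit_dwell_exponential(dwells, method="mle")
    hist = kinetics.fit_dwell_exponential(dwells, method="histogram")
    results[name] = {
        "tau_true_s": tau_true,
        "n": 500,
        "n_censored": int(censored.sum()),
        "tau_mle_s": mle.tau,
        "tau_mle_stderr_s": mle.stderr,
        "tau_histogram_s": hist.tau,
    }
    print(
        f"{name}: tau(MLE) = {mle.tau:.0f} +/- {mle.stderr:.0f} s, "
        f"tau(histogram) = {hist.tau:.0f} s "
        f"({int(censored.sum())} of 500 censored; truth {tau_true:.0f} s)"
    )

(OUT / "capture_dwells.json").write_text(json.dumps(results, indent=1))
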