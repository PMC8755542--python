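"""Kymograph tracking, MSD classification and translocation velocity.

Simulates kymographs (100 nm/px, 0.997 s/line) for the three motion regimes
seen on gapped DNA -- static binding, 1D diffusion, and directed
translocation at 14 nm/s (helicase-recombinase co-complex) -- then tracks
each particle, classifies its motion by the MSD power-law exponent, and
estimates the average velocity of the directed tracks.
Writes results/tracking_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from smquant import motion, simulate, tracking

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SCENARIOS = {
    "static": simulate.ParticleSpec(kind="static", x0=2500.0),
    "diffusive": simulate.ParticleSpec(kind="diffusive", x0=2500.0, D=1e4),
    "directed": simulate.ParticleSpec(kind="directed", x0=500.0, v=14.0),
}

rows = []
for name, spec in SCENARIOS.items():
    for s in range(10):
        cfg = simulate.SimConfig(seed=500 + s, n_frames=300, n_pixels=64)
        kymo, _ = simulate.simulate_kymograph(cfg, [spec])
        tracks = tracking.link_trajectories(
            tracking.localize_all(kymo), line_time=cfg.line_time
        )
        tr = max(tracks, key=len)
        fit = motion.fit_msd(motion.compute_msd(tr))
        rows.append(
            {
                "scenario": name,
                "seed": 500 + s,
                "track_frames": len(tr),
                "alpha": fit.alpha,
                "class": fit.label,
                "velocity_nm_s": motion.estimate_velocity(tr),
            }
        )

df = pd.DataFrame(rows)
df.to_csv(OUT / "tracking_summary.csv", index=False)

for name, grp in df.groupby("scenario"):
    print(
        f"{name:>9}: median alpha {grp.alpha.median():.2f}, "
        f"classes {grp['class'].value_counts().to_dict()}"
    )
directed = df[df.scenario == "directed"]
print(
    f"directed translocation velocity: {directed.velocity_nm_s.mean():.1f} "
    f"+/- {directed.velocity_nm_s.std(ddof=1):.1f} nm/s (truth 14 nm/s)"
)
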