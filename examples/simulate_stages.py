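"""Generate one synthetic curve per crystallization-matrix stage.

Each curve is the composite scattering of that stage's structural
components (purple-membrane sheets, bicelles, ribbons, lamellar orders,
transient long-period peaks, crystal reflections) with 2% counting-like
noise, written as three-column ASCII.
"""

from pathlib import Path

import bicellix as bx

out_dir = Path("scratch/stages")
out_dir.mkdir(parents=True, exist_ok=True)

scenario = bx.SyntheticScenario()
noise = bx.NoiseModel(level=0.02, seed=7)

for stage in bx.StageLabel:
    curve = bx.simulate_stage(scenario, stage, noise)
    path = out_dir / f"{stage.name.lower()}.dat"
    bx.write_sas_curve(curve, path)
    lo, hi = curve.q_range
    print(
        f"{stage.name:22s} -> {path}  ({len(curve)} points, "
        f"q = {lo:.3f}-{hi:.3f} 1/A, peak I = {curve.intensity.max():.1f})"
    )

print(
    "\nEach file is a (q, I, sigma) profile of one matrix state; feed them "
    "to the fitting, peak-analysis or classification examples."
)
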