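"""Fit the core-shell bicelle model to a synthetic bicelle curve.

Builds a noise-free curve from the documented bicelle geometry (total
radius 50 A, total height 45 A), perturbs the free parameters by 30%,
and lets the reduced-chi-square fit walk back to the truth.
"""

from dataclasses import asdict

import numpy as np

import bicellix as bx

q = np.geomspace(0.01, 0.5, 120)
truth = bx.BicelleParams(r_core=38.6, h_tail=28.8, h_head=8.1, delta_r=11.4, scale=3e7)
curve = bx.SASCurve(q, bx.bicelle_intensity(q, truth), label="synthetic bicelles")

rng = np.random.default_rng(0)
init = {
    "r_core": truth.r_core * 1.25,
    "h_head": truth.h_head * 0.75,
    "scale": truth.scale * 1.3,
}
problem = bx.FitProblem(
    curve=curve,
    model="bicelle",
    params={**asdict(truth), **init},
    free={"r_core": (20, 60), "h_head": (2, 11.4), "scale": (3e6, 3e8)},
    sigma_fallback=0.01,  # synthetic curve carries no uncertainties
)
result = bx.fit(problem, seed=0)

p = result.best_params
print(f"converged: {result.converged}   reduced chi2: {result.chi2_red:.3g}")
print(f"core radius : {p['r_core']:7.2f} A   (generated with {truth.r_core})")
print(f"head layer  : {p['h_head']:7.2f} A   (generated with {truth.h_head})")
print(f"total radius: {p['r_core'] + p['delta_r']:7.2f} A  -> the ~50 A disc radius")
print(f"total height: {p['h_tail'] + 2 * p['h_head']:7.2f} A  -> the ~45 A disc height")
print(
    "\nThe total radius counts the detergent belt (11.4 A) and the total "
    "height both polar-head layers on the 28.8 A hydrophobic core."
)
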