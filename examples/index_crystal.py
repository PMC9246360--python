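"""Index a powder peak list on a monoclinic cell and refine it.

Generates Bragg positions from the refined bacteriorhodopsin crystal
cell (a=43.91, b=109.33, c=53.4 A, beta=104.63 deg), perturbs the cell
by 5%, and lets assignment + least-squares refinement recover it.  An
extra 64 A peak that no lattice position explains is flagged as a
candidate crystal-bound lamellar (L_cryst) reflection.
"""

import numpy as np

import bicellix as bx

cell = bx.MonoclinicCell(a=43.91, b=109.33, c=53.4, beta=104.63)
hkls = [
    (0, 1, 0), (0, 2, 0), (0, 0, 1), (1, 0, 0), (0, 1, 1),
    (1, 1, 0), (1, 0, -1), (1, 2, 0), (1, 0, 1), (0, 4, 0),
]
peaks = [bx.q_theor(cell, h) for h in hkls] + [2 * np.pi / 64.0]

start = bx.MonoclinicCell(cell.a * 1.05, cell.b * 0.95, cell.c * 1.04, cell.beta * 0.96)
print(f"start cell : a={start.a:.2f} b={start.b:.2f} c={start.c:.2f} beta={start.beta:.2f}")

sol = bx.refine_cell(peaks, start, index_bound=5)
c = sol.cell
print(f"refined    : a={c.a:.2f} b={c.b:.2f} c={c.c:.2f} beta={c.beta:.2f}")
print(f"objective  : {sol.objective:.3g} (sum of squared relative discrepancies)")
print("assignments:")
for a in sol.assignments:
    print(f"  q={a.q_exp:.5f} -> {a.hkl.as_tuple()}  (residual {a.rel_residual:+.2e})")
for extra in bx.flag_extra_peaks(sol, (60.0, 70.0)):
    print(
        f"unindexed peak at q={extra['q']:.5f} (d={extra['d_spacing']:.1f} A): "
        "candidate crystal-bound lamellar reflection"
    )
print(
    "\nThe 64 A spacing falls in the gap between lattice positions: it "
    "belongs to a lipid phase attached to the crystal, not to the crystal "
    "lattice itself."
)
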