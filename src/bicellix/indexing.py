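"""Monoclinic powder indexing and unit-cell refinement from 1D peak lists.

For a monoclinic cell (edges a, b, c; unique axis b; angle beta between a
and c) the Bragg positions are

    q(hkl) = (2*pi/sin(beta)) * sqrt((h/a)^2 + (k*sin(beta)/b)^2
                                     + (l/c)^2 - 2*h*l*cos(beta)/(a*c))

Indexing alternates two steps until the index assignment is a fixed
point: assign each observed peak to the enumerated reflection nearest in
q, then refine (a, b, c, beta) by bounded least squares on the relative
discrepancies sum_i ((q_exp_i - q_theor_i)/q_theor_i)^2.  A 1D powder
pattern only sees |q|, so reflections degenerate in q are collapsed and
peaks that no reflection explains are reported as unindexed — those with
spacings in a lamellar window are candidate crystal-bound lamellar
(L_cryst) reflections rather than lattice peaks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .curves import ValidationError

__all__ = [
    "MonoclinicCell",
    "MillerIndex",
    "PeakAssignment",
    "IndexingSolution",
    "q_theor",
    "enumerate_reflections",
    "assign_indices",
    "refine_cell",
    "flag_extra_peaks",
]


@dataclass(frozen=True)
class MonoclinicCell:
    """Monoclinic unit cell: edges a, b, c [A] and angle beta [degrees]."""

    a: float
    b: float
    c: float
    beta: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValidationError("cell edges must be > 0")
        if not (0.0 < self.beta < 180.0) or np.sin(np.radians(self.beta)) <= 1e-6:
            raise ValidationError("beta must be in (0, 180) with sin(beta) > 1e-6")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.beta)


@dataclass(frozen=True)
class MillerIndex:
    h: int
    k: int
    l: int

    def __post_init__(self) -> None:
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise ValidationError("(0,0,0) is not a reflection")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)


@dataclass(frozen=True)
class PeakAssignment:
    """One observed peak matched to a reflection of the current cell."""

    q_exp: float
    hkl: MillerIndex
    q_theor: float

    @property
    def rel_residual(self) -> float:
        return (self.q_exp - self.q_theor) / self.q_theor


@dataclass(frozen=True)
class IndexingSolution:
    """Refined cell plus the peak-to-reflection mapping that produced it."""

    cell: MonoclinicCell
    assignments: tuple[PeakAssignment, ...]
    unindexed: tuple[float, ...]
    converged: bool
    n_rounds: int

    @property
    def objective(self) -> float:
        """Sum of squared relative discrepancies over assigned peaks."""
        return float(sum(a.rel_residual**2 for a in self.assignments))


def q_theor(cell: MonoclinicCell, hkl: MillerIndex | tuple[int, int, int]) -> float:
    """Bragg position q(hkl) [1/A] of a monoclinic cell."""
    if not isinstance(hkl, MillerIndex):
        hkl = MillerIndex(*hkl)
    beta = np.radians(cell.beta)
    sb, cb = np.sin(beta), np.cos(beta)
    rad = (
        (hkl.h / cell.a) ** 2
        + (hkl.k * sb / cell.b) ** 2
        + (hkl.l / cell.c) ** 2
        - 2.0 * hkl.h * hkl.l * cb / (cell.a * cell.c)
    )
    if rad <= 0:
        raise ValidationError(
            f"non-positive radicand for hkl={hkl.as_tuple()} on cell {cell}"
        )
    return float(2.0 * np.pi / sb * np.sqrt(rad))


def enumerate_reflections(
    cell: MonoclinicCell,
    q_limit: float,
    index_bound: int = 5,
    p21_absences: bool = False,
) -> list[tuple[MillerIndex, float]]:
    """All distinct reflection positions up to q_limit, sorted by q.

    h runs over both signs (q(h,k,l) != q(-h,k,l) in general for a
    monoclinic cell), while k and l are kept non-negative: a 1D pattern
    only measures |q| and q(h,k,l) == q(-h,k,-l) exactly.  Reflections
    degenerate in q within 1e-9 are collapsed keeping the index smallest
    by |h|+k+l then lexicographic order, so multiplicity never enters the
    1D assignment.  With ``p21_absences`` the 0k0 (k odd) reflections of
    the two-fold screw axis are removed.
    """
    if q_limit <= 0:
        raise ValidationError("q_limit must be > 0")
    if index_bound < 1:
        raise ValidationError("index_bound must be >= 1")
    entries: list[tuple[MillerIndex, float]] = []
    for h, k, l in itertools.product(
        range(-index_bound, index_bound + 1),
        range(0, index_bound + 1),
        range(0, index_bound + 1),
    ):
        if (h, k, l) == (0, 0, 0):
            continue
        if p21_absences and h == 0 and l == 0 and k % 2 == 1:
            continue
        hkl = MillerIndex(h, k, l)
        try:
            q = q_theor(cell, hkl)
        except ValidationError:
            continue
        if q <= q_limit:
            entries.append((hkl, q))
    entries.sort(
        key=lambda e: (
            e[1],
            abs(e[0].h) + e[0].k + e[0].l,
            e[0].as_tuple(),
        )
    )
    collapsed: list[tuple[MillerIndex, float]] = []
    for hkl, q in entries:
        if collapsed and abs(q - collapsed[-1][1]) <= 1e-9:
            continue
        collapsed.append((hkl, q))
    return collapsed


def assign_indices(
    peak_positions,
    cell: MonoclinicCell,
    index_bound: int = 5,
    p21_absences: bool = False,
    q_limit: float | None = None,
) -> list[PeakAssignment]:
    """Match each observed peak to the reflection nearest in q.

    Ties in |q_exp - q_theor| are broken by smallest |h|+k+l, then
    lexicographic (h, k, l).  The enumeration window defaults to 1.05x
    the largest observed q.
    """
    peak_positions = [float(q) for q in peak_positions]
    if not peak_positions:
        raise ValidationError("no peaks to assign")
    if q_limit is None:
        q_limit = 1.05 * max(peak_positions)
    refl = enumerate_reflections(cell, q_limit, index_bound, p21_absences)
    if not refl:
        raise ValidationError(f"no reflections enumerated below q_limit={q_limit}")
    out = []
    for q_exp in peak_positions:
        best = min(
            refl,
            key=lambda e: (
                abs(q_exp - e[1]),
                abs(e[0].h) + e[0].k + e[0].l,
                e[0].as_tuple(),
            ),
        )
        out.append(PeakAssignment(q_exp=q_exp, hkl=best[0], q_theor=best[1]))
    return out


def _refine_once(
    peak_positions: list[float],
    assignments: list[PeakAssignment],
    cell: MonoclinicCell,
) -> MonoclinicCell:
    hkls = [a.hkl for a in assignments]
    x0 = np.array(cell.as_tuple())

    def residuals(x):
        trial = MonoclinicCell(*x)
        out = np.empty(len(hkls))
        for i, (q_exp, hkl) in enumerate(zip(peak_positions, hkls)):
            try:
                qt = q_theor(trial, hkl)
            except ValidationError:
                return np.full(len(hkls), 1e6)
            out[i] = (q_exp - qt) / qt
        return out

    lo = np.array([x0[0] * 0.5, x0[1] * 0.5, x0[2] * 0.5, max(10.0, x0[3] - 40.0)])
    hi = np.array([x0[0] * 2.0, x0[1] * 2.0, x0[2] * 2.0, min(170.0, x0[3] + 40.0)])
    sol = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    return MonoclinicCell(*(float(v) for v in sol.x))


def refine_cell(
    peak_positions,
    initial_cell: MonoclinicCell,
    index_bound: int = 5,
    max_rounds: int = 20,
    p21_absences: bool = False,
    unindexed_threshold: float = 0.02,
    n_starts: int = 48,
    seed: int = 0,
    low_q_warmup: bool = True,
) -> IndexingSolution:
    """Refine a monoclinic cell against observed peak positions.

    Alternates nearest-reflection assignment and bounded least-squares
    minimization of the summed squared relative discrepancies over
    (a, b, c, beta), until the assignment is a fixed point or
    ``max_rounds`` is hit.  Because the assignment step makes the
    objective piecewise (a wrong nearest-reflection map is its own fixed
    point), the alternation is restarted from ``n_starts`` deterministic
    jitters of the initial cell and the solution explaining the most
    peaks at the lowest objective wins.  Peaks whose final relative
    residual exceeds ``unindexed_threshold`` are excluded from the
    refined objective and reported as unindexed (candidate non-lattice
    reflections).
    """
    peak_positions = [float(q) for q in peak_positions]
    if len(peak_positions) < 4:
        raise ValidationError("need >= 4 peaks to refine 4 cell parameters")
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    # the monoclinic angle dominates which assignment basin the
    # alternation falls into: after the caller's cell, scan the angle on a
    # deterministic grid, each angle with the initial edges and a few
    # random edge jitters, then full random jitters of all four
    # parameters; n_starts caps how much of this list is tried, and an
    # exact indexing stops the scan early
    starts = [initial_cell]
    for db in (0.0, -0.02, 0.02, -0.04, 0.04, -0.06, 0.06, -0.08, 0.08, -0.10, 0.10):
        beta = float(np.clip(initial_cell.beta * (1.0 + db), 30.0, 150.0))
        starts.append(
            MonoclinicCell(initial_cell.a, initial_cell.b, initial_cell.c, beta)
        )
        for _ in range(3):
            f = 1.0 + rng.uniform(-0.05, 0.05, size=3)
            starts.append(
                MonoclinicCell(
                    initial_cell.a * f[0],
                    initial_cell.b * f[1],
                    initial_cell.c * f[2],
                    beta,
                )
            )
    while len(starts) < n_starts:
        f = 1.0 + rng.uniform(-0.06, 0.06, size=4)
        starts.append(
            MonoclinicCell(
                initial_cell.a * f[0],
                initial_cell.b * f[1],
                initial_cell.c * f[2],
                float(np.clip(initial_cell.beta * f[3], 30.0, 150.0)),
            )
        )
    best: IndexingSolution | None = None
    for start in starts[:n_starts]:
        sol = _refine_from(
            peak_positions, start, index_bound, max_rounds,
            p21_absences, unindexed_threshold, low_q_warmup,
        )
        key = (len(sol.unindexed), sol.objective)
        if best is None or key < (len(best.unindexed), best.objective):
            best = sol
        if not best.unindexed and best.objective < 1e-16:
            break  # an exact indexing cannot be improved
    assert best is not None
    return best


def _refine_from(
    peak_positions: list[float],
    initial_cell: MonoclinicCell,
    index_bound: int,
    max_rounds: int,
    p21_absences: bool,
    unindexed_threshold: float,
    low_q_warmup: bool = True,
) -> IndexingSolution:
    cell = initial_cell
    prev_hkls: tuple | None = None
    converged = False
    n_rounds = 0
    # warm-up on the low-q half of the pattern: reflections are sparse
    # there, so nearest-q assignment from an inaccurate cell is far more
    # reliable, and the resulting cell anchors the full assignment
    low_half = sorted(peak_positions)[: max(4, len(peak_positions) // 2)]
    if low_q_warmup and 4 <= len(low_half) < len(peak_positions):
        for _ in range(3):
            warm = assign_indices(low_half, cell, index_bound, p21_absences)
            kept_w = [
                (q, a)
                for q, a in zip(low_half, warm)
                if abs(a.rel_residual) <= 0.10
            ]
            if len(kept_w) < 4:
                kept_w = list(zip(low_half, warm))
            cell = _refine_once(
                [q for q, _ in kept_w], [a for _, a in kept_w], cell
            )
    assignments = assign_indices(peak_positions, cell, index_bound, p21_absences)
    for n_rounds in range(1, max_rounds + 1):
        # drop clear outliers from the refinement, keep >= 4 peaks
        kept = [
            (q, a)
            for q, a in zip(peak_positions, assignments)
            if abs(a.rel_residual) <= max(unindexed_threshold, 0.10)
        ]
        if len(kept) < 4:
            kept = list(zip(peak_positions, assignments))
        cell = _refine_once([q for q, _ in kept], [a for _, a in kept], cell)
        assignments = assign_indices(peak_positions, cell, index_bound, p21_absences)
        hkls = tuple(a.hkl.as_tuple() for a in assignments)
        if hkls == prev_hkls:
            converged = True
            break
        prev_hkls = hkls
    final_assign = tuple(
        a for a in assignments if abs(a.rel_residual) <= unindexed_threshold
    )
    unindexed = tuple(
        a.q_exp for a in assignments if abs(a.rel_residual) > unindexed_threshold
    )
    return IndexingSolution(
        cell=cell,
        assignments=final_assign,
        unindexed=unindexed,
        converged=converged,
        n_rounds=n_rounds,
    )


def flag_extra_peaks(
    solution: IndexingSolution,
    spacing_window: tuple[float, float] = (60.0, 70.0),
) -> list[dict]:
    """Unindexed peaks whose spacing d = 2*pi/q falls in a lamellar window.

    These are candidate crystal-bound lamellar (L_cryst) reflections:
    positions the refined lattice cannot explain but that sit at bilayer
    repeat distances.
    """
    d_lo, d_hi = spacing_window
    out = []
    for q in solution.unindexed:
        d = 2.0 * np.pi / q
        if d_lo <= d <= d_hi:
            out.append({"q": q, "d_spacing": d})
    return out
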