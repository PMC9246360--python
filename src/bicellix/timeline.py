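"""Stage classification of crystallization-matrix SAS curves.

A drying bicelle crystallization matrix passes through a reproducible
sequence of states: a fluid mixture of bicelles and purple-membrane
sheets, a concentrated bicelle phase, ribbons, ribbons with a lamellar
phase, a transient long-period ordered phase (repeat distances of several
hundred Angstrom), and finally protein crystals accompanied by a
crystal-bound lamellar phase.  Each state has a scattering signature, and
:func:`classify_stage` applies them as a rule cascade:

1. wide-angle peaks indexable on a monoclinic cell -> CRYSTAL;
2. peaks at spacings d in [450, 750] A -> TRANSIENT_ORDERED;
3. a 1:2 lamellar series with d in [60, 90] A and a ribbon-model best
   fit -> RIBBON_LAMELLAR;
4. ribbon model beating the bicelle model by a chi-square factor ->
   RIBBON;
5. low-q log-log slope at or below the sheet-scattering threshold ->
   BICELLE_PM; otherwise BICELLE_CONCENTRATED.

:func:`track_series` classifies a time series and audits that stages only
move forward in time (the transient phase is allowed to come and go).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .curves import CurveSeries, SASCurve, ValidationError
from . import fitting as _fit
from . import indexing as _idx
from . import models as _m
from . import peaks as _pk

__all__ = ["StageLabel", "StageReport", "ClassifierConfig", "classify_stage", "track_series"]


class StageLabel(enum.IntEnum):
    """Matrix stages in their order of appearance during drying."""

    BICELLE_PM = 0
    BICELLE_CONCENTRATED = 1
    RIBBON = 2
    RIBBON_LAMELLAR = 3
    TRANSIENT_ORDERED = 4
    CRYSTAL = 5


@dataclass(frozen=True)
class StageReport:
    """Classification outcome plus the evidence that produced it."""

    label: StageLabel
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and fit settings of the stage classifier.

    ``candidate_cell`` is the monoclinic cell hypothesis used for
    indexing wide-angle peaks (ab initio indexing is out of scope);
    ``chi2_factor`` is how many times lower the ribbon chi-square must be
    to prefer ribbons over bicelles.
    """

    slope_window: tuple[float, float] = (0.006, 0.04)
    slope_threshold: float = -1.5
    fit_window: tuple[float, float] = (0.035, 0.6)
    chi2_factor: float = 2.0
    transient_d_window: tuple[float, float] = (450.0, 750.0)
    lamellar_d_window: tuple[float, float] = (60.0, 90.0)
    lcryst_d_window: tuple[float, float] = (60.0, 70.0)
    indexing_q_min: float = 0.05
    candidate_cell: _idx.MonoclinicCell = field(
        default_factory=lambda: _idx.MonoclinicCell(43.91, 109.33, 53.4, 104.63)
    )
    index_bound: int = 5
    unindexed_threshold: float = 0.02
    # more assigned peaks than the 4 refined cell parameters, so a handful
    # of spurious peaks cannot be "indexed" with zero degrees of freedom
    min_crystal_peaks: int = 5
    # the refined cell must stay near the candidate hypothesis
    cell_tolerance: float = 0.10
    # the candidate cell is trusted, so one alternation start suffices
    refine_starts: int = 1
    min_prominence: float = 0.03
    # a real Bragg/pseudo-Bragg peak must rise above the smooth background
    # by a finite fraction; baseline-estimation artifacts and noise humps
    # stay far below this
    min_rel_amplitude: float = 0.3
    # Bragg peaks are resolution-limited: anything broader than this
    # fraction of its own position is a background hump, not a reflection
    max_rel_fwhm: float = 0.16
    baseline_half_width: int = 12
    baseline_n_iter: int = 1
    # reduced quadrature + iteration budget: classification needs model
    # discrimination, not publication-grade parameter values
    n_alpha: int = 32
    n_psi: int = 32
    max_nfev: int = 200


def _fast_bicelle_fn(cfg: ClassifierConfig):
    """Bicelle + free q^-2 sheet term, at classification quadrature order."""

    def fn(q, params):
        p = {k: v for k, v in params.items() if k != "pm_amp"}
        return (
            _m.bicelle_intensity(q, _m.BicelleParams(**p), n_alpha=cfg.n_alpha)
            + params["pm_amp"] * q**-2.0
        )

    return fn


def _fast_ribbon_fn(cfg: ClassifierConfig):
    def fn(q, params):
        p = {k: v for k, v in params.items() if k != "pm_amp"}
        return (
            _m.ribbon_intensity(
                q, _m.RibbonParams(**p), n_alpha=cfg.n_alpha, n_psi=cfg.n_psi
            )
            + params["pm_amp"] * q**-2.0
        )

    return fn


def _mask_peaks(curve: SASCurve, peak_set, window) -> SASCurve:
    """Restrict to the fit window and drop points under extracted peaks."""
    c = curve.window(*window)
    keep = np.ones(len(c), dtype=bool)
    for p in peak_set:
        keep &= np.abs(c.q - p.q_max) > 3.5 * p.sigma_q
    if keep.sum() < 20:  # peaks cover too much; fit through them instead
        keep[:] = True
    return SASCurve(
        c.q[keep],
        c.intensity[keep],
        None if c.sigma is None else c.sigma[keep],
        label=c.label,
    )


def _auto_scaled(curve: SASCurve, fn, params: dict, window) -> dict:
    """Set the scale parameter so the model meets the data magnitude."""
    c = curve.window(*window)
    model = fn(c.q, {**params, "scale": 1.0, "background": 0.0})
    pos = model > 0
    if not np.any(pos):
        return params
    ratio = np.median(curve.window(*window).intensity[pos] / model[pos])
    return {**params, "scale": float(max(ratio, 1e-300))}


def _model_comparison(
    curve: SASCurve, peak_set, cfg: ClassifierConfig
) -> tuple[float, float]:
    """Reduced chi2 of bicelle-vs-ribbon fits on peak-masked data.

    Bragg/pseudo-Bragg peaks are excluded so only the particle form
    factor is compared; both candidates carry a free q^-2 amplitude for
    residual membrane-sheet scattering so sheet background cannot decide
    the comparison.
    """
    masked = _mask_peaks(curve, peak_set, cfg.fit_window)
    bic_fn = _fast_bicelle_fn(cfg)
    rib_fn = _fast_ribbon_fn(cfg)
    bkg0 = float(np.median(masked.intensity[-10:]))
    window = masked.q_range
    pm0 = float(masked.intensity[0] * masked.q[0] ** 2)
    bic_p = {
        "r_core": 40.0,
        "h_tail": 28.8,
        "h_head": 8.0,
        "delta_r": 11.4,
        "rho_core": 6.65e-6,
        "rho_face": 1.44e-5,
        "rho_rim": 1.16e-5,
        "rho_solvent": 9.42e-6,
        "scale": 1.0,
        "background": max(bkg0, 1e-6),
        "epsilon": 1.0,
        "pm_amp": 0.0,
    }
    rib_p = {
        "r_minor": 22.0,
        "r_major": 45.0,
        "length": 300.0,
        "t_shell": 11.4,
        "rho_core": 6.65e-6,
        "rho_shell": 1.30e-5,
        "rho_solvent": 9.42e-6,
        "scale": 1.0,
        "background": max(bkg0, 1e-6),
        "pm_amp": 0.0,
    }
    bic_p = _auto_scaled(masked, bic_fn, bic_p, window)
    rib_p = _auto_scaled(masked, rib_fn, rib_p, window)
    sb, sr = bic_p["scale"], rib_p["scale"]
    common = dict(q_window=None, sigma_fallback=0.01)
    bic_problem = _fit.FitProblem(
        curve=masked,
        model=bic_fn,
        params=bic_p,
        free={
            "r_core": (15.0, 90.0),
            "h_head": (2.0, 11.4),
            "scale": (sb * 1e-3, sb * 1e3),
            "background": (0.0, max(10.0 * bkg0, 1.0)),
            "pm_amp": (0.0, max(10.0 * pm0, 1e-6)),
        },
        name="bicelle",
        **common,
    )
    rib_problem = _fit.FitProblem(
        curve=masked,
        model=rib_fn,
        params=rib_p,
        free={
            "r_minor": (10.0, 35.0),
            "r_major": (30.0, 80.0),
            "length": (100.0, 800.0),
            "scale": (sr * 1e-3, sr * 1e3),
            "background": (0.0, max(10.0 * bkg0, 1.0)),
            "pm_amp": (0.0, max(10.0 * pm0, 1e-6)),
        },
        name="ribbon",
        **common,
    )
    chi_b = _fit.fit(bic_problem, max_nfev=cfg.max_nfev).chi2_red
    chi_r = _fit.fit(rib_problem, max_nfev=cfg.max_nfev).chi2_red
    return chi_b, chi_r


def classify_stage(
    curve: SASCurve, config: ClassifierConfig | None = None
) -> StageReport:
    """Classify one curve into a matrix stage with supporting evidence.

    The curve must cover at least 0.01-0.3 1/A.  Evidence keys: low-q
    slope, per-model chi2, lamellar spacing, transient spacings, crystal
    peak count and the crystal-bound-lamellar (L_cryst) flag; every value
    is recomputable from the curve with the referenced operations.
    """
    cfg = config or ClassifierConfig()
    q_lo, q_hi = curve.q_range
    if q_lo > 0.01 or q_hi < 0.3:
        raise ValidationError("curve must span at least 0.01-0.3 1/A")

    evidence: dict = {}
    baseline = _pk.estimate_baseline(
        curve, half_width=cfg.baseline_half_width, n_iter=cfg.baseline_n_iter
    )
    residual = _pk.subtract_baseline(curve, baseline, clip_negative=True)
    raw_peaks = _pk.extract_peaks(residual, min_prominence=cfg.min_prominence)
    base_at = np.interp(
        raw_peaks.positions, baseline.q, baseline.intensity
    ) if len(raw_peaks) else np.empty(0)
    peak_set = _pk.PeakSet(
        tuple(
            p
            for p, b in zip(raw_peaks, base_at)
            if p.amplitude >= cfg.min_rel_amplitude * b
            and p.fwhm <= cfg.max_rel_fwhm * p.q_max
        ),
        source_label=raw_peaks.source_label,
    )
    series = _pk.find_lamellar_series(peak_set)
    slope, slope_err = _pk.low_q_slope(curve, cfg.slope_window)
    evidence["low_q_slope"] = slope
    evidence["low_q_slope_err"] = slope_err
    evidence["n_peaks"] = len(peak_set)

    # transient long-period phase: spacings of several hundred Angstrom
    d_lo, d_hi = cfg.transient_d_window
    transient = [p.d_spacing for p in peak_set if d_lo <= p.d_spacing <= d_hi]
    evidence["transient_d"] = transient
    if len(transient) >= 2:
        evidence["transient_ratio"] = max(transient) / min(transient)

    # lamellar series in the bilayer-repeat window; a genuine stack shows
    # its second order, so a fundamental paired only with higher multiples
    # (e.g. an accidental n=3 coincidence) does not qualify
    lam = [
        s
        for s in series
        if 2 in {n for n, _ in s.orders}
        and cfg.lamellar_d_window[0] <= s.d <= cfg.lamellar_d_window[1]
    ]
    if lam:
        evidence["lamellar_d"] = lam[0].d
        evidence["lamellar_max_order"] = lam[0].max_order

    # wide-angle peaks not explained by the lamellar series -> indexing
    lam_qs = {q for s in lam for _, q in s.orders}
    wide = [
        p.q_max
        for p in peak_set
        if p.q_max >= cfg.indexing_q_min and p.q_max not in lam_qs
    ]
    crystal = False
    if len(wide) >= cfg.min_crystal_peaks:
        try:
            # warm-up anchoring is disabled: the low-q region of a matrix
            # curve carries lamellar and crystal-bound-lamellar peaks that
            # are not lattice reflections, and the candidate cell is
            # trusted anyway
            sol = _idx.refine_cell(
                wide,
                cfg.candidate_cell,
                index_bound=cfg.index_bound,
                unindexed_threshold=cfg.unindexed_threshold,
                n_starts=cfg.refine_starts,
                low_q_warmup=False,
            )
        except ValidationError:
            sol = None
        near_candidate = sol is not None and all(
            abs(got / ref - 1.0) <= cfg.cell_tolerance
            for got, ref in zip(
                sol.cell.as_tuple(), cfg.candidate_cell.as_tuple()
            )
        )
        if (
            sol is not None
            and len(sol.assignments) >= cfg.min_crystal_peaks
            and near_candidate
        ):
            crystal = True
            evidence["n_crystal_assigned"] = len(sol.assignments)
            evidence["cell"] = sol.cell.as_tuple()
            extras = _idx.flag_extra_peaks(sol, cfg.lcryst_d_window)
            evidence["lcryst"] = [e["d_spacing"] for e in extras]
    if crystal:
        return StageReport(StageLabel.CRYSTAL, evidence)
    if transient:
        return StageReport(StageLabel.TRANSIENT_ORDERED, evidence)

    chi_b, chi_r = _model_comparison(curve, peak_set, cfg)
    evidence["chi2_bicelle"] = chi_b
    evidence["chi2_ribbon"] = chi_r
    ribbon_wins = chi_r * cfg.chi2_factor <= chi_b
    if lam and ribbon_wins:
        return StageReport(StageLabel.RIBBON_LAMELLAR, evidence)
    if ribbon_wins:
        return StageReport(StageLabel.RIBBON, evidence)
    if slope <= cfg.slope_threshold:
        return StageReport(StageLabel.BICELLE_PM, evidence)
    return StageReport(StageLabel.BICELLE_CONCENTRATED, evidence)


def track_series(
    series: CurveSeries, config: ClassifierConfig | None = None
) -> tuple[list[StageReport], list[str]]:
    """Classify every curve of a time series and audit stage ordering.

    Stages must be non-decreasing along time; the transient ordered phase
    is exempt (it appears and disappears).  Violations are reported as
    human-readable flags, never corrected.
    """
    if len(series) == 0:
        raise ValidationError("series is empty")
    reports = [classify_stage(c, config) for c in series.curves]
    flags: list[str] = []
    last: tuple[int, StageLabel] | None = None
    for i, rep in enumerate(reports):
        if rep.label is StageLabel.TRANSIENT_ORDERED:
            continue
        if last is not None and rep.label < last[1]:
            flags.append(
                f"stage order violation at index {i}: "
                f"{last[1].name} (index {last[0]}) -> {rep.label.name}"
            )
        last = (i, rep.label)
    return reports, flags
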