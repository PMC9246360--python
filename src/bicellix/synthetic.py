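"""Seeded synthetic SAS curves emulating a bicelle crystallization matrix.

No public deposition of the original curves exists, so every pipeline
stage is exercised on synthetic data with the same statistical structure:

* purple-membrane sheets as a q^-2 power law at low q;
* bicelles (total radius 50 A, total height 45 A) and ribbons
  (length 330 A, hydrophobic-core semi-axes 20/43 A) via the core-shell
  form factors;
* lamellar orders at q_n = 2*pi*n/d with d = 73 A and a 1:2 position
  ratio;
* a transient long-period pair at d = 660 and 350 A (position ratio
  1:1.89, deliberately not a 1:2 series);
* monoclinic crystal reflections of the a=43.91, b=109.33, c=53.4 A,
  beta=104.63 deg cell plus a crystal-bound lamellar peak at d = 64 A
  (precursor 68 A);
* Gaussian counting-like noise with recorded per-point sigma.

Generation is bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curves import CurveSeries, SASCurve, ValidationError
from .indexing import MonoclinicCell, q_theor
from .models import (
    BicelleParams,
    RibbonParams,
    bicelle_intensity,
    gaussian_peak_profile,
    powerlaw_intensity,
    ribbon_intensity,
)
from .timeline import StageLabel

__all__ = [
    "SyntheticScenario",
    "NoiseModel",
    "DEFAULT_SCHEDULE",
    "simulate_stage",
    "simulate_timeline",
    "add_noise",
]

TWO_PI = 2.0 * np.pi

#: Observation schedule (days) with the stage visible at each timepoint.
DEFAULT_SCHEDULE: tuple[tuple[float, StageLabel], ...] = (
    (0.0, StageLabel.BICELLE_PM),
    (4.0, StageLabel.BICELLE_CONCENTRATED),
    (8.0, StageLabel.RIBBON),
    (17.0, StageLabel.RIBBON_LAMELLAR),
    (24.0, StageLabel.TRANSIENT_ORDERED),
    (65.0, StageLabel.CRYSTAL),
)


def _default_q_grid() -> np.ndarray:
    return np.geomspace(0.006, 0.8, 150)


def _default_bicelle() -> BicelleParams:
    # total radius 50 = 38.6 + 11.4, total height 45 = 28.8 + 2 * 8.1
    return BicelleParams(r_core=38.6, h_head=8.1, scale=3.0e7)


def _default_ribbon() -> RibbonParams:
    return RibbonParams(r_minor=20.0, r_major=43.0, length=330.0, scale=3.0e7)


def _default_cell() -> MonoclinicCell:
    return MonoclinicCell(43.91, 109.33, 53.4, 104.63)


#: Low-order reflections used for the synthetic crystal stage, chosen
#: pairwise separated by >= 0.02 1/A (and clear of the lamellar orders
#: and the crystal-bound lamellar peak) so a 150-point instrument grid
#: resolves every reflection as its own maximum.
DEFAULT_CRYSTAL_HKLS: tuple[tuple[int, int, int], ...] = (
    (0, 2, 0),
    (1, 0, 0),
    (1, 0, 1),
    (1, 2, 1),
    (1, 4, 0),
    (2, 0, 0),
    (2, 2, 0),
)


@dataclass(frozen=True)
class NoiseModel:
    """Counting-statistics surrogate: Gaussian noise with recorded sigma.

    ``gaussian_sqrt``: sigma_i = max(floor, level * sqrt(I_i));
    ``gaussian_relative``: sigma_i = max(floor, level * I_i).
    """

    kind: str = "gaussian_relative"
    level: float = 0.02
    sigma_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_sqrt", "gaussian_relative"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise ValidationError("level must be >= 0")
        if self.sigma_floor <= 0:
            raise ValidationError("sigma_floor must be > 0")


@dataclass(frozen=True)
class SyntheticScenario:
    """Stage templates and instrument window of the synthetic study.

    The defaults encode the observed study conditions: combined
    instrument range 0.006-0.8 1/A, lipid:detergent molar ratio
    Q = 2.69, 5.6 % total amphiphile, and the printed structural
    parameters of every stage component.  Amplitude choices (power-law
    amplitude, peak amplitudes, q^-2 crystal envelope) are documented
    package fixtures.
    """

    q_grid: np.ndarray = field(default_factory=_default_q_grid)
    q_ratio: float = 2.69
    c_lp_percent: float = 5.6
    background: float = 0.05
    # purple membranes: extended sheets -> q^-2 power law
    pm_amplitude: float = 1.0e-2
    pm_exponent: float = -2.0
    bicelle: BicelleParams = field(default_factory=_default_bicelle)
    concentration_factor: float = 2.0
    ribbon: RibbonParams = field(default_factory=_default_ribbon)
    lamellar_d: float = 73.0
    lamellar_amplitudes: tuple[float, ...] = (3.0, 0.9)
    lamellar_fwhm: tuple[float, ...] = (0.008, 0.014)
    transient_d: tuple[float, float] = (660.0, 350.0)
    transient_amplitudes: tuple[float, float] = (30.0, 12.0)
    transient_fwhm: tuple[float, float] = (0.0012, 0.0022)
    cell: MonoclinicCell = field(default_factory=_default_cell)
    crystal_hkls: tuple[tuple[int, int, int], ...] = DEFAULT_CRYSTAL_HKLS
    crystal_amplitude: float = 3.0
    crystal_q_ref: float = 0.115
    crystal_fwhm: float = 0.012
    lcryst_d: float = 64.0
    lcryst_precursor_d: float = 68.0
    lcryst_amplitude: float = 2.0
    lcryst_fwhm: float = 0.007

    def __post_init__(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        object.__setattr__(self, "q_grid", q)
        if q.ndim != 1 or len(q) < 2 or np.any(np.diff(q) <= 0) or q[0] <= 0:
            raise ValidationError("q_grid must be strictly increasing and > 0")


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _lamellar_component(scenario: SyntheticScenario, q: np.ndarray) -> np.ndarray:
    out = np.zeros_like(q)
    for n, (amp, fwhm) in enumerate(
        zip(scenario.lamellar_amplitudes, scenario.lamellar_fwhm), start=1
    ):
        center = TWO_PI * n / scenario.lamellar_d
        out += gaussian_peak_profile(q, center, _fwhm_to_sigma(fwhm), amp)
    return out


def _transient_component(scenario: SyntheticScenario, q: np.ndarray) -> np.ndarray:
    out = np.zeros_like(q)
    for d, amp, fwhm in zip(
        scenario.transient_d, scenario.transient_amplitudes, scenario.transient_fwhm
    ):
        out += gaussian_peak_profile(q, TWO_PI / d, _fwhm_to_sigma(fwhm), amp)
    return out


def _crystal_component(scenario: SyntheticScenario, q: np.ndarray) -> np.ndarray:
    out = np.zeros_like(q)
    sigma = _fwhm_to_sigma(scenario.crystal_fwhm)
    for hkl in scenario.crystal_hkls:
        center = q_theor(scenario.cell, hkl)
        amp = scenario.crystal_amplitude * (center / scenario.crystal_q_ref) ** -2
        out += gaussian_peak_profile(q, center, sigma, amp)
    out += gaussian_peak_profile(
        q,
        TWO_PI / scenario.lcryst_d,
        _fwhm_to_sigma(scenario.lcryst_fwhm),
        scenario.lcryst_amplitude,
    )
    return out


def clean_stage_intensity(
    scenario: SyntheticScenario, stage: StageLabel
) -> np.ndarray:
    """Noise-free composite intensity of one stage on the scenario grid."""
    q = scenario.q_grid
    total = np.full_like(q, scenario.background)
    if stage is StageLabel.BICELLE_PM:
        total += powerlaw_intensity(q, scenario.pm_amplitude, scenario.pm_exponent)
        total += bicelle_intensity(q, scenario.bicelle)
    elif stage is StageLabel.BICELLE_CONCENTRATED:
        conc = replace(
            scenario.bicelle,
            scale=scenario.bicelle.scale * scenario.concentration_factor,
        )
        total += bicelle_intensity(q, conc)
    elif stage is StageLabel.RIBBON:
        total += ribbon_intensity(q, scenario.ribbon)
    elif stage is StageLabel.RIBBON_LAMELLAR:
        total += ribbon_intensity(q, scenario.ribbon)
        total += _lamellar_component(scenario, q)
    elif stage is StageLabel.TRANSIENT_ORDERED:
        total += ribbon_intensity(q, scenario.ribbon)
        total += _lamellar_component(scenario, q)
        total += _transient_component(scenario, q)
    elif stage is StageLabel.CRYSTAL:
        total += ribbon_intensity(q, scenario.ribbon)
        total += _lamellar_component(scenario, q)
        total += _crystal_component(scenario, q)
    else:
        raise ValidationError(f"unknown stage {stage!r}")
    return total


def add_noise(curve: SASCurve, noise: NoiseModel) -> SASCurve:
    """Add seeded Gaussian noise; the applied sigma is stored on the curve."""
    rng = np.random.default_rng(noise.seed)
    if noise.kind == "gaussian_sqrt":
        sigma = noise.level * np.sqrt(np.maximum(curve.intensity, 0.0))
    else:
        sigma = noise.level * np.abs(curve.intensity)
    sigma = np.maximum(noise.sigma_floor, sigma)
    intensity = curve.intensity + rng.normal(0.0, 1.0, len(curve)) * sigma * (
        1.0 if noise.level > 0 else 0.0
    )
    return SASCurve(curve.q, intensity, sigma, label=curve.label)


def simulate_stage(
    scenario: SyntheticScenario,
    stage: StageLabel,
    noise: NoiseModel | None = None,
) -> SASCurve:
    """One synthetic curve of the given stage, with noise and sigma."""
    clean = SASCurve(
        scenario.q_grid,
        clean_stage_intensity(scenario, stage),
        None,
        label=f"synthetic:{StageLabel(stage).name}",
    )
    if noise is None:
        return clean
    return add_noise(clean, noise)


def simulate_timeline(
    scenario: SyntheticScenario,
    stage_schedule=DEFAULT_SCHEDULE,
    noise: NoiseModel | None = None,
) -> CurveSeries:
    """A curve per schedule entry; per-entry noise seeds derive from the
    model seed so the whole series is reproducible."""
    schedule = [(float(t), StageLabel(s)) for t, s in stage_schedule]
    if any(b[0] < a[0] for a, b in zip(schedule, schedule[1:])):
        raise ValidationError("schedule times must be non-decreasing")
    curves = []
    for i, (t, stage) in enumerate(schedule):
        n_i = None
        if noise is not None:
            child = np.random.SeedSequence([noise.seed, i]).generate_state(1)[0]
            n_i = replace(noise, seed=int(child % (2**31)))
        curves.append(simulate_stage(scenario, stage, n_i))
    return CurveSeries(tuple(curves), tuple(t for t, _ in schedule))
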