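"""Weighted least-squares fitting of form-factor models to SAS curves.

The objective is the reduced chi-square

    chi2 = 1/(N_exp - N_param) * sum_i ((I_i - I_model(q_i)) / sigma_i)^2

minimized over the free parameters by bounded trust-region least squares
on the residuals r_i = (I_i - I_model)/sigma_i.  Fits are deterministic
given (problem, seed); a multistart wrapper restarts from Latin-hypercube
points inside the bounds to escape local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .curves import SASCurve, ValidationError
from . import models as _m

__all__ = [
    "FitProblem",
    "FitResult",
    "reduced_chi2",
    "fit",
    "multistart_fit",
    "compare_models",
    "MODEL_FUNCTIONS",
]

ModelFn = Callable[[np.ndarray, Mapping[str, float]], np.ndarray]


def _bicelle_fn(q, params):
    return _m.bicelle_intensity(q, _m.BicelleParams(**params))


def _ribbon_fn(q, params):
    return _m.ribbon_intensity(q, _m.RibbonParams(**params))


def _cylinder_fn(q, params):
    return _m.uniform_cylinder_intensity(q, **params)


def _powerlaw_fn(q, params):
    return _m.powerlaw_intensity(q, **params)


#: Built-in model kinds addressable by name in a FitProblem.
MODEL_FUNCTIONS: dict[str, ModelFn] = {
    "bicelle": _bicelle_fn,
    "ribbon": _ribbon_fn,
    "cylinder": _cylinder_fn,
    "powerlaw": _powerlaw_fn,
}


def make_mixture_fn(kinds: Mapping[str, str]) -> ModelFn:
    """Build a mixture model function from {prefix: component kind}.

    The returned function reads parameters named ``<prefix>.<field>`` for
    each component, weights ``phi_<prefix>``, and a shared ``background``.
    Component backgrounds are suppressed (the shared one applies).
    """
    for kind in kinds.values():
        if kind not in ("bicelle", "ribbon"):
            raise ValidationError(f"unknown mixture component kind {kind!r}")

    def fn(q: np.ndarray, params: Mapping[str, float]) -> np.ndarray:
        out = np.full(len(q), float(params.get("background", 0.0)))
        for prefix, kind in kinds.items():
            sub = {
                k.split(".", 1)[1]: v
                for k, v in params.items()
                if k.startswith(prefix + ".")
            }
            sub["background"] = 0.0
            out = out + params[f"phi_{prefix}"] * MODEL_FUNCTIONS[kind](q, sub)
        return out

    return fn


@dataclass(frozen=True)
class FitProblem:
    """One model-vs-curve fitting task.

    Parameters
    ----------
    curve : SASCurve
        Data; must carry sigma unless ``sigma_fallback`` is enabled.
    model : str or callable
        A key of :data:`MODEL_FUNCTIONS` or a function
        ``fn(q, params) -> intensity``.
    params : mapping
        Full parameter set (fixed values and initial values of free ones).
    free : mapping
        ``name -> (lo, hi)`` finite bounds for each free parameter; the
        initial value is taken from ``params`` and must lie inside.
    q_window : (q_lo, q_hi), optional
        Restrict the fit to this q interval.
    sigma_fallback : float, optional
        Opt-in surrogate uncertainty sigma_i = sigma_fallback * I_i for
        curves without sigma (synthetic noise-free data).
    q4_weight : bool
        Multiply data and model by q^4 in the residuals to emphasize
        wide-angle features.
    """

    curve: SASCurve
    model: str | ModelFn
    params: Mapping[str, float]
    free: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    q_window: tuple[float, float] | None = None
    sigma_fallback: float | None = None
    q4_weight: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(self, "free", dict(self.free))
        for pname, bounds in self.free.items():
            if pname not in self.params:
                raise ValidationError(f"free parameter {pname!r} not in params")
            lo, hi = bounds
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValidationError(f"{pname}: bounds must be finite with lo < hi")
            x0 = self.params[pname]
            if not (lo <= x0 <= hi):
                raise ValidationError(
                    f"{pname}: initial value {x0} outside bounds [{lo}, {hi}]"
                )
        if self._windowed_curve().q.size <= len(self.free):
            raise ValidationError("need more data points than free parameters")

    def _windowed_curve(self) -> SASCurve:
        c = self.curve
        if self.q_window is not None:
            c = c.window(*self.q_window)
        return c

    def _data(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = self._windowed_curve()
        if c.sigma is not None:
            sigma = c.sigma
        elif self.sigma_fallback is not None:
            sigma = np.maximum(1e-300, self.sigma_fallback * np.abs(c.intensity))
        else:
            raise ValidationError(
                "curve has no sigma; enable sigma_fallback to fit it"
            )
        return c.q, c.intensity, sigma

    def intensity_fn(self) -> ModelFn:
        if callable(self.model):
            return self.model
        try:
            return MODEL_FUNCTIONS[self.model]
        except KeyError:
            raise ValidationError(f"unknown model kind {self.model!r}") from None

    def model_name(self) -> str:
        if self.name:
            return self.name
        return self.model if isinstance(self.model, str) else getattr(
            self.model, "__name__", "custom"
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a fit: best parameters and the reduced chi-square."""

    best_params: dict[str, float]
    chi2_red: float
    n_exp: int
    n_param: int
    converged: bool
    n_starts_used: int
    seed: int
    model_name: str = ""

    def __post_init__(self) -> None:
        if self.chi2_red < 0:
            raise ValidationError("chi2_red must be >= 0")


def reduced_chi2(
    curve: SASCurve, model_intensity: np.ndarray, n_param: int
) -> float:
    """Reduced chi-square of a model intensity against a measured curve.

    Requires per-point sigma; N_exp must exceed n_param.
    """
    if curve.sigma is None:
        raise ValidationError("reduced_chi2 requires a curve with sigma")
    model_intensity = np.asarray(model_intensity, dtype=float)
    if model_intensity.shape != curve.q.shape:
        raise ValidationError("model intensity length must match the curve")
    n_exp = len(curve)
    if n_exp <= n_param:
        raise ValidationError("need n_exp > n_param")
    r = (curve.intensity - model_intensity) / curve.sigma
    return float(np.sum(r**2) / (n_exp - n_param))


def _residual_fn(problem: FitProblem):
    q, intens, sigma = problem._data()
    fn = problem.intensity_fn()
    names = list(problem.free)
    base = dict(problem.params)
    weight = q**4 if problem.q4_weight else 1.0

    def residuals(x: np.ndarray) -> np.ndarray:
        p = dict(base)
        p.update(zip(names, x))
        model = fn(q, p)
        return (intens - model) * weight / sigma

    return residuals, names, q, intens, sigma, fn


def fit(problem: FitProblem, seed: int = 0, max_nfev: int = 2000) -> FitResult:
    """Minimize the reduced chi-square over the free parameters.

    Bounded trust-region least squares from the initial point in
    ``problem.params``; tolerances 1e-8 on step, gradient and cost.
    Deterministic for a given problem.  With zero free parameters the
    initial parameters are returned with their chi-square.
    """
    residuals, names, q, intens, sigma, fn = _residual_fn(problem)
    n_exp = len(q)
    if not names:
        r = residuals(np.empty(0))
        return FitResult(
            best_params=dict(problem.params),
            chi2_red=float(np.sum(r**2) / n_exp),
            n_exp=n_exp,
            n_param=0,
            converged=True,
            n_starts_used=1,
            seed=seed,
            model_name=problem.model_name(),
        )
    x0 = np.array([problem.params[n] for n in names], dtype=float)
    lo = np.array([problem.free[n][0] for n in names])
    hi = np.array([problem.free[n][1] for n in names])
    sol = least_squares(
        residuals,
        x0,
        bounds=(lo, hi),
        method="trf",
        xtol=1e-8,
        ftol=1e-8,
        gtol=1e-8,
        max_nfev=max_nfev,
    )
    best = dict(problem.params)
    best.update(zip(names, (float(v) for v in sol.x)))
    chi2 = float(2.0 * sol.cost / (n_exp - len(names)))
    return FitResult(
        best_params=best,
        chi2_red=chi2,
        n_exp=n_exp,
        n_param=len(names),
        converged=bool(sol.status > 0),
        n_starts_used=1,
        seed=seed,
        model_name=problem.model_name(),
    )


def multistart_fit(
    problem: FitProblem, n_starts: int = 8, seed: int = 0, max_nfev: int = 2000
) -> FitResult:
    """Best of ``n_starts`` restarts: the problem's own initial point plus
    Latin-hypercube points inside the bounds (one per restart, seeded from
    ``seed`` so that the start sequence is a prefix-stable stream)."""
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    names = list(problem.free)
    best = fit(problem, seed=seed, max_nfev=max_nfev)
    if not names:
        return best
    lo = np.array([problem.free[n][0] for n in names])
    hi = np.array([problem.free[n][1] for n in names])
    for i in range(1, n_starts):
        sampler = qmc.LatinHypercube(
            d=len(names),
            seed=np.random.default_rng(np.random.SeedSequence([seed, i])),
        )
        x0 = lo + sampler.random(1)[0] * (hi - lo)
        params_i = dict(problem.params)
        params_i.update(zip(names, (float(v) for v in x0)))
        problem_i = FitProblem(
            curve=problem.curve,
            model=problem.model,
            params=params_i,
            free=problem.free,
            q_window=problem.q_window,
            sigma_fallback=problem.sigma_fallback,
            q4_weight=problem.q4_weight,
            name=problem.name,
        )
        res = fit(problem_i, seed=seed, max_nfev=max_nfev)
        if res.chi2_red < best.chi2_red:
            best = res
    return FitResult(**{**asdict(best), "n_starts_used": n_starts, "seed": seed})


def compare_models(
    curve: SASCurve,
    problems: Sequence[FitProblem],
    seed: int = 0,
    n_starts: int = 1,
) -> list[FitResult]:
    """Fit competing models to one curve and rank them by reduced chi2.

    Returns FitResults sorted ascending by chi2_red; ties within 1e-12 are
    broken by fewer free parameters, then input order.  All problems must
    reference the given curve.
    """
    if len(problems) < 2:
        raise ValidationError("compare_models needs >= 2 problems")
    for p in problems:
        if p.curve is not curve and p.curve != curve:
            raise ValidationError("all problems must fit the same curve")
    results = [
        multistart_fit(p, n_starts=n_starts, seed=seed) if n_starts > 1 else fit(p, seed=seed)
        for p in problems
    ]
    order = sorted(
        range(len(results)),
        key=lambda i: (round(results[i].chi2_red / 1e-12), results[i].n_param, i),
    )
    return [results[i] for i in order]
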