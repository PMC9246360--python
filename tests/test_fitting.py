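"""Reduced chi-square fitting: the objective, recovery and model ranking."""

import numpy as np
import pytest

from bicellix import (
    BicelleParams,
    FitProblem,
    RibbonParams,
    SASCurve,
    ValidationError,
    bicelle_intensity,
    compare_models,
    fit,
    multistart_fit,
    reduced_chi2,
    ribbon_intensity,
)
from bicellix.fitting import make_mixture_fn


def _bicelle_curve(q, p, sigma_rel=None):
    i = bicelle_intensity(q, p)
    sigma = None if sigma_rel is None else sigma_rel * i
    return SASCurve(q, i, sigma, label="synthetic-bicelle")


class TestReducedChi2:
    def test_perfect_model_gives_zero(self, simple_curve):
        assert reduced_chi2(simple_curve, simple_curve.intensity, 2) == 0.0

    def test_direct_arithmetic(self):
        c = SASCurve([0.01, 0.02, 0.03], [1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        model = np.array([1.5, 2.5, 3.5])  # each residual/sigma = 1
        assert reduced_chi2(c, model, 1) == pytest.approx(3 / (3 - 1))

    def test_quadratic_in_sigma(self, simple_curve):
        model = simple_curve.intensity * 1.02
        base = reduced_chi2(simple_curve, model, 0)
        doubled = SASCurve(
            simple_curve.q, simple_curve.intensity, 2 * simple_curve.sigma
        )
        assert reduced_chi2(doubled, model, 0) == pytest.approx(base / 4)

    def test_permutation_invariance_of_sum(self, simple_curve):
        """chi2 is a pointwise sum: any reordering of points gives the same
        value (checked by reversing the curve)."""
        model = simple_curve.intensity * 1.05
        fwd = reduced_chi2(simple_curve, model, 1)
        # reversing q order violates monotonicity, so rebuild increasing
        # with the same (I, sigma, model) multiset mapped to fresh q
        c2 = SASCurve(
            simple_curve.q,
            simple_curve.intensity[::-1],
            simple_curve.sigma[::-1],
        )
        rev = reduced_chi2(c2, model[::-1], 1)
        assert rev == pytest.approx(fwd)

    def test_missing_sigma_rejected(self):
        c = SASCurve([0.01, 0.02, 0.03], [1, 2, 3])
        with pytest.raises(ValidationError):
            reduced_chi2(c, np.ones(3), 1)


class TestFit:
    def test_noise_free_recovery_within_tenth_percent(self, q_mid, bicelle_5045):
        """A perturbed start on noise-free data walks back to the truth."""
        curve = _bicelle_curve(q_mid, bicelle_5045)
        rng = np.random.default_rng(1)
        truth = {"r_core": 38.6, "h_head": 8.1, "scale": 3.0e7}
        init = {k: v * (1 + rng.uniform(-0.3, 0.3)) for k, v in truth.items()}
        from dataclasses import asdict

        params = {**asdict(bicelle_5045), **init}
        problem = FitProblem(
            curve=curve,
            model="bicelle",
            params=params,
            free={
                "r_core": (20.0, 60.0),
                "h_head": (2.0, 11.4),
                "scale": (3e6, 3e8),
            },
            sigma_fallback=0.01,
        )
        res = fit(problem, seed=0)
        for k, v in truth.items():
            assert res.best_params[k] == pytest.approx(v, rel=1e-3)

    def test_chi2_near_one_for_matched_noise(self, q_mid, bicelle_5045):
        clean = bicelle_intensity(q_mid, bicelle_5045)
        rng = np.random.default_rng(42)
        sigma = 0.02 * clean
        noisy = SASCurve(q_mid, clean + rng.normal(0, 1, len(q_mid)) * sigma, sigma)
        from dataclasses import asdict

        problem = FitProblem(
            curve=noisy,
            model="bicelle",
            params=asdict(bicelle_5045),
            free={"r_core": (20.0, 60.0), "scale": (3e6, 3e8)},
        )
        res = fit(problem)
        assert 0.5 <= res.chi2_red <= 1.6

    def test_noisy_recovery_within_five_percent_median(self, bicelle_5045):
        """2% multiplicative noise: median recovery error over 20 seeds
        stays below 5% for each free parameter."""
        from dataclasses import asdict

        q = np.geomspace(0.01, 0.5, 120)
        clean = bicelle_intensity(q, bicelle_5045)
        errors = {"r_core": [], "h_head": [], "scale": []}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sigma = 0.02 * clean
            noisy = SASCurve(q, clean + rng.normal(0, 1, len(q)) * sigma, sigma)
            init = {
                k: getattr(bicelle_5045, k) * (1 + rng.uniform(-0.3, 0.3))
                for k in errors
            }
            problem = FitProblem(
                curve=noisy,
                model="bicelle",
                params={**asdict(bicelle_5045), **init},
                free={
                    "r_core": (20.0, 60.0),
                    "h_head": (2.0, 11.4),
                    "scale": (3e6, 3e8),
                },
            )
            res = fit(problem, seed=seed)
            for k in errors:
                truth = getattr(bicelle_5045, k)
                errors[k].append(abs(res.best_params[k] - truth) / truth)
        for k, errs in errors.items():
            assert np.median(errs) < 0.05, k

    def test_zero_free_params_returns_initial(self, q_mid, bicelle_5045):
        from dataclasses import asdict

        curve = _bicelle_curve(q_mid, bicelle_5045, sigma_rel=0.02)
        problem = FitProblem(
            curve=curve, model="bicelle", params=asdict(bicelle_5045), free={}
        )
        res = fit(problem)
        assert res.converged and res.n_param == 0
        assert res.best_params["r_core"] == bicelle_5045.r_core

    def test_deterministic(self, q_mid, bicelle_5045):
        from dataclasses import asdict

        curve = _bicelle_curve(q_mid, bicelle_5045, sigma_rel=0.02)
        params = {**asdict(bicelle_5045), "r_core": 45.0}
        problem = FitProblem(
            curve=curve, model="bicelle", params=params,
            free={"r_core": (20.0, 60.0)},
        )
        a = fit(problem, seed=7)
        b = fit(problem, seed=7)
        assert a == b

    def test_initial_point_never_worsened(self, q_mid, bicelle_5045):
        from dataclasses import asdict

        curve = _bicelle_curve(q_mid, bicelle_5045, sigma_rel=0.02)
        params = {**asdict(bicelle_5045), "r_core": 50.0}
        problem = FitProblem(
            curve=curve, model="bicelle", params=params,
            free={"r_core": (20.0, 60.0)},
        )
        start_chi2 = reduced_chi2(
            curve, bicelle_intensity(curve.q, BicelleParams(**params)), 1
        )
        assert fit(problem).chi2_red <= start_chi2

    def test_bounds_must_contain_initial(self, q_mid, bicelle_5045):
        from dataclasses import asdict

        curve = _bicelle_curve(q_mid, bicelle_5045, sigma_rel=0.02)
        with pytest.raises(ValidationError):
            FitProblem(
                curve=curve, model="bicelle", params=asdict(bicelle_5045),
                free={"r_core": (50.0, 60.0)},  # initial 38.6 outside
            )


class TestMultistart:
    def _toy_problem(self):
        """Bimodal toy: two Gaussian dips in a 1-parameter model, global
        basin far from the initial point."""
        q = np.linspace(0.01, 0.1, 60)

        def model(qv, params):
            x = params["x"]
            return np.full(len(qv), 1.0 + 0.5 * np.exp(-((x - 2.0) ** 2))
                           - 1.0 * np.exp(-((x - 8.0) ** 2) / 0.5))

        data = SASCurve(q, model(q, {"x": 8.0}), np.full(len(q), 0.01))
        return FitProblem(
            curve=data, model=model, params={"x": 2.0}, free={"x": (0.0, 10.0)}
        )

    def test_single_start_equals_plain_fit(self, q_mid, bicelle_5045):
        from dataclasses import asdict

        curve = _bicelle_curve(q_mid, bicelle_5045, sigma_rel=0.02)
        params = {**asdict(bicelle_5045), "r_core": 45.0}
        problem = FitProblem(
            curve=curve, model="bicelle", params=params,
            free={"r_core": (20.0, 60.0)},
        )
        assert multistart_fit(problem, n_starts=1, seed=3).best_params == fit(
            problem, seed=3
        ).best_params

    def test_more_starts_never_worse(self):
        problem = self._toy_problem()
        chi = [
            multistart_fit(problem, n_starts=n, seed=0).chi2_red
            for n in (1, 2, 4, 8)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(chi, chi[1:]))

    def test_eight_starts_find_global_basin(self):
        problem = self._toy_problem()
        res = multistart_fit(problem, n_starts=8, seed=0)
        assert res.best_params["x"] == pytest.approx(8.0, abs=0.2)
        assert res.chi2_red < 1e-10


class TestCompareModels:
    def test_generator_model_wins(self, ribbon_330):
        from dataclasses import asdict

        q = np.geomspace(0.01, 0.5, 100)
        i = ribbon_intensity(q, ribbon_330)
        curve = SASCurve(q, i, 0.02 * i)
        rib = FitProblem(
            curve=curve, model="ribbon", params=asdict(ribbon_330),
            free={"r_minor": (12.0, 30.0), "scale": (3e6, 3e8)},
        )
        bic = FitProblem(
            curve=curve, model="bicelle",
            params=asdict(BicelleParams(r_core=38.6, h_head=8.1, scale=3.0e7)),
            free={"r_core": (20.0, 60.0), "scale": (3e6, 3e8)},
        )
        ranking = compare_models(curve, [bic, rib])
        assert ranking[0].model_name == "ribbon"
        assert ranking[0].chi2_red < ranking[1].chi2_red

    def test_mixture_beats_pure_ribbon_on_mixture_data(
        self, ribbon_330, bicelle_5045
    ):
        """The synthetic analog of preferring ribbon+bicelle over ribbon."""
        from dataclasses import asdict

        q = np.geomspace(0.01, 0.5, 100)
        i = 0.6 * ribbon_intensity(q, ribbon_330) + 0.4 * bicelle_intensity(
            q, bicelle_5045
        )
        curve = SASCurve(q, i, 0.02 * i)
        pure = FitProblem(
            curve=curve, model="ribbon", params=asdict(ribbon_330),
            free={"r_minor": (12.0, 30.0), "r_major": (31.0, 60.0),
                  "scale": (3e6, 3e8)},
        )
        mix_fn = make_mixture_fn({"r": "ribbon", "b": "bicelle"})
        mix_params = {
            **{f"r.{k}": v for k, v in asdict(ribbon_330).items()},
            **{f"b.{k}": v for k, v in asdict(bicelle_5045).items()},
            "phi_r": 0.5,
            "phi_b": 0.5,
            "background": 0.0,
        }
        mix = FitProblem(
            curve=curve, model=mix_fn, params=mix_params,
            free={"phi_r": (0.0, 2.0), "phi_b": (0.0, 2.0)}, name="mixture",
        )
        ranking = compare_models(curve, [pure, mix])
        assert ranking[0].model_name == "mixture"
        # mirrors the observed contrast: the mixture fit is decisively better
        assert ranking[0].chi2_red < 0.5 * ranking[1].chi2_red

    def test_tie_keeps_input_order(self, q_mid, bicelle_5045):
        from dataclasses import asdict

        curve = _bicelle_curve(q_mid, bicelle_5045, sigma_rel=0.02)
        p = FitProblem(
            curve=curve, model="bicelle", params=asdict(bicelle_5045),
            free={}, name="first",
        )
        p2 = FitProblem(
            curve=curve, model="bicelle", params=asdict(bicelle_5045),
            free={}, name="second",
        )
        ranking = compare_models(curve, [p, p2])
        assert [r.model_name for r in ranking] == ["first", "second"]
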