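"""Functional forms, derivatives and derived curve features."""

import math

import numpy as np
import pytest

from duckgrowth import (
    MODEL_NAMES,
    MODELS,
    DomainError,
    derivative,
    evaluate,
    final_weight,
    initial_weight,
    janoschek_params_from_bridges,
)
from duckgrowth.models import (
    InvalidParamsError,
    UnknownModelError,
    canonical_sinusoidal_params,
    validate_params,
)

TWO_PI = 2 * math.pi


def test_model_metadata():
    assert set(MODEL_NAMES) == {
        "bridges", "janoschek", "logistic", "gompertz", "von_bertalanffy",
        "richards", "schumacher", "morgan", "sinusoidal",
    }
    for name, mdef in MODELS.items():
        assert mdef.param_count == len(mdef.param_names)
        expected_p = 4 if name in ("bridges", "janoschek", "richards", "sinusoidal") else 3
        assert mdef.param_count == expected_p
        assert mdef.has_asymptote == (name not in ("schumacher", "morgan"))


class TestEvaluate:
    def test_sinusoidal_peak_equals_final_weight(self, kuzi):
        """At the crest of the sinusoid the weight is y0 + a."""
        p = kuzi.param_set("sinusoidal")
        t_peak = p["b"] * (math.pi / 2 - p["c"] + TWO_PI) / TWO_PI
        (y,) = evaluate("sinusoidal", p, [t_peak])
        assert y == pytest.approx(1534.9772, abs=1e-3)

    def test_sinusoidal_zero_amplitude_is_offset(self):
        p = {"y0": 700.0, "a": 0.0, "b": 100.0, "c": 1.0}
        y = evaluate("sinusoidal", p, [1.0, 10.0, 55.5])
        assert np.all(y == 700.0)

    @pytest.mark.parametrize(
        "model, expected",
        [
            ("logistic", 1524.7016),
            ("gompertz", 1559.5286),
            ("von_bertalanffy", 1574.1386),
            ("morgan", 1542.7431),
        ],
    )
    def test_day70_weights_kuzi(self, kuzi, model, expected):
        """Hand-evaluated closed forms at the last Kuzi observation age."""
        (y,) = evaluate(model, kuzi.param_set(model), [70.0])
        assert y == pytest.approx(expected, abs=1e-3)

    def test_gompertz_between_logistic_and_von_bertalanffy_at_70(self, kuzi):
        lo = evaluate("logistic", kuzi.param_set("logistic"), [70.0])[0]
        mid = evaluate("gompertz", kuzi.param_set("gompertz"), [70.0])[0]
        hi = evaluate("von_bertalanffy", kuzi.param_set("von_bertalanffy"), [70.0])[0]
        assert lo < mid < hi

    def test_preserves_input_order(self, kuzi):
        p = kuzi.param_set("gompertz")
        ages = [70.0, 1.0, 35.0]
        y = evaluate("gompertz", p, ages)
        assert list(y) == [evaluate("gompertz", p, [t])[0] for t in ages]

    def test_unknown_model_raises(self):
        with pytest.raises(UnknownModelError):
            evaluate("brody", {"a": 1.0}, [1.0])

    def test_param_mismatch_raises(self):
        with pytest.raises(InvalidParamsError, match="missing"):
            validate_params("logistic", {"a": 1.0, "b": 2.0})
        with pytest.raises(InvalidParamsError, match="unexpected"):
            validate_params("logistic", {"a": 1.0, "b": 2.0, "k": 0.1, "m": 1.0})

    def test_nonpositive_age_raises(self, kuzi):
        with pytest.raises(DomainError):
            evaluate("gompertz", kuzi.param_set("gompertz"), [0.0])

    def test_richards_negative_base_raises_and_names_age(self, kuzi):
        # Kuzi Richards has b > 1: the base is negative at day 1 and the
        # exponent 1/m is fractional, so day 1 is outside the domain
        p = kuzi.param_set("richards")
        with pytest.raises(DomainError, match="age 1"):
            evaluate("richards", p, [1.0])
        y = evaluate("richards", p, [70.0])  # late ages are fine
        assert 1500 < y[0] < 1600


class TestDerivative:
    def test_sinusoidal_maximum_rate(self, kuzi):
        """The AGR peaks at a*2*pi/b where the cosine reaches one."""
        p = kuzi.param_set("sinusoidal")
        t_star = p["b"] * (TWO_PI - p["c"]) / TWO_PI
        (d,) = derivative("sinusoidal", p, [t_star])
        assert d == pytest.approx(p["a"] * TWO_PI / p["b"], rel=1e-12)
        assert d == pytest.approx(32.172, abs=1e-3)
        # cross-check by dense grid evaluation
        grid = np.linspace(1, 70, 20001)
        assert derivative("sinusoidal", p, grid).max() <= d + 1e-9

    def test_sinusoidal_zero_amplitude_zero_rate(self):
        p = {"y0": 700.0, "a": 0.0, "b": 100.0, "c": 1.0}
        assert np.all(derivative("sinusoidal", p, np.arange(1.0, 50.0)) == 0.0)

    def test_logistic_rate_vanishes_at_asymptote(self, kuzi):
        p = kuzi.param_set("logistic")
        (d,) = derivative("logistic", p, [1e4])
        assert d == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("model", MODEL_NAMES)
    def test_matches_numerical_differentiation(self, model, all_breeds):
        """Analytic (or FD) derivative tracks a numeric derivative of
        evaluate() at 100 random draws within fixture-scaled boxes."""
        rng = np.random.default_rng(42)
        base_sets = [fx.param_set(model) for fx in all_breeds.values()]
        h = 1e-4
        checked = 0
        attempts = 0
        while checked < 100 and attempts < 2000:
            attempts += 1
            base = base_sets[rng.integers(3)]
            params = {k: v * rng.uniform(0.8, 1.25) for k, v in base.items()}
            t = np.array([rng.uniform(5.0, 65.0)])
            try:
                d = derivative(model, params, t)
                num = (evaluate(model, params, t + h) - evaluate(model, params, t - h)) / (2 * h)
            except DomainError:
                continue
            scale = max(abs(num[0]), 1e-6)
            assert abs(d[0] - num[0]) / scale < 1e-5, (params, t)
            checked += 1
        assert checked == 100


class TestCurveFeatures:
    def test_initial_weight_conventions(self, kuzi):
        assert initial_weight("bridges", kuzi.param_set("bridges")) == pytest.approx(50.3691)
        p = kuzi.param_set("sinusoidal")
        assert initial_weight("sinusoidal", p) == pytest.approx(22.9409, abs=1e-3)
        p0 = dict(p, c=0.0)
        assert initial_weight("sinusoidal", p0) == pytest.approx(p["y0"])
        pl = kuzi.param_set("logistic")
        assert initial_weight("logistic", pl) == pytest.approx(pl["a"] / (1 + pl["b"]))
        ps = kuzi.param_set("schumacher")
        assert initial_weight("schumacher", ps) == pytest.approx(ps["a"] * ps["k"])
        assert initial_weight("morgan", kuzi.param_set("morgan")) == 0.0

    def test_sinusoidal_final_weights(self, all_breeds):
        expected = {"kuzi": 1534.9772, "polish_pekin": 2030.0527, "peking": 4519.5646}
        for breed, fx in all_breeds.items():
            fw = final_weight("sinusoidal", fx.param_set("sinusoidal"))
            assert fw == pytest.approx(expected[breed], abs=1e-3)

    def test_final_weight_undefined_without_asymptote(self, kuzi):
        assert final_weight("schumacher", kuzi.param_set("schumacher")) is None
        assert final_weight("morgan", kuzi.param_set("morgan")) is None

    def test_final_weight_bridges_is_w0_plus_a(self, kuzi):
        p = kuzi.param_set("bridges")
        assert final_weight("bridges", p) == pytest.approx(p["W0"] + p["a"])


class TestInvariants:
    def test_bridges_janoschek_equivalence(self):
        """a_J = W0 + a_B maps Bridges onto Janoschek exactly."""
        rng = np.random.default_rng(7)
        ages = np.linspace(1, 70, 40)
        for _ in range(20):
            bp = {
                "W0": rng.uniform(20, 80),
                "a": rng.uniform(800, 3000),
                "k": rng.uniform(1e-4, 0.01),
                "m": rng.uniform(1.2, 2.5),
            }
            jp = janoschek_params_from_bridges(bp)
            yb = evaluate("bridges", bp, ages)
            yj = evaluate("janoschek", jp, ages)
            np.testing.assert_allclose(yj, yb, rtol=1e-9)

    def test_sinusoidal_periodicity(self, kuzi):
        p = kuzi.param_set("sinusoidal")
        t = np.linspace(1, 70, 25)
        np.testing.assert_allclose(
            evaluate("sinusoidal", p, t), evaluate("sinusoidal", p, t + p["b"]),
            rtol=1e-12, atol=1e-9,
        )

    @pytest.mark.parametrize("model", ["logistic", "gompertz", "von_bertalanffy",
                                       "bridges", "janoschek"])
    def test_monotone_models_nondecreasing(self, model, all_breeds):
        for fx in all_breeds.values():
            y = evaluate(model, fx.param_set(model), np.linspace(0.5, 120, 4000))
            assert np.all(np.diff(y) >= -1e-9), (model, fx.breed)

    def test_canonical_sinusoidal_preserves_curve(self):
        t = np.linspace(1, 70, 33)
        base = {"y0": 700.0, "a": 750.0, "b": 150.0, "c": 5.0}
        for variant in (
            dict(base, a=-base["a"], c=base["c"] + math.pi),
            dict(base, b=-base["b"], a=-base["a"], c=-base["c"]),
            dict(base, c=base["c"] - 2 * TWO_PI),
        ):
            canon = canonical_sinusoidal_params(variant)
            np.testing.assert_allclose(
                evaluate("sinusoidal", canon, t), evaluate("sinusoidal", base, t), rtol=1e-12
            )
            assert canon["a"] > 0 and canon["b"] > 0 and 0 <= canon["c"] < TWO_PI
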