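"""Nonlinear growth functions for age--body-weight modelling.

Nine models are provided: eight classical sigmoidal growth functions
(Bridges, Janoschek, logistic, Gompertz, von Bertalanffy, Richards,
Schumacher, Morgan) and a sinusoidal function, which on a sub-period
window traces a sigmoid-like rise and has been proposed as an
alternative description of poultry growth.

Each model maps age ``t`` (days) to expected body weight (grams) and is
parameterised by a small set of named parameters:

``a``
    asymptotic (mature) weight in grams for the classical asymptotic
    models; the amplitude (g) for the sinusoidal model.
``b``
    an integration constant fixed by the initial condition (logistic,
    Gompertz, von Bertalanffy, Richards), a time-like constant in days
    (Schumacher, Morgan), or the period in days (sinusoidal).
``k``
    maturation rate per day -- how fast the curve approaches maturity.
``m``
    dimensionless shape parameter locating the inflection point
    (Bridges, Janoschek, Richards).
``W0``
    initial body weight in grams (Bridges, Janoschek).
``y0``
    vertical offset in grams (sinusoidal).
``c``
    phase shift in radians (sinusoidal).

The Bridges function is implemented as ``y = W0 + a*(1 - exp(-k*t^m))``,
i.e. with an explicit amplitude ``a``; some printed sources typeset the
form without the amplitude, but the four-parameter version is the one
whose parameter counts and estimates are internally consistent.
Schumacher and Morgan are implemented in their rate-style forms
``a*b^2*k*(t+b)^-2*exp(b*k*t/(t+b))`` and
``a*b^k*k*t^(k-1)/(t^k+b^k)^2``; for these two the asymptotic weight is
not an estimated parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MODEL_NAMES",
    "MODELS",
    "ModelDefinition",
    "GrowthModelError",
    "DomainError",
    "UnknownModelError",
    "InvalidParamsError",
    "get_model",
    "validate_params",
    "evaluate",
    "derivative",
    "initial_weight",
    "final_weight",
    "janoschek_params_from_bridges",
]

_TWO_PI = 2.0 * math.pi

#: step used for the central-difference derivatives of Schumacher/Morgan
FD_STEP = 1e-4


class GrowthModelError(ValueError):
    """Base class for growth-model errors."""


class DomainError(GrowthModelError):
    """A model was evaluated outside its mathematical domain."""


class UnknownModelError(GrowthModelError):
    """A model name not among the nine supported models."""


class InvalidParamsError(GrowthModelError):
    """A parameter set does not match the model's required symbols."""


@dataclass(frozen=True)
class ModelDefinition:
    """Metadata for one growth function.

    Attributes
    ----------
    name
        Canonical model name (snake_case).
    param_names
        Ordered parameter symbols required by the functional form.
    has_asymptote
        Whether the mature (final) weight is an estimated parameter.
        False for Schumacher and Morgan, whose rate-style forms do not
        contain the asymptote as a parameter.
    """

    name: str
    param_names: tuple[str, ...]
    has_asymptote: bool

    @property
    def param_count(self) -> int:
        return len(self.param_names)


MODELS: dict[str, ModelDefinition] = {
    d.name: d
    for d in (
        ModelDefinition("bridges", ("W0", "a", "k", "m"), True),
        ModelDefinition("janoschek", ("a", "W0", "k", "m"), True),
        ModelDefinition("logistic", ("a", "b", "k"), True),
        ModelDefinition("gompertz", ("a", "b", "k"), True),
        ModelDefinition("von_bertalanffy", ("a", "b", "k"), True),
        ModelDefinition("richards", ("a", "b", "k", "m"), True),
        ModelDefinition("schumacher", ("a", "b", "k"), False),
        ModelDefinition("morgan", ("a", "b", "k"), False),
        ModelDefinition("sinusoidal", ("y0", "a", "b", "c"), True),
    )
}

MODEL_NAMES: tuple[str, ...] = tuple(MODELS)


def get_model(model: str | ModelDefinition) -> ModelDefinition:
    """Resolve a model name (or pass a definition through)."""
    if isinstance(model, ModelDefinition):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise UnknownModelError(
            f"unknown model {model!r}; expected one of {', '.join(MODEL_NAMES)}"
        ) from None


def validate_params(model: str | ModelDefinition, params: Mapping[str, float]) -> ModelDefinition:
    """Check that ``params`` carries exactly the symbols the model needs."""
    mdef = get_model(model)
    got = set(params)
    need = set(mdef.param_names)
    if got != need:
        missing = sorted(need - got)
        extra = sorted(got - need)
        raise InvalidParamsError(
            f"{mdef.name}: parameter set mismatch"
            + (f"; missing {missing}" if missing else "")
            + (f"; unexpected {extra}" if extra else "")
        )
    return mdef


def _as_ages(ages: float | Sequence[float] | np.ndarray) -> np.ndarray:
    t = np.atleast_1d(np.asarray(ages, dtype=float))
    if t.ndim != 1:
        raise GrowthModelError("ages must be a one-dimensional sequence")
    return t


def _is_integer_exponent(x: float, tol: float = 1e-9) -> bool:
    return abs(x - round(x)) < tol


def _richards_base(params: Mapping[str, float], t: np.ndarray, clip: bool) -> np.ndarray:
    base = 1.0 - params["b"] * np.exp(-params["k"] * t)
    if clip:
        return np.maximum(base, 1e-12)
    inv_m = 1.0 / params["m"]
    if not _is_integer_exponent(inv_m):
        bad = base <= 0.0
        if np.any(bad):
            age = t[bad][0]
            raise DomainError(
                f"richards: base 1 - b*exp(-k*t) = {base[bad][0]:.6g} <= 0 at age "
                f"{age:g} d with non-integer exponent 1/m = {inv_m:.6g}"
            )
    return base


def _evaluate_raw(name: str, params: Mapping[str, float], t: np.ndarray, clip: bool) -> np.ndarray:
    p = params
    if name == "bridges":
        return p["W0"] + p["a"] * (1.0 - np.exp(-p["k"] * t ** p["m"]))
    if name == "janoschek":
        return p["a"] - (p["a"] - p["W0"]) * np.exp(-p["k"] * t ** p["m"])
    if name == "logistic":
        return p["a"] / (1.0 + p["b"] * np.exp(-p["k"] * t))
    if name == "gompertz":
        return p["a"] * np.exp(-p["b"] * np.exp(-p["k"] * t))
    if name == "von_bertalanffy":
        return p["a"] * (1.0 - p["b"] * np.exp(-p["k"] * t)) ** 3
    if name == "richards":
        base = _richards_base(p, t, clip)
        inv_m = 1.0 / p["m"]
        if _is_integer_exponent(inv_m) and not clip:
            return p["a"] * np.sign(base) ** round(inv_m) * np.abs(base) ** round(inv_m)
        return p["a"] * base ** inv_m
    if name == "schumacher":
        denom = t + p["b"]
        if clip:
            denom = np.where(np.abs(denom) < 1e-9, 1e-9, denom)
        elif np.any(denom == 0.0):
            age = t[denom == 0.0][0]
            raise DomainError(f"schumacher: t + b = 0 at age {age:g} d")
        return p["a"] * p["b"] ** 2 * p["k"] * denom ** -2 * np.exp(p["b"] * p["k"] * t / denom)
    if name == "morgan":
        tk = t ** p["k"]
        bk = p["b"] ** p["k"]
        return p["a"] * bk * p["k"] * t ** (p["k"] - 1.0) / (tk + bk) ** 2
    if name == "sinusoidal":
        return p["y0"] + p["a"] * np.sin(_TWO_PI * t / p["b"] + p["c"])
    raise UnknownModelError(name)  # pragma: no cover - guarded by get_model


def evaluate(
    model: str | ModelDefinition,
    params: Mapping[str, float],
    ages: float | Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Predict body weight (g) at each age (days).

    Parameters
    ----------
    model
        Model name or :class:`ModelDefinition`.
    params
        Parameter values keyed by symbol; must match the model exactly.
    ages
        Positive ages in days (scalar or sequence); order is preserved.

    Returns
    -------
    numpy.ndarray
        Predicted weights, one per age.

    Raises
    ------
    DomainError
        If the model is evaluated outside its domain (e.g. a Richards
        base ``1 - b*exp(-k*t) <= 0`` with a fractional exponent), or a
        prediction is not finite. The offending age is named.
    """
    mdef = validate_params(model, params)
    t = _as_ages(ages)
    if np.any(t <= 0.0):
        raise DomainError(f"{mdef.name}: ages must be positive, got {t[t <= 0.0][0]:g}")
    y = _evaluate_raw(mdef.name, params, t, clip=False)
    if not np.all(np.isfinite(y)):
        age = t[~np.isfinite(y)][0]
        raise DomainError(f"{mdef.name}: non-finite prediction at age {age:g} d")
    return y


def evaluate_clipped(
    model: str | ModelDefinition,
    params: Mapping[str, float],
    ages: np.ndarray,
) -> np.ndarray:
    """Evaluate with domain violations clipped instead of raised.

    Used internally by the optimiser, where trial parameter vectors may
    wander outside the model's domain; remaining non-finite values are
    replaced by a large penalty so the search is steered back.
    """
    mdef = get_model(model)
    t = np.asarray(ages, dtype=float)
    with np.errstate(all="ignore"):
        y = _evaluate_raw(mdef.name, params, t, clip=True)
    return np.nan_to_num(y, nan=1e12, posinf=1e12, neginf=-1e12)


_ANALYTIC_DERIVATIVES = frozenset(
    {"bridges", "janoschek", "logistic", "gompertz", "von_bertalanffy", "richards", "sinusoidal"}
)


def _derivative_raw(name: str, p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    if name == "bridges":
        return p["a"] * p["k"] * p["m"] * t ** (p["m"] - 1.0) * np.exp(-p["k"] * t ** p["m"])
    if name == "janoschek":
        return (
            (p["a"] - p["W0"])
            * p["k"] * p["m"] * t ** (p["m"] - 1.0)
            * np.exp(-p["k"] * t ** p["m"])
        )
    if name == "logistic":
        e = np.exp(-p["k"] * t)
        return p["a"] * p["b"] * p["k"] * e / (1.0 + p["b"] * e) ** 2
    if name == "gompertz":
        e = np.exp(-p["k"] * t)
        return p["a"] * p["b"] * p["k"] * e * np.exp(-p["b"] * e)
    if name == "von_bertalanffy":
        e = np.exp(-p["k"] * t)
        return 3.0 * p["a"] * p["b"] * p["k"] * e * (1.0 - p["b"] * e) ** 2
    if name == "richards":
        e = np.exp(-p["k"] * t)
        base = _richards_base(p, t, clip=False)
        return p["a"] * (p["b"] * p["k"] / p["m"]) * e * base ** (1.0 / p["m"] - 1.0)
    if name == "sinusoidal":
        return p["a"] * (_TWO_PI / p["b"]) * np.cos(_TWO_PI * t / p["b"] + p["c"])
    raise UnknownModelError(name)  # pragma: no cover


def derivative(
    model: str | ModelDefinition,
    params: Mapping[str, float],
    ages: float | Sequence[float] | np.ndarray,
) -> np.ndarray:
    """First derivative dy/dt of the growth curve -- the absolute growth
    rate (AGR), in g/day.

    Analytic expressions are used for all models except Schumacher and
    Morgan, whose derivatives are computed by central finite differences
    with step :data:`FD_STEP`.
    """
    mdef = validate_params(model, params)
    t = _as_ages(ages)
    if np.any(t <= 0.0):
        raise DomainError(f"{mdef.name}: ages must be positive, got {t[t <= 0.0][0]:g}")
    if mdef.name in _ANALYTIC_DERIVATIVES:
        d = _derivative_raw(mdef.name, params, t)
    else:
        h = FD_STEP
        lo = np.maximum(t - h, 1e-12)
        hi = t + h
        d = (_evaluate_raw(mdef.name, params, hi, clip=False)
             - _evaluate_raw(mdef.name, params, lo, clip=False)) / (hi - lo)
    if not np.all(np.isfinite(d)):
        age = t[~np.isfinite(d)][0]
        raise DomainError(f"{mdef.name}: non-finite derivative at age {age:g} d")
    return d


def initial_weight(model: str | ModelDefinition, params: Mapping[str, float]) -> float:
    """Initial body weight (g), the curve value at t = 0.

    Bridges and Janoschek carry the initial weight as the parameter
    ``W0``; the sinusoidal initial weight is ``y0 + a*sin(c)``.  For the
    remaining models the value follows from the functional form at
    ``t = 0``: logistic ``a/(1+b)``, Gompertz ``a*exp(-b)``,
    von Bertalanffy ``a*(1-b)^3``, Richards ``a*(1-b)^(1/m)``,
    Schumacher ``a*k``, and Morgan 0 (for ``k > 1``).
    """
    mdef = validate_params(model, params)
    p = params
    if mdef.name in ("bridges", "janoschek"):
        return float(p["W0"])
    if mdef.name == "sinusoidal":
        return float(p["y0"] + p["a"] * math.sin(p["c"]))
    if mdef.name == "morgan":
        if p["k"] <= 1.0:
            raise DomainError("morgan: initial weight undefined for k <= 1")
        return 0.0
    if mdef.name == "schumacher":
        return float(p["a"] * p["k"])
    return float(_evaluate_raw(mdef.name, p, np.array([0.0]), clip=False)[0])


def final_weight(model: str | ModelDefinition, params: Mapping[str, float]) -> float | None:
    """Final (asymptotic/mature) weight in grams.

    Returns ``a`` for logistic, Gompertz, von Bertalanffy, Richards and
    Janoschek; ``W0 + a`` for Bridges; ``y0 + a`` for the sinusoidal
    model (its maximum over one period); and ``None`` for Schumacher and
    Morgan, whose asymptotic weight is not an estimated parameter.
    """
    mdef = validate_params(model, params)
    if not mdef.has_asymptote:
        return None
    if mdef.name == "bridges":
        return float(params["W0"] + params["a"])
    if mdef.name == "sinusoidal":
        return float(params["y0"] + params["a"])
    return float(params["a"])


def canonical_sinusoidal_params(params: Mapping[str, float]) -> dict[str, float]:
    """Map a sinusoidal parameter set to its canonical representative.

    The sinusoid ``y0 + a*sin(2*pi*t/b + c)`` is invariant under sign
    flips of ``a`` and ``b`` (absorbed into the phase) and under phase
    shifts by whole turns.  The canonical form has ``a > 0``, ``b > 0``
    and ``c`` in ``[0, 2*pi)``, which makes fitted parameters directly
    comparable with the generating truth.
    """
    validate_params("sinusoidal", params)
    y0, a, b, c = (params[k] for k in ("y0", "a", "b", "c"))
    if b < 0:
        # sin(2*pi*t/b + c) = -sin(2*pi*t/|b| - c)
        b, a, c = -b, -a, -c
    if a < 0:
        a, c = -a, c + math.pi
    return {"y0": float(y0), "a": float(a), "b": float(b), "c": float(c % _TWO_PI)}


def janoschek_params_from_bridges(params: Mapping[str, float]) -> dict[str, float]:
    """Map a Bridges parameter set onto the equivalent Janoschek set.

    The two forms describe the same curve under ``a_J = W0 + a_B`` with
    ``W0``, ``k`` and ``m`` unchanged, which is why the two models
    produce identical fits and identical goodness-of-fit statistics.
    """
    validate_params("bridges", params)
    return {
        "a": params["W0"] + params["a"],
        "W0": params["W0"],
        "k": params["k"],
        "m": params["m"],
    }
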