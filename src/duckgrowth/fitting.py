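"""Nonlinear least-squares fitting of growth models to age--weight series.

Parameters are estimated by minimising the residual sum of squares
(RSS) with the Levenberg--Marquardt algorithm, restarted from a
deterministic grid of heuristic initial values plus a small number of
seeded randomised starts.  The lowest-RSS converged solution wins; a
well-posed problem reaches the same optimum from every converging
start, so the choice of initial values has no bearing on the final
estimates.

A brute-force grid-search minimiser is also provided.  It is far too
coarse for real estimation but serves as an independent oracle: the
optimiser must never return a worse RSS than an exhaustive grid search
over the same region.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
from scipy.optimize import least_squares

from .models import (
    DomainError,
    ModelDefinition,
    evaluate,
    evaluate_clipped,
    get_model,
)

__all__ = [
    "AgeWeightSeries",
    "FitConfig",
    "FitResult",
    "FitInputError",
    "NonConvergenceError",
    "initial_guesses",
    "fit",
    "grid_search_oracle",
]

logger = logging.getLogger(__name__)


class FitInputError(ValueError):
    """The series cannot support the requested fit (e.g. n <= p)."""


class NonConvergenceError(RuntimeError):
    """No start converged; carries the best attempt in ``best``."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class AgeWeightSeries:
    """One group's ordered body-weight observations.

    ``ages`` are days (> 0, strictly increasing); ``weights`` are grams
    (> 0), one per age.
    """

    label: str
    ages: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "weights", weights)
        if ages.ndim != 1 or weights.ndim != 1 or len(ages) != len(weights):
            raise FitInputError(f"{self.label}: ages and weights must be equal-length vectors")
        if len(ages) == 0:
            raise FitInputError(f"{self.label}: empty series")
        if not np.all(np.isfinite(ages)) or not np.all(np.isfinite(weights)):
            raise FitInputError(f"{self.label}: non-finite values")
        if np.any(ages <= 0):
            raise FitInputError(f"{self.label}: ages must be positive")
        if np.any(np.diff(ages) <= 0):
            raise FitInputError(f"{self.label}: ages must be strictly increasing (no duplicates)")
        if np.any(weights <= 0):
            raise FitInputError(f"{self.label}: weights must be positive")

    @property
    def n(self) -> int:
        return len(self.ages)


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings.

    ``tol`` is applied to both the relative RSS change and the relative
    parameter step; ``n_random_starts`` seeded jittered starts are
    appended to the deterministic heuristic grid; ``max_starts`` caps
    the total number of starts actually tried (None = all).
    """

    max_iterations: int = 1000
    tol: float = 1e-10
    n_random_starts: int = 8
    seed: int = 0
    max_starts: int | None = None

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class FitResult:
    """Converged parameter estimates for one model on one series."""

    model: str
    params: dict[str, float]
    rss: float
    converged: bool
    n_iterations: int
    starts_tried: int

    def predict(self, ages) -> np.ndarray:
        return evaluate(self.model, self.params, ages)


def _asymptote_starts(max_w: float) -> tuple[float, ...]:
    return (1.0 * max_w, 1.2 * max_w, 1.5 * max_w)


_K_GRID = (0.01, 0.05, 0.1, 0.5)
_M_GRID = (0.5, 1.0, 2.0)


def initial_guesses(
    model: str | ModelDefinition, series: AgeWeightSeries
) -> list[dict[str, float]]:
    """Deterministic heuristic starting values for one model.

    Asymptote starts bracket the largest observed weight from above;
    integration constants are back-solved from the first observation;
    maturation rates, shape parameters and sinusoidal phases come from
    fixed grids.  At least four starts are returned for every model.
    """
    mdef = get_model(model)
    w = series.weights
    t = series.ages
    w1 = float(w[0])
    max_w = float(w.max())
    starts: list[dict[str, float]] = []

    if mdef.name == "logistic":
        for a in _asymptote_starts(max_w):
            for k in _K_GRID:
                starts.append({"a": a, "b": a / w1 - 1.0, "k": k})
    elif mdef.name == "gompertz":
        for a in _asymptote_starts(max_w):
            for k in _K_GRID:
                starts.append({"a": a, "b": math.log(a / w1), "k": k})
    elif mdef.name == "von_bertalanffy":
        for a in _asymptote_starts(max_w):
            for k in _K_GRID:
                starts.append({"a": a, "b": 1.0 - (w1 / a) ** (1.0 / 3.0), "k": k})
    elif mdef.name == "richards":
        for a in _asymptote_starts(max_w):
            for k in _K_GRID:
                for m in _M_GRID:
                    starts.append({"a": a, "b": 1.0 - (w1 / a) ** m, "k": k, "m": m})
    elif mdef.name == "bridges":
        for a in _asymptote_starts(max_w):
            for k in _K_GRID:
                for m in _M_GRID:
                    starts.append({"W0": w1, "a": a, "k": k, "m": m})
    elif mdef.name == "janoschek":
        for a in _asymptote_starts(max_w):
            for k in _K_GRID:
                for m in _M_GRID:
                    starts.append({"a": a, "W0": w1, "k": k, "m": m})
    elif mdef.name == "schumacher":
        t_last, w_last = float(t[-1]), float(w[-1])
        mean_t = float(t.mean())
        for b in (0.5 * mean_t, 1.0 * mean_t, 2.0 * mean_t):
            for k in _K_GRID:
                scale = b**2 * k * (t_last + b) ** -2 * math.exp(b * k * t_last / (t_last + b))
                starts.append({"a": w_last / scale, "b": b, "k": k})
    elif mdef.name == "morgan":
        t_last, w_last = float(t[-1]), float(w[-1])
        max_t = float(t.max())
        # morgan's k plays the role of a Hill-type exponent (> 1 for
        # sigmoid growth), so its grid differs from the rate-like k grid
        for b in (0.5 * max_t, 1.0 * max_t, 1.5 * max_t):
            for k in (1.5, 2.5, 3.5):
                scale = b**k * k * t_last ** (k - 1.0) / (t_last**k + b**k) ** 2
                starts.append({"a": w_last / scale, "b": b, "k": k})
    elif mdef.name == "sinusoidal":
        y0 = float(w.mean())
        amp = max((max_w - float(w.min())) / 2.0, 1e-6)
        span = float(t[-1] - t[0]) if len(t) > 1 else 1.0
        for b_mult in (2.0, 3.0, 4.0):
            for j in range(8):
                starts.append(
                    {"y0": y0, "a": amp, "b": b_mult * span, "c": j * 2.0 * math.pi / 8.0}
                )
    else:  # pragma: no cover - all nine handled above
        raise AssertionError(mdef.name)
    return starts


def _jittered_starts(
    base: list[dict[str, float]], n: int, seed: int
) -> Iterator[dict[str, float]]:
    rng = np.random.default_rng(seed)
    for _ in range(n):
        proto = base[rng.integers(len(base))]
        start = {}
        for key, val in proto.items():
            if key == "c":
                start[key] = float((val + rng.uniform(0, 2 * math.pi)) % (2 * math.pi))
            else:
                start[key] = float(val * rng.lognormal(0.0, 0.25)) if val != 0 else float(
                    rng.normal(0.0, 0.1)
                )
        yield start


def fit(
    model: str | ModelDefinition,
    series: AgeWeightSeries,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one growth model to a series by multi-start Levenberg--Marquardt.

    Returns the lowest-RSS converged solution over all starts (ties
    broken by earlier start index).  Deterministic for a given config
    seed.

    Raises
    ------
    FitInputError
        If the series has no more observations than the model has
        parameters.
    NonConvergenceError
        If no start converges; the best failed attempt is attached.
    """
    cfg = config or FitConfig()
    mdef = get_model(model)
    if series.n <= mdef.param_count:
        raise FitInputError(
            f"{series.label}: n = {series.n} observations cannot identify "
            f"{mdef.name} (p = {mdef.param_count}); need n > p"
        )
    names = mdef.param_names
    t = series.ages
    y = series.weights

    def residuals(x: np.ndarray) -> np.ndarray:
        params = dict(zip(names, x))
        return evaluate_clipped(mdef, params, t) - y

    starts = initial_guesses(mdef, series)
    starts.extend(_jittered_starts(starts, cfg.n_random_starts, cfg.seed))
    if cfg.max_starts is not None:
        starts = starts[: cfg.max_starts]

    best: FitResult | None = None
    best_failed: FitResult | None = None
    for i, start in enumerate(starts):
        x0 = np.array([start[k] for k in names], dtype=float)
        try:
            sol = least_squares(
                residuals,
                x0,
                method="lm",
                ftol=cfg.tol,
                xtol=cfg.tol,
                gtol=1e-12,
                max_nfev=cfg.max_iterations * (len(names) + 1),
            )
        except (ValueError, FloatingPointError):  # pathological start
            logger.debug("%s start %d failed outright", mdef.name, i)
            continue
        params = dict(zip(names, (float(v) for v in sol.x)))
        # score with the strict evaluator so domain-violating "solutions"
        # (clipped during the search) cannot win
        try:
            with np.errstate(all="ignore"):
                rss = float(np.sum((evaluate(mdef, params, t) - y) ** 2))
        except DomainError:
            logger.debug("%s start %d converged outside the model domain", mdef.name, i)
            continue
        result = FitResult(
            model=mdef.name,
            params=params,
            rss=rss,
            converged=bool(sol.status > 0),
            n_iterations=int(sol.nfev),
            starts_tried=len(starts),
        )
        if result.converged:
            if best is None or result.rss < best.rss:
                best = result
        elif best_failed is None or result.rss < best_failed.rss:
            best_failed = result
    if best is None:
        raise NonConvergenceError(
            f"{mdef.name}: no start converged on series {series.label!r}", best=best_failed
        )
    logger.debug(
        "%s: best RSS %.6g after %d starts", mdef.name, best.rss, best.starts_tried
    )
    return best


def grid_search_oracle(
    model: str | ModelDefinition,
    series: AgeWeightSeries,
    box: Mapping[str, tuple[float, float]],
    steps: int = 11,
) -> dict[str, float]:
    """Exhaustive RSS minimisation over a rectangular parameter grid.

    Intended as a brute-force cross-check of :func:`fit`, not as an
    estimator.  Returns the grid point with the smallest RSS; grid
    points outside the model's domain are skipped.

    Raises
    ------
    DomainError
        If every grid point violates the model's domain.
    ValueError
        If the box is not finite or ``steps < 1``.
    """
    mdef = get_model(model)
    if set(box) != set(mdef.param_names):
        raise ValueError(f"box must cover exactly the parameters {mdef.param_names}")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    axes = []
    for name in mdef.param_names:
        lo, hi = box[name]
        if not (math.isfinite(lo) and math.isfinite(hi)) or hi < lo:
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        axes.append(np.linspace(lo, hi, steps) if hi > lo else np.array([lo]))
    best_rss = math.inf
    best_params: dict[str, float] | None = None
    y = series.weights
    for combo in itertools.product(*axes):
        params = dict(zip(mdef.param_names, (float(v) for v in combo)))
        try:
            pred = evaluate(mdef, params, series.ages)
        except DomainError:
            continue
        rss = float(np.sum((pred - y) ** 2))
        if rss < best_rss:
            best_rss = rss
            best_params = params
    if best_params is None:
        raise DomainError(f"{mdef.name}: every grid point violates the model domain")
    return best_params
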