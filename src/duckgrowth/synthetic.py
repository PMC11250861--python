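"""Synthetic age--weight data and published breed fixtures.

The generator draws body weights as a deterministic growth-model mean
curve plus additive i.i.d. Gaussian noise -- the error structure
implicitly assumed by unweighted least-squares curve fitting -- and is
the workhorse for parameter-recovery and model-selection experiments.

Three breed fixtures ship with the package, transcribed from published
duck growth-curve analyses: Kuzi ducks (10 ages, day 1-70), Polish
Pekin ducks (8 ages, day 1-49) and an average of five Peking breeds
(8 ages, day 1-42).  Each fixture carries the per-model parameter
estimates and goodness-of-fit statistics reported for that breed.  The
raw weight records behind those fits were published elsewhere and are
not included; the exact Peking observation ages are unpublished, so
the Peking grid here is a synthetic stand-in (marked as such) with the
correct number of ages over the correct span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .fitting import AgeWeightSeries
from .models import evaluate, get_model, validate_params

__all__ = [
    "BREEDS",
    "BREED_GRIDS",
    "SyntheticSpec",
    "BreedFixture",
    "GenerationError",
    "generate",
    "fixture",
]

BREED_GRIDS: dict[str, tuple[int, ...]] = {
    "kuzi": (1, 7, 14, 21, 28, 35, 42, 49, 56, 70),
    "polish_pekin": (1, 7, 14, 21, 28, 35, 42, 49),
    # the true Peking observation ages are unpublished; this synthetic
    # grid has the documented size (8) and span (day 1-42)
    "peking": (1, 3, 7, 14, 21, 28, 35, 42),
}

BREEDS = tuple(BREED_GRIDS)

#: grids that are invented stand-ins rather than published designs
_SYNTHETIC_GRIDS = frozenset({"peking"})


class GenerationError(ValueError):
    """The requested synthetic design cannot produce valid series."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of one synthetic experiment.

    weight(t) = model mean curve + Normal(0, noise_sd²) noise,
    truncated below at 1 g so generated series stay valid.
    """

    model: str
    params: Mapping[str, float]
    ages: tuple[float, ...] | np.ndarray
    noise_sd: float = 0.0
    seed: int = 0
    replicates: int = 1

    def __post_init__(self):
        validate_params(self.model, self.params)
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise GenerationError("replicates must be >= 1")


def generate(spec: SyntheticSpec) -> list[AgeWeightSeries]:
    """Draw ``spec.replicates`` series from the spec's noise model.

    Reproducible for a fixed seed; replicates differ only in their
    noise draws.  Raises :class:`GenerationError` if the mean curve is
    non-positive anywhere on the age grid.
    """
    ages = np.asarray(spec.ages, dtype=float)
    mean = evaluate(spec.model, spec.params, ages)
    if np.any(mean <= 0):
        bad = ages[mean <= 0][0]
        raise GenerationError(
            f"{spec.model}: mean curve non-positive at age {bad:g} d; "
            "not a valid weight trajectory"
        )
    rng = np.random.default_rng(spec.seed)
    out = []
    for r in range(spec.replicates):
        noise = rng.normal(0.0, spec.noise_sd, size=len(ages)) if spec.noise_sd > 0 else 0.0
        weights = np.maximum(mean + noise, 1.0)
        out.append(
            AgeWeightSeries(label=f"{spec.model}_sim_{r:04d}", ages=ages, weights=weights)
        )
    return out


@dataclass(frozen=True)
class BreedFixture:
    """Published parameter estimates and fit statistics for one breed."""

    breed: str
    ages: tuple[int, ...]
    parameters: dict[str, dict[str, float]]  # model -> symbol -> value
    gof: dict[str, dict[str, float]]  # model -> statistic -> value
    notes: dict[tuple[str, str], str] = field(default_factory=dict)
    grid_is_synthetic: bool = False

    @property
    def n(self) -> int:
        return len(self.ages)

    def param_set(self, model: str) -> dict[str, float]:
        return dict(self.parameters[get_model(model).name])


def _load_csv(name: str) -> pd.DataFrame:
    ref = resources.files("duckgrowth.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def fixture(breed: str) -> BreedFixture:
    """Load the packaged fixture for one of the three breeds."""
    if breed not in BREED_GRIDS:
        raise KeyError(f"unknown breed {breed!r}; expected one of {BREEDS}")
    params_df = _load_csv(f"{breed}_parameters.csv")
    gof_df = _load_csv(f"{breed}_gof.csv")
    parameters: dict[str, dict[str, float]] = {}
    notes: dict[tuple[str, str], str] = {}
    for row in params_df.itertuples(index=False):
        parameters.setdefault(row.model, {})[row.parameter] = float(row.value)
        if isinstance(row.note, str) and row.note:
            notes[(row.model, row.parameter)] = row.note
    for model, pset in parameters.items():
        validate_params(model, pset)
    gof = {
        row.model: {
            "r2adj": float(row.r2adj), "dw": float(row.dw), "rmse": float(row.rmse),
            "aic": float(row.aic), "bic": float(row.bic),
        }
        for row in gof_df.itertuples(index=False)
    }
    return BreedFixture(
        breed=breed,
        ages=BREED_GRIDS[breed],
        parameters=parameters,
        gof=gof,
        notes=notes,
        grid_is_synthetic=breed in _SYNTHETIC_GRIDS,
    )
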