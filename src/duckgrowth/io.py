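"""CSV input/output and the end-to-end comparison pipelines.

Age--weight series travel as plain UTF-8 CSV with header columns
``age_days`` and ``weight_g`` (optional ``label``).  ``run_compare``
fits every requested model to a series and emits a parameter table and
a ranked goodness-of-fit table; ``run_reproduce`` re-derives the
published fit statistics and curve features from the packaged breed
fixtures and reports a per-cell pass/fail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agr import agr_curve
from .fitting import (
    AgeWeightSeries,
    FitConfig,
    FitInputError,
    FitResult,
    NonConvergenceError,
    fit,
)
from .gof import ComparisonTable, compute_gof, rank_models, stats_from_rmse
from .models import MODEL_NAMES, evaluate, final_weight, get_model
from .synthetic import BREEDS, fixture

__all__ = [
    "RunConfig",
    "read_series",
    "write_series",
    "run_compare",
    "run_reproduce",
    "SeriesParseError",
]

logger = logging.getLogger(__name__)


class SeriesParseError(ValueError):
    """An input CSV could not be parsed into a valid series."""


REQUIRED_COLUMNS = ("age_days", "weight_g")


@dataclass(frozen=True)
class RunConfig:
    """Settings for a model-comparison run."""

    models: tuple[str, ...] = MODEL_NAMES
    rmse_denominator: str = "n_minus_p"
    fit_config: FitConfig = field(default_factory=FitConfig)
    output_dir: Path | None = None

    def __post_init__(self):
        if not self.models:
            raise ValueError("at least one model must be requested")
        for name in self.models:
            get_model(name)


def read_series(path) -> AgeWeightSeries:
    """Read one age--weight series from CSV.

    Requires columns ``age_days`` and ``weight_g``; rows are sorted by
    age.  Non-numeric cells, non-positive ages or weights, and
    duplicate ages are rejected with the offending row named.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise SeriesParseError(f"{path}: cannot read CSV ({exc})") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SeriesParseError(f"{path}: missing required column(s) {missing}")
    for col in REQUIRED_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise SeriesParseError(
                f"{path}: non-numeric {col} in data row {int(bad[0]) + 1}"
            )
        df[col] = vals
    for col, what in (("age_days", "age"), ("weight_g", "weight")):
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise SeriesParseError(
                f"{path}: non-positive {what} in data row {int(bad[0]) + 1}"
            )
    dup = df["age_days"].duplicated()
    if dup.any():
        raise SeriesParseError(
            f"{path}: duplicate age in data row {int(df.index[dup][0]) + 1}"
        )
    df = df.sort_values("age_days", kind="mergesort").reset_index(drop=True)
    if "label" in df.columns and len(df) and isinstance(df["label"].iloc[0], str):
        label = df["label"].iloc[0]
    else:
        label = path.stem
    return AgeWeightSeries(
        label=label,
        ages=df["age_days"].to_numpy(dtype=float),
        weights=df["weight_g"].to_numpy(dtype=float),
    )


def write_series(series: AgeWeightSeries, path) -> None:
    """Write a series to canonical CSV (age-sorted, '.' decimal)."""
    df = pd.DataFrame(
        {
            "age_days": series.ages,
            "weight_g": series.weights,
            "label": series.label,
        }
    )
    df.to_csv(path, index=False)


def run_compare(
    series: AgeWeightSeries, config: RunConfig | None = None
) -> tuple[ComparisonTable, dict[str, FitResult], dict[str, str]]:
    """Fit every requested model to ``series`` and rank the fits.

    Returns the ranked comparison table, the per-model fit results, and
    a dict of models that could not be fitted (model -> reason).  When
    ``config.output_dir`` is set, writes ``parameters.csv`` (long-form
    parameter table) and ``gof.csv`` (comparison table) there.
    """
    cfg = config or RunConfig()
    results: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    rows = []
    for name in cfg.models:
        try:
            res = fit(name, series, cfg.fit_config)
        except FitInputError as exc:
            logger.warning("skipping %s: %s", name, exc)
            failures[name] = str(exc)
            continue
        except NonConvergenceError as exc:
            logger.warning("non-convergence for %s: %s", name, exc)
            failures[name] = str(exc)
            continue
        results[name] = res
        stats = compute_gof(
            series,
            res.predict(series.ages),
            get_model(name).param_count,
            rmse_denominator=cfg.rmse_denominator,
        )
        rows.append((name, stats))
        logger.info("%s: RSS %.6g (%d starts)", name, res.rss, res.starts_tried)
    if not rows:
        raise NonConvergenceError(f"no requested model could be fitted to {series.label!r}")
    table = rank_models(rows)
    if cfg.output_dir is not None:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "gof.csv")
        param_rows = [
            {"model": m, "parameter": k, "value": v}
            for m, res in results.items()
            for k, v in res.params.items()
        ]
        pd.DataFrame(param_rows).to_csv(outdir / "parameters.csv", index=False)
    return table, results, failures


_P = {name: get_model(name).param_count for name in MODEL_NAMES}


def run_reproduce(
    out_path=None, rmse_denominator: str = "n_minus_p"
) -> pd.DataFrame:
    """Re-derive published statistics from the packaged fixtures.

    For all 27 breed x model cells, recomputes AIC and BIC from the
    reported RMSE (via RSS = RMSE²·dof) and compares with the reported
    values at tolerance 0.01.  Also recomputes the three sinusoidal
    final weights (tolerance 0.01 g) and the Kuzi age of maximum AGR
    (exact).  Returns a tidy report with a ``passed`` column; writes it
    to ``out_path`` as CSV when given.
    """
    records = []
    for breed in BREEDS:
        fx = fixture(breed)
        n = fx.n
        for model, g in fx.gof.items():
            stats = stats_from_rmse(
                g["rmse"], n, _P[model], rmse_denominator=rmse_denominator
            )
            for crit, computed in (("aic", stats.aic), ("bic", stats.bic)):
                expected = g[crit]
                records.append(
                    {
                        "check": f"{crit}_consistency", "breed": breed, "model": model,
                        "expected": expected, "computed": computed, "tolerance": 0.01,
                        "passed": abs(computed - expected) <= 0.01,
                    }
                )
    reported_final = {"kuzi": 1534.98, "polish_pekin": 2030.05, "peking": 4519.57}
    for breed, expected in reported_final.items():
        fw = final_weight("sinusoidal", fixture(breed).param_set("sinusoidal"))
        records.append(
            {
                "check": "sinusoidal_final_weight", "breed": breed, "model": "sinusoidal",
                "expected": expected, "computed": fw, "tolerance": 0.01,
                "passed": abs(fw - expected) <= 0.01,
            }
        )
    curve = agr_curve("sinusoidal", fixture("kuzi").param_set("sinusoidal"), 1, 70)
    records.append(
        {
            "check": "kuzi_agr_max_day", "breed": "kuzi", "model": "sinusoidal",
            "expected": 31, "computed": curve.age_of_max, "tolerance": 0.0,
            "passed": curve.age_of_max == 31,
        }
    )
    report = pd.DataFrame.from_records(records)
    if out_path is not None:
        report.to_csv(out_path, index=False)
    n_fail = int((~report["passed"]).sum())
    logger.info("reproduction report: %d checks, %d failed", len(report), n_fail)
    return report
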