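"""Goodness-of-fit statistics and model ranking.

Five statistics are computed for each fitted curve: adjusted R²
(R2adj), root mean square error (RMSE), the Durbin--Watson statistic
(DW) on age-ordered residuals, and the RSS-based Akaike and Bayesian
information criteria

    AIC = n*ln(RSS) + 2p
    BIC = n*ln(RSS/n) + p*ln(n)

with natural logarithms throughout.  Lower AIC/BIC and RMSE, and higher
R2adj, indicate a better fit; DW near 2 indicates uncorrelated
residuals (near 0: positive, near 4: negative autocorrelation).

RMSE convention
---------------
The default is RMSE = sqrt(RSS/(n - p)) -- the residual standard
deviation with one degree of freedom per estimated parameter, and the
convention under which published (RMSE, AIC, BIC) triples for these
data are mutually consistent.  Some texts print sqrt(RSS/(n - p - 1));
pass ``rmse_denominator="n_minus_p_minus_1"`` to use that instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.stattools import durbin_watson as _sm_durbin_watson

from .fitting import AgeWeightSeries, FitInputError
from .models import get_model

__all__ = [
    "GofStats",
    "ComparisonTable",
    "compute_gof",
    "stats_from_rmse",
    "durbin_watson",
    "aic",
    "bic",
    "rank_models",
    "RMSE_DENOMINATORS",
]

RMSE_DENOMINATORS = ("n_minus_p", "n_minus_p_minus_1")


@dataclass(frozen=True)
class GofStats:
    """The five fit statistics plus their ingredients.

    Undefined quantities (R² on flat data, AIC/BIC at RSS = 0, DW for
    all-zero residuals) are carried as NaN.
    """

    n: int
    p: int
    rss: float
    tss: float
    r2: float
    r2adj: float
    rmse: float
    dw: float
    aic: float
    bic: float


def aic(rss: float, n: int, p: int) -> float:
    """Akaike information criterion, n*ln(RSS) + 2p (NaN if RSS = 0)."""
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    if rss == 0:
        return math.nan
    return n * math.log(rss) + 2 * p


def bic(rss: float, n: int, p: int) -> float:
    """Bayesian information criterion, n*ln(RSS/n) + p*ln(n) (NaN if RSS = 0)."""
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    if rss == 0:
        return math.nan
    return n * math.log(rss / n) + p * math.log(n)


def durbin_watson(residuals: Sequence[float] | np.ndarray) -> float:
    """Durbin--Watson statistic of age-ordered residuals.

    DW = sum_{t=2..n} (e_t - e_{t-1})² / sum_t e_t², in [0, 4].
    Returns NaN when all residuals are zero (perfect fit).
    """
    e = np.asarray(residuals, dtype=float)
    if e.ndim != 1 or len(e) < 2:
        raise ValueError("need at least two ordered residuals")
    # also covers residuals so small their squares underflow to zero
    if float(np.sum(e**2)) == 0.0:
        return math.nan
    return float(_sm_durbin_watson(e))


def compute_gof(
    series: AgeWeightSeries | np.ndarray,
    predictions: Sequence[float] | np.ndarray,
    p: int,
    rmse_denominator: str = "n_minus_p",
) -> GofStats:
    """Compute all five statistics for one model's predictions.

    Parameters
    ----------
    series
        Observed series (or a bare weight vector, age-ordered).
    predictions
        Model predictions aligned with the observations.
    p
        Number of estimated parameters.
    rmse_denominator
        ``"n_minus_p"`` (default) or ``"n_minus_p_minus_1"``.
    """
    if rmse_denominator not in RMSE_DENOMINATORS:
        raise ValueError(f"rmse_denominator must be one of {RMSE_DENOMINATORS}")
    y = series.weights if isinstance(series, AgeWeightSeries) else np.asarray(series, float)
    yhat = np.asarray(predictions, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observations and predictions differ in length")
    n = len(y)
    if n <= p:
        raise FitInputError(f"n = {n} observations with p = {p} parameters; need n > p")
    resid = y - yhat
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        r2 = math.nan
        r2adj = math.nan
    else:
        r2 = 1.0 - rss / tss
        r2adj = 1.0 - (n - 1) / (n - p) * (1.0 - r2)
    dof = n - p if rmse_denominator == "n_minus_p" else n - p - 1
    if dof <= 0:
        raise FitInputError(f"no residual degrees of freedom (n = {n}, p = {p})")
    rmse = math.sqrt(rss / dof)
    return GofStats(
        n=n, p=p, rss=rss, tss=tss, r2=r2, r2adj=r2adj, rmse=rmse,
        dw=durbin_watson(resid), aic=aic(rss, n, p), bic=bic(rss, n, p),
    )


def stats_from_rmse(
    rmse: float,
    n: int,
    p: int,
    r2adj: float = math.nan,
    dw: float = math.nan,
    rmse_denominator: str = "n_minus_p",
) -> GofStats:
    """Reconstruct a :class:`GofStats` from a reported RMSE.

    Inverts the RMSE convention to recover RSS = RMSE²·dof and derives
    AIC and BIC from it; statistics that cannot be recovered from the
    RMSE alone (TSS, R²) are NaN unless supplied.
    """
    if rmse_denominator not in RMSE_DENOMINATORS:
        raise ValueError(f"rmse_denominator must be one of {RMSE_DENOMINATORS}")
    dof = n - p if rmse_denominator == "n_minus_p" else n - p - 1
    if dof <= 0:
        raise FitInputError(f"no residual degrees of freedom (n = {n}, p = {p})")
    rss = rmse**2 * dof
    return GofStats(
        n=n, p=p, rss=rss, tss=math.nan, r2=math.nan, r2adj=r2adj, rmse=rmse,
        dw=dw, aic=aic(rss, n, p), bic=bic(rss, n, p),
    )


@dataclass(frozen=True)
class ComparisonTable:
    """Ranked goodness-of-fit comparison across models for one series.

    ``best_model`` minimises AIC (a perfect RSS = 0 fit counts as
    -inf); ties break by smaller parameter count, then by name.
    ``extremes`` records the per-statistic winners.
    """

    rows: tuple[tuple[str, GofStats], ...]
    best_model: str
    criterion: str
    extremes: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for name, s in self.rows:
            records.append(
                {
                    "model": name, "n": s.n, "p": s.p, "RSS": s.rss, "TSS": s.tss,
                    "R2": s.r2, "R2adj": s.r2adj, "RMSE": s.rmse, "DW": s.dw,
                    "AIC": s.aic, "BIC": s.bic,
                }
            )
        return pd.DataFrame.from_records(records)

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def _aic_key(stats: GofStats) -> float:
    # RSS = 0 drives n*ln(RSS) to -inf: a perfect fit ranks first
    if stats.rss == 0.0:
        return -math.inf
    return stats.aic


def rank_models(rows: Sequence[tuple[str, GofStats]]) -> ComparisonTable:
    """Rank models by AIC and record per-statistic extremes.

    The best model minimises AIC; ties are broken by smaller p, then by
    lexicographic model name.
    """
    if not rows:
        raise ValueError("need at least one model row")
    for name, _ in rows:
        get_model(name)
    best_model = min(rows, key=lambda r: (_aic_key(r[1]), r[1].p, r[0]))[0]

    def _extreme(attr: str, sign: float) -> str:
        return min(
            rows,
            key=lambda r: (
                sign * getattr(r[1], attr) if not math.isnan(getattr(r[1], attr))
                else math.inf,
                r[1].p,
                r[0],
            ),
        )[0]

    extremes = {
        "min_aic": best_model,
        "min_bic": _extreme("bic", 1.0),
        "min_rmse": _extreme("rmse", 1.0),
        "max_r2adj": _extreme("r2adj", -1.0),
    }
    return ComparisonTable(
        rows=tuple(rows), best_model=best_model, criterion="aic", extremes=extremes
    )
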