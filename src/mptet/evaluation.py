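"""Model-evaluation statistics on paired observed/predicted ET series.

Five statistics: coefficient of determination (squared Pearson
correlation), root-mean-square error, Willmott's index of agreement,
Nash-Sutcliffe model efficiency, and mean bias error.  The bias
convention is MBE = mean(observed - predicted): a *negative* MBE means
the model overestimates.  Willmott's d uses the standard form with the
square applied per term inside the denominator sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MptetError, UndefinedStatisticError

__all__ = [
    "PairedSeries",
    "EvalReport",
    "r_squared",
    "rmse",
    "agreement_index",
    "nsme",
    "mbe",
    "evaluate",
    "read_pairs_csv",
]


@dataclass
class PairedSeries:
    """Paired observed/predicted ET values (mm day^-1) with labels."""

    observed: np.ndarray
    predicted: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.observed.shape != self.predicted.shape:
            raise MptetError("observed and predicted must have equal length")
        if self.observed.ndim != 1 or self.observed.size < 2:
            raise MptetError("paired series needs at least 2 pairs")
        if not (np.isfinite(self.observed).all() and np.isfinite(self.predicted).all()):
            raise MptetError("paired series contains missing values")

    @property
    def n(self) -> int:
        return int(self.observed.size)


@dataclass(frozen=True)
class EvalReport:
    """The five validation statistics plus the pair count."""

    r2: float
    rmse: float
    d: float
    nsme: float
    mbe: float
    n: int
    #: documented conventions, recorded with every report
    conventions: str = (
        "sample statistics; MBE = mean(observed - predicted); "
        "Willmott d with per-term squared denominator"
    )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def __str__(self) -> str:
        return (
            f"n    = {self.n}\n"
            f"R2   = {self.r2:.4f}\n"
            f"RMSE = {self.rmse:.4f} mm/day\n"
            f"d    = {self.d:.4f}\n"
            f"NSME = {self.nsme:.4f}\n"
            f"MBE  = {self.mbe:+.4f} mm/day  ({self.conventions})"
        )


def r_squared(pairs: PairedSeries) -> float:
    """Squared Pearson correlation between observed and predicted."""
    y, yhat = pairs.observed, pairs.predicted
    sy, syh = y.std(), yhat.std()
    if sy == 0 or syh == 0:
        raise UndefinedStatisticError("R2 undefined for a constant series")
    cov = ((y - y.mean()) * (yhat - yhat.mean())).mean()
    return float((cov / (sy * syh)) ** 2)


def rmse(pairs: PairedSeries) -> float:
    """Root-mean-square error with an n denominator."""
    return float(np.sqrt(np.mean((pairs.observed - pairs.predicted) ** 2)))


def agreement_index(pairs: PairedSeries) -> float:
    """Willmott's index of agreement d in [0, 1]; 1 is a perfect match.

    d = 1 - sum (y - yhat)^2 / sum (|yhat - ybar| + |y - ybar|)^2
    with ybar the observed mean and the square applied per term.
    """
    y, yhat = pairs.observed, pairs.predicted
    ybar = y.mean()
    denom = float(np.sum((np.abs(yhat - ybar) + np.abs(y - ybar)) ** 2))
    if denom == 0:
        raise UndefinedStatisticError(
            "agreement index undefined: both series constant at the observed mean"
        )
    return float(1.0 - np.sum((y - yhat) ** 2) / denom)


def nsme(pairs: PairedSeries) -> float:
    """Nash-Sutcliffe model efficiency: 1 - SSE / SST; <= 1, 1 iff perfect."""
    y, yhat = pairs.observed, pairs.predicted
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise UndefinedStatisticError("NSME undefined for a constant observed series")
    return float(1.0 - np.sum((y - yhat) ** 2) / sst)


def mbe(pairs: PairedSeries) -> float:
    """Mean bias error: mean(observed - predicted)."""
    return float(np.mean(pairs.observed - pairs.predicted))


def evaluate(pairs: PairedSeries) -> EvalReport:
    """All five statistics on one paired series."""
    return EvalReport(
        r2=r_squared(pairs),
        rmse=rmse(pairs),
        d=agreement_index(pairs),
        nsme=nsme(pairs),
        mbe=mbe(pairs),
        n=pairs.n,
    )


def read_pairs_csv(path: str | Path) -> PairedSeries:
    """Read a paired CSV with columns date, observed_mm_day, predicted_mm_day."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MptetError(f"cannot parse paired CSV {path}: {exc}") from exc
    required = {"observed_mm_day", "predicted_mm_day"}
    if not required.issubset(df.columns):
        raise MptetError(
            f"paired CSV {path} must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    labels = (
        df["date"].astype(str).tolist() if "date" in df.columns else None
    )
    return PairedSeries(
        observed=df["observed_mm_day"].to_numpy(float),
        predicted=df["predicted_mm_day"].to_numpy(float),
        labels=labels,
    )
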