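"""Logistic fitting and binary aggregation calls for ThT time series.

Thioflavin-T fluorescence rises sigmoidally when a protein aggregates into
amyloid and stays at baseline when it does not.  The experimental readout
used throughout truncation-construct studies is effectively binary —
competent or not — so this module fits a four-parameter logistic

    y(t) = baseline + amplitude / (1 + exp(-k * (t - t50)))

against a constant-only alternative and calls a curve positive when the
fitted amplitude dominates the baseline and the logistic clearly beats the
flat model.  The logistic is the minimal sigmoid with an interpretable
half-time; it is a phenomenological stand-in, not a mechanistic
nucleation-elongation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = ["ThTCurve", "KineticFit", "fit_logistic", "call_aggregation",
           "logistic"]


def logistic(t: np.ndarray, baseline: float, amplitude: float,
             t50: float, rate_k: float) -> np.ndarray:
    # expit form of baseline + amplitude / (1 + exp(-k (t - t50))),
    # overflow-safe for extreme rate parameters during optimisation
    return baseline + amplitude * expit(rate_k * (t - t50))


@dataclass
class ThTCurve:
    """A fluorescence time series (hours, arbitrary units)."""

    time: np.ndarray
    fluorescence: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_h": self.time,
                      "fluorescence_au": self.fluorescence}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **metadata) -> "ThTCurve":
        df = pd.read_csv(path)
        return cls(time=df["time_h"].to_numpy(),
                   fluorescence=df["fluorescence_au"].to_numpy(),
                   metadata=metadata)


@dataclass(frozen=True)
class KineticFit:
    baseline: float
    amplitude: float
    t50: float
    rate_k: float
    rss_logistic: float
    rss_flat: float
    converged: bool
    positive: bool

    def to_dict(self) -> dict:
        return {"baseline": self.baseline, "amplitude": self.amplitude,
                "t50": self.t50, "rate_k": self.rate_k,
                "rss_logistic": self.rss_logistic, "rss_flat": self.rss_flat,
                "converged": self.converged, "positive": self.positive}


def fit_logistic(curve: ThTCurve,
                 min_fold_amplitude: float = 3.0,
                 min_rss_improvement: float = 0.5) -> KineticFit:
    """Least-squares logistic fit with a deterministic initialisation.

    Initialisation: baseline = first decile of the signal, amplitude =
    signal range, t50 = first time the signal crosses half-range above
    baseline, k = 1 /h.  t50 is bounded inside the observed time window and
    amplitude kept non-negative, so a positive fit always has its half-time
    within the data.  On non-convergence the fit is flagged and falls back
    to the flat model (rss_logistic = rss_flat, never positive).
    """
    t, y = curve.time, curve.fluorescence
    if len(t) < 10:
        raise ValueError("need at least 10 points to fit")
    rss_flat = float(np.sum((y - y.mean()) ** 2))

    b0 = float(np.quantile(y, 0.10))
    a0 = float(y.max() - y.min())
    half = b0 + a0 / 2.0
    crossing = np.nonzero(y >= half)[0]
    t50_0 = float(t[crossing[0]]) if len(crossing) else float(np.median(t))
    t50_0 = float(np.clip(t50_0, t[0], t[-1]))
    p0 = [b0, max(a0, 1e-9), t50_0, 1.0]
    bounds = ([-np.inf, 0.0, float(t[0]), 1e-9],
              [np.inf, np.inf, float(t[-1]), np.inf])
    try:
        popt, _ = curve_fit(logistic, t, y, p0=p0, bounds=bounds,
                            maxfev=20000)
        rss_log = float(np.sum((y - logistic(t, *popt)) ** 2))
        converged = True
    except (RuntimeError, ValueError):
        popt = p0
        rss_log = rss_flat
        converged = False

    fit = KineticFit(baseline=float(popt[0]), amplitude=float(popt[1]),
                     t50=float(popt[2]), rate_k=float(popt[3]),
                     rss_logistic=rss_log, rss_flat=rss_flat,
                     converged=converged, positive=False)
    positive = converged and call_aggregation(
        fit, min_fold_amplitude=min_fold_amplitude,
        min_rss_improvement=min_rss_improvement)
    return KineticFit(**{**fit.to_dict(), "positive": positive})


def call_aggregation(fit: KineticFit,
                     min_fold_amplitude: float = 3.0,
                     min_rss_improvement: float = 0.5) -> bool:
    """Binary competent / not-competent call on a fitted curve.

    Positive iff the fitted amplitude is at least ``min_fold_amplitude``
    times the baseline AND the logistic residual sum of squares is at most
    ``min_rss_improvement`` times the flat-model RSS.
    """
    return (fit.amplitude >= min_fold_amplitude * fit.baseline
            and fit.rss_logistic <= min_rss_improvement * fit.rss_flat)
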