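"""Prediction-based external-evaluation diagnostics.

PE% = (PRED - OBS)/OBS * 100 per observation, summarised as the median
prediction error (MDPE, accuracy), median absolute prediction error
(MAPE, precision) and the fractions of errors within +/-20% (F20) and
+/-30% (F30).  A model's external predictive ability is conventionally
called satisfactory when MDPE is within +/-15%, MAPE <= 30%, F20 > 35%
and F30 > 50%; all four must hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PESummary",
    "CriteriaVerdict",
    "prediction_errors",
    "summarize_pe",
    "check_criteria",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class PESummary:
    """Summary statistics of a list of prediction errors (all in %)."""

    mdpe: float
    mape: float
    f20: float
    f30: float
    n: int
    pe_values: tuple

    def as_dict(self) -> dict:
        return {"mdpe": self.mdpe, "mape": self.mape,
                "f20": self.f20, "f30": self.f30, "n": self.n}


@dataclass(frozen=True)
class CriteriaVerdict:
    """Four-threshold acceptability verdict; ``overall`` is the conjunction."""

    pass_mdpe: bool
    pass_mape: bool
    pass_f20: bool
    pass_f30: bool

    @property
    def overall(self) -> bool:
        return (self.pass_mdpe and self.pass_mape
                and self.pass_f20 and self.pass_f30)

    def as_dict(self) -> dict:
        return {"pass_mdpe": self.pass_mdpe, "pass_mape": self.pass_mape,
                "pass_f20": self.pass_f20, "pass_f30": self.pass_f30,
                "overall": self.overall}


def prediction_errors(pred, obs) -> np.ndarray:
    """Relative prediction errors in percent: (pred - obs)/obs * 100.

    ``pred`` and ``obs`` must have equal length and all observations must
    be strictly positive.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"pred and obs lengths differ: {pred.shape} vs {obs.shape}")
    if np.any(obs <= 0):
        raise ValueError("observations must be strictly positive")
    return (pred - obs) / obs * 100.0


def summarize_pe(pe) -> PESummary:
    """Summarise PE% values.  Median of an even-length list is the mean of
    the two central order statistics; ties exactly at the 20/30 boundary
    count as within."""
    pe = np.asarray(pe, dtype=float)
    if pe.size == 0:
        raise ValueError("cannot summarise an empty list of prediction errors")
    abs_pe = np.abs(pe)
    return PESummary(
        mdpe=float(np.median(pe)),
        mape=float(np.median(abs_pe)),
        f20=float(100.0 * np.mean(abs_pe <= 20.0)),
        f30=float(100.0 * np.mean(abs_pe <= 30.0)),
        n=int(pe.size),
        pe_values=tuple(float(x) for x in pe),
    )


def check_criteria(s: PESummary) -> CriteriaVerdict:
    """Apply the four acceptability thresholds:
    |MDPE| <= 15, MAPE <= 30, F20 > 35, F30 > 50 (all in %)."""
    return CriteriaVerdict(
        pass_mdpe=abs(s.mdpe) <= 15.0,
        pass_mape=s.mape <= 30.0,
        pass_f20=s.f20 > 35.0,
        pass_f30=s.f30 > 50.0,
    )


def evaluate_predictions(pred, obs) -> tuple[PESummary, CriteriaVerdict]:
    """Convenience: PE% -> summary -> verdict in one call."""
    s = summarize_pe(prediction_errors(pred, obs))
    return s, check_criteria(s)
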