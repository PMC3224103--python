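"""Vaporizer calibration regressions.

A vaporizer's delivered concentration at the common gas outlet need not
match its dial setting; the delivery error also drifts with fresh gas
flow (output falls at high flow as the vaporizer cools).  This module
quantifies both: an output-versus-dial line, and linear plus cubic fits
of the percentage performance error against flow.

Calibration is reported, not automatically applied to wash-in
predictions: the empirical wash-in coefficients were estimated against
dial settings, so the mean vaporizer error is already absorbed there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VaporizerMeasurement",
    "LineFit",
    "CubicFit",
    "CalibrationModel",
    "vaporizer_pe",
    "fit_output_line",
    "fit_pe_models",
    "fit_line",
    "fit_cubic",
]


@dataclass(frozen=True)
class VaporizerMeasurement:
    """One (dial, flow, measured output) triple from the common gas outlet."""

    dial: float
    fgf: float
    output: float

    def __post_init__(self) -> None:
        if not self.dial > 0:
            raise ValueError(f"dial must be > 0, got {self.dial!r}")
        if not self.output >= 0:
            raise ValueError(f"output must be >= 0, got {self.output!r}")


@dataclass(frozen=True)
class LineFit:
    intercept: float
    slope: float
    r2: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class CubicFit:
    """Third-order polynomial fit; coefficients in ascending degree order."""

    coef: tuple  # (c0, c1, c2, c3)
    r2: float

    def predict(self, x):
        return np.polynomial.polynomial.polyval(np.asarray(x, float), self.coef)


@dataclass(frozen=True)
class CalibrationModel:
    """Output-vs-dial line plus PE-vs-flow linear and cubic fits."""

    line: LineFit
    pe_line: LineFit
    pe_cubic: CubicFit


def vaporizer_pe(measurement: VaporizerMeasurement) -> float:
    """Vaporizer performance error, % of the dialed concentration.

    PE = 100 * (measured output - dial) / dial.  Undefined at dial 0.
    """
    return float(_pe(measurement.output, measurement.dial))


def _pe(output, dial):
    output = np.asarray(output, dtype=float)
    dial = np.asarray(dial, dtype=float)
    if np.any(dial <= 0):
        raise ValueError("performance error undefined for dial <= 0")
    return 100.0 * (output - dial) / dial


def fit_line(x, y, what: str = "linear") -> LineFit:
    """OLS line with r-squared; needs >= 2 distinct abscissae."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError(
            f"{what} fit failed: regressor is constant (rank-deficient)")
    reg = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(reg.rvalue) else float(reg.rvalue ** 2)
    return LineFit(intercept=float(reg.intercept), slope=float(reg.slope), r2=r2)


def fit_cubic(x, y, what: str = "cubic") -> CubicFit:
    """OLS cubic polynomial with r-squared; needs >= 5 distinct abscissae."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 5:
        raise ValueError(
            f"{what} fit failed: fewer than 5 distinct regressor values")
    coef = np.polynomial.polynomial.polyfit(x, y, deg=3)
    resid = y - np.polynomial.polynomial.polyval(x, coef)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - float(resid @ resid) / tss
    return CubicFit(coef=tuple(coef.tolist()), r2=r2)


def fit_output_line(measurements: Sequence[VaporizerMeasurement]) -> LineFit:
    """OLS of measured output on dial setting."""
    dial = np.array([m.dial for m in measurements])
    output = np.array([m.output for m in measurements])
    return fit_line(dial, output, what="output-vs-dial")


def fit_pe_models(measurements: Sequence[VaporizerMeasurement]
                  ) -> CalibrationModel:
    """Linear and cubic fits of vaporizer PE against fresh gas flow.

    Returns the full :class:`CalibrationModel` including the
    output-vs-dial line.
    """
    fgf = np.array([m.fgf for m in measurements])
    pe = _pe(np.array([m.output for m in measurements]),
             np.array([m.dial for m in measurements]))
    pe_line = fit_line(fgf, pe, what="PE-vs-FGF linear")
    pe_cubic = fit_cubic(fgf, pe, what="PE-vs-FGF cubic")
    return CalibrationModel(line=fit_output_line(measurements),
                            pe_line=pe_line, pe_cubic=pe_cubic)
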