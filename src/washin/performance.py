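"""Prospective-validation statistics: PE, APE, MDPE, MDAPE and flow trends.

Performance is quantified the way target-controlled-infusion systems are
judged: each patient contributes one performance error

    PE = 100 * (F_A measured - F_A predicted) / F_A predicted   (%)

at the group's target time, where the predicted value is the target
concentration the dial equation was asked to reach.  The group medians
MDPE (bias) and MDAPE (accuracy) summarise the cohort, and linear plus
cubic regressions of PE (and APE) against fresh gas flow expose
flow-dependent model misspecification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .calibration import CubicFit, LineFit, fit_cubic, fit_line
from .model import ValidityWarning
from .params import PRINTED_PARAMS, PatientCovariates, WashInModelParams
from .planner import DIAL_MAX, DialSolveError, TargetSpec, round_to_dial, \
    solve_dial
from .synthetic import NoiseModel, measure_fa

__all__ = [
    "PerformanceRecord",
    "PerformanceSummary",
    "performance_error",
    "summarize",
    "run_prospective_trial",
]


@dataclass(frozen=True)
class PerformanceRecord:
    """One patient's prospective-trial outcome."""

    patient_id: str
    fgf: float
    fa_predicted: float   # the target F_At
    fa_measured: float
    pe: float
    ape: float


@dataclass(frozen=True)
class PerformanceSummary:
    """Group medians and PE/APE-vs-flow regression fits."""

    n: int
    mdpe: float
    mdape: float
    pe_vs_fgf_line: Optional[LineFit]
    pe_vs_fgf_cubic: Optional[CubicFit]
    ape_vs_fgf_line: Optional[LineFit]
    ape_vs_fgf_cubic: Optional[CubicFit]


def performance_error(fa_measured: float, fa_predicted: float) -> float:
    """PE (%) of a measured concentration against its prediction."""
    if not fa_predicted > 0:
        raise ValueError(
            f"fa_predicted must be > 0, got {fa_predicted!r}")
    return 100.0 * (fa_measured - fa_predicted) / fa_predicted


def summarize(records: Sequence[PerformanceRecord]) -> PerformanceSummary:
    """MDPE, MDAPE and flow-trend regressions over a group.

    Even-count medians use the mean of the central pair.  The regression
    fits are omitted (None) when the flow spread is insufficient.
    """
    records = list(records)
    if not records:
        raise ValueError("empty performance record list")
    pe = np.array([r.pe for r in records])
    ape = np.array([r.ape for r in records])
    fgf = np.array([r.fgf for r in records])

    def try_fit(fn, x, y, what):
        try:
            return fn(x, y, what=what)
        except ValueError:
            return None

    return PerformanceSummary(
        n=len(records),
        mdpe=float(np.median(pe)),
        mdape=float(np.median(ape)),
        pe_vs_fgf_line=try_fit(fit_line, fgf, pe, "PE-vs-FGF linear"),
        pe_vs_fgf_cubic=try_fit(fit_cubic, fgf, pe, "PE-vs-FGF cubic"),
        ape_vs_fgf_line=try_fit(fit_line, fgf, ape, "APE-vs-FGF linear"),
        ape_vs_fgf_cubic=try_fit(fit_cubic, fgf, ape, "APE-vs-FGF cubic"),
    )


def _default_fgf_sampler(rng: np.random.Generator) -> float:
    # flows on the device's 0.1 L/min grid over the studied range
    return float(rng.choice(np.round(np.arange(0.5, 5.0 + 1e-9, 0.1), 1)))


def run_prospective_trial(fat: float, time_min: float,
                          patients: Sequence[PatientCovariates],
                          params: WashInModelParams = PRINTED_PARAMS,
                          noise: Optional[NoiseModel] = None,
                          seed: int = 0,
                          fgf_sampler: Optional[Callable] = None,
                          dial_rounding: bool = True,
                          dial_max: float = DIAL_MAX,
                          mode: str = "derived",
                          ) -> Tuple[PerformanceSummary, List[PerformanceRecord]]:
    """Simulate one prospective validation group.

    Per patient: draw a fresh gas flow, invert the model for the dial,
    round to the vaporizer's 0.5% resolution (optional), skip patients
    whose required dial exceeds the vaporizer ceiling (those flows cannot
    be tested), simulate the measured F_A at the target time, and score
    PE against the target concentration.  Bit-reproducible given ``seed``.
    """
    if noise is None:
        noise = NoiseModel(sd=0.0, between_patient_cv=0.0)
    if fgf_sampler is None:
        fgf_sampler = _default_fgf_sampler
    rng = np.random.default_rng(seed)
    records: List[PerformanceRecord] = []
    n_skipped = 0
    for i, patient in enumerate(patients):
        fgf = float(fgf_sampler(rng))
        target = TargetSpec(fat=fat, time_min=time_min,
                            height_cm=patient.height_cm, dial_max=dial_max)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ValidityWarning)
                dial = float(solve_dial(fgf, target, params, mode=mode))
        except DialSolveError:
            n_skipped += 1
            continue
        if dial > dial_max:
            n_skipped += 1
            continue
        dial = max(dial, 0.0)
        dial_used = float(round_to_dial(dial)) if dial_rounding else dial
        fa_meas = measure_fa(patient, fgf, dial_used, time_min, params,
                             noise, rng)
        pe = performance_error(fa_meas, fat)
        records.append(PerformanceRecord(
            patient_id=f"p{i:03d}", fgf=fgf, fa_predicted=fat,
            fa_measured=fa_meas, pe=pe, ape=abs(pe)))
    if not records:
        raise ValueError(
            f"all {n_skipped} patients required a dial above the "
            f"{dial_max}% ceiling; nothing to summarise")
    return summarize(records), records
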