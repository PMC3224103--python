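"""Synthetic cohorts, dosing protocols, wash-in series and calibration data.

No raw patient data accompany the published model, so every analysis
stage is exercised against generated data with the statistical structure
the study protocol implies: truncated-normal demographics matching the
derivation cohort, fresh-gas-flow/dial combinations drawn on the device
grids with under-dosing combinations rejected, 10-s concentration
sampling truncated at 8%, and vaporizer calibration points with noise
calibrated to a target r-squared.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .calibration import VaporizerMeasurement
from .fitting import WashInRecord
from .model import predict_fa
from .params import PRINTED_PARAMS, DeliverySettings, PatientCovariates, \
    WashInModelParams

__all__ = [
    "CohortSpec",
    "NoiseModel",
    "sample_cohort",
    "sample_protocol",
    "generate_washin",
    "generate_cohort_records",
    "generate_vaporizer_data",
    "generate_pe_data",
    "measure_fa",
]

#: Protocol exclusion rule: combinations predicted (noise-free, at the
#: reference height) to stay below these concentrations are under-dosing
#: and are redrawn.
MIN_FA_AT_2MIN = 1.0
MIN_FA_AT_5MIN = 2.0

#: Reference height (cm) used for protocol screening: the derivation
#: cohort mean.
HEIGHT_REF = 166.0


@dataclass(frozen=True)
class CohortSpec:
    """Cohort demographics: derivation-group means and SDs by default."""

    n: int
    height_mean: float = 166.0
    height_sd: float = 9.0
    weight_mean: float = 70.0
    weight_sd: float = 14.0
    age_mean: float = 52.0
    age_sd: float = 15.0
    trunc_sd: float = 3.0     # truncation at +/- this many SDs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("height_sd", "weight_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.trunc_sd > 0:
            raise ValueError("trunc_sd must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise plus between-patient uptake variability.

    ``sd`` is the residual sd: absolute % desflurane for ``additive``
    noise, a fraction of the signal for ``multiplicative``.
    ``between_patient_cv`` is the coefficient of variation of a log-normal
    multiplier applied to each patient's rebreathing term — a surrogate
    for the large between-patient spread in agent uptake.
    """

    kind: str = "additive"
    sd: float = 0.25
    between_patient_cv: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "multiplicative"):
            raise ValueError(f"noise kind must be additive|multiplicative, "
                             f"got {self.kind!r}")
        if self.sd < 0 or self.between_patient_cv < 0:
            raise ValueError("sd and between_patient_cv must be >= 0")


def _draw_truncnorm(rng, mean, sd, k, size):
    if sd == 0:
        return np.full(size, mean)
    return stats.truncnorm.rvs(-k, k, loc=mean, scale=sd, size=size,
                               random_state=rng)


def sample_cohort(spec: CohortSpec) -> List[PatientCovariates]:
    """Seeded truncated-normal demographic draws."""
    rng = np.random.default_rng(spec.seed)
    k = spec.trunc_sd
    ht = _draw_truncnorm(rng, spec.height_mean, spec.height_sd, k, spec.n)
    wt = _draw_truncnorm(rng, spec.weight_mean, spec.weight_sd, k, spec.n)
    age = _draw_truncnorm(rng, spec.age_mean, spec.age_sd, k, spec.n)
    return [PatientCovariates(height_cm=float(h), weight_kg=float(w),
                              age_years=float(a))
            for h, w, a in zip(ht, wt, age)]


def _protocol_ok(fgf, dial, params, height_ref) -> bool:
    fa2 = predict_fa(fgf, dial, 2.0, height_ref, params, check_validity=False)
    fa5 = predict_fa(fgf, dial, 5.0, height_ref, params, check_validity=False)
    return bool(fa2 >= MIN_FA_AT_2MIN and fa5 >= MIN_FA_AT_5MIN)


def sample_protocol(n: int, params: WashInModelParams = PRINTED_PARAMS,
                    seed: int = 0,
                    height_ref: float = HEIGHT_REF) -> List[DeliverySettings]:
    """Random fixed FGF - dial combinations on the device grids.

    FGF uniform on {0.5, 0.6, ..., 5.0} L/min; dial uniform on
    {6.0, 6.5, ..., 18.0}%.  Combinations predicted to give less than 1%
    after 2 min or less than 2% after 5 min are rejected and redrawn
    (under-dosing exclusions); the acceptance region is non-empty so the
    loop terminates.
    """
    rng = np.random.default_rng(seed)
    fgf_grid = np.round(np.arange(0.5, 5.0 + 1e-9, 0.1), 1)
    dial_grid = np.round(np.arange(6.0, 18.0 + 1e-9, 0.5), 1)
    out: List[DeliverySettings] = []
    while len(out) < n:
        fgf = float(rng.choice(fgf_grid))
        dial = float(rng.choice(dial_grid))
        if _protocol_ok(fgf, dial, params, height_ref):
            out.append(DeliverySettings(fgf=fgf, dial=dial))
    return out


def _uptake_multiplier(rng, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _noisy(fa_clean: np.ndarray, noise: NoiseModel, rng) -> np.ndarray:
    if noise.sd == 0:
        return fa_clean.copy()
    if noise.kind == "additive":
        out = fa_clean + rng.normal(0.0, noise.sd, size=fa_clean.shape)
    else:
        out = fa_clean * (1.0 + rng.normal(0.0, noise.sd, size=fa_clean.shape))
    return np.clip(out, 0.0, None)


def _series_clean(patient, fgf, dial, t_min, params, mult):
    """Prediction with the patient's uptake multiplier on the rebreathing term."""
    p = params
    reb = (1.0 - np.exp(p.k1 * fgf)) \
        + p.c_reb * (1.0 - np.exp(-p.k2 * fgf)) * p.d_reb * dial
    t_term = p.g_time * (1.0 - np.exp(-np.asarray(t_min, float) / p.tau))
    return (p.a_fgf * fgf + p.scale * reb * mult * t_term) \
        / (p.ht_scale * patient.height_cm)


def measure_fa(patient: PatientCovariates, fgf: float, dial: float,
               time_min: float, params: WashInModelParams,
               noise: NoiseModel, rng: np.random.Generator) -> float:
    """One simulated end-expired measurement at a single time point."""
    mult = _uptake_multiplier(rng, noise.between_patient_cv)
    clean = np.asarray(_series_clean(patient, fgf, dial, time_min, params,
                                     mult), dtype=float)
    return float(_noisy(np.atleast_1d(clean), noise, rng)[0])


def generate_washin(patient: PatientCovariates, settings: DeliverySettings,
                    params: WashInModelParams = PRINTED_PARAMS,
                    noise: Optional[NoiseModel] = None,
                    seed: Optional[int] = None,
                    patient_id: str = "") -> WashInRecord:
    """Simulated 10-s wash-in series for one patient.

    Samples run t = 10, 20, ..., 300 s; the series is truncated at the
    first sample exceeding 8% (the recording would have been terminated
    there).  The record keeps every earlier sample, including the sub-60-s
    ones that the fitting filters later drop.
    """
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    time_s = np.arange(10.0, 300.0 + 1e-9, 10.0)
    mult = _uptake_multiplier(rng, noise.between_patient_cv)
    clean = _series_clean(patient, settings.fgf, settings.dial,
                          time_s / 60.0, params, mult)
    fa = _noisy(clean, noise, rng)
    over = np.nonzero(fa > 8.0)[0]
    if over.size:
        time_s = time_s[:over[0]]
        fa = fa[:over[0]]
    return WashInRecord(patient=patient, settings=settings,
                        time_s=time_s, fa_pct=fa, patient_id=patient_id)


def generate_cohort_records(n: int = 50,
                            params: WashInModelParams = PRINTED_PARAMS,
                            noise: Optional[NoiseModel] = None,
                            seed: int = 0,
                            cohort: Optional[CohortSpec] = None,
                            covariate_effect: bool = True,
                            height_ref: float = HEIGHT_REF
                            ) -> List[WashInRecord]:
    """Full derivation-style dataset: cohort + protocols + wash-in series.

    With ``covariate_effect=False`` the series are generated at the
    reference height for every patient (heights are still recorded),
    giving the null data used to calibrate covariate selection.
    """
    if noise is None:
        noise = NoiseModel()
    ss = np.random.SeedSequence(seed)
    s_cohort, s_protocol, s_series = ss.spawn(3)
    if cohort is None:
        cohort = CohortSpec(n=n, seed=int(s_cohort.generate_state(1)[0] >> 1))
    patients = sample_cohort(cohort)
    protocols = sample_protocol(len(patients), params,
                                seed=int(s_protocol.generate_state(1)[0] >> 1),
                                height_ref=height_ref)
    rng = np.random.default_rng(s_series)
    records = []
    for i, (patient, settings) in enumerate(zip(patients, protocols)):
        gen_patient = patient if covariate_effect else _with_height(
            patient, height_ref)
        rec = generate_washin(gen_patient, settings, params, noise,
                              seed=int(rng.integers(0, 2**31 - 1)),
                              patient_id=f"p{i:03d}")
        # record the true covariates even when they have no effect
        records.append(WashInRecord(patient=patient, settings=settings,
                                    time_s=rec.time_s, fa_pct=rec.fa_pct,
                                    patient_id=rec.patient_id))
    return records


def _with_height(patient: PatientCovariates,
                 height_cm: float) -> PatientCovariates:
    return PatientCovariates(height_cm=height_cm,
                             weight_kg=patient.weight_kg,
                             age_years=patient.age_years)


def _noise_sd_for_r2(signal: np.ndarray, target_r2: float) -> float:
    """Residual sd giving the target r-squared for the realised signal spread.

    r2 = var(signal) / (var(signal) + sd^2)  =>  sd = sd_signal*sqrt((1-r2)/r2)
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    var_sig = float(np.var(signal))
    if var_sig == 0:
        raise ValueError("degenerate regressor spread: signal has no variance")
    return math.sqrt(var_sig * (1.0 - target_r2) / target_r2)


def generate_vaporizer_data(n: int,
                            true_line: Tuple[float, float] = (-0.72, 1.075),
                            target_r2: float = 0.98,
                            fgf_effect: Optional[Sequence[float]] = None,
                            seed: int = 0) -> List[VaporizerMeasurement]:
    """Synthetic (dial, fgf, output) calibration triples.

    Dials are drawn from the integer settings {6, ..., 18}%, flows
    uniformly from [0.5, 5] L/min.  Output follows
    ``intercept + slope*dial``, optionally plus a flow-dependent droop
    given as cubic PE-% coefficients (ascending order), with Gaussian
    noise whose sd is solved so the output-vs-dial OLS attains the target
    r-squared for the realised dial spread.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = np.random.default_rng(seed)
    dial = rng.integers(6, 19, size=n).astype(float)
    fgf = rng.uniform(0.5, 5.0, size=n)
    intercept, slope = true_line
    clean = intercept + slope * dial
    if fgf_effect is not None:
        pe = np.polynomial.polynomial.polyval(fgf, np.asarray(fgf_effect, float))
        clean = clean + dial * pe / 100.0
    sd = _noise_sd_for_r2(clean, target_r2)
    output = np.clip(clean + rng.normal(0.0, sd, size=n), 0.0, None)
    return [VaporizerMeasurement(dial=float(d), fgf=float(f), output=float(o))
            for d, f, o in zip(dial, fgf, output)]


def generate_pe_data(n: int,
                     pe_line: Tuple[float, float] = (4.101, -1.902),
                     target_r2: float = 0.23,
                     seed: int = 0) -> List[VaporizerMeasurement]:
    """Synthetic measurements whose PE follows a line in fresh gas flow.

    PE = intercept + slope*fgf plus Gaussian noise calibrated to the
    target r-squared of the PE-vs-FGF regression; outputs are constructed
    as dial*(1 + PE/100) so :func:`washin.calibration.fit_pe_models`
    recovers the line.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = np.random.default_rng(seed)
    fgf = rng.uniform(0.5, 5.0, size=n)
    dial = rng.integers(6, 19, size=n).astype(float)
    intercept, slope = pe_line
    clean = intercept + slope * fgf
    sd = _noise_sd_for_r2(clean, target_r2)
    pe = clean + rng.normal(0.0, sd, size=n)
    output = np.clip(dial * (1.0 + pe / 100.0), 0.0, None)
    return [VaporizerMeasurement(dial=float(d), fgf=float(f), output=float(o))
            for d, f, o in zip(dial, fgf, output)]
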