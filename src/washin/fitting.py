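"""Estimation of the wash-in coefficients from measured concentration series.

The fitting engine mirrors the original derivation procedure: pool every
usable (patient, sample) pair and minimise the unweighted sum of squared
residuals between measured and predicted F_A with a bounded nonlinear
least-squares optimiser, restarted from jittered initial values.

Two structural redundancies make the full coefficient set unidentifiable
from data: ``scale`` and ``g_time`` enter only as the product
``scale*g_time``, and ``c_reb``/``d_reb`` only as ``c_reb*d_reb``.  The
fitter therefore holds ``g_time`` and ``d_reb`` fixed at their initial
values by default and estimates (a_fgf, scale, k1, k2, c_reb, tau); any
other free/fixed split can be requested.

Covariate parsimony is assessed the way population-PK objective-function
comparisons work: each candidate covariate X multiplies the prediction by
a normalised power factor (X/Xbar)**theta (one extra parameter), and the
drop in the Gaussian -2*log-likelihood, n*log(SSR/n), is compared with the
chi-square(1 df) 5% critical value 3.84.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .params import PRINTED_PARAMS, DeliverySettings, PatientCovariates, \
    WashInModelParams

__all__ = [
    "WashInRecord",
    "WashInModel",
    "WashInResults",
    "FitResult",
    "CovariateSelectionReport",
    "NoUsableObservationsError",
    "fit_model",
    "select_covariates",
    "residual_diagnostics",
]

logger = logging.getLogger(__name__)

#: Samples earlier than this are excluded from fitting (near-zero readings).
MIN_TIME_S = 60.0
#: Samples above this end-expired concentration are excluded from fitting.
MAX_FA_PCT = 8.0
#: A record must contribute at least this many usable samples.
MIN_USABLE_SAMPLES = 3

#: Coefficients estimated by default; g_time and d_reb are scale
#: redundancies and stay fixed.
DEFAULT_FREE = ("a_fgf", "scale", "k1", "k2", "c_reb", "tau")

#: chi-square(1), alpha = 0.05 — the standard objective-function drop
#: required to retain one extra covariate parameter.
MOF_THRESHOLD = 3.84


class NoUsableObservationsError(ValueError):
    """No record retains enough samples after the 60-s and 8% filters."""


@dataclass(frozen=True)
class WashInRecord:
    """One patient's wash-in: fixed settings plus a 10-s F_A series."""

    patient: PatientCovariates
    settings: DeliverySettings
    time_s: np.ndarray
    fa_pct: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        fa = np.asarray(self.fa_pct, dtype=float)
        if t.shape != fa.shape or t.ndim != 1:
            raise ValueError("time_s and fa_pct must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(fa < 0):
            raise ValueError("fa_pct must be non-negative")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "fa_pct", fa)

    @classmethod
    def from_samples(cls, patient, settings, samples, patient_id=""):
        """Build from a list of (time_s, fa_pct) pairs."""
        arr = np.asarray(list(samples), dtype=float).reshape(-1, 2)
        return cls(patient=patient, settings=settings,
                   time_s=arr[:, 0], fa_pct=arr[:, 1], patient_id=patient_id)

    @property
    def samples(self) -> List[Tuple[float, float]]:
        return list(zip(self.time_s.tolist(), self.fa_pct.tolist()))

    def usable_mask(self) -> np.ndarray:
        """Fitting filter: drop samples before 1 min and above 8%."""
        return (self.time_s >= MIN_TIME_S) & (self.fa_pct <= MAX_FA_PCT)

    def n_usable(self) -> int:
        return int(self.usable_mask().sum())


@dataclass
class _Pooled:
    fgf: np.ndarray
    dial: np.ndarray
    t_min: np.ndarray
    ht: np.ndarray
    fa: np.ndarray
    covariate: Optional[np.ndarray]   # per-sample candidate covariate values
    cov_mean: Optional[float]
    record_index: np.ndarray


def _pool(records: Sequence[WashInRecord], covariate: Optional[str],
          height_in_model: bool, height_ref: float) -> _Pooled:
    cols = {k: [] for k in ("fgf", "dial", "t", "ht", "fa", "cov", "idx")}
    kept_means = []
    n_dropped_samples = 0
    n_dropped_records = 0
    for i, rec in enumerate(records):
        mask = rec.usable_mask()
        n_dropped_samples += int((~mask).sum())
        if mask.sum() < MIN_USABLE_SAMPLES:
            n_dropped_records += 1
            continue
        if covariate is not None:
            value = {"age": rec.patient.age_years,
                     "weight": rec.patient.weight_kg,
                     "height": rec.patient.height_cm}[covariate]
            if value is None:
                raise ValueError(
                    f"record {rec.patient_id or i} lacks covariate {covariate!r}"
                )
            if value <= 0:
                raise ValueError(f"covariate {covariate!r} must be > 0 for the "
                                 "power factor")
            kept_means.append(value)
        n = int(mask.sum())
        cols["fgf"].append(np.full(n, rec.settings.fgf))
        cols["dial"].append(np.full(n, rec.settings.dial))
        cols["t"].append(rec.time_s[mask] / 60.0)
        ht = rec.patient.height_cm if height_in_model else height_ref
        cols["ht"].append(np.full(n, ht))
        cols["fa"].append(rec.fa_pct[mask])
        if covariate is not None:
            cols["cov"].append(np.full(n, kept_means[-1]))
        cols["idx"].append(np.full(n, i, dtype=int))
    if n_dropped_samples or n_dropped_records:
        logger.info(
            "fitting filters: dropped %d samples (<60 s or >8%%) and %d "
            "records with fewer than %d usable samples",
            n_dropped_samples, n_dropped_records, MIN_USABLE_SAMPLES,
        )
    if not cols["fa"]:
        raise NoUsableObservationsError("no usable observations")
    cat = {k: np.concatenate(v) if v else None for k, v in cols.items()}
    cov_mean = float(np.mean(kept_means)) if covariate is not None else None
    return _Pooled(fgf=cat["fgf"], dial=cat["dial"], t_min=cat["t"],
                   ht=cat["ht"], fa=cat["fa"], covariate=cat["cov"],
                   cov_mean=cov_mean, record_index=cat["idx"])


class WashInModel:
    """Wash-in model bound to a set of patient records.

    Parameters
    ----------
    records : sequence of WashInRecord
        At least two records must survive the usable-sample filters.
    free : tuple of str
        Coefficient names to estimate (default ``DEFAULT_FREE``).
    covariate : str or None
        Candidate covariate ("age", "height", "weight") entering as a
        normalised power factor (X/Xbar)**theta with theta estimated.
    height_in_model : bool
        When False, the structural 1/(ht_scale*Ht) factor uses a fixed
        reference height for every patient (the covariate-free base model
        used in parsimony testing).
    """

    def __init__(self, records: Sequence[WashInRecord],
                 free: Sequence[str] = DEFAULT_FREE,
                 covariate: Optional[str] = None,
                 height_in_model: bool = True,
                 height_ref: float = 166.0):
        records = list(records)
        if len(records) < 2:
            raise ValueError("at least 2 records are required")
        if covariate is not None and covariate not in ("age", "height", "weight"):
            raise ValueError(f"unknown covariate {covariate!r}")
        unknown = set(free) - {f.name for f in dataclasses.fields(WashInModelParams)}
        if unknown:
            raise ValueError(f"unknown coefficient names: {sorted(unknown)}")
        self.records = records
        self.free = tuple(free)
        self.covariate = covariate
        self.height_in_model = height_in_model
        self.height_ref = float(height_ref)
        self.data = _pool(records, covariate, height_in_model, height_ref)
        if len(np.unique(self.data.record_index)) < 2:
            raise ValueError("at least 2 records with usable samples are required")

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "WashInModel":
        """Build from a long-format records DataFrame (see io.read_records)."""
        from .io import records_from_frame

        return cls(records_from_frame(df), **kwargs)

    # -- prediction ----------------------------------------------------

    def _params_from_vector(self, x: np.ndarray,
                            base: WashInModelParams) -> WashInModelParams:
        merged = {**base.to_dict(), **dict(zip(self.free, x[:len(self.free)]))}
        # lumped constants follow the structural coefficients during fitting
        merged["k_lump1"] = merged["scale"] * merged["g_time"]
        merged["k_lump2"] = merged["k_lump1"] * merged["c_reb"] * merged["d_reb"]
        return WashInModelParams(**merged)

    def _predict(self, x: np.ndarray, base: WashInModelParams) -> np.ndarray:
        d = self.data
        p = self._params_from_vector(x, base)
        reb = (1.0 - np.exp(p.k1 * d.fgf)) \
            + p.c_reb * (1.0 - np.exp(-p.k2 * d.fgf)) * p.d_reb * d.dial
        fa = (p.a_fgf * d.fgf
              + p.scale * reb * p.g_time * (1.0 - np.exp(-d.t_min / p.tau))) \
            / (p.ht_scale * d.ht)
        if self.covariate is not None:
            theta = x[len(self.free)]
            fa = fa * (d.covariate / d.cov_mean) ** theta
        return fa

    # -- fitting -------------------------------------------------------

    def fit(self, init: WashInModelParams = PRINTED_PARAMS,
            bounds: Optional[Dict[str, Tuple[float, float]]] = None,
            n_restarts: int = 10, seed: int = 0,
            max_nfev: Optional[int] = None) -> "WashInResults":
        """Bounded nonlinear least squares with jittered multi-start.

        Restart 0 starts from ``init``; subsequent restarts jitter each
        free coefficient log-uniformly within +/-30%.  The best SSR across
        restarts wins.  Deterministic given ``seed``.
        """
        if n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        x0 = np.array([getattr(init, name) for name in self.free], dtype=float)
        default_bounds = {name: (1e-8, 10.0 * abs(getattr(init, name)))
                          for name in self.free}
        if bounds:
            default_bounds.update(bounds)
        lo = np.array([default_bounds[n][0] for n in self.free])
        hi = np.array([default_bounds[n][1] for n in self.free])
        if self.covariate is not None:
            x0 = np.append(x0, 0.0)          # power exponent theta
            lo = np.append(lo, -5.0)
            hi = np.append(hi, 5.0)

        fa = self.data.fa

        def residual(x):
            return self._predict(x, init) - fa

        rng = np.random.default_rng(seed)
        best = None
        best_cost = np.inf
        history = []
        n_used = 0
        for r in range(n_restarts):
            start = x0.copy()
            if r > 0:
                jitter = np.exp(rng.uniform(np.log(0.7), np.log(1.3),
                                            size=len(self.free)))
                start[:len(self.free)] = np.clip(x0[:len(self.free)] * jitter,
                                                 lo[:len(self.free)],
                                                 hi[:len(self.free)])
                if self.covariate is not None:
                    start[-1] = rng.uniform(-0.3, 0.3)
            try:
                res = optimize.least_squares(
                    residual, start, bounds=(lo, hi), method="trf",
                    max_nfev=max_nfev,
                )
            except Exception as exc:  # numerical failure in one restart
                logger.warning("restart %d failed: %s", r, exc)
                continue
            n_used += 1
            history.append(float(2 * res.cost))
            if 2 * res.cost < best_cost:
                best_cost = 2 * res.cost
                best = res
        if best is None:
            raise RuntimeError("all optimizer restarts failed")
        resid = best.fun
        params = self._params_from_vector(best.x, init)
        theta = float(best.x[len(self.free)]) if self.covariate else None
        bse = self._standard_errors(best, resid)
        return WashInResults(
            model=self, params=params, theta=theta,
            ssr=float(resid @ resid), n_obs=int(fa.size),
            residuals=resid.copy(), converged=bool(best.status > 0),
            n_restarts_used=n_used, seed=seed, bse=bse,
            restart_costs=history,
        )

    def _standard_errors(self, res, resid) -> Dict[str, float]:
        # Gauss-Newton covariance sigma^2 (J'J)^-1 at the optimum.
        names = list(self.free) + (["theta"] if self.covariate else [])
        n, p = resid.size, res.x.size
        if n <= p:
            return {k: float("nan") for k in names}
        sigma2 = float(resid @ resid) / (n - p)
        jtj = res.jac.T @ res.jac
        try:
            cov = sigma2 * np.linalg.pinv(jtj)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
        return dict(zip(names, se.tolist()))


@dataclass
class WashInResults:
    """Fit results: coefficient estimates, uncertainty, and diagnostics."""

    model: WashInModel
    params: WashInModelParams
    theta: Optional[float]
    ssr: float
    n_obs: int
    residuals: np.ndarray
    converged: bool
    n_restarts_used: int
    seed: int
    bse: Dict[str, float]
    restart_costs: List[float] = field(default_factory=list)

    def minus2ll(self) -> float:
        """Gaussian -2*log-likelihood up to an additive constant."""
        return self.n_obs * math.log(self.ssr / self.n_obs)

    def residual_diagnostics(self) -> Dict[str, Tuple[float, float]]:
        """OLS slope and r-squared of residuals against each covariate."""
        return residual_diagnostics(self)

    def summary(self) -> str:
        lines = [
            "Wash-in model fit",
            "=" * 46,
            f"{'n observations':<24}{self.n_obs}",
            f"{'n records':<24}{len(self.model.records)}",
            f"{'SSR (%^2)':<24}{self.ssr:.6g}",
            f"{'residual sd (%)':<24}{math.sqrt(self.ssr / self.n_obs):.4g}",
            f"{'converged':<24}{self.converged}",
            f"{'restarts used':<24}{self.n_restarts_used}",
            "-" * 46,
            f"{'coef':<10}{'estimate':>14}{'std err':>14}",
        ]
        for name in self.model.free:
            est = getattr(self.params, name)
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:<10}{est:>14.5g}{se:>14.3g}")
        if self.theta is not None:
            lines.append(f"{'theta':<10}{self.theta:>14.5g}"
                         f"{self.bse.get('theta', float('nan')):>14.3g}")
        lines.append("-" * 46)
        lines.append(f"fixed: " + ", ".join(
            f"{n}={getattr(self.params, n):g}"
            for n in ("g_time", "d_reb", "ht_scale")
            if n not in self.model.free))
        return "\n".join(lines)


#: Alias matching the domain vocabulary for the fit container.
FitResult = WashInResults


def fit_model(records: Sequence[WashInRecord],
              init: WashInModelParams = PRINTED_PARAMS,
              bounds=None, n_restarts: int = 10, seed: int = 0,
              **kwargs) -> WashInResults:
    """Functional wrapper: pooled SSR fit of the wash-in coefficients."""
    return WashInModel(records, **kwargs).fit(
        init=init, bounds=bounds, n_restarts=n_restarts, seed=seed)


@dataclass(frozen=True)
class CandidateResult:
    delta_objective: Optional[float]
    selected: bool
    theta: Optional[float]
    error: Optional[str] = None


@dataclass(frozen=True)
class CovariateSelectionReport:
    """Per-candidate objective-function drops and selection flags."""

    entries: Dict[str, CandidateResult]
    threshold: float
    base_minus2ll: float

    @property
    def selected(self) -> List[str]:
        return [k for k, v in self.entries.items() if v.selected]


def select_covariates(records: Sequence[WashInRecord],
                      base_params: WashInModelParams = PRINTED_PARAMS,
                      candidates: Sequence[str] = ("age", "height", "weight"),
                      threshold: float = MOF_THRESHOLD,
                      n_restarts: int = 3, seed: int = 0,
                      height_ref: float = 166.0) -> CovariateSelectionReport:
    """Nested-model covariate parsimony test.

    The base model carries no patient covariate (the height prefactor is
    evaluated at a fixed reference height).  Each candidate extends the
    base with a normalised power factor (X/Xbar)**theta and is retained
    when the -2*log-likelihood falls by more than ``threshold``
    (chi-square, 1 df).  Per-candidate failures are recorded without
    aborting the others.
    """
    base = WashInModel(records, covariate=None, height_in_model=False,
                       height_ref=height_ref).fit(
        init=base_params, n_restarts=n_restarts, seed=seed)
    entries: Dict[str, CandidateResult] = {}
    for cand in candidates:
        try:
            ext = WashInModel(records, covariate=cand, height_in_model=False,
                              height_ref=height_ref).fit(
                init=base_params, n_restarts=n_restarts, seed=seed + 1)
            delta = base.minus2ll() - ext.minus2ll()
            entries[cand] = CandidateResult(
                delta_objective=delta, selected=bool(delta > threshold),
                theta=ext.theta)
        except Exception as exc:
            entries[cand] = CandidateResult(
                delta_objective=None, selected=False, theta=None,
                error=str(exc))
    return CovariateSelectionReport(entries=entries, threshold=threshold,
                                    base_minus2ll=base.minus2ll())


def residual_diagnostics(fit: WashInResults,
                         records: Optional[Sequence[WashInRecord]] = None
                         ) -> Dict[str, Tuple[float, float]]:
    """Regress fit residuals on age, height and weight.

    Returns ``{covariate: (slope, r_squared)}`` over pooled samples; a
    constant covariate yields (0, 0) with a warning.
    """
    if records is None:
        records = fit.model.records
    idx = fit.model.data.record_index
    out: Dict[str, Tuple[float, float]] = {}
    getters = {"age": lambda r: r.patient.age_years,
               "height": lambda r: r.patient.height_cm,
               "weight": lambda r: r.patient.weight_kg}
    for name, get in getters.items():
        values = np.array([np.nan if get(records[i]) is None else get(records[i])
                           for i in idx], dtype=float)
        ok = np.isfinite(values)
        if ok.sum() < 2 or np.ptp(values[ok]) == 0:
            warnings.warn(f"covariate {name!r} is constant or missing; "
                          "r^2 reported as 0", UserWarning, stacklevel=2)
            out[name] = (0.0, 0.0)
            continue
        resid = fit.residuals[ok]
        if np.allclose(resid, resid[0]):
            out[name] = (0.0, 0.0)
            continue
        reg = stats.linregress(values[ok], resid)
        out[name] = (float(reg.slope), float(reg.rvalue ** 2))
    return out
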