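"""Forward evaluation of the empirical wash-in equation.

All functions are vectorised over numpy arrays and return scalars for
scalar inputs.
"""

from __future__ import annotations

import warnings

import numpy as np

from .params import DERIVATION_DOMAIN, PRINTED_PARAMS, DeliverySettings, \
    PatientCovariates, WashInModelParams

__all__ = [
    "ValidityWarning",
    "rebreathing_factor",
    "washin_time_fraction",
    "predict_fa",
    "predict_series",
]


class ValidityWarning(UserWarning):
    """Inputs outside the empirical derivation domain (extrapolation)."""


def _as_finite(name, x):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return arr


def rebreathing_factor(fgf, dial, params: WashInModelParams = PRINTED_PARAMS):
    """Empirical rebreathing factor R(FGF, F_D).

    R = (1 - exp(k1*FGF)) + c_reb*(1 - exp(-k2*FGF))*d_reb*F_D

    The first term is negative for FGF > 0 (the source writes its exponent
    as the double negative ``-FGF*-k1``); it makes F_A fall again at high
    flows, mimicking reduced vaporizer output from cooling.  R may be
    negative at high flow with a low dial.
    """
    fgf = _as_finite("fgf", fgf)
    dial = _as_finite("dial", dial)
    if np.any(fgf < 0) or np.any(dial < 0):
        raise ValueError("fgf and dial must be non-negative")
    p = params
    out = (1.0 - np.exp(p.k1 * fgf)) \
        + p.c_reb * (1.0 - np.exp(-p.k2 * fgf)) * p.d_reb * dial
    return out[()] if out.ndim == 0 else out


def washin_time_fraction(time_min, params: WashInModelParams = PRINTED_PARAMS):
    """Exponential wash-in fraction 1 - exp(-t/tau), in [0, 1)."""
    t = _as_finite("time_min", time_min)
    if np.any(t < 0):
        raise ValueError("time_min must be non-negative")
    out = 1.0 - np.exp(-t / params.tau)
    return out[()] if out.ndim == 0 else out


def _check_domain(fgf, dial, time_min, fa):
    dom = DERIVATION_DOMAIN
    msgs = []
    if np.any(fgf < dom["fgf"][0]) or np.any(fgf > dom["fgf"][1]):
        msgs.append(f"fgf outside {dom['fgf']} L/min")
    if np.any(dial > dom["dial"][1]):
        msgs.append(f"dial above {dom['dial'][1]}%")
    if np.any(time_min < dom["time_min"][0]) or np.any(time_min > dom["time_min"][1]):
        msgs.append(f"time outside {dom['time_min']} min")
    if np.any(fa > dom["fa_max"]):
        msgs.append(f"predicted F_A above {dom['fa_max']}%")
    if msgs:
        warnings.warn(
            "outside model derivation domain (" + "; ".join(msgs)
            + "); prediction is an extrapolation",
            ValidityWarning,
            stacklevel=3,
        )


def predict_fa(fgf, dial, time_min, height_cm,
               params: WashInModelParams = PRINTED_PARAMS,
               check_validity: bool = True):
    """Predicted end-expired agent concentration F_A (%).

    F_A = 1/(ht_scale*Ht) * (a_fgf*FGF
          + scale * R(FGF,F_D) * g_time * (1 - exp(-t/tau)))

    Strictly increasing in dial and time, strictly decreasing in height.
    Note the model does not pass through zero at t = 0: the direct
    fresh-gas term ``a_fgf*FGF`` remains.

    Parameters outside the derivation domain (fgf outside [0.5, 5] L/min,
    time outside [1, 5] min, dial above 18%, or predicted F_A above 8%)
    emit a :class:`ValidityWarning` but are evaluated regardless.
    """
    fgf = _as_finite("fgf", fgf)
    dial = _as_finite("dial", dial)
    t = _as_finite("time_min", time_min)
    ht = _as_finite("height_cm", height_cm)
    if np.any(ht <= 0):
        raise ValueError("height_cm must be > 0")
    if np.any(t < 0):
        raise ValueError("time_min must be non-negative")
    p = params
    reb = (1.0 - np.exp(p.k1 * fgf)) \
        + p.c_reb * (1.0 - np.exp(-p.k2 * fgf)) * p.d_reb * dial
    fa = (p.a_fgf * fgf
          + p.scale * reb * p.g_time * (1.0 - np.exp(-t / p.tau))) \
        / (p.ht_scale * ht)
    if check_validity:
        _check_domain(fgf, dial, t, fa)
    return fa[()] if fa.ndim == 0 else fa


def predict_fa_limit(fgf, dial, height_cm,
                     params: WashInModelParams = PRINTED_PARAMS):
    """Asymptotic (t -> infinity) prediction of the wash-in equation."""
    p = params
    reb = rebreathing_factor(fgf, dial, p)
    return (p.a_fgf * np.asarray(fgf, float) + p.scale * reb * p.g_time) \
        / (p.ht_scale * np.asarray(height_cm, float))


def predict_series(settings: DeliverySettings, patient: PatientCovariates,
                   t_grid_min, params: WashInModelParams = PRINTED_PARAMS,
                   check_validity: bool = True) -> np.ndarray:
    """Predicted F_A series over a sorted, non-negative time grid (minutes)."""
    t = np.asarray(t_grid_min, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("time grid must be finite and non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("time grid must be sorted ascending")
    return np.asarray(predict_fa(settings.fgf, settings.dial, t,
                                 patient.height_cm, params,
                                 check_validity=check_validity))
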