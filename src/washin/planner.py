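"""Closed-form vaporizer-dial planning.

The forward wash-in equation is linear in the dial setting F_D, so it
inverts in closed form: given a target end-expired concentration F_At, a
time by which it must be reached, the patient's height and a chosen fresh
gas flow, :func:`solve_dial` returns the dial to set.  Because the
vaporizer tops out (18% for desflurane), not every flow is feasible;
:func:`min_feasible_fgf` finds the lowest flow that still reaches the
target, which is what minimises agent consumption.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .model import ValidityWarning, predict_fa
from .params import PRINTED_PARAMS, WashInModelParams

__all__ = [
    "TargetSpec",
    "IsoTargetCurve",
    "FaSurface",
    "DialSolveError",
    "solve_dial",
    "round_to_dial",
    "min_feasible_fgf",
    "iso_target_curve",
    "fa_surface",
]

#: Dial resolution of the desflurane vaporizer (%).
DIAL_RESOLUTION = 0.5
#: Dial ceiling of the desflurane vaporizer (%).
DIAL_MAX = 18.0


class DialSolveError(ValueError):
    """The dial equation is unsolvable (degenerate dial coefficient)."""


@dataclass(frozen=True)
class TargetSpec:
    """A planning query: reach ``fat`` % at ``time_min`` minutes."""

    fat: float
    time_min: float
    height_cm: float
    dial_max: float = DIAL_MAX

    def __post_init__(self) -> None:
        if not (0 < self.fat <= 8):
            raise ValueError(f"target F_At must lie in (0, 8]%, got {self.fat!r}")
        if not (1 <= self.time_min <= 5):
            raise ValueError(
                f"time_min must lie in [1, 5] min, got {self.time_min!r}"
            )
        if not self.height_cm > 0:
            raise ValueError("height_cm must be > 0")
        if not self.dial_max > 0:
            raise ValueError("dial_max must be > 0")


def solve_dial(fgf, target: TargetSpec,
               params: WashInModelParams = PRINTED_PARAMS,
               mode: str = "derived"):
    """Dial setting (%) that reaches the target at the chosen flow.

    mode="derived"
        Algebraic inversion of the forward equation (exact round trip):

            F_D = (F_At*ht_scale*Ht - a_fgf*FGF - K1*(1-exp(k1*FGF))*T)
                  / (K2*(1-exp(-k2*FGF))*T),      T = 1 - exp(-t/tau)

        with the unrounded lumped constants K1 = scale*g_time and
        K2 = scale*g_time*c_reb*d_reb.

    mode="printed"
        Verbatim evaluation of the published dial expression, which uses
        the independently rounded lumped constants ``k_lump1``/``k_lump2``
        (40.46 / 39.29 for the reference fit).  Algebraically identical to
        "derived" apart from that rounding; the two agree within 0.15
        dial-% over the derivation domain.

    A negative result means the direct fresh-gas term alone already
    exceeds the target; it is returned with a :class:`ValidityWarning`.
    """
    f = np.asarray(fgf, dtype=float)
    if np.any(~np.isfinite(f)):
        raise ValueError("fgf must be finite")
    if np.any(f <= 0):
        raise DialSolveError("unsolvable: fgf must be > 0 (dial term vanishes)")
    p = params
    t = target.time_min
    big_t = 1.0 - math.exp(-t / p.tau)
    if big_t <= 0:
        raise DialSolveError("unsolvable: time term vanishes at time <= 0")

    if mode == "derived":
        numer = (target.fat * p.ht_scale * target.height_cm
                 - p.a_fgf * f
                 - p.k_lump1_derived * (1.0 - np.exp(p.k1 * f)) * big_t)
        denom = p.k_lump2_derived * (1.0 - np.exp(-p.k2 * f)) * big_t
        if np.any(denom == 0):
            raise DialSolveError("unsolvable: dial coefficient is zero")
        dial = numer / denom
    elif mode == "printed":
        # Verbatim transcription of the published closed-form dial
        # expression (exponents appear as e^(-FGF*-k1) etc. in the source;
        # coded with the signs resolved).
        fat, ht, w = target.fat, target.height_cm, 1.0 - big_t  # w = e^(-t/tau)
        a = np.exp(-p.k1 * f)
        l1, l2 = p.k_lump1, p.k_lump2
        numer = -(np.exp(p.k1 * f + p.k2 * f)
                  * (a * fat * ht * p.ht_scale
                     - a * f * p.a_fgf
                     + l1 - a * l1 + a * w * l1 - w * l1))
        denom = (-1.0 + np.exp(p.k2 * f)) * (-1.0 + w) * l2
        if np.any(denom == 0):
            raise DialSolveError("unsolvable: dial coefficient is zero")
        dial = numer / denom
    else:
        raise ValueError(f"mode must be 'derived' or 'printed', got {mode!r}")
    if np.any(dial < 0):
        warnings.warn(
            "negative dial: target already exceeded by the direct "
            "fresh-gas term at this flow",
            ValidityWarning,
            stacklevel=2,
        )
    return dial[()] if dial.ndim == 0 else dial


def round_to_dial(dial, resolution: float = DIAL_RESOLUTION):
    """Round to the vaporizer's dial resolution; ties round half up."""
    d = np.asarray(dial, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("dial must be finite and >= 0")
    out = np.floor(d / resolution + 0.5) * resolution
    return out[()] if out.ndim == 0 else out


def min_feasible_fgf(target: TargetSpec,
                     params: WashInModelParams = PRINTED_PARAMS,
                     fgf_lo: float = 0.5, fgf_hi: float = 5.0,
                     resolution: float = 0.01,
                     mode: str = "derived") -> Optional[float]:
    """Lowest flow whose required dial stays at or below the ceiling.

    Scans [fgf_lo, fgf_hi] at ``resolution``, refines the feasibility
    boundary by bisection to 1e-4 L/min, and rounds the result up to the
    grid so the reported flow is always feasible.  Returns ``None`` when no
    grid point is feasible (the target cannot be reached at any scanned
    flow with this vaporizer).
    """
    if not fgf_lo < fgf_hi:
        raise ValueError("fgf_lo must be < fgf_hi")
    if not resolution > 0:
        raise ValueError("resolution must be > 0")
    n = int(round((fgf_hi - fgf_lo) / resolution)) + 1
    grid = fgf_lo + resolution * np.arange(n)
    dial = solve_dial(grid, target, params, mode=mode)
    feasible = dial <= target.dial_max
    if not np.any(feasible):
        return None
    idx = int(np.argmax(feasible))
    if idx == 0:
        return float(grid[0])
    lo, hi = float(grid[idx - 1]), float(grid[idx])

    def excess(f):
        return float(solve_dial(f, target, params, mode=mode)) - target.dial_max

    try:
        root = brentq(excess, lo, hi, xtol=1e-4)
    except ValueError:  # no sign change (non-monotone corner); keep grid point
        root = hi
    steps = math.ceil((root - fgf_lo) / resolution - 1e-9)
    return float(fgf_lo + steps * resolution)


@dataclass(frozen=True)
class IsoTargetCurve:
    """FGF - dial combinations that all reach the same target."""

    fat: float
    time_min: float
    height_cm: float
    fgf: np.ndarray
    dial: np.ndarray
    feasible: np.ndarray          # dial <= dial_max, per point
    dial_max: float
    min_feasible_fgf: Optional[float]

    @property
    def points(self) -> List[Tuple[float, float]]:
        return list(zip(self.fgf.tolist(), self.dial.tolist()))


def iso_target_curve(target: TargetSpec,
                     params: WashInModelParams = PRINTED_PARAMS,
                     fgf_grid=None, mode: str = "derived") -> IsoTargetCurve:
    """Iso-target curve: required dial across a flow grid.

    The curve turns upward again near high flows, where the empirical
    flow term reduces delivered agent.  Points whose dial exceeds the
    vaporizer ceiling are flagged infeasible.
    """
    if fgf_grid is None:
        fgf_grid = np.arange(0.5, 5.0 + 1e-9, 0.1)
    grid = np.asarray(fgf_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty fgf grid")
    dial = np.asarray(solve_dial(grid, target, params, mode=mode), dtype=float)
    feasible = dial <= target.dial_max
    mff = min_feasible_fgf(target, params, fgf_lo=float(grid.min()),
                           fgf_hi=float(grid.max()), mode=mode)
    return IsoTargetCurve(
        fat=target.fat, time_min=target.time_min, height_cm=target.height_cm,
        fgf=grid, dial=dial, feasible=feasible, dial_max=target.dial_max,
        min_feasible_fgf=mff,
    )


@dataclass(frozen=True)
class FaSurface:
    """Predicted F_A over the outer product of a flow grid and a dial grid."""

    time_min: float
    height_cm: float
    fgf_grid: np.ndarray
    dial_grid: np.ndarray
    fa_matrix: np.ndarray  # shape (len(fgf_grid), len(dial_grid))

    def to_frame(self):
        """Long-format DataFrame with fgf, dial, fa columns."""
        import pandas as pd

        f, d = np.meshgrid(self.fgf_grid, self.dial_grid, indexing="ij")
        return pd.DataFrame({
            "fgf": f.ravel(), "dial": d.ravel(), "fa": self.fa_matrix.ravel(),
        })


def fa_surface(time_min: float, height_cm: float, fgf_grid, dial_grid,
               params: WashInModelParams = PRINTED_PARAMS) -> FaSurface:
    """Evaluate the forward equation over a flow x dial grid."""
    f = np.asarray(fgf_grid, dtype=float)
    d = np.asarray(dial_grid, dtype=float)
    if f.size == 0 or d.size == 0:
        raise ValueError("grids must be non-empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ValidityWarning)
        fa = predict_fa(f[:, None], d[None, :], time_min, height_cm, params)
    return FaSurface(time_min=float(time_min), height_cm=float(height_cm),
                     fgf_grid=f, dial_grid=d,
                     fa_matrix=np.atleast_2d(np.asarray(fa)))
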