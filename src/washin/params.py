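"""Parameter and data containers for the empirical desflurane wash-in model.

The model predicts the end-expired desflurane concentration F_A (%) during
the first minutes after the vaporizer is turned on in a circle breathing
system, as a function of fresh gas flow (FGF, L/min), vaporizer dial
setting F_D (%), elapsed time (min), and patient height (cm):

    F_A = 1/(ht_scale*Ht) * ( a_fgf*FGF
            + scale * R(FGF, F_D) * g_time * (1 - exp(-t/tau)) )

with the empirical rebreathing factor

    R(FGF, F_D) = (1 - exp(k1*FGF)) + c_reb*(1 - exp(-k2*FGF))*d_reb*F_D.

All concentrations are in volume-%, flows in L/min, times in minutes and
heights in cm.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "WashInModelParams",
    "PatientCovariates",
    "DeliverySettings",
    "PRINTED_PARAMS",
    "DERIVATION_DOMAIN",
]

#: Derivation domain of the empirical model: the range of delivery settings
#: and times over which the coefficients were estimated.  Outside this box
#: predictions are extrapolations and are flagged with a ValidityWarning.
DERIVATION_DOMAIN = {
    "fgf": (0.5, 5.0),     # L/min
    "dial": (6.0, 18.0),   # %
    "time_min": (1.0, 5.0),
    "fa_max": 8.0,         # % — measurements above this were never modelled
}


@dataclass(frozen=True)
class WashInModelParams:
    """Coefficients of the empirical wash-in equation.

    The defaults are the published reference fit for desflurane in O2 on an
    ADU circle system.  ``k_lump1``/``k_lump2`` are the lumped constants of
    the published closed-form dial equation; they equal ``scale*g_time`` and
    ``scale*g_time*c_reb*d_reb`` up to the rounding used when the inverse
    was printed (40.46 vs the unrounded 40.44), and are carried separately
    so the published inverse can be reproduced verbatim.

    Parameters
    ----------
    a_fgf : float
        Direct fresh-gas term coefficient, % per (L/min).
    scale : float
        Global scale of the rebreathing/time term, dimensionless.
    k1 : float
        Flow rate constant of the positive-exponent circuit term, per (L/min).
        The exponent is coded as ``+k1*fgf`` (the source notation writes the
        equivalent double negative ``-FGF*-k1``).
    k2 : float
        Flow rate constant of the dial-coupled term, per (L/min).
    c_reb : float
        Rebreathing multiplier on the dial-coupled term, dimensionless.
    d_reb : float
        Dial weight, per %.
    g_time : float
        Scale of the exponential time term, dimensionless.
    tau : float
        Wash-in time constant, min.
    ht_scale : float
        Height divisor factor, per cm (prediction scales as 1/(ht_scale*Ht)).
    k_lump1, k_lump2 : float
        Printed-inverse lumped constants, %.
    """

    a_fgf: float = 2.55
    scale: float = 1348.0
    k1: float = 0.23
    k2: float = 0.24
    c_reb: float = 2.49
    d_reb: float = 0.39
    g_time: float = 0.03
    tau: float = 4.08
    ht_scale: float = 0.1
    k_lump1: float = 40.46
    k_lump2: float = 39.29

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            object.__setattr__(self, f.name, float(getattr(self, f.name)))
        for name in ("k1", "k2", "tau", "scale", "g_time", "ht_scale",
                     "c_reb", "d_reb"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        if abs(self.k_lump1 * self.c_reb * self.d_reb - self.k_lump2) > 0.011:
            raise ValueError(
                "inconsistent lumped constants: k_lump1*c_reb*d_reb = "
                f"{self.k_lump1 * self.c_reb * self.d_reb:.4f} does not round "
                f"to k_lump2 = {self.k_lump2:.2f}"
            )
        if abs(self.scale * self.g_time - self.k_lump1) > 0.05:
            raise ValueError(
                f"scale*g_time = {self.scale * self.g_time:.4f} disagrees with "
                f"k_lump1 = {self.k_lump1:.4f} by more than 0.05"
            )

    @property
    def k_lump1_derived(self) -> float:
        """Unrounded lumped constant ``scale*g_time`` (%)."""
        return self.scale * self.g_time

    @property
    def k_lump2_derived(self) -> float:
        """Unrounded lumped constant ``scale*g_time*c_reb*d_reb`` (%)."""
        return self.scale * self.g_time * self.c_reb * self.d_reb

    def with_derived_lumped(self) -> "WashInModelParams":
        """Return a copy whose lumped constants equal the structural products.

        Used after fitting, where no independently rounded inverse exists.
        """
        return dataclasses.replace(
            self,
            k_lump1=self.k_lump1_derived,
            k_lump2=self.k_lump2_derived,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WashInModelParams":
        expected = {f.name for f in dataclasses.fields(cls)}
        got = set(d)
        if got - expected:
            raise ValueError(f"unknown parameter keys: {sorted(got - expected)}")
        if expected - got:
            raise ValueError(f"missing parameter keys: {sorted(expected - got)}")
        return cls(**{k: float(v) for k, v in d.items()})


#: The published reference coefficients.
PRINTED_PARAMS = WashInModelParams()


@dataclass(frozen=True)
class PatientCovariates:
    """Patient covariates; only height enters the model."""

    height_cm: float
    weight_kg: Optional[float] = None
    age_years: Optional[float] = None

    def __post_init__(self) -> None:
        if not (120.0 <= self.height_cm <= 220.0):
            raise ValueError(
                f"height_cm must lie in [120, 220], got {self.height_cm!r}"
            )
        for name in ("weight_kg", "age_years"):
            value = getattr(self, name)
            if value is not None and not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class DeliverySettings:
    """One fixed fresh-gas-flow / vaporizer-dial combination.

    ``time_min`` is optional: wash-in records carry their own sample times.
    """

    fgf: float
    dial: float
    time_min: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.fgf) and self.fgf > 0):
            raise ValueError(f"fgf must be finite and > 0, got {self.fgf!r}")
        if not (math.isfinite(self.dial) and self.dial >= 0):
            raise ValueError(f"dial must be finite and >= 0, got {self.dial!r}")

    def in_derivation_domain(self) -> bool:
        """True when (fgf, dial, time) lie inside the derivation box."""
        lo, hi = DERIVATION_DOMAIN["fgf"]
        ok = lo <= self.fgf <= hi
        dlo, dhi = DERIVATION_DOMAIN["dial"]
        ok = ok and dlo <= self.dial <= dhi
        if self.time_min is not None:
            tlo, thi = DERIVATION_DOMAIN["time_min"]
            ok = ok and tlo <= self.time_min <= thi
        return ok
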