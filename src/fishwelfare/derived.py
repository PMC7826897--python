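"""Water-chemistry and morphometric quantities that are calculated, not measured.

Three model parameters cannot be read off an instrument directly and are
derived from routine measurements instead:

* **unionized ammonia** (NH3-N, mg/L) from total ammonia nitrogen (TAN),
  pH and temperature via the freshwater ammonia equilibrium,
  ``pKa = 0.09018 + 2729.92 / T(K)`` (Emerson et al. 1975), with
  ``NH3-N = TAN / (1 + 10^(pKa - pH))``;
* **relative dissolved oxygen** (% saturation) as measured DO over the
  freshwater equilibrium concentration from the Benson-Krause closed form,
  scaled by barometric pressure;
* **Fulton's body condition factor** ``K = 100 * W / L^3`` with weight in g
  and *standard* length (snout to caudal peduncle) in cm.

All functions are pure; display rounding is left to the caller (the
:func:`round_half_up` / :func:`round_sig` helpers match tabular reporting
conventions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "WaterChemInputs",
    "FishMorphometrics",
    "fulton_condition_factor",
    "unionized_ammonia",
    "ammonia_pka",
    "oxygen_saturation",
    "oxygen_solubility",
    "round_half_up",
    "round_sig",
]

_T_MIN, _T_MAX = 0.0, 40.0


@dataclass(frozen=True)
class WaterChemInputs:
    """Raw water-chemistry measurements feeding the derived parameters.

    temperature in deg C (liquid range 0-40), TAN and dissolved oxygen in
    mg/L, barometric pressure in atm (default sea level).
    """

    temperature: float
    pH: float = 7.0
    TAN: float = 0.0
    dissolved_oxygen: float = 0.0
    barometric_pressure: float = 1.0

    def __post_init__(self):
        if not _T_MIN <= self.temperature <= _T_MAX:
            raise ValueError(
                f"temperature {self.temperature} degC outside liquid-water "
                f"range {_T_MIN}-{_T_MAX}"
            )
        if self.TAN < 0:
            raise ValueError("TAN must be >= 0")
        if self.dissolved_oxygen < 0:
            raise ValueError("dissolved_oxygen must be >= 0")
        if self.barometric_pressure <= 0:
            raise ValueError("barometric_pressure must be > 0")


@dataclass(frozen=True)
class FishMorphometrics:
    """Lengths (cm) and weight (g) of one fish."""

    standard_length: float
    total_length: float
    body_weight: float

    def __post_init__(self):
        if self.standard_length <= 0:
            raise ValueError("standard_length must be > 0")
        if self.total_length < self.standard_length:
            raise ValueError("total_length must be >= standard_length")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")


def fulton_condition_factor(m: FishMorphometrics) -> float:
    """Fulton's K = 100 * weight / standard_length**3 (g, cm).

    Standard length is used deliberately: it reproduces reported on-farm
    condition factors that total length does not. K is dimensionless and
    invariant under isometric scaling (length * s, weight * s**3).
    """
    return 100.0 * m.body_weight / m.standard_length**3


def ammonia_pka(temperature_c: float) -> float:
    """Freshwater NH4+/NH3 equilibrium pKa at a temperature in deg C."""
    return 0.09018 + 2729.92 / (273.15 + temperature_c)


def unionized_ammonia(w: WaterChemInputs) -> float:
    """Unionized (toxic) ammonia NH3-N in mg/L, in [0, TAN]."""
    pka = ammonia_pka(w.temperature)
    return w.TAN / (1.0 + 10.0 ** (pka - w.pH))


# Benson-Krause (1984) freshwater O2 solubility, mg/L, T in kelvin.
_BK = (-139.34411, 1.575701e5, -6.642308e7, 1.243800e10, -8.621949e11)


def oxygen_solubility(temperature_c: float, barometric_pressure: float = 1.0) -> float:
    """Equilibrium DO concentration C_eq (mg/L) in fresh water.

    Benson-Krause closed form at 1 atm moist air, corrected for barometric
    pressure via the standard (P - p_wv) / (1 - p_wv) factor, where p_wv is
    the water vapour pressure in atm.
    """
    if not _T_MIN <= temperature_c <= _T_MAX:
        raise ValueError(f"temperature {temperature_c} degC out of range")
    t = 273.15 + temperature_c
    a0, a1, a2, a3, a4 = _BK
    c_1atm = math.exp(a0 + a1 / t + a2 / t**2 + a3 / t**3 + a4 / t**4)
    # vapour pressure of water (atm), Benson-Krause companion fit
    p_wv = math.exp(11.8571 - 3840.70 / t - 216961.0 / t**2)
    return c_1atm * (barometric_pressure - p_wv) / (1.0 - p_wv)


def oxygen_saturation(w: WaterChemInputs) -> float:
    """Relative dissolved oxygen: 100 * DO / C_eq(T, P), in percent."""
    return 100.0 * w.dissolved_oxygen / oxygen_solubility(
        w.temperature, w.barometric_pressure
    )


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero to a fixed number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to a number of significant figures (half-up)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round_half_up(x, sig - 1 - exp)
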