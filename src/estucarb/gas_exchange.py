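"""Air-sea CO2 exchange: dry-fraction corrections, fluxes, DIC budgets.

Underway systems measure the dry-air CO2 mole fraction xCO2 (ppm); the
in-situ partial pressure follows from the barometric pressure minus the
seawater vapor pressure, and a temperature correction moves the
equilibrator value to sea surface temperature.  The flux is

    F_CO2 = C2 * k * K0 * (pCO2_water - pCO2_air)

with k the wind-speed-parameterised gas transfer velocity (Ho et al.
2006 quadratic, Schmidt-number normalised), K0 the CO2 solubility and
C2 the wind-distribution (second moment) enhancement.  Negative flux =
uptake by the water.  Units: fluxes in mmol m-2 d-1, k internally in
m d-1, pCO2 in uatm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import _k0_weiss  # CO2 solubility, mol kg-1 atm-1

__all__ = [
    "UnderwayRecord", "FluxResult", "vapor_pressure", "pco2_from_dry",
    "correct_to_sst", "schmidt_number", "gas_transfer_velocity",
    "c2_from_wind", "co2_flux", "flux_to_dic", "process_underway",
]


@dataclass(frozen=True)
class UnderwayRecord:
    """One underway observation (pressures in atm, xCO2 in dry ppm)."""

    timestamp: object
    xCO2_eq: float
    T_eq: float
    SST: float
    S: float
    P_b: float
    wind: float
    xCO2_air: float

    def __post_init__(self):
        if self.P_b <= 0:
            raise ValueError("barometric pressure must be > 0")


def vapor_pressure(T: float, S: float) -> float:
    """Seawater vapor pressure (atm) at 100% humidity; Weiss & Price
    (1980)."""
    TK = T + 273.15
    return math.exp(24.4543 - 67.4509 * (100.0 / TK)
                    - 4.8489 * math.log(TK / 100.0) - 0.000544 * S)


def pco2_from_dry(xCO2: float, P_b: float, *, T: float, S: float) -> float:
    """pCO2 (uatm) from a dry mole fraction (ppm) at barometric pressure
    ``P_b`` (atm), correcting for the vapor pressure of seawater at
    (T, S)."""
    pw = vapor_pressure(T, S)
    if P_b <= pw:
        raise ValueError(
            f"barometric pressure {P_b} atm <= vapor pressure {pw:.4f} atm")
    return xCO2 * (P_b - pw)


def correct_to_sst(pCO2_eq: float, SST: float, T_eq: float) -> float:
    """Move an equilibrator pCO2 to sea surface temperature via the
    empirical 4.3%/degC isochemical correction."""
    return pCO2_eq * math.exp(0.043 * (SST - T_eq))


def schmidt_number(T: float, S: float = 35.0) -> float:
    """Schmidt number of CO2, linearly interpolated in salinity between
    the freshwater and seawater polynomial fits of Wanninkhof (1992)."""
    sea = 2073.1 - 125.62 * T + 3.6276 * T ** 2 - 0.043219 * T ** 3
    fresh = 1911.1 - 118.11 * T + 3.4527 * T ** 2 - 0.041320 * T ** 3
    w = min(max(S / 35.0, 0.0), 1.0)
    return fresh + w * (sea - fresh)


def gas_transfer_velocity(wind: float, T: float, S: float = 35.0,
                          coeff: float = 0.266) -> float:
    """k (m d-1) from 10-m wind speed (m s-1): coeff * u^2 in cm h-1 at
    Sc = 600 (Ho et al. 2006), rescaled by (Sc/600)^-1/2."""
    if wind < 0:
        raise ValueError("wind speed must be >= 0")
    k600_cmh = coeff * wind ** 2
    k_cmh = k600_cmh * (schmidt_number(T, S) / 600.0) ** -0.5
    return k_cmh * 24.0 / 100.0


def c2_from_wind(wind_series) -> float:
    """Wind-distribution enhancement <u^2>/<u>^2 of a quadratic k over a
    wind-speed series."""
    u = np.asarray(wind_series, dtype=float)
    if u.size == 0 or np.mean(u) == 0:
        return 1.0
    return float(np.mean(u ** 2) / np.mean(u) ** 2)


def co2_flux(pCO2_water: float, pCO2_air: float, wind: float,
             S: float, T: float, C2: float = 1.0,
             density: float = 1012.0, k_coeff: float = 0.266) -> float:
    """Air-sea CO2 flux (mmol m-2 d-1); negative = uptake by the water."""
    k = gas_transfer_velocity(wind, T, S, coeff=k_coeff)     # m d-1
    K0 = _k0_weiss(T + 273.15, S)                            # mol kg-1 atm-1
    dp = (pCO2_water - pCO2_air) * 1e-6                      # atm
    return C2 * k * K0 * density * dp * 1000.0               # mmol m-2 d-1


def flux_to_dic(F: float, days: float, depth: float,
                density: float = 1012.09) -> float:
    """Cumulative water-column DIC change (umol kg-1) from a sustained
    flux ``F`` (mmol m-2 d-1) over ``days``, spread over ``depth`` metres
    of water with the given density (kg m-3)."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    return abs(F) * days / depth / density * 1000.0


@dataclass(frozen=True)
class FluxResult:
    """Per-record fluxes plus ensemble aggregates (mean +- sd)."""

    table: pd.DataFrame
    mean_flux: float
    sd_flux: float
    C2: float


def process_underway(records: pd.DataFrame, *, C2: float | None = None,
                     density: float = 1012.0,
                     k_coeff: float = 0.266) -> FluxResult:
    """Compute per-record pCO2(water), pCO2(air) and fluxes for an
    underway table with columns xCO2_eq, T_eq, SST, S, P_b, wind,
    xCO2_air.  The aggregate is the mean of per-record fluxes (not the
    flux of mean pCO2).  ``C2=None`` derives the wind-distribution
    factor from the record's own wind series."""
    need = {"xCO2_eq", "T_eq", "SST", "S", "P_b", "wind", "xCO2_air"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"underway table missing columns {sorted(missing)}")
    c2 = c2_from_wind(records["wind"]) if C2 is None else C2
    rows = []
    for r in records.itertuples():
        p_eq = pco2_from_dry(r.xCO2_eq, r.P_b, T=r.T_eq, S=r.S)
        p_w = correct_to_sst(p_eq, r.SST, r.T_eq)
        p_a = pco2_from_dry(r.xCO2_air, r.P_b, T=r.SST, S=r.S)
        rows.append({
            "pCO2_water": p_w, "pCO2_air": p_a,
            "k": gas_transfer_velocity(r.wind, r.SST, r.S, coeff=k_coeff),
            "F_CO2": co2_flux(p_w, p_a, r.wind, r.S, r.SST, C2=c2,
                              density=density, k_coeff=k_coeff),
        })
    table = pd.DataFrame(rows, index=records.index)
    return FluxResult(table=table,
                      mean_flux=float(table["F_CO2"].mean()),
                      sd_flux=float(table["F_CO2"].std(ddof=1))
                      if len(table) > 1 else 0.0,
                      C2=c2)
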