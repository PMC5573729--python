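"""River-ocean mixing lines, enrichment, and acidification scenarios.

A two-endmember estuary: TA and DIC mix conservatively (linearly in
salinity) between a river and an ocean endmember.  Deviations from the
mixing lines ("excess" TA/DIC) diagnose internal biogeochemistry.
Scenario curves re-equilibrate the ocean endmember with a chosen
atmospheric CO2 level, mix along a salinity grid, optionally add
respiratory CO2, and solve each grid point for pH and the buffer factor
beta_DIC -- exposing the Maximum Estuarine Acidification Zone (MEAZ),
the salinity band where an acid or CO2 addition depresses pH most.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .constants import ConstantOptions, o2_saturation
from .gas_exchange import pco2_from_dry
from .redox_pathways import REACTIONS
from .speciation import WaterParcel, buffer_factors, solve

__all__ = [
    "Endmember", "MixingLine", "fit_mixing_line", "enrichment",
    "apply_preservation_correction", "equilibrate_with_atmosphere",
    "scenario_curves", "acidification_curve", "find_crossover",
    "SUSQUEHANNA", "CHESAPEAKE_OCEAN", "MISSISSIPPI", "GOM_OCEAN",
]


@dataclass(frozen=True)
class Endmember:
    """A river or ocean endmember composition (umol kg-1, uatm)."""

    label: str
    S: float
    TA: float
    DIC: float
    pCO2: float | None = None

    def __post_init__(self):
        if self.S < 0:
            raise ValueError("endmember salinity must be >= 0")
        if self.TA <= 0 or self.DIC <= 0:
            raise ValueError("endmember TA and DIC must be > 0")


# the Chesapeake (Susquehanna) and Mississippi/Gulf-of-Mexico endmembers;
# mixing-line DIC (1115.1) differs from the scenario DIC (1135) for the
# Susquehanna because the two were determined in different ways.
SUSQUEHANNA = Endmember("river", S=0.189, TA=1089.2, DIC=1115.1,
                        pCO2=1514.9)
SUSQUEHANNA_SCENARIO = Endmember("river", S=0.189, TA=1089.2, DIC=1135.0,
                                 pCO2=1514.9)
CHESAPEAKE_OCEAN = Endmember("ocean", S=33.618, TA=2248.4, DIC=2037.9)
MISSISSIPPI = Endmember("river", S=0.1, TA=2400.0, DIC=2430.0, pCO2=1388.9)
GOM_OCEAN = Endmember("ocean", S=36.3, TA=2398.1, DIC=2065.2)


@dataclass(frozen=True)
class MixingLine:
    """property = slope * S + intercept between two endmembers."""

    slope: float       # umol kg-1 per g kg-1
    intercept: float   # umol kg-1
    prop: Literal["TA", "DIC"]

    def __call__(self, S):
        return self.slope * np.asarray(S, dtype=float) + self.intercept


def fit_mixing_line(river: Endmember, ocean: Endmember,
                    prop: Literal["TA", "DIC"]) -> MixingLine:
    """Two-point conservative mixing line of TA or DIC against salinity."""
    if river.S == ocean.S:
        raise ValueError("endmember salinities are equal; no mixing line")
    y_r, y_o = getattr(river, prop), getattr(ocean, prop)
    slope = (y_o - y_r) / (ocean.S - river.S)
    return MixingLine(slope=slope, intercept=y_r - slope * river.S,
                      prop=prop)


def enrichment(parcel_or_df, ta_line: MixingLine,
               dic_line: MixingLine):
    """Observed-minus-conservative (dTA_excess, dDIC_excess).

    Accepts a single :class:`~estucarb.speciation.WaterParcel` (returns a
    tuple) or a DataFrame with columns S, TA, DIC (returns mean +- sd
    rows as a summary dict plus the per-row deltas).
    """
    if isinstance(parcel_or_df, WaterParcel):
        p = parcel_or_df
        return (p.TA - float(ta_line(p.S)), p.DIC - float(dic_line(p.S)))
    df = parcel_or_df
    d = pd.DataFrame({
        "dTA_excess": df["TA"] - ta_line(df["S"]),
        "dDIC_excess": df["DIC"] - dic_line(df["S"]),
    }, index=df.index)
    summary = {
        "dTA_excess": (d["dTA_excess"].mean(), d["dTA_excess"].std(ddof=1)),
        "dDIC_excess": (d["dDIC_excess"].mean(),
                        d["dDIC_excess"].std(ddof=1)),
    }
    return summary, d


def apply_preservation_correction(
        measured: tuple[float, float],
        correction: tuple[float, float]) -> tuple[float, float]:
    """Add a sample-preservation TA correction (value, sd) to a measured
    enrichment (value, sd); uncertainties combine in quadrature."""
    v = measured[0] + correction[0]
    sd = math.hypot(measured[1], correction[1])
    return v, sd


def equilibrate_with_atmosphere(TA: float, S: float, T: float,
                                P: float = 0.0, pCO2_air: float = 384.0,
                                options: ConstantOptions | None = None,
                                ) -> WaterParcel:
    """Solve the parcel that holds alkalinity ``TA`` in equilibrium with
    an atmosphere of ``pCO2_air`` uatm."""
    return solve(S=S, T=T, P=P, TA=TA, pCO2=pCO2_air, options=options)


# ---------------------------------------------------------------------------
# scenario machinery
# ---------------------------------------------------------------------------

RespirationMode = Literal["none", "fixed", "full_o2"]


def _respiration_deltas(S: float, T: float, mode: RespirationMode,
                        fixed_dic: float) -> tuple[float, float]:
    """(dDIC, dTA) added by respiration at grid salinity ``S``."""
    ar = REACTIONS["AR"]
    if mode == "none":
        return 0.0, 0.0
    if mode == "fixed":
        return fixed_dic, fixed_dic * ar.dTA / ar.dDIC
    if mode == "full_o2":
        do2 = o2_saturation(S, T)
        return do2 * ar.dDIC, do2 * ar.dTA
    raise ValueError(f"unknown respiration mode {mode!r}")


def scenario_curves(river: Endmember, ocean: Endmember, *,
                    xco2: float = 396.2, T: float = 25.0,
                    respiration: RespirationMode = "none",
                    respiration_dic: float = 0.0,
                    s_grid: np.ndarray | None = None,
                    options: ConstantOptions | None = None) -> pd.DataFrame:
    """pH(S) and beta_DIC(S) along the river-ocean mixing gradient.

    The ocean endmember is first re-equilibrated with the scenario
    atmosphere (its TA fixed, DIC from ``xco2``): the anthropogenic CO2
    signal enters the estuary only through the ocean endmember, because
    river water is already far above atmospheric pCO2.  River DIC is
    taken as given.  Respiratory CO2, in contrast, is added *after*
    mixing at every salinity (``"fixed"``: a constant DIC addition;
    ``"full_o2"``: complete consumption of the local O2 saturation,
    which grows weakly toward low salinity).

    Returns a DataFrame with columns S, TA, DIC, pH, beta_DIC.
    """
    if s_grid is None:
        s_grid = np.arange(river.S, ocean.S + 1e-9, 0.1)
    pco2_ocean = pco2_from_dry(xco2, 1.0, T=T, S=ocean.S)
    ocean_eq = equilibrate_with_atmosphere(ocean.TA, ocean.S, T,
                                           pCO2_air=pco2_ocean,
                                           options=options)
    ocean_scn = Endmember("ocean", S=ocean.S, TA=ocean.TA, DIC=ocean_eq.DIC)
    ta_line = fit_mixing_line(river, ocean_scn, "TA")
    dic_line = fit_mixing_line(river, ocean_scn, "DIC")

    rows = []
    for S in s_grid:
        ddic, dta = _respiration_deltas(float(S), T, respiration,
                                        respiration_dic)
        ta = float(ta_line(S)) + dta
        dic = float(dic_line(S)) + ddic
        p = solve(S=float(S), T=T, TA=ta, DIC=dic, options=options)
        rows.append({"S": float(S), "TA": ta, "DIC": dic, "pH": p.pH,
                     "beta_DIC": buffer_factors(p).beta_DIC})
    return pd.DataFrame(rows)


def acidification_curve(curves_a: pd.DataFrame,
                        curves_b: pd.DataFrame) -> pd.DataFrame:
    """-dpH(S) between scenario A (reference) and B (perturbed), plus the
    location of its maximum (the MEAZ salinity).

    Both inputs must share the same salinity grid (as produced by
    :func:`scenario_curves`).
    """
    if len(curves_a) != len(curves_b) or \
            not np.allclose(curves_a["S"], curves_b["S"]):
        raise ValueError("scenario curves are on different salinity grids")
    out = pd.DataFrame({"S": curves_a["S"].to_numpy(),
                        "minus_dpH": (curves_a["pH"] - curves_b["pH"])
                        .to_numpy()})
    out.attrs["meaz_salinity"] = float(
        out["S"].iloc[int(out["minus_dpH"].idxmax())])
    out.attrs["max_minus_dpH"] = float(out["minus_dpH"].max())
    return out


def find_crossover(ta_line: MixingLine, dic_line: MixingLine,
                   dic_offset: float | Callable[[float], float] = 0.0,
                   s_max: float | None = None) -> float | None:
    """Salinity where TA:DIC = 1, i.e. the root of
    TA(S) - DIC(S) - offset(S); ``None`` when no crossover exists in
    [0, s_max].  The buffer-factor minimum tracks this point."""
    if callable(dic_offset):
        from scipy.optimize import brentq
        hi = s_max if s_max is not None else 40.0

        def g(S):
            return ta_line(S) - dic_line(S) - dic_offset(S)
        if g(0.0) * g(hi) > 0:
            return None
        return float(brentq(g, 0.0, hi, xtol=1e-10))
    dm = ta_line.slope - dic_line.slope
    if dm == 0.0:
        return None
    s = (dic_line.intercept + dic_offset - ta_line.intercept) / dm
    if s < 0 or (s_max is not None and s > s_max):
        return None
    return s
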