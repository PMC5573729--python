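"""Stoichiometric redox reactions and TA-DIC-pH-Omega pathway traces.

Models the three internal TA/DIC sources of a stratified eutrophic
estuary -- aerobic respiration (AR), sulfate reduction (SR) and CaCO3
dissolution (CD) -- plus the acid-generating oxidation of upward-mixed
reduced species (H2S, NH4+, Mn2+, Fe2+), on Redfield organic matter
(CH2O)106(NH3)16(H3PO4):

    AR:  106 C oxidised per 138 O2; dTA/dDIC = -(16+1)/106
    SR:  per mol H2S produced: +2 DIC, +(2 + 16/53) TA, +16/53 NH3_T
    CD:  CaCO3 + CO2 + H2O -> Ca2+ + 2 HCO3-; dTA/dDIC = 2
    oxidation of any reduced species: -2 TA per mole (2 H+ released)

Every reaction operation updates the conservative fields exactly
(rational stoichiometry) and re-solves the parcel through the
speciation module, so pH and Omega always follow from equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .speciation import WaterParcel, resolve

__all__ = [
    "ReactionSpec", "PathwayTrace", "REACTIONS",
    "aerobic_respiration", "sulfate_reduction", "carbonate_dissolution",
    "close_budget", "oxidize_reduced_species", "mix_parcels",
    "run_sequential_pathway", "run_simultaneous_pathway",
    "denitrification_bound",
]

# Redfield coefficients
_C, _N, _O2_AR = 106.0, 16.0, 138.0


@dataclass(frozen=True)
class ReactionSpec:
    """Per-unit-extent changes of the conservative fields (umol kg-1 per
    umol kg-1 of extent; the extent variable differs per reaction and is
    given in ``extent``)."""

    name: str
    extent: str        # what one unit of extent is
    dO2: float
    dDIC: float
    dTA: float
    dH2S_T: float = 0.0
    dNH3_T: float = 0.0


#: the reaction table; AR extent is O2 consumed, SR extent is H2S produced,
#: CD extent is TA produced, oxidation extents are moles oxidised.
REACTIONS: dict[str, ReactionSpec] = {
    "AR": ReactionSpec("AR", "O2 consumed", dO2=-1.0,
                       dDIC=_C / _O2_AR, dTA=-(_N + 1.0) / _O2_AR),
    "SR": ReactionSpec("SR", "H2S produced", dO2=0.0,
                       dDIC=2.0, dTA=2.0 + _N / 53.0,
                       dH2S_T=1.0, dNH3_T=_N / 53.0),
    "CD": ReactionSpec("CD", "TA produced", dO2=0.0, dDIC=0.5, dTA=1.0),
    "DEN": ReactionSpec("DEN", "DIC produced", dO2=0.0,
                        dDIC=1.0, dTA=(84.8 + _N - 1.0) / _C),
    "OX_H2S": ReactionSpec("OX_H2S", "H2S oxidised", dO2=-2.0,
                           dDIC=0.0, dTA=-2.0, dH2S_T=-1.0),
    "OX_NH4": ReactionSpec("OX_NH4", "NH4+ oxidised", dO2=-2.0,
                           dDIC=0.0, dTA=-2.0, dNH3_T=-1.0),
    "OX_MN": ReactionSpec("OX_MN", "Mn2+ oxidised", dO2=-0.5,
                          dDIC=0.0, dTA=-2.0),
    "OX_FE": ReactionSpec("OX_FE", "Fe2+ oxidised", dO2=-0.25,
                          dDIC=0.0, dTA=-2.0),
}


class PathwayTrace:
    """Ordered loci of (step, O2, DIC, TA, pH, Omega_arag) along a
    simulated pathway, with exact cumulative deltas."""

    def __init__(self, initial: WaterParcel):
        self._records: list[dict] = []
        self.initial = initial
        self._append("initial", initial)

    def _append(self, label: str, parcel: WaterParcel) -> None:
        self._records.append({
            "step": label,
            "O2": parcel.O2,
            "DIC": parcel.DIC,
            "TA": parcel.TA,
            "pH": parcel.pH,
            "omega_arag": parcel.omega_arag,
        })

    @property
    def final(self) -> dict:
        return self._records[-1]

    @property
    def cumulative_dDIC(self) -> float:
        return self._records[-1]["DIC"] - self._records[0]["DIC"]

    @property
    def cumulative_dTA(self) -> float:
        return self._records[-1]["TA"] - self._records[0]["TA"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self._records)
        df["dDIC"] = df["DIC"] - df["DIC"].iloc[0]
        df["dTA"] = df["TA"] - df["TA"].iloc[0]
        return df

    def __len__(self) -> int:
        return len(self._records)


def _apply(parcel: WaterParcel, spec: ReactionSpec,
           extent: float) -> WaterParcel:
    dO2 = spec.dO2 * extent if parcel.O2 is not None else 0.0
    return resolve(parcel,
                   dTA=spec.dTA * extent, dDIC=spec.dDIC * extent,
                   dH2S=spec.dH2S_T * extent, dNH3=spec.dNH3_T * extent,
                   dO2=dO2)


# ---------------------------------------------------------------------------
# single reactions
# ---------------------------------------------------------------------------

def aerobic_respiration(parcel: WaterParcel,
                        dO2_consumed: float) -> WaterParcel:
    """Respire organic matter consuming ``dO2_consumed`` umol kg-1 of O2
    (DIC +106/138 per O2, TA -17/138 per O2)."""
    if dO2_consumed < 0:
        raise ValueError("dO2_consumed must be >= 0")
    if parcel.O2 is not None and dO2_consumed > parcel.O2 + 1e-9:
        raise ValueError(
            f"cannot consume {dO2_consumed} umol kg-1 O2; only "
            f"{parcel.O2} present")
    return _apply(parcel, REACTIONS["AR"], dO2_consumed)


def sulfate_reduction(parcel: WaterParcel, h2s_produced: float,
                      ta_mode: str = "per_h2s") -> WaterParcel:
    """Sulfate reduction producing ``h2s_produced`` umol kg-1 of H2S.

    ``ta_mode="per_h2s"`` (default) uses the per-sulfide alkalinity form
    dTA = (2 + 16/53) x [H2S] -- the observation-driven budget
    convention.  ``ta_mode="per_c"`` instead uses the molar ratio
    dTA/dDIC = (106+16-1)/106 = 1.142 of the reaction equation.  The two
    differ by (1/53 - 1/106)x2x[H2S] ~ 0.7 umol kg-1 at [H2S] = 35.
    """
    if h2s_produced < 0:
        raise ValueError("h2s_produced must be >= 0")
    if ta_mode == "per_h2s":
        return _apply(parcel, REACTIONS["SR"], h2s_produced)
    if ta_mode == "per_c":
        spec = ReactionSpec("SR", "H2S produced", dO2=0.0, dDIC=2.0,
                            dTA=2.0 * (_C + _N - 1.0) / _C,
                            dH2S_T=1.0, dNH3_T=_N / 53.0)
        return _apply(parcel, spec, h2s_produced)
    raise ValueError(f"unknown ta_mode {ta_mode!r}")


def carbonate_dissolution(parcel: WaterParcel, dTA: float) -> WaterParcel:
    """Dissolve CaCO3 adding ``dTA`` umol kg-1 of alkalinity (2:1 TA:DIC)."""
    if dTA < 0:
        raise ValueError("dTA must be >= 0")
    return _apply(parcel, REACTIONS["CD"], dTA)


def close_budget(observed_dTA_excess: float, ar_dTA: float,
                 sr_dTA: float) -> tuple[float, float]:
    """Alkalinity budget closure: the CaCO3-dissolution TA needed so that
    AR + SR + CD reproduce the observed mixing-line TA excess.

    Returns ``(cd_dTA, cd_fraction)`` where ``cd_fraction`` is CD's share
    of the total (net) TA production.
    """
    cd = observed_dTA_excess - ar_dTA - sr_dTA
    total = ar_dTA + sr_dTA + cd
    frac = cd / total if total != 0 else float("nan")
    return cd, frac


def oxidize_reduced_species(parcel: WaterParcel,
                            amounts: Mapping[str, float]) -> WaterParcel:
    """Oxidise reduced species mixed into oxygenated water.

    ``amounts`` maps species ("H2S", "NH4", "Mn", "Fe") to umol kg-1
    oxidised.  Each mole oxidised releases 2 H+ (TA -2) and draws its
    stoichiometric O2 demand (2, 2, 0.5, 0.25) when O2 is tracked.
    """
    key = {"H2S": "OX_H2S", "NH4": "OX_NH4", "Mn": "OX_MN", "Fe": "OX_FE"}
    dTA = dO2 = dH2S = dNH3 = 0.0
    for sp, amt in amounts.items():
        if amt < 0:
            raise ValueError(f"negative oxidation amount for {sp}")
        spec = REACTIONS[key[sp]]
        dTA += spec.dTA * amt
        dO2 += spec.dO2 * amt
        dH2S += spec.dH2S_T * amt
        dNH3 += spec.dNH3_T * amt
    if parcel.H2S_T + dH2S < -1e-9:
        raise ValueError("oxidising more H2S than present")
    if parcel.NH3_T + dNH3 < -1e-9:
        raise ValueError("oxidising more NH4+ than present")
    if parcel.O2 is not None and parcel.O2 + dO2 < -1e-9:
        raise ValueError("oxidation demand exceeds available O2")
    return resolve(parcel, dTA=dTA, dH2S=max(dH2S, -parcel.H2S_T),
                   dNH3=max(dNH3, -parcel.NH3_T),
                   dO2=dO2 if parcel.O2 is not None else 0.0)


def mix_parcels(a: WaterParcel, b: WaterParcel, f: float) -> WaterParcel:
    """Conservative mixture of mass fraction ``f`` of parcel ``a`` with
    ``1 - f`` of ``b``; S, T, TA, DIC, O2 and all totals mix linearly,
    pH/pCO2/Omega are re-solved (they do not mix linearly)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("mass fraction f must be in [0, 1]")
    g = 1.0 - f

    def lin(x, y):
        if x is None or y is None:
            return None
        return f * x + g * y

    from .speciation import solve
    return solve(S=lin(a.S, b.S), T=lin(a.T, b.T), P=lin(a.P, b.P),
                 TA=lin(a.TA, b.TA), DIC=lin(a.DIC, b.DIC),
                 ph_scale=a.ph_scale,
                 PO4_T=lin(a.PO4_T, b.PO4_T), Si_T=lin(a.Si_T, b.Si_T),
                 H2S_T=lin(a.H2S_T, b.H2S_T), NH3_T=lin(a.NH3_T, b.NH3_T),
                 O2=lin(a.O2, b.O2), options=a.constants.options)


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def run_sequential_pathway(initial: WaterParcel, *,
                           dO2_total: float | None = None,
                           h2s_produced: float = 35.0,
                           cd_dTA: float = 115.3,
                           o2_checkpoints: Sequence[float] = (0.75, 0.50,
                                                              0.25, 0.0),
                           sr_ta_mode: str = "per_h2s") -> PathwayTrace:
    """AR to anoxia (recording loci at fractional O2-saturation
    checkpoints), then SR, then CD -- the sequential bottom-water pathway.

    ``dO2_total`` defaults to the parcel's O2 inventory.
    """
    if dO2_total is None:
        if initial.O2 is None:
            raise ValueError("dO2_total required when parcel O2 untracked")
        dO2_total = initial.O2
    trace = PathwayTrace(initial)
    p = initial
    consumed = 0.0
    for frac in o2_checkpoints:
        target = dO2_total * (1.0 - frac)
        p = aerobic_respiration(p, target - consumed)
        consumed = target
        trace._append(f"AR {frac:.0%} O2", p)
    if h2s_produced > 0:
        p = sulfate_reduction(p, h2s_produced, ta_mode=sr_ta_mode)
        trace._append("SR", p)
    if cd_dTA > 0:
        p = carbonate_dissolution(p, cd_dTA)
        trace._append("CD", p)
    return trace


#: CaCO3-dissolution schedule of the simultaneous pathway: each CD
#: fraction completes by the given dissolved-O2 saturation level; the
#: ``"SR"`` key dissolves together with sulfate reduction.
DEFAULT_CD_SCHEDULE: dict[object, float] = {
    0.33: 0.2, 0.16: 0.2, 0.08: 0.2, 0.0: 0.2, "SR": 0.2,
}


def run_simultaneous_pathway(initial: WaterParcel, *,
                             dO2_total: float | None = None,
                             h2s_produced: float = 35.0,
                             cd_dTA: float = 115.3,
                             schedule: Mapping[object, float] | None = None,
                             sr_ta_mode: str = "per_h2s") -> PathwayTrace:
    """AR with CaCO3 dissolution interleaved at prescribed O2 levels
    (default: 20% of the CD alkalinity by DO = 33%, 16%, 8% and 0%, the
    last 20% together with SR).

    Cumulative dTA/dDIC are identical to the sequential pathway -- the
    stoichiometric sums are path-independent; only the intermediate loci
    differ.
    """
    if schedule is None:
        schedule = DEFAULT_CD_SCHEDULE
    elif not schedule:
        return run_sequential_pathway(
            initial, dO2_total=dO2_total, h2s_produced=h2s_produced,
            cd_dTA=cd_dTA, sr_ta_mode=sr_ta_mode)
    fracs = sum(schedule.values())
    if abs(fracs - 1.0) > 1e-9:
        raise ValueError(f"schedule fractions sum to {fracs}, expected 1")
    if dO2_total is None:
        if initial.O2 is None:
            raise ValueError("dO2_total required when parcel O2 untracked")
        dO2_total = initial.O2

    trace = PathwayTrace(initial)
    p = initial
    consumed = 0.0
    o2_steps = sorted((k for k in schedule if not isinstance(k, str)),
                      reverse=True)
    for do_level in o2_steps:
        target = dO2_total * (1.0 - do_level)
        if target > consumed:
            p = aerobic_respiration(p, target - consumed)
            consumed = target
            trace._append(f"AR {do_level:.0%} O2", p)
        p = carbonate_dissolution(p, cd_dTA * schedule[do_level])
        trace._append(f"CD @{do_level:.0%} O2", p)
    if consumed < dO2_total:
        p = aerobic_respiration(p, dO2_total - consumed)
        trace._append("AR 0% O2", p)
    if h2s_produced > 0:
        p = sulfate_reduction(p, h2s_produced, ta_mode=sr_ta_mode)
        if "SR" in schedule:
            p = carbonate_dissolution(p, cd_dTA * schedule["SR"])
        trace._append("SR (+CD)", p)
    return trace


def denitrification_bound(rate: float, days: float, depth: float,
                          density: float = 1012.0) -> tuple[float, float]:
    """Upper-bound (dDIC, dTA) in umol kg-1 from an areal denitrification
    rate (umol m-2 h-1) integrated over ``days`` and spread over a
    ``depth``-metre water column of the given density (kg m-3);
    dTA/dDIC = (84.8+16-1)/106 for canonical denitrification."""
    for name, v in (("rate", rate), ("days", days), ("density", density)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    ddic = rate * 24.0 * days / depth / density
    return ddic, ddic * REACTIONS["DEN"].dTA
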