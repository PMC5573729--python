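"""Thermodynamic constants of the seawater acid-base system.

Evaluates every equilibrium constant, gas solubility and salinity-derived
total needed to speciate an estuarine water parcel, including the two
constants that extend the classical carbonate system into anoxic waters:
the ammonium dissociation constant (Clegg & Whitfield 1995) and the
hydrogen sulfide dissociation constant (Millero et al. 1988).

All constants are returned on the **free** hydrogen-ion scale in
mol kg-sw (Ksp in mol^2 kg^-2, K0 in mol kg^-1 atm^-1).  Published
formulations on other scales are converted internally; ``fH`` (the NBS
activity coefficient of H+) is carried so callers can convert pH to the
NBS scale used by glass-electrode field measurements.

Pressure corrections follow Millero (1995) as propagated by the CO2SYS
program lineage; they are applied on the seawater scale and the corrected
set is then moved back to the free scale, so constants at P = 0 equal
their surface formulations exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "ConstantOptions",
    "ConstantSet",
    "RangeViolation",
    "compute_constants",
    "o2_saturation",
]

# gas constant, cm3 bar mol-1 K-1 (units of the Millero Delta-V fits)
_RGAS = 83.1451


class RangeViolation(ValueError):
    """A constant was requested outside its published (S, T) validity range."""

    def __init__(self, constant: str, message: str):
        self.constant = constant
        super().__init__(f"{constant}: {message}")


@dataclass(frozen=True)
class ConstantOptions:
    """Which published formulation to use for each configurable constant.

    k1k2:
        ``"millero_2010"`` (default) -- carbonic acid constants of
        Millero (2010), valid S = 0-50: full estuarine salinity coverage.
        ``"millero_2006"`` -- S = 0-50 fit of Millero et al. (2006).
        ``"cai_wang_1998"`` -- estuarine fit (NBS scale), S = 0-40.
        ``"lueker_2000"`` -- the open-ocean standard, S = 19-43.
        ``"mehrbach_dm87"`` -- Mehrbach refit by Dickson & Millero (1987).
    borate: ``"uppstrom_1974"`` (default) or ``"lee_2010"``.
    fh: NBS activity factor; ``"takahashi_1982"`` (default) or
        ``"peng_1987"`` (Culberson-Pytkowicz form used by the Peng option).
    check_ranges: raise :class:`RangeViolation` when K_NH3 / K_H2S are
        evaluated outside their published (S, T) windows.
    """

    k1k2: str = "millero_2010"
    borate: str = "uppstrom_1974"
    fh: str = "takahashi_1982"
    check_ranges: bool = True


@dataclass(frozen=True)
class ConstantSet:
    """All constants at one (S, T, P), on the free hydrogen-ion scale."""

    S: float          # practical salinity, g kg-1
    T: float          # temperature, degC
    P: float          # pressure, dbar (0 = surface)
    K0: float         # CO2 solubility, mol kg-1 atm-1 (Weiss 1974)
    K1: float
    K2: float
    KB: float
    KW: float
    KP1: float
    KP2: float
    KP3: float
    KSi: float
    KS: float         # bisulfate, free scale by construction
    KF: float
    KNH3: float
    KH2S: float
    Ksp_cal: float
    Ksp_arag: float
    fH: float         # a_H+ / [H+]_sws  (NBS conversion factor)
    BT: float         # mol kg-1 totals from salinity
    SO4T: float
    FT: float
    CaT: float
    free_to_total: float   # [H]_total = factor * [H]_free
    free_to_sws: float     # [H]_sws   = factor * [H]_free
    fugacity_factor: float  # fCO2 = factor * pCO2
    options: ConstantOptions = field(default=ConstantOptions(), repr=False)

    def as_dict(self) -> dict:
        """Machine-readable dump of every constant (provenance record)."""
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "options"} | {"k1k2": self.options.k1k2,
                                           "borate": self.options.borate,
                                           "fh": self.options.fh}


# ---------------------------------------------------------------------------
# salinity-derived totals (mol kg-sw), CO2SYS-lineage defaults
# ---------------------------------------------------------------------------

def _totals(S: float, borate: str) -> tuple[float, float, float, float]:
    if borate == "uppstrom_1974":
        BT = 0.0004157 * S / 35.0
    elif borate == "lee_2010":
        BT = 0.0004326 * S / 35.0
    else:
        raise ValueError(f"unknown borate option {borate!r}")
    SO4T = (0.14 / 96.062) * (S / 1.80655)      # Morris & Riley 1966
    FT = (0.000067 / 18.998) * (S / 1.80655)    # Riley 1965
    CaT = (0.02128 / 40.087) * (S / 1.80655)    # Riley & Tongudai 1967
    return BT, SO4T, FT, CaT


# ---------------------------------------------------------------------------
# surface (P = 0) formulations
# ---------------------------------------------------------------------------

def _ks_free(TK: float, S: float, IonS: float) -> float:
    # Dickson (1990a), free scale, mol kg-sw
    lnK = (-4276.1 / TK + 141.328 - 23.093 * math.log(TK)
           + (-13856.0 / TK + 324.57 - 47.986 * math.log(TK)) * IonS ** 0.5
           + (35474.0 / TK - 771.54 + 114.723 * math.log(TK)) * IonS
           - 2698.0 / TK * IonS ** 1.5 + 1776.0 / TK * IonS ** 2)
    return math.exp(lnK) * (1.0 - 0.001005 * S)


def _kf_free(TK: float, S: float, IonS: float) -> float:
    # Dickson & Riley (1979), free scale, mol kg-sw
    lnK = 1590.2 / TK - 12.641 + 1.525 * IonS ** 0.5
    return math.exp(lnK) * (1.0 - 0.001005 * S)


def _fh(TK: float, S: float, option: str) -> float:
    if option == "takahashi_1982":
        return (1.2948 - 0.002036 * TK
                + (0.0004607 - 0.000001475 * TK) * S ** 2)
    if option == "peng_1987":
        return 1.29 - 0.00204 * TK + (0.00046 - 0.00000148 * TK) * S ** 2
    raise ValueError(f"unknown fH option {option!r}")


def _k0_weiss(TK: float, S: float) -> float:
    # Weiss (1974), mol kg-sw atm-1
    TK100 = TK / 100.0
    lnK0 = (-60.2409 + 93.4517 / TK100 + 23.3585 * math.log(TK100)
            + S * (0.023517 - 0.023656 * TK100 + 0.0047036 * TK100 ** 2))
    return math.exp(lnK0)


def _k1k2_sws(TK: float, S: float, option: str, fH: float) -> tuple[float, float]:
    """Carbonic acid K1, K2 on the seawater scale."""
    lnTK = math.log(TK)
    sqS = math.sqrt(S)
    if option == "cai_wang_1998":
        # fitted on the NBS scale; convert via fH (aH = fH * [H]_sws)
        F1 = 200.1 / TK + 0.3220
        pK1 = 3404.71 / TK + 0.032786 * TK - 14.8435 - 0.071692 * F1 * sqS \
            + 0.0021487 * S
        F2 = -129.24 / TK + 1.4381
        pK2 = 2902.39 / TK + 0.02379 * TK - 6.4980 - 0.3191 * F2 * sqS \
            + 0.0198 * S
        return 10.0 ** -pK1 / fH, 10.0 ** -pK2 / fH
    if option == "millero_2010":
        pK1 = -126.34048 + 6320.813 / TK + 19.568224 * lnTK
        pK1 += (13.4038 * sqS + 0.03206 * S - 5.242e-5 * S ** 2) \
            + (-530.659 * sqS - 5.8210 * S) / TK + (-2.0664 * sqS) * lnTK
        pK2 = -90.18333 + 5143.692 / TK + 14.613358 * lnTK
        pK2 += (21.3728 * sqS + 0.1218 * S - 3.688e-4 * S ** 2) \
            + (-788.289 * sqS - 19.189 * S) / TK + (-3.374 * sqS) * lnTK
        return 10.0 ** -pK1, 10.0 ** -pK2
    if option == "millero_2006":
        pK1 = -126.34048 + 6320.813 / TK + 19.568224 * lnTK
        pK1 += (13.4191 * sqS + 0.0331 * S - 5.33e-5 * S ** 2) \
            + (-530.123 * sqS - 6.103 * S) / TK + (-2.06950 * sqS) * lnTK
        pK2 = -90.18333 + 5143.692 / TK + 14.613358 * lnTK
        pK2 += (21.0894 * sqS + 0.1248 * S - 3.687e-4 * S ** 2) \
            + (-772.483 * sqS - 20.051 * S) / TK + (-3.3336 * sqS) * lnTK
        return 10.0 ** -pK1, 10.0 ** -pK2
    if option == "mehrbach_dm87":
        pK1 = 3670.7 / TK - 62.008 + 9.7944 * lnTK - 0.0118 * S \
            + 0.000116 * S ** 2
        pK2 = 1394.7 / TK + 4.777 - 0.0184 * S + 0.000118 * S ** 2
        return 10.0 ** -pK1, 10.0 ** -pK2
    if option == "lueker_2000":
        # total scale; caller converts
        pK1 = 3633.86 / TK - 61.2172 + 9.67770 * lnTK - 0.011555 * S \
            + 0.0001152 * S ** 2
        pK2 = 471.78 / TK + 25.9290 - 3.16967 * lnTK - 0.01781 * S \
            + 0.0001122 * S ** 2
        return 10.0 ** -pK1, 10.0 ** -pK2  # NB: total scale
    raise ValueError(f"unknown k1k2 option {option!r}")


def _kb_total(TK: float, S: float) -> float:
    # Dickson (1990b), total scale
    sqS = math.sqrt(S)
    lnKB = ((-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S ** 1.5
             - 0.0996 * S ** 2) / TK
            + 148.0248 + 137.1942 * sqS + 1.62142 * S
            - (24.4344 + 25.085 * sqS + 0.2474 * S) * math.log(TK)
            + 0.053105 * sqS * TK)
    return math.exp(lnKB)


def _kw_sws(TK: float, S: float) -> float:
    # Millero (1995), seawater scale
    lnKW = (148.9802 - 13847.26 / TK - 23.6521 * math.log(TK)
            + (-5.977 + 118.67 / TK + 1.0495 * math.log(TK)) * math.sqrt(S)
            - 0.01615 * S)
    return math.exp(lnKW)


def _phosphate_silicate_sws(TK: float, S: float, IonS: float):
    # Yao & Millero (1995), seawater scale
    lnTK, sqS = math.log(TK), math.sqrt(S)
    lnKP1 = (-4576.752 / TK + 115.525 - 18.453 * lnTK
             + (-106.736 / TK + 0.69171) * sqS
             + (-0.65643 / TK - 0.01844) * S)
    lnKP2 = (-8814.715 / TK + 172.0883 - 27.927 * lnTK
             + (-160.340 / TK + 1.3566) * sqS
             + (0.37335 / TK - 0.05778) * S)
    lnKP3 = (-3070.75 / TK - 18.141
             + (17.27039 / TK + 2.81197) * sqS
             + (-44.99486 / TK - 0.09984) * S)
    sqI = math.sqrt(IonS)
    lnKSi = (-8904.2 / TK + 117.385 - 19.334 * lnTK
             + (-458.79 / TK + 3.5913) * sqI
             + (188.74 / TK - 1.5998) * IonS
             + (-12.1652 / TK + 0.07871) * IonS ** 2)
    KSi = math.exp(lnKSi) * (1.0 - 0.001005 * S)  # mol/kg-H2O -> mol/kg-sw
    return math.exp(lnKP1), math.exp(lnKP2), math.exp(lnKP3), KSi


def _knh3_total(TK: float, S: float) -> float:
    # Clegg & Whitfield (1995); total scale, converted to mol kg-sw
    sqTK = math.sqrt(TK)
    pK = 9.244605 - 2729.33 * (1.0 / 298.15 - 1.0 / TK)
    pK += (0.04203362 - 11.24742 / TK) * S ** 0.25
    pK += (-13.6416 + 1.176949 * sqTK - 0.02860785 * TK
           + 545.4834 / TK) * S ** 0.5
    pK += (-0.1462507 + 0.0090226468 * sqTK - 0.0001471361 * TK
           + 10.5425 / TK) * S ** 1.5
    pK += (0.004669309 - 0.0001691742 * sqTK - 0.5677934 / TK) * S ** 2
    pK += (-2.354039e-05 + 0.009698623 / TK) * S ** 2.5
    return 10.0 ** -pK * (1.0 - 0.001005 * S)


def _kh2s_total(TK: float, S: float) -> float:
    # Millero et al. (1988); total scale, mol kg-sw
    lnK = (225.838 - 13275.3 / TK - 34.6435 * math.log(TK)
           + 0.3449 * math.sqrt(S) - 0.0274 * S)
    return math.exp(lnK)


def _ksp_mucci(TK: float, S: float) -> tuple[float, float]:
    # Mucci (1983): stoichiometric solubility products, (mol kg-sw)^2
    sqS = math.sqrt(S)
    log10TK = math.log10(TK)
    logKC = (-171.9065 - 0.077993 * TK + 2839.319 / TK + 71.595 * log10TK
             + (-0.77712 + 0.0028426 * TK + 178.34 / TK) * sqS
             - 0.07711 * S + 0.0041249 * S ** 1.5)
    logKA = (-171.945 - 0.077993 * TK + 2903.293 / TK + 71.595 * log10TK
             + (-0.068393 + 0.0017276 * TK + 88.135 / TK) * sqS
             - 0.10018 * S + 0.0059415 * S ** 1.5)
    return 10.0 ** logKC, 10.0 ** logKA


# ---------------------------------------------------------------------------
# pressure corrections (Millero 1995 lineage); t in degC, Pbar in bar
# ---------------------------------------------------------------------------

def _pfac(TK: float, t: float, Pbar: float, dV: float, dK: float) -> float:
    return math.exp((-dV + 0.5 * dK * Pbar) * Pbar / (_RGAS * TK))


def _pressure_factors(TK: float, t: float, Pbar: float) -> dict[str, float]:
    f = {}
    f["K1"] = _pfac(TK, t, Pbar, -25.5 + 0.1271 * t, (-3.08 + 0.0877 * t) / 1000)
    f["K2"] = _pfac(TK, t, Pbar, -15.82 - 0.0219 * t, (1.13 - 0.1475 * t) / 1000)
    f["KB"] = _pfac(TK, t, Pbar, -29.48 + 0.1622 * t + 0.002608 * t ** 2,
                    -2.84 / 1000)
    f["KW"] = _pfac(TK, t, Pbar, -20.02 + 0.1119 * t - 0.001409 * t ** 2,
                    (-5.13 + 0.0794 * t) / 1000)
    f["KF"] = _pfac(TK, t, Pbar, -9.78 - 0.009 * t - 0.000942 * t ** 2,
                    (-3.91 + 0.054 * t) / 1000)
    f["KS"] = _pfac(TK, t, Pbar, -18.03 + 0.0466 * t + 0.000316 * t ** 2,
                    (-4.53 + 0.09 * t) / 1000)
    f["KP1"] = _pfac(TK, t, Pbar, -14.51 + 0.1211 * t - 0.000321 * t ** 2,
                     (-2.67 + 0.0427 * t) / 1000)
    f["KP2"] = _pfac(TK, t, Pbar, -23.12 + 0.1758 * t - 0.002647 * t ** 2,
                     (-5.15 + 0.09 * t) / 1000)
    f["KP3"] = _pfac(TK, t, Pbar, -26.57 + 0.2020 * t - 0.003042 * t ** 2,
                     (-4.08 + 0.0714 * t) / 1000)
    f["KSi"] = f["KB"]  # no direct measurement; boric acid analogue
    f["KNH3"] = _pfac(TK, t, Pbar, -26.43 + 0.0889 * t - 0.000905 * t ** 2,
                      (-5.03 + 0.0814 * t) / 1000)
    f["KH2S"] = _pfac(TK, t, Pbar, -14.80 + 0.0020 * t - 0.000400 * t ** 2,
                      (2.89 + 0.054 * t) / 1000)
    dVc = -48.76 + 0.5304 * t
    dKc = (-11.76 + 0.3692 * t) / 1000
    f["Ksp_cal"] = _pfac(TK, t, Pbar, dVc, dKc)
    f["Ksp_arag"] = _pfac(TK, t, Pbar, dVc + 2.8, dKc)
    return f


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def compute_constants(S: float, T: float, P: float = 0.0,
                      options: ConstantOptions | None = None,
                      *, need_nh3: bool = True,
                      need_h2s: bool = True) -> ConstantSet:
    """Evaluate the full :class:`ConstantSet` at salinity ``S`` (g kg-1),
    temperature ``T`` (degC) and pressure ``P`` (dbar).

    ``need_nh3`` / ``need_h2s`` control whether the published validity
    windows of those constants are enforced (K_NH3: S 0-40, t -2-40;
    K_H2S: S 0-40, t 0-35); outside them a :class:`RangeViolation` is
    raised rather than extrapolating silently.
    """
    options = options or ConstantOptions()
    if S < 0 or S > 45:
        raise RangeViolation("salinity", f"S={S} outside 0-45 g kg-1")
    if T < -2 or T > 40:
        raise RangeViolation("temperature", f"T={T} outside -2-40 degC")
    if P < 0:
        raise RangeViolation("pressure", f"P={P} dbar is negative")
    if options.check_ranges and need_nh3 and not (0 <= S <= 40 and -2 <= T <= 40):
        raise RangeViolation("K_NH3", f"valid for S 0-40, t -2-40; got "
                                      f"S={S}, T={T}")
    if options.check_ranges and need_h2s and not (0 <= S <= 40 and 0 <= T <= 35):
        raise RangeViolation("K_H2S", f"valid for S 0-40, t 0-35; got "
                                      f"S={S}, T={T}")

    TK = T + 273.15
    IonS = 19.924 * S / (1000.0 - 1.005 * S)
    BT, SO4T, FT, CaT = _totals(S, options.borate)
    fH = _fh(TK, S, options.fh)

    # surface KS/KF define the surface scale conversions
    KS0 = _ks_free(TK, S, IonS)
    KF0 = _kf_free(TK, S, IonS)
    free_to_total0 = 1.0 + SO4T / KS0
    free_to_sws0 = 1.0 + SO4T / KS0 + FT / KF0
    sws_to_total0 = free_to_total0 / free_to_sws0

    # assemble everything on the seawater scale at the surface
    K1, K2 = _k1k2_sws(TK, S, options.k1k2, fH)
    if options.k1k2 == "lueker_2000":       # published on total scale
        K1 /= sws_to_total0
        K2 /= sws_to_total0
    KB = _kb_total(TK, S) / sws_to_total0
    KW = _kw_sws(TK, S)
    KP1, KP2, KP3, KSi = _phosphate_silicate_sws(TK, S, IonS)
    KNH3 = _knh3_total(TK, S) / sws_to_total0
    KH2S = _kh2s_total(TK, S) / sws_to_total0
    KspC, KspA = _ksp_mucci(TK, S)
    K0 = _k0_weiss(TK, S)

    KS, KF = KS0, KF0
    if P > 0:
        Pbar = P / 10.0
        pf = _pressure_factors(TK, T, Pbar)
        K1 *= pf["K1"]; K2 *= pf["K2"]; KB *= pf["KB"]; KW *= pf["KW"]
        KP1 *= pf["KP1"]; KP2 *= pf["KP2"]; KP3 *= pf["KP3"]
        KSi *= pf["KSi"]; KNH3 *= pf["KNH3"]; KH2S *= pf["KH2S"]
        KspC *= pf["Ksp_cal"]; KspA *= pf["Ksp_arag"]
        KS *= pf["KS"]; KF *= pf["KF"]

    free_to_total = 1.0 + SO4T / KS
    free_to_sws = 1.0 + SO4T / KS + FT / KF

    # move the seawater-scale set onto the free scale
    sws = free_to_sws
    K1, K2, KB, KW = K1 / sws, K2 / sws, KB / sws, KW / sws
    KP1, KP2, KP3, KSi = KP1 / sws, KP2 / sws, KP3 / sws, KSi / sws
    KNH3, KH2S = KNH3 / sws, KH2S / sws

    # CO2 fugacity coefficient (Weiss 1974 virial form), 1 atm total pressure
    b = -1636.75 + 12.0408 * TK - 0.0327957 * TK ** 2 + 3.16528e-5 * TK ** 3
    delta = 57.7 - 0.118 * TK
    fugfac = math.exp((b + 2.0 * delta) * 1.01325 / (_RGAS * TK))

    return ConstantSet(
        S=S, T=T, P=P, K0=K0, K1=K1, K2=K2, KB=KB, KW=KW,
        KP1=KP1, KP2=KP2, KP3=KP3, KSi=KSi, KS=KS, KF=KF,
        KNH3=KNH3, KH2S=KH2S, Ksp_cal=KspC, Ksp_arag=KspA, fH=fH,
        BT=BT, SO4T=SO4T, FT=FT, CaT=CaT,
        free_to_total=free_to_total, free_to_sws=free_to_sws,
        fugacity_factor=fugfac, options=options,
    )


# ---------------------------------------------------------------------------
# oxygen solubility
# ---------------------------------------------------------------------------

_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def o2_saturation(S: float, T: float) -> float:
    """Air-saturation dissolved O2 (umol kg-1) at 1 atm moist atmosphere.

    Garcia & Gordon (1992) combined fit to the Benson & Krause data,
    valid for S 0-42 and T 0-40 degC.
    """
    if not (0 <= S <= 42):
        raise RangeViolation("O2 solubility", f"S={S} outside 0-42")
    if not (0 <= T <= 40):
        raise RangeViolation("O2 solubility", f"T={T} outside 0-40 degC")
    Ts = math.log((298.15 - T) / (273.15 + T))
    A = sum(a * Ts ** i for i, a in enumerate(_GG_A))
    B = sum(b * Ts ** i for i, b in enumerate(_GG_B))
    return math.exp(A + S * (B + _GG_C0 * S))
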