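"""Extended acid-base speciation of estuarine water parcels.

The classical marine CO2 system (any two of TA, DIC, pH, pCO2 fix the
rest) is extended with the two acid-base couples that matter in anoxic
bottom waters: H2S/HS- and NH4+/NH3.  Their alkalinity contributions are

    NH3-Alk = [NH3]_T * K_NH3 / (K_NH3 + [H])
    H2S-Alk = [H2S]_T * K_H2S / (K_H2S + [H])

added to the standard Dickson total-alkalinity expression (carbonate,
borate, water, phosphate, silicate, minus free H+, bisulfate and HF).

Internally everything is solved on the free hydrogen-ion scale at the
parcel's (S, T, P); pH is reported on any of the free / total / seawater
/ NBS scales (field pH in this problem domain is glass-electrode NBS).

Units: TA, DIC and all totals in umol kg-1; pCO2 in uatm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

from .constants import ConstantOptions, ConstantSet, compute_constants

__all__ = [
    "WaterParcel", "BufferFactors", "InfeasibleState",
    "total_alkalinity", "solve", "saturation_state", "buffer_factors",
    "convert_ph_scale",
]

Scale = Literal["free", "total", "sws", "nbs"]

_LN10 = math.log(10.0)


class InfeasibleState(ValueError):
    """No physically meaningful root exists for the requested pair."""


# ---------------------------------------------------------------------------
# pH scale conversions
# ---------------------------------------------------------------------------

def _h_free_from_ph(pH: float, scale: Scale, ks: ConstantSet) -> float:
    """[H+]_free (mol kg-1) from a scale-tagged pH."""
    h = 10.0 ** -pH
    if scale == "free":
        return h
    if scale == "total":
        return h / ks.free_to_total
    if scale == "sws":
        return h / ks.free_to_sws
    if scale == "nbs":
        return h / ks.fH / ks.free_to_sws
    raise ValueError(f"unknown pH scale {scale!r}")


def _ph_from_h_free(h_free: float, scale: Scale, ks: ConstantSet) -> float:
    if scale == "free":
        h = h_free
    elif scale == "total":
        h = h_free * ks.free_to_total
    elif scale == "sws":
        h = h_free * ks.free_to_sws
    elif scale == "nbs":
        h = h_free * ks.free_to_sws * ks.fH
    else:
        raise ValueError(f"unknown pH scale {scale!r}")
    return -math.log10(h)


def convert_ph_scale(pH: float, from_scale: Scale, to_scale: Scale,
                     S: float, T: float, P: float = 0.0,
                     options: ConstantOptions | None = None,
                     constants: ConstantSet | None = None) -> float:
    """Convert a pH value between the free / total / seawater / NBS scales."""
    ks = constants or compute_constants(S, T, P, options,
                                        need_nh3=False, need_h2s=False)
    return _ph_from_h_free(_h_free_from_ph(pH, from_scale, ks), to_scale, ks)


# ---------------------------------------------------------------------------
# the parcel container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterParcel:
    """A fully speciated carbonate-system state.

    Concentrations in umol kg-1, pCO2 in uatm.  ``pH`` is reported on
    ``ph_scale`` at the parcel's own (T, P).  The ``species`` dict holds
    the individual speciated concentrations (umol kg-1).
    """

    S: float
    T: float
    P: float
    TA: float
    DIC: float
    pH: float
    pCO2: float
    ph_scale: Scale = "nbs"
    PO4_T: float = 0.0
    Si_T: float = 0.0
    H2S_T: float = 0.0
    NH3_T: float = 0.0
    O2: float | None = None
    omega_arag: float = float("nan")
    omega_cal: float = float("nan")
    species: dict = field(default_factory=dict, compare=False)
    constants: ConstantSet = field(default=None, repr=False, compare=False)

    @property
    def h_free(self) -> float:
        return _h_free_from_ph(self.pH, self.ph_scale, self.constants)

    def ph_on(self, scale: Scale) -> float:
        return _ph_from_h_free(self.h_free, scale, self.constants)


@dataclass(frozen=True)
class BufferFactors:
    """Egleston-style sensitivity factors, umol kg-1.

    beta_DIC = -(ln10 * dpH/dDIC)^-1 at fixed TA (positive in normal
    waters); beta_TA = -(ln10 * dpH/dTA)^-1 at fixed DIC (negative,
    similar magnitude).  Small magnitudes mean pH responds strongly.
    """

    beta_DIC: float
    beta_TA: float
    near_singular: bool = False


# ---------------------------------------------------------------------------
# alkalinity and its partial derivatives
# ---------------------------------------------------------------------------

def _ta_umol(h: float, dic: float, ks: ConstantSet,
             po4: float, si: float, h2s: float, nh3: float) -> float:
    """TA (umol kg-1) at free-scale [H+] ``h`` (mol kg-1), DIC in umol kg-1."""
    K1, K2 = ks.K1, ks.K2
    denC = h * h + K1 * h + K1 * K2
    CAlk = dic * K1 * (h + 2.0 * K2) / denC
    BAlk = 1e6 * ks.BT * ks.KB / (ks.KB + h)
    OH = 1e6 * ks.KW / h
    KP1, KP2, KP3 = ks.KP1, ks.KP2, ks.KP3
    denP = h ** 3 + KP1 * h ** 2 + KP1 * KP2 * h + KP1 * KP2 * KP3
    PAlk = po4 * (KP1 * KP2 * h + 2.0 * KP1 * KP2 * KP3 - h ** 3) / denP
    SiAlk = si * ks.KSi / (ks.KSi + h)
    NH3Alk = nh3 * ks.KNH3 / (ks.KNH3 + h)
    HSAlk = h2s * ks.KH2S / (ks.KH2S + h)
    Hfree = 1e6 * h
    HSO4 = 1e6 * ks.SO4T * h / (ks.KS + h)
    HF = 1e6 * ks.FT * h / (ks.KF + h)
    return (CAlk + BAlk + OH + PAlk + SiAlk + NH3Alk + HSAlk
            - Hfree - HSO4 - HF)


def _dta_dh(h: float, dic: float, ks: ConstantSet,
            po4: float, si: float, h2s: float, nh3: float) -> float:
    """d(TA)/d[H] (umol kg-1 per mol kg-1), analytic."""
    K1, K2 = ks.K1, ks.K2
    denC = h * h + K1 * h + K1 * K2
    dCAlk = dic * K1 * (denC - (h + 2.0 * K2) * (2.0 * h + K1)) / denC ** 2
    dBAlk = -1e6 * ks.BT * ks.KB / (ks.KB + h) ** 2
    dOH = -1e6 * ks.KW / h ** 2
    KP1, KP2, KP3 = ks.KP1, ks.KP2, ks.KP3
    denP = h ** 3 + KP1 * h ** 2 + KP1 * KP2 * h + KP1 * KP2 * KP3
    numP = KP1 * KP2 * h + 2.0 * KP1 * KP2 * KP3 - h ** 3
    dnumP = KP1 * KP2 - 3.0 * h ** 2
    ddenP = 3.0 * h ** 2 + 2.0 * KP1 * h + KP1 * KP2
    dPAlk = po4 * (dnumP * denP - numP * ddenP) / denP ** 2
    dSiAlk = -si * ks.KSi / (ks.KSi + h) ** 2
    dNH3 = -nh3 * ks.KNH3 / (ks.KNH3 + h) ** 2
    dHS = -h2s * ks.KH2S / (ks.KH2S + h) ** 2
    dHfree = 1e6
    dHSO4 = 1e6 * ks.SO4T * ks.KS / (ks.KS + h) ** 2
    dHF = 1e6 * ks.FT * ks.KF / (ks.KF + h) ** 2
    return (dCAlk + dBAlk + dOH + dPAlk + dSiAlk + dNH3 + dHS
            - dHfree - dHSO4 - dHF)


def total_alkalinity(pH: float, DIC: float, S: float, T: float,
                     P: float = 0.0, *, ph_scale: Scale = "nbs",
                     PO4_T: float = 0.0, Si_T: float = 0.0,
                     H2S_T: float = 0.0, NH3_T: float = 0.0,
                     options: ConstantOptions | None = None) -> float:
    """TA (umol kg-1) from a scale-tagged pH and DIC with the extended
    alkalinity expression (NH3-Alk and H2S-Alk included)."""
    if not (2.0 < pH < 12.0):
        raise InfeasibleState(f"pH={pH} outside (2, 12)")
    for name, v in (("PO4_T", PO4_T), ("Si_T", Si_T),
                    ("H2S_T", H2S_T), ("NH3_T", NH3_T), ("DIC", DIC)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    ks = compute_constants(S, T, P, options,
                           need_nh3=NH3_T > 0, need_h2s=H2S_T > 0)
    h = _h_free_from_ph(pH, ph_scale, ks)
    return _ta_umol(h, DIC, ks, PO4_T, Si_T, H2S_T, NH3_T)


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------

def _solve_h_from_ta_dic(TA: float, dic: float, ks: ConstantSet,
                         po4: float, si: float, h2s: float, nh3: float,
                         tol: float = 1e-8) -> float:
    """Free-scale [H+] such that TA([H], DIC) = TA.

    Bracketed Newton iteration on pH over (2, 12): Newton steps on the
    monotone TA residual, falling back to bisection whenever a step
    leaves the current bracket.  Deterministic start at pH 7.
    """
    ph_lo, ph_hi = 2.0, 12.0

    def resid(ph: float) -> float:
        return _ta_umol(10.0 ** -ph, dic, ks, po4, si, h2s, nh3) - TA

    r_lo, r_hi = resid(ph_lo), resid(ph_hi)
    # TA is increasing in pH (decreasing in [H])
    if r_lo > 0 or r_hi < 0:
        raise InfeasibleState(
            f"no root in pH (2, 12) for TA={TA}, DIC={dic} "
            f"(residuals {r_lo:.3g}, {r_hi:.3g})")
    ph = 7.0
    for _ in range(100):
        h = 10.0 ** -ph
        r = resid(ph)
        if r < 0:
            ph_lo = ph
        else:
            ph_hi = ph
        # dTA/dpH = dTA/dh * dh/dpH, dh/dpH = -ln10 * h
        slope = -_LN10 * h * _dta_dh(h, dic, ks, po4, si, h2s, nh3)
        step = -r / slope if slope != 0 else float("nan")
        ph_new = ph + step
        if not (ph_lo < ph_new < ph_hi):
            ph_new = 0.5 * (ph_lo + ph_hi)
        if abs(ph_new - ph) < tol:
            return 10.0 ** -ph_new
        ph = ph_new
    raise InfeasibleState(
        f"pH iteration did not converge (last residual {r:.3g} umol kg-1)")


def _dic_from_co2_h(co2: float, h: float, ks: ConstantSet) -> float:
    return co2 * (1.0 + ks.K1 / h + ks.K1 * ks.K2 / (h * h))


def solve(*, S: float, T: float, P: float = 0.0,
          TA: float | None = None, DIC: float | None = None,
          pH: float | None = None, pCO2: float | None = None,
          ph_scale: Scale = "nbs",
          PO4_T: float = 0.0, Si_T: float = 0.0,
          H2S_T: float = 0.0, NH3_T: float = 0.0,
          O2: float | None = None,
          options: ConstantOptions | None = None) -> WaterParcel:
    """Speciate a parcel from any two of {TA, DIC, pH, pCO2}.

    The output pH is reported on ``ph_scale`` (the same scale an input pH
    is interpreted on).  Raises :class:`InfeasibleState` when the pair
    admits no root in pH (2, 12).
    """
    known = {k: v for k, v in
             dict(TA=TA, DIC=DIC, pH=pH, pCO2=pCO2).items() if v is not None}
    if len(known) != 2:
        raise ValueError(f"exactly two of TA/DIC/pH/pCO2 required, "
                         f"got {sorted(known)}")
    ks = compute_constants(S, T, P, options,
                           need_nh3=NH3_T > 0, need_h2s=H2S_T > 0)
    tot = dict(po4=PO4_T, si=Si_T, h2s=H2S_T, nh3=NH3_T)

    pair = frozenset(known)
    if pair == {"pH", "DIC"}:
        h = _h_free_from_ph(pH, ph_scale, ks)
        dic = DIC
        ta = _ta_umol(h, dic, ks, **tot)
    elif pair == {"TA", "DIC"}:
        h = _solve_h_from_ta_dic(TA, DIC, ks, **tot)
        dic, ta = DIC, TA
    elif pair == {"TA", "pH"}:
        h = _h_free_from_ph(pH, ph_scale, ks)
        other = _ta_umol(h, 0.0, ks, **tot)
        calk = TA - other
        dic = calk * (h * h + ks.K1 * h + ks.K1 * ks.K2) \
            / (ks.K1 * (h + 2.0 * ks.K2))
        if dic <= 0:
            raise InfeasibleState("TA/pH pair implies non-positive DIC")
        ta = TA
    elif pair == {"DIC", "pCO2"}:
        co2 = ks.K0 * ks.fugacity_factor * pCO2  # umol kg-1
        if co2 >= DIC:
            raise InfeasibleState("pCO2 implies [CO2] >= DIC")
        # (DIC - CO2) h^2 - CO2*K1*h - CO2*K1*K2 = 0
        a, b, c = DIC - co2, -co2 * ks.K1, -co2 * ks.K1 * ks.K2
        h = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
        dic = DIC
        ta = _ta_umol(h, dic, ks, **tot)
    elif pair == {"TA", "pCO2"}:
        co2 = ks.K0 * ks.fugacity_factor * pCO2

        def resid(ph: float) -> float:
            hh = 10.0 ** -ph
            return _ta_umol(hh, _dic_from_co2_h(co2, hh, ks), ks, **tot) - TA

        lo, hi = 2.0, 12.0
        if resid(lo) > 0 or resid(hi) < 0:
            raise InfeasibleState("no root in pH (2, 12) for TA/pCO2 pair")
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if resid(mid) < 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-10:
                break
        h = 10.0 ** -(0.5 * (lo + hi))
        dic = _dic_from_co2_h(co2, h, ks)
        ta = TA
    elif pair == {"pH", "pCO2"}:
        h = _h_free_from_ph(pH, ph_scale, ks)
        co2 = ks.K0 * ks.fugacity_factor * pCO2
        dic = _dic_from_co2_h(co2, h, ks)
        ta = _ta_umol(h, dic, ks, **tot)
    else:  # pragma: no cover
        raise ValueError(f"unsupported pair {sorted(known)}")

    return _assemble(h, ta, dic, ks, ph_scale, PO4_T, Si_T, H2S_T, NH3_T, O2)


def _assemble(h: float, ta: float, dic: float, ks: ConstantSet,
              ph_scale: Scale, po4: float, si: float, h2s: float,
              nh3: float, o2: float | None) -> WaterParcel:
    denC = h * h + ks.K1 * h + ks.K1 * ks.K2
    co2 = dic * h * h / denC
    hco3 = dic * ks.K1 * h / denC
    co3 = dic * ks.K1 * ks.K2 / denC
    pco2 = co2 / (ks.K0 * ks.fugacity_factor)
    boh4 = 1e6 * ks.BT * ks.KB / (ks.KB + h)
    hs = h2s * ks.KH2S / (ks.KH2S + h)
    nh3_free = nh3 * ks.KNH3 / (ks.KNH3 + h)
    co3_mol = co3 * 1e-6
    om_cal = ks.CaT * co3_mol / ks.Ksp_cal
    om_arag = ks.CaT * co3_mol / ks.Ksp_arag
    species = {
        "CO2": co2, "HCO3": hco3, "CO3": co3, "BOH4": boh4,
        "OH": 1e6 * ks.KW / h, "HS": hs, "H2S": h2s - hs,
        "NH3": nh3_free, "NH4": nh3 - nh3_free,
        "H_free": 1e6 * h,
    }
    return WaterParcel(
        S=ks.S, T=ks.T, P=ks.P, TA=ta, DIC=dic,
        pH=_ph_from_h_free(h, ph_scale, ks), pCO2=pco2, ph_scale=ph_scale,
        PO4_T=po4, Si_T=si, H2S_T=h2s, NH3_T=nh3, O2=o2,
        omega_arag=om_arag, omega_cal=om_cal,
        species=species, constants=ks)


def resolve(parcel: WaterParcel, *, dTA: float = 0.0, dDIC: float = 0.0,
            dH2S: float = 0.0, dNH3: float = 0.0,
            dO2: float = 0.0) -> WaterParcel:
    """Re-speciate a parcel after adding increments to its conservative
    fields (the re-solve step every reaction operation delegates to)."""
    o2 = None if parcel.O2 is None else parcel.O2 + dO2
    return solve(S=parcel.S, T=parcel.T, P=parcel.P,
                 TA=parcel.TA + dTA, DIC=parcel.DIC + dDIC,
                 ph_scale=parcel.ph_scale,
                 PO4_T=parcel.PO4_T, Si_T=parcel.Si_T,
                 H2S_T=parcel.H2S_T + dH2S, NH3_T=parcel.NH3_T + dNH3,
                 O2=o2, options=parcel.constants.options)


def saturation_state(parcel: WaterParcel) -> tuple[float, float]:
    """(Omega_aragonite, Omega_calcite) of a solved parcel."""
    if "CO3" not in parcel.species:
        raise ValueError("parcel has no speciated [CO3]; solve it first")
    return parcel.omega_arag, parcel.omega_cal


def buffer_factors(parcel: WaterParcel, *, numeric: bool = False,
                   eps: float = 0.1) -> BufferFactors:
    """beta_DIC and beta_TA (umol kg-1) of a solved parcel.

    Analytic closed forms from the full extended alkalinity expression
    (all acid-base couples included); ``numeric=True`` instead re-solves
    the parcel at DIC +/- ``eps`` (TA +/- ``eps``) and central-differences
    pH -- the independent check, not the default path.
    """
    if numeric:
        def ph_at(dta: float, ddic: float) -> float:
            return resolve(parcel, dTA=dta, dDIC=ddic).ph_on("free")
        dph_ddic = (ph_at(0, +eps) - ph_at(0, -eps)) / (2 * eps)
        dph_dta = (ph_at(+eps, 0) - ph_at(-eps, 0)) / (2 * eps)
    else:
        ks = parcel.constants
        h = parcel.h_free
        args = (parcel.PO4_T, parcel.Si_T, parcel.H2S_T, parcel.NH3_T)
        ta_h = _dta_dh(h, parcel.DIC, ks, *args)
        ta_dic = ks.K1 * (h + 2.0 * ks.K2) \
            / (h * h + ks.K1 * h + ks.K1 * ks.K2)
        # implicit differentiation of TA(h, DIC) = const
        dph_ddic = ta_dic / (_LN10 * h * ta_h)
        dph_dta = -1.0 / (_LN10 * h * ta_h)
    near_singular = abs(dph_ddic) < 1e-12 or abs(dph_dta) < 1e-12
    beta_dic = math.inf if abs(dph_ddic) < 1e-12 \
        else -1.0 / (_LN10 * dph_ddic)
    beta_ta = math.inf if abs(dph_dta) < 1e-12 \
        else -1.0 / (_LN10 * dph_dta)
    return BufferFactors(beta_DIC=beta_dic, beta_TA=beta_ta,
                         near_singular=near_singular)
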