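"""Extended speciation solver: oracles, round trips, buffer factors."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estucarb.constants import compute_constants
from estucarb.speciation import (InfeasibleState, buffer_factors,
                                 convert_ph_scale, resolve,
                                 saturation_state, solve, total_alkalinity)

CTX = dict(S=18.618, T=25.28, P=17.0, PO4_T=3.5, H2S_T=37.79, NH3_T=13.6)


# ---------------------------------------------------------------------------
# an independent brute-force oracle: plain bisection on the TA residual
# ---------------------------------------------------------------------------

def _bisect_ph(TA, DIC, **ctx):
    lo, hi = 2.0, 12.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        ta_mid = total_alkalinity(mid, DIC, ctx["S"], ctx["T"],
                                  ctx.get("P", 0.0), ph_scale="nbs",
                                  PO4_T=ctx.get("PO4_T", 0.0),
                                  H2S_T=ctx.get("H2S_T", 0.0),
                                  NH3_T=ctx.get("NH3_T", 0.0))
        if ta_mid < TA:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@pytest.mark.parametrize("TA,DIC,ctx", [
    (1934.1, 1933.8, CTX),
    (1771.1, 1658.5, dict(S=19.87, T=25.0)),
    (2351.5, 2030.3, dict(S=35.839, T=25.0, P=1.0)),
])
def test_solver_matches_bisection_oracle(TA, DIC, ctx):
    p = solve(TA=TA, DIC=DIC, **ctx)
    assert p.pH == pytest.approx(_bisect_ph(TA, DIC, **ctx), abs=1e-6)


def test_round_trip_ta_recovery(sulfidic_parcel):
    """solve(TA, DIC) -> pH, then the alkalinity expression at that pH
    recovers TA to better than 1e-3 umol/kg."""
    p = sulfidic_parcel
    p2 = solve(S=p.S, T=p.T, P=p.P, TA=p.TA, DIC=p.DIC, PO4_T=p.PO4_T,
               H2S_T=p.H2S_T, NH3_T=p.NH3_T)
    ta = total_alkalinity(p2.pH, p2.DIC, p.S, p.T, p.P, ph_scale="nbs",
                          PO4_T=p.PO4_T, H2S_T=p.H2S_T, NH3_T=p.NH3_T)
    assert ta == pytest.approx(p.TA, abs=1e-3)


@pytest.mark.parametrize("pair", [("TA", "DIC"), ("DIC", "pH"),
                                  ("TA", "pH"), ("TA", "pCO2"),
                                  ("DIC", "pCO2"), ("pH", "pCO2")])
def test_solver_involutive_across_pairs(pair, sulfidic_parcel):
    """Any two outputs of a solved parcel recover the others."""
    p = sulfidic_parcel
    known = {k: getattr(p, k) for k in pair}
    q = solve(S=p.S, T=p.T, P=p.P, PO4_T=p.PO4_T, H2S_T=p.H2S_T,
              NH3_T=p.NH3_T, **known)
    assert q.TA == pytest.approx(p.TA, abs=0.5)
    assert q.DIC == pytest.approx(p.DIC, abs=0.5)
    assert q.pH == pytest.approx(p.pH, abs=0.005)


def test_extension_terms_vanish_at_zero_totals():
    """With H2S_T = NH3_T = 0 the extended expression equals an
    independently hand-written unextended TA."""
    S, T = 15.145, 25.36
    ks = compute_constants(S, T, need_nh3=False, need_h2s=False)
    pH = 7.354
    h = 10.0 ** -pH / ks.fH / ks.free_to_sws
    dic = 1767.7
    denC = h * h + ks.K1 * h + ks.K1 * ks.K2
    expected = (dic * ks.K1 * (h + 2 * ks.K2) / denC
                + 1e6 * ks.BT * ks.KB / (ks.KB + h)
                + 1e6 * ks.KW / h - 1e6 * h
                - 1e6 * ks.SO4T * h / (ks.KS + h)
                - 1e6 * ks.FT * h / (ks.KF + h))
    got = total_alkalinity(pH, dic, S, T)
    assert got == pytest.approx(expected, abs=1e-9)


def test_alkalinity_strictly_decreasing_in_h():
    """Monotonicity in [H+] guarantees a unique solver root."""
    import numpy as np
    phs = np.linspace(2.5, 11.5, 60)
    tas = [total_alkalinity(ph, 1900.0, 18.6, 25.0, ph_scale="free",
                            PO4_T=3.5, H2S_T=37.8, NH3_T=13.6)
           for ph in phs]
    assert all(a < b for a, b in zip(tas, tas[1:]))  # increasing in pH


@settings(max_examples=30, deadline=None)
@given(x=st.floats(min_value=1.0, max_value=80.0))
def test_acid_and_co2_additions_lower_ph(x):
    p = solve(S=19.87, T=25.0, TA=1771.1, DIC=1658.5)
    assert resolve(p, dTA=-x).pH < p.pH      # strong acid
    assert resolve(p, dDIC=+x).pH < p.pH     # CO2 addition


def test_buffer_factors_analytic_vs_numeric(sulfidic_parcel, bottom_parcel):
    for p in (sulfidic_parcel, bottom_parcel):
        a = buffer_factors(p)
        n = buffer_factors(p, numeric=True)
        assert a.beta_DIC == pytest.approx(n.beta_DIC, rel=5e-3)
        assert a.beta_TA == pytest.approx(n.beta_TA, rel=5e-3)
        assert a.beta_DIC > 0 and a.beta_TA < 0


def test_offshore_water_better_buffered_than_bay(chesapeake_lines):
    ta_line, dic_line = chesapeake_lines
    ocean = solve(S=34.0, T=25.0, TA=2350.0, DIC=2030.0)
    bay = solve(S=15.0, T=25.0, TA=float(ta_line(15.0)),
                DIC=float(dic_line(15.0)))
    assert buffer_factors(ocean).beta_DIC > buffer_factors(bay).beta_DIC


def test_beta_minimum_near_ta_dic_crossover(chesapeake_lines):
    """Along the mixing gradient the buffer minimum sits near TA:DIC=1."""
    import numpy as np
    ta_line, dic_line = chesapeake_lines
    grid = np.arange(1.0, 30.0, 0.5)
    betas = [buffer_factors(solve(S=float(s), T=25.0,
                                  TA=float(ta_line(s)) ,
                                  DIC=float(dic_line(s)) + 100.0)).beta_DIC
             for s in grid]
    s_min = grid[int(np.argmin(betas))]
    ratio = float(ta_line(s_min)) / (float(dic_line(s_min)) + 100.0)
    assert abs(ratio - 1.0) < 0.05


def test_omega_mineral_ratio(bottom_parcel):
    """Omega_cal/Omega_arag equals the Ksp ratio exactly; the ratio is
    roughly the canonical 1.5 (it drifts up toward low salinity in the
    Mucci solubility fits: ~1.52 at S=35, ~1.61 at S=20)."""
    om_arag, om_cal = saturation_state(bottom_parcel)
    ks = bottom_parcel.constants
    assert om_cal / om_arag == pytest.approx(ks.Ksp_arag / ks.Ksp_cal,
                                             rel=1e-12)
    assert 1.4 < om_cal / om_arag < 1.7


def test_ph_scale_conversions():
    assert convert_ph_scale(7.6, "total", "total", 20.0, 25.0) == 7.6
    back = convert_ph_scale(
        convert_ph_scale(7.6, "free", "total", 20.0, 25.0),
        "total", "free", 20.0, 25.0)
    assert back == pytest.approx(7.6, abs=1e-10)
    # glass-electrode NBS pH sits roughly a tenth of a unit above total
    offset = 7.476 - convert_ph_scale(7.476, "nbs", "total", 18.618, 25.0)
    assert 0.05 < offset < 0.2
    with pytest.raises(ValueError):
        convert_ph_scale(7.6, "nbs", "martian", 20.0, 25.0)


def test_infeasible_and_invalid_inputs():
    with pytest.raises(InfeasibleState):
        solve(S=20.0, T=25.0, TA=-20000.0, DIC=2000.0)
    with pytest.raises(ValueError):
        solve(S=20.0, T=25.0, TA=2000.0)          # one known only
    with pytest.raises(ValueError):
        total_alkalinity(7.5, 2000.0, 20.0, 25.0, H2S_T=-1.0)
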