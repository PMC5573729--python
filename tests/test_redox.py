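"""Redox reaction stoichiometry and pathway traces."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estucarb.redox_pathways import (REACTIONS, aerobic_respiration,
                                     carbonate_dissolution, close_budget,
                                     denitrification_bound, mix_parcels,
                                     oxidize_reduced_species,
                                     run_sequential_pathway,
                                     run_simultaneous_pathway,
                                     sulfate_reduction)
from estucarb.speciation import solve


@pytest.mark.parametrize("dO2,ddic,dta", [
    (231.7, 178.0, -28.5),   # full saturation inventory of the bay water
    (216.0, 165.9, -26.6),   # full inventory of the offshore water
    (0.0, 0.0, 0.0),
])
def test_aerobic_respiration_redfield_ratios(bottom_parcel, dO2, ddic, dta):
    p = aerobic_respiration(bottom_parcel, dO2)
    assert p.DIC - bottom_parcel.DIC == pytest.approx(ddic, abs=0.05)
    assert p.TA - bottom_parcel.TA == pytest.approx(dta, abs=0.05)
    assert p.O2 == pytest.approx(bottom_parcel.O2 - dO2)


def test_aerobic_respiration_cannot_overdraw_o2(bottom_parcel):
    with pytest.raises(ValueError):
        aerobic_respiration(bottom_parcel, bottom_parcel.O2 + 1.0)


def test_sulfate_reduction_alkalinity(bottom_parcel):
    p = sulfate_reduction(bottom_parcel, 35.0)
    assert p.TA - bottom_parcel.TA == pytest.approx(80.6, abs=0.05)
    assert p.DIC - bottom_parcel.DIC == pytest.approx(70.0, abs=1e-9)
    assert p.H2S_T == pytest.approx(35.0)
    assert p.NH3_T == pytest.approx(35.0 * 16 / 53)
    assert sulfate_reduction(bottom_parcel, 0.0).TA == bottom_parcel.TA


def test_sulfate_reduction_per_h2s_vs_per_c_conventions(bottom_parcel):
    """The per-sulfide form gives dTA/dDIC = (2 + 16/53)/2 = 1.1509...,
    the per-carbon molar ratio gives 117/106 x 2/2 = 1.142; both exist,
    per-sulfide is the default."""
    a = sulfate_reduction(bottom_parcel, 1.0, ta_mode="per_h2s")
    b = sulfate_reduction(bottom_parcel, 1.0, ta_mode="per_c")
    ra = (a.TA - bottom_parcel.TA) / (a.DIC - bottom_parcel.DIC)
    rb = (b.TA - bottom_parcel.TA) / (b.DIC - bottom_parcel.DIC)
    assert ra == pytest.approx((2 + 16 / 53) / 2, abs=1e-12)
    assert rb == pytest.approx(121 / 106, abs=1e-12)
    with pytest.raises(ValueError):
        sulfate_reduction(bottom_parcel, 1.0, ta_mode="bogus")


def test_carbonate_dissolution_two_to_one(bottom_parcel):
    p = carbonate_dissolution(bottom_parcel, 115.3)
    assert p.TA - bottom_parcel.TA == pytest.approx(115.3)
    assert p.DIC - bottom_parcel.DIC == pytest.approx(57.65)
    assert p.pH > bottom_parcel.pH
    assert p.omega_arag > bottom_parcel.omega_arag
    with pytest.raises(ValueError):
        carbonate_dissolution(bottom_parcel, -1.0)


def test_budget_closure_attributes_cd_share():
    cd, frac = close_budget(167.3, -28.543, 80.566)
    assert cd == pytest.approx(115.3, abs=0.05)
    assert frac == pytest.approx(0.69, abs=0.02)
    assert close_budget(0.0, 0.0, 0.0)[0] == 0.0


def test_oxidation_strips_two_ta_per_mole(bottom_parcel):
    start = sulfate_reduction(bottom_parcel, 20.0)
    amounts = {"H2S": 15.0, "NH4": 6.0, "Mn": 5.0, "Fe": 4.0}
    p = oxidize_reduced_species(start, amounts)
    assert p.TA - start.TA == pytest.approx(-60.0)
    assert p.H2S_T == pytest.approx(start.H2S_T - 15.0)
    assert p.NH3_T == pytest.approx(start.NH3_T - 6.0)
    # O2 demand: 2*15 + 2*6 + 0.5*5 + 0.25*4 = 45.5
    assert p.O2 == pytest.approx(start.O2 - 45.5)
    assert p.pH < start.pH
    assert oxidize_reduced_species(start, {}).TA == start.TA


def test_oxidation_cannot_exceed_inventory(bottom_parcel):
    with pytest.raises(ValueError):
        oxidize_reduced_species(bottom_parcel, {"H2S": 1.0})


def test_oxidation_acidifies_ph_minimum_water():
    """Removing 30-60 umol/kg of TA from the pH-minimum parcel lowers
    pH by 0.108-0.202 units."""
    base = solve(S=15.145, T=25.36, P=12.54, DIC=1767.7, pH=7.354,
                 ph_scale="nbs", H2S_T=2.0)
    p30 = solve(S=15.145, T=25.36, P=12.54, TA=base.TA - 30.0,
                DIC=1767.7, H2S_T=2.0)
    p60 = solve(S=15.145, T=25.36, P=12.54, TA=base.TA - 60.0,
                DIC=1767.7, H2S_T=2.0)
    assert base.pH - p30.pH == pytest.approx(0.108, abs=0.02)
    assert base.pH - p60.pH == pytest.approx(0.202, abs=0.02)


@settings(max_examples=25, deadline=None)
@given(f=st.floats(min_value=0.0, max_value=1.0))
def test_mixing_is_conservative_in_every_conservative_field(f):
    a = solve(S=19.87, T=25.0, TA=1771.1, DIC=1658.5, H2S_T=35.0,
              NH3_T=10.0, O2=0.0)
    b = solve(S=12.0, T=25.0, TA=1500.0, DIC=1430.0, O2=230.0)
    m = mix_parcels(a, b, f)
    for attr in ("S", "T", "TA", "DIC", "H2S_T", "NH3_T", "O2"):
        lin = f * getattr(a, attr) + (1 - f) * getattr(b, attr)
        assert getattr(m, attr) == pytest.approx(lin, abs=1e-9)


def test_mixing_halves_reduced_species_and_is_identity_at_f1():
    a = solve(S=19.87, T=25.0, TA=1771.1, DIC=1658.5, H2S_T=50.0,
              NH3_T=10.0, O2=0.0)
    b = solve(S=19.87, T=25.0, TA=1700.0, DIC=1600.0, O2=230.0)
    m = mix_parcels(a, b, 0.5)
    assert m.H2S_T + m.NH3_T == pytest.approx(30.0)
    assert mix_parcels(a, b, 1.0).TA == a.TA
    with pytest.raises(ValueError):
        mix_parcels(a, b, 1.5)


def test_sequential_pathway_reproduces_budget(bottom_parcel):
    tr = run_sequential_pathway(bottom_parcel)
    assert tr.cumulative_dDIC == pytest.approx(305.6, abs=0.1)
    assert tr.cumulative_dTA == pytest.approx(167.3, abs=0.1)
    df = tr.to_frame()
    ar = df[df.step.str.startswith(("initial", "AR"))]
    # pH and Omega strictly decreasing while O2 is consumed
    assert ar["pH"].is_monotonic_decreasing
    assert ar["omega_arag"].is_monotonic_decreasing
    mid = df[df.step == "AR 50% O2"].iloc[0]
    assert mid["pH"] == pytest.approx(7.629, abs=0.03)
    assert mid["omega_arag"] == pytest.approx(0.65, abs=0.1)


def test_zero_amount_pathway_is_flat(bottom_parcel):
    tr = run_sequential_pathway(bottom_parcel, dO2_total=0.0,
                                h2s_produced=0.0, cd_dTA=0.0,
                                o2_checkpoints=[1.0])
    assert tr.cumulative_dDIC == 0.0 and tr.cumulative_dTA == 0.0


def test_pathways_are_path_independent_in_cumulative_deltas(bottom_parcel):
    seq = run_sequential_pathway(bottom_parcel)
    sim = run_simultaneous_pathway(bottom_parcel)
    assert sim.cumulative_dDIC == pytest.approx(seq.cumulative_dDIC,
                                                abs=1e-9)
    assert sim.cumulative_dTA == pytest.approx(seq.cumulative_dTA,
                                               abs=1e-9)


def test_simultaneous_cd_buffers_intermediate_ph(bottom_parcel):
    """Dissolving CaCO3 before anoxia keeps pH above the sequential
    trace at the same O2 level."""
    seq = run_sequential_pathway(bottom_parcel).to_frame()
    sim = run_simultaneous_pathway(bottom_parcel).to_frame()
    ph_seq_0 = seq.loc[seq.step == "AR 0% O2", "pH"].iloc[0]
    ph_sim_0 = sim.loc[sim.step == "CD @0% O2", "pH"].iloc[0]
    assert ph_sim_0 > ph_seq_0


def test_empty_schedule_reduces_to_sequential(bottom_parcel):
    a = run_simultaneous_pathway(bottom_parcel, schedule={})
    b = run_sequential_pathway(bottom_parcel)
    assert a.final["pH"] == b.final["pH"]


def test_bad_schedule_rejected(bottom_parcel):
    with pytest.raises(ValueError):
        run_simultaneous_pathway(bottom_parcel, schedule={0.5: 0.4})


def test_denitrification_bound_scaling():
    ddic, dta = denitrification_bound(70.0, 100.0, 10.0, 1012.0)
    assert ddic == pytest.approx(17.0, abs=1.0)
    assert dta == pytest.approx(16.0, abs=1.0)
    assert denitrification_bound(0.0, 100.0, 10.0) == (0.0, 0.0)
    half = denitrification_bound(70.0, 100.0, 20.0, 1012.0)
    assert half[0] == pytest.approx(ddic / 2)
    with pytest.raises(ValueError):
        denitrification_bound(70.0, 100.0, 0.0)
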