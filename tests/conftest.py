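import pytest

from estucarb import Endmember, fit_mixing_line, solve


@pytest.fixture(scope="session")
def chesapeake_lines():
    """The river-ocean conservative mixing lines of the bay."""
    river = Endmember("river", S=0.189, TA=1089.2, DIC=1115.1)
    ocean = Endmember("ocean", S=33.618, TA=2248.4, DIC=2037.9)
    return (fit_mixing_line(river, ocean, "TA"),
            fit_mixing_line(river, ocean, "DIC"))


@pytest.fixture(scope="session")
def bottom_parcel(chesapeake_lines):
    """Pre-anoxia bottom water at S = 19.87 on the mixing lines, with a
    full saturation O2 inventory as printed in the pathway simulation."""
    ta_line, dic_line = chesapeake_lines
    return solve(S=19.87, T=25.0, TA=float(ta_line(19.87)),
                 DIC=float(dic_line(19.87)), O2=231.7)


@pytest.fixture(scope="session")
def sulfidic_parcel():
    """The day-4 sulfidic mid-depth parcel of the local CO2-uptake
    worked example (S=18.618, 17 m, H2S and NH3 present)."""
    return solve(S=18.618, T=25.28, P=17.0, DIC=1933.8, pH=7.476,
                 ph_scale="nbs", PO4_T=3.5, H2S_T=37.79, NH3_T=13.6)
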