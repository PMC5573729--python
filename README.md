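# estucarb

Carbonate-system chemistry for low-oxygen estuarine waters: an extended
marine CO₂-system solver that includes the H₂S/HS⁻ and NH₄⁺/NH₃ acid–base
couples, plus the redox-pathway, river–ocean mixing and air–sea CO₂ flux
machinery needed to analyse acidification in seasonally anoxic estuaries.

## The problem

Eutrophic, stratified estuaries develop anoxic bottom water every summer.
Below the oxycline, sulfate reduction accumulates H₂S and NH₄⁺; when wind
or tidal mixing carries those reduced species back into oxygenated water,
their oxidation releases protons (2 H⁺ per mole oxidised), strips total
alkalinity, and carves a pH minimum just above the oxic–anoxic boundary.
At the same time the water column takes up atmospheric CO₂, respires
organic matter, and dissolves CaCO₃. Standard CO₂-system programs ignore
the reduced species, so in sulfidic water they mis-speciate alkalinity.
`estucarb` solves the full system:

    TA = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] + phosphate + silicate
       + [NH₃] + [HS⁻] − [H⁺]F − [HSO₄⁻] − [HF]

with   NH₃-Alk = [NH₃]T·K_NH₃/(K_NH₃+[H⁺])   and
H₂S-Alk = [H₂S]T·K_H₂S/(K_H₂S+[H⁺]), where K_NH₃ is from Clegg &
Whitfield (1995) and K_H₂S from Millero et al. (1988).

Any two of {TA, DIC, pH, pCO₂} fix the state. pH is handled on the free,
total, seawater and NBS scales (glass-electrode field pH is NBS).
Buffer factors β_DIC = −(ln10·∂pH/∂DIC)⁻¹ and β_TA = −(ln10·∂pH/∂TA)⁻¹
quantify how hard pH responds to CO₂ or acid additions.

On top of the solver:

- **redox pathways** — Redfield-stoichiometry aerobic respiration
  (ΔDIC/ΔO₂ = 106/138, ΔTA/ΔO₂ = −17/138), sulfate reduction
  (ΔTA = (2+16/53)·[H₂S]), CaCO₃ dissolution (ΔTA:ΔDIC = 2), oxidation
  of reduced species (ΔTA = −2 per mole), alkalinity budget closure, and
  sequential/simultaneous pathway traces of (O₂, DIC, TA, pH, Ω_arag);
- **estuary scenarios** — two-endmember conservative mixing lines,
  enrichment relative to them, atmospheric-equilibrium scenarios
  (preindustrial / present / 2100), pH(S) and β_DIC(S) curves, −ΔpH(S)
  acidification curves and the Maximum Estuarine Acidification Zone,
  TA:DIC crossover points;
- **gas exchange** — dry-xCO₂ → pCO₂ conversion, equilibrator
  temperature correction, Ho et al. (2006) gas transfer velocity, flux
  and flux→ΔDIC budgets;
- **interface** — CSV profile I/O, a synthetic stratified-station
  profile generator (oxycline, sulfidic bottom water, mixing event → pH
  minimum), and a CLI: `solve | pathway | scenario | flux | fixture`.

## Worked example

Speciate a sulfidic mid-depth parcel (S = 18.618 g kg⁻¹, 25.28 °C, 17 m)
from its measured DIC and electrode pH, with 37.79 µmol kg⁻¹ total H₂S
and 13.6 µmol kg⁻¹ total NH₄⁺ in solution:

```sh
estucarb solve --s 18.618 --t 25.28 --p 17 --dic 1933.8 --ph 7.476 \
               --po4 3.5 --h2s 37.79 --nh3 13.6
```

prints (columns abridged):

```
      TA    DIC    pH     pCO2  omega_arag     HS   NH3
1934.207 1933.8 7.476 2389.139       0.474 32.352 0.174
```

The extended alkalinity is 1934.2 µmol kg⁻¹ — of which ≈ 32 µmol kg⁻¹ is
HS⁻: a plain carbonate-system program would misattribute that to
carbonate alkalinity. The parcel is strongly CO₂-supersaturated
(pCO₂ ≈ 2400 µatm) and corrosive to aragonite (Ω ≈ 0.47).

Trace the bottom-water respiration → sulfate-reduction → dissolution
pathway from saturated mixing-line water at S = 19.87:

```sh
estucarb pathway --o2 231.7 --h2s 35 --cd-ta 115.3
```

The trace runs from pH 8.06 / Ω 1.56 down to pH 7.24 / Ω 0.26 at anoxia,
then SR and CaCO₃ dissolution rebuild alkalinity (+80.6 and +115.3
µmol kg⁻¹) for a cumulative ΔDIC = +305.6 and ΔTA = +167.3 µmol kg⁻¹.

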