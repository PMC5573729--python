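# Methods

## The extended acid–base model

A water parcel is described by salinity S (g kg⁻¹, practical salinity
taken at face value; no TEOS-10 conversion), temperature T (°C),
pressure P (dbar, numerically equal to depth in metres for the shallow
applications targeted here), total dissolved inorganic carbon DIC,
total alkalinity TA, and the totals of the minor acid–base systems:
phosphate, silicate, total sulfide [H₂S]T and total ammonium [NH₃]T
(all µmol kg⁻¹ of solution).

Total alkalinity follows the Dickson proton-condition definition,
extended with the two couples that matter in anoxic estuarine water:

    TA = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻]
       + [HPO₄²⁻] + 2[PO₄³⁻] − [H₃PO₄] + [SiO(OH)₃⁻]
       + [NH₃] + [HS⁻] − [H⁺]F − [HSO₄⁻] − [HF]

Only the first dissociation of H₂S is carried (S²⁻ is negligible above
pH 12), and NH₃/NH₄⁺ is a single couple. Organic alkalinity is not
modelled.

Given any two of {TA, DIC, pH, pCO₂} the solver returns the full
speciation; all five parameters of a solved parcel are mutually
consistent, and the speciated fractions of each total sum to that total
by construction.

### pH scales

All equilibrium is computed on the **free** hydrogen-ion scale;
conversions to total ([H]T = [H]F(1+ST/KS)), seawater
([H]SWS = [H]F(1+ST/KS+FT/KF)) and NBS (aH = fH·[H]SWS) scales happen at
the boundary. Reported pH defaults to NBS at the parcel temperature,
matching glass-electrode field practice. fH is the empirical Takahashi
(1982) activity factor (Peng variant available); because fH is an
activity coefficient for an ionic-medium scale, NBS pH carries the
largest formulation uncertainty of the scales — at estuarine salinity
NBS sits ≈ 0.15 above the total scale.

### Equilibrium constants

| constant | default source | alternatives |
|---|---|---|
| K0 (CO₂ solubility) | Weiss (1974) | — |
| K1, K2 | Millero (2010), S 0–50 | Millero 2006, Cai–Wang 1998, Lueker 2000, Mehrbach/DM87 |
| KB | Dickson (1990b) | — |
| KW | Millero (1995) | — |
| KP1–3, KSi | Yao & Millero (1995) | — |
| KS | Dickson (1990a) | — |
| KF | Dickson & Riley (1979) | — |
| K_NH₃ | Clegg & Whitfield (1995), S 0–40, t −2–40 °C | — |
| K_H₂S | Millero et al. (1988), S 0–40, t 0–35 °C | — |
| Ksp (calcite, aragonite) | Mucci (1983) | — |
| B_T | Uppström (1974) | Lee et al. 2010 |
| fH | Takahashi (1982) | Peng (1987) |

Millero (2010) is the default carbonic-acid formulation because it is
valid over the full 0–50 salinity range an estuarine gradient spans;
the choice is configurable (`ConstantOptions`) and a machine-readable
dump of every resolved constant is available for provenance
(`ConstantSet.as_dict`, `estucarb solve --dump-constants`). The K_NH₃
and K_H₂S validity windows are enforced: requesting them outside S 0–40
(or t outside their fitted ranges) raises a range violation instead of
extrapolating silently.

Pressure corrections use the Millero (1995) ΔV/Δκ molal-volume forms,
applied on the seawater scale and converted back, including the NH₃ and
H₂S couples; at P = 0 every constant equals its surface formulation
bit-for-bit. pCO₂ is converted to fugacity with the Weiss (1974) virial
coefficient (a 0.3 % effect at 25 °C). Calculations for samples
measured at 25 °C but collected at depth are performed at in-situ
temperature and depth-as-pressure; at ≤ 20 m the pressure effect on a
computed TA is < 1 µmol kg⁻¹, so either convention would do.

### Solver numerics

pH from (TA, DIC) is found by bracketed Newton iteration on pH over
(2, 12): Newton steps on the analytic dTA/dpH, with bisection fallback
whenever a step leaves the current bracket; deterministic start at
pH 7, tolerance 1e-8 in pH (≲ 1e-5 µmol kg⁻¹ in TA). TA is strictly
increasing in pH, so the root is unique; if the residual does not
change sign over (2, 12) an `InfeasibleState` is raised rather than
returning a spurious value. (TA, pCO₂) uses plain bisection on the same
residual with DIC eliminated through [CO₂]; (DIC, pCO₂) reduces to a
quadratic in [H⁺].

### Buffer factors

β_DIC = −(ln10·∂pH/∂DIC)⁻¹ at constant TA and
β_TA = −(ln10·∂pH/∂TA)⁻¹ at constant DIC are evaluated by implicit
differentiation of the **full** extended alkalinity expression (every
couple contributes, including NH₃ and HS⁻), not the truncated
carbonate+borate+water closed forms — so the analytic values agree with
central-difference numeric derivatives (±0.1 µmol kg⁻¹ perturbations,
re-solved) to ~1e-7 relative. The numeric path is retained as an
independent check. β_DIC is positive in normal waters and smallest —
pH most fragile — where TA:DIC ≈ 1; β_TA is negative and of similar
magnitude. Near the crossover singularity the factors are flagged
(`near_singular`) instead of returning ±∞.

## Redox stoichiometry

Organic matter is Redfield (CH₂O)₁₀₆(NH₃)₁₆(H₃PO₄); full aerobic
oxidation including nitrification consumes 138 O₂ per 106 C (the
106-O₂ convention without nitrification is *not* used), releasing
16 HNO₃ + 1 H₃PO₄, hence ΔTA/ΔO₂ = −17/138. Sulfate reduction produces
HCO₃⁻ and HS⁻ 2:1 per H₂S plus 16/53 NH₃; its alkalinity effect is
implemented in two conventions: per-sulfide ΔTA = (2+16/53)·[H₂S]
(default, the natural form when the observable is accumulated H₂S) and
per-carbon ΔTA/ΔDIC = 121/106 = 1.142; they differ below 1 µmol kg⁻¹
for the amounts relevant here. CaCO₃ dissolution adds TA:DIC = 2:1.
Oxidation of H₂S, NH₄⁺, Mn²⁺ and Fe²⁺ each strip 2 TA per mole and draw
2, 2, 0.5 and 0.25 O₂; the metal couples are implemented but excluded
from default budgets (their bottom-water inventories are an order of
magnitude below the sulfide signal).

Every reaction op changes the conservative fields by exact rational
stoichiometry and re-solves the parcel, so pH and Ω always come from
equilibrium, never from bookkeeping. Mixing is by mass fraction
(described as volume mixing in common usage; the distinction is < 1 %
at these densities). Cumulative ΔTA/ΔDIC of a pathway are
path-independent; sequential vs simultaneous traces differ only in
their intermediate loci. Budget closure attributes to CaCO₃ dissolution
whatever observed TA excess aerobic respiration and sulfate reduction
cannot explain.

Denitrification enters only as an upper bound: an areal rate
(µmol m⁻² h⁻¹) integrated over time, spread over the water column, with
ΔTA/ΔDIC = (84.8+16−1)/106.

## Estuary scenarios

Endmembers are (S, TA, DIC[, pCO₂]) pairs; mixing lines are exact
two-point fits. Scenario curves follow three conventions worth making
explicit: (1) anthropogenic CO₂ enters only through the ocean
endmember — the ocean is re-equilibrated to the scenario atmosphere
(holding its TA) before mixing, while river water, already far above
atmospheric pCO₂, keeps its DIC; (2) respiratory CO₂ is added *after*
mixing at every grid salinity, either as a fixed DIC increment or as
complete consumption of the local O₂ saturation (which grows weakly
toward low salinity), with the −17/138 TA co-change; (3) local
atmospheric uptake, CaCO₃ dissolution and sulfate reduction are
excluded from scenario curves by default — they are separate terms of
the budget, handled by the redox module. The default salinity grid is
0.1 g kg⁻¹. The −ΔpH(S) curve between two scenarios is an accumulated
change; β_DIC(S) is a pointwise sensitivity — their minima need not
(and for the Chesapeake endmembers do not) coincide.

Two endmember sets ship with the package: Susquehanna/Chesapeake (the
river DIC is 1115.1 µmol kg⁻¹ on the observation-fit mixing line but
1135 in the scenario set — both determinations are kept, each used for
its own purpose) and Mississippi/Gulf-of-Mexico.

## Gas exchange

Dry mole fractions convert to partial pressures via the Weiss & Price
(1980) seawater vapor pressure; the equilibrator-to-SST correction is
the empirical exp(0.043·ΔT). The gas transfer velocity is the Ho et al.
(2006) quadratic k₆₀₀ = 0.266 u² (cm h⁻¹), rescaled by (Sc/600)^(−1/2)
with the Wanninkhof (1992) Schmidt-number polynomials interpolated
linearly in salinity; the coefficient is pluggable. The
wind-distribution factor C₂ = ⟨u²⟩/⟨u⟩² is computed from the supplied
wind series by default (a quadratic k under a fluctuating wind exceeds
k at the mean wind) or can be fixed. Fluxes are computed per record and
then averaged — the mean of products, not the product of means.
Negative flux = uptake by the water. Flux-to-DIC budgets spread the
areal flux over a stated depth and density.

## Oxygen solubility

Air-saturation O₂ is the Garcia & Gordon (1992) combined fit (Benson &
Krause data), valid S 0–42, t 0–40 °C, in µmol kg⁻¹ at 1 atm moist
atmosphere. It is strictly decreasing in both S and T over that range.

## The synthetic profile generator

`generate_fixture_profile` emulates one summer cast of a stratified
eutrophic estuary: salinity rising across a pycnocline, O₂ at
saturation above the oxycline and zero below, sulfide and ammonium
(16/53 of the sulfide) accumulating beneath it, TA and DIC riding the
river–ocean mixing lines plus respiration, sulfate-reduction and
CaCO₃-dissolution enrichment scaled by the local anoxia, and —
optionally — a recent mixing event that has entrained bottom water into
the layer just above the oxycline where its reduced species have been
oxidised (−2 TA per mole). pH is always computed by the solver from TA
and DIC. Gaussian measurement-like jitter (default 0.1 % relative,
seeded, applied to S, O₂ and H₂S only) makes casts realistic without
touching the chemistry.

What it does *not* emulate: time dependence and oxidation kinetics (the
"mixing event" is an imposed end-state, not a rate process), horizontal
advection, sediment fluxes, or real covariance structure of field
noise. Tests passing on these fixtures therefore demonstrate that the
*chemistry* — speciation, stoichiometry, the emergence of a pH minimum
above the oxycline when and only when reduced species are supplied —
behaves correctly; they say nothing about transport or kinetics in a
real water column.

## Degenerate inputs and edge behaviour

Zero totals reduce the extended TA expression exactly to the
unextended one. Zero-extent reactions are identities. Empty
simultaneous-dissolution schedules reduce to the sequential pathway;
schedule fractions must sum to 1. Negative concentrations, overdrawn
O₂ or reduced-species inventories, non-monotone cast depths, equal
endmember salinities and vapor pressure exceeding barometric pressure
all raise explicit errors.

## Known limitations

- NBS-scale results inherit the empirical fH factor; scale-internal
  (free/total) results are the thermodynamically clean ones.
- The carbonic-acid constant choice moves computed TA by a few
  µmol kg⁻¹ and pH by ~0.01–0.02 across published formulations; the
  default is one defensible choice, not the elimination of that
  uncertainty.
- Buffer factors assume the parcel stays in equilibrium; no kinetic
  limitation of CO₂ hydration or H₂S oxidation is modelled anywhere.
- The estuary model is strictly two-endmember and steady-state: no
  hydrodynamics, no residence-time distribution.
- Mn/Fe oxidation is implemented with the written 2 H⁺ per mole;
  real oxidation pathways pass through intermediates with different
  instantaneous proton yields.
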