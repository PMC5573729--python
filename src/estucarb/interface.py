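"""Profile I/O and synthetic vertical-profile fixtures.

A :class:`ProfileTable` is one CTD/bottle cast: depth-ordered rows of
(depth, S, T, O2, DIC, TA, pH, H2S_T, NH3_T, PO4_T) with station
metadata.  :func:`generate_fixture_profile` builds a synthetic cast in
the image of a stratified eutrophic-estuary station in peak summer: an
oxycline across which O2 drops to zero, sulfide accumulating below it,
TA/DIC riding the river-ocean mixing lines plus respiration, sulfate
reduction and CaCO3-dissolution enrichment at depth, and (optionally) a
wind-mixing event that has carried reduced species up into oxygenated
water where their oxidation has stripped alkalinity -- producing the
characteristic mid-depth pH minimum.  pH is always computed by the
speciation solver from TA and DIC, never prescribed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ConstantOptions, o2_saturation
from .estuary_scenarios import (CHESAPEAKE_OCEAN, SUSQUEHANNA,
                                fit_mixing_line)
from .redox_pathways import REACTIONS
from .speciation import solve

__all__ = ["ProfileTable", "read_profiles", "generate_fixture_profile"]

log = logging.getLogger("estucarb")

REQUIRED_COLUMNS = ("depth", "S", "T", "DIC", "TA")
OPTIONAL_COLUMNS = ("O2", "pH", "H2S_T", "NH3_T", "PO4_T")


@dataclass
class ProfileTable:
    """A validated, unit-tagged vertical profile (one cast).

    Concentrations in umol kg-1, depth in m, pH on the NBS scale at the
    row temperature.
    """

    data: pd.DataFrame
    station: str = ""
    date: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"profile missing columns {sorted(missing)}")
        depths = self.data["depth"].to_numpy()
        if not (np.diff(depths) > 0).all():
            raise ValueError("depth must be strictly increasing in a cast")
        for col in OPTIONAL_COLUMNS:
            if col not in self.data.columns:
                if col == "H2S_T":
                    log.warning("profile has no H2S column; assuming 0")
                self.data[col] = 0.0 if col != "pH" else np.nan

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# station: {self.station}\n# date: {self.date}\n")
            self.data.to_csv(fh, index=False)

    def __len__(self) -> int:
        return len(self.data)


def read_profiles(path, column_map: dict[str, str] | None = None,
                  station: str = "", date: str = "") -> ProfileTable:
    """Read a cast CSV (optionally renaming columns via ``column_map``,
    {file column -> canonical name}); leading ``#`` lines carry
    metadata."""
    meta = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if column_map:
        df = df.rename(columns=column_map)
    return ProfileTable(df, station=station or meta.get("station", ""),
                        date=date or meta.get("date", ""), meta=meta)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_fixture_profile(seed: int = 0, *,
                             n_depths: int = 23,
                             max_depth: float = 22.0,
                             oxycline_depth: float = 11.0,
                             oxycline_width: float = 1.2,
                             bottom_h2s: float = 35.0,
                             surface_S: float = 12.0,
                             bottom_S: float = 20.0,
                             T: float = 25.0,
                             cd_dTA_bottom: float = 115.3,
                             mixing_event: bool = True,
                             mixed_fraction: float = 0.5,
                             noise: float = 0.001,
                             options: ConstantOptions | None = None,
                             ) -> ProfileTable:
    """Deterministic-by-seed synthetic summer cast.

    The water column mixes from ``surface_S`` to ``bottom_S`` across a
    pycnocline at the oxycline depth.  Above the oxycline O2 is at
    saturation; below, respiration has consumed it fully (AR
    stoichiometry), sulfate reduction has produced ``bottom_h2s`` of
    sulfide (per-sulfide TA stoichiometry) and CaCO3 dissolution has
    added ``cd_dTA_bottom`` of alkalinity.  With ``mixing_event`` a
    recent wind event has entrained a ``mixed_fraction`` of bottom water
    into the layer just above the oxycline, where its reduced species
    have been oxidised (TA -2 per mole), carving a pH minimum between
    the oxycline and the surface.  ``noise`` is the relative sd of the
    measurement-like jitter applied to S, O2 and H2S (never to pH, which
    is solved).
    """
    if bottom_h2s < 0 or oxycline_depth <= 0 or max_depth <= 0:
        raise ValueError("profile parameters must be positive")
    rng = np.random.default_rng(seed)
    z = np.linspace(0.5, max_depth, n_depths)
    ta_line = fit_mixing_line(SUSQUEHANNA, CHESAPEAKE_OCEAN, "TA")
    dic_line = fit_mixing_line(SUSQUEHANNA, CHESAPEAKE_OCEAN, "DIC")
    ar, sr = REACTIONS["AR"], REACTIONS["SR"]

    S = surface_S + (bottom_S - surface_S) \
        * _sigmoid((z - oxycline_depth) / (2.0 * oxycline_width))
    S *= 1.0 + noise * rng.standard_normal(z.size)
    o2_sat = np.array([o2_saturation(float(s), T) for s in S])
    anoxia = _sigmoid((z - oxycline_depth) / oxycline_width)  # 0 top, 1 deep
    o2 = o2_sat * (1.0 - anoxia)
    o2 = np.clip(o2 * (1.0 + noise * rng.standard_normal(z.size)), 0, None)

    h2s = bottom_h2s * _sigmoid((z - oxycline_depth - 2.0) / oxycline_width)
    h2s = np.clip(h2s * (1.0 + noise * rng.standard_normal(z.size)), 0, None)
    nh3 = h2s * sr.dNH3_T / sr.dH2S_T

    ar_o2 = o2_sat * anoxia                       # O2 respired at depth
    dTA = ar_o2 * ar.dTA + h2s * sr.dTA / sr.dH2S_T + cd_dTA_bottom * anoxia
    dDIC = ar_o2 * ar.dDIC + h2s * sr.dDIC / sr.dH2S_T \
        + 0.5 * cd_dTA_bottom * anoxia

    if mixing_event and bottom_h2s > 0:
        # reduced species carried above the oxycline and oxidised there
        band = np.exp(-0.5 * ((z - (oxycline_depth - 2.0))
                              / (1.5 * oxycline_width)) ** 2)
        band *= (z < oxycline_depth)
        reduced_bottom = bottom_h2s * (1.0 + sr.dNH3_T / sr.dH2S_T)
        oxidised = mixed_fraction * reduced_bottom * band
        dTA = dTA - 2.0 * oxidised
        # the mixed-up carbon arrived with the bottom enrichment signature
        dDIC = dDIC + mixed_fraction * band \
            * (o2_sat * ar.dDIC + bottom_h2s * sr.dDIC / sr.dH2S_T)

    rows = []
    for i in range(z.size):
        parcel = solve(S=float(S[i]), T=T, P=float(z[i]),
                       TA=float(ta_line(S[i]) + dTA[i]),
                       DIC=float(dic_line(S[i]) + dDIC[i]),
                       H2S_T=float(h2s[i]), NH3_T=float(nh3[i]),
                       O2=float(o2[i]), options=options)
        rows.append({"depth": float(z[i]), "S": parcel.S, "T": T,
                     "O2": parcel.O2, "DIC": parcel.DIC, "TA": parcel.TA,
                     "pH": parcel.pH, "H2S_T": parcel.H2S_T,
                     "NH3_T": parcel.NH3_T, "PO4_T": 0.0})
    return ProfileTable(pd.DataFrame(rows), station="synthetic-858",
                        date="synthetic",
                        meta={"seed": seed, "oxycline_depth": oxycline_depth,
                              "bottom_h2s": bottom_h2s})
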