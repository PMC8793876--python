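"""Pit and tracheid trait derivation from raw anatomical measurements.

Pit sealing traits from the three pit diameters (all in µm):

    TO = (DT - DPA) / DT        torus overlap
    MF = (DPM - DT) / DPM       margo flexibility
    VE = TO * MF                valve effect

Pit aperture resistance combines a Poiseuille channel term and an
orifice entry term.  The channel-term denominator is (pi * DPA)**4 —
i.e. pi**4 * DPA**4 — which is the convention required to reproduce the
reference subfamily means; the textbook pi * DPA**4 variant is available
behind ``convention='conventional'`` and yields values ~31x smaller for
the channel term.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PitGeometry",
    "DerivedPitTraits",
    "TracheidSection",
    "WoodSample",
    "derive_pit_traits",
    "pit_aperture_resistance",
    "hydraulic_diameter",
    "thickness_to_span",
    "tracheid_summaries",
    "wood_density",
    "pit_table",
    "tracheid_table",
    "wood_table",
    "build_trait_table",
]

#: dynamic viscosity of water at 20 degC, in MPa*s (0.001 Pa*s)
WATER_VISCOSITY_MPA_S = 1e-9

#: single pit border thickness as a fraction of the double wall: T_pa = 0.81 * 2 * Tw
PIT_BORDER_FRACTION = 0.81

MIN_TRACHEID_COUNT = 200


@dataclass(frozen=True)
class PitGeometry:
    """Pit membrane (DPM), torus (DT) and aperture (DPA) diameters, µm."""

    dpm: float
    dt: float
    dpa: float

    def is_valid(self) -> bool:
        return 0 < self.dpa < self.dt < self.dpm


@dataclass(frozen=True)
class DerivedPitTraits:
    to: float
    mf: float
    ve: float
    r_pa: float  # MPa s m^-3
    valid: bool = True


def derive_pit_traits(
    pit: PitGeometry,
    tw_um: float,
    eta_mpa_s: float = WATER_VISCOSITY_MPA_S,
    convention: str = "as_printed",
) -> DerivedPitTraits:
    """TO, MF, VE and R_PA for one pit; ``valid=False`` flags TO<=0 or MF<=0."""
    if pit.dpm <= 0 or pit.dt <= 0 or pit.dpa <= 0:
        raise ValueError(f"nonpositive pit dimension: {pit}")
    if tw_um <= 0:
        raise ValueError("wall thickness must be positive")
    to = (pit.dt - pit.dpa) / pit.dt
    mf = (pit.dpm - pit.dt) / pit.dpm
    ve = to * mf
    r_pa = pit_aperture_resistance(pit.dpa, tw_um, eta_mpa_s=eta_mpa_s, convention=convention)
    return DerivedPitTraits(to=to, mf=mf, ve=ve, r_pa=r_pa, valid=pit.is_valid())


def pit_aperture_resistance(
    dpa_um: float,
    tw_um: float,
    eta_mpa_s: float = WATER_VISCOSITY_MPA_S,
    convention: str = "as_printed",
) -> float:
    """Pit aperture resistance in MPa s m^-3.

    R_PA = 128 * T_pa * eta / (pi * DPA)**4 + 24 * eta / DPA**3
    with T_pa = 0.81 * 2 * Tw, lengths in m, eta in MPa*s.

    ``convention='conventional'`` divides the channel term by pi * DPA**4
    instead (Hagen-Poiseuille as usually written); it does NOT reproduce
    the reference subfamily means.
    """
    if dpa_um <= 0 or tw_um <= 0:
        raise ValueError("DPA and Tw must be positive")
    if eta_mpa_s < 0:
        raise ValueError("viscosity must be >= 0")
    dpa = dpa_um * 1e-6
    t_pa = PIT_BORDER_FRACTION * 2.0 * tw_um * 1e-6
    if convention == "as_printed":
        channel = 128.0 * t_pa * eta_mpa_s / (math.pi * dpa) ** 4
    elif convention == "conventional":
        channel = 128.0 * t_pa * eta_mpa_s / (math.pi * dpa**4)
    else:
        raise ValueError(f"unknown R_PA convention {convention!r}")
    orifice = 24.0 * eta_mpa_s / dpa**3
    return channel + orifice


def hydraulic_diameter(diameters_um) -> float:
    """Hagen-Poiseuille weighted diameter: fourth root of the mean fourth power."""
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter list")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    return float(np.mean(d**4) ** 0.25)


def thickness_to_span(tw_um: float, d_um: float) -> float:
    """TSR = (2*Tw / D)^2, the squared double-wall-to-lumen ratio."""
    if d_um <= 0:
        raise ValueError("lumen diameter must be positive")
    if tw_um <= 0:
        raise ValueError("wall thickness must be positive")
    return (2.0 * tw_um / d_um) ** 2


def diameters_from_areas(areas_um2) -> np.ndarray:
    """Equivalent circular diameter, Di = 2*sqrt(area/pi)."""
    a = np.asarray(areas_um2, dtype=float)
    if np.any(a <= 0):
        raise ValueError("lumen areas must be positive")
    return 2.0 * np.sqrt(a / math.pi)


@dataclass
class TracheidSection:
    """Per-zone tracheid measurements for one branch cross-section."""

    zone: str  # 'earlywood' | 'latewood' | 'whole'
    lumen_areas_um2: np.ndarray | None = None
    diameters_um: np.ndarray | None = None
    section_area_mm2: float = np.nan
    tw_um: float = np.nan

    def __post_init__(self):
        if self.zone not in ("earlywood", "latewood", "whole"):
            raise ValueError(f"unknown zone {self.zone!r}")
        if self.lumen_areas_um2 is None and self.diameters_um is None:
            raise ValueError("need lumen areas or diameters")
        if self.lumen_areas_um2 is not None:
            self.lumen_areas_um2 = np.asarray(self.lumen_areas_um2, dtype=float)
        if self.diameters_um is not None:
            self.diameters_um = np.asarray(self.diameters_um, dtype=float)

    def get_diameters(self) -> np.ndarray:
        if self.diameters_um is not None:
            return self.diameters_um
        return diameters_from_areas(self.lumen_areas_um2)


def tracheid_summaries(section: TracheidSection, min_count: int = MIN_TRACHEID_COUNT) -> dict:
    """Mean diameter D (µm), density TD (mm^-2), Dh, TSR for one section.

    Emits a warning flag (``count_ok=False``) below ``min_count``
    tracheids instead of failing.
    """
    di = section.get_diameters()
    count = int(di.size)
    count_ok = count >= min_count
    if not count_ok:
        warnings.warn(
            f"{section.zone}: only {count} tracheids (< {min_count}); trait averages may be noisy",
            stacklevel=2,
        )
    d_mean = float(np.mean(di))
    td = count / section.section_area_mm2 if section.section_area_mm2 > 0 else np.nan
    out = {
        "zone": section.zone,
        "D_um": d_mean,
        "TD_per_mm2": float(td),
        "Dh_um": hydraulic_diameter(di),
        "n_tracheids": count,
        "count_ok": count_ok,
    }
    if np.isfinite(section.tw_um) and section.tw_um > 0:
        out["Tw_um"] = float(section.tw_um)
        out["TSR"] = thickness_to_span(section.tw_um, d_mean)
    return out


@dataclass(frozen=True)
class WoodSample:
    mass_g: float
    volume_cm3: float

    @property
    def wd(self) -> float:
        return wood_density(self.mass_g, self.volume_cm3)


def wood_density(mass_g: float, volume_cm3: float) -> float:
    """Dry mass over fresh volume, g cm^-3; warns outside (0.2, 1.2)."""
    if mass_g <= 0 or volume_cm3 <= 0:
        raise ValueError("mass and volume must be positive")
    wd = mass_g / volume_cm3
    if not (0.2 < wd < 1.2):
        warnings.warn(f"wood density {wd:.3f} g/cm3 outside the 0.2-1.2 sanity band", stacklevel=2)
    return wd


# ---------------------------------------------------------------------------
# table-level drivers (CSV in -> branch/species trait tables)

def pit_table(
    pits: pd.DataFrame,
    tw_by_branch: pd.Series | None = None,
    eta_mpa_s: float = WATER_VISCOSITY_MPA_S,
    convention: str = "as_printed",
) -> pd.DataFrame:
    """Branch-level pit trait means from a per-pit table.

    ``pits`` columns: branch_id, species, DPM_um, DT_um, DPA_um.
    ``tw_by_branch`` maps branch_id to the wall thickness used in R_PA
    (earlywood by default in the pipeline).  Pits violating
    DPA < DT < DPM are excluded from the means; the exclusion count is
    reported per branch.
    """
    rows = []
    for (bid, sp), grp in pits.groupby(["branch_id", "species"], sort=False):
        tw = float(tw_by_branch.get(bid, np.nan)) if tw_by_branch is not None else np.nan
        per_pit = []
        excluded = 0
        for _, r in grp.iterrows():
            pit = PitGeometry(dpm=r["DPM_um"], dt=r["DT_um"], dpa=r["DPA_um"])
            t = derive_pit_traits(pit, tw if np.isfinite(tw) and tw > 0 else 1.0,
                                  eta_mpa_s=eta_mpa_s, convention=convention)
            if not t.valid:
                excluded += 1
                continue
            per_pit.append((t.to, t.mf, t.ve, t.r_pa, r["DPM_um"], r["DT_um"], r["DPA_um"]))
        if not per_pit:
            warnings.warn(f"branch {bid}: all {len(grp)} pits invalid, skipped", stacklevel=2)
            continue
        arr = np.array(per_pit)
        rows.append(
            {
                "branch_id": bid,
                "species": sp,
                "TO": arr[:, 0].mean(),
                "MF": arr[:, 1].mean(),
                "VE": arr[:, 2].mean(),
                "R_PA_MPa_s_m3": arr[:, 3].mean() if np.isfinite(tw) and tw > 0 else np.nan,
                "DPM_um": arr[:, 4].mean(),
                "DT_um": arr[:, 5].mean(),
                "DPA_um": arr[:, 6].mean(),
                "n_pits": len(per_pit),
                "n_excluded": excluded,
            }
        )
    return pd.DataFrame(rows)


def tracheid_table(trach: pd.DataFrame, min_count: int = MIN_TRACHEID_COUNT) -> pd.DataFrame:
    """Branch x zone tracheid summaries from a per-tracheid (or per-row-list) table.

    ``trach`` columns: branch_id, species, zone, lumen_area_um2 (one row
    per tracheid), section_area_mm2, Tw_um (constant within branch+zone).
    """
    rows = []
    for (bid, sp, zone), grp in trach.groupby(["branch_id", "species", "zone"], sort=False):
        section = TracheidSection(
            zone=zone,
            lumen_areas_um2=grp["lumen_area_um2"].to_numpy(),
            section_area_mm2=float(grp["section_area_mm2"].iloc[0]),
            tw_um=float(grp["Tw_um"].iloc[0]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summ = tracheid_summaries(section, min_count=min_count)
        summ.update({"branch_id": bid, "species": sp})
        rows.append(summ)
    return pd.DataFrame(rows)


def wood_table(wood: pd.DataFrame) -> pd.DataFrame:
    """Species-level wood density from mass/volume samples."""
    out = wood.copy()
    out["WD_g_cm3"] = [wood_density(m, v) for m, v in zip(out["mass_g"], out["volume_cm3"])]
    return out.groupby("species", as_index=False)["WD_g_cm3"].mean()


def build_trait_table(
    pits: pd.DataFrame,
    trach: pd.DataFrame,
    wood: pd.DataFrame | None = None,
    eta_mpa_s: float = WATER_VISCOSITY_MPA_S,
    convention: str = "as_printed",
    tw_zone_for_rpa: str = "earlywood",
    min_count: int = MIN_TRACHEID_COUNT,
) -> pd.DataFrame:
    """Species-level trait table from raw pit/tracheid/wood CSV frames.

    Derivation order: per pit/tracheid -> branch mean -> species mean.
    Pit traits come from earlywood measurements; Tw entering R_PA is
    taken from the ``tw_zone_for_rpa`` zone (configurable).  Whole-section
    tracheid values supply D, TD, Tw, TSR and Dh; earlywood/latewood
    values are carried with _E/_L suffixes.
    """
    tr = tracheid_table(trach, min_count=min_count)
    tw_zone = tr[tr["zone"] == tw_zone_for_rpa].set_index("branch_id")["Tw_um"]
    pt = pit_table(pits, tw_by_branch=tw_zone, eta_mpa_s=eta_mpa_s, convention=convention)

    pit_species = pt.groupby("species", as_index=False)[
        ["DPM_um", "DT_um", "DPA_um", "TO", "MF", "VE", "R_PA_MPa_s_m3"]
    ].mean()

    zone_frames = []
    suffix = {"whole": "", "earlywood": "_E", "latewood": "_L"}
    for zone, suf in suffix.items():
        z = tr[tr["zone"] == zone]
        if z.empty:
            continue
        cols = {"D_um": f"D{suf}_um", "TD_per_mm2": f"TD{suf}_per_mm2", "Tw_um": f"Tw{suf}_um", "TSR": f"TSR{suf}"}
        if zone == "whole":
            cols["Dh_um"] = "Dh_um"
        zs = z.groupby("species", as_index=False)[list(cols)].mean().rename(columns=cols)
        zone_frames.append(zs)

    table = pit_species
    for zf in zone_frames:
        table = table.merge(zf, on="species", how="outer")
    if wood is not None and not wood.empty:
        table = table.merge(wood_table(wood), on="species", how="left")
    return table
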