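"""Synthetic data generator: Yule trees, Brownian traits, anatomy and
centrifuge conductance datasets with known ground truth.

Species traits evolve by Brownian motion on a unit-depth Yule tree, with
a tunable white-noise fraction ``lam`` (lam=0: pure BM, expected
Blomberg K near 1; lam=1: i.i.d. noise, K near 0).  Bounded traits
(ratios, diameters) evolve on a logit scale and are mapped into their
target ranges, so the Brownian covariance structure is preserved without
truncation.

One master seed drives named substreams (tree, traits, anatomy, curves)
so individual components can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from xylemcomp.treeio import PhyloTree, write_newick
from xylemcomp.vcfit import ConductanceSeries

__all__ = [
    "SynthConfig",
    "simulate_tree",
    "simulate_traits",
    "generate_anatomy_table",
    "generate_cavitron_dataset",
    "generate_dataset",
]

_SUBSTREAMS = {"tree": 0, "traits": 1, "anatomy": 2, "curves": 3, "noise": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAMS[stream],)))


@dataclass
class SynthConfig:
    n_species: int = 28
    n_branches_vc: int = 5
    n_branches_anatomy: int = 3
    n_pits: int = 10
    n_tracheids: int = 250
    birth_rate: float = 1.0
    sigma2: float = 1.0
    lam: float = 0.0  # white-noise fraction per trait
    # trait target ranges (species-level means)
    p50_range: tuple[float, float] = (-7.8, -3.0)
    dpm_range: tuple[float, float] = (9.0, 15.0)
    to_range: tuple[float, float] = (0.27, 0.41)
    mf_range: tuple[float, float] = (0.45, 0.57)
    tw_range: tuple[float, float] = (2.3, 3.0)
    s_range: tuple[float, float] = (20.0, 60.0)
    ks_range: tuple[float, float] = (0.15, 0.68)
    wd_range: tuple[float, float] = (0.45, 0.60)
    pressure_step: float = -0.8  # decrement; -0.3 also used
    cv_curves: float = 0.05  # multiplicative conductance noise
    cv_anatomy: float = 0.02  # branch-level replicate noise
    sample_length_m: float = 0.27
    sapwood_area_m2: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lam must be in [0, 1]")
        for name in ("p50_range", "dpm_range", "to_range", "mf_range", "tw_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be (lo, hi) with lo < hi")
        if not (0 < self.to_range[0] and self.to_range[1] < 1):
            raise ValueError("to_range must lie inside (0, 1)")
        if not (0 < self.mf_range[0] and self.mf_range[1] < 1):
            raise ValueError("mf_range must lie inside (0, 1)")


def simulate_tree(config: SynthConfig | int, seed: int | None = None) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_species`` tips, rescaled to unit depth."""
    if isinstance(config, SynthConfig):
        n = config.n_species
        seed = config.seed if seed is None else seed
        rate = config.birth_rate
    else:
        n = int(config)
        rate = 1.0
        if seed is None:
            raise ValueError("seed required")
    rng = _rng(seed, "tree")

    parent = [-1]
    length = [0.0]
    children: list[list[int]] = [[]]

    def add(par: int) -> int:
        nid = len(parent)
        parent.append(par)
        length.append(0.0)
        children.append([])
        children[par].append(nid)
        return nid

    # grow: active lineages carry their birth time; split a random one
    t = 0.0
    active = [(add(0), 0.0), (add(0), 0.0)]  # root splits immediately
    while len(active) < n:
        t += rng.exponential(1.0 / (rate * len(active)))
        i = rng.integers(len(active))
        node, t0 = active.pop(i)
        length[node] = t - t0
        active.append((add(node), t))
        active.append((add(node), t))
    t += rng.exponential(1.0 / (rate * len(active)))
    for node, t0 in active:
        length[node] = t - t0

    labels = {}
    tree = PhyloTree(parent, length, children, labels, root=0)
    tips = tree.tips()
    width = len(str(len(tips)))
    for k, tip in enumerate(tips):
        labels[tip] = f"sp{k + 1:0{width}d}"
    # rescale to unit depth
    depth = tree.depths()[tips[0]]
    tree.length = [l / depth for l in tree.length]
    tree.validate()
    return tree


def _bm_on_tree(tree: PhyloTree, sigma2: float, rng: np.random.Generator) -> np.ndarray:
    """Brownian deviations at the tips (root value 0), tip order = tip_labels()."""
    x = np.zeros(tree.n_nodes)
    for node in reversed(tree.postorder()):
        p = tree.parent[node]
        if p >= 0:
            bl = tree.length[node]
            x[node] = x[p] + (rng.normal(0.0, np.sqrt(sigma2 * bl)) if bl > 0 else 0.0)
    return x[tree.tips()]


def simulate_traits(
    tree: PhyloTree,
    sigma2: float = 1.0,
    lam: float = 0.0,
    mean: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Species values: mean + sqrt(1-lam)*BM + sqrt(lam)*N(0, sigma2) i.i.d.

    On a unit-depth tree the tip variance is sigma2 regardless of lam.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lam must be in [0, 1]")
    if rng is None:
        rng = _rng(0 if seed is None else seed, "traits")
    bm = _bm_on_tree(tree, sigma2, rng)
    noise = rng.normal(0.0, np.sqrt(sigma2), size=len(bm))
    vals = mean + np.sqrt(1.0 - lam) * bm + np.sqrt(lam) * noise
    return pd.Series(vals, index=tree.tip_labels())


def _bounded_trait(
    tree: PhyloTree, lo: float, hi: float, lam: float, rng: np.random.Generator
) -> pd.Series:
    """Evolve a logit-scale BM trait and map it into (lo, hi).

    The latent trait is BM with unit variance; the logistic map keeps the
    output strictly inside the bounds without truncating the process.
    """
    z = simulate_traits(tree, sigma2=1.0, lam=lam, mean=0.0, rng=rng)
    u = 1.0 / (1.0 + np.exp(-z / 1.2))  # mild squashing keeps spread wide
    return lo + (hi - lo) * u


def generate_anatomy_table(tree: PhyloTree, config: SynthConfig):
    """Branch-level pit, tracheid, and wood CSV frames plus ground truth.

    Species-level DPM evolves within ``dpm_range``; DT and DPA follow
    from evolved MF* and TO* (DT = DPM*(1-MF*), DPA = DT*(1-TO*)), which
    guarantees DPA < DT < DPM row-wise.  Branch replicates add
    multiplicative noise with cv ``cv_anatomy``; pit-level jitter is
    relative so the ordering is preserved.
    """
    rng = _rng(config.seed, "anatomy")
    species = tree.tip_labels()

    dpm = _bounded_trait(tree, *config.dpm_range, lam=config.lam, rng=rng)
    to_star = _bounded_trait(tree, *config.to_range, lam=config.lam, rng=rng)
    mf_star = _bounded_trait(tree, *config.mf_range, lam=config.lam, rng=rng)
    tw = _bounded_trait(tree, *config.tw_range, lam=config.lam, rng=rng)
    d_mean = _bounded_trait(tree, 8.0, 18.0, lam=config.lam, rng=rng)  # lumen diameter, µm
    wd = _bounded_trait(tree, *config.wd_range, lam=config.lam, rng=rng)

    dt = dpm * (1.0 - mf_star)
    dpa = dt * (1.0 - to_star)

    cv = config.cv_anatomy
    pit_rows, trach_rows, wood_rows = [], [], []
    for sp in species:
        for b in range(config.n_branches_anatomy):
            bid = f"{sp}_b{b + 1}"
            b_dpm = dpm[sp] * (1.0 + rng.normal(0, cv))
            b_mf = float(np.clip(mf_star[sp] * (1.0 + rng.normal(0, cv)), 0.01, 0.95))
            b_to = float(np.clip(to_star[sp] * (1.0 + rng.normal(0, cv)), 0.01, 0.95))
            b_tw = tw[sp] * (1.0 + rng.normal(0, cv))
            b_dt = b_dpm * (1.0 - b_mf)
            b_dpa = b_dt * (1.0 - b_to)
            for _ in range(config.n_pits):
                scale = 1.0 + rng.normal(0, cv)  # shared pit-level size jitter
                pit_rows.append(
                    {
                        "branch_id": bid,
                        "species": sp,
                        "DPM_um": b_dpm * scale,
                        "DT_um": b_dt * scale,
                        "DPA_um": b_dpa * scale,
                    }
                )
            # tracheids: lognormal lumen areas around the zone mean diameter,
            # TD ~ c / D^2 trade-off fixes the section area
            for zone, dshift in (("earlywood", 1.15), ("latewood", 0.7), ("whole", 1.0)):
                dz = d_mean[sp] * dshift * (1.0 + rng.normal(0, cv))
                mu_area = np.pi * (dz / 2.0) ** 2
                areas = rng.lognormal(np.log(mu_area) - 0.02, 0.2, size=config.n_tracheids)
                td = 2.5e5 / dz**2  # per mm^2
                section_area = config.n_tracheids / td
                tw_zone = b_tw * (1.3 if zone == "latewood" else (0.9 if zone == "earlywood" else 1.0))
                for a in areas:
                    trach_rows.append(
                        {
                            "branch_id": bid,
                            "species": sp,
                            "zone": zone,
                            "lumen_area_um2": a,
                            "section_area_mm2": section_area,
                            "Tw_um": tw_zone,
                        }
                    )
        volume = rng.uniform(8.0, 12.0)
        wood_rows.append(
            {
                "species": sp,
                "mass_g": wd[sp] * volume * (1.0 + rng.normal(0, cv)),
                "volume_cm3": volume,
            }
        )

    truth = {
        "DPM_um": dpm.to_dict(),
        "TO_star": to_star.to_dict(),
        "MF_star": mf_star.to_dict(),
        "Tw_um": tw.to_dict(),
        "D_um": d_mean.to_dict(),
        "WD_g_cm3": wd.to_dict(),
        "note": "within-species cv values are synthetic placeholders, not estimated from data",
    }
    return pd.DataFrame(pit_rows), pd.DataFrame(trach_rows), pd.DataFrame(wood_rows), truth


def generate_cavitron_dataset(tree: PhyloTree, config: SynthConfig):
    """Per-branch centrifuge conductance series with known P50/S ground truth.

    Pressure steps run from -0.8 MPa in ``pressure_step`` decrements
    until the true curve passes 99% loss.  Replicate conductances are
    kmax*(1 - PLC/100)*(1 + eps), eps ~ N(0, cv^2), 3 per step.
    """
    rng = _rng(config.seed, "curves")
    species = tree.tip_labels()
    p50 = _bounded_trait(tree, *config.p50_range, lam=config.lam, rng=rng)
    s = _bounded_trait(tree, *config.s_range, lam=config.lam, rng=rng)
    ks = _bounded_trait(tree, *config.ks_range, lam=config.lam, rng=rng)

    series: list[ConductanceSeries] = []
    truth_rows = []
    for sp in species:
        for b in range(config.n_branches_vc):
            bid = f"{sp}_vc{b + 1}"
            b_p50 = p50[sp] + rng.normal(0, 0.1)
            b_s = max(s[sp] * (1.0 + rng.normal(0, 0.05)), 5.0)
            kmax = ks[sp] * config.sapwood_area_m2 / config.sample_length_m
            pressures = [-0.8]
            while 100.0 / (1.0 + np.exp(b_s / 25.0 * (pressures[-1] - b_p50))) <= 99.0:
                pressures.append(pressures[-1] + config.pressure_step)
                if len(pressures) > 200:
                    break
            while len(pressures) < 5:  # pad so the series stays fittable
                pressures.append(pressures[-1] + config.pressure_step)
            p_arr = np.array(pressures)
            plc_true = 100.0 / (1.0 + np.exp(np.clip(b_s / 25.0 * (p_arr - b_p50), -500, 500)))
            k_true = kmax * (1.0 - plc_true / 100.0)
            # the initial low-speed spin is the unembolised reference measurement
            k_true[0] = kmax
            eps = rng.normal(0.0, config.cv_curves, size=(len(p_arr), 3)) if config.cv_curves > 0 else np.zeros((len(p_arr), 3))
            k_obs = np.clip(k_true[:, None] * (1.0 + eps), 0.0, None)
            series.append(
                ConductanceSeries(
                    branch_id=bid,
                    species=sp,
                    pressures=p_arr,
                    conductances=k_obs,
                    length=config.sample_length_m,
                    area=config.sapwood_area_m2,
                )
            )
            truth_rows.append({"branch_id": bid, "species": sp, "P50_true": b_p50, "S_true": b_s})
    truth = {
        "species_P50": p50.to_dict(),
        "species_S": s.to_dict(),
        "species_Ks": ks.to_dict(),
        "branches": truth_rows,
    }
    return series, truth


def series_to_frame(series: list[ConductanceSeries]) -> pd.DataFrame:
    """Long-format CSV frame (inverse of vcfit.read_curves_csv)."""
    rows = []
    for s in series:
        for i, p in enumerate(s.pressures):
            row = {"branch_id": s.branch_id, "species": s.species, "pressure_MPa": p}
            for j in range(s.conductances.shape[1]):
                row[f"k_rep{j + 1}"] = s.conductances[i, j]
            row["length_m"] = s.length
            row["sapwood_area_m2"] = s.area
            rows.append(row)
    return pd.DataFrame(rows)


def generate_dataset(config: SynthConfig, out_dir: str | Path) -> dict:
    """Emit tree.nwk, curves.csv, pits.csv, tracheids.csv, wood.csv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config)
    pits, trach, wood, anatomy_truth = generate_anatomy_table(tree, config)
    series, curve_truth = generate_cavitron_dataset(tree, config)

    (out / "tree.nwk").write_text(write_newick(tree) + "\n")
    series_to_frame(series).to_csv(out / "curves.csv", index=False)
    pits.to_csv(out / "pits.csv", index=False)
    trach.to_csv(out / "tracheids.csv", index=False)
    wood.to_csv(out / "wood.csv", index=False)
    truth = {"config": asdict(config), "anatomy": anatomy_truth, "curves": curve_truth}
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
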