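"""End-to-end orchestration: data (synthetic or user) -> fits -> traits ->
comparative statistics -> path models, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from xylemcomp import anatomy, compstats, pathmodel, synthgen, treeio, vcfit

logger = logging.getLogger("xylemcomp")

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_SIGNAL_TRAITS = [
    "P50_abs_MPa",
    "Ks",
    "Dh_um",
    "TD_per_mm2",
    "Tw_um",
    "TSR",
    "DPM_um",
    "DT_um",
    "DPA_um",
    "TO",
    "MF",
    "VE",
    "R_PA_MPa_s_m3",
]


@dataclass
class RunConfig:
    """Pipeline configuration; either ``synth`` or explicit input paths."""

    out_dir: str = "runs/latest"
    seed: int = 42
    synth: synthgen.SynthConfig | None = None
    curves_csv: str | None = None
    pits_csv: str | None = None
    tracheids_csv: str | None = None
    wood_csv: str | None = None
    tree_newick: str | None = None
    ks_mode: str = "standard"
    rpa_convention: str = "as_printed"
    delta_aicc: float = 2.0
    n_perm: int = 999
    alpha: float = 0.05
    vif_threshold: float = 5.0
    run_sem: bool = True
    run_signal: bool = True
    run_model_selection: bool = True
    prune_outgroup: list[str] = field(default_factory=list)
    p50_candidates: list[str] = field(default_factory=lambda: ["DPA_um", "MF", "VE"])
    ks_candidates: list[str] = field(default_factory=lambda: ["Dh_um", "TD_per_mm2", "R_PA_MPa_s_m3"])

    def __post_init__(self):
        user_inputs = any([self.curves_csv, self.pits_csv, self.tracheids_csv, self.wood_csv, self.tree_newick])
        if self.synth is not None and user_inputs:
            raise ValueError("provide either a synth config or user data paths, not both")
        if self.synth is None and not user_inputs:
            self.synth = synthgen.SynthConfig(seed=self.seed)

    def config_hash(self) -> str:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Run every enabled stage; returns the output directory.

    Deterministic given ``config.seed``.  Emits CSV/JSON tables plus
    ``manifest.json`` with the seed, config hash, and a SHA-256 per file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

    # --- inputs -----------------------------------------------------------
    if config.synth is not None:
        data_dir = out / "data"
        synthgen.generate_dataset(config.synth, data_dir)
        curves_path = data_dir / "curves.csv"
        pits_path = data_dir / "pits.csv"
        trach_path = data_dir / "tracheids.csv"
        wood_path = data_dir / "wood.csv"
        tree_path = data_dir / "tree.nwk"
    else:
        curves_path, pits_path = config.curves_csv, config.pits_csv
        trach_path, wood_path = config.tracheids_csv, config.wood_csv
        tree_path = config.tree_newick

    tree = treeio.parse_newick(Path(tree_path).read_text()) if tree_path else None
    if tree is not None and config.prune_outgroup:
        tree = tree.prune_tips(config.prune_outgroup)

    # --- vulnerability curves --------------------------------------------
    @_stage("vcfit")
    def stage_vc():
        series = vcfit.read_curves_csv(curves_path)
        branch_fits = vcfit.fit_branches(series, ks_mode=config.ks_mode)
        sp = vcfit.species_means(branch_fits)
        branch_fits.to_csv(out / "vc_branch_fits.csv", index=False)
        sp.to_csv(out / "vc_species_means.csv", index=False)
        return sp

    vc_species = stage_vc() if curves_path else None

    # --- anatomy ----------------------------------------------------------
    @_stage("anatomy")
    def stage_anatomy():
        pits = pd.read_csv(pits_path)
        trach = pd.read_csv(trach_path)
        wood = pd.read_csv(wood_path) if wood_path and Path(wood_path).exists() else None
        table = anatomy.build_trait_table(pits, trach, wood, convention=config.rpa_convention)
        table.to_csv(out / "anatomy_species_traits.csv", index=False)
        return table

    anat_species = stage_anatomy() if pits_path else None

    # --- merged species trait table ---------------------------------------
    @_stage("traits")
    def stage_traits():
        parts = [t for t in (vc_species, anat_species) if t is not None]
        table = parts[0]
        for t in parts[1:]:
            table = table.merge(t, on="species", how="outer")
        table.to_csv(out / "species_trait_table.csv", index=False)
        return compstats.TraitTable.from_frame(
            table.drop(columns=[c for c in ("n_branches",) if c in table]), species_col="species"
        )

    traits = stage_traits()
    analysis_traits = [t for t in DEFAULT_SIGNAL_TRAITS if t in traits.traits]

    # --- correlations: raw + PIC ------------------------------------------
    @_stage("correlations")
    def stage_corr():
        r, p, n = compstats.pearson_matrix(traits, analysis_traits, alpha=config.alpha)
        r.to_csv(out / "correlations_pearson_r.csv")
        p.to_csv(out / "correlations_pearson_p.csv")
        if tree is not None:
            rp, pp = compstats.pic_matrix(tree, traits, analysis_traits)
            rp.to_csv(out / "correlations_pic_r.csv")
            pp.to_csv(out / "correlations_pic_p.csv")
            # mirror of the two-triangle presentation: raw below, PIC above
            combined = r.where(np.tril(np.ones(r.shape), -1).astype(bool), rp)
            combined.to_csv(out / "correlations_two_triangles.csv")
        return r

    stage_corr()

    # --- phylogenetic signal ----------------------------------------------
    if config.run_signal and tree is not None:
        @_stage("signal")
        def stage_signal():
            rows = []
            for i, t in enumerate(analysis_traits):
                res = compstats.blomberg_k(
                    tree, traits, t, n_perm=config.n_perm, seed=config.seed + i
                )
                rows.append(
                    {"trait": t, "K": res.k, "p_value": res.p_value, "n_perm": res.n_perm, "seed": res.seed}
                )
            df = pd.DataFrame(rows)
            df.to_csv(out / "phylogenetic_signal.csv", index=False)
            return df

        stage_signal()

    # --- AICc model selection ----------------------------------------------
    if config.run_model_selection:
        @_stage("model_selection")
        def stage_dredge():
            results = {}
            for response, cands in (
                ("P50_abs_MPa", config.p50_candidates),
                ("Ks", config.ks_candidates),
            ):
                cands = [c for c in cands if c in traits.traits]
                if response not in traits.traits or len(cands) < 1:
                    continue
                vifs = compstats.vif(traits, cands, threshold=config.vif_threshold)
                kept = [c for c in cands if c not in vifs.attrs["flagged"]]
                if not kept:
                    logger.warning("all candidates for %s fail the VIF screen", response)
                    continue
                sel = compstats.aicc_model_selection(
                    traits, response, kept, delta_threshold=config.delta_aicc
                )
                sel.models.assign(
                    predictors=sel.models["predictors"].map(lambda t: "+".join(t) or "(intercept)")
                ).to_csv(out / f"model_selection_{response}.csv", index=False)
                summary = pd.DataFrame(
                    {"Avg": sel.averaged_coef, "SE": sel.averaged_se, "Imp": sel.importance, "P": sel.p_values}
                )
                summary.to_csv(out / f"model_average_{response}.csv")
                results[response] = sel
            return results

        stage_dredge()

    # --- structural path models --------------------------------------------
    if config.run_sem:
        @_stage("sem")
        def stage_sem():
            results = {}
            for name, spec_text, outcome in (
                ("p50", pathmodel.P50_MODEL, "P50_abs_MPa"),
                ("ks", pathmodel.KS_MODEL, "Ks"),
            ):
                spec = pathmodel.parse_spec_text(spec_text)
                if any(v not in traits.traits for v in spec.variables):
                    logger.warning("sem %s skipped: missing variables", name)
                    continue
                fit = pathmodel.fit_path_model(traits, spec)
                fit.coefficients.to_csv(out / f"sem_{name}_coefficients.csv", index=False)
                eff = pathmodel.effects_decomposition(fit, outcome)
                eff.to_csv(out / f"sem_{name}_effects.csv")
                (out / f"sem_{name}_fit.json").write_text(
                    json.dumps({"chi2": fit.chi2, "df": fit.df, "p": fit.p_value, "n": fit.n}, indent=2)
                )
                results[name] = fit
            return results

        stage_sem()

    # --- ANOVA letters (synthetic group = first token of species name) ----
    @_stage("anova")
    def stage_anova():
        # group by clade label when available; synthetic data has none, so
        # split species into halves of the tree as a smoke grouping
        if tree is None:
            return None
        order = tree.tip_labels()
        half = {sp: ("cladeA" if i < len(order) // 2 else "cladeB") for i, sp in enumerate(order)}
        rows = []
        for t in analysis_traits:
            vals = traits.values_for(t, order)
            res = compstats.anova_tukey(vals, [half[s] for s in order], alpha=config.alpha, factor=t)
            rows.append(
                {
                    "trait": t,
                    "F": res.f_statistic,
                    "df1": res.df_between,
                    "df2": res.df_within,
                    "p": res.p_value,
                    **{f"letter_{g}": l for g, l in res.letters.items()},
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "anova_letters.csv", index=False)
        return df

    stage_anova()

    # --- manifest -----------------------------------------------------------
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "files": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest() for p in files
        },
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
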