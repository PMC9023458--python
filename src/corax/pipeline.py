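"""Study-shaped analysis pipeline.

Runs the full sequence on a dataset bundle (synthetic or user-supplied):
(1) diversification-shift search and pulled speciation rates; (2) linear and
landmark morphospaces (pPCA), two-rate Brownian tests and trait-shift
searches on the leading axes; (3) disparity-through-time with single-rate
and rate-informed nulls plus focal-clade exclusion; (4) climate PCA, range
areas and sympatric assemblages; (5) trait-driver analyses (relative brain
size by phylogenetic regression, phylogenetic ANOVA, ancestral states,
time-slice means, phenogram coordinates). Every stage is independently
seeded from the pipeline seed, so disabling one stage never changes the
numbers of another; a stage failure is recorded and later stages still run.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import disparity as dtt_mod
from . import morphospace as morph
from . import niche as niche_mod
from .phylo import (CladePartition, Phylogeny, RateMap, read_newick_file,
                    read_rate_map_csv, read_trait_csv, write_newick)
from .rateshift import (estimate_psr, fit_brownie,
                        search_diversification_shifts, search_trait_shifts)
from .simulate import SimulationConfig, simulate_dataset, write_bundle
from .traitmodels import ancestral_states, pgls, phenogram_coords, \
    time_slice_means

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline",
           "validate_bundle", "load_bundle"]

ALL_STAGES = ("diversification", "morphospace", "disparity", "niche",
              "drivers")


@dataclass
class PipelineConfig:
    """Validated configuration of a pipeline run.

    Either ``bundle_dir`` (a directory with tree.nwk / traits.csv /
    landmarks.csv / occurrences.csv and optional rate_map.csv +
    manifest.yaml) or ``simulation`` (generate the bundle in memory).
    """

    seed: int = 0
    bundle_dir: str = None
    simulation: SimulationConfig = None
    focal_tips: list = None        # defines the focal clade (MRCA)
    stages: tuple = ALL_STAGES
    nsim: int = 1000               # DTT null simulations
    min_clade: int = 5
    max_regimes: int = 4
    aic_threshold: float = 4.0
    psr_grid: int = 8
    psr_bounds: tuple = (0.0, 5.0)
    hull_alpha: float = None       # None: 2x mean nearest-neighbour distance
    thin_cell_km: float = 11.0
    grid_resolution: float = 0.1
    n_axes: int = 3                # leading pPCA axes carried downstream
    outdir: str = None

    def validate(self):
        if (self.bundle_dir is None) == (self.simulation is None):
            raise ValueError("give exactly one of bundle_dir or simulation")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.nsim < 1 or self.min_clade < 2 or self.max_regimes < 1:
            raise ValueError("invalid thresholds")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["psr_bounds"] = list(self.psr_bounds)
        return d


@dataclass
class PipelineReport:
    config: dict
    stages: dict = field(default_factory=dict)   # name -> result dict
    status: dict = field(default_factory=dict)   # name -> ok/failed/skipped
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "status": self.status,
                           "warnings": self.warnings, "stages": self.stages},
                          sort_keys=True, indent=1, default=_jsonify)

    def summary(self) -> str:
        lines = ["Pipeline report"]
        for st in self.config["stages"]:
            lines.append(f"  {st}: {self.status.get(st, 'skipped')}")
        return "\n".join(lines)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


# ---------------------------------------------------------------------------
# Bundle loading / validation
# ---------------------------------------------------------------------------

def load_bundle(bundle_dir: str):
    """Read a bundle directory into (tree, traits, landmarks, occurrences,
    rate_map-or-None, manifest-or-{})."""
    tree = read_newick_file(os.path.join(bundle_dir, "tree.nwk"))
    traits = read_trait_csv(os.path.join(bundle_dir, "traits.csv"))
    landmarks = pd.read_csv(os.path.join(bundle_dir, "landmarks.csv"))
    occurrences = niche_mod.read_occurrence_csv(
        os.path.join(bundle_dir, "occurrences.csv"))
    rm_path = os.path.join(bundle_dir, "rate_map.csv")
    rate_map = read_rate_map_csv(rm_path, tree) if os.path.exists(rm_path) \
        else None
    mf_path = os.path.join(bundle_dir, "manifest.yaml")
    manifest = {}
    if os.path.exists(mf_path):
        with open(mf_path) as fh:
            manifest = yaml.safe_load(fh) or {}
    return tree, traits, landmarks, occurrences, rate_map, manifest


def validate_bundle(bundle_dir: str) -> dict:
    """Cross-consistency report for a bundle directory; lists mismatches
    rather than failing silently."""
    issues = []
    try:
        tree, traits, landmarks, occurrences, rate_map, manifest = \
            load_bundle(bundle_dir)
    except Exception as exc:
        return {"ok": False, "issues": [f"unreadable bundle: {exc}"]}
    tips = set(tree.tip_labels)
    for name, sp in (("traits", set(traits.index)),
                     ("landmarks", set(landmarks["species"])),
                     ("occurrences", set(occurrences["species"]))):
        extra, missing = sorted(sp - tips), sorted(tips - sp)
        if extra:
            issues.append(f"{name}: species not in tree: {extra[:10]}")
        if missing:
            issues.append(f"{name}: tree tips without data: {missing[:10]}")
    if not tree.is_ultrametric():
        issues.append("tree is not ultrametric")
    return {"ok": not issues, "issues": issues}


def _focal_partition(tree: Phylogeny, config: PipelineConfig,
                     manifest: dict) -> CladePartition:
    tips = config.focal_tips or manifest.get("focal_tips")
    if not tips:
        return None
    return CladePartition(tree.mrca(tips), include_stem=True)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_diversification(ctx, rng):
    tree, cfg = ctx["tree"], ctx["config"]
    part = ctx["partition"]
    search = search_diversification_shifts(
        tree, max_shifts=cfg.max_regimes - 1,
        aic_threshold=cfg.aic_threshold, min_clade=cfg.min_clade)
    psr = estimate_psr(tree, grid_size=cfg.psr_grid, bounds=cfg.psr_bounds)
    out = {
        "background": search.background,
        "n_shifts": search.n_shifts,
        "shifts": [
            {**s, "tips": [tree.labels[i] for i in tree.clade_tips(s["node"])]}
            for s in search.shifts],
        "psr": psr.to_frame().to_dict(orient="list"),
    }
    if search.shifts and search.background["lambda"] > 0:
        out["max_rate_ratio"] = max(
            s["lambda"] / search.background["lambda"] for s in search.shifts)
    if part is not None:
        origin_age = float(tree.ages()[tree.parent[part.focal_node]])
        pre = psr.psr[psr.ages >= origin_age]
        post = psr.psr[psr.ages < origin_age]
        out["psr_pre_origin"] = float(pre.mean()) if len(pre) else None
        out["psr_post_origin"] = float(post.mean()) if len(post) else None
        out["focal_detected"] = _detected(tree, search.shifts, part)
    ctx["div_search"] = search
    return out


def _detected(tree: Phylogeny, shifts, part: CladePartition) -> bool:
    """A shift flags the focal clade if it sits at the focal node or an
    immediately adjacent node, or if the detected regime's tip set largely
    coincides with the focal tips (Jaccard >= 0.5) — alternative shift
    placements one or two nodes around a radiating clade are read as the
    same signal, as is standard when interpreting shift configurations."""
    adj = {part.focal_node, int(tree.parent[part.focal_node]),
           *tree.children[part.focal_node]}
    focal = set(part.tip_set(tree).tolist())
    for s in shifts:
        if s["node"] in adj:
            return True
        tips = set(tree.clade_tips(s["node"]).tolist())
        if len(tips & focal) / len(tips | focal) >= 0.5:
            return True
    return False


def _stage_morphospace(ctx, rng):
    tree, cfg, part = ctx["tree"], ctx["config"], ctx["partition"]
    traits = ctx["traits"]
    lin_cols = [c for c in traits.columns if c.startswith("lin")] \
        or list(traits.columns[:max(2, cfg.n_axes)])
    lin = morph.ppca(tree, traits[lin_cols])
    aligned = morph.gpa_align(morph.landmarks_from_frame(ctx["landmarks"]))
    shapes, log_size = morph.species_mean_shapes(aligned)
    shapes = shapes.reindex(tree.tip_labels)
    log_size = log_size.reindex(tree.tip_labels)
    # guard landmark dimensionality with a plain SVD reduction if needed
    gm_input = shapes
    if shapes.shape[1] > tree.n_tips:
        raise ValueError("more landmark coordinates than species")
    gm = morph.ppca(tree, gm_input, is_landmark=True)
    allom = morph.allometry_test(tree, shapes, np.exp(log_size),
                                 nperm=min(1000, max(200, cfg.nsim)),
                                 seed=rng.integers(2**31))
    resid = morph.size_free_residuals(tree, shapes, np.exp(log_size))
    gm_free = morph.ppca(tree, resid, is_landmark=True)

    out = {
        "linear_model": lin.model,
        "linear_pct_variance": lin.percent_variance[:cfg.n_axes].tolist(),
        "shape_model": gm.model,
        "shape_pct_variance": gm.percent_variance[:cfg.n_axes].tolist(),
        "allometry": {"pillai": allom.pillai, "pvalue": allom.pvalue},
        "sizefree_pct_variance":
            gm_free.percent_variance[:cfg.n_axes].tolist(),
    }
    n_ax = min(cfg.n_axes, lin.scores.shape[1])
    lin_scores = lin.scores.iloc[:, :n_ax]
    gm_scores = gm.scores.iloc[:, :min(cfg.n_axes, gm.scores.shape[1])]
    ctx["lin_scores"], ctx["gm_scores"] = lin_scores, gm_scores
    if part is not None:
        focal = set(part.tip_labels(tree))
        is_f = lin.scores.index.isin(focal)
        brown, shift_hits = {}, {}
        for name, sc in (("LIN1", lin_scores.iloc[:, 0]),
                         ("LIN2", lin_scores.iloc[:, 1]
                          if lin_scores.shape[1] > 1 else None),
                         ("GM1", gm_scores.iloc[:, 0])):
            if sc is None:
                continue
            b = fit_brownie(tree, sc, part)
            brown[name] = {"ratio": b.rate_ratio, "lrt": b.lrt,
                           "pvalue": b.pvalue}
            sh = search_trait_shifts(tree, sc, min_clade=cfg.min_clade,
                                     max_regimes=cfg.max_regimes,
                                     aic_threshold=cfg.aic_threshold)
            shift_hits[name] = {"n_shifts": sh.n_shifts,
                                "nodes": [s["node"] for s in sh.shifts],
                                "multipliers": [s["multiplier"]
                                                for s in sh.shifts],
                                "detected": _detected(tree, sh.shifts, part)}
        out["brownie"] = brown
        out["trait_shifts"] = shift_hits
        out["focal_detected"] = any(v["detected"]
                                    for v in shift_hits.values())
        # alpha-hull morphospace occupation, focal vs background; the same
        # alpha (scaled to the pooled point spacing unless configured) keeps
        # the two areas comparable
        pts = gm_scores.iloc[:, :2].to_numpy()
        alpha = cfg.hull_alpha
        if alpha is None:
            from scipy.spatial import cKDTree
            d, _ = cKDTree(pts).query(pts, k=2)
            alpha = 2.0 * float(d[:, 1].mean())
        out["hull_alpha"] = alpha
        out["hull_area_focal"] = morph.alpha_hull_area(
            pts[is_f], alpha) if is_f.sum() >= 3 else None
        out["hull_area_background"] = morph.alpha_hull_area(
            pts[~is_f], alpha) if (~is_f).sum() >= 3 else None
    return out


def _stage_disparity(ctx, rng):
    tree, cfg, part = ctx["tree"], ctx["config"], ctx["partition"]
    if "lin_scores" not in ctx:
        raise RuntimeError("disparity stage needs the morphospace stage")
    X = ctx["lin_scores"]
    if cfg.nsim < 100:
        ctx["report"].warnings.append(
            f"nsim={cfg.nsim} < 100: DTT envelope unstable")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        single = dtt_mod.dtt_null(tree, X, nsim=cfg.nsim,
                                  rng=np.random.default_rng(rng.integers(2**31)))
    out = {"mdi_single_rate": single.mdi,
           "curve": single.to_frame().to_dict(orient="list")}
    if part is not None:
        origin_rel = 1.0 - tree.ages()[part.focal_node] / tree.root_age
        exc = single.exceedances() & (single.times >= origin_rel - 1e-9)
        out["exceedances_post_origin"] = int(exc.sum())
        rm = ctx.get("rate_map")
        if rm is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                informed = dtt_mod.dtt_null(
                    tree, X, rate_map=rm, nsim=cfg.nsim,
                    rng=np.random.default_rng(rng.integers(2**31)))
            exc_i = informed.exceedances() & (informed.times
                                              >= origin_rel - 1e-9)
            out["mdi_rate_informed"] = informed.mdi
            out["exceedances_rate_informed"] = int(exc_i.sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            excl = dtt_mod.dtt_excluding_clade(
                tree, X, part, nsim=cfg.nsim,
                rng=np.random.default_rng(rng.integers(2**31)))
        out["mdi_excluding_focal"] = excl.mdi
        out["exceedances_excluding_focal"] = int(excl.exceedances().sum())
    return out


def _stage_niche(ctx, rng):
    cfg, part, tree = ctx["config"], ctx["partition"], ctx["tree"]
    occ = ctx["occurrences"]
    thinned = niche_mod.thin_occurrences(occ, cell_km=cfg.thin_cell_km)
    cp = niche_mod.climate_pca(thinned)
    grid = niche_mod.build_presence_grid(thinned,
                                         resolution=cfg.grid_resolution)
    out = {
        "n_records": int(len(occ)), "n_thinned": int(len(thinned)),
        "pct_variance": (100 * cp.explained_variance
                         / cp.explained_variance.sum())[:2].tolist(),
        "clim1_top_loading": cp.loadings["PC1"].abs().idxmax(),
        "clim2_top_loading": cp.loadings["PC2"].abs().idxmax(),
    }
    ctx["species_climate"] = cp.species_means
    if part is not None:
        focal = set(part.tip_labels(tree))
        bg = [s for s in grid.species if s not in focal]
        fc = [s for s in grid.species if s in focal]
        out["range_area_focal"] = niche_mod.range_area(grid, fc) if fc else 0
        out["range_area_background"] = (niche_mod.range_area(grid, bg)
                                        if bg else 0)
        genus_map = {s: ("focal" if s in focal else "background")
                     for s in grid.species}
        out["sympatric_assemblages"] = niche_mod.count_sympatric_assemblages(
            grid, genus_map).to_dict()
        m = cp.species_means
        is_f = m.index.isin(focal)
        out["climate_niche_sd"] = {
            "focal": m[is_f].std(ddof=1).to_dict(),
            "background": m[~is_f].std(ddof=1).to_dict()}
    return out


def _stage_drivers(ctx, rng):
    tree, cfg, part = ctx["tree"], ctx["config"], ctx["partition"]
    traits = ctx["traits"]
    need = {"brain", "femur", "hwi"}
    if not need <= set(traits.columns):
        raise ValueError(f"driver stage needs trait columns {sorted(need)}")
    reg = pgls(tree, traits["brain"], traits[["femur"]], model="lambda")
    rel_brain = reg.resid
    out = {"brain_regression": {
        "slope": float(reg.params["femur"]),
        "lambda": reg.lam, "pvalue": float(reg.pvalues["femur"])}}
    series = {"body": traits["femur"], "hwi": traits["hwi"],
              "relative_brain": rel_brain}
    if part is not None:
        focal = set(part.tip_labels(tree))
        group = pd.Series([1.0 if s in focal else 0.0
                           for s in tree.tip_labels],
                          index=tree.tip_labels, name="focal")
        anova = {}
        for name, s in series.items():
            r = pgls(tree, s, group.to_frame(), model="lambda")
            anova[name] = {"effect": float(r.params["focal"]),
                           "t": float(r.tvalues["focal"]),
                           "pvalue": float(r.pvalues["focal"]),
                           "lambda": r.lam}
        out["phylo_anova"] = anova
    slices = np.linspace(0.0, tree.root_age, 21)
    ts, anc_store, pheno = {}, {}, {}
    for name, s in series.items():
        anc = ancestral_states(tree, s)
        anc_store[name] = anc
        full = time_slice_means(tree, anc, slices)
        entry = {"age": full["age"].tolist(),
                 "mean": full["mean_state"].tolist()}
        if part is not None:
            ages = tree.ages()
            sub = slices[slices <= ages[part.focal_node] + 1e-9]
            excl = time_slice_means(tree, anc, slices, part, mode="exclude")
            entry["mean_excluding_focal"] = excl["mean_state"].tolist()
            if len(sub):
                inc = time_slice_means(tree, anc, sub, part, mode="include")
                entry["focal_age"] = inc["age"].tolist()
                entry["focal_mean"] = inc["mean_state"].tolist()
        ts[name] = entry
        pheno[name] = phenogram_coords(tree, s, anc)
    out["time_slices"] = ts
    ctx["phenograms"] = pheno
    ctx["relative_brain"] = rel_brain
    if part is not None:
        out["focal_offsets_at_present"] = {
            name: float(s[s.index.isin(set(part.tip_labels(tree)))].mean()
                        - s[~s.index.isin(set(part.tip_labels(tree)))].mean())
            for name, s in series.items()}
    return out


_STAGE_FUNCS = {"diversification": _stage_diversification,
                "morphospace": _stage_morphospace,
                "disparity": _stage_disparity,
                "niche": _stage_niche,
                "drivers": _stage_drivers}


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the configured stages and return (and optionally write) the
    structured report. Deterministic under a fixed config."""
    config.validate()
    if config.simulation is not None:
        ds = simulate_dataset(config.simulation)
        tree, traits, landmarks, occurrences = (ds.tree, ds.traits,
                                                ds.landmarks, ds.occurrences)
        rate_map, manifest = ds.rate_map, ds.manifest
    else:
        tree, traits, landmarks, occurrences, rate_map, manifest = \
            load_bundle(config.bundle_dir)
        traits = traits.reindex(tree.tip_labels)
    report = PipelineReport(config=config.to_dict())
    part = _focal_partition(tree, config, manifest)
    ctx = {"tree": tree, "traits": traits, "landmarks": landmarks,
           "occurrences": occurrences, "rate_map": rate_map,
           "partition": part, "config": config, "report": report}
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = dict(zip(ALL_STAGES, ss.spawn(len(ALL_STAGES))))
    for st in ALL_STAGES:
        if st not in config.stages:
            report.status[st] = "skipped"
            continue
        rng = np.random.default_rng(stage_seeds[st])
        try:
            report.stages[st] = _STAGE_FUNCS[st](ctx, rng)
            report.status[st] = "ok"
        except Exception as exc:
            report.status[st] = "failed"
            report.stages[st] = {"error": str(exc)}
    if config.outdir:
        _write_outputs(config, report, ctx)
    return report


def _write_outputs(config: PipelineConfig, report: PipelineReport, ctx):
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "report.json"), "w") as fh:
        fh.write(report.to_json())
    with open(os.path.join(out, "config.yaml"), "w") as fh:
        yaml.safe_dump(report.config, fh, sort_keys=True)
    if "lin_scores" in ctx:
        ctx["lin_scores"].to_csv(os.path.join(out, "linear_pca_scores.csv"),
                                 index_label="species")
        ctx["gm_scores"].to_csv(os.path.join(out, "shape_pca_scores.csv"),
                                index_label="species")
    if "species_climate" in ctx:
        ctx["species_climate"].to_csv(
            os.path.join(out, "species_climate.csv"), index_label="species")
    if "phenograms" in ctx:
        rows = []
        for name, segs in ctx["phenograms"].items():
            for t0, v0, t1, v1 in segs:
                rows.append((name, t0, v0, t1, v1))
        pd.DataFrame(rows, columns=["trait", "t_parent", "v_parent",
                                    "t_child", "v_child"]).to_csv(
            os.path.join(out, "phenogram_segments.csv"), index=False)
    if "disparity" in report.stages and "curve" in report.stages["disparity"]:
        pd.DataFrame(report.stages["disparity"]["curve"]).to_csv(
            os.path.join(out, "dtt_curve.csv"), index=False)
    if "diversification" in report.stages \
            and "psr" in report.stages["diversification"]:
        pd.DataFrame(report.stages["diversification"]["psr"]).to_csv(
            os.path.join(out, "psr_curve.csv"), index=False)
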