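"""Synthetic Corvidae-like data with known ground truth.

The generator emulates the structure of a family-level radiation containing
one nested, recently accelerated genus: a ~100-tip birth–death family tree
about 20 time units old with a focal clade originating ~10 units before
present under elevated speciation; correlated size/shape traits with a
focal-clade rate multiplier; clade-offset wing (HWI) and brain traits;
beak-like 23-point landmark configurations with allometry; and per-species
Gaussian climatic niches with broader, shifted niches in the focal clade.

Every generator takes an explicit seed and is byte-deterministic; a single
dataset seed is expanded into independent per-component child streams with
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .phylo import CladePartition, Phylogeny, RateMap, paint_clade

__all__ = [
    "SimulationConfig", "SyntheticDataset",
    "simulate_tree", "simulate_yule_tree", "simulate_bd_tree",
    "simulate_traits", "simulate_bm_tips", "simulate_landmarks",
    "simulate_occurrences", "simulate_dataset", "beak_template",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic radiation; defaults are the study-shaped
    conditions (family of ~100 tips, focal clade of ~45 tips from ~10 units
    before present, roughly double background speciation)."""

    seed: int = 0
    # tree
    root_age: float = 20.0           # family crown age (time units)
    lambda0: float = 0.2             # background speciation /time
    mu0: float = 0.02                # background extinction /time
    lambda1: float = 0.4             # focal-clade speciation /time
    clade_origin: float = 10.0       # focal regime onset, time before present
    min_focal_tips: int = 25         # study-shaped: a ~45-tip focal genus
    family_tips_range: tuple = (70, 180)
    max_attempts: int = 1000
    # traits
    n_linear: int = 6                # log-linear skeletal measurements
    sigma2_body: float = 0.02        # latent body-size BM rate (log units^2/t)
    sigma2_resid: float = 0.004      # per-measurement independent BM rate
    trait_rate_multiplier: float = 4.0   # focal-clade multiplier on body/beak
    allometric_slope: float = 0.75
    offset_body: float = 0.4         # focal-clade mean offsets
    offset_hwi: float = 0.3
    offset_brain: float = 0.2
    brain_slope: float = 0.6
    # landmarks
    n_specimens: int = 3
    sigma2_shape: float = 0.0005     # latent beak-shape BM rate
    shape_allometry: float = 0.05    # landmark displacement per log-size unit
    specimen_noise: float = 0.005
    # occurrences
    records_per_species: int = 60
    niche_sd: float = 0.5
    sigma2_niche: float = 0.05
    focal_niche_shift: tuple = (-1.0, 0.5)   # warmer, wetter
    focal_niche_widen: float = 1.5
    n_climate_vars: int = 6
    geo_jitter: float = 2.0

    def validate(self):
        if self.mu0 < 0 or self.lambda0 <= self.mu0:
            raise ValueError("need lambda0 > mu0 >= 0")
        if self.lambda1 < self.lambda0:
            raise ValueError("focal lambda1 must be >= lambda0")
        if self.trait_rate_multiplier < 1:
            raise ValueError("trait rate multiplier must be >= 1")
        if self.niche_sd <= 0:
            raise ValueError("niche SD must be positive")

    def child_seeds(self, names):
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(names))
        return dict(zip(names, children))


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    partition: CladePartition
    rate_map: RateMap
    traits: pd.DataFrame
    landmarks: pd.DataFrame
    occurrences: pd.DataFrame
    manifest: dict

    @property
    def focal_tips(self):
        return self.partition.tip_labels(self.tree)


# ---------------------------------------------------------------------------
# Birth–death tree simulation
# ---------------------------------------------------------------------------

class _Forward:
    """Gillespie forward birth–death simulation from 2 crown lineages."""

    def __init__(self, rng):
        self.rng = rng
        self.parent = [-1, 0, 0]
        self.start = [0.0, 0.0, 0.0]
        self.end = [0.0, None, None]
        self.regime = [1, 1, 1]
        self.alive = [1, 2]

    def run(self, t0, t1, rates):
        """Advance from time t0 to t1; rates maps regime -> (lambda, mu)."""
        t = t0
        while self.alive:
            lam_mu = np.array([rates[self.regime[v]] for v in self.alive])
            total = lam_mu.sum()
            t_next = t + self.rng.exponential(1.0 / total)
            if t_next >= t1:
                return
            t = t_next
            flat = lam_mu.ravel() / total
            pick = self.rng.choice(len(flat), p=flat)
            idx, is_death = divmod(pick, 2)
            v = self.alive[idx]
            self.end[v] = t
            self.alive.pop(idx)
            if not is_death:
                for _ in range(2):
                    self.parent.append(v)
                    self.start.append(t)
                    self.end.append(None)
                    self.regime.append(self.regime[v])
                    self.alive.append(len(self.parent) - 1)

    def to_phylogeny(self, t_end):
        parent = np.array(self.parent)
        end = np.array([t_end if e is None else e for e in self.end])
        start = np.array(self.start)
        bl = end - start
        bl[0] = 0.0
        labels = [None] * len(parent)
        alive = set(self.alive)
        survivors = []
        for v in range(len(parent)):
            is_tip = v not in np.asarray(parent)[1:] if False else True
        children = [[] for _ in parent]
        for v in range(1, len(parent)):
            children[parent[v]].append(v)
        k = 0
        for v in range(len(parent)):
            if not children[v]:
                labels[v] = f"t{k}"
                k += 1
                if v in alive:
                    survivors.append((labels[v], self.regime[v]))
        # guard against zero-length branches from simultaneous-event ties
        bl[1:] = np.maximum(bl[1:], 1e-9)
        tree = Phylogeny(parent, bl, labels, root=0)
        return tree, survivors


def simulate_bd_tree(root_age: float, lam: float, mu: float, rng,
                     min_tips: int = 2, max_attempts: int = 1000,
                     tips_range=None) -> Phylogeny:
    """Constant-rate birth–death tree conditioned on survival of >=min_tips."""
    for _ in range(max_attempts):
        fwd = _Forward(rng)
        fwd.run(0.0, root_age, {1: (lam, mu)})
        if not fwd.alive:
            continue
        tree, survivors = fwd.to_phylogeny(root_age)
        names = [s for s, _ in survivors]
        if len(names) < max(2, min_tips):
            continue
        if tips_range and not (tips_range[0] <= len(names) <= tips_range[1]):
            continue
        extinct = [l for l in tree.tip_labels if l not in set(names)]
        return tree.drop_tips(extinct) if extinct else tree
    raise RuntimeError("conditioning failed after max_attempts; adjust "
                       "rates or the tip-count window")


def simulate_yule_tree(n_tips: int, lam: float, rng) -> Phylogeny:
    """Pure-birth tree grown forward to exactly n_tips surviving lineages."""
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    parent = [-1, 0, 0]
    start = [0.0, 0.0, 0.0]
    alive = [1, 2]
    t = 0.0
    while len(alive) < n_tips:
        t += rng.exponential(1.0 / (lam * len(alive)))
        v = alive.pop(rng.integers(len(alive)))
        for _ in range(2):
            parent.append(v)
            start.append(t)
            alive.append(len(parent) - 1)
    t_end = t + rng.exponential(1.0 / (lam * len(alive)))
    parent = np.array(parent)
    children = [[] for _ in parent]
    for v in range(1, len(parent)):
        children[parent[v]].append(v)
    bl = np.zeros(len(parent))
    labels = [None] * len(parent)
    k = 0
    for v in range(len(parent)):
        if children[v]:
            bl[v] = start[children[v][0]] - start[v]
        else:
            bl[v] = t_end - start[v]
            labels[v] = f"t{k}"
            k += 1
    bl[0] = 0.0
    return Phylogeny(parent, bl, labels, root=0)


def simulate_tree(config: SimulationConfig, rng=None):
    """Family tree with a nested accelerated focal clade.

    The focal regime is activated at exactly ``clade_origin`` before present
    on one randomly chosen surviving lineage; simulation is rejected until
    the focal clade survives with at least ``min_focal_tips`` tips and the
    family tip count falls in ``family_tips_range``.

    Returns (tree, partition, rate_map).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(
            config.child_seeds(["tree"])["tree"])
    T, t_mark = config.root_age, config.root_age - config.clade_origin
    for _ in range(config.max_attempts):
        fwd = _Forward(rng)
        fwd.run(0.0, t_mark, {1: (config.lambda0, config.mu0)})
        if not fwd.alive:
            continue
        v_mark = fwd.alive[rng.integers(len(fwd.alive))]
        stack = [v_mark]
        fwd.regime[v_mark] = 2
        fwd.run(t_mark, T, {1: (config.lambda0, config.mu0),
                            2: (config.lambda1, config.mu0)})
        tree, survivors = fwd.to_phylogeny(T)
        focal = [s for s, r in survivors if r == 2]
        names = [s for s, _ in survivors]
        lo, hi = config.family_tips_range
        if (len(focal) < config.min_focal_tips
                or len(names) - len(focal) < 2
                or not (lo <= len(names) <= hi)):
            continue
        extinct = [l for l in tree.tip_labels if l not in set(names)]
        if extinct:
            tree = tree.drop_tips(extinct)
        crown = tree.mrca(focal)
        # reject the rare case where the surviving focal tips are not
        # monophyletic in the pruned tree (cannot happen by construction,
        # but a tie in node depth could merge)
        if set(tree.labels[i] for i in tree.clade_tips(crown)) != set(focal):
            continue
        partition = CladePartition(crown, include_stem=True)
        rate_map = paint_clade(tree, partition, config.lambda1 / config.lambda0)
        return tree, partition, rate_map
    raise RuntimeError(
        "tree conditioning failed after max_attempts; relax the focal-clade "
        "or tip-count requirements or raise lambda0")


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

def _path_incidence(tree: Phylogeny) -> np.ndarray:
    """(n_tips, n_nodes) 0/1 matrix: branch b on the root->tip path."""
    A = np.zeros((tree.n_tips, tree.n_nodes))
    tip_pos = {t: k for k, t in enumerate(tree.tip_indices)}
    for t, k in tip_pos.items():
        v = t
        while v != tree.root:
            A[k, v] = 1.0
            v = tree.parent[v]
    return A


def simulate_bm_tips(tree: Phylogeny, sigma2, nsim: int, rng,
                     rate_map: RateMap = None, trait_cov=None,
                     z0: float = 0.0) -> np.ndarray:
    """Vectorized BM tip states: array (nsim, n_tips, n_traits).

    ``sigma2`` is scalar; ``trait_cov`` (d x d) adds cross-trait correlation
    of the increments (must be PSD). Per-branch increment variance is
    sigma2 * multiplier * branch length.
    """
    d = 1 if trait_cov is None else len(trait_cov)
    if trait_cov is not None:
        trait_cov = np.asarray(trait_cov, dtype=float)
        evals = np.linalg.eigvalsh(trait_cov)
        if evals.min() < -1e-10:
            raise ValueError("trait covariance is not PSD")
        L = np.linalg.cholesky(trait_cov + 1e-12 * np.eye(d))
    mult = (rate_map.branch_multipliers(tree) if rate_map is not None
            else np.ones(tree.n_nodes))
    var_b = sigma2 * mult * tree.branch_length
    var_b[tree.root] = 0.0
    Z = rng.standard_normal((tree.n_nodes, nsim, d))
    if trait_cov is not None:
        Z = Z @ L.T
    Z *= np.sqrt(var_b)[:, None, None]
    A = _path_incidence(tree)
    tips = np.einsum("tb,bsd->std", A, Z)  # (nsim, n_tips, d)
    return z0 + tips


def simulate_traits(tree: Phylogeny, rate_map: RateMap = None,
                    model: str = "BM", *, sigma2: float = 1.0,
                    rng=None, seed=None, trait_cov=None, z0=0.0,
                    n_traits: int = 1, names=None,
                    clade_offsets: dict = None,
                    partition: CladePartition = None,
                    alpha: float = None, r: float = None) -> pd.DataFrame:
    """Simulate continuous traits root->tips on the tree.

    BM (optionally rate-mapped and cross-correlated via ``trait_cov``),
    EB (``r`` <= 0, via time-transformed branches) or single-optimum OU
    (``alpha``). Clade mean offsets (trait name -> offset) are added to the
    focal partition's tips after simulation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if trait_cov is not None:
        n_traits = len(trait_cov)
    if model == "BM":
        tips = simulate_bm_tips(tree, sigma2, 1, rng, rate_map=rate_map,
                                trait_cov=trait_cov,
                                z0=0.0)[0]
        if trait_cov is None and n_traits > 1:
            more = simulate_bm_tips(tree, sigma2, n_traits - 1, rng,
                                    rate_map=rate_map)[..., 0].T
            tips = np.column_stack([tips, more])
        vals = z0 + tips
    elif model == "EB":
        from .phylo import _branch_segments_eb
        if r is None or r > 0:
            raise ValueError("EB simulation requires r <= 0")
        tr = tree
        bl = _branch_segments_eb(tree, r)
        tmp = Phylogeny(tree.parent.copy(), np.maximum(bl, 1e-12),
                        list(tree.labels), tree.root)
        return simulate_traits(tmp, rate_map, "BM", sigma2=sigma2, rng=rng,
                               trait_cov=trait_cov, z0=z0, n_traits=n_traits,
                               names=names, clade_offsets=clade_offsets,
                               partition=partition)
    elif model == "OU":
        if alpha is None or alpha <= 0:
            raise ValueError("OU simulation requires alpha > 0")
        mult = (rate_map.branch_multipliers(tree) if rate_map is not None
                else np.ones(tree.n_nodes))
        st = np.zeros((tree.n_nodes, n_traits))
        st[tree.root] = z0
        for v in tree.preorder():
            p = tree.parent[v]
            if p < 0:
                continue
            t = tree.branch_length[v]
            w = np.exp(-alpha * t)
            sd = np.sqrt(sigma2 * mult[v] * (1 - np.exp(-2 * alpha * t))
                         / (2 * alpha))
            st[v] = st[p] * w + z0 * (1 - w) + rng.standard_normal(n_traits) * sd
        vals = st[tree.tip_indices]
    else:
        raise ValueError(f"unknown simulation model {model!r}")
    names = names or [f"trait{i+1}" for i in range(vals.shape[1])]
    df = pd.DataFrame(vals, index=tree.tip_labels, columns=names)
    df.index.name = "species"
    if clade_offsets:
        if partition is None:
            raise ValueError("clade_offsets requires a partition")
        focal = partition.tip_labels(tree)
        for name, off in clade_offsets.items():
            df.loc[focal, name] += off
    return df


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def beak_template() -> np.ndarray:
    """Default 23-point beak outline: 3 landmarks plus 11 upper and 9 lower
    equally spaced semilandmarks (2-D, arbitrary units)."""
    lm1 = np.array([0.0, 0.30])   # craniofacial hinge
    lm2 = np.array([0.08, 0.0])   # antorbital fossa margin
    lm3 = np.array([1.0, 0.02])   # beak tip
    f_up = np.linspace(0, 1, 13)[1:-1]     # 11 between lm1 and lm3
    up = (1 - f_up)[:, None] * lm1 + f_up[:, None] * lm3
    up[:, 1] += 0.06 * np.sin(np.pi * f_up)   # culmen curvature
    f_lo = np.linspace(0, 1, 11)[1:-1]     # 9 between lm2 and lm3
    lo = (1 - f_lo)[:, None] * lm2 + f_lo[:, None] * lm3
    lo[:, 1] -= 0.02 * np.sin(np.pi * f_lo)
    return np.vstack([lm1, lm2, lm3, up, lo])


def simulate_landmarks(tree: Phylogeny, config: SimulationConfig,
                       partition: CladePartition = None, rng=None,
                       log_size: pd.Series = None,
                       template: np.ndarray = None) -> pd.DataFrame:
    """Specimen landmark table ``specimen,species,x1,y1,...,xk,yk``.

    Per species: template + evolved shape deviation + allometric displacement
    proportional to log centroid size; per specimen: random rotation,
    translation and scale (so GPA has work to do) plus coordinate noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.child_seeds(["landmarks"])["landmarks"])
    tpl = beak_template() if template is None else np.asarray(template, float)
    if tpl.shape[0] < 3:
        raise ValueError("need at least 3 landmarks")
    k = tpl.shape[0]
    n = tree.n_tips
    # latent shape factors evolved on the tree
    fac = simulate_bm_tips(tree, config.sigma2_shape, 3, rng)[..., 0].T  # (n,3)
    load_rng = np.random.default_rng(12345)   # fixed loading directions
    loadings = load_rng.standard_normal((3, k, 2))
    loadings /= np.linalg.norm(loadings.reshape(3, -1), axis=1)[:, None, None]
    allo_pat = load_rng.standard_normal((k, 2))
    allo_pat /= np.linalg.norm(allo_pat)
    if log_size is None:
        ls = simulate_traits(tree, sigma2=config.sigma2_body, rng=rng,
                             names=["log_size"],
                             clade_offsets=({"log_size": config.offset_body}
                                            if partition else None),
                             partition=partition)["log_size"]
    else:
        ls = log_size.reindex(tree.tip_labels)
    ls_c = ls - ls.mean()
    rows = []
    spec_id = 0
    for i, sp in enumerate(tree.tip_labels):
        dev = np.einsum("f,fkc->kc", fac[i], loadings)
        shape = tpl + dev + config.shape_allometry * ls_c.iloc[i] * allo_pat
        for _ in range(config.n_specimens):
            cfg = shape + rng.standard_normal((k, 2)) * config.specimen_noise
            th = rng.uniform(-np.pi, np.pi)
            R = np.array([[np.cos(th), -np.sin(th)],
                          [np.sin(th), np.cos(th)]])
            scale = np.exp(ls.iloc[i] + rng.normal(0, 0.02))
            cfg = scale * cfg @ R.T + rng.uniform(-5, 5, size=2)
            rows.append([f"spec{spec_id}", sp] + cfg.ravel().tolist())
            spec_id += 1
    cols = (["specimen", "species"]
            + [f"{ax}{j+1}" for j in range(k) for ax in ("x", "y")])
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

def simulate_occurrences(tree: Phylogeny, config: SimulationConfig,
                         partition: CladePartition = None, rng=None
                         ) -> pd.DataFrame:
    """Occurrence table ``species,lon,lat,<climate...>``.

    Species positions in 2 latent climate axes evolve by BM on the tree;
    focal-clade species receive shifted means and widened SDs. Observable
    climate columns are noisy linear readouts of the latent axes (a
    temperature-like and a precipitation-like family).
    """
    if config.niche_sd <= 0:
        raise ValueError("niche SD must be positive")
    if rng is None:
        rng = np.random.default_rng(config.child_seeds(["occ"])["occ"])
    n = tree.n_tips
    latent = simulate_bm_tips(tree, config.sigma2_niche, 2, rng)[..., 0].T
    sds = np.full((n, 2), config.niche_sd)
    focal_idx = []
    if partition is not None:
        focal = set(partition.tip_labels(tree))
        focal_idx = [i for i, sp in enumerate(tree.tip_labels) if sp in focal]
        latent[focal_idx] += np.asarray(config.focal_niche_shift)
        sds[focal_idx] *= config.focal_niche_widen
    centroids = np.column_stack([rng.uniform(-150, 150, n),
                                 rng.uniform(-55, 65, n)])
    m = config.records_per_species
    half = config.n_climate_vars // 2
    read_rng = np.random.default_rng(54321)
    w_t = read_rng.uniform(0.8, 1.2, half)       # temperature family
    w_p = read_rng.uniform(0.8, 1.2, config.n_climate_vars - half)
    frames = []
    for i, sp in enumerate(tree.tip_labels):
        c1 = rng.normal(latent[i, 0], sds[i, 0], m)
        c2 = rng.normal(latent[i, 1], sds[i, 1], m)
        lon = np.clip(rng.normal(centroids[i, 0], config.geo_jitter, m),
                      -180, 180)
        lat = np.clip(rng.normal(centroids[i, 1], config.geo_jitter, m),
                      -90, 90)
        cols = {"species": sp, "lon": lon, "lat": lat}
        for j in range(half):
            cols[f"temp{j+1}"] = w_t[j] * c1 + rng.normal(0, 0.3, m)
        for j in range(config.n_climate_vars - half):
            cols[f"prec{j+1}"] = w_p[j] * c2 + rng.normal(0, 0.3, m)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic bundle with a manifest of true parameters."""
    config.validate()
    seeds = config.child_seeds(["tree", "traits", "landmarks", "occ"])
    rng_tree = np.random.default_rng(seeds["tree"])
    tree, partition, div_map = simulate_tree(config, rng_tree)
    trait_map = paint_clade(tree, partition, config.trait_rate_multiplier)
    rng_tr = np.random.default_rng(seeds["traits"])
    body = simulate_traits(tree, trait_map, sigma2=config.sigma2_body,
                           rng=rng_tr, names=["body"],
                           clade_offsets={"body": config.offset_body},
                           partition=partition)["body"]
    cols = {}
    # log femur tracks latent body size closely; other measurements are
    # allometric readouts with their own (rate-shifted) BM residuals
    for j, name in enumerate(
            [f"lin{j+1}" for j in range(config.n_linear)]):
        slope = 1.0 if j == 0 else config.allometric_slope
        resid = simulate_traits(tree, trait_map,
                                sigma2=config.sigma2_resid, rng=rng_tr,
                                names=["r"])["r"]
        cols[name] = slope * body + resid
    cols["femur"] = cols["lin1"]
    hwi = simulate_traits(tree, sigma2=config.sigma2_resid * 2, rng=rng_tr,
                          names=["hwi"],
                          clade_offsets={"hwi": config.offset_hwi},
                          partition=partition)["hwi"]
    cols["hwi"] = hwi
    brain_resid = simulate_traits(tree, sigma2=config.sigma2_resid,
                                  rng=rng_tr, names=["b"],
                                  clade_offsets={"b": config.offset_brain},
                                  partition=partition)["b"]
    cols["brain"] = config.brain_slope * cols["femur"] + brain_resid
    traits = pd.DataFrame(cols, index=tree.tip_labels)
    traits.index.name = "species"

    rng_lm = np.random.default_rng(seeds["landmarks"])
    landmarks = simulate_landmarks(tree, config, partition, rng_lm,
                                   log_size=body)
    rng_occ = np.random.default_rng(seeds["occ"])
    occurrences = simulate_occurrences(tree, config, partition, rng_occ)
    manifest = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()}
    manifest.update({
        "n_tips": int(tree.n_tips),
        "n_focal_tips": int(len(partition.tip_set(tree))),
        "focal_node": int(partition.focal_node),
        "focal_tips": partition.tip_labels(tree),
        "diversification_multiplier": config.lambda1 / config.lambda0,
    })
    return SyntheticDataset(tree, partition, trait_map, traits, landmarks,
                            occurrences, manifest)


def write_bundle(ds: SyntheticDataset, outdir) -> None:
    """Write the bundle in the plain-text formats the readers consume."""
    import os
    from .phylo import write_newick, write_rate_map_csv, write_trait_csv
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(write_newick(ds.tree) + "\n")
    write_trait_csv(ds.traits, os.path.join(outdir, "traits.csv"))
    ds.landmarks.to_csv(os.path.join(outdir, "landmarks.csv"), index=False)
    ds.occurrences.to_csv(os.path.join(outdir, "occurrences.csv"), index=False)
    write_rate_map_csv(ds.rate_map, os.path.join(outdir, "rate_map.csv"))
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(ds.manifest, fh, sort_keys=True)
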