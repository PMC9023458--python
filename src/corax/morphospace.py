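"""Geometric morphometrics: Procrustes superimposition, centroid size,
phylogenetic PCA, allometry testing/correction, alpha-hull morphospace
areas and extreme-shape reconstruction.

Landmark configurations are 2-D (k points x 2). Generalized Procrustes
analysis (GPA) iteratively removes translation, scale and rotation against
the current mean shape; semilandmarks are treated as fixed points (no
bending-energy sliding). The phylogenetic PCA estimates the evolutionary
trait covariance by GLS cross-products of phylogenetically whitened,
phylogenetic-mean-centered data under a chosen evolutionary model, converts
it to a correlation matrix and eigen-decomposes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial import ConvexHull, Delaunay, QhullError
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .phylo import Phylogeny, phylo_covariance
from .traitmodels import compare_models

__all__ = [
    "LandmarkSet", "gpa_align", "centroid_size",
    "PPCAResult", "ppca", "reconstruct_extreme_shape",
    "allometry_test", "AllometryTest", "size_free_residuals",
    "alpha_hull_area", "landmarks_from_frame", "species_mean_shapes",
]


@dataclass
class LandmarkSet:
    """Specimen landmark configurations.

    coords: (n_specimens, k, 2); aligned configurations have centroid at the
    origin and unit centroid size.
    """

    specimen: list
    species: list
    coords: np.ndarray
    aligned: bool = False
    centroid_sizes: np.ndarray = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must be (n, k, 2)")
        if self.coords.shape[1] < 3:
            raise ValueError("need at least 3 landmarks")

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.coords.shape[0]


def landmarks_from_frame(df: pd.DataFrame) -> LandmarkSet:
    """Build a LandmarkSet from a ``specimen,species,x1,y1,...`` table."""
    coord_cols = [c for c in df.columns if c not in ("specimen", "species")]
    k = len(coord_cols) // 2
    coords = df[coord_cols].to_numpy(dtype=float).reshape(-1, k, 2)
    return LandmarkSet(df["specimen"].tolist(), df["species"].tolist(),
                       coords)


def centroid_size(config) -> float:
    """Square root of the summed squared distances of each landmark from
    the configuration centroid."""
    X = np.asarray(config, dtype=float)
    c = X.mean(axis=0)
    return float(np.sqrt(((X - c) ** 2).sum()))


def _rotate_onto(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal rotation (det +1) of X onto ref; both centered."""
    U, _, Vt = np.linalg.svd(ref.T @ X)
    R = (U @ Vt)
    if np.linalg.det(R) < 0:   # forbid reflection
        U2 = U.copy()
        U2[:, -1] *= -1
        R = U2 @ Vt
    return X @ R.T


def gpa_align(lms: LandmarkSet, tol: float = 1e-8, max_iter: int = 100
              ) -> LandmarkSet:
    """Generalized Procrustes alignment.

    Each configuration is centered, scaled to unit centroid size and
    iteratively rotated to the running mean shape until the mean changes by
    less than ``tol``. Returns a new LandmarkSet with pre-alignment centroid
    sizes attached.
    """
    X = lms.coords.copy()
    n, k, _ = X.shape
    cs = np.array([centroid_size(X[i]) for i in range(n)])
    if np.any(cs <= 0):
        raise ValueError("degenerate (zero-size) configuration")
    X -= X.mean(axis=1, keepdims=True)
    X /= cs[:, None, None]
    spans = np.array([np.linalg.svd(X[i], compute_uv=False) for i in range(n)])
    if np.any(spans[:, 1] < 1e-12):
        raise ValueError("collinear landmark configuration")
    mean = X[0].copy()
    mean /= np.linalg.norm(mean)
    for _ in range(max_iter):
        for i in range(n):
            X[i] = _rotate_onto(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.linalg.norm(new_mean)
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    for i in range(n):
        X[i] = _rotate_onto(X[i], mean)
    # canonical orientation: principal axes of the mean shape (det +1),
    # with the first landmark's x-coordinate non-negative — makes the
    # output invariant to arbitrary similarity transforms of the input
    cov = mean.T @ mean
    evals, evecs = np.linalg.eigh(cov)
    R = evecs[:, ::-1]
    if np.linalg.det(R) < 0:
        R[:, 1] *= -1
    mean = mean @ R
    if mean[0, 0] < 0:
        mean = -mean                      # rotation by pi
        R = -R
    X = X @ R
    return LandmarkSet(list(lms.specimen), list(lms.species), X,
                       aligned=True, centroid_sizes=cs)


def species_mean_shapes(aligned: LandmarkSet):
    """Per-species mean of aligned configurations and mean log centroid
    size; returns (DataFrame of flattened shapes, Series of log sizes)."""
    if not aligned.aligned:
        raise ValueError("run gpa_align first")
    df = pd.DataFrame(aligned.coords.reshape(len(aligned), -1))
    df["species"] = aligned.species
    mean_shape = df.groupby("species").mean()
    mean_shape.columns = [f"{ax}{j+1}" for j in range(aligned.k)
                          for ax in ("x", "y")]
    ls = pd.Series(np.log(aligned.centroid_sizes), index=aligned.species)
    log_size = ls.groupby(level=0).mean()
    return mean_shape, log_size


# ---------------------------------------------------------------------------
# Phylogenetic PCA
# ---------------------------------------------------------------------------

@dataclass
class PPCAResult:
    loadings: np.ndarray          # (d, d) eigenvectors in columns
    scores: pd.DataFrame          # (n, d) species scores
    percent_variance: np.ndarray
    phylo_mean: np.ndarray
    model: str
    trait_names: list
    trait_sd: np.ndarray          # sqrt of evolutionary variances
    is_landmark: bool = False
    n_landmarks: int = 0

    def summary(self) -> str:
        rows = [f"  PC{i+1}: {p:.2f}%"
                for i, p in enumerate(self.percent_variance[:5])]
        return (f"Phylogenetic PCA ({self.model} model, "
                f"{len(self.trait_names)} traits)\n" + "\n".join(rows))


def ppca(tree: Phylogeny, traits: pd.DataFrame, model: str = None,
         candidate_models=("BM", "EB", "OUfixedRoot"),
         is_landmark: bool = False) -> PPCAResult:
    """Phylogenetic PCA under an evolutionary model.

    With ``model=None`` the model is selected by summed per-trait AIC over
    the candidates. The evolutionary covariance is the GLS cross-product of
    whitened, phylo-mean-centered data; it is converted to a correlation
    matrix before the eigen-decomposition, and scores are the standardized
    centered data projected on the eigenvectors.
    """
    traits = traits.reindex(tree.tip_labels)
    if traits.isna().any().any():
        raise ValueError("traits incomplete for tree tips")
    X = traits.to_numpy(dtype=float)
    n, d = X.shape
    if d > n:
        raise ValueError(
            f"{d} traits for {n} species: reduce dimensionality first "
            "(e.g. PCA of specimen data or fewer landmarks)")
    if model is None:
        total_aic = {}
        for m in candidate_models:
            try:
                total_aic[m] = sum(
                    compare_models(tree, X[:, j], [m])["aic"].iloc[0]
                    for j in range(d))
            except Exception:
                total_aic[m] = np.inf
        model = min(total_aic, key=total_aic.get)
    theta = None
    if model == "BM":
        V = phylo_covariance(tree, "BM")
    else:
        # shape parameter: median of per-trait ML estimates
        from .traitmodels import fit_trait_model
        vals = []
        for j in range(d):
            f = fit_trait_model(tree, X[:, j], model)
            vals.append(f.alpha if f.alpha is not None
                        else (f.r if f.r is not None else f.lam))
        theta = float(np.median(vals))
        kw = ({"rate": theta} if model == "EB" else
              {"lam": theta} if model == "lambda" else {"alpha": theta})
        V = phylo_covariance(tree, model, **kw)
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    one = np.ones(n)
    Vi_X = linalg.cho_solve(cf, X, check_finite=False)
    Vi_1 = linalg.cho_solve(cf, one, check_finite=False)
    mu = (one @ Vi_X) / (one @ Vi_1)
    Xc = X - mu
    R = Xc.T @ linalg.cho_solve(cf, Xc, check_finite=False) / (n - 1)
    sd = np.sqrt(np.maximum(np.diag(R), 1e-300))
    corr = R / sd[:, None] / sd[None, :]
    evals, evecs = np.linalg.eigh(corr)
    idx = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[idx], 0.0), evecs[:, idx]
    # deterministic sign: largest |loading| positive
    for j in range(d):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1
    scores = (Xc / sd) @ evecs
    pct = 100.0 * evals / evals.sum()
    score_df = pd.DataFrame(scores, index=traits.index,
                            columns=[f"PC{i+1}" for i in range(d)])
    return PPCAResult(evecs, score_df, pct, mu, model,
                      list(traits.columns), sd,
                      is_landmark=is_landmark,
                      n_landmarks=d // 2 if is_landmark else 0)


def reconstruct_extreme_shape(res: PPCAResult, axis: int, score: float
                              ) -> np.ndarray:
    """Landmark configuration at ``score`` along a PC axis (k x 2).

    The configuration is the phylogenetic mean plus the back-scaled
    eigenvector displacement; score 0 returns the mean shape exactly.
    """
    if not res.is_landmark:
        raise ValueError("extreme shapes require a landmark-derived pPCA")
    if not (0 <= axis < res.loadings.shape[1]):
        raise ValueError("axis out of range")
    vec = res.phylo_mean + score * (res.trait_sd * res.loadings[:, axis])
    return vec.reshape(res.n_landmarks, 2)


def project_shape(res: PPCAResult, config) -> np.ndarray:
    """Scores of a flattened configuration in the pPCA space."""
    v = (np.asarray(config, dtype=float).ravel() - res.phylo_mean) / res.trait_sd
    return v @ res.loadings


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------

@dataclass
class AllometryTest:
    pillai: float
    pvalue: float
    nperm: int
    model: str
    slope: np.ndarray     # GLS shape-on-size coefficients

    def summary(self) -> str:
        return (f"Phylogenetic MANOVA of shape on log centroid size "
                f"({self.model} covariance, {self.nperm} permutations):\n"
                f"  Pillai's trace = {self.pillai:.4f}, p = {self.pvalue:.4g}")


def _whiten(tree, model, n):
    if model == "BM":
        V = phylo_covariance(tree, "BM")
    elif model == "EB":
        # EB with ML decay shared across shape coordinates is overkill for
        # the permutation test; moderate fixed decay relative to tree depth
        V = phylo_covariance(tree, "EB", rate=-1.0 / tree.root_age)
    else:
        V = phylo_covariance(tree, model)
    L = np.linalg.cholesky(V)
    return linalg.solve_triangular(L, np.eye(n), lower=True)


def _pillai(Yw, Xw):
    """Pillai's trace for H0: size coefficient = 0, in whitened space."""
    Q, _ = np.linalg.qr(Xw)
    H_full = Q @ Q.T
    Qr, _ = np.linalg.qr(Xw[:, :1])
    H_red = Qr @ Qr.T
    E = Yw.T @ (np.eye(len(Yw)) - H_full) @ Yw
    H = Yw.T @ (H_full - H_red) @ Yw
    # dimensionality guard: project onto the non-degenerate subspace
    evals, evecs = np.linalg.eigh(E + H)
    keep = evals > max(evals.max(), 1.0) * 1e-9
    P = evecs[:, keep]
    Ep, Hp = P.T @ E @ P, P.T @ H @ P
    return float(np.trace(np.linalg.solve(Ep + Hp, Hp)))


def allometry_test(tree: Phylogeny, shape: pd.DataFrame, size: pd.Series,
                   nperm: int = 1000, seed=None, model: str = "EB"
                   ) -> AllometryTest:
    """Phylogenetic MANOVA of species mean shape on log centroid size.

    Pillai's trace of the size effect in phylogenetically whitened space;
    the p-value permutes the whitened residuals of the reduced
    (intercept-only) model.
    """
    if nperm < 100:
        warnings.warn("nperm < 100 gives an unstable p-value", stacklevel=2)
    shape = shape.reindex(tree.tip_labels)
    size = size.reindex(tree.tip_labels)
    Y = shape.to_numpy(dtype=float)
    s = np.log(size.to_numpy(dtype=float)) if (size > 0).all() \
        else size.to_numpy(dtype=float)
    n = len(s)
    W = _whiten(tree, model, n)
    Yw = W @ Y
    Xw = W @ np.column_stack([np.ones(n), s - s.mean()])
    obs = _pillai(Yw, Xw)
    # reduced-model whitened residuals, permuted
    Qr, _ = np.linalg.qr(Xw[:, :1])
    resid = Yw - Qr @ (Qr.T @ Yw)
    fit_red = Yw - resid
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(nperm):
        perm = rng.permutation(n)
        Yp = fit_red + resid[perm]
        if _pillai(Yp, Xw) >= obs - 1e-12:
            count += 1
    p = (count + 1) / (nperm + 1)
    beta = np.linalg.lstsq(Xw, Yw, rcond=None)[0]
    return AllometryTest(pillai=obs, pvalue=p, nperm=nperm, model=model,
                         slope=beta[1])


def size_free_residuals(tree: Phylogeny, shape: pd.DataFrame,
                        size: pd.Series, model: str = "EB") -> pd.DataFrame:
    """GLS residuals of shape on log size — allometry-corrected shape data
    ready for a downstream pPCA."""
    shape = shape.reindex(tree.tip_labels)
    size = size.reindex(tree.tip_labels)
    Y = shape.to_numpy(dtype=float)
    s = np.log(size.to_numpy(dtype=float)) if (size > 0).all() \
        else size.to_numpy(dtype=float)
    n = len(s)
    W = _whiten(tree, model, n)
    Yw, Xw = W @ Y, W @ np.column_stack([np.ones(n), s])
    beta = np.linalg.lstsq(Xw, Yw, rcond=None)[0]
    resid = Y - np.column_stack([np.ones(n), s]) @ beta
    return pd.DataFrame(resid, index=shape.index, columns=shape.columns)


# ---------------------------------------------------------------------------
# Alpha hull
# ---------------------------------------------------------------------------

def alpha_hull_area(points, alpha: float) -> float:
    """Area of the alpha-shape of 2-D points.

    Delaunay triangles whose circumradius is at most ``alpha`` are kept and
    their union taken; as alpha grows the area converges to the convex hull
    area. Collinear point sets have area 0 (with a warning).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2 or P.shape[0] < 3:
        raise ValueError("need >= 3 points in 2-D")
    try:
        tri = Delaunay(P)
    except QhullError:
        warnings.warn("collinear points: alpha-hull area is 0", stacklevel=2)
        return 0.0
    polys = []
    for simplex in tri.simplices:
        a, b, c = P[simplex]
        la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c),
                      np.linalg.norm(a - b))
        u, w = b - a, c - a
        area2 = abs(u[0] * w[1] - u[1] * w[0])   # twice the triangle area
        if area2 < 1e-300:
            continue
        circum_r = la * lb * lc / (2 * area2)
        if circum_r <= alpha:
            polys.append(Polygon([a, b, c]))
    if not polys:
        return 0.0
    return float(unary_union(polys).area)
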