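"""Maximum-likelihood models of continuous trait evolution on a phylogeny.

The workhorse is :class:`PhyloTraitModel`, a statsmodels-style model object:
build it from a tree and a trait vector, call ``fit()`` and get a
:class:`TraitModelResult` with estimates, log-likelihood, AIC and a
``summary()`` table. :class:`PGLS` does phylogenetic generalized least
squares (including phylogenetic ANOVA via dummy-coded groups); ancestral
state reconstruction, time-slice averages and phenogram coordinates support
the through-time visual summaries.

All fits are ML (not REML) so that AIC comparisons across models are valid;
a REML flag is available on PGLS for variance-component use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import CladePartition, Phylogeny, RateMap, phylo_covariance

__all__ = [
    "PhyloTraitModel", "TraitModelResult", "fit_trait_model",
    "compare_models", "PGLS", "PGLSResult", "pgls",
    "AncestralStates", "ancestral_states",
    "time_slice_means", "phenogram_coords",
]

TRAIT_MODELS = ("BM", "EB", "OUfixedRoot", "OUrandomRoot", "lambda")
_N_PARAMS = {"BM": 2, "EB": 3, "OUfixedRoot": 3, "OUrandomRoot": 3,
             "lambda": 3}


def _profile_loglik(V: np.ndarray, x: np.ndarray):
    """Profile z0 (GLS mean) and sigma^2 out of the MVN likelihood.

    Returns (loglik, z0_hat, sigma2_hat). V is covariance up to sigma^2.
    """
    n = len(x)
    try:
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular phylogenetic covariance; consider jittering branch "
            "lengths or reducing model flexibility"
        ) from exc
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    one = np.ones(n)
    Vi_x = linalg.cho_solve(cf, x, check_finite=False)
    Vi_1 = linalg.cho_solve(cf, one, check_finite=False)
    z0 = (one @ Vi_x) / (one @ Vi_1)
    r = x - z0
    q = r @ linalg.cho_solve(cf, r, check_finite=False)
    sigma2 = max(q / n, 1e-300)
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + n)
    return ll, z0, sigma2


@dataclass
class TraitModelResult:
    """ML fit of a single-trait evolutionary model."""

    model: str
    sigma2: float
    z0: float
    loglik: float
    n: int
    k: int
    alpha: float = None     # OU pull, 1/time
    r: float = None         # EB decay, <= 0, 1/time
    lam: float = None       # Pagel's lambda in [0, 1]
    messages: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    def params_dict(self) -> dict:
        out = {"model": self.model, "sigma2": self.sigma2, "z0": self.z0,
               "loglik": self.loglik, "aic": self.aic, "n": self.n}
        for name in ("alpha", "r", "lam"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out

    def summary(self) -> str:
        lines = [f"Trait model: {self.model} (n={self.n}, k={self.k})",
                 f"  loglik = {self.loglik:.4f}   AIC = {self.aic:.4f}",
                 f"  sigma2 = {self.sigma2:.6g}   z0 = {self.z0:.6g}"]
        for name, sym in (("alpha", "alpha"), ("r", "r"), ("lam", "lambda")):
            v = getattr(self, name)
            if v is not None:
                lines.append(f"  {sym} = {v:.6g}")
        for m in self.messages:
            lines.append(f"  note: {m}")
        return "\n".join(lines)


class PhyloTraitModel:
    """Continuous-trait evolutionary model on a time-calibrated tree.

    Parameters
    ----------
    tree : Phylogeny
    trait : array-like or pandas Series indexed by species (tip labels)
    model : one of BM, EB, OUfixedRoot, OUrandomRoot, lambda
    measurement_var : optional per-species variance added to the covariance
        diagonal (intraspecific/measurement error); scalar or vector.
    """

    def __init__(self, tree: Phylogeny, trait, model: str = "BM",
                 measurement_var=0.0):
        if model not in TRAIT_MODELS:
            raise ValueError(f"model must be one of {TRAIT_MODELS}")
        self.tree = tree
        self.model = model
        if isinstance(trait, pd.Series):
            trait = trait.reindex(tree.tip_labels)
            if trait.isna().any():
                raise ValueError("trait missing for some tips")
            trait = trait.to_numpy(dtype=float)
        self.x = np.asarray(trait, dtype=float)
        if not np.isfinite(self.x).all():
            raise ValueError("non-finite trait values")
        if len(self.x) != tree.n_tips:
            raise ValueError("trait length != number of tips")
        if _N_PARAMS[model] > 2 and tree.n_tips < 3:
            raise ValueError("need >= 3 species for models with a shape "
                             "parameter")
        if model == "OUrandomRoot" and not tree.is_ultrametric():
            raise ValueError("stationary-root OU requires an ultrametric tree")
        self.me_var = np.broadcast_to(np.asarray(measurement_var, float),
                                      (tree.n_tips,)).copy()
        self._T = tree.root_age if tree.root_age > 0 else 1.0
        self._Cbm = phylo_covariance(tree, "BM")
        self._tip_depths = tree.depths()[tree.tip_indices]

    def _cov(self, theta: float = None) -> np.ndarray:
        from .phylo import covariance_from_bm
        m = self.model
        if m == "BM":
            return self._Cbm
        kw = ({"rate": theta} if m == "EB" else
              {"lam": theta} if m == "lambda" else {"alpha": theta})
        return covariance_from_bm(self._Cbm, self._tip_depths, m, **kw)

    def _profile(self, theta=None):
        V = self._cov(theta)
        if np.any(self.me_var > 0):
            # sigma^2 no longer profiles cleanly; fold error in units of the
            # phylogenetic variance via a 1-D inner optimization over the
            # ratio error/sigma2.
            def neg(lr):
                Ve = V + np.exp(lr) * np.diag(self.me_var / self.me_var.max())
                return -_profile_loglik(Ve, self.x)[0]
            res = optimize.minimize_scalar(neg, bounds=(-12, 12),
                                           method="bounded")
            V = V + np.exp(res.x) * np.diag(self.me_var / self.me_var.max())
        return _profile_loglik(V, self.x)

    def theta_bounds(self):
        T = self._T
        if self.model == "EB":
            return (-10.0 / T, 0.0)
        if self.model == "lambda":
            return (0.0, 1.0)
        return (1e-6 / T, 50.0 / T)  # OU alpha

    def fit(self, restarts: int = 6) -> TraitModelResult:
        msgs = []
        if self.model == "BM":
            ll, z0, s2 = self._profile()
            return TraitModelResult("BM", s2, z0, ll, self.tree.n_tips, 2)
        lo, hi = self.theta_bounds()
        # log-spaced starts (linear for EB/lambda which include 0)
        if self.model in ("OUfixedRoot", "OUrandomRoot"):
            starts = np.geomspace(max(lo, 1e-5), hi, restarts)
        else:
            starts = np.linspace(lo, hi, restarts + 2)[1:-1]

        def neg(theta):
            try:
                return -self._profile(float(np.atleast_1d(theta)[0]))[0]
            except np.linalg.LinAlgError:
                return 1e12

        # coarse multistart scan, then one bounded refinement in the best
        # bracket (the profile likelihood is 1-D but can be multimodal)
        vals = [(neg(s0), s0) for s0 in starts]
        vals.sort()
        i = list(starts).index(vals[0][1])
        blo = starts[max(i - 1, 0)] if i > 0 else lo
        bhi = starts[min(i + 1, len(starts) - 1)] if i < len(starts) - 1 else hi
        res = optimize.minimize_scalar(neg, bounds=(min(blo, bhi),
                                                    max(blo, bhi)),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        res2 = optimize.minimize_scalar(neg, bounds=(lo, hi),
                                        method="bounded",
                                        options={"xatol": 1e-8})
        best = min((res.fun, float(res.x)), (res2.fun, float(res2.x)),
                   (vals[0][0], vals[0][1]))
        # guard against likelihood below the nested BM special case
        bm_ll = _profile_loglik(self._Cbm, self.x)[0]
        # EB, lambda and fixed-root OU include BM on their boundary (r=0,
        # lambda=1, alpha=0); the stationary-root OU does not nest BM.
        nested_theta = {"EB": 0.0, "lambda": 1.0, "OUfixedRoot": 0.0,
                        "OUrandomRoot": None}[self.model]
        if nested_theta is not None:
            nb = neg(nested_theta)
            if nb < best[0]:
                best = (nb, nested_theta)
        theta = best[1]
        ll, z0, s2 = self._profile(theta)
        if self.model == "lambda":
            offdiag = self._cov(1.0)
            np.fill_diagonal(offdiag, 0)
            if np.allclose(offdiag, 0):
                msgs.append("lambda unidentifiable on a star tree; "
                            "reported at boundary")
            if theta in (0.0, 1.0):
                msgs.append(f"lambda estimate at boundary ({theta:g})")
        kw = {"EB": "r", "lambda": "lam", "OUfixedRoot": "alpha",
              "OUrandomRoot": "alpha"}[self.model]
        return TraitModelResult(self.model, s2, z0, ll, self.tree.n_tips,
                                _N_PARAMS[self.model], messages=msgs,
                                **{kw: theta})


def fit_trait_model(tree: Phylogeny, trait, model: str = "BM",
                    **kw) -> TraitModelResult:
    return PhyloTraitModel(tree, trait, model, **kw).fit()


def compare_models(tree: Phylogeny, trait, models=TRAIT_MODELS
                   ) -> pd.DataFrame:
    """Fit candidate models and rank by AIC (ascending; ties -> fewer params).

    Returns a DataFrame with one row per model; failed fits are flagged in
    the ``error`` column and ranked last. The fitted result objects are in
    the ``result`` column.
    """
    if len(models) < 1:
        raise ValueError("need at least one candidate model")
    rows = []
    for m in models:
        try:
            fit = fit_trait_model(tree, trait, m)
            rows.append({"model": m, "aic": fit.aic, "loglik": fit.loglik,
                         "k": fit.k, "result": fit, "error": None})
        except Exception as exc:  # flag, keep ranking the others
            rows.append({"model": m, "aic": np.inf, "loglik": np.nan,
                         "k": _N_PARAMS.get(m, np.nan), "result": None,
                         "error": str(exc)})
    df = pd.DataFrame(rows).sort_values(["aic", "k"], kind="stable")
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSResult:
    """GLS regression under a phylogenetic error covariance."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    resid: pd.Series
    fittedvalues: pd.Series
    sigma2: float
    loglik: float
    k: int
    n: int
    model: str
    lam: float = None

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    def summary(self) -> str:
        tab = pd.DataFrame({"coef": self.params, "se": self.bse,
                            "t": self.tvalues, "p": self.pvalues})
        head = (f"PGLS ({self.model}"
                + (f", lambda={self.lam:.3f}" if self.lam is not None else "")
                + f"): n={self.n}, loglik={self.loglik:.3f}, "
                  f"AIC={self.aic:.3f}, sigma2={self.sigma2:.4g}")
        return head + "\n" + tab.to_string(float_format="%.5g")


class PGLS:
    """Phylogenetic generalized least squares.

    ``exog`` is a DataFrame of predictors (an intercept is added); the error
    covariance comes from the chosen evolutionary model. With
    ``model="lambda"`` and ``lam=None`` Pagel's lambda is ML-optimized.
    A binary/dummy group predictor makes this a phylogenetic ANOVA.
    """

    def __init__(self, tree: Phylogeny, endog, exog, model: str = "BM",
                 lam: float = None, add_intercept: bool = True):
        self.tree = tree
        tips = tree.tip_labels
        if isinstance(endog, pd.Series):
            endog = endog.reindex(tips).to_numpy(dtype=float)
        self.y = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.Series):
            exog = exog.to_frame()
        if isinstance(exog, pd.DataFrame):
            self.names = list(exog.columns)
            exog = exog.reindex(tips).to_numpy(dtype=float)
        else:
            exog = np.atleast_2d(np.asarray(exog, dtype=float))
            if exog.shape[0] != len(self.y):
                exog = exog.T
            self.names = [f"x{i}" for i in range(exog.shape[1])]
        if add_intercept:
            exog = np.column_stack([np.ones(len(self.y)), exog])
            self.names = ["intercept"] + self.names
        self.X = exog
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("collinear predictors (design matrix not full "
                             "rank)")
        self.model = model
        self.lam = lam

    def _cov(self, lam=None):
        if self.model == "lambda":
            return phylo_covariance(self.tree, "lambda",
                                    lam=1.0 if lam is None else lam)
        if self.model == "BM":
            return phylo_covariance(self.tree, "BM")
        raise ValueError("PGLS supports model in {'BM', 'lambda'}")

    @staticmethod
    def _gls(V, y, X):
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        Vi_X = linalg.cho_solve(cf, X, check_finite=False)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, Vi_X.T @ y)
        r = y - X @ beta
        q = r @ linalg.cho_solve(cf, r, check_finite=False)
        n = len(y)
        sigma2 = q / n
        ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(max(sigma2, 1e-300))
                     + logdet + n)
        return beta, r, sigma2, ll, XtViX

    def fit(self) -> PGLSResult:
        lam = self.lam
        if self.model == "lambda" and lam is None:
            def neg(l):
                return -self._gls(self._cov(l), self.y, self.X)[3]
            res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0),
                                           method="bounded",
                                           options={"xatol": 1e-7})
            lam = float(res.x)
        V = self._cov(lam)
        beta, r, sigma2, ll, XtViX = self._gls(V, self.y, self.X)
        n, p = self.X.shape
        dof = n - p
        s2_unbiased = sigma2 * n / dof
        cov_beta = s2_unbiased * np.linalg.inv(XtViX)
        se = np.sqrt(np.diag(cov_beta))
        tvals = beta / se
        pvals = 2 * stats.t.sf(np.abs(tvals), dof)
        k = p + 1 + (1 if (self.model == "lambda" and self.lam is None) else 0)
        tips = self.tree.tip_labels
        return PGLSResult(
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(se, index=self.names),
            tvalues=pd.Series(tvals, index=self.names),
            pvalues=pd.Series(pvals, index=self.names),
            resid=pd.Series(r, index=tips),
            fittedvalues=pd.Series(self.X @ beta, index=tips),
            sigma2=sigma2, loglik=ll, k=k, n=n,
            model=self.model, lam=lam,
        )


def pgls(tree: Phylogeny, endog, exog, model: str = "BM",
         lam: float = None) -> PGLSResult:
    """Convenience wrapper; see :class:`PGLS`. Residuals of a brain ~ body
    regression are the 'relative brain size' trait."""
    return PGLS(tree, endog, exog, model=model, lam=lam).fit()


# ---------------------------------------------------------------------------
# Ancestral states and through-time summaries
# ---------------------------------------------------------------------------

@dataclass
class AncestralStates:
    """GLS (ML) ancestral reconstruction under Brownian motion."""

    states: np.ndarray   # (n_nodes,)
    var: np.ndarray      # (n_nodes,)
    sigma2: float
    z0: float

    def as_series(self, tree: Phylogeny) -> pd.Series:
        idx = [tree.labels[i] or f"node{i}" for i in range(tree.n_nodes)]
        return pd.Series(self.states, index=idx)


def _all_node_cov(tree: Phylogeny) -> np.ndarray:
    """Shared-path-length matrix over *all* nodes (BM covariance, sigma2=1)."""
    n = tree.n_nodes
    depths = tree.depths()
    anc = [None] * n
    for v in tree.preorder():
        p = tree.parent[v]
        anc[v] = (anc[p] | {v}) if p >= 0 else {v}
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            m = anc[i] & anc[j]
            C[i, j] = C[j, i] = depths[max(m, key=lambda v: depths[v])]
    return C


def ancestral_states(tree: Phylogeny, trait) -> AncestralStates:
    """ML / GLS reconstruction of internal states under BM.

    Tip entries equal the observations with zero variance; the root estimate
    is the GLS phylogenetic mean.
    """
    if isinstance(trait, pd.Series):
        trait = trait.reindex(tree.tip_labels)
        if trait.isna().any():
            missing = [t for t in tree.tip_labels
                       if t not in trait.dropna().index]
            raise ValueError(f"missing tip values: {missing[:5]}")
        trait = trait.to_numpy(dtype=float)
    x = np.asarray(trait, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("missing/non-finite tip values (no imputation)")
    tips = tree.tip_indices
    Call = _all_node_cov(tree)
    Ctt = Call[np.ix_(tips, tips)]
    ll, z0, sigma2 = _profile_loglik(Ctt, x)
    cf = linalg.cho_factor(Ctt, lower=True, check_finite=False)
    w = linalg.cho_solve(cf, x - z0, check_finite=False)
    states = np.empty(tree.n_nodes)
    var = np.empty(tree.n_nodes)
    Cnt = Call[:, tips]
    states[:] = z0 + Cnt @ w
    Sol = linalg.cho_solve(cf, Cnt.T, check_finite=False)
    var[:] = sigma2 * (np.diag(Call) - np.einsum("ij,ji->i", Cnt, Sol))
    states[tips] = x
    var[tips] = 0.0
    var = np.maximum(var, 0.0)
    return AncestralStates(states, var, sigma2, z0)


def time_slice_means(tree: Phylogeny, states: AncestralStates, times,
                     partition: CladePartition = None,
                     mode: str = "include") -> pd.DataFrame:
    """Mean reconstructed state of the lineages crossing each time slice.

    ``times`` are ages (time before present) within [0, root age]. States
    are interpolated linearly along each branch spanning the slice. With a
    partition, ``mode="include"`` averages only lineages inside the focal
    clade and ``mode="exclude"`` only those outside — the with/without
    comparison of clade influence.
    """
    ages = tree.ages()
    T = tree.root_age
    sel = np.ones(tree.n_nodes, dtype=bool)
    if partition is not None:
        inside = np.zeros(tree.n_nodes, dtype=bool)
        inside[tree.clade_nodes(partition.focal_node,
                                include_self=partition.include_stem)] = True
        sel = inside if mode == "include" else ~inside
    rows = []
    for t in np.atleast_1d(np.asarray(times, dtype=float)):
        if t < -1e-9 or t > T + 1e-9:
            raise ValueError(f"slice time {t} outside [0, {T}]")
        t = min(max(t, 0.0), T)
        if t >= T - 1e-12:
            rows.append((t, states.states[tree.root], 1))
            continue
        vals = []
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0 or not sel[v]:
                continue
            if ages[p] > t >= ages[v] - 1e-12:
                ap, av = ages[p], ages[v]
                f = 0.0 if ap == av else (t - av) / (ap - av)
                vals.append(states.states[v] * (1 - f)
                            + states.states[p] * f)
        # tips exactly at the present when t == 0
        if not vals:
            rows.append((t, np.nan, 0))
        else:
            rows.append((t, float(np.mean(vals)), len(vals)))
    return pd.DataFrame(rows, columns=["age", "mean_state", "n_lineages"])


def phenogram_coords(tree: Phylogeny, trait, states: AncestralStates = None
                     ) -> np.ndarray:
    """Line segments projecting the tree into (time, trait) space.

    Returns an array of shape (n_branches, 4): columns are parent time,
    parent state, child time, child state, with time measured forward from
    the root. Tip endpoints equal the observed trait values.
    """
    if states is None:
        states = ancestral_states(tree, trait)
    if isinstance(trait, pd.Series):
        trait = trait.reindex(tree.tip_labels).to_numpy(dtype=float)
    depths = tree.depths()
    segs = []
    vals = states.states.copy()
    vals[tree.tip_indices] = np.asarray(trait, dtype=float)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        segs.append((depths[p], vals[p], depths[v], vals[v]))
    return np.array(segs)
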