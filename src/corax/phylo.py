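"""Phylogeny container, Newick I/O, clade algebra and phylogenetic covariance.

Branch lengths are in units of time (e.g. Myr); all variance-like rate
parameters carry the trait-variance units. Trees are rooted; polytomies are
accepted and treated as hard.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "CladePartition",
    "RateMap",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "branching_times",
    "phylo_covariance",
    "paint_clade",
    "read_trait_csv",
    "write_trait_csv",
    "read_rate_map_csv",
    "write_rate_map_csv",
]

ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


@dataclass
class Phylogeny:
    """Rooted tree stored as parent-pointer arrays.

    Nodes are integers ``0..n_nodes-1``; the root has parent ``-1``.
    ``labels[i]`` is the tip label for tips and an optional internal label
    (e.g. bootstrap text) otherwise. Node ages are times before present;
    for non-ultrametric trees the youngest tip defines the present.
    """

    parent: np.ndarray          # (n_nodes,) int, -1 at root
    branch_length: np.ndarray   # (n_nodes,) float, length of edge above node
    labels: list                # (n_nodes,) str or None
    root: int

    # derived, filled in __post_init__
    children: list = field(default_factory=list, repr=False)
    is_tip: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.parent)
        self.parent = np.asarray(self.parent, dtype=int)
        self.branch_length = np.asarray(self.branch_length, dtype=float)
        self.children = [[] for _ in range(n)]
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                self.children[p].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self):
        if (self.parent == -1).sum() != 1:
            raise TreeValidationError("tree must have exactly one root")
        if self.parent[self.root] != -1:
            raise TreeValidationError("root node has a parent")
        tips = self.tip_labels
        if len(set(tips)) != len(tips):
            dups = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dups}")
        nontip = ~self.is_tip
        nontip[self.root] = False
        bl = self.branch_length
        if np.any(bl[self.is_tip | nontip] <= 0):
            bad = np.where((bl <= 0) & (np.arange(len(bl)) != self.root))[0]
            if bad.size:
                raise TreeValidationError(
                    f"non-positive branch length at nodes {bad.tolist()}"
                )
        if bl[self.root] < 0:
            raise TreeValidationError("negative root stem length")

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_indices(self) -> np.ndarray:
        return np.where(self.is_tip)[0]

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices]

    def postorder(self) -> list:
        """Node ids, children before parents."""
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def preorder(self) -> list:
        return self.postorder()[::-1]

    def depths(self) -> np.ndarray:
        """Time from the root to each node (root depth 0)."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.branch_length[v]
        return d

    def ages(self) -> np.ndarray:
        """Time before present of each node; present = deepest tip."""
        d = self.depths()
        return d[self.tip_indices].max() - d

    @property
    def root_age(self) -> float:
        return float(self.ages()[self.root])

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.depths()[self.tip_indices]
        span = d.max()
        return bool(span == 0 or (d.max() - d.min()) <= rtol * span)

    # -- clade algebra ---------------------------------------------------
    def clade_tips(self, node: int) -> np.ndarray:
        """Tip indices descending from ``node`` (node itself if a tip)."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_tip[v]:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return np.array(sorted(out), dtype=int)

    def clade_nodes(self, node: int, include_self: bool = True) -> np.ndarray:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        if not include_self:
            out.remove(node)
        return np.array(sorted(out), dtype=int)

    def mrca(self, labels) -> int:
        idx = {self.labels[i]: i for i in self.tip_indices}
        missing = [l for l in labels if l not in idx]
        if missing:
            raise KeyError(f"labels not in tree: {missing}")
        depths = self.depths()
        nodes = [idx[l] for l in labels]
        paths = []
        for v in nodes:
            path = set()
            while v != -1:
                path.add(v)
                v = self.parent[v]
            paths.append(path)
        common = set.intersection(*paths)
        return int(max(common, key=lambda v: depths[v]))

    def drop_tips(self, labels) -> "Phylogeny":
        """Prune the named tips, suppressing unifurcations created."""
        drop = set(labels)
        missing = drop - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        keep_tips = [i for i in self.tip_indices if self.labels[i] not in drop]
        if len(keep_tips) < 2:
            raise TreeValidationError("pruning would leave fewer than 2 tips")
        keep = np.zeros(self.n_nodes, dtype=bool)
        for t in keep_tips:
            v = t
            while v != -1 and not keep[v]:
                keep[v] = True
                v = self.parent[v]
        # rebuild, suppressing nodes with a single kept child
        new_parent, new_bl, new_labels = [], [], []
        mapping = {}

        def kept_children(v):
            return [c for c in self.children[v] if keep[c]]

        def build(v, parent_new, extra_bl):
            ch = kept_children(v)
            if len(ch) == 1 and not self.is_tip[v]:
                build(ch[0], parent_new, extra_bl + self.branch_length[ch[0]])
                return
            idx = len(new_parent)
            mapping[v] = idx
            new_parent.append(parent_new)
            new_bl.append(extra_bl)
            new_labels.append(self.labels[v])
            for c in ch:
                build(c, idx, self.branch_length[c])

        # root: walk down until a node with >= 2 kept children
        r = self.root
        while not self.is_tip[r] and len(kept_children(r)) == 1:
            r = kept_children(r)[0]
        build(r, -1, 0.0)
        return Phylogeny(np.array(new_parent), np.array(new_bl),
                         new_labels, root=0)

    def keep_tips(self, labels) -> "Phylogeny":
        keep = set(labels)
        return self.drop_tips([l for l in self.tip_labels if l not in keep])


@dataclass(frozen=True)
class CladePartition:
    """A focal clade versus the remainder of the tree."""

    focal_node: int
    include_stem: bool = True

    def validate(self, tree: Phylogeny) -> None:
        if tree.is_tip[self.focal_node]:
            raise ValueError("focal node must be internal")
        if self.focal_node == tree.root:
            raise ValueError("focal node may not be the root (no complement)")

    def tip_set(self, tree: Phylogeny) -> np.ndarray:
        self.validate(tree)
        return tree.clade_tips(self.focal_node)

    def tip_labels(self, tree: Phylogeny) -> list:
        return [tree.labels[i] for i in self.tip_set(tree)]


@dataclass
class RateMap:
    """Branch -> regime assignment with per-regime rate multipliers.

    ``regime[i]`` is the regime id of the edge above node ``i`` (the root
    entry is unused). Regime 1 is the reference with multiplier 1.
    """

    regime: np.ndarray               # (n_nodes,) int
    multipliers: dict                # regime id -> multiplier (> 0)

    def __post_init__(self):
        self.regime = np.asarray(self.regime, dtype=int)
        if not any(abs(m - 1.0) < 1e-12 for m in self.multipliers.values()):
            raise ValueError("at least one regime must have multiplier 1")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("rate multipliers must be positive")
        present = set(np.unique(self.regime).tolist())
        missing = present - set(self.multipliers)
        if missing:
            raise ValueError(f"regimes without multipliers: {sorted(missing)}")

    @classmethod
    def uniform(cls, tree: Phylogeny) -> "RateMap":
        return cls(np.ones(tree.n_nodes, dtype=int), {1: 1.0})

    def branch_multipliers(self, tree: Phylogeny) -> np.ndarray:
        mult = np.ones(tree.n_nodes)
        for rid, m in self.multipliers.items():
            mult[self.regime == rid] = m
        return mult


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Internal labels and support values are stored as node attributes
    (in ``labels``), never interpreted as branch lengths.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty Newick string")
    s = text.strip()
    if s.count("(") != s.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {s.count('(')} '(' vs {s.count(')')} ')'"
        )
    if not s.endswith(";"):
        s += ";"
    try:
        dtree = dendropy.Tree.get(
            data=s, schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    parent = np.full(len(dnodes), -1, dtype=int)
    bl = np.zeros(len(dnodes))
    labels = [None] * len(dnodes)
    for nd in dnodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
        if nd.edge.length is not None:
            bl[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label is not None:
            labels[i] = nd.label
    return Phylogeny(parent, bl, labels, root=0)


def write_newick(tree: Phylogeny, precision: int = 12) -> str:
    """Serialize a Phylogeny to Newick, preserving branch lengths."""

    def fmt(x):
        return np.format_float_positional(x, precision=precision, trim="-")

    def rec(v):
        if tree.is_tip[v]:
            s = tree.labels[v]
        else:
            s = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
            if tree.labels[v]:
                s += str(tree.labels[v])
        if v != tree.root:
            s += ":" + fmt(tree.branch_length[v])
        elif tree.branch_length[v] > 0:
            s += ":" + fmt(tree.branch_length[v])
        return s

    return rec(tree.root) + ";"


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        text = fh.read()
    try:
        return parse_newick(text)
    except NewickParseError as exc:
        raise NewickParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Branching times
# ---------------------------------------------------------------------------

def branching_times(tree: Phylogeny, force: bool = False) -> np.ndarray:
    """Ages of internal nodes, descending; first entry is the root age."""
    if not force and not tree.is_ultrametric():
        raise ValueError(
            "tree is not ultrametric; pass force=True to use mean tip depth"
        )
    ages = tree.ages()
    internal = np.where(~tree.is_tip)[0]
    return np.sort(ages[internal])[::-1]


# ---------------------------------------------------------------------------
# Phylogenetic covariance
# ---------------------------------------------------------------------------

def _branch_segments_eb(tree: Phylogeny, r: float) -> np.ndarray:
    """Early-burst transformed branch lengths: integral of exp(r t) over
    each branch, t measured from the root."""
    if r > 0:
        raise ValueError("EB decay rate r must be <= 0")
    depths = tree.depths()
    bl = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        t0, t1 = depths[p], depths[v]
        if r == 0:
            bl[v] = t1 - t0
        else:
            bl[v] = (np.exp(r * t1) - np.exp(r * t0)) / r
    return bl


def _shared_path_matrix(tree: Phylogeny, bl: np.ndarray) -> np.ndarray:
    """C_ij = sum of (possibly transformed) branch lengths on the shared
    root-to-MRCA path of tips i and j."""
    n_tips = tree.n_tips
    tip_pos = {t: k for k, t in enumerate(tree.tip_indices)}
    wdepth = np.zeros(tree.n_nodes)
    for v in tree.preorder():
        p = tree.parent[v]
        wdepth[v] = (wdepth[p] if p >= 0 else 0.0) + (bl[v] if p >= 0 else 0.0)
    C = np.zeros((n_tips, n_tips))
    # diagonal
    for t, k in tip_pos.items():
        C[k, k] = wdepth[t]
    # off-diagonal: fill per internal node, pairs split across children
    tipsets = {}
    for v in tree.postorder():
        if tree.is_tip[v]:
            tipsets[v] = [tip_pos[v]]
        else:
            kids = [tipsets[c] for c in tree.children[v]]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia = np.array(kids[a])
                    ib = np.array(kids[b])
                    C[np.ix_(ia, ib)] = wdepth[v]
                    C[np.ix_(ib, ia)] = wdepth[v]
            merged = [i for k in kids for i in k]
            tipsets[v] = merged
    return C


def phylo_covariance(tree: Phylogeny, model: str = "BM", *,
                     rate: float = None, lam: float = None,
                     alpha: float = None, rate_map: RateMap = None
                     ) -> np.ndarray:
    """Expected trait covariance among tips, up to the factor sigma^2.

    model: "BM", "EB" (decay ``rate`` r <= 0), "lambda" (Pagel lambda
    ``lam`` in [0,1]), "OUfixedRoot" or "OUrandomRoot" (``alpha`` > 0).
    A ``rate_map`` scales per-branch variance (BM / EB only).
    """
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips")
    mult = (rate_map.branch_multipliers(tree)
            if rate_map is not None else np.ones(tree.n_nodes))
    model = model.upper() if model.upper() != "LAMBDA" else "lambda"
    if model == "BM":
        return _shared_path_matrix(tree, tree.branch_length * mult)
    if model == "EB":
        if rate is None:
            raise ValueError("EB requires rate r")
        if rate_map is not None:
            return _shared_path_matrix(
                tree, _branch_segments_eb(tree, rate) * mult)
        Cbm = _shared_path_matrix(tree, tree.branch_length)
        return covariance_from_bm(Cbm, tree.depths()[tree.tip_indices],
                                  "EB", rate=rate)
    Cbm = _shared_path_matrix(tree, tree.branch_length * mult)
    tip_depths = tree.depths()[tree.tip_indices]
    if model == "lambda":
        return covariance_from_bm(Cbm, tip_depths, "lambda", lam=lam)
    if model in ("OUFIXEDROOT", "OURANDOMROOT"):
        name = "OUfixedRoot" if model == "OUFIXEDROOT" else "OUrandomRoot"
        return covariance_from_bm(Cbm, tip_depths, name, alpha=alpha)
    raise ValueError(f"unknown model {model!r}")


def covariance_from_bm(Cbm: np.ndarray, tip_depths: np.ndarray, model: str,
                       *, rate: float = None, lam: float = None,
                       alpha: float = None) -> np.ndarray:
    """Elementwise model covariance from the BM shared-path matrix.

    Cbm holds root-to-MRCA path lengths, so with time-proportional branch
    lengths every model below is a pointwise transform: the EB per-branch
    integrals telescope to (exp(r * t_mrca) - 1)/r, lambda rescales
    off-diagonals, and the OU kernels need only the MRCA depth and the
    patristic distance, both derivable from Cbm and the tip depths.
    """
    if model == "BM":
        return Cbm
    if model == "EB":
        if rate is None or rate > 0:
            raise ValueError("EB decay rate r must be <= 0")
        if rate == 0:
            return Cbm
        return (np.exp(rate * Cbm) - 1.0) / rate
    if model == "lambda":
        if lam is None or not (0.0 <= lam <= 1.0):
            raise ValueError("lambda model requires lam in [0, 1]")
        d = np.diag(Cbm).copy()
        C = Cbm * lam
        np.fill_diagonal(C, d)
        return C
    if model in ("OUfixedRoot", "OUrandomRoot"):
        if alpha is None or alpha < 0:
            raise ValueError("OU requires alpha >= 0")
        if alpha == 0:
            return Cbm
        ti = tip_depths[:, None]
        tj = tip_depths[None, :]
        tm = np.minimum(Cbm, np.minimum(ti, tj))   # MRCA depth
        dist = ti + tj - 2 * tm                    # patristic distance
        if model == "OUrandomRoot":
            return np.exp(-alpha * dist) / (2 * alpha)
        return (np.exp(-alpha * dist) * (1 - np.exp(-2 * alpha * tm))
                / (2 * alpha))
    raise ValueError(f"unknown model {model!r}")


def paint_clade(tree: Phylogeny, partition: CladePartition,
                multiplier: float, regime_id: int = 2) -> RateMap:
    """Assign the focal clade's branches (plus stem if requested) to a new
    regime with the given rate multiplier; all else is regime 1."""
    partition.validate(tree)
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    regime = np.ones(tree.n_nodes, dtype=int)
    nodes = tree.clade_nodes(partition.focal_node,
                             include_self=partition.include_stem)
    regime[nodes] = regime_id
    return RateMap(regime, {1: 1.0, regime_id: float(multiplier)})


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_trait_csv(path_or_buf) -> pd.DataFrame:
    """Trait table ``species,<trait...>`` indexed by species."""
    df = pd.read_csv(path_or_buf)
    if "species" not in df.columns:
        raise ValueError("trait CSV must have a 'species' column")
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in trait CSV: {dups}")
    df = df.set_index("species")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("trait CSV contains non-finite values")
    return df


def write_trait_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="species")


def read_rate_map_csv(path_or_buf, tree: Phylogeny) -> RateMap:
    """RateMap CSV ``child_node,regime,multiplier`` keyed by node id."""
    df = pd.read_csv(path_or_buf)
    regime = np.ones(tree.n_nodes, dtype=int)
    mult = {1: 1.0}
    for _, row in df.iterrows():
        regime[int(row["child_node"])] = int(row["regime"])
        mult[int(row["regime"])] = float(row["multiplier"])
    return RateMap(regime, mult)


def write_rate_map_csv(rate_map: RateMap, path) -> None:
    rows = [(i, int(r), rate_map.multipliers[int(r)])
            for i, r in enumerate(rate_map.regime)]
    pd.DataFrame(rows, columns=["child_node", "regime", "multiplier"]
                 ).to_csv(path, index=False)


def align_traits_to_tree(tree: Phylogeny, traits: pd.DataFrame
                         ) -> pd.DataFrame:
    """Reorder a trait table to tip order, requiring an exact species match."""
    tips = tree.tip_labels
    missing = set(tips) - set(traits.index)
    extra = set(traits.index) - set(tips)
    if missing or extra:
        raise ValueError(
            f"species mismatch: missing from traits {sorted(missing)[:5]}, "
            f"absent from tree {sorted(extra)[:5]}"
        )
    return traits.loc[tips]
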