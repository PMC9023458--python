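"""Occurrence-based climatic-niche and geographic statistics.

Occurrence tables are plain DataFrames with ``species``, ``lon``, ``lat``
and named climate columns. Thinning keeps one record per species per grid
cell (sampling-bias control); the climate PCA is a correlation-matrix PCA
over all pooled records with species positioned at their mean scores on the
first two axes; presence grids, spherical-cell range areas and sympatric
congener assemblages summarize geography.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "thin_occurrences", "climate_pca", "ClimatePCA",
    "build_presence_grid", "PresenceGrid", "range_area",
    "count_sympatric_assemblages", "read_occurrence_csv",
]

EARTH_RADIUS_KM = 6371.0
KM_PER_DEGREE = 111.0    # equatorial scale used for the thinning grid


def read_occurrence_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"species", "lon", "lat"}
    if not required <= set(df.columns):
        raise ValueError(f"occurrence CSV needs columns {sorted(required)}")
    if ((df["lon"].abs() > 180) | (df["lat"].abs() > 90)).any():
        raise ValueError("coordinates out of bounds")
    return df


def climate_columns(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c not in ("species", "lon", "lat")]


def thin_occurrences(table: pd.DataFrame, cell_km: float = 11.0
                     ) -> pd.DataFrame:
    """Subsample to a single record per species per grid cell.

    The grid is a plain degree grid with cell side ``cell_km`` at the
    equator (no latitude correction, matching an 'approximate resolution').
    The survivor is the first record in (species, lon, lat) sort order, so
    thinning is deterministic and idempotent.
    """
    if len(table) == 0:
        warnings.warn("empty occurrence table", stacklevel=2)
        return table.copy()
    res = cell_km / KM_PER_DEGREE
    t = table.sort_values(["species", "lon", "lat"], kind="stable")
    cx = np.floor(t["lon"] / res).astype(int)
    cy = np.floor(t["lat"] / res).astype(int)
    keep = ~pd.DataFrame({"s": t["species"], "cx": cx, "cy": cy}
                         ).duplicated()
    return t.loc[keep.to_numpy()].reset_index(drop=True)


@dataclass
class ClimatePCA:
    """Correlation-matrix PCA of the pooled climate space."""

    scores: pd.DataFrame          # per record: species + PC columns
    species_means: pd.DataFrame   # CLIM1, CLIM2 (first two axes)
    loadings: pd.DataFrame        # variables x components
    explained_variance: np.ndarray
    dropped: list

    def summary(self) -> str:
        ev = self.explained_variance
        pct = 100 * ev / ev.sum()
        lines = [f"Climate PCA over {len(self.scores)} records, "
                 f"{self.loadings.shape[0]} variables"]
        for i in range(min(2, len(pct))):
            top = self.loadings.iloc[:, i].abs().idxmax()
            lines.append(f"  CLIM{i+1}: {pct[i]:.1f}% of variance, "
                         f"dominated by {top}")
        return "\n".join(lines)


def climate_pca(table: pd.DataFrame, n_components: int = None) -> ClimatePCA:
    """Standardized PCA over all pooled records; species positions are their
    mean scores on the first two axes (CLIM1, CLIM2)."""
    cols = climate_columns(table)
    if len(cols) < 2:
        raise ValueError("need >= 2 climate columns")
    if len(table) < 3:
        raise ValueError("need >= 3 records")
    X = table[cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    dropped = [c for c, s in zip(cols, sd) if s == 0]
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}",
                      stacklevel=2)
        cols = [c for c in cols if c not in dropped]
        X = table[cols].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=1)
    # correlation-matrix PCA: exactly invariant to record duplication and
    # to the ddof convention (eigenvalues sum to the number of variables)
    corr = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    if n_components is not None:
        evals, evecs = evals[:n_components], evecs[:, :n_components]
    # deterministic sign convention
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    S = Z @ evecs
    pc_names = [f"PC{i+1}" for i in range(S.shape[1])]
    scores = pd.DataFrame(S, columns=pc_names)
    scores.insert(0, "species", table["species"].to_numpy())
    means = (scores.groupby("species")[pc_names[:2]].mean()
             .rename(columns={"PC1": "CLIM1", "PC2": "CLIM2"}))
    loadings = pd.DataFrame(evecs, index=cols, columns=pc_names)
    return ClimatePCA(scores, means, loadings, evals, dropped)


@dataclass
class PresenceGrid:
    """Per-cell species sets on a regular lon/lat grid.

    Cells are indexed (floor(lon/res), floor(lat/res)); a record exactly on
    a boundary belongs to the floor cell.
    """

    resolution: float
    cells: dict                  # (ix, iy) -> frozenset of species
    species_cells: dict          # species -> set of (ix, iy)

    @property
    def species(self) -> list:
        return sorted(self.species_cells)


def build_presence_grid(table: pd.DataFrame, resolution: float = 0.1
                        ) -> PresenceGrid:
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    ix = np.floor(table["lon"].to_numpy() / resolution).astype(int)
    iy = np.floor(table["lat"].to_numpy() / resolution).astype(int)
    cells: dict = {}
    species_cells: dict = {}
    for sp, x, y in zip(table["species"], ix, iy):
        cells.setdefault((x, y), set()).add(sp)
        species_cells.setdefault(sp, set()).add((x, y))
    cells = {k: frozenset(v) for k, v in cells.items()}
    return PresenceGrid(resolution, cells, species_cells)


def _cell_area_km2(iy: int, resolution: float) -> float:
    """Spherical area of a lon/lat cell whose south edge is at iy*res."""
    dlat = np.radians(resolution)
    dlon = np.radians(resolution)
    lat_c = np.radians((iy + 0.5) * resolution)
    return (EARTH_RADIUS_KM * dlat) * (EARTH_RADIUS_KM * dlon
                                       * np.cos(lat_c))


def range_area(grid: PresenceGrid, species) -> float:
    """Occupied area in km^2 (spherical cell formula, union over the given
    species or set of species)."""
    if isinstance(species, str):
        species = [species]
    cells = set()
    for sp in species:
        if sp not in grid.species_cells:
            raise KeyError(f"species {sp!r} not in grid")
        cells |= grid.species_cells[sp]
    return float(sum(_cell_area_km2(iy, grid.resolution) for _, iy in cells))


def count_sympatric_assemblages(grid: PresenceGrid, genus_map: dict,
                                pairs: bool = False) -> pd.Series:
    """Number of unique sympatric assemblages of congeners per genus.

    An assemblage is the maximal set (size >= 2) of congeneric species
    co-occurring in a cell; identical sets in different cells count once.
    With ``pairs=True`` unique co-occurring pairs are counted instead.
    """
    genera = sorted(set(genus_map.values()))
    seen: dict = {g: set() for g in genera}
    for cell_species in grid.cells.values():
        by_genus: dict = {}
        for sp in cell_species:
            g = genus_map.get(sp)
            if g is not None:
                by_genus.setdefault(g, set()).add(sp)
        for g, sps in by_genus.items():
            if len(sps) >= 2:
                if pairs:
                    from itertools import combinations
                    seen[g].update(frozenset(p)
                                   for p in combinations(sorted(sps), 2))
                else:
                    seen[g].add(frozenset(sps))
    return pd.Series({g: len(seen[g]) for g in genera}, name="assemblages")
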