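"""Niche assignment from local neighborhood composition.

Each cell is featurized by the cell-type composition of its k nearest
neighbors (k = 20 by default, self excluded, computed within the FOV), and
the composition vectors are clustered with k-means.  The resulting
clusters — "niches" — are recurrent local microenvironments; per-sample
and per-niche composition tables summarize how cell types and niches
distribute across experimental groups.  This is the standard published
k-NN-composition approach to niche detection; labels are stable under a
fixed seed and niche ids are ordered by descending cluster size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io_model import CellTable, ConfigurationError

logger = logging.getLogger("spatialcoloc")

DEFAULT_K_NEIGHBORS = 20


@dataclass
class NicheModel:
    """Per-cell niche labels plus niche composition profiles."""

    k_neighbors: int
    n_niches: int
    niche_profiles: pd.DataFrame  # niche x cell-type mean composition
    labels: np.ndarray            # per-cell niche id ("N1" = largest)
    inertia: float
    seed: int


def neighborhood_composition(
    cells: CellTable,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    scope: str = "per_fov",
) -> pd.DataFrame:
    """Per-cell fraction of each cell type among the k nearest neighbors.

    Distances are Euclidean between centroids within the scope unit; the
    cell itself is excluded; ties at the k-th distance are broken by stable
    cell order.  In FOVs with at most ``k_neighbors`` cells, k is capped at
    n − 1 (logged); a single-cell FOV yields a flagged all-zero vector.
    Returns a DataFrame (cells × types) whose non-degenerate rows sum to 1,
    with a boolean ``attrs["flagged"]`` mask for zero-neighbor cells.
    """
    if k_neighbors < 1:
        raise ConfigurationError("k_neighbors must be >= 1")
    if scope != "per_fov":
        raise ConfigurationError("neighborhood_composition supports per_fov scope only")
    df = cells.df
    types = list(cells.cell_types)
    tcodes = pd.Categorical(df["cell_type"], categories=types).codes
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    comp = np.zeros((len(df), len(types)), dtype=float)
    flagged = np.zeros(len(df), dtype=bool)

    for fov, idx in df.groupby("fov_id", sort=False).indices.items():
        idx = np.asarray(idx)
        n = idx.size
        if n == 1:
            flagged[idx] = True
            logger.warning("FOV %s has a single cell; zero composition vector", fov)
            continue
        k = min(k_neighbors, n - 1)
        if k < k_neighbors:
            logger.info("FOV %s has %d cells; k capped at %d", fov, n, k)
        pts = xy[idx]
        # exact all-pairs with stable tie-break (argsort is stable on ties)
        for chunk in np.array_split(np.arange(n), max(1, n // 512)):
            d = np.sqrt(((pts[chunk, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
            d[np.arange(chunk.size), chunk] = np.inf  # exclude self
            order = np.argsort(d, axis=1, kind="stable")[:, :k]
            nb_codes = tcodes[idx[order]]
            for t in range(len(types)):
                comp[idx[chunk], t] = (nb_codes == t).sum(axis=1) / k
    out = pd.DataFrame(comp, columns=types, index=df.index)
    out.attrs["flagged"] = flagged
    return out


def assign_niches(
    compositions: pd.DataFrame,
    n_niches: int,
    seed: int = 0,
    n_init: int = 10,
) -> NicheModel:
    """k-means clustering of composition vectors into niches.

    Niche ids are relabeled by descending cluster size ("N1" largest) so
    assignments are stable up to that convention under row permutations of
    the input.
    """
    if n_niches < 2:
        raise ConfigurationError("n_niches must be >= 2")
    X = compositions.to_numpy(dtype=float)
    if n_niches >= len(X):
        raise ConfigurationError(
            f"n_niches ({n_niches}) must be smaller than the number of cells ({len(X)})"
        )
    km = KMeans(n_clusters=n_niches, random_state=int(seed), n_init=n_init)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=n_niches)
    order = np.argsort(-sizes, kind="stable")  # ties by original cluster index
    rank = np.empty(n_niches, dtype=int)
    rank[order] = np.arange(n_niches)
    labels = np.array([f"N{rank[c] + 1}" for c in raw], dtype=object)
    profiles = pd.DataFrame(
        [X[raw == c].mean(axis=0) for c in order],
        index=[f"N{i + 1}" for i in range(n_niches)],
        columns=compositions.columns,
    )
    return NicheModel(
        k_neighbors=-1,
        n_niches=n_niches,
        niche_profiles=profiles,
        labels=labels,
        inertia=float(km.inertia_),
        seed=int(seed),
    )


def composition_table(
    cells: CellTable,
    group_by: str = "sample_id",
    of: str = "cell_type",
    region_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-group fractions of ``of`` (cell types or niches) plus n_cells.

    ``region_mask`` restricts to a subset (e.g. nodule-interior cells)
    before tabulation; groups emptied by the mask are omitted with a
    warning.  Fraction columns sum to 1 per group.
    """
    df = cells.df
    if group_by not in df.columns or of not in df.columns:
        missing = [c for c in (group_by, of) if c not in df.columns]
        raise ConfigurationError(f"cell table lacks column(s): {missing}")
    if region_mask is not None:
        before = set(df[group_by].unique())
        df = df.loc[np.asarray(region_mask, dtype=bool)]
        dropped = sorted(before - set(df[group_by].unique()))
        if dropped:
            logger.warning("groups emptied by region mask: %s", dropped)
    counts = pd.crosstab(df[group_by], df[of])
    fractions = counts.div(counts.sum(axis=1), axis=0)
    fractions["n_cells"] = counts.sum(axis=1)
    return fractions
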