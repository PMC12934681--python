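"""Permutation-null cell-type co-localization testing.

For an ordered cell-type pair (A, B) the observed statistic is the number
of type-B cells adjacent to type-A "index" cells in the radius contact
graph (ordered convention: a same-type edge counts twice).  The null
distribution is built by shuffling cell-type labels among the *non-index*
cells — either across the whole sample or within FOV strata, which
preserves each FOV's density and label multiset — while the index cells
keep their positions and labels.  From the null we report the expected
count, its standard deviation (n−1 estimator), a z-score, a two-sided
p-value (normal tail of z by default, or an empirical permutation
p-value), Benjamini–Hochberg q-values over all tested pairs, and
log(observed/expected) enrichment.

Because every cell of the index type is held fixed, homotypic (A, A) tests
have a constant null (sd = 0): they are reported with p = 1 and a
``degenerate`` flag rather than an infinite z.  Per-FOV enrichment maps
repeat the test inside each FOV with FOV-internal shuffles, yielding the
"hotspot" log-enrichment score log((obs + c) / (exp + c)) with pseudocount
c = 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .graph import NeighborGraph, pair_neighbor_count
from .io_model import ConfigurationError, VocabularyError

logger = logging.getLogger("spatialcoloc")

DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_PSEUDOCOUNT = 0.5

_FDR_METHODS = {
    "benjamini-hochberg": "fdr_bh",
    "bh": "fdr_bh",
    "fdr_bh": "fdr_bh",
    "benjamini-yekutieli": "fdr_by",
    "bonferroni": "bonferroni",
    "holm": "holm",
}


@dataclass
class PermutationConfig:
    """Settings for the permutation null."""

    n_permutations: int = DEFAULT_N_PERMUTATIONS
    stratify_by_fov: bool = True
    seed: int = 0
    p_mode: str = "normal_from_z"  # normal_from_z | empirical
    fdr_method: str = "benjamini-hochberg"

    def __post_init__(self):
        if self.n_permutations < 100:
            raise ConfigurationError("n_permutations must be at least 100")
        if self.p_mode not in ("normal_from_z", "empirical"):
            raise ConfigurationError(f"unknown p_mode {self.p_mode!r}")
        if self.fdr_method.lower() not in _FDR_METHODS:
            raise ConfigurationError(f"unknown fdr_method {self.fdr_method!r}")


@dataclass
class PairColocResult:
    """One tested ordered (index, neighbor) cell-type pair."""

    index_type: str
    neighbor_type: str
    observed: int
    expected_mean: float
    null_sd: float
    z: float
    p_two_sided: float
    q: float | None
    log_enrichment: float
    n_index_cells: int
    n_neighbor_cells: int
    degenerate: bool


# ---------------------------------------------------------------------------
# label permutation
# ---------------------------------------------------------------------------

def permute_labels(
    labels: np.ndarray,
    index_type: str,
    stratify: bool,
    strata: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """One label shuffle among non-index cells.

    Index-type cells keep label and position.  With ``stratify`` the
    non-index labels are permuted within each stratum (its label multiset
    is preserved exactly); strata with fewer than two non-index cells are
    left unchanged.
    """
    labels = np.asarray(labels, dtype=object)
    out = labels.copy()
    non_index = np.flatnonzero(labels != index_type)
    if non_index.size < 2:
        return out
    if stratify:
        if strata is None:
            raise ConfigurationError("stratified shuffle requires per-cell strata")
        strata = np.asarray(strata)
        for s in np.unique(strata[non_index]):
            idx = non_index[strata[non_index] == s]
            if idx.size < 2:
                logger.debug("stratum %r has < 2 non-index cells; left unchanged", s)
                continue
            out[idx] = out[idx][rng.permutation(idx.size)]
    else:
        out[non_index] = out[non_index][rng.permutation(non_index.size)]
    return out


# ---------------------------------------------------------------------------
# null engine
# ---------------------------------------------------------------------------

def _codes(labels, types):
    cat = pd.Categorical(np.asarray(labels, dtype=object), categories=list(types))
    if (cat.codes < 0).any():
        unknown = sorted(set(np.asarray(labels)[cat.codes < 0]))
        raise VocabularyError(f"labels outside vocabulary: {unknown}")
    return cat.codes.astype(np.int64)


def _index_multiplicity(graph: NeighborGraph, index_mask: np.ndarray) -> np.ndarray:
    """Per-cell number of ordered contacts received from index cells."""
    m = np.zeros(graph.n_cells, dtype=np.int64)
    on_i = index_mask[graph.edge_i]
    on_j = index_mask[graph.edge_j]
    np.add.at(m, graph.edge_j[on_i], 1)
    np.add.at(m, graph.edge_i[on_j], 1)
    return m


def _null_counts_for_index(
    graph: NeighborGraph,
    codes: np.ndarray,
    index_code: int,
    n_types: int,
    cfg: PermutationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed counts and the permutation-null count matrix for one index type.

    Returns ``(observed, null)`` with shapes (n_types,) and
    (n_permutations, n_types).  Column ``index_code`` holds the constant
    index–index contribution (homotypic null is degenerate by design).
    """
    index_mask = codes == index_code
    m = _index_multiplicity(graph, index_mask)
    const_same = int(m[index_mask].sum())  # 2 x index-index edges (ordered)

    non_index = np.flatnonzero(~index_mask)
    nm = m[non_index].astype(float)
    ncodes = codes[non_index]

    observed = np.bincount(ncodes, weights=nm, minlength=n_types)
    observed[index_code] += const_same

    P = cfg.n_permutations
    null = np.zeros((P, n_types), dtype=float)
    if cfg.stratify_by_fov:
        strata = graph.group_codes[non_index]
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    else:
        groups = [np.arange(non_index.size)]
    for idx in groups:
        if idx.size < 2:
            if idx.size == 1:
                null[:, ncodes[idx[0]]] += nm[idx[0]]
            continue
        # batched uniform permutations: argsort of iid uniforms per row
        keys = rng.random((P, idx.size))
        order = np.argsort(keys, axis=1)
        perm_codes = ncodes[idx][order]  # (P, n_s)
        w = nm[idx]
        for t in range(n_types):
            null[:, t] += ((perm_codes == t) * w).sum(axis=1)
    null[:, index_code] += const_same
    return observed.astype(np.int64), null


def _p_values(observed, null, z, mode):
    if mode == "normal_from_z":
        return 2.0 * norm.sf(np.abs(z))
    P = null.shape[0]
    hi = (1 + (null >= observed[None, :]).sum(axis=0)) / (P + 1)
    lo = (1 + (null <= observed[None, :]).sum(axis=0)) / (P + 1)
    return np.minimum(1.0, 2.0 * np.minimum(hi, lo))


def _results_for_index(graph, codes, types, index_code, cfg, rng):
    n_types = len(types)
    observed, null = _null_counts_for_index(graph, codes, index_code, n_types, cfg, rng)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - mean) / sd
        log_enr = np.log(observed / mean)
    z = np.where(degenerate, np.nan, z)
    p = np.where(degenerate, 1.0, _p_values(observed, null, z, cfg.p_mode))
    n_index = int((codes == index_code).sum())
    type_counts = np.bincount(codes, minlength=n_types)
    rows = []
    for b in range(n_types):
        rows.append({
            "index_type": types[index_code],
            "neighbor_type": types[b],
            "observed": int(observed[b]),
            "expected_mean": float(mean[b]),
            "null_sd": float(sd[b]),
            "z": float(z[b]),
            "p_two_sided": float(p[b]),
            "log_enrichment": float(log_enr[b]),
            "n_index_cells": n_index,
            "n_neighbor_cells": int(type_counts[b]),
            "degenerate": bool(degenerate[b]),
        })
    return rows


def _rng_for_index(cfg: PermutationConfig, index_code: int) -> np.random.Generator:
    # per-index-type stream so coloc_test(A, B) matches the (A, B) row of
    # coloc_all_pairs under the same seed
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, index_code)))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def coloc_test(
    graph: NeighborGraph,
    labels: np.ndarray,
    index_type: str,
    neighbor_type: str,
    cfg: PermutationConfig | None = None,
    vocabulary=None,
) -> PairColocResult:
    """Permutation co-localization test for one ordered (A, B) pair."""
    cfg = cfg or PermutationConfig()
    labels = np.asarray(labels, dtype=object)
    types = list(vocabulary) if vocabulary is not None else sorted(set(labels.tolist()))
    for t in (index_type, neighbor_type):
        if t not in types:
            raise VocabularyError(f"unknown cell type {t!r}")
    if index_type not in set(labels.tolist()):
        raise ConfigurationError(f"index type {index_type!r} has no cells")
    codes = _codes(labels, types)
    a = types.index(index_type)
    rows = _results_for_index(graph, codes, types, a, cfg, _rng_for_index(cfg, a))
    row = rows[types.index(neighbor_type)]
    return PairColocResult(q=None, **row)


def coloc_all_pairs(
    graph: NeighborGraph,
    labels: np.ndarray,
    cfg: PermutationConfig | None = None,
    vocabulary=None,
) -> pd.DataFrame:
    """Test every ordered cell-type pair; FDR-correct across all p-values.

    Returns one row per ordered (A, B) pair — including homotypic pairs,
    which are degenerate-flagged — sorted by q then |z|.
    """
    cfg = cfg or PermutationConfig()
    labels = np.asarray(labels, dtype=object)
    present = sorted(set(labels.tolist()))
    types = list(vocabulary) if vocabulary is not None else present
    if len(present) < 2:
        raise ConfigurationError("co-localization testing needs at least two cell types")
    codes = _codes(labels, types)
    rows = []
    for a, t in enumerate(types):
        if t not in present:
            continue
        rows.extend(_results_for_index(graph, codes, types, a, cfg, _rng_for_index(cfg, a)))
    out = pd.DataFrame(rows)
    method = _FDR_METHODS[cfg.fdr_method.lower()]
    out["q"] = multipletests(out["p_two_sided"].to_numpy(), method=method)[1]
    out = out.sort_values(
        ["q", "z"], key=lambda s: s if s.name == "q" else -s.abs().fillna(-np.inf)
    ).reset_index(drop=True)
    cols = ["index_type", "neighbor_type", "observed", "expected_mean", "null_sd",
            "z", "p_two_sided", "q", "log_enrichment", "n_index_cells",
            "n_neighbor_cells", "degenerate"]
    return out[cols]


def fov_enrichment(
    graph: NeighborGraph,
    labels: np.ndarray,
    pair: tuple[str, str],
    cfg: PermutationConfig | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-FOV enrichment map for one pair: observed, expected, log score.

    ``log_enrichment = log((observed + c) / (expected_mean + c))`` with
    pseudocount ``c`` keeping the score finite at zero counts.  FOVs with
    no index cells or no candidate neighbor cells get a flagged null row
    (NaN expectation).  Requires a per-FOV graph.
    """
    cfg = cfg or PermutationConfig()
    if graph.scope != "per_fov":
        raise ConfigurationError("fov_enrichment requires a per_fov graph")
    index_type, neighbor_type = pair
    labels = np.asarray(labels, dtype=object)
    types = sorted(set(labels.tolist()) | {index_type, neighbor_type})
    codes = _codes(labels, types)
    a, b = types.index(index_type), types.index(neighbor_type)

    rows = []
    for g, fov in enumerate(graph.group_ids):
        idx = np.flatnonzero(graph.group_codes == g)
        pos = np.full(graph.n_cells, -1, dtype=np.int64)
        pos[idx] = np.arange(idx.size)
        on = (graph.group_codes[graph.edge_i] == g)
        sub = NeighborGraph(
            radius_um=graph.radius_um,
            scope="per_fov",
            n_cells=idx.size,
            edge_i=pos[graph.edge_i[on]],
            edge_j=pos[graph.edge_j[on]],
            distance_um=graph.distance_um[on],
            group_codes=np.zeros(idx.size, dtype=np.int64),
            group_ids=np.array([fov]),
            cell_ids=graph.cell_ids[idx],
        )
        sub_codes = codes[idx]
        n_index = int((sub_codes == a).sum())
        n_nb = int((sub_codes == b).sum())
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, a, g)))
        if n_index == 0 or n_nb == 0 or (a == b and n_index < 2):
            observed = 0 if n_index == 0 or n_nb == 0 else None
            if observed is None:
                observed = int(pair_neighbor_count(sub, np.asarray(types, dtype=object)[sub_codes],
                                                   index_type, neighbor_type, vocabulary=types))
            rows.append({"fov_id": str(fov), "observed": observed,
                         "expected_mean": np.nan, "log_enrichment": np.nan,
                         "n_index_cells": n_index, "n_neighbor_cells": n_nb,
                         "flagged": True})
            continue
        obs_vec, null = _null_counts_for_index(sub, sub_codes, a, len(types), cfg, rng)
        obs, exp = float(obs_vec[b]), float(null[:, b].mean())
        rows.append({
            "fov_id": str(fov),
            "observed": int(obs),
            "expected_mean": exp,
            "log_enrichment": float(np.log((obs + pseudocount) / (exp + pseudocount))),
            "n_index_cells": n_index,
            "n_neighbor_cells": n_nb,
            "flagged": False,
        })
    out = pd.DataFrame(rows)
    out.attrs["pair"] = (index_type, neighbor_type)
    out.attrs["pseudocount"] = pseudocount
    return out
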