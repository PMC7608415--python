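"""Spatial statistics on the embedded coordinates.

Per-cell density (neighbors within a radius), density-peaks clustering of
spatially compact structures, connection counting between annotated cell
clusters, and a label-permutation test classifying each cluster pair as
enriched, depleted or other.

The working radius throughout is the median distance of each cell to its
3rd nearest neighbor — a scale at which "neighbor" means physical contact
in the crowded pseudo-space.  Two cells are connected when their distance
is strictly below that cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DISSOCIATIVE = "dissociative"

P_THRESHOLD = 0.05
Q_THRESHOLD = 0.05


@dataclass
class DensityResult:
    """Per-cell density and density-peaks structure assignment.

    ``density`` counts other cells within ``radius``; ``delta`` is the
    distance to the nearest cell of higher density (the global density peak
    gets the maximum pairwise distance); ``structure_labels`` holds a
    compact-structure id ("S1", "S2", ...) or ``"dissociative"`` for
    zero-density cells.
    """

    cell_ids: list[str]
    radius: float
    density: np.ndarray
    delta: np.ndarray
    structure_labels: list[str]

    @property
    def n_structures(self) -> int:
        return len({s for s in self.structure_labels if s != DISSOCIATIVE})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "density": self.density,
                "delta": self.delta,
                "structure_label": self.structure_labels,
            }
        )


@dataclass
class InteractionReport:
    """Connection counts and permutation significance per cluster pair.

    ``table`` has one row per unordered cluster pair (self-pairs included)
    with columns cluster_a, cluster_b, count, p_enrich, q_enrich, p_deplete,
    q_deplete, call.  A pair is *enriched* when both its right-tail p and BH
    q fall below 0.05, *depleted* analogously on the left tail, *other*
    otherwise.
    """

    cluster_names: list[str]
    table: pd.DataFrame
    n_perm: int
    seed: int | None
    radius: float

    def call_for(self, a: str, b: str) -> str:
        a, b = sorted((a, b))
        row = self.table[(self.table.cluster_a == a) & (self.table.cluster_b == b)]
        if row.empty:
            raise KeyError(f"no cluster pair ({a}, {b})")
        return row.call.iloc[0]

    def count_for(self, a: str, b: str) -> int:
        a, b = sorted((a, b))
        row = self.table[(self.table.cluster_a == a) & (self.table.cluster_b == b)]
        if row.empty:
            raise KeyError(f"no cluster pair ({a}, {b})")
        return int(row["count"].iloc[0])

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# density and radius


def neighborhood_radius(coords: np.ndarray, nth: int = 3) -> float:
    """Median distance of each cell to its nth nearest other cell."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= nth:
        raise ValueError(f"need more than nth={nth} cells, got {n}")
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    kth = np.partition(d, nth - 1, axis=1)[:, nth - 1]
    return float(np.median(kth))


def density(coords: np.ndarray, radius: float) -> np.ndarray:
    """Number of other cells within ``radius`` (inclusive) of each cell."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    d = squareform(pdist(np.asarray(coords, dtype=float)))
    within = d <= radius
    np.fill_diagonal(within, False)
    return within.sum(axis=1)


def distance_to_center(coords: np.ndarray) -> np.ndarray:
    """Euclidean distance of each cell to the centroid of all cells."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return np.linalg.norm(coords - coords.mean(axis=0), axis=1)


# ---------------------------------------------------------------------------
# density-peaks clustering


def find_compact_structures(
    coords: np.ndarray,
    radius: float,
    cell_ids: list[str] | None = None,
    center_sd_factor: float = 3.0,
) -> DensityResult:
    """Density-peaks clustering of spatially compact structures.

    Structure centers are cells that are both dense and far from any denser
    cell: with gamma = rho * delta, cells exceeding mean(gamma) +
    ``center_sd_factor`` * sd(gamma) become centers (at least one center is
    always chosen when any cell has positive density).  Every remaining cell
    joins the structure of its nearest higher-density neighbor; zero-density
    cells are labelled dissociative.  Ties in density are ordered by cell
    index, which makes fully degenerate (all-coincident) input collapse to a
    single structure.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells")
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n)]
    d = squareform(pdist(coords))
    rho = density(coords, radius)

    # rank order: density descending, index ascending — defines "higher"
    order = np.lexsort((np.arange(n), -rho))
    delta = np.zeros(n)
    nearest_higher = np.full(n, -1)
    max_dist = float(d.max())
    delta[order[0]] = max_dist
    for pos in range(1, n):
        i = order[pos]
        higher = order[:pos]
        j = higher[np.argmin(d[i, higher])]
        delta[i] = d[i, j]
        nearest_higher[i] = j

    gamma = rho * delta
    threshold = gamma.mean() + center_sd_factor * gamma.std()
    centers = np.flatnonzero((gamma > threshold) & (rho > 0))
    if centers.size == 0 and (rho > 0).any():
        candidates = np.flatnonzero(rho > 0)
        centers = np.array([candidates[np.argmax(gamma[candidates])]])

    assign = np.full(n, -1)
    for rank, c in enumerate(centers):
        assign[c] = rank
    for pos in range(n):
        i = order[pos]
        if rho[i] == 0:
            continue
        if assign[i] < 0:
            parent = nearest_higher[i]
            assign[i] = assign[parent] if parent >= 0 else 0
    labels = [DISSOCIATIVE if a < 0 else f"S{a + 1}" for a in assign]
    return DensityResult(
        cell_ids=list(cell_ids), radius=radius, density=rho, delta=delta,
        structure_labels=labels,
    )


# ---------------------------------------------------------------------------
# cluster-cluster connections and permutation significance


def _as_label_array(annotations, cell_ids: list[str] | None) -> np.ndarray:
    if isinstance(annotations, dict):
        if cell_ids is None:
            raise ValueError("cell_ids required when annotations is a mapping")
        missing = [c for c in cell_ids if c not in annotations]
        if missing:
            raise ValueError(f"unannotated cells: {missing[:5]}")
        return np.array([annotations[c] for c in cell_ids], dtype=object)
    return np.asarray(annotations, dtype=object)


def _pair_counts(
    edge_a: np.ndarray, edge_b: np.ndarray, codes: np.ndarray, n_clusters: int
) -> np.ndarray:
    """Counts per unordered cluster-pair index for edges (edge_a, edge_b)."""
    ca, cb = codes[edge_a], codes[edge_b]
    lo, hi = np.minimum(ca, cb), np.maximum(ca, cb)
    flat = lo * n_clusters + hi
    return np.bincount(flat, minlength=n_clusters * n_clusters)


def count_connections(
    coords: np.ndarray,
    annotations,
    radius: float,
    cell_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Connections (distance strictly < radius) per unordered cluster pair.

    Self-pairs are included; each cell pair is counted once.  Distances
    exactly at the cutoff are excluded.
    """
    labels = _as_label_array(annotations, cell_ids)
    coords = np.asarray(coords, dtype=float)
    if labels.shape[0] != coords.shape[0]:
        raise ValueError("annotations do not cover every embedded cell")
    clusters = sorted(set(labels.tolist()))
    name_to_code = {c: i for i, c in enumerate(clusters)}
    codes = np.array([name_to_code[l] for l in labels])

    d = squareform(pdist(coords))
    iu, ju = np.triu_indices(len(labels), k=1)
    close = d[iu, ju] < radius
    counts = _pair_counts(iu[close], ju[close], codes, len(clusters))

    rows = [
        {"cluster_a": a, "cluster_b": b,
         "count": int(counts[name_to_code[a] * len(clusters) + name_to_code[b]])}
        for a, b in combinations_with_replacement(clusters, 2)
    ]
    return pd.DataFrame(rows)


def permutation_test(
    coords: np.ndarray,
    annotations,
    radius: float,
    n_perm: int = 1000,
    seed: int | None = 0,
    cell_ids: list[str] | None = None,
) -> InteractionReport:
    """Label-permutation significance of cluster-cluster connection counts.

    Coordinates stay fixed; cluster labels are globally shuffled across all
    cells ``n_perm`` times, giving the null distribution of connection
    counts for every cluster pair.  Tail probabilities use add-one
    smoothing, p = (1 + #{null >= observed}) / (n_perm + 1) for enrichment
    (<= for depletion), and Benjamini-Hochberg correction is applied within
    each tail across all pairs.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    labels = _as_label_array(annotations, cell_ids)
    coords = np.asarray(coords, dtype=float)
    if labels.shape[0] != coords.shape[0]:
        raise ValueError("annotations do not cover every embedded cell")
    clusters = sorted(set(labels.tolist()))
    name_to_code = {c: i for i, c in enumerate(clusters)}
    codes = np.array([name_to_code[l] for l in labels])
    nc = len(clusters)

    d = squareform(pdist(coords))
    iu, ju = np.triu_indices(len(labels), k=1)
    close = d[iu, ju] < radius
    ea, eb = iu[close], ju[close]

    observed = _pair_counts(ea, eb, codes, nc)
    rng = np.random.default_rng(seed)
    ge = np.zeros(nc * nc, dtype=int)
    le = np.zeros(nc * nc, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        counts = _pair_counts(ea, eb, perm, nc)
        ge += counts >= observed
        le += counts <= observed

    rows = []
    for a, b in combinations_with_replacement(clusters, 2):
        idx = name_to_code[a] * nc + name_to_code[b]
        rows.append(
            {
                "cluster_a": a,
                "cluster_b": b,
                "count": int(observed[idx]),
                "p_enrich": (1 + ge[idx]) / (n_perm + 1),
                "p_deplete": (1 + le[idx]) / (n_perm + 1),
            }
        )
    table = pd.DataFrame(rows)
    table["q_enrich"] = multipletests(table.p_enrich, method="fdr_bh")[1]
    table["q_deplete"] = multipletests(table.p_deplete, method="fdr_bh")[1]
    enriched = (table.p_enrich < P_THRESHOLD) & (table.q_enrich < Q_THRESHOLD)
    depleted = (table.p_deplete < P_THRESHOLD) & (table.q_deplete < Q_THRESHOLD)
    table["call"] = np.where(enriched, "enriched", np.where(depleted, "depleted", "other"))
    table = table[
        ["cluster_a", "cluster_b", "count", "p_enrich", "q_enrich",
         "p_deplete", "q_deplete", "call"]
    ]
    return InteractionReport(
        cluster_names=clusters, table=table, n_perm=n_perm, seed=seed, radius=radius
    )
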