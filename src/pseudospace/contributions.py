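"""Decomposing cell-cell affinity into per-ligand-receptor contributions.

For a cell pair (i, j) the contribution of LR pair k is its share of the
affinity sum::

    c_k = w_k (e_i^Lk e_j^Rk + e_i^Rk e_j^Lk) / sum_k' w_k' (...)

so the fractions sum to one.  For a cluster pair the contributions are
averaged (unweighted) over all connected cell pairs — those within the
distance cutoff T — identifying which molecular interactions drive the
observed colocalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .affinity import _gene_rows
from .io import ExpressionMatrix, LigandReceptorTable

logger = logging.getLogger(__name__)


@dataclass
class ContributionTable:
    """Fractional LR-pair contributions for one cluster pair.

    ``table`` columns: ligand, receptor, contribution, rank (1 = dominant).
    ``n_pairs`` is the number of connected cell pairs averaged over
    (zero-affinity pairs are skipped and excluded from the mean);
    ``cutoff`` is the distance threshold T used.
    """

    cluster_a: str
    cluster_b: str
    cutoff: float
    n_pairs: int
    n_skipped: int
    table: pd.DataFrame

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(n, "rank")

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _pair_terms(
    expr: ExpressionMatrix, lr: LigandReceptorTable, cells_i: np.ndarray, cells_j: np.ndarray
) -> np.ndarray:
    """(K, n_pairs) matrix of per-LR-pair affinity terms for given cell pairs."""
    L = _gene_rows(expr, lr.ligands)
    R = _gene_rows(expr, lr.receptors)
    w = lr.weights[:, None]
    return w * (L[:, cells_i] * R[:, cells_j] + R[:, cells_i] * L[:, cells_j])


def pair_contribution(
    expr: ExpressionMatrix, lr: LigandReceptorTable, cell_i: str, cell_j: str
) -> np.ndarray:
    """Fraction of the (i, j) affinity carried by each LR pair; sums to 1."""
    pos = {c: idx for idx, c in enumerate(expr.cell_ids)}
    terms = _pair_terms(
        expr, lr, np.array([pos[cell_i]]), np.array([pos[cell_j]])
    )[:, 0]
    total = terms.sum()
    if total <= 0:
        raise ValueError(f"cells ({cell_i}, {cell_j}) have zero total affinity")
    return terms / total


def cluster_contribution(
    expr: ExpressionMatrix,
    lr: LigandReceptorTable,
    coords: np.ndarray,
    annotations,
    cluster_a: str,
    cluster_b: str,
    cutoff: float,
) -> ContributionTable:
    """Mean per-LR-pair contribution over connected (d <= cutoff) cell pairs.

    The cutoff is inclusive here (pairs at exactly the threshold qualify).
    For a self-pair (cluster_a == cluster_b) cell pairs are unordered i < j.
    Cell pairs with zero total affinity inside the neighborhood are skipped
    (their decomposition is undefined) and logged.
    """
    labels = expr.labels() if annotations is None else np.asarray(
        [annotations[c] for c in expr.cell_ids] if isinstance(annotations, dict) else annotations,
        dtype=object,
    )
    coords = np.asarray(coords, dtype=float)
    d = squareform(pdist(coords))
    ia = np.flatnonzero(labels == cluster_a)
    ib = np.flatnonzero(labels == cluster_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError(f"empty cluster among ({cluster_a!r}, {cluster_b!r})")

    if cluster_a == cluster_b:
        pi, pj = np.triu_indices(ia.size, k=1)
        cells_i, cells_j = ia[pi], ia[pj]
    else:
        cells_i, cells_j = np.meshgrid(ia, ib, indexing="ij")
        cells_i, cells_j = cells_i.ravel(), cells_j.ravel()
    within = d[cells_i, cells_j] <= cutoff
    cells_i, cells_j = cells_i[within], cells_j[within]
    if cells_i.size == 0:
        raise ValueError(
            f"no ({cluster_a}, {cluster_b}) cell pair within cutoff {cutoff}; "
            "consider a larger cutoff"
        )

    terms = _pair_terms(expr, lr, cells_i, cells_j)
    totals = terms.sum(axis=0)
    positive = totals > 0
    n_skipped = int((~positive).sum())
    if n_skipped:
        logger.info("skipped %d zero-affinity cell pairs in (%s, %s)",
                    n_skipped, cluster_a, cluster_b)
    if not positive.any():
        raise ValueError(
            f"every ({cluster_a}, {cluster_b}) pair within cutoff {cutoff} has "
            "zero affinity; consider a larger cutoff"
        )
    fractions = (terms[:, positive] / totals[positive]).mean(axis=1)

    table = pd.DataFrame(
        {"ligand": lr.ligands, "receptor": lr.receptors, "contribution": fractions}
    )
    table["rank"] = table.contribution.rank(ascending=False, method="first").astype(int)
    return ContributionTable(
        cluster_a=cluster_a,
        cluster_b=cluster_b,
        cutoff=cutoff,
        n_pairs=int(positive.sum()),
        n_skipped=n_skipped,
        table=table.sort_values("rank").reset_index(drop=True),
    )
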