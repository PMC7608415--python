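"""Ligand-receptor derived cell-cell affinity.

The affinity of two cells is modelled as the summed concentration of every
ligand-receptor complex their surfaces could form, approximating protein
concentration by mRNA abundance (TPM).  For cells *i*, *j* and LR pairs
indexed by *k* with weight ``w_k``::

    A_ij = sum_k w_k * (e_i^Lk * e_j^Rk + e_i^Rk * e_j^Lk)    (i != j)

The symmetric second term covers ligand and receptor being expressed by
both cells.  The matrix is then discretised by keeping, for each cell, its
top-k highest-affinity neighbors (union-symmetrised), and globally
normalised into a joint neighbor probability P with sum(P) = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, LigandReceptorTable, lr_coverage

logger = logging.getLogger(__name__)


@dataclass
class AffinityModel:
    """Symmetric cell-by-cell affinity and its normalised probability form.

    ``affinity`` is the raw summed ligand-receptor product matrix with zero
    diagonal; ``p`` (filled by :func:`normalize_p`) is ``affinity / z`` with
    ``z`` the sum over all ordered pairs, so that ``p`` sums to one.  After
    :func:`sparsify_topk` each row holds at most ``2k`` nonzeros.
    """

    cell_ids: list[str]
    affinity: np.ndarray
    p: np.ndarray | None = None
    k: int | None = None
    z: float | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def _gene_rows(expr: ExpressionMatrix, genes: list[str]) -> np.ndarray:
    """Expression rows for ``genes``; absent genes contribute a zero row."""
    index = expr.gene_index()
    out = np.zeros((len(genes), expr.n_cells))
    for row, gene in enumerate(genes):
        pos = index.get(gene)
        if pos is not None:
            out[row] = expr.values[pos]
    return out


def compute_affinity(expr: ExpressionMatrix, lr: LigandReceptorTable) -> AffinityModel:
    """Raw affinity matrix from TPM expression and a ligand-receptor table.

    Evaluated as ``L.T @ diag(w) @ R`` plus its transpose, where ``L`` and
    ``R`` hold ligand and receptor expression (pairs x cells); equivalent to
    the per-entry sum over pairs.  LR genes absent from the matrix are
    treated as zero expression; if no LR gene is present at all the affinity
    would be identically zero, which is an error.
    """
    if len(lr) == 0:
        raise ValueError("empty ligand-receptor table")
    if lr_coverage(expr, lr) == 0.0:
        raise ValueError("no ligand-receptor gene present in the expression matrix")
    L = _gene_rows(expr, lr.ligands)
    R = _gene_rows(expr, lr.receptors)
    WR = lr.weights[:, None] * R
    M = L.T @ WR
    A = M + M.T
    np.fill_diagonal(A, 0.0)
    return AffinityModel(cell_ids=list(expr.cell_ids), affinity=A)


def sparsify_topk(model: AffinityModel, k: int = 50) -> AffinityModel:
    """Keep, per cell, its k largest affinities; union-symmetrise.

    An entry (i, j) survives if j is among i's k largest affinities or i is
    among j's (so the result stays symmetric).  Ties at the k-th largest are
    broken toward the lower cell index for deterministic runs.  ``k >= n-1``
    is a no-op.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    A = model.affinity
    n = A.shape[0]
    if k >= n - 1:
        return replace(model, k=k)
    # stable argsort of -A breaks ties toward the lower column index
    order = np.argsort(-A, axis=1, kind="stable")[:, :k]
    keep = np.zeros_like(A, dtype=bool)
    np.put_along_axis(keep, order, True, axis=1)
    keep |= keep.T
    out = np.where(keep, A, 0.0)
    np.fill_diagonal(out, 0.0)
    return replace(model, affinity=out, k=k, p=None, z=None)


def normalize_p(model: AffinityModel) -> AffinityModel:
    """Fill the joint probability form P = A / Z, Z = sum over ordered pairs."""
    z = float(model.affinity.sum())
    if z <= 0:
        raise ValueError("all-zero affinity matrix cannot be normalised")
    return replace(model, p=model.affinity / z, z=z)


def affinity_pipeline(
    expr: ExpressionMatrix, lr: LigandReceptorTable, k: int = 50
) -> AffinityModel:
    """compute_affinity -> sparsify_topk -> normalize_p in one call."""
    return normalize_p(sparsify_topk(compute_affinity(expr, lr), k=k))


def write_affinity(model: AffinityModel, path: str | Path) -> None:
    """Write nonzero affinities (upper triangle) as a 3-column TSV."""
    i, j = np.nonzero(np.triu(model.affinity, k=1))
    pd.DataFrame(
        {
            "cell_i": [model.cell_ids[a] for a in i],
            "cell_j": [model.cell_ids[b] for b in j],
            "affinity": model.affinity[i, j],
        }
    ).to_csv(path, sep="\t", index=False)
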