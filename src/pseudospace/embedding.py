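"""Constrained low-dimensional embedding of the affinity probabilities.

Coordinates y for n cells are found by gradient descent with momentum on
the Kullback-Leibler divergence KL(P || Q), where P is the normalised
affinity and Q the heavy-tailed Student-t neighbor kernel

    q_ij = (1 / Z~) * 1 / (1 + d_ij^2),      d_ij = ||y_i - y_j||.

The heavy tail makes nearby slots scarce, so cells with shared partners
compete for proximity instead of all collapsing onto their targets.  Two
spatial constraints model physical tissue: a minimum inter-cell distance r
(cells have positive size) and a bounded space |y| <= R.  The r constraint
is enforced by a per-iteration overlap-resolution pass that pushes pairs
closer than r back apart (with the kernel distance floored at r so Q stays
consistent with the feasible set); the R bound is enforced by clipping
every coordinate to [-R, R] after each update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)


@dataclass
class NeighborKernel:
    """Student-t neighbor probabilities Q with its global normaliser Z~."""

    q: np.ndarray
    z: float


@dataclass
class Embedding:
    """Cell coordinates in the bounded pseudo-space plus the optimiser trace.

    Distances are in pseudo-space units (relative, not micrometres).
    ``trace`` holds the KL loss at every iteration run.
    """

    cell_ids: list[str]
    coords: np.ndarray
    params: dict
    trace: np.ndarray
    checkpoints: dict[int, np.ndarray] | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def _distances(coords: np.ndarray) -> np.ndarray:
    return squareform(pdist(coords))


def _resolve_overlaps(y: np.ndarray, r: float) -> np.ndarray:
    """One position-based pass separating pairs closer than r.

    Every violating pair is pushed apart symmetrically by half its overlap
    along the pair axis (a Jacobi projection step).  Applied once per
    gradient iteration this keeps the configuration close to the feasible
    set d_ij >= r; exactly coincident pairs have no defined axis and are
    left for the next iteration once the gradient has split them.
    """
    d = _distances(y)
    n = d.shape[0]
    viol = d < r
    np.fill_diagonal(viol, False)
    if not viol.any():
        return y
    safe = np.where(d > 0, d, 1.0)
    w = np.where(viol & (d > 0), (r - d) / safe, 0.0)
    # displacement_i = 0.5 * sum_j w_ij (y_i - y_j)
    return y + 0.5 * (w.sum(axis=1)[:, None] * y - w @ y)


def compute_q(coords: np.ndarray, r: float = 0.0) -> NeighborKernel:
    """Normalised t-kernel over all ordered pairs i != j.

    The effective distance is ``max(d_ij, r)``; with ``r = 0`` this is the
    plain kernel.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    if coords.shape[0] < 2:
        raise ValueError("need at least two cells")
    d = np.maximum(_distances(coords), r)
    num = 1.0 / (1.0 + d**2)
    np.fill_diagonal(num, 0.0)
    z = float(num.sum())
    return NeighborKernel(q=num / z, z=z)


def kl_loss(p: np.ndarray, q: np.ndarray) -> float:
    """KL(P || Q) over pairs with p_ij > 0; zero-probability terms drop out."""
    mask = p > 0
    if np.any(q[mask] <= 0):
        raise ValueError("q must be positive wherever p is positive")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def embed(
    model,
    dims: int = 3,
    r: float = 1.0,
    R: float = 50.0,
    max_iter: int = 1000,
    seed: int = 0,
    learning_rate: float = 200.0,
    momentum_early: float = 0.5,
    momentum_late: float = 0.8,
    momentum_switch: int = 250,
    checkpoint_every: int | None = None,
) -> Embedding:
    """Optimise coordinates for an :class:`~pseudospace.affinity.AffinityModel`.

    Initial positions are drawn uniformly inside an R-sided cube centred at
    the origin (the default R = 50 gives the 50 x 50 x 50 cube).  The same
    seed with the same inputs yields bit-identical coordinates.

    Parameters
    ----------
    dims
        Embedding dimensionality, 3 by default (biological space); 1 and 2
        are supported for sheet- or cord-like tissue models.
    r, R
        Minimum inter-cell distance and space radius, pseudo-space units.
    max_iter
        Number of gradient iterations (the trace has this length).
    """
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    if dims not in (1, 2, 3):
        raise ValueError(f"dims must be 1, 2 or 3, got {dims}")
    p = model.p
    if p is None:
        raise ValueError("AffinityModel.p not set; call normalize_p first")
    n = p.shape[0]
    if n < 2:
        raise ValueError("need at least two cells to embed")

    isolated = np.flatnonzero(p.sum(axis=1) == 0)
    if isolated.size:
        logger.warning(
            "%d cells have zero affinity to every other cell and drift under "
            "repulsion only: %s",
            isolated.size,
            [model.cell_ids[i] for i in isolated[:5]],
        )

    rng = np.random.default_rng(seed)
    # one generator, fixed cell order: reproducible initial cube positions
    y = rng.uniform(-R / 2.0, R / 2.0, size=(n, dims))
    update = np.zeros_like(y)
    trace = np.empty(max_iter)
    checkpoints: dict[int, np.ndarray] | None = {} if checkpoint_every else None

    for it in range(max_iter):
        d_raw = _distances(y)
        d = np.maximum(d_raw, r)
        num = 1.0 / (1.0 + d**2)
        np.fill_diagonal(num, 0.0)
        z = num.sum()
        q = num / z
        trace[it] = kl_loss(p, q)
        # t-SNE-style gradient of KL with the t kernel
        pq = (p - q) * num
        grad = 4.0 * (pq.sum(axis=1)[:, None] * y - pq @ y)
        momentum = momentum_early if it < momentum_switch else momentum_late
        update = momentum * update - learning_rate * grad
        y = np.clip(y + update, -R, R)
        if r > 0:
            y = np.clip(_resolve_overlaps(y, r), -R, R)
        if checkpoints is not None and it % checkpoint_every == 0:
            checkpoints[it] = y.copy()

    params = {
        "dims": dims,
        "r": r,
        "R": R,
        "max_iter": max_iter,
        "seed": seed,
        "learning_rate": learning_rate,
        "momentum_early": momentum_early,
        "momentum_late": momentum_late,
        "momentum_switch": momentum_switch,
        "k": getattr(model, "k", None),
        "final_loss": float(trace[-1]),
    }
    return Embedding(
        cell_ids=list(model.cell_ids),
        coords=y,
        params=params,
        trace=trace,
        checkpoints=checkpoints,
    )


def pca_rotate(embedding: Embedding) -> Embedding:
    """Centre and rotate coordinates so axis variances are non-increasing.

    A rigid rotation (plus centring) from the principal axes of the point
    cloud: X captures the most spatial variation, then Y, then Z.  All
    pairwise distances are preserved.  Component signs are fixed so the
    largest-magnitude loading of each axis is positive (deterministic
    output).
    """
    coords = embedding.coords
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    # deterministic sign convention
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    return replace(embedding, coords=centred @ vt.T)
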