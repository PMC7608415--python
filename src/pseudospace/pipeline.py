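"""End-to-end workflow: expression + LR table -> coordinates, density,
interaction report and contribution tables, written to an output directory.

This is the library face of the command-line tool; every stage is also
usable on its own (see the individual modules).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .affinity import AffinityModel, affinity_pipeline, write_affinity
from .contributions import ContributionTable, cluster_contribution
from .embedding import Embedding, embed, pca_rotate
from .perturb import PerturbationSpec, apply_perturbation, compare_reports
from .spatial import (
    DensityResult,
    InteractionReport,
    find_compact_structures,
    neighborhood_radius,
    permutation_test,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters, with the tool's standard defaults.

    k: neighbors kept per cell in the affinity matrix; dims/r/R/max_iter:
    embedding dimensionality, minimum cell distance, space radius and
    iteration budget; nth: which nearest neighbor defines the connection
    radius; n_perm: label permutations for significance.
    """

    k: int = 50
    dims: int = 3
    r: float = 1.0
    R: float = 50.0
    max_iter: int = 1000
    nth: int = 3
    n_perm: int = 1000
    seed: int = 0
    exclude_genes: tuple[str, ...] = ("B2M",)


@dataclass
class RunResult:
    """Bundle of every stage's output for one pipeline run."""

    config: RunConfig
    expr: pio.ExpressionMatrix
    lr: pio.LigandReceptorTable
    model: AffinityModel
    embedding: Embedding
    radius: float
    density: DensityResult
    report: InteractionReport
    contributions: dict[tuple[str, str], ContributionTable] = field(default_factory=dict)


def run_pipeline(
    expr: pio.ExpressionMatrix,
    lr: pio.LigandReceptorTable,
    config: RunConfig | None = None,
    contributions_for: str = "significant",
) -> RunResult:
    """Affinity -> embedding -> spatial statistics -> contributions.

    ``contributions_for`` selects which cluster pairs get a contribution
    decomposition: 'significant' (enriched or depleted pairs), 'all', or
    'none'.
    """
    config = config or RunConfig()
    t0 = time.time()
    model = affinity_pipeline(expr, lr, k=config.k)
    logger.info("affinity: %d cells, Z=%.3g (%.1fs)", model.n_cells, model.z, time.time() - t0)

    t0 = time.time()
    emb = pca_rotate(
        embed(
            model,
            dims=config.dims,
            r=config.r,
            R=config.R,
            max_iter=config.max_iter,
            seed=config.seed,
        )
    )
    logger.info("embedding: final KL loss %.4f (%.1fs)", emb.params["final_loss"], time.time() - t0)

    radius = neighborhood_radius(emb.coords, nth=config.nth)
    dens = find_compact_structures(emb.coords, radius, cell_ids=emb.cell_ids)
    labels = expr.labels()
    report = permutation_test(
        emb.coords, labels, radius, n_perm=config.n_perm, seed=config.seed
    )

    result = RunResult(
        config=config, expr=expr, lr=lr, model=model, embedding=emb,
        radius=radius, density=dens, report=report,
    )
    if contributions_for != "none":
        wanted = report.table if contributions_for == "all" else report.table[
            report.table.call != "other"
        ]
        for _, row in wanted.iterrows():
            try:
                result.contributions[(row.cluster_a, row.cluster_b)] = cluster_contribution(
                    expr, lr, emb.coords, labels, row.cluster_a, row.cluster_b, radius
                )
            except ValueError as exc:
                logger.warning("no contribution table for (%s, %s): %s",
                               row.cluster_a, row.cluster_b, exc)
    return result


def write_bundle(result: RunResult, outdir: str | Path) -> dict[str, Path]:
    """Write coordinates, density, report, contributions and run metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    coords = pd.DataFrame(
        result.embedding.coords,
        columns=["x", "y", "z"][: result.embedding.coords.shape[1]],
    )
    coords.insert(0, "cell_id", result.embedding.cell_ids)
    paths["coordinates"] = outdir / "coordinates.tsv"
    coords.to_csv(paths["coordinates"], sep="\t", index=False)

    paths["density"] = outdir / "density.tsv"
    result.density.to_frame().to_csv(paths["density"], sep="\t", index=False)

    paths["interactions"] = outdir / "interactions.tsv"
    result.report.write(paths["interactions"])

    paths["affinity"] = outdir / "affinity_edges.tsv"
    write_affinity(result.model, paths["affinity"])

    for (a, b), table in result.contributions.items():
        p = outdir / f"contributions_{a}_vs_{b}.tsv"
        table.write(p)
        paths[f"contributions_{a}_vs_{b}"] = p

    meta = {
        **asdict(result.config),
        "n_cells": result.expr.n_cells,
        "n_genes": result.expr.n_genes,
        "n_lr_pairs": len(result.lr),
        "connection_radius": result.radius,
        "final_kl_loss": result.embedding.params["final_loss"],
        "n_structures": result.density.n_structures,
    }
    paths["metadata"] = outdir / "run_metadata.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2, default=str))
    return paths


def run_perturbation(
    expr: pio.ExpressionMatrix,
    lr: pio.LigandReceptorTable,
    spec: PerturbationSpec,
    config: RunConfig | None = None,
) -> tuple[RunResult, RunResult, pd.DataFrame]:
    """Baseline and perturbed pipeline runs (matched seeds) plus the delta table."""
    config = config or RunConfig()
    before = run_pipeline(expr, lr, config, contributions_for="none")
    expr2, lr2 = apply_perturbation(expr, lr, spec)
    after = run_pipeline(expr2, lr2, config, contributions_for="none")
    return before, after, compare_reports(before.report, after.report)
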