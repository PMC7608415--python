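"""Shared fixtures: tiny hand-built inputs plus session-scoped end-to-end
runs on the planted benchmark (reused by several slow tests)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import pseudospace as ps


@pytest.fixture
def tiny_expr() -> ps.ExpressionMatrix:
    """2 genes x 3 cells with simple integer values."""
    return ps.ExpressionMatrix(
        gene_ids=["G1", "G2"],
        cell_ids=["c1", "c2", "c3"],
        values=np.array([[1.0, 0.0, 2.0], [0.0, 5.0, 0.0]]),
    )


@pytest.fixture
def single_pair_lr() -> ps.LigandReceptorTable:
    return ps.LigandReceptorTable(ligands=["L"], receptors=["R"])


def brute_force_affinity(expr: ps.ExpressionMatrix, lr: ps.LigandReceptorTable) -> np.ndarray:
    """Independent O(n^2 K) oracle: explicit double loop over cells and pairs."""
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    n = expr.n_cells
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            total = 0.0
            for ligand, receptor, w in zip(lr.ligands, lr.receptors, lr.weights):
                li = expr.values[index[ligand], i] if ligand in index else 0.0
                lj = expr.values[index[ligand], j] if ligand in index else 0.0
                ri = expr.values[index[receptor], i] if receptor in index else 0.0
                rj = expr.values[index[receptor], j] if receptor in index else 0.0
                total += w * (li * rj + ri * lj)
            out[i, j] = total
    return out


def random_instance(rng: np.random.Generator, n_cells: int, n_pairs: int):
    """Random TPM-scale instance for oracle comparisons."""
    n_genes = 2 * n_pairs + rng.integers(1, 4)
    genes = [f"g{i}" for i in range(n_genes)]
    expr = ps.ExpressionMatrix(
        gene_ids=genes,
        cell_ids=[f"c{i}" for i in range(n_cells)],
        values=rng.random((n_genes, n_cells)) * 100,
    )
    ligands = list(rng.choice(genes, size=n_pairs, replace=True))
    receptors = list(rng.choice(genes, size=n_pairs, replace=True))
    # drop exact duplicate rows the table type forbids
    seen, keep = set(), []
    for idx, pair in enumerate(zip(ligands, receptors)):
        if pair not in seen:
            seen.add(pair)
            keep.append(idx)
    lr = ps.LigandReceptorTable(
        ligands=[ligands[i] for i in keep],
        receptors=[receptors[i] for i in keep],
        weights=rng.random(len(keep)) + 0.1,
    )
    return expr, lr


@dataclass
class BenchmarkRun:
    """One end-to-end benchmark run plus its planted-ligand knockdown rerun."""

    seed: int
    expr: ps.ExpressionMatrix
    lr: ps.LigandReceptorTable
    truth: ps.Truth
    result: ps.RunResult
    knockdown_result: ps.RunResult


@pytest.fixture(scope="session")
def benchmark_runs() -> list[BenchmarkRun]:
    """Five seeds of the planted A/B/C benchmark, baseline + L1 knockdown."""
    runs = []
    for seed in range(5):
        expr, lr, truth = ps.default_benchmark(seed=seed)
        cfg = ps.RunConfig(seed=seed)
        result = ps.run_pipeline(expr, lr, cfg, contributions_for="all")
        kd_expr, kd_lr = ps.apply_perturbation(
            expr, lr, ps.PerturbationSpec(kind="knockdown", gene="L1")
        )
        kd_result = ps.run_pipeline(kd_expr, kd_lr, cfg, contributions_for="none")
        runs.append(BenchmarkRun(seed, expr, lr, truth, result, kd_result))
    return runs
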