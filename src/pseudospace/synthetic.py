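"""Synthetic expression data with planted ligand-receptor interaction structure.

The generator emulates what the pipeline needs from real scRNA-seq data —
cell populations whose complementary ligand/receptor expression wires
specific cluster pairs together — without any claim of modelling a real
transcriptome.  Each population has per-gene mean TPM-scale levels;
cells receive log-normal multiplicative noise around those means (scRNA-seq
abundances are heavy-tailed) and are then TPM-renormalised.  A ``truth``
object records which cluster pairs were wired to interact and through which
dominant LR pair, so recovery can be scored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, LigandReceptorTable, to_tpm


@dataclass
class Population:
    """One cell type: name, size and per-gene mean expression levels."""

    name: str
    n_cells: int
    expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"population {self.name!r} needs >= 1 cell")
        if any(v < 0 for v in self.expression.values()):
            raise ValueError(f"population {self.name!r} has negative mean levels")


@dataclass
class PopulationSpec:
    """Recipe for a planted-interaction dataset.

    ``wiring`` maps an unordered cluster-pair (sorted tuple) to the LR pair
    expected to dominate its affinity; it is declarative truth, derived from
    the population means, not enforced at sampling time.  ``noise_sigma`` is
    the standard deviation of the log-normal multiplicative noise (0 gives
    identical cells per population).  ``background_genes`` uniform low-level
    genes pad each transcriptome so TPM normalisation has a realistic
    denominator.
    """

    populations: list[Population]
    lr_pairs: list[tuple[str, str, float]]
    wiring: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    background_genes: int = 40
    background_level: float = 50.0
    noise_sigma: float = 0.25
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("need at least one population")
        if self.noise_sigma < 0 or not (0 <= self.dropout_rate < 1):
            raise ValueError("invalid noise parameters")


@dataclass
class Truth:
    """Ground truth of a generated instance."""

    wired_pairs: dict[tuple[str, str], tuple[str, str]]

    def dominant_pair(self, a: str, b: str) -> tuple[str, str]:
        return self.wired_pairs[tuple(sorted((a, b)))]


def generate(spec: PopulationSpec) -> tuple[ExpressionMatrix, LigandReceptorTable, Truth]:
    """Sample a TPM-scale annotated expression matrix from a spec.

    Deterministic for a fixed seed.  Cell ids are ``<pop>_<idx>``; the
    annotations of the returned matrix hold the population names.
    """
    rng = np.random.default_rng(spec.seed)
    genes: list[str] = []
    for pop in spec.populations:
        for g in pop.expression:
            if g not in genes:
                genes.append(g)
    for ligand, receptor, _ in spec.lr_pairs:
        for g in (ligand, receptor):
            if g not in genes:
                genes.append(g)
    genes += [f"BG{i}" for i in range(spec.background_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    columns, cell_ids, annotations = [], [], {}
    for pop in spec.populations:
        means = np.full(len(genes), 0.0)
        means[len(genes) - spec.background_genes:] = spec.background_level
        for g, level in pop.expression.items():
            means[gene_pos[g]] = level
        for idx in range(pop.n_cells):
            noise = (
                np.exp(spec.noise_sigma * rng.standard_normal(len(genes)))
                if spec.noise_sigma > 0
                else 1.0
            )
            col = means * noise
            if spec.dropout_rate > 0:
                col = col * (rng.random(len(genes)) >= spec.dropout_rate)
            columns.append(col)
            cid = f"{pop.name}_{idx}"
            cell_ids.append(cid)
            annotations[cid] = pop.name

    expr = ExpressionMatrix(
        gene_ids=genes,
        cell_ids=cell_ids,
        values=np.column_stack(columns),
        annotations=annotations,
    )
    lr = LigandReceptorTable(
        ligands=[l for l, _, _ in spec.lr_pairs],
        receptors=[r for _, r, _ in spec.lr_pairs],
        weights=np.array([w for _, _, w in spec.lr_pairs]),
    )
    truth = Truth(wired_pairs={tuple(sorted(k)): v for k, v in spec.wiring.items()})
    return to_tpm(expr), lr, truth


def default_benchmark_spec(
    seed: int = 0,
    cells_per_type: int = 100,
    signal_level: float = 3000.0,
    decoy_level: float = 20.0,
    noise_sigma: float = 0.25,
) -> PopulationSpec:
    """Three populations — A (ligand L1 high), B (receptor R1 high), C
    (neither) — wired so only the A-B pair interacts, plus 5 decoy LR pairs
    expressed at a low uniform level in every cell."""
    decoys = {f"L{i}": decoy_level for i in range(2, 7)}
    decoys.update({f"R{i}": decoy_level for i in range(2, 7)})
    populations = [
        Population("A", cells_per_type, {"L1": signal_level, **decoys}),
        Population("B", cells_per_type, {"R1": signal_level, **decoys}),
        Population("C", cells_per_type, dict(decoys)),
    ]
    lr_pairs = [("L1", "R1", 1.0)] + [(f"L{i}", f"R{i}", 1.0) for i in range(2, 7)]
    return PopulationSpec(
        populations=populations,
        lr_pairs=lr_pairs,
        wiring={("A", "B"): ("L1", "R1")},
        noise_sigma=noise_sigma,
        seed=seed,
    )


def default_benchmark(seed: int = 0, **kwargs):
    """The canonical planted A/B/C instance (see :func:`default_benchmark_spec`)."""
    return generate(default_benchmark_spec(seed=seed, **kwargs))


def tumor_benchmark_spec(seed: int = 0, cells_per_type: int = 60) -> PopulationSpec:
    """A small tumor-microenvironment-like host for transfer experiments:
    ``malignant`` cells, resident ``T`` cells wired to them, and ``stromal``
    bystanders.

    The background budget (40 genes x 2500) stands in for the bulk of a
    real transcriptome, so after TPM normalisation the signal genes land
    near 5000 TPM — the scale at which the TPM-5000 pseudo TCR-pMHC pair of
    a transfer experiment can meaningfully compete, as it does against real
    data.
    """
    decoys = {f"L{i}": 20.0 for i in range(2, 5)}
    decoys.update({f"R{i}": 20.0 for i in range(2, 5)})
    populations = [
        Population("malignant", cells_per_type, {"L1": 500.0, **decoys}),
        Population("T", cells_per_type, {"R1": 500.0, **decoys}),
        Population("stromal", cells_per_type, dict(decoys)),
    ]
    lr_pairs = [("L1", "R1", 1.0)] + [(f"L{i}", f"R{i}", 1.0) for i in range(2, 5)]
    return PopulationSpec(
        populations=populations,
        lr_pairs=lr_pairs,
        wiring={("T", "malignant"): ("L1", "R1")},
        background_level=2500.0,
        seed=seed,
    )


def donor_t_cells(n_cells: int, seed: int = 0) -> ExpressionMatrix:
    """Donor T cells for adoptive transfer: decoy/background expression only,
    so their tumor affinity is driven entirely by the pseudo TCR-pMHC pair.
    Uses the same transcriptome scale as :func:`tumor_benchmark_spec`."""
    decoys = {f"L{i}": 20.0 for i in range(2, 5)}
    decoys.update({f"R{i}": 20.0 for i in range(2, 5)})
    spec = PopulationSpec(
        populations=[Population("donorT", n_cells, decoys)],
        lr_pairs=[("L2", "R2", 1.0)],
        background_level=2500.0,
        seed=seed,
    )
    expr, _, _ = generate(spec)
    return expr
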