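"""Reading, writing and normalising the pipeline's tabular inputs.

Two container types live here: :class:`ExpressionMatrix` (genes x cells,
TPM-scale values, optional per-cell cluster annotations) and
:class:`LigandReceptorTable` (ordered ligand/receptor gene pairs with
interaction weights).  Expression can be read from a dense TSV (genes as
rows, header of cell ids) or a MatrixMarket triplet with ``genes.tsv`` /
``barcodes.tsv`` sidecars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger(__name__)

TPM_TOTAL = 1e6


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class ExpressionMatrix:
    """Gene-by-cell expression matrix on the TPM scale.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per row of ``values``.
    cell_ids
        Unique cell identifiers, one per column of ``values``.
    values
        Nonnegative ``(n_genes, n_cells)`` array.
    annotations
        Optional mapping cell_id -> cluster label covering a subset of cells.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    annotations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if (self.values < 0).any():
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression for gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.annotations is not None:
            unknown = set(self.annotations) - set(self.cell_ids)
            if unknown:
                raise ValueError(f"annotated cells absent from matrix: {sorted(unknown)[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def labels(self, cell_ids: Sequence[str] | None = None) -> np.ndarray:
        """Annotation labels aligned to ``cell_ids`` (default: all cells)."""
        if self.annotations is None:
            raise ValueError("matrix has no annotations")
        ids = self.cell_ids if cell_ids is None else list(cell_ids)
        missing = [c for c in ids if c not in self.annotations]
        if missing:
            raise ValueError(f"unannotated cells: {missing[:5]}")
        return np.array([self.annotations[c] for c in ids], dtype=object)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class LigandReceptorTable:
    """Ordered ligand-receptor pairs with nonnegative interaction weights.

    The weight summarises the chemical nature of the pair (reaction constant
    and stoichiometry); absent better knowledge it defaults to 1 for every
    pair.
    """

    ligands: list[str]
    receptors: list[str]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.ones(len(self.ligands))
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.ligands) == len(self.receptors) == len(self.weights)):
            raise ValueError("ligands, receptors and weights must have equal length")
        if not np.all(np.isfinite(self.weights)) or (self.weights < 0).any():
            raise ValueError("weights must be finite and >= 0")
        seen = set()
        for pair in zip(self.ligands, self.receptors):
            if pair in seen:
                raise ValueError(f"duplicate ligand-receptor row {pair}")
            seen.add(pair)

    def __len__(self) -> int:
        return len(self.ligands)

    @property
    def genes(self) -> set[str]:
        return set(self.ligands) | set(self.receptors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ligand": self.ligands, "receptor": self.receptors, "weight": self.weights}
        )


# ---------------------------------------------------------------------------
# expression I/O


def _resolve_duplicate_genes(frame: pd.DataFrame) -> pd.DataFrame:
    # keep the duplicate row with the largest total expression
    if frame.index.is_unique:
        return frame
    totals = frame.sum(axis=1).to_numpy()
    order = np.argsort(-totals, kind="stable")
    keep = ~frame.index[order].duplicated()
    kept = frame.iloc[order[keep]]
    dropped = len(frame) - len(kept)
    logger.warning("resolved %d duplicate gene symbol rows (kept max-total row)", dropped)
    # restore first-appearance order of the surviving rows
    first_pos = {g: i for i, g in reversed(list(enumerate(frame.index)))}
    return kept.iloc[np.argsort([first_pos[g] for g in kept.index], kind="stable")]


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from ``tsv`` or ``mtx``.

    TSV: genes as rows, first column gene symbols, header row of cell ids.
    MTX: MatrixMarket triplet (genes x cells) with ``genes.tsv`` and
    ``barcodes.tsv`` sidecars next to the ``.mtx`` file.

    Duplicate gene symbols are resolved by keeping the row with the largest
    total expression (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if frame.columns.size == 0:
            raise FormatError(f"{path}: no cell columns in header")
        for gene, row in frame.iterrows():
            arr = pd.to_numeric(row, errors="coerce")
            if arr.isna().any():
                raise FormatError(f"{path}: non-numeric entry in gene row {gene!r}")
        values = frame.astype(float)
    elif format == "mtx":
        genes_path = path.parent / "genes.tsv"
        barcodes_path = path.parent / "barcodes.tsv"
        for side in (genes_path, barcodes_path):
            if not side.exists():
                raise FormatError(f"missing MatrixMarket sidecar {side}")
        mat = coo_matrix(mmread(path))
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"{path}: matrix shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} barcodes)"
            )
        values = pd.DataFrame(mat.toarray(), index=genes, columns=cells)
    else:
        raise ValueError(f"unknown format {format!r}")

    values.index = values.index.astype(str)
    values = _resolve_duplicate_genes(values)
    neg = values.lt(0).any(axis=1)
    if neg.any():
        raise FormatError(f"{path}: negative value in gene row {values.index[neg][0]!r}")
    return ExpressionMatrix(
        gene_ids=values.index.tolist(),
        cell_ids=[str(c) for c in values.columns],
        values=values.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write an expression matrix as TSV or MatrixMarket triplet + sidecars."""
    path = Path(path)
    if format == "tsv":
        expr.to_frame().to_csv(path, sep="\t")
    elif format == "mtx":
        mmwrite(str(path), coo_matrix(expr.values))
        pd.Series(expr.gene_ids).to_csv(path.parent / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(expr.cell_ids).to_csv(path.parent / "barcodes.tsv", sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def to_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each cell so its values sum to one million (TPM convention).

    Within-cell proportions are preserved.  Cells whose column is entirely
    zero stay zero and are reported with a warning.  For UMI counts without
    gene lengths this is counts-per-million on the provided values.
    """
    sums = expr.values.sum(axis=0)
    zero = sums == 0
    if zero.any():
        logger.warning(
            "%d all-zero cells left unscaled: %s",
            int(zero.sum()),
            [expr.cell_ids[i] for i in np.flatnonzero(zero)[:5]],
        )
    scale = np.divide(TPM_TOTAL, sums, out=np.zeros_like(sums), where=~zero)
    return replace(expr, values=expr.values * scale)


# ---------------------------------------------------------------------------
# annotations and LR tables


def read_annotations(path: str | Path) -> dict[str, str]:
    """Read a 2-column cell_id<TAB>label table (header required)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected 2 columns (cell_id, label)")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def write_annotations(annotations: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"cell_id": list(annotations), "label": list(annotations.values())}
    ).to_csv(path, sep="\t", index=False)


def read_lr_table(
    path: str | Path, exclude_genes: Iterable[str] = ()
) -> LigandReceptorTable:
    """Read a ligand/receptor pair TSV (optional third weight column).

    Rows whose ligand or receptor appears in ``exclude_genes`` are removed —
    the canonical use is dropping housekeeping genes such as B2M whose
    ubiquitous expression would swamp the affinity signal.  Missing weights
    default to 1.
    """
    frame = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected >=2 columns (ligand, receptor[, weight])")
    ligands = frame.iloc[:, 0].astype(str)
    receptors = frame.iloc[:, 1].astype(str)
    if frame.shape[1] >= 3:
        weights = pd.to_numeric(frame.iloc[:, 2], errors="raise").fillna(1.0).to_numpy()
    else:
        weights = np.ones(len(frame))

    exclude = set(exclude_genes)
    keep = ~(ligands.isin(exclude) | receptors.isin(exclude))
    removed = int((~keep).sum())
    if removed:
        logger.info("excluded %d ligand-receptor rows involving %s", removed, sorted(exclude))
    if not keep.any():
        raise ValueError(f"{path}: no ligand-receptor pairs left after filtering")

    # drop exact duplicate (ligand, receptor) rows, keeping the first
    dedup = ~pd.DataFrame({"l": ligands, "r": receptors}).duplicated()
    keep &= dedup
    return LigandReceptorTable(
        ligands=ligands[keep].tolist(),
        receptors=receptors[keep].tolist(),
        weights=np.asarray(weights)[keep.to_numpy()],
    )


def write_lr_table(lr: LigandReceptorTable, path: str | Path) -> None:
    lr.to_frame().to_csv(path, sep="\t", index=False)


def builtin_lr_table(which: str = "core", exclude_genes: Iterable[str] = ("B2M",)) -> LigandReceptorTable:
    """Load one of the bundled synthetic ligand-receptor tables.

    ``core`` plays the role of a FANTOM5-style default list and ``extended``
    of a CellPhoneDB-style alternative in which multi-subunit complexes have
    been expanded all-pairs into binary ligand-receptor rows.  Both are
    synthetic stand-ins (plausible human gene symbols, unit weights) meant to
    be replaced by the user's curated table.  B2M rows are excluded by
    default because of its housekeeping nature.
    """
    from importlib.resources import files

    names = {"core": "synthetic_lr_core.tsv", "extended": "synthetic_lr_extended.tsv"}
    if which not in names:
        raise ValueError(f"unknown builtin table {which!r}; choose from {sorted(names)}")
    with files("pseudospace.data").joinpath(names[which]).open("r") as fh:
        import io as _io

        return read_lr_table(_io.StringIO(fh.read()), exclude_genes=exclude_genes)


def lr_coverage(expr: ExpressionMatrix, lr: LigandReceptorTable) -> float:
    """Fraction of LR genes present in the matrix; warns when genes are missing.

    Pairs with absent genes are retained downstream and contribute zero
    affinity (absent gene treated as expression 0).
    """
    genes = lr.genes
    present = genes & set(expr.gene_ids)
    frac = len(present) / len(genes) if genes else 0.0
    if frac < 1.0:
        logger.warning(
            "%d/%d ligand-receptor genes absent from matrix (contribute zero affinity)",
            len(genes) - len(present),
            len(genes),
        )
    return frac
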