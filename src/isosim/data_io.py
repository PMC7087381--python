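"""Isoform-by-cell count matrices: I/O, filtering, and per-isoform statistics.

The pipeline consumes an isoform-by-cell matrix of nonnegative integer counts
(as produced by transcript-level quantifiers such as Kallisto) together with a
two-column transcript-to-gene map.  This module reads and validates those
inputs, applies the detected-isoform filter (more than ``min_count`` counts in
at least ``min_cells`` cells), selects genes with exactly four detected
isoforms, and computes the per-isoform statistics downstream stages need:
mean expression in counts per million (CPM), empirical detection probability,
and dropout rate.

Conventions
-----------
* Matrices are isoform-major: isoforms as rows, cells as columns.
* CPM normalization uses each cell's total over *all* isoforms in the matrix,
  matching quantification of the full transcriptome.
* The dataset-level "detected isoform" filter is strict (count > 5 in >= 2
  cells by default).  The per-cell detection used for detection probabilities
  is "count > 0" by default, because the dropout machinery treats any zero as
  a dropout; the threshold is exposed as a parameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IsoformCountMatrix",
    "GeneIsoformSet",
    "IsoformStats",
    "read_count_matrix",
    "write_count_matrix",
    "read_t2g",
    "cpm_normalize",
    "isoform_detected",
    "select_four_isoform_genes",
    "compute_isoform_stats",
]


@dataclass
class IsoformCountMatrix:
    """Validated nonnegative-integer counts for isoforms (rows) x cells (columns).

    Parameters
    ----------
    isoform_ids
        Unique transcript identifiers, one per row.
    cell_ids
        Unique cell identifiers, one per column.
    counts
        Integer array of shape ``(n_isoforms, n_cells)``.
    gene_of
        Mapping from every transcript identifier to its gene identifier.
    """

    isoform_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray
    gene_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D isoform x cell array")
        if self.counts.shape != (len(self.isoform_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.isoform_ids)} isoforms x {len(self.cell_ids)} cells"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.floor(as_float)):
                raise ValueError("counts must be integers")
            self.counts = as_float.astype(np.int64)
        if np.any(self.counts < 0):
            bad = int(np.argwhere(self.counts < 0)[0][0])
            raise ValueError(f"negative count in row for isoform {self.isoform_ids[bad]!r}")
        if len(set(self.isoform_ids)) != len(self.isoform_ids):
            raise ValueError("isoform ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids are not unique")
        missing = [t for t in self.isoform_ids if t not in self.gene_of]
        if missing:
            raise ValueError(f"{len(missing)} isoforms lack a gene mapping, e.g. {missing[0]!r}")

    @property
    def n_isoforms(self) -> int:
        return len(self.isoform_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def row(self, isoform_id: str) -> np.ndarray:
        """Counts across cells for one isoform."""
        return self.counts[self.isoform_ids.index(isoform_id)]


@dataclass(frozen=True)
class GeneIsoformSet:
    """One gene with its detected isoforms, ranked by total expression.

    ``isoforms`` is ordered so that rank 1 (highest total counts) comes first.
    The pipeline's simulation unit uses M = 4, but any M >= 1 is permitted.
    """

    gene_id: str
    isoforms: tuple[str, ...]

    @property
    def M(self) -> int:
        return len(self.isoforms)

    @property
    def ranks(self) -> dict[str, int]:
        """Mapping isoform -> rank k in 1..M (1 = most highly expressed)."""
        return {t: k for k, t in enumerate(self.isoforms, start=1)}


@dataclass(frozen=True)
class IsoformStats:
    """Empirical per-isoform statistics.

    ``S`` is the mean expression across cells in CPM (zeros included) — the
    quantity the Michaelis-Menten dropout curve is parameterized by.  Under
    the default nonzero-count detection rule,
    ``p_detection == 1 - dropout_rate``.
    """

    S: float
    p_detection: float
    dropout_rate: float
    total_counts: int


def read_t2g(path: str | Path) -> dict[str, str]:
    """Read a headerless two-column (transcript_id, gene_id) TSV map."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: transcript-to-gene map needs two tab-separated columns")
    dup = df[0].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate transcript id {df[0][dup].iloc[0]!r}")
    return dict(zip(df[0], df[1]))


def _read_counts_table(counts_path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"{counts_path}: malformed table: {exc}") from exc
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        line = int(df.index.get_loc(row)) + 2  # header is line 1
        raise ValueError(f"{counts_path}: missing or unparsable count at line {line} ({row!r})")
    return df


def _read_counts_mtx(counts_path: Path) -> pd.DataFrame:
    from scipy import io as spio

    mat = spio.mmread(counts_path)
    rows = Path(str(counts_path) + ".rows").read_text().split()
    cols = Path(str(counts_path) + ".cols").read_text().split()
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    return pd.DataFrame(dense, index=rows, columns=cols)


def read_count_matrix(counts_path: str | Path, t2g_path: str | Path) -> IsoformCountMatrix:
    """Read and validate a count matrix plus its transcript-to-gene map.

    ``counts_path`` is either a TSV (header row of cell ids, first column
    isoform ids) or a matrix-market ``.mtx`` file with ``<file>.rows`` /
    ``<file>.cols`` sidecar id lists.  Isoforms present in the counts but
    absent from the map are reported and dropped.
    """
    counts_path = Path(counts_path)
    t2g = read_t2g(t2g_path)
    if counts_path.suffix == ".mtx":
        df = _read_counts_mtx(counts_path)
    else:
        df = _read_counts_table(counts_path)

    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        as_float = values.astype(float)
        bad = (as_float != np.floor(as_float)) | ~np.isfinite(as_float)
        if bad.any():
            row = df.index[np.argwhere(bad)[0][0]]
            line = int(df.index.get_loc(row)) + 2
            raise ValueError(f"{counts_path}: non-integer count at line {line} ({row!r})")
        values = as_float.astype(np.int64)
    if (values < 0).any():
        row = df.index[np.argwhere(values < 0)[0][0]]
        line = int(df.index.get_loc(row)) + 2
        raise ValueError(f"{counts_path}: negative count at line {line} ({row!r})")

    isoforms = [str(t) for t in df.index]
    unmapped = [t for t in isoforms if t not in t2g]
    if unmapped:
        logger.warning(
            "%d isoforms absent from the transcript-to-gene map were dropped (e.g. %r)",
            len(unmapped), unmapped[0],
        )
        keep = np.array([t in t2g for t in isoforms])
        values = values[keep]
        isoforms = [t for t in isoforms if t in t2g]

    return IsoformCountMatrix(
        isoform_ids=isoforms,
        cell_ids=[str(c) for c in df.columns],
        counts=values,
        gene_of={t: t2g[t] for t in isoforms},
    )


def write_count_matrix(
    matrix: IsoformCountMatrix,
    counts_path: str | Path,
    t2g_path: str | Path | None = None,
) -> None:
    """Write a count matrix as TSV (or ``.mtx`` + sidecars) and optionally its map."""
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        from scipy import io as spio
        from scipy import sparse

        spio.mmwrite(counts_path, sparse.coo_matrix(matrix.counts))
        Path(str(counts_path) + ".rows").write_text("\n".join(matrix.isoform_ids) + "\n")
        Path(str(counts_path) + ".cols").write_text("\n".join(matrix.cell_ids) + "\n")
    else:
        df = pd.DataFrame(matrix.counts, index=matrix.isoform_ids, columns=matrix.cell_ids)
        df.to_csv(counts_path, sep="\t")
    if t2g_path is not None:
        with open(t2g_path, "w") as fh:
            for t in matrix.isoform_ids:
                fh.write(f"{t}\t{matrix.gene_of[t]}\n")


def cpm_normalize(matrix: IsoformCountMatrix | np.ndarray) -> np.ndarray:
    """Counts-per-million matrix: count / cell total x 1e6, per cell.

    Cells with zero total counts yield all-zero columns and a warning.
    """
    counts = matrix.counts if isinstance(matrix, IsoformCountMatrix) else np.asarray(matrix)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    totals = counts.sum(axis=0).astype(float)
    empty = totals == 0
    if empty.all():
        raise ValueError("every cell has zero total counts")
    if empty.any():
        warnings.warn(f"{int(empty.sum())} cells have zero total counts; their CPM is all zero")
    return counts / np.where(empty, 1.0, totals) * 1e6


def isoform_detected(counts_row: np.ndarray, min_count: int = 5, min_cells: int = 2) -> bool:
    """Dataset-level detection: strictly more than ``min_count`` counts in at
    least ``min_cells`` cells."""
    row = np.asarray(counts_row)
    return int(np.count_nonzero(row > min_count)) >= min_cells


def select_four_isoform_genes(
    matrix: IsoformCountMatrix,
    min_count: int = 5,
    min_cells: int = 2,
    n_isoforms: int = 4,
) -> list[GeneIsoformSet]:
    """Genes for which exactly ``n_isoforms`` isoforms pass the detection filter.

    Detected isoforms are ranked by total counts (descending); ties are broken
    lexicographically by isoform id so the ranking is deterministic.  Genes
    with more or fewer detected isoforms are excluded.  The result is sorted
    by gene id and is invariant to row/column permutations of the input.
    """
    by_gene: dict[str, list[int]] = {}
    for idx, t in enumerate(matrix.isoform_ids):
        by_gene.setdefault(matrix.gene_of[t], []).append(idx)

    out: list[GeneIsoformSet] = []
    for gene_id in sorted(by_gene):
        detected = [
            i for i in by_gene[gene_id]
            if isoform_detected(matrix.counts[i], min_count, min_cells)
        ]
        if len(detected) != n_isoforms:
            continue
        totals = matrix.counts[detected].sum(axis=1)
        order = sorted(
            range(len(detected)),
            key=lambda j: (-int(totals[j]), matrix.isoform_ids[detected[j]]),
        )
        out.append(GeneIsoformSet(
            gene_id=gene_id,
            isoforms=tuple(matrix.isoform_ids[detected[j]] for j in order),
        ))
    return out


def compute_isoform_stats(
    matrix: IsoformCountMatrix,
    detection_min_count: int = 0,
) -> dict[str, IsoformStats]:
    """Per-isoform mean CPM, detection probability, and dropout rate.

    ``S`` is the mean of CPM values across all cells (zeros included).
    ``dropout_rate`` is the fraction of cells with a zero count, and
    ``p_detection`` the fraction of cells with count > ``detection_min_count``
    (default 0, i.e. the complement of the dropout rate).
    """
    cpm = cpm_normalize(matrix)
    n_cells = matrix.n_cells
    s_vals = cpm.mean(axis=1)
    dropout = (matrix.counts == 0).sum(axis=1) / n_cells
    p_det = (matrix.counts > detection_min_count).sum(axis=1) / n_cells
    totals = matrix.counts.sum(axis=1)
    return {
        t: IsoformStats(
            S=float(s_vals[i]),
            p_detection=float(p_det[i]),
            dropout_rate=float(dropout[i]),
            total_counts=int(totals[i]),
        )
        for i, t in enumerate(matrix.isoform_ids)
    }
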