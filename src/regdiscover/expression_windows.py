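"""Cross-species dot-plot statistics and expression-window extraction.

From per-cell counts with (cluster, stage, species) metadata this module
computes the dot-plot summary — fraction of cells expressing a gene and
mean expression per (gene, cluster, stage) — then extracts the contiguous
developmental window over which a gene is expressed in at least a given
fraction of cells, and normalizes the window's duration to the species'
lifespan so expression spans are comparable between, say, zebrafish, mouse
and human.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core_io import SpeciesTimeline

__all__ = ["CellByGeneCounts", "ClusterStageSummary", "ExpressionWindow",
           "summarize_dotplot", "extract_window", "normalize_duration",
           "read_counts_mtx", "write_counts_mtx"]


@dataclass
class CellByGeneCounts:
    """Integer count matrix (cells x genes) with per-cell metadata.

    ``cell_meta`` is indexed by cell id with columns cluster, stage, species;
    every matrix row must have metadata.
    """

    matrix: np.ndarray            # (n_cells, n_genes) non-negative ints
    cells: list[str]
    genes: list[str]
    cell_meta: pd.DataFrame       # index: cell; columns: cluster, stage, species

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.cells), len(self.genes)):
            raise ValueError("matrix shape does not match cell/gene labels")
        if np.any(self.matrix < 0):
            raise ValueError("negative counts")
        missing = set(self.cells) - set(self.cell_meta.index)
        if missing:
            raise ValueError(f"cells without metadata: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class ClusterStageSummary:
    """Per (gene, cluster, stage): fraction of cells expressing, mean count,
    group size.  Stored as a DataFrame with that MultiIndex-free layout."""

    table: pd.DataFrame  # columns: gene, cluster, stage, fraction_expressing, mean_expression, n_cells

    def lookup(self, gene: str, cluster: str, stage: str) -> pd.Series | None:
        t = self.table
        sub = t[(t["gene"] == gene) & (t["cluster"] == cluster) & (t["stage"] == stage)]
        return None if sub.empty else sub.iloc[0]


@dataclass(frozen=True)
class ExpressionWindow:
    gene: str
    cluster: str
    species: str
    first_stage: str
    last_stage: str
    dip_count: int = 0
    duration_days: float | None = None
    normalized_duration: float | None = None


def summarize_dotplot(counts: CellByGeneCounts, genes) -> ClusterStageSummary:
    """Dot-plot summary: per (gene, cluster, stage) the fraction of cells
    with count > 0 and the mean count over all cells in the group."""
    genes = list(genes)
    gene_idx = {g: i for i, g in enumerate(counts.genes)}
    unknown = [g for g in genes if g not in gene_idx]
    if unknown:
        raise KeyError(f"genes not in matrix: {unknown[:5]}")

    meta = counts.cell_meta.loc[counts.cells]
    groups = meta.groupby(["cluster", "stage"], sort=True).indices
    rows = []
    for (cluster, stage), idx in groups.items():
        sub = counts.matrix[np.asarray(idx)]
        n = sub.shape[0]
        for g in genes:
            col = sub[:, gene_idx[g]]
            rows.append({
                "gene": g, "cluster": cluster, "stage": stage,
                "fraction_expressing": float(np.count_nonzero(col)) / n,
                "mean_expression": float(col.mean()),
                "n_cells": int(n),
            })
    table = pd.DataFrame(rows, columns=["gene", "cluster", "stage",
                                        "fraction_expressing",
                                        "mean_expression", "n_cells"])
    return ClusterStageSummary(table)


def extract_window(summary: ClusterStageSummary, gene: str, cluster: str,
                   stage_order: list[str], min_fraction: float = 0.2,
                   species: str = "") -> ExpressionWindow | None:
    """Envelope expression window: FIRST to LAST stage with
    ``fraction_expressing >= min_fraction``.

    Interior stages dipping below the threshold do not split the window;
    their number is reported as ``dip_count``.  Returns None when no stage
    qualifies.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    t = summary.table
    sub = t[(t["gene"] == gene) & (t["cluster"] == cluster)]
    frac = {r.stage: r.fraction_expressing for r in sub.itertuples()}
    qualifying = [i for i, st in enumerate(stage_order)
                  if frac.get(st, 0.0) >= min_fraction]
    if not qualifying:
        return None
    first, last = qualifying[0], qualifying[-1]
    dips = sum(1 for i in range(first, last + 1) if i not in set(qualifying))
    return ExpressionWindow(
        gene=gene, cluster=cluster, species=species,
        first_stage=stage_order[first], last_stage=stage_order[last],
        dip_count=dips,
    )


def normalize_duration(window: ExpressionWindow, timeline: SpeciesTimeline
                       ) -> ExpressionWindow:
    """Complete a window with its absolute duration (days) and the
    lifespan-normalized duration ``duration_days / lifespan_days``."""
    first_age = timeline.age_days(window.first_stage)
    last_age = timeline.age_days(window.last_stage)
    duration = last_age - first_age
    if duration < 0:
        raise ValueError("window stages out of order under the timeline")
    return replace(window, species=window.species or timeline.species,
                   duration_days=duration,
                   normalized_duration=duration / timeline.lifespan_days)


# ---------------------------------------------------------------------------
# MatrixMarket IO
# ---------------------------------------------------------------------------

def read_counts_mtx(mtx_path, genes_path, cells_path, meta_path) -> CellByGeneCounts:
    """Read a counts bundle: MTX (cells x genes) + gene/cell label TSVs +
    cell metadata TSV ``cell cluster stage species``."""
    mat = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].tolist()
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str).set_index("cell")
    return CellByGeneCounts(np.asarray(mat, dtype=int), cells, genes, meta)


def write_counts_mtx(counts: CellByGeneCounts, mtx_path, genes_path, cells_path,
                     meta_path) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(counts.matrix))
    pd.Series(counts.genes).to_csv(genes_path, sep="\t", index=False, header=False)
    pd.Series(counts.cells).to_csv(cells_path, sep="\t", index=False, header=False)
    counts.cell_meta.reset_index().rename(columns={"index": "cell"}).to_csv(
        meta_path, sep="\t", index=False)
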