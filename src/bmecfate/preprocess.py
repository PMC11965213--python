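"""Gene filters, cell quality control and log normalization.

Each input dataset carries its own gene-count floor (the meta-analysis
mixes shallow and deep studies: floors of 10, 50, 100 and 300 total counts
are the stock presets), followed by an expressed-in-fraction filter.
Cell QC applies the standard single-cell cascade: a detected-gene floor
per cell, a cells-per-gene floor, then 5-MAD outlier removal on
log-library size and log-detected genes (two-sided) and mitochondrial
fraction (high side only).
"""

from __future__ import annotations

import logging

import numpy as np

from .types import ExpressionDataset, QCReport, ValidationError

log = logging.getLogger(__name__)

COUNT_FLOOR_PRESETS = (10, 50, 100, 300)


def filter_genes_by_counts(
    dataset: ExpressionDataset,
    min_total_counts: int = 10,
    min_cell_fraction: float = 0.01,
) -> tuple[ExpressionDataset, QCReport]:
    """Keep genes with enough total counts that are seen in enough cells.

    A gene is retained iff its total count across cells is at least
    ``min_total_counts`` AND it is detected (count > 0) in at least
    ``min_cell_fraction`` of cells.  Gene order is preserved.
    """
    if dataset.unit != "raw_counts":
        raise ValidationError("gene count filter expects raw counts")
    totals = dataset.values.sum(axis=1)
    detected_frac = (dataset.values > 0).mean(axis=1)
    keep = (totals >= min_total_counts) & (detected_frac >= min_cell_fraction)
    if not keep.any():
        raise ValidationError(
            f"{dataset.dataset_id}: no gene survives "
            f"min_total_counts={min_total_counts}, "
            f"min_cell_fraction={min_cell_fraction}; review thresholds"
        )
    report = QCReport()
    report.add(
        "gene_counts",
        n_in=dataset.n_genes,
        n_removed=int((~keep).sum()),
        min_total_counts=min_total_counts,
        min_cell_fraction=min_cell_fraction,
    )
    genes = [g for g, k in zip(dataset.gene_ids, keep) if k]
    return dataset.subset(genes=genes), report


def _mad_outliers(x: np.ndarray, n_mads: float, high_only: bool = False) -> np.ndarray:
    """Boolean mask of values more than ``n_mads`` MADs from the median.

    A zero MAD (e.g. perfectly homogeneous cells) means no spread, hence
    no outliers.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x, dtype=bool)
    dev = (x - med) / mad
    return dev > n_mads if high_only else np.abs(dev) > n_mads


def qc_filter_cells(
    dataset: ExpressionDataset,
    min_genes: int = 200,
    min_cells_per_gene: int = 3,
    n_mads: float = 5.0,
    mito_prefix: str = "MT-",
) -> tuple[ExpressionDataset, QCReport]:
    """Standard cell QC cascade on a raw count matrix.

    Order of operations: (1) drop cells with fewer than ``min_genes``
    detected genes, (2) drop genes expressed in fewer than
    ``min_cells_per_gene`` cells, (3) drop cells whose log1p library size
    or log1p detected-gene count deviates more than ``n_mads``
    median-absolute-deviations from the median (two-sided), or whose
    mitochondrial fraction does so on the high side.
    """
    if dataset.unit != "raw_counts":
        raise ValidationError("cell QC expects raw counts")
    report = QCReport()

    detected = (dataset.values > 0).sum(axis=0)
    keep_cells = detected >= min_genes
    report.add(
        "cell_min_genes",
        n_in=dataset.n_samples,
        n_removed=int((~keep_cells).sum()),
        min_genes=min_genes,
    )
    d = dataset.subset(samples=[s for s, k in zip(dataset.sample_ids, keep_cells) if k])

    cells_per_gene = (d.values > 0).sum(axis=1)
    keep_genes = cells_per_gene >= min_cells_per_gene
    report.add(
        "gene_min_cells",
        n_in=d.n_genes,
        n_removed=int((~keep_genes).sum()),
        min_cells_per_gene=min_cells_per_gene,
    )
    d = d.subset(genes=[g for g, k in zip(d.gene_ids, keep_genes) if k])

    lib = np.log1p(d.values.sum(axis=0))
    ngen = np.log1p((d.values > 0).sum(axis=0))
    out = _mad_outliers(lib, n_mads) | _mad_outliers(ngen, n_mads)
    mito_rows = [i for i, g in enumerate(d.gene_ids) if g.startswith(mito_prefix)]
    if mito_rows:
        depth = d.values.sum(axis=0)
        mito_frac = np.divide(
            d.values[mito_rows, :].sum(axis=0),
            depth,
            out=np.zeros(d.n_samples),
            where=depth > 0,
        )
        out |= _mad_outliers(mito_frac, n_mads, high_only=True)
    else:
        log.warning(
            "%s: no gene matches mito prefix %r; mito filter skipped",
            d.dataset_id,
            mito_prefix,
        )
    report.add(
        "cell_mad_outliers",
        n_in=d.n_samples,
        n_removed=int(out.sum()),
        n_mads=n_mads,
        mito_prefix=mito_prefix,
        mito_genes=len(mito_rows),
    )
    d = d.subset(samples=[s for s, o in zip(d.sample_ids, out) if not o])
    return d, report


def normalize_log(dataset: ExpressionDataset, scale: float = 1e4) -> ExpressionDataset:
    """Depth-normalize each cell to ``scale`` total counts, then log1p."""
    if dataset.unit != "raw_counts":
        raise ValidationError("log normalization expects raw counts")
    depth = dataset.values.sum(axis=0)
    if np.any(depth == 0):
        zero = [s for s, d in zip(dataset.sample_ids, depth) if d == 0]
        raise ValidationError(
            f"{dataset.dataset_id}: zero-depth cells {zero[:5]}; run QC first"
        )
    values = np.log1p(dataset.values / depth * scale)
    return ExpressionDataset(
        dataset_id=dataset.dataset_id,
        species=dataset.species,
        gene_ids=list(dataset.gene_ids),
        sample_ids=list(dataset.sample_ids),
        values=values,
        unit="log_normalized",
        metadata=dataset.metadata,
    )
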