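"""Readers and writers for every on-disk format the pipeline touches.

Expression matrices travel as matrix-market triplets with sidecar gene /
sample label files (dense TSV accepted for small fixtures), gene sets as
GMT, per-sample metadata and summary tables as TSV, structured results as
JSON.  Every reader/writer pair is a lossless round trip up to the
documented ordering rules.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import ExpressionDataset, FormatError, Regulon, RegulonSet, ValidationError

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# expression matrices
# --------------------------------------------------------------------------

def _read_labels(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
    metadata_path: str | Path,
    unit: str,
    dataset_id: str | None = None,
    species: str = "human",
) -> ExpressionDataset:
    """Load a gene x sample matrix with labels and per-sample metadata.

    ``matrix_path`` may be a matrix-market triplet (``.mtx``) or a dense
    TSV of raw numbers (no header).  Label files carry one entry per line;
    metadata is a TSV keyed by sample id with a mandatory ``cell_class``
    column (``vascular_bed`` filled with ``"na"`` when absent).
    """
    matrix_path = Path(matrix_path)
    genes = _read_labels(genes_path)
    samples = _read_labels(samples_path)
    if matrix_path.suffix == ".mtx":
        try:
            values = np.asarray(scipy.io.mmread(matrix_path).todense(), dtype=float)
        except Exception as exc:  # malformed header / body
            raise FormatError(f"{matrix_path}: not a valid matrix-market file: {exc}")
    else:
        try:
            values = pd.read_csv(matrix_path, sep="\t", header=None).to_numpy(float)
        except Exception as exc:
            raise FormatError(f"{matrix_path}: not a parseable dense TSV: {exc}")
    if values.shape[0] != len(genes):
        raise FormatError(
            f"{matrix_path} has {values.shape[0]} rows but {genes_path} lists "
            f"{len(genes)} genes"
        )
    if values.shape[1] != len(samples):
        raise FormatError(
            f"{matrix_path} has {values.shape[1]} columns but {samples_path} "
            f"lists {len(samples)} samples"
        )
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    missing = [s for s in samples if s not in metadata.index]
    if missing:
        raise ValidationError(
            f"samples in matrix but absent from {metadata_path}: {missing[:10]}"
        )
    return ExpressionDataset(
        dataset_id=dataset_id or matrix_path.stem,
        species=species,
        gene_ids=genes,
        sample_ids=samples,
        values=values,
        unit=unit,
        metadata=metadata,
    )


def write_expression(dataset: ExpressionDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset as mtx + genes/samples/metadata sidecars.

    Returns the paths written, keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = dataset.dataset_id
    paths = {
        "matrix": out_dir / f"{stem}.mtx",
        "genes": out_dir / f"{stem}.genes.txt",
        "samples": out_dir / f"{stem}.samples.txt",
        "metadata": out_dir / f"{stem}.metadata.tsv",
    }
    sparse = scipy.sparse.coo_matrix(dataset.values)
    scipy.io.mmwrite(paths["matrix"], sparse, precision=12)
    paths["genes"].write_text("".join(g + "\n" for g in dataset.gene_ids))
    paths["samples"].write_text("".join(s + "\n" for s in dataset.sample_ids))
    dataset.metadata.to_csv(paths["metadata"], sep="\t")
    return paths


# --------------------------------------------------------------------------
# gene sets (GMT)
# --------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered name -> gene list mapping.

    GMT dialect: one set per line, tab-separated; field 1 is the set name,
    field 2 a free description (may be empty), fields 3+ the genes.
    Duplicate genes within a set are dropped with a warning.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
            )
        name = fields[0]
        genes: list[str] = []
        seen: set[str] = set()
        dups = 0
        for g in fields[2:]:
            if not g:
                continue
            if g in seen:
                dups += 1
                continue
            seen.add(g)
            genes.append(g)
        if dups:
            log.warning("%s:%d: set %s had %d duplicate genes", path, lineno, name, dups)
        sets[name] = genes
    return sets


def write_gene_sets(
    sets: Mapping[str, Sequence[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_regulons(path: str | Path, source: str = "") -> RegulonSet:
    """Regulons from GMT (name = TF) or JSON ({tf, targets, source} records)."""
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
        return RegulonSet(
            [
                Regulon(r["tf"], frozenset(r["targets"]), r.get("source", source))
                for r in records
            ]
        )
    sets = read_gene_sets(path)
    return RegulonSet(
        [Regulon(tf, frozenset(genes), source) for tf, genes in sets.items()]
    )


def write_regulons(regulons: RegulonSet, path: str | Path) -> None:
    records = [
        {"tf": r.tf, "targets": sorted(r.targets), "source": r.source}
        for r in regulons
    ]
    Path(path).write_text(json.dumps(records, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# ortholog lift-over
# --------------------------------------------------------------------------

def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (source symbol, human symbol) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["src", "dst"], dtype=str)
    return dict(zip(df["src"], df["dst"]))


def apply_ortholog_map(
    dataset: ExpressionDataset, mapping: Mapping[str, str]
) -> ExpressionDataset:
    """Rename rows to human orthologs via an explicit symbol map.

    Rows mapping to the same human symbol are summed for raw counts and
    averaged otherwise; unmapped rows are dropped (count logged).  An empty
    intersection between dataset genes and the map is a hard error — it
    almost always means a species mix-up.
    """
    mapped = [g for g in dataset.gene_ids if g in mapping]
    if not mapped:
        raise ValidationError(
            f"{dataset.dataset_id}: no dataset gene appears in the ortholog map "
            "(species mix-up?)"
        )
    n_dropped = dataset.n_genes - len(mapped)
    if n_dropped:
        log.info(
            "%s: dropping %d genes absent from ortholog map",
            dataset.dataset_id,
            n_dropped,
        )
    # preserve first-appearance order of target symbols
    targets: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(dataset.gene_ids):
        h = mapping.get(g)
        if h is None:
            continue
        if h not in groups:
            groups[h] = []
            targets.append(h)
        groups[h].append(i)
    reduce = np.sum if dataset.unit == "raw_counts" else np.mean
    values = np.vstack(
        [reduce(dataset.values[groups[h], :], axis=0) for h in targets]
    )
    return ExpressionDataset(
        dataset_id=dataset.dataset_id,
        species="human",
        gene_ids=targets,
        sample_ids=dataset.sample_ids,
        values=values,
        unit=dataset.unit,
        metadata=dataset.metadata,
    )


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

def read_tpm_table(path: str | Path) -> pd.Series:
    """Recipient-cell expression: TSV with gene and tpm columns."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "tpm"} <= set(df.columns):
        raise FormatError(f"{path}: TPM table needs 'gene' and 'tpm' columns")
    return df.set_index("gene")["tpm"].astype(float)


def write_tpm_table(tpm: pd.Series, path: str | Path) -> None:
    tpm.rename("tpm").rename_axis("gene").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_motif_rankings(path: str | Path) -> pd.DataFrame:
    """Motif/TF genome-ranking table: rows TFs, columns genes, 1-based ranks."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_motif_rankings(rankings: pd.DataFrame, path: str | Path) -> None:
    rankings.to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
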