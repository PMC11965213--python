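"""Core in-memory containers shared by every pipeline stage.

The pipeline moves gene-by-sample expression matrices, transcription-factor
regulons (a TF with its positive target set), and per-sample activity scores
between stages.  Everything downstream — module detection, AUC activity,
marker selection, the candidate funnel — consumes these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

CELL_CLASSES = ("brain_ec", "other_ec", "other_brain_cell", "nonbrain_ec")
VASCULAR_BEDS = ("arterial", "capillary", "venous", "large", "na")
UNITS = ("raw_counts", "log_normalized", "tpm")


class FormatError(ValueError):
    """An on-disk file does not match its declared format."""


class ValidationError(ValueError):
    """An in-memory object violates a container invariant."""


@dataclass
class ExpressionDataset:
    """A gene x sample expression matrix with per-sample annotations.

    Parameters
    ----------
    dataset_id:
        Short identifier, unique within a cohort.
    species:
        ``"human"`` or ``"mouse"``; mouse datasets are lifted to human
        symbols before cross-dataset steps.
    gene_ids, sample_ids:
        Ordered, unique row / column labels.
    values:
        ``(n_genes, n_samples)`` array of non-negative expression values.
    unit:
        ``"raw_counts"`` (non-negative integers), ``"log_normalized"``
        or ``"tpm"``.
    metadata:
        DataFrame indexed by sample id with at least a ``cell_class``
        column; ``vascular_bed`` defaults to ``"na"`` and ``age_stage``
        to ``""`` when absent.
    """

    dataset_id: str
    species: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.species not in ("human", "mouse"):
            raise ValidationError(f"unknown species {self.species!r}")
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n_g, n_s = self.values.shape
        if len(self.gene_ids) != n_g:
            raise FormatError(
                f"{self.dataset_id}: {len(self.gene_ids)} gene labels for "
                f"{n_g} matrix rows"
            )
        if len(self.sample_ids) != n_s:
            raise FormatError(
                f"{self.dataset_id}: {len(self.sample_ids)} sample labels for "
                f"{n_s} matrix columns"
            )
        for name, labels in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(labels)) != len(labels):
                seen: set[str] = set()
                dups = sorted({x for x in labels if x in seen or seen.add(x)})
                raise ValidationError(
                    f"{self.dataset_id}: duplicate {name} labels: {dups[:10]}"
                )
        if np.any(self.values < 0):
            raise ValidationError(f"{self.dataset_id}: negative expression values")
        if self.unit == "raw_counts" and not np.allclose(
            self.values, np.round(self.values)
        ):
            raise ValidationError(f"{self.dataset_id}: raw counts must be integers")
        md = self.metadata
        if not isinstance(md, pd.DataFrame):
            raise ValidationError("metadata must be a DataFrame")
        missing = [s for s in self.sample_ids if s not in md.index]
        if missing:
            raise ValidationError(
                f"{self.dataset_id}: samples missing from metadata: {missing[:10]}"
            )
        md = md.loc[self.sample_ids].copy()
        if "cell_class" not in md.columns:
            raise ValidationError(f"{self.dataset_id}: metadata lacks cell_class")
        bad = sorted(set(md["cell_class"]) - set(CELL_CLASSES))
        if bad:
            raise ValidationError(f"{self.dataset_id}: unknown cell_class {bad}")
        if "vascular_bed" not in md.columns:
            md["vascular_bed"] = "na"
        md["vascular_bed"] = md["vascular_bed"].fillna("na")
        bad = sorted(set(md["vascular_bed"]) - set(VASCULAR_BEDS))
        if bad:
            raise ValidationError(f"{self.dataset_id}: unknown vascular_bed {bad}")
        if "age_stage" not in md.columns:
            md["age_stage"] = ""
        self.metadata = md

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Integer row positions of ``genes`` (all must be present)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([pos[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in {self.dataset_id}") from exc

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids whose metadata matches every ``column=value`` pair."""
        mask = np.ones(self.n_samples, dtype=bool)
        for col, val in conditions.items():
            mask &= (self.metadata[col] == val).to_numpy()
        return [s for s, keep in zip(self.sample_ids, mask) if keep]

    def subset(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ExpressionDataset":
        """New dataset restricted to the given genes and/or samples."""
        genes = list(genes) if genes is not None else self.gene_ids
        samples = list(samples) if samples is not None else self.sample_ids
        gi = self.gene_index(genes)
        si = {s: i for i, s in enumerate(self.sample_ids)}
        sj = np.array([si[s] for s in samples], dtype=int)
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            species=self.species,
            gene_ids=genes,
            sample_ids=samples,
            values=self.values[np.ix_(gi, sj)].copy(),
            unit=self.unit,
            metadata=self.metadata.loc[samples],
        )


@dataclass(frozen=True)
class Regulon:
    """A transcription factor with its inferred positive target genes."""

    tf: str
    targets: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError(f"regulon {self.tf}: empty target set")
        if self.tf in self.targets:
            raise ValidationError(f"regulon {self.tf}: TF contained in own targets")


@dataclass
class RegulonSet:
    """An ordered collection of regulons; (tf, source) pairs are unique."""

    entries: list[Regulon] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.tf, r.source) for r in self.entries]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, str]] = set()
            dups = sorted({k for k in keys if k in seen or seen.add(k)})
            raise ValidationError(f"duplicate (tf, source) pairs: {dups[:10]}")

    def __iter__(self) -> Iterator[Regulon]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def tfs(self) -> list[str]:
        return [r.tf for r in self.entries]

    def targets_of(self, tf: str) -> frozenset[str]:
        """Union of target sets over all sources for ``tf``."""
        hits = [r.targets for r in self.entries if r.tf == tf]
        if not hits:
            raise KeyError(f"no regulon for {tf}")
        return frozenset().union(*hits)


@dataclass
class RankingContext:
    """Per-sample gene rankings for AUC scoring.

    ``order[:, j]`` lists gene row indices of sample ``j`` from rank 1
    (highest expression, forward direction) downwards; a reversed context
    inverts that order so the AUC scores under-representation.
    """

    context_id: str
    dataset_id: str
    direction: str  # forward | reversed
    gene_ids: list[str]
    sample_ids: list[str]
    order: np.ndarray  # (n_genes, n_samples) int
    tie_seed: int

    @property
    def ranks(self) -> np.ndarray:
        """(n_genes, n_samples) 1-based rank of each gene per sample."""
        n_g, n_s = self.order.shape
        r = np.empty_like(self.order)
        cols = np.arange(n_s)
        r[self.order, cols] = np.arange(1, n_g + 1)[:, None]
        return r


@dataclass
class ActivityMatrix:
    """Regulon x sample AUC activity under one ranking context."""

    context_id: str
    regulon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_regulons, n_samples) in [0, 1]
    top_fraction: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regulon_ids), len(self.sample_ids)):
            raise ValidationError("activity matrix shape mismatch")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValidationError("AUC values outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.regulon_ids, columns=self.sample_ids
        )


@dataclass
class MarkerSet:
    """A criteria-defined brain-EC marker gene list with its predicate."""

    set_id: str
    genes: frozenset[str]
    criteria: dict

    def to_dict(self) -> dict:
        return {
            "set_id": self.set_id,
            "genes": sorted(self.genes),
            "criteria": self.criteria,
        }


@dataclass
class QCReport:
    """Per-filter bookkeeping for gene/cell quality control."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_removed: int, **params) -> None:
        self.steps.append(
            {
                "filter": name,
                "n_in": int(n_in),
                "n_removed": int(n_removed),
                "n_retained": int(n_in - n_removed),
                "params": params,
            }
        )

    def to_dict(self) -> dict:
        return {"steps": self.steps}
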