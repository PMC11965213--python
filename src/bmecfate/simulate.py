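"""Synthetic cohorts, motif rankings, and barcode screens with known truth.

The meta-cohort emulates the mixture of data modalities the funnel was
designed for: single-cell-like negative-binomial counts from brain tissue
(a brain-EC cluster among other brain cells), array-like log-normal
intensities from murine ECs (brain vs other organs) and from human
non-brain ECs, and a zonated brain-EC dataset with arterial / capillary /
venous / large labels.  A shared "brain-EC program" of marker genes is
elevated in brain ECs at controlled fold changes and capillary-biased in
the zonated data; planted master-regulator TFs carry regulons drawn from
that program, decoy TFs carry regulons active in non-brain ECs or
nowhere.  The barcode screen simulates a pooled lentiviral
TF-overexpression experiment at the UMI-count level: transduced cells
carry 1-2 TF barcodes, their targets shift by a multiplicative effect
size, and hit-TF cells concentrate in one cluster.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionDataset, Regulon, RegulonSet, ValidationError

PLANTED_TF_NAMES = (
    "ZIC3",
    "FOXF2",
    "FOXQ1",
    "TCF7",
    "KLF4",
    "PRDM5",
    "TFAP2A",
    "TFAP2C",
    "SPIB",
    "DLX2",
    "PAX5",
    "HNF4A",
)


def _mouse_symbol(human: str) -> str:
    return human.capitalize()


# --------------------------------------------------------------------------
# configs and truth containers
# --------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Knobs of the synthetic meta-cohort.

    Scale defaults to a desk-scale mirror of the published funnel:
    ~2,000 genes, ~1,200 samples over five datasets, 12 planted master
    regulators against 188 decoys.
    """

    n_genes: int = 2000
    planted_tf_names: tuple[str, ...] = PLANTED_TF_NAMES
    n_decoy_tfs: int = 188

    # brain-EC program: core markers pass the strict 4x criterion,
    # secondary markers the lenient 2x criterion
    n_core_markers: int = 60
    n_secondary_markers: int = 60
    core_fold_range: tuple[float, float] = (4.5, 8.0)
    secondary_fold_range: tuple[float, float] = (2.2, 4.0)
    sc_fold_range: tuple[float, float] = (6.0, 12.0)
    capillary_log2fc_range: tuple[float, float] = (1.5, 3.0)
    capillary_bias_fraction: float = 0.85

    # decoy biology
    nonbrain_program_size: int = 100
    nonbrain_fold_range: tuple[float, float] = (3.0, 8.0)

    # regulons
    regulon_size_range: tuple[int, int] = (35, 55)
    marker_overlap_fraction: float = 0.4
    n_background_targets: int = 3
    decoy_regulon_size_range: tuple[int, int] = (30, 60)

    # planted co-expression modules (murine array)
    n_modules: int = 5
    module_size: int = 35
    module_gene_cor: float = 0.8

    # dataset shapes: (dataset_id, kind, species, class composition)
    n_sc_human: dict = field(
        default_factory=lambda: {"brain_ec": 100, "other_brain_cell": 220}
    )
    n_sc_mouse: dict = field(
        default_factory=lambda: {"brain_ec": 90, "other_brain_cell": 190}
    )
    n_murine_array: dict = field(
        default_factory=lambda: {"brain_ec": 60, "other_ec": 90}
    )
    n_zonated: dict = field(
        default_factory=lambda: {
            "arterial": 70,
            "capillary": 120,
            "venous": 60,
            "large": 50,
        }
    )
    n_nonbrain_array: dict = field(default_factory=lambda: {"nonbrain_ec": 120})

    sc_depth_human: float = 2500.0
    sc_depth_mouse: float = 1500.0
    sc_mouse_gene_dropout: float = 0.15
    nb_dispersion: float = 2.0
    array_noise_sd: float = 0.35

    # recipient cells: planted TFs silent except ZIC3 (already expressed)
    recipient_zic3_tpm: float = 5.0

    def __post_init__(self) -> None:
        n_special = (
            self.n_core_markers
            + self.n_secondary_markers
            + self.nonbrain_program_size
            + self.n_modules * self.module_size
        )
        if n_special > self.n_genes:
            raise ValidationError(
                f"planted gene roles need {n_special} genes but n_genes={self.n_genes}"
            )
        if not (0 < self.marker_overlap_fraction <= 1):
            raise ValidationError("marker_overlap_fraction must be in (0, 1]")
        for lo, hi in (self.core_fold_range, self.secondary_fold_range):
            if lo <= 0:
                raise ValidationError("fold values must be > 0")


@dataclass
class CohortTruth:
    """Ground truth of a generated meta-cohort."""

    planted_tfs: list[str]
    decoy_tfs: list[str]
    regulons: RegulonSet
    marker_genes: dict  # gene -> planted murine brain-EC fold (> 1)
    sc_marker_folds: dict  # gene -> planted single-cell brain-EC fold
    zonation_effects: dict  # gene -> capillary-vs-large log2 fold change
    module_genes: dict  # module id -> gene list (murine array, human symbols)
    nonbrain_program: list[str]
    ortholog_map: dict  # mouse symbol -> human symbol
    recipient_tpm: pd.Series
    fetal_expression: dict  # TF -> bool annotation
    seed: int


@dataclass
class ScreenConfig:
    """Knobs of the synthetic barcoded TF-overexpression screen."""

    n_cells: int = 1500
    n_genes: int = 1500
    tf_names: tuple[str, ...] = PLANTED_TF_NAMES
    hit_tfs: tuple[str, ...] = ("ZIC3", "TFAP2C", "TFAP2A", "DLX2")
    transduction_rate: float = 0.7
    doublet_genotype_rate: float = 0.15
    ambient_rate: float = 0.005
    effect_size: float = 3.0
    n_clusters: int = 4
    hit_cluster: int = 0
    hit_enrichment: float = 3.0
    genotype_umi_mean: float = 60.0
    barcode_length: int = 20
    depth: float = 2500.0
    nb_dispersion: float = 2.0
    targets_per_tf: int = 30
    cluster_program_size: int = 40
    cluster_program_fold: float = 4.0
    max_multiplicity: int = 2

    def __post_init__(self) -> None:
        for name in ("transduction_rate", "doublet_genotype_rate", "ambient_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be > 0")


@dataclass
class ScreenTruth:
    """Ground truth of a generated barcode screen."""

    barcodes: dict  # TF -> 20-base sequence
    genotypes: list  # per cell: frozenset of TF names (0-2)
    cluster_labels: np.ndarray  # intended population per cell
    tf_targets: dict  # TF -> target gene list
    effect_size: float
    enriched_cluster_map: dict  # TF -> cluster index (hit TFs only)
    seed: int


# --------------------------------------------------------------------------
# meta-cohort
# --------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture."""
    shape = theta
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam).astype(float)


def _array_values(
    rng: np.random.Generator, mean: np.ndarray, noise_sd: float
) -> np.ndarray:
    """Array-like positive intensities: log-normal noise around the mean."""
    return mean * rng.lognormal(0.0, noise_sd, size=mean.shape)


def generate_meta_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[list[ExpressionDataset], CohortTruth]:
    """Generate the five-dataset meta-cohort with planted ground truth.

    Returns datasets in a fixed order: human brain single-cell counts,
    mouse brain single-cell counts, murine EC array, zonated murine
    brain-EC counts, and human non-brain EC array.  Mouse datasets use
    mouse-cased symbols; ``truth.ortholog_map`` lifts them back.
    """
    config = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(8)]
    r_roles, r_reg, r_sc_h, r_sc_m, r_arr, r_zon, r_nb, r_misc = rngs

    genes = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    ortholog_map = {_mouse_symbol(g): g for g in genes}

    # --- assign gene roles ---
    pool = r_roles.permutation(config.n_genes)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = [genes[i] for i in pool[cursor : cursor + n]]
        cursor += n
        return out

    core_markers = take(config.n_core_markers)
    secondary_markers = take(config.n_secondary_markers)
    nonbrain_program = take(config.nonbrain_program_size)
    module_genes = {
        f"module_{m + 1}": take(config.module_size) for m in range(config.n_modules)
    }

    core_folds = dict(
        zip(core_markers, r_roles.uniform(*config.core_fold_range, len(core_markers)))
    )
    secondary_folds = dict(
        zip(
            secondary_markers,
            r_roles.uniform(*config.secondary_fold_range, len(secondary_markers)),
        )
    )
    marker_folds = {**core_folds, **secondary_folds}
    program = core_markers + secondary_markers
    sc_folds = dict(
        zip(program, r_roles.uniform(*config.sc_fold_range, len(program)))
    )
    nonbrain_folds = dict(
        zip(
            nonbrain_program,
            r_roles.uniform(*config.nonbrain_fold_range, len(nonbrain_program)),
        )
    )
    n_biased = int(round(config.capillary_bias_fraction * len(program)))
    biased = list(r_roles.choice(program, size=n_biased, replace=False))
    zonation_effects = dict(
        zip(biased, r_roles.uniform(*config.capillary_log2fc_range, n_biased))
    )

    # --- regulons ---
    planted = list(config.planted_tf_names)
    decoys = [f"TF{i:03d}" for i in range(1, config.n_decoy_tfs + 1)]
    background = [g for g in genes if g not in set(program) | set(nonbrain_program)]
    entries = []
    for tf in planted:
        size = int(r_reg.integers(*config.regulon_size_range))
        n_marker = max(1, int(round(config.marker_overlap_fraction * size)))
        n_marker = min(n_marker, len(core_markers))
        n_secondary = max(0, size - n_marker - config.n_background_targets)
        n_secondary = min(n_secondary, len(secondary_markers))
        targets = (
            list(r_reg.choice(core_markers, n_marker, replace=False))
            + list(r_reg.choice(secondary_markers, n_secondary, replace=False))
            + list(r_reg.choice(background, config.n_background_targets, replace=False))
        )
        entries.append(Regulon(tf, frozenset(targets), source="synthetic"))
    half = len(decoys) // 2
    for i, tf in enumerate(decoys):
        size = int(r_reg.integers(*config.decoy_regulon_size_range))
        if i < half:  # active in non-brain ECs
            n_prog = int(round(0.8 * size))
            n_prog = min(n_prog, len(nonbrain_program))
            targets = list(
                r_reg.choice(nonbrain_program, n_prog, replace=False)
            ) + list(r_reg.choice(background, size - n_prog, replace=False))
        else:  # active nowhere
            targets = list(r_reg.choice(background, size, replace=False))
        entries.append(Regulon(tf, frozenset(targets), source="synthetic"))
    regulons = RegulonSet(entries)

    gene_pos = {g: i for i, g in enumerate(genes)}
    base_mean = r_misc.lognormal(1.0, 1.0, config.n_genes)

    def fold_vector(folds: dict) -> np.ndarray:
        v = np.ones(config.n_genes)
        for g, f in folds.items():
            v[gene_pos[g]] = f
        return v

    brain_array_fold = fold_vector(marker_folds)
    sc_brain_fold = fold_vector(sc_folds)
    nonbrain_fold = fold_vector(nonbrain_folds)
    cap_boost = fold_vector({g: 2.0**lfc for g, lfc in zonation_effects.items()})

    datasets: list[ExpressionDataset] = []

    def make_sc(
        dataset_id: str,
        species: str,
        composition: dict,
        depth: float,
        rng: np.random.Generator,
        gene_dropout: float = 0.0,
    ) -> ExpressionDataset:
        keep = np.ones(config.n_genes, dtype=bool)
        if gene_dropout > 0:
            keep = rng.random(config.n_genes) >= gene_dropout
        baseline_mass = base_mean.sum()
        cols, classes = [], []
        for cls, n in composition.items():
            fold = sc_brain_fold if cls == "brain_ec" else np.ones(config.n_genes)
            lam = base_mean * fold / baseline_mass * depth
            cell_depth = rng.lognormal(0.0, 0.25, n)
            mean = lam[:, None] * cell_depth[None, :]
            cols.append(_nb_counts(rng, mean, config.nb_dispersion))
            classes += [cls] * n
        values = np.hstack(cols)[keep, :]
        ids = [g if species == "human" else _mouse_symbol(g) for g, k in zip(genes, keep) if k]
        sample_ids = [f"{dataset_id}_c{j:04d}" for j in range(values.shape[1])]
        metadata = pd.DataFrame(
            {"cell_class": classes, "vascular_bed": "na", "age_stage": "adult"},
            index=sample_ids,
        )
        return ExpressionDataset(
            dataset_id, species, ids, sample_ids, values, "raw_counts", metadata
        )

    datasets.append(
        make_sc("sc_human", "human", config.n_sc_human, config.sc_depth_human, r_sc_h)
    )
    datasets.append(
        make_sc(
            "sc_mouse",
            "mouse",
            config.n_sc_mouse,
            config.sc_depth_mouse,
            r_sc_m,
            gene_dropout=config.sc_mouse_gene_dropout,
        )
    )

    # murine EC array: brain vs other-organ ECs, with 5 planted
    # co-expression modules driven by per-sample latent factors
    comp = config.n_murine_array
    n_arr = sum(comp.values())
    classes = sum(([cls] * n for cls, n in comp.items()), [])
    fold_m = np.ones((config.n_genes, n_arr))
    is_brain = np.array([c == "brain_ec" for c in classes])
    fold_m[:, is_brain] *= brain_array_fold[:, None]
    other_cols = ~is_brain
    fold_m[:, other_cols] *= nonbrain_fold[:, None]
    mean = base_mean[:, None] * fold_m
    values = _array_values(r_arr, mean, config.array_noise_sd)
    # module latent factors: correlated multiplicative activity
    rho = config.module_gene_cor
    for mod, mgenes in module_genes.items():
        factor = r_arr.normal(0.0, 1.0, n_arr)
        idx = [gene_pos[g] for g in mgenes]
        loading = np.sqrt(rho)
        noise = r_arr.normal(0.0, 1.0, (len(idx), n_arr))
        signal = loading * factor[None, :] + np.sqrt(1 - rho) * noise
        values[idx, :] *= np.exp(0.6 * signal)
    arr_samples = [f"murine_ec_array_s{j:03d}" for j in range(n_arr)]
    datasets.append(
        ExpressionDataset(
            "murine_ec_array",
            "mouse",
            [_mouse_symbol(g) for g in genes],
            arr_samples,
            values,
            "tpm",
            pd.DataFrame(
                {"cell_class": classes, "vascular_bed": "na", "age_stage": "adult"},
                index=arr_samples,
            ),
        )
    )

    # zonated murine brain-EC counts
    comp = config.n_zonated
    bed_scale = {"arterial": 0.6, "capillary": 1.0, "venous": 0.3, "large": 0.0}
    cols, beds = [], []
    baseline_mass = base_mean.sum()
    for bed, n in comp.items():
        boost = cap_boost ** bed_scale[bed]
        lam = base_mean * brain_array_fold * boost
        lam = lam / baseline_mass * config.sc_depth_human
        cell_depth = r_zon.lognormal(0.0, 0.25, n)
        cols.append(_nb_counts(r_zon, lam[:, None] * cell_depth[None, :], config.nb_dispersion))
        beds += [bed] * n
    values = np.hstack(cols)
    zon_samples = [f"zonated_ec_c{j:04d}" for j in range(values.shape[1])]
    datasets.append(
        ExpressionDataset(
            "zonated_ec",
            "mouse",
            [_mouse_symbol(g) for g in genes],
            zon_samples,
            values,
            "raw_counts",
            pd.DataFrame(
                {"cell_class": "brain_ec", "vascular_bed": beds, "age_stage": "adult"},
                index=zon_samples,
            ),
        )
    )

    # human non-brain EC array
    comp = config.n_nonbrain_array
    n_nb = sum(comp.values())
    fold_nb = nonbrain_fold.copy()
    # the brain program is essentially silent in peripheral ECs
    for g in program:
        fold_nb[gene_pos[g]] = 0.25
    mean = (base_mean * fold_nb)[:, None] * np.ones(n_nb)[None, :]
    values = _array_values(r_nb, mean, config.array_noise_sd)
    nb_samples = [f"nonbrain_ec_array_s{j:03d}" for j in range(n_nb)]
    datasets.append(
        ExpressionDataset(
            "nonbrain_ec_array",
            "human",
            list(genes),
            nb_samples,
            values,
            "tpm",
            pd.DataFrame(
                {"cell_class": "nonbrain_ec", "vascular_bed": "na", "age_stage": "adult"},
                index=nb_samples,
            ),
        )
    )

    # recipient-cell TPM: planted TFs silent except ZIC3; decoys at
    # typical low-lognormal levels
    tpm = {}
    for tf in planted:
        tpm[tf] = (
            config.recipient_zic3_tpm
            if tf == "ZIC3"
            else float(r_misc.uniform(0.0, 1.5))
        )
    for tf in decoys:
        tpm[tf] = float(r_misc.lognormal(0.0, 1.2))
    recipient_tpm = pd.Series(tpm, name="tpm").rename_axis("gene")

    fetal_expression = {tf: True for tf in planted}

    truth = CohortTruth(
        planted_tfs=planted,
        decoy_tfs=decoys,
        regulons=regulons,
        marker_genes=marker_folds,
        sc_marker_folds=sc_folds,
        zonation_effects=zonation_effects,
        module_genes=module_genes,
        nonbrain_program=nonbrain_program,
        ortholog_map=ortholog_map,
        recipient_tpm=recipient_tpm,
        fetal_expression=fetal_expression,
        seed=seed,
    )
    return datasets, truth


# --------------------------------------------------------------------------
# motif rankings
# --------------------------------------------------------------------------

def generate_motif_rankings(
    truth: CohortTruth,
    n_positions: int | None = None,
    seed: int = 0,
    noise: float = 0.25,
) -> pd.DataFrame:
    """TF -> full gene ranking table emulating a motif database.

    Each TF's regulon targets are pushed toward the top of its genome
    ranking; ``noise`` is the standard deviation of a Gaussian
    perturbation on the target indicator, so ``noise=0`` places the
    targets exactly in the top ``|targets|`` ranks.  Other genes are
    shuffled.  Rows are TFs, columns genes, entries 1-based ranks.
    """
    universe = sorted(
        {g for reg in truth.regulons for g in reg.targets}
        | set(truth.marker_genes)
        | set(truth.nonbrain_program)
    )
    # extend to the full gene complement seen in the cohort
    all_genes = sorted(set(truth.ortholog_map.values()))
    universe = all_genes if all_genes else universe
    n = len(universe)
    if n_positions is not None and n_positions < n:
        raise ValidationError(f"n_positions={n_positions} < gene universe of {n}")
    rng = np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(universe)}
    rows = {}
    for reg in truth.regulons:
        key = rng.random(n)  # random tie-break / shuffle
        score = key.copy()
        idx = [pos[g] for g in reg.targets if g in pos]
        score[idx] += 10.0
        if noise > 0:
            score += rng.normal(0.0, noise * 10.0, n)
        order = np.argsort(-score, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        rows[reg.tf] = ranks
    return pd.DataFrame.from_dict(rows, orient="index", columns=universe)


# --------------------------------------------------------------------------
# barcode screen
# --------------------------------------------------------------------------

def _unique_barcodes(
    rng: np.random.Generator, names: tuple[str, ...], length: int
) -> dict:
    seqs: set[str] = set()
    out = {}
    for name in names:
        while True:
            seq = "".join(rng.choice(list("ACGT"), length))
            if seq not in seqs:
                seqs.add(seq)
                out[name] = seq
                break
    return out


def generate_barcode_screen(
    config: ScreenConfig | None = None,
    seed: int = 0,
    with_expression: bool = True,
) -> tuple[ExpressionDataset | None, pd.DataFrame, ScreenTruth]:
    """Simulate the pooled barcoded TF-overexpression screen.

    Returns ``(counts, barcode_umis, truth)``: a cell x gene count
    dataset (``None`` when ``with_expression=False``), a cell x barcode
    UMI table, and the ground truth.  Transduced cells receive high UMI
    counts for their genotype barcodes plus low ambient counts for the
    others; their target genes are scaled by ``effect_size``; cells
    carrying a hit TF concentrate in the hit cluster.  An effect size of
    1 is a biological null: targets shift nowhere and genotypes sort
    into clusters at random.
    """
    config = config or ScreenConfig()
    ss = np.random.SeedSequence(seed)
    r_bc, r_geno, r_clust, r_umi, r_expr = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    tf_names = tuple(config.tf_names)
    barcodes = _unique_barcodes(r_bc, tf_names, config.barcode_length)

    # genotypes
    genotypes: list[frozenset[str]] = []
    for _ in range(config.n_cells):
        if r_geno.random() >= config.transduction_rate:
            genotypes.append(frozenset())
            continue
        k = 2 if r_geno.random() < config.doublet_genotype_rate else 1
        k = min(k, config.max_multiplicity)
        genotypes.append(frozenset(r_geno.choice(tf_names, k, replace=False)))

    # cluster assignment; hit-TF cells pile into the hit cluster only
    # when the TF actually does something (effect_size > 1).
    # hit_enrichment multiplies the hit-cluster occupancy probability
    # itself (a planted e-fold over-representation), so it must stay
    # below the cluster count.
    enrichment = config.hit_enrichment if config.effect_size != 1.0 else 1.0
    if enrichment >= config.n_clusters:
        raise ValidationError(
            f"hit_enrichment={enrichment} must be < n_clusters={config.n_clusters}"
        )
    k = config.n_clusters
    p_hit = np.full(k, (1 - enrichment / k) / (k - 1))
    p_hit[config.hit_cluster] = enrichment / k
    p_base = np.full(k, 1 / k)
    labels = np.empty(config.n_cells, dtype=int)
    hit_set = set(config.hit_tfs)
    for i, g in enumerate(genotypes):
        p = p_hit if g & hit_set else p_base
        labels[i] = r_clust.choice(k, p=p)

    # barcode UMI table
    umis = np.zeros((config.n_cells, len(tf_names)), dtype=int)
    bc_index = {tf: j for j, tf in enumerate(tf_names)}
    ambient_mean = config.ambient_rate * config.genotype_umi_mean
    if ambient_mean > 0:
        umis += r_umi.poisson(ambient_mean, size=umis.shape)
    for i, g in enumerate(genotypes):
        for tf in sorted(g):  # fixed order: set iteration is hash-dependent
            umis[i, bc_index[tf]] += r_umi.poisson(config.genotype_umi_mean)
    cell_ids = [f"cell{i:04d}" for i in range(config.n_cells)]
    barcode_umis = pd.DataFrame(umis, index=cell_ids, columns=list(tf_names))

    # targets per TF, drawn from the gene complement
    genes = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    tf_targets = {
        tf: sorted(r_expr.choice(genes, config.targets_per_tf, replace=False))
        for tf in tf_names
    }

    counts_dataset = None
    if with_expression:
        gene_pos = {g: i for i, g in enumerate(genes)}
        base_mean = r_expr.lognormal(1.0, 1.0, config.n_genes)
        # cluster-specific programs
        program_boost = np.ones((config.n_genes, config.n_clusters))
        free = [g for g in genes if all(g not in t for t in tf_targets.values())]
        free_idx = r_expr.permutation([gene_pos[g] for g in free])
        for c in range(config.n_clusters):
            idx = free_idx[
                c * config.cluster_program_size : (c + 1) * config.cluster_program_size
            ]
            program_boost[idx, c] = config.cluster_program_fold
        mass = base_mean.sum()
        values = np.empty((config.n_genes, config.n_cells))
        cell_depth = r_expr.lognormal(0.0, 0.25, config.n_cells)
        for i in range(config.n_cells):
            lam = base_mean * program_boost[:, labels[i]]
            for tf in sorted(genotypes[i]):
                idx = [gene_pos[g] for g in tf_targets[tf]]
                lam = lam.copy()
                lam[idx] *= config.effect_size
            lam = lam / mass * config.depth * cell_depth[i]
            values[:, i] = _nb_counts(r_expr, lam, config.nb_dispersion)
        metadata = pd.DataFrame(
            {
                "cell_class": "other_ec",
                "vascular_bed": "na",
                "age_stage": "in_vitro",
            },
            index=cell_ids,
        )
        counts_dataset = ExpressionDataset(
            "tf_screen", "human", genes, cell_ids, values, "raw_counts", metadata
        )

    truth = ScreenTruth(
        barcodes=barcodes,
        genotypes=genotypes,
        cluster_labels=labels,
        tf_targets=tf_targets,
        effect_size=config.effect_size,
        enriched_cluster_map={tf: config.hit_cluster for tf in config.hit_tfs}
        if enrichment > 1
        else {},
        seed=seed,
    )
    return counts_dataset, barcode_umis, truth


def simulate_null_screen_labels(
    n_cells: int = 500,
    n_clusters: int = 5,
    genotype_freqs: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[frozenset[str]]]:
    """Cluster labels and genotypes with no association (a null screen).

    Used for type-I calibration of the proportion permutation test:
    cluster membership and genotype are drawn independently.
    """
    genotype_freqs = genotype_freqs or {"TFa": 0.15, "TFb": 0.10, "TFc": 0.08}
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_clusters, size=n_cells)
    genotypes = []
    names = list(genotype_freqs)
    freqs = np.array([genotype_freqs[g] for g in names])
    for _ in range(n_cells):
        carried = frozenset(
            g for g, f in zip(names, freqs) if rng.random() < f
        )
        genotypes.append(carried)
    return labels, genotypes
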