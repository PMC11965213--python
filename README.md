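# bmecfate

Prioritizing transcription factors that fate stem-cell-derived
endothelial cells toward brain microvascular endothelial cells (BMECs),
and analysing the pooled barcoded TF-overexpression single-cell screen
that validates them.

## The problem

Brain microvascular endothelial cells form the blood–brain barrier.
Endothelial cells differentiated from pluripotent stem cells stay
immature: they lack the tight-junction and transporter program of real
BMECs. One route to fix this is to find the handful of *master
regulator* TFs whose overexpression pushes immature ECs toward a
brain-EC identity. This package implements, as a tested pipeline, the
computational side of that search:

1. **Regulon activity.** Each candidate TF comes with a regulon — the
   gene set it positively regulates. Activity per sample is the area
   under the recovery curve (AUC) of the regulon's targets within the
   top 5% of that sample's expression ranking, normalized to [0, 1].
   Activity is computed under four contexts: brain-EC single-cell data
   (forward), murine EC arrays (forward; brain/other relative
   activity), non-brain EC arrays (*reversed* ranking, scoring
   depletion), and a zonated brain-EC dataset (forward, plus the mutual
   information MI(AUC; vascular bed)).
2. **Co-expression modules.** Signed WGCNA-style networks (soft power
   from the scale-free fit, topological overlap, average linkage,
   eigengene merging at dissimilarity 0.3, minimum size 30), with
   motif-recovery NES (z-score of recovery AUC across TFs; NES > 3
   flags candidate regulators of a module).
3. **Marker sets.** Four criteria-defined brain-EC marker gene sets
   (murine 4×/2× fold changes, a 90th-percentile cap on non-brain
   expression at 7/7.5-fold, single-cell 4× enrichment, capillary
   logFC > 0).
4. **The funnel.** Sensitivity (fraction of a marker set inside the
   regulon) > 0.1, specificity (brain-marker share of the regulon's
   marker hits) > 0.8, MI score > −1.3 (on log10(MI + 1e−6)), recipient
   TPM < 2 (with a ZIC3 force-include), capillary median AUC > 0.08 and
   capillary MI > 0.05 — every per-TF verdict stored in a replayable
   record.
5. **The screen.** Genotype deconvolution from 20-bp barcode UMIs
   (UMI floor + dominance rule), PCA → SNN → Leiden clustering
   (15 of 50 PCs, resolution 0.8), Wilcoxon cluster markers, and a
   genotype-proportion permutation test per (cluster, genotype) pair
   (log2FD threshold log2(1.275), bootstrap CI + permutation p).

Because the original cohorts are not publicly deposited, a first-class
synthetic-data module generates the whole study design with known
ground truth — planted regulons, marker fold changes, zonation effects,
modules, and a barcoded transduction experiment — so every stage is
verifiable end to end. See `docs/methods.md` for the full model
description.

## Worked example

```python
from bmecfate.config import RunConfig
from bmecfate.pipeline import run_funnel
from bmecfate.simulate import generate_meta_cohort, generate_motif_rankings

datasets, truth = generate_meta_cohort(seed=1)
rankings = generate_motif_rankings(truth, seed=2)
result = run_funnel(
    datasets, truth.regulons, rankings, truth.recipient_tpm,
    RunConfig(seed=1), ortholog_map=truth.ortholog_map,
    fetal_expression=truth.fetal_expression,
)
print(result.stage_counts)
print(result.shortlist)
```

prints

```
{'input': 200, 'initial_screen': 89, 'sens_spec_mi': 12,
 'recipient_expression': 12, 'capillary_context': 12, 'final': 12}
['ZIC3', 'FOXF2', 'DLX2', 'PAX5', 'SPIB', 'PRDM5', 'TFAP2C', 'KLF4',
 'FOXQ1', 'TFAP2A', 'HNF4A', 'TCF7']
```

— of 200 candidate TFs (12 planted brain-EC master regulators + 188
decoys), the initial activity screen keeps 89, the
sensitivity/specificity/MI filter cuts to exactly the 12 planted TFs,
and all 12 survive the recipient-expression and capillary filters
(ZIC3 via the force-include: it is expressed at TPM 5 in the synthetic
recipient cells). `result.records['ZIC3']` holds every score and
threshold behind that decision.

The same pipeline is scriptable from the shell:

```bash
bmecfate --seed 1 --out-dir out all          # simulate -> funnel -> screen
bmecfate --seed 1 --out-dir out/funnel funnel --cohort-dir out/cohort
```

The numbered drivers under `analysis/` run each stage with a narrative
summary and write small result tables under `results/`
(`01_simulate.py`, `02_regulon_activity.py`, `03_modules_and_markers.py`,
`04_funnel.py`, `05_barcode_screen.py`).

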