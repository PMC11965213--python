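"""Generate the synthetic meta-cohort and barcode screen; summarize them.

The cohort mirrors the study design the funnel needs: two brain
single-cell datasets (human and mouse), a murine EC array contrast
(brain vs other organs), a zonated brain-EC dataset, and a human
non-brain EC array, with 12 planted master-regulator TFs against 188
decoys.  Writes small composition tables under results/; the matrices
themselves are regenerated on demand from (config, seed).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from bmecfate.simulate import (  # noqa: E402
    CohortConfig,
    ScreenConfig,
    generate_barcode_screen,
    generate_meta_cohort,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    datasets, truth = generate_meta_cohort(CohortConfig(), seed=SEED)
    rows = []
    for d in datasets:
        classes = d.metadata["cell_class"].value_counts().to_dict()
        rows.append(
            {
                "dataset_id": d.dataset_id,
                "species": d.species,
                "unit": d.unit,
                "n_genes": d.n_genes,
                "n_samples": d.n_samples,
                "composition": ";".join(f"{k}={v}" for k, v in sorted(classes.items())),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "cohort_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(
        f"\nplanted TFs: {len(truth.planted_tfs)}, decoys: {len(truth.decoy_tfs)}, "
        f"marker genes: {len(truth.marker_genes)} "
        f"({sum(f >= 4 for f in truth.marker_genes.values())} at >= 4-fold)"
    )
    _, umis, struth = generate_barcode_screen(ScreenConfig(), seed=SEED + 2)
    n_transduced = sum(bool(g) for g in struth.genotypes)
    print(
        f"screen: {len(struth.genotypes)} cells, {n_transduced} transduced, "
        f"{sum(len(g) > 1 for g in struth.genotypes)} double-barcode, "
        f"hit TFs {sorted(struth.enriched_cluster_map)} -> cluster "
        f"{set(struth.enriched_cluster_map.values())}"
    )


if __name__ == "__main__":
    main()
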