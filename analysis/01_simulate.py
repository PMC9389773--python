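#!/usr/bin/env python
"""Generate the study's synthetic paired Dx/Re dataset.

Emulates the structure of a paired diagnosis/relapse AML SORT-seq study:
UMI counts with ERCC spike-ins and mitochondrial genes, three expression
clusters with planted markers, a relapse-specific 30 Mb gain (1.5x) and
30 Mb loss (0.5x), a copy-neutral LOH arm, LSC-like G1 cells, and an
exome-like variant panel whose VAFs shift between timepoints.

Writes the dataset under scratch/data/ (large, regenerable) and a summary
table under results/.
"""

from pathlib import Path

import pandas as pd

from relapse_scope import io as rsio
from relapse_scope.simulate import (
    SimConfig,
    simulate_allele_counts,
    simulate_counts,
    simulate_variants,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"
SEED = 20220819


def main() -> None:
    config = SimConfig(seed=SEED)
    adata, truth = simulate_counts(config)
    variants = simulate_variants(config)
    allele_counts, snps = simulate_allele_counts(config, truth)

    rsio.write_counts_dir(adata, DATA / "counts")
    rsio.write_tsv(variants, DATA / "variants.tsv")
    rsio.write_tsv(allele_counts, DATA / "allele_counts.tsv")
    rsio.write_tsv(snps, DATA / "snps.tsv")
    rsio.write_tsv(truth.events, DATA / "truth_events.tsv")

    summary = pd.DataFrame(
        [
            {"quantity": "cells (Dx + Re)", "value": adata.n_obs},
            {"quantity": "features (genes + mito + ERCC)", "value": adata.n_vars},
            {"quantity": "planted clean cells", "value": int(truth.cells["clean"].sum())},
            {"quantity": "planted low-quality cells", "value": int((~truth.cells["clean"]).sum())},
            {"quantity": "planted LSC-like cells", "value": int(truth.cells["lsc"].sum())},
            {"quantity": "CNV events", "value": len(truth.events)},
            {"quantity": "variant panel size", "value": len(variants)},
            {"quantity": "heterozygous SNPs", "value": len(snps)},
        ]
    )
    rsio.write_tsv(summary, RESULTS / "01_dataset_summary.tsv")
    print(summary.to_string(index=False))
    print(f"\ndataset written to {DATA}")


if __name__ == "__main__":
    main()
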