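#!/usr/bin/env python
"""Category-enrichment statistics on the simulated compartment proteome:
volcano classification, per-category fold-change distributions with
Kruskal-Wallis and pairwise Welch tests, and detected-in-all-replicates
presence calls split by release site.

Writes results/protein_volcano_summary.tsv, results/protein_category_stats.tsv
and results/protein_detection.tsv.
"""

from pathlib import Path

import pandas as pd

from prernaseq import io
from prernaseq.diffstats import (
    category_stats,
    detection_by_class,
    detection_summary,
    volcano_classify,
)
from prernaseq.simulate import simulate_protein_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = simulate_protein_table(seed=SEED)
    volcano = volcano_classify(table, fdr=0.05, lfc=0.5)

    vsum = volcano["class"].value_counts().rename_axis("class").to_frame("proteins")
    io.write_tsv(vsum, RESULTS / "protein_volcano_summary.tsv", {"seed": SEED}, index=True)
    print(vsum.to_string())

    cats = table.protein_meta["category"]
    pairs = [("RP", "initiation"), ("RP", "elongation"), ("RP", "RBP"), ("RP", "RBF")]
    stats_ = category_stats(volcano["log2FC"], cats, pairs)
    pairwise = stats_["pairwise"].copy()
    pairwise["p"] = pairwise["p"].map("{:.3g}".format)
    io.write_tsv(pairwise, RESULTS / "protein_category_stats.tsv",
                 {"seed": SEED, "kw_p": stats_["kw_p"]})
    print(f"\nKruskal-Wallis across categories: p = {stats_['kw_p']:.3g}")
    print(pairwise.to_string(index=False))

    det = detection_summary(table, min_replicates=5)
    by_site = detection_by_class(det, table.protein_meta, "release_site")
    io.write_tsv(by_site, RESULTS / "protein_detection.tsv", {"seed": SEED}, index=True)
    print("\nRBFs detected in 5/5 replicates, by release site:")
    print(by_site.to_string())
    print("-> ribosomal proteins and nucleus-released biogenesis factors are "
          "de-enriched in neurites; initiation/elongation factors are evenly "
          "distributed, as planted.")


if __name__ == "__main__":
    main()
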