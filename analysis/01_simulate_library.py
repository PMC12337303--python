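#!/usr/bin/env python
"""Build the synthetic study inputs: the rDNA locus fixture, the five-species
pre-5.8S mix, and the effect of gel size selection on it.

Writes results/species_mix.tsv (pre- and post-selection abundances) and
prints what the library looks like before any analysis touches it.
"""

from pathlib import Path

import pandas as pd

from prernaseq import io
from prernaseq.simulate import (
    SimConfig,
    default_species,
    make_locus,
    simulate_reads,
    size_select,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    locus = make_locus(SEED)
    print(f"locus: {len(locus.seq)} nt, mature 5.8S at "
          f"[{locus.mature_start}, {locus.mature_end}) ({locus.mature_len} nt)")

    before = default_species()
    after = size_select(before, (160, 400), "smeared", sigma=8.0)
    post = {s.label: s.relative_abundance for s in after}
    mix = pd.DataFrame(
        {
            "species": [s.label for s in before],
            "length_nt": [s.length_nt for s in before],
            "abundance_pre_gel": [s.relative_abundance for s in before],
            "abundance_post_gel": [round(post.get(s.label, 0.0), 4) for s in before],
        }
    )
    io.write_tsv(mix, RESULTS / "species_mix.tsv", {"seed": SEED})
    print(mix.to_string(index=False))
    print("-> the 157-nt mature 5.8S sits below the 160-nt gel cut, so the "
          "smeared selection de-enriches it from ~97% to "
          f"{post['mature_5.8S']:.0%} of molecules, enriching the pre-species.")

    cfg = SimConfig(n_reads=20_000, error_rate=0.01, seed=SEED)
    reads, truth = simulate_reads(locus, after, cfg)
    n_mol = truth.molecule_id.nunique()
    print(f"simulated {len(reads)} reads from {n_mol} molecules "
          f"({len(reads)/n_mol:.2f} reads/molecule); "
          f"all reads carry the 5+8+ATG header ({reads[0].seq[:16]}...)")


if __name__ == "__main__":
    main()
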