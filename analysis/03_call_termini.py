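#!/usr/bin/env python
"""Deduplicate molecules, build the 3'-terminus profile downstream of the
mature 5.8S, and call cleavage sites at 50,000-read depth.

Writes results/terminus_profile.tsv and results/species_calls.tsv. The check
that matters: the called pre-5.8S species lengths must equal the lengths the
generator planted (159, 179, 187, 272, 278 nt).
"""

from pathlib import Path

import pandas as pd

from prernaseq import io
from prernaseq.pipeline import recover_species
from prernaseq.termini import umi_collision_estimate

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    res = recover_species(seed=SEED, n_reads=50_000, error_rate=0.01)
    locus, profile = res["locus"], res["profile"]

    prof = pd.DataFrame(
        {
            "position": sorted(profile.counts),
            "offset_from_mature_start": [p - locus.mature_start for p in sorted(profile.counts)],
            "count": [profile.counts[p] for p in sorted(profile.counts)],
        }
    )
    io.write_tsv(prof, RESULTS / "terminus_profile.tsv", {"seed": SEED})

    calls = pd.DataFrame(
        [
            {"terminus": c.terminus, "length_nt": c.length_nt, "support": c.support,
             "fraction": round(c.fraction, 5), "class": c.kind}
            for c in res["calls"]
        ]
    )
    io.write_tsv(calls, RESULTS / "species_calls.tsv", {"seed": SEED})
    print(calls.to_string(index=False))
    n_mature = int(calls.loc[calls["class"] == "mature", "support"].sum())
    print(f"\n{profile.total} deduplicated molecules in the 415-nt window; "
          f"the mature terminus holds {n_mature / profile.total:.0%} of them "
          f"(expected UMI-collision undercount at that position: "
          f"~{umi_collision_estimate(n_mature):.0f} molecules).")
    print(f"called pre-5.8S lengths: {res['pre_lengths']}")
    print(f"planted pre-5.8S lengths: {res['true_pre_lengths']}")
    print("-> exact recovery" if res["pre_lengths"] == res["true_pre_lengths"]
          else "-> MISMATCH against ground truth")


if __name__ == "__main__":
    main()
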