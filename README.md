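# prernaseq

Analysis pipeline for 3'-end sequencing of pre-rRNA processing
intermediates, driven by a synthetic-data generator with known ground truth.

Cytosolic precursors of the 5.8S rRNA (pre-5.8S) differ from the mature
molecule only by short 3' extensions into the internal transcribed spacer 2
(ITS2). Mapping them takes single-nucleotide resolution of RNA 3' termini:
a 3'-biased library whose Read1 is `5-bp index + 8-bp UMI + ATG anchor +
cDNA payload`, where the payload is the reverse complement of the RNA's
3'-terminal ~80 nt. This package implements the full computational chain
for such libraries and validates every step by parameter recovery on
simulated data:

- **simulate** — rDNA locus fixture, species mixes with configurable 3'
  termini, gel size selection (hard or Gaussian-smeared 160–400 nt),
  structured reads with substitution and modification-mismatch errors, and
  two-compartment RNA count / protein intensity tables with planted effects;
- **preprocess** — Read1 parsing (index discarded, UMI recorded, anchor
  validated), adapter and oligo-dT trimming, quality gating;
- **align** — seed-and-extend local alignment (exact 15-mer seeds, banded
  Smith–Waterman extension, affine gaps) and 3'-terminus assignment from the
  alignment end;
- **termini** — UMI deduplication to molecules, terminus pileups over the
  415-nt window downstream of the mature 5.8S start, cleavage-site /
  species-length calling;
- **diffstats** — median-of-ratios normalization, Welch-t/Benjamini–Hochberg
  differential testing between compartments (somata+neurites vs neurites
  only), volcano classification, Kruskal–Wallis category statistics,
  detected-in-all-replicates presence calls;
- **conservation** — Needleman–Wunsch and progressive 3-way alignment,
  per-column conservation classes, identity in flanks around cleavage sites.

The model details, defaults, and their rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
their tables to `results/`. The core result is species recovery
(`analysis/03_call_termini.py`): simulate 50,000 reads at 1% error from a
fixture containing the mature 5.8S plus five pre-5.8S species, then
preprocess, align, deduplicate and call:

```
 terminus  length_nt  support  fraction  class
      256        157    24397   0.89317 mature
      258        159      245   0.00897    pre
      278        179      560   0.02050    pre
      286        187      539   0.01973    pre
      371        272      567   0.02076    pre
      377        278      525   0.01922    pre

called pre-5.8S lengths: [159, 179, 187, 272, 278]
planted pre-5.8S lengths: [159, 179, 187, 272, 278]
-> exact recovery
```

89% of the 27,315 deduplicated molecules end exactly at the mature 3'
terminus (position 256; length 157 nt), and the five planted precursor
termini — including the 159-nt species only 2 nt downstream of the towering
mature peak — are recovered with no false or missed calls. The same
pipeline is available as a library call (`prernaseq.pipeline.recover_species`),
as `prernaseq run-all` (full two-compartment design with differential
testing), and as individual CLI stages (`simulate-reads`, `preprocess`,
`align`, `call-termini`, `diffabund`, `category-stats`, `conserve`).

The other drivers show the compartment statistics on simulated tables:
nuclear-control RNAs are recovered as significantly neurite-depleted
(20/20, all negative) while pre-5.8S features show compartment parity
(`04_differential_rna.py`), ribosomal proteins and nucleus-released
biogenesis factors come out de-enriched in neurites (Kruskal–Wallis
p = 2.8e-18, `05_protein_categories.py`), and called cleavage sites show
high 5'-flank but low 3'-flank identity across synthetic homologs
(`06_conservation.py`).

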