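# Methods

## The problem this package models

Late 5.8S rRNA maturation proceeds through cytosolic precursors (pre-5.8S)
that carry short 3' extensions into the internal transcribed spacer 2 (ITS2)
and differ from the mature molecule by only a few dozen nucleotides at the 3'
end. Resolving them requires single-nucleotide mapping of RNA 3' termini.
The package implements, over fully synthetic data with known ground truth,
the computational side of a 3'-biased sequencing assay built for that
purpose: structured-read parsing, UMI-based molecule counting, seeded local
alignment to an rDNA locus, 3'-terminus pileups with cleavage-site calling,
compartment differential statistics for a two-compartment neuronal design
(somata+neurites vs neurites only), and conservation profiling around called
sites.

## Synthetic data generator

The generator is first-class, tested code: every analysis in the package is
validated as parameter recovery against the ground truth it emits.

**Locus.** A seeded uniform-random nucleotide string with an annotated
mature-5.8S interval: 100 nt of upstream flank, a 157-nt mature 5.8S
(the rat 5.8S length), 500 nt of downstream spacer standing in for ITS2.
The terminus analysis window spans 415 nt downstream of the first mature
nucleotide. A random locus, rather than the real repeat, keeps 15-mers
unique with high probability and makes specificity measurable; nothing in
the pipeline depends on real rDNA content.

**Species mix.** All 5.8S-derived species share the mature 5' end; a species
is defined by its 3'-terminus offset. The default fixture is the mature
157-nt molecule at 97% of the pool plus five pre-5.8S species of 159, 179,
187, 272 and 278 nt at 0.6% each — a pool dominated by the mature molecule,
as in a real cytosolic RNA preparation.

**Gel size selection.** The assay enriches precursors by cutting a
160–400-nt gel band. `hard` mode keeps species inside the window and
renormalizes. The default `smeared` mode multiplies each abundance by
`Phi((L-160)/sigma) * Phi((400-L)/sigma)` with sigma = 8 nt, modelling the
soft edges of a manual band cut; the approximate band boundaries warrant
soft edges rather than a step. Under the defaults the mature species (157
nt, just below the cut) is retained at ~35% while the precursors pass
almost fully, leaving the mature molecule at ~93% of sampled molecules —
still dominant, but with precursors lifted to callable abundance.

**Reads.** Each raw read is `5-bp sample index + 8-bp UMI + ATG + payload`,
the payload being the reverse complement of the molecule's 3'-terminal 80
nt. Molecules are drawn per species abundance; each emits `1 +
Poisson(0.5)` reads with a shared UMI (amplification multiplicity), giving
~1.5 reads/molecule. Substitution errors occur at 1% per base by default;
positions listed as modified mismatch at 30% instead, modelling
modification-induced misincorporation rather than RT stops — the chemistry
being emulated reads through modifications, so the aligner, not a
truncation model, has to absorb them. The sample index is a fixed
placeholder: demultiplexing happens upstream of this package and the parser
discards the field. Ground truth (species, terminus, molecule id, UMI) is
emitted per read. Not modelled: ligation bias, PCR chimeras, quality-score
degradation (qualities are constant), charging-state prefixes.

**Count and protein tables.** RNA counts are negative-binomial
(`var = mu + dispersion * mu^2`, dispersion 0.05) over 500 features —
the scale of a size-selected small-RNA library, not of whole-transcriptome
RNA-seq — with five replicates per compartment. Twenty features are nuclear
controls (snoRNA/scaRNA stand-ins) with a true neurite log2 fold change of
−3; five are pre-5.8S features with true fold change 0 (compartment
parity); the rest are null background. Background abundances are lognormal
(9 ± 1.5 log2); marker classes use a tighter 9 ± 0.5 spread, because purity
markers are chosen in practice for being abundant and robustly detected in
every replicate — a marker drawn at the detection floor would be a useless
control, and the generator should not produce one. Protein tables are
normal log2 intensities (noise sd 0.5) over the study's curated categories
(RP 47, initiation 29, elongation 8, RBP 16, RBF 36, the RBFs split 9
nucleus-released / 27 cytosol-released), with true neurite shifts encoding
the qualitative published pattern: RP and nucleus-released RBFs strongly
de-enriched (−1.5), initiation/elongation flat, RBP and cytosol-released
RBFs mildly negative (−0.3).

## Read preprocessing

Parsing is positional: index discarded, UMI recorded, anchor compared with a
configurable mismatch tolerance (default 0 — the anchor is a synthesis
artifact, and a mismatch suggests a bad ligation; the tolerance the original
assay used is not documented, so strictness is the conservative default).
UMIs containing N are rejected outright, since an ambiguous tag corrupts
molecule counting. Payload cleaning removes 3' adapter read-through by the
longest suffix/prefix overlap (≥ 6 nt, ≤ 10% mismatches), trims a trailing
oligo-dT homopolymer of ≥ 8 nt (the second-strand priming artifact), and
rejects reads below Q20 mean quality or 20 nt. All rejections are counted
per reason, never raised; accepted + rejected always equals input.

## Alignment and terminus assignment

Payloads are reverse-complemented onto the sense strand, so the rightmost
aligned query base is the RNA 3' terminus. Alignment is seed-and-extend:
exact 15-mer seeds (modifications should be detectable within a 15-base
window, so a clean seed survives elsewhere in an 80-nt read even over
modified positions), each distinct seed diagonal extended by Smith–Waterman
over a ±8-nt band. Scoring: match +1, mismatch −1, a length-k gap costs
3 + k (open charged once, every gapped base pays 1); gap penalties are not
dictated by the emulated assay and are configurable — indels in rRNA reads
are rare, so they matter little. Records below score 20 are dropped.

Tie-breaking is toward **maximal extension** (largest query end, then
largest reference end), then fewest mismatches, then smallest start. This
is deliberate: when the second-to-last base of a read is miscalled, the
full extension and a 2-nt-clipped alignment tie in score, and preferring
the fewer-mismatch (clipped) variant would systematically shift ~1% of
termini 2 nt shortward — enough to plant a false cleavage site two
nucleotides upstream of every real one. Since the entire method reads the
terminus off the alignment end, extension wins ties.

The terminus is `ref_end − 1`. A read whose terminus-proximal end is
clipped by more than 2 nt has an untrustworthy 3' coordinate and is
discarded (a terminal miscall clips at most the bases it corrupts; larger
clips mean the read end did not come from this locus position). Equal-score
hits at distant loci flag the record ambiguous; ambiguous records are
excluded from molecule counting.

## Molecule counting and species calling

Molecules are distinct (terminus, UMI) pairs — exact-match collapsing, no
1-mismatch clustering, because with an 8-nt tag space (65,536) the dominant
risk at a single hot position is tag *collision*, not tag sequencing error;
the expected birthday-collision undercount is reported instead
(`umi_collision_estimate`). At the default depth the mature peak holds
~24,000 observed molecules, an undercount of ~15% — irrelevant to species
calling, which needs relative, not absolute, support.

The terminus profile counts molecule 3' ends over
`[mature_start, mature_start + 415)`. Species calling takes positions with
support ≥ 10 molecules and ≥ 0.2% of in-window molecules (the assay's
"significant number of reads" is not quantified; 0.2% sits well below the
weakest fixture species at ~0.7% and well above the error-satellite floor
at ~0.1% of the mature peak), requires them to be local maxima within ±3
nt, and merges calls closer than 3 nt to the higher-count one (ties to the
smaller coordinate). Calls strictly within 2 nt of the mature 3' terminus
are classed `mature`, the rest `pre`; species length is
`terminus − mature_start + 1`.

Peak competition runs separately inside the mature zone and the pre zone.
This is load-bearing: the closest precursor terminus (159 nt) lies only 2
nt downstream of the mature terminus, inside the merge window of a peak two
orders of magnitude larger — one global local-max rule could never call it,
while satellites one nucleotide short of the mature peak (terminal-miscall
artifacts at ~1% of the parent's support) must still merge into it. Zone
separation keeps both properties; merge windows above 5 nt would start
merging the 272/278-nt pair and are not supported by the defaults.

## Differential statistics

Size factors are median-of-ratios over features with nonzero counts in all
samples (median taken on the ratio scale). The RNA differential test is a
two-sided Welch t on `log2(normalized count + 0.5)` with Benjamini–Hochberg
adjustment — a deliberately simple stand-in for a negative-binomial GLM,
validated by calibration (null FDR at the nominal level) and power
(complete recovery of the planted −3 nuclear depletion with no false calls
among pre-5.8S features) rather than by parity with any particular GLM
implementation; the claims it must support depend on direction and FDR
control, not on shrinkage machinery. The 0.5 pseudo-count keeps zero counts
finite without dominating small means. Sign convention throughout:
`log2FC = neurite − somata+neurites`, positive meaning neurite-enriched.

Protein volcano classification applies the same Welch/BH machinery with a
joint gate (adjusted p < 0.05 *and* |log2FC| > 0.5); proteins quantified in
fewer than two replicates of a group are reported `not_tested`, and
zero-variance rows get p = 1 rather than an exception. Category statistics
are Kruskal–Wallis across categories plus pairwise Welch t tests, reported
unadjusted (matching how such figure panels are conventionally annotated)
with an optional BH flag. Presence calls require quantification in all
five replicates of a compartment. Fold changes for proteins missing in any
tested sample are excluded from the tested set and reported separately —
how the original analysis handled missing intensities is not documented,
and exclusion is the assumption-free choice.

## Conservation profiling

Pairwise global alignment is Needleman–Wunsch with match +1, mismatch −1,
linear gap −2; traceback prefers aligned pairs on ties, keeping gap counts
minimal among co-optimal paths and the output deterministic. Three
sequences are aligned progressively — closest pair first, the third against
the pair's majority-base consensus, consensus gaps propagated into both
rows — which is adequate for a handful of closely related rDNA homologs and
avoids pulling in a full MSA engine for a three-row problem. Columns are
`identical` (all non-gap bases equal), `mismatch`, or flagged `allgap`;
identity around an anchor is the fraction of identical columns in the
50-nt flank 5' and 3' of the anchor's alignment column (reference-row gap
columns are skipped during projection). The 5'-vs-3' asymmetry around
cleavage sites is reported descriptively; no significance test is attached
to it.

## Problem sizes and numerical choices

The packaged recovery run is 50,000 reads per sample (~27,000 deduplicated
in-window molecules), which places the weakest fixture species at ~245
molecules of support — an order of magnitude above the calling floor — and
completes in a few seconds per seed; the recovery suite repeats it over 20
seeds. Statistical calibration runs use 1,000 features × 20 seeds (null
FDR), 100 seeded runs (omnibus-test uniformity), and 1,000 random instances
(alignment oracle equality). All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; derived seeds are spawned via
`SeedSequence` and kept below 2^31. Dynamic-programming kernels are
numba-jitted and integer-scored, so scores are exact and platform-stable.

## Known limitations

- The error model is substitution-only; indel-rich chemistry would stress
  the banded extension differently (band half-width 8 bounds the shift).
- Exact-match UMI collapsing undercounts hot positions by the birthday
  effect; the package reports the expected undercount but does not correct
  it.
- The Welch-on-log stand-in is less powerful than a dispersion-sharing GLM
  at low counts and small n; with five replicates it resolves |log2FC| = 3
  reliably, not subtle effects.
- The synthetic locus is random sequence: results say nothing about
  alignability of the real, repeat-embedded, GC-skewed rDNA.
- Progressive alignment is adequate for three close homologs; it is not a
  general MSA.
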