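"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: an artificial rDNA
locus with an annotated mature-5.8S interval, 3'-end sequencing reads with the
library's Read1 architecture (5-bp sample index, 8-bp UMI, ATG anchor, cDNA
payload), gel size selection over the RNA species mix, compartment RNA count
tables with negative-binomial noise, and compartment protein log-intensity
tables with category structure.

Every generator is deterministic under its seed and emits ground truth next to
the data so downstream modules can be validated by parameter recovery rather
than by eyeballing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .diffstats import CountTable, ProteinTable

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

#: mature 5.8S length used by the default fixture (rat 5.8S is 157 nt)
DEFAULT_MATURE_LEN = 157
#: 3' extensions of the pre-5.8S species into ITS2, as total species lengths
#: measured from the first nucleotide of the mature 5.8S
DEFAULT_PRE_LENGTHS = (159, 179, 187, 272, 278)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# locus and species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusReference:
    """An rDNA locus with the mature-5.8S interval annotated.

    Coordinates are 0-based, half-open. ``its2_window`` is the number of
    nucleotides downstream of ``mature_start`` covered by the terminus
    analysis window (the mature 5.8S plus the 5' part of ITS2).
    """

    seq: str
    mature_start: int
    mature_end: int
    its2_window: int = 415

    def __post_init__(self) -> None:
        if not (0 <= self.mature_start < self.mature_end <= len(self.seq)):
            raise ValueError("mature interval out of bounds")
        if self.mature_start + self.its2_window > len(self.seq):
            raise ValueError("its2_window extends past the locus")
        if set(self.seq) - set(_BASES):
            raise ValueError("locus sequence must be over {A,C,G,T}")

    @property
    def mature_len(self) -> int:
        return self.mature_end - self.mature_start

    @property
    def mature_terminus(self) -> int:
        """0-based coordinate of the last nucleotide of the mature 5.8S."""
        return self.mature_end - 1


@dataclass(frozen=True)
class SpeciesSpec:
    """One RNA species: where its 3' end sits and how abundant it is.

    ``terminus_offset`` is the 0-based offset of the species' last nucleotide
    from ``mature_start``, so the species length is ``terminus_offset + 1``
    (all 5.8S-derived species share the mature 5' end).
    """

    label: str
    terminus_offset: int
    relative_abundance: float

    def __post_init__(self) -> None:
        if self.terminus_offset < 0:
            raise ValueError("terminus_offset must be >= 0")
        if not (0.0 < self.relative_abundance <= 1.0):
            raise ValueError("relative_abundance must be in (0, 1]")

    @property
    def length_nt(self) -> int:
        return self.terminus_offset + 1


def validate_species(species: list[SpeciesSpec], locus: LocusReference | None = None) -> None:
    if not species:
        raise ValueError("species list is empty")
    total = sum(s.relative_abundance for s in species)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"species abundances sum to {total}, expected 1")
    if locus is not None:
        for s in species:
            if s.terminus_offset >= len(locus.seq) - locus.mature_start:
                raise ValueError(f"species {s.label}: terminus outside locus")


def make_locus(
    seed: int,
    upstream_len: int = 100,
    mature_len: int = DEFAULT_MATURE_LEN,
    downstream_len: int = 500,
    its2_window: int = 415,
) -> LocusReference:
    """Seeded uniform-random locus with the mature interval placed after
    ``upstream_len`` nt of flanking sequence."""
    for name, n in (("upstream_len", upstream_len), ("mature_len", mature_len),
                    ("downstream_len", downstream_len)):
        if n <= 0:
            raise ValueError(f"{name} must be positive")
    if downstream_len < its2_window - mature_len:
        raise ValueError("downstream_len too short for the analysis window")
    rng = np.random.default_rng(seed)
    n = upstream_len + mature_len + downstream_len
    seq = "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])
    return LocusReference(
        seq=seq,
        mature_start=upstream_len,
        mature_end=upstream_len + mature_len,
        its2_window=its2_window,
    )


def default_species(mature_len: int = DEFAULT_MATURE_LEN) -> list[SpeciesSpec]:
    """Pre-gel species mix: the mature 5.8S dominates the cytosolic pool, with
    five minor pre-5.8S species extending into ITS2."""
    pre_abundance = 0.006
    species = [SpeciesSpec("mature_5.8S", mature_len - 1, 1.0 - pre_abundance * len(DEFAULT_PRE_LENGTHS))]
    for length in DEFAULT_PRE_LENGTHS:
        species.append(SpeciesSpec(f"pre_5.8S_{length}nt", length - 1, pre_abundance))
    return species


# ---------------------------------------------------------------------------
# gel size selection
# ---------------------------------------------------------------------------

def size_select(
    species: list[SpeciesSpec],
    window: tuple[float, float] = (160.0, 400.0),
    mode: str = "hard",
    sigma: float = 8.0,
) -> list[SpeciesSpec]:
    """Apply gel size selection to a species mix and renormalize.

    ``hard`` keeps species whose length lies in [min, max]; ``smeared``
    multiplies each abundance by a Gaussian-CDF retention factor
    ``Phi((L - min)/sigma) * Phi((max - L)/sigma)``, modelling the soft
    boundaries of a band cut from a gel.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("size window min must be < max")
    if mode == "hard":
        weights = [1.0 if lo <= s.length_nt <= hi else 0.0 for s in species]
    elif mode == "smeared":
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        weights = [
            float(norm.cdf((s.length_nt - lo) / sigma) * norm.cdf((hi - s.length_nt) / sigma))
            for s in species
        ]
    else:
        raise ValueError(f"unknown size-selection mode {mode!r}")
    kept = [(s, s.relative_abundance * w) for s, w in zip(species, weights) if w > 0.0]
    total = sum(a for _, a in kept)
    if not kept or total <= 0.0:
        raise ValueError("no species in the size-selection window")
    return [replace(s, relative_abundance=a / total) for s, a in kept]


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of the read simulator.

    ``error_rate`` is the per-base substitution probability; positions listed
    in ``mod_positions`` (locus coordinates) instead mismatch at ``mod_rate``,
    modelling modification-induced misincorporation by the RT. ``duplication``
    is the mean number of extra reads per molecule (UMI multiplicity).
    """

    n_reads: int
    read_len: int = 80
    error_rate: float = 0.01
    mod_positions: frozenset[int] = frozenset()
    mod_rate: float = 0.30
    seed: int = 0
    size_window: tuple[float, float] = (160.0, 400.0)
    size_mode: str = "smeared"
    size_sigma: float = 8.0
    duplication: float = 0.5
    sample_index: str = "ACGTA"

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0.0 <= self.mod_rate < 1.0):
            raise ValueError("mod_rate must be in [0, 1)")
        if self.size_window[0] >= self.size_window[1]:
            raise ValueError("size window min must be < max")
        if len(self.sample_index) != 5:
            raise ValueError("sample_index must be 5 nt")


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    seq: str
    qual: str


INDEX_LEN = 5
UMI_LEN = 8
ANCHOR = "ATG"


def simulate_reads(
    locus: LocusReference,
    species: list[SpeciesSpec],
    cfg: SimConfig,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Simulate Read1 records covering RNA 3' ends, with ground truth.

    Each raw read is ``index(5) + UMI(8) + "ATG" + payload`` where the payload
    is the reverse complement of the last ``read_len`` nt of the molecule
    (truncated at the shared 5' end for species shorter than ``read_len``).
    Molecules are drawn per species abundance; each molecule may emit several
    reads (same UMI), modelling amplification multiplicity.

    Returns the reads and a ground-truth table with one row per read:
    ``read_id, molecule_id, species, terminus, umi``.
    """
    validate_species(species, locus)
    if cfg.read_len < 15:
        import warnings
        warnings.warn("read_len < 15: downstream seeded alignment will find no seeds")
    rng = np.random.default_rng(cfg.seed)

    # reads per molecule: 1 + Poisson(duplication), truncated to exactly n_reads
    mult = 1 + rng.poisson(cfg.duplication, size=cfg.n_reads)
    n_mol = int(np.searchsorted(np.cumsum(mult), cfg.n_reads) + 1)
    mult = mult[:n_mol]
    mult[-1] -= int(np.sum(mult) - cfg.n_reads)

    abundances = np.array([s.relative_abundance for s in species])
    mol_species = rng.choice(len(species), size=n_mol, p=abundances / abundances.sum())
    umi_codes = rng.integers(0, 4, size=(n_mol, UMI_LEN))
    umis = ["".join(_BASES[c] for c in row) for row in umi_codes]

    # per-species payload template and per-base error probability
    templates: list[np.ndarray] = []
    probs: list[np.ndarray] = []
    for s in species:
        t = locus.mature_start + s.terminus_offset
        if t >= len(locus.seq):
            raise ValueError(f"species {s.label}: terminus outside locus")
        length = min(cfg.read_len, s.length_nt)
        window = locus.seq[t - length + 1 : t + 1]
        payload = revcomp(window)
        codes = np.frombuffer(payload.encode(), dtype=np.uint8)
        templates.append(_encode(codes))
        # payload base i comes from locus position t - i
        p = np.full(length, cfg.error_rate)
        for i in range(length):
            if (t - i) in cfg.mod_positions:
                p[i] = cfg.mod_rate
        probs.append(p)

    reads: list[FastqRead] = []
    truth_rows: list[tuple] = []
    read_no = 0
    for mol_id in range(n_mol):
        si = int(mol_species[mol_id])
        s = species[si]
        t = locus.mature_start + s.terminus_offset
        tmpl, p = templates[si], probs[si]
        for _ in range(int(mult[mol_id])):
            codes = tmpl.copy()
            hit = rng.random(len(codes)) < p
            if hit.any():
                # substitute with one of the three other bases
                shift = rng.integers(1, 4, size=int(hit.sum()))
                codes[hit] = (codes[hit] + shift) % 4
            payload = _decode(codes)
            read_id = f"read{read_no:07d}"
            raw = cfg.sample_index + umis[mol_id] + ANCHOR + payload
            reads.append(FastqRead(read_id, raw, "F" * len(raw)))
            truth_rows.append((read_id, mol_id, s.label, t, umis[mol_id]))
            read_no += 1

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "molecule_id", "species", "terminus", "umi"]
    )
    return reads, truth


_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i
_ENC[ord("N")] = 4
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _encode(ascii_codes: np.ndarray) -> np.ndarray:
    return _ENC[ascii_codes]


def _decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode()


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0..T=3, N/other=4)."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# compartment count table (RNA)
# ---------------------------------------------------------------------------

GROUP_SOMA = "somata_neurites"
GROUP_NEURITE = "neurite"


def simulate_count_table(
    n_features: int = 500,
    n_nuclear: int = 20,
    n_pre: int = 5,
    replicates: int = 5,
    nuclear_lfc: float = -3.0,
    dispersion: float = 0.05,
    effects: np.ndarray | None = None,
    mean_log2: float = 9.0,
    sd_log2: float = 1.5,
    marker_sd_log2: float = 0.5,
    seed: int = 0,
) -> CountTable:
    """Negative-binomial count table for the two-compartment design.

    Features are classed ``background`` / ``nuclear_control`` / ``pre_5.8S``.
    Nuclear controls (snoRNA/scaRNA stand-ins) are depleted in the neurite
    compartment by ``nuclear_lfc`` on the log2 scale; pre-5.8S features have
    zero true fold change, mirroring the compartment parity of the cytosolic
    precursors. Marker-class features (controls and pre-5.8S) are drawn with
    the tighter ``marker_sd_log2`` abundance spread: purity markers are
    chosen in practice because they are abundant and robustly detected in
    every replicate. An explicit per-feature ``effects`` vector overrides
    the class-based true fold changes. True effects are stored in
    ``feature_meta["true_log2fc"]``.
    """
    if replicates < 2:
        raise ValueError("at least 2 replicates per group are required")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if n_nuclear + n_pre > n_features:
        raise ValueError("class counts exceed n_features")
    rng = np.random.default_rng(seed)

    classes = np.array(
        ["nuclear_control"] * n_nuclear + ["pre_5.8S"] * n_pre
        + ["background"] * (n_features - n_nuclear - n_pre)
    )
    if effects is None:
        effects = np.where(classes == "nuclear_control", nuclear_lfc, 0.0)
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (n_features,):
        raise ValueError("effects must have one entry per feature")

    sd_per_feature = np.where(classes == "background", sd_log2, marker_sd_log2)
    base = 2.0 ** rng.normal(mean_log2, sd_per_feature)
    group_mu = {GROUP_SOMA: base, GROUP_NEURITE: base * 2.0 ** effects}
    n_nb = 1.0 / dispersion  # NB: var = mu + dispersion * mu^2

    cols, names, meta_rows = [], [], []
    for group in (GROUP_SOMA, GROUP_NEURITE):
        mu = group_mu[group]
        for rep in range(1, replicates + 1):
            p = n_nb / (n_nb + mu)
            cols.append(rng.negative_binomial(n_nb, p))
            names.append(f"{group}_r{rep}")
            meta_rows.append((group, rep))

    counts = pd.DataFrame(
        np.column_stack(cols), columns=names,
        index=[f"feat{i:05d}" for i in range(n_features)],
    )
    sample_meta = pd.DataFrame(meta_rows, columns=["group", "replicate"], index=names)
    feature_meta = pd.DataFrame(
        {"feature_class": classes, "true_log2fc": effects}, index=counts.index
    )
    return CountTable(counts=counts, sample_meta=sample_meta, feature_meta=feature_meta)


# ---------------------------------------------------------------------------
# compartment protein table (log intensities)
# ---------------------------------------------------------------------------

def default_protein_design(seed: int = 0) -> pd.DataFrame:
    """Per-protein design table for the compartment proteomics simulation.

    Category sizes follow the study's curated translation-related gene list
    (RP 47, initiation 29, elongation 8, RBP 16, RBF 36; RBFs split 9
    nucleus-released / 27 cytosol-released). True neurite-vs-soma shifts
    encode the qualitative pattern: ribosomal proteins and nucleus-released
    biogenesis factors de-enriched in neurites, initiation/elongation factors
    evenly distributed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    layout = [
        ("RP", 47, -1.5, None),
        ("initiation", 29, 0.0, None),
        ("elongation", 8, 0.0, None),
        ("RBP", 16, -0.3, None),
        ("RBF", 9, -1.5, "nucleus"),
        ("RBF", 27, -0.3, "cytosol"),
    ]
    i = 0
    for cat, n, shift, release in layout:
        for _ in range(n):
            interaction = "stable" if (release != "cytosol" or rng.random() < 0.8) else "transient"
            rows.append((
                f"prot{i:04d}", cat, shift, release,
                interaction if cat == "RBF" else None,
                bool(rng.random() < 0.2),
            ))
            i += 1
    return pd.DataFrame(
        rows,
        columns=["protein", "category", "true_shift", "release_site", "interaction", "moonlighting"],
    ).set_index("protein")


def simulate_protein_table(
    design: pd.DataFrame | None = None,
    replicates: int = 5,
    noise_sd: float = 0.5,
    base_mean: float = 25.0,
    base_sd: float = 2.0,
    missing_mask: pd.DataFrame | None = None,
    seed: int = 0,
) -> ProteinTable:
    """Protein log2-intensity table for the two-compartment design.

    ``design`` rows define category metadata and the true neurite shift (see
    :func:`default_protein_design`). ``missing_mask`` (proteins x samples,
    True = missing) plants a known missingness pattern for detection calls.
    """
    if replicates < 2:
        raise ValueError("at least 2 replicates per group are required")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if design is None:
        design = default_protein_design(seed)
    rng = np.random.default_rng(seed)

    n = len(design)
    base = rng.normal(base_mean, base_sd, size=n)
    shifts = design["true_shift"].to_numpy(dtype=float)

    cols, names, meta_rows = [], [], []
    for group in (GROUP_SOMA, GROUP_NEURITE):
        mu = base + (shifts if group == GROUP_NEURITE else 0.0)
        for rep in range(1, replicates + 1):
            cols.append(mu + rng.normal(0.0, noise_sd, size=n))
            names.append(f"{group}_r{rep}")
            meta_rows.append((group, rep))

    intensities = pd.DataFrame(np.column_stack(cols), columns=names, index=design.index)
    if missing_mask is not None:
        intensities = intensities.mask(missing_mask.reindex_like(intensities).fillna(False))
    sample_meta = pd.DataFrame(meta_rows, columns=["group", "replicate"], index=names)
    return ProteinTable(
        intensities=intensities, sample_meta=sample_meta, protein_meta=design.copy()
    )


# ---------------------------------------------------------------------------
# synthetic homologs for the conservation analysis
# ---------------------------------------------------------------------------

def simulate_homolog(
    locus: LocusReference,
    div_conserved: float = 0.02,
    div_spacer: float = 0.30,
    indel_rate: float = 0.01,
    max_indel: int = 3,
    seed: int = 0,
) -> str:
    """A synthetic diverged homolog of the locus.

    The mature interval diverges at ``div_conserved`` per base; flanking and
    spacer (ITS2) sequence at ``div_spacer``, with short indels at
    ``indel_rate`` per base outside the mature interval. This emulates the
    cross-species pattern of rDNA: conserved mature rRNA, divergent spacers.
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for pos, base in enumerate(locus.seq):
        conserved = locus.mature_start <= pos < locus.mature_end
        div = div_conserved if conserved else div_spacer
        if not conserved and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append("".join(_BASES[c] for c in rng.integers(0, 4, rng.integers(1, max_indel + 1))))
        if rng.random() < div:
            out.append(_BASES[(_BASES.index(base) + int(rng.integers(1, 4))) % 4])
        else:
            out.append(base)
    return "".join(out)
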