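"""End-to-end orchestration: simulate -> preprocess -> align -> dedup ->
call termini -> differential test.

``recover_species`` is the single-sample parameter-recovery pipeline used to
check that the five packaged pre-5.8S termini are recovered from raw
simulated reads. ``run_all`` runs the full two-compartment design (five
replicates per compartment), merges per-sample species counts into a count
table and tests compartment differences.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignParams, LocusIndex, align_reads
from .diffstats import GROUP_NEURITE, GROUP_SOMA, CountTable, diff_test
from .preprocess import preprocess_reads
from .simulate import (
    DEFAULT_PRE_LENGTHS,
    LocusReference,
    SimConfig,
    default_species,
    make_locus,
    simulate_reads,
    size_select,
)
from .termini import (
    SpeciesCall,
    call_species,
    dedup_umis,
    terminus_profile,
    umi_collision_estimate,
)
from . import io

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "align", "dedup", "profile", "count")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters with their defaults.

    The defaults are the packaged study conditions: a 757-nt locus with a
    157-nt mature 5.8S after 100 nt of flank, the five-species pre-5.8S
    fixture, ~80-nt reads at 1% substitution error, smeared 160-400-nt gel
    selection, and five replicates per compartment.
    """

    seed: int = 0
    replicates: int = 5
    n_reads: int = 50_000
    read_len: int = 80
    error_rate: float = 0.01
    duplication: float = 0.5
    upstream_len: int = 100
    mature_len: int = 157
    downstream_len: int = 500
    its2_window: int = 415
    size_min: float = 160.0
    size_max: float = 400.0
    size_mode: str = "smeared"
    size_sigma: float = 8.0
    seed_len: int = 15
    min_score: int = 20
    max_terminus_clip: int = 2
    min_support: int = 10
    min_fraction: float = 0.002
    merge_window: int = 3
    mature_exclusion: int = 2
    alpha: float = 0.05
    write_fastq: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            raw = data[f.name]
            default = getattr(cls, f.name)
            if isinstance(default, bool):
                coerced[f.name] = str(raw).lower() in ("1", "true", "yes")
            else:
                coerced[f.name] = type(default)(raw)
        return cls(**coerced)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2^31) from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _run_sample(
    locus: LocusReference,
    species,
    cfg: PipelineConfig,
    sample_seed: int,
    index: LocusIndex,
):
    """Simulate one sample's reads and carry them to a molecule table."""
    sim_cfg = SimConfig(
        n_reads=cfg.n_reads,
        read_len=cfg.read_len,
        error_rate=cfg.error_rate,
        seed=sample_seed,
        size_window=(cfg.size_min, cfg.size_max),
        size_mode=cfg.size_mode,
        size_sigma=cfg.size_sigma,
        duplication=cfg.duplication,
    )
    reads, truth = simulate_reads(locus, species, sim_cfg)
    accepted, pp_counts = preprocess_reads((r.read_id, r.seq, r.qual) for r in reads)
    params = AlignParams(seed_len=cfg.seed_len, min_score=cfg.min_score)
    records, al_counts = align_reads(accepted, index, params, cfg.max_terminus_clip)
    molecules, dd_counts = dedup_umis(records)
    profile = terminus_profile(molecules, locus, cfg.its2_window)
    counters = {
        "reads_in": pp_counts["input"],
        "reads_accepted": pp_counts["accepted"],
        "reads_aligned": al_counts["aligned"],
        "molecules": int(dd_counts.get("molecules", 0)),
        "in_window": profile.total,
    }
    return reads, truth, molecules, profile, counters


def recover_species(
    seed: int,
    n_reads: int = 50_000,
    error_rate: float = 0.01,
    config: PipelineConfig | None = None,
) -> dict:
    """Single-sample parameter recovery of the packaged pre-5.8S termini.

    Simulates ``n_reads`` reads from the five-species fixture (locus and read
    noise both derived from ``seed``), runs the full pipeline, and returns
    the species calls together with the fixture's ground truth lengths.
    """
    cfg = config or PipelineConfig()
    cfg = dataclasses.replace(cfg, seed=seed, n_reads=n_reads, error_rate=error_rate)
    locus_seed, read_seed = _spawn_seeds(seed, 2)
    locus = make_locus(
        locus_seed, cfg.upstream_len, cfg.mature_len, cfg.downstream_len, cfg.its2_window
    )
    species = size_select(
        default_species(cfg.mature_len),
        (cfg.size_min, cfg.size_max),
        cfg.size_mode,
        cfg.size_sigma,
    )
    index = LocusIndex(locus.seq, cfg.seed_len)
    _, truth, molecules, profile, counters = _run_sample(locus, species, cfg, read_seed, index)
    calls = call_species(
        profile,
        locus.mature_end,
        cfg.min_support,
        cfg.min_fraction,
        cfg.merge_window,
        cfg.mature_exclusion,
    )
    pre_lengths = sorted(c.length_nt for c in calls if c.kind == "pre")
    return {
        "locus": locus,
        "calls": calls,
        "profile": profile,
        "molecules": molecules,
        "truth": truth,
        "counters": counters,
        "pre_lengths": pre_lengths,
        "true_pre_lengths": sorted(DEFAULT_PRE_LENGTHS),
    }


def _species_count_table(
    per_sample_molecules: dict[str, pd.DataFrame],
    sample_meta: pd.DataFrame,
    calls: list[SpeciesCall],
    merge_window: int,
) -> CountTable:
    """Per-sample molecule counts, each molecule assigned to the nearest
    called terminus within +/- merge_window (ties to the smaller coordinate)."""
    features = [f"{c.kind}_{c.length_nt}nt" for c in calls]
    # position -> feature index, nearest call wins
    assignment: dict[int, int] = {}
    for dist in range(merge_window, -1, -1):
        for fi, c in reversed(list(enumerate(calls))):
            for p in (c.terminus - dist, c.terminus + dist):
                assignment[p] = fi
    data = {}
    for sample, molecules in per_sample_molecules.items():
        col = [0] * len(calls)
        for t in molecules["terminus"].to_numpy():
            fi = assignment.get(int(t))
            if fi is not None:
                col[fi] += 1
        data[sample] = col
    counts = pd.DataFrame(data, index=features)[list(sample_meta.index)]
    feature_meta = pd.DataFrame(
        {
            "feature_class": [c.kind for c in calls],
            "terminus": [c.terminus for c in calls],
            "length_nt": [c.length_nt for c in calls],
        },
        index=features,
    )
    return CountTable(counts=counts, sample_meta=sample_meta, feature_meta=feature_meta)


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full two-compartment pipeline and write all outputs.

    Per sample: simulate, preprocess, align, dedup, profile, count (six
    stages). Species are called on the profile pooled over all samples (the
    coverage view is the sum of replicates); per-sample counts at the called
    termini are merged into a count table and tested between compartments.
    Deterministic under ``config.seed``; outputs are TSV with a version +
    config-hash header, plus a JSON run report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    io.write_config(cfg_dict, outdir / "config.txt")

    locus_seed, *sample_seeds = _spawn_seeds(config.seed, 1 + 2 * config.replicates)
    locus = make_locus(
        locus_seed, config.upstream_len, config.mature_len,
        config.downstream_len, config.its2_window,
    )
    io.write_fasta(outdir / "locus.fasta", [("synthetic_rDNA_locus", locus.seq)])
    species = size_select(
        default_species(config.mature_len),
        (config.size_min, config.size_max),
        config.size_mode,
        config.size_sigma,
    )
    index = LocusIndex(locus.seq, config.seed_len)

    samples = [
        (f"{group}_r{rep}", group, rep)
        for group in (GROUP_SOMA, GROUP_NEURITE)
        for rep in range(1, config.replicates + 1)
    ]
    per_sample_molecules: dict[str, pd.DataFrame] = {}
    report: dict = {"samples": {}, "stages": list(STAGES)}
    pooled: dict[int, int] = {}
    pooled_total = 0

    for (sample, group, rep), sseed in zip(samples, sample_seeds):
        try:
            reads, truth, molecules, profile, counters = _run_sample(
                locus, species, config, sseed, index
            )
        except Exception as exc:  # pragma: no cover - abort contract
            raise RuntimeError(f"stage failure in sample {sample}: {exc}") from exc
        if config.write_fastq:
            io.write_fastq(outdir / f"{sample}.fastq", reads)
        per_sample_molecules[sample] = molecules
        for p, c in profile.counts.items():
            pooled[p] = pooled.get(p, 0) + c
        pooled_total += profile.total
        prof_df = pd.DataFrame(
            {
                "position": sorted(profile.counts),
                "offset_from_mature_start": [p - locus.mature_start for p in sorted(profile.counts)],
                "count": [profile.counts[p] for p in sorted(profile.counts)],
            }
        )
        io.write_tsv(prof_df, outdir / f"{sample}.profile.tsv", cfg_dict)
        report["samples"][sample] = {
            "group": group,
            "replicate": rep,
            "stages_completed": len(STAGES),
            **counters,
            "umi_collision_estimate": round(
                umi_collision_estimate(int(counters["molecules"])), 2
            ),
        }

    from .termini import TerminusProfile

    pooled_profile = TerminusProfile(
        region=(locus.mature_start, locus.mature_start + config.its2_window),
        counts=pooled,
        total=pooled_total,
        n_outside=0,
    )
    calls = call_species(
        pooled_profile,
        locus.mature_end,
        config.min_support,
        config.min_fraction,
        config.merge_window,
        config.mature_exclusion,
    )
    calls_df = pd.DataFrame(
        [
            {
                "terminus": c.terminus,
                "length_nt": c.length_nt,
                "support": c.support,
                "fraction": round(c.fraction, 6),
                "class": c.kind,
            }
            for c in calls
        ]
    )
    io.write_tsv(calls_df, outdir / "species_calls.tsv", cfg_dict)
    bed = pd.DataFrame(
        [
            ("synthetic_rDNA_locus", locus.mature_start, c.terminus + 1,
             f"{c.kind}_{c.length_nt}nt", c.support, "+")
            for c in calls
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    io.write_tsv(bed, outdir / "species_calls.bed.tsv", cfg_dict)

    sample_meta = pd.DataFrame(
        [(group, rep) for _, group, rep in samples],
        columns=["group", "replicate"],
        index=[s for s, _, _ in samples],
    )
    table = _species_count_table(
        per_sample_molecules, sample_meta, calls, config.merge_window
    )
    io.write_tsv(table.counts, outdir / "species_counts.tsv", cfg_dict, index=True)
    diff = diff_test(table, alpha=config.alpha)
    io.write_tsv(diff, outdir / "diff_test.tsv", cfg_dict, index=True)

    report["species_calls"] = calls_df.to_dict("records")
    report["total_molecules"] = int(sum(m.shape[0] for m in per_sample_molecules.values()))
    report["total_in_window"] = pooled_total
    report["n_significant"] = int(diff["significant"].sum())
    report["config_hash"] = io.config_hash(cfg_dict)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
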