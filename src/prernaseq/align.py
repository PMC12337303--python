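"""Seed-and-extend local alignment of cDNA payloads to the locus.

The payload of a Read1 is the reverse complement of the RNA's 3'-terminal
window, so it is first re-oriented to the sense strand; the rightmost aligned
query base then corresponds to the RNA 3' terminus. Alignment is seeded with
exact 15-mers (modified positions are expected to be detectable within a
15-base window, so a clean seed survives elsewhere in the read) and each
candidate diagonal is extended by banded Smith-Waterman. The terminus is read
off the alignment end; records whose terminus-proximal clip exceeds a small
tolerance are discarded as untrustworthy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np

from ._kernels import sw_align
from .preprocess import StructuredRead
from .simulate import encode_seq, revcomp

_VALID = set("ACGTN")


@dataclass(frozen=True)
class AlignParams:
    """Scoring and seeding parameters.

    A length-k gap costs ``|gap_open| + k*|gap_extend|``. ``band`` is the
    half-width, in nt, of the reference window explored around each seed
    diagonal (indels in rRNA reads are rare, so a narrow band suffices).
    """

    seed_len: int = 15
    match: int = 1
    mismatch: int = -1
    gap_open: int = -3
    gap_extend: int = -1
    min_score: int = 20
    band: int = 8


@dataclass(frozen=True)
class AlignmentRecord:
    """A local alignment in sense orientation, 0-based half-open.

    ``clip_terminus`` is the number of query bases clipped at the
    terminus-proximal (query 3') end; ``terminus`` is filled by
    :func:`assign_terminus`.
    """

    read_id: str
    umi: str
    ref_start: int
    ref_end: int
    score: int
    n_mismatch: int
    n_gap: int
    clip_terminus: int
    clip_other: int
    ambiguous: bool = False
    terminus: Optional[int] = None


class LocusIndex:
    """Exact k-mer index of the locus sense strand."""

    def __init__(self, seq: str, seed_len: int = 15):
        if seed_len < 1:
            raise ValueError("seed_len must be positive")
        self.seq = seq
        self.seed_len = seed_len
        self.codes = encode_seq(seq)
        self.kmers: dict[str, list[int]] = {}
        for i in range(len(seq) - seed_len + 1):
            self.kmers.setdefault(seq[i : i + seed_len], []).append(i)


def orient_payload(payload: str) -> str:
    """Reverse-complement a payload onto the sense strand; the returned
    query's rightmost base corresponds to the RNA 3' terminus."""
    if not payload:
        raise ValueError("payload is empty")
    if set(payload) - _VALID:
        raise ValueError("payload contains non-ACGTN characters")
    return revcomp(payload)


def local_align(
    query: str, locus: "LocusIndex | str", params: AlignParams = AlignParams()
) -> Optional[AlignmentRecord]:
    """Best seeded local alignment of a sense-strand query to the locus.

    Exact ``seed_len``-mers of the query are located in the locus; every
    distinct seed diagonal is extended by Smith-Waterman over a band of
    ``params.band`` nt around it. The best-scoring alignment is returned if
    it reaches ``min_score``, else None. Ties are resolved toward maximal
    extension (largest query end, then reference end), then fewest
    mismatches, then smallest ref_start; an equal-scoring alignment at a
    distant locus position flags the record ambiguous.
    """
    index = locus if isinstance(locus, LocusIndex) else LocusIndex(locus, params.seed_len)
    if index.seed_len != params.seed_len:
        raise ValueError("index seed_len does not match params.seed_len")
    if len(query) < params.seed_len:
        return None
    qc = encode_seq(query)
    diagonals: set[int] = set()
    for qi in range(len(query) - params.seed_len + 1):
        for ri in index.kmers.get(query[qi : qi + params.seed_len], ()):
            diagonals.add(ri - qi)
    if not diagonals:
        return None

    candidates: list[tuple] = []
    for d in sorted(diagonals):
        lo = max(0, d - params.band)
        hi = min(len(index.seq), d + len(query) + params.band)
        if hi <= lo:
            continue
        score, qs, qe, rs, re_, nmm, ngap = sw_align(
            qc, index.codes[lo:hi],
            params.match, params.mismatch, params.gap_open, params.gap_extend,
        )
        if score < params.min_score:
            continue
        candidates.append((score, qs, qe, rs + lo, re_ + lo, nmm, ngap))
    if not candidates:
        return None

    # preference: score desc, query end desc (minimal terminus clip),
    # ref end desc, mismatches asc, ref start asc
    candidates.sort(key=lambda c: (-c[0], -c[2], -c[4], c[5], c[3]))
    score, qs, qe, rs, re_, nmm, ngap = candidates[0]
    # multi-mapping: an equal-score alignment at a clearly different position
    ambiguous = any(
        c[0] == score and abs(c[3] - rs) > len(query) // 2 for c in candidates[1:]
    )
    return AlignmentRecord(
        read_id="",
        umi="",
        ref_start=rs,
        ref_end=re_,
        score=score,
        n_mismatch=nmm,
        n_gap=ngap,
        clip_terminus=len(query) - qe,
        clip_other=qs,
        ambiguous=ambiguous,
    )


def assign_terminus(record: AlignmentRecord, max_terminus_clip: int = 2) -> Optional[int]:
    """Infer the RNA 3'-terminus coordinate from an alignment.

    The terminus is the rightmost aligned reference base (``ref_end - 1``);
    clipped terminus-side bases are ignored. If more than
    ``max_terminus_clip`` bases are clipped on the terminus side the position
    is untrustworthy and the record is discarded (returns None).
    """
    if record.clip_terminus > max_terminus_clip:
        return None
    return record.ref_end - 1


def align_reads(
    reads: Iterable[StructuredRead],
    index: LocusIndex,
    params: AlignParams = AlignParams(),
    max_terminus_clip: int = 2,
) -> tuple[list[AlignmentRecord], Counter]:
    """Align preprocessed reads and assign termini.

    Identical payloads share one alignment (memoized). Returns emitted
    records (score >= min_score, terminus assigned, not ambiguous records are
    kept; ambiguous ones are kept but flagged) and per-stage counters.
    """
    counters: Counter = Counter()
    cache: dict[str, Optional[AlignmentRecord]] = {}
    out: list[AlignmentRecord] = []
    for sr in reads:
        counters["input"] += 1
        core = cache.get(sr.payload, "MISS")
        if core == "MISS":
            try:
                core = local_align(orient_payload(sr.payload), index, params)
            except ValueError:
                core = None
            cache[sr.payload] = core
        if core is None:
            counters["no_hit"] += 1
            continue
        terminus = assign_terminus(core, max_terminus_clip)
        if terminus is None:
            counters["terminus_clip_discard"] += 1
            continue
        if core.ambiguous:
            counters["ambiguous"] += 1
        counters["aligned"] += 1
        out.append(replace(core, read_id=sr.read_id, umi=sr.umi, terminus=terminus))
    return out, counters
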