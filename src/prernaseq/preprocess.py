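"""Read1 architecture parsing and read cleaning.

Raw Read1 is ``5-bp sample index + 8-bp UMI + ATG anchor + cDNA payload``.
The index is stripped and discarded (demultiplexing is upstream of this
package), the UMI is recorded for molecule deduplication, the anchor is
validated, and the payload is cleaned: 3' adapter read-through is trimmed by
suffix/prefix overlap, a trailing oligo-dT homopolymer from second-strand
priming is removed, and low-quality or too-short reads are rejected.
Rejections are counted per reason, never raised.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable

INDEX_LEN = 5
UMI_LEN = 8
ANCHOR = "ATG"

REJECT_NONE = "none"
REJECT_SHORT = "short"
REJECT_ANCHOR = "anchor_mismatch"
REJECT_LOW_QUALITY = "low_quality"
REJECT_AMBIGUOUS_UMI = "ambiguous_umi"


@dataclass(frozen=True)
class StructuredRead:
    """A parsed Read1: UMI, payload, and accept/reject state."""

    read_id: str
    umi: str
    payload: str
    qual: str | None
    anchor_ok: bool
    reject_reason: str = REJECT_NONE

    @property
    def accepted(self) -> bool:
        return self.reject_reason == REJECT_NONE


def parse_read(
    read_id: str,
    seq: str,
    qual: str | None = None,
    index_len: int = INDEX_LEN,
    umi_len: int = UMI_LEN,
    anchor: str = ANCHOR,
    anchor_max_mismatch: int = 0,
) -> StructuredRead:
    """Split a raw read into index (discarded), UMI, anchor and payload.

    Reads shorter than the architecture plus one payload base are rejected as
    ``short``; anchors with more than ``anchor_max_mismatch`` mismatches as
    ``anchor_mismatch``; UMIs containing N as ``ambiguous_umi`` (an ambiguous
    molecule identity would corrupt deduplication).
    """
    header = index_len + umi_len + len(anchor)
    if len(seq) < header + 1:
        return StructuredRead(read_id, "", "", qual, False, REJECT_SHORT)
    umi = seq[index_len : index_len + umi_len]
    observed_anchor = seq[index_len + umi_len : header]
    payload = seq[header:]
    payload_qual = qual[header:] if qual is not None else None
    mismatches = sum(1 for a, b in zip(observed_anchor, anchor) if a != b)
    if mismatches > anchor_max_mismatch:
        return StructuredRead(read_id, umi, payload, payload_qual, False, REJECT_ANCHOR)
    if "N" in umi:
        return StructuredRead(read_id, umi, payload, payload_qual, False, REJECT_AMBIGUOUS_UMI)
    return StructuredRead(read_id, umi, payload, payload_qual, True, REJECT_NONE)


def trim_adapter(
    payload: str,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_frac: float = 0.1,
) -> str:
    """Remove 3' adapter read-through from a payload.

    The longest payload suffix matching a prefix of the adapter with at least
    ``min_overlap`` bases and a mismatch fraction of at most
    ``max_mismatch_frac`` is removed; if no overlap qualifies the payload is
    returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    for k in range(min(len(payload), len(adapter)), min_overlap - 1, -1):
        suffix = payload[len(payload) - k :]
        prefix = adapter[:k]
        mism = sum(1 for a, b in zip(suffix, prefix) if a != b)
        if mism <= int(max_mismatch_frac * k):
            return payload[: len(payload) - k]
    return payload


def trim_polyt(payload: str, min_run: int = 8) -> str:
    """Trim a trailing homopolymer-T run of at least ``min_run`` nt (the
    second-strand oligo-dT artifact); shorter runs are kept."""
    n = len(payload)
    i = n
    while i > 0 and payload[i - 1] == "T":
        i -= 1
    return payload[:i] if n - i >= min_run else payload


def mean_quality(qual: str, offset: int = 33) -> float:
    if not qual:
        return 0.0
    return sum(ord(c) - offset for c in qual) / len(qual)


def quality_filter(
    read: StructuredRead, min_mean_q: float = 20.0, min_len: int = 20
) -> StructuredRead:
    """Reject reads with mean payload quality < ``min_mean_q`` (>= passes)
    or payload length < ``min_len``. Reads without qualities pass the quality
    gate with a warning."""
    if not read.accepted:
        return read
    if len(read.payload) < min_len:
        return replace(read, reject_reason=REJECT_SHORT)
    if read.qual is None:
        import warnings
        warnings.warn("read has no qualities; quality gate skipped")
        return read
    if mean_quality(read.qual) < min_mean_q:
        return replace(read, reject_reason=REJECT_LOW_QUALITY)
    return read


def preprocess_reads(
    records: Iterable[tuple[str, str, str | None]],
    index_len: int = INDEX_LEN,
    umi_len: int = UMI_LEN,
    anchor: str = ANCHOR,
    anchor_max_mismatch: int = 0,
    adapter: str | None = None,
    min_overlap: int = 6,
    max_mismatch_frac: float = 0.1,
    polyt_min_run: int = 8,
    min_mean_q: float = 20.0,
    min_len: int = 20,
) -> tuple[list[StructuredRead], Counter]:
    """Full cleaning pass: parse, trim, filter.

    ``records`` yields ``(read_id, sequence, quality-or-None)``. Returns the
    accepted StructuredReads and a Counter of reject reasons; accepted plus
    rejected always equals the input count (key ``input`` in the counter).
    """
    accepted: list[StructuredRead] = []
    counts: Counter = Counter()
    for read_id, seq, qual in records:
        counts["input"] += 1
        sr = parse_read(read_id, seq, qual, index_len, umi_len, anchor, anchor_max_mismatch)
        if sr.accepted:
            payload = sr.payload
            if adapter:
                payload = trim_adapter(payload, adapter, min_overlap, max_mismatch_frac)
            payload = trim_polyt(payload, polyt_min_run)
            qual_trim = sr.qual[: len(payload)] if sr.qual is not None else None
            sr = replace(sr, payload=payload, qual=qual_trim)
            sr = quality_filter(sr, min_mean_q=min_mean_q, min_len=min_len)
        if sr.accepted:
            counts["accepted"] += 1
            accepted.append(sr)
        else:
            counts[sr.reject_reason] += 1
    return accepted, counts
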