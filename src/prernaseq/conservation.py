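"""Cross-sequence conservation profiling around cleavage sites.

Homologous rDNA windows (e.g. the 100 nt upstream / 415 nt downstream of the
first mature-5.8S nucleotide from several species) are globally aligned,
columns are classed identical vs mismatch with a majority-base frequency, and
identity fractions are summarized in flanks 5' and 3' of anchor positions
(called cleavage sites). Three sequences are aligned progressively: the
closest pair first, then the third against the pair's majority consensus —
adequate for a handful of closely related homologs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import nw_align
from .simulate import encode_seq

GAP = "-"
_VALID = set("ACGTN")


def _check_seq(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{name} is empty")
    if set(seq) - _VALID:
        raise ValueError(f"{name} contains non-nucleotide characters")


def global_align(
    seq_a: str, seq_b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[str, str, int]:
    """Optimal Needleman-Wunsch global alignment (linear gap penalty).

    Returns the two gapped rows and the score. Ties are broken
    deterministically toward aligned pairs (fewer gaps).
    """
    _check_seq(seq_a, "seq_a")
    _check_seq(seq_b, "seq_b")
    score, ops = nw_align(encode_seq(seq_a), encode_seq(seq_b), match, mismatch, gap)
    rows = ["", ""]
    ia = ib = 0
    out_a: list[str] = []
    out_b: list[str] = []
    for op in ops:
        if op == 0:
            out_a.append(seq_a[ia]); ia += 1
            out_b.append(seq_b[ib]); ib += 1
        elif op == 1:
            out_a.append(seq_a[ia]); ia += 1
            out_b.append(GAP)
        else:
            out_a.append(GAP)
            out_b.append(seq_b[ib]); ib += 1
    return "".join(out_a), "".join(out_b), int(score)


@dataclass(frozen=True)
class AlignedColumnSet:
    """Aligned rows with per-column class and majority-base frequency.

    ``classes``: 'identical' (all non-gap bases equal), 'mismatch', or
    'allgap' (flagged; frequency is NaN there). Frequency is the majority
    base count over the non-gap count.
    """

    rows: tuple[str, ...]
    classes: np.ndarray
    frequency: np.ndarray

    @property
    def length(self) -> int:
        return len(self.rows[0])


def column_classes(rows: list[str]) -> AlignedColumnSet:
    """Classify every alignment column; rows must be equal length."""
    if not rows:
        raise ValueError("no rows")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("aligned rows must have equal length")
    classes = np.empty(length, dtype=object)
    freq = np.full(length, np.nan)
    for c in range(length):
        bases = [r[c] for r in rows if r[c] != GAP]
        if not bases:
            classes[c] = "allgap"
            continue
        counts = pd.Series(bases).value_counts()
        freq[c] = counts.iloc[0] / len(bases)
        classes[c] = "identical" if len(counts) == 1 else "mismatch"
    return AlignedColumnSet(rows=tuple(rows), classes=classes, frequency=freq)


def _consensus(rows: tuple[str, str]) -> str:
    """Majority base per column of a pairwise alignment (gap-aware; ties and
    gap-vs-base columns resolve to the lexicographically smaller / non-gap
    base, so the consensus is always ungapped)."""
    out = []
    for a, b in zip(*rows):
        if a == GAP and b == GAP:  # cannot occur in a pairwise NW alignment
            out.append("N")
        elif a == GAP:
            out.append(b)
        elif b == GAP:
            out.append(a)
        else:
            out.append(min(a, b))
    return "".join(out)


def progressive_align(seqs: list[str], **scoring) -> list[str]:
    """Progressive multiple alignment of up to three sequences.

    The closest pair (highest pairwise score) is aligned first; the remaining
    sequence is aligned to the pair's majority consensus and its gaps are
    propagated into both rows. Rows come back in input order.
    """
    for s in seqs:
        _check_seq(s)
    if len(seqs) == 1:
        return [seqs[0]]
    if len(seqs) == 2:
        a, b, _ = global_align(seqs[0], seqs[1], **scoring)
        return [a, b]
    if len(seqs) != 3:
        raise ValueError("progressive_align supports at most 3 sequences")
    pairs = [(0, 1), (0, 2), (1, 2)]
    scores = {p: global_align(seqs[p[0]], seqs[p[1]], **scoring)[2] for p in pairs}
    i, j = max(pairs, key=lambda p: scores[p])
    k = ({0, 1, 2} - {i, j}).pop()
    row_i, row_j, _ = global_align(seqs[i], seqs[j], **scoring)
    cons = _consensus((row_i, row_j))
    cons_aln, third_aln, _ = global_align(cons, seqs[k], **scoring)
    # propagate gaps inserted into the consensus back into the pair rows
    merged_i: list[str] = []
    merged_j: list[str] = []
    ptr = 0
    for c in cons_aln:
        if c == GAP:
            merged_i.append(GAP)
            merged_j.append(GAP)
        else:
            merged_i.append(row_i[ptr])
            merged_j.append(row_j[ptr])
            ptr += 1
    out = [None, None, None]
    out[i] = "".join(merged_i)
    out[j] = "".join(merged_j)
    out[k] = third_aln
    return list(out)  # type: ignore[arg-type]


def project_position(ref_row: str, pos: int) -> int:
    """Map a 0-based position in the ungapped reference sequence to its
    alignment column (gap columns in the reference row are skipped)."""
    if pos < 0:
        raise ValueError("position must be non-negative")
    seen = -1
    for col, ch in enumerate(ref_row):
        if ch != GAP:
            seen += 1
            if seen == pos:
                return col
    raise ValueError("position beyond the reference row")


def windowed_identity(
    rows: list[str],
    anchors: list[int],
    flank: int,
    ref_index: int = 0,
) -> pd.DataFrame:
    """Identity fractions 5' and 3' of each anchor.

    ``anchors`` are positions in the ungapped reference row (``ref_index``),
    projected onto alignment columns; the 5' flank is ``[col-flank, col)``
    and the 3' flank ``[col, col+flank)``. Flanks extending past the
    alignment are truncated with a warning. Identity is the fraction of
    'identical' columns among non-allgap columns of the flank.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    colset = column_classes(rows)
    identical = colset.classes == "identical"
    usable = colset.classes != "allgap"
    out = []
    for anchor in anchors:
        col = project_position(rows[ref_index], anchor)
        lo, hi = col - flank, col + flank
        if lo < 0 or hi > colset.length:
            warnings.warn(f"flank around anchor {anchor} truncated at the alignment edge")
            lo, hi = max(lo, 0), min(hi, colset.length)
        up = slice(lo, col)
        down = slice(col, hi)
        out.append(
            (
                anchor,
                float(identical[up].sum() / max(usable[up].sum(), 1)),
                float(identical[down].sum() / max(usable[down].sum(), 1)),
            )
        )
    return pd.DataFrame(out, columns=["anchor", "identity_5prime", "identity_3prime"])
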