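"""Compartment differential-abundance and category-enrichment statistics.

RNA count tables are normalized by median-of-ratios size factors and tested
feature-wise with a two-sided Welch t test on log2(normalized count + 0.5),
with Benjamini-Hochberg control of the false discovery rate. This is a
deliberately simple, calibration-validated stand-in for a negative-binomial
GLM: the inferential claims it supports (direction of nuclear depletion,
compartment parity of the pre-5.8S species) depend on sign and FDR control,
not on shrinkage machinery.

Protein log-intensity tables get the same Welch/BH treatment (volcano
classification against joint FDR and fold-change thresholds), Kruskal-Wallis
omnibus plus pairwise Welch tests across gene categories, and
detected-in-all-replicates presence calls.

Sign convention: log2FC = neurite - (somata+neurites); positive means
enriched in the neurite-only compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GROUP_SOMA = "somata_neurites"
GROUP_NEURITE = "neurite"


@dataclass
class CountTable:
    """Features x samples non-negative integer counts with metadata.

    ``sample_meta`` carries ``group`` and ``replicate`` per sample (rows match
    count columns); ``feature_meta`` carries at least ``feature_class``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise ValueError("sample_meta rows must match count columns")


@dataclass
class ProteinTable:
    """Proteins x samples log2 intensities (NaN = not quantified)."""

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    protein_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.intensities.columns) != list(self.sample_meta.index):
            raise ValueError("sample_meta rows must match intensity columns")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Each sample's factor is the median, over features with nonzero counts in
    every sample, of the ratio of that sample's count to the feature's
    geometric mean across samples.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; "
            "filter features or supply a pseudo-reference"
        )
    sub = mat[all_nonzero]
    geomean = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    factors = np.median(sub / geomean, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / size_factors(counts)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Welch t machinery (vectorized over rows)
# ---------------------------------------------------------------------------

def _welch_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided Welch t; degenerate rows (zero variance in both
    groups) get p = 1 and are logged."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
        t, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    bad = ~np.isfinite(p)
    if bad.any():
        logger.warning("%d feature(s) with degenerate variance; p set to 1", int(bad.sum()))
        p = np.where(bad, 1.0, p)
        t = np.where(np.isfinite(t), t, 0.0)
    return t, p


def _group_columns(sample_meta: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    g = sample_meta["group"]
    soma = sample_meta.index[g == GROUP_SOMA]
    neur = sample_meta.index[g == GROUP_NEURITE]
    for name, cols in ((GROUP_SOMA, soma), (GROUP_NEURITE, neur)):
        if len(cols) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    return soma, neur


# ---------------------------------------------------------------------------
# RNA differential test
# ---------------------------------------------------------------------------

def diff_test(table: CountTable, alpha: float = 0.05, lfc_threshold: float = 0.0) -> pd.DataFrame:
    """Per-feature compartment differential test on an RNA count table.

    Counts are size-factor normalized, shifted by a 0.5 pseudo-count and
    log2-transformed; groups are compared by row-wise Welch t with BH
    adjustment. Returns a frame with ``baseMean``, ``log2FC`` (neurite minus
    somata+neurites), ``p``, ``p_adj`` and ``significant``.
    """
    soma, neur = _group_columns(table.sample_meta)
    norm = normalize_counts(table.counts)
    log_norm = np.log2(norm + 0.5)
    a = log_norm[neur].to_numpy()
    b = log_norm[soma].to_numpy()
    _, p = _welch_rows(a, b)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    p_adj = bh_adjust(p)
    significant = (p_adj < alpha) & (np.abs(lfc) > lfc_threshold)
    return pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2FC": lfc,
            "p": p,
            "p_adj": p_adj,
            "significant": significant,
        },
        index=table.counts.index,
    )


# ---------------------------------------------------------------------------
# protein statistics
# ---------------------------------------------------------------------------

def volcano_classify(table: ProteinTable, fdr: float = 0.05, lfc: float = 0.5) -> pd.DataFrame:
    """Welch/BH volcano classification of a protein table.

    Proteins quantified in fewer than 2 replicates of either group are
    reported with class ``not_tested``. Classes: ``up_neurite``, ``up_soma``
    (p_adj < fdr and |log2FC| > lfc jointly) or ``ns``.
    """
    soma, neur = _group_columns(table.sample_meta)
    a = table.intensities[neur].to_numpy()
    b = table.intensities[soma].to_numpy()
    testable = (np.sum(~np.isnan(a), axis=1) >= 2) & (np.sum(~np.isnan(b), axis=1) >= 2)
    with np.errstate(invalid="ignore"):
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            lfc_vec = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)

    p = np.full(len(table.intensities), np.nan)
    if testable.any():
        _, p_t = _welch_rows(a[testable], b[testable])
        p[testable] = p_t
    p_adj = np.full_like(p, np.nan)
    if testable.any():
        p_adj[testable] = bh_adjust(p[testable])

    cls = np.where(
        testable & (p_adj < fdr) & (np.abs(lfc_vec) > lfc),
        np.where(lfc_vec > 0, "up_neurite", "up_soma"),
        "ns",
    )
    cls = np.where(testable, cls, "not_tested")
    return pd.DataFrame(
        {"log2FC": lfc_vec, "p": p, "p_adj": p_adj, "class": cls},
        index=table.intensities.index,
    )


def category_stats(
    log2fc: pd.Series | np.ndarray,
    categories: pd.Series | np.ndarray,
    pairs: list[tuple[str, str]] | None = None,
    adjust_pairs: bool = False,
) -> dict:
    """Kruskal-Wallis omnibus across categories plus pairwise Welch t tests.

    ``pairs`` lists (category_a, category_b) comparisons; by default every
    category is compared against the first one listed. Pairwise p values are
    reported raw unless ``adjust_pairs`` (BH across the requested pairs).
    """
    lfc = pd.Series(np.asarray(log2fc, dtype=float))
    cats = pd.Series(np.asarray(categories, dtype=object))
    if len(lfc) != len(cats):
        raise ValueError("log2fc and categories must align")
    keep = lfc.notna()
    lfc, cats = lfc[keep], cats[keep]
    levels = list(pd.unique(cats))
    if len(levels) < 2:
        raise ValueError("need at least 2 categories")
    groups = {lev: lfc[cats == lev].to_numpy() for lev in levels}
    for lev, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"category {lev!r} has fewer than 2 members")

    kw_stat, kw_p = stats.kruskal(*groups.values())

    if pairs is None:
        pairs = [(levels[0], lev) for lev in levels[1:]]
    rows = []
    for a_lab, b_lab in pairs:
        if a_lab not in groups or b_lab not in groups:
            raise ValueError(f"unknown category in pair ({a_lab}, {b_lab})")
        t, p = stats.ttest_ind(groups[a_lab], groups[b_lab], equal_var=False)
        rows.append((a_lab, b_lab, float(t), float(p)))
    pairwise = pd.DataFrame(rows, columns=["category_a", "category_b", "t", "p"])
    if adjust_pairs and len(pairwise):
        pairwise["p_adj"] = bh_adjust(pairwise["p"].to_numpy())
    return {"kw_stat": float(kw_stat), "kw_p": float(kw_p), "pairwise": pairwise}


def detection_summary(table: ProteinTable, min_replicates: int = 5) -> pd.DataFrame:
    """Per-protein, per-group detection flags.

    A protein is detected in a group iff it is quantified (non-missing) in at
    least ``min_replicates`` replicates of that group.
    """
    flags = {}
    for group, cols in table.sample_meta.groupby("group").groups.items():
        present = table.intensities[list(cols)].notna().sum(axis=1)
        flags[f"detected_{group}"] = present >= min_replicates
    return pd.DataFrame(flags, index=table.intensities.index)


def detection_by_class(
    detection: pd.DataFrame, protein_meta: pd.DataFrame, class_column: str = "release_site"
) -> pd.DataFrame:
    """Count detected proteins per metadata class and group."""
    joined = detection.join(protein_meta[[class_column]])
    return joined.groupby(class_column, dropna=True).sum(numeric_only=False).astype(int)
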