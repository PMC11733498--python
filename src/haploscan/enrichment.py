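"""Haploblock enrichment among outlier windows and shift tests.

All tests work at the window level, matching the windowed scans: a window
belongs to a haploblock when its midpoint falls inside the haploblock
interval (an overlap-fraction rule is available). Enrichment of outlier
windows inside a haploblock is an upper-tail hypergeometric test,
Bonferroni-corrected across the haploblocks tested; the distributional
shift of haploblock versus non-haploblock window scores is a two-sided
Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io_formats import GenomicWindow, Interval

__all__ = [
    "EnrichmentResult",
    "OverlapResult",
    "windows_in_haploblock",
    "hypergeom_enrichment",
    "outlier_overlap",
    "haploblock_shift_test",
]


@dataclass
class EnrichmentResult:
    haploblock: str
    outlier_set: str
    n_total: int          # N: window universe
    n_in_block: int       # K: windows in the haploblock
    n_outliers: int       # n: outlier windows drawn
    n_overlap: int        # k: outlier windows inside the haploblock
    p: float
    p_adjusted: float
    enriched: bool


@dataclass
class OverlapResult:
    set_a: str
    set_b: str
    n_a: int
    n_b: int
    n_total: int
    n_overlap: int
    expected: float
    p: float


def windows_in_haploblock(
    windows: list[GenomicWindow],
    block: Interval,
    rule: str = "midpoint",
    min_overlap: float = 0.5,
) -> np.ndarray:
    """Indices of windows assigned to the haploblock interval."""
    out = []
    for i, w in enumerate(windows):
        if w.chrom != block.chrom:
            continue
        if rule == "midpoint":
            if block.start <= w.midpoint < block.end:
                out.append(i)
        elif rule == "overlap":
            ov = max(0, min(w.end, block.end) - max(w.start, block.start))
            if ov / (w.end - w.start) >= min_overlap:
                out.append(i)
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return np.array(out, dtype=int)


def hypergeom_enrichment(
    outlier_ids: set[int],
    block_ids: set[int],
    n_total: int,
    n_tests: int = 1,
    alpha: float = 0.05,
    haploblock: str = "",
    outlier_set: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric P(X >= k) of outlier windows inside a
    haploblock, Bonferroni-corrected across ``n_tests`` haploblocks."""
    K, n, k = len(block_ids), len(outlier_ids), len(outlier_ids & block_ids)
    if K > n_total or n > n_total:
        raise ValueError("set sizes exceed the window universe")
    if k > min(K, n):
        raise ValueError(f"overlap {k} exceeds min({K}, {n})")
    p = float(sps.hypergeom.sf(k - 1, n_total, K, n))
    p_adj = min(1.0, p * n_tests)
    return EnrichmentResult(
        haploblock=haploblock, outlier_set=outlier_set, n_total=n_total,
        n_in_block=K, n_outliers=n, n_overlap=k, p=p, p_adjusted=p_adj,
        enriched=bool(p_adj < alpha),
    )


def outlier_overlap(
    set_a: set[int], set_b: set[int], n_total: int,
    name_a: str = "A", name_b: str = "B",
) -> OverlapResult:
    """Overlap between two outlier-window sets with an upper-tail
    hypergeometric p-value against independence."""
    if len(set_a) > n_total or len(set_b) > n_total:
        raise ValueError("set sizes exceed the window universe")
    k = len(set_a & set_b)
    p = float(sps.hypergeom.sf(k - 1, n_total, len(set_a), len(set_b)))
    return OverlapResult(
        set_a=name_a, set_b=name_b, n_a=len(set_a), n_b=len(set_b),
        n_total=n_total, n_overlap=k,
        expected=len(set_a) * len(set_b) / n_total if n_total else np.nan,
        p=p,
    )


def haploblock_shift_test(
    scores: np.ndarray, in_block: np.ndarray
) -> dict:
    """Two-sided Mann-Whitney U comparing haploblock vs non-haploblock
    window scores. Reports which group ranks higher and the star coding
    (0.05 / 0.01 / 0.001)."""
    scores = np.asarray(scores, dtype=float)
    in_block = np.asarray(in_block, dtype=bool)
    a = scores[in_block & np.isfinite(scores)]
    b = scores[~in_block & np.isfinite(scores)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(np.concatenate([a, b]) == a[0] if len(a) else False) or (
        len(np.unique(np.concatenate([a, b]))) == 1
    ):
        return {"U": np.nan, "p": 1.0, "higher": "tied", "stars": ""}
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    mean_rank_a = sps.rankdata(np.concatenate([a, b]))[: len(a)].mean()
    mean_rank_b = sps.rankdata(np.concatenate([a, b]))[len(a):].mean()
    higher = "haploblock" if mean_rank_a > mean_rank_b else "non-haploblock"
    p = float(res.pvalue)
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
    return {"U": float(res.statistic), "p": p, "higher": higher, "stars": stars}
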