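"""Genotype candidate regions as haploblocks and validate the calls.

A real haploblock (two structural arrangements segregating in the sample)
shows three clusters along the leading principal component of its SNPs —
the two arrangement homozygotes and the heterokaryotypes in between. The
heterokaryotype cluster must also carry elevated SNP heterozygosity, and
linkage disequilibrium across the region should collapse when recomputed
within the major-arrangement homozygotes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, SampleFrame, MISSING
from .local_pca import CandidateRegion, _imputed_centered

__all__ = [
    "HaploblockCall",
    "region_pca_genotype",
    "heterozygosity_test",
    "ld_validation",
    "haploblock_frequencies",
    "confirm_haploblock",
    "call_haploblocks",
]

GENOTYPES = ("AA", "AB", "BB")


@dataclass
class HaploblockCall:
    region: CandidateRegion
    name: str = ""
    pc1_scores: np.ndarray | None = None
    genotypes: dict[str, str] = field(default_factory=dict)  # sample -> AA/AB/BB/unassigned
    cluster_means: dict[str, float] = field(default_factory=dict)
    cluster_sizes: dict[str, int] = field(default_factory=dict)
    rejected: bool = False
    reject_reason: str = ""
    het_stats: pd.DataFrame | None = None
    het_test_pass: bool | None = None      # None => inconclusive
    ld_stats: dict[str, float] = field(default_factory=dict)
    ld_test_pass: bool | None = None
    pop_freqs: pd.Series | None = None
    range_freqs: pd.Series | None = None

    @property
    def confirmed(self) -> bool:
        """Trimodal structure plus a passing heterozygosity test.

        The LD contrast is reported as a diagnostic but is not required,
        since its pass threshold is a package convention rather than an
        established criterion.
        """
        return (not self.rejected) and self.het_test_pass is True

    def genotype_array(self, sample_ids) -> np.ndarray:
        return np.array([self.genotypes.get(s, "unassigned") for s in sample_ids])


def region_pca_genotype(
    gm: GenotypeMatrix,
    region: CandidateRegion,
    min_sites: int = 20,
    assign_frac: float = 0.25,
    min_separation: float = 6.0,
    name: str = "",
) -> HaploblockCall:
    """PCA over the region's SNPs and 3-means clustering of PC1 scores.

    Cluster centers are initialized at the min / median / max score. Samples
    farther from every center than ``assign_frac`` times the PC1 span are
    left unassigned. A call is rejected ("no trimodal structure") when a
    cluster is empty or when the gap between adjacent centers is less than
    ``min_separation`` pooled within-cluster standard deviations (unimodal
    PC1 scores split by 3-means never exceed ~4 pooled SDs, while genuine
    arrangement clusters sit far above; 6 separates the regimes). The middle
    cluster is the heterokaryotype AB; orientation is fixed so arrangement A
    is the globally more frequent one.
    """
    call = HaploblockCall(region=region, name=name or f"hb-{region.chrom}")
    site_idx = np.flatnonzero(gm.site_mask_in_region(region.chrom, region.start, region.end))
    if len(site_idx) < min_sites:
        call.rejected = True
        call.reject_reason = f"only {len(site_idx)} SNPs in region"
        return call

    x = _imputed_centered(gm, site_idx)
    # leading eigenvector of the sample covariance = PC1 scores
    cov = (x @ x.T) / x.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    pc1 = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    i = int(np.argmax(np.abs(pc1)))
    if pc1[i] < 0:
        pc1 = -pc1
    call.pc1_scores = pc1

    from sklearn.cluster import KMeans

    init = np.array([[pc1.min()], [np.median(pc1)], [pc1.max()]])
    km = KMeans(n_clusters=3, init=init, n_init=1, random_state=0)
    labels = km.fit_predict(pc1[:, None])
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    centers = centers[order]
    relabel = np.empty(3, dtype=int)
    relabel[order] = np.arange(3)
    labels = relabel[labels]

    sizes = np.bincount(labels, minlength=3)
    if np.any(sizes == 0):
        call.rejected = True
        call.reject_reason = "no trimodal structure"
        return call

    span = centers[2] - centers[0]
    sds = np.array([pc1[labels == c].std() for c in range(3)])
    for c in range(2):
        gap = centers[c + 1] - centers[c]
        pooled = np.sqrt(0.5 * (sds[c] ** 2 + sds[c + 1] ** 2))
        if pooled > 0 and gap < min_separation * pooled:
            call.rejected = True
            call.reject_reason = "no trimodal structure"
            return call

    dist_to_center = np.abs(pc1 - centers[labels])
    unassigned = dist_to_center > assign_frac * span if span > 0 else np.zeros(len(pc1), bool)

    # orientation: A = globally more frequent arrangement
    n_assigned = (~unassigned).sum()
    b_copies = sizes[1] + 2 * sizes[2]  # provisional, high-PC1 side = B
    cluster_names = list(GENOTYPES)
    if b_copies > n_assigned:  # B would be the major arrangement: flip
        cluster_names = list(GENOTYPES[::-1])

    geno = {}
    for s, lab, un in zip(gm.sample_ids, labels, unassigned):
        geno[s] = "unassigned" if un else cluster_names[lab]
    call.genotypes = geno
    call.cluster_means = {cluster_names[c]: float(centers[c]) for c in range(3)}
    call.cluster_sizes = {
        g: int(sum(1 for v in geno.values() if v == g)) for g in GENOTYPES
    }
    call.cluster_sizes["unassigned"] = int(sum(1 for v in geno.values() if v == "unassigned"))
    return call


def heterozygosity_test(
    gm: GenotypeMatrix, region: CandidateRegion, call: HaploblockCall
) -> tuple[pd.DataFrame, bool | None]:
    """Heterokaryotype-heterozygosity criterion.

    Per-sample observed heterozygosity is the fraction of region SNPs called
    heterozygous. The test passes when the mean +- SEM interval of the AB
    class is disjoint from both homozygote intervals and the AB mean is the
    largest. Classes with fewer than 2 samples make the test inconclusive
    (None), not failed.
    """
    site_idx = np.flatnonzero(gm.site_mask_in_region(region.chrom, region.start, region.end))
    d = gm.dosages[:, site_idx]
    called = d != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(called, d == 1, False).sum(axis=1) / np.maximum(called.sum(axis=1), 1)

    geno = call.genotype_array(gm.sample_ids)
    rows = []
    for g in GENOTYPES:
        vals = het[geno == g]
        n = len(vals)
        mean = float(vals.mean()) if n else np.nan
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"class": g, "n": n, "mean_het": mean, "sem": sem})
    stats = pd.DataFrame(rows).set_index("class")

    if (stats["n"] < 2).any():
        return stats, None
    lo = stats["mean_het"] - stats["sem"]
    hi = stats["mean_het"] + stats["sem"]
    ab_disjoint = all(
        hi["AB"] < lo[g] or lo["AB"] > hi[g] for g in ("AA", "BB")
    )
    ab_highest = stats.loc["AB", "mean_het"] > stats.loc["AA", "mean_het"] and (
        stats.loc["AB", "mean_het"] > stats.loc["BB", "mean_het"]
    )
    return stats, bool(ab_disjoint and ab_highest)


def _median_pairwise_r2(dosages: np.ndarray) -> float:
    """Median composite-genotype r^2 over all site pairs (columns)."""
    x = dosages.astype(float)
    x[x == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = mu[inds[1]]
    sd = x.std(axis=0)
    x = x[:, sd > 0]
    if x.shape[1] < 2:
        return np.nan
    r = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices_from(r, k=1)
    return float(np.nanmedian(r[iu] ** 2))


def ld_validation(
    gm: GenotypeMatrix,
    region: CandidateRegion,
    call: HaploblockCall,
    n_snps: int = 5000,
    seed: int = 0,
    delta: float = 0.2,
    min_homozygotes: int = 5,
    maf: float = 0.05,
) -> tuple[dict[str, float], bool | None]:
    """LD collapse inside the major-arrangement homozygotes.

    Median pairwise r^2 across up to ``n_snps`` region SNPs (MAF > ``maf``)
    is compared between all samples and the major-homozygote subset; the
    check passes when the drop is at least ``delta``. Too few homozygotes
    => inconclusive (None).
    """
    site_idx = np.flatnonzero(gm.site_mask_in_region(region.chrom, region.start, region.end))
    p = gm.alt_freqs()[site_idx]
    keep = np.minimum(p, 1 - p) > maf
    site_idx = site_idx[keep]
    if len(site_idx) > n_snps:
        rng = np.random.default_rng(seed)
        site_idx = np.sort(rng.choice(site_idx, size=n_snps, replace=False))

    geno = call.genotype_array(gm.sample_ids)
    major = "AA" if call.cluster_sizes.get("AA", 0) >= call.cluster_sizes.get("BB", 0) else "BB"
    hom_idx = np.flatnonzero(geno == major)

    stats = {
        "median_r2_all": _median_pairwise_r2(gm.dosages[:, site_idx]),
        "median_r2_homozygotes": np.nan,
        "n_snps": float(len(site_idx)),
        "n_homozygotes": float(len(hom_idx)),
        "delta": delta,
    }
    if len(hom_idx) < min_homozygotes:
        return stats, None
    stats["median_r2_homozygotes"] = _median_pairwise_r2(gm.dosages[hom_idx][:, site_idx])
    drop = stats["median_r2_all"] - stats["median_r2_homozygotes"]
    return stats, bool(drop >= delta)


def haploblock_frequencies(
    call: HaploblockCall, samples: SampleFrame, sample_ids: list[str]
) -> tuple[pd.Series, pd.Series]:
    """Arrangement-B frequency per population and per range:
    (n_AB + 2 n_BB) / (2 n_assigned); empty groups give NaN."""
    geno = call.genotype_array(sample_ids)
    meta = samples.aligned(sample_ids)
    out = []
    for col in ("population", "range"):
        freqs = {}
        for group, idx in meta.groupby(col, sort=True).groups.items():
            g = geno[[meta.index.get_loc(s) for s in idx]]
            assigned = g != "unassigned"
            n = int(assigned.sum())
            if n == 0:
                freqs[group] = np.nan
                continue
            b = int((g == "AB").sum() + 2 * (g == "BB").sum())
            freqs[group] = b / (2.0 * n)
        out.append(pd.Series(freqs, name=f"freq_by_{col}"))
    return out[0], out[1]


def confirm_haploblock(
    gm: GenotypeMatrix,
    region: CandidateRegion,
    samples: SampleFrame | None = None,
    name: str = "",
    ld_seed: int = 0,
    **genotype_kwargs,
) -> HaploblockCall:
    """Candidate -> genotypes -> heterozygosity test -> LD diagnostic."""
    call = region_pca_genotype(gm, region, name=name, **genotype_kwargs)
    if call.rejected:
        return call
    call.het_stats, call.het_test_pass = heterozygosity_test(gm, region, call)
    call.ld_stats, call.ld_test_pass = ld_validation(gm, region, call, seed=ld_seed)
    if samples is not None:
        call.pop_freqs, call.range_freqs = haploblock_frequencies(call, samples, gm.sample_ids)
    return call


def call_haploblocks(
    gm: GenotypeMatrix,
    candidates: list[CandidateRegion],
    samples: SampleFrame | None = None,
    ld_seed: int = 0,
    **genotype_kwargs,
) -> list[HaploblockCall]:
    """Run confirmation over all candidate regions; names are assigned as
    hb-<chrom><letter> in genomic order."""
    counters: dict[str, int] = {}
    calls = []
    for reg in sorted(candidates, key=lambda r: (r.chrom, r.start)):
        letter = chr(ord("a") + counters.get(reg.chrom, 0))
        counters[reg.chrom] = counters.get(reg.chrom, 0) + 1
        calls.append(
            confirm_haploblock(gm, reg, samples=samples,
                               name=f"hb-{reg.chrom}{letter}", ld_seed=ld_seed,
                               **genotype_kwargs)
        )
    return calls
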