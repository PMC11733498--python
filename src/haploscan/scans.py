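"""Per-SNP local-adaptation statistics and 10-kbp weighted-Z windows.

The differentiation statistics whiten population allele frequencies by an
estimated among-population covariance matrix (Omega) built from background
SNPs, so shared demography does not masquerade as selection:

* ``xtx_surrogate`` — a moment-based quadratic form p~' Omega^-1 p~ measuring
  overall frequency divergence among populations (a deterministic surrogate
  for the BayPass core-model XtX posterior; outputs are labeled surrogate).
* ``contrast_surrogate`` — a standardized squared frequency difference
  between two population groups (surrogate for the BayPass contrast
  statistic), approximately chi-square(1) under the null.
* ``kendall_tau_eaa`` — rank correlation between population frequencies and
  an environmental variable.
* ``fay_wu_h`` — theta_pi - theta_H from the unfolded site frequency
  spectrum, sensitive to the high-frequency derived alleles left by sweeps.
* ``gwas_scan`` — covariate-adjusted per-SNP association with a phenotype.

Per-SNP statistics are converted to empirical p-values by genome-wide rank
and aggregated into nonoverlapping windows with the weighted-Z approach
(weights = mean-frequency heterozygosity p(1-p)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import (
    GenomicWindow,
    GenotypeMatrix,
    MISSING,
    SampleFrame,
    assign_sites_to_windows,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PopFrequencyTable",
    "OmegaMatrix",
    "population_frequencies",
    "standardize_frequencies",
    "estimate_omega",
    "xtx_surrogate",
    "contrast_surrogate",
    "kendall_tau_eaa",
    "fay_wu_h",
    "fay_wu_h_windows",
    "gwas_scan",
    "empirical_p",
    "wza_window",
]

# paper-style outlier tails per scan type, exposed as config presets
TAIL_PRESETS = {"xtx": 0.05, "eaa": 0.05, "contrast": 0.01, "gwas": 0.001}


@dataclass
class PopFrequencyTable:
    populations: list[str]
    ranges: list[str]                 # range label per population
    freqs: np.ndarray                 # (S, J) allele frequencies
    sizes: np.ndarray                 # (J,) diploid sample sizes

    @property
    def n_pops(self) -> int:
        return len(self.populations)


@dataclass
class OmegaMatrix:
    omega: np.ndarray                 # (J, J), shrunk, invertible
    inverse: np.ndarray
    n_snps: int
    shrink: float


def population_frequencies(
    gm: GenotypeMatrix, samples: SampleFrame, min_n: int = 3
) -> PopFrequencyTable:
    """Alternate-allele frequency per population; populations with fewer
    than ``min_n`` diploids (paper rule: n > 2) are excluded."""
    meta = samples.aligned(gm.sample_ids)
    pops, ranges, cols, sizes = [], [], [], []
    for pop, grp in meta.groupby("population", sort=True):
        if len(grp) < min_n:
            logger.info("population %s excluded (n=%d < %d)", pop, len(grp), min_n)
            continue
        idx = [gm.sample_ids.index(s) for s in grp.index]
        d = gm.dosages[idx]
        called = d != MISSING
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, d, 0).sum(axis=0) / np.maximum(2 * called.sum(axis=0), 1)
        pops.append(pop)
        ranges.append(grp["range"].iloc[0])
        sizes.append(len(grp))
        cols.append(p)
    if not pops:
        raise ValueError("no populations with enough samples")
    return PopFrequencyTable(
        populations=pops, ranges=ranges,
        freqs=np.column_stack(cols), sizes=np.array(sizes),
    )


def standardize_frequencies(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """p~_j = (p_j - pbar) / sqrt(pbar (1 - pbar)) with pbar the
    across-population mean. Returns (p~, valid mask); SNPs monomorphic
    across all populations are invalid."""
    pbar = freqs.mean(axis=1)
    valid = (pbar > 0) & (pbar < 1)
    denom = np.sqrt(np.clip(pbar * (1 - pbar), 1e-12, None))
    ptil = (freqs - pbar[:, None]) / denom[:, None]
    return ptil, valid


def estimate_omega(
    table: PopFrequencyTable,
    background_idx: np.ndarray,
    shrink: float = 0.05,
    min_snps: int = 100,
) -> OmegaMatrix:
    """Among-population covariance of standardized frequencies over the
    background SNPs, shrunk toward its diagonal for invertibility.

    Because standardization centers on the across-population mean, the raw
    covariance is singular (rows of p~ sum to ~0); the diagonal shrinkage
    Omega* = (1-w) Omega + w diag(Omega) restores invertibility.
    """
    ptil, valid = standardize_frequencies(table.freqs[background_idx])
    ptil = ptil[valid]
    if len(ptil) < min_snps:
        raise ValueError(f"need >= {min_snps} polymorphic background SNPs, got {len(ptil)}")
    omega = (ptil.T @ ptil) / len(ptil)
    if np.trace(omega) < 1e-10:
        raise ValueError("degenerate Omega: population frequencies are "
                         "(numerically) identical at every background SNP")
    shrunk = (1 - shrink) * omega + shrink * np.diag(np.diag(omega))
    cond = np.linalg.cond(shrunk)
    if not np.isfinite(cond) or cond > 1e10:
        raise ValueError(f"Omega singular after shrinkage (cond={cond:.3g}); "
                         "populations may be identical")
    return OmegaMatrix(omega=shrunk, inverse=np.linalg.inv(shrunk),
                       n_snps=len(ptil), shrink=shrink)


def xtx_surrogate(freqs: np.ndarray, omega: OmegaMatrix) -> np.ndarray:
    """Whitened divergence XtX* = (J/(J-1)) p~' Omega^-1 p~ per SNP.

    The J/(J-1) factor corrects the degree of freedom absorbed by using the
    across-population mean as the ancestral-frequency estimate, so the null
    expectation is the number of populations J (the standard XtX
    convention). Monomorphic SNPs are returned as NaN.
    """
    f = np.atleast_2d(freqs)
    ptil, valid = standardize_frequencies(f)
    j = f.shape[1]
    q = np.einsum("sj,jk,sk->s", ptil, omega.inverse, ptil)
    q = q * (j / (j - 1.0))
    return np.where(valid, q, np.nan)


def contrast_surrogate(
    freqs: np.ndarray, omega: OmegaMatrix, group_labels: np.ndarray
) -> np.ndarray:
    """Standardized squared group contrast C* = (c'p~)^2 / (c'Omega c).

    ``group_labels`` holds two distinct labels over populations; the
    contrast vector has entries 1/J1 and -1/J2. Approximately chi-square(1)
    under the null; invariant to swapping the groups.
    """
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(uniq)}")
    g1, g2 = labels == uniq[0], labels == uniq[1]
    if g1.sum() == 0 or g2.sum() == 0:
        raise ValueError("a contrast group is empty")
    c = np.where(g1, 1.0 / g1.sum(), -1.0 / g2.sum())
    f = np.atleast_2d(freqs)
    ptil, valid = standardize_frequencies(f)
    denom = float(c @ omega.omega @ c)
    num = (ptil @ c) ** 2
    return np.where(valid, num / denom, np.nan)


def kendall_tau_eaa(freqs: np.ndarray, env: np.ndarray) -> np.ndarray:
    """Kendall tau-b between per-population frequency and an environmental
    value, per SNP. Requires >= 4 populations; constant environments are
    rejected."""
    env = np.asarray(env, dtype=float)
    if len(env) < 4:
        raise ValueError("need >= 4 populations for a rank correlation")
    if np.all(env == env[0]):
        raise ValueError("environment variable is constant")
    f = np.atleast_2d(freqs)
    out = np.empty(f.shape[0])
    for s in range(f.shape[0]):
        if np.all(f[s] == f[s, 0]):
            out[s] = np.nan
            continue
        out[s] = sps.kendalltau(f[s], env).statistic
    return out


def fay_wu_h(derived_counts: np.ndarray, n: int) -> float:
    """Fay & Wu's H = theta_pi - theta_H from unfolded SFS counts.

    ``derived_counts`` are per-site derived-allele counts i with
    1 <= i <= n-1 on n sampled chromosomes;
    theta_pi = sum S_i 2 i (n-i) / (n (n-1)),
    theta_H  = sum S_i 2 i^2 / (n (n-1)).
    With no segregating sites H is NaN (undefined).
    """
    i = np.asarray(derived_counts, dtype=float)
    if len(i) == 0:
        return np.nan
    if np.any((i < 1) | (i > n - 1)):
        raise ValueError("derived counts must lie in [1, n-1]")
    denom = n * (n - 1.0)
    theta_pi = np.sum(2.0 * i * (n - i) / denom)
    theta_h = np.sum(2.0 * i * i / denom)
    return float(theta_pi - theta_h)


def fay_wu_h_windows(
    gm: GenotypeMatrix, windows: list[GenomicWindow]
) -> pd.DataFrame:
    """H per window from polarized, fully-called sites.

    Sites with unknown ancestral state, any missing genotype, or a
    non-segregating derived count are excluded; excluded counts are
    reported. n is 2 x the sample count.
    """
    n = 2 * gm.n_samples
    d = gm.dosages
    anc = gm.sites["ancestral"].to_numpy()
    complete = ~(d == MISSING).any(axis=0)
    alt_counts = d.clip(min=0).sum(axis=0)
    derived = np.where(anc == "ref", alt_counts, n - alt_counts).astype(float)
    polarized = anc != "unknown"
    seg = (derived >= 1) & (derived <= n - 1)
    usable = complete & polarized & seg
    win_of_site = assign_sites_to_windows(gm, windows)

    rows = []
    for w in windows:
        in_w = win_of_site == w.window_id
        use = in_w & usable
        h = fay_wu_h(derived[use], n) if use.any() else np.nan
        rows.append({
            "window_id": w.window_id, "chrom": w.chrom, "start": w.start,
            "end": w.end, "H": h, "n_sites": int(use.sum()),
            "n_excluded": int((in_w & ~usable).sum()),
        })
    return pd.DataFrame(rows)


def gwas_scan(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    background_idx: np.ndarray,
    n_pcs: int = 2,
) -> pd.DataFrame:
    """Per-SNP linear association of a phenotype with dosage, adjusted for
    the top principal components of a background-SNP covariance matrix.

    Phenotype and dosages are residualized against [1, PC1..PCk]; the
    partial correlation yields a two-sided t-test p-value per SNP. Constant
    dosages are skipped (NaN).
    """
    y = np.asarray(phenotype, dtype=float)
    n = gm.n_samples
    if n < 30:
        raise ValueError("phenotype must cover >= 30 samples")

    from .local_pca import _imputed_centered

    xb = _imputed_centered(gm, np.asarray(background_idx))
    u, s, _ = np.linalg.svd(xb, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    cov = np.column_stack([np.ones(n), pcs])
    proj = cov @ np.linalg.pinv(cov)
    ry = y - proj @ y

    g = _imputed_centered(gm, np.arange(gm.n_sites))
    rg = g - proj @ g
    sd = rg.std(axis=0)
    ok = sd > 0
    ry_sd = ry.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rg.T @ ry) / (n * sd * ry_sd)
    df = n - 2 - n_pcs
    r = np.clip(r, -0.999999999, 0.999999999)
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * sps.t.sf(np.abs(t), df)
    p = np.where(ok, p, np.nan)
    return pd.DataFrame({
        "chrom": gm.sites["chrom"], "pos": gm.sites["pos"],
        "beta_t": np.where(ok, t, np.nan), "p": p,
    })


def empirical_p(values: np.ndarray, larger_is_extreme: bool = True) -> np.ndarray:
    """Rank-based empirical p-values in (0, 1]: rank/(N+1), NaN-aware."""
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    out = np.full(v.shape, np.nan)
    x = -v[ok] if larger_is_extreme else v[ok]
    ranks = sps.rankdata(x, method="average")
    out[ok] = ranks / (ok.sum() + 1.0)
    return out


def wza_window(
    snp_p: np.ndarray,
    snp_mean_freqs: np.ndarray,
    site_window_ids: np.ndarray,
    windows: list[GenomicWindow],
    min_snps: int = 2,
) -> pd.DataFrame:
    """Weighted-Z aggregation of per-SNP empirical p-values into windows.

    z_i = Phi^-1(1 - p_i), weight w_i = pbar_i (1 - pbar_i),
    Z_W = sum w_i z_i / sqrt(sum w_i^2). Window empirical p is the rank of
    Z_W among windows with >= ``min_snps`` usable SNPs; thinner windows are
    flagged and excluded from the ranking.
    """
    p = np.asarray(snp_p, dtype=float)
    if np.any((p <= 0) | (p >= 1) & np.isfinite(p)):
        raise ValueError("per-SNP empirical p-values must lie in (0, 1)")
    pbar = np.asarray(snp_mean_freqs, dtype=float)
    z = sps.norm.isf(p)
    w = pbar * (1 - pbar)

    rows = []
    for win in windows:
        in_w = np.flatnonzero((site_window_ids == win.window_id) & np.isfinite(p))
        if len(in_w) == 0:
            zw, nsnp = np.nan, 0
        else:
            ww, zz = w[in_w], z[in_w]
            zw = float(np.sum(ww * zz) / np.sqrt(np.sum(ww**2)))
            nsnp = len(in_w)
        rows.append({"window_id": win.window_id, "chrom": win.chrom,
                     "start": win.start, "end": win.end,
                     "Z_W": zw, "n_snps": nsnp, "flagged": nsnp < min_snps})
    out = pd.DataFrame(rows)
    usable = ~out["flagged"] & np.isfinite(out["Z_W"])
    out["empirical_p"] = np.nan
    out.loc[usable, "empirical_p"] = empirical_p(out.loc[usable, "Z_W"].to_numpy())
    return out
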