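"""Windowed local PCA, MDS embedding and corner-outlier candidate regions.

The signature of a large polymorphic structural variant is a run of genomic
windows whose sample covariance structure disagrees with the genome-wide
pattern. We compute a samples x samples covariance matrix per window,
measure pairwise dissimilarity between windows as the Frobenius distance
between trace-normalized rank-k approximations of their covariances, embed
the windows with classical (Torgerson) MDS on 5 axes, and flag windows in
the corners of each axis pair. Runs of same-corner outlier windows become
candidate haploblock regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomicWindow, GenotypeMatrix, assign_sites_to_windows

logger = logging.getLogger(__name__)

__all__ = [
    "WindowPCA",
    "MDSMap",
    "CandidateRegion",
    "window_covariance",
    "window_pca",
    "window_distance",
    "pairwise_window_distances",
    "mds_embed",
    "corner_outliers",
    "merge_candidates",
    "find_candidate_regions",
]


@dataclass
class WindowPCA:
    window: GenomicWindow
    eigenvalues: np.ndarray      # descending, length k
    eigenvectors: np.ndarray     # samples x k, orthonormal
    n_sites: int
    trace: float                 # trace of the full covariance


@dataclass
class MDSMap:
    windows: list[GenomicWindow]
    coordinates: np.ndarray      # windows x n_axes, column means ~ 0
    eigenvalues: np.ndarray
    degenerate: bool = False
    provenance: str = "frobenius rank-k trace-normalized covariance distance"


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    window_ids: list[int] = field(default_factory=list)
    corner: str = ""

    @property
    def n_windows(self) -> int:
        return len(self.window_ids)


def _imputed_centered(gm: GenotypeMatrix, site_idx: np.ndarray) -> np.ndarray:
    """Samples x sites float matrix, missing dosages mean-imputed, centered
    per site. Imputation happens only here (covariance work), never in
    frequency estimates."""
    x = gm.dosages[:, site_idx].astype(float)
    miss = x < 0
    if miss.any():
        x[miss] = np.nan
        mu = np.nanmean(x, axis=0)
        inds = np.where(miss)
        x[inds] = mu[inds[1]]
    return x - x.mean(axis=0)


def window_covariance(
    gm: GenotypeMatrix,
    window: GenomicWindow,
    min_sites: int = 20,
    scale: bool = False,
    site_idx: np.ndarray | None = None,
) -> np.ndarray | None:
    """Samples x samples covariance over the window's SNPs, or None if the
    window holds fewer than ``min_sites`` polymorphic SNPs.

    Each site is centered; with ``scale=True`` it is also divided by
    sqrt(p(1-p)). The result is sum_s x_s x_s^T / n_sites.
    """
    if site_idx is None:
        site_idx = np.flatnonzero(
            gm.site_mask_in_region(window.chrom, window.start, window.end)
        )
    x = _imputed_centered(gm, site_idx)
    poly = x.std(axis=0) > 0
    x = x[:, poly]
    if x.shape[1] < min_sites:
        logger.debug("window %s skipped: %d sites < %d", window.window_id, x.shape[1], min_sites)
        return None
    if scale:
        p = gm.alt_freqs()[site_idx[poly]]
        x = x / np.sqrt(p * (1.0 - p))
    return (x @ x.T) / x.shape[1]


def window_pca(
    gm: GenotypeMatrix,
    window: GenomicWindow,
    k: int = 2,
    min_sites: int = 20,
    site_idx: np.ndarray | None = None,
) -> WindowPCA | None:
    if site_idx is None:
        site_idx = np.flatnonzero(
            gm.site_mask_in_region(window.chrom, window.start, window.end)
        )
    cov = window_covariance(gm, window, min_sites=min_sites, site_idx=site_idx)
    if cov is None:
        return None
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    return WindowPCA(
        window=window,
        eigenvalues=np.maximum(vals[order], 0.0),
        eigenvectors=vecs[:, order],
        n_sites=int(len(site_idx)),
        trace=float(np.trace(cov)),
    )


def _factor(wpca: WindowPCA) -> np.ndarray:
    """U * sqrt(lambda / trace): the rank-k trace-normalized covariance is
    F F^T for this factor."""
    if wpca.trace <= 0:
        return np.zeros_like(wpca.eigenvectors)
    return wpca.eigenvectors * np.sqrt(wpca.eigenvalues / wpca.trace)


def window_distance(a: WindowPCA, b: WindowPCA, k: int | None = None) -> float:
    """Frobenius distance between the rank-k trace-normalized covariances."""
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise ValueError("window PCAs computed on different sample sets")
    fa, fb = _factor(a), _factor(b)
    if k is not None:
        fa, fb = fa[:, :k], fb[:, :k]
    naa = float(np.sum((fa.T @ fa) ** 2))
    nbb = float(np.sum((fb.T @ fb) ** 2))
    nab = float(np.sum((fa.T @ fb) ** 2))
    return float(np.sqrt(max(naa + nbb - 2.0 * nab, 0.0)))


def pairwise_window_distances(wpcas: list[WindowPCA]) -> np.ndarray:
    """Full symmetric distance matrix via the factor-product identity
    ||A - B||_F^2 = ||A||_F^2 + ||B||_F^2 - 2 ||Fa^T Fb||_F^2."""
    m = len(wpcas)
    factors = [_factor(w) for w in wpcas]
    norms = np.array([np.sum((f.T @ f) ** 2) for f in factors])
    d2 = np.empty((m, m))
    for i in range(m):
        fi = factors[i]
        for j in range(i, m):
            nab = np.sum((fi.T @ factors[j]) ** 2)
            d2[i, j] = d2[j, i] = norms[i] + norms[j] - 2.0 * nab
    return np.sqrt(np.maximum(d2, 0.0))


def mds_embed(distances: np.ndarray, windows: list[GenomicWindow], n_axes: int = 5) -> MDSMap:
    """Classical (Torgerson) MDS: eigendecompose B = -1/2 J D^2 J.

    Axes are ordered by eigenvalue; each axis's sign is fixed so its
    largest-magnitude loading is positive, making runs reproducible.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    m = d.shape[0]
    n_axes = min(n_axes, m - 1) if m > 1 else 1
    j = np.eye(m) - np.ones((m, m)) / m
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    degenerate = bool(np.all(np.abs(d) < 1e-12))
    coords = np.zeros((m, n_axes))
    for ax in range(n_axes):
        lam = max(vals[ax], 0.0)
        v = vecs[:, ax] * np.sqrt(lam)
        i = np.argmax(np.abs(v))
        if v[i] < 0:
            v = -v
        coords[:, ax] = v
    if degenerate:
        logger.warning("all-zero distances: degenerate MDS map")
    return MDSMap(windows=list(windows), coordinates=coords,
                  eigenvalues=vals[:n_axes], degenerate=degenerate)


_DIRS = {
    "++": (1.0, 1.0),
    "+-": (1.0, -1.0),
    "-+": (-1.0, 1.0),
    "--": (-1.0, -1.0),
}


def corner_outliers(mds: MDSMap, tail: float = 0.05) -> dict[str, np.ndarray]:
    """Windows in the diagonal corners of each MDS axis pair.

    For each unordered axis pair (i, j) and each diagonal direction
    u = (+-1, +-1)/sqrt(2), a window is an outlier if its projection onto u
    strictly exceeds the (1 - tail) quantile of all projections. Keys are
    labels like ``"1,2,++"``; values are window-index arrays into
    ``mds.windows``.
    """
    coords = mds.coordinates
    m, n_axes = coords.shape
    if m < 20 and tail < 1.0:
        logger.warning("corner outliers on only %d windows", m)
    out: dict[str, np.ndarray] = {}
    for i in range(n_axes):
        for j in range(i + 1, n_axes):
            for label, (ui, uj) in _DIRS.items():
                proj = (ui * coords[:, i] + uj * coords[:, j]) / np.sqrt(2.0)
                if tail >= 1.0:
                    idx = np.arange(m)
                else:
                    thr = np.quantile(proj, 1.0 - tail)
                    idx = np.flatnonzero(proj > thr)
                out[f"{i + 1},{j + 1},{label}"] = idx
    return out


def merge_candidates(
    outliers: dict[str, np.ndarray],
    windows: list[GenomicWindow],
    max_gap: int = 1,
    min_windows: int = 3,
) -> list[CandidateRegion]:
    """Merge same-chromosome, same-corner outlier windows into candidate
    regions; then union candidates that overlap across corners.

    The gap between outlier windows is counted in ordinal positions among the
    analyzed windows of the chromosome (windows skipped for low SNP counts do
    not break runs). Regions supported by fewer than ``min_windows`` analyzed
    windows are dropped.
    """
    # ordinal position of each analyzed window within its chromosome
    ordinal: dict[int, int] = {}
    chrom_of: dict[int, str] = {}
    counters: dict[str, int] = {}
    for pos, w in enumerate(windows):
        counters.setdefault(w.chrom, 0)
        ordinal[pos] = counters[w.chrom]
        chrom_of[pos] = w.chrom
        counters[w.chrom] += 1

    raw: list[CandidateRegion] = []
    for corner, idx in outliers.items():
        by_chrom: dict[str, list[int]] = {}
        for i in idx:
            by_chrom.setdefault(chrom_of[int(i)], []).append(int(i))
        for chrom, members in by_chrom.items():
            members.sort(key=lambda i: ordinal[i])
            run = [members[0]]
            for i in members[1:]:
                if ordinal[i] - ordinal[run[-1]] <= max_gap + 1:
                    run.append(i)
                else:
                    raw.append(_region_from_run(run, windows, corner))
                    run = [i]
            raw.append(_region_from_run(run, windows, corner))

    raw = [r for r in raw if r.n_windows >= min_windows]

    # union overlapping candidates from different corners
    raw.sort(key=lambda r: (r.chrom, r.start))
    merged: list[CandidateRegion] = []
    for reg in raw:
        if merged and merged[-1].chrom == reg.chrom and reg.start < merged[-1].end:
            prev = merged[-1]
            keep = prev if prev.n_windows >= reg.n_windows else reg
            merged[-1] = CandidateRegion(
                chrom=prev.chrom,
                start=min(prev.start, reg.start),
                end=max(prev.end, reg.end),
                window_ids=sorted(set(prev.window_ids) | set(reg.window_ids)),
                corner=keep.corner,
            )
        else:
            merged.append(reg)
    return merged


def _region_from_run(run: list[int], windows: list[GenomicWindow], corner: str) -> CandidateRegion:
    ws = [windows[i] for i in run]
    return CandidateRegion(
        chrom=ws[0].chrom,
        start=min(w.start for w in ws),
        end=max(w.end for w in ws),
        window_ids=[w.window_id for w in ws],
        corner=corner,
    )


def find_candidate_regions(
    gm: GenotypeMatrix,
    contig_lengths: dict[str, int],
    window_size: int = 100_000,
    n_axes: int = 5,
    tail: float = 0.05,
    k: int = 2,
    min_sites: int = 20,
    max_gap: int = 1,
    min_windows: int = 3,
) -> tuple[list[CandidateRegion], MDSMap]:
    """End-to-end candidate nomination: tile, local PCA, MDS, corners, merge."""
    from .io_formats import tile_windows

    windows = tile_windows(contig_lengths, window_size)
    win_of_site = assign_sites_to_windows(gm, windows)
    wpcas: list[WindowPCA] = []
    kept: list[GenomicWindow] = []
    for w in windows:
        site_idx = np.flatnonzero(win_of_site == w.window_id)
        if len(site_idx) < min_sites:
            continue
        wp = window_pca(gm, w, k=k, min_sites=min_sites, site_idx=site_idx)
        if wp is None:
            continue
        wpcas.append(wp)
        kept.append(w)
    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} windows with >= {min_sites} SNPs")
    d = pairwise_window_distances(wpcas)
    mds = mds_embed(d, kept, n_axes=n_axes)
    outliers = corner_outliers(mds, tail=tail)
    cands = merge_candidates(outliers, kept, max_gap=max_gap, min_windows=min_windows)
    return cands, mds
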