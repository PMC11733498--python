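"""Omega estimation, XtX*/contrast surrogates, tau, Fay & Wu's H, GWAS, WZA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from haploscan.io_formats import GenomicWindow, GenotypeMatrix
from haploscan.scans import (
    OmegaMatrix,
    contrast_surrogate,
    empirical_p,
    estimate_omega,
    fay_wu_h,
    fay_wu_h_windows,
    gwas_scan,
    kendall_tau_eaa,
    population_frequencies,
    standardize_frequencies,
    wza_window,
    xtx_surrogate,
)


def _island_freqs(rng, n_snps, n_pops, F=0.1):
    pi = rng.uniform(0.05, 0.95, n_snps)
    return rng.beta(pi[:, None] * (1 - F) / F, (1 - pi[:, None]) * (1 - F) / F,
                    size=(n_snps, n_pops))


@pytest.fixture(scope="module")
def omega_setup():
    rng = np.random.default_rng(0)
    freqs = _island_freqs(rng, 12_000, 10)
    bg = np.arange(10_000)
    table_like = type("T", (), {"freqs": freqs})
    omega = estimate_omega(table_like, bg)
    return freqs, bg, omega


def test_omega_diagonal_tracks_drift_intensity(omega_setup):
    """Island model: diag(Omega) ~ F (1 - 1/J) from the Beta moment."""
    _, _, omega = omega_setup
    F, J = 0.1, 10
    assert np.mean(np.diag(omega.omega)) == pytest.approx(F * (1 - 1 / J), rel=0.1)


def test_omega_permutation_equivariance():
    rng = np.random.default_rng(1)
    freqs = _island_freqs(rng, 2000, 6)
    t = type("T", (), {"freqs": freqs})
    om = estimate_omega(t, np.arange(2000))
    perm = rng.permutation(6)
    t2 = type("T", (), {"freqs": freqs[:, perm]})
    om2 = estimate_omega(t2, np.arange(2000))
    assert np.allclose(om2.omega, om.omega[np.ix_(perm, perm)], atol=1e-12)


def test_omega_degenerate_identical_populations():
    freqs = np.repeat(np.random.default_rng(2).uniform(0.2, 0.8, (500, 1)), 5, axis=1)
    t = type("T", (), {"freqs": freqs})
    with pytest.raises(ValueError):
        estimate_omega(t, np.arange(500))


def test_xtx_quadratic_form_identities():
    omega = OmegaMatrix(omega=np.eye(4), inverse=np.eye(4), n_snps=100, shrink=0.0)
    # p~ = 0 (all populations at the mean) -> 0
    f = np.full((1, 4), 0.5)
    assert xtx_surrogate(f, omega)[0] == pytest.approx(0.0, abs=1e-12)
    # known standardized vector: quadratic form recovered (with J/(J-1) dof factor)
    f2 = np.array([[0.6, 0.4, 0.5, 0.5]])
    ptil, _ = standardize_frequencies(f2)
    expected = float(ptil[0] @ ptil[0]) * 4 / 3
    assert xtx_surrogate(f2, omega)[0] == pytest.approx(expected, abs=1e-12)
    # monomorphic SNP undefined
    assert np.isnan(xtx_surrogate(np.zeros((1, 4)), omega)[0])


def test_xtx_and_contrast_invariant_to_allele_relabeling(omega_setup):
    freqs, _, omega = omega_setup
    sub = freqs[10_000:10_200]
    labels = np.array(["a"] * 5 + ["b"] * 5)
    assert np.allclose(xtx_surrogate(sub, omega), xtx_surrogate(1 - sub, omega),
                       atol=1e-9, equal_nan=True)
    assert np.allclose(contrast_surrogate(sub, omega, labels),
                       contrast_surrogate(1 - sub, omega, labels),
                       atol=1e-9, equal_nan=True)
    # swapping group labels leaves C* unchanged
    swapped = np.where(labels == "a", "b", "a")
    assert np.allclose(contrast_surrogate(sub, omega, labels),
                       contrast_surrogate(sub, omega, swapped), atol=1e-12,
                       equal_nan=True)


def test_xtx_null_mean_near_J(omega_setup):
    freqs, bg, omega = omega_setup
    fresh = freqs[10_000:]
    xt = xtx_surrogate(fresh, omega)
    assert np.nanmean(xt) == pytest.approx(10.0, rel=0.05)


def test_contrast_null_chisquare(omega_setup):
    freqs, _, omega = omega_setup
    fresh = freqs[10_000:]
    labels = np.array(["a"] * 5 + ["b"] * 5)
    cs = contrast_surrogate(fresh, omega, labels)
    cs = cs[np.isfinite(cs)]
    ks = sps.kstest(cs, "chi2", args=(1,))
    assert ks.pvalue > 0.01
    # equal group means -> 0
    f_eq = np.tile(np.array([[0.3] * 10]), (1, 1))
    assert contrast_surrogate(f_eq, omega, labels)[0] == pytest.approx(0.0, abs=1e-12)


def test_contrast_group_errors(omega_setup):
    _, _, omega = omega_setup
    with pytest.raises(ValueError, match="2 groups"):
        contrast_surrogate(np.full((1, 10), 0.4), omega, np.array(["a"] * 10))


def test_kendall_tau_against_pair_counting_oracle():
    def tau_b_oracle(x, y):
        n = len(x)
        conc = disc = tx = ty = 0
        for i in range(n):
            for j in range(i + 1, n):
                dx, dy = x[i] - x[j], y[i] - y[j]
                if dx == 0 and dy == 0:
                    tx += 1; ty += 1
                elif dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx * dy > 0:
                    conc += 1
                else:
                    disc += 1
        n0 = n * (n - 1) / 2
        return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))

    env = np.array([1.0, 2.0, 2.5, 3.0, 4.0, 5.0])
    freqs = np.array([
        [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],     # perfectly concordant
        [0.6, 0.5, 0.4, 0.3, 0.2, 0.1],     # reversed
    ])
    taus = kendall_tau_eaa(freqs, env)
    assert taus[0] == pytest.approx(1.0, abs=1e-10)
    assert taus[1] == pytest.approx(-1.0, abs=1e-10)
    env_t = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])  # ties in env
    freqs_t = np.vstack([freqs, [0.2, 0.2, 0.5, 0.1, 0.9, 0.3]])  # ties in freqs too
    taus_t = kendall_tau_eaa(freqs_t, env_t)
    for s in range(3):
        assert taus_t[s] == pytest.approx(tau_b_oracle(freqs_t[s], env_t), abs=1e-10)
    with pytest.raises(ValueError, match="constant"):
        kendall_tau_eaa(freqs, np.ones(6))


def test_fay_wu_h_hand_summation():
    """n=5, SFS S=(3,1,2,1): theta_pi=3.4, theta_H=4.1, H=-0.7."""
    counts = [1] * 3 + [2] * 1 + [3] * 2 + [4] * 1
    assert fay_wu_h(np.array(counts), 5) == pytest.approx(-0.7, abs=1e-10)
    # oracle-style independent summation
    S = {1: 3, 2: 1, 3: 2, 4: 1}
    n = 5
    tp = sum(s * 2 * i * (n - i) for i, s in S.items()) / (n * (n - 1))
    th = sum(s * 2 * i * i for i, s in S.items()) / (n * (n - 1))
    assert fay_wu_h(np.array(counts), 5) == pytest.approx(tp - th, abs=1e-12)


def test_fay_wu_h_edge_cases():
    assert np.isnan(fay_wu_h(np.array([]), 10))
    # n=2: theta_pi == theta_H identically
    assert fay_wu_h(np.array([1, 1, 1]), 2) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        fay_wu_h(np.array([0]), 4)
    with pytest.raises(ValueError):
        fay_wu_h(np.array([4]), 4)


def test_fay_wu_h_window_additivity():
    """H over pooled sites equals the weighted combination of per-window
    SFS sums (additivity of the SFS)."""
    rng = np.random.default_rng(0)
    n_samp = 12
    dos = rng.binomial(2, rng.uniform(0.1, 0.9, 200), size=(n_samp, 200)).astype(np.int8)
    keep = (dos.sum(0) > 0) & (dos.sum(0) < 2 * n_samp)
    dos = dos[:, keep]
    pos = np.arange(1, dos.shape[1] + 1) * 40  # spans two 4-kb windows
    sites = pd.DataFrame({"chrom": "chr1", "pos": pos, "ref": "A", "alt": "G",
                          "ancestral": "ref", "missing_frac": 0.0})
    gm = GenotypeMatrix([f"s{i}" for i in range(n_samp)], sites, dos)
    wins = [GenomicWindow("chr1", 0, 4000, 0), GenomicWindow("chr1", 4000, 8000, 1)]
    per_win = fay_wu_h_windows(gm, wins)
    pooled = fay_wu_h(dos.sum(axis=0).astype(float), 2 * n_samp)
    assert per_win["H"].sum() == pytest.approx(pooled, abs=1e-10)


def test_gwas_null_uniform_and_location_invariant(null_ds):
    gm = null_ds.gm.take_sites(np.arange(3000))
    rng = np.random.default_rng(1)
    y = rng.normal(size=gm.n_samples)
    bg = np.arange(2000, 3000)
    res = gwas_scan(gm, y, bg)
    p = res["p"].dropna().to_numpy()
    assert sps.kstest(p, "uniform").pvalue > 0.01
    res2 = gwas_scan(gm, y + 100.0, bg)
    assert np.allclose(res["p"].to_numpy(), res2["p"].to_numpy(), atol=1e-10,
                       equal_nan=True)


def test_gwas_detects_planted_haploblock_effect(full_ds):
    from haploscan.io_formats import sites_in_intervals

    gm = full_ds.gm
    meta = full_ds.samples.aligned(gm.sample_ids)
    y = meta["flowering_onset"].to_numpy()
    in_hb = sites_in_intervals(gm, full_ds.truth.haploblocks)
    bg = np.flatnonzero(~in_hb)[:2000]
    res = gwas_scan(gm, y, bg)
    p = res["p"].to_numpy()
    thr = np.nanquantile(p, 0.001)
    hit_rate_hb = np.nanmean(p[in_hb] <= thr)
    hit_rate_bg = np.nanmean(p[~in_hb] <= thr)
    assert hit_rate_hb > 10 * max(hit_rate_bg, 1e-6)


def test_empirical_p_ranks():
    p = empirical_p(np.array([3.0, 1.0, 2.0]))
    assert np.allclose(p, [1 / 4, 3 / 4, 2 / 4])
    assert np.isnan(empirical_p(np.array([1.0, np.nan]))[1])


def test_wza_window_formulas():
    wins = [GenomicWindow("chr1", 0, 100, 0), GenomicWindow("chr1", 100, 200, 1)]
    # single-SNP window: Z_W = z1
    p = np.array([0.02, 0.5, 0.3, 0.7])
    pbar = np.array([0.5, 0.3, 0.2, 0.4])
    site_win = np.array([0, 1, 1, 1])
    out = wza_window(p, pbar, site_win, wins, min_snps=1)
    z = sps.norm.isf(p)
    assert out.loc[0, "Z_W"] == pytest.approx(z[0], abs=1e-10)
    # unequal weights: direct formula
    w = pbar[1:] * (1 - pbar[1:])
    expected = np.sum(w * z[1:]) / np.sqrt(np.sum(w**2))
    assert out.loc[1, "Z_W"] == pytest.approx(expected, abs=1e-10)
    # equal weights, m SNPs: Z_W = sqrt(m) * mean(z)
    p_eq = np.array([0.1, 0.2, 0.4])
    out_eq = wza_window(p_eq, np.full(3, 0.3), np.zeros(3, int), wins[:1], min_snps=1)
    z_eq = sps.norm.isf(p_eq)
    assert out_eq.loc[0, "Z_W"] == pytest.approx(np.sqrt(3) * z_eq.mean(), abs=1e-10)


def test_wza_flags_thin_windows_and_null_moments():
    rng = np.random.default_rng(0)
    n = 10_000
    wins = [GenomicWindow("chr1", i * 100, (i + 1) * 100, i) for i in range(n // 10)]
    site_win = np.repeat(np.arange(n // 10), 10)
    p = rng.uniform(1e-9, 1 - 1e-9, n)
    pbar = rng.uniform(0.05, 0.95, n)
    out = wza_window(p, pbar, site_win, wins)
    zw = out["Z_W"].to_numpy()
    assert abs(np.mean(zw)) < 0.05 and abs(np.std(zw) - 1) < 0.05
    p_emp = out["empirical_p"].dropna()
    assert p_emp.min() > 0 and p_emp.max() <= 1
    out_thin = wza_window(p[:1], pbar[:1], np.zeros(1, int), wins[:1], min_snps=2)
    assert bool(out_thin.loc[0, "flagged"]) and np.isnan(out_thin.loc[0, "empirical_p"])


def test_population_frequencies_excludes_tiny_populations(small_ds):
    import pandas as pd

    meta = small_ds.samples.table.copy()
    # shrink one population below the threshold
    drop = meta[meta["population"] == "pop01"].index[2:]
    meta2 = meta.drop(index=drop)
    from haploscan.io_formats import SampleFrame

    keep_ids = [s for s in small_ds.gm.sample_ids if s in meta2.index]
    gm = small_ds.gm.take_samples([small_ds.gm.sample_ids.index(s) for s in keep_ids])
    table = population_frequencies(gm, SampleFrame(meta2), min_n=3)
    assert "pop01" not in table.populations
    assert table.freqs.shape[1] == len(table.populations)
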