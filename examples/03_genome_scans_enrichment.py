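"""Whitened differentiation scans, weighted-Z windows and haploblock
enrichment.

Population allele frequencies are standardized and whitened by Omega (their
covariance over 10,000 background SNPs), giving a per-SNP divergence
statistic XtX* with null mean J and a native-vs-invaded contrast statistic
C* ~ chi-square(1) under drift alone. Per-SNP empirical p-values are
aggregated into 100-kbp weighted-Z windows, and haploblock windows are
tested for enrichment among scan outliers.
"""

import numpy as np

from haploscan import SimulationConfig, simulate_dataset
from haploscan.enrichment import (
    haploblock_shift_test, hypergeom_enrichment, windows_in_haploblock,
)
from haploscan.io_formats import (
    AnnotationSet, assign_sites_to_windows, sample_background_snps, tile_windows,
)
from haploscan.scans import (
    contrast_surrogate, empirical_p, estimate_omega, population_frequencies,
    wza_window, xtx_surrogate,
)

cfg = SimulationConfig(seed=11)
ds = simulate_dataset(cfg, with_coding=False)
table = population_frequencies(ds.gm, ds.samples)
ann = AnnotationSet(haploblocks=list(ds.truth.haploblocks))
bg = sample_background_snps(ds.gm, ann, 10_000, seed=2)
omega = estimate_omega(table, bg)
print(f"Omega from {omega.n_snps} background SNPs over J={table.n_pops} "
      f"populations (mean diagonal {np.mean(np.diag(omega.omega)):.3f} "
      f"~ drift F x (1-1/J))")

xtx = xtx_surrogate(table.freqs, omega)
print(f"mean XtX* over background SNPs: {np.nanmean(xtx[bg]):.2f} "
      f"(null expectation J = {table.n_pops}; values above it mark "
      "divergence beyond drift)")

labels = np.array(["native" if r == "native" else "invaded" for r in table.ranges])
c2 = contrast_surrogate(table.freqs, omega, labels)
print(f"native-vs-invaded contrast C*: background mean "
      f"{np.nanmean(c2[bg]):.2f} (~1 under the chi-square(1) null)")

windows = tile_windows(cfg.contig_lengths(), 100_000)
win_of_site = assign_sites_to_windows(ds.gm, windows)
p = empirical_p(xtx)
wza = wza_window(p, table.freqs.mean(axis=1), win_of_site, windows)
usable = wza[np.isfinite(wza["empirical_p"])].reset_index(drop=True)
wins = [w for w in windows if w.window_id in set(usable["window_id"])]
block_rows = windows_in_haploblock(wins, ds.truth.haploblocks[0])
block_ids = set(block_rows.tolist())
outliers = set(usable.index[usable["empirical_p"] <= 0.05].tolist())

res = hypergeom_enrichment(outliers, block_ids, len(usable))
shift = haploblock_shift_test(usable["Z_W"].to_numpy(),
                              np.isin(np.arange(len(usable)), list(block_ids)))
print(f"\n{len(outliers)} outlier windows (5% tail) among {len(usable)}; "
      f"{res.n_overlap}/{res.n_in_block} haploblock windows are outliers")
print(f"hypergeometric enrichment p = {res.p:.3g}; Mann-Whitney shift "
      f"p = {shift['p']:.3g} {shift['stars']} ({shift['higher']} windows "
      "score higher)")
print("Both tests firing on the planted block shows the clinal haploblock "
      "dominates the adaptation scan, as expected for a large-effect "
      "structural variant.")
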