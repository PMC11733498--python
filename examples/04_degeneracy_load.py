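"""Codon degeneracy classification and derived-allele genetic load.

Builds the 0-fold / 4-fold degeneracy map from the simulated coding contig
(FASTA + GFF3, including a minus-strand gene and a phased multi-exon gene),
then estimates per-range genetic load as the mean derived-allele frequency
at zero-fold sites, with equal-n downsampling and a 20%-of-sites bootstrap
for confidence intervals. Four-fold sites serve as the neutral reference.
"""

from haploscan import SimulationConfig, simulate_dataset
from haploscan.degeneracy import build_degeneracy_map, derived_frequency_load

cfg = SimulationConfig(seed=4, n_pops=6, n_per_pop=10, n_chroms=1,
                       chrom_length=4_000_000, n_neutral_snps=2000,
                       haploblocks=[])
ds = simulate_dataset(cfg)

degmap = build_degeneracy_map(ds.fasta, ds.annotations)
counts = degmap["degeneracy"].value_counts()
print("degeneracy classes over the coding contig:")
print(counts.to_string())
print("(second codon positions are never 4-fold; ~ the 4-fold count comes "
      "from third positions of GGN-like codon families)")

meta = ds.samples.aligned(ds.load_gm.sample_ids)
groups = {r: list(g.index) for r, g in meta.groupby("range")}
n_down = min(len(v) for v in groups.values())
print(f"\nload per range (downsampled to n={n_down} per group):")
ests = derived_frequency_load(ds.load_gm, degmap, groups, n_down, seed=1)
for e in ests:
    print(f"  {e.group:>10} {e.site_class:>9}: mean derived freq "
          f"{e.mean_derived_freq:.4f}  95% CI [{e.ci_lower:.4f}, "
          f"{e.ci_upper:.4f}]  ({e.n_sites} sites)")
print("\nZero-fold means sitting well below four-fold means with "
      "non-overlapping CIs reflects purifying selection holding deleterious "
      "(amino-acid-changing) variants at low frequency.")
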