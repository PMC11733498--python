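"""Generator: drift moments, haploblock marker structure, traits, coding truth."""

import numpy as np
import pytest

from haploscan.simulate import (
    GeneSpec,
    HaploblockSpec,
    SimulationConfig,
    simulate_coding_genome,
    simulate_dataset,
    simulate_haploblock,
    simulate_neutral_background,
    simulate_traits,
)


def _cfg(**kw):
    base = dict(n_pops=8, n_per_pop=15, n_chroms=1, chrom_length=2_000_000,
                n_neutral_snps=3000, haploblocks=[], seed=0)
    base.update(kw)
    return SimulationConfig(**base)


def test_small_drift_collapses_to_shared_frequency():
    cfg = _cfg(drift_f=1e-6, n_neutral_snps=500)
    gm = simulate_neutral_background(cfg)
    pop = np.repeat(np.arange(cfg.n_pops), cfg.n_per_pop)
    freqs = np.stack([gm.dosages[pop == j].mean(axis=0) / 2 for j in range(cfg.n_pops)])
    # across-population variance should be pure binomial sampling noise
    expected_noise = (freqs.mean(axis=0) * (1 - freqs.mean(axis=0))) / (2 * cfg.n_per_pop)
    assert np.mean(freqs.var(axis=0)) < 2 * np.mean(expected_noise)


def test_drift_variance_matches_beta_moment():
    """Across-population variance of p approximates F pi (1-pi)."""
    cfg = _cfg(drift_f=0.5, n_per_pop=200, n_pops=30, n_neutral_snps=2000)
    rng = np.random.default_rng(1)
    F = cfg.drift_f
    pi = rng.uniform(0.05, 0.95, cfg.n_neutral_snps)
    p = rng.beta(pi * (1 - F) / F, (1 - pi) * (1 - F) / F, size=(cfg.n_pops, cfg.n_neutral_snps))
    ratio = p.var(axis=0, ddof=1).mean() / (F * (pi * (1 - pi))).mean()
    assert ratio == pytest.approx(1.0, rel=0.05)
    # and the generator's own output matches the same moment at large n
    gm = simulate_neutral_background(cfg)
    pop = np.repeat(np.arange(cfg.n_pops), cfg.n_per_pop)
    freqs = np.stack([gm.dosages[pop == j].mean(axis=0) / 2 for j in range(cfg.n_pops)])
    pbar = freqs.mean(axis=0)
    ratio2 = freqs.var(axis=0, ddof=1).mean() / (F * pbar * (1 - pbar)).mean()
    assert ratio2 == pytest.approx(1.0, rel=0.10)


def test_seeded_reproducibility():
    a = simulate_dataset(SimulationConfig(seed=5, n_pops=4, n_per_pop=5,
                                          n_neutral_snps=500, chrom_length=10**6,
                                          n_chroms=1, haploblocks=[]), with_coding=False)
    b = simulate_dataset(SimulationConfig(seed=5, n_pops=4, n_per_pop=5,
                                          n_neutral_snps=500, chrom_length=10**6,
                                          n_chroms=1, haploblocks=[]), with_coding=False)
    assert np.array_equal(a.gm.dosages, b.gm.dosages)
    assert a.gm.sites.equals(b.gm.sites)


def test_haploblock_markers_track_arrangement():
    cfg = _cfg()
    rng = np.random.default_rng(0)
    hb = HaploblockSpec(chrom="chr1", start=10**5, end=9 * 10**5, n_markers=200, eps=0.0)
    sites, dos, g, q, _ = simulate_haploblock(cfg, hb, rng)
    # eps=0: every marker column equals the arrangement dosage
    assert np.all(dos == g[:, None])
    # all-ancestral cline: zero marker heterozygosity
    hb0 = HaploblockSpec(chrom="chr1", start=10**5, end=9 * 10**5, n_markers=50,
                         eps=0.0, freqs=(0.0,) * cfg.n_pops)
    _, dos0, g0, _, _ = simulate_haploblock(cfg, hb0, rng)
    assert np.all(g0 == 0) and np.all(dos0 == 0)


def test_marker_noise_heterozygosity_expectations():
    """Heterokaryotypes heterozygous at ~(1 - eps) of markers; homokaryotypes
    at the eps level (eps/2 under the two-other-values resampling)."""
    cfg = _cfg(n_pops=2, n_per_pop=300)
    rng = np.random.default_rng(2)
    hb = HaploblockSpec(chrom="chr1", start=0, end=10**6, n_markers=200,
                        eps=0.02, freqs=(0.5, 0.5))
    _, dos, g, _, _ = simulate_haploblock(cfg, hb, rng)
    het = (dos == 1).mean(axis=1)
    assert het[g == 1].mean() == pytest.approx(0.98, abs=0.01)
    assert het[g != 1].mean() == pytest.approx(0.01, abs=0.01)


def test_overlapping_haploblock_interval_rejected():
    cfg = _cfg()
    rng = np.random.default_rng(0)
    from haploscan.io_formats import Interval

    hb = HaploblockSpec(chrom="chr1", start=0, end=10**6)
    with pytest.raises(ValueError, match="overlap"):
        simulate_haploblock(cfg, hb, rng, existing=[Interval("chr1", 5 * 10**5, 15 * 10**5)])


def test_trait_model_components():
    cfg = _cfg(n_neutral_snps=500)
    gm = simulate_neutral_background(cfg)
    rng = np.random.default_rng(3)
    n = gm.n_samples
    g_hb = rng.binomial(2, 0.5, n).astype(np.int8)

    cfg.traits = [__import__("haploscan.simulate", fromlist=["TraitSpec"]).TraitSpec(
        name="t", hb_effect=0.0, n_polygenic=0, resid_sd=1.0)]
    pheno, _ = simulate_traits(cfg, {"hb": g_hb}, gm, rng)
    assert pheno["t"].var() == pytest.approx(1.0, rel=0.3)

    cfg.traits = [__import__("haploscan.simulate", fromlist=["TraitSpec"]).TraitSpec(
        name="t", hb_effect=0.8, n_polygenic=0, resid_sd=1.0)]
    pheno, effects = simulate_traits(cfg, {"hb": g_hb}, gm, rng)
    slope, intercept = np.polyfit(g_hb, pheno["t"], 1)
    se = np.sqrt(pheno["t"].var() / (n * g_hb.var()))
    assert abs(slope - 0.8) < 3 * se
    assert effects["t"]["hb_effect"] == 0.8


def test_coding_genome_truth_matches_exhaustive_oracle():
    """Truth degeneracy equals a re-derivation from the emitted sequence via
    an independently coded genetic-code table."""
    from .codon_oracle import ORACLE_CODE, oracle_classify

    cfg = _cfg()
    cfg.genes = GeneSpec(n_genes=6, cds_length=120)
    fasta, ann, truth = simulate_coding_genome(cfg)
    strands = {tx.strand for tx in ann.transcripts}
    assert strands == {"+", "-"}
    assert any(len(tx.cds) > 1 and any(s.phase for s in tx.cds) for tx in ann.transcripts)

    comp = str.maketrans("ACGT", "TGCA")
    contig = fasta["chrC"]
    checked = 0
    for tx in ann.transcripts:
        segs = sorted(tx.cds, key=lambda s: s.start, reverse=(tx.strand == "-"))
        genomic = []
        for s in segs:
            pos = list(range(s.start, s.end))
            genomic.extend(pos[::-1] if tx.strand == "-" else pos)
        genomic = genomic[segs[0].phase:]
        bases = [contig[p] for p in genomic]
        if tx.strand == "-":
            bases = [b.translate(comp) for b in bases]
        lookup = dict(zip(truth["pos0"], truth["degeneracy"]))
        for i in range(0, len(genomic), 3):
            codon = "".join(bases[i:i + 3])
            for k in range(3):
                assert lookup[genomic[i + k]] == oracle_classify(codon, k, ORACLE_CODE)
                checked += 1
    assert checked >= 6 * 120


def test_dataset_round_trips_and_cline_truth(tmp_path):
    """Emitted VCF/FASTA/GFF3 parse back losslessly and truth arrangement
    frequencies match the specified cline within binomial error."""
    from haploscan.degeneracy import build_degeneracy_map, load_fasta
    from haploscan.io_formats import read_genotypes, read_gff3
    from haploscan.simulate import write_fasta, write_gff3
    from haploscan.io_formats import write_genotypes_vcf

    cfg = SimulationConfig(n_pops=10, n_per_pop=50, n_chroms=1, chrom_length=4_000_000,
                           n_neutral_snps=1000,
                           haploblocks=[HaploblockSpec(chrom="chr1", start=10**6,
                                                       end=2 * 10**6, n_markers=60)],
                           seed=9)
    ds = simulate_dataset(cfg)
    write_genotypes_vcf(ds.gm, tmp_path / "g.vcf")
    gm2 = read_genotypes(tmp_path / "g.vcf", min_maf=0.0, max_missing=1.0)
    assert np.array_equal(gm2.dosages, ds.gm.dosages)
    write_fasta(ds.fasta, tmp_path / "r.fa")
    write_gff3(ds.annotations, tmp_path / "g.gff3")
    m_mem = build_degeneracy_map(ds.fasta, ds.annotations)
    m_file = build_degeneracy_map(load_fasta(tmp_path / "r.fa"), read_gff3(tmp_path / "g.gff3"))
    assert m_mem[["chrom", "pos0", "degeneracy"]].equals(m_file[["chrom", "pos0", "degeneracy"]])

    g = ds.truth.arrangement_genotypes["hb-chr1a"]
    q_true = ds.truth.pop_arrangement_freqs["hb-chr1a"]
    pop = np.repeat(np.arange(cfg.n_pops), cfg.n_per_pop)
    for j in range(cfg.n_pops):
        q_hat = g[pop == j].mean() / 2
        se = np.sqrt(q_true[j] * (1 - q_true[j]) / (2 * cfg.n_per_pop)) + 1e-9
        assert abs(q_hat - q_true[j]) < 4 * se


def test_purifying_selection_lowers_zerofold_frequency():
    cfg = _cfg(zerofold_selection=0.3)
    ds = simulate_dataset(cfg)
    truth = ds.truth.degeneracy
    df = ds.load_gm.derived_freqs()
    lookup = dict(zip(zip(truth["chrom"], truth["pos0"]), truth["degeneracy"]))
    cls = np.array([lookup[(c, p)] for c, p in
                    zip(ds.load_gm.sites["chrom"], ds.load_gm.positions0())])
    assert df[cls == "zerofold"].mean() < df[cls == "fourfold"].mean()
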