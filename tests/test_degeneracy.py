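"""Codon degeneracy classes, genomic mapping, load and bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from haploscan.degeneracy import (
    bootstrap_load,
    build_degeneracy_map,
    classify_site,
    derived_frequency_load,
)
from haploscan.io_formats import AnnotationSet, CDSSegment, GenotypeMatrix, Transcript

from .codon_oracle import ORACLE_CODE, oracle_classify

ALL_CODONS = sorted(ORACLE_CODE)


def test_classify_known_examples():
    assert classify_site("GGG", 2) == "fourfold"   # glycine GGN family
    assert classify_site("ATG", 0) == "zerofold"   # Met: all first-position changes
    assert classify_site("TTA", 0) == "other"      # Leu: TTA/CTA synonymous
    assert classify_site("ANG", 1) == "ambiguous"
    with pytest.raises(ValueError):
        classify_site("ATG", 3)


def test_classify_matches_exhaustive_oracle_all_192_cases():
    for codon in ALL_CODONS:
        for pos in range(3):
            assert classify_site(codon, pos) == oracle_classify(codon, pos), (codon, pos)


def test_no_second_position_is_fourfold():
    assert all(classify_site(c, 1) != "fourfold" for c in ALL_CODONS)


@settings(max_examples=64, deadline=None)
@given(codon=st.sampled_from(ALL_CODONS), pos=st.integers(0, 2))
def test_classify_case_insensitive(codon, pos):
    assert classify_site(codon.lower(), pos) == classify_site(codon, pos)


def _single_exon_setup(strand):
    """Gene encoding ATG GGA CCT TAA; on '-' the genomic sequence carries the
    reverse complement."""
    cds = "ATGGGACCTTAA"
    comp = str.maketrans("ACGT", "TGCA")
    if strand == "+":
        seq = "NN" + cds + "NN"
    else:
        seq = "NN" + cds.translate(comp)[::-1] + "NN"
    tx = Transcript("t1", "c", strand, [CDSSegment(2, 14, 0)])
    ann = AnnotationSet(transcripts=[tx])
    return {"c": seq}, ann, cds


@pytest.mark.parametrize("strand", ["+", "-"])
def test_single_exon_gene_mapping_both_strands(strand):
    fasta, ann, cds = _single_exon_setup(strand)
    m = build_degeneracy_map(fasta, ann)
    assert len(m) == 12
    lookup = dict(zip(m["pos0"], m["degeneracy"]))
    # transcript order of genomic positions
    tx_pos = list(range(2, 14)) if strand == "+" else list(range(13, 1, -1))
    for i in range(0, 12, 3):
        codon = cds[i:i + 3]
        for k in range(3):
            assert lookup[tx_pos[i + k]] == oracle_classify(codon, k)
    # strand symmetry: same classes at mirrored codon positions
    m_plus = build_degeneracy_map(*_single_exon_setup("+")[:2])
    m_minus = build_degeneracy_map(*_single_exon_setup("-")[:2])
    assert sorted(m_plus["degeneracy"]) == sorted(m_minus["degeneracy"])


def test_malformed_transcript_skipped_and_conflicts_ambiguous():
    fasta = {"c": "NNATGGGACCTTAANN"}
    bad = Transcript("t1", "c", "+", [CDSSegment(2, 13, 0)], malformed=True)
    assert build_degeneracy_map(fasta, AnnotationSet(transcripts=[bad])).empty
    # overlapping transcripts in different frames -> ambiguous where they clash
    t1 = Transcript("t1", "c", "+", [CDSSegment(2, 14, 0)])
    t2 = Transcript("t2", "c", "+", [CDSSegment(5, 14, 0)])
    m = build_degeneracy_map(fasta, AnnotationSet(transcripts=[t1, t2]))
    both = m[(m["pos0"] >= 5) & (m["pos0"] < 14)]
    m1 = build_degeneracy_map(fasta, AnnotationSet(transcripts=[t1]))
    m2 = build_degeneracy_map(fasta, AnnotationSet(transcripts=[t2]))
    l1 = dict(zip(m1["pos0"], m1["degeneracy"]))
    l2 = dict(zip(m2["pos0"], m2["degeneracy"]))
    for row in both.itertuples():
        expected = l1[row.pos0] if l1[row.pos0] == l2[row.pos0] else "ambiguous"
        assert row.degeneracy == expected


def test_map_equals_simulation_truth(small_ds):
    m = build_degeneracy_map(small_ds.fasta, small_ds.annotations)
    truth = small_ds.truth.degeneracy
    merged = truth.merge(m, on=["chrom", "pos0"], how="outer", indicator=True)
    assert (merged["_merge"] == "both").all()
    assert (merged["degeneracy_x"] == merged["degeneracy_y"]).all()


def _load_gm(dosages, classes):
    n, s = dosages.shape
    sites = pd.DataFrame({"chrom": "c", "pos": np.arange(1, s + 1), "ref": "A",
                          "alt": "G", "ancestral": "ref", "missing_frac": 0.0})
    gm = GenotypeMatrix([f"i{j}" for j in range(n)], sites, dosages)
    deg = pd.DataFrame({"chrom": "c", "pos0": np.arange(s), "degeneracy": classes})
    return gm, deg


def test_load_extremes_and_downsampling():
    classes = ["zerofold"] * 10 + ["fourfold"] * 10
    gm, deg = _load_gm(np.zeros((8, 20), dtype=np.int8), classes)
    groups = {"g": gm.sample_ids}
    ests = derived_frequency_load(gm, deg, groups, n_down=5, seed=0)
    assert all(e.mean_derived_freq == 0.0 for e in ests)
    gm2, _ = _load_gm(np.full((8, 20), 2, dtype=np.int8), classes)
    ests2 = derived_frequency_load(gm2, deg, groups, n_down=5, seed=0)
    assert all(e.mean_derived_freq == 1.0 for e in ests2)
    assert all(e.n_individuals == 5 for e in ests2)
    with pytest.raises(ValueError, match="n_down"):
        derived_frequency_load(gm, deg, groups, n_down=20)


def test_load_group_means_invariant_to_individual_order():
    rng = np.random.default_rng(0)
    classes = ["zerofold"] * 15 + ["fourfold"] * 15
    dos = rng.binomial(2, 0.3, size=(12, 30)).astype(np.int8)
    gm, deg = _load_gm(dos, classes)
    ests = derived_frequency_load(gm, deg, {"g": gm.sample_ids}, n_down=12, seed=1)
    perm = rng.permutation(12)
    gm_p = gm.take_samples(perm)
    ests_p = derived_frequency_load(gm_p, deg, {"g": gm_p.sample_ids}, n_down=12, seed=9)
    for a, b in zip(ests, ests_p):
        assert a.mean_derived_freq == pytest.approx(b.mean_derived_freq, abs=1e-12)


def test_bootstrap_ci_properties():
    # identical frequencies -> zero-width CI at the value
    lo, hi = bootstrap_load(np.full(50, 0.3), seed=0)
    assert lo == pytest.approx(0.3) and hi == pytest.approx(0.3)
    # reproducible under seed
    x = np.random.default_rng(1).uniform(0, 1, 100)
    assert bootstrap_load(x, seed=7) == bootstrap_load(x, seed=7)
    with pytest.raises(ValueError):
        bootstrap_load(np.ones(5))
    # width shrinks with more sites (in expectation over seeds)
    rng = np.random.default_rng(2)
    widths = []
    for size in (50, 5000):
        ws = []
        for s in range(10):
            xs = rng.uniform(0, 1, size)
            lo, hi = bootstrap_load(xs, seed=s)
            ws.append(hi - lo)
        widths.append(np.mean(ws))
    assert widths[1] < widths[0]


def test_purifying_selection_separates_load_classes(small_ds):
    m = build_degeneracy_map(small_ds.fasta, small_ds.annotations)
    meta = small_ds.samples.aligned(small_ds.load_gm.sample_ids)
    groups = {r: list(g.index) for r, g in meta.groupby("range")}
    n_down = min(len(v) for v in groups.values())
    ests = derived_frequency_load(small_ds.load_gm, m, groups, n_down, seed=3)
    by = {(e.group, e.site_class): e for e in ests}
    for group in groups:
        zero, four = by[(group, "zerofold")], by[(group, "fourfold")]
        assert zero.mean_derived_freq < four.mean_derived_freq
        assert zero.ci_upper < four.ci_lower
        assert zero.ci_lower <= zero.mean_derived_freq <= zero.ci_upper
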