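"""Shared fixtures: simulated cohorts at the package's default study scale
(10 populations x 20 diploids, 2 x 20-Mbp chromosomes, 20,000 background
SNPs, one 2-Mbp haploblock with a 0.1 -> 0.9 latitudinal cline) and smaller
variants for fast unit checks."""

import numpy as np
import pytest

from haploscan.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def full_ds():
    """Default-scale cohort with the planted haploblock."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def null_ds():
    """Default-scale cohort without any haploblock (pure drift background)."""
    return simulate_dataset(SimulationConfig(seed=11, haploblocks=[]), with_coding=False)


@pytest.fixture(scope="session")
def small_ds():
    """Small cohort for fast unit checks (6 pops x 10, 1 x 4-Mbp chrom)."""
    cfg = SimulationConfig(
        n_pops=6, n_per_pop=10, n_chroms=1, chrom_length=4_000_000,
        n_neutral_snps=2000, haploblocks=[], seed=4,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def latitudes_of():
    def _get(ds):
        return ds.samples.aligned(ds.gm.sample_ids)["latitude"].to_numpy()
    return _get


def genotype_concordance(call, ds, hb_name):
    """Fraction of assigned samples whose called arrangement dosage matches
    truth (up to global A/B orientation)."""
    g_truth = ds.truth.arrangement_genotypes[hb_name]
    arr = call.genotype_array(ds.gm.sample_ids)
    dosage = {"AA": 0, "AB": 1, "BB": 2}
    pred = np.array([dosage.get(a, -1) for a in arr])
    ok = pred >= 0
    if not ok.any():
        return 0.0
    return max(
        float(np.mean(pred[ok] == g_truth[ok])),
        float(np.mean((2 - pred[ok]) == g_truth[ok])),
    )


def interval_jaccard(region, truth_iv):
    if region.chrom != truth_iv.chrom:
        return 0.0
    inter = max(0, min(region.end, truth_iv.end) - max(region.start, truth_iv.start))
    union = max(region.end, truth_iv.end) - min(region.start, truth_iv.start)
    return inter / union
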