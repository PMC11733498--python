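"""Synthetic multi-population datasets with planted haploblocks.

The generator produces the statistical structure the downstream analyses
assume, at desk scale:

* a neutral SNP background whose among-population frequency covariance comes
  from a symmetric drift model (Balding–Nichols: population frequencies are
  Beta-distributed around a shared ancestral frequency with intensity F),
* one or more haploblocks — genomic intervals where each sample carries an
  arrangement genotype (0/1/2 copies of the derived arrangement) drawn from a
  latitudinal cline on the logit scale, tagged by marker SNPs that are fixed
  differences between arrangements up to a small within-arrangement noise ε,
* phenotypes with a haploblock additive effect plus a polygenic background,
* a toy coding contig (FASTA + GFF3) with known site degeneracy, including a
  minus-strand gene and a multi-exon gene with nonzero phase, and
* derived-allele genotypes at coding sites with purifying down-weighting at
  zero-fold degenerate sites, for genetic-load estimation.

There is no recombination or coalescent machinery: linkage inside a
haploblock is induced entirely by the shared arrangement latent variable and
background SNPs are unlinked. That is the minimal structure every detector
downstream relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationSet,
    CDSSegment,
    GenotypeMatrix,
    Interval,
    SampleFrame,
    Transcript,
)

__all__ = [
    "HaploblockSpec",
    "TraitSpec",
    "GeneSpec",
    "SimulationConfig",
    "TruthSet",
    "SimulatedDataset",
    "default_config",
    "simulate_neutral_background",
    "simulate_haploblock",
    "simulate_traits",
    "simulate_coding_genome",
    "simulate_load_genotypes",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class HaploblockSpec:
    """One planted structural-variant haploblock.

    Arrangement frequencies per population either follow a logit-linear cline
    ``logit q_j = beta0 + beta1 * |latitude_j|`` or are given explicitly via
    ``freqs`` (which overrides the cline).
    """

    chrom: str = "chr1"
    start: int = 5_000_000
    end: int = 7_000_000
    n_markers: int = 150
    eps: float = 0.02
    beta0: float | None = None
    beta1: float | None = 0.1
    freqs: tuple[float, ...] | None = None


@dataclass
class TraitSpec:
    name: str = "flowering_onset"
    hb_effect: float = 1.0       # additive effect per arrangement copy
    n_polygenic: int = 100
    polygenic_sd: float = 0.05   # SD of per-SNP additive effects
    resid_sd: float = 1.0


@dataclass
class GeneSpec:
    n_genes: int = 12
    cds_length: int = 300        # coding bases per gene (multiple of 3)
    snp_fraction: float = 0.5    # fraction of classified sites made polymorphic


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 10 populations x 20 diploids spanning a latitudinal gradient,
    2 chromosomes x 20 Mbp, 20,000 neutral SNPs, drift intensity F = 0.1 and a
    single 2-Mbp haploblock whose arrangement frequency climbs 0.1 -> 0.9
    along the gradient (logit slope 0.1 per degree).
    """

    n_pops: int = 10
    n_per_pop: int = 20
    latitudes: tuple[float, ...] | None = None
    n_chroms: int = 2
    chrom_length: int = 20_000_000
    n_neutral_snps: int = 20_000
    drift_f: float = 0.1
    haploblocks: list[HaploblockSpec] = field(default_factory=lambda: [HaploblockSpec()])
    traits: list[TraitSpec] = field(default_factory=lambda: [TraitSpec()])
    genes: GeneSpec = field(default_factory=GeneSpec)
    zerofold_selection: float = 0.3   # multiplier on derived-frequency scale at 0-fold sites
    seed: int = 0

    def resolved_latitudes(self) -> np.ndarray:
        if self.latitudes is not None:
            lat = np.asarray(self.latitudes, dtype=float)
            if len(lat) != self.n_pops:
                raise ValueError("latitudes length != n_pops")
            return lat
        # 44-degree span: logit slope 0.1/deg carries q from 0.1 to 0.9
        return np.linspace(10.0, 54.0, self.n_pops)

    def contig_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    def validate(self) -> None:
        lat = self.resolved_latitudes()
        if not np.all(np.isfinite(lat)):
            raise ValueError("non-finite latitude")
        spans: dict[str, list[tuple[int, int]]] = {}
        lengths = self.contig_lengths()
        for hb in self.haploblocks:
            if hb.chrom not in lengths:
                raise ValueError(f"haploblock chrom {hb.chrom} not simulated")
            if not (0 <= hb.start < hb.end <= lengths[hb.chrom]):
                raise ValueError("haploblock interval outside chromosome")
            for s, e in spans.get(hb.chrom, []):
                if hb.start < e and s < hb.end:
                    raise ValueError("haploblock intervals overlap")
            spans.setdefault(hb.chrom, []).append((hb.start, hb.end))
            if hb.freqs is not None:
                f = np.asarray(hb.freqs, dtype=float)
                if len(f) != self.n_pops or np.any((f < 0) | (f > 1)):
                    raise ValueError("haploblock freqs must be n_pops values in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        hbs = [HaploblockSpec(**h) for h in raw.pop("haploblocks", [])]
        traits = [TraitSpec(**t) for t in raw.pop("traits", [])]
        genes = GeneSpec(**raw.pop("genes", {}))
        cfg = cls(**raw, genes=genes)
        if hbs:
            cfg.haploblocks = hbs
        if traits:
            cfg.traits = traits
        return cfg


@dataclass
class TruthSet:
    """Ground truth emitted alongside the simulated data."""

    haploblocks: list[Interval]
    arrangement_genotypes: dict[str, np.ndarray]     # hb name -> (n_samples,) in {0,1,2}
    pop_arrangement_freqs: dict[str, np.ndarray]     # hb name -> (n_pops,)
    cline_params: dict[str, tuple[float, float]]     # hb name -> (beta0, beta1)
    degeneracy: pd.DataFrame | None = None           # chrom, pos0, degeneracy
    trait_effects: dict[str, dict] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {
            "haploblocks": [asdict(iv) for iv in self.haploblocks],
            "arrangement_genotypes": {k: v.tolist() for k, v in self.arrangement_genotypes.items()},
            "pop_arrangement_freqs": {k: v.tolist() for k, v in self.pop_arrangement_freqs.items()},
            "cline_params": self.cline_params,
            "trait_effects": self.trait_effects,
        }
        if self.degeneracy is not None:
            out["degeneracy"] = self.degeneracy.to_dict(orient="list")
        return out


@dataclass
class SimulatedDataset:
    gm: GenotypeMatrix
    samples: SampleFrame
    annotations: AnnotationSet
    truth: TruthSet
    fasta: dict[str, str] | None = None
    load_gm: GenotypeMatrix | None = None


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


# ---------------------------------------------------------------------------
# neutral background
# ---------------------------------------------------------------------------

def _sample_ids(cfg: SimulationConfig) -> list[str]:
    return [f"P{j + 1:02d}_I{i + 1:02d}" for j in range(cfg.n_pops) for i in range(cfg.n_per_pop)]


def _pop_index(cfg: SimulationConfig) -> np.ndarray:
    return np.repeat(np.arange(cfg.n_pops), cfg.n_per_pop)


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Distinct, sorted 1-based positions."""
    pos = rng.choice(length, size=min(n, length), replace=False) + 1
    return np.sort(pos)


def simulate_neutral_background(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Unlinked neutral SNPs under the Balding–Nichols drift model.

    Per SNP the ancestral frequency is pi ~ Uniform(0.05, 0.95); population
    frequencies are Beta(pi(1-F)/F, (1-pi)(1-F)/F) and diploid dosages are
    Binomial(2, p_j) (Hardy–Weinberg within populations).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    F = cfg.drift_f
    n_total = cfg.n_pops * cfg.n_per_pop
    per_chrom = np.full(cfg.n_chroms, cfg.n_neutral_snps // cfg.n_chroms)
    per_chrom[: cfg.n_neutral_snps % cfg.n_chroms] += 1

    pop_idx = _pop_index(cfg)
    chroms_col, pos_col = [], []
    dosage_blocks = []
    for c in range(cfg.n_chroms):
        n = int(per_chrom[c])
        pos = _draw_positions(rng, cfg.chrom_length, n)
        pi = rng.uniform(0.05, 0.95, size=n)
        a = pi * (1.0 - F) / F
        b = (1.0 - pi) * (1.0 - F) / F
        pops = rng.beta(a[None, :], b[None, :], size=(cfg.n_pops, n))
        dos = rng.binomial(2, pops[pop_idx, :]).astype(np.int8)
        chroms_col.extend([f"chr{c + 1}"] * n)
        pos_col.append(pos)
        dosage_blocks.append(dos)

    sites = pd.DataFrame(
        {
            "chrom": chroms_col,
            "pos": np.concatenate(pos_col),
            "ref": rng.choice(_BASES, size=sum(per_chrom)),
            "alt": "",
            "ancestral": "ref",
            "missing_frac": 0.0,
        }
    )
    # alt differs from ref
    shift = rng.integers(1, 4, size=len(sites))
    ref_idx = np.searchsorted(_BASES, sites["ref"].to_numpy())
    sites["alt"] = _BASES[(ref_idx + shift) % 4]
    return GenotypeMatrix(
        sample_ids=_sample_ids(cfg),
        sites=sites,
        dosages=np.concatenate(dosage_blocks, axis=1),
    )


# ---------------------------------------------------------------------------
# haploblocks
# ---------------------------------------------------------------------------

def _cline_freqs(cfg: SimulationConfig, hb: HaploblockSpec) -> tuple[np.ndarray, tuple[float, float]]:
    lat = np.abs(cfg.resolved_latitudes())
    if hb.freqs is not None:
        q = np.asarray(hb.freqs, dtype=float)
        return q, (float("nan"), float("nan"))
    beta1 = 0.1 if hb.beta1 is None else hb.beta1
    if hb.beta0 is None:
        # anchor so the lowest-|latitude| population sits at q = 0.1
        beta0 = np.log(0.1 / 0.9) - beta1 * lat.min()
    else:
        beta0 = hb.beta0
    q = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * lat)))
    return q, (float(beta0), float(beta1))


def simulate_haploblock(
    cfg: SimulationConfig,
    hb: HaploblockSpec,
    rng: np.random.Generator,
    existing: list[Interval] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray, tuple[float, float]]:
    """Draw arrangement genotypes and marker-SNP dosages for one haploblock.

    Returns (marker site table, marker dosages, arrangement genotypes,
    per-population arrangement frequencies, cline parameters).

    Marker SNPs are fixed differences between the two arrangements: a marker
    dosage equals the arrangement dosage with probability 1 - eps, otherwise
    it is resampled uniformly from the two other dosage values, so
    heterokaryotypes are heterozygous at an expected fraction 1 - eps of
    markers while homokaryotypes sit at the eps level.
    """
    for iv in existing or []:
        if iv.chrom == hb.chrom and hb.start < iv.end and iv.start < hb.end:
            raise ValueError(f"haploblock interval overlaps existing block {iv.name}")
    q, cline = _cline_freqs(cfg, hb)
    pop_idx = _pop_index(cfg)
    g = rng.binomial(2, q[pop_idx]).astype(np.int8)

    pos = _draw_positions(rng, hb.end - hb.start, hb.n_markers) + hb.start
    n_total = len(g)
    dos = np.repeat(g[:, None], len(pos), axis=1).astype(np.int8)
    if hb.eps > 0:
        flip = rng.random((n_total, len(pos))) < hb.eps
        # uniform over the two other dosage values
        offset = rng.integers(1, 3, size=(n_total, len(pos)))
        dos = np.where(flip, (dos + offset) % 3, dos).astype(np.int8)

    ref = rng.choice(_BASES, size=len(pos))
    shift = rng.integers(1, 4, size=len(pos))
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    sites = pd.DataFrame(
        {
            "chrom": hb.chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "ancestral": "ref",
            "missing_frac": 0.0,
        }
    )
    return sites, dos, g, q, cline


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_traits(
    cfg: SimulationConfig,
    arrangement_genotypes: dict[str, np.ndarray],
    background: GenotypeMatrix,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Phenotypes: y = a * g_hb + sum_k b_k g_k + e, e ~ N(0, sigma^2)."""
    n = background.n_samples
    pheno = {}
    effects: dict[str, dict] = {}
    hb_names = list(arrangement_genotypes)
    for spec in cfg.traits:
        y = np.zeros(n)
        info: dict = {"hb_effect": spec.hb_effect, "polygenic": {}}
        if hb_names and spec.hb_effect != 0.0:
            y = y + spec.hb_effect * arrangement_genotypes[hb_names[0]].astype(float)
            info["haploblock"] = hb_names[0]
        if spec.n_polygenic > 0 and background.n_sites > 0:
            k = min(spec.n_polygenic, background.n_sites)
            idx = rng.choice(background.n_sites, size=k, replace=False)
            b = rng.normal(0.0, spec.polygenic_sd, size=k)
            g = background.dosages[:, idx].astype(float)
            g[g == -1] = np.nan
            g = np.where(np.isnan(g), np.nanmean(g, axis=0), g)
            y = y + g @ b
            info["polygenic"] = {"idx": idx.tolist(), "sd": spec.polygenic_sd}
        e = rng.normal(0.0, spec.resid_sd, size=n)
        genetic_var = float(np.var(y))
        y = y + e
        info["resid_sd"] = spec.resid_sd
        info["genetic_variance_fraction"] = genetic_var / float(np.var(y)) if np.var(y) > 0 else 0.0
        pheno[spec.name] = y
        effects[spec.name] = info
    return pd.DataFrame(pheno, index=_sample_ids(cfg)), effects


# ---------------------------------------------------------------------------
# coding genome and load
# ---------------------------------------------------------------------------

def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n internal codons, none of them stops."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _oracle_degeneracy(codon: str, pos_in_codon: int, table: dict[str, str]) -> str:
    aa = table[codon]
    changed = 0
    for b in "ACGT":
        if b == codon[pos_in_codon]:
            continue
        alt = codon[:pos_in_codon] + b + codon[pos_in_codon + 1:]
        if table[alt] != aa:
            changed += 1
    if changed == 3:
        return "zerofold"
    if changed == 0:
        return "fourfold"
    return "other"


def _codon_table() -> dict[str, str]:
    from Bio.Seq import Seq

    table = {}
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                table[codon] = str(Seq(codon).translate())
    return table


_COMP = str.maketrans("ACGT", "TGCA")


def simulate_coding_genome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], AnnotationSet, pd.DataFrame]:
    """A dedicated coding contig ("chrC") of toy genes with known degeneracy.

    Genes alternate strand (so at least one is minus-strand) and the second
    gene is split into two exons with a nonzero phase on the downstream
    segment. The truth table is computed during construction by exhaustive
    codon-substitution enumeration on the transcript sequence, then mapped to
    genomic coordinates through the same strand/phase bookkeeping the emitted
    GFF3 encodes.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 7)
    spec = cfg.genes
    n_codons = spec.cds_length // 3
    spacing = spec.cds_length + 400
    contig_len = spec.n_genes * spacing + 400
    seq = rng.choice(_BASES, size=contig_len)
    table = _codon_table()

    genes: list[Interval] = []
    transcripts: list[Transcript] = []
    truth_rows: list[tuple[str, int, str]] = []

    for gi in range(spec.n_genes):
        # odd genes on the minus strand; gene 3 is multi-exon with nonzero phase
        strand = "+" if gi % 2 == 0 else "-"
        multi_exon = gi == 2
        cds_seq = "ATG" + _random_codons(rng, n_codons - 2) + "TAA"
        gstart = 200 + gi * spacing  # 0-based genomic start of the CDS span
        if multi_exon:
            # split after 10 codons + 1 extra base => downstream phase 2
            cut = 31
            intron = 90
            seg_spans = [(gstart, gstart + cut),
                         (gstart + cut + intron, gstart + len(cds_seq) + intron)]
            phases = [0, (3 - cut % 3) % 3]
        else:
            seg_spans = [(gstart, gstart + len(cds_seq))]
            phases = [0]
        gend = seg_spans[-1][1]

        # genomic positions of the CDS bases in transcript (5'->3') order
        genomic_cols = np.concatenate([np.arange(s, e) for s, e in seg_spans])
        if strand == "+":
            tx_positions = genomic_cols
            for j, base in enumerate(cds_seq):
                seq[tx_positions[j]] = base
        else:
            tx_positions = genomic_cols[::-1]
            for j, base in enumerate(cds_seq):
                seq[tx_positions[j]] = base.translate(_COMP)

        for j in range(0, len(cds_seq), 3):
            codon = cds_seq[j:j + 3]
            for k in range(3):
                truth_rows.append(
                    ("chrC", int(tx_positions[j + k]), _oracle_degeneracy(codon, k, table))
                )

        gid = f"gene{gi + 1}"
        genes.append(Interval("chrC", gstart, gend, name=gid))
        segs = [CDSSegment(s, e, ph) for (s, e), ph in zip(seg_spans, phases)]
        transcripts.append(Transcript(f"{gid}.t1", "chrC", strand, segs))

    fasta = {"chrC": "".join(seq)}
    ann = AnnotationSet(genes=genes, transcripts=transcripts)
    truth = (
        pd.DataFrame(truth_rows, columns=["chrom", "pos0", "degeneracy"])
        .drop_duplicates(subset=["chrom", "pos0"])
        .sort_values("pos0")
        .reset_index(drop=True)
    )
    return fasta, ann, truth


def simulate_load_genotypes(
    cfg: SimulationConfig,
    fasta: dict[str, str],
    truth_degeneracy: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Derived-allele genotypes at classified coding sites.

    Per polymorphic site the derived frequency is Uniform(0.05, 0.5); at
    zero-fold degenerate sites it is multiplied by ``cfg.zerofold_selection``
    (< 1 emulates purifying selection). The reference base is ancestral.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 13)
    classified = truth_degeneracy[truth_degeneracy["degeneracy"].isin(["zerofold", "fourfold"])]
    n_pick = max(10, int(len(classified) * cfg.genes.snp_fraction))
    pick = classified.sample(n=min(n_pick, len(classified)), random_state=int(rng.integers(2**31)))
    pick = pick.sort_values("pos0")

    n_total = cfg.n_pops * cfg.n_per_pop
    freqs = rng.uniform(0.05, 0.5, size=len(pick))
    is_zero = (pick["degeneracy"] == "zerofold").to_numpy()
    freqs[is_zero] *= cfg.zerofold_selection
    dos = rng.binomial(2, freqs[None, :], size=(n_total, len(pick))).astype(np.int8)

    contig = fasta["chrC"]
    ref = np.array([contig[p] for p in pick["pos0"]])
    shift = rng.integers(1, 4, size=len(pick))
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    sites = pd.DataFrame(
        {
            "chrom": "chrC",
            "pos": pick["pos0"].to_numpy() + 1,
            "ref": ref,
            "alt": alt,
            "ancestral": "ref",
            "missing_frac": 0.0,
        }
    )
    return GenotypeMatrix(sample_ids=_sample_ids(cfg), sites=sites, dosages=dos)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _range_labels(cfg: SimulationConfig) -> list[str]:
    """Populations split into one native and two invaded ranges.

    Ranges are interleaved along the latitude gradient (native, invaded-1,
    invaded-2, native, ...) so that every range spans the gradient and
    per-range clines are estimable, mirroring study designs where each
    continental range carries its own latitudinal cline.
    """
    cycle = ["native", "invaded-1", "invaded-2"]
    return [cycle[j % 3] for j in range(cfg.n_pops)]


def simulate_dataset(cfg: SimulationConfig, with_coding: bool = True) -> SimulatedDataset:
    """Generate the full dataset: genotypes, metadata, annotations, truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gm = simulate_neutral_background(cfg, rng)

    truth_hbs: list[Interval] = []
    arr_geno: dict[str, np.ndarray] = {}
    pop_freqs: dict[str, np.ndarray] = {}
    clines: dict[str, tuple[float, float]] = {}
    marker_tables = [gm.sites]
    marker_dosages = [gm.dosages]
    for i, hb in enumerate(cfg.haploblocks):
        name = f"hb-{hb.chrom}{chr(ord('a') + i)}"
        sites, dos, g, q, cline = simulate_haploblock(cfg, hb, rng, existing=truth_hbs)
        truth_hbs.append(Interval(hb.chrom, hb.start, hb.end, name=name))
        arr_geno[name] = g
        pop_freqs[name] = q
        clines[name] = cline
        marker_tables.append(sites)
        marker_dosages.append(dos)

    sites = pd.concat(marker_tables, ignore_index=True)
    dosages = np.concatenate(marker_dosages, axis=1)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    dosages = dosages[:, order]
    # drop duplicate positions (marker colliding with a background SNP)
    dup = sites.duplicated(subset=["chrom", "pos"]).to_numpy()
    gm = GenotypeMatrix(gm.sample_ids, sites.loc[~dup].reset_index(drop=True), dosages[:, ~dup])

    lat = cfg.resolved_latitudes()
    ranges = _range_labels(cfg)
    pop_idx = _pop_index(cfg)
    meta = pd.DataFrame(
        {
            "population": [f"pop{j + 1:02d}" for j in pop_idx],
            "range": [ranges[j] for j in pop_idx],
            "latitude": lat[pop_idx],
            "longitude": rng.uniform(-80.0, -60.0, size=len(pop_idx)).round(3),
        },
        index=gm.sample_ids,
    )

    pheno, effects = simulate_traits(cfg, arr_geno, gm, rng)
    meta = meta.join(pheno)
    samples = SampleFrame(meta)

    ann = AnnotationSet(haploblocks=list(truth_hbs))
    fasta = None
    load_gm = None
    degeneracy = None
    if with_coding:
        fasta, coding_ann, degeneracy = simulate_coding_genome(cfg, rng)
        ann.genes = coding_ann.genes
        ann.transcripts = coding_ann.transcripts
        load_gm = simulate_load_genotypes(cfg, fasta, degeneracy, rng)

    truth = TruthSet(
        haploblocks=truth_hbs,
        arrangement_genotypes=arr_geno,
        pop_arrangement_freqs=pop_freqs,
        cline_params=clines,
        degeneracy=degeneracy,
        trait_effects=effects,
    )
    return SimulatedDataset(gm=gm, samples=samples, annotations=ann, truth=truth,
                            fasta=fasta, load_gm=load_gm)


def write_fasta(fasta: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in fasta.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(ann: AnnotationSet, path) -> None:
    """Emit gene/mRNA/CDS features (1-based, inclusive) with phase."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        tx_by_gene: dict[str, list[Transcript]] = {}
        for tx in ann.transcripts:
            gene_id = tx.transcript_id.rsplit(".", 1)[0]
            tx_by_gene.setdefault(gene_id, []).append(tx)
        for gene in ann.genes:
            txs = tx_by_gene.get(gene.name, [])
            strand = txs[0].strand if txs else "+"
            fh.write(f"{gene.chrom}\t.\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                     f"{strand}\t.\tID={gene.name}\n")
            for tx in txs:
                fh.write(f"{tx.chrom}\t.\tmRNA\t{gene.start + 1}\t{gene.end}\t.\t"
                         f"{tx.strand}\t.\tID={tx.transcript_id};Parent={gene.name}\n")
                for seg in tx.cds:
                    fh.write(f"{tx.chrom}\t.\tCDS\t{seg.start + 1}\t{seg.end}\t.\t"
                             f"{tx.strand}\t{seg.phase}\tID={tx.transcript_id}.cds;"
                             f"Parent={tx.transcript_id}\n")
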