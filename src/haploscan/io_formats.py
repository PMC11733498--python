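"""Standard-format IO and genome-windowing primitives.

All internal coordinates are 0-based half-open; VCF positions (1-based) are
converted at the boundary. Dosages are per-sample alternate-allele counts in
{0, 1, 2} with -1 for missing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SampleFrame",
    "GenomicWindow",
    "Interval",
    "CDSSegment",
    "Transcript",
    "AnnotationSet",
    "read_genotypes",
    "write_genotypes_vcf",
    "read_sample_table",
    "read_gff3",
    "tile_windows",
    "assign_sites_to_windows",
    "sites_in_intervals",
    "sample_background_snps",
    "write_haploblocks_bed",
    "read_bed",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a sample panel.

    Attributes
    ----------
    sample_ids
        Ordered sample identifiers (rows of ``dosages``).
    sites
        Per-site table with columns ``chrom``, ``pos`` (1-based, as in VCF),
        ``ref``, ``alt``, ``ancestral`` (one of ``{"ref", "alt", "unknown"}``)
        and ``missing_frac``.
    dosages
        ``(n_samples, n_sites)`` int8 array of alternate-allele counts,
        ``MISSING`` (-1) where the genotype is uncalled.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def positions0(self) -> np.ndarray:
        """0-based site positions."""
        return self.sites["pos"].to_numpy(dtype=np.int64) - 1

    def alt_freqs(self) -> np.ndarray:
        """Per-site alternate allele frequency among non-missing genotypes."""
        d = self.dosages
        called = d != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def derived_freqs(self) -> np.ndarray:
        """Derived-allele frequency; NaN where ancestral state is unknown."""
        p_alt = self.alt_freqs()
        anc = self.sites["ancestral"].to_numpy()
        out = np.full(self.n_sites, np.nan)
        out[anc == "ref"] = p_alt[anc == "ref"]
        out[anc == "alt"] = 1.0 - p_alt[anc == "alt"]
        return out

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            sites=self.sites.copy(),
            dosages=self.dosages[idx],
        )

    def site_mask_in_region(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of sites inside [start, end) (0-based) on chrom."""
        pos0 = self.positions0()
        return (self.sites["chrom"].to_numpy() == chrom) & (pos0 >= start) & (pos0 < end)


class SampleFrame:
    """Sample metadata: population, range, coordinates and optional columns.

    Wraps a DataFrame indexed by sample id with required columns
    ``population``, ``range``, ``latitude``, ``longitude``; further numeric
    columns are treated as phenotypes or environment variables.
    """

    REQUIRED = ("population", "range", "latitude", "longitude")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if not np.all(np.isfinite(table["latitude"].to_numpy(dtype=float))):
            raise ValueError("non-finite latitudes in sample table")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = set(gm.sample_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"samples absent from metadata: {sorted(missing)[:5]}")

    def aligned(self, sample_ids) -> pd.DataFrame:
        """Rows reordered to match a genotype matrix's sample order."""
        return self.table.loc[list(sample_ids)]

    def small_populations(self, min_n: int = 3) -> list[str]:
        counts = self.table["population"].value_counts()
        return sorted(counts.index[counts < min_n])

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample")


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    window_id: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"window end {self.end} <= start {self.start}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str = ""


@dataclass(frozen=True)
class CDSSegment:
    start: int  # 0-based
    end: int
    phase: int


@dataclass
class Transcript:
    transcript_id: str
    chrom: str
    strand: str
    cds: list[CDSSegment]
    malformed: bool = False


@dataclass
class AnnotationSet:
    """Gene intervals (with transcript CDS structure) plus haploblock intervals."""

    genes: list[Interval] = field(default_factory=list)
    transcripts: list[Transcript] = field(default_factory=list)
    haploblocks: list[Interval] = field(default_factory=list)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes(
    vcf_path: str | os.PathLike,
    min_maf: float = 0.05,
    max_missing: float = 0.25,
    ancestral_tag: str | None = None,
    ancestral_table: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNPs passing the minor-allele-frequency and missingness
    filters are retained. Ancestral states are resolved in priority order:
    sidecar ``ancestral_table`` (columns chrom, pos, allele) > ``ancestral_tag``
    INFO field holding the ancestral base > ``"unknown"``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise ValueError(f"cannot parse VCF {vcf_path}: {exc}") from exc

    anc_lookup: dict[tuple[str, int], str] = {}
    if ancestral_table is not None:
        anc_lookup = {
            (str(r.chrom), int(r.pos)): str(r.allele).upper()
            for r in ancestral_table.itertuples()
        }

    sample_ids = list(vcf.samples)
    dosage_map = np.array([0, 1, MISSING, 2], dtype=np.int8)  # cyvcf2 gt_types

    rows = []
    cols = []
    for i, var in enumerate(vcf):
        if not var.is_snp or len(var.ALT) != 1 or len(var.REF) != 1:
            continue
        dos = dosage_map[var.gt_types]
        called = dos != MISSING
        n_called = int(called.sum())
        miss_frac = 1.0 - n_called / len(sample_ids)
        if miss_frac > max_missing or n_called == 0:
            continue
        p = dos[called].sum() / (2.0 * n_called)
        if min(p, 1.0 - p) < min_maf:
            continue
        anc = "unknown"
        anc_base = anc_lookup.get((var.CHROM, var.POS))
        if anc_base is None and ancestral_tag is not None:
            tagval = var.INFO.get(ancestral_tag)
            if tagval is not None:
                anc_base = str(tagval).upper()
        if anc_base == var.REF.upper():
            anc = "ref"
        elif anc_base == var.ALT[0].upper():
            anc = "alt"
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], anc, miss_frac))
        cols.append(dos)

    if not rows:
        raise ValueError(f"no sites in {vcf_path} passed filters "
                         f"(min_maf={min_maf}, max_missing={max_missing})")

    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "ancestral", "missing_frac"]
    )
    dosages = np.column_stack(cols)
    return GenotypeMatrix(sample_ids=sample_ids, sites=sites, dosages=dosages)


def write_genotypes_vcf(
    gm: GenotypeMatrix,
    path: str | os.PathLike,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal VCF 4.2 with GT fields (and AA INFO where known)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        anc = gm.sites["ancestral"].to_numpy()
        for j, site in enumerate(gm.sites.itertuples()):
            if anc[j] == "ref":
                info = f"AA={site.ref}"
            elif anc[j] == "alt":
                info = f"AA={site.alt}"
            else:
                info = "."
            gts = "\t".join(gt_strings[int(d)] for d in gm.dosages[:, j])
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\t.\t"
                     f"{info}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# sample metadata / GFF3 / BED
# ---------------------------------------------------------------------------

def read_sample_table(path: str | os.PathLike) -> SampleFrame:
    """Read a TSV with columns sample, population, range, latitude, longitude
    and optional named numeric columns (phenotypes / environment)."""
    table = pd.read_csv(path, sep="\t", index_col="sample")
    return SampleFrame(table)


def read_gff3(path: str | os.PathLike) -> AnnotationSet:
    """Parse gene and CDS features from a GFF3 file.

    Transcripts whose CDS length (after trimming the initial phase) is not a
    multiple of 3 are flagged malformed and excluded from degeneracy work but
    their gene intervals still count for background-SNP masking.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[Interval] = []
    transcripts: list[Transcript] = []
    for gene in db.features_of_type("gene"):
        genes.append(Interval(gene.seqid, gene.start - 1, gene.end, name=gene.id))
    for mrna in db.features_of_type("mRNA"):
        segs = []
        for cds in db.children(mrna, featuretype="CDS", order_by="start"):
            phase = 0 if cds.frame in (None, ".") else int(cds.frame)
            segs.append(CDSSegment(cds.start - 1, cds.end, phase))
        if not segs:
            continue
        tx = Transcript(mrna.id, mrna.seqid, mrna.strand, segs)
        ordered = segs if mrna.strand == "+" else segs[::-1]
        total = sum(s.end - s.start for s in ordered) - ordered[0].phase
        if total % 3 != 0:
            tx.malformed = True
        transcripts.append(tx)
    return AnnotationSet(genes=genes, transcripts=transcripts)


def write_haploblocks_bed(calls, path: str | os.PathLike) -> None:
    """Write haploblock calls to BED plus a per-sample genotype TSV sidecar.

    ``calls`` is a sequence of objects exposing ``region`` (with chrom, start,
    end), ``name`` and ``genotypes`` (sample -> {AA, AB, BB, unassigned}).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no haploblock calls to write")
    calls = sorted(calls, key=lambda c: (c.region.chrom, c.region.start))
    with open(path, "w") as fh:
        for call in calls:
            fh.write(f"{call.region.chrom}\t{call.region.start}\t"
                     f"{call.region.end}\t{call.name}\n")
    gt_path = str(path) + ".genotypes.tsv"
    frames = []
    for call in calls:
        ser = pd.Series(call.genotypes, name=call.name)
        frames.append(ser)
    pd.concat(frames, axis=1).to_csv(gt_path, sep="\t", index_label="sample")


def read_bed(path: str | os.PathLike) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[3] if len(parts) > 3 else ""
            out.append(Interval(parts[0], int(parts[1]), int(parts[2]), name))
    return out


# ---------------------------------------------------------------------------
# windows and interval masks
# ---------------------------------------------------------------------------

def tile_windows(contig_lengths: dict[str, int], width: int) -> list[GenomicWindow]:
    """Half-open non-overlapping tiling; the last window is truncated at the
    contig end. Zero-length contigs yield no windows."""
    if width <= 0:
        raise ValueError("window width must be positive")
    windows = []
    wid = 0
    for chrom, length in contig_lengths.items():
        for start in range(0, length, width):
            windows.append(GenomicWindow(chrom, start, min(start + width, length), wid))
            wid += 1
    return windows


def assign_sites_to_windows(gm: GenotypeMatrix, windows: list[GenomicWindow]) -> np.ndarray:
    """Window id per site (-1 if no window covers the site)."""
    out = np.full(gm.n_sites, -1, dtype=np.int64)
    pos0 = gm.positions0()
    chroms = gm.sites["chrom"].to_numpy()
    by_chrom: dict[str, list[GenomicWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, wins in by_chrom.items():
        wins = sorted(wins, key=lambda w: w.start)
        starts = np.array([w.start for w in wins])
        ends = np.array([w.end for w in wins])
        ids = np.array([w.window_id for w in wins])
        mask = chroms == chrom
        idx = np.searchsorted(starts, pos0[mask], side="right") - 1
        ok = (idx >= 0) & (pos0[mask] < ends[np.clip(idx, 0, len(ends) - 1)])
        res = np.where(ok, ids[np.clip(idx, 0, len(ids) - 1)], -1)
        out[mask] = res
    return out


def _merged_intervals(intervals: list[Interval]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out)
    return merged


def sites_in_intervals(gm: GenotypeMatrix, intervals: list[Interval]) -> np.ndarray:
    """Boolean mask: True where the site lies in any of the intervals."""
    mask = np.zeros(gm.n_sites, dtype=bool)
    if not intervals:
        return mask
    merged = _merged_intervals(intervals)
    pos0 = gm.positions0()
    chroms = gm.sites["chrom"].to_numpy()
    for chrom, spans in merged.items():
        sel = chroms == chrom
        if not sel.any():
            continue
        idx = np.searchsorted(spans[:, 0], pos0[sel], side="right") - 1
        inside = (idx >= 0) & (pos0[sel] < spans[np.clip(idx, 0, len(spans) - 1), 1])
        mask[sel] = inside
    return mask


def sample_background_snps(
    gm: GenotypeMatrix,
    annotations: AnnotationSet,
    k: int,
    seed: int,
) -> np.ndarray:
    """Sample k site indices uniformly, without replacement, from sites lying
    outside annotated genes and haploblocks."""
    excluded = sites_in_intervals(gm, annotations.genes) | sites_in_intervals(
        gm, annotations.haploblocks
    )
    eligible = np.flatnonzero(~excluded)
    if k > len(eligible):
        raise ValueError(
            f"requested {k} background SNPs but only {len(eligible)} sites lie "
            "outside genes and haploblocks"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(eligible, size=k, replace=False))
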