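"""Codon degeneracy classification and derived-allele genetic load.

A coding position is zero-fold degenerate when every nucleotide substitution
changes the encoded amino acid and four-fold degenerate when none does;
mean derived-allele frequency across zero-fold sites is a standard proxy
for genetic load, with four-fold sites as the neutral comparison. Stop
codons count as amino-acid changes. Confidence intervals come from a
20%-of-sites subsampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AnnotationSet, GenotypeMatrix, MISSING, Transcript

__all__ = [
    "LoadEstimate",
    "classify_site",
    "build_degeneracy_map",
    "derived_frequency_load",
    "bootstrap_load",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _codon_aa(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


@dataclass
class LoadEstimate:
    group: str
    site_class: str
    mean_derived_freq: float
    ci_lower: float
    ci_upper: float
    n_sites: int
    n_individuals: int


def classify_site(codon: str, position_in_codon: int) -> str:
    """Degeneracy class of one codon position.

    Substitute the three alternative bases: "zerofold" if every substitution
    changes the amino acid (a stop counts as a change), "fourfold" if none
    does, else "other". Codons containing ambiguous bases are "ambiguous".
    """
    codon = codon.upper()
    if position_in_codon not in (0, 1, 2):
        raise ValueError("position_in_codon must be 0, 1 or 2")
    if any(b not in "ACGT" for b in codon) or len(codon) != 3:
        return "ambiguous"
    aa = _codon_aa(codon)
    changes = 0
    for b in "ACGT":
        if b == codon[position_in_codon]:
            continue
        mutant = codon[:position_in_codon] + b + codon[position_in_codon + 1:]
        if _codon_aa(mutant) != aa:
            changes += 1
    if changes == 3:
        return "zerofold"
    if changes == 0:
        return "fourfold"
    return "other"


def _transcript_codons(tx: Transcript, contig: str) -> list[tuple[str, np.ndarray]]:
    """(codon, genomic positions of its 3 bases) for an in-frame transcript."""
    ordered = sorted(tx.cds, key=lambda s: s.start, reverse=(tx.strand == "-"))
    genomic: list[int] = []
    for seg in ordered:
        pos = list(range(seg.start, seg.end))
        if tx.strand == "-":
            pos = pos[::-1]
        genomic.extend(pos)
    phase = ordered[0].phase
    genomic = genomic[phase:]
    bases = [contig[p] for p in genomic]
    if tx.strand == "-":
        bases = [b.translate(_COMP) for b in bases]
    out = []
    for i in range(0, len(genomic) - len(genomic) % 3, 3):
        codon = "".join(bases[i:i + 3]).upper()
        out.append((codon, np.array(genomic[i:i + 3])))
    return out


def build_degeneracy_map(
    fasta: dict[str, str], annotations: AnnotationSet
) -> pd.DataFrame:
    """Per-site degeneracy classes from gene models.

    ``fasta`` maps contig name to sequence (e.g. ``dict(pyfaidx.Fasta)``
    contents as strings). Minus-strand codons are read from the reverse
    complement; CDS phase trims out-of-frame leading bases. Sites whose
    class conflicts between overlapping transcripts become "ambiguous".
    Malformed transcripts (CDS length not a multiple of 3 after phase) are
    skipped.

    Returns a DataFrame with columns chrom, pos0, degeneracy, transcripts.
    """
    classes: dict[tuple[str, int], str] = {}
    provenance: dict[tuple[str, int], list[str]] = {}
    for tx in annotations.transcripts:
        if tx.malformed:
            continue
        contig = fasta[tx.chrom]
        for codon, positions in _transcript_codons(tx, contig):
            for k in range(3):
                key = (tx.chrom, int(positions[k]))
                cls = classify_site(codon, k)
                if key in classes and classes[key] != cls:
                    classes[key] = "ambiguous"
                else:
                    classes.setdefault(key, cls)
                provenance.setdefault(key, []).append(tx.transcript_id)
    rows = [
        {"chrom": c, "pos0": p, "degeneracy": cls,
         "transcripts": ",".join(sorted(set(provenance[(c, p)])))}
        for (c, p), cls in classes.items()
    ]
    return (
        pd.DataFrame(rows, columns=["chrom", "pos0", "degeneracy", "transcripts"])
        .sort_values(["chrom", "pos0"])
        .reset_index(drop=True)
    )


def load_fasta(path) -> dict[str, str]:
    """Read a FASTA into contig -> sequence strings (pyfaidx-backed)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def _site_class_mask(gm: GenotypeMatrix, degeneracy: pd.DataFrame, cls: str) -> np.ndarray:
    lookup = {
        (c, p): d
        for c, p, d in zip(degeneracy["chrom"], degeneracy["pos0"], degeneracy["degeneracy"])
    }
    pos0 = gm.positions0()
    chroms = gm.sites["chrom"].to_numpy()
    return np.array([lookup.get((c, p)) == cls for c, p in zip(chroms, pos0)])


def derived_frequency_load(
    gm: GenotypeMatrix,
    degeneracy: pd.DataFrame,
    groups: dict[str, list[str]],
    n_down: int,
    seed: int = 0,
    bootstrap_fraction: float = 0.2,
    bootstrap_reps: int = 100,
) -> list[LoadEstimate]:
    """Mean derived-allele frequency per group x degeneracy class.

    Each group is first downsampled (without replacement, seeded) to
    ``n_down`` individuals so unequal sample sizes cannot bias the
    frequency means. Sites with unknown ancestral state are excluded.
    Confidence intervals are 2.5/97.5 percentiles over ``bootstrap_reps``
    re-draws of ``bootstrap_fraction`` of the sites.
    """
    rng = np.random.default_rng(seed)
    polarized = gm.sites["ancestral"].to_numpy() != "unknown"
    estimates = []
    for gi, (group, members) in enumerate(sorted(groups.items())):
        idx = [gm.sample_ids.index(s) for s in members]
        if len(idx) < n_down:
            raise ValueError(f"group {group} has {len(idx)} < n_down={n_down} individuals")
        take = rng.choice(idx, size=n_down, replace=False)
        sub = gm.dosages[take]
        called = sub != MISSING
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(called, sub, 0).sum(axis=0) / np.maximum(2 * called.sum(axis=0), 1)
        anc = gm.sites["ancestral"].to_numpy()
        derived = np.where(anc == "alt", 1 - p_alt, p_alt)
        for cls in ("zerofold", "fourfold"):
            mask = _site_class_mask(gm, degeneracy, cls) & polarized
            site_freqs = derived[mask]
            if len(site_freqs) == 0:
                continue
            lo, hi = bootstrap_load(
                site_freqs, fraction=bootstrap_fraction, reps=bootstrap_reps,
                seed=int(rng.integers(2**31)),
            )
            estimates.append(LoadEstimate(
                group=group, site_class=cls,
                mean_derived_freq=float(site_freqs.mean()),
                ci_lower=lo, ci_upper=hi,
                n_sites=len(site_freqs), n_individuals=n_down,
            ))
    return estimates


def bootstrap_load(
    site_freqs: np.ndarray,
    fraction: float = 0.2,
    reps: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Subsampling bootstrap CI for the mean: each rep draws
    ceil(fraction * S) sites without replacement and recomputes the mean;
    the CI is the 2.5/97.5 percentile of rep means."""
    x = np.asarray(site_freqs, dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 sites for a bootstrap CI")
    rng = np.random.default_rng(seed)
    m = int(np.ceil(fraction * len(x)))
    means = np.array([rng.choice(x, size=m, replace=False).mean() for _ in range(reps)])
    return float(np.quantile(means, 0.025)), float(np.quantile(means, 0.975))
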