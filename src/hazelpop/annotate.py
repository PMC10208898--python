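"""SNP functional-effect classification against a gene annotation.

Each SNP receives exactly one :class:`EffectClass`, chosen by a
most-severe rule over all transcripts whose features it touches.  Coding
changes are evaluated by translating the reference and alternate codon
through the standard genetic code, with strand handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from hazelpop.variants import VariantMatrix

logger = logging.getLogger(__name__)

#: Extent, in bp, of the promoter/terminator flanks used for the
#: upstream/downstream classes.
DEFAULT_FLANK_BP = 5_000

#: Number of intronic bases adjacent to each exon treated as splice sites.
SPLICE_SITE_BP = 2

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


class EffectClass(str, Enum):
    """Functional class of a SNP, ordered here from least to most severe."""

    INTERGENIC = "intergenic"
    DOWNSTREAM = "downstream"
    UPSTREAM = "upstream"
    INTRONIC = "intronic"
    SYNONYMOUS = "synonymous"
    SPLICE_SITE = "splice_site"
    NONSYNONYMOUS = "nonsynonymous"
    STOP_LOST = "stop_lost"
    STOP_GAIN = "stop_gain"


_SEVERITY = {cls: rank for rank, cls in enumerate(EffectClass)}


@dataclass
class Transcript:
    id: str
    exons: list[tuple[int, int]]          # 0-based half-open, sorted by start
    cds: list[tuple[int, int, int]]       # (start, end, phase)

    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)


@dataclass
class Gene:
    id: str
    chrom: str
    start: int      # 0-based
    end: int        # half-open
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GeneAnnotation:
    """Gene/transcript/CDS structure, 0-based half-open internally."""

    genes: list[Gene]

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneAnnotation":
        """Load gene models from a GFF3 file (gene -> mRNA -> exon/CDS)."""
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes: list[Gene] = []
        for gf in db.features_of_type("gene", order_by="start"):
            gene = Gene(
                id=gf.id, chrom=gf.seqid, start=gf.start - 1, end=gf.end,
                strand=gf.strand,
            )
            for tf in db.children(gf, featuretype=("mRNA", "transcript"), order_by="start"):
                exons = [(e.start - 1, e.end)
                         for e in db.children(tf, featuretype="exon", order_by="start")]
                cds = [(c.start - 1, c.end, 0 if c.frame in (None, ".") else int(c.frame))
                       for c in db.children(tf, featuretype="CDS", order_by="start")]
                gene.transcripts.append(Transcript(id=tf.id, exons=exons, cds=cds))
            genes.append(gene)
        return cls(genes=genes)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a chrom -> uppercase sequence mapping."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def _coding_effect(
    snp_pos: int, ref: str, alt: str, tx: Transcript, strand: str, seq: str
) -> EffectClass | None:
    """Effect of a SNP that lies inside one of ``tx``'s CDS segments."""
    segments = sorted(tx.cds)
    total = sum(e - s for s, e, _ in segments)
    first_phase = segments[0][2] if strand == "+" else segments[-1][2]
    if (total - first_phase) % 3 != 0:
        logger.warning("transcript %s CDS length %d (phase %d) not divisible by 3; skipped",
                       tx.id, total, first_phase)
        return None
    # genomic coordinates of the coding sequence in translation order
    coords: list[int] = []
    if strand == "+":
        for s, e, _ in segments:
            coords.extend(range(s, e))
        coords = coords[first_phase:]
    else:
        for s, e, _ in reversed(segments):
            coords.extend(range(e - 1, s - 1, -1))
        coords = coords[first_phase:]
    try:
        k = coords.index(snp_pos)
    except ValueError:
        return None  # inside a trimmed phase prefix
    codon_i = k // 3
    codon_coords = coords[3 * codon_i: 3 * codon_i + 3]
    if len(codon_coords) < 3:
        return None  # trailing partial codon
    # codon_coords are already in translation order; on the minus strand
    # each coding base is the complement of the genomic base
    if strand == "+":
        codon_ref = [seq[c] for c in codon_coords]
    else:
        codon_ref = [seq[c].translate(_COMPLEMENT) for c in codon_coords]
    codon_alt = list(codon_ref)
    within = codon_coords.index(snp_pos)
    codon_alt[within] = alt if strand == "+" else alt.translate(_COMPLEMENT)
    ref_codon = "".join(codon_ref)
    alt_codon = "".join(codon_alt)
    ref_aa = _CODON_TABLE.get(ref_codon)
    alt_aa = _CODON_TABLE.get(alt_codon)
    if ref_aa is None or alt_aa is None:
        return None
    if ref_aa == alt_aa:
        return EffectClass.SYNONYMOUS
    if alt_aa == "*":
        return EffectClass.STOP_GAIN
    if ref_aa == "*":
        return EffectClass.STOP_LOST
    return EffectClass.NONSYNONYMOUS


def _transcript_effects(
    pos: int, ref: str, alt: str, gene: Gene, seq: str
) -> list[EffectClass]:
    """All candidate classes a single gene assigns to a SNP inside it."""
    out: list[EffectClass] = []
    for tx in gene.transcripts:
        in_cds = any(s <= pos < e for s, e, _ in tx.cds)
        if in_cds:
            eff = _coding_effect(pos, ref, alt, tx, gene.strand, seq)
            if eff is not None:
                out.append(eff)
            continue
        exons = sorted(tx.exons) or [(gene.start, gene.end)]
        in_exon = any(s <= pos < e for s, e in exons)
        if in_exon:
            # non-coding exonic (UTR) positions are pooled with intronic:
            # both are genic, non-coding
            out.append(EffectClass.INTRONIC)
            continue
        if exons[0][0] <= pos < exons[-1][1]:
            near_boundary = any(
                (e <= pos < e + SPLICE_SITE_BP) or (s - SPLICE_SITE_BP <= pos < s)
                for (s, e) in exons
            )
            out.append(EffectClass.SPLICE_SITE if near_boundary else EffectClass.INTRONIC)
    if not out and gene.start <= pos < gene.end:
        out.append(EffectClass.INTRONIC)
    return out


def classify_snp_effects(
    vm: VariantMatrix,
    genome: Mapping[str, str],
    ann: GeneAnnotation,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> pd.DataFrame:
    """Assign one :class:`EffectClass` per SNP (most-severe-wins).

    Returns a DataFrame with columns ``chrom``, ``pos`` (0-based),
    ``ref``, ``alt``, ``effect``.  Reference-allele mismatches against
    the genome are logged, not fatal.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in ann.genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    effects: list[str] = []
    n_mismatch = 0
    for j in range(vm.n_sites):
        chrom = vm.chrom[j]
        pos = int(vm.pos[j])
        ref, alt = vm.ref[j], vm.alt[j]
        seq = genome.get(chrom)
        if seq is None:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        if not (0 <= pos < len(seq)):
            raise IndexError(f"position {pos} outside {chrom} (len {len(seq)})")
        if seq[pos] != ref:
            n_mismatch += 1
        candidates: list[EffectClass] = []
        for gene in by_chrom.get(chrom, []):
            if gene.start <= pos < gene.end:
                candidates.extend(_transcript_effects(pos, ref, alt, gene, seq))
            elif gene.strand == "+":
                if gene.start - flank_bp <= pos < gene.start:
                    candidates.append(EffectClass.UPSTREAM)
                elif gene.end <= pos < gene.end + flank_bp:
                    candidates.append(EffectClass.DOWNSTREAM)
            else:
                if gene.end <= pos < gene.end + flank_bp:
                    candidates.append(EffectClass.UPSTREAM)
                elif gene.start - flank_bp <= pos < gene.start:
                    candidates.append(EffectClass.DOWNSTREAM)
        if not candidates:
            candidates = [EffectClass.INTERGENIC]
        effects.append(max(candidates, key=_SEVERITY.__getitem__).value)
    if n_mismatch:
        logger.warning("%d SNPs whose REF allele mismatches the genome", n_mismatch)
    return pd.DataFrame(
        {
            "chrom": vm.chrom,
            "pos": vm.pos,
            "ref": vm.ref,
            "alt": vm.alt,
            "effect": effects,
        }
    )


def effect_summary(table: pd.DataFrame) -> pd.Series:
    """Fraction of classified SNPs per effect class (sums to 1)."""
    counts = table["effect"].value_counts()
    return counts / counts.sum()
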