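"""Seeded generators for every input the analysis chain consumes.

Coalescent genotype panels (msprime) under the demographic-model
catalog, planted-sweep editing of genotype matrices, toy annotated
genomes with a known-effect SNP truth table, and niche fixtures with
controllable environmental separation.  Every generator is
deterministic under a fixed seed and emits its ground truth alongside
the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from hazelpop.annotate import Gene, GeneAnnotation, Transcript, _CODON_TABLE, _revcomp
from hazelpop.demography import DemographicModel, constant_size_model
from hazelpop.niche import EnvGrid, OccurrenceSet
from hazelpop.variants import PopulationMap, VariantMatrix

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Coalescent-simulation settings.

    ``model`` supplies the (scaled) demography; ``sample_sizes`` gives
    diploid individuals per model population.  ``mu``/``rho`` are per-bp
    per-generation rates on the simulator's time scale, under which the
    population-scaled mutation rate per site is theta = 2 * mu (the
    reference size is baked into the scale).  Seed is mandatory.
    """

    model: DemographicModel
    sample_sizes: Mapping[str, int]
    L: float = 1_000_000.0
    mu: float = 5e-4          # theta/site = 1e-3
    rho: float = 5e-4
    seed: int = 1
    chrom: str = "chr1"
    params: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mu < 0 or self.rho < 0 or self.L <= 0:
            raise ValueError("rates must be >= 0 and L > 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def simulate_genotypes(cfg: SimConfig) -> tuple[VariantMatrix, PopulationMap, dict]:
    """Coalescent-with-recombination diploid genotypes under ``cfg``.

    Returns (matrix, population map, truth record).  Only biallelic
    sites are retained (multi-hit sites on the discrete genome are
    dropped).  Sample ids are ``<pop>_<i>``.
    """
    import msprime

    demog = cfg.model.demography(cfg.params)
    samples = [msprime.SampleSet(n, population=p, ploidy=2)
               for p, n in cfg.sample_sizes.items()]
    seed = max(int(cfg.seed) % (2 ** 31 - 1), 1)
    ts = msprime.sim_ancestry(
        samples=samples, demography=demog, sequence_length=cfg.L,
        recombination_rate=cfg.rho, random_seed=seed, ploidy=2,
    )
    ts = msprime.sim_mutations(ts, rate=cfg.mu, random_seed=seed + 1)

    sample_ids = []
    assignments = {}
    for p, n in cfg.sample_sizes.items():
        for i in range(n):
            sid = f"{p}_{i}"
            sample_ids.append(sid)
            assignments[sid] = p
    n_dip = len(sample_ids)

    chroms, positions, refs, alts, cols = [], [], [], [], []
    last_pos = -1
    for var in ts.variants():
        alleles = var.alleles
        if len(alleles) != 2 or any(a is None or len(a) != 1 for a in alleles):
            continue
        pos = int(var.site.position)
        if pos == last_pos:
            continue
        g = var.genotypes.reshape(n_dip, 2).sum(axis=1).astype(np.int8)
        chroms.append(cfg.chrom)
        positions.append(pos)
        refs.append(alleles[0])
        alts.append(alleles[1])
        cols.append(g)
        last_pos = pos
    if not cols:
        logger.warning("simulation produced zero biallelic SNPs")
        vm = VariantMatrix(
            sample_ids=sample_ids,
            chrom=np.empty(0, dtype=object), pos=np.empty(0, dtype=np.int64),
            ref=np.empty(0, dtype=object), alt=np.empty(0, dtype=object),
            genotypes=np.empty((n_dip, 0), dtype=np.int8),
        )
    else:
        vm = VariantMatrix(
            sample_ids=sample_ids,
            chrom=np.array(chroms, dtype=object),
            pos=np.array(positions, dtype=np.int64),
            ref=np.array(refs, dtype=object),
            alt=np.array(alts, dtype=object),
            genotypes=np.stack(cols, axis=1),
        )
    truth = {
        "model_id": cfg.model.id,
        "seed": cfg.seed, "L": cfg.L, "mu": cfg.mu, "rho": cfg.rho,
        **{f"param_{k}": v for k, v in (cfg.params or cfg.model.params).items()},
    }
    return vm, PopulationMap(assignments), truth


def neutral_panel(
    n_diploid: int = 10, L: float = 1_000_000.0, theta_site: float = 1e-3,
    rho_site: float | None = None, seed: int = 1,
) -> tuple[VariantMatrix, PopulationMap, dict]:
    """Single constant-size population panel (convenience wrapper)."""
    cfg = SimConfig(
        model=constant_size_model(), sample_sizes={"p1": n_diploid},
        L=L, mu=theta_site / 2.0,
        rho=theta_site / 2.0 if rho_site is None else rho_site / 2.0,
        seed=seed,
    )
    return simulate_genotypes(cfg)


def plant_sweep(
    vm: VariantMatrix,
    pops: PopulationMap,
    population: str,
    region: tuple[str, int, int],
    final_freq: float = 0.9,
    seed: int = 1,
) -> VariantMatrix:
    """Plant a hard-sweep signature by fixing one haplotype locally.

    Within ``region`` (chrom, start, end half-open), a haplotype is
    resolved from one donor sample of the target population (het calls
    resolved at random, seeded) and made homozygous in randomly chosen
    samples until ``final_freq`` of the population carries it.
    Diversity inside the region strictly decreases for final_freq
    near 1.
    """
    if not 0.0 <= final_freq <= 1.0:
        raise ValueError("final_freq must be in [0, 1]")
    chrom, start, end = region
    sites = np.flatnonzero((vm.chrom == chrom) & (vm.pos >= start) & (vm.pos < end))
    if sites.size == 0:
        logger.warning("no SNPs in the sweep region; matrix unchanged")
        return vm
    rows = pops.sample_rows(vm, population)
    rng = np.random.default_rng(seed)
    # resolve one haplotype per candidate donor (het calls at random) and
    # sweep the rarest one: selection acts on initially uncommon variants,
    # which is what produces a frequency-change signature
    alt, tot = vm.take_sites(sites).allele_counts(rows)
    freq = alt / np.maximum(tot, 1)
    best_score = np.inf
    swept = None
    for r in rows:
        block = vm.genotypes[r, sites].astype(np.int8)
        hap = np.where(block == 1, rng.integers(0, 2, size=block.size), block // 2)
        score = float(np.mean(np.where(hap == 1, freq, 1.0 - freq)))
        if score < best_score:
            best_score = score
            swept = (2 * hap).astype(np.int8)
    carriers = [r for r in rows
                if np.array_equal(vm.genotypes[r, sites], swept)]
    n_target = int(round(final_freq * len(rows)))
    if len(carriers) >= n_target:
        return vm
    candidates = [r for r in rows if r not in carriers]
    chosen = rng.choice(candidates, size=n_target - len(carriers), replace=False)
    g = vm.genotypes.copy()
    for r in chosen:
        g[r, sites] = swept
    out = VariantMatrix(
        sample_ids=list(vm.sample_ids), chrom=vm.chrom.copy(), pos=vm.pos.copy(),
        ref=vm.ref.copy(), alt=vm.alt.copy(), genotypes=g,
        site_depth=None if vm.site_depth is None else vm.site_depth.copy(),
    )
    return out


# ---------------------------------------------------------------------------
# Toy annotated genome with known-effect SNPs
# ---------------------------------------------------------------------------

def _random_codons(rng: np.random.Generator, n: int) -> str:
    """Random coding sequence of n codons without stop codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _aa(codon: str) -> str:
    return _CODON_TABLE[codon]


def _pick_snp(rng, sense: str, cds_idx: list[int], want: str) -> tuple[int, str] | None:
    """Find a coding SNP in sense space producing the wanted class."""
    order = rng.permutation(len(cds_idx))
    for k in order:
        k = int(k)
        s = cds_idx[k]
        codon_i, within = divmod(k, 3)  # position within the concatenated CDS
        codon_positions = cds_idx[3 * codon_i: 3 * codon_i + 3]
        if len(codon_positions) < 3:
            continue
        ref_codon = "".join(sense[q] for q in codon_positions)
        for alt in "ACGT":
            if alt == sense[s]:
                continue
            alt_codon = (ref_codon[:within] + alt + ref_codon[within + 1:])
            ra, aa = _aa(ref_codon), _aa(alt_codon)
            if want == "synonymous" and ra == aa and ra != "*":
                return s, alt
            if want == "nonsynonymous" and ra != aa and aa != "*" and ra != "*":
                return s, alt
            if want == "stop_gain" and ra != "*" and aa == "*":
                return s, alt
    return None


def make_toy_genome(
    n_genes: int = 4,
    cds_len: int = 120,
    intron_len: int = 60,
    intergenic_len: int = 5_500,
    seed: int = 1,
) -> tuple[dict[str, str], GeneAnnotation, pd.DataFrame]:
    """Toy single-chromosome genome with annotated two-exon genes and a
    truth table of placed SNPs with known effect classes.

    Genes alternate strands.  Each gene is two CDS exons (``cds_len``
    bp each, multiple of 3) flanking one ``intron_len`` bp intron.
    The truth table covers intergenic, upstream, downstream, intronic,
    splice-site, synonymous, nonsynonymous and stop-gain classes where
    placeable.
    """
    if cds_len % 3 != 0:
        raise ValueError("cds_len must be a multiple of 3")
    rng = np.random.default_rng(seed)
    chrom = "toy1"
    pieces: list[str] = []
    genes: list[Gene] = []
    truth_rows: list[dict] = []
    cursor = 0

    def emit_intergenic(n: int) -> None:
        nonlocal cursor
        pieces.append("".join(rng.choice(_BASES, size=n)))
        cursor += n

    emit_intergenic(intergenic_len)
    for gi in range(n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        sense = (_random_codons(rng, cds_len // 3)
                 + "".join(rng.choice(_BASES, size=intron_len))
                 + _random_codons(rng, cds_len // 3))
        glen = len(sense)
        gstart = cursor
        genomic = sense if strand == "+" else _revcomp(sense)
        pieces.append(genomic)
        cursor += glen

        # sense-space feature layout
        cds_sense = list(range(0, cds_len)) + list(range(cds_len + intron_len, glen))
        intron_sense = (cds_len, cds_len + intron_len)  # half-open

        def to_genomic(s: int) -> int:
            return gstart + s if strand == "+" else gstart + (glen - 1 - s)

        def sense_to_alt(base_sense: str) -> str:
            return base_sense if strand == "+" else base_sense.translate(
                str.maketrans("ACGT", "TGCA"))

        if strand == "+":
            cds_iv = [(gstart, gstart + cds_len, 0),
                      (gstart + cds_len + intron_len, gstart + glen, 0)]
        else:
            cds_iv = [(gstart, gstart + cds_len, 0),
                      (gstart + cds_len + intron_len, gstart + glen, 0)]
        exons = [(s, e) for s, e, _ in cds_iv]
        gene = Gene(id=f"gene{gi}", chrom=chrom, start=gstart, end=gstart + glen,
                    strand=strand,
                    transcripts=[Transcript(id=f"gene{gi}.t1", exons=exons, cds=cds_iv)])
        genes.append(gene)

        # coding truth SNPs
        for want in ("synonymous", "nonsynonymous", "stop_gain"):
            hit = _pick_snp(rng, sense, cds_sense, want)
            if hit is None:
                continue
            s, alt_sense = hit
            truth_rows.append({
                "chrom": chrom, "pos": to_genomic(s),
                "ref": genomic[to_genomic(s) - gstart],
                "alt": sense_to_alt(alt_sense), "effect": want, "gene": gene.id,
            })
        # intronic (interior) and splice-site (first intron base)
        mid = (intron_sense[0] + intron_sense[1]) // 2
        for s, eff in ((mid, "intronic"), (intron_sense[0], "splice_site")):
            ref_g = genomic[to_genomic(s) - gstart]
            alt_g = next(b for b in "ACGT" if b != ref_g)
            truth_rows.append({"chrom": chrom, "pos": to_genomic(s), "ref": ref_g,
                               "alt": alt_g, "effect": eff, "gene": gene.id})
        emit_intergenic(intergenic_len)

    seq = "".join(pieces)
    genome = {chrom: seq}
    ann = GeneAnnotation(genes=genes)

    # flank and intergenic truth SNPs relative to the first gene
    if genes:
        g0 = genes[0]
        flank = min(100, intergenic_len)
        up_pos = g0.start - flank if g0.strand == "+" else g0.end + flank - 1
        down_pos = g0.end + flank - 1 if g0.strand == "+" else g0.start - flank
        for pos, eff in ((up_pos, "upstream"), (down_pos, "downstream")):
            if 0 <= pos < len(seq):
                ref_g = seq[pos]
                alt_g = next(b for b in "ACGT" if b != ref_g)
                truth_rows.append({"chrom": chrom, "pos": pos, "ref": ref_g,
                                   "alt": alt_g, "effect": eff, "gene": g0.id})
    # deep intergenic: far beyond the last gene's flank if room, else the
    # very first base when no genes exist
    tail = len(seq) - 1
    last_end = genes[-1].end if genes else 0
    if tail >= last_end + 5_000 or not genes:
        pos = tail if genes else 0
        ref_g = seq[pos]
        alt_g = next(b for b in "ACGT" if b != ref_g)
        truth_rows.append({"chrom": chrom, "pos": pos, "ref": ref_g,
                           "alt": alt_g, "effect": "intergenic", "gene": ""})

    truth = (pd.DataFrame(truth_rows)
             .drop_duplicates("pos")
             .sort_values("pos")
             .reset_index(drop=True))
    return genome, ann, truth


def truth_to_matrix(truth: pd.DataFrame, n_samples: int = 2) -> VariantMatrix:
    """Wrap a truth SNP table as a VariantMatrix (dummy genotypes)."""
    n = len(truth)
    g = np.tile(np.arange(n_samples)[:, None] % 2, (1, n)).astype(np.int8)
    return VariantMatrix(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        chrom=truth["chrom"].to_numpy(object),
        pos=truth["pos"].to_numpy(np.int64),
        ref=truth["ref"].to_numpy(object),
        alt=truth["alt"].to_numpy(object),
        genotypes=g,
    )


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(ann: GeneAnnotation, path: str | Path) -> None:
    """Serialize gene models to GFF3 (1-based inclusive at the boundary)."""
    lines = ["##gff-version 3"]
    for g in ann.genes:
        lines.append("\t".join([
            g.chrom, "toy", "gene", str(g.start + 1), str(g.end), ".",
            g.strand, ".", f"ID={g.id}"]))
        for tx in g.transcripts:
            lines.append("\t".join([
                g.chrom, "toy", "mRNA", str(g.start + 1), str(g.end), ".",
                g.strand, ".", f"ID={tx.id};Parent={g.id}"]))
            for s, e in tx.exons:
                lines.append("\t".join([
                    g.chrom, "toy", "exon", str(s + 1), str(e), ".",
                    g.strand, ".", f"Parent={tx.id}"]))
            for s, e, phase in tx.cds:
                lines.append("\t".join([
                    g.chrom, "toy", "CDS", str(s + 1), str(e), ".",
                    g.strand, str(phase), f"Parent={tx.id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Niche fixtures
# ---------------------------------------------------------------------------

def make_niche_fixture(
    separation: float = 0.0,
    n_per_species: int = 60,
    seed: int = 1,
    grid_size: int = 50,
) -> tuple[OccurrenceSet, OccurrenceSet, EnvGrid, dict]:
    """Two species' occurrences over a synthetic environmental grid.

    The grid spans lon/lat in [0, 10) with two smooth environmental
    layers (a longitudinal and a latitudinal gradient plus mild
    curvature).  Occurrences are Gaussian clouds in coordinate (hence
    environmental) space whose centers are ``separation`` standard
    deviations apart along the longitudinal axis.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    lon = np.linspace(0.25, 9.75, grid_size)
    lat = np.linspace(0.25, 9.75, grid_size)
    LON, LAT = np.meshgrid(lon, lat)
    layers = {
        "env1": LON + 0.05 * LAT ** 2,
        "env2": LAT + 0.05 * (LON - 5.0) ** 2,
    }
    env = EnvGrid(lon=lon, lat=lat, layers=layers)
    sd = 1.0
    center = 5.0
    mu_a = (center - separation * sd / 2.0, center)
    mu_b = (center + separation * sd / 2.0, center)
    def draw(mu):
        pts = rng.normal(loc=mu, scale=sd, size=(n_per_species, 2))
        return np.clip(pts, 0.3, 9.7)
    occ_a = OccurrenceSet("species_a", draw(mu_a))
    occ_b = OccurrenceSet("species_b", draw(mu_b))
    truth = {"separation": separation, "n_per_species": n_per_species, "seed": seed}
    return occ_a, occ_b, env, truth


def write_occurrences(occs: list[OccurrenceSet], path: str | Path) -> None:
    rows = []
    for occ in occs:
        for lon, lat in occ.coords:
            rows.append(f"{occ.species},{lon:.6f},{lat:.6f}")
    Path(path).write_text("species,lon,lat\n" + "\n".join(rows) + "\n")


def write_truth(truth: Mapping, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{k}={v}\n" for k, v in truth.items())
    )
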