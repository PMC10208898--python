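"""Biallelic SNP matrices: VCF I/O, site filtering and LD pruning.

The central container is :class:`VariantMatrix`, a dense samples x sites
genotype-dosage matrix (0/1/2 copies of the alternate allele, ``MISSING``
for no-calls) with per-site chromosome/position metadata.  All coordinates
are 0-based half-open internally; VCF (1-based) is converted at the I/O
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel genotype code for a missing diploid call.
MISSING: int = -1

_VALID_BASES = frozenset("ACGT")


@dataclass
class VariantMatrix:
    """Dense biallelic SNP genotype matrix with site metadata.

    Parameters
    ----------
    sample_ids
        Ordered sample labels (rows of ``genotypes``).
    chrom
        Per-site chromosome label, shape ``(n_sites,)``.
    pos
        Per-site 0-based coordinate, strictly increasing within each
        chromosome.
    ref, alt
        Per-site single-character reference / alternate alleles.
    genotypes
        ``(n_samples, n_sites)`` int8 array of alt-allele counts in
        {0, 1, 2} or :data:`MISSING`.
    site_depth
        Optional per-site mean sequencing depth (NaN where unknown).
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    site_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.site_depth is not None:
            self.site_depth = np.asarray(self.site_depth, dtype=float)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on breach."""
        g = self.genotypes
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x sites)")
        if g.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match genotype rows")
        n = g.shape[1]
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != n:
                raise ValueError(f"{name} length does not match genotype columns")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,MISSING}")
        for r, a in zip(self.ref, self.alt):
            if r == a or r not in _VALID_BASES or a not in _VALID_BASES:
                raise ValueError(f"invalid allele pair ({r},{a})")
        # positions strictly increasing within each chromosome
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def take_sites(self, index: np.ndarray) -> "VariantMatrix":
        """Subset sites by integer or boolean index, preserving order."""
        index = np.asarray(index)
        depth = self.site_depth[index] if self.site_depth is not None else None
        return VariantMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            genotypes=self.genotypes[:, index],
            site_depth=depth,
        )

    def take_samples(self, rows: Sequence[int]) -> "VariantMatrix":
        rows = list(rows)
        depth = None if self.site_depth is None else self.site_depth.copy()
        return VariantMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            genotypes=self.genotypes[rows, :],
            site_depth=depth,
        )

    # -- derived per-site summaries -------------------------------------
    def allele_counts(self, rows: Sequence[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (alt-allele count, called allele copies) per site."""
        g = self.genotypes if rows is None else self.genotypes[list(rows), :]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-site MAF over non-missing calls (NaN where all missing)."""
        alt, tot = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)


@dataclass(frozen=True)
class FilterConfig:
    """Site-level QC thresholds mirroring a strict resequencing filter:
    minimum minor-allele frequency, maximum missing-call fraction, and a
    depth window expressed as multipliers on the genome-wide mean depth
    (one-third to twofold by default)."""

    min_maf: float = 0.05
    max_missing: float = 0.20
    depth_low_factor: float = 1.0 / 3.0
    depth_high_factor: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must be in [0, 0.5)")
        if not (0.0 <= self.max_missing <= 1.0):
            raise ValueError("max_missing must be in [0, 1]")
        if not (self.depth_low_factor < self.depth_high_factor):
            raise ValueError("depth_low_factor must be < depth_high_factor")


class PopulationMap:
    """Assignment of samples to named populations.

    Populations keep their first-seen order.  Unassigned samples are
    allowed (they are simply outside every population).
    """

    def __init__(self, assignments: Mapping[str, str]):
        self.assignments = dict(assignments)
        self.populations = list(dict.fromkeys(self.assignments.values()))
        if not self.populations:
            raise ValueError("population map is empty")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationMap":
        """Read a two-column ``sample<TAB>population`` file."""
        assignments: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed population map line: {line!r}")
            assignments[parts[0]] = parts[1]
        return cls(assignments)

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{s}\t{p}\n" for s, p in self.assignments.items())
        )

    def members(self, population: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == population]
        if not out:
            raise ValueError(f"population {population!r} is empty or unknown")
        return out

    def sample_rows(self, vm: VariantMatrix, population: str) -> list[int]:
        """Row indices of a population's samples within ``vm``."""
        index = {s: i for i, s in enumerate(vm.sample_ids)}
        rows = []
        for s in self.members(population):
            if s not in index:
                raise KeyError(f"sample {s!r} not present in the variant matrix")
            rows.append(index[s])
        return rows


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> VariantMatrix:
    """Read the biallelic-SNP subset of a VCF into a :class:`VariantMatrix`.

    Multiallelic records, indels and non-ACGT alleles are skipped.
    Missing calls (``./.``) map to :data:`MISSING`.  Per-site mean FORMAT
    depth is kept when any sample reports DP.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    geno_cols: list[np.ndarray] = []
    depths: list[float] = []
    any_depth = False
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue
        if ref not in _VALID_BASES or alt not in _VALID_BASES:
            continue
        # gts012: 0/1/2 = alt dosage, 3 = unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        geno_cols.append(g)
        chroms.append(v.CHROM)
        positions.append(v.POS - 1)  # to 0-based
        refs.append(ref)
        alts.append(alt)
        d = v.gt_depths
        site_depth = np.nan
        if d is not None:
            d = np.asarray(d, dtype=float)
            ok = d >= 0
            if ok.any():
                site_depth = float(d[ok].mean())
        if not np.isfinite(site_depth):
            mdp = v.INFO.get("MDP")
            if mdp is not None:
                site_depth = float(mdp)
        if np.isfinite(site_depth):
            any_depth = True
        depths.append(site_depth)
    vcf.close()
    if not geno_cols:
        logger.warning("no biallelic SNP records in %s; returning empty matrix", path)
        return VariantMatrix(
            sample_ids=samples,
            chrom=np.empty(0, dtype=object),
            pos=np.empty(0, dtype=np.int64),
            ref=np.empty(0, dtype=object),
            alt=np.empty(0, dtype=object),
            genotypes=np.empty((len(samples), 0), dtype=np.int8),
        )
    return VariantMatrix(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=np.stack(geno_cols, axis=1),
        site_depth=np.array(depths) if any_depth else None,
    )


def write_vcf(vm: VariantMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (GT, and per-site DP in INFO when known)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=MDP,Number=1,Type=Float,Description="Mean sample depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for c in dict.fromkeys(vm.chrom):
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(vm.sample_ids)
    )
    for j in range(vm.n_sites):
        if vm.site_depth is not None and np.isfinite(vm.site_depth[j]):
            info = f"MDP={vm.site_depth[j]:g}"
        else:
            info = "."
        gts = "\t".join(gt_strings[int(g)] for g in vm.genotypes[:, j])
        lines.append(
            f"{vm.chrom[j]}\t{vm.pos[j] + 1}\t.\t{vm.ref[j]}\t{vm.alt[j]}"
            f"\t.\tPASS\t{info}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Filtering and LD pruning
# ---------------------------------------------------------------------------

def filter_variants(vm: VariantMatrix, cfg: FilterConfig | None = None) -> VariantMatrix:
    """Apply MAF / missingness / depth site filters.

    A site is retained when MAF >= ``min_maf`` (computed on non-missing
    calls), its missing fraction <= ``max_missing``, and — when depth is
    recorded — its mean depth lies within
    ``[mean * depth_low_factor, mean * depth_high_factor]``.  Sites with
    every call missing are removed (and counted in the log).  The sample
    set is unchanged; the operation is idempotent.
    """
    if cfg is None:
        cfg = FilterConfig()
    if vm.n_sites == 0:
        return vm
    _, total = vm.allele_counts()
    all_missing = total == 0
    if all_missing.any():
        logger.info("removing %d sites with all calls missing", int(all_missing.sum()))
    maf = vm.minor_allele_frequency()
    keep = ~all_missing
    keep &= np.nan_to_num(maf, nan=-1.0) >= cfg.min_maf
    keep &= vm.missing_fraction() <= cfg.max_missing
    if vm.site_depth is not None:
        d = vm.site_depth
        finite = np.isfinite(d)
        if finite.any():
            mean_depth = float(d[finite].mean())
            lo = mean_depth * cfg.depth_low_factor
            hi = mean_depth * cfg.depth_high_factor
            in_range = ~finite | ((d >= lo) & (d <= hi))
            keep &= in_range
    return vm.take_sites(np.flatnonzero(keep))


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples; 0.0 when undefined (constant or <2 pairs)."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    vx = xs.var()
    vy = ys.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(
    vm: VariantMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.2,
) -> VariantMatrix:
    """Greedy window-based LD pruning (PLINK ``--indep-pairwise`` style).

    Windows of ``window_snps`` *surviving* sites advance by ``step_snps``;
    within each window, pairs are scanned in left-to-right index order
    and the later (higher-index) member of any pair with r^2 > ``r2_max``
    is removed.  Passes repeat until no removal occurs, so the output
    carries no within-window offending pair even across former gaps.
    Windows never span chromosomes.  The output is a subset of input
    sites in original order and the rule is fully deterministic.
    """
    if step_snps <= 0:
        raise ValueError("step_snps must be positive")
    if window_snps <= 0:
        raise ValueError("window_snps must be positive")
    n = vm.n_sites
    alive = np.ones(n, dtype=bool)
    g = vm.genotypes
    changed = True
    while changed:
        changed = False
        idx_all = np.flatnonzero(alive)
        # chromosome runs within the surviving set
        runs: list[np.ndarray] = []
        start = 0
        for k in range(1, len(idx_all) + 1):
            if k == len(idx_all) or vm.chrom[idx_all[k]] != vm.chrom[idx_all[start]]:
                runs.append(idx_all[start:k])
                start = k
        for run in runs:
            for w0 in range(0, len(run), step_snps):
                window = run[w0: w0 + window_snps]
                for a_i in range(len(window)):
                    i = window[a_i]
                    if not alive[i]:
                        continue
                    for j in window[a_i + 1:]:
                        if not alive[j]:
                            continue
                        if _dosage_r2(g[:, i], g[:, j]) > r2_max:
                            alive[j] = False
                            changed = True
                if w0 + window_snps >= len(run):
                    break
    return vm.take_sites(np.flatnonzero(alive))
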