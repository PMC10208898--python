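"""Windowed diversity and differentiation statistics.

Implements per-site nucleotide diversity (unbiased expected
heterozygosity), per-sample heterozygosity, the Weir & Cockerham (1984)
FST estimator with ratio-of-sums window aggregation, log pi-ratios, and
the r^2 linkage-disequilibrium decay curve with its half-decay distance.

Window coordinates are 0-based half-open.  FST is reported raw (slightly
negative values are possible and deliberate: empirical top-quantile
thresholds operate on raw values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hazelpop.variants import MISSING, PopulationMap, VariantMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 100 kb windows advanced by 10 kb steps by
    default; windows with fewer than ``min_sites`` SNPs report NaN."""

    size: int = 100_000
    step: int = 10_000
    min_sites: int = 1

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("window size must be positive")
        if not (0 < self.step <= self.size):
            raise ValueError("step must be in (0, size]")


def _chrom_lengths(vm: VariantMatrix, given: Mapping[str, int] | None) -> dict[str, int]:
    if given is not None:
        return dict(given)
    out: dict[str, int] = {}
    for c in dict.fromkeys(vm.chrom):
        out[c] = int(vm.pos[vm.chrom == c].max()) + 1
    return out


def _window_grid(length: int, ws: WindowSpec) -> np.ndarray:
    """Window start coordinates covering [0, length)."""
    last = max(0, length - 1)
    n = last // ws.step + 1
    starts = np.arange(n, dtype=np.int64) * ws.step
    return starts[starts < length]


def _windowed_sums(
    pos: np.ndarray, values: np.ndarray, length: int, ws: WindowSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum ``values`` (sites x k) into (possibly overlapping) windows.

    Returns (starts, n_sites per window, sums per window).
    """
    starts = _window_grid(length, ws)
    values = np.atleast_2d(np.asarray(values, dtype=float).T).T  # (n, k)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, np.minimum(starts + ws.size, length), side="left")
    csum = np.vstack([np.zeros((1, values.shape[1])), np.nancumsum(values, axis=0)])
    sums = csum[hi] - csum[lo]
    n_sites = hi - lo
    return starts, n_sites, sums


def per_site_pi(vm: VariantMatrix, rows: Sequence[int]) -> np.ndarray:
    """Unbiased per-site diversity 2j(m-j)/(m(m-1)) within a sample set.

    ``j`` is the alt-allele count and ``m`` the number of non-missing
    allele copies at the site.  Sites with m < 2 give NaN.
    """
    alt, m = vm.allele_counts(rows)
    m = m.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * alt * (m - alt) / (m * (m - 1.0))
    pi[m < 2] = np.nan
    return pi


def window_pi(
    vm: VariantMatrix,
    pops: PopulationMap,
    population: str,
    ws: WindowSpec | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity for one population (per-bp).

    Window pi = (sum of per-site pi in the window) / window size in bp.
    Windows with fewer than ``ws.min_sites`` SNPs report NaN.
    """
    ws = ws or WindowSpec()
    rows = pops.sample_rows(vm, population)
    if len(rows) < 2:
        raise ValueError("population must contain at least 2 samples")
    site_pi = per_site_pi(vm, rows)
    lengths = _chrom_lengths(vm, chrom_lengths)
    frames = []
    for c, length in lengths.items():
        mask = vm.chrom == c
        starts, n_sites, sums = _windowed_sums(vm.pos[mask], site_pi[mask], length, ws)
        ends = np.minimum(starts + ws.size, length)
        pi = sums[:, 0] / (ends - starts)
        pi[n_sites < ws.min_sites] = np.nan
        frames.append(pd.DataFrame(
            {"chrom": c, "start": starts, "end": ends, "n_sites": n_sites, "pi": pi}
        ))
    return pd.concat(frames, ignore_index=True)


def sample_heterozygosity(vm: VariantMatrix, genome_length: int) -> pd.Series:
    """Per-sample heterozygosity: heterozygous-call count / genome length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    het = (vm.genotypes == 1).sum(axis=1) / float(genome_length)
    return pd.Series(het, index=vm.sample_ids, name="heterozygosity")


def wc_fst_components(
    vm: VariantMatrix, rows_a: Sequence[int], rows_b: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components (a, b, c).

    Two-population diploid case from genotype counts.  Sites where either
    population has no called individual, or where n_bar <= 1, are NaN.
    """
    a_out = np.full(vm.n_sites, np.nan)
    b_out = np.full(vm.n_sites, np.nan)
    c_out = np.full(vm.n_sites, np.nan)

    stats = []
    for rows in (rows_a, rows_b):
        g = vm.genotypes[list(rows), :]
        called = g != MISSING
        n = called.sum(axis=0).astype(float)              # individuals
        alt = np.where(called, g, 0).sum(axis=0).astype(float)
        het = ((g == 1) & called).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n)
            h = het / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats

    r = 2.0
    ok = (n1 >= 1) & (n2 >= 1)
    n_bar = (n1 + n2) / r
    ok &= n_bar > 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    # degenerate n_c (equal-size pops always fine; n_c=0 only if one pop empty)
    ok &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a_out[ok], b_out[ok], c_out[ok] = a[ok], b[ok], c[ok]
    return a_out, b_out, c_out


def wc_fst(
    vm: VariantMatrix,
    pops: PopulationMap,
    pop_a: str,
    pop_b: str,
    ws: WindowSpec | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window Weir & Cockerham FST, ratio-of-sums aggregation.

    Window FST = sum(a) / sum(a + b + c) over informative sites; windows
    with no informative site (or denominator 0) report NaN.  Exactly
    symmetric in its two population arguments.
    """
    ws = ws or WindowSpec()
    rows_a = pops.sample_rows(vm, pop_a)
    rows_b = pops.sample_rows(vm, pop_b)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValueError("both populations need at least 2 samples")
    a, b, c = wc_fst_components(vm, rows_a, rows_b)
    lengths = _chrom_lengths(vm, chrom_lengths)
    frames = []
    for chrom, length in lengths.items():
        mask = vm.chrom == chrom
        informative = np.isfinite(a[mask])
        vals = np.column_stack([
            np.where(informative, a[mask], np.nan),
            np.where(informative, a[mask] + b[mask] + c[mask], np.nan),
            informative.astype(float),
        ])
        starts, n_sites, sums = _windowed_sums(vm.pos[mask], vals, length, ws)
        ends = np.minimum(starts + ws.size, length)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = sums[:, 0] / sums[:, 1]
        fst[(sums[:, 2] == 0) | (sums[:, 1] == 0) | (n_sites < ws.min_sites)] = np.nan
        frames.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends,
             "n_sites": n_sites, "fst": fst}
        ))
    return pd.concat(frames, ignore_index=True)


def genome_fst(vm: VariantMatrix, pops: PopulationMap, pop_a: str, pop_b: str) -> float:
    """Genome-wide Weir & Cockerham FST (single ratio of sums)."""
    a, b, c = wc_fst_components(
        vm, pops.sample_rows(vm, pop_a), pops.sample_rows(vm, pop_b)
    )
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    return float(num / den)


def ln_pi_ratio(pi_num: pd.DataFrame, pi_den: pd.DataFrame) -> pd.DataFrame:
    """Per-window ln(pi_num / pi_den) on a shared window grid.

    Windows where either pi is 0 or missing give NaN.  Mismatched grids
    raise ``ValueError``.
    """
    keys = ["chrom", "start", "end"]
    if len(pi_num) != len(pi_den) or not (
        pi_num[keys].reset_index(drop=True).equals(pi_den[keys].reset_index(drop=True))
    ):
        raise ValueError("window grids of the two pi series do not match")
    num = pi_num["pi"].to_numpy(float)
    den = pi_den["pi"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.log(num / den)
    val[(num <= 0) | (den <= 0) | ~np.isfinite(val)] = np.nan
    out = pi_num[keys].copy()
    out["ln_pi_ratio"] = val
    return out


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LDDecayCurve:
    """Binned mean r^2 against pairwise distance, with the fitted maximum
    and the distance at which the (monotone-smoothed) curve falls to half
    of that maximum."""

    bin_edges: np.ndarray          # contiguous, bp
    mean_r2: np.ndarray            # NaN for empty bins
    n_pairs: np.ndarray
    max_r2: float
    half_decay_distance: float     # bp; NaN if the curve never halves

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dist_lo": self.bin_edges[:-1],
            "dist_hi": self.bin_edges[1:],
            "mean_r2": self.mean_r2,
            "n_pairs": self.n_pairs,
        })


def _isotonic_decreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted isotonic non-increasing fit (pool-adjacent-violators)."""
    values = list(y[:1])
    weights = list(w[:1])
    counts = [1]
    for yi, wi in zip(y[1:], w[1:]):
        values.append(yi)
        weights.append(wi)
        counts.append(1)
        while len(values) > 1 and values[-2] < values[-1]:
            wtot = weights[-2] + weights[-1]
            vavg = (values[-2] * weights[-2] + values[-1] * weights[-1]) / wtot
            values[-2:] = [vavg]
            weights[-2:] = [wtot]
            counts[-2:] = [counts[-2] + counts[-1]]
    return np.repeat(values, counts)


def ld_decay(
    vm: VariantMatrix,
    pops: PopulationMap,
    population: str,
    max_dist: int = 500_000,
    bin_width: int = 100,
    min_maf: float = 0.05,
    max_missing: float = 0.2,
) -> LDDecayCurve:
    """r^2 decay curve for one population.

    Sites are pre-filtered to MAF >= ``min_maf`` and missingness <=
    ``max_missing`` within the population.  r^2 is the squared Pearson
    correlation of genotype dosages over pairwise-complete samples.
    Binned means are smoothed by an isotonic decreasing fit before
    locating the half-decay distance.
    """
    rows = pops.sample_rows(vm, population)
    sub = vm.take_samples(rows)
    maf = sub.minor_allele_frequency()
    keep = (np.nan_to_num(maf, nan=-1) >= min_maf) & (sub.missing_fraction() <= max_missing)
    sub = sub.take_sites(np.flatnonzero(keep))

    n_bins = int(np.ceil(max_dist / bin_width))
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_width
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    g = sub.genotypes.astype(float)
    g[sub.genotypes == MISSING] = np.nan
    for chrom in dict.fromkeys(sub.chrom):
        mask = sub.chrom == chrom
        pos = sub.pos[mask]
        gc = g[:, mask]
        n = len(pos)
        for i in range(n):
            hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
            for j in range(i + 1, hi):
                x, y = gc[:, i], gc[:, j]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 2:
                    continue
                xs, ys = x[ok], y[ok]
                vx, vy = xs.var(), ys.var()
                if vx == 0 or vy == 0:
                    continue
                cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
                r2 = cov * cov / (vx * vy)
                b = int((pos[j] - pos[i]) // bin_width)
                if b < n_bins:
                    sums[b] += r2
                    counts[b] += 1
    if counts.sum() == 0:
        raise ValueError("no SNP pair within max_dist; empty LD curve")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    nonempty = counts > 0
    smooth = np.full(n_bins, np.nan)
    smooth[nonempty] = _isotonic_decreasing(means[nonempty], counts[nonempty].astype(float))
    max_r2 = float(np.nanmax(smooth))
    half = max_r2 / 2.0
    below = np.flatnonzero(nonempty & (smooth <= half))
    if below.size:
        half_dist = float(edges[below[0]])
    else:
        half_dist = float("nan")
    return LDDecayCurve(
        bin_edges=edges, mean_r2=means, n_pairs=counts,
        max_r2=max_r2, half_decay_distance=half_dist,
    )
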