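"""Selective-sweep scanning and the three-metric intersection caller.

A cross-population composite-likelihood scan (XP-CLR-style) contrasts
object-population allele frequencies against a reference population: at
each genetic-map grid point, a hitchhiking model — each SNP rides the
sweep to fixation or loss with a probability given by a fitted
sweep-strength parameter decaying with genetic distance from the grid
point — is compared against a pure drift model (object frequency
truncated-normal around the reference frequency, variance scaled by a
genome-wide drift coefficient omega).  Empirical top-quantile thresholds per metric (FST,
ln pi-ratio, XP-CLR) are intersected on a shared window grid; runs of
jointly flagged windows merge into candidate sweep regions which are
then mapped to overlapping genes.

This scan is a deliberately simplified variant of the original XP-CLR:
it omits LD-based SNP down-weighting and is validated by planted-sweep
power rather than score equality with the original implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from hazelpop.annotate import GeneAnnotation
from hazelpop.diversity import WindowSpec, _chrom_lengths, _window_grid
from hazelpop.variants import PopulationMap, VariantMatrix

logger = logging.getLogger(__name__)

#: Sweep-strength grid searched at each point: the hitchhiking
#: probability at the sweep center (0 recovers the neutral model).
_LAMBDA_GRID = np.array([0.1, 0.3, 0.5, 0.7, 0.9, 0.99])


@dataclass(frozen=True)
class SweepScanConfig:
    """XP-CLR scan geometry: genetic-map window width (cM), physical grid
    step (bp), SNP cap per window, uniform map scale (cM/Mb) and the
    empirical flagging quantile."""

    window_cm: float = 0.05
    grid_step_bp: int = 100
    max_snps_per_window: int = 200
    cm_per_mb: float = 1.0
    quantile: float = 0.95
    min_snps: int = 5

    def __post_init__(self) -> None:
        if min(self.window_cm, self.grid_step_bp, self.max_snps_per_window,
               self.cm_per_mb) <= 0:
            raise ValueError("scan parameters must be positive")
        if not (0.5 < self.quantile < 1.0):
            raise ValueError("quantile must be in (0.5, 1)")


@dataclass
class SweepRegion:
    """A merged run of windows flagged by all three metrics."""

    chrom: str
    start: int
    end: int
    supporting_metrics: frozenset = frozenset({"fst", "pi_ratio", "xpclr"})
    genes: list[str] = field(default_factory=list)


def _truncnorm_logpdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Log density of Normal(mu, sigma^2) truncated to [0, 1]."""
    z = (x - mu) / sigma
    lognorm = np.log(norm.cdf((1.0 - mu) / sigma) - norm.cdf((0.0 - mu) / sigma))
    return norm.logpdf(z) - np.log(sigma) - lognorm


def xpclr_scan(
    vm: VariantMatrix,
    pops: PopulationMap,
    ref_pop: str,
    obj_pop: str,
    cfg: SweepScanConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Composite-likelihood sweep scores on a physical grid.

    Returns a DataFrame (chrom, pos, n_snps, xpclr).  Grid points with
    fewer than ``cfg.min_snps`` SNPs inside the cM window are NaN.
    """
    cfg = cfg or SweepScanConfig()
    rows_r = pops.sample_rows(vm, ref_pop)
    rows_o = pops.sample_rows(vm, obj_pop)
    if len(rows_r) < 4 or len(rows_o) < 4:
        raise ValueError("both populations need at least 4 samples")

    alt_r, tot_r = vm.allele_counts(rows_r)
    alt_o, tot_o = vm.allele_counts(rows_o)
    ok = (tot_r > 0) & (tot_o > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ref = np.where(tot_r > 0, alt_r / np.maximum(tot_r, 1), np.nan)
        p_obj = np.where(tot_o > 0, alt_o / np.maximum(tot_o, 1), np.nan)
    eps = 1.0 / (2.0 * len(rows_r) * 2.0)
    p_ref_c = np.clip(p_ref, eps, 1.0 - eps)

    # genome-wide drift variance scale omega; the median-based estimator
    # (median of a 1-df scaled chi-square is 0.4549 omega) keeps loci
    # under selection from inflating the neutral drift model
    base_var = p_ref_c * (1.0 - p_ref_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = (p_obj - p_ref_c) ** 2 / base_var
    omega = float(np.nanmedian(ratios[ok]) / 0.4549)
    if not np.isfinite(omega) or omega <= 0:
        omega = float(np.nanmean(ratios[ok]))
    omega = max(omega, 1e-6)

    half_cm = cfg.window_cm / 2.0
    cm_per_bp = cfg.cm_per_mb / 1e6
    half_bp = half_cm / cm_per_bp
    decay_cm = cfg.window_cm / 4.0

    # binomial sampling variance of the object-sample frequency enters
    # both hypotheses; under the sweep model the drift component shrinks
    # as frequencies concentrate near fixation
    with np.errstate(invalid="ignore", divide="ignore"):
        samp_var_all = p_obj * (1.0 - p_obj) / np.maximum(tot_o, 1) + 1e-4

    lengths = _chrom_lengths(vm, chrom_lengths)
    frames = []
    for chrom, length in lengths.items():
        mask = (vm.chrom == chrom) & ok
        pos = vm.pos[mask]
        pr = p_ref_c[mask]
        po = p_obj[mask]
        samp_var = samp_var_all[mask]
        drift_var = omega * pr * (1.0 - pr)
        sigma0 = np.sqrt(drift_var + samp_var)
        neutral = _truncnorm_logpdf(po, pr, sigma0)
        grid = np.arange(0, length, cfg.grid_step_bp, dtype=np.int64)
        scores = np.full(grid.shape, np.nan)
        n_used = np.zeros(grid.shape, dtype=np.int64)
        lo = np.searchsorted(pos, grid - half_bp, side="left")
        hi = np.searchsorted(pos, grid + half_bp, side="right")
        for gi in range(len(grid)):
            sel = np.arange(lo[gi], hi[gi])
            if sel.size < cfg.min_snps:
                continue
            if sel.size > cfg.max_snps_per_window:
                d_all = np.abs(pos[sel] - grid[gi])
                sel = sel[np.argsort(d_all, kind="stable")[: cfg.max_snps_per_window]]
                sel.sort()
            d_cm = np.abs(pos[sel] - grid[gi]) * cm_per_bp
            w = np.exp(-d_cm / decay_cm)
            ll_neutral_site = neutral[sel]
            ll_neutral = ll_neutral_site.sum()
            best = ll_neutral
            pos_ = po[sel]
            sv = samp_var[sel]
            # boundary (post-hitchhiking) density: the swept allele is at
            # fixation or loss up to sampling noise; either allele may
            # ride the sweep, hence the symmetric mixture
            sig_fix = np.sqrt(sv)
            ll_fix = np.logaddexp(
                _truncnorm_logpdf(pos_, np.ones_like(pos_), sig_fix),
                _truncnorm_logpdf(pos_, np.zeros_like(pos_), sig_fix),
            ) - np.log(2.0)
            for lam in _LAMBDA_GRID:
                # a site at genetic distance d hitchhikes with probability
                # c = lam * w(d); otherwise it drifts neutrally
                c = lam * w
                ll = np.logaddexp(np.log1p(-c) + ll_neutral_site,
                                  np.log(c) + ll_fix).sum()
                if ll > best:
                    best = ll
            scores[gi] = 2.0 * (best - ll_neutral)
            n_used[gi] = sel.size
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": grid, "n_snps": n_used, "xpclr": scores}
        ))
    return pd.concat(frames, ignore_index=True)


def xpclr_to_windows(
    scan: pd.DataFrame,
    ws: WindowSpec | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Reduce grid-point scores to a sliding-window grid by within-window
    maximum, so XP-CLR can be thresholded and intersected on the same
    grid as FST and the pi-ratio."""
    ws = ws or WindowSpec()
    frames = []
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(scan.loc[scan["chrom"] == c, "pos"].max()) + 1
            for c in scan["chrom"].unique()
        }
    for chrom, length in chrom_lengths.items():
        sub = scan[scan["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        val = sub["xpclr"].to_numpy(float)
        starts = _window_grid(length, ws)
        ends = np.minimum(starts + ws.size, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        out = np.full(starts.shape, np.nan)
        for i in range(len(starts)):
            seg = val[lo[i]:hi[i]]
            seg = seg[np.isfinite(seg)]
            if seg.size:
                out[i] = seg.max()
        frames.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "xpclr": out}
        ))
    return pd.concat(frames, ignore_index=True)


def quantile_threshold(
    values: Sequence[float] | np.ndarray | pd.Series, q: float = 0.95
) -> tuple[float, np.ndarray]:
    """Empirical q-quantile cutoff (type-7) and >=-cutoff flags.

    Missing values are excluded from the quantile and always unflagged.
    A degenerate (all-identical) distribution flags everything, with a
    warning.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 20:
        raise ValueError("need at least 20 non-missing values for a quantile cutoff")
    vals = arr[finite]
    if np.allclose(vals, vals[0]):
        logger.warning("degenerate score distribution: all values identical")
        cutoff = float(vals[0])
    else:
        cutoff = float(np.quantile(vals, q))  # linear interpolation = type 7
    flags = np.zeros(arr.shape, dtype=bool)
    flags[finite] = arr[finite] >= cutoff
    return cutoff, flags


def intersect_sweeps(
    windows: pd.DataFrame,
    fst_flags: np.ndarray,
    pi_ratio_flags: np.ndarray,
    xpclr_flags: np.ndarray,
) -> list[SweepRegion]:
    """Designate sweep regions: windows flagged by all three metrics,
    with overlapping or bookended survivors merged into maximal regions.

    ``windows`` supplies the shared grid (chrom, start, end); the three
    flag arrays are boolean over its rows.
    """
    for f in (fst_flags, pi_ratio_flags, xpclr_flags):
        if len(f) != len(windows):
            raise ValueError("flag vector length does not match the window grid")
    joint = np.asarray(fst_flags) & np.asarray(pi_ratio_flags) & np.asarray(xpclr_flags)
    regions: list[SweepRegion] = []
    sub = windows.loc[joint, ["chrom", "start", "end"]].sort_values(
        ["chrom", "start"], kind="stable")
    for chrom, grp in sub.groupby("chrom", sort=False):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = int(s), int(e)
            elif s <= cur_e:  # overlap or bookended (gap 0)
                cur_e = max(cur_e, int(e))
            else:
                regions.append(SweepRegion(chrom=chrom, start=cur_s, end=cur_e))
                cur_s, cur_e = int(s), int(e)
        if cur_s is not None:
            regions.append(SweepRegion(chrom=chrom, start=cur_s, end=cur_e))
    return regions


def regions_to_genes(
    regions: Sequence[SweepRegion], ann: GeneAnnotation
) -> list[str]:
    """Attach overlapping genes (>= 1 bp) to each region; return the
    unique union (the positively-selected-gene list), in genomic order."""
    psgs: list[str] = []
    for region in regions:
        hits = [g.id for g in ann.genes
                if g.chrom == region.chrom
                and g.start < region.end and region.start < g.end]
        region.genes = hits
        for h in hits:
            if h not in psgs:
                psgs.append(h)
    return psgs
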