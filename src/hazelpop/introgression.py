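"""ABBA-BABA (Patterson's D) and f4-ratio introgression statistics.

Both statistics assume the fixed rooted topology (((P1,P2)P3)O): under
incomplete lineage sorting alone, discordant ABBA and BABA site patterns
arise at equal rates and D = 0; an excess of ABBA indicates gene flow
between P3 and P2 (D > 0) or P3 and P1 (D < 0).

Sites are polarized by the outgroup consensus: the allele fixed in the
outgroup (among called copies) is taken as ancestral; sites where the
outgroup is polymorphic or entirely missing are dropped.  Pattern sums
are frequency-weighted.  Significance comes from a delete-one block
jackknife over fixed-size physical blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from hazelpop.variants import PopulationMap, VariantMatrix

logger = logging.getLogger(__name__)


@dataclass
class IntrogressionResult:
    """D / f4-ratio estimates with block-jackknife significance."""

    trio: tuple[str, str, str, str]     # (P1, P2, P3, outgroup)
    d: float
    f4_ratio: float
    jackknife_se: float
    z: float
    p: float
    n_sites_used: int
    n_blocks: int


def _derived_freqs(
    vm: VariantMatrix, pops: PopulationMap, trio: tuple[str, str, str, str]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Outgroup-polarized derived-allele frequencies per population.

    Returns (usable-site boolean mask, {pop: derived frequency at usable
    sites}) including one entry per sample of P3 under keys ``__P3_<i>``
    is NOT done here; only the four trio populations are returned.
    """
    p1, p2, p3, out = trio
    freqs: dict[str, np.ndarray] = {}
    called_ok = np.ones(vm.n_sites, dtype=bool)
    for name in (p1, p2, p3):
        alt, tot = vm.allele_counts(pops.sample_rows(vm, name))
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[name] = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        called_ok &= tot > 0
    alt_o, tot_o = vm.allele_counts(pops.sample_rows(vm, out))
    out_fixed_ref = (tot_o > 0) & (alt_o == 0)
    out_fixed_alt = (tot_o > 0) & (alt_o == tot_o)
    usable = called_ok & (out_fixed_ref | out_fixed_alt)
    for name in (p1, p2, p3):
        f = freqs[name]
        freqs[name] = np.where(out_fixed_alt, 1.0 - f, f)
    return usable, freqs


def _block_ids(vm: VariantMatrix, block_size: int) -> np.ndarray:
    """Integer block label per site: chromosome x floor(pos / block_size)."""
    labels = np.empty(vm.n_sites, dtype=np.int64)
    next_id = 0
    seen: dict[tuple[str, int], int] = {}
    for j in range(vm.n_sites):
        key = (vm.chrom[j], int(vm.pos[j]) // block_size)
        if key not in seen:
            seen[key] = next_id
            next_id += 1
        labels[j] = seen[key]
    return labels


def _jackknife(num_blocks: np.ndarray, den_blocks: np.ndarray) -> tuple[float, float]:
    """Delete-one-block SE of a ratio-of-sums statistic.

    Returns (estimate, SE).  Blocks with zero denominator contribution
    still participate (they shift the sums when deleted).
    """
    num_tot = num_blocks.sum()
    den_tot = den_blocks.sum()
    est = num_tot / den_tot
    b = len(num_blocks)
    if b < 2:
        return float(est), float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (num_tot - num_blocks) / (den_tot - den_blocks)
    loo = loo[np.isfinite(loo)]
    if loo.size < 2:
        return float(est), float("nan")
    se = float(np.sqrt((b - 1) / b * np.sum((loo - loo.mean()) ** 2)))
    return float(est), se


def abba_baba(
    vm: VariantMatrix,
    pops: PopulationMap,
    trio: tuple[str, str, str, str],
    block_size: int = 1_000_000,
    compute_f4_ratio: bool = True,
) -> IntrogressionResult:
    """Patterson's D with block-jackknife Z/p for one (P1,P2,P3,O) trio.

    With outgroup-polarized derived frequencies p1, p2, p3:
    ABBA = sum (1-p1) p2 p3 and BABA = sum p1 (1-p2) p3, and
    D = (ABBA - BABA) / (ABBA + BABA).
    """
    usable, freqs = _derived_freqs(vm, pops, trio)
    p1l, p2l, p3l, _ = trio
    idx = np.flatnonzero(usable)
    if idx.size == 0:
        raise ValueError("no usable (outgroup-polarizable, fully called) sites")
    f1, f2, f3 = (freqs[k][idx] for k in (p1l, p2l, p3l))
    abba = (1.0 - f1) * f2 * f3
    baba = f1 * (1.0 - f2) * f3
    if abba.sum() + baba.sum() == 0:
        raise ValueError("ABBA + BABA is zero; D undefined")

    blocks = _block_ids(vm.take_sites(idx), block_size)
    n_blocks = int(blocks.max()) + 1
    if n_blocks < 20:
        logger.warning("only %d jackknife blocks; SE may be unstable", n_blocks)
    num_b = np.bincount(blocks, weights=abba - baba, minlength=n_blocks)
    den_b = np.bincount(blocks, weights=abba + baba, minlength=n_blocks)
    d, se = _jackknife(num_b, den_b)
    z = d / se if se > 0 else np.inf * np.sign(d) if d != 0 else 0.0
    p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else 0.0

    f4r = np.nan
    if compute_f4_ratio:
        try:
            f4r = f4_ratio(vm, pops, trio)
        except ValueError as exc:  # pragma: no cover - degenerate panels
            logger.warning("f4-ratio unavailable: %s", exc)
    return IntrogressionResult(
        trio=trio, d=d, f4_ratio=f4r, jackknife_se=se, z=float(z), p=p,
        n_sites_used=int(idx.size), n_blocks=n_blocks,
    )


def f4_ratio(
    vm: VariantMatrix,
    pops: PopulationMap,
    trio: tuple[str, str, str, str],
    p3_subset_a: list[str] | None = None,
    p3_subset_b: list[str] | None = None,
) -> float:
    """Admixture-fraction estimate alpha for P3 ancestry in P2.

    alpha = f4(P1, P2; P3a, O) / f4(P1, P3b; P3a, O), where the donor
    population P3 is split into two halves (first/second half of its
    sample list unless explicit subsets are given) and
    f4(W,X;Y,Z) = sum (pW - pX)(pY - pZ) over polarized sites (pZ = 0).
    """
    p1l, p2l, p3l, outl = trio
    members = pops.members(p3l)
    if p3_subset_a is None or p3_subset_b is None:
        if len(members) < 2:
            raise ValueError("P3 needs >= 2 samples to split for the f4-ratio")
        half = len(members) // 2
        p3_subset_a, p3_subset_b = members[:half], members[half:]

    usable, freqs = _derived_freqs(vm, pops, trio)
    # derived frequencies for the two P3 subsets under the same polarization
    index = {s: i for i, s in enumerate(vm.sample_ids)}
    alt_o, tot_o = vm.allele_counts(pops.sample_rows(vm, outl))
    out_fixed_alt = (tot_o > 0) & (alt_o == tot_o)
    sub_freqs = []
    for subset in (p3_subset_a, p3_subset_b):
        rows = [index[s] for s in subset]
        alt, tot = vm.allele_counts(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        f = np.where(out_fixed_alt, 1.0 - f, f)
        sub_freqs.append((f, tot > 0))
    (fa, ok_a), (fb, ok_b) = sub_freqs
    idx = np.flatnonzero(usable & ok_a & ok_b)
    if idx.size == 0:
        raise ValueError("no usable sites for the f4-ratio")
    f1 = freqs[p1l][idx]
    f2 = freqs[p2l][idx]
    fa, fb = fa[idx], fb[idx]
    num = float(np.sum((f1 - f2) * (fa - 0.0)))
    den = float(np.sum((f1 - fb) * (fa - 0.0)))
    if abs(den) < 1e-12:
        raise ValueError("denominator f4 is ~0; f4-ratio undefined")
    return num / den
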