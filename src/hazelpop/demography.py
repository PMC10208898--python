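"""Folded-SFS demographic inference for up to three populations.

The observable is the joint folded (minor-allele) site-frequency
spectrum.  Expected spectra under a parameterized divergence history are
obtained by seeded Monte-Carlo coalescent simulation (branch-length
averaging with msprime), scaled per unit theta; the data then enter a
Poisson composite likelihood whose theta is profiled analytically
(theta_hat = sum(obs)/sum(exp)).  Model selection is by AIC over a
catalog of 17 three-population scenarios in five families: divergence
with continuous gene flow, ancient migration, secondary contact,
simultaneous split, and hybrid origin.

Unit conventions (diffusion-style):
  * population sizes ``nu_i`` are in units of the ancestral reference
    size N_ref;
  * times are in units of 2 N_ref generations (``T2`` = recent split of
    p1/p2, ``T1d`` = additional duration back to the older split, so
    T1 = T2 + T1d >= T2 by construction);
  * migration rates ``m_ij`` are 2 N_ref times the per-generation
    fraction of replaced individuals.
Physical units come from N_ref = theta_hat / (4 mu L).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from hazelpop.variants import MISSING, PopulationMap, VariantMatrix

logger = logging.getLogger(__name__)

#: Reference (diploid) population size used inside the simulator.  With
#: N0 = 1/2 one generation equals one coalescent time unit of 2*N_ref
#: generations, so model times/migration rates pass through unscaled.
_N0 = 0.5


# ---------------------------------------------------------------------------
# Folded SFS container
# ---------------------------------------------------------------------------

def _fold(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fold a joint spectrum by total minor-allele count.

    Cells whose total derived count exceeds N/2 are reflected onto their
    complement; cells exactly at N/2 keep half of the combined mass.
    Returns (folded array, mask) where masked cells (the reflected
    half and the two fixed corners) carry no mass.
    """
    dims = arr.shape
    n_tot = sum(d - 1 for d in dims)
    total = np.zeros(dims, dtype=np.int64)
    for axis, d in enumerate(dims):
        shape = [1] * len(dims)
        shape[axis] = d
        total = total + np.arange(d).reshape(shape)
    rev = arr[tuple(slice(None, None, -1) for _ in dims)]
    combined = arr + rev
    folded = np.where(total * 2 < n_tot, combined,
                      np.where(total * 2 == n_tot, combined / 2.0, 0.0))
    mask = (total * 2 > n_tot) | (total == 0)
    folded = np.where(mask, 0.0, folded)
    return folded, mask


@dataclass
class FoldedSFS:
    """Joint minor-allele-count spectrum (or a per-unit-theta expectation).

    ``dims`` holds allele copies per population; ``data`` has shape
    ``tuple(d + 1 for d in dims)``; masked cells (fixed or
    fold-redundant) carry no mass.
    """

    dims: tuple[int, ...]
    data: np.ndarray
    mask: np.ndarray

    @property
    def n_snps(self) -> float:
        return float(self.data[~self.mask].sum())

    def normalized(self) -> np.ndarray:
        return self.data / self.data[~self.mask].sum()

    @classmethod
    def from_unfolded(cls, unfolded: np.ndarray, dims: Sequence[int]) -> "FoldedSFS":
        folded, mask = _fold(np.asarray(unfolded, dtype=float))
        return cls(dims=tuple(dims), data=folded, mask=mask)

    # -- dadi-style .fs text serialization ------------------------------
    def to_file(self, path: str | Path) -> None:
        shape = " ".join(str(d + 1) for d in self.dims)
        body = " ".join(f"{v:.10g}" for v in self.data.ravel())
        maskline = " ".join("1" if m else "0" for m in self.mask.ravel())
        Path(path).write_text(f"{shape} folded\n{body}\n{maskline}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "FoldedSFS":
        lines = Path(path).read_text().splitlines()
        header = lines[0].split()
        shape = tuple(int(x) for x in header[: len(header) - 1]
                      ) if header[-1] == "folded" else tuple(int(x) for x in header)
        data = np.array([float(x) for x in lines[1].split()]).reshape(shape)
        mask = np.array([x == "1" for x in lines[2].split()]).reshape(shape)
        return cls(dims=tuple(d - 1 for d in shape), data=data, mask=mask)


def build_folded_sfs(
    vm: VariantMatrix, pops: PopulationMap, which: Sequence[str]
) -> FoldedSFS:
    """Observed joint folded SFS over 1-3 populations.

    Only complete-case sites (no missing call in any selected sample)
    contribute; every retained SNP adds exactly one unit of mass.
    """
    if not 1 <= len(which) <= 3:
        raise ValueError("which must name 1-3 populations")
    rows_per_pop = [pops.sample_rows(vm, p) for p in which]
    all_rows = [r for rows in rows_per_pop for r in rows]
    complete = ~(vm.genotypes[all_rows, :] == MISSING).any(axis=0)
    idx = np.flatnonzero(complete)
    if idx.size == 0:
        raise ValueError("no complete-case sites for the selected populations")
    dims = tuple(2 * len(rows) for rows in rows_per_pop)
    unfolded = np.zeros(tuple(d + 1 for d in dims))
    counts = []
    for rows in rows_per_pop:
        alt, _ = vm.take_sites(idx).allele_counts(rows)
        counts.append(alt)
    np.add.at(unfolded, tuple(counts), 1.0)
    return FoldedSFS.from_unfolded(unfolded, dims)


# ---------------------------------------------------------------------------
# Demographic models
# ---------------------------------------------------------------------------

@dataclass
class DemographicModel:
    """A parameterized population history with defaults and box bounds.

    ``builder(params)`` returns an ``msprime.Demography`` whose leaf
    populations are named in ``pops`` (sampling order).  Parameter units
    follow the module docstring.
    """

    id: str
    family: str
    params: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    builder: Callable[[Mapping[str, float]], "object"]
    pops: tuple[str, ...] = ("p1", "p2", "p3")

    @property
    def k_free(self) -> int:
        """Free-parameter count for AIC: simplex parameters plus the
        analytically profiled theta."""
        return len(self.params) + 1

    def demography(self, params: Mapping[str, float] | None = None):
        p = dict(self.params)
        if params:
            p.update(params)
        for name, v in p.items():
            nonneg_ok = name.startswith("m") or name == "alpha"
            if v <= 0 and not nonneg_ok:
                raise ValueError(f"parameter {name} must be positive (got {v})")
            if v < 0:
                raise ValueError(f"rate {name} must be >= 0 (got {v})")
        return self.builder(p)


def _base_split_demography(
    nu1: float, nu2: float, nu3: float, nu12: float, nuA: float,
    t2: float, t1: float,
):
    """Nested-split skeleton: anc -> (anc12, p3) at t1; anc12 -> (p1, p2)
    at t2 (both times backwards from the present, t1 >= t2)."""
    import msprime

    d = msprime.Demography()
    d.add_population(name="p1", initial_size=nu1 * _N0)
    d.add_population(name="p2", initial_size=nu2 * _N0)
    d.add_population(name="p3", initial_size=nu3 * _N0)
    d.add_population(name="anc12", initial_size=nu12 * _N0)
    d.add_population(name="anc", initial_size=nuA * _N0)
    d.add_population_split(time=t2, derived=["p1", "p2"], ancestral="anc12")
    d.add_population_split(time=t1, derived=["anc12", "p3"], ancestral="anc")
    return d


def _sym(d, time: float, pairs, rate: float) -> None:
    for a, b in pairs:
        d.add_symmetric_migration_rate_change(time=time, populations=[a, b], rate=rate)


def _sorted_events(d):
    d.sort_events()
    return d


def _build_dgf(p, pairs_key: str = "adjacent", asym: bool = False, free_nu12: bool = False):
    nu12 = p["nu12"] if free_nu12 else 1.0
    t2 = p["T2"]
    t1 = t2 + p["T1d"]
    d = _base_split_demography(p["nu1"], p["nu2"], p["nu3"], nu12, 1.0, t2, t1)
    if asym:
        d.add_migration_rate_change(time=0, source="p2", dest="p3", rate=p["m23a"])
        d.add_migration_rate_change(time=0, source="p3", dest="p2", rate=p["m23b"])
        d.add_migration_rate_change(time=0, source="p1", dest="p2", rate=p["m12a"])
        d.add_migration_rate_change(time=0, source="p2", dest="p1", rate=p["m12b"])
    elif pairs_key == "all":
        _sym(d, 0, [("p1", "p2"), ("p2", "p3"), ("p1", "p3")], p["m"])
        _sym(d, p["T2"], [("anc12", "p3")], p["m"])
    else:
        m12 = p["m12"] if "m12" in p else p["m"]
        m23 = p["m23"] if "m23" in p else p["m"]
        _sym(d, 0, [("p1", "p2")], m12)
        _sym(d, 0, [("p2", "p3")], m23)
        _sym(d, p["T2"], [("anc12", "p3")], m23)
    return _sorted_events(d)


def _build_am(p, pairs_key: str = "adjacent"):
    """Ancient migration: gene flow only in the older epochs; isolation
    for the most recent f_iso fraction of T2."""
    t2 = p["T2"]
    t1 = t2 + p["T1d"]
    t_stop = p["f_iso"] * t2
    d = _base_split_demography(p["nu1"], p["nu2"], p["nu3"], 1.0, 1.0, t2, t1)
    pairs = ([("p1", "p2"), ("p2", "p3"), ("p1", "p3")] if pairs_key == "all"
             else [("p1", "p2"), ("p2", "p3")])
    _sym(d, t_stop, pairs, p["m"])
    _sym(d, t2, [("anc12", "p3")], p["m"])
    return _sorted_events(d)


def _build_sc(p, pairs_key: str = "adjacent", free_fc: bool = False):
    """Secondary contact: splits in isolation, migration restarts for the
    most recent f_c fraction of T2."""
    t2 = p["T2"]
    t1 = t2 + p["T1d"]
    fc = p["f_c"] if free_fc else 0.5
    t_contact = fc * t2
    d = _base_split_demography(p["nu1"], p["nu2"], p["nu3"], 1.0, 1.0, t2, t1)
    if pairs_key == "all":
        for pair in [("p1", "p2"), ("p2", "p3"), ("p1", "p3")]:
            _sym(d, 0, [pair], p["m"])
            _sym(d, t_contact, [pair], 0.0)
    else:
        for pair, key in [(("p1", "p2"), "m12"), (("p2", "p3"), "m23")]:
            _sym(d, 0, [pair], p[key])
            _sym(d, t_contact, [pair], 0.0)
    return _sorted_events(d)


def _build_ss(p, mig: str = "none"):
    """Simultaneous three-way split at time T."""
    import msprime

    d = msprime.Demography()
    d.add_population(name="p1", initial_size=p["nu1"] * _N0)
    d.add_population(name="p2", initial_size=p["nu2"] * _N0)
    d.add_population(name="p3", initial_size=p["nu3"] * _N0)
    d.add_population(name="anc", initial_size=_N0)
    d.add_population_split(time=p["T"], derived=["p1", "p2", "p3"], ancestral="anc")
    if mig == "all":
        _sym(d, 0, [("p1", "p2"), ("p2", "p3"), ("p1", "p3")], p["m"])
    elif mig == "adjacent":
        _sym(d, 0, [("p1", "p2")], p["m12"])
        _sym(d, 0, [("p2", "p3")], p["m23"])
    elif mig == "asym23":
        d.add_migration_rate_change(time=0, source="p2", dest="p3", rate=p["m23a"])
        d.add_migration_rate_change(time=0, source="p3", dest="p2", rate=p["m23b"])
    return _sorted_events(d)


def _build_hyb(p, mig: str = "none"):
    """Hybrid origin: p2 founded at f_h*T1 as an admixture of p1 and p3."""
    import msprime

    t1 = p["T1"]
    th = p["f_h"] * t1
    d = msprime.Demography()
    d.add_population(name="p1", initial_size=p["nu1"] * _N0)
    d.add_population(name="p2", initial_size=p["nu2"] * _N0)
    d.add_population(name="p3", initial_size=p["nu3"] * _N0)
    d.add_population(name="anc", initial_size=_N0)
    d.add_admixture(time=th, derived="p2", ancestral=["p1", "p3"],
                    proportions=[p["f_adm"], 1.0 - p["f_adm"]])
    d.add_population_split(time=t1, derived=["p1", "p3"], ancestral="anc")
    # migration involving the hybrid must stop (backwards in time) at its
    # founding event, else lineages could migrate into an inactive deme
    if mig == "parents":
        _sym(d, 0, [("p1", "p2"), ("p2", "p3")], p["m"])
        _sym(d, th, [("p1", "p2"), ("p2", "p3")], 0.0)
    elif mig == "m23":
        _sym(d, 0, [("p2", "p3")], p["m"])
        _sym(d, th, [("p2", "p3")], 0.0)
    return _sorted_events(d)


def _trio_outgroup_builder(p):
    """Nested trio (((p1,p2),p3),out) plus an optional introgression
    pulse from p3 into p2 at time ``t_adm`` with fraction ``alpha``."""
    import msprime

    d = msprime.Demography()
    for name, nu in (("p1", p["nu1"]), ("p2", p["nu2"]), ("p3", p["nu3"]),
                     ("out", p.get("nu_out", 1.0))):
        d.add_population(name=name, initial_size=nu * _N0)
    d.add_population(name="anc12", initial_size=_N0)
    d.add_population(name="anc123", initial_size=_N0)
    d.add_population(name="root", initial_size=_N0)
    alpha = p.get("alpha", 0.0)
    if alpha > 0:
        d.add_mass_migration(time=p.get("t_adm", 0.1), source="p2", dest="p3",
                             proportion=alpha)
    d.add_population_split(time=p["T2"], derived=["p1", "p2"], ancestral="anc12")
    d.add_population_split(time=p["T2"] + p["T1d"], derived=["anc12", "p3"],
                           ancestral="anc123")
    d.add_population_split(time=p["T_out"], derived=["anc123", "out"],
                           ancestral="root")
    return _sorted_events(d)


def trio_with_outgroup_model(
    alpha: float = 0.0, t_adm: float = 0.1, T2: float = 0.5, T1d: float = 0.5,
    T_out: float = 3.0,
) -> DemographicModel:
    """Fixed-topology trio + outgroup history for introgression testing.

    ``alpha`` is the admixture fraction of a recent pulse from p3 into
    p2 (0 = incomplete-lineage-sorting-only null, D should be 0).
    """
    params = {"nu1": 1.0, "nu2": 1.0, "nu3": 1.0, "T1d": T1d, "T2": T2,
              "T_out": T_out, "alpha": alpha, "t_adm": t_adm}
    bounds = {k: (1e-3, 100.0) for k in params}
    return DemographicModel(
        id="trio_outgroup", family="introgression_harness", params=params,
        bounds=bounds, builder=_trio_outgroup_builder,
        pops=("p1", "p2", "p3", "out"),
    )


def _two_pop_builder(p):
    import msprime

    d = msprime.Demography()
    d.add_population(name="p1", initial_size=p["nu1"] * _N0)
    d.add_population(name="p2", initial_size=p["nu2"] * _N0)
    d.add_population(name="anc", initial_size=_N0)
    d.add_population_split(time=p["T"], derived=["p1", "p2"], ancestral="anc")
    if p.get("m", 0.0) > 0:
        _sym(d, 0, [("p1", "p2")], p["m"])
    return _sorted_events(d)


def two_pop_split_model(T: float = 0.5, m: float = 0.0,
                        nu1: float = 1.0, nu2: float = 1.0) -> DemographicModel:
    """Two-population split (optionally with symmetric migration), for
    differentiation and sweep-scan test harnesses."""
    params = {"nu1": nu1, "nu2": nu2, "T": T, "m": m}
    return DemographicModel(
        id="two_pop_split", family="harness", params=params,
        bounds={k: (1e-3, 100.0) for k in params},
        builder=_two_pop_builder, pops=("p1", "p2"),
    )


def _constant_builder(p):
    import msprime

    d = msprime.Demography()
    d.add_population(name="p1", initial_size=p.get("nu1", 1.0) * _N0)
    return d


def constant_size_model() -> DemographicModel:
    """Single constant-size population (analytic-oracle reference)."""
    return DemographicModel(
        id="constant_1pop", family="constant",
        params={"nu1": 1.0}, bounds={"nu1": (1e-3, 1e3)},
        builder=_constant_builder, pops=("p1",),
    )


_NU_B = (0.05, 10.0)
_T_B = (0.01, 5.0)
_M_B = (0.0, 10.0)
_F_B = (0.05, 0.95)


def _mk(id_, family, names, builder, defaults=None) -> DemographicModel:
    base = {"nu1": 1.0, "nu2": 1.0, "nu3": 1.0, "nu12": 1.0,
            "T1d": 0.2, "T2": 0.5, "T": 0.5, "T1": 0.7,
            "m": 1.0, "m12": 1.0, "m23": 1.0,
            "m12a": 1.0, "m12b": 1.0, "m23a": 1.0, "m23b": 1.0,
            "f_iso": 0.5, "f_c": 0.5, "f_h": 0.5, "f_adm": 0.5}
    bounds = {}
    for n in names:
        if n.startswith("nu"):
            bounds[n] = _NU_B
        elif n.startswith("T"):
            bounds[n] = _T_B
        elif n.startswith("m"):
            bounds[n] = _M_B
        else:
            bounds[n] = _F_B
    params = {n: base[n] for n in names}
    if defaults:
        params.update(defaults)
    return DemographicModel(id=id_, family=family, params=params,
                            bounds=bounds, builder=builder)


def model_catalog() -> dict[str, DemographicModel]:
    """The 17-model menu over the five divergence-scenario families."""
    models = [
        # divergence with continuous gene flow (1-4)
        _mk("dgf_adjacent_sym", "divergence_with_gene_flow",
            ["nu1", "nu2", "nu3", "T1d", "T2", "m12", "m23"],
            lambda p: _build_dgf(p)),
        _mk("dgf_all_sym", "divergence_with_gene_flow",
            ["nu1", "nu2", "nu3", "T1d", "T2", "m"],
            lambda p: _build_dgf(p, pairs_key="all")),
        _mk("dgf_adjacent_asym", "divergence_with_gene_flow",
            ["nu1", "nu2", "nu3", "T1d", "T2", "m12a", "m12b", "m23a", "m23b"],
            lambda p: _build_dgf(p, asym=True)),
        _mk("dgf_adjacent_sym_nu12", "divergence_with_gene_flow",
            ["nu1", "nu2", "nu3", "nu12", "T1d", "T2", "m12", "m23"],
            lambda p: _build_dgf(p, free_nu12=True)),
        # ancient migration (5-7)
        _mk("am_adjacent_sym", "ancient_migration",
            ["nu1", "nu2", "nu3", "T1d", "T2", "m", "f_iso"],
            lambda p: _build_am(p)),
        _mk("am_all_sym", "ancient_migration",
            ["nu1", "nu2", "nu3", "T1d", "T2", "m"],
            lambda p: _build_am({**p, "f_iso": 0.5}, pairs_key="all")),
        _mk("am_adjacent_sym_long", "ancient_migration",
            ["nu1", "nu2", "nu3", "T1d", "T2", "m"],
            lambda p: _build_am({**p, "f_iso": 0.8})),
        # secondary contact (8-10); model 9 is the flagship scenario:
        # adjacent secondary contact with symmetric migration after a
        # shorter isolation
        _mk("sc_adjacent_sym", "secondary_contact",
            ["nu1", "nu2", "nu3", "T1d", "T2", "m12", "m23"],
            lambda p: _build_sc(p)),
        _mk("sc_adjacent_sym_tc", "secondary_contact",
            ["nu1", "nu2", "nu3", "T1d", "T2", "m12", "m23", "f_c"],
            lambda p: _build_sc(p, free_fc=True)),
        _mk("sc_all_sym", "secondary_contact",
            ["nu1", "nu2", "nu3", "T1d", "T2", "m"],
            lambda p: _build_sc(p, pairs_key="all")),
        # simultaneous split (11-14)
        _mk("ss_nomig", "simultaneous_split",
            ["nu1", "nu2", "nu3", "T"], lambda p: _build_ss(p)),
        _mk("ss_all_sym", "simultaneous_split",
            ["nu1", "nu2", "nu3", "T", "m"], lambda p: _build_ss(p, mig="all")),
        _mk("ss_adjacent_sym", "simultaneous_split",
            ["nu1", "nu2", "nu3", "T", "m12", "m23"],
            lambda p: _build_ss(p, mig="adjacent")),
        _mk("ss_asym23", "simultaneous_split",
            ["nu1", "nu2", "nu3", "T", "m23a", "m23b"],
            lambda p: _build_ss(p, mig="asym23")),
        # hybrid origin (15-17)
        _mk("hyb_nomig", "hybrid_origin",
            ["nu1", "nu2", "nu3", "T1", "f_h", "f_adm"],
            lambda p: _build_hyb(p)),
        _mk("hyb_parent_sym", "hybrid_origin",
            ["nu1", "nu2", "nu3", "T1", "f_h", "f_adm", "m"],
            lambda p: _build_hyb(p, mig="parents")),
        _mk("hyb_m23_sym", "hybrid_origin",
            ["nu1", "nu2", "nu3", "T1", "f_h", "f_adm", "m"],
            lambda p: _build_hyb(p, mig="m23")),
    ]
    return {m.id: m for m in models}


# ---------------------------------------------------------------------------
# Expected SFS by coalescent branch-length averaging
# ---------------------------------------------------------------------------

def expected_sfs(
    model: DemographicModel,
    dims: Sequence[int],
    n_reps: int = 10_000,
    seed: int = 1,
    params: Mapping[str, float] | None = None,
    fold: bool = True,
) -> FoldedSFS:
    """Monte-Carlo expected SFS per unit theta under ``model``.

    Simulates a recombining coalescent whose sequence length carries
    ``n_reps`` units of map length (about one marginal genealogy each)
    and averages the branch-mode joint allele-frequency spectrum.  The
    result is scaled so that an observed spectrum has expectation
    ``theta * exp`` with theta = 4 N_ref mu L.  Deterministic given
    ``seed``.
    """
    import msprime

    if len(dims) != len(model.pops):
        raise ValueError("dims length must match the model's population count")
    demog = model.demography(params)
    samples = [msprime.SampleSet(d, population=p, ploidy=1)
               for d, p in zip(dims, model.pops)]
    sets = []
    offset = 0
    for d in dims:
        sets.append(list(range(offset, offset + d)))
        offset += d
    # the ancestral-recombination-graph cost grows faster than linearly
    # with map length, so the requested map length is simulated in
    # fixed-size chunks and the branch spectra averaged
    chunk = 2_000
    n_left = max(int(n_reps), 1)
    base = max(int(seed) % (2 ** 31 - 1 - 10_000), 1)
    afs_sum = None
    weight = 0.0
    i = 0
    while n_left > 0:
        this = min(chunk, n_left)
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demog,
            sequence_length=float(this),
            recombination_rate=1.0,
            discrete_genome=False,
            random_seed=base + i,
        )
        afs = ts.allele_frequency_spectrum(
            sample_sets=sets, mode="branch", polarised=True, span_normalise=True
        )
        afs_sum = afs * this if afs_sum is None else afs_sum + afs * this
        weight += this
        n_left -= this
        i += 1
    # branch lengths are in generations = coalescent units here (2*N0=1);
    # per-unit-theta expectation is B/(4*N0) = B/2
    exp_unfolded = (afs_sum / weight) / (4.0 * _N0)
    if not fold:
        total = np.zeros_like(exp_unfolded, dtype=bool)
        return FoldedSFS(dims=tuple(dims), data=exp_unfolded, mask=total)
    return FoldedSFS.from_unfolded(exp_unfolded, dims)


def analytic_folded_1pop(n: int) -> np.ndarray:
    """Closed-form folded spectrum shape for one constant-size population
    of ``n`` allele copies: eta_i proportional to 1/i + 1/(n-i), halved at
    i = n/2.  Returned normalized to sum 1 (independent oracle)."""
    vals = []
    for i in range(1, n // 2 + 1):
        v = 1.0 / i + (1.0 / (n - i) if i != n - i else 0.0)
        if 2 * i == n:
            v = 1.0 / i
        vals.append(v)
    out = np.array(vals)
    return out / out.sum()


# ---------------------------------------------------------------------------
# Composite likelihood, fitting, model selection
# ---------------------------------------------------------------------------

def theta_hat(obs: FoldedSFS, exp_per_theta: FoldedSFS) -> float:
    """Closed-form profile-ML theta: sum(obs) / sum(exp) over live cells."""
    live = ~(obs.mask | exp_per_theta.mask)
    denom = exp_per_theta.data[live].sum()
    if denom <= 0:
        raise ValueError("expected spectrum has zero total mass")
    return float(obs.data[live].sum() / denom)


def composite_loglik(
    obs: FoldedSFS,
    exp_per_theta: FoldedSFS,
    theta: float | None = None,
    eps: float = 1e-5,
) -> float:
    """Poisson composite log-likelihood of the observed folded SFS.

    Each live cell contributes obs*ln(theta*exp) - theta*exp - ln(obs!).
    With ``theta=None`` the analytic profile value is used.  Expected
    cells at 0 with positive observations are floored at ``eps`` times
    the total expected mass (a Monte-Carlo expectation can put exactly
    zero mass in a rare cell; a hard zero would let one such cell
    dominate the likelihood).
    """
    if obs.data.shape != exp_per_theta.data.shape:
        raise ValueError("observed and expected spectra have different shapes")
    if theta is None:
        theta = theta_hat(obs, exp_per_theta)
    live = ~(obs.mask | exp_per_theta.mask)
    o = obs.data[live]
    e = exp_per_theta.data[live]
    floor = eps * max(e.sum(), 1e-300)
    zero_exp = (e < floor) & (o > 0)
    if zero_exp.any():
        logger.debug("%d expected-SFS cells below floor with observations",
                     int(zero_exp.sum()))
    e = np.maximum(e, floor)
    lam = theta * e
    return float(np.sum(o * np.log(lam) - lam - gammaln(o + 1.0)))


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2*loglik."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * loglik


@dataclass
class FitResult:
    """Best composite-likelihood fit of one model to an observed SFS."""

    model_id: str
    family: str
    params_hat: dict[str, float]
    theta_hat: float
    loglik: float
    k: int
    aic: float
    n_starts: int
    converted: dict[str, float] = field(default_factory=dict)


def fit_model(
    model: DemographicModel,
    obs: FoldedSFS,
    n_starts: int = 50,
    perturb_fold: float = 3.0,
    maxiter: int = 20,
    seed: int = 1,
    n_reps: int = 200,
    reselect_reps: int = 1_500,
    top_k: int = 2,
    refine_schedule: Sequence[tuple[int, int]] = ((1_500, 40), (2_500, 40)),
    polish: tuple[int, int] = (4_000, 30),
    final_reps: int = 8_000,
) -> FitResult:
    """Multi-start bounded Nelder-Mead fit of ``model`` to ``obs``.

    Each start multiplies the default parameters by independent
    log-uniform factors in [1/perturb_fold, perturb_fold] and runs
    Nelder-Mead in log-parameter space for at most ``maxiter`` simplex
    iterations at Monte-Carlo precision ``n_reps``.  The expected
    spectrum uses one fixed simulation seed throughout (common random
    numbers), making the objective deterministic.  Because the
    low-precision surface can mis-rank candidate optima, every start's
    endpoint is re-evaluated once at ``reselect_reps``, and the best
    ``top_k`` candidates are each refined through ``refine_schedule``
    — a ladder of (simulation reps, max iterations) Nelder-Mead stages
    at increasing precision, each preceded by a 1-D line search along
    the spectrum's soft scale direction (all sizes and times scaled by
    c, migration by 1/c; this near-ridge of SFS-only inference is where
    simplex descent crawls).  The overall winner gets a final
    ``polish`` stage, and the reported log-likelihood, theta and AIC
    are evaluated once at ``final_reps`` so fits of different models
    are comparable.  Theta is profiled analytically everywhere.
    """
    rng = np.random.default_rng(seed)
    names = list(model.params)
    defaults = np.array([model.params[n] for n in names])
    lo = np.array([model.bounds[n][0] for n in names])
    hi = np.array([model.bounds[n][1] for n in names])
    sim_seed = int(rng.integers(1, 2 ** 31 - 1))

    def make_objective(reps: int):
        def objective(x: np.ndarray) -> float:
            vals = np.exp(x)
            if np.any(vals < lo) or np.any(vals > hi):
                return 1e12
            p = dict(zip(names, vals))
            exp = expected_sfs(model, obs.dims, n_reps=reps, seed=sim_seed, params=p)
            try:
                return -composite_loglik(obs, exp)
            except ValueError:
                return 1e12
        return objective

    objective = make_objective(n_reps)
    endpoints = []
    for _ in range(n_starts):
        factors = np.exp(rng.uniform(-np.log(perturb_fold), np.log(perturb_fold),
                                     size=len(names)))
        x0 = np.log(np.clip(defaults * factors, lo, hi))
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-3})
        if np.isfinite(res.fun) and res.fun < 1e11:
            endpoints.append((res.fun, res.x))
    if not endpoints:
        raise RuntimeError(f"all {n_starts} starts failed for model {model.id}")
    if reselect_reps > n_reps and len(endpoints) > 1:
        reselect = make_objective(reselect_reps)
        endpoints = [(reselect(x), x) for _, x in endpoints]
    endpoints.sort(key=lambda t: t[0])

    # soft scale direction: nu, T up by c; m down by c; fractions fixed
    scale_dir = np.array([1.0 if (n.startswith("nu") or n.startswith("T"))
                          else (-1.0 if n.startswith("m") else 0.0)
                          for n in names])

    def line_search(x: np.ndarray, objective_fn) -> np.ndarray:
        if not scale_dir.any():
            return x
        cs = np.exp(np.linspace(np.log(0.4), np.log(2.5), 13))
        vals = [objective_fn(x + np.log(c) * scale_dir) for c in cs]
        return x + np.log(cs[int(np.argmin(vals))]) * scale_dir

    def refine(x: np.ndarray, schedule) -> np.ndarray:
        for reps, iters in schedule:
            fn = make_objective(reps)
            x = line_search(x, fn)
            res = minimize(fn, x, method="Nelder-Mead",
                           options={"maxiter": iters,
                                    "xatol": 1e-5, "fatol": 1e-4})
            if np.isfinite(res.fun) and res.fun < 1e11:
                x = res.x
        return x

    candidates = [refine(x, refine_schedule)
                  for _, x in endpoints[:max(top_k, 1)]]
    if len(candidates) > 1:
        judge = make_objective(max(r for r, _ in refine_schedule)
                               if refine_schedule else reselect_reps)
        best_x = min(candidates, key=judge)
    else:
        best_x = candidates[0]
    if polish is not None:
        best_x = refine(best_x, [polish])
    params_hat = dict(zip(names, np.exp(best_x)))
    exp = expected_sfs(model, obs.dims, n_reps=max(final_reps, n_reps),
                       seed=sim_seed, params=params_hat)
    th = theta_hat(obs, exp)
    ll = composite_loglik(obs, exp, theta=th)
    k = model.k_free
    return FitResult(
        model_id=model.id, family=model.family, params_hat=params_hat,
        theta_hat=th, loglik=ll, k=k, aic=aic(ll, k),
        n_starts=n_starts,
    )


def parametric_bootstrap(
    model: DemographicModel,
    fit: FitResult,
    dims: Sequence[int],
    n_boot: int = 100,
    seed: int = 1,
    alpha: float = 0.05,
    exp_reps: int = 5_000,
    **fit_kwargs,
) -> dict[str, tuple[float, float]]:
    """Percentile confidence intervals by parametric bootstrap.

    Simulates ``n_boot`` Poisson spectra from the fitted model
    (theta_hat times the expected spectrum at the fitted parameters)
    and refits each; returns per-parameter (lower, upper) percentile
    bounds at level ``1 - alpha``.  Off by default in every pipeline —
    refitting is expensive — and exposed for explicit calls;
    ``fit_kwargs`` tune the per-replicate fit (use light settings).
    """
    rng = np.random.default_rng(seed)
    exp = expected_sfs(model, dims, n_reps=exp_reps,
                       seed=int(rng.integers(1, 2 ** 31 - 1)),
                       params=fit.params_hat)
    lam = np.where(exp.mask, 0.0, fit.theta_hat * exp.data)
    draws: dict[str, list[float]] = {k: [] for k in fit.params_hat}
    for _ in range(n_boot):
        boot = FoldedSFS(dims=tuple(dims), data=rng.poisson(lam).astype(float),
                         mask=exp.mask)
        bfit = fit_model(model, boot,
                         seed=int(rng.integers(1, 2 ** 31 - 1)), **fit_kwargs)
        for k, v in bfit.params_hat.items():
            draws[k].append(v)
    out = {}
    for k, vals in draws.items():
        out[k] = (float(np.quantile(vals, alpha / 2)),
                  float(np.quantile(vals, 1 - alpha / 2)))
    return out


def select_model(fits: Sequence[FitResult]) -> list[FitResult]:
    """Rank fits by ascending AIC (ties: fewer parameters, then id)."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to rank")
    return sorted(fits, key=lambda f: (f.aic, f.k, f.model_id))


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitConstants:
    """Physical constants linking genetic to real units: per-generation
    per-base mutation rate, generation time in years, and callable
    genome length in bp."""

    mu: float = 3.75e-8
    gen_time: float = 15.0
    L: float = 370.75e6

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.gen_time <= 0 or self.L <= 0:
            raise ValueError("all unit constants must be positive")


def convert_units(fit: FitResult, const: UnitConstants) -> dict[str, float]:
    """Convert a fit to physical units via N_ref = theta/(4 mu L).

    Sizes ``nu_i`` become diploid Ne; times (2 N_ref generations) become
    years; migration M = 2 N_ref m becomes effective migrant lineages
    per generation, M * nu_receiving / 2, reported per rate parameter
    under the receiving population where identifiable, else as M/2.
    """
    n_ref = fit.theta_hat / (4.0 * const.mu * const.L)
    out: dict[str, float] = {"N_ref": n_ref}
    p = fit.params_hat
    for name, v in p.items():
        if name.startswith("nu"):
            out[f"Ne_{name[2:]}"] = v * n_ref
        elif name.startswith("T"):
            out[f"{name}_years"] = 2.0 * n_ref * v * const.gen_time
        elif name.startswith("m"):
            out[f"migrants_per_gen_{name}"] = v / 2.0
    # cumulative split times where the nested parameterization applies
    if "T1d" in p and "T2" in p:
        out["T1_years"] = 2.0 * n_ref * (p["T1d"] + p["T2"]) * const.gen_time
    fit.converted.update(out)
    return out
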