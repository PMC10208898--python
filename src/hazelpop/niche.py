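"""Niche-overlap statistics and the permutation identity test.

Habitat-suitability surfaces are compared with Schoener's D and the
standardized Hellinger similarity I (both in [0, 1]; 1 = identical
niches, 0 = disjoint).  The identity (niche-equivalency) test pools two
species' occurrence records, re-splits them at random preserving sample
sizes, and compares the observed D/I to the permutation null.

The suitability model is pluggable; the default projects occurrences
into environmental space and fits a Gaussian kernel density, evaluated
over all valid grid cells.  Observed D/I values therefore depend on the
chosen suitability model; inference rests on the permutation null, not
on absolute overlap values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)


@dataclass
class SuitabilityRaster:
    """Non-negative suitability grid with a validity mask; normalized so
    the valid cells sum to 1."""

    grid: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.grid.shape != self.valid.shape:
            raise ValueError("grid and validity mask shapes differ")
        if np.any(self.grid[self.valid] < 0):
            raise ValueError("suitability values must be >= 0")

    def normalized(self) -> "SuitabilityRaster":
        total = self.grid[self.valid].sum()
        if total <= 0:
            raise ValueError("raster has zero total suitability")
        out = np.where(self.valid, self.grid / total, 0.0)
        return SuitabilityRaster(grid=out, valid=self.valid.copy())


@dataclass
class OccurrenceSet:
    """Species occurrence records as (longitude, latitude) pairs."""

    species: str
    coords: np.ndarray  # (n, 2) lon, lat

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_csv(cls, path, species: str | None = None) -> "OccurrenceSet":
        df = pd.read_csv(path)
        if species is not None:
            df = df[df["species"] == species]
        else:
            species = str(df["species"].iloc[0])
        return cls(species=species, coords=df[["lon", "lat"]].to_numpy())


@dataclass
class EnvGrid:
    """Environmental layers on a shared lon/lat grid.

    ``layers`` maps variable name -> 2-D array with shape
    (len(lat), len(lon)); ``valid`` marks usable cells.
    """

    lon: np.ndarray
    lat: np.ndarray
    layers: dict[str, np.ndarray]
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (len(self.lat), len(self.lon))
        for name, arr in self.layers.items():
            if arr.shape != shape:
                raise ValueError(f"layer {name} shape {arr.shape} != {shape}")
        if self.valid is None:
            self.valid = np.ones(shape, dtype=bool)

    def values_at(self, coords: np.ndarray, variables: Sequence[str]) -> np.ndarray:
        """Nearest-cell environmental values at coordinate pairs."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        ci = np.argmin(np.abs(self.lon[None, :] - coords[:, [0]]), axis=1)
        ri = np.argmin(np.abs(self.lat[None, :] - coords[:, [1]]), axis=1)
        return np.column_stack([self.layers[v][ri, ci] for v in variables])

    def cell_values(self, variables: Sequence[str]) -> np.ndarray:
        """(n_valid_cells, k) environmental values over valid cells."""
        return np.column_stack([self.layers[v][self.valid] for v in variables])


def prune_env_correlated(env: pd.DataFrame, r_max: float = 0.75) -> list[str]:
    """Greedy redundancy removal over environmental variables.

    Variables (columns, scanned in input order) are retained unless
    |Pearson r| with an already-retained variable exceeds ``r_max``.
    Constant variables have undefined correlations and are dropped with
    a warning.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least two environmental variables")
    retained: list[str] = []
    for name in env.columns:
        x = env[name].to_numpy(float)
        if np.std(x) == 0:
            logger.warning("variable %s is constant; dropped", name)
            continue
        redundant = False
        for kept in retained:
            r = np.corrcoef(x, env[kept].to_numpy(float))[0, 1]
            if abs(r) > r_max:
                redundant = True
                break
        if not redundant:
            retained.append(name)
    return retained


def _check_pair(a: SuitabilityRaster, b: SuitabilityRaster) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if a.grid.shape != b.grid.shape:
        raise ValueError("rasters have different extents")
    shared = a.valid & b.valid
    an = a.grid.copy()
    bn = b.grid.copy()
    ta = an[shared].sum()
    tb = bn[shared].sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("raster has zero mass on the shared mask")
    return an[shared] / ta, bn[shared] / tb, shared


def schoener_d(a: SuitabilityRaster, b: SuitabilityRaster) -> float:
    """Schoener's D = 1 - 0.5 * sum |a - b| over the shared valid mask
    (both surfaces renormalized on that mask)."""
    av, bv, _ = _check_pair(a, b)
    return float(np.clip(1.0 - 0.5 * np.abs(av - bv).sum(), 0.0, 1.0))


def hellinger_i(a: SuitabilityRaster, b: SuitabilityRaster) -> float:
    """Standardized Hellinger similarity I = 1 - 0.5 * sum (sqrt a - sqrt b)^2.

    Clamped to [0, 1] against floating-point residue at the endpoints.
    """
    av, bv, _ = _check_pair(a, b)
    return float(np.clip(1.0 - 0.5 * np.sum((np.sqrt(av) - np.sqrt(bv)) ** 2),
                         0.0, 1.0))


def kde_suitability(
    occ: OccurrenceSet, env: EnvGrid, variables: Sequence[str]
) -> SuitabilityRaster:
    """Default suitability model: Gaussian KDE in standardized
    environmental space, evaluated at every valid grid cell."""
    train = env.values_at(occ.coords, variables)
    cells = env.cell_values(variables)
    mu = cells.mean(axis=0)
    sd = cells.std(axis=0)
    sd[sd == 0] = 1.0
    kde = gaussian_kde(((train - mu) / sd).T)
    dens = kde(((cells - mu) / sd).T)
    grid = np.zeros(env.valid.shape)
    grid[env.valid] = np.maximum(dens, 0.0)
    return SuitabilityRaster(grid=grid, valid=env.valid.copy()).normalized()


@dataclass
class IdentityTestResult:
    d_observed: float
    i_observed: float
    d_null: np.ndarray
    i_null: np.ndarray
    p_d: float | None
    p_i: float | None


def identity_test(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    env: EnvGrid,
    variables: Sequence[str],
    n_perm: int = 99,
    suitability_model: Callable[[OccurrenceSet, EnvGrid, Sequence[str]], SuitabilityRaster]
        | None = None,
    seed: int = 1,
) -> IdentityTestResult:
    """Niche identity (equivalency) test.

    Observed D and I come from per-species suitability models; the null
    pools all occurrences, re-splits them at random preserving sample
    sizes, and recomputes both statistics ``n_perm`` times.  One-sided
    p = (1 + #{null <= observed}) / (n_perm + 1), so p can never be 0.
    With ``n_perm=0`` only the observed values are returned.
    """
    model = suitability_model or kde_suitability
    if 0 < n_perm < 20:
        logger.warning("n_perm=%d is very small; p-value resolution is coarse", n_perm)
    ra = model(occ_a, env, variables)
    rb = model(occ_b, env, variables)
    d_obs = schoener_d(ra, rb)
    i_obs = hellinger_i(ra, rb)
    if n_perm == 0:
        return IdentityTestResult(d_obs, i_obs, np.array([]), np.array([]), None, None)
    rng = np.random.default_rng(seed)
    pooled = np.vstack([occ_a.coords, occ_b.coords])
    na = occ_a.n
    d_null = np.empty(n_perm)
    i_null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        sa = OccurrenceSet("null_a", pooled[perm[:na]])
        sb = OccurrenceSet("null_b", pooled[perm[na:]])
        rna = model(sa, env, variables)
        rnb = model(sb, env, variables)
        d_null[k] = schoener_d(rna, rnb)
        i_null[k] = hellinger_i(rna, rnb)
    p_d = (1.0 + np.sum(d_null <= d_obs)) / (n_perm + 1.0)
    p_i = (1.0 + np.sum(i_null <= i_obs)) / (n_perm + 1.0)
    return IdentityTestResult(d_obs, i_obs, d_null, i_null, float(p_d), float(p_i))
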