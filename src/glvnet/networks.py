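"""Synthetic interaction networks and host-specific parameter ensembles.

Communities are described by per-species intrinsic growth rates ``r_i``,
carrying capacities ``K_i`` and an interspecific interaction matrix ``A``
(entry ``alpha_ij`` = per-capita effect of species *j* on the growth of
species *i*; the diagonal is zero because self-limitation enters the
dynamics through ``K``). Species-level parameters are drawn once per
community; host-level replicates are lognormal perturbations around them,
with the sign and the zero pattern of ``A`` held fixed across hosts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TopologySpec",
    "StrengthDistribution",
    "InteractionMatrix",
    "SpeciesEnsemble",
    "HostEnsemble",
    "sample_species_baseline",
    "sample_topology",
    "sample_strengths",
    "sample_host_ensemble",
    "sample_community",
    "edge_list",
    "host_ensemble_table",
]

_STRUCTURES = ("random", "producer_consumer", "hub")
_FAMILIES = ("gaussian_mixture", "uniform", "unimodal")


@dataclass(frozen=True)
class TopologySpec:
    """Where interactions sit in the community.

    Parameters
    ----------
    n_species : int
        Community size ``s`` (at least 2).
    density : float
        Fraction of the ``s*(s-1)`` ordered off-diagonal pairs that carry an
        interaction, in [0, 1].
    structure : {"random", "producer_consumer", "hub"}
        ``random``: each ordered pair present independently with probability
        ``density``. ``producer_consumer``: same placement, but the species are
        split into equal producer/consumer halves which later receive
        block-dependent interaction signs (cross-feeding). ``hub``: union of two
        directed preferential-attachment graphs (incoming and outgoing roles),
        adjusted to the requested density, yielding hub species with unusually
        many interactions.
    hub_power : float
        Preferential-attachment exponent for the hub structure (default 2).
    """

    n_species: int
    density: float
    structure: str = "random"
    hub_power: float = 2.0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        if self.structure not in _STRUCTURES:
            raise ValueError(f"structure must be one of {_STRUCTURES}")
        if self.structure == "producer_consumer" and self.n_species % 2:
            raise ValueError("producer_consumer requires an even n_species")
        if self.structure == "hub" and self.n_species < 3:
            raise ValueError("hub structure needs at least 3 species")


@dataclass(frozen=True)
class StrengthDistribution:
    """Distribution of interaction strengths, truncated to ``[-bound, bound]``.

    Families: ``gaussian_mixture`` (equal-weight N(+mu, sd) / N(-mu, sd),
    the default with mu = 0.25, sd = 0.1), ``uniform`` on (-bound, bound),
    and ``unimodal`` N(0, unimodal_sd). Truncation is enforced by rejection
    resampling, not clipping, so no probability mass piles up at the bounds.
    """

    family: str = "gaussian_mixture"
    mixture_mean: float = 0.25
    mixture_sd: float = 0.1
    unimodal_sd: float = 0.15
    bound: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.bound <= 0 or not np.isfinite(self.bound):
            raise ValueError("truncation bound must be positive and finite")
        if self.mixture_sd <= 0 or self.unimodal_sd <= 0:
            raise ValueError("component standard deviations must be positive")


@dataclass(frozen=True)
class InteractionMatrix:
    """Signed interspecific coefficients with their structural mask."""

    values: np.ndarray  # (s, s), zero diagonal
    mask: np.ndarray  # (s, s) bool, zero diagonal

    def __post_init__(self) -> None:
        v, m = np.asarray(self.values, float), np.asarray(self.mask, bool)
        if v.shape != m.shape or v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values and mask must be matching square matrices")
        if np.any(np.diag(v) != 0) or np.any(np.diag(m)):
            raise ValueError("diagonal must be structurally zero")
        if np.any(v[~m] != 0):
            raise ValueError("entries outside the mask must be zero")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)

    @property
    def n_species(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SpeciesEnsemble:
    """Species-level parameters of one community: r, K and (optionally) A."""

    r: np.ndarray
    K: np.ndarray
    A: Optional[InteractionMatrix] = None

    def __post_init__(self) -> None:
        r, K = np.asarray(self.r, float), np.asarray(self.K, float)
        if r.shape != K.shape or r.ndim != 1:
            raise ValueError("r and K must be 1-D and the same length")
        if np.any(r <= 0) or np.any(K <= 0):
            raise ValueError("r and K must be strictly positive")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "K", K)


@dataclass(frozen=True)
class HostEnsemble:
    """Host-level replicates of a community.

    ``r``/``K`` have shape (n_hosts, s); ``A`` has shape (n_hosts, s, s).
    Sigmas are standard deviations on the natural-log scale.
    """

    base: SpeciesEnsemble
    r: np.ndarray
    K: np.ndarray
    A: np.ndarray
    sigma_alpha: float
    sigma_r: float
    sigma_K: float

    @property
    def n_hosts(self) -> int:
        return self.r.shape[0]

    @property
    def n_species(self) -> int:
        return self.r.shape[1]


def sample_species_baseline(
    n_species: int,
    growth_range: Tuple[float, float] = (0.05, 0.1),
    capacity_range: Tuple[float, float] = (0.0, 1.0),
    rng: np.random.Generator | None = None,
) -> SpeciesEnsemble:
    """Draw per-species growth rates and carrying capacities.

    ``r_i ~ U(growth_range)`` and ``K_i ~ U(capacity_range)``. A draw of
    exactly K = 0 is rejected and redrawn (the dynamics divide by K), so the
    capacity range may start at 0 as in the reference setting U(0, 1).
    """
    rng = np.random.default_rng(rng)
    lo, hi = growth_range
    if not (hi > lo and hi > 0):
        raise ValueError("growth_range must be non-degenerate with positive upper bound")
    klo, khi = capacity_range
    if not (khi > klo and khi > 0):
        raise ValueError("capacity_range must be non-degenerate with positive upper bound")
    r = rng.uniform(lo, hi, n_species)
    K = rng.uniform(klo, khi, n_species)
    while np.any(K == 0.0):  # measure-zero event, but contractually excluded
        K[K == 0.0] = rng.uniform(klo, khi, int(np.sum(K == 0.0)))
    return SpeciesEnsemble(r=r, K=K)


def _hub_mask(spec: TopologySpec, rng: np.random.Generator) -> np.ndarray:
    import random as pyrandom

    import igraph

    s = spec.n_species
    # igraph's RNG is separate from numpy's; re-seed it from our stream so the
    # whole draw stays reproducible under a single Generator.
    igraph.set_random_number_generator(pyrandom.Random(int(rng.integers(2**31))))
    masks = []
    for _ in range(2):
        g = igraph.Graph.Barabasi(n=s, m=1, power=spec.hub_power, directed=True)
        masks.append(np.array(g.get_adjacency().data, dtype=bool))
    # union of the two directed graphs on the shared vertex set: hub species
    # accumulate interactions from both draws, and most interacting pairs
    # stay one-directional (transposing one graph before the union would
    # instead symmetrize the pairs around the hubs, which changes the
    # ecology of the network from dominantly one-sided to two-sided)
    mask = masks[0] | masks[1]
    np.fill_diagonal(mask, False)

    # preferential attachment fixes the edge count at ~2(s-1); add or remove
    # uniformly random edges to hit the configured density
    target = int(round(spec.density * s * (s - 1)))
    off = ~np.eye(s, dtype=bool)
    present = np.flatnonzero(mask & off)
    absent = np.flatnonzero(off & ~mask)
    flat = mask.ravel().copy()
    if present.size > target:
        drop = rng.choice(present, size=present.size - target, replace=False)
        flat[drop] = False
    elif present.size < target:
        add = rng.choice(absent, size=target - present.size, replace=False)
        flat[add] = True
    return flat.reshape(s, s)


def sample_topology(spec: TopologySpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the boolean mask of structurally present ordered interactions."""
    rng = np.random.default_rng(rng)
    s = spec.n_species
    if spec.structure == "hub":
        return _hub_mask(spec, rng)
    if spec.structure == "producer_consumer":
        # cross-feeding and shared-resource competition are two-way
        # relations: each selected unordered pair carries both directed
        # interactions (mutualistic between blocks, competitive within),
        # keeping the ordered-pair density at the configured value
        iu = np.triu_indices(s, k=1)
        chosen = rng.random(iu[0].size) < spec.density
        mask = np.zeros((s, s), bool)
        mask[iu[0][chosen], iu[1][chosen]] = True
        return mask | mask.T
    mask = rng.random((s, s)) < spec.density
    np.fill_diagonal(mask, False)
    return mask


def _truncated(draw, size: int, bound: float, rng: np.random.Generator) -> np.ndarray:
    """Rejection-resample `draw(size)` until every value is inside (-bound, bound)."""
    x = draw(size)
    bad = np.abs(x) > bound
    while np.any(bad):
        x[bad] = draw(int(bad.sum()))
        bad = np.abs(x) > bound
    return x


def sample_strengths(
    mask: np.ndarray,
    dist: StrengthDistribution | None = None,
    structure: str = "random",
    rng: np.random.Generator | None = None,
) -> InteractionMatrix:
    """Fill a topology mask with interaction strengths.

    For the Gaussian mixture on random/hub structures each present edge is
    assigned to the positive or negative component with probability 1/2. On
    the producer/consumer structure the between-block (cross-feeding) edges
    come from the positive component and within-block edges (resource
    competition among producers or among consumers) from the negative one.
    """
    rng = np.random.default_rng(rng)
    dist = dist or StrengthDistribution()
    mask = np.asarray(mask, bool)
    if np.any(np.diag(mask)):
        raise ValueError("mask must have a zero diagonal")
    s = mask.shape[0]
    n = int(mask.sum())
    values = np.zeros((s, s))
    if n == 0:
        return InteractionMatrix(values=values, mask=mask)

    b = dist.bound
    if dist.family == "uniform":
        strengths = rng.uniform(-b, b, n)
    elif dist.family == "unimodal":
        strengths = _truncated(lambda k: rng.normal(0.0, dist.unimodal_sd, k), n, b, rng)
    else:  # gaussian_mixture
        if structure == "producer_consumer":
            if s % 2:
                raise ValueError("producer_consumer requires an even number of species")
            half = s // 2
            block = np.zeros((s, s), bool)
            block[:half, :half] = True
            block[half:, half:] = True  # True = within-block -> negative
            signs = np.where(block[mask], -1.0, 1.0)
        else:
            signs = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        mags = _truncated(
            lambda k: rng.normal(dist.mixture_mean, dist.mixture_sd, k), n, b, rng
        )
        # magnitudes from the +mu component; the sign flips it to the -mu one
        strengths = signs * mags
    values[mask] = strengths
    return InteractionMatrix(values=values, mask=mask)


def sample_community(
    n_species: int = 10,
    topology: TopologySpec | None = None,
    dist: StrengthDistribution | None = None,
    growth_range: Tuple[float, float] = (0.05, 0.1),
    capacity_range: Tuple[float, float] = (0.0, 1.0),
    rng: np.random.Generator | None = None,
) -> SpeciesEnsemble:
    """Draw one full species-level community (baseline + topology + strengths)."""
    rng = np.random.default_rng(rng)
    topology = topology or TopologySpec(n_species=n_species, density=0.25)
    base = sample_species_baseline(topology.n_species, growth_range, capacity_range, rng)
    mask = sample_topology(topology, rng)
    A = sample_strengths(mask, dist, topology.structure, rng)
    return SpeciesEnsemble(r=base.r, K=base.K, A=A)


def sample_host_ensemble(
    base: SpeciesEnsemble,
    n_hosts: int = 300,
    sigma_alpha: float = 0.25,
    sigma_r: float = 0.0,
    sigma_K: float = 0.0,
    rng: np.random.Generator | None = None,
) -> HostEnsemble:
    """Expand a species-level community into host-specific replicates.

    Host parameters are lognormal around the species-level values:
    ``ln|alpha_ij,m| ~ N(ln|alpha_ij|, sigma_alpha)`` with the original sign
    restored, ``ln r_im ~ N(ln r_i, sigma_r)``, ``ln K_im ~ N(ln K_i,
    sigma_K)``. A sigma of 0 yields exact copies; structural zeros stay zero
    in every host, so presence and sign of every interaction are conserved
    across hosts.
    """
    rng = np.random.default_rng(rng)
    if base.A is None:
        raise ValueError("base ensemble must carry an interaction matrix")
    if min(sigma_alpha, sigma_r, sigma_K) < 0:
        raise ValueError("sigmas must be non-negative")
    if n_hosts < 1:
        raise ValueError("n_hosts must be >= 1")
    A0, mask = base.A.values, base.A.mask
    if np.any(A0[mask] == 0.0):
        raise ValueError("masked-in interactions with zero strength are contradictory")
    s = base.r.size

    def expand(x: np.ndarray, sigma: float) -> np.ndarray:
        tiled = np.broadcast_to(x, (n_hosts,) + x.shape).copy()
        if sigma == 0.0:
            return tiled
        return np.exp(np.log(tiled) + sigma * rng.standard_normal(tiled.shape))

    r = expand(base.r, sigma_r)
    K = expand(base.K, sigma_K)
    A = np.zeros((n_hosts, s, s))
    vals = A0[mask]
    if sigma_alpha == 0.0:
        per_host = np.broadcast_to(vals, (n_hosts, vals.size)).copy()
    else:
        shocks = sigma_alpha * rng.standard_normal((n_hosts, vals.size))
        per_host = np.sign(vals) * np.exp(np.log(np.abs(vals)) + shocks)
    A[:, mask] = per_host
    return HostEnsemble(
        base=base, r=r, K=K, A=A,
        sigma_alpha=sigma_alpha, sigma_r=sigma_r, sigma_K=sigma_K,
    )


def edge_list(A: InteractionMatrix) -> pd.DataFrame:
    """Export an interaction matrix as a (source, target, sign, weight) table.

    ``source`` is the acting species j, ``target`` the affected species i.
    """
    i, j = np.nonzero(A.mask)
    w = A.values[i, j]
    return pd.DataFrame(
        {"source": j, "target": i, "sign": np.sign(w).astype(int), "weight": w}
    )


def host_ensemble_table(ens: HostEnsemble) -> pd.DataFrame:
    """Tidy long-format dump: one row per host x parameter entry."""
    rows = []
    m, s = ens.r.shape
    for h in range(m):
        for i in range(s):
            rows.append(("r", h, i, -1, ens.r[h, i]))
            rows.append(("K", h, i, -1, ens.K[h, i]))
        ii, jj = np.nonzero(ens.base.A.mask)
        for i, j in zip(ii, jj):
            rows.append(("alpha", h, int(i), int(j), ens.A[h, i, j]))
    return pd.DataFrame(rows, columns=["parameter", "host", "i", "j", "value"])
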