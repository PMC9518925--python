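"""Generalized Lotka-Volterra dynamics, per host and batched across hosts.

The model for species *i* in host *m* is

    dN_im/dt = r_im * N_im * (1 - N_im / K_im + sum_{j != i} alpha_ij,m N_jm)

Self-limitation enters through the carrying capacity (alpha_ii = -1/K_i), so
the interaction matrix carries only interspecific terms. All hosts of one
community are independent, which lets us integrate them as one block-diagonal
system with a vectorized right-hand side — much cheaper than a Python-level
loop over hosts.

Optional ingredients mirror the study design: multiplicative lognormal
process noise applied at discrete intervals, and a carrying-capacity
perturbation window during which every K is replaced by a fresh uniform draw
and restored afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .networks import HostEnsemble, InteractionMatrix

__all__ = [
    "SimulationSettings",
    "ProcessNoiseSpec",
    "PerturbationSpec",
    "Trajectory",
    "EnsembleTrajectory",
    "AbundanceSample",
    "TwoSpeciesEquilibrium",
    "glv_rhs",
    "simulate",
    "simulate_ensemble",
    "check_survival",
    "sample_abundances",
    "two_species_equilibrium",
    "coexistence_region",
]


@dataclass(frozen=True)
class SimulationSettings:
    """Integration horizon, tolerances and screening thresholds.

    ``record_step`` is the spacing of the recorded (and extinction-checked)
    time grid; 1 time unit by default so threshold crossings between coarse
    samples are not missed. ``equilibrium_tolerance`` is the max |dN/dt|
    accepted as "at equilibrium" at the horizon.
    """

    horizon: float = 1000.0
    record_step: float = 1.0
    rtol: float = 1e-6
    atol: float = 1e-9
    extinction_threshold: float = 1e-3
    equilibrium_tolerance: float = 1e-8
    method: str = "RK45"

    def __post_init__(self) -> None:
        if self.horizon <= 0 or self.record_step <= 0:
            raise ValueError("horizon and record_step must be positive")
        if min(self.rtol, self.atol, self.extinction_threshold) <= 0:
            raise ValueError("tolerances and extinction threshold must be positive")


@dataclass(frozen=True)
class ProcessNoiseSpec:
    """Discrete multiplicative shocks on abundance.

    Every ``dt`` time units each abundance is multiplied by exp(eps) with
    eps ~ N(0, sigma), a lognormal shock that keeps abundances positive.
    sigma = 1 is the study's high setting, 0.1 the low one; sigma = 0 is a
    no-op that reproduces the deterministic path bitwise.
    """

    sigma: float = 0.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.dt <= 0:
            raise ValueError("sigma must be >= 0 and dt > 0")

    @property
    def enabled(self) -> bool:
        return self.sigma > 0


@dataclass(frozen=True)
class PerturbationSpec:
    """Carrying-capacity perturbation window.

    During [start, start + duration] every host's carrying capacities are
    replaced by fresh draws (U(0, 1) by default, matching the baseline
    distribution) and restored afterwards; the community then relaxes back to
    its original equilibrium.
    """

    start: float = 175.0
    duration: float = 50.0
    capacity_range: tuple = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.start < 0 or self.duration <= 0:
            raise ValueError("start must be >= 0 and duration > 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Trajectory:
    """Single-host time series: times (T,), abundances (T, s)."""

    times: np.ndarray
    abundances: np.ndarray
    survived: bool
    converged: bool

    def at(self, t: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-9:
            raise ValueError(f"time {t} is not on the recorded grid")
        return self.abundances[idx]


@dataclass(frozen=True)
class EnsembleTrajectory:
    """Batched time series over hosts: times (T,), abundances (T, m, s)."""

    times: np.ndarray
    abundances: np.ndarray
    survived: np.ndarray  # (m,) bool
    converged: np.ndarray  # (m,) bool

    @property
    def n_hosts(self) -> int:
        return self.abundances.shape[1]

    def at(self, t: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-9:
            raise ValueError(f"time {t} is not on the recorded grid")
        return self.abundances[idx]


@dataclass(frozen=True)
class AbundanceSample:
    """Hosts x species abundance matrix at a sampling time, with noise."""

    matrix: np.ndarray  # (m, s)
    upsilon: float
    times: np.ndarray  # (m,) per-host sampling times


@dataclass(frozen=True)
class TwoSpeciesEquilibrium:
    n1: float
    n2: float
    coexists: bool
    stable: bool


def glv_rhs(
    N: np.ndarray, r: np.ndarray, K: np.ndarray, A: np.ndarray | InteractionMatrix
) -> np.ndarray:
    """Right-hand side dN_i/dt = r_i N_i (1 - N_i/K_i + sum_j alpha_ij N_j)."""
    if isinstance(A, InteractionMatrix):
        A = A.values
    N = np.asarray(N, float)
    if not np.all(np.isfinite(N)):
        raise ValueError("non-finite abundances")
    return r * N * (1.0 - N / K + A @ N)


def _batch_rhs_factory(r, K, A):
    """Vectorized RHS over a (m, s) batch; A is (m, s, s) or (s, s)."""
    m, s = r.shape
    if A.ndim == 2:
        def rhs(t, y):
            N = y.reshape(m, s)
            return (r * N * (1.0 - N / K + N @ A.T)).ravel()
    else:
        def rhs(t, y):
            N = y.reshape(m, s)
            inter = np.einsum("mij,mj->mi", A, N)
            return (r * N * (1.0 - N / K + inter)).ravel()
    return rhs


def _solve_segment(r, K, A, y0, t0, t1, t_eval, settings):
    rhs = _batch_rhs_factory(r, K, A)
    # always evaluate at the segment end so the next segment continues exactly
    need_end = t_eval.size == 0 or t_eval[-1] < t1 - 1e-12
    ts = np.append(t_eval, t1) if need_end else t_eval
    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method=settings.method,
        t_eval=ts,
        rtol=settings.rtol,
        atol=settings.atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
    return sol.y[:, : t_eval.size].T, sol.y[:, -1]


def _integrate_batch(
    r: np.ndarray,
    K: np.ndarray,
    A: np.ndarray,
    n0: np.ndarray,
    settings: SimulationSettings,
    process_noise: Optional[ProcessNoiseSpec],
    perturbation: Optional[PerturbationSpec],
    rng: Optional[np.random.Generator],
) -> EnsembleTrajectory:
    m, s = r.shape
    grid = np.arange(0.0, settings.horizon + 0.5 * settings.record_step, settings.record_step)

    # perturbation segments: (t0, t1, K for that segment)
    if perturbation is not None and perturbation.start < settings.horizon:
        rng = np.random.default_rng(rng)
        lo, hi = perturbation.capacity_range
        K_pert = rng.uniform(lo, hi, size=K.shape)
        while np.any(K_pert == 0.0):
            K_pert[K_pert == 0.0] = rng.uniform(lo, hi, int(np.sum(K_pert == 0.0)))
        end = min(perturbation.end, settings.horizon)
        segments = [(0.0, perturbation.start, K), (perturbation.start, end, K_pert)]
        if end < settings.horizon:
            segments.append((end, settings.horizon, K))
        segments = [(a, b, Ks) for a, b, Ks in segments if b > a]
    else:
        segments = [(0.0, settings.horizon, K)]

    noisy = process_noise is not None and process_noise.enabled
    if noisy:
        rng = np.random.default_rng(rng)

    out = np.empty((grid.size, m * s))
    out[0] = n0.ravel()
    y = n0.ravel().copy()
    for t0, t1, K_seg in segments:
        if noisy:
            # integrate in dt-long sub-segments, shocking after each
            edges = np.arange(t0, t1, process_noise.dt)
            edges = np.append(edges, t1)
            for a, b in zip(edges[:-1], edges[1:]):
                t_eval = grid[(grid > a + 1e-12) & (grid <= b + 1e-12)]
                ys, y = _solve_segment(r, K_seg, A, y, a, b, t_eval, settings)
                if t_eval.size:
                    idx = np.searchsorted(grid, t_eval)
                    out[idx] = ys
                shock = np.exp(process_noise.sigma * rng.standard_normal(m * s))
                y = y * shock
                # the recorded value at b reflects the pre-shock state; the
                # shock applies to the dynamics going forward
        else:
            t_eval = grid[(grid > t0 + 1e-12) & (grid <= t1 + 1e-12)]
            ys, y = _solve_segment(r, K_seg, A, y, t0, t1, t_eval, settings)
            if t_eval.size:
                idx = np.searchsorted(grid, t_eval)
                out[idx] = ys

    abundances = out.reshape(grid.size, m, s)
    final = abundances[-1]
    dN = r * final * (1.0 - final / K + (
        np.einsum("mij,mj->mi", A, final) if A.ndim == 3 else final @ A.T
    ))
    converged = np.max(np.abs(dN), axis=1) < settings.equilibrium_tolerance
    survived = np.all(abundances >= settings.extinction_threshold, axis=(0, 2))
    return EnsembleTrajectory(
        times=grid, abundances=abundances, survived=survived, converged=converged
    )


def simulate(
    r: np.ndarray,
    K: np.ndarray,
    A: np.ndarray | InteractionMatrix,
    settings: SimulationSettings | None = None,
    process_noise: ProcessNoiseSpec | None = None,
    perturbation: PerturbationSpec | None = None,
    rng: np.random.Generator | None = None,
    n0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate one host's community.

    Initial abundances default to half the carrying capacity of each species
    (strictly positive and scale-appropriate; the model does not prescribe
    them). Returns the trajectory on the recording grid with survival and
    convergence flags.
    """
    settings = settings or SimulationSettings()
    if isinstance(A, InteractionMatrix):
        A = A.values
    r = np.atleast_2d(np.asarray(r, float))
    K = np.atleast_2d(np.asarray(K, float))
    if n0 is None:
        n0 = 0.5 * K
    else:
        n0 = np.atleast_2d(np.asarray(n0, float))
        if np.any(n0 <= 0):
            raise ValueError("initial abundances must be positive")
    ens = _integrate_batch(r, K, np.asarray(A, float), n0, settings, process_noise, perturbation, rng)
    return Trajectory(
        times=ens.times,
        abundances=ens.abundances[:, 0, :],
        survived=bool(ens.survived[0]),
        converged=bool(ens.converged[0]),
    )


def simulate_ensemble(
    hosts: HostEnsemble,
    settings: SimulationSettings | None = None,
    process_noise: ProcessNoiseSpec | None = None,
    perturbation: PerturbationSpec | None = None,
    rng: np.random.Generator | None = None,
) -> EnsembleTrajectory:
    """Integrate every host of an ensemble as one batched system."""
    settings = settings or SimulationSettings()
    A = hosts.A
    if hosts.sigma_alpha == 0.0:
        A = hosts.A[0]  # identical across hosts; use the cheap matmul path
    return _integrate_batch(
        hosts.r, hosts.K, A, 0.5 * hosts.K, settings, process_noise, perturbation, rng
    )


def check_survival(
    traj: Trajectory | EnsembleTrajectory,
    threshold: float = 1e-3,
    ignore_window: tuple | None = None,
) -> bool | np.ndarray:
    """True iff no species ever drops below ``threshold`` on the recorded grid.

    ``ignore_window = (t0, t1)`` excludes recorded times in [t0, t1] from the
    check — used for perturbation runs, where transiently depressed abundances
    inside and shortly after the window are part of the design, not
    extinctions (species regrow once capacities are restored).
    """
    ab = traj.abundances
    keep = np.ones(traj.times.size, bool)
    if ignore_window is not None:
        t0, t1 = ignore_window
        keep = (traj.times < t0) | (traj.times > t1)
    alive = ab[keep] >= threshold
    if isinstance(traj, Trajectory):
        return bool(np.all(alive))
    return np.all(alive, axis=(0, 2))


def sample_abundances(
    traj: EnsembleTrajectory,
    timepoint: float | np.ndarray | str = "final",
    upsilon: float = 0.01,
    rng: np.random.Generator | None = None,
    random_window: tuple = (100.0, 1000.0),
) -> AbundanceSample:
    """Sample every host at a timepoint and add uniform measurement noise.

    ``timepoint`` may be a single time, a per-host array of times, ``"final"``
    (the horizon) or ``"random"`` (per-host uniform over ``random_window``,
    snapped to the recording grid). Noise is i.i.d. U(-upsilon, upsilon),
    added without clipping at zero, mimicking measurement error.
    """
    rng = np.random.default_rng(rng)
    m = traj.n_hosts
    times = traj.times
    if isinstance(timepoint, str):
        if timepoint == "final":
            t = np.full(m, times[-1])
        elif timepoint == "random":
            lo, hi = random_window
            t = rng.uniform(lo, hi, m)
        else:
            raise ValueError(f"unknown timepoint policy {timepoint!r}")
    else:
        t = np.broadcast_to(np.asarray(timepoint, float), (m,))
    if np.any(t < times[0] - 1e-9) or np.any(t > times[-1] + 1e-9):
        raise ValueError("sampling timepoint outside the recorded horizon")
    idx = np.clip(np.searchsorted(times, t - 1e-9), 0, times.size - 1)
    snapped = times[idx]
    mat = traj.abundances[idx, np.arange(m), :].copy()
    if upsilon > 0:
        mat = mat + rng.uniform(-upsilon, upsilon, mat.shape)
    return AbundanceSample(matrix=mat, upsilon=upsilon, times=snapped)


def two_species_equilibrium(
    K1: float, K2: float, a12: float, a21: float
) -> TwoSpeciesEquilibrium:
    """Closed-form interior equilibrium of the two-species model.

    N1* = K1 (1 + a12 K2) / (1 - a12 a21 K1 K2) and symmetrically for N2*.
    The pair coexists iff both equilibria are strictly positive and the
    interior fixed point is locally stable, which for this model reduces to
    1 - a12 a21 K1 K2 > 0 (the Jacobian trace is automatically negative at a
    positive interior point).
    """
    if K1 <= 0 or K2 <= 0:
        raise ValueError("carrying capacities must be positive")
    denom = 1.0 - a12 * a21 * K1 * K2
    if denom == 0.0:
        return TwoSpeciesEquilibrium(np.nan, np.nan, coexists=False, stable=False)
    n1 = K1 * (1.0 + a12 * K2) / denom
    n2 = K2 * (1.0 + a21 * K1) / denom
    stable = denom > 0.0
    coexists = bool(n1 > 0 and n2 > 0 and stable)
    return TwoSpeciesEquilibrium(n1=n1, n2=n2, coexists=coexists, stable=stable)


def coexistence_region(
    a12_grid: Sequence[float], a21_grid: Sequence[float], K1: float, K2: float
) -> np.ndarray:
    """Boolean field over (a12, a21): True where stable coexistence holds.

    Entry [i, j] corresponds to (a12_grid[i], a21_grid[j]).
    """
    out = np.zeros((len(a12_grid), len(a21_grid)), bool)
    for i, a12 in enumerate(a12_grid):
        for j, a21 in enumerate(a21_grid):
            out[i, j] = two_species_equilibrium(K1, K2, a12, a21).coexists
    return out
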