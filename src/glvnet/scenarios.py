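"""Replicate sweeps: simulate -> infer -> evaluate, for every study scenario.

One replicate is one accepted species-level parameter set (topology +
strengths + baseline r, K), expanded to a host ensemble, integrated to the
horizon, sampled cross-sectionally with measurement noise, passed through
partial-correlation inference with BH control, and scored against the true
interaction matrix under all three matching rules. A parameter set in which
any species goes extinct (abundance below threshold) in any host is rejected
and redrawn, so replicate counts refer to accepted sets.

``builtin_scenarios`` provides the base case and every published variation;
``compare_f1`` performs the Mann-Whitney U comparison used to rank scenarios.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import networks as nw
from . import dynamics as dyn
from . import inference as inf
from . import evaluation as ev

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "RankSumResult",
    "RetryBudgetExceeded",
    "run_scenario",
    "builtin_scenarios",
    "compare_f1",
    "summarize",
]


class RetryBudgetExceeded(RuntimeError):
    """Raised when rejection resampling cannot find a surviving parameter set."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Every knob of one simulation scenario. Fully serializable.

    ``sampling_time`` is a model time on the recording grid, or ``"random"``
    for a per-host uniform draw on [100, horizon]. ``n_networks`` defaults to
    the desk-scale 100 replicates; the study's full scale is 1000.
    """

    name: str = "base"
    # community
    n_species: int = 10
    density: float = 0.25
    structure: str = "random"
    hub_power: float = 2.0
    strength_family: str = "gaussian_mixture"
    growth_low: float = 0.05
    growth_high: float = 0.1
    capacity_low: float = 0.0
    capacity_high: float = 1.0
    # host variation (log-scale sds)
    sigma_alpha: float = 0.25
    sigma_r: float = 0.0
    sigma_K: float = 0.0
    n_hosts: int = 300
    # sampling & noise
    measurement_noise: float = 0.01
    process_noise_sigma: float = 0.0
    process_noise_dt: float = 1.0
    perturbation: bool = False
    perturbation_start: float = 175.0
    perturbation_duration: float = 50.0
    # None samples at the horizon (equilibrium); "random" draws per-host
    # uniform times on [100, horizon]; a number samples that model time
    sampling_time: Union[float, str, None] = None
    # inference & scoring
    alpha_level: float = 0.05
    matching_rule: str = "either_sign"
    # integration
    horizon: float = 1000.0
    record_step: float = 1.0
    rtol: float = 1e-6
    atol: float = 1e-9
    extinction_threshold: float = 0.001
    equilibrium_tolerance: float = 1e-8
    # replication
    n_networks: int = 100
    max_retries: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        if self.matching_rule not in ev.MATCHING_RULES:
            raise ValueError(f"matching_rule must be one of {ev.MATCHING_RULES}")
        if self.strength_family not in ("gaussian_mixture", "uniform", "unimodal"):
            raise ValueError("unknown strength_family")
        if min(self.sigma_alpha, self.sigma_r, self.sigma_K) < 0:
            raise ValueError("sigmas must be non-negative")
        if self.n_hosts < self.n_species + 3:
            raise ValueError("need n_hosts > n_species + 2 for partial correlations")
        if isinstance(self.sampling_time, str) and self.sampling_time != "random":
            raise ValueError("sampling_time must be a number or 'random'")
        if self.n_networks < 1 or self.max_retries < 1:
            raise ValueError("n_networks and max_retries must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    # convenience views onto the upstream module types -------------------
    def topology_spec(self) -> nw.TopologySpec:
        return nw.TopologySpec(
            n_species=self.n_species,
            density=self.density,
            structure=self.structure,
            hub_power=self.hub_power,
        )

    def strength_distribution(self) -> nw.StrengthDistribution:
        return nw.StrengthDistribution(family=self.strength_family)

    def simulation_settings(self) -> dyn.SimulationSettings:
        return dyn.SimulationSettings(
            horizon=self.horizon,
            record_step=self.record_step,
            rtol=self.rtol,
            atol=self.atol,
            extinction_threshold=self.extinction_threshold,
            equilibrium_tolerance=self.equilibrium_tolerance,
        )

    def process_noise_spec(self) -> Optional[dyn.ProcessNoiseSpec]:
        if self.process_noise_sigma > 0:
            return dyn.ProcessNoiseSpec(
                sigma=self.process_noise_sigma, dt=self.process_noise_dt
            )
        return None

    def perturbation_spec(self) -> Optional[dyn.PerturbationSpec]:
        if self.perturbation:
            return dyn.PerturbationSpec(
                start=self.perturbation_start,
                duration=self.perturbation_duration,
                capacity_range=(self.capacity_low, self.capacity_high),
            )
        return None


@dataclass(frozen=True)
class ScenarioResult:
    """Per-replicate metrics plus aggregated per-type detection counts."""

    config: ScenarioConfig
    metrics: pd.DataFrame  # scenario, replicate, sampling, rule, counts, metrics
    detection: pd.DataFrame  # summed per-type detection counts (primary sampling)
    n_rejections: int

    def f1(self, rule: str | None = None, sampling: str | None = None) -> np.ndarray:
        """Per-replicate F1 vector for one rule and sampling label."""
        rule = rule or self.config.matching_rule
        m = self.metrics
        sel = m["rule"] == rule
        labels = m["sampling"].unique()
        sel &= m["sampling"] == (sampling if sampling is not None else labels[0])
        return m.loc[sel, "f1"].to_numpy()


@dataclass(frozen=True)
class RankSumResult:
    u: float
    p: float
    degenerate: bool = False


def _draw_accepted_set(config: ScenarioConfig, rng: np.random.Generator):
    """Rejection-resample until a parameter set survives in every host.

    A cheap species-level pre-screen (one deterministic run of the baseline
    parameters) filters sets whose typical host would lose a species before
    the full host ensemble is integrated. Perturbation runs are screened
    outside the perturbation window (transient dips during and shortly after
    the window are by design, not extinctions); with process noise enabled,
    screening uses the deterministic skeleton only, since lognormal shocks
    make threshold dips certain at any noise level.
    """
    settings = config.simulation_settings()
    pert = config.perturbation_spec()
    pnoise = config.process_noise_spec()
    rejections = 0
    for _ in range(config.max_retries):
        community = nw.sample_community(
            topology=config.topology_spec(),
            dist=config.strength_distribution(),
            growth_range=(config.growth_low, config.growth_high),
            capacity_range=(config.capacity_low, config.capacity_high),
            rng=rng,
        )
        base_traj = dyn.simulate(community.r, community.K, community.A, settings)
        if not dyn.check_survival(base_traj, config.extinction_threshold):
            rejections += 1
            continue
        hosts = nw.sample_host_ensemble(
            community,
            n_hosts=config.n_hosts,
            sigma_alpha=config.sigma_alpha,
            sigma_r=config.sigma_r,
            sigma_K=config.sigma_K,
            rng=rng,
        )
        traj = dyn.simulate_ensemble(
            hosts, settings, process_noise=pnoise, perturbation=pert, rng=rng
        )
        if pnoise is not None:
            survived = True  # screened via the deterministic pre-screen
        elif pert is not None:
            window = (pert.start, config.horizon - config.record_step)
            survived = bool(np.all(dyn.check_survival(
                traj, config.extinction_threshold, ignore_window=window
            )))
        else:
            survived = bool(np.all(traj.survived))
        if survived:
            return community, hosts, traj, rejections
        rejections += 1
    raise RetryBudgetExceeded(
        f"no surviving parameter set within {config.max_retries} draws "
        f"(scenario {config.name!r})"
    )


def _resolve_sampling(config: ScenarioConfig) -> Dict[str, Union[float, str]]:
    if config.sampling_time is None:
        return {"equilibrium": "final"}
    if isinstance(config.sampling_time, str):
        return {"random": "random"}
    return {f"t{config.sampling_time:g}": float(config.sampling_time)}


def run_scenario(
    config: ScenarioConfig,
    n_networks: int | None = None,
    sampling_times: Mapping[str, Union[float, str]] | None = None,
    progress: bool = False,
) -> ScenarioResult:
    """Run one scenario end to end.

    ``sampling_times`` optionally maps labels to sampling-time specs so one
    set of simulations can be scored at several timepoints (used for the
    perturbation analysis); by default the configured single timepoint is
    used. Replicate seeds derive from the master seed by counter-based
    spawning, so replicates are independently reproducible.
    """
    n_networks = n_networks or config.n_networks
    sampling_times = dict(sampling_times or _resolve_sampling(config))
    primary = next(iter(sampling_times))
    children = np.random.SeedSequence(config.master_seed).spawn(n_networks)

    rows = []
    detection_acc: Optional[pd.DataFrame] = None
    total_rejections = 0
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        community, hosts, traj, rejections = _draw_accepted_set(config, rng)
        total_rejections += rejections
        for label, tspec in sampling_times.items():
            sample = dyn.sample_abundances(
                traj,
                timepoint=tspec,
                upsilon=config.measurement_noise,
                rng=rng,
                random_window=(100.0, config.horizon),
            )
            result = inf.infer_network(sample.matrix, level=config.alpha_level)
            for rule in ev.MATCHING_RULES:
                counts = ev.confusion_counts(community.A, result, rule)
                precision, recall, f1 = ev.precision_recall_f1(counts)
                rows.append(
                    {
                        "scenario": config.name,
                        "replicate": rep,
                        "sampling": label,
                        "rule": rule,
                        "tp": counts.tp,
                        "fp": counts.fp,
                        "tn": counts.tn,
                        "fn": counts.fn,
                        "precision": precision,
                        "recall": recall,
                        "f1": f1,
                        "n_rejected": rejections,
                    }
                )
            if label == primary:
                det = ev.detection_rate_by_type(community.A, result)
                cols = ["n_pairs", "n_detected", "n_pos", "n_neg"]
                if detection_acc is None:
                    detection_acc = det.set_index("type")[cols]
                else:
                    detection_acc = detection_acc + det.set_index("type")[cols]
        if progress:
            print(f"[{config.name}] replicate {rep + 1}/{n_networks} "
                  f"({rejections} rejected draws)")

    detection = detection_acc.reset_index()
    detection["rate_pct"] = np.where(
        detection["n_pairs"] > 0,
        100.0 * detection["n_detected"] / detection["n_pairs"].replace(0, 1),
        np.nan,
    )
    return ScenarioResult(
        config=config,
        metrics=pd.DataFrame(rows),
        detection=detection,
        n_rejections=total_rejections,
    )


def compare_f1(
    a: Union[ScenarioResult, Sequence[float]],
    b: Union[ScenarioResult, Sequence[float]],
    rule: str | None = None,
) -> RankSumResult:
    """Two-sided Mann-Whitney U comparison of per-replicate F1 scores."""
    xa = a.f1(rule) if isinstance(a, ScenarioResult) else np.asarray(a, float)
    xb = b.f1(rule) if isinstance(b, ScenarioResult) else np.asarray(b, float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("need at least two replicates per group")
    if np.ptp(np.concatenate([xa, xb])) == 0.0:
        # all observations identical: no evidence of any difference
        return RankSumResult(u=xa.size * xb.size / 2.0, p=1.0, degenerate=True)
    u, p = mannwhitneyu(xa, xb, alternative="two-sided")
    return RankSumResult(u=float(u), p=float(p))


def summarize(result: ScenarioResult) -> pd.DataFrame:
    """Median, quartiles and Tukey whisker bounds per sampling/rule/metric."""
    records = []
    for (sampling, rule), grp in result.metrics.groupby(["sampling", "rule"]):
        for metric in ("precision", "recall", "f1"):
            x = grp[metric].to_numpy()
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            iqr = q3 - q1
            lo = x[x >= q1 - 1.5 * iqr].min()
            hi = x[x <= q3 + 1.5 * iqr].max()
            records.append(
                {
                    "scenario": result.config.name,
                    "sampling": sampling,
                    "rule": rule,
                    "metric": metric,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_low": lo,
                    "whisker_high": hi,
                    "n": x.size,
                }
            )
    return pd.DataFrame(records)


def builtin_scenarios() -> Dict[str, ScenarioConfig]:
    """Named registry of the base case and every studied variation."""
    base = ScenarioConfig(name="base")
    pert_times = {"t1": 176.0, "t2": 190.0, "t3": 210.0, "t4": 224.0, "t5": 1000.0}
    reg: Dict[str, ScenarioConfig] = {
        "base": base,
        # host-level variability in r and K on top of the base alpha variation
        "var_rK": replace(base, name="var_rK", sigma_r=0.25, sigma_K=0.25),
        "var_r_only": replace(
            base, name="var_r_only", sigma_alpha=0.0, sigma_r=0.25, sigma_K=0.0
        ),
        "var_K_only": replace(
            base, name="var_K_only", sigma_alpha=0.0, sigma_r=0.0, sigma_K=0.25
        ),
        "no_variation": replace(
            base, name="no_variation", sigma_alpha=0.0, sigma_r=0.0, sigma_K=0.0
        ),
        # measurement noise
        "noise_low": replace(base, name="noise_low", measurement_noise=0.001),
        "noise_high": replace(base, name="noise_high", measurement_noise=0.1),
        # process noise
        "process_noise_low": replace(
            base, name="process_noise_low", process_noise_sigma=0.1
        ),
        "process_noise_high": replace(
            base, name="process_noise_high", process_noise_sigma=1.0
        ),
        # strength distributions
        "strengths_uniform": replace(
            base, name="strengths_uniform", strength_family="uniform"
        ),
        "strengths_unimodal": replace(
            base, name="strengths_unimodal", strength_family="unimodal"
        ),
        # network structure
        "species30": replace(base, name="species30", n_species=30, density=1.0 / 6.0),
        "producer_consumer": replace(
            base, name="producer_consumer", structure="producer_consumer"
        ),
        "hub": replace(base, name="hub", structure="hub"),
        # matching rules
        "rule_strongest": replace(
            base, name="rule_strongest", matching_rule="strongest_sign"
        ),
        "rule_strict": replace(base, name="rule_strict", matching_rule="strict_both"),
        # sample size
        "hosts3000": replace(base, name="hosts3000", n_hosts=3000),
        "hosts3000_producer_consumer": replace(
            base, name="hosts3000_producer_consumer", n_hosts=3000,
            structure="producer_consumer",
        ),
        "hosts3000_hub": replace(base, name="hosts3000_hub", n_hosts=3000, structure="hub"),
        # perturbation sampling
        "perturbation_random": replace(
            base, name="perturbation_random", perturbation=True, sampling_time="random"
        ),
    }
    for label, t in pert_times.items():
        reg[f"perturbation_{label}"] = replace(
            base, name=f"perturbation_{label}", perturbation=True, sampling_time=t
        )
    return reg
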