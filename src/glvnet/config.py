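"""Configuration files, result serialization and small test fixtures.

Scenario configs are flat YAML mappings of ``ScenarioConfig`` fields; unknown
keys are rejected and missing keys fall back to the base-case defaults.
Results are written as tab-separated metric tables at full float precision
(downstream rank-sum comparisons must not be perturbed by rounding) next to a
JSON manifest carrying the config hash, master seed and record counts, so any
run is reconstructible from (config file, master seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .scenarios import ScenarioConfig, ScenarioResult

__all__ = [
    "load_config",
    "save_config",
    "config_hash",
    "write_results",
    "read_results",
    "make_fixture",
]

_FIELDS = {f.name: f for f in dataclasses.fields(ScenarioConfig)}


def load_config(path: Union[str, Path]) -> ScenarioConfig:
    """Parse and validate a YAML scenario config.

    Unknown keys raise; defaults fill missing keys; range violations raise
    with the offending field named (via ``ScenarioConfig`` validation).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raise ValueError(f"{path}: empty config file")
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    unknown = set(raw) - set(_FIELDS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return ScenarioConfig(**raw)


def save_config(config: ScenarioConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def config_hash(config: ScenarioConfig) -> str:
    """Stable hash of the canonical JSON form of a config."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_results(result: ScenarioResult, outdir: Union[str, Path]) -> Path:
    """Write metrics/detection tables plus a manifest; returns the directory.

    Data files are deterministic (byte-identical across writes of the same
    result); only the manifest carries a timestamp.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False,
                          float_format="%.17g")
    result.detection.to_csv(outdir / "detection.tsv", sep="\t", index=False,
                            float_format="%.17g")
    save_config(result.config, outdir / "config.yaml")
    manifest = {
        "artifact_version": __version__,
        "config_hash": config_hash(result.config),
        "master_seed": result.config.master_seed,
        "scenario": result.config.name,
        "n_metric_rows": int(len(result.metrics)),
        "n_replicates": int(result.metrics["replicate"].nunique()),
        "n_rejections": int(result.n_rejections),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def read_results(outdir: Union[str, Path]) -> ScenarioResult:
    """Load a result directory written by :func:`write_results`."""
    outdir = Path(outdir)
    config = load_config(outdir / "config.yaml")
    manifest = json.loads((outdir / "manifest.json").read_text())
    if manifest["config_hash"] != config_hash(config):
        raise ValueError(f"{outdir}: manifest does not match config.yaml")
    metrics = pd.read_csv(outdir / "metrics.tsv", sep="\t")
    detection = pd.read_csv(outdir / "detection.tsv", sep="\t")
    return ScenarioResult(
        config=config,
        metrics=metrics,
        detection=detection,
        n_rejections=manifest["n_rejections"],
    )


def make_fixture(kind: str, seed: int = 0):
    """Small deterministic datasets exercising every downstream module.

    Kinds
    -----
    two_species_grid : dict with K1, K2 and a 21x21 (a12, a21) grid.
    tiny_base_case : dict with a 4-species community, 50-host trajectory and
        sampled abundance matrix (shortened horizon).
    null_no_interactions : dict with an empty true network and a noise-only
        300x10 abundance matrix (each species sits exactly at its carrying
        capacity, the no-interaction equilibrium).
    chain_dependence : dict with a 500x3 Gaussian sample from the chain
        X1 -> X2 -> X3, whose precision matrix has a structural zero on (1, 3).
    """
    from . import dynamics as dyn
    from . import networks as nw

    rng = np.random.default_rng(seed)
    if kind == "two_species_grid":
        grid = np.linspace(-1.2, 1.2, 21)
        return {"K1": 1.5, "K2": 1.1, "r1": 1.0, "r2": 2.0,
                "a12": grid, "a21": grid}
    if kind == "tiny_base_case":
        community = nw.sample_community(
            topology=nw.TopologySpec(n_species=4, density=0.25), rng=rng
        )
        hosts = nw.sample_host_ensemble(community, n_hosts=50, rng=rng)
        settings = dyn.SimulationSettings(horizon=400.0)
        traj = dyn.simulate_ensemble(hosts, settings)
        sample = dyn.sample_abundances(traj, "final", upsilon=0.01, rng=rng)
        return {"community": community, "hosts": hosts, "trajectory": traj,
                "abundances": sample.matrix}
    if kind == "null_no_interactions":
        s, m = 10, 300
        K = rng.uniform(0.2, 1.0, s)
        A = nw.InteractionMatrix(values=np.zeros((s, s)),
                                 mask=np.zeros((s, s), bool))
        X = K + rng.uniform(-0.01, 0.01, (m, s))
        return {"A": A, "K": K, "abundances": X}
    if kind == "chain_dependence":
        n = 500
        x1 = rng.standard_normal(n)
        x2 = 0.9 * x1 + 0.4 * rng.standard_normal(n)
        x3 = 0.9 * x2 + 0.4 * rng.standard_normal(n)
        return {"X": np.column_stack([x1, x2, x3])}
    raise ValueError(f"unknown fixture kind {kind!r}")
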