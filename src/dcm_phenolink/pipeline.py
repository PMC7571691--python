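"""Stage orchestration: config-driven runs with a reproducibility manifest.

A run is described by a YAML/dict config selecting stages and their
parameter blocks. Deterministic stages are bit-stable across reruns;
stochastic stages are stable given the seed. Every run writes a manifest
recording inputs, a hash of the effective parameters, the outputs and the
package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dcm_phenolink._version import __version__
from dcm_phenolink.calcium import aggregate_cell, segment_transients, transient_metrics
from dcm_phenolink.spd import analyze_image
from dcm_phenolink.stats import compare_groups
from dcm_phenolink.synth.images import ImageSpec, generate_sarcomere_image
from dcm_phenolink.synth.traces import TraceSpec, generate_calcium_trace

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("dcm_phenolink")

STAGES = ("simulate_images", "spd", "simulate_traces", "calcium", "compare")

_TOP_KEYS = {"seed", "out_dir", "stages", "log_level"} | set(STAGES)


class RunConfig:
    """Validated pipeline configuration.

    Unknown top-level keys are rejected before execution. ``stages`` is an
    ordered subset of :data:`STAGES`; per-stage parameter blocks live under
    the stage name.
    """

    def __init__(self, cfg: dict):
        unknown = set(cfg) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.seed = int(cfg.get("seed", 0))
        self.out_dir = Path(cfg.get("out_dir", "phenolink_run"))
        stages = cfg.get("stages", list(STAGES))
        bad = [s for s in stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}; available: {list(STAGES)}")
        # execute in canonical dependency order regardless of listing order
        self.stages = [s for s in STAGES if s in stages]
        self.params = {s: dict(cfg.get(s, {})) for s in STAGES}
        self.log_level = cfg.get("log_level", "INFO")
        self.raw = cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})


def _param_hash(cfg: RunConfig) -> str:
    canon = json.dumps({"seed": cfg.seed, "stages": cfg.stages, "params": cfg.params}, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig | dict | str | Path) -> dict:
    """Execute the configured stages and return the manifest.

    On stage failure the exception propagates after partial outputs and the
    manifest-so-far are preserved on disk.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig(config)
    cfg = config
    logging.basicConfig(level=cfg.log_level)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": cfg.stages,
        "param_hash": _param_hash(cfg),
        "outputs": {},
    }
    state: dict = {}
    try:
        for stage in cfg.stages:
            logger.info("stage %s: params=%s", stage, cfg.params[stage])
            _RUNNERS[stage](cfg, state, manifest)
    finally:
        (cfg.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _stage_simulate_images(cfg: RunConfig, state: dict, manifest: dict) -> None:
    p = cfg.params["simulate_images"]
    groups = p.get("groups", {"control": {"organized_fraction": 0.9}, "mutant": {"organized_fraction": 0.3}})
    n = int(p.get("n_per_group", 5))
    base = {k: v for k, v in p.items() if k not in ("groups", "n_per_group")}
    images = {}
    seed = cfg.seed
    for label, overrides in groups.items():
        specs = []
        for i in range(n):
            spec = ImageSpec(**{**base, **overrides, "seed": seed})
            seed += 1
            specs.append(spec)
        images[label] = [generate_sarcomere_image(s) for s in specs]
    state["images"] = images
    manifest["outputs"]["simulate_images"] = {g: len(v) for g, v in images.items()}


def _stage_spd(cfg: RunConfig, state: dict, manifest: dict) -> None:
    if "images" not in state:
        raise RuntimeError("spd stage needs simulate_images (or image inputs) first")
    rows = []
    for label, imgs in state["images"].items():
        for i, img in enumerate(imgs):
            metrics, qc = analyze_image(img, **cfg.params["spd"])
            rows.append(
                {
                    "group": label,
                    "image_id": f"{label}_{i}",
                    "SL_um": metrics.SL_um,
                    "SPD": metrics.SPD,
                    "orientation_deg": qc["orientation_deg"],
                    "residual": qc["residual_norm"],
                    "low_confidence": qc["orientation_low_confidence"],
                }
            )
    df = pd.DataFrame(rows)
    out = cfg.out_dir / "spd_metrics.csv"
    df.to_csv(out, index=False)
    state["spd_metrics"] = df
    manifest["outputs"]["spd"] = str(out)


def _stage_simulate_traces(cfg: RunConfig, state: dict, manifest: dict) -> None:
    p = cfg.params["simulate_traces"]
    groups = p.get("groups", {"control": {"tau_decay_s": 0.5}, "mutant": {"tau_decay_s": 0.4}})
    n = int(p.get("n_per_group", 10))
    base = {k: v for k, v in p.items() if k not in ("groups", "n_per_group")}
    traces = {}
    seed = cfg.seed + 10_000
    for label, overrides in groups.items():
        tr = []
        for _ in range(n):
            tr.append(generate_calcium_trace(TraceSpec(**{**base, **overrides, "seed": seed})))
            seed += 1
        traces[label] = tr
    state["traces"] = traces
    manifest["outputs"]["simulate_traces"] = {g: len(v) for g, v in traces.items()}


def _stage_calcium(cfg: RunConfig, state: dict, manifest: dict) -> None:
    if "traces" not in state:
        raise RuntimeError("calcium stage needs simulate_traces (or trace inputs) first")
    rows = []
    for label, traces in state["traces"].items():
        for i, tr in enumerate(traces):
            windows = segment_transients(tr)
            cell = aggregate_cell([transient_metrics(w) for w in windows])
            cell.update({"group": label, "cell_id": f"{label}_{i}"})
            rows.append(cell)
    df = pd.DataFrame(rows)
    out = cfg.out_dir / "calcium_metrics.csv"
    df.to_csv(out, index=False)
    state["calcium_metrics"] = df
    manifest["outputs"]["calcium"] = str(out)


def _stage_compare(cfg: RunConfig, state: dict, manifest: dict) -> None:
    p = cfg.params["compare"]
    alpha = float(p.get("alpha", 0.05))
    results = {}
    for key, metric in (("spd_metrics", "SPD"), ("calcium_metrics", "tau_decay_s")):
        if key not in state:
            continue
        df = state[key]
        metric = p.get("metric", metric) if key == "spd_metrics" else metric
        groups = list(df["group"].unique())
        if len(groups) != 2:
            continue
        a = df.loc[df["group"] == groups[0], metric].dropna().to_numpy()
        b = df.loc[df["group"] == groups[1], metric].dropna().to_numpy()
        cmp_ = compare_groups(a, b, alpha=alpha, labels=(groups[0], groups[1]))
        results[metric] = cmp_.__dict__
    out = cfg.out_dir / "comparisons.json"
    out.write_text(json.dumps(results, indent=1, default=lambda o: None if isinstance(o, float) and not np.isfinite(o) else o))
    manifest["outputs"]["compare"] = str(out)


_RUNNERS = {
    "simulate_images": _stage_simulate_images,
    "spd": _stage_spd,
    "simulate_traces": _stage_simulate_traces,
    "calcium": _stage_calcium,
    "compare": _stage_compare,
}
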