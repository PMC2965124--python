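"""End-to-end orchestration: simulate -> DTI -> fMRI graph -> stats.

A single YAML config (plus one mandatory global seed) drives the whole run.
Each stage draws its randomness from a named substream derived from the global
seed by hashing the stage name, so outputs are reproducible and insensitive to
stage reordering.  All run products are plain CSV/JSON; a run log captures every
parameter and an input provenance hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dti, fmri_graph, stats, synth

__all__ = ["RunConfig", "load_config", "demo_config", "validate_config",
           "run_full", "substream_seed"]

log = logging.getLogger("motornet")


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters for a full pipeline run."""

    seed: int | None
    out_dir: str
    phantom: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    bold: dict = field(default_factory=dict)
    filter: dict = field(default_factory=lambda: {"low_hz": 0.01, "high_hz": 0.1})
    graph: dict = field(default_factory=lambda: {"thresholds": [0.3, 0.4],
                                                 "n_random": 100})
    cohort: dict = field(default_factory=dict)
    profile_points: int = 100

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(seed=d.get("seed"), out_dir=d.get("out_dir", "motornet_out"),
                   phantom=d.get("phantom", {}), tracking=d.get("tracking", {}),
                   bold=d.get("bold", {}),
                   filter=d.get("filter", {"low_hz": 0.01, "high_hz": 0.1}),
                   graph=d.get("graph", {"thresholds": [0.3, 0.4], "n_random": 100}),
                   cohort=d.get("cohort", {}),
                   profile_points=int(d.get("profile_points", 100)))


def load_config(path: str, seed: int | None = None,
                out_dir: str | None = None) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if seed is not None:
        d["seed"] = seed
    if out_dir is not None:
        d["out_dir"] = out_dir
    return RunConfig.from_dict(d)


def demo_config(seed: int | None = 42, out_dir: str = "motornet_demo") -> RunConfig:
    """The bundled small-scale demo configuration."""
    text = resources.files("motornet").joinpath("data/demo_config.yaml").read_text()
    d = yaml.safe_load(text)
    d["seed"] = seed
    d["out_dir"] = out_dir
    return RunConfig.from_dict(d)


def substream_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived by hashing the stage name."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % (2 ** 31)


def validate_config(config: RunConfig) -> list[str]:
    """Collect every configuration error (empty list means valid)."""
    errors: list[str] = []
    if config.seed is None:
        errors.append("seed: required (the pipeline has stochastic stages)")
    elif not isinstance(config.seed, (int, np.integer)):
        errors.append("seed: must be an integer")
    for thr in config.graph.get("thresholds", []):
        if not 0 < thr < 1:
            errors.append(f"graph.thresholds: {thr} outside (0, 1)")
    n_random = config.graph.get("n_random", 100)
    if n_random < 1:
        errors.append("graph.n_random: must be >= 1")
    dt = config.bold.get("dt", 0.5)
    nyq = 0.5 / dt
    low = config.filter.get("low_hz", 0.01)
    high = config.filter.get("high_hz", 0.1)
    if not 0 <= low < high:
        errors.append(f"filter: need 0 <= low_hz < high_hz (got {low}, {high})")
    if high >= nyq:
        errors.append(f"filter.high_hz: {high} Hz >= Nyquist {nyq} Hz for "
                      f"bold.dt={dt} s")
    if config.profile_points < 2:
        errors.append("profile_points: must be >= 2")
    track = {**{"seed_fa": 0.2, "stop_fa": 0.2, "max_angle_deg": 45.0,
                "min_length_mm": 10.0}, **config.tracking}
    try:
        dti.TrackingParams(**track).validate()
    except (TypeError, ValueError) as exc:
        errors.append(f"tracking: {exc}")
    n = config.cohort.get("n_per_group", 12)
    if n < 3:
        errors.append("cohort.n_per_group: must be >= 3")
    fa_start = config.phantom.get("fa_start", 0.5)
    fa_end = config.phantom.get("fa_end", 0.7)
    for name, v in [("fa_start", fa_start), ("fa_end", fa_end),
                    ("control_fa", config.phantom.get("control_fa", 0.7)),
                    ("background_fa", config.phantom.get("background_fa", 0.05))]:
        if not 0 <= v < 1:
            errors.append(f"phantom.{name}: {v} outside [0, 1)")
    return errors


def _provenance_hash(config: RunConfig) -> str:
    # hash of the scientific inputs only — where the outputs land is irrelevant
    blob = yaml.safe_dump(
        {k: getattr(config, k) for k in config.__dataclass_fields__
         if k != "out_dir"},
        sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _phantom_stage(config: RunConfig, seed: int, out: Path) -> dict:
    """Two tube phantoms — control (flat FA) and patient (rostral FA deficit) —
    tracked and profiled along the simulated corticospinal tract."""
    p = config.phantom
    grid = tuple(p.get("grid_shape", (16, 16, 36)))
    fa_start, fa_end = p.get("fa_start", 0.5), p.get("fa_end", 0.7)
    common = dict(grid_shape=grid, voxel_size=p.get("voxel_size", 2.0),
                  radius_mm=p.get("radius_mm", 4.0),
                  background_fa=p.get("background_fa", 0.05),
                  S0=p.get("s0", 1000.0),
                  noise_sigma=p.get("noise_sigma", 0.0))
    specs = {
        "control": synth.PhantomSpec(fa_profile=p.get("control_fa", 0.7),
                                     seed=substream_seed(seed, "phantom-control"),
                                     **common),
        "patient": synth.PhantomSpec(
            fa_profile=lambda t: fa_end - (fa_end - fa_start) * (1 - t),
            seed=substream_seed(seed, "phantom-patient"), **common),
    }
    track = dti.TrackingParams(**{**{"seed_fa": 0.2, "stop_fa": 0.2,
                                     "max_angle_deg": 45.0, "min_length_mm": 10.0},
                                  **config.tracking})
    result = {}
    for name, spec in specs.items():
        phantom = synth.make_tract_phantom(spec)
        tensors = dti.fit_tensor_loglinear(phantom.dwi)
        famap = dti.fa_map(tensors)
        streamlines = dti.fact_track(tensors, famap, track)
        tract = dti.select_tract_by_rois(streamlines, phantom.masks["cortex"],
                                         phantom.masks["brainstem"],
                                         famap.affine, label=f"CST-{name}")
        profile = dti.tract_fa_profile(tract, famap, config.profile_points)
        dti.save_profile_csv(profile, str(out / f"profile_{name}.csv"))
        result[name] = {
            "n_streamlines": len(tract),
            "mean_fa": float(profile.mean_fa.mean()),
            "rostral_fa": dti.segment_fa(profile, "rostral"),
            "caudal_fa": dti.segment_fa(profile, "caudal"),
        }
        log.info("phantom %s: %d streamlines, mean tract FA %.3f", name,
                 len(tract), result[name]["mean_fa"])
    return result


def _fmri_stage(config: RunConfig, seed: int, out: Path) -> dict:
    """Simulated motor-network BOLD for each group, filtered, correlated and
    summarised at the configured graph thresholds."""
    b = config.bold
    result = {}
    targets = {
        "control": synth.motor_network_target(
            within_r=b.get("within_r", 0.55), between_r=b.get("between_r", 0.35),
            homotopic_r=b.get("homotopic_r", 0.55)),
        "patient": synth.motor_network_target(
            within_r=b.get("within_r", 0.55),
            between_r=b.get("patient_between_r", 0.25),
            homotopic_r=b.get("patient_homotopic_r", 0.45)),
    }
    low, high = config.filter.get("low_hz", 0.01), config.filter.get("high_hz", 0.1)
    n_random = config.graph.get("n_random", 100)
    for name, target in targets.items():
        spec = synth.BoldSpec(target_corr=target,
                              n_timepoints=b.get("n_timepoints", 960),
                              dt=b.get("dt", 0.5),
                              noise_frac=b.get("noise_frac", 0.1),
                              seed=substream_seed(seed, f"bold-{name}"))
        ts = synth.make_bold_dataset(spec)
        filtered = fmri_graph.bandpass_filter(ts, low, high)
        corr = fmri_graph.correlation_matrix(filtered)
        result[name] = {}
        for thr in config.graph.get("thresholds", [0.3, 0.4]):
            g = fmri_graph.threshold_graph(corr, float(thr), ts.nodes, ts.hemispheres)
            metrics = fmri_graph.graph_metrics(
                g, n_random=n_random,
                seed=substream_seed(seed, f"gamma-{name}-{thr}"))
            fmri_graph.save_edge_list_csv(
                g, str(out / f"edges_{name}_thr{thr:.2f}.csv"))
            result[name][f"thr{thr:.2f}"] = {
                "n_connections": metrics.n_connections,
                "n_interhemispheric": metrics.n_interhemispheric,
                "clustering": metrics.clustering,
                "gamma": metrics.gamma,
            }
            log.info("bold %s thr %.2f: E=%d inter=%d gamma=%s", name, thr,
                     metrics.n_connections, metrics.n_interhemispheric,
                     metrics.gamma)
    return result


def _stats_stage(config: RunConfig, seed: int, out: Path) -> dict:
    """Simulated cohort -> progression rates -> group GLMs -> integrated report."""
    cohort_spec = synth.CohortSpec(**{**config.cohort,
                                      "seed": substream_seed(seed, "cohort")})
    cohort = stats.add_progression_rate(synth.make_cohort_tables(cohort_spec))
    cohort.to_csv(out / "cohort.csv", index=False)

    glm = stats.glm_group_compare(
        cohort["thickness_lh_precentral"], cohort["group"],
        cohort[["age", "thickness_whole_brain"]])
    report = stats.structure_function_clinic_report(cohort)
    report.to_csv(out / "report.csv", index=False)
    log.info("precentral thickness GLM: effect %.4f mm, t=%.2f, p=%.4f",
             glm.effect, glm.statistic, glm.p)
    return {
        "precentral_glm": {"effect_mm": glm.effect, "t": glm.statistic,
                           "p": glm.p, "covariates": list(glm.covariates)},
        "gamma_vs_progression": report.loc[
            (report.x == "gamma") & (report.y == "progression_rate"),
            ["r", "p"]].iloc[0].to_dict(),
    }


def run_full(config: RunConfig) -> dict:
    """Run every stage and write the output bundle; returns the summary dict.

    Aborts with a ``RuntimeError`` naming the failing stage.  Identical
    config + seed give byte-identical output files.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"seed": int(config.seed),
                     "provenance": _provenance_hash(config),
                     "parameters": {k: getattr(config, k)
                                    for k in ("phantom", "tracking", "bold",
                                              "filter", "graph", "cohort",
                                              "profile_points")}}
    log.info("run start: seed=%d provenance=%s", config.seed, summary["provenance"])
    try:
        for stage, fn in [("dti", _phantom_stage), ("fmri", _fmri_stage),
                          ("stats", _stats_stage)]:
            try:
                summary[stage] = fn(config, int(config.seed), out)
            except Exception as exc:
                raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        log.info("run complete")
    finally:
        log.removeHandler(handler)
        handler.close()
    return summary
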