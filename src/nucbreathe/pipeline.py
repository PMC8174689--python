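"""Config-driven orchestration: generate -> annotate -> observables ->
cluster -> crosstab -> report.

A run is described by a YAML/JSON config with exactly one input source:
either a ``synthetic`` block (the coupled tail-release/arm-opening scenario
of :func:`nucbreathe.synthetic.coupled_opening_scenario`) or an ``input``
block pointing at a topology PDB plus a DCD/multi-model-PDB trajectory with
an annotation profile.  Every output is a deterministically named CSV/JSON
in the output directory, and a manifest records the config echo, seeds,
per-stage row counts and output checksums, so a rerun with the same config
reproduces the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (build_feature_matrix, cross_tabulate, kmeans_cluster,
                         map_clusters_to_gamma, percentile_summary)
from .geometry import breathing_series, gamma_histogram2d
from .interactions import tail_configuration_series
from .structure_io import (NucleosomeIndex, annotate_nucleosome,
                           read_structure, read_trajectory, write_series_csv,
                           write_structure)
from .synthetic import (SyntheticSpec, coupled_opening_scenario,
                        synthetic_profile)

log = logging.getLogger("nucbreathe")


class ConfigError(Exception):
    """Invalid run configuration (unknown key, missing input, bad value)."""


_TOP_KEYS = {"seed", "out_dir", "synthetic", "input", "strides", "clustering",
             "tails", "histogram"}
_SYNTH_KEYS = {"n_frames", "switch_frame", "lag", "open_angles", "arm",
               "jitter_sigma"}
_INPUT_KEYS = {"topology", "trajectory", "format", "frame_interval",
               "profile", "profile_file"}
_CLUSTER_KEYS = {"k", "selections", "opening_arm", "n_init", "max_iter"}


def derive_seed(base: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one global seed."""
    return (int(base) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    for key in cfg:
        if key not in _TOP_KEYS:
            raise ConfigError(f"unknown config key: {key!r}")
    has_syn, has_inp = "synthetic" in cfg, "input" in cfg
    if has_syn == has_inp:
        raise ConfigError(
            "config must contain exactly one of 'synthetic' or 'input'")
    for block, allowed in (("synthetic", _SYNTH_KEYS), ("input", _INPUT_KEYS),
                           ("clustering", _CLUSTER_KEYS)):
        for key in cfg.get(block) or {}:
            if key not in allowed:
                raise ConfigError(f"unknown config key: {block}.{key!r}")
    strides = cfg.get("strides") or {}
    for name, v in strides.items():
        if name not in ("angles", "interactions"):
            raise ConfigError(f"unknown config key: strides.{name!r}")
        if int(v) < 1:
            raise ConfigError(f"stride {name} must be >= 1")
    return cfg


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_generate(cfg: dict, out: Path, seed: int):
    """Generate (or load) the trajectory; returns (traj, nuc, truth|None)."""
    if "synthetic" in cfg:
        syn = cfg["synthetic"] or {}
        spec = SyntheticSpec(seed=derive_seed(seed, "generate"))
        if "jitter_sigma" in syn:
            spec.jitter_sigma = float(syn["jitter_sigma"])
        traj, truth = coupled_opening_scenario(
            n_frames=int(syn.get("n_frames", 240)),
            switch_frame=int(syn.get("switch_frame", 120)),
            lag=int(syn.get("lag", 12)),
            open_angles=tuple(syn.get("open_angles", (35.0, 35.0))),
            arm=syn.get("arm", "3p"),
            seed=derive_seed(seed, "generate"),
            spec=spec,
        )
        profile = synthetic_profile(spec)
        write_structure(traj.topology, out / "topology.pdb")
        truth.to_json(out / "ground_truth.json")
    else:
        inp = cfg["input"]
        topo = read_structure(inp["topology"])
        traj = read_trajectory(topo, inp["trajectory"],
                               format=inp.get("format", "dcd"),
                               frame_interval=float(inp.get("frame_interval", 1.0)))
        truth = None
        if "profile" in inp:
            profile = inp["profile"]
        elif "profile_file" in inp:
            profile = yaml.safe_load(Path(inp["profile_file"]).read_text())
        else:
            raise ConfigError("input block needs 'profile' or 'profile_file'")
    nuc = NucleosomeIndex(traj.topology, annotate_nucleosome(traj.topology,
                                                            profile))
    log.info("generate: %d frames, %d atoms, %d bp", traj.n_frames,
             traj.topology.n_atoms, nuc.annotation.n_bp)
    return traj, nuc, truth


def stage_observables(cfg: dict, out: Path, traj, nuc) -> pd.DataFrame:
    strides = cfg.get("strides") or {}
    obs = breathing_series(traj, nuc, stride=int(strides.get("angles", 1)))
    write_series_csv(obs, out / "angles_rg.csv")
    hist = {arm: gamma_histogram2d(obs, arm,
                                   **(cfg.get("histogram") or {})).summary()
            for arm in ("3p", "5p")}
    (out / "gamma_histograms.json").write_text(json.dumps(hist, indent=1))
    log.info("observables: %d rows", len(obs))
    return obs


def stage_tails(cfg: dict, out: Path, traj, nuc) -> dict[str, pd.DataFrame]:
    strides = cfg.get("strides") or {}
    stride = int(strides.get("interactions", 5))
    result = {}
    for tail in cfg.get("tails") or []:
        series = tail_configuration_series(traj, nuc, tail, stride=stride)
        write_series_csv(series, out / f"tail_{tail}.csv")
        result[tail] = series
        log.info("tails: %s, %d rows", tail, len(series))
    return result


def stage_cluster(cfg: dict, out: Path, traj, nuc, seed: int) -> dict:
    cl = cfg.get("clustering") or {}
    k = int(cl.get("k", 8))
    selections = cl.get("selections", ["dna", "h3", "h2ac"])
    opening_arm = cl.get("opening_arm", "3p")
    models = {}
    labels = pd.DataFrame({"frame": np.arange(traj.n_frames)})
    for tag in selections:
        X = build_feature_matrix(traj, nuc, tag, opening_arm=opening_arm)
        models[tag] = kmeans_cluster(
            X, k=k, seed=derive_seed(seed, f"kmeans-{tag}"),
            n_init=int(cl.get("n_init", 10)),
            max_iter=int(cl.get("max_iter", 500)), selection_tag=tag)
        labels[f"{tag}_cluster"] = models[tag].assignment
        log.info("cluster[%s]: sizes %s", tag, models[tag].sizes.tolist())
    write_series_csv(labels, out / "cluster_labels.csv")
    return models


def stage_crosstab(out: Path, models: dict, obs: pd.DataFrame,
                   opening_arm: str) -> None:
    if "dna" not in models:
        return
    for tag in models:
        if tag == "dna":
            continue
        tab = cross_tabulate(models["dna"], models[tag])
        tab.to_csv(out / f"crosstab_dna_{tag}.csv")
    stride_obs = obs.set_index("frame")
    # per-cluster gamma means need one observable row per clustered frame
    if len(obs) == models["dna"].n_frames:
        gam = map_clusters_to_gamma(models["dna"], obs, opening_arm)
        write_series_csv(gam, out / "cluster_gamma.csv")
    del stride_obs


def stage_report(out: Path, obs: pd.DataFrame,
                 tails: dict[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for col in ("rg", "gamma1_3p", "gamma2_3p", "gamma1_5p", "gamma2_5p"):
        s = percentile_summary(obs[col], label=col)
        rows.append((s.label, s.p_lo, s.p_hi))
    for tail, series in tails.items():
        for col in ("delta_ldna", "nc_inner", "nc_outer", "tail_rg"):
            s = percentile_summary(series[col], label=f"{tail}.{col}")
            rows.append((s.label, s.p_lo, s.p_hi))
    table = pd.DataFrame(rows, columns=["label", "p5", "p95"])
    write_series_csv(table, out / "summary.csv")
    return table


def run_analysis(cfg: dict, out_dir: str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    cfg = validate_config(dict(cfg))
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "nucbreathe_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else cfg.get("seed", 0))

    stage = "generate"
    try:
        traj, nuc, truth = stage_generate(cfg, out, seed)
        stage = "observables"
        obs = stage_observables(cfg, out, traj, nuc)
        stage = "tails"
        tails = stage_tails(cfg, out, traj, nuc)
        stage = "cluster"
        models = stage_cluster(cfg, out, traj, nuc, seed)
        stage = "crosstab"
        opening = (cfg.get("clustering") or {}).get("opening_arm", "3p")
        stage_crosstab(out, models, obs, opening)
        stage = "report"
        table = stage_report(out, obs, tails)
    except Exception:
        log.exception("stage %s failed", stage)
        raise

    outputs = sorted(p.name for p in out.iterdir() if p.is_file()
                     and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": {s: derive_seed(seed, s) for s in
                        ["generate"] + [f"kmeans-{t}" for t in models]},
        "config": cfg,
        "rows": {"angles_rg": len(obs),
                 **{f"tail_{t}": len(s) for t, s in tails.items()},
                 "summary": len(table)},
        "checksums": {name: hashlib.sha256((out / name).read_bytes()).hexdigest()
                      for name in outputs},
    }
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=1, default=str))
    tmp.replace(out / "manifest.json")  # atomic finalize
    return manifest
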