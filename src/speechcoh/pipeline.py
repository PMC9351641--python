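"""End-to-end orchestration: simulate, estimate, test, report.

A single run configuration (dict, JSON or YAML) drives the whole chain:
synthetic cohort generation, coherence and partial coherence with permuted
baselines per subject, group-level cluster statistics, ROI contrasts and
behavioral analysis.  Every random stage receives a seed derived from the
run seed, and a manifest records the configuration and SHA-256 hashes of
all written artifacts, so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import correlate_bootstrap, hartigans_dip
from .cluststats import SubjectStatMap, one_sample_cluster_test, roi_average, roi_contrast
from .nulls import coherence_with_baseline
from .synthetic import (CONDITIONS, GroupSpec, SyntheticConfig,
                        generate_behavioral_cohort, generate_envelope_trials,
                        generate_recording, grid_adjacency, jitter_config)

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    """Baseline run configuration; override any key from file or CLI."""
    return {
        "seed": 0,
        "n_subjects": 14,
        "condition": "AV_low",
        "modality": "auditory",          # envelope whose tracking is tested
        "partial": True,                  # condition on the other envelope
        "freq_grid": [2, 3, 4, 5, 6, 7, 8],
        "n_perm_baseline": 50,
        "n_perm_cluster": 1000,
        "cdt_p": 0.05,
        "alpha": 0.05,
        "roi_band": [2.0, 6.0],
        "rois": ["STG", "occipital"],
        "subject_gain_jitter": 0.2,
        "synthetic": {},                  # SyntheticConfig field overrides
        "behavior": {
            "n_subjects": 14,
            "benefit_lipreading_r": 0.9,
            "n_boot": 1000,
            "dip_mc": 2000,
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _synthetic_config(cfg: dict) -> SyntheticConfig:
    overrides = dict(cfg.get("synthetic") or {})
    groups = overrides.pop("channel_groups", None)
    kwargs = dict(overrides)
    if groups is not None:
        kwargs["channel_groups"] = {
            name: GroupSpec(**spec) for name, spec in groups.items()
        }
    if "coupling_band" in kwargs:
        kwargs["coupling_band"] = tuple(kwargs["coupling_band"])
    kwargs.setdefault("seed", cfg["seed"])
    return SyntheticConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | None = None, out_dir: str | Path = "speechcoh_run") -> dict:
    """Execute the full simulate-and-analyze chain; returns the report dict.

    Writes into ``out_dir``: per-subject ROI table (CSV), cluster result
    (JSON), behavioral table (CSV), report (JSON) and a manifest with
    hashes of everything.
    """
    cfg = _merge(default_config(), config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}

    base_synth = _synthetic_config(cfg)
    condition = cfg["condition"]
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    modality = cfg["modality"]
    if modality not in ("auditory", "visual"):
        raise ValueError("modality must be 'auditory' or 'visual'")
    other = "visual" if modality == "auditory" else "auditory"
    freq_grid = np.asarray(cfg["freq_grid"], dtype=float)
    rng = np.random.default_rng(cfg["seed"])

    # --- per-subject coherence maps against the permuted baseline
    t0 = time.time()
    subject_effects = []
    roi_rows = []
    adjacency = None
    channel_names = None
    for s in range(int(cfg["n_subjects"])):
        sub_cfg = jitter_config(base_synth, rng, sd_log=cfg["subject_gain_jitter"])
        env_seed = int(rng.integers(2**31 - 1))
        rec_seed = int(rng.integers(2**31 - 1))
        base_seed = int(rng.integers(2**31 - 1))
        aud, vis = generate_envelope_trials(sub_cfg, seed=env_seed)
        rec = generate_recording(sub_cfg, aud, vis, condition, seed=rec_seed)
        envs = {"auditory": aud, "visual": vis}
        cmap = coherence_with_baseline(
            rec, envs[modality], fs=sub_cfg.fs, freq_grid=freq_grid,
            n_perm=int(cfg["n_perm_baseline"]), seed=base_seed,
            z_trials=envs[other] if cfg["partial"] else None,
            estimator="partial_coherence" if cfg["partial"] else "coherence",
        )
        subject_effects.append(cmap.effect)
        adjacency = rec.adjacency
        channel_names = rec.channel_names
        row = {"subject": f"S{s:02d}"}
        for roi in cfg["rois"]:
            row[roi] = roi_average(cmap, rec.groups[roi], band=tuple(cfg["roi_band"]))
        roi_rows.append(row)
    timings["subjects"] = time.time() - t0

    maps = SubjectStatMap(np.stack(subject_effects), adjacency=adjacency,
                          freqs=freq_grid, channel_names=channel_names)

    # --- group-level cluster test
    t0 = time.time()
    clusters = one_sample_cluster_test(
        maps, n_perm=int(cfg["n_perm_cluster"]), cdt_p=cfg["cdt_p"],
        alpha=cfg["alpha"], seed=int(rng.integers(2**31 - 1)))
    timings["cluster_test"] = time.time() - t0

    # --- ROI contrasts vs the permuted baseline (one-tailed)
    roi_df = pd.DataFrame(roi_rows)
    roi_stats = {}
    for roi in cfg["rois"]:
        t, p, mean = roi_contrast(roi_df[roi].to_numpy(), 0.0, tail="one")
        roi_stats[roi] = {"mean_effect": mean, "t": t, "p_one_tailed": p}

    # --- behavioral cohort
    t0 = time.time()
    bcfg = cfg["behavior"]
    behav = generate_behavioral_cohort(
        int(bcfg["n_subjects"]), bcfg["benefit_lipreading_r"],
        seed=int(rng.integers(2**31 - 1)))
    r, p_r, ci = correlate_bootstrap(
        behav["lip_reading"].to_numpy(), behav["av_benefit"].to_numpy(),
        n_boot=int(bcfg["n_boot"]), seed=int(rng.integers(2**31 - 1)))
    dip, p_dip = hartigans_dip(behav["av_benefit"].to_numpy(),
                               n_mc=int(bcfg["dip_mc"]),
                               seed=int(rng.integers(2**31 - 1)))
    timings["behavior"] = time.time() - t0

    # --- write artifacts + manifest
    roi_df.to_csv(out / "roi_effects.csv", index=False)
    clusters.save(out / "clusters.json")
    behav.to_csv(out / "behavior.csv", index=False)
    sig = clusters.significant
    report = {
        "condition": condition,
        "modality": modality,
        "estimator": "partial_coherence" if cfg["partial"] else "coherence",
        "n_subjects": int(cfg["n_subjects"]),
        "n_clusters": len(clusters.clusters),
        "significant_clusters": [
            {
                "mass": float(clusters.masses[i]),
                "p": float(clusters.p_values[i]),
                "channels": sorted({channel_names[c] for c, _ in clusters.clusters[i]}),
                "freqs_hz": sorted({float(freq_grid[f]) for _, f in clusters.clusters[i]}),
            }
            for i in sig
        ],
        "roi_stats": roi_stats,
        "behavior": {
            "lipreading_benefit_r": r,
            "r_p_two_tailed": p_r,
            "r_ci95": list(ci),
            "dip": dip,
            "dip_p": p_dip,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    artifacts = ["roi_effects.csv", "clusters.json", "behavior.csv", "report.json"]
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    # stage timings are diagnostics only; they stay out of the hashed artifacts
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    report["elapsed_s"] = round(time.time() - t_start, 3)
    return report
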