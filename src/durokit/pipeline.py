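"""End-to-end pipeline driver and run manifests.

``run_pipeline`` executes up to three flows from one validated config dict:

* ``elastography``: synthesize force curves over a grid of a reference
  pattern → fit the Hertz model per curve → assemble the stiffness map →
  average-slope statistic (and peak/valley detection);
* ``migration``: simulate persistent (optionally gradient-biased) walkers on
  a pattern → coverage filter → per-track metrics → rose histogram;
* ``assay``: simulate walkers on a step pattern and score the end-point
  durotactic index against the plating-time baseline.

Every run writes its outputs plus one ``manifest.json`` (command, config
hash, package version, seeds, timestamps, output digests) into the output
directory; rerunning the same config reproduces the numbers exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__, afm, assay, gradients, io, migration, simulate, substrates
from .exceptions import DurokitError

_TOP_KEYS = {"seed", "elastography", "migration", "assay"}
_STAGE_KEYS = {
    "elastography": {"pattern", "field", "pitch_um", "noise_frac", "n_slopes",
                     "min_prominence_Pa", "smooth_window", "extent_um",
                     "detect_smooth_sigma_px"},
    "migration": {"pattern", "n", "bias_strength", "duration_s",
                  "frame_interval_s", "speed_mean_um_min", "persistence_time_s",
                  "min_coverage"},
    "assay": {"pattern", "n", "bias_strength", "duration_s", "frame_interval_s",
              "baseline_h"},
}
_PATTERN_FACTORIES = {
    "step_stripes": substrates.step_pattern,
    "linear_gradient": substrates.gradient_pattern,
    "island": substrates.island_pattern,
    "uniform": substrates.uniform_pattern,
}


def validate_config(config: dict) -> dict:
    """Reject unknown keys before any compute."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise DurokitError(f"unknown config keys: {sorted(unknown)}")
    for stage, allowed in _STAGE_KEYS.items():
        sub = config.get(stage)
        if sub is None:
            continue
        extra = set(sub) - allowed
        if extra:
            raise DurokitError(f"unknown {stage} config keys: {sorted(extra)}")
    if not config.get("elastography") and not config.get("migration") \
            and not config.get("assay"):
        raise DurokitError("config enables no pipeline stage")
    return config


def _pattern_from_config(spec):
    if spec is None:
        return None
    if isinstance(spec, str):
        return _PATTERN_FACTORIES[spec]()
    return substrates.SubstratePattern.from_dict(spec)


def demo_config() -> dict:
    """The bundled small demo configuration (also shipped as data/demo_config.yaml)."""
    import yaml

    path = Path(__file__).parent / "data" / "demo_config.yaml"
    return yaml.safe_load(path.read_text())


def run_pipeline(config: dict, out_dir, command="run") -> dict:
    """Execute the configured flows; returns the result bundle as a dict."""
    validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    started = time.time()
    results = {}
    outputs = []
    try:
        if config.get("elastography"):
            results["elastography"] = _run_elastography(
                config["elastography"], seed, out_dir, outputs)
        if config.get("migration"):
            results["migration"] = _run_migration(
                config["migration"], seed, out_dir, outputs)
        if config.get("assay"):
            results["assay"] = _run_assay(config["assay"], seed, out_dir, outputs)
    except Exception as exc:
        raise DurokitError(
            f"pipeline failed in stage {_current_stage(results)}: {exc}") from exc

    manifest = {
        "command": command,
        "config": io._jsonable(config),
        "config_sha256": hashlib.sha256(
            json.dumps(io._jsonable(config), sort_keys=True).encode()).hexdigest(),
        "package_version": __version__,
        "seed": seed,
        "started_unix": started,
        "finished_unix": time.time(),
        "outputs": {name: _digest(out_dir / name) for name in outputs},
    }
    io.write_json(manifest, out_dir / "manifest.json")
    io.write_json(results, out_dir / "results.json")
    return results


def _current_stage(results):
    done = list(results)
    order = ["elastography", "migration", "assay"]
    for s in order:
        if s not in done:
            return s
    return "finalize"


def _digest(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _run_elastography(cfg, seed, out_dir, outputs):
    pitch = float(cfg.get("pitch_um", 5.0))
    noise = float(cfg.get("noise_frac", 0.02))
    if "field" in cfg:
        # ground truth is a synthetic tissue-like field (healthy/fibrotic)
        extent = tuple(cfg.get("extent_um", (200.0, 200.0)))
        truth_map, _ = simulate.gen_stiffness_field(seed, kind=cfg["field"],
                                                    extent=extent, pitch=pitch)
        pattern = substrates.field_pattern(truth_map)
    else:
        pattern = _pattern_from_config(cfg.get("pattern", "step_stripes"))
    w, h = pattern.extent
    nc, nr = int(round(w / pitch)), int(round(h / pitch))
    fits = []
    for r in range(nr):
        for c in range(nc):
            x, y = (c + 0.5) * pitch, (r + 0.5) * pitch
            e_true = substrates.stiffness_at(pattern, (x, y))
            curves, _ = simulate.gen_force_curves(
                seed + r * nc + c, e_true, n_curves=1, n_samples=60,
                noise_frac=noise, positions=[(x, y)])
            fits.append(afm.fit_hertz(curves[0]))
    smap = afm.build_stiffness_map(fits, pitch=pitch)
    io.write_map(smap, out_dir / "stiffness_map.tif")
    outputs += ["stiffness_map.tif"]
    summary = gradients.average_slope(smap, n_slopes=int(cfg.get("n_slopes", 50)),
                                      seed=seed,
                                      smooth_window=int(cfg.get("smooth_window", 1)))
    foci = gradients.detect_peaks_valleys(
        smap, min_prominence=float(cfg.get("min_prominence_Pa", 5e3)),
        smooth_sigma_px=float(cfg.get("detect_smooth_sigma_px", 0.0)))
    res = {
        "n_fits": len(fits),
        "n_invalid": sum(not f.valid for f in fits),
        "average_slope_Pa_per_um": summary.average_slope,
        "n_slopes": summary.n_slopes,
        "n_peaks": sum(1 for f in foci if f[2] == "peak"),
        "n_valleys": sum(1 for f in foci if f[2] == "valley"),
    }
    io.write_json({"slopes": summary.slopes, "average": summary.average_slope,
                   "seed": summary.seed, "scheme": summary.scheme},
                  out_dir / "slopes.json")
    outputs += ["slopes.json"]
    return res


def _sim_config(cfg, seed):
    return simulate.SimulationConfig(
        seed=seed,
        n=int(cfg.get("n", 75)),
        bias_strength=float(cfg.get("bias_strength", 0.0)),
        persistence_time=float(cfg.get("persistence_time_s", 1800.0)),
        speed_mean=float(cfg.get("speed_mean_um_min", 0.5)),
        duration=float(cfg.get("duration_s", 24 * 3600.0)),
        frame_interval=float(cfg.get("frame_interval_s", 300.0)),
    )


def _run_migration(cfg, seed, out_dir, outputs):
    pattern = _pattern_from_config(cfg.get("pattern", "linear_gradient"))
    sim = _sim_config(cfg, seed)
    tracks, _ = simulate.gen_tracks(pattern, sim)
    kept = migration.filter_tracks(tracks, sim.duration,
                                   float(cfg.get("min_coverage", 0.10)))
    table = migration.metrics_table(kept)
    rose = migration.rose_histogram(kept)
    io.write_tracks(kept, out_dir / "tracks.csv")
    table.to_csv(out_dir / "track_metrics.csv", index=False)
    io.write_json({"bin_edges_deg": rose.bin_edges, "counts": rose.counts,
                   "reference_axis": rose.reference_axis,
                   "n_excluded": rose.n_excluded}, out_dir / "rose.json")
    outputs += ["tracks.csv", "track_metrics.csv", "rose.json"]
    return {
        "n_tracks": len(kept),
        "mean_fmi_parallel": float(table["fmi_parallel"].mean()),
        "mean_speed_um_min": float(table["mean_speed"].mean()),
        "mean_directionality": float(table["directionality"].mean()),
        "resultant_length": migration.resultant_length(rose),
    }


def _run_assay(cfg, seed, out_dir, outputs):
    pattern = _pattern_from_config(cfg.get("pattern", "step_stripes"))
    sim = _sim_config(cfg, seed)
    tracks, _ = simulate.gen_tracks(pattern, sim)
    baseline_h = float(cfg.get("baseline_h", 4.0))
    t = tracks[0].t
    k_base = int(np.argmin(np.abs(t - baseline_h * 3600.0)))
    obs_base = assay.AssayObservation(
        t[k_base] / 3600.0,
        np.array([[tr.x[k_base], tr.y[k_base]] for tr in tracks]), pattern)
    obs_end = assay.AssayObservation(
        t[-1] / 3600.0,
        np.array([[tr.x[-1], tr.y[-1]] for tr in tracks]), pattern)
    course = assay.assay_timecourse([obs_base, obs_end])
    res = {}
    for tp, r in course:
        res[f"{tp:g}h"] = {
            "n_stiff": r.n_stiff, "n_soft": r.n_soft, "n_excluded": r.n_excluded,
            "index_raw": r.index_raw, "index_normalized": r.index_normalized,
            "saturated": r.saturated,
            "label": (assay.classify_durotaxis(r.index_normalized)
                      if np.isfinite(r.index_normalized) else "saturated"),
        }
    io.write_json(res, out_dir / "assay.json")
    outputs += ["assay.json"]
    return res
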