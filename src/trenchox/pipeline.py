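"""Orchestrate simulate -> extract -> analyze -> model -> report runs.

A run produces a deterministic directory layout::

    out/
      tracks/<label>.csv          one track table per treatment schedule
      features/features.csv       mother-cell feature matrix (+ manifest.json)
      reports/response.json       occupancy, calibration, attenuation, lag
      reports/model.json          regression/classification report
      manifest.json               config digests, seeds, stage wall-clock

Scenarios mirror the study's experimental designs (full/partial loading,
wide trenches, genotype mixes, step versus ramp high-dose treatment, pulse
trains, the calibration concentration panel and the multi-concentration
panel used for model training).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from . import ml
from . import metrics
from . import response as rs
from .config import SimConfig, TreatmentSchedule, Segment, config_digest
from .simulate import simulate

log = logging.getLogger(__name__)

STAGES = ("simulate", "features", "response", "model", "report")
ML_PANEL_UM = (37.5, 50.0, 62.5, 75.0, 100.0)


@dataclass
class Scenario:
    """A named experiment: one config and one or more treatment schedules."""

    name: str
    config: SimConfig
    schedules: dict  # label -> TreatmentSchedule
    description: str = ""


def _standard_config(seed: int, **overrides) -> SimConfig:
    return SimConfig(seed=seed, **overrides)


def scenario(name: str, seed: int = 0, n_trenches: int | None = None) -> Scenario:
    """Build a named scenario; unknown names raise with the list of options."""
    nt = n_trenches
    if name == "full_loading":
        cfg = _standard_config(seed, n_trenches=nt or 100)
        return Scenario(name, cfg, {"c100": TreatmentSchedule.step(100.0)},
                        "fully loaded trenches, continuous 100 uM step")
    if name == "partial_loading":
        cfg = _standard_config(seed, n_trenches=nt or 100, loading_mean_cells=5.0,
                               t_start_min=-60.0)
        return Scenario(name, cfg, {"c100": TreatmentSchedule.step(100.0)},
                        "variable 5 +/- 2 cells per trench at treatment time")
    if name == "wide_trench":
        cfg = _standard_config(seed, n_trenches=nt or 100, trench_width_um=1.4)
        return Scenario(name, cfg, {"c100": TreatmentSchedule.step(100.0)},
                        "1.4 um wide trenches (lower effective cell density)")
    if name == "mixed_genotypes":
        cfg = _standard_config(seed, n_trenches=nt or 100,
                               genotype_mix={"WT": 0.7, "delta_oxyR": 0.3})
        return Scenario(name, cfg, {"c100": TreatmentSchedule.step(100.0)},
                        "WT and delta-oxyR cells mixed in the same trenches")
    if name == "step_500":
        cfg = _standard_config(seed, n_trenches=nt or 200, t_start_min=-60.0,
                               t_end_min=720.0)
        sched = TreatmentSchedule([Segment(0.0, 60.0, 500.0)])
        return Scenario(name, cfg, {"step500": sched},
                        "sudden 1 h pulse of 500 uM, then recovery")
    if name == "ramp_500":
        cfg = _standard_config(seed, n_trenches=nt or 200, t_start_min=-60.0,
                               t_end_min=720.0)
        sched = TreatmentSchedule([Segment(0.0, 9.0, 25.0),
                                   Segment(9.0, 18.0, 100.0),
                                   Segment(18.0, 78.0, 500.0)])
        return Scenario(name, cfg, {"ramp500": sched},
                        "gradual 25 -> 100 -> 500 uM within 18 min, 1 h at "
                        "500 uM, then recovery")
    if name == "pulse_train":
        cfg = _standard_config(seed, n_trenches=nt or 100, t_end_min=300.0)
        sched = TreatmentSchedule.pulse_train(100.0, n_pulses=4, on_min=15.0,
                                              off_min=45.0)
        return Scenario(name, cfg, {"pulses": sched},
                        "repeated short 100 uM pulses")
    if name == "calibration_panel":
        # sparse loading: the fully exposed reference cells are then nearly
        # static, so their intensities equilibrate to the local concentration
        cfg = _standard_config(seed, n_trenches=nt or 40, t_start_min=-60.0,
                               t_end_min=185.0, loading_mean_cells=2.0)
        scheds = {f"c{c:g}": TreatmentSchedule.step(c)
                  for c in rs.CALIBRATION_PANEL_UM}
        return Scenario(name, cfg, scheds,
                        "seven-concentration panel for intensity calibration")
    if name == "ml_panel":
        cfg = _standard_config(seed, n_trenches=nt or 176, t_end_min=140.0)
        scheds = {f"c{c:g}": TreatmentSchedule.step(c) for c in ML_PANEL_UM}
        return Scenario(name, cfg, scheds,
                        "37.5-100 uM panel for model training/evaluation")
    known = ("full_loading", "partial_loading", "wide_trench", "mixed_genotypes",
             "step_500", "ramp_500", "pulse_train", "calibration_panel",
             "ml_panel")
    raise ValueError(f"unknown scenario {name!r}; known scenarios: {known}")


def simulate_panel(base_config: SimConfig, concentrations, label_prefix="c",
                   t_end: float | None = None) -> dict:
    """Simulate one run per external concentration with per-run derived
    seeds; returns label -> (tracks, meta)."""
    out = {}
    for i, c in enumerate(concentrations):
        cfg = base_config.replace(seed=(base_config.seed * 1000 + i) % (2 ** 31))
        if t_end is not None:
            cfg = cfg.replace(t_end_min=t_end)
        sched = TreatmentSchedule.step(float(c))
        out[f"{label_prefix}{c:g}"] = simulate(cfg, sched)
    return out


def occupancy(tracks: pd.DataFrame, burn_in_min: float = 180.0,
              from_start: bool = True) -> float:
    """Mean number of cells per trench per frame after a burn-in.

    ``burn_in_min`` is measured from the first recorded frame when
    ``from_start`` (the convention for untreated growth runs).
    """
    t0 = tracks["time_min"].min() if from_start else 0.0
    sel = tracks[tracks["time_min"] >= t0 + burn_in_min]
    counts = sel.groupby(["trench_id", "frame"], observed=True).size()
    return float(counts.mean())


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def run(out_dir, scen: Scenario | str, seed: int | None = None,
        stages=STAGES) -> dict:
    """Execute the pipeline stages for a scenario into ``out_dir``.

    Stages are resumable: a stage whose outputs already exist is skipped
    (the manifest still lists digests), and later stages read the stored
    artifacts, so a resumed run equals a fresh one.  Returns the manifest.
    """
    if isinstance(scen, str):
        scen = scenario(scen, seed=seed or 0)
    elif seed is not None:
        scen = Scenario(scen.name, scen.config.replace(seed=seed),
                        scen.schedules, scen.description)
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    (out / "features").mkdir(exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)
    manifest = {"scenario": scen.name, "seed": scen.config.seed,
                "config_digest": config_digest(scen.config),
                "stages": {}, "outputs": {}}
    timings = {}

    def _stage_done(name, *paths):
        timings[name] = timings.get(name, 0.0)
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _digest_file(p)

    track_paths = {lab: out / "tracks" / f"{lab}.csv" for lab in scen.schedules}
    if "simulate" in stages:
        t0 = time.perf_counter()
        for lab, sched in scen.schedules.items():
            if track_paths[lab].exists():
                continue
            df, meta = simulate(scen.config, sched)
            tio.write_tracks(df, track_paths[lab], meta)
        timings["simulate"] = time.perf_counter() - t0
        _stage_done("simulate", *track_paths.values())

    feat_path = out / "features" / "features.csv"
    man_path = out / "features" / "manifest.json"
    if "features" in stages:
        missing = [p for p in track_paths.values() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"features stage requires track tables: "
                                    f"{[str(m) for m in missing]}")
        t0 = time.perf_counter()
        if not feat_path.exists():
            frames = []
            for lab, p in track_paths.items():
                df, _ = tio.read_tracks(p)
                fm = metrics.build_feature_matrix(df)
                fm.insert(0, "run_label", lab)
                frames.append(fm)
            metrics.write_feature_matrix(pd.concat(frames, ignore_index=True),
                                         feat_path, man_path)
        timings["features"] = time.perf_counter() - t0
        _stage_done("features", feat_path, man_path)

    resp_path = out / "reports" / "response.json"
    if "response" in stages:
        t0 = time.perf_counter()
        if not resp_path.exists():
            report = {}
            for lab, p in track_paths.items():
                df, meta = tio.read_tracks(p)
                report[lab] = {
                    "occupancy": occupancy(df),
                    "n_trenches": int(df["trench_id"].nunique()),
                    "exited": meta.get("exited"),
                    "died": meta.get("died"),
                }
            resp_path.write_text(json.dumps(report, indent=1))
        timings["response"] = time.perf_counter() - t0
        _stage_done("response", resp_path)

    model_path = out / "reports" / "model.json"
    if "model" in stages:
        if not feat_path.exists():
            raise FileNotFoundError("model stage requires features/features.csv")
        t0 = time.perf_counter()
        if not model_path.exists():
            fm = pd.read_csv(feat_path)
            report = ml.full_report(fm, seed=scen.config.seed)
            model_path.write_text(json.dumps(report.to_dict(), indent=1))
        timings["model"] = time.perf_counter() - t0
        _stage_done("model", model_path)

    manifest["stages"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if "report" in stages:
        (out / "report.txt").write_text(report_text(out))
    return manifest


def report_text(out_dir) -> str:
    """Human-readable summary of a run directory's key numbers."""
    out = Path(out_dir)
    lines = []
    man_path = out / "manifest.json"
    if man_path.exists():
        man = json.loads(man_path.read_text())
        lines.append(f"scenario: {man.get('scenario')}  seed: {man.get('seed')}"
                     f"  config: {man.get('config_digest')}")
    else:
        lines.append("WARNING: incomplete run (no manifest)")
    resp_path = out / "reports" / "response.json"
    if resp_path.exists():
        resp = json.loads(resp_path.read_text())
        for lab, r in resp.items():
            lines.append(f"[{lab}] occupancy {r['occupancy']:.2f} cells/trench "
                         f"({r['n_trenches']} trenches; {r['exited']} exits, "
                         f"{r['died']} deaths)")
    feat_path = out / "features" / "features.csv"
    if feat_path.exists():
        fm = pd.read_csv(feat_path, nrows=1)
        n_feat = len([c for c in fm.columns if c in metrics.FEATURE_COLUMNS])
        lines.append(f"feature matrix: {n_feat} feature columns")
    model_path = out / "reports" / "model.json"
    if model_path.exists():
        m = json.loads(model_path.read_text())
        lines.append(f"regression accuracy A = {m['accuracy']:.3f} "
                     f"(train {m['n_train']}, test {m['n_test']})")
        imp = m["importance"]
        lines.append(f"importance: barrier share {imp['barrier_share']:.3f}, "
                     f"top-2 share {imp['top2_share']:.3f}")
        if m.get("barrier_only_accuracy") is not None:
            lines.append(f"barrier-only model: A = {m['barrier_only_accuracy']:.3f} "
                         f"({m['barrier_only_n_features']} features)")
        if m.get("classifier_accuracy") is not None:
            lines.append(f"concentration classifier accuracy "
                         f"{m['classifier_accuracy']:.3f}")
    if len(lines) <= 1:
        lines.append("WARNING: partial run, no stage outputs found")
    return "\n".join(lines) + "\n"


GRADIENT_LENGTHS_UM = (10.0, 15.0, 20.0, 25.0)


def shielding_inference(base_config: SimConfig | None = None, seed: int = 0,
                        c0: float = 50.0, n_trenches: int = 40,
                        panel_trenches: int = 10, n_boot: int = 1000,
                        calibration=None):
    """Estimate the per-barrier-cell attenuation fraction from simulations.

    Mirrors the study's design: a sparse-loading calibration panel maps
    steady-state intensity of fully exposed cells to concentration, and the
    shielding gradient is read from static mother cells.  Persistent
    variation in barrier count comes from simulating trenches of several
    lengths (stable occupancies of roughly 3-9 cells); within one geometry,
    occupancy fluctuations are too transient for the slow reporter to track.

    Returns a :class:`response.CalibrationResult` with ``attenuation`` and
    its bootstrap confidence interval filled in.
    """
    cfg = (base_config or SimConfig()).replace(
        seed=seed, t_start_min=-60.0, t_end_min=185.0)
    if calibration is None:
        panel = {}
        pcfg = cfg.replace(loading_mean_cells=2.0, n_trenches=panel_trenches)
        for i, c in enumerate(rs.CALIBRATION_PANEL_UM):
            df, _ = simulate(pcfg.replace(seed=(seed * 977 + i) % (2 ** 31)),
                             TreatmentSchedule.step(c))
            per = rs.steady_state_intensities(df, window=(60.0, 180.0),
                                              outermost_only=True)
            panel[c] = float(np.mean(per["intensity"]))
        cal = rs.calibrate(panel)
    else:
        cal = calibration
    pieces = []
    for j, length in enumerate(GRADIENT_LENGTHS_UM):
        gcfg = cfg.replace(trench_length_um=length, n_trenches=n_trenches,
                           loading_mean_cells=min(cfg.loading_mean_cells,
                                                  length / 2.6),
                           seed=(seed * 601 + 7 * j + 1) % (2 ** 31))
        df, _ = simulate(gcfg, TreatmentSchedule.step(c0))
        df = df.copy()
        df["trench_id"] = df["trench_id"] + 1000 * j
        pieces.append(df)
    tracks = pd.concat(pieces, ignore_index=True)
    return rs.attenuation_from_tracks(tracks, cal, n_boot=n_boot, seed=seed)


def ml_panel_matrix(seed: int = 0, trenches_per_conc: int = 170,
                    concentrations=ML_PANEL_UM) -> pd.DataFrame:
    """Simulate the multi-concentration panel and build the pooled
    mother-cell feature matrix used for model training and evaluation."""
    frames = []
    for i, c in enumerate(concentrations):
        cfg = SimConfig(n_trenches=trenches_per_conc, t_start_min=-165.0,
                        t_end_min=140.0, seed=(seed * 7919 + 100 + i) % (2 ** 31))
        df, _ = simulate(cfg, TreatmentSchedule.step(float(c)))
        fm = metrics.build_feature_matrix(df)
        fm["trench_id"] = fm["trench_id"] + 100_000 * i
        frames.append(fm)
    return pd.concat(frames, ignore_index=True)


def occupancy_run(seed: int = 0, n_trenches: int = 120,
                  duration_min: float = 540.0, burn_in_min: float = 180.0):
    """Untreated growth run; returns (mean cells/trench after burn-in, tracks)."""
    cfg = SimConfig(n_trenches=n_trenches, t_start_min=0.0,
                    t_end_min=duration_min, seed=seed)
    df, _ = simulate(cfg, TreatmentSchedule([]))
    return occupancy(df, burn_in_min=burn_in_min), df
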