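"""End-to-end pipeline: simulate → (render/segment) → measure → analyze → report.

A run is driven by a flat YAML config and a root seed; every stage draws its
randomness from named substreams of that seed, and every output file carries
the config hash and seed in a comment header, so reruns are byte-identical.
Stages write into a run directory (SWC skeletons per arbor per session,
event CSVs, morphometry tables, a JSON summary) and are skipped on rerun
when their outputs already exist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from arbortrack import longitudinal as lg
from arbortrack.grid import write_stack
from arbortrack.morphometry import (
    MIN_TERMINAL_LENGTH_UM,
    detect_swellings,
    enumerate_terminal_branches,
    tree_width_profile,
)
from arbortrack.segmentation import SegConfig, component_table, segment_arbor, tubularity_filter
from arbortrack.skeleton import read_swc, write_swc
from arbortrack.stats import gated_group_comparison
from arbortrack.synth import (
    ImagingParams,
    SimulationConfig,
    TurnoverParams,
    render_stack,
    simulate_cohort,
)
from arbortrack.turnover_null import compare_observed_to_null

__all__ = ["RunConfig", "run_pipeline", "load_config", "detect_swelling_onsets"]

log = logging.getLogger("arbortrack")


@dataclass
class AnalysisParams:
    tip_tolerance_um: float = lg.TIP_TOLERANCE_UM
    min_length_um: float = MIN_TERMINAL_LENGTH_UM
    stop_epsilon_um: float = lg.STOP_EPSILON_UM
    sampling_intervals_h: tuple[float, ...] = ()
    window_days: float = 10.0
    with_hull: bool = True


@dataclass
class RunConfig:
    mode: str = "full"  # simulate | analyze | full
    out_dir: str = "arbortrack_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    segmentation: SegConfig = field(default_factory=SegConfig)
    turnover: TurnoverParams = field(default_factory=TurnoverParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    render_demo: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze", "full"):
            raise ValueError(f"mode must be simulate|analyze|full, got {self.mode!r}")

    def config_hash(self) -> str:
        """Hash of the study conditions (execution details like output paths,
        mode and log level excluded, so reruns elsewhere hash identically)."""
        plain = _to_plain(self)
        for key in ("out_dir", "log_level", "mode"):
            plain.pop(key, None)
        blob = yaml.safe_dump(plain, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "imaging": ImagingParams,
    "segmentation": SegConfig,
    "turnover": TurnoverParams,
    "analysis": AnalysisParams,
}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; unknown keys raise a validation error that
    names every offending key."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    bad = [k for k in raw if k not in top_fields]
    kwargs = {}
    for key, value in raw.items():
        if key in bad:
            continue
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            bad.extend(f"{key}.{k}" for k in value if k not in sub_fields)
            clean = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in value.items()
                if k in sub_fields
            }
            kwargs[key] = cls(**clean)
        else:
            kwargs[key] = value
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return RunConfig(**kwargs)


# -- swelling detection over a series ----------------------------------------


def detect_swelling_onsets(
    series: lg.ArborTimeSeries,
    ratio_threshold: float = 3.0,
    min_length_um: float = MIN_TERMINAL_LENGTH_UM,
    tip_tolerance_um: float = lg.TIP_TOLERANCE_UM,
):
    """Swelling annotations at the first session each bulb is visible.

    A branch flagged as swollen at session k is an *onset* unless its match
    in session k−1 was already swollen (the same bulb observed again while
    the branch retracts).
    """
    onsets = []
    prev_swollen: set[int] = set()
    for k, tree in enumerate(series.trees):
        swollen = {}
        for b in enumerate_terminal_branches(tree, min_length_um):
            ann = detect_swellings(
                tree_width_profile(b),
                ratio_threshold,
                branch_id=b.branch_id,
                time_h=series.times_h[k],
            )
            if ann.is_swelling:
                swollen[b.branch_id] = ann
        if k == 0:
            onsets.extend(swollen.values())
        else:
            ev = lg.match_terminal_branches(
                series.trees[k - 1], tree, tip_tolerance_um, min_length_um=0.0
            )
            back = {n: p for p, n in ev.matches}
            for bid, ann in swollen.items():
                if back.get(bid) not in prev_swollen:
                    onsets.append(ann)
        prev_swollen = set(swollen)
    return onsets


# -- pipeline stages ----------------------------------------------------------


def _swc_name(arbor_id: int, time_h: float) -> str:
    return f"arbor{arbor_id}_t{int(round(time_h)):03d}.swc"


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Deterministic given the config (including seed). Existing stage outputs
    are reused, so a failed run resumes where it stopped.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    provenance = [f"config_hash={cfg.config_hash()}", f"seed={cfg.seed}"]
    try:
        sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        if cfg.mode in ("simulate", "full"):
            _stage_simulate(sim, out, provenance)
        if cfg.mode in ("analyze", "full"):
            series_list = _read_series(out, cfg)
            _stage_analyze(cfg, series_list, out, provenance)
            if cfg.render_demo:
                _stage_render_demo(cfg, out, provenance)
        with open(out / "config.yaml", "w") as f:
            yaml.safe_dump(_to_plain(cfg), f, sort_keys=True)
        return out
    finally:
        log.removeHandler(fh)
        fh.close()


def _write_csv(df: pd.DataFrame, path: Path, provenance: list[str]) -> None:
    with open(path, "w") as f:
        for line in provenance:
            f.write(f"# {line}\n")
        df.to_csv(f, index=False)


def _stage_simulate(sim: SimulationConfig, out: Path, provenance: list[str]) -> None:
    events_path = out / "events.csv"
    if events_path.exists():
        log.info("simulate: outputs present, skipping")
        return
    log.info("simulate: %d arbors over %.0f h", sim.n_arbors, sim.duration_h)
    series, times, events = simulate_cohort(sim)
    for arbor_id, snaps in series.items():
        for t, tree in zip(times, snaps):
            write_swc(tree, out / _swc_name(arbor_id, t), header=provenance)
    _write_csv(events.to_frame(), events_path, provenance)


def _read_series(out: Path, cfg: RunConfig) -> list[lg.ArborTimeSeries]:
    sim = cfg.simulation
    n_snaps = int(np.floor(sim.duration_h / sim.snapshot_interval_h)) + 1
    times = [k * sim.snapshot_interval_h for k in range(n_snaps)]
    series_list = []
    for arbor_id in range(sim.n_arbors):
        paths = [out / _swc_name(arbor_id, t) for t in times]
        missing = [p.name for p in paths if not p.exists()]
        if missing:
            raise FileNotFoundError(
                f"analyze mode: missing skeletons {missing[:3]}… for arbor {arbor_id}"
            )
        trees = [read_swc(p) for p in paths]
        series_list.append(
            lg.ArborTimeSeries.from_trees(
                arbor_id,
                times,
                trees,
                cfg.analysis.min_length_um,
                with_hull=cfg.analysis.with_hull,
            )
        )
    return series_list


def _stage_analyze(
    cfg: RunConfig,
    series_list: list[lg.ArborTimeSeries],
    out: Path,
    provenance: list[str],
) -> None:
    if (out / "summary.json").exists():
        log.info("analyze: summary present, skipping")
        return
    tol = cfg.analysis.tip_tolerance_um
    morpho = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    _write_csv(morpho, out / "morphometry.csv", provenance)

    rates, first_changes, obs_rows = [], [], []
    traces = []
    for s in series_list:
        events = lg.observed_events(s, tol)
        rates.append(lg.change_rate(s, events))
        first_changes.append(lg.time_to_first_change(s, events))
        obs_rows.extend(
            {
                "arbor_id": e.arbor_id,
                "t_start": e.t_start,
                "t_end": e.t_end,
                "gains": e.gains,
                "losses": e.losses,
            }
            for e in events
        )
        for ann in detect_swelling_onsets(s, tip_tolerance_um=tol):
            traces.append(
                lg.track_retraction(s, ann, cfg.analysis.stop_epsilon_um, tol)
            )
    _write_csv(pd.DataFrame(obs_rows), out / "events_observed.csv", provenance)

    trace_df = pd.DataFrame(
        {
            "arbor_id": t.arbor_id,
            "branch_id": t.branch_id,
            "onset_time_h": t.onset_time_h,
            "end_time_h": t.end_time_h,
            "total_retraction_um": t.total_retraction_um,
            "outcome": t.outcome,
        }
        for t in traces
    )
    _write_csv(trace_df, out / "retraction_traces.csv", provenance)

    duration_h = series_list[0].times_h[-1] - series_list[0].times_h[0]
    windows = duration_h / 24.0 / cfg.analysis.window_days
    n_retracted = int(sum(t.outcome == "retracted" for t in traces))
    observed_rate = n_retracted / len(series_list) / windows if windows > 0 else 0.0
    null_cmp = compare_observed_to_null(observed_rate, cfg.turnover)

    if traces:
        frac_ret, frac_not = lg.swelling_outcomes(traces)
    else:
        frac_ret = frac_not = float("nan")

    summary = {
        "provenance": {"config_hash": cfg.config_hash(), "seed": cfg.seed},
        "rate": {
            "per_arbor_events_per_h": rates,
            "median_events_per_h": float(np.median(rates)),
            "mean_events_per_h": float(np.mean(rates)),
            "sampling_interval_h": series_list[0].sampling_interval_h,
        },
        "time_to_first_change": {
            "per_arbor_h": first_changes,
            "all_changed_within_h": (
                max(c for c in first_changes if c is not None)
                if all(c is not None for c in first_changes)
                else None
            ),
        },
        "bulb_outcomes": {
            "n_swellings": len(traces),
            "fraction_retracted": frac_ret,
            "fraction_not_retracted": frac_not,
        },
        "null_comparison": json.loads(null_cmp.to_json()),
    }

    for interval in cfg.analysis.sampling_intervals_h:
        sub_rates = [
            lg.change_rate(lg.subsample_series(s, interval), tip_tolerance_um=tol)
            for s in series_list
        ]
        summary["rate"].setdefault("subsampled", {})[str(interval)] = {
            "median_events_per_h": float(np.median(sub_rates)),
            "mean_events_per_h": float(np.mean(sub_rates)),
        }

    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2)
    log.info("analyze: %d arbors, median rate %.4f events/h", len(series_list), np.median(rates))


def _stage_render_demo(cfg: RunConfig, out: Path, provenance: list[str]) -> None:
    """Render, filter and segment the first snapshot of the first arbor —
    exercises the imaging stages on one example without the cost of
    rendering the whole cohort."""
    tif = out / "arbor0_t000.tif"
    if tif.exists():
        return
    tree = read_swc(out / _swc_name(0, 0.0))
    stack = render_stack(tree, cfg.imaging, seed=cfg.seed)
    write_stack(stack, tif)
    response = tubularity_filter(stack, cfg.segmentation)
    labels = segment_arbor(response, cfg.segmentation)
    write_stack(labels, out / "arbor0_t000_labels.tif")
    _write_csv(component_table(labels), out / "arbor0_t000_components.csv", provenance)


def stats_report(df: pd.DataFrame, value_col: str = "value", group_col: str = "group"):
    """Gated group comparison on a tidy table (used by the CLI stats command)."""
    groups = [g[value_col].to_numpy() for _, g in df.groupby(group_col, sort=True)]
    return gated_group_comparison(groups)
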