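"""End-to-end runs: configuration loading, the two evaluation tracks, manifest.

A run executes the behavioral track (schedule generation → cohort simulation
→ RT analysis) and the timing track (bench simulation → device validation)
from one flat YAML config, writing every output CSV plus a manifest that
records the file list and the seeds used, so a run is reproducible
end to end from the config alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import analysis, behavior, bench, paradigm, sensors
from .profiles import DeviceProfile, bundled_profile, load_profile

logger = logging.getLogger("audiotactile")

__all__ = ["RunConfig", "load_run_config", "run_end_to_end", "resolve_profile"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run (all sections optional but seeded)."""

    profile: str = "pixel_2_xl"
    seed: int = 0
    out_dir: str = "results"
    n_blocks: int = 6
    bench_trials: int = 1000
    isi_range_ms: tuple[float, float] = (500.0, 1500.0)
    tap_delay_range_ms: tuple[float, float] = (1000.0, 2000.0)
    suitability_threshold_ms: float = bench.DEFAULT_SUITABILITY_THRESHOLD_MS
    cohort: dict = field(default_factory=dict)
    rt_bounds_ms: tuple[float, float] = analysis.DEFAULT_RT_BOUNDS_MS


def resolve_profile(name_or_path: str) -> DeviceProfile:
    """Interpret a profile reference as a file path, else a bundled name."""
    p = Path(name_or_path)
    if p.suffix in {".yaml", ".yml"} or p.exists():
        if not p.exists():
            raise FileNotFoundError(f"device profile file not found: {p}")
        return load_profile(p)
    return bundled_profile(name_or_path)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a run configuration from flat YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("isi_range_ms", "tap_delay_range_ms", "rt_bounds_ms"):
        if key in data:
            data[key] = tuple(float(v) for v in data[key])
    return RunConfig(**data)


def _write_timing_csv(path: Path, rows: dict[str, bench.TimingSummary], verdict) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["metric", "mean_delta_ms", "min_delta_ms", "max_delta_ms", "sd_delta_ms", "n"])
        for name, s in rows.items():
            writer.writerow([name, s.mean_delta_ms, s.min_delta_ms, s.max_delta_ms, s.sd_delta_ms, s.n])
        writer.writerow(
            ["verdict", "suitable" if verdict.suitable else "not_suitable",
             verdict.sync_precision_ms, verdict.rt_precision_ms, verdict.threshold_ms, ""]
        )


def run_end_to_end(config: RunConfig) -> dict:
    """Execute both tracks; return the manifest (also written to disk).

    Any stage failure raises RuntimeError naming the stage and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "profile": config.profile, "outputs": {}}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("gen-schedule")
        schedule = paradigm.generate_schedule(n_blocks=config.n_blocks, seed=config.seed)
        schedule_path = out / "schedule.csv"
        paradigm.write_session_csv(schedule_path, schedule)
        manifest["outputs"]["schedule"] = {"path": str(schedule_path), "seed": config.seed}
    except Exception as exc:
        raise RuntimeError(f"stage gen-schedule failed: {exc}") from exc

    try:
        stage("simulate-cohort")
        params = behavior.CohortParams(seed=config.seed + 1, **config.cohort)
        cohort_df = behavior.simulate_cohort(schedule, params)
        cohort_dir = out / "cohort"
        behavior.write_cohort_csvs(cohort_df, schedule, params, cohort_dir)
        manifest["outputs"]["cohort"] = {"path": str(cohort_dir), "seed": params.seed}
    except Exception as exc:
        raise RuntimeError(f"stage simulate-cohort failed: {exc}") from exc

    try:
        stage("analyze")
        result = analysis.analyze(cohort_df, rt_bounds_ms=config.rt_bounds_ms)
        summary_path = out / "condition_means.csv"
        result.summary.group_cells.merge(
            result.summary.facilitation_ms, left_on="delay_label", right_index=True
        ).to_csv(summary_path, index=False)
        anova_path = out / "anova.csv"
        result.anova.to_csv(anova_path, index=False)
        contrasts_path = out / "contrasts.csv"
        result.contrasts.to_csv(contrasts_path, index=False)
        manifest["outputs"]["analysis"] = {
            "paths": [str(summary_path), str(anova_path), str(contrasts_path)],
            "excluded": result.exclusion_report["excluded"],
            "removed_rt_pct": result.removed_rt_pct,
        }
    except Exception as exc:
        raise RuntimeError(f"stage analyze failed: {exc}") from exc

    try:
        stage("simulate-bench")
        profile = resolve_profile(config.profile)
        records = sensors.simulate_bench_session(
            profile,
            n_trials=config.bench_trials,
            isi_range_ms=config.isi_range_ms,
            tap_delay_range_ms=config.tap_delay_range_ms,
            seed=config.seed + 2,
        )
        bench_path = out / "bench.csv"
        sensors.write_bench_csv(records, bench_path)
        manifest["outputs"]["bench"] = {"path": str(bench_path), "seed": config.seed + 2}
    except Exception as exc:
        raise RuntimeError(f"stage simulate-bench failed: {exc}") from exc

    try:
        stage("validate-device")
        sync, rt = bench.bench_deltas(records)
        sync_summary = bench.timing_summary(sync)
        rt_summary = bench.timing_summary(rt)
        verdict = bench.classify_device(
            sync_summary.sd_delta_ms, rt_summary.sd_delta_ms, config.suitability_threshold_ms
        )
        timing_path = out / "timing_summary.csv"
        _write_timing_csv(timing_path, {"sync_AA": sync_summary, "rt_BB": rt_summary}, verdict)
        manifest["outputs"]["validation"] = {
            "path": str(timing_path),
            "suitable": verdict.suitable,
            "sync_precision_ms": verdict.sync_precision_ms,
            "rt_precision_ms": verdict.rt_precision_ms,
        }
    except Exception as exc:
        raise RuntimeError(f"stage validate-device failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = {"path": str(manifest_path)}
    return manifest
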