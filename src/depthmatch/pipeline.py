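"""Run configuration and the end-to-end pipeline: simulate/ingest -> fit -> predict -> analyze."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .analysis import segmented_slopes, signed_difference, summarize_matches
from .fitting import DEFAULT_BOUNDS, fit_panel, predict_panel, sigma_opacity_summary
from .io import (
    dump_json,
    fitted_to_dict,
    read_localizations,
    read_trials,
    validate_dataset,
    write_panel,
)
from .model import ABSENT, DistanceGrid
from .simulate import make_design, simulate_panel

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("depthmatch")


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    Either simulate a panel (default) or ingest existing CSVs by setting
    ``trials_csv``/``localizations_csv``.  All distances in meters.
    """

    experiment: str = "exp1"
    n_observers: int = 12
    seed: int = 0
    grid_min_m: float = 0.5
    grid_max_m: float = 2.5
    grid_step_m: float = 0.001
    n_localizations: int = 10
    fit_lower_m: float = DEFAULT_BOUNDS[0]
    fit_upper_m: float = DEFAULT_BOUNDS[1]
    objective: str = "means"
    out_dir: str = "results"
    log_level: str = "INFO"
    trials_csv: str | None = None
    localizations_csv: str | None = None

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def problems(self) -> list[str]:
        """All validation failures at once (empty list when valid)."""
        out = []
        if self.experiment not in ("exp1", "exp2"):
            out.append(f"experiment must be 'exp1' or 'exp2', got {self.experiment!r}")
        if self.n_observers < 1:
            out.append("n_observers must be >= 1")
        if not 0 < self.grid_min_m < self.grid_max_m:
            out.append("grid bounds must satisfy 0 < min < max")
        if not self.grid_step_m > 0:
            out.append("grid_step_m must be positive")
        if not 0 < self.fit_lower_m < self.fit_upper_m:
            out.append("fit bounds must satisfy 0 < lower < upper")
        if self.objective not in ("means", "trials"):
            out.append("objective must be 'means' or 'trials'")
        if self.n_localizations < 2:
            out.append("n_localizations must be >= 2")
        if (self.trials_csv is None) != (self.localizations_csv is None):
            out.append("trials_csv and localizations_csv must be given together")
        return out

    def grid(self) -> DistanceGrid:
        return DistanceGrid(self.grid_min_m, self.grid_max_m, self.grid_step_m)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest.

    Identical config and seed reproduce byte-identical numeric outputs.
    Stage failures abort with the stage name and cause.
    """
    problems = config.problems()
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.grid()
    files: dict[str, str] = {}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("simulate/ingest")
        if config.trials_csv is not None:
            trials = read_trials(config.trials_csv)
            locs = read_localizations(config.localizations_csv)
            report = validate_dataset(config.trials_csv, config.localizations_csv, grid)
            if not report.ok:
                raise ValueError("dataset failed validation: " + "; ".join(report.errors))
        else:
            panel = simulate_panel(
                n_observers=config.n_observers,
                design=make_design(config.experiment),
                seed=config.seed,
                grid=grid,
                n_localizations=config.n_localizations,
            )
            files.update(write_panel(panel, out))
            trials, locs = panel.trials, panel.localizations
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate/ingest' failed: {exc}") from exc

    try:
        stage("fit")
        fits = fit_panel(trials, locs, grid, (config.fit_lower_m, config.fit_upper_m), config.objective)
        files["fits"] = str(out / "fitted_observers.json")
        dump_json([fitted_to_dict(f) for f in fits], files["fits"])
        files["sigma_opacity_summary"] = str(out / "sigma_opacity_summary.csv")
        sigma_opacity_summary(fits).to_csv(files["sigma_opacity_summary"], index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    try:
        stage("predict")
        files["predictions"] = str(out / "predictions.csv")
        predict_panel(fits, grid).to_csv(files["predictions"], index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'predict' failed: {exc}") from exc

    try:
        stage("analyze")
        summaries = summarize_matches(trials)
        files["summaries"] = str(out / "summaries.csv")
        summaries.to_csv(files["summaries"], index=False)
        files["slopes"] = str(out / "slopes.csv")
        segmented_slopes(trials).to_csv(files["slopes"], index=False)
        if ABSENT in set(summaries["condition"]):
            files["differences"] = str(out / "differences.csv")
            signed_difference(summaries).to_csv(files["differences"], index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'analyze' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "files": dict(sorted(files.items())),
    }
    manifest_path = out / "manifest.json"
    dump_json(manifest, manifest_path)
    files["manifest"] = str(manifest_path)
    return manifest
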