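"""Dataset and parameter serialization plus schema validation.

All files are plain text: comma-separated UTF-8 CSV with a header row and
"." decimals for trial and localization tables, pretty-printed JSON with
sorted keys for parameters and manifests.  Every distance is in meters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import ABSENT, CONDITIONS, DisparityCue, DistanceGrid, SurfaceCondition, VisibilityParams
from .fitting import FittedObserver
from .simulate import (
    LOCALIZATION_COLUMNS,
    TRIAL_COLUMNS,
    ObserverParams,
    PanelData,
    distance_key,
)

__all__ = [
    "read_trials",
    "write_trials",
    "read_localizations",
    "write_localizations",
    "params_to_dict",
    "params_from_dict",
    "fitted_to_dict",
    "fitted_from_dict",
    "write_panel",
    "ValidationReport",
    "validate_dataset",
]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so write -> read -> write is bit-identical
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials file {path} is missing columns {sorted(missing)}")
    return df[TRIAL_COLUMNS]


def write_localizations(localizations: pd.DataFrame, path: str | Path) -> None:
    localizations.to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(LOCALIZATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"localizations file {path} is missing columns {sorted(missing)}")
    return df[LOCALIZATION_COLUMNS]


def _surface_to_dict(cond: SurfaceCondition) -> dict:
    return {
        "label": cond.label,
        "mu_surf_m": cond.mu_surf,
        "sigma_surf_m": cond.sigma_surf,
        "contrast": cond.contrast,
    }


def _surface_from_dict(d: dict) -> SurfaceCondition:
    return SurfaceCondition(
        label=d["label"],
        mu_surf=d.get("mu_surf_m"),
        sigma_surf=d.get("sigma_surf_m"),
        contrast=d.get("contrast"),
    )


def params_to_dict(params: ObserverParams) -> dict:
    """JSON-ready representation of generative observer parameters."""
    return {
        "observer_id": params.observer_id,
        "sigma_resp_m": params.sigma_resp,
        "disparity_by_distance": {
            f"{d:g}": {"mu_disp_m": c.mu_disp, "sigma_disp_m": c.sigma_disp}
            for d, c in sorted(params.disparity_by_distance.items())
        },
        "surface_by_condition": {
            label: _surface_to_dict(c) for label, c in sorted(params.surface_by_condition.items())
        },
        "sigma_opacity_by_condition": {
            label: vp.sigma_opacity
            for label, vp in sorted(params.sigma_opacity_by_condition.items())
        },
    }


def params_from_dict(d: dict) -> ObserverParams:
    return ObserverParams(
        observer_id=d["observer_id"],
        disparity_by_distance={
            distance_key(float(k)): DisparityCue(v["mu_disp_m"], v["sigma_disp_m"])
            for k, v in d["disparity_by_distance"].items()
        },
        surface_by_condition={
            label: _surface_from_dict(v) for label, v in d["surface_by_condition"].items()
        },
        sigma_opacity_by_condition={
            label: VisibilityParams(v) for label, v in d["sigma_opacity_by_condition"].items()
        },
        sigma_resp=d["sigma_resp_m"],
    )


def fitted_to_dict(fo: FittedObserver) -> dict:
    return {
        "observer_id": fo.observer_id,
        "disparity_by_distance": {
            f"{d:g}": {"mu_disp_m": c.mu_disp, "sigma_disp_m": c.sigma_disp}
            for d, c in sorted(fo.disparity_by_distance.items())
        },
        "surface_by_condition": {
            label: _surface_to_dict(c) for label, c in sorted(fo.surface_by_condition.items())
        },
        "sigma_opacity_by_condition": {
            label: vp.sigma_opacity for label, vp in sorted(fo.sigma_opacity_by_condition.items())
        },
        "fit_quality": dict(sorted(fo.fit_quality.items())),
        "pinned_by_condition": dict(sorted(fo.pinned_by_condition.items())),
    }


def fitted_from_dict(d: dict) -> FittedObserver:
    return FittedObserver(
        observer_id=d["observer_id"],
        disparity_by_distance={
            distance_key(float(k)): DisparityCue(v["mu_disp_m"], v["sigma_disp_m"])
            for k, v in d["disparity_by_distance"].items()
        },
        surface_by_condition={
            label: _surface_from_dict(v) for label, v in d["surface_by_condition"].items()
        },
        sigma_opacity_by_condition={
            label: VisibilityParams(v) for label, v in d["sigma_opacity_by_condition"].items()
        },
        fit_quality=d.get("fit_quality", {}),
        pinned_by_condition=d.get("pinned_by_condition", {}),
    )


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def write_panel(panel: PanelData, out_dir: str | Path) -> dict[str, str]:
    """Write a simulated panel (trials, localizations, ground-truth sidecar).

    Returns a mapping of artifact names to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "trials": str(out / "trials.csv"),
        "localizations": str(out / "localizations.csv"),
        "true_params": str(out / "true_params.json"),
    }
    write_trials(panel.trials, files["trials"])
    write_localizations(panel.localizations, files["localizations"])
    sidecar = {
        "design": {
            "name": panel.design.name,
            "target_distances_m": list(panel.design.target_distances),
            "trials_per_distance": panel.design.trials_per_distance,
            "surface_conditions": list(panel.design.surface_conditions),
            "size_mode": panel.design.size_mode,
            "surface_distance_m": panel.design.surface_distance,
        },
        "seed": panel.seed,
        "seed_offsets": panel.seed_offsets,
        "observers": [params_to_dict(p) for p in panel.params],
    }
    dump_json(sidecar, files["true_params"])
    return files


@dataclass
class ValidationReport:
    """Outcome of dataset schema and referential checks."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    cell_counts: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_dataset(
    trials_path: str | Path,
    localizations_path: str | Path,
    grid: DistanceGrid | None = None,
) -> ValidationReport:
    """Validate a trials CSV plus localizations CSV.

    Checks columns, value ranges against the grid, condition labels,
    duplicated trial keys, and that every present-surface condition with
    trials also has localization records for that observer.  All problems
    are accumulated and reported together.
    """
    grid = grid or DistanceGrid()
    report = ValidationReport()
    try:
        trials = read_trials(trials_path)
    except Exception as exc:
        report.errors.append(f"trials: {exc}")
        return report
    try:
        locs = read_localizations(localizations_path)
    except Exception as exc:
        report.errors.append(f"localizations: {exc}")
        return report

    unknown = sorted(set(trials["condition"]) - set(CONDITIONS))
    if unknown:
        report.errors.append(f"unknown surface conditions in trials: {unknown}")
    for col in ("target_distance_m", "matched_distance_m"):
        vals = pd.to_numeric(trials[col], errors="coerce")
        if vals.isna().any():
            report.errors.append(f"non-numeric values in column {col!r}")
            continue
        out_of_range = trials.loc[(vals < grid.min_m) | (vals > grid.max_m), col]
        if not out_of_range.empty:
            report.errors.append(
                f"{len(out_of_range)} value(s) in {col!r} outside grid bounds "
                f"[{grid.min_m}, {grid.max_m}] m: first offender {out_of_range.iloc[0]}"
            )
    dup_keys = ["observer_id", "condition", "target_distance_m", "trial_index"]
    dups = trials.duplicated(subset=dup_keys)
    if dups.any():
        report.errors.append(f"{int(dups.sum())} duplicated (observer, condition, distance, trial_index) row(s)")

    loc_pairs = set(zip(locs["observer_id"], locs["condition"]))
    present = trials[trials["condition"] != ABSENT]
    for oid, cond in sorted(set(zip(present["observer_id"], present["condition"]))):
        if (oid, cond) not in loc_pairs:
            report.errors.append(
                f"observer {oid!r} has {cond!r} trials but no surface localizations for it"
            )
    vals = pd.to_numeric(locs["localized_distance_m"], errors="coerce")
    if vals.isna().any():
        report.errors.append("non-numeric values in 'localized_distance_m'")
    elif ((vals < grid.min_m) | (vals > grid.max_m)).any():
        report.errors.append("localized distances outside grid bounds")

    report.cell_counts = (
        trials.groupby(["observer_id", "condition", "target_distance_m"])
        .size()
        .rename("n_trials")
        .reset_index()
    )
    return report
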