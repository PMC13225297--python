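"""Synthetic observers for the depth-matching experiments.

Generates trial-level datasets with the statistical structure the observer
model assumes: Gaussian perceived-surface localization per opacity, a
per-distance Gaussian disparity likelihood, posterior-mode responding, and
trial-level response noise.  Two designs are provided: the constant-visual-
angle experiment (four surface conditions, 12 observers) and the constant-
physical-size experiment (three conditions).

Noise model.  In surface-present conditions each match is the posterior-mode
prediction plus Gaussian response noise of SD ``sigma_resp``.  In the
surface-absent baseline the match SD *defines* the disparity-likelihood SD
(that is how sigma_disp is estimated from data), so absent-condition matches
are drawn as N(mu_disp, sigma_disp); this keeps generation and fitting
self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    ABSENT,
    DEFAULT_GRID,
    DisparityCue,
    DistanceGrid,
    PRESENT_CONDITIONS,
    SurfaceCondition,
    VisibilityParams,
    predict_matches,
)

__all__ = [
    "ExperimentDesign",
    "ObserverParams",
    "TrialRecord",
    "PanelData",
    "EXPERIMENTS",
    "MICHELSON_CONTRAST",
    "DEFAULT_SIGMA_OPACITY",
    "make_design",
    "default_observer",
    "simulate_trials",
    "simulate_surface_localizations",
    "simulate_panel",
    "distance_key",
]

TRIAL_COLUMNS = [
    "observer_id",
    "experiment",
    "condition",
    "size_mode",
    "target_distance_m",
    "matched_distance_m",
    "trial_index",
]
LOCALIZATION_COLUMNS = ["observer_id", "condition", "localized_distance_m", "trial_index"]

#: Measured Michelson contrast of the background seen through each surface state.
MICHELSON_CONTRAST = {
    "opaque": 0.001,
    "semi_transparent": 0.62,
    "highly_transparent": 0.77,
    "absent": 0.98,
}

#: Default occlusion-prior fall-off SD (m) per opacity: stronger occlusion,
#: steeper fall-off.
DEFAULT_SIGMA_OPACITY = {
    "opaque": 0.08,
    "semi_transparent": 0.10,
    "highly_transparent": 0.25,
}


def distance_key(d: float) -> float:
    """Canonical float key for a target distance (guards against FP drift)."""
    return round(float(d), 6)


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of one depth-matching experiment."""

    name: str
    target_distances: tuple[float, ...]
    trials_per_distance: int
    surface_conditions: tuple[str, ...]
    size_mode: str
    surface_distance: float

    def __post_init__(self) -> None:
        d = self.target_distances
        if len(d) < 2 or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("target_distances must be strictly increasing with at least 2 entries")
        if self.trials_per_distance < 1:
            raise ValueError("trials_per_distance must be at least 1")
        if self.size_mode not in ("constant_angle", "constant_physical"):
            raise ValueError("size_mode must be 'constant_angle' or 'constant_physical'")
        if len(set(self.surface_conditions)) != len(self.surface_conditions):
            raise ValueError("surface_conditions must be unique")

    @property
    def present_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.surface_conditions if c != ABSENT)


_EXP1_DISTANCES = tuple(round(0.9 + 0.1 * i, 1) for i in range(8))

EXPERIMENTS = {
    "exp1": ExperimentDesign(
        name="exp1",
        target_distances=_EXP1_DISTANCES,
        trials_per_distance=10,
        surface_conditions=PRESENT_CONDITIONS + (ABSENT,),
        size_mode="constant_angle",
        surface_distance=1.2,
    ),
    "exp2": ExperimentDesign(
        name="exp2",
        target_distances=_EXP1_DISTANCES,
        trials_per_distance=10,
        surface_conditions=("opaque", "highly_transparent", ABSENT),
        size_mode="constant_physical",
        surface_distance=1.2,
    ),
}


def make_design(experiment: str = "exp1", **overrides) -> ExperimentDesign:
    """Return a named experimental design, optionally with fields overridden."""
    try:
        design = EXPERIMENTS[experiment]
    except KeyError:
        raise ValueError(f"unknown experiment {experiment!r}; expected one of {sorted(EXPERIMENTS)}") from None
    return replace(design, **overrides) if overrides else design


@dataclass(frozen=True)
class ObserverParams:
    """Generative (or fitted) parameters of one synthetic observer."""

    observer_id: str
    disparity_by_distance: dict[float, DisparityCue]
    surface_by_condition: dict[str, SurfaceCondition]
    sigma_opacity_by_condition: dict[str, VisibilityParams]
    sigma_resp: float = 0.03

    def __post_init__(self) -> None:
        if self.sigma_resp < 0:
            raise ValueError("sigma_resp must be nonnegative")


@dataclass(frozen=True)
class TrialRecord:
    """One depth-matching trial."""

    observer_id: str
    experiment: str
    condition: str
    size_mode: str
    target_distance_m: float
    matched_distance_m: float
    trial_index: int


@dataclass
class PanelData:
    """A simulated multi-observer dataset plus its generative ground truth."""

    trials: pd.DataFrame
    localizations: pd.DataFrame
    params: list[ObserverParams]
    design: ExperimentDesign
    seed: int
    seed_offsets: dict[str, int] = field(default_factory=dict)


def default_observer(
    observer_id: str,
    seed: int,
    design: ExperimentDesign | None = None,
    *,
    sigma_disp_range: tuple[float, float] = (0.02, 0.10),
    sigma_surf_range: tuple[float, float] = (0.01, 0.05),
    sigma_opacity: dict[str, float] | None = None,
    sigma_resp: float = 0.03,
) -> ObserverParams:
    """Sample a plausible observer for ``design``.

    Per-distance disparity SDs are log-uniform in ``sigma_disp_range`` and
    sorted so uncertainty grows with distance (disparity precision falls off
    with viewing distance); disparity means are veridical.  Surface
    localization SDs are uniform per condition; the occlusion fall-off SDs
    default to :data:`DEFAULT_SIGMA_OPACITY`.
    """
    design = design or make_design("exp1")
    rng = np.random.default_rng(seed)
    lo, hi = sigma_disp_range
    sig_d = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), len(design.target_distances))))
    disparity = {
        distance_key(d): DisparityCue(mu_disp=float(d), sigma_disp=float(s))
        for d, s in zip(design.target_distances, sig_d)
    }
    sigma_opacity = dict(DEFAULT_SIGMA_OPACITY if sigma_opacity is None else sigma_opacity)
    surface: dict[str, SurfaceCondition] = {}
    visibility: dict[str, VisibilityParams] = {}
    for label in design.present_conditions:
        surface[label] = SurfaceCondition(
            label=label,
            mu_surf=design.surface_distance,
            sigma_surf=float(rng.uniform(*sigma_surf_range)),
            contrast=MICHELSON_CONTRAST.get(label),
        )
        visibility[label] = VisibilityParams(sigma_opacity[label])
    return ObserverParams(
        observer_id=observer_id,
        disparity_by_distance=disparity,
        surface_by_condition=surface,
        sigma_opacity_by_condition=visibility,
        sigma_resp=sigma_resp,
    )


def simulate_trials(
    params: ObserverParams,
    design: ExperimentDesign,
    grid: DistanceGrid = DEFAULT_GRID,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate every trial of ``design`` for one observer.

    Surface-present matches are posterior-mode predictions plus response
    noise; absent matches are draws from the disparity likelihood (see the
    module docstring for why).  Matches are clipped to the grid bounds.
    """
    rng = np.random.default_rng(seed)
    missing = [
        c for c in design.surface_conditions if c != ABSENT and c not in params.surface_by_condition
    ]
    missing += [
        d for d in design.target_distances if distance_key(d) not in params.disparity_by_distance
    ]
    if missing:
        raise ValueError(f"observer {params.observer_id} lacks parameters for {missing}")

    rows = []
    n = design.trials_per_distance
    for label in design.surface_conditions:
        cues = {distance_key(d): params.disparity_by_distance[distance_key(d)] for d in design.target_distances}
        if label == ABSENT:
            centers = {d: c.mu_disp for d, c in cues.items()}
            scales = {d: c.sigma_disp for d, c in cues.items()}
        else:
            centers = predict_matches(
                cues, params.surface_by_condition[label], params.sigma_opacity_by_condition[label], grid
            )
            scales = {d: params.sigma_resp for d in cues}
        for d in design.target_distances:
            k = distance_key(d)
            matched = centers[k] + rng.normal(0.0, 1.0, n) * scales[k]
            matched = np.clip(matched, grid.min_m, grid.max_m)
            for i, m in enumerate(matched):
                rows.append(
                    (params.observer_id, design.name, label, design.size_mode, float(d), float(m), i)
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_surface_localizations(
    params: ObserverParams,
    n_trials: int = 10,
    seed: int = 0,
    grid: DistanceGrid = DEFAULT_GRID,
) -> pd.DataFrame:
    """Simulate probe localizations of the surface, per present condition.

    Draws from each condition's perceived-surface Gaussian, clipped to grid
    bounds.  The absent condition yields no records.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be at least 2 to estimate a localization SD")
    rng = np.random.default_rng(seed)
    rows = []
    for label, cond in params.surface_by_condition.items():
        draws = np.clip(
            rng.normal(cond.mu_surf, cond.sigma_surf, n_trials), grid.min_m, grid.max_m
        )
        rows.extend((params.observer_id, label, float(v), i) for i, v in enumerate(draws))
    return pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)


# Fixed integer offsets deriving per-observer child seeds from the master
# seed; recorded in PanelData.seed_offsets for reproducibility.
_OBSERVER_STRIDE = 1000
_PARAMS_OFFSET, _TRIALS_OFFSET, _LOC_OFFSET = 1, 2, 3


def simulate_panel(
    n_observers: int = 12,
    design: ExperimentDesign | None = None,
    seed: int = 0,
    grid: DistanceGrid = DEFAULT_GRID,
    n_localizations: int = 10,
    **observer_kwargs,
) -> PanelData:
    """Simulate a full panel of independent observers.

    Each observer gets deterministic child seeds ``seed + 1000*(i+1) + k``
    for parameter sampling, trial generation, and localizations, so panels
    are reproducible and observers independent.
    """
    if n_observers < 1:
        raise ValueError("n_observers must be at least 1")
    design = design or make_design("exp1")
    params: list[ObserverParams] = []
    trial_frames, loc_frames = [], []
    offsets: dict[str, int] = {}
    for i in range(n_observers):
        base = seed + _OBSERVER_STRIDE * (i + 1)
        oid = f"obs{i + 1:02d}"
        offsets[oid] = base
        p = default_observer(oid, seed=base + _PARAMS_OFFSET, design=design, **observer_kwargs)
        params.append(p)
        trial_frames.append(simulate_trials(p, design, grid, seed=base + _TRIALS_OFFSET))
        loc_frames.append(
            simulate_surface_localizations(p, n_localizations, seed=base + _LOC_OFFSET, grid=grid)
        )
    return PanelData(
        trials=pd.concat(trial_frames, ignore_index=True),
        localizations=pd.concat(loc_frames, ignore_index=True),
        params=params,
        design=design,
        seed=seed,
        seed_offsets=offsets,
    )
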