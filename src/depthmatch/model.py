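"""Bayesian observer core for occlusion-disparity cue integration.

Perceived target distance is modelled as the mode of a posterior over a
discretized distance axis.  The likelihood is a Gaussian in metric distance
supplied by binocular disparity; the prior encodes the ordinal occlusion
constraint: a target that remains visible is expected to lie in front of an
occluding surface, so the prior is flat up to the perceived surface location
and falls off as a (renormalized) Gaussian beyond it.  Uncertainty about
where the surface itself is perceived enters as a mixture over surface
positions.

All densities live on a :class:`DistanceGrid`; distances are in meters.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.stats import norm

__all__ = [
    "ABSENT",
    "PRESENT_CONDITIONS",
    "CONDITIONS",
    "DistanceGrid",
    "GridDensity",
    "SurfaceCondition",
    "VisibilityParams",
    "DisparityCue",
    "DEFAULT_GRID",
    "gaussian_density",
    "perceived_surface_density",
    "visibility_function",
    "build_occlusion_prior",
    "flat_prior",
    "disparity_likelihood",
    "posterior",
    "predict_match",
    "predict_matches",
]

#: Surface-present opacity labels, ordered from strongest to weakest occlusion.
PRESENT_CONDITIONS = ("opaque", "semi_transparent", "highly_transparent")
#: Baseline condition with no occluding surface (flat-prior semantics).
ABSENT = "absent"
CONDITIONS = PRESENT_CONDITIONS + (ABSENT,)


@dataclass(frozen=True)
class DistanceGrid:
    """Uniform discretization of the distance axis (meters).

    The default grid spans 0.5-2.5 m at 1 mm resolution so that all
    experimental target distances (0.9-1.6 m) and the tails of every
    density involved are interior.
    """

    min_m: float = 0.5
    max_m: float = 2.5
    step_m: float = 0.001

    def __post_init__(self) -> None:
        if not self.min_m > 0:
            raise ValueError("grid must start at a strictly positive distance")
        if not self.max_m > self.min_m:
            raise ValueError("grid max_m must exceed min_m")
        if not self.step_m > 0:
            raise ValueError("grid step_m must be positive")
        n = (self.max_m - self.min_m) / self.step_m
        if abs(n - round(n)) > 1e-9 * max(n, 1.0):
            raise ValueError("grid span must be an integer multiple of step_m")

    @property
    def n_points(self) -> int:
        return int(round((self.max_m - self.min_m) / self.step_m)) + 1

    @cached_property
    def values(self) -> np.ndarray:
        """Grid points as a read-only float array."""
        v = np.linspace(self.min_m, self.max_m, self.n_points)
        v.setflags(write=False)
        return v

    def contains(self, x: float) -> bool:
        return self.min_m <= x <= self.max_m

    def nearest(self, x: float) -> float:
        """Grid point closest to ``x``; ties resolve to the smaller distance."""
        v = self.values
        return float(v[int(np.argmin(np.abs(v - x)))])


@dataclass
class GridDensity:
    """Nonnegative values on a :class:`DistanceGrid`.

    ``normalized`` densities sum to one over grid points (probability mass
    per grid point, not per meter).
    """

    grid: DistanceGrid
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.grid.n_points,):
            raise ValueError(
                f"density has {vals.shape} values for a grid of {self.grid.n_points} points"
            )
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("density values must be finite and nonnegative")
        if self.normalized and abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("normalized density must sum to 1 within 1e-9")
        self.values = vals

    def normalize(self) -> "GridDensity":
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an identically-zero density")
        return GridDensity(self.grid, self.values / total, normalized=True)

    def mode(self) -> float:
        """Grid point of the first maximum (ties break toward smaller distance)."""
        return float(self.grid.values[int(np.argmax(self.values))])


@dataclass(frozen=True)
class SurfaceCondition:
    """An opacity condition with its perceived-surface location model.

    For present surfaces, the perceived surface location is Gaussian with
    mean ``mu_surf`` and SD ``sigma_surf`` (both meters).  ``contrast`` is
    the optional Michelson contrast of the background seen through the
    surface; it is metadata and does not enter the model directly.
    """

    label: str
    mu_surf: float | None = None
    sigma_surf: float | None = None
    contrast: float | None = None

    def __post_init__(self) -> None:
        if self.label not in CONDITIONS:
            raise ValueError(f"unknown surface condition {self.label!r}; expected one of {CONDITIONS}")
        if self.label != ABSENT:
            if self.mu_surf is None or self.sigma_surf is None:
                raise ValueError(f"present surface {self.label!r} requires mu_surf and sigma_surf")
            if not self.sigma_surf > 0:
                raise ValueError("sigma_surf must be strictly positive")
        if self.contrast is not None and not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")

    @property
    def is_absent(self) -> bool:
        return self.label == ABSENT


@dataclass(frozen=True)
class VisibilityParams:
    """Fall-off scale of the occlusion prior beyond the surface.

    ``sigma_opacity`` (meters) is the free parameter of the visibility
    function: small values give a near-step prior (strong occlusion
    constraint), large values a shallow fall-off (weak constraint, as for
    a highly transparent surface).
    """

    sigma_opacity: float

    def __post_init__(self) -> None:
        if not self.sigma_opacity > 0:
            raise ValueError("sigma_opacity must be strictly positive")


@dataclass(frozen=True)
class DisparityCue:
    """Gaussian disparity likelihood parameters for one target distance."""

    mu_disp: float
    sigma_disp: float

    def __post_init__(self) -> None:
        if not self.sigma_disp > 0:
            raise ValueError("sigma_disp must be strictly positive")


DEFAULT_GRID = DistanceGrid()


def gaussian_density(x, mu: float, sigma: float):
    """Normal density N(x; mu, sigma) per meter.

    Accepts scalar or array ``x``.
    """
    if not sigma > 0:
        raise ValueError("sigma must be strictly positive")
    return norm.pdf(x, loc=mu, scale=sigma)


def perceived_surface_density(cond: SurfaceCondition, grid: DistanceGrid = DEFAULT_GRID) -> GridDensity:
    """Distribution of the perceived surface location on the grid (normalized).

    Raises for the surface-absent condition: no surface exists to localize,
    and callers should use :func:`flat_prior` instead.
    """
    if cond.is_absent:
        raise ValueError("no perceived-surface density for the absent condition; use flat_prior")
    vals = gaussian_density(grid.values, cond.mu_surf, cond.sigma_surf)
    return GridDensity(grid, vals).normalize()


def visibility_function(x, x_surf: float, vp: VisibilityParams):
    """Probability that the target is visible at distance ``x`` given a surface at ``x_surf``.

    Equal to 1 for x <= x_surf; beyond the surface it is a Gaussian fall-off
    renormalized to peak at 1 at the surface:
    exp(-(x - x_surf)^2 / (2 sigma_opacity^2)).
    """
    x = np.asarray(x, dtype=float)
    behind = np.maximum(x - x_surf, 0.0)
    out = np.exp(-0.5 * (behind / vp.sigma_opacity) ** 2)
    return out if out.ndim else float(out)


# Relative weight below which surface positions are dropped from the mixture.
# At 1e-14 of the peak the truncation error is far below every tolerance used.
_SURFACE_WEIGHT_TOL = 1e-14


def build_occlusion_prior(
    cond: SurfaceCondition, vp: VisibilityParams, grid: DistanceGrid = DEFAULT_GRID
) -> GridDensity:
    """Occlusion prior: visibility mixed over the perceived surface location.

    prior(x) = sum_s P(surface perceived at s) * visibility(x | s), with the
    surface distribution sum-normalized over grid points.  The result is left
    unnormalized (values in (0, 1], equal to 1 far in front of the surface);
    the posterior mode is invariant to prior scaling.
    """
    if cond.is_absent:
        raise ValueError("absent condition has no occlusion prior; use flat_prior")
    x = grid.values
    w = perceived_surface_density(cond, grid).values
    keep = w >= w.max() * _SURFACE_WEIGHT_TOL
    s = x[keep]
    wk = w[keep]
    wk = wk / wk.sum()
    behind = np.maximum(x[:, None] - s[None, :], 0.0)
    vals = np.exp(-0.5 * (behind / vp.sigma_opacity) ** 2) @ wk
    return GridDensity(grid, vals)


def flat_prior(grid: DistanceGrid = DEFAULT_GRID) -> GridDensity:
    """Uninformative prior of ones, used for the surface-absent condition."""
    return GridDensity(grid, np.ones(grid.n_points))


def disparity_likelihood(cue: DisparityCue, grid: DistanceGrid = DEFAULT_GRID) -> GridDensity:
    """Gaussian disparity likelihood evaluated on the grid (unnormalized)."""
    return GridDensity(grid, gaussian_density(grid.values, cue.mu_disp, cue.sigma_disp))


def posterior(likelihood: GridDensity, prior: GridDensity) -> GridDensity:
    """Pointwise product of likelihood and prior, sum-normalized."""
    if likelihood.grid != prior.grid:
        raise ValueError("likelihood and prior must live on the same grid")
    product = likelihood.values * prior.values
    if product.max() <= 0:
        raise ValueError("posterior is identically zero: likelihood and prior do not overlap")
    return GridDensity(likelihood.grid, product).normalize()


def predict_match(
    cue: DisparityCue,
    cond: SurfaceCondition,
    vp: VisibilityParams | None = None,
    grid: DistanceGrid = DEFAULT_GRID,
) -> float:
    """Predicted depth match (meters): the posterior mode on the grid.

    For the surface-absent condition the prior is flat, so the prediction is
    the grid point nearest ``mu_disp``.  Ties break toward the smaller
    distance.
    """
    if cond.is_absent:
        return grid.nearest(cue.mu_disp)
    if vp is None:
        raise ValueError("visibility parameters are required for present-surface conditions")
    prior = build_occlusion_prior(cond, vp, grid)
    return posterior(disparity_likelihood(cue, grid), prior).mode()


def predict_matches(
    cues: dict[float, DisparityCue],
    cond: SurfaceCondition,
    vp: VisibilityParams | None = None,
    grid: DistanceGrid = DEFAULT_GRID,
) -> dict[float, float]:
    """Posterior-mode predictions for many target distances of one condition.

    Builds the occlusion prior once and reuses it across distances, which is
    the inner loop of fitting and simulation.
    """
    if cond.is_absent:
        return {d: grid.nearest(c.mu_disp) for d, c in cues.items()}
    if vp is None:
        raise ValueError("visibility parameters are required for present-surface conditions")
    x = grid.values
    prior = build_occlusion_prior(cond, vp, grid).values
    out: dict[float, float] = {}
    for d, cue in cues.items():
        post = gaussian_density(x, cue.mu_disp, cue.sigma_disp) * prior
        if post.max() <= 0:
            raise ValueError(f"posterior identically zero at target distance {d}")
        out[d] = float(x[int(np.argmax(post))])
    return out
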