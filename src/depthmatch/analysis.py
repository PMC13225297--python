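"""Descriptive analyses of depth-matching data.

Condition x distance summaries with within-subject confidence intervals
(Cousineau normalization with the Morey cell-count correction), signed
differences against the surface-absent baseline, and segmented linear
regressions for distances in front of vs. behind the surface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model import ABSENT

__all__ = [
    "summarize_matches",
    "within_subject_ci",
    "segmented_slopes",
    "signed_difference",
]


def within_subject_ci(per_subject_means: pd.DataFrame, level: float = 0.95) -> pd.Series:
    """Within-subject CI half-widths per cell of a subjects x cells table.

    Each subject's scores are first normalized by subtracting the subject's
    own mean and adding the grand mean, which removes between-subject
    variance; the per-cell SDs of the normalized scores are then inflated by
    the Morey factor sqrt(C/(C-1)) for C cells, and half-widths are
    t(level, n-1) * SD / sqrt(n).  Subject-specific constant shifts leave
    the result unchanged.
    """
    arr = per_subject_means.to_numpy(dtype=float)
    n, c = arr.shape
    if n < 2:
        raise ValueError("within-subject CIs require at least 2 subjects")
    if c < 2:
        raise ValueError("within-subject CIs require at least 2 cells")
    if np.isnan(arr).any():
        raise ValueError("per-subject table is incomplete; no imputation is performed")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    normalized = arr - arr.mean(axis=1, keepdims=True) + arr.mean()
    sd = normalized.std(axis=0, ddof=1) * np.sqrt(c / (c - 1))
    half = stats.t.ppf((1 + level) / 2, n - 1) * sd / np.sqrt(n)
    return pd.Series(half, index=per_subject_means.columns, name="ci_halfwidth")


def _per_observer_cells(trials: pd.DataFrame) -> pd.DataFrame:
    g = trials.groupby(["condition", "target_distance_m", "observer_id"])["matched_distance_m"]
    return g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()


def summarize_matches(trials: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Condition x distance summary of matched distances.

    Means are across-observer means of per-observer cell means; SDs pool the
    per-observer cell SDs (square root of the df-weighted mean variance).
    CI half-widths are within-subject (Cousineau-Morey) across the full
    condition x distance cell layout and require a complete table with at
    least two observers; otherwise they are NaN.
    """
    if trials.empty:
        raise ValueError("no trials to summarize")
    cells = _per_observer_cells(trials)

    def pooled_sd(grp: pd.DataFrame) -> float:
        dof = grp["n"] - 1
        if dof.sum() <= 0:
            return float("nan")
        return float(np.sqrt((dof * grp["sd"] ** 2).sum() / dof.sum()))

    rows = []
    for (cond, d), grp in cells.groupby(["condition", "target_distance_m"]):
        rows.append((cond, d, grp["mean"].mean(), pooled_sd(grp), int(grp["n"].sum())))
    out = pd.DataFrame(
        rows,
        columns=["condition", "target_distance_m", "mean_matched_m", "sd_matched_m", "n_trials"],
    )

    table = cells.pivot(index="observer_id", columns=["condition", "target_distance_m"], values="mean")
    if table.shape[0] >= 2 and table.shape[1] >= 2 and not table.isna().any().any():
        half = within_subject_ci(table, ci_level)
        out["ci_halfwidth_m"] = [
            float(half[(cond, d)]) for cond, d in zip(out["condition"], out["target_distance_m"])
        ]
    else:
        out["ci_halfwidth_m"] = np.nan
    return out.sort_values(["condition", "target_distance_m"], ignore_index=True)


def _fit_segment(df: pd.DataFrame, condition: str, segment: str) -> tuple[float, float]:
    if df["target_distance_m"].nunique() < 2:
        raise ValueError(
            f"condition {condition!r}: fewer than 2 distinct distances in the {segment} segment"
        )
    res = stats.linregress(df["target_distance_m"], df["matched_distance_m"])
    return float(res.slope), float(res.intercept)


def segmented_slopes(
    trials: pd.DataFrame, split_at: float = 1.2, per_observer: bool = False
) -> pd.DataFrame:
    """OLS slopes of matched vs. target distance, in front of vs. behind the surface.

    The front segment includes distances <= ``split_at`` (the surface sits
    at the boundary of the front segment).  By default slopes are fit to
    per-distance mean matches pooled over observers; with
    ``per_observer=True`` they are fit per observer and averaged.
    """
    rows = []
    for cond, cgrp in trials.groupby("condition"):
        units = list(cgrp.groupby("observer_id")) if per_observer else [(None, cgrp)]
        fits = []
        for _, ugrp in units:
            means = (
                ugrp.groupby("target_distance_m")["matched_distance_m"].mean().reset_index()
            )
            front = means[means["target_distance_m"] <= split_at]
            behind = means[means["target_distance_m"] > split_at]
            sf, inf = _fit_segment(front, str(cond), "front")
            sb, inb = _fit_segment(behind, str(cond), "behind")
            fits.append((sf, inf, sb, inb))
        arr = np.array(fits).mean(axis=0)
        rows.append((cond, *arr))
    return pd.DataFrame(
        rows,
        columns=["condition", "slope_front", "intercept_front", "slope_behind", "intercept_behind"],
    ).sort_values("condition", ignore_index=True)


def signed_difference(summaries: pd.DataFrame, reference: str = ABSENT) -> pd.DataFrame:
    """Reference-minus-condition mean match per distance (positive = underestimation
    relative to the reference).

    ``summaries`` is the output of :func:`summarize_matches`.  The reference
    condition must be present at every distance where any other condition
    has data.
    """
    ref = summaries[summaries["condition"] == reference].set_index("target_distance_m")[
        "mean_matched_m"
    ]
    if ref.empty:
        raise ValueError(f"reference condition {reference!r} not found in summaries")
    rows = []
    for cond, grp in summaries[summaries["condition"] != reference].groupby("condition"):
        for _, r in grp.iterrows():
            d = r["target_distance_m"]
            if d not in ref.index:
                raise ValueError(f"reference condition lacks a cell at {d} m")
            rows.append((cond, d, float(ref[d] - r["mean_matched_m"])))
    return pd.DataFrame(rows, columns=["condition", "target_distance_m", "difference_m"]).sort_values(
        ["condition", "target_distance_m"], ignore_index=True
    )
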