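"""ROI and peak-frame extraction of deformation indices, and group
statistics: two-way factorial ANOVA (age × %MVC) with Levene and
Shapiro–Wilk diagnostics and Bonferroni-adjusted post hoc t-tests, plus
univariate regression of the indices to %MVC and absolute force.

The nine deformation indices per record are the sorted strain-rate and
strain eigenvalues (fiber / out-plane / in-plane), the maximum shear
invariants SR_max and L_max and the volumetric strain L_vol.  Strain
indices are extracted at the frame of maximum force, strain-rate indices at
the frame of peak |SR_fiber| during the contraction phase (which precedes
the force peak).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ROISpec",
    "INDEX_NAMES",
    "resample_force_to_frames",
    "peak_frames",
    "roi_extract",
    "two_way_anova",
    "univariate_regression",
    "percent_difference",
]

INDEX_NAMES = (
    "SR_fiber", "SR_out_plane", "SR_in_plane", "SR_max",
    "L_fiber", "L_out_plane", "L_in_plane", "L_max", "L_vol",
)


@dataclass(frozen=True)
class ROISpec:
    """Rectangular ROI placed on the first-frame magnitude image of the
    middle slice; the default size matches the in-vivo protocol
    (7.81 mm across × 23.44 mm along the muscle long axis)."""

    muscle: str  # "MG" | "Sol"
    center_mm: tuple[float, float]  # (y, x), same origin as the voxel grid
    size_mm: tuple[float, float] = (23.44, 7.81)  # (y extent, x extent)
    slice_index: int | None = None  # None -> middle slice

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size_mm):
            raise ValueError("ROI size must be positive")

    def voxel_slices(self, shape_yx, spacing_yx):
        """(y-slice, x-slice) of the ROI on a grid with mm coordinates
        measured from voxel (0, 0)."""
        out = []
        for c, s, n, d in zip(self.center_mm, self.size_mm, shape_yx, spacing_yx):
            lo = int(round((c - s / 2.0) / d))
            hi = int(round((c + s / 2.0) / d)) + 1
            if lo < 0 or hi > n:
                raise ValueError("ROI extends beyond the field of view")
            out.append(slice(lo, hi))
        return tuple(out)


def resample_force_to_frames(force, n_frames: int, frame_interval_ms: float):
    """Cycle-average the force trace and linearly interpolate it onto the
    acquisition frame times."""
    cycle_s = n_frames * frame_interval_ms / 1000.0
    phase = np.mod(force.time_s, cycle_s) / cycle_s
    frame_phase = np.arange(n_frames) / n_frames
    # average within frame-width bins of the cycle phase
    bins = np.clip(np.floor(phase * n_frames).astype(int), 0, n_frames - 1)
    sums = np.bincount(bins, weights=force.force_n, minlength=n_frames)
    counts = np.bincount(bins, minlength=n_frames)
    if (counts == 0).any():
        return np.interp(
            frame_phase, phase[np.argsort(phase)], force.force_n[np.argsort(phase)]
        )
    return sums / counts


def peak_frames(force_at_frames, sr_fiber_course):
    """Frames at which strain-rate and strain indices are extracted.

    Strain indices are read at the frame of maximum force; strain-rate
    indices at the frame of maximum |SR_fiber| within the contraction phase
    (up to the force peak).  Returns (strain-rate frame, strain frame).
    """
    f = np.asarray(force_at_frames, dtype=float)
    sr = np.asarray(sr_fiber_course, dtype=float)
    if f.ndim != 1 or f.size != sr.size:
        raise ValueError("force and SR courses must be 1D and the same length")
    if np.ptp(f) == 0:
        raise ValueError("flat force curve: no contraction peak")
    strain_frame = int(np.argmax(f))
    sr_frame = int(np.argmax(np.abs(sr[: strain_frame + 1])))
    return sr_frame, strain_frame


def roi_extract(map_values, roi: ROISpec, spacing_mm, exclude_mask=None):
    """Mean ± SD of a per-voxel map over the ROI on its slice.

    ``map_values`` is (y, x, z); flagged voxels (``exclude_mask`` True) are
    left out and the number of contributing voxels is returned.
    """
    arr = np.asarray(map_values, dtype=float)
    if arr.ndim != 3:
        raise ValueError("map must be (y, x, z)")
    z = roi.slice_index if roi.slice_index is not None else arr.shape[2] // 2
    ys, xs = roi.voxel_slices(arr.shape[:2], spacing_mm[:2])
    patch = arr[ys, xs, z]
    keep = np.ones(patch.shape, dtype=bool)
    if exclude_mask is not None:
        keep &= ~np.asarray(exclude_mask, dtype=bool)[ys, xs, z]
    if not keep.any():
        raise ValueError("all ROI voxels are flagged for exclusion")
    vals = patch[keep]
    return float(vals.mean()), float(vals.std(ddof=1) if vals.size > 1 else 0.0), int(vals.size)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


def two_way_anova(
    records: pd.DataFrame,
    index: str,
    alpha: float = 0.05,
    diagnostics: bool = True,
):
    """Two-way factorial ANOVA of one deformation index on age group and
    %MVC with interaction, plus assumption diagnostics and Bonferroni
    post hoc t-tests across %MVC levels.

    ``records`` needs columns ``group`` (young/senior), ``mvc_percent`` and
    the index.  Post hoc pairwise independent-sample t-tests are run only
    when the %MVC main effect is significant at ``alpha``; raw p-values are
    multiplied by the number of pairwise comparisons (capped at 1).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in ("group", "mvc_percent", index):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    cells = records.groupby(["group", "mvc_percent"], observed=True)[index]
    sizes = cells.size()
    n_groups = records["group"].nunique()
    n_levels = records["mvc_percent"].nunique()
    if len(sizes) < n_groups * n_levels or (sizes < 2).any():
        raise ValueError("every age × %MVC cell needs at least 2 records")

    df = records.rename(columns={index: "_y"})[["group", "mvc_percent", "_y"]].copy()
    model = smf.ols("_y ~ C(group) * C(mvc_percent)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    effects = {
        "age": {"F": float(table.loc["C(group)", "F"]),
                "p": float(table.loc["C(group)", "PR(>F)"])},
        "mvc": {"F": float(table.loc["C(mvc_percent)", "F"]),
                "p": float(table.loc["C(mvc_percent)", "PR(>F)"])},
        "interaction": {
            "F": float(table.loc["C(group):C(mvc_percent)", "F"]),
            "p": float(table.loc["C(group):C(mvc_percent)", "PR(>F)"]),
        },
    }
    result = {"effects": effects, "anova_table": table}

    if diagnostics:
        groups = [v.values for _, v in cells]
        result["levene_p"] = float(sps.levene(*groups).pvalue)
        result["shapiro_p"] = float(sps.shapiro(model.resid).pvalue)

    result["posthoc"] = None
    if effects["mvc"]["p"] < alpha:
        levels = sorted(records["mvc_percent"].unique())
        pairs = list(combinations(levels, 2))
        rows = []
        for a, b in pairs:
            xa = records.loc[records["mvc_percent"] == a, index]
            xb = records.loc[records["mvc_percent"] == b, index]
            t, p = sps.ttest_ind(xa, xb)
            rows.append({
                "pair": f"{a}-{b}",
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": float(min(p * len(pairs), 1.0)),
            })
        result["posthoc"] = pd.DataFrame(rows)
    return result


def univariate_regression(records: pd.DataFrame, index: str, predictor: str):
    """Standardized univariate regression slope β of one index on one
    predictor (``mvc_percent`` or ``force_n``).

    Both variables are z-scored, so β equals the Pearson correlation; the
    two-sided p-value comes from the t distribution with n − 2 degrees of
    freedom.
    """
    for col in (index, predictor):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    x = records[predictor].to_numpy(dtype=float)
    y = records[index].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 records")
    if np.std(x) == 0:
        raise ValueError("zero-variance predictor")
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std() if np.std(y) > 0 else y - y.mean()
    res = sps.linregress(xz, yz)
    return {"beta": float(res.slope), "p": float(res.pvalue), "n": int(x.size)}


def percent_difference(reference: float, other: float) -> float:
    """Percent difference of ``other`` relative to ``reference``:
    100·(reference − other)/reference (e.g. young 198 N vs senior 110 N →
    44.4%, conventionally reported as "lower by ~45%")."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (reference - other) / reference
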