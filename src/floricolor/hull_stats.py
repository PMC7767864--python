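"""Color-space area occupancy and a random-subsample null test.

How much of a pollinator's chromaticity diagram a group of flowers fills
is measured by the minimum convex polygon (MCP): optionally discard the
points farthest from the group centroid (default: keep the closest 95%),
then take the convex-hull area of the rest. Whether a focal group (e.g.
the deoxyanthocyanin-dominated flowers) occupies *less* color space than
expected is tested by drawing many random same-size subsets from the full
sample pool and comparing the observed area with the null areas: a
t-model p-value (primary, able to resolve tail probabilities a 100-draw
empirical proportion cannot) plus the empirical proportion
``(count(null <= observed) + 1) / (n_iter + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import t as t_dist

DEFAULT_PERCENT = 95.0
DEFAULT_N_ITER = 100


def mcp_area(points: np.ndarray, percent: float = DEFAULT_PERCENT) -> float:
    """Minimum-convex-polygon area of a 2-D point cloud.

    The ``(100 - percent)%`` of points farthest from the arithmetic
    centroid are discarded (percent = 100 keeps everything), then the
    convex-hull area of the remainder is returned. Fewer than 3
    non-collinear points give area 0 with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not 0 < percent <= 100:
        raise ValueError(f"percent must be in (0, 100], got {percent}")
    if percent < 100 and len(pts) >= 3:
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        keep = max(3, int(np.ceil(len(pts) * percent / 100.0)))
        pts = pts[np.argsort(d, kind="stable")[:keep]]
    if len(pts) < 3:
        warnings.warn("fewer than 3 points: area is 0", stacklevel=2)
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("degenerate (collinear) point cloud: area is 0", stacklevel=2)
        return 0.0
    return float(hull.volume)  # in 2-D, qhull's "volume" is the area


@dataclass
class HullTestResult:
    """Observed group area against a random-subsample null."""

    observed_area: float
    null_areas: np.ndarray
    null_mean: float
    ci_low: float
    ci_high: float
    p_value: float  # t-model, one-sided (smaller than null)
    p_empirical: float
    n_iter: int
    subset_size: int
    percent: float
    seed: int | None


def subsample_area_null(
    all_points: np.ndarray,
    observed_points: np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    percent: float = DEFAULT_PERCENT,
    seed: int | None = None,
    subset_size: int | None = None,
) -> HullTestResult:
    """Test whether a group's MCP area is small relative to random subsets.

    Draws `n_iter` simple random subsets (without replacement, size =
    the observed group unless `subset_size` overrides) from `all_points`,
    computes each subset's MCP area, and locates the observed group's
    area in that null: 95% CI on the null mean via the t distribution,
    one-sided t-model p for an area <= observed, and the +1/+1 empirical
    proportion.
    """
    pool = np.asarray(all_points, dtype=float)
    obs = np.asarray(observed_points, dtype=float)
    k = len(obs) if subset_size is None else int(subset_size)
    if k > len(pool):
        raise ValueError(f"subset size {k} exceeds pool size {len(pool)}")
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    rng = np.random.default_rng(seed)
    null_areas = np.array(
        [mcp_area(pool[rng.choice(len(pool), size=k, replace=False)], percent)
         for _ in range(n_iter)]
    )
    observed_area = mcp_area(obs, percent)
    mean = float(null_areas.mean())
    sd = float(null_areas.std(ddof=1))
    sem = sd / np.sqrt(n_iter)
    tcrit = float(t_dist.ppf(0.975, n_iter - 1))
    if sd == 0:
        warnings.warn("all null areas identical: degenerate null", stacklevel=2)
        p_t = 1.0 if observed_area >= mean else np.nan
    else:
        p_t = float(t_dist.cdf((observed_area - mean) / sd, df=n_iter - 1))
    p_emp = (int(np.sum(null_areas <= observed_area)) + 1) / (n_iter + 1)
    return HullTestResult(
        observed_area=observed_area,
        null_areas=null_areas,
        null_mean=mean,
        ci_low=mean - tcrit * sem,
        ci_high=mean + tcrit * sem,
        p_value=p_t,
        p_empirical=p_emp,
        n_iter=n_iter,
        subset_size=k,
        percent=percent,
        seed=seed,
    )
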