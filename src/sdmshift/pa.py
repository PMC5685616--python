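"""Protected-area effectiveness: inside vs buffer richness comparison.

For each reserve, the mean richness over random pixels whose centres fall
inside the polygon is paired with the mean over random pixels lying
outside the polygon but within a 50-km buffer of its boundary (the buffer
keeps the outside habitat comparable while capturing enough pixels).
Reserves smaller than one pixel, or that caught no random pixel, take the
richness of the pixel containing the reserve centroid. The per-reserve
inside-minus-outside differences are then tested against zero with a
one-sample t-test, pooled over maps and per map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import Polygon

from .errors import GeometryError, SamplingError
from .grid import ProtectedArea, RasterGrid, distance_to_polygon_km

logger = logging.getLogger(__name__)


def sample_random_pixels(
    land_mask: np.ndarray, n: int = 2000, seed: int = 0
) -> list[tuple[int, int]]:
    """Uniform sample of n land cells without replacement."""
    rows, cols = np.nonzero(np.asarray(land_mask, dtype=bool))
    if n > len(rows):
        raise SamplingError(f"requested {n} pixels but only {len(rows)} land cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=False)
    return [(int(rows[i]), int(cols[i])) for i in idx]


def classify_pixels(
    pa: ProtectedArea,
    grid: RasterGrid,
    random_pixels: list[tuple[int, int]],
    buffer_km: float = 50.0,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split random pixels into inside-polygon and outside-but-in-buffer.

    Membership uses pixel centres; the buffer is measured from the polygon
    boundary with the grid's distance metric (km when geographic).
    """
    poly = pa.polygon  # raises GeometryError when degenerate
    pixels = np.asarray(random_pixels, dtype=int)
    xs, ys = grid.cell_center(pixels[:, 0], pixels[:, 1])
    pts = shapely.points(xs, ys)
    inside_mask = shapely.covers(poly, pts)

    # bounding-box prefilter before exact distances
    if grid.crs == "geographic":
        from .grid import KM_PER_DEG

        pad = buffer_km / KM_PER_DEG / max(
            np.cos(np.radians(poly.centroid.y)), 0.1
        )
    else:
        pad = buffer_km
    minx, miny, maxx, maxy = poly.bounds
    near = (
        (xs >= minx - pad) & (xs <= maxx + pad)
        & (ys >= miny - pad) & (ys <= maxy + pad)
        & ~inside_mask
    )
    outside_mask = np.zeros(len(pixels), dtype=bool)
    if near.any():
        d = distance_to_polygon_km(xs[near], ys[near], pa.vertices, crs=grid.crs)
        hit = np.zeros(len(pixels), dtype=bool)
        hit[np.nonzero(near)[0][d <= buffer_km]] = True
        outside_mask = hit
    inside = [tuple(p) for p in pixels[inside_mask]]
    outside = [tuple(p) for p in pixels[outside_mask]]
    return inside, outside


@dataclass
class PAComparison:
    pa_id: str
    map_tag: str
    inside_mean: float
    outside_mean: float
    difference: float
    n_inside: int
    n_outside: int
    small_pa_rule_used: bool
    valid: bool = True


def pa_paired_means(
    richness_map: RasterGrid,
    pa: ProtectedArea,
    inside_set: list[tuple[int, int]],
    outside_set: list[tuple[int, int]],
) -> PAComparison:
    """One paired inside/outside row for a reserve on one richness map.

    When no random pixel fell inside (sub-pixel reserves included), the
    inside value is the richness of the pixel containing the reserve
    centroid. A reserve with an empty outside set yields an invalid row
    that t-tests must exclude.
    """
    small_rule = False
    if inside_set:
        vals = [richness_map.values[r, c] for r, c in inside_set]
        inside_mean = float(np.mean(vals))
    else:
        cx, cy = pa.centroid
        cell = richness_map.cell_of(cx, cy)
        if cell is None:
            raise GeometryError(f"PA {pa.pa_id} centroid outside grid")
        inside_mean = float(richness_map.values[cell])
        small_rule = True
    if not outside_set:
        logger.info("PA %s: empty outside set; row marked invalid", pa.pa_id)
        return PAComparison(
            pa_id=pa.pa_id, map_tag="", inside_mean=inside_mean,
            outside_mean=float("nan"), difference=float("nan"),
            n_inside=len(inside_set), n_outside=0,
            small_pa_rule_used=small_rule, valid=False,
        )
    outside_vals = [richness_map.values[r, c] for r, c in outside_set]
    outside_mean = float(np.mean(outside_vals))
    return PAComparison(
        pa_id=pa.pa_id, map_tag="", inside_mean=inside_mean,
        outside_mean=outside_mean, difference=inside_mean - outside_mean,
        n_inside=len(inside_set), n_outside=len(outside_set),
        small_pa_rule_used=small_rule,
    )


@dataclass
class TTestResult:
    n: int
    mean_diff: float
    se: float
    t_statistic: float
    df: int
    p_two_sided: float


def one_sample_t(differences) -> TTestResult:
    """One-sample t-test of the mean difference against zero.

    t = mean / (sd / sqrt(n)) with df = n - 1 and a two-sided p-value.
    A zero-variance sample gives t = 0, p = 1 when the mean is zero and a
    signed infinity with p = 0 otherwise.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise SamplingError("t-test needs at least two differences")
    if not np.isfinite(d).all():
        raise SamplingError("non-finite differences")
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(n, 0.0, 0.0, 0.0, df, 1.0)
        t_val = float(np.inf) if mean > 0 else float(-np.inf)
        return TTestResult(n, mean, 0.0, t_val, df, 0.0)
    se = sd / np.sqrt(n)
    t_val = mean / se
    p = 2.0 * float(stats.t.sf(abs(t_val), df))
    return TTestResult(n, mean, float(se), float(t_val), df, p)


def percent_excess(mean_difference: float, outside_grand_mean: float) -> int:
    """Inside excess as a percentage of the outside mean, to the nearest
    integer percent."""
    if not outside_grand_mean > 0:
        raise SamplingError("outside grand mean must be positive")
    return int(round(100.0 * mean_difference / outside_grand_mean))


# ---------------------------------------------------------------------------
# Whole-assessment driver
# ---------------------------------------------------------------------------

def assess_protected_areas(
    richness_maps: dict[str, RasterGrid],
    pas: list[ProtectedArea],
    land_mask: np.ndarray,
    n_random_pixels: int = 2000,
    buffer_km: float = 50.0,
    seed: int = 0,
):
    """Compare richness inside vs outside every reserve on every map.

    Returns (comparisons, ttests) DataFrames. The t-tests include one row
    per map plus a pooled row over every valid (reserve, map) difference;
    because the exact pairing unit is a modelling choice, per-PA means
    pooled over maps are also provided as scope "per_pa".
    """
    import pandas as pd

    grid = next(iter(richness_maps.values()))
    pixels = sample_random_pixels(land_mask, n=n_random_pixels, seed=seed)
    rows = []
    for pa in pas:
        inside, outside = classify_pixels(pa, grid, pixels, buffer_km=buffer_km)
        for tag, rmap in richness_maps.items():
            comp = pa_paired_means(rmap, pa, inside, outside)
            comp.map_tag = tag
            rows.append(comp.__dict__.copy())
    comparisons = pd.DataFrame(rows)

    ttest_rows = []
    valid = comparisons[comparisons["valid"]]
    for tag, sub in valid.groupby("map_tag", sort=True):
        if len(sub) >= 2:
            res = one_sample_t(sub["difference"].to_numpy())
            ttest_rows.append(_ttest_row(f"map:{tag}", res))
    if len(valid) >= 2:
        res = one_sample_t(valid["difference"].to_numpy())
        ttest_rows.append(_ttest_row("pooled", res))
    per_pa = valid.groupby("pa_id", sort=True)["difference"].mean()
    if len(per_pa) >= 2:
        res = one_sample_t(per_pa.to_numpy())
        ttest_rows.append(_ttest_row("per_pa", res))
    ttests = pd.DataFrame(
        ttest_rows, columns=["scope", "n", "mean_diff", "se", "t", "df", "p"]
    )
    return comparisons, ttests


def _ttest_row(scope: str, res: TTestResult) -> dict:
    return {
        "scope": scope, "n": res.n, "mean_diff": res.mean_diff, "se": res.se,
        "t": res.t_statistic, "df": res.df, "p": res.p_two_sided,
    }
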