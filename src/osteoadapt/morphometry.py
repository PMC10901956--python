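"""Local bone adaptation measurements: Δη, cortical thickness, group stats.

Adaptation of a surface is quantified point by point as the minimum distance
between the adapted contour and a fourfold-interpolated copy of the baseline
contour, signed so that bone formation is positive on both surfaces
(outward motion of the periosteum, marrow-ward motion of the endosteum).
Cortical thickness uses a hybrid of two measures — minimum distance to the
endosteal surface and distance along the inward normal to the first cortical
edge — taking the smaller, which stays well-behaved on ridge-bearing
sections where a normal ray can re-cross the periosteum first.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import shapely
from scipy import stats
from scipy.spatial import cKDTree

from .contours import (
    ENDOSTEAL,
    PERIOSTEAL,
    Contour,
    interpolate_fourfold,
    surface_normals,
)


class MeasurementError(ValueError):
    pass


@dataclasses.dataclass
class FieldStats:
    """Pointwise group statistics of one adaptation measure over P."""

    P: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    n: int
    alpha: float = 0.05


@dataclasses.dataclass
class AdaptationMeasurement:
    """Per-point Δη^P, Δη^E and ΔCt.Th with group mean, SD and significance.

    Sign convention: positive = bone formation (cortex thickening) on both
    surfaces, so pointwise ΔCt.Th ≈ Δη^P + Δη^E on near-parallel surfaces.
    """

    delta_eta_p: FieldStats
    delta_eta_e: FieldStats
    delta_ct_th: FieldStats


def _min_distances(points: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance from each point to any target point."""
    return cKDTree(targets).query(points)[0]


class BaselineAdaptation:
    """Signed minimum-distance Δη against a fixed baseline contour.

    Caches the fourfold-interpolated point tree and the prepared baseline
    polygon, so repeated measurements against the same baseline (the
    calibration inner loop) avoid rebuilding them.
    """

    def __init__(self, baseline: Contour) -> None:
        self.surface = baseline.surface
        self._tree = cKDTree(interpolate_fourfold(baseline.xy))
        self._poly = shapely.Polygon(baseline.xy)
        shapely.prepare(self._poly)

    def __call__(self, adapted: Contour | np.ndarray) -> np.ndarray:
        xy = adapted.xy if isinstance(adapted, Contour) else np.asarray(adapted, float)
        dist = self._tree.query(xy)[0]
        inside = shapely.contains_xy(self._poly, xy[:, 0], xy[:, 1])
        if self.surface == PERIOSTEAL:
            sign = np.where(inside, -1.0, 1.0)
        else:
            sign = np.where(inside, 1.0, -1.0)
        return sign * dist


def surface_adaptation(adapted: Contour, baseline: Contour) -> np.ndarray:
    """Signed per-point net adaptation Δη (μm) of ``adapted`` vs ``baseline``.

    The baseline is linearly interpolated to four times its point count;
    each adapted point takes the shortest distance to any interpolated
    baseline point.  The sign is decided by a point-in-polygon (winding
    number) test against the baseline contour: positive on the formation
    side — outside for the periosteum, marrow side for the endosteum.
    """
    if adapted.surface != baseline.surface:
        raise MeasurementError("contours are from different surfaces")
    return BaselineAdaptation(baseline)(adapted)


def _ray_first_crossing(
    origins: np.ndarray,
    directions: np.ndarray,
    segments_a: np.ndarray,
    segments_b: np.ndarray,
    exclude: np.ndarray | None = None,
    t_min: float = 1e-9,
) -> np.ndarray:
    """Distance along each ray to its first segment crossing (inf if none).

    ``exclude`` is an optional (n_rays, n_segments) boolean mask of
    segment hits to ignore (used for the two segments incident to a ray's
    own origin vertex).
    """
    e = segments_b - segments_a  # (m, 2)
    ao = segments_a[None, :, :] - origins[:, None, :]  # (n, m, 2)
    denom = directions[:, None, 0] * e[None, :, 1] - directions[:, None, 1] * e[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ao[:, :, 0] * e[None, :, 1] - ao[:, :, 1] * e[None, :, 0]) / denom
        u = (ao[:, :, 0] * directions[:, None, 1] - ao[:, :, 1] * directions[:, None, 0]) / denom
    valid = (np.abs(denom) > 1e-300) & (u >= 0.0) & (u <= 1.0) & (t > t_min)
    if exclude is not None:
        valid &= ~exclude
    t = np.where(valid, t, np.inf)
    return t.min(axis=1)


def hybrid_thickness(
    periosteal: Contour,
    endosteal: Contour,
    return_components: bool = False,
):
    """Cortical thickness Ct.Th (μm) at each periosteal point.

    Measurement 1: minimum distance to the fourfold-interpolated endosteal
    contour.  Measurement 2: distance along the inward periosteal normal to
    the first crossing of either cortical edge.  Ct.Th is the smaller of
    the two.  Points whose inward ray never crosses an edge fall back to
    measurement 1 (flagged in the components).
    """
    if periosteal.surface != PERIOSTEAL or endosteal.surface != ENDOSTEAL:
        raise MeasurementError("hybrid_thickness expects a (periosteal, endosteal) pair")
    endo4 = interpolate_fourfold(endosteal.xy)
    m1 = _min_distances(periosteal.xy, endo4)

    origins = periosteal.xy
    inward = -surface_normals(periosteal)
    n_p = len(origins)
    peri_a = periosteal.xy
    peri_b = np.roll(periosteal.xy, -1, axis=0)
    endo_a = endosteal.xy
    endo_b = np.roll(endosteal.xy, -1, axis=0)
    seg_a = np.vstack([peri_a, endo_a])
    seg_b = np.vstack([peri_b, endo_b])
    # origin i lies on periosteal segments i-1 and i; ignore those hits
    exclude = np.zeros((n_p, len(seg_a)), dtype=bool)
    rows = np.arange(n_p)
    exclude[rows, rows] = True
    exclude[rows, (rows - 1) % n_p] = True
    m2 = _ray_first_crossing(origins, inward, seg_a, seg_b, exclude=exclude)
    fallback = ~np.isfinite(m2)
    ct = np.where(fallback, m1, np.minimum(m1, m2))
    if return_components:
        return ct, m1, m2, fallback
    return ct


def thickness_change(
    loaded: tuple[Contour, Contour],
    control: tuple[Contour, Contour],
) -> np.ndarray:
    """Per-point ΔCt.Th = Ct.Th(loaded) − Ct.Th(control) at matched P."""
    th_r = hybrid_thickness(*loaded)
    th_l = hybrid_thickness(*control)
    if len(th_r) != len(th_l):
        raise MeasurementError("loaded and control pairs use different P grids")
    return th_r - th_l


def pointwise_stats(samples: np.ndarray, alpha: float = 0.05) -> FieldStats:
    """Mean, SD and a one-sample two-sided t-test against 0 at each point.

    ``samples`` is (n_mice, n_points).  Degenerate points (SD = 0) are
    handled explicitly: a nonzero common value is significant, an all-zero
    point is not.  n = 1 yields the mean only (no test).
    """
    samples = np.atleast_2d(np.asarray(samples, float))
    n = samples.shape[0]
    mean = samples.mean(axis=0)
    npts = samples.shape[1]
    if n < 2:
        sd = np.zeros(npts)
        p = np.full(npts, np.nan)
        sig = np.zeros(npts, bool)
    else:
        sd = samples.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_1samp(samples, popmean=0.0, axis=0)
            p = np.asarray(res.pvalue, float)
        degenerate = sd == 0.0
        p = np.where(degenerate & (mean != 0.0), 0.0, p)
        p = np.where(degenerate & (mean == 0.0), 1.0, p)
        sig = p < alpha
    return FieldStats(
        P=np.arange(npts) / npts, mean=mean, sd=sd, p_value=p, significant=sig, n=n, alpha=alpha
    )


def measurement_summary(measurement: AdaptationMeasurement) -> dict:
    """Scalar summary of a group measurement: surface averages, peaks and
    their P locations, and the significant fraction per measure."""
    out = {}
    for name, field in (
        ("delta_eta_p", measurement.delta_eta_p),
        ("delta_eta_e", measurement.delta_eta_e),
        ("delta_ct_th", measurement.delta_ct_th),
    ):
        i_max, i_min = int(np.argmax(field.mean)), int(np.argmin(field.mean))
        out[name] = {
            "mean_um": float(field.mean.mean()),
            "peak_um": float(field.mean[i_max]),
            "peak_P": float(field.P[i_max]),
            "trough_um": float(field.mean[i_min]),
            "trough_P": float(field.P[i_min]),
            "significant_fraction": float(np.mean(field.significant)),
        }
    return out


def group_stats(
    delta_eta_p: np.ndarray,
    delta_eta_e: np.ndarray,
    delta_ct_th: np.ndarray,
    alpha: float = 0.05,
) -> AdaptationMeasurement:
    """Group statistics for the three adaptation measures (n_mice × n_points)."""
    shapes = {np.atleast_2d(a).shape for a in (delta_eta_p, delta_eta_e, delta_ct_th)}
    if len({s[1] for s in shapes}) != 1:
        raise MeasurementError("measures must share the resampled P grid")
    return AdaptationMeasurement(
        delta_eta_p=pointwise_stats(delta_eta_p, alpha),
        delta_eta_e=pointwise_stats(delta_eta_e, alpha),
        delta_ct_th=pointwise_stats(delta_ct_th, alpha),
    )
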