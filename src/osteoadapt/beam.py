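"""Cross-section properties and Euler–Bernoulli flexure strain.

The tibia under axial compression is treated as a beam loaded eccentrically
at the tibial plateau: the load point offset from the section centroid
induces bending moments on top of the axial term.  Longitudinal strain at a
surface point (x, y) of the cross section follows the generalised flexure
formula for an asymmetric section,

    ε_z = (1/E) [ −0.9 F / A
                  + (M_x I_yy + M_y I_xy) / (I_xx I_yy − I_xy²) · (y − y_c)
                  − (M_y I_xx + M_x I_xy) / (I_xx I_yy − I_xy²) · (x − x_c) ]

with F the applied peak load magnitude (compression, entered positive), the
tibia carrying 90 % of it (the fibula takes the rest), and (M_x, M_y) the
moment of the compressive force about the centroid.  Strain is linear over
the section; its zero set is the neutral axis.

Section properties are computed exactly from the bounding polygons (outer
minus inner ring) via Green's-theorem integrals, not from pixels.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .contours import Contour

#: Young's modulus of cortical bone, Pa.
DEFAULT_E_PA = 14.8e9

#: Fraction of the applied peak load carried by the tibia.
DEFAULT_TIBIAL_SHARE = 0.9

#: N/μm² → Pa
_STRESS_TO_PA = 1.0e12


class SectionError(ValueError):
    """Raised for invalid cross-section input."""


@dataclasses.dataclass(frozen=True)
class SectionProperties:
    """Area, centroid and second moments of area of the cortical ring.

    Areas in μm², coordinates in μm, moments in μm⁴.  Moments are central
    (taken about axes through the centroid).
    """

    area: float
    xc: float
    yc: float
    ixx: float
    iyy: float
    ixy: float

    def __post_init__(self) -> None:
        if not (self.area > 0 and self.ixx > 0 and self.iyy > 0):
            raise SectionError("section must have positive area and bending moments")
        if self.ixx * self.iyy - self.ixy**2 <= 0:
            raise SectionError("second-moment tensor must be positive definite")

    @property
    def centroid(self) -> np.ndarray:
        return np.array([self.xc, self.yc])

    @property
    def det(self) -> float:
        return self.ixx * self.iyy - self.ixy**2


@dataclasses.dataclass(frozen=True)
class LoadCase:
    """Peak compressive load and where it is applied.

    ``F`` is the applied peak load magnitude in newtons (compression,
    F ≥ 0); ``p_F`` the in-plane load point in μm; ``tibial_share`` the
    fraction of F carried by the tibia; ``E`` Young's modulus in Pa.
    """

    F: float
    p_F: tuple[float, float] = (0.0, 0.0)
    tibial_share: float = DEFAULT_TIBIAL_SHARE
    E: float = DEFAULT_E_PA

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("peak load F must be non-negative")
        if not (0 < self.tibial_share <= 1):
            raise ValueError("tibial_share must lie in (0, 1]")
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")


@dataclasses.dataclass
class StrainField:
    """Longitudinal strain (in με) at the surface points of both envelopes."""

    periosteal: np.ndarray
    endosteal: np.ndarray

    def stress_pa(self, E: float = DEFAULT_E_PA) -> "StrainField":
        return StrainField(self.periosteal * 1e-6 * E, self.endosteal * 1e-6 * E)


def _next(v: np.ndarray) -> np.ndarray:
    out = np.empty_like(v)
    out[:-1] = v[1:]
    out[-1] = v[0]
    return out


def _ring_integrals(xy: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Raw polygon integrals about the origin for a CCW-oriented ring.

    Returns (A, ∫x dA, ∫y dA, ∫x² dA, ∫y² dA, ∫xy dA).
    """
    xy = np.asarray(xy, float)
    x, y = xy[:, 0], xy[:, 1]
    xn, yn = _next(x), _next(y)
    cr = x * yn - xn * y
    a = 0.5 * np.sum(cr)
    sx = ((x + xn) @ cr) / 6.0
    sy = ((y + yn) @ cr) / 6.0
    sxx = ((x * x + x * xn + xn * xn) @ cr) / 12.0
    syy = ((y * y + y * yn + yn * yn) @ cr) / 12.0
    sxy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) @ cr) / 24.0
    return a, sx, sy, sxx, syy, sxy


def _ccw(xy: np.ndarray) -> np.ndarray:
    from .contours import signed_area

    xy = np.asarray(xy, float)
    if signed_area(xy) < 0:
        return xy[::-1]
    return xy


def section_properties_xy(peri_xy: np.ndarray, endo_xy: np.ndarray | None = None) -> SectionProperties:
    """Section properties from bare coordinate arrays (simulation hot path)."""
    a, sx, sy, sxx, syy, sxy = _ring_integrals(_ccw(peri_xy))
    if endo_xy is not None:
        ai, sxi, syi, sxxi, syyi, sxyi = _ring_integrals(_ccw(endo_xy))
        if ai >= a:
            raise SectionError("endosteal ring at least as large as periosteal ring")
        a, sx, sy = a - ai, sx - sxi, sy - syi
        sxx, syy, sxy = sxx - sxxi, syy - syyi, sxy - sxyi
    if a <= 0:
        raise SectionError("non-positive cortical area")
    xc, yc = sx / a, sy / a
    return SectionProperties(
        area=a,
        xc=xc,
        yc=yc,
        ixx=syy - a * yc * yc,
        iyy=sxx - a * xc * xc,
        ixy=sxy - a * xc * yc,
    )


def section_properties(periosteal: Contour, endosteal: Contour | None = None) -> SectionProperties:
    """Exact area, centroid and central second moments of the cortical ring.

    ``endosteal=None`` computes properties of the solid outer polygon
    (useful for analytic fixtures).  Moments are returned about centroidal
    axes via the parallel-axis transfer.
    """
    return section_properties_xy(
        periosteal.xy, None if endosteal is None else endosteal.xy
    )


def bending_moments(load: LoadCase, props: SectionProperties) -> tuple[float, float]:
    """Moments (M_x, M_y) in N·μm of the eccentric compressive load.

    The axial force of magnitude 0.9F acts along −z at the load point; its
    moment about the centroid is r × F with r the in-plane offset, giving
    M_x = −0.9F·e_y and M_y = +0.9F·e_x for e = p_F − p_c.  These signs put
    extra compression on the load-offset side of the section.
    """
    f = load.tibial_share * load.F
    ex = load.p_F[0] - props.xc
    ey = load.p_F[1] - props.yc
    return (-f * ey, f * ex)


def flexure_strain(
    props: SectionProperties,
    load: LoadCase,
    periosteal: Contour | np.ndarray,
    endosteal: Contour | np.ndarray | None = None,
) -> StrainField | np.ndarray:
    """Longitudinal strain (με) at surface points under an eccentric load.

    Accepts either a pair of contours (returning a :class:`StrainField`) or
    a bare (n, 2) coordinate array (returning a strain array), which the
    simulation loop uses directly.
    """
    mx, my = bending_moments(load, props)
    det = props.det
    f = load.tibial_share * load.F
    cy = (mx * props.iyy + my * props.ixy) / det
    cx = (my * props.ixx + mx * props.ixy) / det

    def _eval(xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, float)
        stress = -f / props.area + cy * (xy[:, 1] - props.yc) - cx * (xy[:, 0] - props.xc)
        return stress * _STRESS_TO_PA / load.E * 1e6  # → με

    peri_xy = periosteal.xy if isinstance(periosteal, Contour) else periosteal
    if endosteal is None:
        return _eval(peri_xy)
    endo_xy = endosteal.xy if isinstance(endosteal, Contour) else endosteal
    return StrainField(periosteal=_eval(peri_xy), endosteal=_eval(endo_xy))
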