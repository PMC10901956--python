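"""Raster pre-processing: binarisation, cavity fill, contour extraction,
principal-axis registration and contralateral alignment.

The working representation of a scanned cross section is a binary raster
(:class:`BinarySlice`) on a grid of isotropic pixels.  Pre-processing turns
it into a registered pair of periosteal/endosteal contours: small
intracortical cavities (blood-vessel lumens) are filled, sub-pixel
boundaries are traced by marching squares, the section is rotated so the
principal axis of minimum second moment of area lies along y and translated
so the marrow centroid sits at the origin, and contours are resampled to a
uniform P grid.  Control-limb images are mirrored horizontally so left and
right limbs share a frame, and a small (±5°) rotation search refines the
contralateral alignment in place of the manual adjustment used when
registering scans by hand.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings

import numpy as np
import shapely
import shapely.affinity
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu

from . import beam
from .contours import (
    ENDOSTEAL,
    PERIOSTEAL,
    Contour,
    ensure_clockwise,
    mirror_contour,
    resample_contour,
    rotate_points,
    signed_area,
)
from .morphometry import _min_distances

#: Working pixel size after downsampling, μm.
DEFAULT_PIXEL_SIZE_UM = 9.56


class ImageError(ValueError):
    pass


@dataclasses.dataclass
class BinarySlice:
    """Binary raster of cortical bone pixels with physical pixel geometry.

    ``grid[r, c]`` is True for bone; the centre of pixel (0, 0) sits at
    ``origin`` (μm) and row/column indices increase along +y/+x.  (Image
    files store rows top-down; the readers/writers flip accordingly.)
    """

    grid: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 2:
            raise ImageError("slice grid must be 2-D")
        if self.pixel_size <= 0:
            raise ImageError("pixel size must be positive")

    @property
    def bone_area(self) -> float:
        """Pixel-count estimate of the cortical area, μm²."""
        return float(self.grid.sum()) * self.pixel_size**2

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.grid.shape
        x = self.origin[0] + np.arange(cols) * self.pixel_size
        y = self.origin[1] + np.arange(rows) * self.pixel_size
        return x, y


@dataclasses.dataclass
class RigidTransform:
    """Record of the mirror/rotation/translation applied during registration.

    Applied in the order: mirror (x ↦ −x), rotation (CCW, about the origin),
    translation.
    """

    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    mirrored: bool = False

    def apply(self, xy: np.ndarray) -> np.ndarray:
        out = np.asarray(xy, float).copy()
        if self.mirrored:
            out[:, 0] = -out[:, 0]
        out = rotate_points(out, np.deg2rad(self.rotation_deg))
        return out + np.asarray(self.translation, float)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def binarize_otsu(
    grayscale: np.ndarray,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    origin: tuple[float, float] = (0.0, 0.0),
) -> BinarySlice:
    """Threshold a grayscale raster by Otsu's criterion; bone = bright class."""
    gray = np.asarray(grayscale, dtype=float)
    if np.ptp(gray) == 0:
        raise ImageError("uniform image cannot be thresholded")
    thr = threshold_otsu(gray)
    return BinarySlice(grid=gray > thr, pixel_size=pixel_size, origin=origin)


def fill_cavities(slc: BinarySlice) -> BinarySlice:
    """Fill small intracortical cavities, keeping only the marrow cavity.

    Background components are labelled (4-connectivity); the exterior is
    every component touching the image border and the marrow is the largest
    remaining one.  All other background components are set to bone.  A
    slice with no interior cavity at all is returned unchanged with a
    warning.
    """
    bg = ~slc.grid
    labels = skmeasure.label(bg, connectivity=1)
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border = border[border != 0]
    interior = [lab for lab in np.unique(labels) if lab != 0 and lab not in border]
    if not interior:
        warnings.warn("no interior cavity found; slice returned unchanged", stacklevel=2)
        return BinarySlice(slc.grid.copy(), slc.pixel_size, slc.origin)
    sizes = {lab: int((labels == lab).sum()) for lab in interior}
    marrow = max(sizes, key=sizes.get)
    fill = np.isin(labels, [lab for lab in interior if lab != marrow])
    return BinarySlice(slc.grid | fill, slc.pixel_size, slc.origin)


def _contour_to_um(rc: np.ndarray, slc: BinarySlice) -> np.ndarray:
    xy = np.column_stack(
        [
            slc.origin[0] + rc[:, 1] * slc.pixel_size,
            slc.origin[1] + rc[:, 0] * slc.pixel_size,
        ]
    )
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return xy


def extract_contours(slc: BinarySlice) -> tuple[Contour, Contour]:
    """Trace sub-pixel periosteal and endosteal boundaries of a filled slice.

    Marching squares at level 0.5 yields closed polylines between pixel
    centres; the largest-area loop is the periosteal envelope and the
    second largest the endosteal (marrow) envelope.
    """
    if skmeasure.label(slc.grid, connectivity=2).max() > 1:
        raise ImageError("more than one bone component in slice")
    loops = skmeasure.find_contours(slc.grid.astype(float), 0.5)
    if len(loops) < 2:
        raise ImageError("expected periosteal and endosteal boundaries; is the slice filled?")
    polys = [_contour_to_um(rc, slc) for rc in loops]
    areas = [abs(signed_area(p)) for p in polys]
    order = np.argsort(areas)[::-1]
    peri_xy = ensure_clockwise(polys[order[0]])
    endo_xy = ensure_clockwise(polys[order[1]])
    if not shapely.Polygon(peri_xy).contains(shapely.Polygon(endo_xy)):
        raise ImageError("endosteal contour is not inside the periosteal contour")
    return (
        Contour(peri_xy, surface=PERIOSTEAL),
        Contour(endo_xy, surface=ENDOSTEAL),
    )


def _principal_rotation(props: beam.SectionProperties) -> float:
    """CCW rotation (rad) aligning the minimum-moment principal axis with y.

    The axis about which the second moment of area is minimal is the "long"
    axis of the section: the top eigenvector of the scatter tensor
    [[∫x², ∫xy], [∫xy, ∫y²]] (central).  Returns the angle that rotates it
    onto the +y direction.
    """
    scatter = np.array([[props.iyy, props.ixy], [props.ixy, props.ixx]])
    evals, evecs = np.linalg.eigh(scatter)
    long_axis = evecs[:, np.argmax(evals)]
    return np.pi / 2 - np.arctan2(long_axis[1], long_axis[0])


def register_section(
    periosteal: Contour,
    endosteal: Contour,
    n_points: int | None = None,
) -> tuple[Contour, Contour, RigidTransform]:
    """Rotate/translate a contour pair into the common reference frame.

    After registration the cortical section's principal axis of minimal
    second moment of area lies along y (I_xy ≈ 0), the marrow centroid is
    at the origin, and the 180° principal-axis ambiguity is resolved by
    placing the centroid of the thickest-cortex arc (the posterior-ridge
    proxy) in the y < 0 half-plane.  Optionally resamples both contours.
    """
    props = beam.section_properties(periosteal, endosteal)
    if abs(props.ixx - props.iyy) < 1e-3 * max(props.ixx, props.iyy):
        warnings.warn("near-degenerate principal axes; rotation is ill-conditioned", stacklevel=2)
    theta = _principal_rotation(props)

    def _transform(xy: np.ndarray, extra_pi: bool) -> np.ndarray:
        ang = theta + (np.pi if extra_pi else 0.0)
        return rotate_points(xy, ang)

    for extra_pi in (False, True):
        peri_xy = _transform(periosteal.xy, extra_pi)
        endo_xy = _transform(endosteal.xy, extra_pi)
        marrow = beam.section_properties(Contour(endo_xy)).centroid
        peri_xy = peri_xy - marrow
        endo_xy = endo_xy - marrow
        # ridge proxy: thickness-weighted mean direction of periosteal points
        th = _min_distances(peri_xy, endo_xy)
        radial = peri_xy / np.hypot(peri_xy[:, 0], peri_xy[:, 1])[:, None]
        direction = (th[:, None] * radial).sum(axis=0)
        if direction[1] <= 0:
            break
    angle = theta + (np.pi if extra_pi else 0.0)
    transform = RigidTransform(
        rotation_deg=float(np.rad2deg(np.angle(np.exp(1j * angle)))),
        translation=(-float(marrow[0]), -float(marrow[1])),
    )
    peri = periosteal.with_xy(ensure_clockwise(peri_xy))
    endo = endosteal.with_xy(ensure_clockwise(endo_xy))
    if n_points is not None:
        peri = resample_contour(peri, n_points)
        endo = resample_contour(endo, n_points)
    return peri, endo, transform


def mirror_control(obj):
    """Mirror left-limb data horizontally (x ↦ −x about the frame origin).

    Accepts a :class:`BinarySlice` or a :class:`~osteoadapt.contours.Contour`
    (or a sequence of contours).  Contour orientation is re-fixed to
    clockwise; mirroring twice is the identity.
    """
    if isinstance(obj, BinarySlice):
        ncols = obj.grid.shape[1]
        new_origin_x = -(obj.origin[0] + (ncols - 1) * obj.pixel_size)
        return BinarySlice(obj.grid[:, ::-1].copy(), obj.pixel_size, (new_origin_x, obj.origin[1]))
    if isinstance(obj, Contour):
        return mirror_contour(obj)
    return type(obj)(mirror_control(o) for o in obj)


def _cortical_polygon(peri: Contour, endo: Contour) -> shapely.Polygon:
    return shapely.Polygon(peri.xy, [endo.xy])


def _rigid_from_points(src: np.ndarray, dst: np.ndarray, w: np.ndarray):
    """Weighted rigid Procrustes fit src → dst; returns (R, t)."""
    wsum = w.sum()
    mu_s = (w[:, None] * src).sum(axis=0) / wsum
    mu_t = (w[:, None] * dst).sum(axis=0) / wsum
    cov = ((src - mu_s) * w[:, None]).T @ (dst - mu_t)
    u, _, vt = np.linalg.svd(cov)
    rot = u @ np.diag([1.0, np.sign(np.linalg.det(u @ vt))]) @ vt
    return rot, mu_t - mu_s @ rot


def fine_align(
    control: tuple[Contour, Contour],
    loaded: tuple[Contour, Contour],
    search_deg: float = 5.0,
    search_translation_um: float = 20.0,
    robust_scale_um: float = 6.0,
    inlier_um: float = 1.5,
    max_iter: int = 50,
) -> tuple[float, tuple[Contour, Contour]]:
    """Small rigid refinement of the control onto the loaded section.

    Replaces the 1–5° manual adjustment used with hand-registered scans by
    a robust iterative-closest-point search: a rotation within
    ±``search_deg`` about the marrow centroid (frame origin) plus a bounded
    in-plane translation that compensates the marrow-centroid drift which
    asymmetric endosteal adaptation induces between the two limbs' own
    registrations.

    Correspondences use both surfaces against the fourfold-interpolated
    loaded contours with a redescending (Tukey) weight of scale
    ``robust_scale_um``, so the transform locks onto the arcs of cortex that
    did not adapt rather than absorbing genuine formation/resorption into
    the alignment.  Among multi-start solutions the one with the most
    points matching within ``inlier_um`` wins (ties: smallest residual).
    Returns the rotation angle (degrees, CCW) and the aligned control pair.
    """
    from scipy.spatial import cKDTree

    from .contours import interpolate_fourfold

    targets = [interpolate_fourfold(loaded[0].xy), interpolate_fourfold(loaded[1].xy)]
    trees = [cKDTree(t) for t in targets]

    def _poly_normals(xy: np.ndarray) -> np.ndarray:
        chord = np.roll(xy, -1, axis=0) - np.roll(xy, 1, axis=0)
        n = np.column_stack([-chord[:, 1], chord[:, 0]])
        return n / np.hypot(n[:, 0], n[:, 1])[:, None]

    target_normals = [_poly_normals(t) for t in targets]
    sources = [control[0].xy, control[1].xy]
    pts = np.vstack(sources)
    n_split = len(sources[0])
    c2 = robust_scale_um**2
    t_max = search_translation_um

    def _match(cur: np.ndarray):
        """Per point: nearest loaded surface point, its normal, distance."""
        q_pts = np.empty_like(cur)
        q_nrm = np.empty_like(cur)
        dist = np.empty(len(cur))
        for sl, tree, tgt, nrm in (
            (slice(0, n_split), trees[0], targets[0], target_normals[0]),
            (slice(n_split, None), trees[1], targets[1], target_normals[1]),
        ):
            d, idx = tree.query(cur[sl])
            q_pts[sl] = tgt[idx]
            q_nrm[sl] = nrm[idx]
            dist[sl] = d
        return q_pts, q_nrm, dist

    def _rotmat(ang: float) -> np.ndarray:
        c, s = np.cos(ang), np.sin(ang)
        return np.array([[c, s], [-s, c]])

    def _run(start_ang: float, start_shift: np.ndarray):
        ang = float(start_ang)
        shift = start_shift.astype(float)
        for _ in range(max_iter):
            cur = pts @ _rotmat(ang) + shift
            q_pts, q_nrm, d = _match(cur)
            w = np.where(d < robust_scale_um, (1.0 - d**2 / c2) ** 2, 0.0)
            if w.sum() < 16:
                break
            # linearised point-to-plane update: minimise
            # Σ w (n·(cur + δθ·J·cur + δt − q))² over (δθ, δt)
            r = np.einsum("ij,ij->i", cur - q_pts, q_nrm)
            j_theta = q_nrm[:, 0] * (-cur[:, 1]) + q_nrm[:, 1] * cur[:, 0]
            a_mat = np.column_stack([j_theta, q_nrm])
            aw = a_mat * w[:, None]
            try:
                delta = np.linalg.solve(aw.T @ a_mat, -aw.T @ r)
            except np.linalg.LinAlgError:
                break
            ang = float(np.clip(ang + delta[0], -np.deg2rad(search_deg), np.deg2rad(search_deg)))
            shift = np.clip(shift + delta[1:], -t_max, t_max)
            if abs(delta[0]) < 1e-8 and np.all(np.abs(delta[1:]) < 1e-6):
                break
        cur = pts @ _rotmat(ang) + shift
        q_pts, q_nrm, d = _match(cur)
        # score with the point-to-plane distance where the point-to-point
        # match is close (avoids the sample-spacing quantisation of d)
        r = np.abs(np.einsum("ij,ij->i", cur - q_pts, q_nrm))
        d_eff = np.where(d < robust_scale_um, r, d)
        inliers = int((d_eff < inlier_um).sum())
        resid = float(np.sqrt(np.mean(np.minimum(d_eff, robust_scale_um) ** 2)))
        return (inliers, -resid, ang, _rotmat(ang), shift)

    t_steps = (
        np.array([0.0])
        if t_max == 0
        else np.array([-t_max, -t_max / 2, 0.0, t_max / 2, t_max])
    )
    start_angles = np.deg2rad(np.linspace(-search_deg, search_deg, 5))
    candidates = [
        _run(a, np.array([0.0, ty])) for a in start_angles for ty in t_steps
    ]
    best = max(candidates, key=lambda r: (r[0], r[1]))
    _, _, ang, rot, shift = best
    angle = float(np.rad2deg(ang))
    if abs(abs(angle) - search_deg) < 1e-3:
        warnings.warn("fine alignment hit the rotation search bound", stacklevel=2)
    aligned = tuple(c.with_xy(c.xy @ rot + shift) for c in control)
    return angle, aligned


# -- slice / contour file formats -----------------------------------------

def write_slice(path, slc: BinarySlice, meta: dict | None = None) -> None:
    """Write a slice as an 8-bit image (0/255) plus a JSON sidecar."""
    import imageio.v3 as iio

    path = pathlib.Path(path)
    img = np.flipud(slc.grid.astype(np.uint8) * 255)  # row 0 at top of file
    iio.imwrite(path, img)
    sidecar = {
        "pixel_size_um": slc.pixel_size,
        "origin_um": list(slc.origin),
        **(meta or {}),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_slice(path) -> tuple[BinarySlice, dict]:
    """Read a slice image and its JSON sidecar."""
    import imageio.v3 as iio

    path = pathlib.Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise ImageError(f"missing sidecar file {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    img = np.flipud(np.asarray(iio.imread(path)))
    slc = BinarySlice(
        grid=img > 127,
        pixel_size=float(meta["pixel_size_um"]),
        origin=tuple(meta.get("origin_um", (0.0, 0.0))),
    )
    return slc, meta


def contours_to_frame(contours) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate contours as (surface, limb, P, x_um, y_um) rows."""
    import pandas as pd

    rows = []
    for c in contours:
        rows.append(
            pd.DataFrame(
                {
                    "surface": c.surface,
                    "limb": c.limb,
                    "P": c.P,
                    "x_um": c.x,
                    "y_um": c.y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
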