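"""Synthetic tibia-like cross-section cohorts with known ground truth.

Raw scans for the loading experiment this package models are not publicly
deposited, so validation runs on synthetic cohorts instead.  A baseline
cross section is a low-order Fourier perturbation of two concentric
circles — outer (periosteal) and inner (endosteal) rings — plus a single
Gaussian ridge bump on the outer ring standing in for the posteromedial
tibial ridge.  Only geometric genericity matters here (asymmetry, ridge,
eccentric marrow); the shapes are not digitised anatomy.

A cohort holds n mice per load group.  Each mouse gets an amplitude-jittered
baseline; its right (loaded) limb endpoint geometry is the forward
mechanostat simulation of that baseline under the ground-truth parameters
and schedule, and its left (control) limb is the baseline mirrored
horizontally.  Per-point ground-truth Δη fields are stored before
rasterisation.  Noise is applied to geometry (point-wise radial roughness,
per-limb scan-pose rotation); rasterisation itself supplies pixel-level
noise.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings

import numpy as np
import shapely

from . import beam, image, mechanostat, morphometry
from .contours import (
    ENDOSTEAL,
    PERIOSTEAL,
    Contour,
    ensure_clockwise,
    mirror_contour,
    resample_contour,
    rotate_points,
    smooth_contour,
    surface_normals,
)

#: Default in-plane load point (μm) in the registered section frame.
#: Chosen so the neutral axis crosses the surfaces near P ≈ 0.27 and 0.68
#: and peak strains straddle the 1100/2785 με thresholds over 0–12 N.
DEFAULT_LOAD_POINT_UM = (0.0, -1250.0)


class SyntheticError(ValueError):
    pass


@dataclasses.dataclass
class GeometrySpec:
    """Parameters of the tibia-like baseline cross section.

    Radii and amplitudes in μm; harmonics are (order, amplitude, phase)
    triples modulating each ring's radius; the ridge is a Gaussian bump on
    the outer ring.  The k = 1 inner harmonic shifts the marrow cavity off
    centre.
    """

    outer_base_radius: float = 600.0
    inner_base_radius: float = 400.0
    outer_harmonics: tuple = ((2, 50.0, 0.4), (3, 18.0, 1.1))
    inner_harmonics: tuple = ((1, 45.0, -1.9), (2, 35.0, 0.9))
    ridge_amplitude: float = 90.0
    ridge_angle_rad: float = -0.8
    ridge_width_rad: float = 0.45
    pixel_size: float = image.DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.outer_base_radius <= 0 or self.inner_base_radius <= 0:
            raise SyntheticError("base radii must be positive")
        if self.inner_base_radius >= self.outer_base_radius:
            raise SyntheticError("inner ring must be smaller than outer ring")
        if self.pixel_size <= 0:
            raise SyntheticError("pixel size must be positive")


@dataclasses.dataclass
class ShapeJitter:
    """Per-mouse perturbation of the geometry spec (deterministic record)."""

    outer_radius: float = 0.0
    inner_radius: float = 0.0
    outer_amplitudes: tuple = ()
    inner_amplitudes: tuple = ()
    ridge: float = 0.0

    @classmethod
    def draw(cls, rng: np.random.Generator, sd_um: float, spec: GeometrySpec) -> "ShapeJitter":
        if sd_um == 0.0:
            return cls()
        return cls(
            outer_radius=float(rng.normal(0.0, sd_um)),
            inner_radius=float(rng.normal(0.0, sd_um)),
            outer_amplitudes=tuple(rng.normal(0.0, sd_um, len(spec.outer_harmonics))),
            inner_amplitudes=tuple(rng.normal(0.0, sd_um, len(spec.inner_harmonics))),
            ridge=float(rng.normal(0.0, sd_um)),
        )


def _radius_profile(theta, base, harmonics, amp_jitter):
    r = np.full_like(theta, float(base))
    jit = list(amp_jitter) + [0.0] * (len(harmonics) - len(amp_jitter))
    for (k, amp, phase), dj in zip(harmonics, jit):
        r = r + (amp + dj) * np.cos(k * theta + phase)
    return r


def make_baseline_geometry(
    spec: GeometrySpec,
    mouse_jitter: ShapeJitter | None = None,
    n_points: int = 500,
    register: bool = True,
) -> tuple[Contour, Contour]:
    """Generate a registered (periosteal, endosteal) baseline contour pair.

    Deterministic given the jitter record.  The pair is registered into the
    common frame (minimum-moment axis along y, marrow centroid at the
    origin) and resampled to ``n_points``; invalid geometry — contour
    self-intersection, inner ring escaping the outer, cortex thinner than
    five pixels — raises :class:`SyntheticError`.
    """
    jit = mouse_jitter or ShapeJitter()
    m = max(4 * n_points, 1000)
    theta = -np.pi / 2 - 2 * np.pi * np.arange(m) / m  # clockwise
    r_out = _radius_profile(
        theta, spec.outer_base_radius + jit.outer_radius, spec.outer_harmonics, jit.outer_amplitudes
    )
    dang = np.angle(np.exp(1j * (theta - spec.ridge_angle_rad)))
    r_out = r_out + (spec.ridge_amplitude + jit.ridge) * np.exp(
        -0.5 * (dang / spec.ridge_width_rad) ** 2
    )
    r_in = _radius_profile(
        theta, spec.inner_base_radius + jit.inner_radius, spec.inner_harmonics, jit.inner_amplitudes
    )
    if np.any(r_out <= 0) or np.any(r_in <= 0):
        raise SyntheticError("perturbation produced non-positive radii")
    outer = np.column_stack([r_out * np.cos(theta), r_out * np.sin(theta)])
    inner = np.column_stack([r_in * np.cos(theta), r_in * np.sin(theta)])
    peri = Contour(ensure_clockwise(outer), surface=PERIOSTEAL)
    endo = Contour(ensure_clockwise(inner), surface=ENDOSTEAL)

    poly_out = shapely.Polygon(peri.xy)
    poly_in = shapely.Polygon(endo.xy)
    if not (poly_out.is_valid and poly_in.is_valid):
        raise SyntheticError("perturbation produced a self-intersecting contour")
    if not poly_out.contains(poly_in):
        raise SyntheticError("inner contour is not strictly inside the outer contour")

    if register:
        peri, endo, _ = image.register_section(peri, endo, n_points=n_points)
    else:
        peri = resample_contour(peri, n_points)
        endo = resample_contour(endo, n_points)

    min_th = morphometry.hybrid_thickness(peri, endo).min()
    if min_th <= 5 * spec.pixel_size:
        raise SyntheticError(
            f"cortex thinner than 5 pixels (min {min_th:.1f} μm at {spec.pixel_size} μm/px)"
        )
    return peri, endo


def rasterize(
    periosteal: Contour,
    endosteal: Contour,
    pixel_size: float = image.DEFAULT_PIXEL_SIZE_UM,
    margin_px: int = 3,
) -> image.BinarySlice:
    """Rasterise a contour pair: a pixel is bone iff its centre lies in the
    cortical ring.  Pixel centres sit at integer multiples of ``pixel_size``.
    """
    xy = periosteal.xy
    span = xy.max(axis=0) - xy.min(axis=0)
    if np.all(span < pixel_size):
        raise SyntheticError("contour fits entirely inside one pixel")
    i_lo = np.floor(xy.min(axis=0) / pixel_size).astype(int) - margin_px
    i_hi = np.ceil(xy.max(axis=0) / pixel_size).astype(int) + margin_px
    xs = np.arange(i_lo[0], i_hi[0] + 1) * pixel_size
    ys = np.arange(i_lo[1], i_hi[1] + 1) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    ring = shapely.Polygon(periosteal.xy, [endosteal.xy])
    shapely.prepare(ring)
    grid = shapely.contains_xy(ring, gx.ravel(), gy.ravel()).reshape(gy.shape)
    slc = image.BinarySlice(grid=grid, pixel_size=pixel_size, origin=(float(xs[0]), float(ys[0])))
    min_th = morphometry.hybrid_thickness(periosteal, endosteal).min()
    if min_th < 2 * pixel_size:
        warnings.warn("cortex thinner than 2 pixels; measurements may be invalid", stacklevel=2)
    return slc


def add_contour_noise(contour: Contour, sd_um: float, rng: np.random.Generator) -> Contour:
    """Point-wise roughness along the surface normal (geometry-level noise)."""
    if sd_um == 0.0:
        return contour
    normals = surface_normals(contour)
    return contour.with_xy(contour.xy + rng.normal(0.0, sd_um, (contour.n, 1)) * normals)


@dataclasses.dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the experimental design: 6 mice per group across peak
    loads 0–12 N; ground-truth adaptation follows the reference fitted M4
    mechanostat under the 5 + 14 + 2 day schedule.  Jitter/noise SDs are
    geometric (μm or degrees); a fixed seed makes the cohort byte-identical
    across runs.
    """

    n_mice: int = 6
    load_levels: tuple = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    shape_jitter_sd: float = 20.0
    contour_noise_sd: float = 3.0
    rotation_jitter_sd: float = 2.0
    seed: int = 0
    truth_params: mechanostat.MechanostatParams = dataclasses.field(
        default_factory=lambda: mechanostat.MechanostatParams(
            model_id="M4", k_pt=2.148, k_pc=0.981, k_et=7.055, k_ec=0.794
        )
    )
    schedule: mechanostat.SimulationSchedule = dataclasses.field(
        default_factory=mechanostat.SimulationSchedule
    )
    geometry: GeometrySpec = dataclasses.field(default_factory=GeometrySpec)
    load_point: tuple[float, float] = DEFAULT_LOAD_POINT_UM
    n_points: int = 500

    def __post_init__(self) -> None:
        if self.n_mice < 2:
            raise SyntheticError("a cohort needs at least 2 mice per group")
        if min(self.shape_jitter_sd, self.contour_noise_sd, self.rotation_jitter_sd) < 0:
            raise SyntheticError("noise standard deviations must be non-negative")


@dataclasses.dataclass
class CohortMember:
    """One mouse in one load group, with slices and ground truth."""

    mouse_id: int
    load_n: float
    left_slice: image.BinarySlice
    right_slice: image.BinarySlice
    baseline: tuple[Contour, Contour]
    endpoint: tuple[Contour, Contour]
    truth_delta_p: np.ndarray
    truth_delta_e: np.ndarray
    noisy_delta_p: np.ndarray
    noisy_delta_e: np.ndarray
    failed: bool = False


@dataclasses.dataclass
class Cohort:
    spec: CohortSpec
    members: list

    def group(self, load_n: float) -> list:
        return [m for m in self.members if m.load_n == load_n and not m.failed]

    def truth_mean_fields(self, load_n: float) -> tuple[np.ndarray, np.ndarray]:
        """Group-mean ground-truth Δη fields (periosteal, endosteal)."""
        grp = self.group(load_n)
        return (
            np.mean([m.truth_delta_p for m in grp], axis=0),
            np.mean([m.truth_delta_e for m in grp], axis=0),
        )

    def noisy_mean_fields(self, load_n: float) -> tuple[np.ndarray, np.ndarray]:
        """Group-mean contour-level Δη fields with roughness noise applied."""
        grp = self.group(load_n)
        return (
            np.mean([m.noisy_delta_p for m in grp], axis=0),
            np.mean([m.noisy_delta_e for m in grp], axis=0),
        )

    def mean_baseline(self, load_n: float) -> tuple[Contour, Contour]:
        """Point-wise mean baseline contour pair of a load group."""
        grp = self.group(load_n)
        peri = np.mean([m.baseline[0].xy for m in grp], axis=0)
        endo = np.mean([m.baseline[1].xy for m in grp], axis=0)
        return (
            Contour(peri, surface=PERIOSTEAL),
            Contour(endo, surface=ENDOSTEAL),
        )


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort: slices, contours and ground-truth records.

    The right-limb endpoint geometry is the forward mechanostat simulation
    of the mouse's baseline; the left limb is the baseline mirrored
    horizontally.  A mouse whose simulation fails (surface
    self-intersection) is flagged and the cohort is still returned.
    """
    master = np.random.SeedSequence(spec.seed)
    members: list[CohortMember] = []
    for li, load_n in enumerate(spec.load_levels):
        for mi in range(spec.n_mice):
            rng = np.random.Generator(
                np.random.PCG64(np.random.SeedSequence((spec.seed, li, mi)))
            )
            jitter = ShapeJitter.draw(rng, spec.shape_jitter_sd, spec.geometry)
            peri0, endo0 = make_baseline_geometry(
                spec.geometry, jitter, n_points=spec.n_points
            )
            load = beam.LoadCase(F=float(load_n), p_F=spec.load_point)
            failed = False
            try:
                end_state = mechanostat.simulate(
                    peri0, endo0, spec.truth_params, spec.schedule, load
                )
                peri1, endo1 = end_state.periosteal, end_state.endosteal
            except mechanostat.MechanostatError:
                failed = True
                peri1, endo1 = peri0, endo0

            truth_p = morphometry.surface_adaptation(peri1, peri0)
            truth_e = morphometry.surface_adaptation(endo1, endo0)

            # roughness noise, applied independently per limb; measurement
            # always runs on smoothed contours (as the raster path does)
            left_peri = add_contour_noise(peri0, spec.contour_noise_sd, rng)
            left_endo = add_contour_noise(endo0, spec.contour_noise_sd, rng)
            right_peri = add_contour_noise(peri1, spec.contour_noise_sd, rng)
            right_endo = add_contour_noise(endo1, spec.contour_noise_sd, rng)
            noisy_p = morphometry.surface_adaptation(
                smooth_contour(right_peri), smooth_contour(left_peri)
            )
            noisy_e = morphometry.surface_adaptation(
                smooth_contour(right_endo), smooth_contour(left_endo)
            )

            # scan pose: per-limb rotation jitter; left limb stored mirrored
            ang_l, ang_r = np.deg2rad(rng.normal(0.0, spec.rotation_jitter_sd, 2))
            lp = mirror_contour(left_peri.with_xy(rotate_points(left_peri.xy, ang_l)))
            le = mirror_contour(left_endo.with_xy(rotate_points(left_endo.xy, ang_l)))
            rp = right_peri.with_xy(rotate_points(right_peri.xy, ang_r))
            re_ = right_endo.with_xy(rotate_points(right_endo.xy, ang_r))
            left_slice = rasterize(lp, le, spec.geometry.pixel_size)
            right_slice = rasterize(rp, re_, spec.geometry.pixel_size)

            members.append(
                CohortMember(
                    mouse_id=mi,
                    load_n=float(load_n),
                    left_slice=left_slice,
                    right_slice=right_slice,
                    baseline=(peri0, endo0),
                    endpoint=(peri1, endo1),
                    truth_delta_p=truth_p,
                    truth_delta_e=truth_e,
                    noisy_delta_p=noisy_p,
                    noisy_delta_e=noisy_e,
                    failed=failed,
                )
            )
    del master
    return Cohort(spec=spec, members=members)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write slices (PNG + JSON sidecar) and ground truth (CSV) to disk."""
    import pandas as pd

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for m in cohort.members:
        tag = f"F{m.load_n:g}N_mouse{m.mouse_id}"
        for limb, slc in (("L", m.left_slice), ("R", m.right_slice)):
            image.write_slice(
                out / f"{tag}_{limb}.png",
                slc,
                meta={
                    "limb": limb,
                    "mouse_id": m.mouse_id,
                    "load_N": m.load_n,
                    "seed": cohort.spec.seed,
                },
            )
        n = len(m.truth_delta_p)
        for surface, field in (("periosteal", m.truth_delta_p), ("endosteal", m.truth_delta_e)):
            truth_rows.append(
                pd.DataFrame(
                    {
                        "mouse_id": m.mouse_id,
                        "load_N": m.load_n,
                        "surface": surface,
                        "P": np.arange(n) / n,
                        "delta_eta_um": field,
                    }
                )
            )
    pd.concat(truth_rows, ignore_index=True).to_csv(out / "ground_truth.csv", index=False)
    (out / "cohort.json").write_text(
        json.dumps(
            {
                "n_mice": cohort.spec.n_mice,
                "load_levels": list(cohort.spec.load_levels),
                "seed": cohort.spec.seed,
                "pixel_size_um": cohort.spec.geometry.pixel_size,
            },
            indent=1,
        )
    )
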