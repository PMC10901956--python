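"""End-to-end measurement pipeline gluing the image and morphometry stages.

``process_slice`` takes a raw binary slice to a registered, resampled
contour pair; ``measure_pair`` aligns a (mirrored) control against its
loaded counterpart and produces the three per-mouse adaptation fields;
``measure_group`` aggregates a load group into group statistics.
"""

from __future__ import annotations

import numpy as np

from . import image, morphometry
from .contours import Contour


def process_slice(
    slc: image.BinarySlice,
    n_points: int = 500,
    mirror: bool = False,
    smooth_sigma: float = 2.0,
) -> tuple[Contour, Contour]:
    """Raw slice → registered (periosteal, endosteal) contour pair.

    Steps: cavity fill, sub-pixel contour extraction, optional horizontal
    mirroring (control limbs), principal-axis + marrow-centroid
    registration, resampling to the P grid, and a light cyclic Gaussian
    smoothing (``smooth_sigma`` in points) that suppresses the
    marching-squares staircase without measurably shrinking the section
    (radial bias < 0.2 μm at the default resolution).
    """
    from .contours import smooth_contour

    filled = image.fill_cavities(slc)
    peri, endo = image.extract_contours(filled)
    if mirror:
        peri = image.mirror_control(peri)
        endo = image.mirror_control(endo)
    peri, endo, _ = image.register_section(peri, endo, n_points=n_points)
    return smooth_contour(peri, smooth_sigma), smooth_contour(endo, smooth_sigma)


def measure_pair(
    loaded: tuple[Contour, Contour],
    control: tuple[Contour, Contour],
    fine_align: bool = True,
) -> dict:
    """Per-mouse adaptation fields from registered loaded/control pairs.

    Returns Δη^P, Δη^E (loaded vs control as the baseline proxy) and
    ΔCt.Th, plus the fine-alignment angle applied to the control.
    """
    angle = 0.0
    if fine_align:
        angle, control = image.fine_align(control, loaded)
    delta_p = morphometry.surface_adaptation(loaded[0], control[0])
    delta_e = morphometry.surface_adaptation(loaded[1], control[1])
    dct = morphometry.thickness_change(loaded, control)
    return {
        "delta_eta_p": delta_p,
        "delta_eta_e": delta_e,
        "delta_ct_th": dct,
        "fine_align_deg": angle,
    }


def measure_group(
    pairs: list[tuple[image.BinarySlice, image.BinarySlice]],
    n_points: int = 500,
    alpha: float = 0.05,
    fine_align: bool = True,
) -> tuple[morphometry.AdaptationMeasurement, dict]:
    """Measure a load group of (left control, right loaded) slices.

    Returns group statistics plus the stacked per-mouse fields.
    """
    stacks = {"delta_eta_p": [], "delta_eta_e": [], "delta_ct_th": []}
    angles = []
    for left, right in pairs:
        ctrl = process_slice(left, n_points=n_points, mirror=True)
        load = process_slice(right, n_points=n_points, mirror=False)
        fields = measure_pair(load, ctrl, fine_align=fine_align)
        for key in stacks:
            stacks[key].append(fields[key])
        angles.append(fields["fine_align_deg"])
    arrays = {k: np.vstack(v) for k, v in stacks.items()}
    stats = morphometry.group_stats(
        arrays["delta_eta_p"], arrays["delta_eta_e"], arrays["delta_ct_th"], alpha=alpha
    )
    arrays["fine_align_deg"] = np.asarray(angles)
    return stats, arrays
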