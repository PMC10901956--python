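"""Scoring simulated adaptation against measurements.

Prediction accuracy is the fraction of surface points whose simulated value
falls within a band of the measured one; the default bands are one image
resolution (9.56 μm) for surface fields and two resolutions (19.12 μm) for
cortical-thickness fields.  Regional summaries sample the fields at four
anatomical stations of the normalised position coordinate:
P = 0.27 (lateral), 0.46 (anterior), 0.68 (medial) and 0.99 (posterior) —
the neutral-axis, peak-tension and peak-compression sites.
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: Accuracy bands, μm (one and two image resolutions).
SURFACE_BAND_UM = 9.56
THICKNESS_BAND_UM = 19.12

#: Default anatomical stations on the P grid.
DEFAULT_STATIONS = (0.27, 0.46, 0.68, 0.99)
STATION_NAMES = {0.27: "lateral", 0.46: "anterior", 0.68: "medial", 0.99: "posterior"}


class EvaluationError(ValueError):
    pass


@dataclasses.dataclass
class AccuracyReport:
    """Fractions of accurately predicted points per field."""

    periosteal: float
    endosteal: float
    thickness: float | None = None
    surface_band_um: float = SURFACE_BAND_UM
    thickness_band_um: float = THICKNESS_BAND_UM

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class RegionalSummary:
    """Field values at the anatomical stations.

    ``simulated`` maps station → point value; ``experimental`` maps
    station → (mean, sd).
    """

    stations: tuple
    simulated: dict
    experimental: dict


def prediction_accuracy(sim: np.ndarray, exp: np.ndarray, band_um: float) -> float:
    """Fraction of points with |sim − exp| ≤ band (both endpoints accurate)."""
    sim, exp = np.asarray(sim, float), np.asarray(exp, float)
    if sim.size == 0 or exp.size == 0:
        raise EvaluationError("empty field")
    if sim.shape != exp.shape:
        raise EvaluationError("fields must share the P grid")
    if band_um <= 0:
        raise EvaluationError("accuracy band must be positive")
    return float(np.mean(np.abs(sim - exp) <= band_um))


def accuracy_report(
    sim_p: np.ndarray,
    exp_p: np.ndarray,
    sim_e: np.ndarray,
    exp_e: np.ndarray,
    sim_th: np.ndarray | None = None,
    exp_th: np.ndarray | None = None,
    surface_band_um: float = SURFACE_BAND_UM,
    thickness_band_um: float = THICKNESS_BAND_UM,
) -> AccuracyReport:
    """Per-surface (and optional thickness) accuracy fractions."""
    th = None
    if sim_th is not None and exp_th is not None:
        th = prediction_accuracy(sim_th, exp_th, thickness_band_um)
    return AccuracyReport(
        periosteal=prediction_accuracy(sim_p, exp_p, surface_band_um),
        endosteal=prediction_accuracy(sim_e, exp_e, surface_band_um),
        thickness=th,
        surface_band_um=surface_band_um,
        thickness_band_um=thickness_band_um,
    )


def station_index(station: float, n_points: int) -> int:
    """Deterministic nearest-grid-point index for a station on P = i/n."""
    if not (0.0 <= station < 1.0):
        raise EvaluationError("station must lie in [0, 1)")
    return int(np.round(station * n_points)) % n_points


def regional_summary(
    simulated: np.ndarray,
    experimental_mean: np.ndarray | None = None,
    experimental_sd: np.ndarray | None = None,
    stations: tuple = DEFAULT_STATIONS,
) -> RegionalSummary:
    """Sample a field (and optional experimental mean ± SD) at the stations."""
    simulated = np.asarray(simulated, float)
    n = len(simulated)
    sim_vals, exp_vals = {}, {}
    for st in stations:
        idx = station_index(st, n)
        sim_vals[st] = float(simulated[idx])
        if experimental_mean is not None:
            sd = float(experimental_sd[idx]) if experimental_sd is not None else np.nan
            exp_vals[st] = (float(np.asarray(experimental_mean, float)[idx]), sd)
    return RegionalSummary(stations=tuple(stations), simulated=sim_vals, experimental=exp_vals)


def plot_adaptation(measurement, sim_p=None, sim_e=None, ax=None):
    """Quick matplotlib view of mean ± SD adaptation traces (optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for field, color, label in (
        (measurement.delta_eta_p, "tab:blue", "Δη periosteal"),
        (measurement.delta_eta_e, "tab:red", "Δη endosteal"),
        (measurement.delta_ct_th, "tab:olive", "ΔCt.Th"),
    ):
        ax.plot(field.P, field.mean, color=color, label=label)
        ax.fill_between(field.P, field.mean - field.sd, field.mean + field.sd, color=color, alpha=0.2)
    if sim_p is not None:
        ax.plot(np.arange(len(sim_p)) / len(sim_p), sim_p, "--", color="tab:blue")
    if sim_e is not None:
        ax.plot(np.arange(len(sim_e)) / len(sim_e), sim_e, "--", color="tab:red")
    ax.set_xlabel("P (normalised position)")
    ax.set_ylabel("adaptation (μm)")
    ax.legend()
    return ax
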