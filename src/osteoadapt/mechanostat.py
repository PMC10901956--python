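"""Mechanostat models M1–M4 and forward-Euler surface evolution.

Frost's mechanostat maps local strain to a surface formation/resorption
rate.  Four model classes of increasing freedom are supported:

* M1 — one universal formation rate, one threshold (1100 με on both
  surfaces);
* M2 — separate rates for tension and compression, shared by both surfaces,
  one threshold;
* M3 — separate rates per surface (periosteal/endosteal), surface-specific
  thresholds (2785 / 1100 με);
* M4 — four rates (surface × strain direction), surface-specific thresholds.

Within the lazy zone |ε| ≤ ε_hom there is no load-driven response.  Above
it the rate is linear in the normalised strain difference
ε_norm = (|ε| − ε_hom)/ε_hom.  The endosteum additionally loses bone at the
constant sciatic-neurectomy rate k_SN on every day of the protocol.

Surfaces evolve by explicit forward Euler: each day every point moves by
M·û·Δt along its formation-direction normal, after which both contours are
re-resampled to uniform arc length so the P coordinate (not the point
index) carries identity across days.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import shapely

from . import beam
from .contours import (
    ENDOSTEAL,
    PERIOSTEAL,
    Contour,
    ContourError,
    resample_closed,
)

MODEL_IDS = ("M1", "M2", "M3", "M4")

#: Homeostatic strain thresholds, με.
EPS_HOM_PERIOSTEAL = 2785.0
EPS_HOM_ENDOSTEAL = 1100.0

#: Endosteal resorption rate due to sciatic neurectomy, μm/day (magnitude).
K_SN_DEFAULT = 1.398


class MechanostatError(ValueError):
    pass


@dataclasses.dataclass
class MechanostatParams:
    """Thresholds, formation rates and the model-class equality constraints.

    Rates are μm/day per unit normalised strain difference; ``k_sn`` is the
    magnitude of the constant endosteal resorption (it acts negatively).
    """

    model_id: str = "M4"
    eps_hom_p: float = EPS_HOM_PERIOSTEAL
    eps_hom_e: float = EPS_HOM_ENDOSTEAL
    k_pt: float = 0.0
    k_pc: float = 0.0
    k_et: float = 0.0
    k_ec: float = 0.0
    k_sn: float = K_SN_DEFAULT

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise MechanostatError(f"unknown model id {self.model_id!r}")
        if self.eps_hom_p <= 0 or self.eps_hom_e <= 0:
            raise MechanostatError("strain thresholds must be positive")
        if min(self.k_pt, self.k_pc, self.k_et, self.k_ec) < 0:
            raise MechanostatError("formation rates must be non-negative")
        if self.model_id == "M1":
            if not (self.k_pt == self.k_pc == self.k_et == self.k_ec):
                raise MechanostatError("M1 requires a single formation rate")
            if self.eps_hom_p != self.eps_hom_e:
                raise MechanostatError("M1 requires a single threshold")
        elif self.model_id == "M2":
            if not (self.k_pt == self.k_et and self.k_pc == self.k_ec):
                raise MechanostatError("M2 ties rates across surfaces per direction")
            if self.eps_hom_p != self.eps_hom_e:
                raise MechanostatError("M2 requires a single threshold")
        elif self.model_id == "M3":
            if not (self.k_pt == self.k_pc and self.k_et == self.k_ec):
                raise MechanostatError("M3 ties rates across directions per surface")

    @classmethod
    def from_free_rates(
        cls,
        model_id: str,
        rates,
        k_sn: float = K_SN_DEFAULT,
        eps_hom_p: float | None = None,
        eps_hom_e: float | None = None,
    ) -> "MechanostatParams":
        """Build full parameters from a model's free-rate vector.

        Free-rate ordering: M1 → (k,), M2 → (k_T, k_C), M3 → (k_P, k_E),
        M4 → (k_PT, k_PC, k_ET, k_EC).  M1/M2 default to the shared
        1100 με threshold; M3/M4 to the surface-specific pair.
        """
        rates = tuple(float(r) for r in rates)
        if model_id in ("M1", "M2"):
            hp = EPS_HOM_ENDOSTEAL if eps_hom_p is None else eps_hom_p
            he = EPS_HOM_ENDOSTEAL if eps_hom_e is None else eps_hom_e
        else:
            hp = EPS_HOM_PERIOSTEAL if eps_hom_p is None else eps_hom_p
            he = EPS_HOM_ENDOSTEAL if eps_hom_e is None else eps_hom_e
        if model_id == "M1":
            (k,) = rates
            full = (k, k, k, k)
        elif model_id == "M2":
            kt, kc = rates
            full = (kt, kc, kt, kc)
        elif model_id == "M3":
            kp, ke = rates
            full = (kp, kp, ke, ke)
        elif model_id == "M4":
            full = rates
            if len(full) != 4:
                raise MechanostatError("M4 expects four free rates")
        else:
            raise MechanostatError(f"unknown model id {model_id!r}")
        return cls(
            model_id=model_id,
            eps_hom_p=hp,
            eps_hom_e=he,
            k_pt=full[0],
            k_pc=full[1],
            k_et=full[2],
            k_ec=full[3],
            k_sn=k_sn,
        )

    def free_rates(self) -> tuple[float, ...]:
        if self.model_id == "M1":
            return (self.k_pt,)
        if self.model_id == "M2":
            return (self.k_pt, self.k_pc)
        if self.model_id == "M3":
            return (self.k_pt, self.k_et)
        return (self.k_pt, self.k_pc, self.k_et, self.k_ec)

    def threshold(self, surface: str) -> float:
        return self.eps_hom_p if surface == PERIOSTEAL else self.eps_hom_e


N_FREE_RATES = {"M1": 1, "M2": 2, "M3": 2, "M4": 4}


def normalized_strain(eps_ue, eps_hom: float):
    """Normalised strain difference (|ε| − ε_hom)/ε_hom, defined above threshold.

    The caller must gate out the lazy zone: calling this with |ε| ≤ ε_hom is
    an error, since the piecewise rate equations handle that region as zero
    load-driven response.
    """
    if eps_hom <= 0:
        raise MechanostatError("eps_hom must be positive")
    eps_abs = np.abs(np.asarray(eps_ue, dtype=float))
    if np.any(eps_abs <= eps_hom):
        raise MechanostatError("normalized_strain called inside the lazy zone")
    out = (eps_abs - eps_hom) / eps_hom
    return float(out) if np.isscalar(eps_ue) else out


def surface_rate(eps_ue, params: MechanostatParams, surface: str):
    """Net surface adaptation rate M (μm/day) for strain ε (με).

    Piecewise: zero (periosteum) or −k_SN (endosteum) inside the lazy zone,
    ε_norm·k_C below −ε_hom, ε_norm·k_T above +ε_hom; the endosteal branches
    all carry the −k_SN offset.  Threshold boundaries (|ε| = ε_hom) belong
    to the lazy zone.
    """
    eps = np.asarray(eps_ue, dtype=float)
    if surface == PERIOSTEAL:
        hom, kt, kc, base = params.eps_hom_p, params.k_pt, params.k_pc, 0.0
    elif surface == ENDOSTEAL:
        hom, kt, kc, base = params.eps_hom_e, params.k_et, params.k_ec, -params.k_sn
    else:
        raise MechanostatError(f"unknown surface {surface!r}")
    norm = np.maximum(np.abs(eps) - hom, 0.0) / hom
    rate = np.where(eps > hom, norm * kt, np.where(eps < -hom, norm * kc, 0.0))
    out = rate + base
    return float(out) if np.isscalar(eps_ue) else out


@dataclasses.dataclass
class SimulationSchedule:
    """Day-by-day protocol: disuse lead-in, loading window, disuse tail.

    Defaults replicate the 21-day experiment: sciatic-neurectomy catabolism
    alone for 5 days, 14 days with daily mechanical loading, then 2 final
    disuse days.  k_SN acts on the endosteum on every day.
    """

    sn_lead_days: int = 5
    loading_days: int = 14
    sn_tail_days: int = 2
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise MechanostatError("time step must be positive")
        if min(self.sn_lead_days, self.loading_days, self.sn_tail_days) < 0:
            raise MechanostatError("phase lengths must be non-negative")

    @property
    def total_days(self) -> int:
        return self.sn_lead_days + self.loading_days + self.sn_tail_days

    def daily_loaded(self) -> np.ndarray:
        """Boolean flag per simulated day: is external load applied?"""
        return np.concatenate(
            [
                np.zeros(self.sn_lead_days, bool),
                np.ones(self.loading_days, bool),
                np.zeros(self.sn_tail_days, bool),
            ]
        )


@dataclasses.dataclass
class DayRecord:
    """Audit-trail entry for one simulated day."""

    day: int
    loaded: bool
    props: beam.SectionProperties | None
    strain: beam.StrainField | None
    rate_periosteal: np.ndarray
    rate_endosteal: np.ndarray


@dataclasses.dataclass
class SimulationState:
    """Evolving geometry plus the per-day audit trail."""

    periosteal: Contour
    endosteal: Contour
    day: int = 0
    audit: list = dataclasses.field(default_factory=list)


def _outward_normals(xy: np.ndarray) -> np.ndarray:
    """Outward unit normals of a clockwise ring (chord rule, hot path)."""
    chord = np.empty_like(xy)
    chord[1:-1] = xy[2:] - xy[:-2]
    chord[0] = xy[1] - xy[-1]
    chord[-1] = xy[0] - xy[-2]
    norm = np.hypot(chord[:, 0], chord[:, 1])
    if np.any(norm == 0.0):
        raise ContourError("coincident neighbouring points; cannot form normals")
    return np.column_stack([-chord[:, 1], chord[:, 0]]) / norm[:, None]


def _advance(
    peri_xy: np.ndarray,
    endo_xy: np.ndarray,
    params: MechanostatParams,
    load: beam.LoadCase | None,
    dt: float,
    n: int,
):
    """One forward-Euler day on bare coordinate arrays (hot path)."""
    if load is not None and load.F * load.tibial_share != 0.0:
        props = beam.section_properties_xy(peri_xy, endo_xy)
        eps_p = beam.flexure_strain(props, load, peri_xy)
        eps_e = beam.flexure_strain(props, load, endo_xy)
    else:
        props = None
        eps_p = np.zeros(len(peri_xy))
        eps_e = np.zeros(len(endo_xy))
    rate_p = surface_rate(eps_p, params, PERIOSTEAL)
    rate_e = surface_rate(eps_e, params, ENDOSTEAL)
    if np.any(rate_p != 0.0):
        peri_xy = peri_xy + (rate_p * dt)[:, None] * _outward_normals(peri_xy)
        peri_xy = resample_closed(peri_xy, n)
    if np.any(rate_e != 0.0):
        # endosteal formation direction is marrow-ward: minus the outward normal
        endo_xy = endo_xy - (rate_e * dt)[:, None] * _outward_normals(endo_xy)
        endo_xy = resample_closed(endo_xy, n)
    return peri_xy, endo_xy, props, eps_p, eps_e, rate_p, rate_e


def step(
    state: SimulationState,
    params: MechanostatParams,
    load: beam.LoadCase | None,
    dt: float = 1.0,
    record_audit: bool = False,
) -> SimulationState:
    """Advance the surfaces by one day under the given load (None = disuse).

    Executes the four algorithm stages in order — section properties, strain,
    mechanostat rate, Euler position update — then re-resamples both contours
    so arc-length spacing and the P-origin convention are preserved.
    """
    n_p, n_e = state.periosteal.n, state.endosteal.n
    peri, endo, props, eps_p, eps_e, rp, re_ = _advance(
        state.periosteal.xy, state.endosteal.xy, params, load, dt, max(n_p, n_e)
    )
    audit = state.audit
    if record_audit:
        strain = beam.StrainField(eps_p, eps_e) if props is not None else None
        audit = audit + [DayRecord(state.day + 1, props is not None, props, strain, rp, re_)]
    return SimulationState(
        periosteal=state.periosteal.with_xy(peri),
        endosteal=state.endosteal.with_xy(endo),
        day=state.day + 1,
        audit=audit,
    )


def _check_simple(peri_xy: np.ndarray, endo_xy: np.ndarray, day: int) -> None:
    ring_p = shapely.LinearRing(peri_xy)
    ring_e = shapely.LinearRing(endo_xy)
    if not (ring_p.is_simple and ring_e.is_simple):
        raise MechanostatError(f"surface self-intersection after day {day}")
    if not shapely.Polygon(peri_xy).contains(shapely.Polygon(endo_xy)):
        raise MechanostatError(f"endosteal surface escaped the periosteum after day {day}")


def audit_to_frame(state: SimulationState) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate a simulation's per-day audit trail (one row per day)."""
    import pandas as pd

    rows = []
    for rec in state.audit:
        row = {
            "day": rec.day,
            "loaded": rec.loaded,
            "rate_p_mean_um_day": float(np.mean(rec.rate_periosteal)),
            "rate_e_mean_um_day": float(np.mean(rec.rate_endosteal)),
        }
        if rec.props is not None:
            row.update(
                area_um2=rec.props.area,
                ixx_um4=rec.props.ixx,
                iyy_um4=rec.props.iyy,
                ixy_um4=rec.props.ixy,
            )
        if rec.strain is not None:
            row.update(
                peak_compressive_ue=float(rec.strain.periosteal.min()),
                peak_tensile_ue=float(rec.strain.periosteal.max()),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def simulate(
    periosteal: Contour,
    endosteal: Contour,
    params: MechanostatParams,
    schedule: SimulationSchedule,
    load: beam.LoadCase,
    record_audit: bool = False,
    check_geometry: bool = True,
) -> SimulationState:
    """Run the full daily protocol and return the endpoint state.

    Deterministic: a pure function of (baseline, params, schedule, load).
    ``check_geometry`` verifies endpoint simplicity/nesting (skipped inside
    the calibration hot loop, where a failed candidate is detected by a
    non-finite RMS instead).
    """
    n = periosteal.n
    peri_xy = periosteal.xy
    endo_xy = endosteal.xy
    audit: list[DayRecord] = []
    disuse = beam.LoadCase(F=0.0, p_F=load.p_F, tibial_share=load.tibial_share, E=load.E)
    steps_per_day = int(round(1.0 / schedule.dt))
    for day, loaded in enumerate(schedule.daily_loaded(), start=1):
        day_load = load if loaded else disuse
        for _ in range(max(steps_per_day, 1)):
            peri_xy, endo_xy, props, eps_p, eps_e, rp, re_ = _advance(
                peri_xy, endo_xy, params, day_load, schedule.dt, n
            )
        if record_audit:
            strain = beam.StrainField(eps_p, eps_e) if props is not None else None
            audit.append(DayRecord(day, bool(loaded), props, strain, rp, re_))
    if check_geometry:
        _check_simple(peri_xy, endo_xy, schedule.total_days)
    return SimulationState(
        periosteal=periosteal.with_xy(peri_xy),
        endosteal=endosteal.with_xy(endo_xy),
        day=schedule.total_days,
        audit=audit,
    )
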