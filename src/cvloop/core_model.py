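"""Six-compartment closed-loop hydraulic model of the systemic and pulmonary
circulations.

The circuit is a single ring of six volume compartments — left ventricle (LV),
aorta (AO), vena cava (VC), right ventricle (RV), pulmonary artery (PA) and
pulmonary veins (PU) — joined by six resistive segments.  Four of the segments
represent heart valves (aortic, tricuspid, pulmonary, mitral) and behave as
ideal diodes: flow through them is one-way.  The two remaining segments are
the systemic and pulmonary peripheral resistances and conduct in either
direction.

Passive compartments (AO, VC, PA, PU) obey a linear pressure-volume relation
above their unstressed volume and sit at zero pressure below it.  Ventricular
pressures are supplied by a pluggable pressure source: either a time-varying
elastance (see :mod:`cvloop.muscle_models`) or, in the hybrid configuration,
the Laplace-transformed stress of a contracting muscle.  Right-ventricular
pressure defaults to the left-ventricular pressure scaled by the RV/LV
end-systolic elastance ratio.

Integration uses an explicit fixed-step (Euler) update at a 20 kHz tick,
mirroring a real-time control loop; an adaptive high-order reference
integrator over the identical right-hand side is provided for verification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "COMPARTMENTS",
    "SEGMENTS",
    "SEGMENT_PATH",
    "VALVE_SEGMENTS",
    "CirculationParameters",
    "SystemState",
    "LoopRecord",
    "passive_pressure",
    "segment_flow",
    "volume_derivatives",
    "system_pressures",
    "step_fixed",
    "run_cycles",
    "reference_solution",
]

logger = logging.getLogger(__name__)

#: Compartment order used by every state vector in this package.
COMPARTMENTS = ("LV", "AO", "VC", "RV", "PA", "PU")

#: Segment order: aortic valve, systemic resistance, tricuspid valve,
#: pulmonary valve, pulmonary resistance, mitral valve.
SEGMENTS = ("AV", "SYS", "TC", "PV", "PUL", "MT")

#: (upstream, downstream) compartment of each segment.  The circuit is a ring:
#: LV -AV-> AO -SYS-> VC -TC-> RV -PV-> PA -PUL-> PU -MT-> LV.
SEGMENT_PATH = {
    "AV": ("LV", "AO"),
    "SYS": ("AO", "VC"),
    "TC": ("VC", "RV"),
    "PV": ("RV", "PA"),
    "PUL": ("PA", "PU"),
    "MT": ("PU", "LV"),
}

#: Segments modelled as ideal diodes (one-way flow).
VALVE_SEGMENTS = frozenset({"AV", "TC", "PV", "MT"})

_CIDX = {name: i for i, name in enumerate(COMPARTMENTS)}
_SIDX = {name: i for i, name in enumerate(SEGMENTS)}

# Default tick of the real-time loop the model emulates: 20 kHz.
DEFAULT_DT = 5.0e-5
# Default stimulus period: 2 Hz pacing.
DEFAULT_PERIOD = 0.5
# Steady-state tolerance: cycle-to-cycle volume change per compartment [m^3].
DEFAULT_SS_TOL = 1.0e-10


class InvalidParameterError(ValueError):
    """A model parameter violates its physical constraint."""


class PressureSourceError(RuntimeError):
    """A ventricular pressure source produced a non-finite value."""


@dataclass(frozen=True)
class CirculationParameters:
    """Parameters of the six-compartment circulation.

    All values are SI: resistances in Pa·s·m⁻³, compliances in m³·Pa⁻¹,
    elastances in Pa·m⁻³, volumes in m³.  Defaults describe a rat-scale
    circulation (total volume 24 mL, of which 3 mL stressed).

    The end-systolic elastances are stored in Pa·m⁻³; the defaults
    (1.7e11 / 4.0e10) are the physiologically consistent reading of the
    rat-scale parameter set — only their ratio enters the hybrid
    (muscle-driven) configuration, where it slaves RV pressure to LV
    pressure.
    """

    R_AV: float = 5.0e9
    R_SYS: float = 175.0e9
    R_TC: float = 2.5e9
    R_PV: float = 3.38e9
    R_PUL: float = 12.5e9
    R_MT: float = 2.5e9

    C_AO: float = 32.0e-12
    C_VC: float = 1.7e-9
    C_PA: float = 0.32e-9
    C_PU: float = 0.19e-9

    E_ESLV: float = 170.0e9
    E_ESRV: float = 40.0e9

    V_t: float = 24.0e-6
    V_s: float = 3.0e-6
    V_u: float = 21.0e-6
    V_LV_init: float = 0.23e-6
    V_RV_init: float = 0.23e-6

    #: Per-compartment unstressed volumes, ordered as COMPARTMENTS.
    #: By default the total unstressed volume is distributed over the four
    #: passive compartments in proportion to compliance; ventricles carry
    #: none (their zero-pressure volume is taken as zero).
    unstressed_split: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("R_AV", "R_SYS", "R_TC", "R_PV", "R_PUL", "R_MT",
                     "C_AO", "C_VC", "C_PA", "C_PU", "E_ESLV", "E_ESRV"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not math.isclose(self.V_t, self.V_s + self.V_u, rel_tol=1e-12):
            raise InvalidParameterError(
                f"V_t ({self.V_t}) must equal V_s + V_u ({self.V_s + self.V_u})"
            )
        if self.unstressed_split is None:
            c_total = self.C_AO + self.C_VC + self.C_PA + self.C_PU
            split = (
                0.0,
                self.V_u * self.C_AO / c_total,
                self.V_u * self.C_VC / c_total,
                0.0,
                self.V_u * self.C_PA / c_total,
                self.V_u * self.C_PU / c_total,
            )
            object.__setattr__(self, "unstressed_split", split)
        else:
            split = tuple(float(v) for v in self.unstressed_split)
            if len(split) != 6:
                raise InvalidParameterError("unstressed_split needs 6 entries")
            if any(v < 0 for v in split):
                raise InvalidParameterError("unstressed volumes must be >= 0")
            if not math.isclose(sum(split), self.V_u, rel_tol=1e-9):
                raise InvalidParameterError(
                    f"sum(unstressed_split) ({sum(split)}) must equal V_u ({self.V_u})"
                )
            object.__setattr__(self, "unstressed_split", split)

    @property
    def compliances(self) -> tuple[float, float, float, float]:
        return (self.C_AO, self.C_VC, self.C_PA, self.C_PU)

    @property
    def resistances(self) -> tuple[float, ...]:
        return (self.R_AV, self.R_SYS, self.R_TC, self.R_PV, self.R_PUL, self.R_MT)

    def with_(self, **kwargs) -> "CirculationParameters":
        """Return a copy with the given fields replaced.

        If volumes are changed inconsistently this re-raises the
        constructor's validation error.
        """
        return replace(self, **kwargs)

    def initial_state(self) -> "SystemState":
        """Default initial volume partition.

        Ventricles start at their configured initial volumes; the remaining
        stressed volume is spread over the passive compartments in
        proportion to compliance (so all passive compartments start at a
        common pressure), on top of their unstressed volumes.
        """
        v_vent = self.V_LV_init + self.V_RV_init
        v_rest = self.V_s - v_vent
        if v_rest < 0:
            raise InvalidParameterError(
                "ventricular initial volumes exceed total stressed volume"
            )
        c_total = self.C_AO + self.C_VC + self.C_PA + self.C_PU
        u = self.unstressed_split
        V = (
            self.V_LV_init,
            u[1] + v_rest * self.C_AO / c_total,
            u[2] + v_rest * self.C_VC / c_total,
            self.V_RV_init,
            u[4] + v_rest * self.C_PA / c_total,
            u[5] + v_rest * self.C_PU / c_total,
        )
        return SystemState(t=0.0, V=V)


@dataclass(frozen=True)
class SystemState:
    """Simulation time and the six compartment volumes [m³], ordered
    (LV, AO, VC, RV, PA, PU)."""

    t: float
    V: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        V = tuple(float(v) for v in self.V)
        if len(V) != 6:
            raise InvalidParameterError("SystemState.V needs 6 volumes")
        if any(v < 0 for v in V):
            raise InvalidParameterError("compartment volumes must be >= 0")
        object.__setattr__(self, "V", V)

    @property
    def total_volume(self) -> float:
        return sum(self.V)


@dataclass
class LoopRecord:
    """Time series produced by a simulation run.

    Columns follow the package-wide compartment/segment order.  ``L``,
    ``sigma`` and ``dLdt`` are populated only by muscle-coupled protocols.
    """

    t: np.ndarray                 # (n,)
    V: np.ndarray                 # (n, 6) volumes [m^3]
    P: np.ndarray                 # (n, 6) pressures [Pa]
    Q: np.ndarray                 # (n, 6) segment flows [m^3/s]
    dt: float
    period: float
    converged: bool = False
    cycles_run: int = 0
    L: np.ndarray | None = None       # muscle length [m]
    sigma: np.ndarray | None = None   # muscle stress [Pa]
    dLdt: np.ndarray | None = None    # muscle velocity [m/s]
    cycle_metrics: list[dict] = field(default_factory=list)
    label: str = ""

    def to_dataframe(self):
        import pandas as pd

        data = {"t": self.t}
        for i, c in enumerate(COMPARTMENTS):
            data[f"V_{c}"] = self.V[:, i]
        for i, c in enumerate(COMPARTMENTS):
            data[f"P_{c}"] = self.P[:, i]
        for i, s in enumerate(SEGMENTS):
            data[f"Q_{s}"] = self.Q[:, i]
        if self.L is not None:
            data["L"] = self.L
        if self.sigma is not None:
            data["sigma"] = self.sigma
        if self.dLdt is not None:
            data["dLdt"] = self.dLdt
        return pd.DataFrame(data)

    def summary(self) -> dict:
        out = {
            "converged": bool(self.converged),
            "cycles_run": int(self.cycles_run),
            "dt": self.dt,
            "period": self.period,
            "total_volume_drift_rel": float(
                np.max(np.abs(self.V.sum(axis=1) - self.V[0].sum()))
                / self.V[0].sum()
            ),
        }
        for i, c in enumerate(COMPARTMENTS):
            out[f"V_{c}_min"] = float(self.V[:, i].min())
            out[f"V_{c}_max"] = float(self.V[:, i].max())
            out[f"P_{c}_max"] = float(self.P[:, i].max())
        for i, s in enumerate(SEGMENTS):
            out[f"Q_{s}_min"] = float(self.Q[:, i].min())
        return out


# ---------------------------------------------------------------------------
# Elementary constitutive relations
# ---------------------------------------------------------------------------

def passive_pressure(V_x: float, V_u_x: float, C_x: float) -> float:
    """Pressure of a passive compartment: (V − V_u)/C, floored at zero.

    The unstressed volume ``V_u_x`` is the volume the compartment holds
    without raising its pressure above zero, so pressure is clamped to zero
    at or below it.
    """
    if C_x <= 0:
        raise InvalidParameterError("compliance must be > 0")
    return max(0.0, (V_x - V_u_x) / C_x)


def segment_flow(P_up: float, P_down: float, R: float, is_valve: bool = False) -> float:
    """Flow through a resistive segment, Q = (P_up − P_down)/R.

    Valve segments are ideal diodes: flow is clamped to zero whenever the
    downstream pressure exceeds the upstream pressure.
    """
    if R <= 0:
        raise InvalidParameterError("resistance must be > 0")
    q = (P_up - P_down) / R
    if is_valve and q < 0.0:
        return 0.0
    return q


def volume_derivatives(flows: Sequence[float]) -> np.ndarray:
    """Per-compartment dV/dt = inflow − outflow for the ring topology.

    ``flows`` is ordered as SEGMENTS.  Each flow drains its upstream
    compartment and fills its downstream one, so the six rates sum to zero
    exactly.
    """
    q_av, q_sys, q_tc, q_pv, q_pul, q_mt = flows
    return np.array([
        q_mt - q_av,    # LV
        q_av - q_sys,   # AO
        q_sys - q_tc,   # VC
        q_tc - q_pv,    # RV
        q_pv - q_pul,   # PA
        q_pul - q_mt,   # PU
    ])


def _ratio_rv_rule(params: CirculationParameters):
    """RV pressure slaved to LV pressure by the elastance ratio."""
    ratio = params.E_ESRV / params.E_ESLV

    def rule(t: float, v_rv: float, p_lv: float) -> float:
        return p_lv * ratio

    return rule


def system_pressures(
    state: SystemState,
    params: CirculationParameters,
    lv_pressure_source: Callable[[float, float], float],
    rv_pressure_source: Callable[[float, float, float], float] | None = None,
) -> np.ndarray:
    """Pressures of all six compartments at the given state.

    ``lv_pressure_source(t, V_LV)`` supplies LV pressure.  RV pressure comes
    from ``rv_pressure_source(t, V_RV, P_LV)``; by default it is LV pressure
    multiplied by the RV/LV end-systolic elastance ratio.
    """
    t = state.t
    V = state.V
    p_lv = lv_pressure_source(t, V[0])
    if not math.isfinite(p_lv):
        raise PressureSourceError(f"LV pressure source returned {p_lv!r} at t={t}")
    if rv_pressure_source is None:
        p_rv = p_lv * (params.E_ESRV / params.E_ESLV)
    else:
        p_rv = rv_pressure_source(t, V[3], p_lv)
    if not math.isfinite(p_rv):
        raise PressureSourceError(f"RV pressure source returned {p_rv!r} at t={t}")
    u = params.unstressed_split
    return np.array([
        p_lv,
        passive_pressure(V[1], u[1], params.C_AO),
        passive_pressure(V[2], u[2], params.C_VC),
        p_rv,
        passive_pressure(V[4], u[4], params.C_PA),
        passive_pressure(V[5], u[5], params.C_PU),
    ])


def _flows_from_pressures(
    P: Sequence[float],
    params: CirculationParameters,
    blocked: frozenset[str] = frozenset(),
) -> np.ndarray:
    R = params.resistances
    Q = np.empty(6)
    for i, seg in enumerate(SEGMENTS):
        if seg in blocked:
            Q[i] = 0.0
            continue
        up, down = SEGMENT_PATH[seg]
        Q[i] = segment_flow(P[_CIDX[up]], P[_CIDX[down]], R[i], seg in VALVE_SEGMENTS)
    return Q


def _clamp_flows_to_available(Q: np.ndarray, V: Sequence[float], dt: float) -> None:
    """Limit each segment flow so its donor cannot be driven below zero
    volume in one explicit step.  Positive flow drains the upstream
    compartment; negative flow (possible only through the two non-valve
    segments) drains the downstream one."""
    for i, seg in enumerate(SEGMENTS):
        up, down = SEGMENT_PATH[seg]
        if Q[i] > 0.0:
            avail = V[_CIDX[up]] / dt
            if Q[i] > avail:
                Q[i] = avail
        elif Q[i] < 0.0:
            avail = V[_CIDX[down]] / dt
            if -Q[i] > avail:
                Q[i] = -avail


def step_fixed(
    state: SystemState,
    dt: float,
    params: CirculationParameters,
    lv_pressure_source: Callable[[float, float], float],
    rv_pressure_source: Callable[[float, float, float], float] | None = None,
    pressure_clamp: Mapping[str, float] | None = None,
    blocked_segments: Iterable[str] = (),
) -> SystemState:
    """One explicit-Euler update V ← V + dt·dV/dt.

    Total volume is conserved to machine precision (every flow enters the
    bookkeeping once with each sign) and no compartment is driven below
    zero volume thanks to the per-step donor clamp.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    P = system_pressures(state, params, lv_pressure_source, rv_pressure_source)
    if pressure_clamp:
        for name, val in pressure_clamp.items():
            P[_CIDX[name]] = val
    Q = _flows_from_pressures(P, params, frozenset(blocked_segments))
    _clamp_flows_to_available(Q, state.V, dt)
    dV = volume_derivatives(Q)
    V_new = tuple(v + dt * dv for v, dv in zip(state.V, dV))
    return SystemState(t=state.t + dt, V=V_new)


# ---------------------------------------------------------------------------
# Fixed-step cycle runner
# ---------------------------------------------------------------------------

def run_cycles(
    state0: SystemState,
    params: CirculationParameters,
    lv_pressure_source: Callable[[float, float], float],
    n_cycles: int,
    period: float = DEFAULT_PERIOD,
    dt: float = DEFAULT_DT,
    rv_pressure_source: Callable[[float, float, float], float] | None = None,
    pressure_clamp: Mapping[str, float] | None = None,
    blocked_segments: Iterable[str] = (),
    ss_tol: float = DEFAULT_SS_TOL,
    record: str = "all",
    stop_at_steady_state: bool = True,
) -> LoopRecord:
    """Integrate the circulation for up to ``n_cycles`` stimulus periods.

    The run is flagged converged once the maximum cycle-to-cycle volume
    change, over all compartments and all samples within a period, falls
    below ``ss_tol`` (default 0.1 µL).  Failure to converge within
    ``n_cycles`` is reported on the record, not raised.

    ``record`` selects how much of the trajectory is returned: ``"all"``
    keeps every tick, ``"last"`` keeps only the final simulated cycle (the
    steady-state work-loop).  ``pressure_clamp`` maps compartment names to
    fixed pressures (overriding the constitutive relation) and
    ``blocked_segments`` forces the named segment flows to zero; both exist
    to carve reduced sub-circuits out of the full ring for comparator and
    verification studies.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    spc = int(round(period / dt))
    if abs(spc * dt - period) > 1e-9 * period:
        raise InvalidParameterError("period must be an integer number of ticks")
    if record not in ("all", "last"):
        raise InvalidParameterError("record must be 'all' or 'last'")

    blocked = frozenset(blocked_segments)
    clamp_items = tuple(
        (_CIDX[name], float(val)) for name, val in (pressure_clamp or {}).items()
    )
    if rv_pressure_source is None:
        rv_pressure_source = _ratio_rv_rule(params)

    # Unpack parameters into locals for the hot loop.
    r_av, r_sys, r_tc, r_pv, r_pul, r_mt = params.resistances
    inv_c = (0.0, 1.0 / params.C_AO, 1.0 / params.C_VC, 0.0,
             1.0 / params.C_PA, 1.0 / params.C_PU)
    u = params.unstressed_split
    blk = tuple(seg in blocked for seg in SEGMENTS)

    n_max = n_cycles * spc + 1
    if record == "all":
        t_arr = np.empty(n_max)
        V_arr = np.empty((n_max, 6))
        P_arr = np.empty((n_max, 6))
        Q_arr = np.empty((n_max, 6))
    else:
        t_arr = np.empty(spc + 1)
        V_arr = np.empty((spc + 1, 6))
        P_arr = np.empty((spc + 1, 6))
        Q_arr = np.empty((spc + 1, 6))

    prev_cycle = np.empty((spc, 6))
    cur_cycle = np.empty((spc, 6))

    v = list(state0.V)
    t = state0.t
    converged = False
    cycles_run = 0
    cycle_metrics: list[dict] = []
    lv_src = lv_pressure_source
    rv_src = rv_pressure_source

    k = 0  # write index into record arrays ("all" mode)
    for cycle in range(n_cycles):
        for j in range(spc):
            v0, v1, v2, v3, v4, v5 = v
            p0 = lv_src(t, v0)
            p3 = rv_src(t, v3, p0)
            p1 = (v1 - u[1]) * inv_c[1]
            if p1 < 0.0:
                p1 = 0.0
            p2 = (v2 - u[2]) * inv_c[2]
            if p2 < 0.0:
                p2 = 0.0
            p4 = (v4 - u[4]) * inv_c[4]
            if p4 < 0.0:
                p4 = 0.0
            p5 = (v5 - u[5]) * inv_c[5]
            if p5 < 0.0:
                p5 = 0.0
            if p0 != p0 or p3 != p3:  # NaN guard
                raise PressureSourceError(
                    f"non-finite ventricular pressure at t={t}"
                )
            for ci, val in clamp_items:
                if ci == 0:
                    p0 = val
                elif ci == 1:
                    p1 = val
                elif ci == 2:
                    p2 = val
                elif ci == 3:
                    p3 = val
                elif ci == 4:
                    p4 = val
                else:
                    p5 = val
            # Valve diodes clamp to forward flow; peripheral segments may
            # conduct backwards.
            q_av = (p0 - p1) / r_av
            if q_av < 0.0 or blk[0]:
                q_av = 0.0
            q_sys = 0.0 if blk[1] else (p1 - p2) / r_sys
            q_tc = (p2 - p3) / r_tc
            if q_tc < 0.0 or blk[2]:
                q_tc = 0.0
            q_pv = (p3 - p4) / r_pv
            if q_pv < 0.0 or blk[3]:
                q_pv = 0.0
            q_pul = 0.0 if blk[4] else (p4 - p5) / r_pul
            q_mt = (p5 - p0) / r_mt
            if q_mt < 0.0 or blk[5]:
                q_mt = 0.0
            # Donor clamp: no compartment may be driven below zero volume.
            lim = v0 / dt
            if q_av > lim:
                q_av = lim
            if q_sys > v1 / dt:
                q_sys = v1 / dt
            elif q_sys < -(v2 / dt):
                q_sys = -(v2 / dt)
            if q_tc > v2 / dt:
                q_tc = v2 / dt
            if q_pv > v3 / dt:
                q_pv = v3 / dt
            if q_pul > v4 / dt:
                q_pul = v4 / dt
            elif q_pul < -(v5 / dt):
                q_pul = -(v5 / dt)
            if q_mt > v5 / dt:
                q_mt = v5 / dt

            if record == "all":
                t_arr[k] = t
                V_arr[k, 0] = v0
                V_arr[k, 1] = v1
                V_arr[k, 2] = v2
                V_arr[k, 3] = v3
                V_arr[k, 4] = v4
                V_arr[k, 5] = v5
                P_arr[k, 0] = p0
                P_arr[k, 1] = p1
                P_arr[k, 2] = p2
                P_arr[k, 3] = p3
                P_arr[k, 4] = p4
                P_arr[k, 5] = p5
                Q_arr[k, 0] = q_av
                Q_arr[k, 1] = q_sys
                Q_arr[k, 2] = q_tc
                Q_arr[k, 3] = q_pv
                Q_arr[k, 4] = q_pul
                Q_arr[k, 5] = q_mt
                k += 1
            else:
                t_arr[j] = t
                V_arr[j, 0] = v0
                V_arr[j, 1] = v1
                V_arr[j, 2] = v2
                V_arr[j, 3] = v3
                V_arr[j, 4] = v4
                V_arr[j, 5] = v5
                P_arr[j, 0] = p0
                P_arr[j, 1] = p1
                P_arr[j, 2] = p2
                P_arr[j, 3] = p3
                P_arr[j, 4] = p4
                P_arr[j, 5] = p5
                Q_arr[j, 0] = q_av
                Q_arr[j, 1] = q_sys
                Q_arr[j, 2] = q_tc
                Q_arr[j, 3] = q_pv
                Q_arr[j, 4] = q_pul
                Q_arr[j, 5] = q_mt

            cur_cycle[j, 0] = v0
            cur_cycle[j, 1] = v1
            cur_cycle[j, 2] = v2
            cur_cycle[j, 3] = v3
            cur_cycle[j, 4] = v4
            cur_cycle[j, 5] = v5

            v[0] = v0 + dt * (q_mt - q_av)
            v[1] = v1 + dt * (q_av - q_sys)
            v[2] = v2 + dt * (q_sys - q_tc)
            v[3] = v3 + dt * (q_tc - q_pv)
            v[4] = v4 + dt * (q_pv - q_pul)
            v[5] = v5 + dt * (q_pul - q_mt)
            t += dt

        cycles_run = cycle + 1
        p_lv_cycle = P_arr[k - spc : k, 0] if record == "all" else P_arr[:spc, 0]
        metrics = {
            "cycle": cycles_run,
            "V_LV_min": float(cur_cycle[:, 0].min()),
            "V_LV_max": float(cur_cycle[:, 0].max()),
            "P_LV_max": float(p_lv_cycle.max()),
        }
        if cycle > 0:
            dv_cycle = float(np.max(np.abs(cur_cycle - prev_cycle)))
            metrics["max_cycle_volume_change"] = dv_cycle
            if dv_cycle < ss_tol:
                converged = True
        cycle_metrics.append(metrics)
        prev_cycle, cur_cycle = cur_cycle, prev_cycle
        if converged and stop_at_steady_state:
            break

    # Append the final state sample (pressures/flows recomputed for it).
    final_state = SystemState(t=t, V=tuple(v))
    P_end = system_pressures(final_state, params, lv_src, rv_src)
    for ci, val in clamp_items:
        P_end[ci] = val
    Q_end = _flows_from_pressures(P_end, params, blocked)
    if record == "all":
        t_arr[k] = t
        V_arr[k] = v
        P_arr[k] = P_end
        Q_arr[k] = Q_end
        n = k + 1
    else:
        t_arr[spc] = t
        V_arr[spc] = v
        P_arr[spc] = P_end
        Q_arr[spc] = Q_end
        n = spc + 1

    rec = LoopRecord(
        t=t_arr[:n].copy(),
        V=V_arr[:n].copy(),
        P=P_arr[:n].copy(),
        Q=Q_arr[:n].copy(),
        dt=dt,
        period=period,
        converged=converged,
        cycles_run=cycles_run,
        cycle_metrics=cycle_metrics,
    )
    logger.info(
        "run_cycles: %d cycle(s), converged=%s, final max cycle volume change=%s",
        cycles_run,
        converged,
        cycle_metrics[-1].get("max_cycle_volume_change", "n/a"),
    )
    return rec


# ---------------------------------------------------------------------------
# Reference integrator (verification oracle)
# ---------------------------------------------------------------------------

def reference_solution(
    state0: SystemState,
    params: CirculationParameters,
    lv_pressure_source: Callable[[float, float], float],
    t_end: float,
    rv_pressure_source: Callable[[float, float, float], float] | None = None,
    pressure_clamp: Mapping[str, float] | None = None,
    blocked_segments: Iterable[str] = (),
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-9,
) -> LoopRecord:
    """Adaptive high-order integration of the identical right-hand side.

    Intended as a verification oracle for the fixed-step loop, not as a
    production integrator.  Uses an embedded Runge-Kutta method at tight
    tolerance; the diode clamps make the right-hand side only piecewise
    smooth, which the adaptive step control resolves by brute force.
    """
    blocked = frozenset(blocked_segments)
    if rv_pressure_source is None:
        rv_pressure_source = _ratio_rv_rule(params)

    def rhs(t: float, V: np.ndarray) -> np.ndarray:
        st = SystemState(t=t, V=tuple(max(0.0, x) for x in V))
        P = system_pressures(st, params, lv_pressure_source, rv_pressure_source)
        if pressure_clamp:
            for name, val in pressure_clamp.items():
                P[_CIDX[name]] = val
        Q = _flows_from_pressures(P, params, blocked)
        return volume_derivatives(Q)

    sol = solve_ivp(
        rhs,
        (state0.t, t_end),
        np.array(state0.V),
        method="RK45",
        rtol=rtol,
        atol=1e-16,
        t_eval=t_eval,
        dense_output=False,
        max_step=(t_end - state0.t) / 50.0,
    )
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")

    n = sol.t.size
    P_out = np.empty((n, 6))
    Q_out = np.empty((n, 6))
    for i in range(n):
        st = SystemState(t=float(sol.t[i]), V=tuple(max(0.0, x) for x in sol.y[:, i]))
        P = system_pressures(st, params, lv_pressure_source, rv_pressure_source)
        if pressure_clamp:
            for name, val in pressure_clamp.items():
                P[_CIDX[name]] = val
        P_out[i] = P
        Q_out[i] = _flows_from_pressures(P, params, blocked)
    return LoopRecord(
        t=sol.t.copy(),
        V=sol.y.T.copy(),
        P=P_out,
        Q=Q_out,
        dt=float("nan"),
        period=DEFAULT_PERIOD,
        converged=True,
        cycles_run=0,
        label="reference",
    )
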