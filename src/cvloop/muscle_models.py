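"""Ventricular pressure sources and muscle↔ventricle geometry transforms.

Two pressure sources can drive the left ventricle of the circulation model:

* a *virtual trabecula* — a stress-length muscle emulator standing in for a
  hardware-mounted preparation.  Its twitch stress, evaluated at the
  commanded muscle length, is mapped to ventricular pressure through the
  law of Laplace for a thin-walled sphere, and ventricular volume is mapped
  back to commanded length through the sphere geometry;
* a *time-varying elastance* ventricle, P = e(t)·E_ES·(V − V0), used for
  fully in silico simulation and parameter validation.

The geometry chain is: ventricular volume → spherical radius
(V = 4/3·π·r³) → muscle length (L = r/r₀·L₀, capped at the optimal length
L₀ so the emulated preparation is never overstretched).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MuscleGeometry",
    "TwitchActivation",
    "VirtualTrabecula",
    "ellipse_csa",
    "stress_to_lv_pressure",
    "volume_to_radius",
    "radius_to_volume",
    "radius_to_length",
    "length_to_radius",
    "virtual_trabecula_stress",
    "elastance_ventricle_pressure",
    "ElastanceVentricle",
]


class InvalidGeometryError(ValueError):
    """A geometric quantity violates its physical constraint."""


def ellipse_csa(d_major: float, d_minor: float) -> float:
    """Cross-sectional area of an elliptical muscle section, π·d₁·d₂/4."""
    if d_major <= 0 or d_minor <= 0:
        raise InvalidGeometryError("diameters must be > 0")
    return math.pi * d_major * d_minor / 4.0


def volume_to_radius(V: float) -> float:
    """Radius of a sphere of volume V (V = 4/3·π·r³ inverted)."""
    if V < 0:
        raise InvalidGeometryError("volume must be >= 0")
    return (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)


def radius_to_volume(r: float) -> float:
    """Volume of a sphere of radius r."""
    if r < 0:
        raise InvalidGeometryError("radius must be >= 0")
    return 4.0 / 3.0 * math.pi * r ** 3


@dataclass(frozen=True)
class MuscleGeometry:
    """Trabecula and assumed-ventricle geometry.

    ``A`` is the muscle cross-sectional area [m²] and ``L_o`` its optimal
    length [m].  ``h`` is the assumed ventricular wall thickness and ``r_0``
    the reference ventricular radius at which the commanded muscle length
    equals L₀; only the ratio h/r enters the Laplace pressure map.
    """

    A: float
    L_o: float
    h: float = 1.1e-3
    r_0: float = 3.8e-3
    d_major: float | None = None
    d_minor: float | None = None

    def __post_init__(self) -> None:
        for name in ("A", "L_o", "h", "r_0"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be > 0")

    @classmethod
    def from_diameters(
        cls,
        d_major: float,
        d_minor: float,
        L_o: float,
        h: float = 1.1e-3,
        r_0: float = 3.8e-3,
    ) -> "MuscleGeometry":
        return cls(
            A=ellipse_csa(d_major, d_minor),
            L_o=L_o,
            h=h,
            r_0=r_0,
            d_major=d_major,
            d_minor=d_minor,
        )

    @property
    def volume(self) -> float:
        """Muscle volume A·L₀ [m³]."""
        return self.A * self.L_o


def stress_to_lv_pressure(sigma: float, geom: MuscleGeometry, r: float) -> float:
    """Laplace's law for a thin-walled sphere: P = 2·h·σ/r.

    With σ = F/A this is identical to the force form P = 2·h·F/(r·A).
    """
    if r <= 0:
        raise InvalidGeometryError("radius must be > 0")
    return 2.0 * geom.h * sigma / r


def radius_to_length(r: float, geom: MuscleGeometry) -> float:
    """Commanded muscle length for a ventricular radius: L = (r/r₀)·L₀,
    capped at L₀ so the muscle is never stretched past optimal length."""
    if r < 0:
        raise InvalidGeometryError("radius must be >= 0")
    L = (r / geom.r_0) * geom.L_o
    return min(L, geom.L_o)


def length_to_radius(L: float, geom: MuscleGeometry) -> float:
    """Inverse of the (uncapped) radius→length proportionality."""
    if L < 0:
        raise InvalidGeometryError("length must be >= 0")
    return (L / geom.L_o) * geom.r_0


@dataclass(frozen=True)
class TwitchActivation:
    """Normalized periodic activation waveform e(t) ∈ [0, 1].

    The parametric form is a rise-relaxation product
    ``(1 − exp(−t/τ_r))·exp(−t/τ_d)`` normalized to unit peak, evaluated on
    t mod period.  Defaults (τ_r = 30 ms, τ_d = 110 ms at 2 Hz) give a
    twitch time course typical of rat trabeculae at 32 °C.  Alternatively a
    sampled waveform (t, e) covering one period may be supplied, which is
    interpolated linearly and renormalized to unit peak.
    """

    freq: float = 2.0
    tau_rise: float = 0.030
    tau_decay: float = 0.110
    samples: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    _peak: float = field(init=False, repr=False, default=1.0)

    def __post_init__(self) -> None:
        if self.freq <= 0:
            raise ValueError("stimulus frequency must be > 0")
        if self.samples is None:
            if self.tau_rise <= 0 or self.tau_decay <= 0:
                raise ValueError("time constants must be > 0")
            # Peak of the unnormalized waveform, from d/dt = 0:
            # t* = τ_r·ln((τ_r + τ_d)/τ_r).
            t_peak = self.tau_rise * math.log(
                (self.tau_rise + self.tau_decay) / self.tau_rise
            )
            peak = (1.0 - math.exp(-t_peak / self.tau_rise)) * math.exp(
                -t_peak / self.tau_decay
            )
        else:
            ts, es = self.samples
            if len(ts) != len(es) or len(ts) < 3:
                raise ValueError("sampled waveform needs matched t/e arrays")
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError("sampled waveform times must be increasing")
            if min(es) < 0:
                raise ValueError("sampled activation must be >= 0")
            peak = max(es)
            if peak <= 0:
                raise ValueError("sampled activation must have positive peak")
        object.__setattr__(self, "_peak", peak)

    @property
    def period(self) -> float:
        return 1.0 / self.freq

    def __call__(self, t: float) -> float:
        tt = t % self.period
        if self.samples is None:
            e = (1.0 - math.exp(-tt / self.tau_rise)) * math.exp(
                -tt / self.tau_decay
            )
            return e / self._peak
        ts, es = self.samples
        return float(np.interp(tt, ts, es)) / self._peak

    def integral(self, n: int = 20000) -> float:
        """Time integral of e(t) over one period [s] (trapezoidal)."""
        tt = np.linspace(0.0, self.period, n, endpoint=False)
        ee = np.array([self(float(x)) for x in tt])
        return float(np.trapezoid(ee, dx=self.period / n))


@dataclass(frozen=True)
class VirtualTrabecula:
    """Stress-length muscle emulator.

    Total stress is σ(L, t) = e(t)·σ_active(L) + σ_passive(L).

    * σ_active rises linearly from zero at the slack length
      (``slack_rel``·L₀) to ``sigma_max`` at L₀ and is held constant above
      L₀ (the circulation never commands L > L₀ anyway).
    * σ_passive is the end-diastolic stress-length relation (EDSLR), an
      exponential ``a·(exp(b·(L/L₀ − slack)) − 1)`` above the slack length.
      This passive stress feeds back on diastolic restretch: it is what the
      pulmonary venous pressure works against while refilling the
      ventricle.  The defaults (a = 3 Pa, b = 30) give ≈1.2 kPa of passive
      stress at L₀ falling steeply below it — a compliant preparation whose
      diastolic Laplace pressure matches the venous return pressure the
      closed-loop circulation can generate, so the emergent end-diastolic
      length spans roughly L₀ down to 0.95 L₀ across the afterload range.
      The steep slope near L₀ is also what stabilizes the emergent
      end-diastolic length in closed-loop operation.
    * ``heat_coeff`` parameterizes a simple energetics surrogate used when
      no calorimetric measurement exists: active heat per twitch is
      ``heat_coeff·A·L₀·⟨σ_active⟩`` with ⟨·⟩ the cycle time-average, i.e.
      heat proportional to the tension-time integral.
    """

    geometry: MuscleGeometry
    activation: TwitchActivation = field(default_factory=TwitchActivation)
    sigma_max: float = 50.0e3
    slack_rel: float = 0.8
    passive_a: float = 3.0
    passive_b: float = 30.0
    heat_coeff: float = 0.25

    def __post_init__(self) -> None:
        if self.sigma_max <= 0:
            raise ValueError("sigma_max must be > 0")
        if not 0.0 < self.slack_rel < 1.0:
            raise ValueError("slack_rel must lie in (0, 1)")
        if self.passive_a < 0 or self.passive_b <= 0:
            raise ValueError("EDSLR parameters must be positive")

    def active_stress(self, L: float) -> float:
        """Peak (fully activated) active stress at length L [Pa]."""
        rel = L / self.geometry.L_o
        if rel <= self.slack_rel:
            return 0.0
        if rel >= 1.0:
            return self.sigma_max
        return self.sigma_max * (rel - self.slack_rel) / (1.0 - self.slack_rel)

    def passive_stress(self, L: float) -> float:
        """EDSLR: passive stress at length L [Pa], zero below slack."""
        rel = L / self.geometry.L_o
        if rel <= self.slack_rel:
            return 0.0
        return self.passive_a * (
            math.exp(self.passive_b * (rel - self.slack_rel)) - 1.0
        )

    def stress(self, L: float, t: float) -> float:
        """Total stress e(t)·σ_active(L) + σ_passive(L) [Pa]."""
        if L <= 0:
            raise InvalidGeometryError("length must be > 0")
        return self.activation(t) * self.active_stress(L) + self.passive_stress(L)

    def active_stress_at(self, L: float, t: float) -> float:
        return self.activation(t) * self.active_stress(L)


def virtual_trabecula_stress(m: VirtualTrabecula, L: float, t: float) -> float:
    """Functional alias for :meth:`VirtualTrabecula.stress`."""
    return m.stress(L, t)


def elastance_ventricle_pressure(
    V: float,
    t: float,
    E_ES: float,
    act: TwitchActivation,
    V_0: float = 0.0,
) -> float:
    """Time-varying elastance ventricle: P = e(t)·E_ES·(V − V₀).

    With the default V₀ = 0 the end-systolic pressure-volume relation is a
    line through the origin with slope E_ES.
    """
    if V < 0:
        raise InvalidGeometryError("volume must be >= 0")
    return act(t) * E_ES * max(0.0, V - V_0)


@dataclass(frozen=True)
class ElastanceVentricle:
    """Callable ventricular pressure source P(t, V) from Eq.-style
    time-varying elastance theory."""

    E_ES: float
    activation: TwitchActivation = field(default_factory=TwitchActivation)
    V_0: float = 0.0

    def __call__(self, t: float, V: float) -> float:
        return elastance_ventricle_pressure(V, t, self.E_ES, self.activation, self.V_0)

    def rv_source(self):
        """Adapter with the (t, V_RV, P_LV) signature the circulation
        expects for an independent right-ventricular source."""

        def rule(t: float, v_rv: float, p_lv: float) -> float:
            return self(t, v_rv)

        return rule
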