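"""Work-loop mechanoenergetics: stress/length normalization, loop work,
heat conversions and corrections, enthalpy, mechanical efficiency, and the
polynomial regression fits used for presentation.

Conventions
-----------
* Work per twitch is the area of the closed stress-length loop,
  W = −∮ σ·A dL; a counterclockwise loop in the (L, σ) plane — shortening
  under high stress, restretch under low stress — is positive.
* Heat per twitch converts thermopile voltage through
  heat = voltage / (sensitivity · stimulus frequency); the instrument-level
  defaults are 4000 V/W and 2 Hz.
* Active heat = total − basal − stimulus artifact, floored at zero (a
  negative result indicates inconsistent measurements and is flagged).
* Enthalpy = work + active heat; mechanical efficiency = work / enthalpy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnergeticsRecord",
    "RegressionFit",
    "LoopWorkResult",
    "normalize",
    "loop_work",
    "shortening_extent",
    "heat_per_twitch",
    "active_heat",
    "efficiency",
    "fit_relation",
]

DEFAULT_SENSITIVITY = 4000.0  # thermopile sensitivity [V/W]
DEFAULT_FREQ = 2.0            # stimulus frequency [Hz]


class EnergeticsError(ValueError):
    pass


@dataclass(frozen=True)
class EnergeticsRecord:
    """Per-twitch energy bookkeeping at steady state.

    All energies in joules; ``loop_area_norm`` is the normalized loop area
    in kPa·(L/L₀); ``shortening`` is the loop width as a fraction of L₀.
    Invariants: enthalpy = work + active heat exactly, and
    efficiency = work/enthalpy ∈ [0, 1).
    """

    work: float
    loop_area_norm: float
    shortening: float
    heat_total: float
    heat_basal: float
    heat_stim: float
    heat_active: float
    enthalpy: float
    efficiency: float

    @classmethod
    def from_components(
        cls,
        work: float,
        loop_area_norm: float,
        shortening: float,
        heat_total: float | None = None,
        heat_basal: float = 0.0,
        heat_stim: float = 0.0,
        heat_active: float | None = None,
    ) -> "EnergeticsRecord":
        """Assemble a record from either a total-heat measurement (basal and
        stimulus-artifact corrections applied here) or a direct active-heat
        value."""
        if heat_active is None:
            if heat_total is None:
                raise EnergeticsError("need heat_total or heat_active")
            heat_active = active_heat(heat_total, heat_basal, heat_stim)
        elif heat_total is None:
            heat_total = heat_active + heat_basal + heat_stim
        eff, enthalpy = efficiency(work, heat_active)
        return cls(
            work=work,
            loop_area_norm=loop_area_norm,
            shortening=shortening,
            heat_total=heat_total,
            heat_basal=heat_basal,
            heat_stim=heat_stim,
            heat_active=heat_active,
            enthalpy=enthalpy,
            efficiency=eff,
        )


def normalize(force: np.ndarray, length: np.ndarray, A: float, L_o: float):
    """Convert a force trace to stress (σ = F/A) and a length trace to
    relative length (L/L₀)."""
    if A <= 0:
        raise EnergeticsError("cross-sectional area must be > 0")
    if L_o <= 0:
        raise EnergeticsError("optimal length must be > 0")
    return np.asarray(force, dtype=float) / A, np.asarray(length, dtype=float) / L_o


@dataclass(frozen=True)
class LoopWorkResult:
    work: float             # absolute work per twitch [J]
    area_norm: float        # loop area in kPa·(L/L_o)
    closed: bool            # start/end matched within tolerance


def loop_work(
    sigma: np.ndarray,
    length: np.ndarray,
    A: float,
    L_o: float,
    close_rtol: float = 1e-3,
) -> LoopWorkResult:
    """Work per twitch as the shoelace area of the closed (σ, L) loop.

    ``sigma`` in Pa and ``length`` in metres over exactly one cycle.  The
    trajectory is treated as a polygon; if start and end do not coincide
    (beyond ``close_rtol`` of the trace ranges) the loop is flagged open and
    closed by the final segment.  Counterclockwise traversal (shortening at
    high stress) yields positive work.
    """
    sigma = np.asarray(sigma, dtype=float)
    length = np.asarray(length, dtype=float)
    if sigma.shape != length.shape or sigma.ndim != 1 or sigma.size < 3:
        raise EnergeticsError("sigma and length must be equal-length 1-D traces")
    if A <= 0 or L_o <= 0:
        raise EnergeticsError("A and L_o must be > 0")

    s_range = max(np.ptp(sigma), abs(sigma).max(), 1e-300)
    l_range = max(np.ptp(length), abs(length).max(), 1e-300)
    closed = (
        abs(sigma[0] - sigma[-1]) <= close_rtol * s_range
        and abs(length[0] - length[-1]) <= close_rtol * l_range
    )
    if not closed:
        warnings.warn(
            "stress-length trajectory does not close; closing with final segment",
            stacklevel=2,
        )
    # Shoelace: A = 1/2 Σ (x_i·y_{i+1} − x_{i+1}·y_i), positive for CCW.
    x = length
    y = sigma
    area = 0.5 * float(
        np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    )  # [Pa·m]
    work = area * A
    area_norm = area / L_o / 1e3  # kPa·(L/L_o)
    return LoopWorkResult(work=work, area_norm=area_norm, closed=closed)


def shortening_extent(length: np.ndarray, L_o: float) -> float:
    """Width of the work-loop: (max L − min L)/L₀ over one cycle."""
    if L_o <= 0:
        raise EnergeticsError("optimal length must be > 0")
    length = np.asarray(length, dtype=float)
    return float((length.max() - length.min()) / L_o)


def heat_per_twitch(
    voltage: float,
    sensitivity: float = DEFAULT_SENSITIVITY,
    freq: float = DEFAULT_FREQ,
) -> float:
    """Heat per twitch [J] from steady-state thermopile voltage [V]:
    voltage / (sensitivity · stimulus frequency)."""
    if sensitivity <= 0:
        raise EnergeticsError("thermopile sensitivity must be > 0")
    if freq <= 0:
        raise EnergeticsError("stimulus frequency must be > 0")
    return voltage / (sensitivity * freq)


def active_heat(total: float, basal: float, stim_artifact: float) -> float:
    """Active heat per twitch: total − basal − stimulus artifact.

    A negative result signals a measurement inconsistency; it is clamped to
    zero with a warning rather than propagated.
    """
    if total < 0 or basal < 0 or stim_artifact < 0:
        raise EnergeticsError("heat components must be >= 0")
    q = total - basal - stim_artifact
    if q < 0:
        warnings.warn(
            f"active heat {q:.3e} J < 0 (corrections exceed total); clamping to 0",
            stacklevel=2,
        )
        return 0.0
    return q


def efficiency(work: float, heat_active: float) -> tuple[float, float]:
    """Mechanical efficiency work/(work + active heat) and the enthalpy
    (work + active heat) it is normalized by."""
    if work < 0 or heat_active < 0:
        raise EnergeticsError("work and active heat must be >= 0")
    enthalpy = work + heat_active
    if enthalpy == 0:
        raise EnergeticsError("efficiency undefined: work and active heat both zero")
    return work / enthalpy, enthalpy


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary-least-squares polynomial fit, optionally on log-transformed
    predictor.  ``coefficients`` are in descending powers (numpy
    convention)."""

    transform: str
    order: int
    coefficients: np.ndarray
    x: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rss", float(np.sum(self.residuals ** 2)))

    def predict(self, x: np.ndarray) -> np.ndarray:
        xt = np.log(np.asarray(x, dtype=float)) if self.transform == "log" \
            else np.asarray(x, dtype=float)
        return np.polyval(self.coefficients, xt)


def fit_relation(
    x: np.ndarray,
    y: np.ndarray,
    transform: str = "identity",
    order: int = 2,
) -> RegressionFit:
    """Polynomial regression of y on x (or on log x), order 2 or 3.

    With exactly order + 1 points the fit interpolates exactly.
    """
    if transform not in ("identity", "log"):
        raise EnergeticsError("transform must be 'identity' or 'log'")
    if order not in (2, 3):
        raise EnergeticsError("order must be 2 or 3")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EnergeticsError("x and y must be equal-length 1-D arrays")
    if x.size < order + 1:
        raise EnergeticsError(
            f"need at least {order + 1} points for order-{order} fit, got {x.size}"
        )
    if transform == "log":
        if np.any(x <= 0):
            raise EnergeticsError("log transform requires positive x")
        xt = np.log(x)
    else:
        xt = x
    coeffs = np.polyfit(xt, y, order)
    fitted = np.polyval(coeffs, xt)
    return RegressionFit(
        transform=transform,
        order=order,
        coefficients=coeffs,
        x=x.copy(),
        fitted=fitted,
        residuals=y - fitted,
    )
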