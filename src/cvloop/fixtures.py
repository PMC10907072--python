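"""Deterministic fixture generator emulating the raw calorimeter signals.

No deposited experimental data accompany the method, so tests and worked
examples run on synthetic signals: a twitch force trace (the virtual
muscle's stress times its cross-sectional area) and a thermopile voltage
trace built from a *known* per-twitch (work, heat) schedule by inverting
the heat-per-twitch conversion.  Gaussian noise and a slow linear drift can
be layered on top.  The ground-truth schedule is written alongside, so the
energetics pipeline can be validated end-to-end: at zero noise it must
recover the schedule exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .energetics import heat_per_twitch
from .protocols import (
    WindkesselParameters,
    energetics_from_record,
    run_windkessel,
)

__all__ = ["FixtureBundle", "generate_fixtures", "recover_schedule"]

logger = logging.getLogger(__name__)

# Basal-heat surrogate: basal = b0 + b1·(shortening extent) + b2·⟨|dL/dt|⟩,
# reflecting the dependence of quiescent-muscle heat on the rate and extent
# of imposed length change.  Coefficients are fixture-scale choices (J,
# J per unit shortening, J·s/m).
BASAL_B0 = 0.3e-6
BASAL_B1 = 2.0e-6
BASAL_B2 = 2.0e-4
STIM_ARTIFACT_J = 0.05e-6


@dataclass
class FixtureBundle:
    """Synthetic calorimeter signals plus their generating ground truth."""

    force_t: np.ndarray
    force: np.ndarray            # [N]
    voltage_t: np.ndarray
    voltage: np.ndarray          # [V], noisy
    voltage_clean: np.ndarray    # [V], before noise/drift
    truth: pd.DataFrame          # per-twitch schedule
    period: float
    sensitivity: float
    seed: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        force_df = pd.DataFrame({"t": self.force_t, "F": self.force})
        volt_df = pd.DataFrame({"t": self.voltage_t, "voltage": self.voltage})
        for name, df, units in (
            ("force", force_df, "# units: t [s], F [N]"),
            ("voltage", volt_df, "# units: t [s], voltage [V]"),
            ("truth", self.truth, "# units: energies [J], shortening [L/L_o]"),
        ):
            p = out / f"fixture_{name}.csv"
            with open(p, "w") as fh:
                fh.write(f"# synthetic fixture (seed={self.seed})\n{units}\n")
                df.to_csv(fh, index=False, float_format="%.12e")
            paths[name] = p
        return paths


def generate_fixtures(config: RunConfig, seed: int | None = None) -> FixtureBundle:
    """Build a virtual-muscle run and derive calorimeter-like signals.

    The muscle performs fixed-end-diastolic-length work-loops at a few
    afterloads (each repeated), giving a non-trivial per-twitch schedule of
    work, active heat, basal heat and stimulus-artifact heat.  Total heat
    is inverted to a thermopile voltage level per twitch; the voltage trace
    is that staircase plus configured Gaussian noise and linear drift.
    """
    fx = config.fixtures
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    muscle = config.muscle
    T = muscle.activation.period
    freq = muscle.activation.freq

    n_levels = max(1, fx.n_twitches // fx.repeats)
    r_grid = np.geomspace(400e9, 80e9, n_levels)

    force_chunks: list[np.ndarray] = []
    rows = []
    p_ao = 0.0
    for r_p in r_grid:
        wk = WindkesselParameters.from_circulation(
            config.circulation.with_(R_SYS=float(r_p)), EDL=1.0
        )
        rec = run_windkessel(
            muscle, wk, n_cycles=80, dt=fx.dt, p_ao0=p_ao, record="last"
        )
        p_ao = float(rec.P[-1, 1])
        en = energetics_from_record(muscle, rec)
        basal = (
            BASAL_B0
            + BASAL_B1 * en.shortening
            + BASAL_B2 * float(np.mean(np.abs(rec.dLdt)))
        )
        total = en.heat_active + basal + STIM_ARTIFACT_J
        for _ in range(fx.repeats):
            force_chunks.append(rec.sigma[:-1] * muscle.geometry.A)
            rows.append(
                {
                    "R_p": float(r_p),
                    "work_J": en.work,
                    "active_J": en.heat_active,
                    "basal_J": basal,
                    "stim_J": STIM_ARTIFACT_J,
                    "total_J": total,
                    "enthalpy_J": en.enthalpy,
                    "efficiency": en.efficiency,
                    "shortening": en.shortening,
                }
            )

    truth = pd.DataFrame(rows)
    truth.insert(0, "twitch", np.arange(len(rows)))
    n_tw = len(rows)

    force = np.concatenate(force_chunks)
    force_t = np.arange(force.size) * fx.dt

    # Thermopile voltage: per-twitch constant level from inverting the
    # heat-per-twitch conversion, sampled at the (slow) thermal rate.
    samples_per_twitch = max(2, int(round(fx.sample_rate * T)))
    voltage_t = np.arange(n_tw * samples_per_twitch) / fx.sample_rate
    levels = truth["total_J"].to_numpy() * fx.sensitivity * freq
    voltage_clean = np.repeat(levels, samples_per_twitch)
    voltage = (
        voltage_clean
        + fx.drift_rate * voltage_t
        + rng.normal(0.0, fx.noise_sd, voltage_clean.size)
    )

    logger.info(
        "fixtures: %d twitches at %d afterload level(s), noise SD %.2e V",
        n_tw, n_levels, fx.noise_sd,
    )
    return FixtureBundle(
        force_t=force_t,
        force=force,
        voltage_t=voltage_t,
        voltage=voltage,
        voltage_clean=voltage_clean,
        truth=truth,
        period=T,
        sensitivity=fx.sensitivity,
        seed=seed,
    )


def recover_schedule(
    voltage_t: np.ndarray,
    voltage: np.ndarray,
    period: float,
    basal_J: np.ndarray,
    stim_J: np.ndarray,
    sensitivity: float = 4000.0,
    freq: float = 2.0,
) -> pd.DataFrame:
    """Run the heat pipeline on a voltage trace: per-twitch mean voltage →
    total heat → active heat after the basal and stimulus-artifact
    corrections.  The inverse of the fixture construction."""
    n_tw = int(round((voltage_t[-1] + (voltage_t[1] - voltage_t[0])) / period))
    idx = np.minimum((voltage_t / period).astype(int), n_tw - 1)
    rows = []
    for i in range(n_tw):
        v_mean = float(voltage[idx == i].mean())
        total = heat_per_twitch(v_mean, sensitivity, freq)
        from .energetics import active_heat

        rows.append(
            {
                "twitch": i,
                "total_J": total,
                "active_J": active_heat(total, float(basal_J[i]), float(stim_J[i])),
            }
        )
    return pd.DataFrame(rows)
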