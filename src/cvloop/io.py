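"""CSV/JSON writers and readers for run outputs.

Time series go to comma-separated files with '#'-prefixed metadata lines
(units, package version, seed, configuration digest) followed by a header
row; summaries go to JSON.  All numeric output uses enough digits for a
lossless float round trip.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_model import COMPARTMENTS, SEGMENTS, LoopRecord
from .protocols import SweepResult

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_run_summary",
    "write_sweep_summary",
]

logger = logging.getLogger(__name__)

_UNITS_LINE = (
    "# units: t [s], V_* [m^3], P_* [Pa], Q_* [m^3/s], "
    "L [m], sigma [Pa], dLdt [m/s]"
)


def _metadata_lines(seed=None, config_digest=None, label="") -> list[str]:
    lines = [f"# cvloop v{__version__}" + (f" | {label}" if label else "")]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config_digest is not None:
        lines.append(f"# config: {config_digest}")
    lines.append(_UNITS_LINE)
    return lines


def write_timeseries(
    record: LoopRecord,
    path: str | Path,
    seed: int | None = None,
    config_digest: str | None = None,
) -> Path:
    """Write a run's time series as tidy CSV with a commented header."""
    df = record.to_dataframe()
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValueError("record contains non-finite values; refusing to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _metadata_lines(seed, config_digest, record.label):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    logger.info("wrote %d samples to %s", len(df), path)
    return path


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_run_summary(
    record: LoopRecord,
    path: str | Path,
    seed: int | None = None,
    config_digest: str | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "version": __version__,
        "label": record.label,
        "seed": seed,
        "config": config_digest,
        **record.summary(),
        "cycle_metrics": record.cycle_metrics[-5:],
    }
    path.write_text(json.dumps(payload, indent=2, default=float))
    return path


def write_sweep_summary(
    result: SweepResult,
    path: str | Path,
    seed: int | None = None,
    config_digest: str | None = None,
) -> Path:
    """One row per afterload point: lengths, stresses and energetics."""
    rows = []
    for p in result.points:
        rows.append(
            {
                "R_SYS": p.R_SYS,
                "EDL_rel": p.EDL,
                "ESL_rel": p.ESL,
                "peak_stress_Pa": p.peak_stress,
                "shortening_rel": p.energetics.shortening,
                "work_J": p.energetics.work,
                "loop_area_kPa": p.energetics.loop_area_norm,
                "heat_active_J": p.energetics.heat_active,
                "enthalpy_J": p.energetics.enthalpy,
                "efficiency": p.energetics.efficiency,
                "converged": p.converged,
            }
        )
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# cvloop v{__version__} | sweep: {result.protocol}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if config_digest is not None:
            fh.write(f"# config: {config_digest}\n")
        fh.write(
            "# units: R_SYS [Pa·s/m^3], lengths [L/L_o], stress [Pa], "
            "energies [J]\n"
        )
        df.to_csv(fh, index=False, float_format="%.17g")
    logger.info("wrote sweep summary (%d points) to %s", len(df), path)
    return path
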