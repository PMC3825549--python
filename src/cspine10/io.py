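"""CSV writers and readers for curves, simulation results and design tables.

Conventions: comma-separated, '.' decimal, UTF-8, LF line endings, units in
the column names.  Package-wide units are N, mm, MPa, N*m and degrees;
conversions happen only at this boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .constitutive import LigamentCurve
from .errors import CSpineError
from .solver import SimulationResult

__all__ = [
    "write_corridor_csv",
    "read_corridor_csv",
    "write_curve_csv",
    "export_results",
    "read_result_csv",
    "export_table",
    "log_run_context",
]

logger = logging.getLogger(__name__)

_CSV_KW = dict(index=False, lineterminator="\n", encoding="utf-8")


def _wrap_io(path: Path, exc: Exception) -> CSpineError:
    return CSpineError(f"I/O failure for {path}: {exc}")


def write_corridor_csv(curve: np.ndarray, path: str | Path) -> None:
    """Write an (n, 2) moment-angle corridor as angle_deg,moment_Nm."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(curve, dtype=float), columns=["angle_deg", "moment_Nm"])
    try:
        df.to_csv(path, float_format="%.10g", **_CSV_KW)
    except OSError as exc:
        raise _wrap_io(path, exc) from exc


def read_corridor_csv(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except OSError as exc:
        raise _wrap_io(path, exc) from exc
    return df[["angle_deg", "moment_Nm"]].to_numpy(dtype=float)


def write_curve_csv(curve: LigamentCurve, path: str | Path) -> None:
    """Write a ligament force-deflection curve as deflection_mm,force_N."""
    path = Path(path)
    df = pd.DataFrame(curve.points, columns=["deflection_mm", "force_N"])
    try:
        df.to_csv(path, float_format="%.17g", **_CSV_KW)
    except OSError as exc:
        raise _wrap_io(path, exc) from exc


def export_results(result: SimulationResult, path: str | Path) -> list[Path]:
    """Write a simulation history plus its failure-event log.

    The history goes to ``path`` with the loading column named after the
    mode (displacement_mm for tension, angle_deg for bending) and the
    reaction column reaction_N or moment_Nm; the event log goes to
    ``<stem>_events.csv`` alongside.  Full float precision, deterministic
    bytes for a fixed input.
    """
    path = Path(path)
    tension_like = result.mode in ("tension", "whole_spine_tension")
    load_col = "displacement_mm" if tension_like else "angle_deg"
    react_col = "reaction_N" if tension_like else "moment_Nm"
    df = pd.DataFrame({load_col: result.displacement, react_col: result.reaction})
    events = pd.DataFrame(
        [
            {
                "step": ev.step,
                load_col: ev.displacement,
                "element": ev.element,
                "kind": ev.kind,
                "warning": ev.warning,
            }
            for ev in result.failure_events
        ],
        columns=["step", load_col, "element", "kind", "warning"],
    )
    events_path = path.with_name(path.stem + "_events.csv")
    try:
        df.to_csv(path, float_format="%.17g", **_CSV_KW)
        events.to_csv(events_path, float_format="%.17g", **_CSV_KW)
    except OSError as exc:
        raise _wrap_io(path, exc) from exc
    return [path, events_path]


def read_result_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except OSError as exc:
        raise _wrap_io(path, exc) from exc


def export_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a design/response table preserving its row order."""
    path = Path(path)
    try:
        table.to_csv(path, float_format="%.17g", **_CSV_KW)
    except OSError as exc:
        raise _wrap_io(path, exc) from exc
    return path


def log_run_context(cfg_hash: str, seed: int) -> None:
    """Log the reproducibility context: config hash, package version, seed."""
    from . import __version__

    logger.info(
        "run context: config_hash=%s version=%s seed=%d", cfg_hash, __version__, seed
    )
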