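"""Reading and writing marker trajectories (CSV, TRC, optional C3D).

The canonical interchange format is a plain CSV with header
``frame,<marker>_x,<marker>_y,<marker>_z,...``, one row per frame, NaN or an
empty cell marking a missing sample, and an optional leading comment line
``# frame_rate_hz: <rate>``.  A minimal Motion-Analysis/OpenSim-style TRC
dialect is supported for interoperability; C3D reading is available when the
optional ``ezc3d`` dependency is installed.  Units are millimetres
throughout; frames are 0-based in files and APIs.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import ObservationMask, TrajectoryMatrix, mask_from_nan

__all__ = ["read_trajectories", "write_trajectories", "write_gap_manifest"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # round-trip safe well below 1e-9 mm


def _atomicize(values: np.ndarray) -> np.ndarray:
    """A marker-frame with any missing coordinate loses all three (occlusion
    is all-or-nothing); returns the mask after enforcement."""
    observed = mask_from_nan(values)
    n_markers = values.shape[1] // 3
    for k in range(n_markers):
        sl = slice(3 * k, 3 * k + 3)
        partial = observed[:, sl].any(axis=1) & ~observed[:, sl].all(axis=1)
        if partial.any():
            logger.info(
                "marker %d: %d frames with partially missing coordinates "
                "treated as fully missing",
                k,
                int(partial.sum()),
            )
            values[partial, sl] = np.nan
            observed[partial, sl] = False
    return observed


def _marker_names_from_columns(columns: list[str]) -> list[str]:
    names: list[str] = []
    expected_suffix = ("_x", "_y", "_z")
    coords = columns[1:]
    if len(coords) % 3 != 0:
        raise ValueError(f"expected 3 columns per marker, got {len(coords)} coordinate columns")
    for i in range(0, len(coords), 3):
        triple = coords[i : i + 3]
        base = triple[0][:-2]
        if [c.lower()[-2:] for c in triple] != list(expected_suffix) or any(
            not c.startswith(base) for c in triple
        ):
            raise ValueError(f"malformed coordinate columns {triple}; expected {base}_x,_y,_z")
        names.append(base)
    return names


def _read_csv(path: Path, frame_rate: float | None) -> TrajectoryMatrix:
    rate = frame_rate
    with open(path) as fh:
        pos = 0
        for line in fh:
            if line.startswith("#"):
                pos += 1
                if "frame_rate_hz" in line:
                    rate = float(line.split(":", 1)[1])
            else:
                break
    df = pd.read_csv(path, skiprows=pos)
    if df.columns[0].lower() != "frame":
        raise ValueError(f"{path}: first column must be 'frame', got {df.columns[0]!r}")
    names = _marker_names_from_columns(list(df.columns))
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return TrajectoryMatrix(values, rate if rate is not None else 240.0, names)


def _read_trc(path: Path) -> TrajectoryMatrix:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise ValueError(f"{path}: truncated TRC header")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    meta = dict(zip(header_keys, header_vals))
    rate = float(meta["DataRate"])
    n_frames = int(meta["NumFrames"])
    n_markers = int(meta["NumMarkers"])
    marker_row = lines[3].split("\t")
    names = [c for c in marker_row[2:] if c.strip()]
    if len(names) != n_markers:
        raise ValueError(
            f"{path}: NumMarkers={n_markers} but {len(names)} marker labels found"
        )
    data_lines = [l for l in lines[5:] if l.strip()]
    if len(data_lines) != n_frames:
        raise ValueError(f"{path}: NumFrames={n_frames} but {len(data_lines)} data rows found")
    values = np.full((n_frames, 3 * n_markers), np.nan)
    for r, line in enumerate(data_lines):
        cells = line.split("\t")
        if len(cells) != 2 + 3 * n_markers:
            raise ValueError(
                f"{path}: line {6 + r}: expected {2 + 3 * n_markers} columns, got {len(cells)}"
            )
        for c, cell in enumerate(cells[2:]):
            cell = cell.strip()
            if cell and cell.lower() != "nan":
                values[r, c] = float(cell)
    return TrajectoryMatrix(values, rate, names)


def _read_c3d(path: Path) -> TrajectoryMatrix:
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D requires the optional 'ezc3d' package "
            "(pip install gaitfill[c3d]); convert to CSV/TRC otherwise"
        ) from exc
    c3d = ezc3d.c3d(str(path))
    points = c3d["data"]["points"]  # 4 x m x n
    residuals = c3d["data"]["meta_points"]["residuals"][0]  # m x n
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    names = [str(n) for n in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    n = points.shape[2]
    values = np.full((n, 3 * len(names)), np.nan)
    for k in range(len(names)):
        xyz = points[:3, k, :].T  # n x 3
        invalid = residuals[k] < 0
        xyz = xyz.copy()
        xyz[invalid] = np.nan
        values[:, 3 * k : 3 * k + 3] = xyz
    return TrajectoryMatrix(values, rate, names)


def read_trajectories(
    path: str | Path, dialect: str | None = None, frame_rate: float | None = None
) -> tuple[TrajectoryMatrix, ObservationMask]:
    """Read marker trajectories; missing samples become NaN and the mask.

    ``dialect`` is inferred from the suffix (.csv / .trc / .c3d) when not
    given.  Partially missing marker-frames are promoted to fully missing.
    """
    path = Path(path)
    dialect = dialect or path.suffix.lstrip(".").lower()
    if dialect == "csv":
        traj = _read_csv(path, frame_rate)
    elif dialect == "trc":
        traj = _read_trc(path)
    elif dialect == "c3d":
        traj = _read_c3d(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected csv, trc or c3d")
    observed = _atomicize(traj.values)
    return traj, ObservationMask(observed)


def write_trajectories(
    matrix: TrajectoryMatrix,
    mask: ObservationMask | None,
    path: str | Path,
    dialect: str | None = None,
) -> None:
    """Write trajectories; entries unobserved in ``mask`` serialise as NaN."""
    path = Path(path)
    dialect = dialect or path.suffix.lstrip(".").lower()
    values = matrix.values.copy()
    if mask is not None:
        mask.check_compatible(matrix)
        values[~mask.observed] = np.nan
        dead = np.flatnonzero((~mask.observed).all(axis=0))
        if dead.size:
            logger.warning("writing %d channel(s) with no observed samples", dead.size)

    if dialect == "csv":
        cols = ["frame"] + [
            f"{name}_{c}" for name in matrix.marker_names for c in ("x", "y", "z")
        ]
        df = pd.DataFrame(
            np.column_stack([np.arange(matrix.n_frames), values]), columns=cols
        )
        df["frame"] = df["frame"].astype(int)
        with open(path, "w") as fh:
            fh.write(f"# frame_rate_hz: {matrix.frame_rate}\n")
            df.to_csv(fh, index=False, float_format=_FLOAT_FMT, na_rep="NaN")
    elif dialect == "trc":
        _write_trc(matrix, values, path)
    else:
        raise ValueError(f"unsupported output dialect {dialect!r}; expected csv or trc")


def _write_trc(matrix: TrajectoryMatrix, values: np.ndarray, path: Path) -> None:
    rate = matrix.frame_rate
    n, m = matrix.n_frames, matrix.n_markers
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{rate:g}\t{rate:g}\t{n}\t{m}\tmm\t{rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(matrix.marker_names) + "\t\t",
        "\t\t" + "\t".join(f"X{k + 1}\tY{k + 1}\tZ{k + 1}" for k in range(m)),
    ]
    for r in range(n):
        cells = [str(r + 1), _FLOAT_FMT % (r / rate)]
        for v in values[r]:
            cells.append("" if math.isnan(v) else _FLOAT_FMT % v)
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def write_gap_manifest(gaps, marker_names, path: str | Path) -> None:
    """Gap manifest CSV: marker label, half-open frame interval [start, end)."""
    df = pd.DataFrame(
        [(marker_names[g.marker], g.start, g.end) for g in gaps],
        columns=["marker", "start_frame", "end_frame"],
    )
    df.to_csv(path, index=False)
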