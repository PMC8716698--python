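"""Readers and writers for the text formats the pipeline exchanges.

GRO coordinate frames (fixed-width records) are read into pandas frames
with atom tags preserved for head-group selection; series data use the
XVG dialect ('#'/'@' comment and metadata lines, whitespace-delimited
numeric columns).  CSV outputs embed the resolved parameters and the
package version as '#'-comment headers so every artifact is
self-describing and reruns are byte-identical.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import Frame, PoreSeries, PressureTensorSeries, SyntheticTrajectory


class FormatError(ValueError):
    """Raised for malformed coordinate or series files, naming the spot."""


# --- GRO coordinate frames -------------------------------------------------

def read_gro_frames(path):
    """Yield (title, atoms, box) per frame of a (possibly concatenated) GRO file.

    ``atoms`` is a DataFrame with columns resid, resname, name, x, y, z
    (nm); ``box`` is the (lx, ly, lz) vector.  Malformed counts or box
    lines raise :class:`FormatError` with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_index = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i].rstrip("\n")
        if i + 1 >= len(lines):
            raise FormatError(f"{path}: truncated frame {frame_index} (missing atom count)")
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError:
            raise FormatError(
                f"{path}:{i + 2}: malformed atom count {lines[i + 1].strip()!r}"
            ) from None
        end = i + 2 + n_atoms
        if end >= len(lines):
            raise FormatError(f"{path}: truncated frame {frame_index} (expected {n_atoms} atoms)")
        rows = []
        for j in range(i + 2, end):
            line = lines[j]
            try:
                rows.append(
                    {
                        "resid": int(line[0:5]),
                        "resname": line[5:10].strip(),
                        "name": line[10:15].strip(),
                        "x": float(line[20:28]),
                        "y": float(line[28:36]),
                        "z": float(line[36:44]),
                    }
                )
            except (ValueError, IndexError):
                raise FormatError(f"{path}:{j + 1}: malformed atom record") from None
        box_fields = lines[end].split()
        if len(box_fields) < 3:
            raise FormatError(f"{path}:{end + 1}: malformed box line")
        try:
            box = tuple(float(v) for v in box_fields[:3])
        except ValueError:
            raise FormatError(f"{path}:{end + 1}: malformed box line") from None
        yield title, pd.DataFrame(rows), box
        i = end + 1
        frame_index += 1


def write_gro_frames(traj: SyntheticTrajectory, path, resname: str = "LIP", atom_name: str = "HG"):
    """Write a synthetic trajectory as concatenated GRO coordinate blocks.

    The 2-D head positions are stored with z fixed at the monolayer
    plane (h_z / 2).
    """
    path = Path(path)
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"synthetic monolayer t= {frame.time:.3f} ps\n")
            fh.write(f"{frame.n_lipids:5d}\n")
            z = frame.h_z / 2.0
            for k, (x, y) in enumerate(frame.positions, start=1):
                fh.write(
                    f"{k % 100000:5d}{resname:<5s}{atom_name:>5s}{k % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{frame.h_xy:10.5f}{frame.h_xy:10.5f}{frame.h_z:10.5f}\n")


def frames_from_gro(path, time_per_frame: float = 1.0):
    """Read a GRO file written by :func:`write_gro_frames` back into Frames."""
    frames = []
    for k, (title, atoms, box) in enumerate(read_gro_frames(path)):
        time = k * time_per_frame
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        frames.append(
            Frame(
                time=time,
                positions=atoms[["x", "y"]].to_numpy(),
                h_xy=box[0],
                h_z=box[2],
            )
        )
    return frames


# --- XVG-style series ------------------------------------------------------

def read_xvg_series(path):
    """Numeric columns of an XVG-dialect file, skipping '#'/'@' lines.

    Returns (data ndarray, metadata lines).  Ragged rows raise
    :class:`FormatError` with the row number.
    """
    path = Path(path)
    meta, rows, width = [], [], None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("#", "@")):
                meta.append(stripped)
                continue
            fields = stripped.split()
            try:
                values = [float(v) for v in fields]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric data row") from None
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(values)} columns, expected {width})"
                )
            rows.append(values)
    if not rows:
        raise FormatError(f"{path}: no numeric data rows")
    return np.array(rows), meta


def write_xvg_series(path, data, column_labels, comments=()):
    """Write numeric columns as XVG-dialect text with '@' column labels."""
    path = Path(path)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    with open(path, "w") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        for k, label in enumerate(column_labels):
            fh.write(f"@ s{k} legend \"{label}\"\n")
        for row in data:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_pressure_series(path, pressure_unit: str, h_z: float, n_interfaces: int = 2):
    """Pressure-tensor series from an XVG file (columns: time, Px, Py, Pz).

    ``pressure_unit`` declares the file's pressure columns ("bar" or
    "MPa"); values are converted to the package's MPa convention.
    """
    from .units import convert_units

    data, _ = read_xvg_series(path)
    if data.shape[1] < 4:
        raise FormatError(f"{path}: need 4 columns (time, Px, Py, Pz)")
    scale = convert_units(1.0, pressure_unit, "MPa")
    return PressureTensorSeries(
        times=data[:, 0],
        Px=data[:, 1] * scale,
        Py=data[:, 2] * scale,
        Pz=data[:, 3] * scale,
        h_z=h_z,
        n_interfaces=n_interfaces,
    )


# --- CSV with self-describing headers --------------------------------------

def write_csv_with_header(path, df: pd.DataFrame, params: dict | None = None):
    """CSV with '#'-comment lines embedding version and resolved parameters."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# sapfilm {__version__}\n")
    for key in sorted(params or {}):
        buf.write(f"# {key} = {params[key]}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_csv_with_header(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_pore_series_xvg(path, series: PoreSeries):
    """Two-column (time ps, pore fraction) XVG output."""
    write_xvg_series(
        path,
        np.column_stack([series.times, series.pore_fraction]),
        ["time_ps", "pore_fraction"],
        comments=[
            f"grid M={series.grid.M} spacing_nm={series.grid.spacing:.6g} "
            f"offset_nm={series.grid.offset:.6g} policy={series.grid_policy}"
        ],
    )
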