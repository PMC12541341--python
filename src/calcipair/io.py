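"""Readers and writers for the three text formats the pipeline touches.

* extended-XYZ dialect: per frame a count line, a comment line
  ``Lattice="Lx 0 0 0 Ly 0 0 0 Lz" Time=<ps> Wrapped=<T|F>``, then one
  ``label x y z`` record per particle.
* COLVAR dialect: ``#! FIELDS time <cv...> opes.bias wall.bias`` header and
  whitespace-separated numeric rows.
* FES grid text: ``#! FIELDS <cv...> free_energy`` plus ``#! SET`` lines with
  axis metadata, one row per grid point with the last axis fastest.

Numbers are serialized with 6 decimal places and deterministic column order;
all readers/writers round-trip within 1e-6.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cvtable import BIAS_COL, BIAS_FILE_COL, TIME_COL, WALL_COL, WALL_FILE_COL, CVRecordTable
from .errors import ParseError
from .fes import FESAxis, FESGrid
from .geometry import SimulationBox, require_orthorhombic
from .trajectory import DEFAULT_SPECIES, Frame, Trajectory

logger = logging.getLogger(__name__)

_FMT = "%.6f"


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_KEYVAL_RE = re.compile(r'(\w+)=("[^"]*"|\S+)')


def _parse_comment_line(comment: str, lineno: int) -> tuple[SimulationBox, float, bool]:
    pairs = dict(_KEYVAL_RE.findall(comment))
    if "Lattice" not in pairs:
        raise ParseError("comment line missing Lattice=...", lineno)
    lattice_values = pairs["Lattice"].strip('"').split()
    if len(lattice_values) != 9:
        raise ParseError(
            f"Lattice must have 9 components, got {len(lattice_values)}", lineno
        )
    lattice = np.array([float(v) for v in lattice_values]).reshape(3, 3)
    edges = require_orthorhombic(lattice)
    time = float(pairs.get("Time", "0").strip('"'))
    wrapped = pairs.get("Wrapped", "F").strip('"').upper() in ("T", "TRUE", "1")
    return SimulationBox(edges), time, wrapped


def read_extended_xyz(
    path: str | Path, alphabet: Sequence[str] | None = DEFAULT_SPECIES
) -> Trajectory:
    """Read a (possibly multi-frame) extended-XYZ file into a Trajectory."""
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"expected particle count, got {lines[i]!r}", i + 1) from exc
        if i + 1 >= len(lines):
            raise ParseError("missing comment line after count", i + 2)
        box, time, wrapped = _parse_comment_line(lines[i + 1], i + 2)
        records = lines[i + 2 : i + 2 + count]
        if len(records) < count or any(len(r.split()) < 4 for r in records):
            bad = i + 2 + next(
                (j for j, r in enumerate(records) if len(r.split()) < 4), len(records)
            )
            raise ParseError(
                f"frame starting at line {i + 1} declares {count} particles "
                "but records are missing or malformed",
                bad + 1,
            )
        species = []
        positions = np.empty((count, 3))
        for j, rec in enumerate(records):
            parts = rec.split()
            species.append(parts[0])
            try:
                positions[j] = [float(x) for x in parts[1:4]]
            except ValueError as exc:
                raise ParseError(f"bad coordinate in record {rec!r}", i + 3 + j) from exc
        if alphabet is not None:
            unknown = sorted(set(species) - set(alphabet))
            if unknown:
                raise ParseError(f"unknown species labels {unknown}", i + 3)
        frames.append(Frame(tuple(species), positions, box, time=time, wrapped=wrapped))
        i += 2 + count
    if not frames:
        raise ParseError("no frames found", 1)
    return Trajectory.from_frames(frames)


def write_extended_xyz(path: str | Path, traj: Trajectory) -> None:
    L = traj.box.edge_lengths
    lattice = (
        f'Lattice="{L[0]:.6f} 0.000000 0.000000 '
        f"0.000000 {L[1]:.6f} 0.000000 "
        f'0.000000 0.000000 {L[2]:.6f}"'
    )
    out = []
    for frame in traj:
        out.append(str(frame.n_atoms))
        wrapped = "T" if frame.wrapped else "F"
        out.append(f"{lattice} Time={frame.time:.6f} Wrapped={wrapped}")
        for label, pos in zip(frame.species, frame.positions):
            out.append(f"{label} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# COLVAR tables
# ---------------------------------------------------------------------------


def read_cv_table(path: str | Path) -> CVRecordTable:
    """Read a COLVAR-dialect whitespace table with a ``#! FIELDS`` header."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#!"):
        raise ParseError("first line must declare '#! FIELDS ...'", 1)
    header = lines[0].split()
    if header[:2] != ["#!", "FIELDS"]:
        raise ParseError(f"malformed FIELDS header: {lines[0]!r}", 1)
    fields = header[2:]
    if TIME_COL not in fields:
        raise ParseError("FIELDS must include a 'time' column", 1)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != len(fields):
            raise ParseError(
                f"row has {len(parts)} values but header declares {len(fields)} fields",
                lineno,
            )
        try:
            rows.append([float(x) for x in parts])
        except ValueError as exc:
            raise ParseError(f"non-numeric value in row {line!r}", lineno) from exc
    df = pd.DataFrame(rows, columns=fields)
    rename = {BIAS_FILE_COL: BIAS_COL, WALL_FILE_COL: WALL_COL}
    df = df.rename(columns=rename)
    if BIAS_COL not in df.columns:
        logger.warning(
            "%s: no '%s' column in FIELDS; bias_energy set identically to 0", path, BIAS_FILE_COL
        )
    return CVRecordTable(df)


def write_cv_table(path: str | Path, table: CVRecordTable) -> None:
    df = table.data
    ordered = [TIME_COL] + table.cv_names + [BIAS_COL, WALL_COL]
    fields = [
        {BIAS_COL: BIAS_FILE_COL, WALL_COL: WALL_FILE_COL}.get(c, c) for c in ordered
    ]
    out = ["#! FIELDS " + " ".join(fields)]
    arr = df[ordered].to_numpy()
    for row in arr:
        out.append(" ".join(_FMT % v for v in row))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FES grids
# ---------------------------------------------------------------------------


def write_fes(path: str | Path, fes: FESGrid) -> None:
    names = [ax.name for ax in fes.axes]
    out = ["#! FIELDS " + " ".join(names) + " free_energy"]
    for ax in fes.axes:
        out.append(f"#! SET min_{ax.name} {_FMT % ax.edges[0]}")
        out.append(f"#! SET max_{ax.name} {_FMT % ax.edges[-1]}")
        out.append(f"#! SET nbins_{ax.name} {ax.nbins}")
    out.append(f"#! SET min_subtracted {'T' if fes.min_subtracted else 'F'}")
    centers = [ax.centers for ax in fes.axes]
    # last axis fastest
    mesh = np.meshgrid(*centers, indexing="ij")
    flat_coords = [m.ravel() for m in mesh]
    flat_values = fes.values.ravel()
    for k in range(flat_values.size):
        coords = " ".join(_FMT % c[k] for c in flat_coords)
        v = flat_values[k]
        out.append(f"{coords} {'nan' if not np.isfinite(v) else _FMT % v}")
    Path(path).write_text("\n".join(out) + "\n")


def read_fes(path: str | Path) -> FESGrid:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise ParseError("first line must declare '#! FIELDS ...'", 1)
    fields = lines[0].split()[2:]
    if fields[-1] != "free_energy":
        raise ParseError("last field must be 'free_energy'", 1)
    names = fields[:-1]
    meta: dict[str, str] = {}
    data_rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line.startswith("#! SET"):
            parts = line.split()
            meta[parts[2]] = parts[3]
        elif line.strip() and not line.startswith("#"):
            parts = line.split()
            if len(parts) != len(fields):
                raise ParseError("row arity does not match FIELDS", lineno)
            data_rows.append([float(x) for x in parts])
    axes = []
    for name in names:
        try:
            lo = float(meta[f"min_{name}"])
            hi = float(meta[f"max_{name}"])
            nb = int(meta[f"nbins_{name}"])
        except KeyError as exc:
            raise ParseError(f"missing '#! SET' metadata for axis {name!r}") from exc
        axes.append(FESAxis.linear(name, lo, hi, nb))
    shape = tuple(ax.nbins for ax in axes)
    values = np.array([row[-1] for row in data_rows]).reshape(shape)
    min_subtracted = meta.get("min_subtracted", "F") == "T"
    return FESGrid(axes, values, min_subtracted=min_subtracted)


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------


def write_json_report(path: str | Path, report: dict) -> None:
    """Write a JSON report of scalar results (floats, ints, strings, lists)."""

    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")
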