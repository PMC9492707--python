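"""Reading and writing simulation-engine text formats.

Covers the ITEM-delimited trajectory dump dialect (absolute ``x y z`` and
fractional ``xs ys zs`` coordinate columns, optional ``mol``, ``q``,
``ix iy iz`` image flags and ``vx vy vz`` velocities), thermodynamic log
files with one or more ``Step ...`` column sections, and XYZ coordinate
files.  Orthorhombic cells only: dumps carrying triclinic tilt factors are
rejected.

Atom records are stored internally ordered by ascending atom id, so every
downstream module shares one indexing convention regardless of the order the
engine wrote the atoms in.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, StructureError
from .units import convert_units, si_factor  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)

PathOrStream = Union[str, Path, IO[str]]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxBounds:
    """Orthorhombic simulation cell, in the trajectory's native length units."""

    xlo: float
    xhi: float
    ylo: float
    yhi: float
    zlo: float
    zhi: float

    def __post_init__(self) -> None:
        for lo, hi, ax in (
            (self.xlo, self.xhi, "x"),
            (self.ylo, self.yhi, "y"),
            (self.zlo, self.zhi, "z"),
        ):
            if not hi > lo:
                raise ValueError(f"box bounds require hi > lo on {ax}: [{lo}, {hi}]")

    @property
    def lengths(self) -> np.ndarray:
        return np.array(
            [self.xhi - self.xlo, self.yhi - self.ylo, self.zhi - self.zlo]
        )

    @property
    def lows(self) -> np.ndarray:
        return np.array([self.xlo, self.ylo, self.zlo])

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))


@dataclass
class Frame:
    """One trajectory snapshot; per-atom arrays are ordered by ascending id."""

    step: int
    box: BoxBounds
    ids: np.ndarray
    types: np.ndarray
    positions: np.ndarray
    mol_ids: Optional[np.ndarray] = None
    images: Optional[np.ndarray] = None
    charges: Optional[np.ndarray] = None
    velocities: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.types = np.asarray(self.types, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(np.unique(self.ids)) != len(self.ids):
            raise StructureError(f"duplicate atom ids in frame at step {self.step}")
        if not np.all(np.isfinite(self.positions)):
            raise StructureError(f"non-finite positions in frame at step {self.step}")
        order = np.argsort(self.ids, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            self.ids = self.ids[order]
            self.types = self.types[order]
            self.positions = self.positions[order]
            for name in ("mol_ids", "images", "charges", "velocities"):
                arr = getattr(self, name)
                if arr is not None:
                    setattr(self, name, np.asarray(arr)[order])

    @property
    def n_atoms(self) -> int:
        return len(self.ids)


@dataclass
class Trajectory:
    """Ordered periodic snapshots sharing one atom-id set and unit style.

    ``dt_sample`` is the physical time between stored frames, in the native
    time unit of ``unit_style``.
    """

    frames: List[Frame]
    unit_style: str = "real"
    dt_sample: float = 1.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        ref = self.frames[0]
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != ref.n_atoms or not np.array_equal(fr.ids, ref.ids):
                raise StructureError(
                    f"frame {i} has a different atom set than frame 0"
                )
        steps = [fr.step for fr in self.frames]
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise StructureError("frame steps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) position stack."""
        return np.stack([fr.positions for fr in self.frames])


@dataclass
class ThermoTable:
    """One thermodynamic-output section of a log file, as a DataFrame."""

    data: pd.DataFrame
    run_label: str = ""

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    @property
    def columns(self) -> List[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# dump reading / writing
# ---------------------------------------------------------------------------


def _open(source: PathOrStream) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    return open(source, "r")


_COORD_SETS = (("x", "y", "z"), ("xs", "ys", "zs"))


def read_dump(source: PathOrStream) -> Trajectory:
    """Parse an ITEM-delimited text trajectory dump.

    One :class:`Frame` per ``ITEM: TIMESTEP`` block.  Wrapped coordinates are
    retained verbatim; fractional (``xs ys zs``) coordinates are converted to
    absolute positions using the frame's box bounds.

    Raises
    ------
    FormatError
        If the box-bounds block is missing, the per-atom header is absent, or
        the cell is triclinic.
    StructureError
        If the atom count changes between frames (the offending frame index
        is named).
    """
    fh = _open(source)
    close = not hasattr(source, "read")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()

    frames: List[Frame] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line.startswith("ITEM: TIMESTEP"):
            i += 1
            continue
        step = int(lines[i + 1].split()[0])
        i += 2
        n_atoms: Optional[int] = None
        box: Optional[BoxBounds] = None
        atoms_header: Optional[List[str]] = None
        rows: List[List[str]] = []
        while i < n_lines and not lines[i].startswith("ITEM: TIMESTEP"):
            item = lines[i].strip()
            if item.startswith("ITEM: NUMBER OF ATOMS"):
                n_atoms = int(lines[i + 1].split()[0])
                i += 2
            elif item.startswith("ITEM: BOX BOUNDS"):
                if any(t in item.split()[3:] for t in ("xy", "xz", "yz")):
                    raise FormatError(
                        "triclinic box bounds are not supported (orthorhombic only)"
                    )
                bounds = []
                for k in range(3):
                    parts = lines[i + 1 + k].split()
                    if len(parts) > 2:
                        raise FormatError(
                            "triclinic tilt factors are not supported (orthorhombic only)"
                        )
                    bounds.extend(float(p) for p in parts[:2])
                box = BoxBounds(*bounds)
                i += 4
            elif item.startswith("ITEM: ATOMS"):
                atoms_header = item.split()[2:]
                if not atoms_header:
                    raise FormatError("per-atom column header missing in ITEM: ATOMS")
                i += 1
                while i < n_lines and lines[i].strip() and not lines[i].startswith("ITEM:"):
                    rows.append(lines[i].split())
                    i += 1
            else:
                i += 1
        if box is None:
            raise FormatError(f"frame at step {step}: missing BOX BOUNDS block")
        if atoms_header is None:
            raise FormatError(f"frame at step {step}: missing ATOMS block")
        frame = _build_frame(step, box, atoms_header, rows)
        if frames and frame.n_atoms != frames[0].n_atoms:
            raise StructureError(
                f"frame index {len(frames)} (step {step}) has {frame.n_atoms} atoms, "
                f"expected {frames[0].n_atoms}"
            )
        frames.append(frame)
    if not frames:
        raise FormatError("no ITEM: TIMESTEP blocks found")
    return Trajectory(frames=frames)


def _build_frame(
    step: int, box: BoxBounds, header: Sequence[str], rows: List[List[str]]
) -> Frame:
    col = {name: k for k, name in enumerate(header)}
    if "id" not in col or "type" not in col:
        raise FormatError("dump ATOMS header must contain 'id' and 'type'")
    data = np.array(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(header):
        raise FormatError(f"frame at step {step}: ragged per-atom rows")

    def grab(*names: str) -> Optional[np.ndarray]:
        if all(n in col for n in names):
            return data[:, [col[n] for n in names]]
        return None

    pos = grab("x", "y", "z")
    if pos is None:
        frac = grab("xs", "ys", "zs")
        if frac is None:
            raise FormatError(
                f"frame at step {step}: no coordinate columns (x y z or xs ys zs)"
            )
        pos = box.lows + frac * box.lengths
    images = grab("ix", "iy", "iz")
    if images is not None:
        images = images.astype(np.int64)
    vel = grab("vx", "vy", "vz")
    return Frame(
        step=step,
        box=box,
        ids=data[:, col["id"]].astype(np.int64),
        types=data[:, col["type"]].astype(np.int64),
        positions=pos,
        mol_ids=data[:, col["mol"]].astype(np.int64) if "mol" in col else None,
        images=images,
        charges=data[:, col["q"]] if "q" in col else None,
        velocities=vel,
    )


def write_dump(traj: Trajectory, dest: PathOrStream) -> None:
    """Write a trajectory in the same ITEM-delimited dialect :func:`read_dump` parses.

    The column set reflects the fields actually present on the frames, so a
    read/write/read cycle is lossless and a second write is byte-identical.
    """
    fh = dest if hasattr(dest, "write") else open(dest, "w")
    close = not hasattr(dest, "write")
    try:
        for fr in traj.frames:
            cols = ["id", "type"]
            arrays: List[np.ndarray] = [fr.ids, fr.types]
            fmts = ["%d", "%d"]
            if fr.mol_ids is not None:
                cols.append("mol")
                arrays.append(fr.mol_ids)
                fmts.append("%d")
            if fr.charges is not None:
                cols.append("q")
                arrays.append(fr.charges)
                fmts.append("%.10g")
            cols += ["x", "y", "z"]
            fmts += ["%.10g"] * 3
            if fr.images is not None:
                cols += ["ix", "iy", "iz"]
                fmts += ["%d"] * 3
            if fr.velocities is not None:
                cols += ["vx", "vy", "vz"]
                fmts += ["%.10g"] * 3
            fh.write("ITEM: TIMESTEP\n%d\n" % fr.step)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % fr.n_atoms)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            fh.write("%.10g %.10g\n" % (fr.box.xlo, fr.box.xhi))
            fh.write("%.10g %.10g\n" % (fr.box.ylo, fr.box.yhi))
            fh.write("%.10g %.10g\n" % (fr.box.zlo, fr.box.zhi))
            fh.write("ITEM: ATOMS " + " ".join(cols) + "\n")
            for k in range(fr.n_atoms):
                parts: List[str] = []
                for arr, fmt in zip(arrays, fmts):
                    parts.append(fmt % arr[k])
                x, y, z = fr.positions[k]
                idx = 2 + (fr.mol_ids is not None) + (fr.charges is not None)
                parts = parts[:idx] + ["%.10g" % x, "%.10g" % y, "%.10g" % z] + parts[idx:]
                if fr.images is not None:
                    parts += ["%d" % v for v in fr.images[k]]
                if fr.velocities is not None:
                    parts += ["%.10g" % v for v in fr.velocities[k]]
                fh.write(" ".join(parts) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# thermo log reading
# ---------------------------------------------------------------------------


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_log_thermo(source: PathOrStream) -> List[ThermoTable]:
    """Extract thermodynamic-output tables from an engine log.

    A section starts at a header line whose first token is ``Step`` and whose
    tokens are all column names; numeric rows follow until any non-numeric
    interruption (restart banner, warning, end of run), which terminates the
    section.  Returns the sections in file order.

    Raises :class:`FormatError` when the log contains no thermo section.
    """
    fh = _open(source)
    close = not hasattr(source, "read")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()

    tables: List[ThermoTable] = []
    i = 0
    run_idx = 0
    while i < len(lines):
        tokens = lines[i].split()
        if tokens and tokens[0] == "Step" and not any(_is_number(t) for t in tokens):
            header = tokens
            rows: List[List[float]] = []
            i += 1
            while i < len(lines):
                rtoks = lines[i].split()
                if len(rtoks) == len(header) and all(_is_number(t) for t in rtoks):
                    rows.append([float(t) for t in rtoks])
                    i += 1
                else:
                    break
            df = pd.DataFrame(rows, columns=header)
            if (df["Step"].diff().dropna() < 0).any():
                raise StructureError(f"thermo section {run_idx}: Step decreases")
            tables.append(ThermoTable(data=df, run_label=f"run-{run_idx}"))
            run_idx += 1
        else:
            i += 1
    if not tables:
        raise FormatError("no thermo sections found in log")
    return tables


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------


def write_xyz(
    elements: Sequence[str],
    coords: Iterable[Sequence[float]],
    comment: str,
    dest: PathOrStream,
) -> None:
    """Write a standard XYZ file (count line, comment line, ``El x y z`` rows)."""
    coords = np.asarray(list(coords), dtype=float)
    if coords.size == 0:
        raise ValueError("cannot write an XYZ file with zero atoms")
    if len(elements) != len(coords):
        raise ValueError("element and coordinate counts differ")
    fh = dest if hasattr(dest, "write") else open(dest, "w")
    close = not hasattr(dest, "write")
    try:
        fh.write(f"{len(coords)}\n")
        fh.write(comment.replace("\n", " ") + "\n")
        for el, (x, y, z) in zip(elements, coords):
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
    finally:
        if close:
            fh.close()


def read_xyz(source: PathOrStream) -> tuple[List[str], np.ndarray, str]:
    """Read an XYZ file; returns (elements, coords, comment)."""
    fh = _open(source)
    close = not hasattr(source, "read")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    if len(lines) < 2:
        raise FormatError("XYZ file too short")
    n = int(lines[0].split()[0])
    comment = lines[1]
    elements: List[str] = []
    coords: List[List[float]] = []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        elements.append(parts[0])
        coords.append([float(p) for p in parts[1:4]])
    if len(elements) != n:
        raise FormatError("XYZ atom count does not match header")
    return elements, np.array(coords), comment


def dump_from_string(text: str) -> Trajectory:
    """Convenience: parse a dump given as an in-memory string."""
    return read_dump(io.StringIO(text))
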