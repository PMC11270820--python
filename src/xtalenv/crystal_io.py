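"""Trajectory frame I/O, molecule grouping and periodic neighbor lists.

Supported text formats: extended XYZ (``Lattice``/``Properties`` comment-line
dialect) and the LAMMPS text dump (``ITEM: ATOMS`` column auto-detection).
All coordinates are Cartesian Å; fractional (``xs ys zs``) dump coordinates
are converted at read time.  Atom and molecule indices are 0-based
internally; 1-based ids are written for the LAMMPS dialect.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SimulationFrame",
    "MoleculeGroup",
    "NeighborList",
    "ParseError",
    "ValidationError",
    "read_frames",
    "write_frames",
    "group_molecules",
    "minimum_image",
    "build_neighbor_list",
]

# fmt: off
_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm",
    "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W",
    "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At", "Rn",
    "Fr", "Ra", "Ac", "Th", "Pa", "U",
}
# fmt: on


class ParseError(ValueError):
    """Malformed file content; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(ValueError):
    """Semantically invalid data (bad element code, mismatched signature...)."""


@dataclass
class SimulationFrame:
    """One trajectory snapshot.

    Attributes
    ----------
    positions : (n, 3) float array, Cartesian Å.
    atom_types : element code per atom.
    cell : (3, 3) lattice-vector matrix (rows are lattice vectors), or
        ``None`` for non-periodic frames (clusters).
    pbc : periodicity flag per cell vector.
    molecule_ids : 0-based integer molecule label per atom, or ``None``
        when the source file carried none.
    """

    positions: np.ndarray
    atom_types: list[str]
    cell: np.ndarray | None = None
    pbc: tuple[bool, bool, bool] = (False, False, False)
    molecule_ids: np.ndarray | None = None
    frame_index: int = 0
    time: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        if self.molecule_ids is not None:
            self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("non-finite positions")
        if len(self.atom_types) != self.n_atoms:
            raise ValidationError("atom_types length mismatch")
        if any(self.pbc):
            if self.cell is None:
                raise ValidationError("periodic frame without a cell")
            if abs(np.linalg.det(self.cell)) < 1e-12:
                raise ValidationError("cell is not invertible")
        if self.molecule_ids is not None and len(self.molecule_ids) != self.n_atoms:
            raise ValidationError("molecule_ids length mismatch")


@dataclass
class MoleculeGroup:
    """Atoms of one molecule, in template order."""

    molecule_id: int
    atom_indices: list[int]
    species_signature: Counter = field(default_factory=Counter)


@dataclass
class NeighborList:
    """Ragged per-center neighbor lists with minimum-image displacements."""

    center_ids: np.ndarray
    neighbor_ids: list[np.ndarray]
    displacement_vectors: list[np.ndarray]
    cutoff: float

    def distances(self, i: int) -> np.ndarray:
        return np.linalg.norm(self.displacement_vectors[i], axis=1)


# ---------------------------------------------------------------------------
# periodic geometry


def _perpendicular_widths(cell: np.ndarray) -> np.ndarray:
    """Perpendicular width of the cell along each lattice direction."""
    vol = abs(np.linalg.det(cell))
    cross = np.stack(
        [
            np.cross(cell[1], cell[2]),
            np.cross(cell[2], cell[0]),
            np.cross(cell[0], cell[1]),
        ]
    )
    return vol / np.linalg.norm(cross, axis=1)


_SHIFTS = np.array(
    [
        [i, j, k]
        for i in (-2, -1, 0, 1, 2)
        for j in (-2, -1, 0, 1, 2)
        for k in (-2, -1, 0, 1, 2)
    ],
    dtype=float,
)


def minimum_image(delta: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """Shortest periodic image of displacement(s) ``delta`` under ``cell``.

    The fractional round is refined by a search over the 125 adjacent
    images, which is exact for any cell a half-cutoff-safe neighbor search
    can use (and for all but pathologically skewed cells in general).
    """
    cell = np.asarray(cell, dtype=float)
    if abs(np.linalg.det(cell)) < 1e-12:
        raise ValidationError("cell is not invertible")
    delta = np.asarray(delta, dtype=float)
    single = delta.ndim == 1
    d = delta.reshape(-1, 3)
    frac = d @ np.linalg.inv(cell)
    frac -= np.round(frac)
    base = frac @ cell
    # running minimum over the adjacent images, O(n) memory
    best = base.copy()
    best_n2 = np.einsum("ij,ij->i", base, base)
    for shift in _SHIFTS @ cell:
        if not shift.any():
            continue
        cand = base + shift
        n2 = np.einsum("ij,ij->i", cand, cand)
        mask = n2 < best_n2
        if mask.any():
            best[mask] = cand[mask]
            best_n2[mask] = n2[mask]
    return best[0] if single else best


def build_neighbor_list(
    points: np.ndarray,
    cell: np.ndarray | None,
    cutoff: float,
) -> NeighborList:
    """All pairs with (minimum-image) distance ≤ cutoff.

    For periodic systems the cutoff must not exceed half the smallest
    perpendicular cell width — image replication is not performed.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    n = len(points)
    if cell is not None:
        widths = _perpendicular_widths(np.asarray(cell, dtype=float))
        if cutoff > 0.5 * widths.min() + 1e-9:
            raise ValidationError(
                f"cutoff {cutoff:g} Å exceeds half the minimum cell width "
                f"({0.5 * widths.min():g} Å); replicate images explicitly"
            )
    neighbor_ids: list[np.ndarray] = [np.empty(0, dtype=int) for _ in range(n)]
    disp: list[np.ndarray] = [np.empty((0, 3)) for _ in range(n)]
    if n > 1:
        # chunked vectorized O(N^2) scan; N is at most a few thousand here
        chunk = max(1, int(2e6 // max(n, 1)))
        for start in range(0, n, chunk):
            stop = min(n, start + chunk)
            d = points[None, :, :] - points[start:stop, None, :]
            if cell is not None:
                d = minimum_image(d.reshape(-1, 3), cell).reshape(d.shape)
            dist = np.linalg.norm(d, axis=2)
            for i in range(start, stop):
                row = dist[i - start]
                mask = (row <= cutoff) & (np.arange(n) != i)
                neighbor_ids[i] = np.nonzero(mask)[0]
                disp[i] = d[i - start][mask]
    return NeighborList(
        center_ids=np.arange(n),
        neighbor_ids=neighbor_ids,
        displacement_vectors=disp,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# molecule grouping


def group_molecules(
    frame: SimulationFrame,
    molecule_size: int | None = None,
    template_species: Sequence[str] | None = None,
) -> list[MoleculeGroup]:
    """Group frame atoms into molecules.

    File-provided ``molecule_ids`` are honored (atom order within a group
    follows file order); otherwise atoms are grouped into contiguous blocks
    of ``molecule_size``.  When ``template_species`` is given, each group's
    species multiset is validated against it.
    """
    groups: list[MoleculeGroup] = []
    if frame.molecule_ids is not None:
        order: dict[int, list[int]] = {}
        for idx, mid in enumerate(frame.molecule_ids):
            order.setdefault(int(mid), []).append(idx)
        for new_id, mid in enumerate(sorted(order)):
            atoms = order[mid]
            groups.append(
                MoleculeGroup(
                    molecule_id=new_id,
                    atom_indices=atoms,
                    species_signature=Counter(frame.atom_types[i] for i in atoms),
                )
            )
    else:
        if molecule_size is None:
            raise ValidationError("molecule_size required when molecule_ids absent")
        if frame.n_atoms % molecule_size != 0:
            raise ValidationError(
                f"atom count {frame.n_atoms} not divisible by molecule_size {molecule_size}"
            )
        for new_id in range(frame.n_atoms // molecule_size):
            atoms = list(range(new_id * molecule_size, (new_id + 1) * molecule_size))
            groups.append(
                MoleculeGroup(
                    molecule_id=new_id,
                    atom_indices=atoms,
                    species_signature=Counter(frame.atom_types[i] for i in atoms),
                )
            )
    if template_species is not None:
        want = Counter(template_species)
        bad = [g.molecule_id for g in groups if g.species_signature != want]
        if bad:
            raise ValidationError(
                f"species signature mismatch for molecule_id(s) {bad}: expected {dict(want)}"
            )
    return groups


# ---------------------------------------------------------------------------
# extended XYZ

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_extxyz_comment(comment: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(comment)}


def _read_extxyz(lines: list[str]) -> list[SimulationFrame]:
    frames: list[SimulationFrame] = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise ParseError(f"expected atom count, got {lines[ln]!r}", ln + 1)
        if ln + 1 + natoms >= len(lines) + 1 and natoms > 0 and ln + 1 + natoms > len(lines):
            raise ParseError(f"truncated frame: {natoms} atoms declared", ln + 1)
        meta = _parse_extxyz_comment(lines[ln + 1])
        cell = None
        pbc = (False, False, False)
        if "Lattice" in meta:
            vals = [float(x) for x in meta["Lattice"].split()]
            if len(vals) != 9:
                raise ParseError("Lattice must have 9 numbers", ln + 2)
            cell = np.array(vals).reshape(3, 3)
            pbc = (True, True, True)
        if "pbc" in meta:
            toks = meta["pbc"].split()
            pbc = tuple(t in ("T", "True", "1") for t in toks)  # type: ignore[assignment]
        props = meta.get("Properties", "species:S:1:pos:R:3")
        fields = props.split(":")
        columns: list[tuple[str, str, int]] = []
        for i in range(0, len(fields), 3):
            columns.append((fields[i], fields[i + 1], int(fields[i + 2])))
        positions = np.zeros((natoms, 3))
        types: list[str] = []
        mol = None
        for a in range(natoms):
            row = lines[ln + 2 + a].split()
            col = 0
            for name, _kind, width in columns:
                vals = row[col : col + width]
                if len(vals) != width:
                    raise ParseError("short atom record", ln + 3 + a)
                if name == "species":
                    sym = vals[0]
                    if sym not in _ELEMENTS:
                        raise ValidationError(f"unknown element code {sym!r}")
                    types.append(sym)
                elif name == "pos":
                    positions[a] = [float(v) for v in vals]
                elif name == "mol":
                    if mol is None:
                        mol = np.zeros(natoms, dtype=int)
                    mol[a] = int(vals[0])
                col += width
        frames.append(
            SimulationFrame(
                positions=positions,
                atom_types=types,
                cell=cell,
                pbc=pbc,
                molecule_ids=mol,
                frame_index=len(frames),
                time=float(meta["Time"]) if "Time" in meta else None,
            )
        )
        ln += 2 + natoms
    return frames


def _write_extxyz(frames: Iterable[SimulationFrame], path: Path) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{fr.n_atoms}\n")
            parts = []
            if fr.cell is not None:
                lat = " ".join(f"{x:.10g}" for x in fr.cell.ravel())
                parts.append(f'Lattice="{lat}"')
            props = "species:S:1:pos:R:3"
            if fr.molecule_ids is not None:
                props += ":mol:I:1"
            parts.append(f"Properties={props}")
            parts.append('pbc="' + " ".join("T" if p else "F" for p in fr.pbc) + '"')
            if fr.time is not None:
                parts.append(f"Time={fr.time:.10g}")
            fh.write(" ".join(parts) + "\n")
            for a in range(fr.n_atoms):
                x, y, z = fr.positions[a]
                line = f"{fr.atom_types[a]} {x:.10f} {y:.10f} {z:.10f}"
                if fr.molecule_ids is not None:
                    line += f" {int(fr.molecule_ids[a])}"
                fh.write(line + "\n")


# ---------------------------------------------------------------------------
# LAMMPS text dump


def _read_lammps_dump(
    lines: list[str], type_map: dict[int, str] | None
) -> list[SimulationFrame]:
    frames: list[SimulationFrame] = []
    ln = 0
    nlines = len(lines)
    while ln < nlines:
        if not lines[ln].strip():
            ln += 1
            continue
        if not lines[ln].startswith("ITEM: TIMESTEP"):
            raise ParseError(f"expected 'ITEM: TIMESTEP', got {lines[ln]!r}", ln + 1)
        step = int(lines[ln + 1])
        if not lines[ln + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise ParseError("expected 'ITEM: NUMBER OF ATOMS'", ln + 3)
        natoms = int(lines[ln + 3])
        bounds_hdr = lines[ln + 4]
        if not bounds_hdr.startswith("ITEM: BOX BOUNDS"):
            raise ParseError("expected 'ITEM: BOX BOUNDS'", ln + 5)
        toks = bounds_hdr.split()[3:]
        triclinic = any(t in ("xy", "xz", "yz") for t in toks)
        pbc_toks = [t for t in toks if t in ("pp", "ff", "sm", "fs", "fm")]
        pbc = tuple(t == "pp" for t in pbc_toks) if len(pbc_toks) == 3 else (True,) * 3
        rows = [lines[ln + 5 + i].split() for i in range(3)]
        if triclinic:
            (xlo_b, xhi_b, xy), (ylo_b, yhi_b, xz), (zlo, zhi, yz) = (
                tuple(map(float, r)) for r in rows
            )
            xlo = xlo_b - min(0.0, xy, xz, xy + xz)
            xhi = xhi_b - max(0.0, xy, xz, xy + xz)
            ylo = ylo_b - min(0.0, yz)
            yhi = yhi_b - max(0.0, yz)
            cell = np.array(
                [[xhi - xlo, 0, 0], [xy, yhi - ylo, 0], [xz, yz, zhi - zlo]]
            )
        else:
            (xlo, xhi), (ylo, yhi), (zlo, zhi) = (tuple(map(float, r[:2])) for r in rows)
            cell = np.diag([xhi - xlo, yhi - ylo, zhi - zlo])
        atoms_hdr = lines[ln + 8]
        if not atoms_hdr.startswith("ITEM: ATOMS"):
            raise ParseError("expected 'ITEM: ATOMS'", ln + 9)
        cols = atoms_hdr.split()[2:]
        ci = {name: i for i, name in enumerate(cols)}
        scaled = "xs" in ci
        if not scaled and "x" not in ci:
            raise ParseError("dump has neither x/y/z nor xs/ys/zs columns", ln + 9)
        positions = np.zeros((natoms, 3))
        types: list[str] = [""] * natoms
        mol = np.zeros(natoms, dtype=int) if "mol" in ci else None
        ids = np.zeros(natoms, dtype=int)
        for a in range(natoms):
            row = lines[ln + 9 + a].split()
            ids[a] = int(row[ci["id"]]) if "id" in ci else a + 1
            if scaled:
                frac = np.array([float(row[ci[c]]) for c in ("xs", "ys", "zs")])
                positions[a] = frac @ cell
            else:
                positions[a] = [float(row[ci[c]]) for c in ("x", "y", "z")]
            if "element" in ci:
                types[a] = row[ci["element"]]
            elif "type" in ci:
                t = int(row[ci["type"]])
                if type_map is not None:
                    if t not in type_map:
                        raise ValidationError(f"type {t} missing from type_map")
                    types[a] = type_map[t]
                else:
                    types[a] = f"X{t}"  # opaque placeholder code
            if mol is not None:
                mol[a] = int(row[ci["mol"]])
        order = np.argsort(ids, kind="stable")
        positions = positions[order]
        types = [types[i] for i in order]
        if mol is not None:
            mol = mol[order] - mol.min()  # 0-based internally
        frames.append(
            SimulationFrame(
                positions=positions,
                atom_types=types,
                cell=cell,
                pbc=pbc,  # type: ignore[arg-type]
                molecule_ids=mol,
                frame_index=len(frames),
                time=float(step),
            )
        )
        ln += 9 + natoms
    return frames


def _write_lammps_dump(frames: Iterable[SimulationFrame], path: Path) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{int(fr.time) if fr.time is not None else fr.frame_index}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{fr.n_atoms}\n")
            cell = fr.cell
            if cell is None:
                lo = fr.positions.min(axis=0) - 1.0
                hi = fr.positions.max(axis=0) + 1.0
                cell = np.diag(hi - lo)
                flags = ["ff"] * 3
            else:
                offdiag = cell - np.diag(np.diag(cell))
                if np.abs(offdiag).max() > 1e-10:
                    raise ValidationError(
                        "LAMMPS dump writer supports orthogonal cells only"
                    )
                lo = np.zeros(3)
                hi = np.diag(cell)
                flags = ["pp" if p else "ff" for p in fr.pbc]
            fh.write("ITEM: BOX BOUNDS " + " ".join(flags) + "\n")
            for k in range(3):
                fh.write(f"{lo[k]:.10g} {hi[k]:.10g}\n")
            cols = "id mol element x y z" if fr.molecule_ids is not None else "id element x y z"
            fh.write(f"ITEM: ATOMS {cols}\n")
            for a in range(fr.n_atoms):
                x, y, z = fr.positions[a]
                if fr.molecule_ids is not None:
                    fh.write(
                        f"{a + 1} {int(fr.molecule_ids[a]) + 1} {fr.atom_types[a]} "
                        f"{x:.10f} {y:.10f} {z:.10f}\n"
                    )
                else:
                    fh.write(f"{a + 1} {fr.atom_types[a]} {x:.10f} {y:.10f} {z:.10f}\n")


# ---------------------------------------------------------------------------
# public read/write


def read_frames(
    path: str | Path,
    format: str = "extxyz",
    type_map: dict[int, str] | None = None,
) -> list[SimulationFrame]:
    """Read all frames from ``path`` in the named dialect.

    Parameters
    ----------
    format : ``"extxyz"`` or ``"lammps_dump"``.
    type_map : optional LAMMPS numeric type → element code mapping.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text().splitlines()
    if format == "extxyz":
        frames = _read_extxyz(lines)
    elif format == "lammps_dump":
        frames = _read_lammps_dump(lines, type_map)
    else:
        raise ValidationError(f"unknown format {format!r}")
    for fr in frames:
        fr.validate()
    return frames


def write_frames(
    frames: Iterable[SimulationFrame], path: str | Path, format: str = "extxyz"
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "extxyz":
        _write_extxyz(frames, path)
    elif format == "lammps_dump":
        _write_lammps_dump(frames, path)
    else:
        raise ValidationError(f"unknown format {format!r}")
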