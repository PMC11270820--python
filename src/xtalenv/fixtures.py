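"""Synthetic labeled crystal fixtures.

Generates the statistical structure the classifiers assume, without MD:
periodic point-vector polymorph lattices with distinct packing and
orientation order, a disordered melt, spherical clusters with a surface,
two-phase slabs, and seeded rigid-molecule thermal noise.

All fixtures share one 3-atom toy molecule (position atom plus two
vector-defining atoms), so a single point-vector template serves every
generator.  Densities are chosen so a perfect bulk lattice has
coordination number >= 20 at R_c = molecule radius + 6 Å and is therefore
labeled all-bulk by the surface rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .crystal_io import SimulationFrame, ValidationError, minimum_image
from .point_vector import PointVectorTemplate

__all__ = [
    "NoiseModel",
    "FixturePolymorph",
    "toy_template",
    "toy_species",
    "toy_molecule_radius",
    "shipped_polymorphs",
    "make_lattice_polymorph",
    "make_melt",
    "make_cluster",
    "make_interface_slab",
    "perturb",
]

# local-frame toy molecule: position atom first
_TOY_SPECIES = ["C", "N", "O"]
_TOY_COORDS = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.2, 0.0, 0.0],
        [0.0, 1.0, 0.5],
    ]
)

MELT_CLASS = "melt"


def toy_template() -> PointVectorTemplate:
    """Point-vector template of the shipped 3-atom toy molecule."""
    return PointVectorTemplate(position_atom=0, vector_specs=[(0, 1), (0, 2)])


def toy_species() -> list[str]:
    return list(_TOY_SPECIES)


def toy_molecule_radius() -> float:
    """Max distance from the position atom to any template atom."""
    return float(np.linalg.norm(_TOY_COORDS - _TOY_COORDS[0], axis=1).max())


@dataclass
class NoiseModel:
    """Rigid-molecule Gaussian thermal noise."""

    sigma_trans: float = 0.0  # Å
    sigma_rot: float = 0.0  # radians
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_trans < 0 or self.sigma_rot < 0:
            raise ValidationError("noise sigmas must be non-negative")


@dataclass
class FixturePolymorph:
    """A periodic packing: lattice vectors plus a molecular basis."""

    name: str
    lattice: np.ndarray  # (3,3), rows are lattice vectors, Å
    basis: list[tuple[np.ndarray, Rotation]]  # (fractional position, orientation)
    species: list[str] = field(default_factory=toy_species)
    coords: np.ndarray = field(default_factory=lambda: _TOY_COORDS.copy())

    def __post_init__(self) -> None:
        self.lattice = np.asarray(self.lattice, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(self.lattice)) < 1e-12:
            raise ValidationError("lattice is not invertible")
        if not self.basis:
            raise ValidationError("basis must be nonempty")


def shipped_polymorphs() -> dict[str, FixturePolymorph]:
    """Three toy polymorphs with distinct packing and orientation order.

    * ``aligned`` — simple cubic, all molecules parallel.
    * ``antiparallel`` — body-centered tetragonal, alternate molecules
      flipped 180° about z (layered antiparallel order).
    * ``herringbone`` — body-centered tetragonal, alternate molecules
      tilted ±55° about x.
    """
    ident = Rotation.identity()
    flip_z = Rotation.from_euler("z", 180, degrees=True)
    tilt_p = Rotation.from_euler("x", 55, degrees=True)
    tilt_m = Rotation.from_euler("x", -55, degrees=True)
    return {
        "aligned": FixturePolymorph(
            name="aligned",
            lattice=np.diag([4.0, 4.0, 4.0]),
            basis=[(np.zeros(3), ident)],
        ),
        # c = 6.4 keeps every neighbor shell >= 1.5% away from the default
        # coordination radius (molecule radius + 6 Å); with c = 6.0 the
        # (±a, 0, ±c) shell sits at 7.211 Å, 0.15% from the 7.2 Å boundary
        "antiparallel": FixturePolymorph(
            name="antiparallel",
            lattice=np.diag([4.0, 4.0, 6.4]),
            basis=[(np.zeros(3), ident), (np.array([0.5, 0.5, 0.5]), flip_z)],
        ),
        "herringbone": FixturePolymorph(
            name="herringbone",
            lattice=np.diag([3.9, 3.9, 6.2]),
            basis=[(np.zeros(3), tilt_p), (np.array([0.5, 0.5, 0.5]), tilt_m)],
        ),
    }


def _noise_moves(
    n: int, noise: NoiseModel | None, rng: np.random.Generator
) -> tuple[np.ndarray, list[Rotation]]:
    """Per-molecule rigid displacement and rotation draws."""
    if noise is None or (noise.sigma_trans == 0 and noise.sigma_rot == 0):
        return np.zeros((n, 3)), [Rotation.identity()] * n
    shifts = rng.normal(0.0, noise.sigma_trans, size=(n, 3)) if noise.sigma_trans else np.zeros((n, 3))
    rots = []
    for _ in range(n):
        if noise.sigma_rot:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.normal(0.0, noise.sigma_rot)
            rots.append(Rotation.from_rotvec(angle * axis))
        else:
            rots.append(Rotation.identity())
    return shifts, rots


def _assemble(
    centers: np.ndarray,
    orientations: list[Rotation],
    spec_coords: np.ndarray,
    species: list[str],
    cell: np.ndarray | None,
    pbc: tuple[bool, bool, bool],
) -> SimulationFrame:
    n_mol = len(centers)
    n_at = len(spec_coords)
    positions = np.empty((n_mol * n_at, 3))
    types: list[str] = []
    mol_ids = np.repeat(np.arange(n_mol), n_at)
    for m in range(n_mol):
        positions[m * n_at : (m + 1) * n_at] = centers[m] + orientations[m].apply(
            spec_coords
        )
        types.extend(species)
    return SimulationFrame(
        positions=positions,
        atom_types=types,
        cell=cell,
        pbc=pbc,
        molecule_ids=mol_ids,
    )


def _lattice_sites(
    spec: FixturePolymorph, supercell: tuple[int, int, int]
) -> tuple[np.ndarray, list[Rotation]]:
    centers = []
    orients: list[Rotation] = []
    for i in range(supercell[0]):
        for j in range(supercell[1]):
            for k in range(supercell[2]):
                for frac, rot in spec.basis:
                    centers.append((np.array([i, j, k]) + frac) @ spec.lattice)
                    orients.append(rot)
    return np.array(centers), orients


def _check_overlaps(frame: SimulationFrame, threshold: float = 0.5) -> bool:
    """True when no intermolecular atom pair is closer than ``threshold``."""
    pos = frame.positions
    mol = frame.molecule_ids
    n = len(pos)
    cell = frame.cell if any(frame.pbc) else None
    for i in range(n):
        d = pos[i + 1 :] - pos[i]
        if cell is not None:
            d = minimum_image(d, cell)
        dist = np.linalg.norm(d, axis=1)
        other = mol[i + 1 :] != mol[i]
        if np.any(dist[other] < threshold):
            return False
    return True


def make_lattice_polymorph(
    spec: FixturePolymorph,
    supercell: tuple[int, int, int] = (4, 4, 3),
    noise: NoiseModel | None = None,
    max_retries: int = 5,
) -> tuple[SimulationFrame, list[str]]:
    """Periodic supercell of one polymorph; labels are ``spec.name`` per molecule."""
    if min(supercell) < 2:
        raise ValidationError("supercell must be at least (2, 2, 2)")
    cell = np.diag(supercell) @ spec.lattice
    centers, orients = _lattice_sites(spec, supercell)
    seed = noise.seed if noise is not None else 0
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        shifts, extra = _noise_moves(len(centers), noise, rng)
        frame = _assemble(
            centers + shifts,
            [e * o for e, o in zip(extra, orients)],
            spec.coords,
            spec.species,
            cell,
            (True, True, True),
        )
        if _check_overlaps(frame):
            return frame, [spec.name] * len(centers)
    raise ValidationError(f"overlapping molecules after {max_retries} noise retries")


def make_melt(
    n_molecules: int,
    box: float,
    min_distance: float = 3.3,
    seed: int = 0,
    max_tries_per_molecule: int = 2000,
) -> tuple[SimulationFrame, list[str]]:
    """Random sequential insertion with uniform random orientations."""
    rng = np.random.default_rng(seed)
    cell = np.diag([box, box, box])
    centers: list[np.ndarray] = []
    for _ in range(n_molecules):
        for attempt in range(max_tries_per_molecule):
            cand = rng.random(3) * box
            if centers:
                d = minimum_image(np.array(centers) - cand, cell)
                if np.linalg.norm(d, axis=1).min() < min_distance:
                    continue
            centers.append(cand)
            break
        else:
            raise ValidationError(
                f"could not insert molecule {len(centers)}; lower the density"
            )
    orients = [Rotation.random(random_state=rng) for _ in range(n_molecules)]
    frame = _assemble(
        np.array(centers), orients, _TOY_COORDS, _TOY_SPECIES, cell, (True,) * 3
    )
    return frame, [MELT_CLASS] * n_molecules


def make_cluster(
    spec: FixturePolymorph,
    diameter: float = 30.0,
    noise: NoiseModel | None = None,
) -> tuple[SimulationFrame, list[str]]:
    """Spherical, non-periodic cluster cut from the periodic lattice."""
    spacings = np.linalg.norm(spec.lattice, axis=1)
    if diameter <= 2 * spacings.min():
        raise ValidationError("diameter must exceed two lattice spacings")
    reps = tuple(int(np.ceil(diameter / s)) + 2 for s in spacings)
    centers, orients = _lattice_sites(spec, reps)
    mid = centers.mean(axis=0)
    keep = np.linalg.norm(centers - mid, axis=1) <= diameter / 2
    if not np.any(keep):
        raise ValidationError("empty cluster")
    centers = centers[keep]
    orients = [o for o, k in zip(orients, keep) if k]
    rng = np.random.default_rng(noise.seed if noise is not None else 0)
    shifts, extra = _noise_moves(len(centers), noise, rng)
    frame = _assemble(
        centers + shifts,
        [e * o for e, o in zip(extra, orients)],
        spec.coords,
        spec.species,
        None,
        (False, False, False),
    )
    return frame, [spec.name] * len(centers)


def make_interface_slab(
    spec_top: FixturePolymorph,
    spec_bottom: FixturePolymorph,
    supercell: tuple[int, int, int] = (4, 4, 2),
    noise: NoiseModel | None = None,
    boundary_frac: float = 0.5,
    strain_tolerance: float = 0.15,
) -> tuple[SimulationFrame, list[str], dict]:
    """Two-phase slab stacked along z, periodic in all directions.

    ``supercell = (nx, ny, nz)`` gives ``nz`` unit-cell layers per half at
    ``boundary_frac = 0.5``; ``boundary_frac`` is the fraction of the
    2*nz layers assigned to the top phase.  The top phase is strained
    in-plane to the bottom phase's lattice; applied strains are reported
    in the returned metadata.  Both lattices must be diagonal.
    """
    for sp in (spec_top, spec_bottom):
        offdiag = sp.lattice - np.diag(np.diag(sp.lattice))
        if np.abs(offdiag).max() > 1e-10:
            raise ValidationError("interface slab requires diagonal lattices")
    if not 0.0 <= boundary_frac <= 1.0:
        raise ValidationError("boundary_frac must be in [0, 1]")
    nx, ny, nz = supercell
    a_bot, b_bot = spec_bottom.lattice[0, 0], spec_bottom.lattice[1, 1]
    a_top, b_top = spec_top.lattice[0, 0], spec_top.lattice[1, 1]
    strain = ((a_bot - a_top) / a_top, (b_bot - b_top) / b_top)
    if max(abs(strain[0]), abs(strain[1])) > strain_tolerance:
        raise ValidationError(
            f"incommensurate in-plane lattices: required strain {strain} exceeds "
            f"tolerance {strain_tolerance}"
        )
    total_layers = 2 * nz
    n_top = int(round(boundary_frac * total_layers))
    layers = [spec_bottom] * (total_layers - n_top) + [spec_top] * n_top

    centers: list[np.ndarray] = []
    orients: list[Rotation] = []
    labels: list[str] = []
    z_off = 0.0
    for sp in layers:
        strained = np.diag([a_bot, b_bot, sp.lattice[2, 2]])
        for i in range(nx):
            for j in range(ny):
                for frac, rot in sp.basis:
                    pos = (np.array([i, j, 0]) + frac) @ strained
                    pos[2] += z_off
                    centers.append(pos)
                    orients.append(rot)
                    labels.append(sp.name)
        z_off += sp.lattice[2, 2]
    cell = np.diag([nx * a_bot, ny * b_bot, z_off])
    rng = np.random.default_rng(noise.seed if noise is not None else 0)
    shifts, extra = _noise_moves(len(centers), noise, rng)
    frame = _assemble(
        np.array(centers) + shifts,
        [e * o for e, o in zip(extra, orients)],
        spec_bottom.coords,
        spec_bottom.species,
        cell,
        (True, True, True),
    )
    meta = {
        "strain_x": strain[0],
        "strain_y": strain[1],
        "n_top_layers": n_top,
        "n_layers": total_layers,
        "top_fraction": labels.count(spec_top.name) / len(labels) if labels else 0.0,
    }
    return frame, labels, meta


def perturb(
    frame: SimulationFrame, noise: NoiseModel, molecule_size: int | None = None
) -> SimulationFrame:
    """Rigidly translate and rotate each molecule; intramolecular geometry
    is preserved exactly."""
    from .crystal_io import group_molecules

    if noise.sigma_trans == 0 and noise.sigma_rot == 0:
        return SimulationFrame(
            positions=frame.positions.copy(),
            atom_types=list(frame.atom_types),
            cell=None if frame.cell is None else frame.cell.copy(),
            pbc=frame.pbc,
            molecule_ids=None if frame.molecule_ids is None else frame.molecule_ids.copy(),
            frame_index=frame.frame_index,
            time=frame.time,
        )
    groups = group_molecules(frame, molecule_size=molecule_size)
    rng = np.random.default_rng(noise.seed)
    shifts, rots = _noise_moves(len(groups), noise, rng)
    positions = frame.positions.copy()
    periodic = any(frame.pbc) and frame.cell is not None
    for g, t, R in zip(groups, shifts, rots):
        coords = frame.positions[g.atom_indices]
        rel = coords - coords[0]
        if periodic:
            rel = minimum_image(rel, frame.cell)
        centroid = rel.mean(axis=0)
        moved = coords[0] + centroid + R.apply(rel - centroid) + t
        positions[g.atom_indices] = moved
    return SimulationFrame(
        positions=positions,
        atom_types=list(frame.atom_types),
        cell=None if frame.cell is None else frame.cell.copy(),
        pbc=frame.pbc,
        molecule_ids=None if frame.molecule_ids is None else frame.molecule_ids.copy(),
        frame_index=frame.frame_index,
        time=frame.time,
    )
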