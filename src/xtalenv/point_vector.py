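"""Point-vector reduction of molecules.

Each molecule is reduced to a position point ``r_I`` (a selected atom, or
optionally the center of mass) plus one or more unit orientation vectors
``v_I;s`` defined between two selected atoms.  Intramolecular separations
are unwrapped with the minimum image relative to the position atom, so
molecules split across periodic boundaries are handled as long as they are
smaller than half the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal_io import (
    MoleculeGroup,
    SimulationFrame,
    ValidationError,
    minimum_image,
)

__all__ = [
    "PointVectorTemplate",
    "PointVectorMolecule",
    "extract_point_vectors",
    "validate_template",
]

# rough atomic masses for center-of-mass mode
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


@dataclass
class PointVectorTemplate:
    """Which template atoms define the molecule point and vectors.

    ``position_atom`` indexes into the molecule's template atom ordering;
    ``vector_specs`` holds one ``(from_atom, to_atom)`` pair per vector
    slot ``s``.
    """

    position_atom: int
    vector_specs: list[tuple[int, int]] = field(default_factory=list)
    position_mode: str = "atom"  # "atom" | "com"


@dataclass
class PointVectorMolecule:
    molecule_id: int
    r: np.ndarray  # (3,) Å
    v: np.ndarray  # (n_slots, 3) unit vectors

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float).reshape(3)
        self.v = np.asarray(self.v, dtype=float).reshape(-1, 3)


def validate_template(template: PointVectorTemplate, molecule_size: int) -> list[str]:
    """Report template problems; an empty list means the template is valid."""
    problems: list[str] = []
    if not 0 <= template.position_atom < molecule_size:
        problems.append(f"position_atom {template.position_atom} out of range")
    seen: set[tuple[int, int]] = set()
    for s, (a, b) in enumerate(template.vector_specs):
        if a == b:
            problems.append(f"vector slot {s}: from_atom == to_atom ({a})")
        for idx in (a, b):
            if not 0 <= idx < molecule_size:
                problems.append(f"vector slot {s}: index {idx} out of range")
        if (a, b) in seen:
            problems.append(f"vector slot {s}: duplicate spec ({a}, {b})")
        seen.add((a, b))
    if template.position_mode not in ("atom", "com"):
        problems.append(f"unknown position_mode {template.position_mode!r}")
    return problems


def extract_point_vectors(
    frame: SimulationFrame,
    groups: list[MoleculeGroup],
    template: PointVectorTemplate,
) -> list[PointVectorMolecule]:
    """One :class:`PointVectorMolecule` per group, vectors normalized.

    Raises :class:`ValidationError` for degenerate vectors (norm < 1e-8 Å),
    naming the offending molecule_id.
    """
    periodic = any(frame.pbc) and frame.cell is not None
    out: list[PointVectorMolecule] = []
    for g in groups:
        coords = frame.positions[g.atom_indices]
        anchor = coords[template.position_atom]
        rel = coords - anchor
        if periodic:
            rel = minimum_image(rel, frame.cell)
        unwrapped = anchor + rel
        if template.position_mode == "com":
            masses = np.array(
                [_MASSES.get(frame.atom_types[i], 12.0) for i in g.atom_indices]
            )
            r_i = (masses[:, None] * unwrapped).sum(axis=0) / masses.sum()
        else:
            r_i = anchor
        vecs = np.zeros((len(template.vector_specs), 3))
        for s, (a, b) in enumerate(template.vector_specs):
            d = unwrapped[b] - unwrapped[a]
            norm = np.linalg.norm(d)
            if norm < 1e-8:
                raise ValidationError(
                    f"degenerate vector slot {s} in molecule_id {g.molecule_id}"
                )
            vecs[s] = d / norm
        out.append(PointVectorMolecule(molecule_id=g.molecule_id, r=r_i, v=vecs))
    return out
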