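"""Molecular symmetry functions over point-vector molecules.

Four families, all gated by the cosine cutoff ``f_c`` and summed over
neighbor molecules J within ``r_c`` of molecule I:

* ``radial_gaussian``:  sum_J exp(-eta (|r_IJ| - R_s)^2) f_c(|r_IJ|)
* ``radial_cosine``:    sum_J cos(kappa |r_IJ|) f_c(|r_IJ|)
* ``orient_a``:         sum_J exp(-eta (cos th^s_IJ - cos th_S)^2) f_c(|r_IJ|)
* ``orient_b``:         sum_J cos(kappa (cos th^s_IJ - cos th_S)) f_c(|r_IJ|)

with ``cos th^s_IJ = v_I;s . v_J;s`` the angle cosine between the slot-s
unit vectors of molecules I and J.  Every family is invariant under global
rotation, translation, inversion and molecule relabeling by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .crystal_io import NeighborList, ValidationError
from .point_vector import PointVectorMolecule

__all__ = [
    "SymFuncParams",
    "DescriptorSet",
    "DescriptorVector",
    "cutoff_fn",
    "radial_gaussian_sf",
    "radial_cosine_sf",
    "orient_a_sf",
    "orient_b_sf",
    "compute_descriptors",
    "default_descriptor_set",
]

_KINDS = ("radial_gaussian", "radial_cosine", "orient_a", "orient_b")


@dataclass
class SymFuncParams:
    """One symmetry function's kind and tunable parameters.

    Which parameters are read depends on ``kind``:
    radial_gaussian uses (eta, R_s); radial_cosine uses kappa; orient_a uses
    (eta, cos_theta_S, vector_slot); orient_b uses (kappa, cos_theta_S,
    vector_slot).  ``r_c`` applies to all kinds.
    """

    kind: str
    r_c: float
    eta: float | None = None
    R_s: float | None = None
    kappa: float | None = None
    cos_theta_S: float | None = None
    vector_slot: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown symmetry-function kind {self.kind!r}")
        if not self.r_c > 0:
            raise ValidationError("r_c must be positive")
        need = {
            "radial_gaussian": ("eta", "R_s"),
            "radial_cosine": ("kappa",),
            "orient_a": ("eta", "cos_theta_S", "vector_slot"),
            "orient_b": ("kappa", "cos_theta_S", "vector_slot"),
        }[self.kind]
        for name in need:
            val = getattr(self, name)
            if val is None or not np.isfinite(val):
                raise ValidationError(f"{self.kind} requires finite {name}")
        if self.cos_theta_S is not None and not -1.0 <= self.cos_theta_S <= 1.0:
            raise ValidationError("cos_theta_S must lie in [-1, 1]")

    @property
    def name(self) -> str:
        if self.kind == "radial_gaussian":
            return f"G_rad(eta={self.eta:g},Rs={self.R_s:g},rc={self.r_c:g})"
        if self.kind == "radial_cosine":
            return f"G_cos(kappa={self.kappa:g},rc={self.r_c:g})"
        if self.kind == "orient_a":
            return (
                f"G_angA(s={self.vector_slot},eta={self.eta:g},"
                f"cosS={self.cos_theta_S:g},rc={self.r_c:g})"
            )
        return (
            f"G_angB(s={self.vector_slot},kappa={self.kappa:g},"
            f"cosS={self.cos_theta_S:g},rc={self.r_c:g})"
        )


@dataclass
class DescriptorSet:
    """Ordered list of symmetry functions defining the feature vector."""

    entries: list[SymFuncParams]
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_names:
            self.feature_names = [p.name for p in self.entries]
        if len(self.feature_names) != len(self.entries):
            raise ValidationError("feature_names length mismatch")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def max_cutoff(self) -> float:
        return max(p.r_c for p in self.entries)

    def content_hash(self) -> str:
        """Checksum binding a trained model to its descriptor set."""
        payload = [
            {
                "kind": p.kind,
                "r_c": p.r_c,
                "eta": p.eta,
                "R_s": p.R_s,
                "kappa": p.kappa,
                "cos_theta_S": p.cos_theta_S,
                "vector_slot": p.vector_slot,
            }
            for p in self.entries
        ]
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()

    def to_dicts(self) -> list[dict]:
        return [
            {k: v for k, v in vars(p).items() if v is not None} for p in self.entries
        ]

    @classmethod
    def from_dicts(cls, dicts: Sequence[dict]) -> "DescriptorSet":
        return cls(entries=[SymFuncParams(**d) for d in dicts])


@dataclass
class DescriptorVector:
    molecule_id: int
    values: np.ndarray


def cutoff_fn(r: float | np.ndarray, r_c: float) -> float | np.ndarray:
    """Behler cosine cutoff: 1 at r=0, smoothly 0 at and beyond r_c."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValidationError("negative distance in cutoff_fn")
    if not r_c > 0:
        raise ValidationError("r_c must be positive")
    out = np.where(r_arr < r_c, 0.5 * (np.cos(np.pi * r_arr / r_c) + 1.0), 0.0)
    return float(out) if np.isscalar(r) else out


def _dists(neighbors: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(neighbors, dtype=float).reshape(-1, 3), axis=1)


def radial_gaussian_sf(
    center: PointVectorMolecule, neighbors: np.ndarray, params: SymFuncParams
) -> float:
    """Gaussian radial symmetry function over neighbor displacements."""
    if params.kind != "radial_gaussian":
        raise ValidationError("params.kind must be radial_gaussian")
    d = _dists(neighbors)
    if d.size == 0:
        return 0.0
    return float(np.sum(np.exp(-params.eta * (d - params.R_s) ** 2) * cutoff_fn(d, params.r_c)))


def radial_cosine_sf(
    center: PointVectorMolecule, neighbors: np.ndarray, params: SymFuncParams
) -> float:
    if params.kind != "radial_cosine":
        raise ValidationError("params.kind must be radial_cosine")
    d = _dists(neighbors)
    if d.size == 0:
        return 0.0
    return float(np.sum(np.cos(params.kappa * d) * cutoff_fn(d, params.r_c)))


def _orient_cosines(
    center: PointVectorMolecule,
    neighbor_molecules: Sequence[tuple[PointVectorMolecule, np.ndarray]],
    slot: int,
) -> tuple[np.ndarray, np.ndarray]:
    if slot >= center.v.shape[0]:
        raise ValidationError(f"vector_slot {slot} out of range for center molecule")
    cosines = np.empty(len(neighbor_molecules))
    dists = np.empty(len(neighbor_molecules))
    for k, (nb, disp) in enumerate(neighbor_molecules):
        if slot >= nb.v.shape[0]:
            raise ValidationError(
                f"vector_slot {slot} out of range for molecule {nb.molecule_id}"
            )
        cosines[k] = float(np.dot(center.v[slot], nb.v[slot]))
        dists[k] = float(np.linalg.norm(disp))
    return cosines, dists


def orient_a_sf(
    center: PointVectorMolecule,
    neighbor_molecules: Sequence[tuple[PointVectorMolecule, np.ndarray]],
    params: SymFuncParams,
) -> float:
    """Gaussian-in-cosine orientational symmetry function."""
    if params.kind != "orient_a":
        raise ValidationError("params.kind must be orient_a")
    if not neighbor_molecules:
        return 0.0
    cosines, d = _orient_cosines(center, neighbor_molecules, params.vector_slot)
    ang = np.exp(-params.eta * (cosines - params.cos_theta_S) ** 2)
    return float(np.sum(ang * cutoff_fn(d, params.r_c)))


def orient_b_sf(
    center: PointVectorMolecule,
    neighbor_molecules: Sequence[tuple[PointVectorMolecule, np.ndarray]],
    params: SymFuncParams,
) -> float:
    """Cosine-family orientational symmetry function."""
    if params.kind != "orient_b":
        raise ValidationError("params.kind must be orient_b")
    if not neighbor_molecules:
        return 0.0
    cosines, d = _orient_cosines(center, neighbor_molecules, params.vector_slot)
    ang = np.cos(params.kappa * (cosines - params.cos_theta_S))
    return float(np.sum(ang * cutoff_fn(d, params.r_c)))


def compute_descriptors(
    molecules: Sequence[PointVectorMolecule],
    nlist: NeighborList,
    dset: DescriptorSet,
) -> list[DescriptorVector]:
    """Per-molecule descriptor vectors, entries ordered as in ``dset``.

    The neighbor list must have been built over the molecule positions with
    a cutoff at least the largest ``r_c`` in the set.
    """
    if nlist.cutoff < dset.max_cutoff - 1e-12:
        raise ValidationError(
            f"neighbor-list cutoff {nlist.cutoff:g} Å smaller than the "
            f"descriptor set's maximum r_c {dset.max_cutoff:g} Å"
        )
    n_slots = molecules[0].v.shape[0] if molecules else 0
    out: list[DescriptorVector] = []
    for i, mol in enumerate(molecules):
        nbr_idx = nlist.neighbor_ids[i]
        disp = nlist.displacement_vectors[i]
        d = np.linalg.norm(disp, axis=1) if len(nbr_idx) else np.empty(0)
        # slot-wise cosine matrix (n_slots, n_neighbors), vectorized
        if len(nbr_idx) and n_slots:
            nbr_v = np.stack([molecules[j].v for j in nbr_idx])  # (J, S, 3)
            cos = np.einsum("sk,jsk->sj", mol.v, nbr_v)
        else:
            cos = np.empty((n_slots, 0))
        values = np.empty(len(dset))
        for f, p in enumerate(dset.entries):
            if d.size == 0:
                values[f] = 0.0
                continue
            fc = cutoff_fn(d, p.r_c)
            if p.kind == "radial_gaussian":
                values[f] = np.sum(np.exp(-p.eta * (d - p.R_s) ** 2) * fc)
            elif p.kind == "radial_cosine":
                values[f] = np.sum(np.cos(p.kappa * d) * fc)
            elif p.kind == "orient_a":
                c = cos[p.vector_slot]
                values[f] = np.sum(np.exp(-p.eta * (c - p.cos_theta_S) ** 2) * fc)
            else:  # orient_b
                c = cos[p.vector_slot]
                values[f] = np.sum(np.cos(p.kappa * (c - p.cos_theta_S)) * fc)
        out.append(DescriptorVector(molecule_id=mol.molecule_id, values=values))
    return out


def default_descriptor_set(n_vector_slots: int = 2) -> DescriptorSet:
    """The shipped 24-function default set.

    8 radial Gaussians on an R_s grid 1–7 Å, 4 radial cosines on a kappa
    grid, and 6 + 6 orientational functions split over two vector slots.
    """
    entries: list[SymFuncParams] = []
    for R_s in np.linspace(1.0, 7.0, 8):
        entries.append(
            SymFuncParams(kind="radial_gaussian", eta=1.0, R_s=float(R_s), r_c=7.5)
        )
    for kappa in (0.5, 1.0, 1.5, 2.0):
        entries.append(SymFuncParams(kind="radial_cosine", kappa=kappa, r_c=7.5))
    slots = list(range(n_vector_slots)) or [0]
    for s in slots[:2]:
        for cos_s in (1.0, 0.0, -1.0):
            entries.append(
                SymFuncParams(
                    kind="orient_a", eta=4.0, cos_theta_S=cos_s, r_c=6.0, vector_slot=s
                )
            )
    for s in slots[:2]:
        for kappa in (1.0, 2.0, 3.0):
            entries.append(
                SymFuncParams(
                    kind="orient_b", kappa=kappa, cos_theta_S=1.0, r_c=6.0, vector_slot=s
                )
            )
    return DescriptorSet(entries=entries)
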