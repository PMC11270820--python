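"""Trajectory post-processing: topology labels, per-frame class series,
core/surface splits and region filtering.

The surface rule: a molecule is "surface" when its coordination number
CN_I — the count of other molecules within R_c, with R_c the molecule
radius plus the graph convolution cutoff — is smaller than the threshold
(default 20).  The boundary |r_IJ| = R_c counts as coordinated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .crystal_io import (
    MoleculeGroup,
    SimulationFrame,
    ValidationError,
    group_molecules,
    minimum_image,
)
from .point_vector import PointVectorTemplate, extract_point_vectors

__all__ = [
    "TopologyConfig",
    "MoleculeRecord",
    "CompositionSeries",
    "coordination_number",
    "label_topology",
    "classify_trajectory",
    "class_time_series",
    "region_filter",
]

OTHER_CLASS = "other"


@dataclass
class TopologyConfig:
    R_c: float = 7.0  # molecule radius + graph convolution cutoff, Å
    cn_threshold: int = 20

    def __post_init__(self) -> None:
        if self.R_c <= 0:
            raise ValidationError("R_c must be positive")
        if self.cn_threshold < 1:
            raise ValidationError("cn_threshold must be >= 1")


@dataclass
class MoleculeRecord:
    """Classification of one molecule in one frame."""

    frame_index: int
    molecule_id: int
    class_label: str
    class_probs: np.ndarray
    topology: str  # "surface" | "bulk"
    tie_flag: bool = False
    time: float | None = None


@dataclass
class CompositionSeries:
    times: list[float]
    counts: dict[str, list[int]]
    region: str = "all"

    def totals(self) -> list[int]:
        return [sum(c[i] for c in self.counts.values()) for i in range(len(self.times))]


def coordination_number(
    positions: np.ndarray,
    center: int,
    R_c: float,
    cell: np.ndarray | None = None,
) -> int:
    """Number of other molecules with |r_IJ| <= R_c (theta(0) = 1)."""
    if R_c <= 0:
        raise ValidationError("R_c must be positive")
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    d = np.delete(positions, center, axis=0) - positions[center]
    if cell is not None:
        d = minimum_image(d, cell)
    return int(np.sum(np.linalg.norm(d, axis=1) <= R_c))


def label_topology(
    positions: np.ndarray,
    config: TopologyConfig,
    cell: np.ndarray | None = None,
) -> list[str]:
    """Surface/bulk label per molecule position: surface iff CN < threshold."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    labels = []
    for i in range(n):
        cn = coordination_number(positions, i, config.R_c, cell)
        labels.append("surface" if cn < config.cn_threshold else "bulk")
    return labels


def _predict_frame(model, frame, groups, template, descriptor_set):
    """Dispatch to either classifier; returns (probs, class_names)."""
    from .gnn import GNNModel
    from .sf_classifier import SFClassifierModel, predict_proba

    if isinstance(model, GNNModel):
        poly, _ = model.predict_frame(frame, groups)
        return poly, model.class_names
    if isinstance(model, SFClassifierModel):
        if template is None or descriptor_set is None:
            raise ValidationError("SF model needs a template and a descriptor set")
        if model.descriptor_set_hash and (
            model.descriptor_set_hash != descriptor_set.content_hash()
        ):
            raise ValidationError(
                "descriptor set does not match the hash stored with the model"
            )
        from .crystal_io import build_neighbor_list
        from .symfuncs import compute_descriptors

        pv = extract_point_vectors(frame, groups, template)
        positions = np.array([m.r for m in pv])
        cell = frame.cell if any(frame.pbc) else None
        nlist = build_neighbor_list(positions, cell, descriptor_set.max_cutoff)
        desc = compute_descriptors(pv, nlist, descriptor_set)
        X = np.array([d.values for d in desc])
        return predict_proba(model, X), model.class_names
    raise ValidationError(f"unsupported model type {type(model).__name__}")


def classify_trajectory(
    frames: Sequence[SimulationFrame],
    model,
    topology: TopologyConfig,
    template: PointVectorTemplate | None = None,
    descriptor_set=None,
    molecule_size: int | None = None,
) -> list[MoleculeRecord]:
    """One record per molecule per frame, with class and topology labels."""
    records: list[MoleculeRecord] = []
    pv_template = template if template is not None else PointVectorTemplate(0, [])
    for fi, frame in enumerate(frames):
        groups = group_molecules(frame, molecule_size=molecule_size)
        probs, class_names = _predict_frame(model, frame, groups, template, descriptor_set)
        pv = extract_point_vectors(frame, groups, pv_template)
        positions = np.array([m.r for m in pv])
        cell = frame.cell if any(frame.pbc) else None
        topo = label_topology(positions, topology, cell)
        for k, g in enumerate(groups):
            p = probs[k]
            best = int(np.argmax(p))
            records.append(
                MoleculeRecord(
                    frame_index=frame.frame_index if frame.frame_index else fi,
                    molecule_id=g.molecule_id,
                    class_label=class_names[best],
                    class_probs=p,
                    topology=topo[k],
                    tie_flag=bool(np.sum(p == p[best]) > 1),
                    time=frame.time,
                )
            )
    return records


def class_time_series(
    records: Iterable[MoleculeRecord],
    tracked_classes: Sequence[str],
    known_classes: Sequence[str] | None = None,
    topology_filter: str | None = None,
    molecule_filter: set[int] | None = None,
    region: str = "all",
) -> CompositionSeries:
    """Per-frame molecule counts for the tracked classes, remaining classes
    collapsed into ``"other"``.  Counts conserve the in-scope molecule number.
    """
    recs = list(records)
    if known_classes is not None:
        unknown = set(tracked_classes) - set(known_classes)
        if unknown:
            raise ValidationError(f"unknown class(es) in collapse map: {sorted(unknown)}")
    if topology_filter is not None:
        recs = [r for r in recs if r.topology == topology_filter]
    if molecule_filter is not None:
        recs = [r for r in recs if r.molecule_id in molecule_filter]
    frame_keys = sorted({r.frame_index for r in recs})
    times = []
    counts: dict[str, list[int]] = {c: [] for c in tracked_classes}
    counts[OTHER_CLASS] = []
    for fk in frame_keys:
        frame_recs = [r for r in recs if r.frame_index == fk]
        times.append(frame_recs[0].time if frame_recs[0].time is not None else float(fk))
        per_class = {c: 0 for c in tracked_classes}
        other = 0
        for r in frame_recs:
            if r.class_label in per_class:
                per_class[r.class_label] += 1
            else:
                other += 1
        for c in tracked_classes:
            counts[c].append(per_class[c])
        counts[OTHER_CLASS].append(other)
    return CompositionSeries(times=times, counts=counts, region=region)


def region_filter(
    frame: SimulationFrame,
    groups: list[MoleculeGroup],
    template: PointVectorTemplate,
    axis: int,
    bounds: tuple[float, float],
) -> set[int]:
    """Molecule ids whose position's fractional coordinate on ``axis`` lies
    within ``bounds`` (inclusive)."""
    lo, hi = bounds
    if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
        raise ValidationError("bounds must lie within [0, 1]")
    if frame.cell is None:
        raise ValidationError("region_filter requires a periodic cell")
    pv = extract_point_vectors(frame, groups, template)
    inv = np.linalg.inv(frame.cell)
    ids = set()
    for m in pv:
        frac = (m.r @ inv) % 1.0
        if lo <= frac[axis] <= hi:
            ids.add(m.molecule_id)
    if not ids:
        import warnings

        warnings.warn("region_filter selected no molecules", stacklevel=2)
    return ids
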