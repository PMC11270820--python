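"""Shared fixtures: synthetic frames, descriptor helpers and (session-scoped)
trained models reused by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from xtalenv.crystal_io import build_neighbor_list, group_molecules
from xtalenv.fixtures import (
    NoiseModel,
    make_cluster,
    make_lattice_polymorph,
    make_melt,
    shipped_polymorphs,
    toy_molecule_radius,
    toy_template,
)
from xtalenv.point_vector import extract_point_vectors
from xtalenv.symfuncs import compute_descriptors, default_descriptor_set

CLASS_NAMES = ["aligned", "antiparallel", "herringbone", "melt"]
SUPERCELLS = {"aligned": (3, 3, 3), "antiparallel": (4, 4, 2), "herringbone": (4, 4, 2)}
# larger cells for the 7.5 Å molecule-level descriptor cutoff
SUPERCELLS_SF = {"aligned": (4, 4, 4), "antiparallel": (4, 4, 3), "herringbone": (4, 4, 3)}
VOCAB = {"C": 0, "N": 1, "O": 2}
TRAIN_NOISE = (0.05, 0.02)
TOPO_RC = toy_molecule_radius() + 6.0


def frame_descriptors(frame, dset=None):
    """(groups, descriptor matrix) for a frame of toy molecules."""
    dset = dset or default_descriptor_set()
    groups = group_molecules(frame)
    pv = extract_point_vectors(frame, groups, toy_template())
    pos = np.array([m.r for m in pv])
    cell = frame.cell if any(frame.pbc) else None
    nlist = build_neighbor_list(pos, cell, dset.max_cutoff)
    return groups, np.array([d.values for d in compute_descriptors(pv, nlist, dset)])


def labeled_sf_dataset(seeds, sigma_t, sigma_r, melt_seed_offset=1000):
    """Stacked descriptor matrix + integer labels over the 4 fixture classes."""
    polys = shipped_polymorphs()
    X, y = [], []
    for seed in seeds:
        for ci, name in enumerate(CLASS_NAMES[:3]):
            fr, _ = make_lattice_polymorph(
                polys[name], SUPERCELLS_SF[name], NoiseModel(sigma_t, sigma_r, seed)
            )
            _, D = frame_descriptors(fr)
            X.append(D)
            y.extend([ci] * len(D))
        fr, _ = make_melt(60, 16.0, seed=seed + melt_seed_offset)
        _, D = frame_descriptors(fr)
        X.append(D)
        y.extend([3] * len(D))
    return np.vstack(X), np.array(y)


@pytest.fixture(scope="session")
def polymorphs():
    return shipped_polymorphs()


@pytest.fixture(scope="session")
def aligned_frame(polymorphs):
    frame, labels = make_lattice_polymorph(polymorphs["aligned"], (4, 4, 4))
    return frame, labels


@pytest.fixture(scope="session")
def trained_sf_model():
    """SF classifier trained at sigma_t = 0.05 Å on the 4 fixture classes."""
    from xtalenv.sf_classifier import TrainingConfig, train_sf_classifier

    X, y = labeled_sf_dataset(range(3), *TRAIN_NOISE)
    model, report = train_sf_classifier(
        X,
        y,
        CLASS_NAMES,
        TrainingConfig(seed=1, max_epochs=200),
        descriptor_set=default_descriptor_set(),
    )
    return model, report


def gnn_labeled_graphs(
    cfg,
    seeds,
    sigma_t,
    sigma_r,
    with_clusters=False,
    zero_noise=False,
    cluster_diameters=(24.0, 24.0),
):
    """Whole-frame LabeledGraphs with polymorph + topology labels."""
    from xtalenv.analysis import TopologyConfig, label_topology
    from xtalenv.gnn import LabeledGraph, build_frame_graph

    polys = shipped_polymorphs()
    topo_cfg = TopologyConfig(R_c=TOPO_RC)

    def to_graph(frame, class_index):
        groups = group_molecules(frame)
        g = build_frame_graph(frame, groups, cfg.r_c, VOCAB)
        pv = extract_point_vectors(frame, groups, toy_template())
        pos = np.array([m.r for m in pv])
        cell = frame.cell if any(frame.pbc) else None
        topo = label_topology(pos, topo_cfg, cell)
        return LabeledGraph(
            g,
            np.full(g.n_mols, class_index),
            np.array([0 if t == "bulk" else 1 for t in topo]),
        )

    out = []
    for seed in seeds:
        for ci, name in enumerate(CLASS_NAMES[:3]):
            fr, _ = make_lattice_polymorph(
                polys[name],
                SUPERCELLS[name],
                None if zero_noise else NoiseModel(sigma_t, sigma_r, seed),
            )
            out.append(to_graph(fr, ci))
        fr, _ = make_melt(40, 13.5, min_distance=3.1, seed=seed + 1000)
        out.append(to_graph(fr, 3))
        if with_clusters:
            for (name, ci), diam in zip(
                (("aligned", 0), ("antiparallel", 1)), cluster_diameters
            ):
                fr, _ = make_cluster(
                    polys[name],
                    diam,
                    None if zero_noise else NoiseModel(sigma_t, sigma_r, seed + 7),
                )
                out.append(to_graph(fr, ci))
    return out


@pytest.fixture(scope="session")
def gnn_config():
    from xtalenv.gnn import GNNConfig

    return GNNConfig(
        node_dim=48,
        message_dim=32,
        graph_dim=48,
        n_bessel=8,
        n_convolutions=2,
        dropout=0.1,
        n_polymorph_classes=4,
        topology_head=True,
    )


@pytest.fixture(scope="session")
def trained_gnn(gnn_config):
    """Polymorph-recovery GNN: noisy bulk + melt frames (criterion 4)."""
    from xtalenv.gnn import train_gnn

    train = gnn_labeled_graphs(gnn_config, range(3), *TRAIN_NOISE)
    test = gnn_labeled_graphs(gnn_config, [50, 51], *TRAIN_NOISE)
    model, report = train_gnn(
        train,
        test,
        gnn_config,
        CLASS_NAMES,
        VOCAB,
        seed=2,
        lr=2e-3,
        max_epochs=60,
        patience=15,
    )
    return model, report


# cluster diameters used to TRAIN the topology model; held-out evaluation
# must avoid these exactly (zero-noise clusters are deterministic objects,
# so an equal diameter would be memorization, not generalization)
TOPO_TRAIN_DIAMS_ALIGNED = (18.0, 20.0, 22.0, 24.0, 26.0)
TOPO_TRAIN_DIAMS_ANTIPARALLEL = (19.0, 21.0, 23.0, 25.0, 27.0)
TOPO_EVAL_DIAMS = {"aligned": (23.0, 25.5), "antiparallel": (22.5, 24.0, 28.5)}


@pytest.fixture(scope="session")
def topo_gnn_config():
    from xtalenv.gnn import GNNConfig

    # softmax attention is degree-blind, so the neighbor-count surface rule
    # is learnable only through shell-fraction statistics: the topology
    # model needs more capacity, a topology-weighted loss and a long
    # schedule with lr decay
    return GNNConfig(
        node_dim=64,
        message_dim=40,
        graph_dim=64,
        n_bessel=8,
        n_convolutions=2,
        dropout=0.0,
        n_polymorph_classes=4,
        topology_head=True,
        topo_loss_weight=3.0,
    )


@pytest.fixture(scope="session")
def trained_topo_gnn(topo_gnn_config):
    """Topology-focused GNN: zero-noise cluster-diameter ladder + noisy
    clusters + zero-noise bulk/melt frames (criterion 5)."""
    from xtalenv.gnn import train_gnn

    cfg = topo_gnn_config
    train = []
    for da, dap in zip(TOPO_TRAIN_DIAMS_ALIGNED, TOPO_TRAIN_DIAMS_ANTIPARALLEL):
        train += gnn_labeled_graphs(
            cfg, [5], 0.0, 0.0, with_clusters=True, zero_noise=True,
            cluster_diameters=(da, dap),
        )[4:]
    train += gnn_labeled_graphs(
        cfg, [6], *TRAIN_NOISE, with_clusters=True, cluster_diameters=(24.0, 21.0)
    )[4:]
    train += gnn_labeled_graphs(cfg, [5], 0.0, 0.0, zero_noise=True)
    test = gnn_labeled_graphs(
        cfg, [50], 0.0, 0.0, with_clusters=True, zero_noise=True,
        cluster_diameters=(30.0, 28.0),
    )
    model, report = train_gnn(
        train,
        test,
        cfg,
        CLASS_NAMES,
        VOCAB,
        seed=2,
        lr=3e-3,
        max_epochs=250,
        patience=250,
        lr_decay_epoch=180,
    )
    return model, report
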