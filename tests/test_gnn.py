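import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from xtalenv import autodiff as ad
from xtalenv.crystal_io import SimulationFrame, ValidationError, group_molecules
from xtalenv.fixtures import NoiseModel, make_lattice_polymorph, shipped_polymorphs
from xtalenv.gnn import (
    GNNConfig,
    GNNModel,
    LabeledGraph,
    bessel_basis,
    build_frame_graph,
    build_molecule_graph,
    train_gnn,
)

from conftest import VOCAB

TINY = GNNConfig(
    r_c=6.0,
    n_bessel=2,
    node_dim=2,
    message_dim=2,
    graph_dim=2,
    n_convolutions=1,
    dropout=0.0,
    n_polymorph_classes=2,
)


def tiny_model(seed=0, config=TINY, class_names=("a", "b"), vocab=None):
    return GNNModel(
        config, list(class_names), vocab or {"C": 0, "N": 1}, np.random.default_rng(seed)
    )


# ---------------------------------------------------------------------------
# Bessel edge embedding


def test_bessel_basis_size():
    b = bessel_basis(np.array([3.0]), 6.0, 32)
    assert b.shape == (1, 32)


def test_bessel_zero_at_cutoff():
    b = bessel_basis(np.array([6.0]), 6.0, 8)
    assert np.allclose(b, 0.0, atol=1e-12)


def test_bessel_closed_form_halfway():
    rc = 6.0
    b = bessel_basis(np.array([rc / 2]), rc, 1)
    want = np.sqrt(2.0 / rc) * np.sin(np.pi / 2) / (rc / 2)
    assert b[0, 0] == pytest.approx(want, rel=1e-12)


def test_bessel_nonpositive_raises():
    with pytest.raises(ValidationError):
        bessel_basis(np.array([0.0]), 6.0, 4)


# ---------------------------------------------------------------------------
# node embedding


def test_same_element_same_embedding():
    m = tiny_model()
    x = m.embed_nodes(np.array([0, 1, 0]))
    assert np.allclose(x.data[0], x.data[2])
    assert not np.allclose(x.data[0], x.data[1])


def test_permuted_nodes_permuted_embeddings():
    m = tiny_model()
    z = np.array([0, 1, 1, 0])
    perm = np.array([2, 0, 3, 1])
    a = m.embed_nodes(z).data
    b = m.embed_nodes(z[perm]).data
    assert np.allclose(b, a[perm])


def test_embed_nodes_hand_computed():
    m = tiny_model()
    m.params["emb_table"].data = np.array([[1.0, 2.0], [3.0, 4.0]])
    m.params["emb_W"].data = np.array([[1.0, 0.5], [-1.0, 2.0]])
    m.params["emb_b"].data = np.array([0.1, -0.2])
    got = m.embed_nodes(np.array([1])).data
    want = np.array([3.0, 4.0]) @ np.array([[1.0, 0.5], [-1.0, 2.0]]) + [0.1, -0.2]
    np.testing.assert_allclose(got[0], want, atol=1e-12)


def test_unknown_type_code_raises():
    m = tiny_model()
    with pytest.raises(ValidationError):
        m.embed_nodes(np.array([7]))


# ---------------------------------------------------------------------------
# graph convolution: 3-node manual forward oracle


def test_graph_convolution_manual_oracle():
    m = tiny_model()
    rng = np.random.default_rng(42)
    for name in list(m.params):
        m.params[name].data = rng.normal(size=m.params[name].data.shape).round(2)
    x = np.array([[0.3, -0.1], [1.0, 0.4], [-0.5, 0.2]])
    e = np.array([[0.2, 0.1], [-0.3, 0.5], [0.7, 0.0]])
    src = np.array([1, 2, 0])
    tgt = np.array([0, 0, 2])
    out = m.graph_convolution(ad.tensor(x), ad.tensor(e), src, tgt, 0).data

    # independent by-hand computation
    p = {k: v.data for k, v in m.params.items()}
    q = x @ p["q_W0"] + p["q_b0"]
    k = x[src] @ p["k_W0"] + p["k_b0"] + e @ p["ke_W0"]
    v = x[src] @ p["v_W0"] + p["v_b0"] + e @ p["ve_W0"]
    scores = np.array([q[t] @ k[i] for i, t in enumerate(tgt)]) / np.sqrt(2.0)
    want = x @ p["root_W0"] + p["root_b0"]
    # node 0 has two incoming edges (0, 1); node 2 has one (2); node 1 none
    w01 = np.exp(scores[0]) / (np.exp(scores[0]) + np.exp(scores[1]))
    w02 = 1.0 - w01
    want[0] += w01 * v[0] + w02 * v[1]
    want[2] += v[2]
    np.testing.assert_allclose(out, want, atol=1e-10)


def test_isolated_node_passes_through_root():
    m = tiny_model()
    x = ad.tensor(np.array([[1.0, 2.0]]))
    e = ad.tensor(np.zeros((0, 2)))
    out = m.graph_convolution(x, e, np.array([], int), np.array([], int), 0)
    want = x.data @ m.params["root_W0"].data + m.params["root_b0"].data
    np.testing.assert_allclose(out.data, want)


def test_duplicate_symmetric_neighbors_equal_messages():
    m = tiny_model()
    x = np.array([[0.5, -0.2], [1.0, 1.0], [1.0, 1.0]])
    e = np.array([[0.3, 0.3], [0.3, 0.3]])
    src = np.array([1, 2])
    tgt = np.array([0, 0])
    out = m.graph_convolution(ad.tensor(x), ad.tensor(e), src, tgt, 0).data
    # identical neighbors share attention 50/50 -> same as one full message
    single = m.graph_convolution(
        ad.tensor(x[:2]), ad.tensor(e[:1]), np.array([1]), np.array([0]), 0
    ).data
    np.testing.assert_allclose(out[0], single[0], atol=1e-12)


# ---------------------------------------------------------------------------
# node update / aggregation / head


def test_node_update_zero_fc_is_layernorm():
    m = tiny_model()
    m.params["upd_W0"].data[:] = 0.0
    m.params["upd_b0"].data[:] = 0.0
    x = np.array([[1.0, 3.0], [2.0, -1.0]])
    out = m.node_update(ad.tensor(x), ad.tensor(np.zeros_like(x)), 0, None).data
    mu = x.mean(axis=1, keepdims=True)
    sd = np.sqrt(x.var(axis=1, keepdims=True) + 1e-5)
    np.testing.assert_allclose(out, (x - mu) / sd, atol=1e-10)


def test_node_update_deterministic_at_inference():
    m = tiny_model(config=GNNConfig(**{**vars(TINY), "dropout": 0.5}))
    x = ad.tensor(np.random.default_rng(0).normal(size=(3, 2)))
    a = m.node_update(x, x, 0, None).data
    b = m.node_update(x, x, 0, None).data
    np.testing.assert_array_equal(a, b)


def test_aggregate_max_examples():
    m = tiny_model()
    x = ad.tensor(np.array([[1.0, 5.0], [3.0, 2.0]]))
    g = m.aggregate_max(x, np.array([0, 0]), 1)
    np.testing.assert_allclose(g.data, [[3.0, 5.0]])
    single = m.aggregate_max(ad.tensor(np.array([[7.0, -1.0]])), np.array([0]), 1)
    np.testing.assert_allclose(single.data, [[7.0, -1.0]])


def test_aggregate_max_permutation_invariant():
    m = tiny_model()
    rng = np.random.default_rng(3)
    x = rng.normal(size=(6, 2))
    mol = np.array([0, 0, 0, 1, 1, 1])
    perm = rng.permutation(6)
    a = m.aggregate_max(ad.tensor(x), mol, 2).data
    b = m.aggregate_max(ad.tensor(x[perm]), mol[perm], 2).data
    np.testing.assert_array_equal(a, b)


def test_head_probabilities_normalized():
    cfg = GNNConfig(**{**vars(TINY), "topology_head": True})
    m = tiny_model(config=cfg)
    g = ad.tensor(np.random.default_rng(1).normal(size=(4, 2)))
    poly, topo = m.classify_molecule(g, None)
    from xtalenv.gnn import _softmax_np

    assert np.allclose(_softmax_np(poly.data).sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(_softmax_np(topo.data).sum(axis=1), 1.0, atol=1e-9)


def test_zeroed_final_layer_uniform():
    m = tiny_model()
    m.params["head2_W"].data[:] = 0.0
    m.params["head2_b"].data[:] = 0.0
    g = ad.tensor(np.random.default_rng(1).normal(size=(3, 2)))
    poly, _ = m.classify_molecule(g, None)
    from xtalenv.gnn import _softmax_np

    assert np.allclose(_softmax_np(poly.data), 0.5)


# ---------------------------------------------------------------------------
# whole-model properties


def _noisy_frame(seed=0):
    frame, _ = make_lattice_polymorph(
        shipped_polymorphs()["antiparallel"], (3, 3, 2), NoiseModel(0.08, 0.05, seed)
    )
    return frame


def _medium_model():
    cfg = GNNConfig(
        n_bessel=4,
        node_dim=8,
        message_dim=6,
        graph_dim=8,
        n_convolutions=2,
        dropout=0.0,
        n_polymorph_classes=3,
    )
    return GNNModel(cfg, ["a", "b", "c"], VOCAB, np.random.default_rng(5)), cfg


def test_full_model_geometric_invariance():
    model, cfg = _medium_model()
    frame = _noisy_frame()
    groups = group_molecules(frame)
    base, _ = model.predict_proba(build_frame_graph(frame, groups, cfg.r_c, VOCAB))
    R = Rotation.random(random_state=np.random.default_rng(2)).as_matrix()
    for kind in ("rotation", "translation", "inversion"):
        if kind == "rotation":
            pos, cell = frame.positions @ R.T, frame.cell @ R.T
        elif kind == "translation":
            pos, cell = frame.positions + np.array([2.0, -1.0, 0.5]), frame.cell
        else:
            pos, cell = -frame.positions, -frame.cell
        other = SimulationFrame(
            positions=pos,
            atom_types=list(frame.atom_types),
            cell=cell,
            pbc=frame.pbc,
            molecule_ids=frame.molecule_ids,
        )
        probs, _ = model.predict_proba(
            build_frame_graph(other, group_molecules(other), cfg.r_c, VOCAB)
        )
        np.testing.assert_allclose(probs, base, rtol=1e-5, atol=1e-8)


def test_full_model_atom_permutation_invariance():
    model, cfg = _medium_model()
    frame = _noisy_frame()
    groups = group_molecules(frame)
    base, _ = model.predict_proba(build_frame_graph(frame, groups, cfg.r_c, VOCAB))
    # shuffle atoms globally; molecule ids preserved per atom
    rng = np.random.default_rng(7)
    perm = rng.permutation(frame.n_atoms)
    other = SimulationFrame(
        positions=frame.positions[perm],
        atom_types=[frame.atom_types[i] for i in perm],
        cell=frame.cell,
        pbc=frame.pbc,
        molecule_ids=frame.molecule_ids[perm],
    )
    probs, _ = model.predict_proba(
        build_frame_graph(other, group_molecules(other), cfg.r_c, VOCAB)
    )
    np.testing.assert_allclose(probs, base, rtol=1e-6, atol=1e-10)


def test_receptive_field_limited():
    # two molecules ~25 Å apart, non-periodic: beyond (n_conv + 1) * r_c
    model, cfg = _medium_model()
    spec = shipped_polymorphs()["aligned"]
    pos = np.vstack([spec.coords, spec.coords + np.array([25.0, 0, 0])])
    frame = SimulationFrame(
        positions=pos,
        atom_types=spec.species * 2,
        molecule_ids=[0, 0, 0, 1, 1, 1],
    )
    groups = group_molecules(frame)
    base, _ = model.predict_proba(build_frame_graph(frame, groups, cfg.r_c, VOCAB))
    moved = frame.positions.copy()
    moved[3:] += np.array([0.0, 3.0, -1.0])  # move the far molecule
    other = SimulationFrame(
        positions=moved, atom_types=list(frame.atom_types), molecule_ids=frame.molecule_ids
    )
    probs, _ = model.predict_proba(
        build_frame_graph(other, group_molecules(other), cfg.r_c, VOCAB)
    )
    np.testing.assert_allclose(probs[0], base[0], atol=1e-12)


def test_molecule_subgraph_matches_frame_graph():
    model, cfg = _medium_model()
    frame = _noisy_frame(seed=3)
    groups = group_molecules(frame)
    frame_probs, _ = model.predict_proba(build_frame_graph(frame, groups, cfg.r_c, VOCAB))
    for k in (0, 5):
        sub = build_molecule_graph(
            frame, groups[k], cfg.r_c, VOCAB, n_shells=cfg.n_convolutions
        )
        probs, _ = model.predict_proba(sub)
        np.testing.assert_allclose(probs[0], frame_probs[k], rtol=1e-8, atol=1e-10)


def test_empty_molecule_raises():
    from xtalenv.crystal_io import MoleculeGroup

    frame = _noisy_frame()
    with pytest.raises(ValidationError, match="empty"):
        build_molecule_graph(frame, MoleculeGroup(0, []), 6.0, VOCAB)


def test_two_far_molecules_disconnected():
    spec = shipped_polymorphs()["aligned"]
    pos = np.vstack([spec.coords, spec.coords + np.array([20.0, 0, 0])])
    frame = SimulationFrame(
        positions=pos, atom_types=spec.species * 2, molecule_ids=[0, 0, 0, 1, 1, 1]
    )
    groups = group_molecules(frame)
    sub = build_molecule_graph(frame, groups[0], 6.0, VOCAB)
    assert sub.n_nodes == 3  # far molecule excluded entirely


def test_save_load_round_trip(tmp_path):
    model, cfg = _medium_model()
    frame = _noisy_frame(seed=1)
    groups = group_molecules(frame)
    g = build_frame_graph(frame, groups, cfg.r_c, VOCAB)
    base, _ = model.predict_proba(g)
    path = tmp_path / "gnn.json"
    model.save(path)
    back = GNNModel.load(path)
    probs, _ = back.predict_proba(g)
    np.testing.assert_array_equal(probs, base)


def test_default_fullsize_config_forward_smoke():
    # full-size hyperparameters: 256/128/256 dims, 32 Bessel functions, 2 convs
    cfg = GNNConfig(n_polymorph_classes=4, topology_head=True)
    assert (cfg.node_dim, cfg.message_dim, cfg.graph_dim) == (256, 128, 256)
    assert cfg.n_bessel == 32 and cfg.r_c == 6.0 and cfg.dropout == 0.25
    model = GNNModel(cfg, ["a", "b", "c", "d"], VOCAB, np.random.default_rng(0))
    spec = shipped_polymorphs()["aligned"]
    pos = np.vstack([spec.coords, spec.coords + np.array([4.0, 0, 0])])
    frame = SimulationFrame(
        positions=pos, atom_types=spec.species * 2, molecule_ids=[0, 0, 0, 1, 1, 1]
    )
    g = build_frame_graph(frame, group_molecules(frame), cfg.r_c, VOCAB)
    poly, topo = model.predict_proba(g)
    assert poly.shape == (2, 4) and topo.shape == (2, 2)
    assert np.allclose(poly.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(topo.sum(axis=1), 1.0, atol=1e-9)
    assert model.n_parameters() > 300_000  # same order as the full-scale model


def test_missing_topology_labels_raises():
    cfg = GNNConfig(
        n_bessel=2,
        node_dim=4,
        message_dim=4,
        graph_dim=4,
        n_convolutions=1,
        dropout=0.0,
        n_polymorph_classes=2,
        topology_head=True,
    )
    frame = _noisy_frame()
    groups = group_molecules(frame)
    g = build_frame_graph(frame, groups, cfg.r_c, VOCAB)
    data = [LabeledGraph(g, np.zeros(g.n_mols, dtype=int), None)]
    with pytest.raises(ValidationError, match="topo"):
        train_gnn(data, data, cfg, ["a", "b"], VOCAB, max_epochs=1)


def test_training_smoke_loss_decreases():
    cfg = GNNConfig(
        n_bessel=2,
        node_dim=6,
        message_dim=4,
        graph_dim=6,
        n_convolutions=1,
        dropout=0.0,
        n_polymorph_classes=2,
    )
    frames = []
    for name, ci, sc in (("aligned", 0, (3, 3, 3)), ("antiparallel", 1, (3, 3, 2))):
        fr, _ = make_lattice_polymorph(
            shipped_polymorphs()[name], sc, NoiseModel(0.05, 0.02, 1)
        )
        g = build_frame_graph(fr, group_molecules(fr), cfg.r_c, VOCAB)
        frames.append(LabeledGraph(g, np.full(g.n_mols, ci)))
    model, report = train_gnn(
        frames, frames, cfg, ["a", "b"], VOCAB, seed=1, max_epochs=8, patience=8
    )
    assert report.test_losses[report.best_epoch] <= report.test_losses[0]
    assert report.n_parameters == model.n_parameters() > 0
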