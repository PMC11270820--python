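"""Graph-convolutional per-molecule environment classifier.

Pipeline: learnable atom-type node embeddings -> spherical-Bessel edge
embeddings -> attention-based (TransformerConv-style, single head) graph
convolutions with residual node updates and layer norm -> per-molecule
channel-wise max aggregation -> shared two-layer head with a C-way
polymorph output and an optional surface/bulk topology output.

Only interatomic distances and atom types enter, so inference is invariant
under global rotation, translation and inversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .crystal_io import (
    MoleculeGroup,
    SimulationFrame,
    ValidationError,
    build_neighbor_list,
    minimum_image,
)

__all__ = [
    "GNNConfig",
    "MoleculeGraph",
    "GNNModel",
    "bessel_basis",
    "build_frame_graph",
    "build_molecule_graph",
    "train_gnn",
]


@dataclass
class GNNConfig:
    r_c: float = 6.0
    n_bessel: int = 32
    node_dim: int = 256
    message_dim: int = 128
    graph_dim: int = 256
    n_convolutions: int = 2
    dropout: float = 0.25
    n_polymorph_classes: int = 2
    topology_head: bool = False
    # relative weight of the topology cross-entropy in the combined loss;
    # 1.0 = equal weighting (the weighting is not pinned down externally)
    topo_loss_weight: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_bessel, self.node_dim, self.message_dim, self.graph_dim) <= 0:
            raise ValidationError("dimensions must be positive")
        if self.r_c <= 0:
            raise ValidationError("r_c must be positive")
        if self.n_convolutions < 1:
            raise ValidationError("need at least one convolution")


@dataclass
class MoleculeGraph:
    """Atomistic graph for one frame (or one molecule's neighborhood)."""

    node_z: np.ndarray  # integer atom-type codes (vocabulary indices)
    edge_src: np.ndarray
    edge_tgt: np.ndarray
    edge_dist: np.ndarray
    node_mol: np.ndarray  # molecule index per node; -1 = environment only
    mol_ids: list[int]  # original molecule ids, one per classified molecule

    @property
    def n_nodes(self) -> int:
        return len(self.node_z)

    @property
    def n_mols(self) -> int:
        return len(self.mol_ids)


def bessel_basis(distances: np.ndarray, r_c: float, n_basis: int) -> np.ndarray:
    """DimeNet radial basis: sqrt(2/r_c) sin(n pi r / r_c) / r, n = 1..n_basis."""
    d = np.asarray(distances, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("edge distances must be positive")
    n = np.arange(1, n_basis + 1)
    return np.sqrt(2.0 / r_c) * np.sin(n[None, :] * np.pi * d[:, None] / r_c) / d[:, None]


def _edges_within(
    positions: np.ndarray, cell: np.ndarray | None, r_c: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nlist = build_neighbor_list(positions, cell, r_c)
    src, tgt, dist = [], [], []
    for i in range(len(positions)):
        for j, d in zip(nlist.neighbor_ids[i], nlist.distances(i)):
            src.append(j)  # message flows j -> i
            tgt.append(i)
            dist.append(d)
    return (
        np.array(src, dtype=int),
        np.array(tgt, dtype=int),
        np.array(dist, dtype=float),
    )


def _vocab_indices(
    atom_types: Sequence[str], vocab: dict[str, int]
) -> np.ndarray:
    z = np.empty(len(atom_types), dtype=int)
    for i, sym in enumerate(atom_types):
        if sym not in vocab:
            raise ValidationError(f"atom type {sym!r} not in model vocabulary")
        z[i] = vocab[sym]
    return z


def build_frame_graph(
    frame: SimulationFrame,
    groups: list[MoleculeGroup],
    r_c: float,
    vocab: dict[str, int],
) -> MoleculeGraph:
    """Whole-frame graph; every molecule in ``groups`` is classified."""
    cell = frame.cell if any(frame.pbc) else None
    src, tgt, dist = _edges_within(frame.positions, cell, r_c)
    node_mol = np.full(frame.n_atoms, -1, dtype=int)
    for k, g in enumerate(groups):
        node_mol[g.atom_indices] = k
    return MoleculeGraph(
        node_z=_vocab_indices(frame.atom_types, vocab),
        edge_src=src,
        edge_tgt=tgt,
        edge_dist=dist,
        node_mol=node_mol,
        mol_ids=[g.molecule_id for g in groups],
    )


def build_molecule_graph(
    frame: SimulationFrame,
    center: MoleculeGroup,
    r_c: float,
    vocab: dict[str, int],
    n_shells: int = 1,
) -> MoleculeGraph:
    """Graph of one molecule plus all atoms within ``n_shells * r_c`` of it.

    With ``n_shells = n_convolutions`` the center molecule's logits match
    the whole-frame computation exactly.
    """
    if not center.atom_indices:
        raise ValidationError("empty molecule")
    cell = frame.cell if any(frame.pbc) else None
    center_pos = frame.positions[center.atom_indices]
    delta = frame.positions[:, None, :] - center_pos[None, :, :]
    if cell is not None:
        delta = minimum_image(delta.reshape(-1, 3), cell).reshape(delta.shape)
    dmin = np.linalg.norm(delta, axis=2).min(axis=1)
    keep = np.nonzero(dmin <= n_shells * r_c)[0]
    local = {orig: k for k, orig in enumerate(keep)}
    src, tgt, dist = _edges_within(frame.positions[keep], cell, r_c)
    node_mol = np.full(len(keep), -1, dtype=int)
    for a in center.atom_indices:
        node_mol[local[a]] = 0
    return MoleculeGraph(
        node_z=_vocab_indices([frame.atom_types[i] for i in keep], vocab),
        edge_src=src,
        edge_tgt=tgt,
        edge_dist=dist,
        node_mol=node_mol,
        mol_ids=[center.molecule_id],
    )


class GNNModel:
    """Parameters + forward pass of the graph classifier."""

    def __init__(
        self,
        config: GNNConfig,
        class_names: Sequence[str],
        vocab: dict[str, int],
        rng: np.random.Generator | None = None,
    ):
        if len(class_names) != config.n_polymorph_classes:
            raise ValidationError("class_names length != n_polymorph_classes")
        self.config = config
        self.class_names = list(class_names)
        self.vocab = dict(vocab)
        rng = rng or np.random.default_rng(0)
        self.params: dict[str, ad.Tensor] = {}
        self._init_params(rng)

    # -- parameters ---------------------------------------------------------

    def _add(self, name: str, shape: tuple[int, ...], rng: np.random.Generator) -> None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        scale = np.sqrt(1.0 / fan_in)
        self.params[name] = ad.parameter(rng.normal(0.0, scale, size=shape))

    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.config
        nt = len(self.vocab)
        self._add("emb_table", (nt, c.node_dim), rng)
        self._add("emb_W", (c.node_dim, c.node_dim), rng)
        self.params["emb_b"] = ad.parameter(np.zeros(c.node_dim))
        self._add("edge_W", (c.n_bessel, c.message_dim), rng)
        self.params["edge_b"] = ad.parameter(np.zeros(c.message_dim))
        for l in range(c.n_convolutions):
            for nm, shape in [
                (f"q_W{l}", (c.node_dim, c.message_dim)),
                (f"k_W{l}", (c.node_dim, c.message_dim)),
                (f"ke_W{l}", (c.message_dim, c.message_dim)),
                (f"v_W{l}", (c.node_dim, c.message_dim)),
                (f"ve_W{l}", (c.message_dim, c.message_dim)),
                (f"root_W{l}", (c.node_dim, c.message_dim)),
                (f"upd_W{l}", (c.message_dim, c.node_dim)),
            ]:
                self._add(nm, shape, rng)
            for nm, dim in [
                (f"q_b{l}", c.message_dim),
                (f"k_b{l}", c.message_dim),
                (f"v_b{l}", c.message_dim),
                (f"root_b{l}", c.message_dim),
                (f"upd_b{l}", c.node_dim),
            ]:
                self.params[nm] = ad.parameter(np.zeros(dim))
            self.params[f"ln_g{l}"] = ad.parameter(np.ones(c.node_dim))
            self.params[f"ln_b{l}"] = ad.parameter(np.zeros(c.node_dim))
        self._add("head1_W", (c.node_dim, c.graph_dim), rng)
        self.params["head1_b"] = ad.parameter(np.zeros(c.graph_dim))
        self.params["head_ln_g"] = ad.parameter(np.ones(c.graph_dim))
        self.params["head_ln_b"] = ad.parameter(np.zeros(c.graph_dim))
        n_out = c.n_polymorph_classes + (2 if c.topology_head else 0)
        self._add("head2_W", (c.graph_dim, n_out), rng)
        self.params["head2_b"] = ad.parameter(np.zeros(n_out))

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # -- forward stages (exposed for unit tests) ----------------------------

    def embed_nodes(self, z: np.ndarray) -> ad.Tensor:
        if np.any(z < 0) or np.any(z >= self.params["emb_table"].shape[0]):
            raise ValidationError("atom-type code outside embedding table")
        emb = ad.gather_rows(self.params["emb_table"], z)
        return ad.matmul(emb, self.params["emb_W"]) + self.params["emb_b"]

    def embed_edges(self, distances: np.ndarray) -> ad.Tensor:
        basis = bessel_basis(distances, self.config.r_c, self.config.n_bessel)
        return ad.matmul(ad.tensor(basis), self.params["edge_W"]) + self.params["edge_b"]

    def graph_convolution(
        self,
        x: ad.Tensor,
        e: ad.Tensor,
        edge_src: np.ndarray,
        edge_tgt: np.ndarray,
        layer: int,
    ) -> ad.Tensor:
        """Attention-weighted message passing; output has message_dim."""
        p = self.params
        n = x.shape[0]
        root = ad.matmul(x, p[f"root_W{layer}"]) + p[f"root_b{layer}"]
        if len(edge_src) == 0:
            return root
        q = ad.matmul(x, p[f"q_W{layer}"]) + p[f"q_b{layer}"]
        x_src = ad.gather_rows(x, edge_src)
        k = ad.matmul(x_src, p[f"k_W{layer}"]) + p[f"k_b{layer}"] + ad.matmul(
            e, p[f"ke_W{layer}"]
        )
        v = ad.matmul(x_src, p[f"v_W{layer}"]) + p[f"v_b{layer}"] + ad.matmul(
            e, p[f"ve_W{layer}"]
        )
        scores = (ad.gather_rows(q, edge_tgt) * k).sum(axis=1) * (
            1.0 / np.sqrt(self.config.message_dim)
        )
        alpha = ad.segment_softmax(scores, edge_tgt, n)
        agg = ad.segment_sum(alpha.reshape(-1, 1) * v, edge_tgt, n)
        return agg + root

    def node_update(
        self, x: ad.Tensor, m: ad.Tensor, layer: int, rng: np.random.Generator | None
    ) -> ad.Tensor:
        """x' = LayerNorm(x + Dropout(GeLU(FC(m)))) — post-norm residual."""
        p = self.params
        h = ad.gelu(ad.matmul(m, p[f"upd_W{layer}"]) + p[f"upd_b{layer}"])
        h = ad.dropout(h, self.config.dropout, rng)
        return ad.layer_norm(x + h, p[f"ln_g{layer}"], p[f"ln_b{layer}"])

    def aggregate_max(self, x: ad.Tensor, node_mol: np.ndarray, n_mols: int) -> ad.Tensor:
        keep = np.nonzero(node_mol >= 0)[0]
        return ad.segment_max(ad.gather_rows(x, keep), node_mol[keep], n_mols)

    def classify_molecule(
        self, g: ad.Tensor, rng: np.random.Generator | None
    ) -> tuple[ad.Tensor, ad.Tensor | None]:
        """Head logits (polymorph, topology-or-None) from molecule embeddings."""
        p = self.params
        h = ad.gelu(ad.matmul(g, p["head1_W"]) + p["head1_b"])
        h = ad.layer_norm(h, p["head_ln_g"], p["head_ln_b"])
        h = ad.dropout(h, self.config.dropout, rng)
        logits = ad.matmul(h, p["head2_W"]) + p["head2_b"]
        C = self.config.n_polymorph_classes
        if self.config.topology_head:
            poly = _slice_cols(logits, 0, C)
            topo = _slice_cols(logits, C, C + 2)
            return poly, topo
        return logits, None

    # -- full forward -------------------------------------------------------

    def forward(
        self, graph: MoleculeGraph, rng: np.random.Generator | None = None
    ) -> tuple[ad.Tensor, ad.Tensor | None]:
        """Per-molecule logits for one graph; ``rng=None`` = inference mode."""
        x = self.embed_nodes(graph.node_z)
        e = (
            self.embed_edges(graph.edge_dist)
            if len(graph.edge_dist)
            else ad.tensor(np.zeros((0, self.config.message_dim)))
        )
        for l in range(self.config.n_convolutions):
            m = self.graph_convolution(x, e, graph.edge_src, graph.edge_tgt, l)
            x = self.node_update(x, m, l, rng)
        g = self.aggregate_max(x, graph.node_mol, graph.n_mols)
        return self.classify_molecule(g, rng)

    def predict_proba(
        self, graph: MoleculeGraph
    ) -> tuple[np.ndarray, np.ndarray | None]:
        poly, topo = self.forward(graph, rng=None)
        return _softmax_np(poly.data), (_softmax_np(topo.data) if topo is not None else None)

    def predict_frame(
        self, frame: SimulationFrame, groups: list[MoleculeGroup]
    ) -> tuple[np.ndarray, np.ndarray | None]:
        graph = build_frame_graph(frame, groups, self.config.r_c, self.vocab)
        return self.predict_proba(graph)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "config": vars(self.config),
            "class_names": self.class_names,
            "vocab": self.vocab,
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GNNModel":
        d = json.loads(Path(path).read_text())
        model = cls(GNNConfig(**d["config"]), d["class_names"], d["vocab"])
        for k, v in d["params"].items():
            model.params[k] = ad.parameter(np.array(v))
        return model


def _slice_cols(t: ad.Tensor, lo: int, hi: int) -> ad.Tensor:
    n = t.shape[0]
    rows = np.repeat(np.arange(n), hi - lo)
    cols = np.tile(np.arange(lo, hi), n)
    return ad.pick(t, rows, cols).reshape(n, hi - lo)


def _softmax_np(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# training


@dataclass
class LabeledGraph:
    graph: MoleculeGraph
    poly_labels: np.ndarray
    topo_labels: np.ndarray | None = None


@dataclass
class GNNTrainingReport:
    train_losses: list[float] = field(default_factory=list)
    test_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    n_parameters: int = 0
    test_poly_accuracy: float = float("nan")
    test_topo_accuracy: float = float("nan")


def _graph_loss(
    model: GNNModel, lg: LabeledGraph, rng: np.random.Generator | None
) -> ad.Tensor:
    from .sf_classifier import cross_entropy

    poly, topo = model.forward(lg.graph, rng)
    loss = cross_entropy(poly, lg.poly_labels)
    if model.config.topology_head:
        if lg.topo_labels is None:
            raise ValidationError("topology head enabled but topo_labels missing")
        loss = loss + model.config.topo_loss_weight * cross_entropy(topo, lg.topo_labels)
    return loss


def train_gnn(
    train_data: list[LabeledGraph],
    test_data: list[LabeledGraph],
    config: GNNConfig,
    class_names: Sequence[str],
    vocab: dict[str, int],
    seed: int = 0,
    lr: float = 1e-3,
    max_epochs: int = 60,
    patience: int = 10,
    lr_decay_epoch: int | None = None,
    lr_decay_factor: float = 0.3,
) -> tuple[GNNModel, GNNTrainingReport]:
    """Adam training with early stopping at the test-loss minimum.

    Loss = CE(polymorph) + CE(topology) with equal weights (topology term
    only when the head is enabled).  One graph (frame) per optimizer step.
    """
    if not train_data or not test_data:
        raise ValidationError("need non-empty train and test sets")
    rng = np.random.default_rng(seed)
    model = GNNModel(config, class_names, vocab, rng=rng)
    names = sorted(model.params)
    opt = ad.Adam([model.params[k] for k in names], lr=lr)
    report = GNNTrainingReport(n_parameters=model.n_parameters())

    best_loss = np.inf
    best_params: dict[str, np.ndarray] | None = None
    since_best = 0
    for epoch in range(max_epochs):
        if lr_decay_epoch is not None and epoch == lr_decay_epoch:
            opt.lr *= lr_decay_factor
        order = rng.permutation(len(train_data))
        ep_losses = []
        for gi in order:
            opt.zero_grad()
            loss = _graph_loss(model, train_data[gi], rng)
            loss.backward()
            opt.step()
            ep_losses.append(float(loss.data))
        report.train_losses.append(float(np.mean(ep_losses)))
        test_loss = float(
            np.mean([_graph_loss(model, lg, None).data for lg in test_data])
        )
        report.test_losses.append(test_loss)
        if test_loss < best_loss - 1e-12:
            best_loss = test_loss
            best_params = {k: v.data.copy() for k, v in model.params.items()}
            report.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best_params is not None:
        for k, v in best_params.items():
            model.params[k].data = v

    # held-out accuracies at the restored checkpoint
    poly_ok = poly_n = topo_ok = topo_n = 0
    for lg in test_data:
        poly, topo = model.predict_proba(lg.graph)
        poly_ok += int(np.sum(poly.argmax(axis=1) == lg.poly_labels))
        poly_n += len(lg.poly_labels)
        if topo is not None and lg.topo_labels is not None:
            topo_ok += int(np.sum(topo.argmax(axis=1) == lg.topo_labels))
            topo_n += len(lg.topo_labels)
    report.test_poly_accuracy = poly_ok / max(poly_n, 1)
    if topo_n:
        report.test_topo_accuracy = topo_ok / topo_n
    return model, report
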