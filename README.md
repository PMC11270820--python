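# xtalenv

Per-molecule classification of local structural environments in molecular
crystals, with two parallel models:

* **SF classifier** — handcrafted *molecular symmetry functions* computed on a
  point-vector reduction of each molecule (a position atom plus intramolecular
  orientation vectors), fed to a small MLP (two hidden layers of 25, softmax
  output). Four descriptor families: radial Gaussian, radial cosine, and two
  orientational families over the angle between same-slot vectors of
  neighboring molecules, all gated by a smooth cosine cutoff. The shipped
  default set has 24 functions.
* **GNN classifier** — an atomistic graph network: learnable atom-type node
  embeddings, spherical-Bessel edge embeddings (cutoff 6 Å), attention-based
  (TransformerConv-style) graph convolutions with residual/layer-norm node
  updates, per-molecule channel-wise **max aggregation**, and a two-head
  output (polymorph class + surface/bulk topology).

Around the models: trajectory I/O (extended XYZ and LAMMPS text dump),
periodic-boundary-aware neighbor lists, the coordination-number surface rule
(surface ⇔ CN < 20 within R\_c = molecule radius + graph cutoff), per-frame
composition time series and region filters for interface tracking, and a
fully synthetic fixture generator (three toy polymorph lattices, melt,
spherical clusters, two-phase slabs, seeded rigid-molecule thermal noise) so
everything is testable without MD data.

Both neural models are implemented in NumPy on a small reverse-mode autodiff
engine (`xtalenv.autodiff`) that is gradient-checked against finite
differences; no GPU or deep-learning framework is required.

## CLI

```bash
# generate labeled synthetic fixtures (extxyz + labels.csv + manifest.json)
xtalenv make-fixtures --out data/ --seed 1

# per-molecule descriptors to CSV
xtalenv descriptors --frames data/aligned.extxyz --out desc.csv

# train either model; writes a JSON checkpoint and a metrics report
xtalenv train --data data/ --model sf  --out sf.json  --report sf_report.json --seed 1
xtalenv train --data data/ --model gnn --out gnn.json --report gnn_report.json --seed 1

# classify a trajectory, then build composition time series
xtalenv classify --model sf.json --model-kind sf --frames data/cluster.extxyz --out records.csv
xtalenv analyze --records records.csv --out series.json --grouping core_surface
```

Exit codes: 0 success, 2 configuration error, 3 data error. Every command
honors `--seed` and emits a provenance block (config hash, seed, version).

## Library quick start

```python
import numpy as np
from xtalenv import (read_frames, group_molecules, build_neighbor_list,
                     extract_point_vectors, compute_descriptors,
                     default_descriptor_set)
from xtalenv.fixtures import shipped_polymorphs, make_lattice_polymorph, toy_template

frame, labels = make_lattice_polymorph(shipped_polymorphs()["aligned"], (4, 4, 4))
groups = group_molecules(frame)
pv = extract_point_vectors(frame, groups, toy_template())
nlist = build_neighbor_list(np.array([m.r for m in pv]), frame.cell, 7.5)
descriptors = compute_descriptors(pv, nlist, default_descriptor_set())
```

## Layout

| module | role |
| --- | --- |
| `xtalenv.crystal_io` | frame I/O, molecule grouping, minimum image, neighbor lists |
| `xtalenv.point_vector` | point-vector molecule extraction and template validation |
| `xtalenv.symfuncs` | the four molecular symmetry-function families + descriptor sets |
| `xtalenv.autodiff` | minimal reverse-mode autodiff (NumPy) |
| `xtalenv.sf_classifier` | descriptor MLP: training, prediction, checkpointing |
| `xtalenv.gnn` | graph classifier: graph building, forward pass, training |
| `xtalenv.analysis` | CN topology rule, trajectory classification, composition series |
| `xtalenv.fixtures` | synthetic polymorph/melt/cluster/slab generators |
| `xtalenv.metrics` | confusion matrix, micro F1, per-class precision/recall |
| `xtalenv.cli` | `xtalenv` command-line entry point |
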