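# fedceph

Federated CNN simulation for orthodontic skeletal classification from
lateral cephalograms.

Orthodontists classify the sagittal jaw relationship into skeletal Class I
(normal), II (retruded mandible) or III (protruded mandible) from the **ANB
angle** — the angle at nasion (N) between the rays to A-point (maxilla) and
B-point (supramentale, mandible). Clinics that would benefit from pooling
their radiographs to train a classifier usually cannot share images.
`fedceph` is a desk-scale laboratory for that setting: it labels images by
their ANB angle under configurable threshold standards, builds dense
convolutional classifiers augmented with attention blocks, and compares
three training regimes on two simulated clinic clients —

- **LL** (local learning): each client trains alone, tested on the shared
  test pool;
- **CL** (centralized learning): all training data pooled;
- **FL** (federated learning): FedAvg — per round, clients train locally
  and a server averages their parameter vectors weighted by sample count,
  with no data leaving a client.

## What is inside

- `fedceph.labeling` / `fedceph.manifest` — landmark-file parsing (A/N/B as
  the 5th/2nd/6th of 19 landmarks), the signed ANB angle, the Steiner
  ([3.2°, 5.7°] Class I band) and Kim ([0°, 4°]) standards, manifest
  labeling with per-client standards.
- `fedceph.attention` — channel attention, spatial attention (7×7 gate),
  squeeze-and-excitation and spatial pyramid pooling ([4, 8, 16] grids) as
  pure feature-map transforms.
- `fedceph.models` — a DenseNet-121-style backbone (plus a `tiny` preset
  for CPU work) with six heads: plain, CA, SA, SE, SA_SE, SPP, on a compact
  numpy autodiff engine (`fedceph.nn`).
- `fedceph.estimator` — `CephCNNClassifier`, a scikit-learn-compatible
  `fit`/`predict`/`predict_proba` wrapper.
- `fedceph.federated` — fault-tolerant FedAvg simulation (failed clients
  excluded, weights renormalized).
- `fedceph.harness` / `fedceph.metrics` / `fedceph.stats` — LL/CL/FL runs,
  weighted P/R/F1, Cohen's kappa, mean one-vs-rest AUC, confusion matrices,
  the federation contribution table, paired t-test, Shapiro–Wilk, stratified
  five-fold splits.
- `fedceph.synthetic` — a two-client synthetic cephalogram generator with
  exact, provably self-consistent class control (see `docs/methods.md`).
- `fedceph.cli` — the `fedceph` command (`generate`, `label`, `train`,
  `report`, `stats`).

## Worked example

```python
from fedceph import KIM, STEINER, Point2D, classify_skeletal, compute_anb_angle

a, n, b = Point2D(600.9, 724.9), Point2D(598.1, 564.9), Point2D(583.7, 770.2)
ang = compute_anb_angle(a, n, b)          # pixel coordinates, y down
print(f"ANB = {ang:.2f}")
print("Kim ->", classify_skeletal(ang, KIM).label,
      "; Steiner ->", classify_skeletal(ang, STEINER).label)
```

prints

```
ANB = 5.01
Kim -> II ; Steiner -> I
```

— the same patient is Class II under one clinic's convention and Class I
under the other's, the cross-standard disagreement band the federated
setting has to absorb.

End to end from the shell:

```sh
fedceph generate --out data/ --n-a 856 --n-b 400 --seed 0
fedceph label --manifest data/manifest.csv --out-report data/labels.json
fedceph train --data data/ --setting fl --model sa_se --seed 0 --out fl.json
fedceph report --contributions
```

`fedceph report --contributions` prints, per model variant, the published
benchmark's federation gains (FL−LL accuracy per client dataset) and the
centralization sacrifice (CL−FL); for the SA+SE variant the gains are
0.0373 (large client) and 0.1522 (small client) with CL−FL = −0.0112, i.e.
the federated model beat centralized pooling.

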