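# sparsemil

Multiple-instance bag classification with **sparsemax attention pooling**.

A *bag* (e.g. a tissue sample) carries one binary label and a variable-size
set of fixed-length instance feature vectors (e.g. 30-dimensional TCR
embeddings). Only a subset of instances — the *primary* instances — explains
the label. The classifier here is an instance-wise residual network with
shared weights, a masked attention scorer, and sparsemax pooling: the
Euclidean projection of the attention scores onto the probability simplex.
Unlike softmax, sparsemax assigns **exact zero** weight to uninformative
instances, so the support of the attention vector doubles as an instance
selector and makes predictions interpretable.

The package is pure NumPy (no deep-learning framework): forward and backward
passes, including the Jacobian of the simplex projection, are implemented and
verified against finite differences and a brute-force KKT enumeration oracle.

## Contents

| module                  | what it does |
|-------------------------|--------------|
| `sparsemil.sparsemax`   | simplex projection: forward map, adaptive threshold, support, JVP, masked/batched variants, brute-force oracle |
| `sparsemil.model`       | the network: residual instance-wise blocks, dropout, attention scorer, sparsemax/softmax pooling, batch norm, sigmoid head |
| `sparsemil.data`        | bag data model, zero-padding + masking, TSV/CSV readers/writers, seeded synthetic-bag generator with ground-truth primary flags |
| `sparsemil.atchley`     | Atchley-factor encoding of amino-acid strings (checksummed packaged table) |
| `sparsemil.train`       | Adam training loop with epoch-wise model selection, AUC, stratified k-fold CV |
| `sparsemil.experiments` | ablation grid, bag-capacity sweep, attention/feature heatmaps, primary-instance selection, reference-distance report, method rank statistics |
| `sparsemil.cli`         | `sparsemil` command-line interface |

## Quick start (library)

```python
from sparsemil import (
    SyntheticSpec, generate_synthetic, ModelConfig, TrainConfig,
    train, cross_validate,
)

bags = generate_synthetic(SyntheticSpec(n_bags=400, positive_fraction=0.5, seed=1))
cv = cross_validate(bags, ModelConfig(), TrainConfig(epochs=100, seed=1))
print(cv.mean_auc, cv.sd_auc)

model, history = train(bags, ModelConfig(), TrainConfig(epochs=100, seed=1))
from sparsemil.experiments import label_primary_instances
print(label_primary_instances(model, bags[0]))  # attention support = selected instances
```

## Command line

```bash
sparsemil --seed 1 --out-dir runs/sim simulate --n-bags 400 --signal-shift 1.0
sparsemil --seed 1 --out-dir runs/cv cv runs/sim/bags.tsv --k 10
sparsemil --seed 1 --out-dir runs/abl ablation runs/sim/bags.tsv
sparsemil --seed 1 --out-dir runs/sens sensitivity runs/sim/bags.tsv --grid 30,60,90,120,150
sparsemil --out-dir runs/train train runs/sim/bags.tsv
sparsemil --out-dir runs/hm heatmap runs/sim/bags.tsv runs/train/model
sparsemil --out-dir runs/sel select-instances runs/sim/bags.tsv runs/train/model
sparsemil --out-dir runs/cmp compare aucs.csv --method-a sparse-attn --method-b baseline
```

Model/training hyperparameters come from a YAML config
(`--config cfg.yaml`):

```yaml
model:
  p: 30
  n_blocks: 4
  use_skip: true
  pooling: sparsemax   # or softmax
  dropout_rate: 0.3
train:
  epochs: 100
  learning_rate: 1e-3
  batch_size: 32
```

Every run writes a `manifest.json` (command, seed, package version, resolved
config, input checksums) next to its outputs.

### Bag file format

Long form, one row per instance, TSV (comma accepted via `sep`):

```
bag_id  label  instance_id  f1  f2 ... fp
```

Labels are {0,1}; instance order within a bag is meaningful (bags larger
than the capacity m* keep their first m* instances). The synthetic generator
additionally writes `bags.truth.tsv` with ground-truth primary flags.

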