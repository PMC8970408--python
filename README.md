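# pcnet

Predictive-coding learning algorithms for feedforward neural networks,
implemented from first principles in NumPy, together with a
backpropagation reference, fixed-point diagnostics, a finite-difference
gradient oracle, a mini-batch training driver, and seeded synthetic
datasets.

Three algorithms share one result contract (`PCResult`):

- **`backprop_update`** — exact gradients via the standard backward
  recursion of vector–Jacobian products.
- **`strict_pc_update`** — strict predictive coding: iterative gradient
  descent of the free energy (half the summed squared prediction errors)
  on per-layer beliefs, with predictions recomputed from the current
  beliefs each sweep. Its converged updates generally *differ* from the
  true gradients but still support learning.
- **`fixed_pred_pc_update`** — predictive coding under the fixed
  prediction assumption: predictions and Jacobian linearization points are
  frozen at the forward-pass activations. With step size `eta=1` and `n=L`
  inference iterations (L = network depth) the updates equal
  backpropagation's gradients exactly, layer by layer, and the errors
  converge on a strict layer-by-layer schedule (layer `l` is correct from
  iteration `L - l + 1`).
- **`precision_fixed_pred_update`** — the precision-weighted variant:
  hidden-layer precision matrices reshape the inference trajectory but
  leave converged updates unchanged; an output-layer precision
  (squared-Euclidean loss only) re-weights the converged updates.

`pc_infer(model, loss, x, y, err_type=...)` dispatches between
`"exact"`, `"strict"`, and `"fixed_pred"`.

Layers: `affine`, `conv2d` (naive, stride 1), `relu`, `tanh`, `flatten`,
and `block` (a chain of sub-layers acting as one layer). Losses:
squared-Euclidean and softmax cross-entropy, mean-over-batch.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the headline guarantees (exact
equivalence over random networks, the iteration schedule, oracle
agreement, strict-PC fixed-point equations, precision invariance, and
training parity); the rest are unit and property tests.

## CLI

All commands take a JSON (or YAML) config; see the module docstring of
`pcnet/cli.py` for the schema. Common overrides: `--seed`, `--out`,
`--err-type`, `--eta`, `--n`.

```sh
pcnet train config.json          # metrics.csv + parameter checkpoint
pcnet compare config.json        # (eta, n) sweep vs backprop -> sweep.csv
pcnet gradcheck config.json      # backprop vs finite differences
pcnet make-data config.json      # generate + archive a synthetic dataset
```

Invalid configs exit with status 2; a failed gradient check exits 1.

## Library example

```python
import numpy as np
import pcnet as pc

model = pc.sequential_mlp([10, 16, 4], "tanh", seed=0)
data = pc.make_blobs(seed=0, n_samples=256, dim=10, n_classes=4)

# one inference/update step
res = pc.pc_infer(model, "squared_euclidean", data.x[:32],
                  data.y_onehot[:32], err_type="fixed_pred",
                  eta=1.0, n=model.depth)

# full training run
cfg = pc.TrainConfig(seed=0, err_type="strict", eta=0.1, n_iters=20,
                     epochs=10, learning_rate=0.1)
metrics = pc.train(model, data, cfg)
```
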