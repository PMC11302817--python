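# cylqa

Delivery-error simulation, gamma-index analysis and CNN error classification
for cylindrical-array patient-specific radiotherapy QA.

The package implements an end-to-end study of whether a small convolutional
network can identify *which* delivery error caused a plan-verification
failure — something the clinical gamma-pass-rate (GPR) criterion cannot do.
It provides:

- **`cylqa.simulate`** — a synthetic generator of paired dose maps on an
  unwrapped 21x66 cylindrical diode array. Each plan pair consists of a
  "calculated" channel carrying exactly one injected delivery error (gantry
  ±1°, collimator ±1°, couch ±1°, dose ±2%, or none) and an error-free
  "measured" channel with multiplicative detector noise. Balanced over the
  five classes; gantry errors are never drawn from arc (VMAT) plans.
- **`cylqa.gamma`** — per-point gamma index and pass rate on the cylinder
  surface (global normalization, geodesic surface distance with
  circumferential wraparound, bilinear sub-diode search), plus the three
  clinical criteria 3%/3 mm (>95%), 3%/2 mm (>90%) and 2%/2 mm (>85%).
- **`cylqa.dataset`** — resampling onto the diode lattice, joint
  (pair-preserving) max normalization, label-preserving augmentation
  (300 plans → 1125 training instances), and the stratified 3:1 split with
  5 folds of 225.
- **`cylqa.model`** — the 5-class CNN (stem conv 2→16; three conv+BN+ReLU
  blocks with 2x2 pooling; global average pooling; FC 64→128; dropout 0.5;
  FC 128→5; softmax), trained with Adam on categorical cross-entropy,
  5-fold cross-validation with softmax averaging, and a hyperparameter grid
  search. Implemented in pure NumPy (no GPU/torch dependency), ~35k
  parameters, CPU-trainable.
- **`cylqa.evaluate`** — accuracy/precision/recall/F1 (macro for
  multi-class), one-vs-rest ROC/AUC, per-class GPR distributions, and the
  binary-collapse CNN-vs-GPR comparison tables.
- **`cylqa.io` / `cylqa.cli`** — HDF5 and delimited-text dataset containers
  (bit-exact round trips), a minimal DICOM RT-DOSE reader, YAML run
  configurations, and a `click` CLI.

## CLI

```bash
cylqa simulate --n-per-class 60 --seed 0 --noise 0.005 --out dataset.h5
cylqa gamma --measured meas.tsv --calculated calc.tsv --criteria 3,3 \
            --threshold 10 --pass 95 --report gamma.json
cylqa split --data dataset.h5 --seed 0 --out split.json
cylqa train --data dataset.h5 --split split.json --epochs 20 --out model/
cylqa predict --model model/ --data dataset.h5 --out preds.json
cylqa evaluate --preds preds.json --data dataset.h5 --out report/
cylqa run --out run/           # whole pipeline with defaults
```

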