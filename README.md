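# seednet

Classify crop-seed varieties from near-infrared hyperspectral images when
labeled samples are scarce.

Breeders screening offspring for a trait, and market regulators checking
seed-lot purity, both need fast non-destructive variety identification.
Hyperspectral imaging (HSI) delivers a full NIR reflectance spectrum at
every pixel of a scene of seeds, and a deep 1D network can classify those
spectra very accurately — *if* thousands of labeled seeds exist. For most
target crops they do not. `seednet` implements the workflow that bridges
that gap: train a deep network on one sample-rich crop, then **transplant
its weights, freeze the convolutional feature extractor, and fine-tune the
dense head** on the few dozen labeled seeds of the target crop.

The package covers the full chain:

* **hsi_io** — ENVI / HDF5 / delimited cube I/O, reflectance calibration
  `R = (I_raw − I_dark)/(I_white − I_dark)`, cropping to the usable
  975–1646 nm window;
* **segmentation** — automatic contrast-band selection (Otsu inter-class
  variance), threshold + morphology + connected components, per-seed ROI
  mean spectra with per-pixel wavelet denoising *before* averaging;
* **preprocess** — stratified 3:1:1 / 1:2:2 splits with exact-total
  rounding, nested 10–100 % training-fraction subsampling, spectra tables;
* **deep_models** — three 1D architectures in a self-contained NumPy
  engine with verified backprop: a VGG-style net (two conv blocks, 16/32
  filters), a residual net (1×7 stem, four blocks, 32→256 filters), and an
  inception net (four 4-branch multi-scale blocks, 16→128 base filters);
  SGD-momentum training with validation-accuracy checkpointing;
* **transfer** — bit-exact weight transplant (output layer reinitialized
  only when class counts differ), freezing before the flatten boundary
  (batch-norm statistics included), gentle fine-tuning (batch 3, lr 1e-4);
* **baselines** — LDA, PLS-DA, RBF-SVM and MLP with their full
  hyperparameter grids, all selected on validation accuracy;
* **synthetic** — seeded generators for realistic seed spectra (absorption
  features at 1119/1207/1308/1470 nm, per-sample scatter drift), related
  source/target domain pairs, and full calibration-ready scenes;
* **viz / experiments** — t-SNE of raw spectra and flatten/Fc1/Fc2
  features, spatial classification maps, and the comparison / sample-size
  sweep harness.

## A worked example

Transfer from a sample-rich synthetic crop (4 varieties, 100 seeds each)
to a related crop with only **5 labeled training seeds per variety**
(`examples/04_transfer_learning.py`):

```python
import seednet as sn
from seednet.transfer import TransferPlan, default_finetune_config, finetune, transplant

src_cfg = sn.SpectraGeneratorConfig(n_classes=4, n_per_class=100, seed=10, name="src")
tgt_cfg = sn.SpectraGeneratorConfig(n_classes=3, n_per_class=250, seed=20, name="tgt")
source, target = sn.generate_domain_pair(src_cfg, tgt_cfg, shared_structure=0.8)

s_split = sn.split_stratified(source.labels, (3, 1, 1), seed=0)
src_model = sn.build_vgg(source.n_bands, 4, seed=0)
sn.train(src_model, source, s_split, sn.TrainConfig(epochs=60, seed=0))

full = sn.split_stratified(target.labels, (1, 2, 2), seed=0)
split = sn.subsample_training(full, target.labels, 0.1, seed=0)   # 5 per class

ft = default_finetune_config(0); ft.epochs = 100
plan = TransferPlan(source=src_model, target_n_classes=3, finetune_cfg=ft, seed=0)
tr = finetune(transplant(plan), plan, target, split)

scratch = sn.build_vgg(target.n_bands, 3, seed=0)
sc = sn.train(scratch, target, split, sn.TrainConfig(epochs=100, seed=0))
```

Output:

```
source model test accuracy: 0.975
transplanted; reinitialized layers: ['fc2']
fine-tuned transfer: 1.000   from scratch: 0.940
```

The source model reaches 97.5 % on its own test set. Because the target
crop shares most of the source's absorption-band structure, the
transplanted feature extractor lets the fine-tuned model hit 100 % on the
300-spectrum target test set from just 15 training spectra, while the same
architecture trained from scratch on those 15 spectra reaches 94 %.
Accuracies at such tiny training sizes are seed-sensitive; the experiment
harness (`run_size_sweep`) repeats over seeds and reports medians.

A thin CLI mirrors the library for shell pipelines:

```bash
seednet simulate --n-classes 4 --n-per-class 250 --seed 0 --out data/source.csv
seednet train-source --table data/source.csv --arch vgg --epochs 60 --out models/src.npz
seednet transfer --source models/src.npz --table data/target.csv --fraction 0.1 --out models/tgt.npz
```

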