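"""Generate a synthetic seed-spectra dataset and split it for modeling.

Builds a 4-variety NIR dataset (200 bands, 975-1646 nm, absorption features
near 1119/1207/1308/1470 nm), splits it 3:1:1 per variety, and shows the
nested 10%-of-training subsampling used for sample-size sweeps.
"""

import numpy as np

import seednet as sn

cfg = sn.SpectraGeneratorConfig(n_classes=4, n_per_class=250, seed=0, name="demo")
data = sn.generate_spectra(cfg)
print(f"dataset: {data.n_samples} spectra x {data.n_bands} bands, "
      f"classes {data.class_names}")

split = sn.split_stratified(data.labels, (3, 1, 1), seed=0)
print(f"3:1:1 split -> train/val/test = {split.counts()}")

sub = sn.subsample_training(split, data.labels, 0.1, seed=0)
per_class = np.bincount(data.labels[sub.train_idx])
print(f"10% of the training set keeps {per_class} samples per class")
# The three subset sizes always sum to the dataset size; the 10% subset is
# contained in the 20% subset for the same seed (nested subsampling).
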