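"""The three augmentation operators and oversampling, on one dataset.

Each method samples 50% of a 100-spectrum training set, transforms the
sampled items (or duplicates them, for oversampling), and appends the
results: the output always holds exactly 100 + 50 spectra. Horizontal
shift and vertical noise keep labels; linear combination unions them.
"""

import numpy as np

from irfgnet import (
    AugmentationConfig,
    SyntheticConfig,
    augment_dataset,
    generate_dataset,
    synthetic_catalog,
)

catalog = synthetic_catalog(4)
dataset = generate_dataset(SyntheticConfig(n_samples=100, catalog=catalog, seed=3))

for method in ("oversample", "horizontal_shift", "vertical_noise", "linear_combination"):
    out = augment_dataset(dataset, AugmentationConfig(method=method, fraction=0.5, seed=11))
    appended = out[len(dataset):]
    mean_popcount = np.mean([item.labels.bits.sum() for item in appended])
    print(
        f"{method:>18}: {len(dataset)} -> {len(out)} spectra; "
        f"mean groups per appended spectrum {mean_popcount:.2f}"
    )
print("(linear combination shows the largest mean group count: its labels")
print(" are the OR of both parents'.)")
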