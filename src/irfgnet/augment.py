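"""Training-set augmentation and oversampling for IR spectra.

Three augmentation operators plus plain oversampling as a control:

* horizontal shift — translate the spectrum a few grid bins, filling the
  vacated edge with the nearest retained value (max-pooling makes the
  network tolerant to such translations);
* vertical noise — multiplicative Gaussian noise, so the perturbation at a
  point scales with the intensity there;
* linear combination — convex mix of two spectra with label union;
* oversample — exact duplicates of a sampled subset.

Operators are applied to a sampled fraction (25/50/75/100%) of the training
split only; augmented copies are appended to the originals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import LabelVector
from .spectra import ProcessedSpectrum
from .synth import LabeledSpectrum

__all__ = [
    "AugmentationConfig",
    "horizontal_shift",
    "vertical_noise",
    "linear_combination",
    "oversample",
    "augment_dataset",
]

_FRACTIONS = (0.25, 0.5, 0.75, 1.0)
_METHODS = ("oversample", "horizontal_shift", "vertical_noise", "linear_combination")


@dataclass
class AugmentationConfig:
    method: str
    fraction: float
    seed: int
    max_shift_bins: int = 5  # ~30 cm^-1 on the default grid
    noise_sd_rel: float = 0.05
    mix_low: float = 0.3
    mix_high: float = 0.7

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown augmentation method {self.method!r}")
        if self.fraction not in _FRACTIONS:
            raise ValueError(f"fraction must be one of {_FRACTIONS}, got {self.fraction}")
        if not (0 < self.mix_low <= self.mix_high < 1):
            raise ValueError("require 0 < mix_low <= mix_high < 1")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be nonnegative")
        if not (1 <= self.max_shift_bins <= 30):
            raise ValueError("max_shift_bins must be in 1..30")


def horizontal_shift(s: ProcessedSpectrum, shift_bins: int) -> ProcessedSpectrum:
    """Translate intensities by ``shift_bins`` grid positions.

    Positive shifts move features toward higher wavenumbers. Vacated edge
    bins repeat the nearest retained edge value. Labels are unaffected.
    """
    n = len(s.intensities)
    if abs(shift_bins) >= n:
        raise ValueError(f"|shift_bins| = {abs(shift_bins)} exceeds grid length {n}")
    if shift_bins == 0:
        return ProcessedSpectrum(s.intensities.copy(), grid=s.grid, meta=dict(s.meta))
    y = s.intensities
    if shift_bins > 0:
        out = np.concatenate([np.full(shift_bins, y[0]), y[:-shift_bins]])
    else:
        k = -shift_bins
        out = np.concatenate([y[k:], np.full(k, y[-1])])
    return ProcessedSpectrum(out, grid=s.grid, meta=dict(s.meta))


def vertical_noise(
    s: ProcessedSpectrum, noise_sd_rel: float, rng: np.random.Generator
) -> ProcessedSpectrum:
    """Multiplicative noise: x' = x * (1 + eps), eps ~ N(0, noise_sd_rel^2).

    The perturbation magnitude at each point is proportional to the
    intensity there; zero bins stay exactly zero. Clipped back to [0, 1].
    """
    if noise_sd_rel < 0:
        raise ValueError("noise_sd_rel must be nonnegative")
    if noise_sd_rel == 0:
        return ProcessedSpectrum(s.intensities.copy(), grid=s.grid, meta=dict(s.meta))
    eps = rng.normal(0.0, noise_sd_rel, size=s.intensities.shape)
    out = np.clip(s.intensities * (1.0 + eps), 0.0, 1.0)
    return ProcessedSpectrum(out, grid=s.grid, meta=dict(s.meta))


def linear_combination(a: LabeledSpectrum, b: LabeledSpectrum, lam: float) -> LabeledSpectrum:
    """Mix two labeled spectra: lam*a + (1-lam)*b, labels = a OR b.

    The mixture is re-normalized to [0, 1]. Labels stay binary: the mixed
    spectrum contains every band of both parents, so the union is the
    faithful multi-label reading.
    """
    if a.spectrum.grid != b.spectrum.grid:
        raise ValueError("linear_combination requires a common grid")
    if len(a.labels.bits) != len(b.labels.bits):
        raise ValueError("linear_combination requires a common catalog")
    if not (0 < lam <= 1):
        raise ValueError("lam must lie in (0, 1]")
    y = lam * a.spectrum.intensities + (1.0 - lam) * b.spectrum.intensities
    lo, hi = y.min(), y.max()
    y = np.zeros_like(y) if hi - lo < 1e-12 else (y - lo) / (hi - lo)
    bits = np.maximum(a.labels.bits, b.labels.bits)
    sid = f"{a.labels.source_id}+{b.labels.source_id}"
    return LabeledSpectrum(
        spectrum=ProcessedSpectrum(y, grid=a.spectrum.grid, meta={"augmented": "linear_combination"}),
        labels=LabelVector(bits=bits, source_id=sid),
    )


def oversample(
    dataset: list[LabeledSpectrum], fraction: float, rng: np.random.Generator
) -> list[LabeledSpectrum]:
    """Append exact duplicates of round(fraction*n) sampled items.

    Sampling is without replacement within the sampled subset (every
    duplicate has a distinct source), so at fraction 1.0 each item appears
    exactly twice.
    """
    if not dataset:
        raise ValueError("empty dataset")
    if fraction not in _FRACTIONS:
        raise ValueError(f"fraction must be one of {_FRACTIONS}, got {fraction}")
    n = len(dataset)
    k = round(fraction * n)
    idx = rng.choice(n, size=k, replace=False)
    extra = [
        LabeledSpectrum(
            spectrum=ProcessedSpectrum(
                dataset[i].spectrum.intensities.copy(),
                grid=dataset[i].spectrum.grid,
                meta={**dataset[i].spectrum.meta, "augmented": "oversample"},
            ),
            labels=dataset[i].labels,
        )
        for i in idx
    ]
    return list(dataset) + extra


def augment_dataset(
    dataset: list[LabeledSpectrum], config: AugmentationConfig
) -> list[LabeledSpectrum]:
    """Apply the configured augmentation to a sampled training fraction.

    Samples round(fraction*n) items without replacement, transforms each
    (random nonzero shift, multiplicative noise, or mixing with a uniform
    random partner from the full set), and appends the results. Output size
    is exactly n + round(fraction*n). Never apply to evaluation splits.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    if config.method == "oversample":
        return oversample(dataset, config.fraction, rng)
    n = len(dataset)
    k = round(config.fraction * n)
    idx = rng.choice(n, size=k, replace=False)
    extra: list[LabeledSpectrum] = []
    for i in idx:
        item = dataset[i]
        if config.method == "horizontal_shift":
            choices = [s for s in range(-config.max_shift_bins, config.max_shift_bins + 1) if s]
            shift = int(rng.choice(choices))
            extra.append(
                LabeledSpectrum(
                    spectrum=horizontal_shift(item.spectrum, shift), labels=item.labels
                )
            )
        elif config.method == "vertical_noise":
            extra.append(
                LabeledSpectrum(
                    spectrum=vertical_noise(item.spectrum, config.noise_sd_rel, rng),
                    labels=item.labels,
                )
            )
        else:  # linear_combination
            j = int(rng.integers(n))
            lam = float(rng.uniform(config.mix_low, config.mix_high))
            extra.append(linear_combination(item, dataset[j], lam))
    return list(dataset) + extra
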