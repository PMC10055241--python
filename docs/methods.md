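# Methods

## Problem and scope

`irfgnet` performs multi-label classification of functional groups from
infrared spectra. A molecule may carry any subset of the catalog's groups;
the network outputs one independent sigmoid probability per group. The
package covers the full workflow: ground-truth labeling of molecules from
SMILES, spectrum preprocessing, synthetic data generation, the CNN with its
two losses, augmentation, threshold tuning, and evaluation. It does not
attempt structure elucidation (assembling groups into a parent molecule),
baseline correction or peak picking, or any quantum-chemical simulation of
vibrational spectra.

## Functional-group catalogs

The extended catalog holds 37 groups in a fixed canonical order (Alkane,
Alkene, …, Sulfide); label vectors and model outputs are always indexed in
this order. The original catalog is the first 22 rows — the most common
groups in organic chemistry — and is exposed as a configurable list, since
"most common" is corpus-dependent.

Membership is decided by SMARTS matching with deliberately disjoint sibling
definitions: Alcohol is a hydroxyl on a non-aromatic carbon outside
carboxyl/enol context; Phenol is hydroxyl on aromatic carbon; ester and
anhydride oxygens are excluded from Ether; amide, imide, carbamate and
enamine nitrogens are excluded from Amine; formyl carbons inside acids,
esters, amides and related carbonyls are excluded from Aldehyde. Two
mechanisms implement this: recursive SMARTS environments inside the
patterns, and a priority-exclusion pass — the first atom of every pattern
is the group's *key* atom, and a candidate match is discarded when its key
atom lies inside any raw match of a group listed in its
`priority_exclusions`. The exclusion semantics are a design choice of this
package; where the community disagrees (e.g. whether phenols count as
alcohols), the patterns are data and can be replaced.

Alkane deserves a note: it matches sp³ carbons whose neighbors are all
carbon or hydrogen, so a lone methyl on a heteroatom (dimethyl sulfide,
methylphosphine) is *not* an alkane fragment, while any molecule with an
unperturbed CH₂/CH₃ backbone is.

## Spectrum preprocessing

Raw spectra are read from JCAMP-DX (the `(X++(Y..Y))` AFFN and
`XYPOINTS` dialects, honoring XFACTOR/YFACTOR/FIRSTX/LASTX/NPOINTS;
compressed SQZ/DIF ordinates are out of scope) or two-column CSV.
Processing is intentionally minimal:

* transmittance → absorbance by A = −log₁₀(T), percent divided by 100
  first, T clipped below at 10⁻⁶ (bounding A at 6);
* linear interpolation onto 600 evenly spaced points over 400–4000 cm⁻¹
  inclusive (≈6.01 cm⁻¹ spacing) — grid points outside the measured range
  take the nearest observed value rather than zero, to avoid fabricating
  absorption edges;
* per-spectrum min–max normalization to [0,1]. A constant spectrum maps to
  all zeros with a warning rather than an error, so degenerate inputs
  cannot poison a batch.

CNN inputs benefit from the bounded range, and min–max is insensitive to
the (arbitrary) absorbance scale of archival spectra. No smoothing,
atmospheric-line removal or baseline correction is applied: the network is
expected to learn through those nuisances.

## Synthetic data generator

The generator emulates the features of real IR corpora that matter for the
classification task: group membership encoded as characteristic bands with
positional jitter and variable width/intensity, band overlap, a congested
fingerprint region, baseline drift and noise.

* Labels: independent Bernoulli draws per group (default prevalence 0.3),
  truncated to at most 10 groups per molecule — the regime observed in
  organic corpora, where molecules carry between one and ten functional
  groups. All-zero vectors are allowed.
* Bands: Gaussian profiles. Chemical groups use textbook correlation-chart
  center ranges (carbonyl near 1700 cm⁻¹, hydroxyl 3200–3550 cm⁻¹, …) with
  broad σ for hydride stretches; abstract study groups (`SynthGroupNN`) get
  single well-separated bands evenly spaced over 1550–3900 cm⁻¹. Gaussian
  rather than Lorentzian: fewer heavy tails on a 600-bin grid and one fewer
  parameter.
* Clutter: 2–6 random bands (amplitude 0.05–0.3) confined to 400–1500
  cm⁻¹, mimicking fingerprint congestion.
* Baseline: a random quadratic scaled by `baseline_amplitude` (default
  0.05); noise: i.i.d. Gaussian, default σ = 0.01.

Generation is a pure function of (config, seed). What the generator does
*not* model: vibrational coupling, solvent/matrix effects, instrument
artifacts, or real co-occurrence chemistry between groups. Tests passing
on synthetic data therefore certify the pipeline's mechanics and the
network's capacity to learn band-position codes — not state-of-the-art
accuracy on measured spectra.

## Network and training

Architecture: repeated Conv1D → BatchNorm → ReLU → MaxPool blocks, a
flatten, FC → ReLU → Dropout layers, and a final FC with sigmoid outputs.
The default is three conv blocks (16/32/64 filters, kernel 9, pool 2), one
FC layer of 128 units, dropout 0.5 — compact enough to train in minutes on
one CPU while solving the synthetic task; every size is a config field, so
larger variants (e.g. 32/64/128 filters, kernel 11, FC 256/128) are a
one-line change. Same-padding convolutions keep the pooling arithmetic
transparent (600 → 300 → 150 → 75).

The layers are implemented directly in NumPy (`irfgnet._nn`): Conv1D as
im2col plus GEMM, batch normalization over batch and length per channel
with running statistics for inference, max pooling with argmax routing,
inverted dropout, and Adam (β₁ = 0.9, β₂ = 0.999). float32 throughout;
analytic gradients are verified against central differences in the test
suite. All randomness (init, shuffling, dropout) flows from the training
seed, so single-threaded runs are reproducible to ~10⁻⁶ in the logged
losses.

Losses: BCE is the shipped default; WBCE multiplies each class's positive
log-term by w_pos[c] = (#negatives_c)/(#positives_c) with w_neg ≡ 1, the
standard imbalance correction. Classes with no positives get a capped
weight (default 100) with a warning. Unit weights reduce WBCE to BCE
bit-for-bit. Probabilities are clipped at 10⁻⁷ inside the losses; the
gradient is taken analytically through the sigmoid for stability. A
validation fraction (default 10%) is split off before training for
per-epoch monitoring and optional early stopping; NaN loss aborts with a
learning-rate hint.

## Thresholds

Default classification threshold is 0.5 per class, with ties counting as
positive. Tuning maximizes per-class F1 over candidate thresholds = unique
observed scores plus 0.5: F1 is piecewise constant between observed
scores, so the scan is exhaustive. Ties break toward the smallest
maximizing threshold (favoring recall, deterministic). Classes with no
positive tuning labels fall back to 0.5 with a warning. Tuning on the
training split is the default; a held-out tuning split is a caller choice.

## Metrics

Zero-denominator conventions are fixed once: precision with no predicted
positives is 1, recall with no true positives is 1, F1 is 0 when P+R = 0,
and classes with an empty denominator are excluded from means with a
warning — avoiding NaN propagation while never silently inventing a score.
Average precision is the step-interpolated sum Σ (Rₙ − Rₙ₋₁)·Pₙ traversed
from the highest threshold down (no trapezoidal smoothing), which makes a
perfect ranking score exactly 1 and a random scorer's expectation equal to
the positive prevalence (up to an O(1/n_pos) finite-sample bias). EMR by
class count uses the most-to-least-abundant class order computed from the
evaluated split's supports, ties broken by catalog index.

## Augmentation

Applied only to training data, on a sampled fraction ∈ {25, 50, 75, 100}%
(without replacement below 100%), appended to the originals so the output
size is exactly n + round(fraction·n).

* Horizontal shift: ±`max_shift_bins` grid bins (default 5 ≈ 30 cm⁻¹,
  within typical characteristic-range jitter while preserving band
  identity), edges filled with the nearest retained value; zero shift is
  excluded when sampling.
* Vertical noise: x′ = x(1+ε), ε ~ N(0, σ_rel²) — the perturbation at a
  point is proportional to the intensity there; zero bins stay zero;
  clipped to [0,1].
* Linear combination: λ·a + (1−λ)·b with λ uniform on [0.3, 0.7] (both
  parents' bands stay visible), re-normalized; labels are the element-wise
  OR of the parents, the faithful multi-label reading of a mixture.
* Oversampling: exact duplicates of the sampled subset, the control
  treatment.

## Validation studies and problem sizes

Two studies exercise the pipeline end to end at desk scale
(`irfgnet.experiments`):

* **Recovery**: 12 abstract groups, 4,000 training + 1,000 test spectra,
  default network, 10 epochs, BCE. With well-separated bands the task is
  solvable and the network should essentially solve it (macro F1 and EMR
  near 1 held out); the suite asserts macro F1 ≥ 0.90 and EMR ≥ 0.70.
* **Imbalance**: 8 groups, one at 2% prevalence with a weak band
  (amplitude 0.15–0.45) hidden at 1150–1250 cm⁻¹ among clutter of the same
  intensity scale; 2,000 train + 500 test, 6 epochs, 3 paired seeds. BCE
  tends to abandon the rare positives; WBCE (w_pos ≈ 49) recovers most of
  them at the cost of some false positives — presence accuracy of the rare
  class rises sharply while absence accuracy falls slightly, the expected
  direction of positive-term re-weighting.

These sizes were chosen as the smallest at which the two effects are
clearly resolved on a single CPU; `scripts/acceptance.py` re-runs both from
scratch for any seed.

## Known limitations

* The catalog's SMARTS are one defensible convention, not the only one;
  tautomer enumeration and 3D context are out of scope.
* The JCAMP reader covers the uncompressed tabular dialects only.
* Synthetic spectra cannot certify accuracy on measured corpora (no
  vibrational coupling or co-occurrence chemistry); they certify the
  machinery.
* The NumPy network is CPU-oriented; there is no GPU path, and very large
  architectures will be slow.
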