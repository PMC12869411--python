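# vsmo — thresholded visual-search model observer

`vsmo` simulates a nuclear-medicine-style planar imaging chain and evaluates
a two-stage **visual-search model observer** on the task of detecting *and
localizing* a lesion whose position is unknown. It provides:

- **Phantoms** — lumpy backgrounds (Poisson number of Gaussian lumps) with
  optional Gaussian lesions, imaged through a Gaussian pinhole aperture whose
  relative diameter trades blur against Poisson quantum noise
  (`vsmo.phantoms`).
- **Features** — a 48-kernel Gabor filter bank (2 window sizes × 3 center
  frequencies × 4 orientations × 2 phases) applied by FFT cross-correlation,
  refined to 12 kernels per study by greedy Hotelling-SNR selection
  (`vsmo.gabor`, `vsmo.features`).
- **The observer** — stage 1 scans a linear search statistic for candidate
  locations (local maxima with separation and border rules); stage 2 applies
  per-feature lower **thresholds** at each candidate and scores the surviving
  feature subset with its own branch discriminant (up to 2^k − 1 branches).
  Candidates with no surviving feature are discarded; images with no
  surviving candidate get a sentinel rating (no lesion reported). Setting
  every threshold to −∞ recovers a classical linear observer exactly
  (`vsmo.observer`).
- **Scoring** — empirical ROC and LROC areas with exact tie handling; a
  lesion is localized when the report falls within one lesion FWHM of truth
  (`vsmo.lroc`).
- **Experiments** — a pinhole-diameter sweep and a training-set-size study
  with CSV + manifest outputs (`vsmo.experiments`), plus a `vsmo` CLI
  (`simulate`, `fit`, `rate`, `score`, `sweep`, `train-study`).

See [`docs/methods.md`](docs/methods.md) for the full model description,
calibration choices, and a documented negative result about threshold-induced
variance reduction.

## Worked example

`examples/01_simulate_fit_rate.py` simulates 60 training and 60 test pairs at
the default aperture, trains both observer variants, and scores the test set
(~1 minute on one CPU):

```text
simulating 60 training and 60 test pairs ...
refining the 48-kernel Gabor bank to 12 kernels ...
training the two-stage observer ...
 unthresholded: ROC AUC = 0.899   LROC AUC = 0.775   correct localization = 0.85
   thresholded: ROC AUC = 0.907   LROC AUC = 0.768   correct localization = 0.83
fitted decision thresholds: [-inf, -inf, -inf]
branches in use: [(0, 1, 2)]
```

At this training size the one-standard-error rule judged every candidate
threshold to be noise and kept the thresholds at −∞ — by design: a threshold
is only accepted when its training gain exceeds the sampling noise of the
training objective.

The same pipeline in code:

```python
from vsmo import (ApertureModel, PhantomConfig, ObserverConfig,
                  default_filter_bank, generate_dataset,
                  fit_observer, rate_dataset, empirical_lroc_auc)

phantom, aperture = PhantomConfig(), ApertureModel(relative_diameter=1.0)
train = generate_dataset(phantom, aperture, n_pairs=60, seed=1)
test = generate_dataset(phantom, aperture, n_pairs=60, seed=2)
observer = fit_observer(train, default_filter_bank(), ObserverConfig())
records = rate_dataset(test, observer)
print(empirical_lroc_auc(records, radius=9.4).auc)
```

Other examples: `02_feature_pairing.py` (the analytic rule for when a weaker,
less correlated feature beats a strong redundant one — instant),
`03_pinhole_sweep.py` (the aperture trade-off peaking at relative diameter
1.0 — minutes), `04_training_size_study.py` (SE-vs-training-size curves and
the plateau rule — minutes).

## Command line

```bash
vsmo simulate --seed 1 --out data/train          # paired dataset
vsmo fit --train data/train --seed 1 --out model.json
vsmo rate --model model.json --data data/test --out ratings.csv
vsmo score --ratings ratings.csv --out scores.json
vsmo sweep --config sweep.yaml --out sweep.csv   # aperture sweep
vsmo train-study --config study.yaml --out study.csv
```

Config files are YAML whose keys mirror the corresponding dataclass fields
(`PhantomConfig`, `ObserverConfig`, `SweepConfig`, `TrainingSizeConfig`).

## Reproduction

Run the test suite (the two reduced-scale acceptance studies make this take
a few minutes):

```bash
python -m pytest -o addopts= -p no:cacheprovider -q
```

Recompute the headline study numbers from scratch (~5–10 minutes, one CPU;
all randomness derives from the seed):

```bash
python scripts/acceptance.py --seed 2025 --out targets.json
```

This reports the plateau standard error of the LROC AUC across training
trials (t3), the plateau training size of the thresholded observer (t4), the
relative SE change from thresholding at the smallest training size (t5), and
the best relative pinhole diameter (t6).

### Known-failing acceptance tests

Three acceptance tests encode claims that our reduced-scale studies do not
support, and are deliberately left failing rather than weakened:

- `test_acceptance_thresholding_se_reduction` and
  `test_acceptance_thresholding_plateau_efficiency`: decision thresholds did
  not cut the across-trial SE by >50% at small training sizes, nor reach the
  SE plateau with substantially fewer training cases. A stage-by-stage
  variance decomposition (see `docs/methods.md`) shows search-stage and
  decision-stage training noise are jointly produced and negatively
  correlated, so no single-stage mechanism can remove most of the variance.
- `test_acceptance_property_pw_vs_npw`: the prewhitening observer beats the
  nonprewhitening one in ROC area at every aperture, but the mean **LROC**
  ordering at one reduced-scale sweep is inside single-run sampling noise
  (multi-seed probes put the true mean difference at ≈ +0.001 ± 0.009).

Everything else — exact combinatorial and closed-form checks, reduction
tests, the aperture trade-off peak at relative diameter 1.0, and the SE
plateau magnitude — passes.
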