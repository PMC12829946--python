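# predscan

Analysis pipeline for testing whether visual-cortical firing rates are
modulated by the *spatial predictability* of each neuron's receptive-field
(RF) image patch — the signature of predictive processing during natural
vision — validated end to end on synthetic sessions with known ground
truth.

The pipeline mirrors a large-scale electrophysiology design: head-fixed
animals view full-field natural images (118 scenes, 250 ms per trial, 50
repetitions), RFs are mapped with Gabor probes and fitted as 2-D
Gaussians, and spiking is converted to normalized rate time courses. For
every (unit, image) pair the RF patch is masked out, inpainted from its
surround, and compared against the actual patch in the feature space of a
five-stage convolutional hierarchy:

- **unpredictability** `d_l = || phi_l(actual) - phi_l(predicted) ||_2`
  per level `l`, overall `P = mean(d_1..d_5)` — low levels index edge
  predictability, high levels texture/arrangement predictability;
- a **baseline contrast model** (quadrature Gabor energy with divisive
  normalization `Enorm = E*max(E)/(E + max(E)*S)`) supplies 16 control
  regressors: CE1-5, SC1-5, CEpref, circular variance, CE at +/-30
  degrees from the preferred orientation, RMS contrast, running speed;
- per neuron and 10-ms bin, OLS of fold-change rates
  `y_t = X beta_t + eps` (all predictors z-scored) yields modulation
  functions `beta(t)`; adding `P` to the baseline design gives **Delta-R**,
  the cross-validated increase in prediction correlation;
- inference is two-stage (units averaged within animal, equal-tail
  bootstrap t-tests and CIs across animals, >= 10^4 resamples) with
  threshold-free cluster enhancement (TFCE) for time-resolved contrasts.

A first-class synthetic-data module generates stimuli, sessions, RF
mapping trials and responses from planted temporal kernels (contrast
peaking at 70 ms, unpredictability at 100 ms, laminar scaling for
superficial units), so parameter recovery, error calibration, laminar
detection and the encoding/unpredictability dissociation are all testable
against ground truth. The partial-convolution UNet inpainter, its loss
(valid/hole/TV/perceptual/style) and the feature hierarchy run on a
compact numpy autograd included in the package.

## Worked example

Recover a planted unpredictability effect from a synthetic session
(8 animals x 30 units, 118 images x 5 chunks, planted window coefficient
0.08 in fold change per SD):

```python
from predscan.simulations import parameter_recovery_run

r = parameter_recovery_run(seed=1)
print(f"recovered window coefficient: {r['recovered_mean']:.4f}")
print(f"95% bootstrap CI: ({r['ci'][0]:.4f}, {r['ci'][1]:.4f})")
print(f"latency to 50% peak: unpredictability {r['latency_unpred']:.1f} ms, "
      f"contrast {r['latency_contrast']:.1f} ms")
```

```
recovered window coefficient: 0.0801
95% bootstrap CI: (0.0773, 0.0822)
latency to 50% peak: unpredictability 78.1 ms, contrast 48.2 ms
```

The across-animal mean of the 75-150 ms window-averaged unpredictability
coefficient lands on the planted 0.08, the bootstrap CI covers it, and
the unpredictability modulation rises later than the contrast modulation,
as planted.

The classical end-stopping control — a bar confined to the RF mask,
extending 20% beyond it, or spanning the image — shows unpredictability
falling as the surround provides more context:

```python
import numpy as np
from predscan.inpaint import endstopping_experiment

for name, levels in endstopping_experiment().items():
    print(name, np.round(levels, 3))
```

```
no_context [1. 1. 1. 1. 1.]
some_context [0.921 0.979 0.986 0.983 0.927]
full_context [0.921 0.979 0.986 0.981 0.918]
```

Per level, losses are normalized by the maximum across conditions; the
fully-masked bar is maximally unpredictable at every level, and context
reduces the loss (the two context conditions nearly tie under the
boundary-local harmonic inpainter — see `docs/methods.md`).

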