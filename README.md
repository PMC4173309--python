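# mlhmax — the Müller-Lyer illusion in an HMAX simple/complex-cell hierarchy

`mlhmax` is a research package for computational visual psychophysics. It
asks where, inside a hierarchical model of the ventral visual stream, the
Müller-Lyer illusion arises — and measures how simple-cell (template
matching) and complex-cell (max pooling) operations change illusory *bias*
and *precision* from layer to layer, and how positional variance of the
input modulates the effect. It is aimed at researchers studying visual
illusions with image-computable models, and at anyone who wants a clean,
fully seeded HMAX + psychophysics pipeline on CPU.

The package contains:

* **`mlhmax.stimuli`** — a generator for three families of 256 × 256 binary
  two-line stimuli: cross-fin training images, control (CTL) arrow images,
  and Müller-Lyer (ML) images with 20° or 40° fins, under
  horizontal+vertical (HV) or vertical-only (V) positional jitter, with an
  exact-rasterization renderer and an overlap-exclusion rule.
* **`mlhmax.hmax`** — a four-layer HMAX hierarchy: a 10-scale image pyramid
  (factor 2^(1/4)), S1 Gabor template matching with 50 % lateral
  inhibition, C1 spatial/scale max pooling, an S2 prototype dictionary
  sampled from training C1 responses, and a C2 global-max feature vector.
* **`mlhmax.readout`** — deterministic per-layer feature vectorization and
  an L2-regularized linear long/short classifier.
* **`mlhmax.psychometrics`** — statsmodels-style model/results objects for
  cumulative-Gaussian psychometric fits.
* **`mlhmax.experiments`** — the full seeded procedure: parameterization to
  an accuracy criterion, the layer-wise experiment, and the jitter-variance
  experiment.

## The model in brief

Each trial shows two horizontal shafts; the task is to classify whether the
top shaft is *long*er or *short*er than the bottom one, as a function of
the signed length difference Δ = top − bottom (px). Decisions aggregated
over trials give the proportion classified "long" at each Δ, fitted by
least squares with a cumulative Gaussian

    p(Δ) = Φ((Δ − μ) / σ)

The **PSE** (point of subjective equality) is μ: the Δ at which responses
are at chance; its displacement from 0 measures the illusory bias induced
by the fins (arrow-tails on top push the PSE negative). The **JND** is the
semi-interquartile range 0.6745 σ: lower JND = higher precision. Fits that
do not beat a flat 50 % line in an extra-sum-of-squares F-test (α = 0.05)
are discarded. See `docs/methods.md` for the complete specification.

## Worked example

Fit a psychometric function to simulated decisions and read off PSE/JND:

```python
import numpy as np
from scipy import stats
from mlhmax.psychometrics import CumulativeGaussianModel

deltas = np.array([-60, -50, -40, -30, -20, -10, 10, 20, 30, 40, 50, 60], float)
rng = np.random.default_rng(0)
p_true = stats.norm.cdf((deltas + 14.0) / 12.0)       # biased observer: PSE = -14
obs = rng.binomial(200, p_true) / 200.0               # 200 trials per delta
res = CumulativeGaussianModel(deltas, obs).fit()
print(res.summary())
```

```
Cumulative Gaussian psychometric fit
------------------------------------
points (deltas)          12
PSE (mu) [px]            -13.261
sigma [px]               12.724
JND = 0.6745*sigma [px]  8.582
SSE full / flat          0.00567 / 2.45153
F vs flat 50% line       2155.601 (p = 6.637e-14)
accepted (p < 0.05)      True
```

The fitted PSE of −13.3 px means a top line 13 px *shorter* than the bottom
one is already judged equal — the signature of an expansion bias — and the
JND of 8.6 px is the precision of the judgment. The enormous F confirms the
curve beats chance responding.

Running a desk-scale version of the layer-wise experiment:

```python
from mlhmax.experiments import ExperimentConfig, scale_profile, run_experiment1

cfg = scale_profile(ExperimentConfig(), 0.1)   # 50 train/category, 100 prototypes, 3 runs
res = run_experiment1(cfg, seed=0)
print(res.table()[["layer", "fin_angle", "pse_mean", "jnd_mean", "n_accepted"]])
```

prints one row per (layer, fin angle) with the mean PSE and JND across
accepted runs; at every layer the 20° condition shows the larger bias
magnitude, and the input layer shows the largest JND of all (patterns
asserted, together with stricter per-layer orderings, by the acceptance
suite).

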