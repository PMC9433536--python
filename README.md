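# nirsmoco

Kinematics, fNIRS hemodynamics and phase-locking brain networks for bimanual
circle-drawing coordination experiments.

When subjects trace a guide circle with one or both index fingers, two
questions arise: *how well* do they move, and *what is the brain doing while
they move?* This package implements the full analysis chain that links the
two, for experiments recording finger trajectories (tablet, ~28.5 Hz)
synchronously with multichannel functional near-infrared spectroscopy
(30 channels over prefrontal, motor and occipital cortex, ~11 Hz) in a
block design (12 s movement, 15 s rest, eight unilateral/bilateral
clockwise/counterclockwise conditions). It is aimed at motor-control and
neurorehabilitation researchers who need a tested, scriptable alternative to
ad-hoc MATLAB pipelines.

## What it computes

**Kinematics** — each trial is converted to polar coordinates about the
guide-circle center; four metrics summarize tracing quality (population
form, divisor *n*):

```
SDR  = sqrt( Σ (r_i − r̄)²  / n )     radius variability
RE   = sqrt( Σ (r_i − r_o)² / n )     radius error vs guide radius r_o
SDAV = sqrt( Σ (w_i − w̄)²  / n )     angular-velocity variability
AVE  = sqrt( Σ (w_i − w_o)² / n )     angular-velocity error vs guide w_o
```

**fNIRS preprocessing** — modified Beer-Lambert inversion of
optical-density changes at 740/808/850 nm to ΔHbO/ΔHbR (µmol/L);
moving-std motion-artifact detection with cubic-spline repair; zero-phase
Butterworth band-pass 0.021–0.6 Hz plus band-stop 0.08–0.12 Hz (Mayer waves).

**Activation** — per-channel GLM (HRF-convolved condition boxcars +
intercept + drift, OLS with classical t statistics) and task-minus-rest
activation integrals of ΔHbO.

**Connectivity** — instantaneous phase by complex Morlet CWT (ω₀ = 6) on a
log-spaced grid in the low-frequency band (0.021–0.145 Hz), phase-locking
values `PLV = |n⁻¹ Σ_t exp(i(φ_xt − φ_yt))|` between all channel pairs,
binarized at the largest threshold that keeps the network connected (the
maximum-spanning-tree bottleneck).

**Graph metrics** — global efficiency, clustering coefficient, small-world
σ against degree-preserving rewired nulls; node degree, node efficiency,
node-local efficiency; region-level aggregation.

**Group statistics** — factorial ANOVA (Type-II SS) for
handedness/orientation/phase effects, paired t tests for in-phase vs
anti-phase network metrics, per-channel activation tests with
Benjamini-Hochberg FDR, and Pearson correlations between brain measures and
kinematic performance.

A first-class **synthetic cohort generator** produces trajectories and raw
optical recordings with known ground truth (activation amplitudes,
pairwise LF phase coupling, physiological nuisance, artifacts), which powers
the test suite and lets you calibrate every estimator without real data.
See `docs/methods.md` for the models, defaults, and limitations.

## Worked example

```python
import numpy as np
from nirsmoco import (
    CohortDesign, compute_metrics, connectivity_matrix, cwt_phase,
    threshold_connected, compute_network_metrics, fit_glm,
)
from nirsmoco.glm import build_design
from nirsmoco.preprocess import preprocess_recording
from nirsmoco.synthetic_data import default_effect_spec, gen_cohort

design = CohortDesign(n_subjects=1, n_blocks_per_condition=4, seed=7)
cohort = gen_cohort(design, default_effect_spec(design, amplitude=2.0))
subject = cohort.subjects[0]

trial = subject.trajectories[0]          # left hand, clockwise
m = compute_metrics(trial, trim_s=0.5)
print(f"{trial.condition} {trial.hand}: SDR={m.sdr:.4f}  RE={m.re:.4f}  "
      f"SDAV={m.sdav:.4f}  AVE={m.ave:.4f}  (n={m.n})")

hemo, artifacts = preprocess_recording(subject.recording)
res = fit_glm(hemo, build_design(hemo.events, hemo.t))
c = res.conditions.index("LHCW")
rmc = [k for k, r in enumerate(hemo.channel_regions) if r == "RMC"]
print(f"LHCW mean beta over RMC channels: {res.beta[rmc, c].mean():.3f} uM")

net = threshold_connected(connectivity_matrix(cwt_phase(hemo)))
ms = compute_network_metrics(net.adjacency, channel_regions=hemo.channel_regions,
                             sigma_nulls=100, seed=0)
print(f"LF network: threshold tau*={net.threshold:.3f}, "
      f"E_glob={ms.global_efficiency:.3f}, C={ms.clustering_coefficient:.3f}, "
      f"sigma={ms.small_world_sigma:.2f}")
```

prints

```
LHCW left: SDR=0.0773  RE=0.0778  SDAV=0.0636  AVE=0.0637  (n=312)
LHCW mean beta over RMC channels: 1.526 uM
LF network: threshold tau*=0.247, E_glob=0.482, C=0.434, sigma=1.27
```

Reading it: the trial stays within ~0.08 guide-radius units of the circle
(SDR ≈ RE because there is no systematic bias); the GLM recovers strong
activation in the right motor cortex — the contralateral side for a
left-hand movement, as injected by the generator; and the thresholded
low-frequency PLV network keeps every channel connected at PLV ≥ 0.25 with
mildly small-world topology (σ > 1).

The same chain runs from the shell on a whole cohort:

```
nirsmoco run-all --run-dir runs/demo --seed 7
```

which writes raw and cleaned recordings, per-trial kinematics, activation
tables, PLV matrices and adjacency lists, network metrics, and the
statistics CSVs plus a text summary, with a manifest of hashes for
reproducibility. Individual stages (`simulate`, `preprocess`, `kinematics`,
`activation`, `connectivity`, `metrics`, `stats`) rerun from a run
directory; a YAML config (`--config`) overrides any default parameter and
unknown keys are rejected up front.

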