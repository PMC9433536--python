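# Methods

`nirsmoco` analyses coordinated circle-drawing experiments in which subjects
trace a guide circle with one or both index fingers while cortical
hemodynamics are recorded with multichannel fNIRS. This note documents the
models and procedures the package implements, the choices made where the
design was genuinely open, and the limits of what the synthetic-data tests
demonstrate.

## Task and data model

A cohort performs eight conditions — four unilateral (left/right hand x
clockwise/counterclockwise) and four bilateral (all combinations of the two
hands' rotation directions) — in a block design: 12 s of movement followed by
15 s of rest, repeated over blocks (10 by default), with 21 subjects.
Bilateral conditions in which the hands rotate in opposite screen directions
are mirror-symmetric **in-phase (IP)** movements; same-direction rotations
are **anti-phase (AP)**. Trajectories are sampled at 28.5 Hz, fNIRS at 11 Hz
from 30 channels covering six regions (left/right prefrontal cortex, motor
cortex, occipital lobe; 5 channels per region in the default montage).

## Kinematics

Each trial is converted to polar coordinates about the *known* guide-circle
center (the guide is a task parameter displayed to the subject, so it is not
fitted; a least-squares circle fit is available for exploratory use). The
angle is unwrapped and differentiated by central finite differences
(one-sided at the endpoints) to give a per-sample angular velocity. Four
metrics summarize a trial, all in population form (divisor *n*):

* `SDR = sqrt(mean((r_i - rbar)^2))` — radius variability,
* `RE = sqrt(mean((r_i - r_o)^2))` — radius error against the guide radius,
* `SDAV = sqrt(mean((w_i - wbar)^2))` — angular-velocity variability,
* `AVE = sqrt(mean((w_i - w_o)^2))` — angular-velocity error against the
  signed guide velocity (direction must match; a clockwise trace has
  negative `w`).

These satisfy the exact identity `RE^2 = SDR^2 + (rbar - r_o)^2`, which the
tests assert to 1e-12. A configurable 0.5 s lead/trail trim per trial drops
samples contaminated by task-mode switching; no rule for this exists beyond
"remove the redundant data", so the window is a package choice.

## fNIRS preprocessing

**Optics.** Raw data arrive as optical-density changes at 740/808/850 nm.
The modified Beer-Lambert law `dOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ)`
is inverted per sample by least squares over the three wavelengths
(source-detector distance d = 30 mm, DPF = 6.0 at all wavelengths by
default, both configurable). Extinction coefficients come from the standard
compiled in-vitro hemoglobin tables and are exposed as a configurable
constant; concentrations are reported in µmol/L. With three wavelengths and
two chromophores the forward/inverse round trip is exact to numerical
precision, which the tests verify.

**Motion artifacts.** A sample is flagged when the centered 10-sample moving
standard deviation of ΔHbO strictly exceeds a threshold (default 5.0 in the
data's concentration units — the threshold is a dial, not a physical
constant, because plausible Δ-concentrations live on the µmol/L scale).
Flagged runs are merged, padded by ±0.5 s, and replaced by a cubic spline
fitted through the clean samples; unflagged samples are untouched
bit-for-bit, and repair is idempotent. Segments touching a record boundary
fall back to nearest-clean-value extension.

**Filtering.** A 4th-order Butterworth band-pass (0.021–0.6 Hz) plus a
2nd-order Butterworth band-stop over the Mayer-wave band (0.08–0.12 Hz),
both applied forward-backward (zero phase). The filter family and orders are
package choices (flat passband, no phase distortion of hemodynamics).
Measured on 11 Hz probes: ≥ 20 dB attenuation at 1 Hz (cardiac) and 0.10 Hz
(Mayer), 0.05 Hz passed within 5%. **Known limitation:** ~0.25 Hz
respiratory oscillations lie inside the pass band and are *not* removed by
this filter pair; respiratory nuisance therefore survives preprocessing,
exactly as it would with these published band edges.

## Activation (GLM and integrals)

The design matrix holds one regressor per condition — the task boxcar
convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
undershoot ratio 1/6, peak-normalized) — plus an intercept and a single
linear drift. The same HRF drives the synthetic generator, so amplitude
recovery is an identity check. Estimation is ordinary least squares per
channel with classical t statistics (no prewhitening; at 11 Hz with slow
regressors the practical impact is modest, and calibration is verified
empirically: the null rejection rate at α = 0.05 falls in [0.03, 0.07] over
500 simulations).

Activation intensity is additionally quantified without the GLM: the
trapezoidal integral of ΔHbO over each task window minus the integral over
the duration-matched window immediately preceding the onset (the rest
baseline), averaged over blocks of the same condition. Blocks with under 5 s
of preceding rest are skipped with a warning. Note that the 0.021 Hz
high-pass removes part of the sustained block response, so integrals are
systematically smaller than the naive `duration x amplitude` area (roughly
40% of it under the default design); this is a property of the published
band edges, not of the estimator.

## Phase connectivity

Instantaneous phase is extracted with a complex Morlet continuous wavelet
transform (ω₀ = 6, a standard time/frequency trade-off; configurable) on a
20-point log-spaced frequency grid inside each band: LF 0.021–0.145 Hz (the
band used for network analysis, where myogenic/neurogenic activity lives)
and HF 0.145–0.6 Hz (computed on request). Samples within √2 Gaussian
e-folding widths of either record edge are excluded per frequency (cone of
influence).

The phase-locking value between channels x and y is
`PLV = |mean_t exp(i(φ_xt − φ_yt))|`, computed per grid frequency over the
valid samples and averaged (unweighted by default; amplitude-weighted
behind a flag) to one value per pair. For a condition, the PLV average runs
over the concatenated task samples of that condition, with phases extracted
once from the continuous record so block boundaries introduce no wavelet
edge effects.

**Thresholding.** The complete PLV matrix is binarized at the largest
threshold that keeps the network connected, which equals the bottleneck
(minimum) edge weight of the maximum spanning tree; ties at the threshold
are retained. This is the literal reading of "remove weak connections while
ensuring connectivity"; an exhaustive-sweep oracle confirms the
equivalence on random graphs.

**Temporal resolution caveat.** At LF frequencies the wavelets span 45–700 s,
far longer than one 12 s block. A coupling state that switches per block is
therefore unrecoverable by any phase estimator at these frequencies. The
synthetic generator supports condition-dependent coupling for completeness,
but the end-to-end IP-vs-AP recovery test injects coupling at *session*
granularity (one recording per condition), which is the scale at which the
analysis can resolve it.

A second structural point: under the connectivity-preserving binarization, a
coupling increase confined strictly *within* one region moves that region's
clustering and local efficiency but leaves region node efficiency nearly
untouched, because node efficiency is dominated by paths to the other 25
channels. Region differences in node efficiency require the region's
coupling *to the rest of the network* to change. The IP-vs-AP recovery test
therefore models coupling as a region-varying loading onto a global
low-frequency drive (uniform background coupling 0.3, raised to 1.0 for
RPFC during in-phase sessions), which moves within-region and
region-to-network synchronization together — and both clustering and node
efficiency respond.

## Graph metrics

Networks are binary and undirected (channels = nodes). Implemented directly
on adjacency matrices with dense BFS: global efficiency (mean of 1/d over
ordered pairs), mean clustering coefficient (0 for degree < 2), node degree,
node efficiency, node-local efficiency (global efficiency of the
neighbor-induced subgraph), and the small-world index
`σ = (C/C_rand)/(L/L_rand)` against degree-preserving Maslov-Sneppen
rewired nulls (default 100 per graph, seeded; graphs that admit no rewiring,
e.g. complete graphs, use themselves as null, giving σ = 1 exactly). The
exact identity `global efficiency = mean(node efficiency)` holds on
connected graphs and is asserted in tests. Local metrics aggregate to
regions by unweighted means over member channels. Weighted variants are out
of scope; the thresholded binary graph is the analysis object.

## Group statistics

* Factorial ANOVA with Type-II sums of squares (main-effect-focused designs,
  robust to mild unbalance): two-way handedness x orientation for unilateral
  conditions, three-way handedness x orientation x phase (IP/AP) for
  bilateral ones.
* Paired t tests across subjects for IP-vs-AP comparisons of global and
  region-level network metrics.
* One-sample t per channel on activation integrals, Benjamini-Hochberg FDR
  at q = 0.05 across the 30 channels within each condition.  Note what BH
  does and does not promise: it bounds the expected false-discovery
  *proportion*, not the probability of any false discovery.  With five
  strongly activated channels among thirty, the chance that at least one
  unactivated channel joins the discovery set is about 20% per analysis even
  with perfectly calibrated p-values — so a "significant channels are exactly
  the activated ones" reading is wrong roughly one time in five by
  construction, while "all activated channels found, at most one spurious"
  holds ≥ 95% of the time.  The test suite asserts both forms explicitly.
* Pearson correlations between activation/network measures and kinematic
  metrics, pooled over subject x condition cells. Pooling inflates the
  nominal n because cells within a subject are correlated; a subject-mean
  analysis is a one-line groupby away and the caveat is intentional — the
  pooled form mirrors the common practice of scatter-plotting all cells.

Calibration of the ANOVA and the BH family-level null rejection rate is
verified by simulation (1000 null datasets; rates within [0.035, 0.065]).

## Synthetic generator

Each channel's ΔHbO is a sum of interpretable parts:

* HRF-convolved task boxcars scaled by per-channel, per-condition
  amplitudes. The default effect pattern is contralateral: each hand drives
  the opposite hemisphere's motor cortex; during IP movement the
  non-dominant (right) motor cortex receives half the base amplitude.
* A coupled low-frequency oscillation: every channel's phase is a convex mix
  `φ_k = λ_k·θ_common + (1−λ_k)·θ_k` of a shared and an independent phase
  process (0.05 Hz carrier plus Wiener phase diffusion of 0.3 rad/√s).
  Pairwise coupling targets κ map to loadings λ_k = sqrt(max_j κ_kj), exact
  for rank-one targets; λ = 1 gives PLV = 1 identically and the measured PLV
  is monotone in κ, which is the tested contract.
* Cardiac (1 Hz), respiratory (0.25 Hz) and Mayer (0.1 Hz) sinusoids with
  random phases; white noise (0.1 µM default); Poisson spike artifacts
  (1/min, 15 µM default). ΔHbR is −0.3 x the task component plus noise.

Recordings leave the generator as optical densities through the
Beer-Lambert forward model, so preprocessing performs a genuine inversion.
Subject heterogeneity is Gaussian: multiplicative jitter (10% default) on
scalar effects, plus an optional shared latent z that shifts the radius bias
and scales the activation amplitudes in opposite directions — the mechanism
used to inject a negative activation-kinematics dependence.

What the generator does **not** emulate: photon transport and superficial
(scalp) contamination, serially correlated physiological noise, non-Poisson
artifact clustering, learning/fatigue trends, or hand-specific bilateral
kinematic parameters beyond a left-hand noise scale. Passing tests
demonstrate the estimators' correctness and calibration under this model,
not performance on real recordings.

## Problem sizes and numerical choices

The verification suite scales the study design down to fit a single-CPU
budget while keeping the 21-subject, 8-condition structure: 2 blocks per
condition for the contralateral-confinement Monte-Carlo (50 cohorts), 1
block for the activation-kinematics correlation (200 cohorts), and
10-block single-condition sessions for the IP-vs-AP coupling power test (10
cohorts). Injected effect sizes are fixed at physiologically plausible
levels that survive the band-pass: activation amplitude 2.0 µM, radius bias
0.15 with 0.05 subject SD, activation-bias coupling 0.3, and RPFC coupling
1.0 (IP) vs 0.3 (AP) over a 0.3 background. Small-world nulls use 100
rewires per graph in tests.

Degenerate inputs: empty traces, single-level factors, zero-variance
correlations and disconnected graphs raise `ValueError`; zero-variance
nonzero-mean paired differences report p = 0 with a warning; a constant
ANOVA response reports F = 0, p = 1 for every effect.

Determinism: every stochastic component draws from a
`numpy.random.SeedSequence` tree rooted at a single seed; identical seed and
configuration reproduce byte-identical pipeline CSV outputs (asserted in
tests).
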