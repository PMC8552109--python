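# Methods

## Overview

`sepsiscast` is a proof-of-concept workflow for training artificial
neural networks as surrogates of a stochastic agent-based model (ABM) of
acute systemic inflammation. The pipeline has four stages:

1. **Simulation** (`sepsiscast.abm`): a minimal ABM of the
   endothelial–blood interface generates per-patient time series of 11
   whole-grid cytokine concentrations (the *microstate*) and an
   aggregate oxygen-deficit health metric (the *macrostate*).
2. **Windowing** (`sepsiscast.windows`): trajectories become shuffled
   supervised pairs — five consecutive 11-d profiles as input, the next
   profile (or deficit) as label.
3. **Surrogate training** (`sepsiscast.nn`, `sepsiscast.surrogates`):
   per-cytokine predictor networks, a profile→deficit regressor, and a
   deficit-only Markov forecaster.
4. **Forecasting** (`sepsiscast.forecast`, `sepsiscast.experiments`):
   recursive rollout of the predictors, health regression of the
   predicted profiles, Monte-Carlo-dropout forecast cones, rolling
   re-anchored forecasts, and validation against reseeded simulator
   replicates.

## The simulator

The ABM lives on a toroidal W×H grid (default 101×101). Each cell
carries a damage level in [0, 1] and a binary infection state; eleven
non-negative cytokine fields diffuse over the grid; two mobile agent
populations (pro-inflammatory phagocytes, anti-inflammatory regulators)
walk on it. A patient is defined by five scalar parameters: initial
injury radius, microbial virulence (per-neighbour spread probability),
toxigenesis (per-step damage from infected cells), environmental
toxicity (background damage probability), and host resilience (per-step
healing probability).

The oxygen deficit is the sum of per-cell damage, so its ceiling is
W·H (10 201 by default) and death is declared when it exceeds
`floor(0.8·W·H)` = 8160 — damage beyond 80% of the tissue. Complete
healing (zero damage, zero infection) is the other absorbing state; runs
hitting the step cap are labelled censored. One step represents 6
minutes, so 240 steps ≈ 1 day.

Two structural properties are deliberate and load-bearing:

* **Activity-scaled (heteroscedastic) noise.** Every stochastic event
  (spread, background damage, healing) is an independent per-cell
  Bernoulli draw, so the variance of the one-step deficit change grows
  with the number of active cells — i.e. with total cytokine signal.
  On a toy grid with one infected cell, spread probability *p* and heal
  probability *q*, the one-step infected-count law is exactly
  Bernoulli(1−q) + Binomial(4, p); the test suite checks the simulator
  against this enumeration. To make that law exact, spread and
  spontaneous resolution both act on the snapshot of infection taken at
  step start (newly infected cells cannot resolve in the same step), and
  infected cells resolve spontaneously with the same resilience
  probability that heals damaged cells.
* **A non-unique microstate→macrostate map.** Damage accumulates and
  persists while cytokines decay and diffuse, so near-identical cytokine
  profiles co-occur with very different deficits across patients and
  phases. This bounds the attainable accuracy of any profile→deficit
  regressor.

Randomness comes from one counter-based generator (Philox) per patient;
checkpoints serialize the full state including the generator, so
`restore → step` is bit-identical to stepping through, and branching
replicates reseed only the generator. Cohort parameters are drawn
uniformly from documented ranges chosen once so that a mid-range insult
yields a mixed healed/dead/censored outcome distribution.

## Windowing and standardization

A trajectory of length T yields T−5 windows; windows never cross a
terminal step because recording stops there. The train/validation split
is by patient (default 90/10) to prevent leakage between overlapping
windows; per-channel z-score statistics are computed from the training
portion only and travel with every trained model so the forecasting
layer can invert them exactly. The early-phase exclusion filter drops
all records before a cutoff (240 steps ≈ 1 day at full scale) because
the homogeneous initial insult floods the first day with stochastic
shock. Each window also carries the six aligned deficit values
(steps t…t+5), serving both the regressor (deficit at the last input
step) and the deficit-only forecaster (five past deficits → next).

## Networks

Four families, built on a small numpy backprop engine written for this
package (dense, time-distributed dense, flatten, inverted dropout, and
stacked LSTM layers; Adam; MAE/MSE):

| family | architecture | loss | parameters |
|---|---|---|---|
| `lstm_predictor` (×11) | 3×LSTM(100) → dense 300 → 200 → 1 | MAE | 296 301 |
| `mlp_predictor` (×11) | dense 1000 per step → flatten(5000) → 1000 → 1% dropout → 500 → 500 → 1 | MSE | 5 764 501 |
| `health_regressor` | 11 → 1500 → 1500 → 150 → 1 | MSE | 2 494 801 |
| `deficit_only_mlp` | 5 → 1000 → 1% dropout → 150 → 150 → 1 | MSE | 178 951 |

Choices not fixed by the architecture description: sigmoid/tanh LSTM
gates with forget bias 1; ReLU hidden activations and linear outputs;
He/Glorot initialization; the third LSTM layer emits only its final
state (making the dense input 100-dimensional, consistent with the
296 301 count); the first MLP dense layer is applied per time step
(5×11 → 5×1000 before the length-5000 flatten); the deficit-only input
is flattened to a 5-vector before its first layer. Parameter counts are
pure functions of the layer sizes: dense = n·m+m, LSTM =
4·((d+u)·u+u).

"1% permanent dropout" means rate 0.01 kept active at inference when a
stochastic prediction is requested; dropout masks are drawn
independently per batch row, so a batch of repeated inputs is a
Monte-Carlo ensemble in one forward pass. Deterministic prediction
disables the layer. The printed LSTM stack has no dropout layer; an
optional flag inserts the same 1% layer before its first dense layer so
that family can also produce ensembles (an interpretation, off by
default).

Training uses Adam (step 1e-3 by default) with early stopping: patience
10 epochs on validation loss, minimum improvement 1e-4 of the initial
loss, best weights restored. Loss selection is fixed per family (MAE
for the LSTM predictor, MSE otherwise) and enforced. Training is
deterministic given the initialization, shuffling and dropout seeds and
single-threaded numpy.

## Forecasting

* **Rollout**: each of the 11 predictors advances its channel one step;
  the predicted profile (clipped at zero concentration) is appended to
  the sliding five-point window, which after five steps consists
  entirely of predictions. The default depth is 100 steps. Accuracy is
  scored as MSE averaged over the 11 channels at depths
  1, 2, 3, 4, 5, 10, 25, 50, 100, in standardized units so channels are
  commensurate.
* **Health regression**: predicted profiles map to deficits through the
  regressor, clipped to [0, W·H].
* **Cones**: M independent stochastic rollouts (default M = 100,
  matching the simulator replicate count) pass through the regressor;
  the cone is the pointwise min/max envelope (5th/95th percentiles are
  stored alongside). Dropout masks are redrawn at every rollout step
  from the cone's seeded generator rather than frozen per member; with
  dropout disabled the cone collapses to the deterministic rollout.
* **Rolling forecast**: the cone at step t is always anchored on the
  true observations t−5…t−1 — stale predictions never re-enter the
  window; chained-prediction error is what the horizon score measures.
* **Replicate validation**: the simulator is restarted from a
  checkpointed state with fresh seeds; the envelope over replicates is
  the ground-truth stochastic spread. Replicates are reseeded from the
  true checkpointed state (not from cone-envelope states, which the
  simulator cannot reach exactly).

## Desk-scale study conditions

Full-scale training (tens of thousands of patients × 10 000 steps ×
multi-million-parameter networks) is far beyond a single-CPU test run,
so the figure-level experiments and behavioral acceptance checks run at
a documented desk scale: a 33×33 torus (death threshold 871), 200
training patients, ≤ 600 steps, early-phase cutoff rescaled to 60 steps
(the injury shock settles faster on the small grid), hidden widths
scaled by 0.05 for predictor families and 0.2 for the regressor, fixed
seeds throughout. The full-size grid and full-width architectures
remain the package defaults; the width-scaled variants exist only as
experiment configuration.

At this scale the package asserts the qualitative claims: top-tercile
one-step deficit variance exceeds the bottom tercile; rollout MSE at
depth 100 exceeds depth 1; dropout-off cones have zero width; mean cone
width is non-decreasing in depth.

Three further figure-level claims do **not** reproduce under this
generator at desk scale, and their acceptance tests are left failing
rather than weakened:

* *Horizon-1 envelope coverage ≥ 70%.* The cone's spread at depth 1
  comes only from 1% dropout in the cytokine predictors mapped through
  a deterministic regressor (≈ 6 deficit units here), while the
  regressor's error floor is set by the non-unique microstate→macrostate
  map (≈ 16 units median). Better-trained predictors make the cone
  *narrower* without moving that floor, so a min–max envelope over 100
  members cannot systematically cover the truth one step ahead.
* *Dual-network beats deficit-only on median MSE.* In this simplified
  ABM the aggregate deficit evolves smoothly, so the Markov treatment
  (extrapolating five past deficits) is genuinely strong, while the
  dual route pays the regressor floor plus recursive profile drift.
  With true future profiles the dual route does win over full
  trajectory spans (its error floor is ~10× below the deficit-only
  full-span error), so the claim hinges on long-horizon profile rollout
  fidelity that desk-scale surrogates of a stochastic system do not
  reach.
* *Early-data exclusion is non-inferior at depth 25.* The desk
  simulator's first day is comparatively tame (a deterministic disc and
  a fast cytokine ramp), so discarding it just removes training data;
  the measured effect is a ~10% penalty rather than a benefit.

These are properties of the simplified generator and scale, not of the
pipeline code; the mechanisms are exercised and tested either way.

## What the synthetic generator does and does not emulate

It emulates: heteroscedastic, spatially generated noise; concurrent
pro- and anti-inflammatory signaling; absorbing healed/dead states with
the 80% damage death rule; non-unique profile→deficit mapping; and
checkpoint-and-reseed branching. It does not emulate the original
model's cell-type repertoire (neutrophils, macrophages, T-cell suite),
its mediator list, its recrudescence/immunoparalysis dynamics, or any
quantitative output distribution — so green tests here demonstrate that
the surrogate workflow functions and that the stated structural
properties hold, not that clinical sepsis trajectories are forecastable.

## Numerical notes

Everything is float64. Trajectory CSVs serialize floats with `%.17g`
(round-trip exact); HDF5 stores native doubles. Cytokine standard
deviations of zero are replaced by 1 to keep standardization defined.
Predicted concentrations clip at zero and predicted deficits at
[0, W·H]. Ties in the phagocyte gradient walk resolve by `argmax`
(first maximal neighbour). Degenerate inputs: empty trajectory lists
yield empty window sets; trajectories shorter than six records
contribute no windows; horizon-0 rollouts return empty blocks.
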