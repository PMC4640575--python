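# Methods

## The model

`emtquad` implements a ten-species ODE model of the core regulatory
circuit controlling epithelial–mesenchymal transition (EMT), built
around three mutual-inhibition loops:

* **SNAIL1 / miR-34a** — SNAIL1 represses miR-34a transcription; miR-34a
  silences snail1 translation and destabilises its mRNA.
* **ZEB1 / miR-200** — ZEB1 represses miR-200 transcription; miR-200
  silences zeb1 translation and destabilises its mRNA.
* **Ovol2 / Zeb1** — Ovol2 represses zeb1 transcription; ZEB1 represses
  Ovol2 production.

External TGF-β (a dimensionless signal) plus an endogenous, miR-200–
repressed TGF-β pool drive snail1 transcription; Ovol2 attenuates the
TGF-β input to the snail1 promoter, implementing its negative
regulation of TGF-β signalling. E-cadherin (repressed by SNAIL/ZEB) and
vimentin (activated by SNAIL/ZEB, repressed by Ovol2) are downstream
readout species, mirroring the two flow-cytometry axes used to stage
EMT experimentally. Species: `tgfb_endo, snail_mrna, SNAIL, mir34,
zeb_mrna, ZEB, mir200, OVOL2, ECAD, VIM`; concentrations in μM, time in
hours.

Transcription-factor regulation uses Hill kinetics. miRNA silencing
uses a binding-site occupancy model: an mRNA with `n` equivalent miRNA
sites is distributed over occupancy states with binomial weights
`C(n,i) (μ/μ0)^i / (1+μ/μ0)^n`, and its translation rate and
degradation rate are occupancy-weighted sums with coefficient vectors
`l` (non-increasing) and `γ` (non-decreasing). snail1 carries 2 miR-34a
sites, zeb1 6 miR-200 sites. The silencing strengths `K_SR` (miR-34a on
snail1) and `K_1` (miR-200 on zeb1) scale the effective miRNA
concentration entering the occupancy weights, so scaling a strength to
0.1 % removes that silencing arm — the semantics the loop-knockdown
conditions rely on.

Two structural choices deserve mention:

* the zeb1 basal (constitutive) transcription term sits outside the
  Ovol2/SNAIL Hill gates. It emulates ectopic expression from a
  constitutive promoter: raising it to 0.01 μM/hr is the model's
  Zeb1-overexpression protocol and must not be silenced by Ovol2. The
  snail1 basal term, by contrast, is gated by Ovol2 — the
  overexpression protocols only ever touch zeb1 and Ovol2.
* Ovol2 production keeps a small ZEB-independent leak fraction
  (`leak_O = 0.15`). Without it, complete repression by high ZEB would
  decouple the M state from the Ovol2 production knob entirely, and
  raising Ovol2 production could never reprogram M-state cells — the
  leak is what lets an increased supply re-engage the Ovol2–Zeb1
  switch.

Ovol2 is a single protein species (no separate mRNA): every
perturbation of interest acts through its basal production rate.

## The reconstructed basal parameter set

The packaged default parameters (`emtquad/params_data/
default_params.json`) are a *reconstruction*: they were obtained by the
documented calibration procedure in `emtquad.calibrate`, which searches
the Ovol2-edge and zeb/miR-200 couplings on top of the two-miRNA-switch
core until a candidate satisfies every structural constraint of the
four-state circuit:

1. exactly four stable states (E, I1, I2, M) over an external-TGF-β
   window at least 0.5 signal units wide (the window of the default set
   spans ≈ [0, 1.5], containing the working point 0.5);
2. monostable M at TGF-β = 10; bistable {I2, M} at TGF-β = 2.5;
3. monostable E when Ovol2 basal production is raised to 2 μM/hr;
4. deterministic reprogramming: raising Ovol2 production to 2 μM/hr
   sends both I1- and M-state cells to E; raising zeb1 basal
   transcription to 0.01 μM/hr sends I1-state cells to M.

`calibrate` evaluates candidates with the steady-state machinery and
accepts the first fully passing set; budget exhaustion returns the
best-found candidate together with an explicit failing report. Outputs
derived from the packaged set are labelled "reconstructed" in run logs.

The four phenotypes of the default set at TGF-β = 0.5:

| state | SNAIL | ZEB  | OVOL2 | miR-200 | Ecad | Vim  |
|-------|-------|------|-------|---------|------|------|
| E     | 0.12  | 0.07 | 1.96  | 0.41    | 2.00 | 0.02 |
| I1    | 3.60  | 0.09 | 1.79  | 0.33    | 0.48 | 0.42 |
| I2    | 4.04  | 0.75 | 0.30  | 0.31    | 0.36 | 1.73 |
| M     | 4.80  | 4.68 | 0.30  | 0.011   | 0.06 | 1.84 |

I1 and I2 differ chiefly in the state of the Ovol2–Zeb1 switch (Ovol2
high / ZEB pinned low versus Ovol2 collapsed / ZEB at the
miR-200-limited plateau), which is exactly the mechanism by which the
added loop splits the classical single intermediate into two.

## Steady states and phenotype labels

Roots are found by multistart damped Newton iteration (batched over
starts), seeded log-uniformly over [1e-4, 10] μM plus endpoints of long
relaxation integrations; duplicates merge below 5e-3 decades;
stability uses eigenvalues of a central-finite-difference Jacobian
(per-species step `max(|x|, 1e-6)·1e-6`, stability margin 1e-8 /hr).

Labels: when exactly four stable states coexist they are named E, I1,
I2, M by descending E-cadherin. Otherwise states are matched to the
basal archetypes by nearest-neighbour distance in (log10 Ecad, log10
Vim) — the operational space of the flow-cytometry figures — with a
one-to-one assignment so no label repeats, and a 0.6-decade
classification radius beyond which a state is `unclassified`. The
radius covers the drift of each basal branch across its full stability
region while excluding the hybrid states produced by strong loop
ablation, which is what makes "disappearance" of a phenotype region a
well-defined outcome.

## Bifurcation analysis

One-parameter diagrams use pseudo-arclength continuation (secant
predictor, Newton corrector on the bordered system) with saddle-node
detection by sign change of the tangent's parameter component, refined
by bisection; step collapse truncates the branch with a diagnostic. An
independent dense grid scan (`sweep_states`) provides the fold-location
oracle: the two routes agree within 1 % of the sweep range in the test
suite.

Two-parameter maps are grid-based (default 64×64 over TGF-β ∈ [0, 10] ×
Ovol2 basal ∈ (0, 4× basal]): each cell is solved by a row-batched
Newton pass from archetype starts, followed by global sweeps in which
every cell re-solves from its neighbours' roots (with a mid-iteration
relaxation rescue for stiff stragglers), so branches propagate across
the grid. Cells with no converged root are reported as failed, never
interpolated. Fold curves are the region boundaries. Loop-knockdown
scans compare I1/I2 region areas (grid-cell counts) against the basal
map with declared verdict thresholds: disappearance = 0 cells,
decrease/increase = at least a 20 % area change (boundary inclusive),
and a merge heuristic (cells that basally carried both intermediates
now carry exactly one, with the union area at least half preserved).

## Stochastic simulation

Euler–Maruyama with multiplicative noise `dX = f(X) dt + σ X ∘ dW`,
dt = 0.01 hr, applied to the mRNA and protein species but not the
miRNAs (configurable). Non-negativity is enforced by reflection at
zero. A single counter-based Philox stream keyed by the protocol seed
drives the whole ensemble, making snapshots bit-reproducible for a
given (seed, n_cells, dt). Parameter-change events at specified times
express the perturbation protocols (a t = 0 event emulates constitutive
overexpression while the initial state is still resolved under
unperturbed parameters).

After the noise-off time the ensemble relaxes deterministically,
extended in blocks until `max|f| < 1e-6` μM/hr (up to a bounded
extension); each converged cell is assigned the basin of the nearest
stable steady state in log-state space, and unconverged cells are
labelled and counted rather than dropped.

Noise amplitudes are not observable from the published material; the
defaults were fixed by the calibration criteria for the propensity
protocols: σ_small = 0.02 keeps ≥ 95 % of an I1 population in place
over 250 h, σ_large = 0.30 produces the heterogeneous E + M outcome
from I1. The same σ_small yields the characteristic I2/M mixture at
TGF-β = 2.5.

## Quasi-potential landscapes

`U = −ln ρ` of the pooled, post-burn-in (20 %) occupancy density of one
coordinate (default E-cadherin, log-binned, 60 bins) over a noisy
ensemble with noise kept on for the whole horizon. Minima are reported
with a 0.5-nat topographic-prominence filter to suppress counting
noise; empty bins are NaN, never zero. These landscapes are projection
diagnostics: only minima locations (which co-locate with stable states
within bin width) and barrier orderings are treated as meaningful, not
absolute barrier heights.

## Synthetic flow-cytometry stage

`to_flow_readout` maps per-cell Ecad/Vim concentrations to
fluorescence-like signals `gain · c · LogNormal(0, cv)` independently
per event and channel — log-normal multiplicative measurement noise
with per-channel coefficient of variation, no autofluorescence floor by
default, no spillover or compensation modelling.
`generate_reference_archetypes` samples E-, I1- and M-like event clouds
around the corresponding steady states at zero TGF-β; the I1 centroid
falls between E and M in (log Ecad, log Vim), reproducing the geometry
of untreated epithelial, intermediate and mesenchymal populations. What
passing these tests shows is that the classification stage is
informative under realistic measurement noise (nearest-centroid
recovery ≥ 95 % at cv = 0.2); it does not make the generator a model of
any real cytometer (no debris, doublets, spectral overlap or
autofluorescence).

## Problem sizes and numerical defaults

Test-suite and acceptance-script runs use scaled-down study sizes
chosen as the package's own defaults: ensembles of 200–400 cells
(binomial error ≤ 2.5 % on reported fractions) against the study-scale
2000–5000, region scans at 48–64 grid cells per axis, and simulation
horizons of 200–300 h with a 150–250 h noise window. All stochastic
results are seeded and reproducible; `--seed` on the acceptance script
propagates to every source of randomness.

## Known limitations

* The basal parameter set is a calibrated reconstruction, not a
  transcription of the original kinetic constants; quantitative fold
  positions and region areas are therefore specific to this set, and a
  subset of the printed loop-ablation verdicts (those hinging on which
  intermediate the miR-34a arm stabilises, and on the sign of the
  miR-200/ZEB-arm sensitivity) does not reproduce. The structural
  claims — four states, their ordering, the reprogramming directions,
  the dose ladder, the propensity shifts — are all reproduced and
  tested.
* No spatial or tissue-level coupling, no epigenetic slow variables, no
  cell division; limit cycles are not searched for (none are expected
  in this fixed-point multistability regime).
* The SDE scheme is first-order Euler–Maruyama with reflection;
  near-zero species therefore carry an O(√dt) boundary bias that the
  small default step keeps negligible relative to basin-assignment
  scales.
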