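# Methods

## The model

`tumorpulse` simulates a population of cancer cells treated with periodic
pulses of the cytokine TNF, coupling four submodels across scales.

**Microenvironment.** TNF lives on a uniform voxel grid (2-D for monolayer
discs, 3-D for spheroids; cubic voxels, default 20 μm) and obeys a
diffusion–decay equation solved by operator splitting: one backward-Euler
tridiagonal solve per axis (reflecting, i.e. no-flux, ends) followed by
backward-Euler decay `c ← c/(1 + λ·dt)`. The implicit scheme is
unconditionally stable and preserves non-negativity, which lets the
whole-simulation tests run with a 1-min transport step while the default
remains 0.1 min. During a pulse all boundary voxels are clamped to the pulse
concentration (Dirichlet); outside a pulse the boundary reverts to no-flux.
A `supply: uniform` switch instead bathes the whole domain, used to emulate
well-mixed sustained exposure. Defaults D = 1,200 μm²/min and
λ = 0.0275 /min are cytokine-scale transport choices of this package (decay
length ≈ 210 μm), not measured values. Every mass movement in or out of the
field (boundary supply, decay, cellular uptake) is booked on a ledger, and
`supplied − decayed − consumed − remaining = 0` is enforced in tests to 1e−6
relative.

**Receptor kinetics.** Each cell carries a three-pool TNF-receptor model —
free surface receptor `Re`, surface complex `Re*`, internalized complex
`Ri*` — with mass-action binding (k_bind), endocytosis (k_endo, where the
ligand is degraded) and receptor recycling (k_recycle). The right-hand sides
sum to zero, so `Re + Re* + Ri* = R_total` exactly; the integrator (classic
RK4, substeps ≤ 0.1 min, local TNF held constant over the 6-min intracellular
window) preserves this to 1e−9 over 10⁵ random steps. The closed-form fixed
point

    Re*_ss = R_total / ( k_endo/(k_bind·[TNF]) + 1 + k_endo/k_recycle )

serves as the analytic oracle. The signal handed to the fate network is a
threshold transfer function: the Boolean TNF input is ON iff
`Re* ≥ 0.5·R_total` (ties count as active). Internalized-and-degraded ligand
(`k_endo·∫Re*dt`) is withdrawn from the cell's voxel via a receptors-per-cell
scale (default 200 ng·μm³/L per receptor unit, < 5% of a voxel's content per
window at defaults); uptake can be disabled.

Default rates — k_bind = 2.0 /((ng/L)·min), k_endo = 0.05 /min,
k_recycle = 0.2 /min, R_total = 1 — are a package calibration with a specific
design goal: concentrations in roughly the lower half of the treatment search
box (≳ 0.05 ng/L) must drive `Re*` over the 0.5 threshold within a few
minutes to ~15 min, and the signal must relax back below threshold within
~10 min of washout (rate governed by k_endo). Note that the saturation level
is `R_total/(1 + k_endo/k_recycle)`; any parameterization with
k_endo/k_recycle ≥ 1 makes a 0.5·R_total threshold unreachable at every
concentration, so the recycling rate must exceed the endocytosis rate for the
transfer function to fire at all.

**Fate network.** Cell fate is governed by a Boolean network under
continuous-time stochastic semantics: a node whose logic value disagrees with
its current value flips after an exponential waiting time at its up/down
rate; the next flip is chosen by the Gillespie direct method (asynchronous
updates). Input nodes are clamped by the simulator. The engine loads
arbitrary network files (`name : logic : rate_up : rate_down` plus `input`
and `readout` declarations); a 6-node surrogate is shipped:

* TNF (clamped input);
* NFkB — activated by TNF (up 0.005 /min), decays when TNF is absent
  (down 0.02 /min), blocked by death commitment;
* Apoptosis, NonACD — the two mutually exclusive death commitments, each
  triggered at 0.02 /min by TNF when neither NFkB nor Survival protects;
  self-locking (down 0);
* Survival — locks (up 0.001 /min, down 0) while NFkB and TNF are
  simultaneously active: the resistant state;
* Proliferation — fast-tracking readout (up/down 0.1 /min), active when the
  cell is uncommitted and either Survival is on or TNF is absent.

This produces the intended pharmacodynamics as analytic properties of the
race between death (total hazard 0.04 /min) and NFkB (0.005 /min): a single
30-min exposure commits ≈ 66% of cells to death and Survival-locks ≈ 0.2%;
sustained exposure kills ≈ 89% and locks the remaining ≈ 11%, which then
regrow as a resistant clone. Short, well-separated pulses therefore eradicate
(NFkB resets in the gaps at 0.02 /min), while long-duty-cycle or continuous
supply breeds resistance. The test suite freezes these numbers as regression
bounds computed from the analytic Markov chain and calibration oracle runs of
the shipped fixture; they are properties of the surrogate, not literature
values. Rate choices matter: raising the Survival up-rate by an order of
magnitude makes the expected number of locked cells per 151-cell replicate
exceed one under every schedule in the search box, abolishing effective
treatments altogether.

**Cell agents.** Cells divide with probability `1 − exp(−b·dt)` per window
when their Proliferation readout is on, b = ln2/1320 min⁻¹ (22-h doubling);
daughters are placed one cell radius away in a uniform random direction
(in-plane in 2-D), inherit the parent's kinetic parameters, and start with a
naive network state and a full free-receptor pool. Death is a fixed-duration
countdown (apoptosis 516 min, necrosis 1,440 min — stand-ins for the
conventional agent-based defaults, configurable); dying cells leave the alive
count immediately, keep exerting contact forces, and are removed at expiry.
Mechanics is overdamped pairwise repulsion, force ∝ (1 − d/(rᵢ+rⱼ))² for
overlapping pairs, with uniform-grid neighbour search. Volume dynamics of
dying cells and adhesion/motility are deliberately omitted — they feed back
into no reported quantity here.

Initial geometries are packed lattices with frozen spacing calibrated once
against the published initial counts: the 2-D disc uses a hexagonal lattice
with nearest-neighbour spacing 0.95 × cell diameter (151 cells at r = 100 μm,
37 at 50 μm, 1,069 at 275 μm, 3,559 at 500 μm; cell volume 2,494 μm³), and
the 3-D spheroid uses the layered lattice of PhysiCell's spheroid examples —
x/z spacing r√3, y spacing 2r with parity offsets, factor 1.0 — giving 1,173
cells at r = 100 μm. A single spacing factor cannot reproduce both the 2-D
and 3-D counts (they imply packing densities on opposite sides of contact
spacing), which is why the defaults are per-geometry.

**Orchestration.** The loop advances 6-min intracellular windows: transport
substeps with pulsed supply → receptor RK4 at the beginning-of-window local
TNF + uptake → transfer function clamps the network input → one CTMC window
per alive cell → phenotype update (fate → divide/die/idle) → cycle and death
clocks → mechanics substeps. Everything is deterministic given (config,
seed): each cell owns counter-based RNG streams (splitmix64 over a key
derived from seed, cell id and a purpose tag), so the draws of one cell never
depend on how many other cells exist; replicates differ only by seed.
Treatments are scored by the replicate-averaged final alive count (default 3
replicates) and called *effective* when the final count is below 1% of the
initial count in every replicate.

## Exploration workflow

The search point is (pulse period, pulse duration, TNF concentration) in the
box 5–800 min × 5–200 min × 0.001–1 ng/L. The sweep evaluates uniform or
grid candidates; the GA is generational (pop 24, tournament 3, BLX-0.5
crossover, per-gene Gaussian mutation with σ = 10% of range at probability
0.3, one elite); CMA-ES follows the standard formulation (rank-one + rank-μ
covariance updates, cumulative step-size adaptation, λ = 12, σ₀ = 0.3) in
box-normalized coordinates with clipping repair plus a quadratic out-of-box
penalty, restarting with inflated σ on a degenerate covariance, and reports
its final sampling distribution (mean, C, σ). Noisy fitness is handled by
common random numbers — the same replicate seeds for every candidate — rather
than re-evaluation, so optimizer runs are reproducible and sweeps are
embarrassingly parallel with identical serial/parallel results. Optimizer
correctness is checked against benchmark oracles (sphere, Rosenbrock, and a
deterministic synthetic treatment surface with a known minimizer); the sphere
benchmark uses benchmark-appropriate settings (λ = 6, σ₀ = 0.05), since the
treatment-tuned λ = 12/σ₀ = 0.3 spends ~40% more evaluations on that
function.

Post-hoc analyses: per-parameter summary statistics and Spearman correlations
of the effective set; ranking of effective treatments by total supplied dose
`TNF_total = duration × concentration × floor(horizon/period)` (the final
partial pulse is excluded — the printed formula is ambiguous there and floor
is the conservative reading); and a robustness analysis that re-scores top
treatments under per-cell heterogeneity.

**Heterogeneity.** Population variability draws each cell's k_bind, k_endo
and k_recycle from Normal(mean, σ·mean) truncated below at 1% of the mean by
resampling; σ ∈ [0, 1] with σ = 0 the homogeneous population. The standard
deviation is *relative* — an absolute σ across rates spanning two orders of
magnitude would be meaningless — and resampling (not clipping) avoids a point
mass at the floor. Heterogeneity creates parametric resistance: a cell whose
sampled rates keep steady-state `Re*` below threshold at the pulse
concentration never receives the death signal and regrows the tumor after
the sensitive cells die. At the default calibration the per-cell
insensitivity probability is negligible for σ ≲ 0.15 and of order 1/150 near
σ ≈ 0.25, so a 151-cell disc transitions from robust to failing around
σ ≈ 0.25 — the behaviour the robustness tests assert as a monotonicity
property (median final %alive non-decreasing in σ).

## Problem sizes and numerical choices in the shipped tests

Whole-simulation tests and the mechanism suite run with dt_diffusion = 1 min
and dt_mechanics = 5 min (defaults 0.1/0.5 min); a convergence-guard test
checks that halving the numerical steps moves the final alive count by < 5%.
The intracellular window (6 min) is part of the stochastic model definition —
it fixes the input-clamping interval and the draw sequence — so the guard
holds it fixed and verifies separately that halving it preserves eradication
under an effective schedule. The mechanism properties use one n = 100 uniform
sweep per geometry (2-D disc and 3-D spheroid, both r = 100 μm, 3 replicates,
common candidates and seeds) rather than the 10,000-candidate sweeps a
cluster would run; with the shipped calibration the 2-D effective fraction is
a few percent and the 3-D fraction lower (shorter pulses under-dose the
spheroid core, where arrival is delayed by the ~30-min boundary-to-centre
diffusion time and attenuated by uptake), so the 2-D-vs-3-D ordering is
resolved at this n.

## What the simulated data do and do not show

All experiments are generated by the simulator itself; there is no external
data. The synthetic populations capture the mechanisms of interest —
receptor-gated death/survival races, spatial drug penetration, phenotypic
(state-locked) versus parametric (insensitive-kinetics) resistance — but the
fate network is a reduced surrogate, its rates are calibrations, and receptor
kinetics, TNF transport constants and death durations are order-of-magnitude
choices. Passing tests therefore demonstrate internal consistency and the
qualitative treatment phenomenology, not quantitative predictions for any
cell line. Quantities tied to the unpublished full fate network (effective
counts out of 10,000, exact effective-set summary tables, exact critical
variability values) are reproduced as orderings and mechanism properties, not
as numbers.

## Known limitations

* One diffusible species is active by default; the oxygen field exists but is
  non-limiting and off.
* No cell adhesion, motility, or volume change during death; mechanics is
  pure repulsion.
* Fates in the surrogate network are first-order races; real commitment
  cascades have non-exponential waiting times, which changes how sharply
  pulse-duration thresholds act.
* The CTMC window length (6 min) quantizes the transfer-function signal;
  pulses shorter than a window can be missed at low concentrations.
* `alive` for scoring excludes committed-but-present dying cells (switchable
  via `alive_includes_dying`).
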