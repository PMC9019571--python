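# tumorpulse

Multi-scale simulation of pulsed-TNF tumor treatment, and optimization of the
treatment schedule.

Finding a drug schedule that kills a tumor without breeding resistance is a
search problem over dose timing. `tumorpulse` addresses it in silico for the
classic TNF paradigm: brief exposure to the cytokine commits cells to
apoptosis or necrosis, but prolonged exposure activates NFkB and locks a
Survival state that makes cells permanently insensitive. The package is aimed
at computational/systems biologists who want a scriptable, deterministic,
desk-scale version of the agent-based tumor–cytokine models usually run on
clusters, together with the model-exploration machinery (sweep, genetic
algorithm, CMA-ES) used to search treatment spaces.

## The model

Each in-silico experiment couples four submodels:

* **Microenvironment** — TNF concentration *c* on a 2-D/3-D voxel grid,
  ∂c/∂t = D∇²c − λc, solved by dimension-split implicit (backward-Euler)
  diffusion plus backward-Euler decay; pulses enter as a Dirichlet boundary
  condition while active.
* **Receptor kinetics** — per cell, three pools (free receptor Re, surface
  complex Re\*, internalized complex Ri\*):

      dRe/dt  = −k_bind·Re·[TNF] + k_recycle·Ri*
      dRe*/dt =  k_bind·Re·[TNF] − k_endo·Re*
      dRi*/dt =  k_endo·Re*      − k_recycle·Ri*

  integrated by RK4 at the local TNF value; Re+Re\*+Ri\* is conserved.
* **Fate network** — a continuous-time stochastic Boolean network (Gillespie
  direct method over asynchronous node flips with per-node up/down rates).
  Its TNF input is ON iff Re\* ≥ 0.5·R_total; its readouts (Proliferation,
  Apoptosis, NonACD) drive the agent's phenotype. A 6-node surrogate
  cell-fate network ships with the package; arbitrary network files load.
* **Cell agents** — hexagonally packed discs (151 cells at r = 100 μm) or
  spheroids (1,173 cells), 22-h-doubling live cycle, fixed-duration
  apoptosis/necrosis, overdamped repulsion mechanics.

A treatment is the 3-vector (pulse period, pulse duration, TNF
concentration) in the box 5–800 min × 5–200 min × 0.001–1 ng/L. Its score is
the replicate-averaged final alive count after 4,640 min; it is *effective*
when every replicate ends below 1% of the initial population. Heterogeneous
populations sample each cell's receptor rates from a relative-sd truncated
normal (σ ∈ [0, 1]).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate the 151-cell monolayer disc under a pulsed schedule found effective
by a sweep (period 365.5 min, duration 37.3 min, 0.213 ng/L):

```
$ tumorpulse simulate --period 365.5 --duration 37.3 --tnf 0.213 --seed 1 --out out/
final alive: 2 / 151 (total TNF 95.3 ng*min/L)
```

The tumor is reduced to 2/151 cells (1.3%) using a total supplied dose of
95.3 ng·min/L. Compare a high-duty-cycle schedule with the *same*
concentration but 200-min pulses every 800 min:

```
$ tumorpulse simulate --period 800 --duration 200 --tnf 0.213 --seed 1 --out out2/
final alive: 5 / 151 (total TNF 213 ng*min/L)
```

More than twice the dose, a worse outcome — the long pulses let NFkB activate
and Survival-lock part of the population (the resistant cells are visible in
`out2/snapshot_final.csv` as alive cells with the Survival node ON).
`out/timecourse.csv` holds the alive/apoptotic/necrotic counts and the
population-averaged receptor state every 10 min; `out/summary.json` the
finals and the TNF mass ledger.

The same machinery drives searches (the library API exposes `sweep`,
`ga_optimize`, `cmaes_optimize`, `characterize_effective`,
`rank_by_total_tnf`, `robustness_analysis`):

```
$ tumorpulse sweep --n 100 --seed 0 --out sweep/     # uniform sweep, 3 replicates each
$ tumorpulse optimize --algo cmaes --out opt/        # CMA-ES over the box
$ tumorpulse robustness --records sweep/records.csv --sigmas 0,0.25,0.5 --out rob/
```

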