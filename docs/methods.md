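# Methods

## The model

`pdl1net` simulates deterministic reaction-network kinetics for a
neuroblastoma signaling cascade whose downstream readout is PD-L1 (CD274)
mRNA. A network is a set of compartments, species and reactions; each
reaction carries one of three rate laws:

* **Mass action**: `v = k1·∏[S] − k2·∏[P]` (k2 optional; irreversible when
  absent). Used for degradation and simple interconversions. An empty
  substrate list denotes constitutive synthesis (`v = k1`).
* **Henri–Michaelis–Menten (HMM)**: `v = Kcat·[E]·[S]/(Km+[S])`, with
  `[E] ≡ 1` when no enzyme species is referenced (then `Kcat` is `Vmax`).
  Used for transcription and translation events.
* **Modified HMM**: `v = Kcat·[M]·[S]/(Km+[S])`, linear in the modifier
  concentration `[M]`. This is the drug-inactivation form: the inhibitor is
  the modifier of a reaction converting its target to an inactive species.
  Only the activator form is implemented; repression is expressed
  topologically (the "activated" product is an inhibited state).

Each species obeys `d[X]/dt = Σ ±ν·v` over the reactions that touch it.
Compartment volumes are constant, so the volume factor in
`d([X]·V)/dt = ±V·v` cancels and the engine integrates concentrations
directly; simulations are provably invariant to volume (tested). Units are
nominal — mmol/mL for concentrations, seconds for time — and are labels
only; the engine never converts units.

Imported models may carry **opaque** rate laws: an arbitrary symbolic
expression over species ids, compiled with sympy and evaluated alongside
the structured laws. This preserves fidelity for SBML documents whose
kinetics do not match the three structured forms.

## Numerical choices

* **Integrator**: LSODA via `scipy.integrate.odeint` — genuine
  stiff/non-stiff switching, and it exposes the maximum-internal-steps cap
  (`mxstep`) that the settings vocabulary requires. Output times are the
  requested grid; LSODA produces exact-time values internally rather than
  nearest-step snapping.
* **State clamping**: rates are evaluated at `max(y, 0)` so integrator
  undershoot below zero cannot destabilize Michaelis–Menten denominators.
  Reported trajectories are clipped at zero; the pre-clip minimum is kept
  in the diagnostics and a warning fires if it falls below −10·atol.
* **Settings**: `relative_tolerance` (default 1e-6) and
  `absolute_tolerance` (default 1e-12) pass straight to the solver.
  `n_intervals` is derived as `round(duration/interval_size)` whenever an
  interval size is given; a stated count that disagrees by ≥1% is treated
  as a typo (warned, overridden). `max_internal_steps` defaults to 1e5;
  requesting ≤10 warns, because such runs almost always truncate.
  `integrate_reduced_model` is accepted for config fidelity with
  COPASI-style blocks and is a no-op: the full state is always integrated.
* **Plateau detection** (`find_plateau`): the earliest sampled time after
  which every finite-difference slope magnitude stays ≤ `rel_slope_threshold`
  (default 1%) of the trajectory's maximum slope magnitude; `None` when the
  curve never settles (sustained linear growth). A constant trajectory
  plateaus at t=0.
* **Steady state**: integration to a long horizon followed by a damped
  Gauss–Newton polish (`least_squares` with non-negative bounds) of the
  endpoint. A free Newton search from the initial state is deliberately
  avoided as the primary method: conservation relations make the root set a
  continuum, and an unconstrained search can return a steady state the
  dynamics never reach. Sink species are excluded from the residual — they
  are pure accumulators whose inflow never vanishes. Failure to settle is a
  first-class result, not an exception; complex networks may genuinely not
  reach steady state within any practical horizon.
* **Sensitivities**: central finite differences on the readout endpoint,
  `s = (c(p(1+δ)) − c(p(1−δ)))/(2δp)` with default δ = 1%, optionally
  scaled by `p/c` (elasticity). Central FD was chosen over forward ODE
  sensitivities for solver independence; a δ-halving convergence test
  (<5% movement) guards accuracy. Parameters with baseline zero are
  skipped (a relative perturbation is undefined); a failed perturbed
  simulation flags the entry rather than reporting zero. Readout can be
  endpoint or AUC.
* **Fitting**: bounded nonlinear least squares
  (`scipy.optimize.least_squares`, trust-region reflective, numeric
  Jacobian), minimizing `Σ w·(sim−obs)²`. A candidate whose simulation
  fails contributes a large constant residual instead of crashing; the
  returned estimate is never worse than the initial guess; optional seeded
  multistart handles multimodal losses. "Linear-regression" style
  estimation cannot produce Michaelis constants — the laws are nonlinear in
  Km — hence the nonlinear solver.
* **Quantile normalization**: each column's sorted values are replaced by
  the row-means of the sorted columns; ties receive the average of the
  quantile values they span. Idempotent and rank-preserving; cross-checked
  against limma's `normalizeQuantiles` in the test suite.
* **Fold change**: mean linear-scale control over mean linear-scale
  treated (log2 matrices are de-logged first), so a value of 4.33 means
  treatment lowered expression 4.33-fold. Arithmetic group means by
  default (geometric available). Multiple probes for one gene are averaged
  after normalization.

## Scenario surgery

All interventions are pure transformations (deep copy in, fresh model out;
verified by hashing):

* **ALK-F1174L**: adds a constitutively active `ALK_Mutated` species at
  nonzero initial concentration (default: the wild-type inactive ALK pool)
  and duplicates every reaction driven by active ALK so the mutant drives
  it identically. The mutant has no deactivation reaction — its activity is
  constitutive, and it is only consumed if an inhibitor targets it.
  Idempotent.
* **Crizotinib**: one drug species at the dose (default 1.4×10⁻³ mM) plus
  two reactions — modified-HMM inactivation of `ALK_Mutated` (drug as
  modifier) and first-order drug decay.
* **Gefitinib**: drug species at the dose (default 3×10⁻³ mM), an
  `EGFR_inhibited` species if absent, a modified-HMM
  `EGFR_free → EGFR_inhibited` reaction, and first-order drug decay.

Drug kinetic constants are configuration with defaults `Kcat=500`,
`Km=0.5`, `k_deg=1e-3`, sized so the standard doses act on an O(1 mmol/mL)
target pool within the reference time course. Drugs enter as initial
concentrations (no dosing schedules); ligand stimulation likewise.

## The synthetic reference cascade

The generator builds layered receptor → kinase → transcription networks:
EGF→EGFR and NGF→ALK branches, `n_layers` of kinase activation/deactivation
pairs per branch, and terminal transcription of the PD-L1 mRNA readout
driven by the last active kinase, plus ligand and mRNA turnover. Every
rate constant is drawn from documented ranges with a fixed seed and
returned as a ground-truth record, so recovery tests are exact.

Defaults are chosen once to put the network in the regime the biology
implies, and are frozen:

* activation `Kcat` ∈ [0.1, 0.3] against deactivation `k` ∈ [0.5, 1.0]
  keeps active kinase fractions small and approximately linear in their
  drive, so a constitutively active mutant propagates to the readout
  instead of saturating mid-cascade;
* ligand decay 0.1 s⁻¹ makes wild-type signaling transient — the readout
  plateaus mid-run — while the constitutive mutant keeps producing,
  yielding near-linear growth (plateau never detected);
* the EGFR branch's transcription drive is scaled by 1e-3, making the
  readout ALK-dominated: EGFR inhibition then moves PD-L1 by ≪1%, the
  regime in which an EGFR inhibitor is clinically silent for this readout.

Under these conditions the reference cascade (seed 2019, 21 species,
21 reactions, 100 s horizon) gives: mutant/wild-type endpoint ≈ 150×,
ALK-inhibitor AUC ≈ 4% of control, EGFR-inhibitor AUC within 0.01% of
control, combination within 0.02% of the ALK inhibitor alone.

Noise models: kinetic observations get multiplicative Gaussian noise on
the relative scale (`value = truth·(1+ε)`); expression matrices get
additive Gaussian noise on the log2 scale with per-probe baselines from
N(8, 1.5) over the 2D/3D × DMSO/crizotinib/alectinib design.

### What the generator does and does not emulate

It reproduces the *shape* of the curated signaling network (layered
branches converging on PD-L1 transcription, inactive/active pairs starting
with active forms at zero) and the validation design, with known truth.
It does not reproduce the curated network's 93-species topology, its
fitted constants, cross-talk between branches, feedback loops, or real
microarray artifacts (probe effects, batch structure, heavy-tailed noise).
Passing tests therefore demonstrate correctness of the machinery and the
qualitative pharmacology under controlled conditions — not quantitative
agreement with any particular curated parameterization, which requires
loading the deposited SBML model through `read_sbml`.

## Problem sizes

Test and acceptance runs use the reference cascade (21 species, 201 time
points, 100 s), a two-layer single-branch cascade for recovery studies
(20 seeded replicates, 2 free parameters, 5% noise), a 200-probe × 18-sample
expression matrix, and 10⁴-step RK4 cross-checks — sizes at which the whole
pipeline, including the Monte-Carlo studies, completes in seconds while
leaving every statistical claim testable.

## Known limitations

* No stochastic (Gillespie) simulation, events, dosing schedules, or
  algebraic/assignment rules; SBML documents using events or non-rate rules
  are rejected explicitly.
* SBML is read, not written; export is the native YAML format.
* Sensitivity analysis is local; no Sobol/Morris global methods.
* The identifiability check is a warning heuristic (observation count vs
  free-parameter count), not a structural analysis.
* Fold-change validation reports ratios only; no differential-expression
  testing.
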