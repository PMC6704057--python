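# Methods

## Model

Each learning experience is idealised as a step input of magnitude `u`
switched on at the event onset and persisting thereafter: hippocampal
activity integrates the brief training episode into a long-lasting drive
on the timescale of the behavioral experiments (days), and only the
resulting step matters to the dynamics. The step feeds two parallel
first-order linear processes, τ·dx/dt = −x + K·u(t): a fast
memory-strengthening signal x₁ and a slow memory-weakening signal x₂.
Their difference, saturated to [0, 1], is the *Pathway Activity* — the
net short-term learning capacity the event engages — and 1 − Pathway
Activity is the fraction of a finite downstream effector pool still free.

Per-event memory combines two normalisations. The peak activity the event
would reach alone (evaluated analytically at
t\* = ln(τ₂/τ₁)/(1/τ₁ − 1/τ₂)) is its **need**; the effector fraction
left at its onset, after the summed raw (x₁ − x₂) of all earlier events
is passed through the same single saturation, is its **have**. Memory at
time t is the event's activity trace normalised by its own peak, weighted
by min(have/need, 1). The cap means surplus capacity never amplifies
memory beyond full learning; the weight only ever reduces it. In
excess-effector mode the weight is identically 1.

Assumptions worth making explicit:

- **Initial conditions** are x₁ = x₂ = 0 for every event pair: a naive
  animal with no residual pathway activity.
- **Per-event state.** Each event drives its own (x₁, x₂) pair; effector
  accounting sums the raw differences across events *before* the single
  saturation (sum-then-saturate). Saturating per event before summation
  is the main alternative; it would only differ when individual events
  swing negative or above 1, which the shipped parameters never do.
- **have is a scalar at onset** by default — the capacity that exists
  when the stimulus arrives is what limits encoding. A pointwise
  time-varying variant is available via `have_mode="time_varying"` on
  `memory_trajectory`/`run_protocol`; at the event onset the two agree.
- Negative transients of x₁ − x₂ are clipped only at the Pathway
  Activity stage, never inside the linear states.

## Parameters

| parameter | meaning | control | weakening-deficient | units |
|---|---|---|---|---|
| τ₁ | strengthening time constant | 0.5 | 0.5 | h |
| τ₂ | weakening time constant | 36 | 144 | h |
| K₁ = K₂ | steady-state gains | 3 | 7.2 | — |
| u | step-input magnitude | 0.125 | 0.125 | — |

The 7.2/3 = 2.4-fold gain increase encodes the electrophysiologically
estimated amplification when WT1 is not functional; gain and input enter
the linear stage only through K·u, so applying the factor to K rather
than u is a labelling choice with no dynamical consequence. The default
parameter-variation sweep covers u ∈ [0.025, 0.15]; note 1/K = 0.139 for
the deficient genotype, so the top of the range deliberately crosses the
saturation onset (a warning is emitted).

Shipped protocols: `single` (task 1 at 0 h), `sequential-short` (task 2
at 48 h: train day 0, test day 1, retrain the next day) and
`sequential-long` (task 2 at 240 h). All memory tests are read 24 h after
the corresponding training event.

## Numerics

Trajectories are evaluated on a fixed grid of 0.01 h (τ₁ = 0.5 h must be
resolved) spanning [0, last test + 24 h]; step responses use the closed
form, so grid values are exact. The generic-input integrator is a
fixed-step classical RK4 with substeps capped at 0.01 h; declared input
discontinuities (`jumps=`) split the integration so no RK4 stage averages
across a jump, with the input taken right-continuous there. For step
inputs the integrator matches the closed form to better than 1e-6
(measured ~2e-10 over 0–300 h). Memory-at-test reads the nearest grid
node. CSV output is fixed at 12 significant digits, which makes repeated
runs under one seed byte-identical.

Degenerate inputs: a zero-magnitude event has need = 0 and raises an
explicit undefined-memory error (the input sweep instead flags such rows
with `memory_defined=False`); saturation bounds out of order, negative
time constants, non-monotone grids and empty read samples are rejected
with descriptive errors. Enrichment ranking breaks p-value ties
alphabetically by TF name so ranks are total and reproducible.

## Synthetic cohorts and parameter recovery

`generate_cohort` maps memory values to behavioral scales through an
affine link — freezing 0–100 %, place preference 50–100 % with 50 % =
chance — plus truncated Gaussian noise (default SD 5 percentage points),
one seeded RNG stream per cohort. This emulates the *structure* of
behavioral cohort data (group means ordered as the underlying memory,
bounded scales, animal-level noise); it does not emulate real behavioral
features such as inter-animal parameter heterogeneity, floor compression
in freezing scores, or session/handling effects, so passing recovery
tests demonstrate identifiability of the model from idealised readouts,
not from real mice.

Recovery searches a (K, τ₂) grid — K ∈ [3, 12] step 0.2, τ₂ ∈ [48, 288] h
step 4, both containing the deficient-genotype truth — minimising squared
error between per-(task, time) cohort means and model-predicted readouts,
with τ₁ and u held at their known values. The measurement design is the
sequential-short schedule read at task 1 +24 h and +48 h and task 2
+24 h. Two facts drove that design: an unsaturated single-event trace is
normalised by its own peak and therefore contains *no* information about
K (the flat-ridge case `recover_parameters` flags as non-identifiable);
and once K·u exceeds 1 the clipped peak lets K leak back into the
normalised trace, creating a spurious high-K/low-τ₂ branch that a single
task-1 time point cannot reject — the second retention time point
separates the branches. With n = 30 and 5 % noise the grid search
recovers K within 20 % and τ₂ within 30 % in 100/100 replicate cohorts
(the acceptance suite re-measures this).

## Enrichment stage

Read-count equalization subsamples every sample, without replacement and
under a named seed, to the cohort minimum — depth, not normalisation,
determines which lowly expressed genes are detected at all, and equal
depth removes that artifact before alignment. The DEG gate is
q ≤ 0.05 (FDR-adjusted) and |log₂((FPKM₁+1)/(FPKM₂+1))| ≥ log₂ 1.3, both
boundaries inclusive (the fold-change comparison carries a 1e-12 epsilon
against floating-point rounding at the boundary). Library preprocessing
replaces symbols by their homologs (one-to-many expands, unmapped drop)
and restricts both library and DEG set to the annotated, library-covered
universe, whose size N is recorded in every result row for audit. The
per-TF p-value is the hypergeometric right tail P(X ≥ k) (scipy's
survival function; an exact integer-combinatorics summation serves as the
independent oracle in the tests), ranked by −log₁₀ p. Raw p-values are
ranked, matching the stated procedure; `bh_adjust` offers an optional
Benjamini–Hochberg column. The planted-signal generator (2000 genes, 50
TFs × 100 targets, 150 DEGs drawn with 4× weight on one TF's targets)
provides the end-to-end positive control: the spiked TF ranks first in
100/100 replicates.

## Limitations

- The model covers sequential *acquisition* only — no extinction or
  reversal learning, and no stochastic/noisy ODE variant.
- τ and K are not fitted to plasticity traces; the shipped values are the
  stated defaults and the fitting surface is exposed only through the
  synthetic-recovery machinery.
- Real TF-library rankings depend on the library and homology-database
  versions; the enrichment stage validates the computation on planted
  signals rather than attempting to reproduce any particular published
  ranking.
- FPKM quantification and read alignment are out of scope; the
  equalization step operates on read collections or FASTQ files and
  hands off to external aligners.
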