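# Methods

## The model

`melmark` implements a deterministic, mean-field, discrete-time Markov
cohort model of melanoma epidemiology. A closed population is tracked as
occupancy fractions of eight states — Baseline, undiagnosed Stage 1 / 2-3 /
4, diagnosed (treated) Stage 1 / 2-3 / 4, and Death — with a one-year cycle.
The matrix is row-stochastic: every off-diagonal edge carries an annual
transition probability and the diagonal absorbs the remainder. Death
recycles to Baseline with probability 1, keeping the population constant, so
"deaths per year" equals the annual inflow to the Death state.

Three probabilities are time-dependent, which makes the chain
time-inhomogeneous (an out-of-equilibrium dynamical system rather than one
relaxing to a stationary law):

* **I(t)** — the *intrinsic* incidence: annual probability that a Baseline
  individual develops undiagnosed invasive melanoma. It is partitioned over
  the three undiagnosed entry states by fractions (f1, f23, f4), with
  f1 = 1 − f23 − f4 overwhelmingly dominant: most disease starts thin, a
  small fraction presents late or metastatic at first recognition.
* **D(t)** — the detection likelihood: annual probability that undiagnosed
  Stage-1 disease is diagnosed. This is the model's handle on *secondary
  prevention*: screening campaigns and diagnostic vigilance raise D(t).
* **O(t)** — the over-diagnosis fraction: the proportion of each year's
  Stage-1 diagnoses that concern lesions without life-threatening
  potential. O(t) is a counting overlay, not a transition — it adds
  O(t) × (Stage-1 diagnosis flux) to the diagnosis tally while the
  individuals remain dynamically at Baseline. This reproduces the defining
  epidemiological signature of over-diagnosis: counted incidence rises,
  disease dynamics and mortality are bit-identical.

Progression from Stage 1 runs at `r` per year toward Stage 2/3 and `r/3`
directly toward Stage 4; treated (diagnosed) Stage 1 progresses `p`-fold
more slowly (`r/p`, `r/3p`). Undiagnosed Stage 2/3 and 4 are diagnosed at
fixed rates `t4` and `t5`; Stage 2/3 deteriorates at `t6` (undiagnosed) and
`t7` (diagnosed). Melanoma-specific death occurs **only** from diagnosed
Stage 4, at rate `q` — a forced reading: with `t5 = 0.9`, adding a
`q`-sized death edge to the undiagnosed-Stage-4 row would push its row sum
past 1. Background (non-melanoma) mortality `d` applies from every living
state. Lowering `q` is the model's handle on *tertiary prevention*.

Fixed values: `q = 0.37`, `t4 = 0.2`, `t5 = 0.9`, `t6 = 0.1`, `t7 = 0.168`;
configuration axes `D0 ∈ {0.01, 0.05}` (the 1982 detection level) and
`p ∈ {2, 5, 15, 50, 125}`, ten configurations in all, with (0.05, 15) as the
reference. Calibration seeds: `I0 = 0.00031`, `r = 0.00375`, `d = 0.006`,
`f23 = 0.03`, `f4 = 0.01`.

Flux tallies (diagnoses by stage, over-diagnoses, melanoma and other
deaths) are attributed as start-of-year occupancy × edge probability, with
no intra-year chaining.

## Emulated registry data

The model is meant to be calibrated against national annual melanoma rates
(1982–2013) and published projections to 2028. Those extracts are not
redistributable, so `synthetic_aihw` reconstructs smooth stand-ins from
published summary anchors:

* incidence: the unique parabola over the 32 years with value 27.08 per
  100,000 in 1982, vertex at the 2008 diagnostic-incidence peak, and
  cumulative total 1319 per 100,000 (implied 2013 level ≈ 46.2);
* mortality: the unique parabola through 4.76 (1982) and 6.0 (2013) with
  cumulative total 171 per 100,000;
* projections: flat at the 2013 level of each series for 2014–2028,
  matching published expectations of a stable age-standardised rate.

Because the original analysis fits the least-squares smooth of the registry
data, the generator emits the smooth curves directly; a seeded Gaussian
noise option exists for robustness testing only. What the emulation does
*not* carry is the true smooth's local shape between the anchors — our
incidence is exactly parabolic and our mortality slightly convex, whereas
the real smoothed mortality may flatten into its 2013 plateau. Quantities
that difference two model runs (excess excisions, deaths averted,
projection-era cumulative deaths) inherit a few percent of shape
sensitivity from this, which is why the acceptance suite checks them at the
few-percent level while exact identities are checked tightly.

## 1982 calibration

The pre-campaign era is treated as an equilibrium: with time-constant 1982
values the chain must be stationary at the three anchors — diagnostic
incidence 27.08/100k/yr, melanoma mortality 4.76/100k/yr, diagnosed-thin-
melanoma prevalence 3215/100k.

Stationarity imposes a useful identity: inflow to the diagnosed block
equals its outflow, so

    diagnostic incidence = melanoma mortality + d × (diagnosed occupancy).

With the three anchors fixed, this pins `d` near 0.0069 — `d` must
therefore be among the calibrated parameters (its 0.006 seed reflects the
whole-population death rate; the melanoma anchors demand the small upward
adjustment). A consequence worth knowing: the model's all-cause mortality
runs at ≈ 695/100k/yr rather than the ≈ 600 a strict `d = 0.006` would
give; the calibration resolves the tension in favour of the melanoma
anchors, and the all-cause output is checked only at the
order-of-magnitude level.

The calibrator adjusts (I0, r, f23, f4, d) by bounded least squares on the
three relative anchor residuals, with a weak (1e-3) pull toward the seeds
to select among equally good solutions, making re-calibration idempotent.
Boxes: ±50% for I0 and d, which the data determine robustly, and
[0.05×, 3×] / [0, 2×] for r and f23/f4 — these are only loosely pinned by
published evidence and genuinely vary with the configuration geometry (at
D0 = 0.01 the undiagnosed Stage-1 pool is five times larger, so the
mortality anchor requires r well below half its seed; calibrated r spans
0.0006–0.0058 across the ten configurations). All ten configurations meet
all three anchors to better than 0.001%.

## Curve families and fitting

D(t) candidates are monotone non-decreasing curves on rescaled time
u = t/31 (u = 0 ↔ 1982, u = 1 ↔ 2013): a line, concave-up and concave-down
parabolas (vertex pinned at u = 0 / u = 1), and an endpoint-normalised
logistic (steepness 8). Candidate 2013 levels: {0.075, 0.10, 0.15} for
D0 = 0.05 and {0.02, 0.05, 0.10} for D0 = 0.01 — a documented choice, each
representing a different maximal increase in secondary prevention. Degree
≥ 3 polynomials are deliberately excluded (overfitting risk with only two
smooth series as data).

I(t) = I0 + b·u + c·u² with I0 pinned by the 1982 calibration. For each
D-candidate, (b, c) are found by exhaustive search on a log-spaced grid:
100 b-values in [B/10, 10B] and 100 c-values in ±[C/10, 10C] (50 per
sign), with (B, C) coarse endpoint-slope estimates. Ties break toward
smaller |c|, then smaller |b|. Since only the Baseline row depends on
I(t), all 10,000 candidates propagate together as one batched
matrix-vector recursion per year — a grid fit takes well under a second.

Fit quality is the pooled RMS relative deviation over both annual series
(64 terms); it is dimensionless and invariant to common rescaling. The ten
best-fit errors land at 0.027–0.043, all below the 4.5% bound, worst for
D0 = 0.01. For the reference configuration the selected D(t) reaches 0.10
in 2013 — a doubling of the 1982 detection likelihood.

## Scenario conventions

* Every scenario runs from the calibrated 1982 steady state; only the
  years inside the scenario window are tallied.
* Retrospective comparisons (1982–2013, 32 iterations) pair the fitted
  history against D frozen at its 1982 level.
* Prospective policies — maintain-2013, revert-1982, double-2013, and
  reduced `q` — take effect **from the 2013 iteration**, and "2013–2028"
  windows contain 16 iterations. The q-halving average quoted for
  "2014–2028" is the mean over those 15 years with the switch already in
  2013, i.e. it excludes the sharp first-year drop.
* After 2013 the intrinsic incidence is held at its fitted 2013 value and
  rescaled by a single factor, solved once per model (Brent's method on
  the mean), so the maintain-policy diagnostic incidence matches the flat
  projected series within 1%; every policy reuses that factor, so policy
  differences, not baseline drift, drive the comparisons.
* Over-diagnosis scenarios ramp O(t) linearly from 0 (1982) to α (2013),
  α ∈ {0.01, 0.03, 0.10}; the excess-diagnosis count is exactly linear
  in α.

## Monte-Carlo sensitivity

One parameter at a time, n seeded normal draws (SD = 10% of the calibrated
value) replace the parameter; the stationary state is recomputed per draw
(a batched 8×8 linear solve) and the deviations of steady incidence,
mortality and Stage-1 prevalence recorded. Draws that leave the admissible
region are redrawn rather than clipped (no boundary atoms), with an error
once redraws exceed 50% of n.

Two structural findings the suite asserts:

* `q` moves mortality while leaving incidence untouched up to the
  closed-population renormalisation residual (≈ 2×10⁻³ per 100k — the
  surviving Stage-4 pool displaces a sliver of Baseline mass; in an open
  population the coupling would vanish exactly).
* At *full* stationarity, `q`'s influence on mortality itself largely
  cancels: mortality = (D4 inflow) × q/(q+d), so re-equilibration of the
  Stage-4 pool absorbs most of the perturbation and `q`'s spread is
  comparable to `t7`'s rather than dominant. A large steady-state `q`
  signature can only arise from incompletely relaxed (transient)
  dynamics; the dramatic `q` effects in this package are dynamic ones,
  visible in the scenario engine, not in the equilibrium sensitivity.

The headline sweep uses 10,000 draws per parameter; the test suite uses
hundreds to low thousands, where the spreads are already stable to well
under the asserted margins.

## Economics

The screening-economics identities are deliberately plain arithmetic:
NNS = consultations-per-excision × NNT × excisions-per-life; cost per
excision = $300 (consultation + excision + pathology) + $50 for each
additional consultation; cost per life = cost-per-excision × NNT ×
excisions-per-life, usually over the interpolated 50–120 excisions-per-life
range; primary-prevention cost = per-capita spend × population / lives
saved, optionally inflation-compounded. The scenario engine's
excisions-per-death-averted ratio plugs in directly.

## Numerical choices

* Steady states: direct solve of the stationary system (null space of
  Mᵀ − I with a normalisation row) in hot paths; an iterative
  matrix-squaring path (tolerance 1e-12 on a doubling, cap 10⁶ effective
  steps — robust to the chain's slow modes, e.g. the treated-Stage-1 pool
  draining at r/p per year) is kept as an independent cross-check, and the
  suite asserts agreement to 1e-10.
* State vectors are validated to non-negativity and unit mass (1e-12
  drift tolerance over a century of iterations).
* Infeasible parameter combinations (row sums above 1) raise a named
  error identifying the offending row; grid points with inadmissible I(t)
  are masked rather than clipped.
* All reported rates are per 100,000 persons per year; cumulative
  quantities are per 100,000 over the stated window.

## Problem sizes

The default analysis — ten configurations × 12 detection candidates ×
10,000-point grids, the full scenario suite, and an 11-parameter × 2,000
draw sensitivity sweep — completes in well under a minute on one CPU; the
headline 10,000-draw sweep adds a few seconds more.

## Limitations

* Mean-field: no age structure, risk strata, or cohort effects; in-situ
  melanoma is not a separate state (its incidence is unobserved in the
  registry data this emulates).
* Deterministic cohort dynamics: no individual-level stochasticity, so no
  uncertainty intervals on fitted curves — point fits only.
* The emulated series match the published anchors exactly but cannot
  reproduce the unpublished local shape of the original smoothed data;
  paired-difference outputs carry a few percent of resulting
  shape-sensitivity.
* The five-year-survival reading of `q = 0.37` is not enforced:
  (1−q)⁵ ≈ 9.9%, close to but not exactly the ~12% sometimes quoted, and
  the survival convention behind such quotes is ambiguous.
* Absolute national counts (total excisions, campaign budgets) are out of
  scope: all outputs are per 100,000.
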