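# Methods

## The experimental design being modeled

A cohort of participants answers an `n`-item questionnaire (Likert integers
1–6; the reference design has n = 11 items and 30 participants).  Each item
has one matched scenario intended to push that item's answer in a known
direction: +1 (toward agreement) when the baseline answer is ≤ 3, else −1.
After each scenario the full questionnaire is re-administered, giving a
`participants × scenarios × items` response tensor plus the baseline.
Participants may also draw the causal relations they perceive among the
items; the drawing is used directly as an interaction matrix.

## Effect quantification

With baseline `r_k0` and post-scenario response `r_sk`, the normalized change
is `e_sk = (r_sk − r_k0)/r_k0`.  The baseline index is per *item*: every
column of the change tensor is normalized by that item's own baseline.  (An
alternative reading — normalizing all items by the targeted item's baseline —
would change off-target effects; the per-item reading is used throughout.)

- Sensitivity `se_s = e_ss · g_s`: positive when the target moved the
  intended way.
- Specificity `sp_s = |e_ss| / (Σ_{k≠s} |e_sk| / (n−1))`: > 1 when the target
  moved more than the other items on average.  A zero denominator (no
  off-target movement) leaves the ratio undefined; the default is to mask the
  cell rather than fabricate a large ratio, with an optional `ε` floor for
  users who prefer a defined value.

Summaries report mean ± sample standard deviation (ddof = 1; the convention
is recorded in the output metadata).  Distributions "across participants"
take one value per participant (mean over that participant's scenarios);
"across items" one value per item (mean over participants).  Both pooling
conventions are exported so they can be compared directly.

## Dynamical models

State dynamics are the noise-free LTI system `x(k+1) = A x(k) + B u(k)` on
the (integer-valued, but modeled as real) response vector.

**Self-constructed.**  `A` equals the participant's drawn network under the
convention `A[target, source]` (so `A·x` propagates source values into
targets; verified by a single-edge unit test).  Drawn weights are used as
drawn, with no normalization — simulation and fitting need no stability
assumption, so `A` is never silently altered.  `B = I`; scenario `s` is the
input `±1·e_s` signed by the intended direction.

**DMDc.**  `[A B] = X2 [X1; U]⁺` via SVD pseudoinverse with relative cutoff
`rcond = 1e−10` (recorded in model metadata).  In the study design every X1
column is the same baseline, so the stacked regressor has rank ≤ n + 1 and
the problem is under-determined; the pseudoinverse returns the
minimum-Frobenius-norm solution.  Because the system `A x0 + B e_s = x_s` is
always consistent for this design, the fit reproduces the training snapshots
exactly — which is also why in-sample one-step prediction accuracy is r ≈ 1
for dmdc models: it is a reproduction property, not generalization.  Fitting
uses input magnitude +1; prediction mirrors each family's fitting convention
(±1 self-constructed, +1 dmdc).  Predictions stay real-valued; rounding back
onto the Likert grid would only degrade the correlations used to assess them.
An exact-identifiability regime (full-rank random snapshots, `m ≥ 2n`) is
provided for verification and recovers a planted `(A, B)` to < 1e−8.

## Controllability and energy

**Average controllability** `AC_j` is the trace of the infinite-horizon
controllability Gramian for the single input `e_j`, computed from one
discrete Lyapunov solve `M = AᵀMA + I` (then `AC_j = M_jj = Σ_i ‖A^i e_j‖²`).
It requires Schur stability; matrices with spectral radius ≥ 1 (possible for
drawn networks and DMDc fits) are rescaled `A → A/(1+|λ_max|)` inside the
controllability computations only, and the rescaling is recorded and surfaced
as a pipeline warning.  **Modal controllability** uses
`MC_j = Σ_i (1−|ξ_i|²)|v_ji|²` with eigenvector columns normalized to unit
Euclidean norm (MC is not invariant to that scaling, so the convention is
fixed); complex eigenpairs enter via squared moduli, and a near-defective
eigenbasis (condition number > 1e8) is flagged in metadata rather than
raised.

**Control energy.**  The transition of interest is baseline → observed
post-scenario state, driven through input column `s` over horizon K (default
K = 1) with input-cost weight ρ (default 1).  The quadratic cost sums squared
deviations of the trajectory from the target plus `ρ·uᵀu`.  With a single
input column and K = 1 the hard terminal constraint is generically
unreachable, so the implementation is a dual contract:

- *feasible* (terminal state in the K-step reachable set, relative residual
  ≤ 1e−8): terminal equality enforced, cost minimized over the remaining
  freedom via an equality-constrained QP (KKT solve); at K = 1 this is the
  least-norm input `u = B_s⁺(x_T − A x_0)`;
- *relaxed* (otherwise): terminal equality replaced by the quadratic tracking
  penalty already present in the cost (a ridge problem), and the result
  flagged `feasible = False` so downstream statistics can separate regimes.

The reported energy is `E = Σ_k u(k)ᵀu(k)` in both regimes.

One consequence deserves emphasis: for any model whose fitted `B` column
exactly explains its own training transition (as the in-sample DMDc fit
does), the K = 1 energy toward the observed post state is identically the
squared fitting input — a tautology carrying no information, and every
scenario ties.  Cohort profiles therefore accept an `energy_input` switch:
`"fitted"` (the model's own B column) or `"canonical"` (the unit vector
`e_s`).  The pipeline uses the canonical column for both model families so
the energy statistic reflects the network structure rather than the fit's
bookkeeping.

## Group statistics

Per participant, the 11 node-wise AC/MC values (node j ↔ scenario j) or the
11 scenario-wise energies are paired with the 11 scenario-wise sensitivities
or specificities and summarized by Kendall τ-b — the tie-corrected variant,
since Likert-derived quantities guarantee ties.  Two-sided p-values come from
the exact permutation null (enumeration, tie-aware) for n ≤ 9 and from the
tie-corrected normal approximation otherwise; the study's n = 11 always uses
the approximation.  Participants with an undefined τ (a constant argument)
are excluded from combination with their count reported.  Cohort-level
significance is Fisher's method, `−2 Σ ln p ~ χ²(2k)`; the per-participant
significance count is reported at α = 0.05 with no multiple-testing
correction (a Benjamini–Hochberg adjustment can be applied downstream from
the exported per-participant table).  Prediction accuracy is the Pearson
correlation between predicted and observed responses, pooled per participant
(all scenario × item cells) and per item (all participant × scenario cells);
undefined units (zero variance) are reported with a reason.

Calibration is verified empirically: under within-participant permutation of
the outcome, the Fisher-combined group test's false-positive rate at
α = 0.05 sits within binomial sampling error of 0.05 over 200 simulated
cohorts.

## Synthetic cohorts

The generator emulates the design exactly: per participant a dense random
`A` rescaled to spectral radius 0.6 (stable but strongly coupled), `B = g·I`
with intervention gain g = 1, baseline uniform on {1..6}, directions from the
push-away rule, one-step latent responses `A x0 + B(±e_s)` plus Gaussian
noise (sd 0.25, a quarter Likert step — a modest response-noise level; the
underlying model itself is noise-free), then rounding half away from zero and
clipping to 1..6.  The "drawn" network is the true `A` with its diagonal
removed and each entry kept with probability 0.9 (imperfect introspection).
Ground-truth matrices and per-scenario energies are returned alongside the
study.

What this does *not* emulate: real attitude dynamics are neither linear nor
time-invariant; real drawn networks are sparse, signed and subjective rather
than noisy copies of a generating matrix; responses may drift over the
session; and the strong clipping a dense `A` induces at the grid edges is an
artifact of the linear latent model.  Passing tests therefore demonstrate the
*machinery* — estimation, metrics, statistics — not the adequacy of the
linear model for human data.

**Planted association.**  The `energy_sensitivity_negative` mode builds a
cohort in which high-energy scenarios genuinely under-shoot.  Energy
heterogeneity must come from the network, not from the achieved displacement:
a scenario whose intended unit change opposes a large free drift
`(A x0 − x0)_s` has high one-step energy regardless of what the intervention
achieves.  Scenarios are ranked by that theoretical energy and their achieved
intended change is attenuated linearly in rank (factor `1 − 1.1·rank/(n−1)`,
so the hardest scenario slightly backfires — an empirically familiar
reactance pattern); off-target items stay at baseline plus noise so the plant
governs the outcome.  The measured transition energy then stays high for
attenuated scenarios (the drift term dominates the on-target residual) while
their sensitivity shrinks, producing a recoverable negative τ.  A naive plant
that attenuates the post state toward the free-dynamics state would fail
here: it shrinks the measured on-target residual, hence the measured energy,
in step with the sensitivity, coupling the two *positively*.  The attenuation
strength is a calibrated construction for power analysis, not an empirical
claim.

## Pipeline, sizes, and numerical choices

The pipeline writes every stage's tidy CSV plus a `report.json` validated
against a shipped schema; the report excludes wall-clock content so reruns
with identical configuration are byte-identical, and all stabilization and
feasibility events appear in its `warnings` list.  Default problem sizes
throughout the tests and the acceptance script are the design sizes (30 × 11)
with oracle comparisons on 4–6-node systems, 50–200 simulation replicates for
calibration checks, and 200-term series truncations — small enough to run
interactively, large enough for the binomial/recovery margins asserted.

Degenerate inputs are contracts, not crashes: all-tied correlation arguments,
all-masked specificity units, zero-variance prediction units and participants
without drawn networks are reported as missing with a reason and excluded
from aggregates with counts.

## Known limitations

- One-step (K = 1) energies are evaluated in the regime the relaxed contract
  defines; published analyses of this design used an unspecified customized
  optimal-control solver, so numerical energy values are a documented
  reading, not a verified match to any external implementation.
- In-sample dmdc prediction accuracy is a reproduction property (see above);
  a leave-one-scenario-out evaluation would measure generalization instead
  and is not implemented.
- The exclusion of specific participants from published group statistics has
  no stated criterion; exclusion here is an explicit, default-empty config
  list, never automatic.
- Exact τ p-values are enumerated only up to n = 9; the design's n = 11 uses
  the normal approximation, whose group-level calibration is checked by
  simulation rather than guaranteed.
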