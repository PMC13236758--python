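# Methods

## Model

Each stimulus — an object, or an arena location acting as a context — is a
node whose representational elements occupy one of three states: inactive
(`I`), primary activity (`A1`, which drives vigorous responding and stands
in for exploration) and secondary/refractory activity (`A2`, which encodes
recency and suppresses re-activation).  With `I + A1 + A2 = 1` the dynamics
of a node are

    dI/dt  = pd2·A2 − (p1 + p2)·I
    dA1/dt = p1·I − pd1·A1
    dA2/dt = pd1·A1 + p2·I − pd2·A2

`p1` is the stimulus-driven activation rate (nonzero only while the
stimulus is scheduled on), `pd1` and `pd2` are stimulus-independent decay
rates, and `p2` is the associative promotion probability: each directed
context→object link carries opponent accumulators

    dV+/dt = L+·A1_context·A1_object
    dV−/dt = L−·A1_context·A2_object

and `p2_object = clip(Σ_c A1_c·(V+_c − V−_c), 0, 1)` over the contexts
linked to the object.  A net-inhibitory context never promotes on its own;
it only offsets concurrent excitatory drive.  Contexts receive no
associative input (`p2 = 0`); object→object and object→context links are
out of scope.  Two priming routes fall out of the equations: residual `A2`
from a stimulus's own recent presentation (self-generated priming) and
promotion into `A2` by an associated, active context (associatively
generated priming).  Both deplete the pool available to enter `A1` at test,
and peak `A1` within an object's test window is the behavioral proxy.

## Parameters

All rates are per internal time unit τ, with 1 τ = one 3-s grid step
(`dt_seconds = 3` converts to wall clock; the unit is a single config
constant).  Canonical values, held fixed across every simulation:

| parameter | value | meaning |
|---|---|---|
| p1 (objects) | 0.75 | object salience |
| p1 (contexts) | 0.25 | contexts are behaviorally more neutral |
| pd1 | 0.1 | A1→A2 decay; A1 transients last ~10 τ (~30 s) |
| pd2 | 0.02 | A2→I recovery; self-priming dissipates within ~2 h |
| L+ | 0.25 | excitatory learning rate (rapid single-trial learning) |
| L− | 0.025 | inhibitory learning rate (10:1 ratio, net-excitatory links) |

pd2 < pd1 makes `A2` outlast `A1`, the precondition for all priming
effects; the per-τ reading of the rates is the only one under which a
5-min and a 120-min retention interval produce distinguishably different
self-priming while still decaying completely within two hours.

## Integration

The coupled node/link system is advanced by classic fixed-step RK4 on the
3-s grid, with activity flags held constant within a step.  Each grid step
is subdivided into 8 RK4 substeps: at rates near the top of the admissible
range a single 3-s RK4 stage deviates from the exact solution by ~1e-3,
whereas 8 substeps keep the worst-case deviation from the
matrix-exponential solution of an isolated node near 1e-7 — comfortably
inside the 1e-6 agreement the integrator tests demand — at negligible cost
next to the batched vectorization.  Within any constant-input segment an
isolated (link-free) node is a linear time-invariant 3×3 system, so
`closed_form_isolated_node` chains `scipy.linalg.expm` across segments as
an independent oracle; the Padé-based `expm` handles repeated or defective
eigenvalues without special-casing.  States are renormalized only if the
conservation drift `|I+A1+A2−1|` exceeds 1e-9, which doubles as an error
detector (a triggered clamp is logged, and never occurs in the shipped
suites).  Simulations are fully deterministic; repeated runs are
bit-identical.

All schedule boundaries are snapped to the 3-s grid at construction
(rounded to the nearest step, logged when the input was off-grid; e.g. a
0.625-min object window is 12.5 steps and rounds to 13).

## Task schedules

Conceptual presets share one timeline — sample, ISI, sample, RI, test, with
5-min samples and test and configurable delays — holding four condition
objects: *novel* (test only), *recent in-place* (sample 2, tested in its
sampled context), *remote in-place* (sample 1, tested in its sampled
context) and *recent displaced* (sample 2, tested under a fresh context).
SOR contrasts novel vs recent in-place, RR remote vs recent, OIP displaced
vs recent in-place; Q denotes the preferred object (novel/remote/displaced)
and P the comparison.

Two sub-timing choices were genuinely open and were fixed as follows, the
same arrangement the arena renderings use:

* the context window spans each phase and the object is on during its
  final half (the animal enters the location before encountering the
  object).  Fully coextensive context/object windows weaken associative
  priming at test so severely that the canonical OIP ratio falls to ~1.07,
  inconsistent with the local-robustness bound the suite checks (Q/P >
  1.15 at every factorial corner);
* the sampled context is on during both samples (the arena is present
  throughout sampling).  This is what lets the second sample pair context
  `A1` with the remote object's residual `A2` and accrue the
  extinction-like inhibition that amplifies the recency effect; restricting
  each context to its own sample collapses the RR contrast to ~1.06.

During ISI/RI all stimuli are off (holding-cage reading); an in-arena
delay can be composed manually from events but is not a preset.

Empirical presets reproduce four study designs: `good_*` (20-min
habituation presented context-by-context in fixed ascending order; 5-min
samples and tests; contexts tile each phase equally with objects on the
final half; RR+OIP swaps two of four objects at test), `tam_*` (3-min
tests; the manipulated delay is the RI for SOR/OIP and the ISI for RR),
`whitt` (eight 30-s samples as two 15-s context periods with the object on
the final 7.5 s, short/long ISI, 15-min RI, 2-min test; the lead-in period
before the first sample is 1 min, a choice the source designs leave open),
and `sanderson` (Y-maze: 10 visits of a 0.5-min START context followed by
a 1-min arm whose location context is exactly coextensive with it;
counterbalancing permutes only the familiar/novel arm assignment).
Counterbalancing enumerates the full Cartesian product of context-order
permutations per phase (4, 8, 576, 13 824, 512 and 2 schedules for Good
SOR/RR/OIP/RR+OIP, Whitt and Sanderson) and reports means plus the
max−min spread across permutations.

## Observation model

`y_hat_i = k·A1_hat_i` maps peak activation to exploration seconds.  `k`
is the closed-form weighted least-squares slope through the origin.  Raw
weights are inverse-variance (`1/se²`); within each (study, task) cell
they are rescaled to a common total, cells within a study share the
study's weight equally, and studies share the overall weight equally, so
no study or task dominates by reporting more means.  At the contrast
level the same scheme runs on the propagated variance `se_Q² + se_P²`,
except that a combined procedure's component contrasts split that task's
weight equally.  The 95% CI for `k` enumerates all `S^S` ordered
study-level resamples exactly (256 for four studies) and takes 2.5/97.5
percentiles; because weight normalization is study-local, each resample's
`k` reduces to a ratio of per-study moment sums, making the enumeration
exact and cheap.  A leave-one-study-out pass reports the percent change
in `k` per omitted study.

The synthetic generator emulates a multi-study corpus: per study it runs
the conceptual presets at study-specific delays, emits
`y = k_true·A1_hat + N(0, noise_sd²)` (clipped at zero) with
heteroscedastic standard errors drawn from [0.8, 2.5] s.  It reproduces
the *structure* of real data (study/task nesting, unequal precision), not
its between-study heterogeneity: noise is record-level only, so passing
recovery tests show the estimator and its bootstrap are correctly
implemented, not that the model fits any real corpus.  A known limitation
measured by the coverage experiment: the percentile study bootstrap
undercovers nominal 95% when only four clusters exist (~74%, rising to
~85% at six studies); with so few studies the CI should be read as a
stability diagnostic, not an exact frequentist interval.

## Sensitivity suites

All three tiers vary (pd1, pd2, L+, L−) log-uniformly over [0.001, 1]
(log10-uniform prior; the Sobol' indices are defined on that measure) with
the salience values fixed, and score the conceptual contrasts
`A1_Q − A1_P`.

**Parameter space partitioning.**  Each sampled point is classified per
task: *fail* if both peaks are at or below the negligible-activity floor
0.005 or the ordinal relation is violated (ties are strict failures),
*robust* if `A1_Q > (1+ε)·A1_P` for ε ∈ {0.05, 0.10, 0.15}, else *weak*.
Volumes are plain Monte-Carlo fractions of 20 000 points per run, five
runs (mean ± across-run SD); no MCMC volume correction is applied, so
agreement with corrected published volumes is expected only within a few
percentage points.  Region summaries (geometric mean and geometric SD per
parameter, probabilities of pd1 > pd2 and L+ > L− and their conjunction)
are reported for the all-robust region and for the selective-failure
region (SOR and RR robust, OIP fail).

**Sobol' decomposition.**  A second-order Saltelli design (blocks A, B,
AB_i, BA_i from one scrambled Sobol' sequence; `n_base·(2·4+2)`
evaluations with `n_base = 1024`) feeds the Saltelli-2010 estimator for
S1, the Jansen estimator for ST and the closed-pair estimator for S2; the
residual `1 − ΣS1 − ΣS2` absorbs higher-order terms.  Indices are
averaged over three independently scrambled replicates and the reported
uncertainty is the mean 95% bootstrap half-width (500 resamples of the
base rows).  Small negative estimates within the CI are sampling noise.

**Local 2⁴ factorial.**  The 16 corners perturb each canonical parameter
by ×1.1 or ÷1.1 (log-symmetric ±10%).  Effects use orthogonal ±1 coding —
a term's effect is the mean corner response times the product of its
factors' signs, i.e. half the high-minus-low difference for a main effect
(the half-vs-full convention is unstated in the sources; sum-of-squares
shares are invariant to it).  Relative effects divide by the canonical
(center-point) contrast; terms below a 1% SST share are filtered from the
report.

## Numerical and degenerate-input conventions

Peaks are taken on grid points only (the grid is the model's stated
resolution).  A contrast ratio with a zero comparison peak is reported as
undefined and excluded from ratio summaries with a logged count.  NaN/Inf
in any derivative aborts the run naming the node.  Every stochastic suite
takes an explicit seed; replicate r uses seed + r, and results are
reproducible from the run manifest alone.

## Problem sizes

The shipped suites use the full study conditions: PSP at 20 000 points ×
5 runs × 3 tasks, Sobol' at `n_base = 1024` with 3 replicates, the
complete counterbalance sets (up to 13 824 schedules batched through the
vectorized engine), and 8 RK4 substeps per 3-s step throughout.

## Known limitations

Exploration is read out as peak A1 under fixed presentation durations; the
mutually exclusive choice structure of real tests (time on one object
reduces time on the other) is not modeled.  Distractor-rule capacity
limits, arousal modulation and object→object links are out of scope.  The
conceptual sub-timing choices above are documented assumptions: the local
factorial's exact SST split between pd1 and the learning rates in SOR is
sensitive to them (the pd1 share computes to ~0.73 here), while the
orderings, the corner-ratio bound and the Sobol'/PSP structure are not.
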