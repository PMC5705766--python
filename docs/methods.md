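# Methods

## The analysis model

The package treats a scene arrangement as a set of 3D object-center
positions `x ∈ ℝ³` (meters; right-handed, origin at the room-floor center,
z up) produced by one participant for one room under one instruction
condition. Three statistics carry the scientific content:

1. **Displacement.** Memory for an object's location is the Euclidean
   distance between its build-phase and recall-phase centers. Chance level
   is estimated by a cross-participant resampling baseline: for each
   (participant, room) one partner is drawn uniformly from the other
   participants who built the same room *under the same condition*, and the
   per-object distances between the two builds are scored exactly like
   displacements. Partners are redrawn independently per room and a
   participant is never its own partner. Requiring condition match avoids
   conflating the two placement regimes in the null. All displacement-type
   variables are log-transformed (natural log, with ε = 10⁻⁶ m added before
   the log so that exactly re-snapped objects do not produce −∞), averaged
   into per-participant cells (condition × object type × kind), and compared
   with classical paired *t* tests (df = n−1, two-sided, Cohen's
   d = mean(diff)/sd(diff)). An all-zero difference vector reports
   t = 0, p = 1, d = 0 by convention rather than NaN; a constant nonzero
   difference (zero variance, nonzero mean) is an error.

2. **Nearest-local-neighbor pairing.** For every object in a room — global
   and local alike — the closest *local* object by 3D distance, excluding
   the focal itself, with ties broken lexicographically by object id
   (deterministic, seed-free). Pairs are **ordered** (focal → neighbor), so
   each participant contributes exactly one token per object and counts
   within a (room, condition) cell sum to participants × 15; an unordered
   collapse is available behind a flag. Repetition counts (number of
   participants exhibiting an identical pair) are contrasted by condition
   with a Poisson log-linear model (count ~ condition + room fixed effects)
   fitted by IRLS; the condition coefficient is the log rate ratio of
   consistent over inconsistent. Room fixed effects replace a random-effects
   structure: the fixed-effect target is identical and the desk-scale model
   is fully specifiable and deterministic.

3. **Rank-frequency laws.** Pair counts sorted descending define a
   rank-frequency distribution; it is fitted by multinomial maximum
   likelihood to the Zipf law p(r) ∝ r^(−α) and the Zipf–Mandelbrot (ZM)
   law p(r) ∝ (r+β)^(−α) on the finite observed support r = 1..R. Finite
   support (rather than an infinite Hurwitz-zeta vocabulary) is deliberate:
   pair vocabularies are small and bounded by the design. The likelihood is
   over tokens at each rank (counts-of-counts style fitting of type
   frequencies is *not* used).

## The synthetic-data generator

No raw arrangement data are public, so the generator is a first-class part
of the package. It emulates the design: 10 participants; 4 room categories
× 4 rooms (16 rooms; the search preset uses 2 per category); 15 objects per
room (10 local + 5 global); 3 × 3 m floor plan; objects spawn on a circle
of radius 1.5 m at 1 m height (recorded as design metadata; analyses only
use final positions). Condition assignment is counterbalanced
deterministically: room parity within category alternates with participant
parity, so every participant builds half of their rooms consistent and
every room is built consistent by exactly half of the participants.

Placement is anchor-based. Each category's five global objects carry
canonical floor positions (≥ 0.8 m apart); each local object carries a
canonical anchor and an offset of ≤ 0.5 m. Consistent rooms realise this
shared layout with Gaussian jitter (σ = 0.15 m globals, 0.10 m locals) and
locals keep their canonical anchor with probability 0.9. Inconsistent rooms
permute the global slots per participant (jitter σ = 0.60 m) and locals
keep their canonical anchor only with probability 0.1. Recall adds
isotropic Gaussian memory noise with σ keyed by condition × object type
(0.25 / 0.35 / 0.35 / 0.55 m for global-con / global-incon / local-con /
local-incon). Positions are clipped to the room bounds rather than
rejection-sampled, preserving determinism.

Grab durations are lognormal per condition × object type (location 0.9 for
globals in both conditions, 0.7 / 1.0 for locals consistent/inconsistent;
scale 0.4; recall shifted −0.3), gaze totals share a latent factor with
grab durations (ρ = 0.5), and first-grab order is an exponential race with
a 3× priority weight for globals. Search log-RT is
`base + inconsistency (0.12) + local (0.18) + other-room (0.15, locals
only) + slope(condition, type) × centered trial + N(0, 0.22²)`, with
slopes −0.028/−0.032 (local) vs −0.010/−0.012 (global); errors are
Bernoulli(0.038). Noise magnitudes are free calibration constants (the
source design constants fix only the structure and effect directions);
they were chosen once to give realistic effect sizes at this scale and are
all exposed in `GeneratorConfig`.

What the generator does **not** emulate: semantic object identity (names
are labels, not embeddings), physics or collision beyond anchor spacing,
within-trial grab dynamics (only summed durations and first-grab order),
eye-movement time courses (only summed gaze totals), and any
participant-level individual differences beyond sampling noise. Passing
tests therefore show that the *analyses* recover the structure the
generator injects — not that real behavior has that structure.

## Numerical choices

- **Bounds tolerance** 0.25 m beyond the 1.5 m half-width in validation,
  for wall-leaning object centers; clipping caps z at 2.5 m and floors it
  at 0.
- **Boundary clipping vs the Maxwell mean.** Under unbounded isotropic
  noise, E‖recall − build‖ = σ√(8/π); clipping recall positions at the room
  bounds truncates the noise and shrinks realized mean displacement by a
  few percent at σ = 0.3 (≈ 7% in the default layout, mostly the z ≥ 0
  floor). Closed-form checks of the displacement statistic therefore apply
  the isotropic noise directly; the generator keeps its clipping.
- **ZM optimisation.** Grid initialisation (α ∈ 0.6..3.0 step 0.2,
  β ∈ {0,1,2,5,10,20}, plus the pure-Zipf ML solution as a second start)
  followed by Nelder–Mead to |Δloglik| < 10⁻⁸; out-of-domain proposals get
  +∞. The pure-Zipf 1D fit uses bounded scalar minimisation on
  α ∈ (10⁻⁴, 30). A final guard returns the Zipf solution if the simplex
  ends below it, so `loglik(ZM) ≥ loglik(Zipf)` holds identically.
- **GOF binning.** Expected token counts are pooled over adjacent ranks
  (walking from the head, so the sparse tail merges) until every bin
  expects ≥ 5 tokens; leftovers fold into the last bin;
  df = bins − 1 − free parameters. The pooled Pearson statistic is exactly
  calibrated on multinomial draws in true rank order (simulation: mean
  p ≈ 0.52, 5–6% below 0.05). Re-ranking counts by realized frequency —
  inherent to rank-frequency data — turns them into order statistics and
  makes the same statistic *conservative* (p skewed toward 1) even under
  the true model, so fitted-model GOF p-values are reported as descriptive
  fit indices, not calibrated tests.
- **Likelihood-ratio nesting.** Because β ≥ 0 is a boundary, the LR
  statistic under a true Zipf law follows the mixture ½δ₀ + ½χ²(1), not
  χ²(1); tests assert the always-true inequality and bias decay rather
  than the naive reference distribution.
- **Degenerate KDE inputs.** First-grab densities use Silverman's
  rule-of-thumb bandwidth with a fixed 0.5 fallback for zero-spread data,
  evaluated on the grid 1..15 (step 0.1) and renormalised to unit trapezoid
  mass so kernel mass leaking past the grid edges does not bias
  comparisons.
- **Trial centering** maps search trials 1..15 to −7..+7 before slope
  fitting; slopes are per-participant OLS and require ≥ 3 trials, else
  reported missing.

## Design choices that were genuinely open

- Mixed-effects machinery is deliberately replaced by per-participant cell
  means + paired contrasts (and per-participant OLS slopes): the factorial
  questions survive aggregation, and the pipeline stays deterministic and
  exactly testable at this scale. This is a documented divergence from the
  source analyses, not an approximation of their coefficients.
- The baseline partner is redrawn per room (not once per participant), and
  only among same-condition builders.
- Pair tokens are ordered; token conservation is the invariant that makes
  the frequency table checkable.
- With 10 counterbalanced participants, each room × condition cell has 5
  builders, so pair counts are capped at 5 and several near-deterministic
  anchor pairs hit the cap. Head-shape comparisons based on f₁/f₂ tie at
  1.0 under this design (and GOF p saturates at 1.0 for both conditions);
  the condition difference is instead carried by mean counts, top counts
  and the Poisson rate ratio, which separate cleanly. At the source study's
  scale (10 builders per cell) f₁/f₂ would be informative.

## Problem sizes

Default runs use 10 participants × 16 rooms × 15 objects (2,400 placements
per phase; 2,400 search trials in the 8-room search preset). Closed-form
and calibration checks use n = 2,400 displacements, 500 calibration
replicates, and 20 recovery seeds at R = 200, n = 5,000 tokens. A full
pipeline run completes in seconds on one CPU.

## Known limitations

- The generator's noise magnitudes are plausible but uncalibrated against
  any real dataset; only effect *directions* and design structure are
  anchored.
- The Poisson contrast conditions on observed pairs (counts ≥ 1);
  structural zeros (possible-but-unseen pairs) are not modelled.
- ZM parameter pairs (α, β) are weakly identified on flat tails: large-β,
  large-α fits can describe near-uniform count distributions. Interpret the
  two parameters jointly, not separately.
- The CLI loads whole datasets into memory; it targets desk-scale data.
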