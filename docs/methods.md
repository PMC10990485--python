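# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the limitations of `rotgen`.

## Task geometry

The manifold is a 4×4 grid with 0-based coordinates (i, j); i is the
first/horizontal dimension, j the second/vertical; north is +j, east is
+i, and rotations are counterclockwise (↶ = 90° CCW), which reproduces
the compass identity {NE, W, SE} → {NW, S, NE} under a quarter turn.
Each category template walks four distinct cells that tile one unit
square. A quadruplet's translation is parameterised by its *anchor*, the
lower-left corner of the occupied square; there are nine anchors (the 3×3
unit squares that fit in the grid), drawn uniformly per trial. Given
category, rotation and anchor, the start stimulus is the unique cell of
the square from which the rotated walk stays inside it. The description
of the start location as one of "nine possible positions" is ambiguous on
a 4×4 grid (it has four inner cells, not nine); the anchor reading is
the reconstruction used here because it yields exactly nine equiprobable
translations and keeps every rotation in-grid.

Far transfer replays the same geometry on a second manifold (★i, ★j);
physical feature identities (frequencies, colours, screen positions) are
metadata and never enter the computation.

## Schedules

`build_schedule` reproduces the published schedule tables row for row:
Exp. 1 is a single 330-trial session (120 canonical training trials, then
105 training + 105 transfer trials interleaved); Exp. 2–4 run 396 trials
on day 1 and 600 on day 2, mixing categorisation, 48-trial mapping blocks
and (Exp. 4) a filler task. Within every 30-trial categorisation block
each category appears exactly 10 times. Where a phase allows two training
rotations (0° and 90°), rotations are assigned per category by round
robin, giving a 5/5 split in pure training blocks; in the final mixed
phases (15 feedback trials per block) an exact per-block split is
impossible, so balance holds per category across the phase (15/15).
Transfer transformations are balanced overall (15 per transformation in
Exp. 1; the exact mix per block follows a rotating assignment), a neutral
choice where the original counts are unstated. Mapping blocks present
each of the 16 cells three times per 48 trials; in dimension-restricted
blocks the fixed dimension is held constant within runs of 12 trials, so
only the requested dimension varies within a run while the block still
covers all 16 cells.

## Ideal observers

1D models are idealised on the training distribution: enumerate every
category × trained-rotation × anchor exemplar (all weighted equally,
matching the balanced blocks), read off the signed or unsigned level
pattern on the tracked dimension, and store the per-pattern category
posterior. Prediction for a trial is a lookup of its pattern;
*ambiguous* patterns yield the graded posterior (e.g. (½, ½, 0) when a
pattern arises from two categories), and patterns absent from training
yield a uniform vector — the observer has no evidence about them. This
unseen-pattern convention matters: under canonical-only training a signed
observer meets unseen (swapped) patterns on 90°/180° probes and responds
uniformly there, but still commits a specific category permutation on
270° probes, which is what distinguishes it from the non-generaliser
`R'`.

The 2D model matches a trial's vector sequence against all 12 rotated
templates (they are pairwise distinct, so the match is unique) and is the
only strategy that assigns rotated exemplars to their canonical category.
In far transfer the 2D model maps dimensions identically (★i→i, ★j→j);
no cross-mapped 2D variant is defined. `R'` responds with the true
category on any feedback-trained trial regardless of history — all models
are static observers, not learners — and uniformly on transfer.

Behavioural accuracy of an observer is computed as argmax responding with
uniform tie-breaking over the enumerated training distribution; together
with the graded prediction vectors this reproduces the designed accuracy
table (random 33%; everything at 100% under canonical-only training;
unsigned models and signed-j at 50%, signed-i and 2D at 100% under the
{0°, 90°} mix).

## Likelihood and fitting

The softmax likelihood uses temperature *division*, exp(p/β): larger β is
noisier, which is what makes β = 0.5 a high-noise regime (a
multiplicative reading would invert that, so the division convention is
used throughout). The grid is
200 linearly spaced values on the inclusive interval [0.01, 0.5]; ties go
to the smallest β so fits are deterministic. `R'`'s temperature acts on
its prediction vectors everywhere (uniform transfer vectors are
unaffected, so the parameter is informed by training trials only — it is
still counted as k = 1 in the BIC). Near-transfer selection fits training
plus near-transfer trials of the testing modality; far-transfer selection
fits training plus far-transfer trials; pre-training trials (a different
modality) are excluded from fitting. The cross-validation split is by
0-based position parity within the fitted trial subset (even half fits,
odd half is held out); the indexing origin is unstated in the original
task description, so it is fixed here for determinism.

The temperature is weakly identified at low β: a deterministic-prediction
agent at β = 0.05 makes essentially no errors in a session, the
likelihood is then monotone toward the grid floor, and β̂ = 0.01. The
Fisher information of β makes this precise, and the parameter-recovery
test bounds the median error by one grid step plus the asymptotic SE
derived from it.

## Group inference

The group method is the standard variational Dirichlet random-effects
scheme with a uniform prior (α₀ = 1): iterate responsibilities
∝ evidence × exp(ψ(αₘ) − ψ(Σα)) and concentration updates α = α₀ + Σg
until the relative free-energy change is below 1e−8 (cap 10 000
iterations; the free energy is non-decreasing by construction and this is
asserted in tests). The implementation follows the standard published
form of variational random-effects model selection and is validated
against brute-force Monte-Carlo Dirichlet integration (within one
log-unit on small problems). Evidence arithmetic is in the log domain
throughout.

Family inference averages member evidences (uniform within-family prior).
For family-restricted comparisons (1D-family vs 2D; random vs informed)
participants whose BIC-best model falls outside the partition are dropped
before collapsing, mirroring the reporting of strategy fractions "among
non-random participants"; the original analysis pipeline is not explicit
on this point. The between-group construction is pooled-vs-split free
energies; p(H0|C) = 1/(1+BF) under a uniform hypothesis prior. Jeffreys
labels use strict thresholds (>3/>10/>100 for a difference, <0.3/<0.1/
<0.01 against one). Protected exceedance probabilities are available as a
diagnostic but are not part of the headline statistics.

## Synthetic data

Agents emulate the study conditions directly: each simulated participant
receives its own pseudo-randomised schedule of the chosen experiment and
samples every categorisation choice from the softmax of its generating
model's prediction at its temperature. The recovery experiment defaults
to 100 agents per model at temperatures {0.05, 0.2, 0.35, 0.5}, the
published setting; tests run a scaled-down version (10 agents per model
at β ∈ {0.05, 0.5} on the Exp-1a schedule) to stay within an ordinary
test-suite budget, and the CLI exposes the full run. Mapping agents are
analytic anchors rather than cognitive models: chance responding is
1/16, attending a single dimension yields 25%, a perfect mapper 100%.
The generator does not emulate learning curves, drop-out between days,
response times, perceptual confusability of physical stimuli, or any
trial-order effects — so passing tests certify the inference machinery
under the design's idealised conditions, not the behaviour of human
cohorts. Cohort-level tests use the smallest sizes at which the checked
property is stable (e.g. 12 agents per cohort for decisive between-group
BFs, 41 agents per temperature for a stable median in parameter
recovery); these are the package's own problem-size choices.

All randomness derives from integer master seeds via `SeedSequence`
spawning; identical (config, seed) pairs produce byte-identical outputs,
and the pipeline writes JSON with sorted keys to keep that guarantee at
the file level.

## Known limitations

* The published per-cohort results (model-frequency fractions, the BF
  tables, the r ≈ 0.8 correlation with training accuracy) depend on the
  deposited participant data and are not reproduced here; the package
  supports loading such choice tables but ships only synthetic agents.
* The 1D-observer convention for unseen patterns (uniform) is a modelling
  choice; alternatives (e.g. nearest-pattern generalisation) would change
  predictions only on probe types never seen in training.
* β̂ is censored at the grid edges by design (matching the original grid
  fit); temperatures outside [0.01, 0.5] are not recoverable.
* The variational free energy is a lower bound; its error is validated at
  small scale against Monte-Carlo integration but grows unchecked for
  very large rosters/cohorts.
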