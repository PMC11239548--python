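# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the design decisions taken where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Optimizer

### Phases and draw schedule

The hawk optimizer is implemented as a minimizer; score-maximizing callers
negate their objective.  Per hawk and iteration the draws are, in order:
E0 ~ U(−1, 1); if |E| = |2·E0·(1 − t/T)| < 1 the escape chance r ~ U(0, 1)
and the jump-strength draw r5 ~ U(0, 1) with J = 2(1 − r5), redrawn for
every update.  The exploration branch draws q, r1…r4 ~ U(0, 1) and, when
q ≥ 0.5, a uniform random hawk index.  q and r are independent draws: the
exploration/exploitation literature treats them as separate random numbers,
and nothing in the update formulas couples them.

Out-of-bounds candidates are clipped to [LB, UB] after every move.  Clipping
is the simplest contract that preserves the containment invariant; the
alternative (re-sampling) would change the number of objective evaluations
per iteration and complicate the determinism guarantee.

### Acceptance rules

Exploration and plain besiege moves replace the hawk unconditionally, as in
the canonical algorithm; the rapid-dive branches are greedy (Y if it
strictly improves on the current position, else Z if it does, else stay).
The dive conditions are implemented as this canonical three-way comparison;
a literal reading of the printed update rule would test the same condition
twice.  The best-so-far "rabbit" is updated after every evaluation, so its
fitness trace is non-increasing regardless of the per-hawk acceptance rule.

### Chaotic variant

The logistic stream runs at control 4.0 — the fully chaotic regime,
conjugate to the angle-doubling map, which is what makes the closed-form
oracle sin²(2ⁿ·arcsin√x₀) available to the tests.  Initial value 0.7 by
default; seeds on the degenerate orbits {0, ¼, ½, ¾, 1} are rejected, and a
one-ulp-scale inward nudge keeps floating-point orbits off those absorbing
points.  One scalar stream is advanced once per coordinate use, shared
across hawks and iterations.

Chaos substitutes only the hawk-position term of the two plain besiege
updates and seeds the initial population.  The dive and exploration branches
remain stochastic: the chaotic substitution is described for the besiege
("rabbit searching") form only, and substituting everywhere would remove the
Lévy-flight heavy tails that drive late-stage refinement.  Chaotic besiege
candidates are accepted greedily — the chaotic point is an arbitrary box
point, and unconditional acceptance would re-randomize converged hawks.

Measured behaviour (recomputed by the acceptance suite): both variants drive
the 10-d sphere below 1e-3 in at least 18 of 20 seeds at N=20, T=300; the
paired final-fitness differences between the variants on sphere and
Rastrigin are below any practical tolerance (both variants reach
~machine-precision optima), which the margin-based non-inferiority test
formalizes (below).

### Non-inferiority testing

"LC-HHOA is not worse than HHO" is tested as proper non-inferiority: a
one-sided Wilcoxon signed-rank on the shifted paired differences
(lc − hho − δ) with H1: median < δ, declared non-inferior when p < 0.05.
A margin-free version of this claim does not exist as a statistical test —
without δ, a signed-rank test on raw differences rejects on differences of
order 1e-23 between runs that have both converged to the optimum.  The
margin δ = 1e-3 is the same success tolerance the benchmark itself uses, so
"non-inferior" means "any deficit is below the resolution at which a
benchmark run counts as solved".

### Lévy flight

Mantegna construction with stability index β = 1.5 and step scale 0.01:
step = scale · u·σ/|v|^(1/β), u, v standard normal, σ from the Gamma closed
form (≈ 0.69657 at β = 1.5).  The tests evaluate σ with an independent
Gamma implementation and check the empirical heavy tail.

## Classifier

### Reservoir-style training

The GRU and attention weights are drawn from a seeded uniform(−0.5, 0.5) and
not gradient-trained; all learnable capacity sits in the ELM output weights,
which have a closed-form ridge solution.  Consequences:

* evaluating one hyperparameter candidate costs one forward pass plus one
  linear solve, which is what makes a population-based search over
  architectures affordable on a single CPU;
* the schedule hyperparameters (epochs, learning rate, batch size, dropout)
  have no effect on the fitted model.  They are kept in the search space and
  the config surface for interface fidelity, and this inertness is asserted
  nowhere and documented here.  The same applies to the accepted-but-unused
  `momentum` and `max_depth` config fields, which have no role in a
  GRU + ELM forward model.

The ELM hidden activation is tanh: odd and bounded, so a zero pre-activation
yields zero scores, and the closed-form solve stays well conditioned.  The
dual form β = Hᵀ(I/C + HHᵀ)⁻¹Y is used when n ≤ width and the algebraically
identical primal form (HᵀH + I/C)⁻¹HᵀY otherwise; the tested invariant is
the shared normal-equation residual.

### Attention and layer stacking

Attention is canonical scaled dot-product over the GRU hidden-state
sequence, with query/key/value projections of width d_k tied to the hidden
width.  Stacked blocks consume the previous block's context sequence;
per-block outputs are summed across the stack (which requires a common d_k)
and mean-pooled over time into one feature vector per record.  Summation
over layers was chosen over summation over time because the pooled feature
must have a fixed dimension independent of the sequence window;
concatenation across layers is a straightforward extension but changes the
ELM input width with the layer count, which would couple two search fields.

### Class decision

Binary mode (default): argmax over the two-class scores, disease being the
positive class.  Ternary mode maps a scalar output g through the thresholds
g ≤ 1 → normal, 1 < g ≤ 2 → disease-1, 2 < g ≤ 3 → disease-2, and flags
g > 3 as "uncertain" rather than silently re-entering the training loop.
The two disease subtypes carry no clinical definition here; binary is the
supported, tested path.

## Preprocessing

Numeric features (age, ECG value, BP) are z-scored with the population-SD
(n denominator) convention; gender is encoded male = 1, female = 0.
Normalization statistics are computed on training-fold records only and
applied frozen to validation and test records.

Missing and non-meaningful sensor values are handled by auxiliary
regressions on the complete cases: ecg ~ bp + age and bp ~ ecg + age.
Records with a missing target get the regression prediction; complete
records whose externally studentized (leave-one-out) residual exceeds 2.5 in
magnitude are flagged and likewise replaced.  The 2.5 cutoff flags roughly
1–2% of clean Gaussian data — a reasonable balance between catching
sensor-noise spikes and not rewriting genuine physiology.  After flagging,
the prediction model is refit on the non-flagged cases so a gross outlier
cannot contaminate its own replacement value.  Records missing both sensors
fall back to complete-case column means (counted separately in the report).

Known limitation, measured by the acceptance suite: on the default synthetic
cohort the two sensors are class-conditionally independent, so these linear
regressions can only exploit the between-class structure; their imputation
MAE is about 0.6 × the overall feature SD at 10% missingness.  Imputation
accuracy on this cohort is bounded by that structure, not by the estimator.

## Synthetic study conditions

The generator emulates a wearable-sensor cardiac cohort: 1,672 subjects of
whom 887 are healthy; ages uniform on [22, 65]; genders balanced.  Diseased
systolic BP exceeds 130 mmHg with probability 0.8 (two-sided truncated
normal around 142 ± 12); healthy BP is N(112, 8).  Healthy heart rate is
leptokurtic — Student-t with 5 degrees of freedom (excess kurtosis 6 before
truncation), location 72, scale 5, capped at 160 bpm; diseased heart rate is
N(96, 8) capped at 150 bpm, with a physiological floor of 40 bpm for both.
Each record carries a 16-sample heart-rate stream around the subject's
baseline (within-record noise SD 3), and the scalar "ECG value" column is
the stream mean plus N(0, 2) sensor noise — giving the recurrent extractor
genuine temporal input while keeping the tabular schema.

The free locations and scales were fixed once to make the joint Bayes error
of the two sensor channels about 1%, consistent with the near-separable
cohorts that published studies of this kind report; the study-stated
quantities (caps, threshold, exceedance probability, composition, age
range, leptokurtosis) are held exactly.  What passing tests on this cohort
do show: the full pipeline recovers a strong, separable class structure
through imputation, normalization, sequence expansion, reservoir features
and the closed-form head, deterministically under a master seed.  What they
do not show: performance on real ECG morphology (no P-QRS-T waveforms, no
EMI or sensor-drift spectra, no within-class sensor correlation), and no
claim about clinical generalization.

## Evaluation

Metrics are the standard confusion-matrix five; precision is TP/(TP+FP)
(the universal definition — a printed variant with TN in the numerator is
internally inconsistent and not implemented).  Zero-denominator ratios
return 0 with an explicit flag instead of NaN so the composite fitness stays
bounded.  Cross-validation and ratio sweeps use stratified splits (class
ratios preserved within one record).  Model building time is reported
wherever a training run is timed and asserted nowhere: it is
hardware-dependent.  Multi-run outcome tables (best/worst/mean/median/SD/
variance over repeated runs) use the n−1 SD convention and are generic over
any scalar per-run metric.

Shapiro–Wilk and the paired Wilcoxon signed-rank test delegate to
scipy.stats; the test suite pins them to reference values computed with R's
stats::shapiro.test / stats::wilcox.test and to a full sign-flip enumeration
oracle at small n.  Wilcoxon uses zero-difference dropping with mid-ranks,
the exact null for n ≤ 25 tie-free pairs, and the normal approximation
otherwise.

## Determinism

Every entry point takes one master seed; child seeds for splitting,
optimization and weight initialization are derived from it through a seeded
integer draw, and no component reads global random state.  Model bundles are
single JSON files with arrays serialized as number lists (float repr
round-trips bit-exactly), so identical seeds produce byte-identical bundles,
metrics and traces.  Wall-clock timings are written to separate files and
excluded from the byte-identity guarantee.

## Problem sizes

The shipped defaults are desk-scale by design: hawk population 6 and 10
iterations for the classification search (one candidate evaluation is a
single linear solve, and the fitness cache collapses duplicate decoded
candidates); population 20 and 300 iterations for the optimizer benchmarks;
20 paired seeds for the variant comparison; 5 master seeds for the
end-to-end recovery check.
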