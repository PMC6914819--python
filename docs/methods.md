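# Methods

`metabotraj` implements the statistical analysis of a longitudinal GC-MS
metabolomics study of the mouse spinal cord in the SOD1^G93A model of ALS:
a 2 × 2 × 3 factorial design crossing genetic background (C57, 129S, slow-
vs fast-progressing), SOD1 genotype (non-transgenic NTG vs mutant G93A)
and disease stage (presymptomatic PRE, onset ONS, late LATE), with n = 5
mice per cell, measured per spinal-cord segment (lumbar, thoracic) in one
analytical batch each, with repeat-injected pooled QC samples.

## QC drift normalization

GC-MS response drifts smoothly over a run. Because every pooled QC
injection is chemically identical, per (batch, metabolite) the QC trend
over injection order estimates the drift. We fit a cubic smoothing spline
to QC log10 intensity versus injection order and correct every sample
multiplicatively:

    corrected(s, m) = raw(s, m) · reference_level(batch, m) / fit(order(s))

with `reference_level` the batch-wise median of the QC fitted values.
Choices, all configurable:

- **Scale.** The spline is fitted on log10 intensities and applied as a
  ratio on the raw scale. Drift is multiplicative (source/detector gain),
  and the ratio form preserves positivity exactly.
- **Smoothing parameter.** Leave-one-out cross-validation over a fixed
  log-spaced penalty grid (1e-3 … 1e7) spanning near-interpolating to
  near-linear fits; ties break toward the smoother fit so that drift-free
  series are not over-fitted. A fixed penalty can be passed instead
  (`smoothing=<float>`, CLI `--smoothing fixed:<λ>`).
- **Extrapolation.** Outside the QC-covered order range the fit is held
  constant at its terminal value; splines extrapolate polynomially and
  would blow up at the run ends.
- **Sparse QC fallbacks.** The penalized cubic spline needs five points,
  so with fewer than six usable QC points a least-squares line on the log
  scale replaces it; below `min_qc` (default 4) the drift is a constant at
  the QC median and a warning is raised.
- **Batch independence.** The two segments were run as separate batches
  and are normalized fully independently; no between-batch harmonization
  is attempted because all downstream analysis is per segment.

The correction is equivariant to rescaling a metabolite by a positive
constant, and never changes labels, ordering or missingness.

## Preprocessing

Metabolite abundances are approximately log-normal, so the analysis scale
is log10. Zeros (empty integrated peaks) are rejected by default; the
explicit alternative substitutes half the metabolite's smallest positive
value. Each metabolite is then mean-centered and scaled to unit variance
(UV scaling, ddof = 1) over study samples only — QCs are instrument
controls, not biology, and are dropped after normalization. Shapiro–Wilk
W before and after the log transform documents the improvement in
per-metabolite normality (most common normality measure at n ≤ 60;
metabolites with under three values or zero range are reported missing).

## PCA and stage trajectories

PCA is fitted per segment on the scaled study matrix by SVD. Component
signs are fixed by making each loading vector's largest-magnitude element
positive, so repeated runs are bit-identical. Explained fractions are
singular values squared over total variance.

Each PC's score vector is decomposed against the factorial model (same
engine as the per-metabolite ANOVA, below) giving a per-PC, per-term
percent-of-variance table. This table guides which PCs to plot: a
component dominated by the residual carries no design signal. PC
selection for trajectories is analyst-driven configuration
(`pcs_for_trajectories`; defaults PC2/PC3 lumbar, PC2/PC4 thoracic) —
no automatic threshold is imposed, because the choice is a judgment about
which design-driven components to display.

A trajectory is the path of a (background, genotype) group's mean scores
across PRE → ONS → LATE, with s.e.m. = s.d./√n per cell. **Alignment**
translates each group so its PRE mean sits exactly at the origin,
isolating the direction and magnitude of the disease-stage response from
baseline differences. It is a per-group translation: segment vectors,
lengths and s.e.m. are untouched, and it is idempotent. No rescaling is
applied, so path-length ratios remain interpretable as a scalar
enlargement diagnostic. Geometry summaries report stage-to-stage segment
vectors, Euclidean lengths, total path length, between-group angles of
corresponding segments (arccos of the normalized dot product, computed in
the selected-PC subspace via the numerically stable atan2 form) and
path-length ratios. A zero-length segment yields a missing angle. The
geometry comparison is descriptive; no test on trajectory shape is
performed.

## Factorial variance decomposition

Every feature y (metabolite log10 level or PC score — one shared code
path) is modeled as

    y ~ genotype * background * stage

with sum-to-zero coding: seven terms (three mains, three two-way, one
three-way interaction) plus residual. For the balanced design the term
subspaces are mutually orthogonal, so each term's ANOVA sum of squares is
the squared projection of the centered response onto that subspace, the
decomposition is unique, and

    R²_term = SS_term / SS_total × 100,

with all terms plus residual summing to exactly 100%. F statistics use
the residual mean square (df = N − 12). Unbalanced data (a lost sample)
fall back to Type-II sums of squares via statsmodels with a warning; Type
II terms no longer partition the total exactly, which the warning states.
A zero-variance feature reports all terms 0 with residual 100% rather
than erroring. Stage is an unordered factor — no trend contrasts — and
each stage uses distinct mice, so no repeated-measures structure exists.

## FDR and the two-tier t-test scheme

Benjamini–Hochberg step-up adjustment is applied within families defined
as: one model term across metabolites (ANOVA tables), or one contrast
definition across metabolites (t-test tables), per segment. This is the
most conservative family definition consistent with term-wise and
contrast-wise reporting. ANOVA effects are flagged significant at
p_FDR ≤ 0.05.

Two-group comparisons use the classical pooled-variance Student's t-test
(Welch available by flag). The default scheme tests NTG vs G93A within
each background × stage cell (6 contrasts); arbitrary pooled splits
(e.g. all C57 vs all 129S) are configured as selector pairs. Flags:
`sig_fdr20` for p ≤ 0.05 and FDR < 20% (significant), `sig_fdr5` for
p ≤ 0.05 and FDR < 5% (highlighted). Groups with n < 2 are flagged
untestable, not dropped.

## Synthetic-study generator

The generator emulates the study design so that every stage is testable
with known ground truth: per batch, a randomized injection order of the
60 study samples with a pooled QC first, last and after every
`qc_every` = 5 study injections; log10 intensities

    10^(baseline_m + Σ_t effect_t(cell) + drift_batch(order) + ε),
    ε ~ N(0, noise_sd²)

with per-metabolite baselines drawn N(4, 0.5²) (arbitrary units) and
residual noise `noise_sd` = 0.1 log10 units (~26% CV, a typical combined
biological + technical spread for tissue GC-MS). QC samples are noisy
copies of the pooled grand mean subjected to the same drift. Effects are
injected on the log10 scale along fixed sign patterns (first level
negative; stage pattern −1, 0, +1), so a term with effect size e
contributes a between-cell variance of e²/4 (two-level-factor terms) or
e²/6 (terms involving stage) and every per-term variance fraction has a
closed form — the basis of all recovery tests. Drift families are linear,
cubic (Chebyshev T3) and sinusoidal (1.5 cycles), amplitude = max |log10
fold change|; defaults 0.05 per batch, representative of routine runs.
`default_study_effects` echoes the study's findings qualitatively:
~15% of metabolites carry background effects, ~10% stage, ~5%
genotype × stage, the rest null.

What the generator does **not** emulate: correlated metabolite panels
(features are independent given the design), missing-not-at-random
dropout (only uniform dropout is available), heavy-tailed or
heteroscedastic noise, retention-time or spectral artifacts, and
between-batch biological differences (both segments reuse one effect
specification). Passing tests therefore demonstrate correctness of the
statistical machinery under the design's sampling noise, not robustness
to every pathology of real chromatography.

## Numerical and reproducibility choices

- Missing values are a NaN mask carried through every stage; readers
  reject malformed cells rather than coercing, and nothing imputes
  silently.
- Factor level order is fixed (C57 < 129S, NTG < G93A, PRE < ONS < LATE),
  fixing contrast signs and output ordering.
- All randomness descends from one seed; the pipeline fans out
  counter-based child seeds (`SeedSequence([seed, k])`, kept below 2³¹)
  so stages can be rerun independently. Tables are written at 12
  significant digits; two runs of one config + seed are byte-identical.
- Angles use atan2 of (cross-norm, dot) rather than arccos of a clipped
  cosine: exact 0°/180° for parallel/antiparallel segments instead of
  ~1e-6° floating-point residue.

## Test problem sizes

The suite validates the engines against brute-force oracles (group-mean
ANOVA on 200 random balanced designs, step-up BH on 10⁴ random p-vectors,
covariance-eigendecomposition PCA on 50 matrices), calibration under the
null (2000 replicate null studies at n = 5; 500 replicate studies of 100
metabolites with 5% true signals for the empirical FDR of the per-term
flag), ground-truth recovery (n = 200/cell for consistency within 2
percentage points per term; 1000 replicate features at n = 5 against the
finite-sample expectation E[SS_t]/E[SS_total], which at small n is
df-inflated above the population fraction), drift correction (amplitude
0.1 log10 units with 0.01 technical QC noise, the regime the QC-RSD
diagnostic addresses; drift-free runs at 0.05 noise bound the correction
perturbation below a median |log10 ratio| of 0.02), and trajectory
geometry (a 2-residual-s.d. genotype × stage response on a third of the
metabolome; the two carrier groups' aligned onset segments are nearly
parallel, asserted on the median angle over replicate studies because a
single n = 5 draw is noisy). These sizes keep the whole suite around a
minute on one CPU while leaving Monte-Carlo error well inside each
tolerance.

## Known limitations

- Type-II fallback percentages for unbalanced data do not sum to 100%.
- The LOO-CV spline selection refits per left-out point; it is exact but
  O(grid × n_QC) spline fits per metabolite-batch. For very wide panels
  pass a fixed penalty.
- No glog/Pareto scaling alternatives, no supervised projections
  (PLS-DA), no pathway enrichment, and no mixed-effects models — the
  design is cross-sectional by construction.
- The per-metabolite models analyze log10 values; analyzing normalized
  (raw-scale) values is possible by passing that matrix but is not the
  default, consistent with the normality reporting.
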