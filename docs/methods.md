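# Methods

## Model

`mscolor` models multi-stage disease progression from longitudinal imaging
quantitative traits (QTs) and genotypes, borrowing power from external GWAS
summary statistics.

A study is an ordered list of **stages**: contiguous windows of visits, each
modeled with its own intercept/slope pair so a multi-phase trajectory can
deviate from a single monotone line.  Stage `s` holds standardized dosages
`X_s` (`n_s × d`), QT slices `Z_ks` (`n_s × c`) at stage-local visit times
`t_ks` (months, first visit at 0), and subjects may appear in several stages
(tracked through a registry of subject ids).

The fitted trajectory for stage `s` at time `t` is

```
Z ≈ γ (X_s W_s + X_s V_s t) + (1 − γ) (A + B t)
```

* `W_s`, `V_s` (`d × c`) — genetic effects on the stage's baseline level and
  rate of change;
* `A`, `B` (`N × c`) — per-subject population aging intercepts and slopes,
  shared across the stages a subject appears in (a per-stage variant
  `A_s`, `B_s` is available via `share_aging=False`);
* `γ ∈ [0, 1]` — balance between the genetic and population components.

### Collaborative GWAS term

A large GWAS cohort reports marginal effects `β_g = x_g'y/(n−1)` on
standardized data; the multivariate (joint) effects solve `Σ u = β` with `Σ`
the SNP correlation (LD) matrix, estimated from a reference panel when
individual-level genotypes are unavailable.  Because `y'y` is not available
from summary data, the GWAS data-fit term `‖y − X u_s‖²` is evaluated up to
that additive constant as `(n_ref − 1)(u_s'Σu_s − 2u_s'β)` plus a small ridge
`ridge·u_s'u_s` that keeps the system invertible when the panel is smaller
than the SNP set.

The per-stage joint-effect vectors `u_s` are coupled to the longitudinal
coefficients through row-structured penalties on the stacked matrices
`P_s = [u_s W_s]` and `Q_s = [u_s V_s]`:

```
min  Σ_s Σ_k ‖Z_ks − fit‖²_F  +  τ (n_ref−1)(u_s'Σu_s − 2u_s'β)
     + Σ_s λ_P ‖P_s‖_{∞,1} + λ_Q ‖Q_s‖_{∞,1}
```

`‖·‖_{∞,1}` sums each row's maximum absolute entry, so a SNP is selected
jointly across all QTs, both time coefficients, *and* the external GWAS: a
small imaging cohort inherits the ranking power of a cohort orders of
magnitude larger.  Setting `τ = 0` (or passing no summary) removes the
collaborative term.

### Comparison methods

* **sMTR** — one coefficient matrix per pooled time point with an `ℓ2,1`
  penalty across tasks; ranks SNPs but has no trajectory model.
* **sMML** — one-stage mixed-effects model `Z_k = A + XW + (B + XV)t_k` on
  the pooled follow-up (stages laid end to end), `ℓ2,1` penalties.
* **MSMML** — the multi-stage model with per-stage aging effects and the
  `ℓ∞,1` penalty but no GWAS term; isolates the collaborative contribution.

## Optimization

All blocks have closed-form minimizers given the others.  The nonsmooth row
norms are handled by iteratively reweighted least squares: each row `i`
contributes a diagonal weight `1/(2·max(ρ_i, δ))` with `ρ_i` the current row
max (or row 2-norm for `ℓ2,1`) and smoothing floor `δ = 1e−8`.  One iteration
updates `A`, `B`, then per stage `u_s`, `W_s`, `V_s`, refreshing the weights
before every solve.  Systems are solved by Cholesky factorization; the `u_s`
system is `Σ + diag((λ_P d_P + λ_Q d_Q)/τ(n_ref−1)) + ridge·I`.

The logged **surrogate objective** replaces each penalty row by its
frozen-weight quadratic completion `‖p‖²/(2μ) + μ/2` with `μ = max(ρ, δ)`,
the quantity that the closed-form updates minimize exactly blockwise.  It is
a fixed, self-consistent function of the parameters, which is what the oracle
test compares against a general-purpose minimizer.

Numerical choices worth knowing:

* **Warm start** (`init_scheme="warm"`, default): reweighting a zero iterate
  pins every row at the smoothing floor (weights `1/(2δ) = 5·10⁷`), which can
  freeze the fit near zero.  One identity-weight ridge sweep before the
  reweighted loop gives the weights a meaningful scale.  `"zeros"` and
  `"random"` initializations are retained for study.
* **Stall stop**: the weight refresh is not an exact majorizer of the
  surrogate for the `ℓ∞,1` penalty, so near row-max ties the objective can
  bounce by a few parts in 10⁵.  Any non-decrease triggers a revert to the
  previous (no worse) iterate and a stop; the logged trace is therefore
  non-increasing by construction, and only a non-finite objective raises.
* **Convergence**: otherwise the loop stops when no coefficient moves more
  than `tol` (default `1e−5`) in one sweep, up to `max_iter` sweeps.
* Subjects observed at a single time point keep their slope row fixed (with a
  warning); `λ = 0` requires full-column-rank genotypes (`d < n_s`).

### Identifiability

With a free intercept/slope pair per subject, any genetic contribution that
is constant within a subject's visit span can be absorbed into `A`, `B`: the
genetic blocks are only identified through what the aging blocks cannot
express.  Consequences worth knowing when interpreting fits:

* In **MSMML** (per-stage aging, no GWAS) the per-stage aging blocks span the
  entire genetic signal, and the fitted `W_s`, `V_s` shrink to zero at any
  meaningful penalty; held-out subjects receive the per-stage population
  lines.
* In **sMML** the pooled model has a single global line per subject, so
  held-out subjects receive one global population line.
* In **MSColoR** the aging pair is shared across stages, so *stage
  deviations* of the genetic slopes (`V_s` around their subject-mean) remain
  identified, and the GWAS coupling keeps SNP-level signal in `u_s`.  This is
  exactly why the collaborative model can rank causal SNPs and predict
  held-out stage trajectories better than the controls, and why its
  recovered `V_s` norms track the generating stage-slope profile in shape
  (largest where progression is fastest) rather than in absolute scale.

## Prediction and evaluation

For fitted (training) subjects, prediction uses their fitted `A`, `B` rows.
For held-out subjects, prediction uses the population means of the fit's own
aging blocks plus the genetic part from the subject's genotypes.  Evaluation
is subject-level nested cross-validation: inner folds select the penalty
weight on a decade grid (ties break toward the sparser model), outer folds
score per-stage trajectory RMSE; QT and genotype standardization is refit on
each fold's training subjects only.

SNP selection scores each SNP by the row-max absolute coefficient over the
stacked intercept and slope blocks (including `u_s`), the max over stages and
blocks, averaged across fold fits; ranking quality against a known support is
summarized by rank-based ROC AUC and precision@k.  The statistics harness
provides Welch t-tests between fitted slope distributions (stage pairs or
diagnosis groups) with conventional star banding, Pearson correlations of
per-subject trajectory summaries with cognitive scores, and a
covariate-adjusted one-way ANOVA of a SNP dosage factor.

## Synthetic studies

The generator emulates a staged neurodegeneration cohort: per-SNP minor
allele frequencies uniform in `maf_range`, binomial dosages (optional AR(1)
LD), row-sparse genetic effects on a random causal support, stage-invariant
intercept effects and slope effects scaled by a three-phase profile (default
`[1.0, 1.8, 0.7]`: subtle early change, rapid middle stage, slower late
stage).  Per-subject aging slopes decline on average
(`aging_slope_mean = −0.05`/month): a nonzero population trend makes the
stage-local trajectory non-monotone on the global clock, which is the regime
multi-stage models exist for — a pooled one-stage model is structurally
biased there, while each stage window remains exactly linear.  An independent
GWAS cohort is phenotyped on the composite intercept effect
(`u* = mean of W* across QTs`) at heritability `gwas_h2`, and a separate
reference panel provides the LD estimate.  Cognitive covariates
(MMSE/ADAS/RAVLT, diagnosis grade) are correlated with each subject's true
aging slope so the statistical procedures have realistic inputs.

## Limitations

* SNP LD in the generator is none or AR(1); no haplotype structure.
* The GWAS phenotype shares only the *intercept* composite with the cohort;
  slope-specific GWAS signal is not simulated.
* `ℓ∞,1` reweighting is not a strict descent method; the stall-stop returns
  the best visited iterate rather than certifying stationarity to machine
  precision.
* Absolute scales of `W_s` are weakly identified (see Identifiability);
  interpret support and rankings, not coefficient magnitudes.
* Missing genotype calls and missing visits must be resolved upstream; the
  data model requires complete stage blocks.
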