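# Methods

This note documents the statistical models implemented in `nrseqkit`, the
choices made where the design was genuinely open, and what the simulation
suite does and does not establish.

## The data

Nucleotide-recoding RNA-seq (NR-seq: TimeLapse-seq, SLAM-seq, TUC-seq, ...)
feeds cells a metabolic label — 4-thiouridine (s4U) and/or 6-thioguanosine
(s6G) — and applies a chemistry that recodes the incorporated label so it
reads out as a point mutation (T-to-C for s4U, G-to-A for s6G).  A read from
RNA synthesized during the label pulse therefore carries binomially many
mutations at the labeled-read rate `p_labeled`, while a read from
pre-existing RNA carries background mutations at `p_unlabeled`
(sequencing/alignment error, SNPs).

All modeling starts from the counts-Binomial (cB) table: one row per unique
combination of sample, feature assignment(s), per-mutation-type mutable
nucleotide count `nN` and mutation count `nM`, with a multiplicity column
`n`.  This is a lossless compression of the per-read mutation data; row
order never matters and aggregating duplicate keys is the canonical form.

## Mixture model

For a read r in feature f, conditional on its population p (labeled with
one label, another, or unlabeled),

    nM[t] | p  ~  Binomial(nN[t], rate[p, t])   independently over types t,

where `rate[p, t]` is `p_labeled[t]` or `p_unlabeled[t]` according to the
population design.  A design is a P x T table; the all-unlabeled population
is always present, and designs may omit structurally impossible populations
(TILAC mixes s4U-fed with s6G-fed cells, so the doubly-labeled population
does not exist).

Estimation is two-step:

1. **Sample-wide rates.**  For each sample and mutation type independently,
   a two-component binomial mixture is fit by EM to all reads pooled across
   features (initialized at `p_labeled = 0.05`, `p_unlabeled = 0.002`,
   mixing 0.5; the component with the larger rate is "labeled").  When
   unlabeled control samples exist, `p_unlabeled` is instead the pooled
   single-binomial MLE over control reads and is held fixed — strongly
   recommended whenever long label times leave few unlabeled reads, or when
   incorporation rates vary between features (both situations degrade the
   pooled EM's background-rate estimate; see *Limitations*).
2. **Per-feature fractions.**  The population proportions theta (the
   "fraction labeled" vector) maximize the mixture log-likelihood plus a
   weakly informative normal prior, N(0, 1.5), on each free coordinate of
   the multinomial-logit parameterization (flat prior available).  Standard
   errors come from the observed information (finite-difference Hessian of
   the penalized objective) on the logit scale; a singular Hessian falls
   back to a conservative sd of 2.0 with a flag.  All probabilities are
   clamped to [1e-12, 1 - 1e-12] inside logarithms.

The prior constant 1.5 was chosen once as weakly informative: it is broad
on the probability scale (95% of the mass between roughly 0.05 and 0.95 for
P = 2) yet keeps zero-mutation features finite.

The naive alternative — calling a read "labeled" when it has at least k
mutations — is provided as `cutoff_estimator` purely as a comparator: its
expectation, theta (1 - F_lab(k-1)) + (1 - theta)(1 - F_unlab(k-1)), is
biased whenever background mutations can reach k or labeled reads can miss
it, and the bias does not vanish with coverage.

## Hierarchical (feature-specific) incorporation rates

Some transcript classes incorporate label at atypical rates —
mitochondrially encoded RNAs are the canonical low-incorporation example —
so one sample-wide `p_labeled` misclassifies their reads.  The hierarchical
variant (two-component designs only) proceeds in three steps:

1. Joint MLE of (theta, p_labeled) per feature, restricted to features with
   more than 300 reads (default), with logit(p_labeled) bounded to [-9, 0]
   and `p_unlabeled` fixed at the sample-wide value.  The 2-D bounded
   quasi-Newton search runs from three starts because the joint likelihood
   has boundary optima.
2. A normal prior on logit(p_labeled) per sample: mean equal to the
   sample-wide logit(p_labeled) (from step 1 of the non-hierarchical fit,
   not the mean of the per-feature estimates), sd equal to the standard
   deviation of the step-1 estimates minus their average standard error
   (excess spread), clamped to [0.01, 0.15].  Estimates at a parameter
   bound (within 1e-6) are excluded as "extreme" first.  With several
   labeled samples the smallest sd is used for all.  The "average
   uncertainty" is the arithmetic mean of standard errors.
3. MAP fit of (theta, p_labeled) for every feature under that prior.
   Low-coverage features shrink to the sample-wide rate; high-coverage
   features keep their own.

With the prior sd driven to zero this reproduces the non-hierarchical
estimates, which is tested.

## Kinetics (one-compartment steady state)

Under first-order turnover at steady state, pre-existing RNA decays as
exp(-kdeg tl), so

    kdeg = -ln(1 - theta) / tl    [1/h],     ksyn = kdeg * R,

with R the normalized read count (median-of-ratios size factors, or
spike-in factors passed through).  Uncertainties propagate by the delta
method from the logit-scale fraction standard error
(se(kdeg) = theta/tl * se(logit theta)).  Saturated fractions
(theta >= 1 - 1e-4) are clamped to a finite capped rate and flagged.

**Dropout normalization.**  Label-dependent loss of labeled RNA during
library preparation ("dropout") biases theta downward.  The implemented
model is deliberately minimal: a labeled read survives with probability
1/(1+d), so observed and true fractions relate by
theta_obs = theta / (1 + d(1 - theta)).  Within each user-defined group the
sample with the highest global labeled fraction is the lowest-dropout
reference; d is fit per sample by weighted least squares of corrected
fractions against the reference, and factors 1/(1+d) are reported.  This is
a one-parameter stand-in for richer published dropout estimators, kept
behind its own interface so a fuller model can replace it; its fidelity to
those estimators has not been assessed here.

## Linear dynamical-systems models

An RNA life-cycle model is a directed graph over species with
rate-constant-labeled edges and degradation edges to a sink, plus a single
synthesis inflow.  With abundance vector u,

    du/dt = K u + s,     u* = -K^{-1} s    (steady state),

and old RNA decays as u_old(t) = expm(K t) u*, so the fraction labeled of
species i is 1 - u_old,i(t)/u*_i; measured populations (e.g. whole cell =
N + C) use abundance-weighted sums.  The matrix exponential uses SciPy's
scaling-and-squaring, which handles repeated eigenvalues (the k_p = k_deg
processing model is tested against the (1 + kt)e^{-kt} limit).  Models must
be Hurwitz (every species has outflow); this is checked at evaluation time.

**Fitting.**  Per feature, a Gaussian likelihood on logit(fraction labeled)
— and, when rigorous normalization is possible, on log normalized read
counts — is maximized over log-parameterized rates by L-BFGS from five
log-uniform starts in [1e-3, 10] /h.  Without counts, fractions are
abundance ratios and the synthesis rate drops out; structural
identifiability is checked up front by the numeric rank of the prediction
Jacobian at a random admissible point, and unidentifiable configurations
are refused.  Standard errors are sqrt(diag(inv(H))) of the
negative-log-likelihood Hessian; a parameter loading on a zero-curvature
direction gets an infinite standard error and a flag — that is what
practical unidentifiability means operationally, and `se > 1` (natural-log
scale, default) flags "low confidence".

Count observations are log read *shares* within a library (samples
sequenced together, e.g. premature and mature RNA of one total-RNA
library, share a depth).  Their standard error is sqrt(1/n + phi) with
phi = 0.1 by default — the gamma-Poisson approximation.  Treating
single-replicate counts as Poisson-precise lets count noise corrupt the
split between outflow rates (e.g. export vs nuclear degradation) and
drives spurious boundary estimates.

Compartment-flow models are fit to condition-level averages (inverse-
variance pooling across replicates), not to single samples: integrating
across independent subcellular fractions is only meaningful at the
condition level.

**Scale factors** map normalized reads to relative molecular abundance
(R * s ~ u*; the global unit constant is absorbed by the per-feature
synthesis rate).  Three strategies:

1. *Spike-ins*: user-supplied factors passed through.
2. *Fractions only*: fitted non-synthesis rates imply steady-state
   abundance ratios (e.g. u*_N/u*_C = kdeg/kexp for nuclear export without
   nuclear degradation), from which factors follow; results are flagged
   lower-confidence.
3. *Mixing model*: the combined pool's global labeled fraction is a convex
   combination of the compartments', f_W = sum_i alpha_i f_i with
   sum alpha_i = 1; two compartments give a closed-form solve (refused when
   |f_N - f_C| < 1e-3), more give constrained least squares.  The weights
   alpha are molecule shares, so scale_i = alpha_i / read-share_i with the
   reference fixed at 1.

## Condition-level linear models and comparisons

Responses (logit fractions or log rate constants) are fit per feature to a
design matrix built from a Wilkinson-style formula over the sample
metadata.  Single-factor and interaction-only (`~a:b`) formulas use
intercept-free cell-means coding, so any pairwise comparison is a contrast
of group means; `~a*b` keeps the intercept and treatment coding so the
interaction coefficient is the difference-of-differences.  Design matrices
come from patsy and rank deficiency is refused with the aliased columns
named.

The first pass is weighted least squares with inverse input-variance
weights.  Residual standard deviations are estimated per variance group —
user-specified factors, or the non-overlapping sample sets of a cell-means
design, else pooled.  Log-variances are then shrunk toward a linear trend
in log coverage with empirical-Bayes weights: the prior degrees of freedom
d0 solve trigamma(d0/2) = excess spread of log s^2 beyond its chi-square
sampling variance (the moderated-variance scheme familiar from
expression analysis), and moderated variances are floored at 0.25x the
trend.  The final pass refits with observation variances
input-se^2 + moderated-group-variance, giving regularized coefficient
covariances.  Contrasts c'beta are tested with moderated-t statistics
(df = residual + prior df) and Benjamini-Hochberg correction across
features; estimates can be reported as log2 fold changes.

## Synthetic data

The simulators emit canonical cB tables plus a ground-truth record (true
fractions, rates, per-read population origins, seed), so every estimator is
tested by parameter recovery:

- `simulate_one_rep`: reads per feature ~ negative binomial (dispersion
  0.1) around the configured mean; mutable nucleotides per read ~
  Poisson(25) per type (zero-nN reads are legal and exercised); population
  per read ~ categorical(theta); mutations binomial at the population rate,
  optionally with feature-specific labeled rates (logit-normal around the
  global).  Default global rates 0.05 / 0.002 — typical s4U incorporation
  and background mutation levels.
- `simulate_multilabel`: the same with a multi-population design; excluded
  populations receive exactly zero reads.
- `simulate_dynamics`: per feature, rates drawn log-uniformly from
  configured ranges; fractions from the analytic solver at each label time;
  expected read counts proportional to steady-state abundance within each
  library; optional replicates.
- `apply_dropout`: thins labeled-origin reads with retention probability
  1/(1+d) using the truth record.

What these simulations do **not** emulate: sequence-level artifacts (SNPs,
alignment error beyond a flat background rate), U-content bias within
reads, transcript-length effects on counts, batch effects, and real
dropout's dependence on labeling chemistry.  Passing recovery tests
demonstrates correctness of the estimators under the stated generative
model, not robustness to all real-data pathologies.

## Validation study sizes

The bundled studies (see `scripts/acceptance.py`) use: 500 features x 500
reads for two-component recovery; 300 features x 200 reads for the
three-population dual-label design; 300 features (mean 1000 reads, plus a
tl = 0 control) for the hierarchical model; 100 random models (<= 5
species) against an RK45 integrator for the solver; 300 features at label
times {1, 4} h for the processing and export designs (3 averaged
replicates for the compartment model); 40 features per nuclear-degradation
ratio in {1, 0.1, 0.01}; and 2000 features, 3 vs 3, for null calibration.
These sizes give stable summary statistics while keeping any single study
in the minutes range on one core.

## Known limitations

- The pooled EM's `p_unlabeled` degenerates when a sample has almost no
  unlabeled reads (long label times, fast turnover) or when labeled rates
  vary across features; use unlabeled controls whenever available.
- Hierarchical modeling is restricted to single-label two-component
  designs.
- The dropout model is a one-parameter simplification (above).
- Deep in the practically unidentifiable regime, inverse-Hessian standard
  errors saturate: medians of se(log kNdeg) distinguish identifiable from
  unidentifiable regimes cleanly, but ordering *within* the saturated
  regime is noisy.
- Pulse-chase designs, time-varying rates, saturable kinetics and Bayesian
  posterior sampling are out of scope.
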