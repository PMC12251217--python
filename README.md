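# nrseqkit

Mixture-model and dynamical-systems analysis of nucleotide-recoding RNA-seq
(NR-seq) data — TimeLapse-seq, SLAM-seq, TUC-seq and their multi-label and
subcellular-fractionation extensions.

NR-seq feeds cells a metabolic label (s4U and/or s6G) whose chemical
recoding shows up as point mutations in sequencing reads (T-to-C, G-to-A).
Reads from RNA made during the label pulse are mutation-rich; pre-existing
RNA yields background-level mutations.  From that signal, `nrseqkit`:

- estimates the **fraction of reads from labeled RNA** (theta) per feature
  with a P-population x T-mutation-type binomial mixture model — including
  dual-label designs such as TILAC, where the doubly-labeled population is
  structurally absent, and a **hierarchical** variant that gives every
  feature its own incorporation rate (rescuing low-incorporation
  transcripts such as mitochondrially encoded RNAs);
- converts fractions into **kinetic rate constants**: the standard
  steady-state synthesis/degradation analysis
  (kdeg = -ln(1 - theta)/tl, ksyn = kdeg * R), and maximum-likelihood fits
  of **arbitrary linear ODE models** of the RNA life cycle (premature ->
  mature processing, nuclear -> cytoplasmic export, nuclear degradation)
  with analytic solutions, inverse-Hessian uncertainties, and three
  compartment normalization strategies (spike-ins, fractions-only,
  fraction-labeled mixing model);
- runs **design-matrix linear models** over conditions with
  empirical-Bayes variance moderation and contrast tests (BH-corrected
  moderated-t), for comparisons like L2FC(kdeg) across perturbations,
  including interaction effects;
- ships **seeded simulators** for every stage (read-level mixtures,
  multi-label designs, dynamics-driven experiments, dropout), emitting
  ground truth alongside every dataset so all estimators are validated by
  parameter recovery.

Input is the compact counts-Binomial ("cB") table produced by NR-seq
preprocessing pipelines — one row per unique (sample, feature, mutation
counts, mutable-nucleotide counts) with a read multiplicity column — plus a
sample metadata table (label times, condition factors).  See
`docs/methods.md` for the models, assumptions, defaults and limitations.

## Worked example

Simulate one TimeLapse-seq-like sample (200 features, ~500 reads each,
2 h label; truth: p_labeled = 0.05, p_unlabeled = 0.002), then run the full
fraction -> kinetics pipeline:

```python
import pandas as pd
from nrseqkit.simulate import SimConfig, simulate_one_rep
from nrseqkit.mixture import estimate_global_rates, estimate_fractions
from nrseqkit.kinetics import estimate_kinetics

cfg = SimConfig(n_features=200, reads_per_feature=500, tl=2.0, seed=42)
cb, truth = simulate_one_rep(cfg)

rates = estimate_global_rates(cb)          # sample-wide mutation rates (EM)
print(rates.table[["p_labeled", "p_unlabeled"]].round(4))

fractions = estimate_fractions(cb, rates)  # per-feature fraction labeled
meta = pd.DataFrame({"sample": ["sample1"], "tl": [2.0]})
kinetics = estimate_kinetics(fractions, meta)
print(kinetics[["feature", "fraction_labeled", "kdeg", "se_log_kdeg"]]
      .head(5).round(4).to_string(index=False))
```

prints

```
                       p_labeled  p_unlabeled
sample  mutation_type
sample1 TC                0.0508       0.0025
   feature  fraction_labeled   kdeg  se_log_kdeg
  feature1            0.7020 0.6054       0.0836
 feature10            0.4537 0.3023       0.0873
feature100            0.8945 1.1244       0.1149
feature101            0.8414 0.9205       0.1074
feature102            0.6397 0.5104       0.0811
```

The EM recovers the simulated mutation rates (0.0508 vs 0.05 labeled,
0.0025 vs 0.002 background).  Each feature then gets its fraction labeled
and the implied degradation rate constant in 1/h with a log-scale standard
error: feature1's theta = 0.702 at a 2 h label means
kdeg = -ln(1 - 0.702)/2 = 0.61/h, a ~1.1 h RNA half-life.  Against the
simulation's ground truth, r(theta_hat, theta) = 0.993 here.

A `nrseqkit` command-line interface wraps the same steps
(`nrseqkit estimate-fractions`, `estimate-kinetics`, `dynamics`, `average`,
`compare`); each subcommand's `--help` lists its options.

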