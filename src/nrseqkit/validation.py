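"""Simulation-based validation studies for every estimation stage.

Each function simulates data with known ground truth under this package's
default study conditions, runs the corresponding estimator, and returns the
summary quantities of the recovery (correlations, biases, error bounds)
together with the problem size.  They are exercised by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.special import logit

from .cb import CBTable
from .dynamics import (
    DynamicsModel,
    Edge,
    average_observations,
    build_observations,
    fit_dynamics,
    mixing_weights,
    nuclear_cytoplasmic,
    premature_mature,
    solve_old_fraction,
    steady_state,
)
from .hierarchy import build_prior, fit_all_features, fit_high_coverage
from .linmodel import (
    LinearModelSpec,
    average_and_regularize,
    compare_parameters,
    estimate_group_sds,
    fit_feature_lm,
    regularize_se,
)
from .mixture import (
    GlobalRates,
    cutoff_estimator,
    estimate_fractions,
    estimate_global_rates,
    tilac,
)
from .simulate import (
    DynamicsSimConfig,
    SimConfig,
    simulate_dynamics,
    simulate_multilabel,
    simulate_one_rep,
)

__all__ = [
    "mixture_recovery",
    "grid_search_theta",
    "small_instance_oracle",
    "tilac_recovery",
    "hierarchical_recovery",
    "random_admissible_model",
    "solver_vs_integrator",
    "dynamics_recovery",
    "identifiability_profile",
    "glm_calibration",
]


# ---------------------------------------------------------------------------
# mixture-model studies
# ---------------------------------------------------------------------------

def mixture_recovery(
    seed: int,
    n_features: int = 500,
    reads_per_feature: int = 500,
) -> dict:
    """Two-component recovery plus the mutation-cutoff comparator bias."""
    cfg = SimConfig(
        n_features=n_features, reads_per_feature=reads_per_feature,
        reads_law="fixed", theta="uniform", seed=seed,
    )
    cb, truth = simulate_one_rep(cfg)
    rates = estimate_global_rates(cb)
    fr = estimate_fractions(cb, rates)
    m = fr.merge(truth.features, on=["sample", "feature"])
    r = float(np.corrcoef(m["fraction_labeled"], m["theta"])[0, 1])
    bias = float((m["fraction_labeled"] - m["theta"]).mean())
    cut = cutoff_estimator(cb, k=1).merge(
        truth.features, on=["sample", "feature"]
    )
    cut_bias = float((cut["fraction_labeled"] - cut["theta"]).mean())
    return {
        "pearson_r": r,
        "mean_bias": bias,
        "cutoff_mean_bias": cut_bias,
        "n": n_features,
    }


def grid_search_theta(
    nM: np.ndarray, nN: np.ndarray, p_labeled: float, p_unlabeled: float,
    step: float = 1e-4,
) -> float:
    """Exhaustive maximizer of the two-component mixture likelihood.

    Independent oracle for the per-feature optimizer: evaluates the
    flat-prior log-likelihood on a theta grid of the given step.
    """
    from .mixture import binom_logpmf

    grid = np.arange(0.0, 1.0 + step / 2, step)
    l1 = binom_logpmf(nM, nN, p_labeled)
    l0 = binom_logpmf(nM, nN, p_unlabeled)
    # rows x grid mixture log-likelihood, summed over reads
    with np.errstate(divide="ignore"):
        ll = np.logaddexp(
            np.log(grid)[None, :] + l1[:, None],
            np.log1p(-grid)[None, :] + l0[:, None],
        ).sum(axis=0)
    return float(grid[np.argmax(ll)])


def small_instance_oracle(seed: int, n_cases: int = 50) -> dict:
    """Optimizer vs exhaustive grid search on tiny (<=5 read) features."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        k = int(rng.integers(1, 6))
        nN = rng.integers(5, 40, size=k)
        p1 = float(rng.uniform(0.03, 0.3))
        p0 = float(rng.uniform(0.0005, 0.01))
        true_theta = float(rng.uniform(0, 1))
        nM = rng.binomial(nN, np.where(rng.random(k) < true_theta, p1, p0))
        rows = pd.DataFrame({
            "sample": "s", "feature": "f",
            "nT": nN, "TC": nM, "n": 1,
        })
        cb = CBTable(rows, ("TC",))
        rates = GlobalRates.from_values(["s"], ["TC"], p1, p0)
        fr = estimate_fractions(cb, rates, prior_sd=None)
        got = float(fr["fraction_labeled"].iloc[0])
        want = grid_search_theta(nM.astype(float), nN.astype(float), p1, p0)
        worst = max(worst, abs(got - want))
    # the printed worked example: reads (5,20),(0,20),(0,20) at rates .25/.001
    cb = CBTable(
        pd.DataFrame({"sample": "s", "feature": "f",
                      "nT": [20, 20, 20], "TC": [5, 0, 0], "n": 1}),
        ("TC",),
    )
    rates = GlobalRates.from_values(["s"], ["TC"], 0.25, 0.001)
    worked = float(
        estimate_fractions(cb, rates, prior_sd=None)["fraction_labeled"].iloc[0]
    )
    return {"max_grid_deviation": worst, "worked_example_theta": worked,
            "n": n_cases}


def tilac_recovery(
    seed: int, n_features: int = 300, reads_per_feature: int = 200
) -> dict:
    """Three-population dual-label recovery; excluded population is empty."""
    design = tilac()
    cfg = SimConfig(
        n_features=n_features, reads_per_feature=reads_per_feature,
        reads_law="fixed", design=design,
        nn_mean={"TC": 25.0, "GA": 25.0},
        p_labeled={"TC": 0.05, "GA": 0.05},
        p_unlabeled={"TC": 0.002, "GA": 0.002},
        seed=seed,
    )
    cb, truth = simulate_multilabel(cfg)
    # reads drawn from the structurally absent doubly-labeled population
    doubly_high = int((truth.reads["population"] >= design.n_populations).sum())
    rates = estimate_global_rates(cb, ("TC", "GA"))
    fr = estimate_fractions(cb, rates, design)
    m = fr.merge(truth.features, on=["sample", "feature"])
    rs = {
        name: float(np.corrcoef(m[f"fraction_{name}"], m[f"theta_{name}"])[0, 1])
        for name in design.names
    }
    return {"min_pearson_r": min(rs.values()), "per_population_r": rs,
            "doubly_high_reads": doubly_high, "n": n_features}


def hierarchical_recovery(
    seed: int,
    n_features: int = 300,
    reads_per_feature: int = 1000,
    p_sd: float = 0.3,
) -> dict:
    """Feature-specific p_labeled recovery under the three-step procedure.

    The simulated experiment includes a tl=0 unlabeled control from which
    p_unlabeled is estimated and held fixed (the recommended configuration
    whenever control samples exist — a pooled-EM p_unlabeled is inflated
    when labeled rates vary between features).
    """
    cfg = SimConfig(
        n_features=n_features, reads_per_feature=reads_per_feature,
        feature_p_sd=p_sd, seed=seed,
    )
    cb, truth = simulate_one_rep(cfg)
    ctrl = SimConfig(
        n_features=n_features, reads_per_feature=200, theta=0.0,
        sample="control", tl=0.0, seed=seed + 1,
    )
    cb_ctrl, _ = simulate_one_rep(ctrl)
    merged = CBTable(
        pd.concat([cb.data, cb_ctrl.data], ignore_index=True),
        ("TC",), ("feature",),
    )
    rates = estimate_global_rates(merged, controls=["control"])
    step1 = fit_high_coverage(cb, rates, min_reads=300)
    prior = build_prior(step1, rates)
    fit = fit_all_features(cb, rates, prior)
    m = fit.merge(truth.features, on=["sample", "feature"])
    hi = m[m["n_reads"] >= 300]
    r_p = float(np.corrcoef(hi["logit_p_labeled"], logit(hi["p_labeled"]))[0, 1])
    r_theta = float(np.corrcoef(hi["fraction_labeled"], hi["theta"])[0, 1])
    return {"r_p_labeled": r_p, "r_theta": r_theta,
            "prior_sd": float(list(prior.sds.values())[0]),
            "n": int((m["n_reads"] >= 300).sum())}


def hierarchical_low_p_direction(seed: int, n_features: int = 60) -> dict:
    """Low-incorporation subpopulation: hierarchical vs standard theta.

    Half the features get a labeled-read mutation rate at half the global
    value (mitochondrial-like).  The sample-wide rate overestimates theirs,
    so the standard fit underestimates their fraction labeled while the
    hierarchical fit recovers it.
    """
    from .simulate import _aggregate, _simulate_reads, _theta_matrix

    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_features=n_features, reads_per_feature=1000,
                    theta=0.5, seed=seed)
    theta = _theta_matrix(cfg, rng)
    p_feat = np.full(n_features, 0.05)
    low = np.arange(n_features) >= n_features // 2
    p_feat[low] = 0.025
    reads = _simulate_reads(cfg, rng, theta, p_feat)
    cb = _aggregate(reads, cfg)
    ctrl = SimConfig(n_features=n_features, reads_per_feature=200, theta=0.0,
                     sample="control", tl=0.0, seed=seed + 1)
    cb_ctrl, _ = simulate_one_rep(ctrl)
    merged = CBTable(pd.concat([cb.data, cb_ctrl.data], ignore_index=True),
                     ("TC",), ("feature",))
    rates = estimate_global_rates(merged, controls=["control"])
    step1 = fit_high_coverage(cb, rates, min_reads=300)
    prior = build_prior(step1, rates)
    hier = fit_all_features(cb, rates, prior)
    std = estimate_fractions(cb, rates)
    m = hier.merge(std[["sample", "feature", "fraction_labeled"]],
                   on=["sample", "feature"], suffixes=("_hier", "_std"))
    idx = m["feature"].str.replace("feature", "").astype(int) - 1
    m["low"] = idx.to_numpy() >= n_features // 2
    lowm = m[m["low"]]
    frac_higher = float(
        (lowm["fraction_labeled_hier"] > lowm["fraction_labeled_std"]).mean()
    )
    return {
        "fraction_strictly_higher": frac_higher,
        "mean_theta_hier": float(lowm["fraction_labeled_hier"].mean()),
        "mean_theta_std": float(lowm["fraction_labeled_std"].mean()),
        "n": int(m["low"].sum()),
    }


# ---------------------------------------------------------------------------
# dynamics studies
# ---------------------------------------------------------------------------

def random_admissible_model(
    rng: np.random.Generator, max_species: int = 5
) -> tuple[DynamicsModel, dict]:
    """Random connected chain/branch model with positive outflow everywhere.

    Species form a chain from the synthesis entry with occasional branch
    edges; every species gets a degradation edge so the rate matrix is
    strictly Hurwitz.
    """
    n = int(rng.integers(1, max_species + 1))
    species = tuple(f"S{i}" for i in range(n))
    edges = []
    rates = {}
    for i in range(n - 1):
        name = f"k{i}{i + 1}"
        edges.append(Edge(species[i], species[i + 1], name))
        rates[name] = float(np.exp(rng.uniform(np.log(0.05), np.log(5.0))))
    for i in range(n):
        name = f"kd{i}"
        edges.append(Edge(species[i], None, name))
        rates[name] = float(np.exp(rng.uniform(np.log(0.05), np.log(5.0))))
    # occasional skip edge
    if n >= 3 and rng.random() < 0.5:
        j = int(rng.integers(2, n))
        name = "kskip"
        edges.append(Edge(species[0], species[j], name))
        rates[name] = float(np.exp(rng.uniform(np.log(0.05), np.log(5.0))))
    model = DynamicsModel(
        species=species, edges=tuple(edges), synthesis_species=species[0],
        measurements={"all": species},
    )
    rates[model.synthesis_rate] = float(np.exp(rng.uniform(0.0, 2.0)))
    return model, rates


def solver_vs_integrator(seed: int, n_models: int = 100) -> dict:
    """Analytic old-RNA solution vs Runge-Kutta integration."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_models):
        model, rates = random_admissible_model(rng)
        t = float(rng.uniform(0.2, 6.0))
        K = model.rate_matrix(rates)
        ustar = steady_state(model, rates)
        sol = solve_ivp(
            lambda _, u: K @ u, (0.0, t), ustar,
            rtol=1e-10, atol=1e-12, method="RK45", t_eval=[t],
        )
        frac_num = 1.0 - sol.y[:, -1] / ustar
        got = solve_old_fraction(model, rates, t, include_measurements=False)
        dev = max(abs(got[sp] - frac_num[i]) for i, sp in enumerate(model.species))
        worst = max(worst, dev)
    # closed-form two-compartment checks
    pm = premature_mature()
    kp, kd, t = 2.0, 0.5, 1.0
    closed = 1.0 - (kp * np.exp(-kd * t) - kd * np.exp(-kp * t)) / (kp - kd)
    got_pm = solve_old_fraction(pm, {"ksyn": 1.0, "kp": kp, "kdeg": kd}, t)["M"]
    k = 0.7
    limit = 1.0 - (1.0 + k * t) * np.exp(-k * t)
    got_eq = solve_old_fraction(pm, {"ksyn": 1.0, "kp": k, "kdeg": k}, t)["M"]
    return {
        "max_integrator_deviation": worst,
        "pm_theta_M": float(got_pm),
        "pm_closed_form_deviation": float(abs(got_pm - closed)),
        "equal_rate_deviation": float(abs(got_eq - limit)),
        "n": n_models,
    }


def _with_tl0_control(
    cb: CBTable, n_features: int, seed: int, reads: int = 200
) -> tuple[CBTable, list[str]]:
    """Append an unlabeled (tl=0) control sample to a simulated experiment.

    Long label times saturate the labeled fraction, leaving too few
    unlabeled reads for the pooled EM to estimate p_unlabeled reliably;
    fixing it from a no-label control (the recommended configuration when
    controls exist) keeps the per-sample mixture fits stable.
    """
    ctrl = SimConfig(n_features=n_features, reads_per_feature=reads,
                     theta=0.0, sample="control_tl0", tl=0.0, seed=seed + 9)
    cb_ctrl, _ = simulate_one_rep(ctrl)
    merged = CBTable(
        pd.concat([cb.data, cb_ctrl.data], ignore_index=True),
        cb.mutation_types, cb.feature_cols,
    )
    return merged, ["control_tl0"]


def _mixing_scales(fr: pd.DataFrame, meta: pd.DataFrame) -> tuple[dict, dict]:
    fr_m = fr.merge(meta[["sample", "measurement", "tl"]], on="sample")
    tl0 = sorted(fr_m["tl"].unique())[0]
    gl = {
        m: float((s["fraction_labeled"] * s["n"]).sum() / s["n"].sum())
        for m, s in fr_m[fr_m["tl"] == tl0].groupby("measurement")
    }
    alpha = mixing_weights(
        {"nuclear": gl["nuclear"], "cytoplasmic": gl["cytoplasmic"]},
        gl["whole_cell"],
    )
    scales = {"nuclear": alpha["nuclear"],
              "cytoplasmic": alpha["cytoplasmic"], "whole_cell": 1.0}
    return alpha, scales


def dynamics_recovery(seed: int, n_features: int = 300) -> dict:
    """Parameter recovery for the premature->mature and nuclear->cytoplasmic
    designs, plus the mixing-model normalization."""
    out: dict = {"n": n_features}

    pm = premature_mature()
    cfg = DynamicsSimConfig(
        model=pm, n_features=n_features, reads_per_feature=500,
        rate_ranges={"ksyn": (1.0, 20.0), "kp": (0.3, 3.0), "kdeg": (0.1, 1.0)},
        tls=(1.0, 4.0), libraries={"total": ("premature", "mature")},
        seed=seed,
    )
    cb, meta, truth = simulate_dynamics(cfg)
    merged, controls = _with_tl0_control(cb, n_features, seed)
    rates = estimate_global_rates(merged, controls=controls)
    fr = estimate_fractions(cb, rates)
    obs = build_observations(fr, meta, counts=cb.reads_per_feature())
    fit = fit_dynamics(pm, obs, seed=seed)
    m = fit.merge(truth.features, on="feature")
    for r in pm.all_rate_names:
        out[f"pm_r_{r}"] = float(np.corrcoef(m[f"log_{r}"], np.log(m[r]))[0, 1])

    nc = nuclear_cytoplasmic()
    cfg = DynamicsSimConfig(
        model=nc, n_features=n_features, reads_per_feature=500,
        rate_ranges={"ksyn": (1.0, 20.0), "kexp": (0.3, 3.0),
                     "kdeg": (0.1, 1.0)},
        tls=(1.0, 4.0), n_reps=3, seed=seed + 1,
    )
    cb, meta, truth = simulate_dynamics(cfg)
    merged, controls = _with_tl0_control(cb, n_features, seed + 1)
    rates = estimate_global_rates(merged, controls=controls)
    fr = estimate_fractions(cb, rates)
    alpha, scales = _mixing_scales(fr, meta)
    ta = truth.features["abundance_nuclear"].sum()
    tc = truth.features["abundance_cytoplasmic"].sum()
    out["alpha_nuclear"] = float(alpha["nuclear"])
    out["alpha_nuclear_true"] = float(ta / (ta + tc))
    obs = average_observations(
        build_observations(fr, meta, counts=cb.reads_per_feature())
    )
    fit = fit_dynamics(nc, obs, scales=scales, seed=seed + 1)
    m = fit.merge(truth.features, on="feature")
    for r in nc.all_rate_names:
        out[f"nc_r_{r}"] = float(np.corrcoef(m[f"log_{r}"], np.log(m[r]))[0, 1])
    return out


def identifiability_profile(
    seed: int,
    ratios: tuple[float, ...] = (1.0, 0.1, 0.01),
    n_features: int = 40,
) -> dict:
    """Median se(log kNdeg) as nuclear degradation slows relative to export.

    When kNdeg << kexp, almost all nuclear RNA leaves by export and the data
    carry almost no information about kNdeg: its inverse-Hessian uncertainty
    must grow.
    """
    model = nuclear_cytoplasmic(nuclear_degradation=True)
    med = {}
    for ratio in ratios:
        cfg = DynamicsSimConfig(
            model=model, n_features=n_features, reads_per_feature=500,
            rate_ranges={"ksyn": (1.0, 20.0), "kexp": (0.5, 2.0),
                         "kdeg": (0.2, 1.0),
                         "kNdeg": (0.5 * ratio, 2.0 * ratio)},
            tls=(1.0, 4.0), n_reps=3, seed=seed,
        )
        cb, meta, truth = simulate_dynamics(cfg)
        merged, controls = _with_tl0_control(cb, n_features, seed)
        rates = estimate_global_rates(merged, controls=controls)
        fr = estimate_fractions(cb, rates)
        _, scales = _mixing_scales(fr, meta)
        obs = average_observations(
            build_observations(fr, meta, counts=cb.reads_per_feature())
        )
        fit = fit_dynamics(model, obs, scales=scales, seed=seed)
        med[ratio] = float(fit["se_log_kNdeg"].median())
    return {"median_se_by_ratio": med, "n": n_features}


# ---------------------------------------------------------------------------
# linear-model studies
# ---------------------------------------------------------------------------

def glm_calibration(
    seed: int, n_features: int = 2000, reps: int = 3
) -> dict:
    """Null false-discovery control and variance-moderation gain."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(2 * reps)]
    meta = pd.DataFrame({"sample": samples,
                         "condition": ["A"] * reps + ["B"] * reps})
    mu = rng.normal(0.0, 1.0, n_features)
    sigma = 0.3
    Y = mu[:, None] + rng.normal(0.0, sigma, (n_features, 2 * reps))
    vals = pd.DataFrame({
        "feature": np.repeat([f"g{i}" for i in range(n_features)], 2 * reps),
        "sample": np.tile(samples, n_features),
        "y": Y.ravel(),
        "se": 0.05,
        "n": np.repeat(rng.integers(50, 5000, n_features), 2 * reps),
    })
    spec = LinearModelSpec("~condition", "y", "se")
    fit = average_and_regularize(vals, meta, spec)
    res = compare_parameters(fit, "condition[B] - condition[A]")
    fdr = float((res["padj"] < 0.05).mean())

    # moderation gain: MSE of variance estimates vs shared truth
    first = fit_feature_lm(vals, meta, spec)
    sds, group_df = estimate_group_sds(first)
    coverage = vals.groupby("feature")["n"].mean()
    mod_sds, _, _ = regularize_se(sds, group_df, coverage)
    truth_var = sigma**2 + 0.05**2  # residuals include the input noise
    raw_mse = float(((sds.to_numpy() ** 2 - truth_var) ** 2).mean())
    mod_mse = float(((mod_sds.to_numpy() ** 2 - truth_var) ** 2).mean())
    return {"null_fdr": fdr, "raw_variance_mse": raw_mse,
            "moderated_variance_mse": mod_mse, "n": n_features}


def interaction_identity(seed: int = 0) -> dict:
    """Noise-free interaction coefficient vs the cell-means identity."""
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame({
        "sample": [f"s{i}" for i in range(8)],
        "state": ["ctrl", "ctrl", "treat", "treat"] * 2,
        "oxy": ["norm"] * 4 + ["hypo"] * 4,
    })
    mu = {k: float(v) for k, v in zip(
        [("ctrl", "norm"), ("treat", "norm"), ("ctrl", "hypo"), ("treat", "hypo")],
        rng.normal(0, 1, 4),
    )}
    vals = pd.DataFrame({
        "feature": "g",
        "sample": meta["sample"],
        "y": [mu[(s, o)] for s, o in zip(meta["state"], meta["oxy"])],
        "se": 0.1,
    })
    fit = fit_feature_lm(vals, meta, LinearModelSpec("~state*oxy", "y", "se"))
    inter_col = [c for c in fit.coef_names if ":" in c][0]
    got = float(fit.coef[0, fit.coef_names.index(inter_col)])
    # patsy baseline is the first level alphabetically (ctrl, hypo)
    want = (mu[("treat", "norm")] - mu[("ctrl", "norm")]) - (
        mu[("treat", "hypo")] - mu[("ctrl", "hypo")]
    )
    return {"interaction_estimate": got, "cell_means_value": want,
            "abs_deviation": abs(got - want), "n": 8}
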