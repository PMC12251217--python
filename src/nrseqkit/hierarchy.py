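"""Hierarchical two-component mixture: feature-specific labeled-read rates.

Some transcript classes (mitochondrially encoded RNAs being the canonical
example) incorporate metabolic label at a much lower rate than the sample
average, so a single sample-wide p_labeled misclassifies their
moderately-mutated reads as unlabeled and underestimates their fraction
labeled.  The remedy is to let every feature carry its own p_labeled,
strongly regularized so that low-coverage features shrink to the sample-wide
rate.  The procedure (two-component designs only):

1. :func:`fit_high_coverage` — joint MLE of (theta, p_labeled) per feature,
   restricted to features with more than ``min_reads`` reads (300 by
   default); logit(p_labeled) is bounded to [-9, 0].
2. :func:`build_prior` — a normal prior on logit(p_labeled) per sample with
   mean the sample-wide logit(p_labeled) and sd equal to the spread of the
   step-1 estimates minus their average uncertainty, clamped to
   [sd_min, sd_max] (defaults 0.01, 0.15).  Estimates at the parameter
   bounds are excluded; with multiple labeled samples the smallest
   sample-specific sd is used for all of them.
3. :func:`fit_all_features` — MAP fit of (theta, p_labeled) for every
   feature under the step-2 prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .cb import CBTable, mutation_columns
from .mixture import (
    HESSIAN_FALLBACK_SD,
    GlobalRates,
    binom_logpmf,
)

__all__ = [
    "FeatureRatePrior",
    "fit_high_coverage",
    "build_prior",
    "fit_all_features",
    "LOGIT_P_BOUNDS",
]

LOGIT_P_BOUNDS = (-9.0, 0.0)
BOUND_TOL = 1e-6  # "extreme" = within this of a logit(p_labeled) bound


@dataclass(frozen=True)
class FeatureRatePrior:
    """Per-sample normal prior on logit(p_labeled)."""

    means: dict  # sample -> prior mean (sample-wide logit p_labeled)
    sds: dict  # sample -> prior sd (common minimum across samples)
    provenance: dict  # sample -> "computed" | "clamped_low" | "clamped_high" | "fallback"
    bounds: tuple[float, float] = LOGIT_P_BOUNDS


def _require_two_component(cb: CBTable) -> str:
    if len(cb.mutation_types) != 1:
        raise ValueError(
            "hierarchical modeling is currently only compatible with standard "
            "two-component (single-label) mixture modeling"
        )
    return cb.mutation_types[0]


def _feature_map_fit(
    nM: np.ndarray,
    nN: np.ndarray,
    w: np.ndarray,
    p_unlabeled: float,
    b0: float,
    p_prior: tuple[float, float] | None,
    theta_prior_sd: float | None,
    bounds: tuple[float, float] = LOGIT_P_BOUNDS,
) -> tuple[float, float, float, float, str]:
    """2-D bounded fit over x = (logit theta, logit p_labeled).

    Returns (logit_theta, logit_p, se_logit_theta, se_logit_p, flag).
    """
    ll0 = binom_logpmf(nM, nN, p_unlabeled)

    def nll(x: np.ndarray) -> float:
        a, b = x
        theta = expit(a)
        ll1 = binom_logpmf(nM, nN, expit(b))
        row = np.logaddexp(np.log(theta) + ll1, np.log1p(-theta) + ll0)
        val = -float((w * row).sum())
        if theta_prior_sd is not None:
            val += 0.5 * a**2 / theta_prior_sd**2
        if p_prior is not None:
            mu, sd = p_prior
            val += 0.5 * (b - mu) ** 2 / sd**2
        return val

    lo, hi = bounds
    starts = [(0.0, np.clip(b0, lo, hi))]
    for shift in (-1.0, 1.0):
        starts.append((0.0, np.clip(b0 + shift, lo, hi)))
    best = None
    for x0 in starts:
        res = minimize(nll, np.asarray(x0), method="L-BFGS-B",
                       bounds=[(-30.0, 30.0), (lo, hi)])
        if best is None or res.fun < best.fun:
            best = res
    a_hat, b_hat = best.x
    flag = "" if best.success else "nonconverged"
    if min(b_hat - lo, hi - b_hat) <= BOUND_TOL:
        flag = (flag + ";" if flag else "") + "extreme"

    h = 1e-4
    H = np.empty((2, 2))
    x = best.x
    f0 = best.fun
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = h
            ej = np.zeros(2); ej[j] = h
            if i == j:
                H[i, i] = (nll(x + ei) - 2 * f0 + nll(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    nll(x + ei + ej) - nll(x + ei - ej)
                    - nll(x - ei + ej) + nll(x - ei - ej)
                ) / (4 * h**2)
    try:
        eig = np.linalg.eigvalsh(H)
        if eig.min() <= 0:
            raise np.linalg.LinAlgError
        cov = np.linalg.inv(H)
        se_a, se_b = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se_a = se_b = HESSIAN_FALLBACK_SD
        flag = (flag + ";" if flag else "") + "singular_hessian"
    return float(a_hat), float(b_hat), float(se_a), float(se_b), flag


def fit_high_coverage(
    cb: CBTable,
    rates: GlobalRates,
    min_reads: int = 300,
    feature_col: str | None = None,
    bounds: tuple[float, float] = LOGIT_P_BOUNDS,
) -> pd.DataFrame:
    """Step 1: joint MLE of (theta, p_labeled) for high-coverage features.

    Only features with more than ``min_reads`` reads in a sample are fit —
    below that, a feature-specific rate is not stably estimable.
    p_unlabeled is fixed at the sample-wide value and logit(p_labeled) is
    constrained to ``bounds``; estimates at a bound are flagged "extreme".
    """
    mut = _require_two_component(cb)
    nn_col, nm_col = mutation_columns(mut)
    fc = feature_col or cb.feature_cols[0]
    records = []
    for sample, sdf in cb.data.groupby("sample", sort=True):
        p1, p0 = rates.rates(sample, mut)
        b0 = float(np.clip(logit(p1), *bounds))
        for feat, sub in sdf.groupby(fc, sort=True):
            n_reads = int(sub["n"].sum())
            if n_reads <= min_reads:
                continue
            a, b, se_a, se_b, flag = _feature_map_fit(
                sub[nm_col].to_numpy(float), sub[nn_col].to_numpy(float),
                sub["n"].to_numpy(float), p0, b0,
                p_prior=None, theta_prior_sd=None, bounds=bounds,
            )
            records.append({
                "sample": sample, fc: feat, "n": n_reads,
                "logit_theta": a, "logit_p_labeled": b,
                "logit_theta_se": se_a, "logit_p_labeled_se": se_b,
                "flag": flag,
            })
    return pd.DataFrame.from_records(
        records,
        columns=["sample", fc, "n", "logit_theta", "logit_p_labeled",
                 "logit_theta_se", "logit_p_labeled_se", "flag"],
    )


def build_prior(
    step1: pd.DataFrame,
    rates: GlobalRates,
    sd_min: float = 0.01,
    sd_max: float = 0.15,
    bounds: tuple[float, float] = LOGIT_P_BOUNDS,
) -> FeatureRatePrior:
    """Step 2: regularizing normal prior on logit(p_labeled) per sample.

    sd = clamp( sd(step-1 estimates) - mean(step-1 uncertainties),
                sd_min, sd_max ),
    computed after excluding extreme (at-bound) estimates; the prior mean is
    the sample-wide logit(p_labeled).  Across multiple labeled samples the
    minimum sd is broadcast to all, to guard against under-conservativeness.
    """
    mut = rates.table.index.get_level_values("mutation_type")[0]
    means: dict = {}
    sds: dict = {}
    prov: dict = {}
    for sample in rates.table.index.get_level_values("sample").unique():
        means[sample] = float(np.clip(rates.logit_p_labeled(sample, mut), *bounds))
        sub = step1[step1["sample"] == sample]
        usable = sub[~sub["flag"].str.contains("extreme", na=False)]
        if len(usable) < 2:
            warnings.warn(
                f"sample {sample!r}: fewer than 2 usable high-coverage features; "
                f"falling back to prior sd {sd_min}"
            )
            sds[sample] = sd_min
            prov[sample] = "fallback"
            continue
        spread = float(usable["logit_p_labeled"].std(ddof=1))
        avg_unc = float(usable["logit_p_labeled_se"].mean())
        raw = spread - avg_unc
        if raw < sd_min:
            sds[sample] = sd_min
            prov[sample] = "clamped_low"
        elif raw > sd_max:
            sds[sample] = sd_max
            prov[sample] = "clamped_high"
        else:
            sds[sample] = raw
            prov[sample] = "computed"
    if sds:
        common = min(sds.values())
        sds = {s: common for s in sds}
    return FeatureRatePrior(means=means, sds=sds, provenance=prov, bounds=bounds)


def fit_all_features(
    cb: CBTable,
    rates: GlobalRates,
    prior: FeatureRatePrior,
    theta_prior_sd: float | None = 1.5,
    feature_col: str | None = None,
) -> pd.DataFrame:
    """Step 3: MAP fit of (theta, p_labeled) for every feature.

    Uses the step-2 normal prior on logit(p_labeled); theta keeps the same
    weakly informative logit-normal prior as the non-hierarchical fit, so
    that as the p_labeled prior tightens the estimates converge to the
    non-hierarchical ones.
    """
    mut = _require_two_component(cb)
    nn_col, nm_col = mutation_columns(mut)
    fc = feature_col or cb.feature_cols[0]
    records = []
    for sample, sdf in cb.data.groupby("sample", sort=True):
        _, p0 = rates.rates(sample, mut)
        mu, sd = prior.means[sample], prior.sds[sample]
        for feat, sub in sdf.groupby(fc, sort=True):
            n_reads = int(sub["n"].sum())
            rec = {"sample": sample, fc: feat, "n": n_reads,
                   "prior_sd_used": sd}
            if int(sub[nn_col].sum()) == 0:
                rec.update({
                    "fraction_labeled": np.nan, "logit_fraction_labeled": np.nan,
                    "logit_fraction_labeled_se": np.nan,
                    "logit_p_labeled": np.nan, "logit_p_labeled_se": np.nan,
                    "flag": "no_mutable_nucleotides",
                })
                records.append(rec)
                continue
            a, b, se_a, se_b, flag = _feature_map_fit(
                sub[nm_col].to_numpy(float), sub[nn_col].to_numpy(float),
                sub["n"].to_numpy(float), p0, mu,
                p_prior=(mu, sd), theta_prior_sd=theta_prior_sd,
                bounds=prior.bounds,
            )
            rec.update({
                "fraction_labeled": float(expit(a)),
                "logit_fraction_labeled": a, "logit_fraction_labeled_se": se_a,
                "logit_p_labeled": b, "logit_p_labeled_se": se_b,
                "flag": flag,
            })
            records.append(rec)
    return pd.DataFrame.from_records(records)
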