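"""Kinetic parameter estimation under the one-compartment steady-state model.

With first-order turnover at steady state, RNA present before the label
pulse decays as exp(-kdeg * tl), so the fraction labeled after labeling for
tl hours is theta = 1 - exp(-kdeg * tl), giving

    kdeg = -ln(1 - theta) / tl        [1/h]
    ksyn = kdeg * R                   [normalized reads / h]

where R is the feature's normalized read count.  Uncertainties are
propagated from the logit-scale fraction standard errors by the delta
method.  Also provides median-of-ratios count normalization (or spike-in
pass-through) and a one-parameter dropout normalization across samples.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cb import CBTable

__all__ = [
    "kdeg_from_theta",
    "ksyn_from_kdeg",
    "normalize_counts",
    "estimate_kinetics",
    "normalize_for_dropout",
    "dropout_adjust",
]

THETA_EPS = 1e-4  # saturation clamp: theta >= 1 - eps is treated as 1 - eps


def kdeg_from_theta(
    theta,
    tl: float,
    logit_se=None,
    eps: float = THETA_EPS,
) -> pd.DataFrame:
    """Degradation rate constant(s) from fraction labeled.

    kdeg = -ln(1 - theta)/tl, with theta clamped at 1 - eps (flagged
    "saturated") so saturated features get a finite capped estimate of
    ln(1/eps)/tl.  theta = 0 yields kdeg = 0 (flagged "zero": no log-scale
    uncertainty exists there).  If ``logit_se`` is given, the returned
    ``se_log_kdeg`` is the delta-method propagation of the logit-scale
    fraction standard error.
    """
    if tl <= 0:
        raise ValueError("label time tl must be > 0")
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("theta must lie in [0, 1]")
    flag = np.where(theta >= 1 - eps, "saturated",
                    np.where(theta == 0, "zero", ""))
    th = np.clip(theta, 0.0, 1.0 - eps)
    kdeg = -np.log1p(-th) / tl
    out = pd.DataFrame({"kdeg": kdeg, "flag": flag})
    if logit_se is not None:
        logit_se = np.atleast_1d(np.asarray(logit_se, dtype=float))
        # d kdeg / d logit(theta) = theta(1-theta) * 1/((1-theta) tl) = theta/tl
        se_kdeg = th / tl * logit_se
        with np.errstate(divide="ignore", invalid="ignore"):
            out["se_log_kdeg"] = np.where(kdeg > 0, se_kdeg / kdeg, np.inf)
    return out


def ksyn_from_kdeg(kdeg, R, se_log_kdeg=None, se_log_R=None) -> pd.DataFrame:
    """Synthesis rate ksyn = kdeg * R with log-scale error propagation."""
    kdeg = np.atleast_1d(np.asarray(kdeg, dtype=float))
    R = np.atleast_1d(np.asarray(R, dtype=float))
    if np.any(kdeg < 0) or np.any(R < 0):
        raise ValueError("kdeg and R must be non-negative")
    out = pd.DataFrame({"ksyn": kdeg * R})
    if se_log_kdeg is not None or se_log_R is not None:
        a = np.zeros_like(kdeg) if se_log_kdeg is None else np.asarray(se_log_kdeg, float)
        b = np.zeros_like(R) if se_log_R is None else np.asarray(se_log_R, float)
        out["se_log_ksyn"] = np.sqrt(a**2 + b**2)
    return out


def normalize_counts(
    cb: CBTable,
    feature_col: str | None = None,
    method: str = "median_of_ratios",
    factors: Mapping[str, float] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample size factors and normalized read counts R.

    ``median_of_ratios``: each sample's factor is the median across features
    of its count ratio to the geometric-mean pseudo-reference (features with
    a zero count in any sample are excluded from the reference).
    ``spike_in``: user-supplied ``factors`` are passed through unchanged.
    Returns (size_factors, long frame with sample, feature, n, R = n/factor).
    """
    fc = feature_col or cb.feature_cols[0]
    counts = (
        cb.data.groupby(["sample", fc])["n"].sum().unstack("sample", fill_value=0)
    )
    if method == "spike_in":
        if factors is None:
            raise ValueError("spike_in normalization requires factors")
        sf = pd.Series({s: float(factors[s]) for s in counts.columns})
    elif method == "median_of_ratios":
        pos = counts[(counts > 0).all(axis=1)]
        if not len(pos):
            raise ValueError("no feature has nonzero counts in every sample")
        log_ref = np.log(pos).mean(axis=1)
        sf = np.exp(np.log(pos).sub(log_ref, axis=0).median(axis=0))
        sf = sf / np.exp(np.log(sf).mean())  # geometric mean 1
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    long = counts.stack().rename("n").reset_index()
    long = long.rename(columns={fc: "feature"})
    long["R"] = long["n"] / long["sample"].map(sf)
    return sf, long


def estimate_kinetics(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    reads: pd.DataFrame | None = None,
    feature_col: str = "feature",
) -> pd.DataFrame:
    """Per-(sample, feature) kdeg and (when counts are given) ksyn.

    ``fractions`` must carry fraction_labeled and logit_fraction_labeled_se
    (output of the mixture stage); ``meta`` provides the label time ``tl``
    per sample; ``reads`` optionally provides normalized counts R from
    :func:`normalize_counts`.
    """
    df = fractions.merge(meta[["sample", "tl"]], on="sample", how="left")
    if df["tl"].isna().any():
        missing = df.loc[df["tl"].isna(), "sample"].unique()
        raise ValueError(f"samples missing from metadata: {list(missing)}")
    parts = []
    for tl, sub in df.groupby("tl"):
        kd = kdeg_from_theta(
            sub["fraction_labeled"].to_numpy(),
            float(tl),
            logit_se=sub["logit_fraction_labeled_se"].to_numpy(),
        )
        kd.index = sub.index
        parts.append(pd.concat([sub, kd], axis=1))
    out = pd.concat(parts).sort_index()
    if reads is not None:
        out = out.merge(
            reads.rename(columns={"feature": feature_col})[
                ["sample", feature_col, "R"]
            ],
            on=["sample", feature_col],
            how="left",
        )
        ks = ksyn_from_kdeg(
            out["kdeg"].to_numpy(),
            out["R"].fillna(0).to_numpy(),
            se_log_kdeg=out["se_log_kdeg"].to_numpy(),
        )
        ks.index = out.index
        out = pd.concat([out, ks], axis=1)
    return out


# ---------------------------------------------------------------------------
# dropout normalization
# ---------------------------------------------------------------------------

def dropout_adjust(theta, d: float):
    """Invert label-dependent read loss on a fraction-labeled estimate.

    Under the one-parameter dropout model, a labeled read survives library
    preparation with probability 1/(1+d), so the observed fraction is
    theta_obs = theta / (1 + d (1 - theta)); this inverts it:
    theta = theta_obs (1+d) / (1 + d theta_obs).
    """
    theta = np.asarray(theta, dtype=float)
    return theta * (1.0 + d) / (1.0 + d * theta)


def _global_labeled_fraction(sub: pd.DataFrame) -> float:
    return float((sub["fraction_labeled"] * sub["n"]).sum() / sub["n"].sum())


def normalize_for_dropout(
    fractions: pd.DataFrame,
    grouping: Mapping[str, str] | None = None,
    feature_col: str = "feature",
    d_max: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize fraction-labeled estimates for sample-to-sample dropout.

    Within each group (e.g. a subcellular fraction), the sample with the
    highest global labeled fraction is taken as the lowest-dropout reference.
    For every other sample a single dropout parameter d >= 0 is fitted by
    matching its dropout-corrected per-feature fractions to the reference's
    (read-count-weighted least squares over shared features), and its
    fractions are corrected accordingly.  Returns
    (factors frame with one row per sample, adjusted fractions).

    The one-parameter retention model is a deliberately simple stand-in for
    full dropout-correction estimators; it is isolated here so a richer
    model can replace it.
    """
    df = fractions.copy()
    groups = (
        pd.Series({s: "all" for s in df["sample"].unique()})
        if grouping is None
        else pd.Series(dict(grouping))
    )
    factor_rows = []
    adjusted = []
    for group, samples in groups.groupby(groups):
        names = list(samples.index)
        gdf = df[df["sample"].isin(names)]
        if len(names) == 1:
            warnings.warn(
                f"dropout group {group!r} has a single sample; identity factor"
            )
            factor_rows.append({"sample": names[0], "group": group,
                                "reference": names[0], "d": 0.0, "factor": 1.0})
            adjusted.append(gdf)
            continue
        gl = {s: _global_labeled_fraction(gdf[gdf["sample"] == s]) for s in names}
        ref = max(gl, key=gl.get)
        ref_df = gdf[gdf["sample"] == ref].set_index(feature_col)
        for s in names:
            sub = gdf[gdf["sample"] == s]
            if s == ref:
                factor_rows.append({"sample": s, "group": group, "reference": ref,
                                    "d": 0.0, "factor": 1.0})
                adjusted.append(sub)
                continue
            merged = sub.set_index(feature_col).join(
                ref_df[["fraction_labeled"]], rsuffix="_ref", how="inner"
            ).dropna(subset=["fraction_labeled", "fraction_labeled_ref"])
            w = merged["n"].to_numpy(float)
            th = merged["fraction_labeled"].to_numpy(float)
            th_ref = merged["fraction_labeled_ref"].to_numpy(float)

            def loss(d: float) -> float:
                return float((w * (dropout_adjust(th, d) - th_ref) ** 2).sum())

            res = minimize_scalar(loss, bounds=(0.0, d_max), method="bounded",
                                  options={"xatol": 1e-8})
            d_hat = float(res.x) if res.x > 1e-6 else 0.0
            factor_rows.append({"sample": s, "group": group, "reference": ref,
                                "d": d_hat, "factor": 1.0 / (1.0 + d_hat)})
            sub = sub.copy()
            sub["fraction_labeled"] = dropout_adjust(
                sub["fraction_labeled"].to_numpy(float), d_hat
            )
            if "logit_fraction_labeled" in sub.columns:
                clipped = np.clip(sub["fraction_labeled"], 1e-12, 1 - 1e-12)
                sub["logit_fraction_labeled"] = np.log(clipped) - np.log1p(-clipped)
            adjusted.append(sub)
    factors = pd.DataFrame(factor_rows)
    out = pd.concat(adjusted, ignore_index=True)
    return factors, out
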