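"""Condition-level averaging and comparison of kinetic parameters.

Per feature, a response (logit fraction labeled, log kdeg, log ksyn, ...)
measured in each sample is fit to a design-matrix linear model specified by
a Wilkinson-style formula over the sample metadata (``~condition``,
``~state:oxy`` for interaction-only cell means, ``~state*oxy`` for mains
plus interaction).  Weighted least squares uses the upstream per-sample
standard errors; residual standard deviations are estimated per
variance group (handling heteroskedasticity across e.g. compartments) and
shrunk toward a coverage-dependent trend by an empirical-Bayes moderated-
variance scheme.  Contrasts of coefficients are tested with moderated-t
statistics and Benjamini-Hochberg correction across features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LinearModelSpec",
    "FeatureLMFit",
    "RegularizedFit",
    "design_matrix",
    "fit_feature_lm",
    "estimate_group_sds",
    "regularize_se",
    "average_and_regularize",
    "compare_parameters",
    "contrast_vector",
]

SE_FLOOR = 1e-8
TREND_FLOOR_FRACTION = 0.25  # moderated variances never fall below this x trend


@dataclass(frozen=True)
class LinearModelSpec:
    """Formula + response description for the per-feature linear model."""

    formula: str
    response: str
    se: str | None = None
    vargroups: tuple[str, ...] | None = None


def design_matrix(formula: str, meta: pd.DataFrame) -> pd.DataFrame:
    """Build the design matrix for a formula over the sample metadata.

    Single-factor and interaction-only (":") formulas use intercept-free
    cell-means coding, so coefficients are directly interpretable as group
    means and any pairwise comparison is a simple contrast.  "*" formulas
    keep the intercept and treatment coding so the interaction coefficient
    is the difference-of-differences.
    """
    f = formula.strip().lstrip("~").strip()
    if "*" not in f:
        f = "0 + " + f
    X = patsy.dmatrix(f, meta, return_type="dataframe")
    X.index = meta.index
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix for {formula!r} is rank deficient "
            f"(rank {rank} < {X.shape[1]} columns {list(X.columns)}); "
            "some terms are aliased"
        )
    return X


@dataclass
class FeatureLMFit:
    """Per-feature weighted-least-squares fits against a shared design."""

    X: pd.DataFrame  # samples x p
    features: np.ndarray
    coef: np.ndarray  # features x p
    cov: np.ndarray  # features x p x p (propagated from input se)
    residuals: np.ndarray  # features x samples
    input_se: np.ndarray  # features x samples
    response: np.ndarray  # features x samples
    spec: LinearModelSpec
    meta: pd.DataFrame

    @property
    def coef_names(self) -> list[str]:
        return list(self.X.columns)

    def coef_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coef, columns=self.coef_names)
        df.insert(0, "feature", self.features)
        return df


def fit_feature_lm(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    spec: LinearModelSpec,
    feature_col: str = "feature",
) -> FeatureLMFit:
    """Weighted least squares per feature.

    ``values`` is long with columns (feature, sample, response[, se]).
    Weights are inverse input variances; with no se column (or all-zero se)
    the fit is ordinary least squares.  The returned covariance is
    (X' W X)^-1, i.e. the propagation of the supplied observation
    uncertainties through the fit.
    """
    X = design_matrix(spec.formula, meta)
    samples = meta["sample"].to_numpy()
    wide = values.pivot_table(index=feature_col, columns="sample",
                              values=spec.response, aggfunc="first")
    missing = set(samples) - set(wide.columns)
    if missing:
        raise ValueError(f"values missing for samples {sorted(missing)}")
    Y = wide[samples].to_numpy(float)
    if spec.se is not None:
        se_wide = values.pivot_table(index=feature_col, columns="sample",
                                     values=spec.se, aggfunc="first")
        SE = np.maximum(se_wide[samples].to_numpy(float), SE_FLOOR)
    else:
        SE = np.ones_like(Y)
    keep = ~np.isnan(Y).any(axis=1)
    Y, SE = Y[keep], SE[keep]
    features = wide.index.to_numpy()[keep]

    Xm = X.to_numpy()
    p = Xm.shape[1]
    nf = len(features)
    coef = np.empty((nf, p))
    cov = np.empty((nf, p, p))
    resid = np.empty_like(Y)
    for i in range(nf):
        w = 1.0 / SE[i] ** 2
        XtW = Xm.T * w
        A = XtW @ Xm
        Ainv = np.linalg.inv(A)
        coef[i] = Ainv @ (XtW @ Y[i])
        cov[i] = Ainv
        resid[i] = Y[i] - Xm @ coef[i]
    return FeatureLMFit(
        X=X, features=features, coef=coef, cov=cov, residuals=resid,
        input_se=SE, response=Y, spec=spec, meta=meta,
    )


def _variance_groups(fit: FeatureLMFit) -> pd.Series:
    """Sample -> variance-group label.

    User factors win; otherwise, if the design is cell-means (each sample
    loads on exactly one coefficient), samples estimating different
    coefficients form non-overlapping sets and get their own group; any
    other design pools all samples.
    """
    meta = fit.meta
    if fit.spec.vargroups:
        lab = meta[list(fit.spec.vargroups)].astype(str).agg("|".join, axis=1)
        return pd.Series(lab.to_numpy(), index=meta["sample"].to_numpy())
    Xm = fit.X.to_numpy()
    nonzero = np.abs(Xm) > 1e-12
    if np.all(nonzero.sum(axis=1) == 1):
        col = nonzero.argmax(axis=1)
        return pd.Series([fit.coef_names[j] for j in col],
                         index=meta["sample"].to_numpy())
    return pd.Series("pooled", index=meta["sample"].to_numpy())


def estimate_group_sds(fit: FeatureLMFit) -> tuple[pd.DataFrame, pd.Series]:
    """Per-feature, per-group residual standard deviations.

    The residual degrees of freedom of a group are its sample count minus
    the number of coefficients estimated entirely within it.  Groups with
    zero residual df fall back to the input uncertainties alone (sd 0, with
    a warning).
    Returns (features x groups sd frame, residual df per group).
    """
    groups = _variance_groups(fit)
    samples = fit.meta["sample"].to_numpy()
    glabels = groups[samples].to_numpy()
    Xm = fit.X.to_numpy()
    nonzero = np.abs(Xm) > 1e-12
    uniq = pd.unique(glabels)
    sd = {}
    dfs = {}
    for g in uniq:
        mask = glabels == g
        # coefficients supported only by this group's samples
        p_g = int(np.sum(nonzero[mask].any(axis=0) & ~nonzero[~mask].any(axis=0)))
        df_g = int(mask.sum()) - p_g
        if df_g <= 0:
            warnings.warn(
                f"variance group {g!r} has no residual degrees of freedom; "
                "uncertainty will come from input standard errors only"
            )
            sd[g] = np.zeros(len(fit.features))
            dfs[g] = 0
            continue
        ss = (fit.residuals[:, mask] ** 2).sum(axis=1)
        sd[g] = np.sqrt(ss / df_g)
        dfs[g] = df_g
    return (
        pd.DataFrame(sd, index=fit.features),
        pd.Series(dfs, dtype=float),
    )


def _fit_d0(excess_var: float) -> float:
    """Invert trigamma(d0/2) = excess_var for the prior df (limma-style)."""
    if excess_var <= 1e-8:
        return np.inf
    x = 0.5 + 1.0 / excess_var  # starting point per Welham & Thompson style inversion
    for _ in range(50):
        tri = polygamma(1, x)
        delta = tri * (1.0 - tri / excess_var) / polygamma(2, x)
        x = max(x - delta, 1e-6)
        if abs(delta) < 1e-10:
            break
    return 2.0 * x


def regularize_se(
    sds: pd.DataFrame,
    group_df: pd.Series,
    coverage: pd.Series,
    floor_fraction: float = TREND_FLOOR_FRACTION,
    min_features: int = 10,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Shrink per-feature log-variances toward a coverage trend.

    Within each variance group: a linear trend of log variance vs log
    coverage is fit across features; the prior df d0 comes from the spread
    of log variances in excess of their chi-square sampling variance
    (trigamma inversion); moderated variances are the df-weighted average
    (d0*trend + df*s2)/(d0+df), floored at ``floor_fraction`` times the
    trend.  With fewer than ``min_features`` features the raw values pass
    through unchanged.

    Returns (moderated sds, prior df per group, trend values).
    """
    out = sds.copy()
    trend_out = sds.copy()
    d0s = {}
    logc = np.log(np.maximum(coverage.reindex(sds.index).to_numpy(float), 1.0))
    for g in sds.columns:
        s2 = sds[g].to_numpy(float) ** 2
        d = float(group_df[g])
        ok = (s2 > 0) & np.isfinite(s2)
        if d <= 0 or ok.sum() < min_features:
            if ok.sum() < min_features:
                warnings.warn(
                    f"variance group {g!r}: fewer than {min_features} features; "
                    "skipping regularization"
                )
            d0s[g] = 0.0
            trend_out[g] = sds[g] ** 2
            continue
        z = np.log(s2[ok])
        # E[log s2] = log sigma2 + digamma(d/2) - log(d/2); the additive bias
        # is constant across features so the trend absorbs it
        if np.ptp(logc[ok]) < 1e-8:  # constant coverage: intercept-only trend
            slope, intercept = 0.0, float(np.mean(z))
        else:
            slope, intercept = np.polyfit(logc[ok], z, 1)
        bias = polygamma(0, d / 2.0) - np.log(d / 2.0)
        log_trend = slope * logc + intercept - bias
        s0 = np.exp(log_trend)
        sampling_var = float(polygamma(1, d / 2.0))
        excess = float(np.var(z - (slope * logc[ok] + intercept), ddof=1)) - sampling_var
        d0 = _fit_d0(max(excess, 0.0))
        d0s[g] = d0
        if np.isinf(d0):
            s2_mod = s0.copy()
        else:
            s2_mod = (d0 * s0 + d * np.where(ok, s2, s0)) / (d0 + d)
        s2_mod = np.maximum(s2_mod, floor_fraction * s0)
        out[g] = np.sqrt(s2_mod)
        trend_out[g] = s0
    return out, pd.Series(d0s), trend_out


@dataclass
class RegularizedFit:
    """Final per-feature fit with moderated uncertainties."""

    X: pd.DataFrame
    features: np.ndarray
    coef: np.ndarray  # features x p (refit with combined weights)
    cov: np.ndarray  # features x p x p
    raw_se: np.ndarray  # features x p, from the first-pass fit
    sds: pd.DataFrame  # raw residual sds
    moderated_sds: pd.DataFrame
    group_df: pd.Series
    prior_df: pd.Series
    spec: LinearModelSpec
    groups: pd.Series  # sample -> group

    @property
    def coef_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def total_df(self) -> float:
        d0 = float(np.min(self.prior_df)) if len(self.prior_df) else 0.0
        return float(self.group_df.sum()) + d0

    def coef_se(self) -> np.ndarray:
        return np.sqrt(np.einsum("fii->fi", self.cov))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coef, columns=self.coef_names)
        for j, name in enumerate(self.coef_names):
            df[f"se_{name}"] = np.sqrt(self.cov[:, j, j])
        df.insert(0, "feature", self.features)
        return df


def average_and_regularize(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    spec: LinearModelSpec,
    coverage: pd.Series | None = None,
    feature_col: str = "feature",
) -> RegularizedFit:
    """Full pipeline: WLS fit, group sds, EB moderation, final refit.

    Observation weights in the final pass combine the upstream standard
    errors and the moderated group residual sd in quadrature.  ``coverage``
    (reads per feature, for the variance trend) defaults to an ``n`` column
    in ``values`` summed per feature, else a constant.
    """
    first = fit_feature_lm(values, meta, spec, feature_col)
    sds, group_df = estimate_group_sds(first)
    if coverage is None:
        if "n" in values.columns:
            coverage = values.groupby(feature_col)["n"].mean()
        else:
            coverage = pd.Series(1.0, index=pd.Index(first.features))
    mod_sds, prior_df, _ = regularize_se(sds, group_df, coverage)

    groups = _variance_groups(first)
    samples = first.meta["sample"].to_numpy()
    glabels = groups[samples].to_numpy()
    g_idx = np.array([list(mod_sds.columns).index(g) for g in glabels])
    Xm = first.X.to_numpy()
    p = Xm.shape[1]
    nf = len(first.features)
    coef = np.empty((nf, p))
    cov = np.empty((nf, p, p))
    mod = mod_sds.to_numpy(float)
    for i in range(nf):
        total_var = first.input_se[i] ** 2 + mod[i, g_idx] ** 2
        w = 1.0 / np.maximum(total_var, SE_FLOOR**2)
        XtW = Xm.T * w
        Ainv = np.linalg.inv(XtW @ Xm)
        coef[i] = Ainv @ (XtW @ first.response[i])
        cov[i] = Ainv
    raw_se = np.sqrt(np.einsum("fii->fi", first.cov))
    return RegularizedFit(
        X=first.X, features=first.features, coef=coef, cov=cov, raw_se=raw_se,
        sds=sds, moderated_sds=mod_sds, group_df=group_df, prior_df=prior_df,
        spec=spec, groups=groups,
    )


def contrast_vector(fit: RegularizedFit | FeatureLMFit, contrast) -> np.ndarray:
    """Resolve a contrast into a coefficient weight vector.

    Accepts an array, a {coefficient: weight} mapping, or a string
    "colB - colA" (patsy column names).
    """
    names = fit.coef_names
    if isinstance(contrast, str):
        plus, _, minus = contrast.partition("-")
        mapping = {}
        if plus.strip():
            mapping[plus.strip()] = 1.0
        if minus.strip():
            mapping[minus.strip()] = -1.0
        contrast = mapping
    if isinstance(contrast, Mapping):
        c = np.zeros(len(names))
        for key, wgt in contrast.items():
            if key not in names:
                raise ValueError(
                    f"contrast references unknown coefficient {key!r}; "
                    f"available: {names}"
                )
            c[names.index(key)] = wgt
        return c
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(names),):
        raise ValueError(f"contrast length {c.shape} != {len(names)} coefficients")
    return c


def compare_parameters(
    fit: RegularizedFit,
    contrast,
    log2_scale: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test a contrast of coefficients per feature.

    estimate = c'beta with se from the moderated covariance; the statistic
    is moderated-t with df = residual df + prior df (normal when the prior
    df is infinite).  P-values are Benjamini-Hochberg adjusted across
    features.  ``log2_scale`` rescales natural-log responses so the
    estimate column is an L2FC.
    """
    c = contrast_vector(fit, contrast)
    est = fit.coef @ c
    se = np.sqrt(np.einsum("fij,i,j->f", fit.cov, c, c))
    scale = 1.0 / np.log(2.0) if log2_scale else 1.0
    stat = est / np.maximum(se, SE_FLOOR)
    df = fit.total_df
    if np.isfinite(df) and df > 0:
        pval = 2.0 * stats.t.sf(np.abs(stat), df)
    else:
        pval = 2.0 * stats.norm.sf(np.abs(stat))
    reject, padj, _, _ = multipletests(pval, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({
        "feature": fit.features,
        "estimate": est * scale,
        "se": se * scale,
        "stat": stat,
        "pval": pval,
        "padj": padj,
        "significant": reject,
    })
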