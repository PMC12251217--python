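"""Linear dynamical-systems modeling of RNA flow.

An RNA life-cycle model is a directed graph over RNA species (e.g. premature
-> mature, or nuclear -> cytoplasmic), with rate-constant-labeled edges and
degradation edges to an implicit sink.  Writing u(t) for the vector of
species abundances, the dynamics are

    du/dt = K(k) u + s,

where K collects transfer and outflow rates and s is the synthesis inflow
(rate ``ksyn`` into a single entry species).  At steady state u* solves
K u* + s = 0.  RNA made before the metabolic label was added ("old" RNA)
receives no further synthesis, so it decays as u_old(t) = expm(K t) u*, and
the fraction labeled of species i after labeling for time t is
1 - u_old,i(t) / u*_i.  Measured RNA populations (e.g. whole cell = N + C)
are sums over species subsets, with abundance-weighted fractions.

Kinetic parameters are estimated per feature by maximum likelihood on
Gaussian observations of logit(fraction labeled) (and optionally
log normalized read counts), with standard errors from the inverse Hessian
of the negative log-likelihood at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.special import logit

__all__ = [
    "Edge",
    "DynamicsModel",
    "one_compartment",
    "premature_mature",
    "nuclear_cytoplasmic",
    "solve_old_fraction",
    "steady_state",
    "fit_dynamics",
    "build_observations",
    "average_observations",
    "flag_practical_identifiability",
    "mixing_weights",
    "scales_from_mixing",
    "scales_from_fractions_only",
    "ModelError",
]

SINK = None  # degradation edges point here


class ModelError(ValueError):
    """The model is inadmissible or unidentifiable for the requested fit."""


@dataclass(frozen=True)
class Edge:
    src: str
    dst: str | None  # None = degradation to the sink
    rate: str


@dataclass(frozen=True)
class DynamicsModel:
    """Directed-graph linear ODE model of RNA species.

    ``measurements`` maps each measured RNA population to the subset of
    species it sums over, e.g. {"nuclear": ("N",), "whole_cell": ("N", "C")}.
    """

    species: tuple[str, ...]
    edges: tuple[Edge, ...]
    synthesis_species: str
    measurements: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    synthesis_rate: str = "ksyn"

    def __post_init__(self) -> None:
        if self.synthesis_species not in self.species:
            raise ModelError(f"synthesis entry {self.synthesis_species!r} not a species")
        for e in self.edges:
            if e.src not in self.species:
                raise ModelError(f"edge source {e.src!r} not a species")
            if e.dst is not None and e.dst not in self.species:
                raise ModelError(f"edge target {e.dst!r} not a species")
        for name, subset in self.measurements.items():
            if not subset:
                raise ModelError(f"measurement {name!r} maps to no species")
            unknown = set(subset) - set(self.species)
            if unknown:
                raise ModelError(f"measurement {name!r} references {sorted(unknown)}")
        # connectivity from the synthesis entry point
        reach = {self.synthesis_species}
        frontier = [self.synthesis_species]
        adj: dict[str, list[str]] = {}
        for e in self.edges:
            if e.dst is not None:
                adj.setdefault(e.src, []).append(e.dst)
        while frontier:
            nxt = [d for s in frontier for d in adj.get(s, []) if d not in reach]
            reach.update(nxt)
            frontier = nxt
        if reach != set(self.species):
            raise ModelError(
                f"species {sorted(set(self.species) - reach)} unreachable from synthesis"
            )

    @property
    def rate_names(self) -> tuple[str, ...]:
        """Non-synthesis rate constants, in edge order (unique)."""
        seen: list[str] = []
        for e in self.edges:
            if e.rate not in seen:
                seen.append(e.rate)
        return tuple(seen)

    @property
    def all_rate_names(self) -> tuple[str, ...]:
        return (self.synthesis_rate, *self.rate_names)

    def rate_matrix(self, params: Mapping[str, float]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.species)}
        K = np.zeros((len(self.species),) * 2)
        for e in self.edges:
            k = float(params[e.rate])
            if k < 0:
                raise ModelError(f"rate {e.rate} must be positive, got {k}")
            K[idx[e.src], idx[e.src]] -= k
            if e.dst is not None:
                K[idx[e.dst], idx[e.src]] += k
        return K

    def synthesis_vector(self, params: Mapping[str, float]) -> np.ndarray:
        s = np.zeros(len(self.species))
        s[self.species.index(self.synthesis_species)] = float(
            params.get(self.synthesis_rate, 1.0)
        )
        return s

    def check_admissible(self, params: Mapping[str, float]) -> np.ndarray:
        """Hurwitz check; returns K or raises ModelError."""
        K = self.rate_matrix(params)
        if np.max(np.linalg.eigvals(K).real) >= -1e-12:
            raise ModelError(
                "rate matrix is not Hurwitz (a species has no outflow); "
                "old RNA would not decay"
            )
        return K

    # -- (de)serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        doc = {
            "species": list(self.species),
            "synthesis": {"species": self.synthesis_species,
                          "rate": self.synthesis_rate},
            "edges": [
                {"from": e.src, "to": e.dst if e.dst is not None else "sink",
                 "rate": e.rate}
                for e in self.edges
            ],
            "measurements": {k: list(v) for k, v in self.measurements.items()},
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DynamicsModel":
        doc = yaml.safe_load(Path(path).read_text())
        edges = tuple(
            Edge(e["from"], None if e["to"] in (None, "sink") else e["to"], e["rate"])
            for e in doc["edges"]
        )
        return cls(
            species=tuple(doc["species"]),
            edges=edges,
            synthesis_species=doc["synthesis"]["species"],
            synthesis_rate=doc["synthesis"].get("rate", "ksyn"),
            measurements={k: tuple(v) for k, v in doc.get("measurements", {}).items()},
        )


# -- canonical models ---------------------------------------------------------

def one_compartment() -> DynamicsModel:
    """Mature mRNA synthesized at ksyn, degraded at kdeg."""
    return DynamicsModel(
        species=("M",),
        edges=(Edge("M", SINK, "kdeg"),),
        synthesis_species="M",
        measurements={"total": ("M",)},
    )


def premature_mature() -> DynamicsModel:
    """Premature mRNA processed into mature mRNA, which is degraded."""
    return DynamicsModel(
        species=("P", "M"),
        edges=(Edge("P", "M", "kp"), Edge("M", SINK, "kdeg")),
        synthesis_species="P",
        measurements={"premature": ("P",), "mature": ("M",)},
    )


def nuclear_cytoplasmic(nuclear_degradation: bool = False) -> DynamicsModel:
    """Nuclear RNA exported to the cytoplasm and degraded there.

    With ``nuclear_degradation``, nuclear RNA is additionally degraded in
    the nucleus at kNdeg.
    """
    edges = [Edge("N", "C", "kexp"), Edge("C", SINK, "kdeg")]
    if nuclear_degradation:
        edges.append(Edge("N", SINK, "kNdeg"))
    return DynamicsModel(
        species=("N", "C"),
        edges=tuple(edges),
        synthesis_species="N",
        measurements={"nuclear": ("N",), "cytoplasmic": ("C",),
                      "whole_cell": ("N", "C")},
    )


# ---------------------------------------------------------------------------
# forward solution
# ---------------------------------------------------------------------------

def steady_state(model: DynamicsModel, params: Mapping[str, float]) -> np.ndarray:
    """Steady-state species abundances u* solving K u* + s = 0."""
    K = model.check_admissible(params)
    s = model.synthesis_vector(params)
    return np.linalg.solve(K, -s)


def solve_old_fraction(
    model: DynamicsModel,
    params: Mapping[str, float],
    t: float,
    include_measurements: bool = True,
) -> dict[str, float]:
    """Fraction labeled of every species (and measured population) at time t.

    Pre-existing RNA decays as u_old(t) = expm(K t) u*; fraction labeled of
    species i is 1 - u_old,i(t)/u*_i.  Measured populations are
    abundance-weighted: 1 - sum(u_old over subset)/sum(u* over subset).
    """
    if t < 0:
        raise ValueError("label time must be >= 0")
    K = model.check_admissible(params)
    s = model.synthesis_vector(params)
    ustar = np.linalg.solve(K, -s)
    u_old = expm(K * t) @ ustar
    frac = 1.0 - u_old / ustar
    out = {sp: float(frac[i]) for i, sp in enumerate(model.species)}
    if include_measurements:
        idx = {sp: i for i, sp in enumerate(model.species)}
        for name, subset in model.measurements.items():
            ii = [idx[sp] for sp in subset]
            out[name] = float(1.0 - u_old[ii].sum() / ustar[ii].sum())
    return out


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _predictions(
    model: DynamicsModel,
    params: Mapping[str, float],
    obs: pd.DataFrame,
    scales: Mapping[str, float] | None,
    use_counts: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted (logit fraction, log reads) stacked to match ``obs`` rows."""
    K = model.rate_matrix(params)
    s = model.synthesis_vector(params)
    ustar = np.linalg.solve(K, -s)
    idx = {sp: i for i, sp in enumerate(model.species)}
    pred_lf = np.empty(len(obs))
    pred_lr = np.full(len(obs), np.nan)
    for tl, tl_rows in obs.groupby("tl"):
        u_old = expm(K * float(tl)) @ ustar
        for r in tl_rows.itertuples():
            ii = [idx[sp] for sp in model.measurements[r.measurement]]
            f = 1.0 - u_old[ii].sum() / ustar[ii].sum()
            pred_lf[r.Index] = logit(np.clip(f, 1e-12, 1 - 1e-12))
            if use_counts:
                # scale factors map normalized reads to relative abundance
                # (R * s ~ u*), so the model predicts log R as
                # log(u*) - log(s); the global unit constant is absorbed by
                # the per-feature synthesis rate.
                sc = 1.0 if scales is None else scales[r.measurement]
                pred_lr[r.Index] = np.log(ustar[ii].sum()) - np.log(sc)
    return pred_lf, pred_lr


def _check_structural_identifiability(
    model: DynamicsModel,
    obs: pd.DataFrame,
    scales: Mapping[str, float] | None,
    use_counts: bool,
    rate_names: Sequence[str],
    rng: np.random.Generator,
) -> None:
    """Numeric Jacobian rank check at a random admissible point."""
    x0 = np.log(rng.uniform(0.2, 2.0, size=len(rate_names)))

    def stacked(x: np.ndarray) -> np.ndarray:
        params = dict(zip(rate_names, np.exp(x)))
        params.setdefault(model.synthesis_rate, 1.0)
        lf, lr = _predictions(model, params, obs, scales, use_counts)
        return np.concatenate([lf, lr[~np.isnan(lr)]])

    f0 = stacked(x0)
    if len(f0) < len(rate_names):
        raise ModelError(
            f"{len(rate_names)} parameters but only {len(f0)} observations; "
            "model is structurally unidentifiable"
        )
    J = np.empty((len(f0), len(rate_names)))
    h = 1e-6
    for j in range(len(rate_names)):
        e = np.zeros(len(rate_names))
        e[j] = h
        J[:, j] = (stacked(x0 + e) - stacked(x0 - e)) / (2 * h)
    rank = np.linalg.matrix_rank(J, tol=1e-9)
    if rank < len(rate_names):
        raise ModelError(
            f"model is structurally unidentifiable from these observations: "
            f"Jacobian rank {rank} < {len(rate_names)} parameters"
        )


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


def fit_dynamics(
    model: DynamicsModel,
    observations: pd.DataFrame,
    scales: Mapping[str, float] | None = None,
    use_counts: bool | None = None,
    n_starts: int = 5,
    start_range: tuple[float, float] = (1e-3, 10.0),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-feature maximum-likelihood fit of a linear dynamics model.

    ``observations`` is tidy with columns: feature, measurement, tl,
    logit_fraction, logit_fraction_se, and optionally log_reads,
    log_reads_se (normalized read counts on the log scale).  The likelihood
    is Gaussian on logit(fraction labeled) and, when counts are supplied,
    on log(read counts) against scale-factor-adjusted steady-state
    abundances.  Without counts the synthesis rate is unidentifiable
    (fractions are abundance ratios) and only non-synthesis rates are fit.

    Parameters are log-transformed and optimized by L-BFGS from
    ``n_starts`` log-uniform random starts in ``start_range`` (1/h).
    Standard errors are sqrt(diag(inv(H))) of the negative log-likelihood
    Hessian; a non-positive-definite Hessian falls back to the
    pseudo-inverse and flags the feature.

    Returns one row per feature with log_<rate>, se_log_<rate>, loglik,
    converged and identifiability flags.
    """
    rng = np.random.default_rng(seed)
    if use_counts is None:
        use_counts = "log_reads" in observations.columns
    if use_counts and "log_reads" not in observations.columns:
        raise ValueError("use_counts=True but observations lack log_reads")
    rate_names = list(model.all_rate_names if use_counts else model.rate_names)

    probe = observations[observations["feature"] == observations["feature"].iloc[0]]
    probe = probe.reset_index(drop=True)
    _check_structural_identifiability(model, probe, scales, use_counts, rate_names, rng)

    idx = {sp: i for i, sp in enumerate(model.species)}
    records = []
    for feat, obs in observations.groupby("feature", sort=True):
        obs = obs.reset_index(drop=True)
        lf_obs = obs["logit_fraction"].to_numpy(float)
        lf_se = np.maximum(obs["logit_fraction_se"].to_numpy(float), 1e-6)
        if use_counts:
            lr_obs = obs["log_reads"].to_numpy(float)
            lr_se = np.maximum(obs["log_reads_se"].to_numpy(float), 1e-6)

        # precompute per-row structure so the objective is pure numpy
        tls = np.sort(obs["tl"].unique())
        tl_pos = obs["tl"].map({t: i for i, t in enumerate(tls)}).to_numpy()
        members = [
            np.array([idx[sp] for sp in model.measurements[m]])
            for m in obs["measurement"]
        ]
        log_sc = np.array([
            0.0 if scales is None else np.log(scales[m])
            for m in obs["measurement"]
        ])

        def nll(x: np.ndarray) -> float:
            params = dict(zip(rate_names, np.exp(np.clip(x, -30, 30))))
            params.setdefault(model.synthesis_rate, 1.0)
            try:
                K = model.rate_matrix(params)
                s = model.synthesis_vector(params)
                ustar = np.linalg.solve(K, -s)
                u_old = np.stack([expm(K * t) @ ustar for t in tls])
            except (np.linalg.LinAlgError, FloatingPointError):
                return 1e12
            val = 0.0
            for r in range(len(lf_obs)):
                ii = members[r]
                us = ustar[ii].sum()
                f = 1.0 - u_old[tl_pos[r], ii].sum() / us
                if not (0.0 < f < 1.0) or not np.isfinite(f):
                    f = min(max(f, 1e-12), 1 - 1e-12)
                lf = np.log(f) - np.log1p(-f)
                val += 0.5 * ((lf - lf_obs[r]) / lf_se[r]) ** 2
                if use_counts:
                    lr = np.log(us) - log_sc[r]
                    val += 0.5 * ((lr - lr_obs[r]) / lr_se[r]) ** 2
            if not np.isfinite(val):
                return 1e12
            return float(val)

        best = None
        for i in range(n_starts):
            lo, hi = np.log(start_range[0]), np.log(start_range[1])
            x0 = rng.uniform(lo, hi, size=len(rate_names))
            res = minimize(nll, x0, method="L-BFGS-B")
            if best is None or res.fun < best.fun:
                best = res
        x_hat = best.x
        flag = "" if best.success else "nonconverged"

        H = _numeric_hessian(nll, x_hat)
        H = 0.5 * (H + H.T)
        eigvals, V = np.linalg.eigh(H)
        tol = max(1e-10, 1e-10 * eigvals.max()) if eigvals.max() > 0 else 1e-10
        pos = eigvals > tol
        if pos.all():
            se = np.sqrt(np.diag(np.linalg.inv(H)))
        else:
            # a parameter loading on a zero/negative-curvature direction is
            # unconstrained by the data: its uncertainty is infinite, not 0
            se = np.sqrt((V[:, pos] ** 2 / eigvals[pos]).sum(axis=1))
            null_load = (V[:, ~pos] ** 2).sum(axis=1)
            se[null_load > 1e-8] = np.inf
            flag = (flag + ";" if flag else "") + "singular_hessian"

        rec: dict = {"feature": feat, "loglik": -best.fun,
                     "converged": best.success, "flag": flag}
        for j, name in enumerate(rate_names):
            rec[f"log_{name}"] = x_hat[j]
            rec[f"se_log_{name}"] = se[j]
        records.append(rec)
    return pd.DataFrame.from_records(records)


def build_observations(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    count_dispersion: float = 0.1,
    feature_col: str = "feature",
) -> pd.DataFrame:
    """Assemble the tidy observation table consumed by :func:`fit_dynamics`.

    ``fractions`` carries per-(sample, feature) logit_fraction_labeled and
    its se (mixture output or condition-level averages keyed by a sample
    alias).  ``meta`` maps sample -> measurement, tl and optionally
    ``library`` (samples sequenced from the same physical library, whose
    read counts share a depth).  ``counts`` (sample, feature, n) adds
    log-share read observations normalized within each library; their
    log-scale standard error is sqrt(1/n + count_dispersion), the
    gamma-Poisson (negative binomial) approximation — single-replicate read
    counts are overdispersed relative to Poisson, and understating that
    error lets count noise corrupt the rate-constant attribution.
    """
    cols = ["sample", "measurement", "tl"]
    if "library" in meta.columns:
        cols.append("library")
    obs = fractions.merge(meta[cols], on="sample", how="inner")
    obs = obs.rename(columns={
        "logit_fraction_labeled": "logit_fraction",
        "logit_fraction_labeled_se": "logit_fraction_se",
        feature_col: "feature",
    })
    keep = ["feature", "sample", "measurement", "tl",
            "logit_fraction", "logit_fraction_se"]
    if counts is not None:
        counts = counts.rename(columns={feature_col: "feature"})
        if "library" not in meta.columns:
            meta = meta.assign(library=meta["sample"])
        counts = counts.merge(meta[["sample", "library"]], on="sample")
        # one library depth per (library, tl): samples of a library at the
        # same label time were sequenced together
        counts = counts.merge(meta[["sample", "tl"]], on="sample")
        depth = counts.groupby(["library", "tl"])["n"].transform("sum")
        counts["log_reads"] = np.log(counts["n"]) - np.log(depth)
        counts["log_reads_se"] = np.sqrt(
            1.0 / np.maximum(counts["n"], 1) + count_dispersion
        )
        obs = obs.merge(
            counts[["sample", "feature", "log_reads", "log_reads_se"]],
            on=["sample", "feature"], how="left",
        )
        keep += ["log_reads", "log_reads_se"]
    return obs[keep].dropna(subset=["logit_fraction"]).reset_index(drop=True)


def average_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance average of replicate observations.

    Compartment-flow models integrate information across independent
    samples, so they are fit to condition-level averages per
    (feature, measurement, tl) rather than to single replicates.
    """
    have_counts = "log_reads" in obs.columns

    def combine(g: pd.DataFrame) -> pd.Series:
        w = 1.0 / np.maximum(g["logit_fraction_se"], 1e-6) ** 2
        out = {
            "logit_fraction": float((g["logit_fraction"] * w).sum() / w.sum()),
            "logit_fraction_se": float(np.sqrt(1.0 / w.sum())),
        }
        if have_counts:
            ok = g["log_reads"].notna()
            w2 = 1.0 / np.maximum(g.loc[ok, "log_reads_se"], 1e-6) ** 2
            out["log_reads"] = float((g.loc[ok, "log_reads"] * w2).sum() / w2.sum())
            out["log_reads_se"] = float(np.sqrt(1.0 / w2.sum()))
        return pd.Series(out)

    grouped = (
        obs.groupby(["feature", "measurement", "tl"])
        .apply(combine, include_groups=False)
        .reset_index()
    )
    return grouped


def flag_practical_identifiability(
    fit: pd.DataFrame, se_threshold: float = 1.0
) -> pd.DataFrame:
    """Flag low-confidence parameters (log-scale se above threshold).

    A parameter can be structurally identifiable yet practically
    unidentifiable when the data barely constrain it (e.g. nuclear
    degradation much slower than export); large inverse-Hessian standard
    errors diagnose this.  Features with a singular Hessian are flagged
    regardless of the threshold.
    """
    out = fit.copy()
    se_cols = [c for c in fit.columns if c.startswith("se_log_")]
    singular = out["flag"].str.contains("singular_hessian", na=False)
    for c in se_cols:
        name = c[len("se_log_"):]
        out[f"low_confidence_{name}"] = (out[c] > se_threshold) | singular
    return out


# ---------------------------------------------------------------------------
# scale-factor strategies
# ---------------------------------------------------------------------------

def mixing_weights(
    component_fractions: Mapping[str, float],
    combined_fraction: float,
    degeneracy_tol: float = 1e-3,
) -> dict[str, float]:
    """Abundance shares of compartments from global labeled fractions.

    Models the combined pool's global fraction labeled as a convex
    combination of the component compartments': f_combined = sum_i a_i f_i
    with sum a_i = 1, a_i >= 0.  With two compartments this is a closed-form
    linear solve; with more it is a constrained least-squares problem.
    """
    names = list(component_fractions)
    f = np.array([component_fractions[k] for k in names], dtype=float)
    if np.ptp(f) < degeneracy_tol:
        raise ModelError(
            "compartment global fractions are (nearly) equal "
            f"(spread {np.ptp(f):.2e} < {degeneracy_tol}); "
            "the mixing system is degenerate"
        )
    if len(names) == 2:
        a0 = (combined_fraction - f[1]) / (f[0] - f[1])
        alpha = np.array([a0, 1.0 - a0])
    else:
        res = minimize(
            lambda a: (a @ f - combined_fraction) ** 2,
            np.full(len(names), 1.0 / len(names)),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * len(names),
            constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
        )
        alpha = res.x
    if np.any(alpha < 0) or np.any(alpha > 1):
        warnings.warn(
            f"mixing weights {dict(zip(names, alpha))} fall outside [0, 1]; "
            "clipping — check that the combined sample really mixes these "
            "compartments"
        )
        alpha = np.clip(alpha, 0.0, 1.0)
        alpha = alpha / alpha.sum()
    return dict(zip(names, alpha))


def scales_from_mixing(
    component_fractions: Mapping[str, float],
    combined_fraction: float,
    read_shares: Mapping[str, float],
    reference: str | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Scale factors from the fraction-labeled mixing model.

    ``read_shares`` gives each compartment's share of normalized reads.
    The mixing weight alpha_i is compartment i's share of molecules in the
    combined pool, so scale_i = alpha_i / read_share_i maps normalized reads
    to relative abundance; the reference compartment (first by default) is
    fixed at 1.  Returns (mixing weights, scale factors).
    """
    alpha = mixing_weights(component_fractions, combined_fraction)
    names = list(alpha)
    reference = reference or names[0]
    shares = np.array([read_shares[k] for k in names], dtype=float)
    shares = shares / shares.sum()
    raw = {k: alpha[k] / sh for k, sh in zip(names, shares)}
    scales = {k: v / raw[reference] for k, v in raw.items()}
    return alpha, scales


def scales_from_fractions_only(
    model: DynamicsModel,
    fit_without_counts: pd.DataFrame,
    read_shares: Mapping[str, float],
    reference: str | None = None,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Scale factors inferred from non-synthesis rate estimates alone.

    Because the synthesis rate is shared by all species of a feature, the
    fitted non-synthesis rates determine the expected steady-state abundance
    ratios across single-species measurements; comparing those ratios with
    observed normalized-read shares yields scale factors.  Uses the median
    fitted rates across features.  Typically yields lower-confidence
    downstream estimates than spike-ins or the mixing model; the returned
    fit is flagged accordingly.
    """
    single = {
        name: subset[0]
        for name, subset in model.measurements.items()
        if len(subset) == 1 and name in read_shares
    }
    if len(single) < 2:
        raise ModelError(
            "need >= 2 single-species measurements with read shares to infer "
            "scale factors from fractions alone"
        )
    med = {
        r: float(np.exp(fit_without_counts[f"log_{r}"].median()))
        for r in model.rate_names
    }
    med[model.synthesis_rate] = 1.0
    ustar = steady_state(model, med)
    idx = {sp: i for i, sp in enumerate(model.species)}
    names = list(single)
    reference = reference or names[0]
    ab = np.array([ustar[idx[single[k]]] for k in names])
    ab = ab / ab.sum()
    shares = np.array([read_shares[k] for k in names], dtype=float)
    shares = shares / shares.sum()
    raw = {k: a / s for k, a, s in zip(names, ab, shares)}
    scales = {k: v / raw[reference] for k, v in raw.items()}
    flagged = fit_without_counts.copy()
    flagged["flag"] = flagged["flag"].where(
        flagged["flag"].str.len() > 0, ""
    ) + ";scales_from_fractions_only"
    flagged["flag"] = flagged["flag"].str.lstrip(";")
    return scales, flagged
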