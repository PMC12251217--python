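"""Seeded generators of synthetic NR-seq data with known ground truth.

Every generator emits a canonical cB table together with a :class:`SimTruth`
record (true fractions, mutation rates, rate constants, read-level origin
labels and the seed), so that every estimation stage can be tested by
parameter recovery without external data.

Default read composition: the number of mutable nucleotides per read is
Poisson(25) per mutation type (reads with zero mutable nucleotides are legal
and exercised), and reads per feature are negative binomial with dispersion
0.1 around the configured mean, emulating realistic coverage spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cb import CBTable, mutation_columns
from .dynamics import DynamicsModel, solve_old_fraction, steady_state
from .mixture import LABELED, PopulationDesign, two_component

__all__ = [
    "SimConfig",
    "DynamicsSimConfig",
    "SimTruth",
    "simulate_one_rep",
    "simulate_multilabel",
    "simulate_dynamics",
    "apply_dropout",
]


@dataclass
class SimConfig:
    """Shared knobs for the read-level simulators.

    theta may be a scalar (same fraction labeled everywhere), "uniform"
    (per-feature U(theta_range)), or an explicit array of length n_features
    (or n_features x P for multi-label designs, rows summing to 1).
    feature_p_sd switches on feature-to-feature variation of the labeled
    mutation rate: per feature, logit(p_labeled) ~ N(logit(global), sd).
    """

    n_features: int = 100
    reads_per_feature: float = 500
    reads_law: str = "nb"  # "nb" (dispersion nb_dispersion) or "fixed"
    nb_dispersion: float = 0.1
    nn_mean: Mapping[str, float] | float = 25.0
    p_labeled: Mapping[str, float] | float = 0.05
    p_unlabeled: Mapping[str, float] | float = 0.002
    design: PopulationDesign = field(default_factory=two_component)
    theta: float | str | np.ndarray = "uniform"
    theta_range: tuple[float, float] = (0.05, 0.95)
    feature_p_sd: float | None = None
    sample: str = "sample1"
    tl: float = 2.0
    seed: int = 1

    def rate_for(self, which: Mapping[str, float] | float, mut: str) -> float:
        return float(which[mut]) if isinstance(which, Mapping) else float(which)


@dataclass
class SimTruth:
    """Ground truth emitted beside every simulated dataset.

    ``features`` has one row per (sample, feature) with the true theta
    (one column per population), true p_labeled and read count.  ``reads``
    is the pre-aggregation read-level table (population origin per read),
    retained so that label-dependent thinning (dropout) can be applied after
    the fact.
    """

    features: pd.DataFrame
    reads: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.features.to_csv(path, sep="\t", index=False)


def _logit(p: np.ndarray | float) -> np.ndarray:
    return np.log(p) - np.log1p(-np.asarray(p, dtype=float))


def _expit(x: np.ndarray | float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _draw_read_counts(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    mean = float(cfg.reads_per_feature)
    if cfg.reads_law == "fixed":
        return np.full(n, int(round(mean)), dtype=np.int64)
    if cfg.reads_law != "nb":
        raise ValueError(f"unknown reads law {cfg.reads_law!r}")
    # NB with mean mu, dispersion a: var = mu + a mu^2 (gamma-Poisson mixture)
    a = cfg.nb_dispersion
    lam = rng.gamma(shape=1.0 / a, scale=a * mean, size=n)
    counts = rng.poisson(lam)
    return np.maximum(counts, 1).astype(np.int64)


def _theta_matrix(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """n_features x P matrix of true population fractions (rows sum to 1)."""
    P = cfg.design.n_populations
    if isinstance(cfg.theta, np.ndarray):
        th = np.asarray(cfg.theta, dtype=float)
        if th.ndim == 1:
            if P != 2:
                raise ValueError("1-D theta array only valid for two-population designs")
            th = np.column_stack([th, 1.0 - th])
        if th.shape != (cfg.n_features, P):
            raise ValueError(f"theta array must be ({cfg.n_features}, {P})")
    elif cfg.theta == "uniform":
        lo, hi = cfg.theta_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("theta_range must lie in [0, 1]")
        if P == 2:
            t = rng.uniform(lo, hi, size=cfg.n_features)
            th = np.column_stack([t, 1.0 - t])
        else:
            # labeled shares uniform in range, split uniformly among the
            # P-1 labeled populations via a Dirichlet draw
            t = rng.uniform(lo, hi, size=cfg.n_features)
            parts = rng.dirichlet(np.ones(P - 1), size=cfg.n_features)
            th = np.column_stack([parts * t[:, None], 1.0 - t])
    else:
        t = float(cfg.theta)
        if not 0 <= t <= 1:
            raise ValueError("theta must be a probability")
        if P == 2:
            th = np.tile([t, 1.0 - t], (cfg.n_features, 1))
        else:
            th = np.tile([*([t / (P - 1)] * (P - 1)), 1.0 - t], (cfg.n_features, 1))
    if np.any(th < -1e-12) or np.any(np.abs(th.sum(axis=1) - 1) > 1e-9):
        raise ValueError("theta rows must be probabilities summing to 1")
    return np.clip(th, 0.0, 1.0)


def _simulate_reads(
    cfg: SimConfig,
    rng: np.random.Generator,
    theta: np.ndarray,
    p_labeled_feat: np.ndarray | None = None,
) -> pd.DataFrame:
    """Read-level table: feature, population, nN/nM per mutation type."""
    design = cfg.design
    P = design.n_populations
    feats = np.array([f"feature{i + 1}" for i in range(cfg.n_features)])
    counts = _draw_read_counts(cfg, rng, cfg.n_features)

    feat_col = np.repeat(feats, counts)
    feat_idx = np.repeat(np.arange(cfg.n_features), counts)
    total = int(counts.sum())

    # population origin per read
    u = rng.random(total)
    cum = np.cumsum(theta, axis=1)[feat_idx]
    pop = (u[:, None] > cum).sum(axis=1)

    data = {"sample": cfg.sample, "feature": feat_col}
    for t_i, mut in enumerate(design.mutation_types):
        nn_col, nm_col = mutation_columns(mut)
        nN = rng.poisson(cfg.rate_for(cfg.nn_mean, mut), size=total)
        pl = cfg.rate_for(cfg.p_labeled, mut)
        pu = cfg.rate_for(cfg.p_unlabeled, mut)
        p = np.where(
            np.array([row[t_i] == LABELED for row in design.populations])[pop],
            pl, pu,
        )
        if p_labeled_feat is not None:
            is_lab = np.array([row[t_i] == LABELED for row in design.populations])[pop]
            p = np.where(is_lab, p_labeled_feat[feat_idx], p)
        nM = rng.binomial(nN, p)
        data[nn_col] = nN
        data[nm_col] = nM
    data["population"] = pop
    return pd.DataFrame(data)


def _aggregate(reads: pd.DataFrame, cfg: SimConfig) -> CBTable:
    cols = [c for c in reads.columns if c != "population"]
    df = reads[cols].copy()
    df["n"] = 1
    return CBTable(df, cfg.design.mutation_types, ("feature",))


def simulate_one_rep(cfg: SimConfig) -> tuple[CBTable, SimTruth]:
    """Simulate one sample under a (by default two-population) mixture.

    Per feature: reads are assigned to populations by the true theta; per
    mutation type, nN ~ Poisson(nn_mean) and nM | population ~
    Binomial(nN, rate), where the labeled rate is feature-specific when
    ``feature_p_sd`` is set (logit-normal around the global rate).
    """
    rng = np.random.default_rng(cfg.seed)
    theta = _theta_matrix(cfg, rng)

    p_feat = None
    if cfg.feature_p_sd is not None:
        if len(cfg.design.mutation_types) != 1:
            raise ValueError("feature-specific p_labeled requires a single-label design")
        mut = cfg.design.mutation_types[0]
        mu = _logit(cfg.rate_for(cfg.p_labeled, mut))
        p_feat = _expit(rng.normal(mu, cfg.feature_p_sd, size=cfg.n_features))

    reads = _simulate_reads(cfg, rng, theta, p_feat)
    cb = _aggregate(reads, cfg)

    feat_names = [f"feature{i + 1}" for i in range(cfg.n_features)]
    truth = pd.DataFrame({"sample": cfg.sample, "feature": feat_names})
    for p_i, name in enumerate(cfg.design.names):
        truth[f"theta_{name}"] = theta[:, p_i]
    if cfg.design.n_populations == 2:
        truth["theta"] = theta[:, 0]
    if p_feat is not None:
        truth["p_labeled"] = p_feat
    truth["n_reads"] = reads.groupby("feature").size().reindex(feat_names).to_numpy()
    return cb, SimTruth(
        features=truth, reads=reads, seed=cfg.seed,
        params={"p_labeled": cfg.p_labeled, "p_unlabeled": cfg.p_unlabeled,
                "tl": cfg.tl},
    )


def simulate_multilabel(cfg: SimConfig) -> tuple[CBTable, SimTruth]:
    """Simulate a multi-label sample (e.g. TILAC).

    Reads are drawn from exactly the admissible populations of
    ``cfg.design``; structurally excluded populations (such as the
    doubly-labeled population in TILAC) receive zero reads.
    """
    if cfg.design.n_populations < 2:
        raise ValueError("multi-label simulation needs >= 2 admissible populations")
    return simulate_one_rep(cfg)


@dataclass
class DynamicsSimConfig:
    """Simulation of measurements generated by a linear dynamics model.

    Per feature, each non-synthesis rate is drawn log-uniformly from
    ``rate_ranges`` (1/h); the synthesis rate sets the scale of read counts.
    For each label time and measured population a sample named
    ``<measurement>_tl<tl>`` is emitted whose true fraction labeled comes
    from the model's analytic solution and whose expected read count is
    proportional to the measured steady-state abundance.
    """

    model: DynamicsModel = None  # required
    rate_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    tls: Sequence[float] = (1.0, 4.0)
    n_features: int = 100
    reads_per_feature: float = 500
    nn_mean: float = 25.0
    p_labeled: float = 0.05
    p_unlabeled: float = 0.002
    libraries: Mapping[str, Sequence[str]] | None = None
    n_reps: int = 1
    count_dispersion: float = 0.1
    seed: int = 1

    def draw_rates(self, rng: np.random.Generator) -> pd.DataFrame:
        cols = {}
        for r in self.model.all_rate_names:
            lo, hi = self.rate_ranges.get(r, (0.1, 2.0))
            cols[r] = np.exp(rng.uniform(np.log(lo), np.log(hi), self.n_features))
        return pd.DataFrame(cols)


def simulate_dynamics(cfg: DynamicsSimConfig) -> tuple[CBTable, pd.DataFrame, SimTruth]:
    """Simulate cB data for every (measurement, label time) of a model.

    Returns (cb, meta, truth).  meta has one row per emitted sample with its
    measurement and label time.  truth.features records the true rates and
    the true fraction labeled per measurement and label time
    (columns theta_<measurement>_tl<tl>).
    """
    model = cfg.model
    if model is None:
        raise ValueError("a DynamicsModel is required")
    rng = np.random.default_rng(cfg.seed)
    rates = cfg.draw_rates(rng)
    feat_names = [f"feature{i + 1}" for i in range(cfg.n_features)]
    idx = {sp: i for i, sp in enumerate(model.species)}

    # per feature: theta per (measurement, tl) and measured abundance share
    theta_cols: dict[str, np.ndarray] = {
        f"theta_{m}_tl{tl:g}": np.empty(cfg.n_features)
        for m in model.measurements for tl in cfg.tls
    }
    abundance = {m: np.empty(cfg.n_features) for m in model.measurements}
    for i in range(cfg.n_features):
        params = rates.iloc[i].to_dict()
        ustar = steady_state(model, params)
        for m, subset in model.measurements.items():
            abundance[m][i] = ustar[[idx[sp] for sp in subset]].sum()
        for tl in cfg.tls:
            sol = solve_old_fraction(model, params, tl)
            for m in model.measurements:
                theta_cols[f"theta_{m}_tl{tl:g}"][i] = sol[m]

    # reads: within a library (measurements sequenced together, e.g.
    # premature + mature RNA of a total-RNA sample) expected counts are
    # proportional to steady-state abundance across all member
    # (feature, measurement) pairs; each (library, tl) has its own depth
    libraries = cfg.libraries or {m: (m,) for m in model.measurements}
    frames = []
    reads_frames = []
    meta_rows = []
    for lib, members in libraries.items():
        members = tuple(members)
        lib_total = sum(abundance[m].sum() for m in members)
        depth = cfg.reads_per_feature * cfg.n_features * len(members)
        for tl in cfg.tls:
            for m, rep in ((m, r) for m in members
                           for r in range(1, cfg.n_reps + 1)):
                sample = (f"{m}_tl{tl:g}" if cfg.n_reps == 1
                          else f"{m}_tl{tl:g}_rep{rep}")
                meta_rows.append({"sample": sample, "measurement": m,
                                  "tl": tl, "rep": rep,
                                  "library": f"{lib}" if cfg.n_reps == 1
                                  else f"{lib}_rep{rep}"})
                th = np.clip(theta_cols[f"theta_{m}_tl{tl:g}"], 0.0, 1.0)
                means = abundance[m] / lib_total * depth
                a = cfg.count_dispersion
                lam = (rng.gamma(1.0 / a, a * means) if a > 0 else means)
                counts = np.maximum(rng.poisson(lam), 1)
                feat_idx = np.repeat(np.arange(cfg.n_features), counts)
                total = int(counts.sum())
                u = rng.random(total)
                labeled = u < th[feat_idx]
                nN = rng.poisson(cfg.nn_mean, size=total)
                nM = rng.binomial(nN, np.where(labeled, cfg.p_labeled,
                                               cfg.p_unlabeled))
                nn_col, nm_col = mutation_columns("TC")
                reads = pd.DataFrame({
                    "sample": sample,
                    "feature": np.array(feat_names)[feat_idx],
                    nn_col: nN, nm_col: nM,
                    "population": np.where(labeled, 0, 1),
                })
                reads_frames.append(reads)
                cbd = reads.drop(columns="population").copy()
                cbd["n"] = 1
                frames.append(cbd)

    all_reads = pd.concat(reads_frames, ignore_index=True)
    cb = CBTable(pd.concat(frames, ignore_index=True), ("TC",), ("feature",))
    meta = pd.DataFrame(meta_rows)
    truth_feat = pd.DataFrame({"feature": feat_names})
    for r in model.all_rate_names:
        truth_feat[r] = rates[r].to_numpy()
    for cname, vals in theta_cols.items():
        truth_feat[cname] = vals
    for m in model.measurements:
        truth_feat[f"abundance_{m}"] = abundance[m]
    truth = SimTruth(features=truth_feat, reads=all_reads, seed=cfg.seed,
                     params={"tls": list(cfg.tls)})
    return cb, meta, truth


def apply_dropout(
    cb: CBTable,
    truth: SimTruth,
    d: float,
    samples: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[CBTable, SimTruth]:
    """Thin labeled-origin reads: each retained with probability 1/(1+d).

    Emulates label-dependent loss of labeled RNA during library
    preparation.  Unlabeled-origin reads are untouched.  Operates on the
    read-level origin table carried in ``truth``; returns the thinned cB and
    an updated truth whose provenance records d.
    """
    if d < 0:
        raise ValueError("dropout parameter d must be >= 0")
    reads = truth.reads
    if d == 0:
        return cb, truth
    rng = np.random.default_rng(seed)
    unlabeled_pop = len(truth_design_names(truth, cb)) - 1
    is_labeled = reads["population"] != unlabeled_pop
    in_scope = (
        reads["sample"].isin(samples) if samples is not None
        else pd.Series(True, index=reads.index)
    )
    keep = (~(is_labeled & in_scope)) | (rng.random(len(reads)) < 1.0 / (1.0 + d))
    thinned = reads[keep].reset_index(drop=True)
    cbd = thinned.drop(columns="population").copy()
    cbd["n"] = 1
    new_cb = CBTable(cbd, cb.mutation_types, cb.feature_cols)
    new_truth = SimTruth(
        features=truth.features, reads=thinned, seed=truth.seed,
        params={**truth.params, "dropout": d, "dropout_samples": list(samples or [])},
    )
    return new_cb, new_truth


def truth_design_names(truth: SimTruth, cb: CBTable) -> list[str]:
    """Population names implied by a truth table (unlabeled is last)."""
    names = [c[len("theta_"):] for c in truth.features.columns
             if c.startswith("theta_") and c != "theta" and "_tl" not in c]
    if names:
        return names
    return ["labeled", "unlabeled"]
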