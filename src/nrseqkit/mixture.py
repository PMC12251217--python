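"""Binomial mixture modeling of NR-seq mutational data.

Each sequencing read carries, for every modeled mutation type t, a count of
mutable reference nucleotides nN[t] and a count of observed mutations nM[t].
Conditional on the (latent) mutational population the read belongs to, nM[t]
is Binomial(nN[t], rate[t]) independently across types, where rate[t] is
either the labeled-read rate p_labeled[t] or the background rate
p_unlabeled[t].  A feature's reads are a mixture over P admissible
populations with proportions theta (the "fraction labeled" vector).

Estimation is two-step:

1. :func:`estimate_global_rates` fits, per sample and per mutation type
   independently, a two-component mixture to all reads pooled across
   features, yielding sample-wide p_labeled / p_unlabeled (EM).  With
   unlabeled control samples, p_unlabeled can instead be the pooled
   single-binomial MLE and held fixed (``pold_from_nolabel``).
2. :func:`estimate_fractions` maximizes, per feature, the mixture likelihood
   over theta on the simplex with a weakly informative logit-normal prior
   (prior-penalized maximum likelihood), reporting logit-scale standard
   errors from the observed information.

:func:`cutoff_estimator` implements the naive mutation-count-cutoff
classifier as a biased comparator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logit, logsumexp

from .cb import CBTable, mutation_columns

__all__ = [
    "PopulationDesign",
    "GlobalRates",
    "read_loglik",
    "estimate_global_rates",
    "estimate_fractions",
    "cutoff_estimator",
    "two_component",
    "tilac",
    "full_factorial",
]

P_FLOOR = 1e-12  # probabilities are clamped to [P_FLOOR, 1-P_FLOOR] inside logs
HESSIAN_FALLBACK_SD = 2.0  # conservative logit-scale sd when curvature is singular

LABELED = "labeled"
UNLABELED = "unlabeled"


# ---------------------------------------------------------------------------
# population designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationDesign:
    """P populations x T mutation types table of component rates.

    ``populations[p][t]`` is either ``"labeled"`` or ``"unlabeled"``,
    selecting which sample-wide rate applies to mutation type
    ``mutation_types[t]`` in population p.  The all-unlabeled population must
    be present (pre-existing RNA always exists); designs may exclude other
    populations (e.g. TILAC has no doubly-labeled reads).
    """

    mutation_types: tuple[str, ...]
    populations: tuple[tuple[str, ...], ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("a design needs at least one population")
        T = len(self.mutation_types)
        for row in self.populations:
            if len(row) != T:
                raise ValueError("population row length != number of mutation types")
            for cell in row:
                if cell not in (LABELED, UNLABELED):
                    raise ValueError(f"population cell must reference a rate, got {cell!r}")
        if (UNLABELED,) * T not in self.populations:
            raise ValueError("the all-unlabeled population must be admissible")
        if len(self.names) != len(self.populations):
            raise ValueError("one name per population required")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def rate_matrix(self, rates: "GlobalRates", sample: str) -> np.ndarray:
        """P x T matrix of per-nucleotide mutation probabilities for a sample."""
        R = np.empty((self.n_populations, len(self.mutation_types)))
        for t, mut in enumerate(self.mutation_types):
            pl, pu = rates.rates(sample, mut)
            for p, row in enumerate(self.populations):
                R[p, t] = pl if row[t] == LABELED else pu
        return R


def two_component(mutation_type: str = "TC") -> PopulationDesign:
    """Standard single-label design: labeled vs unlabeled reads."""
    return PopulationDesign(
        mutation_types=(mutation_type,),
        populations=((LABELED,), (UNLABELED,)),
        names=(LABELED, UNLABELED),
    )


def tilac(mutation_types: tuple[str, str] = ("TC", "GA")) -> PopulationDesign:
    """Dual-label mix-and-match design (TILAC).

    s4U-fed cells are mixed with s6G-fed cells, so reads are high in T-to-C
    mutations, or high in G-to-A mutations, or background in both — the
    doubly-high population is structurally absent.
    """
    t1, t2 = mutation_types
    return PopulationDesign(
        mutation_types=(t1, t2),
        populations=(
            (LABELED, UNLABELED),
            (UNLABELED, LABELED),
            (UNLABELED, UNLABELED),
        ),
        names=(f"{t1}_labeled", f"{t2}_labeled", UNLABELED),
    )


def full_factorial(mutation_types: Sequence[str]) -> PopulationDesign:
    """All 2^T label/background combinations (unlabeled population last)."""
    rows = [r for r in product((LABELED, UNLABELED), repeat=len(mutation_types))]
    rows.sort(key=lambda r: sum(c == LABELED for c in r), reverse=True)
    names = tuple(
        "_".join(m for m, c in zip(mutation_types, r) if c == LABELED) or UNLABELED
        for r in rows
    )
    return PopulationDesign(tuple(mutation_types), tuple(rows), names)


# ---------------------------------------------------------------------------
# global rates
# ---------------------------------------------------------------------------

@dataclass
class GlobalRates:
    """Sample-wide mutation rates per mutation type.

    ``table`` is indexed by (sample, mutation_type) with columns p_labeled,
    p_unlabeled, mixing (global labeled fraction from the pooled fit),
    converged, flag.
    """

    table: pd.DataFrame
    pold_from_nolabel: bool = False

    def rates(self, sample: str, mutation_type: str) -> tuple[float, float]:
        row = self.table.loc[(sample, mutation_type)]
        return float(row["p_labeled"]), float(row["p_unlabeled"])

    def logit_p_labeled(self, sample: str, mutation_type: str) -> float:
        return float(logit(self.rates(sample, mutation_type)[0]))

    @classmethod
    def from_values(
        cls,
        samples: Iterable[str],
        mutation_types: Iterable[str],
        p_labeled: float | Mapping[str, float],
        p_unlabeled: float | Mapping[str, float],
    ) -> "GlobalRates":
        """Build known-rate tables (simulations, worked examples)."""
        rows = []
        for s in samples:
            for t in mutation_types:
                pl = p_labeled[t] if isinstance(p_labeled, Mapping) else p_labeled
                pu = p_unlabeled[t] if isinstance(p_unlabeled, Mapping) else p_unlabeled
                rows.append((s, t, pl, pu, np.nan, True, ""))
        df = pd.DataFrame(
            rows,
            columns=["sample", "mutation_type", "p_labeled", "p_unlabeled",
                     "mixing", "converged", "flag"],
        ).set_index(["sample", "mutation_type"])
        return cls(df)


def _clamp(p: np.ndarray | float) -> np.ndarray:
    return np.clip(p, P_FLOOR, 1.0 - P_FLOOR)


def binom_logpmf(nM, nN, p):
    """log Binomial pmf via log-gamma; p clamped away from {0, 1}."""
    nM = np.asarray(nM, dtype=float)
    nN = np.asarray(nN, dtype=float)
    p = _clamp(np.asarray(p, dtype=float))
    return (
        gammaln(nN + 1.0)
        - gammaln(nM + 1.0)
        - gammaln(nN - nM + 1.0)
        + nM * np.log(p)
        + (nN - nM) * np.log1p(-p)
    )


def read_loglik(
    nM: Sequence[float], nN: Sequence[float], rates: Sequence[float]
) -> float:
    """Log-probability of one read's mutation counts under given rates.

    The read likelihood is the product over mutation types of the binomial
    pmf at (nM[t]; nN[t], rates[t]); types are independent by construction.
    """
    nM = np.atleast_1d(np.asarray(nM, dtype=float))
    nN = np.atleast_1d(np.asarray(nN, dtype=float))
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(nM > nN) or np.any(nM < 0):
        raise ValueError("require 0 <= nM <= nN for every mutation type")
    return float(np.sum(binom_logpmf(nM, nN, rates)))


def _em_two_component(
    nM: np.ndarray,
    nN: np.ndarray,
    w: np.ndarray,
    p_labeled0: float = 0.05,
    p_unlabeled0: float = 0.002,
    mixing0: float = 0.5,
    fix_unlabeled: float | None = None,
    max_iter: int = 5000,
    tol: float = 1e-10,
) -> tuple[float, float, float, bool]:
    """EM for the pooled read-level two-component binomial mixture.

    Rows are unique (nM, nN) signatures with multiplicities ``w``.  Returns
    (p_labeled, p_unlabeled, mixing, converged), components ordered so the
    larger rate is "labeled".
    """
    p1, p0, pi = p_labeled0, p_unlabeled0, mixing0
    if fix_unlabeled is not None:
        p0 = fix_unlabeled
    ll_prev = -np.inf
    converged = False
    W = w.sum()
    prev = (p1, p0, pi)
    for _ in range(max_iter):
        l1 = binom_logpmf(nM, nN, p1) + np.log(pi)
        l0 = binom_logpmf(nM, nN, p0) + np.log1p(-pi)
        m = np.maximum(l1, l0)
        denom = m + np.log(np.exp(l1 - m) + np.exp(l0 - m))
        r = np.exp(l1 - denom)  # responsibility of the labeled component
        pi = float(np.clip((w * r).sum() / W, 1e-8, 1 - 1e-8))
        wr = w * r
        p1 = float(_clamp((wr * nM).sum() / max((wr * nN).sum(), P_FLOOR)))
        if fix_unlabeled is None:
            w0 = w * (1.0 - r)
            p0 = float(_clamp((w0 * nM).sum() / max((w0 * nN).sum(), P_FLOOR)))
        ll = float((w * denom).sum())
        delta = max(abs(p1 - prev[0]), abs(p0 - prev[1]), abs(pi - prev[2]))
        if abs(ll - ll_prev) < tol * (1.0 + abs(ll)) or delta < 1e-12:
            converged = True
            break
        ll_prev = ll
        prev = (p1, p0, pi)
    if fix_unlabeled is None and p0 > p1:
        p1, p0, pi = p0, p1, 1.0 - pi
    return p1, p0, pi, converged


def estimate_global_rates(
    cb: CBTable,
    mutation_types: Sequence[str] | None = None,
    controls: Sequence[str] | None = None,
    min_reads: int = 1000,
    init: tuple[float, float, float] = (0.05, 0.002, 0.5),
) -> GlobalRates:
    """Fit sample-wide p_labeled / p_unlabeled per mutation type.

    Pools all reads of a sample across features and fits a two-component
    binomial mixture per mutation type independently (EM, initialized at
    p_labeled=0.05, p_unlabeled=0.002, mixing=0.5).  If ``controls`` names
    unlabeled samples, p_unlabeled is the closed-form single-binomial MLE
    over the pooled control reads and is held fixed for all other samples.

    Raises if any modeled sample has fewer than ``min_reads`` reads.
    """
    mutation_types = tuple(mutation_types or cb.mutation_types)
    df = cb.data
    controls = list(controls or [])

    fixed_p0: dict[str, float] = {}
    if controls:
        ctrl = df[df["sample"].isin(controls)]
        if not len(ctrl):
            raise ValueError(f"no reads found for control samples {controls}")
        for t in mutation_types:
            nn, nm = mutation_columns(t)
            tot_nN = float((ctrl[nn] * ctrl["n"]).sum())
            if tot_nN == 0:
                raise ValueError(f"control samples have no mutable {nn} nucleotides")
            fixed_p0[t] = float(_clamp((ctrl[nm] * ctrl["n"]).sum() / tot_nN))

    rows = []
    labeled_samples = [s for s in cb.samples if s not in controls]
    for s in labeled_samples:
        sub = df[df["sample"] == s]
        n_reads = int(sub["n"].sum())
        if n_reads < min_reads:
            raise ValueError(
                f"sample {s!r} has only {n_reads} reads "
                f"(< {min_reads} required for a stable global fit)"
            )
        for t in mutation_types:
            nn, nm = mutation_columns(t)
            agg = sub.groupby([nm, nn])["n"].sum().reset_index()
            p1, p0, pi, conv = _em_two_component(
                agg[nm].to_numpy(float),
                agg[nn].to_numpy(float),
                agg["n"].to_numpy(float),
                *init,
                fix_unlabeled=fixed_p0.get(t),
            )
            flag = ""
            if p1 <= 10 * P_FLOOR:
                flag = "pinned_low"
                warnings.warn(
                    f"p_labeled for sample {s!r}, type {t} pinned at the lower "
                    "bound (no labeled signal?)"
                )
            elif p1 <= p0 * (1 + 1e-9):
                flag = "rate_tie"
                warnings.warn(
                    f"labeled and unlabeled rates indistinguishable for {s!r}/{t}"
                )
            if not conv:
                warnings.warn(f"global-rate EM did not converge for {s!r}/{t}")
            rows.append((s, t, p1, p0, pi, conv, flag))
    out = pd.DataFrame(
        rows,
        columns=["sample", "mutation_type", "p_labeled", "p_unlabeled",
                 "mixing", "converged", "flag"],
    ).set_index(["sample", "mutation_type"])
    return GlobalRates(out, pold_from_nolabel=bool(controls))


# ---------------------------------------------------------------------------
# per-feature fraction estimation
# ---------------------------------------------------------------------------

def _population_logliks(
    sub: pd.DataFrame, design: PopulationDesign, R: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rows x P matrix of per-read log-likelihoods plus row weights."""
    P = design.n_populations
    ll = np.zeros((len(sub), P))
    for t, mut in enumerate(design.mutation_types):
        nn, nm = mutation_columns(mut)
        nM = sub[nm].to_numpy(float)[:, None]
        nN = sub[nn].to_numpy(float)[:, None]
        ll += binom_logpmf(nM, nN, R[:, t][None, :])
    return ll, sub["n"].to_numpy(float)


def _fit_theta(
    ll: np.ndarray,
    w: np.ndarray,
    prior_sd: float | None,
    n_starts: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    """Maximize the penalized mixture likelihood over the theta simplex.

    theta is parameterized by P-1 free logits a (multinomial logit with the
    last population as reference); the optional prior is N(0, prior_sd) on
    each free coordinate.  Returns (theta, a_hat, se(a), flag).
    """
    P = ll.shape[1]
    if P == 1:
        return np.array([1.0]), np.zeros(0), np.zeros(0), ""

    def unpack(a: np.ndarray) -> np.ndarray:
        z = np.concatenate([a, [0.0]])
        z = z - logsumexp(z)
        return np.exp(z)

    def negloglik(a: np.ndarray) -> tuple[float, np.ndarray]:
        theta = unpack(a)
        with np.errstate(divide="ignore"):
            log_theta = np.log(np.maximum(theta, P_FLOOR))
        row_ll = logsumexp(ll + log_theta[None, :], axis=1)
        post = np.exp(ll + log_theta[None, :] - row_ll[:, None])
        f = -float((w * row_ll).sum())
        g = -(w[:, None] * (post - theta[None, :])).sum(axis=0)[:-1]
        if prior_sd is not None:
            f += 0.5 * float(a @ a) / prior_sd**2
            g = g + a / prior_sd**2
        return f, g

    starts = [np.zeros(P - 1)]
    for k in range(1, n_starts):
        starts.append(np.full(P - 1, (-1.0) ** k * 2.0))
    best = None
    for a0 in starts:
        res = minimize(negloglik, a0, jac=True, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    a_hat = best.x
    flag = "" if best.success else "nonconverged"

    # observed information: central finite differences of the gradient
    h = 1e-5
    K = P - 1
    H = np.zeros((K, K))
    for j in range(K):
        e = np.zeros(K)
        e[j] = h
        _, gp = negloglik(a_hat + e)
        _, gm = negloglik(a_hat - e)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
        if not np.all(np.isfinite(se)) or np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        se = np.full(K, HESSIAN_FALLBACK_SD)
        flag = (flag + ";" if flag else "") + "singular_hessian"
    return unpack(a_hat), a_hat, se, flag


def estimate_fractions(
    cb: CBTable,
    rates: GlobalRates,
    design: PopulationDesign | None = None,
    prior_sd: float | None = 1.5,
    feature_col: str | None = None,
) -> pd.DataFrame:
    """Estimate per-feature population fractions (fraction labeled).

    For each (sample, feature), maximizes

        sum_rows n * log( sum_p theta_p * exp(read_loglik(row | population p)) )

    plus an optional logit-normal prior on theta (``prior_sd=None`` for the
    flat-prior MLE), and reports logit-scale standard errors from the
    observed information at the optimum.

    Returns a tidy frame with one row per (sample, feature): read count
    ``n``, ``fraction_<name>`` for every population, and
    ``logit_<name>``/``logit_<name>_se`` for every non-reference population.
    A feature with no mutable nucleotides in any read is returned with NaN
    estimates and flag ``no_mutable_nucleotides``.
    """
    design = design or two_component(cb.mutation_types[0])
    fc = feature_col or cb.feature_cols[0]
    P = design.n_populations
    free_names = design.names[:-1]

    nn_cols = [mutation_columns(t)[0] for t in design.mutation_types]
    records = []
    for sample, sample_df in cb.data.groupby("sample", sort=True):
        R = design.rate_matrix(rates, sample)
        for feat, sub in sample_df.groupby(fc, sort=True):
            n_reads = int(sub["n"].sum())
            rec: dict = {"sample": sample, fc: feat, "n": n_reads}
            if int(sub[nn_cols].to_numpy().sum()) == 0:
                for name in design.names:
                    rec[f"fraction_{name}"] = np.nan
                for name in free_names:
                    rec[f"logit_{name}"] = np.nan
                    rec[f"logit_{name}_se"] = np.nan
                rec["flag"] = "no_mutable_nucleotides"
                records.append(rec)
                continue
            ll, w = _population_logliks(sub, design, R)
            theta, a_hat, se, flag = _fit_theta(ll, w, prior_sd)
            for name, th in zip(design.names, theta):
                rec[f"fraction_{name}"] = th
            for j, name in enumerate(free_names):
                rec[f"logit_{name}"] = a_hat[j] if P > 1 else np.nan
                rec[f"logit_{name}_se"] = se[j] if P > 1 else np.nan
            rec["flag"] = flag
            records.append(rec)
    out = pd.DataFrame.from_records(records)
    if P == 2:
        # convenience aliases for the standard single-label design
        name = design.names[0]
        out["fraction_labeled"] = out[f"fraction_{name}"]
        out["logit_fraction_labeled"] = out[f"logit_{name}"]
        out["logit_fraction_labeled_se"] = out[f"logit_{name}_se"]
    return out


def cutoff_estimator(
    cb: CBTable,
    k: int = 1,
    mutation_type: str | None = None,
    feature_col: str | None = None,
) -> pd.DataFrame:
    """Naive comparator: fraction of reads with >= k mutations per feature.

    This mutation-count-cutoff classifier is biased whenever background
    mutations can reach k (upward) or labeled reads can fall below k
    (downward); it is included to quantify that bias against the mixture
    model.
    """
    if k < 1:
        raise ValueError("cutoff k must be >= 1")
    mut = mutation_type or cb.mutation_types[0]
    fc = feature_col or cb.feature_cols[0]
    _, nm = mutation_columns(mut)
    df = cb.data.copy()
    df["_hit"] = (df[nm] >= k).astype(float) * df["n"]
    g = df.groupby(["sample", fc], as_index=False).agg(
        n=("n", "sum"), hits=("_hit", "sum")
    )
    g["fraction_labeled"] = g["hits"] / g["n"]
    return g.rename(columns={fc: "feature"})[
        ["sample", "feature", "n", "fraction_labeled"]
    ]
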