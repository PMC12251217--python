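"""Binomial mixture model: likelihoods, global rates, fraction estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrseqkit.cb import CBTable
from nrseqkit.mixture import (
    GlobalRates,
    cutoff_estimator,
    estimate_fractions,
    estimate_global_rates,
    full_factorial,
    read_loglik,
    tilac,
)
from nrseqkit.validation import grid_search_theta


def _cb(nM, nN, n=None, sample="s", feature="f"):
    n = n if n is not None else [1] * len(nM)
    return CBTable(
        pd.DataFrame({"sample": sample, "feature": feature,
                      "nT": nN, "TC": nM, "n": n}),
        ("TC",),
    )


class TestReadLoglik:
    def test_empty_read_has_probability_one(self):
        assert read_loglik([0], [0], [0.3]) == 0.0

    def test_binomial_pmf_value(self):
        # C(10,2) 0.5^10 = 45/1024
        assert read_loglik([2], [10], [0.5]) == pytest.approx(
            np.log(45 / 1024), abs=1e-12
        )

    def test_types_are_independent(self):
        joint = read_loglik([1, 0], [10, 8], [0.1, 0.002])
        separate = read_loglik([1], [10], [0.1]) + read_loglik([0], [8], [0.002])
        assert joint == pytest.approx(separate, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            read_loglik([5], [3], [0.1])

    @settings(deadline=None, max_examples=50)
    @given(nN=st.integers(0, 60), frac=st.floats(0, 1),
           p=st.floats(0.001, 0.999))
    def test_always_a_log_probability(self, nN, frac, p):
        nM = int(round(frac * nN))
        assert read_loglik([nM], [nN], [p]) <= 1e-12


class TestGlobalRates:
    def test_control_closed_form(self):
        # control reads totaling 50 mutations over 25000 nucleotides
        df = pd.DataFrame({
            "sample": ["ctrl"] * 2 + ["lab"] * 2,
            "feature": "f",
            "nT": [12500, 12500, 20, 20],
            "TC": [25, 25, 1, 0],
            "n": [1, 1, 600, 600],
        })
        cb = CBTable(df, ("TC",))
        rates = estimate_global_rates(cb, controls=["ctrl"], min_reads=100)
        assert rates.pold_from_nolabel
        _, p0 = rates.rates("lab", "TC")
        assert p0 == pytest.approx(50 / 25000, rel=1e-12)

    def test_em_recovery_on_simulation(self, sim_two_component):
        # 100 features x 500 reads = 50k reads, truth 0.05 / 0.002
        _, cb, _ = sim_two_component
        rates = estimate_global_rates(cb)
        p1, p0 = rates.rates("sample1", "TC")
        assert p1 == pytest.approx(0.05, rel=0.10)
        assert p0 == pytest.approx(0.002, rel=0.25)

    def test_no_labeled_signal_is_flagged(self):
        rng = np.random.default_rng(0)
        nN = rng.poisson(25, 3000)
        cb = _cb(np.zeros_like(nN), nN, n=[1] * len(nN))
        with pytest.warns(UserWarning):
            rates = estimate_global_rates(cb)
        row = rates.table.loc[("s", "TC")]
        assert row["flag"] in ("pinned_low", "rate_tie")

    def test_refuses_tiny_samples(self):
        cb = _cb([1, 0], [20, 20])
        with pytest.raises(ValueError, match="reads"):
            estimate_global_rates(cb)


class TestEstimateFractions:
    def test_perfect_separation(self):
        # 100 reads, 30 with nM = nN > 0, rates at the numerical extremes
        nM = [20] * 30 + [0] * 70
        nN = [20] * 100
        cb = _cb(nM, nN)
        rates = GlobalRates.from_values(["s"], ["TC"], 1.0 - 1e-9, 1e-9)
        fr = estimate_fractions(cb, rates, prior_sd=None)
        assert fr["fraction_labeled"].iloc[0] == pytest.approx(0.30, abs=1e-6)

    def test_worked_three_read_example(self):
        # stationary point at theta = B / (3 (B - A)) with
        # A = Binom(0; 20, 0.25), B = Binom(0; 20, 0.001)
        cb = _cb([5, 0, 0], [20, 20, 20])
        rates = GlobalRates.from_values(["s"], ["TC"], 0.25, 0.001)
        fr = estimate_fractions(cb, rates, prior_sd=None)
        A, B = 0.75**20, 0.999**20
        expected = B / (3 * (B - A))
        assert fr["fraction_labeled"].iloc[0] == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.334, abs=1e-3)

    @pytest.mark.parametrize("case_seed", [11, 12, 13])
    def test_matches_grid_search_oracle(self, case_seed):
        rng = np.random.default_rng(case_seed)
        k = int(rng.integers(1, 6))
        nN = rng.integers(5, 40, size=k)
        nM = rng.binomial(nN, np.where(rng.random(k) < 0.5, 0.1, 0.002))
        cb = _cb(nM.tolist(), nN.tolist())
        rates = GlobalRates.from_values(["s"], ["TC"], 0.1, 0.002)
        fr = estimate_fractions(cb, rates, prior_sd=None)
        want = grid_search_theta(nM.astype(float), nN.astype(float), 0.1, 0.002)
        assert abs(fr["fraction_labeled"].iloc[0] - want) <= 1e-3

    def test_simplex_and_se_columns(self, sim_two_component, known_rates):
        _, cb, _ = sim_two_component
        design = tilac()
        df = cb.data.copy()
        rng = np.random.default_rng(1)
        df["nG"] = rng.poisson(25, len(df))
        df["GA"] = rng.binomial(df["nG"], 0.002)
        cb2 = CBTable(df, ("TC", "GA"))
        rates = GlobalRates.from_values(
            ["sample1"], ["TC", "GA"], 0.05, 0.002
        )
        fr = estimate_fractions(cb2, rates, design)
        total = sum(fr[f"fraction_{nm}"] for nm in design.names)
        assert np.allclose(total, 1.0, atol=1e-8)
        assert (fr["logit_TC_labeled_se"] > 0).all()

    def test_monotone_in_fully_mutated_reads(self):
        rates = GlobalRates.from_values(["s"], ["TC"], 0.1, 0.002)
        nM = [1, 0, 0, 0]
        nN = [25, 25, 25, 25]
        prev = -1.0
        for extra in range(4):
            cb = _cb(nM + [30] * extra, nN + [30] * extra)
            fr = estimate_fractions(cb, rates, prior_sd=None)
            now = fr["fraction_labeled"].iloc[0]
            assert now >= prev - 1e-9
            prev = now

    def test_zero_mutable_nucleotides_is_missing(self):
        cb = _cb([0, 0], [0, 0])
        rates = GlobalRates.from_values(["s"], ["TC"], 0.05, 0.002)
        fr = estimate_fractions(cb, rates)
        assert np.isnan(fr["fraction_labeled"].iloc[0])
        assert fr["flag"].iloc[0] == "no_mutable_nucleotides"

    def test_recovery_and_bias(self, sim_two_component):
        _, cb, truth = sim_two_component
        rates = estimate_global_rates(cb)
        fr = estimate_fractions(cb, rates)
        m = fr.merge(truth.features, on=["sample", "feature"])
        r = np.corrcoef(m["fraction_labeled"], m["theta"])[0, 1]
        assert r >= 0.95
        assert abs((m["fraction_labeled"] - m["theta"]).mean()) <= 0.02

    def test_logit_rmse_decreases_with_coverage(self):
        from scipy.special import logit
        from nrseqkit.simulate import SimConfig, simulate_one_rep

        rmses = []
        for reads in (50, 500):
            cfg = SimConfig(n_features=150, reads_per_feature=reads,
                            reads_law="fixed", seed=77)
            cb, truth = simulate_one_rep(cfg)
            rates = GlobalRates.from_values(["sample1"], ["TC"], 0.05, 0.002)
            fr = estimate_fractions(cb, rates)
            m = fr.merge(truth.features, on=["sample", "feature"])
            err = logit(np.clip(m["fraction_labeled"], 1e-6, 1 - 1e-6)) - logit(m["theta"])
            rmses.append(float(np.sqrt((err**2).mean())))
        assert rmses[1] < rmses[0]


class TestPopulationDesigns:
    def test_tilac_excludes_doubly_labeled(self):
        d = tilac()
        assert d.n_populations == 3
        assert ("labeled", "labeled") not in d.populations

    def test_full_factorial_has_all_populations(self):
        d = full_factorial(("TC", "GA"))
        assert d.n_populations == 4
        assert d.names[-1] == "unlabeled"

    def test_unlabeled_population_required(self):
        from nrseqkit.mixture import PopulationDesign
        with pytest.raises(ValueError, match="all-unlabeled"):
            PopulationDesign(("TC",), (("labeled",),), ("labeled",))


class TestCutoffEstimator:
    def test_no_mutations_gives_zero(self):
        cb = _cb([0, 0, 0], [20, 20, 20])
        out = cutoff_estimator(cb, k=1)
        assert out["fraction_labeled"].iloc[0] == 0.0

    def test_direct_count(self):
        cb = _cb([5, 0, 0], [20, 20, 20])
        out = cutoff_estimator(cb, k=2)
        assert out["fraction_labeled"].iloc[0] == pytest.approx(1 / 3)

    def test_positive_bias_at_zero_theta(self):
        # theta = 0, p_unlabeled = 0.01, nN = 100:
        # E[fraction with >= 1 mutation] = 1 - 0.99^100 ~ 0.634
        rng = np.random.default_rng(5)
        n_reads = 20000
        nM = rng.binomial(100, 0.01, n_reads)
        cb = _cb(nM.tolist(), [100] * n_reads)
        out = cutoff_estimator(cb, k=1)
        expected = 1 - 0.99**100
        mc_sd = np.sqrt(expected * (1 - expected) / n_reads)
        assert out["fraction_labeled"].iloc[0] == pytest.approx(
            expected, abs=4 * mc_sd
        )

    def test_k_must_be_positive(self):
        cb = _cb([0], [20])
        with pytest.raises(ValueError):
            cutoff_estimator(cb, k=0)
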