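"""Linear dynamical-systems solver, fitting and normalization strategies."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from nrseqkit.dynamics import (
    DynamicsModel,
    Edge,
    ModelError,
    average_observations,
    fit_dynamics,
    flag_practical_identifiability,
    mixing_weights,
    nuclear_cytoplasmic,
    one_compartment,
    premature_mature,
    scales_from_fractions_only,
    scales_from_mixing,
    solve_old_fraction,
    steady_state,
)
from nrseqkit.validation import random_admissible_model, solver_vs_integrator


class TestSolver:
    def test_one_species_closed_form(self):
        sol = solve_old_fraction(one_compartment(),
                                 {"ksyn": 3.0, "kdeg": np.log(2) / 2}, 2.0)
        assert sol["M"] == pytest.approx(0.5, abs=1e-12)

    def test_two_compartment_closed_form(self):
        kp, kd, t = 2.0, 0.5, 1.0
        sol = solve_old_fraction(premature_mature(),
                                 {"ksyn": 1.0, "kp": kp, "kdeg": kd}, t)
        assert sol["P"] == pytest.approx(1 - np.exp(-kp * t), abs=1e-12)
        old_m = (kp * np.exp(-kd * t) - kd * np.exp(-kp * t)) / (kp - kd)
        assert sol["M"] == pytest.approx(1 - old_m, abs=1e-12)

    def test_equal_rates_limit(self):
        k, t = 0.7, 2.0
        sol = solve_old_fraction(premature_mature(),
                                 {"ksyn": 1.0, "kp": k, "kdeg": k}, t)
        assert sol["M"] == pytest.approx(1 - (1 + k * t) * np.exp(-k * t),
                                         abs=1e-8)

    def test_measurement_is_abundance_weighted(self):
        model = nuclear_cytoplasmic()
        params = {"ksyn": 2.0, "kexp": 1.0, "kdeg": 0.25}
        ustar = steady_state(model, params)
        sol = solve_old_fraction(model, params, 1.5)
        want = (ustar[0] * sol["N"] + ustar[1] * sol["C"]) / ustar.sum()
        assert sol["whole_cell"] == pytest.approx(want, abs=1e-12)

    def test_matches_numerical_integrator(self):
        out = solver_vs_integrator(3, n_models=25)
        assert out["max_integrator_deviation"] <= 1e-6

    def test_theta_nondecreasing_in_time(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            model, rates = random_admissible_model(rng)
            prev = {sp: 0.0 for sp in model.species}
            for t in (0.5, 1.0, 2.0, 4.0, 8.0):
                sol = solve_old_fraction(model, rates, t,
                                         include_measurements=False)
                for sp in model.species:
                    assert sol[sp] >= prev[sp] - 1e-10
                    prev[sp] = sol[sp]

    def test_non_hurwitz_model_rejected(self):
        # C has no outflow: pre-existing RNA accumulates there forever
        model = DynamicsModel(
            species=("N", "C"), edges=(Edge("N", "C", "kexp"),),
            synthesis_species="N", measurements={"n": ("N",)},
        )
        with pytest.raises(ModelError, match="Hurwitz"):
            solve_old_fraction(model, {"ksyn": 1.0, "kexp": 1.0}, 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            solve_old_fraction(one_compartment(), {"ksyn": 1, "kdeg": 1}, -1.0)


class TestModelSpec:
    def test_yaml_round_trip(self, tmp_path):
        model = nuclear_cytoplasmic(nuclear_degradation=True)
        path = model.to_yaml(tmp_path / "model.yaml")
        again = DynamicsModel.from_yaml(path)
        assert again == model

    def test_unreachable_species_rejected(self):
        with pytest.raises(ModelError, match="unreachable"):
            DynamicsModel(
                species=("A", "B"),
                edges=(Edge("A", None, "ka"), Edge("B", None, "kb")),
                synthesis_species="A",
            )

    def test_empty_measurement_rejected(self):
        with pytest.raises(ModelError):
            DynamicsModel(
                species=("A",), edges=(Edge("A", None, "ka"),),
                synthesis_species="A", measurements={"m": ()},
            )


def _noise_free_obs(model, params, tls=(1.0, 4.0), lf_se=0.05, with_counts=True):
    ustar = steady_state(model, params)
    idx = {sp: i for i, sp in enumerate(model.species)}
    rows = []
    for tl in tls:
        sol = solve_old_fraction(model, params, tl)
        for meas, subset in model.measurements.items():
            ii = [idx[s] for s in subset]
            row = {"feature": "g", "measurement": meas, "tl": tl,
                   "logit_fraction": float(logit(sol[meas])),
                   "logit_fraction_se": lf_se}
            if with_counts:
                row["log_reads"] = float(np.log(ustar[ii].sum()))
                row["log_reads_se"] = lf_se
            rows.append(row)
    return pd.DataFrame(rows)


class TestFitDynamics:
    def test_noise_free_exact_inversion(self):
        model = premature_mature()
        truth = {"ksyn": 3.0, "kp": 1.3, "kdeg": 0.4}
        obs = _noise_free_obs(model, truth)
        fit = fit_dynamics(model, obs, scales=None, seed=5)
        for name, val in truth.items():
            assert fit[f"log_{name}"].iloc[0] == pytest.approx(
                np.log(val), abs=1e-4
            )
        flags = flag_practical_identifiability(fit)
        assert not flags[[c for c in flags if c.startswith("low_confidence")]].any().any()

    def test_fractions_only_drops_synthesis(self):
        model = premature_mature()
        truth = {"ksyn": 3.0, "kp": 1.3, "kdeg": 0.4}
        obs = _noise_free_obs(model, truth, with_counts=False)
        fit = fit_dynamics(model, obs, seed=5)
        assert "log_ksyn" not in fit.columns
        assert fit["log_kp"].iloc[0] == pytest.approx(np.log(1.3), abs=1e-4)

    def test_unidentifiable_model_refused(self):
        # only the whole-cell fraction at one time cannot pin two rates
        model = nuclear_cytoplasmic()
        truth = {"ksyn": 1.0, "kexp": 1.0, "kdeg": 0.5}
        obs = _noise_free_obs(model, truth, tls=(2.0,), with_counts=False)
        obs = obs[obs["measurement"] == "whole_cell"].reset_index(drop=True)
        with pytest.raises(ModelError, match="unidentifiable"):
            fit_dynamics(model, obs, seed=1)

    def test_singular_hessian_flagged_with_infinite_se(self):
        # nuclear degradation indistinguishable at kNdeg ~ 0: drive data
        # from the no-Ndeg model but fit the Ndeg model
        gen = nuclear_cytoplasmic()
        truth = {"ksyn": 5.0, "kexp": 1.0, "kdeg": 0.5}
        obs = _noise_free_obs(gen, truth)
        model = nuclear_cytoplasmic(nuclear_degradation=True)
        fit = fit_dynamics(model, obs, scales=None, seed=2)
        flags = flag_practical_identifiability(fit)
        assert flags["low_confidence_kNdeg"].iloc[0]


class TestAverageObservations:
    def test_inverse_variance_pooling(self):
        obs = pd.DataFrame({
            "feature": "g", "measurement": "total", "tl": 2.0,
            "sample": ["a", "b"],
            "logit_fraction": [0.0, 1.0],
            "logit_fraction_se": [0.1, 0.2],
        })
        out = average_observations(obs)
        w = np.array([1 / 0.01, 1 / 0.04])
        assert out["logit_fraction"].iloc[0] == pytest.approx(
            (w * [0, 1]).sum() / w.sum()
        )
        assert out["logit_fraction_se"].iloc[0] == pytest.approx(
            np.sqrt(1 / w.sum())
        )


class TestScaleStrategies:
    def test_mixing_worked_example(self):
        alpha = mixing_weights({"nuclear": 0.6, "cytoplasmic": 0.2}, 0.3)
        assert alpha["nuclear"] == pytest.approx(0.25, abs=1e-12)
        assert alpha["cytoplasmic"] == pytest.approx(0.75, abs=1e-12)

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ModelError, match="degenerate"):
            mixing_weights({"nuclear": 0.4, "cytoplasmic": 0.4}, 0.4)

    def test_out_of_range_weights_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            alpha = mixing_weights({"nuclear": 0.6, "cytoplasmic": 0.2}, 0.7)
        assert 0 <= alpha["nuclear"] <= 1

    def test_scales_from_mixing_reference_is_one(self):
        alpha, scales = scales_from_mixing(
            {"nuclear": 0.6, "cytoplasmic": 0.2}, 0.3,
            read_shares={"nuclear": 0.5, "cytoplasmic": 0.5},
        )
        assert scales["nuclear"] == 1.0
        # alpha 0.25/0.75 at equal read shares -> cytoplasm 3x the nuclear scale
        assert scales["cytoplasmic"] == pytest.approx(3.0)

    def test_scales_from_fractions_only_steady_state_algebra(self):
        # without nuclear degradation u*_N / u*_C = kdeg / kexp = 0.25
        model = nuclear_cytoplasmic()
        fit = pd.DataFrame({
            "feature": ["g1", "g2"],
            "log_kexp": np.log(1.0), "log_kdeg": np.log(0.25),
            "flag": ["", ""],
        })
        scales, flagged = scales_from_fractions_only(
            model, fit, read_shares={"nuclear": 0.5, "cytoplasmic": 0.5},
        )
        assert scales["cytoplasmic"] / scales["nuclear"] == pytest.approx(4.0)
        assert flagged["flag"].str.contains("fractions_only").all()

    def test_scales_from_fractions_only_needs_two_compartments(self):
        model = one_compartment()
        fit = pd.DataFrame({"feature": ["g"], "log_kdeg": [0.0], "flag": [""]})
        with pytest.raises(ModelError):
            scales_from_fractions_only(model, fit, read_shares={"total": 1.0})
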