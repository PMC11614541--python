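"""Cox models, episode splitting, hazard-ratio arithmetic, AIC confidence sets."""

import numpy as np
import pandas as pd
import pytest

from nutrigeom.survival import (CoxModel, aic_confidence_set, episode_split,
                                fit_cox, hr_to_percent)


def brute_force_partial_loglik(durations, events, X, beta):
    """Risk-set product enumeration of the Cox partial likelihood (no ties)."""
    eta = X @ beta
    ll = 0.0
    for i in np.flatnonzero(events):
        at_risk = durations >= durations[i]
        ll += eta[i] - np.log(np.sum(np.exp(eta[at_risk])))
    return ll


def two_group_frame(durations, events, groups):
    return pd.DataFrame({
        "id": [f"s{i}" for i in range(len(durations))],
        "entry_day": 0.0, "exit_day": durations, "event": events,
        "pc_label": np.where(groups == 1, "1P:1C", "3P:1C"),
        "cellulose_level": "low",
    })


class TestEpisodeSplit:
    def test_death_on_day_ten_splits_into_censored_then_event(self):
        df = pd.DataFrame({"id": ["a"], "entry_day": [0.0], "exit_day": [10.0],
                           "event": [1], "cellulose_level": ["high"]})
        ep = episode_split(df)
        assert len(ep) == 2
        first, second = ep.iloc[0], ep.iloc[1]
        assert (first["start"], first["stop"], first["event"]) == (0.0, 7.0, 0)
        assert (second["start"], second["stop"], second["event"]) == (7.0, 10.0, 1)
        assert list(ep["interval"]) == ["0-7", "7-14"]

    def test_censored_at_study_end_has_three_censored_episodes(self):
        df = pd.DataFrame({"id": ["a"], "entry_day": [0.0], "exit_day": [153.0],
                           "event": [0], "cellulose_level": ["low"]})
        ep = episode_split(df)
        assert len(ep) == 3
        assert (ep["event"] == 0).all()

    def test_follow_up_time_conserved(self, rng):
        df = pd.DataFrame({
            "id": [f"s{i}" for i in range(40)],
            "entry_day": 0.0,
            "exit_day": rng.uniform(0.5, 153.0, 40),
            "event": rng.integers(0, 2, 40),
            "cellulose_level": rng.choice(["low", "medium", "high"], 40),
        })
        ep = episode_split(df)
        total = (ep["stop"] - ep["start"]).groupby(ep["id"]).sum()
        original = df.set_index("id")["exit_day"]
        assert np.allclose(total.sort_index(), original.sort_index())
        # exactly one event row per event subject
        assert ep.groupby("id")["event"].sum().sort_index().equals(
            df.set_index("id")["event"].astype(np.int64).sort_index())

    def test_exit_beyond_final_cutpoint_rejected(self):
        df = pd.DataFrame({"id": ["a"], "entry_day": [0.0], "exit_day": [200.0],
                           "event": [1], "cellulose_level": ["low"]})
        with pytest.raises(ValueError, match="final cutpoint"):
            episode_split(df)


class TestFitCox:
    def test_partial_likelihood_matches_brute_force_on_tiny_instances(self, rng):
        for trial in range(5):
            n = int(rng.integers(5, 9))
            durations = rng.uniform(1, 100, n)  # continuous: no ties
            events = rng.integers(0, 2, n)
            groups = rng.integers(0, 2, n)
            if events.sum() == 0 or len(np.unique(groups)) < 2:
                continue
            df = two_group_frame(durations, events, groups)
            model = fit_cox(df, terms=("pc",))
            X = (df["pc_label"] == "1P:1C").to_numpy(float)[:, None]
            oracle = brute_force_partial_loglik(durations, events, X,
                                                model.params_.to_numpy())
            assert model.log_likelihood_ == pytest.approx(oracle, abs=1e-10)

    def test_two_group_exponential_recovers_hazard_ratio(self):
        rng = np.random.default_rng(3)
        n = 2000
        groups = np.repeat([0, 1], n // 2)
        rates = np.where(groups == 1, 0.02, 0.01)  # true HR = 2
        durations = rng.exponential(1.0 / rates)
        events = np.ones(n, dtype=int)
        df = two_group_frame(durations, events, groups)
        model = fit_cox(df, terms=("pc",))
        hr = float(model.hazard_ratios_.iloc[0])
        assert 1.85 <= hr <= 2.15

    def test_reference_category_absent_from_design(self, cohort):
        from nutrigeom.simulate import records_to_subjects
        subjects = records_to_subjects(cohort)
        df = subjects.assign(event=(subjects["fate"] == "died").astype(int))
        model = fit_cox(df, terms=("pc", "cellulose"))
        assert "pc[3P:1C]" not in model.params_.index
        assert "cell[low]" not in model.params_.index
        assert model.aic_ == pytest.approx(-2 * model.log_likelihood_ + 2 * model.k_)

    def test_constant_term_dropped_with_warning(self, rng):
        durations = rng.uniform(1, 50, 30)
        df = two_group_frame(durations, np.ones(30, int), rng.integers(0, 2, 30))
        df["cellulose_level"] = "medium"  # single level: term is constant
        with pytest.warns(UserWarning, match="constant"):
            model = fit_cox(df, terms=("pc", "cellulose"))
        assert all(not name.startswith("cell") for name in model.params_.index)

    def test_no_events_rejected(self, rng):
        df = two_group_frame(rng.uniform(1, 50, 10), np.zeros(10, int),
                             rng.integers(0, 2, 10))
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, terms=("pc",))

    def test_episode_split_leaves_shared_coefficient_fit_unchanged(self, rng):
        n = 120
        durations = rng.uniform(0.5, 152.0, n)  # continuous: no ties
        events = rng.integers(0, 2, n)
        events[0] = 1
        groups = rng.integers(0, 2, n)
        df = two_group_frame(durations, events, groups)
        whole = fit_cox(df, terms=("pc",))
        ep = episode_split(df)
        split = fit_cox(ep, terms=("pc",))
        assert split.log_likelihood_ == pytest.approx(whole.log_likelihood_, abs=1e-6)
        # the two fitters stop at slightly different gradient norms
        assert split.params_.iloc[0] == pytest.approx(whole.params_.iloc[0], abs=1e-4)

    def test_block_chi_square_positive_for_informative_term(self):
        rng = np.random.default_rng(5)
        n = 400
        groups = np.repeat([0, 1], n // 2)
        durations = rng.exponential(1.0 / np.where(groups == 1, 0.03, 0.01))
        df = two_group_frame(durations, np.ones(n, int), groups)
        model = fit_cox(df, terms=("pc",))
        res = model.block_test("pc")
        assert res["df"] == 1
        assert res["chi2"] > 10
        assert res["p"] < 0.001


class TestIntervalHazardRecovery:
    def test_interval_specific_cellulose_coefficients_recover_generator_truth(self):
        """Episode-split Cox fit recovers the configured piecewise multipliers."""
        import warnings
        from nutrigeom.simulate import SimConfig, records_to_subjects, simulate_no_choice
        cfg = SimConfig(seed=99, n_per_diet=100)
        subj = records_to_subjects(simulate_no_choice(cfg))
        srv = subj.assign(event=(subj["fate"] == "died").astype(int)).drop(columns=["fate"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_cox(episode_split(srv), terms=("pc", "cellulose_by_interval"))
        truth = {
            "cell[medium]@0-7": np.log(cfg.hazard_multipliers["medium"][0]),
            "cell[high]@0-7": np.log(cfg.hazard_multipliers["high"][0]),
            "cell[high]@7-14": np.log(cfg.hazard_multipliers["high"][1]),
            "cell[medium]@14-153": 0.0,
            "cell[high]@14-153": 0.0,
            "pc[8P:1C]": np.log(cfg.diet_hazard["8P:1C"]),
        }
        for term, target in truth.items():
            est, se = model.params_[term], model.bse_[term]
            assert abs(est - target) < 3.5 * se, (term, est, target, se)


class TestHrToPercent:
    @pytest.mark.parametrize("hr, percent, direction", [
        (0.07, 93.0, "less likely"),
        (0.14, 86.0, "less likely"),
        (0.22, 78.0, "less likely"),
        (0.36, 64.0, "less likely"),
        (6.05, 505.0, "higher risk"),
        (1.45, 45.0, "higher risk"),
        (1.0, 0.0, "no difference"),
    ])
    def test_conversion(self, hr, percent, direction):
        res = hr_to_percent(hr)
        assert res.percent == pytest.approx(percent, abs=1e-9)
        assert res.direction == direction

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            hr_to_percent(0.0)


class TestAicConfidenceSet:
    def test_equal_aic_gives_half_weights(self):
        cs = aic_confidence_set([
            {"name": "A", "aic": 100.0, "terms": {"x"}},
            {"name": "B", "aic": 100.0, "terms": {"y"}},
        ])
        assert np.allclose(cs.table["weight"], 0.5)
        assert set(cs.retained) == {"A", "B"}

    def test_nesting_rule_removes_more_complex_variant(self):
        cs = aic_confidence_set([
            {"name": "A", "aic": 100.0, "terms": {"x"}},
            {"name": "B", "aic": 101.0, "terms": {"x", "y"}},
        ])
        assert cs.retained == ["A"]
        assert cs.best == "A"

    def test_delta_threshold_and_weight_normalization(self):
        cs = aic_confidence_set([
            {"name": "A", "aic": 10.0, "terms": {"x"}},
            {"name": "B", "aic": 13.0, "terms": {"z"}},
            {"name": "C", "aic": 20.0, "terms": {"w"}},
        ])
        t = cs.table.set_index("name")
        assert t.loc["A", "delta_aic"] == 0.0
        assert t.loc["C", "delta_aic"] == 10.0
        assert not t.loc["C", "in_delta_set"]
        assert set(cs.retained) == {"A", "B"}
        assert cs.table["weight"].sum() == pytest.approx(1.0)

    def test_non_nested_complex_model_survives(self):
        cs = aic_confidence_set([
            {"name": "A", "aic": 100.0, "terms": {"x"}},
            {"name": "B", "aic": 101.0, "terms": {"y", "z"}},  # not a superset
        ])
        assert set(cs.retained) == {"A", "B"}

    def test_hand_computed_weights(self):
        cs = aic_confidence_set([
            {"name": "A", "aic": 0.0, "terms": {"x"}},
            {"name": "B", "aic": 2.0, "terms": {"y"}},
        ])
        w = np.array([1.0, np.exp(-1.0)])
        w = w / w.sum()
        assert np.allclose(np.sort(cs.table["weight"]), np.sort(w))

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            aic_confidence_set([])
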