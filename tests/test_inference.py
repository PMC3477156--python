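"""Inference stack: regressions, group tests, ANOVA, multiplicity,
awareness contrasts, Bayes factor."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aglab.inference import (
    _firth_logistic,
    _ridge_logistic,
    accuracy_table,
    dienes_bf,
    fit_all_participants,
    fit_participant_regression,
    group_coefficient_tests,
    hochberg_correct,
    mixed_anova_2x2,
    participant_accuracy,
    pdp_confidence_analysis,
)
from aglab.simulate import ModelDistribution, simulate_group


def _records(rows):
    return pd.DataFrame(rows)


class TestAccuracyTable:
    def _toy_records(self, chose):
        rows = []
        for pid in ("a", "b"):
            for phase in ("inclusion", "exclusion"):
                for i, (gs, us, vl, loc) in enumerate([
                    ("old-grammatical", "layer-ungrammatical", 1, "local"),
                    ("new-grammatical", "random-ungrammatical", None, "n/a"),
                ]):
                    rows.append(
                        {
                            "participant": pid,
                            "group": "trained",
                            "variant": "centre-left",
                            "phase": phase,
                            "pair_id": i,
                            "chose_grammatical": chose,
                            "confidence": 60,
                            "gram_status": gs,
                            "ungram_status": us,
                            "violated_layer": vl,
                            "locality": loc,
                        }
                    )
        return _records(rows)

    def test_all_correct_records_give_unit_cells(self):
        table = accuracy_table(self._toy_records(True))
        assert (table["mean"] == 1.0).all()

    def test_exclusion_scored_as_grammatical_choice(self):
        """Cells never flip the exclusion score: choosing grammatical
        counts as 1 in both phases."""
        table = accuracy_table(self._toy_records(False))
        assert (table["mean"] == 0.0).all()

    def test_breakdown_levels_present(self, centre_left_design,
                                      centre_left_features, rng):
        rec = simulate_group(
            centre_left_design, centre_left_features, 4, "control", rng
        )
        table = accuracy_table(rec)
        loc = table[table.breakdown == "locality"]
        assert {"local", "nonlocal", "n/a"} <= set(loc.level)
        vl = table[table.breakdown == "violated_layer"].level.dropna()
        assert {1.0, 2.0, 3.0} <= set(vl)


class TestLogisticFits:
    def test_ridge_fit_matches_grid_search_mle(self):
        """Two-predictor toy problem: the ridge path at tiny lambda
        agrees with a brute-force grid-search MLE to 1e-4."""
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(400), rng.normal(size=(400, 1))])
        w_true = np.array([0.4, -0.7])
        y = (rng.random(400) < 1 / (1 + np.exp(-X @ w_true))).astype(float)
        w_fit, ok = _ridge_logistic(X, y, lam=1e-8)
        assert ok

        def nll(w):
            z = X @ w
            return np.logaddexp(0, -(2 * y - 1) * z).sum()

        # coarse-to-fine grid search around the fit
        best = None
        for a in np.linspace(w_fit[0] - 0.3, w_fit[0] + 0.3, 121):
            for b in np.linspace(w_fit[1] - 0.3, w_fit[1] + 0.3, 121):
                v = nll(np.array([a, b]))
                if best is None or v < best[0]:
                    best = (v, a, b)
        assert abs(best[1] - w_fit[0]) <= 0.3 / 60 + 1e-4
        assert abs(best[2] - w_fit[1]) <= 0.3 / 60 + 1e-4

    def test_firth_shrinks_separated_data_to_finite_estimates(self):
        X = np.column_stack([np.ones(20), np.linspace(-1, 1, 20)])
        y = (X[:, 1] > 0).astype(float)  # perfectly separated
        w, ok = _firth_logistic(X, y)
        assert ok and np.all(np.isfinite(w))
        assert abs(w[1]) < 50

    def test_zero_weight_participant_recovers_zero(
        self, centre_left_design, centre_left_features
    ):
        dist = ModelDistribution(
            mean={"intercept": 0.0}, sd={}, conscious_control=0.0
        )
        rec = simulate_group(
            centre_left_design,
            centre_left_features,
            40,
            dist,
            np.random.default_rng(0),
        )
        coefs = fit_all_participants(rec, centre_left_features)
        g = group_coefficient_tests(coefs)
        # group means of every coefficient compatible with zero
        assert (g["p"] > 0.01).all()
        assert abs(g.loc["intercept", "mean"]) < 0.1

    def test_constant_features_dropped_not_fatal(
        self, centre_left_design, centre_left_features
    ):
        fm = centre_left_features.copy()
        fm["dead"] = 3.0
        dist = ModelDistribution(mean={"intercept": 0.3}, sd={})
        rec = simulate_group(
            centre_left_design, fm, 1, dist, np.random.default_rng(0)
        )
        res = fit_participant_regression(
            rec[rec.participant == "p000"], fm
        )
        assert "dead" in res.dropped
        assert np.isnan(res.coefficients["dead"])
        assert np.isfinite(res.coefficients["intercept"])


class TestGroupTests:
    def test_zero_coefficients_give_t_zero_p_one(self):
        coefs = pd.DataFrame({"a": [0.0] * 10, "b": [0.0] * 10})
        g = group_coefficient_tests(coefs)
        assert g.loc["a", "t"] == 0.0 and g.loc["a", "p"] == 1.0

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        coefs = pd.DataFrame({"a": rng.normal(size=80)})
        g = group_coefficient_tests(coefs)
        assert g.loc["a", "df"] == 79

    def test_requires_two_participants(self):
        with pytest.raises(ValueError):
            group_coefficient_tests(pd.DataFrame({"a": [1.0]}))

    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.2, 1.0, size=25)
        g = group_coefficient_tests(pd.DataFrame({"a": x}))
        t, p = sps.ttest_1samp(x, 0)
        assert g.loc["a", "t"] == pytest.approx(t)
        assert g.loc["a", "p"] == pytest.approx(p)


class TestMixedAnova:
    def _long(self, rng, shift=0.0, n=16):
        rows = []
        for grp in ("trained", "control"):
            for s in range(n):
                base = rng.normal(0.5 + (shift if grp == "trained" else 0),
                                  0.05)
                for phase in ("inclusion", "exclusion"):
                    rows.append(
                        {
                            "participant": f"{grp}{s}",
                            "group": grp,
                            "phase": phase,
                            "accuracy": base + rng.normal(0, 0.02),
                        }
                    )
        return _records(rows)

    def test_between_effect_equals_squared_t(self, rng):
        """With a pure between-group difference, the ANOVA group F
        equals the squared two-sample t on participant means."""
        data = self._long(rng, shift=0.08)
        aov = mixed_anova_2x2(data).set_index("effect")
        means = data.groupby(["group", "participant"]).accuracy.mean()
        t, _ = sps.ttest_ind(means.loc["trained"], means.loc["control"])
        assert aov.loc["group", "F"] == pytest.approx(t**2, rel=1e-8)

    def test_identical_groups_give_tiny_interaction(self, rng):
        data = self._long(rng, shift=0.0)
        aov = mixed_anova_2x2(data).set_index("effect")
        assert aov.loc["Interaction", "p"] > 0.01

    def test_training_effect_detected_at_preset_size(self, rng):
        data = self._long(rng, shift=0.1, n=40)
        aov = mixed_anova_2x2(data).set_index("effect")
        assert aov.loc["group", "p"] < 0.001
        assert aov.loc["group", "partial_eta_sq"] > 0.2

    def test_single_level_factor_rejected(self, rng):
        data = self._long(rng)
        with pytest.raises(ValueError):
            mixed_anova_2x2(data[data.group == "trained"])


class TestHochberg:
    def test_hand_computed_example(self):
        # p(2)=.04 <= .05/1 -> reject all
        assert hochberg_correct([0.01, 0.04], 0.05).tolist() == [True, True]

    def test_step_up_oracle(self):
        """Agreement with a direct implementation of the step-up rule
        over random p-value sets."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(1, 8))
            m = len(p)
            order = np.argsort(p)
            k_best = 0
            for rank, idx in enumerate(order, start=1):
                if p[idx] <= 0.05 / (m - rank + 1):
                    k_best = rank
            expected = np.zeros(m, bool)
            expected[order[:k_best]] = True
            assert hochberg_correct(p, 0.05).tolist() == expected.tolist()

    def test_all_ones_rejected_none(self):
        assert not hochberg_correct([1.0, 1.0, 1.0]).any()

    def test_single_p_plain_alpha(self):
        assert hochberg_correct([0.049]).tolist() == [True]
        assert hochberg_correct([0.051]).tolist() == [False]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            hochberg_correct([0.5, 1.2])


class TestPdpConfidence:
    def _two_group_records(self, c, rng, n=12, intercept=1.2):
        from aglab.stimuli import build_stimulus_set
        from aglab.features import CorpusStatistics, feature_matrix

        design = build_stimulus_set("tail-left", 3)
        stats = CorpusStatistics.from_corpus(design.training)
        fm = feature_matrix(design.pairs, stats)
        trained = simulate_group(
            design,
            fm,
            n,
            ModelDistribution(
                mean={"intercept": intercept},
                sd={"intercept": 0.2},
                conscious_control=c,
                confidence_gain=0.3,
            ),
            rng,
            group="trained",
            id_prefix="t",
        )
        control = simulate_group(
            design, fm, n, "control", rng, group="control", id_prefix="c"
        )
        return pd.concat([trained, control], ignore_index=True)

    def test_no_control_group_shows_no_inclusion_exclusion_gap(self, rng):
        rec = self._two_group_records(c=0.0, rng=rng)
        out = pdp_confidence_analysis(rec)
        row = out.loc["trained inclusion vs exclusion"]
        assert abs(row["mean_1"] - row["mean_2"]) < 0.05

    def test_strong_control_pushes_exclusion_below_chance(self, rng):
        rec = self._two_group_records(c=1.0, rng=rng, intercept=3.0)
        out = pdp_confidence_analysis(rec)
        assert out.loc["trained inclusion vs exclusion", "mean_2"] < 0.5

    def test_unconscious_knowledge_signature(self, rng):
        """Zero control, real knowledge: exclusion stays above the
        control group."""
        rec = self._two_group_records(c=0.0, rng=rng)
        out = pdp_confidence_analysis(rec)
        row = out.loc["trained exclusion vs control exclusion"]
        assert row["mean_1"] > row["mean_2"]
        assert row["p"] < 0.01


class TestDienesBF:
    def test_closed_form_at_unit_values(self):
        assert dienes_bf(0.0, 1.0, 1.0) == pytest.approx(
            1 / np.sqrt(2), rel=1e-9
        )

    def test_matches_gaussian_closed_form(self):
        """Adaptive quadrature agrees with the analytic half-normal
        marginal over a spread of scales."""
        def closed(m, se, sd):
            s2 = se**2 + sd**2
            mu_p = m * sd**2 / s2
            sig_p = np.sqrt(se**2 * sd**2 / s2)
            return (
                2
                * sps.norm.pdf(m, 0, np.sqrt(s2))
                * sps.norm.cdf(mu_p / sig_p)
                / sps.norm.pdf(m, 0, se)
            )

        for m, se, sd in [
            (0.02, 0.008, 0.015),
            (-1.0, 2.0, 1.5),
            (0.5, 0.2, 0.015),
            (3.0, 0.1, 0.5),
        ]:
            assert dienes_bf(m, se, sd) == pytest.approx(
                closed(m, se, sd), rel=1e-6
            )

    def test_vanishing_prior_sd_gives_bf_one(self):
        assert dienes_bf(0.3, 1.0, 1e-8) == pytest.approx(1.0, rel=1e-4)

    def test_diffuse_prior_gives_bf_zero(self):
        assert dienes_bf(0.3, 1.0, 1e6) < 1e-4

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dienes_bf(0.1, 0.0, 1.0)
        with pytest.raises(ValueError):
            dienes_bf(np.nan, 1.0, 1.0)
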