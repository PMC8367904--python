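"""ROC/AUC machinery, evaluation designs and sample-size planning."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from stylesalience.corpus import filter_min_words
from stylesalience.model import TrainingConfig, train
from stylesalience.synthetic import generate_scenario
from stylesalience.validation import (
    auc_ci,
    auc_test_power,
    confusion_matrix,
    cross_platform_test,
    delong_se,
    experimental_eval,
    hanley_mcneil_se,
    roc_auc,
    sample_size_for_auc,
    within_user_cv,
)
from .conftest import make_corpus


def pairwise_auc_oracle(scores, labels):
    """Exhaustive pairwise comparison: mean over all (pos, neg) pairs of
    1 / 0.5 / 0 for win / tie / loss."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_tied_example_hand_counted(self):
        # pairs: (.9>.8)=1, (.9>.1)=1, (.8==.8)=.5, (.8>.1)=1 -> 3.5/4
        assert roc_auc([0.9, 0.8, 0.8, 0.1], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.4, 0.6], [1, 1])

    def test_permuted_scores_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_label_swap_maps_auc_to_complement(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        a = roc_auc(scores, labels)
        assert roc_auc(scores, 1 - labels) == pytest.approx(1.0 - a)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_exhaustive_pairwise_oracle(self, data):
        n = data.draw(st.integers(4, 60))
        # low-resolution scores force ties
        scores = data.draw(st.lists(st.integers(0, 8), min_size=n, max_size=n))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        scores = np.array(scores) / 8.0
        assert roc_auc(scores, labels) == pytest.approx(
            pairwise_auc_oracle(scores, labels), abs=1e-12
        )


class TestConfusionMatrix:
    def test_perfect_scores_off_diagonal_zero(self):
        cm = confusion_matrix([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert cm == {"tp": 2, "fn": 0, "fp": 0, "tn": 2}

    def test_ties_at_threshold_predict_positive(self):
        cm = confusion_matrix([0.5, 0.5, 0.5], [1, 0, 1])
        assert cm["fn"] == 0 and cm["tn"] == 0
        assert cm["tp"] + cm["fp"] == 3

    def test_hand_counted_mixed_case(self):
        cm = confusion_matrix([0.6, 0.4, 0.7, 0.2], [1, 1, 0, 0])
        assert cm == {"tp": 1, "fn": 1, "fp": 1, "tn": 1}

    def test_cells_sum_to_n(self, rng):
        scores, labels = rng.random(57), rng.integers(0, 2, 57)
        cm = confusion_matrix(scores, labels)
        assert sum(cm.values()) == 57


class TestAucUncertainty:
    def test_hanley_mcneil_ci_width_at_moderate_auc(self):
        # AUC .71 with ~21/22 per class: SE ~ .08, 95% CI width ~ .31
        se, lo, hi = auc_ci(0.71, 21, 22)
        assert se == pytest.approx(0.080, abs=0.005)
        assert (hi - lo) == pytest.approx(0.31, abs=0.02)

    def test_ci_truncated_to_unit_interval(self):
        _, lo, hi = auc_ci(0.98, 10, 10)
        assert hi == 1.0 and 0.0 <= lo < 1.0

    def test_delong_close_to_hanley_mcneil_on_smooth_scores(self, rng):
        pos = rng.normal(1.0, 1.0, 150)
        neg = rng.normal(0.0, 1.0, 150)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 150 + [0] * 150)
        auc = roc_auc(scores, labels)
        hm = hanley_mcneil_se(auc, 150, 150)
        dl = delong_se(scores, labels)
        assert dl == pytest.approx(hm, rel=0.35)


class TestWithinUserCV:
    def test_requires_dual_label_users(self, study1_model):
        corpus = make_corpus(
            [("p1", "u1", "parent", "w " * 30), ("p2", "u2", "feminist", "w " * 30)],
            label_set=("parent", "feminist"),
        )
        with pytest.raises(ValueError, match="both labels"):
            within_user_cv(study1_model, corpus)

    def test_reproducible_and_prefix_stable(self, study1, study1_model):
        corpus, _, features = study1
        r1 = within_user_cv(study1_model, corpus, rounds=3, seed=11, features=features)
        r2 = within_user_cv(study1_model, corpus, rounds=3, seed=11, features=features)
        r5 = within_user_cv(study1_model, corpus, rounds=5, seed=11, features=features)
        assert r1.per_round_aucs == r2.per_round_aucs
        # dedicated stream per round: adding rounds never changes earlier ones
        assert r5.per_round_aucs[:3] == r1.per_round_aucs

    def test_single_round_flags_se(self, study1, study1_model):
        corpus, _, features = study1
        rep = within_user_cv(study1_model, corpus, rounds=1, seed=0, features=features)
        assert np.isnan(rep.se_rounds)
        assert rep.rounds == 1

    def test_detects_true_identity_effect(self, study1, study1_model):
        corpus, _, features = study1
        rep = within_user_cv(study1_model, corpus, rounds=10, seed=2, features=features)
        assert rep.mean_auc - 0.5 > 2 * rep.combined_se
        assert rep.ci95[0] <= rep.mean_auc <= rep.ci95[1]
        assert sum(rep.confusion.values()) == 2 * rep.n_users * rep.rounds

    def test_cross_platform_tagged(self, study1_model):
        cross, _ = generate_scenario("study3_platform", seed=21)
        rep = cross_platform_test(study1_model, filter_min_words(cross, 25), rounds=3, seed=4)
        assert rep.design == "cross_platform"


class TestExperimentalEval:
    def test_topics_reported_with_capped_ci(self, study1_model):
        exp, _ = generate_scenario("study4_experiment", seed=31)
        rep = experimental_eval(study1_model, exp)
        assert set(rep.table["topic"]) == {"climate", "objectification", "mealtimes"}
        assert (rep.table["ci_high"] <= 1.0).all()
        assert (rep.table["auc"] > 0.5).all()

    def test_single_class_topic_skipped(self, study1_model):
        from stylesalience.corpus import Corpus

        exp, _ = generate_scenario("study4_experiment", seed=32)
        posts = exp.posts.copy()
        posts.loc[posts["topic"] == "climate", "label"] = "parent"
        broken = Corpus(posts=posts, label_set=exp.label_set, provenance=dict(exp.provenance))
        rep = experimental_eval(study1_model, broken)
        assert rep.skipped == ["climate"]
        assert set(rep.table["topic"]) == {"objectification", "mealtimes"}

    def test_per_topic_aucs_agree_within_sampling_error(self, study1_model):
        # style signal is topic-independent by construction
        exp, _ = generate_scenario("study4_experiment", seed=33)
        rep = experimental_eval(study1_model, exp)
        aucs, ses = rep.table["auc"].to_numpy(), rep.table["se"].to_numpy()
        for i in range(len(aucs)):
            for j in range(i + 1, len(aucs)):
                z = abs(aucs[i] - aucs[j]) / np.hypot(ses[i], ses[j])
                assert z < 3.0


class TestSampleSize:
    def test_n_non_increasing_in_target_auc(self):
        targets = [0.6, 0.65, 0.7, 0.75, 0.8, 0.9]
        ns = [sample_size_for_auc(a).total_n for a in targets]
        assert ns == sorted(ns, reverse=True)

    def test_tiny_power_returns_minimal_group_size(self):
        res = sample_size_for_auc(0.8, power=1e-9)
        assert res.total_n == 4  # two per class is the design minimum

    def test_result_echoes_method_options(self):
        res = sample_size_for_auc(0.71, sided="one", variance_model="binormal")
        assert res.sided == "one" and res.variance_model == "binormal"
        assert res.achieved_power >= 0.80

    def test_minimality_of_returned_n(self):
        res = sample_size_for_auc(0.71, power=0.80, alpha=0.05)
        below = auc_test_power(0.71, res.n_pos - 1, res.n_neg - 1)
        assert below < 0.80 <= res.achieved_power

    @pytest.mark.parametrize("bad", [0.5, 1.0, 0.3])
    def test_infeasible_target_errors(self, bad):
        with pytest.raises(ValueError):
            sample_size_for_auc(bad)

    def test_monte_carlo_power_confirms_analytic_model(self, rng):
        """Simulated binormal scores at the returned N reach the requested
        power within Monte-Carlo error."""
        res = sample_size_for_auc(0.71, power=0.80, alpha=0.05)
        delta = np.sqrt(2.0) * norm.ppf(res.target_auc)
        reps, hits = 1200, 0
        crit = norm.ppf(0.975)
        for _ in range(reps):
            pos = rng.normal(delta, 1.0, res.n_pos)
            neg = rng.normal(0.0, 1.0, res.n_neg)
            auc = roc_auc(np.concatenate([pos, neg]), [1] * res.n_pos + [0] * res.n_neg)
            se0 = hanley_mcneil_se(0.5, res.n_pos, res.n_neg)
            if (auc - 0.5) / se0 > crit:
                hits += 1
        mc_power = hits / reps
        assert mc_power == pytest.approx(res.achieved_power, abs=0.07)
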