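"""Event-table construction, survival estimators, and discrimination."""

import numpy as np
import pandas as pd
import pytest

from subtypegan import survival, synthetic
from subtypegan.survival import (
    UNASSIGNED,
    EventTable,
    assign_dominant_pattern,
    build_pattern_event_table,
    concordance_index,
    cumulative_incidence_competing,
    horizon_discrimination,
    incidence_at,
    kaplan_meier,
    repeated_cv_cox_cindex,
)


def simple_events(times, events, features=None):
    return EventTable(
        subject_id=np.array([f"s{i}" for i in range(len(times))], dtype=object),
        time=np.asarray(times, dtype=float),
        event=np.asarray(events, dtype=int),
        event_names={1: "P2", 2: "P3"},
        features=features,
    )


class TestAssignDominantPattern:
    def test_clear_dominant(self):
        labels = assign_dominant_pattern(np.array([[0.7, 0.1, 0.1, 0.1]]))
        assert labels[0] == 0

    def test_sub_threshold_row_unassigned(self):
        labels = assign_dominant_pattern(np.array([[0.4, 0.3, 0.2, 0.1]]), threshold=0.5)
        assert labels[0] == UNASSIGNED

    def test_boundary_is_strictly_greater(self):
        labels = assign_dominant_pattern(np.array([[0.5, 0.5, 0.0, 0.0]]), threshold=0.5)
        assert labels[0] == UNASSIGNED

    def test_out_of_range_threshold_warns(self):
        with pytest.warns(UserWarning, match="threshold"):
            assign_dominant_pattern(np.array([[0.6, 0.4]]), threshold=0.3)


class TestBuildPatternEventTable:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(rows, columns=["participant_id", "visit_time", "P1", "P2", "P3"])

    def test_conversion_at_year_three(self):
        df = self.frame(
            [
                ["a", 0.0, 0.9, 0.05, 0.05],
                ["a", 1.0, 0.8, 0.15, 0.05],
                ["a", 3.0, 0.3, 0.6, 0.1],
                ["a", 5.0, 0.2, 0.7, 0.1],
            ]
        )
        ev = build_pattern_event_table(df, "P1", ["P2", "P3"])
        assert ev.event[0] == 1
        assert ev.time[0] == 3.0

    def test_never_converting_subject_censored_at_last_visit(self):
        df = self.frame(
            [["a", 0.0, 0.9, 0.05, 0.05], ["a", 2.0, 0.85, 0.1, 0.05], ["a", 6.0, 0.8, 0.1, 0.1]]
        )
        ev = build_pattern_event_table(df, "P1", ["P2", "P3"])
        assert ev.event[0] == 0
        assert ev.time[0] == 6.0

    def test_competing_targets_get_distinct_codes(self):
        df = self.frame(
            [
                ["a", 0.0, 0.9, 0.05, 0.05],
                ["a", 2.0, 0.2, 0.1, 0.7],
                ["b", 0.0, 0.8, 0.1, 0.1],
                ["b", 2.0, 0.2, 0.7, 0.1],
            ]
        )
        ev = build_pattern_event_table(df, "P1", ["P2", "P3"])
        assert set(zip(ev.subject_id, ev.event)) == {("a", 2), ("b", 1)}
        assert ev.event_names == {1: "P2", 2: "P3"}

    def test_baseline_filter_excludes_low_source_probability(self):
        df = self.frame(
            [["a", 0.0, 0.6, 0.3, 0.1], ["a", 1.0, 0.2, 0.7, 0.1]]
        )
        ev = build_pattern_event_table(df, "P1", ["P2", "P3"], baseline_threshold=0.7)
        assert len(ev) == 0

    def test_unordered_visits_refused(self):
        df = self.frame(
            [["a", 2.0, 0.9, 0.05, 0.05], ["a", 1.0, 0.8, 0.1, 0.1]]
        )
        with pytest.raises(ValueError, match="sorted"):
            build_pattern_event_table(df, "P1", ["P2", "P3"])

    def test_noise_free_closed_loop_recovers_planted_times(self):
        spec = synthetic.SyntheticCohortSpec(
            n_cn=5, n_pt_per_subtype=(40, 40), n_gm=20, n_wm=4, n_vent=4, mask_size=4,
            n_visits=7, seed=13,
        )
        _, gt = synthetic.generate_longitudinal(spec)
        prob = synthetic.stage_probabilities(gt)
        ev = build_pattern_event_table(prob, "P1", ["P2", "P3"], baseline_threshold=0.7)
        # planted first stage-2 visit per included subject
        df = gt.data
        for sid, t, code in zip(ev.subject_id, ev.time, ev.event):
            sub = df[df["participant_id"] == sid]
            prog = sub[sub["stage"] >= 2]
            if code == 0:
                assert prog.empty
            else:
                assert t == prog["visit_time"].min()
                assert code - 1 == sub["pathway"].iloc[0]


class TestKaplanMeier:
    def test_hand_product_limit_example(self):
        ev = simple_events([1, 2, 3, 4], [1, 1, 1, 1])
        curve = kaplan_meier(ev)
        np.testing.assert_allclose(curve.at([1, 2, 3, 4]), [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_gives_unit_survival_with_warning(self):
        ev = simple_events([1, 2, 3], [0, 0, 0])
        with pytest.warns(UserWarning, match="censored"):
            curve = kaplan_meier(ev)
        np.testing.assert_allclose(curve.survival, 1.0)

    def test_monotone_from_one(self):
        rng = np.random.default_rng(0)
        ev = simple_events(rng.exponential(2, 50), rng.integers(0, 2, 50))
        curve = kaplan_meier(ev)
        assert curve.at(0) == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)


class TestCompetingRisks:
    def test_single_event_type_reduces_to_one_minus_km(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(2, 80).round(2)
        ev = simple_events(times, np.ones(80))
        cif = cumulative_incidence_competing(ev)[1]
        km = kaplan_meier(ev)
        for t in (0.5, 1.0, 2.0, 4.0):
            assert incidence_at(cif, t) == pytest.approx(1 - km.at(t), abs=1e-10)

    def test_conservation_of_probability(self):
        rng = np.random.default_rng(2)
        n = 120
        times = rng.exponential(3, n)  # continuous: tie-free
        events = rng.choice([0, 1, 2], n, p=[0.3, 0.4, 0.3])
        ev = simple_events(times, events)
        curves = cumulative_incidence_competing(ev)
        km_any = kaplan_meier(simple_events(times, (events != 0).astype(int)))
        for t in (1.0, 2.0, 5.0):
            total = sum(incidence_at(c, t) for c in curves.values()) + km_any.at(t)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_planted_pathway_split_recovered(self):
        """70/30 routing shows up as terminal cumulative incidences."""
        spec = synthetic.SyntheticCohortSpec(
            n_cn=5, n_pt_per_subtype=(250, 250), n_gm=20, n_wm=4, n_vent=4, mask_size=4,
            pathway_mix=0.7, n_visits=10, seed=21,
        )
        _, gt = synthetic.generate_longitudinal(spec)
        prob = synthetic.stage_probabilities(gt)
        ev = build_pattern_event_table(prob, "P1", ["P2", "P3"], baseline_threshold=0.7)
        curves = cumulative_incidence_competing(ev)
        t_end = ev.time.max()
        inc2 = incidence_at(curves[1], t_end)
        inc3 = incidence_at(curves[2], t_end)
        assert inc2 / (inc2 + inc3) == pytest.approx(0.7, abs=0.05)


class TestConcordance:
    def test_perfectly_ordered_risk(self):
        ev = simple_events([5, 4, 3, 2, 1], [1, 1, 1, 1, 1])
        assert concordance_index([1, 2, 3, 4, 5], ev) == 1.0

    def test_constant_risk_is_half(self):
        ev = simple_events([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index([2, 2, 2, 2], ev) == 0.5

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 40
            times = rng.exponential(1, n).round(2)
            events = rng.integers(0, 2, n)
            risk = rng.normal(size=n)
            ev = simple_events(times, events)
            num = den = 0.0
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    # pair comparable when i has an observed event before j's time
                    if events[i] and (times[i] < times[j] or (times[i] == times[j] and not events[j])):
                        den += 1
                        if risk[i] > risk[j]:
                            num += 1
                        elif risk[i] == risk[j]:
                            num += 0.5
            assert concordance_index(risk, ev) == pytest.approx(num / den)

    def test_null_risk_concentrates_at_half(self):
        rng = np.random.default_rng(4)
        means = []
        for _ in range(100):
            times = rng.exponential(1, 200)
            ev = simple_events(times, np.ones(200))
            means.append(concordance_index(rng.normal(size=200), ev))
        assert abs(np.mean(means) - 0.5) < 0.02

    def test_no_comparable_pairs_refused(self):
        ev = simple_events([1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1, 2, 3], ev)


class TestRepeatedCVCox:
    @staticmethod
    def ph_cohort(n, rng, informative=True):
        x = rng.normal(size=n)
        hazard = np.exp(1.5 * x) if informative else np.ones(n)
        times = rng.exponential(1.0 / hazard)
        cens = rng.exponential(2.0, n)
        obs = (times <= cens).astype(int)
        t = np.minimum(times, cens)
        feats = pd.DataFrame({"x": x})
        return feats, simple_events(t, obs, features=feats)

    def test_informative_feature_beats_null(self):
        rng = np.random.default_rng(5)
        feats, ev = self.ph_cohort(300, rng, informative=True)
        res = repeated_cv_cox_cindex(feats, ev, n_repeats=10, rng=np.random.default_rng(0))
        assert res.mean > 0.7
        assert res.values.shape == (20,)

    def test_null_feature_near_half(self):
        rng = np.random.default_rng(6)
        feats, ev = self.ph_cohort(300, rng, informative=False)
        res = repeated_cv_cox_cindex(feats, ev, n_repeats=20, rng=np.random.default_rng(0))
        assert abs(res.mean - 0.5) < 0.03

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        feats, ev = self.ph_cohort(120, rng)
        a = repeated_cv_cox_cindex(feats, ev, n_repeats=5, rng=np.random.default_rng(1))
        b = repeated_cv_cox_cindex(feats, ev, n_repeats=5, rng=np.random.default_rng(1))
        np.testing.assert_array_equal(a.values, b.values)


class TestHorizonDiscrimination:
    def test_score_equal_to_outcome_is_perfect(self):
        times = np.array([1, 1, 1, 9, 9, 9], dtype=float)
        ev = simple_events(times, [1, 1, 1, 0, 0, 0])
        score = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        out = horizon_discrimination(score, ev, [5.0])
        assert out[5.0]["auc"] == 1.0
        thr = out[5.0]["threshold"]
        assert np.all(score[:3] >= thr) and np.all(score[3:] < thr)

    def test_threshold_sits_at_sensitivity_equals_specificity(self):
        rng = np.random.default_rng(8)
        n = 400
        score = rng.random(n)
        times = np.where(rng.random(n) < score, 1.0, 9.0)
        ev = simple_events(times, np.ones(n))
        out = horizon_discrimination(score, ev, [5.0])
        thr = out[5.0]["threshold"]
        pos = (times <= 5.0)
        tpr = np.mean(score[pos] >= thr)
        fpr = np.mean(score[~pos] >= thr)
        assert abs(tpr + fpr - 1.0) < 0.05

    def test_null_score_auc_near_half(self):
        rng = np.random.default_rng(9)
        aucs = []
        for _ in range(100):
            times = np.where(rng.random(500) < 0.4, 1.0, 9.0)
            ev = simple_events(times, np.ones(500))
            aucs.append(horizon_discrimination(rng.random(500), ev, [5.0])[5.0]["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_degenerate_horizon_reported_missing(self):
        ev = simple_events([9, 9, 9], [0, 0, 0])
        out = horizon_discrimination([0.1, 0.2, 0.3], ev, [5.0])
        assert np.isnan(out[5.0]["auc"])

    def test_censored_before_horizon_excluded(self):
        times = np.array([2.0, 3.0, 9.0, 9.0])
        ev = simple_events(times, [0, 1, 0, 0])
        out = horizon_discrimination([0.9, 0.8, 0.1, 0.2], ev, [5.0])
        assert out[5.0]["n_pos"] == 1
        assert out[5.0]["n_neg"] == 2
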