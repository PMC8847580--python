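import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegfp.authentication import AuthPolicy
from eegfp.errors import ShapeError, UndefinedRateError
from eegfp.evaluation import (
    CohortSplit,
    Trial,
    TrialSet,
    accuracy_precision_recall,
    build_trials,
    compute_fingerprint_table,
    det_curve,
    eer_threshold,
    far_frr,
    four_case_matrix,
)
from eegfp.fingerprint_model import FingerprintVector


def make_trials(genuine, impostor, name="cosine", group="alpha"):
    trials = [
        Trial("a", "a", i, group, True, float(d)) for i, d in enumerate(genuine)
    ] + [
        Trial("a", "b", i, group, False, float(d)) for i, d in enumerate(impostor)
    ]
    return TrialSet(name, trials)


class TestFarFrr:
    def test_threshold_below_everything(self):
        ts = make_trials([0.2, 0.3], [0.5, 0.6])
        assert far_frr(ts, 0.1) == (0.0, 1.0)

    def test_threshold_above_everything(self):
        ts = make_trials([0.2, 0.3], [0.5, 0.6])
        assert far_frr(ts, 1.0) == (1.0, 0.0)

    def test_separated_toy(self):
        ts = make_trials([0.1, 0.2], [0.3, 0.4])
        assert far_frr(ts, 0.25) == (0.0, 0.0)

    def test_boundary_accepts(self):
        ts = make_trials([0.2], [0.2])
        far, frr = far_frr(ts, 0.2)  # acceptance is <= threshold
        assert (far, frr) == (1.0, 0.0)

    def test_empty_class(self):
        with pytest.raises(UndefinedRateError):
            far_frr(make_trials([], [0.5]), 0.2)


class TestDetCurve:
    def test_separated_toy_contains_origin(self):
        ts = make_trials([0.1, 0.2], [0.3, 0.4])
        curve = det_curve(ts)
        assert any(f == 0.0 and r == 0.0 for f, r in zip(curve.far, curve.frr))

    def test_identical_distributions(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        curve = det_curve(make_trials(vals, list(vals)))
        point = eer_threshold(curve)
        assert point.eer == pytest.approx(0.5, abs=0.13)
        # at every threshold the acceptance fraction is shared
        np.testing.assert_allclose(curve.far, 1.0 - curve.frr)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        ts = make_trials(rng.random(10), rng.random(10))
        curve = det_curve(ts)
        gen = ts.genuine_distances
        imp = ts.impostor_distances
        for t, f, r in zip(curve.thresholds, curve.far, curve.frr):
            assert f == (imp <= t).mean()
            assert r == (gen > t).mean()

    def test_monotone_rates(self):
        rng = np.random.default_rng(10)
        ts = make_trials(rng.random(25), rng.random(25) + 0.2)
        curve = det_curve(ts)
        assert (np.diff(curve.far) >= 0).all()
        assert (np.diff(curve.frr) <= 0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ShapeError):
            det_curve(make_trials([0.1], [0.5]), threshold_grid=[])

    @settings(max_examples=50, deadline=None)
    @given(
        gen=st.lists(st.floats(0, 1), min_size=1, max_size=20),
        imp=st.lists(st.floats(0, 1), min_size=1, max_size=20),
    )
    def test_monotonicity_property(self, gen, imp):
        curve = det_curve(make_trials(gen, imp))
        assert (np.diff(curve.far) >= 0).all()
        assert (np.diff(curve.frr) <= 0).all()
        assert ((curve.far >= 0) & (curve.far <= 1)).all()
        assert ((curve.frr >= 0) & (curve.frr <= 1)).all()


class TestEerThreshold:
    def test_separated_toy_zero_eer(self):
        point = eer_threshold(det_curve(make_trials([0.1, 0.2], [0.3, 0.4])))
        assert point.eer == 0.0
        # last point of the bottom-left corner: the far edge of the margin
        assert 0.2 < point.threshold < 0.3

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        ts = make_trials(rng.random(10), rng.random(10))
        curve = det_curve(ts)
        point = eer_threshold(curve)
        gaps = np.abs(curve.far - curve.frr)
        assert gaps[np.flatnonzero(curve.thresholds == point.threshold)[0]] == gaps.min()

    def test_duplication_invariance(self):
        rng = np.random.default_rng(12)
        gen, imp = rng.random(8), rng.random(8)
        p1 = eer_threshold(det_curve(make_trials(gen, imp)))
        p2 = eer_threshold(det_curve(make_trials(
            np.repeat(gen, 2), np.repeat(imp, 2))))
        assert p1.eer == pytest.approx(p2.eer)
        assert p1.threshold == pytest.approx(p2.threshold)

    def test_empty_curve(self):
        from eegfp.evaluation import DetCurve
        with pytest.raises(ShapeError):
            eer_threshold(DetCurve(np.array([]), np.array([]), np.array([])))


class TestFourCaseMatrix:
    def make_mixed(self):
        trials = []
        for group, base in (("alpha", 0.0), ("beta", 0.05)):
            for i in range(4):
                trials.append(Trial("a", "a", i, group, True, base + 0.1))
                trials.append(Trial("a", "b", i, group, False, base + 0.5))
        return TrialSet("cosine", trials)

    def test_separating_threshold_all_cells_one(self):
        cells = four_case_matrix(self.make_mixed(), AuthPolicy("cosine", 0.3))
        assert cells == {
            "alpha_genuine": 1.0, "alpha_impostor": 1.0,
            "beta_genuine": 1.0, "beta_impostor": 1.0,
        }

    def test_zero_threshold_boundary(self):
        ts = self.make_mixed()
        cells = four_case_matrix(ts, AuthPolicy("cosine", 0.0))
        assert cells["alpha_genuine"] == 0.0  # no genuine distance is exactly 0
        assert cells["alpha_impostor"] == 1.0
        assert cells["beta_impostor"] == 1.0

    def test_empty_cell_reported_absent(self):
        ts = make_trials([0.1], [0.5], group="alpha")
        cells = four_case_matrix(ts, AuthPolicy("cosine", 0.3))
        assert cells["beta_genuine"] is None
        assert cells["alpha_genuine"] == 1.0

    def test_pooled_accuracy_equals_weighted_cells(self):
        ts = self.make_mixed()
        policy = AuthPolicy("cosine", 0.12)
        cells = four_case_matrix(ts, policy)
        acc, _, _ = accuracy_precision_recall(ts, policy)
        weighted = 0.0
        for group in ("alpha", "beta"):
            for genuine in (True, False):
                cell = [t for t in ts.trials
                        if t.group == group and t.genuine == genuine]
                key = f"{group}_{'genuine' if genuine else 'impostor'}"
                weighted += cells[key] * len(cell)
        assert acc == pytest.approx(weighted / len(ts))

    def test_recount_oracle(self):
        rng = np.random.default_rng(13)
        trials = [
            Trial("a", "b", i, rng.choice(["alpha", "beta"]),
                  bool(rng.integers(2)), float(rng.random()))
            for i in range(60)
        ]
        ts = TrialSet("cosine", trials)
        policy = AuthPolicy("cosine", 0.4)
        cells = four_case_matrix(ts, policy)
        for group in ("alpha", "beta"):
            for genuine in (True, False):
                cell = [t for t in trials
                        if t.group == group and t.genuine == genuine]
                key = f"{group}_{'genuine' if genuine else 'impostor'}"
                if not cell:
                    assert cells[key] is None
                    continue
                correct = sum((t.distance <= 0.4) == t.genuine for t in cell)
                assert cells[key] == pytest.approx(correct / len(cell))

    def test_distance_mismatch(self):
        with pytest.raises(ShapeError):
            four_case_matrix(make_trials([0.1], [0.5]),
                             AuthPolicy("euclidean", 0.3))


class TestAccuracyPrecisionRecall:
    def test_perfect_separation(self):
        ts = make_trials([0.1, 0.2], [0.5, 0.6])
        point = eer_threshold(det_curve(ts))
        assert accuracy_precision_recall(ts, AuthPolicy("cosine", point.threshold)) \
            == (1.0, 1.0, 1.0)

    def test_all_rejected_recall_zero(self):
        ts = make_trials([0.5, 0.6], [0.7, 0.8])
        acc, prec, rec = accuracy_precision_recall(ts, AuthPolicy("cosine", 0.1))
        assert rec == 0.0
        assert prec is None  # no acceptances at all

    def test_hand_computed_confusion(self):
        # 10 trials with known confusion at threshold 0.35:
        # genuine: 0.1 0.2 0.3 (TP) / 0.4 0.5 (FN); impostor: 0.3 0.25 (FP) /
        # 0.6 0.7 0.8 (TN) -> acc 6/10, prec 3/5, recall 3/5
        ts = make_trials([0.1, 0.2, 0.3, 0.4, 0.5],
                         [0.3, 0.25, 0.6, 0.7, 0.8])
        acc, prec, rec = accuracy_precision_recall(ts, AuthPolicy("cosine", 0.35))
        assert acc == pytest.approx(0.6)
        assert prec == pytest.approx(0.6)
        assert rec == pytest.approx(0.6)

    def test_empty_trials(self):
        with pytest.raises(UndefinedRateError):
            accuracy_precision_recall(TrialSet("cosine", []),
                                      AuthPolicy("cosine", 0.1))


class TestCohortSplit:
    def test_disjoint_enforced(self):
        with pytest.raises(ShapeError):
            CohortSplit(("a", "b"), ("b", "c"))

    def test_group_lookup(self):
        split = CohortSplit(("a",), ("b",))
        assert split.group_of("a") == "alpha"
        assert split.group_of("b") == "beta"
        with pytest.raises(ShapeError):
            split.group_of("c")


class TestBuildTrials:
    def synthetic_table(self, n_subjects, n_probes, m=8, seed=0):
        rng = np.random.default_rng(seed)
        table = {}
        for i in range(n_subjects):
            table[f"S{i:03d}"] = {
                "enroll": FingerprintVector(rng.random(m), "v"),
                "probes": [FingerprintVector(rng.random(m), "v")
                           for _ in range(n_probes)],
            }
        return table

    @pytest.mark.parametrize("s, p", [(2, 1), (3, 2), (5, 3)])
    def test_counts_match_closed_form(self, s, p):
        table = self.synthetic_table(s, p)
        ids = sorted(table)
        split = CohortSplit(tuple(ids[:-1]), (ids[-1],))
        ts = build_trials([], None, [], None, split, table=table)
        assert ts.genuine_distances.size == s * p
        assert ts.impostor_distances.size == s * (s - 1) * p

    def test_counts_match_brute_force_enumeration(self):
        table = self.synthetic_table(4, 2)
        ids = sorted(table)
        split = CohortSplit(tuple(ids), ())
        ts = build_trials([], None, [], None, split, table=table)
        expected = {(c, o, j) for c in ids for o in ids for j in range(2)}
        got = {(t.claimed, t.probe_subject, t.probe_index) for t in ts.trials}
        assert got == expected

    def test_identical_probes_zero_genuine_distance(self):
        rng = np.random.default_rng(1)
        vec = rng.random(8)
        table = {
            sid: {"enroll": FingerprintVector(vec.copy(), "v"),
                  "probes": [FingerprintVector(vec.copy(), "v")]}
            for sid in ("S000", "S001")
        }
        split = CohortSplit(("S000", "S001"), ())
        ts = build_trials([], None, [], None, split, table=table,
                          distance_name="euclidean")
        assert ts.genuine_distances.size == 2
        assert ts.impostor_distances.size == 2
        np.testing.assert_allclose(ts.genuine_distances, 0.0)

    def test_subsampled_impostors(self):
        table = self.synthetic_table(6, 2)
        ids = sorted(table)
        split = CohortSplit(tuple(ids), ())
        ts = build_trials([], None, [], None, split, table=table,
                          max_impostors_per_claim=2, pairing_seed=3)
        assert ts.impostor_distances.size == 6 * 2 * 2

    def test_end_to_end_with_model(self, tiny_trained, tiny_cohort):
        _, f, channels, params = tiny_trained
        ids = sorted({r.subject_id for r in tiny_cohort})
        split = CohortSplit(tuple(ids[:2]), tuple(ids[2:]))
        ts = build_trials(tiny_cohort, f, channels, params, split,
                          probes_per_subject=2)
        s = len(ids)
        assert ts.genuine_distances.size == s * 2
        assert ts.impostor_distances.size == s * (s - 1) * 2
        assert (ts.genuine_distances >= 0).all()

    def test_single_session_subject_excluded(self, tiny_trained, tiny_cohort):
        _, f, channels, params = tiny_trained
        # drop one subject's second session
        cohort = [r for r in tiny_cohort
                  if not (r.subject_id == "S002" and r.meta["session"] == 1)]
        table = compute_fingerprint_table(cohort, f, channels, params)
        assert "S002" not in table
        assert len(table) == 2
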