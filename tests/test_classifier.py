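"""Feature construction, balanced-cost SVM training (vs a QP oracle),
cross-validated ROC, motif ranking and FPR calibration."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import cisclassify as cc
from cisclassify.classifier import (
    FeatureMatrix,
    class_costs,
    roc_from_scores,
)
from cisclassify.records import SequenceRecord

from .conftest import point_mass_pwm
from .oracles import svm_qp_oracle


def toy_matrix(values, labels, ids=None, motif_ids=None):
    """Feature matrix from toy data, shifted per-column to respect the
    non-negativity invariant of match densities (a constant column shift
    only moves the SVM bias)."""
    values = np.asarray(values, float)
    values = values - np.minimum(values.min(axis=0), 0.0)[None, :]
    n, m = values.shape
    return FeatureMatrix(
        ids or [f"s{i}" for i in range(n)],
        motif_ids or [f"m{j}" for j in range(m)],
        values,
        np.asarray(labels),
    )


# ---------------------------------------------------------------------------
# Matched controls


class TestMatchedControls:
    def test_n_zero(self, world, study):
        out = cc.sample_matched_controls(
            study["positives"], world.genome, study["exclusions"], n=0, seed=0
        )
        assert out == []

    def test_acceptance_rule(self, study, world):
        """Each control matches its drawn template in length exactly and in
        GC within +/- 0.05."""
        positives = study["positives"]
        lengths = {len(p) for p in positives}
        gcs = [p.gc_fraction for p in positives]
        controls = cc.sample_matched_controls(
            positives, world.genome, study["exclusions"], n=50, seed=3
        )
        for ctl in controls:
            assert len(ctl) in lengths
            assert min(gcs) - 0.05 <= ctl.gc_fraction <= max(gcs) + 0.05

    def test_controls_avoid_exclusions(self, study, world):
        controls = cc.sample_matched_controls(
            study["positives"], world.genome, study["exclusions"], n=30, seed=4
        )
        for ctl in controls:
            assert not any(ctl.origin.overlaps(x) for x in study["exclusions"])

    def test_length_distribution_ks(self, world):
        """KS statistic between control and positive length distributions is
        small for a 5-length positive set at n = 1000."""
        rng = np.random.default_rng(5)
        positives = []
        for i, L in enumerate((400, 600, 800, 1000, 1200)):
            for j in range(4):
                positives.append(
                    SequenceRecord(f"p{i}{j}", cc.sample_background(L, 0.43, seed=50 + i * 7 + j).residues)
                )
        controls = cc.sample_matched_controls(
            positives, world.genome, [], n=1000, seed=6
        )
        ks = ks_2samp([len(p) for p in positives], [len(c) for c in controls]).statistic
        assert ks <= 0.1


# ---------------------------------------------------------------------------
# Feature matrix


class TestBuildFeatureMatrix:
    def test_zero_match_row(self, signal_pwms):
        seq = SequenceRecord("bg", "AT" * 300)
        fm = cc.build_feature_matrix([seq], signal_pwms, p_threshold=1e-6)
        assert np.all(fm.values == 0)

    def test_locality_of_extra_planted_copy(self, signal_pwms):
        """Planting one extra copy of motif j into sequence i increases only
        entry (i, j), by 1/length."""
        seqs = [
            cc.sample_background(1000, 0.43, seed=70 + i) for i in range(3)
        ]
        for i, s in enumerate(seqs):
            s.id = f"s{i}"
        bg = np.full(4, 0.25)
        before = cc.build_feature_matrix(seqs, signal_pwms, background=bg)
        target = seqs[1]
        planted, placements = cc.plant_motifs(target, signal_pwms[:1], 1, seed=71)
        # ensure the planted copy is scanner-visible and no old site destroyed
        seqs2 = [seqs[0], planted, seqs[2]]
        after = cc.build_feature_matrix(seqs2, signal_pwms, background=bg)
        delta = after.values - before.values
        expected = np.zeros_like(delta)
        n_new = after.values[1, 0] * 1000 - before.values[1, 0] * 1000
        assert delta[0].sum() == 0 and delta[2].sum() == 0
        assert delta[1, 1] == 0 and delta[1, 2] == 0
        assert n_new >= 0  # planting can only add or relocate matches of pwm 0

    def test_entries_match_scanner_counts(self, signal_pwms):
        seqs, _ = cc.make_positives(5, signal_pwms, seed=72)
        fm = cc.build_feature_matrix(seqs, signal_pwms)
        for i, seq in enumerate(seqs):
            for j, pwm in enumerate(signal_pwms):
                matches = cc.scan_sequence(seq, pwm, fm.p_threshold, background=fm.background)
                assert fm.values[i, j] == pytest.approx(len(matches) / len(seq))

    def test_duplicate_ids_rejected(self, signal_pwms):
        seq = SequenceRecord("dup", "ACGT" * 50)
        with pytest.raises(ValueError):
            cc.build_feature_matrix([seq, seq], signal_pwms)


# ---------------------------------------------------------------------------
# SVM


class TestTrainSvm:
    def test_1d_symmetric_separable(self):
        # the classic +/-1, +/-2 example shifted by +2 into density space:
        # the margin is still defined by the inner pair, so w = 1, b = -2
        fm = FeatureMatrix(["a", "b", "c", "d"], ["m0"],
                           np.array([[3.0], [4.0], [1.0], [0.0]]),
                           np.array([1, 1, -1, -1]))
        model = cc.train_svm(fm, C=1e6)
        assert model.weights[0] == pytest.approx(1.0, abs=1e-3)
        assert model.bias == pytest.approx(-2.0, abs=1e-3)
        assert model.total_slack == pytest.approx(0.0, abs=1e-6)

    def test_balance_arithmetic(self):
        y = np.array([1] * 10 + [-1] * 1000)
        c_pos, c_neg = class_costs(y, C=1.0)
        assert c_pos / c_neg == pytest.approx(100.0)
        assert c_pos * 10 == pytest.approx(c_neg * 1000)

    def test_single_class_rejected(self):
        fm = toy_matrix([[1.0], [2.0]], [1, 1])
        with pytest.raises(ValueError):
            cc.train_svm(fm)

    @pytest.mark.parametrize("C,imbalance", [(1.0, False), (10.0, True)])
    def test_matches_qp_oracle(self, C, imbalance):
        """(w, b) agree with a generic dual-QP solution within 1e-4 on
        20-point 2-feature instances."""
        rng = np.random.default_rng(42 if imbalance else 7)
        n_pos = 6 if imbalance else 10
        X = np.vstack(
            [
                rng.normal(loc=[1.0, 0.5], scale=0.8, size=(n_pos, 2)),
                rng.normal(loc=[-1.0, -0.5], scale=0.8, size=(20 - n_pos, 2)),
            ]
        )
        y = np.array([1] * n_pos + [-1] * (20 - n_pos))
        fm = toy_matrix(X, y)
        model = cc.train_svm(fm, C=C)
        c_pos, c_neg = class_costs(y, C)
        costs = np.where(y == 1, c_pos, c_neg)
        w_ref, b_ref = svm_qp_oracle(fm.values, y, costs)
        assert np.allclose(model.weights, w_ref, atol=1e-4)
        assert model.bias == pytest.approx(b_ref, abs=1e-4)

    def test_label_swap_symmetry(self):
        """Swapping class labels negates the decision function."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        y = np.array([1] * 15 + [-1] * 15)
        m1 = cc.train_svm(toy_matrix(X, y), C=10.0)
        m2 = cc.train_svm(toy_matrix(X, -y), C=10.0)
        assert np.allclose(m1.decision(X), -m2.decision(X), atol=1e-6)


# ---------------------------------------------------------------------------
# ROC / cross-validation


class TestRoc:
    def test_pair_counting_example(self):
        roc = roc_from_scores(
            np.array([1, 1, -1, -1]), np.array([0.9, 0.4, 0.8, 0.1])
        )
        assert roc.auc == pytest.approx(0.75)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        y = np.array([1] * 20 + [-1] * 20)
        s = rng.normal(size=40) + (y == 1)
        a1 = roc_from_scores(y, s).auc
        a2 = roc_from_scores(y, np.exp(3 * s) + 7).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(10)
        y = np.array([1] * 30 + [-1] * 30)
        roc = roc_from_scores(y, rng.normal(size=60))
        assert np.all(np.diff(roc.fpr_points) >= 0)
        assert np.all(np.diff(roc.tpr_points) >= 0)


class TestCrossValidate:
    def test_separable_auc_one(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(5, 0.1, (20, 2)), rng.normal(-5, 0.1, (20, 2))])
        y = np.array([1] * 20 + [-1] * 20)
        roc, _ = cc.cross_validate(toy_matrix(X, y), k=10, C=10.0, seed=0)
        assert roc.auc == pytest.approx(1.0)

    def test_permuted_labels_near_half(self):
        """Random labels give AUC near 0.5 at n = 400."""
        rng = np.random.default_rng(12)
        X = rng.normal(size=(400, 5))
        for seed in range(3):
            y = rng.permutation(np.array([1] * 200 + [-1] * 200))
            roc, _ = cc.cross_validate(toy_matrix(X, y), k=10, C=1.0, seed=seed)
            assert 0.40 <= roc.auc <= 0.60

    def test_k_exceeding_class_size_rejected(self):
        fm = toy_matrix(np.random.default_rng(0).normal(size=(8, 2)), [1] * 4 + [-1] * 4)
        with pytest.raises(ValueError):
            cc.cross_validate(fm, k=5)


# ---------------------------------------------------------------------------
# Ranking and calibration


class TestRankMotifs:
    def test_planted_feature_ranks_first(self):
        rng = np.random.default_rng(13)
        n = 60
        y = np.array([1] * 30 + [-1] * 30)
        X = rng.normal(size=(n, 51)) * 0.5
        X[:, 17] = y * 1.0 + rng.normal(size=n) * 0.05
        ranked = cc.rank_motifs(toy_matrix(X, y), C=10.0, n_partitions=100, seed=1)
        assert ranked[0].motif_id == "m17"
        assert ranked[0].median_rank == 1.0

    def test_duplicated_columns_equal_share(self):
        rng = np.random.default_rng(14)
        y = np.array([1] * 15 + [-1] * 15)
        base = y + rng.normal(size=30) * 0.3
        X = np.column_stack([base, base, rng.normal(size=30)])
        ranked = cc.rank_motifs(toy_matrix(X, y), C=10.0, n_partitions=20, seed=2)
        shares = {r.motif_id: r.weight_share for r in ranked}
        assert shares["m0"] == pytest.approx(shares["m1"], abs=1e-9)

    def test_constant_zero_feature_gets_zero_share(self):
        rng = np.random.default_rng(15)
        y = np.array([1] * 15 + [-1] * 15)
        X = np.column_stack([y + rng.normal(size=30) * 0.2, np.zeros(30)])
        ranked = cc.rank_motifs(toy_matrix(X, y), C=10.0, n_partitions=20, seed=3)
        zero = [r for r in ranked if r.motif_id == "m1"][0]
        assert zero.weight_share == pytest.approx(0.0, abs=1e-12)
        assert zero.sign == "0"

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(16)
        y = np.array([1] * 20 + [-1] * 20)
        X = rng.normal(size=(40, 7)) + y[:, None] * 0.3
        ranked = cc.rank_motifs(toy_matrix(X, y), C=10.0, n_partitions=10, seed=4)
        assert sum(r.weight_share for r in ranked) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "weights,fraction,expected",
    [((5, 3, 1, 1), 0.5, 2), ((1, 1, 1, 1), 0.5, 3), ((10,), 0.5, 1), ((0, 0), 0.5, 0)],
)
def test_weight_concentration(weights, fraction, expected):
    assert cc.weight_concentration(np.array(weights, float), fraction) == expected


@pytest.fixture(scope="module")
def calib_fm():
    rng = np.random.default_rng(17)
    X = np.vstack(
        [rng.normal(1.0, 1.0, (40, 3)), rng.normal(-1.0, 1.0, (400, 3))]
    )
    y = np.array([1] * 40 + [-1] * 400)
    return toy_matrix(X, y)


class TestCalibrateFprCutoff:

    def test_fpr_one_is_lower_bound(self, calib_fm):
        fm = calib_fm
        cutoff, model = cc.calibrate_fpr_cutoff(fm, C=1.0, fpr=1.0, n_partitions=20, seed=5)
        pool_min = model.decision(fm.values[fm.labels == -1]).min()
        assert cutoff <= pool_min + 1e-6 or cutoff <= 0  # pooled min over partitions

    def test_cutoff_monotone_in_fpr(self, calib_fm):
        fm = calib_fm
        cuts = [
            cc.calibrate_fpr_cutoff(fm, C=1.0, fpr=f, n_partitions=20, seed=6)[0]
            for f in (0.01, 0.05, 0.1, 0.5)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(cuts, cuts[1:]))

    def test_invalid_fpr(self, calib_fm):
        fm = calib_fm
        with pytest.raises(ValueError):
            cc.calibrate_fpr_cutoff(fm, fpr=0.0)

    def test_model_json_roundtrip(self, calib_fm, tmp_path):
        fm = calib_fm
        cutoff, model = cc.calibrate_fpr_cutoff(fm, C=1.0, fpr=0.05, n_partitions=10, seed=7)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = cc.LinearModel.from_json(path)
        assert np.allclose(back.weights, model.weights)
        assert back.cutoff == pytest.approx(cutoff)
        assert back.class_costs == pytest.approx(model.class_costs)
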