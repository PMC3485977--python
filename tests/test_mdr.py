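import numpy as np
import pytest

from hcymdr.genotype_data import FormatError, impute_mode
from hcymdr.mdr import (
    HIGH,
    LOW,
    UNASSIGNED,
    MdrConfig,
    MissingGenotypeError,
    ModelEvaluation,
    balanced_accuracy,
    enumerate_models,
    evaluate_models,
    fit_risk_model,
    make_folds,
    permutation_test,
    predict,
    risk_cell_summary,
    select_best,
)
from hcymdr.simulate import SimConfig, SimMarkerSpec, simulate_epistatic, simulate_null, xor_penetrance
from conftest import (
    build_dataset,
    build_paired_dataset,
    oracle_balanced_accuracy,
    oracle_risk_labels,
)


def xor_toy():
    """Cases at cells (0,0) and (1,1); controls at (0,1) and (1,0)."""
    codes = [[0, 0], [1, 1], [0, 1], [1, 0]]
    return build_dataset(codes, ["case", "case", "control", "control"])


class TestEnumerateModels:
    @pytest.mark.parametrize("k,expected", [(1, 4), (2, 6), (3, 4), (4, 1)])
    def test_subset_counts(self, k, expected):
        assert len(enumerate_models(list("ABCD"), k)) == expected

    def test_lexicographic_order(self):
        assert enumerate_models(["A", "B", "C"], 2) == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_models(["A"], 2)


class TestFitRiskModel:
    def test_majority_case_cell_is_high(self):
        ds = build_dataset([[0]] * 4, ["case", "case", "case", "control"])
        model = fit_risk_model(ds, ["M1"], MdrConfig(ratio_threshold=1.0))
        assert model.cells[(0,)].label == HIGH
        assert (model.cells[(0,)].n_case, model.cells[(0,)].n_control) == (3, 1)

    def test_default_threshold_is_training_ratio(self):
        # 3:1 cases overall, so a 3:1 cell sits exactly at the threshold
        ds = build_dataset([[0]] * 4, ["case", "case", "case", "control"])
        model = fit_risk_model(ds, ["M1"])
        assert model.threshold == pytest.approx(3.0)
        assert model.cells[(0,)].label == UNASSIGNED

    @pytest.mark.parametrize("policy", [HIGH, LOW, UNASSIGNED])
    def test_tie_policy(self, policy):
        ds = build_dataset([[0]] * 4, ["case", "case", "control", "control"])
        model = fit_risk_model(ds, ["M1"], MdrConfig(tie_policy=policy))
        assert model.cells[(0,)].label == policy

    def test_xor_pattern(self):
        model = fit_risk_model(xor_toy(), ["M1", "M2"])
        assert model.cells[(0, 0)].label == HIGH
        assert model.cells[(1, 1)].label == HIGH
        assert model.cells[(0, 1)].label == LOW
        assert model.cells[(1, 0)].label == LOW
        assert model.cells[(2, 2)].label == UNASSIGNED  # unobserved

    def test_missing_genotypes_rejected(self):
        ds = build_dataset([[0], [-1]], ["case", "control"])
        with pytest.raises(MissingGenotypeError, match="impute"):
            fit_risk_model(ds, ["M1"])

    def test_matches_bruteforce_on_random_small_data(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(1, 4))
            codes = rng.integers(0, 3, size=(n, k))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            statuses = ["case" if v else "control" for v in y]
            ds = build_dataset(codes, statuses)
            model = fit_risk_model(ds, ds.marker_names)
            t = y.sum() / (n - y.sum())
            expected = oracle_risk_labels(codes, y, threshold=t)
            for combo, cell in model.cells.items():
                assert cell.label == expected.get(combo, UNASSIGNED)


class TestPredictAndAccuracy:
    def test_high_cell_predicts_case(self):
        ds = xor_toy()
        model = fit_risk_model(ds, ["M1", "M2"])
        np.testing.assert_array_equal(predict(model, ds), [1, 1, 0, 0])
        assert balanced_accuracy(predict(model, ds), ds.is_case.astype(int)) == 1.0

    def test_unassigned_cell_prediction_modes(self):
        train = xor_toy()
        model = fit_risk_model(train, ["M1", "M2"])
        fresh = build_dataset([[2, 2]], ["case"])
        assert predict(model, fresh)[0] == 0  # default: predicted control
        assert predict(model, fresh, MdrConfig(empty_cell_prediction="exclude"))[0] == -1

    def test_balanced_accuracy_arithmetic(self):
        true = np.array([1] * 10 + [0] * 10)
        pred = np.array([1] * 8 + [0] * 2 + [0] * 6 + [1] * 4)
        assert balanced_accuracy(pred, true) == pytest.approx(0.7)

    def test_all_control_prediction_is_half(self):
        true = np.array([1, 1, 0, 0])
        assert balanced_accuracy(np.zeros(4), true) == pytest.approx(0.5)

    def test_excluded_subjects_leave_denominator(self):
        true = np.array([1, 1, 0, 0])
        pred = np.array([1, -1, 0, -1])
        assert balanced_accuracy(pred, true) == 1.0

    def test_one_class_truth_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.array([1, 0]), np.array([1, 1]))

    def test_matches_bruteforce_confusion(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 13))
            codes = rng.integers(0, 3, size=(n, 2))
            y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
            ds = build_dataset(codes, ["case" if v else "control" for v in y])
            model = fit_risk_model(ds, ds.marker_names)
            acc = balanced_accuracy(predict(model, ds), y)
            labels = {c: cell.label for c, cell in model.cells.items()}
            assert acc == pytest.approx(oracle_balanced_accuracy(codes, y, labels))


class TestMakeFolds:
    def _cohort(self, n_pairs=409, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        case = rng.integers(0, 3, size=(n_pairs, 2))
        ctrl = rng.integers(0, 3, size=(n_pairs, 2))
        return build_paired_dataset(case, ctrl)

    def test_pairs_kept_intact_and_balanced(self):
        ds = self._cohort()
        cfg = MdrConfig(folds=10, reps=3, seed=5)
        folds = make_folds(ds, cfg)
        assert folds.shape == (3, ds.n_subjects)
        for r in range(3):
            # case and control of each pair share a fold
            np.testing.assert_array_equal(folds[r, 0::2], folds[r, 1::2])
            sizes = np.bincount(folds[r, 0::2], minlength=10)
            assert sizes.min() >= 40 and sizes.max() <= 41
            case_mask = ds.is_case
            for f in range(10):
                in_fold = folds[r] == f
                assert (in_fold & case_mask).sum() == (in_fold & ~case_mask).sum()

    def test_deterministic_given_seed(self):
        ds = self._cohort()
        cfg = MdrConfig(seed=17)
        np.testing.assert_array_equal(make_folds(ds, cfg), make_folds(ds, cfg))

    def test_split_count_is_folds_times_reps(self):
        cfg = MdrConfig(folds=10, reps=10)
        assert cfg.n_splits == 100

    def test_orphan_pair_rejected(self):
        ds = build_dataset([[0], [1], [2]], ["case", "control", "case"],
                           pair_ids=["p1", "p1", "p2"])
        with pytest.raises(FormatError, match="orphan"):
            make_folds(ds, MdrConfig(folds=2))

    def test_unpaired_mode_partitions_all_subjects(self):
        ds = build_dataset([[0]] * 20, ["case", "control"] * 10)
        folds = make_folds(ds, MdrConfig(folds=5, reps=2, paired=False))
        for r in range(2):
            assert np.bincount(folds[r], minlength=5).sum() == 20


class TestEvaluateModels:
    def test_single_marker_cvc_is_all_splits(self):
        ds = build_paired_dataset(
            np.random.default_rng(1).integers(0, 3, size=(60, 1)),
            np.random.default_rng(2).integers(0, 3, size=(60, 1)),
        )
        res = evaluate_models(ds, MdrConfig(k_min=1, k_max=1, folds=5, reps=2))
        assert len(res.evaluations) == 1
        assert res.evaluations[0].cvc == 10

    def test_cvc_conservation_within_size(self, rng):
        case = rng.integers(0, 3, size=(80, 3))
        ctrl = rng.integers(0, 3, size=(80, 3))
        ds = build_paired_dataset(case, ctrl)
        cfg = MdrConfig(k_min=1, k_max=3, folds=5, reps=4, seed=3)
        res = evaluate_models(ds, cfg)
        for k in (1, 2, 3):
            total = sum(ev.cvc for ev in res.evaluations if ev.k == k)
            assert total == cfg.n_splits

    def test_vectorized_search_matches_per_split_refits(self, rng):
        """Per-split accuracies agree with explicit fit/predict/score loops."""
        case = rng.integers(0, 3, size=(30, 2))
        ctrl = rng.integers(0, 3, size=(30, 2))
        ds = build_paired_dataset(case, ctrl)
        cfg = MdrConfig(k_min=1, k_max=2, folds=3, reps=2, seed=9)
        res = evaluate_models(ds, cfg)
        folds = make_folds(ds, cfg)
        y = ds.is_case.astype(int)
        for ev in res.evaluations:
            s = 0
            for r in range(cfg.reps):
                for f in range(cfg.folds):
                    test_mask = folds[r] == f
                    train = build_dataset(
                        ds.calls[~test_mask], np.array(["control", "case"])[y[~test_mask]],
                        marker_names=ds.marker_names,
                    )
                    model = fit_risk_model(train, ev.markers, cfg)
                    test = build_dataset(
                        ds.calls[test_mask], np.array(["control", "case"])[y[test_mask]],
                        marker_names=ds.marker_names,
                    )
                    acc = balanced_accuracy(predict(model, test, cfg), y[test_mask])
                    assert ev.test_per_split[s] == pytest.approx(acc)
                    train_acc = balanced_accuracy(predict(model, train, cfg), y[~test_mask])
                    assert ev.train_per_split[s] == pytest.approx(train_acc)
                    s += 1

    def test_determinism(self):
        ds = simulate_null(SimConfig(n_pairs=60, seed=4))
        ds = impute_mode(ds)
        cfg = MdrConfig(seed=11)
        a = evaluate_models(ds, cfg)
        b = evaluate_models(ds, cfg)
        for ea, eb in zip(a.evaluations, b.evaluations):
            assert ea.markers == eb.markers
            assert ea.testing_accuracy == eb.testing_accuracy
            assert ea.cvc == eb.cvc

    def test_label_swap_antisymmetry(self):
        panel = [SimMarkerSpec(f"M{i}", maf=0.5) for i in range(1, 3)]
        ds = simulate_null(SimConfig(n_pairs=200, markers=panel, seed=8))
        swapped_subjects = [
            type(s)(id=s.id, status="control" if s.status == "case" else "case",
                    pair_id=s.pair_id, sex=s.sex, age=s.age)
            for s in ds.subjects
        ]
        swapped = type(ds)(ds.markers, swapped_subjects, ds.calls)
        m1 = fit_risk_model(ds, ["M1", "M2"])
        m2 = fit_risk_model(swapped, ["M1", "M2"])
        for combo, cell in m1.cells.items():
            if cell.label == HIGH:
                assert m2.cells[combo].label == LOW
            elif cell.label == LOW:
                assert m2.cells[combo].label == HIGH
        # excluding tie/unseen cells makes the swap exactly symmetric:
        # strict cells flip, so sensitivity and specificity trade places
        cfg = MdrConfig(k_min=2, k_max=2, folds=5, reps=2, seed=2,
                        empty_cell_prediction="exclude")
        ta1 = evaluate_models(ds, cfg).best.testing_accuracy
        ta2 = evaluate_models(swapped, cfg).best.testing_accuracy
        assert ta1 == pytest.approx(ta2, abs=1e-12)


class TestSelectBest:
    def _ev(self, markers, ta, cvc):
        return ModelEvaluation(markers=markers, training_accuracy=ta,
                               testing_accuracy=ta, cvc=cvc, n_splits=100)

    def test_highest_ta_wins(self):
        evs = [self._ev(("A",), 0.4951, 97), self._ev(("B", "C"), 0.5526, 100),
               self._ev(("A", "B", "C"), 0.4780, 68)]
        assert select_best(evs).markers == ("B", "C")

    def test_parsimony_on_full_tie(self):
        evs = [self._ev(("A", "B"), 0.52, 80), self._ev(("A",), 0.52, 80)]
        assert select_best(evs).markers == ("A",)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestPermutationTest:
    def test_pvalue_formula_and_determinism(self):
        panel = [SimMarkerSpec(f"M{i}", maf=0.5) for i in range(1, 4)]
        pen = xor_penetrance("M1", "M2", high=0.95, low=0.05)
        ds = simulate_epistatic(SimConfig(n_pairs=100, markers=panel, penetrance=pen, seed=21))
        cfg = MdrConfig(k_min=1, k_max=2, folds=5, reps=2, seed=21)
        res = permutation_test(ds, cfg, n_perm=19)
        # strong signal: observed TA should beat every label permutation
        assert res.p_value == pytest.approx(1 / 20)
        assert res.p_value == (1 + (res.null_tas >= res.observed_ta).sum()) / (1 + 19)
        res2 = permutation_test(ds, cfg, n_perm=19)
        np.testing.assert_array_equal(res.null_tas, res2.null_tas)

    def test_null_tas_center_near_half(self):
        ds = impute_mode(simulate_null(SimConfig(n_pairs=150, seed=33)))
        cfg = MdrConfig(folds=5, reps=2, seed=33)
        res = permutation_test(ds, cfg, n_perm=30)
        assert 0.45 < res.null_tas.mean() < 0.58  # selection optimism stays small


class TestRiskCellSummary:
    def test_xor_toy_collapse(self):
        ds = xor_toy()
        model = fit_risk_model(ds, ["M1", "M2"])
        s = risk_cell_summary(model, ds)
        assert (s.high_cases, s.high_controls) == (2, 0)
        assert (s.low_cases, s.low_controls) == (0, 2)
        assert (s.unassigned_cases, s.unassigned_controls) == (0, 0)

    def test_tie_cells_join_neither_group(self):
        ds = build_dataset([[0]] * 4, ["case", "case", "control", "control"])
        model = fit_risk_model(ds, ["M1"])
        s = risk_cell_summary(model, ds)
        assert s.high_cases == s.low_cases == 0
        assert (s.unassigned_cases, s.unassigned_controls) == (2, 2)

    def test_totals_cover_dataset(self, rng):
        case = rng.integers(0, 3, size=(50, 2))
        ctrl = rng.integers(0, 3, size=(50, 2))
        ds = build_paired_dataset(case, ctrl)
        model = fit_risk_model(ds, ds.marker_names)
        s = risk_cell_summary(model, ds)
        total = (s.high_cases + s.low_cases + s.unassigned_cases
                 + s.high_controls + s.low_controls + s.unassigned_controls)
        assert total == ds.n_subjects
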