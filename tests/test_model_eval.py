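import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acpred import (
    ConfusionCounts,
    LabeledDataset,
    Peptide,
    SVMConfig,
    compute_metrics,
    encode_dataset,
    grid_search,
    independent_test,
    jackknife,
    kfold,
    load_model,
    predict,
    save_model,
    train,
)
from acpred.model_eval import (
    NEGATIVE_VERDICT,
    POSITIVE_VERDICT,
    confusion_from_predictions,
    decision_values,
    make_folds,
)


def classical_mcc(tp, fn, tn, fp):
    """Textbook Matthews coefficient from the 2x2 contingency table."""
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return None
    return (tp * tn - fp * fn) / denom


confusion_strategy = st.tuples(
    st.integers(1, 12), st.integers(1, 12)
).flatmap(
    lambda nn: st.tuples(
        st.just(nn[0]), st.just(nn[1]),
        st.integers(0, nn[0]), st.integers(0, nn[1]),
    )
)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics(ConfusionCounts(138, 206, 0, 0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_half_errors_give_zero_mcc(self):
        m = compute_metrics(ConfusionCounts(10, 20, 5, 10))
        assert m.mcc == pytest.approx(0.0)

    def test_back_derived_benchmark_row(self):
        # N+=138, N-=206 with 14 missed positives and 3 false positives
        m = compute_metrics(ConfusionCounts(138, 206, 14, 3))
        assert m.sn == pytest.approx(0.8986, abs=5e-5)
        assert m.sp == pytest.approx(0.9854, abs=5e-5)
        assert m.acc == pytest.approx(0.9506, abs=5e-5)
        assert m.mcc == pytest.approx(0.8978, abs=5e-5)
        # same counts through the classical contingency-table formula
        assert m.mcc == pytest.approx(classical_mcc(124, 14, 203, 3), abs=1e-12)

    def test_all_negative_prediction_has_undefined_mcc(self):
        m = compute_metrics(ConfusionCounts(10, 10, 10, 0))
        assert m.mcc is None
        assert m.acc == 0.5

    def test_absent_class_marks_sn_or_sp_undefined(self):
        m = compute_metrics(ConfusionCounts(0, 10, 0, 2))
        assert m.sn is None and m.mcc is None
        assert m.sp == pytest.approx(0.8)

    def test_total_disagreement(self):
        m = compute_metrics(ConfusionCounts(5, 7, 5, 7))
        assert m.mcc == pytest.approx(-1.0)
        assert m.acc == 0.0

    @given(confusion_strategy)
    def test_count_form_equals_classical_mcc(self, counts):
        n_pos, n_neg, fn, fp = counts
        m = compute_metrics(ConfusionCounts(n_pos, n_neg, fn, fp))
        ref = classical_mcc(n_pos - fn, fn, n_neg - fp, fp)
        if m.mcc is None or ref is None:
            # both formulations must agree the value is degenerate
            assert m.mcc is None and ref is None
        else:
            assert m.mcc == pytest.approx(ref, abs=1e-12)

    @given(confusion_strategy)
    def test_acc_is_prevalence_weighted_sn_sp(self, counts):
        n_pos, n_neg, fn, fp = counts
        m = compute_metrics(ConfusionCounts(n_pos, n_neg, fn, fp))
        assert m.acc == pytest.approx(
            (n_pos * m.sn + n_neg * m.sp) / (n_pos + n_neg), abs=1e-12
        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(5, 5, 6, 0)


class TestTrainPredict:
    def test_separable_resubstitution(self, separable_dataset):
        matrix = encode_dataset(separable_dataset, "ggap", 1)
        model = train(matrix)
        np.testing.assert_array_equal(predict(model, matrix), matrix.labels)

    def test_subset_out_of_range_is_error(self, separable_dataset):
        matrix = encode_dataset(separable_dataset, "ggap", 1)
        with pytest.raises(ValueError, match=r"\[0, 400\)"):
            train(matrix, subset=[0, 400])

    def test_single_class_training_is_error(self, separable_dataset):
        matrix = encode_dataset(separable_dataset, "ggap", 1)
        matrix.labels = np.ones_like(matrix.labels)
        with pytest.raises(ValueError, match="single class"):
            train(matrix)

    def test_empty_matrix_predicts_empty(self, separable_dataset):
        matrix = encode_dataset(separable_dataset, "ggap", 1)
        model = train(matrix)
        empty = encode_dataset(separable_dataset, "ggap", 1)
        empty.X = empty.X[:0]
        assert predict(model, empty).shape == (0,)

    def test_mismatched_encoding_is_error(self, separable_dataset):
        matrix = encode_dataset(separable_dataset, "ggap", 1)
        model = train(matrix)
        other = encode_dataset(separable_dataset, "ggap", 2)
        with pytest.raises(ValueError, match="does not match"):
            predict(model, other)

    def test_persistence_roundtrip(self, tmp_path, separable_dataset):
        matrix = encode_dataset(separable_dataset, "ggap", 1)
        model = train(matrix, subset=np.arange(50))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.encoding == "ggap" and loaded.g == 1 and loaded.omega == 400
        np.testing.assert_array_equal(loaded.subset, model.subset)
        np.testing.assert_array_equal(
            decision_values(loaded, matrix), decision_values(model, matrix)
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SVMConfig(C=0)
        with pytest.raises(ValueError):
            SVMConfig(gamma=-1)
        with pytest.raises(ValueError):
            SVMConfig(kernel="linear")


class TestGridSearch:
    def test_singleton_grid_returned_unconditionally(self, separable_dataset):
        matrix = encode_dataset(separable_dataset, "ggap", 1)
        config = grid_search(matrix, C_grid=[2.0], gamma_grid=[0.125], k=2)
        assert (config.C, config.gamma) == (2.0, 0.125)

    def test_separable_toy_finds_perfect_config(self, separable_dataset):
        from acpred.model_eval import compute_metrics as cm
        from acpred.model_eval import pooled_cv_counts

        matrix = encode_dataset(separable_dataset, "ggap", 1)
        config = grid_search(
            matrix, C_grid=[0.5, 2.0, 32.0], gamma_grid=[0.125, 2.0], k=2, seed=0
        )
        folds = make_folds(matrix.labels, 2, 0)
        counts = pooled_cv_counts(matrix.X, matrix.labels, folds, config)
        assert cm(counts).acc == 1.0

    def test_empty_grid_is_error(self, separable_dataset):
        matrix = encode_dataset(separable_dataset, "ggap", 1)
        with pytest.raises(ValueError, match="non-empty"):
            grid_search(matrix, C_grid=[], gamma_grid=[0.125])


class TestProtocols:
    def test_jackknife_separable_is_perfect(self, separable_dataset):
        metrics, counts = jackknife(separable_dataset, "ggap", 1)
        assert metrics.acc == 1.0
        assert counts.total == separable_dataset.M

    def test_jackknife_counts_conserve_m(self, separable_dataset):
        _, counts = jackknife(separable_dataset, "ggap", 1)
        assert counts.n_pos + counts.n_neg == separable_dataset.M

    def test_jackknife_invariant_to_row_order(self, separable_dataset):
        _, c1 = jackknife(separable_dataset, "ggap", 1)
        rng = np.random.default_rng(3)
        perm = rng.permutation(separable_dataset.M)
        shuffled = separable_dataset.subset(perm)
        _, c2 = jackknife(shuffled, "ggap", 1)
        assert (c1.pos_as_neg, c1.neg_as_pos) == (c2.pos_as_neg, c2.neg_as_pos)

    def test_shuffled_labels_never_beat_chance(self, random_peptides):
        """Random labels on random peptides carry no signal, so mean
        jackknife accuracy over repeated shuffles cannot exceed chance.

        Leave-one-out on a balanced set is actually pessimistically
        biased below 0.5 here: holding out a sample leaves its class in
        the training minority, and an uninformative classifier then
        predicts the training majority — the wrong class — so accuracy
        can drop far below chance rather than hover at it.
        """
        peps = random_peptides(20, seed=11)
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = np.array([1] * 10 + [-1] * 10)
            rng.shuffle(labels)
            ds = LabeledDataset(peps, labels)
            metrics, _ = jackknife(ds, "ggap", 0)
            accs.append(metrics.acc)
        assert np.mean(accs) <= 0.55

    def test_kfold_equals_jackknife_at_k_m(self, separable_dataset):
        mj, cj = jackknife(separable_dataset, "ggap", 1)
        mk, ck = kfold(separable_dataset, "ggap", 1, k=separable_dataset.M, seed=9)
        assert (cj.pos_as_neg, cj.neg_as_pos) == (ck.pos_as_neg, ck.neg_as_pos)
        assert mj == mk

    def test_kfold_separable_any_seed(self, separable_dataset):
        for seed in (0, 1, 2):
            metrics, _ = kfold(separable_dataset, "ggap", 1, k=5, seed=seed)
            assert metrics.acc == 1.0

    def test_kfold_k_too_small(self, separable_dataset):
        with pytest.raises(ValueError, match="k must be"):
            kfold(separable_dataset, "ggap", 1, k=1)


class TestIndependentTest:
    def test_resubstitution_overlap_warns(self, separable_dataset):
        matrix = encode_dataset(separable_dataset, "ggap", 1)
        model = train(matrix)
        with pytest.warns(UserWarning, match="training set"):
            metrics, counts, verdicts = independent_test(
                model, separable_dataset, training_dataset=separable_dataset
            )
        assert metrics.acc == 1.0
        assert len(verdicts) == separable_dataset.M

    def test_verdict_vocabulary(self, separable_dataset):
        matrix = encode_dataset(separable_dataset, "ggap", 1)
        model = train(matrix)
        _, _, verdicts = independent_test(model, separable_dataset)
        seen = {v["verdict"] for v in verdicts}
        assert seen == {POSITIVE_VERDICT, NEGATIVE_VERDICT}

    def test_single_peptide_class_undefined_metrics(self, separable_dataset):
        matrix = encode_dataset(separable_dataset, "ggap", 1)
        model = train(matrix)
        one = LabeledDataset([Peptide("q", "A" * 12)], np.array([1]))
        metrics, _, verdicts = independent_test(model, one)
        assert metrics.sp is None and metrics.mcc is None
        assert len(verdicts) == 1

    def test_empty_test_set_is_error(self, separable_dataset):
        matrix = encode_dataset(separable_dataset, "ggap", 1)
        model = train(matrix)
        with pytest.raises(ValueError, match="empty"):
            independent_test(model, LabeledDataset([], np.array([], int)))


def test_confusion_from_predictions_counts():
    y = np.array([1, 1, 1, -1, -1])
    yp = np.array([1, -1, 1, 1, -1])
    c = confusion_from_predictions(y, yp)
    assert (c.n_pos, c.n_neg, c.pos_as_neg, c.neg_as_pos) == (3, 2, 1, 1)
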