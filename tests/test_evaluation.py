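"""Evaluation machinery: repeated splits, baselines, method comparison."""

import numpy as np
import pytest

from mitransfer.evaluation import (EvalResult, baseline_classify,
                                   compare_methods, evaluate_subject,
                                   make_split_sequence)
from mitransfer.io import TrialTensor
from mitransfer.transfer import TrainConfig, TransferPlan

_PLAN = TransferPlan.from_name("eegnet_0")


class _LookupOracle:
    """Cheating classifier: memorizes every trial's true label by content."""

    def __init__(self, trials: TrialTensor):
        self.table = {trials.data[i].tobytes(): int(trials.labels[i])
                      for i in range(trials.n_trials)}

    def predict(self, data):
        return np.array([self.table[data[i].tobytes()]
                         for i in range(data.shape[0])])


class _ConstantPredictor:
    def predict(self, data):
        return np.zeros(data.shape[0], dtype=int)


@pytest.fixture(scope="module")
def balanced60():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(60, 4, 50))
    labels = np.array([0, 1] * 30)
    return TrialTensor(data, labels, 100.0, ["left", "right"])


class TestEvaluateSubject:
    def test_perfect_oracle_scores_one(self, balanced60, fast_model_cfg):
        oracle = _LookupOracle(balanced60)
        res = evaluate_subject(
            balanced60, _PLAN, fast_model_cfg, TrainConfig(seed=0),
            n_repeats=10, model_fn=lambda train, seed: oracle)
        assert res.accuracies.tolist() == [1.0] * 10
        assert res.mean == 1.0

    def test_constant_predictor_scores_base_rate(self, balanced60,
                                                 fast_model_cfg):
        res = evaluate_subject(
            balanced60, _PLAN, fast_model_cfg, TrainConfig(seed=0),
            n_repeats=10, model_fn=lambda train, seed: _ConstantPredictor())
        assert res.accuracies.tolist() == [0.5] * 10  # stratified 10/10 tests

    def test_repeat_count_respected(self, balanced60, fast_model_cfg):
        res = evaluate_subject(
            balanced60, _PLAN, fast_model_cfg, TrainConfig(seed=3),
            n_repeats=10, model_fn=lambda train, seed: _ConstantPredictor())
        assert len(res.accuracies) == 10
        assert len(res.seeds) == 10

    def test_too_few_trials_rejected(self, fast_model_cfg):
        small = TrialTensor(np.zeros((30, 4, 50)), [0, 1] * 15, 100.0,
                            ["l", "r"])
        with pytest.raises(ValueError, match="40"):
            evaluate_subject(small, _PLAN, fast_model_cfg, TrainConfig(),
                             n_train=40)


class TestBaselines:
    def test_pairing_contract(self, fast_trials):
        splits = make_split_sequence(fast_trials, 4, 12, base_seed=5)
        svm = baseline_classify(fast_trials, "svm", splits)
        lda = baseline_classify(fast_trials, "lda", splits)
        assert svm.seeds == lda.seeds == [5, 6, 7, 8]

    def test_separable_features_classified_perfectly(self):
        """LDA on linearly separable log-variance features is exact."""
        rng = np.random.default_rng(1)
        scale = np.where(np.arange(40) % 2 == 0, 0.1, 3.0)
        data = rng.normal(size=(40, 2, 100)) * scale[:, None, None]
        trials = TrialTensor(data, np.arange(40) % 2, 100.0, ["l", "r"])
        splits = make_split_sequence(trials, 5, 28, base_seed=0)
        res = baseline_classify(trials, "lda", splits, feature="bandpower")
        assert res.mean == 1.0

    def test_label_permutation_null(self, fast_trials, rng):
        """With permuted labels mean CSP+LDA accuracy sits at chance."""
        permuted = TrialTensor(fast_trials.data,
                               rng.permutation(fast_trials.labels),
                               fast_trials.fs, fast_trials.class_names)
        splits = make_split_sequence(permuted, 20, 12, base_seed=0)
        res = baseline_classify(permuted, "lda", splits)
        n_pred = 20 * (permuted.n_trials - 12)
        half_width = 1.96 * np.sqrt(0.25 / n_pred)
        assert abs(res.mean - 0.5) <= half_width + 0.05

    def test_unknown_method_rejected(self, fast_trials):
        splits = make_split_sequence(fast_trials, 2, 12, base_seed=0)
        with pytest.raises(ValueError, match="svm or lda"):
            baseline_classify(fast_trials, "forest", splits)


class TestCompareMethods:
    @staticmethod
    def _results(method, accs):
        return [EvalResult(f"S{i:02d}", method, [a]) for i, a in enumerate(accs)]

    def test_identical_vectors_give_p_one(self):
        accs = np.linspace(0.5, 0.9, 11)
        res = self._results("A", accs) + self._results("B", accs)
        cmp = compare_methods(res)
        assert cmp.p_values[[m for m in cmp.p_values][0]] == 1.0
        diff = cmp.table["A"] - cmp.table["B"]
        assert np.allclose(diff, 0)

    def test_uniform_offset_significant_at_n11(self):
        base = np.linspace(0.5, 0.8, 11)
        res = self._results("A", base + 0.10) + self._results("B", base)
        cmp = compare_methods(res)
        assert cmp.best_method == "A"
        assert cmp.p_values["B"] < 0.05

    def test_three_method_table_layout(self):
        base = np.linspace(0.5, 0.8, 11)
        res = (self._results("proposed", base + 0.1)
               + self._results("svm", base)
               + self._results("lda", base - 0.05))
        cmp = compare_methods(res)
        assert list(cmp.table.columns) == ["lda", "proposed", "svm"]
        assert "Mean" in cmp.table.index
        subject_rows = cmp.table.drop(index="Mean")
        np.testing.assert_allclose(cmp.table.loc["Mean"],
                                   subject_rows.mean(axis=0))

    def test_mismatched_subjects_rejected(self):
        res = self._results("A", [0.6, 0.7]) + [EvalResult("S09", "B", [0.5])]
        with pytest.raises(ValueError):
            compare_methods(res)

    def test_ttest_option_recorded(self):
        base = np.linspace(0.5, 0.8, 8)
        res = self._results("A", base + 0.1) + self._results("B", base)
        cmp = compare_methods(res, test="ttest")
        assert cmp.test == "ttest"
        assert cmp.p_values["B"] < 0.05
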