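"""Per-subject repeated-split evaluation, baselines, and method comparison.

Each subject is evaluated by repeated random stratified 40/20 splits
("10 cross-validation" read as 10 repeated splits): the network is trained
per split and scored on the held-out trials.  Classical baselines (linear
SVM and LDA on common-spatial-pattern log-variance features) consume the
*same* split sequence, giving a paired comparison, and a paired
significance test aggregates accuracies across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import SplitSpec, TrialTensor, make_split
from .model import EEGNetConfig
from .transfer import TrainConfig, TransferPlan, apply_plan, finetune


@dataclass
class EvalResult:
    """Accuracies (fractions in [0, 1]) over repeated splits of one subject."""

    subject_id: str
    method: str
    accuracies: np.ndarray
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=np.float64)
        if self.accuracies.size and not (
                (self.accuracies >= 0).all() and (self.accuracies <= 1).all()):
            raise ValueError("accuracies must be fractions in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())


def make_split_sequence(trials: TrialTensor, n_repeats: int, n_train: int,
                        base_seed: int, stratified: bool = True) -> list[SplitSpec]:
    """The canonical split sequence shared by network and baseline runs."""
    return [make_split(trials, n_train, seed=base_seed + i, stratified=stratified)
            for i in range(n_repeats)]


def evaluate_subject(
    trials: TrialTensor,
    plan: TransferPlan,
    cfg: EEGNetConfig,
    tc: TrainConfig,
    n_repeats: int = 10,
    n_train: int = 40,
    source_weights: dict | None = None,
    subject_id: str = "S01",
    splits: list[SplitSpec] | None = None,
    model_fn=None,
) -> EvalResult:
    """Train and score one model per repeated split.

    ``model_fn`` may inject an alternative classifier factory
    ``model_fn(train_trials, seed) -> object with .predict(data)`` (used by
    oracle/permutation checks); by default the transfer plan is applied and
    fine-tuned with ``tc``.
    """
    if trials.n_trials <= n_train:
        raise ValueError(
            f"need more than {n_train} trials for a {n_train}-train split, "
            f"got {trials.n_trials}"
        )
    if splits is None:
        splits = make_split_sequence(trials, n_repeats, n_train, tc.seed)
    accs, seeds = [], []
    for split in splits:
        train_set = trials.subset(split.train_indices)
        test_set = trials.subset(split.test_indices)
        if model_fn is not None:
            clf = model_fn(train_set, split.seed)
        else:
            clf = apply_plan(source_weights, plan, cfg, seed=split.seed)
            finetune(clf, train_set, dc_replace(tc, seed=split.seed))
        preds = np.asarray(clf.predict(test_set.data))
        accs.append(float((preds == test_set.labels).mean()))
        seeds.append(split.seed)
    return EvalResult(subject_id=subject_id, method=plan.name,
                      accuracies=np.asarray(accs), seeds=seeds)


# ---------------------------------------------------------------------------
# Classical baselines: CSP features + SVM / LDA
# ---------------------------------------------------------------------------

def _csp_features(train: TrialTensor, test: TrialTensor, n_components: int):
    from mne.decoding import CSP
    from mne.utils import use_log_level

    csp = CSP(n_components=n_components, log=True, reg="ledoit_wolf")
    with use_log_level("error"):
        f_train = csp.fit_transform(train.data, train.labels)
        return f_train, csp.transform(test.data)


def _logvar_features(train: TrialTensor, test: TrialTensor, _n):
    def feat(t):
        return np.log(t.data.var(axis=-1) + 1e-12)
    return feat(train), feat(test)


def baseline_classify(
    trials: TrialTensor,
    method: str,
    splits: list[SplitSpec],
    feature: str = "csp",
    n_csp_components: int = 6,
    subject_id: str = "S01",
) -> EvalResult:
    """Fit a classical pipeline per split on the given (paired) split list.

    ``feature="csp"`` uses common spatial patterns (3 filter pairs,
    log-variance); ``feature="bandpower"`` falls back to per-channel
    log-variance of the band-passed signal.  ``method`` is ``"svm"``
    (linear kernel, C=1) or ``"lda"``.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.svm import SVC

    if method == "svm":
        make_clf = lambda: SVC(kernel="linear", C=1.0)
    elif method == "lda":
        make_clf = lambda: LinearDiscriminantAnalysis()
    else:
        raise ValueError(f"unknown baseline method {method!r}; expected svm or lda")
    if feature == "csp":
        featurize = _csp_features
    elif feature == "bandpower":
        featurize = _logvar_features
    else:
        raise ValueError(f"unknown feature {feature!r}; expected csp or bandpower")

    accs, seeds = [], []
    for split in splits:
        train_set = trials.subset(split.train_indices)
        test_set = trials.subset(split.test_indices)
        f_train, f_test = featurize(train_set, test_set, n_csp_components)
        clf = make_clf()
        clf.fit(f_train, train_set.labels)
        accs.append(float((clf.predict(f_test) == test_set.labels).mean()))
        seeds.append(split.seed)
    return EvalResult(subject_id=subject_id, method=method,
                      accuracies=np.asarray(accs), seeds=seeds)


# ---------------------------------------------------------------------------
# Cross-subject aggregation and significance
# ---------------------------------------------------------------------------

@dataclass
class MethodComparison:
    """Subjects x methods accuracy table (percent) with paired p-values.

    ``p_values`` maps each non-leading method to the p-value of the paired
    test against the best-mean method; ``test`` records which test was used.
    """

    table: pd.DataFrame
    p_values: dict[str, float]
    test: str
    best_method: str

    def render(self) -> str:
        lines = [self.table.to_string(float_format=lambda v: f"{v:.2f}")]
        lines.append(f"paired test: {self.test}; reference: {self.best_method}")
        for method, p in self.p_values.items():
            lines.append(f"  {self.best_method} vs {method}: p = {p:.3g}")
        return "\n".join(lines)


def _paired_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    diff = a - b
    if np.allclose(diff, 0):
        return 1.0
    if test == "wilcoxon":
        return float(stats.wilcoxon(a, b, zero_method="zsplit").pvalue)
    if test == "ttest":
        return float(stats.ttest_rel(a, b).pvalue)
    raise ValueError(f"unknown test {test!r}; expected wilcoxon or ttest")


def compare_methods(results: list[EvalResult], test: str = "wilcoxon",
                    ) -> MethodComparison:
    """Build the subjects-x-methods table and paired cross-subject p-values.

    Every method must supply one result per subject.  The grand "Mean" row
    weights subjects equally.  Accuracies are reported in percent.
    """
    frame = pd.DataFrame(
        [{"subject": r.subject_id, "method": r.method, "acc": 100 * r.mean}
         for r in results]
    )
    if frame.duplicated(["subject", "method"]).any():
        raise ValueError("duplicate (subject, method) results")
    table = frame.pivot(index="subject", columns="method", values="acc")
    if table.isna().any().any():
        missing = table.columns[table.isna().any()].tolist()
        raise ValueError(f"methods {missing} are missing some subjects")
    table = table.sort_index()
    means = table.mean(axis=0)
    best = str(means.idxmax())
    p_values = {
        str(m): _paired_p(table[best].to_numpy(), table[m].to_numpy(), test)
        for m in table.columns if m != best
    }
    table.loc["Mean"] = means
    return MethodComparison(table=table, p_values=p_values, test=test,
                            best_method=best)


__all__ = [
    "EvalResult", "MethodComparison",
    "make_split_sequence", "evaluate_subject", "baseline_classify",
    "compare_methods",
]
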