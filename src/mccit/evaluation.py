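"""Nested cross-validation benchmarking of selection + classification.

The protocol estimates, for each feature-selection method, the accuracy a
signature-based classifier achieves on unseen samples:

* an **outer** stratified CV loop holds out each fold for testing;
* an **inner** stratified CV loop on each outer-training set picks, per
  selection method, the (selection parameters x classifier x classifier
  parameters) combination with the best inner accuracy;
* the winning combination is refit on the full outer-training set and scored
  on the held-out fold.

Accuracies of two methods are compared with an exact two-sided binomial test
on the *pooled* outer-loop predictions (the discordant pairs drive the
test — the McNemar-style design), and signature sizes with a two-sample
two-tailed t-test on the per-fold selected-feature counts.  The baseline is
the trivial classifier that always predicts the most frequent training
class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import LabeledDataset
from .glm import MultinomialLogit, OrderedLogit
from .mmpc import MMPCConfig, mmpc

__all__ = [
    "FoldPlan",
    "MethodGrid",
    "EvaluationReport",
    "make_fold_plan",
    "nested_cv",
    "accuracy",
    "trivial_classifier",
    "exact_binomial_compare",
    "compare_feature_counts",
    "default_classifier_registry",
    "mmpc_selector",
    "lasso_selector",
]


# ---------------------------------------------------------------------------
# elementary metrics and comparisons
# ---------------------------------------------------------------------------


def accuracy(predictions, truth) -> float:
    """Fraction of exact matches."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) != len(truth):
        raise ValueError("length mismatch")
    if len(truth) == 0:
        raise ValueError("empty input")
    return float(np.mean(predictions == truth))


def trivial_classifier(train_labels) -> Callable[[int], np.ndarray]:
    """Constant predictor of the modal training class (ties -> lowest code)."""
    train_labels = np.asarray(train_labels)
    if len(train_labels) == 0:
        raise ValueError("empty training labels")
    counts = np.bincount(train_labels)
    modal = int(np.argmax(counts))  # argmax takes the lowest index on ties

    def predict(n_or_features) -> np.ndarray:
        n = n_or_features if np.isscalar(n_or_features) else len(n_or_features)
        return np.full(int(n), modal, dtype=int)

    return predict


def exact_binomial_compare(
    preds_a, preds_b, truth, method: str = "min_likelihood"
) -> float:
    """Exact two-sided binomial comparison of two prediction vectors.

    Only discordant samples matter: b = (a right, b wrong), c = (a wrong,
    b right); under equal accuracy each discordance is a fair coin.  The
    default two-sided convention sums all outcomes whose probability does
    not exceed that of the observed count (minimum-likelihood); the
    ``"doubling"`` convention doubles the one-sided tail.
    """
    preds_a = np.asarray(preds_a)
    preds_b = np.asarray(preds_b)
    truth = np.asarray(truth)
    if not (len(preds_a) == len(preds_b) == len(truth)):
        raise ValueError("length mismatch")
    ok_a = preds_a == truth
    ok_b = preds_b == truth
    b = int(np.sum(ok_a & ~ok_b))
    c = int(np.sum(~ok_a & ok_b))
    n = b + c
    if n == 0:
        return 1.0
    if method == "min_likelihood":
        pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
        p = float(pmf[pmf <= pmf[b] * (1 + 1e-12)].sum())
    elif method == "doubling":
        tail = float(stats.binom.sf(max(b, c) - 1, n, 0.5))
        p = min(1.0, 2.0 * tail)
    else:
        raise ValueError("method must be 'min_likelihood' or 'doubling'")
    return min(1.0, p)


def compare_feature_counts(counts_a, counts_b) -> float:
    """Two-sample two-tailed t-test p-value on per-fold signature sizes."""
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if len(counts_a) < 2 or len(counts_b) < 2:
        raise ValueError("need at least 2 folds per method")
    if np.allclose(counts_a, counts_a[0]) and np.allclose(counts_b, counts_b[0]) and np.isclose(
        counts_a[0], counts_b[0]
    ):
        return 1.0
    res = stats.ttest_ind(counts_a, counts_b)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """Outer folds (disjoint, exhaustive test sets) plus the inner fold count
    reused inside every outer-training set."""

    outer: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    n_inner: int
    stratified: bool
    seed: int

    def inner_folds(self, train_idx: np.ndarray, y: np.ndarray):
        splitter = StratifiedKFold(
            n_splits=self.n_inner, shuffle=True, random_state=self.seed + 1
        )
        for tr, te in splitter.split(np.zeros(len(train_idx)), y[train_idx]):
            yield train_idx[tr], train_idx[te]


def make_fold_plan(
    data: LabeledDataset, n_outer: int = 10, n_inner: int = 5, seed: int = 0
) -> FoldPlan:
    """Stratified outer/inner fold plan; stratification keeps every class
    present in every training fold (an invariant of the data container)."""
    splitter = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
    outer = [
        (tr, te)
        for tr, te in splitter.split(np.zeros(data.n_samples), data.outcome)
    ]
    return FoldPlan(outer=outer, n_inner=n_inner, stratified=True, seed=seed)


# ---------------------------------------------------------------------------
# feature-selection methods and classifiers (plug-in contracts)
# ---------------------------------------------------------------------------


def mmpc_selector(test: str = "mc_cit"):
    """Selection plug-in: MMPC with the given CIT; params = {alpha, k_max}."""

    def select(data: LabeledDataset, params: dict) -> list[int]:
        cfg = MMPCConfig(alpha=params["alpha"], k_max=params["k_max"], test=test)
        return mmpc(data, cfg).selected

    return select


def lasso_selector():
    """Selection plug-in: features with nonzero Lasso coefficients when the
    class code is regressed on all features with an L1 penalty."""

    def select(data: LabeledDataset, params: dict) -> list[int]:
        model = Lasso(alpha=params["lam"], max_iter=5000)
        model.fit(data.features, data.outcome.astype(float))
        return [int(j) for j in np.flatnonzero(np.abs(model.coef_) > 1e-10)]

    return select


class _SvmOneVsAll:
    """One-vs-all SVM: one binary SVC per class, predicted class = argmax of
    the per-class decision values."""

    def __init__(self, kernel: str, C: float):
        degree = {"poly2": 2, "poly3": 3}.get(kernel, 3)
        self._kernel = {"poly2": "poly", "poly3": "poly", "gaussian": "rbf"}.get(
            kernel, kernel
        )
        self._degree = degree
        self._C = C
        self._models: list[SVC] = []
        self._classes: np.ndarray | None = None

    def fit(self, X, y):
        self._classes = np.unique(y)
        self._models = []
        for cls in self._classes:
            m = SVC(kernel=self._kernel, degree=self._degree, C=self._C, gamma="scale")
            m.fit(X, (y == cls).astype(int))
            self._models.append(m)
        return self

    def predict(self, X):
        scores = np.column_stack([m.decision_function(X) for m in self._models])
        return self._classes[np.argmax(scores, axis=1)]


class _LassoClassifier:
    """Lasso regression on the integer class code; predictions snap to the
    nearest class code."""

    def __init__(self, lam: float, n_classes: int):
        self._model = Lasso(alpha=lam, max_iter=5000)
        self._k = n_classes

    def fit(self, X, y):
        self._model.fit(X, np.asarray(y, dtype=float))
        return self

    def predict(self, X):
        raw = self._model.predict(X)
        return np.clip(np.rint(raw), 0, self._k - 1).astype(int)


class _GlmClassifier:
    """Multinomial-logit (nominal) or ordered-logit (ordinal) classifier."""

    def __init__(self, outcome_kind: str, n_classes: int):
        self._kind = outcome_kind
        self._k = n_classes
        self._res = None

    def fit(self, X, y):
        model_cls = OrderedLogit if self._kind == "ordinal" else MultinomialLogit
        self._res = model_cls(y, X, n_classes=self._k).fit()
        return self

    def predict(self, X):
        return self._res.predict(X)


def default_classifier_registry() -> dict:
    """Name -> factory(params, data) for the study's three classifier
    families; complexity ranks break inner-CV ties toward simpler models."""

    def svm_factory(params, data):
        return _SvmOneVsAll(params["kernel"], params["C"])

    def lasso_factory(params, data):
        return _LassoClassifier(params["lam"], data.n_classes)

    def glm_factory(params, data):
        return _GlmClassifier(data.outcome_kind, data.n_classes)

    return {
        "glm": {"factory": glm_factory, "params": [{}], "complexity": 0},
        "lasso_reg": {
            "factory": lasso_factory,
            "params": [{"lam": l} for l in (0.05, 0.1, 0.15, 0.20)],
            "complexity": 1,
        },
        "svm": {
            "factory": svm_factory,
            "params": [
                {"kernel": k, "C": c}
                for k in ("linear", "poly2", "poly3", "gaussian")
                for c in (1.0, 10.0)
            ],
            "complexity": 2,
        },
    }


@dataclass
class MethodGrid:
    """Feature-selection methods with their parameter grids.

    ``methods`` maps a method name to ``{"select": callable(data, params) ->
    feature indices, "params": [param dicts]}``.  The study grid couples MMPC
    (alpha in {0.01, 0.05} x k_max in {3, 4}, per CIT) and Lasso selection
    (lambda in {0.05, 0.1, 0.15, 0.20}).
    """

    methods: dict

    @classmethod
    def study_default(cls, tests=("mc_cit", "fisher_z", "g2")) -> "MethodGrid":
        mm_params = [
            {"alpha": a, "k_max": k} for a in (0.01, 0.05) for k in (3, 4)
        ]
        methods = {
            f"mmpc_{t}": {"select": mmpc_selector(t), "params": list(mm_params)}
            for t in tests
        }
        methods["lasso"] = {
            "select": lasso_selector(),
            "params": [{"lam": l} for l in (0.05, 0.1, 0.15, 0.20)],
        }
        return cls(methods)


# ---------------------------------------------------------------------------
# the nested-CV protocol
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Aggregated nested-CV results, mirroring an accuracy table and a
    signature-size table with pairwise comparison p-values."""

    method_names: list[str]
    outer_accuracies: dict  # method -> list of per-fold accuracies
    pooled_predictions: dict  # method -> ndarray of length n
    feature_counts: dict  # method -> list of per-fold signature sizes
    winners: dict  # method -> list of per-fold winning configurations
    truth: np.ndarray
    accuracy_pvalues: dict = field(default_factory=dict)  # (a, b) -> p
    count_pvalues: dict = field(default_factory=dict)

    def mean_accuracy(self, method: str) -> tuple[float, float]:
        a = np.asarray(self.outer_accuracies[method])
        return float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0

    def pooled_accuracy(self, method: str) -> float:
        return accuracy(self.pooled_predictions[method], self.truth)

    def mean_feature_count(self, method: str) -> tuple[float, float]:
        c = np.asarray(self.feature_counts[method], dtype=float)
        if len(c) == 0:
            return float("nan"), float("nan")
        return float(c.mean()), float(c.std(ddof=1)) if len(c) > 1 else 0.0

    def compare_accuracy(self, a: str, b: str, method="min_likelihood") -> float:
        return exact_binomial_compare(
            self.pooled_predictions[a], self.pooled_predictions[b], self.truth,
            method=method,
        )

    def to_tables(self) -> tuple[str, str]:
        """Two TSV tables: accuracies (mean +/- sd, pooled, p vs first
        method) and signature sizes (mean +/- sd, p vs first method)."""
        ref = self.method_names[0]
        acc_rows = ["method\tmean_acc\tsd\tpooled_acc\tp_vs_" + ref]
        cnt_rows = ["method\tmean_count\tsd\tp_vs_" + ref]
        for m in self.method_names:
            mu, sd = self.mean_accuracy(m)
            p = self.accuracy_pvalues.get((ref, m), float("nan"))
            acc_rows.append(
                f"{m}\t{mu:.3f}\t{sd:.3f}\t{self.pooled_accuracy(m):.3f}\t{p:.3g}"
            )
            if m in self.feature_counts and len(self.feature_counts[m]):
                cu, cs = self.mean_feature_count(m)
                pc = self.count_pvalues.get((ref, m), float("nan"))
                cnt_rows.append(f"{m}\t{cu:.2f}\t{cs:.2f}\t{pc:.3g}")
        return "\n".join(acc_rows), "\n".join(cnt_rows)

    def to_dict(self) -> dict:
        return {
            "methods": self.method_names,
            "mean_accuracy": {
                m: list(map(float, self.outer_accuracies[m]))
                for m in self.method_names
            },
            "pooled_accuracy": {
                m: self.pooled_accuracy(m) for m in self.method_names
            },
            "feature_counts": {
                m: list(map(int, self.feature_counts.get(m, [])))
                for m in self.method_names
            },
            "accuracy_pvalues": {
                f"{a}|{b}": float(p) for (a, b), p in self.accuracy_pvalues.items()
            },
            "count_pvalues": {
                f"{a}|{b}": float(p) for (a, b), p in self.count_pvalues.items()
            },
            "winners": self.winners,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        acc, cnt = self.to_tables()
        return "Accuracy (outer CV)\n" + acc + "\n\nSignature size\n" + cnt


def _fit_predict(clf_entry, clf_params, sel_features, train: LabeledDataset,
                 test_X: np.ndarray, data: LabeledDataset):
    if not sel_features:
        pred = trivial_classifier(train.outcome)(test_X.shape[0])
        return pred
    clf = clf_entry["factory"](clf_params, data)
    clf.fit(train.features[:, sel_features], train.outcome)
    return np.asarray(clf.predict(test_X[:, sel_features]))


def nested_cv(
    data: LabeledDataset,
    grid: MethodGrid,
    plan: FoldPlan,
    classifier_registry: Optional[dict] = None,
    log: Optional[list] = None,
) -> EvaluationReport:
    """Run the full nested-CV protocol.

    For every outer fold and selection method, the inner CV averages fold
    accuracies over every (selection params x classifier x classifier
    params) combination; ties break toward fewer selected features, then the
    simpler classifier family.  A configuration selecting zero features falls
    back to the trivial classifier for that fold (logged).  The trivial
    classifier itself is always reported as the baseline method "trivial".
    """
    registry = classifier_registry or default_classifier_registry()
    n = data.n_samples
    method_names = list(grid.methods) + ["trivial"]
    outer_acc = {m: [] for m in method_names}
    pooled = {m: np.full(n, -1, dtype=int) for m in method_names}
    counts = {m: [] for m in method_names if m != "trivial"}
    winners = {m: [] for m in method_names if m != "trivial"}

    for train_idx, test_idx in plan.outer:
        inner = list(plan.inner_folds(train_idx, data.outcome))
        # precompute selections per (method, fs params, inner fold / outer train)
        for mname, spec in grid.methods.items():
            best = None  # (-acc, n_feat, complexity, ...) minimized
            for fs_params in spec["params"]:
                sel_by_fold = []
                for itr, ite in inner:
                    sel = spec["select"](data.subset(itr), fs_params)
                    sel_by_fold.append(sel)
                for cname, centry in registry.items():
                    for cparams in centry["params"]:
                        accs = []
                        for (itr, ite), sel in zip(inner, sel_by_fold):
                            tr_data = data.subset(itr)
                            pred = _fit_predict(
                                centry, cparams, sel, tr_data,
                                data.features[ite], data,
                            )
                            accs.append(accuracy(pred, data.outcome[ite]))
                        mean_inner = float(np.mean(accs))
                        mean_nfeat = float(np.mean([len(s) for s in sel_by_fold]))
                        key = (
                            -mean_inner,
                            mean_nfeat,
                            centry.get("complexity", 0),
                            cname,
                            tuple(sorted(map(str, cparams.items()))),
                        )
                        if best is None or key < best[0]:
                            best = (key, fs_params, cname, cparams)
            _, fs_params, cname, cparams = best
            tr_data = data.subset(train_idx)
            sel = grid.methods[mname]["select"](tr_data, fs_params)
            if not sel and log is not None:
                log.append(
                    f"{mname}: zero features selected on an outer fold; "
                    "trivial-classifier fallback"
                )
            pred = _fit_predict(
                registry[cname], cparams, sel, tr_data, data.features[test_idx], data
            )
            pooled[mname][test_idx] = pred
            outer_acc[mname].append(accuracy(pred, data.outcome[test_idx]))
            counts[mname].append(len(sel))
            winners[mname].append(
                {"fs_params": fs_params, "classifier": cname, "clf_params": cparams}
            )
        tpred = trivial_classifier(data.outcome[train_idx])(len(test_idx))
        pooled["trivial"][test_idx] = tpred
        outer_acc["trivial"].append(accuracy(tpred, data.outcome[test_idx]))

    assert all((p >= 0).all() for p in pooled.values()), "pooled predictions must cover every sample"
    report = EvaluationReport(
        method_names=method_names,
        outer_accuracies=outer_acc,
        pooled_predictions=pooled,
        feature_counts=counts,
        winners=winners,
        truth=data.outcome.copy(),
    )
    ref = method_names[0]
    for m in method_names:
        if m == ref:
            report.accuracy_pvalues[(ref, m)] = 1.0
            continue
        report.accuracy_pvalues[(ref, m)] = report.compare_accuracy(ref, m)
        if m in counts and ref in counts:
            report.count_pvalues[(ref, m)] = compare_feature_counts(
                counts[ref], counts[m]
            )
    return report
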