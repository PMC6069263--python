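"""Feature-subset evaluation: six classifiers under repeated stratified 5-fold CV.

Given an SVM-RFE ranking, nested subsets are formed by taking the top-s
ranked features for s = 1..D.  Each subset is scored for each classifier by
repeated stratified k-fold cross-validated accuracy (fraction of correctly
labelled samples, i.e. the micro average of the per-class one-vs-rest
(TP+TN)/(TP+TN+FP+FN) tallies).  The optimal subset per classifier is the
prefix with maximal mean accuracy, ties resolved toward fewer features.

Classifier families: SVM with linear, polynomial (degree 3) and RBF kernels
(C = 1; RBF bandwidth 1/(D·Var(X)) — the usual "scale" heuristic), k-nearest
neighbours (k = 5), LDA, and QDA with a small covariance regulariser so
near-singular small-sample folds do not abort the sweep.  A classifier that
still fails on a fold is recorded as a fold failure, warned about, and
excluded from that repeat's tally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .ranking import MinMaxRecord, SVMRFERanking

CLASSIFIER_FAMILIES: tuple[str, ...] = (
    "svm_linear", "svm_poly", "svm_rbf", "knn", "lda", "qda",
)


class RidgeQDA:
    """Quadratic discriminant analysis with a scaled-ridge covariance floor.

    Per-class Gaussian discriminant with covariance Σ_c + λ·(tr Σ_c / D)·I,
    λ = ``ridge`` (default 1e-6).  The additive ridge keeps the discriminant
    defined when features are exactly collinear — which the HRV vector is by
    construction (nHF = 100 − nLF, lnLFHF = lnLF − lnHF) — while perturbing a
    well-conditioned covariance negligibly.
    """

    def __init__(self, ridge: float = 1e-6) -> None:
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeQDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        D = X.shape[1]
        self._means, self._inv_cov, self._logdet, self._logprior = [], [], [], []
        for cls in self.classes_:
            Xc = X[y == cls]
            if Xc.shape[0] < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 samples")
            mu = Xc.mean(axis=0)
            cov = np.cov(Xc, rowvar=False, ddof=1).reshape(D, D)
            scale = np.trace(cov) / D
            if scale <= 0:
                raise np.linalg.LinAlgError(
                    f"class {cls!r} has a zero covariance matrix"
                )
            cov = cov + self.ridge * scale * np.eye(D)
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    f"class {cls!r} covariance not positive definite"
                )
            self._means.append(mu)
            self._inv_cov.append(np.linalg.inv(cov))
            self._logdet.append(logdet)
            self._logprior.append(np.log(Xc.shape[0] / X.shape[0]))
        return self

    def _discriminants(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        scores = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            d = X - self._means[k]
            maha = np.einsum("ij,jk,ik->i", d, self._inv_cov[k], d)
            scores[:, k] = self._logprior[k] - 0.5 * (self._logdet[k] + maha)
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._discriminants(X), axis=1)]


@dataclass(frozen=True)
class ClassifierSpec:
    """One evaluation classifier: family name plus hyperparameter overrides."""

    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; "
                f"expected one of {CLASSIFIER_FAMILIES}"
            )

    def build(self):
        hp = dict(self.hyperparameters)
        if self.family == "svm_linear":
            return SVC(kernel="linear", C=hp.pop("C", 1.0), **hp)
        if self.family == "svm_poly":
            return SVC(kernel="poly", degree=hp.pop("degree", 3),
                       C=hp.pop("C", 1.0), **hp)
        if self.family == "svm_rbf":
            return SVC(kernel="rbf", C=hp.pop("C", 1.0),
                       gamma=hp.pop("gamma", "scale"), **hp)
        if self.family == "knn":
            return KNeighborsClassifier(n_neighbors=hp.pop("k", 5), **hp)
        if self.family == "lda":
            return LinearDiscriminantAnalysis(**hp)
        return RidgeQDA(ridge=hp.pop("ridge", 1e-6))


def default_classifiers() -> list[ClassifierSpec]:
    return [ClassifierSpec(f) for f in CLASSIFIER_FAMILIES]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary (one-vs-rest) confusion tally."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP + self.FP + self.TN + self.FN == 0:
            raise ValueError("total count must be positive")


def accuracy(conf: ConfusionCounts) -> float:
    """ACC = (TN + TP) / (TP + TN + FN + FP)."""
    return (conf.TN + conf.TP) / (conf.TP + conf.TN + conf.FN + conf.FP)


def multiclass_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Overall fraction correct; equals the micro-averaged OVA accuracy."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty prediction set")
    return float(np.mean(y_true == y_pred))


def _repeat_seeds(seed: int, repeats: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(repeats)]


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
    folds: int, repeat_seeds: list[int],
) -> tuple[float, float, int]:
    """Mean ± SD accuracy over repeats; also the number of failed folds."""
    accs = []
    n_failed = 0
    for rs in repeat_seeds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        correct = 0
        counted = 0
        for train, test in skf.split(X, y):
            clf = spec.build()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(X[train], y[train])
                pred = clf.predict(X[test])
            except Exception as exc:  # singular covariance etc.
                n_failed += 1
                warnings.warn(
                    f"{spec.family} failed on a fold ({exc}); fold excluded",
                    stacklevel=2,
                )
                continue
            correct += int((pred == y[test]).sum())
            counted += test.size
        if counted:
            accs.append(correct / counted)
    if not accs:
        return float("nan"), float("nan"), n_failed
    return float(np.mean(accs)), float(np.std(accs, ddof=0)), n_failed


def evaluate_subsets(
    X: np.ndarray,
    y: np.ndarray,
    ranking: SVMRFERanking,
    classifiers: list[ClassifierSpec] | None = None,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Accuracy curve over nested top-s feature subsets for each classifier.

    Returns the subset curve as a tidy frame with columns ``classifier,
    subset_size, features, acc_mean, acc_sd, n_failed_folds``; ``features``
    joins the top-s prefix with ``|``.  Deterministic for fixed ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if classifiers is None:
        classifiers = default_classifiers()
    if folds < 2:
        raise ValueError("folds must be at least 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` samples")
    if feature_names is None:
        feature_names = list(ranking.rank_order)
        if X.shape[1] != len(feature_names):
            raise ValueError("pass feature_names matching X's columns")
    col = {name: j for j, name in enumerate(feature_names)}
    repeat_seeds = _repeat_seeds(seed, repeats)
    rows = []
    for s in range(1, ranking.n_features + 1):
        top = ranking.top(s)
        Xs = X[:, [col[f] for f in top]]
        for spec in classifiers:
            mean, sd, n_failed = _cv_accuracy(Xs, y, spec, folds, repeat_seeds)
            rows.append({
                "classifier": spec.family,
                "subset_size": s,
                "features": "|".join(top),
                "acc_mean": mean,
                "acc_sd": sd,
                "n_failed_folds": n_failed,
            })
    return pd.DataFrame(rows)


def select_optimal_subset(curve: pd.DataFrame, classifier: ClassifierSpec | str) -> list[str]:
    """The top-s prefix with maximal mean accuracy; ties toward smaller s."""
    family = classifier.family if isinstance(classifier, ClassifierSpec) else classifier
    sub = curve[curve["classifier"] == family].sort_values("subset_size")
    if sub.empty:
        raise ValueError(f"classifier {family!r} absent from the curve")
    best = sub.loc[sub["acc_mean"].idxmax()]  # first occurrence = smallest s
    return best["features"].split("|")


def compare_all_vs_optimal(
    X: np.ndarray,
    y: np.ndarray,
    ranking: SVMRFERanking,
    classifiers: list[ClassifierSpec] | None = None,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    feature_names: list[str] | None = None,
    curve: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per classifier: accuracy on all D features vs its optimal subset.

    Returns one row per classifier with columns ``classifier, n_optimal,
    optimal_features, acc_all, sd_all, acc_optimal, sd_optimal, gain`` where
    gain = acc_optimal − acc_all (accuracies as fractions).
    """
    if classifiers is None:
        classifiers = default_classifiers()
    if curve is None:
        curve = evaluate_subsets(
            X, y, ranking, classifiers, folds=folds, repeats=repeats,
            seed=seed, feature_names=feature_names,
        )
    D = ranking.n_features
    rows = []
    for spec in classifiers:
        sub = curve[curve["classifier"] == spec.family].sort_values("subset_size")
        all_row = sub[sub["subset_size"] == D].iloc[0]
        best_row = sub.loc[sub["acc_mean"].idxmax()]
        rows.append({
            "classifier": spec.family,
            "n_optimal": int(best_row["subset_size"]),
            "optimal_features": best_row["features"],
            "acc_all": float(all_row["acc_mean"]),
            "sd_all": float(all_row["acc_sd"]),
            "acc_optimal": float(best_row["acc_mean"]),
            "sd_optimal": float(best_row["acc_sd"]),
            "gain": float(best_row["acc_mean"] - all_row["acc_mean"]),
        })
    return pd.DataFrame(rows)


@dataclass
class SubsetEvaluationResults:
    """Fitted subset-evaluation results: the accuracy curve plus selections."""

    curve: pd.DataFrame
    ranking: SVMRFERanking
    classifiers: list[ClassifierSpec]
    folds: int
    repeats: int
    seed: int

    def optimal_subset(self, classifier: ClassifierSpec | str) -> list[str]:
        return select_optimal_subset(self.curve, classifier)

    def comparison(self) -> pd.DataFrame:
        """All-features vs optimal-subset accuracies, one row per classifier."""
        D = self.ranking.n_features
        rows = []
        for spec in self.classifiers:
            sub = self.curve[self.curve["classifier"] == spec.family]
            sub = sub.sort_values("subset_size")
            all_row = sub[sub["subset_size"] == D].iloc[0]
            best_row = sub.loc[sub["acc_mean"].idxmax()]
            rows.append({
                "classifier": spec.family,
                "n_optimal": int(best_row["subset_size"]),
                "optimal_features": best_row["features"],
                "acc_all": float(all_row["acc_mean"]),
                "sd_all": float(all_row["acc_sd"]),
                "acc_optimal": float(best_row["acc_mean"]),
                "sd_optimal": float(best_row["acc_sd"]),
                "gain": float(best_row["acc_mean"] - all_row["acc_mean"]),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        comp = self.comparison()
        lines = [
            "Feature-subset evaluation "
            f"({self.folds}-fold CV × {self.repeats} repeats, seed {self.seed})",
            "=" * 72,
            f"{'classifier':<11} {'s*':>3} {'acc(all)':>10} {'acc(opt)':>10} "
            f"{'gain':>7}  optimal features",
        ]
        for _, r in comp.iterrows():
            lines.append(
                f"{r['classifier']:<11} {r['n_optimal']:>3} "
                f"{100 * r['acc_all']:>9.2f}% {100 * r['acc_optimal']:>9.2f}% "
                f"{100 * r['gain']:>6.2f}%  {r['optimal_features']}"
            )
        return "\n".join(lines)

    def plot_curves(self, ax=None):
        """Accuracy vs subset size, one line per classifier."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for spec in self.classifiers:
            sub = self.curve[self.curve["classifier"] == spec.family]
            sub = sub.sort_values("subset_size")
            ax.errorbar(sub["subset_size"], 100 * sub["acc_mean"],
                        yerr=100 * sub["acc_sd"], label=spec.family,
                        capsize=2)
        ax.set_xlabel("number of top-ranked features")
        ax.set_ylabel("CV accuracy (%)")
        ax.legend(fontsize=8)
        return ax


class SubsetEvaluation:
    """Model object for the nested-subset classifier sweep.

    ``fit()`` runs the repeated stratified k-fold sweep and returns a
    ``SubsetEvaluationResults``.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        ranking: SVMRFERanking,
        classifiers: list[ClassifierSpec] | None = None,
        feature_names: list[str] | None = None,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.ranking = ranking
        self.classifiers = classifiers or default_classifiers()
        self.feature_names = feature_names

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        ranking: SVMRFERanking,
        label_col: str = "group",
        **kwargs,
    ) -> "SubsetEvaluation":
        """Build from a labelled feature frame, on the ranking's scale.

        If the ranking was fitted with min-max normalization its stored
        (min, max) record is applied here too, so ranking and evaluation see
        the same 0–1 data, as the procedure prescribes.
        """
        cols = list(ranking.rank_order)
        X = df[cols].to_numpy(dtype=float)
        if ranking.minmax_record is not None:
            rec = ranking.minmax_record
            order = [rec.feature_names.index(c) for c in cols]
            X = MinMaxRecord(
                feature_names=tuple(cols),
                mins=rec.mins[order],
                maxs=rec.maxs[order],
            ).transform(X)
        return cls(
            X,
            df[label_col].to_numpy(),
            ranking,
            feature_names=cols,
            **kwargs,
        )

    def fit(self, folds: int = 5, repeats: int = 10, seed: int = 0) -> SubsetEvaluationResults:
        curve = evaluate_subsets(
            self.X, self.y, self.ranking, self.classifiers,
            folds=folds, repeats=repeats, seed=seed,
            feature_names=self.feature_names,
        )
        return SubsetEvaluationResults(
            curve=curve, ranking=self.ranking, classifiers=self.classifiers,
            folds=folds, repeats=repeats, seed=seed,
        )
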