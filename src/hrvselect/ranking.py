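"""One-versus-all multiclass SVM-RFE feature ranking.

The ranking procedure extends binary SVM recursive feature elimination to a
three-class problem (control / SS / LS) by training one linear soft-margin SVM
per class against the rest, scoring each feature j by the *maximum* squared
weight it attains across the three one-versus-all (OVA) models,

    J_j = max_r (w_j^r)^2 ,   r in {C-SVM, SS-SVM, LS-SVM},

eliminating the feature with the smallest J, and retraining on the survivors
until a single feature remains.  Features eliminated later rank higher; the
last survivor is rank 1.  Per-iteration weight magnitudes (normalised to unit
Euclidean norm per model) are recorded for the weight-colormap diagnostic.

The linear-kernel requirement is structural: J is defined on primal weights,
which exist only for the linear kernel.  Nonlinear kernels enter only in the
downstream subset evaluation.

Model/Results interface
-----------------------
``SVMRFE`` is the model object (data + configuration); ``fit()`` returns an
``SVMRFERanking`` results object carrying ``rank_order``,
``elimination_order``, the tidy per-iteration weight table, and ``summary()``.
The module-level functions (``minmax_normalize``, ``train_ova_svms``,
``ova_predict``, ``ranking_scores``, ``rfe_rank``) are the procedural surface
the classes are built from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .simulate import CLASS_ORDER, FEATURE_NAMES


@dataclass(frozen=True)
class MinMaxRecord:
    """Per-feature (min, max) of the training data, for reuse on held-out rows."""

    feature_names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.maxs - self.mins
        out = np.zeros_like(X)
        ok = span > 0
        out[:, ok] = (X[:, ok] - self.mins[ok]) / span[ok]
        return out


def minmax_normalize(
    X: np.ndarray, feature_names: list[str] | tuple[str, ...] | None = None
) -> tuple[np.ndarray, MinMaxRecord]:
    """Map each column to [0, 1] by (x − min)/(max − min).

    Constant columns map to all-zeros with a warning (there is no information
    to rescale).  Returns the transformed matrix and the (min, max) record.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    if feature_names is None:
        feature_names = tuple(f"f{j}" for j in range(X.shape[1]))
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    const = maxs == mins
    if const.any():
        bad = [feature_names[j] for j in np.flatnonzero(const)]
        warnings.warn(f"constant column(s) {bad} mapped to all-zeros",
                      stacklevel=2)
    record = MinMaxRecord(feature_names=tuple(feature_names), mins=mins, maxs=maxs)
    return record.transform(X), record


@dataclass(frozen=True)
class BinarySVMModel:
    """A fitted linear one-versus-rest SVM: f(x) = w·x + b."""

    w: np.ndarray
    b: float
    C: float
    positive_class: str
    training_diagnostics: dict = field(default_factory=dict)

    def decision_value(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != self.w.shape:
            raise ValueError(
                f"dimension mismatch: model has D={self.w.size}, got {x.size}"
            )
        return float(self.w @ x + self.b)


def _ordered_classes(y: np.ndarray) -> list[str]:
    present = set(np.asarray(y).tolist())
    ordered = [c for c in CLASS_ORDER if c in present]
    ordered += sorted(c for c in present if c not in CLASS_ORDER)
    return ordered


def train_ova_svms(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> list[BinarySVMModel]:
    """Train one linear binary SVM per class (target class +1, rest −1).

    Models are returned in fixed class order control < SS < LS (other labels
    after, sorted), which also defines the prediction tie-break.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if C <= 0:
        raise ValueError("C must be positive")
    classes = _ordered_classes(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    models = []
    for cls in classes:
        target = np.where(y == cls, 1, -1)
        if (target == 1).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        svc = SVC(kernel="linear", C=C)
        svc.fit(X, target)
        w = svc.coef_.ravel().copy()
        b = float(svc.intercept_[0])
        # libsvm orients the decision function toward its internal first
        # label; flip so +1 (the target class) is always the positive side
        if svc.classes_[1] != 1:
            w, b = -w, -b
        margins = target * (X @ w + b)
        models.append(
            BinarySVMModel(
                w=w, b=b, C=C, positive_class=str(cls),
                training_diagnostics={
                    "objective": 0.5 * float(w @ w)
                    + C * float(np.clip(1.0 - margins, 0.0, None).sum()),
                    "n_margin_violations": int((margins < 1.0).sum()),
                    "n_support": int(svc.n_support_.sum()),
                },
            )
        )
    return models


def ova_predict(models: list[BinarySVMModel], x: np.ndarray) -> str:
    """Predict the class whose OVA model has the maximal decision value.

    Ties go to the earliest model in the fixed class order.
    """
    if not models:
        raise ValueError("models must be non-empty")
    values = [m.decision_value(x) for m in models]
    return models[int(np.argmax(values))].positive_class


def ranking_scores(models: list[BinarySVMModel]) -> np.ndarray:
    """Per-feature ranking score J_j = max over models of the squared weight."""
    if not models:
        raise ValueError("models must be non-empty")
    D = models[0].w.size
    if any(m.w.size != D for m in models):
        raise ValueError("all models must share the feature dimension")
    W = np.stack([m.w for m in models])
    return (W**2).max(axis=0)


@dataclass
class SVMRFERanking:
    """Results of a fitted multiclass SVM-RFE ranking.

    Attributes
    ----------
    rank_order
        Feature names, best (rank 1) first.
    elimination_order
        Features in the order they were removed (worst first).
    iteration_weights
        Tidy frame with columns ``iteration, model, feature, weight`` where
        weight is |w_j|/‖w‖ for each OVA model plus the row-wise ``max``
        criterion (the weight-colormap data).
    C, normalized, minmax_record
        Fit configuration echoes.
    """

    rank_order: list[str]
    elimination_order: list[str]
    iteration_weights: pd.DataFrame
    C: float
    normalized: bool
    minmax_record: MinMaxRecord | None = None

    @property
    def n_features(self) -> int:
        return len(self.rank_order)

    def top(self, s: int) -> list[str]:
        """The best-s feature prefix of the ranking."""
        if not 1 <= s <= self.n_features:
            raise ValueError(f"s must be in [1, {self.n_features}]")
        return self.rank_order[:s]

    def summary(self) -> str:
        lines = [
            "Multiclass SVM-RFE feature ranking",
            "=" * 42,
            f"features ranked : {self.n_features}",
            f"penalty C       : {self.C}",
            f"min-max applied : {self.normalized}",
            "",
            f"{'rank':>4}  feature",
            f"{'----':>4}  -------",
        ]
        lines += [f"{i + 1:>4}  {name}" for i, name in enumerate(self.rank_order)]
        return "\n".join(lines)

    def weight_matrix(self, model: str = "max") -> pd.DataFrame:
        """Iteration × feature weight table for one model (colormap layout)."""
        sub = self.iteration_weights[self.iteration_weights["model"] == model]
        if sub.empty:
            raise ValueError(f"no recorded weights for model {model!r}")
        return sub.pivot(index="iteration", columns="feature", values="weight")

    def plot_weight_colormap(self, model: str = "max", ax=None):
        """Heatmap of per-iteration normalised weights (eliminated = blank)."""
        import matplotlib.pyplot as plt

        mat = self.weight_matrix(model)[self.rank_order]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        im = ax.imshow(mat.to_numpy(dtype=float), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(mat.index)), [str(i) for i in mat.index])
        ax.set_xlabel("feature")
        ax.set_ylabel("elimination iteration")
        ax.set_title(f"{model} normalised |w| per iteration")
        ax.figure.colorbar(im, ax=ax, label="|w| / ‖w‖")
        return ax


class SVMRFE:
    """Multiclass (one-versus-all) SVM recursive feature elimination.

    Parameters
    ----------
    X, y
        Feature matrix (n × D) and class labels.
    feature_names
        D names; defaults to the canonical 11 HRV names when D == 11.
    C
        Soft-margin penalty shared by the three OVA SVMs.
    normalize
        Min-max scale all data once before the elimination loop (the
        procedure's default preprocessing); set False if X is already scaled.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        feature_names: list[str] | None = None,
        C: float = 1.0,
        normalize: bool = True,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on the number of samples")
        if not np.isfinite(self.X).all():
            raise ValueError("X must contain no missing/non-finite values")
        D = self.X.shape[1]
        if feature_names is None:
            feature_names = list(FEATURE_NAMES) if D == len(FEATURE_NAMES) \
                else [f"f{j}" for j in range(D)]
        if len(feature_names) != D:
            raise ValueError("feature_names length must equal the feature count")
        self.feature_names = list(feature_names)
        self.C = float(C)
        self.normalize = bool(normalize)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "group",
        feature_cols: list[str] | None = None,
        **kwargs,
    ) -> "SVMRFE":
        if feature_cols is None:
            feature_cols = [c for c in FEATURE_NAMES if c in df.columns]
            if not feature_cols:
                raise ValueError("no canonical feature columns found")
        return cls(
            df[feature_cols].to_numpy(dtype=float),
            df[label_col].to_numpy(),
            feature_names=list(feature_cols),
            **kwargs,
        )

    def fit(self) -> SVMRFERanking:
        X = self.X
        record = None
        if self.normalize:
            X, record = minmax_normalize(X, self.feature_names)
        surviving = list(range(len(self.feature_names)))
        eliminated: list[int] = []
        rows: list[dict] = []
        iteration = 1
        while len(surviving) > 1:
            models = train_ova_svms(X[:, surviving], self.y, C=self.C)
            for m in models:
                norm = float(np.linalg.norm(m.w))
                wn = np.abs(m.w) / norm if norm > 0 else np.abs(m.w)
                for k, j in enumerate(surviving):
                    rows.append({
                        "iteration": iteration,
                        "model": f"{m.positive_class}-SVM",
                        "feature": self.feature_names[j],
                        "weight": wn[k],
                    })
            W = np.stack([
                np.abs(m.w) / (np.linalg.norm(m.w) or 1.0) for m in models
            ])
            for k, j in enumerate(surviving):
                rows.append({
                    "iteration": iteration,
                    "model": "max",
                    "feature": self.feature_names[j],
                    "weight": float(W[:, k].max()),
                })
            J = ranking_scores(models)
            worst = J.min()
            # tie-break: among minimal-J features drop the latest in
            # canonical (input) order
            candidates = [surviving[k] for k in np.flatnonzero(J == worst)]
            drop = max(candidates)
            eliminated.append(drop)
            surviving.remove(drop)
            iteration += 1
        rank_idx = surviving + eliminated[::-1]
        weights = pd.DataFrame(
            rows, columns=["iteration", "model", "feature", "weight"]
        )
        return SVMRFERanking(
            rank_order=[self.feature_names[j] for j in rank_idx],
            elimination_order=[self.feature_names[j] for j in eliminated],
            iteration_weights=weights,
            C=self.C,
            normalized=self.normalize,
            minmax_record=record,
        )


def rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    C: float = 1.0,
    normalize: bool = True,
) -> SVMRFERanking:
    """Procedural wrapper: rank features by multiclass SVM-RFE."""
    return SVMRFE(X, y, feature_names=feature_names, C=C, normalize=normalize).fit()
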