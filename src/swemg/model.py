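"""Dysphagia-severity classification model.

The estimator chain is the two-stage design the indicators feed into:

* per-feature standardization (fitted on the training split only),
* Gaussian-noise augmentation of the training pool to balance the four
  severity classes,
* scatter-matrix linear discriminant analysis reducing the 448 features to
  at most C - 1 = 3 discriminant coordinates,
* a random forest on the 3-D projection, with hyperparameters optionally
  tuned by a genetic algorithm whose fitness is mean cross-validated
  accuracy.

Usage follows the fit/results idiom::

    model = DysphagiaSeverityModel(X, y, feature_names=names, seed=7)
    res = model.fit()            # or model.fit(tune="ga")
    print(res.summary())
    res.predict_proba(X_new)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (auc, confusion_matrix, precision_recall_curve,
                             roc_curve)
from sklearn.model_selection import StratifiedKFold, train_test_split

from .recording import SEVERITIES

#: hyperparameters reported as the tuned optimum for the reference model
DEFAULT_RF_PARAMS = {"n_estimators": 500, "max_depth": 15,
                     "min_samples_split": 2, "min_samples_leaf": 2}

#: GA search space
GA_SPACE = {
    "n_estimators": list(range(10, 501, 10)),
    "max_depth": list(range(5, 51)) + [None],
    "min_samples_split": list(range(2, 11)),
    "min_samples_leaf": list(range(1, 11)),
}

DEFAULT_AUGMENT_TOTAL = 2124


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_gaussian(X: np.ndarray, y: np.ndarray, target_total: int,
                     sigma: float = 0.05, seed: int = 0,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Balance and enlarge a dataset by Gaussian-noise jitter.

    Synthetic samples are randomly chosen originals plus
    ``N(0, (sigma * per-feature SD)^2)`` noise with inherited labels.
    Classes are equalized: each class is topped up to
    ``target_total / n_classes`` (remainder spread over the first
    classes).  Originals are always retained.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if target_total < len(y):
        raise ValueError("target_total must be >= current sample count")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    classes = [c for c in SEVERITIES if c in set(y)] or sorted(set(y))
    per_class = np.full(len(classes), target_total // len(classes))
    per_class[: target_total % len(classes)] += 1
    rng = np.random.default_rng(seed)
    sd = X.std(axis=0)
    out_X, out_y = [X], [y]
    for cls, target in zip(classes, per_class):
        idx = np.nonzero(y == cls)[0]
        if idx.size == 0:
            raise ValueError(f"class {cls!r} has no samples to augment from")
        need = int(target) - idx.size
        if need <= 0:
            continue
        picks = rng.choice(idx, size=need, replace=True)
        noise = rng.normal(0.0, 1.0, size=(need, X.shape[1])) * (sigma * sd)
        out_X.append(X[picks] + noise)
        out_y.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(out_X), np.concatenate(out_y)


# ---------------------------------------------------------------------------
# scatter-matrix LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAProjection:
    """Fitted discriminant projection (class means + leading eigenvectors)."""

    components: np.ndarray          # (n_features, n_components)
    eigenvalues: np.ndarray
    class_means: dict
    grand_mean: np.ndarray
    degenerate: bool = False        # leading eigenvalue ~ 0

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.grand_mean) @ self.components


def lda_reduce(X: np.ndarray, y: np.ndarray, n_components: int = 3,
               ridge: float = 1e-3) -> tuple[np.ndarray, LDAProjection]:
    """Fisher discriminant reduction via within/between scatter matrices.

    Solves the generalized eigenproblem ``S_b v = lambda S_w v`` and
    projects onto the leading ``min(n_components, C - 1)`` eigenvectors;
    four classes give a 3-D representation.  ``ridge`` shrinks ``S_w``
    toward a scaled identity, which keeps the eigenproblem well posed when
    samples are scarcer than features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("LDA needs at least two classes")
    n, p = X.shape
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    means = {}
    for cls in classes:
        Xc = X[y == cls]
        mu = Xc.mean(axis=0)
        means[cls] = mu
        d = Xc - mu
        Sw += d.T @ d
        m = (mu - grand)[:, None]
        Sb += Xc.shape[0] * (m @ m.T)
    scale = np.trace(Sw) / p if np.trace(Sw) > 0 else 1.0
    Sw_reg = Sw + ridge * scale * np.eye(p)
    eigvals, eigvecs = linalg.eigh(Sb, Sw_reg)
    order = np.argsort(eigvals)[::-1]
    k = min(n_components, len(classes) - 1)
    eigvals, eigvecs = eigvals[order[:k]], eigvecs[:, order[:k]]
    # canonical sign: largest-magnitude loading positive
    for j in range(eigvecs.shape[1]):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    proj = LDAProjection(components=eigvecs, eigenvalues=eigvals,
                         class_means=means, grand_mean=grand,
                         degenerate=bool(eigvals[0] <= 1e-12))
    return proj.transform(X), proj


# ---------------------------------------------------------------------------
# genetic-algorithm hyperparameter tuning
# ---------------------------------------------------------------------------

def _cv_accuracy(X: np.ndarray, y: np.ndarray, params: dict,
                 cv_folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        rf = RandomForestClassifier(random_state=seed, **params)
        rf.fit(X[tr], y[tr])
        accs.append(rf.score(X[te], y[te]))
    return float(np.mean(accs))


def ga_tune(X: np.ndarray, y: np.ndarray, cv_folds: int = 3, seed: int = 0,
            generations: int = 40, population: int = 50,
            tournament: int = 3, p_crossover: float = 0.7,
            p_mutation: float = 0.1,
            space: dict | None = None) -> dict:
    """Genetic-algorithm search over random-forest hyperparameters.

    Individuals are index vectors into the discrete search space
    (``n_estimators`` 10..500 step 10, ``max_depth`` 5..50 or unlimited,
    ``min_samples_split`` 2..10, ``min_samples_leaf`` 1..10).  Tournament
    selection, uniform crossover, per-gene mutation, one elite carried
    over; fitness is mean stratified-CV accuracy.  Reproducible per seed.
    """
    space = dict(space or GA_SPACE)
    keys = list(space)
    sizes = [len(space[k]) for k in keys]
    if min(np.bincount(pd.factorize(y)[0])) < cv_folds:
        raise ValueError("cv_folds exceeds the smallest class count")
    rng = np.random.default_rng(seed)

    def decode(ind):
        return {k: space[k][g] for k, g in zip(keys, ind)}

    cache: dict[tuple, float] = {}

    def fitness(ind):
        key = tuple(ind)
        if key not in cache:
            cache[key] = _cv_accuracy(X, y, decode(ind), cv_folds, seed)
        return cache[key]

    pop = [tuple(rng.integers(0, s) for s in sizes) for _ in range(population)]
    if all(s == 1 for s in sizes):
        return decode(pop[0])
    fits = [fitness(i) for i in pop]
    for _ in range(generations):
        elite = pop[int(np.argmax(fits))]
        nxt = [elite]
        while len(nxt) < population:
            def pick():
                cand = rng.integers(0, population, size=tournament)
                return pop[cand[int(np.argmax([fits[c] for c in cand]))]]
            a, b = pick(), pick()
            if rng.random() < p_crossover:
                child = tuple(a[g] if rng.random() < 0.5 else b[g]
                              for g in range(len(sizes)))
            else:
                child = a
            child = tuple(int(rng.integers(0, sizes[g]))
                          if rng.random() < p_mutation else child[g]
                          for g in range(len(sizes)))
            nxt.append(child)
        pop = nxt
        fits = [fitness(i) for i in pop]
    return decode(pop[int(np.argmax(fits))])


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class SeverityResults:
    """Fitted-model results: projection, forest, and test-set diagnostics."""

    model: "DysphagiaSeverityModel"
    lda: LDAProjection
    rf: RandomForestClassifier
    rf_params: dict
    classes: list
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    accuracy: float
    confusion: np.ndarray
    per_class_recall: dict
    test_proba: np.ndarray
    test_labels: np.ndarray
    roc: dict = field(repr=False, default_factory=dict)
    prc: dict = field(repr=False, default_factory=dict)
    seed: int = 0

    # -- inference -------------------------------------------------------
    def _project(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = (X - self.scaler_mean) / self.scaler_sd
        return self.lda.transform(Xs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.rf.predict(self._project(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.rf.predict_proba(self._project(X))

    def assess_new_subject(self, trials: np.ndarray) -> dict:
        """Per-trial class calls plus the aggregate probability pie over a
        subject's repeated swallow-test trials (typically nine)."""
        trials = np.atleast_2d(np.asarray(trials, dtype=float))
        proba = self.predict_proba(trials)
        preds = self.predict(trials)
        agg = proba.mean(axis=0)
        return {"per_trial_class": list(preds),
                "per_trial_proba": proba,
                "aggregate_proba": dict(zip(self.rf.classes_, agg)),
                "aggregate_class": self.rf.classes_[int(np.argmax(agg))]}

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        lines = ["Dysphagia severity classification",
                 "=" * 46,
                 f"classes:        {', '.join(map(str, self.classes))}",
                 f"LDA components: {self.lda.components.shape[1]}",
                 "RF params:      " + ", ".join(
                     f"{k}={v}" for k, v in self.rf_params.items()),
                 f"test accuracy:  {self.accuracy:.3f}",
                 "",
                 "confusion matrix (rows = true, cols = predicted):"]
        df = pd.DataFrame(self.confusion, index=self.classes,
                          columns=self.classes)
        lines.append(df.to_string())
        lines.append("")
        lines.append("per-class recall: " + ", ".join(
            f"{c}={r:.3f}" for c, r in self.per_class_recall.items()))
        for c in self.classes:
            if c in self.roc:
                lines.append(f"ROC AUC[{c}] = {self.roc[c]['auc']:.3f}   "
                             f"PR AUC[{c}] = {self.prc[c]['auc']:.3f}")
        return "\n".join(lines)

    def plot_confusion(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.confusion, cmap="Blues")
        ax.set_xticks(range(len(self.classes)), self.classes)
        ax.set_yticks(range(len(self.classes)), self.classes)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(len(self.classes)):
            for j in range(len(self.classes)):
                ax.text(j, i, str(self.confusion[i, j]),
                        ha="center", va="center")
        plt.colorbar(im, ax=ax)
        return ax


class DysphagiaSeverityModel:
    """Severity classifier built from a (n_samples, 448) feature matrix.

    Parameters
    ----------
    X, y
        Feature matrix and severity labels.
    feature_names
        Optional column names (used to subset channels for ablations).
    augment_total
        Size the balanced training pool is augmented to (0 disables).
    augment_sigma
        Noise scale as a fraction of each feature's SD.
    augment_before_split
        Augment the full dataset before the 70/30 split instead of the
        training pool only.  Off by default to avoid train/test leakage.
    """

    def __init__(self, X: np.ndarray, y, feature_names: list[str] | None = None,
                 test_size: float = 0.3, augment_total: int = DEFAULT_AUGMENT_TOTAL,
                 augment_sigma: float = 0.05, augment_before_split: bool = False,
                 n_components: int = 3, seed: int = 0) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.feature_names = list(feature_names) if feature_names else None
        self.test_size = test_size
        self.augment_total = augment_total
        self.augment_sigma = augment_sigma
        self.augment_before_split = augment_before_split
        self.n_components = n_components
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "severity",
                       **kwargs) -> "DysphagiaSeverityModel":
        cols = [c for c in df.columns if c != label_col]
        return cls(df[cols].to_numpy(float), df[label_col].to_numpy(),
                   feature_names=cols, **kwargs)

    def fit(self, tune: str | dict | None = None,
            ga_generations: int = 40, ga_population: int = 50,
            cv_folds: int = 3) -> SeverityResults:
        """Split, augment, project, fit and evaluate.

        ``tune`` is ``None`` (reference hyperparameters), ``"ga"``
        (genetic-algorithm search), or an explicit hyperparameter dict.
        """
        X, y, seed = self.X, self.y, self.seed
        if self.augment_before_split and self.augment_total:
            X, y = augment_gaussian(X, y, max(self.augment_total, len(y)),
                                    sigma=self.augment_sigma, seed=seed)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=self.test_size, random_state=seed, stratify=y)
        if not self.augment_before_split and self.augment_total:
            target = max(int(self.augment_total * (1 - self.test_size)),
                         len(y_tr))
            X_tr, y_tr = augment_gaussian(X_tr, y_tr, target,
                                          sigma=self.augment_sigma, seed=seed)
        # standardization fitted on the (augmented) training pool
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd[sd == 0] = 1.0
        Z_tr = (X_tr - mu) / sd
        Z_te = (X_te - mu) / sd

        P_tr, lda = lda_reduce(Z_tr, y_tr, n_components=self.n_components)
        P_te = lda.transform(Z_te)

        if tune == "ga":
            rf_params = ga_tune(P_tr, y_tr, cv_folds=cv_folds, seed=seed,
                                generations=ga_generations,
                                population=ga_population)
        elif isinstance(tune, dict):
            rf_params = dict(tune)
        else:
            rf_params = dict(DEFAULT_RF_PARAMS)

        rf = RandomForestClassifier(random_state=seed, **rf_params)
        rf.fit(P_tr, y_tr)
        classes = list(rf.classes_)
        pred = rf.predict(P_te)
        proba = rf.predict_proba(P_te)
        cm = confusion_matrix(y_te, pred, labels=classes)
        recall = {c: (cm[i, i] / cm[i].sum() if cm[i].sum() else np.nan)
                  for i, c in enumerate(classes)}
        roc, prc = {}, {}
        for i, c in enumerate(classes):
            truth = (y_te == c).astype(int)
            if truth.min() == truth.max():
                continue
            fpr, tpr, _ = roc_curve(truth, proba[:, i])
            prec, rec, _ = precision_recall_curve(truth, proba[:, i])
            roc[c] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
            prc[c] = {"precision": prec, "recall": rec,
                      "auc": float(auc(rec, prec))}
        return SeverityResults(
            model=self, lda=lda, rf=rf, rf_params=rf_params, classes=classes,
            scaler_mean=mu, scaler_sd=sd,
            accuracy=float(np.mean(pred == y_te)), confusion=cm,
            per_class_recall=recall, test_proba=proba, test_labels=y_te,
            roc=roc, prc=prc, seed=seed)
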