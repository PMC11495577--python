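"""Flux-capacity features and developmental-stage classification.

Per sample-specific context model, the flux capacity of a reaction is
its FVA span at >= 80% of that model's own biomass optimum, computed
on the reversibility-split (all-irreversible) model:

    FCa(r) = Fluxmax(r) - Fluxmin(r) >= 0

Reactions absent from a sample's model get capacity 0. The resulting
samples x reactions matrix feeds five classifier families (logistic
regression, k-nearest neighbors, decision tree, RBF support-vector
machine, random forest) evaluated under repeated stratified
cross-validation (10 folds x 10 repeats). Inside every fold, fitted on
the training split only: a zero-variance filter, ANOVA-F K-best
selection (K = 500 or all remaining features), and standardization.
Metrics (recall, precision, balanced accuracy, F1) are averaged over
all fold x repeat evaluations with "mature" as the positive class.

Feature attribution uses a model-agnostic permutation-sampling Shapley
estimator with the training-split median vector as background,
evaluated on each fold's test samples and averaged per sample across
folds and repeats.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import cobra
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectKBest, VarianceThreshold, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .netcore import FLUX_TOL, split_reversible
from .simulate import fva

logger = logging.getLogger("dielflux")

CLASSIFIER_FAMILIES = ("logistic-regression", "k-nearest-neighbors",
                       "decision-tree", "support-vector-machine",
                       "random-forest")


@dataclasses.dataclass
class MLConfig:
    n_folds: int = 10
    n_repeats: int = 10
    k_best: int = 500
    classifier_families: tuple[str, ...] = CLASSIFIER_FAMILIES
    seed: int = 0
    positive_label: str = "mature"

    def __post_init__(self):
        if self.n_folds < 2 or self.k_best < 1:
            raise ValueError("need n_folds >= 2 and k_best >= 1")


@dataclasses.dataclass
class FluxCapacityMatrix:
    """Samples x reactions FCa features with class labels."""

    X: pd.DataFrame
    y: pd.Series
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if (self.X.values < -FLUX_TOL).any():
            raise ValueError("flux capacities must be nonnegative")
        self.X = self.X.clip(lower=0.0)

    def to_tsv(self, path) -> None:
        out = self.X.copy()
        out["label"] = self.y
        out.rename_axis("sample_id").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "FluxCapacityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        y = df.pop("label")
        return cls(X=df, y=y)


@dataclasses.dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Recall, precision, balanced accuracy and F1 from raw counts.

    Zero denominators yield 0 with a ``zero_division`` flag listing the
    affected metrics.
    """
    flags = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    recall = safe(counts.TP, counts.TP + counts.FN, "recall")
    precision = safe(counts.TP, counts.TP + counts.FP, "precision")
    specificity = safe(counts.TN, counts.TN + counts.FP, "specificity")
    f1 = safe(counts.TP, counts.TP + 0.5 * (counts.FP + counts.FN), "f1")
    return dict(recall=recall, precision=precision,
                balanced_accuracy=0.5 * (recall + specificity), f1=f1,
                zero_division=flags)


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def flux_capacity(model: cobra.Model,
                  biomass_fraction: float = 0.8) -> pd.Series:
    """FCa per reaction of the reversibility-split model.

    FVA is run at >= ``biomass_fraction`` of the model's own biomass
    optimum; forward and reverse copies of a reversible reaction are
    separate features. A model unable to grow yields an all-zero row
    with a warning.
    """
    split, _ = split_reversible(model)
    opt = split.slim_optimize(error_value=0.0)
    if opt is None or opt <= FLUX_TOL:
        logger.warning("flux_capacity: model %s cannot grow; all-zero row",
                       model.id)
        return pd.Series(0.0, index=[r.id for r in split.reactions])
    result = fva(split, fraction_of_optimum=biomass_fraction)
    return result.span().clip(lower=0.0)


def build_dataset(
    capacities: Mapping[str, pd.Series] | Mapping[str, cobra.Model],
    labels: Mapping[str, str],
    biomass_fraction: float = 0.8,
) -> FluxCapacityMatrix:
    """Union-reaction FCa matrix over samples; absent reactions are 0.

    Accepts per-sample FCa series or context models (capacities are
    computed on the fly). Every sample needs a label; fewer than two
    classes is an error.
    """
    series: dict[str, pd.Series] = {}
    for sample, item in capacities.items():
        if sample not in labels:
            raise KeyError(f"no label for sample {sample!r}")
        if isinstance(item, cobra.Model):
            item = flux_capacity(item, biomass_fraction)
        series[sample] = item
    X = pd.DataFrame(series).T.fillna(0.0).sort_index(axis=1)
    y = pd.Series({s: labels[s] for s in X.index}, name="label")
    if y.nunique() < 2:
        raise ValueError("need at least two classes")
    return FluxCapacityMatrix(X=X, y=y,
                              provenance=dict(fva_fraction=biomass_fraction))


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

def _make_classifier(family: str, seed: int):
    if family == "logistic-regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if family == "k-nearest-neighbors":
        return KNeighborsClassifier()
    if family == "decision-tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "support-vector-machine":
        return SVC(kernel="rbf", probability=False, random_state=seed)
    if family == "random-forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown classifier family {family!r}")


@dataclasses.dataclass
class FoldArtifacts:
    repeat: int
    fold: int
    test_samples: list[str]
    feature_names: list[str]  # after variance filter + K-best
    scaler: StandardScaler
    background: np.ndarray  # training-split medians, scaled space
    models: dict[str, object]  # family -> fitted classifier
    transform: object  # callable X(df) -> scaled selected matrix


@dataclasses.dataclass
class EvalReport:
    per_fold: pd.DataFrame  # repeat, fold, family, metrics
    summary: pd.DataFrame  # family x mean metrics
    config: MLConfig
    artifacts: list[FoldArtifacts]

    def to_tsv(self, path) -> None:
        self.summary.rename_axis("classifier").reset_index().to_csv(
            path, sep="\t", index=False)


def evaluate_classifiers(data: FluxCapacityMatrix, config: MLConfig,
                         keep_artifacts: bool = True) -> EvalReport:
    """Repeated stratified cross-validation of all classifier families.

    All preprocessing statistics (variances, F-scores, scaler moments)
    are fitted on the training split only.
    """
    X, y = data.X, data.y
    cv = RepeatedStratifiedKFold(n_splits=config.n_folds,
                                 n_repeats=config.n_repeats,
                                 random_state=config.seed)
    rows = []
    artifacts: list[FoldArtifacts] = []
    for split_index, (train, test) in enumerate(cv.split(X, y)):
        repeat, fold = divmod(split_index, config.n_folds)
        X_tr, X_te = X.iloc[train], X.iloc[test]
        y_tr, y_te = y.iloc[train], y.iloc[test]

        var = VarianceThreshold(0.0).fit(X_tr)
        kept = X.columns[var.get_support()]
        k = min(config.k_best, len(kept))
        with np.errstate(divide="ignore", invalid="ignore"):
            kbest = SelectKBest(f_classif, k=k).fit(X_tr[kept], y_tr)
        selected = list(kept[kbest.get_support()])
        scaler = StandardScaler().fit(X_tr[selected])

        def transform(frame: pd.DataFrame, _sel=selected, _sc=scaler):
            return _sc.transform(frame[_sel])

        Z_tr, Z_te = transform(X_tr), transform(X_te)
        background = np.median(Z_tr, axis=0)
        fitted: dict[str, object] = {}
        for family in config.classifier_families:
            clf = _make_classifier(family, config.seed)
            clf.fit(Z_tr, y_tr)
            fitted[family] = clf
            pred = clf.predict(Z_te)
            pos = config.positive_label
            counts = ConfusionCounts(
                TP=int(((pred == pos) & (y_te == pos)).sum()),
                FP=int(((pred == pos) & (y_te != pos)).sum()),
                TN=int(((pred != pos) & (y_te != pos)).sum()),
                FN=int(((pred != pos) & (y_te == pos)).sum()))
            metrics = compute_metrics(counts)
            rows.append(dict(repeat=repeat, fold=fold, family=family,
                             recall=metrics["recall"],
                             precision=metrics["precision"],
                             balanced_accuracy=metrics["balanced_accuracy"],
                             f1=metrics["f1"]))
        if keep_artifacts:
            artifacts.append(FoldArtifacts(
                repeat=repeat, fold=fold,
                test_samples=list(X_te.index), feature_names=selected,
                scaler=scaler, background=background, models=fitted,
                transform=transform))
    per_fold = pd.DataFrame(rows)
    summary = (per_fold.groupby("family")
               [["balanced_accuracy", "precision", "recall", "f1"]].mean()
               .loc[list(config.classifier_families)])
    return EvalReport(per_fold=per_fold, summary=summary, config=config,
                      artifacts=artifacts)


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------

def _decision_value(clf, Z: np.ndarray, positive_label: str) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(Z)
        pos = list(clf.classes_).index(positive_label)
        return proba[:, pos]
    if hasattr(clf, "decision_function"):
        raw = clf.decision_function(Z)
        sign = 1.0 if clf.classes_[-1] == positive_label else -1.0
        return sign * raw
    return (clf.predict(Z) == positive_label).astype(float)


def _permutation_shapley(clf, x: np.ndarray, background: np.ndarray,
                         positive_label: str, n_permutations: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Sampled-permutation Shapley values of one sample.

    For each random feature order, features switch one by one from the
    background value to the sample's value; the marginal change in the
    positive-class score is credited to the switched feature. Averaging
    over permutations preserves local additivity exactly:
    sum(phi) = f(x) - f(background).
    """
    d = x.size
    phi = np.zeros(d)
    for _ in range(n_permutations):
        order = rng.permutation(d)
        points = np.tile(background, (d + 1, 1))
        current = background.copy()
        for step, j in enumerate(order, start=1):
            current[j] = x[j]
            points[step] = current
        values = _decision_value(clf, points, positive_label)
        phi[order] += np.diff(values)
    return phi / n_permutations


@dataclasses.dataclass
class AttributionReport:
    family: str
    per_sample: pd.DataFrame  # samples x features, fold-averaged Shapley
    ranking: pd.DataFrame  # feature, mean_abs_shap, sign
    never_selected: list[str]

    def to_tsv(self, path) -> None:
        self.ranking.to_csv(path, sep="\t", index=False)

    def top_features(self, n: int) -> list[str]:
        return list(self.ranking["feature"].head(n))


def shapley_attribution(report: EvalReport, data: FluxCapacityMatrix,
                        family: str = "random-forest",
                        n_permutations: int = 8,
                        seed: int | None = None) -> AttributionReport:
    """Fold-averaged Shapley attribution for one classifier family.

    Each fold's fitted model is explained on that fold's test samples
    in the fold's selected-feature space against the training-median
    background; per-sample values are averaged across every fold and
    repeat in which the sample was tested; features never selected in
    any fold get attribution 0.
    """
    if not report.artifacts:
        raise ValueError("evaluation was run without keep_artifacts")
    rng = np.random.default_rng(seed if seed is not None
                                else report.config.seed)
    features = list(data.X.columns)
    sums = pd.DataFrame(0.0, index=data.X.index, columns=features)
    counts = pd.Series(0, index=data.X.index, dtype=int)
    selected_ever: set[str] = set()
    positive = report.config.positive_label
    for art in report.artifacts:
        clf = art.models[family]
        selected_ever |= set(art.feature_names)
        Z = art.transform(data.X.loc[art.test_samples])
        for row, sample in enumerate(art.test_samples):
            phi = _permutation_shapley(clf, Z[row], art.background,
                                       positive, n_permutations, rng)
            sums.loc[sample, art.feature_names] += phi
            counts[sample] += 1
    per_sample = sums.div(counts.replace(0, 1), axis=0)
    mean_abs = per_sample.abs().mean(axis=0)
    sign = np.sign(per_sample.mean(axis=0))
    ranking = (pd.DataFrame({"feature": features,
                             "mean_abs_shap": mean_abs.values,
                             "sign": sign.values})
               .sort_values("mean_abs_shap", ascending=False)
               .reset_index(drop=True))
    never = sorted(set(features) - selected_ever)
    return AttributionReport(family=family, per_sample=per_sample,
                             ranking=ranking, never_selected=never)
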