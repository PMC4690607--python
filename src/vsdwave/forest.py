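"""Bagged decision-tree classification of waveforms with OOB diagnostics.

The classifier is a random forest in the bagging tradition: each of
``n_trees`` (default 50) trees is grown on a bootstrap resample of the
training set, with a random subset of ``ceil(sqrt(p))`` features considered
at each split.  The rows left out of a tree's bootstrap (its out-of-bag or
OOB set) provide:

* a cumulative OOB error curve over 1..n_trees (majority vote of the trees
  for which a row is OOB), used to confirm that 50 trees suffice;
* standardized permutation importances — for each feature, the mean increase
  in a tree's OOB error after permuting that feature, divided by the standard
  deviation of the increase across trees (so "importance < 1" is a
  signal-to-noise threshold);
* OOB class scores (vote fractions), the confidence measure behind the ROC
  analysis.

Model reduction first drops every feature below the importance threshold,
then removes the weakest remaining feature one at a time until held-out
accuracy degrades by more than a configurable margin.  Per-waveform
predictions are finally aggregated per recording by majority vote.

Individual trees are grown with scikit-learn's CART implementation; the
bagging, OOB bookkeeping, importances, scores and reduction logic live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .synthdata import FEATURES

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SplitSpec:
    """Stratified training-split specification.

    Either a per-class ``fraction`` (default 33%, rounded per class) or
    explicit ``per_class_counts``; sampling is without replacement.
    """

    fraction: float = 0.33
    per_class_counts: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must be in (0, 1)")


def stratified_split(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a feature table into disjoint training and validation tables.

    Per class, ``round(fraction * class count)`` rows (or the explicit
    per-class count) are sampled without replacement; the union of the two
    tables is the input.
    """
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    for label, group in table.groupby("label", sort=True):
        n = len(group)
        if n < 2:
            raise ValueError(f"class {label!r} has fewer than 2 rows")
        if spec.per_class_counts is not None:
            k = spec.per_class_counts[label]
            if k > n:
                raise ValueError(f"requested {k} training rows for {label!r}, have {n}")
        else:
            k = int(round(spec.fraction * n))
            k = min(max(k, 1), n - 1)
        train_idx.append(rng.choice(group.index.to_numpy(), size=k, replace=False))
    chosen = np.concatenate(train_idx)
    train = table.loc[np.sort(chosen)]
    valid = table.drop(index=chosen)
    return train.reset_index(drop=True), valid.reset_index(drop=True)


@dataclass
class ForestModel:
    """A trained bagged-tree ensemble with its OOB diagnostics."""

    trees: list[DecisionTreeClassifier]
    classes: np.ndarray
    feature_names: list[str]
    oob_indices: list[np.ndarray]          # per tree: training rows left out
    oob_error_curve: np.ndarray            # cumulative OOB error at 1..n_trees
    importances: pd.Series                 # standardized permutation importance
    oob_scores: pd.DataFrame               # per training row: OOB vote fractions
    seed: int
    n_training_rows: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def oob_error(self) -> float:
        return float(self.oob_error_curve[-1])

    def save(self, path) -> None:
        joblib.dump({"format_version": _MODEL_FORMAT_VERSION, "model": self}, path)

    @staticmethod
    def load(path) -> "ForestModel":
        payload = joblib.load(path)
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model file version")
        return payload["model"]


@dataclass
class PredictionSet:
    """Per-waveform predicted classes and vote-fraction scores."""

    frame: pd.DataFrame  # columns: predicted, score_<class>..., recording_id
    classes: np.ndarray

    @property
    def predicted(self) -> pd.Series:
        return self.frame["predicted"]

    def scores(self) -> pd.DataFrame:
        return self.frame[[f"score_{c}" for c in self.classes]]


def _vote_matrix(
    preds: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """Stack per-tree label predictions (trees x rows) into per-class counts."""
    counts = np.zeros((preds.shape[1], classes.size))
    for ci, c in enumerate(classes):
        counts[:, ci] = (preds == c).sum(axis=0)
    return counts


def _majority(counts: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return classes[np.argmax(counts, axis=1)]  # ties: first class in sorted order


def train_forest(
    train: pd.DataFrame,
    n_trees: int = 50,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> ForestModel:
    """Grow a bagged ensemble and compute its OOB diagnostics.

    Each tree is grown to purity (Gini, minimum leaf size 1) on a bootstrap
    resample the size of the training set, considering ``ceil(sqrt(p))``
    random features per split.  Deterministic given ``seed``.
    """
    feature_names = list(feature_names or FEATURES)
    X = train[feature_names].to_numpy(dtype=float)
    y = train["label"].to_numpy()
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 training rows")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")

    rng = np.random.default_rng(seed)
    max_features = int(np.ceil(np.sqrt(p)))
    trees, oob_indices, all_preds = [], [], np.empty((n_trees, n), dtype=object)
    for k in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=max_features,
            min_samples_leaf=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)
        oob_indices.append(oob)
        all_preds[k] = tree.predict(X)

    # cumulative OOB error: majority vote over trees for which a row is OOB
    counts = np.zeros((n, classes.size))
    oob_mask = np.zeros(n, dtype=bool)
    curve = np.empty(n_trees)
    class_index = {c: i for i, c in enumerate(classes)}
    for k in range(n_trees):
        oob = oob_indices[k]
        for i in oob:
            counts[i, class_index[all_preds[k][i]]] += 1
        oob_mask[oob] = True
        voted = oob_mask & (counts.sum(axis=1) > 0)
        pred = _majority(counts[voted], classes)
        curve[k] = float(np.mean(pred != y[voted])) if voted.any() else 1.0

    importances = _permutation_importance(trees, oob_indices, X, y, rng)
    total = counts.sum(axis=1, keepdims=True)
    frac = np.divide(counts, total, out=np.zeros_like(counts), where=total > 0)
    oob_scores = pd.DataFrame(frac, columns=[f"score_{c}" for c in classes])
    oob_scores["label"] = y

    return ForestModel(
        trees=trees,
        classes=classes,
        feature_names=feature_names,
        oob_indices=oob_indices,
        oob_error_curve=curve,
        importances=pd.Series(importances, index=feature_names),
        oob_scores=oob_scores,
        seed=seed,
        n_training_rows=n,
    )


def _permutation_importance(
    trees, oob_indices, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Standardized OOB permutation importance.

    For each tree and feature: permute the feature among the tree's OOB rows
    and measure the increase in that tree's OOB error.  The importance is
    the across-tree mean increase divided by its across-tree standard
    deviation (zero when the deviation vanishes).
    """
    n_trees, p = len(trees), X.shape[1]
    deltas = np.zeros((n_trees, p))
    for k, (tree, oob) in enumerate(zip(trees, oob_indices)):
        if oob.size == 0:
            continue
        Xo, yo = X[oob], y[oob]
        base_err = np.mean(tree.predict(Xo) != yo)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            deltas[k, j] = np.mean(tree.predict(Xp) != yo) - base_err
    mean = deltas.mean(axis=0)
    sd = deltas.std(axis=0, ddof=1)
    return np.divide(mean, sd, out=np.zeros(p), where=sd > 0)


def predict(model: ForestModel, table: pd.DataFrame) -> PredictionSet:
    """Classify each waveform by the mode of the per-tree predictions.

    Scores are vote fractions per class (non-negative, summing to 1);
    deterministic given the model.
    """
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    X = table[model.feature_names].to_numpy(dtype=float)
    preds = np.stack([tree.predict(X) for tree in model.trees])
    counts = _vote_matrix(preds, model.classes)
    frac = counts / model.n_trees
    frame = pd.DataFrame(frac, columns=[f"score_{c}" for c in model.classes])
    frame.insert(0, "predicted", _majority(counts, model.classes))
    if "recording_id" in table.columns:
        frame["recording_id"] = table["recording_id"].to_numpy()
    if "label" in table.columns:
        frame["label"] = table["label"].to_numpy()
    return PredictionSet(frame=frame, classes=model.classes)


@dataclass
class ReductionStep:
    features: list[str]
    importances: dict[str, float]
    oob_error: float
    validation_accuracy: float
    removed: list[str] = field(default_factory=list)
    accepted: bool = True


@dataclass
class ReductionReport:
    steps: list[ReductionStep]
    final_features: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(len(self.steps)),
                "n_features": [len(s.features) for s in self.steps],
                "features": ["|".join(s.features) for s in self.steps],
                "removed": ["|".join(s.removed) for s in self.steps],
                "oob_error": [s.oob_error for s in self.steps],
                "validation_accuracy": [s.validation_accuracy for s in self.steps],
                "accepted": [s.accepted for s in self.steps],
            }
        )


def reduce_model(
    train: pd.DataFrame,
    valid: pd.DataFrame,
    n_trees: int = 50,
    seed: int = 0,
    importance_threshold: float = 1.0,
    stop_margin: float = 0.05,
    feature_names: list[str] | None = None,
) -> tuple[ReductionReport, ForestModel]:
    """Sequential feature removal driven by standardized OOB importance.

    Step 0 trains on all features.  Step 1 removes every feature whose
    importance falls below ``importance_threshold`` and retrains.  Each
    further step removes the single least-important remaining feature and
    retrains; reduction stops when held-out accuracy drops by more than
    ``stop_margin`` (fraction) relative to the previous accepted step, or
    when fewer than 2 features would remain.  The returned model is the one
    from the last accepted step.
    """
    feature_names = list(feature_names or FEATURES)

    def acc(model: ForestModel) -> float:
        pred = predict(model, valid)
        return float(np.mean(pred.predicted.to_numpy() == valid["label"].to_numpy()))

    def fit(feats: list[str], removed: list[str]) -> tuple[ForestModel, ReductionStep]:
        model = train_forest(train, n_trees=n_trees, seed=seed, feature_names=feats)
        step = ReductionStep(
            features=feats,
            importances=model.importances.to_dict(),
            oob_error=model.oob_error,
            validation_accuracy=acc(model),
            removed=removed,
        )
        return model, step

    model, step0 = fit(feature_names, [])
    steps = [step0]
    best_model, best_acc = model, step0.validation_accuracy

    below = [f for f in feature_names if model.importances[f] < importance_threshold]
    feats = [f for f in feature_names if f not in below]
    if below and len(feats) >= 2:
        model, step = fit(feats, below)
        steps.append(step)
        if step.validation_accuracy >= best_acc - stop_margin:
            best_model, best_acc = model, step.validation_accuracy
        else:
            step.accepted = False

    while len(best_model.feature_names) > 2:
        feats = list(best_model.feature_names)
        weakest = min(feats, key=lambda f: best_model.importances[f])
        remaining = [f for f in feats if f != weakest]
        model, step = fit(remaining, [weakest])
        steps.append(step)
        if step.validation_accuracy < best_acc - stop_margin:
            step.accepted = False
            break
        best_model, best_acc = model, step.validation_accuracy

    return ReductionReport(steps=steps, final_features=list(best_model.feature_names)), best_model


def aggregate_recording(predictions: PredictionSet) -> pd.DataFrame:
    """Recording-level call: mode of per-waveform predictions per recording.

    Vote ties are broken by the higher mean class score within the
    recording.  Returns a frame indexed by ``recording_id`` with the
    aggregated ``predicted`` class and the per-waveform vote share.
    """
    frame = predictions.frame
    if "recording_id" not in frame.columns:
        raise ValueError("predictions carry no recording_id")
    rows = []
    for rec_id, group in frame.groupby("recording_id", sort=True):
        if len(group) == 0:
            raise ValueError(f"recording {rec_id!r} has no waveforms")
        counts = group["predicted"].value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) > 1:
            mean_scores = {c: group[f"score_{c}"].mean() for c in top}
            winner = max(sorted(top), key=lambda c: mean_scores[c])
        else:
            winner = top[0]
        rows.append(
            {
                "recording_id": rec_id,
                "predicted": winner,
                "n_waveforms": len(group),
                "vote_share": counts.max() / len(group),
            }
        )
    return pd.DataFrame(rows).set_index("recording_id")


def vote_aggregation_simulation(
    n_recordings: int = 1000,
    n_waveforms: int = 60,
    p_correct: float = 0.6,
    n_classes: int = 3,
    seed: int = 0,
) -> float:
    """Monte-Carlo check of recording-level aggregation.

    Each simulated recording holds ``n_waveforms`` independent per-waveform
    calls that are correct with probability ``p_correct`` (wrong classes
    equally likely); the recording is called by majority vote via
    :func:`aggregate_recording`.  Returns the percentage of recordings whose
    aggregated call matches the truth.

    Simulated vote-fraction scores mimic a forest's confidence structure:
    a correctly called waveform scores ``p_correct`` on the true class, and a
    miscalled waveform keeps the true class as runner-up — so exact vote
    ties between the true class and a wrong class resolve through the
    contracted mean-score tie-break, as they do for real vote fractions.
    """
    rng = np.random.default_rng(seed)
    classes = np.array([f"c{i}" for i in range(n_classes)])
    p_wrong = (1.0 - p_correct) / (n_classes - 1)
    correct = 0
    frames = []
    truths = []
    runner_up = (1.0 - 0.5) * 0.6  # score kept by the true class when miscalled
    for r in range(n_recordings):
        true_idx = r % n_classes
        probs = np.full(n_classes, p_wrong)
        probs[true_idx] = p_correct
        calls = rng.choice(classes, size=n_waveforms, p=probs)
        df = pd.DataFrame({"predicted": calls, "recording_id": f"rec{r:04d}"})
        scores = np.empty((n_waveforms, n_classes))
        hit = calls == classes[true_idx]
        for ci, c in enumerate(classes):
            is_pred = calls == c
            if ci == true_idx:
                scores[:, ci] = np.where(hit, p_correct, runner_up)
            else:
                rest = (1.0 - 0.5 - runner_up) / max(n_classes - 2, 1)
                scores[:, ci] = np.where(is_pred, 0.5, rest)
        scores /= scores.sum(axis=1, keepdims=True)
        for ci, c in enumerate(classes):
            df[f"score_{c}"] = scores[:, ci]
        frames.append(df)
        truths.append((f"rec{r:04d}", classes[true_idx]))
    preds = PredictionSet(frame=pd.concat(frames, ignore_index=True), classes=classes)
    agg = aggregate_recording(preds)
    for rec_id, true_class in truths:
        if agg.loc[rec_id, "predicted"] == true_class:
            correct += 1
    return 100.0 * correct / n_recordings
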