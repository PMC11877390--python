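"""Label-merging schemes and gradient-boosted tree classification.

The study design measures each subject at five time points.  Because
adjacent time points produce similar physiology, classifiers are trained
under several label-merging schemes: the identity five-label scheme, two
three-label consolidations, and three binary "alcohol"/"no alcohol"
schemes (A, B, C) that draw the boundary at different time points.

Training uses XGBoost with a seeded random search over the number of trees,
tree depth and learning rate, selecting the combination that maximizes
accuracy on the held-out validation subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .features import SelectionResult, feature_columns
from .simulate import FIVE_LABELS

NO_ALCOHOL = "no alcohol"
ALCOHOL = "alcohol"


@dataclass(frozen=True)
class LabelScheme:
    """A total mapping from the five time-point labels to merged classes."""

    name: str
    mapping: dict[str, str]
    positive_class: str | None = None

    def __post_init__(self) -> None:
        missing = [lab for lab in FIVE_LABELS if lab not in self.mapping]
        if missing:
            raise ValueError(f"scheme {self.name!r} does not map labels {missing}")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @property
    def is_binary(self) -> bool:
        return len(self.classes) == 2


def _scheme(name, pairs, positive=None):
    return LabelScheme(name=name, mapping=dict(zip(FIVE_LABELS, pairs)), positive_class=positive)


#: The six labeling schemes. Binary model A splits at 60 min, B at 30 min,
#: C right after drinking (any consumption counts as "alcohol").
SCHEMES: dict[str, LabelScheme] = {
    "five": _scheme("five", FIVE_LABELS),
    "three_case1": _scheme(
        "three_case1", (NO_ALCOHOL, NO_ALCOHOL, "30 min", ALCOHOL, ALCOHOL)
    ),
    "three_case2": _scheme(
        "three_case2", (NO_ALCOHOL, "0 and 30 min", "0 and 30 min", ALCOHOL, ALCOHOL)
    ),
    "binary_A": _scheme(
        "binary_A", (NO_ALCOHOL, NO_ALCOHOL, NO_ALCOHOL, ALCOHOL, ALCOHOL), ALCOHOL
    ),
    "binary_B": _scheme(
        "binary_B", (NO_ALCOHOL, NO_ALCOHOL, ALCOHOL, ALCOHOL, ALCOHOL), ALCOHOL
    ),
    "binary_C": _scheme(
        "binary_C", (NO_ALCOHOL, ALCOHOL, ALCOHOL, ALCOHOL, ALCOHOL), ALCOHOL
    ),
}


def apply_scheme(labels: Sequence[str], scheme: LabelScheme) -> list[str]:
    """Map five-label annotations elementwise through a merging scheme."""
    out = []
    for lab in labels:
        if lab not in scheme.mapping:
            raise ValueError(
                f"unknown label {lab!r}; scheme {scheme.name!r} maps {FIVE_LABELS}"
            )
        out.append(scheme.mapping[lab])
    return out


@dataclass
class TrainedModel:
    """A fitted boosted-tree ensemble plus everything needed to replay it."""

    ensemble: XGBClassifier
    classes: list[str]
    hyperparameters: dict
    selected_features: list[str]
    scheme: LabelScheme
    seed: int
    search_trials: int
    search_trace: list[dict] = field(default_factory=list)

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.selected_features if c not in table.columns]
        if missing:
            raise ValueError(f"table is missing feature columns: {missing}")
        return table[self.selected_features].to_numpy(dtype=float)

    def predict(self, table: pd.DataFrame) -> list[str]:
        idx = self.ensemble.predict(self._matrix(table))
        return [self.classes[i] for i in idx]

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Class-membership probabilities, columns ordered as ``classes``."""
        return self.ensemble.predict_proba(self._matrix(table))


def _make_estimator(params: dict, n_classes: int, seed: int) -> XGBClassifier:
    common = dict(
        n_estimators=params["n_trees"],
        max_depth=params["max_depth"],
        learning_rate=params["learning_rate"],
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )
    if n_classes == 2:
        return XGBClassifier(objective="binary:logistic", **common)
    return XGBClassifier(objective="multi:softprob", num_class=n_classes, **common)


def tune_and_train(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    scheme: LabelScheme,
    trials: int = 50,
    seed: int = 0,
    selection: SelectionResult | None = None,
    n_trees_range: tuple[int, int] = (50, 500),
    max_depth_range: tuple[int, int] = (2, 8),
    learning_rate_range: tuple[float, float] = (0.01, 0.3),
    objective: str = "holdout",
) -> TrainedModel:
    """Random-search hyperparameters and fit the final ensemble.

    ``trials`` parameter combinations are drawn from the search space
    (learning rate on a log scale) with a seeded generator; the objective is
    plain accuracy on the validation table after label merging.  Ties break
    toward the smallest model: fewest trees, then shallowest depth.  The
    winning parameters are refit on the full training table.

    ``objective="loso"`` scores each trial by leave-one-subject-out
    cross-validation inside the training table instead of the held-out
    validation table — a more robust (and slower) criterion for studies of
    the search itself.

    The validation table influences only the search objective — never
    feature selection (done upstream on training rows) or tree fitting.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if objective not in ("holdout", "loso"):
        raise ValueError("objective must be 'holdout' or 'loso'")
    feats = selection.kept if selection is not None else feature_columns(train)
    missing = [c for c in feats if c not in train.columns or c not in validation.columns]
    if missing:
        raise ValueError(f"feature columns missing from input tables: {missing}")
    if not feats:
        raise ValueError("no features to train on")

    y_train = apply_scheme(train["time_label"].tolist(), scheme)
    y_val = apply_scheme(validation["time_label"].tolist(), scheme)
    classes = sorted(set(y_train))
    if len(classes) < 2:
        raise ValueError(
            f"training set has a single class {classes} after applying "
            f"scheme {scheme.name!r}"
        )
    if len(set(y_val)) < 2:
        raise ValueError("validation set has a single class after mapping")
    class_index = {c: i for i, c in enumerate(classes)}
    X_train = train[feats].to_numpy(dtype=float)
    X_val = validation[feats].to_numpy(dtype=float)
    yi_train = np.array([class_index[c] for c in y_train])
    yi_val = np.array([class_index[c] for c in y_val])

    subjects = train["subject_id"].to_numpy() if "subject_id" in train.columns else None
    if objective == "loso" and (subjects is None or len(set(subjects)) < 2):
        raise ValueError("objective='loso' needs >= 2 training subjects")

    def trial_accuracy(params: dict) -> float:
        if objective == "holdout":
            est = _make_estimator(params, len(classes), seed)
            est.fit(X_train, yi_train)
            return float((est.predict(X_val) == yi_val).mean())
        accs = []
        for s in sorted(set(subjects)):
            held = subjects == s
            if len(set(yi_train[~held])) < 2 or held.all() or not held.any():
                continue
            est = _make_estimator(params, len(classes), seed)
            est.fit(X_train[~held], yi_train[~held])
            accs.append(float((est.predict(X_train[held]) == yi_train[held]).mean()))
        return float(np.mean(accs))

    rng = np.random.default_rng(seed)
    log_lo, log_hi = math.log10(learning_rate_range[0]), math.log10(learning_rate_range[1])
    best: dict | None = None
    trace: list[dict] = []
    for trial in range(trials):
        params = {
            "n_trees": int(rng.integers(n_trees_range[0], n_trees_range[1] + 1)),
            "max_depth": int(rng.integers(max_depth_range[0], max_depth_range[1] + 1)),
            "learning_rate": float(10 ** rng.uniform(log_lo, log_hi)),
        }
        acc = trial_accuracy(params)
        trace.append({"trial": trial, **params, "val_accuracy": acc})
        key = (-acc, params["n_trees"], params["max_depth"])
        if best is None or key < best["key"]:
            best = {"key": key, "params": params, "accuracy": acc}
    assert best is not None
    final = _make_estimator(best["params"], len(classes), seed)
    final.fit(X_train, yi_train)
    return TrainedModel(
        ensemble=final,
        classes=classes,
        hyperparameters=best["params"],
        selected_features=list(feats),
        scheme=scheme,
        seed=seed,
        search_trials=trials,
        search_trace=trace,
    )
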