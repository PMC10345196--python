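"""Four-class variant classifier: Model/Results objects.

`VariantClassifierModel` holds a complete eight-feature variant table together
with its 4-class labels; `fit` / `grid_search` return a
`VariantClassifierResults` carrying the trained gradient-boosted trees, the
selected hyperparameters, stratified cross-validation metrics and prediction
helpers.

The boosted-tree backend is LightGBM with multiclass cross-entropy loss and
L2 leaf regularization, run in deterministic single-threaded mode so that the
whole train -> predict path is bit-identical for a fixed seed, input ordering
and hyperparameters.  Baselines: a most-frequent-class null model and a
random-forest comparator evaluated on the same folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
import lightgbm as lgb
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    matthews_corrcoef,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES
from .mave import CLASS_ORDER

__all__ = [
    "VariantClassifierModel",
    "VariantClassifierResults",
    "evaluate",
    "DEFAULT_GRID",
    "DEFAULT_PARAMS",
]

#: Hyperparameter grid scanned by grid_search (depth x learning rate x L2).
DEFAULT_GRID = {
    "max_depth": [4, 6, 8],
    "learning_rate": [0.03, 0.1, 0.3],
    "reg_lambda": [1.0, 3.0, 10.0],
}

#: The "vanilla" setting used to fix the iteration count before the grid scan.
DEFAULT_PARAMS = {"max_depth": 6, "learning_rate": 0.1, "reg_lambda": 3.0}

_MAX_ITERATIONS = 2000
_EARLY_STOPPING_PATIENCE = 50


def _make_booster(params: dict, n_estimators: int, seed: int) -> lgb.LGBMClassifier:
    depth = int(params.get("max_depth", 6))
    return lgb.LGBMClassifier(
        objective="multiclass",
        n_estimators=n_estimators,
        max_depth=depth,
        num_leaves=min(2**depth, 63),
        learning_rate=float(params.get("learning_rate", 0.1)),
        reg_lambda=float(params.get("reg_lambda", 3.0)),
        class_weight=params.get("class_weight"),
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        random_state=seed,
        verbose=-1,
    )


def evaluate(y_true, y_pred, classes=CLASS_ORDER) -> dict:
    """Multiclass metrics report: accuracy, per-class precision/recall,
    generalized (Gorodkin) Matthews correlation coefficient, confusion matrix.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} truths vs {y_pred.shape[0]} "
            "predictions"
        )
    classes = [c for c in classes if c in set(y_true) | set(y_pred)] or list(classes)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "mcc": float(matthews_corrcoef(y_true, y_pred)),
        "precision": dict(
            zip(
                classes,
                precision_score(
                    y_true, y_pred, labels=classes, average=None, zero_division=0.0
                ).tolist(),
            )
        ),
        "recall": dict(
            zip(
                classes,
                recall_score(
                    y_true, y_pred, labels=classes, average=None, zero_division=0.0
                ).tolist(),
            )
        ),
        "confusion_matrix": pd.DataFrame(cm, index=classes, columns=classes),
    }


class VariantClassifierModel:
    """Gradient-boosting 4-class variant classifier (unfitted model object).

    Parameters
    ----------
    features
        DataFrame containing at least the eight feature columns
        (:data:`funcsites.features.FEATURE_NAMES`); extra identifier columns
        are carried through to predictions.  Rows with missing features are
        rejected — filter on the table's ``complete`` flag first.
    labels
        4-class label per row (strings from
        :data:`funcsites.mave.CLASS_ORDER`).
    seed
        Master seed; fans out to fold assignment and model initialisation.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels,
        feature_names=FEATURE_NAMES,
        seed: int = 0,
        class_weighting: bool = False,
    ):
        self.feature_names = tuple(feature_names)
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        labels = np.asarray(
            [getattr(l, "value", l) for l in labels], dtype=object
        )
        if len(labels) != len(features):
            raise ValueError("features and labels have different lengths")
        X = features[list(self.feature_names)].astype(float).reset_index(drop=True)
        if not np.isfinite(X.to_numpy()).all():
            raise ValueError(
                "feature table contains missing values; drop incomplete rows "
                "before model construction"
            )
        self.features = features.reset_index(drop=True)
        self.X = X
        self.y = labels
        self.seed = int(seed)
        self.class_weighting = class_weighting
        self.classes_ = [c for c in CLASS_ORDER if c in set(labels)]

    @classmethod
    def from_tables(
        cls,
        feature_table: pd.DataFrame,
        labelled: pd.DataFrame,
        seed: int = 0,
        **kwargs,
    ) -> "VariantClassifierModel":
        """Join an assembled feature table with a labelled MAVE table.

        Matches on (position, wt, mut); keeps only complete feature rows with
        a non-missing class label.
        """
        lab = labelled.rename(columns={"wt": "wt_aa", "mut": "target_aa"})
        merged = feature_table.merge(
            lab[["position", "wt_aa", "target_aa", "class"]],
            on=["position", "wt_aa", "target_aa"],
            how="inner",
        )
        merged = merged[merged["complete"] & merged["class"].notna()]
        return cls(
            merged.drop(columns=["class"]), merged["class"], seed=seed, **kwargs
        )

    # ------------------------------------------------------------------ folds
    def stratified_folds(self, k: int = 5) -> list[tuple[np.ndarray, np.ndarray]]:
        """Stratified k-fold partition (each validation set holds 1/k of the data)."""
        counts = pd.Series(self.y).value_counts()
        rare = counts[counts < k]
        if not rare.empty:
            raise ValueError(
                f"classes {rare.index.tolist()} have fewer than k={k} members; "
                "merge classes or use more data"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=self.seed)
        return list(skf.split(self.X, self.y))

    # ------------------------------------------------------------- iterations
    def select_iterations(self, params: "dict | None" = None) -> int:
        """Fix the boosting iteration count by early stopping.

        Holds out one stratified fold (20%), trains with up to
        ``_MAX_ITERATIONS`` rounds and patience 50 on validation multiclass
        log-loss, and returns the best iteration.
        """
        params = dict(DEFAULT_PARAMS if params is None else params)
        train_idx, val_idx = self.stratified_folds(k=5)[0]
        booster = _make_booster(params, _MAX_ITERATIONS, self.seed)
        booster.fit(
            self.X.iloc[train_idx],
            self.y[train_idx],
            eval_set=[(self.X.iloc[val_idx], self.y[val_idx])],
            eval_metric="multi_logloss",
            callbacks=[
                lgb.early_stopping(_EARLY_STOPPING_PATIENCE, verbose=False)
            ],
        )
        best = booster.best_iteration_ or _MAX_ITERATIONS
        return int(best)

    # ------------------------------------------------------------------- fits
    def _cv_metrics(self, params: dict, n_estimators: int, folds) -> list[dict]:
        reports = []
        for train_idx, val_idx in folds:
            booster = _make_booster(params, n_estimators, self.seed)
            booster.fit(self.X.iloc[train_idx], self.y[train_idx])
            pred = booster.predict(self.X.iloc[val_idx])
            rep = evaluate(self.y[val_idx], pred, classes=self.classes_)
            rep.pop("confusion_matrix")
            reports.append(rep)
        return reports

    def fit(
        self,
        params: "dict | None" = None,
        n_estimators: "int | None" = None,
        k: int = 5,
        cross_validate: bool = True,
    ) -> "VariantClassifierResults":
        """Fit with a single hyperparameter setting.

        Runs stratified k-fold CV for the report (unless disabled), then
        refits on all data.  ``n_estimators=None`` selects the iteration count
        by early stopping first.
        """
        params = dict(DEFAULT_PARAMS if params is None else params)
        if self.class_weighting:
            params["class_weight"] = "balanced"
        if n_estimators is None:
            n_estimators = self.select_iterations(params)
        cv_report = (
            self._cv_metrics(params, n_estimators, self.stratified_folds(k))
            if cross_validate
            else []
        )
        booster = _make_booster(params, n_estimators, self.seed)
        booster.fit(self.X, self.y)
        return VariantClassifierResults(
            model=self,
            booster=booster,
            params=params,
            n_estimators=int(n_estimators),
            cv_report=cv_report,
        )

    def grid_search(
        self,
        grid: "dict | None" = None,
        k: int = 5,
        n_estimators: "int | None" = None,
    ) -> "VariantClassifierResults":
        """Scan a hyperparameter grid by mean stratified-CV accuracy.

        The iteration count is fixed first on the default setting (early
        stopping), then every grid point is scored on the same k folds; the
        best setting (ties broken by grid order) is refitted on all data.  The
        full scan is kept on the results object.
        """
        grid = dict(DEFAULT_GRID if grid is None else grid)
        if not grid or any(len(v) == 0 for v in grid.values()):
            raise ValueError("hyperparameter grid is empty")
        if n_estimators is None:
            n_estimators = self.select_iterations()
        folds = self.stratified_folds(k)
        keys = list(grid)
        combos = [{}]
        for key in keys:
            combos = [{**c, key: v} for c in combos for v in grid[key]]
        scan_rows = []
        best = None
        for combo in combos:
            params = dict(combo)
            if self.class_weighting:
                params["class_weight"] = "balanced"
            reports = self._cv_metrics(params, n_estimators, folds)
            mean_acc = float(np.mean([r["accuracy"] for r in reports]))
            scan_rows.append({**combo, "mean_cv_accuracy": mean_acc})
            if best is None or mean_acc > best[0]:
                best = (mean_acc, params, reports)
        _, best_params, best_reports = best
        booster = _make_booster(best_params, n_estimators, self.seed)
        booster.fit(self.X, self.y)
        return VariantClassifierResults(
            model=self,
            booster=booster,
            params=best_params,
            n_estimators=int(n_estimators),
            cv_report=best_reports,
            grid_scan=pd.DataFrame(scan_rows),
        )

    # -------------------------------------------------------------- baselines
    def null_model(self) -> "VariantClassifierResults":
        """Most-frequent-class baseline (ties: lexicographically first label)."""
        dummy = DummyClassifier(strategy="prior")
        dummy.fit(self.X, self.y)
        reports = []
        for train_idx, val_idx in self.stratified_folds(5):
            d = DummyClassifier(strategy="prior").fit(
                self.X.iloc[train_idx], self.y[train_idx]
            )
            rep = evaluate(self.y[val_idx], d.predict(self.X.iloc[val_idx]),
                           classes=self.classes_)
            rep.pop("confusion_matrix")
            reports.append(rep)
        return VariantClassifierResults(
            model=self, booster=dummy, params={"strategy": "prior"},
            n_estimators=0, cv_report=reports,
        )

    def random_forest(
        self, params: "dict | None" = None, k: int = 5
    ) -> "VariantClassifierResults":
        """Random-forest comparator evaluated on the same stratified folds."""
        params = dict(params or {"n_estimators": 300, "max_depth": None})
        reports = []
        for train_idx, val_idx in self.stratified_folds(k):
            rf = RandomForestClassifier(random_state=self.seed, n_jobs=1, **params)
            rf.fit(self.X.iloc[train_idx], self.y[train_idx])
            rep = evaluate(self.y[val_idx], rf.predict(self.X.iloc[val_idx]),
                           classes=self.classes_)
            rep.pop("confusion_matrix")
            reports.append(rep)
        rf = RandomForestClassifier(random_state=self.seed, n_jobs=1, **params)
        rf.fit(self.X, self.y)
        return VariantClassifierResults(
            model=self, booster=rf, params=params, n_estimators=0,
            cv_report=reports,
        )


@dataclass
class VariantClassifierResults:
    """Fitted classifier plus hyperparameters and CV diagnostics."""

    model: VariantClassifierModel
    booster: object
    params: dict
    n_estimators: int
    cv_report: list = field(default_factory=list)
    grid_scan: "pd.DataFrame | None" = None

    @property
    def classes_(self) -> list:
        return list(self.booster.classes_)

    def cv_summary(self) -> dict:
        """Mean CV accuracy / MCC over folds (empty dict when CV was skipped)."""
        if not self.cv_report:
            return {}
        return {
            "mean_cv_accuracy": float(
                np.mean([r["accuracy"] for r in self.cv_report])
            ),
            "mean_cv_mcc": float(np.mean([r["mcc"] for r in self.cv_report])),
            "n_folds": len(self.cv_report),
        }

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Class call and 4-class probability vector per complete row.

        ``features`` must contain the training feature columns by name (no
        positional matching); rows flagged incomplete (or with missing
        values) are returned with class ``unpredicted`` and NaN probabilities.
        """
        missing = [f for f in self.model.feature_names if f not in features.columns]
        if missing:
            raise ValueError(
                f"feature columns {missing} absent; the feature contract is "
                f"{list(self.model.feature_names)}"
            )
        X = features[list(self.model.feature_names)].astype(float).reset_index(drop=True)
        ok = np.isfinite(X.to_numpy()).all(axis=1)
        if "complete" in features.columns:
            ok &= features["complete"].to_numpy(dtype=bool)
        id_cols = [
            c for c in ("position", "wt_aa", "target_aa") if c in features.columns
        ]
        out = features[id_cols].copy().reset_index(drop=True)
        proba = np.full((len(out), len(self.classes_)), np.nan)
        if ok.any():
            proba[ok] = self.booster.predict_proba(X[ok])
        pred = np.where(
            ok,
            np.asarray(self.classes_, dtype=object)[
                np.nan_to_num(proba, nan=-1.0).argmax(axis=1)
            ],
            "unpredicted",
        )
        out["predicted_class"] = pred
        for j, cls in enumerate(self.classes_):
            out[f"prob_{cls}"] = proba[:, j]
        return out

    def evaluate(self, features: pd.DataFrame, truth) -> dict:
        pred = self.predict(features)
        ok = pred["predicted_class"] != "unpredicted"
        truth = np.asarray([getattr(t, "value", t) for t in truth], dtype=object)
        report = evaluate(truth[ok.to_numpy()], pred.loc[ok, "predicted_class"])
        report["n_unpredicted"] = int((~ok).sum())
        return report

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Variant classifier (gradient-boosted trees)",
            "=" * 47,
            f"n variants        {len(self.model.y)}",
            f"classes           {', '.join(self.model.classes_)}",
            f"features          {', '.join(self.model.feature_names)}",
            f"iterations        {self.n_estimators}",
            f"hyperparameters   {json.dumps({k: v for k, v in self.params.items() if k != 'class_weight'})}",
            f"seed              {self.model.seed}",
        ]
        cv = self.cv_summary()
        if cv:
            lines += [
                "-" * 47,
                f"CV accuracy       {cv['mean_cv_accuracy']:.3f} "
                f"({cv['n_folds']} folds)",
                f"CV MCC            {cv['mean_cv_mcc']:.3f}",
            ]
        if self.grid_scan is not None:
            lines += ["-" * 47, f"grid points scanned  {len(self.grid_scan)}"]
        return "\n".join(lines)

    # ------------------------------------------------------------ persistence
    def manifest(self) -> dict:
        return {
            "feature_names": list(self.model.feature_names),
            "classes": self.classes_,
            "params": {k: v for k, v in self.params.items()},
            "n_estimators": self.n_estimators,
            "seed": self.model.seed,
            "n_training_rows": int(len(self.model.y)),
            "cv": self.cv_summary(),
        }

    def save(self, path) -> None:
        """Single-file bundle: serialized booster + JSON manifest."""
        joblib.dump({"booster": self.booster, "manifest": self.manifest()}, path)

    @classmethod
    def load(cls, path) -> "VariantClassifierResults":
        bundle = joblib.load(path)
        manifest = bundle["manifest"]
        dummy_features = pd.DataFrame(
            np.zeros((1, len(manifest["feature_names"]))),
            columns=manifest["feature_names"],
        )
        model = VariantClassifierModel(
            dummy_features,
            [manifest["classes"][0]],
            feature_names=manifest["feature_names"],
            seed=manifest["seed"],
        )
        return cls(
            model=model,
            booster=bundle["booster"],
            params=manifest["params"],
            n_estimators=manifest["n_estimators"],
        )
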