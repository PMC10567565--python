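"""Taxonomy prediction from colony morphology and targeted-isolation scoring.

A multiclass random forest is trained on the 14 morphology features plus the
antibiotic condition (one-hot) and the nearby-colony count, on a stratified
70% split, and evaluated on the held-out 30%. Training and evaluation are
bootstrapped (default 20 resplits) and compared against a frequency null
model whose per-genus precision equals that genus's share of all isolates.
The fitted model can screen new plates for colonies of a target genus; the
value of such targeted picking is summarised as precision over base rate
(fold improvement).
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .imaging import MORPHOLOGY_FEATURES

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1
FEATURE_COLUMNS = MORPHOLOGY_FEATURES + ["condition", "n_neighbors"]
MIN_GENUS_COUNT = 100  # data-rich genus floor for pooled models
MIN_GENUS_COUNT_INDIVIDUAL = 15  # floor for per-individual targeted models


def _validate_table(table: pd.DataFrame, min_genus_count: int) -> None:
    missing = [c for c in FEATURE_COLUMNS + ["genus"] if c not in table.columns]
    if missing:
        raise KeyError(f"training table missing column(s): {missing}")
    if table[FEATURE_COLUMNS].isna().any().any():
        raise ValueError("training table has missing feature values")
    counts = table["genus"].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 genera to train a classifier")
    poor = counts[counts < min_genus_count]
    if len(poor):
        raise ValueError(
            f"genera below the minimum isolate count ({min_genus_count}): "
            f"{dict(poor)}"
        )


@dataclass
class MorphologyModel:
    """Fitted forest plus the encoding needed to featurize new colonies."""

    forest: RandomForestClassifier
    condition_levels: list[str]
    classes: list[str]
    format_version: int = MODEL_FORMAT_VERSION

    def featurize(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
        if missing:
            raise KeyError(f"colony table missing feature column(s): {missing}")
        X = table[MORPHOLOGY_FEATURES + ["n_neighbors"]].to_numpy(dtype=float)
        onehot = np.column_stack(
            [
                (table["condition"].astype(str) == lvl).to_numpy(dtype=float)
                for lvl in self.condition_levels
            ]
        )
        return np.hstack([X, onehot])

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(self.featurize(table))

    def predict_proba(self, table: pd.DataFrame) -> pd.DataFrame:
        proba = self.forest.predict_proba(self.featurize(table))
        return pd.DataFrame(proba, columns=self.forest.classes_, index=table.index)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(
                {
                    "format_version": self.format_version,
                    "forest": self.forest,
                    "condition_levels": self.condition_levels,
                    "classes": self.classes,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "MorphologyModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {blob.get('format_version')}"
            )
        return cls(
            forest=blob["forest"],
            condition_levels=blob["condition_levels"],
            classes=blob["classes"],
        )


def train_model(
    table: pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 500,
    min_genus_count: int = MIN_GENUS_COUNT,
) -> MorphologyModel:
    """Fit the multiclass random forest on the full table."""
    _validate_table(table, min_genus_count)
    levels = sorted(table["condition"].astype(str).unique())
    model = MorphologyModel(
        forest=RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(seed) % 2**31, n_jobs=1
        ),
        condition_levels=levels,
        classes=sorted(table["genus"].unique()),
    )
    model.forest.fit(model.featurize(table), table["genus"].to_numpy())
    return model


def null_precision(table: pd.DataFrame) -> pd.Series:
    """Frequency null: each genus's precision equals its isolate share."""
    freq = table["genus"].value_counts(normalize=True)
    freq.name = "null_precision"
    return freq.sort_index()


@dataclass
class EvaluationReport:
    metrics: pd.DataFrame  # columns: genus, repeat, precision, recall (NaN = missing)
    null_precision: pd.Series
    n_bootstraps: int

    def summary(self) -> pd.DataFrame:
        g = self.metrics.groupby("genus")
        out = pd.DataFrame(
            {
                "precision_median": g["precision"].median(),
                "precision_mean": g["precision"].mean(),
                "precision_sd": g["precision"].std(),
                "recall_median": g["recall"].median(),
            }
        )
        out["null_precision"] = self.null_precision
        return out


def bootstrap_evaluate(
    table: pd.DataFrame,
    n_boot: int = 20,
    train_frac: float = 0.7,
    seed: int = 0,
    n_estimators: int = 500,
    min_genus_count: int = MIN_GENUS_COUNT,
) -> EvaluationReport:
    """Repeated stratified resplit -> fit -> held-out per-genus precision/recall.

    A genus absent from a test split, or never predicted in it, has its
    metric recorded as missing (NaN) for that repeat, never as zero.
    """
    _validate_table(table, min_genus_count)
    rng = np.random.default_rng(seed)
    genera = sorted(table["genus"].unique())
    rows = []
    for rep in range(n_boot):
        rs = int(rng.integers(0, 2**31 - 1))
        train, test = train_test_split(
            table,
            train_size=train_frac,
            stratify=table["genus"],
            random_state=rs,
        )
        model = train_model(
            train, seed=rs, n_estimators=n_estimators, min_genus_count=1
        )
        pred = model.predict(test)
        truth = test["genus"].to_numpy()
        for g in genera:
            predicted_g = pred == g
            actual_g = truth == g
            precision = (
                float((predicted_g & actual_g).sum() / predicted_g.sum())
                if predicted_g.any()
                else np.nan
            )
            recall = (
                float((predicted_g & actual_g).sum() / actual_g.sum())
                if actual_g.any()
                else np.nan
            )
            rows.append((g, rep, precision, recall))
    metrics = pd.DataFrame(rows, columns=["genus", "repeat", "precision", "recall"])
    return EvaluationReport(metrics, null_precision(table), n_boot)


def predict_targets(
    model: MorphologyModel,
    colonies: pd.DataFrame,
    target: str,
    probability_threshold: float | None = None,
) -> pd.DataFrame:
    """Colonies predicted to be the target genus, ordered by probability.

    Decision is by maximum class probability; an optional threshold
    additionally requires P(target) >= threshold. Returns a table of
    (colony_id if present, probability), descending.
    """
    proba = model.predict_proba(colonies)
    if target not in proba.columns:
        return pd.DataFrame(columns=["colony_id", "probability"])
    is_target = proba.idxmax(axis=1) == target
    if probability_threshold is not None:
        is_target &= proba[target] >= probability_threshold
    hits = proba.loc[is_target, target].sort_values(ascending=False)
    out = pd.DataFrame({"probability": hits})
    if "colony_id" in colonies.columns:
        out.insert(0, "colony_id", colonies.loc[hits.index, "colony_id"])
    else:
        out.insert(0, "colony_id", hits.index.astype(str))
    return out.reset_index(drop=True)


@dataclass
class TargetedPrecision:
    precision: float  # NaN when no predictions were made
    base_rate: float
    fold_improvement: float  # NaN when base_rate == 0 or precision undefined
    n_predicted: int
    undefined: bool


def targeted_precision(
    predicted_ids, true_labels, target: str
) -> TargetedPrecision:
    """Precision of a targeted pick set against true labels, vs the base rate."""
    labels = pd.Series(true_labels)
    predicted_ids = list(predicted_ids)
    missing = [i for i in predicted_ids if i not in labels.index]
    if missing:
        raise ValueError(f"predicted colonies without true labels: {missing[:5]}")
    base_rate = float((labels == target).mean())
    if len(predicted_ids) == 0:
        logger.warning("empty prediction set; targeted precision undefined")
        return TargetedPrecision(np.nan, base_rate, np.nan, 0, True)
    precision = float((labels.loc[predicted_ids] == target).mean())
    if base_rate == 0:
        logger.warning("base rate is zero; fold improvement undefined")
        return TargetedPrecision(precision, 0.0, np.nan, len(predicted_ids), True)
    return TargetedPrecision(
        precision, base_rate, precision / base_rate, len(predicted_ids), False
    )
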