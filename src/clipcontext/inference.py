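"""Two-class alcohol inference task.

For each data source and coarse location type, a random-forest classifier
predicts "drinking alcohol" vs "drinking no alcohol" from the three context
ratings plus prior drinks.  The minority class is oversampled (duplication
with replacement) to balance the classes, and accuracy is estimated by
stratified 10-fold cross-validation repeated for 10 iterations.

Two protocols are provided.  ``paper_mode`` oversamples the full dataset
first and then cross-validates, which lets duplicated minority rows appear
in both a training and a test fold; ``leakage_safe`` (the default)
oversamples inside each training fold only, so reported accuracy is an
honest out-of-sample estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from clipcontext.config import COARSE_LEVELS, SOURCES

_SOURCE_PREFIX = {"participants": "p", "annotators": "a", "algorithms": "g"}


@dataclass
class InferenceReport:
    """Cross-validated accuracy for one (source, location) stratum."""

    source: str
    location: str
    fold_accuracies: np.ndarray  # (iterations, folds)
    n_before: int
    n_after: int
    n_trees: int
    mode: str
    seed: int
    error: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean()) if self.fold_accuracies.size else np.nan


def oversample_minority(X, y, seed: int = 0):
    """Duplicate minority-class rows (sampled with replacement) to balance.

    The majority class is untouched; every added row is an exact copy of an
    original minority row.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need two classes to oversample")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    idx = np.flatnonzero(y == minority)
    extra = rng.choice(idx, size=deficit, replace=True)
    return np.concatenate([X, X[extra]]), np.concatenate([y, y[extra]])


def cv_inference(
    X,
    y,
    n_trees: int = 300,
    folds: int = 10,
    iterations: int = 10,
    mode: str = "leakage_safe",
    seed: int = 0,
    source: str = "",
    location: str = "",
) -> InferenceReport:
    """Repeated stratified k-fold cross-validated random-forest accuracy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if mode not in ("leakage_safe", "paper_mode"):
        raise ValueError("mode must be 'leakage_safe' or 'paper_mode'")
    if y.size < 50:
        raise ValueError("need at least 50 observations")
    if np.unique(y).size < 2:
        raise ValueError("need two classes")
    n_before = y.size
    accs = np.zeros((iterations, folds))
    rng = np.random.default_rng(seed)
    n_after = n_before
    for it in range(iterations):
        it_seed = int(rng.integers(2**31 - 1))
        if mode == "paper_mode":
            Xb, yb = oversample_minority(X, y, seed=it_seed)
        else:
            Xb, yb = X, y
        n_after = yb.size
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=it_seed % (2**31))
        for f, (tr, te) in enumerate(skf.split(Xb, yb)):
            Xtr, ytr = Xb[tr], yb[tr]
            if mode == "leakage_safe":
                Xtr, ytr = oversample_minority(Xtr, ytr, seed=it_seed + f + 1)
            clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=(it_seed + f) % (2**31), n_jobs=1
            )
            clf.fit(Xtr, ytr)
            accs[it, f] = float(np.mean(clf.predict(Xb[te]) == yb[te]))
    return InferenceReport(
        source=source,
        location=location,
        fold_accuracies=accs,
        n_before=n_before,
        n_after=n_after,
        n_trees=n_trees,
        mode=mode,
        seed=seed,
    )


def inference_report(
    source_table: pd.DataFrame,
    n_trees: int = 300,
    mode: str = "leakage_safe",
    seed: int = 0,
    iterations: int = 10,
    folds: int = 10,
    sources=SOURCES,
) -> list[InferenceReport]:
    """Run the inference task for all 3 sources x 3 coarse locations."""
    reports = []
    for si, source in enumerate(sources):
        pre = _SOURCE_PREFIX[source]
        for li, coarse in enumerate(COARSE_LEVELS):
            sub = source_table[source_table["location_coarse"] == coarse]
            stratum_seed = (seed + 1000 * si + 100 * li) % (2**31)
            try:
                X = sub[
                    [f"{pre}_brightness", f"{pre}_loudness", f"{pre}_attendance", "prior_drinks"]
                ].to_numpy(dtype=float)
                rep = cv_inference(
                    X,
                    sub["alcohol"].to_numpy(),
                    n_trees=n_trees,
                    mode=mode,
                    seed=stratum_seed,
                    source=source,
                    location=coarse,
                    iterations=iterations,
                    folds=folds,
                )
            except ValueError as exc:
                rep = InferenceReport(
                    source=source,
                    location=coarse,
                    fold_accuracies=np.zeros((0, 0)),
                    n_before=len(sub),
                    n_after=len(sub),
                    n_trees=n_trees,
                    mode=mode,
                    seed=stratum_seed,
                    error=str(exc),
                )
            reports.append(rep)
    return reports


def reports_to_frame(reports: list[InferenceReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source": r.source,
                "location": r.location,
                "accuracy": r.mean_accuracy,
                "n_before": r.n_before,
                "n_after": r.n_after,
                "n_trees": r.n_trees,
                "mode": r.mode,
                "seed": r.seed,
                "error": r.error,
            }
            for r in reports
        ]
    )
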