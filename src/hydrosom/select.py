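"""Three-stage univariate feature selection, fitted on training rows only.

Stage order is fixed: (1) drop exactly the zero-variance columns, (2) keep
the ceil(50%) of survivors with the highest ANOVA F statistic, (3) keep
survivors whose two-sided Welch t-test p-value is below 0.05.  Each stage
selects from the previous stage's survivors; the fitted pipeline stores
the retained column indices into the original feature vector and is frozen
for test-time and inference use.

Ties at the F cutoff break toward the lower column index so a fit is a
pure function of (matrix, labels).  Binary fingerprint bits pass through
the same numeric tests as continuous descriptors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.feature_selection import f_classif


class SelectorError(ValueError):
    pass


@dataclass
class SelectorPipeline:
    """Fitted cascade; ``retained_indices`` index the original columns."""

    n_features_in: int
    variance_mask: np.ndarray  # bool over original columns
    f_mask: np.ndarray         # bool over original columns, subset of variance_mask
    t_mask: np.ndarray         # bool over original columns, subset of f_mask
    keep_fraction: float = 0.5
    alpha: float = 0.05
    fitted: bool = True
    metadata: dict = field(default_factory=dict)

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.t_mask)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_features_in": self.n_features_in,
            "keep_fraction": self.keep_fraction,
            "alpha": self.alpha,
            "variance_mask": np.flatnonzero(self.variance_mask).tolist(),
            "f_mask": np.flatnonzero(self.f_mask).tolist(),
            "t_mask": np.flatnonzero(self.t_mask).tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(doc), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectorPipeline":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        n = int(doc["n_features_in"])

        def mask(key):
            m = np.zeros(n, dtype=bool)
            m[np.asarray(doc[key], dtype=int)] = True
            return m

        return cls(
            n_features_in=n,
            variance_mask=mask("variance_mask"),
            f_mask=mask("f_mask"),
            t_mask=mask("t_mask"),
            keep_fraction=float(doc["keep_fraction"]),
            alpha=float(doc["alpha"]),
            metadata=doc.get("metadata", {}),
        )


def _as_binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise SelectorError(f"need exactly 2 classes, got {list(classes)}")
    return y == classes[1]


def fit_selector(
    features: np.ndarray,
    labels,
    keep_fraction: float = 0.5,
    alpha: float = 0.05,
) -> SelectorPipeline:
    """Fit the variance -> ANOVA-F -> Welch-t cascade on training data."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 4:
        raise SelectorError("need a 2-D matrix with >= 4 rows")
    if not np.all(np.isfinite(X)):
        raise SelectorError("features must be finite")
    pos = _as_binary_labels(labels)
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise SelectorError("need >= 2 samples in each class")
    n_cols = X.shape[1]

    # stage 1: exact zero-variance removal
    variance_mask = ~np.all(X == X[0, :], axis=0)
    surv1 = np.flatnonzero(variance_mask)
    if surv1.size == 0:
        raise SelectorError("all features are constant")

    # stage 2: top ceil(keep_fraction) by ANOVA F, ties to lower index
    F, _ = f_classif(X[:, surv1], pos)
    F = np.where(np.isfinite(F), F, np.inf * (F > 0))  # inf kept, nan -> 0
    F = np.nan_to_num(F, nan=0.0)
    k = math.ceil(keep_fraction * surv1.size)
    order = np.lexsort((np.arange(surv1.size), -F))  # F desc, then index asc
    keep2 = np.sort(surv1[order[:k]])
    f_mask = np.zeros(n_cols, dtype=bool)
    f_mask[keep2] = True

    # stage 3: two-sided Welch t-test, p < alpha
    a, b = X[pos][:, keep2], X[~pos][:, keep2]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    keep3 = keep2[p < alpha]
    t_mask = np.zeros(n_cols, dtype=bool)
    t_mask[keep3] = True

    if keep3.size == 0:
        raise SelectorError("no informative features survive the cascade")
    return SelectorPipeline(
        n_features_in=n_cols,
        variance_mask=variance_mask,
        f_mask=f_mask,
        t_mask=t_mask,
        keep_fraction=keep_fraction,
        alpha=alpha,
        metadata={"n_retained": int(keep3.size)},
    )


def apply_selector(pipeline: SelectorPipeline, features: np.ndarray) -> np.ndarray:
    """Project a feature matrix onto the retained columns (order preserved)."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != pipeline.n_features_in:
        raise SelectorError(
            f"expected {pipeline.n_features_in} columns, got "
            f"{X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    return X[:, pipeline.retained_indices]
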