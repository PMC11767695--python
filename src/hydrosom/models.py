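"""Site-classifier training: pre-training, tuning, final selection, serving.

The workflow mirrors a standard tabular-ML protocol: eight classifier
families are pre-trained with stratified k-fold cross-validation on the
training atoms of a dataset, the top five by mean CV accuracy move on to a
random search over per-family hyperparameter spaces (the default
configuration is always candidate 0), and the final model per dataset is
the tuned candidate with the best held-out test MCC (accuracy breaks
ties).  A fitted bundle couples the frozen feature selector with the
classifier and can score every tracked heavy atom of a query molecule
with a hydrolysis-site probability.

Class imbalance is left untouched: rarity of hydrolysis sites is real
signal, not sampling bias.  A ``class_weight`` switch exists for the
families that support it but defaults to off.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import ParameterSampler, StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from . import __version__ as _pkg_version
from .chem import ELEMENT_CLASS, mol_from_smiles
from .corpus import GLOBAL_CLASSES, DatasetSplit
from .features import FEATURE_VERSION, N_FEATURES, featurize, featurize_table
from .select import SelectorPipeline, apply_selector, fit_selector

#: fixed family order; doubles as the deterministic tie-break order.
FAMILY_ORDER = ("lightgbm", "rf", "dt", "et", "lda", "ada", "qda", "gbc")

_SEARCH_SPACES: dict[str, object] = {
    "dt": {
        "max_depth": [None, 3, 5, 8, 12, 20],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [1, 2, 5],
        "criterion": ["gini", "entropy"],
    },
    "rf": {
        "n_estimators": [50, 100, 200, 300],
        "max_depth": [None, 5, 10, 20],
        "max_features": ["sqrt", "log2", None],
        "min_samples_leaf": [1, 2, 5],
    },
    "et": {
        "n_estimators": [50, 100, 200, 300],
        "max_depth": [None, 5, 10, 20],
        "max_features": ["sqrt", "log2", None],
        "min_samples_leaf": [1, 2, 5],
    },
    # learning-rate grid spans 1.0 down to 0.05 and tree counts up to 300,
    # covering the slow-learning/deep-ensemble corner where boosting gains.
    "gbc": {
        "learning_rate": [1.0, 0.5, 0.3, 0.15, 0.1, 0.05],
        "n_estimators": [50, 100, 150, 200, 230, 300],
        "max_depth": [2, 3, 5],
        "subsample": [1.0, 0.8],
    },
    "lightgbm": {
        "n_estimators": [50, 100, 200, 300],
        "learning_rate": [0.3, 0.1, 0.05],
        "num_leaves": [15, 31, 63],
        "min_child_samples": [5, 10, 20],
    },
    "ada": {
        "n_estimators": [50, 100, 200, 300],
        "learning_rate": [1.0, 0.5, 0.1],
    },
    "lda": [
        {"solver": ["svd"]},
        {"solver": ["lsqr"], "shrinkage": [None, "auto", 0.1, 0.5]},
    ],
    "qda": {"reg_param": [1e-4, 1e-3, 1e-2, 0.1, 0.5]},
}


class ModelError(ValueError):
    pass


def make_classifier(family: str, seed: int, params: dict | None = None, class_weight=None):
    """Instantiate one classifier family with optional hyperparameters."""
    params = dict(params or {})
    if family == "dt":
        clf = DecisionTreeClassifier(random_state=seed, class_weight=class_weight, **params)
    elif family == "rf":
        clf = RandomForestClassifier(
            random_state=seed, n_jobs=1, class_weight=class_weight, **params
        )
    elif family == "et":
        clf = ExtraTreesClassifier(
            random_state=seed, n_jobs=1, class_weight=class_weight, **params
        )
    elif family == "gbc":
        clf = GradientBoostingClassifier(random_state=seed, **params)
    elif family == "lightgbm":
        from lightgbm import LGBMClassifier

        clf = LGBMClassifier(
            random_state=seed,
            n_jobs=1,
            verbose=-1,
            deterministic=True,
            force_row_wise=True,
            class_weight=class_weight,
            **params,
        )
    elif family == "ada":
        clf = AdaBoostClassifier(random_state=seed, **params)
    elif family == "lda":
        clf = LinearDiscriminantAnalysis(**params)
    elif family == "qda":
        # binary fingerprint bits are heavily collinear; an unregularised
        # class covariance is rank-deficient, so ridge by default
        params.setdefault("reg_param", 1e-3)
        clf = QuadraticDiscriminantAnalysis(**params)
    else:
        raise ModelError(f"unknown model family {family!r}")
    return clf


@dataclass
class MetricsReport:
    """Confusion counts and the derived classification metrics.

    Metrics with a zero denominator are reported as 0.0 and named in
    ``flags`` rather than raising.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    recall: float
    precision: float
    mcc: float
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "ACC": self.acc, "Recall": self.recall,
            "Precision": self.precision, "MCC": self.mcc,
            "flags": list(self.flags),
        }


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    """ACC, recall, precision and MCC from integer confusion counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), computed
    in exact integer arithmetic before the final square root.
    """
    for name, v in (("TP", tp), ("TN", tn), ("FP", fp), ("FN", fn)):
        if v < 0 or int(v) != v:
            raise ModelError(f"{name} must be a non-negative integer, got {v!r}")
    tp, tn, fp, fn = int(tp), int(tn), int(fp), int(fn)
    total = tp + tn + fp + fn
    if total == 0:
        raise ModelError("all confusion counts are zero")
    flags = []
    acc = (tp + tn) / total
    if tp + fn == 0:
        recall = 0.0
        flags.append("recall_undefined")
    else:
        recall = tp / (tp + fn)
    if tp + fp == 0:
        precision = 0.0
        flags.append("precision_undefined")
    else:
        precision = tp / (tp + fp)
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        mcc = 0.0
        flags.append("mcc_undefined")
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom_sq)
    return MetricsReport(tp, tn, fp, fn, acc, recall, precision, mcc, tuple(flags))


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    return compute_metrics(
        tp=int((y_true & y_pred).sum()),
        tn=int((~y_true & ~y_pred).sum()),
        fp=int((~y_true & y_pred).sum()),
        fn=int((y_true & ~y_pred).sum()),
    )


@dataclass
class PreparedDataset:
    """A featurized, selector-reduced train/test split ready for fitting."""

    dataset_name: str
    split: DatasetSplit
    selector: SelectorPipeline
    X_train: np.ndarray   # selector-reduced
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


def prepare_dataset(split: DatasetSplit) -> PreparedDataset:
    """Featurize a split and fit the feature selector on the training rows.

    Test rows never touch the selector fit; they are only projected.
    """
    X_train_full = featurize_table(split.train_rows)
    X_test_full = featurize_table(split.test_rows)
    y_train = (split.train_rows["label"] == "SOM+").to_numpy()
    y_test = (split.test_rows["label"] == "SOM+").to_numpy()
    selector = fit_selector(X_train_full, y_train)
    return PreparedDataset(
        dataset_name=split.dataset_name,
        split=split,
        selector=selector,
        X_train=apply_selector(selector, X_train_full),
        y_train=y_train,
        X_test=apply_selector(selector, X_test_full),
        y_test=y_test,
    )


def _as_prepared(dataset) -> PreparedDataset:
    return dataset if isinstance(dataset, PreparedDataset) else prepare_dataset(dataset)


def _cv_accuracy(clf, X, y, folds: int, seed: int) -> float:
    counts = np.bincount(y.astype(int))
    if counts.min() < folds:
        raise ModelError(
            f"cannot stratify {folds} folds: minority class has {counts.min()} rows"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy", n_jobs=1)
    return float(np.mean(scores))


def pretrain(dataset, families=FAMILY_ORDER, folds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Mean stratified-CV accuracy of each family on the training atoms."""
    prep = _as_prepared(dataset)
    rows = []
    for family in families:
        clf = make_classifier(family, seed)
        rows.append((family, _cv_accuracy(clf, prep.X_train, prep.y_train, folds, seed)))
    return pd.DataFrame(rows, columns=["family", "cv_accuracy"])


def select_top(cv_table: pd.DataFrame, n: int = 5) -> list[str]:
    """The n best families by CV accuracy; ties break in FAMILY_ORDER."""
    if len(cv_table) < n:
        raise ModelError(f"need >= {n} families, got {len(cv_table)}")
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}
    ranked = sorted(
        cv_table.itertuples(index=False),
        key=lambda r: (-r.cv_accuracy, order.get(r.family, len(order))),
    )
    return [r.family for r in ranked[:n]]


@dataclass
class TunedCandidate:
    family: str
    params: dict
    cv_accuracy: float


def tune(
    family: str,
    dataset,
    n_configs: int = 50,
    folds: int = 10,
    seed: int = 0,
) -> TunedCandidate:
    """Random search over the family's space; best config by mean CV accuracy.

    Candidate 0 is always the default configuration, so the tuned score can
    never fall below the untuned one.  Sampling is seeded and therefore
    reproducible.
    """
    if family not in _SEARCH_SPACES:
        raise ModelError(f"no search space for family {family!r}")
    prep = _as_prepared(dataset)
    candidates: list[dict] = [{}]
    if n_configs > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sampler warns when grid < n_iter
            sampler = ParameterSampler(
                _SEARCH_SPACES[family], n_iter=n_configs - 1, random_state=seed
            )
            candidates.extend(dict(c) for c in sampler)
    best: TunedCandidate | None = None
    for i, params in enumerate(candidates):
        clf = make_classifier(family, seed, params)
        score = _cv_accuracy(clf, prep.X_train, prep.y_train, folds, seed)
        if best is None or score > best.cv_accuracy:
            best = TunedCandidate(family=family, params=params, cv_accuracy=score)
    return best


@dataclass
class ModelBundle:
    """A frozen selector + classifier pair for one dataset."""

    dataset_name: str
    family: str
    selector: SelectorPipeline
    classifier: object
    hyperparameters: dict
    metadata: dict = field(default_factory=dict)

    @property
    def atom_classes(self) -> tuple[str, ...]:
        if self.dataset_name == "Global-Hydrolysis":
            return GLOBAL_CLASSES
        return (self.dataset_name[0],)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.selector.to_json(d / "selector.json")
        joblib.dump(self.classifier, d / "model.joblib")
        meta = dict(self.metadata)
        meta.update(
            dataset_name=self.dataset_name,
            family=self.family,
            hyperparameters=self.hyperparameters,
            feature_version=FEATURE_VERSION,
            package_version=_pkg_version,
        )
        (d / "metadata.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text(encoding="utf-8"))
        if meta.get("feature_version") != FEATURE_VERSION:
            raise ModelError(
                f"bundle feature version {meta.get('feature_version')!r} does not "
                f"match this installation ({FEATURE_VERSION!r}); retrain"
            )
        return cls(
            dataset_name=meta["dataset_name"],
            family=meta["family"],
            selector=SelectorPipeline.from_json(d / "selector.json"),
            classifier=joblib.load(d / "model.joblib"),
            hyperparameters=meta.get("hyperparameters", {}),
            metadata=meta,
        )


def finalize(dataset, tuned: list[TunedCandidate], seed: int = 0) -> tuple[ModelBundle, pd.DataFrame]:
    """Fit tuned candidates on the training rows and pick the test winner.

    Winner by test MCC, then test accuracy, then FAMILY_ORDER.  The full
    test metrics of every candidate are returned for reporting.
    """
    if not tuned:
        raise ModelError("no tuned candidates")
    prep = _as_prepared(dataset)
    rows = []
    fitted = {}
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}
    for cand in tuned:
        clf = make_classifier(cand.family, seed, cand.params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(prep.X_train, prep.y_train.astype(int))
            y_pred = clf.predict(prep.X_test).astype(bool)
        rep = metrics_from_predictions(prep.y_test, y_pred)
        fitted[cand.family] = (clf, cand, rep)
        rows.append({"family": cand.family, **rep.as_dict()})
    table = pd.DataFrame(rows)
    winner_family = min(
        fitted,
        key=lambda f: (-fitted[f][2].mcc, -fitted[f][2].acc, order.get(f, len(order))),
    )
    clf, cand, rep = fitted[winner_family]
    bundle = ModelBundle(
        dataset_name=prep.dataset_name,
        family=winner_family,
        selector=prep.selector,
        classifier=clf,
        hyperparameters=cand.params,
        metadata={
            "seed": seed,
            "split_seed": prep.split.split_seed,
            "test_metrics": rep.as_dict(),
            "n_train_rows": int(len(prep.y_train)),
            "n_test_rows": int(len(prep.y_test)),
            "n_retained_features": int(prep.selector.retained_indices.size),
        },
    )
    return bundle, table


@dataclass(frozen=True)
class SitePrediction:
    atom_index: int
    element: str
    probability: float
    dataset_name: str
    is_site: bool
    threshold: float


def predict_sites(bundle: ModelBundle, mol_or_smiles, threshold: float = 0.5) -> list[SitePrediction]:
    """Hydrolysis-site probability for every atom of the bundle's classes.

    ``is_site`` is simply ``probability >= threshold``; the default 0.5 is
    a neutral choice and every report records the value used.
    """
    mol = mol_from_smiles(mol_or_smiles) if isinstance(mol_or_smiles, str) else mol_or_smiles
    X_full, atom_indices = featurize(mol, atom_classes=bundle.atom_classes)
    if not atom_indices:
        return []
    X = apply_selector(bundle.selector, X_full)
    clf = bundle.classifier
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        proba = clf.predict_proba(X)
    pos_col = list(clf.classes_).index(1)
    out = []
    for i, idx in enumerate(atom_indices):
        p = float(proba[i, pos_col])
        out.append(
            SitePrediction(
                atom_index=idx,
                element=mol.GetAtomWithIdx(idx).GetSymbol(),
                probability=p,
                dataset_name=bundle.dataset_name,
                is_site=p >= threshold,
                threshold=threshold,
            )
        )
    return out


@dataclass
class TrainResult:
    dataset_name: str
    cv_table: pd.DataFrame
    tuning_log: pd.DataFrame
    candidate_metrics: pd.DataFrame
    bundle: ModelBundle


def train_dataset(
    split: DatasetSplit,
    families=FAMILY_ORDER,
    folds: int = 10,
    n_configs: int = 50,
    top_n: int = 5,
    seed: int = 0,
) -> TrainResult:
    """The full protocol for one dataset: pretrain -> top-n -> tune -> finalize."""
    prep = prepare_dataset(split)
    cv_table = pretrain(prep, families=families, folds=folds, seed=seed)
    top = select_top(cv_table, n=min(top_n, len(cv_table)))
    tuned = [tune(f, prep, n_configs=n_configs, folds=folds, seed=seed) for f in top]
    tuning_log = pd.DataFrame(
        [
            {"family": t.family, "cv_accuracy": t.cv_accuracy, "params": json.dumps(t.params)}
            for t in tuned
        ]
    )
    bundle, cand_metrics = finalize(prep, tuned, seed=seed)
    return TrainResult(
        dataset_name=split.dataset_name,
        cv_table=cv_table,
        tuning_log=tuning_log,
        candidate_metrics=cand_metrics,
        bundle=bundle,
    )
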