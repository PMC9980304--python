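"""Predictive modelling on ROI features: repeated cross-validation,
learner benchmarking, hyperparameter grid search, recursive feature
elimination, and ensembles of gradient-boosted tree models.

The evaluation protocol throughout is stratified five-fold cross-validation
repeated with fresh patient randomization per repeat; performance is the
ROC AUC of the pooled out-of-fold predictions of each repeat.  The final
predictor is an ensemble of boosted-tree models, each trained on a random
patient subset, whose probability predictions are averaged.

All randomness derives from a single ``base_seed``: fold assignment for
repeat r uses ``base_seed + r``, ensemble member i uses ``base_seed + i``,
and the learner itself is seeded per fit, so a run is reproducible from the
seed alone.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from xgboost import XGBClassifier

from evmap.binning import BinningSpec, FeatureMatrix
from evmap.maps import roi_auc

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVSpec:
    """Repeated cross-validation settings."""

    folds: int = 5
    repeats: int = 10
    stratified: bool = True
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class HyperGrid:
    """Value lists per boosted-tree hyperparameter."""

    nrounds: tuple[int, ...] = (50, 100, 150, 200, 250, 300, 400)
    max_depth: tuple[int, ...] = (3, 4, 5, 6)
    eta: tuple[float, ...] = (0.01, 0.1)
    gamma: tuple[float, ...] = (0.0,)
    colsample_bytree: tuple[float, ...] = (1.0,)
    min_child_weight: tuple[float, ...] = (1.0,)
    subsample: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        for name, vals in asdict(self).items():
            if len(vals) == 0:
                raise ValueError(f"empty value list for {name}")

    def combinations(self) -> list[dict]:
        names = list(asdict(self))
        out = []
        for combo in itertools.product(*(getattr(self, n) for n in names)):
            out.append(dict(zip(names, combo)))
        return out

    def __len__(self) -> int:
        return len(self.combinations())


def xgb_classifier(params: Mapping[str, object] | None = None,
                   seed: int = 0) -> XGBClassifier:
    """A deterministic, single-threaded boosted-tree classifier.

    ``params`` uses the grid's naming (nrounds, eta, ...) and is translated
    to the library's argument names.
    """
    p = dict(params or {})
    return XGBClassifier(
        n_estimators=int(p.get("nrounds", 100)),
        max_depth=int(p.get("max_depth", 6)),
        learning_rate=float(p.get("eta", 0.3)),
        gamma=float(p.get("gamma", 0.0)),
        colsample_bytree=float(p.get("colsample_bytree", 1.0)),
        min_child_weight=float(p.get("min_child_weight", 1.0)),
        subsample=float(p.get("subsample", 1.0)),
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed),
        eval_metric="logloss",
        verbosity=0,
    )


def default_learners(seed: int = 0) -> dict[str, BaseEstimator]:
    """Baseline learner panel: boosted trees, bagged trees, penalized
    logistic regression, k-nearest neighbours."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return {
        "boosted_trees": xgb_classifier(seed=seed),
        "bagged_trees": RandomForestClassifier(
            n_estimators=200, random_state=seed, n_jobs=1
        ),
        "penalized_logistic": make_pipeline(
            StandardScaler(), LogisticRegression(C=0.1, max_iter=2000)
        ),
        "knn": make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=11)),
    }


class ConstantScore(BaseEstimator, ClassifierMixin):
    """Learner that predicts a fixed probability for every patient."""

    def __init__(self, value: float = 0.5):
        self.value = value

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        n = np.asarray(X).shape[0]
        return np.column_stack([np.full(n, 1 - self.value), np.full(n, self.value)])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass
class CVResult:
    """Out-of-fold predictions and per-repeat AUCs of a repeated CV run."""

    oof: np.ndarray  # repeats × patients
    aucs: np.ndarray  # per repeat
    fold_sizes: list[list[int]]

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.aucs.std(ddof=1)) if len(self.aucs) > 1 else 0.0


def _as_array(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.asarray(features, dtype=np.float64)


def make_folds(
    y: np.ndarray, folds: int, seed: int, stratified: bool = True
) -> list[np.ndarray]:
    """Random fold assignment (validation index arrays), both classes
    guaranteed in every training fold; reshuffles with an incremented seed
    on failure (max 100 attempts)."""
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < folds:
        raise ValueError(f"{n} patients cannot fill {folds} folds")
    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        if stratified:
            assign = np.empty(n, dtype=int)
            offset = 0  # rotate per-class remainders so fold sizes balance
            for cls in np.unique(y):
                idx = np.flatnonzero(y == cls)
                rng.shuffle(idx)
                assign[idx] = (np.arange(len(idx)) + offset) % folds
                offset += len(idx) % folds
        else:
            assign = rng.permutation(np.arange(n) % folds)
        val_folds = [np.flatnonzero(assign == f) for f in range(folds)]
        ok = all(
            len(np.unique(y[np.concatenate([v for g, v in enumerate(val_folds)
                                            if g != f])])) == 2
            for f in range(folds)
        )
        if ok:
            if attempt:
                logger.info("fold assignment reshuffled %d time(s)", attempt)
            return val_folds
    raise RuntimeError("could not build folds with both classes in training")


def make_repeated_folds(y: np.ndarray, spec: CVSpec) -> list[list[np.ndarray]]:
    return [
        make_folds(y, spec.folds, spec.base_seed + r, spec.stratified)
        for r in range(spec.repeats)
    ]


def repeated_cv(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    learner: BaseEstimator,
    spec: CVSpec,
    folds: list[list[np.ndarray]] | None = None,
) -> CVResult:
    """Stratified k-fold CV repeated ``spec.repeats`` times.

    Per repeat every patient is scored exactly once, by a model that never
    saw its label; the repeat's AUC is computed on the pooled out-of-fold
    scores.  Passing precomputed ``folds`` makes comparisons across
    learners paired.
    """
    X = _as_array(features)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if folds is None:
        folds = make_repeated_folds(y, spec)

    oof = np.full((spec.repeats, len(y)), np.nan)
    aucs = np.empty(spec.repeats)
    fold_sizes = []
    for r, val_folds in enumerate(folds):
        fold_sizes.append([len(v) for v in val_folds])
        for val_idx in val_folds:
            train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
            est = clone(learner)
            if "random_state" in est.get_params():
                est.set_params(random_state=spec.base_seed + r)
            est.fit(X[train_idx], y[train_idx])
            oof[r, val_idx] = est.predict_proba(X[val_idx])[:, 1]
        assert not np.isnan(oof[r]).any(), "a patient was never scored"
        aucs[r] = roi_auc(oof[r], y)
    return CVResult(oof=oof, aucs=aucs, fold_sizes=fold_sizes)


def benchmark(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    learners: Mapping[str, BaseEstimator],
    spec: CVSpec,
) -> pd.DataFrame:
    """Paired comparison of learners under identical fold assignments.

    Returns a table (sorted by mean AUC, descending) with mean and SD of
    the per-repeat AUCs.  A failing learner is recorded with NaNs and the
    run continues.
    """
    if len(learners) < 2:
        raise ValueError("benchmark needs at least 2 learners")
    y = np.asarray(labels).astype(int)
    folds = make_repeated_folds(y, spec)
    rows = []
    for name, learner in learners.items():
        try:
            res = repeated_cv(features, y, learner, spec, folds=folds)
            rows.append({"learner": name, "mean_auc": res.mean_auc,
                         "sd_auc": res.sd_auc})
        except Exception as exc:  # noqa: BLE001 — a learner crash is data
            logger.warning("learner %s failed: %s", name, exc)
            rows.append({"learner": name, "mean_auc": np.nan, "sd_auc": np.nan})
    df = pd.DataFrame(rows).sort_values(
        "mean_auc", ascending=False, na_position="last"
    )
    return df.reset_index(drop=True)


def grid_search(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    grid: HyperGrid,
    spec: CVSpec,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive hyperparameter search by repeated CV.

    Best = highest mean AUC; exact ties broken by fewer boosting rounds,
    then shallower trees.  Returns (best parameters, full results table).
    """
    y = np.asarray(labels).astype(int)
    folds = make_repeated_folds(y, spec)
    rows = []
    for params in grid.combinations():
        res = repeated_cv(features, y, xgb_classifier(params), spec, folds=folds)
        rows.append({**params, "mean_auc": res.mean_auc, "sd_auc": res.sd_auc})
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["mean_auc", "nrounds", "max_depth"], ascending=[False, True, True]
    )
    best = order.iloc[0][[c for c in table.columns if c not in
                          ("mean_auc", "sd_auc")]].to_dict()
    best = {k: (int(v) if k in ("nrounds", "max_depth") else float(v))
            for k, v in best.items()}
    return best, table


def _total_gain(booster, n_features: int) -> np.ndarray:
    gains = np.zeros(n_features)
    for name, g in booster.get_score(importance_type="total_gain").items():
        gains[int(name[1:])] = g
    return gains


def rfe(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    spec: CVSpec,
    drop_fraction: float = 0.5,
    min_features: int = 4,
    params: Mapping[str, object] | None = None,
    rank_members: int = 8,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Backward recursive feature elimination ranked by total split gain.

    At each step a model on the current columns is scored by repeated CV,
    then the lowest-gain ``drop_fraction`` of columns is removed.  The gain
    ranking averages over ``rank_members`` models trained on random patient
    subsets: a single boosted-tree model concentrates its gain on one
    member of each group of correlated ROIs, which makes single-model
    rankings unstable; subset-averaged gain spreads credit across the
    group.  Remaining ties resolve by column order.

    Returns (selected column indices, AUC-vs-size profile).  The selected
    subset is the evaluated size with the highest mean AUC; ties favour
    the smaller subset.
    """
    X = _as_array(features)
    y = np.asarray(labels).astype(int)
    if X.shape[1] < 2:
        raise ValueError("rfe needs at least 2 columns")
    current = np.arange(X.shape[1])
    profile_rows = []
    subsets: dict[int, np.ndarray] = {}
    while True:
        res = repeated_cv(X[:, current], y, xgb_classifier(params), spec)
        profile_rows.append({"n_features": len(current),
                             "mean_auc": res.mean_auc, "sd_auc": res.sd_auc})
        subsets[len(current)] = current.copy()
        if len(current) <= min_features:
            break
        ranker = train_ensemble(
            X[:, current], y, n_members=rank_members, params=params,
            subsample_fraction=0.8 if rank_members > 1 else 1.0,
            base_seed=spec.base_seed,
        )
        gains = ranker.gain_per_feature(len(current))
        n_keep = max(min_features, int(np.ceil(len(current) * (1 - drop_fraction))))
        # stable sort: equal gains resolved by column order
        order = np.argsort(-gains, kind="stable")
        current = np.sort(current[order[:n_keep]])
    profile = pd.DataFrame(profile_rows)
    best = profile.sort_values(
        ["mean_auc", "n_features"], ascending=[False, True]
    ).iloc[0]
    return subsets[int(best["n_features"])], profile


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


@dataclass
class EnsembleModel:
    """Ensemble of boosted-tree members trained on random patient subsets.

    Prediction is the arithmetic mean of member probabilities.  The model
    serializes (members in the library's native JSON text format plus a
    manifest) and reloads with bit-identical predictions.
    """

    members: list[XGBClassifier]
    member_seeds: list[int]
    subsample_fraction: float
    selected_features: np.ndarray | None = None
    hyperparameters: dict = field(default_factory=dict)
    binning_specs: list[BinningSpec] = field(default_factory=list)
    feature_columns: list | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("ensemble needs >= 1 member")

    def _restrict(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        if isinstance(features, FeatureMatrix) and self.feature_columns is not None:
            missing = [c for c in self.feature_columns if c not in features.columns]
            if missing:
                raise ValueError(
                    f"feature matrix lacks {len(missing)} model columns, e.g. "
                    f"{missing[:3]}; rebuild features with the model's frozen "
                    f"binning spec"
                )
            idx = [features.columns.index(c) for c in self.feature_columns]
            return features.values[:, idx]
        X = _as_array(features)
        if self.selected_features is not None:
            X = X[:, self.selected_features]
        return X

    @staticmethod
    def _booster(member):
        return member.get_booster() if hasattr(member, "get_booster") else member

    def predict(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        X = self._restrict(features)
        probs = np.stack([
            self._booster(m).inplace_predict(X) for m in self.members
        ]).astype(np.float64)
        return probs.mean(axis=0)

    def gain_per_feature(self, n_features: int) -> np.ndarray:
        """Mean total split gain per (selected-subset) feature column."""
        g = np.zeros(n_features)
        for m in self.members:
            g += _total_gain(self._booster(m), n_features)
        return g / len(self.members)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.members):
            self._booster(m).save_model(str(directory / f"member_{i:03d}.json"))
        manifest = {
            "n_members": len(self.members),
            "member_seeds": [int(s) for s in self.member_seeds],
            "subsample_fraction": self.subsample_fraction,
            "selected_features": (
                None if self.selected_features is None
                else [int(i) for i in self.selected_features]
            ),
            "hyperparameters": self.hyperparameters,
            "binning_specs": [s.to_dict() for s in self.binning_specs],
            "feature_columns": (
                None if self.feature_columns is None
                else [[list(p), i, j] for p, i, j in self.feature_columns]
            ),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        import xgboost

        members = []
        for i in range(manifest["n_members"]):
            booster = xgboost.Booster()
            booster.load_model(str(directory / f"member_{i:03d}.json"))
            members.append(booster)
        sel = manifest["selected_features"]
        cols = manifest["feature_columns"]
        return cls(
            members=members,
            member_seeds=manifest["member_seeds"],
            subsample_fraction=manifest["subsample_fraction"],
            selected_features=None if sel is None else np.asarray(sel),
            hyperparameters=manifest["hyperparameters"],
            binning_specs=[
                BinningSpec.from_dict(d) for d in manifest["binning_specs"]
            ],
            feature_columns=(
                None if cols is None
                else [(tuple(p), i, j) for p, i, j in cols]
            ),
        )


def train_ensemble(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    n_members: int,
    params: Mapping[str, object] | None = None,
    subsample_fraction: float = 0.8,
    base_seed: int = 0,
    selected_features: np.ndarray | None = None,
) -> EnsembleModel:
    """Train an ensemble on random patient subsets (without replacement).

    Member i draws its subset with seed ``base_seed + i``; a subset missing
    a class is redrawn (logged).  ``subsample_fraction == 1.0`` makes every
    member see the full cohort, so a single-member ensemble equals one
    plain model.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    X = _as_array(features)
    y = np.asarray(labels).astype(int)
    if selected_features is not None:
        X = X[:, selected_features]
    n = len(y)
    size = max(2, int(round(subsample_fraction * n)))
    members, seeds = [], []
    for i in range(n_members):
        seed = base_seed + i
        for attempt in range(100):
            rng = np.random.default_rng(seed + 1_000_003 * attempt)
            idx = (np.arange(n) if size >= n else
                   rng.choice(n, size=size, replace=False))
            if len(np.unique(y[idx])) == 2:
                break
            logger.info("member %d: subset missing a class, redrawing", i)
        else:
            raise RuntimeError("could not draw a subset with both classes")
        est = xgb_classifier(params, seed=seed)
        est.fit(X[idx], y[idx])
        members.append(est)
        seeds.append(seed)
    fm = features if isinstance(features, FeatureMatrix) else None
    return EnsembleModel(
        members=members,
        member_seeds=seeds,
        subsample_fraction=subsample_fraction,
        selected_features=selected_features,
        hyperparameters=dict(params or {}),
        binning_specs=fm.specs if fm is not None else [],
        feature_columns=(
            [fm.columns[k] for k in (selected_features if selected_features
                                     is not None else range(fm.n_features))]
            if fm is not None else None
        ),
    )


def predict(model: EnsembleModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Per-patient probability of the positive class, in [0, 1]."""
    return model.predict(features)


class OptimizedClassifier(BaseEstimator, ClassifierMixin):
    """The full μFCM predictor as one sklearn-style estimator.

    ``fit`` optionally grid-searches hyperparameters and runs recursive
    feature elimination *inside the training data only* (inner CV), then
    trains a patient-subset ensemble; ``predict_proba`` averages member
    probabilities on the selected columns.  Wrapping the whole pipeline in
    an estimator lets :func:`repeated_cv` evaluate it without leakage.
    """

    def __init__(
        self,
        grid: HyperGrid | None = None,
        do_rfe: bool = True,
        rfe_drop_fraction: float = 0.75,
        rfe_min_features: int = 8,
        rfe_rank_members: int = 4,
        n_members: int = 12,
        subsample_fraction: float = 0.8,
        params: dict | None = None,
        inner_folds: int = 3,
        inner_repeats: int = 1,
        random_state: int = 0,
    ):
        self.grid = grid
        self.do_rfe = do_rfe
        self.rfe_drop_fraction = rfe_drop_fraction
        self.rfe_min_features = rfe_min_features
        self.rfe_rank_members = rfe_rank_members
        self.n_members = n_members
        self.subsample_fraction = subsample_fraction
        self.params = params
        self.inner_folds = inner_folds
        self.inner_repeats = inner_repeats
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        inner = CVSpec(
            folds=self.inner_folds,
            repeats=self.inner_repeats,
            base_seed=self.random_state + 17,
        )
        params = dict(self.params or {})
        if self.grid is not None:
            params, _ = grid_search(X, y, self.grid, inner)
        if self.do_rfe and X.shape[1] > self.rfe_min_features:
            selected, _ = rfe(
                X, y, inner,
                drop_fraction=self.rfe_drop_fraction,
                min_features=self.rfe_min_features,
                params=params,
                rank_members=self.rfe_rank_members,
            )
        else:
            selected = None
        self.best_params_ = params
        self.selected_features_ = selected
        self.model_ = train_ensemble(
            X, y,
            n_members=self.n_members,
            params=params,
            subsample_fraction=self.subsample_fraction,
            base_seed=self.random_state,
            selected_features=selected,
        )
        return self

    def predict_proba(self, X):
        p = self.model_.predict(np.asarray(X, dtype=np.float64))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
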