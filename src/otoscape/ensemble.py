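"""Multi-model ensemble contingent classification by Bayesian model averaging.

A registry of probabilistic binary classifiers (four classical statistical
methods, six machine-learning methods, plus an intercept-only null
benchmark) is tuned by grid search and evaluated by stratified 10-fold
cross-validation on the balanced, standardized baseline. The
top-performing members — those whose mean CV accuracy exceeds a cutoff, or
the top K — are aggregated into a weighted ensemble whose weights are
proportional to cross-validated accuracy and normalized to sum to one:

    w(k) = Accuracy(k) / Σ_k Accuracy(k)
    P_ensemble(northern | x) = Σ_k w(k) · P_k(northern | x)

A fish is assigned "northern" when the ensemble probability exceeds the
abstention threshold τ (default 0.7), "southern" when the complementary
probability does, and is otherwise left unassigned and excluded from the
downstream geographic assignment.

Year-class enters every member as a predictor: as one-hot dummies for the
generic classifiers, and as per-year-class isotope slopes for the
mixed-effect logistic member (MELR), implemented as an L2-penalized
logistic regression on year-class × isotope interactions — the MAP
estimate of the corresponding Gaussian random-slopes model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, log_loss, roc_auc_score
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedGroupKFold,
    StratifiedKFold,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .baseline import BaselineDataset, PREDICTORS

POSITIVE_CLASS = "northern"
NEGATIVE_CLASS = "southern"
LOGLOSS_CLIP = 1e-15

CLASSIFIER_NAMES = (
    "LR", "MELR", "LDA", "QDA", "ANN", "DT", "kNN", "NB", "RF", "SVM", "NULL",
)


class EnsembleError(ValueError):
    """Raised on structural errors in ensemble construction."""


# ---------------------------------------------------------------------------
# feature construction


class FeatureBuilder:
    """Map otolith records to a numeric design matrix.

    ``mode="onehot"`` produces [z18, z13, onehot(year_class)] — the design
    shared by the generic members. ``mode="melr"`` produces
    [z18, z13, z18·1{yc}, z13·1{yc} for each yc] so that an L2-penalized
    logistic regression on it estimates per-year-class isotope slopes
    shrunk toward the global slopes. ``mode="null"`` emits a constant
    column (the null member ignores predictors).

    Year-class categories are frozen at fit time (from the baseline) so
    unknown adults are encoded consistently.
    """

    def __init__(self, mode: str = "onehot"):
        if mode not in ("onehot", "melr", "null"):
            raise ValueError(f"unknown feature mode {mode!r}")
        self.mode = mode
        self.categories_: list[int] | None = None

    def fit(self, df: pd.DataFrame) -> "FeatureBuilder":
        self.categories_ = sorted(int(v) for v in df["year_class"].unique())
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if self.categories_ is None:
            raise EnsembleError("FeatureBuilder not fitted")
        n = len(df)
        if self.mode == "null":
            return np.ones((n, 1))
        iso = df[list(PREDICTORS)].to_numpy(dtype=float)
        yc = df["year_class"].to_numpy()
        cols = [iso]
        for cat in self.categories_:
            ind = (yc == cat).astype(float)[:, None]
            if self.mode == "onehot":
                cols.append(ind)
            else:  # melr: per-year-class isotope slopes
                cols.append(iso * ind)
        return np.hstack(cols)


# ---------------------------------------------------------------------------
# registry

def _build_estimator(name: str, params: dict, seed: int) -> BaseEstimator:
    p = dict(params)
    if name == "LR":
        return LogisticRegression(max_iter=2000, C=p.get("C", 1e6))
    if name == "MELR":
        # L2 penalty on the interaction design = Gaussian prior on the
        # per-year-class slope deviations (MAP of a random-slopes model).
        return LogisticRegression(max_iter=5000, C=p.get("C", 1.0))
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "QDA":
        return QuadraticDiscriminantAnalysis(reg_param=p.get("reg_param", 0.1))
    if name == "ANN":
        return MLPClassifier(
            hidden_layer_sizes=p.get("hidden_layer_sizes", (8,)),
            alpha=p.get("alpha", 1e-3),
            max_iter=3000,
            random_state=seed,
        )
    if name == "DT":
        return DecisionTreeClassifier(
            max_depth=p.get("max_depth", 5),
            min_samples_leaf=p.get("min_samples_leaf", 5),
            random_state=seed,
        )
    if name == "kNN":
        return KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 7))
    if name == "NB":
        return GaussianNB(var_smoothing=p.get("var_smoothing", 1e-9))
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 200),
            min_samples_leaf=p.get("min_samples_leaf", 2),
            random_state=seed,
        )
    if name == "SVM":
        return SVC(
            C=p.get("C", 1.0),
            gamma=p.get("gamma", "scale"),
            probability=True,
            random_state=seed,
        )
    if name == "NULL":
        return DummyClassifier(strategy="prior")
    raise EnsembleError(f"unknown classifier {name!r}")


#: Default hyperparameter grids (user-overridable via config). Kept small:
#: two predictors plus year-class dummies rarely reward large grids.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "LR": {},
    "MELR": {"C": [0.1, 1.0, 10.0]},
    "LDA": {},
    "QDA": {"reg_param": [0.0, 0.1, 0.5]},
    "ANN": {"hidden_layer_sizes": [(4,), (8,)], "alpha": [1e-3, 1e-1]},
    "DT": {"max_depth": [3, 5, 8], "min_samples_leaf": [2, 5]},
    "kNN": {"n_neighbors": [5, 9, 15]},
    "NB": {},
    "RF": {"n_estimators": [200], "min_samples_leaf": [1, 3]},
    "SVM": {"C": [0.5, 2.0], "gamma": ["scale", 0.5]},
    "NULL": {},
}

_FEATURE_MODE = {"MELR": "melr", "NULL": "null"}


@dataclass
class ClassifierSpec:
    """One registry member: name, search grid, and tuned parameter values."""

    name: str
    hyperparameter_grid: dict[str, list] = field(default_factory=dict)
    tuned_params: dict = field(default_factory=dict)

    @classmethod
    def default(cls, name: str) -> "ClassifierSpec":
        if name not in CLASSIFIER_NAMES:
            raise EnsembleError(f"unknown classifier {name!r}")
        return cls(name=name, hyperparameter_grid=dict(DEFAULT_GRIDS[name]))

    @property
    def feature_mode(self) -> str:
        return _FEATURE_MODE.get(self.name, "onehot")


@dataclass
class FittedMember:
    """A classifier fitted on the full balanced baseline."""

    spec: ClassifierSpec
    features: FeatureBuilder
    estimator: BaseEstimator

    def predict_probability(self, df: pd.DataFrame) -> np.ndarray:
        """P(northern) per record, guaranteed within [0, 1]."""
        X = self.features.transform(df)
        proba = self.estimator.predict_proba(X)
        idx = list(self.estimator.classes_).index(POSITIVE_CLASS)
        p = proba[:, idx]
        if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
            raise EnsembleError(
                f"member {self.spec.name} produced probabilities outside [0, 1]"
            )
        return p


@dataclass
class CVReport:
    """Per-fold cross-validation metrics for one classifier."""

    name: str
    fold_accuracy: list[float]
    fold_auc: list[float]
    fold_logloss: list[float]
    seed: int
    failed: bool = False

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_logloss(self) -> float:
        return float(np.mean(self.fold_logloss))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "fold_accuracy": list(map(float, self.fold_accuracy)),
            "fold_auc": list(map(float, self.fold_auc)),
            "fold_logloss": list(map(float, self.fold_logloss)),
            "mean_accuracy": self.mean_accuracy,
            "mean_auc": self.mean_auc,
            "mean_logloss": self.mean_logloss,
            "seed": self.seed,
            "failed": self.failed,
        }


# ---------------------------------------------------------------------------
# cross-validation machinery


def _strata(df: pd.DataFrame, folds: int) -> np.ndarray:
    """Stratification labels: contingent × year-class when every cell can
    populate each fold, else contingent alone."""
    fine = df["contingent"].astype(str) + "/" + df["year_class"].astype(str)
    if fine.value_counts().min() >= folds:
        return fine.to_numpy()
    return df["contingent"].to_numpy(dtype=object)


def _fold_metrics(y_true, p_northern) -> tuple[float, float, float]:
    y = (np.asarray(y_true) == POSITIVE_CLASS).astype(int)
    p = np.clip(np.asarray(p_northern, dtype=float), LOGLOSS_CLIP, 1 - LOGLOSS_CLIP)
    acc = accuracy_score(y, (p > 0.5).astype(int))
    auc = roc_auc_score(y, p) if len(np.unique(y)) > 1 else 0.5
    ll = log_loss(y, p, labels=[0, 1])
    return float(acc), float(auc), float(ll)


def _iter_folds(df: pd.DataFrame, folds: int, seed: int):
    """Stratified folds; refold on coarser strata if any fold is single-class.

    Folds are grouped by fish id so oversampling replicates of one fish
    never straddle the train/test boundary (otherwise duplicated records
    leak and flexible members memorize them).
    """
    labels = _strata(df, folds)
    y = df["contingent"].to_numpy(dtype=object)
    groups = df["fish_id"].to_numpy(dtype=object)
    grouped = len(np.unique(groups)) < len(df)
    for attempt, strat in enumerate((labels, y)):
        if grouped:
            skf = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                       random_state=seed + attempt)
            splits = list(skf.split(np.zeros(len(df)), strat, groups))
        else:
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=seed + attempt)
            splits = list(skf.split(np.zeros(len(df)), strat))
        if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
               for tr, te in splits):
            if attempt:
                warnings.warn("refolded CV on contingent-only strata")
            return splits
    raise EnsembleError("cannot build two-class folds")


def tune(ds: BaselineDataset, spec: ClassifierSpec, folds: int = 10,
         seed: int = 0) -> ClassifierSpec:
    """Grid-search hyperparameters with stratified k-fold CV on the baseline.

    Returns a copy of *spec* with ``tuned_params`` filled; specs with empty
    grids are returned as-is.
    """
    if not spec.hyperparameter_grid:
        return ClassifierSpec(spec.name, {}, {})
    df = ds.records
    fb = FeatureBuilder(spec.feature_mode).fit(df)
    X = fb.transform(df)
    y = df["contingent"].to_numpy(dtype=object)
    base = _build_estimator(spec.name, {}, seed)
    splits = _iter_folds(df, folds, seed)
    gs = GridSearchCV(base, spec.hyperparameter_grid, cv=splits,
                      scoring="accuracy", n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gs.fit(X, y)
    return ClassifierSpec(spec.name, dict(spec.hyperparameter_grid),
                          dict(gs.best_params_))


def cross_validate(ds: BaselineDataset, spec: ClassifierSpec,
                   folds: int = 10, seed: int = 0) -> CVReport:
    """Stratified k-fold CV of one tuned classifier.

    Log-loss probabilities are clipped to [1e-15, 1 − 1e-15]. A member that
    raises during fitting is returned with ``failed=True`` and chance-level
    metrics so selection can exclude it without aborting the run.
    """
    if folds < 2:
        raise EnsembleError("folds must be >= 2")
    df = ds.records
    accs, aucs, lls = [], [], []
    try:
        for tr, te in _iter_folds(df, folds, seed):
            dtr, dte = df.iloc[tr], df.iloc[te]
            member = fit_member(dtr, spec, seed)
            p = member.predict_probability(dte)
            a, u, l = _fold_metrics(dte["contingent"], p)
            accs.append(a); aucs.append(u); lls.append(l)
    except EnsembleError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        warnings.warn(f"classifier {spec.name} failed during CV: {exc}")
        return CVReport(spec.name, [0.0], [0.5], [np.log(2)], seed, failed=True)
    return CVReport(spec.name, accs, aucs, lls, seed)


def fit_member(df: pd.DataFrame, spec: ClassifierSpec, seed: int = 0) -> FittedMember:
    """Fit one registry member on (a subset of) the balanced baseline."""
    fb = FeatureBuilder(spec.feature_mode).fit(df)
    X = fb.transform(df)
    y = df["contingent"].to_numpy(dtype=object)
    est = _build_estimator(spec.name, spec.tuned_params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return FittedMember(spec, fb, est)


# ---------------------------------------------------------------------------
# selection, weighting, prediction


def select_members(reports: list[CVReport],
                   accuracy_cutoff: float | None = 0.76,
                   top_k: int | None = None) -> list[CVReport]:
    """Pick ensemble members from CV reports.

    Either every member with mean accuracy strictly above
    ``accuracy_cutoff``, or the ``top_k`` best by mean accuracy. The null
    benchmark and failed members are never selected. Ties break by higher
    AUC, then lower log-loss, then name order.
    """
    if not reports:
        raise EnsembleError("no CV reports supplied")
    pool = [r for r in reports if r.name != "NULL" and not r.failed]
    key = lambda r: (-r.mean_accuracy, -r.mean_auc, r.mean_logloss, r.name)
    pool.sort(key=key)
    if top_k is not None:
        if top_k < 1:
            raise EnsembleError("top_k must be >= 1")
        return pool[:top_k]
    sel = [r for r in pool if r.mean_accuracy > accuracy_cutoff]
    if not sel:
        raise EnsembleError(
            f"no classifier exceeded accuracy cutoff {accuracy_cutoff}; "
            "consider top_k selection"
        )
    return sel


def compute_weights(reports: list[CVReport]) -> np.ndarray:
    """Accuracy-proportional ensemble weights, normalized to sum to 1.

    The final weight is computed as one minus the rest so the sum is exact.
    """
    if not reports:
        raise EnsembleError("empty selection")
    acc = np.array([r.mean_accuracy for r in reports], dtype=float)
    if np.any(acc <= 0):
        raise EnsembleError("selected member with non-positive accuracy")
    w = acc / acc.sum()
    w[-1] = 1.0 - w[:-1].sum()
    return w


@dataclass
class EnsembleModel:
    """Accuracy-weighted ensemble of fitted members with abstention."""

    members: list[FittedMember]
    weights: np.ndarray
    threshold: float = 0.7
    reports: list[CVReport] = field(default_factory=list)
    selection_rule: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != len(self.weights) or len(self.members) < 1:
            raise EnsembleError("weights must align with members (K >= 1)")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise EnsembleError("weights must be nonnegative and sum to 1")
        if not (0.5 < self.threshold <= 1.0):
            raise EnsembleError("assignment threshold must lie in (0.5, 1]")

    def member_probabilities(self, df: pd.DataFrame) -> np.ndarray:
        """K × n matrix of member P(northern)."""
        P = np.vstack([m.predict_probability(df) for m in self.members])
        if np.any(~np.isfinite(P)) or np.any(P < 0) or np.any(P > 1):
            raise EnsembleError("member probability outside [0, 1]")
        return P

    def predict_probability(self, df: pd.DataFrame) -> np.ndarray:
        """Ensemble P(northern): the weight-convex combination of members."""
        return self.weights @ self.member_probabilities(df)

    def assign(self, df: pd.DataFrame) -> pd.DataFrame:
        """Assign contingent with abstention below the threshold.

        northern if p > τ, southern if 1 − p > τ, else unassigned.
        """
        p = self.predict_probability(df)
        decision = np.where(
            p > self.threshold, POSITIVE_CLASS,
            np.where(1 - p > self.threshold, NEGATIVE_CLASS, "unassigned"),
        )
        out = df[["fish_id", "year_class"]].copy()
        out["p_northern"] = p
        out["decision"] = decision
        return out


def bma_predict(model: EnsembleModel, df: pd.DataFrame) -> np.ndarray:
    """Functional alias for the ensemble probability (weighted member mean)."""
    return model.predict_probability(df)


def cross_validate_ensemble(ds: BaselineDataset, specs: list[ClassifierSpec],
                            weights: np.ndarray, folds: int = 10,
                            seed: int = 0) -> CVReport:
    """CV the weighted ensemble itself: members are refitted per fold, the
    (fixed) accuracy-proportional weights combine their held-out
    probabilities."""
    df = ds.records
    w = np.asarray(weights, dtype=float)
    accs, aucs, lls = [], [], []
    for tr, te in _iter_folds(df, folds, seed):
        dtr, dte = df.iloc[tr], df.iloc[te]
        P = np.vstack([
            fit_member(dtr, spec, seed).predict_probability(dte)
            for spec in specs
        ])
        p = w @ P
        a, u, l = _fold_metrics(dte["contingent"], p)
        accs.append(a); aucs.append(u); lls.append(l)
    return CVReport("BMA", accs, aucs, lls, seed)


def fit_ensemble(ds: BaselineDataset, names: list[str] | None = None,
                 folds: int = 10, seed: int = 0,
                 accuracy_cutoff: float | None = 0.76,
                 top_k: int | None = None,
                 threshold: float = 0.7,
                 grids: dict[str, dict] | None = None,
                 ) -> tuple[EnsembleModel, list[CVReport]]:
    """Full pipeline: tune, cross-validate, select, weight, refit.

    Returns the fitted ensemble plus every member's CV report (the
    ensemble's own CV report is appended last under the name "BMA").
    """
    names = list(names or CLASSIFIER_NAMES)
    specs = []
    for name in names:
        spec = ClassifierSpec.default(name)
        if grids is not None and name in grids:
            spec.hyperparameter_grid = dict(grids[name])
        specs.append(tune(ds, spec, folds=folds, seed=seed))
    reports = [cross_validate(ds, s, folds=folds, seed=seed) for s in specs]
    by_name = {s.name: s for s in specs}
    selected = select_members(reports, accuracy_cutoff=accuracy_cutoff,
                              top_k=top_k)
    weights = compute_weights(selected)
    sel_specs = [by_name[r.name] for r in selected]
    members = [fit_member(ds.records, s, seed) for s in sel_specs]
    rule = ({"top_k": top_k} if top_k is not None
            else {"accuracy_cutoff": accuracy_cutoff})
    ens_report = cross_validate_ensemble(ds, sel_specs, weights,
                                         folds=folds, seed=seed)
    model = EnsembleModel(members=members, weights=weights,
                          threshold=threshold,
                          reports=reports + [ens_report],
                          selection_rule=rule)
    return model, reports + [ens_report]


def composition_report(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-year-class contingent composition.

    %northern is computed among assigned fish only; %unassigned among all
    fish. Year-classes with no fish are omitted; an all-unassigned
    year-class reports %northern as missing.
    """
    if len(assignments) == 0:
        raise EnsembleError("no assignments to summarize")
    rows = []
    for yc, grp in assignments.groupby("year_class", sort=True):
        n = len(grp)
        n_north = int((grp["decision"] == POSITIVE_CLASS).sum())
        n_south = int((grp["decision"] == NEGATIVE_CLASS).sum())
        n_un = int((grp["decision"] == "unassigned").sum())
        assigned = n_north + n_south
        rows.append({
            "year_class": yc,
            "n_total": n,
            "n_northern": n_north,
            "n_southern": n_south,
            "n_unassigned": n_un,
            "pct_northern": 100.0 * n_north / assigned if assigned else np.nan,
            "pct_unassigned": 100.0 * n_un / n,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: EnsembleModel, outdir) -> None:
    """Persist the ensemble: JSON for weights/reports/specs, joblib for
    fitted estimators."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "weights": model.weights.tolist(),
        "threshold": model.threshold,
        "selection_rule": model.selection_rule,
        "members": [
            {
                "name": m.spec.name,
                "tuned_params": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in m.spec.tuned_params.items()},
                "feature_mode": m.features.mode,
                "year_classes": m.features.categories_,
            }
            for m in model.members
        ],
        "cv_reports": [r.to_dict() for r in model.reports],
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    joblib.dump([m.estimator for m in model.members], out / "estimators.joblib")


def load_model(indir) -> EnsembleModel:
    from pathlib import Path

    src = Path(indir)
    meta = json.loads((src / "model.json").read_text())
    ests = joblib.load(src / "estimators.joblib")
    members = []
    for mm, est in zip(meta["members"], ests):
        params = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in mm["tuned_params"].items()}
        spec = ClassifierSpec(mm["name"], {}, params)
        fb = FeatureBuilder(mm["feature_mode"])
        fb.categories_ = list(mm["year_classes"])
        members.append(FittedMember(spec, fb, est))
    reports = [CVReport(r["name"], r["fold_accuracy"], r["fold_auc"],
                        r["fold_logloss"], r["seed"], r["failed"])
               for r in meta["cv_reports"]]
    return EnsembleModel(members=members,
                         weights=np.array(meta["weights"]),
                         threshold=meta["threshold"],
                         reports=reports,
                         selection_rule=meta["selection_rule"])
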