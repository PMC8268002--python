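"""The modeling chain: standardization, correlation filtering, SMOTE,
RFE-AdaBoost selection, stratified splitting, cross-validated probability
estimation, grid search, and the nine model configurations.

Everything that learns parameters (z-scoring, the correlation filter,
SMOTE, RFE, the classifier) is fitted strictly on training cases — inside
each cross-validation fold when estimating out-of-fold probabilities — so
test folds never leak into preprocessing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.feature_selection import RFE
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.tree._tree import Tree

from .shells import VOI_ORDER

# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Cases x features with binary STAS labels.

    ``mu``/``sigma`` hold per-feature standardization parameters once a
    table has been fitted; they always come from training cases only.
    """

    values: pd.DataFrame  # index = case ids, columns = feature names
    labels: np.ndarray  # 1 = STAS+, 0 = STAS-
    mu: pd.Series | None = None
    sigma: pd.Series | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        if len(self.labels) != len(self.values):
            raise ValueError("labels and rows mismatch")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")

    @property
    def n_cases(self) -> int:
        return len(self.values)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def subset_cases(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.values.iloc[idx].copy(), self.labels[idx], self.mu, self.sigma)

    def subset_features(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(
            self.values[names].copy(),
            self.labels.copy(),
            None if self.mu is None else self.mu[names],
            None if self.sigma is None else self.sigma[names],
        )

    def drop_incomplete_cases(self) -> tuple["FeatureTable", list[str]]:
        """Remove cases with missing feature blocks (empty-shell exclusions)."""
        bad = self.values.isna().any(axis=1)
        dropped = list(self.values.index[bad])
        if dropped:
            warnings.warn(f"excluding {len(dropped)} case(s) with missing VOI blocks: {dropped}")
        keep = np.flatnonzero(~bad.to_numpy())
        return self.subset_cases(keep), dropped


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one model run."""

    voi_scope: str = "eight-voi"  # one of VOI_ORDER or "eight-voi"
    feature_groups: str = "all"  # all | firstorder+shape | texture | wavelet
    n_selected: int = 20
    cv_folds: int = 5
    cv_iterations: int = 5
    n_estimators: int = 50
    max_depth: int = 1
    grid: tuple[tuple[int, int], ...] = ()  # (n_estimators, max_depth) points
    rfe_step: float = 0.5
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voi_scope not in (*VOI_ORDER, "eight-voi"):
            raise ValueError(f"invalid voi_scope {self.voi_scope!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.feature_groups not in ("all", "firstorder+shape", "texture", "wavelet"):
            raise ValueError(f"invalid feature_groups {self.feature_groups!r}")


def select_feature_group(names: list[str], group: str) -> list[str]:
    """Columns belonging to a feature-group configuration."""
    if group == "all":
        return list(names)
    out = []
    for n in names:
        parts = n.split("__")
        filt, fam = parts[-3], parts[-2]
        if group == "firstorder+shape" and filt == "original" and fam in ("firstorder", "shape"):
            out.append(n)
        elif group == "texture" and filt == "original" and fam not in ("firstorder", "shape"):
            out.append(n)
        elif group == "wavelet" and filt.startswith("wavelet"):
            out.append(n)
    return out


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def stratified_split(
    table: FeatureTable, train_frac: float = 0.8, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Per-class split; training size is floor(frac * class size) per class."""
    if not 0 < train_frac <= 1:
        raise ValueError("train_frac must be in (0, 1]")
    classes, counts = np.unique(table.labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if (counts < 2).any() and train_frac < 1:
        raise ValueError("each class needs at least 2 cases to split")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(table.labels == c)
        rng.shuffle(idx)
        k = int(np.floor(train_frac * len(idx)))
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return (
        table.subset_cases(np.sort(np.concatenate(train_idx))),
        table.subset_cases(np.sort(np.concatenate(test_idx))),
    )


def zscore_fit_apply(train: FeatureTable, *others: FeatureTable) -> tuple[FeatureTable, ...]:
    """Standardize with training mean/SD; zero-variance features dropped."""
    mu = train.values.mean(axis=0)
    sigma = train.values.std(axis=0, ddof=0)
    keep = sigma > 0
    dropped = list(sigma.index[~keep])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s)")
    mu, sigma = mu[keep], sigma[keep]
    cols = list(mu.index)

    def _apply(t: FeatureTable) -> FeatureTable:
        vals = (t.values[cols] - mu) / sigma
        return FeatureTable(vals, t.labels.copy(), mu.copy(), sigma.copy())

    return tuple(_apply(t) for t in (train, *others))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation rho = Cov(X, Y) / (sigma_x sigma_y); population SDs."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sx, sy = x.std(), y.std()
    if sx * sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def pcc_filter(table: FeatureTable, threshold: float = 0.99) -> FeatureTable:
    """Drop the later member of every feature pair with |rho| > threshold.

    Features are scanned in column (name) order; the filter is
    deterministic and the surviving set contains no offending pair.
    """
    X = table.values.to_numpy(float)
    n = X.shape[1]
    if n <= 1:
        return table.subset_features(table.feature_names)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = Xc / sd_safe
    corr = np.abs(Z.T @ Z / len(Z))
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    keep: list[int] = []
    for j in range(n):
        if all(corr[j, k] <= threshold for k in keep):
            keep.append(j)
    return table.subset_features([table.feature_names[j] for j in keep])


def smote_oversample(train: FeatureTable, k_neighbors: int = 5, seed: int = 0) -> FeatureTable:
    """SMOTE: interpolated minority samples until classes balance.

    Each synthetic case is x + u (x_nn - x) with u ~ U(0, 1) and x_nn one
    of the k nearest minority neighbors of x.  Applied to training data
    only; never to test folds.
    """
    y = train.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() == counts.max():
        return train.subset_cases(np.arange(train.n_cases))
    minority = classes[np.argmin(counts)]
    n_new = int(counts.max() - counts.min())
    Xmin = train.values.to_numpy(float)[y == minority]
    if len(Xmin) < 2:
        raise ValueError("SMOTE needs at least 2 minority cases")
    k = k_neighbors
    if len(Xmin) < k + 1:
        k = len(Xmin) - 1
        warnings.warn(f"minority class smaller than k+1; reducing k to {k}")

    rng = np.random.default_rng(seed)
    d2 = np.sum((Xmin[:, None, :] - Xmin[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]

    base = rng.integers(len(Xmin), size=n_new)
    pick = nn[base, rng.integers(k, size=n_new)]
    u = rng.uniform(size=(n_new, 1))
    Xnew = Xmin[base] + u * (Xmin[pick] - Xmin[base])

    new_ids = [f"smote_{i:04d}" for i in range(n_new)]
    vals = pd.concat(
        [train.values, pd.DataFrame(Xnew, index=new_ids, columns=train.values.columns)]
    )
    labels = np.concatenate([y, np.full(n_new, minority)])
    return FeatureTable(vals, labels, train.mu, train.sigma)


# ---------------------------------------------------------------------------
# AdaBoost model + serialization
# ---------------------------------------------------------------------------


def _make_adaboost(n_estimators: int, max_depth: int, seed: int) -> AdaBoostClassifier:
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=max_depth, random_state=seed),
        n_estimators=n_estimators,
        random_state=seed,
    )


@dataclass
class ModelBundle:
    """A fitted, serializable AdaBoost model with its preprocessing state."""

    selected_features: list[str]
    model: AdaBoostClassifier
    mu: pd.Series
    sigma: pd.Series
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        """STAS+ probability per case; standardizes with the stored params."""
        cols = self.selected_features
        vals = (table.values[cols] - self.mu[cols]) / self.sigma[cols]
        return self.model.predict_proba(vals.to_numpy(float))[:, 1]

    # -- JSON serialization (trees stored as their node arrays) -----------

    def to_json(self) -> str:
        trees = []
        for est in self.model.estimators_:
            st = est.tree_.__getstate__()
            trees.append(
                {
                    "max_depth": int(st["max_depth"]),
                    "node_count": int(st["node_count"]),
                    "nodes": {n: st["nodes"][n].tolist() for n in st["nodes"].dtype.names},
                    "values": st["values"].tolist(),
                    "classes": est.classes_.tolist(),
                }
            )
        payload = {
            "selected_features": self.selected_features,
            "mu": {k: float(v) for k, v in self.mu.items()},
            "sigma": {k: float(v) for k, v in self.sigma.items()},
            "estimator_weights": self.model.estimator_weights_.tolist(),
            "estimator_errors": self.model.estimator_errors_.tolist(),
            "classes": self.model.classes_.tolist(),
            "n_features": int(self.model.n_features_in_),
            "trees": trees,
            "metadata": self.metadata,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ModelBundle":
        payload = json.loads(text)
        n_features = payload["n_features"]
        classes = np.asarray(payload["classes"])
        estimators = []
        for tr in payload["trees"]:
            nodes_dtype = np.dtype(
                [
                    ("left_child", "<i8"),
                    ("right_child", "<i8"),
                    ("feature", "<i8"),
                    ("threshold", "<f8"),
                    ("impurity", "<f8"),
                    ("n_node_samples", "<i8"),
                    ("weighted_n_node_samples", "<f8"),
                    ("missing_go_to_left", "u1"),
                ]
            )
            nodes = np.zeros(tr["node_count"], dtype=nodes_dtype)
            for name in nodes.dtype.names:
                nodes[name] = tr["nodes"][name]
            tree = Tree(n_features, np.array([len(classes)]), 1)
            tree.__setstate__(
                {
                    "max_depth": tr["max_depth"],
                    "node_count": tr["node_count"],
                    "nodes": nodes,
                    "values": np.asarray(tr["values"], float),
                }
            )
            dt = DecisionTreeClassifier()
            dt.tree_ = tree
            dt.classes_ = np.asarray(tr["classes"])
            dt.n_features_in_ = n_features
            dt.n_outputs_ = 1
            dt.n_classes_ = len(classes)
            estimators.append(dt)
        model = _make_adaboost(len(estimators), 1, 0)
        model.estimators_ = estimators
        model.estimator_weights_ = np.asarray(payload["estimator_weights"])
        model.estimator_errors_ = np.asarray(payload["estimator_errors"])
        model.classes_ = classes
        model.n_classes_ = len(classes)
        model.n_features_in_ = n_features
        return cls(
            selected_features=payload["selected_features"],
            model=model,
            mu=pd.Series(payload["mu"]),
            sigma=pd.Series(payload["sigma"]),
            metadata=payload.get("metadata", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        return cls.from_json(Path(path).read_text())


def fit_adaboost(
    train: FeatureTable,
    n_estimators: int = 50,
    max_depth: int = 1,
    seed: int = 0,
    metadata: dict | None = None,
) -> ModelBundle:
    """Fit a boosted decision-tree ensemble on (already standardized) data."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data contains a single class")
    if train.mu is None or train.sigma is None:
        raise ValueError("training table must be standardized (use zscore_fit_apply)")
    clf = _make_adaboost(n_estimators, max_depth, seed)
    clf.fit(train.values.to_numpy(float), train.labels)
    return ModelBundle(
        selected_features=train.feature_names,
        model=clf,
        mu=train.mu,
        sigma=train.sigma,
        metadata=metadata or {"n_estimators": n_estimators, "max_depth": max_depth, "seed": seed},
    )


def rfe_select(train: FeatureTable, spec: ModelSpec) -> list[str]:
    """Recursive feature elimination under an AdaBoost ranker.

    Iteratively fits AdaBoost, drops the lowest-importance fraction
    (``rfe_step``) of features, and stops at ``n_selected``.  Returns the
    selected names ordered by final-fit ensemble importance (descending).
    """
    if spec.n_selected <= 0:
        raise ValueError("n_selected must be > 0")
    names = train.feature_names
    if spec.n_selected >= len(names):
        return list(names)
    est = _make_adaboost(spec.n_estimators, spec.max_depth, spec.seed)
    rfe = RFE(est, n_features_to_select=spec.n_selected, step=spec.rfe_step)
    X, y = train.values.to_numpy(float), train.labels
    rfe.fit(X, y)
    chosen = [n for n, s in zip(names, rfe.support_) if s]
    final = _make_adaboost(spec.n_estimators, spec.max_depth, spec.seed)
    final.fit(train.values[chosen].to_numpy(float), y)
    order = np.argsort(-final.feature_importances_, kind="stable")
    return [chosen[i] for i in order]


# ---------------------------------------------------------------------------
# cross-validation, grid search, nine models
# ---------------------------------------------------------------------------


def _fit_fold(
    train: FeatureTable, spec: ModelSpec, n_estimators: int, max_depth: int, fold_seed: int
) -> ModelBundle:
    """One fold's full training chain: z-score, PCC, SMOTE, RFE, AdaBoost."""
    (ztrain,) = zscore_fit_apply(train)
    ztrain = pcc_filter(ztrain)
    ztrain = smote_oversample(ztrain, spec.smote_k, seed=fold_seed)
    sel = rfe_select(ztrain, replace(spec, n_estimators=n_estimators, max_depth=max_depth, seed=fold_seed))
    return fit_adaboost(
        ztrain.subset_features(sel),
        n_estimators,
        max_depth,
        seed=fold_seed,
        metadata={"n_estimators": n_estimators, "max_depth": max_depth, "seed": fold_seed},
    )


def cross_validated_probabilities(
    table: FeatureTable,
    spec: ModelSpec,
    n_estimators: int | None = None,
    max_depth: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Out-of-fold STAS+ probabilities, averaged over CV iterations.

    Returns (probabilities, fold assignment of the last iteration,
    per-fold validation AUCs pooled over iterations).  The whole
    preprocessing chain is refit inside each training fold.
    """
    n_estimators = n_estimators or spec.n_estimators
    max_depth = max_depth or spec.max_depth
    n = table.n_cases
    probs = np.zeros(n)
    folds = np.full(n, -1)
    fold_aucs: list[float] = []
    for it in range(spec.cv_iterations):
        skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed + it)
        for f, (tr, te) in enumerate(skf.split(np.zeros(n), table.labels)):
            if len(np.unique(table.labels[te])) < 2:
                # stratified folds should always carry both classes; guard anyway
                warnings.warn(f"fold {f} lacks a class; AUC for it is skipped")
            fold_seed = spec.seed * 10007 + it * 101 + f
            bundle = _fit_fold(table.subset_cases(tr), spec, n_estimators, max_depth, fold_seed)
            p = bundle.predict_proba(table.subset_cases(te))
            probs[te] += p
            folds[te] = f
            if len(np.unique(table.labels[te])) == 2:
                fold_aucs.append(float(roc_auc_score(table.labels[te], p)))
    probs /= spec.cv_iterations
    return probs, folds, fold_aucs


def grid_search(spec: ModelSpec, table: FeatureTable) -> tuple[int, int]:
    """Pick (n_estimators, max_depth) maximizing mean validation-fold AUC.

    Ties break toward fewer estimators, then shallower trees.
    """
    grid = spec.grid or ((spec.n_estimators, spec.max_depth),)
    scored = []
    for n_est, depth in grid:
        _, _, fold_aucs = cross_validated_probabilities(table, spec, n_est, depth)
        scored.append((-float(np.mean(fold_aucs)), n_est, depth))
    scored.sort()
    _, n_est, depth = scored[0]
    return n_est, depth


def train_and_evaluate(
    train: FeatureTable, test: FeatureTable | None, spec: ModelSpec
) -> dict:
    """Grid-search (if configured), estimate out-of-fold AUC, fit the final
    model on all training cases and score the held-out set."""
    n_est, depth = grid_search(spec, train) if spec.grid else (spec.n_estimators, spec.max_depth)
    probs, _, fold_aucs = cross_validated_probabilities(train, spec, n_est, depth)
    auc_train = float(roc_auc_score(train.labels, probs))
    bundle = _fit_fold(train, spec, n_est, depth, spec.seed)
    out = {
        "model": spec.voi_scope,
        "groups": spec.feature_groups,
        "n_estimators": n_est,
        "max_depth": depth,
        "auc_train": auc_train,
        "auc_folds_mean": float(np.mean(fold_aucs)),
        "bundle": bundle,
        "probs_train": probs,
    }
    if test is not None and test.n_cases > 0:
        p_test = bundle.predict_proba(test)
        out["probs_test"] = p_test
        if len(np.unique(test.labels)) == 2:
            out["auc_test"] = float(roc_auc_score(test.labels, p_test))
    return out


def split_voi_blocks(case_table: FeatureTable) -> dict[str, FeatureTable]:
    """Per-VOI feature tables from a 6,808-column case table."""
    blocks: dict[str, FeatureTable] = {}
    for voi in VOI_ORDER:
        cols = [c for c in case_table.feature_names if c.startswith(f"{voi}__")]
        if not cols:
            raise ValueError(f"case table has no columns for VOI {voi!r}")
        blocks[voi] = case_table.subset_features(cols)
    return blocks


def run_nine_models(
    case_table: FeatureTable,
    spec: ModelSpec,
    train_frac: float = 0.8,
    with_holdout: bool = True,
) -> pd.DataFrame:
    """Fit the 8 single-VOI models and the eight-VOI model.

    All models share the same stratified train/test split of the cases.
    Returns one row per model with training (out-of-fold) and test AUCs.
    """
    table, _ = case_table.drop_incomplete_cases()
    group_cols = select_feature_group(table.feature_names, spec.feature_groups)
    table = table.subset_features(group_cols)
    if with_holdout and train_frac < 1:
        train_all, test_all = stratified_split(table, train_frac, spec.seed)
    else:
        train_all, test_all = table, None

    rows = []
    scopes = list(VOI_ORDER) + ["eight-voi"]
    for scope in scopes:
        if scope == "eight-voi":
            tr, te = train_all, test_all
        else:
            cols = [c for c in train_all.feature_names if c.startswith(f"{scope}__")]
            tr = train_all.subset_features(cols)
            te = None if test_all is None else test_all.subset_features(cols)
        res = train_and_evaluate(tr, te, replace(spec, voi_scope=scope))
        rows.append(
            {
                "model": scope,
                "groups": spec.feature_groups,
                "auc_train": res["auc_train"],
                "auc_test": res.get("auc_test", float("nan")),
            }
        )
    return pd.DataFrame(rows)
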