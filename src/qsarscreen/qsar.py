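"""Feature-selected SVM regression models with an applicability domain.

The modeling recipe:

1. rank fingerprint bits by unscaled out-of-bag permutation variable
   importance from a bootstrap ensemble of regression trees;
2. fit stepwise SVM (RBF) regressions on growing prefixes of the ranked
   bits, scoring each prefix by 5-fold cross-validated RMSE with a fixed
   fold assignment, and keep the smallest prefix attaining the minimum
   (the selected-features, "SF", model);
3. validate externally on a held-out set via PVE, RMSE, and r^2;
4. guard predictions with a Tanimoto nearest-neighbor applicability
   domain against the training fingerprints.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor
from sklearn.svm import SVR

from .chem import Dataset, MoleculeRecord, canonicalize, fingerprint

__all__ = [
    "FeatureRanking", "StepwiseCurve", "QsarModel", "ValidationMetrics",
    "AdVerdict", "rank_features", "stepwise_fit", "pve", "rmse",
    "external_validate", "applicability_domain", "predict",
    "save_model", "load_model",
]


@dataclass
class FeatureRanking:
    """Bit indices sorted by descending permutation importance."""

    order: np.ndarray          # permutation of bit indices
    vi_scores: np.ndarray      # unscaled importance per bit (original index order)
    n_trees: int
    seed: int


@dataclass
class StepwiseCurve:
    """Cross-validated RMSE as a function of the number of top-ranked bits."""

    k_values: list[int]
    cv_rmse: list[float]

    @property
    def best_k(self) -> int:
        arr = np.asarray(self.cv_rmse)
        return self.k_values[int(np.argmin(arr))]  # argmin takes smallest k on ties


@dataclass
class ValidationMetrics:
    pve: float
    rmse: float
    r2: float
    n: int


@dataclass(frozen=True)
class AdVerdict:
    """Nearest-neighbor similarity verdict for one query molecule."""

    nn_similarity: float
    in_domain: bool
    threshold: float = 0.7

    @property
    def nn_distance(self) -> float:
        return 1.0 - self.nn_similarity


@dataclass
class QsarModel:
    """A fitted selected-features SVM regressor plus everything needed to apply it."""

    endpoint: str
    ranking: FeatureRanking
    selected_bits: np.ndarray
    regressor: SVR
    train_fingerprints: np.ndarray      # n_train x nbits uint8, full bit space
    train_smiles: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def nbits(self) -> int:
        return self.train_fingerprints.shape[1]

    @property
    def scheme(self) -> str:
        return self.metadata.get("scheme", "atompair")


# ---------------------------------------------------------------------------
# metrics


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have identical shapes")
    if y.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pve(y, yhat) -> float:
    """Proportion of variance explained: 1 - SSres / SStot about the observed mean."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have identical shapes")
    if y.size < 2:
        raise ValueError("need at least two observations")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise ValueError("PVE undefined for constant y")
    ssres = float(np.sum((y - yhat) ** 2))
    return 1.0 - ssres / sstot


# ---------------------------------------------------------------------------
# variable importance


def rank_features(train: Dataset, n_trees: int = 200, seed: int = 0,
                  min_rows: int = 20) -> FeatureRanking:
    """Rank bits by unscaled out-of-bag permutation importance.

    A bootstrap ensemble of regression trees is grown (mtry = p/3); for
    each tree, every feature the tree actually splits on is permuted over
    that tree's out-of-bag rows and the increase in OOB MSE recorded.
    Importance is the increase averaged over all trees — the classic
    unscaled %IncMSE convention.  Features a tree never uses contribute
    exactly zero for that tree.
    """
    if train.X is None:
        raise ValueError("dataset must be featurized before ranking")
    X = np.asarray(train.X, dtype=np.float32)
    y = np.asarray(train.y, dtype=float)
    n, p = X.shape
    if n < min_rows:
        raise ValueError(f"need at least {min_rows} training rows, got {n}")

    if np.unique(y).size < 2:
        warnings.warn("constant response: all importances are zero; "
                      "ranking falls back to bit index")
        return FeatureRanking(order=np.arange(p), vi_scores=np.zeros(p),
                              n_trees=n_trees, seed=seed)

    rng = np.random.default_rng(seed)
    vi = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size < 2:
            continue
        tree = DecisionTreeRegressor(
            max_features=1.0 / 3.0,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        X_oob = X[oob]
        y_oob = y[oob]
        base_mse = np.mean((tree.predict(X_oob) - y_oob) ** 2)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            perm = rng.permutation(oob.size)
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            perm_mse = np.mean((tree.predict(X_perm) - y_oob) ** 2)
            vi[j] += perm_mse - base_mse
    vi /= n_trees
    # stable sort: descending importance, ties by bit index
    order = np.lexsort((np.arange(p), -vi))
    return FeatureRanking(order=order, vi_scores=vi, n_trees=n_trees, seed=seed)


# ---------------------------------------------------------------------------
# stepwise SVM fitting


def _make_svr(k: int) -> SVR:
    # e1071-style defaults: RBF kernel, cost 1, epsilon 0.1, gamma 1/(n features)
    return SVR(kernel="rbf", C=1.0, epsilon=0.1, gamma=1.0 / k)


def _cv_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), folds)


def stepwise_fit(train: Dataset, ranking: FeatureRanking,
                 k_grid: list[int] | None = None, folds: int = 5,
                 seed: int = 0, max_k: int = 200,
                 stride: int = 1) -> tuple[StepwiseCurve, QsarModel]:
    """Grow SVM models on prefixes of the ranked bits; keep the CV-best prefix.

    The fold assignment is fixed across all k so curve points are directly
    comparable.  ``best_k`` is the smallest k attaining the minimum
    cross-validated RMSE; the returned model is refit on the whole
    training set at that k.
    """
    if train.X is None:
        raise ValueError("dataset must be featurized before fitting")
    X = np.asarray(train.X, dtype=float)
    y = np.asarray(train.y, dtype=float)
    n, p = X.shape
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if k_grid is None:
        k_grid = list(range(1, min(p, max_k) + 1, stride))
    k_grid = sorted(set(int(k) for k in k_grid))
    if max(k_grid) > p:
        raise ValueError(f"k_grid exceeds number of bits ({p})")

    fold_idx = _cv_folds(n, folds, seed)
    cv_rmse: list[float] = []
    for k in k_grid:
        cols = ranking.order[:k]
        errs = []
        for f in range(folds):
            test = fold_idx[f]
            tr = np.concatenate([fold_idx[g] for g in range(folds) if g != f])
            svr = _make_svr(k)
            svr.fit(X[np.ix_(tr, cols)], y[tr])
            pred = svr.predict(X[np.ix_(test, cols)])
            errs.append(rmse(y[test], pred))
        cv_rmse.append(float(np.mean(errs)))

    curve = StepwiseCurve(k_values=list(k_grid), cv_rmse=cv_rmse)
    best_k = curve.best_k
    cols = ranking.order[:best_k]
    final = _make_svr(best_k)
    final.fit(X[:, cols], y)
    model = QsarModel(
        endpoint=train.endpoint,
        ranking=ranking,
        selected_bits=np.asarray(cols),
        regressor=final,
        train_fingerprints=np.asarray(train.X, dtype=np.uint8),
        train_smiles=train.canonical_smiles,
        metadata={
            "scheme": train.scheme or "atompair",
            "nbits": int(p),
            "seed": int(seed),
            "ranking_seed": int(ranking.seed),
            "n_trees": int(ranking.n_trees),
            "folds": int(folds),
            "best_k": int(best_k),
            "cv_rmse_at_best_k": float(min(cv_rmse)),
        },
    )
    return curve, model


# ---------------------------------------------------------------------------
# applicability domain


def _tanimoto_to_train(bits: np.ndarray, train_fps: np.ndarray) -> float:
    q = bits.astype(np.int64)
    t = train_fps.astype(np.int64)
    inter = t @ q
    union = t.sum(axis=1) + q.sum() - inter
    sims = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return float(sims.max())


def applicability_domain(query_bits: np.ndarray, model: QsarModel,
                         threshold: float = 0.7,
                         rule: str = "distance") -> AdVerdict:
    """Nearest-neighbor Tanimoto verdict for one query fingerprint.

    ``rule='distance'`` (default): in-domain iff 1 - max similarity <=
    threshold.  ``rule='similarity'``: in-domain iff max similarity >=
    threshold.  Both readings of the threshold are supported because the
    distance/similarity convention differs across tools.
    """
    if model.train_fingerprints.shape[0] == 0:
        raise ValueError("model has no training fingerprints")
    query_bits = np.asarray(query_bits).ravel()
    if query_bits.size != model.nbits:
        raise ValueError("query fingerprint length does not match the model")
    sim = _tanimoto_to_train(query_bits, model.train_fingerprints)
    if rule == "distance":
        in_dom = (1.0 - sim) <= threshold
    elif rule == "similarity":
        in_dom = sim >= threshold
    else:
        raise ValueError(f"unknown AD rule {rule!r}")
    return AdVerdict(nn_similarity=sim, in_domain=bool(in_dom), threshold=threshold)


# ---------------------------------------------------------------------------
# validation and prediction


def _predict_bits(model: QsarModel, X: np.ndarray) -> np.ndarray:
    return model.regressor.predict(np.asarray(X, dtype=float)[:, model.selected_bits])


def external_validate(model: QsarModel, ivs: Dataset) -> ValidationMetrics:
    """PVE, RMSE, and squared Pearson r of predictions on a held-out set.

    The held-out set must be structurally disjoint from the training set
    (checked by canonical SMILES).
    """
    if ivs.X is None:
        raise ValueError("validation dataset must be featurized")
    overlap = set(ivs.canonical_smiles) & set(model.train_smiles)
    if overlap:
        ids = [r.id for r in ivs.records if r.smiles_canonical in overlap]
        raise ValueError(f"validation set overlaps training set: {sorted(ids)}")
    yhat = _predict_bits(model, ivs.X)
    r = stats.pearsonr(ivs.y, yhat).statistic if len(ivs) > 1 else np.nan
    return ValidationMetrics(
        pve=pve(ivs.y, yhat),
        rmse=rmse(ivs.y, yhat),
        r2=float(r ** 2),
        n=len(ivs),
    )


def predict(model: QsarModel, molecules: list[MoleculeRecord] | list[str],
            ad_threshold: float = 0.7, ad_rule: str = "distance") -> pd.DataFrame:
    """Predict the model endpoint for each molecule, with an AD verdict per row.

    Accepts records or raw SMILES strings.  Unparsable molecules are kept
    as flagged rows with NaN predictions rather than silently dropped.
    Predictions are on the endpoint's native scale (spIC50 or logBB).
    """
    rows = []
    for i, m in enumerate(molecules):
        if isinstance(m, MoleculeRecord):
            mol_id, smiles = m.id, m.smiles_canonical
        else:
            mol_id, smiles = f"mol-{i}", m
        canon = canonicalize(smiles)
        if canon is None:
            rows.append({"id": mol_id, "smiles": smiles, "prediction": np.nan,
                         "nn_similarity": np.nan, "in_domain": False,
                         "parse_error": True})
            continue
        fp = fingerprint(canon, model.scheme, model.nbits)
        verdict = applicability_domain(fp.bits, model, ad_threshold, ad_rule)
        yhat = _predict_bits(model, fp.bits[None, :])[0]
        rows.append({"id": mol_id, "smiles": canon, "prediction": float(yhat),
                     "nn_similarity": verdict.nn_similarity,
                     "in_domain": verdict.in_domain, "parse_error": False})
    columns = ["id", "smiles", "prediction", "nn_similarity", "in_domain",
               "parse_error"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# serialization


def save_model(model: QsarModel, path) -> None:
    """Serialize a model to a directory (metadata JSON + regressor + fingerprints)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dict(model.metadata)
    meta.update({
        "endpoint": model.endpoint,
        "selected_bits": [int(b) for b in model.selected_bits],
        "train_smiles": model.train_smiles,
        "ranking_order": [int(b) for b in model.ranking.order],
        "vi_scores": [float(v) for v in model.ranking.vi_scores],
    })
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    joblib.dump(model.regressor, path / "regressor.joblib")
    np.save(path / "train_fingerprints.npy", model.train_fingerprints)


def load_model(path) -> QsarModel:
    """Load a model saved by :func:`save_model`; predictions round-trip exactly."""
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    ranking = FeatureRanking(
        order=np.asarray(meta.pop("ranking_order"), dtype=int),
        vi_scores=np.asarray(meta.pop("vi_scores"), dtype=float),
        n_trees=meta.get("n_trees", 0),
        seed=meta.get("ranking_seed", 0),
    )
    return QsarModel(
        endpoint=meta.pop("endpoint"),
        ranking=ranking,
        selected_bits=np.asarray(meta.pop("selected_bits"), dtype=int),
        regressor=joblib.load(path / "regressor.joblib"),
        train_fingerprints=np.load(path / "train_fingerprints.npy"),
        train_smiles=list(meta.pop("train_smiles")),
        metadata=meta,
    )
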