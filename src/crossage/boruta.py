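"""All-relevant feature selection with shadow attributes (Boruta).

Each real feature competes against a permuted copy of itself inside a
random forest: a feature scores a "hit" in a run when its importance
exceeds the best shadow importance, and repeated hit counts are turned
into confirmed / tentative / rejected decisions by a two-sided binomial
test (p = 0.5) with Bonferroni correction over the still-undecided
attributes. Rejected features are removed from subsequent runs;
confirmed features stay in the model, since they still shape
multivariate importance. The engine is run as an iterated ensemble:
independent repetitions whose meanImp and normHits are averaged and
whose non-rejections are counted per feature.

Two target modes mirror the numerical- vs categorical-dependent
variable analyses (NVA / CVA): age as a number drives a regression
forest, age as a class label a classification forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

CONFIRMED = "confirmed"
TENTATIVE = "tentative"
REJECTED = "rejected"


@dataclass(frozen=True)
class BorutaConfig:
    n_trees: int = 500
    max_runs: int = 100
    alpha: float = 0.01
    multiple_testing: bool = True  # Bonferroni over undecided attributes
    mode: str = "numeric"  # "numeric" (regression) or "categorical"
    n_iterations: int = 30
    min_nonrejected_iterations: int = 1
    seed: int = 0
    importance: str = "impurity"  # "impurity" (per-tree Z) or "permutation"
    max_features: str | float = "sqrt"

    def __post_init__(self) -> None:
        if self.max_runs < 5:
            raise ValueError("max_runs must be >= 5")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.mode not in ("numeric", "categorical"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError(f"unknown importance {self.importance!r}")


@dataclass
class BorutaRunResult:
    decision: pd.Series  # feature -> confirmed/tentative/rejected
    mean_imp: pd.Series  # mean importance over runs feature was present
    norm_hits: pd.Series  # hits / runs present
    runs_present: pd.Series
    n_runs: int

    @property
    def confirmed(self) -> list[str]:
        return list(self.decision.index[self.decision == CONFIRMED])

    @property
    def nonrejected(self) -> list[str]:
        return list(self.decision.index[self.decision != REJECTED])


@dataclass
class BorutaEnsemble:
    n_nonrejected: pd.Series  # iterations with decision != rejected
    n_confirmed: pd.Series
    mean_imp: pd.Series  # mean over iterations of per-iteration meanImp
    norm_hits: pd.Series
    n_iterations: int
    min_nonrejected_iterations: int
    runs: list[BorutaRunResult] = field(default_factory=list, repr=False)

    @property
    def hit_set(self) -> list[str]:
        mask = self.n_nonrejected >= self.min_nonrejected_iterations
        return list(self.n_nonrejected.index[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_nonrejected": self.n_nonrejected,
                "n_confirmed": self.n_confirmed,
                "meanImp": self.mean_imp,
                "normHits": self.norm_hits,
            }
        ).rename_axis("feature")


@dataclass(frozen=True)
class PredictionEval:
    accuracy: float
    kappa: float
    folds: int
    mode: str
    confusion: np.ndarray

    def __post_init__(self) -> None:
        acc = np.trace(self.confusion) / self.confusion.sum()
        if not np.isclose(acc, self.accuracy, atol=1e-9):
            raise ValueError("accuracy inconsistent with confusion matrix")


def kappa_from_confusion(cm: np.ndarray) -> float:
    """Cohen's kappa from a confusion matrix: (p_o - p_e) / (1 - p_e)."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) / total) @ (cm.sum(axis=0) / total))
    if np.isclose(p_e, 1.0):
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def shadow_augment(X: pd.DataFrame, seed: int | np.random.Generator) -> pd.DataFrame:
    """Append one independently permuted ("shadow") copy of every column."""
    if X.shape[1] < 1 or X.shape[0] < 2:
        raise ValueError("need >= 1 feature and >= 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shadows = {
        f"shadow_{c}": rng.permutation(X[c].to_numpy()) for c in X.columns
    }
    return pd.concat([X, pd.DataFrame(shadows, index=X.index)], axis=1)


def decide(hits: int, runs: int, alpha: float, m: int) -> str:
    """Binomial decision on a hit count: confirmed / rejected / tentative.

    Two-sided test at p = 0.5 with the significance level divided by the
    number of undecided attributes ``m`` (Bonferroni).
    """
    if not 0 <= hits <= runs:
        raise ValueError("hits must lie in [0, runs]")
    if runs == 0:
        return TENTATIVE
    thr = alpha / max(m, 1)
    if stats.binom.sf(hits - 1, runs, 0.5) < thr:
        return CONFIRMED
    if stats.binom.cdf(hits, runs, 0.5) < thr:
        return REJECTED
    return TENTATIVE


def _importance_z(model, X: np.ndarray, y: np.ndarray, method: str,
                  rng: np.random.Generator) -> np.ndarray:
    if method == "impurity":
        per_tree = np.stack([t.feature_importances_ for t in model.estimators_])
        mean = per_tree.mean(axis=0)
        sd = per_tree.std(axis=0, ddof=0)
        return np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), mean / 1e-12)
    res = permutation_importance(
        model, X, y, n_repeats=5, random_state=int(rng.integers(2**31))
    )
    sd = res.importances_std
    return np.where(sd > 0, res.importances_mean / np.where(sd > 0, sd, 1.0),
                    res.importances_mean / 1e-12)


def _make_forest(config: BorutaConfig, seed: int):
    kwargs = dict(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        random_state=seed,
        n_jobs=1,
    )
    if config.mode == "numeric":
        return RandomForestRegressor(**kwargs)
    return RandomForestClassifier(**kwargs)


def boruta_run(X: pd.DataFrame, y, config: BorutaConfig) -> BorutaRunResult:
    """One Boruta process: iterated shadow comparison until all features
    are decided or ``max_runs`` is reached (undecided -> tentative)."""
    X = pd.DataFrame(X)
    bad = [c for c in X.columns if not np.isfinite(X[c].to_numpy(dtype=float)).all()]
    if bad:
        raise ValueError(f"non-finite values in feature columns: {bad[:10]}")
    y_arr = np.asarray(y)
    if config.mode == "numeric":
        y_arr = y_arr.astype(float)
        if not np.isfinite(y_arr).all():
            raise ValueError("non-finite values in target")

    rng = np.random.default_rng(config.seed)
    features = list(X.columns)
    decision = {f: None for f in features}
    hits = {f: 0 for f in features}
    imp_sum = {f: 0.0 for f in features}
    present = {f: 0 for f in features}
    active = list(features)  # not-yet-rejected
    n_runs = 0

    for _ in range(config.max_runs):
        undecided = [f for f in active if decision[f] is None]
        if not undecided:
            break
        n_runs += 1
        Xa = X[active]
        aug = shadow_augment(Xa, rng)
        model = _make_forest(config, int(rng.integers(2**31)))
        Xmat = aug.to_numpy(dtype=float)
        model.fit(Xmat, y_arr)
        z = _importance_z(model, Xmat, y_arr, config.importance, rng)
        n_active = len(active)
        real_z = dict(zip(active, z[:n_active]))
        shadow_max = z[n_active:].max()
        for f in active:
            imp_sum[f] += real_z[f]
            present[f] += 1
            if real_z[f] > shadow_max:
                hits[f] += 1
        m = len(undecided)
        for f in undecided:
            d = decide(hits[f], present[f], config.alpha, m if config.multiple_testing else 1)
            if d != TENTATIVE:
                decision[f] = d
        active = [f for f in active if decision[f] != REJECTED]

    final = pd.Series(
        {f: (decision[f] if decision[f] is not None else TENTATIVE) for f in features}
    )
    runs_present = pd.Series(present)
    mean_imp = pd.Series(
        {f: (imp_sum[f] / present[f] if present[f] else 0.0) for f in features}
    )
    norm_hits = pd.Series(
        {f: (hits[f] / present[f] if present[f] else 0.0) for f in features}
    )
    return BorutaRunResult(
        decision=final.loc[features],
        mean_imp=mean_imp.loc[features],
        norm_hits=norm_hits.loc[features],
        runs_present=runs_present.loc[features],
        n_runs=n_runs,
    )


def boruta_ensemble(X: pd.DataFrame, y, config: BorutaConfig) -> BorutaEnsemble:
    """Repeat the Boruta process with independent derived seeds and
    aggregate: meanImp/normHits averaged over iterations, non-rejections
    counted, the hit set thresholded on ``min_nonrejected_iterations``."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_iterations)
    runs = []
    for child in children:
        it_seed = int(child.generate_state(1)[0] % (2**31))
        runs.append(boruta_run(X, y, replace(config, seed=it_seed)))
    features = runs[0].decision.index
    dec = pd.DataFrame({i: r.decision for i, r in enumerate(runs)})
    n_nonrejected = (dec != REJECTED).sum(axis=1)
    n_confirmed = (dec == CONFIRMED).sum(axis=1)
    mean_imp = pd.DataFrame({i: r.mean_imp for i, r in enumerate(runs)}).mean(axis=1)
    norm_hits = pd.DataFrame({i: r.norm_hits for i, r in enumerate(runs)}).mean(axis=1)
    return BorutaEnsemble(
        n_nonrejected=n_nonrejected.loc[features],
        n_confirmed=n_confirmed.loc[features],
        mean_imp=mean_imp.loc[features],
        norm_hits=norm_hits.loc[features],
        n_iterations=config.n_iterations,
        min_nonrejected_iterations=config.min_nonrejected_iterations,
        runs=runs,
    )


def evaluate_prediction(X: pd.DataFrame, y, feature_subset=None, mode: str = "numeric",
                        folds: int = 10, seed: int = 0, n_trees: int = 200) -> PredictionEval:
    """Cross-validated forest accuracy and Cohen's kappa.

    Numeric mode fits a regression forest and snaps each prediction to
    the nearest observed target level before scoring, so accuracy and
    kappa are comparable between the numeric and categorical analyses.
    """
    X = pd.DataFrame(X)
    if feature_subset is not None:
        X = X[list(feature_subset)]
    y_arr = np.asarray(y)
    labels = np.unique(y_arr)
    if len(labels) < 2:
        raise ValueError("target must have >= 2 classes")
    y_codes = np.searchsorted(labels, y_arr)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    Xmat = X.to_numpy(dtype=float)
    pred_codes = np.empty_like(y_codes)
    for i, (tr, te) in enumerate(skf.split(Xmat, y_codes)):
        if mode == "numeric":
            model = RandomForestRegressor(
                n_estimators=n_trees, max_features="sqrt", random_state=seed + i, n_jobs=1
            )
            model.fit(Xmat[tr], y_arr[tr].astype(float))
            raw = model.predict(Xmat[te])
            # snap to nearest design level
            pred_codes[te] = np.abs(raw[:, None] - labels[None, :].astype(float)).argmin(axis=1)
        elif mode == "categorical":
            model = RandomForestClassifier(
                n_estimators=n_trees, max_features="sqrt", random_state=seed + i, n_jobs=1
            )
            model.fit(Xmat[tr], y_codes[tr])
            pred_codes[te] = model.predict(Xmat[te])
        else:
            raise ValueError(f"unknown mode {mode!r}")
    cm = confusion_matrix(y_codes, pred_codes, labels=np.arange(len(labels)))
    acc = float(np.trace(cm) / cm.sum())
    return PredictionEval(
        accuracy=acc, kappa=kappa_from_confusion(cm), folds=folds, mode=mode, confusion=cm
    )
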