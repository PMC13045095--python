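"""Boosted-regression-tree habitat model: fitting, selection and evaluation.

The response is binary (presence = 1, CRW pseudo-absence = 0) and the learner
is a gradient-boosted tree ensemble with Bernoulli deviance loss. Tree
induction is delegated to scikit-learn's ``GradientBoostingClassifier``;
everything the analysis depends on beyond single-model fitting is implemented
here:

* stagewise tree-number selection by cross-validated deviance (the
  ``gbm.step`` procedure: grow in increments, track mean held-out deviance
  over k folds, stop after it fails to improve, refit at the optimum);
* the presence:background ratio experiment (1:1 .. 1:5 at fixed learning
  rate 0.01 and tree complexity 5);
* the learning-rate x tree-complexity grid search;
* the five evaluation metrics (AUC, C-index, pseudo-R2, RMSE, predicted/
  observed ratio) under three regimes: 100/100 (train = test), 75/25 split,
  and 10-fold cross-validation;
* relative influence (per-variable share of loss reduction, summing to 100).

"Tree complexity" maps to the maximum interaction depth of each tree; the
bag fraction is the per-tree row subsample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from lostyears.covariates import MODEL_VARIABLES

log = logging.getLogger(__name__)

LR_GRID = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.3, 0.5)
TC_GRID = (3, 4, 5)
RATIOS = (1, 2, 3, 4, 5)
MIN_TREES = 50


@dataclass
class BRTConfig:
    """Hyperparameters of one boosted-tree model."""

    learning_rate: float = 0.01
    tree_complexity: int = 5
    bag_fraction: float = 0.6
    n_trees: int | None = None  # selected stagewise, not fixed a priori
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.tree_complexity < 1 or not 0 < self.bag_fraction <= 1:
            raise ValueError("invalid BRT hyperparameters")


@dataclass
class FittedModel:
    """A trained ensemble plus its provenance."""

    estimator: GradientBoostingClassifier
    config: BRTConfig
    variables: tuple[str, ...]
    n_rows: int
    cv_deviance: float | None = None
    cv_null_deviance: float | None = None
    cv_curve: pd.DataFrame | None = None

    @property
    def cv_pseudo_r2(self) -> float | None:
        if self.cv_deviance is None or not self.cv_null_deviance:
            return None
        return 1.0 - self.cv_deviance / self.cv_null_deviance

    def predict(self, X) -> np.ndarray:
        """Suitability (probability of presence) in [0, 1]."""
        X = np.asarray(X, dtype=float)
        return self.estimator.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def bernoulli_deviance(y, p, eps: float = 1e-12) -> float:
    """Mean Bernoulli deviance -2/n * sum(y log p + (1-y) log(1-p))."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def auc_score(y, p) -> float:
    """Rank-based AUC: probability a presence outranks an absence (ties 1/2)."""
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: single-class data")
    r = rankdata(p)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def c_index(y, p) -> float:
    """Concordance over presence-absence pairs, ties counted as 1/2.

    For a binary response this coincides with the rank-based AUC; both are
    computed so the equivalence can be verified rather than assumed.
    """
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    pres = np.sort(p[y == 1])
    absn = np.sort(p[y == 0])
    if len(pres) == 0 or len(absn) == 0:
        raise ValueError("C-index undefined: single-class data")
    # count concordant and tied pairs via searchsorted on the sorted absences
    lower = np.searchsorted(absn, pres, side="left")
    upper = np.searchsorted(absn, pres, side="right")
    concordant = lower.sum()
    ties = (upper - lower).sum()
    return float((concordant + 0.5 * ties) / (len(pres) * len(absn)))


def metric_table(y, p) -> dict:
    """The five evaluation metrics on one test set."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    prevalence = y.mean()
    null_dev = bernoulli_deviance(y, np.full_like(y, prevalence))
    dev = bernoulli_deviance(y, p)
    return {
        "auc": auc_score(y, p),
        "c_index": c_index(y, p),
        "pseudo_r2": 1.0 - dev / null_dev if null_dev > 0 else float("nan"),
        "rmse": float(np.sqrt(np.mean((y - p) ** 2))),
        "pred_obs_ratio": float(p.sum() / y.sum()),
    }


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def assemble_dataset(table: pd.DataFrame, ratio: int, seed: int = 0,
                     variables: tuple[str, ...] = MODEL_VARIABLES) -> pd.DataFrame:
    """Build a 1:ratio presence:pseudo-absence dataset.

    All presence rows are kept; ``ratio * n_presence`` pseudo-absence rows
    are drawn uniformly without replacement from the entire CRW pool.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    pres = table[table["label"] == 1]
    absn = table[table["label"] == 0]
    need = ratio * len(pres)
    if need > len(absn):
        raise ValueError(
            f"need {need} pseudo-absence rows for ratio 1:{ratio} with "
            f"{len(pres)} presences; only {len(absn)} available")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(absn), size=need, replace=False)
    out = pd.concat([pres, absn.iloc[np.sort(pick)]], ignore_index=True)
    missing = [v for v in variables if v not in out.columns]
    if missing:
        raise KeyError(f"dataset missing covariates: {missing}")
    return out


def _xy(data: pd.DataFrame, variables):
    return data[list(variables)].to_numpy(dtype=float), data["label"].to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# stagewise fitting
# ---------------------------------------------------------------------------

def fit_brt(data: pd.DataFrame, config: BRTConfig, step_size: int = 50,
            cv_folds: int = 10, max_trees: int = 1000, patience: int = 3,
            variables: tuple[str, ...] = MODEL_VARIABLES) -> FittedModel:
    """Fit a BRT with stagewise cross-validated tree-number selection.

    The ensemble grows in increments of ``step_size`` trees simultaneously in
    ``cv_folds`` stratified folds (warm-started); at each stage the mean
    held-out Bernoulli deviance is recorded. Growth stops when the mean CV
    deviance has not improved for ``patience`` consecutive stages (or at
    ``max_trees``); the tree count minimizing mean CV deviance is selected
    and the final model refit on all rows. A selection below 50 trees
    triggers the standard advice to lower the learning rate.
    """
    X, y = _xy(data, variables)
    if len(np.unique(y)) < 2:
        raise ValueError("data must contain both labels")
    if len(y) < 2 * cv_folds:
        raise ValueError("too few rows for the requested number of CV folds")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))
    models = []
    for k, (tr, _) in enumerate(folds):
        models.append(GradientBoostingClassifier(
            learning_rate=config.learning_rate, max_depth=config.tree_complexity,
            subsample=config.bag_fraction, n_estimators=0, warm_start=True,
            random_state=config.seed + 1000 + k))
    null_devs = []
    for tr, te in folds:
        prev = y[tr].mean()
        null_devs.append(bernoulli_deviance(y[te], np.full(len(te), prev)))
    cv_null = float(np.mean(null_devs))

    stages = []
    mean_devs = []
    best_dev = np.inf
    since_best = 0
    n = 0
    while n < max_trees:
        n += step_size
        fold_devs = []
        for m, (tr, te) in zip(models, folds):
            m.set_params(n_estimators=n)
            m.fit(X[tr], y[tr])
            p = m.predict_proba(X[te])[:, 1]
            fold_devs.append(bernoulli_deviance(y[te], p))
        d = float(np.mean(fold_devs))
        stages.append(n)
        mean_devs.append(d)
        if d < best_dev - 1e-9:
            best_dev = d
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    i_best = int(np.argmin(mean_devs))
    n_best = stages[i_best]
    if n_best < MIN_TREES:
        warnings.warn(
            f"selected n_trees = {n_best} < {MIN_TREES}; consider a smaller learning rate")
    final = GradientBoostingClassifier(
        learning_rate=config.learning_rate, max_depth=config.tree_complexity,
        subsample=config.bag_fraction, n_estimators=n_best, random_state=config.seed)
    final.fit(X, y)
    return FittedModel(
        estimator=final, config=replace(config, n_trees=n_best), variables=tuple(variables),
        n_rows=len(y), cv_deviance=float(mean_devs[i_best]), cv_null_deviance=cv_null,
        cv_curve=pd.DataFrame({"n_trees": stages, "cv_deviance": mean_devs}))


def _refit(model: FittedModel, X, y, seed: int) -> GradientBoostingClassifier:
    cfg = model.config
    est = GradientBoostingClassifier(
        learning_rate=cfg.learning_rate, max_depth=cfg.tree_complexity,
        subsample=cfg.bag_fraction, n_estimators=cfg.n_trees or MIN_TREES,
        random_state=seed)
    est.fit(X, y)
    return est


# ---------------------------------------------------------------------------
# evaluation regimes
# ---------------------------------------------------------------------------

REGIMES = ("full", "split75", "kfold10")


def evaluate(model: FittedModel, data: pd.DataFrame, regime: str, seed: int = 0) -> dict:
    """Five-metric evaluation under one regime.

    ``full``: score the fitted model on the whole dataset (train = test).
    ``split75``: refit at the selected tree count on a stratified 75% and
    score the held-out 25%. ``kfold10``: refit per stratified fold, score the
    held-out 10%, average the metrics over the 10 folds. Tree count is the
    one already selected on the full dataset.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    X, y = _xy(data, model.variables)
    if regime == "full":
        return metric_table(y, model.predict(X))
    if regime == "split75":
        itr, ite = train_test_split(np.arange(len(y)), test_size=0.25,
                                    stratify=y, random_state=seed)
        if len(np.unique(y[ite])) < 2:
            raise ValueError("single-class test partition")
        est = _refit(model, X[itr], y[itr], seed)
        return metric_table(y[ite], est.predict_proba(X[ite])[:, 1])
    # kfold10
    skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
    rows = []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[te])) < 2:
            raise ValueError("single-class test partition in fold")
        est = _refit(model, X[tr], y[tr], seed + k)
        rows.append(metric_table(y[te], est.predict_proba(X[te])[:, 1]))
    return {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}


def evaluate_all(model: FittedModel, data: pd.DataFrame, seed: int = 0,
                 regimes=REGIMES) -> pd.DataFrame:
    """EvalReport: the five metrics under the requested regimes + the
    cross-regime mean of the 100/100 and 75/25 rows (the headline row)."""
    rows = {r: evaluate(model, data, r, seed) for r in regimes}
    if "full" in rows and "split75" in rows:
        rows["mean_full_split75"] = {
            k: 0.5 * (rows["full"][k] + rows["split75"][k]) for k in rows["full"]}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _rank_key(row) -> tuple:
    # higher AUC, then higher pseudo-R2, then lower RMSE
    return (-row["auc"], -row["pseudo_r2"], row["rmse"])


def ratio_experiment(table: pd.DataFrame, ratios=RATIOS, learning_rate: float = 0.01,
                     tree_complexity: int = 5, seed: int = 0,
                     variables=MODEL_VARIABLES, **fit_kw) -> tuple[int, pd.DataFrame]:
    """Fit one model per presence:background ratio and pick the best.

    Models use the fixed learning rate 0.01 and tree complexity 5; the winner
    has the best mean AUC over the 100/100 and 75/25 regimes, ties broken by
    pseudo-R2 then RMSE. Returns (best ratio, comparison table).
    """
    records = []
    for r in ratios:
        ds = assemble_dataset(table, r, seed=seed + r, variables=variables)
        cfg = BRTConfig(learning_rate=learning_rate, tree_complexity=tree_complexity, seed=seed)
        model = fit_brt(ds, cfg, variables=variables, **fit_kw)
        rep = evaluate_all(model, ds, seed=seed)
        row = rep.loc["mean_full_split75"].to_dict()
        row.update(ratio=r, n_trees=model.config.n_trees)
        records.append(row)
    report = pd.DataFrame(records).set_index("ratio")
    best = min(report.index, key=lambda r: _rank_key(report.loc[r]))
    return int(best), report


def grid_search(table: pd.DataFrame, lr_grid=LR_GRID, tc_grid=TC_GRID, ratio: int = 1,
                seed: int = 0, variables=MODEL_VARIABLES,
                **fit_kw) -> tuple[BRTConfig, pd.DataFrame]:
    """Learning-rate x tree-complexity grid search at a fixed ratio.

    Every combination is fitted (stagewise tree selection) and evaluated
    under all three regimes; the winner maximizes the mean AUC of the 100/100
    and 75/25 regimes, ties broken by pseudo-R2 then RMSE. Cells whose
    selected tree count falls below 50 are kept in the leaderboard and
    flagged, not treated as fatal.
    """
    if not lr_grid or not tc_grid:
        raise ValueError("grids must be nonempty")
    ds = assemble_dataset(table, ratio, seed=seed, variables=variables)
    records = []
    for lr in lr_grid:
        for tc in tc_grid:
            cfg = BRTConfig(learning_rate=lr, tree_complexity=tc, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_brt(ds, cfg, variables=variables, **fit_kw)
            rep = evaluate_all(model, ds, seed=seed)
            rec = {"learning_rate": lr, "tree_complexity": tc,
                   "n_trees": model.config.n_trees,
                   "under_min_trees": model.config.n_trees < MIN_TREES}
            for regime in rep.index:
                for m, val in rep.loc[regime].items():
                    rec[f"{regime}_{m}"] = val
            rec["auc"] = rec["mean_full_split75_auc"]
            rec["pseudo_r2"] = rec["mean_full_split75_pseudo_r2"]
            rec["rmse"] = rec["mean_full_split75_rmse"]
            records.append(rec)
            log.info("grid cell lr=%g tc=%d: n_trees=%d auc=%.3f", lr, tc,
                     model.config.n_trees, rec["auc"])
    board = pd.DataFrame(records)
    board = board.sort_values(by=["auc", "pseudo_r2", "rmse"],
                              ascending=[False, False, True],
                              kind="stable").reset_index(drop=True)
    best = board.iloc[0]
    cfg = BRTConfig(learning_rate=float(best["learning_rate"]),
                    tree_complexity=int(best["tree_complexity"]),
                    n_trees=int(best["n_trees"]), seed=seed)
    return cfg, board


def relative_influence(model: FittedModel) -> pd.Series:
    """Per-variable relative influence, in percent summing to 100.

    The per-variable reduction in loss aggregated over every split of every
    tree; variables never split on get exactly 0.
    """
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:
        imp = np.full_like(imp, 1.0 / len(imp))
        total = 1.0
    pct = 100.0 * imp / total
    return pd.Series(pct, index=list(model.variables)).sort_values(ascending=False)
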