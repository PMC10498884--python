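"""Outcome prediction: elastic-net cluster classifiers and a multiobjective
evolutionary search for a minimal prognostic protein signature.

``moea_select`` runs an NSGA-II loop over chromosomes that combine a feature
bitmask with real-coded SVM hyperparameters (log2 C, log2 gamma).  The two
objectives are (maximize mean stratified k-fold CV AUC of an RBF SVM on the
masked features, minimize subset size).  The final model is the smallest
subset whose AUC is within a parsimony tolerance of the front's best — the
procedure behind a compact plaque-protein outcome signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ElasticNetModel", "MoeaConfig", "ParetoFront",
    "fit_elasticnet", "cv_auc", "moea_select", "final_signature_model",
]


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------

@dataclass
class ElasticNetModel:
    features: list[str]
    coefficients: pd.DataFrame        # classes x features
    intercept: np.ndarray
    mixing: float                     # alpha in [0,1]; 1 = lasso
    C: float                          # inverse penalty strength
    selected: list[str]               # nonzero-coefficient features
    classes: list
    estimator: object
    scaler: StandardScaler


def fit_elasticnet(features: pd.DataFrame, labels, mixing: float = 0.5,
                   seed: int = 0, cv: int = 5, Cs=None,
                   C: float | None = None,
                   one_se_rule: bool = True) -> ElasticNetModel:
    """Penalized (elastic-net) logistic regression with internal CV on
    deviance choosing the penalty, unless ``C`` is given explicitly.

    With ``one_se_rule`` (default) the strongest penalty whose CV deviance is
    within one standard error of the optimum is refit — the conventional
    parsimony rule for feature selection; otherwise the deviance-minimising
    penalty is used.  Features are standardized internally; constant features
    get coefficient 0 with a warning.  Works for binary and multiclass
    labels.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    x = features.to_numpy(dtype=float)
    scaler = StandardScaler()
    const = x.std(axis=0) == 0
    if const.any():
        warnings.warn(f"constant features get zero coefficients: "
                      f"{list(features.columns[const])}", stacklevel=2)
    xs = scaler.fit_transform(x)
    xs[:, const] = 0.0
    if C is None:
        if Cs is None:
            # grid fine enough for the 1-SE rule to find a sparser penalty
            Cs = np.logspace(-3, 2, 26)
        cv_est = LogisticRegressionCV(
            Cs=Cs, penalty="elasticnet", solver="saga", l1_ratios=[mixing],
            scoring="neg_log_loss",
            cv=StratifiedKFold(cv, shuffle=True, random_state=seed),
            max_iter=5000, tol=1e-4, random_state=seed)
        cv_est.fit(xs, y)
        c_used = float(np.atleast_1d(cv_est.C_)[0])
        if one_se_rule:
            # scores_: folds x Cs (x l1_ratios) per class; average classes
            score_mat = np.mean([np.asarray(v)[..., 0] if np.asarray(v).ndim == 3
                                 else np.asarray(v)
                                 for v in cv_est.scores_.values()], axis=0)
            mean = score_mat.mean(axis=0)
            se = score_mat.std(axis=0, ddof=1) / np.sqrt(score_mat.shape[0])
            best = int(np.argmax(mean))
            ok = np.where(mean >= mean[best] - se[best])[0]
            c_used = float(cv_est.Cs_[ok.min()])  # Cs_ ascending: min = sparsest
        est = LogisticRegression(penalty="elasticnet", solver="saga",
                                 l1_ratio=mixing, C=c_used, max_iter=5000,
                                 tol=1e-4, random_state=seed)
        est.fit(xs, y)
    else:
        est = LogisticRegression(penalty="elasticnet", solver="saga",
                                 l1_ratio=mixing, C=C, max_iter=5000,
                                 tol=1e-6, random_state=seed)
        est.fit(xs, y)
        c_used = float(C)
    coef = pd.DataFrame(est.coef_, columns=features.columns,
                        index=list(est.classes_) if est.coef_.shape[0] > 1
                        else [est.classes_[1]])
    selected = [c for c in features.columns
                if np.any(np.abs(coef[c]) > 1e-10)]
    return ElasticNetModel(
        features=list(features.columns), coefficients=coef,
        intercept=np.asarray(est.intercept_), mixing=mixing, C=c_used,
        selected=selected, classes=list(est.classes_), estimator=est,
        scaler=scaler)


# ---------------------------------------------------------------------------
# cross-validated AUC
# ---------------------------------------------------------------------------

def _default_svm(log2c: float = 0.0, log2gamma: float | None = None):
    gamma = "scale" if log2gamma is None else 2.0 ** log2gamma
    return make_pipeline(StandardScaler(),
                         SVC(C=2.0 ** log2c, gamma=gamma, kernel="rbf"))


def cv_auc(features: pd.DataFrame | np.ndarray, labels, estimator=None,
           folds: int = 10, seed: int = 0, pooled: bool = False,
           splits=None) -> float:
    """Mean out-of-fold AUC under stratified k-fold CV.

    Default aggregation is the mean of per-fold AUCs (robust to fold-size
    imbalance); ``pooled=True`` computes one AUC on the pooled out-of-fold
    scores instead.  ``splits`` allows reusing fold indices (common random
    numbers across candidate models).
    """
    x = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("cv_auc requires a binary outcome")
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} members < {folds} folds; "
            "use fewer folds")
    if estimator is None:
        estimator = _default_svm()
    if splits is None:
        skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
        splits = list(skf.split(x, y))
    from sklearn.base import clone
    fold_aucs, pooled_scores, pooled_y = [], [], []
    for train, test in splits:
        est = clone(estimator)
        est.fit(x[train], y[train])
        if hasattr(est, "decision_function"):
            s = est.decision_function(x[test])
        else:
            s = est.predict_proba(x[test])[:, 1]
        if len(np.unique(y[test])) == 2:
            fold_aucs.append(roc_auc_score(y[test], s))
        pooled_scores.append(s)
        pooled_y.append(y[test])
    if pooled:
        return float(roc_auc_score(np.concatenate(pooled_y),
                                   np.concatenate(pooled_scores)))
    return float(np.mean(fold_aucs))


# ---------------------------------------------------------------------------
# NSGA-II feature-subset + hyperparameter search
# ---------------------------------------------------------------------------

@dataclass
class MoeaConfig:
    candidate_features: tuple[str, ...] = ()
    population: int = 64
    generations: int = 100
    crossover_p: float = 0.9
    mutation_p: float | None = None       # default 1/L bit-flip
    log2c_bounds: tuple[float, float] = (-5.0, 15.0)
    log2gamma_bounds: tuple[float, float] = (-15.0, 3.0)
    cv_folds: int = 10
    seed: int = 0
    parsimony_tol: float = 0.01
    init_bit_p: float = 0.15
    early_stop_patience: int | None = None  # stop after N unchanged fronts

    def validate(self, n_features: int) -> None:
        if self.population < 4 or self.population % 2:
            raise ValueError("population must be even and >= 4")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for lo, hi in (self.log2c_bounds, self.log2gamma_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("hyperparameter bounds must be finite, lo<hi")
        if n_features == 0:
            raise ValueError("no candidate features present in the data")


@dataclass
class Solution:
    features: tuple[str, ...]
    log2c: float
    log2gamma: float
    mean_cv_auc: float
    size: int


@dataclass
class ParetoFront:
    solutions: list[Solution]
    selected: int                      # index of the final (parsimonious) model

    def selected_solution(self) -> Solution:
        return self.solutions[self.selected]


def _fast_nondominated_sort(objs: np.ndarray) -> list[np.ndarray]:
    """Fronts of indices for minimization objectives (rows = individuals)."""
    n = objs.shape[0]
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(objs[i], objs[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif _dominates(objs[j], objs[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts = []
    current = np.where(dom_count == 0)[0]
    while current.size:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(set(nxt)), dtype=int)
    return fronts


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def _crowding(objs: np.ndarray, front: np.ndarray) -> np.ndarray:
    dist = np.zeros(front.size)
    for m in range(objs.shape[1]):
        order = front[np.argsort(objs[front, m], kind="stable")]
        span = objs[order[-1], m] - objs[order[0], m]
        pos = {idx: k for k, idx in enumerate(order)}
        for k, idx in enumerate(order):
            if k == 0 or k == order.size - 1:
                dist[np.where(front == idx)[0][0]] = np.inf
            elif span > 0:
                gain = (objs[order[k + 1], m] - objs[order[k - 1], m]) / span
                dist[np.where(front == idx)[0][0]] += gain
    return dist


def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank-sum (Mann-Whitney) identity; ties get average rank."""
    from scipy.stats import rankdata
    y_true = np.asarray(y_true, dtype=bool)
    n1 = int(y_true.sum())
    n0 = y_true.size - n1
    if n0 == 0 or n1 == 0:
        return np.nan
    ranks = rankdata(scores)
    return float((ranks[y_true].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


class _FoldedSvmCV:
    """Stratified folds fixed for a whole search run, with per-fold feature
    standardization precomputed, so evaluating one chromosome costs only the
    SVM fits.  Results are cached by (mask, hyperparameters)."""

    def __init__(self, x: np.ndarray, y: np.ndarray, folds: int, seed: int):
        skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
        self.y = y
        self.folds = []
        for train, test in skf.split(x, y):
            mu = x[train].mean(axis=0)
            sd = x[train].std(axis=0)
            sd[sd == 0] = 1.0
            self.folds.append((train, test, mu, sd))
        self.x = x
        self.cache: dict = {}

    def mean_auc(self, mask: np.ndarray, log2c: float, log2g: float) -> float:
        key = (mask.tobytes(), round(log2c, 5), round(log2g, 5))
        if key in self.cache:
            return self.cache[key]
        cols = np.where(mask)[0]
        aucs = []
        try:
            for train, test, mu, sd in self.folds:
                xt = (self.x[np.ix_(train, cols)] - mu[cols]) / sd[cols]
                xv = (self.x[np.ix_(test, cols)] - mu[cols]) / sd[cols]
                # iteration cap keeps pathological hyperparameter corners from
                # dominating the search runtime; weak fits are discarded by
                # selection anyway
                svc = SVC(C=2.0 ** log2c, gamma=2.0 ** log2g, kernel="rbf",
                          max_iter=2000)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    svc.fit(xt, self.y[train])
                s = svc.decision_function(xv)
                a = _rank_auc(self.y[test], s)
                if not np.isnan(a):
                    aucs.append(a)
            auc = float(np.mean(aucs))
        except Exception:
            auc = 0.0
        self.cache[key] = auc
        return auc


def moea_select(data: pd.DataFrame, outcome, cfg: MoeaConfig) -> ParetoFront:
    """NSGA-II search over feature subsets and RBF-SVM hyperparameters.

    See :func:`_moea_select`; input validation is skipped inside the loop
    (the data are validated once up front) to keep evaluations cheap.
    """
    import sklearn
    data = data.astype(float)
    if data.isna().any().any():
        raise ValueError("candidate features contain missing values")
    with sklearn.config_context(assume_finite=True,
                                skip_parameter_validation=True):
        return _moea_select(data, outcome, cfg)


def _moea_select(data: pd.DataFrame, outcome, cfg: MoeaConfig) -> ParetoFront:
    """NSGA-II loop.

    Chromosome = feature bitmask (uniform crossover, 1/L bit-flip mutation,
    empty masks repaired by activating one random bit) + (log2 C, log2 gamma)
    (arithmetic crossover, Gaussian mutation, clipped to bounds).  One set of
    stratified fold splits is drawn per run and shared by every individual
    (common random numbers, cached evaluations).  A CV failure scores the
    individual AUC 0.
    """
    names = list(cfg.candidate_features) or list(data.columns)
    names = [f for f in names if f in data.columns]
    cfg.validate(len(names))
    x = data.loc[:, names].to_numpy(dtype=float)
    y = np.asarray(outcome)
    rng = np.random.default_rng(cfg.seed)
    L = len(names)
    mut_p = cfg.mutation_p if cfg.mutation_p is not None else 1.0 / L
    clo, chi = cfg.log2c_bounds
    glo, ghi = cfg.log2gamma_bounds
    cv = _FoldedSvmCV(x, y, cfg.cv_folds, cfg.seed)

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(L)] = True
        return mask

    # init
    masks = [repair(rng.random(L) < cfg.init_bit_p)
             for _ in range(cfg.population)]
    cs = rng.uniform(clo, chi, cfg.population)
    gs = rng.uniform(glo, ghi, cfg.population)

    def eval_pop(masks, cs, gs):
        aucs = np.array([cv.mean_auc(m, c, g)
                         for m, c, g in zip(masks, cs, gs)])
        sizes = np.array([int(m.sum()) for m in masks])
        return np.column_stack([-aucs, sizes]).astype(float), aucs

    objs, aucs = eval_pop(masks, cs, gs)

    front_signature = None
    unchanged = 0
    for gen in range(1, cfg.generations + 1):
        fronts = _fast_nondominated_sort(objs)
        rank = np.empty(len(masks), dtype=int)
        crowd = np.empty(len(masks))
        for r, front in enumerate(fronts):
            rank[front] = r
            crowd[front] = _crowding(objs, front)

        def tournament() -> int:
            i, j = rng.integers(len(masks), size=2)
            if rank[i] != rank[j]:
                return i if rank[i] < rank[j] else j
            return i if crowd[i] >= crowd[j] else j

        child_masks, child_cs, child_gs = [], [], []
        while len(child_masks) < cfg.population:
            p1, p2 = tournament(), tournament()
            m1, m2 = masks[p1].copy(), masks[p2].copy()
            c1, c2 = cs[p1], cs[p2]
            g1, g2 = gs[p1], gs[p2]
            if rng.random() < cfg.crossover_p:
                swap = rng.random(L) < 0.5
                m1[swap], m2[swap] = masks[p2][swap], masks[p1][swap]
                w = rng.random()
                c1, c2 = w * c1 + (1 - w) * c2, w * c2 + (1 - w) * c1
                g1, g2 = w * g1 + (1 - w) * g2, w * g2 + (1 - w) * g1
            for m in (m1, m2):
                flips = rng.random(L) < mut_p
                m[flips] = ~m[flips]
            c1 += rng.normal(0, 0.1 * (chi - clo)) * (rng.random() < 0.2)
            c2 += rng.normal(0, 0.1 * (chi - clo)) * (rng.random() < 0.2)
            g1 += rng.normal(0, 0.1 * (ghi - glo)) * (rng.random() < 0.2)
            g2 += rng.normal(0, 0.1 * (ghi - glo)) * (rng.random() < 0.2)
            child_masks += [repair(m1), repair(m2)]
            child_cs += [float(np.clip(c1, clo, chi)),
                         float(np.clip(c2, clo, chi))]
            child_gs += [float(np.clip(g1, glo, ghi)),
                         float(np.clip(g2, glo, ghi))]
        child_masks = child_masks[:cfg.population]
        child_cs = np.array(child_cs[:cfg.population])
        child_gs = np.array(child_gs[:cfg.population])

        # parents + children compete on the shared folds (parents hit cache)
        all_masks = masks + child_masks
        all_cs = np.concatenate([cs, child_cs])
        all_gs = np.concatenate([gs, child_gs])
        objs_all, aucs_all = eval_pop(all_masks, all_cs, all_gs)

        # environmental selection
        fronts = _fast_nondominated_sort(objs_all)
        chosen: list[int] = []
        for front in fronts:
            if len(chosen) + front.size <= cfg.population:
                chosen.extend(front.tolist())
            else:
                cd = _crowding(objs_all, front)
                order = front[np.argsort(-cd, kind="stable")]
                chosen.extend(order[:cfg.population - len(chosen)].tolist())
                break
        masks = [all_masks[i] for i in chosen]
        cs = all_cs[chosen]
        gs = all_gs[chosen]
        objs = objs_all[chosen]
        aucs = aucs_all[chosen]

        if cfg.early_stop_patience is not None:
            # convergence = per-size front AUCs stable to 3 decimals
            sig = frozenset((int(o[1]), round(float(-o[0]), 3))
                            for o in objs[_fast_nondominated_sort(objs)[0]])
            if sig == front_signature:
                unchanged += 1
                if unchanged >= cfg.early_stop_patience:
                    break
            else:
                front_signature = sig
                unchanged = 0

    # final candidates are re-scored on validation folds independent of the
    # search folds: the search may overfit its fixed partition, so reported
    # AUCs and the parsimony selection use an unseen fold assignment
    cv_val = _FoldedSvmCV(x, y, cfg.cv_folds, seed=cfg.seed + 7919)
    fronts = _fast_nondominated_sort(objs)
    seen = set()
    candidates: list[tuple] = []
    for i in fronts[0]:
        feats = tuple(str(f) for f in np.array(names)[masks[i]])
        key = (feats, round(cs[i], 5), round(gs[i], 5))
        if key in seen:
            continue
        seen.add(key)
        auc_val = cv_val.mean_auc(masks[i], cs[i], gs[i])
        candidates.append((feats, float(cs[i]), float(gs[i]), auc_val,
                           int(masks[i].sum())))
    # the validation scores can re-order candidates: keep the non-dominated
    val_objs = np.array([[-a, sz] for *_, a, sz in candidates])
    nd = _fast_nondominated_sort(val_objs)[0]
    solutions, dedup = [], set()
    for k, c in enumerate(candidates):
        if k not in set(nd.tolist()):
            continue
        sig = (c[0], round(c[3], 12))
        if sig in dedup:
            continue  # same mask + same validation AUC: hyperparameter ties
        dedup.add(sig)
        solutions.append(Solution(features=c[0], log2c=c[1], log2gamma=c[2],
                                  mean_cv_auc=c[3], size=c[4]))
    solutions.sort(key=lambda s: (s.size, -s.mean_cv_auc, s.features))
    best_auc = max(s.mean_cv_auc for s in solutions)
    selected = next(i for i, s in enumerate(solutions)
                    if s.mean_cv_auc >= best_auc - cfg.parsimony_tol)
    return ParetoFront(solutions=solutions, selected=selected)


def final_signature_model(front: ParetoFront, data: pd.DataFrame, outcome,
                          folds: int = 10, seed: int = 0) -> dict:
    """Refit the selected SVM on all data and report per-fold CV AUCs."""
    if not front.solutions:
        raise ValueError("empty Pareto front")
    sol = front.selected_solution()
    x = data.loc[:, list(sol.features)]
    y = np.asarray(outcome)
    est = _default_svm(sol.log2c, sol.log2gamma)
    est.fit(x.to_numpy(dtype=float), y)
    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    fold_aucs = []
    xv = x.to_numpy(dtype=float)
    from sklearn.base import clone
    for train, test in skf.split(xv, y):
        e = clone(est)
        e.fit(xv[train], y[train])
        s = e.decision_function(xv[test])
        if len(np.unique(y[test])) == 2:
            fold_aucs.append(float(roc_auc_score(y[test], s)))
    return {
        "members": list(sol.features),
        "log2C": sol.log2c,
        "log2gamma": sol.log2gamma,
        "search_cv_auc": sol.mean_cv_auc,
        "refit_cv_auc_mean": float(np.mean(fold_aucs)),
        "refit_cv_auc_sd": float(np.std(fold_aucs, ddof=1)),
        "fold_aucs": fold_aucs,
        "model": est,
    }
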