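"""Outer generalization schemes with nested hyperparameter search.

Three outer schemes test increasingly hard generalization claims:

* ``kfold`` — shuffled k-fold over participants (new individuals),
* ``cross_diagnosis`` — leave-one-diagnosis-out (unseen diagnostic groups),
* ``cross_treatment`` — leave-one-treatment-arm-out (different modalities).

Inside every outer training set, a 5-fold grid search over (c, k) picks the
hyperparameters by the same statistic the outer loop reports: the Pearson
correlation of the pooled inner-held-out canonical score pairs.  The chosen
model is fit once on the outer training rows and applied, frozen, to the
held-out rows; the prediction r is the correlation of the pooled held-out
(u, v) pairs across all participants.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .cohort import CohortTable
from .rcca import (
    EIG_FLOOR,
    SINGULAR_TOL,
    HyperGrid,
    Standardizer,
    fit_pipeline,
    fit_standardize_pca,
    project,
)

SCHEMES = ("kfold", "cross_diagnosis", "cross_treatment")
MIN_GROUP_SIZE = 3
MIN_INNER_TRAIN = 15


def _fold_seed(seed: int, fold_index: int) -> int:
    """Deterministic per-fold child seed below 2^31."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(fold_index),))
    return int(ss.generate_state(1)[0] % (2**31))


def _checksum(ids) -> str:
    return hashlib.sha1("|".join(map(str, ids)).encode()).hexdigest()


@dataclass(frozen=True)
class FoldPlan:
    """Participant -> outer-fold assignment for one scheme."""

    scheme: str
    assignments: pd.Series  # participant_id -> fold label
    K: int
    seed: int

    def fold_labels(self) -> list:
        return sorted(self.assignments.unique().tolist(), key=str)

    def test_ids(self, fold) -> pd.Index:
        return self.assignments.index[self.assignments == fold]

    def train_ids(self, fold) -> pd.Index:
        return self.assignments.index[self.assignments != fold]


def make_folds(cohort: CohortTable, scheme: str, K: int = 10, seed: int = 0) -> FoldPlan:
    """Build the outer fold plan; group schemes derive folds from labels.

    k-fold partitions are shuffled with the given seed and sized within one
    of each other; every participant lands in exactly one test fold.  Group
    schemes ignore K, and any diagnosis/treatment group smaller than 3 is
    an error (too small to ever test on).
    """
    ids = cohort.participant_ids
    n = len(ids)
    if scheme == "kfold":
        if not 2 <= K <= n:
            raise ValueError(f"kfold needs 2 <= K <= n, got K={K}, n={n}")
        if n < 2 * K:
            raise ValueError(
                f"n={n} participants cannot fill K={K} folds with >= 2 members each"
            )
        assign = pd.Series(index=ids, dtype=int, name="fold")
        kf = KFold(n_splits=K, shuffle=True, random_state=seed)
        for fold, (_, test_idx) in enumerate(kf.split(np.arange(n))):
            assign.iloc[test_idx] = fold
        return FoldPlan("kfold", assign, K, seed)
    if scheme in ("cross_diagnosis", "cross_treatment"):
        labels = cohort.diagnosis if scheme == "cross_diagnosis" else cohort.treatment
        counts = labels.value_counts()
        if len(counts) < 2:
            raise ValueError(f"{scheme} needs >= 2 groups, found {len(counts)}")
        small = counts[counts < MIN_GROUP_SIZE]
        if len(small):
            raise ValueError(
                f"group(s) too small for {scheme}: "
                + ", ".join(f"{g} (n={c})" for g, c in small.items())
            )
        assign = labels.copy()
        assign.name = "fold"
        return FoldPlan(scheme, assign, len(counts), seed)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def select_best_cell(cells, criteria) -> int:
    """Index of the best grid cell: max criterion, ties to larger c then smaller k.

    Non-finite criteria (singular solves, constant scores) are never selected.
    """
    best = None
    best_i = -1
    for i, ((c, k), cr) in enumerate(zip(cells, criteria)):
        if not np.isfinite(cr):
            continue
        key = (cr, c, -k)
        if best is None or key > best:
            best, best_i = key, i
    if best_i < 0:
        raise ValueError("grid-search criterion undefined for every cell (constant scores)")
    return best_i


@dataclass(frozen=True)
class GridSearchResult:
    c: float
    k: int
    criterion: float
    table: pd.DataFrame  # (c, k, criterion) for every evaluated cell


def inner_grid_search(
    edges: np.ndarray,
    metrics: np.ndarray,
    grid: HyperGrid,
    seed: int,
    n_inner: int = 5,
) -> GridSearchResult:
    """Pick (c, k) by pooled inner-held-out canonical correlation.

    All grid cells share each inner fold's standardization and PCA at the
    largest feasible k (principal axes are nested, so truncation to any
    smaller k is exact), which is what keeps the 21 x |k| grid tractable.
    Cells whose classical (c=0) solve hits a singular covariance are skipped;
    ties are broken toward larger c, then smaller k.
    """
    edges = np.asarray(edges, dtype=float)
    metrics = np.asarray(metrics, dtype=float)
    n, p = edges.shape
    q = metrics.shape[1]
    if n < MIN_INNER_TRAIN:
        raise ValueError(f"inner grid search needs >= {MIN_INNER_TRAIN} training rows, got {n}")

    min_tr = n - math.ceil(n / n_inner)  # smallest inner-train size
    # requested k beyond what the data supports (restricted edge sets, small
    # folds) is clamped to the feasible maximum rather than dropped
    k_cap = min(min_tr - 1, p)
    if k_cap < 1:
        raise ValueError(
            f"no feasible k for inner-train size {min_tr} and {p} features"
        )
    k_values = sorted({min(k, k_cap) for k in grid.k_values})
    c_values = list(grid.reg_values)
    cells = [(c, k) for c in c_values for k in k_values]
    if len(cells) == 1:
        c, k = cells[0]
        return GridSearchResult(c, k, float("nan"),
                                pd.DataFrame([(c, k, float("nan"))],
                                             columns=["c", "k", "criterion"]))

    kmax = max(k_values)
    cell_index = {cell: i for i, cell in enumerate(cells)}
    pooled_u = np.full((len(cells), n), np.nan)
    pooled_v = np.full((len(cells), n), np.nan)
    ok = np.ones(len(cells), dtype=bool)

    kf = KFold(n_splits=n_inner, shuffle=True, random_state=seed)
    for tr_idx, te_idx in kf.split(np.arange(n)):
        estd, basis, scores = fit_standardize_pca(edges[tr_idx], kmax)
        mstd = Standardizer.fit(metrics[tr_idx], what="metric")
        ytr = mstd.transform(metrics[tr_idx])
        yte = mstd.transform(metrics[te_idx])
        te_scores = basis.project(estd.transform(edges[te_idx]), kmax)
        ntr = len(tr_idx)

        s_xx = scores.T @ scores / (ntr - 1)
        s_xy = scores.T @ ytr / (ntr - 1)
        s_yy = ytr.T @ ytr / (ntr - 1)
        lam_y, v_y = np.linalg.eigh(s_yy)
        anchor = ytr.mean(axis=1)
        anchor_sd = anchor.std()

        # per-c metric-side inverse square roots (q x q, cheap)
        cyy_is = {}
        y_singular = {}
        for c in c_values:
            y_singular[c] = c == 0 and lam_y[0] < SINGULAR_TOL * max(lam_y[-1], 0.0)
            dy = (1 - c) * lam_y + c
            dy = np.maximum(dy, EIG_FLOOR * max(dy[-1], 1.0))
            cyy_is[c] = (v_y / np.sqrt(dy)) @ v_y.T

        for k in k_values:
            lam, v = np.linalg.eigh(s_xx[:k, :k])
            m = v.T @ s_xy[:k]
            xte_k = te_scores[:, :k]
            x_singular = lam[0] < SINGULAR_TOL * max(lam[-1], 0.0)
            for c in c_values:
                i = cell_index[(c, k)]
                if (c == 0 and x_singular) or y_singular[c]:
                    ok[i] = False
                    continue
                d = (1 - c) * lam + c
                d = np.maximum(d, EIG_FLOOR * max(d[-1], 1.0))
                b = (m / np.sqrt(d)[:, None]) @ cyy_is[c]
                ub, _, wtb = np.linalg.svd(b, full_matrices=False)
                w_x = v @ (ub[:, 0] / np.sqrt(d))
                w_y = cyy_is[c] @ wtb[0]
                # orient against the mean standardized change on the inner-train
                v_tr = ytr @ w_y
                if v_tr.std() > 0 and anchor_sd > 0:
                    r = float(np.corrcoef(v_tr, anchor)[0, 1])
                else:
                    r = 0.0
                if (r < 0) or (r == 0 and w_y[int(np.abs(w_y).argmax())] < 0):
                    w_x, w_y = -w_x, -w_y
                pooled_u[i, te_idx] = xte_k @ w_x
                pooled_v[i, te_idx] = yte @ w_y

    crit = np.full(len(cells), -np.inf)
    for i in range(len(cells)):
        if not ok[i]:
            continue
        u, v = pooled_u[i], pooled_v[i]
        if np.std(u) == 0 or np.std(v) == 0 or np.isnan(u).any():
            continue
        crit[i] = float(np.corrcoef(u, v)[0, 1])
    best = select_best_cell(cells, crit)
    table = pd.DataFrame(
        [(c, k, cr) for (c, k), cr in zip(cells, crit)],
        columns=["c", "k", "criterion"],
    )
    c_star, k_star = cells[best]
    return GridSearchResult(c_star, k_star, float(crit[best]), table)


@dataclass(frozen=True)
class ValidationResult:
    """Pooled held-out canonical scores and per-fold fit records."""

    scheme: str
    seed: int
    per_fold: list
    pooled: pd.DataFrame  # participant_id index; columns u, v, fold
    prediction_r: float
    prediction_p_parametric: float

    def per_fold_r(self) -> dict:
        return {rec["fold"]: rec["test_r"] for rec in self.per_fold}

    def to_json_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "prediction_r": self.prediction_r,
            "prediction_p_parametric": self.prediction_p_parametric,
            "per_fold": [
                {key: rec[key] for key in
                 ("fold", "c", "k", "train_r", "test_r", "n_test", "train_checksum")}
                for rec in self.per_fold
            ],
        }

    def save(self, json_path, scores_path=None) -> None:
        Path(json_path).write_text(json.dumps(self.to_json_dict(), indent=1, sort_keys=True))
        if scores_path is not None:
            self.pooled.to_csv(scores_path, sep="\t")


def run_validation(
    cohort: CohortTable,
    scheme: str,
    grid: HyperGrid | None = None,
    K: int = 10,
    seed: int = 0,
    n_inner: int = 5,
) -> ValidationResult:
    """One full outer validation run with per-fold hyperparameter search.

    Every fold's model sees training rows only (each record carries a
    checksum of its training ids so leakage is assertable); held-out (u, v)
    pairs are pooled over all participants and summarized by their Pearson
    correlation.
    """
    if cohort.metrics.isna().any().any():
        raise ValueError("cohort has missing clinical metrics; completers only")
    plan = make_folds(cohort, scheme, K=K, seed=seed)
    edges = cohort.edge_values()
    metrics = cohort.metric_values()
    ids = cohort.participant_ids
    pos = {pid: i for i, pid in enumerate(ids)}

    pooled_u = np.full(len(ids), np.nan)
    pooled_v = np.full(len(ids), np.nan)
    fold_of = np.empty(len(ids), dtype=object)
    per_fold = []
    for f_idx, fold in enumerate(plan.fold_labels()):
        tr_ids = plan.train_ids(fold)
        te_ids = plan.test_ids(fold)
        tr = [pos[i] for i in tr_ids]
        te = [pos[i] for i in te_ids]
        fold_grid = grid or HyperGrid.default(len(tr), edges.shape[1])
        inner_seed = _fold_seed(seed, f_idx)
        search = inner_grid_search(edges[tr], metrics[tr], fold_grid, seed=inner_seed,
                                   n_inner=n_inner)
        model = fit_pipeline(edges[tr], metrics[tr], c=search.c, k=search.k)
        u, v = project(model, edges[te], metrics[te])
        pooled_u[te] = u
        pooled_v[te] = v
        fold_of[te] = fold
        test_r = float(np.corrcoef(u, v)[0, 1]) if len(te) >= 3 and u.std() > 0 and v.std() > 0 else float("nan")
        per_fold.append({
            "fold": fold,
            "c": search.c,
            "k": search.k,
            "inner_criterion": search.criterion,
            "train_r": model.canonical_correlation_train,
            "test_r": test_r,
            "n_test": len(te),
            "train_checksum": _checksum(tr_ids),
            "model": model,
            "test_ids": list(te_ids),
        })

    assert not np.isnan(pooled_u).any(), "fold plan failed to cover every participant"
    r, p = stats.pearsonr(pooled_u, pooled_v)
    pooled = pd.DataFrame({"u": pooled_u, "v": pooled_v, "fold": fold_of}, index=ids)
    return ValidationResult(
        scheme=scheme,
        seed=seed,
        per_fold=per_fold,
        pooled=pooled,
        prediction_r=float(r),
        prediction_p_parametric=float(p),
    )


def outcome_variant(cohort: CohortTable, variant: str) -> CohortTable:
    """Recompute the outcome block as difference or percent-change scores.

    ``difference`` is post - pre; ``percent_change`` is 100 * (post - pre) /
    pre and requires a nonzero pre score for every participant and metric.
    """
    if variant not in ("difference", "percent_change"):
        raise ValueError(f"unknown outcome variant {variant!r}")
    if cohort.metrics_pre is None or cohort.metrics_post is None:
        raise ValueError("cohort carries no pre/post scores")
    pre = cohort.metrics_pre
    post = cohort.metrics_post
    if variant == "difference":
        return cohort.with_metrics(post - pre)
    zero = (pre == 0).any(axis=1)
    if zero.any():
        raise ValueError(
            f"percent_change undefined: zero pre score for rows {pre.index[zero].tolist()}"
        )
    return cohort.with_metrics(100.0 * (post - pre) / pre)
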