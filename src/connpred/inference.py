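"""Significance, stability, and attribution for the fitted canonical pair.

Four post-fit questions are answered here:

* Is the prediction better than chance?  A permutation test shuffles the
  row-alignment of the clinical block against the FC block and reruns the
  *entire* nested validation (inner grid search included) per permutation, so
  the null distribution reflects the selection effects of the search.
* Which edges drive the brain variate?  Per-edge Pearson correlation with
  the brain canonical score, exact t-based two-sided p (n-2 df), and
  Benjamini-Hochberg FDR, summarized as signed counts per network-pair cell.
* Which clinical scales drive the symptom variate?  Canonical loadings:
  the correlation of each change score with the symptom variate.
* Is any of it stable?  A participant-level bootstrap refits the model at
  the full-fit hyperparameters and tracks sign consistency and percentile
  CIs of the loadings against the full-fit reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable
from .rcca import HyperGrid, RccaModel, fit_pipeline, project
from .validation import ValidationResult, inner_grid_search, run_validation


def exceedance_p(observed: float, null_values: np.ndarray, add_one: bool = False) -> float:
    """Strict-exceedance permutation p: proportion of nulls > observed.

    ``add_one`` switches to the (b+1)/(m+1) variant that never returns 0.
    """
    null_values = np.asarray(null_values, dtype=float)
    m = null_values.size
    b = int(np.sum(null_values > observed))
    if add_one:
        return (b + 1) / (m + 1)
    return b / m


@dataclass(frozen=True)
class PermutationResult:
    observed_r: float
    null_rs: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    def null_histogram(self, bins: int = 40) -> pd.DataFrame:
        counts, edges = np.histogram(self.null_rs, bins=bins)
        return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def permutation_test(
    cohort: CohortTable,
    scheme: str,
    grid: HyperGrid | None = None,
    K: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    observed: ValidationResult | None = None,
    add_one: bool = False,
) -> PermutationResult:
    """Permutation significance of the pooled held-out prediction r.

    Each permutation shuffles which participant's clinical row is paired
    with which FC row (rows themselves stay intact), then reruns the full
    validation with the same scheme, grid and fold seed.  The p-value is the
    strict proportion of null r values exceeding the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed is None:
        observed = run_validation(cohort, scheme, grid=grid, K=K, seed=seed)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    metrics = cohort.metrics
    for b in range(n_perm):
        perm = rng.permutation(cohort.n)
        shuffled = pd.DataFrame(
            metrics.to_numpy()[perm], index=metrics.index, columns=metrics.columns
        )
        null_res = run_validation(
            cohort.with_metrics(shuffled), scheme, grid=grid, K=K, seed=seed
        )
        nulls[b] = null_res.prediction_r
    p = exceedance_p(observed.prediction_r, nulls, add_one=add_one)
    return PermutationResult(
        observed_r=observed.prediction_r,
        null_rs=nulls,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


# ---- full-cohort reference fit --------------------------------------------


def fit_full_cohort(
    cohort: CohortTable,
    grid: HyperGrid | None = None,
    seed: int = 0,
    c: float | None = None,
    k: int | None = None,
) -> RccaModel:
    """Reference model on all participants for attribution and bootstrap.

    Hyperparameters come from one 5-fold grid search on the whole cohort
    unless (c, k) are given explicitly.
    """
    edges = cohort.edge_values()
    metrics = cohort.metric_values()
    if c is None or k is None:
        grid = grid or HyperGrid.default(cohort.n, cohort.n_edges)
        search = inner_grid_search(edges, metrics, grid, seed=seed)
        c, k = search.c, search.k
    return fit_pipeline(edges, metrics, c=c, k=k)


def _columnwise_corr(u: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson correlation of a vector with every column of a matrix."""
    uc = u - u.mean()
    xc = x - x.mean(axis=0)
    denom = np.linalg.norm(uc) * np.linalg.norm(xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ uc) / denom
    return np.clip(r, -1.0, 1.0)


@dataclass(frozen=True)
class EdgeAttribution:
    """Per-edge association with the brain variate plus cell-level counts."""

    table: pd.DataFrame  # edge, r, p, q, sign, significant, network_pair
    network_pair_counts: pd.DataFrame  # cell_a, cell_b, positive, negative, total
    q_threshold: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_positive(self) -> int:
        return int((self.table["significant"] & (self.table["sign"] > 0)).sum())

    @property
    def n_negative(self) -> int:
        return int((self.table["significant"] & (self.table["sign"] < 0)).sum())

    def count_matrix(self, sign: str, labels) -> pd.DataFrame:
        """9 x 9 count matrix (upper cells mirrored) for one sign."""
        m = pd.DataFrame(0, index=list(labels), columns=list(labels))
        for _, row in self.network_pair_counts.iterrows():
            m.loc[row["net_a"], row["net_b"]] = row[sign]
            m.loc[row["net_b"], row["net_a"]] = row[sign]
        return m


def edge_attribution(
    cohort: CohortTable,
    model_full: RccaModel,
    q_threshold: float = 0.05,
) -> EdgeAttribution:
    """FDR-controlled per-edge correlation with the brain canonical variate.

    p-values use the exact t transform t = r sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom; Benjamini-Hochberg step-up controls the FDR at
    ``q_threshold``.  Significant edges are split by sign and counted per
    unordered network-pair cell (the tables behind chord diagrams).
    """
    n = cohort.n
    if n <= 3:
        raise ValueError("edge attribution needs n > 3 participants")
    edges = cohort.edge_values()
    u, _ = project(model_full, edges, cohort.metric_values())
    r = _columnwise_corr(u, edges)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    significant = q < q_threshold
    sign = np.sign(r).astype(int)

    label_to_cell = dict(zip(cohort.atlas.edge_labels(), cohort.atlas.edge_cells()))
    cells = [label_to_cell[lab] for lab in cohort.edges.columns]
    table = pd.DataFrame({
        "edge": cohort.edges.columns,
        "r": r,
        "p": p,
        "q": q,
        "sign": sign,
        "significant": significant,
        "network_pair": [f"{a}-{b}" for a, b in cells],
    })
    rows = []
    for cell in cohort.atlas.all_cells():
        mask = np.array([c == cell for c in cells])
        sig = significant & mask
        pos = int(np.sum(sig & (sign > 0)))
        neg = int(np.sum(sig & (sign < 0)))
        rows.append((cell[0], cell[1], pos, neg, pos + neg))
    counts = pd.DataFrame(rows, columns=["net_a", "net_b", "positive", "negative", "total"])
    return EdgeAttribution(table=table, network_pair_counts=counts, q_threshold=q_threshold)


@dataclass(frozen=True)
class MetricLoadings:
    """Canonical loadings of the clinical metrics on the symptom variate."""

    loadings: pd.Series  # metric -> corr(change score, v)

    def ranked(self) -> pd.Series:
        return self.loadings.reindex(self.loadings.abs().sort_values(ascending=False).index)


def metric_loadings(cohort: CohortTable, model_full: RccaModel) -> MetricLoadings:
    """Correlation of each clinical change score with the symptom variate."""
    metrics = cohort.metric_values()
    sd = metrics.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = cohort.metrics.columns[sd == 0].tolist()
        raise ValueError(f"loading undefined for constant metric(s): {bad}")
    _, v = project(model_full, cohort.edge_values(), metrics)
    r = _columnwise_corr(v, metrics)
    return MetricLoadings(pd.Series(r, index=cohort.metrics.columns, name="loading"))


@dataclass(frozen=True)
class BootstrapStability:
    """Sign-consistency fractions and percentile CIs of bootstrap loadings."""

    edge_table: pd.DataFrame    # edge, reference_loading, sign_consistency, ci_low, ci_high
    metric_table: pd.DataFrame  # same per clinical metric
    n_boot: int
    seed: int


def bootstrap_stability(
    cohort: CohortTable,
    model_full: RccaModel,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> BootstrapStability:
    """Participant-level bootstrap of edge and metric canonical loadings.

    Each replicate resamples participants with replacement, refits
    standardize/PCA/rCCA at the full-fit (c, k) — no hyperparameter
    re-search — and is sign-aligned to the reference by the cosine of its
    symptom weights with the reference symptom weights.  Sign consistency is
    the fraction of replicates whose loading agrees in sign with the
    full-cohort reference loading.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable reporting")
    rng = np.random.default_rng(seed)
    edges = cohort.edge_values()
    metrics = cohort.metric_values()
    n = cohort.n

    u_ref, v_ref = project(model_full, edges, metrics)
    ref_edge = _columnwise_corr(u_ref, edges)
    ref_metric = _columnwise_corr(v_ref, metrics)
    w_y_ref = model_full.symptom_weights

    edge_load = np.empty((n_boot, edges.shape[1]))
    metric_load = np.empty((n_boot, metrics.shape[1]))
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        if np.unique(idx).size < 3:
            continue  # degenerate resample; draw again
        try:
            rep = fit_pipeline(edges[idx], metrics[idx],
                               c=model_full.reg_param, k=model_full.k)
        except ValueError:
            continue  # e.g. a constant column in this resample
        if float(rep.symptom_weights @ w_y_ref) < 0:
            rep = rep.flipped()
        u_b, v_b = project(rep, edges[idx], metrics[idx])
        edge_load[b] = _columnwise_corr(u_b, edges[idx])
        metric_load[b] = _columnwise_corr(v_b, metrics[idx])
        b += 1

    alpha = (1.0 - ci) / 2.0

    def _summary(loads: np.ndarray, ref: np.ndarray, names) -> pd.DataFrame:
        with np.errstate(invalid="ignore"):
            consistency = np.nanmean(np.sign(loads) == np.sign(ref), axis=0)
        lo = np.nanpercentile(loads, 100 * alpha, axis=0)
        hi = np.nanpercentile(loads, 100 * (1 - alpha), axis=0)
        return pd.DataFrame({
            "reference_loading": ref,
            "sign_consistency": consistency,
            "ci_low": lo,
            "ci_high": hi,
        }, index=names)

    return BootstrapStability(
        edge_table=_summary(edge_load, ref_edge, cohort.edges.columns),
        metric_table=_summary(metric_load, ref_metric, cohort.metrics.columns),
        n_boot=n_boot,
        seed=seed,
    )


@dataclass(frozen=True)
class TierComparison:
    """Held-out symptom-score contrast between top-tier and lower-tier responders."""

    mean_difference: float     # mean v (top tier) - mean v (rest)
    rank_sum_statistic: float  # Mann-Whitney U of the top tier
    p_value: float             # permutation p, two-sided on the centered U
    n_top: int
    n_rest: int
    tier_fraction: float


def responder_tier_comparison(
    cohort: CohortTable,
    validation_result: ValidationResult,
    top_scales: list[str],
    tier_fraction: float = 1 / 3,
    direction: str = "increase",
    n_draws: int = 10_000,
    seed: int = 0,
) -> TierComparison:
    """Do top-tier responders on selected scales get higher predicted v?

    Participants are ranked by their mean standardized change on
    ``top_scales`` (``direction="decrease"`` ranks score drops as
    improvement); the top ``tier_fraction`` is compared with the rest on the
    pooled held-out symptom canonical score via the Mann-Whitney rank-sum
    statistic with a permutation p over ``n_draws`` group-label shuffles.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    if not 0 < tier_fraction < 1:
        raise ValueError("tier_fraction must lie strictly between 0 and 1")
    missing = [s for s in top_scales if s not in cohort.metrics.columns]
    if missing:
        raise ValueError(f"unknown scales: {missing}")
    v = validation_result.pooled["v"].reindex(cohort.participant_ids).to_numpy()
    sub = cohort.metrics[list(top_scales)]
    z = (sub - sub.mean()) / sub.std(ddof=1)
    score = z.mean(axis=1).to_numpy()
    if direction == "decrease":
        score = -score

    n = len(score)
    n_top = int(round(tier_fraction * n))
    n_rest = n - n_top
    if n_top < 5 or n_rest < 5:
        raise ValueError(
            f"tier groups too small (top={n_top}, rest={n_rest}); need >= 5 each"
        )
    order = np.argsort(-score, kind="stable")
    is_top = np.zeros(n, dtype=bool)
    is_top[order[:n_top]] = True

    # Mann-Whitney U of the top tier from midranks: U1 = R1 - n1(n1+1)/2
    ranks = stats.rankdata(v)
    rank_offset = n_top * (n_top + 1) / 2.0
    obs_u = float(ranks[is_top].sum() - rank_offset)
    mean_diff = float(v[is_top].mean() - v[~is_top].mean())
    center = n_top * n_rest / 2.0

    rng = np.random.default_rng(seed)
    null_u = np.empty(n_draws)
    for d in range(n_draws):
        top = rng.permutation(n)[:n_top]
        null_u[d] = ranks[top].sum() - rank_offset
    p = float(np.mean(np.abs(null_u - center) >= np.abs(obs_u - center)))
    return TierComparison(
        mean_difference=mean_diff,
        rank_sum_statistic=obs_u,
        p_value=p,
        n_top=n_top,
        n_rest=n_rest,
        tier_fraction=tier_fraction,
    )
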