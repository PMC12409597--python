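"""Regularized canonical correlation analysis on PCA-reduced edge features.

The model couples a high-dimensional FC edge block with the 8-dimensional
clinical change block.  Edges are z-scored with training statistics and
projected onto the top-k principal axes; the reduced scores X and the
standardized metrics Y then enter a regularized CCA: with sample covariances
S_xx, S_yy, S_xy (denominator n-1), the block covariances are shrunk by the
convex interpolation

    C_xx = (1 - c) S_xx + c I,      C_yy = (1 - c) S_yy + c I,   c in [0, 1]

and the first singular triplet of K = C_xx^{-1/2} S_xy C_yy^{-1/2} gives the
canonical weight pair (w_x, w_y) after back-transformation.  c = 0 is
classical CCA; c = 1 degenerates to the SVD of the cross-covariance (a
PLS-like limit).  Only the first canonical pair is validated and exported;
higher pairs are computed but flagged non-validated.

Because CCA weights are defined only up to a joint sign flip, fitted models
are oriented so the symptom variate correlates non-negatively with the
row-mean of the standardized clinical change scores on the training set —
this makes held-out scores poolable across folds and bootstrap replicates
comparable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

# Relative eigenvalue floor for the inverse square roots; guards c -> 0 on
# ill-conditioned blocks without changing well-posed solutions.
EIG_FLOOR = 1e-12
# Relative eigenvalue level below which a block is treated as singular at c=0.
SINGULAR_TOL = 1e-10


@dataclass(frozen=True)
class Standardizer:
    """Per-feature train means and SDs (ddof=1) for z-scoring."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray, what: str = "feature") -> "Standardizer":
        x = np.asarray(x, dtype=float)
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(f"zero-variance {what} column(s): {dead.tolist()}")
        return cls(mean=mean, sd=sd)

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.mean.size:
            raise ValueError(
                f"feature-count mismatch: got {x.shape[1]}, expected {self.mean.size}"
            )
        return (x - self.mean) / self.sd


@dataclass(frozen=True)
class PCABasis:
    """Top-k principal axes of the standardized training data.

    ``components`` is p x k, eigenvector sign fixed so each axis's
    largest-magnitude element is positive (bit-reproducible across runs).
    """

    components: np.ndarray
    explained_variance: np.ndarray  # eigenvalues, descending

    @property
    def k(self) -> int:
        return self.components.shape[1]

    def project(self, z: np.ndarray, k: int | None = None) -> np.ndarray:
        k = self.k if k is None else k
        return np.asarray(z, dtype=float) @ self.components[:, :k]


def fit_standardize_pca(
    edge_table: np.ndarray, k: int
) -> tuple[Standardizer, PCABasis, np.ndarray]:
    """Z-score columns with train statistics, then project onto top-k axes.

    Returns (standardizer, basis, scores) where scores is n x k.  The axes
    are eigenvectors of the train correlation matrix in descending
    eigenvalue order, computed through an economy SVD of the standardized
    data (never forming the p x p matrix).
    """
    x = np.asarray(edge_table, dtype=float)
    n, p = x.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} out of range [1, min(n-1, p)={min(n - 1, p)}]")
    std = Standardizer.fit(x, what="edge")
    z = std.transform(x)
    _, svals, vt = np.linalg.svd(z, full_matrices=False)
    comps = vt[:k].T
    # deterministic sign: largest-|element| of each axis positive
    flip = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(k)])
    comps = comps * flip
    eigvals = (svals[:k] ** 2) / (n - 1)
    basis = PCABasis(components=comps, explained_variance=eigvals)
    return std, basis, z @ comps


@dataclass(frozen=True)
class RccaModel:
    """A fitted first canonical pair with everything needed for projection."""

    edge_standardizer: Standardizer
    metric_standardizer: Standardizer
    pca_basis: PCABasis
    k: int
    reg_param: float
    brain_weights_pca: np.ndarray    # w_x, length k
    symptom_weights: np.ndarray      # w_y, length q
    canonical_correlation_train: float
    orientation: dict = None  # record of the sign decision
    higher_pairs: tuple = ()  # (singular values beyond the first) — not validated

    @property
    def brain_weights_edges(self) -> np.ndarray:
        """w_x back-projected into (standardized) edge space."""
        return self.pca_basis.components[:, : self.k] @ self.brain_weights_pca

    def flipped(self) -> "RccaModel":
        """Joint sign flip of both weight vectors (correlation preserved)."""
        return replace(
            self,
            brain_weights_pca=-self.brain_weights_pca,
            symptom_weights=-self.symptom_weights,
        )


def _inv_sqrt(s: np.ndarray, c: float, what: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecompose (1-c)S + cI and return (V, lam_reg, inv_sqrt matrix)."""
    lam, v = np.linalg.eigh(s)
    lam_max = float(lam[-1]) if lam[-1] > 0 else 1.0
    if c == 0 and lam[0] < SINGULAR_TOL * lam_max:
        raise ValueError(
            f"{what} covariance is singular at c=0; use c > 0 or fewer components"
        )
    lam_reg = (1 - c) * lam + c
    lam_reg = np.maximum(lam_reg, EIG_FLOOR * max(lam_reg[-1], 1.0))
    m = (v / np.sqrt(lam_reg)) @ v.T
    return v, lam_reg, m


def fit_rcca(x: np.ndarray, y: np.ndarray, c: float) -> dict:
    """Solve the regularized CCA problem for centered blocks X (n x k), Y (n x q).

    Returns a dict with w_x, w_y, the first canonical correlation (the train
    Pearson correlation of the two variates, clipped to [0, 1]; it equals
    the leading singular value of K exactly at c=0, which is also returned),
    and the non-validated higher singular values.  The weights satisfy the
    regularized unit-variance normalization w' ((1-c) S + c I) w = 1 on each
    side.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n <= 2:
        raise ValueError("need n > 2 rows")
    if y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if not 0 <= c <= 1:
        raise ValueError("regularization parameter c must lie in [0, 1]")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    s_xx = xc.T @ xc / (n - 1)
    s_yy = yc.T @ yc / (n - 1)
    s_xy = xc.T @ yc / (n - 1)
    _, _, cxx_is = _inv_sqrt(s_xx, c, "edge-side")
    _, _, cyy_is = _inv_sqrt(s_yy, c, "metric-side")
    kmat = cxx_is @ s_xy @ cyy_is
    u, svals, vt = np.linalg.svd(kmat)
    w_x = cxx_is @ u[:, 0]
    w_y = cyy_is @ vt[0]
    # The leading singular value equals the train Pearson correlation of the
    # variates only at c=0; report the correlation itself so that projecting
    # the training rows always reproduces it.
    num = w_x @ s_xy @ w_y
    den = math.sqrt((w_x @ s_xx @ w_x) * (w_y @ s_yy @ w_y))
    corr = abs(num) / den if den > 0 else 0.0
    return {
        "w_x": w_x,
        "w_y": w_y,
        "canonical_correlation": float(np.clip(corr, 0.0, 1.0)),
        "singular_value_1": float(svals[0]),
        "higher_singular_values": tuple(float(s) for s in svals[1:]),
    }


def fit_pipeline(
    edge_table: np.ndarray,
    metric_table: np.ndarray,
    c: float,
    k: int,
) -> RccaModel:
    """Standardize -> PCA(k) -> rCCA(c) -> orient, on training rows only."""
    edge_std, basis, scores = fit_standardize_pca(edge_table, k)
    metric_std = Standardizer.fit(metric_table, what="metric")
    y = metric_std.transform(metric_table)
    sol = fit_rcca(scores, y, c)
    model = RccaModel(
        edge_standardizer=edge_std,
        metric_standardizer=metric_std,
        pca_basis=basis,
        k=k,
        reg_param=c,
        brain_weights_pca=sol["w_x"],
        symptom_weights=sol["w_y"],
        canonical_correlation_train=sol["canonical_correlation"],
        higher_pairs=sol["higher_singular_values"],
    )
    return orient(model, metric_table)


def project(
    model: RccaModel, edge_rows: np.ndarray, metric_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-sample canonical scores (u, v), one pair per row.

    Inputs are standardized with the model's TRAIN statistics; nothing is
    refit here, which is what makes held-out scores honest predictions.
    """
    z = model.edge_standardizer.transform(np.atleast_2d(edge_rows))
    u = model.pca_basis.project(z, model.k) @ model.brain_weights_pca
    y = model.metric_standardizer.transform(np.atleast_2d(metric_rows))
    v = y @ model.symptom_weights
    return u, v


def orient(model: RccaModel, train_metrics: np.ndarray) -> RccaModel:
    """Resolve the CCA sign indeterminacy against the training outcome block.

    Both weight vectors are flipped jointly (their correlation is untouched)
    so that the symptom variate correlates non-negatively with the row-mean
    of the standardized clinical change scores; an exactly-zero correlation
    falls back to making the largest-|weight| metric's weight positive.
    """
    y = model.metric_standardizer.transform(np.atleast_2d(train_metrics))
    v = y @ model.symptom_weights
    anchor = y.mean(axis=1)
    if np.std(v) == 0 or np.std(anchor) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(v, anchor)[0, 1])
    if r != 0:
        flip = r < 0
        rule = "mean-change-correlation"
    else:
        j = int(np.abs(model.symptom_weights).argmax())
        flip = model.symptom_weights[j] < 0
        rule = "largest-weight-positive"
    out = model.flipped() if flip else model
    return replace(out, orientation={"rule": rule, "flipped": bool(flip)})


# ---- serialization ---------------------------------------------------------


def save_model(model: RccaModel, json_path, weights_path) -> None:
    """Serialize to a JSON descriptor plus one TSV of edge-space weights."""
    payload = {
        "k": model.k,
        "reg_param": model.reg_param,
        "canonical_correlation_train": model.canonical_correlation_train,
        "orientation": model.orientation,
        "edge_mean": model.edge_standardizer.mean.tolist(),
        "edge_sd": model.edge_standardizer.sd.tolist(),
        "metric_mean": model.metric_standardizer.mean.tolist(),
        "metric_sd": model.metric_standardizer.sd.tolist(),
        "brain_weights_pca": model.brain_weights_pca.tolist(),
        "symptom_weights": model.symptom_weights.tolist(),
        "explained_variance": model.pca_basis.explained_variance.tolist(),
        "higher_pairs": list(model.higher_pairs),
    }
    Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True))
    np.savetxt(weights_path, model.pca_basis.components, delimiter="\t")


def load_model(json_path, weights_path) -> RccaModel:
    d = json.loads(Path(json_path).read_text())
    comps = np.loadtxt(weights_path, delimiter="\t", ndmin=2)
    return RccaModel(
        edge_standardizer=Standardizer(np.array(d["edge_mean"]), np.array(d["edge_sd"])),
        metric_standardizer=Standardizer(np.array(d["metric_mean"]), np.array(d["metric_sd"])),
        pca_basis=PCABasis(comps, np.array(d["explained_variance"])),
        k=d["k"],
        reg_param=d["reg_param"],
        brain_weights_pca=np.array(d["brain_weights_pca"]),
        symptom_weights=np.array(d["symptom_weights"]),
        canonical_correlation_train=d["canonical_correlation_train"],
        orientation=d["orientation"],
        higher_pairs=tuple(d["higher_pairs"]),
    )


@dataclass(frozen=True)
class HyperGrid:
    """Candidate regularization values and PCA component counts.

    Defaults follow the search the method prescribes: c from 0 to 1 in steps
    of 0.05, and k over a range in steps of 5 (here 10 .. min(100,
    n_train - 10), set when building the default grid for a given problem).
    """

    reg_values: tuple[float, ...]
    k_values: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.reg_values or not self.k_values:
            raise ValueError("grid must be non-empty on both axes")
        if any(not 0 <= c <= 1 for c in self.reg_values):
            raise ValueError("reg_values must lie in [0, 1]")
        if any(k < 1 for k in self.k_values):
            raise ValueError("k_values must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.reg_values) * len(self.k_values)

    @classmethod
    def default(cls, n_train: int, n_features: int) -> "HyperGrid":
        regs = tuple(round(0.05 * i, 2) for i in range(21))  # 0, 0.05, ..., 1.0
        k_hi = min(100, n_train - 10, n_features)
        ks = tuple(range(10, k_hi + 1, 5)) or (min(10, n_train - 2, n_features),)
        return cls(reg_values=regs, k_values=ks)

    @classmethod
    def single(cls, c: float, k: int) -> "HyperGrid":
        return cls(reg_values=(c,), k_values=(k,))
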