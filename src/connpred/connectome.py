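"""Functional-connectivity matrices from parcellated time series.

A participant's FC matrix is the region-by-region Pearson correlation of the
parcellated time series; an optional Fisher z transform (atanh) stabilizes the
variance of the correlations before modeling.  FC matrices are vectorized into
edge vectors using the fixed upper-triangle (i < j, row-major) ordering shared
with :mod:`connpred.atlas`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasSpec

# Correlations are clipped to +/-(1 - CLIP_EPS) before atanh so perfectly
# (anti)correlated regions map to a large finite z rather than +/-inf.
CLIP_EPS = 1e-7
MIN_TIMEPOINTS = 20


@dataclass(frozen=True)
class ConnectomeMatrix:
    """Symmetric region-by-region edge-weight matrix.

    ``kind`` is ``"pearson"`` (diagonal 1, off-diagonals in [-1, 1]) or
    ``"fisher_z"`` (diagonal set to 0 by convention).
    """

    values: np.ndarray
    kind: str = "pearson"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectome matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectome matrix must be symmetric")
        if self.kind not in ("pearson", "fisher_z"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def compute_fc(timeseries: np.ndarray) -> ConnectomeMatrix:
    """Pearson FC matrix from a T x R parcellated time-series array.

    Parameters
    ----------
    timeseries:
        Rows are timepoints, columns are regions.  At least 20 timepoints are
        required; shorter series give meaningless correlation estimates.

    Raises
    ------
    ValueError
        On NaNs, too few timepoints, or any zero-variance region (silent NaN
        propagation into the downstream model is the alternative failure
        mode, so constant regions are a hard error naming the region).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a 2-D (timepoints x regions) array")
    if np.isnan(ts).any():
        raise ValueError("timeseries contains NaNs")
    t, r = ts.shape
    if t < MIN_TIMEPOINTS:
        raise ValueError(f"need at least {MIN_TIMEPOINTS} timepoints, got {t}")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance region column(s): {dead.tolist()}")
    corr = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    # symmetrize away float asymmetry from BLAS ordering
    corr = (corr + corr.T) / 2.0
    return ConnectomeMatrix(corr, kind="pearson")


def fisher_z(fc: ConnectomeMatrix) -> ConnectomeMatrix:
    """Variance-stabilize a Pearson FC matrix with z = atanh(r).

    Off-diagonal correlations are clipped to +/-(1 - 1e-7) first; the
    diagonal is set to 0 by convention.
    """
    if fc.kind != "pearson":
        raise ValueError("fisher_z expects a pearson-kind matrix")
    z = np.arctanh(np.clip(fc.values, -(1 - CLIP_EPS), 1 - CLIP_EPS))
    np.fill_diagonal(z, 0.0)
    return ConnectomeMatrix(z, kind="fisher_z")


def vectorize(fc: ConnectomeMatrix) -> np.ndarray:
    """Upper-triangle (i < j, row-major) edge vector of length R(R-1)/2."""
    r = fc.n_regions
    iu = np.triu_indices(r, k=1)
    return fc.values[iu].copy()


def devectorize(edge_values: np.ndarray, n_regions: int, kind: str = "pearson") -> ConnectomeMatrix:
    """Rebuild a symmetric matrix from an edge vector (inverse of vectorize).

    The diagonal is 1 for ``kind="pearson"`` and 0 otherwise.
    """
    ev = np.asarray(edge_values, dtype=float).ravel()
    expected = n_regions * (n_regions - 1) // 2
    if ev.size != expected:
        raise ValueError(
            f"edge vector has length {ev.size}, expected R(R-1)/2 = {expected} for R={n_regions}"
        )
    m = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    m[iu] = ev
    m = m + m.T
    np.fill_diagonal(m, 1.0 if kind == "pearson" else 0.0)
    return ConnectomeMatrix(m, kind=kind)


# ---- file-level helpers ----------------------------------------------------


def read_timeseries_tsv(path) -> pd.DataFrame:
    """Read one participant's parcellated series (rows = timepoints, cols = regions)."""
    return pd.read_csv(path, sep="\t")


def fc_edge_table(
    timeseries_by_participant: dict[str, pd.DataFrame],
    atlas: AtlasSpec,
    apply_fisher_z: bool = True,
) -> pd.DataFrame:
    """Participants-by-edges table from per-participant time-series frames.

    Column order in each time-series frame must match the atlas region order
    (checked by name when the frame has a header of region names).
    """
    labels = atlas.edge_labels()
    rows = {}
    for pid, ts in timeseries_by_participant.items():
        if list(ts.columns) != list(atlas.region_names):
            raise ValueError(f"participant {pid}: region columns do not match atlas order")
        fc = compute_fc(ts.to_numpy())
        if apply_fisher_z:
            fc = fisher_z(fc)
        rows[pid] = vectorize(fc)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    table.index.name = "participant_id"
    return table
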