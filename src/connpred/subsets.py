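"""Network- and metric-restricted model scans.

Two post hoc questions about localization: does any single network, or any
small set of networks, carry the predictive signal, and how many clinical
dimensions does the outcome block need?  Both scans rerun the standard
validation on restricted inputs and tabulate the resulting prediction r per
subset size — the data behind performance-versus-size violin plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .rcca import HyperGrid
from .validation import run_validation

#: Sizes with more combinations than this are randomly subsampled (recorded
#: in the output table's ``subsampled`` column).
MAX_COMBOS_PER_SIZE = 200


def restrict_edges(cohort: CohortTable, networks, mode: str = "both") -> CohortTable:
    """Keep only edges whose endpoint networks both lie in ``networks``.

    mode="within" keeps same-network edges, "between" keeps cross-network
    edges among the set, "both" keeps every edge internal to the set.  The
    full nine-network set with mode="both" is the identity restriction.
    """
    networks = set(networks)
    if not networks:
        raise ValueError("networks must be non-empty")
    unknown = networks - set(cohort.atlas.network_labels)
    if unknown:
        raise ValueError(f"unknown network label(s): {sorted(unknown)}")
    if mode not in ("within", "between", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    keep = []
    for a, b in cohort.atlas.edge_cells():
        if a not in networks or b not in networks:
            keep.append(False)
        elif mode == "within":
            keep.append(a == b)
        elif mode == "between":
            keep.append(a != b)
        else:
            keep.append(True)
    keep = np.asarray(keep)
    if not keep.any():
        raise ValueError(f"restriction to {sorted(networks)} (mode={mode}) keeps no edges")
    if keep.all():
        return cohort  # identity restriction: bit-identical downstream
    return cohort.with_edges(cohort.edges.loc[:, keep])


@dataclass(frozen=True)
class SubsetScanResult:
    """Long-format scan rows plus per-size summaries."""

    rows: pd.DataFrame  # subset, size, seed, prediction_r, subsampled
    kind: str           # "network" or "metric"

    def per_size_summary(self) -> pd.DataFrame:
        g = self.rows.groupby("size")["prediction_r"]
        return pd.DataFrame({"mean_r": g.mean(), "sd_r": g.std(), "n_models": g.size()})


def network_scan(
    cohort: CohortTable,
    sizes=range(1, 10),
    seeds=(0,),
    grid: HyperGrid | None = None,
    K: int = 10,
    mode: str = "both",
) -> SubsetScanResult:
    """Prediction r for network subsets of each size.

    Size-1 models are run once per seed per network (their spread over fold
    splits is the interesting quantity); sizes >= 2 run every combination —
    subsampled above 200 per size — at the first seed.
    """
    labels = list(cohort.atlas.network_labels)
    seeds = list(seeds)
    rows = []
    for size in sizes:
        if not 1 <= size <= len(labels):
            raise ValueError(f"network subset size {size} out of range [1, {len(labels)}]")
        combos = list(combinations(labels, size))
        subsampled = False
        if size >= 2 and len(combos) > MAX_COMBOS_PER_SIZE:
            rng = np.random.default_rng(seeds[0])
            pick = rng.choice(len(combos), size=MAX_COMBOS_PER_SIZE, replace=False)
            combos = [combos[i] for i in sorted(pick)]
            subsampled = True
        run_seeds = seeds if size == 1 else seeds[:1]
        for combo in combos:
            restricted = restrict_edges(cohort, combo, mode=mode)
            for seed in run_seeds:
                res = run_validation(restricted, "kfold", grid=grid, K=K, seed=seed)
                rows.append(("+".join(combo), size, seed, res.prediction_r, subsampled))
    return SubsetScanResult(
        rows=pd.DataFrame(
            rows, columns=["subset", "size", "seed", "prediction_r", "subsampled"]
        ),
        kind="network",
    )


def metric_scan(
    cohort: CohortTable,
    sizes=range(1, 9),
    grid: HyperGrid | None = None,
    K: int = 10,
    seed: int = 0,
) -> SubsetScanResult:
    """Prediction r for clinical-metric subsets of each size.

    A 1-D outcome block simply degenerates the Y side of the CCA to a single
    weight, so every combination — including single metrics — runs through
    the same validation; sizes with more than 200 combinations are randomly
    subsampled (flagged in the output).
    """
    names = list(cohort.metrics.columns)
    rows = []
    for size in sizes:
        if not 1 <= size <= len(names):
            raise ValueError(f"metric subset size {size} out of range [1, {len(names)}]")
        combos = list(combinations(names, size))
        subsampled = False
        if len(combos) > MAX_COMBOS_PER_SIZE:
            rng = np.random.default_rng(seed)
            pick = rng.choice(len(combos), size=MAX_COMBOS_PER_SIZE, replace=False)
            combos = [combos[i] for i in sorted(pick)]
            subsampled = True
        for combo in combos:
            restricted = cohort.with_metrics(cohort.metrics[list(combo)])
            res = run_validation(restricted, "kfold", grid=grid, K=K, seed=seed)
            rows.append(("+".join(combo), size, seed, res.prediction_r, subsampled))
    return SubsetScanResult(
        rows=pd.DataFrame(
            rows, columns=["subset", "size", "seed", "prediction_r", "subsampled"]
        ),
        kind="metric",
    )
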