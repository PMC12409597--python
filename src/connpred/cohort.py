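"""The universal pipeline input: per-participant edges, outcomes, and labels.

A :class:`CohortTable` couples a participants-by-edges FC table with an
8-metric clinical outcome block (difference scores by default), a diagnosis
category and a treatment arm per participant, and the atlas that defines the
edge ordering.  Pre/post scale scores may be carried alongside so the outcome
block can be recomputed as difference or percent-change scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasSpec

logger = logging.getLogger(__name__)

#: The eight clinical outcome scales: Beck Depression Inventory, Hamilton
#: Anxiety, Hamilton Depression, Penn State Worry Questionnaire, Liebowitz
#: Social Anxiety Scale, Ruminative Response Scale, and the two Emotion
#: Regulation Questionnaire subscales (suppression, reappraisal).
METRIC_NAMES = ("BDI", "HAMA", "HAMD", "PSWQ", "LSAS", "RUM", "ERQ_S", "ERQ_R")


@dataclass(frozen=True)
class CohortTable:
    """Aligned per-participant FC edge vectors, outcomes, and group labels.

    All frames share the same participant-id index, in the same order.
    ``metrics`` holds the outcome block actually fed to the model (difference
    scores unless recomputed); ``metrics_pre``/``metrics_post`` are optional
    raw scale scores.
    """

    edges: pd.DataFrame
    metrics: pd.DataFrame
    diagnosis: pd.Series
    treatment: pd.Series
    atlas: AtlasSpec
    metrics_pre: pd.DataFrame | None = None
    metrics_post: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = self.edges.index
        if ids.has_duplicates:
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicated participant ids: {dups}")
        for name, other in (
            ("metrics", self.metrics.index),
            ("diagnosis", self.diagnosis.index),
            ("treatment", self.treatment.index),
        ):
            if not ids.equals(other):
                raise ValueError(f"participant ids of {name} do not match edges")
        expected = self.atlas.n_edges
        if self.edges.shape[1] != expected:
            # network-restricted cohorts carry a subset of the atlas's edges
            known = set(self.atlas.edge_labels())
            if not set(self.edges.columns) <= known:
                raise ValueError(
                    f"edge table has {self.edges.shape[1]} columns, expected "
                    f"R(R-1)/2 = {expected} for the declared {self.atlas.n_regions}-region atlas"
                )

    @property
    def n(self) -> int:
        return len(self.edges)

    @property
    def participant_ids(self) -> pd.Index:
        return self.edges.index

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    @property
    def n_metrics(self) -> int:
        return self.metrics.shape[1]

    def edge_values(self) -> np.ndarray:
        return self.edges.to_numpy(dtype=float)

    def metric_values(self) -> np.ndarray:
        return self.metrics.to_numpy(dtype=float)

    def subset_rows(self, ids) -> "CohortTable":
        """Row subset (e.g. one cross-validation fold), order preserved."""
        return replace(
            self,
            edges=self.edges.loc[ids],
            metrics=self.metrics.loc[ids],
            diagnosis=self.diagnosis.loc[ids],
            treatment=self.treatment.loc[ids],
            metrics_pre=None if self.metrics_pre is None else self.metrics_pre.loc[ids],
            metrics_post=None if self.metrics_post is None else self.metrics_post.loc[ids],
        )

    def with_edges(self, edges: pd.DataFrame) -> "CohortTable":
        out = replace(self, edges=edges)
        return out

    def with_metrics(self, metrics: pd.DataFrame) -> "CohortTable":
        return replace(self, metrics=metrics)


# ---- directory I/O ---------------------------------------------------------

ATLAS_FILE = "atlas.tsv"
EDGES_FILE = "edges.tsv"
PHENOTYPE_FILE = "phenotype.tsv"


def write_cohort(cohort: CohortTable, directory) -> None:
    """Write a cohort as three TSVs: atlas, edge table, phenotype table."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.atlas.to_tsv(d / ATLAS_FILE)
    cohort.edges.to_csv(d / EDGES_FILE, sep="\t")
    pheno = pd.DataFrame(
        {"diagnosis": cohort.diagnosis, "treatment": cohort.treatment}
    )
    for m in cohort.metrics.columns:
        pheno[f"{m}_change"] = cohort.metrics[m]
    if cohort.metrics_pre is not None and cohort.metrics_post is not None:
        for m in cohort.metrics_pre.columns:
            pheno[f"{m}_pre"] = cohort.metrics_pre[m]
            pheno[f"{m}_post"] = cohort.metrics_post[m]
    pheno.index.name = "participant_id"
    pheno.to_csv(d / PHENOTYPE_FILE, sep="\t")


def read_cohort(directory) -> CohortTable:
    """Read a cohort directory; drop participants with incomplete outcomes.

    Completers-only: rows with any missing clinical metric are dropped with a
    logged count, and the edge/phenotype participant ids must agree exactly
    otherwise (orphans on either side are an error).
    """
    d = Path(directory)
    atlas = AtlasSpec.from_tsv(d / ATLAS_FILE)
    edges = pd.read_csv(d / EDGES_FILE, sep="\t", index_col="participant_id")
    pheno = pd.read_csv(d / PHENOTYPE_FILE, sep="\t", index_col="participant_id")
    for frame, name in ((edges, "edge"), (pheno, "phenotype")):
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicated participant ids in {name} table: {dups}")
    orphans = set(edges.index).symmetric_difference(pheno.index)
    if orphans:
        raise ValueError(
            f"participant ids do not match between edge and phenotype tables: {sorted(orphans)}"
        )
    expected = atlas.n_edges
    if edges.shape[1] != expected:
        raise ValueError(
            f"edge table has {edges.shape[1]} columns, expected R(R-1)/2 = {expected} "
            f"for the declared {atlas.n_regions}-region atlas"
        )
    pheno = pheno.loc[edges.index]

    change_cols = [c for c in pheno.columns if c.endswith("_change")]
    metric_names = [c[: -len("_change")] for c in change_cols]
    metrics = pheno[change_cols].copy()
    metrics.columns = metric_names
    complete = metrics.notna().all(axis=1)
    if (~complete).any():
        dropped = metrics.index[~complete].tolist()
        logger.info(
            "dropping %d participant(s) with incomplete clinical data: %s",
            len(dropped), dropped,
        )
    keep = metrics.index[complete]

    pre_cols = [f"{m}_pre" for m in metric_names]
    post_cols = [f"{m}_post" for m in metric_names]
    has_prepost = all(c in pheno.columns for c in pre_cols + post_cols)
    metrics_pre = metrics_post = None
    if has_prepost:
        metrics_pre = pheno.loc[keep, pre_cols].copy()
        metrics_pre.columns = metric_names
        metrics_post = pheno.loc[keep, post_cols].copy()
        metrics_post.columns = metric_names

    return CohortTable(
        edges=edges.loc[keep],
        metrics=metrics.loc[keep],
        diagnosis=pheno.loc[keep, "diagnosis"],
        treatment=pheno.loc[keep, "treatment"],
        atlas=atlas,
        metrics_pre=metrics_pre,
        metrics_post=metrics_post,
    )
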