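"""Brain parcellation metadata: regions, network labels, and edge/cell bookkeeping.

The pipeline works on a whole-brain parcellation whose regions are grouped
into nine large-scale networks: seven cortical resting-state networks (visual,
sensorimotor, dorsal attention, ventral attention, limbic, frontoparietal
control, default mode) plus subcortex and cerebellum.  The full-scale
configuration has 442 regions (400 cortical + 32 subcortical + 10 cerebellar);
a 60-region layout with the same nine networks is provided for fast runs.

Edges (region pairs) are ordered as the upper triangle of the region-by-region
matrix, row-major with i < j.  Every edge belongs to an unordered network-pair
"cell" such as (DMN, DMN) or (DMN, DAN); cells are the aggregation unit for
edge-attribution summaries and for planting synthetic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical nine-network label set: 7 cortical networks + subcortical + cerebellum.
NETWORK_LABELS = ("VIS", "SMN", "DAN", "VAN", "LIM", "CON", "DMN", "SUB", "CEM")

#: Region counts per network in the 442-region whole-brain configuration
#: (400 cortical split over the 7 networks, 32 subcortical, 10 cerebellar).
FULL_NETWORK_SIZES = (61, 77, 46, 47, 26, 52, 91, 32, 10)

#: Compact 60-region layout used for fast test-scale runs.
TEST_NETWORK_SIZES = (10, 8, 8, 6, 6, 6, 6, 5, 5)


@dataclass(frozen=True)
class AtlasSpec:
    """Region-to-network mapping that fixes edge ordering and cell membership.

    Parameters
    ----------
    table:
        DataFrame with columns ``region_index`` (0..R-1, gap-free),
        ``region_name`` and ``network_label`` (drawn from a nine-label set).
    """

    table: pd.DataFrame
    network_labels: tuple[str, ...] = NETWORK_LABELS

    def __post_init__(self) -> None:
        t = self.table
        required = {"region_index", "region_name", "network_label"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        idx = np.asarray(t["region_index"])
        if not np.array_equal(idx, np.arange(len(t))):
            raise ValueError("region_index must be 0..R-1 with no gaps")
        bad = set(t["network_label"]) - set(self.network_labels)
        if bad:
            raise ValueError(f"unknown network labels: {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def n_edges(self) -> int:
        r = self.n_regions
        return r * (r - 1) // 2

    @property
    def region_networks(self) -> np.ndarray:
        """Network label of each region, in region order."""
        return self.table["network_label"].to_numpy()

    @property
    def region_names(self) -> np.ndarray:
        return self.table["region_name"].to_numpy()

    def network_sizes(self) -> dict[str, int]:
        counts = self.table["network_label"].value_counts()
        return {lab: int(counts.get(lab, 0)) for lab in self.network_labels}

    # ---- edge bookkeeping -------------------------------------------------

    def edge_index_pairs(self) -> np.ndarray:
        """(n_edges, 2) array of region index pairs (i, j), i < j, row-major."""
        i, j = np.triu_indices(self.n_regions, k=1)
        return np.column_stack([i, j])

    def edge_labels(self) -> list[str]:
        """Edge identifiers ``regionNameA|regionNameB`` in edge order."""
        names = self.region_names
        pairs = self.edge_index_pairs()
        return [f"{names[i]}|{names[j]}" for i, j in pairs]

    def edge_cells(self) -> list[tuple[str, str]]:
        """Unordered network-pair cell of each edge, as a canonically sorted tuple.

        Cells are sorted by position in ``network_labels`` so that
        ("DMN", "DAN") and ("DAN", "DMN") map to the same key.
        """
        nets = self.region_networks
        order = {lab: k for k, lab in enumerate(self.network_labels)}
        pairs = self.edge_index_pairs()
        out = []
        for i, j in pairs:
            a, b = nets[i], nets[j]
            out.append((a, b) if order[a] <= order[b] else (b, a))
        return out

    def cell_mask(self, cell: tuple[str, str]) -> np.ndarray:
        """Boolean mask over edges belonging to one network-pair cell."""
        a, b = canonical_cell(cell, self.network_labels)
        return np.array([c == (a, b) for c in self.edge_cells()])

    def all_cells(self) -> list[tuple[str, str]]:
        """All 45 unordered network-pair cells (incl. within-network)."""
        labs = self.network_labels
        return [(labs[i], labs[j]) for i in range(len(labs)) for j in range(i, len(labs))]

    # ---- I/O --------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AtlasSpec":
        return cls(pd.read_csv(path, sep="\t"))


def canonical_cell(cell: tuple[str, str], labels=NETWORK_LABELS) -> tuple[str, str]:
    """Sort a network pair into canonical order (position in the label set)."""
    a, b = cell
    order = {lab: k for k, lab in enumerate(labels)}
    if a not in order or b not in order:
        raise ValueError(f"unknown network label in cell {cell!r}")
    return (a, b) if order[a] <= order[b] else (b, a)


def make_atlas(network_sizes=TEST_NETWORK_SIZES, labels=NETWORK_LABELS) -> AtlasSpec:
    """Build an atlas with the given per-network region counts.

    Region names are ``{network}_{k}``; regions are laid out network by
    network in label order.
    """
    if len(network_sizes) != len(labels):
        raise ValueError("network_sizes and labels must have equal length")
    rows = []
    idx = 0
    for lab, size in zip(labels, network_sizes):
        for k in range(int(size)):
            rows.append((idx, f"{lab}_{k + 1}", lab))
            idx += 1
    return AtlasSpec(pd.DataFrame(rows, columns=["region_index", "region_name", "network_label"]))


def full_atlas() -> AtlasSpec:
    """442-region whole-brain configuration (400 cortical + 32 + 10)."""
    return make_atlas(FULL_NETWORK_SIZES)


def test_scale_atlas() -> AtlasSpec:
    """60-region nine-network layout for seconds-scale runs."""
    return make_atlas(TEST_NETWORK_SIZES)
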