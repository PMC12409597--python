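"""Synthetic cohorts with a planted, recoverable brain-symptom latent factor.

The generator emulates the statistical structure the downstream analysis
assumes: a single latent severity-change factor ``z`` that loads on a
structured subset of FC edges (selected network-pair cells) and on the eight
clinical change scores.  For participant ``i``:

    edges_i   = mu + a * (gamma * z_i) + eps_i,   eps ~ N(0, sigma_b^2 I)
    metrics_i =      b * (delta * z_i) + eta_i,   eta ~ N(0, sigma_y^2 I)

with unit-norm loading vectors ``a`` (supported only on loaded cells, signs
alternating) and ``b``.  The population correlation between the two sides'
best projections has the closed form

    rho* = gamma * delta / sqrt((gamma^2 + sigma_b^2) * (delta^2 + sigma_y^2))

which recovery tests compare against.  Diagnosis categories and treatment
arms are assigned at the stated proportions and may carry nuisance mean
shifts, but by default do not modulate the latent slope — group structure is
noise, not signal, which is what makes cross-group generalization possible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasSpec, TEST_NETWORK_SIZES, canonical_cell, make_atlas
from .cohort import METRIC_NAMES, CohortTable

DIAGNOSIS_LABELS = ("MDD", "SAD", "GAD", "PD", "PTSD", "PDD")
#: Internalizing-psychopathology case mix: depression and social anxiety
#: dominate, with smaller GAD/panic/PTSD/persistent-depression groups.
DIAGNOSIS_PROPORTIONS = (0.30, 0.30, 0.12, 0.10, 0.10, 0.08)

TREATMENT_LABELS = ("SSRI", "CBT", "ST")
#: Arm mix of the emulated two-trial design: 46 SSRI, 41+48 CBT, 46 ST of 181.
TREATMENT_PROPORTIONS = (46 / 181, 89 / 181, 46 / 181)

#: Cells carrying true edge loadings: default-mode couplings plus
#: sensorimotor/visual/attention cells, echoing where treatment-relevant
#: connectivity concentrates in internalizing disorders.
DEFAULT_LOADED_CELLS = (
    ("DMN", "DMN"),
    ("DMN", "DAN"),
    ("DMN", "VAN"),
    ("DMN", "CON"),
    ("SMN", "SMN"),
    ("SMN", "VIS"),
    ("DAN", "VAN"),
)

#: Raw (pre-normalization) metric loadings; rumination (RUM), worry (PSWQ)
#: and social anxiety (LSAS) dominate the symptom side.
DEFAULT_METRIC_LOADINGS = (0.50, 0.45, 0.45, 0.85, 0.80, 1.00, 0.25, 0.30)

#: Plausible pre-treatment scale means for the eight metrics, used when
#: synthesizing pre/post scores around the generated change scores.
DEFAULT_METRIC_BASELINES = (25.0, 18.0, 17.0, 55.0, 60.0, 45.0, 30.0, 28.0)


def expected_latent_correlation(
    gamma: float, delta: float, sigma_b: float, sigma_y: float
) -> float:
    """Closed-form population correlation between the two sides' projections."""
    denom = math.sqrt((gamma**2 + sigma_b**2) * (delta**2 + sigma_y**2))
    if denom == 0:
        return 0.0
    return (gamma * delta) / denom


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-factor cohort generator.

    The default signal/noise scales (gamma=6, sigma_b=1, delta=1,
    sigma_y=sqrt(107/37)) are calibrated once so that rho* = 0.5 while the
    edge-side factor sits safely above the spiked-covariance detection
    threshold at n=181 x 1770 edges (gamma^2/sigma_b^2 >> sqrt(p/n)); most of
    the attenuating noise is placed on the symptom side, where estimation is
    low-dimensional and stable.  They encode the study conditions, not real
    effect sizes (the source trials report no edge-level effect sizes).
    """

    n_participants: int = 181
    network_sizes: tuple[int, ...] = TEST_NETWORK_SIZES
    latent_strength_brain: float = 6.0     # gamma
    latent_strength_symptom: float = 1.0   # delta
    edge_noise_sd: float = 1.0             # sigma_b
    symptom_noise_sd: float = math.sqrt(107 / 37)  # sigma_y -> rho* = 0.5
    loading_fraction: float = 0.5
    loaded_network_pairs: tuple[tuple[str, str], ...] = DEFAULT_LOADED_CELLS
    n_metrics: int = 8
    true_metric_loadings: tuple[float, ...] = DEFAULT_METRIC_LOADINGS
    diagnosis_labels: tuple[str, ...] = DIAGNOSIS_LABELS
    diagnosis_proportions: tuple[float, ...] = DIAGNOSIS_PROPORTIONS
    treatment_labels: tuple[str, ...] = TREATMENT_LABELS
    treatment_proportions: tuple[float, ...] = TREATMENT_PROPORTIONS
    group_offset_sd: float = 0.1
    edge_mean: float = 0.0
    metric_baselines: tuple[float, ...] = DEFAULT_METRIC_BASELINES
    baseline_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError("n_participants must be at least 4")
        if not 0 < self.loading_fraction <= 1:
            raise ValueError("loading_fraction must lie in (0, 1]")
        for name in ("latent_strength_brain", "latent_strength_symptom",
                     "edge_noise_sd", "symptom_noise_sd", "group_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.true_metric_loadings) != self.n_metrics:
            raise ValueError("true_metric_loadings must have length n_metrics")
        if len(self.metric_baselines) != self.n_metrics:
            raise ValueError("metric_baselines must have length n_metrics")
        if len(self.diagnosis_proportions) != len(self.diagnosis_labels):
            raise ValueError("diagnosis proportions/labels length mismatch")
        if len(self.treatment_proportions) != len(self.treatment_labels):
            raise ValueError("treatment proportions/labels length mismatch")
        for props in (self.diagnosis_proportions, self.treatment_proportions):
            if abs(sum(props) - 1.0) > 1e-8:
                raise ValueError("group proportions must sum to 1")
        if self.latent_strength_brain > 0 and not self.loaded_network_pairs:
            raise ValueError(
                "loaded_network_pairs is empty but a brain loading is requested "
                "(latent_strength_brain > 0)"
            )

    @property
    def n_regions(self) -> int:
        return int(sum(self.network_sizes))

    @property
    def rho_star(self) -> float:
        return expected_latent_correlation(
            self.latent_strength_brain,
            self.latent_strength_symptom,
            self.edge_noise_sd,
            self.symptom_noise_sd,
        )

    def atlas(self) -> AtlasSpec:
        return make_atlas(self.network_sizes)

    @classmethod
    def from_target_rho(cls, rho: float, **kwargs) -> "SyntheticSpec":
        """Spec with sigma_y solved so the planted rho* equals ``rho``.

        gamma, delta, sigma_b are taken from kwargs or the defaults; rho=0
        is produced by zeroing the symptom loading instead.
        """
        if not 0 <= rho < 1:
            raise ValueError("target rho must lie in [0, 1)")
        if rho == 0:
            return cls(latent_strength_symptom=0.0, **kwargs)
        gamma = kwargs.get("latent_strength_brain", cls.latent_strength_brain)
        delta = kwargs.get("latent_strength_symptom", cls.latent_strength_symptom)
        sigma_b = kwargs.get("edge_noise_sd", cls.edge_noise_sd)
        ratio = gamma**2 / (rho**2 * (gamma**2 + sigma_b**2))
        if ratio <= 1:
            raise ValueError("target rho unreachable with the given gamma/sigma_b")
        sigma_y = math.sqrt((ratio - 1) * delta**2)
        kwargs.pop("symptom_noise_sd", None)
        return cls(symptom_noise_sd=sigma_y, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery tests."""

    latent_scores: np.ndarray          # z_i, length n
    true_edge_loadings: np.ndarray     # a, unit norm over edges
    true_metric_loadings: np.ndarray   # b, unit norm over metrics
    expected_latent_correlation: float  # rho*

    def loaded_edge_mask(self) -> np.ndarray:
        return self.true_edge_loadings != 0

    def to_json(self, path) -> None:
        payload = {
            "latent_scores": self.latent_scores.tolist(),
            "true_edge_loadings": self.true_edge_loadings.tolist(),
            "true_metric_loadings": self.true_metric_loadings.tolist(),
            "expected_latent_correlation": self.expected_latent_correlation,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _group_counts(n: int, proportions) -> list[int]:
    """Deterministic per-group counts at the stated proportions (largest-remainder)."""
    raw = [n * p for p in proportions]
    counts = [int(math.floor(x)) for x in raw]
    short = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainders first
    for j in order[:short]:
        counts[j] += 1
    return counts


def _assign_groups(n: int, labels, proportions, rng) -> np.ndarray:
    counts = _group_counts(n, proportions)
    flat = np.repeat(np.asarray(labels, dtype=object), counts)
    return flat[rng.permutation(n)]


def _edge_loadings(atlas: AtlasSpec, loaded_cells, fraction: float) -> np.ndarray:
    """Unit-norm loading vector supported on the loaded cells.

    Within each cell the first ceil(fraction * cell size) edges (in edge
    order) carry equal-magnitude loadings with alternating signs +,-,+,...
    so both positively and negatively contributing edges exist.
    """
    a = np.zeros(atlas.n_edges)
    cells = [canonical_cell(c, atlas.network_labels) for c in loaded_cells]
    for cell in cells:
        idx = np.flatnonzero(atlas.cell_mask(cell))
        if idx.size == 0:
            raise ValueError(f"loaded cell {cell!r} contains no edges in this atlas")
        n_load = max(1, math.ceil(fraction * idx.size))
        chosen = idx[:n_load]
        signs = np.where(np.arange(n_load) % 2 == 0, 1.0, -1.0)
        a[chosen] = signs
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("no edges received a true loading")
    return a / norm


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort plus its ground truth; bit-identical given (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    atlas = spec.atlas()
    n, p, q = spec.n_participants, atlas.n_edges, spec.n_metrics

    a = _edge_loadings(atlas, spec.loaded_network_pairs, spec.loading_fraction)
    b_raw = np.asarray(spec.true_metric_loadings, dtype=float)
    if np.linalg.norm(b_raw) == 0:
        raise ValueError("true_metric_loadings must not be all zero")
    b = b_raw / np.linalg.norm(b_raw)

    z = rng.standard_normal(n)
    edges = spec.edge_mean + np.outer(spec.latent_strength_brain * z, a)
    edges += rng.normal(0.0, spec.edge_noise_sd, size=(n, p)) if spec.edge_noise_sd > 0 else 0.0
    change = np.outer(spec.latent_strength_symptom * z, b)
    change += rng.normal(0.0, spec.symptom_noise_sd, size=(n, q)) if spec.symptom_noise_sd > 0 else 0.0

    diagnosis = _assign_groups(n, spec.diagnosis_labels, spec.diagnosis_proportions, rng)
    treatment = _assign_groups(n, spec.treatment_labels, spec.treatment_proportions, rng)

    if spec.group_offset_sd > 0:
        # Nuisance per-group mean shifts (no group-specific latent slope).
        for labels, assigned in ((spec.diagnosis_labels, diagnosis),
                                 (spec.treatment_labels, treatment)):
            for lab in labels:
                mask = assigned == lab
                edges[mask] += rng.normal(0.0, spec.group_offset_sd, size=p)
                change[mask] += rng.normal(0.0, spec.group_offset_sd, size=q)

    pre = np.tile(np.asarray(spec.metric_baselines, dtype=float), (n, 1))
    if spec.baseline_sd > 0:
        pre = pre + rng.normal(0.0, spec.baseline_sd, size=(n, q))
    post = pre + change

    ids = pd.Index([f"sub-{i + 1:04d}" for i in range(n)], name="participant_id")
    metric_names = list(METRIC_NAMES[:q]) if q <= len(METRIC_NAMES) else [
        f"metric_{j + 1}" for j in range(q)
    ]
    cohort = CohortTable(
        edges=pd.DataFrame(edges, index=ids, columns=atlas.edge_labels()),
        metrics=pd.DataFrame(change, index=ids, columns=metric_names),
        diagnosis=pd.Series(diagnosis, index=ids, name="diagnosis"),
        treatment=pd.Series(treatment, index=ids, name="treatment"),
        atlas=atlas,
        metrics_pre=pd.DataFrame(pre, index=ids, columns=metric_names),
        metrics_post=pd.DataFrame(post, index=ids, columns=metric_names),
    )
    truth = GroundTruth(
        latent_scores=z,
        true_edge_loadings=a,
        true_metric_loadings=b,
        expected_latent_correlation=spec.rho_star,
    )
    return cohort, truth


def generate_timeseries_cohort(
    spec: SyntheticSpec,
    n_timepoints: int,
    network_coupling: float = 0.3,
) -> dict[str, pd.DataFrame]:
    """Parcellated time series whose expected FC has block structure by network.

    Each region's signal mixes its network's shared factor with idiosyncratic
    white noise: ``x = sqrt(w) * f_net + sqrt(1 - w) * e`` with
    ``w = network_coupling``, so within-network pairs have expected
    correlation ``w`` and between-network pairs 0.  ``network_coupling=1``
    makes same-network regions identical; ``0`` makes all regions independent.
    """
    if n_timepoints < 20:
        raise ValueError("n_timepoints must be >= 20 (correlation estimates meaningless)")
    if not 0 <= network_coupling <= 1:
        raise ValueError("network_coupling must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    atlas = spec.atlas()
    nets = atlas.region_networks
    w = network_coupling
    out: dict[str, pd.DataFrame] = {}
    for i in range(spec.n_participants):
        factors = {lab: rng.standard_normal(n_timepoints) for lab in atlas.network_labels}
        x = np.empty((n_timepoints, atlas.n_regions))
        for r in range(atlas.n_regions):
            noise = rng.standard_normal(n_timepoints)
            x[:, r] = math.sqrt(w) * factors[nets[r]] + math.sqrt(1 - w) * noise
        out[f"sub-{i + 1:04d}"] = pd.DataFrame(x, columns=atlas.region_names)
    return out
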