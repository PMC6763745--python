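"""Permutation test on linear-SVM weights: which edges discriminate?

The classifier is fit once on the true diagnostic labels of the entire
cohort (no cross-validation), then refit under B random permutations of
the labels. For each edge the observed absolute weight is compared with
its own permutation distribution, giving the add-one Monte-Carlo p-value

    p_j = (1 + #{b : |w_perm(b, j)| >= |w_obs(j)|}) / (B + 1),

which is never zero and, at B = 10,000, resolves the strictest reporting
tier (p < 0.001). Edges passing p < 0.01 are called over-connected when
the observed weight is positive (feature larger in ASD pushes the score
toward the ASD side) and under-connected when negative, and are binned by
tiers (0.01 / 0.005 / 0.001) and by Mesulam division pairs.

No multiple-testing correction is applied across edges: each edge is
tested against its own null, and results are reported at the tiered
thresholds. This is a per-edge screen, not a family-wise procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas_io import MESULAM_DIVISIONS, AtlasMetadata, EdgeIndex
from .classification import fit_lsvm

__all__ = [
    "DEFAULT_TIERS",
    "PermutationResult",
    "ConnectionSignificance",
    "MesulamTabulation",
    "permutation_weight_test",
    "call_connections",
    "mesulam_tabulate",
]

DEFAULT_TIERS = (0.01, 0.005, 0.001)


@dataclass(frozen=True)
class PermutationResult:
    observed_weights: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    seed: int
    warning: str | None = None

    @property
    def min_attainable_p(self) -> float:
        return 1.0 / (self.n_permutations + 1)


@dataclass(frozen=True)
class ConnectionSignificance:
    pair: tuple[int, int]
    labels: tuple[str, str]
    weight: float
    p_value: float
    direction: str  # 'over' (weight > 0) or 'under' (weight < 0)
    tier: float  # strictest threshold passed


@dataclass(frozen=True)
class MesulamTabulation:
    """Significant-edge counts by (unordered) division pair plus the
    number of significant edges touching each region."""

    counts: pd.DataFrame  # 6 x 6 symmetric, divisions as index/columns
    region_counts: pd.DataFrame  # index, label, n_connections

    @property
    def total(self) -> int:
        c = self.counts.to_numpy()
        return int((c.sum() + np.trace(c)) / 2)


def permutation_weight_test(
    X: np.ndarray,
    y: Sequence[int],
    n_permutations: int = 10_000,
    seed: int = 0,
    c: float = 1.0,
    sites: Sequence[str] | None = None,
    stratify_by_site: bool = False,
    tiers: Sequence[float] = DEFAULT_TIERS,
) -> PermutationResult:
    """Label-permutation null for every edge's absolute SVM weight.

    The observed model is fit on the true labels over the whole dataset;
    each of the B permutations reshuffles the labels (optionally within
    site) with a stream derived from ``(seed, b)`` and refits with the
    same solver settings.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if stratify_by_site and sites is None:
        raise ValueError("stratify_by_site requires site labels")

    observed = fit_lsvm(X, y, c=c).weights
    abs_obs = np.abs(observed)
    exceed = np.zeros_like(abs_obs, dtype=int)
    sites_arr = np.asarray(sites) if sites is not None else None
    for b in range(n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        if stratify_by_site:
            y_perm = y.copy()
            for site in np.unique(sites_arr):
                idx = np.flatnonzero(sites_arr == site)
                y_perm[idx] = y[idx[rng.permutation(len(idx))]]
        else:
            y_perm = y[rng.permutation(len(y))]
        if len(np.unique(y_perm)) < 2:  # cannot happen for shuffles, defensive
            continue
        w_perm = fit_lsvm(X, y_perm, c=c).weights
        exceed += (np.abs(w_perm) >= abs_obs).astype(int)

    p = (1.0 + exceed) / (n_permutations + 1.0)
    warning = None
    strictest = min(tiers) if len(tiers) else None
    if strictest is not None and 1.0 / (n_permutations + 1.0) >= strictest:
        warning = (
            f"minimum attainable p-value {1.0 / (n_permutations + 1.0):.3g} does "
            f"not resolve the strictest tier {strictest}; increase permutations"
        )
    return PermutationResult(
        observed_weights=observed,
        p_values=p,
        n_permutations=n_permutations,
        seed=seed,
        warning=warning,
    )


def call_connections(
    result: PermutationResult,
    edge_index: EdgeIndex,
    atlas: AtlasMetadata | None = None,
    tiers: Sequence[float] = DEFAULT_TIERS,
) -> list[ConnectionSignificance]:
    """Edges significant at the loosest tier, with direction and the
    strictest tier passed; sorted by tier strictness then |weight|
    descending, ties broken by (i, j)."""
    tiers = sorted(tiers, reverse=True)  # loosest first
    if len(result.p_values) != edge_index.n_edges:
        raise ValueError("p-value vector does not match the edge index")
    labels = atlas.labels if atlas is not None else [
        f"region_{i}" for i in range(edge_index.n_regions)
    ]
    calls: list[ConnectionSignificance] = []
    for k, (i, j) in enumerate(edge_index.pairs):
        p = float(result.p_values[k])
        if p >= tiers[0]:
            continue
        passed = [t for t in tiers if p < t]
        w = float(result.observed_weights[k])
        calls.append(
            ConnectionSignificance(
                pair=(i, j),
                labels=(labels[i], labels[j]),
                weight=w,
                p_value=p,
                direction="over" if w > 0 else "under",
                tier=min(passed),
            )
        )
    calls.sort(key=lambda cs: (cs.tier, -abs(cs.weight), cs.pair))
    return calls


def connections_frame(connections: Sequence[ConnectionSignificance]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "i": [cs.pair[0] for cs in connections],
            "j": [cs.pair[1] for cs in connections],
            "label_i": [cs.labels[0] for cs in connections],
            "label_j": [cs.labels[1] for cs in connections],
            "weight": [cs.weight for cs in connections],
            "p_value": [cs.p_value for cs in connections],
            "direction": [cs.direction for cs in connections],
            "tier": [cs.tier for cs in connections],
        }
    )


def mesulam_tabulate(
    connections: Sequence[ConnectionSignificance], atlas: AtlasMetadata
) -> MesulamTabulation:
    """Count significant edges within and between the six Mesulam
    divisions (unordered pairs; within-division on the diagonal) and per
    region."""
    divisions = list(MESULAM_DIVISIONS)
    counts = pd.DataFrame(
        np.zeros((6, 6), dtype=int), index=divisions, columns=divisions
    )
    region_hits = np.zeros(atlas.n_regions, dtype=int)
    for cs in connections:
        i, j = cs.pair
        di = atlas.regions[i].mesulam_division
        dj = atlas.regions[j].mesulam_division
        counts.loc[di, dj] += 1
        if di != dj:
            counts.loc[dj, di] += 1
        region_hits[i] += 1
        region_hits[j] += 1
    region_counts = pd.DataFrame(
        {
            "index": range(atlas.n_regions),
            "label": atlas.labels,
            "n_connections": region_hits,
        }
    )
    return MesulamTabulation(counts=counts, region_counts=region_counts)
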