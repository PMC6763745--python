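"""From ROI time series to Fisher-normalized edge features.

The pipeline per subject is: Pearson correlation between all region
pairs (an N x N symmetric matrix), variance-normalized Fisher transform
Z = sqrt(n - 3) * arctanh(r) with n the subject's own timepoint count, and
vectorization of the upper triangle into N(N-1)/2 features.

Before any correlation is computed the module applies the exclusion
policy: cerebellar regions are dropped, regions with zero-variance
("null") time series are detected per subject, and depending on how many
subjects are affected either those subjects are removed (few affected)
or the offending regions are removed for everyone (many affected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .atlas_io import AtlasMetadata, EdgeIndex, build_edge_index

__all__ = [
    "FCMatrix",
    "FeatureMatrix",
    "ExclusionReport",
    "NullRegionError",
    "pearson_fc",
    "fisher_normalize",
    "detect_null_regions",
    "apply_exclusion_policy",
    "drop_cerebellum",
    "build_feature_matrix",
]

#: |r| is clipped to this bound before arctanh so that duplicate columns
#: (r = +/-1) yield large finite features instead of infinities.
R_CLIP = 1.0 - 1e-12

DEFAULT_SUBJECT_THRESHOLD = 10


class NullRegionError(ValueError):
    """A zero-variance region reached an operation that requires variance."""


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric N x N Pearson correlation matrix with its timepoint count."""

    values: np.ndarray
    n_timepoints: int


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x edges table of Fisher-normalized connectivity features."""

    values: np.ndarray
    edge_index: EdgeIndex
    subject_ids: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ExclusionReport:
    """Null-region hits and the removals the policy derived from them."""

    null_region_hits: list[tuple[str, int]] = field(default_factory=list)
    removed_subjects: list[str] = field(default_factory=list)
    removed_regions: list[int] = field(default_factory=list)
    policy: str | None = None
    threshold: int | None = None

    @property
    def affected_subjects(self) -> list[str]:
        return sorted({sid for sid, _ in self.null_region_hits})

    @property
    def affected_regions(self) -> list[int]:
        return sorted({r for _, r in self.null_region_hits})

    def to_jsonable(self) -> dict:
        return {
            "null_region_hits": [[sid, int(r)] for sid, r in self.null_region_hits],
            "removed_subjects": list(self.removed_subjects),
            "removed_regions": [int(r) for r in self.removed_regions],
            "policy": self.policy,
            "threshold": self.threshold,
        }


def pearson_fc(series: np.ndarray) -> FCMatrix:
    """Sample Pearson correlation between every pair of region columns.

    Requires T >= 3 rows and positive variance in every column (apply the
    exclusion stage first); the result is exactly symmetric with unit
    diagonal.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a T x N table")
    t, n = series.shape
    if t < 3:
        raise ValueError(f"need at least 3 timepoints, got {t}")
    if n < 2:
        raise ValueError(f"need at least 2 regions, got {n}")
    variances = series.var(axis=0)
    dead = np.flatnonzero(variances == 0.0)
    if dead.size:
        raise NullRegionError(
            f"zero-variance region(s) {dead.tolist()} — exclusion must run first"
        )
    corr = np.corrcoef(series, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return FCMatrix(values=corr, n_timepoints=t)


def fisher_normalize(
    r: np.ndarray | float, n: int, variance_normalized: bool = True
) -> np.ndarray | float:
    """Fisher z transform of correlations, scaled by the scan length.

    ``Z = sqrt(n - 3) * arctanh(r)`` with ``n`` the number of timepoints,
    so that features from scans of different length live on a common
    (approximately unit-variance under the null) scale. With
    ``variance_normalized=False`` the plain arctanh is returned.
    """
    if n < 4:
        raise ValueError(f"need at least 4 timepoints for the transform, got {n}")
    arr = np.clip(np.asarray(r, dtype=float), -R_CLIP, R_CLIP)
    z = np.arctanh(arr)
    if variance_normalized:
        z = np.sqrt(n - 3.0) * z
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(z)
    return z


def detect_null_regions(series_set: Mapping[str, np.ndarray]) -> ExclusionReport:
    """Flag every (subject, region) whose time series has zero variance.

    A constant (not merely all-zero) column also counts: its correlation
    with anything is undefined. Hits are sorted by region then subject.
    """
    n_regions: int | None = None
    hits: list[tuple[str, int]] = []
    for sid, series in series_set.items():
        series = np.asarray(series, dtype=float)
        if n_regions is None:
            n_regions = series.shape[1]
        elif series.shape[1] != n_regions:
            raise ValueError(
                f"region-count mismatch: subject {sid} has {series.shape[1]} "
                f"columns, expected {n_regions}"
            )
        for region in np.flatnonzero(series.var(axis=0) == 0.0):
            hits.append((sid, int(region)))
    hits.sort(key=lambda h: (h[1], h[0]))
    return ExclusionReport(null_region_hits=hits)


def apply_exclusion_policy(
    report: ExclusionReport, subject_threshold: int = DEFAULT_SUBJECT_THRESHOLD
) -> ExclusionReport:
    """Decide between dropping affected subjects and dropping regions.

    When at most ``subject_threshold`` distinct subjects carry a null
    region they are removed; when more are affected the regions are
    removed instead so no subject is lost.
    """
    if subject_threshold < 1:
        raise ValueError("subject_threshold must be >= 1")
    affected = report.affected_subjects
    if len(affected) <= subject_threshold:
        policy = "remove_subjects"
        removed_subjects = affected
        removed_regions: list[int] = []
    else:
        policy = "remove_regions"
        removed_subjects = []
        removed_regions = report.affected_regions
    return ExclusionReport(
        null_region_hits=list(report.null_region_hits),
        removed_subjects=removed_subjects,
        removed_regions=removed_regions,
        policy=policy,
        threshold=subject_threshold,
    )


def drop_cerebellum(
    series_set: Mapping[str, np.ndarray], atlas: AtlasMetadata
) -> tuple[dict[str, np.ndarray], AtlasMetadata]:
    """Remove cerebellar regions from the atlas and every subject's series,
    preserving the order of the surviving regions."""
    keep = [r.index for r in atlas.regions if not r.is_cerebellum]
    if len(keep) == atlas.n_regions:
        return dict(series_set), atlas
    reduced_atlas = atlas.subset(keep)
    reduced = {sid: np.asarray(s)[:, keep] for sid, s in series_set.items()}
    return reduced, reduced_atlas


def build_feature_matrix(
    series_set: Mapping[str, np.ndarray],
    atlas: AtlasMetadata | None = None,
    subject_threshold: int = DEFAULT_SUBJECT_THRESHOLD,
    variance_normalized: bool = True,
) -> tuple[FeatureMatrix, ExclusionReport]:
    """Full feature extraction: cerebellum removal, null-region exclusion,
    per-subject Pearson FC, Fisher normalization with each subject's own
    timepoint count, and upper-triangle vectorization.
    """
    series_set = {sid: np.asarray(s, dtype=float) for sid, s in series_set.items()}
    if atlas is not None:
        series_set, atlas = drop_cerebellum(series_set, atlas)

    report = detect_null_regions(series_set)
    report = apply_exclusion_policy(report, subject_threshold=subject_threshold)

    retained = {
        sid: s for sid, s in series_set.items() if sid not in set(report.removed_subjects)
    }
    if report.removed_regions:
        n_all = next(iter(series_set.values())).shape[1]
        keep = [i for i in range(n_all) if i not in set(report.removed_regions)]
        retained = {sid: s[:, keep] for sid, s in retained.items()}

    if len(retained) < 2:
        raise ValueError("fewer than 2 subjects remain after exclusion")

    n = next(iter(retained.values())).shape[1]
    edge_index = build_edge_index(n)
    iu = np.triu_indices(n, k=1)
    rows = np.empty((len(retained), edge_index.n_edges))
    ids = []
    for row, (sid, series) in enumerate(retained.items()):
        fc = pearson_fc(series)
        rows[row] = fisher_normalize(
            fc.values[iu], fc.n_timepoints, variance_normalized=variance_normalized
        )
        ids.append(sid)
    return FeatureMatrix(values=rows, edge_index=edge_index, subject_ids=tuple(ids)), report
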