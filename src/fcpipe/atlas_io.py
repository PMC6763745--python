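"""Input/output and canonical indexing for the connectivity pipeline.

This module defines the on-disk formats shared by every stage — atlas
metadata, phenotype (cohort) tables, ROI time-series tables and result
tables — plus the canonical edge indexing that maps the upper triangle of
an N x N connectivity matrix onto a flat feature vector.

All region indices are 0-based internally; human-readable outputs always
carry both the index and the anatomical label.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MESULAM_DIVISIONS",
    "RegionRecord",
    "AtlasMetadata",
    "SubjectRecord",
    "CohortTable",
    "EdgeIndex",
    "TimeSeriesTable",
    "ParseError",
    "read_timeseries",
    "write_timeseries",
    "read_cohort",
    "write_cohort",
    "read_atlas",
    "write_atlas",
    "build_edge_index",
    "write_results",
    "make_synthetic_atlas",
]

#: The six functional divisions used to summarize where altered edges fall.
MESULAM_DIVISIONS = (
    "heteromodal",
    "unimodal",
    "paralimbic",
    "limbic",
    "primary",
    "subcortical",
)

_HEMISPHERES = ("L", "R", "midline")
_GROUPS = ("ASD", "TD")
_SEXES = ("M", "F")
_EYE_STATUSES = ("open", "closed", "unknown")


class ParseError(ValueError):
    """Raised when an on-disk table violates the format contract."""


@dataclass(frozen=True)
class RegionRecord:
    """One atlas region: position, label, location and functional division."""

    index: int
    label: str
    hemisphere: str
    centroid: tuple[float, float, float]
    mesulam_division: str
    is_cerebellum: bool = False

    def __post_init__(self) -> None:
        if self.hemisphere not in _HEMISPHERES:
            raise ValueError(
                f"hemisphere must be one of {_HEMISPHERES}, got {self.hemisphere!r}"
            )
        if self.mesulam_division not in MESULAM_DIVISIONS:
            raise ValueError(
                f"mesulam_division must be one of {MESULAM_DIVISIONS}, "
                f"got {self.mesulam_division!r}"
            )


@dataclass(frozen=True)
class AtlasMetadata:
    """An ordered parcellation: region records indexed 0..N-1."""

    name: str
    regions: tuple[RegionRecord, ...]

    def __post_init__(self) -> None:
        indices = [r.index for r in self.regions]
        if indices != list(range(len(self.regions))):
            raise ValueError("region indices must be contiguous 0..N-1 in order")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]

    def subset(self, keep: Sequence[int]) -> "AtlasMetadata":
        """New atlas keeping only the listed region positions, re-indexed
        0..K-1 with the survivors' original order preserved."""
        keep = sorted(set(int(k) for k in keep))
        regions = tuple(
            RegionRecord(
                index=new_idx,
                label=self.regions[old].label,
                hemisphere=self.regions[old].hemisphere,
                centroid=self.regions[old].centroid,
                mesulam_division=self.regions[old].mesulam_division,
                is_cerebellum=self.regions[old].is_cerebellum,
            )
            for new_idx, old in enumerate(keep)
        )
        return AtlasMetadata(name=self.name, regions=regions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [r.index for r in self.regions],
                "label": [r.label for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "x": [r.centroid[0] for r in self.regions],
                "y": [r.centroid[1] for r in self.regions],
                "z": [r.centroid[2] for r in self.regions],
                "mesulam_division": [r.mesulam_division for r in self.regions],
                "is_cerebellum": [r.is_cerebellum for r in self.regions],
            }
        )


_MISSING = float("nan")


def _opt_float(v) -> float:
    if v is None:
        return _MISSING
    try:
        if isinstance(v, str) and v.strip() in ("", "NA", "nan", "NaN", "+"):
            return _MISSING
        return float(v)
    except (TypeError, ValueError):
        return _MISSING


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject phenotype row.

    ``fiq``, ``ados_total`` and ``ados_severity`` may be missing (NaN);
    ADOS scores are only defined for the ASD group.
    """

    subject_id: str
    site_id: str
    group: str
    sex: str
    age: float
    fiq: float = _MISSING
    ados_total: float = _MISSING
    ados_severity: float = _MISSING
    eye_status: str = "unknown"

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}, got {self.group!r}")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.eye_status not in _EYE_STATUSES:
            raise ValueError(
                f"eye_status must be one of {_EYE_STATUSES}, got {self.eye_status!r}"
            )
        if not (self.age > 0):
            raise ValueError(f"age must be positive, got {self.age}")


@dataclass(frozen=True)
class CohortTable:
    """Ordered collection of subjects with unique ids."""

    subjects: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.subjects:
            if s.subject_id in seen:
                raise ValueError(f"duplicate subject_id {s.subject_id!r}")
            seen.add(s.subject_id)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def site_ids(self) -> list[str]:
        return sorted({s.site_id for s in self.subjects})

    def subset(self, subject_ids: Iterable[str]) -> "CohortTable":
        keep = set(subject_ids)
        return CohortTable(tuple(s for s in self.subjects if s.subject_id in keep))

    def group_counts(self) -> dict[str, int]:
        counts = {"ASD": 0, "TD": 0}
        for s in self.subjects:
            counts[s.group] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "site_id": [s.site_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "fiq": [s.fiq for s in self.subjects],
                "ados_total": [s.ados_total for s in self.subjects],
                "ados_severity": [s.ados_severity for s in self.subjects],
                "eye_status": [s.eye_status for s in self.subjects],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortTable":
        required = {"subject_id", "site_id", "group", "sex", "age"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"cohort table missing columns: {sorted(missing)}")
        records = []
        for _, row in df.iterrows():
            group = str(row["group"]).strip().upper()
            sex = str(row["sex"]).strip().upper()
            eye = str(row.get("eye_status", "unknown")).strip().lower()
            if eye in ("nan", ""):
                eye = "unknown"
            try:
                age = float(row["age"])
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"unparsable age {row['age']!r} for subject "
                    f"{row['subject_id']!r}"
                ) from exc
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    site_id=str(row["site_id"]),
                    group=group,
                    sex=sex,
                    age=age,
                    fiq=_opt_float(row.get("fiq")),
                    ados_total=_opt_float(row.get("ados_total")),
                    ados_severity=_opt_float(row.get("ados_severity")),
                    eye_status=eye,
                )
            )
        try:
            return cls(tuple(records))
        except ValueError as exc:
            raise ParseError(str(exc)) from exc


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical mapping between region pairs (i, j), i < j, and flat
    feature positions, in row-major upper-triangle order:
    (0,1), (0,2), ..., (0,N-1), (1,2), ..., (N-2,N-1).
    """

    n_regions: int
    pairs: tuple[tuple[int, int], ...] = field(repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.pairs)

    def position(self, i: int, j: int) -> int:
        """Flat position of pair (i, j); order of arguments irrelevant."""
        if i == j:
            raise ValueError("diagonal (i == j) has no edge position")
        if i > j:
            i, j = j, i
        n = self.n_regions
        if not (0 <= i < j < n):
            raise ValueError(f"pair ({i}, {j}) out of range for N={n}")
        # closed form for row-major upper triangle
        return i * n - i * (i + 1) // 2 + (j - i - 1)

    def pair(self, k: int) -> tuple[int, int]:
        return self.pairs[k]

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "edge": range(self.n_edges),
                "i": [p[0] for p in self.pairs],
                "j": [p[1] for p in self.pairs],
            }
        )
        if labels is not None:
            df["label_i"] = [labels[p[0]] for p in self.pairs]
            df["label_j"] = [labels[p[1]] for p in self.pairs]
        return df


def build_edge_index(n_regions: int) -> EdgeIndex:
    """Edge index over the non-redundant upper triangle: N(N-1)/2 pairs."""
    if n_regions < 2:
        raise ValueError(f"need at least 2 regions, got {n_regions}")
    iu = np.triu_indices(n_regions, k=1)
    pairs = tuple(zip(iu[0].tolist(), iu[1].tolist()))
    assert len(pairs) == n_regions * (n_regions - 1) // 2
    return EdgeIndex(n_regions=n_regions, pairs=pairs)


@dataclass(frozen=True)
class TimeSeriesTable:
    """A T x N table of region time series, optionally labelled columns."""

    values: np.ndarray
    labels: tuple[str, ...] | None = None

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def _is_numeric_row(tokens: Sequence[str]) -> bool:
    for t in tokens:
        try:
            float(t)
        except ValueError:
            return False
    return True


def _split_line(line: str, delimiter: str | None) -> list[str]:
    if delimiter == ",":
        return [t.strip() for t in line.split(",")]
    return line.split()


def read_timeseries(path: str | Path) -> TimeSeriesTable:
    """Read a delimited T x N time-series table.

    The delimiter (comma vs. whitespace/tab) is auto-detected from the
    first non-empty line, and a single optional header row of region
    labels is recognized when its tokens are not all numeric.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty time-series file")
    delimiter = "," if "," in lines[0] else None

    labels: tuple[str, ...] | None = None
    first = _split_line(lines[0], delimiter)
    data_lines = lines
    start_lineno = 1
    if not _is_numeric_row(first):
        labels = tuple(first)
        data_lines = lines[1:]
        start_lineno = 2
        if not data_lines:
            raise ParseError(f"{path}: header only, no data rows")

    rows: list[list[float]] = []
    n_cols: int | None = None
    for offset, ln in enumerate(data_lines):
        tokens = _split_line(ln, delimiter)
        lineno = start_lineno + offset
        if n_cols is None:
            n_cols = len(tokens)
        elif len(tokens) != n_cols:
            raise ParseError(
                f"{path}: line {lineno} has {len(tokens)} columns, expected {n_cols}"
            )
        try:
            rows.append([float(t) for t in tokens])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value on line {lineno}") from exc

    values = np.asarray(rows, dtype=float)
    if values.shape[1] < 2:
        raise ParseError(f"{path}: need at least 2 region columns")
    if labels is not None and len(labels) != values.shape[1]:
        raise ParseError(f"{path}: header width does not match data width")
    return TimeSeriesTable(values=values, labels=labels)


def write_timeseries(
    table: TimeSeriesTable | np.ndarray, path: str | Path, delimiter: str = "\t"
) -> Path:
    path = Path(path)
    if isinstance(table, TimeSeriesTable):
        values, labels = table.values, table.labels
    else:
        values, labels = np.asarray(table, dtype=float), None
    with path.open("w") as fh:
        if labels is not None:
            fh.write(delimiter.join(labels) + "\n")
        for row in values:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")
    return path


def read_cohort(path: str | Path) -> CohortTable:
    """Read a phenotype CSV into a validated :class:`CohortTable`.

    Enumerated fields (group, sex, eye status) are normalized
    case-insensitively; missing FIQ/ADOS cells become NaN.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "site_id": str})
    return CohortTable.from_frame(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_frame().to_csv(path, index=False)
    return path


def read_atlas(path: str | Path) -> AtlasMetadata:
    """Read atlas metadata from CSV (columns index,label,hemisphere,x,y,z,
    mesulam_division,is_cerebellum) or an equivalent JSON record."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        name = payload.get("name", path.stem)
        rows = payload["regions"]
    else:
        df = pd.read_csv(path)
        name = path.stem
        rows = df.to_dict("records")
    regions = tuple(
        RegionRecord(
            index=int(r["index"]),
            label=str(r["label"]),
            hemisphere=str(r["hemisphere"]),
            centroid=(float(r["x"]), float(r["y"]), float(r["z"])),
            mesulam_division=str(r["mesulam_division"]).strip().lower(),
            is_cerebellum=_parse_bool(r.get("is_cerebellum", False)),
        )
        for r in rows
    )
    return AtlasMetadata(name=name, regions=regions)


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


def write_atlas(atlas: AtlasMetadata, path: str | Path) -> Path:
    path = Path(path)
    atlas.to_frame().to_csv(path, index=False)
    return path


def make_synthetic_atlas(
    n_regions: int, n_cerebellum: int = 0, name: str = "synthetic"
) -> AtlasMetadata:
    """Fixture atlas with deterministically cycled Mesulam divisions.

    Regions are labelled ``region_000`` ... and assigned divisions by
    cycling through the six Mesulam divisions in order; the last
    ``n_cerebellum`` regions are flagged cerebellar. Centroids are laid
    out on a deterministic 3-D grid (millimetre-scale placeholders).
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not (0 <= n_cerebellum < n_regions):
        raise ValueError("n_cerebellum must be in [0, n_regions)")
    side = max(2, math.ceil(n_regions ** (1.0 / 3.0)))
    regions = []
    for idx in range(n_regions):
        gx, rem = divmod(idx, side * side)
        gy, gz = divmod(rem, side)
        centroid = (gx * 20.0 - 60.0, gy * 20.0 - 60.0, gz * 20.0 - 60.0)
        regions.append(
            RegionRecord(
                index=idx,
                label=f"region_{idx:03d}",
                hemisphere="L" if idx % 2 == 0 else "R",
                centroid=centroid,
                mesulam_division=MESULAM_DIVISIONS[idx % len(MESULAM_DIVISIONS)],
                is_cerebellum=idx >= n_regions - n_cerebellum,
            )
        )
    return AtlasMetadata(name=name, regions=tuple(regions))


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: Mapping | None = None,
) -> list[Path]:
    """Write named result tables as CSV plus a JSON run manifest.

    The manifest records whatever the caller passes (seed, config,
    version); tables are written with headers even when empty.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    if manifest is not None:
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        written.append(p)
    return written
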