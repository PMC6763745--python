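"""End-to-end orchestration: simulate/ingest -> select -> features ->
classify -> permutation test -> site effects -> matching -> correlations.

Every stage writes delimited result tables into the run directory, and a
JSON manifest records the configuration, package version, per-stage row
counts and elapsed wall-clock. Reruns with the same config and seed are
byte-identical except for the timing entries in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas_io import (
    AtlasMetadata,
    CohortTable,
    make_synthetic_atlas,
    read_atlas,
    read_cohort,
    read_timeseries,
    write_atlas,
    write_cohort,
    write_timeseries,
)
from .classification import ASD_LABEL, TD_LABEL, leave_site_out_cv
from .cohort_stats import (
    across_site_tests,
    clinical_correlations,
    filter_cohort,
    site_effect_screen,
    within_site_matching,
)
from .connectivity import build_feature_matrix
from .significance import (
    DEFAULT_TIERS,
    call_connections,
    connections_frame,
    mesulam_tabulate,
    permutation_weight_test,
)
from .synthetic_cohort import (
    PlantedEdge,
    SimulationConfig,
    default_study_config,
    generate_cohort,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "report", "load_config"]

logger = logging.getLogger("fcpipe")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Single-file configuration for a full pipeline run."""

    mode: str = "simulate"  # 'simulate' | 'ingest'
    out_dir: str = "fcpipe_run"
    seed: int = 0
    # --- simulate mode
    n_regions: int = 30
    planted_edges: tuple[tuple[int, int, float, float], ...] = ()  # (i, j, r_td, r_asd)
    site_shift: float = 0.0
    null_region_subjects: int = 3
    # --- ingest mode
    cohort_path: str | None = None
    timeseries_dir: str | None = None
    atlas_path: str | None = None
    # --- selection
    age_range: tuple[float, float] = (6.5, 13.0)
    sex: str | None = "M"
    eye_status: str | None = "open"
    top_k_sites: int | None = 4
    # --- features
    subject_threshold: int = 10
    variance_normalized_fisher: bool = True
    # --- classifier / permutation test
    svm_c: float = 1.0
    n_permutations: int = 10_000
    tiers: tuple[float, ...] = DEFAULT_TIERS
    # --- site effects / correlations
    q: float = 0.05

    def to_jsonable(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML (JSON is a YAML subset)."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("planted_edges",):
        if key in payload and payload[key] is not None:
            payload[key] = tuple(tuple(e) for e in payload[key])
    for key in ("age_range", "tiers"):
        if key in payload and payload[key] is not None:
            payload[key] = tuple(payload[key])
    return RunConfig(**payload)


def _simulation_config(config: RunConfig) -> SimulationConfig:
    edges = tuple(
        PlantedEdge(pair=(int(i), int(j)), r_td=float(r_td), r_asd=float(r_asd))
        for i, j, r_td, r_asd in config.planted_edges
    )
    return default_study_config(
        n_regions=config.n_regions,
        planted_edges=edges,
        site_shift=config.site_shift,
        null_region_subjects=config.null_region_subjects,
        seed=config.seed,
    )


def _load_inputs(
    config: RunConfig,
) -> tuple[CohortTable, dict[str, np.ndarray], AtlasMetadata, dict | None]:
    if config.mode == "simulate":
        sim = _simulation_config(config)
        cohort, series, truth = generate_cohort(sim)
        atlas = make_synthetic_atlas(config.n_regions)
        return cohort, series, atlas, truth.to_jsonable()
    if config.mode != "ingest":
        raise ValueError(f"unknown mode {config.mode!r}")
    if not (config.cohort_path and config.timeseries_dir and config.atlas_path):
        raise ValueError("ingest mode needs cohort_path, timeseries_dir, atlas_path")
    cohort = read_cohort(config.cohort_path)
    atlas = read_atlas(config.atlas_path)
    ts_dir = Path(config.timeseries_dir)
    series: dict[str, np.ndarray] = {}
    for s in cohort.subjects:
        candidates = list(ts_dir.glob(f"{s.subject_id}.*"))
        if not candidates:
            raise FileNotFoundError(f"no time-series file for {s.subject_id}")
        series[s.subject_id] = read_timeseries(candidates[0]).values
    return cohort, series, atlas, None


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages, returning the run directory.

    Any stage failure writes a ``FAILED`` marker naming the stage and
    re-raises as :class:`PipelineError`; outputs of completed stages are
    retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_jsonable(),
        "version": __version__,
        "stages": {},
        "timing_seconds": {},
    }
    stage = "init"
    t_start = time.perf_counter()

    def finish_stage(name: str, **info) -> None:
        manifest["stages"][name] = info
        manifest["timing_seconds"][name] = round(time.perf_counter() - t_stage, 4)
        logger.info("[%s] done: %s", name, info)

    try:
        # ---- inputs -------------------------------------------------
        stage = "inputs"
        t_stage = time.perf_counter()
        cohort, series, atlas, truth = _load_inputs(config)
        write_cohort(cohort, out / "cohort.csv")
        write_atlas(atlas, out / "atlas.csv")
        if config.mode == "simulate":
            ts_dir = out / "timeseries"
            ts_dir.mkdir(exist_ok=True)
            for sid in cohort.subject_ids:
                write_timeseries(series[sid], ts_dir / f"{sid}.tsv")
            _write_json(out / "ground_truth.json", truth)
        finish_stage("inputs", n_subjects=len(cohort), n_regions=atlas.n_regions)

        # ---- selection ----------------------------------------------
        stage = "select"
        t_stage = time.perf_counter()
        selected, log = filter_cohort(
            cohort,
            age_range=config.age_range,
            sex=config.sex,
            eye_status=config.eye_status,
            top_k_sites=config.top_k_sites,
        )
        log.to_frame().to_csv(out / "selection_log.csv", index=False)
        write_cohort(selected, out / "cohort_selected.csv")
        series = {sid: series[sid] for sid in selected.subject_ids}
        finish_stage("select", n_selected=len(selected))

        # ---- features -----------------------------------------------
        stage = "fc"
        t_stage = time.perf_counter()
        features, exclusion = build_feature_matrix(
            series,
            atlas=atlas,
            subject_threshold=config.subject_threshold,
            variance_normalized=config.variance_normalized_fisher,
        )
        analysis_atlas = atlas.subset(
            [r.index for r in atlas.regions if not r.is_cerebellum]
        )
        if exclusion.removed_regions:
            keep = [
                i for i in range(analysis_atlas.n_regions)
                if i not in set(exclusion.removed_regions)
            ]
            analysis_atlas = analysis_atlas.subset(keep)
        feat_df = pd.DataFrame(
            features.values,
            columns=[f"e{k}" for k in range(features.n_features)],
        )
        feat_df.insert(0, "subject_id", list(features.subject_ids))
        feat_df.to_csv(out / "features.csv", index=False)
        features.edge_index.to_frame(analysis_atlas.labels).to_csv(
            out / "edge_index.csv", index=False
        )
        _write_json(out / "exclusion_report.json", exclusion.to_jsonable())
        analysis = selected.subset(features.subject_ids)
        order = {sid: k for k, sid in enumerate(features.subject_ids)}
        labels = np.empty(len(order), dtype=int)
        sites = np.empty(len(order), dtype=object)
        for s in analysis.subjects:
            labels[order[s.subject_id]] = ASD_LABEL if s.group == "ASD" else TD_LABEL
            sites[order[s.subject_id]] = s.site_id
        finish_stage(
            "fc",
            n_subjects=features.n_subjects,
            n_features=features.n_features,
            policy=exclusion.policy,
        )

        # ---- classification -----------------------------------------
        stage = "classify"
        t_stage = time.perf_counter()
        cv = leave_site_out_cv(features.values, labels, sites, c=config.svm_c)
        cv.to_frame().to_csv(out / "cv_report.csv", index=False)
        finish_stage("classify", n_folds=len(cv.folds), mean_auc=cv.mean("auc"))

        # ---- permutation test ---------------------------------------
        stage = "permtest"
        t_stage = time.perf_counter()
        if config.n_permutations > 0:
            perm = permutation_weight_test(
                features.values,
                labels,
                n_permutations=config.n_permutations,
                seed=config.seed,
                c=config.svm_c,
                tiers=config.tiers,
            )
            pd.DataFrame(
                {
                    "edge": range(features.n_features),
                    "weight": perm.observed_weights,
                    "p_value": perm.p_values,
                }
            ).to_csv(out / "pvalues.csv", index=False)
            connections = call_connections(
                perm, features.edge_index, analysis_atlas, tiers=config.tiers
            )
            connections_frame(connections).to_csv(out / "connections.csv", index=False)
            tab = mesulam_tabulate(connections, analysis_atlas)
            tab.counts.to_csv(out / "mesulam_counts.csv")
            tab.region_counts.to_csv(out / "region_counts.csv", index=False)
            finish_stage(
                "permtest",
                n_permutations=config.n_permutations,
                n_significant=len(connections),
                warning=perm.warning,
            )
        else:
            connections = []
            finish_stage("permtest", skipped="n_permutations == 0")

        # ---- site effects -------------------------------------------
        stage = "site_effects"
        t_stage = time.perf_counter()
        td_mask = labels == TD_LABEL
        if len(set(sites[td_mask].tolist())) >= 2:
            screen = site_effect_screen(
                features.values[td_mask], sites[td_mask], q=config.q
            )
            pd.DataFrame(
                {
                    "site_id": [r.site_id for r in screen],
                    "n_td": [r.n_site_td for r in screen],
                    "n_other_td": [r.n_other_td for r in screen],
                    "n_significant_edges": [r.n_significant for r in screen],
                    "skipped": [r.skipped for r in screen],
                }
            ).to_csv(out / "site_effects.csv", index=False)
            finish_stage("site_effects", n_sites=len(screen))
        else:
            finish_stage("site_effects", skipped="fewer than 2 TD sites")

        # ---- demographic matching -----------------------------------
        stage = "match"
        t_stage = time.perf_counter()
        match = within_site_matching(analysis)
        pd.DataFrame(
            {
                "site_id": [m.site_id for m in match],
                "variable": [m.variable for m in match],
                "test_used": [m.test_used for m in match],
                "statistic": [m.statistic for m in match],
                "p_value": [m.p_value for m in match],
                "n_asd": [m.n_asd for m in match],
                "n_td": [m.n_td for m in match],
            }
        ).to_csv(out / "matching.csv", index=False)
        omnibus = across_site_tests(analysis)
        rows = []
        for o in omnibus:
            sig_pairs = ", ".join(
                f"{p.site_a}-{p.site_b}" for p in o.posthoc if p.significant
            )
            rows.append(
                {
                    "variable": o.variable,
                    "test_used": o.test_used,
                    "statistic": o.statistic,
                    "p_value": o.p_value,
                    "n": o.n,
                    "significant_pairs": sig_pairs,
                }
            )
        pd.DataFrame(rows).to_csv(out / "across_sites.csv", index=False)
        finish_stage("match", n_tests=len(match) + len(omnibus))

        # ---- clinical correlations ----------------------------------
        stage = "correlate"
        t_stage = time.perf_counter()
        pairs = [cs.pair for cs in connections][:10]
        if pairs:
            corr = clinical_correlations(
                features.values,
                features.subject_ids,
                analysis,
                features.edge_index,
                pairs,
            )
            pd.DataFrame(
                {
                    "i": [r.pair[0] for r in corr],
                    "j": [r.pair[1] for r in corr],
                    "score": [r.score_name for r in corr],
                    "group_scope": [r.group_scope for r in corr],
                    "rho": [r.rho for r in corr],
                    "p_value": [r.p_value for r in corr],
                    "n_used": [r.n_used for r in corr],
                }
            ).to_csv(out / "clinical_correlations.csv", index=False)
            finish_stage("correlate", n_correlations=len(corr))
        else:
            finish_stage("correlate", skipped="no significant connections")

    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc

    manifest["timing_seconds"]["total"] = round(time.perf_counter() - t_start, 4)
    _write_json(out / "manifest.json", manifest)
    return out


def report(run_dir: str | Path) -> str:
    """Markdown summary of a (possibly partial) run directory."""
    run_dir = Path(run_dir)
    lines: list[str] = ["# Pipeline run summary", ""]

    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"- package version: {manifest.get('version')}")
        lines.append(f"- seed: {manifest['config'].get('seed')}")
        fc_stage = manifest.get("stages", {}).get("fc", {})
        if "n_features" in fc_stage:
            lines.append(
                f"- subjects analysed: {fc_stage['n_subjects']}, "
                f"edge features: m = {fc_stage['n_features']}"
            )
        lines.append("")
    if (run_dir / "FAILED").exists():
        lines.append("**RUN FAILED** — " + (run_dir / "FAILED").read_text().strip())
        lines.append("")

    cv_path = run_dir / "cv_report.csv"
    if cv_path.exists():
        lines.append("## Leave-site-out cross-validation")
        lines.append("")
        lines.append("```\n" + pd.read_csv(cv_path).to_string(index=False) + "\n```")
        lines.append("")

    conn_path = run_dir / "connections.csv"
    if conn_path.exists():
        conn = pd.read_csv(conn_path)
        for direction, title in (("over", "Over-connectivity (ASD > TD)"),
                                 ("under", "Under-connectivity (ASD < TD)")):
            sub = conn[conn["direction"] == direction]
            lines.append(f"## {title}")
            lines.append("")
            lines.append("```\n" + sub.to_string(index=False) + "\n```" if len(sub) else "(none)")
            lines.append("")

    mes_path = run_dir / "mesulam_counts.csv"
    if mes_path.exists():
        lines.append("## Significant edges by Mesulam division pair")
        lines.append("")
        lines.append("```\n" + pd.read_csv(mes_path, index_col=0).to_string() + "\n```")
        lines.append("")

    se_path = run_dir / "site_effects.csv"
    if se_path.exists():
        lines.append("## Site-effect screen (control subjects)")
        lines.append("")
        lines.append("```\n" + pd.read_csv(se_path).to_string(index=False) + "\n```")
        lines.append("")

    return "\n".join(lines)
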