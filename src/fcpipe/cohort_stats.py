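"""Supporting cohort statistics around the classifier.

Covers four jobs:

* cohort selection (age window, sex, eye status, the k best-populated
  sites) with a step-by-step selection log;
* ASD-vs-TD demographic matching within each site — Shapiro-Wilk gates
  the choice between the two-sample t-test (both groups normal) and the
  Mann-Whitney U test reported as a z statistic;
* cross-site comparisons — one-way ANOVA for normal variables,
  Kruskal-Wallis otherwise, followed by Bonferroni-corrected pairwise
  post-hocs of the same family;
* mass-univariate site-effect screening on TD edge features (per-site
  Mann-Whitney against the pooled other sites, Benjamini-Hochberg FDR at
  q <= 0.05) and Spearman correlations between selected edges and
  clinical scores (ADOS in the ASD group, FIQ per group).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas_io import CohortTable, EdgeIndex

__all__ = [
    "MatchTestResult",
    "OmnibusResult",
    "SiteEffectResult",
    "ClinicalCorrelation",
    "SelectionLog",
    "filter_cohort",
    "within_site_matching",
    "across_site_tests",
    "site_effect_screen",
    "benjamini_hochberg",
    "mann_whitney_z",
    "spearman_rho",
    "clinical_correlations",
]

NORMALITY_ALPHA = 0.05
_EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class MatchTestResult:
    site_id: str
    variable: str
    test_used: str  # 't_test' | 'mann_whitney' | 'untestable'
    statistic: float
    p_value: float
    normality_p: tuple[float, float]  # (ASD, TD) Shapiro-Wilk p
    n_asd: int
    n_td: int


@dataclass(frozen=True)
class OmnibusResult:
    variable: str
    test_used: str  # 'anova' | 'kruskal_wallis'
    statistic: float
    p_value: float
    n: int
    posthoc: tuple  # PairwiseResult tuples


@dataclass(frozen=True)
class PairwiseResult:
    site_a: str
    site_b: str
    statistic: float
    p_value: float  # Bonferroni-corrected
    significant: bool


@dataclass(frozen=True)
class SiteEffectResult:
    site_id: str
    p_values: np.ndarray
    fdr_mask: np.ndarray
    n_significant: int
    n_site_td: int
    n_other_td: int
    skipped: bool = False


@dataclass(frozen=True)
class ClinicalCorrelation:
    pair: tuple[int, int]
    score_name: str
    group_scope: str  # 'ASD' | 'TD' | 'all'
    rho: float
    p_value: float
    n_used: int
    testable: bool = True


@dataclass
class SelectionLog:
    steps: list[tuple[str, int]] = field(default_factory=list)

    def record(self, step: str, n: int) -> None:
        self.steps.append((step, n))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_subjects"])


def filter_cohort(
    cohort: CohortTable,
    age_range: tuple[float, float] = (6.5, 13.0),
    sex: str | None = "M",
    eye_status: str | None = "open",
    top_k_sites: int | None = 4,
) -> tuple[CohortTable, SelectionLog]:
    """Apply the selection funnel: age window, sex, eye status, then keep
    the k sites with the most remaining subjects (ties alphabetical)."""
    log = SelectionLog()
    subjects = list(cohort.subjects)
    log.record("input", len(subjects))

    lo, hi = age_range
    subjects = [s for s in subjects if lo <= s.age <= hi]
    log.record(f"age in [{lo}, {hi}]", len(subjects))
    if sex is not None:
        subjects = [s for s in subjects if s.sex == sex]
        log.record(f"sex == {sex}", len(subjects))
    if eye_status is not None:
        subjects = [s for s in subjects if s.eye_status == eye_status]
        log.record(f"eye_status == {eye_status}", len(subjects))
    if top_k_sites is not None:
        counts: dict[str, int] = {}
        for s in subjects:
            counts[s.site_id] = counts.get(s.site_id, 0) + 1
        # largest counts first, alphabetical on ties
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        keep_sites = {site for site, _ in ranked[:top_k_sites]}
        subjects = [s for s in subjects if s.site_id in keep_sites]
        log.record(f"top {top_k_sites} sites", len(subjects))
    if not subjects:
        raise ValueError("no subjects satisfy the selection criteria; relax them")
    return CohortTable(tuple(subjects)), log


def _shapiro_p(x: np.ndarray) -> float:
    if len(x) < 3:
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def mann_whitney_z(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Mann-Whitney U with the normal approximation (continuity and tie
    corrected), returned as (U, z, two-sided p). For both samples of size
    <= 8 the exact null distribution is used and z is reported from the
    approximation for reference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    # tie-corrected variance of U
    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u1, 0.0, 1.0
    sigma = math.sqrt(sigma2)
    # continuity correction toward the mean
    diff = u1 - mu
    z = (diff - 0.5 * np.sign(diff)) / sigma if diff != 0 else 0.0
    if n1 <= _EXACT_MW_MAX_N and n2 <= _EXACT_MW_MAX_N:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return u1, float(z), min(p, 1.0)


def within_site_matching(
    cohort: CohortTable,
    variables: Sequence[str] = ("age", "fiq"),
    alpha: float = NORMALITY_ALPHA,
    welch: bool = False,
) -> list[MatchTestResult]:
    """Per site and variable, test whether ASD and TD groups differ.

    Shapiro-Wilk decides the test: when both groups look normal at
    ``alpha`` a two-sample t-test (pooled variance; Welch by flag) is
    used, otherwise Mann-Whitney U reported as z.
    """
    df = cohort.to_frame()
    results: list[MatchTestResult] = []
    for site in sorted(df["site_id"].unique()):
        sub = df[df["site_id"] == site]
        for var in variables:
            a = sub.loc[sub["group"] == "ASD", var].dropna().to_numpy()
            t = sub.loc[sub["group"] == "TD", var].dropna().to_numpy()
            if len(a) < 3 or len(t) < 3:
                results.append(
                    MatchTestResult(site, var, "untestable", math.nan, math.nan,
                                    (math.nan, math.nan), len(a), len(t))
                )
                continue
            pa, pt = _shapiro_p(a), _shapiro_p(t)
            if pa > alpha and pt > alpha:
                res = stats.ttest_ind(a, t, equal_var=not welch)
                results.append(
                    MatchTestResult(site, var, "t_test", float(res.statistic),
                                    float(res.pvalue), (pa, pt), len(a), len(t))
                )
            else:
                _, z, p = mann_whitney_z(a, t)
                results.append(
                    MatchTestResult(site, var, "mann_whitney", z, p, (pa, pt),
                                    len(a), len(t))
                )
    return results


def across_site_tests(
    cohort: CohortTable,
    variables: Sequence[str] = ("age", "fiq", "ados_total", "ados_severity"),
    alpha: float = NORMALITY_ALPHA,
    posthoc_alpha: float = 0.05,
) -> list[OmnibusResult]:
    """Omnibus cross-site comparison per variable with Bonferroni
    post-hocs.

    Each site's pooled sample (both groups; ADOS is ASD-only by
    construction) is gated through Shapiro-Wilk: all-normal variables get
    one-way ANOVA with pairwise t-tests, anything else Kruskal-Wallis
    with pairwise Mann-Whitney. Post-hoc p-values are multiplied by the
    number of pairs (capped at 1).
    """
    df = cohort.to_frame()
    sites = sorted(df["site_id"].unique())
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    results: list[OmnibusResult] = []
    for var in variables:
        samples = {
            site: df.loc[df["site_id"] == site, var].dropna().to_numpy()
            for site in sites
        }
        usable = {s: v for s, v in samples.items() if len(v) >= 3}
        if len(usable) < 2:
            results.append(OmnibusResult(var, "untestable", math.nan, math.nan, 0, ()))
            continue
        normal = all(_shapiro_p(v) > alpha for v in usable.values())
        values = list(usable.values())
        if normal:
            stat, p = stats.f_oneway(*values)
            test = "anova"
        else:
            stat, p = stats.kruskal(*values)
            test = "kruskal_wallis"
        pairs = list(combinations(sorted(usable), 2))
        m = len(pairs)
        posthoc = []
        for a, b in pairs:
            if test == "anova":
                res = stats.ttest_ind(usable[a], usable[b])
                s_ab, p_ab = float(res.statistic), float(res.pvalue)
            else:
                _, s_ab, p_ab = mann_whitney_z(usable[a], usable[b])
            p_corr = min(1.0, p_ab * m)
            posthoc.append(
                PairwiseResult(a, b, s_ab, p_corr, p_corr < posthoc_alpha)
            )
        results.append(
            OmnibusResult(
                var, test, float(stat), float(p),
                int(sum(len(v) for v in usable.values())), tuple(posthoc),
            )
        )
    return results


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Standard step-up FDR: sort ascending, find the largest k with
    p_(k) <= k*q/m (inclusive), reject all p-values ranked <= k."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresholds = q * (np.arange(1, m + 1) / m)
    passing = np.flatnonzero(p[order] <= thresholds)
    mask = np.zeros(m, dtype=bool)
    if passing.size:
        mask[order[: passing[-1] + 1]] = True
    return mask


def site_effect_screen(
    features: np.ndarray,
    sites: Sequence[str],
    q: float = 0.05,
) -> list[SiteEffectResult]:
    """Per-site, per-edge Mann-Whitney of one site's (TD) features against
    all other sites pooled, BH-corrected across edges at level q.

    The caller restricts ``features``/``sites`` to control (TD) subjects;
    the screen itself is diagnosis-agnostic.
    """
    features = np.asarray(features, dtype=float)
    sites_arr = np.asarray(sites)
    if features.shape[0] != len(sites_arr):
        raise ValueError("features and sites must be aligned")
    unique_sites = sorted(set(sites_arr.tolist()))
    if len(unique_sites) < 2:
        raise ValueError("need TD subjects from at least 2 sites")
    results: list[SiteEffectResult] = []
    m = features.shape[1]
    for site in unique_sites:
        in_site = sites_arr == site
        n_site, n_other = int(in_site.sum()), int((~in_site).sum())
        if n_site < 2 or n_other < 2:
            warnings.warn(
                f"site {site!r}: too few control subjects ({n_site}); skipped",
                stacklevel=2,
            )
            results.append(
                SiteEffectResult(site, np.ones(m), np.zeros(m, dtype=bool), 0,
                                 n_site, n_other, skipped=True)
            )
            continue
        res = stats.mannwhitneyu(
            features[in_site], features[~in_site], alternative="two-sided", axis=0
        )
        p = np.asarray(res.pvalue, dtype=float)
        mask = benjamini_hochberg(p, q=q)
        results.append(
            SiteEffectResult(site, p, mask, int(mask.sum()), n_site, n_other)
        )
    return results


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation as Pearson on average ranks, with the
    two-sided p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return math.nan, math.nan  # constant after ranking: undefined
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


_SCORE_SCOPES = {"ados_total": "ASD", "ados_severity": "ASD"}


def clinical_correlations(
    features: np.ndarray,
    feature_subject_ids: Sequence[str],
    cohort: CohortTable,
    edge_index: EdgeIndex,
    pairs_of_interest: Sequence[tuple[int, int]],
    scores: Sequence[str] = ("ados_total", "ados_severity", "fiq"),
    fiq_scopes: Sequence[str] = ("ASD", "TD"),
) -> list[ClinicalCorrelation]:
    """Spearman correlations between chosen edges and clinical scores.

    ADOS scores exist only for the ASD group, so those correlations are
    ASD-only by construction; FIQ is evaluated within each group
    separately. Missing scores are dropped pairwise.
    """
    features = np.asarray(features, dtype=float)
    df = cohort.to_frame().set_index("subject_id")
    df = df.loc[[sid for sid in feature_subject_ids if sid in df.index]]
    row_of = {sid: k for k, sid in enumerate(feature_subject_ids)}
    results: list[ClinicalCorrelation] = []
    for (i, j) in pairs_of_interest:
        col = edge_index.position(i, j)
        for score in scores:
            scopes = [_SCORE_SCOPES[score]] if score in _SCORE_SCOPES else list(fiq_scopes)
            for scope in scopes:
                sub = df if scope == "all" else df[df["group"] == scope]
                vals = sub[score]
                keep = vals.notna()
                sids = sub.index[keep]
                y = vals[keep].to_numpy(dtype=float)
                x = np.array([features[row_of[sid], col] for sid in sids])
                if len(x) < 4:
                    results.append(
                        ClinicalCorrelation((i, j), score, scope, math.nan,
                                            math.nan, len(x), testable=False)
                    )
                    continue
                rho, p = spearman_rho(x, y)
                results.append(
                    ClinicalCorrelation(
                        (i, j), score, scope, rho, p, len(x),
                        testable=not math.isnan(rho),
                    )
                )
    return results
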