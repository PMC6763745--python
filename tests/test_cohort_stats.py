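import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from fcpipe import default_study_config, generate_cohort
from fcpipe.atlas_io import CohortTable, SubjectRecord, build_edge_index
from fcpipe.cohort_stats import (
    across_site_tests,
    benjamini_hochberg,
    clinical_correlations,
    filter_cohort,
    mann_whitney_z,
    site_effect_screen,
    spearman_rho,
    within_site_matching,
)


def _subject(sid, site="A", group="TD", age=10.0, **kw):
    defaults = dict(sex="M", eye_status="open", fiq=100.0)
    defaults.update(kw)
    return SubjectRecord(subject_id=sid, site_id=site, group=group, age=age, **defaults)


class TestFilterCohort:
    def test_default_study_cohort_passes_selection(self):
        cohort, _, _ = generate_cohort(default_study_config(seed=2))
        selected, log = filter_cohort(cohort)
        assert len(selected) == 190
        assert log.steps[-1][1] == 190

    def test_overage_subject_excluded(self):
        cohort, _, _ = generate_cohort(default_study_config(seed=2))
        extra = _subject("old1", age=14.0)
        augmented = CohortTable(cohort.subjects + (extra,))
        selected, _ = filter_cohort(augmented)
        assert len(selected) == 190
        assert "old1" not in selected.subject_ids

    def test_top_k_ties_broken_alphabetically(self):
        subjects = tuple(
            _subject(f"{site}{i}", site=site)
            for site in ("D", "C", "B", "A")
            for i in range(3)
        )
        selected, _ = filter_cohort(
            CohortTable(subjects), top_k_sites=2, sex=None, eye_status=None
        )
        assert {s.site_id for s in selected.subjects} == {"A", "B"}

    def test_empty_selection_raises(self):
        cohort = CohortTable((_subject("s1", age=20.0),))
        with pytest.raises(ValueError, match="relax"):
            filter_cohort(cohort)

    def test_selection_log_funnel(self):
        subjects = (
            _subject("a", age=5.0),
            _subject("b", sex="F"),
            _subject("c", eye_status="closed"),
            _subject("d"),
        )
        selected, log = filter_cohort(CohortTable(subjects), top_k_sites=None)
        counts = [n for _, n in log.steps]
        assert counts == [4, 3, 2, 1]
        assert selected.subject_ids == ["d"]


class TestWithinSiteMatching:
    def _cohort(self, asd_ages, td_ages, site="A"):
        subjects = [
            _subject(f"a{i}", site=site, group="ASD", age=v, fiq=100 + v)
            for i, v in enumerate(asd_ages)
        ] + [
            _subject(f"t{i}", site=site, group="TD", age=v, fiq=100 + v)
            for i, v in enumerate(td_ages)
        ]
        return CohortTable(tuple(subjects))

    def test_identical_groups_mann_whitney_p_one(self):
        vals = [8.0, 9.0, 10.0, 11.0, 12.0]
        _, z, p = mann_whitney_z(vals, vals)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_null_t_test_rarely_significant(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for rep in range(20):
            a = rng.normal(10, 1.5, size=200)
            b = rng.normal(10, 1.5, size=200)
            cohort = self._cohort(a.tolist(), b.tolist())
            res = [r for r in within_site_matching(cohort, ("age",))
                   if r.variable == "age"][0]
            rejections += res.p_value < 0.05
        assert rejections <= 2

    def test_two_sd_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 1.0, size=50)
        b = rng.normal(12, 1.0, size=50)
        res = within_site_matching(self._cohort(a.tolist(), b.tolist()), ("age",))[0]
        assert res.p_value < 0.001

    def test_normality_gate_selects_test(self):
        rng = np.random.default_rng(2)
        normal = rng.normal(10, 1, 40)
        skewed = np.exp(rng.normal(0, 1, 40)) + 6.5
        cohort = self._cohort(normal.tolist(), normal.tolist())
        assert within_site_matching(cohort, ("age",))[0].test_used == "t_test"
        cohort2 = self._cohort(skewed.tolist(), skewed.tolist())
        assert within_site_matching(cohort2, ("age",))[0].test_used == "mann_whitney"

    def test_tiny_group_untestable(self):
        cohort = self._cohort([10.0, 11.0], [9.0, 10.0, 11.0, 12.0])
        assert within_site_matching(cohort, ("age",))[0].test_used == "untestable"


class TestAcrossSiteTests:
    def _multisite(self, shifts, n=40, seed=0):
        rng = np.random.default_rng(seed)
        subjects = []
        for s, shift in enumerate(shifts):
            site = f"S{s}"
            for i in range(n):
                group = "ASD" if i % 2 == 0 else "TD"
                subjects.append(
                    _subject(f"{site}_{i}", site=site, group=group,
                             age=float(np.clip(rng.normal(10 + shift, 1.0), 6.5, 13.0)),
                             fiq=rng.normal(105 + 5 * shift, 10.0))
                )
        return CohortTable(tuple(subjects))

    def test_null_omnibus_rarely_significant(self):
        rejections = 0
        for seed in range(20):
            cohort = self._multisite([0, 0, 0, 0], seed=seed)
            res = [r for r in across_site_tests(cohort, ("fiq",))][0]
            rejections += res.p_value < 0.05
        assert rejections <= 2

    def test_shifted_site_in_every_significant_pair(self):
        cohort = self._multisite([0, 0, 0, 2.5], seed=3)
        res = across_site_tests(cohort, ("age",))[0]
        assert res.p_value < 0.01
        sig = [p for p in res.posthoc if p.significant]
        assert sig, "expected at least one significant post-hoc pair"
        assert all("S3" in (p.site_a, p.site_b) for p in sig)

    def test_two_sites_posthoc_reduces_to_omnibus_pair(self):
        cohort = self._multisite([0, 2.0], seed=4)
        res = across_site_tests(cohort, ("age",))[0]
        assert len(res.posthoc) == 1

    def test_ados_asd_only_sample_sizes(self):
        cohort, _, _ = generate_cohort(default_study_config(seed=6))
        res = {r.variable: r for r in across_site_tests(cohort)}
        assert res["ados_total"].n == 102
        assert res["age"].n == 190


class TestBenjaminiHochberg:
    def test_stepup_example(self):
        mask = benjamini_hochberg([0.001, 0.2, 0.9], q=0.05)
        assert mask.tolist() == [True, False, False]

    def test_all_ones_nothing_rejected(self):
        assert not benjamini_hochberg([1.0, 1.0, 1.0], q=0.05).any()

    def test_boundary_is_inclusive(self):
        m = 5
        p = [0.05 * (1) / m] * m  # all equal to q * 1/m <= q * k/m for k=m
        assert benjamini_hochberg(p, q=0.05).all()

    def test_step_up_rescues_smaller_ranks(self):
        # p_(2) passes its threshold, so p_(1) is rejected too even though
        # monotone thresholds would also pass it; classic step-up behavior
        mask = benjamini_hochberg([0.024, 0.025], q=0.05)
        assert mask.tolist() == [True, True]

    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=1, max_size=8,
        ),
        st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    def test_matches_exhaustive_stepup_oracle(self, p_values, q):
        p = np.asarray(p_values)
        m = len(p)
        order = np.argsort(p, kind="stable")
        k_star = 0
        for k in range(m, 0, -1):  # independent top-down scan
            if p[order[k - 1]] <= k * q / m:
                k_star = k
                break
        expected = np.zeros(m, dtype=bool)
        expected[order[:k_star]] = True
        np.testing.assert_array_equal(benjamini_hochberg(p, q=q), expected)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=200) ** 2
        ours = benjamini_hochberg(p, q=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(ours, ref)


@given(
    st.lists(st.integers(min_value=-20, max_value=20), min_size=2, max_size=12),
    st.lists(st.integers(min_value=-20, max_value=20), min_size=2, max_size=12),
)
def test_mann_whitney_u_matches_all_pairs_brute_force(xs, ys):
    u, _, _ = mann_whitney_z(xs, ys)
    brute = sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x in xs for y in ys
    )
    assert u == pytest.approx(brute, abs=1e-9)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_reversed_monotone(self):
        rho, _ = spearman_rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_hand_ranked_example_with_tie(self):
        rho, _ = spearman_rho([1, 2, 3, 4, 5], [5, 6, 7, 8, 7])
        assert rho == pytest.approx(8 / math.sqrt(95), rel=1e-12)

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=4, max_size=25,
        )
    )
    def test_matches_pearson_on_average_ranks(self, ys):
        xs = list(range(len(ys)))
        rho, _ = spearman_rho(xs, ys)
        rx, ry = stats.rankdata(xs), stats.rankdata(ys)
        if np.std(ry) == 0:
            return  # constant after ranking: correlation undefined
        oracle = float(np.corrcoef(rx, ry)[0, 1])
        assert rho == pytest.approx(np.clip(oracle, -1, 1), abs=1e-12)


class TestSiteEffectScreen:
    def _features(self, n_per_site, shift_site=None, shift=0.0, m=50, seed=0):
        rng = np.random.default_rng(seed)
        X, sites = [], []
        for site, n in n_per_site.items():
            for _ in range(n):
                row = rng.standard_normal(m)
                if site == shift_site:
                    row += shift
                X.append(row)
                sites.append(site)
        return np.array(X), np.array(sites)

    def test_null_screen_near_zero_discoveries(self):
        total = 0
        for seed in range(10):
            X, sites = self._features({"A": 20, "B": 20, "C": 20}, seed=seed)
            results = site_effect_screen(X, sites)
            total += sum(r.n_significant for r in results)
        assert total / 10 <= 0.05 * 50 * 3

    def test_shifted_site_dominates_discoveries(self):
        X, sites = self._features(
            {"A": 25, "B": 25, "C": 25}, shift_site="B", shift=2.0, seed=1
        )
        results = {r.site_id: r.n_significant for r in site_effect_screen(X, sites)}
        assert results["B"] > max(results["A"], results["C"])
        assert results["B"] > 25

    def test_single_subject_site_skipped_with_warning(self):
        X, sites = self._features({"A": 10, "B": 1, "C": 10}, seed=2)
        with pytest.warns(UserWarning, match="skipped"):
            results = site_effect_screen(X, sites)
        skipped = [r for r in results if r.skipped]
        assert [r.site_id for r in skipped] == ["B"]


class TestClinicalCorrelations:
    def _setup(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        edge_index = build_edge_index(4)
        X = rng.standard_normal((n, edge_index.n_edges))
        subjects = []
        ids = []
        for i in range(n):
            group = "ASD" if i < n // 2 else "TD"
            ados = float(np.clip(10 + 5 * X[i, 0] + rng.normal(), 0, 28))
            subjects.append(
                _subject(
                    f"s{i}", group=group,
                    ados_total=ados if group == "ASD" else float("nan"),
                    ados_severity=7.0 if group == "ASD" else float("nan"),
                    fiq=100 + rng.normal(0, 10),
                )
            )
            ids.append(f"s{i}")
        return X, ids, CohortTable(tuple(subjects)), edge_index

    def test_ados_restricted_to_asd(self):
        X, ids, cohort, ei = self._setup()
        results = clinical_correlations(X, ids, cohort, ei, [(0, 1)])
        ados = [r for r in results if r.score_name == "ados_total"]
        assert len(ados) == 1
        assert ados[0].group_scope == "ASD"
        assert ados[0].n_used == 20

    def test_planted_monotone_association_detected(self):
        X, ids, cohort, ei = self._setup()
        results = clinical_correlations(X, ids, cohort, ei, [(0, 1)])
        r = [x for x in results if x.score_name == "ados_total"][0]
        assert r.rho > 0.5 and r.p_value < 0.01

    def test_fiq_per_group_scopes(self):
        X, ids, cohort, ei = self._setup()
        results = clinical_correlations(X, ids, cohort, ei, [(0, 1)])
        fiq_scopes = {r.group_scope for r in results if r.score_name == "fiq"}
        assert fiq_scopes == {"ASD", "TD"}

    def test_all_missing_score_untestable(self):
        X, ids, cohort, ei = self._setup(n=8)
        # TD half has no ADOS; restrict to a cohort of TD only
        td_ids = [s.subject_id for s in cohort.subjects if s.group == "TD"]
        td_cohort = cohort.subset(td_ids)
        rows = [ids.index(sid) for sid in td_ids]
        results = clinical_correlations(
            X[rows], td_ids, td_cohort, ei, [(0, 1)], scores=("ados_total",)
        )
        assert results[0].testable is False
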