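"""Unit and property tests for the distributed score test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from sumshare import (
    SingularVarianceError,
    SiteDataset,
    ValidationError,
    concatenate_sites,
    distributed_test,
    pool_stage1,
    pool_stage2,
    pooled_test,
    pvalue_from_statistic,
    score_statistic,
    site_stage1,
    site_stage2,
)
from sumshare.core import P_FLOOR
from sumshare.types import UNSTRATIFIED, Stage2Summary

from conftest import random_sites


# ---------------------------------------------------------------------------
# round 1
# ---------------------------------------------------------------------------

class TestStage1:
    def test_single_stratum_sums(self):
        d = SiteDataset("a", [0, 1, 2], np.array([[0.0], [1.0], [1.0]]))
        s = site_stage1(d)
        cell = s.cells[0][UNSTRATIFIED]
        assert (s.n, cell.x_sum, cell.y_sum) == (3, 3.0, 2.0)

    def test_per_stratum_split(self):
        d = SiteDataset(
            "a", [1, 1], np.array([[0.0], [0.0]]), strata=np.array(["A", "B"])
        )
        s = site_stage1(d)
        assert s.cells[0]["A"] == s.cells[0]["B"]
        assert s.cells[0]["A"].n == 1
        assert s.cells[0]["A"].y_sum == 0.0
        assert s.cells[0]["A"].x_sum == 1.0

    def test_empty_site_rejected(self):
        with pytest.raises(ValidationError, match="empty site"):
            SiteDataset("a", [], np.empty((0, 1)))

    @pytest.mark.parametrize(
        "geno,pheno",
        [([0, 3], [[0.0], [1.0]]), ([0, 1], [[0.0], [2.0]])],
    )
    def test_invalid_codings_rejected(self, geno, pheno):
        with pytest.raises(ValidationError):
            SiteDataset("a", geno, np.array(pheno))


class TestPoolStage1:
    def test_pooled_mean_is_weighted(self):
        d1 = SiteDataset("a", [0, 1], np.array([[0.0], [1.0]]))
        d2 = SiteDataset("b", [2, 2], np.array([[1.0], [1.0]]))
        ref = pool_stage1([site_stage1(d1), site_stage1(d2)])
        assert ref.n == 4
        assert ref.cells[0][UNSTRATIFIED].y_mean == pytest.approx(0.75)

    def test_single_site_identity(self):
        d = SiteDataset("a", [0, 1, 2], np.array([[0.0], [1.0], [1.0]]))
        ref = pool_stage1([site_stage1(d)])
        cell = ref.cells[0][UNSTRATIFIED]
        assert cell.y_mean == pytest.approx(2 / 3)
        assert cell.x_mean == pytest.approx(1.0)

    def test_union_of_strata(self):
        d1 = SiteDataset("a", [1], np.array([[1.0]]), strata=np.array(["A"]))
        d2 = SiteDataset(
            "b", [0, 2], np.array([[0.0], [1.0]]), strata=np.array(["A", "B"])
        )
        ref = pool_stage1([site_stage1(d1), site_stage1(d2)])
        assert set(ref.cells[0]) == {"A", "B"}
        assert ref.cells[0]["A"].n == 2
        assert ref.cells[0]["A"].y_mean == pytest.approx(0.5)

    def test_inconsistent_q_rejected(self):
        d1 = SiteDataset("a", [0, 1], np.array([[0.0], [1.0]]))
        d2 = SiteDataset("b", [0, 1], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError, match="q"):
            pool_stage1([site_stage1(d1), site_stage1(d2)])


# ---------------------------------------------------------------------------
# round 2 and the statistic
# ---------------------------------------------------------------------------

class TestStage2:
    def test_worked_example_sums(self, worked_dataset):
        ref = pool_stage1([site_stage1(worked_dataset)])
        s2 = site_stage2(worked_dataset, ref)
        assert s2.S[0] == 1.0
        assert s2.V[0, 0] == 0.5

    def test_constant_phenotype_gives_zero_component(self):
        d = SiteDataset("a", [0, 1, 2], np.array([[0, 0], [1, 0], [1, 0]], dtype=float))
        ref = pool_stage1([site_stage1(d)])
        s2 = site_stage2(d, ref)
        assert s2.S[1] == 0.0
        assert np.all(s2.V[1, :] == 0.0)
        assert np.all(s2.V[:, 1] == 0.0)

    def test_single_stratum_equals_unstratified_bitwise(self):
        rng = np.random.default_rng(7)
        for sites in (random_sites(rng), random_sites(rng, k=1)):
            labelled = [
                SiteDataset(
                    d.site_id, d.genotype, d.phenotypes,
                    strata=np.full(d.n, "only", dtype=object),
                )
                for d in sites
            ]
            ref_u = pool_stage1([site_stage1(d) for d in sites])
            ref_l = pool_stage1([site_stage1(d) for d in labelled])
            for d_u, d_l in zip(sites, labelled):
                a = site_stage2(d_u, ref_u)
                b = site_stage2(d_l, ref_l)
                assert np.array_equal(a.S, b.S)
                assert np.array_equal(a.V, b.V)

    def test_missing_stratum_in_reference_rejected(self):
        d1 = SiteDataset("a", [0, 1], np.array([[0.0], [1.0]]), strata=np.array(["A", "A"]))
        d2 = SiteDataset("b", [0, 1], np.array([[0.0], [1.0]]), strata=np.array(["A", "B"]))
        ref = pool_stage1([site_stage1(d1)])
        with pytest.raises(ValidationError, match="missing"):
            site_stage2(d2, ref)


class TestPoolStage2:
    def test_linearity_and_identity(self):
        s = Stage2Summary("a", np.array([1.0, -0.5]), np.array([[2.0, 0.3], [0.3, 1.0]]))
        S, V = pool_stage2([s])
        assert np.array_equal(S, s.S) and np.array_equal(V, s.V)
        S2, V2 = pool_stage2([s, s])
        assert np.array_equal(S2, 2 * s.S) and np.array_equal(V2, 2 * s.V)

    def test_dimension_mismatch_rejected(self):
        a = Stage2Summary("a", np.array([1.0]), np.array([[1.0]]))
        b = Stage2Summary("b", np.array([1.0, 2.0]), np.eye(2))
        with pytest.raises(ValidationError):
            pool_stage2([a, b])


class TestScoreStatistic:
    def test_worked_scalar_quadratic_form(self):
        r = score_statistic(np.array([1.0]), np.array([[0.5]]))
        assert r.statistic == 2.0
        assert r.df == 1

    def test_zero_score_gives_zero_statistic(self):
        r = score_statistic(np.zeros(3), np.eye(3))
        assert r.statistic == 0.0

    def test_zero_variance_matrix_is_singular(self):
        with pytest.raises(SingularVarianceError):
            score_statistic(np.array([1.0, 1.0]), np.zeros((2, 2)))

    def test_pseudo_inverse_reduces_df_to_rank(self):
        V = np.array([[1.0, 1.0], [1.0, 1.0]])
        S = np.array([1.0, 1.0])
        with pytest.raises(SingularVarianceError):
            score_statistic(S, V)
        r = score_statistic(S, V, pseudo_inverse=True)
        assert r.df == 1
        assert r.rank_deficient
        # rank-1 V = vv' with v=(1,1): T = (S.v)^2 / |v|^4 = 4/4
        assert r.statistic == pytest.approx(1.0)


class TestPValue:
    def test_boundary_and_chi2_oracle(self):
        assert pvalue_from_statistic(0.0, 1).p_value == 1.0
        r = pvalue_from_statistic(2.0, 1)
        assert r.p_value == pytest.approx(chi2.sf(2.0, 1))
        assert r.p_value == pytest.approx(0.1573, abs=5e-5)
        assert not r.p_floored

    def test_floor_applied_at_reporting_only(self):
        r = pvalue_from_statistic(1000.0, 5)
        assert r.p_value == P_FLOOR == 2.22e-16
        assert r.p_floored
        assert 0 < r.p_raw < P_FLOOR

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValidationError):
            pvalue_from_statistic(-1.0, 1)
        with pytest.raises(ValidationError):
            pvalue_from_statistic(1.0, 0)


# ---------------------------------------------------------------------------
# orchestration: lossless, partition- and recoding-invariance
# ---------------------------------------------------------------------------

class TestDistributedVsPooled:
    def test_worked_example_end_to_end(self, worked_dataset):
        res = pooled_test(worked_dataset)
        assert res.statistic == 2.0
        assert res.df == 1
        assert res.p_value == pytest.approx(0.15729920705028105, rel=1e-12)

    def test_single_site_paths_identical(self, worked_dataset):
        a = distributed_test([worked_dataset])
        b = pooled_test(worked_dataset)
        assert a.statistic == b.statistic
        assert a.p_value == b.p_value

    def test_duplicated_phenotype_column_is_singular(self):
        y = np.array([[0, 0], [1, 1], [1, 1], [0, 0]], dtype=float)
        d = SiteDataset("a", [0, 1, 2, 1], y)
        with pytest.raises(SingularVarianceError):
            pooled_test(d)

    def test_allele_flip_leaves_statistic_unchanged(self):
        rng = np.random.default_rng(11)
        sites = random_sites(rng, k=2, q=2)
        flipped = [
            SiteDataset(d.site_id, 2.0 - d.genotype, d.phenotypes) for d in sites
        ]
        t1 = distributed_test(sites)
        t2 = distributed_test(flipped)
        assert t1.statistic == pytest.approx(t2.statistic, rel=1e-12)

    def test_phenotype_permutation_leaves_pvalue_unchanged(self):
        rng = np.random.default_rng(5)
        sites = random_sites(rng, k=2, q=3)
        perm = [2, 0, 1]
        permuted = [
            SiteDataset(d.site_id, d.genotype, d.phenotypes[:, perm]) for d in sites
        ]
        assert distributed_test(sites).p_raw == pytest.approx(
            distributed_test(permuted).p_raw, rel=1e-12
        )


@st.composite
def multisite_data(draw):
    q = draw(st.integers(1, 3))
    n = draw(st.integers(6, 40))
    x = draw(
        st.lists(st.integers(0, 2), min_size=n, max_size=n).filter(
            lambda v: len(set(v)) > 1
        )
    )
    y = [
        draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda v: len(set(v)) > 1
            )
        )
        for _ in range(q)
    ]
    cuts = sorted(draw(st.sets(st.integers(1, n - 1), min_size=0, max_size=3)))
    return np.array(x, float), np.array(y, float).T, cuts


def _split(x, y, cuts):
    bounds = [0] + list(cuts) + [len(x)]
    return [
        SiteDataset(f"s{i}", x[a:b], y[a:b])
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]


class TestLosslessProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(multisite_data())
    def test_distributed_matches_pooled_and_any_partition(self, data):
        """Lossless and partition-invariance on arbitrary small datasets."""
        x, y, cuts = data
        combined = SiteDataset("all", x, y)
        try:
            ref = pooled_test(combined)
            res = distributed_test(_split(x, y, cuts))
        except SingularVarianceError:
            return  # degenerate draw: the statistic is undefined
        T = max(1.0, ref.statistic)
        assert abs(res.statistic - ref.statistic) / T <= 1e-12
        assert abs(res.p_raw - ref.p_raw) <= 1e-12

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(multisite_data())
    def test_variance_matrix_symmetric_psd(self, data):
        x, y, cuts = data
        sites = _split(x, y, cuts)
        ref = pool_stage1([site_stage1(d) for d in sites])
        _, V = pool_stage2([site_stage2(d, ref) for d in sites])
        assert np.allclose(V, V.T, atol=1e-10)
        assert np.linalg.eigvalsh(V).min() >= -1e-10


class TestConcatenate:
    def test_roundtrip_row_counts_and_strata(self):
        d1 = SiteDataset("a", [0, 1], np.array([[0.0], [1.0]]), strata=np.array(["A", "B"]))
        d2 = SiteDataset("b", [2, 1], np.array([[1.0], [0.0]]))
        combined = concatenate_sites([d1, d2])
        assert combined.n == 4
        assert combined.strata is not None
        assert list(combined.strata[:, 0]) == ["A", "B", UNSTRATIFIED, UNSTRATIFIED]
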