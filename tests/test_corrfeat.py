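import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cortsep.corrfeat import (
    CorrelationMatrix,
    FeatureSet,
    SubsetDraw,
    build_feature_matrix,
    cohort_correlation,
    correlation_difference,
    count_candidate_features,
    sample_subsets,
    select_top_features,
    subset_feature_vector,
)
from cortsep.io_atlas import CASE, CONTROL, RegionAtlas, ThicknessTable
from cortsep.synthetic import hub_scenario, simulate_cohorts


def small_atlas(p):
    return RegionAtlas(tuple(f"lh_r{i:02d}" for i in range(p)), ("lh",) * p)


def table_from_values(values, cohort=CASE, prefix="S"):
    values = np.asarray(values, float)
    atlas = small_atlas(values.shape[1])
    ids = tuple(f"{prefix}{i:03d}" for i in range(values.shape[0]))
    return ThicknessTable(ids, (cohort,) * values.shape[0], values, atlas)


class TestCohortCorrelation:
    def test_affine_pair_gives_unit_correlation(self, rng):
        x = 2.0 + rng.random(10)
        values = np.column_stack([x, 0.5 * x + 1.0, 2.0 + rng.random(10)])
        cm = cohort_correlation(table_from_values(values))
        assert cm.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_negative_correlation(self):
        # region A: 2.1 2.3 2.5 2.7 ; region B: 3.0 2.9 2.8 2.7 (exactly
        # affine with negative slope, so the Pearson formula gives -1)
        values = np.array([[2.1, 3.0], [2.3, 2.9], [2.5, 2.8], [2.7, 2.7]])
        cm = cohort_correlation(table_from_values(values))
        assert cm.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_region_named_in_error(self):
        values = np.array([[2.0, 2.5], [2.1, 2.5], [2.2, 2.5]])
        with pytest.raises(ValueError, match="lh_r01"):
            cohort_correlation(table_from_values(values))

    def test_too_few_subjects(self):
        values = np.array([[2.0, 2.5], [2.1, 2.6]])
        with pytest.raises(ValueError, match="3 subjects"):
            cohort_correlation(table_from_values(values))

    def test_symmetric_unit_diagonal(self, rng):
        values = 2.5 + 0.2 * rng.standard_normal((12, 8))
        cm = cohort_correlation(table_from_values(values))
        np.testing.assert_array_equal(cm.values, cm.values.T)
        np.testing.assert_allclose(np.diag(cm.values), 1.0)
        assert cm.n_subjects == 12


class TestCorrelationDifference:
    def _cm(self, values, atlas, n=10):
        return CorrelationMatrix(values, n, atlas)

    def test_identical_inputs_zero(self, rng):
        atlas = small_atlas(5)
        R = np.corrcoef(rng.standard_normal((5, 30)))
        d = correlation_difference(self._cm(R, atlas), self._cm(R, atlas))
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_arithmetic(self):
        atlas = small_atlas(3)
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.8
        b = np.eye(3)
        b[0, 1] = b[1, 0] = -0.1
        d = correlation_difference(self._cm(a, atlas), self._cm(b, atlas))
        assert d[0, 1] == pytest.approx(0.9, abs=1e-12)
        assert d[1, 0] == pytest.approx(0.9, abs=1e-12)

    def test_symmetry_and_zero_diagonal(self, rng):
        atlas = small_atlas(6)
        a = np.corrcoef(rng.standard_normal((6, 25)))
        b = np.corrcoef(rng.standard_normal((6, 25)))
        d = correlation_difference(self._cm(a, atlas), self._cm(b, atlas))
        np.testing.assert_array_equal(d, d.T)
        np.testing.assert_array_equal(np.diag(d), 0.0)

    def test_atlas_mismatch_rejected(self, rng):
        a = np.corrcoef(rng.standard_normal((3, 25)))
        with pytest.raises(Exception, match="atlas"):
            correlation_difference(
                self._cm(a, small_atlas(3)),
                self._cm(a, RegionAtlas(("lh_x", "lh_y", "lh_z"), ("lh",) * 3)),
            )

    def test_fisher_z_changes_scale(self):
        atlas = small_atlas(3)
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.8
        b = np.eye(3)
        d = correlation_difference(self._cm(a, atlas), self._cm(b, atlas), fisher_z=True)
        assert d[0, 1] == pytest.approx(np.arctanh(0.8), abs=1e-12)


def brute_force_top_k(diff, k):
    p = diff.shape[0]
    pairs = sorted(
        itertools.combinations(range(p), 2), key=lambda ij: (-diff[ij[0], ij[1]], ij)
    )
    return pairs[:k]


class TestSelectTopFeatures:
    def test_default_k_is_15(self, rng):
        diff = np.abs(np.corrcoef(rng.standard_normal((70, 80))))
        np.fill_diagonal(diff, 0)
        fs = select_top_features(diff)
        assert fs.k == 15

    def test_all_equal_ties_lexicographic(self):
        diff = np.full((6, 6), 0.5)
        np.fill_diagonal(diff, 0)
        fs = select_top_features(diff, 4, small_atlas(6))
        assert fs.pairs == ((0, 1), (0, 2), (0, 3), (0, 4))

    def test_matches_brute_force_random_6x6(self, rng):
        diff = np.abs(rng.standard_normal((6, 6)))
        diff = (diff + diff.T) / 2
        np.fill_diagonal(diff, 0)
        fs = select_top_features(diff, 4, small_atlas(6))
        assert list(fs.pairs) == brute_force_top_k(diff, 4)

    def test_scores_non_increasing(self, rng):
        diff = np.abs(rng.standard_normal((10, 10)))
        diff = (diff + diff.T) / 2
        np.fill_diagonal(diff, 0)
        fs = select_top_features(diff, 10, small_atlas(10))
        assert np.all(np.diff(fs.scores) <= 1e-12)

    @pytest.mark.parametrize("k", [0, -1, 2416])
    def test_bad_k_rejected(self, k, rng):
        diff = np.zeros((70, 70))
        with pytest.raises(ValueError):
            select_top_features(diff, k)

    @given(
        matrix=arrays(
            float,
            st.integers(3, 8).map(lambda p: (p, p)),
            elements=st.floats(0, 1, allow_nan=False, width=32),
        ),
        k=st.integers(1, 3),
    )
    @settings(max_examples=60, deadline=None)
    def test_property_matches_exhaustive_sort(self, matrix, k):
        diff = (matrix + matrix.T) / 2
        np.fill_diagonal(diff, 0)
        p = diff.shape[0]
        fs = select_top_features(diff, k, small_atlas(p))
        assert list(fs.pairs) == brute_force_top_k(diff, k)


class TestCountCandidateFeatures:
    def test_full_matrix_count_with_diagonal(self, dk70):
        assert count_candidate_features(dk70, include_diagonal=True) == 2485

    def test_off_diagonal_count(self, dk70):
        assert count_candidate_features(dk70, include_diagonal=False) == 2415

    def test_three_regions(self):
        assert count_candidate_features(3, include_diagonal=False) == 3


class TestSampleSubsets:
    def test_draw_counts_and_sizes(self, cohort_tables):
        case, _ = cohort_tables
        draws = sample_subsets(case, CASE, g=6, n_subsets=500, seed=1)
        assert len(draws) == 500
        for d in draws[:20]:
            assert len(set(d.subject_ids)) == 6
            assert d.cohort == CASE

    def test_determinism(self, cohort_tables):
        case, _ = cohort_tables
        a = sample_subsets(case, CASE, 6, 50, seed=3)
        b = sample_subsets(case, CASE, 6, 50, seed=3)
        assert [d.subject_ids for d in a] == [d.subject_ids for d in b]

    def test_subjects_recur_across_draws(self, cohort_tables):
        case, _ = cohort_tables
        draws = sample_subsets(case, CASE, 6, 100, seed=0)
        all_ids = [s for d in draws for s in d.subject_ids]
        assert len(all_ids) > len(set(all_ids))

    def test_g_exceeding_cohort_errors(self, rng):
        values = 2.5 + 0.1 * rng.standard_normal((6, 4))
        table = table_from_values(values)
        with pytest.raises(ValueError, match="exceeds"):
            sample_subsets(table, CASE, g=7, n_subsets=1, seed=0)


class TestSubsetFeatureVector:
    def test_hand_evaluated_pearson_n6(self):
        # direct formula evaluation on the printed values gives 31/35
        a = np.array([2.0, 2.1, 2.2, 2.3, 2.4, 2.5])
        b = np.array([1.0, 1.2, 1.1, 1.4, 1.3, 1.5])
        values = np.column_stack([a, b, np.linspace(2.0, 3.0, 6)])
        table = table_from_values(values)
        fs = FeatureSet(((0, 1),), np.array([1.0]), table.atlas)
        vec = subset_feature_vector(table, SubsetDraw(table.subject_ids, CASE), fs)
        assert vec[0] == pytest.approx(31 / 35, abs=1e-12)

    def test_proportional_pair_gives_one(self):
        a = np.array([2.0, 2.2, 2.1, 2.5, 2.4, 2.3])
        values = np.column_stack([a, 2.0 * a])
        table = table_from_values(values)
        fs = FeatureSet(((0, 1),), np.array([1.0]), table.atlas)
        vec = subset_feature_vector(table, SubsetDraw(table.subject_ids, CASE), fs)
        assert vec[0] == pytest.approx(1.0, abs=1e-12)

    def test_vector_length_k(self, cohort_tables, selected_features):
        case, _ = cohort_tables
        draw = sample_subsets(case, CASE, 6, 1, seed=0)[0]
        vec = subset_feature_vector(case, draw, selected_features)
        assert vec.shape == (15,)
        assert np.all(np.abs(vec) <= 1)

    def test_zero_variance_errors_by_default(self):
        values = np.column_stack([np.full(6, 2.5), np.linspace(2, 3, 6)])
        table = table_from_values(values)
        fs = FeatureSet(((0, 1),), np.array([1.0]), table.atlas)
        draw = SubsetDraw(table.subject_ids, CASE)
        with pytest.raises(ValueError, match="zero within-subset variance"):
            subset_feature_vector(table, draw, fs)
        vec = subset_feature_vector(table, draw, fs, nan_feature=True)
        assert np.isnan(vec[0])


class TestBuildFeatureMatrix:
    def test_protocol_shape_1000x15(self, cohort_tables, selected_features):
        case, control = cohort_tables
        fm = build_feature_matrix(case, control, selected_features, 500, 6, seed=0)
        assert fm.values.shape == (1000, 15)
        labels = fm.label_array()
        assert (labels == CASE).sum() == 500
        assert (labels == CONTROL).sum() == 500
        assert len(fm.provenance) == 1000

    def test_single_subset_per_cohort(self, cohort_tables, selected_features):
        case, control = cohort_tables
        fm = build_feature_matrix(case, control, selected_features, 1, 6, seed=0)
        assert fm.n_rows == 2

    def test_entries_in_range_and_provenance_cohorts(self, cohort_tables, selected_features):
        case, control = cohort_tables
        fm = build_feature_matrix(case, control, selected_features, 50, 6, seed=2)
        assert np.all(np.abs(fm.values) <= 1)
        case_ids = set(case.subject_ids)
        for row, lab in zip(fm.provenance, fm.labels):
            assert (set(row) <= case_ids) == (lab == CASE)

    def test_planted_feature_case_mean_exceeds_control(
        self, cohort_tables, selected_features, default_scenario
    ):
        _, hub_pairs = default_scenario
        case, control = cohort_tables
        fm = build_feature_matrix(case, control, selected_features, 500, 6, seed=7)
        labels = fm.label_array()
        hub_set = {(p.i, p.j) for p in hub_pairs}
        planted_cols = [c for c, pair in enumerate(selected_features.pairs) if pair in hub_set]
        assert planted_cols, "no planted pair selected"
        for c in planted_cols:
            assert fm.values[labels == CASE, c].mean() > fm.values[labels == CONTROL, c].mean()

    def test_determinism(self, cohort_tables, selected_features):
        case, control = cohort_tables
        a = build_feature_matrix(case, control, selected_features, 20, 6, seed=5)
        b = build_feature_matrix(case, control, selected_features, 20, 6, seed=5)
        np.testing.assert_array_equal(a.values, b.values)


class TestPlantedRecovery:
    """Weakened, true version of the strict 95% acceptance criterion.

    The strict criterion (all 15 hub pairs in the top 15 for >= 95% of
    seeds) is asserted in the acceptance suite, where it documents an
    unattainable target at this effect size and cohort size; here we pin
    the recovery level that actually holds.
    """

    def test_mean_recovery_at_strong_effect(self):
        recovered = []
        for seed in range(20):
            spec, hub_pairs = hub_scenario(seed=seed)
            case, control = simulate_cohorts(spec, seed=seed)
            diff = correlation_difference(
                cohort_correlation(case), cohort_correlation(control)
            )
            fs = select_top_features(diff, 15, case.atlas)
            recovered.append(len({(p.i, p.j) for p in hub_pairs} & set(fs.pairs)))
        assert np.mean(recovered) >= 11.0
        assert np.median(recovered) >= 12.0
        assert max(recovered) == 15
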