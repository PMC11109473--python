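"""Pairwise/multigroup tests, the permutation engine, FDR, orchestration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from isodiff.diffstats import (
    ConfigurationError,
    InsufficientDataError,
    SpecificationError,
    adjust_pvalues,
    effect_size,
    multigroup_test,
    pairwise_test,
    permutation_test,
    run_comparison,
    time_responsive,
    timecourse_comparisons,
)
from isodiff.preprocess import Dataset
from isodiff.simulate import generate_preset
from isodiff.tables import ComparisonSpec, GroupSelector


class TestPairwise:
    def test_identical_groups_give_p_one(self):
        a = [1.0, 2.0, 3.0]
        stat, p = pairwise_test(a, a, "mann_whitney")
        assert p == 1.0
        assert stat == 0.0

    def test_rank_sum_matches_enumeration_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        _, p = pairwise_test(a, b, "wilcoxon_rank_sum")
        assert p == pytest.approx(oracles.rank_sum_tail_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("test", ["t_test", "mann_whitney", "wilcoxon_rank_sum",
                                      "permutation", "wilcoxon_signed_rank"])
    def test_statistic_sign_positive_when_A_larger(self, test):
        a, b = [5.0, 6.0, 7.0, 8.0], [1.0, 2.0, 3.0, 4.0]
        stat, _ = pairwise_test(a, b, test, rng=0)
        assert stat > 0
        stat_rev, _ = pairwise_test(b, a, test, rng=0)
        assert stat_rev < 0

    def test_insufficient_data_raises_with_reason(self):
        with pytest.raises(InsufficientDataError):
            pairwise_test([1.0], [2.0, 3.0], "mann_whitney")
        with pytest.raises(InsufficientDataError):
            pairwise_test([1.0, np.nan, np.nan], [2.0, 3.0, 4.0], "t_test")

    def test_unknown_test_lists_supported(self):
        with pytest.raises(ConfigurationError, match="mann_whitney"):
            pairwise_test([1.0, 2.0], [3.0, 4.0], "anova")

    def test_paired_test_drops_incomplete_pairs(self):
        a = [1.0, 2.0, 3.0, np.nan, 5.0]
        b = [1.1, 2.2, 2.9, 4.0, np.nan]
        stat, p = pairwise_test(a, b, "wilcoxon_signed_rank")
        stat2, p2 = pairwise_test(a[:3], b[:3], "wilcoxon_signed_rank")
        assert (stat, p) == (stat2, p2)


class TestPermutation:
    @pytest.mark.parametrize("na,nb", [(2, 2), (2, 3), (3, 3), (2, 4), (3, 4), (4, 4)])
    @pytest.mark.parametrize("statistic", ["mean_diff", "abs_mean_diff", "rank_sum"])
    def test_exhaustive_equals_brute_force(self, rng, na, nb, statistic):
        a = rng.integers(0, 50, na).astype(float)
        b = rng.integers(0, 50, nb).astype(float)
        _, p, exact = permutation_test(a, b, statistic=statistic)
        assert exact
        assert p == oracles.brute_force_permutation_p(a, b, statistic)

    def test_separated_groups_example(self):
        # both extreme labelings of fully separated groups → p = 2/20
        _, p, exact = permutation_test([1.0, 2.0, 3.0], [7.0, 8.0, 9.0])
        assert exact
        assert p == pytest.approx(0.1)

    def test_identical_constant_vectors_degenerate(self):
        _, p, _ = permutation_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_monte_carlo_seeded_determinism(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=9)  # C(18,9) = 48620 > n_permutations
        r1 = permutation_test(a, b, n_permutations=10_000, rng=42)
        r2 = permutation_test(a, b, n_permutations=10_000, rng=42)
        assert r1 == r2
        assert not r1[2]  # Monte Carlo, not exact
        assert r1[1] > 0  # add-one rule forbids p = 0

    def test_too_few_permutations_is_config_error(self):
        with pytest.raises(ConfigurationError):
            permutation_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], n_permutations=50)


class TestMultigroup:
    def test_identical_groups(self):
        g = [1.0, 1.0]
        h, p = multigroup_test([g, g, g])
        assert (h, p) == (0.0, 1.0)

    def test_hand_computed_h(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        h, _ = multigroup_test(groups)
        assert h == pytest.approx(oracles.kruskal_h(groups), rel=1e-12)

    def test_fully_missing_group_raises(self):
        with pytest.raises(InsufficientDataError):
            multigroup_test([[1.0, 2.0], [np.nan, np.nan], [3.0, 4.0]])


class TestAdjustPvalues:
    def test_hand_stepup(self):
        got = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert adjust_pvalues([0.03], "BH")[0] == pytest.approx(0.03)

    def test_matches_independent_stepup_oracle(self, rng):
        for _ in range(200):
            p = rng.uniform(1e-6, 1.0, rng.integers(1, 40))
            np.testing.assert_allclose(adjust_pvalues(p, "BH"), oracles.stepup_bh(p),
                                       rtol=0, atol=1e-14)

    def test_nan_passthrough_and_family_size(self):
        got = adjust_pvalues([0.05, np.nan, 0.05])
        assert np.isnan(got[1])
        # family of 2, both at the max rank: p_adj = 0.05
        np.testing.assert_allclose(got[[0, 2]], [0.05, 0.05])

    def test_unknown_method_lists_supported(self):
        with pytest.raises(ConfigurationError, match="BH"):
            adjust_pvalues([0.1], "fdr_magic")

    @settings(max_examples=30, deadline=None)
    @given(p=st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_bh_bounds_and_order_preserved(self, p):
        adj = adjust_pvalues(p, "BH")
        assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestEffectSize:
    def test_abundance_log2_geometric_ratio(self):
        a, b = np.array([4.0, 16.0]), np.array([1.0, 4.0])
        # geometric means 8 and 2 → log2 ratio = 2
        assert effect_size(a, b, "total_abundance") == pytest.approx(2.0)

    def test_bounded_quantities_use_mean_difference(self):
        a, b = np.array([0.5, 0.7]), np.array([0.1, 0.3])
        assert effect_size(a, b, "fractional_contribution") == pytest.approx(0.4)


@pytest.fixture(scope="module")
def dataset():
    return generate_preset("ldh_ko_48h", seed=7)


@pytest.fixture(scope="module")
def spec():
    return ComparisonSpec(
        kind="pairwise_condition",
        groups=[GroupSelector("KO", 48.0), GroupSelector("control", 48.0)],
    )


class TestRunComparison:
    def test_one_row_per_feature_per_quantity(self, dataset, spec):
        ds, _ = dataset
        res = run_comparison(ds, spec, seed=7)
        assert set(res) == {"total_abundance", "fractional_contribution",
                           "isotopologue_proportion"}
        assert len(res["total_abundance"]) == len(ds.abundance.data)
        assert len(res["isotopologue_proportion"]) == len(ds.isotopologues_proportion.data)

    def test_alpha_zero_yields_no_significant_features(self, dataset):
        ds, _ = dataset
        spec = ComparisonSpec(
            kind="pairwise_condition",
            groups=[GroupSelector("KO"), GroupSelector("control")],
            alpha=0.0,
        )
        res = run_comparison(ds, spec, seed=7)
        for frame in res.values():
            assert not frame["significant"].any()

    def test_same_seed_reproduces_byte_identical_tables(self, dataset, spec, tmp_path):
        from isodiff import io

        ds, _ = dataset
        paths = []
        for i in (1, 2):
            res = run_comparison(ds, spec, seed=99)
            path = tmp_path / f"run{i}.tsv"
            io.write_result_table(res["total_abundance"], path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_fdr_families_never_mix_quantity_types(self, dataset, spec):
        """Abundance results are invariant to removing isotopologue features."""
        ds, _ = dataset
        full = run_comparison(ds, spec, seed=7)["total_abundance"]
        stripped = Dataset(samplesheet=ds.samplesheet, abundance=ds.abundance)
        alone = run_comparison(stripped, spec, seed=7)["total_abundance"]
        pd.testing.assert_frame_equal(full, alone)

    def test_empty_selector_is_specification_error(self, dataset):
        ds, _ = dataset
        spec = ComparisonSpec(
            kind="pairwise_condition",
            groups=[GroupSelector("missing_condition"), GroupSelector("control")],
        )
        with pytest.raises(SpecificationError, match="missing_condition"):
            run_comparison(ds, spec, seed=7)

    def test_feature_with_missing_values_gets_reason_not_nan_surprise(self, dataset, spec):
        ds, _ = dataset
        crippled = ds.abundance.data.copy()
        crippled.loc["AKG_like", ds.samplesheet.select("KO")] = np.nan
        ds2 = Dataset(
            samplesheet=ds.samplesheet,
            abundance=type(ds.abundance)(data=crippled, quantity="total_abundance"),
        )
        res = run_comparison(ds2, spec, seed=7)["total_abundance"]
        row = res.set_index("feature_id").loc["AKG_like"]
        assert row["reason"].startswith("skipped")
        assert np.isnan(row["p_raw"]) and not row["significant"]


class TestTimecourse:
    def test_six_timepoints_yield_five_labeled_families(self, timecourse_dataset):
        ds, _ = timecourse_dataset
        res = timecourse_comparisons(ds, condition="control", seed=5)
        labels = list(dict.fromkeys(res["comparison"]))
        assert labels == ["1vs0", "2vs1", "4vs2", "6vs4", "24vs6"]

    def test_two_timepoints_single_family(self, timecourse_dataset):
        ds, _ = timecourse_dataset
        keep = ds.samplesheet.data["timepoint_hours"].isin([0.0, 24.0])
        sheet = type(ds.samplesheet)(data=ds.samplesheet.data[keep].copy())
        sub = Dataset(
            samplesheet=sheet,
            abundance=type(ds.abundance)(
                data=ds.abundance.data[list(sheet.samples)], quantity="total_abundance"
            ),
        )
        res = timecourse_comparisons(sub, condition="control", seed=5)
        assert res["comparison"].nunique() == 1

    def test_single_timepoint_rejected(self, ldh_dataset):
        ds, _ = ldh_dataset
        with pytest.raises(SpecificationError):
            timecourse_comparisons(ds, condition="control", seed=5)

    def test_time_responsive_flag_requires_one_significant_interval(self):
        frame = pd.DataFrame(
            {
                "feature_id": ["a", "a", "b", "b"],
                "quantity": ["total_abundance"] * 4,
                "comparison": ["1vs0", "2vs1"] * 2,
                "significant": [False, True, False, False],
            }
        )
        flags = time_responsive(frame).set_index("feature_id")["time_responsive"]
        assert bool(flags["a"]) and not bool(flags["b"])
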