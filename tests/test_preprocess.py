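"""The three derivation formulas and the dataset harmonization contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isodiff.preprocess import (
    ModeError,
    fractional_contribution,
    harmonize_inputs,
    isotopologue_proportions,
    total_abundance,
)
from isodiff.tables import ABSOLUTE, PROPORTION, MetaboliteTable
from conftest import make_iso_table


class TestTotalAbundance:
    def test_hand_sum(self):
        t = make_iso_table({"A": [[10.0, 30.0, 60.0]]}, ["s1"], ABSOLUTE)
        assert total_abundance(t).data.loc["A", "s1"] == 100.0

    def test_all_zero_vector_sums_to_zero(self):
        t = make_iso_table({"A": [[0.0, 0.0, 0.0]]}, ["s1"], ABSOLUTE)
        assert total_abundance(t).data.loc["A", "s1"] == 0.0

    def test_matches_independent_per_column_summation(self, rng):
        mets = {f"m{i}": [list(rng.uniform(0, 1e5, 4)) for _ in range(3)] for i in range(50)}
        t = make_iso_table(mets, ["s1", "s2", "s3"], ABSOLUTE)
        got = total_abundance(t).data
        for met, vecs in mets.items():
            for s, vec in zip(["s1", "s2", "s3"], vecs):
                assert got.loc[met, s] == pytest.approx(sum(vec), rel=1e-12)

    def test_missing_isotopologue_propagates(self):
        t = make_iso_table({"A": [[10.0, np.nan, 60.0]]}, ["s1"], ABSOLUTE)
        assert np.isnan(total_abundance(t).data.loc["A", "s1"])

    def test_proportion_mode_rejected(self, prop_table):
        with pytest.raises(ModeError):
            total_abundance(prop_table)


class TestProportions:
    def test_hand_normalization(self):
        t = make_iso_table({"A": [[10.0, 30.0, 60.0]]}, ["s1"], ABSOLUTE)
        got = isotopologue_proportions(t).data["s1"].to_numpy()
        np.testing.assert_allclose(got, [0.10, 0.30, 0.60])

    def test_zero_sum_cell_becomes_missing(self):
        t = make_iso_table({"A": [[0.0, 0.0, 0.0]]}, ["s1"], ABSOLUTE)
        assert isotopologue_proportions(t).data["s1"].isna().all()

    def test_proportions_sum_to_one_wherever_defined(self, rng):
        mets = {f"m{i}": [list(rng.uniform(0, 100, 5)) for _ in range(3)] for i in range(20)}
        t = make_iso_table(mets, ["s1", "s2", "s3"], ABSOLUTE)
        sums = isotopologue_proportions(t).data.groupby(level=0).sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, rtol=1e-12)


class TestFractionalContribution:
    @pytest.mark.parametrize(
        "c,expected",
        [
            ([1.0, 0.0, 0.0, 0.0], 0.0),  # fully unlabeled
            ([0.0, 0.0, 0.0, 1.0], 1.0),  # fully labeled
            ([0.25, 0.50, 0.25], 0.5),    # n=2: (0.5·1 + 0.25·2)/2
        ],
    )
    def test_hand_evaluations(self, c, expected):
        t = make_iso_table({"A": [c]}, ["s1"], PROPORTION)
        assert fractional_contribution(t).data.loc["A", "s1"] == pytest.approx(
            expected, abs=1e-15
        )

    def test_zero_carbon_metabolite_rejected(self):
        t = make_iso_table({"CO2ish": [[1.0]]}, ["s1"], PROPORTION)
        with pytest.raises(ValueError, match="n=0"):
            fractional_contribution(t)

    def test_absolute_mode_rejected(self, abs_table):
        with pytest.raises(ModeError):
            fractional_contribution(abs_table)


class TestAlgebraicProperties:
    @settings(max_examples=50, deadline=None)
    @given(
        mvec=st.lists(st.floats(1e-3, 1e6), min_size=2, max_size=7),
        k=st.floats(1e-6, 1e6),
    )
    def test_composition_identity_and_scale_invariance(self, mvec, k):
        """φ(proportions(M)) == Σ(Mj·j)/(n·ΣMj), and both are k-invariant."""
        n = len(mvec) - 1
        t = make_iso_table({"A": [mvec]}, ["s1"], ABSOLUTE)
        phi = fractional_contribution(isotopologue_proportions(t)).data.loc["A", "s1"]
        direct = sum(m * j for j, m in enumerate(mvec)) / (n * sum(mvec))
        assert phi == pytest.approx(direct, rel=1e-12)

        scaled = make_iso_table({"A": [[k * m for m in mvec]]}, ["s1"], ABSOLUTE)
        phi_scaled = fractional_contribution(
            isotopologue_proportions(scaled)
        ).data.loc["A", "s1"]
        assert phi_scaled == pytest.approx(phi, rel=1e-9)


class TestHarmonize:
    def test_all_three_tables_from_absolutes(self, abs_table, two_sample_sheet):
        t = make_iso_table(
            {"Ala": [[10.0, 30.0, 60.0]] * 6, "Mal": [[5.0, 5.0, 5.0, 5.0]] * 6},
            list(two_sample_sheet.samples),
            ABSOLUTE,
        )
        ds = harmonize_inputs(samplesheet=two_sample_sheet, isotopologues=t)
        assert ds.abundance is not None
        assert ds.fractional is not None
        assert ds.isotopologues_proportion is not None

    def test_proportions_only_flags_abundance_unavailable(self, two_sample_sheet):
        t = make_iso_table(
            {"Ala": [[0.1, 0.3, 0.6]] * 6}, list(two_sample_sheet.samples), PROPORTION
        )
        ds = harmonize_inputs(samplesheet=two_sample_sheet, isotopologues=t)
        assert ds.abundance is None
        assert ds.fractional is not None
        assert any("total abundances unavailable" in line for line in ds.log)

    def test_supplied_table_wins_and_discrepancy_logged(self, two_sample_sheet):
        samples = list(two_sample_sheet.samples)
        t = make_iso_table({"Ala": [[10.0, 30.0, 60.0]] * 6}, samples, ABSOLUTE)
        supplied = MetaboliteTable(
            data=pd.DataFrame({s: [999.0] for s in samples}, index=["Ala"]),
            quantity="total_abundance",
        )
        ds = harmonize_inputs(
            samplesheet=two_sample_sheet, isotopologues=t, abundance=supplied
        )
        assert (ds.abundance.data.loc["Ala"] == 999.0).all()
        assert any("differs" in line for line in ds.log)

    def test_percentage_proportions_autodetected(self, two_sample_sheet):
        t = make_iso_table(
            {"Ala": [[10.0, 30.0, 60.0]] * 6},  # sums to 100: percentages
            list(two_sample_sheet.samples),
            PROPORTION,
        )
        ds = harmonize_inputs(samplesheet=two_sample_sheet, isotopologues=t)
        np.testing.assert_allclose(
            ds.isotopologues_proportion.data["c1"].to_numpy(), [0.1, 0.3, 0.6]
        )

    def test_unknown_sample_column_is_alignment_error(self, two_sample_sheet):
        t = make_iso_table({"Ala": [[1.0, 2.0, 3.0]]}, ["mystery"], ABSOLUTE)
        with pytest.raises(Exception, match="mystery"):
            harmonize_inputs(samplesheet=two_sample_sheet, isotopologues=t)
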