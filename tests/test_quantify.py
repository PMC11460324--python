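"""Normalization, precursor filtering, protein roll-up, imputation, CVs."""

import math

import numpy as np
import pandas as pd
import pytest

from bioidkit.quantify import (
    compute_cv,
    filter_precursors_percentile,
    impute_global,
    normalize_global_median,
    summarize_to_protein,
    ProteinQuantMatrix,
)


def frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "protein_group", "modified_sequence", "charge", "intensity"])


def sample_medians_log2(f):
    return {
        s: float(np.median(np.log2(sub["intensity"].dropna())))
        for s, sub in f.groupby("sample_id")
    }


class TestNormalization:
    def test_two_sample_medians_meet_at_grand_mean(self):
        # sample medians 10 and 12 (log2) -> both 11 after normalization
        f = frame([
            ("s1", "P1", "_AK_", 2, 2.0 ** 9), ("s1", "P2", "_CK_", 2, 2.0 ** 10),
            ("s1", "P3", "_DK_", 2, 2.0 ** 11),
            ("s2", "P1", "_AK_", 2, 2.0 ** 11), ("s2", "P2", "_CK_", 2, 2.0 ** 12),
            ("s2", "P3", "_DK_", 2, 2.0 ** 13),
        ])
        out = normalize_global_median(f)
        medians = sample_medians_log2(out)
        assert medians["s1"] == pytest.approx(11.0, abs=1e-9)
        assert medians["s2"] == pytest.approx(11.0, abs=1e-9)

    def test_equal_medians_are_identity(self):
        f = frame([("s1", "P1", "_AK_", 2, 100.0), ("s2", "P1", "_AK_", 2, 100.0)])
        out = normalize_global_median(f)
        assert np.allclose(out["intensity"], f["intensity"])

    def test_single_sample_unchanged(self):
        f = frame([("s1", "P1", "_AK_", 2, 123.0), ("s1", "P2", "_CK_", 2, 456.0)])
        out = normalize_global_median(f)
        assert np.allclose(out["intensity"], f["intensity"])

    def test_all_missing_sample_is_error(self):
        f = frame([("s1", "P1", "_AK_", 2, 100.0), ("s2", "P1", "_AK_", 2, np.nan)])
        with pytest.raises(ValueError, match="s2"):
            normalize_global_median(f)

    def test_median_equality_holds_on_generated_data(self, small_experiment):
        from bioidkit.io_annotations import records_to_frame

        out = normalize_global_median(records_to_frame(small_experiment.records))
        medians = sample_medians_log2(out)
        grand = np.mean(list(medians.values()))
        assert all(abs(m - grand) < 1e-9 for m in medians.values())


class TestPrecursorFilter:
    def _ten_precursors(self):
        rows = []
        for i in range(10):
            # cross-sample median intensity of precursor i is 2**(10+i)
            rows.append(("s1", f"P{i}", f"_PEP{chr(65 + i)}K_", 2, 2.0 ** (10 + i)))
            rows.append(("s2", f"P{i}", f"_PEP{chr(65 + i)}K_", 2, 2.0 ** (10 + i)))
        return frame(rows)

    def test_fraction_zero_is_identity(self):
        f = self._ten_precursors()
        assert filter_precursors_percentile(f, 0.0).equals(f)

    def test_fraction_removes_lowest_median_precursors(self):
        # brute-force expectation: fraction 0.2 of 10 precursors -> the 2 lowest
        out = filter_precursors_percentile(self._ten_precursors(), 0.2)
        assert set(out["protein_group"]) == {f"P{i}" for i in range(2, 10)}

    def test_fraction_one_empties_the_table(self):
        assert filter_precursors_percentile(self._ten_precursors(), 1.0).empty

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            filter_precursors_percentile(self._ten_precursors(), 1.5)


class TestProteinSummarization:
    def test_top3_mean_of_three_precursors(self):
        f = frame([
            ("s1", "P1", "_AK_", 2, 2.0 ** 10),
            ("s1", "P1", "_CK_", 2, 2.0 ** 11),
            ("s1", "P1", "_DK_", 2, 2.0 ** 12),
        ])
        matrix = summarize_to_protein(f)
        assert matrix.values.at["P1", "s1"] == pytest.approx(11.0)

    def test_single_hit_protein_excluded_and_reported(self):
        f = frame([
            ("s1", "SOLO", "_AK_", 2, 100.0),
            ("s1", "PAIR", "_CK_", 2, 100.0),
            ("s1", "PAIR", "_DK_", 2, 100.0),
        ])
        matrix = summarize_to_protein(f)
        assert "SOLO" not in matrix.values.index
        assert matrix.excluded_single_hit == ["SOLO"]
        assert matrix.n_precursors["PAIR"] == 2

    def test_five_precursors_only_top3_by_median_used(self):
        # medians 10..14; top-3 are 12,13,14 -> mean 13 in every sample
        rows = []
        for i in range(5):
            rows.append(("s1", "P1", f"_PEP{chr(65 + i)}K_", 2, 2.0 ** (10 + i)))
            rows.append(("s2", "P1", f"_PEP{chr(65 + i)}K_", 2, 2.0 ** (10 + i)))
        matrix = summarize_to_protein(frame(rows))
        assert matrix.values.at["P1", "s1"] == pytest.approx(13.0)
        assert matrix.values.at["P1", "s2"] == pytest.approx(13.0)

    def test_empty_input_gives_empty_matrix(self):
        matrix = summarize_to_protein(frame([]))
        assert matrix.values.empty

    def test_protein_count_conservation(self, small_experiment):
        """|matrix proteins| + |excluded single hits| = |distinct input proteins|."""
        from bioidkit.io_annotations import records_to_frame

        f = records_to_frame(small_experiment.records)
        matrix = summarize_to_protein(f)
        assert len(matrix.proteins) + len(matrix.excluded_single_hit) == f["protein_group"].nunique()

    def test_shift_equivariance(self):
        """A constant per-sample log2 shift propagates unchanged to the matrix."""
        rows = [
            ("s1", "P1", "_AK_", 2, 2.0 ** 10), ("s1", "P1", "_CK_", 2, 2.0 ** 12),
            ("s2", "P1", "_AK_", 2, 2.0 ** 11), ("s2", "P1", "_CK_", 2, 2.0 ** 13),
        ]
        f = frame(rows)
        shifted = f.copy()
        shifted.loc[shifted["sample_id"] == "s2", "intensity"] *= 2.0 ** 3
        base = summarize_to_protein(f).values
        out = summarize_to_protein(shifted).values
        assert out.at["P1", "s1"] == pytest.approx(base.at["P1", "s1"])
        assert out.at["P1", "s2"] == pytest.approx(base.at["P1", "s2"] + 3.0)


class TestImputation:
    def _matrix_with_missing(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(
            rng.normal(25, 2, size=(10, 4)),
            index=[f"P{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(4)],
        )
        values.iloc[0, 0] = np.nan
        values.iloc[3, 2] = np.nan
        return ProteinQuantMatrix(values, {f"P{i}": 2 for i in range(10)})

    def test_observed_values_untouched(self):
        matrix = self._matrix_with_missing()
        out = impute_global(matrix, seed=1)
        observed = ~matrix.values.isna()
        assert out.values.values[observed.values] == pytest.approx(
            matrix.values.values[observed.values]
        )
        assert not out.values.isna().any().any()

    def test_no_missing_is_identity(self):
        matrix = self._matrix_with_missing()
        matrix.values.iloc[0, 0] = 25.0
        matrix.values.iloc[3, 2] = 25.0
        out = impute_global(matrix, seed=1)
        assert out.values.equals(matrix.values)

    def test_same_seed_identical_imputations(self):
        matrix = self._matrix_with_missing()
        a = impute_global(matrix, seed=9).values
        b = impute_global(matrix, seed=9).values
        assert a.equals(b)

    def test_imputed_values_below_observed_median(self):
        matrix = self._matrix_with_missing()
        out = impute_global(matrix, seed=2)
        observed = matrix.values.to_numpy()
        median = np.nanmedian(observed)
        imputed = out.values.to_numpy()[matrix.values.isna().to_numpy()]
        assert (imputed < median).all()

    def test_too_few_observed_is_error(self):
        values = pd.DataFrame([[1.0, np.nan]], index=["P1"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="observed"):
            impute_global(ProteinQuantMatrix(values, {"P1": 2}), seed=0)


class TestCV:
    def _matrix(self, linear_rows):
        values = pd.DataFrame(
            np.log2(linear_rows),
            index=[f"P{i}" for i in range(len(linear_rows))],
            columns=[f"s{j}" for j in range(len(linear_rows[0]))],
        )
        return ProteinQuantMatrix(values, {p: 2 for p in values.index})

    def test_constant_values_have_zero_cv(self):
        cvs = compute_cv(self._matrix([[10.0, 10.0, 10.0]]), ["s0", "s1", "s2"])
        assert cvs["P0"] == pytest.approx(0.0)

    def test_cv_is_sd_over_mean_linear(self):
        # sd([8,10,12]) = 2 (ddof=1), mean = 10 -> CV 0.2
        cvs = compute_cv(self._matrix([[8.0, 10.0, 12.0]]), ["s0", "s1", "s2"])
        assert cvs["P0"] == pytest.approx(0.2)

    def test_single_observation_omitted(self):
        matrix = self._matrix([[8.0, 10.0, 12.0]])
        matrix.values.iloc[0, [1, 2]] = np.nan
        assert compute_cv(matrix, ["s0", "s1", "s2"]) == {}

    @pytest.mark.parametrize("scale", [0.5, 3.0, 1000.0])
    def test_scale_invariance(self, scale):
        base = compute_cv(self._matrix([[8.0, 10.0, 12.0]]), ["s0", "s1", "s2"])["P0"]
        scaled = compute_cv(
            self._matrix([[8.0 * scale, 10.0 * scale, 12.0 * scale]]), ["s0", "s1", "s2"]
        )["P0"]
        assert scaled == pytest.approx(base)
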