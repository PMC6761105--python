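import numpy as np
import pandas as pd
import pytest

from homapanel import (
    CohortSpec,
    FollowupParams,
    compute_homa_ir,
    read_cohort,
    simulate_cohort,
    simulate_followup,
    write_cohort,
)
from homapanel.errors import ConfigurationError, FormatError, InvalidInputError


class TestComputeHomaIr:
    @pytest.mark.parametrize(
        "glucose, insulin, expected",
        [(405.0, 1.0, 1.0), (93.25, 0.0, 0.0), (93.25, 10.25, 2.3600)],
    )
    def test_values(self, glucose, insulin, expected):
        assert compute_homa_ir(glucose, insulin) == pytest.approx(expected, abs=5e-5)

    def test_vectorized(self):
        out = compute_homa_ir([405.0, 81.0], [1.0, 5.0])
        assert np.allclose(out, [1.0, 1.0])

    @pytest.mark.parametrize("glucose, insulin", [(0.0, 5.0), (-10.0, 5.0), (90.0, -1.0)])
    def test_invalid_inputs(self, glucose, insulin):
        with pytest.raises(InvalidInputError):
            compute_homa_ir(glucose, insulin)


class TestCohortSpecValidation:
    def test_blocks_exceeding_features(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(n_subjects=50, n_metabolites=10, block_structure=((12, 0.5),))

    def test_bad_correlation(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(n_subjects=50, block_structure=((5, 1.0),))

    def test_missing_rates_ordering(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(n_subjects=50, missing_rate=0.25)
        with pytest.raises(ConfigurationError):
            CohortSpec(n_subjects=50, high_missing_rate=0.15)

    def test_effect_sizes_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(n_subjects=50, n_signal=3, effect_sizes=(1.0,))


class TestSimulateCohort:
    def test_deterministic_and_seed_sensitive(self):
        spec = CohortSpec(n_subjects=40, seed=3)
        a = simulate_cohort(spec)
        b = simulate_cohort(CohortSpec(n_subjects=40, seed=3))
        c = simulate_cohort(CohortSpec(n_subjects=40, seed=4))
        pd.testing.assert_frame_equal(a.metabolites, b.metabolites)
        assert np.array_equal(a.homa_ir, b.homa_ir)
        assert not a.metabolites.equals(c.metabolites)

    def test_homa_identity(self):
        cohort = simulate_cohort(CohortSpec(n_subjects=200, seed=11))
        np.testing.assert_allclose(
            cohort.homa_ir, cohort.glucose * cohort.insulin / 405.0, rtol=1e-9
        )

    def test_null_signal_mean_correlation_near_zero(self, null_cohort_500):
        cohort = null_cohort_500
        M = cohort.metabolites.to_numpy()
        corr = np.array(
            [np.corrcoef(M[:, j], cohort.homa_ir)[0, 1] for j in range(1, M.shape[1])]
        )  # met_glucose (col 0) tracks the assay and is excluded from the null set
        assert abs(corr.mean()) < 0.05

    def test_planted_signal_stands_out(self):
        spec = CohortSpec(
            n_subjects=500, n_metabolites=60, n_high_missing=0, n_signal=1,
            effect_sizes=(1.0,), block_structure=(), missing_rate=0.0, seed=5,
        )
        cohort = simulate_cohort(spec)
        M = cohort.metabolites
        sig = cohort.truth["signal_names"][0]
        corr = M.apply(lambda col: abs(np.corrcoef(col, cohort.homa_ir)[0, 1]))
        null_names = [
            c for c in M.columns if c != sig and c != "met_glucose"
        ]
        assert corr[sig] > np.percentile(corr[null_names], 99)

    def test_block_correlations_match_spec(self):
        blocks = ((10, 0.7), (8, 0.4))
        spec = CohortSpec(
            n_subjects=600, n_metabolites=30, n_high_missing=0, n_signal=0,
            block_structure=blocks, missing_rate=0.0, seed=9,
        )
        cohort = simulate_cohort(spec)
        M = cohort.metabolites.to_numpy()
        pos = 1
        for size, rho in blocks:
            sub = M[:, pos:pos + size]
            C = np.corrcoef(sub, rowvar=False)
            off = C[np.triu_indices(size, k=1)]
            assert abs(off.mean() - rho) < 0.1
            pos += size

    def test_missingness_fractions(self):
        spec = CohortSpec(n_subjects=100, seed=2)
        cohort = simulate_cohort(spec)
        frac = cohort.metabolites.isna().mean()
        high = set(cohort.truth["high_missing_names"])
        for name, f in frac.items():
            if name in high:
                assert f > 0.20
            else:
                assert f < 0.20


class TestFollowup:
    def test_zero_coefficients_zero_noise(self):
        cohort = simulate_cohort(CohortSpec(n_subjects=50, seed=1))
        params = FollowupParams(coef_weight=0.0, coef_baseline=0.0, noise_sd=0.0)
        out = simulate_followup(cohort, params, seed=0)
        np.testing.assert_allclose(out.followup["homa_ir"], cohort.homa_ir)

    def test_recovers_weight_slope_exactly(self):
        cohort = simulate_cohort(CohortSpec(n_subjects=80, seed=1))
        params = FollowupParams(coef_weight=0.1, coef_baseline=0.0, noise_sd=0.0)
        out = simulate_followup(cohort, params, seed=0)
        delta = out.followup["homa_ir"] - cohort.homa_ir
        delta_bw = out.followup["body_weight"] - cohort.body_weight
        slope = np.polyfit(delta_bw, delta, 1)[0]
        assert slope == pytest.approx(0.1, abs=1e-9)

    def test_deterministic(self):
        cohort = simulate_cohort(CohortSpec(n_subjects=50, seed=1))
        a = simulate_followup(cohort, FollowupParams(), seed=5)
        b = simulate_followup(cohort, FollowupParams(), seed=5)
        np.testing.assert_array_equal(a.followup["homa_ir"], b.followup["homa_ir"])

    def test_requires_baseline_phenotypes(self):
        cohort = simulate_cohort(CohortSpec(n_subjects=50, seed=1))
        cohort.body_weight = None
        with pytest.raises(InvalidInputError):
            simulate_followup(cohort, FollowupParams(), seed=0)


class TestCohortIO:
    def test_roundtrip_exact(self, tmp_path, fixture_cohorts):
        train, _ = fixture_cohorts
        path = tmp_path / "cohort.csv"
        write_cohort(train, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(
            back.metabolites, train.metabolites, check_exact=True
        )
        np.testing.assert_array_equal(back.homa_ir, train.homa_ir)
        np.testing.assert_array_equal(
            back.followup["homa_ir"], train.followup["homa_ir"]
        )
        assert back.truth["signal_names"] == train.truth["signal_names"]

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject_id,homa_ir,metA\nS1,1.2,5.0\nS2,1.4,oops\nS3,2.0,6.1\n"
        )
        with pytest.raises(FormatError, match="oops") as err:
            read_cohort(path)
        assert "metA" in str(err.value)
        assert "S2" in str(err.value)

    def test_partial_phenotypes_load(self, tmp_path):
        path = tmp_path / "partial.csv"
        path.write_text("subject_id,homa_ir,metA\nS1,1.2,5.0\nS2,1.4,4.0\n")
        cohort = read_cohort(path)
        assert cohort.insulin is None
        assert cohort.homa_ir is not None
        assert cohort.metabolite_names == ["metA"]

    def test_duplicate_metabolite_columns_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("subject_id,metA,metA\nS1,1.0,2.0\n")
        with pytest.raises(FormatError, match="metA"):
            read_cohort(path)

    def test_missing_encoded_as_empty_cells(self, tmp_path):
        cohort = simulate_cohort(CohortSpec(n_subjects=30, seed=6))
        path = tmp_path / "c.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert back.metabolites.isna().sum().sum() == cohort.metabolites.isna().sum().sum()
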