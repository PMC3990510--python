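"""Generator calibration: exposure copula, HWE dosages, planted effects."""

import math

import numpy as np
import pandas as pd
import pytest

from gxediet.synthetic import (
    default_consortium,
    generate_consortium,
    generate_dosages,
    generate_exposures,
    snp_metadata,
)
from gxediet.types import (
    GeneratorConfig,
    StudySpec,
    default_exposure_correlation,
)

MEANS = {"red_meat": 0.9, "processed_meat": 0.55, "vegetable": 2.4,
         "fruit": 2.0, "fiber": 18.0}
SDS = {"red_meat": 0.55, "processed_meat": 0.4, "vegetable": 1.1,
       "fruit": 1.0, "fiber": 7.0}


def _spec(**kw):
    base = dict(study_id="s", n_cases=100, n_controls=100,
                exposure_means=MEANS, exposure_sds=SDS)
    base.update(kw)
    return StudySpec(**base)


class TestGenerateExposures:
    def test_independent_exposures_under_identity_correlation(self):
        corr = pd.DataFrame(np.eye(5), index=list(MEANS), columns=list(MEANS))
        df = generate_exposures(_spec(), corr, 1000, seed=1)
        r = df.corr().to_numpy()
        off = r[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_default_profile_correlations_recovered(self):
        df = generate_exposures(_spec(), default_exposure_correlation(), 10_000, seed=2)
        assert np.corrcoef(df.fruit, df.vegetable)[0, 1] == pytest.approx(0.38, abs=0.03)
        assert np.corrcoef(df.fruit, df.fiber)[0, 1] == pytest.approx(0.52, abs=0.03)
        assert np.corrcoef(df.red_meat, df.processed_meat)[0, 1] == pytest.approx(0.62, abs=0.03)

    def test_marginal_mean_sd_and_truncation(self):
        df = generate_exposures(_spec(), default_exposure_correlation(), 20_000, seed=3)
        assert (df >= 0).all().all()
        assert df["fiber"].mean() == pytest.approx(18.0, rel=0.02)
        assert df["fiber"].std() == pytest.approx(7.0, rel=0.05)

    def test_empty_request_keeps_schema(self):
        df = generate_exposures(_spec(), default_exposure_correlation(), 0, seed=1)
        assert list(df.columns) == list(MEANS)
        assert len(df) == 0

    def test_non_psd_matrix_rejected_with_eigenvalue(self):
        bad = default_exposure_correlation().copy()
        bad.loc["fruit", "vegetable"] = bad.loc["vegetable", "fruit"] = 0.99
        bad.loc["fruit", "fiber"] = bad.loc["fiber", "fruit"] = 0.99
        bad.loc["vegetable", "fiber"] = bad.loc["fiber", "vegetable"] = -0.9
        with pytest.raises(ValueError, match="eigenvalue"):
            generate_exposures(_spec(), bad, 10, seed=1)

    def test_coarse_exposure_emitted_as_categories(self):
        spec = _spec(n_exposure_categories={"fiber": 3})
        df = generate_exposures(spec, default_exposure_correlation(), 5000, seed=4)
        assert set(df["fiber"].unique()) == {1.0, 2.0, 3.0}
        # equal-probability bins
        assert df["fiber"].value_counts(normalize=True).max() < 0.40


class TestGenerateDosages:
    def test_hardy_weinberg_proportions_at_quarter_frequency(self):
        spec = _spec(n_cases=25_000, n_controls=25_000,
                     allele_freq={f"snp_{i + 1:06d}": 0.25 for i in range(3)})
        panel = generate_dosages(spec, 3, imputed_fraction=0.0, r2=1.0, seed=5)
        g = panel.dosages
        props = [(g == k).mean(axis=1) for k in (0, 1, 2)]
        assert np.allclose(props[0], 0.5625, atol=0.01)
        assert np.allclose(props[1], 0.375, atol=0.01)
        assert np.allclose(props[2], 0.0625, atol=0.01)

    def test_perfect_imputation_equals_hard_calls(self):
        spec = _spec()
        panel = generate_dosages(spec, 20, imputed_fraction=1.0, r2=1.0, seed=6)
        assert np.array_equal(panel.dosages, panel.truth)

    def test_imputation_noise_calibrated_to_target_r2(self):
        spec = _spec(n_cases=10_000, n_controls=10_000)
        for target in (0.5, 0.9):
            panel = generate_dosages(spec, 12, imputed_fraction=1.0, r2=target, seed=7)
            r2 = [
                np.corrcoef(panel.dosages[i], panel.truth[i])[0, 1] ** 2
                for i in range(panel.n_snps)
            ]
            assert np.mean(r2) == pytest.approx(target, abs=0.05)

    def test_dosages_stay_in_range(self):
        panel = generate_dosages(_spec(), 30, imputed_fraction=0.5, r2=0.6, seed=8)
        assert panel.dosages.min() >= 0.0 and panel.dosages.max() <= 2.0

    def test_invalid_allele_frequency_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 0.5\]"):
            generate_dosages(
                _spec(), 3, 0.0, 1.0, seed=1,
                freqs=np.array([0.2, 0.7, 0.1]),
            )

    def test_positions_strictly_increasing_within_chromosome(self):
        meta = snp_metadata(500)
        for _, grp in meta.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
            assert grp["pos"].nunique() == len(grp)


class TestGenerateConsortium:
    def test_exact_case_control_counts(self, small_consortium):
        cfg, studies = small_consortium
        for spec, (ds, panel) in zip(cfg.studies, studies):
            assert ds.n_cases == spec.n_cases
            assert ds.n_controls == spec.n_controls
            assert panel.n_subjects == spec.n_total

    def test_deterministic_given_seed(self):
        cfg1 = default_consortium(n_snps=10, seed=99, scale=0.05)
        cfg2 = default_consortium(n_snps=10, seed=99, scale=0.05)
        (ds1, p1), (ds2, p2) = generate_consortium(cfg1)[0], generate_consortium(cfg2)[0]
        pd.testing.assert_frame_equal(ds1.phenotypes, ds2.phenotypes)
        assert np.array_equal(p1.dosages, p2.dosages)

    def test_null_model_exposures_balanced_between_cases_and_controls(self):
        from scipy import stats

        spec = StudySpec("n", 800, 800, exposure_means={"red_meat": 0.9},
                         exposure_sds={"red_meat": 0.55})
        cfg = GeneratorConfig(studies=[spec], exposures=("red_meat",),
                              n_snps=2, seed=21)
        ds, _ = generate_consortium(cfg)[0]
        cases = ds.phenotypes.loc[ds.phenotypes.case == 1, "red_meat"]
        ctrls = ds.phenotypes.loc[ds.phenotypes.case == 0, "red_meat"]
        assert stats.ks_2samp(cases, ctrls).pvalue > 0.001

    def test_study_specific_hit_frequency_respected(self, small_consortium):
        cfg, studies = small_consortium
        from gxediet.synthetic import hit_snp_id

        hit = hit_snp_id(cfg.n_snps)
        for spec, (ds, panel) in zip(cfg.studies, studies):
            i = panel.snps.index[panel.snps.snp_id == hit][0]
            want = spec.allele_freq[hit]
            # controls approximate the population under rare disease; cases
            # are enriched for the count allele by the planted interaction
            ctrl = ds.phenotypes["case"].to_numpy() == 0
            got = panel.truth[i][ctrl].mean() / 2
            se = math.sqrt(want * (1 - want) / (2 * ctrl.sum()))
            assert got == pytest.approx(want, abs=3 * se + 0.01)

    def test_oversized_request_fails_cleanly(self):
        spec = StudySpec("big", 10_000_000, 10, exposure_means={"red_meat": 1.0},
                         exposure_sds={"red_meat": 0.5})
        cfg = GeneratorConfig(studies=[spec], exposures=("red_meat",), n_snps=1, seed=1)
        with pytest.raises(RuntimeError, match="pool"):
            generate_consortium(cfg)
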