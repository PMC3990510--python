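"""Per-study models against closed-form oracles and simulation checks."""

import math

import numpy as np
import pandas as pd
import pytest

from gxediet.harmonize import harmonize_study
from gxediet.models import (
    case_only_test,
    fit_logistic,
    ge_correlation_test,
    gxe_interaction,
    stratified_by_genotype,
)
from gxediet.synthetic import hit_snp_id


def _two_by_two(n11, n10, n01, n00):
    """Outcome x exposure counts -> long-format frame."""
    rows = (
        [{"case": 1, "x": 1}] * n11
        + [{"case": 1, "x": 0}] * n10
        + [{"case": 0, "x": 1}] * n01
        + [{"case": 0, "x": 0}] * n00
    )
    return pd.DataFrame(rows)


class TestFitLogistic:
    def test_two_by_two_matches_closed_form_log_odds_ratio(self):
        d = _two_by_two(20, 80, 10, 90)
        res = fit_logistic(d, "case", ["x"])["x"]
        want = math.log((20 * 90) / (80 * 10))
        assert res.beta == pytest.approx(want, abs=1e-6)
        # Wald SE closed form: sqrt(sum of reciprocal cell counts)
        assert res.se == pytest.approx(
            math.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90), abs=1e-6
        )
        assert res.z == pytest.approx(res.beta / res.se, abs=1e-8)

    def test_allele_relabel_flips_effect_sign(self, rng):
        g = rng.binomial(2, 0.3, 600).astype(float)
        y = (rng.random(600) < 0.3 + 0.1 * (g / 2)).astype(int)
        d = pd.DataFrame({"case": y, "g": g, "g_flip": 2 - g})
        b1 = fit_logistic(d, "case", ["g"])["g"].beta
        b2 = fit_logistic(d, "case", ["g_flip"])["g_flip"].beta
        assert b1 == pytest.approx(-b2, abs=1e-8)

    def test_null_p_values_approximately_uniform(self, rng):
        ps = []
        for _ in range(200):
            d = pd.DataFrame(
                {"case": rng.integers(0, 2, 300), "x": rng.standard_normal(300)}
            )
            ps.append(fit_logistic(d, "case", ["x"])["x"].p)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_collinear_term_reported_not_estimable(self, rng):
        x = rng.standard_normal(200)
        d = pd.DataFrame(
            {"case": rng.integers(0, 2, 200), "x": x, "x2": 2.0 * x}
        )
        res = fit_logistic(d, "case", ["x", "x2"])
        assert res["x"].converged
        assert not res["x2"].converged
        assert "NOT_ESTIMABLE" in res["x2"].flags

    def test_single_class_outcome_rejected(self):
        d = pd.DataFrame({"case": [1, 1, 1], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(d, "case", ["x"])


def _interaction_population(rng, n, beta_ge, beta_g=0.05, beta_e=0.1, freq=0.3):
    """Population draw under the multiplicative interaction model.

    The intercept keeps the disease rare in every (G, E) cell so the
    case-only estimand matches the planted interaction.
    """
    from scipy.special import expit

    g = rng.binomial(2, freq, n).astype(float)
    e = rng.integers(1, 5, n).astype(float)
    eta = -5.0 + beta_g * g + beta_e * e + beta_ge * g * e
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame({"case": y, "G": g, "E_q": e})


class TestGxeInteraction:
    def test_binary_collapse_matches_difference_of_stratum_log_odds_ratios(self):
        # binary G, binary E (codes 1/2), no covariates: the interaction
        # coefficient equals the difference of the two stratum log-ORs
        rows = []
        counts = {
            (1, 1, 1): 30, (1, 1, 0): 70, (1, 0, 1): 40, (1, 0, 0): 160,
            (0, 1, 1): 25, (0, 1, 0): 75, (0, 0, 1): 35, (0, 0, 0): 65,
        }
        for (y, g, e), k in counts.items():
            rows += [{"case": y, "G": g, "E_q": e + 1}] * k
        d = pd.DataFrame(rows)

        def log_or(sub):
            a = len(sub[(sub.case == 1) & (sub.E_q == 2)])
            b = len(sub[(sub.case == 1) & (sub.E_q == 1)])
            c = len(sub[(sub.case == 0) & (sub.E_q == 2)])
            e_ = len(sub[(sub.case == 0) & (sub.E_q == 1)])
            return math.log(a * e_ / (b * c))

        want = log_or(d[d.G == 1]) - log_or(d[d.G == 0])
        res = fit_logistic(d.assign(GxE=d.G * d.E_q), "case", ["G", "E_q", "GxE"])
        assert res["GxE"].beta == pytest.approx(want, abs=1e-6)

    def test_monomorphic_snp_not_estimable(self):
        from gxediet.types import StudyDataset

        pheno = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(40)],
                "case": [0, 1] * 20,
                "age": 60.0,
                "sex": [0, 1] * 20,
                "pc1": 0.0, "pc2": 0.0, "pc3": 0.0,
                "red_meat_q": list(np.tile([1, 2, 3, 4], 10)),
            }
        )
        ds = StudyDataset("t", pheno, energy_available=False)
        res = gxe_interaction(ds, np.zeros(40), "snpX", "red_meat")
        assert not res.converged
        assert "NOT_ESTIMABLE" in res.flags


class TestCaseOnly:
    def test_case_only_recovers_interaction_and_beats_case_control_variance(self, rng):
        from gxediet.types import StudyDataset

        beta_ge = math.log(1.25)
        co_est, cc_est, co_se, cc_se = [], [], [], []
        for _ in range(30):
            d = _interaction_population(rng, 200_000, beta_ge)
            cases = d[d.case == 1]
            ctrls = d[d.case == 0].sample(n=len(cases), random_state=1)
            samp = pd.concat([cases, ctrls]).reset_index(drop=True)
            samp["subject_id"] = [f"s{i}" for i in range(len(samp))]
            samp["age"] = 60.0
            samp["sex"] = 0
            ds = StudyDataset("t", samp, energy_available=False)
            co = case_only_test(ds, samp["G"].to_numpy(), "s", "E",
                                covariates=())
            cc = gxe_interaction(ds, samp["G"].to_numpy(), "s", "E",
                                 covariates=())
            co_est.append(co.beta)
            cc_est.append(cc.beta)
            co_se.append(co.se)
            cc_se.append(cc.se)
        mc_se = np.std(co_est, ddof=1) / math.sqrt(len(co_est))
        assert np.mean(co_est) == pytest.approx(beta_ge, abs=3 * mc_se + 0.02)
        # efficiency gain of the case-only test under G-E independence
        assert np.mean(co_se) < np.mean(cc_se)

    def test_case_only_biased_when_ge_independence_fails(self, rng):
        from scipy.special import expit
        from gxediet.types import StudyDataset

        # E directly shifts allele frequency: G-E correlation in the source
        # population, no interaction at all
        n = 80_000
        e = rng.integers(1, 5, n).astype(float)
        freq = np.clip(0.2 + 0.05 * (e - 2.5), 0.05, 0.5)
        g = rng.binomial(2, freq).astype(float)
        y = (rng.random(n) < expit(-3.0 + 0.1 * e)).astype(int)
        d = pd.DataFrame({"case": y, "G": g, "E_q": e})
        d["subject_id"] = [f"s{i}" for i in range(n)]
        d["age"], d["sex"] = 60.0, 0
        ds = StudyDataset("t", d, energy_available=False)
        co = case_only_test(ds, d["G"].to_numpy(), "s", "E", covariates=())
        assert co.p < 1e-6  # detects the G-E association, not interaction

    def test_low_case_count_flagged(self, rng):
        from gxediet.types import StudyDataset

        d = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(60)],
                "case": [1] * 30 + [0] * 30,
                "age": 60.0, "sex": 0,
                "E_q": list(np.tile([1, 2, 3, 4], 15)),
            }
        )
        ds = StudyDataset("t", d, energy_available=False)
        g = rng.binomial(2, 0.3, 60).astype(float)
        res = case_only_test(ds, g, "s", "E", covariates=())
        assert "LOW_N" in res.flags


class TestGeCorrelation:
    def test_null_z_standard_normal_over_replicates(self, rng):
        from gxediet.types import StudyDataset

        zs = []
        for _ in range(150):
            n = 400
            d = pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(n)],
                    "case": rng.integers(0, 2, n),
                    "age": 60.0, "sex": 0,
                    "E_q": rng.integers(1, 5, n).astype(float),
                }
            )
            ds = StudyDataset("t", d, energy_available=False)
            g = rng.binomial(2, 0.3, n).astype(float)
            zs.append(ge_correlation_test(ds, g, "s", "E", covariates=()).z)
        assert np.mean(zs) == pytest.approx(0.0, abs=0.2)
        assert np.var(zs) == pytest.approx(1.0, abs=0.35)

    def test_planted_latent_correlation_detected(self, rng):
        from gxediet.types import StudyDataset

        n = 10_000
        e = rng.integers(1, 5, n).astype(float)
        freq = np.clip(0.25 + 0.03 * (e - 2.5), 0.05, 0.5)
        g = rng.binomial(2, freq).astype(float)
        d = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "case": rng.integers(0, 2, n), "age": 60.0, "sex": 0,
                "E_q": e,
            }
        )
        ds = StudyDataset("t", d, energy_available=False)
        assert ge_correlation_test(ds, g, "s", "E", covariates=()).p < 0.001


class TestStratifiedByGenotype:
    def test_stratum_pattern_with_planted_interaction(self, harmonized_consortium):
        from gxediet.meta import fixed_effects_meta

        cfg, studies = harmonized_consortium
        hit = hit_snp_id(cfg.n_snps)
        per_stratum = {0: [], 1: [], 2: []}
        for ds, panel in studies:
            i = panel.snps.index[panel.snps.snp_id == hit][0]
            for r in stratified_by_genotype(
                ds, panel.dosages[i], hit, "processed_meat"
            ):
                if r.converged:
                    per_stratum[int(r.model[-1])].append(r)
        ors = {
            g: math.exp(fixed_effects_meta(v).beta) for g, v in per_stratum.items() if v
        }
        # per-allele interaction: monotone increase across genotype strata
        assert ors[0] < ors[1] < ors[2]

    def test_stratum_counts_conserve_subjects(self, harmonized_consortium):
        cfg, studies = harmonized_consortium
        ds, panel = studies[0]
        hit = hit_snp_id(cfg.n_snps)
        i = panel.snps.index[panel.snps.snp_id == hit][0]
        res = stratified_by_genotype(ds, panel.dosages[i], hit, "processed_meat")
        assert sum(r.n_used for r in res) == len(ds.phenotypes)
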