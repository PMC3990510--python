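"""Two-step scan mechanics: screening, pruning, weighted groups, testing."""

import math

import numpy as np
import pandas as pd
import pytest

from gxediet.cocktail import (
    assign_weight_groups,
    cocktail_scan,
    conventional_scan,
    hybrid_test,
    prune_by_proximity,
    screen_statistics,
)
from gxediet.synthetic import generate_consortium, hit_snp_id
from gxediet.types import GeneratorConfig, StudySpec, TrueEffects, WeightScheme


def _meta_frame(ids, z):
    return pd.DataFrame({"snp_id": ids, "z": z})


def _info(ids, chrom=None, pos=None):
    n = len(ids)
    return pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chrom or ["1"] * n,
            "pos": pos or list(range(1_000_000, 1_000_000 + n * 200_000, 200_000)),
        }
    )


class TestScreenStatistics:
    def test_max_statistic_and_winner(self):
        rec = screen_statistics(
            _meta_frame(["a"], [3.0]), _meta_frame(["a"], [-1.2]), _info(["a"])
        )
        assert rec.screen_stat[0] == 3.0
        assert rec.screen_winner[0] == "marginal"

    def test_tie_goes_to_marginal(self):
        rec = screen_statistics(
            _meta_frame(["a"], [-2.0]), _meta_frame(["a"], [2.0]), _info(["a"])
        )
        assert rec.screen_winner[0] == "marginal"

    def test_mismatched_snp_sets_reported(self):
        rec = screen_statistics(
            _meta_frame(["a", "b"], [1.0, 2.0]),
            _meta_frame(["b", "c"], [0.5, 0.7]),
            _info(["a", "b", "c"]),
        )
        assert list(rec.snp_id) == ["b"]
        assert rec.attrs["excluded"]["marginal_only"] == ["a"]
        assert rec.attrs["excluded"]["correlation_only"] == ["c"]


class TestPruneByProximity:
    def _rec(self, pos, stats, chrom=None):
        n = len(pos)
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "chrom": chrom or ["1"] * n,
                "pos": pos,
                "screen_stat": stats,
                "screen_winner": ["marginal"] * n,
                "z_marginal": stats,
                "z_correlation": [0.0] * n,
            }
        )

    def test_close_neighbour_pruned(self):
        out = prune_by_proximity(self._rec([100_000, 110_000], [5.0, 4.0]))
        by_id = out.set_index("snp_id")
        assert not by_id.loc["s0", "pruned"]
        assert by_id.loc["s1", "pruned"]

    def test_sixty_kb_apart_both_retained(self):
        out = prune_by_proximity(self._rec([100_000, 160_000], [5.0, 4.0]))
        assert not out.pruned.any()

    def test_same_position_different_chromosomes_retained(self):
        out = prune_by_proximity(
            self._rec([100_000, 100_000], [5.0, 4.0], chrom=["1", "2"])
        )
        assert not out.pruned.any()

    def test_result_independent_of_input_order(self, rng):
        rec = self._rec(
            list(rng.choice(np.arange(1, 300) * 20_000, 40, replace=False)),
            list(rng.uniform(0, 6, 40)),
        )
        a = prune_by_proximity(rec).set_index("snp_id")["pruned"]
        b = prune_by_proximity(rec.sample(frac=1, random_state=3)).set_index(
            "snp_id"
        )["pruned"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_chain_pruning_is_greedy_not_transitive(self):
        # middle SNP is pruned by the best; the far SNP survives because it
        # is only within the window of the (already pruned) middle one
        out = prune_by_proximity(
            self._rec([100_000, 140_000, 180_000], [5.0, 4.0, 3.0])
        ).set_index("snp_id")
        assert list(out["pruned"]) == [False, True, False]


class TestWeightScheme:
    def test_published_group_cutoffs(self):
        s = WeightScheme(alpha_total=0.05)
        assert s.alpha_for_rank(3) == pytest.approx(0.005)
        assert s.alpha_for_rank(10) == pytest.approx(0.00125)
        assert s.alpha_for_rank(20) == pytest.approx(0.0003125)

    def test_group_boundaries(self):
        # doubling sizes 5, 10, 20 put the group edges at ranks 5, 15, 35
        s = WeightScheme()
        assert s.group_of_rank(5) == 1
        assert s.group_of_rank(6) == 2
        assert s.group_of_rank(15) == 2
        assert s.group_of_rank(16) == 3
        assert s.group_of_rank(35) == 3
        assert s.group_of_rank(36) == 4

    def test_alpha_budget_geometric(self):
        s = WeightScheme(alpha_total=0.05)
        # each group spends exactly alpha / 2^j
        for j in range(1, 20):
            assert s.group_size(j) * s.group_alpha(j) == pytest.approx(
                0.05 / 2**j, rel=1e-12
            )
        assert s.realized_budget(10_000) < 0.05
        assert s.realized_budget(10**9) == pytest.approx(0.05, abs=1e-6)

    def test_assignment_on_records(self):
        rec = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(40)],
                "chrom": "1",
                "pos": np.arange(40) * 200_000,
                "screen_stat": np.linspace(6, 1, 40),
                "pruned": [False] * 40,
            }
        )
        out = assign_weight_groups(rec, WeightScheme())
        assert out.loc[out["rank"] == 1, "alpha_cutoff"].iloc[0] == 0.005
        assert out.loc[out["rank"] == 16, "group_index"].iloc[0] == 3
        assert out.loc[out["rank"] == 37, "group_index"].iloc[0] == 4


class TestHybridTest:
    def _records(self):
        return pd.DataFrame(
            {
                "snp_id": ["a", "b", "c"],
                "chrom": "1",
                "pos": [1, 300_000, 600_000],
                "screen_stat": [4.0, 3.0, 2.0],
                "screen_winner": ["marginal", "correlation", "marginal"],
                "pruned": [False, False, False],
                "rank": [1, 2, 3],
                "group_index": [1, 1, 1],
                "alpha_cutoff": [0.005, 0.005, 0.005],
            }
        )

    def test_winner_selects_test(self):
        co = pd.Series([1e-4, 0.5, 0.9], index=["a", "b", "c"])
        cc = pd.Series([0.2, 1e-4, 0.8], index=["a", "b", "c"])
        out = hybrid_test(self._records(), co, cc).set_index("snp_id")
        assert out.loc["a", "chosen_test"] == "CO"
        assert out.loc["a", "p_test"] == 1e-4
        assert out.loc["b", "chosen_test"] == "CC"
        assert out.loc["b", "p_test"] == 1e-4
        assert bool(out.loc["a", "significant"]) and bool(out.loc["b", "significant"])

    def test_boundary_p_exactly_at_cutoff_not_significant(self):
        co = pd.Series([0.005, 0.5, 0.9], index=["a", "b", "c"])
        cc = pd.Series([0.5, 0.5, 0.5], index=["a", "b", "c"])
        out = hybrid_test(self._records(), co, cc).set_index("snp_id")
        assert not out.loc["a", "significant"]

    def test_missing_chosen_test_falls_back_with_flag(self):
        co = pd.Series([np.nan, 0.5, 0.9], index=["a", "b", "c"])
        cc = pd.Series([1e-5, 0.5, 0.5], index=["a", "b", "c"])
        out = hybrid_test(self._records(), co, cc).set_index("snp_id")
        assert out.loc["a", "chosen_test"] == "CC"
        assert out.loc["a", "test_flag"] == "FALLBACK"
        assert bool(out.loc["a", "significant"])


class TestCocktailScan:
    def test_planted_hit_detected_where_conventional_threshold_misses(self):
        # strong marginal + interaction effect at a modest sample size:
        # screening ranks the SNP first (cutoff 0.005), far above what the
        # genome-wide 5e-8 threshold can see at this n
        hit = hit_snp_id(30)
        specs = [
            StudySpec(
                f"s{i}", 500, 500,
                exposure_means={"processed_meat": 0.55},
                exposure_sds={"processed_meat": 0.4},
                allele_freq={hit: 0.3},
            )
            for i in range(4)
        ]
        cfg = GeneratorConfig(
            studies=specs, exposures=("processed_meat",), n_snps=30,
            imputed_fraction=0.0, seed=4242,
            true_effects=TrueEffects(
                beta_g={hit: math.log(1.4)},
                beta_ge={(hit, "processed_meat"): math.log(1.25)},
            ),
        )
        data = generate_consortium(cfg)
        rec, summary = cocktail_scan(data, "processed_meat")
        row = rec.set_index("snp_id").loc[hit]
        assert row["rank"] == 1
        assert row["significant"]
        cc = conventional_scan(data, "processed_meat").set_index("snp_id")
        assert not cc.loc[hit, "significant"]
        assert cc.loc[hit, "p"] < 0.005  # real signal, wrong threshold

    def test_deterministic_given_inputs(self, null_pair):
        _, studies = null_pair
        rec1, _ = cocktail_scan(studies, "processed_meat")
        rec2, _ = cocktail_scan(studies, "processed_meat")
        pd.testing.assert_frame_equal(rec1, rec2)

    def test_no_qc_passing_snps_exits_cleanly(self, null_pair):
        import copy

        _, studies = null_pair
        studies2 = []
        for ds, panel in studies:
            p2 = copy.deepcopy(panel)
            p2.snps["qc_pass"] = False
            p2.snps["qc_reasons"] = "MAC"
            studies2.append((ds, p2))
        rec, summary = cocktail_scan(studies2, "processed_meat")
        assert summary["n_significant"] == 0
        assert summary["n_retained"] == 0

    def test_summary_budget_never_exceeds_alpha(self, null_pair):
        _, studies = null_pair
        _, summary = cocktail_scan(studies, "processed_meat")
        assert summary["realized_budget"] <= summary["alpha_total"] + 1e-12


class TestLdProxy:
    def test_proxy_signal_attenuated_and_pruned(self):
        """A +/-10 kb LD proxy (r2=0.8) of the hit shows a correlated but
        weaker interaction signal, appears in the regional window, and is
        pruned by the scan's proximity rule."""
        from gxediet.harmonize import harmonize_study
        from gxediet.pipeline import regional_table
        from gxediet.synthetic import add_ld_proxy, default_consortium, generate_consortium

        cfg = default_consortium(n_snps=30, seed=919, scale=0.6)
        studies = generate_consortium(cfg)
        hit = hit_snp_id(30)
        proxy = "snp_000001"
        add_ld_proxy(studies, hit, proxy, r2=0.8, seed=5)
        for ds, _ in studies:
            harmonize_study(ds, ["processed_meat"])

        cc = conventional_scan(studies, "processed_meat").set_index("snp_id")
        z_hit, z_prox = abs(cc.loc[hit, "z"]), abs(cc.loc[proxy, "z"])
        assert z_hit > 3.0
        assert 0.3 * z_hit < z_prox < z_hit  # attenuated but correlated

        region = regional_table(cc.reset_index(), hit, window=50_000)
        assert set(region["snp_id"]) == {hit, proxy}
        assert region.loc[region.snp_id == proxy, "distance_bp"].iloc[0] == 10_000

        rec, _ = cocktail_scan(studies, "processed_meat")
        by_id = rec.set_index("snp_id")
        assert by_id.loc[proxy, "pruned"] or by_id.loc[hit, "pruned"]
        assert not (by_id.loc[proxy, "pruned"] and by_id.loc[hit, "pruned"])
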