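"""Burden / SKAT / SKAT-O statistics, their oracles and the reconstruction utility."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from melvar.aggregation import (
    AggregationConfig,
    GenotypeMatrix,
    MonomorphicVariantError,
    ReconstructionError,
    ReconstructionPolicy,
    aggregate,
    beta_maf_weights,
    burden_test,
    fit_null_binary,
    permutation_pvalue,
    permutation_reference,
    reconstruct_from_counts,
    skat_test,
    skato_test,
)
from melvar.screen import CarrierCell, CarrierTable
from tests.conftest import AGGREGATION_GENES, TABLE1


def case_control_instance(seed, mafs, n_case, n_ctrl, enrichment=1.0):
    """Fixed-seed case/control genotype draw with every column polymorphic."""
    rng = np.random.default_rng(seed)
    mafs = np.asarray(mafs)
    while True:
        Gc = rng.binomial(2, np.minimum(mafs * enrichment, 0.5), size=(n_case, len(mafs)))
        G0 = rng.binomial(2, mafs, size=(n_ctrl, len(mafs)))
        G = np.vstack([Gc, G0]).astype(float)
        if (G.var(axis=0) > 0).all():
            break
    y = np.r_[np.ones(n_case), np.zeros(n_ctrl)]
    return GenotypeMatrix(G), y


@pytest.fixture(scope="module")
def table1_counts_table() -> CarrierTable:
    """Summary-level carrier counts of the seven aggregation-set variants."""
    table = CarrierTable(groups=("MPM", "CONTROL"))
    for i, (gene, _c, _p, chrom, mpm, _idx, ctl, _pct) in enumerate(TABLE1):
        if gene not in AGGREGATION_GENES:
            continue
        key = (chrom, 1000 + i, "A", "G")
        table.rows[key] = {
            "MPM": CarrierCell.from_counts(*mpm),
            "CONTROL": CarrierCell.from_counts(*ctl),
        }
    return table


class TestWeightsAndNull:
    def test_beta_weights_limits_and_closed_form(self):
        assert beta_maf_weights([1e-9])[0] == pytest.approx(25.0, rel=1e-6)
        assert beta_maf_weights([0.5], a=1, b=1)[0] == pytest.approx(1.0)
        assert beta_maf_weights([0.1])[0] == pytest.approx(25 * 0.9 ** 24, rel=1e-12)

    def test_weights_decrease_with_maf_under_default(self):
        w = beta_maf_weights(np.linspace(0.001, 0.5, 50))
        assert np.all(np.diff(w) < 0)

    def test_monomorphic_maf_rejected(self):
        with pytest.raises(MonomorphicVariantError):
            beta_maf_weights([0.1, 0.0])

    def test_null_model_mean_and_variance(self):
        y = np.r_[np.ones(26), np.zeros(100)]
        null = fit_null_binary(y)
        assert null.mu == pytest.approx(26 / 126)
        assert null.variance == pytest.approx(null.mu * (1 - null.mu))
        with pytest.raises(ValueError, match="classes"):
            fit_null_binary(np.ones(10))


class TestBurden:
    def test_single_carrier_variant_matches_pearson_chi_square(self):
        # m=1, unit weight, 0/1 genotypes: the score test equals the Pearson
        # chi-square on the 2x2 carrier-by-status table
        rng = np.random.default_rng(4)
        g = (rng.random(150) < 0.2).astype(float)
        g[0] = 1.0
        y = np.r_[np.ones(40), np.zeros(110)]
        res = burden_test(g[:, None], y, [1.0])
        table = np.array(
            [
                [np.sum((g == 1) & (y == 1)), np.sum((g == 0) & (y == 1))],
                [np.sum((g == 1) & (y == 0)), np.sum((g == 0) & (y == 0))],
            ]
        )
        expected = chi2_contingency(table, correction=False)[1]
        assert res.p == pytest.approx(expected, rel=1e-12)

    def test_degenerate_burden_reports_p_one(self, caplog):
        G = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        y = np.array([1.0, 1.0, 0.0, 0.0])
        with caplog.at_level("WARNING"):
            res = burden_test(G, y, [1.0, 1.0])  # b_i = 1 for every sample
        assert res.p == 1.0
        assert res.method == "degenerate"

    def test_monomorphic_column_rejected(self):
        G = np.zeros((10, 1))
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(MonomorphicVariantError):
            burden_test(G, y, [1.0])

    def test_asymptotic_matches_permutation_oracle(self):
        Gm, y = case_control_instance(8, [0.25, 0.15, 0.2], 50, 100, enrichment=1.4)
        w = beta_maf_weights(Gm.maf)
        res = burden_test(Gm, y, w)
        B = 10_000
        p_perm = permutation_pvalue(
            lambda G, yy: burden_test(G, yy, w).Q / 1.0, Gm, y,
            n_permutations=B, seed=2,
        )
        se = np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(res.p - p_perm) < 3 * se


class TestSkat:
    def test_single_variant_collapses_to_burden(self):
        Gm, y = case_control_instance(5, [0.2], 40, 80)
        w = np.array([3.7])
        bur = burden_test(Gm, y, w)
        ska = skat_test(Gm, y, w)
        assert ska.Q == pytest.approx(bur.Q * w[0] ** 2 / w[0] ** 2)
        # identical p to at least 10 significant digits
        assert ska.p == pytest.approx(bur.p, rel=1e-10)

    def test_davies_p_matches_mixture_simulation(self):
        Gm, y = case_control_instance(12, [0.1, 0.05, 0.2, 0.08, 0.15], 30, 30)
        w = beta_maf_weights(Gm.maf)
        res = skat_test(Gm, y, w)
        rng = np.random.default_rng(99)
        draws = rng.chisquare(1, size=(1_000_000, len(res.lambdas))) @ res.lambdas
        p_mc = float((draws > res.Q).mean())
        se = max(np.sqrt(p_mc * (1 - p_mc) / 1_000_000), 1e-9)
        assert abs(res.p - p_mc) < 3 * se

    def test_permutation_method_is_reproducible(self):
        Gm, y = case_control_instance(5, [0.2, 0.3], 30, 60)
        w = beta_maf_weights(Gm.maf)
        p1 = skat_test(Gm, y, w, pvalue_method="permutation", n_permutations=500, seed=11).p
        p2 = skat_test(Gm, y, w, pvalue_method="permutation", n_permutations=500, seed=11).p
        assert p1 == p2


class TestSkatO:
    def test_endpoint_identities(self):
        Gm, y = case_control_instance(7, [0.3, 0.2, 0.25, 0.15], 60, 90, enrichment=1.3)
        w = beta_maf_weights(Gm.maf)
        bur = burden_test(Gm, y, w)
        ska = skat_test(Gm, y, w)
        assert skato_test(Gm, y, w, rho_grid=[1.0]).p == pytest.approx(bur.p, rel=1e-9)
        assert skato_test(Gm, y, w, rho_grid=[0.0]).p == pytest.approx(ska.p, rel=1e-9)

    def test_omnibus_bounded_by_best_component_and_bonferroni(self):
        Gm, y = case_control_instance(7, [0.3, 0.2, 0.25, 0.15], 60, 90, enrichment=1.3)
        w = beta_maf_weights(Gm.maf)
        res = skato_test(Gm, y, w)
        T = float(np.min(res.p_rho))
        assert T <= res.p <= min(1.0, T * len(res.rho_grid))

    def test_agrees_with_min_p_permutation_omnibus(self):
        # moderately significant fixed-seed instance; reference is the
        # assumption-free min-p omnibus over 1e5 label permutations
        Gm, y = case_control_instance(3, [0.3, 0.25, 0.2, 0.35, 0.15], 80, 120,
                                      enrichment=1.5)
        w = beta_maf_weights(Gm.maf)
        res = skato_test(Gm, y, w)
        B = 100_000
        ref = permutation_reference(Gm, y, w, n_permutations=B, seed=5)
        p_perm = ref["p_skato"]
        se = np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(res.p - p_perm) < 3 * se

    def test_grid_must_span_the_endpoints_in_config(self):
        with pytest.raises(ValueError):
            AggregationConfig(rho_grid=(0.0, 0.5))


class TestPermutation:
    def test_extreme_rank_gives_minimum_p(self):
        # a statistic that only the observed labelling can maximize
        Gm, y = case_control_instance(6, [0.2, 0.3], 20, 20)
        obs = {"first": True}

        def statistic(G, yy):
            if obs["first"]:
                obs["first"] = False
                return 1e9
            return 0.0

        p = permutation_pvalue(statistic, Gm, y, n_permutations=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_seed_reproducibility(self):
        Gm, y = case_control_instance(6, [0.2, 0.3], 20, 40)
        w = beta_maf_weights(Gm.maf)

        def stat(G, yy):
            return burden_test(G, yy, w).Q

        assert permutation_pvalue(stat, Gm, y, 300, seed=7) == permutation_pvalue(
            stat, Gm, y, 300, seed=7
        )

    def test_vectorized_reference_matches_generic_loop(self):
        Gm, y = case_control_instance(9, [0.25, 0.3, 0.2], 30, 50)
        w = beta_maf_weights(Gm.maf)
        B = 2_000
        ref = permutation_reference(Gm, y, w, n_permutations=B, seed=123)

        def stat(G, yy):
            mu = yy.mean()
            S = (yy - mu) @ (G * w)
            return float(np.sum(S) ** 2)

        p_loop = permutation_pvalue(stat, Gm, y, n_permutations=B, seed=42)
        se = np.sqrt(ref["p_burden"] * (1 - ref["p_burden"]) / B)
        assert abs(ref["p_burden"] - p_loop) < 4 * se


class TestGenotypeMatrix:
    def test_entries_validated_and_maf_folded(self):
        G = np.array([[0.0, 2.0], [1.0, 2.0], [2.0, 2.0], [1.0, 1.0]])
        gm = GenotypeMatrix(G)
        assert gm.maf[0] == pytest.approx(0.5)
        assert gm.maf[1] == pytest.approx(1 - 7 / 8)  # folded major-allele column
        with pytest.raises(ValueError):
            GenotypeMatrix(np.array([[0.5, 1.0], [1.0, 0.0]]))

    def test_imputation_fills_untyped_with_column_mean(self):
        G = np.array([[1.0, np.nan], [0.0, 2.0], [1.0, 0.0]])
        gm = GenotypeMatrix(G)
        X = gm.imputed()
        assert X[0, 1] == pytest.approx(1.0)
        assert not np.isnan(X).any()


class TestReconstruction:
    def test_case_block_has_exactly_one_carrier_per_row(self, table1_counts_table):
        Gm, y, log = reconstruct_from_counts(table1_counts_table)
        cases = Gm.G[y == 1]
        assert cases.shape == (26, 7)
        # carrier totals sum to the group size, so disjoint placement is exact
        np.testing.assert_array_equal(np.nansum(cases, axis=1), np.ones(26))
        col_sums = np.nansum(cases, axis=0)
        assert sorted(col_sums.tolist()) == sorted([4, 5, 3, 3, 3, 4, 4])

    def test_column_sums_reproduce_control_counts_with_padding(self, table1_counts_table):
        Gm, y, _ = reconstruct_from_counts(table1_counts_table)
        controls = Gm.G[y == 0]
        assert controls.shape == (200, 7)
        expected = {
            ("12", "NTN4"): (5, 200), ("18", "MTCL1"): (4, 100),
        }
        for j, key in enumerate(Gm.variant_keys):
            col = controls[:, j]
            typed = ~np.isnan(col)
            cell = table1_counts_table.rows[key]["CONTROL"]
            assert typed.sum() == cell.denominator
            assert np.nansum(col) == cell.carriers

    def test_round_trip_counts(self, table1_counts_table):
        Gm, y, _ = reconstruct_from_counts(table1_counts_table)
        for j, key in enumerate(Gm.variant_keys):
            for group, mask in (("MPM", y == 1), ("CONTROL", y == 0)):
                col = Gm.G[mask, j]
                cell = table1_counts_table.rows[key][group]
                assert int(np.nansum(col > 0)) == cell.carriers
                assert int(np.sum(~np.isnan(col))) == cell.denominator

    def test_infeasible_counts_rejected(self):
        table = CarrierTable(groups=("MPM", "CONTROL"))
        table.rows[("1", 1, "A", "G")] = {
            "MPM": CarrierCell.from_counts(3, 4),
            "CONTROL": CarrierCell.from_counts(0, 10),
        }
        table.rows[("1", 2, "A", "G")] = {
            "MPM": CarrierCell.from_counts(3, 4),
            "CONTROL": CarrierCell.from_counts(0, 10),
        }
        with pytest.raises(ReconstructionError, match="MPM"):
            reconstruct_from_counts(table)

    def test_scale_to_min_policy_rescales_and_logs(self, table1_counts_table):
        policy = ReconstructionPolicy(denominators="scale_to_min")
        Gm, y, log = reconstruct_from_counts(table1_counts_table, policy)
        assert Gm.G[y == 0].shape == (100, 7)
        assert not np.isnan(Gm.G).any()
        assert any("scaled" in line for line in log)


class TestAggregateFacade:
    def test_permutation_config_routes_all_three_tests(self):
        Gm, y = case_control_instance(2, [0.2, 0.3, 0.25], 30, 60)
        config = AggregationConfig(pvalue_method="permutation", n_permutations=500, seed=3)
        res = aggregate(Gm, y, config)
        assert res.method_burden == "permutation"
        assert 0 < res.p_skato <= 1

    def test_asymptotic_result_is_complete(self):
        Gm, y = case_control_instance(2, [0.2, 0.3, 0.25], 30, 60)
        res = aggregate(Gm, y)
        assert res.Q_burden >= 0 and res.Q_skat >= 0
        assert len(res.lambdas) >= 1
        for p in (res.p_burden, res.p_skat, res.p_skato):
            assert 0.0 <= p <= 1.0


class TestOracleEquivalence:
    """Asymptotic p-values track the label-permutation null on small cohorts."""

    @pytest.mark.parametrize("seed,n_case,n_ctrl", [(5, 60, 140), (14, 60, 140)])
    def test_burden_and_skat_within_monte_carlo_error(self, seed, n_case, n_ctrl):
        # balanced minor-allele fractions keep the Beta weights comparable, so
        # the mixture null is genuinely multivariate and the asymptotic
        # approximation holds through the rejection region
        Gm, y = case_control_instance(
            seed, [0.22, 0.2, 0.18, 0.25, 0.21], n_case, n_ctrl, enrichment=1.45
        )
        w = beta_maf_weights(Gm.maf)
        B = 10_000
        ref = permutation_reference(Gm, y, w, n_permutations=B, seed=6)
        bur = burden_test(Gm, y, w)
        ska = skat_test(Gm, y, w)
        for p_asym, p_perm in ((bur.p, ref["p_burden"]), (ska.p, ref["p_skat"])):
            se = max(np.sqrt(p_perm * (1 - p_perm) / B), 1e-6)
            assert abs(p_asym - p_perm) < 3 * se
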