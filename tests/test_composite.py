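import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from ldhotscan.composite import (
    HotspotModel,
    LikelihoodGrids,
    composite_loglik,
    estimate_rho_constant,
    lrt_statistic,
    pair_rho,
    rho_profile,
)
from ldhotscan.simulate import (
    HaplotypeMatrix,
    SimulationParams,
    build_hotspot_map,
    simulate_haplotypes,
)
from ldhotscan.twolocus import pair_config, pair_loglik

from conftest import FAST_RHO0, FAST_RHO1


class TestPairRho:
    def test_piecewise_integration_through_hotspot(self):
        m = HotspotModel(rho0=0.5, rho1=25.0, test_interval=(10_000, 12_000))
        assert pair_rho(m, 9_000, 13_000) == pytest.approx(0.5 * 1 + 25 * 2 + 0.5 * 1)

    def test_zero_distance(self):
        m = HotspotModel(0.5, 25.0, (10_000, 12_000))
        assert pair_rho(m, 5_000, 5_000) == 0.0

    def test_constant_rate(self):
        m = HotspotModel(0.5, 0.5, (10_000, 12_000))
        assert pair_rho(m, 0, 10_000) == pytest.approx(5.0)

    def test_map_positions_outside_region_rejected(self):
        rmap = build_hotspot_map(10_000, 0.5)
        with pytest.raises(ValueError):
            pair_rho(rmap, 5_000, 15_000)


class TestCompositeLoglik:
    def test_two_snps_equals_single_pair_term(self, table30, window_20kb):
        h2 = HaplotypeMatrix(
            window_20kb.positions[:2], window_20kb.alleles[:, :2], 20_000
        )
        model = HotspotModel(0.5, 5.0, (9_000, 11_000))
        cfg = pair_config(h2, 0, 1)
        rho = pair_rho(model, int(h2.positions[0]), int(h2.positions[1]))
        assert composite_loglik(h2, model, table30) == pytest.approx(
            pair_loglik(table30, cfg, rho)
        )

    def test_flat_hotspot_model_equals_constant(self, table30, window_20kb):
        model = HotspotModel(0.7, 0.7, (9_000, 11_000))
        assert composite_loglik(window_20kb, model, table30) == pytest.approx(
            composite_loglik(window_20kb, 0.7, table30)
        )

    def test_sum_over_pairs(self, table30, window_20kb):
        """The composite log-likelihood is the plain sum of pair terms."""
        h5 = HaplotypeMatrix(
            window_20kb.positions[:5], window_20kb.alleles[:, :5], 20_000
        )
        model = HotspotModel(0.5, 10.0, (9_000, 11_000))
        expected = sum(
            pair_loglik(
                table30,
                pair_config(h5, i, j),
                pair_rho(model, int(h5.positions[i]), int(h5.positions[j])),
            )
            for i in range(5)
            for j in range(i + 1, 5)
        )
        assert composite_loglik(h5, model, table30) == pytest.approx(expected)

    def test_insufficient_snps_rejected(self, table30):
        h1 = HaplotypeMatrix(
            np.array([100]), np.array([[0], [1], [0]] * 10, dtype=np.int8), 20_000
        )
        with pytest.raises(ValueError, match="insufficient"):
            composite_loglik(h1, 0.5, table30)


class TestEstimateRhoConstant:
    def test_equals_brute_force_grid_argmax(self, table30, window_20kb, hotspot_window_20kb):
        grid = FAST_RHO0
        for h in (window_20kb, hotspot_window_20kb):
            brute = max(
                ((composite_loglik(h, float(r), table30), -r) for r in grid),
            )
            assert estimate_rho_constant(h, table30, grid) == pytest.approx(-brute[1])

    def test_zero_recombination_estimates_at_grid_minimum(self, table30):
        """Strong-LD data (rho = 0) should mostly hit the smallest grid rate."""
        at_min = 0
        reps = 40
        rmap = build_hotspot_map(20_000, 0.0)
        for k in range(reps):
            h = simulate_haplotypes(SimulationParams(30, 1.0, 20_000, 900 + k), rmap)
            if h.num_sites < 2:
                continue
            if estimate_rho_constant(h, table30, FAST_RHO0) == FAST_RHO0[0]:
                at_min += 1
        assert at_min > reps / 2

    def test_tie_breaks_toward_smaller_rate(self, table30, window_20kb):
        # duplicated grid values produce exact loglik ties; the smaller
        # (first) rate must win, so the estimate matches the deduplicated grid
        est_dup = estimate_rho_constant(window_20kb, table30, (1.0, 0.5, 0.5, 0.2))
        est = estimate_rho_constant(window_20kb, table30, (0.2, 0.5, 1.0))
        assert est_dup == est


class TestLrtStatistic:
    def test_lambda_nonnegative(self, table30, window_20kb, hotspot_window_20kb, fast_grids):
        for h in (window_20kb, hotspot_window_20kb):
            res = lrt_statistic(h, (9_000, 11_000), table30, fast_grids)
            assert res.Lambda >= 0

    def test_lambda_zero_when_alternative_restricted_to_diagonal(
        self, table30, window_20kb, hotspot_window_20kb, fast_grids
    ):
        """With rho1 forced equal to rho0 the models coincide exactly."""
        for h in (window_20kb, hotspot_window_20kb):
            res = lrt_statistic(
                h, (9_000, 11_000), table30, fast_grids, constrain_equal_rates=True
            )
            assert res.Lambda == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_exhaustive_double_grid_enumeration(self, table30, window_20kb):
        h10 = HaplotypeMatrix(
            window_20kb.positions[:10], window_20kb.alleles[:, :10], 20_000
        )
        core = (int(h10.positions[3]), int(h10.positions[3]) + 2000)
        grids = LikelihoodGrids(
            const_grid=(0.0, 0.5, 1.0), rho0_grid=(0.0, 0.5, 1.0),
            rho1_grid=(0.0, 0.5, 1.0, 5.0, 25.0),
        )
        res = lrt_statistic(h10, core, table30, grids)
        best_alt = max(
            composite_loglik(h10, HotspotModel(r0, r1, core), table30)
            for r0 in grids.rho0_grid
            for r1 in grids.rho1_grid
        )
        best_const = max(
            composite_loglik(h10, float(r), table30) for r in grids.const_grid
        )
        assert res.Lambda == pytest.approx(2 * (best_alt - best_const))

    def test_invariant_under_allele_relabeling(self, table30, hotspot_window_20kb, fast_grids):
        h = hotspot_window_20kb
        flip = np.zeros(h.num_sites, dtype=np.int8)
        flip[::3] = 1  # relabel alleles at every third SNP
        h2 = HaplotypeMatrix(h.positions, h.alleles ^ flip, h.region_length)
        r1 = lrt_statistic(h, (9_000, 11_000), table30, fast_grids)
        r2 = lrt_statistic(h2, (9_000, 11_000), table30, fast_grids)
        assert r1.Lambda == pytest.approx(r2.Lambda)

    def test_invariant_under_coordinate_reversal(self, table30, hotspot_window_20kb, fast_grids):
        h = hotspot_window_20kb
        L = h.region_length
        rev_pos = (L - 1 - h.positions)[::-1]
        h2 = HaplotypeMatrix(rev_pos, h.alleles[:, ::-1], L)
        core = (9_000, 11_000)
        mirrored = (L - 1 - core[1], L - 1 - core[0])  # same axis as L-1-pos
        r1 = lrt_statistic(h, core, table30, fast_grids)
        r2 = lrt_statistic(h2, mirrored, table30, fast_grids)
        assert r1.Lambda == pytest.approx(r2.Lambda, rel=1e-6)

    def test_null_lambda_stochastically_below_hotspot_lambda(self, table30, fast_grids):
        """A 50-fold hotspot shifts the LRT distribution upward."""
        lam_null, lam_hot = [], []
        null_map = build_hotspot_map(20_000, 0.5)
        hot_map = build_hotspot_map(20_000, 0.5, [((9_000, 11_000), 25.0)])
        for k in range(30):
            hn = simulate_haplotypes(SimulationParams(30, 1.0, 20_000, 1500 + k), null_map)
            hh = simulate_haplotypes(SimulationParams(30, 1.0, 20_000, 2500 + k), hot_map)
            lam_null.append(lrt_statistic(hn, (9_000, 11_000), table30, fast_grids).Lambda)
            lam_hot.append(lrt_statistic(hh, (9_000, 11_000), table30, fast_grids).Lambda)
        p = mannwhitneyu(lam_hot, lam_null, alternative="greater").pvalue
        assert p < 0.01


class TestRhoProfile:
    def test_profile_length(self, table30, window_20kb, fast_grids):
        prof = rho_profile(window_20kb, table30, fast_grids)
        assert len(prof) == 20

    def test_hotspot_elevates_profile(self, table30, fast_grids):
        """A 50-fold (25/kb) hotspot pushes the profile over 5/kb at its
        tiles in most replicates; constant-rate data does so at a much
        lower rate.  The profiled-argmax estimator has a heavy upper
        tail, so its null exceedance of the 5/kb threshold is ~10%
        (measured over 40 regions); the bound here allows for that plus
        sampling noise at this replicate count."""
        hot_hits = 0
        null_high = []
        rmap_hot = build_hotspot_map(40_000, 0.5, [((19_000, 21_000), 25.0)])
        rmap_null = build_hotspot_map(40_000, 0.5)
        reps = 20
        for k in range(reps):
            hh = simulate_haplotypes(SimulationParams(30, 1.0, 40_000, 3100 + k), rmap_hot)
            hn = simulate_haplotypes(SimulationParams(30, 1.0, 40_000, 4100 + k), rmap_null)
            ph = rho_profile(hh, table30, fast_grids)
            pn = rho_profile(hn, table30, fast_grids)
            hot_hits += ph[19:21].max() >= 5.0
            null_high.append(np.mean(pn >= 5.0))
        assert hot_hits > reps / 2
        assert np.mean(null_high) < 0.20
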