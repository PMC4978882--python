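import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msprime

from ldhotscan._seeds import derive_rng, derive_seed
from ldhotscan.simulate import HaplotypeMatrix
from ldhotscan.twolocus import (
    PairConfig,
    TwoLocusTable,
    _sample_branch_split,
    build_two_locus_table,
    canonicalize,
    pair_config,
    pair_loglik,
)


def toy_matrix(rows: list[str]) -> HaplotypeMatrix:
    """Haplotype matrix from one 0/1 string per haplotype."""
    alleles = np.array([[int(c) for c in r] for r in rows], dtype=np.int8)
    S = alleles.shape[1]
    pos = np.arange(S) * 100 + 50
    return HaplotypeMatrix(pos, alleles, region_length=S * 100 + 100)


class TestCanonicalization:
    def test_perfect_ld_form(self):
        assert canonicalize(15, 0, 0, 15) == PairConfig(15, 0, 0, 15)

    def test_pair_config_perfect_ld(self):
        h = HaplotypeMatrix(
            np.array([10, 20]),
            np.repeat([[0, 0], [1, 1]], [15, 15], axis=0).astype(np.int8),
            1000,
        )
        assert pair_config(h, 0, 1) == PairConfig(15, 0, 0, 15)

    def test_allele_flip_invariance(self):
        h = toy_matrix(["01", "00", "11", "10", "01", "11"])
        flipped = HaplotypeMatrix(h.positions, h.alleles ^ np.array([0, 1], dtype=np.int8), h.region_length)
        assert pair_config(h, 0, 1) == pair_config(flipped, 0, 1)

    def test_locus_exchange_invariance(self):
        h = toy_matrix(["01", "00", "11", "10", "01", "11"])
        swapped = HaplotypeMatrix(h.positions, h.alleles[:, ::-1], h.region_length)
        assert pair_config(h, 0, 1) == pair_config(swapped, 0, 1)

    def test_monomorphic_column_rejected(self):
        alleles = np.array([[0, 0], [0, 1], [0, 1]], dtype=np.int8)
        h = HaplotypeMatrix.__new__(HaplotypeMatrix)
        object.__setattr__(h, "positions", np.array([10, 20]))
        object.__setattr__(h, "alleles", alleles)
        object.__setattr__(h, "region_length", 100)
        with pytest.raises(ValueError, match="monomorphic"):
            pair_config(h, 0, 1)

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10)))
    def test_canonical_fixed_point_and_symmetry(self, counts):
        c = canonicalize(*counts)
        assert canonicalize(*c) == c  # fixed point
        c00, c01, c10, c11 = counts
        assert canonicalize(c01, c00, c11, c10) == c  # allele flip, locus 2
        assert canonicalize(c10, c11, c00, c01) == c  # allele flip, locus 1
        assert canonicalize(c00, c10, c01, c11) == c  # locus exchange


class TestTableBuild:
    def test_four_gamete_impossible_at_rho_zero(self, table30):
        """theta->0 on a single genealogy cannot produce all four gametes."""
        col0 = table30.logp[:, 0]
        for k, cfg in enumerate(table30.configs):
            if min(cfg) > 0:  # all four gametes present
                assert col0[k] == pytest.approx(table30.floor_logp)

    def test_columns_normalized(self, table30):
        """Observed (non-floor) probability mass in each column is exactly 1."""
        for g in range(len(table30.rho_grid)):
            col = table30.logp[:, g]
            obs = np.exp(col[col > table30.floor_logp + 1e-9]).sum()
            assert obs == pytest.approx(1.0, abs=1e-9)

    def test_rebuild_same_seed_bit_exact(self):
        t1 = build_two_locus_table(n=8, rho_grid=(0, 5, 50), reps=500, seed=21)
        t2 = build_two_locus_table(n=8, rho_grid=(0, 5, 50), reps=500, seed=21)
        assert t1.configs == t2.configs
        assert np.array_equal(t1.logp, t2.logp)

    def test_perfect_ld_decays_with_rho(self, table30):
        """Recombination destroys perfect LD: P(k,0,0,n-k) falls along the grid."""
        for k in (10, 15):
            row = table30.row(canonicalize(k, 0, 0, 30 - k))
            assert row is not None
            smooth = np.convolve(np.exp(row), np.ones(3) / 3, mode="valid")
            assert smooth[0] > 2 * smooth[-1]
            assert np.exp(row[0]) > np.exp(row).min() * 2

    def test_unlinked_loci_factorize(self):
        """At the grid maximum the joint config distribution matches two
        independent genealogies (independent-loci oracle)."""
        n, reps = 4, 8000
        tab = build_two_locus_table(n=n, rho_grid=(0, 500), reps=reps, seed=31)
        # oracle: two completely independent single-locus genealogies
        rng = derive_rng(99, "oracle")
        counts: dict[PairConfig, int] = {}
        sims = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1, sequence_length=1,
            num_replicates=2 * reps, random_seed=derive_seed(99, "oracle-anc"),
        )
        masks = []
        for ts in sims:
            masks.append(_sample_branch_split(ts.first(), ts.tables.nodes.time, rng, n))
        for left, right in zip(masks[:reps], masks[reps:]):
            c11 = int(np.sum(left & right))
            c10 = int(left.sum()) - c11
            c01 = int(right.sum()) - c11
            cfg = canonicalize(n - c11 - c10 - c01, c01, c10, c11)
            counts[cfg] = counts.get(cfg, 0) + 1
        for cfg, c in counts.items():
            p_oracle = c / reps
            if p_oracle < 0.02:
                continue
            p_table = np.exp(pair_loglik(tab, cfg, 500.0))
            se = np.sqrt(p_oracle * (1 - p_oracle) / reps) * np.sqrt(2)
            assert abs(p_table - p_oracle) < 4 * se, cfg

    def test_independent_builds_agree(self):
        """Tables from different seeds agree within combined MC error."""
        kw = dict(n=10, rho_grid=(0, 5, 50), reps=4000)
        t1 = build_two_locus_table(seed=41, **kw)
        t2 = build_two_locus_table(seed=42, **kw)
        for cfg in set(t1.configs) & set(t2.configs):
            p1 = np.exp(t1.row(cfg))
            p2 = np.exp(t2.row(cfg))
            for g in range(3):
                if max(p1[g], p2[g]) > 1e-3:
                    se = np.sqrt(
                        p1[g] * (1 - p1[g]) / kw["reps"] + p2[g] * (1 - p2[g]) / kw["reps"]
                    )
                    assert abs(p1[g] - p2[g]) < 4 * max(se, 1e-4), (cfg, g)


class TestPairLoglik:
    def test_on_grid_point_returns_stored_value(self, table10):
        cfg = table10.configs[0]
        k = 3
        assert pair_loglik(table10, cfg, float(table10.rho_grid[k])) == pytest.approx(
            table10.logp[0, k]
        )

    def test_interpolation_between_grid_points(self, table10):
        cfg = table10.configs[0]
        g = table10.rho_grid
        mid = (g[2] + g[3]) / 2
        v = pair_loglik(table10, cfg, float(mid))
        lo, hi = sorted([table10.logp[0, 2], table10.logp[0, 3]])
        assert lo <= v <= hi

    def test_clamps_above_grid_max(self, table10):
        cfg = table10.configs[0]
        assert pair_loglik(table10, cfg, 10 * float(table10.rho_grid[-1])) == pytest.approx(
            table10.logp[0, -1]
        )

    def test_unobserved_config_gets_floor(self, table10):
        cfg = canonicalize(4, 3, 2, 1)
        if table10.row(cfg) is None:
            assert pair_loglik(table10, cfg, 1.0) == pytest.approx(table10.floor_logp)

    def test_n_mismatch_rejected(self, table10):
        with pytest.raises(ValueError, match="n="):
            pair_loglik(table10, PairConfig(20, 5, 3, 2), 1.0)


def test_save_load_round_trip(tmp_path, table10):
    table10.save(tmp_path / "tab")
    back = TwoLocusTable.load(tmp_path / "tab")
    assert back.n == table10.n and back.reps == table10.reps
    assert back.configs == table10.configs
    assert np.array_equal(back.logp, table10.logp)
    assert np.array_equal(back.rho_grid, table10.rho_grid)


def test_load_refuses_wrong_format(tmp_path, table10):
    table10.save(tmp_path / "tab")
    meta = (tmp_path / "tab.json").read_text().replace("ldhotscan-two-locus-table", "other")
    (tmp_path / "tab.json").write_text(meta)
    with pytest.raises(ValueError, match="version-1"):
        TwoLocusTable.load(tmp_path / "tab")
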