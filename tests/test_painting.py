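import numpy as np
import pytest

from conftest import brute_force_painting
from phageflux.alignio import SnpHaplotypes, extract_core_snps
from phageflux.errors import ConfigError
from phageflux.painting import (
    PaintingParams,
    coancestry,
    estimate_params,
    paint_recipient,
)
from phageflux.synthdata import SimConfig, simulate_populations


class TestPaintRecipient:
    def test_matches_exhaustive_path_enumeration(self, tiny_snps):
        params = PaintingParams(switch_scale=0.005, miscopy=0.05)
        chunks, post = paint_recipient(tiny_snps, 0, params)
        chunks_bf, post_bf = brute_force_painting(tiny_snps, 0, params)
        np.testing.assert_allclose(post, post_bf, atol=1e-10)
        np.testing.assert_allclose(chunks, chunks_bf, atol=1e-10)

    def test_posterior_rows_sum_to_one(self, tiny_snps):
        params = PaintingParams(switch_scale=0.01, miscopy=0.1)
        _, post = paint_recipient(tiny_snps, 1, params)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_donor_dominates(self):
        # donor A identical to recipient, donor B maximally mismatched
        m = np.array([[0, 1, 0, 1, 1], [0, 1, 0, 1, 1], [1, 0, 1, 0, 0]], dtype=np.int8)
        snps = SnpHaplotypes(["r", "A", "B"], m, [0, 10, 20, 30, 40])
        params = PaintingParams(switch_scale=1e-4, miscopy=0.01)
        chunks, post = paint_recipient(snps, 0, params)
        assert np.all(post[:, 0] > 0.99)
        assert chunks[1] < 0.01

    def test_exchangeable_donors_share_chunks(self):
        m = np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0]], dtype=np.int8)
        snps = SnpHaplotypes(["r", "A", "B"], m, [0, 50, 120])
        chunks, post = paint_recipient(snps, 0, PaintingParams(0.01, 0.05))
        assert chunks[0] == pytest.approx(chunks[1])
        np.testing.assert_allclose(post[:, 0], post[:, 1])

    def test_donor_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 2, size=(5, 12)).astype(np.int8)
        snps = SnpHaplotypes([f"s{i}" for i in range(5)], m, np.arange(12) * 17)
        params = PaintingParams(0.01, 0.05)
        chunks, post = paint_recipient(snps, 0, params)
        perm = [0, 3, 1, 2, 4]  # recipient stays first
        snps2 = SnpHaplotypes([f"s{i}" for i in perm], m[perm], np.arange(12) * 17)
        chunks2, post2 = paint_recipient(snps2, 0, params)
        donor_perm = [2, 0, 1, 3]  # new panel order s3,s1,s2,s4 in old indices
        np.testing.assert_allclose(chunks2, chunks[donor_perm], atol=1e-12)
        np.testing.assert_allclose(post2, post[:, donor_perm], atol=1e-12)

    def test_long_track_stays_finite(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, size=(4, 5000)).astype(np.int8)
        snps = SnpHaplotypes([f"s{i}" for i in range(4)], m, np.arange(5000) * 7)
        chunks, post = paint_recipient(snps, 0, PaintingParams(0.001, 0.02))
        assert np.all(np.isfinite(post)) and np.all(np.isfinite(chunks))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


class TestEstimateParams:
    def test_defaults_positive_and_in_range(self, tiny_snps):
        p = estimate_params(tiny_snps)
        assert p.switch_scale > 0 and 0 < p.miscopy < 0.5

    def test_override_passthrough(self, tiny_snps):
        p = estimate_params(tiny_snps, switch_scale=0.001)
        assert p.switch_scale == 0.001

    def test_miscopy_matches_harmonic_number_formula(self):
        # panel of k=5 donors -> theta_w = 1/(1+1/2+1/3+1/4)
        m = np.zeros((6, 4), dtype=np.int8)
        m[0] = [0, 1, 0, 1]
        snps = SnpHaplotypes([f"s{i}" for i in range(6)], m, [0, 5, 9, 20])
        theta = 1.0 / (1 + 0.5 + 1 / 3 + 0.25)
        expected = theta / (theta + 2 * 5)
        assert estimate_params(snps).miscopy == pytest.approx(expected)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            PaintingParams(switch_scale=-1.0, miscopy=0.1)
        with pytest.raises(ConfigError):
            PaintingParams(switch_scale=0.1, miscopy=0.6)


class TestCoancestry:
    def test_identical_samples_symmetric(self):
        m = np.tile(np.array([0, 1, 0, 1], dtype=np.int8), (3, 1))
        snps = SnpHaplotypes(["a", "b", "c"], m, [0, 10, 20, 30])
        X = coancestry(snps, PaintingParams(0.01, 0.05))
        off = X.X[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, off[0])

    def test_row_sums_positive_and_diag_zero(self, tiny_snps):
        X = coancestry(tiny_snps, PaintingParams(0.01, 0.05))
        assert np.all(X.row_sums() >= 1.0 - 1e-9)
        assert np.all(np.diag(X.X) == 0)

    def test_within_population_exceeds_between(self):
        cfg = SimConfig(n_pops=2, pop_sizes=(6, 6), genome_len=8000, seed=11)
        aln, labels, _ = simulate_populations(cfg)
        snps = extract_core_snps(aln)
        X = coancestry(snps)
        ids = X.sample_ids
        same = np.array([[labels[a] == labels[b] for b in ids] for a in ids])
        mask_off = ~np.eye(len(ids), dtype=bool)
        within = X.X[same & mask_off].mean()
        between = X.X[~same].mean()
        assert within > between

    def test_migration_monotonicity(self):
        """Chunk share attributed to the source population grows with m."""
        shares = []
        for m in (0.0, 0.1, 0.3):
            M = np.array([[1.0 - m, m], [0.0, 1.0]])
            cfg = SimConfig(n_pops=2, pop_sizes=(5, 8), genome_len=12_000,
                            migration=M, seed=42)
            aln, labels, _ = simulate_populations(cfg)
            X = coancestry(extract_core_snps(aln))
            ids = X.sample_ids
            a_rows = [i for i, s in enumerate(ids) if labels[s] == "pop0"]
            b_cols = [i for i, s in enumerate(ids) if labels[s] == "pop1"]
            share = X.X[np.ix_(a_rows, b_cols)].sum() / X.X[a_rows].sum()
            shares.append(share)
        assert shares[0] < shares[1] < shares[2]

    def test_roundtrip_tsv(self, tiny_snps, tmp_path):
        from phageflux.painting import CoancestryMatrix

        X = coancestry(tiny_snps, PaintingParams(0.01, 0.05))
        path = tmp_path / "co.tsv"
        X.write_tsv(path)
        X2 = CoancestryMatrix.read_tsv(path)
        assert X2.sample_ids == X.sample_ids
        np.testing.assert_allclose(X2.X, X.X, atol=1e-6)
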