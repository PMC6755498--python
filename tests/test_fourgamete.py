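import numpy as np
import pytest

from conftest import exhaustive_rmin
from phageflux.alignio import GeneStats, HaplotypeAlignment
from phageflux.errors import InputError
from phageflux.fourgamete import (
    incompatible,
    intensity_report,
    ols_fit,
    regress,
    rmin,
)
from phageflux.synthdata import simulate_recombining_gene


def random_binary_alignment(rng, n_haps, n_sites):
    m = rng.integers(0, 2, size=(n_haps, n_sites))
    seqs = ["".join("AC"[v] for v in row) for row in m]
    return HaplotypeAlignment([(f"h{i}", s) for i, s in enumerate(seqs)]), m


class TestIncompatible:
    def test_all_four_gametes(self):
        assert incompatible(np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]))

    def test_three_gametes_compatible(self):
        a = np.array([0, 0, 1, 1, 0, 1])
        b = np.array([0, 0, 1, 1, 1, 1])  # gametes 00, 01, 11 only
        assert not incompatible(a, b)

    def test_two_haplotypes_never_incompatible(self):
        assert not incompatible(np.array([0, 1]), np.array([1, 0]))

    def test_allele_label_swap_invariance(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        assert incompatible(a, b) == incompatible(1 - a, b) == incompatible(a, 1 - b)

    def test_non_biallelic_rejected(self):
        with pytest.raises(InputError):
            incompatible(np.array([0, 0, 0]), np.array([0, 1, 0]))


class TestRmin:
    def test_clonal_alignment_zero(self):
        aln, _ = simulate_recombining_gene(8, 30, 0, seed=0, private_mutations=5)
        assert rmin(aln)[0] == 0

    def test_single_incompatible_pair_gives_one(self):
        aln = HaplotypeAlignment(
            [("h0", "AA"), ("h1", "AC"), ("h2", "CA"), ("h3", "CC")]
        )
        r, intervals = rmin(aln)
        assert r == 1 and intervals == [(0, 1)]

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(4, 9))
            L = int(rng.integers(2, 13))
            aln, m = random_binary_alignment(rng, n, L)
            biallelic = [j for j in range(L) if len(set(m[:, j].tolist())) == 2]
            assert rmin(aln)[0] == exhaustive_rmin(m[:, biallelic])

    def test_reorder_and_relabel_invariance(self):
        rng = np.random.default_rng(5)
        aln, m = random_binary_alignment(rng, 8, 10)
        r0 = rmin(aln)[0]
        shuffled = HaplotypeAlignment(list(reversed(aln.records)))
        assert rmin(shuffled)[0] == r0
        # swap alleles at site 0
        m2 = m.copy()
        m2[:, 0] = 1 - m2[:, 0]
        aln2 = HaplotypeAlignment(
            [(f"h{i}", "".join("AC"[v] for v in row)) for i, row in enumerate(m2)]
        )
        assert rmin(aln2)[0] == r0

    def test_bounded_by_segregating_sites(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            aln, m = random_binary_alignment(rng, 6, 8)
            S = sum(len(set(m[:, j].tolist())) == 2 for j in range(8))
            assert rmin(aln)[0] <= max(S - 1, 0)

    def test_few_haplotypes_give_zero(self):
        aln = HaplotypeAlignment([("a", "ACAC"), ("b", "CACA")])
        assert rmin(aln)[0] == 0

    def test_planted_crossovers_upper_bound(self):
        for seed in range(50):
            aln, bps = simulate_recombining_gene(10, 40, 3, seed=seed, private_mutations=4)
            assert rmin(aln)[0] <= 3

    def test_gap_columns_ignored(self):
        # incompatibility exists only through a gapped column: must vanish
        aln = HaplotypeAlignment(
            [("h0", "A-A"), ("h1", "A-C"), ("h2", "C-A"), ("h3", "CCC")]
        )
        r, _ = rmin(aln)
        aln_nogap = HaplotypeAlignment(
            [("h0", "AA"), ("h1", "AC"), ("h2", "CA"), ("h3", "CC")]
        )
        assert r == rmin(aln_nogap)[0] == 1  # same sites survive either way


class TestRegress:
    def test_noiseless_plane_recovered(self):
        rng = np.random.default_rng(0)
        x1 = rng.uniform(0.01, 0.2, size=20)
        x2 = rng.integers(8, 30, size=20).astype(float)
        y = 0.01 + 2.0 * x1 + 0.001 * x2
        fit = ols_fit(y, x1, x2)
        assert fit.beta0 == pytest.approx(0.01, abs=1e-10)
        assert fit.beta1 == pytest.approx(2.0, abs=1e-10)
        assert fit.beta2 == pytest.approx(0.001, abs=1e-10)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_matches_normal_equations(self):
        y = np.array([0.02, 0.05, 0.11, 0.03, 0.09, 0.07])
        x1 = np.array([0.01, 0.03, 0.06, 0.02, 0.05, 0.04])
        x2 = np.array([10.0, 12.0, 9.0, 15.0, 11.0, 13.0])
        fit = ols_fit(y, x1, x2)
        X = np.column_stack([np.ones(6), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert [fit.beta0, fit.beta1, fit.beta2] == pytest.approx(list(beta))

    def test_intercept_shift_equivariance(self):
        rng = np.random.default_rng(1)
        x1 = rng.uniform(0, 1, 10)
        x2 = rng.uniform(5, 20, 10)
        y = 0.1 + 0.5 * x1 + 0.01 * x2 + rng.normal(0, 0.01, 10)
        f1 = ols_fit(y, x1, x2)
        f2 = ols_fit(y + 3.0, x1, x2)
        assert f2.beta0 == pytest.approx(f1.beta0 + 3.0)
        assert f2.beta1 == pytest.approx(f1.beta1)
        assert f2.beta2 == pytest.approx(f1.beta2)

    def test_constant_n_drops_term(self):
        stats = [
            GeneStats(f"g{i}", n=10, L=1000, S=5, pi=p, rmin=i % 3)
            for i, p in enumerate([0.01, 0.02, 0.05, 0.03, 0.04])
        ]
        with pytest.warns(UserWarning, match="rank"):
            fit = regress(stats)
        assert fit.beta2 is None

    def test_line_at_mean_n(self):
        x1 = np.array([0.0, 0.1, 0.2, 0.3])
        x2 = np.array([10.0, 20.0, 10.0, 20.0])
        y = 1.0 + 2.0 * x1 + 0.5 * x2
        fit = ols_fit(y, x1, x2)
        assert fit.line_at_mean_n(0.1) == pytest.approx(1.0 + 0.2 + 0.5 * 15.0)

    def test_too_few_genes_rejected(self):
        stats = [GeneStats("g", n=4, L=100, S=2, pi=0.01, rmin=1)] * 3
        with pytest.raises(InputError):
            regress(stats)


class TestIntensityReport:
    def _stats(self, y, x1, n):
        return [
            GeneStats(f"g{i}", n=int(n[i]), L=1000, S=200, pi=float(x1[i]),
                      rmin=int(round(y[i] * 1000)))
            for i in range(len(y))
        ]

    def test_on_line_genes_not_flagged(self):
        x1 = np.linspace(0.01, 0.1, 8)
        n = np.array([10, 12, 14, 16, 10, 12, 14, 16])
        y = (np.round((0.002 + 0.1 * x1 + 0.0001 * n) * 1000)) / 1000
        stats = self._stats(y, x1, n)
        fit = regress(stats)
        report = intensity_report(stats, fit)
        assert not report.deviating.any()

    def test_planted_outlier_flagged_alone(self):
        x1 = np.linspace(0.01, 0.1, 10)
        n = np.full(10, 12.0)
        n[::2] = 16.0
        y = np.round((0.002 + 0.1 * x1 + 0.0001 * n) * 1000) / 1000
        y[4] *= 5  # inflate one gene well off the plane
        stats = self._stats(y, x1, n)
        fit = regress(stats)
        report = intensity_report(stats, fit)
        flagged = set(report[report.deviating].gene_id)
        assert flagged == {"g4"}

    def test_report_covers_all_genes(self):
        x1 = np.linspace(0.01, 0.1, 6)
        n = np.array([8.0, 10, 12, 8, 10, 12])
        y = np.round((0.01 + 0.2 * x1 + 0.0002 * n) * 1000) / 1000
        stats = self._stats(y, x1, n)
        report = intensity_report(stats, regress(stats))
        assert len(report) == 6
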