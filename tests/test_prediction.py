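"""Kernels and the mixed model: hand-computed cases, algebraic
equivalences, and an independent REML oracle."""
import numpy as np
import pytest
from scipy import optimize

from syngs.ancestral import BaseFrequencies
from syngs.genome import PedigreeBook
from syngs.prediction import (RelationshipMatrix, extend_pedigree_A,
                              fit_mixed_model, pedigree_A, predict,
                              thin_snps, vanraden_G, vanraden_cross,
                              write_kernel)


class TestVanRaden:
    def test_hand_computed_single_snp(self):
        """x_i=2, x_j=0 at one SNP with p=0.5: k_ij = (1)(-1)/0.5 = -2."""
        G = vanraden_G(np.array([[2], [0]]), np.array([0.5])).values
        assert G[0, 1] == pytest.approx(-2.0)
        assert G[0, 0] == pytest.approx(2.0)

    def test_identical_individuals_share_row(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, (5, 40))
        X[1] = X[0]
        G = vanraden_G(X, np.full(40, 0.25)).values
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_mean_diagonal_is_one_under_hwe(self):
        """For genotypes drawn at HWE with the centering frequencies,
        E[diag] = 1 by construction of the denominator."""
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.5, 3000)
        X = rng.binomial(2, p, size=(300, 3000))
        G = vanraden_G(X, p).values
        assert np.diag(G).mean() == pytest.approx(1.0, abs=0.03)

    def test_monomorphic_base_raises(self):
        with pytest.raises(ValueError):
            vanraden_G(np.array([[0], [1]]), np.array([0.0]))

    def test_cross_block_matches_full_matrix(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.5, 100)
        X = rng.binomial(2, p, size=(12, 100))
        G = vanraden_G(X, p).values
        cross = vanraden_cross(X[8:], X[:8], p)
        assert np.allclose(cross, G[8:, :8])


def _dh_family_book():
    book = PedigreeBook()
    a = book.add_base()
    b = book.add_base()
    dh_a = book.add(a, a, dh=True)
    dh_b = book.add(b, b, dh=True)
    f1 = book.add(dh_a, dh_b)
    return book, a, b, dh_a, dh_b, f1


class TestPedigreeA:
    def test_base_individuals_unrelated_non_inbred(self):
        book = PedigreeBook()
        book.add_base(); book.add_base()
        assert np.allclose(pedigree_A(book), np.eye(2))

    def test_dh_line_fully_inbred(self):
        book, a, b, dh_a, dh_b, f1 = _dh_family_book()
        A = pedigree_A(book)
        assert A[dh_a, dh_a] == pytest.approx(2.0)
        assert A[dh_a, a] == pytest.approx(1.0)
        assert A[dh_a, dh_b] == 0.0

    def test_f1_of_unrelated_dh_lines(self):
        book, a, b, dh_a, dh_b, f1 = _dh_family_book()
        A = pedigree_A(book)
        assert A[f1, f1] == pytest.approx(1.0)
        assert A[f1, dh_a] == pytest.approx(1.0)

    def test_selfed_progeny_of_non_inbred_has_F_half(self):
        book = PedigreeBook()
        x = book.add_base()
        s = book.add(x, x)
        A = pedigree_A(book)
        assert A[s, s] == pytest.approx(1.5)        # F = 0.5

    def test_extension_matches_full_recursion(self):
        book, a, b, dh_a, dh_b, f1 = _dh_family_book()
        A_partial = pedigree_A(book)
        f2a = book.add(f1, f1)
        f2b = book.add(f1, f1)
        assert np.allclose(extend_pedigree_A(A_partial, book),
                           pedigree_A(book))


class TestThinSnps:
    def _base(self, gmap, rng):
        p = rng.uniform(0.05, 0.5, gmap.n_loci)
        return BaseFrequencies(p, np.ones(gmap.n_loci, bool))

    def test_density_yields_printed_counts(self, rng):
        from syngs.genome import build_map
        gmap = build_map(10, 1913.0, 12_000, n_qtl=1500, seed=2)
        base = self._base(gmap, rng)
        assert len(thin_snps(gmap, 2.5, base, rng)) == 4783
        assert len(thin_snps(gmap, 0.125, base, rng)) == 239

    def test_qtl_never_in_panel(self, small_map, rng):
        base = self._base(small_map, rng)
        panel = thin_snps(small_map, 1.0, base, rng)
        assert not np.any(small_map.is_qtl[panel])

    def test_insufficient_snps_raise(self, small_map, rng):
        base = self._base(small_map, rng)
        with pytest.raises(ValueError):
            thin_snps(small_map, 10.0, base, rng)


def _simulate_gblup_instance(rng, n_ts=12, n_cand=8, m=30, h2=0.6):
    p = rng.uniform(0.1, 0.5, m)
    X = rng.binomial(2, p, size=(n_ts + n_cand, m))
    Z = X - 2 * p
    beta = rng.normal(0, 1, m)
    g = Z @ beta
    g = g / g.std() * np.sqrt(h2)
    y = g + rng.normal(0, np.sqrt(1 - h2), len(g))
    return p, X, Z, y


class TestMixedModel:
    def test_no_shrinkage_limit_recovers_phenotypes(self):
        """With noise-free phenotypes the estimated residual variance
        goes to zero and the fitted values approach y - mu."""
        rng = np.random.default_rng(4)
        p, X, Z, _ = _simulate_gblup_instance(rng, n_ts=30, n_cand=0, m=60)
        K = vanraden_G(X, p)
        y = Z @ rng.normal(0, 1, Z.shape[1])        # pure genetic signal
        fit = fit_mixed_model(y, K)
        assert fit.delta < 1e-4
        assert np.allclose(fit.ebv_ts, y - fit.mu, atol=1e-3 * y.std())

    def test_gblup_equals_ridge_snp_blup(self):
        """GBLUP with K = ZZ'/c and ridge SNP-BLUP with matched penalty
        lambda = delta*c give identical predictions (20 individuals)."""
        rng = np.random.default_rng(11)
        p, X, Z, y = _simulate_gblup_instance(rng)
        n_ts = 12
        c = np.sum(2 * p * (1 - p))
        K = vanraden_G(X, p)
        fit = fit_mixed_model(y[:n_ts], K)
        # independent ridge route: marker effects from the TS only
        Zt = Z[:n_ts]
        lam = fit.delta * c
        beta_hat = Zt.T @ np.linalg.solve(Zt @ Zt.T + lam * np.eye(n_ts),
                                          y[:n_ts] - fit.mu)
        ghat_ridge = Z @ beta_hat
        assert np.allclose(fit.ebv, ghat_ridge, atol=1e-8)

    def test_profile_reml_matches_direct_two_parameter_optimum(self):
        """The 1-D spectral profile solver agrees with a direct
        Nelder-Mead optimization of the full REML criterion written from
        the MVN definition (independent oracle)."""
        rng = np.random.default_rng(21)
        for _ in range(3):
            p, X, Z, y = _simulate_gblup_instance(rng, n_ts=40, n_cand=0,
                                                  m=60)
            K = vanraden_G(X, p)
            fit = fit_mixed_model(y, K)
            n = len(y)
            ones = np.ones(n)

            def neg2reml(theta):
                s2a, s2e = np.exp(theta)
                V = s2a * K.values + s2e * np.eye(n)
                Vi = np.linalg.inv(V)
                xvx = ones @ Vi @ ones
                beta = (ones @ Vi @ y) / xvx
                r = y - beta
                sign, logdet = np.linalg.slogdet(V)
                return logdet + np.log(xvx) + r @ Vi @ r

            res = optimize.minimize(
                neg2reml, np.log([fit.sigma2_a * 2, fit.sigma2_eps * 0.5]),
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 4000})
            s2a, s2e = np.exp(res.x)
            assert s2e / s2a == pytest.approx(fit.delta, rel=1e-6)

    def test_reml_recovers_true_variance_components(self):
        """Parameter recovery: data simulated from the model with known
        (sigma2_a, sigma2_eps) at n=250 yields near-unbiased REML
        estimates across replicates."""
        rng = np.random.default_rng(31)
        n, m = 250, 400
        s2a_true, s2e_true = 2.0, 1.0
        est_a, est_e = [], []
        for _ in range(60):
            p = rng.uniform(0.1, 0.5, m)
            X = rng.binomial(2, p, size=(n, m))
            K = vanraden_G(X, p)
            L = np.linalg.cholesky(K.values + 1e-8 * np.eye(n))
            g = np.sqrt(s2a_true) * (L @ rng.normal(0, 1, n))
            y = 3.0 + g + rng.normal(0, np.sqrt(s2e_true), n)
            fit = fit_mixed_model(y, K)
            est_a.append(fit.sigma2_a)
            est_e.append(fit.sigma2_eps)
        se_a = np.std(est_a, ddof=1) / np.sqrt(len(est_a))
        se_e = np.std(est_e, ddof=1) / np.sqrt(len(est_e))
        assert np.mean(est_a) == pytest.approx(s2a_true, abs=4 * se_a)
        assert np.mean(est_e) == pytest.approx(s2e_true, abs=4 * se_e)

    def test_predictions_invariant_to_phenotype_shift(self):
        rng = np.random.default_rng(41)
        p, X, Z, y = _simulate_gblup_instance(rng)
        K = vanraden_G(X, p)
        f0 = fit_mixed_model(y[:12], K)
        f1 = fit_mixed_model(y[:12] + 100.0, K)
        assert f1.mu == pytest.approx(f0.mu + 100.0, abs=1e-6)
        assert np.allclose(f0.ebv, f1.ebv, atol=1e-6)

    def test_candidate_projection_matches_manual_blup(self):
        rng = np.random.default_rng(51)
        p, X, Z, y = _simulate_gblup_instance(rng)
        K = vanraden_G(X, p)
        fit = fit_mixed_model(y[:12], K)
        Ktt = K.values[:12, :12]
        manual = K.values[12:, :12] @ np.linalg.solve(
            Ktt + fit.delta * np.eye(12), y[:12] - fit.mu)
        assert np.allclose(fit.ebv_candidates, manual, atol=1e-8)
        assert np.allclose(predict(fit, K.values[12:, :12]),
                           fit.ebv_candidates)

    def test_f2_family_pedigree_gives_constant_candidate_ebv(self):
        """With the numerator kernel of an F2 family from one selfed F1,
        all candidates relate identically to every TS member, so their
        EBVs coincide exactly."""
        book = PedigreeBook()
        a, b = book.add_base(), book.add_base()
        dh_a = book.add(a, a, dh=True)
        dh_b = book.add(b, b, dh=True)
        f1 = book.add(dh_a, dh_b)
        f2 = [book.add(f1, f1) for _ in range(30)]
        A = pedigree_A(book)
        idx = np.array(f2)
        K = RelationshipMatrix(A[np.ix_(idx, idx)], "pedigree")
        rng = np.random.default_rng(61)
        fit = fit_mixed_model(rng.normal(0, 1, 20), K,
                              ts_index=np.arange(20))
        cand = fit.ebv_candidates
        assert np.allclose(cand, cand[0], atol=1e-9 * max(1, abs(cand[0])))

    def test_non_psd_kernel_rejected(self):
        M = np.eye(4)
        M[0, 0] = -1.0
        with pytest.raises(ValueError):
            fit_mixed_model(np.zeros(4), RelationshipMatrix(M, "genomic"))

    def test_kernel_export(self, tmp_path):
        K = RelationshipMatrix(np.eye(3), "pedigree")
        path = tmp_path / "K.txt"
        write_kernel(K, ["x", "y", "z"], path)
        lines = path.read_text().splitlines()
        assert lines[0].split() == ["id", "x", "y", "z"]
        assert lines[1].split()[1] == "1"
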