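import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

import isosplice as iso
from isosplice.diffsplice_core import _trigamma_inverse
from isosplice.limma_fit import TranscriptFit


def _toy_fit(rng, n_genes=50, tx_per_gene=(2, 3, 4), n=8, p=2):
    """Random linear-model-style TranscriptFit plus gene ids."""
    sizes = rng.choice(tx_per_gene, size=n_genes)
    gene_ids = np.repeat([f"g{i:03d}" for i in range(n_genes)], sizes).astype(object)
    T = int(sizes.sum())
    beta = rng.normal(0, 1, size=(T, p))
    v = rng.uniform(0.05, 1.0, size=T)
    cov = np.zeros((T, p, p))
    cov[:, 0, 0] = rng.uniform(0.05, 1.0, size=T)
    cov[:, 1, 1] = v
    s2 = rng.chisquare(5, size=T) / 5.0
    df = np.full(T, float(n - p))
    return (
        TranscriptFit(beta=beta, unscaled_cov=cov, s2=s2, resid_df=df,
                      fitted=np.zeros((T, n)), log_base=2.0),
        gene_ids,
    )


class TestTrigammaInverse:
    @pytest.mark.parametrize("y", [0.05, 0.3, 1.0, 4.0, 25.0])
    def test_round_trip(self, y):
        x = _trigamma_inverse(special.polygamma(1, y))
        assert x == pytest.approx(y, rel=1e-6)


class TestSqueezeVariances:
    def test_equal_variances_give_infinite_prior_df(self):
        eb = iso.squeeze_variances(np.array([2.0, 2.0]), np.array([4.0, 4.0]))
        assert np.isinf(eb.prior_df)
        # every posterior collapses onto the common prior variance
        np.testing.assert_allclose(eb.posterior_s2, eb.prior_s2, rtol=1e-12)
        np.testing.assert_allclose(eb.posterior_s2, 2.0, rtol=0.5)

    def test_hyperparameter_recovery_on_generative_model(self, rng):
        d0, s0 = 10.0, 4.0
        G = 20000
        dg = rng.integers(3, 9, size=G).astype(float)
        sigma2 = s0 * d0 / rng.chisquare(d0, size=G)
        s2 = sigma2 * rng.chisquare(dg) / dg
        eb = iso.squeeze_variances(s2, dg)
        assert 8.0 < eb.prior_df < 12.5
        assert 3.8 < eb.prior_s2 < 4.2

    def test_posterior_between_prior_and_observed(self, rng):
        dg = rng.integers(2, 10, size=500).astype(float)
        s2 = rng.chisquare(dg) / dg * 3.0
        eb = iso.squeeze_variances(s2, dg)
        lo = np.minimum(eb.prior_s2, s2)
        hi = np.maximum(eb.prior_s2, s2)
        assert np.all(eb.posterior_s2 >= lo - 1e-12)
        assert np.all(eb.posterior_s2 <= hi + 1e-12)

    def test_degenerate_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            iso.squeeze_variances(np.zeros(5), np.full(5, 4.0))


class TestSimes:
    @pytest.mark.parametrize(
        "p,expected",
        [([0.01, 0.04], 0.02), ([0.5], 0.5), ([0.2, 0.2, 0.2], 0.2)],
    )
    def test_closed_form(self, p, expected):
        assert iso.simes_p(np.array(p)) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_bounds(self, p):
        p = np.array(p)
        s = iso.simes_p(p)
        assert min(1.0, p.min()) - 1e-12 <= s <= min(1.0, len(p) * p.min()) + 1e-12


class TestBHAdjust:
    def test_closed_form(self):
        np.testing.assert_allclose(
            iso.bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(iso.bh_adjust(np.array([0.4])), [0.4])

    @settings(deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_dominates_raw_and_capped(self, p):
        p = np.array(p)
        adj = iso.bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            iso.bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12
        )


class TestLimmaDiffsplice:
    def test_two_transcript_genes_have_equal_f_and_simes_p(self, rng):
        fit, genes = _toy_fit(rng, tx_per_gene=(2,))
        res = iso.limma_diffsplice(fit, genes, coef=1)
        np.testing.assert_allclose(
            res.genes["p_F"], res.genes["p_simes"], rtol=1e-12
        )

    def test_equal_coefficients_give_null_statistics(self, rng):
        fit, genes = _toy_fit(rng, tx_per_gene=(3,))
        fit.beta[:, 1] = 0.7  # identical within every gene
        res = iso.limma_diffsplice(fit, genes, coef=1)
        np.testing.assert_allclose(res.transcripts["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.genes["F"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.genes["p_F"], 1.0)

    def test_weighted_centering_identity(self, rng):
        fit, genes = _toy_fit(rng)
        res = iso.limma_diffsplice(fit, genes, coef=1)
        tx = res.transcripts
        u = 1.0 / fit.unscaled_var(1)
        # recompute beta - beta_bar from the reported log2 relative effect
        dev = tx["rel_logFC"].to_numpy()
        sums = (
            np.bincount(
                np.unique(tx["gene_id"], return_inverse=True)[1], weights=u * dev
            )
        )
        assert np.abs(sums).max() < 1e-10

    def test_leverage_identity(self, rng):
        """beta_t - beta_bar = (1 - h)(beta_t - leave-one-out mean)."""
        fit, genes = _toy_fit(rng)
        res = iso.limma_diffsplice(fit, genes, coef=1)
        tx = res.transcripts
        codes = np.unique(tx["gene_id"], return_inverse=True)[1]
        u = 1.0 / fit.unscaled_var(1)
        b = fit.beta[:, 1]
        ug = np.bincount(codes, weights=u)
        ub = np.bincount(codes, weights=u * b)
        bbar = ub / ug
        loo = (ub[codes] - u * b) / (ug[codes] - u)
        lhs = b - bbar[codes]
        rhs = (1.0 - tx["leverage"].to_numpy()) * (b - loo)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_f_statistic_recomputed_from_t_and_leverage(self, rng):
        fit, genes = _toy_fit(rng)
        res = iso.limma_diffsplice(fit, genes, coef=1)
        tx = res.transcripts
        codes, uniq = np.unique(tx["gene_id"], return_inverse=True)[1], np.unique(tx["gene_id"])
        contrib = (1.0 - tx["leverage"].to_numpy()) * tx["t"].to_numpy() ** 2
        ntx = np.bincount(codes)
        F = np.bincount(codes, weights=contrib) / (ntx - 1)
        g = res.genes.set_index("gene_id").loc[uniq]
        np.testing.assert_allclose(F, g["F"].to_numpy(), atol=1e-10)


def _nb_dataset(rng, n_genes=120, n_per=4, phi=0.05, dtu_frac=0.3):
    sizes = rng.integers(2, 8, size=n_genes)
    gene_ids = np.repeat([f"g{i:03d}" for i in range(n_genes)], sizes).astype(object)
    tx_ids = np.array([f"t{i:04d}" for i in range(sizes.sum())], dtype=object)
    T = int(sizes.sum())
    g = np.repeat([0.0, 1.0], n_per)
    X = np.column_stack([np.ones(2 * n_per), g])
    base = rng.uniform(30, 400, size=T)
    lfc = np.zeros(T)
    dtu = rng.random(T) < dtu_frac
    lfc[dtu] = rng.normal(0, 0.8, size=int(dtu.sum()))
    mu = base[:, None] * np.exp(lfc[:, None] * g[None, :])
    lam = rng.gamma(1.0 / phi, phi * mu)
    y = rng.poisson(lam).astype(float)
    return y, X, gene_ids, tx_ids


class TestEdgerDiffsplice:
    def test_two_transcript_gene_transcript_equals_gene_test(self, rng):
        y, X, genes, txs = _nb_dataset(rng, n_genes=40)
        fit = iso.fit_nb_glm(
            iso.DividedCounts(y, y.sum(axis=0), np.ones(X.shape[0])),
            X, phi=0.05, offsets=np.zeros(X.shape[0]),
        )
        res = iso.edger_diffsplice(y, X, np.zeros(X.shape[0]), fit, genes, 1, 0.05,
                                   transcript_id=txs)
        two = res.genes[res.genes["n_transcripts"] == 2]
        assert len(two) > 0
        tx = res.transcripts.set_index("gene_id")
        for _, row in two.iterrows():
            sub = tx.loc[[row["gene_id"]]]
            np.testing.assert_allclose(sub["F"], row["F"], rtol=1e-6)
            np.testing.assert_allclose(sub["p"], row["p_F"], rtol=1e-6)
            np.testing.assert_allclose(row["p_simes"], row["p_F"], rtol=1e-6)

    def test_fast_path_tracks_exact_path(self, rng):
        y, X, genes, txs = _nb_dataset(rng, n_genes=120)
        off = np.zeros(X.shape[0])
        fit = iso.fit_nb_glm(
            iso.DividedCounts(y, y.sum(axis=0), np.ones(X.shape[0])),
            X, phi=0.05, offsets=off,
        )
        exact = iso.edger_diffsplice(y, X, off, fit, genes, 1, 0.05, transcript_id=txs)
        fast = iso.edger_diffsplice(y, X, off, fit, genes, 1, 0.05, transcript_id=txs,
                                    fast_threshold=2)
        e = exact.transcripts.set_index("transcript_id")
        f = fast.transcripts.set_index("transcript_id")
        multi = exact.genes.loc[exact.genes["n_transcripts"].between(3, 10), "gene_id"]
        sel = e["gene_id"].isin(set(multi))
        rho = stats.spearmanr(e.loc[sel, "F"], f.loc[e.index[sel], "F"]).statistic
        assert rho > 0.95
        agree = np.mean(np.sign(e.loc[sel, "t"]) == np.sign(f.loc[e.index[sel], "t"]))
        assert agree > 0.99


class TestTopSplice:
    def _tables(self, rng):
        fit, genes = _toy_fit(rng)
        return iso.limma_diffsplice(fit, genes, coef=1)

    def test_zero_rows_and_full_table(self, rng):
        tables = self._tables(rng)
        assert len(iso.top_splice(tables, "gene-F", n=0)) == 0
        assert len(iso.top_splice(tables, "gene-F", fdr_cutoff=1.0)) == len(tables.genes)

    def test_sorted_by_raw_p(self, rng):
        tables = self._tables(rng)
        top = iso.top_splice(tables, "transcript")
        assert np.all(np.diff(top["p"].to_numpy()) >= 0)

    def test_order_invariant_to_input_permutation(self, rng):
        tables = self._tables(rng)
        shuffled = iso.DTUResultTables(
            genes=tables.genes.sample(frac=1.0, random_state=7).reset_index(drop=True),
            transcripts=tables.transcripts,
        )
        a = iso.top_splice(tables, "gene-Simes")
        b = iso.top_splice(shuffled, "gene-Simes")
        assert list(a["gene_id"]) == list(b["gene_id"])

    def test_unknown_level_rejected(self, rng):
        with pytest.raises(ValueError, match="level"):
            iso.top_splice(self._tables(rng), "exon")
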