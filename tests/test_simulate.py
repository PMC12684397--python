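import numpy as np
import pandas as pd
import pytest

import isosplice as iso
from isosplice.simulate import assign_truth, build_catalog, draw_dispersions


@pytest.fixture(scope="module")
def cfg():
    return iso.SimConfig.desk_scale(seed=5, n_genes=400, resamples=20)


class TestBuildCatalog:
    def test_deterministic_for_fixed_seed(self, cfg):
        c1, b1 = build_catalog(cfg, np.random.default_rng(3))
        c2, b2 = build_catalog(cfg, np.random.default_rng(3))
        assert list(c1.transcript_id) == list(c2.transcript_id)
        np.testing.assert_array_equal(b1, b2)

    def test_requested_gene_count(self, cfg):
        cat, _ = build_catalog(cfg, np.random.default_rng(0))
        assert cat.n_genes == cfg.n_genes

    def test_mostly_multi_transcript_genes(self, cfg):
        cat, _ = build_catalog(cfg, np.random.default_rng(0))
        per_gene = cat.transcripts_per_gene()
        assert (per_gene >= 2).mean() > 0.5
        assert per_gene.max() <= cfg.max_transcripts


class TestDrawDispersions:
    def test_chi_squared_transformation_has_df_mean(self, cfg):
        rng = np.random.default_rng(42)
        phi = draw_dispersions(cfg, 100_000, rng)
        x = cfg.bcv_df * cfg.prior_bcv**2 / phi
        assert x.mean() == pytest.approx(cfg.bcv_df, rel=0.01)
        assert np.all(phi > 0)

    def test_reproducible(self, cfg):
        a = draw_dispersions(cfg, 100, np.random.default_rng(7))
        b = draw_dispersions(cfg, 100, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestAssignTruth:
    @pytest.fixture(scope="class")
    def truth_and_catalog(self, cfg):
        rng = np.random.default_rng(9)
        catalog, baseline = build_catalog(cfg, rng)
        truth = assign_truth(catalog, baseline, cfg, rng)
        return catalog, baseline, truth

    def test_category_counts_match_split(self, cfg, truth_and_catalog):
        _, _, truth = truth_and_catalog
        counts = truth.gene_category.value_counts()
        assert counts.get("dtu_only", 0) == cfg.split[0]
        assert counts.get("dge_dtu", 0) == cfg.split[1]
        assert counts.get("dge_only", 0) == cfg.split[2]

    def test_dtu_only_swaps_two_fold_and_conserves_gene_total(self, cfg, truth_and_catalog):
        catalog, _, truth = truth_and_catalog
        exp = truth.expected_tpm
        for gene in truth.gene_category.index[truth.gene_category == "dtu_only"]:
            rows = np.flatnonzero(catalog.gene_id == gene)
            sel = rows[truth.is_dtu[rows]]
            assert sel.size == 2
            ratio = exp[sel, 1] / exp[sel, 0]
            assert sorted(np.round(ratio, 12)) == [0.5, 2.0]
            assert exp[rows, 1].sum() == pytest.approx(exp[rows, 0].sum(), rel=1e-12)

    def test_dge_only_changes_all_transcripts_no_usage_change(self, cfg, truth_and_catalog):
        catalog, _, truth = truth_and_catalog
        exp = truth.expected_tpm
        fc = cfg.fold_change
        for gene in truth.gene_category.index[truth.gene_category == "dge_only"][:50]:
            rows = np.flatnonzero(catalog.gene_id == gene)
            ratio = exp[rows, 1] / exp[rows, 0]
            assert np.allclose(ratio, ratio[0])
            assert ratio[0] == pytest.approx(fc) or ratio[0] == pytest.approx(1 / fc)
            assert not truth.is_dtu[rows].any()
            # proportions within the gene are unchanged between groups
            np.testing.assert_allclose(
                exp[rows, 0] / exp[rows, 0].sum(), exp[rows, 1] / exp[rows, 1].sum(),
                rtol=1e-12,
            )

    def test_dge_dtu_flags_whole_gene(self, truth_and_catalog):
        catalog, _, truth = truth_and_catalog
        for gene in truth.gene_category.index[truth.gene_category == "dge_dtu"][:50]:
            rows = np.flatnonzero(catalog.gene_id == gene)
            assert truth.is_dtu[rows].all()
            assert truth.is_de[rows].sum() == 1

    def test_null_mode_identical_expectations(self, cfg):
        rng = np.random.default_rng(9)
        catalog, baseline = build_catalog(cfg, rng)
        truth = assign_truth(catalog, baseline, cfg, rng, null_mode=True)
        np.testing.assert_array_equal(truth.expected_tpm[:, 0], truth.expected_tpm[:, 1])
        assert (truth.gene_category == "null").all()

    def test_infeasible_split_raises(self):
        cfg = iso.SimConfig.desk_scale(seed=0, n_genes=30)
        bad = iso.SimConfig.desk_scale(seed=0, n_genes=30)
        bad.n_de_genes = 500
        bad.split = (500, 0, 0)
        rng = np.random.default_rng(0)
        catalog, baseline = build_catalog(cfg, rng)
        with pytest.raises(ValueError, match="multi-transcript"):
            assign_truth(catalog, baseline, bad, rng)


class TestCounts:
    def test_quasi_poisson_variance_inflation(self, rng):
        # y = tau * Poisson(mu/tau) has var/mean = tau for fixed mu
        tau, mu = 4.0, 400.0
        draws = tau * rng.poisson(mu / tau, size=2000)
        assert 3.2 < draws.var() / draws.mean() < 4.8

    def test_near_poisson_when_bcv_vanishes(self, rng):
        mu = 500.0
        shape = 1e8  # phi -> 1e-8
        tpm = rng.gamma(shape, 1.0, size=1000) / shape * mu
        y = rng.poisson(tpm)
        cv = y.std() / y.mean()
        assert cv == pytest.approx(1 / np.sqrt(mu), rel=0.2)

    def test_column_sums_near_library_sizes(self, small_sim):
        libs = np.array(
            [small_sim.config.lib_sizes[i % 2] for i in range(small_sim.bundle.n_samples)]
        )
        colsums = small_sim.bundle.counts.sum(axis=0)
        assert np.all(np.abs(colsums - libs) < 5 * np.sqrt(libs))

    def test_same_seed_bitwise_identical(self):
        cfg = iso.SimConfig.desk_scale(seed=21, n_genes=50, resamples=5)
        d1 = iso.simulate_dataset(cfg)
        d2 = iso.simulate_dataset(cfg)
        np.testing.assert_array_equal(d1.bundle.counts, d2.bundle.counts)
        np.testing.assert_array_equal(d1.bundle.resamples[0], d2.bundle.resamples[0])
        np.testing.assert_array_equal(d1.tau, d2.tau)


class TestEvaluatePerformance:
    def _fake_results(self, genes, p):
        g = pd.DataFrame(
            {
                "gene_id": genes,
                "n_transcripts": 2,
                "F": 1.0,
                "df1": 1,
                "df2": 10.0,
                "p_F": p,
                "fdr_F": iso.bh_adjust(np.asarray(p)),
                "p_simes": p,
                "fdr_simes": iso.bh_adjust(np.asarray(p)),
            }
        )
        t = pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(len(genes))],
                "gene_id": genes,
                "rel_logFC": 0.0,
                "t": 0.0,
                "p": p,
                "fdr": iso.bh_adjust(np.asarray(p)),
            }
        )
        return iso.DTUResultTables(genes=g, transcripts=t)

    def _truth(self, genes, dtu_genes):
        cat = pd.Series(
            ["dtu_only" if g in dtu_genes else "null" for g in genes], index=genes
        )
        truth = iso.SimTruth(
            gene_category=cat,
            is_de=np.zeros(len(genes), bool),
            is_dtu=np.zeros(len(genes), bool),
            direction=np.zeros(len(genes), int),
            expected_tpm=np.zeros((len(genes), 2)),
        )
        catalog = iso.TranscriptCatalog(
            transcript_id=np.array([f"t{i}" for i in range(len(genes))], dtype=object),
            gene_id=np.asarray(genes, dtype=object),
            length=np.full(len(genes), 1000.0),
            effective_length=np.full(len(genes), 1000.0),
        )
        return truth, catalog

    def test_all_true_discoveries_fdr_zero(self):
        genes = [f"g{i}" for i in range(10)]
        p = [0.001] * 5 + [0.9] * 5
        res = self._fake_results(genes, p)
        truth, cat = self._truth(genes, set(genes[:5]))
        perf = iso.evaluate_performance(res, truth, cutoffs=(0.05,), catalog=cat)
        gene_f = perf[perf["level"] == "gene-F"].iloc[0]
        assert gene_f["FDR"] == 0.0 and gene_f["TP"] == 5

    def test_exact_fdr_arithmetic(self):
        # 95 true + 5 false discoveries -> FDR 0.05 exactly
        genes = [f"g{i}" for i in range(200)]
        p = [1e-6] * 100 + [0.99] * 100
        res = self._fake_results(genes, p)
        truth, cat = self._truth(genes, set(genes[:95]) | set(genes[100:105]))
        perf = iso.evaluate_performance(res, truth, cutoffs=(0.05,), catalog=cat)
        gene_f = perf[perf["level"] == "gene-F"].iloc[0]
        assert gene_f["TP"] == 95 and gene_f["FP"] == 5
        assert gene_f["FDR"] == pytest.approx(0.05)

    def test_uniform_p_on_null_truth_type1_in_band(self, rng):
        n = 4000
        genes = [f"g{i}" for i in range(n)]
        p = rng.uniform(size=n)
        res = self._fake_results(genes, p)
        truth, cat = self._truth(genes, set())
        perf = iso.evaluate_performance(res, truth, cutoffs=(0.05,), catalog=cat)
        t1 = perf[perf["level"] == "gene-F"].iloc[0]["type1"]
        band = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert abs(t1 - 0.05) < band

    def test_id_mismatch_raises(self):
        res = self._fake_results(["gX"], [0.5])
        truth, cat = self._truth(["gY"], set())
        with pytest.raises(ValueError):
            iso.evaluate_performance(res, truth, catalog=cat)
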