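"""Cis pairing, OLS associations, Storey/local-FDR, eGene calling."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import pseudofactor as pf
from pseudofactor.eqtl import MapConfig, _lfdr_from_p, call_egenes, cis_pairs, fit_associations, local_fdr, storey_pi0
from pseudofactor.io import ValidationError


def _gt(dosages, chrom, pos):
    dosages = np.asarray(dosages, dtype=float)
    return pf.GenotypeMatrix(
        dosages=dosages,
        individual_ids=np.array([f"i{k}" for k in range(dosages.shape[0])]),
        snp_ids=np.array([f"s{j}" for j in range(dosages.shape[1])]),
        chrom=np.asarray(chrom, dtype=str),
        pos=np.asarray(pos, dtype=np.int64),
    )


def _ann(rows):
    return pf.GeneAnnotation(
        pd.DataFrame(rows, columns=["chrom", "start", "end"], index=pd.Index([f"g{i}" for i in range(len(rows))]))
    )


def _tm(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    return pf.TransformedMatrix(
        values,
        np.array([f"i{k}" for k in range(values.shape[0])]),
        np.array(gene_ids if gene_ids is not None else [f"g{j}" for j in range(values.shape[1])]),
    )


class TestCisPairs:
    def test_window_boundary_inclusive(self):
        rng = np.random.default_rng(0)
        gt = _gt(rng.binomial(2, 0.3, size=(20, 2)), ["1", "1"], [1_000_000, 999_999])
        ann = _ann([["1", 2_000_000, 2_010_000]])
        pairs = cis_pairs(ann, gt, MapConfig())
        assert set(pairs["snp"]) == {"s0"}  # exactly 1 Mb away included, 1 bp further excluded

    def test_maf_filter(self):
        n = 50
        low = np.zeros(n)
        low[:2] = 1.0  # f = 0.02 -> MAF 0.02 < 0.05
        ok = np.zeros(n)
        ok[:10] = 1.0  # f = 0.10
        gt = _gt(np.column_stack([low, ok]), ["1", "1"], [2_000_500, 2_000_600])
        ann = _ann([["1", 2_000_000, 2_010_000]])
        pairs = cis_pairs(ann, gt, MapConfig())
        assert set(pairs["snp"]) == {"s1"}

    def test_matches_exhaustive_double_loop(self):
        rng = np.random.default_rng(1)
        gt = _gt(
            rng.binomial(2, 0.4, size=(30, 10)),
            rng.choice(["1", "2"], size=10),
            rng.integers(1, 5_000_000, size=10),
        )
        ann = _ann(
            [[c, s, s + 10_000] for c, s in zip(rng.choice(["1", "2"], size=3), rng.integers(1, 4_000_000, size=3))]
        )
        cfg = MapConfig()
        pairs = cis_pairs(ann, gt, cfg)
        got = set(zip(pairs["gene"], pairs["snp"]))
        maf = gt.maf()
        expected = set()
        for gi, (gene, rec) in enumerate(ann.table.iterrows()):
            for j in range(gt.n_snps):
                if (
                    gt.chrom[j] == rec["chrom"]
                    and rec["start"] - cfg.cis_window <= gt.pos[j] <= rec["end"] + cfg.cis_window
                    and maf[j] >= cfg.maf_min
                ):
                    expected.add((gene, gt.snp_ids[j]))
        assert got == expected


class TestFitAssociations:
    def test_perfect_fit_capped(self):
        n = 12
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.5, size=n).astype(float)
        y = 1.7 * dos
        gt = _gt(dos[:, None], ["1"], [100])
        tm = _tm(y[:, None])
        pairs = pd.DataFrame({"gene": ["g0"], "snp": ["s0"], "chrom": ["1"], "pos": [100], "snp_idx": [0]})
        res = fit_associations(tm, gt, None, None, 0, pairs)
        assert res.loc[0, "beta"] == pytest.approx(1.7, rel=1e-10)
        assert res.loc[0, "p"] <= np.finfo(float).tiny * 10

    def test_matches_per_pair_normal_equations(self):
        """Residualize-then-correlate equals per-pair OLS (brute-force oracle)."""
        rng = np.random.default_rng(3)
        n, n_genes, n_snps = 60, 10, 15
        Y = rng.normal(size=(n, n_genes))
        dos = rng.binomial(2, 0.3, size=(n, n_snps)).astype(float)
        gt = _gt(dos, ["1"] * n_snps, np.arange(100, 100 + n_snps))
        cov = pf.CovariateTable(
            pd.DataFrame(
                {"sex": rng.integers(0, 2, n).astype(float), "age": rng.uniform(20, 70, n)},
                index=[f"i{k}" for k in range(n)],
            )
        )
        fs = pf.FactorSet(
            scores=rng.normal(size=(n, 3)), weights=np.zeros((n_genes, 3)),
            relevance=np.array([3.0, 2.0, 1.0]), method="pca", K=3,
        )
        tm = _tm(Y)
        pairs = pd.DataFrame(
            [(f"g{i}", f"s{j}", "1", 100 + j, j) for i in range(n_genes) for j in range(n_snps)],
            columns=["gene", "snp", "chrom", "pos", "snp_idx"],
        )
        res = fit_associations(tm, gt, cov, fs, 3, pairs).set_index(["gene", "snp"])
        X_cov = np.column_stack([np.ones(n), cov.values(), fs.scores[:, :3]])
        df = n - X_cov.shape[1] - 1
        for i in range(n_genes):
            for j in range(n_snps):
                X = np.column_stack([X_cov, dos[:, j]])
                beta_hat = np.linalg.solve(X.T @ X, X.T @ Y[:, i])
                resid = Y[:, i] - X @ beta_hat
                sigma2 = resid @ resid / df
                se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
                t = beta_hat[-1] / se
                p = 2 * scipy.stats.t.sf(abs(t), df)
                row = res.loc[(f"g{i}", f"s{j}")]
                assert row["beta"] == pytest.approx(beta_hat[-1], abs=1e-8)
                assert row["se"] == pytest.approx(se, abs=1e-8)
                assert row["t"] == pytest.approx(t, abs=1e-6)
                assert row["p"] == pytest.approx(p, abs=1e-8)

    def test_null_pvalues_uniform(self):
        """Permuted-dosage null: KS statistic against uniform < 0.15."""
        rng = np.random.default_rng(5)
        n = 80
        Y = rng.normal(size=(n, 100))
        dos = rng.binomial(2, 0.4, size=(n, 100)).astype(float)
        for j in range(100):
            dos[:, j] = dos[rng.permutation(n), j]
        gt = _gt(dos, ["1"] * 100, np.arange(1, 101))
        pairs = pd.DataFrame(
            {"gene": [f"g{j}" for j in range(100)], "snp": [f"s{j}" for j in range(100)],
             "chrom": ["1"] * 100, "pos": np.arange(1, 101), "snp_idx": np.arange(100)}
        )
        res = fit_associations(_tm(Y), gt, None, None, 0, pairs)
        ks = scipy.stats.kstest(res["p"], "uniform").statistic
        assert ks < 0.15

    def test_invariant_to_pair_order_and_zero_covariate(self):
        rng = np.random.default_rng(6)
        n = 40
        Y = rng.normal(size=(n, 5))
        dos = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        gt = _gt(dos, ["1"] * 5, np.arange(10, 15))
        pairs = pd.DataFrame(
            {"gene": [f"g{j}" for j in range(5)], "snp": [f"s{j}" for j in range(5)],
             "chrom": ["1"] * 5, "pos": np.arange(10, 15), "snp_idx": np.arange(5)}
        )
        shuffled = pairs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1 = fit_associations(_tm(Y), gt, None, None, 0, pairs).set_index(["gene", "snp"]).sort_index()
        r2 = fit_associations(_tm(Y), gt, None, None, 0, shuffled).set_index(["gene", "snp"]).sort_index()
        pd.testing.assert_frame_equal(r1, r2)
        cov0 = pf.CovariateTable(
            pd.DataFrame({"zero": np.zeros(n)}, index=[f"i{k}" for k in range(n)])
        )
        r3 = fit_associations(_tm(Y), gt, cov0, None, 0, pairs).set_index(["gene", "snp"]).sort_index()
        np.testing.assert_allclose(r1["beta"], r3["beta"], atol=1e-12)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(7)
        n = 30
        x = rng.normal(size=n)
        cov = pf.CovariateTable(
            pd.DataFrame({"a": x, "b": 2 * x}, index=[f"i{k}" for k in range(n)])
        )
        gt = _gt(rng.binomial(2, 0.3, size=(n, 1)).astype(float), ["1"], [5])
        pairs = pd.DataFrame({"gene": ["g0"], "snp": ["s0"], "chrom": ["1"], "pos": [5], "snp_idx": [0]})
        with pytest.raises(ValidationError, match="rank-deficient"):
            fit_associations(_tm(rng.normal(size=(n, 1))), gt, cov, None, 0, pairs)


class TestLocalFdr:
    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=10_000)
        lfdr = _lfdr_from_p(p)
        assert (lfdr < 0.05).mean() <= 0.005

    def test_strong_signal_gets_low_lfdr(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.uniform(0, 1e-6, size=8_000), rng.uniform(size=2_000)])
        lfdr = _lfdr_from_p(p)
        assert np.all(lfdr[:8_000] < 0.05)

    def test_degenerate_pvalues_near_one(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.98, 1.0 - 1e-12, size=500)
        assert storey_pi0(p) == pytest.approx(1.0)
        assert np.all(_lfdr_from_p(p) > 0.95)

    def test_fewer_than_two_distinct_pvalues_rejected(self):
        with pytest.raises(ValidationError, match="distinct"):
            _lfdr_from_p(np.full(200, 0.5))

    def test_per_chromosome_grouping_with_pooled_fallback(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(250)],
                "snp": [f"s{i}" for i in range(250)],
                "chrom": ["1"] * 200 + ["2"] * 50,  # chr2 below min_group_size
                "pos": np.arange(250),
                "p": rng.uniform(size=250),
            }
        )
        out = local_fdr(table, MapConfig())
        assert out["lfdr"].notna().all()
        assert out["lfdr"].between(0, 1).all()


class TestCallEgenes:
    def _table(self, lfdrs):
        return pd.DataFrame(
            {"gene": ["g"] * len(lfdrs), "snp": [f"s{i}" for i in range(len(lfdrs))], "lfdr": lfdrs}
        )

    def test_below_threshold_is_egene(self):
        out = call_egenes(self._table([0.03, 0.2]))
        assert bool(out.loc[0, "is_egene"]) and out.loc[0, "n_significant"] == 1

    def test_exact_threshold_not_egene(self):
        out = call_egenes(self._table([0.05, 0.5]))
        assert not bool(out.loc[0, "is_egene"])

    def test_empty_table(self):
        out = call_egenes(pd.DataFrame(columns=["gene", "snp", "lfdr"]))
        assert out.empty
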