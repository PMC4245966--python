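"""Surrogate variable estimation: residualization, dimension choice,
weighting, weighted extraction, and the assembled algorithms."""

import numpy as np
import pandas as pd
import pytest

import svaseq as sv
from svaseq.sva import block_f_pvalues


def _design(y, adjust=None):
    n = len(y)
    return sv.DesignInfo(
        [f"s{j}" for j in range(n)],
        primary=pd.DataFrame({"group": np.asarray(y, dtype=float)}),
        known_adjust=(pd.DataFrame({"a": adjust}) if adjust is not None
                      else pd.DataFrame(index=range(n))),
    )


class TestResidualize:
    def test_intercept_only_is_mean_centering(self):
        out = sv.residualize(np.array([[1.0, 2.0, 3.0]]), np.ones((3, 1)))
        np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]], atol=1e-12)

    def test_exact_fit_gives_zero_residuals(self):
        design = np.column_stack([np.ones(4), [0.0, 0.0, 1.0, 1.0]])
        out = sv.residualize(np.array([[1.0, 1.0, 3.0, 3.0]]), design)
        np.testing.assert_allclose(out, np.zeros((1, 4)), atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        xt = rng.normal(size=(10, 6))
        design = np.column_stack([np.ones(6), rng.normal(size=(6, 2))])
        # explicit (X'X)^{-1} X' solution
        beta = np.linalg.inv(design.T @ design) @ design.T @ xt.T
        expected = xt - (design @ beta).T
        np.testing.assert_allclose(sv.residualize(xt, design), expected,
                                   atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        xt = rng.normal(size=(20, 8))
        design = np.column_stack([np.ones(8), rng.normal(size=8)])
        resid = sv.residualize(xt, design)
        inner = np.abs(resid @ design)
        assert inner.max() <= 1e-8 * np.abs(xt).max()

    def test_rank_deficient_design_rejected(self):
        design = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(sv.SvaseqError, match="rank deficient"):
            sv.residualize(np.zeros((3, 5)), design)


class TestEstimateNumSv:
    def test_pure_noise_false_detection_matches_alpha(self):
        # permuting an iid matrix within rows reproduces its own null, so
        # by construction the first component exceeds the 90% null quantile
        # in ~alpha = 10% of draws; check the rate is in the binomial band
        hits = 0
        n_trials = 100
        for s in range(n_trials):
            xt = np.random.default_rng(s).normal(size=(500, 12))
            q = sv.estimate_num_sv(xt, np.ones((12, 1)), n_perm=50, seed=s)
            hits += q == 0
        assert 82 <= hits <= 98  # 99% band around 90/100

    def test_planted_factor_detected(self, rng):
        u = rng.normal(size=12)
        d = rng.normal(size=500)
        noise = rng.normal(size=(500, 12))
        scale = 10 * np.linalg.norm(noise) / (np.linalg.norm(d) * np.linalg.norm(u))
        xt = noise + scale * np.outer(d, u)
        q = sv.estimate_num_sv(xt, np.ones((12, 1)), n_perm=50, seed=0)
        assert q >= 1

    def test_no_residual_df_errors(self):
        with pytest.raises(sv.SvaseqError):
            sv.estimate_num_sv(np.zeros((10, 3)), np.ones((3, 2)), seed=0)

    def test_deterministic_given_seed(self, rng):
        xt = rng.normal(size=(100, 10))
        q1 = sv.estimate_num_sv(xt, np.ones((10, 1)), n_perm=30, seed=7)
        q2 = sv.estimate_num_sv(xt, np.ones((10, 1)), n_perm=30, seed=7)
        assert q1 == q2

    def test_n_perm_below_one_errors(self):
        with pytest.raises(sv.SvaseqError, match="n_perm"):
            sv.estimate_num_sv(np.zeros((5, 6)), np.ones((6, 1)), n_perm=0,
                               seed=0)


class TestLfdr:
    def test_all_ones_is_pure_null(self):
        out = sv.lfdr_from_pvalues(np.ones(100))
        np.testing.assert_array_equal(out, np.ones(100))

    def test_two_group_mixture_orders_correctly(self, rng):
        p = np.concatenate([np.full(50, 1e-6), rng.uniform(size=50)])
        out = sv.lfdr_from_pvalues(p)
        assert out[0] < 0.5
        assert out[np.argmax(p)] > out[np.argmin(p)]

    def test_constant_half_gives_single_value(self):
        out = sv.lfdr_from_pvalues(np.full(100, 0.5))
        assert len(np.unique(out)) == 1

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        out = sv.lfdr_from_pvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_out_of_range_and_short_inputs_error(self):
        with pytest.raises(sv.SvaseqError):
            sv.lfdr_from_pvalues(np.array([0.5] * 19 + [1.5]))
        with pytest.raises(sv.SvaseqError):
            sv.lfdr_from_pvalues(np.full(10, 0.5))


@pytest.fixture(scope="module")
def planted():
    # a realistic mixture background: a third of the genes load on the
    # artifact (otherwise the p-value density near zero is empty and no
    # local-fdr estimate can recognize an isolated signal gene)
    rng = np.random.default_rng(5)
    n = 12
    y = np.repeat([0.0, 1.0], 6)
    u = np.tile([0.0, 1.0], 6)  # orthogonal to y
    xt = rng.normal(size=(1000, n))
    loaders = np.arange(100, 400)
    xt[loaders] += np.outer(rng.normal(0, 3.0, size=loaders.size), u)
    xt[0] = 3.0 * u + 0.1 * rng.normal(size=n)   # artifact gene
    xt[1] = y.copy()                              # pure phenotype gene
    design = _design(y)
    factors = sv.LatentFactors((u - u.mean())[:, None]
                               / np.linalg.norm(u - u.mean()))
    return sv.estimate_weights(xt, design, factors)


class TestEstimateWeights:
    def test_supervised_indicator(self):
        xt = np.zeros((5, 4))
        w = sv.estimate_weights(
            xt, None, controls=sv.GeneSet(frozenset({"g2", "g4"})),
            mode="supervised", gene_ids=["g1", "g2", "g3", "g4", "g5"])
        np.testing.assert_array_equal(w.lam, [0, 1, 0, 1, 0])
        assert w.mode == "supervised"

    def test_disjoint_controls_error(self):
        with pytest.raises(sv.SvaseqError, match="disjoint"):
            sv.estimate_weights(
                np.zeros((2, 4)), None,
                controls=sv.GeneSet(frozenset({"nope"})), mode="supervised",
                gene_ids=["g1", "g2"])

    def test_artifact_gene_upweighted(self, planted):
        # the local-fdr product is deliberately conservative (isotonic
        # pooling near p = 0), so a strong artifact gene lands well above
        # the background but below 1
        assert planted.lam[0] > 0.6
        assert planted.lam[0] > 10 * np.median(planted.lam)

    def test_phenotype_gene_downweighted(self, planted):
        assert planted.lam[1] < 0.2

    def test_weights_within_unit_interval(self, planted):
        assert np.all((planted.lam >= 0) & (planted.lam <= 1))

    def test_weight_monotone_in_artifact_loading(self):
        # growing the gene's loading on the planted factor must not push
        # its weight down (phenotype association held at zero)
        rng = np.random.default_rng(9)
        n = 12
        y = np.repeat([0.0, 1.0], 6)
        u = np.tile([0.0, 1.0], 6)
        background = rng.normal(size=(1000, n))
        loaders = np.arange(100, 400)
        background[loaders] += np.outer(rng.normal(0, 1.5, loaders.size), u)
        noise = rng.normal(size=n)
        design = _design(y)
        factors = sv.LatentFactors((u - u.mean())[:, None]
                                   / np.linalg.norm(u - u.mean()))
        lams = []
        for a in [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]:
            xt = background.copy()
            xt[0] = a * u + 0.3 * noise
            w = sv.estimate_weights(xt, design, factors)
            lams.append(w.lam[0])
        assert np.all(np.diff(lams) >= -0.05)
        assert lams[-1] > lams[0]


class TestFactorExtract:
    def test_noiseless_rank_one_recovery(self, rng):
        u = rng.normal(size=10)
        u -= u.mean()
        d = rng.normal(size=50)
        xt = np.outer(d, u)
        fac = sv.factor_extract(xt, np.ones(50), 1)
        r = np.corrcoef(fac.values[:, 0], u)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10
        np.testing.assert_allclose(np.linalg.norm(fac.values[:, 0]), 1.0,
                                   atol=1e-12)

    def test_unit_weights_match_direct_svd(self, rng):
        xt = rng.normal(size=(80, 9))
        centered = xt - xt.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        fac = sv.factor_extract(xt, np.ones(80), 3)
        for k in range(3):
            v = vt[k]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(fac.values[:, k], v, atol=1e-10)

    def test_zero_weighted_rows_cannot_influence_output(self, rng):
        xt = rng.normal(size=(100, 8))
        lam = np.zeros(100)
        lam[:30] = 1.0
        fac1 = sv.factor_extract(xt, lam, 2)
        corrupted = xt.copy()
        corrupted[30:] = rng.normal(size=(70, 8)) * 1e6  # mutate λ=0 rows
        fac2 = sv.factor_extract(corrupted, lam, 2)
        np.testing.assert_allclose(fac1.values, fac2.values, atol=1e-10)

    def test_weights_zeroing_signal_rows_lose_the_factor(self, rng):
        n = 12
        u = np.tile([-1.0, 1.0], 6)
        xt = rng.normal(size=(1000, n))
        carriers = np.arange(200)
        xt[carriers] += np.outer(rng.normal(2, 0.5, size=200), u)
        lam = np.ones(1000)
        lam[carriers] = 0.0
        with_signal = sv.factor_extract(xt, np.ones(1000), 1)
        fac = sv.factor_extract(xt, lam, 1)
        r_with = abs(np.corrcoef(with_signal.values[:, 0], u)[0, 1])
        r_without = abs(np.corrcoef(fac.values[:, 0], u)[0, 1])
        assert r_with > 0.95
        assert r_without < 0.5  # a noise direction in 12 samples

    def test_all_zero_weights_error(self):
        with pytest.raises(sv.SvaseqError, match="all weights"):
            sv.factor_extract(np.ones((5, 4)), np.zeros(5), 1)

    def test_q_exceeding_samples_errors(self):
        with pytest.raises(sv.SvaseqError, match="exceeds"):
            sv.factor_extract(np.ones((5, 4)), np.ones(5), 4)


class TestSvaseqPipeline:
    def test_supervised_recovers_planted_batch_across_seeds(self):
        rs = []
        for seed in range(20):
            d = sv.simulate_dataset(sv.SimConfig(seed=seed))
            res = sv.svaseq(d.counts, d.design, "supervised",
                            controls=d.controls, n_sv=1)
            rs.append(abs(np.corrcoef(res.factors.values[:, 0], d.u)[0, 1]))
        assert np.median(rs) >= 0.95

    def test_zero_sv_request_is_noop(self, small_dataset):
        d = small_dataset
        res = sv.svaseq(d.counts, d.design, "irw", n_sv=0)
        assert res.n_sv == 0
        assert res.factors.n_factors == 0
        assert res.weights.lam.shape == (d.counts.n_genes,)

    def test_irw_orthogonal_scenario_tracks_batch_not_group(self):
        d = sv.simulate_dataset(sv.SimConfig(seed=2, design_r2=0.0))
        res = sv.svaseq(d.counts, d.design, "irw", n_sv=1, seed=2)
        f = res.factors.values[:, 0]
        assert abs(np.corrcoef(f, d.u)[0, 1]) >= 0.9
        assert abs(np.corrcoef(f, d.y)[0, 1]) <= 0.3

    def test_forced_supervised_weights_reproduce_supervised_output(self, small_dataset):
        d = small_dataset
        xt = sv.moderated_log(d.counts)
        mask = np.array([g in d.controls.ids for g in d.counts.gene_ids])
        forced = sv.factor_extract(xt, mask.astype(float), 1)
        supervised = sv.svaseq(d.counts, d.design, "supervised",
                               controls=d.controls, n_sv=1)
        np.testing.assert_allclose(forced.values,
                                   supervised.factors.values, atol=1e-12)

    def test_noiseless_single_factor_all_methods_agree(self, rng):
        # counts exp(d_i u_j): one artifact, no phenotype effect, no noise
        n = 8
        u = np.tile([0.0, 1.0], 4)
        d_load = rng.uniform(0.5, 1.5, size=60)
        counts = sv.CountMatrix(
            100.0 * np.exp(np.outer(d_load, u)),
            [f"g{i}" for i in range(60)], [f"s{j}" for j in range(n)])
        design = _design(np.repeat([0.0, 1.0], 4))
        controls = sv.GeneSet(frozenset(f"g{i}" for i in range(30)))
        outs = [
            sv.svaseq(counts, design, "irw", n_sv=1, seed=0).factors,
            sv.svaseq(counts, design, "two_step", n_sv=1, seed=0).factors,
            sv.svaseq(counts, design, "supervised", controls=controls,
                      n_sv=1).factors,
        ]
        for fac in outs[1:]:
            r = np.corrcoef(outs[0].values[:, 0], fac.values[:, 0])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-10

    def test_supervised_invariant_to_non_control_corruption(self, small_dataset):
        d = small_dataset
        res1 = sv.svaseq(d.counts, d.design, "supervised",
                         controls=d.controls, n_sv=1)
        corrupted = d.counts.values.copy()
        mask = np.array([g in d.controls.ids for g in d.counts.gene_ids])
        rng = np.random.default_rng(0)
        corrupted[~mask] = rng.integers(0, 10_000, size=corrupted[~mask].shape)
        cm = sv.CountMatrix(corrupted, d.counts.gene_ids, d.counts.sample_ids)
        res2 = sv.svaseq(cm, d.design, "supervised", controls=d.controls,
                         n_sv=1)
        np.testing.assert_allclose(res1.factors.values, res2.factors.values,
                                   atol=1e-12)

    def test_irw_requires_primary(self, small_dataset):
        bare = sv.DesignInfo(
            small_dataset.counts.sample_ids,
            primary=pd.DataFrame(index=range(12)),
            known_adjust=pd.DataFrame(index=range(12)),
        )
        with pytest.raises(sv.SvaseqError, match="primary"):
            sv.svaseq(small_dataset.counts, bare, "irw", n_sv=1)

    def test_supervised_requires_controls(self, small_dataset):
        with pytest.raises(sv.SvaseqError, match="control"):
            sv.svaseq(small_dataset.counts, small_dataset.design,
                      "supervised", n_sv=1)


class TestBlockFTest:
    def test_matches_scipy_anova_on_single_gene(self):
        # one-way two-group comparison equals the textbook F = t^2 test
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        vals = np.array([[1.0, 2.0, 1.5, 3.0, 3.5, 2.8]])
        full = np.column_stack([np.ones(6), y])
        reduced = np.ones((6, 1))
        p = block_f_pvalues(vals, full, reduced)
        import scipy.stats
        t, p_t = scipy.stats.ttest_ind(vals[0, 3:], vals[0, :3])
        np.testing.assert_allclose(p[0], p_t, rtol=1e-10)


def test_cross_check_against_bioconductor_sva(tmp_path):
    """Independent oracle: the Bioconductor sva package's svaseq on a small
    simulated dataset should produce a first surrogate highly correlated
    with ours (algorithms differ in weighting details, so the check is on
    agreement, not equality)."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    d = sv.simulate_dataset(sv.SimConfig(m=400, n=12, seed=8))
    counts_path = tmp_path / "counts.tsv"
    sv.write_counts(d.counts, counts_path)
    script = tmp_path / "run_sva.R"
    y_r = ", ".join(str(int(v)) for v in d.y)
    script.write_text(f"""
suppressMessages(library(sva))
x <- as.matrix(read.delim("{counts_path}", row.names = 1))
group <- c({y_r})
mod <- model.matrix(~group)
mod0 <- model.matrix(~1, data = data.frame(group))
res <- svaseq(x, mod, mod0, n.sv = 1)
write.table(res$sv, "{tmp_path / 'sv.txt'}", row.names = FALSE,
            col.names = FALSE)
""")
    proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                          text=True, timeout=300)
    if proc.returncode != 0:
        pytest.skip(f"Rscript sva failed: {proc.stderr[-300:]}")
    ref = np.loadtxt(tmp_path / "sv.txt")
    ours = sv.svaseq(d.counts, d.design, "irw", n_sv=1, seed=8)
    r = np.corrcoef(ours.factors.values[:, 0], ref)[0, 1]
    assert abs(r) > 0.9
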