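"""Background correction, quantile normalization, concordance and
moderated differential statistics."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from droughtmem.preprocess_stats import (
    ExpressionMatrix,
    background_correct,
    estimate_prior,
    filter_significant,
    moderated_differential,
    quantile_normalize,
    replicate_concordance,
    summarize_probes,
    _quantile_normalize_array,
)

from conftest import make_matrix


class TestBackground:
    def test_subtraction_with_floor(self):
        m = make_matrix(np.tile([[10.0], [100.0], [1000.0]], (1, 8)),
                        scale="raw")
        out = background_correct(m, offset=1.0, percentile=0.0)
        np.testing.assert_allclose(out.values.iloc[:, 0], [1.0, 90.0, 990.0])

    def test_all_equal_column_floors_to_offset(self):
        m = make_matrix(np.full((5, 8), 7.0), scale="raw")
        out = background_correct(m, offset=1.0)
        assert (out.values.to_numpy() == 1.0).all()

    def test_nonpositive_offset_rejected(self):
        m = make_matrix(np.ones((3, 8)), scale="raw")
        with pytest.raises(ValueError, match="offset"):
            background_correct(m, offset=0.0)


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        x = np.array([[1.0, 2.0], [3.0, 6.0]])
        out = _quantile_normalize_array(x)
        np.testing.assert_allclose(out, [[1.5, 1.5], [4.5, 4.5]])

    def test_identical_columns_fixed_point(self):
        col = np.array([2.0, 5.0, 9.0, 1.0])
        x = np.column_stack([col, col, col])
        np.testing.assert_allclose(_quantile_normalize_array(x), x)

    def test_ties_share_mean_of_rank_targets(self):
        x = np.array([[2.0, 1.0], [2.0, 3.0], [8.0, 9.0]])
        out = _quantile_normalize_array(x)
        # targets: mean of sorted columns = (1.5, 2.5, 8.5); the tie in
        # column 1 (ranks 1-2) gets mean(1.5, 2.5) = 2.0
        np.testing.assert_allclose(out[:, 0], [2.0, 2.0, 8.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 2.5, 8.5])

    def test_single_column_unchanged(self):
        m = ExpressionMatrix(
            values=pd.DataFrame({"s1": [1.0, 2.0]}),
            sample_meta=pd.DataFrame(
                {"condition": ["WT1"], "replicate": [1]}, index=["s1"]
            ),
            scale="log2",
        )
        assert quantile_normalize(m).values.equals(m.values)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        x=arrays(
            np.float64,
            (17, 5),
            elements=st.floats(min_value=-20, max_value=20,
                               allow_nan=False, allow_infinity=False),
        )
    )
    def test_columns_share_one_multiset(self, x):
        out = _quantile_normalize_array(x)
        ref = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            col = np.sort(out[:, j])
            if all(len(np.unique(x[:, j])) == x.shape[0] for j in range(x.shape[1])):
                np.testing.assert_allclose(col, ref, atol=1e-12)

    def test_agrees_with_limma_normalizeQuantiles(self, tmp_path):
        """Independent oracle: Bioconductor limma on the same matrix."""
        rng = np.random.default_rng(0)
        x = rng.normal(8, 2, size=(40, 6))
        np.savetxt(tmp_path / "x.tsv", x, delimiter="\t")
        script = (
            "suppressMessages(library(limma));"
            f"x <- as.matrix(read.delim('{tmp_path}/x.tsv', header=FALSE));"
            f"write.table(normalizeQuantiles(x), '{tmp_path}/out.tsv',"
            "sep='\\t', row.names=FALSE, col.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        expected = np.loadtxt(tmp_path / "out.tsv", delimiter="\t")
        np.testing.assert_allclose(_quantile_normalize_array(x), expected,
                                   atol=1e-8)


class TestConcordance:
    def test_identity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert replicate_concordance(x, x) == (1.0, 0.0, 1.0)

    def test_exact_linear_map(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r = replicate_concordance(x, 2 * x + 1)
        np.testing.assert_allclose([slope, intercept, r], [2.0, 1.0, 1.0])

    def test_degenerate_regressor(self):
        with pytest.raises(ValueError, match="degenerate"):
            replicate_concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSummarize:
    def test_median_collapse(self):
        m = make_matrix(
            [[1.0] * 8, [3.0] * 8, [10.0] * 8, [5.0] * 8], scale="log2",
            row_ids=["p1", "p2", "p3", "q1"],
        )
        mapping = pd.Series({"p1": "tA", "p2": "tA", "p3": "tA", "q1": "tB"})
        out = summarize_probes(m, mapping)
        assert out.values.loc["tA"].tolist() == [3.0] * 8
        assert out.values.loc["tB"].tolist() == [5.0] * 8
        out_mean = summarize_probes(m, mapping, how="mean")
        np.testing.assert_allclose(out_mean.values.loc["tA"], 14.0 / 3)


def ordinary_t(m, a, b):
    """Independent per-row linear-model t: residual variance pooled over
    within-condition scatter, no shrinkage."""
    conds = list(dict.fromkeys(m.sample_meta["condition"]))
    X = m.values
    means = {c: m.condition_columns(c).mean(axis=1) for c in conds}
    ss = sum(
        ((m.condition_columns(c).T - means[c]).T ** 2).sum(axis=1)
        for c in conds
    )
    d = X.shape[1] - len(conds)
    s2 = ss / d
    na = (m.sample_meta["condition"] == a).sum()
    nb = (m.sample_meta["condition"] == b).sum()
    return (means[a] - means[b]) / np.sqrt(s2 * (1 / na + 1 / nb))


class TestModeratedT:
    @pytest.fixture
    def random_matrix(self):
        rng = np.random.default_rng(7)
        base = rng.normal(8, 1, size=(200, 1))
        return make_matrix(base + rng.normal(0, 0.4, size=(200, 8)))

    def test_zero_prior_df_equals_ordinary_t(self, random_matrix):
        res = moderated_differential(random_matrix, prior_df=0.0)
        expected = ordinary_t(random_matrix, "DR1", "WT1")
        np.testing.assert_allclose(res.table["t_DR1_WT1"], expected,
                                   rtol=1e-10)

    def test_infinite_prior_df_pools_variance(self, random_matrix):
        res_inf = moderated_differential(random_matrix, prior_df=np.inf)
        res_big = moderated_differential(random_matrix, prior_df=1e9)
        np.testing.assert_allclose(
            res_inf.table["t_DR1_WT1"], res_big.table["t_DR1_WT1"], rtol=1e-5
        )
        # variance used is constant across rows
        t = res_inf.table
        ratio = t["lfc_DR1_WT1"] / t["t_DR1_WT1"]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_equal_variance_rows_unchanged_by_shrinkage(self):
        # rows engineered to share the same residual variance exactly
        base = np.zeros((50, 8))
        pattern = np.array([0.5, -0.5, 0.5, -0.5, 0.5, -0.5, 0.5, -0.5])
        rng = np.random.default_rng(1)
        shifts = rng.normal(0, 3, size=(50, 1))
        m = make_matrix(base + pattern + shifts)
        res0 = moderated_differential(m, prior_df=0.0)
        res5 = moderated_differential(m, prior_df=5.0)
        np.testing.assert_allclose(
            res0.table["t_DR1_WT1"], res5.table["t_DR1_WT1"], rtol=1e-8
        )

    def test_planted_rows_dominate_small_adjusted_p(self):
        rng = np.random.default_rng(3)
        n, planted = 1000, 50
        x = rng.normal(8, 0.25 / np.sqrt(1), size=(n, 8))
        x = rng.normal(0, 0.25, size=(n, 8)) + 8.0
        dr_cols = [2, 3, 6, 7]  # DR1 and DR2 replicates
        x[:planted, dr_cols] += 2.0
        m = make_matrix(x)
        res = moderated_differential(m)
        top = set(res.table["adj_p_DR1_WT1"].nsmallest(planted).index)
        recovered = len(top & {f"t{i}" for i in range(planted)}) / planted
        assert recovered >= 0.90

    def test_missing_replicate_errors(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(5, 8)))
        broken = ExpressionMatrix(
            values=m.values.iloc[:, :7],
            sample_meta=m.sample_meta.iloc[:7],
            scale="log2",
        )
        with pytest.raises(ValueError, match="DR2"):
            moderated_differential(broken)

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent oracle: limma lmFit + eBayes moderated t on the
        same design (condition means, three contrasts)."""
        rng = np.random.default_rng(11)
        x = rng.normal(8, 1, size=(120, 8)) + rng.normal(
            0, 0.3, size=(120, 8)
        )
        m = make_matrix(x)
        res = moderated_differential(m)
        df = pd.DataFrame(x)
        df.to_csv(tmp_path / "x.tsv", sep="\t", index=False, header=False)
        script = f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim('{tmp_path}/x.tsv', header=FALSE))
cond <- factor(rep(c('WT1','DR1','WT2','DR2'), each=2),
               levels=c('WT1','DR1','WT2','DR2'))
design <- model.matrix(~0+cond)
colnames(design) <- levels(cond)
fit <- lmFit(x, design)
cm <- makeContrasts(DR1-WT1, WT2-WT1, DR2-DR1, levels=design)
fit2 <- eBayes(contrasts.fit(fit, cm))
out <- data.frame(t1=fit2$t[,1], t2=fit2$t[,2], t3=fit2$t[,3],
                  d0=fit2$df.prior, s02=fit2$s2.prior)
write.table(out, '{tmp_path}/out.tsv', sep='\\t', row.names=FALSE)
"""
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        np.testing.assert_allclose(res.d0, ref["d0"].iloc[0], rtol=0.05)
        np.testing.assert_allclose(res.s0_2, ref["s02"].iloc[0], rtol=0.05)
        np.testing.assert_allclose(res.table["t_DR1_WT1"], ref["t1"],
                                   rtol=0.02, atol=0.02)
        np.testing.assert_allclose(res.table["t_DR2_DR1"], ref["t3"],
                                   rtol=0.02, atol=0.02)


class TestFilterAndBH:
    def _result(self):
        rng = np.random.default_rng(5)
        x = 8.0 + rng.normal(0, 0.3, size=(60, 8))
        x[0, [2, 3, 6, 7]] += 1.5   # significant and large level
        x[1, [2, 3, 6, 7]] += 0.8   # significant but small level
        return moderated_differential(make_matrix(x))

    def test_joint_p_and_level_filter(self):
        res = self._result()
        kept = filter_significant(res, alpha=0.05, level_cut=1.0)
        assert "t0" in kept and "t1" not in kept

    def test_level_only_never_suffices(self):
        res = self._result()
        table = res.table.copy()
        # a row with huge level but no significance must be excluded
        adj_cols = [c for c in table.columns if c.startswith("adj_p_")]
        fake = res.table.copy()
        fake.loc["t2", adj_cols] = 0.5
        fake.loc["t2", "max_abs_level"] = 3.0
        res.table = fake
        kept = filter_significant(res)
        assert "t2" not in kept

    def test_bh_is_monotone(self):
        rng = np.random.default_rng(9)
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500)
        adj = multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestPriorEstimation:
    def test_recovers_known_prior(self):
        rng = np.random.default_rng(2)
        d, d0, s0_2 = 4, 8.0, 0.09
        n = 20000
        s2 = s0_2 * stats.f.rvs(d, d0, size=n, random_state=rng)
        # s^2 | true variance v ~ v * chi2_d / d with v ~ s0^2 d0/chi2_d0
        d0_hat, s0_hat = estimate_prior(s2, d)
        assert abs(d0_hat - d0) / d0 < 0.15
        assert abs(s0_hat - s0_2) / s0_2 < 0.05
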