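"""Moderated-t differential expression, BH adjustment, polarization scoring."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from slemod.data import GeneSetCollection, SLE_ACTIVE, SLE_INACTIVE
from slemod.diffexp import (
    ModeratedTTest,
    adjust_bh,
    common_foldchange_compare,
    fit_moderated_t,
    polarization_fraction,
    select_de,
)
from slemod.simulate import SyntheticConfig, generate_dataset
from slemod.workflows import de_workflow

from conftest import make_eset


def bruteforce_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i in range(m):
        q[order[rank_i]] = min(
            min(p[order[j]] * m / (j + 1) for j in range(rank_i, m)), 1.0
        )
    return q


class TestModeratedT:
    def test_equal_groups_give_zero_t_unit_p(self, rng):
        # one informative comparison plus filler genes for prior estimation
        vals = np.vstack([[1, 2, 3, 1, 2, 3], rng.normal(0, 1, (30, 6))])
        eset = make_eset(vals)
        de = fit_moderated_t(eset, eset.sample_ids[:3], eset.sample_ids[3:])
        first = de.table.iloc[0]
        assert first["log2fc"] == pytest.approx(0.0, abs=1e-12)
        assert first["t"] == pytest.approx(0.0, abs=1e-12)
        assert first["p"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_limma_reference(self, rng, tmp_path):
        """Independent oracle: R limma lmFit + eBayes on the same matrix."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        X = rng.standard_normal((80, 12)) * rng.uniform(0.5, 2, (80, 1)) + 7
        X[:10, :6] += 1.5
        frame = pd.DataFrame(
            X, index=[f"G{i}" for i in range(80)],
            columns=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)],
        )
        frame.to_csv(tmp_path / "expr.csv")
        script = tmp_path / "limma.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"x <- as.matrix(read.csv('{tmp_path}/expr.csv', row.names=1))\n"
            "design <- cbind(Intercept=1, grp=c(rep(1,6), rep(0,6)))\n"
            "fit <- eBayes(lmFit(x, design))\n"
            "out <- data.frame(logFC=fit$coefficients[,'grp'], t=fit$t[,'grp'],"
            " p=fit$p.value[,'grp'], d0=fit$df.prior, s02=fit$s2.prior)\n"
            f"write.csv(out, '{tmp_path}/limma_out.csv')\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma_out.csv", index_col=0)

        est = ModeratedTTest(baseline="b").fit(
            X.T, np.array(["a"] * 6 + ["b"] * 6)
        )
        assert est.prior_df_ == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert est.prior_var_ == pytest.approx(ref["s02"].iloc[0], rel=1e-6)
        assert np.abs(est.t_ - ref["t"].to_numpy()).max() < 1e-8
        assert np.abs(est.p_values_ - ref["p"].to_numpy()).max() < 1e-8
        assert np.abs(est.log2fc_ - ref["logFC"].to_numpy()).max() < 1e-10

    def test_null_pvalues_uniform(self, rng):
        X = rng.standard_normal((2000, 20))
        est = ModeratedTTest().fit(X.T, np.array(["a"] * 10 + ["b"] * 10))
        ks = stats.kstest(est.p_values_, "uniform")
        assert ks.pvalue > 0.01

    def test_infinite_prior_df_limit(self):
        """Equal residual variances: d0 -> inf and t = delta / (s0 sqrt(2/n))."""
        rng = np.random.default_rng(0)
        A = rng.standard_normal((50, 4))
        X = np.hstack([A, A + rng.uniform(-1, 1, (50, 1))])  # identical spreads
        # force identical per-gene variances by using one shared residual pattern
        resid = rng.standard_normal(8)
        X = np.outer(np.ones(50), resid) + rng.uniform(-1, 1, (50, 1)) * np.array([0] * 4 + [1] * 4)
        est = ModeratedTTest(baseline="b").fit(X.T, np.array(["a"] * 4 + ["b"] * 4))
        assert np.isinf(est.prior_df_)
        expected = est.log2fc_ / np.sqrt(est.prior_var_ * (1 / 4 + 1 / 4))
        assert np.allclose(est.t_, expected)

    def test_zero_prior_df_limit_is_ordinary_t(self, rng):
        """With d0 = 0 the moderated construction is the two-sample pooled t."""
        X = rng.standard_normal((100, 14))
        y = np.array(["a"] * 7 + ["b"] * 7)
        est = ModeratedTTest(baseline="b").fit(X.T, y)
        plain_t = est.log2fc_ / np.sqrt(est.s2_ * (1 / 7 + 1 / 7))
        ref = stats.ttest_ind(X[:, :7], X[:, 7:], axis=1)
        assert np.allclose(plain_t, ref.statistic, atol=1e-10)

    def test_zero_variance_gene_shrunk_to_finite_t(self, rng):
        vals = np.vstack([np.repeat([5.0, 9.0], 5), rng.normal(0, 1, (40, 10))])
        eset = make_eset(vals)
        de = fit_moderated_t(eset, eset.sample_ids[:5], eset.sample_ids[5:])
        assert np.isfinite(de.table.iloc[0]["t"])
        assert de.table.iloc[0]["p"] < 0.05  # clear shift, shrunk variance > 0

    def test_small_groups_rejected(self, small_eset):
        with pytest.raises(ValueError, match="two samples"):
            fit_moderated_t(small_eset, small_eset.sample_ids[:1], small_eset.sample_ids[1:])

    def test_overlapping_groups_rejected(self, small_eset):
        with pytest.raises(ValueError, match="disjoint"):
            fit_moderated_t(small_eset, small_eset.sample_ids[:3], small_eset.sample_ids[2:])


class TestAdjustBH:
    def test_stepup_hand_example(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue(self):
        assert adjust_bh([1.0]) == pytest.approx([1.0])

    def test_matches_bruteforce_and_statsmodels(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 60))
            q = adjust_bh(p)
            assert np.abs(q - bruteforce_bh(p)).max() < 1e-12
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_rank_monotone_and_permutation_invariant(self, p):
        """Adjusted values are monotone in p-rank and permutation-equivariant."""
        p = np.array(p)
        q = adjust_bh(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(adjust_bh(p[perm]), q[perm])


class TestSelectDE:
    def _de(self, fdr, p=None, index=None):
        from slemod.diffexp import DEResult
        n = len(fdr)
        table = pd.DataFrame(
            {
                "log2fc": np.ones(n),
                "s2": np.ones(n),
                "t": np.ones(n),
                "p": p if p is not None else np.asarray(fdr) / 2,
                "fdr": fdr,
                "direction": ["up"] * n,
            },
            index=index if index is not None else [f"g{i}" for i in range(n)],
        )
        return DEResult(table=table, prior_df=1, prior_var=1, residual_df=8, contrast=("a", "b"))

    def test_gate_is_strictly_below_cutoff(self):
        out = select_de(self._de([0.1, 0.2, 0.3]), fdr_cut=0.2)
        assert len(out) == 1 and out.index[0] == "g0"

    def test_most_significant_probe_per_gene_kept(self):
        de = self._de([0.01, 0.01], p=[1e-5, 1e-3], index=["p2", "p1"])
        out = select_de(de, probe_map={"p1": "A", "p2": "A"})
        assert list(out.index) == ["A"] and out["probe"].iloc[0] == "p2"

    def test_probe_tie_breaks_to_smallest_id(self):
        de = self._de([0.01, 0.01], p=[1e-4, 1e-4], index=["p9", "p1"])
        out = select_de(de, probe_map={"p1": "A", "p9": "A"})
        assert out["probe"].iloc[0] == "p1"

    def test_cut_of_one_keeps_everything_below_one(self):
        out = select_de(self._de([0.3, 0.99, 0.5]), fdr_cut=1.0)
        assert len(out) == 3


class TestPolarization:
    def test_saturated_fraction(self):
        table = pd.DataFrame({"direction": ["up"] * 8, "log2fc": 1.0}, index=[f"m{i}" for i in range(8)])
        sigs = GeneSetCollection({"M1": [f"m{i}" for i in range(8)]})
        out = polarization_fraction({"SLE_active": table}, sigs)
        assert out.fractions["fraction_up"].iloc[0] == 1.0

    def test_partial_fraction_arithmetic(self):
        table = pd.DataFrame(
            {"direction": ["up"] * 4 + ["down"] * 6, "log2fc": 1.0},
            index=[f"m{i}" for i in range(10)],
        )
        sigs = GeneSetCollection({"M2": [f"m{i}" for i in range(10)]})
        out = polarization_fraction({"SLE_inactive": table}, sigs)
        assert out.fractions["fraction_up"].iloc[0] == pytest.approx(0.4)

    def test_zero_overlap_reported_missing(self):
        table = pd.DataFrame({"direction": ["up"], "log2fc": 1.0}, index=["x"])
        sigs = GeneSetCollection({"M1": ["y"]})
        out = polarization_fraction({"SLE_active": table}, sigs)
        assert np.isnan(out.fractions["fraction_up"].iloc[0])

    def test_planted_m1_signature_mostly_up_in_active(self):
        """Default study conditions: nearly all DE M1 genes up in active SLE."""
        eset, truth = generate_dataset(SyntheticConfig(), seed=12)
        result = de_workflow(eset, signatures=truth.signature_gene_sets())
        fr = result["polarization"].fractions
        m1_active = fr.query("signature == 'M1' and cohort == @SLE_ACTIVE")
        assert m1_active["fraction_up"].iloc[0] >= 0.9


class TestCommonFoldchange:
    def test_intersection_rule_and_delta(self):
        act = pd.DataFrame({"direction": ["up", "up"], "log2fc": [2.0, 1.2]}, index=["a", "b"])
        ina = pd.DataFrame({"direction": ["up", "down"], "log2fc": [1.0, 0.5]}, index=["a", "b"])
        out = common_foldchange_compare(act, ina)
        assert list(out.index) == ["a"]  # b not upregulated in both
        assert out.loc["a", "delta"] == pytest.approx(1.0)

    def test_signature_ordering_on_planted_data(self):
        """M1 genes more up in active, M2 genes more up in inactive."""
        eset, truth = generate_dataset(SyntheticConfig(), seed=12)
        result = de_workflow(eset, signatures=truth.signature_gene_sets())
        common = result["common_foldchange"]
        m1 = common.query("signature == 'M1'")["delta"]
        m2 = common.query("signature == 'M2'")["delta"]
        assert len(m1) and m1.median() > 0
        assert len(m2) and m2.median() < 0
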