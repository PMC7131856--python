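import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iopanel.differential import (
    Contrast,
    ModeratedTTest,
    call_degs,
    deg_table,
    fold_change,
    log_transform,
    overlap,
    signed_fold_change,
    two_group_ttest,
)

from oracles import moderated_t_oracle, pooled_t_oracle, venn_regions_oracle


def _random_logx(rng, n_genes=60, samples=("A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4")):
    sd = rng.lognormal(-1.0, 0.5, n_genes)
    data = rng.normal(6.0, 1.0, (n_genes, 1)) + rng.normal(
        0.0, 1.0, (n_genes, len(samples))
    ) * sd[:, None]
    return pd.DataFrame(
        data,
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=list(samples),
    )


class TestLogTransform:
    def test_known_values_and_oracle(self, rng):
        nrpm = pd.DataFrame({"S1": [0.0, 7.0, 3.0]}, index=["a", "b", "c"])
        logx = log_transform(nrpm, pseudocount=1.0)
        assert logx.loc["a", "S1"] == 0.0
        assert logx.loc["b", "S1"] == 3.0
        random = pd.DataFrame(rng.uniform(0, 1e4, (20, 4)))
        assert np.array_equal(
            log_transform(random, 1.0).to_numpy(),
            np.log2(random.to_numpy() + 1.0),
        )

    def test_rejects_nonpositive_pseudocount(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame({"S1": [1.0]}), pseudocount=0.0)


class TestFoldChange:
    def test_sign_convention(self):
        logx = pd.DataFrame(
            {"A1": [5.0, 3.0, 4.0], "A2": [5.0, 3.0, 4.0],
             "B1": [3.0, 5.0, 4.0], "B2": [3.0, 5.0, 4.0]},
            index=["up", "down", "flat"],
        )
        c = Contrast("t", "unpaired", ["A1", "A2"], ["B1", "B2"])
        fc = fold_change(logx, c)
        assert fc.loc["up", "log2_fc"] == 2.0
        assert fc.loc["up", "fold_change"] == 4.0
        assert fc.loc["down", "fold_change"] == -4.0
        assert abs(fc.loc["flat", "fold_change"]) == 1.0

    def test_threshold_equivalence(self, rng):
        # |fold_change| >= 2 is exactly |log2_fc| >= 1
        lfc = rng.normal(0, 1.5, 500)
        fc = signed_fold_change(lfc)
        assert np.array_equal(np.abs(fc) >= 2.0, np.abs(lfc) >= 1.0)


class TestCallDEGs:
    @pytest.mark.parametrize(
        "fc, p, is_deg, direction",
        [
            (4.0, 0.01, True, "up"),
            (-4.0, 0.01, True, "down"),
            (2.0, 0.049, True, "up"),    # FC boundary inclusive
            (2.0, 0.05, False, "none"),  # p boundary strict
            (1.9, 1e-6, False, "none"),
            (np.nan, np.nan, False, "none"),  # degenerate gene never called
        ],
    )
    def test_calling_rule_boundaries(self, fc, p, is_deg, direction):
        table = pd.DataFrame(
            {"log2_fc": [np.log2(abs(fc)) * np.sign(fc) if fc == fc else np.nan],
             "fold_change": [fc], "p": [p]}
        )
        out = call_degs(table)
        assert bool(out["is_deg"].iloc[0]) is is_deg
        assert out["direction"].iloc[0] == direction

    def test_monotone_in_fc_threshold(self, rng):
        table = pd.DataFrame(
            {
                "log2_fc": rng.normal(0, 1.5, 300),
                "p": rng.uniform(0, 0.2, 300),
            }
        )
        table["fold_change"] = signed_fold_change(table["log2_fc"])
        loose = call_degs(table, fc_threshold=1.5)
        strict = call_degs(table, fc_threshold=2.5)
        assert set(table.index[strict["is_deg"]]) <= set(table.index[loose["is_deg"]])


class TestModeratedT:
    def test_prior_df_zero_is_ordinary_t(self, rng):
        logx = _random_logx(rng)
        X = logx.T
        y = np.array(["a"] * 4 + ["b"] * 4)
        fit = ModeratedTTest(design="unpaired", prior_df=0).fit(X, y)
        ref_t, ref_p = stats.ttest_ind(
            logx.iloc[:, :4], logx.iloc[:, 4:], axis=1, equal_var=True
        )
        assert np.allclose(fit.t_, ref_t, atol=1e-10)
        assert np.allclose(fit.p_value_, ref_p, atol=1e-10)

    def test_infinite_prior_fully_pools_variances(self, rng):
        logx = _random_logx(rng)
        fit = ModeratedTTest(design="unpaired", prior_df=np.inf).fit(
            logx.T, np.array(["a"] * 4 + ["b"] * 4)
        )
        assert np.allclose(fit.s2_post_, fit.s2_prior_)

    def test_common_variance_drives_strong_shrinkage(self, rng):
        # all genes share one true variance -> estimated prior df is large
        data = rng.normal(0.0, 0.7, (400, 10))
        X = pd.DataFrame(data.T, columns=[f"G{i}" for i in range(400)])
        fit = ModeratedTTest(design="unpaired").fit(
            X, np.array(["a"] * 5 + ["b"] * 5)
        )
        assert fit.df_prior_ > 10 * fit.df_residual_
        spread_raw = np.std(fit.s2_residual_)
        spread_post = np.std(fit.s2_post_)
        assert spread_post < 0.2 * spread_raw

    @pytest.mark.parametrize("paired", [False, True])
    def test_matches_independent_oracle(self, rng, paired):
        n = 200
        sd = rng.lognormal(-0.5, 0.6, n)
        xa = 5.0 + rng.normal(0, 1, (n, 6)) * sd[:, None]
        xb = 5.0 + rng.normal(0, 1, (n, 6)) * sd[:, None]
        ot, op, od0, os02 = moderated_t_oracle(xa, xb, paired=paired)
        X = pd.DataFrame(np.hstack([xa, xb]).T)
        y = np.array(["a"] * 6 + ["b"] * 6)
        pairs = np.array(list(range(6)) + list(range(6))) if paired else None
        fit = ModeratedTTest(design="paired" if paired else "unpaired").fit(
            X, y, pairs=pairs
        )
        assert np.isclose(fit.df_prior_, od0, rtol=1e-8) or (
            od0 == np.inf and fit.df_prior_ >= 1e6
        )
        assert np.isclose(fit.s2_prior_, os02, rtol=1e-8)
        assert np.allclose(fit.t_, ot, rtol=1e-8)
        assert np.allclose(fit.p_value_, op, rtol=1e-8)

    def test_matches_limma_reference(self, rng, tmp_path):
        # cross-check the re-implementation against Bioconductor limma
        logx = _random_logx(rng, n_genes=80)
        infile = tmp_path / "x.tsv"
        outfile = tmp_path / "limma.tsv"
        logx.to_csv(infile, sep="\t")
        script = tmp_path / "ref.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.delim(args[1], row.names=1, check.names=FALSE))
            design <- cbind(Intercept=1, avsb=c(rep(1,4), rep(0,4)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,"avsb"], p=fit$p.value[,"avsb"],
                              d0=fit$df.prior, s02=fit$s2.prior)
            write.table(out, args[2], sep="\t", quote=FALSE)
            """
        )
        subprocess.run(
            ["Rscript", str(script), str(infile), str(outfile)],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(outfile, sep="\t")
        fit = ModeratedTTest(design="unpaired").fit(
            logx.T, np.array(["a"] * 4 + ["b"] * 4)
        )
        assert np.isclose(fit.df_prior_, ref["d0"].iloc[0], rtol=1e-6)
        assert np.isclose(fit.s2_prior_, ref["s02"].iloc[0], rtol=1e-6)
        assert np.allclose(fit.t_, ref["t"], rtol=1e-6)
        assert np.allclose(fit.p_value_, ref["p"], rtol=1e-6)

    def test_group_swap_antisymmetry(self, rng):
        logx = _random_logx(rng)
        ca = Contrast("ab", "unpaired", ["A1", "A2", "A3", "A4"], ["B1", "B2", "B3", "B4"])
        cb = Contrast("ba", "unpaired", ["B1", "B2", "B3", "B4"], ["A1", "A2", "A3", "A4"])
        ta = deg_table(logx, ca)
        tb = deg_table(logx, cb)
        assert np.allclose(ta["log2_fc"], -tb["log2_fc"])
        assert np.allclose(ta["t"], -tb["t"])
        assert np.allclose(ta["p"], tb["p"])
        assert (ta["is_deg"] == tb["is_deg"]).all()

    def test_self_paired_contrast_yields_no_degs(self, rng):
        logx = _random_logx(rng, samples=("A1", "A2", "A3", "A4"))
        dup = pd.concat([logx, logx.add_suffix("_copy", axis=1)], axis=1)
        c = Contrast(
            "self", "paired",
            ["A1", "A2", "A3", "A4"],
            ["A1_copy", "A2_copy", "A3_copy", "A4_copy"],
            pairing={f"P{i}": (f"A{i}", f"A{i}_copy") for i in range(1, 5)},
        )
        table = deg_table(dup, c)
        assert np.allclose(table["log2_fc"], 0.0)
        assert not table["is_deg"].any()

    def test_degenerate_genes_flagged_not_called(self, rng):
        logx = _random_logx(rng, n_genes=30)
        logx.iloc[0] = 4.0  # identical in every sample
        c = Contrast("ab", "unpaired", ["A1", "A2", "A3", "A4"], ["B1", "B2", "B3", "B4"])
        table = deg_table(logx, c)
        assert np.isnan(table["p"].iloc[0])
        assert not table["is_deg"].iloc[0]
        assert table["p"].iloc[1:].notna().all()

    def test_bh_column_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        logx = _random_logx(rng)
        c = Contrast("ab", "unpaired", ["A1", "A2", "A3", "A4"], ["B1", "B2", "B3", "B4"])
        table = deg_table(logx, c)
        expect = multipletests(table["p"], method="fdr_bh")[1]
        assert np.allclose(table["bh_q"], expect)


class TestStudentT:
    def test_identical_groups(self):
        assert two_group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_strong_separation(self):
        t, p = two_group_ttest([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert abs(t) > 10 and p < 0.001

    def test_zero_variance_unequal_means(self):
        t, p = two_group_ttest([2.0, 2.0], [1.0, 1.0])
        assert t == np.inf and p == 0.0

    def test_matches_closed_form_oracle(self, rng):
        a = rng.normal(0, 1, 6).tolist()
        b = rng.normal(0.5, 1.3, 7).tolist()
        t, p = two_group_ttest(a, b)
        ot, op = pooled_t_oracle(a, b)
        assert np.isclose(t, ot, atol=1e-10)
        assert np.isclose(p, op, atol=1e-10)


class TestOverlap:
    def test_set_algebra_example(self):
        ov = overlap({"x": {"A", "B", "C"}, "y": {"B", "C", "D"}})
        assert ov.region("x", "y") == ["B", "C"]
        assert ov.region("x") == ["A"]
        assert ov.region("y") == ["D"]

    def test_identical_sets(self):
        ov = overlap({"x": {"A", "B"}, "y": {"A", "B"}})
        assert ov.region("x", "y") == ["A", "B"]
        assert ov.region("x") == [] and ov.region("y") == []

    def test_matches_brute_force_on_random_triples(self, rng):
        genes = [f"G{i}" for i in range(120)]
        for _ in range(25):
            sets = {
                lab: set(rng.choice(genes, size=50, replace=False))
                for lab in ("s1", "s2", "s3")
            }
            ov = overlap(sets)
            labels, expect = venn_regions_oracle(sets)
            got = {k: v for k, v in ov.regions.items() if v}
            assert got == expect
            # conservation: region sizes sum to the union
            assert sum(len(v) for v in ov.regions.values()) == len(
                set().union(*sets.values())
            )
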