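"""Moderated DE, BH-FDR, AUROC ranking and hypergeometric enrichment."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from screpurpose import (
    auroc_markers,
    bh_fdr,
    fit_moderated_de,
    ora_hypergeom,
    significant_genes,
)


def _two_group_frame(rng, n_genes=80, na=8, nb=8, shift=0.0):
    X = rng.normal(5.0, 1.0, size=(na + nb, n_genes))
    X[:na] += shift
    groups = np.array(["A"] * na + ["B"] * nb)
    return pd.DataFrame(X, columns=[f"g{i}" for i in range(n_genes)]), groups


class TestModeratedT:
    def test_d0_zero_equals_ordinary_t(self, rng):
        frame, groups = _two_group_frame(rng)
        res = fit_moderated_de(frame, groups, "A", d0_override=0.0)
        t_ref, p_ref = stats.ttest_ind(frame[groups == "A"],
                                       frame[groups == "B"])
        np.testing.assert_allclose(res["t_mod"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p_value"], p_ref, rtol=1e-10)

    def test_d0_infinity_uses_prior_variance_only(self, rng):
        from screpurpose.de import estimate_prior

        frame, groups = _two_group_frame(rng, na=6, nb=6)
        res = fit_moderated_de(frame, groups, "A", d0_override=np.inf)
        na = nb = 6
        X = frame.to_numpy()
        s2 = (
            ((X[:na] - X[:na].mean(0)) ** 2).sum(0)
            + ((X[na:] - X[na:].mean(0)) ** 2).sum(0)
        ) / (na + nb - 2)
        _, s02 = estimate_prior(s2, na + nb - 2)
        expected = res["log2FC"] / np.sqrt(s02 * (1 / na + 1 / nb))
        np.testing.assert_allclose(res["t_mod"], expected, rtol=1e-6)

    def test_matches_limma_ebayes_oracle(self, rng, tmp_path):
        """Full agreement with the Bioconductor eBayes moderated t."""
        frame, groups = _two_group_frame(rng, n_genes=60, na=6, nb=6)
        frame *= rng.uniform(0.5, 2.0, size=frame.shape[1])  # vary variances
        res = fit_moderated_de(frame, groups, "A")
        x_path = tmp_path / "x.tsv"
        out_path = tmp_path / "limma.tsv"
        np.savetxt(x_path, frame.to_numpy().T, delimiter="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.table("{x_path}", sep="\\t"))
            design <- cbind(Intercept=1, A=c(rep(1,6), rep(0,6)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(lfc=fit$coefficients[,"A"], t=fit$t[,"A"],
                              p=fit$p.value[,"A"])
            write.table(out, "{out_path}", sep="\\t", row.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        ref = pd.read_csv(out_path, sep="\t")
        np.testing.assert_allclose(res["log2FC"], ref["lfc"], rtol=1e-8)
        np.testing.assert_allclose(res["t_mod"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(res["p_value"], ref["p"], rtol=1e-8)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        rejections, total = 0, 0
        for _ in range(20):
            frame, groups = _two_group_frame(rng, n_genes=500, na=40, nb=40)
            res = fit_moderated_de(frame, groups, "A")
            rejections += int((res["p_value"] < 0.05).sum())
            total += len(res)
        rate = rejections / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 2.807 * se  # 99.5% two-sided binomial CI

    def test_zero_variance_gene_flagged(self):
        frame = pd.DataFrame({"flat": [1.0] * 8, "ok": np.arange(8.0)})
        groups = np.array(["A"] * 4 + ["B"] * 4)
        res = fit_moderated_de(frame, groups, "A").set_index("gene")
        assert res.loc["flat", "flagged"]
        assert res.loc["flat", "p_value"] == 1.0
        assert res.loc["flat", "t_mod"] == 0.0

    def test_planted_lfc_recovered_unbiased(self):
        rng = np.random.default_rng(5)
        frame, groups = _two_group_frame(rng, n_genes=200, na=100, nb=100,
                                         shift=1.0)
        res = fit_moderated_de(frame, groups, "A")
        assert abs(res["log2FC"].mean() - 1.0) < 0.05


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_degenerate_inputs(self):
        assert bh_fdr([0.2]).tolist() == [0.2]
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_matches_reference_step_up(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), ref, rtol=1e-12)

    def test_dominates_raw_p(self, rng):
        p = rng.uniform(size=200)
        assert (bh_fdr(p) >= p - 1e-15).all()


class TestSignificantGenes:
    DE = pd.DataFrame(
        {
            "gene": ["a", "b", "c", "d"],
            "log2FC": [0.58, 0.60, -1.2, -0.9],
            "p_value": [0.001, 0.01, 0.2, 0.04],
            "fdr": [0.004, 0.04, 0.4, 0.12],
        }
    )

    def test_boundary_lfc_excluded(self):
        signed = significant_genes(self.DE)
        assert "a" not in signed.directions  # |lfc| == cut is excluded

    def test_directions(self):
        signed = significant_genes(self.DE)
        assert signed.directions == {"b": "Up", "d": "Down"}

    def test_fdr_mode(self):
        signed = significant_genes(self.DE, use_fdr=True)
        assert signed.directions == {"b": "Up"}
        assert signed.provenance["thresholded_on"] == "fdr"

    @given(
        p_cut=st.floats(0.01, 0.2),
        lfc_cut=st.floats(0.1, 1.5),
        slack=st.floats(0.0, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_both_cuts(self, p_cut, lfc_cut, slack):
        tight = significant_genes(self.DE, p_cut=p_cut, lfc_cut=lfc_cut)
        loose = significant_genes(self.DE, p_cut=p_cut + slack,
                                  lfc_cut=max(lfc_cut - slack, 0.0))
        assert set(tight.directions) <= set(loose.directions)


def _auroc_bruteforce(x, y):
    wins = sum((a > b) + 0.5 * (a == b) for a in x for b in y)
    return wins / (len(x) * len(y))


class TestAurocMarkers:
    def test_perfect_separation(self):
        frame = pd.DataFrame({"g": [5.0, 6.0, 7.0, 1.0, 2.0]})
        res = auroc_markers(frame, [True, True, True, False, False])
        assert res["auroc"].iloc[0] == 1.0

    def test_label_swap_symmetry(self, rng):
        frame = pd.DataFrame(rng.normal(size=(12, 5)),
                             columns=[f"g{i}" for i in range(5)])
        mask = np.array([True] * 5 + [False] * 7)
        a = auroc_markers(frame, mask)["auroc"]
        b = auroc_markers(frame, ~mask)["auroc"]
        np.testing.assert_allclose(a + b, 1.0)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(30):
            n1 = int(rng.integers(2, 11))
            n2 = int(rng.integers(2, 11))
            if n1 * n2 > 100:
                continue
            vals = rng.integers(0, 6, size=n1 + n2).astype(float)  # ties
            frame = pd.DataFrame({"g": vals})
            mask = np.array([True] * n1 + [False] * n2)
            res = auroc_markers(frame, mask)
            assert res["auroc"].iloc[0] == pytest.approx(
                _auroc_bruteforce(vals[:n1], vals[n1:])
            )

    def test_empty_group_rejected(self):
        frame = pd.DataFrame({"g": [1.0, 2.0]})
        with pytest.raises(ValueError, match="non-empty"):
            auroc_markers(frame, [True, True])


class TestOraHypergeom:
    def test_hand_enumeration(self):
        # N=10, K=4, n=3: P(k>=2) = [C(4,2)C(6,1)+C(4,3)]/C(10,3) = 40/120
        bg = [f"g{i}" for i in range(10)]
        collection = {"s": bg[:4]}
        query = bg[2:5]  # overlap 2 with s
        res = ora_hypergeom(query, collection, bg)
        assert res["p_value"].iloc[0] == pytest.approx(40 / 120)

    def test_query_equals_set_is_minimal_tail(self):
        bg = [f"g{i}" for i in range(6)]
        res = ora_hypergeom(bg, {"all": bg}, bg)
        assert res["overlap"].iloc[0] == 6
        assert res["p_value"].iloc[0] == pytest.approx(1.0)  # point mass

    def test_empty_overlap_gives_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        res = ora_hypergeom(bg[:3], {"s": bg[7:]}, bg)
        assert res["p_value"].iloc[0] == 1.0
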