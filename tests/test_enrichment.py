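"""Moderated-t ranking and the pre-ranked GSEA engine (ES / NES)."""

import itertools
import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import brute_force_es, brute_force_moderated_t
from vaxsig.enrichment import (
    NullCache,
    enrichment_score,
    moderated_t,
    moderated_t_rank,
    nes_profile,
    normalized_es,
    trigamma_inverse,
)
from vaxsig.ica import Signature


def _groups(n1=3, n2=3):
    cols = [f"v{i}" for i in range(n1)] + [f"c{i}" for i in range(n2)]
    return cols, pd.Series(["vector"] * n1 + ["control"] * n2, index=cols)


class TestModeratedT:
    def test_matches_independent_oracle_to_1e10(self):
        rng = np.random.default_rng(3)
        cols, groups = _groups()
        m = pd.DataFrame(
            rng.normal(8, 1, (50, 6)) * rng.uniform(0.2, 3.0, (50, 1)),
            index=[f"g{i}" for i in range(50)],
            columns=cols,
        )
        ours = moderated_t(m, groups)
        oracle = brute_force_moderated_t(m, cols[:3], cols[3:])
        assert (ours - oracle).abs().max() < 1e-10

    def test_zero_prior_df_reduces_to_ordinary_t(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(4)
        cols, groups = _groups()
        m = pd.DataFrame(rng.normal(0, 1, (20, 6)), columns=cols)
        ours = moderated_t(m, groups, prior_df=0.0)
        ordinary = ttest_ind(m[cols[:3]], m[cols[3:]], axis=1).statistic
        np.testing.assert_allclose(ours.to_numpy(), ordinary, atol=1e-12)

    def test_matches_r_limma_ebayes(self, tmp_path):
        """Cross-check against the reference empirical-Bayes implementation."""
        rng = np.random.default_rng(7)
        cols, groups = _groups()
        m = pd.DataFrame(
            rng.normal(8, 1, (80, 6)) * rng.uniform(0.3, 2.5, (80, 1)),
            index=[f"g{i}" for i in range(80)],
            columns=cols,
        )
        xfile, rfile = tmp_path / "x.tsv", tmp_path / "t.tsv"
        m.to_csv(xfile, sep="\t")
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'X <- as.matrix(read.delim("{xfile}", row.names=1))\n'
            "design <- cbind(Intercept=1, vector=c(1,1,1,0,0,0))\n"
            "fit <- eBayes(lmFit(X, design))\n"
            f'write.table(data.frame(t=fit$t[,"vector"]), "{rfile}", sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True, text=True
        )
        r_t = pd.read_csv(rfile, sep="\t", index_col=0)["t"]
        ours = moderated_t(m, groups)
        assert (ours - r_t).abs().max() < 1e-8

    def test_identical_groups_give_zero_t_with_name_tiebreak(self):
        cols, groups = _groups()
        m = pd.DataFrame(
            np.repeat([[1.0], [2.0], [3.0], [4.0]], 6, axis=1),
            index=["gb", "ga", "gd", "gc"],
            columns=cols,
        )
        with pytest.warns(UserWarning, match="zero within-group variance"):
            ranked = moderated_t_rank(m_to_dataset(m, groups))
        assert (ranked == 0).all()
        assert list(ranked.index) == ["ga", "gb", "gc", "gd"]

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for x in (1e-5, 0.01, 0.5, 3.0, 1e6):
            y = trigamma_inverse(x)
            assert float(polygamma(1, y)) == pytest.approx(x, rel=1e-6)


def m_to_dataset(m, groups):
    from vaxsig.datasets import ExpressionDataset

    return ExpressionDataset(values=m, groups=groups, vector_id="toy")


def _ranked(scores):
    return pd.Series(scores, index=[f"g{i}" for i in range(len(scores))])


class TestEnrichmentScore:
    def test_single_top_gene_gives_unit_score(self):
        assert enrichment_score(_ranked([3.0, 2.0, 1.0, 0.5]), ["g0"]) == 1.0

    def test_exhaustive_oracle_all_subsets_of_length8_list(self):
        """Every subset of size <= 3 on an 8-gene list matches the walk oracle."""
        rng = np.random.default_rng(5)
        scores = _ranked(np.sort(rng.normal(0, 2, 8))[::-1])
        genes = list(scores.index)
        for k in (1, 2, 3):
            for subset in itertools.combinations(genes, k):
                ours = enrichment_score(scores, subset)
                oracle = brute_force_es(scores, subset)
                assert ours == oracle, f"subset {subset}"

    def test_no_overlap_flagged_absent(self):
        assert enrichment_score(_ranked([1.0, 0.5]), ["zz"]) is None

    def test_whole_list_degenerate(self):
        with pytest.warns(UserWarning, match="whole ranked list"):
            assert enrichment_score(_ranked([1.0, 0.5]), ["g0", "g1"]) is None

    def test_bounded_in_minus_one_one(self):
        rng = np.random.default_rng(6)
        for trial in range(20):
            scores = _ranked(np.sort(rng.normal(0, 1, 30))[::-1])
            genes = rng.choice(scores.index, size=rng.integers(1, 15), replace=False)
            es = enrichment_score(scores, genes)
            assert -1.0 <= es <= 1.0

    def test_rank_only_mode_invariant_to_monotone_rescaling(self):
        scores = _ranked([5.0, 4.0, 2.0, 1.0, 0.5, -1.0])
        monotone = pd.Series(np.exp(scores.to_numpy()), index=scores.index)
        genes = ["g1", "g4"]
        assert enrichment_score(scores, genes, weight=0.0) == enrichment_score(
            monotone, genes, weight=0.0
        )

    def test_weighted_mode_invariant_to_positive_rescaling(self):
        scores = _ranked([5.0, 4.0, 2.0, 1.0, 0.5, -1.0])
        genes = ["g1", "g4"]
        assert enrichment_score(scores, genes, weight=1.0) == pytest.approx(
            enrichment_score(scores * 7.3, genes, weight=1.0)
        )

    def test_antisymmetric_under_list_reversal_and_negation(self):
        scores = _ranked([3.0, 1.0, 0.5, -0.5, -1.0, -3.0])
        flipped = (-scores).iloc[::-1]
        genes = ["g0", "g2"]
        assert enrichment_score(flipped, genes) == pytest.approx(
            -enrichment_score(scores, genes)
        )

    @given(st.integers(1, 7))
    def test_matches_oracle_on_random_lists(self, k):
        rng = np.random.default_rng(k)
        scores = _ranked(np.sort(rng.normal(0, 1, 12))[::-1])
        genes = rng.choice(scores.index, size=k, replace=False)
        assert enrichment_score(scores, genes) == brute_force_es(scores, genes)

    def test_matches_gseapy_prerank_es(self):
        """The external pre-ranked GSEA implementation agrees on ES."""
        import gseapy

        rng = np.random.default_rng(1)
        scores = _ranked(np.sort(rng.normal(0, 2, 200))[::-1])
        genes = [f"g{i}" for i in (3, 17, 44, 90, 150, 199)]
        res = gseapy.prerank(
            rnk=scores.reset_index(),
            gene_sets={"SET1": genes},
            permutation_num=5,
            min_size=2,
            max_size=500,
            seed=1,
            no_plot=True,
            outdir=None,
            threads=1,
            weight=1.0,
        )
        external = float(res.res2d.loc[res.res2d.Term == "SET1", "ES"].iloc[0])
        assert enrichment_score(scores, genes) == pytest.approx(external, abs=1e-12)


class TestNormalizedES:
    def test_division_contract(self):
        """NES = ES / mean of same-signed permutation scores."""
        scores = _ranked(np.linspace(3, -3, 40))
        cache = NullCache(scores, weight=1.0, n_perm=500, seed=9)
        null = cache.get(5)
        es = enrichment_score(scores, [f"g{i}" for i in (0, 1, 2, 3, 4)])
        nes = normalized_es(es, scores, 5, n_perm=500, seed=9)
        assert nes == pytest.approx(es / null[null > 0].mean())

    def test_deterministic_given_seed(self):
        scores = _ranked(np.linspace(2, -2, 30))
        a = normalized_es(0.4, scores, 4, n_perm=200, seed=3)
        b = normalized_es(0.4, scores, 4, n_perm=200, seed=3)
        assert a == b

    def test_sign_preserved(self):
        scores = _ranked(np.linspace(2, -2, 30))
        neg = normalized_es(-0.4, scores, 4, n_perm=200, seed=3)
        assert neg < 0

    def test_absent_es_propagates_nan(self):
        scores = _ranked(np.linspace(2, -2, 30))
        assert np.isnan(normalized_es(None, scores, 4, n_perm=100, seed=0))


class TestNesProfile:
    def test_profile_length_and_imputation(self):
        scores = _ranked(np.linspace(3, -3, 50))
        db = [
            Signature("present", tuple(f"g{i}" for i in range(10))),
            Signature("absent", tuple(f"zz{i}" for i in range(10))),
            Signature("toofew", tuple([f"g{i}" for i in range(3)] + ["z1", "z2", "z3", "z4"])),
        ]
        prof = nes_profile(scores, db, n_perm=100, seed=1)
        assert list(prof.index) == ["present", "absent", "toofew"]
        assert np.isfinite(prof["present"])
        assert np.isnan(prof["absent"]) and np.isnan(prof["toofew"])

    def test_empty_db_gives_empty_profile(self):
        assert nes_profile(_ranked([1.0, -1.0, 0.5]), [], n_perm=50, seed=0).empty

    def test_decoys_do_not_appear_in_output(self):
        scores = _ranked(np.linspace(3, -3, 50))
        db = [Signature("real", tuple(f"g{i}" for i in range(10)))]
        decoys = [Signature("DECOY_1", tuple(f"g{i}" for i in range(12)), "decoy")]
        prof = nes_profile(scores, db, decoys=decoys, n_perm=100, seed=1)
        assert list(prof.index) == ["real"]

    def test_profile_independent_of_signature_order(self):
        scores = _ranked(np.linspace(3, -3, 50))
        db = [
            Signature("a", tuple(f"g{i}" for i in range(8))),
            Signature("b", tuple(f"g{i}" for i in range(20, 32))),
        ]
        fwd = nes_profile(scores, db, n_perm=100, seed=4)
        rev = nes_profile(scores, db[::-1], n_perm=100, seed=4)
        pd.testing.assert_series_equal(fwd.sort_index(), rev.sort_index())
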