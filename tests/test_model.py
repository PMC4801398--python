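"""Bootstrapping, NES matrix assembly, the forest classifier and metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vaxsig.ica import Signature
from vaxsig.model import (
    NESMatrix,
    SignatureForestModel,
    VectorPrediction,
    bootstrap_dataset,
    build_nes_matrix,
    classification_metrics,
    votes_from_counts,
)


class TestBootstrap:
    def test_group_sizes_preserved(self, small_dataset):
        for bs in bootstrap_dataset(small_dataset, B=10, seed=0):
            groups = small_dataset.groups.iloc[list(bs.positions)]
            assert (groups == "control").sum() == 3
            assert (groups == "vector").sum() == 3

    def test_deterministic_given_seed(self, small_dataset):
        a = bootstrap_dataset(small_dataset, B=5, seed=7)
        b = bootstrap_dataset(small_dataset, B=5, seed=7)
        assert [x.positions for x in a] == [y.positions for y in b]

    def test_paired_mode_draws_whole_pairs(self, small_dataset):
        for bs in bootstrap_dataset(small_dataset, B=20, seed=1, paired=True):
            half = len(bs.positions) // 2
            ctl, vec = bs.positions[:half], bs.positions[half:]
            # pair j is (control position j, vector position j + 3)
            assert [p + 3 for p in ctl] == list(vec)

    def test_paired_mode_requires_matched_groups(self, small_dataset):
        unbalanced = small_dataset.subset_positions([0, 1, 2, 3, 4], tag="x")
        with pytest.raises(ValueError, match="matched group sizes"):
            bootstrap_dataset(unbalanced, B=2, paired=True)

    def test_minimum_group_size_enforced(self, small_dataset):
        tiny = small_dataset.subset_positions([0, 3, 4], tag="x")
        with pytest.raises(ValueError, match=">= 2 samples"):
            bootstrap_dataset(tiny, B=2)


class TestNESMatrixShape:
    @given(st.integers(1, 3), st.integers(1, 4))
    def test_shape_law_columns_and_rows(self, n_datasets, B):
        """columns = #datasets * B, rows = |signature DB|, any configuration."""
        sig_names = [f"s{i}" for i in range(5)]
        cols, meta = _synthetic_matrix_parts(n_datasets, B, sig_names)
        nes = NESMatrix(values=cols, col_meta=meta)
        assert nes.values.shape == (5, n_datasets * B)

    def test_built_matrix_shape_and_determinism(self, small_dataset):
        db = [
            Signature(f"sig{i}", tuple(f"G{j:02d}" for j in range(i, i + 8)))
            for i in range(3)
        ]
        ds2 = small_dataset.subset_positions(list(range(6)), tag="copy")
        a = build_nes_matrix([small_dataset, ds2], db, B=4, seed=5, n_perm=50)
        b = build_nes_matrix([small_dataset, ds2], db, B=4, seed=5, n_perm=50)
        assert a.values.shape == (3, 8)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_misaligned_metadata_rejected(self):
        values = pd.DataFrame({"c1": [0.1]}, index=["s"])
        meta = pd.DataFrame({"dataset_id": ["d"]}, index=["other"])
        with pytest.raises(ValueError, match="misaligned"):
            NESMatrix(values=values, col_meta=meta)


def _synthetic_matrix_parts(n_datasets, B, sig_names, seed=0, strong_half=True):
    rng = np.random.default_rng(seed)
    cols = {}
    meta = []
    for d in range(n_datasets):
        label = "Strong" if (d % 2 == 0 and strong_half) else "Weak"
        for b in range(1, B + 1):
            col = f"d{d}|b{b}"
            shift = 1.5 if label == "Strong" else -1.5
            cols[col] = rng.normal(0, 1, len(sig_names)) + shift
            meta.append(
                {
                    "column": col,
                    "dataset_id": f"d{d}",
                    "vector_id": f"d{d}",
                    "bootstrap": b,
                    "class_label": label,
                }
            )
    values = pd.DataFrame(cols, index=pd.Index(sig_names, name="signature"))
    return values, pd.DataFrame(meta).set_index("column")


def _labelled_matrix(n_datasets=6, B=10, n_sigs=8, seed=0):
    values, meta = _synthetic_matrix_parts(
        n_datasets, B, [f"s{i}" for i in range(n_sigs)], seed=seed
    )
    return NESMatrix(values=values, col_meta=meta)


class TestForest:
    def test_single_class_training_rejected(self):
        nes = _labelled_matrix()
        labels = {f"d{i}": "Strong" for i in range(6)}
        with pytest.raises(ValueError, match="both classes"):
            SignatureForestModel(nes, labels=labels)

    def test_default_mtry_is_sqrt_of_signature_count(self):
        nes = _labelled_matrix(n_sigs=8)
        model = SignatureForestModel(nes, n_trees=50)
        assert model.mtry == 2  # floor(sqrt(8))

    def test_same_seed_identical_predictions(self):
        nes = _labelled_matrix()
        r1 = SignatureForestModel(nes, n_trees=100).fit(seed=4)
        r2 = SignatureForestModel(nes, n_trees=100).fit(seed=4)
        p1 = r1.predict_proba_columns(nes.values)
        p2 = r2.predict_proba_columns(nes.values)
        pd.testing.assert_series_equal(p1, p2)

    def test_separable_matrix_oob_error_reaches_zero(self):
        """Well-separated classes: OOB misclassification hits 0 in the forest."""
        nes = _labelled_matrix(n_datasets=8, B=15, seed=1)
        res = SignatureForestModel(nes, n_trees=300).fit(seed=0)
        assert res.oob_path.iloc[-1] == 0.0

    def test_label_permutation_oob_accuracy_near_half(self):
        nes = _labelled_matrix(n_datasets=8, B=20, seed=2)
        rng = np.random.default_rng(0)
        meta = nes.col_meta.copy()
        meta["class_label"] = rng.permutation(meta["class_label"].to_numpy())
        permuted = NESMatrix(values=nes.values, col_meta=meta)
        res = SignatureForestModel(permuted, n_trees=500).fit(seed=0)
        assert 1.0 - res.oob_error == pytest.approx(0.5, abs=0.1)

    def test_importances_flag_above_threshold(self):
        nes = _labelled_matrix(n_datasets=8, B=15, seed=3)
        res = SignatureForestModel(nes, n_trees=200).fit(seed=0)
        ranking = res.importance_ranking(threshold=np.inf)
        assert not ranking["important"].any()  # threshold = inf -> empty set
        assert (ranking["gini_mean_decrease"].diff().dropna() <= 1e-12).all()

    def test_model_roundtrip_through_file(self, tmp_path):
        from vaxsig.model import SignatureForestResults

        nes = _labelled_matrix()
        res = SignatureForestModel(nes, n_trees=60).fit(seed=0)
        res.save(tmp_path / "model.pkl")
        back = SignatureForestResults.load(tmp_path / "model.pkl")
        pd.testing.assert_series_equal(
            back.predict_proba_columns(nes.values),
            res.predict_proba_columns(nes.values),
        )


class TestVotes:
    @pytest.mark.parametrize(
        "n_strong, n_weak, expected",
        [(3, 97, "Weak"), (31, 69, "Weak"), (100, 0, "Strong"), (1, 0, "Strong")],
    )
    def test_majority_rule_on_counts(self, n_strong, n_weak, expected):
        assert votes_from_counts(n_strong, n_weak) == expected

    def test_exact_probability_tie_counts_as_weak(self):
        pred = VectorPrediction("v", np.array([0.5, 0.6]), ["Weak", "Strong"], n_ties=1)
        assert pred.n_ties == 1
        # exact vector-level split is also conservative
        even = VectorPrediction("v", np.array([0.4, 0.6]), ["Weak", "Strong"])
        assert even.vector_class == "Weak"

    def test_vector_class_invariant_to_column_order(self):
        nes = _labelled_matrix(n_datasets=4, B=10)
        res = SignatureForestModel(nes, n_trees=80).fit(seed=0)
        cols = nes.columns_of(dataset_ids=["d0"])
        fwd = res.predict_vector(nes.values[cols], "d0")
        rev = res.predict_vector(nes.values[cols[::-1]], "d0")
        assert fwd.vector_class == rev.vector_class
        assert fwd.n_strong == rev.n_strong


class TestMetrics:
    def test_all_correct_gives_ones(self):
        votes = pd.DataFrame({"truth": ["Strong", "Weak"] * 5, "vote": ["Strong", "Weak"] * 5})
        m = classification_metrics(votes)
        assert (m[["sensitivity", "specificity", "ppv", "npv", "accuracy"]] == 1.0).all().all()

    def test_confusion_matrix_arithmetic(self):
        """TP=98 FN=2 TN=89 FP=11 for Strong: sens 0.98, PPV ~ 0.899."""
        votes = pd.DataFrame(
            {
                "truth": ["Strong"] * 100 + ["Weak"] * 100,
                "vote": ["Strong"] * 98 + ["Weak"] * 2 + ["Weak"] * 89 + ["Strong"] * 11,
            }
        )
        m = classification_metrics(votes)
        assert m.loc["Strong", "sensitivity"] == pytest.approx(0.98)
        assert m.loc["Strong", "ppv"] == pytest.approx(98 / 109)
        assert m.loc["Strong", "accuracy"] == pytest.approx(187 / 200)

    def test_two_class_duality(self):
        rng = np.random.default_rng(1)
        votes = pd.DataFrame(
            {
                "truth": rng.choice(["Strong", "Weak"], 60),
                "vote": rng.choice(["Strong", "Weak"], 60),
            }
        )
        m = classification_metrics(votes)
        assert m.loc["Strong", "sensitivity"] == m.loc["Weak", "specificity"]
        assert m.loc["Strong", "ppv"] == m.loc["Weak", "npv"]

    def test_single_class_truth_reports_nan(self):
        votes = pd.DataFrame({"truth": ["Strong"] * 5, "vote": ["Strong", "Weak"] * 2 + ["Strong"]})
        m = classification_metrics(votes)
        assert np.isnan(m.loc["Weak", "sensitivity"])  # no Weak truths

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(pd.DataFrame(columns=["truth", "vote"]))
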