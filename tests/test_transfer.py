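"""Transfer scoring: preprocessing, hazard model, strata, library queries."""

import numpy as np
import pandas as pd
import pytest

from screpurpose import (
    HazardModel,
    SignedGeneSet,
    degas_preprocess,
    gen_patient_cohort,
    gen_sc_dataset,
    median_split,
    score_cells,
    signature_query,
    train_hazard_model,
)
from screpurpose.simulate import DrugSignatureLibrary, SimConfig


class TestPreprocess:
    def test_minmax_endpoints(self):
        out = degas_preprocess(np.array([[0.0, 3.0]]))
        assert out[0, 0] == 0.0 and out[0, 1] == 1.0

    def test_constant_sample_maps_to_half(self):
        out = degas_preprocess(np.array([[4.0, 4.0, 4.0]]))
        np.testing.assert_allclose(out, 0.5)

    def test_not_idempotent(self, rng):
        X = rng.uniform(0, 100, size=(3, 20))
        once = degas_preprocess(X)
        twice = degas_preprocess(once)
        assert not np.allclose(once, twice)

    def test_output_in_unit_interval(self, rng):
        out = degas_preprocess(rng.uniform(0, 1e6, size=(5, 30)))
        assert out.min() >= 0.0 and out.max() <= 1.0


def _toy_cohort(rng, n=12, p=10, shift=4.0):
    X = rng.normal(20, 2, size=(n, p))
    labels = np.array(["case"] * (n // 2) + ["control"] * (n - n // 2))
    X[labels == "case", :3] += shift
    frame = pd.DataFrame(X, columns=[f"g{i}" for i in range(p)])
    return frame, labels


class TestHazardModel:
    def test_separable_cohort_training_auroc_one(self, rng):
        from sklearn.metrics import roc_auc_score

        frame, labels = _toy_cohort(rng, shift=30.0)
        model = train_hazard_model(frame, labels, list(frame.columns), seed=0)
        scores = score_cells(model, frame)
        assert roc_auc_score(labels == "case", scores) == 1.0

    def test_same_seed_identical_weights(self, rng):
        frame, labels = _toy_cohort(rng)
        m1 = train_hazard_model(frame, labels, list(frame.columns), seed=3)
        m2 = train_hazard_model(frame, labels, list(frame.columns), seed=3)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_label_permuted_cohort_no_signal(self):
        """Held-out AUROC hovers at chance when labels carry no signal."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        aurocs = []
        for _ in range(20):
            frame, labels = _toy_cohort(rng, n=24, shift=0.0)
            held = rng.permutation(24)
            train_idx, test_idx = held[:16], held[16:]
            model = train_hazard_model(
                frame.iloc[train_idx], labels[train_idx],
                list(frame.columns), seed=0,
            )
            scores = score_cells(model, frame.iloc[test_idx])
            aurocs.append(roc_auc_score(labels[test_idx] == "case", scores))
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_missing_features_listed(self, rng):
        frame, labels = _toy_cohort(rng)
        with pytest.raises(ValueError, match="absent"):
            train_hazard_model(frame, labels, ["g0", "nope"], seed=0)

    def test_zero_weight_model_scores_half(self, rng):
        model = HazardModel(["g0", "g1"], np.zeros((2, 2)), np.zeros(2), 2)
        frame = pd.DataFrame(rng.uniform(size=(4, 2)), columns=["g0", "g1"])
        np.testing.assert_allclose(score_cells(model, frame), 0.5)

    def test_scores_bounded_for_extreme_inputs(self, rng):
        model = HazardModel(["g0", "g1"], np.array([[50.0, -50.0]]),
                            np.array([0.0]), 1)
        frame = pd.DataFrame([[1e9, 0.0], [0.0, 1e9]], columns=["g0", "g1"])
        s = score_cells(model, frame)
        assert (s >= 0).all() and (s <= 1).all()

    def test_gene_order_invariance(self, rng):
        frame, labels = _toy_cohort(rng)
        model = train_hazard_model(frame, labels, list(frame.columns), seed=0)
        shuffled = frame[list(rng.permutation(frame.columns))]
        np.testing.assert_allclose(
            score_cells(model, frame), score_cells(model, shuffled)
        )

    def test_json_roundtrip(self, rng, tmp_path):
        frame, labels = _toy_cohort(rng)
        model = train_hazard_model(frame, labels, list(frame.columns), seed=0)
        model.to_json(tmp_path / "m.json")
        loaded = HazardModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(model.weights, loaded.weights)
        assert model.features == loaded.features

    def test_large_effect_held_out_patient_auroc(self):
        from sklearn.metrics import roc_auc_score

        cfg = SimConfig(seed=9, de_effect_lfc=2.0, n_patients_per_class=30)
        _, truth = gen_sc_dataset(cfg)
        cohort = gen_patient_cohort(cfg, truth)
        rng = np.random.default_rng(9)
        idx = rng.permutation(cohort.n_obs)
        train_idx, test_idx = idx[:40], idx[40:]
        model = train_hazard_model(
            cohort[train_idx], cohort.obs["condition"].iloc[train_idx],
            sorted(truth.disease_signature), seed=9,
        )
        scores = score_cells(model, cohort[test_idx])
        labels = cohort.obs["condition"].iloc[test_idx] == "case"
        assert roc_auc_score(labels, scores) >= 0.9

    def test_case_cells_score_higher(self):
        from sklearn.metrics import roc_auc_score

        from screpurpose.preprocess import normalize_log

        cfg = SimConfig(seed=4)
        adata, truth = gen_sc_dataset(cfg)
        cohort = gen_patient_cohort(cfg, truth)
        model = train_hazard_model(
            cohort, cohort.obs["condition"],
            sorted(truth.disease_signature), seed=4,
        )
        cells = normalize_log(adata)
        cells = cells[~cells.obs["is_doublet"].astype(bool)]
        scores = score_cells(model, cells)
        auroc = roc_auc_score(cells.obs["condition"] == "case", scores)
        assert auroc >= 0.8


class TestMedianSplit:
    def test_tie_at_median_goes_low(self):
        out = median_split(pd.Series([0.1, 0.5, 0.9]))
        assert out["stratum"].tolist() == ["low", "low", "high"]

    def test_all_equal_all_low(self):
        out = median_split(pd.Series([0.3, 0.3, 0.3]))
        assert (out["stratum"] == "low").all()

    def test_even_distinct_scores_split_evenly(self):
        out = median_split(pd.Series([0.1, 0.2, 0.8, 0.9]))
        assert (out["stratum"] == "high").sum() == 2


def _library_from(series_by_drug):
    meta = pd.DataFrame(
        {"context": ["CNS"] * len(series_by_drug)},
        index=pd.Index(sorted(series_by_drug), name="drug_id"),
    )
    return DrugSignatureLibrary(series_by_drug, meta)


class TestSignatureQuery:
    SIG = SignedGeneSet({f"u{i}": "Up" for i in range(4)}
                        | {f"d{i}": "Down" for i in range(4)})

    def test_negation_tops_reverse_with_similarity_minus_one(self):
        neg = -self.SIG.sign_series()
        lib = _library_from({"anti": neg, "noise": pd.Series(
            [1.0, -1.0, 1.0, -1.0, 1.0],
            index=["u0", "u1", "d0", "d1", "u2"])})
        out = signature_query(self.SIG, lib, mode="reverse")
        assert out["drug_id"].iloc[0] == "anti"
        assert out["similarity"].iloc[0] == pytest.approx(-1.0)

    def test_orthogonal_drug_similarity_zero(self):
        vals = pd.Series([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0],
                         index=list(self.SIG.directions))
        # sign pattern matches Up half, opposes Down half -> cancels
        vals[["d0", "d1", "d2", "d3"]] = [1.0, 1.0, -1.0, -1.0]
        vals[["u0", "u1", "u2", "u3"]] = [1.0, -1.0, 1.0, -1.0]
        lib = _library_from({"orth": vals})
        out = signature_query(self.SIG, lib, mode="mimic")
        assert out["similarity"].iloc[0] == pytest.approx(0.0)

    def test_min_shared_exclusion(self):
        lib = _library_from({"tiny": pd.Series([1.0], index=["u0"])})
        out = signature_query(self.SIG, lib, mode="reverse", min_shared=5)
        assert len(out) == 0

    def test_reverse_equals_mimic_of_flipped_signature(self, rng):
        drugs = {
            f"drug{i}": pd.Series(
                rng.normal(size=8), index=list(self.SIG.directions)
            )
            for i in range(6)
        }
        lib = _library_from(drugs)
        rev = signature_query(self.SIG, lib, mode="reverse")
        mim = signature_query(self.SIG.flipped(), lib, mode="mimic")
        assert rev["drug_id"].tolist() == mim["drug_id"].tolist()
        np.testing.assert_allclose(rev["similarity"], -mim["similarity"])

    def test_planted_reverser_and_mimic_top_their_queries(self, config):
        from screpurpose.pipeline import run_transfer

        out = run_transfer(config)
        truth = out["truth"]
        assert out["reverse_query"]["drug_id"].iloc[0] == truth.reverser_drug_id
        assert out["mimic_query"]["drug_id"].iloc[0] == truth.mimic_drug_id
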