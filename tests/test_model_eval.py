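import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synergraph import (
    BoostConfig,
    cross_validate,
    evaluate,
    grid_search,
    stratified_performance,
    train_classifier,
)
from synergraph.featurize import FeatureTable
from synergraph.model_eval import CVResult
from oracles import concordance_auc, confusion_metrics


def gaussian_table(n=240, d=4, separation=3.0, seed=0) -> FeatureTable:
    """A FeatureTable with a planted linear margin between the classes."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, 3 * d))
    X[:, 0] += separation * y
    meta = pd.DataFrame(
        {"drug_a": "A", "drug_b": "B",
         "cell": [f"C{i % 3}" for i in range(n)],
         "tissue": [f"T{i % 2}" for i in range(n)]}
    )
    return FeatureTable(X=X, y=y, meta=meta, d=d)


class TestTrainClassifier:
    def test_separable_data_fits(self):
        table = gaussian_table(separation=6.0)
        model = train_classifier(table)
        pred = model.predict_proba(table.X)[:, 1] >= 0.5
        assert np.mean(pred == table.y) >= 0.99

    def test_no_signal_gives_chance_auc(self):
        table = gaussian_table(separation=0.0, n=600)
        half = len(table) // 2
        model = train_classifier(table.X[:half], table.y[:half])
        score = model.predict_proba(table.X[half:])[:, 1]
        auc = evaluate(table.y[half:], score)["auc_roc"]
        assert 0.45 <= auc <= 0.55

    def test_single_class_errors(self):
        table = gaussian_table()
        with pytest.raises(ValueError):
            train_classifier(table.X, np.ones_like(table.y))


class TestEvaluate:
    def test_hand_tallied_confusion(self):
        # TP=1, FN=1, FP=1, TN=1 at threshold 0.5
        m = evaluate([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert m["acc"] == m["recall"] == m["precision"] == m["f1"] == 0.5

    def test_perfect_scores(self):
        m = evaluate([1, 1, 0], [0.99, 0.95, 0.01])
        assert all(m[k] == 1.0 for k in m)

    def test_reversed_scores_flip_auc(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.random(50)
        assert evaluate(y, s)["auc_roc"] == pytest.approx(
            1.0 - evaluate(y, 1.0 - s)["auc_roc"], abs=1e-12
        )

    def test_one_class_is_explicit_error(self):
        with pytest.raises(ValueError):
            evaluate([1, 1, 1], [0.2, 0.5, 0.9])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        y=st.lists(st.integers(0, 1), min_size=2, max_size=12),
        draw=st.data(),
    )
    def test_matches_brute_force_oracles(self, y, draw):
        if len(set(y)) < 2:
            y = y[:-1] + [1 - y[-1]]
        # scores on a coarse grid so ties actually occur
        s = draw.draw(
            st.lists(
                st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                min_size=len(y), max_size=len(y),
            )
        )
        m = evaluate(y, s)
        assert m["auc_roc"] == pytest.approx(concordance_auc(y, s), abs=1e-12)
        for key, val in confusion_metrics(y, s).items():
            assert m[key] == pytest.approx(val, abs=1e-12)
        if m["precision"] + m["recall"] > 0:
            assert m["f1"] == pytest.approx(
                2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"]),
                abs=1e-12,
            )


@pytest.fixture(scope="module")
def cv():
    return cross_validate(gaussian_table(n=103), folds=5, repeats=2,
                          cfg=BoostConfig(seed=0, n_rounds=20))


class TestCrossValidate:

    def test_fold_sizes_differ_by_at_most_one(self, cv):
        for rep in range(cv.fold_of.shape[0]):
            sizes = sorted(np.bincount(cv.fold_of[rep]), reverse=True)
            assert sizes == [21, 21, 21, 20, 20]

    def test_each_record_in_exactly_one_test_fold(self, cv):
        assert (cv.fold_of >= 0).all()
        assert not np.isnan(cv.oof_scores).any()

    def test_stratification_preserves_class_ratio(self):
        table = gaussian_table(n=100)
        cv = cross_validate(table, folds=5, repeats=1, cfg=BoostConfig(n_rounds=10))
        overall = table.y.mean()
        for fold in range(5):
            mask = cv.fold_of[0] == fold
            n_pos = table.y[mask].sum()
            assert abs(n_pos - overall * mask.sum()) <= 1

    def test_metrics_bounded_and_summarised(self, cv):
        assert ((cv.fold_metrics[list("acc recall precision f1".split())] >= 0).all().all())
        summary = cv.summary
        assert set(summary.index) >= {"acc", "auc_roc"}
        assert ((summary["mean"] >= 0) & (summary["mean"] <= 1)).all()

    def test_signal_beats_permuted_labels_every_fold(self):
        table = gaussian_table(n=150, separation=3.0)
        rng = np.random.default_rng(0)
        permuted = FeatureTable(
            X=table.X, y=rng.permutation(table.y), meta=table.meta, d=table.d
        )
        cfg = BoostConfig(seed=0, n_rounds=20)
        auc_signal = cross_validate(table, folds=3, repeats=1, cfg=cfg)
        auc_null = cross_validate(permuted, folds=3, repeats=1, cfg=cfg)
        per_fold_signal = auc_signal.fold_metrics["auc_roc"]
        per_fold_null = auc_null.fold_metrics["auc_roc"]
        assert (per_fold_signal.values > per_fold_null.values).all()


class TestStratifiedPerformance:
    def make_cvres(self, groups, y, scores):
        n = len(y)
        return CVResult(
            fold_metrics=pd.DataFrame([{"repeat": 0, "fold": 0}]),
            y=np.asarray(y),
            meta=pd.DataFrame({"drug_a": "A", "drug_b": "B", "cell": groups,
                               "tissue": ["t"] * n}),
            oof_scores=np.asarray(scores)[None, :],
            fold_of=np.zeros((1, n), dtype=int),
        )

    def test_one_class_group_reported_undefined(self):
        cvres = self.make_cvres(["g1", "g1", "g2", "g2"], [1, 0, 1, 1],
                                [0.9, 0.1, 0.8, 0.7])
        out = stratified_performance(cvres, by="cell").set_index("cell")
        assert out.loc["g1", "auc_roc"] == 1.0
        assert np.isnan(out.loc["g2", "auc_roc"])
        assert out.loc["g2", "n_records"] == 2  # undefined but not dropped

    def test_single_group_equals_overall_auc(self):
        y = [1, 0, 1, 0, 1]
        s = [0.9, 0.2, 0.7, 0.6, 0.3]
        cvres = self.make_cvres(["g"] * 5, y, s)
        out = stratified_performance(cvres, by="cell")
        assert out["auc_roc"].iloc[0] == pytest.approx(concordance_auc(y, s))

    def test_unknown_key_errors(self):
        cvres = self.make_cvres(["g"], [1], [0.5])
        with pytest.raises(ValueError):
            stratified_performance(cvres, by="drug")

    def test_planted_per_cell_signal_ordering(self):
        """Out-of-fold AUC is high for the signal cells, ~chance for the null cell."""
        from synergraph import make_synergy_study, run_study

        study = make_synergy_study(
            n_drugs=10, n_cells=4, n_records=400, seed=2,
            n_motifs=6, motif_size=6, cell_signals=[1.5, 1.5, 1.5, 0.0],
        )
        cvres, _, _ = run_study(study, dim=32, folds=3, repeats=1, epochs=3)
        out = stratified_performance(cvres, by="cell").set_index("cell")
        signal_aucs = out.loc[["C00", "C01", "C02"], "auc_roc"]
        assert (signal_aucs > out.loc["C03", "auc_roc"]).all()
        assert 0.35 <= out.loc["C03", "auc_roc"] <= 0.65


class TestGridSearch:
    def test_grid_of_one_returns_that_config(self):
        table = gaussian_table(n=80)
        best, scores = grid_search(table, {"max_depth": [3]}, folds=3,
                                   base_cfg=BoostConfig(n_rounds=10))
        assert best.max_depth == 3
        assert len(scores) == 1

    def test_score_table_covers_grid_and_argmax(self):
        table = gaussian_table(n=120, separation=2.0)
        grid = {"max_depth": [2, 7], "learning_rate": [0.1, 0.3]}
        best, scores = grid_search(table, grid, folds=3,
                                   base_cfg=BoostConfig(n_rounds=10))
        assert len(scores) == 4
        best_row = scores["mean_auc_roc"].max()
        chosen = scores[
            (scores["max_depth"] == best.max_depth)
            & (scores["learning_rate"] == best.learning_rate)
        ]["mean_auc_roc"].iloc[0]
        assert chosen == best_row

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            grid_search(gaussian_table(n=40), {}, folds=2)


class TestLeaveCellOut:
    def test_held_out_cells_never_in_training_fold(self):
        table = gaussian_table(n=120)
        cv = cross_validate(table, folds=3, repeats=1,
                            cfg=BoostConfig(n_rounds=10), split_by="cell")
        cells = table.meta["cell"].to_numpy()
        for fold in range(3):
            held_out = set(cells[cv.fold_of[0] == fold])
            in_train = set(cells[cv.fold_of[0] != fold])
            assert not held_out & in_train

    def test_unknown_split_mode_errors(self):
        with pytest.raises(ValueError):
            cross_validate(gaussian_table(n=40), folds=2, repeats=1,
                           split_by="drug")
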