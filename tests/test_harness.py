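import numpy as np
import pytest

from confusenn.harness import (
    ContractError,
    DegradationReport,
    PredictionFiles,
    aggregate_instances,
    evaluate_classifier,
    evaluate_regressor,
    read_report,
    run_shuffle_test,
    write_report,
)
from confusenn.matrix import ShuffleLevel
from confusenn.synthetic import (
    fit_logistic_stat_predictor,
    fit_oracle,
    sweep_neutral_task,
)


def all_pairs_auc(y_bin, scores):
    """Probability-of-correct-ranking oracle: fraction of (pos, neg) pairs
    ranked correctly, ties counting 1/2."""
    pos = [s for y, s in zip(y_bin, scores) if y]
    neg = [s for y, s in zip(y_bin, scores) if not y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluateClassifier:
    def test_perfect_predictions(self):
        truth = ["a", "a", "b", "b"]
        out = evaluate_classifier(truth, truth, scores=[0, 0, 1, 1])
        assert out["accuracy"] == 1.0
        assert out["confusion"] == [[2, 0], [0, 2]]
        assert out["auc"] == 1.0
        assert out["no_information_rate"] == 0.5

    def test_fully_wrong_predictions(self):
        out = evaluate_classifier(["a", "a", "b", "b"], ["b", "b", "a", "a"])
        assert out["accuracy"] == 0.0
        assert out["confusion"] == [[0, 2], [2, 0]]

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(0)
        truth = ["a"] * 1000 + ["b"] * 1000
        scores = rng.random(2000).tolist()
        out = evaluate_classifier(truth, ["a"] * 2000, scores=scores)
        # null AUC sd ~ sqrt((n+1)/(12 n1 n2)) ~ 0.013
        assert abs(out["auc"] - 0.5) < 0.05

    def test_trapezoidal_auc_matches_all_pairs_ranking(self):
        rng = np.random.default_rng(1)
        for trial in range(10):
            n = int(rng.integers(10, 200))
            truth = (rng.random(n) < 0.5).tolist()
            if len(set(truth)) < 2:
                continue
            scores = np.round(rng.random(n), 2).tolist()  # force score ties
            labels = ["pos" if t else "neg" for t in truth]
            out = evaluate_classifier(labels, labels, scores=scores,
                                      positive_label="pos")
            assert out["auc"] == pytest.approx(
                all_pairs_auc(truth, scores), abs=1e-12
            )

    def test_multiclass_confusion_rows_sum_to_true_counts(self):
        truth = ["a", "a", "b", "c", "c", "c"]
        pred = ["a", "b", "b", "a", "c", "c"]
        out = evaluate_classifier(truth, pred)
        assert [sum(r) for r in out["confusion"]] == [2, 1, 3]
        assert "auc" not in out

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_classifier(["a", "a"], ["a", "b"])


class TestEvaluateRegressor:
    def test_perfect_predictions(self):
        out = evaluate_regressor([1, 2, 3], [1, 2, 3])
        assert out["spearman_r"] == 1.0 and out["rmse"] == 0.0

    def test_rank_reversed(self):
        out = evaluate_regressor([1, 2, 3], [3, 2, 1])
        assert out["spearman_r"] == -1.0

    def test_shifted_predictions(self):
        out = evaluate_regressor([1, 2, 3], [2, 3, 4])
        assert out["spearman_r"] == 1.0 and out["rmse"] == pytest.approx(1.0)

    def test_constant_predictions_flagged_degenerate(self):
        out = evaluate_regressor([1, 2, 3], [5, 5, 5])
        assert out["degenerate"] and out["spearman_r"] == 0.0


@pytest.fixture(scope="module")
def dataset():
    return sweep_neutral_task(40, master_seed=20)


class TestRunShuffleTest:

    def test_identity_always_prepended(self, dataset):
        oracle = fit_oracle(dataset, "pi")
        rep = run_shuffle_test(dataset, oracle, [ShuffleLevel.COLUMNS], 1)
        assert rep.levels == ["IDENTITY", "COLUMNS"]

    def test_pi_oracle_metrics_invariant_under_count_preserving_levels(
        self, dataset
    ):
        oracle = fit_oracle(dataset, "pi")
        rep = run_shuffle_test(dataset, oracle, master_seed=2)
        for level in ("COLUMNS", "WITHIN_COLUMNS"):
            assert rep.metrics[level] == rep.metrics["IDENTITY"]

    def test_h1_oracle_survives_only_column_shuffle(self, dataset):
        oracle = fit_oracle(dataset, "h1")
        rep = run_shuffle_test(dataset, oracle, master_seed=3)
        assert rep.metrics["COLUMNS"] == rep.metrics["IDENTITY"]
        assert (
            rep.metrics["WITHIN_COLUMNS"]["accuracy"]
            < rep.metrics["IDENTITY"]["accuracy"]
        )

    def test_run_is_deterministic(self, dataset):
        oracle = fit_oracle(dataset, "h1")
        a = run_shuffle_test(dataset, oracle, master_seed=4)
        b = run_shuffle_test(dataset, oracle, master_seed=4)
        assert a.to_dict() == b.to_dict()

    def test_prediction_count_mismatch_names_level(self, dataset):
        def bad_predictor(matrices):
            return [("neutral", 0.0)] * (len(matrices) - 1)

        with pytest.raises(ContractError, match="IDENTITY"):
            run_shuffle_test(dataset, bad_predictor, [ShuffleLevel.IDENTITY], 0)

    def test_prediction_files_route_matches_in_process(self, dataset, tmp_path):
        oracle = fit_oracle(dataset, "seg_sites")
        in_process = run_shuffle_test(dataset, oracle, master_seed=5)
        from confusenn.shuffles import battery
        from confusenn.synthetic import predict_oracle

        levels = [ShuffleLevel(l) for l in ShuffleLevel]
        shuffled = battery(dataset.matrices, levels, 5)
        for level in levels:
            with open(tmp_path / f"{level.name}.tsv", "w") as fh:
                for label, score in predict_oracle(oracle, shuffled[level]):
                    fh.write(f"{label}\t{score}\n")
        via_files = run_shuffle_test(
            dataset,
            PredictionFiles(str(tmp_path)),
            master_seed=5,
            positive_label=oracle.class_high,
        )
        assert via_files.metrics == in_process.metrics


class TestRegressionRoute:
    def test_statistic_regressor_degrades_when_statistic_destroyed(self):
        """A regressor predicting pi from the matrix keeps r = 1 under
        count-preserving shuffles and loses rank fidelity at the block
        groupings."""
        from confusenn.stats import pairwise_pi
        from confusenn.synthetic import LabeledDataset, sweep_neutral_task

        base = sweep_neutral_task(20, master_seed=40)
        ds = LabeledDataset(
            base.matrices,
            [pairwise_pi(m) for m in base.matrices],
            "regression",
            metadata=base.metadata,
        )
        rep = run_shuffle_test(ds, lambda mats: [pairwise_pi(m) for m in mats],
                               master_seed=41)
        for level in ("IDENTITY", "COLUMNS", "WITHIN_COLUMNS"):
            assert rep.metrics[level]["spearman_r"] == pytest.approx(1.0)
            assert rep.metrics[level]["rmse"] == 0.0
        assert rep.metrics["BLOCK_KEEP_PADDING"]["rmse"] > 1.0


class TestAggregateInstances:
    def make_report(self, acc):
        return DegradationReport(
            task="classification",
            levels=["IDENTITY"],
            metrics={
                "IDENTITY": {"accuracy": acc, "no_information_rate": 0.5}
            },
        )

    def test_identical_reports_give_zero_width_interval(self):
        agg = aggregate_instances([self.make_report(0.8)] * 3)
        a = agg.aggregate["IDENTITY"]["accuracy"]
        assert a["ci_low"] == a["ci_high"] == pytest.approx(0.8)
        assert a["mean"] == pytest.approx(0.8)

    def test_two_instances_percentile_interpolation(self):
        agg = aggregate_instances([self.make_report(0.4), self.make_report(0.6)])
        a = agg.aggregate["IDENTITY"]["accuracy"]
        assert a["mean"] == pytest.approx(0.5)
        # linear-interpolation 2.5/97.5 percentiles of {0.4, 0.6}
        assert a["ci_low"] == pytest.approx(0.405)
        assert a["ci_high"] == pytest.approx(0.595)

    def test_single_report_rejected(self):
        with pytest.raises(ValueError):
            aggregate_instances([self.make_report(0.5)])

    def test_mismatched_levels_rejected(self):
        other = DegradationReport(
            task="classification",
            levels=["IDENTITY", "COLUMNS"],
            metrics={
                "IDENTITY": {"accuracy": 0.5, "no_information_rate": 0.5},
                "COLUMNS": {"accuracy": 0.5, "no_information_rate": 0.5},
            },
        )
        with pytest.raises(ValueError):
            aggregate_instances([self.make_report(0.5), other])


class TestReportSerialization:
    def test_json_round_trip(self, tmp_path):
        ds = sweep_neutral_task(10, master_seed=30)
        rep = run_shuffle_test(ds, fit_oracle(ds, "h1"), master_seed=6)
        path = str(tmp_path / "report.json")
        write_report(rep, path, format="json")
        assert read_report(path).to_dict() == rep.to_dict()

    def test_tsv_row_count(self, tmp_path):
        import pandas as pd

        ds = sweep_neutral_task(10, master_seed=31)
        reports = [
            run_shuffle_test(ds, fit_oracle(ds, "h1"), master_seed=s)
            for s in (1, 2)
        ]
        agg = aggregate_instances(reports)
        path = str(tmp_path / "report.tsv")
        write_report(agg, path, format="tsv")
        df = pd.read_csv(path, sep="\t")
        # 6 levels x 3 scalar metrics x (2 instances + 3 aggregate rows)
        assert len(df) == 6 * 3 * 5
        assert set(df["level"]) == set(agg.levels)

    def test_unknown_format_rejected(self, tmp_path):
        rep = DegradationReport("classification", [], {})
        with pytest.raises(ValueError):
            write_report(rep, str(tmp_path / "x"), format="xml")


def test_combined_statistic_predictor_degrades_monotonically():
    """A predictor pooling pi, H1 and singleton fraction loses accuracy as
    successive shuffle levels strip those statistics away."""
    levels = ["IDENTITY", "COLUMNS", "WITHIN_COLUMNS", "ALL_PIXELS"]
    means = {l: [] for l in levels}
    for s in range(10):
        ds = sweep_neutral_task(30, master_seed=200 + s)
        predictor = fit_logistic_stat_predictor(ds)
        rep = run_shuffle_test(
            ds,
            predictor,
            [ShuffleLevel[l] for l in levels],
            master_seed=s,
            positive_label=predictor.positive_label,
        )
        for l in levels:
            means[l].append(rep.metrics[l]["accuracy"])
    avg = [np.mean(means[l]) for l in levels]
    for earlier, later in zip(avg, avg[1:]):
        assert later <= earlier + 0.02
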