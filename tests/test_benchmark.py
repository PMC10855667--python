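"""Dataset loading, human aggregation, correlation, and the panel runner."""

import math

import numpy as np
import pytest

from embedhdp import (
    Dataset,
    InvalidInputError,
    MalformedRowError,
    PairRecord,
    SchemaError,
    UndefinedCorrelationError,
    aggregate_human,
    load_dataset,
    pearson_r,
    run_benchmark,
    spearman_r,
)


def write_csv(tmp_path, text, name="pairs.csv"):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


GOOD_CSV = (
    "id,suggestion,ground_truth,human_1,human_2\n"
    "a,x y,x z,0.5,0.7\n"
    "b,p q,p q,1.0,0.9\n"
    "c,m n,u v,0.1,0.2\n"
)


class TestLoadDataset:
    def test_well_formed_csv(self, tmp_path):
        ds = load_dataset(write_csv(tmp_path, GOOD_CSV))
        assert ds.n == 3
        assert ds.records[0].human_scores == (0.5, 0.7)
        assert ds.records[1].id == "b"

    def test_single_human_column(self, tmp_path):
        ds = load_dataset(write_csv(tmp_path, "suggestion,ground_truth,human\nx,y,0.4\nz,w,0.6\n"))
        assert ds.records[0].human_scores == (0.4,)

    def test_tsv_by_extension(self, tmp_path):
        ds = load_dataset(
            write_csv(tmp_path, "suggestion\tground_truth\thuman\nx a\ty b\t0.5\n", "p.tsv")
        )
        assert ds.records[0].suggestion == "x a"

    def test_empty_ground_truth_rejected_with_line_number(self, tmp_path):
        path = write_csv(
            tmp_path,
            "suggestion,ground_truth,human\nx,y,0.5\nz,,0.6\n",
        )
        with pytest.raises(MalformedRowError, match="line 3"):
            load_dataset(path)

    def test_non_numeric_human_rejected_with_line_number(self, tmp_path):
        path = write_csv(tmp_path, "suggestion,ground_truth,human\nx,y,high\n")
        with pytest.raises(MalformedRowError, match="line 2"):
            load_dataset(path)

    def test_missing_column_schema_error(self, tmp_path):
        with pytest.raises(SchemaError, match="ground_truth"):
            load_dataset(write_csv(tmp_path, "suggestion,human\nx,0.5\n"))

    def test_empty_file_schema_error(self, tmp_path):
        with pytest.raises(SchemaError):
            load_dataset(write_csv(tmp_path, ""))
        with pytest.raises(SchemaError):
            load_dataset(write_csv(tmp_path, "suggestion,ground_truth,human\n"))

    def test_human_optional_when_not_required(self, tmp_path):
        ds = load_dataset(
            write_csv(tmp_path, "suggestion,ground_truth\nx,y\n"), require_human=False
        )
        assert ds.records[0].human_scores is None


class TestAggregateHuman:
    def test_mean_default(self):
        assert aggregate_human([2, 4, 6]) == 4.0

    def test_single_score(self):
        assert aggregate_human([5]) == 5.0

    def test_median(self):
        assert aggregate_human([1, 2, 4], method="median") == 2.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            aggregate_human([])


def brute_force_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


class TestPearson:
    def test_exact_linear(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_formula_example(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_matches_direct_formula_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            x = rng.standard_normal(n).tolist()
            y = rng.standard_normal(n).tolist()
            assert pearson_r(x, y) == pytest.approx(brute_force_pearson(x, y), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(InvalidInputError):
            pearson_r([1, 2], [1, 2, 3])
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 2], [2, 1])

    def test_spearman_monotone_transform(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_r(x, [math.exp(v) for v in x]) == pytest.approx(1.0)


def tiny_dataset():
    rng = np.random.default_rng(0)
    records = []
    for i in range(12):
        theta = i / 11
        score = min(max(theta + rng.normal(0, 0.02), 0.0), 1.0)
        records.append(
            PairRecord(f"s{i} tok", f"g{i} tok", human_scores=(score,), id=f"p{i}")
        )
    return Dataset(tuple(records))


class TestRunBenchmark:
    def test_identity_metric_scores_r_one(self, cfg42, stub16):
        ds = tiny_dataset()
        scorers = {"oracle": lambda p: aggregate_human(p.human_scores)}
        report = run_benchmark(ds, scorers, cfg42, stub16)
        assert report.per_metric["oracle"].r == pytest.approx(1.0)
        assert report.per_metric["oracle"].n_used == 12

    def test_constant_metric_degrades_gracefully(self, cfg42, stub16):
        ds = tiny_dataset()
        scorers = {
            "flat": lambda p: 0.5,
            "oracle": lambda p: aggregate_human(p.human_scores),
        }
        report = run_benchmark(ds, scorers, cfg42, stub16)
        assert report.per_metric["flat"].r is None
        assert report.per_metric["flat"].error is not None
        assert report.per_metric["oracle"].r == pytest.approx(1.0)

    def test_partition_counts_always_consistent(self, cfg42, stub16):
        long_pair = PairRecord(" ".join(["a"] * 14), "b c", human_scores=(0.1,), id="long")
        ds = Dataset(tiny_dataset().records + (long_pair,))
        report = run_benchmark(
            ds, {"oracle": lambda p: aggregate_human(p.human_scores)}, cfg42, stub16
        )
        assert report.n_kept + report.n_removed == report.n_input == 13
        assert report.n_removed == 1
        assert report.per_metric["oracle"].n_used <= report.n_kept

    def test_failing_pairs_excluded_not_fatal(self, cfg42, stub16):
        def flaky(p):
            if p.id == "p3":
                raise InvalidInputError("boom")
            return aggregate_human(p.human_scores)

        report = run_benchmark(tiny_dataset(), {"flaky": flaky}, cfg42, stub16)
        assert report.per_metric["flaky"].n_used == 11
        assert report.per_metric["flaky"].r == pytest.approx(1.0, abs=0.01)

    def test_report_serialization_is_byte_stable(self, cfg42, stub16):
        ds = tiny_dataset()
        scorers = {"oracle": lambda p: aggregate_human(p.human_scores)}
        r1 = run_benchmark(ds, scorers, cfg42, stub16).to_json()
        r2 = run_benchmark(ds, scorers, cfg42, stub16).to_json()
        assert r1 == r2

    def test_unknown_metric_name_rejected(self, cfg42, stub16):
        with pytest.raises(InvalidInputError, match="unknown metric"):
            run_benchmark(tiny_dataset(), ["nope"], cfg42, stub16)

    def test_all_filtered_out_rejected(self, stub16, cfg42):
        long_pair = PairRecord(" ".join(["a"] * 20), "b", human_scores=(0.5,), id="x")
        with pytest.raises(InvalidInputError, match="length filter"):
            run_benchmark(Dataset((long_pair,)), ["cosine"], cfg42, stub16)

    def test_markdown_table_lists_all_metrics(self, cfg42, stub16):
        report = run_benchmark(tiny_dataset(), ["cosine", "rouge1"], cfg42, stub16)
        md = report.to_markdown()
        assert "cosine" in md and "rouge1" in md
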