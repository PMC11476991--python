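"""FPKM arithmetic, replicate summaries and expressed-gene classification."""

import numpy as np
import pandas as pd
import pytest

from cmlight.expression import (
    classify_and_call,
    compute_fpkm,
    condition_means,
    count_filter,
    replicate_summary,
    round_half_up,
)


def frame(rows, samples=("s1", "s2")):
    return pd.DataFrame(rows, columns=list(samples))


class TestCountFilter:
    def test_below_threshold_everywhere_dropped(self):
        counts = pd.DataFrame({"s1": [4], "s2": [3]}, index=["gA"])
        filtered, stats = count_filter(counts, min_reads=5)
        assert len(filtered) == 0 and stats == {"n_kept": 0, "n_dropped": 1}

    def test_single_sample_at_threshold_kept(self):
        counts = pd.DataFrame({"s1": [5], "s2": [0]}, index=["gA"])
        filtered, _ = count_filter(counts, min_reads=5)
        assert list(filtered.index) == ["gA"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            count_filter(pd.DataFrame({"s1": [-1]}, index=["g"]))

    def test_matches_bruteforce_row_filter(self, rng_factory):
        rng = rng_factory(0)
        counts = pd.DataFrame(
            rng.integers(0, 30, size=(200, 4)),
            index=[f"g{i}" for i in range(200)],
            columns=list("abcd"),
        )
        filtered, _ = count_filter(counts, min_reads=5)
        expected = [g for g in counts.index if (counts.loc[g] >= 5).any()]
        assert list(filtered.index) == expected


class TestFpkm:
    def test_arithmetic_identity(self):
        counts = pd.DataFrame({"s": [10]}, index=["g"])
        fpkm = compute_fpkm(counts, {"g": 1000}, {"s": 1_000_000})
        assert fpkm.loc["g", "s"] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        counts = pd.DataFrame({"s": [0]}, index=["g"])
        assert compute_fpkm(counts, {"g": 500}, {"s": 100}).loc["g", "s"] == 0.0

    def test_matches_elementwise_oracle(self, rng_factory):
        rng = rng_factory(1)
        counts = pd.DataFrame(
            rng.integers(0, 5000, size=(100, 4)),
            index=[f"g{i}" for i in range(100)],
            columns=list("wxyz"),
        )
        lengths = pd.Series(rng.integers(300, 10000, 100), index=counts.index)
        fpkm = compute_fpkm(counts, lengths)
        lib = counts.sum(axis=0)
        for g in list(counts.index)[::17]:
            for s in counts.columns:
                expected = counts.loc[g, s] * 1e9 / (lengths[g] * lib[s])
                assert fpkm.loc[g, s] == pytest.approx(expected, rel=1e-12)

    def test_scale_consistency(self, rng_factory):
        rng = rng_factory(2)
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(20, 3)),
            index=[f"g{i}" for i in range(20)],
            columns=list("abc"),
        )
        lengths = pd.Series(rng.integers(300, 3000, 20), index=counts.index)
        lib = counts.sum(axis=0)
        a = compute_fpkm(counts, lengths, lib)
        b = compute_fpkm(counts * 2, lengths, lib * 2)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            compute_fpkm(pd.DataFrame({"s": [1]}, index=["g"]), {"g": 0}, {"s": 10})


class TestConditionMeans:
    def test_geometric_mean(self):
        fpkm = pd.DataFrame({"r1": [4.0], "r2": [16.0]}, index=["g"])
        m = condition_means(fpkm, {"r1": "L", "r2": "L"})
        assert m.loc["g", "L"] == pytest.approx(8.0)

    def test_zero_replicate_propagates(self):
        fpkm = pd.DataFrame({"r1": [0.0], "r2": [100.0]}, index=["g"])
        m = condition_means(fpkm, {"r1": "L", "r2": "L"})
        assert m.loc["g", "L"] == 0.0

    def test_matches_log_mean_oracle(self, rng_factory):
        rng = rng_factory(3)
        fpkm = pd.DataFrame(
            rng.uniform(0.5, 200, size=(50, 3)),
            index=[f"g{i}" for i in range(50)],
            columns=["r1", "r2", "r3"],
        )
        m = condition_means(fpkm, {c: "L" for c in fpkm.columns})
        oracle = np.exp(np.log(fpkm.to_numpy()).mean(axis=1))
        np.testing.assert_allclose(m["L"].to_numpy(), oracle, atol=1e-12)


class TestClassifyAndCall:
    def test_fpkm_exactly_ten_is_moderate(self):
        means = pd.DataFrame({"D": [10.0], "L": [10.0]}, index=["g"])
        s = classify_and_call(means)
        assert s.category.loc["g", "D"] == "10<=FPKM<100"

    def test_below_one_everywhere_outside_venn(self):
        means = pd.DataFrame({"D": [0.99], "L": [0.99]}, index=["g"])
        s = classify_and_call(means)
        assert s.venn == {"only_a": 0, "only_b": 0, "both": 0}
        assert s.n_expressed_total == 0

    def test_venn_matches_set_algebra(self, rng_factory):
        rng = rng_factory(4)
        means = pd.DataFrame(
            rng.uniform(0, 50, size=(1000, 2)),
            index=[f"g{i}" for i in range(1000)],
            columns=["D", "L"],
        )
        s = classify_and_call(means)
        in_d = {g for g in means.index if means.loc[g, "D"] >= 1}
        in_l = {g for g in means.index if means.loc[g, "L"] >= 1}
        assert s.venn == {
            "only_a": len(in_d - in_l),
            "only_b": len(in_l - in_d),
            "both": len(in_d & in_l),
        }
        assert s.n_expressed_total == len(in_d | in_l)

    def test_bins_partition_the_axis(self, rng_factory):
        rng = rng_factory(5)
        vals = np.concatenate([[0.0, 1.0, 10.0, 100.0], rng.uniform(0, 500, 200)])
        means = pd.DataFrame({"D": vals, "L": vals})
        s = classify_and_call(means)
        assert s.category.notna().all().all()
        # boundary values land in the right-closed-on-the-left bin
        assert s.category.iloc[1, 0] == "1<=FPKM<10"
        assert s.category.iloc[3, 0] == "FPKM>=100"


class TestReplicateSummary:
    def test_reported_sequencing_means(self):
        table = pd.DataFrame(
            {
                "clean_reads": [24.88, 19.96, 22.25, 24.48],
                "gc": [56, 56, 56, 57],
            }
        )
        out = replicate_summary(table)
        assert out.loc["clean_reads", "mean"] == 22.89
        assert out.loc["gc", "mean"] == 56.25

    def test_constant_column(self):
        out = replicate_summary(pd.DataFrame({"x": [5, 5, 5]}))
        assert out.loc["x", "mean"] == 5.00
        assert out.loc["x", "sd_sample"] == 0.00
        assert out.loc["x", "sd_population"] == 0.00

    def test_non_numeric_cell_named(self):
        with pytest.raises(ValueError, match="'x'"):
            replicate_summary(pd.DataFrame({"x": [1, "oops"]}))

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            replicate_summary(pd.DataFrame({"x": [1]}))


@pytest.mark.parametrize(
    "value,expected",
    [(0.005, 0.01), (2.675, 2.68), (95.755, 95.76), (22.8925, 22.89), (-0.005, -0.01)],
)
def test_round_half_up(value, expected):
    assert round_half_up(value, 2) == expected
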