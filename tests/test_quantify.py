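"""Counting, QC, normalization, isomiR grouping and batch adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_reads
from mirtriad import synthdata
from mirtriad.io import MirnaLocus
from mirtriad.quantify import (
    CountMatrix,
    NormalizedMatrix,
    batch_adjust,
    count_reads_per_mirna,
    detection_filter,
    group_isomirs,
    read_length_qc,
    rpm_normalize,
)


class TestCounting:
    LOCUS = MirnaLocus(name="mirA", chrom="chr1", start=90, end=130,
                       strand="+", mature_sequence="A" * 40)

    def test_contained_read_counts_once(self):
        reads = make_reads([("chr1", 100, 122, "s1", "+")])
        cm = count_reads_per_mirna(reads, [self.LOCUS])
        assert cm.values.loc["mirA", "s1"] == 1
        assert cm.sample_totals["s1"] == 1

    def test_opposite_strand_not_counted(self):
        reads = make_reads([("chr1", 100, 122, "s1", "-")])
        cm = count_reads_per_mirna(reads, [self.LOCUS])
        assert cm.values.loc["mirA", "s1"] == 0

    def test_single_base_overlap_counts(self):
        reads = make_reads([("chr1", 60, 91, "s1", "+"), ("chr1", 130, 150, "s1", "+")])
        cm = count_reads_per_mirna(reads, [self.LOCUS])
        # [60,91) overlaps base 90; [130,150) starts past the half-open end
        assert cm.values.loc["mirA", "s1"] == 1

    def test_multi_locus_read_counts_toward_each(self):
        other = MirnaLocus(name="mirB", chrom="chr1", start=110, end=150,
                           strand="+", mature_sequence="A" * 40)
        reads = make_reads([("chr1", 108, 130, "s1", "+")])
        cm = count_reads_per_mirna(reads, [self.LOCUS, other])
        assert cm.values["s1"].tolist() == [1, 1]
        assert cm.sample_totals["s1"] == 1  # the read itself is one read

    def test_malformed_interval_rejected(self):
        reads = make_reads([("chr1", 100, 100, "s1", "+")])
        reads.loc[0, "end"] = 90
        with pytest.raises(ValueError):
            count_reads_per_mirna(reads, [self.LOCUS])

    def test_simulated_reads_are_conserved(self):
        genome = synthdata.random_genome(600, seed=5)
        locus = MirnaLocus(name="mirC", chrom="chr1", start=300, end=322,
                           strand="+", mature_sequence=genome["chr1"][300:322])
        reads = synthdata.simulate_reads_at_locus(
            locus, {0: 0.6, -1: 0.25, 2: 0.15}, 1000, genome, seed=6
        )
        cm = count_reads_per_mirna(reads, [locus])
        assert cm.values.to_numpy().sum() == 1000


class TestReadLengthQC:
    def test_identical_histograms_all_pass(self):
        lengths = {f"s{i}": np.full(100, 22) for i in range(5)}
        report = read_length_qc(lengths)
        assert report["pass"].all()

    def test_uniform_outlier_flagged(self):
        rng = np.random.default_rng(0)
        lengths = {f"s{i}": rng.normal(22, 1, 500).round().astype(int) for i in range(9)}
        lengths["odd"] = rng.integers(15, 37, 500)
        report = read_length_qc(lengths, outlier_threshold=5)
        assert not report.loc["odd", "pass"]
        assert report.drop("odd")["pass"].all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            read_length_qc({"a": np.full(5, 22), "b": np.full(5, 22)})

    def test_empty_sample_fails_with_reason(self):
        lengths = {f"s{i}": np.full(50, 22) for i in range(4)}
        lengths["empty"] = np.array([], dtype=int)
        report = read_length_qc(lengths)
        assert not report.loc["empty", "pass"]
        assert report.loc["empty", "reason"] == "empty sample"


class TestNormalization:
    def test_rpm_arithmetic(self):
        cm = CountMatrix(
            values=pd.DataFrame({"s1": [999, 0]}, index=["a", "b"]),
            sample_totals=pd.Series({"s1": 1_000_000}),
        )
        nm = rpm_normalize(cm)
        assert nm.values.loc["a", "s1"] == pytest.approx(np.log2(1000), abs=1e-9)
        assert nm.values.loc["b", "s1"] == 0.0

    def test_zero_total_names_sample(self):
        cm = CountMatrix(
            values=pd.DataFrame({"s1": [1], "s2": [0]}, index=["a"]),
            sample_totals=pd.Series({"s1": 1, "s2": 0}),
        )
        with pytest.raises(ValueError, match="s2"):
            rpm_normalize(cm)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 10_000))
    def test_normalization_strictly_monotone(self, count, extra):
        total = 50_000
        cm = CountMatrix(
            values=pd.DataFrame({"s": [count, count + extra]}, index=["lo", "hi"]),
            sample_totals=pd.Series({"s": total}),
        )
        nm = rpm_normalize(cm)
        assert nm.values.loc["hi", "s"] > nm.values.loc["lo", "s"]


class TestDetectionFilter:
    @pytest.mark.parametrize(
        "row,kept",
        [([2, 2, 0, 0], True),     # exactly 50%
         ([2, 1, 1, 1], False),    # 25%
         ([0, 0, 0, 0], False)],
    )
    def test_detection_rule(self, row, kept):
        mat = pd.DataFrame([row], index=["m"], columns=list("abcd"))
        assert (["m"] if kept else []) == detection_filter(mat)

    def test_filter_is_idempotent(self, rng):
        mat = pd.DataFrame(rng.integers(0, 5, size=(30, 8)))
        once = detection_filter(mat)
        assert detection_filter(mat.loc[once]) == once


class TestIsomirs:
    GENOME = synthdata.random_genome(800, seed=9)

    def locus(self, strand="+"):
        return MirnaLocus(name="mirI", chrom="chr1", start=500, end=522,
                          strand=strand,
                          mature_sequence=self.GENOME["chr1"][500:522])

    def test_direct_grouping(self):
        rows = (
            [("chr1", 500, 522, "s1", "+")] * 70
            + [("chr1", 499, 521, "s1", "+")] * 20
            + [("chr1", 501, 523, "s1", "+")] * 10
        )
        records = group_isomirs(make_reads(rows), self.locus())
        assert [(r.offset5, r.total) for r in records] == [(-1, 20), (0, 70), (1, 10)]

    def test_single_read(self):
        records = group_isomirs(make_reads([("chr1", 498, 520, "s1", "+")]), self.locus())
        assert len(records) == 1 and records[0].offset5 == -2 and records[0].total == 1

    def test_wrong_strand_ignored(self):
        rows = [("chr1", 500, 522, "s1", "+"), ("chr1", 500, 522, "s1", "-")]
        records = group_isomirs(make_reads(rows), self.locus())
        assert sum(r.total for r in records) == 1

    def test_minus_strand_offset_from_interval_end(self):
        records = group_isomirs(make_reads([("chr1", 501, 523, "s1", "-")]),
                                self.locus("-"))
        assert records[0].offset5 == -1

    def test_counts_conserve_locus_total(self, rng):
        locus = self.locus()
        reads = synthdata.simulate_reads_at_locus(
            locus, {0: 0.5, -1: 0.2, 1: 0.2, 3: 0.1}, 500, self.GENOME, seed=13
        )
        records = group_isomirs(reads, locus)
        assert sum(r.total for r in records) == 500


class TestBatchAdjust:
    def test_single_batch_is_identity(self, rng):
        nm = NormalizedMatrix(values=pd.DataFrame(rng.normal(size=(5, 10))))
        out = batch_adjust(nm, pd.Series(["A"] * 10, index=nm.values.columns))
        pd.testing.assert_frame_equal(out.values, nm.values)
        assert out.batch_adjusted

    def test_singleton_batch_rejected(self, rng):
        nm = NormalizedMatrix(values=pd.DataFrame(rng.normal(size=(5, 5))))
        batch = pd.Series(["A", "A", "A", "A", "B"], index=nm.values.columns)
        with pytest.raises(ValueError):
            batch_adjust(nm, batch)

    def test_batch_shift_largely_removed_and_group_effect_preserved(self, rng):
        n = 200
        vals = rng.normal(size=(20, 2 * n))
        vals[:, n:] += 3.0
        group = np.tile(np.r_[np.zeros(n // 2), np.ones(n // 2)], 2)
        vals[:5] += 2.0 * group
        cols = [f"s{i}" for i in range(2 * n)]
        nm = NormalizedMatrix(values=pd.DataFrame(vals, columns=cols))
        batch = pd.Series(["A"] * n + ["B"] * n, index=cols)
        covs = pd.DataFrame({"group": group}, index=cols)
        adj = batch_adjust(nm, batch, covariates=covs)
        mean_diff = (adj.values.iloc[:, :n].mean(axis=1)
                     - adj.values.iloc[:, n:].mean(axis=1))
        # the planted shift of 3 is removed down to EB sampling noise
        assert np.abs(mean_diff).max() < 0.3
        g1 = adj.values.loc[:, group == 1].iloc[:5].mean(axis=1)
        g0 = adj.values.loc[:, group == 0].iloc[:5].mean(axis=1)
        assert np.abs((g1 - g0) - 2.0).max() < 0.1
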