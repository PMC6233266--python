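"""Peak parsing, window geometry, nearest-TSS assignment and enrichment calls."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from coreg_ir.binding import (
    PeakParseError,
    assign_peaks,
    call_enhanced,
    enhanced_binding_test,
    read_narrowpeak,
    regulatory_windows,
)


class TestReadNarrowPeak:
    def test_summit_from_offset(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t0\t.\t5.0\t3.0\t2.0\t50\n")
        peaks = read_narrowpeak(path)
        assert peaks.loc[0, "summit"] == 150

    def test_missing_offset_uses_midpoint(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t0\t.\t5.0\t3.0\t2.0\t-1\n")
        assert read_narrowpeak(path).loc[0, "summit"] == 150

    def test_empty_file_empty_frame(self, tmp_path):
        path = tmp_path / "empty.narrowPeak"
        path.write_text("")
        assert len(read_narrowpeak(path)) == 0

    @pytest.mark.parametrize("line", [
        "chr1\t100\t200\tp1\t0\t.\t5.0\t3.0\t2.0",      # 9 columns
        "chr1\t200\t100\tp1\t0\t.\t5.0\t3.0\t2.0\t10",  # inverted interval
        "chr1\tx\t200\tp1\t0\t.\t5.0\t3.0\t2.0\t10",    # non-numeric
        "chr1\t100\t200\tp1\t0\t.\t5.0\t3.0\t2.0\t150", # offset outside
    ])
    def test_malformed_line_reports_line_number(self, tmp_path, line):
        path = tmp_path / "bad.narrowPeak"
        path.write_text(line + "\n")
        with pytest.raises(PeakParseError, match=":1"):
            read_narrowpeak(path)


class TestRegulatoryWindows:
    def test_symmetric_window(self):
        ann = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                            "tss": [5000], "strand": ["+"]})
        win = regulatory_windows(ann)
        assert (win.loc[0, "start"], win.loc[0, "end"]) == (2000, 8000)

    def test_clipped_at_contig_bounds(self):
        ann = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                            "tss": [1000], "strand": ["-"]})
        win = regulatory_windows(ann, contig_lengths={"chr1": 10_000})
        assert (win.loc[0, "start"], win.loc[0, "end"]) == (0, 4000)

    def test_overlapping_windows_both_emitted(self):
        ann = pd.DataFrame({"gene_id": ["a", "b"], "chrom": ["chr1"] * 2,
                            "tss": [5000, 5002], "strand": ["+", "-"]})
        win = regulatory_windows(ann)
        assert len(win) == 2

    def test_tss_off_contig_rejected(self):
        ann = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                            "tss": [20_000], "strand": ["+"]})
        with pytest.raises(ValueError):
            regulatory_windows(ann, contig_lengths={"chr1": 10_000})


class TestAssignPeaks:
    def _windows(self, tss_list):
        ann = pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(tss_list))],
                            "chrom": "chr1", "tss": tss_list,
                            "strand": "+"})
        return regulatory_windows(ann)

    def _peaks(self, summits):
        return pd.DataFrame({"chrom": "chr1", "summit": summits,
                             "start": [s - 10 for s in summits],
                             "end": [s + 10 for s in summits]})

    def test_window_boundary_half_open(self):
        """3000 bp upstream is the last position inside; 3001 falls out."""
        windows = self._windows([10_000])
        out = assign_peaks(self._peaks([7000, 6999]), windows)
        assert out.loc[0, "gene_id"] == "g0"
        assert pd.isna(out.loc[1, "gene_id"])

    def test_equidistant_tie_breaks_to_smaller_gene_id(self):
        windows = self._windows([10_000, 12_000])
        out = assign_peaks(self._peaks([11_000]), windows)
        assert out.loc[0, "gene_id"] == "g0"

    def test_summit_at_tss(self):
        windows = self._windows([10_000])
        out = assign_peaks(self._peaks([10_000]), windows)
        assert out.loc[0, "gene_id"] == "g0"
        assert out.loc[0, "tss_distance"] == 0

    def test_assigned_summits_always_inside_window(self, rng):
        """Invariant: every assignment keeps the summit in its gene's window."""
        tss = np.sort(rng.choice(np.arange(5000, 500_000), size=40, replace=False))
        windows = self._windows(list(tss))
        summits = rng.integers(0, 510_000, size=500)
        out = assign_peaks(self._peaks(list(summits)), windows)
        merged = out.dropna(subset=["gene_id"]).merge(
            windows, on="gene_id", suffixes=("", "_w"))
        assert ((merged["summit"] >= merged["start_w"])
                & (merged["summit"] < merged["end_w"])).all()


class TestEnhancedBindingTest:
    def test_balanced_counts_not_significant(self):
        assert enhanced_binding_test(10, 10, 1e6, 1e6) > 0.5

    def test_matches_exact_binomial_tail(self):
        """p equals the enumerated tail sum over k = 30..35 of C(35,k)/2^35."""
        p = enhanced_binding_test(30, 5, 1e6, 1e6)
        oracle = sum(comb(35, k) for k in range(30, 36)) * 0.5 ** 35
        assert p == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("treated,control", [(0, 0), (0, 25)])
    def test_no_treated_reads_is_null(self, treated, control):
        assert enhanced_binding_test(treated, control, 1e6, 1e6) == 1.0

    def test_tail_matches_enumeration_for_unequal_libsizes(self):
        pr = 2e6 / 3e6
        p = enhanced_binding_test(20, 10, 2e6, 1e6)
        oracle = sum(comb(30, k) * pr ** k * (1 - pr) ** (30 - k) for k in range(20, 31))
        assert p == pytest.approx(oracle, rel=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            enhanced_binding_test(-1, 0, 1e6, 1e6)
        with pytest.raises(ValueError):
            enhanced_binding_test(1, 0, 0, 1e6)


def _region_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "tf", "timepoint", "peak_id",
                                       "treated_count", "control_count",
                                       "treated_libsize", "control_libsize"])


class TestCallEnhanced:
    def test_no_peaks_no_flags(self):
        calls, flags = call_enhanced(_region_table([]))
        assert len(calls) == 0 and len(flags) == 0

    def test_either_timepoint_or(self):
        rows = [("g1", "p53", "2h", "p1", 10, 11, 1e6, 1e6),
                ("g1", "p53", "4h", "p2", 200, 10, 1e6, 1e6)]
        _, flags = call_enhanced(_region_table(rows))
        row = flags.set_index(["gene_id", "tf"]).loc[("g1", "p53")]
        assert not row["enhanced_2h"]
        assert row["enhanced_4h"]
        assert row["enhanced_either"]

    def test_enlarging_fdr_never_removes_calls(self, rng):
        """Benjamini-Hochberg monotonicity in the FDR level."""
        rows = [(f"g{i}", "RelA", "2h", f"p{i}",
                 int(rng.poisson(60 if i % 5 == 0 else 20)), int(rng.poisson(20)),
                 1e6, 1e6) for i in range(50)]
        calls_small, _ = call_enhanced(_region_table(rows), fdr=0.01)
        calls_big, _ = call_enhanced(_region_table(rows), fdr=0.10)
        small = set(calls_small.loc[calls_small["enhanced"], "peak_id"])
        big = set(calls_big.loc[calls_big["enhanced"], "peak_id"])
        assert small <= big

    def test_enhanced_implies_q_below_threshold(self, rng):
        rows = [(f"g{i}", "p53", "4h", f"p{i}",
                 int(rng.poisson(100 if i < 10 else 20)), int(rng.poisson(20)),
                 1e6, 1e6) for i in range(40)]
        calls, _ = call_enhanced(_region_table(rows), fdr=0.05)
        assert (calls.loc[calls["enhanced"], "q_value"] <= 0.05).all()
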