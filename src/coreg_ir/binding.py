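"""Peak-to-gene assignment and radiation-enhanced binding calls.

A gene's putative regulatory region is the symmetric window from 3000 bp
upstream to 3000 bp downstream of its TSS (0-based half-open, clipped at
contig ends). A peak belongs to the gene with the nearest TSS provided its
summit lies inside that gene's window. Enhancement of binding after
irradiation is decided from region read counts with a one-sided binomial
rate-ratio test, Benjamini-Hochberg corrected per TF and timepoint at
FDR 0.05, with gene-level flags OR-ed over peaks and over the 2 h / 4 h
timepoints ("either timepoint").
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

WINDOW = 3000

NARROWPEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                      "signal_value", "p_value", "q_value", "summit_offset"]


class PeakParseError(ValueError):
    pass


def read_narrowpeak(path) -> pd.DataFrame:
    """Parse an ENCODE narrowPeak file into a validated DataFrame.

    Adds an absolute ``summit`` column (start + offset, or the interval
    midpoint when the offset is -1). An empty file yields an empty frame.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 10:
                raise PeakParseError(f"{path}:{lineno}: expected 10 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
                offset = int(parts[9])
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: {exc}") from exc
            if not 0 <= start < end:
                raise PeakParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if offset >= end - start:
                raise PeakParseError(f"{path}:{lineno}: summit offset outside interval")
            rows.append((parts[0], start, end, parts[3], parts[4], parts[5],
                         float(parts[6]), float(parts[7]), float(parts[8]), offset))
    peaks = pd.DataFrame(rows, columns=NARROWPEAK_COLUMNS)
    if peaks.empty:
        peaks = pd.DataFrame(columns=NARROWPEAK_COLUMNS + ["summit"])
        return peaks.astype({"start": int, "end": int, "summit": int}, errors="ignore")
    mid = (peaks["start"] + peaks["end"]) // 2
    peaks["summit"] = np.where(peaks["summit_offset"] >= 0,
                               peaks["start"] + peaks["summit_offset"], mid)
    return peaks


def regulatory_windows(
    annotation: pd.DataFrame,
    contig_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """TSS +/- 3000 bp windows, strand-agnostic, clipped at contig bounds."""
    win = annotation[["gene_id", "chrom", "tss", "strand"]].copy()
    win["start"] = (win["tss"] - WINDOW).clip(lower=0)
    win["end"] = win["tss"] + WINDOW
    if contig_lengths:
        lengths = win["chrom"].map(contig_lengths)
        if lengths.isna().any() or (win["tss"] >= lengths).any() or (win["tss"] < 0).any():
            bad = win.loc[lengths.isna() | (win["tss"] >= lengths.fillna(0)), "gene_id"].tolist()
            raise ValueError(f"TSS off contig for genes {bad}")
        win["end"] = np.minimum(win["end"], lengths)
    return win[["gene_id", "chrom", "start", "end", "tss", "strand"]]


def assign_peaks(peaks: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Assign each peak summit to the nearest-TSS gene whose window holds it.

    Ties in TSS distance break to the lexicographically smaller gene_id.
    Peaks whose nearest window does not contain the summit stay unassigned
    (gene_id is missing in the returned frame).
    """
    out = peaks.copy()
    out["gene_id"] = pd.NA
    out["tss_distance"] = np.nan
    for chrom, wsub in windows.groupby("chrom"):
        mask = out["chrom"] == chrom
        if not mask.any():
            continue
        # sort by (tss, gene_id) so equidistant neighbours resolve to the
        # smaller gene_id deterministically
        wsub = wsub.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        tss = wsub["tss"].to_numpy()
        summits = out.loc[mask, "summit"].to_numpy()
        right = np.searchsorted(tss, summits, side="left")
        left = np.clip(right - 1, 0, len(tss) - 1)
        right = np.clip(right, 0, len(tss) - 1)
        d_left = np.abs(summits - tss[left])
        d_right = np.abs(summits - tss[right])
        pick_left = (d_left < d_right) | (
            (d_left == d_right)
            & (wsub["gene_id"].to_numpy()[left] <= wsub["gene_id"].to_numpy()[right]))
        idx = np.where(pick_left, left, right)
        dist = np.where(pick_left, d_left, d_right)
        starts = wsub["start"].to_numpy()[idx]
        ends = wsub["end"].to_numpy()[idx]
        inside = (summits >= starts) & (summits < ends)
        genes = wsub["gene_id"].to_numpy()[idx]
        assigned = np.where(inside, genes, None)
        out.loc[mask, "gene_id"] = assigned
        out.loc[mask, "tss_distance"] = np.where(inside, dist, np.nan)
    return out


def enhanced_binding_test(
    treated_count: int,
    control_count: int,
    treated_libsize: float,
    control_libsize: float,
) -> float:
    """One-sided binomial test for read-rate enrichment in the treated sample.

    Conditions on n = treated + control reads; under the null each read is
    treated with probability treated_libsize / (treated + control libsize).
    Small p means enrichment after treatment.
    """
    if treated_count < 0 or control_count < 0:
        raise ValueError("counts must be non-negative")
    if treated_libsize <= 0 or control_libsize <= 0:
        raise ValueError("library sizes must be positive")
    n = treated_count + control_count
    if n == 0:
        return 1.0
    pr = treated_libsize / (treated_libsize + control_libsize)
    return stats.binomtest(treated_count, n, pr, alternative="greater").pvalue


def call_enhanced(
    tested_regions: pd.DataFrame,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BH-corrected enhanced-binding calls plus per-gene either-timepoint flags.

    ``tested_regions`` needs columns gene_id, tf, timepoint, peak_id and the
    four count/libsize columns; rows without a gene assignment are tested
    but excluded from gene flags. Correction is applied across all tested
    regions within each TF x timepoint stratum.
    Returns (per-region calls with q-values, per-gene flag table).
    """
    calls = tested_regions.copy()
    calls["p_value"] = [
        enhanced_binding_test(r.treated_count, r.control_count,
                              r.treated_libsize, r.control_libsize)
        for r in calls.itertuples(index=False)
    ]
    calls["q_value"] = np.nan
    calls["enhanced"] = False
    for _, idx in calls.groupby(["tf", "timepoint"]).groups.items():
        p = calls.loc[idx, "p_value"].to_numpy()
        _, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
        calls.loc[idx, "q_value"] = q
        calls.loc[idx, "enhanced"] = q <= fdr
    assigned = calls.dropna(subset=["gene_id"])
    flags = (assigned.groupby(["gene_id", "tf", "timepoint"])["enhanced"]
             .any().unstack("timepoint", fill_value=False))
    flags = flags.reindex(columns=["2h", "4h"], fill_value=False)
    gene_flags = flags.reset_index().rename(
        columns={"2h": "enhanced_2h", "4h": "enhanced_4h"})
    gene_flags["enhanced_either"] = gene_flags["enhanced_2h"] | gene_flags["enhanced_4h"]
    return calls, gene_flags


def binding_calls_from_regions(
    regions: pd.DataFrame,
    annotation: pd.DataFrame,
    contig_lengths: dict[str, int] | None = None,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window assignment + enhancement testing for a region-count table."""
    windows = regulatory_windows(annotation, contig_lengths)
    assigned = assign_peaks(regions, windows)
    return call_enhanced(assigned, fdr=fdr)
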