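"""Count normalization and radiation-modulated expression calls.

Normalization is the classical median-of-ratios: each sample's size factor
is the median, over genes with all-positive counts, of the ratio of the
sample's count to the gene's geometric mean across samples. Differential
calls use a mean-based fold change on the normalized scale plus a classical
equal-variance Student t-test on log2(x+1) values; a gene is modulated when
either dose shows ratio > 1.5 (up) or < 0.67 (down) with raw p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionThresholds:
    ratio_hi: float = 1.5
    ratio_lo: float = 0.67
    p_max: float = 0.05

    def __post_init__(self) -> None:
        if not self.ratio_lo < 1.0 < self.ratio_hi:
            raise ValueError("need ratio_lo < 1 < ratio_hi")
        if not 0.0 < self.p_max < 1.0:
            raise ValueError("p_max must be in (0, 1)")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Only genes with strictly positive counts in every sample contribute.
    The geometric mean of the factors is not rescaled to 1.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError("no gene has positive counts in all samples")
    ref = np.exp(np.log(x[positive]).mean(axis=1))
    factors = np.median(x[positive] / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def filter_low_signal(normalized: pd.DataFrame) -> pd.Index:
    """Genes whose maximal normalized signal exceeds the grand median.

    The median is taken over every gene x sample cell; the comparison is
    strict, so a flat matrix retains nothing.
    """
    if normalized.size == 0:
        raise ValueError("empty matrix")
    grand_median = float(np.median(normalized.to_numpy()))
    keep = normalized.max(axis=1) > grand_median
    return normalized.index[keep]


def differential_expression(
    normalized: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Per-gene fold change mean(B)/mean(A) and two-sided Student t p-value.

    The t-test is the classical equal-variance form on log2(x+1) normalized
    values. Genes with zero group-A mean get a missing fold change;
    degenerate tests (zero variance in both groups) report p = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = normalized[group_a].to_numpy(dtype=float)
    b = normalized[group_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_a > 0, mean_b / mean_a, np.nan)
    if np.isnan(fc).any():
        warnings.warn(f"{int(np.isnan(fc).sum())} genes have zero reference mean; "
                      "fold change reported as missing", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(np.log2(b + 1), np.log2(a + 1), axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({"fold_change": fc, "p_value": p}, index=normalized.index)


def call_modulated(
    records: pd.DataFrame,
    thresholds: ExpressionThresholds = ExpressionThresholds(),
) -> pd.DataFrame:
    """Either-dose modulation call: up, down or none per gene.

    ``records`` needs columns fc_4gy, p_4gy, fc_10gy, p_10gy. A gene is up
    if any dose passes (fc > ratio_hi and p < p_max), down symmetrically.
    Genes significant in opposite directions at the two doses are marked as
    conflicts and called none.
    """
    for col in ("fc_4gy", "p_4gy", "fc_10gy", "p_10gy"):
        if col not in records.columns:
            raise ValueError(f"missing dose column {col!r}")
    th = thresholds
    up = pd.Series(False, index=records.index)
    down = pd.Series(False, index=records.index)
    for dose in ("4gy", "10gy"):
        fc = records[f"fc_{dose}"]
        p = records[f"p_{dose}"]
        sig = p < th.p_max
        up |= (fc > th.ratio_hi) & sig
        down |= (fc < th.ratio_lo) & sig
    conflict = up & down
    out = pd.DataFrame(index=records.index)
    out["modulated"] = np.select(
        [conflict, up, down], ["none", "up", "down"], default="none")
    out["conflict"] = conflict
    return out


def expression_table(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    arm: str = "siCTR",
    doses: tuple[int, ...] = (4, 10),
    thresholds: ExpressionThresholds = ExpressionThresholds(),
) -> pd.DataFrame:
    """Full per-gene record: fold change + p per dose and modulation call.

    Fold changes compare each irradiated condition against the untreated
    control within one siRNA arm (the wild-type-like siCTR arm by default).
    """
    def samples(cond: str) -> list[str]:
        sel = design[(design["condition"] == cond) & (design["arm"] == arm)]
        return sel["sample"].tolist()

    ctrl = samples("control")
    out = pd.DataFrame(index=normalized.index)
    for dose in doses:
        de = differential_expression(normalized, ctrl, samples(f"IR{dose}"))
        out[f"fc_{dose}gy"] = de["fold_change"]
        out[f"p_{dose}gy"] = de["p_value"]
    calls = call_modulated(out, thresholds)
    out["modulated"] = calls["modulated"]
    out["conflict"] = calls["conflict"]
    return out
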