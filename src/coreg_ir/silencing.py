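"""Effect of TF knockdown on stimulus-modulated expression, plus qPCR math.

The screen's silencing rule is ratio-only: expression under stimulation in
the TF-silenced arm divided by the control-siRNA arm; a gene is inhibited
by the knockdown when the ratio falls below 0.67 at either dose and
stimulated when it exceeds 1.5 (a difference larger than 50% either way).
The qPCR helper implements relative quantification against the geometric
mean of reference genes (delta-delta-Cq, base 2).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionThresholds

ARM_TO_TF = {"siRELA": "RelA", "siTP53": "p53"}


def silencing_ratio(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    arm: str,
    dose: int,
    control_arm: str = "siCTR",
) -> pd.Series:
    """Per-gene mean expression ratio siTF / siCTR under a given dose."""
    cond = f"IR{dose}"

    def cols(a: str) -> list[str]:
        sel = design[(design["condition"] == cond) & (design["arm"] == a)]
        if sel.empty:
            raise ValueError(f"no samples for arm {a!r} at condition {cond!r}")
        return sel["sample"].tolist()

    num = normalized[cols(arm)].mean(axis=1)
    den = normalized[cols(control_arm)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio = ratio.where(den > 0)
    if ratio.isna().any():
        warnings.warn(f"{int(ratio.isna().sum())} genes have zero control-arm mean; "
                      "ratio reported as missing", stacklevel=2)
    ratio.name = f"{arm}_ratio_{dose}gy"
    return ratio


def call_affected(
    ratio_4gy: pd.Series,
    ratio_10gy: pd.Series,
    thresholds: ExpressionThresholds = ExpressionThresholds(),
) -> pd.DataFrame:
    """Either-dose direction call: inhibited, stimulated or none.

    A gene hitting both thresholds across the two doses is a conflict and
    is called none.
    """
    th = thresholds
    inhibited = (ratio_4gy < th.ratio_lo) | (ratio_10gy < th.ratio_lo)
    stimulated = (ratio_4gy > th.ratio_hi) | (ratio_10gy > th.ratio_hi)
    conflict = inhibited & stimulated
    direction = np.select(
        [conflict, inhibited.fillna(False), stimulated.fillna(False)],
        ["none", "inhibited", "stimulated"], default="none")
    return pd.DataFrame({
        "ratio_4gy": ratio_4gy, "ratio_10gy": ratio_10gy,
        "direction": direction, "conflict": conflict.fillna(False),
    })


def silencing_table(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    doses: tuple[int, ...] = (4, 10),
    thresholds: ExpressionThresholds = ExpressionThresholds(),
) -> pd.DataFrame:
    """Long-format SilencingCall table over both TF arms.

    Columns: gene_id, tf, ratio_4gy, ratio_10gy, direction, conflict.
    """
    frames = []
    for arm, tf in ARM_TO_TF.items():
        ratios = {d: silencing_ratio(normalized, design, arm, d) for d in doses}
        calls = call_affected(ratios[doses[0]], ratios[doses[1]], thresholds)
        calls.insert(0, "tf", tf)
        calls.index.name = "gene_id"
        frames.append(calls.reset_index())
    return pd.concat(frames, ignore_index=True)


def qpcr_relative_expression(
    cq_table: pd.DataFrame,
    reference_genes: list[str],
    target: str,
    test_condition: str,
    control_condition: str,
) -> dict:
    """Relative expression of ``target`` in test vs control condition.

    ``cq_table`` is long format with columns gene, condition, replicate, Cq.
    Each replicate's delta-Cq is the target Cq minus the arithmetic mean of
    the reference-gene Cq values in the same replicate (equivalently the
    geometric mean of their linear quantities). Fold change is
    2**(mean dCq_control - mean dCq_test); a two-sample t-test on the two
    delta-Cq sets gives the p-value.
    """
    if not reference_genes:
        raise ValueError("need at least one reference gene")

    def delta_cqs(condition: str) -> np.ndarray:
        sub = cq_table[cq_table["condition"] == condition]
        deltas = []
        for rep, grp in sub.groupby("replicate"):
            by_gene = grp.set_index("gene")["Cq"]
            missing = [g for g in reference_genes + [target] if g not in by_gene.index]
            if missing:
                raise ValueError(f"missing Cq for {missing} in condition {condition!r}, "
                                 f"replicate {rep!r}")
            deltas.append(by_gene[target] - by_gene[reference_genes].mean())
        if not deltas:
            raise ValueError(f"no replicates for condition {condition!r}")
        return np.asarray(deltas, dtype=float)

    d_test = delta_cqs(test_condition)
    d_ctrl = delta_cqs(control_condition)
    fold = float(2.0 ** (d_ctrl.mean() - d_test.mean()))
    if len(d_test) >= 2 and len(d_ctrl) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.ttest_ind(d_test, d_ctrl, equal_var=True)
        p = 1.0 if np.isnan(p) else float(p)
    else:
        p = float("nan")
    return {"fold_change": fold, "p_value": p,
            "delta_cq_test": d_test, "delta_cq_control": d_ctrl}
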