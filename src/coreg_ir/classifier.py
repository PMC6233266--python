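"""Integration of expression, binding and silencing evidence per gene.

A gene is called dependent on a transcription factor when three conditions
coincide: its expression is radiation-modulated, radiation enhances binding
of that TF in its regulatory window (at either timepoint), and silencing
the TF's gene shifts the stimulus-driven expression past the ratio
thresholds. Genes dependent on both factors are further assigned a
co-regulation mode: co-activated when silencing either factor inhibits
expression, antagonistic when the two silencings act in opposite
directions (sub-labelled by which factor activates), co-repressed when
both silencings stimulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .expression import ExpressionThresholds, call_modulated
from .silencing import call_affected
from .fixtures import load_table1, load_validation

MODES = ("coactivated", "antagonistic_nfkb_act_p53_rep",
         "antagonistic_p53_act_nfkb_rep", "corepressed",
         "single_tf", "unclassified")


@dataclass(frozen=True)
class GeneClassification:
    gene_id: str
    modulated: str
    p53_dependent: bool
    nfkb_dependent: bool
    group: str
    mode: str


def classify_gene(
    gene_id: str,
    modulated: str,
    p53_bound_either: bool,
    rela_bound_either: bool,
    sitp53_direction: str,
    sirela_direction: str,
) -> GeneClassification:
    """TF-dependency classification of one gene.

    Dependency on a TF needs all three legs: modulation, enhanced binding
    of that TF, and a silencing effect of that TF's knockdown. A silencing
    effect without binding (or vice versa) does not confer dependency.
    """
    is_modulated = modulated in ("up", "down")
    p53_dep = bool(p53_bound_either) and sitp53_direction != "none" and is_modulated
    nfkb_dep = bool(rela_bound_either) and sirela_direction != "none" and is_modulated
    if p53_dep and nfkb_dep:
        group = "both"
    elif p53_dep:
        group = "p53_only"
    elif nfkb_dep:
        group = "nfkb_only"
    else:
        group = "neither"
    mode = coregulation_mode(
        modulated=modulated,
        p53_bound=p53_dep, nfkb_bound=nfkb_dep,
        sitp53_direction=sitp53_direction, sirela_direction=sirela_direction,
    )
    return GeneClassification(gene_id, modulated, p53_dep, nfkb_dep, group, mode)


def coregulation_mode(
    modulated: str,
    p53_bound: bool,
    nfkb_bound: bool,
    sitp53_direction: str,
    sirela_direction: str,
) -> str:
    """Mode of co-regulation given confirmed binding and silencing directions.

    Defined for radiation-upregulated genes with both factors confirmed;
    one confirmed factor gives ``single_tf``, anything else is
    ``unclassified``.
    """
    if modulated != "up":
        return "unclassified"
    if p53_bound and nfkb_bound:
        if sitp53_direction == "inhibited" and sirela_direction == "inhibited":
            return "coactivated"
        if sitp53_direction == "stimulated" and sirela_direction == "inhibited":
            return "antagonistic_nfkb_act_p53_rep"
        if sitp53_direction == "inhibited" and sirela_direction == "stimulated":
            return "antagonistic_p53_act_nfkb_rep"
        if sitp53_direction == "stimulated" and sirela_direction == "stimulated":
            return "corepressed"
        return "unclassified"
    if p53_bound or nfkb_bound:
        return "single_tf"
    return "unclassified"


def classify_genes(
    expression: pd.DataFrame,
    binding_flags: pd.DataFrame,
    silencing: pd.DataFrame,
) -> pd.DataFrame:
    """Classify every gene present in all three evidence tables.

    ``expression`` is indexed by gene with a ``modulated`` column;
    ``binding_flags`` is long format (gene_id, tf, enhanced_either);
    ``silencing`` is long format (gene_id, tf, direction). Genes missing
    from an input are skipped (binding/silencing absence is treated as a
    negative, missing expression as missing input).
    """
    bind = binding_flags.pivot_table(index="gene_id", columns="tf",
                                     values="enhanced_either", aggfunc="any")
    sil = silencing.pivot(index="gene_id", columns="tf", values="direction")
    rows = []
    for gene_id, erow in expression.iterrows():
        p53_b = bool(bind.at[gene_id, "p53"]) if (
            gene_id in bind.index and "p53" in bind.columns
            and pd.notna(bind.at[gene_id, "p53"])) else False
        rela_b = bool(bind.at[gene_id, "RelA"]) if (
            gene_id in bind.index and "RelA" in bind.columns
            and pd.notna(bind.at[gene_id, "RelA"])) else False
        sitp53 = sil.at[gene_id, "p53"] if (
            gene_id in sil.index and "p53" in sil.columns
            and pd.notna(sil.at[gene_id, "p53"])) else "none"
        sirela = sil.at[gene_id, "RelA"] if (
            gene_id in sil.index and "RelA" in sil.columns
            and pd.notna(sil.at[gene_id, "RelA"])) else "none"
        cls = classify_gene(gene_id, erow["modulated"], p53_b, rela_b, sitp53, sirela)
        rows.append(cls.__dict__)
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# packaged candidate-table fixture

def classify_table1(
    fixture: pd.DataFrame | None = None,
    thresholds: ExpressionThresholds = ExpressionThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the classification rules on the packaged 28-gene candidate table.

    Modulation is recomputed from the fold changes and significance marks,
    silencing directions from the ratio columns, binding from the
    per-timepoint flags. Returns (per-gene table, group counts).
    """
    df = load_table1() if fixture is None else fixture.copy()
    # significance marks stand in for the raw p-values of the full screen
    records = pd.DataFrame({
        "fc_4gy": df["fc_4gy"].to_numpy(),
        "p_4gy": [0.01 if s else 0.5 for s in df["sig_4gy"]],
        "fc_10gy": df["fc_10gy"].to_numpy(),
        "p_10gy": [0.01 if s else 0.5 for s in df["sig_10gy"]],
    }, index=pd.Index(df["gene_id"], name="gene_id"))
    modulated = call_modulated(records, thresholds)["modulated"]
    sirela = call_affected(df.set_index("gene_id")["sirela_4gy"],
                           df.set_index("gene_id")["sirela_10gy"], thresholds)
    sitp53 = call_affected(df.set_index("gene_id")["sitp53_4gy"],
                           df.set_index("gene_id")["sitp53_10gy"], thresholds)
    rows = []
    for g in df.itertuples(index=False):
        cls = classify_gene(
            g.gene_id,
            modulated[g.gene_id],
            p53_bound_either=bool(g.p53_2h or g.p53_4h),
            rela_bound_either=bool(g.rela_2h or g.rela_4h),
            sitp53_direction=sitp53.at[g.gene_id, "direction"],
            sirela_direction=sirela.at[g.gene_id, "direction"],
        )
        rows.append(cls.__dict__)
    out = pd.DataFrame(rows).set_index("gene_id")
    counts = {grp: int((out["group"] == grp).sum())
              for grp in ("p53_only", "nfkb_only", "both", "neither")}
    return out, counts


def validated_candidates(fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """Directly co-regulated candidates from the validation fixture.

    A candidate requires qPCR-confirmed radiation-enhanced binding of both
    factors plus a significant silencing effect for both knockdowns; each
    candidate carries its co-regulation mode. Genes failing either leg are
    returned with candidate=False.
    """
    df = load_validation() if fixture is None else fixture.copy()
    rows = []
    for g in df.itertuples(index=False):
        both_bound = bool(g.rela_binding_confirmed and g.p53_binding_confirmed)
        both_affected = g.sirela_direction != "none" and g.sitp53_direction != "none"
        mode = coregulation_mode(
            modulated="up",
            p53_bound=bool(g.p53_binding_confirmed),
            nfkb_bound=bool(g.rela_binding_confirmed),
            sitp53_direction=g.sitp53_direction,
            sirela_direction=g.sirela_direction,
        )
        rows.append({"gene_id": g.gene_id,
                     "candidate": both_bound and both_affected,
                     "mode": mode})
    return pd.DataFrame(rows).set_index("gene_id")


def evaluate_recovery(truth: pd.DataFrame, classifications: pd.DataFrame) -> dict:
    """Precision/recall of planted-class recovery on synthetic data.

    Detection treats any non-null planted class as positive and
    ``group != neither`` as a positive call; the dual-dependency metrics
    restrict truth to coactivated+antagonistic classes and calls to
    ``group == both``.
    """
    t = truth.set_index("gene_id")
    c = classifications.reindex(t.index)
    pos_truth = t["reg_class"] != "null"
    pos_call = (c["group"] != "neither").fillna(False)
    both_truth = t["reg_class"].isin(
        ["coactivated", "antagonistic_nfkb_act_p53_rep", "antagonistic_p53_act_nfkb_rep"])
    both_call = (c["group"] == "both").fillna(False)

    def pr(truth_mask: pd.Series, call_mask: pd.Series) -> tuple[float, float]:
        tp = int((truth_mask & call_mask).sum())
        recall = tp / int(truth_mask.sum()) if truth_mask.any() else float("nan")
        precision = tp / int(call_mask.sum()) if call_mask.any() else float("nan")
        return precision, recall

    p_det, r_det = pr(pos_truth, pos_call)
    p_both, r_both = pr(both_truth, both_call)
    return {"detection_precision": p_det, "detection_recall": r_det,
            "both_precision": p_both, "both_recall": r_both}
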