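# coreg-ir

Integrative screen for protein-coding genes co-regulated by the p53 and
NF-κB transcription factors in cells exposed to high doses of ionizing
radiation (IR). Written for computational biologists who want to re-run or
adapt the classification logic of such a screen without the raw sequencing
data: every stage consumes small text tables (TSV / FASTA / narrowPeak) and
a synthetic-data generator can emulate the full study design offline.

## What it computes

A gene is called **dependent on a transcription factor (TF)** when three
independent lines of evidence coincide:

1. **Radiation-modulated expression** — fold change of normalized RNA-seq
   signal (irradiated vs. untreated, at either a 4 Gy or 10 Gy dose)
   satisfies FC > 1.5 or FC < 0.67 with Student-t p < 0.05. Counts are
   normalized by median-of-ratios size factors
   `s_j = median_g ( K_gj / (∏_j K_gj)^(1/m) )` and genes whose maximal
   normalized signal does not exceed the grand median are filtered out.
2. **Radiation-enhanced TF binding** — a ChIP peak whose summit falls in
   the gene's putative regulatory window (TSS ± 3000 bp) shows read-count
   enrichment in irradiated vs. control chromatin (one-sided binomial
   rate-ratio test, Benjamini–Hochberg FDR ≤ 0.05, at either the 2 h or
   4 h post-IR timepoint).
3. **A silencing effect** — the expression ratio siTF / siCTR under
   stimulation crosses 1.5 (TF is repressive) or 0.67 (TF is activating)
   at either dose; this rule is ratio-only.

Genes dependent on both factors get a **co-regulation mode**: *coactivated*
(silencing either TF inhibits expression), *antagonistic* (the two
silencings act in opposite directions, sub-labelled by which factor
activates), or *corepressed*.

Supporting modules provide PWM motif scanning with exact p-values computed
by dynamic programming over the discretized log-odds score distribution
(the method used by FIMO-style scanners), and GO-term clustering by Wang
(G-SESAME) semantic similarity with Fisher exact contrasts of per-cluster
gene contributions between two gene subsets.

## Worked example

Classify the packaged 28-gene candidate table (per-gene binding flags at
2 h / 4 h, fold changes at 4 / 10 Gy with significance marks, and
siRELA/siCTR, siTP53/siCTR expression ratios):

```bash
$ coreg-ir table1
...
IL4I1           up       both  antagonistic_nfkb_act_p53_rep
RRAD            up       both                    coactivated
{"p53_only": 14, "nfkb_only": 12, "both": 2, "neither": 0}
```

14 genes are exclusively p53-dependent, 12 exclusively NF-κB-dependent,
and 2 (IL4I1 and RRAD) depend on both: IL4I1 is activated by NF-κB and
repressed by p53 (its expression drops under siRELA, ratio 0.48/0.39, and
rises under siTP53, ratio 1.58/1.23) while RRAD is co-activated (both
silencings drop it below 0.67).

The same machinery runs end-to-end on synthetic data:

```python
from coreg_ir import SimulationConfig
from coreg_ir.pipeline import synthetic_screen

out = synthetic_screen(SimulationConfig(seed=0))
print(out["recovery"])
# {'detection_precision': 1.0, 'detection_recall': 0.92,
#  'both_precision': 1.0, 'both_recall': 0.825}
```

With the default design (2000 genes, 200 planted regulators, 3 replicates
per condition) the screen recovers 92% of planted regulated genes with no
false positives, and 82.5% of the dual-dependency genes.

## Command-line interface

`coreg-ir simulate | expression | binding | silencing | classify | table1 |
motif scan | goclust` — each a thin wrapper over the library; run with
`--help` for options.
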