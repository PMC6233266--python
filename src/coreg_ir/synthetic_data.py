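"""Synthetic inputs emulating an irradiation co-regulation screen.

Generates every input the downstream stages consume — a random genome with
non-overlapping gene loci, planted transcription-factor binding motifs,
negative-binomial RNA-seq count matrices over a
{control, 4 Gy, 10 Gy} x {siCTR, siRELA, siTP53} x replicates design,
per-TF/timepoint peak sets with region read counts, and a ground-truth
table of planted regulatory classes — so the whole pipeline is testable
without any external download.

The effect model is log-additive: each gene carries a p53-driven and an
NF-kB-driven log2 component whose sum is the planted irradiation response.
Silencing an arm's TF scales that TF's component by the residual activity
fraction; antagonistic classes give the repressing TF a negative component.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REG_CLASSES = (
    "p53_activated",
    "nfkb_activated",
    "coactivated",
    "antagonistic_nfkb_act_p53_rep",
    "antagonistic_p53_act_nfkb_rep",
    "null",
)

#: canonical consensus sites used for planting (IUPAC); discovery is out of scope
KB_CONSENSUS = "GGGRNNYYCC"
P53_CONSENSUS = "RRRCWWGYYY" * 2
#: the classical kB site and a canonical p53 response element, used as the
#: preferred resolution of the degenerate consensus positions: real binding
#: sites are not maximum-entropy draws from the IUPAC pattern but cluster
#: around a preferred word, which is what a PWM scanner exploits
KB_CANONICAL = "GGGACTTTCC"
P53_CANONICAL = "GGGCATGTCC" * 2

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG",
    "K": "GT", "M": "AC", "N": "ACGT",
}

WINDOW = 3000  # regulatory half-window around the TSS, bp


class SizingError(ValueError):
    """Genome too short to place the requested genes without overlap."""


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic screen.

    silencing_efficiency is the *residual* TF activity after knockdown
    (the study reports transcription-factor levels reduced to 10-30% of
    initial, hence the 0.2 default).
    """

    n_genes: int = 2000
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    doses: tuple[int, ...] = (4, 10)
    timepoints: tuple[str, ...] = ("2h", "4h")
    silencing_efficiency: float = 0.2
    seed: int = 0
    # class mixture: fraction of genes per non-null planted class
    frac_per_class: float = 0.02
    base_mean_range: tuple[float, float] = (20.0, 5000.0)
    peak_enrichment: float = 4.0
    peak_base_rate: float = 20.0
    background_peak_rate: float = 0.1
    library_size: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0.0 < self.silencing_efficiency < 1.0:
            raise ValueError("silencing_efficiency must be in (0, 1)")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def generate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Assign planted regulatory classes, effect sizes and binding flags.

    Non-null classes each take ``frac_per_class`` of the genes (at least one
    gene per class when n_genes allows); the rest are null. Effect sizes are
    drawn so that planted genes pass the downstream fold-change and
    silencing-ratio thresholds in expectation, with 4 Gy responses scaled
    below the 10 Gy ones as observed for dose-responsive targets.
    """
    rng = config.rng(1)
    n = config.n_genes
    per_class = 0 if config.frac_per_class == 0 else max(1, int(round(config.frac_per_class * n)))
    if 5 * per_class > n:
        per_class = n // 5
    classes = ["null"] * n
    order = rng.permutation(n)
    pos = 0
    for cls in REG_CLASSES[:-1]:
        for i in order[pos:pos + per_class]:
            classes[i] = cls
        pos += per_class

    gene_ids = [f"G{i:05d}" for i in range(n)]
    lo, hi = config.base_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    c_p53_10 = np.zeros(n)
    c_nfkb_10 = np.zeros(n)
    for i, cls in enumerate(classes):
        if cls == "p53_activated":
            c_p53_10[i] = rng.uniform(1.2, 2.5)
        elif cls == "nfkb_activated":
            c_nfkb_10[i] = rng.uniform(1.2, 2.5)
        elif cls == "coactivated":
            c_p53_10[i] = rng.uniform(1.0, 1.8)
            c_nfkb_10[i] = rng.uniform(1.0, 1.8)
        elif cls == "antagonistic_nfkb_act_p53_rep":
            rep = rng.uniform(1.0, 1.4)
            c_nfkb_10[i] = rep + rng.uniform(0.8, 1.5)
            c_p53_10[i] = -rep
        elif cls == "antagonistic_p53_act_nfkb_rep":
            rep = rng.uniform(1.0, 1.4)
            c_p53_10[i] = rep + rng.uniform(0.8, 1.5)
            c_nfkb_10[i] = -rep
    dose_scale = rng.uniform(0.5, 0.85, size=n)
    c_p53_4 = c_p53_10 * dose_scale
    c_nfkb_4 = c_nfkb_10 * dose_scale

    bound_p53 = np.abs(c_p53_10) > 0
    bound_rela = np.abs(c_nfkb_10) > 0
    # binding may appear at one or both timepoints; at least one for bound genes
    tp_draw = rng.integers(0, 3, size=(n, 2))  # 0: 2h only, 1: 4h only, 2: both
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "reg_class": classes,
        "base_mean": base_mean,
        "ir_log2fc_4gy": c_p53_4 + c_nfkb_4,
        "ir_log2fc_10gy": c_p53_10 + c_nfkb_10,
        "c_p53_4gy": c_p53_4,
        "c_p53_10gy": c_p53_10,
        "c_nfkb_4gy": c_nfkb_4,
        "c_nfkb_10gy": c_nfkb_10,
        "bound_p53_2h": bound_p53 & (tp_draw[:, 0] != 1),
        "bound_p53_4h": bound_p53 & (tp_draw[:, 0] != 0),
        "bound_rela_2h": bound_rela & (tp_draw[:, 1] != 1),
        "bound_rela_4h": bound_rela & (tp_draw[:, 1] != 0),
    })
    return truth


# ---------------------------------------------------------------------------
# genome & annotation

GENE_SPACING = 6600  # > 2*WINDOW so regulatory windows never overlap
CHROM = "chr1"


def generate_annotation(config: SimulationConfig) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Random genome plus non-overlapping gene loci on a single contig.

    Returns (annotation, genome). The annotation has columns gene_id, chrom,
    tss (0-based), strand; every TSS is at least 3000 bp from the contig
    ends so each +/-3000 bp window lies fully in-bounds. The genome maps
    contig name to a uint8 array of ASCII bases.
    """
    rng = config.rng(2)
    n = config.n_genes
    length = 2 * WINDOW + (n - 1) * GENE_SPACING + 2 * WINDOW + 1000
    if length < n * 2 * WINDOW:
        raise SizingError("genome too short for requested gene count")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {CHROM: rng.choice(bases, size=length)}
    jitter = rng.integers(0, 500, size=n)
    tss = WINDOW + np.arange(n) * GENE_SPACING + jitter
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    # guarantee both strands appear
    if n >= 2 and len(set(strands)) == 1:
        strands[0] = "+" if strands[0] == "-" else "-"
    ann = pd.DataFrame({
        "gene_id": [f"G{i:05d}" for i in range(n)],
        "chrom": CHROM,
        "tss": tss.astype(int),
        "strand": strands,
    })
    return ann, genome


def _resolve_consensus(consensus: str, rng: np.random.Generator,
                       canonical: str | None = None, bias: float = 0.7) -> str:
    """Resolve IUPAC codes to bases.

    With a ``canonical`` word given, each degenerate position takes the
    canonical base with probability ``bias`` and otherwise a uniform draw
    from the allowed set — mimicking how genomic binding sites cluster
    around a preferred word rather than sampling the pattern uniformly.
    """
    out = []
    for i, code in enumerate(consensus):
        allowed = IUPAC[code]
        if canonical is not None and len(allowed) > 1 and rng.random() < bias:
            out.append(canonical[i])
        else:
            out.append(str(rng.choice(list(allowed))))
    return "".join(out)


def plant_motifs(
    genome: dict[str, np.ndarray],
    annotation: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Write kB / p53 consensus instances into bound genes' windows in place.

    Each gene with any RelA (resp. p53) bound flag receives one resolved
    consensus instance at a uniform position inside its +/-3000 bp window;
    null genes are untouched. Collisions between the two sites within one
    window are re-drawn. Returns a table of planted sites
    (gene_id, tf, chrom, start, end, site).
    """
    rng = config.rng(3)
    ann = annotation.set_index("gene_id")
    planted: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for row in truth.itertuples(index=False):
        if row.gene_id not in ann.index:
            raise KeyError(f"truth gene {row.gene_id} missing from annotation")
        tss = int(ann.at[row.gene_id, "tss"])
        chrom = ann.at[row.gene_id, "chrom"]
        seq = genome[chrom]
        sites = []
        if row.bound_rela_2h or row.bound_rela_4h:
            sites.append(("RelA", _resolve_consensus(KB_CONSENSUS, rng, KB_CANONICAL)))
        if row.bound_p53_2h or row.bound_p53_4h:
            sites.append(("p53", _resolve_consensus(P53_CONSENSUS, rng, P53_CANONICAL)))
        for tf, site in sites:
            w = len(site)
            lo = max(0, tss - WINDOW)
            hi = min(len(seq) - w, tss + WINDOW - w)
            for _ in range(100):
                start = int(rng.integers(lo, hi + 1))
                span = (start, start + w)
                if all(span[1] <= s or span[0] >= e for s, e in occupied.get(chrom, [])):
                    break
            occupied.setdefault(chrom, []).append(span)
            seq[start:start + w] = np.frombuffer(site.encode(), dtype=np.uint8)
            planted.append({"gene_id": row.gene_id, "tf": tf, "chrom": chrom,
                            "start": start, "end": start + w, "site": site})
    return pd.DataFrame(planted, columns=["gene_id", "tf", "chrom", "start", "end", "site"])


def write_fasta(genome: dict[str, np.ndarray], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(arr.tobytes().decode()), id=name, description="")
               for name, arr in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# counts

ARMS = ("siCTR", "siRELA", "siTP53")


def design_table(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet for the full expression design."""
    rows = []
    conditions = ["control"] + [f"IR{d}" for d in config.doses]
    for cond in conditions:
        for arm in ARMS:
            for rep in range(1, config.n_replicates + 1):
                rows.append({"sample": f"{cond}_{arm}_rep{rep}",
                             "condition": cond, "arm": arm, "replicate": rep})
    return pd.DataFrame(rows)


def simulate_counts(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Negative-binomial count matrix (genes x samples) over the full design.

    The expected count of gene g in (condition, arm) is
    ``base_mean * 2**(a_p53 * c_p53 + a_nfkb * c_nfkb)`` where the c's are the
    planted per-dose log2 components (zero in control) and the a's are 1
    except in the arm silencing that TF, where a = silencing_efficiency.
    """
    rng = config.rng(4)
    design = design_table(config)
    eff = config.silencing_efficiency
    n = len(truth)
    cols = {}
    for row in design.itertuples(index=False):
        if row.condition == "control":
            mu = truth["base_mean"].to_numpy()
        else:
            dose = row.condition.removeprefix("IR")
            c_p53 = truth[f"c_p53_{dose}gy"].to_numpy()
            c_nfkb = truth[f"c_nfkb_{dose}gy"].to_numpy()
            a_p53 = eff if row.arm == "siTP53" else 1.0
            a_nfkb = eff if row.arm == "siRELA" else 1.0
            mu = truth["base_mean"].to_numpy() * 2.0 ** (a_p53 * c_p53 + a_nfkb * c_nfkb)
        size = 1.0 / config.nb_dispersion
        p = size / (size + mu)
        cols[row.sample] = rng.negative_binomial(size, p, size=n)
    counts = pd.DataFrame(cols, index=truth["gene_id"].to_numpy())
    counts.index.name = "gene_id"
    return counts


# ---------------------------------------------------------------------------
# peaks

def simulate_peaks(
    truth: pd.DataFrame,
    annotation: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Candidate peak regions with treated/control read counts.

    Bound (gene, TF, timepoint) triples get a peak whose summit falls inside
    the gene's window and whose irradiated-condition read count is drawn at
    the planted Poisson enrichment over control. Unbound triples get a
    background peak with probability ``background_peak_rate`` and
    equal-rate counts, so the enhanced-binding caller has true nulls to
    calibrate against. Columns: tf, timepoint, chrom, start, end, peak_id,
    summit, treated_count, control_count, treated_libsize, control_libsize.
    """
    rng = config.rng(5)
    ann = annotation.set_index("gene_id")
    rows = []
    flag = {("p53", "2h"): "bound_p53_2h", ("p53", "4h"): "bound_p53_4h",
            ("RelA", "2h"): "bound_rela_2h", ("RelA", "4h"): "bound_rela_4h"}
    for tf in ("p53", "RelA"):
        for tp in config.timepoints:
            col = flag[(tf, tp)]
            for g in truth.itertuples(index=False):
                bound = bool(getattr(g, col))
                if not bound and rng.random() >= config.background_peak_rate:
                    continue
                tss = int(ann.at[g.gene_id, "tss"])
                chrom = ann.at[g.gene_id, "chrom"]
                summit = tss + int(rng.integers(-2000, 2001))
                rate = config.peak_base_rate
                treated = rng.poisson(rate * (config.peak_enrichment if bound else 1.0))
                control = rng.poisson(rate)
                rows.append({
                    "tf": tf, "timepoint": tp, "chrom": chrom,
                    "start": max(0, summit - 150), "end": summit + 150,
                    "peak_id": f"{tf}_{tp}_{g.gene_id}",
                    "summit": summit,
                    "treated_count": int(treated), "control_count": int(control),
                    "treated_libsize": config.library_size,
                    "control_libsize": config.library_size,
                })
    return pd.DataFrame(rows, columns=["tf", "timepoint", "chrom", "start", "end",
                                       "peak_id", "summit", "treated_count",
                                       "control_count", "treated_libsize",
                                       "control_libsize"])


def write_narrowpeak(regions: pd.DataFrame, out_dir: str | os.PathLike) -> list[str]:
    """One ENCODE narrowPeak file per TF x timepoint (irradiated condition)."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for (tf, tp), sub in regions.groupby(["tf", "timepoint"], sort=True):
        path = os.path.join(out_dir, f"{tf}_{tp}_IR.narrowPeak")
        with open(path, "w") as fh:
            for r in sub.itertuples(index=False):
                offset = r.summit - r.start
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.peak_id}\t0\t.\t"
                         f"{r.treated_count / max(r.control_count, 1):.4f}\t-1\t-1\t{offset}\n")
        paths.append(path)
    return paths


def simulate_all(config: SimulationConfig, out_dir: str | os.PathLike | None = None):
    """Generate truth, annotation+genome, counts and peak regions in one call.

    When ``out_dir`` is given, also writes genome.fa, annotation.tsv,
    counts.tsv, design.tsv, truth.tsv, regions.tsv and narrowPeak files.
    """
    truth = generate_truth(config)
    annotation, genome = generate_annotation(config)
    planted = plant_motifs(genome, annotation, truth, config)
    counts = simulate_counts(truth, config)
    regions = simulate_peaks(truth, annotation, config)
    design = design_table(config)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_fasta(genome, os.path.join(out_dir, "genome.fa"))
        annotation.to_csv(os.path.join(out_dir, "annotation.tsv"), sep="\t", index=False)
        counts.to_csv(os.path.join(out_dir, "counts.tsv"), sep="\t")
        design.to_csv(os.path.join(out_dir, "design.tsv"), sep="\t", index=False)
        truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
        regions.to_csv(os.path.join(out_dir, "regions.tsv"), sep="\t", index=False)
        write_narrowpeak(regions, os.path.join(out_dir, "peaks"))
        with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
            import yaml
            yaml.safe_dump(dataclasses.asdict(config), fh)
    return {"truth": truth, "annotation": annotation, "genome": genome,
            "planted_sites": planted, "counts": counts, "regions": regions,
            "design": design}
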