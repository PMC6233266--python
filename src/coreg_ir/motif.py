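"""PWM scanning with exact log-odds p-values.

Position weight matrices are built from aligned sites with pseudocounts;
windows are scored as log2 odds against a background base composition, and
p-values come from the exact distribution of the discretized score under
the background model, computed by dynamic-programming convolution across
positions (the approach used by exact-p-value motif scanners). Both
strands are scanned; ambiguous bases contribute zero log-odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Probability matrix (width x 4, rows sum to 1) with a background model."""

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be width x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValueError("per-position probabilities must sum to 1")
        if (self.background <= 0).any() or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be strictly positive and sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """log2(p / background), width x 4, in bits."""
        bg = self.background if background is None else np.asarray(background, float)
        return np.log2(self.probs / bg)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


def build_pwm(sites: list[str], pseudocount: float = 0.25,
              background: np.ndarray | None = None, name: str = "motif") -> PWM:
    """PWM from equal-length aligned sites.

    Counts get ``pseudocount`` added per base; an N in a site spreads unit
    mass 0.25 per base before pseudocounts. Probability is
    (count + pseudocount) / (n_sites + 4 * pseudocount).
    """
    if not sites:
        raise ValueError("empty site set")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("ragged site lengths")
    counts = np.zeros((w, 4))
    for site in sites:
        for i, base in enumerate(site.upper()):
            if base == "N":
                counts[i] += 0.25
            elif base in _BASE_INDEX:
                counts[i, _BASE_INDEX[base]] += 1.0
            else:
                raise ValueError(f"invalid base {base!r}")
    probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else background
    return PWM(probs, bg, name=name)


@dataclass
class ScoreDistribution:
    """Discretized exact null distribution of PWM scores.

    ``int_scores`` maps (position, base) to integer bin contributions
    (with a 5th column of zeros-offset entries for N); ``tail`` maps an
    integer total to P(score >= total) under the background.
    """

    int_scores: np.ndarray  # width x 5
    tail: np.ndarray
    scale: float
    offsets: np.ndarray  # per-position subtracted minima

    def pvalue_of_int(self, total: int) -> float:
        total = int(np.clip(total, 0, len(self.tail) - 1))
        return float(self.tail[total])


def score_pvalues(pwm: PWM, background: np.ndarray | None = None,
                  granularity: int = 1000) -> ScoreDistribution:
    """Exact tail distribution of the discretized log-odds score.

    Per-position log-odds are shifted by their minima and scaled to at most
    ``granularity`` integer bins over the full score range, then the exact
    probability mass function under the background is built by convolving
    position by position.
    """
    if granularity < 100:
        raise ValueError("granularity must be >= 100")
    bg = pwm.background if background is None else np.asarray(background, float)
    if (bg <= 0).any():
        raise ValueError("degenerate background")
    lo = pwm.log_odds(bg)  # width x 4
    offsets = lo.min(axis=1)
    shifted = lo - offsets[:, None]
    span = shifted.max(axis=1).sum()
    scale = granularity / span if span > 0 else 1.0
    ints = np.rint(shifted * scale).astype(int)
    # N contributes raw log-odds 0, i.e. shifted score -offset per position
    n_ints = np.rint((0.0 - offsets) * scale).astype(int)
    int_scores = np.column_stack([ints, n_ints])
    max_total = int(ints.max(axis=1).sum())
    pmf = np.zeros(max_total + 1)
    pmf[0] = 1.0
    top = 0
    for i in range(pwm.width):
        new = np.zeros(max_total + 1)
        for b in range(4):
            s = ints[i, b]
            new[s:top + s + 1] += bg[b] * pmf[:top + 1]
        top += int(ints[i].max())
        pmf = new
    tail = np.minimum(pmf[::-1].cumsum()[::-1], 1.0)
    return ScoreDistribution(int_scores=int_scores, tail=tail,
                             scale=scale, offsets=offsets)


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def _window_int_scores(encoded: np.ndarray, dist: ScoreDistribution) -> np.ndarray:
    w = dist.int_scores.shape[0]
    if len(encoded) < w:
        return np.zeros(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    return dist.int_scores[np.arange(w)[None, :], windows].sum(axis=1)


def scan(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    granularity: int = 1000,
    sequence_id: str = "seq",
    tss: int | None = None,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan a sequence for PWM matches with exact p-values.

    The background defaults to the scanned sequence's own base composition
    (falling back to uniform for degenerate sequences). Hits on the minus
    strand are reported at their forward-strand start position. When
    ``tss`` is given, each hit carries its signed offset to it.
    Columns: sequence_id, position, strand, score, p_value, tss_offset.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    cols = ["sequence_id", "position", "strand", "score", "p_value", "tss_offset"]
    if len(sequence) < pwm.width:
        return pd.DataFrame(columns=cols)
    if background is None:
        enc_all = _encode(sequence)
        counts = np.bincount(enc_all[enc_all < 4], minlength=4).astype(float)
        background = counts / counts.sum() if counts.sum() and (counts > 0).all() \
            else np.full(4, 0.25)
    dist = score_pvalues(pwm, background, granularity)
    lo = pwm.log_odds(background)
    lo5 = np.column_stack([lo, np.zeros(pwm.width)])
    rows: list[dict] = []

    def collect(seq_str: str, strand: str) -> None:
        enc = _encode(seq_str)
        ints = _window_int_scores(enc, dist)
        pvals = dist.tail[np.clip(ints, 0, len(dist.tail) - 1)]
        hit_pos = np.nonzero(pvals <= p_threshold)[0]
        w = pwm.width
        for j in hit_pos:
            window = enc[j:j + w]
            score = float(lo5[np.arange(w), window].sum())
            pos = j if strand == "+" else len(seq_str) - w - j
            rows.append({"sequence_id": sequence_id, "position": int(pos),
                         "strand": strand, "score": score,
                         "p_value": float(pvals[j]),
                         "tss_offset": int(pos) - tss if tss is not None else pd.NA})

    collect(sequence, "+")
    if both_strands:
        collect(sequence.translate(_COMPLEMENT)[::-1], "-")
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["position", "strand"], kind="stable").reset_index(drop=True)


def peak_summit_windows(peaks: pd.DataFrame, flank: int = 500,
                        contig_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """[summit - flank, summit + flank) extraction intervals, clipped."""
    out = peaks[["chrom", "summit"]].copy()
    out["start"] = (out["summit"] - flank).clip(lower=0)
    out["end"] = out["summit"] + flank
    if contig_lengths:
        out["end"] = np.minimum(out["end"], out["chrom"].map(contig_lengths))
    if "name" in peaks.columns:
        out["name"] = peaks["name"].to_numpy()
    elif "peak_id" in peaks.columns:
        out["name"] = peaks["peak_id"].to_numpy()
    else:
        out["name"] = [f"window_{i}" for i in range(len(out))]
    return out[["chrom", "start", "end", "name"]]


# ---------------------------------------------------------------------------
# MEME minimal text format

def read_meme(path) -> list[PWM]:
    """Parse motifs from a MEME minimal-format text file."""
    motifs: list[PWM] = []
    background = np.full(4, 0.25)
    name = None
    rows: list[list[float]] = []
    expecting_bg = False

    def flush() -> None:
        nonlocal rows, name
        if name is not None and rows:
            motifs.append(PWM(np.array(rows), background.copy(), name=name))
        rows, name = [], None

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if expecting_bg and line:
                parts = line.split()
                freqs = {parts[i]: float(parts[i + 1]) for i in range(0, len(parts), 2)}
                background = np.array([freqs.get(b, 0.25) for b in ALPHABET])
                expecting_bg = False
                continue
            if line.startswith("Background letter frequencies"):
                expecting_bg = True
            elif line.startswith("MOTIF"):
                flush()
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                continue
            elif name is not None and line and (line[0].isdigit() or line[0] == "."):
                rows.append([float(x) for x in line.split()])
    flush()
    return motifs


def write_meme(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width}\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
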