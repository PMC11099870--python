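"""PWM scanning (ZOOPS) and motif enrichment in promoter or enhancer windows.

Position frequency matrices (JASPAR-style) are converted to log-odds PWMs
with a pseudocount; each sequence is scanned on both strands and counted as
hit/no-hit (zero-or-one occurrence per sequence, ZOOPS) against a threshold
expressed as a fraction of the motif's maximum achievable score. Enrichment
of target over background hit counts is a hypergeometric upper tail with BH
adjustment across motifs. The default background is a seeded dinucleotide
shuffle of the targets (3x), which preserves base and adjacent-pair
composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GeneModel, GenomicInterval, PROMOTER_DOWNSTREAM, PROMOTER_UPSTREAM

#: pseudocount added per base when converting PFM counts to probabilities
PFM_PSEUDOCOUNT = 0.25
#: default hit threshold as a fraction of the maximum achievable log-odds
DEFAULT_THRESHOLD_FRAC = 0.8

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC degeneracy used when building a PFM from a consensus word
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Log-odds position weight matrix with background frequencies."""

    motif_id: str
    probs: np.ndarray  # (length, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probability matrix must be (length, 4)")
        if len(self) < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.probs[::-1, ::-1],
                   self.background[::-1])

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray,
                    pseudocount: float = PFM_PSEUDOCOUNT,
                    background: np.ndarray | None = None) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else background
        return cls(motif_id, probs, bg)

    @classmethod
    def from_biopython(cls, motif, pseudocount: float = PFM_PSEUDOCOUNT,
                       background: np.ndarray | None = None) -> "PWM":
        counts = np.array([[motif.counts[b][i] for b in BASES]
                           for i in range(motif.length)])
        name = motif.matrix_id or motif.name or "motif"
        return cls.from_counts(str(name), counts, pseudocount, background)

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str,
                       weight: float = 100.0,
                       pseudocount: float = PFM_PSEUDOCOUNT) -> "PWM":
        """A sharp PFM encoding a (possibly IUPAC-degenerate) consensus."""
        counts = np.zeros((len(consensus), 4))
        for i, ch in enumerate(consensus.upper()):
            allowed = _IUPAC.get(ch)
            if allowed is None:
                raise ValueError(f"consensus character {ch!r} outside IUPAC/ACGT")
            for b in allowed:
                counts[i, _BASE_INDEX[b]] = weight / len(allowed)
        return cls.from_counts(motif_id, counts, pseudocount)


def encode(seq: str) -> np.ndarray:
    """Map a sequence to base indices; non-ACGT becomes 4 (invalid)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _best_window_score(codes: np.ndarray, log_odds: np.ndarray) -> float:
    w = log_odds.shape[0]
    if codes.size < w:
        return -np.inf
    padded = np.vstack([log_odds.T, np.full((1, w), -np.inf)])  # row 4: invalid
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    scores = padded[windows, np.arange(w)].sum(axis=1)
    return float(scores.max())


def scan_zoops(
    sequences: dict[str, str],
    pwm: PWM,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> pd.DataFrame:
    """Per-sequence ZOOPS hit flag and best log-odds score, both strands.

    The hit threshold is ``threshold_frac`` times the maximum achievable
    score of the PWM. Sequences shorter than the motif (or all-invalid)
    never hit; their best score is -inf.
    """
    threshold = threshold_frac * pwm.max_score
    lo_fwd = pwm.log_odds
    lo_rev = pwm.reverse_complement().log_odds
    rows = []
    for name, seq in sequences.items():
        codes = encode(seq)
        best = max(_best_window_score(codes, lo_fwd),
                   _best_window_score(codes, lo_rev))
        rows.append((name, best, best >= threshold))
    return pd.DataFrame(rows, columns=["sequence", "best_score", "hit"]
                        ).set_index("sequence")


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the dinucleotide (adjacent-pair) composition.

    Random Eulerian-path resampling of the first-order transition
    multigraph (Altschul-Erickson): the shuffled sequence starts and ends
    on the original's first and last characters and has exactly the
    original dinucleotide counts.
    """
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    for _ in range(100):
        # pick a candidate "last out-edge" per vertex and test that they
        # form an arborescence into the final vertex
        last_edge = {u: edges[u][rng.integers(len(edges[u]))]
                     for u in vertices if u != last}
        if all(_reaches(u, last, last_edge) for u in vertices):
            break
    else:  # pragma: no cover - retry bound is generous
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian order")
    out_order: dict[str, list[str]] = {}
    for u in vertices:
        rest = list(edges[u])
        if u != last:
            rest.remove(last_edge[u])
        rng.shuffle(rest)
        out_order[u] = rest + ([last_edge[u]] if u != last else [])
    chars = [seq[0]]
    ptr = {u: 0 for u in vertices}
    u = seq[0]
    total = len(seq) - 1
    for _ in range(total):
        v = out_order[u][ptr[u]]
        ptr[u] += 1
        chars.append(v)
        u = v
    return "".join(chars)


def _reaches(u: str, last: str, last_edge: dict[str, str]) -> bool:
    seen = set()
    while u != last:
        if u in seen:
            return False
        seen.add(u)
        u = last_edge[u]
    return True


def shuffle_background(sequences: dict[str, str], rng: np.random.Generator,
                       copies: int = 3) -> dict[str, str]:
    """Seeded dinucleotide-shuffled copies of the target set (default 3x)."""
    out = {}
    for name in sorted(sequences):
        for c in range(copies):
            out[f"{name}|shuf{c}"] = dinucleotide_shuffle(sequences[name], rng)
    return out


def extract_windows(
    mode: str,
    features: list[GeneModel] | list[GenomicInterval],
    genome: dict[str, str],
    half_width: int = 50,
) -> dict[str, str]:
    """Sequence windows for motif analysis.

    ``promoter`` mode takes the strand-aware TSS-1000..TSS+100 window of
    each gene (reverse-complemented for minus-strand genes so the motif
    search sees the transcribed orientation); ``dae_center`` takes the
    +/- ``half_width`` bp window around each region's center. Windows are
    clipped to chromosome bounds with a warning.
    """
    if mode not in {"promoter", "dae_center"}:
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[str, str] = {}
    for feat in features:
        chrom = feat.chrom
        if chrom not in genome:
            raise KeyError(f"no sequence for chromosome {chrom!r}")
        seq = genome[chrom]
        if mode == "promoter":
            # raw strand-aware TSS-1000..TSS+100 coordinates, before clipping
            if feat.strand == "+":  # type: ignore[union-attr]
                lo, hi = feat.tss - PROMOTER_UPSTREAM, feat.tss + PROMOTER_DOWNSTREAM
            else:
                lo = feat.tss - PROMOTER_DOWNSTREAM + 1
                hi = feat.tss + PROMOTER_UPSTREAM + 1
            name, minus = feat.gene_id, feat.strand == "-"
        else:
            center = feat.midpoint  # type: ignore[union-attr]
            name = feat.name if feat.name != "." else f"{chrom}:{feat.start}-{feat.end}"
            lo, hi, minus = center - half_width, center + half_width, False
        if lo < 0 or hi > len(seq):
            warnings.warn(f"window [{lo},{hi}) clipped to {chrom} bounds",
                          stacklevel=2)
            lo, hi = max(0, lo), min(len(seq), hi)
        window = seq[lo:hi]
        out[name] = revcomp(window) if minus else window
    return out


def motif_enrichment(
    targets: dict[str, str],
    background: dict[str, str] | None,
    pwms: list[PWM],
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """ZOOPS hypergeometric enrichment of each motif in targets vs background.

    With ``background=None`` a seeded dinucleotide-shuffle background (3x
    the targets) is built, which requires ``rng``. Explicit backgrounds must
    be disjoint from the target ids. Rows are sorted by p (ties by motif id);
    ``rank`` is 1-based.
    """
    if background is None:
        if rng is None:
            raise ValueError("background is required, or pass rng for the "
                             "dinucleotide-shuffle default")
        background = shuffle_background(targets, rng)
    overlap_ids = targets.keys() & background.keys()
    if overlap_ids:
        raise ValueError(f"background overlaps targets: {sorted(overlap_ids)[:3]}")
    rows = []
    for pwm in pwms:
        t_hits = int(scan_zoops(targets, pwm, threshold_frac)["hit"].sum())
        b_hits = int(scan_zoops(background, pwm, threshold_frac)["hit"].sum())
        n_t, n_b = len(targets), len(background)
        # P(X >= t_hits) drawing n_t from a pool of n_t+n_b with t+b hits
        p = float(stats.hypergeom.sf(t_hits - 1, n_t + n_b, t_hits + b_hits, n_t))
        rows.append((pwm.motif_id, t_hits, n_t, b_hits, n_b, p))
    df = pd.DataFrame(rows, columns=["motif_id", "target_hits", "n_targets",
                                     "background_hits", "n_background", "p"]
                      ).set_index("motif_id")
    df["padj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1] if len(df) else []
    df = df.sort_values(["p", "motif_id"], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df
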