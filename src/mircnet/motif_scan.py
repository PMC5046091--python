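"""PWM promoter scanning with exact log-odds p-values.

Promoter windows span 1.5 kb upstream to 0.5 kb downstream of a TSS
(2 kb total, strand-oriented).  Motifs are scored as log2 odds against a
0-order background; the p-value of a match is the exact tail probability
P(score >= observed) of the score of a random background string of motif
length, computed by positionwise convolution over a discretized score grid.
Matches with p <= 0.05 are retained, then reduced to the best hit per
(TF, target) pair and truncated to the top fraction.

Scores are discretized once, and both the p-value table and the window
scores use the same integer grid, so a table lookup is exact for every
scanned window (no float/bin mismatch).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from mircnet.io_formats import Motif, MotifSet

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
# uppercase bases scannable; lowercase (repeat-masked) and N are not
_CODE = {c: i for i, c in enumerate("ACGT")}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Base codes A=0 C=1 G=2 T=3; masked/N/other = 4 (unscannable)."""
    return np.fromiter((_CODE.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


@dataclass
class PromoterWindow:
    target: str
    sequence: str  # strand-oriented, upstream end first
    tss: int
    strand: str  # "+" | "-"


@dataclass(frozen=True)
class MotifHit:
    tf: str
    target: str
    offset: int  # 0-based start of the match footprint in the window
    strand: str  # strand of the match relative to the window
    score: float  # bits
    p_value: float


class ScoreModel:
    """Integer-discretized log-odds scoring of one motif.

    ``pseudocount`` is added to motif probabilities (then renormalized)
    before taking log2 against the background; ``granularity`` is the score
    step of the integer grid, defaulting to (score range)/1000.
    """

    def __init__(
        self,
        motif: Motif,
        background: np.ndarray,
        pseudocount: float = 1e-3,
        granularity: float | None = None,
    ):
        self.name = motif.name
        self.background = np.asarray(background, dtype=float)
        probs = motif.matrix + pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        self.log_odds = np.log2(probs / self.background)  # L × 4, bits
        score_range = float(
            (self.log_odds.max(axis=1) - self.log_odds.min(axis=1)).sum()
        )
        if granularity is None:
            granularity = score_range / 1000 if score_range > 0 else 1.0
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        if score_range > 0 and score_range / granularity < 100:
            warnings.warn(
                f"motif {self.name}: granularity {granularity:.3g} gives fewer "
                "than 100 score bins; p-values will be coarse",
                stacklevel=2,
            )
        self.granularity = granularity
        self.q = np.rint(self.log_odds / granularity).astype(np.int64)  # L × 4

    @property
    def length(self) -> int:
        return self.q.shape[0]

    def reverse_complement(self) -> "ScoreModel":
        rc = object.__new__(ScoreModel)
        rc.name = self.name
        rc.background = self.background
        rc.log_odds = self.log_odds[::-1, ::-1].copy()
        rc.granularity = self.granularity
        rc.q = self.q[::-1, ::-1].copy()
        return rc

    def to_bits(self, int_score: int) -> float:
        return int_score * self.granularity


def exact_score_pvalue_table(model: ScoreModel) -> tuple[int, np.ndarray]:
    """Exact distribution of the integer score of a background string.

    Returns ``(min_score, tail)`` where ``tail[s - min_score]`` is
    P(score >= s) for a string of motif length drawn i.i.d. from the
    background.  Computed by convolving the per-position 4-point score
    distributions on the integer grid.
    """
    lo = model.q.min(axis=1).sum()
    hi = model.q.max(axis=1).sum()
    dist = np.zeros(hi - lo + 1, dtype=float)
    # running support starts at the sum of per-position minima
    offset = 0
    cur = np.array([1.0])
    for pos in range(model.length):
        qs = model.q[pos]
        pmin = qs.min()
        width = qs.max() - pmin
        nxt = np.zeros(len(cur) + width, dtype=float)
        for base in range(4):
            shift = qs[base] - pmin
            nxt[shift : shift + len(cur)] += model.background[base] * cur
        cur = nxt
        offset += pmin
    assert offset == lo and len(cur) == hi - lo + 1
    dist[:] = cur
    tail = np.cumsum(dist[::-1])[::-1]
    # guard against accumulation slightly above 1
    np.clip(tail, 0.0, 1.0, out=tail)
    return int(lo), tail


def lookup_pvalue(table: tuple[int, np.ndarray], int_score: int) -> float:
    lo, tail = table
    if int_score <= lo:
        return 1.0
    idx = int_score - lo
    if idx >= len(tail):
        return float(tail[-1])
    return float(tail[idx])


# ---------------------------------------------------------------------------
# promoter extraction


def extract_promoter(
    seq_source: str,
    tss: int,
    strand: str,
    upstream: int = 1500,
    downstream: int = 500,
    target: str = "",
) -> PromoterWindow:
    """Strand-oriented promoter window [−upstream, +downstream) around a TSS.

    Plus strand: source interval [tss−upstream, tss+downstream).  Minus
    strand: [tss−downstream, tss+upstream), reverse-complemented, so that
    position 0 of the window is −upstream relative to the TSS in transcript
    orientation.  Positions beyond the sequence ends are N-padded.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream, tss + upstream
    left_pad = max(0, -start)
    right_pad = max(0, end - len(seq_source))
    if left_pad or right_pad:
        logger.warning(
            "promoter window for %r at tss=%d extends past the sequence; "
            "N-padding %d+%d bases", target, tss, left_pad, right_pad,
        )
    chunk = seq_source[max(0, start) : min(len(seq_source), end)]
    window = "N" * left_pad + chunk + "N" * right_pad
    if strand == "-":
        window = reverse_complement(window)
    assert len(window) == upstream + downstream
    return PromoterWindow(target=target, sequence=window, tss=tss, strand=strand)


# ---------------------------------------------------------------------------
# scanning


def _window_scores(model: ScoreModel, codes: np.ndarray) -> np.ndarray:
    """Integer score at every offset; unscannable footprints get INT_MIN."""
    L = model.length
    n_off = len(codes) - L + 1
    if n_off <= 0:
        return np.empty(0, dtype=np.int64)
    invalid = codes >= 4
    # offsets whose footprint contains a masked base
    bad = np.convolve(invalid.astype(np.int64), np.ones(L, dtype=np.int64))[
        L - 1 : L - 1 + n_off
    ] > 0
    safe = np.minimum(codes, 3).astype(np.int64)
    scores = np.zeros(n_off, dtype=np.int64)
    for pos in range(L):
        scores += model.q[pos, safe[pos : pos + n_off]]
    scores[bad] = np.iinfo(np.int64).min
    return scores


def scan_promoters(
    windows: Iterable[PromoterWindow],
    motifs: MotifSet,
    p_threshold: float = 0.05,
    both_strands: bool = True,
    pseudocount: float = 1e-3,
    granularity: float | None = None,
) -> list[MotifHit]:
    """Slide every motif over every window, keep matches with p <= threshold.

    Footprints containing N or lowercase (repeat-masked) bases are skipped.
    Minus-strand matches are scored with the reverse-complement motif on the
    forward window; their offset is the footprint start in window
    coordinates.
    """
    windows = list(windows)
    hits: list[MotifHit] = []
    for motif in motifs:
        model = ScoreModel(
            motif, motifs.background, pseudocount=pseudocount,
            granularity=granularity,
        )
        table = exact_score_pvalue_table(model)
        strands = [("+", model, table)]
        if both_strands:
            rc = model.reverse_complement()
            strands.append(("-", rc, exact_score_pvalue_table(rc)))
        for win in windows:
            codes = encode(win.sequence)
            for strand, mod, tab in strands:
                scores = _window_scores(mod, codes)
                valid = scores > np.iinfo(np.int64).min
                for off in np.nonzero(valid)[0]:
                    p = lookup_pvalue(tab, int(scores[off]))
                    if p <= p_threshold:
                        hits.append(
                            MotifHit(
                                tf=motif.name,
                                target=win.target,
                                offset=int(off),
                                strand=strand,
                                score=model.to_bits(int(scores[off])),
                                p_value=p,
                            )
                        )
    return hits


def rank_and_truncate(
    hits: Sequence[MotifHit], top_fraction: float = 0.01
) -> list[MotifHit]:
    """Best hit per (tf, target), sorted by p, truncated to the top fraction.

    Ties in p break lexicographically by (tf, target); the retained count is
    ceil(top_fraction × number of unique pairs).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0,1], got {top_fraction}")
    best: dict[tuple[str, str], MotifHit] = {}
    for h in hits:
        key = (h.tf, h.target)
        cur = best.get(key)
        if cur is None or h.p_value < cur.p_value:
            best[key] = h
    ranked = sorted(best.values(), key=lambda h: (h.p_value, h.tf, h.target))
    keep = math.ceil(top_fraction * len(ranked))
    return ranked[:keep]


def hits_to_rows(
    hits: Iterable[MotifHit], upstream: int = 1500
) -> list[dict]:
    """TSV-ready rows with TSS-relative match start coordinates."""
    return [
        {
            "tf": h.tf,
            "target": h.target,
            "tss_rel_start": h.offset - upstream,
            "strand": h.strand,
            "score_bits": round(h.score, 4),
            "p_value": h.p_value,
        }
        for h in hits
    ]
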