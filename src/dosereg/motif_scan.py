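"""PWM scanning with exact p-values and a central-enrichment statistic.

Scores are log2 odds of motif vs background letter probabilities, discretized
onto an integer lattice (``resolution`` bins per column).  The lattice scores
are the PWM's *definitive* scores: scanning and the p-value table use the same
integers, so the dynamic-programming null distribution is exact for the scores
the scanner reports (no further discretization error).  The p-value of a score
s is the probability, under the background model, that a random word of motif
width scores >= s.

Central enrichment asks whether the best-scoring site per peak clusters at the
peak center: successes are best-site anchors inside a central window, and the
null success probability is the fraction of valid anchor positions that fall
in that window (one-sided binomial upper tail).  This is a simplified,
testable stand-in for tools that model the full positional distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PWM",
    "MotifHit",
    "pax9_consensus_pwm",
    "exact_score_pvalue",
    "scan",
    "trim_central",
    "central_enrichment",
    "CentralEnrichment",
]

BASES = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}

PAX9_CONSENSUS = "CGCGTGACCG"


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN -> 0..3, N -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    """Position weight matrix with background model and lattice scores."""

    probs: np.ndarray  # width x 4, rows sum to 1 (A,C,G,T)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.001
    resolution: int = 1000
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, float)
        self.background = np.asarray(self.background, float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be width x 4")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-3):
            raise ValueError("PWM probability rows must sum to 1 within 1e-3")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background must sum to 1")
        if np.any((self.background == 0) & (self.probs > 0)) and self.pseudocount == 0:
            raise ValueError("zero-background letter with nonzero motif probability "
                             "and zero pseudocount")
        adj = self.probs + self.pseudocount
        adj = adj / adj.sum(axis=1, keepdims=True)
        lo = np.log2(adj / self.background)
        # quantize onto an integer lattice; lattice values are the PWM's scores
        col_range = (lo.max(axis=1) - lo.min(axis=1)).max()
        self._scale = self.resolution / col_range if col_range > 0 else 1.0
        self.int_scores = np.rint(lo * self._scale).astype(np.int64)
        self.log_odds = self.int_scores / self._scale

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.background[::-1].copy(),
                   self.pseudocount, self.resolution, self.name + "_rc")

    def score_word(self, word: str) -> float:
        idx = encode(word)
        if len(idx) != self.width or (idx >= 4).any():
            raise ValueError("word must be motif width over ACGT")
        return float(self.int_scores[np.arange(self.width), idx].sum() / self._scale)


@dataclass
class MotifHit:
    sequence_id: str
    offset: int  # 0-based start on the forward strand
    strand: str
    score: float  # bits
    p_value: float


def pax9_consensus_pwm(consensus: str = PAX9_CONSENSUS, consensus_prob: float = 0.85,
                       background: Sequence[float] | None = None, **kw) -> PWM:
    """PWM from a printed consensus: consensus base gets ``consensus_prob``,
    the other three letters share the remainder equally."""
    idx = encode(consensus)
    if (idx >= 4).any():
        raise ValueError("consensus must be over ACGT")
    probs = np.full((len(consensus), 4), (1 - consensus_prob) / 3)
    probs[np.arange(len(consensus)), idx] = consensus_prob
    bg = np.asarray(background, float) if background is not None else np.full(4, 0.25)
    return PWM(probs, bg, **kw)


def exact_score_pvalue(pwm: PWM) -> "ScorePValueMap":
    """Exact background null distribution of the lattice score, by column-wise
    convolution (dynamic programming)."""
    ints = pwm.int_scores
    offset = int(-ints.min(axis=1).sum())  # shift so totals start at 0
    size = int((ints.max(axis=1) - ints.min(axis=1)).sum()) + 1
    dist = np.zeros(size)
    dist[0] = 1.0
    pos = 0  # current occupied length - 1
    for i in range(pwm.width):
        col = ints[i] - ints[i].min()
        width = int(col.max())
        new = np.zeros(pos + width + 1)
        for b in range(4):
            new[col[b] : col[b] + pos + 1] += pwm.background[b] * dist[: pos + 1]
        pos += width
        dist = new
    sf = np.concatenate([np.cumsum(dist[::-1])[::-1], [0.0]])
    sf = np.minimum(sf, 1.0)
    return ScorePValueMap(scale=pwm._scale, offset=offset, sf=sf)


@dataclass
class ScorePValueMap:
    """Maps lattice scores to exact upper-tail background probabilities."""

    scale: float
    offset: int
    sf: np.ndarray  # sf[t] = P(total_int >= t - offset)... indexed by shifted total

    def pvalue_int(self, total_int: int | np.ndarray) -> np.ndarray:
        t = np.asarray(total_int) + self.offset
        t = np.clip(t, 0, len(self.sf) - 1)
        return self.sf[t]

    def pvalue(self, score: float | np.ndarray) -> np.ndarray:
        return self.pvalue_int(np.rint(np.asarray(score) * self.scale).astype(np.int64))

    def score_threshold_int(self, p_threshold: float) -> int:
        """Smallest shifted-lattice total with p <= threshold (may exceed max)."""
        idx = np.searchsorted(-self.sf, -p_threshold, side="left")
        return int(idx) - self.offset


def _scan_one_strand(idx: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Integer window scores and validity mask for the + orientation of ``pwm``."""
    w = pwm.width
    n = len(idx) - w + 1
    if n <= 0:
        return np.zeros(0, np.int64), np.zeros(0, bool)
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = (windows < 4).all(axis=1)
    safe = np.where(windows < 4, windows, 0)
    scores = np.take_along_axis(
        np.broadcast_to(pwm.int_scores, (n, w, 4)), safe[:, :, None], axis=2
    )[:, :, 0].sum(axis=1)
    return scores, valid


def scan(sequences: Mapping[str, str], pwm: PWM, p_threshold: float = 0.001) -> list[MotifHit]:
    """Scan both strands of every sequence; report hits with p <= threshold.

    Windows containing N are skipped; sequences shorter than the motif yield
    no hits.  Offsets are 0-based starts on the forward strand for both
    strands; minus-strand scores are computed on the reverse complement.
    """
    pmap = exact_score_pvalue(pwm)
    rc = pwm.reverse_complement()
    hits: list[MotifHit] = []
    for sid, seq in sequences.items():
        idx = encode(seq)
        for strand, mat in (("+", pwm), ("-", rc)):
            scores, valid = _scan_one_strand(idx, mat)
            if not len(scores):
                continue
            p = pmap.pvalue_int(scores)
            keep = valid & (p <= p_threshold)
            for off in np.nonzero(keep)[0]:
                hits.append(MotifHit(sid, int(off), strand,
                                     float(scores[off] / pmap.scale),
                                     float(p[off])))
    hits.sort(key=lambda h: (h.sequence_id, h.offset, h.strand))
    return hits


def trim_central(seq: str, length: int = 500) -> str:
    """Central ``length`` bp of a sequence (whole sequence if shorter)."""
    if len(seq) <= length:
        return seq
    start = (len(seq) - length) // 2
    return seq[start : start + length]


@dataclass
class CentralEnrichment:
    n_central: int
    n_total: int
    null_prob: float
    binomial_p: float | None


def central_enrichment_from_anchors(anchors: Sequence[int], seq_length: int,
                                    motif_width: int,
                                    central_window: int = 100) -> CentralEnrichment:
    """Binomial central-enrichment test given best-site anchor positions.

    ``anchors`` are site midpoints (offset + width//2) of the best passing site
    per peak.  Valid anchor positions are the midpoints of all windows; the
    null success probability is the fraction of them within +-central_window/2
    of the sequence center.
    """
    n_pos = seq_length - motif_width + 1
    if n_pos <= 0:
        raise ValueError("sequence shorter than motif")
    positions = np.arange(n_pos) + motif_width // 2
    center = seq_length / 2.0
    in_window = np.abs(positions - center) <= central_window / 2.0
    null_p = in_window.sum() / n_pos
    n_total = len(anchors)
    if n_total == 0:
        return CentralEnrichment(0, 0, float(null_p), None)
    a = np.asarray(anchors)
    n_central = int((np.abs(a - center) <= central_window / 2.0).sum())
    p = float(stats.binom.sf(n_central - 1, n_total, null_p))
    return CentralEnrichment(n_central, n_total, float(null_p), p)


def central_enrichment(peak_sequences: Mapping[str, str], pwm: PWM,
                       p_threshold: float = 0.001,
                       central_window: int = 100) -> CentralEnrichment:
    """Central-enrichment test over the best passing site per peak sequence.

    Sequences should already be trimmed to a common central length (see
    :func:`trim_central`); peaks with no site at ``p_threshold`` are skipped.
    Returns a flagged null result (``binomial_p=None``) if no peak has a site.
    """
    lengths = {len(s) for s in peak_sequences.values()}
    if len(lengths) != 1:
        raise ValueError("peak sequences must share one length (trim first)")
    (L,) = lengths
    pmap = exact_score_pvalue(pwm)
    rc = pwm.reverse_complement()
    anchors = []
    for seq in peak_sequences.values():
        idx = encode(seq)
        best_score = None
        best_off = None
        for mat in (pwm, rc):
            scores, valid = _scan_one_strand(idx, mat)
            if not len(scores):
                continue
            s = np.where(valid, scores, np.iinfo(np.int64).min)
            off = int(s.argmax())
            if valid[off] and (best_score is None or s[off] > best_score):
                best_score = int(s[off])
                best_off = off
        if best_score is None:
            continue
        if pmap.pvalue_int(best_score) <= p_threshold:
            anchors.append(best_off + pwm.width // 2)
    return central_enrichment_from_anchors(anchors, L, pwm.width, central_window)
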