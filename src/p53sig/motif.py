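"""Position weight matrix model of the p53 response element.

The p53 response element (RE) is a 20-bp site made of two tandem 10-bp
half sites, each the quasi-palindrome 5'-PuPuPuC(A/T)(T/A)GPyPyPy-3',
occasionally separated by a short spacer.  This module represents the
half site as a position frequency matrix (PFM), converts it to a
log-odds position weight matrix (PWM), and scans peak sequences for the
highest-scoring spacer-tolerant RE on either strand.

Scoring conventions
-------------------
* Both half sites are scored by the same 10-column half-site PWM; the
  spacer, if any, is removed before scoring, so every candidate is
  reduced to a 20-mer.
* Scores are log-odds in bits against a background base composition.
* ``N`` contributes zero log-odds (background-neutral).
* Hits are reported in canonical orientation: ``site20`` is written on
  the strand with the higher score (ties go to ``+``), so signature
  positions such as C9/G12 are comparable across hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC consensus of one 10-bp half site: purine/purine/purine, the
#: invariant C, the central A/T pair, the invariant G, three pyrimidines.
HALF_SITE_CONSENSUS = "RRRCWWGYYY"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

HALF_LEN = 10
SITE_LEN = 20


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HalfSitePFM:
    """Base frequencies of the 10-bp p53 half site.

    ``counts`` is a 4x10 array (rows A, C, G, T); columns may be counts
    or probabilities — only column totals must be positive.
    """

    counts: np.ndarray
    name: str = "p53_half_site"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (4, HALF_LEN):
            raise ValueError(
                f"half-site PFM must be 4x{HALF_LEN}, got {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError("PFM counts must be nonnegative")
        if np.any(counts.sum(axis=0) <= 0):
            raise ValueError("every PFM column must have a positive total")
        object.__setattr__(self, "counts", counts)

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)


def build_default_pfm(degeneracy_epsilon: float = 0.04) -> HalfSitePFM:
    """Consensus-derived half-site PFM.

    Each column spreads probability ``1 - epsilon`` equally over the
    bases allowed by the consensus symbol and ``epsilon`` equally over
    the disallowed bases, so the model tolerates the off-consensus
    bases seen in genomic REs without losing the consensus optimum.
    """
    if not 0 <= degeneracy_epsilon < 0.5:
        raise ValueError("degeneracy_epsilon must be in [0, 0.5)")
    counts = np.zeros((4, HALF_LEN))
    for j, symbol in enumerate(HALF_SITE_CONSENSUS):
        allowed = [BASE_INDEX[b] for b in _IUPAC[symbol]]
        disallowed = [i for i in range(4) if i not in allowed]
        counts[allowed, j] = (1.0 - degeneracy_epsilon) / len(allowed)
        if disallowed:
            counts[disallowed, j] = degeneracy_epsilon / len(disallowed)
    return HalfSitePFM(counts, name=f"consensus_eps{degeneracy_epsilon:g}")


@dataclass(frozen=True)
class PWM:
    """Log-odds (base 2) scoring matrix over the full 20-bp RE.

    ``weights`` is 4x20: the half-site log-odds matrix concatenated
    with itself, both half sites being scored by the same model.
    """

    weights: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        background = np.asarray(self.background, dtype=float)
        if weights.shape != (4, SITE_LEN):
            raise ValueError(f"PWM must be 4x{SITE_LEN}, got {weights.shape}")
        if background.shape != (4,) or abs(background.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "background", background)

    @property
    def max_score(self) -> float:
        """Score of the best base at every position (the consensus score)."""
        return float(self.weights.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        """One argmax 20-mer (ties resolved alphabetically)."""
        return "".join(BASES[i] for i in self.weights.argmax(axis=0))

    def score(self, site20: str) -> float:
        """Score a spacer-removed 20-mer; ``N`` scores 0 at its position."""
        if len(site20) != SITE_LEN:
            raise ValueError(f"site must be {SITE_LEN} bp, got {len(site20)}")
        total = 0.0
        for j, base in enumerate(site20.upper()):
            if base == "N":
                continue
            try:
                total += self.weights[BASE_INDEX[base], j]
            except KeyError:
                raise ValueError(f"invalid base {base!r} at offset {j}") from None
        return total


def pfm_to_pwm(
    pfm: HalfSitePFM,
    pseudocount: float = 1.0,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> PWM:
    """Convert a half-site PFM to a full-site log-odds PWM.

    weight[b, j] = log2( (count[b,j] + pc*bg[b]) / (total_j + pc) / bg[b] )

    with the background-proportional pseudocount ``pc`` shared across
    the column.  The 20-position matrix tiles the half-site matrix
    twice.
    """
    background = np.asarray(background, dtype=float)
    if abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    counts = pfm.counts
    totals = counts.sum(axis=0)
    if pseudocount == 0 and np.any(totals == 0):
        raise ValueError("degenerate PFM: zero column total with zero pseudocount")
    probs = (counts + pseudocount * background[:, None]) / (totals + pseudocount)
    if pseudocount == 0 and np.any(probs == 0):
        # log2(0) is -inf; legal, but scores become non-finite.
        half = np.where(probs > 0, np.log2(np.where(probs > 0, probs, 1.0)), -np.inf)
        half = half - np.log2(background)[:, None]
    else:
        half = np.log2(probs / background[:, None])
    return PWM(np.concatenate([half, half], axis=1), background, pseudocount)


@dataclass(frozen=True)
class ResponseElementHit:
    """A scored, oriented, spacer-annotated RE located in a peak.

    ``start`` is the 0-based offset of the first half site within the
    peak sequence; ``site20`` is the spacer-removed 20-mer written in
    canonical orientation (the higher-scoring strand).
    """

    peak_id: str
    start: int
    strand: str
    spacer_len: int
    score: float
    site20: str

    def __post_init__(self) -> None:
        if len(self.site20) != SITE_LEN:
            raise ValueError("site20 must be exactly 20 characters")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")


def _encode(sequence: str) -> np.ndarray:
    """Map ACGTN to 0..4; any other character is an error naming its offset."""
    seq = sequence.upper()
    idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(256, 255, dtype=np.uint8)
    for base, i in BASE_INDEX.items():
        table[ord(base)] = i
    table[ord("N")] = 4
    encoded = table[idx]
    bad = np.nonzero(encoded == 255)[0]
    if bad.size:
        off = int(bad[0])
        raise ValueError(f"non-ACGTN character {seq[off]!r} at offset {off}")
    return encoded.astype(np.intp)


def _half_scores(encoded: np.ndarray, half_weights: np.ndarray) -> np.ndarray:
    """Score of the 10-mer starting at every offset (vectorised)."""
    n = encoded.size - HALF_LEN + 1
    if n <= 0:
        return np.empty(0)
    padded = np.vstack([half_weights, np.zeros((1, HALF_LEN))])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(encoded, HALF_LEN)
    return padded[windows, np.arange(HALF_LEN)].sum(axis=1)


def scan_re(
    sequence: str,
    pwm: PWM,
    spacer_range: tuple[int, int] = (0, 13),
    min_score: float | None = None,
    peak_id: str = "",
) -> list[ResponseElementHit]:
    """Enumerate every spacer-tolerant RE candidate on both strands.

    A candidate is a 10-bp half site, an unscored spacer of each length
    in ``spacer_range`` (inclusive), and a second 10-bp half site; its
    score is the PWM score of the spacer-removed 20-mer.  Each
    (start, spacer) window is reported once, in canonical orientation.
    ``min_score`` defaults to 80% of the maximal attainable score.
    """
    lo, hi = spacer_range
    if not (0 <= lo <= hi <= 20):
        raise ValueError("spacer_range must satisfy 0 <= lo <= hi <= 20")
    if len(sequence) < SITE_LEN:
        raise ValueError(f"sequence shorter than {SITE_LEN} bp")
    if min_score is None:
        min_score = 0.8 * pwm.max_score

    encoded = _encode(sequence)
    half_fwd = pwm.weights[:, :HALF_LEN]
    # Scoring the reverse complement of window w under the PWM equals
    # scoring w under the complement-and-reverse of the full matrix;
    # because the 20-mer matrix is the half matrix tiled twice, the
    # reverse-strand half matrix is complement(half)[:, ::-1].
    half_rev = half_fwd[::-1, ::-1]

    fwd = _half_scores(encoded, half_fwd)
    rev = _half_scores(encoded, half_rev)

    hits: list[ResponseElementHit] = []
    length = encoded.size
    for spacer in range(lo, hi + 1):
        span = SITE_LEN + spacer
        n_start = length - span + 1
        if n_start <= 0:
            continue
        second = HALF_LEN + spacer
        plus = fwd[:n_start] + fwd[second : second + n_start]
        minus = rev[:n_start] + rev[second : second + n_start]
        best = np.maximum(plus, minus)
        for start in np.nonzero(best >= min_score)[0]:
            start = int(start)
            site = sequence[start : start + HALF_LEN] + sequence[
                start + second : start + second + HALF_LEN
            ]
            site = site.upper()
            if plus[start] >= minus[start]:
                strand, score = "+", float(plus[start])
            else:
                strand, score = "-", float(minus[start])
                site = reverse_complement(site)
            hits.append(
                ResponseElementHit(
                    peak_id=peak_id,
                    start=start,
                    strand=strand,
                    spacer_len=spacer,
                    score=score,
                    site20=site,
                )
            )
    return hits


def best_hit_per_peak(
    hits: Iterable[ResponseElementHit],
) -> ResponseElementHit | None:
    """Highest-scoring hit of one peak, with deterministic tie-breaking.

    Ties break toward the smaller start, then the ``+`` strand, then
    the smaller spacer.  Peaks with no hit return ``None`` and are
    dropped downstream — this is how a peak set can yield fewer REs
    than peaks (e.g. 208 REs from 214 peaks).
    """
    hits = list(hits)
    if not hits:
        return None
    peak_ids = {h.peak_id for h in hits}
    if len(peak_ids) > 1:
        raise ValueError(f"hits span multiple peaks: {sorted(peak_ids)}")
    return min(
        hits, key=lambda h: (-h.score, h.start, h.strand != "+", h.spacer_len)
    )
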