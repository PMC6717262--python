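"""Per-position nucleotide statistics for response-element sets.

Given two sets of aligned, spacer-removed 20-bp response elements
(e.g. REs called from two experimental conditions), this module builds
20x4 nucleotide count matrices, exports logo-ready frequency tables,
and tests each (position, base) pair — and arbitrary multi-position
signatures such as C9∧G12 — for enrichment between the two sets with
a two-tailed Fisher's exact test and Bonferroni correction over the
m = 80 positionwise tests (20 positions x 4 bases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .motif import BASE_INDEX, BASES, SITE_LEN

#: Number of positionwise tests in the default family (20 positions x 4 bases).
BONFERRONI_M = 80

#: Relative tolerance when comparing outcome probabilities to the observed
#: table's probability; guards against floating-point boundary misclassification.
_TWO_TAIL_RTOL = 1e-7


@dataclass(frozen=True)
class NucleotideCountMatrix:
    """Base counts per motif position over a set of REs.

    ``counts`` is 20x4 (positions x bases A,C,G,T); ``n`` is the number
    of REs counted.  Ns count toward no base, so a column total may be
    below ``n``.
    """

    counts: np.ndarray
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (SITE_LEN, 4):
            raise ValueError(f"count matrix must be {SITE_LEN}x4")
        if np.any(counts < 0) or np.any(counts.sum(axis=1) > self.n):
            raise ValueError("column sums must lie in [0, n]")
        object.__setattr__(self, "counts", counts)

    def count(self, position: int, base: str) -> int:
        """Count of ``base`` at 1-based ``position``."""
        return int(self.counts[position - 1, BASE_INDEX[base]])


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a = set-A REs with the base, b = A without, c = B with, d = B without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n_a(self) -> int:
        return self.a + self.b

    @property
    def n_b(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class PositionEnrichment:
    """One (position, base) comparison between two RE sets.

    ``fold`` is prop_a / prop_b.  ``degenerate`` marks tables where the
    fold is not informative: +inf when the base is absent from set B
    but present in A, and 1.0 when absent from both.
    """

    position: int
    base: str
    table: ContingencyTable2x2
    prop_a: float
    prop_b: float
    fold: float
    p: float
    p_bonf: float
    degenerate: bool = False


@dataclass(frozen=True)
class SignatureSpec:
    """A conjunction of (1-based position, base) requirements, e.g. C9∧G12."""

    pairs: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("signature spec must be nonempty")
        positions = [p for p, _ in self.pairs]
        if len(set(positions)) != len(positions):
            raise ValueError("signature positions must be distinct")
        for p, b in self.pairs:
            if not 1 <= p <= SITE_LEN:
                raise ValueError(f"position {p} outside 1..{SITE_LEN}")
            if b not in BASES:
                raise ValueError(f"base {b!r} not one of {BASES}")

    def matches(self, site20: str) -> bool:
        """True iff the site carries every required base (N never matches)."""
        return all(site20[p - 1] == b for p, b in self.pairs)

    def label(self) -> str:
        return "&".join(f"{b}{p}" for p, b in self.pairs)


def count_nucleotides(
    sites: Iterable[str], label: str = ""
) -> NucleotideCountMatrix:
    """Tally bases per position over aligned 20-mers; N counts nowhere."""
    counts = np.zeros((SITE_LEN, 4), dtype=int)
    n = 0
    for i, site in enumerate(sites):
        site = site.upper()
        if len(site) != SITE_LEN:
            raise ValueError(f"site {i} has length {len(site)}, expected {SITE_LEN}")
        for pos, base in enumerate(site):
            if base == "N":
                continue
            if base not in BASE_INDEX:
                raise ValueError(f"site {i}: invalid base {base!r}")
            counts[pos, BASE_INDEX[base]] += 1
        n += 1
    return NucleotideCountMatrix(counts, n=n, label=label)


def to_logo_matrix(m: NucleotideCountMatrix) -> pd.DataFrame:
    """Per-position base frequencies plus information content in bits.

    IC(p) = 2 - H(p) where H is the Shannon entropy of the column's
    base frequencies; the table (columns A,C,G,T,info_bits, one row per
    motif position) is directly consumable by external logo renderers.
    """
    if m.n == 0:
        raise ValueError("cannot build a logo from an empty RE set")
    totals = m.counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a position has no counted bases (all N)")
    freqs = m.counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    out = pd.DataFrame(freqs, columns=list(BASES))
    out.insert(0, "position", np.arange(1, SITE_LEN + 1))
    out["info_bits"] = info
    return out


def _log_hypergeom_pmf(k: np.ndarray, n1: int, n2: int, m1: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom(rows n1,n2; first column total m1)."""
    n = n1 + n2
    return (
        gammaln(n1 + 1)
        - gammaln(k + 1)
        - gammaln(n1 - k + 1)
        + gammaln(n2 + 1)
        - gammaln(m1 - k + 1)
        - gammaln(n2 - (m1 - k) + 1)
        - (gammaln(n + 1) - gammaln(m1 + 1) - gammaln(n - m1 + 1))
    )


def fisher_exact_two_tailed(t: ContingencyTable2x2) -> float:
    """Two-tailed Fisher's exact p-value, computed in log space.

    Sums the hypergeometric probabilities of every table with the same
    margins whose probability does not exceed the observed table's
    (within relative tolerance 1e-7) — the two-sided convention of
    standard statistical packages.  Log-space evaluation keeps the
    sum stable for the large counts of genome-scale RE sets.
    """
    n1, n2 = t.a + t.b, t.c + t.d
    m1 = t.a + t.c
    n = n1 + n2
    if n1 == 0 or n2 == 0 or m1 == 0 or m1 == n:
        raise ValueError("Fisher's exact test undefined: a margin is zero")
    lo = max(0, m1 - n2)
    hi = min(n1, m1)
    k = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(k, n1, n2, m1)
    log_obs = logpmf[t.a - lo]
    include = logpmf <= log_obs + math.log1p(_TWO_TAIL_RTOL)
    # logsumexp over the included tail(s)
    shifted = logpmf[include]
    top = shifted.max()
    p = float(np.exp(top) * np.exp(shifted - top).sum())
    return min(p, 1.0)


def _enrichment_record(
    position: int,
    base: str,
    a: int,
    n_a: int,
    c: int,
    n_b: int,
    bonferroni_m: int,
) -> PositionEnrichment:
    table = ContingencyTable2x2(a, n_a - a, c, n_b - c)
    prop_a = a / n_a
    prop_b = c / n_b
    degenerate = False
    if a == 0 and c == 0:
        fold, p, degenerate = 1.0, 1.0, True
    elif c == 0:
        fold, degenerate = math.inf, True
        p = fisher_exact_two_tailed(table)
    elif a == n_a and c == n_b:
        fold, p, degenerate = 1.0, 1.0, True
    else:
        fold = prop_a / prop_b
        p = fisher_exact_two_tailed(table)
    return PositionEnrichment(
        position=position,
        base=base,
        table=table,
        prop_a=prop_a,
        prop_b=prop_b,
        fold=fold,
        p=p,
        p_bonf=min(1.0, bonferroni_m * p),
        degenerate=degenerate,
    )


def position_enrichment(
    m_a: NucleotideCountMatrix,
    m_b: NucleotideCountMatrix,
    bonferroni_m: int = BONFERRONI_M,
) -> list[PositionEnrichment]:
    """All 80 (position, base) enrichment tests between two RE sets.

    For each record, fold = (a/n_A)/(c/n_B); p from the two-tailed
    Fisher test on (REs with the base vs without, set A vs set B); the
    Bonferroni-adjusted p is min(1, m*p) with m = 80 by default.
    Records are returned in (position, base) order and can be sorted
    by p by the caller.
    """
    if m_a.n == 0 or m_b.n == 0:
        raise ValueError("both RE sets must be nonempty")
    records = []
    for position in range(1, SITE_LEN + 1):
        for base in BASES:
            records.append(
                _enrichment_record(
                    position,
                    base,
                    m_a.count(position, base),
                    m_a.n,
                    m_b.count(position, base),
                    m_b.n,
                    bonferroni_m,
                )
            )
    return records


def concurrent_enrichment(
    sites_a: Sequence[str],
    sites_b: Sequence[str],
    spec: SignatureSpec,
    bonferroni_m: int = 1,
) -> PositionEnrichment:
    """Enrichment of REs carrying *every* base in ``spec`` (e.g. C9∧G12).

    An RE has the signature iff it matches all (position, base) pairs;
    the resulting 2x2 table is tested exactly as a single-position
    record.  With a single-pair spec this reduces to the corresponding
    ``position_enrichment`` record.
    """
    if not sites_a or not sites_b:
        raise ValueError("both RE sets must be nonempty")
    a = sum(spec.matches(s.upper()) for s in sites_a)
    c = sum(spec.matches(s.upper()) for s in sites_b)
    position, base = spec.pairs[0]
    return _enrichment_record(
        position, base, a, len(sites_a), c, len(sites_b), bonferroni_m
    )


def enrichment_frame(records: Sequence[PositionEnrichment]) -> pd.DataFrame:
    """Tabular view of enrichment records (full precision)."""
    return pd.DataFrame(
        {
            "position": [r.position for r in records],
            "base": [r.base for r in records],
            "a": [r.table.a for r in records],
            "n_a": [r.table.n_a for r in records],
            "c": [r.table.c for r in records],
            "n_b": [r.table.n_b for r in records],
            "prop_a": [r.prop_a for r in records],
            "prop_b": [r.prop_b for r in records],
            "fold": [r.fold for r in records],
            "p": [r.p for r in records],
            "p_bonf": [r.p_bonf for r in records],
            "degenerate": [r.degenerate for r in records],
        }
    )
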