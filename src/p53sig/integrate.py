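"""Differential-binding x differential-expression integration.

Calls condition-responsive p53 peaks (binding-signal fold change > 2),
filters differentially expressed genes (FDR < 0.05 and more than
2-fold change on FPKM + 1), links peaks to genes by gene-body overlap
or TSS proximity, and intersects the two to produce regulated
target-gene records — each annotated with its peak's best response
element and the element's signature flags (C9/G12 plus the conserved
C4, G7, C14 and G17 of the consensus).

Both filters use strict inequalities, so boundary values (fold exactly
2, FDR exactly 0.05) are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .motif import SITE_LEN, ResponseElementHit

#: Conserved consensus bases on the written strand.  Position 17's
#: consensus base is G (the dyad partner of C4); some annotations label
#: it by the cytosine on the opposite strand.
CONSERVED_POSITIONS: dict[int, str] = {4: "C", 7: "G", 14: "C", 17: "G"}

#: The enriched-signature positions.
SIGNATURE_POSITIONS: dict[int, str] = {9: "C", 12: "G"}


@dataclass(frozen=True)
class PeakRecord:
    """A binding interval with normalised signal in two conditions."""

    chrom: str
    start: int
    end: int
    peak_id: str
    signal_test: float
    signal_ctrl: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.peak_id}: start must be < end")
        if self.signal_test < 0 or self.signal_ctrl < 0:
            raise ValueError(f"peak {self.peak_id}: signals must be nonnegative")


@dataclass(frozen=True)
class GeneRecord:
    """Expression of one gene in two conditions (FPKM) with DE statistics.

    ``log2fc`` is the upstream caller's estimate and is carried through;
    the DE filter recomputes the fold change from FPKM + 1.
    """

    gene_id: str
    fpkm_ctrl: float
    fpkm_test: float
    log2fc: float
    fdr: float

    def __post_init__(self) -> None:
        if self.fpkm_ctrl < 0 or self.fpkm_test < 0:
            raise ValueError(f"gene {self.gene_id}: FPKM must be nonnegative")
        if not 0 <= self.fdr <= 1:
            raise ValueError(f"gene {self.gene_id}: FDR must be in [0, 1]")

    @property
    def log2fc_fpkm1(self) -> float:
        """log2 fold change computed on FPKM + 1."""
        return math.log2((self.fpkm_test + 1.0) / (self.fpkm_ctrl + 1.0))


@dataclass(frozen=True)
class GeneModel:
    """Genomic span and strand of a gene; TSS derived from the strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class SignatureFlags:
    """Presence of the signature and conserved consensus bases in a site."""

    c9: bool
    g12: bool
    c4: bool
    g7: bool
    c14: bool
    g17: bool
    conserved_deviation: bool

    @property
    def concurrent(self) -> bool:
        return self.c9 and self.g12


@dataclass(frozen=True)
class IPTGRecord:
    """A condition-regulated p53 target gene call.

    One record per (DE gene, differential peak) linked pair; carries
    the signed RNA fold (log2 on FPKM+1), the ChIP signal fold, the
    peak's best RE (None if the peak had no RE above threshold) and the
    RE's signature flags.
    """

    gene_id: str
    peak_id: str
    rna_log2fc: float
    direction: str
    chip_fold: float
    re: ResponseElementHit | None
    flags: SignatureFlags | None


def call_differential_peaks(
    peaks: Iterable[PeakRecord],
    fold_threshold: float = 2.0,
    pseudo: float = 1.0,
) -> list[PeakRecord]:
    """Peaks whose (test+pseudo)/(ctrl+pseudo) signal ratio strictly exceeds the threshold."""
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    if pseudo < 0:
        raise ValueError("pseudo must be nonnegative")
    kept = []
    for p in peaks:
        ratio = (p.signal_test + pseudo) / (p.signal_ctrl + pseudo)
        if ratio > fold_threshold:
            kept.append(p)
    return kept


def peak_fold(p: PeakRecord, pseudo: float = 1.0) -> float:
    return (p.signal_test + pseudo) / (p.signal_ctrl + pseudo)


def filter_de_genes(
    genes: Iterable[GeneRecord],
    fdr_max: float = 0.05,
    fold_min: float = 2.0,
) -> list[tuple[GeneRecord, str]]:
    """Genes with FDR < fdr_max and |log2 FC on FPKM+1| > log2(fold_min).

    Returns (gene, direction) pairs with direction "up" or "down".
    Both inequalities are strict: a gene at exactly 2-fold or exactly
    the FDR cutoff is excluded.
    """
    log2_min = math.log2(fold_min)
    kept = []
    for g in genes:
        if g.fdr >= fdr_max:
            continue
        lfc = g.log2fc_fpkm1
        if abs(lfc) > log2_min:
            kept.append((g, "up" if lfc > 0 else "down"))
    return kept


def assign_peaks_to_genes(
    peaks: Iterable[PeakRecord],
    models: Sequence[GeneModel],
    tss_window: int = 5000,
) -> dict[str, set[str]]:
    """Map each peak to every gene it can regulate.

    A peak maps to a gene if the peak interval overlaps the gene body,
    or if the gene's TSS lies within ``tss_window`` bp of the peak.
    One peak may map to several genes (overlapping gene bodies);
    chromosome mismatches simply produce no link.
    """
    if tss_window < 0:
        raise ValueError("tss_window must be nonnegative")
    assignment: dict[str, set[str]] = {}
    for peak in peaks:
        linked = set()
        for gene in models:
            if gene.chrom != peak.chrom:
                continue
            body_overlap = peak.start < gene.end and gene.start < peak.end
            tss_near = (
                peak.start - tss_window <= gene.tss < peak.end + tss_window
            )
            if body_overlap or tss_near:
                linked.add(gene.gene_id)
        assignment[peak.peak_id] = linked
    return assignment


def annotate_signature(site20: str) -> SignatureFlags:
    """Flags for C9/G12 and the conserved C4, G7, C14, G17.

    The deviation flag is raised when any conserved position mismatches
    its consensus base (N counts as a mismatch).
    """
    site20 = site20.upper()
    if len(site20) != SITE_LEN:
        raise ValueError(f"site must be {SITE_LEN} bp, got {len(site20)}")
    conserved = {p: site20[p - 1] == b for p, b in CONSERVED_POSITIONS.items()}
    return SignatureFlags(
        c9=site20[8] == "C",
        g12=site20[11] == "G",
        c4=conserved[4],
        g7=conserved[7],
        c14=conserved[14],
        g17=conserved[17],
        conserved_deviation=not all(conserved.values()),
    )


def call_iptgs(
    de_genes: Sequence[tuple[GeneRecord, str]],
    diff_peaks: Sequence[PeakRecord],
    assignment: Mapping[str, set[str]],
    re_per_peak: Mapping[str, ResponseElementHit | None],
    pseudo: float = 1.0,
) -> list[IPTGRecord]:
    """Intersect DE genes with differential peaks into target-gene records.

    Emits one record per (gene, peak) pair where the gene passed the DE
    filter, the peak passed the differential-binding filter, and the
    assignment links them.  A peak that has no RE above threshold still
    yields a record, with the RE and flags marked absent.
    """
    missing = [p.peak_id for p in diff_peaks if p.peak_id not in assignment]
    if missing:
        raise ValueError(f"assignment does not cover peaks: {missing}")
    de_by_id = {g.gene_id: (g, direction) for g, direction in de_genes}
    records = []
    for peak in diff_peaks:
        hit = re_per_peak.get(peak.peak_id)
        flags = annotate_signature(hit.site20) if hit is not None else None
        for gene_id in sorted(assignment[peak.peak_id]):
            if gene_id not in de_by_id:
                continue
            gene, direction = de_by_id[gene_id]
            records.append(
                IPTGRecord(
                    gene_id=gene_id,
                    peak_id=peak.peak_id,
                    rna_log2fc=gene.log2fc_fpkm1,
                    direction=direction,
                    chip_fold=peak_fold(peak, pseudo),
                    re=hit,
                    flags=flags,
                )
            )
    return records
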