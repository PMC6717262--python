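"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython; the tabular formats are TSV with a
header row and ``.`` for missing values.  Peak intervals travel as
BED6+2 (name in column 4, strand column unused, two trailing signal
columns: test then control), with 0-based half-open coordinates
preserved exactly.  Half-site frequency matrices are JASPAR-style
plain text (4 rows A/C/G/T of 10 whitespace-separated numbers, with or
without the ``A [ ... ]`` bracket dressing and ``>`` header).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .integrate import GeneModel, GeneRecord, IPTGRecord, PeakRecord
from .motif import HALF_LEN, BASES, HalfSitePFM, ResponseElementHit
from .signature import PositionEnrichment, enrichment_frame

logger = logging.getLogger("p53sig")

MISSING = "."


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        logger.warning("FASTA file %s contained no sequences", path)
    return seqs


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------------- BED

def read_peaks_bed(path: str | Path) -> list[PeakRecord]:
    """BED6+2 peaks: chrom, start, end, name, score, strand, signal_test, signal_ctrl."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected 8 BED6+2 fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                signal_test, signal_ctrl = float(fields[6]), float(fields[7])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            peaks.append(
                PeakRecord(fields[0], start, end, fields[3], signal_test, signal_ctrl)
            )
    if not peaks:
        logger.warning("peak file %s contained no records", path)
    return peaks


def write_peaks_bed(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t.\t"
                f"{p.signal_test:g}\t{p.signal_ctrl:g}\n"
            )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Gene spans as BED6 (chrom, start, end, gene_id, score, strand)."""
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            models.append(GeneModel(fields[3], fields[0], start, end, fields[5]))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_id}\t0\t{m.strand}\n")


# ----------------------------------------------------------------- PFM

def read_pfm(path: str | Path, name: str | None = None) -> HalfSitePFM:
    """JASPAR-style half-site matrix: 4 rows (A, C, G, T) x 10 columns."""
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    label = name
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                label = label or line[1:].split()[0]
                continue
            token = line[0].upper()
            body = line[1:] if token in BASES else line
            base = token if token in BASES else BASES[len(order)] if len(order) < 4 else None
            if base is None:
                raise ValueError(f"{path}:{lineno}: unexpected extra matrix row")
            body = body.replace("[", " ").replace("]", " ")
            try:
                values = [float(v) for v in body.split()]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if len(values) != HALF_LEN:
                raise ValueError(
                    f"{path}:{lineno}: expected {HALF_LEN} columns, got {len(values)}"
                )
            rows[base] = values
            order.append(base)
    if sorted(rows) != list(BASES):
        raise ValueError(f"{path}: need one row per base A/C/G/T, got {sorted(rows)}")
    counts = np.array([rows[b] for b in BASES])
    return HalfSitePFM(counts, name=label or Path(path).stem)


def write_pfm(pfm: HalfSitePFM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pfm.name}\n")
        for i, base in enumerate(BASES):
            values = " ".join(repr(float(v)) for v in pfm.counts[i])
            fh.write(f"{base} [ {values} ]\n")


# ----------------------------------------------------------------- TSV

def read_de_table(path: str | Path) -> list[GeneRecord]:
    """TSV with header gene_id, fpkm_ctrl, fpkm_test, log2fc, fdr."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    required = {"gene_id", "fpkm_ctrl", "fpkm_test", "log2fc", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DE columns {sorted(missing)}")
    return [
        GeneRecord(
            gene_id=str(row.gene_id),
            fpkm_ctrl=float(row.fpkm_ctrl),
            fpkm_test=float(row.fpkm_test),
            log2fc=float(row.log2fc),
            fdr=float(row.fdr),
        )
        for row in df.itertuples(index=False)
    ]


def write_de_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    genes = list(genes)
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "fpkm_ctrl": [g.fpkm_ctrl for g in genes],
            "fpkm_test": [g.fpkm_test for g in genes],
            "log2fc": [g.log2fc for g in genes],
            "fdr": [g.fdr for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def write_hits(hits: Iterable[ResponseElementHit], path: str | Path) -> None:
    """Hit table; start is printed 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("peak_id\tstart\tstrand\tspacer_len\tscore\tsite20\n")
        for h in hits:
            fh.write(
                f"{h.peak_id}\t{h.start + 1}\t{h.strand}\t{h.spacer_len}\t"
                f"{h.score:.6f}\t{h.site20}\n"
            )


def read_hits(path: str | Path) -> list[ResponseElementHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        ResponseElementHit(
            peak_id=str(r.peak_id),
            start=int(r.start) - 1,
            strand=str(r.strand),
            spacer_len=int(r.spacer_len),
            score=float(r.score),
            site20=str(r.site20),
        )
        for r in df.itertuples(index=False)
    ]


def write_enrichment(
    records: Sequence[PositionEnrichment], path: str | Path
) -> None:
    """Enrichment TSV; percentages to 1 decimal and folds to 2 in display columns,
    full-precision p-values alongside."""
    df = enrichment_frame(records)
    df["pct_a"] = (100 * df["prop_a"]).round(1)
    df["pct_b"] = (100 * df["prop_b"]).round(1)
    df["fold_2dp"] = df["fold"].round(2)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def write_logo_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_iptg_table(records: Sequence[IPTGRecord], path: str | Path) -> None:
    """Target-gene table: gene, peak, RNA fold, ChIP fold, RE and flags."""
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tpeak_id\trna_log2fc\tdirection\tchip_fold\t"
            "re_site20\tre_score\tC9\tG12\tconcurrent\tconserved_deviation\n"
        )
        for r in records:
            if r.re is None:
                re_site, re_score = MISSING, MISSING
                c9 = g12 = conc = dev = MISSING
            else:
                re_site, re_score = r.re.site20, f"{r.re.score:.4f}"
                c9, g12 = str(r.flags.c9), str(r.flags.g12)
                conc = str(r.flags.concurrent)
                dev = str(r.flags.conserved_deviation)
            fh.write(
                f"{r.gene_id}\t{r.peak_id}\t{r.rna_log2fc:.4f}\t{r.direction}\t"
                f"{r.chip_fold:.4f}\t{re_site}\t{re_score}\t{c9}\t{g12}\t"
                f"{conc}\t{dev}\n"
            )


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
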