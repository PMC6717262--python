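"""High-level pipeline stages in the published analysis order.

simulate/ingest -> scan (best RE per peak) -> per-position enrichment
-> differential integration.  The command-line interface and the
acceptance harness are thin wrappers over these functions.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io
from .integrate import (
    IPTGRecord,
    call_differential_peaks,
    call_iptgs,
    assign_peaks_to_genes,
    filter_de_genes,
)
from .motif import (
    PWM,
    HalfSitePFM,
    ResponseElementHit,
    best_hit_per_peak,
    build_default_pfm,
    pfm_to_pwm,
    scan_re,
)
from .signature import (
    BONFERRONI_M,
    PositionEnrichment,
    SignatureSpec,
    concurrent_enrichment,
    count_nucleotides,
    position_enrichment,
    to_logo_matrix,
)
from .simulate import (
    DESimConfig,
    PeakSimConfig,
    simulate_integration_scenario,
    simulate_peaks,
)

logger = logging.getLogger("p53sig")

#: The enriched signature tested concurrently: C at position 9, G at 12.
C9_G12 = SignatureSpec(((9, "C"), (12, "G")))


def make_pwm(
    pfm: HalfSitePFM | None = None,
    pseudocount: float = 1.0,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> PWM:
    """The scoring matrix used by default throughout the pipeline."""
    return pfm_to_pwm(pfm or build_default_pfm(), pseudocount, background)


def best_res_per_peak(
    sequences: Mapping[str, str],
    pwm: PWM,
    spacer_range: tuple[int, int] = (0, 13),
    min_score: float | None = None,
) -> dict[str, ResponseElementHit | None]:
    """Scan every peak and keep its highest-scored RE (None if no hit)."""
    out: dict[str, ResponseElementHit | None] = {}
    for peak_id, seq in sequences.items():
        hits = scan_re(seq, pwm, spacer_range, min_score, peak_id=peak_id)
        out[peak_id] = best_hit_per_peak(hits)
    return out


def re_set(per_peak: Mapping[str, ResponseElementHit | None]) -> list[str]:
    """The aligned 20-mers of all peaks that produced an RE."""
    return [hit.site20 for hit in per_peak.values() if hit is not None]


@dataclass
class EnrichmentResult:
    records: list[PositionEnrichment]
    concurrent: PositionEnrichment
    n_a: int
    n_b: int


def enrich_re_sets(
    sites_a: Sequence[str],
    sites_b: Sequence[str],
    bonferroni_m: int = BONFERRONI_M,
    spec: SignatureSpec = C9_G12,
) -> EnrichmentResult:
    """All 80 positionwise tests plus the concurrent-signature test."""
    m_a = count_nucleotides(sites_a, label="set_a")
    m_b = count_nucleotides(sites_b, label="set_b")
    records = position_enrichment(m_a, m_b, bonferroni_m)
    conc = concurrent_enrichment(sites_a, sites_b, spec)
    return EnrichmentResult(records, conc, len(sites_a), len(sites_b))


@dataclass
class RunAllResult:
    """Headline numbers of a full synthetic run (also written to disk)."""

    n_res_a: int
    n_res_b: int
    c9_fold: float
    c9_p: float
    g12_fold: float
    g12_p: float
    concurrent_fold: float
    concurrent_p: float
    n_de_genes: int
    n_diff_peaks: int
    n_iptgs: int
    n_iptgs_concurrent: int


def run_all(
    outdir: str | Path,
    seed: int,
    peaks_a: PeakSimConfig | None = None,
    peaks_b: PeakSimConfig | None = None,
    de_config: DESimConfig | None = None,
    pwm: PWM | None = None,
    spacer_range: tuple[int, int] = (0, 13),
    min_score: float | None = None,
    fold_threshold: float = 2.0,
    fdr_max: float = 0.05,
    fold_min: float = 2.0,
    tss_window: int = 5000,
    bonferroni_m: int = BONFERRONI_M,
) -> RunAllResult:
    """Simulate both assays at study scale and run every stage.

    Condition A mirrors the signature condition (214 peaks, 6 without a
    callable RE, C9/G12 at 73.1%); condition B the reference condition
    (1,328 peaks, 38 without an RE, C9 at 57.2% and G12 at 56.0%).
    Writes FASTA/BED/TSV outputs, logo tables, the 80-record enrichment
    table, the target-gene table, the truth files, and a JSON run log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pwm = pwm or make_pwm()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=3)

    peaks_a = peaks_a or PeakSimConfig()
    peaks_b = peaks_b or PeakSimConfig(
        n_peaks=1328, n_decoy=38, p_c9=0.572, p_g12=0.560
    )

    sim_a = simulate_peaks(peaks_a, int(seeds[0]), pwm, min_score, prefix="peakA")
    sim_b = simulate_peaks(peaks_b, int(seeds[1]), pwm, min_score, prefix="peakB")
    for tag, sim in (("a", sim_a), ("b", sim_b)):
        io.write_fasta(sim.sequences, outdir / f"peaks_{tag}.fa")
        io.write_peaks_bed(sim.records, outdir / f"peaks_{tag}.bed")
        io.write_truth(sim.truth, outdir / f"peaks_{tag}.truth.json")

    best_a = best_res_per_peak(sim_a.sequences, pwm, spacer_range, min_score)
    best_b = best_res_per_peak(sim_b.sequences, pwm, spacer_range, min_score)
    sites_a, sites_b = re_set(best_a), re_set(best_b)
    io.write_hits(
        [h for h in best_a.values() if h], outdir / "res_a.tsv"
    )
    io.write_hits(
        [h for h in best_b.values() if h], outdir / "res_b.tsv"
    )
    logger.info("called %d REs from %d peaks (condition A)", len(sites_a), len(best_a))
    logger.info("called %d REs from %d peaks (condition B)", len(sites_b), len(best_b))

    m_a = count_nucleotides(sites_a, "condition_a")
    m_b = count_nucleotides(sites_b, "condition_b")
    io.write_logo_matrix(to_logo_matrix(m_a), outdir / "logo_a.tsv")
    io.write_logo_matrix(to_logo_matrix(m_b), outdir / "logo_b.tsv")
    enr = enrich_re_sets(sites_a, sites_b, bonferroni_m)
    io.write_enrichment(enr.records, outdir / "enrichment.tsv")
    io.write_enrichment([enr.concurrent], outdir / "enrichment_concurrent.tsv")

    by_pos = {(r.position, r.base): r for r in enr.records}
    c9, g12 = by_pos[(9, "C")], by_pos[(12, "G")]

    scenario = simulate_integration_scenario(int(seeds[2]), de_config)
    io.write_fasta(scenario.peak_sequences, outdir / "integration_peaks.fa")
    io.write_peaks_bed(scenario.peaks, outdir / "integration_peaks.bed")
    io.write_gene_models(scenario.gene_models, outdir / "gene_models.bed")
    io.write_de_table(scenario.genes, outdir / "de_table.tsv")
    io.write_truth(scenario.truth, outdir / "integration.truth.json")

    de_genes = filter_de_genes(scenario.genes, fdr_max, fold_min)
    diff_peaks = call_differential_peaks(scenario.peaks, fold_threshold)
    assignment = assign_peaks_to_genes(scenario.peaks, scenario.gene_models, tss_window)
    best_int = best_res_per_peak(scenario.peak_sequences, pwm, spacer_range, min_score)
    iptgs = call_iptgs(de_genes, diff_peaks, assignment, best_int)
    io.write_iptg_table(iptgs, outdir / "iptgs.tsv")

    result = RunAllResult(
        n_res_a=len(sites_a),
        n_res_b=len(sites_b),
        c9_fold=c9.fold,
        c9_p=c9.p,
        g12_fold=g12.fold,
        g12_p=g12.p,
        concurrent_fold=enr.concurrent.fold,
        concurrent_p=enr.concurrent.p,
        n_de_genes=len(de_genes),
        n_diff_peaks=len(diff_peaks),
        n_iptgs=len(iptgs),
        n_iptgs_concurrent=sum(
            1 for r in iptgs if r.flags is not None and r.flags.concurrent
        ),
    )
    run_log = {
        "seed": seed,
        "stage_seeds": [int(s) for s in seeds],
        "python": platform.python_version(),
        "numpy": np.__version__,
        "parameters": {
            "spacer_range": list(spacer_range),
            "min_score": min_score,
            "fold_threshold": fold_threshold,
            "fdr_max": fdr_max,
            "fold_min": fold_min,
            "tss_window": tss_window,
            "bonferroni_m": bonferroni_m,
        },
        "results": result.__dict__,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return result
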