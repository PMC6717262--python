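"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate the study design end to end at desk scale: two
response-element (RE) sets whose per-position base probabilities differ
only at the signature positions (C at 9, G at 12), ChIP peak sets with
one embedded RE per peak and condition-dependent binding-signal fold
changes, and an RNA-seq differential-expression (DE) table with a
planted set of responsive genes.  Every generator is driven by a
``numpy.random.Generator`` seeded with PCG64, so a fixed seed gives
byte-identical outputs across platforms.

Defaults mirror the study's headline set sizes: 214 peaks / 208 REs in
the signature condition versus 1,328 peaks / 1,290 REs in the reference
condition, C9 present at 73.1% vs 57.2% and G12 at 73.1% vs 56.0%, and
a DE table with 194 up- and 281 down-regulated genes (475 total).

Embedded REs are drawn over consensus-allowed bases only (signature
positions biased per configuration), so every planted site attains the
PWM maximum and scanner recovery is a structural property; decoy peaks
(those carrying no RE, the reason an RE set is smaller than its peak
set) are rejection-sampled to contain no spurious motif match.  The
``re_epsilon`` knob introduces off-consensus substitutions for
robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .integrate import GeneModel, GeneRecord, PeakRecord
from .motif import (
    BASES,
    HALF_LEN,
    SITE_LEN,
    PWM,
    build_default_pfm,
    pfm_to_pwm,
    reverse_complement,
    scan_re,
)

_DEFAULT_SPACER_PROBS: dict[int, float] = {0: 0.80, 1: 0.10, 2: 0.05, 3: 0.05}


def _default_pwm() -> PWM:
    return pfm_to_pwm(build_default_pfm())


def signature_base_probs(
    p_c9: float,
    p_g12: float,
    epsilon: float = 0.0,
) -> np.ndarray:
    """20x4 per-position base probabilities for RE sampling.

    Every position follows the consensus-derived distribution (allowed
    bases uniform, ``epsilon`` spread over disallowed bases); positions
    9 and 12 are overridden so that P(C9) = ``p_c9`` and
    P(G12) = ``p_g12`` exactly, the complement going to the other
    allowed base (T at 9, A at 12).
    """
    if not 0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    for name, p in (("p_c9", p_c9), ("p_g12", p_g12)):
        if not 0 <= p <= 1 - epsilon:
            raise ValueError(f"{name} must be in [0, 1 - epsilon]")
    half = build_default_pfm(epsilon).probabilities.T  # 10x4
    probs = np.vstack([half, half])  # 20x4, rows = positions
    a, c, g, t = (BASES.index(b) for b in "ACGT")
    probs[8] = 0.0
    probs[8, c] = p_c9
    probs[8, t] = 1.0 - p_c9 - epsilon
    probs[8, [a, g]] = epsilon / 2.0
    probs[11] = 0.0
    probs[11, g] = p_g12
    probs[11, a] = 1.0 - p_g12 - epsilon
    probs[11, [c, t]] = epsilon / 2.0
    return probs


def _validate_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (SITE_LEN, 4):
        raise ValueError(f"base probabilities must be {SITE_LEN}x4")
    if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each probability row must be nonnegative and sum to 1")
    return probs


def draw_sites(n: int, base_probs: np.ndarray, rng: np.random.Generator) -> list[str]:
    """Draw ``n`` 20-mers column-independently from per-position probabilities."""
    probs = _validate_probs(base_probs)
    if n == 0:
        return []
    cum = probs.cumsum(axis=1)
    u = rng.random((n, SITE_LEN))
    idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    letters = np.array(list(BASES))
    return ["".join(row) for row in letters[idx]]


def simulate_re_sets(
    n_a: int,
    n_b: int,
    base_probs_a: np.ndarray,
    base_probs_b: np.ndarray,
    seed: int,
) -> tuple[list[str], list[str], dict]:
    """Two aligned RE sets plus the truth table of sampling parameters."""
    rng = np.random.default_rng(seed)
    sites_a = draw_sites(n_a, base_probs_a, rng)
    sites_b = draw_sites(n_b, base_probs_b, rng)
    truth = {
        "seed": seed,
        "n_a": n_a,
        "n_b": n_b,
        "base_probs_a": np.asarray(base_probs_a).tolist(),
        "base_probs_b": np.asarray(base_probs_b).tolist(),
    }
    return sites_a, sites_b, truth


@dataclass
class PeakSimConfig:
    """One condition's ChIP peak simulation.

    ``n_decoy`` peaks carry no RE (they are guaranteed motif-free), so
    scanning yields ``n_peaks - n_decoy`` REs.  ``n_differential``
    peaks (default: all) receive the planted binding-signal fold
    change; the rest sit at fold 1.
    """

    n_peaks: int = 214
    n_decoy: int = 6
    n_differential: int | None = None
    peak_length: int = 200
    genome_gc: float = 0.41
    p_c9: float = 0.731
    p_g12: float = 0.731
    re_epsilon: float = 0.0
    spacer_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_SPACER_PROBS)
    )
    signal_fold: float = 3.0
    signal_base: float = 10.0
    signal_spread: float = 0.5
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_differential is None:
            self.n_differential = self.n_peaks
        if not 0 <= self.n_decoy <= self.n_peaks:
            raise ValueError("n_decoy must be within [0, n_peaks]")
        if not 0 <= self.n_differential <= self.n_peaks:
            raise ValueError("n_differential must be within [0, n_peaks]")
        spacers = dict(self.spacer_probs)
        if abs(sum(spacers.values()) - 1.0) > 1e-9 or any(
            s < 0 for s in spacers
        ):
            raise ValueError("spacer_probs must be a distribution over lengths >= 0")
        max_span = SITE_LEN + max(spacers)
        if self.peak_length < max_span:
            raise ValueError(
                f"peak_length {self.peak_length} cannot hold a {max_span}-bp RE"
            )


@dataclass
class SimulatedPeaks:
    """Emitted peak sequences, interval/signal records, and ground truth."""

    sequences: dict[str, str]
    records: list[PeakRecord]
    truth: dict


def _random_background(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def simulate_peaks(
    config: PeakSimConfig,
    seed: int,
    pwm: PWM | None = None,
    min_score: float | None = None,
    chrom: str = "chrSim",
    prefix: str = "peak",
) -> SimulatedPeaks:
    """Simulate one condition's peak set (FASTA-able sequences + signals).

    Each non-decoy peak embeds exactly one RE at a uniform offset on a
    uniform strand, with a spacer drawn from ``spacer_probs``.  Binding
    signals are log-normal around a per-peak intensity, with the
    planted fold applied to the test condition of differential peaks.
    Decoy peaks are redrawn until they contain no window at or above
    ``min_score`` (default: 80% of the PWM maximum).
    """
    rng = np.random.default_rng(seed)
    if pwm is None:
        pwm = _default_pwm()
    if min_score is None:
        min_score = 0.8 * pwm.max_score

    base_probs = signature_base_probs(
        config.p_c9, config.p_g12, config.re_epsilon
    )
    spacer_lengths = np.array(sorted(config.spacer_probs))
    spacer_p = np.array([config.spacer_probs[s] for s in spacer_lengths], dtype=float)
    spacer_p = spacer_p / spacer_p.sum()

    decoy_flags = np.zeros(config.n_peaks, dtype=bool)
    decoy_flags[
        rng.choice(config.n_peaks, size=config.n_decoy, replace=False)
    ] = True
    diff_flags = np.zeros(config.n_peaks, dtype=bool)
    diff_flags[
        rng.choice(config.n_peaks, size=config.n_differential, replace=False)
    ] = True

    sequences: dict[str, str] = {}
    records: list[PeakRecord] = []
    truth_peaks = []
    cursor = 0
    for i in range(config.n_peaks):
        peak_id = f"{prefix}{i + 1:05d}"
        if decoy_flags[i]:
            while True:
                seq = _random_background(config.peak_length, config.genome_gc, rng)
                if not scan_re(seq, pwm, min_score=min_score, peak_id=peak_id):
                    break
            planted = None
        else:
            site = draw_sites(1, base_probs, rng)[0]
            spacer = int(rng.choice(spacer_lengths, p=spacer_p))
            insert = site[:HALF_LEN] + _random_background(
                spacer, config.genome_gc, rng
            ) + site[HALF_LEN:]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                insert = reverse_complement(insert)
            offset = int(rng.integers(0, config.peak_length - len(insert) + 1))
            background = _random_background(config.peak_length, config.genome_gc, rng)
            seq = background[:offset] + insert + background[offset + len(insert):]
            planted = {
                "offset": offset,
                "strand": strand,
                "spacer": spacer,
                "site20": site,
            }
        intensity = config.signal_base * float(
            np.exp(rng.normal(0.0, config.signal_spread))
        )
        fold = config.signal_fold if diff_flags[i] else 1.0
        ctrl = intensity * float(np.exp(rng.normal(0.0, config.noise_sd)))
        test = intensity * fold * float(np.exp(rng.normal(0.0, config.noise_sd)))
        sequences[peak_id] = seq
        records.append(
            PeakRecord(
                chrom=chrom,
                start=cursor,
                end=cursor + config.peak_length,
                peak_id=peak_id,
                signal_test=round(test, 4),
                signal_ctrl=round(ctrl, 4),
            )
        )
        truth_peaks.append(
            {
                "peak_id": peak_id,
                "decoy": bool(decoy_flags[i]),
                "differential": bool(diff_flags[i]),
                "re": planted,
            }
        )
        cursor += config.peak_length + 100
    truth = {"seed": seed, "config": _config_dict(config), "peaks": truth_peaks}
    return SimulatedPeaks(sequences=sequences, records=records, truth=truth)


def _config_dict(config) -> dict:
    d = asdict(config)
    for key, value in d.items():
        if isinstance(value, Mapping):
            d[key] = {str(k): v for k, v in value.items()}
    return d


@dataclass
class DESimConfig:
    """Planted differential-expression table.

    Planted genes receive fold changes of at least ``effect_fold`` on
    FPKM + 1 with FDR below the cutoff; null genes sit near fold 1 with
    FDR uniform on (0.05, 1], so the strict DE filter recovers exactly
    the planted set.
    """

    n_up: int = 194
    n_down: int = 281
    n_null: int = 11525
    effect_fold: float = 4.0
    effect_spread: float = 0.3
    null_sd: float = 0.1
    fpkm_log_mean: float = 1.6
    fpkm_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_up, self.n_down, self.n_null) < 0:
            raise ValueError("gene counts must be nonnegative")
        if self.effect_fold <= 2.0:
            raise ValueError("effect_fold must exceed the 2-fold filter")


def simulate_de_table(
    config: DESimConfig,
    seed: int,
    gene_ids: Sequence[str] | None = None,
) -> tuple[list[GeneRecord], dict]:
    """DE table of GeneRecords plus per-gene planted truth.

    Order: planted up genes, planted down genes, null genes; pass
    ``gene_ids`` to override the generated identifiers (length must
    match the total gene count).
    """
    rng = np.random.default_rng(seed)
    n_total = config.n_up + config.n_down + config.n_null
    if gene_ids is None:
        gene_ids = [f"gene{i + 1:05d}" for i in range(n_total)]
    elif len(gene_ids) != n_total:
        raise ValueError("gene_ids length must equal total gene count")

    records: list[GeneRecord] = []
    truth_genes = []
    for i, gene_id in enumerate(gene_ids):
        if i < config.n_up:
            status = "up"
        elif i < config.n_up + config.n_down:
            status = "down"
        else:
            status = "null"
        if status == "null":
            ctrl = float(rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd))
            ratio = float(np.exp(rng.normal(0.0, config.null_sd)))
            test = max(0.0, ratio * (ctrl + 1.0) - 1.0)
            fdr = float(rng.uniform(0.05, 1.0))
        else:
            fold = config.effect_fold * float(
                np.exp(abs(rng.normal(0.0, config.effect_spread)))
            )
            # keep below 0.0499995 so 6-decimal rounding cannot reach the
            # strict 0.05 cutoff
            fdr = float(rng.uniform(0.0, 0.0499))
            if status == "up":
                ctrl = float(rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd))
                test = fold * (ctrl + 1.0) - 1.0
            else:
                # floor the control expression so a 0-FPKM test value
                # still realises a >2-fold drop on FPKM + 1
                ctrl = 3.0 + float(
                    rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd)
                )
                test = max(0.0, (ctrl + 1.0) / fold - 1.0)
        ctrl, test = round(ctrl, 4), round(test, 4)
        record = GeneRecord(
            gene_id=gene_id,
            fpkm_ctrl=ctrl,
            fpkm_test=test,
            log2fc=round(
                float(np.log2((test + 1.0) / (ctrl + 1.0))), 6
            ),
            fdr=round(fdr, 6),
        )
        records.append(record)
        truth_genes.append({"gene_id": gene_id, "status": status})
    truth = {"seed": seed, "config": _config_dict(config), "genes": truth_genes}
    return records, truth


@dataclass
class IntegrationScenario:
    """A complete synthetic integration fixture.

    Thirteen regulated genes sit on one synthetic chromosome, linked to
    twelve differential peaks; one peak lies in the shared overlap of
    two gene bodies (the two-genes-one-peak configuration seen for
    ACTA2/FAS).  Nine of the twelve peak REs carry both C9 and G12.
    Distractor content exercises every filter: DE genes with no peak,
    non-DE genes hosting non-differential peaks, and decoy-free
    background peaks.
    """

    genes: list[GeneRecord]
    gene_models: list[GeneModel]
    peaks: list[PeakRecord]
    peak_sequences: dict[str, str]
    truth: dict


#: (C9 base, G12 base) for the twelve fixture REs; nine carry both
#: signature bases, three lack at least one.  The first entry belongs
#: to the peak shared by two overlapping genes and is non-concurrent so
#: the per-record and per-site concurrent counts coincide at nine.
_FIXTURE_SIGNATURES = [("T", "A")] + [("C", "G")] * 9 + [("T", "G"), ("C", "A")]


def simulate_integration_scenario(
    seed: int,
    de_config: DESimConfig | None = None,
    peak_length: int = 200,
    genome_gc: float = 0.41,
    chrom: str = "chrS",
) -> IntegrationScenario:
    """Build the two-assay integration fixture.

    The DE table plants 194 up + 281 down genes (475 total by default);
    the first 13 planted genes are the regulated targets.  Twelve
    differential peaks (signal fold 3) are placed inside their gene
    bodies — the first peak inside the overlap of gene 12 and gene 13 —
    and thirty non-differential peaks are scattered over other genes.
    """
    rng = np.random.default_rng(seed)
    de_config = de_config or DESimConfig()
    genes, de_truth = simulate_de_table(de_config, seed=int(rng.integers(2**31)))

    n_planted = de_config.n_up + de_config.n_down
    if n_planted < 13:
        raise ValueError("scenario needs at least 13 planted DE genes")
    # interleave up/down so the 13 targets span both directions
    planted_ids = [g.gene_id for g in genes[:n_planted]]
    order = rng.permutation(n_planted)
    target_ids = [planted_ids[i] for i in sorted(order[:13])]

    gene_len = 10_000
    spacing = 50_000
    models: list[GeneModel] = []
    positions: dict[str, tuple[int, int]] = {}
    # genes 1..11 isolated; genes 12 & 13 overlap by 4 kb
    for k, gene_id in enumerate(target_ids[:11]):
        start = 100_000 + k * spacing
        models.append(GeneModel(gene_id, chrom, start, start + gene_len, "+"))
        positions[gene_id] = (start, start + gene_len)
    start = 100_000 + 11 * spacing
    models.append(GeneModel(target_ids[11], chrom, start, start + gene_len, "+"))
    models.append(
        GeneModel(
            target_ids[12], chrom, start + gene_len - 4_000,
            start + 2 * gene_len - 4_000, "-",
        )
    )
    positions[target_ids[11]] = (start, start + gene_len)
    positions[target_ids[12]] = (start + gene_len - 4_000, start + 2 * gene_len - 4_000)

    # distractor models: DE genes without differential peaks and
    # non-DE genes that will host non-differential peaks
    distractor_ids = [g.gene_id for g in genes[n_planted : n_planted + 15]]
    extra_de_ids = [i for i in planted_ids if i not in target_ids][:15]
    for k, gene_id in enumerate(distractor_ids + extra_de_ids):
        start = 2_000_000 + k * spacing
        models.append(GeneModel(gene_id, chrom, start, start + gene_len, "+"))
        positions[gene_id] = (start, start + gene_len)

    pwm = _default_pwm()
    consensus = pwm.consensus

    def make_peak_sequence(c9: str, g12: str) -> tuple[str, dict]:
        site = list(consensus)
        site[8], site[11] = c9, g12
        site = "".join(site)
        strand = "+" if rng.random() < 0.5 else "-"
        insert = site if strand == "+" else reverse_complement(site)
        offset = int(rng.integers(0, peak_length - SITE_LEN + 1))
        background = _random_background(peak_length, genome_gc, rng)
        seq = background[:offset] + insert + background[offset + SITE_LEN:]
        return seq, {"offset": offset, "strand": strand, "spacer": 0, "site20": site}

    peaks: list[PeakRecord] = []
    sequences: dict[str, str] = {}
    truth_peaks = []

    def add_peak(peak_id, pos, fold, c9="C", g12="G"):
        seq, planted = make_peak_sequence(c9, g12)
        # a fixture peak is differential *by definition*: redraw the
        # noisy signals until they sit on the intended side of the
        # fold-2 filter, so the planted structure is recovered exactly
        while True:
            intensity = 10.0 * float(np.exp(rng.normal(0.0, 0.5)))
            ctrl = round(intensity * float(np.exp(rng.normal(0.0, 0.1))), 4)
            test = round(
                intensity * fold * float(np.exp(rng.normal(0.0, 0.1))), 4
            )
            ratio = (test + 1.0) / (ctrl + 1.0)
            if (ratio > 2.0) == (fold > 1.0):
                break
        peaks.append(
            PeakRecord(chrom, pos, pos + peak_length, peak_id, test, ctrl)
        )
        sequences[peak_id] = seq
        truth_peaks.append(
            {"peak_id": peak_id, "differential": fold > 1.0, "re": planted}
        )

    # peak 1 sits in the shared overlap of target genes 12 and 13
    shared_start = positions[target_ids[12]][0] + 1_000
    add_peak("peakD001", shared_start, 3.0, *_FIXTURE_SIGNATURES[0])
    for k in range(11):
        c9, g12 = _FIXTURE_SIGNATURES[k + 1]
        start = positions[target_ids[k]][0] + 2_000
        add_peak(f"peakD{k + 2:03d}", start, 3.0, c9, g12)

    # thirty non-differential peaks over distractor genes and open space
    hosts = (distractor_ids + extra_de_ids) * 2
    for k in range(30):
        if k < len(hosts):
            start = positions[hosts[k]][0] + 3_000
        else:
            start = 5_000_000 + k * 10_000
        add_peak(f"peakN{k + 1:03d}", start, 1.0)

    truth = {
        "seed": seed,
        "target_gene_ids": target_ids,
        "shared_peak": "peakD001",
        "n_concurrent_res": sum(
            1 for c9, g12 in _FIXTURE_SIGNATURES if c9 == "C" and g12 == "G"
        ),
        "de": de_truth,
        "peaks": truth_peaks,
    }
    return IntegrationScenario(
        genes=genes,
        gene_models=models,
        peaks=peaks,
        peak_sequences=sequences,
        truth=truth,
    )
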