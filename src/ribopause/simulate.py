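"""Synthetic Ribo-seq / RNA-seq generator with ground truth.

Emulates the data structure the analysis assumes: two conditions (wild type
and a wobble-U34 modification mutant) with biological replicates, ribosome
footprints of 28-29 nt carrying 3-nt periodicity, codon-specific A-site
dwell effects concentrated on the cognate AAA/GAA/CAA codons in the mutant,
and negative-binomially distributed gene-level RNA/ribosome counts.

The generator exists so that every downstream stage can be verified by
parameter recovery: it emits the exact P-site of every footprint and the
true translational-efficiency ratio of every gene.

The occupancy model: the expected footprint density at an in-frame P-site
position ``p`` on transcript ``t`` is proportional to

    abundance(t) * dwell[codon at p + 3]

i.e. the dwell multiplier acts on the codon one codon 3' of the P site —
the ribosomal A site, where slow decoding by hypomodified tRNAs causes
pausing.  Footprints are drawn multinomially to the configured depth, so a
library is a closed composition: boosting dwell at some codons necessarily
dilutes the per-million share of all others (see docs/methods.md).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .footprints import P_SITE_OFFSETS
from .transcripts import SENSE_CODONS, STOP_CODONS, TranscriptModel, codon_at

log = logging.getLogger(__name__)

#: worst-case margins so that any 28/29-nt read window, including +/-1 nt
#: jitter, fits on the transcript: 5' end >= p - 13 - 1, 3' end <= p + 17
_UP_MARGIN = max(P_SITE_OFFSETS.values()) + 1
_DOWN_MARGIN = max(L - P_SITE_OFFSETS[L] for L in P_SITE_OFFSETS) + 1


def _default_dwell() -> dict[str, dict[str, float]]:
    # mutant: 3-fold A-site dwell on the cognate [A/G/C]AA codons
    return {"wt": {}, "mut": {"AAA": 3.0, "GAA": 3.0, "CAA": 3.0}}


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults describe the emulated study design: two conditions x two
    replicates, 28/29-nt footprints, 2x10^5 footprints per library, a
    3-fold A-site dwell increase on AAA/GAA/CAA in the mutant, and 10% of
    genes with a 4-fold translational-efficiency shift.
    """

    n_transcripts: int = 200
    cds_length_range: tuple[int, int] = (300, 1500)  # nt, start..stop inclusive
    utr_length: int = 30  # nt padding each side so footprints near CDS ends fit
    codon_weights: dict[str, float] | None = None  # None = uniform over 61 sense codons
    dwell_multipliers: dict[str, dict[str, float]] = field(default_factory=_default_dwell)
    depth: int = 200_000  # expected footprints per library
    len28_fraction: float = 0.5
    offnoise_rate: float = 0.1  # probability of a +/-1 nt 5'-end shift
    abundance_sigma: float = 1.0  # log-normal spread of transcript abundances
    nb_mean: float = 100.0  # mean RNA count of an average-abundance gene
    nb_dispersion: float = 0.05  # NB dispersion alpha; var = mu + alpha*mu^2
    te_signal_fraction: float = 0.1  # genes with a true TE shift in the mutant
    te_signal_ratio: float = 4.0
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.cds_length_range
        if not (9 <= lo <= hi):
            raise ValueError("cds_length_range must satisfy 9 <= lo <= hi")
        for p, name in [
            (self.len28_fraction, "len28_fraction"),
            (self.offnoise_rate, "offnoise_rate"),
            (self.te_signal_fraction, "te_signal_fraction"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for cond, dw in self.dwell_multipliers.items():
            for codon, m in dw.items():
                if m <= 0:
                    raise ValueError(f"dwell multiplier {cond}:{codon} must be > 0, got {m}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator, for recovery tests."""

    footprints: pd.DataFrame | None = None  # read_id, transcript_id, p_site, length, jitter
    te_ratio: pd.DataFrame | None = None  # gene_id, te_ratio
    dwell_multipliers: dict[str, dict[str, float]] | None = None


def _rng(cfg: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, *stream])


def _condition_key(condition: str) -> int:
    return zlib.crc32(condition.encode()) & 0x7FFFFFFF


def generate_transcriptome(cfg: SimConfig) -> list[TranscriptModel]:
    """Sample a transcriptome: ATG + sense codons + stop, flanked by UTRs.

    CDS codons are drawn from ``codon_weights`` (uniform by default), so no
    internal stop codons occur; total CDS length (start codon through stop)
    is uniform over the codon-rounded ``cds_length_range``.  Deterministic
    given ``cfg.seed``.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    codons = np.array(SENSE_CODONS)
    if cfg.codon_weights is None:
        weights = np.full(len(codons), 1.0 / len(codons))
    else:
        weights = np.array([cfg.codon_weights.get(c, 0.0) for c in SENSE_CODONS], float)
        if weights.sum() <= 0:
            raise ValueError("codon_weights assigns no mass to any sense codon")
        weights = weights / weights.sum()
    stops = sorted(STOP_CODONS)
    lo, hi = cfg.cds_length_range
    models = []
    width = len(str(cfg.n_transcripts))
    for i in range(cfg.n_transcripts):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))  # incl. start + stop
        body = rng.choice(codons, size=n_codons - 2, p=weights)
        stop = stops[rng.integers(0, len(stops))]
        utr5 = "".join(rng.choice(list("ACGT"), size=cfg.utr_length))
        utr3 = "".join(rng.choice(list("ACGT"), size=cfg.utr_length))
        seq = utr5 + "ATG" + "".join(body) + stop + utr3
        models.append(
            TranscriptModel(
                transcript_id=f"t{i + 1:0{width}d}",
                sequence=seq,
                cds_start=cfg.utr_length,
                cds_end=cfg.utr_length + 3 * n_codons,
            )
        )
    return models


def transcript_abundances(cfg: SimConfig) -> np.ndarray:
    """Log-normal relative abundances, shared by both conditions and assays."""
    rng = _rng(cfg, 2)
    return rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=cfg.n_transcripts)


def simulate_footprints(
    transcripts: list[TranscriptModel],
    cfg: SimConfig,
    condition: str,
    replicate: int = 1,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw one footprint library for ``condition`` and its truth table.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence)`` and ``truth`` has one row per emitted read with
    the exact P-site used.  Footprint 5' ends sit at ``p - 12`` (28-nt) or
    ``p - 13`` (29-nt), shifted +/-1 nt with probability ``offnoise_rate``.
    P-site positions whose read window would exit the transcript are
    excluded from the sampling support.
    """
    cfg.validate()
    rng = _rng(cfg, 3, _condition_key(condition), replicate)
    abundance = transcript_abundances(cfg)
    if len(abundance) != len(transcripts):
        raise ValueError("cfg.n_transcripts does not match the transcript list")
    dwell = cfg.dwell_multipliers.get(condition, {})

    tidx_parts, pos_parts, w_parts = [], [], []
    n_excluded = 0
    for ti, t in enumerate(transcripts):
        # P site on any sense codon; the stop codon is never a P-site codon
        p = np.arange(t.cds_start, t.cds_end - 3, 3)
        ok = (p >= _UP_MARGIN) & (p <= len(t.sequence) - _DOWN_MARGIN)
        n_excluded += int((~ok).sum())
        p = p[ok]
        w = np.empty(len(p), float)
        for j, pj in enumerate(p):
            a_codon = codon_at(t, pj + 3)  # A site = one codon 3' of P
            w[j] = dwell.get(a_codon, 1.0) if a_codon is not None else 1.0
        tidx_parts.append(np.full(len(p), ti))
        pos_parts.append(p)
        w_parts.append(abundance[ti] * w)
    if n_excluded:
        log.info(
            "%s rep %d: excluded %d P-site positions too close to transcript ends",
            condition, replicate, n_excluded,
        )
    tidx = np.concatenate(tidx_parts)
    pos = np.concatenate(pos_parts)
    weights = np.concatenate(w_parts)
    probs = weights / weights.sum()

    counts = rng.multinomial(cfg.depth, probs)
    support_idx = np.repeat(np.arange(len(probs)), counts)
    n = len(support_idx)
    lengths = np.where(rng.random(n) < cfg.len28_fraction, 28, 29)
    r = cfg.offnoise_rate
    jitter = rng.choice(np.array([-1, 0, 1]), size=n, p=[r / 2, 1 - r, r / 2])

    reads: list[tuple[str, str]] = []
    rows = []
    seqs = [t.sequence for t in transcripts]
    ids = [t.transcript_id for t in transcripts]
    offsets = P_SITE_OFFSETS
    for i in range(n):
        si = support_idx[i]
        ti, p, L, j = int(tidx[si]), int(pos[si]), int(lengths[i]), int(jitter[i])
        start = p - offsets[L] + j
        if start < 0 or start + L > len(seqs[ti]):
            continue  # jittered window exits the transcript; drop, never clip
        rid = f"{condition}_{replicate}_{i:07d}"
        reads.append((rid, seqs[ti][start : start + L]))
        rows.append((rid, ids[ti], p, L, j))
    truth = pd.DataFrame(
        rows, columns=["read_id", "transcript_id", "p_site", "length", "jitter"]
    )
    return reads, truth


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, alpha) with var = mu + alpha*mu^2; alpha = 0 degenerates to round(mu)."""
    mu = np.asarray(mu, float)
    if dispersion <= 0:
        return np.rint(mu).astype(int)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    transcripts: list[TranscriptModel],
    cfg: SimConfig,
    conditions: tuple[str, str] = ("wt", "mut"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene-level RNA and ribosome count matrices plus true TE ratios.

    RNA counts are NB with mean ``nb_mean * relative abundance`` in every
    sample (transcription is unchanged between conditions); ribosome counts
    take the same mean multiplied, in the second condition, by the gene's
    true TE ratio.  A fraction ``te_signal_fraction`` of genes receives
    ratio ``te_signal_ratio``; the rest have ratio 1.  Columns are named
    ``<condition>_<replicate>``.
    """
    cfg.validate()
    rng = _rng(cfg, 4)
    genes = [t.transcript_id for t in transcripts]
    n = len(genes)
    abundance = transcript_abundances(cfg)[:n]
    rel = abundance / abundance.mean()
    mu_rna = cfg.nb_mean * rel

    te = np.ones(n)
    n_sig = int(round(cfg.te_signal_fraction * n))
    if n_sig:
        sig_idx = rng.choice(n, size=n_sig, replace=False)
        te[sig_idx] = cfg.te_signal_ratio

    wt_label, mut_label = conditions
    rna_cols, ribo_cols = {}, {}
    for cond in conditions:
        ribo_mu = mu_rna * (te if cond == mut_label else 1.0)
        for rep in range(1, cfg.n_replicates + 1):
            name = f"{cond}_{rep}"
            rna_cols[name] = _nb_sample(rng, mu_rna, cfg.nb_dispersion)
            ribo_cols[name] = _nb_sample(rng, ribo_mu, cfg.nb_dispersion)
    rna = pd.DataFrame(rna_cols, index=pd.Index(genes, name="gene_id"))
    ribo = pd.DataFrame(ribo_cols, index=pd.Index(genes, name="gene_id"))
    truth = pd.DataFrame({"gene_id": genes, "te_ratio": te})
    return rna, ribo, truth


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    """Write reads as FASTQ with constant 'I' (Q40) qualities."""
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
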