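"""Footprint placement, P-site assignment and 3-nt periodicity QC.

Ribosome footprints of 28 or 29 nt are placed on the transcript set by
exact, unique substring matching (the in-silico equivalent of a 100%-match
search).  The P site is a fixed offset from the footprint 5' end: 12 nt for
28-nt reads, 13 nt for 29-nt reads.  P-site plots (per-position count
profiles, per-million normalized) and the frame-fraction periodicity check
are built from the resulting alignments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .transcripts import TranscriptModel

#: distance from the footprint 5' end to the first nucleotide of the P-site codon
P_SITE_OFFSETS: dict[int, int] = {28: 12, 29: 13}


def assign_p_site(start: int, length: int) -> int:
    """P-site position for a footprint with 5' end at ``start``.

    Only 28- and 29-nt footprints carry a defined offset (12 and 13 nt);
    any other length is an error.
    """
    try:
        return start + P_SITE_OFFSETS[length]
    except KeyError:
        raise ValueError(
            f"no P-site offset for footprint length {length}; "
            f"supported lengths: {sorted(P_SITE_OFFSETS)}"
        ) from None


@dataclass
class FootprintAlignment:
    """A uniquely placed footprint with its inferred P site.

    ``frame`` is ``(p_site - cds_start) mod 3`` when the P site lies within
    the CDS, else None.
    """

    read_id: str
    transcript_id: str
    start: int
    length: int
    p_site: int
    frame: int | None


class _Multi:
    __slots__ = ()


_MULTI = _Multi()  # sentinel marking a k-mer seen at more than one location


class FootprintMatcher:
    """Exact-match index over a transcript set for 28/29-nt reads.

    Every 28- and 29-mer of every transcript is indexed once; a read is
    accepted only when its sequence occurs at exactly one (transcript,
    position) across the whole set.  Reverse-complement matching is not
    attempted: footprints derive from the mRNA sense strand.
    """

    def __init__(self, transcripts: list[TranscriptModel]):
        self.transcripts = list(transcripts)
        index: dict[str, object] = {}
        for ti, t in enumerate(self.transcripts):
            seq = t.sequence
            for k in P_SITE_OFFSETS:
                for i in range(len(seq) - k + 1):
                    key = seq[i : i + k]
                    hit = index.get(key)
                    if hit is None:
                        index[key] = (ti, i)
                    elif hit is not _MULTI and hit != (ti, i):
                        index[key] = _MULTI
        self._index = index

    def match(
        self, reads: Iterable[tuple[str, str]]
    ) -> tuple[list[FootprintAlignment], Counter]:
        """Place reads; returns (alignments, counters).

        Counters report ``accepted``, ``wrong_length``, ``no_match`` and
        ``multi_match`` read tallies.
        """
        alignments: list[FootprintAlignment] = []
        counters: Counter = Counter(
            accepted=0, wrong_length=0, no_match=0, multi_match=0
        )
        index = self._index
        transcripts = self.transcripts
        for rid, seq in reads:
            if len(seq) not in P_SITE_OFFSETS:
                counters["wrong_length"] += 1
                continue
            hit = index.get(seq)
            if hit is None:
                counters["no_match"] += 1
                continue
            if hit is _MULTI:
                counters["multi_match"] += 1
                continue
            ti, start = hit
            t = transcripts[ti]
            p = assign_p_site(start, len(seq))
            frame = (p - t.cds_start) % 3 if t.cds_start <= p < t.cds_end else None
            alignments.append(
                FootprintAlignment(rid, t.transcript_id, start, len(seq), p, frame)
            )
            counters["accepted"] += 1
        return alignments, counters


def match_footprints(
    reads: Iterable[tuple[str, str]], transcripts: list[TranscriptModel]
) -> tuple[list[FootprintAlignment], Counter]:
    """One-shot convenience wrapper around :class:`FootprintMatcher`."""
    return FootprintMatcher(transcripts).match(reads)


@dataclass
class PSiteProfile:
    """Per-position P-site counts for one transcript and one library."""

    transcript_id: str
    sample: str
    counts: np.ndarray  # int counts over transcript nt positions
    normalized: np.ndarray  # per-million-library-reads
    library_total: int


def build_profile(
    alignments: Iterable[FootprintAlignment],
    transcript: TranscriptModel,
    sample: str,
    library_total: int,
) -> PSiteProfile:
    """P-site plot: counts[p] = alignments with p_site = p, per-million scaled."""
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    n = len(transcript.sequence)
    p_sites = [
        a.p_site for a in alignments if a.transcript_id == transcript.transcript_id
    ]
    counts = np.bincount(p_sites, minlength=n) if p_sites else np.zeros(n, int)
    normalized = counts * (1e6 / library_total)
    return PSiteProfile(transcript.transcript_id, sample, counts, normalized, library_total)


class PeriodicityResult(NamedTuple):
    f0: float
    f1: float
    f2: float
    passed: bool


def periodicity(
    profile: PSiteProfile, t: TranscriptModel, threshold: float = 0.6
) -> PeriodicityResult:
    """Frame fractions of CDS-internal P-site counts.

    Uses only positions in ``[cds_start, cds_end - 3)`` — the first ATG up
    to the last codon before the stop.  Fractions sum to 1 when any counts
    exist; a transcript passes the periodicity QC when the in-frame
    fraction ``f0`` reaches ``threshold``.
    """
    if profile.transcript_id != t.transcript_id:
        raise ValueError("profile and transcript ids differ")
    region = profile.counts[t.cds_start : t.cds_end - 3]
    sums = [int(region[f::3].sum()) for f in range(3)]
    total = sum(sums)
    if total == 0:
        return PeriodicityResult(0.0, 0.0, 0.0, False)
    f0, f1, f2 = (s / total for s in sums)
    return PeriodicityResult(f0, f1, f2, f0 >= threshold)


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Load a FASTQ as (read_id, sequence) pairs; qualities are ignored."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def alignments_frame(alignments: Iterable[FootprintAlignment]) -> pd.DataFrame:
    """Alignments as a tidy table for TSV export."""
    return pd.DataFrame(
        [
            (a.read_id, a.transcript_id, a.start, a.length, a.p_site,
             -1 if a.frame is None else a.frame)
            for a in alignments
        ],
        columns=["read_id", "transcript_id", "start", "length", "p_site", "frame"],
    )
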