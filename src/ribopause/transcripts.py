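"""Transcript models and codon addressing on spliced-mRNA coordinates.

Every downstream stage — footprint placement, P-site assignment, codon-level
occupancy counting, codon-usage statistics — works in the coordinate frame
defined here: 0-based, half-open nucleotide positions on the mature
transcript, with the coding sequence given as a ``[cds_start, cds_end)``
slice whose length is a multiple of three.  Genomic coordinates, strand and
isoform structure are deliberately out of scope; the analysis is
per-transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
#: the 61 sense codons, lexicographic
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
ALL_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")

_VALID_NT = frozenset("ACGT")


@dataclass
class TranscriptModel:
    """A transcript sequence with its CDS bounds.

    Parameters
    ----------
    transcript_id : str
        Unique identifier shared between the FASTA and the CDS table.
    sequence : str
        Nucleotide sequence over {A, C, G, T} (ambiguity codes tolerated in
        non-strict mode; codons containing them are masked from counting).
    cds_start, cds_end : int
        0-based half-open CDS bounds on ``sequence``; the CDS runs from the
        start codon through (and including) the stop codon.
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    def cds_codons(self) -> list[str]:
        """All CDS codons in order, start codon first, stop codon last."""
        return [
            self.sequence[i : i + 3]
            for i in range(self.cds_start, self.cds_end, 3)
        ]

    def validate(self, strict: bool = True, require_start_stop: bool = True) -> None:
        """Raise ``ValueError`` on any violated invariant.

        With ``require_start_stop=False`` the ATG/stop requirement is
        relaxed (for user-supplied annotation sets that include partial
        CDS models); coordinate sanity is always enforced.
        """
        tid = self.transcript_id
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{tid}: CDS [{self.cds_start}, {self.cds_end}) outside "
                f"sequence of length {len(self.sequence)}"
            )
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{tid}: CDS length {self.cds_length} is not a multiple of 3"
            )
        if strict and (set(self.sequence) - _VALID_NT):
            bad = sorted(set(self.sequence) - _VALID_NT)
            raise ValueError(f"{tid}: sequence contains non-ACGT characters {bad}")
        if require_start_stop:
            first = self.sequence[self.cds_start : self.cds_start + 3]
            last = self.sequence[self.cds_end - 3 : self.cds_end]
            if first != START_CODON:
                raise ValueError(f"{tid}: CDS does not begin with ATG (got {first})")
            if last not in STOP_CODONS:
                raise ValueError(f"{tid}: CDS does not end with a stop codon (got {last})")


def codon_at(t: TranscriptModel, nt_pos: int) -> str | None:
    """Codon starting at transcript position ``nt_pos``, or None.

    Returns the in-frame CDS codon ``sequence[nt_pos:nt_pos+3]`` when
    ``nt_pos`` is inside the CDS and on the reading frame set by
    ``cds_start``; otherwise None (out of frame, outside the CDS, or a
    codon containing an ambiguity character).
    """
    if nt_pos < t.cds_start or nt_pos + 3 > t.cds_end:
        return None
    if (nt_pos - t.cds_start) % 3 != 0:
        return None
    codon = t.sequence[nt_pos : nt_pos + 3]
    if set(codon) - _VALID_NT:
        return None  # masked: ambiguity codes cannot be attributed to a codon
    return codon


def read_transcripts(
    fasta_path: str | Path,
    cds_table_path: str | Path,
    strict: bool = True,
    require_start_stop: bool = True,
) -> list[TranscriptModel]:
    """Load transcript models from a FASTA plus a CDS coordinate TSV.

    The CDS table is tab-separated with a header row and columns
    ``transcript_id``, ``cds_start``, ``cds_end`` (0-based, half-open).
    In strict mode any identifier present in only one input, and any
    invariant violation, raises; otherwise offending records are dropped
    with a log message.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()

    table = pd.read_csv(cds_table_path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "cds_start", "cds_end"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"CDS table {cds_table_path} must have columns {sorted(required)}"
        )
    cds = {
        str(r.transcript_id): (int(r.cds_start), int(r.cds_end))
        for r in table.itertuples()
    }

    only_fasta = sorted(set(seqs) - set(cds))
    only_table = sorted(set(cds) - set(seqs))
    if strict and (only_fasta or only_table):
        raise ValueError(
            f"transcript ids present in only one input: "
            f"FASTA-only {only_fasta}, table-only {only_table}"
        )
    for tid in only_fasta:
        log.warning("dropping %s: no CDS table row", tid)
    for tid in only_table:
        log.warning("dropping %s: no FASTA record", tid)

    models: list[TranscriptModel] = []
    for tid in sorted(set(seqs) & set(cds)):
        start, end = cds[tid]
        m = TranscriptModel(tid, seqs[tid], start, end)
        try:
            m.validate(strict=strict, require_start_stop=require_start_stop)
        except ValueError as exc:
            if strict:
                raise
            log.warning("dropping %s: %s", tid, exc)
            continue
        models.append(m)
    return models


def write_transcripts(
    models: list[TranscriptModel],
    fasta_path: str | Path,
    cds_table_path: str | Path,
) -> None:
    """Write models back to FASTA + CDS TSV (round-trips with read_transcripts)."""
    records = [
        SeqRecord(Seq(m.sequence), id=m.transcript_id, description="")
        for m in models
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "transcript_id": [m.transcript_id for m in models],
            "cds_start": [m.cds_start for m in models],
            "cds_end": [m.cds_end for m in models],
        }
    ).to_csv(cds_table_path, sep="\t", index=False)
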