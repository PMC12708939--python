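"""Codon-resolved ribosome-site occupancy and condition differentials.

For every accepted footprint the codon occupying each ribosome site
position (E, P, A and the -6/+6 nt flanks by default) is read off the
transcript, and normalized counts (per million library reads) are
accumulated per (codon, site).  Codon groups — the cognate [A/G/C]AA and
[A/G/C]AG codons of the wobble-U34 tRNAs and the unrelated [A/G/C]GA /
[A/G/C]GG controls — are summed, and the mutant-minus-wild-type difference
per (group, site) is the pause readout: a slow A-site codon shows a
positive (group, A) differential.

Because each library is normalized to its own total, the table is a closed
composition: genuine enrichment at paused codons is necessarily mirrored
by a small per-million depletion everywhere else (see docs/methods.md).
Poisson standard errors for each differential entry are provided so that
this can be judged against counting noise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .footprints import FootprintAlignment
from .transcripts import ALL_CODONS, TranscriptModel, codon_at


@dataclass(frozen=True)
class SiteSpec:
    """A ribosome site as a codon-aligned nt offset from the P-site start."""

    name: str
    nt_offset: int

    def __post_init__(self):
        if self.nt_offset % 3 != 0:
            raise ValueError(
                f"site {self.name!r}: offset {self.nt_offset} is not codon-aligned"
            )


def default_sites() -> list[SiteSpec]:
    """The five analyzed positions: -6 nt, E, P, A, +6 nt relative to the P site."""
    return [
        SiteSpec("minus6", -6),
        SiteSpec("E", -3),
        SiteSpec("P", 0),
        SiteSpec("A", 3),
        SiteSpec("plus6", 6),
    ]


#: cognate codons of tRNA-Lys(UUU)/Glu(UUC)/Gln(UUG) (NAA), their G-ending
#: synonyms decoded independently of the wobble modification (NAG), and the
#: unrelated control groups (NGA, NGG)
DEFAULT_GROUPS: dict[str, frozenset[str]] = {
    "NAA": frozenset({"AAA", "GAA", "CAA"}),
    "NAG": frozenset({"AAG", "GAG", "CAG"}),
    "NGA": frozenset({"AGA", "GGA", "CGA"}),
    "NGG": frozenset({"AGG", "GGG", "CGG"}),
}


@dataclass
class CodonSiteCounts:
    """Raw and per-million footprint counts per (codon, site) for one library."""

    condition: str
    table: pd.DataFrame  # columns: codon, site, raw, normalized
    library_total: int
    sites: tuple[SiteSpec, ...]


@dataclass
class GroupedCounts:
    """Codon-group sums of a :class:`CodonSiteCounts` table."""

    condition: str
    table: pd.DataFrame  # columns: group, site, raw, normalized
    library_total: int


@dataclass
class DifferentialOccupancy:
    """Mutant-minus-wild-type occupancy differences per (group, site).

    ``se_normalized`` is the Poisson standard error of the per-million
    difference, for judging entries against counting noise.  The table is
    antisymmetric under swapping the two conditions.
    """

    mutant: str
    wildtype: str
    table: pd.DataFrame  # columns: group, site, diff_raw, diff_normalized, se_normalized


def count_by_codon_site(
    alignments: Iterable[FootprintAlignment],
    transcripts: list[TranscriptModel],
    sites: Iterable[SiteSpec] | None = None,
    library_total: int | None = None,
    condition: str = "",
) -> CodonSiteCounts:
    """Accumulate footprint counts by the codon at each ribosome site.

    For each alignment and site the codon at ``p_site + nt_offset`` is read
    off; positions outside the CDS or out of frame contribute nothing at
    that site (exclusion is per site, not per footprint, so a footprint
    near the start codon still counts at P/A).  Footprints with an
    out-of-frame P site contribute at no site.
    """
    sites = tuple(sites) if sites is not None else tuple(default_sites())
    alignments = list(alignments)
    if library_total is None:
        library_total = len(alignments)
    tmap = {t.transcript_id: t for t in transcripts}
    acc: Counter = Counter()
    for a in alignments:
        t = tmap.get(a.transcript_id)
        if t is None:
            raise KeyError(f"alignment references unknown transcript {a.transcript_id}")
        p = a.p_site
        for s in sites:
            c = codon_at(t, p + s.nt_offset)
            if c is not None:
                acc[c, s.name] += 1
    scale = 1e6 / library_total if library_total > 0 else 0.0
    rows = [
        (codon, s.name, acc[codon, s.name], acc[codon, s.name] * scale)
        for codon in ALL_CODONS
        for s in sites
    ]
    table = pd.DataFrame(rows, columns=["codon", "site", "raw", "normalized"])
    return CodonSiteCounts(condition, table, library_total, sites)


def group_counts(
    csc: CodonSiteCounts, groups: Mapping[str, frozenset[str] | set[str]] | None = None
) -> GroupedCounts:
    """Sum member codons' counts per (group, site); groups must be disjoint."""
    if groups is None:
        groups = DEFAULT_GROUPS
    seen: set[str] = set()
    for name, codons in groups.items():
        overlap = seen & set(codons)
        if overlap:
            raise ValueError(f"codon groups overlap: {sorted(overlap)} (group {name})")
        seen |= set(codons)
    t = csc.table
    rows = []
    for name in groups:
        member = t[t["codon"].isin(groups[name])]
        by_site = member.groupby("site", sort=False)[["raw", "normalized"]].sum()
        for s in csc.sites:
            raw = int(by_site["raw"].get(s.name, 0))
            norm = float(by_site["normalized"].get(s.name, 0.0))
            rows.append((name, s.name, raw, norm))
    table = pd.DataFrame(rows, columns=["group", "site", "raw", "normalized"])
    return GroupedCounts(csc.condition, table, csc.library_total)


def differential_occupancy(
    mut: GroupedCounts, wt: GroupedCounts
) -> DifferentialOccupancy:
    """Per-(group, site) normalized-count difference, mutant minus wild type."""
    key_m = list(zip(mut.table["group"], mut.table["site"]))
    key_w = list(zip(wt.table["group"], wt.table["site"]))
    if set(key_m) != set(key_w):
        raise ValueError("grouped tables have mismatched (group, site) keys")
    m = mut.table.set_index(["group", "site"])
    w = wt.table.set_index(["group", "site"]).loc[m.index]
    sm = 1e6 / mut.library_total if mut.library_total > 0 else 0.0
    sw = 1e6 / wt.library_total if wt.library_total > 0 else 0.0
    diff_raw = m["raw"] - w["raw"]
    diff_norm = m["normalized"] - w["normalized"]
    se = np.sqrt(m["raw"] * sm**2 + w["raw"] * sw**2)
    table = pd.DataFrame(
        {
            "group": [g for g, _ in m.index],
            "site": [s for _, s in m.index],
            "diff_raw": diff_raw.to_numpy(),
            "diff_normalized": diff_norm.to_numpy(),
            "se_normalized": se.to_numpy(),
        }
    )
    return DifferentialOccupancy(mut.condition, wt.condition, table)


def per_transcript_differential(
    alignments_by_condition: Mapping[str, Iterable[FootprintAlignment]],
    transcript: TranscriptModel,
    sites: Iterable[SiteSpec] | None = None,
    groups: Mapping[str, frozenset[str]] | None = None,
    library_totals: Mapping[str, int] | None = None,
    mutant: str = "mut",
    wildtype: str = "wt",
) -> DifferentialOccupancy:
    """The same differential restricted to a single transcript.

    Library totals stay whole-library (per-million units remain comparable
    across transcripts), so per-transcript tables sum to the whole-set
    table.  A transcript with no footprints in a condition is an error.
    """
    tid = transcript.transcript_id
    grouped = {}
    for cond in (wildtype, mutant):
        alns = [a for a in alignments_by_condition[cond] if a.transcript_id == tid]
        if not alns:
            raise ValueError(f"transcript {tid} absent from condition {cond!r}")
        total = (
            library_totals[cond]
            if library_totals is not None
            else len(list(alignments_by_condition[cond]))
        )
        csc = count_by_codon_site(alns, [transcript], sites, total, cond)
        grouped[cond] = group_counts(csc, groups)
    return differential_occupancy(grouped[mutant], grouped[wildtype])


class CodonOccupancy:
    """Codon-site occupancy model over conditions (fit → results object).

    Parameters
    ----------
    transcripts : list of TranscriptModel
    alignments : mapping of condition label → footprint alignments
    library_totals : optional mapping of condition label → library size used
        for per-million normalization (defaults to the number of alignments)
    sites, groups : optional overrides of the analyzed ribosome sites and
        codon groups
    """

    def __init__(
        self,
        transcripts: list[TranscriptModel],
        alignments: Mapping[str, Iterable[FootprintAlignment]],
        library_totals: Mapping[str, int] | None = None,
        sites: Iterable[SiteSpec] | None = None,
        groups: Mapping[str, frozenset[str]] | None = None,
    ):
        self.transcripts = list(transcripts)
        self.alignments = {c: list(a) for c, a in alignments.items()}
        self.library_totals = dict(library_totals) if library_totals else {
            c: len(a) for c, a in self.alignments.items()
        }
        self.sites = tuple(sites) if sites is not None else tuple(default_sites())
        self.groups = dict(groups) if groups is not None else dict(DEFAULT_GROUPS)

    def fit(self) -> "CodonOccupancyResults":
        counts = {
            c: count_by_codon_site(
                a, self.transcripts, self.sites, self.library_totals[c], c
            )
            for c, a in self.alignments.items()
        }
        grouped = {c: group_counts(csc, self.groups) for c, csc in counts.items()}
        return CodonOccupancyResults(self, counts, grouped)


class CodonOccupancyResults:
    """Fitted codon-site occupancy tables with differential accessors."""

    def __init__(self, model: CodonOccupancy, counts, grouped):
        self.model = model
        self.counts: dict[str, CodonSiteCounts] = counts
        self.grouped: dict[str, GroupedCounts] = grouped

    def differential(self, mutant: str = "mut", wildtype: str = "wt") -> DifferentialOccupancy:
        return differential_occupancy(self.grouped[mutant], self.grouped[wildtype])

    def summary(self, mutant: str = "mut", wildtype: str = "wt") -> str:
        d = self.differential(mutant, wildtype)
        lines = [
            f"Codon-site occupancy differential: {mutant} - {wildtype}",
            f"libraries: "
            + ", ".join(f"{c}={n}" for c, n in sorted(self.model.library_totals.items())),
            f"{'group':<8}{'site':<8}{'diff (per 1e6)':>16}{'SE':>10}",
        ]
        for r in d.table.itertuples():
            lines.append(
                f"{r.group:<8}{r.site:<8}{r.diff_normalized:>16.1f}{r.se_normalized:>10.1f}"
            )
        return "\n".join(lines)
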