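"""Per-transcript codon-usage frequencies and their relation to TE changes.

If slow decoding of the cognate [A/G/C]AA codons drove translational-
efficiency shifts transcriptome-wide, transcripts richer in those codons
should show larger TE fold changes.  This module computes per-CDS codon
frequencies (stop codon excluded — it is decoded by release factors, not
tRNAs), sums them over codon groups, and correlates the group frequency
with TE_FClog2 across genes (rank correlation by default).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .occupancy import DEFAULT_GROUPS
from .transcripts import TranscriptModel


def codon_frequencies(t: TranscriptModel) -> pd.Series:
    """Fractions of CDS codons (start codon included, stop excluded).

    Codons containing ambiguity characters are masked from the tally.
    Raises on a CDS shorter than two codons (nothing to count besides the
    stop).
    """
    if t.cds_length < 6:
        raise ValueError(
            f"{t.transcript_id}: CDS of {t.cds_length} nt is too short for usage"
        )
    codons = t.cds_codons()[:-1]  # exclude the stop codon
    valid = [c for c in codons if set(c) <= set("ACGT")]
    counts = pd.Series(valid).value_counts()
    freq = counts / counts.sum()
    freq.name = t.transcript_id
    return freq


def group_frequency(freq: pd.Series, codons) -> float:
    """Summed frequency of a codon group."""
    return float(freq.reindex(sorted(codons)).fillna(0.0).sum())


def codon_usage_table(
    transcripts: list[TranscriptModel],
    groups: Mapping[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Per-transcript usage: one column per observed codon plus group sums."""
    if groups is None:
        groups = DEFAULT_GROUPS
    rows = {t.transcript_id: codon_frequencies(t) for t in transcripts}
    table = pd.DataFrame(rows).T.fillna(0.0)
    table = table[sorted(table.columns)]
    table.index.name = "transcript_id"
    for name in groups:
        table[name] = sum(
            (table[c] for c in sorted(groups[name]) if c in table.columns),
            start=pd.Series(0.0, index=table.index),
        )
    return table


def usage_te_correlation(
    usage: pd.DataFrame,
    records: pd.DataFrame,
    group: str = "NAA",
    method: str = "rank",
) -> tuple[float | None, float | None, int]:
    """Correlation of a codon-group frequency with TE_FClog2 across genes.

    Returns ``(coefficient, pvalue, n)``; Spearman rank correlation by
    default, Pearson with ``method="linear"``.  Degenerate input (constant
    frequency or TE values) yields ``(None, None, n)`` with a warning.
    """
    common = usage.index.intersection(records.index)
    n = len(common)
    if n < 3:
        raise ValueError(f"need at least 3 genes in common, got {n}")
    x = usage.loc[common, group].to_numpy(float)
    y = records.loc[common, "TE_FClog2"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            f"correlation undefined: constant {'usage' if np.ptp(x) == 0 else 'TE'} values",
            stacklevel=2,
        )
        return None, None, n
    if method == "rank":
        r = stats.spearmanr(x, y)
    elif method == "linear":
        r = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r.statistic), float(r.pvalue), n
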