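"""Translational-efficiency statistics from RNA-seq and Ribo-seq counts.

Given gene-level count matrices for the two assays, this module computes
median-of-ratios size factors, normalized counts, log2 fold changes of
mRNA abundance (mRNA_FClog2) and ribosome occupancy (ribo_FClog2), the
translational efficiency TE = ribosome occupancy per transcript (Ribo-seq
counts divided by RNA-seq counts), its log2 fold change between conditions
(TE_FClog2), and a per-gene significance test with Benjamini-Hochberg FDR
control.

The significance test is a pooled permutation test on the replicate-level
log2 TE contrast, standardized by a trend-shrunk pooled variance and
completed by a normal tail where the permutation resolution is exhausted.
With two replicates per condition the genewise variance has only two
degrees of freedom and — crucially — is built from the same within-pair
differences as the permuted statistic, so a genewise denominator would be
correlated with the permutation numerator and make the pooled null
anti-conservative, thinning the tails of the pooled null relative to the
observed scores.  The default denominator is therefore the trended
variance alone — the mean pooled variance among genes of similar mRNA
abundance — which is essentially independent of any single gene's
replicate noise; a finite ``prior_df`` re-admits the genewise estimate at
weight ``df / (df + prior_df)`` for designs with more replicates.
Pooling the permutation null across genes gives usable resolution despite
the tiny per-gene design.

The user-facing surface is the :class:`TranslationalEfficiency` model:

    model = TranslationalEfficiency(rna, ribo, labels)
    res = model.fit(seed=1)
    print(res.summary())
    res.ma_table()
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style).

    For each sample the factor is the median over genes of
    ``count / geometric-mean-across-samples``, using only genes with
    strictly positive counts in every sample.
    """
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; size factors are "
            "undefined (consider adding a pseudocount to the matrix)"
        )
    logc = np.log(counts.loc[positive].to_numpy(float))
    log_geomean = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _condition_samples(labels: Mapping[str, str], wildtype: str, mutant: str):
    wt = sorted(s for s, c in labels.items() if c == wildtype)
    mut = sorted(s for s, c in labels.items() if c == mutant)
    if not wt or not mut:
        raise ValueError(
            f"labels must assign samples to both {wildtype!r} and {mutant!r}"
        )
    return wt, mut


def fold_changes(
    rna: pd.DataFrame,
    ribo: pd.DataFrame,
    labels: Mapping[str, str],
    pseudocount: float = 1.0,
    wildtype: str = "wt",
    mutant: str = "mut",
) -> pd.DataFrame:
    """Per-gene expression records: normalized counts, fold changes, TE.

    ``labels`` maps each sample (column name, shared by both matrices) to
    its condition.  Size factors are computed separately per assay.  All
    log2 fold changes use ``(mean_mut + pseudocount) / (mean_wt +
    pseudocount)``; TE per condition is ``(ribo mean + pseudocount) /
    (rna mean + pseudocount)``.  ``mRNA_NormClog2`` is the log2 of the
    wild-type mean normalized mRNA count (plus pseudocount).

    Genes present in only one assay are dropped.  The returned frame keeps
    raw and normalized per-sample columns (``rna:<s>``, ``rna_norm:<s>``,
    ...) alongside the derived statistics, and records the label map in
    ``.attrs``.
    """
    samples = list(rna.columns)
    if list(ribo.columns) != samples:
        raise ValueError("rna and ribo matrices must share sample columns")
    missing = set(labels) ^ set(samples)
    if missing:
        raise ValueError(f"labels and sample columns disagree on {sorted(missing)}")
    genes = rna.index.intersection(ribo.index)
    rna = rna.loc[genes]
    ribo = ribo.loc[genes]

    sf_rna = size_factors(rna)
    sf_ribo = size_factors(ribo)
    rna_norm = rna / sf_rna
    ribo_norm = ribo / sf_ribo

    wt, mut = _condition_samples(labels, wildtype, mutant)
    pc = pseudocount
    rna_wt, rna_mut = rna_norm[wt].mean(axis=1), rna_norm[mut].mean(axis=1)
    ribo_wt, ribo_mut = ribo_norm[wt].mean(axis=1), ribo_norm[mut].mean(axis=1)

    te_wt = (ribo_wt + pc) / (rna_wt + pc)
    te_mut = (ribo_mut + pc) / (rna_mut + pc)

    rec = pd.DataFrame(index=genes)
    rec.index.name = "gene_id"
    rec["mRNA_NormClog2"] = np.log2(rna_wt + pc)
    rec["mRNA_FClog2"] = np.log2((rna_mut + pc) / (rna_wt + pc))
    rec["ribo_FClog2"] = np.log2((ribo_mut + pc) / (ribo_wt + pc))
    rec["TE_wt"] = te_wt
    rec["TE_mut"] = te_mut
    rec["TE_FClog2"] = np.log2(te_mut) - np.log2(te_wt)
    for s in samples:
        rec[f"rna:{s}"] = rna[s]
        rec[f"ribo:{s}"] = ribo[s]
        rec[f"rna_norm:{s}"] = rna_norm[s]
        rec[f"ribo_norm:{s}"] = ribo_norm[s]
    rec.attrs["labels"] = dict(labels)
    rec.attrs["pseudocount"] = pc
    rec.attrs["conditions"] = (wildtype, mutant)
    return rec


def te_significance(
    records: pd.DataFrame,
    seed: int = 0,
    n_mc: int = 10_000,
    pseudocount: float | None = None,
    n_bins: int = 20,
    prior_df: float = float("inf"),
    min_mean: float = 1.0,
    tail_min_exceed: int = 10,
) -> pd.DataFrame:
    """Fill per-gene ``pvalue`` (and ``tested``) on a fold_changes table.

    Statistic: the absolute difference of condition means of replicate-level
    log2 TE.  The null is built by pooling, across all tested genes, the
    statistic under every balanced reassignment of condition labels to
    replicate sample pairs (subsampled to ``n_mc`` if larger), standardized
    by the gene's shrunk pooled standard error.  Where fewer than
    ``tail_min_exceed`` null values reach the observed statistic the
    permutation p-value is replaced by the two-sided normal tail of the
    standardized statistic.

    Genes whose mean normalized count is below ``min_mean`` in both assays
    are excluded from testing (``tested = False``, ``pvalue = NaN``): the
    permutation null degenerates at zero counts.
    """
    labels = records.attrs.get("labels")
    if labels is None:
        raise ValueError("records must come from fold_changes (missing labels)")
    wildtype, mutant = records.attrs.get("conditions", ("wt", "mut"))
    pc = records.attrs.get("pseudocount", 1.0) if pseudocount is None else pseudocount
    wt, mut = _condition_samples(labels, wildtype, mutant)
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError("need at least 2 replicates per condition")

    samples = wt + mut
    rna_n = records[[f"rna_norm:{s}" for s in samples]].to_numpy(float)
    ribo_n = records[[f"ribo_norm:{s}" for s in samples]].to_numpy(float)
    y = np.log2(ribo_n + pc) - np.log2(rna_n + pc)  # replicate-level log2 TE

    tested = ~((rna_n.mean(axis=1) < min_mean) & (ribo_n.mean(axis=1) < min_mean))

    nw, nm = len(wt), len(mut)
    iw = np.arange(nw)
    im = np.arange(nw, nw + nm)
    d_obs = y[:, im].mean(axis=1) - y[:, iw].mean(axis=1)

    # pooled within-condition variance of replicate-level log2 TE
    df = (nw - 1) + (nm - 1)
    ss = ((y[:, iw] - y[:, iw].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((y[:, im] - y[:, im].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df

    # trended variance: mean pooled variance in bins of mRNA abundance;
    # with prior_df = inf (default) it replaces the genewise estimate
    # outright, otherwise the two are blended at prior_df pseudo-df
    norm_c = records["mRNA_NormClog2"].to_numpy(float)
    s2_prior = np.full(len(s2), np.nan)
    if tested.any():
        q = pd.qcut(norm_c[tested], min(n_bins, max(1, int(tested.sum()))),
                    duplicates="drop", labels=False)
        bin_mean = pd.Series(s2[tested]).groupby(q).transform("mean").to_numpy()
        s2_prior[tested] = bin_mean
    if np.isinf(prior_df):
        s2_shrunk = np.where(np.isnan(s2_prior), s2, s2_prior)
    else:
        s2_shrunk = np.where(
            np.isnan(s2_prior),
            s2,
            (df * s2 + prior_df * np.nan_to_num(s2_prior)) / (df + prior_df),
        )
    se = np.sqrt(s2_shrunk * (1.0 / nw + 1.0 / nm))
    se = np.maximum(se, 1e-12)
    z_obs = d_obs / se

    # balanced label reassignments of the replicate pairs, excluding the
    # observed assignment and its mirror image
    n = nw + nm
    observed = frozenset(im.tolist())
    assigns = [
        c for c in combinations(range(n), nm)
        if frozenset(c) != observed and frozenset(range(n)) - frozenset(c) != observed
    ]
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    if len(assigns) > n_mc:
        keep = rng.choice(len(assigns), size=n_mc, replace=False)
        assigns = [assigns[i] for i in sorted(keep)]
    null_z = []
    all_idx = np.arange(n)
    for c in assigns:
        pm = np.array(c)
        pw = np.setdiff1d(all_idx, pm)
        d_p = y[:, pm].mean(axis=1) - y[:, pw].mean(axis=1)
        null_z.append(np.abs(d_p[tested] / se[tested]))
    null_pool = np.sort(np.concatenate(null_z)) if null_z else np.array([])

    pvalue = np.full(len(records), np.nan)
    if len(null_pool):
        abs_z = np.abs(z_obs[tested])
        n_ge = len(null_pool) - np.searchsorted(null_pool, abs_z, side="left")
        p_perm = (1.0 + n_ge) / (1.0 + len(null_pool))
        p_tail = 2.0 * stats.norm.sf(abs_z)
        p = np.where(n_ge >= tail_min_exceed, p_perm, np.minimum(p_perm, p_tail))
        pvalue[tested] = np.clip(p, 0.0, 1.0)
    out = records.copy()
    out["tested"] = tested
    out["pvalue"] = pvalue
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def ma_table(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Plot-ready MA-style table: TE_FClog2 against mRNA abundance.

    One row per gene with ``mRNA_NormClog2``, ``TE_FClog2`` and the
    significance flag (``padj < alpha``); stably sorted by abundance then
    gene id.
    """
    if "padj" in records.columns:
        significant = records["padj"] < alpha
    else:
        significant = pd.Series(False, index=records.index)
    out = pd.DataFrame(
        {
            "gene_id": records.index,
            "mRNA_NormClog2": records["mRNA_NormClog2"].to_numpy(),
            "TE_FClog2": records["TE_FClog2"].to_numpy(),
            "significant": significant.fillna(False).to_numpy(),
        }
    )
    return out.sort_values(
        ["mRNA_NormClog2", "gene_id"], kind="mergesort", ignore_index=True
    )


class TranslationalEfficiency:
    """Model of differential translational efficiency between two conditions.

    Parameters
    ----------
    rna, ribo : DataFrame
        Gene x sample count matrices (same sample columns, gene ids as index).
    labels : mapping sample → condition
    wildtype, mutant : str
        Condition labels; fold changes are mutant relative to wild type.
    """

    def __init__(
        self,
        rna: pd.DataFrame,
        ribo: pd.DataFrame,
        labels: Mapping[str, str],
        wildtype: str = "wt",
        mutant: str = "mut",
    ):
        self.rna = rna
        self.ribo = ribo
        self.labels = dict(labels)
        self.wildtype = wildtype
        self.mutant = mutant

    @classmethod
    def from_tsv(cls, rna_path, ribo_path, **kwargs) -> "TranslationalEfficiency":
        """Build from two TSV count matrices whose column names encode
        condition and replicate as ``<condition>_<replicate>``."""
        rna = pd.read_csv(rna_path, sep="\t", index_col=0)
        ribo = pd.read_csv(ribo_path, sep="\t", index_col=0)
        labels = {s: s.rsplit("_", 1)[0] for s in rna.columns}
        return cls(rna, ribo, labels, **kwargs)

    def fit(
        self,
        pseudocount: float = 1.0,
        alpha: float = 0.05,
        seed: int = 0,
        **test_kwargs,
    ) -> "TEResults":
        rec = fold_changes(
            self.rna, self.ribo, self.labels, pseudocount, self.wildtype, self.mutant
        )
        rec = te_significance(rec, seed=seed, **test_kwargs)
        padj = np.full(len(rec), np.nan)
        mask = rec["tested"].to_numpy()
        if mask.any():
            padj[mask] = bh_adjust(rec.loc[mask, "pvalue"].to_numpy())
        rec["padj"] = padj
        rec["significant"] = pd.Series(padj, index=rec.index) < alpha
        return TEResults(self, rec, alpha)


class TEResults:
    """Fitted translational-efficiency results."""

    def __init__(self, model: TranslationalEfficiency, records: pd.DataFrame, alpha: float):
        self.model = model
        self.records = records
        self.alpha = alpha

    @property
    def n_significant(self) -> int:
        return int(self.records["significant"].sum())

    def ma_table(self) -> pd.DataFrame:
        return ma_table(self.records, self.alpha)

    def summary(self) -> str:
        r = self.records
        tested = r["tested"]
        lines = [
            "Translational efficiency: "
            f"{self.model.mutant} vs {self.model.wildtype}",
            f"genes: {len(r)}   tested: {int(tested.sum())}   "
            f"significant (padj < {self.alpha:g}): {self.n_significant}",
            f"TE_FClog2 median: {r['TE_FClog2'].median():+.3f}   "
            f"range: [{r['TE_FClog2'].min():+.2f}, {r['TE_FClog2'].max():+.2f}]",
            f"ribo_FClog2 range: [{r['ribo_FClog2'].min():+.2f}, "
            f"{r['ribo_FClog2'].max():+.2f}]",
        ]
        if self.n_significant:
            up = int((r["significant"] & (r["TE_FClog2"] > 0)).sum())
            lines.append(
                f"significant with TE_FClog2 > 0: {up}/{self.n_significant}"
            )
        return "\n".join(lines)
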