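# Methods

## Overview

`ribopause` implements a codon-resolved analysis of ribosome occupancy for
organisms in which slow decoding of specific codons is suspected — the
motivating case being an *Arabidopsis* mutant lacking both wobble-U34
modifications (mcm⁵ and s²) of tRNA-Lys(UUU), tRNA-Glu(UUC) and
tRNA-Gln(UUG), whose cognate codons are AAA, GAA and CAA. The package has
two measurement arms and a synthetic-data arm that makes both verifiable:

1. **Footprint arm** — place 28/29-nt ribosome-protected fragments on
   transcripts, assign P sites, check 3-nt periodicity, count occupancy by
   the codon at each ribosome site, and difference two conditions.
2. **Expression arm** — gene-level translational-efficiency (TE)
   statistics from RNA-seq and Ribo-seq count matrices, with a calibrated
   significance test and BH FDR control, plus the codon-usage/TE
   correlation.
3. **Simulator** — generates transcriptomes, footprint libraries and count
   matrices with known ground truth (exact P sites, dwell multipliers,
   true TE ratios) so that every stage is tested by parameter recovery.

## Footprint placement and P-site assignment

Reads are accepted only if they are 28 or 29 nt long and occur as an exact
substring at exactly one (transcript, position) across the whole
transcript set. Multi-mapping reads are discarded and counted: single-base
codon attribution requires unique placement. Reverse-complement matching
is not attempted, since footprints derive from the mRNA sense strand. The
P site is a fixed offset from the 5′ end: 12 nt for 28-nt reads, 13 nt for
29-nt reads; these offsets are constants of the protocol being modeled,
not learned from metagene profiles.

Periodicity QC computes the frame fractions (f0, f1, f2) of P-site counts
over CDS positions from the start codon up to (excluding) the stop codon.
A transcript passes when f0 ≥ 0.6 (configurable). The threshold is a QC
convention: noiseless data give f0 = 1.0, and the simulator's ±1-nt
5′-end jitter (default rate 0.1) degrades f0 to ≈ 0.9, so 0.6 separates
correctly offset libraries from scrambled ones without being brittle.

## Codon-site occupancy and the pause differential

For each accepted footprint and each analyzed site — by default −6 nt, E
(−3), P (0), A (+3) and +6 nt relative to the P-site codon — the codon at
`p_site + offset` is read off the transcript. Exclusion is per site, not
per footprint: a footprint whose P site sits on the start codon still
counts at P and A even though E and −6 fall outside the CDS. Footprints
with out-of-frame P sites (jitter casualties) address no codon and
contribute nothing. Stop codons are counted where addressed (possible at
A/+6 near the CDS end) but are not members of any default group.

Counts are normalized per million library reads, codon groups are summed
(NAA = {AAA, GAA, CAA}, NAG, and the control groups NGA, NGG), and the
differential is mutant − wild type per (group, site). Replicates are
normalized per library and then summed by default (the alternative order
is available). Per-entry Poisson standard errors,
`sqrt(raw_mut·s_mut² + raw_wt·s_wt²)` with `s = 1e6/library_total`, are
attached so differentials can be judged against counting noise.

### Compositional closure

A per-million-normalized library is a closed composition: the normalized
counts across all positions sum to a constant. A genuine k-fold dwell
increase on a codon class occupying share *q* of the library therefore
appears as an enrichment of that class by `k/(1+(k−1)q)` and a *dilution
of every other class* by `1/(1+(k−1)q)`. With the default 3× dwell on NAA
(q ≈ 0.05 under uniform codon usage) the A-site cells of unboosted groups
sit ≈ 9% below zero — several Poisson SE at 2×10⁵ reads — while non-A-site
cells stay at zero because the dwell reweighting is independent of the
codons at the other sites. This is not an artifact of the simulator: any
real library normalized to its own total behaves the same way. The
package therefore reports control groups on their **net** differential
(summed over sites), which stays within Monte-Carlo noise of zero, and
documents the per-cell dilution rather than pretending it away; the unit
tests assert the A-site control cells match the predicted dilution
quantitatively.

## Translational-efficiency statistics

Size factors are median-of-ratios per assay (RNA and Ribo libraries have
different compositions). With pseudocount 1 (configurable; zero-count
genes are otherwise undefined):

* `mRNA_FClog2 = log2((rna_mut+1)/(rna_wt+1))` on condition means of
  normalized counts; `ribo_FClog2` likewise;
* `TE_cond = (ribo_cond+1)/(rna_cond+1)`;
  `TE_FClog2 = log2(TE_mut) − log2(TE_wt)`, which equals
  `ribo_FClog2 − mRNA_FClog2` exactly when the pseudocount is zero;
* `mRNA_NormClog2 = log2(rna_wt + 1)`, the abscissa of the MA-style plot.

### Significance test

The test statistic is the difference of condition means of replicate-level
log2 TE. The null distribution is built by pooling, across all tested
genes, the statistic under every balanced reassignment of condition labels
to replicate sample pairs, standardized per gene. With two replicates per
condition there are only four informative reassignments per gene, so the
pool over ~2000 genes is what provides resolution; below the pool's
resolution (fewer than 10 null exceedances) the p-value falls back to the
two-sided normal tail of the standardized statistic.

The standardization deliberately uses a **trended** variance — the mean
pooled within-condition variance among genes of similar mRNA abundance
(20 quantile bins) — rather than the genewise estimate. With a 2+2 design
the genewise variance is built from the same within-pair differences that
form the permuted statistic, so a genewise denominator correlates the
null's numerator and denominator and thins its tails, which measurably
inflates the false-positive rate (~2× in the tail even at 4% genewise
weight). With the trended denominator the test is calibrated at 0.05,
0.01, 0.005 and 0.001 on both ideal normal data and the NB generator. A
finite `prior_df` re-admits the genewise component for designs with more
replicates.

Genes with mean normalized count below 1 in both assays are excluded from
testing (reported untested): the permutation null degenerates at zero
counts. BH adjustment (statsmodels step-up) is applied to tested genes
only; significance is `padj < 0.05`.

### Codon-usage correlation

Per-CDS codon frequencies include the start codon and exclude the stop
(decoded by release factors, not tRNAs). The group frequency (e.g. summed
NAA fraction) is correlated with TE_FClog2 across genes by Spearman rank
correlation by default (no distributional claim is warranted); Pearson is
available. Constant inputs return nil with a warning.

## The simulator

* **Transcripts**: ATG + sense codons drawn from configurable weights
  (uniform by default) + one stop, flanked by 30-nt random UTRs so that
  footprints near CDS ends fit. CDS lengths are uniform over 300–1500 nt.
* **Abundances**: log-normal (σ = 1) across transcripts, shared by
  conditions and assays — a realistic dynamic range with no extra
  machinery.
* **Footprints**: density at in-frame P-site position p is proportional to
  `abundance × dwell[A-site codon]`; libraries are multinomial draws of
  2×10⁵ reads. Lengths are 28/29 with equal probability; the 5′ end is
  shifted ±1 nt with probability 0.1 (equal split), the minimal
  perturbation that degrades periodicity without destroying it. Reads
  whose window would leave the transcript are excluded, never clipped,
  matching the exact-match analysis. Qualities are constant 'I' and never
  used.
* **Counts**: RNA ~ NB(mean 100 × relative abundance, dispersion 0.05)
  identically in all samples (transcription unchanged); Ribo means are
  multiplied by the gene's true TE ratio in the mutant — 10% of genes at
  ratio 4 by default. Dispersion 0 degenerates to rounded means.
* **Truth**: every read's exact P site; every gene's TE ratio.

What the simulator does **not** emulate: rRNA/tRNA contamination, adapter
read-through, sequencing error, alignment ambiguity beyond genuine k-mer
repeats, UTR/uORF ribosome occupancy, position-dependent coverage biases,
or correlated biological replicates. Passing recovery tests therefore
demonstrates the correctness of the computations under the stated
generative model, not robustness to every artifact of real libraries.

## Numerical and design choices

* Coordinates are 0-based half-open throughout; the CDS table dialect is
  `(transcript_id, cds_start, cds_end)` TSV with a header.
* Ambiguity characters are rejected in strict mode and masked from codon
  counting otherwise (an exact-match read cannot span them anyway).
* Five sites are analyzed by default; the site list is configuration so
  further positions (e.g. +9) can be added without code changes.
* Seeds: every stochastic routine takes the run seed; condition and
  replicate enter the stream as distinct integers so libraries are
  independent draws while sharing the transcriptome and abundances.
* Degenerate inputs: empty profiles give all-zero frame fractions and a
  failed QC flag; an all-identical count table gives statistic 0 and
  p-value 1; constant usage vectors give a nil correlation with a warning.
* Problem sizes used in the test suite (200 transcripts × 2×10⁵ reads for
  pause recovery, 2000 genes × 10 seeds for FDR calibration) were chosen
  so Monte-Carlo error is well below the assessed effects while a full run
  completes in well under a minute per scenario.

## Known limitations

* The exact-match placement cannot use reads containing any sequencing
  error; it models a 100%-identity extraction, not a general aligner.
* The TE test is designed for the two-condition, few-replicate case; it
  does not model batch covariates or interaction designs, and it is not a
  reimplementation of a negative-binomial GLM framework.
* Per-million occupancy differentials inherit compositional closure (see
  above); cross-condition comparisons of absolute pause magnitude should
  use the reported ratios with that in mind.
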