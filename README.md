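# ribopause

Codon-resolved ribosome-occupancy and translational-efficiency analysis
for Ribo-seq / RNA-seq experiments, with a fully ground-truthed synthetic
data generator.

## The problem

When a tRNA decodes its codon slowly — for example when the wobble-U34
modifications (mcm⁵ and s²) of tRNA-Lys(UUU), tRNA-Glu(UUC) and
tRNA-Gln(UUG) are missing — ribosomes dwell longer with that codon in the
aminoacyl (A) site. Ribosome profiling makes this visible: 28–29-nt
ribosome-protected footprints pile up at paused positions. `ribopause`
provides the analysis chain that turns raw footprints into that evidence,
for anyone studying codon-specific elongation defects:

* **P-site assignment** — footprints are placed on transcripts by exact,
  unique matching; the P site is the fixed 12-nt (28-nt reads) or 13-nt
  (29-nt reads) offset from the 5′ end, validated by 3-nt periodicity QC
  over the CDS.
* **Codon-site occupancy** — per-million-normalized footprint counts by
  the codon occupying the E, P, A, −6 and +6 positions, summed over codon
  groups (cognate NAA = {AAA, GAA, CAA}, synonymous NAG, and control NGA /
  NGG), and differenced between mutant and wild type. A slow A-site codon
  shows up as a dominant positive (NAA, A) differential.
* **Translational efficiency (TE)** — per gene,
  `TE = Ribo-seq / RNA-seq` on median-of-ratios-normalized counts;
  `TE_FClog2 = log2 TE_mut − log2 TE_wt`, tested with a calibrated
  pooled-permutation test and Benjamini–Hochberg FDR control, plus the
  codon-usage vs TE_FClog2 correlation.
* **Simulator** — transcriptomes, footprint FASTQs and NB count matrices
  with known dwell multipliers, exact per-read P sites and true TE
  ratios, so every stage is verified by parameter recovery.

## Worked example

Simulate the default experiment — 200 transcripts, two conditions at
2×10⁵ footprints each, with a 3× A-site dwell on AAA/GAA/CAA in the
mutant — and recover the pause signal:

```python
import ribopause as rp
from ribopause.occupancy import CodonOccupancy

cfg = rp.SimConfig(seed=1)
ts = rp.generate_transcriptome(cfg)
matcher = rp.FootprintMatcher(ts)
alns = {c: matcher.match(rp.simulate_footprints(ts, cfg, c)[0])[0]
        for c in ("wt", "mut")}
print(CodonOccupancy(ts, alns).fit().summary("mut", "wt"))
```

```
Codon-site occupancy differential: mut - wt
libraries: mut=200000, wt=200000
group   site      diff (per 1e6)        SE
NAA     minus6            -835.0     662.7
NAA     E                 1830.0     667.2
NAA     P                  485.0     669.2
NAA     A                78415.0     911.3
NAA     plus6             -635.0     662.0
NAG     A                -4035.0     652.2
NGA     A                -4140.0     613.1
NGG     A                -4280.0     627.5
...
```

The planted pause dominates: (NAA, A) is +78 415 footprints per million —
two orders of magnitude above counting noise — while every other cell of
the cognate group sits within a few SE of zero. The small negative A-site
entries of the other groups are the compositional dilution that
per-million normalization forces when one codon class genuinely gains
occupancy (see `docs/methods.md`).

The expression arm on the same configuration (10% of genes simulated with
a 4-fold TE shift):

```python
rna, ribo, truth = rp.simulate_counts(ts, cfg)
labels = {c: c.rsplit("_", 1)[0] for c in rna.columns}
res = rp.TranslationalEfficiency(rna, ribo, labels).fit(seed=1)
print(res.summary())
```

```
Translational efficiency: mut vs wt
genes: 200   tested: 200   significant (padj < 0.05): 19
TE_FClog2 median: +0.053   range: [-1.40, +2.91]
ribo_FClog2 range: [-0.91, +2.63]
significant with TE_FClog2 > 0: 18/19
```

Of 200 genes, 20 carry a true TE shift; 19 genes are called at
padj < 0.05, 18 of them with TE_FClog2 > 0 — i.e. increased ribosome
occupancy, the signature expected when pausing raises footprint density.
`res.records` holds the full per-gene table (fold changes, TE, p-values)
and `res.ma_table()` the plot-ready TE_FClog2-vs-abundance table.

The same pipeline runs from the shell:

```sh
ribopause simulate --seed 1 --out sim/
ribopause all --seed 1 --data sim/ --out results/
```

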