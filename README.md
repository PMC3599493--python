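# tdmrscan

**In-silico methylation-sensitive restriction profiling and T-DMR discovery.**

`tdmrscan` is a tested, reusable re-implementation of a classic
promoter-tiling DNA-methylation screen: genome-wide profiling of
tissue-dependent and differentially methylated regions (T-DMRs) with a
methylation-sensitive restriction enzyme, as used to compare mouse neural
progenitor populations from different developmental stages. Because the
original array data cannot be reanalyzed at desk scale, every stage of the
pipeline is driven by a first-class synthetic-data generator with a known
ground truth, so the whole analysis — from restriction digestion to called
regions — is verifiable end to end.

It is aimed at epigenomics methodologists and tool developers who need a
fully controlled model of restriction-based methylation profiling: the
assay readout, the scoring statistic, the region caller and the validation
assays are all explicit, parameterized and unit-tested against independent
oracles.

## The assay and the statistic

The profiled signal comes from a tag-amplification protocol:

1. genomic DNA is digested with **HpyCH4IV** (recognition site `ACGT`),
   which cuts only when the site's internal CpG is **unmethylated**;
2. cut ends receive one adaptor; after fill-in, **TaqI** (`TCGA`,
   methylation-insensitive here) cuts and its ends receive a second
   adaptor;
3. only fragments carrying one adaptor of each kind amplify by PCR
   (same-adaptor fragments are suppressed), and the product is hybridized
   to promoter tiling arrays covering −6 kb … +2.5 kb around each TSS.

Probe intensity therefore reports **unmethylated** HpyCH4IV sites. Per
replicate, log2 intensities are robustly standardized,

  z = (log₂ I − median) / (1.4826 · MAD),

and scored with a MAT-style windowed trimmed mean: for each probe position,
take all probes within ±250 bp, drop a fraction from each tail of the
sorted z-values, and set

  MATscore = trimmed-mean(z) · √n′,

where n′ is the number of retained probes. The differential statistic is
the between-condition difference, ΔMATscore = MATscore(test) −
MATscore(control); Δ > 0 means hypomethylated in the test sample. T-DMRs
are maximal same-sign runs of probe positions with |Δ| ≥ threshold
(default 2.0), with ≥ 4 probes per run and gaps ≤ 300 bp. Called regions
are assigned to genes by promoter-window midpoint, characterized by
TSS-distance histograms (250-bp bins) and CpG-island association
(Gardiner-Garden–Frommer criteria: ≥200 bp, GC ≥ 0.5, CpG obs/exp ≥ 0.6),
clustered by K-means under Pearson correlation distance, and screened for
the 5′→3′ hypomethylation position shift seen in adult brain. In-silico
bisulfite sequencing and COBRA (restriction digestion of bisulfite PCR
products with densitometric quantification) provide orthogonal per-region
validation.

## Worked example

The statsmodels-style model surface wraps scoring and calling; the demo
study (200 promoter-tiled genes, 60 implanted T-DMRs with a methylation
difference of 0.6, duplicate arrays, log-normal intensity noise σ = 0.3)
runs in a few seconds:

```python
from tdmrscan import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1))
print(result.report)
```

```
Differential methylation summary
================================
test sample:        B
control sample:     A
probes scored:      48600
|Delta| threshold:  2.0
min probes per run: 4   max gap: 300 bp
T-DMRs called:      60
  hypo in test:     30  (genes: 30)
  hypo in control:  30  (genes: 30)
mean |Delta| of calls: 3.897 (range -4.488 .. 4.251)

CGI-gene bias
  hypo_in_test:    0.433
  hypo_in_control: 0.567
  Fisher two-sided p: 0.439

Recovery vs implanted truth
  implanted: 60   called: 60   hits: 60
  sensitivity: 1.000
  precision:   1.000
  direction fidelity: 1.000

TSS-distance mass (250-bp bins)
  within ±2.5 kb: 0.500
  −6 kb .. −2 kb: 0.500

Top enriched terms
  implanted_program: k=60/60, p=1.42e-52, q=8.52e-52
  random_term_0: k=10/20, p=0.0394, q=0.118
```

Reading the numbers: all 60 implanted regions are recovered (sensitivity,
precision and direction fidelity 1.0 at this seed), each call overlapping
its implant with Jaccard ≥ 0.5. Half of the recovered T-DMRs were
implanted proximal to TSSs for one direction and 6–2 kb upstream for the
other, which is exactly the 0.5/0.5 split of histogram mass the report
shows, and the one annotation term loaded with implant genes dominates the
enrichment table. Lower-level use — building a
`DifferentialMethylation` model from your own intensity matrices and
calling `fit()` — returns a results object with the called regions
(`results.tdmrs`), the ΔMATscore track, per-direction counts and
`summary()`.

A command-line interface mirrors the stages:

```bash
tdmrscan run --seed 1                 # full pipeline, report to stdout
tdmrscan simulate --seed 1 --out sim/ # genome, methylomes, truth, intensities
tdmrscan call --test sim/intensity_B.tsv --control sim/intensity_A.tsv \
              --genes sim/genes.bed --out tdmrs.tsv
tdmrscan cluster --matrix profiles.tsv --k 3 --out labels.tsv
tdmrscan enrich --query genes.txt --annotation ann.tsv --universe all.txt --out enr.tsv
tdmrscan cobra --fasta sim/genome.fa --contig chr1 --start 500 --end 800 \
               --methylome meth.tsv --out bands.tsv
```

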