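# Methods

This note documents the models behind `tdmrscan`: what each stage assumes,
which parameters matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was genuinely open.

## 1. Synthetic genome and gene models

One contig carries `n_genes` non-overlapping promoter windows spanning
6 kb upstream to 2.5 kb downstream of each TSS (8.5 kb per gene), separated
by 0.5–1.5 kb spacers, with strands drawn at random. Promoter windows are
forced non-overlapping so that every called region maps to exactly one
gene; real genomes violate this, and the midpoint-assignment tie-break
(nearest TSS, then lexicographic) exists for that case.

Background sequence is drawn iid at GC 0.42, then each CpG's G is mutated
to A/T with probability 0.8, leaving CpG observed/expected ≈ 0.2 — the
depletion level of the mouse genome. This matters quantitatively: it sets
the density of both HpyCH4IV (`ACGT`) and TaqI (`TCGA`) sites to ≈ 0.74
per kb, the site sparsity the real assay contends with. CpG-island blocks
(1 kb centred on the TSS; GC 0.6, obs/exp 0.8) are embedded at a
configurable fraction of promoters (default 0.5, matching the rule of
thumb that about half of promoters are CGI-associated) and reliably
pass/fail the Gardiner-Garden–Frommer detector by construction.

**Assessability guarantee.** A promoter sub-region with no usable
restriction-site layout cannot be read by the assay at all — the real
screen simply cannot interrogate such genes. The generator therefore
resamples each promoter sub-region (proximal −2 kb…+0.5 kb, distal
−6…−2 kb, downstream +0.5…+2.5 kb) until it contains a *readable segment*:
a pair of adjacent TaqI cuts 0.6–1.8 kb apart with exactly one HpyCH4IV
cut between them and both halves of amplifiable size (40–1000 bp). The
synthetic cohort is thus a model of the *assessable* fraction of a genome,
not of an unbiased genomic sample; conclusions about completely
site-depleted promoters are out of reach of the assay and of this
simulator alike.

## 2. Methylomes

Methylation is a per-CpG population **fraction** in [0, 1], not a binary
state: partial methylation is the rule in mixed cell populations, and the
restriction readout responds to exactly this fraction. Baseline levels are
drawn once and shared by all samples — Beta(1, 9) inside CGI blocks (CGIs
are normally unmethylated), Beta(8, 2) elsewhere — so any between-sample
difference outside implants is exactly zero and the null of the
differential statistic is clean. The Beta parameters are conventions
(exposed in `baseline_params`), chosen to give strongly bimodal, realistic
baselines; no published value constrains them.

Implants overwrite one readable segment per request: the hypomethylated
sample(s) get level 0.1, all others 0.1 + Δ (default Δ = 0.6; clipped at
1 with a warning). The implanted difference is therefore recovered exactly
from profile means, and the implant interval equals the assay-visible
footprint: because no restriction fragment can cross a TaqI cut, the
differential signal of a TaqI-bounded implant cannot leak outside it.

**Why segment layout is tiered.** The readout contrast of a segment
depends sharply on its internal HpyCH4IV layout. With one internal cut
(T·H·T), point coverage in the hypomethylated sample is the cut
probability (≈ 0.9) while the hypermethylated sample retains only ≈ 0.3 —
a uniform, strong contrast. With several internal sites, skip-fragments
over uncut sites restore coverage in the hypermethylated sample, and
adjacent HpyCH4IV–HpyCH4IV stretches are adaptor-suppressed *only* in the
hypomethylated sample, so interior signal weakens and can locally invert.
Implant placement prefers T·H·T segments, then two-site segments whose
middle stretch is short enough (≤ 150 bp) for the windowed score to
bridge, then any segment with readable fraction ≥ 0.7.

## 3. Assay simulation

Digestion has two modes. `sampled` draws one Bernoulli cut per
methylation-sensitive site (probability 1 − fraction) and yields fragments
that partition the contig. `deterministic_expected` enumerates every
possible fragment with its expected copy number, P(cut left)·P(cut
right)·Π P(uncut interior) — the infinite-molecule limit appropriate for a
microgram-scale digest, and the default because it makes validation
noise-free below the array-noise stage. Selection keeps fragments with
exactly one HpyCH4IV and one TaqI end and length 40–1000 bp; the bounds
are a modeling choice standing in for PCR extension-time and column
-cleanup limits, which no protocol figure pins down precisely.
Hemimethylation is ignored: a site is cut according to its top-strand CpG
fraction only.

Probe readout: 25-mer probes tiled every 35 bp across promoter windows;
intensity = (b + g · Σ overlapping fragment weights) · exp(N(0, σ²)) per
replicate, defaults b = 10, g = 50, σ = 0.3, two replicates. b and g are
instrument constants with no biological meaning; b = 10 was chosen so the
null spread of log2 intensities (the MAD used for standardization) is
dominated by biological coverage variation rather than by the mass of
zero-coverage probes, which a very low optical floor would spread over
many octaves. σ = 0 gives a fully deterministic readout.

## 4. Scoring and calling

Standardization is median/MAD per replicate (1.4826·MAD estimates σ under
normality); mean/sd would be dragged by the heavy right tail of
fragment-covered probes. A zero-MAD column (constant intensities) is a
degenerate input and raises.

The windowed score uses bandwidth 500 bp, trim fraction 0.1 and a minimum
of 4 probes per window; the score is trimmed-mean · √n′, so it grows with
probe support like a t-statistic. Replicates are scored separately,
averaged positionwise, and differenced between conditions on shared
positions. None of these four constants is published for the original
screen; they are package defaults exposed in `PipelineConfig` and chosen
to suit 35-bp tiling (≈ 14 probes per window).

Calling takes maximal same-sign runs of |Δ| ≥ 2.0 with ≥ 4 qualifying
probes and inter-probe gaps ≤ 300 bp; an opposite-sign qualifying probe
always terminates a run. The reported interval spans first to last
qualifying probe plus one probe length. The threshold is the analysis'
main free parameter (the original screen's cutoff is unpublished);
raising it monotonically removes calls.

## 5. Characterization

* **TSS histograms**: fixed 250-bp bins over [−6000, +2500), proportions
  normalized to 1; distances are strand-oriented midpoint offsets.
* **CGI detection**: union of all 200-bp windows with GC ≥ 0.5 and CpG
  obs/exp = (#CG·L)/(#C·#G) ≥ 0.6, merged; bounds are exactly the union
  of passing windows (no outward trimming), which makes the detector
  invariant to non-CpG flanking sequence.
* **Clustering**: K-means under Pearson correlation distance, implemented
  by centering rows and scaling by max(‖row‖, 1.0) followed by Euclidean
  Lloyd iterations (unit-norm rows make squared Euclidean distance
  monotone in 1 − r). The norm floor handles the degeneracy of flat
  profiles — Pearson r is undefined at zero profile variance, and raw
  normalization would inflate pure replicate noise onto the unit sphere —
  by shrinking weak profiles toward the origin, where they form their own
  cluster. The floor of 1.0 is calibrated to the calling threshold
  (profile variation below half the |Δ| cutoff is treated as flat) and is
  exposed as `flat_norm`. Best of 20 restarts by within-cluster SS;
  deterministic given a seed.
* **Position shift**: a gene is flagged when a progenitor-stage
  hypomethylated region upstream of the TSS is *not* hypomethylated in
  the adult comparison (mean adult Δ over the same interval below the
  calling threshold) *and* the adult sample carries its own
  hypomethylated region downstream. Both conditions are required; genes
  whose upstream hypomethylation persists, or that gain a downstream
  region without losing the upstream one, are not flagged.
* **Enrichment**: one-sided hypergeometric upper tail per term with
  Benjamini–Hochberg correction; the EASE variant (overlap reduced by
  one, p = 1 for overlap ≤ 1) reproduces the conservative DAVID-style
  score. The annotation table is a user input; no live ontology service
  is queried.

## 6. Bisulfite tools

Conversion is modeled on the top strand only (bisulfite PCR primers are
strand-specific): every non-CpG C becomes T, CpG C's survive iff
methylated, and a `non_conversion_rate` lets unmethylated C's escape
conversion to model incomplete chemistry. Clone sequencing draws a binary
state per CpG per molecule from the population fraction and masks calls to
"undetermined" at a configurable rate — a summary of unreadable trace
positions, not a base-caller simulation. COBRA digests each molecule's
retained (methylated) sites completely and weights each electrophoresis
band by molecule count × fragment length (ethidium staining scales with
mass); the methylation percentage is the cut-derived share of total band
intensity, which for a single site is exactly the methylated-molecule
fraction. Consistency across modules is a tested invariant: the expected
assay fragment weight at a site equals 1 − COBRA percent/100 under the
same methylome.

## 7. The demo study and what passing it shows

The shipped demo uses 200 genes, 30 implants per direction (Δ = 0.6),
proximal placement for the hypo-in-test direction and distal (6–2 kb
upstream) for the other, duplicate arrays and σ = 0.3. Recovery is scored
by interval Jaccard ≥ 0.5 against the implant truth. These sizes keep the
full analysis under ~5 s on one CPU while leaving every probe window well
populated; they are the package's reference conditions, not limits of the
implementation.

Passing this simulation demonstrates that the statistic, segmentation,
orientation and positional readout are internally correct and that the
assay model is information-preserving at Δ = 0.6 on assessable segments.
It does **not** demonstrate performance on real arrays: probe-sequence
hybridization bias, copy-number variation, cross-hybridization,
partial-digestion artifacts, hemimethylation and repeat content are all
outside the simulator, and the synthetic cohort is biased to assessable
promoter regions by construction.

## 8. Degenerate inputs and tie-breaks

Empty gene designs, zero-length intervals, non-positive intensities,
zero-MAD replicate columns, k larger than the number of profile rows,
queries outside the enrichment universe, and methylomes missing a site's
CpG all raise immediately with the offending entity named. Overlapping
promoter windows resolve by nearest TSS then lexicographic gene id (and
log the event); equal-distance probes at a window edge are included on
both sides (closed window bounds); trimming uses ⌊trim·n⌋ per tail so
small windows are never over-trimmed. All randomness descends from one
integer seed through named, stage-keyed substreams, so each stage's draws
are independent of every other stage's parameters.
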