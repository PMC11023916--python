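# Methods

## Genome partition

The capture BED is merged and clipped, then resized: targets shorter
than `minOntarget` (100 bp) are extended symmetrically about their
midpoint to exactly that length (odd remainder to the 3′ side; an
extension clipped at a chromosome end is completed on the opposite
side), and targets longer than `maxOntarget` (300 bp) are split into
⌈len/maxOntarget⌉ parts differing by ≤1 bp (remainder bases to the
leftmost parts). Targets that overlap after extension are re-merged
before splitting so the final bins are disjoint. Off-target bins are
the per-chromosome complement of the on-target set padded by
`paddingOfftarget` (300 bp) — capture spillover inflates depth next to
probes — split at `maxOfftarget` (50,000 bp) and discarded below
`minOfftarget` (1 bp). Coordinates are 0-based half-open throughout.
chrY, chrM and alternate/decoy contigs are excluded by default
(configurable via the genome map). GC per bin is (G+C)/(non-N bases);
bins over 50% N keep GC = NaN.

The advised `maxOfftarget` is 2·maxOntarget·(on/off per-base depth
ratio), rounded to 1,000 bp. With the typical ratio of ~80 this gives
~50 kbp; the factor 2 absorbs the larger variability of off-target
coverage. The depth ratio itself follows from read-mapping fractions:
with 47.2% of reads on target, 33.6% nearby and 18.0% elsewhere while
targets+vicinity cover 5.7% of the genome, off-target depth is
18.0/(47.2+33.6)×0.057 ≈ 1/80 of on-target depth.

## Coverage

Per bin and sample we count total aligned bases (mean depth × length):
reads with MAPQ ≥ 50, excluding unmapped, secondary, supplementary,
duplicate and QC-fail records. CIGAR M/=/X/D consume and cover the
reference (a deleted stretch inside a read still witnesses the
fragment), N consumes without covering, I/S add nothing. Overlapping
mate pairs double-count (no mate-overlap correction). A precomputed
coverage TSV can replace BAM input entirely.

## Normalization

Controls are chosen by Pearson correlation on log₂(count+1) over up to
10,000 autosomal on-target probe bins passing the signal/variance
requirements (sampled without replacement from a recorded seed);
log-scaling stops the deepest bins from dominating. Samples with
correlation ≥ `mincor` (0.9) are kept, floored at 15 (top-15 by
correlation if fewer pass; all others in batches below 16) and capped
at 96.

Analysis bins are those containing an annotated exon or at least 1,000
bp long. Each sample's column is divided by its total over analysis
bins and rescaled by the batch-mean total; autosomes and chrX are
scaled independently (no sex inference — the correlation criterion
implicitly matches X dosage). The test/mean-control ratio is regressed
on GC per class and the fitted deviation from the class mean
subtracted (additive rather than divisive correction: stable when
fitted values approach zero; divisive mode available). Each sample's
corrected ratio is then re-centred at its class median: because a
large CNV shifts its carrier's *total* coverage, total-based scaling
would deflate or inflate every other bin of that sample, and the
median is insensitive to that mass shift while the mean is not.
Finally bins with mean raw control coverage < `minsignal` (2,500) or
log₁₀(control-ratio variance) > `maxvar` (−0.2) are dropped. The
`maxvar` threshold is interpreted on the log₁₀ scale — a plain
variance cannot be negative — so variance > 10^−0.2 ≈ 0.63 is removed.

## LOO-PCA denoising

The control ratio matrix (bins × m controls) is centred per bin and
decomposed by SVD; components are orthonormal bin-space directions
ordered by explained variance. Denoising subtracts the projection of a
profile onto the first k components. The basis is fitted on controls
only (leave-one-out): a CNV private to the test sample is absent from
the basis and survives removal, whereas test-included PCA turns a
sizeable CNV into a component of its own and erases it. No variance
scaling is applied before the SVD (ratios are already commensurate);
a scaling mode exists in the code for experimentation.

k is calibrated per sample: 1,000 analysis bins (or half the bins on
small sets, so that untouched bins remain to anchor the ROC) are
selected without replacement, half multiplied by 0.5 and half by 1.5,
and for each candidate k the AUC of per-bin |Z| for recovering the
injected bins is computed. The smallest k within 0.002 of the peak
AUC wins — differences below that are sampling noise of the artificial
set, and small k minimizes signal distortion. Candidate k leaving the
controls fewer than 3 residual degrees of freedom are excluded: their
per-bin SDs would be floor-dominated and meaningless. The default grid
is 0..min(20, m−1).

**Degrees-of-freedom recalibration.** Removing k of the controls'
m−1 sample-space dimensions shrinks their per-bin residual SD by about
√((m−1−k)/(m−1)) even for unstructured noise, while the test sample —
projected off only k directions of a much larger bin space — keeps
essentially all of its own noise. Denoised control deviations are
therefore scaled back by the inverse factor before Z-scores are
formed. The factor is global per k, so rank-based quantities (the
calibration AUC) are unchanged; what it fixes is the absolute Z scale
used by the |Z| ≥ 4 rule and the HMM emissions. Residual heavy tails
remain at small m−1−k because each per-bin SD is itself noisy; the
floor of 0.01 on SDs bounds the worst case.

## Segmentation and calling

Per bin, controls outside mean ± 2 SD are dropped (single pass, at
least 3 retained — the closest to the mean), and Z = (test − μ)/σ with
σ floored at 0.01. The 3-state HMM uses transition probabilities
P(normal→del) = P(normal→dup) = `p_enter` = 5·10⁻⁵,
P(CNV→same) = `p_stay` = 0.5, P(CNV→other CNV) = `p_enter`, rows
normalized; the initial distribution is normal-biased. Emissions are
state-conditional Gaussians on the denoised ratio with means 0.5 /
1.0 / 1.5 and the per-bin trimmed control SD — the emission family is
this implementation's reconstruction, chosen as the simplest model
consistent with ratio data. Decoding is exact Viterbi in log space,
restarted per chromosome. Maximal same-state non-normal runs of ≥2
bins become candidate events; 1-bin runs are deferred to the Z rule
(|Z| ≥ `minZ` = 4, suppressed inside multi-bin events), keeping the two
event classes mutually exclusive.

Ploidy is the integer p ∈ {0..6} whose expected ratio p/E (E = 2 on
autosomes, configurable for chrX) minimizes the event-level |Z| (ties
toward E); the reported ploidy is railed to agree with the event
direction. Event quality is the log-probability contrast (nats)
between the decoded path and a forced all-normal path over the event's
bins, transitions included — threshold-free and comparable across
events. The HQ flag marks calls with (|mean Z| ≥ 5 or ≥ 3 bins),
quality ≥ 10 nats, and a carrier whose best pairwise correlation
reaches `mincor`; these thresholds are this implementation's own
calibration of a high-confidence tier, and the flag never removes a
call from the output.

## Synthetic data

The generator emulates a capture batch: exonic on-target bins
(100–300 bp) alternating with non-exonic off-target bins (1–50 kbp) on
synthetic chromosomes (autosomes + chrX), GC ~ Beta(10, 14) (mean
≈0.42). Expected counts are depth × length × exp(gc_slope·(gc − mean
gc)) × exp(loadings·factors) × cn/2, drawn negative-binomial with
dispersion α = 4·10⁻⁴ (~2% extra CV on deep bins); Poisson when α = 0.
Defaults: 200× on-target per-base depth and an off/on depth ratio of
1/80, which lands off-target bins in the ~2–3× regime. Batch noise has
rank 3 with geometrically decaying strengths (leading per-bin log-SD
0.02, decay 0.4 per factor): real coverage batches show a dominant
first component with a fast-decaying tail, and that spectrum is what
makes one-component removal already effective. CNVs are specified as
(sample, first bin, span, ploidy, fraction); fraction < 1 confines the
event to that fraction of each bin, mimicking partial-exon events.

Not modelled: capture chemistry, fragment-size distributions,
mappability/repeat artifacts, related samples sharing CNVs, sex-mixed
batches. Passing recovery benchmarks on this generator therefore
demonstrates the statistical machinery (normalization, LOO-PCA,
decoding) under realistic depth and noise structure, not robustness to
every artifact of real capture data.

## Benchmarks and problem sizes

The recovery study simulates 20-sample batches of 5,000 bins (3,800
on-target + 1,200 off-target); 3 carrier samples per batch each
receive 3 non-overlapping CNVs of 1–30 callable bins (60% het
deletions, 20% hom deletions, 20% duplications; ~a third of single-bin
het deletions get fraction 0.6–0.9). CNVs are placed on analysis bins
whose expected coverage clears the signal filter with margin — the
in-silico analogue of validating against events in covered territory.
Detection = same-type call overlapping the truth span; ploidy accuracy
is scored among detected events; single-bin recovery is scored among
single-bin truths whose realized |Z| ≥ 6. The test suite runs 50 such
batches; the acceptance script 20. The LOO-vs-PCA benchmark uses
batches of 11 and 97 samples (3,000 bins, leading factor SD 0.05) with
1,000 artificial CNVs, k = 0..10.

## Numerical choices and degenerate inputs

Ties in equal-splitting go to the left parts; ties in AUC to smaller
k; ties in ploidy to the expected ploidy. Constant-GC classes skip the
GC fit with a warning; zero-variance control matrices yield an empty
basis (denoising becomes identity); SD floors are 0.01 throughout;
Viterbi is computed in log space (no underflow up to 10⁶ bins).
Control selection, probe sampling, artificial-CNV placement and the
generator all derive from explicit seeds; identical inputs and seeds
give byte-identical outputs.

## Known limitations

Breakpoints are bin-resolution only (no split-read refinement); no
B-allele-frequency integration; no mobile-element detection; chrX
expected ploidy is a flag, not inferred; annotation is limited to
user-supplied BED tracks; batches below ~10 samples leave too few
controls for the SD estimates and produce noisy Z-scores; very small
analysis sets (hundreds of bins) make the sample-correlation HQ gate
and the control-selection correlations pessimistic, because a single
CNV is then a visible fraction of all bins.
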