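# offcall

CNV detection from targeted sequencing that refuses to throw away the
reads everyone else throws away.

Hybridization-capture experiments (exomes, gene panels) enrich chosen
regions, but 30–50% of reads still map elsewhere: library contaminants
at roughly 1/80 of the on-target per-base depth. `offcall` partitions
the genome into small on-target bins and large off-target bins so that
every bin collects a comparable number of aligned bases, then detects
rare copy-number variants (CNVs) — deletions and duplications, coding
or not — from the per-bin depth of a test sample relative to a panel
of batch controls. It is aimed at rare-disease and cancer groups who
have exome/panel BAMs and want CNV calls without extra wet-lab work.

## Method

For each test sample:

1. **Controls.** Batch samples with Pearson correlation ≥ 0.9 to the
   test sample (log₂ counts over ≤10,000 probe bins) form the control
   panel: at least 15, at most 96.
2. **Normalization.** Per-bin ratio r = test / mean(controls) after
   per-sample total-coverage scaling; a least-squares regression of r
   on bin GC removes capture bias (autosomes and chrX separately);
   bins with mean control coverage < 2,500 or control-ratio variance
   > 10^−0.2 are dropped.
3. **LOO-PCA denoising.** Principal components are fitted on the
   *controls only*; the test sample is merely projected and its
   projection removed. A true CNV exists only in the test sample, so
   it cannot become a component and survives removal — unlike standard
   PCA, where it is subtracted away. The number k of removed
   components is calibrated per sample by injecting 1,000 artificial
   CNVs (500 bins × 0.5, 500 × 1.5) and maximizing the ROC AUC of
   |Z| for recovering them.
4. **Segmentation.** A 3-state HMM (deletion / normal / duplication;
   P(normal→CNV) = 5·10⁻⁵, P(stay in CNV) = 0.5; Gaussian emissions at
   ratio 0.5 / 1.0 / 1.5 with per-bin control SDs) is Viterbi-decoded
   per chromosome for multi-bin events; isolated bins with
   |Z| = |(r − μ_ctrl)/σ_ctrl| ≥ 4 become single-bin events. Each event
   gets the integer copy number p minimizing the event-level |Z|
   against expected ratio p/2, plus a high-quality (HQ) flag.

## Worked example

Simulate a 16-sample batch (400 bins on 3 synthetic chromosomes) in
which sample S004 carries a 12-bin heterozygous deletion and a
single-bin homozygous deletion, then call S004:

```
$ offcall simulate --n-samples 16 --n-on-bins 300 --n-off-bins 100 --seed 7 \
      --cnv S004:50:12:1 --cnv S004:210:1:0 --out demo/sim
wrote simulated batch (16 samples, 400 bins) to demo/sim

$ offcall call --targetsBED demo/sim/bins.bed --coverage demo/sim/coverage.tsv \
      --samples S004 --seed 1 --out demo/calls
wrote 7 calls to demo/calls/events.tsv
```

The two injected events head the output with the right ploidy (the
remaining rows are |Z|≈4 single-bin borderline calls, the kind the HQ
filter exists to separate):

```
chrom  start    end     type      ploidy  n_bins  mean_z   mean_ratio  quality
chr1   791058   990640  deletion  1       12      -30.63   0.507        5796.3
chr2   884340   884526  deletion  0       1       -67.06   0.011        1676.9
```

`mean_ratio` 0.507 ≈ one copy lost of two; 0.011 ≈ both copies lost;
`quality` is the log-probability contrast (nats) between the decoded
path and an all-normal path. `demo/calls/` also contains a per-bin
`.seg` file for genome browsers and a BED export for SV annotators.

Real data enters through `offcall targets` (vendor capture BED +
reference FASTA → processed bins) and `offcall count` (indexed BAMs →
coverage matrix, MAPQ ≥ 50).

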