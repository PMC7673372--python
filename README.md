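# kdcnv

Single-sample copy-number-variation (CNV) caller for WGS read-depth data.

The caller bins per-position read counts, filters bins overlapping assembly
gaps, corrects GC bias against per-stratum depth means, denoises the depth
track with an exact 1-D total-variation solver, and merges the resulting
plateaus into read-depth segments. Each segment becomes a 2-D feature point
(a copy-ratio-like coordinate and a local mean-absolute-contrast
coordinate); every point is then scored with a **relative kernel-density
outlier score**: the ratio between the mean Gaussian-kernel density of its
extended neighbor set (k-nearest ∪ reverse-nearest ∪ shared-nearest
neighbors) and its own density. Segments scoring above a threshold θ are
declared candidate CNVs, merged, trimmed to their deviating cores, typed
gain/loss, and finally boundary-corrected to base precision using
soft-clipped split reads (clip-then-match reads for tandem gains;
match-then-clip / clip-then-match read pairs for losses).

A fully self-contained simulator (reference contig, planted CNVs,
purity-mixed Poisson read counts with GC bias, breakpoint-spanning split
reads in SAM) makes the whole pipeline testable without external data, and
an evaluation module scores calls against truth (recall/precision/F1,
loss-power score, boundary correctness, overlap-density score).

## Test

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) and acceptance tests
(`tests/test_acceptance.py`) that validate the numerical kernels against
independent brute-force oracles and run the pipeline end to end on
simulated samples.

## CLI

```sh
# generate a synthetic tumor sample (FASTA, read counts, SAM, truth BED)
kdcnv simulate --out-dir sim --seed 1 --tumor-purity 0.2 --coverage 30

# call CNVs from the read-count table, refining boundaries with split reads
kdcnv call --rc-table sim/rc.tsv --sr-alignment sim/reads.sam \
    --reference sim/ref.fa --contig sim0 --out-prefix sim/out

# score the calls against the planted truth
kdcnv evaluate --calls sim/out.calls.bed --truth sim/truth.bed

# or do all of the above in one shot
kdcnv run-all --out-dir run1 --seed 1
```

`kdcnv call` also accepts `--alignment reads.bam` to derive the depth
profile directly from a coordinate-sorted SAM/BAM. All tunables (bin size,
k, m, θ, TV λ, kernel bandwidth σ, split-read window, …) are exposed as
flags and via `--config-file` (JSON); defaults are bin 2000 bp, k = 60,
m = 10, θ = 1.1.

Outputs per run: `<prefix>.scores.tsv` (per-segment features and scores),
`<prefix>.pre.bed` (pre-refinement candidate regions), `<prefix>.calls.bed`
and `<prefix>.calls.tsv` (final calls with refinement status and split-read
support). BED coordinates are 0-based half-open; everything internal is
1-based inclusive (SAM convention).

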