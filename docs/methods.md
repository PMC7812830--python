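# Methods

This note documents the models, estimators and numerical choices behind
`neocent`, and what the synthetic-data generators do and do not emulate.

## Spike-in calibration model

Quantitative ChIP-seq spikes each sample with a fixed proportion of chromatin
from another species before immunoprecipitation. We model a sample's four
read totals as

- IP target reads ∝ depth · efficiency · (target chromatin signal),
- IP spike reads ∝ depth · efficiency · mixing,
- input target reads ∝ depth,
- input spike reads ∝ depth · mixing,

where *depth* is sequencing depth of the library, *efficiency* the antibody
pull-down efficiency (assumed to act equally on target and spike chromatin),
and *mixing* the spike:target chromatin ratio. The factor

```
factor = 10^6 · (Ns_input / Nh_input) / Ns_IP  ∝  1 / (depth · efficiency)
```

therefore cancels depth, efficiency and mixing when applied to raw IP bin
counts (which scale with depth · efficiency). Two consequences worth noting:

- The factor itself is **not** invariant under uniform scaling of all four
  totals — it scales as 1/depth, exactly compensating the doubled bin counts.
  The invariant object is the *calibrated track*, and that is what the tests
  assert (equal-truth samples agree within a mean per-bin log-ratio of ±0.02
  across 2× depth and 2× mixing perturbations at ≥500 reads/bin/allele).
- The constant 10⁶ only keeps calibrated values in a readable range; every
  downstream statistic is invariant to it.

Unit transforms: RPKM is `raw · 10⁹ / (bin_size · total_reads)`; min–max
scaling maps a track onto [0, 1] and refuses constant tracks (an explicit
error rather than silent zeros). Bins are 10 kb by default, 0-based
half-open, written/read as bedGraph with optional run-length merging.

## Allele deconvolution

On a diploid locus where exactly one homologue carries the engineered change
and the parental line is an unchanged two-allele reference,

```
derived / parent = (1 + a) / 2    =>    a = 2r − 1
```

with *r* the per-bin calibrated coverage ratio and *a* the fraction of
one-parental-allele signal remaining on the engineered homologue. The
domain summary is `100 · (1 − mean a)` over bins fully inside the domain
(mean, not median, to match a single-number percent-reduction readout;
median is available). Values of *a* below 0 (noise pushing *r* under 0.5)
are floored at 0 for reporting with the unclipped values retained, and the
allele-equivalence assumption is taken as exact — no copy-number
re-estimation is attempted.

The ratio uses a pseudocount expressed in **raw-count equivalents**: on
calibrated tracks it is multiplied by each track's own scaling factor, so one
pseudocount always weighs one sequenced read. Adding a flat pseudocount in
calibrated units would shrink deep bins' ratios toward 1 and bias the
recovered reduction downward by about a point at default depths.

Estimator precision: with 500 IP reads per bin per allele and a 10-bin
domain, the delta-method standard deviation of the recovered percent
reduction is ≈2.0–2.5 points (domain totals of ~6,000–10,000 reads in each
track, plus ~0.5% scaling-factor noise). The recovery tests are calibrated
to that floor: mean error within ±2 points over 50 independent experiments,
and at least 90% of individual runs within ±5 points, for planted losses of
30%, 50% and 78%.

## SV callset subtraction

Tolerance rule: `x = 5 bp` for parental SV length < 250 bp, `x = length/50`
otherwise (continuous at 250; fractional x kept). Matching requires equal
chromosome and SVTYPE with |Δstart| ≤ x and |Δlength| ≤ x. Choices made
where the convention was open:

- The tolerance derives from the **parental** call's length (asymmetric by
  construction, as the rule is phrased).
- Any-match elimination: a parental call can cancel several derived calls
  and is never consumed; subtraction is therefore anti-monotone in the
  parental set.
- Thresholds are inclusive (≥), matching minimum-length/minimum-support
  caller semantics (-l 10 -s 5 defaults).
- Breakends carry length 0 and match on position only within the small
  tolerance; strand/orientation of INV/BND mates is not compared.
- Genomic footprints for region overlap: INS/BND occupy one base; DEL, DUP,
  INV span start … start+length−1 (1-based inclusive, as in VCF).

The production implementation indexes parental calls by (chrom, type) with
position-sorted starts and a per-group maximal tolerance window; the test
suite checks it for exact set equality against a literal all-pairs oracle on
1,000 random callset pairs (sizes up to 200).

## Domain calling and formation frequency

No standard peak caller fits a single compact enriched block on an otherwise
flat chromosome, so the caller is deliberately minimal and fully
parameterized: seeds are bins above mean + z·SD (z = 3); background mean/SD
are re-estimated once with the initial seeds excluded (one pass is enough to
undo the SD inflation a strong domain causes); seed runs with gaps of at
most 2 bins are merged; regions under 3 bins are dropped; the primary domain
is the *widest* (span, not summit, is the biologically characterized
quantity). On pure Poisson noise the per-bin exceedance probability at z = 3
is ~10⁻³, and isolated exceedances cannot form a ≥3-bin run, which is what
keeps the false-call rate below 5%.

Domain metrics are edge-to-point distances in bp (0 inside the domain).
Formation frequency is events / challenged cells, with challenged cells
derived as round(total · sorted-positive fraction); when events count
recovered isolates the report flags the figure as an upper-limit estimate.

## Spread quantification

- **Spot intensity**: sum over a fixed ROI box (default 18 rows × 10
  columns — the conventional 10 × 18 box read as width × height; orientation
  is configurable) minus area × background, where background defaults to the
  median of a 2-pixel frame surrounding the box (corner-mean and
  lowest-quartile estimators available). Negative results are floored at 0
  with a flag. Sum vs mean of the box is immaterial once signals are
  normalized within a spread, which divides by the mean of reference
  intensities from the same spread.
- **Distances**: the two most prominent local maxima of a line profile
  (scipy `find_peaks`), each refined by 3-point parabolic interpolation, and
  converted to µm via the pixel size. Subpixel refinement can be switched
  off for literal integer-pixel readings. Fewer than two qualifying maxima
  raise an explicit "no pair" error.
- **Dot patterns**: two qualifying maxima separated by ≥3 px (default
  resolution limit; configurable) classify as "two-dots", one maximum or an
  unresolved pair as "one-dot", none as "undetermined".

## Synthetic data: what it emulates, and what it does not

`SimulationConfig` defaults are the study conditions all recovery tests run
under: a 10-Mb chromosome ("chr4") in 10-kb bins; a 100-kb (10-bin)
engineered domain; a 78% planted single-allele loss; **base_signal = 500
mean IP reads per bin per allele** in the parent line (a diploid bin expects
2 × 500); unit depth/efficiency multipliers and 1% spike mixing; 20
background SVs with ≤3 bp position and ≤2 bp length jitter plus 3 novel
calls; 4 Gaussian dot pairs (σ = 2 px) separated by 1 µm at 0.1 µm/px with
noise at 5% of amplitude on a flat background.

`base_signal` is defined per allele so the planted fraction *f* removes
exactly *f* × base_signal from one allele, keeping the truth independent of
ploidy bookkeeping; the expected calibrated derived:parent ratio is 1 − f/2
in-domain and 1 outside. Bin counts are Poisson (the minimal sequencing
noise model); library totals are Poisson at genome scale (10⁷ target reads
× depth; spike = mixing fraction thereof), drawn independently of the
window's bin sums because the simulated window is a small slice of a
genome-wide library. Novel SVs are rejection-sampled away from parental
calls so subtraction truth is exact.

Not emulated: read-level artifacts (FASTQ, alignment, mappability, GC),
copy-number variation on the engineered chromosome, overdispersion beyond
Poisson, chromatic/PSF effects in imaging, and crowded spreads where spot
ROIs overlap chromosomes. Passing recovery tests therefore demonstrates the
estimators' correctness and calibration under these idealized conditions,
not robustness to alignment or staining artifacts in real data; on real
inputs the same code paths apply but accuracy depends on those upstream
factors.

## Problem sizes

Recovery suites use 50 independent simulations per condition (1,000-bin
tracks; 20 spread images of 4 pairs; 1,000 random callset pairs for the
subtraction oracle), sizes at which the binomial uncertainty on the asserted
rates is small relative to the margins being tested.
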