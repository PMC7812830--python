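# neocent

Quantitative analysis toolkit for **induced-neocentromere experiments**:
paired parent/derived cell lines in which a centromere has been deleted and a
new one (a neocentromere) has formed at a naive locus. The package implements
the downstream quantitative analyses such an experiment needs, each
exercisable end-to-end on synthetic data with known ground truth:

- **Spike-in calibrated ChIP-seq** — binned coverage tracks with explicit
  unit states (raw / RPKM / calibrated / min–max), and a spike-in scaling
  factor that removes sequencing depth, IP efficiency and spike-mixing
  differences between samples.
- **Allele-specific signal deconvolution** — on a diploid locus where exactly
  one homologue is engineered, the calibrated derived:parent coverage ratio
  *r* yields the engineered allele's remaining signal *a* = 2*r* − 1 and a
  domain-averaged percent reduction.
- **SV callset subtraction** — removes parental structural-variant calls from
  a derived callset under an adaptive matching tolerance (5 bp below 250 bp
  of parental SV length, length/50 above), with inclusive length/support and
  region filters.
- **CENP-A domain analysis** — a parameterized enriched-domain caller
  (mean + z·SD seeds, gap merging, minimum width), domain width/distance
  metrics, and a formation-frequency estimator.
- **Mitotic-spread quantification** — background-corrected spot intensities
  in a fixed ROI box, within-spread normalization, subpixel peak-to-peak
  distances along line profiles, and one-dot/two-dots pattern classification.
- **Synthetic data** — generators for all of the above with planted truth:
  Poisson-sampled diploid ChIP experiments, jittered SV callsets with novel
  calls, and Gaussian dot-pair spread images.

It is written for computational biologists analysing calibrated ChIP-seq and
long-read SV data around engineered chromosomal loci, and is used primarily
as a Python library (see `examples/`); a thin `neocent` CLI covers the common
file-to-file steps.

## The statistics at the core

**Spike-in calibration.** For a sample with IP and input libraries whose read
totals split into target-genome reads *Nh* and spike-in reads *Ns*, the
factor applied to raw IP bin counts is

```
factor = 10^6 · (Ns_input / Nh_input) / Ns_IP
```

*Ns*_IP scales with depth × IP efficiency × mixing; the input spike fraction
estimates mixing; their quotient cancels all three, so calibrated tracks from
equal chromatin states agree regardless of depth or mixing.

**Allele deconvolution.** Assuming the parental signal originates equally
from both homologues and the unengineered homologue is unchanged,
`derived = parent · (1 + a)/2`, hence `a = 2r − 1` per bin and
`percent reduction = 100 · (1 − mean a)` over the domain. A planted 78%
single-allele loss shows up as an in-domain ratio of (1 + 0.22)/2 = 0.61.

**SV matching.** Two calls are the same variant when their types agree and
both |Δstart| and |Δlength| fall within `x = 5 bp` (parental length < 250 bp)
or `x = parental length / 50` (otherwise; continuous at 250). Subtraction
keeps every derived call matching no parental call.

## Worked example

```python
from neocent import SimulationConfig, simulate_chip_experiment
from neocent.workflows import chip_reduction_estimate

cfg = SimulationConfig(reduction_fraction=0.78)   # plant a 78% loss
exp = simulate_chip_experiment(cfg, seed=2)       # 2 IP tracks + 4 library totals
reduction, signal = chip_reduction_estimate(exp)  # calibrate -> ratio -> 2r-1
print(f"estimated reduction: {reduction:.1f}%")
```

```
estimated reduction: 76.7%
```

The pipeline calibrated both tracks with their spike-in factors, formed the
per-bin ratio, deconvolved the allele signal and averaged it over the 100-kb
(10-bin) domain: the planted 78% loss is recovered to within the ~2-point
Poisson noise floor of a 500 reads/bin/allele experiment. The scripts in
`examples/` walk through each capability the same way (calibration
invariance, SV subtraction, domain calling and formation frequency, spread
quantification) and print the numbers they compute.

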