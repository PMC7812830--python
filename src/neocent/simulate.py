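"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study design end to end:

* a two-line (parent / derived) spike-in ChIP-seq experiment on a diploid
  locus where the derived line has lost a planted fraction ``f`` of a
  chromatin mark on exactly one allele inside a planted domain — Poisson
  bin counts with per-sample sequencing depth, IP efficiency and spike-in
  mixing, plus genome-scale library totals for the four libraries;
* parental / derived SV callsets sharing jittered background calls plus
  derived-only novel calls (the subtraction truth);
* mitotic-spread images of Gaussian dot pairs on a noisy background, with a
  truth table of centers, integrated amplitudes and pair separations.

All randomness flows through explicit seeds; the same seed reproduces
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sv import SVCall, SVCallSet, calls_match, DEFAULT_RULE
from .tracks import CoverageTrack, LibraryCounts

__all__ = [
    "SimulationConfig",
    "ChipExperiment",
    "ChipTruth",
    "simulate_chip_experiment",
    "simulate_enrichment_track",
    "simulate_sv_callsets",
    "simulate_spread",
    "simulate_profile_cohort",
    "write_chip_truth",
    "read_chip_truth",
]

#: genome-scale read total per unit depth; the simulated window is a small
#: slice of a genome-wide library, so library totals are drawn independently
#: of the window's bin sums
LIBRARY_SCALE = 10_000_000

SAMPLES = ("parent", "derived")


def _per_sample(value) -> dict[str, float]:
    if isinstance(value, dict):
        return {k: float(v) for k, v in value.items()}
    return {s: float(value) for s in SAMPLES}


@dataclass
class SimulationConfig:
    """Ground-truth parameters for all three generators.

    Defaults mirror the experimental design being emulated: 10-kb bins, a
    100-kb (10-bin) engineered domain, a 78% single-allele loss of the mark,
    a mean of 500 IP reads per bin per allele in the parent line, and a
    spike-in amounting to ~1% of target-genome reads.  Spread defaults give
    2-px-sigma dots (0.2 um at 0.1 um/px) separated by 1 um, with noise at
    5% of the dot amplitude.
    """

    seed: int = 0
    chrom_name: str = "chr4"
    chrom_length: int = 10_000_000
    bin_size: int = 10_000
    domain_start: int = 4_500_000
    domain_end: int = 4_600_000
    reduction_fraction: float = 0.78
    base_signal: float = 500.0  # mean IP reads per bin per allele (parent)
    domain_enrichment: float = 10.0  # fold enrichment for CENP-A-like tracks
    depth_multipliers: dict = field(default_factory=lambda: {s: 1.0 for s in SAMPLES})
    spike_mix: dict = field(default_factory=lambda: {s: 0.01 for s in SAMPLES})
    ip_efficiency: dict = field(default_factory=lambda: {s: 1.0 for s in SAMPLES})
    # SV callsets
    n_background_svs: int = 20
    n_novel_svs: int = 3
    position_jitter: int = 3
    length_jitter: int = 2
    # spreads
    n_spot_pairs: int = 4
    image_size: tuple = (128, 128)
    spot_separation: float = 1.0  # um
    pixel_size: float = 0.1  # um per pixel
    spot_sigma: float = 0.2  # um (2 px at the default pixel size)
    spot_amplitude: float = 1000.0  # peak intensity units
    background_level: float = 100.0
    noise_sd: float = 50.0

    def __post_init__(self) -> None:
        self.depth_multipliers = _per_sample(self.depth_multipliers)
        self.spike_mix = _per_sample(self.spike_mix)
        self.ip_efficiency = _per_sample(self.ip_efficiency)
        self.image_size = tuple(int(x) for x in self.image_size)
        if not 0.0 <= self.reduction_fraction <= 1.0:
            raise ValueError(
                f"reduction_fraction must be in [0, 1], got {self.reduction_fraction}"
            )
        if not (0 <= self.domain_start < self.domain_end <= self.chrom_length):
            raise ValueError(
                f"domain [{self.domain_start}, {self.domain_end}) must lie inside "
                f"[0, {self.chrom_length})"
            )
        if self.domain_start % self.bin_size or self.domain_end % self.bin_size:
            raise ValueError("domain edges must be multiples of bin_size")
        for name, d in (
            ("depth_multipliers", self.depth_multipliers),
            ("spike_mix", self.spike_mix),
            ("ip_efficiency", self.ip_efficiency),
        ):
            for s in SAMPLES:
                if d.get(s, 0) <= 0:
                    raise ValueError(f"{name}[{s!r}] must be positive")
        if self.n_background_svs < 0 or self.n_novel_svs < 0:
            raise ValueError("SV counts must be >= 0")
        if self.position_jitter < 0 or self.length_jitter < 0:
            raise ValueError("jitters must be >= 0")
        if self.base_signal <= 0 or self.domain_enrichment <= 0:
            raise ValueError("base_signal and domain_enrichment must be positive")
        if self.pixel_size <= 0 or self.spot_sigma <= 0 or self.spot_separation < 0:
            raise ValueError("spread geometry parameters must be positive")
        if self.noise_sd < 0 or self.background_level < 0 or self.spot_amplitude <= 0:
            raise ValueError("spread intensity parameters out of range")

    # -- YAML ---------------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    # -- derived geometry ---------------------------------------------------

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)

    def domain_bin_mask(self) -> np.ndarray:
        starts = self.bin_size * np.arange(self.n_bins)
        return (starts >= self.domain_start) & (starts + self.bin_size <= self.domain_end)


@dataclass(frozen=True)
class ChipTruth:
    """Planted ground truth of a simulated ChIP experiment."""

    reduction_fraction: float
    domain_start: int
    domain_end: int
    chrom: str

    @property
    def expected_in_domain_ratio(self) -> float:
        """Calibrated derived:parent ratio inside the domain, (1 + (1-f))/2."""
        return 1.0 - self.reduction_fraction / 2.0


@dataclass
class ChipExperiment:
    parent_ip: CoverageTrack
    derived_ip: CoverageTrack
    counts: list  # four LibraryCounts: parent/derived x IP/input
    truth: ChipTruth

    def counts_for(self, sample_id: str, role: str) -> LibraryCounts:
        for c in self.counts:
            if c.sample_id == sample_id and c.role == role:
                return c
        raise KeyError(f"no {role} library for sample {sample_id!r}")


def _rng(config: SimulationConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(config.seed if seed is None else seed)


def simulate_chip_experiment(
    config: SimulationConfig, seed: int | None = None
) -> ChipExperiment:
    """Paired parent/derived IP tracks plus the four library read totals.

    The locus is diploid: each bin's expected parent signal is
    2 x base_signal; in the derived line one allele loses ``f`` of the mark
    inside the domain, so the in-domain expectation drops to
    (2 - f) x base_signal and the expected calibrated derived:parent ratio
    is 1 - f/2.  Bin counts are Poisson scaled by depth x IP efficiency;
    library totals are Poisson at genome scale with spike reads reflecting
    the per-sample spike:target mixing ratio.
    """
    rng = _rng(config, seed)
    in_domain = config.domain_bin_mask()
    f = config.reduction_fraction
    lam = {
        "parent": np.full(config.n_bins, 2.0 * config.base_signal),
        "derived": config.base_signal * (2.0 - f * in_domain),
    }
    tracks = {}
    counts = []
    for s in SAMPLES:
        depth = config.depth_multipliers[s]
        eff = config.ip_efficiency[s]
        mix = config.spike_mix[s]
        values = rng.poisson(depth * eff * lam[s]).astype(float)
        tracks[s] = CoverageTrack(
            chrom=config.chrom_name,
            bin_size=config.bin_size,
            values=values,
            unit_state="raw",
            meta={"sample_id": s, "role": "IP"},
        )
        counts.append(
            LibraryCounts(
                sample_id=s,
                role="IP",
                target_reads=max(int(rng.poisson(depth * eff * LIBRARY_SCALE)), 1),
                spike_reads=max(int(rng.poisson(depth * eff * mix * LIBRARY_SCALE)), 1),
            )
        )
        counts.append(
            LibraryCounts(
                sample_id=s,
                role="input",
                target_reads=max(int(rng.poisson(depth * LIBRARY_SCALE)), 1),
                spike_reads=max(int(rng.poisson(depth * mix * LIBRARY_SCALE)), 1),
            )
        )
    truth = ChipTruth(
        reduction_fraction=f,
        domain_start=config.domain_start,
        domain_end=config.domain_end,
        chrom=config.chrom_name,
    )
    return ChipExperiment(
        parent_ip=tracks["parent"], derived_ip=tracks["derived"], counts=counts, truth=truth
    )


def simulate_enrichment_track(
    config: SimulationConfig, seed: int | None = None, sample: str = "derived"
) -> tuple[CoverageTrack, ChipTruth]:
    """A CENP-A-like track: flat background with a planted enriched domain.

    Expected signal is base_signal outside the domain and
    base_signal x domain_enrichment inside; counts are Poisson scaled by the
    sample's depth multiplier.  Returned raw (normalize before domain
    calling).
    """
    rng = _rng(config, seed)
    in_domain = config.domain_bin_mask()
    lam = config.base_signal * (1.0 + (config.domain_enrichment - 1.0) * in_domain)
    depth = config.depth_multipliers[sample]
    track = CoverageTrack(
        chrom=config.chrom_name,
        bin_size=config.bin_size,
        values=rng.poisson(depth * lam).astype(float),
        unit_state="raw",
        meta={"sample_id": sample, "role": "IP", "planted_enrichment": config.domain_enrichment},
    )
    truth = ChipTruth(
        reduction_fraction=0.0,
        domain_start=config.domain_start,
        domain_end=config.domain_end,
        chrom=config.chrom_name,
    )
    return track, truth


# ---------------------------------------------------------------------------
# SV callsets

def simulate_sv_callsets(
    config: SimulationConfig, seed: int | None = None
) -> tuple[SVCallSet, SVCallSet, list[str]]:
    """Parental and derived callsets plus the ids of derived-only calls.

    Background calls appear in both sets, the derived copy with its start
    perturbed by at most ``position_jitter`` bp and its length by at most
    ``length_jitter`` bp.  Novel calls appear only in the derived set and are
    regenerated if they would match any parental call under the default
    adaptive tolerance, so the truth ids are exact.
    """
    rng = _rng(config, seed)
    types = ("INS", "DEL", "DUP", "INV")
    parental, derived = [], []
    for i in range(config.n_background_svs):
        call = _random_call(rng, config, f"bg{i}", types)
        parental.append(call)
        dstart = max(call.start + int(rng.integers(-config.position_jitter, config.position_jitter + 1)), 1)
        dlen = max(call.length + int(rng.integers(-config.length_jitter, config.length_jitter + 1)), 1)
        derived.append(
            SVCall(
                id=f"bg{i}.d",
                chrom=call.chrom,
                start=dstart,
                svtype=call.svtype,
                length=dlen,
                support=int(rng.integers(5, 41)),
            )
        )
    truth = []
    for i in range(config.n_novel_svs):
        for _ in range(1000):
            cand = _random_call(rng, config, f"novel{i}", types)
            if not any(calls_match(cand, p, DEFAULT_RULE) for p in parental):
                break
        else:  # pragma: no cover - astronomically unlikely on a 10 Mb window
            raise RuntimeError("could not place a novel SV away from parental calls")
        derived.append(cand)
        truth.append(cand.id)
    parental_set = SVCallSet(parental).sorted()
    derived_set = SVCallSet(derived).sorted()
    return parental_set, derived_set, truth


def _random_call(rng, config: SimulationConfig, call_id: str, types) -> SVCall:
    length = int(round(math.exp(rng.uniform(math.log(20), math.log(5000)))))
    start = int(rng.integers(1, max(config.chrom_length - length, 2)))
    return SVCall(
        id=call_id,
        chrom=config.chrom_name,
        start=start,
        svtype=str(rng.choice(types)),
        length=length,
        support=int(rng.integers(5, 41)),
    )


# ---------------------------------------------------------------------------
# mitotic spreads

def simulate_spread(
    config: SimulationConfig, seed: int | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """A spread image of Gaussian dot pairs plus its planted truth table.

    Spots are isotropic Gaussians (sigma = spot_sigma / pixel_size px) of
    per-spot peak amplitude drawn within +/-30% of spot_amplitude, placed on
    ``background_level`` with additive Gaussian noise of sd ``noise_sd``.
    Pairs are separated by exactly ``spot_separation`` um at random
    orientations, kept clear of the border and of each other.  The truth
    table lists one row per spot: pair id, center, peak and integrated
    amplitude, and the pair separation in px and um.
    """
    rng = _rng(config, seed)
    h, w = config.image_size
    sep_px = config.spot_separation / config.pixel_size
    sigma_px = config.spot_sigma / config.pixel_size
    margin = 14 + sep_px / 2  # ROI box + background frame must fit around each spot
    if 2 * margin >= min(h, w):
        raise ValueError(
            f"image {config.image_size} too small for spots with separation "
            f"{sep_px:.1f} px and the quantification margin"
        )
    centers = []
    for _ in range(config.n_spot_pairs):
        for _ in range(2000):
            cr = rng.uniform(margin, h - margin)
            cc = rng.uniform(margin, w - margin)
            if all((cr - r) ** 2 + (cc - c) ** 2 > (2.5 * sep_px + 12) ** 2 for r, c in centers):
                centers.append((cr, cc))
                break
        else:
            raise ValueError("could not place all spot pairs without overlap; enlarge image_size")

    rows_idx, cols_idx = np.mgrid[0:h, 0:w]
    image = np.full((h, w), float(config.background_level))
    records = []
    for pair_id, (cr, cc) in enumerate(centers):
        theta = rng.uniform(0, np.pi)
        dr, dc = (sep_px / 2) * np.sin(theta), (sep_px / 2) * np.cos(theta)
        for k, (r0, c0) in enumerate(((cr - dr, cc - dc), (cr + dr, cc + dc))):
            amp = config.spot_amplitude * rng.uniform(0.7, 1.3)
            image += amp * np.exp(
                -((rows_idx - r0) ** 2 + (cols_idx - c0) ** 2) / (2 * sigma_px**2)
            )
            records.append(
                {
                    "pair_id": pair_id,
                    "spot_id": f"p{pair_id}s{k}",
                    "row": r0,
                    "col": c0,
                    "peak_amplitude": amp,
                    "integrated_amplitude": amp * 2 * np.pi * sigma_px**2,
                    "separation_px": sep_px,
                    "separation_um": config.spot_separation,
                }
            )
    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, size=image.shape)
    return image, pd.DataFrame.from_records(records)


def simulate_profile_cohort(
    config: SimulationConfig,
    n_profiles: int,
    two_dot_fraction: float,
    seed: int | None = None,
    n_samples: int = 41,
) -> tuple[list[np.ndarray], list[str]]:
    """1-D dot-pair line profiles with a planted one-dot/two-dots mixture.

    Each profile is one or two Gaussian peaks (sigma = spot_sigma/pixel_size)
    on the configured background with the configured noise; two-dot profiles
    place the peaks ``spot_separation`` apart around the profile center.
    Returns the profiles and their planted labels.
    """
    if not 0.0 <= two_dot_fraction <= 1.0:
        raise ValueError("two_dot_fraction must be in [0, 1]")
    rng = _rng(config, seed)
    sigma_px = config.spot_sigma / config.pixel_size
    sep_px = config.spot_separation / config.pixel_size
    x = np.arange(n_samples, dtype=float)
    mid = (n_samples - 1) / 2
    profiles, labels = [], []
    for _ in range(n_profiles):
        two = rng.random() < two_dot_fraction
        amp = config.spot_amplitude * rng.uniform(0.7, 1.3)
        y = np.full(n_samples, float(config.background_level))
        if two:
            for c in (mid - sep_px / 2, mid + sep_px / 2):
                y += amp * np.exp(-((x - c) ** 2) / (2 * sigma_px**2))
        else:
            y += 2 * amp * np.exp(-((x - mid) ** 2) / (2 * sigma_px**2))
        if config.noise_sd > 0:
            y += rng.normal(0.0, config.noise_sd, size=n_samples)
        profiles.append(y)
        labels.append("two-dots" if two else "one-dot")
    return profiles, labels


# ---------------------------------------------------------------------------
# ground-truth round-trip I/O

def write_chip_truth(truth: ChipTruth, path: str | Path) -> None:
    pd.DataFrame([asdict(truth)]).to_csv(path, sep="\t", index=False)


def read_chip_truth(path: str | Path) -> ChipTruth:
    row = pd.read_csv(path, sep="\t").iloc[0]
    return ChipTruth(
        reduction_fraction=float(row.reduction_fraction),
        domain_start=int(row.domain_start),
        domain_end=int(row.domain_end),
        chrom=str(row.chrom),
    )
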