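"""Allele-specific signal deconvolution for a diploid locus.

ChIP-seq coverage aggregates both homologues.  When exactly one homologue
carries an engineered change (here: a neocentromere that evicts a chromatin
mark) and the other is assumed unchanged and equivalent to the parental
line, the remaining fraction *a* of parental-allele signal on the engineered
homologue follows from the calibrated derived:parent coverage ratio *r*:

    derived = (1 + a) / 2 * parent    =>    a = 2 r - 1

r = 1 means the engineered allele is unchanged (a = 1); r = 0.5 means it has
lost the mark completely (a = 0).  A domain-averaged percent reduction
100 * (1 - mean a) summarizes the loss over a region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ConstantTrackError, minmax_normalize
from .tracks import CoverageTrack

__all__ = ["AlleleSignal", "estimate_allele_signal", "percent_reduction", "allele_profile_report"]


@dataclass
class AlleleSignal:
    """Per-bin estimate of the engineered allele's remaining signal.

    ``values`` holds a = 2r - 1 clipped below at 0 (noise can push r under
    0.5, which has no physical meaning for a signal fraction); ``unclipped``
    retains the raw statistic for diagnostics and ``clipped`` marks the bins
    where flooring was applied.
    """

    chrom: str
    bin_size: int
    start: int
    values: np.ndarray
    unclipped: np.ndarray
    clipped: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.values.size

    def bin_starts(self) -> np.ndarray:
        return self.start + self.bin_size * np.arange(self.n_bins)

    def bins_inside(self, start: int, end: int) -> np.ndarray:
        b0 = self.bin_starts()
        return (b0 >= start) & (b0 + self.bin_size <= end)


def estimate_allele_signal(ratio: CoverageTrack) -> AlleleSignal:
    """Convert a per-bin derived:parent ratio track into allele signal a = 2r - 1."""
    if ratio.unit_state != "ratio":
        raise ValueError(f"expected a ratio track, got unit state {ratio.unit_state!r}")
    a = 2.0 * ratio.values - 1.0
    clipped = a < 0
    return AlleleSignal(
        chrom=ratio.chrom,
        bin_size=ratio.bin_size,
        start=ratio.start,
        values=np.where(clipped, 0.0, a),
        unclipped=a,
        clipped=clipped,
        provenance=dict(ratio.meta),
    )


def percent_reduction(
    signal: AlleleSignal,
    domain,
    statistic: str = "mean",
    use_clipped: bool = True,
) -> float:
    """Percent loss of the mark on the engineered allele over a domain.

    100 * (1 - <a>) over bins fully inside the domain, clipped to [0, 100].
    ``domain`` is anything with chrom/start/end attributes or a (start, end)
    pair (0-based half-open).  The mean matches the single-number summary
    convention; ``statistic="median"`` is offered for heavy-tailed bins.
    """
    start, end = _domain_span(signal.chrom, domain)
    mask = signal.bins_inside(start, end)
    if not mask.any():
        raise ValueError(f"domain [{start}, {end}) covers no full bin of the signal track")
    a = signal.values if use_clipped else signal.unclipped
    agg = np.mean if statistic == "mean" else np.median
    if statistic not in ("mean", "median"):
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    return float(np.clip(100.0 * (1.0 - agg(a[mask])), 0.0, 100.0))


def allele_profile_report(signal: AlleleSignal, domain, flank: int = 0) -> pd.DataFrame:
    """Per-bin table of r, a and min-max scaled a over domain +/- flank.

    Columns: chrom, start, end, r, a, a_unclipped, a_minmax, in_domain.  When
    the window is constant (min-max scaling undefined) a_minmax is NaN and
    the frame carries ``attrs["minmax_degenerate"] = True``.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    start, end = _domain_span(signal.chrom, domain)
    w0, w1 = start - flank, end + flank
    window = signal.bins_inside(w0, w1)
    if not window.any():
        raise ValueError("report window covers no bins")
    b0 = signal.bin_starts()[window]
    a = signal.values[window]
    r = (signal.unclipped[window] + 1.0) / 2.0
    report = pd.DataFrame(
        {
            "chrom": signal.chrom,
            "start": b0,
            "end": b0 + signal.bin_size,
            "r": r,
            "a": a,
            "a_unclipped": signal.unclipped[window],
            "in_domain": (b0 >= start) & (b0 + signal.bin_size <= end),
        }
    )
    scale_input = CoverageTrack(
        chrom=signal.chrom, bin_size=signal.bin_size, values=a, unit_state="ratio", start=int(b0[0])
    )
    try:
        report["a_minmax"] = minmax_normalize(scale_input).values
        report.attrs["minmax_degenerate"] = False
    except ConstantTrackError:
        report["a_minmax"] = np.nan
        report.attrs["minmax_degenerate"] = True
    return report


def _domain_span(chrom: str, domain) -> tuple[int, int]:
    if hasattr(domain, "start") and hasattr(domain, "end"):
        dchrom = getattr(domain, "chrom", chrom)
        if dchrom != chrom:
            raise ValueError(f"domain chromosome {dchrom!r} does not match signal {chrom!r}")
        start, end = int(domain.start), int(domain.end)
    else:
        start, end = map(int, domain)
    if end <= start:
        raise ValueError(f"empty or inverted domain [{start}, {end})")
    return start, end
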