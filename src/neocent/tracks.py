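"""Binned coverage tracks and sequencing-library bookkeeping.

A :class:`CoverageTrack` is a fixed-width binned signal over one chromosome
with an explicit unit state (``raw`` counts, ``rpkm``, spike-in ``calibrated``,
``minmax``-scaled, or a derived:parent ``ratio``).  :class:`LibraryCounts`
carries the per-library read totals split by target vs spike-in genome that
drive quantitative (spike-in) calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "LibraryCounts",
    "ScalingFactor",
    "UnitStateError",
    "read_bedgraph",
    "write_bedgraph",
    "read_library_counts",
    "write_library_counts",
]

#: unit states a track may declare
UNIT_STATES = ("raw", "rpkm", "calibrated", "minmax", "ratio")


class UnitStateError(ValueError):
    """An operation received a track in the wrong unit state."""


@dataclass
class CoverageTrack:
    """Fixed-width binned per-chromosome signal.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    bin_size : int
        Width of each bin in bp.  The last bin may be truncated on disk but is
        represented full-width in memory.
    values : ndarray of float
        One value per bin, ordered along the chromosome.
    unit_state : str
        One of ``raw``, ``rpkm``, ``calibrated``, ``minmax``, ``ratio``.
    start : int
        0-based coordinate of the first bin's left edge (half-open intervals).
    meta : dict
        Free-form provenance (scaling factor applied, pseudocount, ...).
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    unit_state: str = "raw"
    start: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.unit_state not in UNIT_STATES:
            raise UnitStateError(
                f"unknown unit state {self.unit_state!r}; expected one of {UNIT_STATES}"
            )
        if self.unit_state in ("raw", "rpkm", "calibrated") and np.any(self.values < 0):
            raise ValueError(f"{self.unit_state} track has negative values")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def end(self) -> int:
        """0-based half-open right edge of the covered span."""
        return self.start + self.n_bins * self.bin_size

    def bin_starts(self) -> np.ndarray:
        return self.start + self.bin_size * np.arange(self.n_bins)

    def same_binning(self, other: "CoverageTrack") -> bool:
        return (
            self.chrom == other.chrom
            and self.bin_size == other.bin_size
            and self.start == other.start
            and self.n_bins == other.n_bins
        )

    def with_values(self, values: np.ndarray, unit_state: str, **meta) -> "CoverageTrack":
        """New track sharing this track's binning."""
        new = replace(self, values=np.asarray(values, dtype=float), unit_state=unit_state)
        new.meta = {**self.meta, **meta}
        return new

    def bins_inside(self, start: int, end: int) -> np.ndarray:
        """Boolean mask of bins lying fully inside [start, end) (0-based half-open)."""
        b0 = self.bin_starts()
        return (b0 >= start) & (b0 + self.bin_size <= end)

    def to_frame(self) -> pd.DataFrame:
        b0 = self.bin_starts()
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": b0,
                "end": b0 + self.bin_size,
                "value": self.values,
            }
        )


@dataclass(frozen=True)
class LibraryCounts:
    """Read totals of one sequencing library, split by genome of origin.

    ``target_reads`` (Nh) map to the experimental (human) genome and
    ``spike_reads`` (Ns) to the exogenous spike-in (mouse) genome.
    """

    sample_id: str
    role: str  # "IP" or "input"
    target_reads: int
    spike_reads: int

    def __post_init__(self) -> None:
        if self.role not in ("IP", "input"):
            raise ValueError(f"role must be 'IP' or 'input', got {self.role!r}")
        if self.target_reads <= 0:
            raise ValueError("target_reads must be positive")
        if self.spike_reads <= 0:
            raise ValueError("spike_reads must be positive")


@dataclass(frozen=True)
class ScalingFactor:
    """Spike-in calibration factor for one sample's IP library."""

    sample_id: str
    value: float

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("scaling factor must be positive")


# ---------------------------------------------------------------------------
# bedGraph I/O (0-based, half-open)

def write_bedgraph(track: CoverageTrack, path: str | Path, merge_runs: bool = False) -> None:
    """Write a track as bedGraph.

    With ``merge_runs`` adjacent equal-value bins are run-length merged into a
    single interval (they are re-expanded on read).  The final bin is clipped
    to the declared span, never extended.
    """
    df = track.to_frame()
    if merge_runs and len(df) > 0:
        v = df["value"].to_numpy()
        run_id = np.concatenate([[0], np.cumsum(v[1:] != v[:-1])])
        df = (
            df.groupby(run_id)
            .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"), value=("value", "first"))
            .reset_index(drop=True)
        )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bedgraph(
    path: str | Path,
    bin_size: int | None = None,
    unit_state: str = "raw",
    chrom: str | None = None,
) -> CoverageTrack:
    """Read a bedGraph into a fixed-bin track.

    Run-length merged intervals are expanded back into ``bin_size`` bins; if
    ``bin_size`` is not given it is inferred as the most common interval width.
    Only one chromosome is read (``chrom`` selects it when several appear).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    if df.empty:
        raise ValueError(f"no intervals read from {path}")
    chroms = df["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError(f"multiple chromosomes in {path}; pass chrom= to select one")
    widths = (df["end"] - df["start"]).to_numpy()
    if bin_size is None:
        bin_size = int(np.bincount(widths).argmax())
    origin = int(df["start"].iloc[0])
    span = int(df["end"].iloc[-1]) - origin
    n_bins = -(-span // bin_size)  # ceil
    values = np.zeros(n_bins, dtype=float)
    for s, e, v in zip(df["start"], df["end"], df["value"]):
        i0 = (int(s) - origin) // bin_size
        i1 = -(-(int(e) - origin) // bin_size)
        values[i0:i1] = v
    return CoverageTrack(
        chrom=str(chroms[0]), bin_size=bin_size, values=values, unit_state=unit_state, start=origin
    )


# ---------------------------------------------------------------------------
# library-count TSV I/O

_COUNT_COLUMNS = ["sample_id", "role", "target_reads", "spike_reads"]


def write_library_counts(counts: Iterable[LibraryCounts], path: str | Path) -> None:
    rows = [
        (c.sample_id, c.role, c.target_reads, c.spike_reads) for c in counts
    ]
    pd.DataFrame(rows, columns=_COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library_counts(path: str | Path) -> list[LibraryCounts]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "role": str})
    missing = set(_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"library count table missing columns: {sorted(missing)}")
    return [
        LibraryCounts(
            sample_id=r.sample_id,
            role=r.role,
            target_reads=int(r.target_reads),
            spike_reads=int(r.spike_reads),
        )
        for r in df.itertuples(index=False)
    ]
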