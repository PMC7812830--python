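"""Structural-variant callset subtraction with an adaptive matching tolerance.

Long-read SV callers re-detect the same variant in related samples with
small jitter in start position and length, roughly proportional to the
variant's size.  To isolate calls private to a derived cell line, each
derived call is removed if it matches any parental call of the same type
with both |delta start| and |delta length| within a tolerance x derived from
the *parental* call's length:

    x = 5 bp          if parental length < 250 bp
    x = length / 50   otherwise          (continuous at 250: 250/50 = 5)

Length and support filters mirror the caller's minimum-length / minimum-read
-support semantics (inclusive thresholds), and region filters use 1-based
inclusive intervals as printed in genome-browser coordinates.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam

__all__ = [
    "SVCall",
    "SVCallSet",
    "ToleranceRule",
    "match_tolerance",
    "calls_match",
    "subtract_callsets",
    "filter_calls",
    "inspect_region",
    "NEOCENTROMERE_WINDOW",
    "CHR4_ANALYSIS_REGION",
]

SV_TYPES = ("INS", "DEL", "DUP", "INV", "BND")

#: chr4 window examined call-by-call around the neocentromere (1-based inclusive)
NEOCENTROMERE_WINDOW = ("chr4", 43_000_000, 43_250_000)
#: broader chr4 region the genome-wide callsets are first restricted to
CHR4_ANALYSIS_REGION = ("chr4", 40_000_000, 60_000_000)


@dataclass(frozen=True)
class SVCall:
    """One structural-variant call (1-based start, absolute length, read support)."""

    id: str
    chrom: str
    start: int
    svtype: str
    length: int
    support: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"SV start must be >= 1 (1-based), got {self.start}")
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}; expected one of {SV_TYPES}")
        if self.length < 0:
            raise ValueError("SV length must be >= 0")
        if self.support < 0:
            raise ValueError("read support must be >= 0")

    @property
    def end(self) -> int:
        """1-based inclusive end of the genomic footprint.

        Insertions and breakends occupy a single reference base; deletions,
        duplications and inversions span their length.
        """
        if self.svtype in ("INS", "BND"):
            return self.start
        return self.start + max(self.length - 1, 0)


class SVCallSet:
    """Ordered collection of :class:`SVCall` with VCF/TSV round-trip I/O."""

    def __init__(self, calls: Iterable[SVCall] = ()):  # order preserved
        self.calls: list[SVCall] = list(calls)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[SVCall]:
        return iter(self.calls)

    def __getitem__(self, i):
        return self.calls[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, SVCallSet) and self.calls == other.calls

    def __repr__(self) -> str:
        return f"SVCallSet({len(self.calls)} calls)"

    def ids(self) -> list[str]:
        return [c.id for c in self.calls]

    def sorted(self) -> "SVCallSet":
        return SVCallSet(sorted(self.calls, key=lambda c: (c.chrom, c.start, c.id)))

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.id, c.chrom, c.start, c.svtype, c.length, c.support) for c in self.calls],
            columns=["id", "chrom", "start", "svtype", "length", "support"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SVCallSet":
        return cls(
            SVCall(
                id=str(r.id),
                chrom=str(r.chrom),
                start=int(r.start),
                svtype=str(r.svtype),
                length=int(r.length),
                support=int(r.support),
            )
            for r in df.itertuples(index=False)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SVCallSet":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str}))

    def to_vcf(self, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
        """Write VCF v4.2 with INFO keys SVTYPE, SVLEN, END, RE."""
        header = pysam.VariantHeader()
        header.add_meta("source", "neocent")
        header.info.add("SVTYPE", 1, "String", "Type of structural variant")
        header.info.add("SVLEN", 1, "Integer", "Length of structural variant")
        header.info.add("END", 1, "Integer", "End position of structural variant")
        header.info.add("RE", 1, "Integer", "Number of reads supporting the variant")
        contigs = contig_lengths or {}
        seen = dict(contigs)
        for c in self.calls:
            seen.setdefault(c.chrom, max(c.end + 1_000, 1_000_000))
            seen[c.chrom] = max(seen[c.chrom], c.end + 1_000)
        for name, length in seen.items():
            header.contigs.add(name, length=int(length))
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for c in self.calls:
                rec = vcf.new_record(
                    contig=c.chrom,
                    start=c.start - 1,  # pysam is 0-based
                    alleles=("N", f"<{c.svtype}>"),
                    id=c.id,
                )
                rec.info["SVTYPE"] = c.svtype
                rec.info["SVLEN"] = c.length
                rec.info["RE"] = c.support
                # INFO/END is reserved in pysam and written via record.stop
                rec.stop = c.end
                vcf.write(rec)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "SVCallSet":
        calls = []
        with pysam.VariantFile(str(path)) as vcf:
            for i, rec in enumerate(vcf):
                svtype = rec.info.get("SVTYPE")
                if svtype is None:
                    continue
                svlen = rec.info.get("SVLEN", 0)
                if isinstance(svlen, (tuple, list)):
                    svlen = svlen[0] if svlen else 0
                support = rec.info.get("RE", 0)
                if isinstance(support, (tuple, list)):
                    support = support[0] if support else 0
                calls.append(
                    SVCall(
                        id=rec.id or f"sv_{i}",
                        chrom=rec.chrom,
                        start=rec.pos,  # pysam .pos is 1-based
                        svtype=str(svtype),
                        length=abs(int(svlen or 0)),
                        support=int(support or 0),
                    )
                )
        return cls(calls)


@dataclass(frozen=True)
class ToleranceRule:
    """Adaptive matching tolerance: flat below ``branch_length``, linear above."""

    branch_length: int = 250
    small_tolerance: float = 5.0
    divisor: float = 50.0

    def __post_init__(self) -> None:
        if self.branch_length <= 0 or self.small_tolerance <= 0 or self.divisor <= 0:
            raise ValueError("tolerance rule parameters must be positive")


DEFAULT_RULE = ToleranceRule()


def match_tolerance(parental_length: float, rule: ToleranceRule = DEFAULT_RULE) -> float:
    """Tolerance x (bp) allowed on both |delta start| and |delta length|.

    x = small_tolerance for parental lengths below the branch point, else
    length / divisor.  Fractional values are kept (no rounding).
    """
    if parental_length < 0:
        raise ValueError("parental SV length must be >= 0")
    if parental_length < rule.branch_length:
        return float(rule.small_tolerance)
    return parental_length / rule.divisor


def calls_match(derived: SVCall, parental: SVCall, rule: ToleranceRule = DEFAULT_RULE) -> bool:
    """Whether two calls are "the same" variant under the adaptive rule.

    Same chromosome and SVTYPE, |delta start| <= x and |delta length| <= x
    with x computed from the parental call's length.  Breakends have no
    meaningful length, so BND pairs match on position alone within the small
    tolerance.
    """
    if derived.chrom != parental.chrom or derived.svtype != parental.svtype:
        return False
    if parental.svtype == "BND":
        return abs(derived.start - parental.start) <= rule.small_tolerance
    x = match_tolerance(parental.length, rule)
    return (
        abs(derived.start - parental.start) <= x
        and abs(derived.length - parental.length) <= x
    )


def subtract_callsets(
    derived: SVCallSet, parental: SVCallSet, rule: ToleranceRule = DEFAULT_RULE
) -> SVCallSet:
    """Derived calls matching no parental call (derived-only variants).

    Any-match semantics: one parental call may eliminate several derived
    calls, and elimination never consumes the parental call.  Output order
    follows the derived set.  Parental calls are indexed by (chrom, svtype)
    with position-sorted starts so each derived call only tests candidates
    within the widest possible start tolerance of its position.
    """
    index: dict[tuple[str, str], tuple[list[int], list[SVCall], float]] = {}
    for key, group in _group_by(parental, lambda c: (c.chrom, c.svtype)).items():
        group.sort(key=lambda c: c.start)
        starts = [c.start for c in group]
        if key[1] == "BND":
            max_x = rule.small_tolerance
        else:
            max_x = max(match_tolerance(c.length, rule) for c in group)
        index[key] = (starts, group, max_x)

    kept = []
    for d in derived:
        bucket = index.get((d.chrom, d.svtype))
        if bucket is None:
            kept.append(d)
            continue
        starts, group, max_x = bucket
        lo = bisect_left(starts, d.start - max_x)
        hi = bisect_right(starts, d.start + max_x)
        if not any(calls_match(d, p, rule) for p in group[lo:hi]):
            kept.append(d)
    return SVCallSet(kept)


def filter_calls(
    calls: SVCallSet,
    min_length: int = 10,
    min_support: int = 5,
    region: tuple[str, int, int] | None = None,
) -> SVCallSet:
    """Length / support / region filter (all thresholds inclusive).

    ``region`` is (chrom, start, end), 1-based inclusive; a call is kept when
    its genomic footprint overlaps the region.
    """
    if region is not None:
        rchrom, rstart, rend = region
        if rend < rstart:
            raise ValueError(f"inverted region {rstart}-{rend}")
    kept = []
    for c in calls:
        if c.length < min_length or c.support < min_support:
            continue
        if region is not None and not (
            c.chrom == rchrom and c.start <= rend and c.end >= rstart
        ):
            continue
        kept.append(c)
    return SVCallSet(kept)


def inspect_region(
    calls: SVCallSet, window: tuple[str, int, int] = NEOCENTROMERE_WINDOW
) -> tuple[SVCallSet, str]:
    """Calls overlapping a window, plus a one-call-per-line report for review."""
    hits = filter_calls(calls, min_length=0, min_support=0, region=window)
    lines = [
        f"{c.chrom}:{c.start}\t{c.svtype}\tlen={c.length}\tsupport={c.support}\tid={c.id}"
        for c in hits
    ]
    return hits, "\n".join(lines)


def _group_by(calls: Iterable[SVCall], key) -> dict:
    groups: dict = {}
    for c in calls:
        groups.setdefault(key(c), []).append(c)
    return groups
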