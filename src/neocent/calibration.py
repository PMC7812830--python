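"""Spike-in calibration and unit transforms for binned ChIP-seq coverage.

Quantitative ChIP-seq adds a fixed admixture of chromatin from another
species (the spike-in) to every sample before immunoprecipitation.  Because
the spike-in sees the same antibody and the same sequencing run as the
target chromatin, its read counts absorb both IP efficiency and sequencing
depth; dividing them out makes profiles comparable across samples.  Mixing
itself can vary between samples, so the spike:target ratio observed in each
*input* library is used to correct the factor.

The factor applied to a sample's raw IP bin counts is

    factor = C * (Ns_input / Nh_input) / Ns_IP,        C = 10^6

where Nh/Ns are target-genome/spike-genome read totals.  ``Ns_IP`` scales
with depth x efficiency x mixing; ``Ns_input/Nh_input`` estimates mixing;
their quotient therefore removes depth, efficiency and mixing at once.  The
constant C only keeps calibrated values in a readable range.
"""

from __future__ import annotations

import numpy as np

from .tracks import CoverageTrack, LibraryCounts, ScalingFactor, UnitStateError

__all__ = [
    "compute_scaling_factor",
    "calibrate_track",
    "rpkm_normalize",
    "minmax_normalize",
    "ratio_track",
    "ConstantTrackError",
]

READABILITY_CONSTANT = 1e6


class ConstantTrackError(ValueError):
    """Min-max scaling of a constant track is undefined."""


def compute_scaling_factor(ip: LibraryCounts, input_: LibraryCounts) -> ScalingFactor:
    """Spike-in scaling factor for one sample from its IP and input libraries.

    The value is invariant under uniform rescaling of all four read totals
    (depth changes) and under joint rescaling of both spike totals (mixing
    changes), which is the property that makes calibrated tracks comparable.

    Raises
    ------
    ValueError
        If the sample ids differ, the roles are wrong, or any count is
        non-positive (zero spike reads in the IP leave the IP efficiency
        undefined).
    """
    if ip.sample_id != input_.sample_id:
        raise ValueError(
            f"mismatched sample ids: IP {ip.sample_id!r} vs input {input_.sample_id!r}"
        )
    if ip.role != "IP" or input_.role != "input":
        raise ValueError(f"expected roles IP/input, got {ip.role!r}/{input_.role!r}")
    value = READABILITY_CONSTANT * (input_.spike_reads / input_.target_reads) / ip.spike_reads
    return ScalingFactor(sample_id=ip.sample_id, value=value)


def calibrate_track(raw: CoverageTrack, factor: ScalingFactor) -> CoverageTrack:
    """Multiply a raw counts track by a spike-in scaling factor."""
    if raw.unit_state != "raw":
        raise UnitStateError(f"calibrate_track expects a raw track, got {raw.unit_state!r}")
    return raw.with_values(
        raw.values * factor.value,
        "calibrated",
        scaling_factor=factor.value,
        scaling_sample=factor.sample_id,
    )


def rpkm_normalize(raw: CoverageTrack, total_reads: int) -> CoverageTrack:
    """Reads per kilobase per million mapped reads.

    value_b = raw_b * 1e9 / (bin_size * total_reads)
    """
    if raw.unit_state != "raw":
        raise UnitStateError(f"rpkm_normalize expects a raw track, got {raw.unit_state!r}")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    values = raw.values * 1e9 / (raw.bin_size * total_reads)
    return raw.with_values(values, "rpkm", total_reads=int(total_reads))


def minmax_normalize(track: CoverageTrack) -> CoverageTrack:
    """Rescale a track to [0, 1] (min -> 0, max -> 1, order preserved).

    Idempotent on tracks that already span [0, 1].  A constant track has no
    defined scaling and raises :class:`ConstantTrackError` rather than
    silently returning zeros.
    """
    lo = float(np.min(track.values))
    hi = float(np.max(track.values))
    if hi == lo:
        raise ConstantTrackError("cannot min-max scale a constant track")
    return track.with_values((track.values - lo) / (hi - lo), "minmax", minmax_range=(lo, hi))


def ratio_track(
    derived: CoverageTrack,
    parent: CoverageTrack,
    pseudocount: float = 1.0,
    require_calibrated: bool = True,
    pseudocount_units: str = "raw-equivalent",
) -> CoverageTrack:
    """Per-bin derived:parent coverage ratio r_b = (d_b + pc_d) / (p_b + pc_p).

    Both tracks must share binning and (by default) be spike-in calibrated so
    that the ratio is depth- and mixing-invariant.  The pseudocount keeps
    empty-bin ratios finite and anchors 0/0 near 1.  By default it is
    expressed in *raw-count equivalents*: on a calibrated track it is scaled
    by the track's own scaling factor, so one pseudocount always weighs as
    much as one sequenced read and does not shrink the ratio toward 1 on
    deeply covered bins.  Pass ``pseudocount_units="track"`` to add the value
    as-is in the tracks' units.
    """
    if not derived.same_binning(parent):
        raise ValueError("ratio_track requires identical binning on both tracks")
    if derived.unit_state != parent.unit_state:
        raise UnitStateError(
            f"unit states differ: {derived.unit_state!r} vs {parent.unit_state!r}"
        )
    if require_calibrated and derived.unit_state != "calibrated":
        raise UnitStateError(
            f"ratio_track expects calibrated tracks, got {derived.unit_state!r}"
        )
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount_units == "raw-equivalent":
        pc_d = pseudocount * derived.meta.get("scaling_factor", 1.0)
        pc_p = pseudocount * parent.meta.get("scaling_factor", 1.0)
    elif pseudocount_units == "track":
        pc_d = pc_p = pseudocount
    else:
        raise ValueError(
            f"pseudocount_units must be 'raw-equivalent' or 'track', got {pseudocount_units!r}"
        )
    r = (derived.values + pc_d) / (parent.values + pc_p)
    return derived.with_values(r, "ratio", pseudocount=pseudocount)
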