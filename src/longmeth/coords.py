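"""Genomic coordinate conventions.

Array manifests give each CpG a 1-based point coordinate.  Regions are
carried internally (and written to BED) as 0-based half-open intervals.
All conversion arithmetic lives here so the +/-1 bookkeeping happens in
exactly one place.
"""
from __future__ import annotations


def points_to_interval(min_pos: int, max_pos: int) -> tuple[int, int]:
    """Convert an inclusive span of 1-based point coordinates to 0-based half-open.

    A single point ``(p, p)`` maps to the width-1 interval ``(p - 1, p)``.
    """
    if min_pos < 1 or max_pos < min_pos:
        raise ValueError(f"invalid point span ({min_pos}, {max_pos})")
    return min_pos - 1, max_pos


def interval_to_points(start: int, stop: int) -> tuple[int, int]:
    """Inverse of :func:`points_to_interval`."""
    if start < 0 or stop <= start:
        raise ValueError(f"invalid half-open interval ({start}, {stop})")
    return start + 1, stop


def interval_width(start: int, stop: int) -> int:
    """Width in bases of a 0-based half-open interval."""
    if stop <= start:
        raise ValueError(f"invalid half-open interval ({start}, {stop})")
    return stop - start


def interval_midpoint(start: int, stop: int) -> int:
    """Midpoint (floor) of a 0-based half-open interval."""
    return (start + stop) // 2
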