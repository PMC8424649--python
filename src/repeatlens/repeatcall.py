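"""Allele calling from sized peaks: bp -> repeat conversion, allele
splitting, modal calling and the 20%-of-modal inclusion threshold.

The conversion from fragment size to repeat units is calibrated against a
known allele rather than an absolute flank length, because amplicon flank
lengths are assay-specific and sizing is slightly non-linear; a single
reference allele (e.g. a stable endogenous allele of known repeat count)
anchors the scale.

The inclusion threshold is the mechanism that suppresses PCR stutter:
only peaks whose height reaches a fixed fraction (default 20%) of the
modal peak height enter any downstream index.  The comparison is
*inclusive* (>=), matching the convention of the widely used
instability-index protocol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import AmbiguityError, CalibrationError, CallError, ParameterError
from .fragio import PeakTable

#: Relative tolerance used when comparing heights against the threshold, so
#: that exact-boundary peaks (height == fraction * modal in real arithmetic)
#: are not dropped by floating-point representation error.
_REL_TOL = 1e-9


class ModalTieWarning(UserWarning):
    """Two repeat lengths share the maximal height; smaller one returned."""


@dataclass(frozen=True)
class Calibration:
    """Anchors the bp -> repeat-unit conversion to a known allele.

    ``reference_repeat`` is the repeat count of the calibrator allele and
    ``reference_size_bp`` its observed fragment size; ``repeat_unit_bp`` is
    the repeat-unit length (3 for CAG).
    """

    reference_repeat: int
    reference_size_bp: float
    repeat_unit_bp: int = 3

    def __post_init__(self) -> None:
        if self.repeat_unit_bp < 1:
            raise ParameterError("repeat_unit_bp must be >= 1")
        if not self.reference_size_bp > 0:
            raise ParameterError("reference_size_bp must be positive")
        if self.reference_repeat < 1:
            raise ParameterError("reference_repeat must be >= 1")


@dataclass(frozen=True)
class AlleleCall:
    """Modal call plus the threshold-included peak set for one allele window."""

    allele_window: tuple[int, int]
    modal_repeat: int
    modal_height: float
    included_peaks: tuple[tuple[int, float], ...]
    threshold_fraction: float = 0.20
    allele: int | None = None  # configured/expected allele label, if any

    def __post_init__(self) -> None:
        lo, hi = self.allele_window
        if not lo <= self.modal_repeat <= hi:
            raise ValueError("modal repeat outside allele window")
        if self.modal_repeat not in {r for r, _ in self.included_peaks}:
            raise ValueError("modal peak must be in the included set")
        floor = self.threshold_fraction * self.modal_height
        for r, h in self.included_peaks:
            if h < floor and not math.isclose(h, floor, rel_tol=_REL_TOL):
                raise ValueError(
                    f"included peak ({r}, {h}) below threshold {floor}"
                )


def size_to_repeats(size_bp: float, cal: Calibration) -> int:
    """Convert a fragment size to an integer repeat count.

    Rounds to the nearest whole repeat (halves round up):
    ``reference_repeat + round((size - reference_size)/unit)``.
    """
    delta = (size_bp - cal.reference_size_bp) / cal.repeat_unit_bp
    repeats = cal.reference_repeat + math.floor(delta + 0.5)
    if repeats < 1:
        raise CalibrationError(
            f"size {size_bp} bp maps to repeat count {repeats} (< 1); "
            "check calibration"
        )
    return int(repeats)


def aggregate_by_repeat(table: PeakTable, cal: Calibration) -> dict[int, float]:
    """Collapse a peak table to repeat space, summing heights of peaks that
    round to the same repeat count."""
    agg: dict[int, float] = {}
    for p in table.peaks:
        r = size_to_repeats(p.size_bp, cal)
        agg[r] = agg.get(r, 0.0) + p.height
    return agg


def split_alleles(
    table: PeakTable,
    expected_alleles: Sequence[int],
    cal: Calibration,
    min_separation: int = 6,
) -> dict[int, PeakTable]:
    """Partition peaks into per-allele sub-tables at the midpoint between
    expected alleles (in repeat units).

    With two expected alleles closer than ``min_separation`` (twice the
    default stutter-ladder depth) the windows could swallow each other's
    stutter, so an :class:`AmbiguityError` is raised.  Each peak is
    assigned to exactly one allele; the union of the sub-tables is the
    input table.
    """
    alleles = sorted(set(int(a) for a in expected_alleles))
    if not 1 <= len(alleles) <= 2:
        raise ParameterError("expected 1 or 2 expected allele positions")
    if len(alleles) == 2 and alleles[1] - alleles[0] < min_separation:
        raise AmbiguityError(
            f"expected alleles {alleles} closer than {min_separation} repeats"
        )

    out: dict[int, list] = {a: [] for a in alleles}
    if len(alleles) == 1:
        out[alleles[0]] = list(table.peaks)
    else:
        midpoint = (alleles[0] + alleles[1]) / 2.0
        for p in table.peaks:
            r = size_to_repeats(p.size_bp, cal)
            out[alleles[0] if r < midpoint else alleles[1]].append(p)
    return {
        a: PeakTable(sample_id=table.sample_id, locus=table.locus,
                     peaks=pks, day=table.day)
        for a, pks in out.items()
    }


def call_modal(
    repeat_heights: Mapping[int, float] | PeakTable,
    cal: Calibration | None = None,
) -> tuple[int, float]:
    """Return ``(modal_repeat, modal_height)`` of a repeat-height mapping.

    Accepts either an aggregated ``{repeat: height}`` mapping or a raw
    :class:`PeakTable` plus calibration.  Ties break to the smaller repeat
    and emit :class:`ModalTieWarning` so the trace can be flagged for
    manual review.
    """
    if isinstance(repeat_heights, PeakTable):
        if cal is None:
            raise ParameterError("calibration required when passing a PeakTable")
        repeat_heights = aggregate_by_repeat(repeat_heights, cal)
    if not repeat_heights:
        raise CallError("cannot call modal allele of an empty window")
    max_h = max(repeat_heights.values())
    winners = sorted(r for r, h in repeat_heights.items() if h == max_h)
    if len(winners) > 1:
        warnings.warn(
            f"modal tie between repeats {winners}; returning {winners[0]}",
            ModalTieWarning,
            stacklevel=2,
        )
    return winners[0], max_h


def threshold_peaks(
    repeat_heights: Mapping[int, float],
    modal_height: float,
    fraction: float = 0.20,
) -> list[tuple[int, float]]:
    """Keep peaks with height >= ``fraction`` x modal height, in repeat order.

    The boundary is inclusive; a small relative tolerance absorbs
    floating-point error in ``fraction * modal_height``.
    """
    if not modal_height > 0:
        raise ParameterError("modal_height must be positive")
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    floor = fraction * modal_height
    return sorted(
        (r, h)
        for r, h in repeat_heights.items()
        if h >= floor or math.isclose(h, floor, rel_tol=_REL_TOL)
    )


def call_allele(
    table: PeakTable,
    cal: Calibration,
    threshold_fraction: float = 0.20,
    allele: int | None = None,
) -> AlleleCall:
    """Full per-allele pipeline: aggregate, call modal, apply threshold."""
    agg = aggregate_by_repeat(table, cal)
    if not agg:
        raise CallError(f"no peaks in window for {table.sample_id}/{table.locus}")
    modal, modal_h = call_modal(agg)
    included = threshold_peaks(agg, modal_h, threshold_fraction)
    window = (min(agg), max(agg))
    return AlleleCall(
        allele_window=window,
        modal_repeat=modal,
        modal_height=modal_h,
        included_peaks=tuple(included),
        threshold_fraction=threshold_fraction,
        allele=allele,
    )
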