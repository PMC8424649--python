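"""Instability and expansion indices, modal change, and time-course assembly.

Both indices are normalized peak-height weighted sums of the change in
repeat units from the modal allele over the threshold-included peak set:

* ``instability_index`` sums over all included peaks and is signed
  (contractions contribute negatively);
* ``expansion_index`` sums only over peaks longer than the modal allele and
  is therefore non-negative.  By default it shares the instability index's
  normalizer (total included height) so the two indices are directly
  comparable; normalizing by expansion-side height only is available via
  ``normalizer="expansion_only"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import CallError, PairingError
from .repeatcall import AlleleCall

log = logging.getLogger(__name__)

METRICS = ("modal_repeat", "instability_index", "expansion_index")


@dataclass(frozen=True)
class InstabilityResult:
    """Per-sample/time-point instability summary for one allele window."""

    instability_index: float
    expansion_index: float
    modal_repeat: int
    modal_change_from_baseline: int | None = None

    def __post_init__(self) -> None:
        if self.expansion_index < 0:
            raise ValueError("expansion index must be >= 0")


@dataclass
class TimeCourse:
    """One metric tracked over days for a (genotype, replicate) pair."""

    genotype: str
    replicate: str
    metric: str
    points: list[tuple[float, float]] = field(default_factory=list)
    locus: str | None = None
    allele: int | None = None

    def __post_init__(self) -> None:
        self.points = sorted(self.points)
        days = [d for d, _ in self.points]
        if len(set(days)) != len(days):
            raise ValueError("time-course days must be distinct")

    @property
    def days(self) -> list[float]:
        return [d for d, _ in self.points]

    @property
    def values(self) -> list[float]:
        return [v for _, v in self.points]


def instability_index(call: AlleleCall) -> float:
    """Signed height-weighted mean change from modal over included peaks."""
    if not call.included_peaks:
        raise CallError("instability index of an empty included set")
    total = sum(h for _, h in call.included_peaks)
    return sum(h * (r - call.modal_repeat) for r, h in call.included_peaks) / total


def expansion_index(call: AlleleCall, normalizer: str = "included") -> float:
    """Expansion-direction component of the instability index (>= 0).

    ``normalizer="included"`` (default) divides by the total height of all
    included peaks; ``"expansion_only"`` divides by the height of
    expansion-side peaks only.
    """
    if not call.included_peaks:
        raise CallError("expansion index of an empty included set")
    expanded = [(r, h) for r, h in call.included_peaks if r > call.modal_repeat]
    if not expanded:
        return 0.0
    if normalizer == "included":
        denom = sum(h for _, h in call.included_peaks)
    elif normalizer == "expansion_only":
        denom = sum(h for _, h in expanded)
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    return sum(h * (r - call.modal_repeat) for r, h in expanded) / denom


def contraction_index(call: AlleleCall) -> float:
    """Contraction-direction mass (>= 0), normalized like the default
    expansion index; useful for decomposition checks."""
    if not call.included_peaks:
        raise CallError("contraction index of an empty included set")
    total = sum(h for _, h in call.included_peaks)
    return sum(
        h * (call.modal_repeat - r)
        for r, h in call.included_peaks
        if r < call.modal_repeat
    ) / total


def modal_change(call: AlleleCall, baseline_call: AlleleCall) -> int:
    """Modal repeat difference from a baseline call on the same allele."""
    if call.allele != baseline_call.allele:
        raise PairingError(
            f"allele windows differ: {call.allele!r} vs {baseline_call.allele!r}"
        )
    return call.modal_repeat - baseline_call.modal_repeat


def result_from_calls(
    call: AlleleCall, baseline_call: AlleleCall | None = None
) -> InstabilityResult:
    """Bundle indices (and modal change, if a baseline is given)."""
    return InstabilityResult(
        instability_index=instability_index(call),
        expansion_index=expansion_index(call),
        modal_repeat=call.modal_repeat,
        modal_change_from_baseline=(
            None if baseline_call is None else modal_change(call, baseline_call)
        ),
    )


def build_time_courses(
    indices: pd.DataFrame,
    manifest: pd.DataFrame,
    metric: str = "modal_repeat",
) -> list[TimeCourse]:
    """Assemble per-(genotype, replicate, locus, allele) time courses.

    ``indices`` must carry sample_id, locus, allele and the metric column;
    ``manifest`` maps sample_id to (genotype, replicate, day).  Groups with
    fewer than two distinct days are dropped with a warning.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if metric not in indices.columns:
        raise ValueError(f"indices table lacks column {metric!r}")
    merged = indices.merge(
        manifest[["sample_id", "genotype", "replicate", "day"]],
        on="sample_id",
        how="inner",
        validate="many_to_one",
    )
    courses: list[TimeCourse] = []
    for (genotype, replicate, locus, allele), grp in merged.groupby(
        ["genotype", "replicate", "locus", "allele"], sort=True
    ):
        grp = grp.drop_duplicates(subset="day").sort_values("day")
        if grp["day"].nunique() < 2:
            log.warning(
                "dropping (%s, %s, %s, %s): fewer than 2 distinct days",
                genotype, replicate, locus, allele,
            )
            continue
        courses.append(
            TimeCourse(
                genotype=str(genotype),
                replicate=str(replicate),
                metric=metric,
                points=list(zip(grp["day"].astype(float), grp[metric].astype(float))),
                locus=str(locus),
                allele=int(allele),
            )
        )
    return courses
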