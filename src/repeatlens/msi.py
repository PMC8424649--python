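"""Multi-locus microsatellite-instability (MSI/EMAST) classification.

Each marker locus is genotyped from its peak table with the same modal /
20%-threshold machinery used for the CAG assay, then compared against a
matched baseline (day-0 / parental line).  A locus is unstable when a
sample allele differs from every baseline allele by at least one repeat
unit (minus a sizing tolerance).  Control pentanucleotide loci are stable
by construction; a shift there flags a sample-level QC failure instead of
instability.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError, SummaryError
from .fragio import PeakTable
from .repeatcall import _REL_TOL

VALID_UNITS = (1, 2, 4, 5)
UNIT_CLASS = {1: "mono", 2: "di", 4: "tetra", 5: "penta"}


@dataclass(frozen=True)
class MsiLocus:
    name: str
    unit_bp: int
    role: str = "marker"  # "marker" or "control"

    def __post_init__(self) -> None:
        if self.unit_bp not in VALID_UNITS:
            raise ConfigError(
                f"{self.name}: unit_bp must be one of {VALID_UNITS}, "
                f"got {self.unit_bp}"
            )
        if self.role not in ("marker", "control"):
            raise ConfigError(f"{self.name}: role must be 'marker' or 'control'")


@dataclass(frozen=True)
class MsiCall:
    locus: str
    status: str  # "stable", "unstable" or "failed"
    shifted_units: int = 0
    evidence: tuple[tuple[float, ...], tuple[float, ...]] = ((), ())

    def __post_init__(self) -> None:
        if self.status not in ("stable", "unstable", "failed"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "unstable" and abs(self.shifted_units) < 1:
            raise ValueError("unstable call requires |shifted_units| >= 1")


@dataclass(frozen=True)
class PanelSummary:
    unstable_by_class: dict
    emast: bool
    qc_fail: bool
    n_failed: int


def load_panel(path: str | Path | None = None) -> list[MsiLocus]:
    """Load a locus panel from YAML; default is the packaged 18-locus panel
    (6 mono-, 5 di-, 5 tetra-nucleotide markers and 2 pentanucleotide
    controls)."""
    if path is None:
        ref = importlib.resources.files("repeatlens.data") / "msi_panel.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    try:
        return [MsiLocus(**entry) for entry in cfg["loci"]]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed panel config: {exc}") from exc


def call_locus_alleles(
    table: PeakTable,
    locus: MsiLocus,
    threshold_fraction: float = 0.20,
    max_alleles: int = 2,
) -> list[float]:
    """Call up to two allele sizes (bp) for one locus.

    Peaks below ``threshold_fraction`` of the tallest peak are discarded
    (this removes stutter, which for microsatellite PCR stays well under
    20% of the main product).  Surviving peaks are clustered: a gap larger
    than 1.5 repeat units starts a new allele cluster, and each cluster's
    allele is the size of its tallest peak.  The ``max_alleles`` tallest
    clusters are reported, sorted by size.  An empty list means the locus
    failed.
    """
    if not table.peaks:
        return []
    modal_h = max(p.height for p in table.peaks)
    floor = threshold_fraction * modal_h
    kept = [
        p for p in table.peaks
        if p.height >= floor or math.isclose(p.height, floor, rel_tol=_REL_TOL)
    ]
    if not kept:
        return []
    clusters: list[list] = [[kept[0]]]
    for p in kept[1:]:
        if p.size_bp - clusters[-1][-1].size_bp > 1.5 * locus.unit_bp:
            clusters.append([p])
        else:
            clusters[-1].append(p)
    clusters.sort(key=lambda c: max(p.height for p in c), reverse=True)
    alleles = [
        max(c, key=lambda p: p.height).size_bp for c in clusters[:max_alleles]
    ]
    return sorted(alleles)


def classify_msi(
    sample_alleles: list[float],
    baseline_alleles: list[float],
    locus: MsiLocus,
    tolerance_bp: float = 0.5,
) -> MsiCall:
    """Compare sample alleles to baseline alleles for one locus.

    Unstable iff any sample allele differs from *every* baseline allele by
    at least ``unit_bp - tolerance_bp``; ``shifted_units`` is the rounded
    unit shift of the most novel allele relative to its nearest baseline
    allele.  Either call missing -> status "failed".
    """
    evidence = (tuple(baseline_alleles), tuple(sample_alleles))
    if not sample_alleles or not baseline_alleles:
        return MsiCall(locus=locus.name, status="failed", evidence=evidence)
    cutoff = locus.unit_bp - tolerance_bp
    best_delta = 0.0  # signed delta of the most-shifted sample allele
    for s in sample_alleles:
        delta = min((s - b for b in baseline_alleles), key=abs)
        if abs(delta) > abs(best_delta):
            best_delta = delta
    if abs(best_delta) >= cutoff:
        units = round(best_delta / locus.unit_bp)
        if units == 0:  # sub-unit shift beyond tolerance still counts one unit
            units = 1 if best_delta > 0 else -1
        return MsiCall(
            locus=locus.name, status="unstable",
            shifted_units=int(units), evidence=evidence,
        )
    return MsiCall(locus=locus.name, status="stable", evidence=evidence)


def panel_summary(calls: list[MsiCall], panel: list[MsiLocus]) -> PanelSummary:
    """Summarize per-locus calls: unstable counts per unit class, the EMAST
    flag (any unstable tetranucleotide marker), and a QC-failure flag when
    a control locus shifts."""
    by_name = {l.name: l for l in panel}
    informative = [c for c in calls if c.status != "failed"]
    if not informative:
        raise SummaryError("all loci failed; no informative locus")
    counts = {cls: 0 for cls in UNIT_CLASS.values()}
    emast = False
    qc_fail = False
    for call in informative:
        locus = by_name.get(call.locus)
        if locus is None:
            raise ConfigError(f"call for unknown locus {call.locus!r}")
        if call.status != "unstable":
            continue
        if locus.role == "control":
            qc_fail = True
            continue
        cls = UNIT_CLASS[locus.unit_bp]
        counts[cls] += 1
        if cls == "tetra":
            emast = True
    return PanelSummary(
        unstable_by_class=counts,
        emast=emast,
        qc_fail=qc_fail,
        n_failed=len(calls) - len(informative),
    )
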