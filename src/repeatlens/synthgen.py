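"""Synthetic repeat-instability data: population dynamics, rendered peak
tables, MSI panel fixtures, and crosslink/toy-structure fixtures.

The expansion model is deliberately minimal: each cell's allele takes a
+1 repeat step with probability ``p_expand`` and a -1 step with
probability ``p_contract`` per day, independently across cells and days.
This biased unit-step random walk reproduces the two features the
downstream analyses rely on - linear modal drift at rate
``p_expand - p_contract`` repeat units per day, and gradual broadening of
the length distribution - without claiming anything about the underlying
repair chemistry.

Rendering converts a per-allele repeat-length histogram into a sized peak
table: each true length contributes a main peak at
``flank_bp + repeat * repeat_unit_bp`` plus a geometric PCR-stutter
ladder toward shorter lengths (``stutter_ratio ** k`` of the main signal
at the -k position), with Gaussian sizing jitter and multiplicative
height noise.
"""

from __future__ import annotations

import copy
import importlib.resources
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

import biotite.structure as struc
from biotite.structure.io import pdb as _pdbio

from .errors import ConfigError, ParameterError
from .fragio import PeakTable, Peak, write_peak_table, write_manifest
from .msi import MsiLocus, load_panel
from .xlinkseq import CrosslinkRecord

# ---------------------------------------------------------------------------
# parameter types


@dataclass(frozen=True)
class ExpansionModelParams:
    """Per-day biased unit-step random-walk model of a cell population."""

    p_expand: float
    p_contract: float
    n_cells: int
    days: tuple[int, ...]
    founder_repeats: tuple[int, ...]
    seed: int
    #: Alleles with founder length below this stay fixed (short stable
    #: alleles do not measurably expand on assay time scales).
    min_unstable_repeat: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_expand and 0 <= self.p_contract):
            raise ParameterError("step probabilities must be >= 0")
        if self.p_expand + self.p_contract > 1:
            raise ParameterError("p_expand + p_contract must be <= 1")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        days = tuple(self.days)
        if any(d < 0 for d in days) or list(days) != sorted(set(days)):
            raise ParameterError("days must be non-negative and strictly increasing")
        if not self.founder_repeats or any(r < 1 for r in self.founder_repeats):
            raise ParameterError("founder repeat lengths must be >= 1")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "founder_repeats", tuple(self.founder_repeats))


@dataclass(frozen=True)
class TraceRenderParams:
    """How a repeat-length histogram is rendered into sized peaks."""

    stutter_ratio: float = 0.15
    stutter_steps: int = 3
    size_noise_sd: float = 0.25
    height_noise_cv: float = 0.05
    repeat_unit_bp: int = 3
    flank_bp: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.stutter_ratio < 1:
            raise ParameterError("stutter_ratio must be in [0, 1)")
        if self.stutter_steps < 0:
            raise ParameterError("stutter_steps must be >= 0")
        if self.size_noise_sd < 0 or self.height_noise_cv < 0:
            raise ParameterError("noise parameters must be >= 0")
        if self.repeat_unit_bp < 1:
            raise ParameterError("repeat_unit_bp must be >= 1")


@dataclass(frozen=True)
class FixtureEntry:
    genotype: str
    replicate: int
    day: int
    sample_id: str
    path: str
    seed: int


@dataclass(frozen=True)
class FixtureManifest:
    seed: int
    entries: tuple[FixtureEntry, ...]

    def __post_init__(self) -> None:
        triples = [(e.genotype, e.replicate, e.day) for e in self.entries]
        if len(set(triples)) != len(triples):
            raise ValueError("(genotype, replicate, day) triples must be unique")

    def save(self, path: str | Path) -> Path:
        payload = {
            "seed": self.seed,
            "entries": [asdict(e) for e in self.entries],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return Path(path)


# ---------------------------------------------------------------------------
# population simulation


def _step_histogram(
    hist: dict[int, int], p_expand: float, p_contract: float,
    rng: np.random.Generator,
) -> dict[int, int]:
    """Advance one allele histogram by one day of unit steps."""
    new: dict[int, int] = {}
    probs = [p_expand, p_contract, 1.0 - p_expand - p_contract]
    for repeat in sorted(hist):
        count = hist[repeat]
        up, down, stay = rng.multinomial(count, probs)
        if down and repeat == 1:  # repeat lengths never drop below 1
            stay += down
            down = 0
        for r, c in ((repeat + 1, up), (repeat - 1, down), (repeat, stay)):
            if c:
                new[r] = new.get(r, 0) + int(c)
    return new


def simulate_population(
    params: ExpansionModelParams,
    rng: np.random.Generator | None = None,
) -> dict[int, list[dict[int, int]]]:
    """Simulate per-day repeat-length histograms for each founder allele.

    Returns ``{day: [histogram per founder allele]}`` where each histogram
    maps repeat length to cell count and sums to ``n_cells``.  Alleles with
    founder length below ``min_unstable_repeat`` stay point masses.
    Reproducible for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    hists = [{int(r): params.n_cells} for r in params.founder_repeats]
    dynamic = [r >= params.min_unstable_repeat for r in params.founder_repeats]
    any_moves = params.p_expand + params.p_contract > 0

    out: dict[int, list[dict[int, int]]] = {}
    day_set = set(params.days)
    if 0 in day_set:
        out[0] = copy.deepcopy(hists)
    last = max(params.days) if params.days else 0
    for day in range(1, last + 1):
        if any_moves:
            hists = [
                _step_histogram(h, params.p_expand, params.p_contract, rng)
                if dyn else h
                for h, dyn in zip(hists, dynamic)
            ]
        if day in day_set:
            out[day] = copy.deepcopy(hists)
    return out


def histogram_mean(hist: Mapping[int, int]) -> float:
    total = sum(hist.values())
    return sum(r * c for r, c in hist.items()) / total


# ---------------------------------------------------------------------------
# rendering


def render_peak_table(
    allele_histograms: Sequence[Mapping[int, int]],
    render: TraceRenderParams,
    sample_id: str,
    locus: str = "HTT",
    day: float | None = None,
    rng: np.random.Generator | None = None,
    peak_scale: float = 10_000.0,
) -> PeakTable:
    """Render per-allele histograms into one biallelic peak table.

    Each allele is normalized so its tallest true length has signal
    ``peak_scale`` (fluorescence units are arbitrary; only ratios matter
    downstream).  Every true peak echoes ``stutter_ratio ** k`` of its
    signal at the -k repeat position for k = 1..``stutter_steps``, then
    sizing jitter and multiplicative height noise are applied per rendered
    peak.  Peaks from all alleles land in one table, sorted by size.
    """
    if not allele_histograms or any(not h for h in allele_histograms):
        raise ParameterError("every allele histogram must be non-empty")
    if rng is None:
        rng = np.random.default_rng(0)

    signal: dict[int, float] = {}
    for hist in allele_histograms:
        top = max(hist.values())
        for repeat, count in sorted(hist.items()):
            main = peak_scale * count / top
            for k in range(0, render.stutter_steps + 1):
                r = repeat - k
                if r < 1:
                    break
                signal[r] = signal.get(r, 0.0) + main * render.stutter_ratio**k

    peaks = []
    for repeat in sorted(signal):
        size = render.flank_bp + repeat * render.repeat_unit_bp
        if render.size_noise_sd > 0:
            size += rng.normal(0.0, render.size_noise_sd)
        height = signal[repeat]
        if render.height_noise_cv > 0:
            height *= max(0.0, 1.0 + render.height_noise_cv * rng.normal())
        peaks.append(Peak(size_bp=float(size), height=float(height)))
    return PeakTable(sample_id=sample_id, locus=locus, peaks=peaks, day=day)


# ---------------------------------------------------------------------------
# packaged cell-line-like fixture


def load_fixture_config(path: str | Path | None = None) -> dict:
    """Load the fixture configuration (packaged default if no path)."""
    if path is None:
        ref = importlib.resources.files("repeatlens.data") / "u2os_fixture.yaml"
        return yaml.safe_load(ref.read_text())
    return yaml.safe_load(Path(path).read_text())


def _child_seed(seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)).generate_state(1)[0]
    )


def make_fixture_u2os(
    out_dir: str | Path,
    seed: int = 1,
    config: dict | str | Path | None = None,
) -> FixtureManifest:
    """Write the packaged biallelic fixture: peak tables for every
    (genotype, replicate, day), a JSON manifest and a CSV sample manifest.

    Deterministic per seed (byte-identical files); per-replicate child
    seeds are derived from the top-level seed and recorded in the
    manifest.
    """
    if config is None or isinstance(config, (str, Path)):
        config = load_fixture_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    render = TraceRenderParams(**config["render"])
    days = tuple(int(d) for d in config["days"])
    entries: list[FixtureEntry] = []
    manifest_rows = []

    for gi, (genotype, gparams) in enumerate(sorted(config["genotypes"].items())):
        for replicate in range(1, int(config["replicates"]) + 1):
            child = _child_seed(seed, gi, replicate)
            params = ExpansionModelParams(
                p_expand=float(gparams["p_expand"]),
                p_contract=float(gparams.get("p_contract", 0.0)),
                n_cells=int(config["n_cells"]),
                days=days,
                founder_repeats=tuple(int(r) for r in config["founder_repeats"]),
                seed=child,
                min_unstable_repeat=int(config.get("min_unstable_repeat", 0)),
            )
            rng = np.random.default_rng(child)
            by_day = simulate_population(params, rng=rng)
            for day in days:
                sample_id = f"{genotype}_r{replicate}_d{day}"
                table = render_peak_table(
                    by_day[day], render, sample_id=sample_id,
                    locus=str(config["locus"]), day=float(day), rng=rng,
                )
                fname = f"{sample_id}.tsv"
                write_peak_table([table], out_dir / fname)
                entries.append(FixtureEntry(
                    genotype=genotype, replicate=replicate, day=day,
                    sample_id=sample_id, path=fname, seed=child,
                ))
                manifest_rows.append({
                    "sample_id": sample_id, "genotype": genotype,
                    "replicate": replicate, "day": day,
                })

    manifest = FixtureManifest(seed=seed, entries=tuple(entries))
    manifest.save(out_dir / "manifest.json")
    import pandas as pd

    write_manifest(pd.DataFrame(manifest_rows), out_dir / "manifest.csv")
    return manifest


# ---------------------------------------------------------------------------
# MSI fixture


@dataclass(frozen=True)
class MsiFixture:
    baseline: tuple[PeakTable, ...]
    followup: tuple[PeakTable, ...]
    truth: dict[str, str]  # locus name -> "stable" | "unstable"
    shifts: dict[str, int]  # locus name -> injected unit shift


def _msi_allele_peaks(
    size: float, unit_bp: int, rng: np.random.Generator,
    height: float = 1000.0,
) -> list[Peak]:
    """Main peak plus one -1-unit stutter peak with light noise."""
    jitter = rng.normal(0.0, 0.05, size=2)
    h_noise = 1.0 + 0.03 * rng.normal(size=2)
    return [
        Peak(size_bp=size + jitter[0], height=height * max(0.1, h_noise[0])),
        Peak(size_bp=size - unit_bp + jitter[1],
             height=0.10 * height * max(0.1, h_noise[1])),
    ]


def make_msi_fixture(
    panel: Sequence[MsiLocus] | None = None,
    seed: int = 0,
    shifts: Mapping[str, int] | None = None,
    n_unstable: int = 3,
    out_dir: str | Path | None = None,
) -> MsiFixture:
    """Baseline + follow-up MSI peak tables with injected allele shifts.

    If ``shifts`` is not given, ``n_unstable`` marker loci are picked at
    random to gain a +1-unit allele; control loci are never picked (they
    can still be shifted explicitly, e.g. to exercise QC handling).
    Ground-truth labels are returned alongside the tables.
    """
    panel = list(load_panel() if panel is None else panel)
    rng = np.random.default_rng(seed)
    names = {l.name for l in panel}

    if shifts is None:
        markers = [l.name for l in panel if l.role == "marker"]
        if n_unstable > len(markers):
            raise ConfigError("n_unstable exceeds number of marker loci")
        chosen = rng.choice(markers, size=n_unstable, replace=False)
        shifts = {name: 1 for name in chosen}
    else:
        unknown = set(shifts) - names
        if unknown:
            raise ConfigError(f"shift requested for unknown locus {sorted(unknown)}")
        shifts = {k: int(v) for k, v in shifts.items()}
        if any(v == 0 for v in shifts.values()):
            raise ConfigError("injected shifts must be >= 1 unit in magnitude")

    baseline_tables: list[PeakTable] = []
    followup_tables: list[PeakTable] = []
    truth: dict[str, str] = {}

    for li, locus in enumerate(panel):
        base = 100.0 + 5 * li + locus.unit_bp * int(rng.integers(0, 15))
        alleles = [base]
        if rng.random() < 0.5:  # heterozygous locus
            alleles.append(base + locus.unit_bp * int(rng.integers(2, 5)))
        peaks = []
        for a in alleles:
            peaks.extend(_msi_allele_peaks(a, locus.unit_bp, rng))
        baseline_tables.append(
            PeakTable(sample_id="baseline", locus=locus.name, peaks=peaks)
        )

        sample_alleles = list(alleles)
        shift = shifts.get(locus.name, 0)
        if shift:
            novel = sample_alleles[-1] + shift * locus.unit_bp
            # keep the novel allele >= 1 unit away from every retained allele
            while any(abs(novel - a) < locus.unit_bp for a in sample_alleles[:-1]):
                novel += locus.unit_bp * (1 if shift > 0 else -1)
            sample_alleles[-1] = novel
            truth[locus.name] = "unstable"
        else:
            truth[locus.name] = "stable"
        peaks = []
        for a in sample_alleles:
            peaks.extend(_msi_allele_peaks(a, locus.unit_bp, rng))
        followup_tables.append(
            PeakTable(sample_id="followup", locus=locus.name, peaks=peaks)
        )

    fixture = MsiFixture(
        baseline=tuple(baseline_tables),
        followup=tuple(followup_tables),
        truth=truth,
        shifts=dict(shifts),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_peak_table(baseline_tables, out_dir / "msi_baseline.tsv")
        write_peak_table(followup_tables, out_dir / "msi_followup.tsv")
        (out_dir / "msi_truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True) + "\n"
        )
    return fixture


# ---------------------------------------------------------------------------
# crosslink / toy-structure fixture


@dataclass(frozen=True)
class XlinkFixture:
    links_path: Path
    structure_path: Path
    map_path: Path
    records: tuple[CrosslinkRecord, ...]


#: (protein1, res1, aa1, protein2, res2, aa2, score).  Scores straddle the
#: 20 cutoff, one record sits exactly on it, one residue pair is
#: duplicated, and after strict filtering the unique-pair counts are
#: FAN1-MLH1 = 3 and FAN1-PMS2 = 6.
_XLINK_ROWS: tuple[tuple[str, int, str, str, int, str, float], ...] = (
    ("FAN1", 120, "K", "MLH1", 400, "K", 28.5),
    ("FAN1", 126, "S", "MLH1", 87, "S", 25.0),
    ("FAN1", 128, "Y", "MLH1", 550, "T", 31.2),
    ("MLH1", 400, "K", "FAN1", 120, "K", 27.0),   # duplicate, swapped sides
    ("FAN1", 1, "M", "PMS2", 77, "K", 22.0),      # N-terminal crosslink
    ("FAN1", 122, "K", "PMS2", 130, "S", 24.1),
    ("FAN1", 131, "S", "PMS2", 210, "K", 26.7),
    ("FAN1", 160, "T", "PMS2", 480, "Y", 21.5),
    ("FAN1", 543, "K", "PMS2", 602, "K", 23.3),
    ("FAN1", 700, "Y", "PMS2", 33, "T", 30.9),
    ("FAN1", 539, "K", "FAN1", 646, "S", 35.4),   # intra, structured region
    ("FAN1", 10, "K", "FAN1", 20, "S", 50.0),     # resolvable on toy structure
    ("FAN1", 165, "T", "MLH1", 88, "S", 20.0),    # boundary: excluded by filter
    ("FAN1", 90, "K", "PMS2", 310, "K", 19.9),    # below cutoff
)

#: Toy structure atoms: (chain, res_id, res_name, x, y, z).  A10-A20 CA
#: distance is exactly 5.0 A (3-4-5 triangle).
_TOY_ATOMS = (
    ("A", 10, "LYS", 0.0, 0.0, 0.0),
    ("A", 20, "SER", 3.0, 4.0, 0.0),
    ("A", 30, "TYR", 10.0, 0.0, 0.0),
    ("B", 5, "LYS", 0.0, 0.0, 12.0),
    ("B", 50, "THR", 30.0, 40.0, 0.0),
)


def toy_structure_atoms():
    """The toy multi-chain Calpha-only structure as an atom array."""
    n = len(_TOY_ATOMS)
    atoms = struc.AtomArray(n)
    atoms.coord = np.array([a[3:] for a in _TOY_ATOMS], dtype=float)
    atoms.chain_id = np.array([a[0] for a in _TOY_ATOMS])
    atoms.res_id = np.array([a[1] for a in _TOY_ATOMS])
    atoms.res_name = np.array([a[2] for a in _TOY_ATOMS])
    atoms.atom_name = np.array(["CA"] * n)
    atoms.element = np.array(["C"] * n)
    return atoms


def make_xlink_fixture(out_dir: str | Path, seed: int = 0) -> XlinkFixture:
    """Write a crosslink TSV, a toy PDB structure and a chain map YAML.

    Content is fixed (the fixture is a constructed truth table, not a
    random draw); ``seed`` is accepted for interface symmetry.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    links_path = out_dir / "links.tsv"
    header = "protein1\tresidue1\taa1\tprotein2\tresidue2\taa2\tscore\n"
    lines = [
        f"{p1}\t{r1}\t{a1}\t{p2}\t{r2}\t{a2}\t{s:g}\n"
        for p1, r1, a1, p2, r2, a2, s in _XLINK_ROWS
    ]
    links_path.write_text(header + "".join(lines))

    structure_path = out_dir / "toy_structure.pdb"
    pdb_file = _pdbio.PDBFile()
    pdb_file.set_structure(toy_structure_atoms())
    pdb_file.write(structure_path)

    map_path = out_dir / "toy_map.yaml"
    map_path.write_text(
        "structure_id: TOY\n"
        "chains:\n"
        "  A: {protein: FAN1, offset: 0}\n"
        "  B: {protein: MLH1, offset: 0}\n"
    )

    records = tuple(
        CrosslinkRecord(
            protein_a=p1, res_a=r1, residue_letter_a=a1,
            protein_b=p2, res_b=r2, residue_letter_b=a2, score=s,
        )
        for p1, r1, a1, p2, r2, a2, s in _XLINK_ROWS
    )
    return XlinkFixture(
        links_path=links_path, structure_path=structure_path,
        map_path=map_path, records=records,
    )
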