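"""Crosslink-table post-processing, structural distance validation, and
sequence utilities (consensus profiles, motif scan, span arithmetic).

Crosslink identifications arrive as tab-delimited tables of residue pairs
with scores (one row per identification).  Post-processing keeps records
scoring strictly above a cutoff, counts unique residue pairs per
unordered protein pair, and - where a structure covers both residues -
measures the Calpha-Calpha Euclidean distance and flags it against the
maximal span of the crosslinker (default 30 A, appropriate for an
amine-reactive ~11 A spacer such as BS3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio import AlignIO

from biotite.structure.io import pdb as _pdbio
from biotite.structure.io import pdbx as _pdbxio

from .errors import FormatError, MappingError, ParameterError

#: Residue types the amine-reactive crosslinker can attach to (plus the
#: protein N terminus, position 1).
LINKABLE = frozenset("KSTY")

#: Default maximal Calpha-Calpha distance (A) considered consistent with
#: the crosslinker span.
MAX_CONSISTENT_DISTANCE = 30.0

XLINK_COLUMNS = {
    "protein_a": "protein1",
    "res_a": "residue1",
    "letter_a": "aa1",
    "protein_b": "protein2",
    "res_b": "residue2",
    "letter_b": "aa2",
    "score": "score",
}


@dataclass(frozen=True)
class CrosslinkRecord:
    """One crosslinked residue-pair identification."""

    protein_a: str
    res_a: int
    protein_b: str
    res_b: int
    score: float
    residue_letter_a: str | None = None
    residue_letter_b: str | None = None

    def __post_init__(self) -> None:
        if self.res_a < 1 or self.res_b < 1:
            raise ValueError("residue positions are 1-based (>= 1)")

    @property
    def kind(self) -> str:
        return "intra" if self.protein_a == self.protein_b else "inter"

    def linkability_warnings(self) -> list[str]:
        """Sides whose residue letter is not a linkable type (and not the
        N-terminal position)."""
        out = []
        for pos, letter, side in (
            (self.res_a, self.residue_letter_a, "a"),
            (self.res_b, self.residue_letter_b, "b"),
        ):
            if letter is not None and letter not in LINKABLE and pos != 1:
                out.append(f"side {side}: residue {letter}{pos} is not linkable")
        return out


@dataclass(frozen=True)
class ChainAssignment:
    protein: str
    offset: int = 0  # structure residue number = sequence position + offset


@dataclass(frozen=True)
class StructureMap:
    """Chain-to-protein assignments with per-chain numbering offsets."""

    structure_id: str
    chains: dict[str, ChainAssignment] = field(default_factory=dict)

    def chain_for(self, protein: str) -> tuple[str, ChainAssignment]:
        for chain_id in sorted(self.chains):
            if self.chains[chain_id].protein == protein:
                return chain_id, self.chains[chain_id]
        raise MappingError(f"protein {protein!r} not mapped to any chain")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StructureMap":
        cfg = yaml.safe_load(Path(path).read_text())
        chains = {
            str(cid): ChainAssignment(
                protein=str(entry["protein"]), offset=int(entry.get("offset", 0))
            )
            for cid, entry in cfg["chains"].items()
        }
        return cls(structure_id=str(cfg.get("structure_id", "")), chains=chains)


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-column consensus residue and non-gap consensus fraction."""

    residues: tuple[str | None, ...]
    fractions: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# crosslink tables


def read_crosslinks(
    path: str | Path,
    columns: dict[str, str] | None = None,
    warn: list[str] | None = None,
) -> list[CrosslinkRecord]:
    """Read a tab-delimited crosslink identification table.

    ``columns`` overrides the default header mapping (see
    :data:`XLINK_COLUMNS`); residue-letter columns are optional.  Records
    whose residue letters violate the linkability rule are kept but their
    warnings are appended to ``warn``.
    """
    cols = dict(XLINK_COLUMNS, **(columns or {}))
    df = pd.read_csv(path, sep="\t")
    needed = [cols[k] for k in ("protein_a", "res_a", "protein_b", "res_b", "score")]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing crosslink column(s) {missing}")
    has_letters = cols["letter_a"] in df.columns and cols["letter_b"] in df.columns
    records = []
    for _, row in df.iterrows():
        rec = CrosslinkRecord(
            protein_a=str(row[cols["protein_a"]]),
            res_a=int(row[cols["res_a"]]),
            protein_b=str(row[cols["protein_b"]]),
            res_b=int(row[cols["res_b"]]),
            score=float(row[cols["score"]]),
            residue_letter_a=str(row[cols["letter_a"]]) if has_letters else None,
            residue_letter_b=str(row[cols["letter_b"]]) if has_letters else None,
        )
        if warn is not None:
            warn.extend(rec.linkability_warnings())
        records.append(rec)
    return records


def filter_by_score(
    records: Iterable[CrosslinkRecord], min_score: float = 20.0
) -> list[CrosslinkRecord]:
    """Keep records scoring *strictly* above ``min_score``."""
    return [r for r in records if r.score > min_score]


def _pair_key(rec: CrosslinkRecord):
    sides = sorted([(rec.protein_a, rec.res_a), (rec.protein_b, rec.res_b)])
    return (sides[0][0], sides[1][0]), (sides[0], sides[1])


def count_pairs(records: Iterable[CrosslinkRecord]) -> dict[tuple[str, str], int]:
    """Unique residue-pair count per unordered protein pair.

    Duplicate identifications of the same residue pair (in either
    orientation) count once.
    """
    seen: dict[tuple[str, str], set] = {}
    for rec in records:
        proteins, respair = _pair_key(rec)
        seen.setdefault(proteins, set()).add(respair)
    return {proteins: len(pairs) for proteins, pairs in seen.items()}


# ---------------------------------------------------------------------------
# structures


def load_structure(path: str | Path):
    """Load the first model of a PDB or mmCIF file as an atom array."""
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        f = _pdbxio.CIFFile.read(path)
        return _pdbxio.get_structure(f, model=1)
    f = _pdbio.PDBFile.read(path)
    return f.get_structure(model=1)


def map_distance(
    record: CrosslinkRecord,
    atoms,
    smap: StructureMap,
) -> float | None:
    """Calpha-Calpha Euclidean distance (A) of a crosslinked pair, or
    ``None`` when either residue is unresolved in the structure.

    Residue positions are sequence (1-based) coordinates; the per-chain
    offsets in ``smap`` bridge to the structure's author numbering.  A
    protein with no chain assignment raises :class:`MappingError`; a
    mapped residue simply missing from the coordinates (disordered or
    outside the construct) returns ``None``.
    """
    coords = []
    for protein, pos in (
        (record.protein_a, record.res_a),
        (record.protein_b, record.res_b),
    ):
        chain_id, assignment = smap.chain_for(protein)
        res_num = pos + assignment.offset
        mask = (
            (atoms.chain_id == chain_id)
            & (atoms.res_id == res_num)
            & (atoms.atom_name == "CA")
        )
        if not mask.any():
            return None
        coords.append(atoms.coord[mask][0])
    return float(np.linalg.norm(coords[0] - coords[1]))


def flag_consistency(
    distance: float, max_dist: float = MAX_CONSISTENT_DISTANCE
) -> bool:
    """True iff the measured distance is within the crosslinker span
    (boundary inclusive)."""
    if distance < 0:
        raise ParameterError("distance must be >= 0")
    return distance <= max_dist


# ---------------------------------------------------------------------------
# sequences


GAP_CHARS = frozenset("-.")


def consensus_profile(alignment) -> ConsensusProfile:
    """Per-column consensus of a multiple sequence alignment.

    ``alignment`` is a FASTA path or a Biopython alignment object.  For
    each column the most frequent non-gap residue is reported with its
    fraction of non-gap rows (ties break alphabetically for determinism);
    all-gap columns yield ``(None, 0.0)``.
    """
    if isinstance(alignment, (str, Path)):
        try:
            alignment = AlignIO.read(str(alignment), "fasta")
        except ValueError as exc:
            raise FormatError(f"not a valid alignment: {exc}") from exc
    rows = [str(rec.seq).upper() for rec in alignment]
    if len(rows) < 2:
        raise FormatError("alignment needs >= 2 sequences")
    if len({len(r) for r in rows}) != 1:
        raise FormatError("ragged alignment (unequal sequence lengths)")
    residues: list[str | None] = []
    fractions: list[float] = []
    for col in zip(*rows):
        letters = [c for c in col if c not in GAP_CHARS]
        if not letters:
            residues.append(None)
            fractions.append(0.0)
            continue
        counts: dict[str, int] = {}
        for c in letters:
            counts[c] = counts.get(c, 0) + 1
        best = min(counts, key=lambda c: (-counts[c], c))
        residues.append(best)
        fractions.append(counts[best] / len(letters))
    return ConsensusProfile(residues=tuple(residues), fractions=tuple(fractions))


def highlight(profile: ConsensusProfile, fraction_threshold: float = 0.80) -> list[int]:
    """1-based columns whose consensus fraction is *strictly* above the
    threshold (all-gap columns are never highlighted)."""
    return [
        i + 1
        for i, (res, frac) in enumerate(zip(profile.residues, profile.fractions))
        if res is not None and frac > fraction_threshold
    ]


def find_motif(sequence: str, motif: str = "SPYF") -> list[int]:
    """All 1-based start positions of exact (possibly overlapping) motif
    matches in a protein sequence."""
    if not motif:
        raise ParameterError("motif must be non-empty")
    seq = str(sequence).upper()
    motif = motif.upper()
    hits = []
    start = seq.find(motif)
    while start != -1:
        hits.append(start + 1)
        start = seq.find(motif, start + 1)
    return hits


def span_length(start: int, end: int) -> int:
    """Length in residues of a 1-based inclusive span."""
    if start < 1 or start > end:
        raise ParameterError(f"invalid span ({start}, {end})")
    return end - start + 1
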