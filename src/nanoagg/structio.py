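"""PDB structure ingestion and mapping onto IMGT numbering.

Builds the atom/residue model the biophysics layer consumes: heavy atoms
only, one alternate location per atom (highest occupancy, first-in-file on
ties), element-wise van der Waals radii from a fixed table, and a
hydrophobicity flag per atom (side-chain C/S not bonded to N or O).
Structures come from any predictor; only a single polypeptide chain is
scored, and residues are matched to the numbered sequence by alignment so
author numbering is irrelevant.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
import gemmi
import numpy as np
from Bio import Align

from .annotate import NumberedDomain
from .config import HYDROPHOBIC_ATOMS, THREE_TO_ONE, VDW_RADII

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureError(ValueError):
    """Raised for unusable structure files or failed sequence mapping."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    vdw_radius: float
    is_hydrophobic: bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError("vdW radius must be positive")


@dataclasses.dataclass
class StructResidue:
    chain_id: str
    author_seq_id: int
    insertion_code: str
    amino_acid: str          # one-letter code
    residue_name: str        # three-letter PDB name
    atoms: list[Atom]
    imgt_position: int | None = None
    imgt_insertion: str = ""

    @property
    def imgt_label(self) -> str | None:
        if self.imgt_position is None:
            return None
        return f"{self.imgt_position}{self.imgt_insertion}"

    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]


@dataclasses.dataclass
class DomainStructure:
    residues: list[StructResidue]
    source: str = ""

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def by_imgt(self) -> dict[str, StructResidue]:
        return {r.imgt_label: r for r in self.residues if r.imgt_position is not None}


def _is_hydrophobic(residue_name: str, atom_name: str) -> bool:
    return atom_name in HYDROPHOBIC_ATOMS.get(residue_name, frozenset())


def _pick_altlocs(raw: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """One atom per name: highest occupancy, first in file on ties."""
    best: dict[str, gemmi.Atom] = {}
    for atom in raw:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of the winners
    chosen = set(id(a) for a in best.values())
    return [a for a in raw if id(a) in chosen]


def read_structure(pdb_source: str | Path, chain: str | None = None) -> DomainStructure:
    """Parse a PDB file into a single-chain heavy-atom :class:`DomainStructure`.

    HETATM records are ignored except selenomethionine (MSE -> MET);
    hydrogens are dropped; unknown residue types are skipped with a warning;
    only the first model of a multi-model file is read.
    """
    st = gemmi.read_structure(str(pdb_source))
    if len(st) == 0:
        raise StructureError(f"{pdb_source}: no models")
    if len(st) > 1:
        logger.warning("%s: %d models; using the first", pdb_source, len(st))
    model = st[0]
    chains = [ch for ch in model if any(r.name in THREE_TO_ONE or r.name == "MSE" for r in ch)]
    if not chains:
        raise StructureError(f"{pdb_source}: no protein chain")
    if chain is not None:
        chains = [ch for ch in chains if ch.name == chain]
        if not chains:
            raise StructureError(f"{pdb_source}: chain {chain!r} not found")
    if len(chains) > 1:
        raise StructureError(
            f"{pdb_source}: multiple protein chains ({[c.name for c in chains]}); specify one"
        )
    picked = chains[0]

    residues: list[StructResidue] = []
    for res in picked:
        name = res.name
        if res.het_flag == "H" and name != "MSE":
            continue
        if name == "MSE":
            name = "MET"
        if name not in THREE_TO_ONE:
            logger.warning("%s: skipping unknown residue %s %s", pdb_source, res.name, res.seqid)
            continue
        atoms: list[Atom] = []
        heavy = [a for a in res if a.element.name not in ("H", "D")]
        for ga in _pick_altlocs(heavy):
            element = ga.element.name.upper()
            if element == "SE":  # selenomethionine: treat selenium as sulfur
                element = "S"
            radius = VDW_RADII.get(element)
            if radius is None:
                logger.warning("%s: no vdW radius for element %s; atom %s skipped",
                               pdb_source, element, ga.name)
                continue
            atom_name = ga.name if res.name != "MSE" else ga.name.replace("SE", "SD")
            atoms.append(Atom(
                name=atom_name,
                element=element,
                coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                vdw_radius=radius,
                is_hydrophobic=_is_hydrophobic(name, atom_name),
            ))
        if not atoms:
            logger.warning("%s: residue %s has no usable heavy atoms; skipped", pdb_source, res.seqid)
            continue
        residues.append(StructResidue(
            chain_id=picked.name,
            author_seq_id=res.seqid.num,
            insertion_code=(res.seqid.icode or "").strip(),
            amino_acid=THREE_TO_ONE[name],
            residue_name=name,
            atoms=atoms,
        ))
    if not residues:
        raise StructureError(f"{pdb_source}: no standard residues parsed")
    return DomainStructure(residues=residues, source=str(pdb_source))


def write_structure(structure: DomainStructure, path: str | Path) -> None:
    """Write the atom model as a minimal fixed-precision PDB file."""
    lines: list[str] = []
    serial = 0
    for res in structure.residues:
        for atom in res.atoms:
            serial += 1
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {res.residue_name:<3s} "
                f"{res.chain_id:1s}{res.author_seq_id:4d}{res.insertion_code or ' ':1s}   "
                f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _align(struct_seq: str, domain_seq: str) -> tuple[list[tuple[int, int]], float]:
    """Aligned index pairs (structure, domain) and identity.

    End gaps are free, so truncated structures and fusion constructs align
    on the shared domain; identity is therefore normalised by the shorter
    sequence length rather than the aligned span, which a partial core
    match could otherwise saturate.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    alignment = aligner.align(struct_seq, domain_seq)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (s_lo, s_hi), (d_lo, d_hi) in zip(*alignment.aligned):
        for si, di in zip(range(s_lo, s_hi), range(d_lo, d_hi)):
            pairs.append((si, di))
            if struct_seq[si] == domain_seq[di]:
                matches += 1
    identity = matches / min(len(struct_seq), len(domain_seq))
    return pairs, identity


def map_to_numbering(structure: DomainStructure, domain: NumberedDomain) -> DomainStructure:
    """Attach IMGT positions to structure residues by sequence alignment.

    Requires >= 95% identity over the aligned span; on failure the alignment
    statistics are reported.  Residues outside the aligned span keep
    ``imgt_position`` unset, which also trims fusion partners down to the
    VHH domain.
    """
    pairs, identity = _align(structure.sequence, domain.sequence)
    if not pairs or identity < 0.95:
        raise StructureError(
            f"structure/domain sequence identity {identity:.2%} over "
            f"{len(pairs)} aligned residues is below the 95% requirement"
        )
    mapped = DomainStructure(
        residues=[dataclasses.replace(r, atoms=list(r.atoms)) for r in structure.residues],
        source=structure.source,
    )
    for si, di in pairs:
        res = mapped.residues[si]
        dres = domain.residues[di]
        if res.amino_acid == dres.amino_acid:
            res.imgt_position = dres.imgt_position
            res.imgt_insertion = dres.insertion_code
    return mapped
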