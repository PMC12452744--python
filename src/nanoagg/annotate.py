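"""IMGT numbering of VHH sequences and framework-region extraction.

A VHH (nanobody) variable domain is numbered under the IMGT unique scheme:
FR1 1-26, CDR1 27-38, FR2 39-55, CDR2 56-65, FR3 66-104, CDR3 105-117
(insertions beyond 13 residues carried on position 111), FR4 118-128.
Positions 39-55 form framework region 2 (FR2); together with position 118
(first FR4 residue) they constitute the "former VH:VL interface" — the
solvent-exposed patch that in conventional VH domains packs against the
light chain, and the surface the aggregation score analyses.

Two numbering paths are provided: a lightweight builtin anchor aligner
(conserved Cys23/Cys104, the conserved Trp41, and the FR4 W/R-G-x-G motif
locating position 118) and ingestion of an externally produced numbering
table (e.g. reshaped ANARCI output).  The builtin path assumes indel-free
framework regions; domains with framework deletions are supplied through
the external table.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
from Bio import SeqIO

from .config import CANONICAL_AA

logger = logging.getLogger(__name__)

_REGION_BOUNDS = (
    ("FR1", 1, 26),
    ("CDR1", 27, 38),
    ("FR2", 39, 55),
    ("CDR2", 56, 65),
    ("FR3", 66, 104),
    ("CDR3", 105, 117),
    ("FR4", 118, 128),
)

FR2_POSITIONS = frozenset(range(39, 56))
INTERFACE_POSITIONS = frozenset(range(39, 56)) | {118}


class NumberingError(ValueError):
    """Raised when a sequence cannot be assigned IMGT numbers."""


def region_of(imgt_position: int) -> str:
    """Region label for an IMGT position (positions past 128 stay FR4)."""
    for name, lo, hi in _REGION_BOUNDS:
        if lo <= imgt_position <= hi:
            return name
    if imgt_position > 128:
        return "FR4"
    raise ValueError(f"IMGT position out of range: {imgt_position}")


@dataclasses.dataclass(frozen=True, order=True)
class AnnotatedResidue:
    imgt_position: int
    insertion_code: str  # "" when absent; single letter otherwise
    amino_acid: str
    region: str = dataclasses.field(compare=False)

    def __post_init__(self) -> None:
        if self.amino_acid not in CANONICAL_AA:
            raise ValueError(f"non-canonical residue {self.amino_acid!r}")
        if self.insertion_code and (len(self.insertion_code) != 1 or not self.insertion_code.isalpha()):
            raise ValueError(f"bad insertion code {self.insertion_code!r}")
        if self.region != region_of(self.imgt_position):
            raise ValueError(
                f"region {self.region} inconsistent with IMGT position {self.imgt_position}"
            )

    @property
    def label(self) -> str:
        return f"{self.imgt_position}{self.insertion_code}"


@dataclasses.dataclass(frozen=True)
class NumberedDomain:
    """An IMGT-numbered VHH domain: ordered residues plus a source id."""

    residues: tuple[AnnotatedResidue, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        keys = [(r.imgt_position, r.insertion_code) for r in self.residues]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("IMGT positions must be strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def fr2_sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues if r.region == "FR2")


@dataclasses.dataclass(frozen=True)
class RegionSpec:
    """Position sets defining FR2 and the former VH:VL interface."""

    fr2_positions: frozenset[int] = FR2_POSITIONS
    interface_positions: frozenset[int] = INTERFACE_POSITIONS

    def __post_init__(self) -> None:
        if self.interface_positions != self.fr2_positions | {118}:
            raise ValueError("interface must equal FR2 plus position 118")


def _check_sequence(sequence: str) -> str:
    sequence = sequence.strip().upper()
    for offset, aa in enumerate(sequence):
        if aa not in CANONICAL_AA:
            raise NumberingError(f"non-canonical character {aa!r} at offset {offset}")
    return sequence


def _loop_positions(length: int, lo: int, hi: int) -> list[tuple[int, str]]:
    """IMGT loop numbering: fill from both ends toward a middle gap.

    For loops longer than the span, extra residues carry ascending insertion
    letters on the anchor position floor((lo+hi)/2) (position 111 for CDR3).
    """
    span = hi - lo + 1
    if length <= span:
        n_front = (length + 1) // 2
        n_back = length - n_front
        front = [(lo + i, "") for i in range(n_front)]
        back = [(hi - n_back + 1 + i, "") for i in range(n_back)]
        return front + back
    extra = length - span
    if extra > 26:
        raise NumberingError(f"loop of length {length} exceeds insertion capacity")
    anchor = (lo + hi) // 2
    out = [(p, "") for p in range(lo, anchor + 1)]
    out += [(anchor, chr(ord("A") + i)) for i in range(extra)]
    out += [(p, "") for p in range(anchor + 1, hi + 1)]
    return out


def _number_builtin(sequence: str, source_id: str) -> NumberedDomain:
    seq = sequence
    if not 90 <= len(seq) <= 170:
        raise NumberingError(
            f"sequence length {len(seq)} outside the 90-170 range of a VHH domain"
        )
    # First conserved cysteine -> IMGT 23.
    cys23_candidates = [i for i in range(10, min(35, len(seq))) if seq[i] == "C"]
    if not cys23_candidates:
        raise NumberingError("missing first conserved cysteine anchor (IMGT 23)")
    i23 = cys23_candidates[0]
    # FR4 anchor: W118 (R in ~10% of VHHs) followed by the G-x-G motif.
    i118 = -1
    for i in range(len(seq) - 4, max(len(seq) - 20, i23), -1):
        if seq[i] in "WRF" and seq[i + 1] == "G" and seq[i + 3] == "G":
            i118 = i
            break
    if i118 < 0:
        raise NumberingError("cannot locate the FR4 [WRF]GxG motif (IMGT 118)")
    # Second conserved cysteine -> IMGT 104; the earliest Cys far enough from
    # Cys23 to hold CDR1+FR2+CDR2+FR3, so non-canonical CDR3 cysteines
    # (the CDR1:CDR3 disulfide common in camelid VHHs) are not mistaken for it.
    c104_candidates = [
        i for i in range(i23 + 60, i118 - 4) if seq[i] == "C"
    ]
    if not c104_candidates:
        raise NumberingError("missing second conserved cysteine anchor (IMGT 104)")
    i104 = c104_candidates[0]
    i66 = i104 - 38  # FR3 spans IMGT 66-104 as 39 contiguous residues
    if i66 <= i23 + 4:
        raise NumberingError("second cysteine anchor too close to the first")
    # Conserved Trp41: a Trp two residues into FR2, constrained so CDR2
    # (between position 55 and 66) keeps a plausible 3-10 residue length.
    w_candidates = [
        i for i in range(max(i23 + 4, i66 - 25), i66 - 17) if seq[i] == "W"
    ]
    if w_candidates:
        i41 = w_candidates[0]
    else:
        i41 = i66 - 23  # canonical 8-residue CDR2 fallback
        logger.warning("%s: conserved Trp41 not found; assuming 8-residue CDR2", source_id)
    i39 = i41 - 2
    if i39 <= i23 + 3:
        raise NumberingError("FR2 anchor overlaps FR1")

    assignments: list[tuple[int, str]] = []
    n_fr1 = i23 + 4  # residues through IMGT 26
    if n_fr1 > 26:
        raise NumberingError(f"FR1 of {n_fr1} residues exceeds IMGT positions 1-26")
    assignments += [(26 - n_fr1 + 1 + i, "") for i in range(n_fr1)]
    assignments += _loop_positions(i39 - (i23 + 4), 27, 38)          # CDR1
    assignments += [(39 + i, "") for i in range(17)]                 # FR2 39-55
    assignments += _loop_positions(i66 - (i39 + 17), 56, 65)         # CDR2
    assignments += [(66 + i, "") for i in range(39)]                 # FR3 66-104
    assignments += _loop_positions(i118 - (i104 + 1), 105, 117)      # CDR3
    assignments += [(118 + i, "") for i in range(len(seq) - i118)]   # FR4
    if len(assignments) != len(seq):
        raise NumberingError("internal numbering inconsistency")
    residues = tuple(
        AnnotatedResidue(pos, icode, aa, region_of(pos))
        for (pos, icode), aa in zip(assignments, seq)
    )
    return NumberedDomain(residues=residues, source_id=source_id)


def read_numbering_table(path: str | Path) -> pd.DataFrame:
    """Read an external numbering CSV.

    Columns: ``source_id, imgt_position, insertion_code, amino_acid`` —
    the dialect common antibody-numbering tools produce after reshaping.
    """
    df = pd.read_csv(path, dtype={"insertion_code": str}, keep_default_na=False)
    required = {"source_id", "imgt_position", "insertion_code", "amino_acid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"numbering table missing columns: {sorted(missing)}")
    return df


def _number_from_table(sequence: str, source_id: str, table: pd.DataFrame) -> NumberedDomain:
    rows = table[table["source_id"] == source_id]
    if rows.empty:
        raise NumberingError(f"no numbering rows for {source_id!r} in external table")
    residues = tuple(
        AnnotatedResidue(
            int(row.imgt_position),
            str(row.insertion_code).strip(),
            str(row.amino_acid).strip().upper(),
            region_of(int(row.imgt_position)),
        )
        for row in rows.itertuples()
    )
    domain = NumberedDomain(residues=residues, source_id=source_id)
    if domain.sequence != sequence:
        raise NumberingError(
            f"external numbering for {source_id!r} does not spell the input sequence"
        )
    return domain


def number_sequence(
    sequence: str,
    mode: Literal["builtin", "external_table"] = "builtin",
    *,
    source_id: str = "",
    table: pd.DataFrame | None = None,
) -> NumberedDomain:
    """Assign IMGT numbers to a VHH amino-acid sequence.

    ``builtin`` uses the anchor-based aligner; ``external_table`` requires a
    numbering table from :func:`read_numbering_table` and validates that it
    spells the input sequence.
    """
    seq = _check_sequence(sequence)
    if mode == "builtin":
        domain = _number_builtin(seq, source_id)
    elif mode == "external_table":
        if table is None:
            raise ValueError("external_table mode requires a numbering table")
        domain = _number_from_table(seq, source_id, table)
    else:
        raise ValueError(f"unknown numbering mode {mode!r}")
    fr2_len = sum(1 for r in domain.residues if r.region == "FR2")
    if fr2_len > 17:
        raise NumberingError(f"FR2 holds {fr2_len} residues; at most 17 are allowed")
    return domain


def extract_region(
    domain: NumberedDomain,
    spec: RegionSpec = RegionSpec(),
    which: Literal["fr2", "interface"] = "fr2",
) -> list[AnnotatedResidue]:
    """Residues of the domain falling in FR2 or the former VH:VL interface.

    Absent positions (framework deletions, missing 118) are silently
    omitted; an interface extraction lacking position 118 logs a warning.
    An empty result raises — a VHH without FR2 residues is malformed.
    """
    positions = spec.fr2_positions if which == "fr2" else spec.interface_positions
    picked = [r for r in domain.residues if r.imgt_position in positions]
    if not picked:
        raise ValueError(f"domain {domain.source_id!r} has no residues in {which}")
    if which == "interface" and not any(r.imgt_position == 118 for r in picked):
        logger.warning("%s: position 118 absent; interface reduces to FR2", domain.source_id)
    return picked


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
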