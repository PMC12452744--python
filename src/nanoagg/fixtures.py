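"""Deterministic synthetic inputs for building and testing without downloads.

Everything here is idealized by construction so expectations are analytic:

* sphere clusters — toy structures (isolated atom, contact pair, fully
  caged atom, occluded pair) whose ASA and contact outcomes are known in
  closed form;
* mini domains — a short FR2-labelled polypeptide with an exposed
  hydrophobic face and an optional shielding cap that buries a controlled
  fraction of the FR2 surface, emulating how a CDR3 loop covering the FR2
  patch reduces exposure;
* VHH-like full-length sequences with construction-known IMGT numbering,
  for exercising the sequence numberer against an independent record;
* labelled score datasets realising prescribed confusion-matrix counts;
* FR2 sequence sets with controlled within/between-cluster divergence.

All generation is seed-deterministic; structures are written with
fixed-precision coordinates so regenerated files are byte-identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import AnnotatedResidue, NumberedDomain, region_of
from .config import ONE_TO_THREE, VDW_RADII
from .evaluate import LabeledScore
from .structio import Atom, DomainStructure, StructResidue


def _carbon(name: str, xyz, hydrophobic: bool = True) -> Atom:
    return Atom(name=name, element="C", coords=np.asarray(xyz, dtype=float),
                vdw_radius=VDW_RADII["C"], is_hydrophobic=hydrophobic)


def _oxygen(name: str, xyz) -> Atom:
    return Atom(name=name, element="O", coords=np.asarray(xyz, dtype=float),
                vdw_radius=VDW_RADII["O"], is_hydrophobic=False)


def _single_atom_residue(index: int, atom: Atom, residue_name: str, one_letter: str,
                         imgt: int | None = None) -> StructResidue:
    return StructResidue(
        chain_id="A", author_seq_id=index + 1, insertion_code="",
        amino_acid=one_letter, residue_name=residue_name, atoms=[atom],
        imgt_position=imgt,
    )


def make_sphere_cluster(
    geometry: str,
    spacing: float = 3.5,
    n_atoms: int = 100,
) -> DomainStructure:
    """Toy structures with analytic ASA/contact outcomes.

    ``isolated``: one carbon atom (ASA is the bare expanded-sphere area).
    ``pair``: two hydrophobic CB carbons ``spacing`` Å apart on x.
    ``buried``: a central carbon caged by ``n_atoms`` carbons on a tight
    shell so every surface sample point is covered (ASA 0 for the center).
    ``occluded_pair``: the pair plus a non-hydrophobic oxygen blocker at
    the midpoint, defeating the unobstructed-path test.

    Residues carry IMGT positions 39, 40, ... so contact counting can
    address them directly.
    """
    residues: list[StructResidue] = []
    if geometry == "isolated":
        residues.append(_single_atom_residue(0, _carbon("CB", (0, 0, 0)), "ALA", "A", 39))
    elif geometry == "pair":
        residues.append(_single_atom_residue(0, _carbon("CB", (0, 0, 0)), "ALA", "A", 39))
        residues.append(_single_atom_residue(1, _carbon("CB", (spacing, 0, 0)), "ALA", "A", 40))
    elif geometry == "buried":
        residues.append(_single_atom_residue(0, _carbon("CB", (0, 0, 0)), "ALA", "A", 39))
        from .biophys import unit_sphere_points
        shell = 0.5 * unit_sphere_points(max(n_atoms, 60))
        for i, point in enumerate(shell):
            residues.append(_single_atom_residue(i + 1, _carbon("CB", point), "ALA", "A", 40 + i))
    elif geometry == "occluded_pair":
        residues.append(_single_atom_residue(0, _carbon("CB", (0, 0, 0)), "ALA", "A", 39))
        residues.append(_single_atom_residue(1, _oxygen("OG", (spacing / 2.0, 0, 0)), "SER", "S", 40))
        residues.append(_single_atom_residue(2, _carbon("CB", (spacing, 0, 0)), "ALA", "A", 41))
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return DomainStructure(residues=residues, source=f"sphere_cluster:{geometry}")


def make_mini_domain(
    fr2_seq: str,
    shield: float = 0.0,
    residue_118: str = "W",
) -> tuple[NumberedDomain, DomainStructure]:
    """A small FR2-labelled polypeptide with a controllable shielding cap.

    FR2 residues (IMGT 39 onward) lie along x with Cβ atoms on the exposed
    +z face, spaced so sequence neighbours form hydrophobic contacts;
    residue 118 follows the chain.  ``shield`` ∈ [0, 0.9] adds oxygen cap
    atoms above a growing fraction of the FR2 face, strictly decreasing the
    summed FR2 ASA as it increases.  Deterministic: no randomness anywhere.
    """
    fr2_seq = fr2_seq.upper()
    if not 15 <= len(fr2_seq) <= 17:
        raise ValueError("FR2 sequence must be 15-17 residues")
    if not 0.0 <= shield <= 0.9:
        raise ValueError(f"unrealizable shield fraction {shield}")

    annotated = [
        AnnotatedResidue(39 + i, "", aa, region_of(39 + i)) for i, aa in enumerate(fr2_seq)
    ]
    annotated.append(AnnotatedResidue(118, "", residue_118, "FR4"))
    domain = NumberedDomain(residues=tuple(annotated), source_id=f"mini:{fr2_seq}:{shield:g}")

    pitch, cb_z = 3.8, 2.2
    residues: list[StructResidue] = []
    chain = list(fr2_seq) + [residue_118]
    for i, aa in enumerate(chain):
        x = pitch * i
        name3 = ONE_TO_THREE[aa]
        atoms = [
            Atom("N", "N", (x - 0.5, -1.2, 0.0), VDW_RADII["N"], False),
            Atom("CA", "C", (x, 0.0, 0.0), VDW_RADII["C"], False),
            Atom("C", "C", (x + 0.9, -1.0, 0.6), VDW_RADII["C"], False),
            Atom("O", "O", (x + 1.0, -2.2, 0.7), VDW_RADII["O"], False),
        ]
        if aa != "G":
            from .config import HYDROPHOBIC_ATOMS
            atoms.append(Atom("CB", "C", (x, 0.0, cb_z), VDW_RADII["C"],
                              "CB" in HYDROPHOBIC_ATOMS[name3]))
        imgt = 39 + i if i < len(fr2_seq) else 118
        residues.append(StructResidue(
            chain_id="A", author_seq_id=i + 1, insertion_code="",
            amino_acid=aa, residue_name=name3, atoms=atoms, imgt_position=imgt,
        ))

    # shielding cap: oxygen atoms over the FR2 face, two sites per residue
    n_sites = 2 * len(fr2_seq)
    n_caps = int(round(shield * n_sites))
    for k in range(n_caps):
        x = pitch / 2.0 * k
        residues.append(StructResidue(
            chain_id="A", author_seq_id=len(chain) + k + 1, insertion_code="",
            amino_acid="S", residue_name="SER",
            atoms=[_oxygen("OG", (x, 0.0, cb_z + 2.4))],
        ))
    structure = DomainStructure(residues=residues, source=domain.source_id)
    return domain, structure


# --- VHH-like sequences with construction-known numbering -----------------

_FR1 = "QVQLVESGGGGLVQAGGSLRLSCAAS"          # IMGT 1-26, Cys at 23
_FR3 = "NYADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAAVYYC"  # IMGT 66-104, Cys at 104
_FR4 = "WGQGTQVTVSS"                          # IMGT 118-128, Trp at 118
_FR2_HALLMARK = "ELWFRQAPGKEREGVAA"           # IMGT 39-55; F42/E49/R50/G52 hallmarks
_CDR_ALPHABET = "ADEFGHIKLMNPQRSTVY"          # no Cys (anchor), no Trp (anchor)


def _loop_numbering(length: int, lo: int, hi: int) -> list[tuple[int, str]]:
    """IMGT loop positions by explicit enumeration from both ends."""
    span = hi - lo + 1
    labels: list[tuple[int, str]] = []
    if length <= span:
        for i in range((length + 1) // 2):
            labels.append((lo + i, ""))
        for i in range(length - (length + 1) // 2):
            labels.append((hi - (length - (length + 1) // 2) + 1 + i, ""))
        return labels
    anchor = (lo + hi) // 2
    labels = [(p, "") for p in range(lo, anchor + 1)]
    labels += [(anchor, chr(ord("A") + i)) for i in range(length - span)]
    labels += [(p, "") for p in range(anchor + 1, hi + 1)]
    return labels


def make_vhh_sequence(seed: int) -> tuple[str, pd.DataFrame]:
    """A VHH-like sequence plus its construction-known IMGT numbering table.

    Framework regions are fixed camelid-consensus-like templates; CDR
    lengths and compositions are drawn from the seed.  The returned table
    has columns ``source_id, imgt_position, insertion_code, amino_acid``
    and records the position of every residue as placed at construction
    time, independent of any numbering algorithm.
    """
    rng = np.random.default_rng(seed)
    cdr1 = "".join(rng.choice(list(_CDR_ALPHABET), size=rng.integers(6, 11)))
    cdr2 = "".join(rng.choice(list(_CDR_ALPHABET), size=rng.integers(6, 10)))
    cdr3 = "".join(rng.choice(list(_CDR_ALPHABET), size=rng.integers(5, 17)))
    pieces = [
        (_FR1, [(p, "") for p in range(1, 27)]),
        (cdr1, _loop_numbering(len(cdr1), 27, 38)),
        (_FR2_HALLMARK, [(p, "") for p in range(39, 56)]),
        (cdr2, _loop_numbering(len(cdr2), 56, 65)),
        (_FR3, [(p, "") for p in range(66, 105)]),
        (cdr3, _loop_numbering(len(cdr3), 105, 117)),
        (_FR4, [(p, "") for p in range(118, 129)]),
    ]
    sequence = "".join(seq for seq, _ in pieces)
    sid = f"vhh_synth_{seed}"
    rows = []
    for seq, labels in pieces:
        assert len(seq) == len(labels)
        for aa, (pos, icode) in zip(seq, labels):
            rows.append({"source_id": sid, "imgt_position": pos,
                         "insertion_code": icode, "amino_acid": aa})
    return sequence, pd.DataFrame(rows)


def make_labeled_dataset(
    counts: tuple[int, int, int, int],
    monomer_cut: float = 90.0,
    threshold: float = 1.0,
    seed: int = 0,
) -> list[LabeledScore]:
    """Labelled scores realising exact confusion counts (TP, FN, FP, TN).

    Scores fall in fixed intervals strictly above/below the threshold and
    monomer percentages strictly above/below the cut, so
    :func:`nanoagg.evaluate.confusion` at the same threshold and cut
    reproduces the requested counts exactly.
    """
    tp, fn, fp, tn = counts
    if min(counts) < 0:
        raise ValueError("confusion counts must be non-negative")
    rng = np.random.default_rng(seed)
    lo = max(0.0, threshold - 1.0)
    records: list[LabeledScore] = []
    spec = [
        ("tp", tp, (threshold + 0.05, threshold + 1.0), (monomer_cut, 100.0)),
        ("fn", fn, (lo, max(lo, threshold - 0.05)), (monomer_cut, 100.0)),
        ("fp", fp, (threshold + 0.05, threshold + 1.0), (0.0, max(0.0, monomer_cut - 0.5))),
        ("tn", tn, (lo, max(lo, threshold - 0.05)), (0.0, max(0.0, monomer_cut - 0.5))),
    ]
    i = 0
    for kind, n, score_range, label_range in spec:
        for _ in range(n):
            records.append(LabeledScore(
                id=f"vhh{i:03d}_{kind}",
                aggregation_score=float(rng.uniform(*score_range)),
                monomer_pct=float(rng.uniform(*label_range)),
            ))
            i += 1
    return records


def make_fr2_set(
    n_clusters: int = 3,
    cluster_size: int = 5,
    within_mutations: int = 1,
    between_mutations: int = 5,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """FR2 17-mer sets with controlled within/between-cluster divergence.

    Each cluster descends from its own centroid; centroids differ from the
    hallmark template at ``between_mutations`` positions (pairwise disjoint
    position blocks, so inter-centroid distance is 2×``between_mutations``),
    members differ from their centroid at ``within_mutations`` positions.
    """
    rng = np.random.default_rng(seed)
    base = _FR2_HALLMARK
    out: list[tuple[str, str]] = []
    for c in range(n_clusters):
        centroid = list(base)
        for pos in range(c * between_mutations, (c + 1) * between_mutations):
            pos = pos % len(base)
            centroid[pos] = "Y" if centroid[pos] != "Y" else "T"
        centroid_seq = "".join(centroid)
        for m in range(cluster_size):
            member = list(centroid_seq)
            for pos in rng.choice(len(base), size=within_mutations, replace=False):
                choices = [aa for aa in _CDR_ALPHABET if aa != member[pos]]
                member[pos] = choices[int(rng.integers(len(choices)))]
            out.append((f"c{c}_m{m}", "".join(member)))
    return out
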