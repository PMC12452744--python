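"""Physical ingredients of the aggregation score.

Three quantities are computed on a numbered VHH structure:

* per-residue accessible surface area (ASA, Å²) by the Shrake-Rupley
  method — a deterministic golden-section-spiral point set on each atom's
  solvent-expanded sphere, a point counting as accessible iff it lies
  strictly outside every other atom's expanded sphere;
* per-residue intramolecular hydrophobic contact counts — pairs of
  hydrophobic atoms within a distance cutoff whose connecting segment is
  not obstructed by a third atom's van der Waals sphere;
* the Guruprasad dipeptide instability index of the FR2 substring,
  (10/L) Σ DIWV(x_i, x_{i+1}).

The spiral directions are expressed in a rotation-covariant frame built
from the principal axes of the atom cloud, so ASA is invariant under rigid
motions of the input coordinates (for structures with non-degenerate
principal axes); contact counts are distance-based and always invariant.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .config import CANONICAL_AA, load_diwv_table
from .structio import BACKBONE_ATOMS, DomainStructure

logger = logging.getLogger(__name__)

_GOLDEN_ANGLE = math.pi * (1.0 + math.sqrt(5.0))


@dataclasses.dataclass(frozen=True)
class SASAResult:
    """Accessible surface areas: per atom (structure atom order) and per residue."""

    atom_areas: np.ndarray                 # Å², aligned with structure.atoms()
    residue_areas: tuple[float, ...]       # Å², aligned with structure.residues
    per_residue_asa: Mapping[str, float]   # IMGT label -> Å² (mapped residues only)
    probe_radius: float
    n_points: int


@dataclasses.dataclass(frozen=True)
class ContactResult:
    """Hydrophobic contact counts per target residue (keyed by IMGT position label)."""

    per_residue_contacts: Mapping[str, int]
    cutoff: float
    pairs: tuple[tuple[int, int], ...] = ()   # atom indices of counted pairs


def unit_sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden-section spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * k / n
    polar = np.arccos(np.clip(z, -1.0, 1.0))
    azimuth = _GOLDEN_ANGLE * k
    sin_p = np.sin(polar)
    return np.column_stack((np.cos(azimuth) * sin_p, np.sin(azimuth) * sin_p, z))


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotation-covariant orthonormal frame (rows) from the atom cloud.

    Principal axes of the centered coordinates, each axis signed so that the
    first atom with a non-negligible projection projects positively.  Under
    a rigid motion of the input the frame co-rotates, making sphere sampling
    and hence ASA invariant.  Single atoms or degenerate clouds fall back
    toward the identity frame.
    """
    centered = coords - coords.mean(axis=0)
    if len(coords) < 2 or not np.any(np.abs(centered) > 1e-12):
        return np.eye(3)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axes = vecs.T[::-1].copy()  # descending variance
    for i, axis in enumerate(axes):
        proj = centered @ axis
        idx = np.flatnonzero(np.abs(proj) > 1e-9)
        if idx.size and proj[idx[0]] < 0:
            axes[i] = -axis
    return axes


def compute_sasa(
    structure: DomainStructure,
    probe_radius: float = 1.4,
    n_points: int = 100,
) -> SASAResult:
    """Shrake-Rupley accessible surface area of every atom and residue.

    Each atom's solvent-expanded sphere (radius ``r_vdw + probe``) carries
    ``n_points`` deterministic sample points; a point on or inside any other
    atom's expanded sphere is buried.  Atom ASA is the accessible fraction
    of the expanded sphere's area; residue ASA sums its atoms.
    """
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    atoms = structure.atoms()
    if not atoms:
        raise ValueError("empty structure")
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe_radius

    frame = _canonical_frame(coords)
    sphere = unit_sphere_points(n_points) @ frame  # covariant directions

    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        points = coords[i] + radii[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        if neighbours:
            deltas = points[:, None, :] - coords[neighbours][None, :, :]
            buried = (np.einsum("pjk,pjk->pj", deltas, deltas)
                      <= (radii[neighbours] ** 2)[None, :] + 1e-12).any(axis=1)
            accessible = float(np.count_nonzero(~buried)) / n_points
        else:
            accessible = 1.0
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * accessible

    residue_areas: list[float] = []
    per_imgt: dict[str, float] = {}
    offset = 0
    for res in structure.residues:
        total = float(areas[offset:offset + len(res.atoms)].sum())
        residue_areas.append(total)
        if res.imgt_label is not None:
            per_imgt[res.imgt_label] = total
        offset += len(res.atoms)
    return SASAResult(
        atom_areas=areas,
        residue_areas=tuple(residue_areas),
        per_residue_asa=per_imgt,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def _segment_obstructed(
    a: np.ndarray,
    b: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
) -> bool:
    """True if the open segment a-b passes through any sphere (center, radius)."""
    if centers.size == 0:
        return False
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return False
    t = np.clip((centers - a) @ ab / denom, 0.0, 1.0)
    nearest = a + t[:, None] * ab
    dist2 = np.einsum("ij,ij->i", centers - nearest, centers - nearest)
    return bool(np.any(dist2 < radii ** 2))


def count_hydrophobic_contacts(
    structure: DomainStructure,
    target_positions: Iterable[int],
    cutoff: float = 4.0,
    *,
    occlusion_enabled: bool = True,
    granularity: str = "atom_pair",
) -> ContactResult:
    """Intramolecular hydrophobic contacts for each target IMGT position.

    A contact is a pair (a, b): ``a`` a hydrophobic side-chain atom of the
    target residue, ``b`` a hydrophobic atom of any *other* residue of the
    domain, with ||a-b|| <= cutoff and (when occlusion is enabled) the
    segment between the atom centers not passing through a third atom's
    van der Waals sphere.  ``granularity="residue_pair"`` collapses all
    qualifying atom pairs between two residues to a single contact.
    """
    targets = sorted(set(int(p) for p in target_positions))
    if not targets:
        raise ValueError("target_positions must be nonempty")
    mapped = {r.imgt_position: i for i, r in enumerate(structure.residues)
              if r.imgt_position is not None}
    missing = [p for p in targets if p not in mapped]
    if missing:
        raise ValueError(f"target positions not mapped in structure: {missing}")

    atoms = structure.atoms()
    coords = np.array([a.coords for a in atoms])
    vdw = np.array([a.vdw_radius for a in atoms])
    # atom index -> residue index
    res_of = np.empty(len(atoms), dtype=int)
    offset = 0
    for ri, res in enumerate(structure.residues):
        res_of[offset:offset + len(res.atoms)] = ri
        offset += len(res.atoms)
    hydrophobic = np.array([a.is_hydrophobic for a in atoms])
    side_chain = np.array([a.name not in BACKBONE_ATOMS for a in atoms])

    tree = cKDTree(coords)
    counts: dict[str, int] = {}
    counted_pairs: list[tuple[int, int]] = []
    for pos in targets:
        ri = mapped[pos]
        label = structure.residues[ri].imgt_label or str(pos)
        n_contacts = 0
        partner_residues: set[int] = set()
        own = [i for i in np.flatnonzero((res_of == ri) & hydrophobic & side_chain)]
        for ai in own:
            for bi in tree.query_ball_point(coords[ai], cutoff):
                if res_of[bi] == ri or not hydrophobic[bi]:
                    continue
                if not occlusion_enabled or not _segment_obstructed(
                    coords[ai], coords[bi],
                    np.delete(coords, [ai, bi], axis=0),
                    np.delete(vdw, [ai, bi]),
                ):
                    n_contacts += 1
                    partner_residues.add(int(res_of[bi]))
                    counted_pairs.append((int(ai), int(bi)))
        counts[label] = len(partner_residues) if granularity == "residue_pair" else n_contacts
    return ContactResult(per_residue_contacts=counts, cutoff=cutoff,
                         pairs=tuple(counted_pairs))


def instability_index(
    fr2_sequence: str,
    table: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Guruprasad dipeptide instability index of a sequence: (10/L) Σ DIWV.

    Computed here on the FR2 substring only.  A single residue has no
    dipeptides and scores 0.
    """
    seq = fr2_sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = [aa for aa in seq if aa not in CANONICAL_AA]
    if bad:
        raise ValueError(f"non-canonical residues in sequence: {bad}")
    if table is None:
        table = load_diwv_table()
    total = sum(table[(a, b)] for a, b in zip(seq, seq[1:]))
    return 10.0 / len(seq) * total
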