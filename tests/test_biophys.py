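"""Accessible surface area, hydrophobic contacts, and the instability index.

Oracles: a dense latitude-longitude quadrature for ASA (independent of the
golden-spiral sampler), exhaustive pair enumeration for contacts, and
instability-index values frozen from an independent ProtParam
implementation.
"""

import dataclasses
import math

import numpy as np
import pytest

import nanoagg as na
from conftest import HALLMARK_FR2, random_atom_cluster


# ---------------------------------------------------------------------------
# independent oracles

def sasa_latlong_oracle(structure, probe=1.4, n_theta=100, n_phi=200):
    """Per-atom ASA by latitude-longitude quadrature with sin(θ) weights."""
    atoms = structure.atoms()
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe
    theta = (np.arange(n_theta) + 0.5) * math.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2.0 * math.pi / n_phi
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    directions = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp),
                           np.cos(tt)], axis=-1).reshape(-1, 3)
    weights = np.repeat(np.sin(theta), n_phi)
    weights = weights / weights.sum()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        points = coords[i] + radii[i] * directions
        free = np.ones(len(points), dtype=bool)
        for j in range(len(atoms)):
            if j == i:
                continue
            free &= np.linalg.norm(points - coords[j], axis=1) > radii[j]
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * float(weights[free].sum())
    return areas


def contacts_bruteforce_oracle(structure, targets, cutoff=4.0, occlusion=True):
    """Contact counts by plain nested loops over every atom pair."""
    flat = []
    for ri, res in enumerate(structure.residues):
        for atom in res.atoms:
            flat.append((ri, res, atom))
    counts = {}
    for pos in targets:
        (ri, res) = next((i, r) for i, r in enumerate(structure.residues)
                         if r.imgt_position == pos)
        n = 0
        for a in res.atoms:
            if not a.is_hydrophobic or a.name in ("N", "CA", "C", "O", "OXT"):
                continue
            for rj, _, b in flat:
                if rj == ri or not b.is_hydrophobic:
                    continue
                if np.linalg.norm(a.coords - b.coords) > cutoff:
                    continue
                if occlusion:
                    blocked = False
                    for rk, _, c in flat:
                        if c is a or c is b:
                            continue
                        ab = b.coords - a.coords
                        t = float(np.dot(c.coords - a.coords, ab) / np.dot(ab, ab))
                        t = min(1.0, max(0.0, t))
                        if np.linalg.norm(c.coords - (a.coords + t * ab)) < c.vdw_radius:
                            blocked = True
                            break
                    if blocked:
                        continue
                n += 1
        counts[str(pos)] = n
    return counts


def rigid_transform(structure, rotation, translation):
    return na.DomainStructure(
        residues=[dataclasses.replace(
            r, atoms=[dataclasses.replace(a, coords=rotation @ a.coords + translation)
                      for a in r.atoms])
            for r in structure.residues],
        source=structure.source,
    )


def rotation_matrix(angles_deg):
    a, b, c = np.deg2rad(angles_deg)
    rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    rx = np.array([[1, 0, 0], [0, np.cos(c), -np.sin(c)], [0, np.sin(c), np.cos(c)]])
    return rz @ ry @ rx


# ---------------------------------------------------------------------------
# ASA

class TestSASA:
    def test_isolated_carbon_is_analytic(self):
        """A lone carbon with a 1.4 Å probe exposes the full expanded sphere,
        4π(1.70+1.4)² ≈ 120.76 Å², within 1% at 100 points."""
        st = na.make_sphere_cluster("isolated")
        result = na.compute_sasa(st, probe_radius=1.4, n_points=100)
        expected = 4.0 * math.pi * 3.1 ** 2
        assert result.atom_areas[0] == pytest.approx(expected, rel=0.01)

    def test_fully_caged_atom_has_zero_area(self):
        st = na.make_sphere_cluster("buried")
        assert na.compute_sasa(st).atom_areas[0] == 0.0

    def test_carbon_pair_matches_dense_quadrature(self):
        """Per-atom ASA of two carbons 2.0 Å apart agrees with the ~20k-point
        latitude-longitude quadrature oracle within 2% at 100 points."""
        st = na.make_sphere_cluster("pair", spacing=2.0)
        mine = na.compute_sasa(st, n_points=100).atom_areas
        oracle = sasa_latlong_oracle(st)
        np.testing.assert_allclose(mine, oracle, rtol=0.02)

    @pytest.mark.parametrize("spacing", [2.0, 3.0, 3.4])
    def test_carbon_pair_converges_to_closed_form(self, spacing):
        """Two equal spheres bury a spherical cap of half-angle arccos(d/2R)
        on each other; at 2000 points the sampler is within 0.5% of the
        closed form, and the quadrature oracle agrees too."""
        st = na.make_sphere_cluster("pair", spacing=spacing)
        radius = 1.70 + 1.4
        buried_fraction = (1.0 - spacing / (2.0 * radius)) / 2.0
        exact = 4.0 * math.pi * radius ** 2 * (1.0 - buried_fraction)
        fine = na.compute_sasa(st, n_points=2000).atom_areas
        np.testing.assert_allclose(fine, exact, rtol=0.005)
        np.testing.assert_allclose(sasa_latlong_oracle(st), exact, rtol=0.005)

    def test_mini_domain_cross_checked_against_biotite(self, mini_domain, tmp_path):
        """Per-residue ASA agrees with an independent Shrake-Rupley
        implementation (biotite, element radii) within 2% at 1000 points."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as biotite_pdb

        _, st = mini_domain
        path = tmp_path / "mini.pdb"
        na.write_structure(st, path)
        arr = biotite_pdb.PDBFile.read(str(path)).get_structure(model=1)
        theirs = struc.apply_residue_wise(
            arr, struc.sasa(arr, probe_radius=1.4, point_number=1000,
                            vdw_radii="Single"),
            np.nansum,
        )
        mine = np.array(na.compute_sasa(st, n_points=1000).residue_areas)
        np.testing.assert_allclose(mine, theirs, rtol=0.02)

    def test_mini_domain_matches_dense_quadrature(self, mini_domain):
        """Residue ASA on a multi-residue structure agrees with the
        independent latitude-longitude quadrature within 3%."""
        _, st = mini_domain
        mine = na.compute_sasa(st, n_points=1000)
        oracle = sasa_latlong_oracle(st, n_theta=60, n_phi=120)
        offset = 0
        oracle_res = []
        for res in st.residues:
            oracle_res.append(oracle[offset:offset + len(res.atoms)].sum())
            offset += len(res.atoms)
        np.testing.assert_allclose(np.array(mine.residue_areas),
                                   np.array(oracle_res), rtol=0.03)

    def test_convergence_from_100_to_1000_points(self, mini_domain):
        _, st = mini_domain
        coarse = np.array(na.compute_sasa(st, n_points=100).residue_areas)
        fine = np.array(na.compute_sasa(st, n_points=1000).residue_areas)
        assert np.all(np.abs(coarse - fine) <= 0.05 * np.maximum(fine, 1.0))

    def test_rigid_motion_invariance(self, mini_domain):
        _, st = mini_domain
        moved = rigid_transform(st, rotation_matrix((31, -57, 113)),
                                np.array([11.0, -3.0, 42.0]))
        np.testing.assert_allclose(
            na.compute_sasa(st).atom_areas, na.compute_sasa(moved).atom_areas,
            rtol=1e-9,
        )

    def test_adding_an_atom_never_increases_asa(self):
        """Monotonicity: every other atom's ASA can only shrink."""
        st = na.make_sphere_cluster("pair", spacing=3.0)
        before = na.compute_sasa(st).atom_areas
        blocker = na.StructResidue(
            chain_id="A", author_seq_id=99, insertion_code="", amino_acid="A",
            residue_name="ALA",
            atoms=[na.Atom("CB", "C", np.array([1.5, 1.5, 0.0]), 1.70, True)],
        )
        crowded = na.DomainStructure(residues=list(st.residues) + [blocker], source="x")
        after = na.compute_sasa(crowded).atom_areas[:2]
        assert np.all(after <= before + 1e-9)

    def test_upper_bound_invariant(self, mini_domain):
        _, st = mini_domain
        result = na.compute_sasa(st)
        for atom, area in zip(st.atoms(), result.atom_areas):
            assert 0.0 <= area <= 4.0 * math.pi * (atom.vdw_radius + 1.4) ** 2 + 1e-9

    def test_bad_inputs(self, mini_domain):
        _, st = mini_domain
        with pytest.raises(ValueError):
            na.compute_sasa(st, probe_radius=0.0)
        with pytest.raises(ValueError):
            na.compute_sasa(st, n_points=5)
        with pytest.raises(ValueError):
            na.compute_sasa(na.DomainStructure(residues=[], source="empty"))


# ---------------------------------------------------------------------------
# hydrophobic contacts

class TestContacts:
    def test_pair_under_cutoff_counts_once_each(self):
        st = na.make_sphere_cluster("pair", spacing=3.5)
        counts = na.count_hydrophobic_contacts(st, [39, 40]).per_residue_contacts
        assert counts == {"39": 1, "40": 1}

    def test_pair_beyond_cutoff(self):
        st = na.make_sphere_cluster("pair", spacing=4.2)
        counts = na.count_hydrophobic_contacts(st, [39, 40]).per_residue_contacts
        assert counts == {"39": 0, "40": 0}

    def test_boundary_distance_counts_as_contact(self):
        st = na.make_sphere_cluster("pair", spacing=4.0)
        counts = na.count_hydrophobic_contacts(st, [39, 40]).per_residue_contacts
        assert counts == {"39": 1, "40": 1}

    def test_occluding_atom_defeats_the_path(self):
        st = na.make_sphere_cluster("occluded_pair", spacing=3.5)
        counts = na.count_hydrophobic_contacts(st, [39, 41]).per_residue_contacts
        assert counts == {"39": 0, "41": 0}
        free = na.count_hydrophobic_contacts(
            st, [39, 41], occlusion_enabled=False).per_residue_contacts
        assert free == {"39": 1, "41": 1}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_random_clusters(self, seed):
        """Counts equal exhaustive pair enumeration with the same occlusion
        rule on randomized 5-15 atom clusters."""
        rng = np.random.default_rng(1000 + seed)
        st = random_atom_cluster(rng, int(rng.integers(5, 16)))
        targets = [r.imgt_position for r in st.residues]
        mine = na.count_hydrophobic_contacts(st, targets).per_residue_contacts
        oracle = contacts_bruteforce_oracle(st, targets)
        assert mine == oracle

    def test_contact_symmetry(self):
        """Every counted pair appears from both sides: summed per-residue
        counts are even and the pair list is symmetric."""
        rng = np.random.default_rng(42)
        st = random_atom_cluster(rng, 12)
        result = na.count_hydrophobic_contacts(st, [r.imgt_position for r in st.residues])
        pairs = set(result.pairs)
        assert all((b, a) in pairs for a, b in pairs)
        assert sum(result.per_residue_contacts.values()) % 2 == 0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        st = random_atom_cluster(rng, 10)
        targets = [r.imgt_position for r in st.residues]
        moved = rigid_transform(st, rotation_matrix((12, 155, -78)), np.array([5.0, 5.0, 5.0]))
        assert (na.count_hydrophobic_contacts(st, targets).per_residue_contacts
                == na.count_hydrophobic_contacts(moved, targets).per_residue_contacts)

    def test_blocking_atom_only_removes_contacts(self):
        """Monotonicity: inserting a blocker between a pair cannot add contacts."""
        open_pair = na.make_sphere_cluster("pair", spacing=3.5)
        blocked = na.make_sphere_cluster("occluded_pair", spacing=3.5)
        open_counts = na.count_hydrophobic_contacts(open_pair, [39]).per_residue_contacts
        blocked_counts = na.count_hydrophobic_contacts(blocked, [39]).per_residue_contacts
        assert blocked_counts["39"] <= open_counts["39"]

    def test_residue_pair_granularity_collapses_atom_pairs(self, mini_domain):
        _, st = mini_domain
        positions = list(range(39, 39 + 17))
        atom_level = na.count_hydrophobic_contacts(st, positions)
        residue_level = na.count_hydrophobic_contacts(
            st, positions, granularity="residue_pair")
        for key in atom_level.per_residue_contacts:
            assert (residue_level.per_residue_contacts[key]
                    <= atom_level.per_residue_contacts[key])

    def test_unmapped_targets_are_listed(self, mini_domain):
        _, st = mini_domain
        with pytest.raises(ValueError, match=r"\[77\]"):
            na.count_hydrophobic_contacts(st, [39, 77])


# ---------------------------------------------------------------------------
# instability index

# ProtParam oracle values, frozen (computed by an independent implementation
# of the Guruprasad index on the same strings).
PROTPARAM_ORACLE = [
    ("ELWFRQAPGKEREGVAA", 41.005882),
    ("ELWVRQAPGKGLEWVSA", 17.182353),
    ("MGWFRQAPGEREFVAAI", 34.894118),
    ("QAWFRQAPGKQRELVAA", 40.982353),
    ("ELWFRQTPGKEREFVAA", 29.676471),
    ("ELWFRQAPGKEREGVA", 42.943750),
    ("KGWFRQAPGKEREFVSS", 40.670588),
    ("ELWYRQAPGKQRELVAH", 39.970588),
    ("PPWFRQAPGKEREGVAP", 48.041176),
    ("AAWFRQGPGKEREGWAA", 14.164706),
]


class TestInstabilityIndex:
    @pytest.mark.parametrize("sequence,expected", PROTPARAM_ORACLE)
    def test_matches_protparam_oracle(self, sequence, expected):
        assert na.instability_index(sequence) == pytest.approx(expected, abs=5e-3)

    def test_single_residue_scores_zero(self):
        assert na.instability_index("W") == 0.0

    def test_uniform_table_gives_closed_form(self):
        """With all 400 weights equal to one, the index is 10(L-1)/L."""
        ones = {(a, b): 1.0 for a in "ACDEFGHIKLMNPQRSTVWY"
                for b in "ACDEFGHIKLMNPQRSTVWY"}
        seq = HALLMARK_FR2  # L = 17
        assert na.instability_index(seq, ones) == pytest.approx(10 * 16 / 17)

    def test_non_canonical_rejected(self):
        with pytest.raises(ValueError):
            na.instability_index("ELWFRQX")

    def test_diwv_table_complete(self):
        table = na.load_diwv_table()
        assert len(table) == 400
        assert all(isinstance(v, float) for v in table.values())
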