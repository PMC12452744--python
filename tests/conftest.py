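import numpy as np
import pytest

import nanoagg as na

HALLMARK_FR2 = "ELWFRQAPGKEREGVAA"


@pytest.fixture(scope="session")
def mini_domain():
    """A deterministic FR2-labelled mini domain with its structure."""
    return na.make_mini_domain(HALLMARK_FR2, shield=0.0)


@pytest.fixture(scope="session")
def synth_vhh():
    """A synthetic full-length VHH with construction-known numbering."""
    return na.make_vhh_sequence(17)


def random_atom_cluster(rng, n_atoms):
    """A random toy structure of single-CB residues (plus some O blockers).

    Used as input for contact brute-force comparisons; roughly half the
    positions are hydrophobic carbons, the rest non-hydrophobic oxygens.
    """
    residues = []
    for i in range(n_atoms):
        coords = rng.uniform(-6.0, 6.0, size=3)
        if rng.random() < 0.7:
            atom = na.Atom("CB", "C", coords, 1.70, True)
            name3, one = "ALA", "A"
        else:
            atom = na.Atom("OG", "O", coords, 1.52, False)
            name3, one = "SER", "S"
        residues.append(na.StructResidue(
            chain_id="A", author_seq_id=i + 1, insertion_code="",
            amino_acid=one, residue_name=name3, atoms=[atom],
            imgt_position=39 + i,
        ))
    return na.DomainStructure(residues=residues, source="random_cluster")
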