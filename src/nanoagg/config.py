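"""Run configuration and bundled physical-constant tables.

The defaults reproduce the published analysis parameters: a 1.4 Å solvent
probe with 100 sphere sample points for accessible surface area, a 4.0 Å
cutoff with an occlusion test for hydrophobic contacts, the Wimley-White
interfacial hydropathy scale, a score threshold of 1.0 and a 90% monomer
cut for classification.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Mapping

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Element-wise van der Waals radii in Å (fixed published values).
VDW_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}

#: Side-chain carbon/sulfur atoms not covalently bonded to N or O, per
#: standard amino-acid topology.  These are the atoms that participate in
#: hydrophobic interactions; backbone C/CA are excluded (bonded to O/N).
HYDROPHOBIC_ATOMS: Mapping[str, frozenset[str]] = {
    "ALA": frozenset({"CB"}),
    "ARG": frozenset({"CB", "CG"}),
    "ASN": frozenset({"CB"}),
    "ASP": frozenset({"CB"}),
    "CYS": frozenset({"CB", "SG"}),
    "GLN": frozenset({"CB", "CG"}),
    "GLU": frozenset({"CB", "CG"}),
    "GLY": frozenset(),
    "HIS": frozenset({"CB"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "LYS": frozenset({"CB", "CG", "CD"}),
    "MET": frozenset({"CB", "CG", "SD", "CE"}),
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "PRO": frozenset({"CB", "CG"}),
    "SER": frozenset(),
    "THR": frozenset({"CG2"}),
    "TRP": frozenset({"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"}),
    "TYR": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
}

THREE_TO_ONE: Mapping[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: Mapping[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


def _data_text(name: str) -> str:
    return resources.files("nanoagg.data").joinpath(name).read_text()


def load_hydropathy_table(source: str | Path = "wimley-white-interface") -> dict[str, float]:
    """Load a per-residue hydropathy table (kcal/mol).

    ``source`` is either a bundled scale name (``wimley-white-interface``,
    ``wimley-white-octanol``) or a path to a TSV file with lines
    ``one_letter<TAB>value``.
    """
    bundled = {
        "wimley-white-interface": "wimley_white_interface.tsv",
        "wimley-white-octanol": "wimley_white_octanol.tsv",
    }
    if str(source) in bundled:
        text = _data_text(bundled[str(source)])
    else:
        text = Path(source).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        table[aa] = float(value)
    missing = set(CANONICAL_AA) - set(table)
    if missing:
        raise ValueError(f"hydropathy table missing residues: {sorted(missing)}")
    return table


def load_diwv_table(source: str | Path | None = None) -> dict[tuple[str, str], float]:
    """Load the 400-entry dipeptide instability weight table (DIWV).

    Defaults to the bundled Guruprasad et al. dipeptide weights; a custom
    TSV (``first<TAB>second<TAB>weight``) may be supplied instead.
    """
    text = _data_text("diwv_guruprasad.tsv") if source is None else Path(source).read_text()
    table: dict[tuple[str, str], float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b, w = line.split("\t")
        table[(a, b)] = float(w)
    if len(table) != 400:
        raise ValueError(f"DIWV table has {len(table)} entries, expected 400")
    return table


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Parameters governing a scoring run; defaults match the published ones."""

    probe_radius: float = 1.4          # solvent probe, Å
    n_points: int = 100                # sphere sample points per atom
    contact_cutoff: float = 4.0        # hydrophobic-contact distance cutoff, Å
    occlusion_enabled: bool = True     # require an unobstructed inter-atom path
    contact_granularity: str = "atom_pair"   # or "residue_pair"
    hydropathy_table: str = "wimley-white-interface"
    diwv_table: str | None = None      # None -> bundled Guruprasad weights
    threshold: float = 1.0             # score cut for pass/fail
    monomer_cut: float = 90.0          # %-monomer cut defining the positive class
    seed: int = 0                      # seed for fixture generation

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if self.contact_granularity not in ("atom_pair", "residue_pair"):
            raise ValueError("contact_granularity must be 'atom_pair' or 'residue_pair'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read ``key=value`` lines (# comments allowed) into a config."""
        kwargs: dict[str, object] = {}
        casts = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in casts:
                raise ValueError(f"unknown config key: {key}")
            if key in ("n_points", "seed"):
                kwargs[key] = int(value)
            elif key in ("probe_radius", "contact_cutoff", "threshold", "monomer_cut"):
                kwargs[key] = float(value)
            elif key == "occlusion_enabled":
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif key == "diwv_table":
                kwargs[key] = None if value.lower() in ("", "none") else value
            else:
                kwargs[key] = value
        return cls(**kwargs)  # type: ignore[arg-type]
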