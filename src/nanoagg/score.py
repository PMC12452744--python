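"""The FR2-restricted aggregation score.

    AS = | mean_i(A_i × H_i) × mean_i(h_i) / II(FR2) |

where the means run over the n residues of the former VH:VL interface
(IMGT 39-55 plus 118) present in the structure, A_i is the residue's
accessible surface area, H_i its Wimley-White hydropathy, h_i its
intramolecular hydrophobic contact count, and II(FR2) the Guruprasad
instability index of the FR2 substring (length L).  Higher scores indicate
lower aggregation propensity; in practice a threshold near 1 separates
well-behaved from aggregation-prone nanobodies.

The absolute value is applied to the final product only: under the
interfacial hydropathy convention hydrophobic residues carry negative H_i,
so a more hydrophobic exposed patch drives the signed product toward zero
or negative values, and the magnitude restores an interpretable scale.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Literal, Mapping

from .annotate import INTERFACE_POSITIONS, NumberedDomain
from .biophys import compute_sasa, count_hydrophobic_contacts, instability_index
from .config import RunConfig, load_diwv_table, load_hydropathy_table
from .structio import DomainStructure

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ScoreBreakdown:
    """The three terms of the aggregation score, never just the scalar.

    term_I:  mean ASA-weighted hydropathy over the interface (kcal·Å²/mol)
    term_II: mean hydrophobic contacts per interface residue
    term_III: instability index of FR2
    n: interface residues actually scored; L: FR2 residues in the domain
    """

    term_I: float
    term_II: float
    term_III: float
    n: int
    L: int
    aggregation_score: float

    def __post_init__(self) -> None:
        if self.aggregation_score < 0:
            raise ValueError("aggregation score is a magnitude and cannot be negative")


def aggregation_score(
    structure: DomainStructure,
    domain: NumberedDomain,
    config: RunConfig = RunConfig(),
    *,
    hydropathy: Mapping[str, float] | None = None,
    diwv: Mapping[tuple[str, str], float] | None = None,
) -> ScoreBreakdown:
    """Compute the aggregation score of a numbered structure.

    ``structure`` must already carry IMGT positions (see
    :func:`nanoagg.structio.map_to_numbering`).  Custom hydropathy or DIWV
    tables may be injected, e.g. for sensitivity analyses; defaults come
    from ``config``.
    """
    if hydropathy is None:
        hydropathy = load_hydropathy_table(config.hydropathy_table)
    if diwv is None:
        diwv = load_diwv_table(config.diwv_table)

    fr2_seq = domain.fr2_sequence()
    if len(fr2_seq) < 2:
        raise ValueError(f"FR2 of {domain.source_id!r} has {len(fr2_seq)} residues; need >= 2")

    interface = [r for r in structure.residues
                 if r.imgt_position is not None and r.imgt_position in INTERFACE_POSITIONS]
    if not interface:
        raise ValueError(f"no interface residues mapped in structure {structure.source!r}")
    if not any(r.imgt_position == 118 for r in interface):
        logger.warning("%s: position 118 missing; scoring over FR2 only", domain.source_id)

    sasa = compute_sasa(structure, config.probe_radius, config.n_points)
    positions = sorted({r.imgt_position for r in interface})
    contacts = count_hydrophobic_contacts(
        structure,
        positions,
        config.contact_cutoff,
        occlusion_enabled=config.occlusion_enabled,
        granularity=config.contact_granularity,
    )

    n = len(interface)
    term_I = sum(
        sasa.per_residue_asa[r.imgt_label] * hydropathy[r.amino_acid] for r in interface
    ) / n
    term_II = sum(contacts.per_residue_contacts[str(p)] for p in positions) / n
    term_III = instability_index(fr2_seq, diwv)
    if term_III == 0:
        raise ValueError(
            f"instability index of FR2 {fr2_seq!r} is zero; score undefined"
        )
    return ScoreBreakdown(
        term_I=term_I,
        term_II=term_II,
        term_III=term_III,
        n=n,
        L=len(fr2_seq),
        aggregation_score=abs(term_I * term_II / term_III),
    )


def classify(score: ScoreBreakdown, threshold: float = 1.0) -> Literal["pass", "fail"]:
    """``pass`` iff the score strictly exceeds the threshold.

    A score exactly at the threshold fails: empirically, every domain
    scoring above 1 stayed >90% monomeric, so the selection boundary is
    strict.
    """
    return "pass" if score.aggregation_score > threshold else "fail"
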