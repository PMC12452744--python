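"""Greedy identity clustering of FR2 sequences and position frequencies.

FR2 segments are short (15-17 residues), so exhaustive pairwise comparison
is exact and fast; the parameters mirror the usual sequence-clustering
defaults for this analysis: minimum identity 0.8, minimum alignment
coverage 0.9, clusters below 4 members discarded.  Identity is
matches / alignment length at the best ungapped offset; coverage is
alignment length / max(sequence lengths).  Per-cluster position-frequency
matrices (counts, WebLogo-style) summarise the composition.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .config import CANONICAL_AA


@dataclasses.dataclass(frozen=True)
class FR2Cluster:
    representative: str                      # member id of the founding sequence
    members: tuple[tuple[str, str], ...]     # (id, FR2 sequence)
    pfm: pd.DataFrame                        # rows = amino acids, cols = positions

    @property
    def size(self) -> int:
        return len(self.members)


def _best_ungapped(a: str, b: str) -> tuple[int, int]:
    """(matches, alignment_length) over all ungapped sliding offsets.

    The best offset maximises identity among offsets whose overlap is
    maximal-coverage-feasible; ties favour longer overlaps, then smaller
    absolute offset.
    """
    best = (0, max(len(a), len(b)))
    best_identity = -1.0
    for offset in range(-(len(b) - 1), len(a)):
        lo_a = max(0, offset)
        hi_a = min(len(a), offset + len(b))
        overlap = hi_a - lo_a
        if overlap <= 0:
            continue
        matches = sum(1 for i in range(lo_a, hi_a) if a[i] == b[i - offset])
        identity = matches / overlap
        if (identity > best_identity
                or (identity == best_identity and overlap > best[1])):
            best_identity = identity
            best = (matches, overlap)
    return best


def identity_and_coverage(a: str, b: str) -> tuple[float, float]:
    """Pairwise identity and coverage under the best ungapped alignment."""
    matches, aln_len = _best_ungapped(a, b)
    return matches / aln_len, aln_len / max(len(a), len(b))


def position_frequencies(members: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Per-position amino-acid counts over cluster members.

    Columns are 0-based offsets from the start of each member sequence; at
    positions covered by all members the column sums equal the member count.
    """
    if not members:
        raise ValueError("empty cluster")
    width = max(len(seq) for _, seq in members)
    counts = np.zeros((len(CANONICAL_AA), width), dtype=int)
    index = {aa: i for i, aa in enumerate(CANONICAL_AA)}
    for _, seq in members:
        for pos, aa in enumerate(seq):
            counts[index[aa], pos] += 1
    return pd.DataFrame(counts, index=list(CANONICAL_AA), columns=range(width))


def cluster_fr2(
    sequences: Sequence[tuple[str, str]],
    min_identity: float = 0.8,
    min_coverage: float = 0.9,
    min_size: int = 4,
) -> tuple[list[FR2Cluster], list[tuple[str, str]]]:
    """Greedy centroid clustering of (id, FR2 sequence) pairs.

    Sequences are canonically sorted (descending length, then sequence,
    then id) so the result is independent of input order; each sequence
    joins the first existing representative it matches at the identity and
    coverage thresholds, else founds a new cluster.  Returns the clusters
    of at least ``min_size`` members (ordered by size descending, then
    representative id) and the leftover members of discarded clusters.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    for sid, seq in sequences:
        bad = [aa for aa in seq if aa not in CANONICAL_AA]
        if bad:
            raise ValueError(f"{sid}: non-canonical residues {bad}")
    ordered = sorted(sequences, key=lambda item: (-len(item[1]), item[1], item[0]))
    reps: list[tuple[str, str]] = []
    assignments: list[list[tuple[str, str]]] = []
    for sid, seq in ordered:
        for k, (_, rep_seq) in enumerate(reps):
            identity, coverage = identity_and_coverage(rep_seq, seq)
            if identity >= min_identity and coverage >= min_coverage:
                assignments[k].append((sid, seq))
                break
        else:
            reps.append((sid, seq))
            assignments.append([(sid, seq)])

    kept: list[FR2Cluster] = []
    discarded: list[tuple[str, str]] = []
    for (rep_id, _), members in zip(reps, assignments):
        if len(members) >= min_size:
            kept.append(FR2Cluster(
                representative=rep_id,
                members=tuple(members),
                pfm=position_frequencies(members),
            ))
        else:
            discarded.extend(members)
    kept.sort(key=lambda c: (-c.size, c.representative))
    return kept, discarded


def write_pfm(cluster: FR2Cluster, path) -> None:
    """Write a cluster's position-frequency matrix as a TSV (positions as rows)."""
    cluster.pfm.T.rename_axis("position").to_csv(path, sep="\t")
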