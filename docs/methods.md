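# Methods

## Model

The package treats nanobody aggregation as a property of the former VH:VL
interface: framework region 2 (IMGT positions 39–55) plus position 118,
the first framework-4 residue. In a conventional VH this surface is buried
against the light chain; in a VHH it faces solvent, and its residual
hydrophobicity, conformational looseness and local sequence instability
drive self-association. The aggregation score condenses these three
effects into

AS = | mean(Aᵢ·Hᵢ) × mean(hᵢ) / II(FR2) |,

with the two means over the n interface residues present in the structure
and II the dipeptide instability index of the FR2 substring of length L.
The absolute value is applied to the final product only; the signed
term I is always reported in the breakdown, because its sign carries
information (negative = net hydrophobic exposed surface under the
interfacial hydropathy convention). Position 118 contributes to terms I
and II but not to the FR2-only instability term. A missing position 118
(e.g. a truncated model) downgrades to FR2-only scoring with a logged
warning; an FR2 with fewer than two residues, or a zero instability
index, is an error rather than a silent degenerate score.

## Accessible surface area

Shrake–Rupley with defaults probe = 1.4 Å and n_points = 100 per atom,
on heavy atoms only, with element van der Waals radii C 1.70, N 1.55,
O 1.52, S 1.80 Å. Sample points come from a golden-section spiral —
deterministic, no RNG — and a point lying exactly on a neighbouring
expanded sphere counts as buried (fixed tie-break). The spiral directions
are expressed in a canonical frame built from the principal axes of the
atom cloud, each axis signed by the first atom with a non-negligible
projection. Because this frame co-rotates with the molecule, ASA is
exactly invariant under rigid motions of the coordinates; the exception
is a structure with degenerate principal axes (an isolated atom, perfectly
symmetric toy systems), where the frame is arbitrary but still
deterministic for a given input. Increasing n_points from 100 to 1000
changes per-residue ASA by under 5% on the bundled fixtures; tests also
cross-check against a closed-form two-sphere solution, an independent
latitude–longitude quadrature, and biotite's Shrake–Rupley.

## Hydrophobic contacts

A contact is an atom pair (a, b) with a a side-chain hydrophobic atom of
the target residue, b a hydrophobic atom of any other residue, distance
≤ 4.0 Å (boundary counts), and — by default — an unobstructed path: the
segment between the centers must not pass through a third atom's bare
van der Waals sphere (point-to-segment distance < r_vdw blocks).
Hydrophobic atoms are the carbons and sulfurs not covalently bonded to
nitrogen or oxygen, per standard amino-acid topology — a fixed per-residue
atom-name table, which excludes all backbone atoms by construction.
Counting is per atom pair; per-residue-pair collapsing and disabling the
occlusion test are configuration options for sensitivity analyses.
Intra-residue pairs are excluded; sequence-adjacent residues are included,
as no exclusion rule is defined for them. Counts are symmetric at the
pair level and invariant under rigid motions.

## Instability index

The Guruprasad dipeptide index, (10/L) Σ DIWV(xᵢ, xᵢ₊₁), computed on the
FR2 substring only, with the published 400-entry weight table bundled as
plain-text data. A single-residue sequence scores 0. Values agree with
the ProtParam implementation to the displayed precision (frozen oracle
values in the tests).

## Hydropathy scale

The Wimley–White interfacial (POPC) scale is the default Hᵢ, with
charged-state values for D, E, K, R and His neutral: under this sign
convention hydrophobic residues are negative, so term I shrinks (and can
go negative) as the exposed surface becomes more hydrophobic, which is the
behaviour the score is built around; the final absolute value absorbs the
sign. The octanol sub-scale ships as an alternative
(`hydropathy_table = wimley-white-octanol`) because published analyses do
not always state which sub-scale they used; both tables are plain-text
data files and custom tables can be injected. The score is exactly linear
in the scale (×c on every Hᵢ gives ×c on AS) and reciprocal in the DIWV
weights, which the tests exploit as algebraic identities.

## IMGT numbering

The builtin numberer is a lightweight anchor aligner: the first conserved
cysteine (IMGT 23), the FR4 `[W/R/F]-G-x-G` motif (118), the second
conserved cysteine (104, located as the first cysteine far enough
downstream that CDR3 cysteines from non-canonical disulfides cannot be
mistaken for it), and the conserved tryptophan (41, with an 8-residue-CDR2
fallback). Framework regions are assumed indel-free: FR3 is anchored as 39
contiguous residues ending at the second cysteine, FR2 as 17 residues from
position 39. CDR loops are numbered from both ends toward a middle gap;
CDR3 insertions beyond 13 residues are carried as ascending insertion
letters on position 111 (a simplification of the strict IMGT
111.x/112.x convention that keeps insertion codes alphabetically ordered
within a position). Domains with framework indels — e.g. an FR2 deletion
at position 53 — are supplied through `external_table` mode, a CSV of
(source_id, imgt_position, insertion_code, amino_acid) as produced by
reshaping the output of standard antibody-numbering tools; the table is
validated to spell the input sequence. The sequence-length precondition
(90–170 residues) applies to the builtin path only, so external tables can
number domain fragments such as the synthetic mini-domain.

Structure residues are matched to the numbered sequence by global
alignment with free end gaps; identity is normalised by the shorter
sequence (not the aligned span, which a partial core match could
saturate) and must reach 95%. Only sequence content matters, so author
renumbering is irrelevant, and unaligned residues — fusion partners,
tags — simply stay unmapped and unscored.

## Threshold evaluation

The positive class is the non-aggregation-prone domain (monomer
percentage ≥ the cut, 90 or 95); prediction is positive when the score
strictly exceeds the threshold, so a score exactly at the threshold fails.
The sweep enumerates midpoints between consecutive distinct scores plus
±∞ sentinels — every achievable confusion matrix exactly once — and
reports accuracy, balanced accuracy, sensitivity, specificity, Youden J
and Fβ (β = 0.5, 1, 2 by default) per row, with NaN for undefined ratios
rather than silent zeros. Argmax thresholds break ties toward the lowest
threshold. ROC AUC (trapezoidal) is informational. Records between the
90 and 95 cuts are negatives under the 95 cut; the three-band stratified
summary reports them separately.

## Clustering

FR2 segments are clustered greedily: canonical sort (length descending,
then sequence, then id) for order independence, then each sequence joins
the first representative reaching identity ≥ 0.8 and coverage ≥ 0.9,
where identity = matches / alignment length at the best ungapped offset
and coverage = alignment length / max(length). Clusters under 4 members
are discarded but reported. This is deliberately not a reimplementation
of a k-mer-prefiltered clustering engine: at the scale of a few hundred
17-mers, exhaustive pairwise comparison is exact, and the thresholds —
not the engine — define the result. Position-frequency matrices are raw
per-position counts in a WebLogo-compatible layout.

## Synthetic data

The fixtures module generates every test input programmatically:

* **Sphere clusters** place single-atom residues at exact coordinates so
  ASA and contact outcomes are analytic: an isolated carbon (full
  expanded-sphere area, 4π·3.1² ≈ 120.76 Å²), a contact pair, a caged
  atom (zero ASA), and an occluded pair with an oxygen blocker on the
  segment.
* **Mini domains** lay an FR2 peptide along an axis with Cβ atoms on an
  exposed face, spaced so sequence neighbours form contacts, plus residue
  118; a cap of oxygen atoms buries a chosen fraction of the FR2 face,
  emulating CDR3 shielding — summed FR2 ASA strictly decreases as the
  shield grows.
* **VHH-like sequences** combine fixed camelid-consensus-like framework
  templates (hallmark residues F42/E49/R50/G52 included) with
  seed-drawn CDR lengths and compositions, recording every residue's
  IMGT position at construction time — an oracle independent of the
  numbering algorithm. CDRs exclude Cys and Trp so the anchors stay
  unambiguous.
* **Labelled datasets** realise prescribed confusion counts exactly by
  drawing scores and monomer percentages from intervals strictly above or
  below the threshold and cut. Dataset sizes follow the screens they
  reconstruct (106 domains for the combined collection).
* **FR2 sets** derive cluster members from centroids with controlled
  within- (1 mutation ≈ 16/17 identity) and between-cluster (≥ 4
  mutations ≤ 13/17) divergence.

What this synthetic data does not emulate: real immunoglobulin-fold
geometry, predictor error, CDR3 loops with realistic conformations, or
the correlation structure of real screens. Passing tests therefore
demonstrate that the machinery computes its definitions correctly and
deterministically, not that the score's biological discrimination
transfers to any particular dataset; the published per-domain scores
(0.68–1.45 across the characterized variants) depend on full sequences
and predictor structures that are not redistributable and are treated as
documentation anchors, not test targets.

## Numerical and design choices

* TSV (tab, dot decimal, UTF-8, header) for all tables; floats written at
  17 significant digits and re-read with round-trip parsing, so re-running
  a command reproduces byte-identical output; every output directory gets
  a manifest with the configuration, version and input digests.
* Fixed tie-breaks throughout: on-sphere sample points buried, distance
  exactly at cutoff is a contact, score exactly at threshold fails,
  argmax ties to the lowest threshold, altloc ties to first-in-file.
* Alternate locations resolve to highest occupancy; hydrogens are ignored
  (predicted models are heavy-atom); selenomethionine maps to methionine
  with selenium treated as sulfur; other non-standard residues are
  skipped with a warning.
* Scoring requires exactly one polypeptide chain; fusion constructs are
  trimmed implicitly by the mapping step, which leaves non-domain
  residues unmapped. Mapped-but-side-chain-less residues still contribute
  backbone ASA and zero side-chain contacts.
* Insertion-coded FR2 residues are retained and counted in n and L; the
  per-position contact lookup collapses insertion duplicates of the same
  integer position, a documented simplification (framework insertions are
  rare).
* The ≥95%-cut operating point at threshold 1.06 is reported from its
  confusion counts (balanced accuracy ≈ 0.770); where a printed rounding
  of that figure disagrees with the counts, the count arithmetic is
  authoritative here.

## Problem sizes

Test and acceptance runs use the sizes the analyses themselves define:
106-record labelled datasets for the screen metrics, 20 randomized
fixtures of 5–15 atoms for contact-oracle agreement, 20 random datasets
of 15–200 records for sweep-oracle agreement, and an 18-residue
mini-domain for end-to-end scoring. The whole suite completes in seconds.

## Known limitations

* The builtin numberer cannot represent framework indels; such domains
  need an external numbering table.
* mmCIF input is not supported (PDB only), and multi-domain complexes are
  out of scope.
* ASA rotation invariance relies on non-degenerate principal axes;
  symmetric toy structures fall back to a deterministic but
  orientation-dependent frame.
* The hydrophobic-atom table and occlusion rule mirror a common
  visualization-tool convention but are not guaranteed to match any
  specific viewer's internals bit-for-bit.
* The score is calibrated for camelid-derived or humanized VHHs;
  VGLW-motif domains and domains whose aggregation is driven by CDR
  composition (hydrophobic CDR2/CDR3 patches, very short CDR3) fall
  outside what the FR2-restricted score can see.
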