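# nanoagg

Aggregation-propensity scoring for nanobody (VHH) domains from sequence
and predicted structure, restricted to framework region 2.

## The problem

VHHs — the variable domains of camelid heavy-chain-only antibodies — are
naturally soluble single-domain binders, but humanization and affinity
maturation frequently produce variants that aggregate during recombinant
expression. The solvent-exposed FR2 patch (IMGT positions 39–55), which in
conventional VH domains packs against the light chain, is the main culprit:
camelid hallmark substitutions at positions 42/49/50/52 keep it hydrophilic,
and reverting them (or perturbing the packing around them) exposes a sticky
hydrophobic surface. `nanoagg` quantifies this with a single interpretable
score so aggregation-prone candidates can be excluded early in discovery,
before expression and SEC characterization.

## The score

For the former VH:VL interface — FR2 (IMGT 39–55) plus position 118, the
first FR4 residue — the aggregation score of a domain is

```
AS = | (1/n) Σᵢ Aᵢ·Hᵢ  ×  (1/n) Σᵢ hᵢ  /  (10/L) Σᵢ DIWV(xᵢ, xᵢ₊₁) |
```

* **Aᵢ** — accessible surface area of interface residue *i* (Å²),
  Shrake–Rupley with a 1.4 Å probe and 100 deterministic sphere points;
* **Hᵢ** — Wimley–White interfacial hydropathy of the residue (kcal/mol;
  hydrophobic residues negative, so an exposed hydrophobic patch drives
  term I toward zero or negative values);
* **hᵢ** — intramolecular hydrophobic contacts of the residue: pairs of
  hydrophobic atoms within 4 Å whose connecting segment is not blocked by
  a third atom's van der Waals sphere (residues already engaged in many
  stabilizing contacts have less capacity for intermolecular stickiness);
* the denominator is the Guruprasad dipeptide instability index of the
  FR2 substring (length *L*); *n* counts interface residues present.

Higher scores mean better-behaved domains. Empirically, domains scoring
above 1 stay >90% monomeric in SEC, so `AS > 1` (strict) is the default
pass/fail boundary; the `evaluate` command sweeps all thresholds and
reports Youden-J and Fβ optima for tuning the boundary to a screen's
precision/recall needs.

Structure prediction is out of scope: structures are consumed as PDB input
from any predictor (the score was developed against NanoBodyBuilder2
models). Domains carrying the VH-type `VGLW` FR2 motif score low regardless
of their actual behaviour and should be assessed experimentally.

## Worked example

Generate the bundled synthetic mini-domain (an idealized FR2 peptide with
an exposed hydrophobic face plus residue 118) and score it:

```sh
nanoagg fixtures --kind mini_domain --shield 0.0 --out fx
nanoagg score --fasta fx/mini_domain.fasta --pdb fx/mini_domain.pdb \
    --numbering fx/mini_domain.numbering.csv --out scores.tsv
cat scores.tsv
```

```
id	term_I	term_II	term_III	n	L	AS	classification
mini_domain	30.4314001278556	1.4444444444444444	41.005882352941185	18	17	1.0719551520196506	pass
```

Term I is the mean ASA-weighted hydropathy over the 18 interface residues
(positive here: the hallmark FR2 is net hydrophilic), term II the mean
hydrophobic contact count, term III the FR2 instability index, and
AS = |I × II / III| ≈ 1.07 — above the threshold of 1, so the domain is
classified as non-aggregation-prone. Raising `--shield` buries the FR2
face under a synthetic cap (emulating CDR3 shielding) and moves the terms
accordingly.

Evaluation against SEC labels and FR2 clustering work the same way:

```sh
nanoagg fixtures --kind labeled_dataset --counts 61,20,4,21 --threshold 0.89 --out fx
nanoagg evaluate --scores fx/labeled_scores.tsv --monomer-cut 90 --out eval/
nanoagg fixtures --kind fr2_set --out fx
nanoagg cluster --fasta fx/fr2_set.fasta --out clusters/
```

`eval/metrics.tsv` holds one row per candidate threshold with the
confusion counts, accuracy, balanced accuracy, sensitivity, specificity,
Youden J and Fβ; `best_thresholds.tsv` the argmax operating points;
`roc.tsv`/`pr.tsv` the curve coordinates.

## Layout

* `src/nanoagg/annotate.py` — IMGT numbering (builtin anchor aligner or
  external numbering tables), FR2/interface extraction
* `src/nanoagg/structio.py` — PDB parsing (gemmi), writing, sequence-based
  mapping of structure residues to IMGT positions
* `src/nanoagg/biophys.py` — Shrake–Rupley ASA, hydrophobic contacts with
  occlusion, instability index
* `src/nanoagg/score.py` — score assembly and classification
* `src/nanoagg/evaluate.py` — confusion matrices, metrics, threshold sweep
* `src/nanoagg/cluster.py` — greedy FR2 identity clustering, PFMs
* `src/nanoagg/fixtures.py` — deterministic synthetic inputs
* `src/nanoagg/cli.py` — the `nanoagg` command
* `docs/methods.md` — models, parameters, numerical choices, limitations
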