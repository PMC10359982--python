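# Methods

This document records the model implemented by `chbkit`, the conventions it
adopts, and what the synthetic generator does and does not emulate.

## Chalcogen-bond model

A disulphide sulfur SG is covalently bound to two partners: the CB of its own
cysteine and the SG of the bridge partner. For a candidate nucleophile Nu
(an O or S atom of another residue) approaching SG, the interacting moiety is
(C,S)–S···Nu and the geometry is described by

- `d = |Nu − SG|`, the contact distance;
- `θ_C = ∠(Nu, SG, CB)` and `θ_S = ∠(Nu, SG, SG′)`, the angles at the
  sulfur toward each covalent partner;
- `α = 180° − θ`, the deviation of Nu from the prolongation of the
  corresponding covalent bond. The reported `α_min = min(α_C, α_S)`.

A contact is classified as a chalcogen bond iff, with the default
parameters (`ChBParams`),

1. `d ≤ r_vdw(Nu) + r_vdw(S) + 0.1 Å`, with radii O = 1.52 Å and
   S = 1.80 Å (cutoffs: O···S 3.42 Å, S···S 3.70 Å), and
2. `α_min ≤ 25°`.

Both thresholds are **inclusive**: a contact at exactly 3.42 Å / 25° passes.
Collinear far-side geometry (Nu opposite the bond prolongation) gives
α = 180° and fails; coincident atoms raise `DegenerateGeometryError` rather
than returning NaN.

Disulphide bridges are the union of SSBOND-declared pairs and geometric CYS
SG pairs with `|SG−SG′| ≤ 2.5 Å`; pairs are matched greedily by ascending
distance so each SG belongs to at most one bridge and the result is
deterministic. Both sulfurs of a bridge act as donors. Candidate acceptors
are found with a k-d tree (`scipy.spatial.cKDTree`) at the maximal van der
Waals shell; the index is behaviorally invisible (tested against an
exhaustive all-pairs scan). Waters, atoms of the donor residue itself, and
the covalent partners are excluded.

## Curation of experimental entries

`apply_curation` evaluates five independent rules; missing metadata fails the
corresponding rule rather than passing silently:

| rule | default |
|---|---|
| method | X-ray diffraction |
| resolution | ≤ 1.5 Å (inclusive) |
| temperature | 90–110 K (inclusive) |
| single_model | exactly 1 model |
| nonprotein_fraction | ≤ 5 % non-amino-acid, non-water atoms (waters counted in the denominator only) |

Sequence redundancy is removed at 40 % identity. The canonical interface is
an external clusterer (CD-HIT); the built-in fallback is a documented greedy
stub: global alignment (`Bio.Align.PairwiseAligner`, match +1, mismatch 0,
gap −1), identity = matches / alignment length, representatives chosen by
descending sequence length. The stub is exact for small sets but O(n²).

## Pairing experimental and predicted structures

Residues are mapped through shared database accessions (DBREF):
`model_seq = exp_seq − seq_begin + db_begin`, requiring residue-name
agreement; insertion-code residues are left unmapped. For each experimental
ChB the model geometry is recomputed **with the model's own covalent
partners** (model CB and model bridge partner found by the same disulphide
search). A ChB is *recovered* when the model geometry passes the identical
`ChBParams`. Absent bonds are attributed to one of: `residue-unmapped`,
`atom-missing`, or `disulphide-broken`. Deltas are `model − experimental`,
so swapping roles negates them exactly.

As a control, main-chain O···N contacts (`d < 3.5 Å`, strict) with at least
one residue among the ChB donors/acceptors are tracked, excluding
same-residue and sequence-adjacent (`|Δseq| ≤ 1`, same chain) pairs —
hydrogen-bond-like geometry that every force field handles, against which
ChB-specific errors can be judged.

Model confidence is the mean pLDDT (B-factor column) of the donor and
acceptor residues, banded as low < 50, high > 90, medium otherwise
(exactly 50 and exactly 90 are medium).

## Statistics

Summary values are mean ± standard error of the mean (`ddof = 1`; SEM is
reported as 0 for n = 1, by convention and logged). Pooling across entries
concatenates the per-bond values (counts are additive); it never averages
per-entry means, so entries with many ChBs carry proportional weight.

## Synthetic generator

`build_toy_chb` inverts the measurement: given a spec (d, α, dihedral φ), it
places a nucleophile at `Nu = SG + d·(cos α, sin α cos φ, sin α sin φ)` in
the frame of the CB→SG prolongation, on a fixed two-cysteine scaffold
(SG–SG 2.05 Å, CB–SG 1.81 Å, CB–S–S 104°, partner side chain rotated out of
the nucleophile's dihedral sweep). Acceptor contexts: backbone O (GLY O,
default), side-chain O (SER OG), side-chain S (CYS SG). Every fixture is
validated for feasibility — no non-bonded pair under 1.5 Å, sulfur
acceptors more than 2.6 Å from both SG atoms, and no *second*
near-detectable contact (margin d ≤ 3.75 Å, α ≤ 27°) — so the prescribed
contact is the unique detectable ChB; infeasible specs raise
`InfeasibleSpecError` (e.g. side-chain S acceptors with φ near 270°, which
would graze the partner SG).

Coordinates are quantized to 3 decimals **at construction** (PDB precision),
so the generator's truth table and the pipeline classify boundary geometries
identically; the exactness of `recovery == truth` is a tested invariant.

`perturb_structure` adds i.i.d. Gaussian noise per coordinate
(`np.random.default_rng(seed)`), relabels the structure as predicted, sets a
constant pLDDT (default 95) and drops SSBOND records (the geometric
disulphide search must re-find the bridge). Default sampling for paired
datasets: `d ~ U[3.0, 3.42] Å` (the detectable O···S window),
`α ~ U[0°, 25°]`, `φ ~ U[0°, 360°)`, backbone-O acceptors, noise
σ = 0.046 Å — the coordinate-error scale typical of high-resolution
crystallography, which propagates in quadrature to
`σ_d = 0.046·√2 ≈ 0.065 Å` on distances and a mean absolute distance shift
`σ_d·√(2/π) ≈ 0.052 Å`.

What the generator deliberately does **not** emulate: pLDDT-correlated or
spatially coherent (rigid-domain) error, side-chain rotamer swaps, missing
residues, or alternate conformations. It is a calibration instrument for the
detection/pairing/statistics machinery, not a model of AlphaFold error
structure.

## Problem sizes and limitations

The shipped verification uses sizes chosen for statistical power at
negligible cost: 200 paired entries per noise level for recovery fractions
(binomial SE ≈ 0.03), 10,000 replicate pairs for the Monte-Carlo
error-propagation check (3 SE tolerance), 1,000 random specs for the
generator/detector round-trip, and random structures of ≤ 500 atoms for the
index-vs-brute-force equivalence.

Limitations: PDB parsing keeps altloc '' or 'A' only and model 1 of
multi-model files; DBREF and REMARK 200 temperature are parsed from raw PDB
text (not available through the mmCIF path); the redundancy stub is not a
substitute for CD-HIT at survey scale; curation treats each rule on the
metadata as given and cannot detect mislabeled deposition fields.
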