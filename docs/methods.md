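# Methods

This document describes the models and numerical choices behind `dmiminer`,
the parameters users are most likely to adjust, how the synthetic generators
approximate real study conditions, and the known limitations.

## Problem statement

Domain–motif interactions (DMIs) are transient contacts in which a globular
domain binds a short linear stretch (4–20 residues) of another protein. The
pipeline discovers candidate DMIs directly from 3D structures: it finds
peptide-like chain segments bound in an extended conformation, verifies that
the interface looks like a genuine domain–peptide interface, groups
recurring interfaces into interaction types, derives consensus sequence
motifs, and cross-validates motifs by over-representation among the domain
family's interaction partners in a protein-interaction network.

## Structure handling (`structio`)

* PDB and mmCIF files are parsed with gemmi; only heavy atoms of polymer
  residues are kept. Chains must have contiguous 1-based sequence indices.
* Secondary structure: a DSSP classic output file is parsed when available.
  Otherwise an internal Cα-trace assigner is used: helix when the virtual
  torsion of four consecutive Cα lies in [25°, 85°] and d(i, i+3) ∈
  [4.2, 6.2] Å; strand when d(i, i+2) geometry indicates full extension
  (d13 ≥ 9.5 Å over a 3-residue window); coil otherwise. A Cα-trace rule is
  used because synthetic fixtures and many PDB entries are Cα-complete but
  not backbone-ideal.
* Solvent accessibility: internal Shrake–Rupley with 960 deterministic
  golden-spiral sphere points and probe radius 1.4 Å. Coordinates are first
  mapped to a canonical principal-axes frame (eigenvectors of the coordinate
  covariance, signs fixed by third moments), which makes SASA exactly
  invariant under rigid motions of the input. Per-residue SASA changes by
  less than 2% when the point count doubles on peptide chains; compact
  cubic-lattice decoys are a degenerate worst case (~4%) and real globular
  packing sits between the two.

## Peptide geometry (`geometry`)

A candidate peptide is described by 12 features: length, elongation
(distance between first and last Cα, Å), linearity (maximum Cα deviation
from the first–last line, Å), mean relative accessibility, and a one-hot
encoding of the modal DSSP class (ties broken H>E>G>I>B>T>S>-). Elongation
and linearity are intrinsic — invariant under rigid motions to machine
precision — and separate conformations sharply: at n = 7, an ideal strand
has linearity ≈ 0.3 Å and elongation ≈ 22.8 Å, an ideal helix ≈ 3.3 Å and
≈ 9.8 Å.

## Candidate classification (`candidates`)

All windows of length 4–20 outside annotated (sequence-defined) domains are
enumerated. A linear SVM classifies windows as motif-like; it reproduces
SVM-light semantics via sklearn's `SVC(kernel="linear", C=0.1,
class_weight={1: 10})` — the asymmetric cost factor makes false negatives
ten times more expensive than false positives, which matters because true
bound motifs are rare. Features are z-scored with a scaler frozen at
training time; `tol=1e-8` keeps the decision function invariant to training
row order (to 1e-6). Acceptance is strictly `decision > 0`. Windows fully
covered by an accepted longer window are removed; remaining overlapping
windows merge into peptide regions.

## Interface validation (`interfaces`)

* Contact: any heavy-atom pair within 5 Å. A domain–peptide pair passes
  when ≥ 60% of peptide residues contact the domain and no gap of > 4
  consecutive non-contacting residues exists.
* Interface area: A(a,b) = (SASA_a + SASA_b − SASA_ab) / 2. Each
  domain–peptide interface must bury ≥ 150 Å².
* Stoichiometry: with N domains contacting one peptide, every domain must
  contribute an interface ratio ≥ 0.5/N of the peptide chain's total
  interface; domains below the threshold are dropped iteratively (N
  shrinks, the threshold rises) and the candidate dies if the surviving
  ratios sum below 0.5. The worked case (0.45, 0.10): the 0.10 domain is
  dropped (0.10 < 0.25), then 0.45 < 0.5 rejects the candidate.
* Intrachain candidates must not be covered by a structure-defined
  (CATH-like) domain span and must be ≥ 10 residues from the binding
  domain in sequence.
* Homomer filter: interactions between near-identical chains (≥ 98%
  identity over the shorter chain) are crystal-packing artefacts and are
  removed. This identity comes from a semi-global alignment (free end
  gaps, internal gaps forbidden): a gapped global alignment would embed
  almost any short peptide chain into a long chain and flag unrelated
  pairs (observed at ~10% for random 10-vs-99 sequences).

## Clustering (`clustering`)

Interfaces of one domain family are compared by their profile-mapped
contact positions with a Dice-style distance d = 1 − 2|A∩B| / (|A|+|B|),
forced to 1 when one interface is more than twice the size of the other.
Complete-linkage agglomeration with a strict cut (merge while the maximum
pairwise distance is strictly below the cut, deterministic lexicographic
tie-break) yields topological clusters ("interaction types"). Member
sequences are grouped into unrelated protein clusters (UPCs) at 90%
combined identity (mean of domain-column identity and peptide-region
identity, complete linkage at distance cut 0.1) — support for a motif is
counted once per UPC.

## Motif derivation (`motifs`)

Eligible clusters need ≥ 3 UPCs, at least one interchain member, and at
least one member not explainable by a known domain–domain interaction.
Patterns with up to 5 defined positions over a span of ≤ 8 are enumerated
from residues actually present in the peptides; one position may hold a
bracket of 2–3 alternatives when every alternative has ≥ 2 UPC support and
the union strictly beats each alternative alone. Raw significance is a
binomial tail: probability that ≥ s of n UPCs contain a match given the
per-sequence match probability under background residue frequencies. The
reported p-value is Bonferroni-adjusted by the theoretical size of the
pattern's complexity class (for k defined positions: T_k·20^k patterns;
with one b-letter bracket: T_k·k·C(20,b)·20^(k−1)), where T_k counts the
offset templates of span ≤ 8. The adjustment is data-independent, so it
cannot be gamed by the post-hoc bracket construction; ranking is by
adjusted p. Measured behaviour: a planted D-E-x-F pattern in 5 UPCs is
recovered at rank 1 in ≥ 99/100 replicates, and null sequence sets report
a (family-wise) significant motif in ~4–6/100 replicates at threshold
0.05, matching the nominal type-I rate.

When > 50% of cluster members are modified at an aligned position, the
modification is attached to the motif as a requirement; when > 50% of
members are helical, pattern offsets are restricted to one helix face
({0, 3, 4, 7}).

## Network cross-validation (`enrichment`)

For a motif/family pair, proteins are counted in a 2×2 table: interactors
of family carriers vs everyone, pattern match (outside the protein's own
globular domains; a match straddling a domain boundary counts as inside)
vs no match. Edges already explainable by a known domain–domain
interaction are removed first. The enrichment factor is (i_m/i)/(m/p) and
significance is a one-sided Fisher exact test computed from log-gamma
terms with compensated summation — verified against exact integer
hypergeometric enumeration over all tables with total ≤ 60 to a maximum
relative error of ~1.4e-13.

## Synthetic generators (`synthfix`) and realism

The generators define the study conditions; their defaults are the
conditions under which all reported numbers hold.

* Peptides: ideal strand (3.8 Å Cα spacing, < 10° wobble), ideal helix
  (1.5 Å rise, 2.3 Å radius, 100°/residue), self-avoiding random-walk
  coil. Each Cα gets decoy backbone heavy atoms so contact and SASA
  computations run on realistic atom counts.
* Complexes: a compact Cα-grid domain with a peptide running 4.2 Å above
  one surface row (every peptide residue has heavy-atom contacts in the
  4–5 Å range), or 20 Å away for unbound controls. Domain annotations and
  identity profile maps accompany each complex.
* Motif sets: one 20-mer per UPC from i.i.d. background frequencies with
  an optional planted pattern instance at a random offset.
* Interactomes: p proteins, 10% family carriers, Erdős–Rényi edges at mean
  degree 4; pattern matches are planted outside domain spans at 15% for
  interactors vs 5% for others (a 3× enrichment), with the base alphabet
  excluding the pattern's letters so matches cannot arise by accident.

## Numerics

* Fisher test: log-gamma + `math.fsum`; p-values clipped to [0, 1].
* Binomial motif tail: per-UPC sequence lengths enter one average match
  probability; results floored at 1e-300.
* SASA: canonical-frame Shrake–Rupley; deterministic golden-spiral points.
* All stochastic components take explicit integer seeds (< 2^31) and use
  `numpy.random.default_rng`; reruns are bit-identical.

## Limitations

* The motif enumerator allows a single bracketed position; multi-bracket
  patterns (e.g. R.I[AG]D.[LV]) are out of reach.
* Required modifications annotate a motif but are not rewritten into the
  pattern string.
* The binomial significance model is a documented stand-in; it ignores
  positional dependence within sequences and between overlapping windows.
* The internal secondary-structure assigner is a Cα-trace heuristic; for
  real structures a DSSP file is preferred.
* Full-proteome figures from large PDB snapshots are release-dependent and
  are not reproduced at desk scale; the scaled synthetic benchmark and the
  property suites stand in for them.
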