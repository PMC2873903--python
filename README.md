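# dmiminer

Structure-based discovery of domain–motif interactions (DMIs).

Many protein interactions are not mediated by two globular domains but by a
**short linear motif** — a 4–20 residue stretch, often in a disordered
region, that a domain recognizes by sequence pattern (think SH3 binding
PxxP, or 14-3-3 binding phosphoserine motifs). Such interfaces are small,
transient, and systematically under-annotated. `dmiminer` mines them
directly from 3D structures:

1. **Find bound peptides.** Enumerate all chain windows outside annotated
   domains and classify them with a linear SVM on bound-conformation
   geometry: elongation (first-to-last Cα distance), linearity (maximum Cα
   deviation from the first–last line), secondary structure, accessibility.
2. **Validate the interface.** Contact coverage (≥ 60% of peptide residues,
   no gap > 4), buried area ≥ 150 Å², an iterative 0.5/N stoichiometry rule,
   removal of intrachain artefacts and crystal-packing homomers.
3. **Cluster recurring interfaces** of each domain family by their
   profile-mapped contact positions (complete linkage on a Dice-style
   distance) into interaction types, and group member sequences into
   unrelated protein clusters (UPCs) so each protein family counts once.
4. **Derive consensus motifs** by sparse pattern enumeration with a
   binomial over-representation test, Bonferroni-corrected by the
   theoretical size of each pattern's complexity class.
5. **Cross-validate in interaction networks**: does the motif occur more
   often among the domain family's interaction partners than in the
   proteome background? (One-sided Fisher exact test on a 2×2 table.)

## Worked example: geometry separates bound motifs

```text
$ python examples/01_geometry_descriptors.py
conformation  elongation (A)  linearity (A)
strand               22.74           0.34
helix                 9.84           3.35
coil                 12.00           6.68
```

An extended (motif-like) 7-mer is three times longer end-to-end and ten
times straighter than a helical one — the core signal the SVM learns.
Both descriptors are rigid-motion invariant to ~1e-15 Å.

## Worked example: discovery on a synthetic complex

```text
$ python examples/02_scan_toy_complex.py
SVM training accuracy: 0.9875

stage counts:
  structures              1
  enumerated              28
  svm_accepted            28
  contact_passed          28
  after_covered_removal   1
  ...
candidate: chain B 1-10 (TKSHFSVCCQ) <-> TOYDOM on chain A;
           interface 345 A^2 of 345 A^2 total
```

## Worked example: motif recovery and the null

```text
$ python examples/03_motif_discovery.py
significant motifs (adjusted p <= 0.05):
  rank 1: DE.F       support 5/5 raw p 4.31e-14  adjusted p 7.24e-09
  rank 2: D..F       support 5/5 raw p 1.25e-07  adjusted p 3.51e-04
  ...
null run (no planted pattern): no significant motif
```

A D-E-x-F pattern planted into five unrelated 20-mers is recovered at
rank 1; a matched null set reports nothing.

## Worked example: network enrichment

```text
$ python examples/04_enrichment.py
worked example: enrichment 2.57x, Fisher p = 2.827e-10
  interactors matching: 8.4%; background matching: 2.9%
```

The classic 14-3-3 numbers: 50 of 593 interactors match the motif outside
their own domains versus 206 of 7215 non-interactors.

## Command line

```bash
dmi-miner train --seed 1 --out model.json         # train the motif-likeness SVM
dmi-miner synth --kind complex --n 10 --out toy/  # write a synthetic complex
dmi-miner scan toy/toy0.pdb --annotations toy/annotations.tsv \
    --profile-map toy/profile_map.tsv --model model.json --out results/
dmi-miner enrich --edges edges.tsv --proteins proteins.tsv \
    --family SH3 --pattern "P..P"
dmi-miner benchmark --seed 0                      # scaled LOO benchmark
```

`cluster` and `motifs` are aliases of `scan` (the cascade always runs
end-to-end and writes candidate, cluster and motif tables).

## Reproduction

```bash
python -m pytest -q tests/                       # unit + property + acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script derives all randomness from `--seed` and reports
(seed 1): Fisher implementation vs exact integer enumeration over all
635,375 tables with total ≤ 60 — max relative error 1.4e-13; planted-motif
rank-first fraction 0.99 with null rate 0.04 (nominal 0.05); enrichment
simulation type-I rate 0.012 at threshold 0.025 with power 1.00 at 3×
planted enrichment (p = 1000); leave-one-domain-out benchmark sensitivity
1.0 with zero accepted negatives.

See `docs/methods.md` for the models, parameter meanings, generator
realism, numerics and limitations; `examples/` for one narrative script
per capability.
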