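"""Synthetic fixtures for every pipeline stage.

Generators for ideal peptide geometries (helix, strand, coil), toy
domain–peptide complexes with known filter verdicts, planted-motif
sequence sets, and planted-enrichment interactomes. Everything is
deterministic under its seed and emits the same in-memory types (and, via
the writers, the same standard formats: PDB, FASTA, TSV) the main pipeline
consumes. Fixtures are geometric decoys, not energetically realistic
molecules: each residue carries a five-atom backbone decoy (N, CA, C, O,
CB), which is all the contact and surface-area contracts need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .enrichment import InteractomeNetwork, ProteinRecord
from .geometry import PeptideFeatures, features_from_residues
from .structio import (
    Chain,
    DomainAnnotation,
    Residue,
    Structure,
    assign_secondary_structure,
    compute_accessibility,
)

__all__ = [
    "ideal_peptide_coords",
    "peptide_chain",
    "toy_complex",
    "toy_intrachain",
    "training_features",
    "synth_motif_set",
    "synth_interactome",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

HELIX_RISE = 1.5      # Å per residue along the axis
HELIX_RADIUS = 2.3    # Å
HELIX_TWIST = 100.0   # degrees per residue
CA_SPACING = 3.8      # Å between consecutive Cα


def ideal_peptide_coords(kind: str, n: int, seed: int = 0) -> np.ndarray:
    """Cα coordinates for an ideal helix, extended strand, or random coil.

    Helix: rise 1.5 Å/residue, radius 2.3 Å, 100 deg/residue twist.
    Strand: 3.8 Å Cα spacing along an axis with a small (< 10 deg)
    perpendicular wobble. Coil: self-avoiding random walk with 3.8 Å steps.
    """
    if not 4 <= n <= 20:
        raise ValueError(f"peptide length {n} outside 4–20")
    rng = np.random.default_rng(seed)
    if kind == "helix":
        i = np.arange(n)
        ang = np.radians(HELIX_TWIST * i)
        return np.column_stack(
            [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * i]
        )
    if kind == "strand":
        wobble = rng.uniform(-0.2, 0.2, size=(n, 2))  # ~6 deg direction jitter
        coords = np.zeros((n, 3))
        coords[:, 1:] = wobble
        x = 0.0
        for i in range(1, n):
            dyz = coords[i, 1:] - coords[i - 1, 1:]
            x += math.sqrt(CA_SPACING**2 - float(dyz @ dyz))
            coords[i, 0] = x
        return coords
    if kind == "coil":
        for _ in range(200):  # bounded retries for self-avoidance
            coords = [np.zeros(3)]
            ok = True
            for _i in range(1, n):
                placed = False
                for _try in range(50):
                    step = rng.normal(size=3)
                    step *= CA_SPACING / np.linalg.norm(step)
                    cand = coords[-1] + step
                    if all(np.linalg.norm(cand - c) >= 3.5 for c in coords[:-1]):
                        coords.append(cand)
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if ok:
                return np.array(coords)
        raise RuntimeError("self-avoiding walk failed after bounded retries")
    raise ValueError(f"unknown peptide kind {kind!r}")


def _decoy_atoms(cas: np.ndarray, i: int) -> tuple[np.ndarray, list[str], list[str]]:
    """Backbone decoy (N, CA, C, O, CB) around Cα i of a trace."""
    ca = cas[i]
    prev_dir = ca - cas[i - 1] if i > 0 else cas[i] - cas[i + 1]
    next_dir = cas[i + 1] - ca if i < len(cas) - 1 else ca - cas[i - 1]
    prev_dir = prev_dir / np.linalg.norm(prev_dir)
    next_dir = next_dir / np.linalg.norm(next_dir)
    perp = np.cross(prev_dir, next_dir)
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(next_dir, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(perp) < 1e-6:
            perp = np.array([0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    atoms = np.array(
        [
            ca - 1.45 * prev_dir,   # N
            ca,                     # CA
            ca + 1.5 * next_dir,    # C
            ca + 1.5 * next_dir + 1.2 * perp,  # O
            ca + 1.5 * perp,        # CB
        ]
    )
    return atoms, ["N", "C", "C", "O", "C"], ["N", "CA", "C", "O", "CB"]


def _residues_from_trace(
    cas: np.ndarray, sequence: str, chain_id: str, start_index: int = 1
) -> list[Residue]:
    residues = []
    for i, aa in enumerate(sequence):
        atoms, elements, names = _decoy_atoms(cas, i)
        residues.append(
            Residue(
                chain=chain_id,
                seq_index=start_index + i,
                aa=aa,
                ca=cas[i].copy(),
                heavy_atoms=atoms,
                elements=elements,
                atom_names=names,
            )
        )
    return residues


def peptide_chain(
    kind: str,
    n: int,
    seed: int = 0,
    chain_id: str = "B",
    sequence: Optional[str] = None,
) -> Chain:
    """A standalone peptide Chain with decoy backbone atoms."""
    rng = np.random.default_rng(seed + 7919)
    if sequence is None:
        sequence = "".join(rng.choice(list(AA20), size=n))
    if len(sequence) != n:
        raise ValueError("sequence length must equal n")
    cas = ideal_peptide_coords(kind, n, seed)
    return Chain(id=chain_id, residues=_residues_from_trace(cas, sequence, chain_id))


def _domain_grid(nx: int, ny: int, nz: int) -> np.ndarray:
    """Cα positions of a compact grid decoy domain, x fastest."""
    cas = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                cas.append([i * CA_SPACING, j * CA_SPACING, k * CA_SPACING])
    return np.array(cas, dtype=float)


@dataclass
class ToyComplex:
    structure: Structure
    annotations: list[DomainAnnotation]
    profile_maps: dict[tuple[str, str, str], dict[int, int]]
    peptide_chain_id: str
    peptide_span: tuple[int, int]


def toy_complex(
    peptide_len: int = 10,
    peptide_kind: str = "strand",
    bound: bool = True,
    seed: int = 0,
    structure_id: Optional[str] = None,
    family: str = "TOYDOM",
    peptide_sequence: Optional[str] = None,
    domain_sequence: Optional[str] = None,
    domain_span: Optional[tuple[int, int]] = None,
    contact_offset: float = 4.2,
) -> ToyComplex:
    """A two-chain decoy complex: grid domain (chain A) + peptide (chain B).

    When bound, the peptide runs 4.2 Å above one row of the domain's top
    layer so every residue has heavy-atom contacts in the 4–5 Å range;
    otherwise it sits 20 Å away. The domain annotation (both
    sequence-defined and structure-defined kinds) covers the whole domain
    chain unless a narrower span is requested, and an identity profile map
    accompanies the family.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = peptide_len + 1, 3, 3
    dom_cas = _domain_grid(nx, ny, nz)
    dom_n = len(dom_cas)
    if domain_sequence is None:
        domain_sequence = "".join(rng.choice(list(AA20), size=dom_n))
    if peptide_sequence is None:
        peptide_sequence = "".join(rng.choice(list(AA20), size=peptide_len))
    if structure_id is None:
        structure_id = f"toy{seed}"

    pep_cas = ideal_peptide_coords(peptide_kind, peptide_len, seed)
    # orient the peptide over the middle row of the top grid layer
    z_top = (nz - 1) * CA_SPACING
    y_mid = 1 * CA_SPACING
    offset = np.array([CA_SPACING * 0.5, y_mid, z_top + (contact_offset if bound else 20.0)])
    if peptide_kind == "helix":
        # axis along x; keep the closest approach at the contact offset
        pep = pep_cas[:, [2, 0, 1]]  # axis (z) -> x
        pep[:, 2] += HELIX_RADIUS
        pep_cas = pep
    pep_cas = pep_cas + offset

    chain_a = Chain(id="A", residues=_residues_from_trace(dom_cas, domain_sequence, "A"))
    chain_b = Chain(id="B", residues=_residues_from_trace(pep_cas, peptide_sequence, "B"))
    structure = Structure(id=structure_id, chains=[chain_a, chain_b])
    span = domain_span if domain_span is not None else (1, dom_n)
    annotations = [
        DomainAnnotation(structure_id, "A", family, span[0], span[1], "sequence"),
        DomainAnnotation(structure_id, "A", family, span[0], span[1], "structure"),
    ]
    profile_maps = {
        (family, structure_id, "A"): {i: i - span[0] + 1 for i in range(span[0], span[1] + 1)}
    }
    return ToyComplex(
        structure=structure,
        annotations=annotations,
        profile_maps=profile_maps,
        peptide_chain_id="B",
        peptide_span=(1, peptide_len),
    )


def toy_intrachain(
    peptide_len: int = 10,
    seed: int = 0,
    covered_by_structure_domain: bool = True,
    structure_id: Optional[str] = None,
    family: str = "TOYDOM",
) -> ToyComplex:
    """Single-chain decoy: grid domain followed by a strand peptide above it.

    With covered_by_structure_domain the structure-defined (CATH-like) span
    covers the peptide too, so the intrachain filter must reject it; without
    it, the peptide still sits sequentially right after the binding domain
    (separation 1 < 10), exercising the sequence-distance rule.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = peptide_len + 1, 3, 3
    dom_cas = _domain_grid(nx, ny, nz)
    dom_n = len(dom_cas)
    pep_cas = ideal_peptide_coords("strand", peptide_len, seed)
    pep_cas = pep_cas + np.array([CA_SPACING * 0.5, CA_SPACING, (nz - 1) * CA_SPACING + 4.2])
    seq = "".join(rng.choice(list(AA20), size=dom_n + peptide_len))
    cas = np.vstack([dom_cas, pep_cas])
    chain = Chain(id="A", residues=_residues_from_trace(cas, seq, "A"))
    if structure_id is None:
        structure_id = f"toyintra{seed}"
    structure = Structure(id=structure_id, chains=[chain])
    cath_end = dom_n + peptide_len if covered_by_structure_domain else dom_n
    annotations = [
        DomainAnnotation(structure_id, "A", family, 1, dom_n, "sequence"),
        DomainAnnotation(structure_id, "A", family, 1, cath_end, "structure"),
    ]
    profile_maps = {(family, structure_id, "A"): {i: i for i in range(1, dom_n + 1)}}
    return ToyComplex(
        structure=structure,
        annotations=annotations,
        profile_maps=profile_maps,
        peptide_chain_id="A",
        peptide_span=(dom_n + 1, dom_n + peptide_len),
    )


def training_features(
    n_per_class: int = 40,
    seed: int = 0,
    lengths: Sequence[int] = (5, 7, 9, 11, 14),
) -> tuple[list[PeptideFeatures], list[PeptideFeatures]]:
    """Synthetic SVM training set: motif-like strands vs helices and coils.

    Emulates the study conditions of a positive set of bound, linear,
    elongated peptides against a globular-background control: positives are
    ideal strands, negatives alternate between helices and compact coils.
    Features (including internal secondary structure and accessibility) are
    computed from the generated coordinates, never synthesized directly.
    """
    positives, negatives = [], []
    k = 0
    while len(positives) < n_per_class or len(negatives) < n_per_class:
        n = lengths[k % len(lengths)]
        if len(positives) < n_per_class:
            positives.append(_features_of("strand", n, seed * 100003 + k))
        if len(negatives) < n_per_class:
            kind = "helix" if k % 2 == 0 else "coil"
            negatives.append(_features_of(kind, n, seed * 100003 + 50000 + k))
        k += 1
    return positives, negatives


def _features_of(kind: str, n: int, seed: int) -> PeptideFeatures:
    chain = peptide_chain(kind, n, seed)
    st = Structure(id=f"feat{seed}", chains=[chain])
    assign_secondary_structure(st)
    compute_accessibility(st, n_points=240)  # coarse grid is plenty for features
    return features_from_residues(chain.residues)


# ---------------------------------------------------------------------------
# sequence / network fixtures


def _instantiate_pattern(pattern: str, rng: np.random.Generator, alphabet: str, probs) -> str:
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            out.append(rng.choice(list(pattern[i + 1 : j])))
            i = j + 1
        elif ch == ".":
            out.append(rng.choice(list(alphabet), p=probs))
            i += 1
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def synth_motif_set(
    n_upcs: int,
    planted_pattern: Optional[str],
    flank_len: int = 10,
    background_freqs: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> tuple[list[str], list[int]]:
    """One background-flanked sequence per UPC, with an optional planted
    pattern instance at a random offset."""
    if n_upcs < 3:
        raise ValueError("need at least 3 UPCs")
    rng = np.random.default_rng(seed)
    if background_freqs is None:
        background_freqs = {a: 1.0 / len(AA20) for a in AA20}
    alphabet = "".join(sorted(background_freqs))
    probs = np.array([background_freqs[a] for a in alphabet])
    probs = probs / probs.sum()
    sequences = []
    for _u in range(n_upcs):
        flanks = "".join(rng.choice(list(alphabet), size=2 * flank_len, p=probs))
        if planted_pattern is None:
            sequences.append(flanks)
            continue
        instance = _instantiate_pattern(planted_pattern, rng, alphabet, probs)
        if len(instance) > len(flanks):
            raise ValueError("pattern longer than sequence")
        pos = int(rng.integers(0, len(flanks) - len(instance) + 1))
        sequences.append(flanks[:pos] + instance + flanks[pos + len(instance) :])
    return sequences, list(range(n_upcs))


def synth_interactome(
    p: int,
    domain_frac: float = 0.1,
    match_prob_interactor: float = 0.15,
    match_prob_other: float = 0.05,
    seed: int = 0,
    mean_degree: float = 4.0,
    family: str = "DOM",
    pattern: str = "WWKW",
    seq_len: int = 80,
    species: str = "synthetic",
) -> InteractomeNetwork:
    """Random network with planted pattern enrichment among interactors.

    Proteins carry the family with probability domain_frac; edges are
    sampled with a fixed mean degree; a protein whose neighborhood contains
    a carrier receives a pattern match with match_prob_interactor,
    otherwise with match_prob_other. Matches are planted outside domain
    spans; base sequences exclude tryptophan so the W-containing default
    pattern cannot occur by accident.
    """
    if p < 20:
        raise ValueError("need at least 20 proteins")
    for prob in (domain_frac, match_prob_interactor, match_prob_other):
        if not 0.0 <= prob <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"P{i:05d}" for i in range(p)]
    carriers = rng.random(p) < domain_frac
    edge_prob = min(1.0, mean_degree / (p - 1))
    iu = np.triu_indices(p, k=1)
    chosen = rng.random(len(iu[0])) < edge_prob
    edges = {frozenset((ids[a], ids[b])) for a, b in zip(iu[0][chosen], iu[1][chosen])}
    neighbors: dict[str, set[str]] = {pid: set() for pid in ids}
    for e in edges:
        a, b = tuple(e)
        neighbors[a].add(b)
        neighbors[b].add(a)
    carrier_ids = {ids[i] for i in range(p) if carriers[i]}
    base_alphabet = [a for a in AA20 if a not in set(pattern)]
    proteins: dict[str, ProteinRecord] = {}
    dom_len = 20
    for i, pid in enumerate(ids):
        seq = "".join(rng.choice(base_alphabet, size=seq_len))
        domains = [(family, 1, dom_len)] if carriers[i] else []
        is_interactor = bool(neighbors[pid] & carrier_ids)
        q = match_prob_interactor if is_interactor else match_prob_other
        if rng.random() < q:
            pos = int(rng.integers(dom_len + 5, seq_len - len(pattern)))
            seq = seq[:pos] + pattern + seq[pos + len(pattern) :]
        proteins[pid] = ProteinRecord(id=pid, species=species, sequence=seq, domains=domains)
    return InteractomeNetwork(proteins=proteins, edges=edges, species=species)


def synth_benchmark_families(
    seed: int = 0,
    patterns: Optional[Mapping[str, str]] = None,
    n_structures: int = 3,
    n_negatives: int = 3,
):
    """Positive and negative benchmark cases for the scaled LOO benchmark.

    Each family plants one motif pattern into strand 10-mer peptides bound
    to independent decoy domains; negatives are bound helical peptides that
    a motif-likeness classifier must reject. Returns (positives, negatives)
    as lists of pipeline.BenchmarkCase.
    """
    from .pipeline import BenchmarkCase  # local import: pipeline builds on synthfix users

    if patterns is None:
        patterns = {"FAMA": "DE.F", "FAMB": "KW.R", "FAMC": "YH.N"}
    rng = np.random.default_rng(seed)
    probs = np.ones(len(AA20)) / len(AA20)
    positives = []
    for f, (fam, pat) in enumerate(sorted(patterns.items())):
        for i in range(n_structures):
            inst = _instantiate_pattern(pat, rng, AA20, probs)
            flank = "".join(rng.choice(list(AA20), size=10 - len(inst)))
            pos = int(rng.integers(0, 10 - len(inst) + 1))
            seq = flank[:pos] + inst + flank[pos:]
            toy = toy_complex(
                peptide_len=10, seed=seed + 500 + 10 * f + i,
                structure_id=f"{fam.lower()}{i}", family=fam, peptide_sequence=seq,
            )
            positives.append(BenchmarkCase(
                family=fam, structure=toy.structure, annotations=toy.annotations,
                peptide_chain="B", peptide_span=(1, 10),
                profile_maps=toy.profile_maps,
            ))
    negatives = []
    for i in range(n_negatives):
        toy = toy_complex(
            peptide_len=10, peptide_kind="helix", seed=seed + 900 + i,
            structure_id=f"neg{i}", family="NEGFAM",
        )
        negatives.append(BenchmarkCase(
            family="NEGFAM", structure=toy.structure, annotations=toy.annotations,
            peptide_chain="B", peptide_span=(1, 10), profile_maps=toy.profile_maps,
        ))
    return positives, negatives
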