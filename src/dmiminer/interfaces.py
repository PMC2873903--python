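"""Domain–peptide interface filters.

An accepted peptide only becomes a candidate domain–motif interaction when
it forms a genuine, connected interface with a binding domain: at least
60% of its residues contact the domain with no non-contacting run longer
than 4 residues; the domain–peptide interface buries at least 150 Å² (half
buried-SASA convention); and across the N binding domains the summed
interface ratio reaches 0.5 with each domain contributing at least 0.5/N.
Intrachain candidates inside structure-defined (CATH-like) domains or
sequentially closer than 10 residues to their binding domain are
artefacts of domain-boundary mismatches and are rejected, as are
interchain candidates between near-identical (homomeric) chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .candidates import Peptide
from .structio import DomainAnnotation, Residue, shrake_rupley_sasa

__all__ = [
    "ContactMap",
    "CandidateDMI",
    "residue_contacts",
    "domain_contact_filter",
    "interface_area",
    "interface_ratio_filter",
    "intrachain_filters",
    "homomer_filter",
]


@dataclass
class ContactMap:
    peptide_id: str
    domain_id: str
    peptide_span: tuple[int, int]
    peptide_residues: set[int] = field(default_factory=set)  # contacting, seq_index
    domain_residues: set[int] = field(default_factory=set)
    cutoff: float = 5.0


@dataclass
class CandidateDMI:
    peptide: Peptide
    domains: list[DomainAnnotation]
    contact_maps: dict[str, ContactMap] = field(default_factory=dict)  # by domain id
    interface_areas: dict[str, float] = field(default_factory=dict)    # A_dp per domain id
    full_area: Optional[float] = None                                  # A_full
    chain_relation: str = "interchain"  # or "intrachain"
    provenance: list[tuple[str, str]] = field(default_factory=list)    # (filter, pass|fail)

    def record(self, filter_name: str, passed: bool) -> bool:
        self.provenance.append((filter_name, "pass" if passed else "fail"))
        return passed

    def ratios(self) -> dict[str, float]:
        if not self.full_area:
            raise ValueError("full interface area is zero or unset")
        return {d: a / self.full_area for d, a in self.interface_areas.items()}


def domain_id(d: DomainAnnotation) -> str:
    return f"{d.structure}/{d.chain}:{d.family}:{d.start}-{d.end}"


def residue_contacts(
    peptide_residues: Sequence[Residue],
    domain_residues: Sequence[Residue],
    cutoff: float = 5.0,
    peptide_id: str = "",
    domain_id: str = "",
) -> ContactMap:
    """Residue pairs with any heavy-atom distance <= cutoff (Å)."""
    cm = ContactMap(
        peptide_id=peptide_id,
        domain_id=domain_id,
        peptide_span=(peptide_residues[0].seq_index, peptide_residues[-1].seq_index),
        cutoff=cutoff,
    )
    d_coords, d_owner = [], []
    for res in domain_residues:
        d_coords.append(res.heavy_atoms)
        d_owner.extend([res.seq_index] * len(res.heavy_atoms))
    if not d_coords:
        return cm
    tree = cKDTree(np.vstack(d_coords))
    d_owner_arr = np.asarray(d_owner)
    for res in peptide_residues:
        if len(res.heavy_atoms) == 0:
            continue
        hits = tree.query_ball_point(res.heavy_atoms, cutoff)
        touched = {d_owner_arr[j] for lst in hits for j in lst}
        if touched:
            cm.peptide_residues.add(res.seq_index)
            cm.domain_residues.update(touched)
    return cm


def domain_contact_filter(cm: ContactMap, peptide_length: int, min_fraction: float = 0.60, max_gap: int = 4) -> bool:
    """Connected-interface rule: >= 60% of peptide residues in contact and
    no run of more than 4 consecutive non-contacting residues."""
    start, end = cm.peptide_span
    if peptide_length != end - start + 1:
        raise ValueError("peptide_length inconsistent with contact-map span")
    contacting = len(cm.peptide_residues)
    if contacting / peptide_length < min_fraction:
        return False
    run = 0
    for idx in range(start, end + 1):
        if idx in cm.peptide_residues:
            run = 0
        else:
            run += 1
            if run > max_gap:
                return False
    return True


def _group_sasa(residues: Sequence[Residue], probe_radius: float, n_points: int) -> float:
    coords, elements = [], []
    for res in residues:
        if len(res.heavy_atoms) == 0:
            continue
        coords.append(res.heavy_atoms)
        elements.extend(res.elements or ["C"] * len(res.heavy_atoms))
    if not coords:
        raise ValueError("residue group has no heavy atoms")
    return float(
        shrake_rupley_sasa(np.vstack(coords), elements, probe_radius=probe_radius, n_points=n_points).sum()
    )


def interface_area(
    group_a: Sequence[Residue],
    group_b: Sequence[Residue],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Buried area per side: (SASA_a + SASA_b - SASA_ab) / 2, Å².

    Symmetric in its arguments and zero for non-touching groups (clamped at
    zero against SASA discretization noise).
    """
    if not group_a or not group_b:
        raise ValueError("interface_area requires two non-empty residue groups")
    sa = _group_sasa(group_a, probe_radius, n_points)
    sb = _group_sasa(group_b, probe_radius, n_points)
    sab = _group_sasa(list(group_a) + list(group_b), probe_radius, n_points)
    return max(0.0, (sa + sb - sab) / 2.0)


def interface_ratio_filter(
    c: CandidateDMI,
    min_area: float = 150.0,
    min_total_ratio: float = 0.5,
) -> Optional[CandidateDMI]:
    """Stoichiometry-aware interface size/ratio rule.

    With N current domains, every domain whose ratio r_d = A_dp / A_full
    falls below min_total_ratio / N is dropped; N is recomputed and the
    rule re-applied until no domain is removed. The candidate is accepted
    (with the retained domains) iff the remaining ratios sum to at least
    min_total_ratio, each retained r_d >= min_total_ratio / N, and each
    retained A_dp >= min_area. Returns the pruned candidate or None.
    """
    if not c.full_area:
        raise ValueError(f"{c.peptide.id}: no inter-protein interface (A_full is zero/unset)")
    retained = [d for d in c.domains]
    while True:
        n = len(retained)
        if n == 0:
            c.record("interface_ratio", False)
            return None
        threshold = min_total_ratio / n
        drops = [
            d for d in retained
            if c.interface_areas[domain_id(d)] / c.full_area < threshold
        ]
        if not drops:
            break
        retained = [d for d in retained if d not in drops]
    ratios = [c.interface_areas[domain_id(d)] / c.full_area for d in retained]
    areas = [c.interface_areas[domain_id(d)] for d in retained]
    ok = (
        sum(ratios) >= min_total_ratio
        and all(r >= min_total_ratio / len(retained) for r in ratios)
        and all(a >= min_area for a in areas)
    )
    c.record("interface_ratio", ok)
    if not ok:
        return None
    c.domains = retained
    c.contact_maps = {domain_id(d): c.contact_maps[domain_id(d)] for d in retained}
    c.interface_areas = {domain_id(d): c.interface_areas[domain_id(d)] for d in retained}
    return c


def intrachain_filters(
    c: CandidateDMI,
    structure_domains: Sequence[DomainAnnotation],
    min_seq_dist: int = 10,
) -> bool:
    """Intrachain artefact rules.

    Fails when the peptide lies within any structure-defined (CATH-like)
    domain span on its chain, or when the minimum sequence separation
    between any peptide residue and its binding domain's boundary is below
    min_seq_dist. A separation of exactly min_seq_dist passes.
    """
    if c.chain_relation != "intrachain":
        raise ValueError("intrachain_filters applies to intrachain candidates only")
    pep = c.peptide
    for dom in structure_domains:
        if dom.kind != "structure" or dom.structure != pep.structure or dom.chain != pep.chain:
            continue
        if dom.start <= pep.start and pep.end <= dom.end:
            c.record("intrachain_cath", False)
            return False
    c.record("intrachain_cath", True)
    for dom in c.domains:
        if dom.chain != pep.chain:
            continue
        if pep.end < dom.start:
            dist = dom.start - pep.end
        elif dom.end < pep.start:
            dist = pep.start - dom.end
        else:
            dist = 0  # overlap
        if dist < min_seq_dist:
            c.record("intrachain_seqdist", False)
            return False
    c.record("intrachain_seqdist", True)
    return True


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -1.0
_aligner.extend_gap_score = -0.5

# Homomer detection compares chains of very different lengths (a short
# peptide chain against a full domain chain). A gapped global alignment can
# embed almost any short sequence into a long one, so identity over the
# shorter sequence must come from a semi-global alignment: end gaps are
# free, internal gaps are effectively forbidden.
_homomer_aligner = Align.PairwiseAligner()
_homomer_aligner.mode = "global"
_homomer_aligner.match_score = 1.0
_homomer_aligner.mismatch_score = 0.0
_homomer_aligner.open_internal_gap_score = -1e9
_homomer_aligner.extend_internal_gap_score = -1e9
_homomer_aligner.end_gap_score = 0.0


def global_identity(seq_a: str, seq_b: str, over: str = "columns") -> float:
    """Global-alignment identity.

    over='columns': identical pairs / alignment length (for clustering);
    over='shorter': identical pairs / length of shorter sequence (for
    homomer detection).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = _homomer_aligner if over == "shorter" else _aligner
    aln = aligner.align(seq_a, seq_b)[0]
    ident = 0
    a, b = aln[0], aln[1]
    for x, y in zip(a, b):
        if x == y and x != "-":
            ident += 1
    if over == "columns":
        return ident / len(a)
    if over == "shorter":
        return ident / min(len(seq_a), len(seq_b))
    raise ValueError(f"unknown normalization {over!r}")


def homomer_filter(
    domain_chain_seq: str,
    peptide_chain_seq: str,
    identity_threshold: float = 0.98,
) -> bool:
    """True (keep) unless the two chains are near-identical (homomer).

    Identity is measured over the shorter sequence after global alignment;
    peptide-mediated interactions between copies of the same protein are
    usually crystallographic artefacts.
    """
    return global_identity(domain_chain_seq, peptide_chain_seq, over="shorter") < identity_threshold
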