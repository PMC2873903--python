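"""End-to-end discovery runs and the leave-one-domain-out benchmark.

`run_discovery` executes the full filter cascade in order — peptide
enumeration outside sequence-domain masks, SVM classification, the
connected-contact rule, covered-peptide removal, intrachain and homomer
artefact filters, the interface size/ratio rule — then clusters the
surviving candidates by interface topology and by combined sequence
identity, selects eligible interaction types and derives consensus motifs.
Per-stage survivor counts are recorded so any filter can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import motifs as motifs_mod
from .candidates import (
    Peptide,
    PeptideRegion,
    SvmModel,
    build_peptide_regions,
    classify_peptides,
    enumerate_peptides,
    remove_covered_peptides,
    train_svm,
)
from .clustering import (
    TopologyCluster,
    complete_linkage,
    interface_profile_positions,
    sequence_clusters,
    topology_distance,
)
from .geometry import PeptideFeatures, features_from_residues
from .interfaces import (
    CandidateDMI,
    domain_contact_filter,
    domain_id,
    homomer_filter,
    interface_area,
    interface_ratio_filter,
    intrachain_filters,
    residue_contacts,
)
from .motifs import (
    MemberInfo,
    MotifResult,
    background_frequencies,
    find_motifs,
    helical_mode,
    required_modifications,
    select_eligible_clusters,
)
from .structio import (
    DomainAnnotation,
    Structure,
    assign_secondary_structure,
    compute_accessibility,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "DiscoveryResult", "run_discovery", "run_loo_benchmark", "BenchmarkCase"]


@dataclass
class RunConfig:
    """All pipeline thresholds, serialized into run metadata."""

    lmin: int = 4
    lmax: int = 20
    contact_cutoff: float = 5.0          # Å, heavy-atom
    min_contact_fraction: float = 0.60
    max_contact_gap: int = 4
    min_interface_area: float = 150.0    # Å², per domain-peptide interface
    min_total_ratio: float = 0.5         # summed interface ratio (0.5/N per domain)
    min_seq_dist: int = 10               # intrachain peptide-domain separation
    homomer_identity: float = 0.98
    topo_cut: float = 1.0
    seq_cut: float = 0.1                 # 90% combined identity
    min_upcs: int = 3
    motif_p: float = 0.05
    enrichment_p: float = 0.025
    sasa_points: int = 960
    probe_radius: float = 1.4
    svm_cost_factor: float = 10.0
    svm_tradeoff: float = 0.1
    seed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ClusterMotifs:
    family: str
    cluster_id: int
    member_ids: list[str]
    motifs: list[MotifResult]


@dataclass
class DiscoveryResult:
    candidates: list[CandidateDMI]
    regions: list[PeptideRegion]
    topo_clusters: list[TopologyCluster]
    upc_of_member: dict[str, int]
    cluster_motifs: list[ClusterMotifs]
    stage_counts: dict[str, int]
    config: dict


def _chains_are_homomer(struct: Structure, chain_a: str, chain_b: str, threshold: float) -> bool:
    return not homomer_filter(
        struct.get_chain(chain_a).sequence,
        struct.get_chain(chain_b).sequence,
        identity_threshold=threshold,
    )


def run_discovery(
    structures: Sequence[Structure],
    annotations: Sequence[DomainAnnotation],
    model: SvmModel,
    config: Optional[RunConfig] = None,
    profile_maps: Optional[Mapping[tuple[str, str, str], Mapping[int, int]]] = None,
    modified_residues: Optional[Mapping[tuple[str, str, int], str]] = None,
    ddi_pairs: Iterable[tuple[str, str]] = (),
    background: Optional[Mapping[str, float]] = None,
) -> DiscoveryResult:
    """Run the discovery cascade on a set of structures.

    Stage order: biological-unit gate, peptide enumeration, SVM, contact
    filter, covered-peptide removal, intrachain filters, homomer filter,
    interface size/ratio, then clustering, eligibility, and motif
    derivation. Deterministic for fixed inputs and config.
    """
    cfg = config or RunConfig()
    profile_maps = dict(profile_maps or {})
    modified_residues = dict(modified_residues or {})
    ddi_set = {frozenset(p) for p in ddi_pairs}
    counts: dict[str, int] = {}

    structures = [s for s in structures if s.is_biological_unit]
    counts["structures"] = len(structures)
    struct_by_id = {s.id: s for s in structures}
    ann_by_struct: dict[str, list[DomainAnnotation]] = {}
    for a in annotations:
        ann_by_struct.setdefault(a.structure, []).append(a)

    for st in structures:
        if not all(r.ss_assigned for c in st.chains for r in c.residues):
            assign_secondary_structure(st)
        if any(r.accessibility is None for c in st.chains for r in c.residues):
            compute_accessibility(st, probe_radius=cfg.probe_radius, n_points=cfg.sasa_points)
        for chain in st.chains:
            for res in chain.residues:
                label = modified_residues.get((st.id, chain.id, res.seq_index))
                if label is not None:
                    res.modified = label

    # 1-2: enumerate windows outside sequence-domain masks
    peptides: list[Peptide] = []
    for st in structures:
        anns = ann_by_struct.get(st.id, [])
        for chain in st.chains:
            masks = [a.span for a in anns if a.kind == "sequence" and a.chain == chain.id]
            peptides.extend(
                enumerate_peptides(chain, masks, structure_id=st.id, lmin=cfg.lmin, lmax=cfg.lmax)
            )
    counts["enumerated"] = len(peptides)

    # 3: SVM
    accepted = [p for p in classify_peptides(model, peptides) if p.accepted]
    counts["svm_accepted"] = len(accepted)

    # 4: contact filter -> provisional candidates
    provisional: dict[str, CandidateDMI] = {}
    for pep in accepted:
        st = struct_by_id[pep.structure]
        pep_res = st.get_chain(pep.chain).residues[pep.start - 1 : pep.end]
        passing: list[DomainAnnotation] = []
        cms = {}
        for dom in ann_by_struct.get(pep.structure, []):
            if dom.kind != "sequence":
                continue
            if dom.chain == pep.chain and not (pep.end < dom.start or dom.end < pep.start):
                continue  # peptide windows never overlap their own masks
            dom_res = st.get_chain(dom.chain).residues[dom.start - 1 : dom.end]
            cm = residue_contacts(
                pep_res, dom_res, cutoff=cfg.contact_cutoff,
                peptide_id=pep.id, domain_id=domain_id(dom),
            )
            if not cm.peptide_residues:
                continue
            if domain_contact_filter(
                cm, len(pep), min_fraction=cfg.min_contact_fraction, max_gap=cfg.max_contact_gap
            ):
                passing.append(dom)
                cms[domain_id(dom)] = cm
        if passing:
            relation = "intrachain" if all(d.chain == pep.chain for d in passing) else "interchain"
            cand = CandidateDMI(peptide=pep, domains=passing, contact_maps=cms, chain_relation=relation)
            cand.record("contact", True)
            provisional[pep.id] = cand
    counts["contact_passed"] = len(provisional)

    # 5: covered-peptide removal
    surviving_peps = remove_covered_peptides([c.peptide for c in provisional.values()])
    candidates = [provisional[p.id] for p in surviving_peps]
    counts["after_covered_removal"] = len(candidates)

    # 6-7: intrachain artefact filters; homomer filter for interchain
    kept: list[CandidateDMI] = []
    for cand in candidates:
        if cand.chain_relation == "intrachain":
            struct_domains = [
                a for a in ann_by_struct.get(cand.peptide.structure, []) if a.kind == "structure"
            ]
            if intrachain_filters(cand, struct_domains, min_seq_dist=cfg.min_seq_dist):
                kept.append(cand)
            continue
        st = struct_by_id[cand.peptide.structure]
        retained = [
            d for d in cand.domains
            if d.chain == cand.peptide.chain
            or not _chains_are_homomer(st, d.chain, cand.peptide.chain, cfg.homomer_identity)
        ]
        if cand.record("homomer", bool(retained)):
            cand.domains = retained
            cand.contact_maps = {domain_id(d): cand.contact_maps[domain_id(d)] for d in retained}
            kept.append(cand)
    candidates = kept
    counts["after_context_filters"] = len(candidates)

    # 8: interface size and ratio
    final: list[CandidateDMI] = []
    for cand in candidates:
        st = struct_by_id[cand.peptide.structure]
        pep_res = st.get_chain(cand.peptide.chain).residues[cand.peptide.start - 1 : cand.peptide.end]
        for dom in cand.domains:
            dom_res = st.get_chain(dom.chain).residues[dom.start - 1 : dom.end]
            cand.interface_areas[domain_id(dom)] = interface_area(
                pep_res, dom_res, probe_radius=cfg.probe_radius, n_points=cfg.sasa_points
            )
        if cand.chain_relation == "interchain":
            partner_chains = sorted({d.chain for d in cand.domains if d.chain != cand.peptide.chain})
            partner_res = [r for cid in partner_chains for r in st.get_chain(cid).residues]
            own = st.get_chain(cand.peptide.chain).residues
            cand.full_area = interface_area(
                own, partner_res, probe_radius=cfg.probe_radius, n_points=cfg.sasa_points
            )
        else:
            chain_res = st.get_chain(cand.peptide.chain).residues
            dom_idx = {
                i for d in cand.domains for i in range(d.start, d.end + 1)
            }
            dom_res = [r for r in chain_res if r.seq_index in dom_idx]
            rest = [r for r in chain_res if r.seq_index not in dom_idx]
            cand.full_area = interface_area(
                dom_res, rest, probe_radius=cfg.probe_radius, n_points=cfg.sasa_points
            )
        if cand.full_area <= 0:
            cand.record("interface_ratio", False)
            continue
        pruned = interface_ratio_filter(
            cand, min_area=cfg.min_interface_area, min_total_ratio=cfg.min_total_ratio
        )
        if pruned is not None:
            final.append(pruned)
    counts["after_interface_ratio"] = len(final)

    # peptide regions (for motif support and sequence clustering)
    regions = build_peptide_regions([c.peptide for c in final])
    region_of_pep: dict[str, PeptideRegion] = {}
    for reg in regions:
        for mid in reg.member_ids:
            region_of_pep[mid] = reg
    counts["regions"] = len(regions)

    # clustering per family
    topo_clusters: list[TopologyCluster] = []
    upc_of_member: dict[str, int] = {}
    member_info: dict[str, MemberInfo] = {}
    by_family: dict[str, list[tuple[CandidateDMI, DomainAnnotation]]] = {}
    for cand in final:
        for dom in cand.domains:
            by_family.setdefault(dom.family, []).append((cand, dom))

    upc_base = 0
    for family in sorted(by_family):
        members = by_family[family]
        member_ids = [f"{c.peptide.id}|{domain_id(d)}" for c, d in members]
        positions = []
        domain_cols = []
        region_seqs = []
        for (cand, dom), mid in zip(members, member_ids):
            pmap = profile_maps.get((family, dom.structure, dom.chain))
            if pmap is None:  # identity fallback: columns are span offsets
                pmap = {i: i - dom.start + 1 for i in range(dom.start, dom.end + 1)}
            cm = cand.contact_maps[domain_id(dom)]
            positions.append(interface_profile_positions(cm, pmap))
            chain_seq = struct_by_id[dom.structure].get_chain(dom.chain).sequence
            domain_cols.append(
                {col: chain_seq[idx - 1] for idx, col in pmap.items() if idx <= len(chain_seq)}
            )
            region_seqs.append(region_of_pep[cand.peptide.id].sequence)
        n = len(members)
        dmat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dmat[i, j] = dmat[j, i] = topology_distance(positions[i], positions[j])
        for cid, grp in enumerate(complete_linkage(dmat, cfg.topo_cut)):
            consensus: set[int] = set.intersection(*(positions[i] for i in grp))
            topo_clusters.append(
                TopologyCluster(
                    family=family,
                    cluster_id=cid,
                    member_ids=[member_ids[i] for i in grp],
                    consensus_interface=consensus,
                )
            )
        for sc in sequence_clusters(member_ids, domain_cols, region_seqs, cut=cfg.seq_cut):
            for mid in sc.member_ids:
                upc_of_member[mid] = upc_base + sc.cluster_id
        upc_base += n  # keep UPC ids unique across families

        for (cand, dom), mid in zip(members, member_ids):
            pep_chain_fams = {
                a.family
                for a in ann_by_struct.get(cand.peptide.structure, [])
                if a.kind == "sequence" and a.chain == cand.peptide.chain
            }
            interchain = dom.chain != cand.peptide.chain
            if interchain:
                ddi_known = any(
                    frozenset((fa, dom.family)) in ddi_set for fa in pep_chain_fams
                )
            else:
                ddi_known = False  # intrachain pairs have no inter-protein DDI
            member_info[mid] = MemberInfo(
                member_id=mid,
                upc_id=upc_of_member[mid],
                interchain=interchain,
                ddi_free=not ddi_known,
            )
    counts["topology_clusters"] = len(topo_clusters)
    counts["upcs"] = len(set(upc_of_member.values()))

    # eligibility + motif derivation
    eligible = select_eligible_clusters(topo_clusters, member_info, min_upcs=cfg.min_upcs)
    counts["eligible_clusters"] = len(eligible)
    if background is None and eligible:
        background = background_frequencies([c.sequence for s in structures for c in s.chains])

    cand_by_pep = {c.peptide.id: c for c in final}
    cluster_motifs: list[ClusterMotifs] = []
    for tc in eligible:
        seqs, upcs, ss_classes, mods = [], [], [], []
        seen_regions = set()
        for mid in tc.member_ids:
            pep_id = mid.split("|")[0]
            cand = cand_by_pep[pep_id]
            reg = region_of_pep[pep_id]
            ss_classes.append(cand.peptide.features.ss_class)
            st = struct_by_id[cand.peptide.structure]
            chain = st.get_chain(cand.peptide.chain)
            mods.append(
                {
                    r.seq_index - reg.start: r.modified
                    for r in chain.residues[reg.start - 1 : reg.end]
                    if r.modified is not None
                }
            )
            if reg.id in seen_regions:
                continue
            seen_regions.add(reg.id)
            seqs.append(reg.sequence)
            upcs.append(upc_of_member[mid])
        helical = helical_mode(ss_classes)
        req = required_modifications(mods)
        results = find_motifs(
            seqs, upcs, background,
            required_mods=req, helical=helical, p_threshold=cfg.motif_p,
        )
        cluster_motifs.append(
            ClusterMotifs(
                family=tc.family, cluster_id=tc.cluster_id,
                member_ids=list(tc.member_ids), motifs=results,
            )
        )
    counts["clusters_with_motifs"] = sum(1 for cm in cluster_motifs if cm.motifs)

    return DiscoveryResult(
        candidates=final,
        regions=regions,
        topo_clusters=topo_clusters,
        upc_of_member=upc_of_member,
        cluster_motifs=cluster_motifs,
        stage_counts=counts,
        config=cfg.as_dict(),
    )


# ---------------------------------------------------------------------------
# leave-one-domain-out benchmark


@dataclass
class BenchmarkCase:
    """One known domain-peptide interaction for the benchmark."""

    family: str
    structure: Structure
    annotations: list[DomainAnnotation]
    peptide_chain: str
    peptide_span: tuple[int, int]
    profile_maps: dict = field(default_factory=dict)


@dataclass
class BenchmarkReport:
    per_family: dict[str, float]        # sensitivity per held-out family
    sensitivity: float                  # over counted positives
    ignored_families: list[str]         # too few non-redundant sequences
    n_negative_accepted: int
    specificity: float


def _case_features(case: BenchmarkCase, cfg: RunConfig) -> PeptideFeatures:
    st = case.structure
    if not all(r.ss_assigned for c in st.chains for r in c.residues):
        assign_secondary_structure(st)
    if any(r.accessibility is None for c in st.chains for r in c.residues):
        compute_accessibility(st, probe_radius=cfg.probe_radius, n_points=cfg.sasa_points)
    chain = st.get_chain(case.peptide_chain)
    s, e = case.peptide_span
    return features_from_residues(chain.residues[s - 1 : e])


def run_loo_benchmark(
    positives: Sequence[BenchmarkCase],
    background_features: Sequence[PeptideFeatures],
    config: Optional[RunConfig] = None,
    negatives: Sequence[BenchmarkCase] = (),
) -> BenchmarkReport:
    """Leave-one-domain-out benchmark.

    For each family, the SVM is retrained without that family's peptides
    and discovery is rerun on its structures. A case counts positive when
    an accepted surviving peptide overlaps the test peptide in at least 3
    sequence positions and its topological cluster yields a significant
    pattern. Families whose clusters have fewer than the minimum number of
    non-redundant sequences are ignored, not counted as false negatives.
    Negative cases are scored with the all-family model; specificity is the
    fraction rejected.
    """
    cfg = config or RunConfig()
    families = sorted({c.family for c in positives})
    if len(families) < 2:
        raise ValueError("benchmark requires at least 2 domain families")

    feats = {id(c): _case_features(c, cfg) for c in positives}
    per_family: dict[str, float] = {}
    ignored: list[str] = []
    n_pos_total, n_pos_hit = 0, 0
    for fam in families:
        train_pos = [feats[id(c)] for c in positives if c.family != fam]
        model = train_svm(
            train_pos, list(background_features),
            cost_factor=cfg.svm_cost_factor, tradeoff=cfg.svm_tradeoff,
        )
        test_cases = [c for c in positives if c.family == fam]
        anns = [a for c in test_cases for a in c.annotations]
        pmaps = {}
        for c in test_cases:
            pmaps.update(c.profile_maps)
        result = run_discovery(
            [c.structure for c in test_cases], anns, model, cfg, profile_maps=pmaps
        )
        sig_clusters = {
            (cm.family, cm.cluster_id) for cm in result.cluster_motifs if cm.motifs
        }
        mid_cluster = {
            mid: (tc.family, tc.cluster_id)
            for tc in result.topo_clusters
            for mid in tc.member_ids
        }
        searched = {(cm.family, cm.cluster_id) for cm in result.cluster_motifs}
        if not searched:
            ignored.append(fam)
            continue
        hits = 0
        for case in test_cases:
            s, e = case.peptide_span
            found = False
            for cand in result.candidates:
                pep = cand.peptide
                if pep.structure != case.structure.id or pep.chain != case.peptide_chain:
                    continue
                overlap = min(e, pep.end) - max(s, pep.start) + 1
                if overlap < 3:
                    continue
                mids = [f"{pep.id}|{domain_id(d)}" for d in cand.domains]
                if any(mid_cluster.get(m) in sig_clusters for m in mids):
                    found = True
                    break
            hits += int(found)
        per_family[fam] = hits / len(test_cases)
        n_pos_total += len(test_cases)
        n_pos_hit += hits

    n_neg_accepted = 0
    if negatives:
        model = train_svm(
            [feats[id(c)] for c in positives], list(background_features),
            cost_factor=cfg.svm_cost_factor, tradeoff=cfg.svm_tradeoff,
        )
        for case in negatives:
            result = run_discovery(
                [case.structure], case.annotations, model, cfg, profile_maps=case.profile_maps
            )
            if result.candidates:
                n_neg_accepted += 1
    return BenchmarkReport(
        per_family=per_family,
        sensitivity=(n_pos_hit / n_pos_total) if n_pos_total else float("nan"),
        ignored_families=ignored,
        n_negative_accepted=n_neg_accepted,
        specificity=(1.0 - n_neg_accepted / len(negatives)) if negatives else float("nan"),
    )
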