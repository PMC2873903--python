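"""Grouping candidate interactions into interaction types and UPCs.

Interfaces of one domain family are compared on profile-normalized contact
positions: mapping each domain's contacting residues to the columns of the
family profile makes interfaces from different structures directly
comparable. A Dice-style distance (1 at no shared contacts, or when one
interface has more than double the contacts of the other) feeds
complete-linkage clustering cut at 1.0, yielding *topological clusters*
(interaction types). Independently, candidates are grouped into
*unrelated protein clusters* (UPCs) by a combined domain+peptide sequence
identity, complete linkage cut at 0.1 (= 90% combined identity), so that
near-duplicate structures lend a motif support only once.

Both distance formulas are reconstructions from their stated anchors
(zero on identity, one on disjoint contact sets, the double-size override;
0.1 corresponding to 90% combined identity) — see the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .interfaces import ContactMap, global_identity

__all__ = [
    "TopologyCluster",
    "SequenceCluster",
    "interface_profile_positions",
    "topology_distance",
    "complete_linkage",
    "pairwise_identity_domains",
    "pairwise_identity_peptides",
    "combined_distance",
    "sequence_clusters",
]

logger = logging.getLogger(__name__)


@dataclass
class TopologyCluster:
    family: str
    cluster_id: int
    member_ids: list[str] = field(default_factory=list)
    consensus_interface: set[int] = field(default_factory=set)  # profile columns


@dataclass
class SequenceCluster:
    cluster_id: int
    member_ids: list[str] = field(default_factory=list)


def interface_profile_positions(cm: ContactMap, profile_map: Mapping[int, int]) -> set[int]:
    """Translate contacting domain residues into profile columns.

    Residues outside the map (insertions relative to the profile) are
    dropped with a warning, mirroring unmatched lowercase positions in a
    profile alignment.
    """
    if not profile_map:
        raise ValueError("empty profile map")
    cols = set()
    for seq_index in cm.domain_residues:
        if seq_index in profile_map:
            cols.add(profile_map[seq_index])
        else:
            logger.warning(
                "contact at unmapped residue %d (domain %s) dropped", seq_index, cm.domain_id
            )
    return cols


def topology_distance(pos_a: set[int], pos_b: set[int]) -> float:
    """Interface-topology distance in [0, 1].

    1 when one interface has more than double the other's contacts;
    otherwise the Dice-style 1 - 2|A∩B|/(|A|+|B|): 0 iff identical sets,
    1 iff disjoint.
    """
    na, nb = len(pos_a), len(pos_b)
    if na == 0 or nb == 0:
        raise ValueError("empty contact-position set")
    if max(na, nb) > 2 * min(na, nb):
        return 1.0
    return 1.0 - 2.0 * len(pos_a & pos_b) / (na + nb)


def complete_linkage(dist_matrix: np.ndarray, cut: float) -> list[list[int]]:
    """Complete-linkage agglomeration; merges happen strictly below `cut`.

    Ties are broken by merging the lexicographically smallest cluster pair
    (clusters compared by their sorted member tuples), making the result
    independent of input permutation. Returns sorted member-index lists.
    """
    d = np.asarray(dist_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = max(d[a, b] for a in clusters[i] for b in clusters[j])
                key = (dist, tuple(clusters[i]), tuple(clusters[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dist, _, _), i, j = best
        if dist >= cut:
            break
        merged = sorted(clusters[i] + clusters[j])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        clusters.sort()
    return sorted(clusters)


def pairwise_identity_domains(
    cols_a: Mapping[int, str], cols_b: Mapping[int, str]
) -> float:
    """Domain sequence identity over shared profile columns.

    Each argument maps profile column -> residue one-letter code; identity
    is identical residues / number of columns mapped in both (0 when none
    is shared).
    """
    if not cols_a or not cols_b:
        raise ValueError("empty profile-column mapping")
    shared = set(cols_a) & set(cols_b)
    if not shared:
        return 0.0
    same = sum(1 for c in shared if cols_a[c] == cols_b[c])
    return same / len(shared)


def pairwise_identity_peptides(seq_a: str, seq_b: str) -> float:
    """Needleman–Wunsch global identity: identical positions / aligned length."""
    return global_identity(seq_a, seq_b, over="columns")


def combined_distance(sd: float, sp: float) -> float:
    """Combined domain+peptide distance: 1 - (sd + sp)/2, in [0, 1]."""
    if not (0.0 <= sd <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValueError("identities must lie in [0, 1]")
    return 1.0 - (sd + sp) / 2.0


def sequence_clusters(
    member_ids: Sequence[str],
    domain_cols: Sequence[Mapping[int, str]],
    region_seqs: Sequence[str],
    cut: float = 0.1,
) -> list[SequenceCluster]:
    """Complete-linkage UPCs of one family's candidates at the given cut.

    Distances combine profile-aligned domain identity with global peptide
    (region) identity; the default cut 0.1 corresponds to 90% combined
    sequence identity.
    """
    n = len(member_ids)
    if not (len(domain_cols) == len(region_seqs) == n):
        raise ValueError("member_ids, domain_cols and region_seqs must align")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sd = pairwise_identity_domains(domain_cols[i], domain_cols[j])
            sp = pairwise_identity_peptides(region_seqs[i], region_seqs[j])
            d[i, j] = d[j, i] = combined_distance(sd, sp)
    groups = complete_linkage(d, cut)
    return [
        SequenceCluster(cluster_id=k, member_ids=[member_ids[i] for i in grp])
        for k, grp in enumerate(groups)
    ]
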