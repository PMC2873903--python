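"""Cross-validation of derived motifs in protein-interaction networks.

A real recognition motif should be over-represented among proteins that
interact with carriers of its binding domain. For a domain family and a
pattern, each protein in the interactome is classified by (a) whether it
interacts with a family carrier, counting only interactions that cannot be
explained by a known domain-domain interaction, and (b) whether it matches
the pattern entirely outside its own globular domains. The resulting 2x2
table yields an enrichment factor (i_m/i)/(m/p) and a one-sided Fisher
exact p-value (hypergeometric upper tail, computed with log-factorials).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ProteinRecord",
    "InteractomeNetwork",
    "EnrichmentResult",
    "load_interactome",
    "filter_ddi_edges",
    "match_outside_domains",
    "build_contingency",
    "enrichment_factor",
    "fisher_one_sided",
    "test_enrichment",
]


@dataclass
class ProteinRecord:
    id: str
    species: str = ""
    sequence: str = ""
    domains: list[tuple[str, int, int]] = field(default_factory=list)  # (family, start, end)

    def families(self) -> set[str]:
        return {f for f, _, _ in self.domains}


@dataclass
class InteractomeNetwork:
    proteins: dict[str, ProteinRecord]
    edges: set[frozenset[str]]
    species: str = ""

    def neighbors(self, pid: str) -> set[str]:
        out = set()
        for e in self.edges:
            if pid in e:
                other = set(e) - {pid}
                out.add(next(iter(other)) if other else pid)
        return out

    def neighbor_index(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {p: set() for p in self.proteins}
        for e in self.edges:
            pair = tuple(e)
            if len(pair) == 1:
                continue
            a, b = pair
            idx[a].add(b)
            idx[b].add(a)
        return idx


@dataclass
class EnrichmentResult:
    pattern: str
    family: str
    i_m: int  # interactor proteins with a match
    i: int    # interactor proteins
    m: int    # all proteins with a match
    p: int    # all proteins
    enrichment: float
    p_value: float


def _parse_domains(cell: str) -> list[tuple[str, int, int]]:
    out = []
    if not cell or (isinstance(cell, float) and math.isnan(cell)):
        return out
    for item in str(cell).split(";"):
        item = item.strip()
        if not item:
            continue
        fam, span = item.split(":")
        s, e = span.split("-")
        out.append((fam, int(s), int(e)))
    return out


def load_interactome(
    edges_path: str | Path,
    proteins_path: str | Path,
    sequences: Optional[Mapping[str, str]] = None,
    fasta_path: str | Path | None = None,
) -> InteractomeNetwork:
    """Load an interactome from an edge TSV and a protein TSV.

    Protein table columns: id, species, domains ("fam:start-end;..."),
    optionally sequence. Sequences may instead come from a FASTA file or a
    mapping. Duplicate and reversed edges collapse to one undirected edge;
    edges between proteins of different species are dropped.
    """
    pdf = pd.read_csv(proteins_path, sep="\t", dtype=str).fillna("")
    proteins: dict[str, ProteinRecord] = {}
    for row in pdf.itertuples(index=False):
        rec = ProteinRecord(
            id=row.id,
            species=getattr(row, "species", ""),
            sequence=getattr(row, "sequence", ""),
            domains=_parse_domains(getattr(row, "domains", "")),
        )
        proteins[rec.id] = rec
    if fasta_path is not None:
        from Bio import SeqIO

        for record in SeqIO.parse(str(fasta_path), "fasta"):
            if record.id in proteins:
                proteins[record.id].sequence = str(record.seq)
    if sequences:
        for pid, seq in sequences.items():
            if pid in proteins:
                proteins[pid].sequence = seq
    edf = pd.read_csv(edges_path, sep="\t", dtype=str, header=None, names=["a", "b"], comment="#")
    edges: set[frozenset[str]] = set()
    unknown = set()
    for row in edf.itertuples(index=False):
        a, b = row.a, row.b
        if a not in proteins or b not in proteins:
            unknown.update(x for x in (a, b) if x not in proteins)
            continue
        if proteins[a].species != proteins[b].species:
            continue  # cross-species (hybrid) interaction
        if a == b:
            continue
        edges.add(frozenset((a, b)))
    if unknown:
        raise ValueError(f"edges reference unknown proteins: {sorted(unknown)[:10]}")
    species = {r.species for r in proteins.values()}
    return InteractomeNetwork(
        proteins=proteins,
        edges=edges,
        species=next(iter(species)) if len(species) == 1 else "",
    )


def filter_ddi_edges(
    net: InteractomeNetwork, ddi_family_pairs: Iterable[tuple[str, str]]
) -> InteractomeNetwork:
    """Remove edges explainable by a known domain-domain interaction.

    An edge is dropped when the two proteins carry a family pair present in
    the DDI table (unordered)."""
    ddi = {frozenset(p) for p in ddi_family_pairs}
    kept = set()
    for e in net.edges:
        a, b = tuple(e)
        fams_a = net.proteins[a].families()
        fams_b = net.proteins[b].families()
        explained = any(frozenset((fa, fb)) in ddi for fa in fams_a for fb in fams_b)
        if not explained:
            kept.add(e)
    return InteractomeNetwork(proteins=net.proteins, edges=kept, species=net.species)


def _pattern_width(pattern: str) -> int:
    width = 0
    i = 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            i = j + 1
        else:
            i += 1
        width += 1
    return width


def match_outside_domains(
    protein_seq: str,
    domain_spans: Sequence[tuple[int, int]],
    pattern: str,
) -> bool:
    """True iff the pattern matches with every position outside all domains.

    Spans are inclusive 1-based. A match straddling a domain boundary
    counts as inside (strict outside-globular-domains rule). Overlapping
    matches are all considered.
    """
    try:
        rx = re.compile(f"(?=({pattern}))")
    except re.error as exc:
        raise ValueError(f"invalid pattern {pattern!r}: {exc}") from exc
    width = _pattern_width(pattern)
    for m in rx.finditer(protein_seq):
        start = m.start() + 1           # 1-based first matched position
        end = start + width - 1
        inside = any(not (end < s or start > e) for s, e in domain_spans)
        if not inside:
            return True
    return False


def build_contingency(
    net: InteractomeNetwork, family: str, pattern: str
) -> tuple[int, int, int, int]:
    """Counts (i_m, i, m, p) for one family/pattern on a (DDI-filtered) net.

    i: proteins with >= 1 retained neighbor carrying the family; m: all
    proteins with a pattern match outside their own domains; i_m: both;
    p: all proteins.
    """
    carriers = {pid for pid, rec in net.proteins.items() if family in rec.families()}
    if not carriers:
        raise ValueError(f"family {family!r} absent from network")
    neigh = net.neighbor_index()
    i_set = {pid for pid in net.proteins if neigh[pid] & carriers}
    m_set = {
        pid
        for pid, rec in net.proteins.items()
        if match_outside_domains(rec.sequence, [(s, e) for _, s, e in rec.domains], pattern)
    }
    return (len(i_set & m_set), len(i_set), len(m_set), len(net.proteins))


def enrichment_factor(table: tuple[int, int, int, int]) -> float:
    """(i_m/i) / (m/p): how much more often interactors match the pattern."""
    i_m, i, m, p = table
    if i == 0 or m == 0:
        raise ValueError("enrichment undefined for i = 0 or m = 0")
    return (i_m / i) / (m / p)


def fisher_one_sided(table: tuple[int, int, int, int]) -> float:
    """One-sided Fisher exact p-value: hypergeometric P(X >= i_m).

    Margins: population p, m marked proteins, a sample of i interactors.
    Computed from log-factorials (lgamma) with compensated summation.
    """
    i_m, i, m, p = table
    if min(i_m, i, m, p) < 0 or i > p or m > p or i_m > min(i, m) or i_m < max(0, i + m - p):
        raise ValueError(f"inconsistent contingency margins {table}")

    def logc(n: int, k: int) -> float:
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    denom = logc(p, i)
    terms = [
        math.exp(logc(m, k) + logc(p - m, i - k) - denom)
        for k in range(i_m, min(i, m) + 1)
    ]
    return min(1.0, math.fsum(terms))


def test_enrichment(
    net: InteractomeNetwork,
    family: str,
    pattern: str,
    ddi_family_pairs: Iterable[tuple[str, str]] = (),
    p_threshold: float = 0.025,
) -> EnrichmentResult:
    """Full single-pattern cross-validation: DDI filter, contingency,
    enrichment factor and one-sided Fisher test."""
    reduced = filter_ddi_edges(net, ddi_family_pairs)
    table = build_contingency(reduced, family, pattern)
    i_m, i, m, p = table
    enr = enrichment_factor(table) if (i and m) else float("nan")
    return EnrichmentResult(
        pattern=pattern,
        family=family,
        i_m=i_m,
        i=i,
        m=m,
        p=p,
        enrichment=enr,
        p_value=fisher_one_sided(table),
    )
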