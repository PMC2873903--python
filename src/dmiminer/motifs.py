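"""Consensus-motif derivation per interaction type.

For each eligible topological cluster (>= 3 UPCs, at least one interchain
member, at least one member whose protein pair has no known domain-domain
interaction) an internal enumerator searches the non-redundant peptide
region sequences for over-represented patterns: 2-5 fixed positions over a
span of at most 8 residues, fixed-width wildcards in between, optionally a
single bracketed residue class merged from variants that co-occur across
UPCs. No terminal anchoring is ever inferred — peptides cut out of 3D
structures are often truncated, so an apparent terminus need not be one.

Significance is a binomial stand-in for a dedicated motif-discovery tool's
model: the probability that at least `support` of the n UPCs contain a
match by chance under background residue frequencies, Bonferroni-adjusted
by the theoretical size of the pattern's complexity class (the number of
patterns with the same count of defined positions and the same bracket
size the enumeration could produce). Ranking uses the adjusted value. An export adapter writes the sequences and UPC grouping in
a form consumable by external motif-discovery tools (e.g. SLiMFinder).
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from scipy.stats import binom

from .clustering import TopologyCluster

__all__ = [
    "MotifPattern",
    "MotifResult",
    "MemberInfo",
    "select_eligible_clusters",
    "required_modifications",
    "helical_mode",
    "find_motifs",
    "motif_pvalue",
    "pattern_to_regex",
    "export_motif_inputs",
]

HELIX_CLASSES = {"H", "G", "I"}
HELIX_FACE_OFFSETS = (0, 3, 4, 7)  # residues on one face of an alpha helix

_TOKEN_RE = re.compile(r"\[([A-Z]+)\]|([A-Z])|(\.)")


@dataclass(frozen=True)
class MotifPattern:
    """A consensus pattern over fixed residues, bracketed residue classes
    and fixed-length wildcards '.'."""

    pattern: str
    required_modifications: tuple[tuple[int, str], ...] = ()
    helical_mode: bool = False

    def tokens(self) -> list[str]:
        toks = []
        pos = 0
        for m in _TOKEN_RE.finditer(self.pattern):
            if m.start() != pos:
                raise ValueError(f"invalid pattern {self.pattern!r}")
            toks.append(m.group(0))
            pos = m.end()
        if pos != len(self.pattern) or not toks:
            raise ValueError(f"invalid pattern {self.pattern!r}")
        return toks

    @property
    def width(self) -> int:
        return len(self.tokens())

    @property
    def n_defined(self) -> int:
        return sum(1 for t in self.tokens() if t != ".")


@dataclass
class MotifResult:
    pattern: MotifPattern
    support: int        # UPCs matched (each counted at most once)
    p_value: float      # adjusted significance, in (0, 1]
    p_raw: float        # unadjusted binomial tail
    rank: int = 0


@dataclass(frozen=True)
class MemberInfo:
    member_id: str
    upc_id: int
    interchain: bool
    ddi_free: bool      # protein pair has no known domain-domain interaction


def pattern_to_regex(pattern: str) -> re.Pattern:
    return re.compile(pattern)


def select_eligible_clusters(
    topo_clusters: Sequence[TopologyCluster],
    member_info: Mapping[str, MemberInfo],
    min_upcs: int = 3,
) -> list[TopologyCluster]:
    """Clusters worth searching: >= min_upcs UPCs, >= 1 interchain member,
    and >= 1 member whose protein pair lacks a known DDI."""
    eligible = []
    for tc in topo_clusters:
        infos = [member_info[m] for m in tc.member_ids]
        n_upcs = len({i.upc_id for i in infos})
        if n_upcs < min_upcs:
            continue
        if not any(i.interchain for i in infos):
            continue
        if not any(i.ddi_free for i in infos):
            continue
        eligible.append(tc)
    return eligible


def required_modifications(
    mods_per_peptide: Sequence[Mapping[int, str]],
) -> dict[int, str]:
    """Aligned positions modified in strictly more than half of the peptides.

    Each element maps aligned position -> modification label for one
    peptide; a position/label pair modified in > 50% of peptides is
    required for the motif.
    """
    if not mods_per_peptide:
        return {}
    counts: dict[tuple[int, str], int] = {}
    for mods in mods_per_peptide:
        for pos, label in mods.items():
            counts[(pos, label)] = counts.get((pos, label), 0) + 1
    half = len(mods_per_peptide) / 2.0
    return {pos: label for (pos, label), n in counts.items() if n > half}


def helical_mode(ss_classes: Sequence[str]) -> bool:
    """True iff strictly more than half the peptides are helical (H/G/I)."""
    if not ss_classes:
        return False
    helical = sum(1 for c in ss_classes if c in HELIX_CLASSES)
    return helical > len(ss_classes) / 2.0


# ---------------------------------------------------------------------------
# pattern enumeration


def _templates(max_defined: int, max_span: int, helical: bool) -> list[tuple[int, ...]]:
    """Offset templates: first offset 0, strictly increasing, span <= max_span.

    In helical mode, defined positions are restricted to one helix face
    (offsets 0, 3, 4, 7 from the anchor)."""
    out: list[tuple[int, ...]] = []
    if helical:
        pool = [o for o in HELIX_FACE_OFFSETS if o < max_span]
        for k in range(2, min(max_defined, len(pool)) + 1):
            for combo in itertools.combinations(pool[1:], k - 1):
                out.append((0,) + combo)
        return out
    for span in range(2, max_span + 1):
        last = span - 1
        interior = list(range(1, last))
        for k in range(2, max_defined + 1):
            if k - 2 > len(interior):
                continue
            for combo in itertools.combinations(interior, k - 2):
                out.append((0,) + combo + (last,))
    return out


def _motif_space(templates: Sequence[tuple[int, ...]]) -> dict[tuple[int, int], float]:
    """Theoretical number of patterns per complexity class.

    The class of a pattern is (number of defined positions k, bracket
    size b) with b = 0 for exact patterns. An exact class holds
    T_k * 20^k patterns (T_k templates with k defined positions); a
    single-bracket class of size b holds T_k * k * C(20, b) * 20^(k-1).
    These counts are the multiple-testing universe actually searched, so
    the family-wise Bonferroni adjustment is data-independent.
    """
    t_k: dict[int, int] = {}
    for tmpl in templates:
        t_k[len(tmpl)] = t_k.get(len(tmpl), 0) + 1
    space: dict[tuple[int, int], float] = {}
    for k, count in t_k.items():
        space[(k, 0)] = count * 20.0**k
        for b in (2, 3):
            space[(k, b)] = count * k * math.comb(20, b) * 20.0 ** (k - 1)
    return space


def _pattern_class(pattern: str) -> tuple[int, int]:
    """(defined positions, bracket size or 0) of a pattern string."""
    mp = MotifPattern(pattern)
    b = 0
    for t in mp.tokens():
        if t.startswith("["):
            b = len(t) - 2
    return mp.n_defined, b


def _pattern_string(template: tuple[int, ...], residues: tuple[str, ...]) -> str:
    span = template[-1] + 1
    cells = ["."] * span
    for off, res in zip(template, residues):
        cells[off] = res if len(res) == 1 else f"[{res}]"
    return "".join(cells)


def _position_prob(token: str, background: Mapping[str, float]) -> float:
    if token == ".":
        return 1.0
    if token.startswith("["):
        return sum(background.get(a, 0.0) for a in token[1:-1])
    return background.get(token, 0.0)


def motif_pvalue(
    pattern: str,
    support: int,
    n_upcs: int,
    background: Mapping[str, float],
    lengths: Sequence[int],
) -> float:
    """Binomial tail probability of >= support UPC matches by chance.

    The per-UPC match probability q is the chance that a background
    sequence of the given length contains at least one match of the
    pattern (independent-positions approximation); the per-UPC lengths are
    averaged into a single q and the tail P(X >= support | n_upcs, q) is
    returned, floored at 1e-300 so it stays in (0, 1].
    """
    if support > n_upcs:
        raise ValueError("support cannot exceed the number of UPCs")
    if support <= 0:
        return 1.0
    mp = MotifPattern(pattern)
    toks = mp.tokens()
    m = 1.0
    for t in toks:
        m *= _position_prob(t, background)
    span = len(toks)
    qs = []
    for L in lengths:
        n_sites = max(0, L - span + 1)
        qs.append(1.0 - (1.0 - m) ** n_sites)
    q = sum(qs) / len(qs) if qs else 0.0
    p = float(binom.sf(support - 1, n_upcs, q))
    return max(p, 1e-300)


def find_motifs(
    sequences: Sequence[str],
    upc_ids: Sequence[int],
    background: Mapping[str, float],
    required_mods: Optional[Mapping[int, str]] = None,
    helical: bool = False,
    max_defined: int = 5,
    max_span: int = 8,
    p_threshold: float = 0.05,
) -> list[MotifResult]:
    """Enumerate and rank over-represented patterns in the region sequences.

    Support is counted at most once per UPC. Each pattern's raw binomial
    tail is Bonferroni-adjusted by the theoretical size of its complexity
    class (all patterns with the same number of defined positions and the
    same bracket size that the enumeration could have produced), so the
    adjustment does not depend on which patterns the data happened to
    instantiate. Patterns whose adjusted significance is at or below the
    threshold are returned, ranked ascending by adjusted then raw
    probability with the pattern string as tie-break.
    """
    if len(sequences) != len(upc_ids):
        raise ValueError("sequences and upc_ids must align")
    n_upcs = len(set(upc_ids))
    if n_upcs < 3:
        raise ValueError("motif derivation requires at least 3 UPCs")
    templates = _templates(max_defined, max_span, helical)

    exact: dict[tuple[tuple[int, ...], tuple[str, ...]], set[int]] = {}
    for seq, upc in zip(sequences, upc_ids):
        L = len(seq)
        for start in range(L):
            for tmpl in templates:
                if start + tmpl[-1] >= L:
                    continue
                residues = tuple(seq[start + o] for o in tmpl)
                if any(not r.isalpha() for r in residues):
                    continue
                exact.setdefault((tmpl, residues), set()).add(upc)

    candidates: dict[str, set[int]] = {}
    for (tmpl, residues), upcs in exact.items():
        candidates.setdefault(_pattern_string(tmpl, residues), set()).update(upcs)

    # single-position ambiguity classes: merge variants at one defined
    # position when each variant is itself supported by >= 2 UPCs and the
    # merge strictly broadens UPC support
    groups: dict[tuple, list[tuple[str, set[int]]]] = {}
    for (tmpl, residues), upcs in exact.items():
        for i in range(len(tmpl)):
            masked = residues[:i] + ("*",) + residues[i + 1 :]
            groups.setdefault((tmpl, i, masked), []).append((residues[i], upcs))
    for (tmpl, i, masked), variants in groups.items():
        variants = [v for v in variants if len(v[1]) >= 2]
        if len(variants) < 2:
            continue
        variants = sorted(variants, key=lambda v: (-len(v[1]), v[0]))[:6]
        for size in (2, 3):
            for combo in itertools.combinations(variants, size):
                union: set[int] = set()
                for _, u in combo:
                    union |= u
                if len(union) <= max(len(u) for _, u in combo):
                    continue
                cls = "".join(sorted(r for r, _ in combo))
                residues = masked[:i] + (cls,) + masked[i + 1 :]
                candidates.setdefault(_pattern_string(tmpl, residues), set()).update(union)

    if not candidates:
        return []
    space = _motif_space(templates)
    # one representative length per UPC (the longest region in it)
    upc_len: dict[int, int] = {}
    for seq, upc in zip(sequences, upc_ids):
        upc_len[upc] = max(upc_len.get(upc, 0), len(seq))
    lengths = sorted(upc_len.values())

    mods = tuple(sorted((required_mods or {}).items()))
    results: list[MotifResult] = []
    for pattern, upcs in candidates.items():
        support = len(upcs)
        p_raw = motif_pvalue(pattern, support, n_upcs, background, lengths)
        p_adj = min(1.0, p_raw * space[_pattern_class(pattern)])
        if p_adj <= p_threshold:
            results.append(
                MotifResult(
                    pattern=MotifPattern(pattern, required_modifications=mods, helical_mode=helical),
                    support=support,
                    p_value=p_adj,
                    p_raw=p_raw,
                )
            )
    results.sort(key=lambda r: (r.p_value, r.p_raw, r.pattern.pattern))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


def background_frequencies(sequences: Sequence[str]) -> dict[str, float]:
    """Amino-acid frequencies over the given sequence set."""
    counts: dict[str, int] = {}
    total = 0
    for seq in sequences:
        for aa in seq:
            if aa.isalpha():
                counts[aa] = counts.get(aa, 0) + 1
                total += 1
    if total == 0:
        raise ValueError("no residues to compute background frequencies from")
    return {aa: n / total for aa, n in counts.items()}


def export_motif_inputs(
    sequences: Sequence[str],
    upc_ids: Sequence[int],
    out_prefix: str | Path,
    ids: Optional[Sequence[str]] = None,
) -> tuple[Path, Path]:
    """Write FASTA + UPC-grouping TSV for external motif-discovery tools."""
    out_prefix = Path(out_prefix)
    fasta = out_prefix.with_suffix(".fasta")
    upc_tsv = out_prefix.with_suffix(".upc.tsv")
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(len(sequences))]
    with fasta.open("w") as fh:
        for sid, seq in zip(ids, sequences):
            fh.write(f">{sid}\n{seq}\n")
    with upc_tsv.open("w") as fh:
        fh.write("sequence\tupc\n")
        for sid, upc in zip(ids, upc_ids):
            fh.write(f"{sid}\t{upc}\n")
    return fasta, upc_tsv
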