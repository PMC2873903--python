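"""Peptide enumeration, SVM classification, and overlap reduction.

All contiguous 4–20-residue windows outside sequence-defined (Pfam-like)
domain masks are candidate peptides. A linear SVM trained on the
structural descriptors (with a 10x penalty on misclassified positives,
mirroring SVM-light's cost-factor) accepts the motif-like ones; accepted
peptides completely covered by longer accepted peptides are dropped, and
the survivors are merged into disjoint peptide-containing regions so each
pattern match counts only once for motif support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from .geometry import FeatureScaler, PeptideFeatures, encode_features, features_from_residues
from .structio import Chain

__all__ = [
    "Peptide",
    "PeptideRegion",
    "SvmModel",
    "enumerate_peptides",
    "train_svm",
    "classify_peptides",
    "remove_covered_peptides",
    "build_peptide_regions",
]


@dataclass
class Peptide:
    structure: str
    chain: str
    start: int                     # 1-based seq_index, inclusive
    end: int
    sequence: str
    features: Optional[PeptideFeatures] = None
    accepted: bool = False

    def __post_init__(self) -> None:
        if not 4 <= len(self) <= 20:
            raise ValueError(f"peptide length {len(self)} outside 4–20")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def id(self) -> str:
        return f"{self.structure}/{self.chain}:{self.start}-{self.end}"


@dataclass
class PeptideRegion:
    structure: str
    chain: str
    start: int
    end: int
    sequence: str
    member_ids: list[str] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def id(self) -> str:
        return f"{self.structure}/{self.chain}:{self.start}-{self.end}"


def enumerate_peptides(
    chain: Chain,
    masks: Sequence[tuple[int, int]],
    structure_id: str = "",
    lmin: int = 4,
    lmax: int = 20,
    compute_features: bool = True,
) -> list[Peptide]:
    """All windows of length lmin..lmax lying wholly outside every mask.

    Masks are inclusive (start, end) spans of sequence-defined domains.
    Windows containing residues without Cα are skipped when features are
    requested (they cannot be scored).
    """
    n = len(chain.residues)
    masked = np.zeros(n + 1, dtype=bool)  # 1-based
    for s, e in masks:
        masked[max(1, s) : min(n, e) + 1] = True
    out: list[Peptide] = []
    for length in range(lmin, lmax + 1):
        for start in range(1, n - length + 2):
            end = start + length - 1
            if masked[start : end + 1].any():
                continue
            residues = chain.residues[start - 1 : end]
            feats = None
            if compute_features:
                try:
                    feats = features_from_residues(residues)
                except ValueError:
                    continue
            out.append(
                Peptide(
                    structure=structure_id,
                    chain=chain.id,
                    start=start,
                    end=end,
                    sequence="".join(r.aa for r in residues),
                    features=feats,
                )
            )
    return out


@dataclass
class SvmModel:
    """Linear decision function over standardized descriptor vectors."""

    weights: np.ndarray
    bias: float
    scaler: FeatureScaler
    cost_factor: float = 10.0
    tradeoff: float = 0.1
    metadata: dict = field(default_factory=dict)

    def decision_value(self, features: PeptideFeatures) -> float:
        x = self.scaler.transform(encode_features(features))
        return float(x @ self.weights + self.bias)

    def save(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "scaler_mean": self.scaler.mean.tolist(),
            "scaler_sd": self.scaler.sd.tolist(),
            "cost_factor": self.cost_factor,
            "tradeoff": self.tradeoff,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SvmModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(d["weights"]),
            bias=float(d["bias"]),
            scaler=FeatureScaler(np.asarray(d["scaler_mean"]), np.asarray(d["scaler_sd"])),
            cost_factor=d.get("cost_factor", 10.0),
            tradeoff=d.get("tradeoff", 0.1),
            metadata=d.get("metadata", {}),
        )


def train_svm(
    positives: Iterable[PeptideFeatures],
    negatives: Iterable[PeptideFeatures],
    cost_factor: float = 10.0,
    tradeoff: float = 0.1,
) -> SvmModel:
    """Train the linear motif-likeness classifier.

    `tradeoff` is the margin/error trade-off C; `cost_factor` multiplies the
    error penalty of positive examples (SVM-light cost-factor semantics:
    C+ = cost_factor * C, C- = C). Deterministic for fixed inputs: the dual
    optimizer's solution is unique for a linear kernel with distinct points,
    and row order does not affect it.
    """
    pos = [encode_features(f) for f in positives]
    neg = [encode_features(f) for f in negatives]
    if not pos or not neg:
        raise ValueError("need at least one example per class")
    X = np.vstack(pos + neg)
    y = np.array([1] * len(pos) + [0] * len(neg))
    scaler = FeatureScaler.fit(X)
    Xs = scaler.transform(X)
    clf = SVC(kernel="linear", C=tradeoff, class_weight={1: cost_factor, 0: 1.0}, tol=1e-8)
    clf.fit(Xs, y)
    train_acc = float((clf.predict(Xs) == y).mean())
    return SvmModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        scaler=scaler,
        cost_factor=cost_factor,
        tradeoff=tradeoff,
        metadata={
            "n_positive": len(pos),
            "n_negative": len(neg),
            "training_accuracy": train_acc,
        },
    )


def classify_peptides(model: SvmModel, peptides: Iterable[Peptide]) -> list[Peptide]:
    """Set the accepted flag: accepted iff decision value strictly > 0."""
    out = []
    for pep in peptides:
        if pep.features is None:
            raise ValueError(f"peptide {pep.id} has no features")
        pep.accepted = model.decision_value(pep.features) > 0.0
        out.append(pep)
    return out


def remove_covered_peptides(accepted: Sequence[Peptide]) -> list[Peptide]:
    """Drop peptides whose span is contained in another accepted peptide's.

    Partial overlaps are retained; duplicates collapse to one. Idempotent
    and independent of input order.
    """
    seen: dict[tuple[str, str, int, int], Peptide] = {}
    for pep in accepted:
        seen.setdefault((pep.structure, pep.chain, pep.start, pep.end), pep)
    peps = sorted(seen.values(), key=lambda p: (p.structure, p.chain, -len(p), p.start))
    kept: list[Peptide] = []
    for pep in peps:
        covered = any(
            k.structure == pep.structure
            and k.chain == pep.chain
            and k.start <= pep.start
            and pep.end <= k.end
            for k in kept
        )
        if not covered:
            kept.append(pep)
    kept.sort(key=lambda p: (p.structure, p.chain, p.start, p.end))
    return kept


def build_peptide_regions(accepted: Sequence[Peptide]) -> list[PeptideRegion]:
    """Connected components of the accepted-peptide span union, per chain.

    Two spans join only when they share at least one residue; mere
    adjacency does not merge. Regions on a chain are pairwise disjoint and
    cover exactly the residues covered by at least one accepted peptide.
    """
    by_chain: dict[tuple[str, str], list[Peptide]] = {}
    for pep in accepted:
        by_chain.setdefault((pep.structure, pep.chain), []).append(pep)
    regions: list[PeptideRegion] = []
    for (struct, chain_id), peps in sorted(by_chain.items()):
        peps = sorted(peps, key=lambda p: (p.start, p.end))
        cur_start, cur_end, members = None, None, []
        seqs: dict[int, str] = {}
        for pep in peps:
            for off, aa in enumerate(pep.sequence):
                seqs[pep.start + off] = aa
            if cur_start is None:
                cur_start, cur_end, members = pep.start, pep.end, [pep.id]
            elif pep.start <= cur_end:  # shared residue -> same region
                cur_end = max(cur_end, pep.end)
                members.append(pep.id)
            else:
                regions.append(_make_region(struct, chain_id, cur_start, cur_end, members, seqs))
                cur_start, cur_end, members = pep.start, pep.end, [pep.id]
        if cur_start is not None:
            regions.append(_make_region(struct, chain_id, cur_start, cur_end, members, seqs))
    return regions


def _make_region(struct, chain_id, start, end, members, seqs) -> PeptideRegion:
    return PeptideRegion(
        structure=struct,
        chain=chain_id,
        start=start,
        end=end,
        sequence="".join(seqs[i] for i in range(start, end + 1)),
        member_ids=list(members),
    )
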