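"""Structure and annotation input/output.

Parses PDB/mmCIF models into light per-residue containers, fills
secondary-structure classes (from a DSSP output file or an internal
Cα-trace assigner) and solvent accessibility (Shrake–Rupley), and loads
the tab-separated annotation tables the pipeline consumes: domain spans,
modified residues and per-family profile maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Residue",
    "Chain",
    "Structure",
    "DomainAnnotation",
    "read_structure",
    "write_structure",
    "parse_dssp",
    "assign_secondary_structure",
    "compute_accessibility",
    "shrake_rupley_sasa",
    "load_annotations",
    "load_modified_residues",
    "load_profile_maps",
]

DSSP_CLASSES = "HGIEBTS-"

# van der Waals radii (Å) for the elements that occur in protein heavy atoms
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
DEFAULT_VDW = 1.70


@dataclass
class Residue:
    chain: str
    seq_index: int               # 1-based, contiguous within the chain
    aa: str                      # one-letter code, 'X' if unknown
    ca: Optional[np.ndarray]     # (3,) or None when missing
    heavy_atoms: np.ndarray      # (n, 3) heavy-atom coordinates
    elements: list[str] = field(default_factory=list)
    atom_names: list[str] = field(default_factory=list)
    ss_class: str = "-"
    ss_assigned: bool = False
    accessibility: Optional[float] = None
    modified: Optional[str] = None
    author_seq_id: Optional[int] = None
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.ca is not None:
            self.ca = np.asarray(self.ca, dtype=float)
        self.heavy_atoms = np.asarray(self.heavy_atoms, dtype=float).reshape(-1, 3)
        if self.ca is None:
            self.incomplete = True


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, seq_index: int) -> Residue:
        r = self.residues[seq_index - 1]
        if r.seq_index != seq_index:  # contiguity is an invariant
            raise IndexError(f"seq_index {seq_index} not contiguous in chain {self.id}")
        return r


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    is_biological_unit: bool = True

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain identifiers in structure {self.id}")

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    def __iter__(self):
        return iter(self.chains)


@dataclass(frozen=True)
class DomainAnnotation:
    """A domain span on one chain.

    kind is 'sequence' for sequence-defined (Pfam-like) assignments — these
    form the peptide-exclusion mask — or 'structure' for structure-defined
    (CATH-like) assignments used by the intrachain filters.
    """

    structure: str
    chain: str
    family: str
    start: int
    end: int
    kind: str  # 'sequence' | 'structure'

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"annotation start {self.start} > end {self.end}")
        if self.kind not in ("sequence", "structure"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# structure reading / writing


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code.isalpha() else "X"
    return "X"


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a Structure.

    The first model is used; alternate conformations are reduced to the
    highest-occupancy one; waters and non-amino-acid hetero groups are
    dropped; insertion codes are collapsed into a contiguous 1-based
    seq_index per chain (author numbering is kept as metadata).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {format}: {exc}") from exc
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_waters()
    if len(st) == 0:
        raise ValueError(f"{path}: empty model (no ATOM records)")
    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        idx = 0
        for gres in gchain:
            aa = _one_letter(gres.name)
            info = gemmi.find_tabulated_residue(gres.name)
            if info is None or not info.is_amino_acid():
                continue  # ligands excluded from peptide enumeration
            coords, elements, names = [], [], []
            ca = None
            for atom in gres:
                if atom.element.is_hydrogen:
                    continue
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                coords.append(pos)
                elements.append(atom.element.name.upper())
                names.append(atom.name)
                if atom.name == "CA":
                    ca = pos
            if not coords:
                continue
            idx += 1
            residues.append(
                Residue(
                    chain=gchain.name,
                    seq_index=idx,
                    aa=aa,
                    ca=ca,
                    heavy_atoms=np.array(coords),
                    elements=elements,
                    atom_names=names,
                    author_seq_id=gres.seqid.num,
                )
            )
        if residues:
            chains.append(Chain(id=gchain.name, residues=residues))
    if not chains:
        raise ValueError(f"{path}: no amino-acid residues found")
    return Structure(id=path.stem, chains=chains)


def to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = _three_letter(res.aa)
            gres.seqid = gemmi.SeqId(
                res.author_seq_id if res.author_seq_id is not None else res.seq_index, " "
            )
            for xyz, el, name in zip(res.heavy_atoms, res.elements, res.atom_names):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(el)
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def _three_letter(aa: str) -> str:
    return _AA3.get(aa.upper(), "UNK")


def write_structure(structure: Structure, path: str | Path, format: str | None = None) -> None:
    """Write a Structure as PDB or mmCIF (fixture dialect: heavy atoms only)."""
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = to_gemmi(structure)
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# secondary structure


def parse_dssp(path: str | Path) -> dict[tuple[str, int], tuple[str, float]]:
    """Parse a classic DSSP output file.

    Returns {(chain_id, author_residue_number): (ss_class, accessibility)}.
    Blank structure codes are mapped to '-'.
    """
    out: dict[tuple[str, int], tuple[str, float]] = {}
    in_body = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("  #  RESIDUE"):
            in_body = True
            continue
        if not in_body or len(line) < 38:
            continue
        if line[13] == "!":  # chain break record
            continue
        try:
            resnum = int(line[5:10])
        except ValueError:
            continue
        chain = line[11].strip() or " "
        ss = line[16]
        if ss not in DSSP_CLASSES:
            ss = "-"
        try:
            acc = float(line[34:38])
        except ValueError:
            acc = 0.0
        out[(chain, resnum)] = (ss, acc)
    if not out:
        raise ValueError(f"{path}: no residue records found in DSSP file")
    return out


def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees for four points."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _assign_ss_chain(chain: Chain) -> None:
    """Cα-trace secondary-structure assigner.

    A window of four consecutive Cα is helical when the virtual torsion is
    in the right-handed helix range (~+50 deg) and Cα(i)–Cα(i+3) is a
    helix-like ~5 Å contact; it is strand-like when the trace is extended
    (Cα(i)–Cα(i+3) >= 9.5 Å — the torsion of a near-collinear trace is
    numerically unstable, so extension alone decides). All four residues of
    a qualifying window are marked, so ideal fixtures are labelled end to
    end. Everything else is '-'.
    """
    n = len(chain.residues)
    cas = [r.ca for r in chain.residues]
    labels = ["-"] * n
    for i in range(n - 3):
        window = cas[i : i + 4]
        if any(c is None for c in window):
            continue
        theta = _dihedral(*window)
        d13 = float(np.linalg.norm(window[3] - window[0]))
        if 25.0 <= theta <= 85.0 and 4.2 <= d13 <= 6.2:
            for j in range(i, i + 4):
                if labels[j] != "H":
                    labels[j] = "H"
        elif d13 >= 9.5:
            for j in range(i, i + 4):
                if labels[j] == "-":
                    labels[j] = "E"
    for r, lab in zip(chain.residues, labels):
        r.ss_class = lab
        r.ss_assigned = True


def assign_secondary_structure(
    structure: Structure, dssp_path: str | Path | None = None
) -> Structure:
    """Fill ss_class for every residue (idempotent; mutates and returns).

    When a DSSP file is given, its classes (and accessibilities) are mapped
    by chain id + author residue number and must cover every residue of the
    chains it names. Otherwise the internal Cα-trace assigner is used,
    chain by chain — each chain is treated with all other chains removed.
    """
    if dssp_path is not None:
        table = parse_dssp(dssp_path)
        chains_in_file = {c for c, _ in table}
        unmatched = []
        for chain in structure.chains:
            if chain.id not in chains_in_file:
                _assign_ss_chain(chain)
                continue
            for res in chain.residues:
                key = (chain.id, res.author_seq_id if res.author_seq_id is not None else res.seq_index)
                if key not in table:
                    unmatched.append(key)
                    continue
                ss, acc = table[key]
                res.ss_class = ss
                res.ss_assigned = True
                if res.accessibility is None:
                    res.accessibility = acc
        if unmatched:
            raise ValueError(f"DSSP file does not cover residues: {unmatched[:10]}")
        return structure
    for chain in structure.chains:
        _assign_ss_chain(chain)
    return structure


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake–Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Express coordinates in a rigid-motion-independent frame.

    Centers on the centroid and rotates onto the principal axes, with each
    axis sign fixed by the third moment (falling back to +) and handedness
    fixed by a cross product, so that a rotated/translated copy of the
    structure yields identical local coordinates and hence identical SASA.
    """
    centred = coords - coords.mean(axis=0)
    if len(centred) < 2:
        return centred
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1].T  # rows: axes by decreasing variance
    local = centred @ axes.T
    for k in range(2):
        skew = (local[:, k] ** 3).sum()
        if skew < 0:
            axes[k] = -axes[k]
            local[:, k] = -local[:, k]
    axes[2] = np.cross(axes[0], axes[1])  # right-handed frame
    return centred @ axes.T


def shrake_rupley_sasa(
    coords: np.ndarray,
    elements: Iterable[str],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley.

    Deterministic for a fixed sphere-point count (golden-spiral points) and
    invariant under rigid motion of the input (coordinates are expressed in
    a canonical principal-axes frame before sampling).
    """
    coords = _canonical_frame(np.asarray(coords, dtype=float))
    radii = np.array([VDW_RADII.get(e.upper(), DEFAULT_VDW) for e in elements]) + probe_radius
    n_atoms = len(coords)
    if n_atoms == 0:
        return np.zeros(0)
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        if neigh:
            nb = np.asarray(neigh)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * radii[i] ** 2
    return areas


def compute_accessibility(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    per_chain: bool = True,
) -> Structure:
    """Fill per-residue accessibility (mutates and returns the structure).

    By default each chain is treated in isolation (other chains removed),
    matching the convention for peptide-accessibility features; set
    per_chain=False to compute on the whole assembly.
    """
    groups: list[list[Residue]]
    if per_chain:
        groups = [list(c.residues) for c in structure.chains]
    else:
        groups = [[r for c in structure.chains for r in c.residues]]
    for residues in groups:
        coords, elements, owner = [], [], []
        for ri, res in enumerate(residues):
            if len(res.heavy_atoms) == 0:
                res.accessibility = None
                res.incomplete = True
                continue
            coords.append(res.heavy_atoms)
            elements.extend(res.elements or ["C"] * len(res.heavy_atoms))
            owner.extend([ri] * len(res.heavy_atoms))
        if not coords:
            continue
        areas = shrake_rupley_sasa(
            np.vstack(coords), elements, probe_radius=probe_radius, n_points=n_points
        )
        owner_arr = np.asarray(owner)
        for ri, res in enumerate(residues):
            mask = owner_arr == ri
            if mask.any():
                res.accessibility = float(areas[mask].sum())
    return structure


# ---------------------------------------------------------------------------
# annotation tables


def load_annotations(path: str | Path) -> list[DomainAnnotation]:
    """Load a domain-annotation TSV (structure, chain, family, start, end, kind)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"structure", "chain", "family", "start", "end", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                DomainAnnotation(
                    structure=row.structure,
                    chain=row.chain,
                    family=row.family,
                    start=int(row.start),
                    end=int(row.end),
                    kind=row.kind,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {rownum}: {exc}") from exc
    return out


def load_modified_residues(path: str | Path) -> dict[tuple[str, str, int], str]:
    """Load modified-residue TSV (structure, chain, seq_index, modification)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"structure", "chain", "seq_index", "modification"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {
        (row.structure, row.chain, int(row.seq_index)): row.modification
        for row in df.itertuples(index=False)
    }


def load_profile_maps(path: str | Path) -> dict[tuple[str, str, str], dict[int, int]]:
    """Load profile-map TSV (family, structure, chain, seq_index, column).

    Returns {(family, structure, chain): {seq_index: profile column}}; each
    mapping must be injective where defined.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family", "structure", "chain", "seq_index", "column"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    maps: dict[tuple[str, str, str], dict[int, int]] = {}
    for row in df.itertuples(index=False):
        key = (row.family, row.structure, row.chain)
        maps.setdefault(key, {})[int(row.seq_index)] = int(row.column)
    for key, m in maps.items():
        if len(set(m.values())) != len(m):
            raise ValueError(f"profile map for {key} is not injective")
    return maps


def apply_modifications(
    structure: Structure, table: Mapping[tuple[str, str, int], str]
) -> Structure:
    """Attach modification labels from a modified-residue table."""
    for chain in structure.chains:
        for res in chain.residues:
            label = table.get((structure.id, chain.id, res.seq_index))
            if label is not None:
                res.modified = label
    return structure
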