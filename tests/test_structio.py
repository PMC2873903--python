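"""structio: structure I/O, secondary structure, accessibility, tables."""

import math

import numpy as np
import pytest

from dmiminer.structio import (
    Chain,
    DomainAnnotation,
    Residue,
    Structure,
    assign_secondary_structure,
    compute_accessibility,
    load_annotations,
    load_profile_maps,
    parse_dssp,
    read_structure,
    shrake_rupley_sasa,
    write_structure,
)
from dmiminer.synthfix import peptide_chain, toy_complex

from conftest import make_residue, rigid_motion


# --- read/write round trips ------------------------------------------------

def test_round_trip_pdb_and_mmcif(tmp_path):
    toy = toy_complex(peptide_len=8, seed=3)
    pdb = tmp_path / "toy.pdb"
    cif = tmp_path / "toy.cif"
    write_structure(toy.structure, pdb)
    write_structure(toy.structure, cif)
    s_pdb = read_structure(pdb)
    s_cif = read_structure(cif)
    assert [c.id for c in s_pdb.chains] == [c.id for c in s_cif.chains] == ["A", "B"]
    for orig, got in ((toy.structure, s_pdb), (toy.structure, s_cif)):
        for co, cg in zip(orig.chains, got.chains):
            assert len(co) == len(cg)
            assert co.sequence == cg.sequence
            for ro, rg in zip(co.residues, cg.residues):
                np.testing.assert_allclose(ro.ca, rg.ca, atol=1e-2)


def test_read_structure_pdb_equals_mmcif_contents(tmp_path):
    toy = toy_complex(peptide_len=6, seed=11)
    write_structure(toy.structure, tmp_path / "a.pdb")
    write_structure(toy.structure, tmp_path / "a.cif")
    a = read_structure(tmp_path / "a.pdb")
    b = read_structure(tmp_path / "a.cif")
    for ca, cb in zip(a.chains, cb_list := b.chains):
        assert ca.sequence == cb.sequence
        np.testing.assert_allclose(
            np.vstack([r.heavy_atoms for r in ca.residues]),
            np.vstack([r.heavy_atoms for r in cb.residues]),
            atol=1e-2,
        )


def test_read_structure_no_atoms_errors(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("HEADER    EMPTY\nEND\n")
    with pytest.raises(ValueError):
        read_structure(path)


def test_seq_index_contiguous_and_chain_ids_unique():
    toy = toy_complex(seed=0)
    for chain in toy.structure.chains:
        assert [r.seq_index for r in chain.residues] == list(range(1, len(chain) + 1))
    with pytest.raises(ValueError):
        Structure(id="dup", chains=[Chain(id="A"), Chain(id="A")])


# --- secondary structure ---------------------------------------------------

def test_internal_assigner_ideal_helix_all_h():
    chain = peptide_chain("helix", 7, seed=2)
    st = assign_secondary_structure(Structure(id="h", chains=[chain]))
    assert [r.ss_class for r in st.chains[0].residues] == ["H"] * 7


def test_internal_assigner_ideal_strand_no_helix():
    chain = peptide_chain("strand", 7, seed=2)
    st = assign_secondary_structure(Structure(id="e", chains=[chain]))
    classes = [r.ss_class for r in st.chains[0].residues]
    assert set(classes) <= {"E", "-"}
    assert "E" in classes


def test_assign_secondary_structure_idempotent():
    chain = peptide_chain("helix", 9, seed=5)
    st = Structure(id="h", chains=[chain])
    assign_secondary_structure(st)
    first = [r.ss_class for r in st.chains[0].residues]
    assign_secondary_structure(st)
    assert [r.ss_class for r in st.chains[0].residues] == first


def _dssp_line(serial, resnum, chain, aa, ss, acc):
    line = f"{serial:>5}{resnum:>5} {chain} {aa}  {ss}"
    return line.ljust(34) + f"{acc:>4}"


def test_parse_dssp_and_assignment(tmp_path):
    classes = "HHHTT-EE"
    accs = [10, 20, 30, 40, 50, 60, 70, 80]
    lines = ["  #  RESIDUE AA STRUCTURE ..."]
    for i, (ss, acc) in enumerate(zip(classes, accs), start=1):
        lines.append(_dssp_line(i, i, "B", "A", ss if ss != "-" else " ", acc))
    path = tmp_path / "toy.dssp"
    path.write_text("HEADER\n" + "\n".join(lines) + "\n")

    table = parse_dssp(path)
    assert table[("B", 1)] == ("H", 10.0)
    assert table[("B", 6)] == ("-", 60.0)

    chain = peptide_chain("coil", 8, seed=1)
    st = assign_secondary_structure(Structure(id="x", chains=[chain]), dssp_path=path)
    assert "".join(r.ss_class for r in st.chains[0].residues) == classes


def test_dssp_mismatch_errors(tmp_path):
    lines = ["  #  RESIDUE AA STRUCTURE ...", _dssp_line(1, 1, "B", "A", "H", 10)]
    path = tmp_path / "short.dssp"
    path.write_text("\n".join(lines) + "\n")
    chain = peptide_chain("coil", 5, seed=1)
    with pytest.raises(ValueError, match="does not cover"):
        assign_secondary_structure(Structure(id="x", chains=[chain]), dssp_path=path)


# --- accessibility ---------------------------------------------------------

def _chain_atoms(chain):
    coords = np.vstack([r.heavy_atoms for r in chain.residues])
    elements = [e for r in chain.residues for e in r.elements]
    return coords, elements


def test_isolated_atom_exposed():
    sasa = shrake_rupley_sasa(np.array([[0.0, 0.0, 0.0]]), ["C"])
    # full sphere of radius 1.7 + 1.4 = 3.1 Å -> 4*pi*3.1^2 ~ 120.8 Å²
    assert abs(sasa[0] - 4 * math.pi * 3.1**2) < 1.0


def test_buried_atom_in_cage():
    # surround a central atom with a dense shell of atoms at 3 Å
    golden = math.pi * (3 - math.sqrt(5))
    pts = [(0.0, 0.0, 0.0)]
    for i in range(60):
        z = 1 - 2 * (i + 0.5) / 60
        r = math.sqrt(max(0.0, 1 - z * z))
        th = golden * i
        pts.append((3 * r * math.cos(th), 3 * r * math.sin(th), 3 * z))
    sasa = shrake_rupley_sasa(np.asarray(pts), ["C"] * len(pts))
    assert sasa[0] <= 1.0


@pytest.mark.parametrize("kind", ["coil", "helix", "strand"])
def test_sasa_convergence_with_point_count(kind):
    chain = peptide_chain(kind, 20, seed=3)
    coords, elements = _chain_atoms(chain)
    a = shrake_rupley_sasa(coords, elements, n_points=960)
    b = shrake_rupley_sasa(coords, elements, n_points=1920)
    atoms_per_res = [len(r.heavy_atoms) for r in chain.residues]
    start = 0
    for n in atoms_per_res:
        s960, s1920 = a[start : start + n].sum(), b[start : start + n].sum()
        assert abs(s960 - s1920) / max(s1920, 1.0) < 0.02
        start += n


def test_sasa_rigid_motion_invariant():
    rng = np.random.default_rng(12)
    toy = toy_complex(peptide_len=6, seed=9)
    coords, elements = _chain_atoms(toy.structure.get_chain("B"))
    base = shrake_rupley_sasa(coords, elements)
    q, t = rigid_motion(rng)
    got = shrake_rupley_sasa(coords @ q.T + t, elements)
    np.testing.assert_allclose(got, base, rtol=1e-6)


def test_compute_accessibility_fills_all():
    toy = toy_complex(peptide_len=5, seed=4)
    compute_accessibility(toy.structure)
    for chain in toy.structure.chains:
        for res in chain.residues:
            assert res.accessibility is not None and res.accessibility >= 0


# --- annotation tables -----------------------------------------------------

def test_load_annotations_and_errors(tmp_path):
    good = tmp_path / "ann.tsv"
    good.write_text(
        "structure\tchain\tfamily\tstart\tend\tkind\n"
        "1abc\tA\tPF001\t10\t60\tsequence\n"
        "1abc\tA\tCATH1\t5\t80\tstructure\n"
        "2xyz\tB\tPF002\t1\t30\tsequence\n"
    )
    anns = load_annotations(good)
    assert len(anns) == 3
    assert anns[0].family == "PF001" and anns[0].kind == "sequence"

    bad_span = tmp_path / "bad1.tsv"
    bad_span.write_text(
        "structure\tchain\tfamily\tstart\tend\tkind\n1abc\tA\tPF001\t60\t10\tsequence\n"
    )
    with pytest.raises(ValueError):
        load_annotations(bad_span)

    bad_kind = tmp_path / "bad2.tsv"
    bad_kind.write_text(
        "structure\tchain\tfamily\tstart\tend\tkind\n1abc\tA\tPF001\t1\t9\tweird\n"
    )
    with pytest.raises(ValueError):
        load_annotations(bad_kind)


def test_load_profile_maps_injective(tmp_path):
    rows = ["family\tstructure\tchain\tseq_index\tcolumn"]
    rows += [f"PF001\t1abc\tA\t{i}\t{i - 9}" for i in range(10, 61)]
    path = tmp_path / "pm.tsv"
    path.write_text("\n".join(rows) + "\n")
    maps = load_profile_maps(path)
    m = maps[("PF001", "1abc", "A")]
    assert m[10] == 1 and m[60] == 51 and len(m) == 51

    rows.append("PF001\t1abc\tA\t61\t51")  # duplicate column -> not injective
    path.write_text("\n".join(rows) + "\n")
    with pytest.raises(ValueError):
        load_profile_maps(path)


def test_domain_annotation_validation():
    with pytest.raises(ValueError):
        DomainAnnotation("s", "A", "F", 5, 4, "sequence")
    with pytest.raises(ValueError):
        DomainAnnotation("s", "A", "F", 1, 4, "banana")
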