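"""interfaces: contacts, areas, stoichiometry ratios, context filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmiminer.candidates import Peptide
from dmiminer.geometry import PeptideFeatures
from dmiminer.interfaces import (
    CandidateDMI,
    ContactMap,
    domain_contact_filter,
    domain_id,
    global_identity,
    homomer_filter,
    interface_area,
    interface_ratio_filter,
    intrachain_filters,
    residue_contacts,
)
from dmiminer.structio import DomainAnnotation
from dmiminer.synthfix import toy_complex

from conftest import make_residue


def _res_at(idx, xyz, chain="A"):
    return make_residue(chain, idx, "A", ca=xyz)


# --- residue contacts ---------------------------------------------------------

def test_contact_at_4_9_angstrom():
    cm = residue_contacts([_res_at(1, (0, 0, 0), "B")], [_res_at(1, (4.9, 0, 0))])
    assert cm.peptide_residues == {1} and cm.domain_residues == {1}


def test_no_contact_at_5_1_angstrom():
    cm = residue_contacts([_res_at(1, (0, 0, 0), "B")], [_res_at(1, (5.1, 0, 0))])
    assert cm.peptide_residues == set() and cm.domain_residues == set()


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=40, deadline=None)
def test_contacts_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    pep = [_res_at(i + 1, rng.uniform(0, 15, 3), "B") for i in range(6)]
    dom = [_res_at(i + 1, rng.uniform(0, 15, 3)) for i in range(12)]
    cm = residue_contacts(pep, dom, cutoff=5.0)
    exp_p, exp_d = set(), set()
    for p in pep:
        for d in dom:
            if np.linalg.norm(p.heavy_atoms[0] - d.heavy_atoms[0]) <= 5.0:
                exp_p.add(p.seq_index)
                exp_d.add(d.seq_index)
    assert cm.peptide_residues == exp_p and cm.domain_residues == exp_d


# --- 60% / gap-4 contact rule ---------------------------------------------------

def _cm(contacting, span):
    return ContactMap("p", "d", span, peptide_residues=set(contacting))


def test_contact_rule_pass_60_percent_gap2():
    cm = _cm([1, 2, 3, 6, 7, 8], (1, 10))  # 6/10, max gap 2
    assert domain_contact_filter(cm, 10) is True


def test_contact_rule_fail_below_60_percent():
    cm = _cm([1, 2, 3, 4, 5], (1, 10))  # 5/10
    assert domain_contact_filter(cm, 10) is False


def test_contact_rule_fail_gap_of_5():
    contacting = [i for i in range(1, 21) if i not in (8, 9, 10, 11, 12)]
    cm = _cm(contacting[:14] if len(contacting) > 14 else contacting, (1, 20))
    cm = _cm([1, 2, 3, 4, 5, 6, 7, 13, 14, 15, 16, 17, 18, 19], (1, 20))  # 14/20, gap 5
    assert domain_contact_filter(cm, 20) is False


def test_contact_rule_gap_of_exactly_4_passes():
    cm = _cm([1, 2, 3, 4, 5, 6, 7, 12, 13, 14, 15, 16, 17, 18, 19, 20], (1, 20))
    assert domain_contact_filter(cm, 20) is True


# --- interface area --------------------------------------------------------------

def test_interface_area_distant_groups_zero():
    a = [_res_at(1, (0, 0, 0))]
    b = [_res_at(1, (30, 0, 0), "B")]
    assert interface_area(a, b) == 0.0


def test_interface_area_symmetric():
    toy = toy_complex(peptide_len=5, seed=2)
    dom = toy.structure.get_chain("A").residues[36:]  # top grid layer
    pep = toy.structure.get_chain("B").residues
    assert interface_area(dom, pep) == pytest.approx(interface_area(pep, dom))


def test_interface_area_two_sphere_analytic_cap():
    # two carbon atoms (expanded radius R = 1.7 + 1.4 = 3.1 Å) at distance d:
    # each loses a spherical cap of height h = R - d/2, area 2*pi*R*h;
    # the per-side buried area convention returns exactly 2*pi*R*h
    R = 1.7 + 1.4
    for d in (3.0, 4.0, 5.0):
        a = [_res_at(1, (0, 0, 0))]
        b = [_res_at(1, (d, 0, 0), "B")]
        analytic = 2 * math.pi * R * (R - d / 2)
        got = interface_area(a, b)
        assert abs(got - analytic) / analytic < 0.03


def test_interface_area_empty_group_errors():
    with pytest.raises(ValueError):
        interface_area([], [_res_at(1, (0, 0, 0))])


# --- stoichiometry ratio filter ---------------------------------------------------

def _candidate(areas, full_area, relation="interchain"):
    pep = Peptide("s", "B", 1, 10, "A" * 10,
                  features=PeptideFeatures(10, 20.0, 0.4, "E", 60.0))
    domains, area_map, cms = [], {}, {}
    for i, a in enumerate(areas):
        d = DomainAnnotation("s", "A", f"FAM{i}", 1 + 40 * i, 30 + 40 * i, "sequence")
        domains.append(d)
        area_map[domain_id(d)] = a
        cms[domain_id(d)] = ContactMap(pep.id, domain_id(d), (1, 10))
    return CandidateDMI(peptide=pep, domains=domains, contact_maps=cms,
                        interface_areas=area_map, full_area=full_area,
                        chain_relation=relation)


def test_ratio_single_domain_accept():
    c = _candidate([200.0], full_area=200.0 / 0.6)
    assert interface_ratio_filter(c) is not None


def test_ratio_two_domains_30_30_accept():
    c = _candidate([300.0, 300.0], full_area=1000.0)
    out = interface_ratio_filter(c)
    assert out is not None and len(out.domains) == 2


def test_ratio_drop_then_reject_045_010():
    c = _candidate([450.0, 100.0], full_area=1000.0)
    # 0.10 < 0.5/2 -> drop; then single domain 0.45 < 0.5 -> reject
    assert interface_ratio_filter(c) is None
    assert ("interface_ratio", "fail") in c.provenance


def test_ratio_area_floor_rejects():
    c = _candidate([149.0], full_area=149.0 / 0.9)  # ratio fine, area below floor
    assert interface_ratio_filter(c) is None


def test_ratio_area_floor_boundary_passes():
    c = _candidate([150.0], full_area=150.0 / 0.9)
    assert interface_ratio_filter(c) is not None


def test_ratio_full_area_zero_errors():
    c = _candidate([100.0], full_area=0.0)
    with pytest.raises(ValueError):
        interface_ratio_filter(c)


def test_ratio_three_domains_sum_rule():
    c = _candidate([200.0, 200.0, 200.0], full_area=1000.0)
    out = interface_ratio_filter(c)  # each 0.2 >= 0.5/3, sum 0.6 >= 0.5
    assert out is not None and len(out.domains) == 3


def test_ratio_rejection_from_real_sasa_construction():
    # annotated domain covers only part of the peptide's true interface:
    # A_dp passes the area floor but the ratio falls below 0.5
    toy = toy_complex(peptide_len=10, seed=0, domain_span=(1, 77))
    dom_chain = toy.structure.get_chain("A").residues
    pep_res = toy.structure.get_chain("B").residues
    d = toy.annotations[0]
    a_dp = interface_area(pep_res, dom_chain[d.start - 1 : d.end])
    a_full = interface_area(pep_res, dom_chain)
    assert a_dp >= 150.0 and a_dp / a_full < 0.5  # construction sanity
    pep = Peptide(toy.structure.id, "B", 1, 10, "A" * 10)
    c = CandidateDMI(peptide=pep, domains=[d],
                     contact_maps={domain_id(d): ContactMap(pep.id, domain_id(d), (1, 10))},
                     interface_areas={domain_id(d): a_dp}, full_area=a_full)
    assert interface_ratio_filter(c) is None


# --- intrachain filters --------------------------------------------------------

def _intra_candidate(pep_span, dom_span):
    pep = Peptide("s", "A", pep_span[0], pep_span[1],
                  "A" * (pep_span[1] - pep_span[0] + 1))
    d = DomainAnnotation("s", "A", "FAM", dom_span[0], dom_span[1], "sequence")
    return CandidateDMI(peptide=pep, domains=[d], chain_relation="intrachain")


def test_intrachain_peptide_inside_cath_span_fails():
    c = _intra_candidate((30, 38), (60, 120))
    cath = [DomainAnnotation("s", "A", "CATH1", 20, 50, "structure")]
    assert intrachain_filters(c, cath) is False
    assert ("intrachain_cath", "fail") in c.provenance


def test_intrachain_distance_5_fails():
    c = _intra_candidate((90, 100), (105, 160))
    assert intrachain_filters(c, []) is False


def test_intrachain_distance_exactly_10_passes():
    c = _intra_candidate((90, 100), (110, 160))
    assert intrachain_filters(c, []) is True


def test_intrachain_distance_9_fails():
    c = _intra_candidate((90, 100), (109, 160))
    assert intrachain_filters(c, []) is False


# --- homomer filter -------------------------------------------------------------

def test_homomer_identical_chains_rejected():
    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    assert homomer_filter(seq, seq) is False


def test_homomer_unrelated_chains_pass():
    assert homomer_filter("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
                          "GGSPLLWGHHHAEDTRCCNNNPPPQQ") is True


def test_homomer_point_mutant_rejected():
    a = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE"
    b = a[:50] + "G" + a[51:]  # single substitution, > 99% identity
    mismatches = sum(x != y for x, y in zip(a, b))
    assert mismatches == 1
    assert homomer_filter(a, b) is False


def test_global_identity_values():
    assert global_identity("AAAA", "AAAA") == 1.0
    assert global_identity("AAAA", "AATA") == pytest.approx(0.75)
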