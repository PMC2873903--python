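"""candidates: peptide enumeration, SVM classification, overlap reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmiminer.candidates import (
    Peptide,
    SvmModel,
    build_peptide_regions,
    classify_peptides,
    enumerate_peptides,
    remove_covered_peptides,
    train_svm,
)
from dmiminer.geometry import FeatureScaler, PeptideFeatures
from dmiminer.structio import Chain
from dmiminer.synthfix import peptide_chain, training_features

from conftest import make_residue


def _chain(n, chain_id="A"):
    return Chain(
        id=chain_id,
        residues=[make_residue(chain_id, i + 1, "A", ca=(i * 3.8, 0, 0)) for i in range(n)],
    )


def _window_count_oracle(n, masks, lmin=4, lmax=20):
    free = [True] * (n + 1)
    for s, e in masks:
        for i in range(max(1, s), min(n, e) + 1):
            free[i] = False
    count = 0
    for length in range(lmin, lmax + 1):
        for start in range(1, n - length + 2):
            if all(free[start : start + length]):
                count += 1
    return count


# --- enumeration -------------------------------------------------------------

def test_enumerate_masked_chain():
    peps = enumerate_peptides(_chain(30), [(1, 20)], "s", lmax=10, compute_features=False)
    assert len(peps) == 28  # sum over L=4..10 of (10 - L + 1)
    assert all(p.start >= 21 for p in peps)


def test_enumerate_unmasked_20_residues():
    peps = enumerate_peptides(_chain(20), [], "s", compute_features=False)
    # sum over L=4..20 of (21 - L) = 17 + 16 + ... + 1
    assert len(peps) == sum(21 - L for L in range(4, 21)) == 153


def test_enumerate_free_region_below_lmin():
    peps = enumerate_peptides(_chain(10), [(4, 10)], "s", compute_features=False)
    assert peps == []


@given(
    st.integers(min_value=4, max_value=40),
    st.lists(st.tuples(st.integers(1, 40), st.integers(0, 12)), max_size=3),
)
@settings(max_examples=60, deadline=None)
def test_enumerate_count_matches_oracle(n, raw_masks):
    masks = [(s, min(n, s + w)) for s, w in raw_masks]
    peps = enumerate_peptides(_chain(n), masks, "s", compute_features=False)
    assert len(peps) == _window_count_oracle(n, masks)


# --- SVM ----------------------------------------------------------------------

def test_train_svm_separable_perfect_accuracy():
    # clearly separable clouds: ideal strands vs ideal helices
    rng = np.random.default_rng(3)
    pos = [PeptideFeatures(10, rng.normal(30, 1), rng.normal(0.3, 0.05), "E", 80.0)
           for _ in range(30)]
    neg = [PeptideFeatures(10, rng.normal(14, 1), rng.normal(2.2, 0.1), "H", 80.0)
           for _ in range(30)]
    model = train_svm(pos, neg)
    assert model.metadata["training_accuracy"] == 1.0


def test_study_conditions_model_nearly_separable(svm_model):
    # coil negatives occasionally look strand-like; the asymmetric cost
    # keeps all positives correct
    assert svm_model.metadata["training_accuracy"] >= 0.95


def test_train_svm_single_class_errors():
    pos, _ = training_features(n_per_class=5, seed=0)
    with pytest.raises(ValueError):
        train_svm(pos, [])


def test_cost_factor_raises_positive_recall():
    # overlapping clouds in feature space: encode via PeptideFeatures with
    # jittered elongation/linearity so the classes are not separable
    rng = np.random.default_rng(5)
    def cloud(mu_e, mu_l, n):
        out = []
        for _ in range(n):
            e = max(0.1, rng.normal(mu_e, 4.0))
            l = max(0.0, rng.normal(mu_l, 1.5))
            out.append(PeptideFeatures(10, e, l, "-", 80.0))
        return out
    pos = cloud(20.0, 1.0, 60)
    neg = cloud(14.0, 3.0, 60)
    weighted = train_svm(pos, neg, cost_factor=10.0)
    flat = train_svm(pos, neg, cost_factor=1.0)
    rec_w = sum(weighted.decision_value(f) > 0 for f in pos)
    rec_f = sum(flat.decision_value(f) > 0 for f in pos)
    assert rec_w >= rec_f


def test_training_row_order_irrelevant():
    pos, neg = training_features(n_per_class=20, seed=2)
    m1 = train_svm(pos, neg)
    m2 = train_svm(list(reversed(pos)), list(reversed(neg)))
    # the decision function (not the raw solver state) must match
    probes = pos[:5] + neg[:5]
    for f in probes:
        assert m1.decision_value(f) == pytest.approx(m2.decision_value(f), abs=1e-6)


def test_classify_boundary_is_rejected():
    scaler = FeatureScaler(mean=np.zeros(12), sd=np.ones(12))
    model = SvmModel(weights=np.zeros(12), bias=0.0, scaler=scaler)
    pep = Peptide("s", "A", 1, 5, "AAAAA",
                  features=PeptideFeatures(5, 10.0, 1.0, "E", 50.0))
    classify_peptides(model, [pep])
    assert pep.accepted is False  # decision exactly 0 -> strict > rejects
    model_pos = SvmModel(weights=np.zeros(12), bias=0.1, scaler=scaler)
    classify_peptides(model_pos, [pep])
    assert pep.accepted is True


def test_classify_missing_features_errors(svm_model):
    pep = Peptide("s", "A", 1, 5, "AAAAA")
    with pytest.raises(ValueError):
        classify_peptides(svm_model, [pep])


def test_classify_accepts_training_like_strand(svm_model):
    pos, neg = training_features(n_per_class=5, seed=99)
    assert svm_model.decision_value(pos[0]) > 0
    assert svm_model.decision_value(neg[0]) <= 0


def test_model_save_load_round_trip(tmp_path, svm_model):
    path = tmp_path / "model.json"
    svm_model.save(path)
    loaded = SvmModel.load(path)
    np.testing.assert_allclose(loaded.weights, svm_model.weights)
    assert loaded.bias == svm_model.bias
    f = training_features(n_per_class=2, seed=7)[0][0]
    assert loaded.decision_value(f) == pytest.approx(svm_model.decision_value(f))


# --- covered-peptide removal ---------------------------------------------------

def _pep(start, end, chain="A"):
    return Peptide("s", chain, start, end, "A" * (end - start + 1))


def test_covered_subset_removed():
    kept = remove_covered_peptides([_pep(1, 10), _pep(2, 8)])
    assert [(p.start, p.end) for p in kept] == [(1, 10)]


def test_partial_overlap_retained():
    kept = remove_covered_peptides([_pep(1, 10), _pep(5, 14)])
    assert sorted((p.start, p.end) for p in kept) == [(1, 10), (5, 14)]


def test_duplicates_deduplicated():
    kept = remove_covered_peptides([_pep(3, 9), _pep(3, 9)])
    assert [(p.start, p.end) for p in kept] == [(3, 9)]


@given(st.lists(st.tuples(st.integers(1, 30), st.integers(3, 15)), min_size=1, max_size=12),
       st.randoms(use_true_random=False))
@settings(max_examples=60, deadline=None)
def test_covered_removal_idempotent_order_independent(raw, rnd):
    peps = [_pep(s, s + w) for s, w in raw]
    once = remove_covered_peptides(peps)
    twice = remove_covered_peptides(once)
    assert {(p.start, p.end) for p in once} == {(p.start, p.end) for p in twice}
    shuffled = peps[:]
    rnd.shuffle(shuffled)
    other = remove_covered_peptides(shuffled)
    assert {(p.start, p.end) for p in once} == {(p.start, p.end) for p in other}
    # postcondition: no kept span is a subset of another kept span
    spans = [(p.start, p.end) for p in once]
    for a in spans:
        for b in spans:
            if a != b:
                assert not (b[0] <= a[0] and a[1] <= b[1])


# --- regions -------------------------------------------------------------------

def test_regions_overlap_merges():
    regs = build_peptide_regions([_pep(1, 10), _pep(5, 14), _pep(20, 25)])
    assert sorted((r.start, r.end) for r in regs) == [(1, 14), (20, 25)]


def test_region_single_peptide():
    regs = build_peptide_regions([_pep(4, 9)])
    assert [(r.start, r.end) for r in regs] == [(4, 9)]
    assert len(regs[0].member_ids) == 1


def test_regions_adjacency_does_not_merge():
    regs = build_peptide_regions([_pep(1, 5), _pep(6, 10)])
    assert sorted((r.start, r.end) for r in regs) == [(1, 5), (6, 10)]


@given(st.lists(st.tuples(st.integers(1, 40), st.integers(3, 15)), min_size=1, max_size=12))
@settings(max_examples=60, deadline=None)
def test_regions_partition_covered_residues(raw):
    peps = [_pep(s, s + w) for s, w in raw]
    covered = set()
    for p in peps:
        covered |= set(range(p.start, p.end + 1))
    regs = build_peptide_regions(peps)
    region_residues = []
    for r in regs:
        region_residues.extend(range(r.start, r.end + 1))
    assert len(region_residues) == len(set(region_residues))  # disjoint
    assert set(region_residues) == covered                     # exact cover
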