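"""Shared fixtures and helpers for the dmiminer test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dmiminer import train_svm
from dmiminer.structio import Residue
from dmiminer.synthfix import _instantiate_pattern, training_features

AA20 = "ACDEFGHIKLMNPQRSTVWY"
UNIFORM_BG = {a: 1.0 / 20 for a in AA20}


def make_residue(chain, seq_index, aa="A", atoms=None, ca=None, ss="-", acc=None):
    """Minimal residue with explicit heavy-atom coordinates."""
    if atoms is None:
        atoms = [ca if ca is not None else (0.0, 0.0, 0.0)]
    atoms = np.asarray(atoms, dtype=float).reshape(-1, 3)
    if ca is None:
        ca = atoms[0]
    r = Residue(
        chain=chain,
        seq_index=seq_index,
        aa=aa,
        ca=np.asarray(ca, dtype=float),
        heavy_atoms=atoms,
        elements=["C"] * len(atoms),
        atom_names=["CA"] * len(atoms),
    )
    r.ss_class = ss
    if acc is not None:
        r.accessibility = acc
    return r


def residue_line(seq_indices, spacing=3.8, chain="A", aa="A"):
    """Residues along the x axis, one CA atom each, given seq indices."""
    return [
        make_residue(chain, idx, aa, ca=(i * spacing, 0.0, 0.0))
        for i, idx in enumerate(seq_indices)
    ]


def seq_with_pattern(rng, pattern, n=10, alphabet=AA20):
    """Random sequence of length n containing one instance of the pattern."""
    probs = np.ones(len(alphabet)) / len(alphabet)
    inst = _instantiate_pattern(pattern, rng, alphabet, probs)
    flank = "".join(rng.choice(list(alphabet), size=n - len(inst)))
    pos = int(rng.integers(0, n - len(inst) + 1))
    return flank[:pos] + inst + flank[pos:]


def rigid_motion(rng):
    """A random rotation matrix (via QR) and translation vector."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=50.0, size=3)
    return q, t


@pytest.fixture(scope="session")
def svm_model():
    """Motif-likeness SVM trained on the synthetic study conditions."""
    pos, neg = training_features(n_per_class=40, seed=1)
    return train_svm(pos, neg)


@pytest.fixture(scope="session")
def background_features():
    return training_features(n_per_class=40, seed=1)[1]
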