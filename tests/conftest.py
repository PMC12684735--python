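"""Shared fixtures and numeric helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from molproto.mol_io import MoleculeRecord, parse_smiles, tokenize_smiles


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=float)
    grad = np.zeros_like(x)
    flat = x.reshape(-1)
    gflat = grad.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f(x)
        flat[i] = orig - eps
        lo = f(x)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return grad


def relative_error(a: np.ndarray, b: np.ndarray) -> float:
    denom = max(np.abs(a).max(), np.abs(b).max(), 1e-12)
    return float(np.abs(a - b).max() / denom)


def make_record(smiles: str, label: float, task_kind: str = "classification",
                text: str | None = None) -> MoleculeRecord:
    tokens = text.split() if text else tokenize_smiles(smiles)
    return MoleculeRecord(smiles=smiles, graph=parse_smiles(smiles),
                          tokens=tokens, labels=np.array([float(label)]),
                          label_mask=np.array([True]), task_kind=task_kind)


@pytest.fixture(scope="session")
def tiny_records() -> list[MoleculeRecord]:
    """Four small labelled molecules: two rings, two chains."""
    return [
        make_record("C1CCCC1CC", 0, text="ring motif compound"),
        make_record("C1CCCC1O", 0, text="ring motif oxide"),
        make_record("CCCCCC", 1, text="chain motif compound"),
        make_record("CCCCCN", 1, text="chain motif amine"),
    ]
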