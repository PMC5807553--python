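import numpy as np
import pytest

from facecov.basis import make_basis, penalty_matrices, subject_design
from facecov.io import FunctionalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_instance(rng, n_subjects, m, n_basis, weighted=False, degree=3):
    """Random per-subject design blocks + responses for oracle comparisons."""
    basis = make_basis(n_basis, degree)
    pen = penalty_matrices(basis)
    X_blocks, C_blocks, W_blocks, offsets = [], [], [], [0]
    for _ in range(n_subjects):
        m_i = m if np.isscalar(m) else int(rng.integers(m[0], m[1] + 1))
        t = np.sort(rng.uniform(0, 1, m_i))
        X, _, _ = subject_design(t, basis, pen.G)
        X_blocks.append(X)
        C_blocks.append(rng.normal(size=X.shape[0]))
        if weighted:
            R = rng.normal(size=(X.shape[0], X.shape[0]))
            W_blocks.append(R @ R.T + 0.5 * np.eye(X.shape[0]))
        offsets.append(offsets[-1] + X.shape[0])
    return {
        "basis": basis,
        "pen": pen,
        "X_blocks": X_blocks,
        "C_blocks": C_blocks,
        "W_blocks": W_blocks if weighted else None,
        "offsets": offsets,
        "X": np.vstack(X_blocks),
        "C": np.concatenate(C_blocks),
    }


def full_weight(inst):
    import scipy.linalg as sla

    if inst["W_blocks"] is None:
        return np.eye(len(inst["C"]))
    return sla.block_diag(*inst["W_blocks"])


@pytest.fixture
def tiny_dataset():
    """Six subjects, two observations each, smooth signal + noise."""
    r = np.random.default_rng(7)
    subs, ts, ys = [], [], []
    for i in range(6):
        t = np.sort(r.uniform(0, 1, 2))
        subs.append(np.full(2, i))
        ts.append(t)
        ys.append(np.sin(2 * np.pi * t) + 0.1 * r.normal(size=2))
    return FunctionalDataset(
        subjects=np.concatenate(subs), t=np.concatenate(ts), y=np.concatenate(ys)
    )
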