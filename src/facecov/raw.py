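"""Residuals and subject-stacked raw covariances (auxiliary variables).

For residuals ``r_ij = y_ij - f(t_ij)`` the products ``C_{i j1 j2} = r_{ij1} r_{ij2}``
are unbiased for the covariance surface ``C(t_{ij1}, t_{ij2})`` when ``j1 != j2``
and for ``C(t, t) + sigma2_eps`` on the diagonal ("nugget") pairs.  These
products, stacked subject by subject in the fixed pair order of
:func:`facecov.basis.pair_indices`, are the response vector of the covariance
smoother.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import pair_indices
from .io import FunctionalDataset

__all__ = ["RawCovariances", "compute_residuals", "build_raw_covariances"]


@dataclass(frozen=True)
class RawCovariances:
    """Stacked auxiliary variables with their pair bookkeeping.

    ``values[offsets[i]:offsets[i+1]]`` is subject ``i``'s vector of length
    ``n_i = m_i (m_i + 1) / 2``; ``j1/j2`` are within-subject 0-based indices
    and ``delta`` flags nugget rows (``j1 == j2``, index equality — two
    distinct observations at the same time form an off-diagonal pair).
    """

    values: np.ndarray
    j1: np.ndarray
    j2: np.ndarray
    delta: np.ndarray
    offsets: np.ndarray  # length n_subjects + 1
    times: list  # per-subject observation times, same order

    @property
    def n_total(self) -> int:
        return len(self.values)

    def subject_slice(self, i: int) -> slice:
        return slice(self.offsets[i], self.offsets[i + 1])


def compute_residuals(dataset: FunctionalDataset, mean=None) -> np.ndarray:
    """``r_ij = y_ij - f_hat(t_ij)`` aligned with the dataset rows.

    ``mean`` is any object with a ``predict(t)`` method (or None for a zero
    mean, used when the data are already centred).
    """
    if mean is None:
        return dataset.y.copy()
    return dataset.y - np.asarray(mean.predict(dataset.t), dtype=float)


def build_raw_covariances(dataset: FunctionalDataset, residuals: np.ndarray) -> RawCovariances:
    values, J1, J2, delta, times = [], [], [], [], []
    offsets = [0]
    for rows in dataset.groups:
        r = residuals[rows]
        j1, j2 = pair_indices(len(rows))
        values.append(r[j1] * r[j2])
        J1.append(j1)
        J2.append(j2)
        delta.append((j1 == j2).astype(float))
        times.append(dataset.t[rows])
        offsets.append(offsets[-1] + len(j1))
    return RawCovariances(
        values=np.concatenate(values),
        j1=np.concatenate(J1),
        j2=np.concatenate(J2),
        delta=np.concatenate(delta),
        offsets=np.asarray(offsets),
        times=times,
    )
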