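"""Long-format functional data: reading, time rescaling and fit serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "FormatError",
    "TimeTransform",
    "FunctionalDataset",
    "as_dataset",
    "read_long_table",
    "write_long_table",
    "rescale_times",
    "serialize_fit",
    "deserialize_fit",
    "write_covariance_grid",
]

DEFAULT_COLUMNS = {"subject": "subj", "time": "argvals", "value": "y"}

FIT_FORMAT = "facecov-fit"
FIT_VERSION = 1


class SchemaError(ValueError):
    """The input table does not have the declared columns/types."""


class FormatError(ValueError):
    """A serialized fit archive is corrupted or not in the expected format."""


@dataclass(frozen=True)
class TimeTransform:
    """Affine map between the original time axis and the unit interval."""

    lo: float = 0.0
    hi: float = 1.0

    def forward(self, t):
        return (np.asarray(t, dtype=float) - self.lo) / (self.hi - self.lo)

    def inverse(self, u):
        return self.lo + (self.hi - self.lo) * np.asarray(u, dtype=float)


@dataclass(frozen=True)
class FunctionalDataset:
    """Sparse longitudinal observations ``{(y_ij, t_ij)}`` grouped by subject.

    Rows keep their original within-subject order; subjects are ordered by
    first appearance.  ``t`` is expected on the unit interval after
    :func:`rescale_times`.
    """

    subjects: np.ndarray  # per-row subject label
    t: np.ndarray
    y: np.ndarray
    time_transform: TimeTransform = field(default_factory=TimeTransform)

    def __post_init__(self):
        if len(self.t) == 0:
            raise ValueError("empty dataset")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite time or value entries")

    @property
    def subject_ids(self) -> np.ndarray:
        _, idx = np.unique(self.subjects, return_index=True)
        return self.subjects[np.sort(idx)]

    @property
    def groups(self) -> list[np.ndarray]:
        """Row-index arrays per subject, in order of first appearance."""
        order = {s: i for i, s in enumerate(self.subject_ids)}
        buckets: list[list[int]] = [[] for _ in order]
        for row, s in enumerate(self.subjects):
            buckets[order[s]].append(row)
        return [np.asarray(b) for b in buckets]

    @property
    def counts(self) -> np.ndarray:
        """Observations per subject, ``m_i``."""
        return np.array([len(g) for g in self.groups])

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def as_dataset(data) -> FunctionalDataset:
    """Coerce a FunctionalDataset or a long-format DataFrame (default columns)."""
    if isinstance(data, FunctionalDataset):
        return data
    if isinstance(data, pd.DataFrame):
        return _from_frame(data, DEFAULT_COLUMNS)
    raise TypeError(f"cannot interpret {type(data).__name__} as functional data")


def _from_frame(df: pd.DataFrame, columns: dict) -> FunctionalDataset:
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    for role in ("subject", "time", "value"):
        if cols[role] not in df.columns:
            raise SchemaError(f"missing column {cols[role]!r} (role: {role})")
    if len(df) == 0:
        raise ValueError("empty input table")
    for role in ("time", "value"):
        raw = df[cols[role]]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {raw.iloc[row]!r} in column {cols[role]!r} at row {row}"
            )
        if parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
            raise ValueError(f"missing value in column {cols[role]!r} at row {row}")
        df = df.assign(**{cols[role]: parsed.astype(float)})
    return FunctionalDataset(
        subjects=df[cols["subject"]].to_numpy(),
        t=df[cols["time"]].to_numpy(dtype=float),
        y=df[cols["value"]].to_numpy(dtype=float),
    )


def read_long_table(path, columns: dict | None = None) -> FunctionalDataset:
    """Read a long-format CSV (default columns ``subj,argvals,y``)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty input file: {path}") from exc
    return _from_frame(df, columns or {})


def write_long_table(dataset: FunctionalDataset, path, columns: dict | None = None) -> None:
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    pd.DataFrame(
        {cols["subject"]: dataset.subjects, cols["time"]: dataset.t, cols["value"]: dataset.y}
    ).to_csv(path, index=False)


def rescale_times(dataset: FunctionalDataset) -> FunctionalDataset:
    """Affinely map observed times onto [0, 1]; the transform is stored on the dataset."""
    lo, hi = float(np.min(dataset.t)), float(np.max(dataset.t))
    if hi == lo:
        raise ValueError("all observation times identical; time domain is degenerate")
    tr = TimeTransform(lo=lo, hi=hi)
    return replace(dataset, t=tr.forward(dataset.t), time_transform=tr)


def _fit_payload(fit) -> dict:
    from .mean import MeanPSpline

    mean = fit.mean_
    if isinstance(mean, MeanPSpline):
        mean_block = {
            "kind": "pspline",
            "n_basis": mean.n_basis,
            "degree": mean.degree,
            "coef": mean.coef_.tolist(),
            "lambda": mean.lambda_,
        }
    elif mean is None:
        mean_block = {"kind": "zero"}
    else:
        raise ValueError("only P-spline or zero means can be serialized")
    return {
        "format": FIT_FORMAT,
        "version": FIT_VERSION,
        "n_basis": fit.n_basis,
        "degree": fit.degree,
        "beta": fit.beta,
        "theta": np.asarray(fit.theta_).tolist(),
        "sigma2": float(fit.sigma2_),
        "lambdas": [float(v) for v in fit.lambda_],
        "mean": mean_block,
        "time_transform": {"lo": fit.time_transform_.lo, "hi": fit.time_transform_.hi},
    }


def serialize_fit(fit, path) -> None:
    """Write a fitted covariance smoother to a versioned JSON archive.

    JSON floats round-trip IEEE doubles exactly, so covariance evaluations of
    the restored fit are bit-identical.
    """
    with open(path, "w") as fh:
        json.dump(_fit_payload(fit), fh)


def deserialize_fit(path):
    """Restore a :class:`~facecov.estimator.FacesSmoother` from its archive."""
    from .basis import make_basis
    from .estimator import FacesSmoother
    from .mean import MeanPSpline

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"corrupted fit archive: {path}") from exc
    if not isinstance(payload, dict) or payload.get("format") != FIT_FORMAT:
        raise FormatError(f"not a {FIT_FORMAT} archive: {path}")
    if payload.get("version") != FIT_VERSION:
        raise FormatError(f"unsupported archive version {payload.get('version')!r}")
    try:
        fit = FacesSmoother(
            n_basis=payload["n_basis"], degree=payload["degree"], beta=payload["beta"]
        )
        fit.basis_ = make_basis(payload["n_basis"], payload["degree"])
        fit.theta_ = np.asarray(payload["theta"], dtype=float)
        fit.sigma2_ = float(payload["sigma2"])
        fit.lambda_ = tuple(payload["lambdas"])
        fit.time_transform_ = TimeTransform(**payload["time_transform"])
        mb = payload["mean"]
        if mb["kind"] == "pspline":
            mean = MeanPSpline(n_basis=mb["n_basis"], degree=mb["degree"])
            mean.basis_ = make_basis(mb["n_basis"], mb["degree"])
            mean.coef_ = np.asarray(mb["coef"], dtype=float)
            mean.lambda_ = mb["lambda"]
            fit.mean_ = mean
        else:
            fit.mean_ = None
    except (KeyError, TypeError) as exc:
        raise FormatError(f"incomplete fit archive: {path}") from exc
    return fit


def write_covariance_grid(fit, path, grid_size: int = 100) -> None:
    """Evaluate the smoothed covariance on a square grid and write TSV ``s\\tt\\tC``."""
    g = np.linspace(0.0, 1.0, grid_size)
    C = fit.covariance(g)
    with open(path, "w") as fh:
        fh.write("s\tt\tC\n")
        for a, row in zip(g, C):
            for b, v in zip(g, row):
                fh.write(f"{a:.10g}\t{b:.10g}\t{v!r}\n")
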