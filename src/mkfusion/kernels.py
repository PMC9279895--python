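"""Per-modality kernel computation and convex kernel combination.

A kernel matrix is the subject-by-subject similarity matrix induced by one
modality's features.  Kernels from several modalities are made commensurate
by unit-diagonal normalisation and fused by a convex combination
``K = sum_m beta_m K^(m)`` with simplex-constrained weights ``beta`` — the
weights are then read as modality contributions.

Standardisation statistics (and the RBF median-heuristic bandwidth) are
always computed from a designated training row set so cross-validation folds
never leak held-out information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KernelSpec",
    "KernelMatrix",
    "KernelWeights",
    "compute_kernel",
    "normalize_kernel",
    "combine_kernels",
    "center_kernel",
]

SYMMETRY_TOL = 1e-10
PSD_TOL_FACTOR = 1e-8  # min eigenvalue >= -factor * trace / n


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and preprocessing for one modality.

    ``family`` is ``"linear"`` or ``"rbf"``; ``gamma`` is a positive float or
    ``"median-heuristic"`` (RBF only); ``standardize`` z-scores features with
    training-row statistics before the kernel is evaluated.
    """

    family: str = "linear"
    gamma: float | str | None = None
    standardize: bool = True

    def validate(self) -> None:
        if self.family not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "rbf":
            g = self.gamma if self.gamma is not None else "median-heuristic"
            if isinstance(g, str):
                if g != "median-heuristic":
                    raise ValueError(f"gamma must be positive or 'median-heuristic', got {g!r}")
            elif not g > 0:
                raise ValueError(f"gamma must be > 0, got {g}")


@dataclass
class KernelMatrix:
    """Symmetric PSD similarity matrix over an ordered set of subjects."""

    values: np.ndarray
    subject_ids: tuple[str, ...]
    modality: str = ""
    spec: KernelSpec | None = None
    train_mean: np.ndarray | None = None
    train_sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.subject_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kernel has shape {self.values.shape}, expected ({n}, {n})")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def check(self, psd: bool = True) -> None:
        """Assert symmetry (and optionally positive semidefiniteness)."""
        K = self.values
        asym = np.abs(K - K.T).max()
        if asym > SYMMETRY_TOL:
            raise ValueError(f"kernel not symmetric: max |K - K^T| = {asym:.2e}")
        if psd:
            w = np.linalg.eigvalsh((K + K.T) / 2.0)
            bound = -PSD_TOL_FACTOR * max(np.trace(K), 1.0) / self.n
            if w.min() < bound:
                raise ValueError(
                    f"kernel not PSD: min eigenvalue {w.min():.2e} < {bound:.2e}"
                )

    def submatrix(self, rows: Sequence[int], cols: Sequence[int] | None = None) -> np.ndarray:
        cols = rows if cols is None else cols
        return self.values[np.ix_(np.asarray(rows), np.asarray(cols))]

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.subject_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


@dataclass(frozen=True)
class KernelWeights:
    """Simplex-constrained modality weights: beta_m >= 0, sum beta_m = 1."""

    beta: tuple[float, ...]
    modalities: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        beta = tuple(float(b) for b in self.beta)
        object.__setattr__(self, "beta", beta)
        if self.modalities and len(self.modalities) != len(beta):
            raise ValueError("modalities and beta lengths differ")
        if any(b < 0 for b in beta):
            raise ValueError(f"weights must be non-negative, got {beta}")
        if abs(sum(beta) - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got sum = {sum(beta)!r}")

    def __len__(self) -> int:
        return len(self.beta)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...], list[str]]:
    if isinstance(X, pd.DataFrame):
        return (X.to_numpy(dtype=float),
                tuple(str(i) for i in X.index),
                [str(c) for c in X.columns])
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("feature block must be 2-D")
    return arr, tuple(f"row{i}" for i in range(arr.shape[0])), \
        [f"f{j}" for j in range(arr.shape[1])]


def compute_kernel(
    X,
    spec: KernelSpec,
    train_rows: Sequence[int] | None = None,
    modality: str = "",
) -> KernelMatrix:
    """Evaluate the kernel of one feature block over all its rows.

    ``train_rows`` (positional indices; default all rows) supplies the rows
    from which standardisation statistics — and, for the RBF median
    heuristic, the bandwidth — are computed, so the same call serves both a
    training fit and the scoring of held-out rows without leakage.

    Zero-variance features (on the training rows) are dropped with a warning
    and recorded in ``meta['dropped_features']``.
    """
    spec.validate()
    values, ids, names = _as_matrix(X)
    n = values.shape[0]
    if n == 0 or values.shape[1] == 0:
        raise ValueError("feature block is empty")
    train = np.arange(n) if train_rows is None else np.asarray(train_rows, dtype=int)
    if train.size == 0:
        raise ValueError("train_rows is empty")

    meta: dict = {}
    mean = sd = None
    Z = values
    if spec.standardize:
        mean = values[train].mean(axis=0)
        sd = values[train].std(axis=0, ddof=0)
        dead = sd <= 0
        if dead.any():
            dropped = [names[j] for j in np.flatnonzero(dead)]
            warnings.warn(
                f"{modality or 'block'}: dropping {len(dropped)} zero-variance "
                f"feature(s): {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                stacklevel=2,
            )
            meta["dropped_features"] = dropped
            keep = ~dead
            values, mean, sd = values[:, keep], mean[keep], sd[keep]
            if values.shape[1] == 0:
                raise ValueError("all features have zero variance on the training rows")
        Z = (values - mean) / sd

    if spec.family == "linear":
        K = Z @ Z.T
    else:  # rbf
        sq = np.sum(Z ** 2, axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T), 0.0)
        gamma = spec.gamma if spec.gamma is not None else "median-heuristic"
        if gamma == "median-heuristic":
            tri = np.triu_indices(train.size, k=1)
            dists = np.sqrt(d2[np.ix_(train, train)][tri])
            med = float(np.median(dists)) if dists.size else 0.0
            if med <= 0:
                raise ValueError("median pairwise training distance is zero; "
                                 "cannot apply the median heuristic")
            gamma = 1.0 / (2.0 * med ** 2)
        meta["gamma"] = float(gamma)
        K = np.exp(-float(gamma) * d2)

    K = (K + K.T) / 2.0  # exact symmetry against round-off
    return KernelMatrix(values=K, subject_ids=ids, modality=modality, spec=spec,
                        train_mean=mean, train_sd=sd, meta=meta)


def normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Scale to unit diagonal: K'_ij = K_ij / sqrt(K_ii K_jj).

    Makes modality kernels commensurate before convex combination, so the
    combination weights measure information content rather than raw scale.
    """
    diag = np.diag(K.values).copy()
    bad = np.flatnonzero(diag <= 0)
    if bad.size:
        raise ValueError(
            f"cannot normalize: non-positive diagonal for subject(s) "
            f"{[K.subject_ids[i] for i in bad[:5]]}"
        )
    inv = 1.0 / np.sqrt(diag)
    values = K.values * inv[:, None] * inv[None, :]
    np.fill_diagonal(values, 1.0)
    out = replace(K, values=values)
    out.meta = {**K.meta, "normalized": True}
    return out


def combine_kernels(kernels: Sequence[KernelMatrix], weights: KernelWeights) -> KernelMatrix:
    """Convex combination ``K = sum_m beta_m K^(m)`` of aligned kernels."""
    if len(kernels) != len(weights):
        raise ValueError(f"{len(kernels)} kernels but {len(weights)} weights")
    ids = kernels[0].subject_ids
    for k in kernels[1:]:
        if k.subject_ids != ids:
            raise ValueError(
                f"kernel subject order mismatch between "
                f"{kernels[0].modality!r} and {k.modality!r}"
            )
    beta = weights.as_array()
    values = np.zeros_like(kernels[0].values)
    for b, k in zip(beta, kernels):
        if b != 0.0:
            values += b * k.values
    return KernelMatrix(
        values=values, subject_ids=ids, modality="combined", spec=None,
        meta={"beta": beta.tolist(),
              "components": [k.modality for k in kernels]},
    )


def center_kernel(K: KernelMatrix) -> KernelMatrix:
    """Double-center: K_c = K - 1K/n - K1/n + 1K1/n^2 (feature-space centering).

    Every row (and column) of the output sums to zero; required before the
    eigendecomposition used by kernel PCA.
    """
    V = K.values
    if V.shape[0] != V.shape[1]:
        raise ValueError("kernel must be square")
    row_mean = V.mean(axis=1, keepdims=True)
    col_mean = V.mean(axis=0, keepdims=True)
    grand = V.mean()
    values = V - row_mean - col_mean + grand
    values = (values + values.T) / 2.0
    out = replace(K, values=values)
    out.meta = {**K.meta, "centered": True}
    return out
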