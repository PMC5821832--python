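"""Kernel functions and Gram-matrix computation.

The workhorse is the ANOVA kernel

    K(x, y) = (sum_k exp(-sigma * (x_k - y_k)^2))^d

where the sum runs over the feature coordinates.  With d=1 it is the sum of
per-coordinate 1-D Gaussian kernels, so K(x, x) = p^d for p features.
Gaussian, Laplace and linear kernels are provided for comparison runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

KERNEL_FAMILIES = ("anova", "gaussian", "laplace", "linear")


class KernelError(ValueError):
    pass


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus parameters (bandwidth ``sigma``, ANOVA ``degree``)."""

    family: str = "anova"
    sigma: float = 0.135
    degree: int = 1

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise KernelError(f"unknown kernel family {self.family!r}")
        if self.family != "linear" and not self.sigma > 0:
            raise KernelError("sigma must be positive")
        if int(self.degree) != self.degree or self.degree < 1:
            raise KernelError("degree must be a positive integer")


@dataclass
class GramMatrix:
    """An n x n kernel matrix together with the spec that produced it."""

    values: np.ndarray
    kernel: KernelSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise KernelError("Gram matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise KernelError("Gram matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _check_pair(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise KernelError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise KernelError("vectors must have at least one coordinate")
    return x, y


def anova_kernel(x, y, sigma: float, degree: int = 1) -> float:
    x, y = _check_pair(x, y)
    return float(np.exp(-sigma * (x - y) ** 2).sum() ** degree)


def gaussian_kernel(x, y, sigma: float) -> float:
    x, y = _check_pair(x, y)
    return float(np.exp(-sigma * np.sum((x - y) ** 2)))


def laplace_kernel(x, y, sigma: float) -> float:
    x, y = _check_pair(x, y)
    return float(np.exp(-sigma * np.sqrt(np.sum((x - y) ** 2))))


def linear_kernel(x, y) -> float:
    x, y = _check_pair(x, y)
    return float(x @ y)


def gram_matrix(X: np.ndarray, spec: KernelSpec) -> GramMatrix:
    """Pairwise kernel matrix of the rows of ``X`` under ``spec``.

    ANOVA is evaluated coordinate-wise (one n x n accumulation per feature),
    which keeps memory at O(n^2) for wide matrices.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise KernelError("X must be 2-D")
    n, p = X.shape
    if n < 2:
        raise KernelError("need at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise KernelError("non-finite values in input")
    if spec.family == "anova":
        K = np.zeros((n, n))
        for k in range(p):
            d = X[:, k, None] - X[None, :, k]
            K += np.exp(-spec.sigma * d * d)
        K **= spec.degree
    elif spec.family == "gaussian":
        K = np.exp(-spec.sigma * cdist(X, X, "sqeuclidean"))
    elif spec.family == "laplace":
        K = np.exp(-spec.sigma * cdist(X, X, "euclidean"))
    elif spec.family == "linear":
        K = X @ X.T
    else:  # pragma: no cover - guarded by KernelSpec
        raise KernelError(spec.family)
    K = (K + K.T) / 2.0  # clean round-off asymmetry
    return GramMatrix(K, spec)
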