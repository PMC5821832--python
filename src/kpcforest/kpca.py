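"""Kernel PCA, contribution rates, bandwidth scanning and quadrant labels.

The model eigendecomposes the double-centered Gram matrix; component scores
are the projections of the training samples on the feature-space principal
axes.  Sample classes for the downstream importance analysis are derived from
the signs of the first two component scores (quadrant pseudo-labels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .kernels import GramMatrix, KernelSpec, gram_matrix
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

#: eigenvalues below this fraction of the largest are treated as null space
EIGENVALUE_RTOL = 1e-10

#: (sign(PC1), sign(PC2)) -> class, with scores of exactly 0 counted positive
DEFAULT_QUADRANT_MAP = {(1, 1): 1, (-1, 1): 2, (-1, -1): 3, (1, -1): 4}


class KpcaError(ValueError):
    pass


@dataclass
class KpcaModel:
    eigenvalues: np.ndarray  # all positive eigenvalues, descending
    dual_coef: np.ndarray  # n x n_components, columns alpha_i with lambda_i * |alpha_i|^2 = 1
    scores: np.ndarray  # n x n_components
    kernel: KernelSpec
    sample_ids: Optional[list[str]] = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def contribution_rates(self) -> np.ndarray:
        return contribution_rates(self)

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores[:, i] for i in range(self.n_components)}
        df = pd.DataFrame(cols)
        if self.sample_ids is not None:
            df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class QuadrantLabeling:
    """Per-sample class in {1, 2, 3, 4} from the PC1/PC2 sign pair."""

    classes: np.ndarray
    mapping: dict
    sample_ids: Optional[list[str]] = None

    def counts(self) -> dict:
        uniq, cnt = np.unique(self.classes, return_counts=True)
        return dict(zip(uniq.tolist(), cnt.tolist()))

    def to_frame(self, model: Optional[KpcaModel] = None) -> pd.DataFrame:
        df = pd.DataFrame({"class": self.classes})
        if self.sample_ids is not None:
            df.insert(0, "sample_id", self.sample_ids)
        if model is not None:
            df.insert(len(df.columns) - 1, "PC1", model.scores[:, 0])
            df.insert(len(df.columns) - 1, "PC2", model.scores[:, 1])
        return df


def center_gram(K: Union[GramMatrix, np.ndarray]) -> np.ndarray:
    """Feature-space double centering: K - 1K - K1 + 1K1 with 1 = J/n.

    Every row and column of the result sums to zero; the operation is
    idempotent.
    """
    values = K.values if isinstance(K, GramMatrix) else np.asarray(K, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise KpcaError("Gram matrix must be square")
    if not np.allclose(values, values.T, atol=1e-10, rtol=0):
        raise KpcaError("Gram matrix must be symmetric")
    row_mean = values.mean(axis=1, keepdims=True)
    col_mean = values.mean(axis=0, keepdims=True)
    grand = values.mean()
    return values - row_mean - col_mean + grand


def _fix_signs(alphas: np.ndarray) -> np.ndarray:
    """Deterministic orientation: the largest-|entry| dual coefficient is positive."""
    out = alphas.copy()
    for i in range(out.shape[1]):
        j = int(np.argmax(np.abs(out[:, i])))
        if out[j, i] < 0:
            out[:, i] = -out[:, i]
    return out


def kpca_fit(
    X: Union[FeatureMatrix, np.ndarray],
    spec: KernelSpec,
    n_components: int = 2,
) -> KpcaModel:
    """Fit kernel PCA on the rows of ``X``.

    Eigenvectors v of the centered Gram matrix are rescaled to dual
    coefficients alpha = v / sqrt(lambda) so that lambda * alpha'alpha = 1;
    scores are then K_centered @ alpha = sqrt(lambda) * v.
    """
    if isinstance(X, FeatureMatrix):
        sample_ids = list(X.sample_ids)
        data = X.values
    else:
        sample_ids = None
        data = np.asarray(X, dtype=float)
    n = data.shape[0]
    if n_components > n - 1:
        raise KpcaError(f"n_components={n_components} exceeds n-1={n - 1}")
    K = gram_matrix(data, spec)
    Kc = center_gram(K)
    eigvals, eigvecs = np.linalg.eigh(Kc)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    positive = eigvals > EIGENVALUE_RTOL * max(eigvals[0], 0.0)
    n_pos = int(positive.sum())
    if n_pos < n_components:
        raise KpcaError(
            f"only {n_pos} positive eigenvalues available for "
            f"{n_components} requested components"
        )
    lam = eigvals[:n_pos]
    vec = _fix_signs(eigvecs[:, :n_components])
    alphas = vec / np.sqrt(lam[:n_components])
    scores = Kc @ alphas
    return KpcaModel(
        eigenvalues=lam,
        dual_coef=alphas,
        scores=scores,
        kernel=spec,
        sample_ids=sample_ids,
    )


def contribution_rates(model: KpcaModel) -> np.ndarray:
    """Each positive eigenvalue's share of the total positive eigenvalue mass."""
    lam = model.eigenvalues
    return lam / lam.sum()


def score_dispersion(scores: np.ndarray) -> float:
    """Mean nearest-neighbor distance of min-max-normalized 2-D scores.

    Used as the spread criterion when scanning sigma: a well-dispersed score
    plot (no piled-up samples) maximizes this quantity.
    """
    S = np.asarray(scores, dtype=float)[:, :2]
    lo, hi = S.min(axis=0), S.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Z = (S - lo) / span
    dist, _ = cKDTree(Z).query(Z, k=2)
    return float(dist[:, 1].mean())


def scan_sigma(
    X: Union[FeatureMatrix, np.ndarray],
    sigma_grid: Sequence[float],
    degree: int = 1,
    n_components: int = 2,
    family: str = "anova",
) -> pd.DataFrame:
    """Fit one KPCA per sigma; report PC1 contribution rate and dispersion.

    Failed fits are recorded as missing rows and the scan continues.
    """
    grid = [float(s) for s in sigma_grid]
    if not grid or any(s <= 0 for s in grid):
        raise KpcaError("sigma grid must be non-empty and positive")
    rows = []
    for sigma in grid:
        try:
            model = kpca_fit(X, KernelSpec(family, sigma, degree), n_components)
            rates = contribution_rates(model)
            rows.append(
                {
                    "sigma": sigma,
                    "pc1_contribution": float(rates[0]),
                    "dispersion": score_dispersion(model.scores),
                }
            )
        except Exception as exc:  # noqa: BLE001 - scan is best-effort by contract
            logger.warning("scan_sigma: fit failed at sigma=%g (%s)", sigma, exc)
            rows.append(
                {"sigma": sigma, "pc1_contribution": np.nan, "dispersion": np.nan}
            )
    return pd.DataFrame(rows)


def default_sigma_grid(lo: float = 0.05, hi: float = 0.30, steps: int = 11) -> list[float]:
    return list(np.linspace(lo, hi, steps))


def pick_sigma(scan: pd.DataFrame) -> float:
    """Sigma maximizing score-plot dispersion (ties: smallest sigma)."""
    ok = scan.dropna(subset=["dispersion"])
    if ok.empty:
        raise KpcaError("no successful fit in sigma scan")
    best = ok["dispersion"].max()
    return float(ok.loc[ok["dispersion"] == best, "sigma"].min())


def quadrant_labels(
    model_or_scores: Union[KpcaModel, np.ndarray],
    mapping: Optional[dict] = None,
    sample_ids: Optional[list[str]] = None,
) -> QuadrantLabeling:
    """Assign each sample a class from the signs of its first two scores.

    Scores of exactly zero count as positive so that the rule is a
    deterministic partition.
    """
    if isinstance(model_or_scores, KpcaModel):
        scores = model_or_scores.scores
        if sample_ids is None:
            sample_ids = model_or_scores.sample_ids
    else:
        scores = np.asarray(model_or_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise KpcaError("need at least two score components for quadrant labels")
    mapping = dict(DEFAULT_QUADRANT_MAP if mapping is None else mapping)
    if sorted(mapping.keys()) != sorted(DEFAULT_QUADRANT_MAP.keys()):
        raise KpcaError("mapping must cover the four sign pairs")
    s1 = np.where(scores[:, 0] >= 0, 1, -1)
    s2 = np.where(scores[:, 1] >= 0, 1, -1)
    classes = np.array([mapping[(a, b)] for a, b in zip(s1, s2)], dtype=int)
    return QuadrantLabeling(classes=classes, mapping=mapping, sample_ids=sample_ids)
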