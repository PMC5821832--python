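"""Normalization, scaling and merging of heterogeneous feature blocks.

The canonical analysis input is a sample x variable table (``FeatureMatrix``)
assembled from one or more modality blocks (NMR peak intensities, element
concentrations, nutrient amounts).  Raw spectra are represented by
``SpectralBlock`` and can be dilution-corrected with probabilistic quotient
normalization (PQN) and reduced to a feature table with a simple peak picker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

MODALITIES = ("nmr", "element", "nutrient")

#: header-prefix convention used by the TSV reader/writer
MODALITY_PREFIX = {"nmr": "nmr:", "element": "elem:", "nutrient": "nutr:"}
PREFIX_MODALITY = {v: k for k, v in MODALITY_PREFIX.items()}


class PreprocessError(ValueError):
    """Raised for invalid preprocessing inputs."""


@dataclass
class SpectralBlock:
    """A sample x point spectral matrix with a shared coordinate axis."""

    intensities: np.ndarray
    axis: np.ndarray
    sample_ids: list[str]
    subject_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.intensities.ndim != 2:
            raise PreprocessError("intensities must be 2-D (samples x points)")
        n, m = self.intensities.shape
        if len(self.axis) != m:
            raise PreprocessError("axis length must equal the number of points")
        if len(self.sample_ids) != n:
            raise PreprocessError("sample_ids length must equal the number of samples")
        if len(set(self.sample_ids)) != n:
            raise PreprocessError("sample_ids must be unique and non-missing")
        diffs = np.diff(self.axis)
        if m > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise PreprocessError("axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensities)):
            raise PreprocessError("intensities must be finite")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]


@dataclass
class FeatureMatrix:
    """A sample x variable numeric table with per-variable modality tags."""

    values: np.ndarray
    variable_names: list[str]
    modalities: list[str]
    sample_ids: list[str]
    subject_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PreprocessError("values must be 2-D (samples x variables)")
        n, p = self.values.shape
        if len(self.variable_names) != p:
            raise PreprocessError(
                f"{len(self.variable_names)} variable names for {p} columns"
            )
        if len(self.modalities) != p:
            raise PreprocessError("one modality tag per variable is required")
        for m in self.modalities:
            if m not in MODALITIES:
                raise PreprocessError(f"unknown modality {m!r}")
        if len(self.sample_ids) != n:
            raise PreprocessError("sample_ids length must equal the number of rows")
        if len(set(self.sample_ids)) != n:
            raise PreprocessError("sample_ids must be unique")
        if self.subject_ids is not None and len(self.subject_ids) != n:
            raise PreprocessError("subject_ids length must equal the number of rows")
        if not np.all(np.isfinite(self.values)):
            raise PreprocessError("feature values must be finite (no missing values)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [MODALITY_PREFIX[m] + v for v, m in zip(self.variable_names, self.modalities)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        if self.subject_ids is not None:
            df.insert(1, "subject_id", self.subject_ids)
        return df

    def select(self, variables: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given order; unknown names raise."""
        index = {v: i for i, v in enumerate(self.variable_names)}
        missing = [v for v in variables if v not in index]
        if missing:
            raise PreprocessError(f"unknown variables: {missing}")
        idx = [index[v] for v in variables]
        return FeatureMatrix(
            values=self.values[:, idx],
            variable_names=[self.variable_names[i] for i in idx],
            modalities=[self.modalities[i] for i in idx],
            sample_ids=list(self.sample_ids),
            subject_ids=None if self.subject_ids is None else list(self.subject_ids),
        )

    def reorder_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise PreprocessError(f"unknown sample ids: {missing}")
        idx = [index[s] for s in sample_ids]
        return FeatureMatrix(
            values=self.values[idx],
            variable_names=list(self.variable_names),
            modalities=list(self.modalities),
            sample_ids=list(sample_ids),
            subject_ids=None
            if self.subject_ids is None
            else [self.subject_ids[i] for i in idx],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, default_modality: str = "nmr") -> "FeatureMatrix":
        df = df.copy()
        if "sample_id" not in df.columns:
            raise PreprocessError("first column must be 'sample_id'")
        sample_ids = [str(s) for s in df.pop("sample_id")]
        subject_ids = None
        if "subject_id" in df.columns:
            subject_ids = [str(s) for s in df.pop("subject_id")]
        names, modalities = [], []
        for col in df.columns:
            for prefix, modality in PREFIX_MODALITY.items():
                if col.startswith(prefix):
                    names.append(col[len(prefix):])
                    modalities.append(modality)
                    break
            else:
                names.append(col)
                modalities.append(default_modality)
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            bad = [names[j] for j in np.where(np.isnan(values).any(axis=0))[0]]
            raise PreprocessError(f"missing values in variables {bad}; imputation is not supported")
        return cls(values, names, modalities, sample_ids, subject_ids)

    @classmethod
    def read_tsv(cls, path, default_modality: str = "nmr") -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"), default_modality=default_modality)


def pqn_normalize(
    block: SpectralBlock,
    reference: Optional[np.ndarray] = None,
    return_factors: bool = False,
):
    """Probabilistic quotient normalization of a spectral block.

    Each sample is divided by the median of its point-wise quotients against a
    reference spectrum.  When ``reference`` is omitted it defaults to the
    point-wise median spectrum of the total-area-normalized samples, which
    makes the output invariant to per-sample multiplicative dilution.
    """
    X = block.intensities
    if np.any(X < 0):
        raise PreprocessError("PQN requires non-negative intensities")
    sums = X.sum(axis=1)
    zero = np.where(sums == 0)[0]
    if zero.size:
        raise PreprocessError(
            f"all-zero sample(s): {[block.sample_ids[i] for i in zero]}"
        )
    if reference is None:
        if block.n_samples < 2:
            raise PreprocessError("PQN needs >=2 samples when no reference is given")
        # default reference: point-wise median of the area-normalized samples;
        # quotients are then taken against the *raw* samples so that the
        # per-sample factor absorbs the full dilution (and a rerun yields
        # factors of exactly 1)
        reference = np.median(X / sums[:, None], axis=0)
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != (X.shape[1],):
            raise PreprocessError("reference length must match the number of points")
    ok = reference > 0
    if not ok.any():
        raise PreprocessError("reference spectrum has no positive points")
    quotients = X[:, ok] / reference[ok]
    factors = np.median(quotients, axis=1)
    if np.any(factors <= 0):
        bad = [block.sample_ids[i] for i in np.where(factors <= 0)[0]]
        raise PreprocessError(f"non-positive quotient median for sample(s): {bad}")
    out = replace(block, intensities=X / factors[:, None])
    if return_factors:
        return out, factors
    return out


def peak_pick(block: SpectralBlock, min_height: float, min_separation: int = 1) -> FeatureMatrix:
    """Pick local maxima of the mean spectrum as variables.

    Variables are mean-spectrum local maxima exceeding ``min_height`` and
    separated by at least ``min_separation`` points (the higher apex wins
    within a separation window).  Values are the per-sample intensities at the
    picked coordinates.
    """
    if min_separation < 1:
        raise PreprocessError("min_separation must be >= 1")
    mean_spec = block.intensities.mean(axis=0)
    peaks, _ = find_peaks(mean_spec, height=min_height, distance=min_separation)
    if peaks.size == 0:
        logger.warning("peak_pick: no peaks found above height %g", min_height)
    names = [f"{block.axis[i]:g}" for i in peaks]
    return FeatureMatrix(
        values=block.intensities[:, peaks],
        variable_names=names,
        modalities=["nmr"] * len(peaks),
        sample_ids=list(block.sample_ids),
        subject_ids=None if block.subject_ids is None else list(block.subject_ids),
    )


def autoscale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Center each column to mean 0 and scale to unit sample standard deviation.

    Zero-variance columns carry no information after centering and are dropped
    with a logged warning rather than raising.
    """
    if matrix.n_samples < 2:
        raise PreprocessError("autoscale needs >=2 samples")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [matrix.variable_names[j] for j in np.where(~keep)[0]]
        logger.warning("autoscale: dropping zero-variance variables %s", dropped)
    values = (matrix.values[:, keep] - mean[keep]) / sd[keep]
    return FeatureMatrix(
        values=values,
        variable_names=[v for v, k in zip(matrix.variable_names, keep) if k],
        modalities=[m for m, k in zip(matrix.modalities, keep) if k],
        sample_ids=list(matrix.sample_ids),
        subject_ids=None if matrix.subject_ids is None else list(matrix.subject_ids),
    )


def merge_blocks(blocks: Iterable[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of feature blocks aligned on sample ids.

    All blocks must cover exactly the same sample id set (order-insensitive;
    rows are aligned to the first block's order).  Variable names colliding
    across blocks are disambiguated with their modality prefix.
    """
    blocks = list(blocks)
    if not blocks:
        raise PreprocessError("merge_blocks needs at least one block")
    first = blocks[0]
    ref_ids = list(first.sample_ids)
    ref_set = set(ref_ids)
    aligned = [first]
    for b in blocks[1:]:
        if set(b.sample_ids) != ref_set:
            only_ref = sorted(ref_set - set(b.sample_ids))
            only_b = sorted(set(b.sample_ids) - ref_set)
            raise PreprocessError(
                f"sample_id mismatch: missing {only_ref} / unexpected {only_b}"
            )
        aligned.append(b.reorder_samples(ref_ids))
    names: list[str] = []
    modalities: list[str] = []
    seen: set[str] = set()
    for b in aligned:
        for v, m in zip(b.variable_names, b.modalities):
            name = v if v not in seen else MODALITY_PREFIX[m] + v
            if name in seen:  # same name and modality twice
                raise PreprocessError(f"duplicate variable {v!r} within modality {m}")
            names.append(name)
            modalities.append(m)
            seen.add(name)
    subject_ids = first.subject_ids
    return FeatureMatrix(
        values=np.hstack([b.values for b in aligned]) if names else np.empty((len(ref_ids), 0)),
        variable_names=names,
        modalities=modalities,
        sample_ids=ref_ids,
        subject_ids=None if subject_ids is None else list(subject_ids),
    )
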