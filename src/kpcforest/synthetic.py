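"""Seeded generator of study-like data with known ground truth.

The generator reproduces the statistical *shape* the analysis pipeline
assumes rather than spectral realism: four latent classes whose informative
variables differ through a non-linear (radial) map that no linear projection
separates, blocks of correlated decoy variables, subject-level random
effects, and a parallel nutrient table with planted metabolite-nutrient
co-occurrences that association mining should recover.

In the ``radial`` design the informative variables are split into two axis
blocks; a sample's class fixes a small or large radius on each block and the
values are drawn on the corresponding sphere shell.  All four classes share
a zero mean on every variable, so linear PCA quadrants cannot recover them,
while radial kernels can.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix

#: class-size imbalance of the motivating study, used as the default mix
DEFAULT_CLASS_PROPORTIONS = (73, 94, 96, 123)

RADIUS_SMALL = 0.3
RADIUS_LARGE = 2.7
#: axis A gets a larger radius contrast than axis B; unequal eigenvalue mass
#: keeps the two class contrasts from rotating into each other in KPCA
AXIS_ASYMMETRY = 1.4


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticStudy:
    features: FeatureMatrix  # metabolite + element block
    nutrients: FeatureMatrix
    true_classes: np.ndarray  # per sample, in {1, 2, 3, 4}
    informative: list[str]
    decoy_map: dict[str, str]  # decoy variable -> informative target
    planted_pairs: list[tuple[str, str]]  # (metabolite, nutrient)
    seed: int
    config: dict = field(default_factory=dict)


def _class_counts(n: int, proportions) -> np.ndarray:
    props = np.asarray(proportions, dtype=float)
    props = props / props.sum()
    counts = np.floor(props * n).astype(int)
    # hand out the remainder by largest fractional part (stable order)
    frac = props * n - counts
    for i in np.argsort(-frac, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    if counts.min() < 2:
        raise SyntheticError(f"infeasible config: class sizes {counts.tolist()} (<2)")
    return counts


def _sphere(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    if dim == 1:
        return rng.choice([-1.0, 1.0], size=(n, 1))
    g = rng.normal(size=(n, dim))
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def generate_study(
    n: int = 400,
    n_subjects: int = 8,
    p: int = 120,
    n_informative: int = 5,
    noise_sd: float = 0.15,
    nonlinearity: str = "radial",
    seed: int = 0,
    kernel_scale: float = 4.2,
    n_nutrients: int = 20,
    n_planted: Optional[int] = None,  # default: min(5, n_informative)
    n_decoys: Optional[int] = None,
    n_elements: int = 5,
    decoy_rho: float = 0.9,
    nutrient_rho: float = 0.9,
    subject_sd: float = 0.1,
    class_proportions=DEFAULT_CLASS_PROPORTIONS,
) -> SyntheticStudy:
    """Draw a complete synthetic study from ``seed``.

    Every random quantity comes from a single generator seeded with ``seed``,
    so outputs are byte-identical across calls with equal arguments.
    """
    if nonlinearity not in ("radial", "subject_clusters", "none"):
        raise SyntheticError(f"unknown nonlinearity {nonlinearity!r}")
    if n_informative > p:
        raise SyntheticError("n_informative must not exceed p")
    if n_subjects > n:
        raise SyntheticError("n_subjects must not exceed n")
    if nonlinearity in ("radial", "subject_clusters") and n_informative < 2:
        raise SyntheticError("radial designs need at least 2 informative variables")
    n_planted = min(5, n_informative) if n_planted is None else n_planted
    if n_planted > n_informative:
        raise SyntheticError("planted pairs must reference informative variables")
    n_decoys = n_informative if n_decoys is None else n_decoys
    n_noise = p - n_informative - n_decoys
    if n_noise < 0:
        raise SyntheticError("p too small for the requested informative + decoy variables")
    n_elements = min(n_elements, n_noise)

    rng = np.random.default_rng(seed)

    counts = _class_counts(n, class_proportions)
    classes = np.repeat(np.arange(1, 5), counts)
    classes = classes[rng.permutation(n)]

    subjects = rng.integers(0, n_subjects, size=n)
    subject_ids = [f"subj{s + 1:02d}" for s in subjects]
    sample_ids = [f"sample{i + 1:04d}" for i in range(n)]

    X = np.empty((n, p))
    inf_names = [f"met_inf{i + 1:02d}" for i in range(n_informative)]
    dec_names = [f"met_dec{i + 1:02d}" for i in range(n_decoys)]
    noise_names = [f"met_noise{i + 1:03d}" for i in range(n_noise - n_elements)] + [
        f"elem{i + 1:02d}" for i in range(n_elements)
    ]
    names = inf_names + dec_names + noise_names
    modalities = (
        ["nmr"] * (n_informative + n_decoys)
        + ["nmr"] * (n_noise - n_elements)
        + ["element"] * n_elements
    )

    if nonlinearity == "none":
        # linearly separable: each informative variable carries 4 class means
        means = (classes - 1)[:, None] * 2.0
        X[:, :n_informative] = means + rng.normal(
            scale=max(noise_sd, 1e-12), size=(n, n_informative)
        )
    else:
        dim_a = (n_informative + 1) // 2
        dim_b = n_informative - dim_a
        level_a = np.isin(classes, (3, 4)).astype(float)  # large radius on axis A
        level_b = np.isin(classes, (2, 4)).astype(float)  # large radius on axis B
        radius_a = np.where(level_a > 0, RADIUS_LARGE * AXIS_ASYMMETRY, RADIUS_SMALL)
        radius_b = np.where(level_b > 0, RADIUS_LARGE, RADIUS_SMALL)
        X[:, :dim_a] = radius_a[:, None] * _sphere(rng, n, dim_a)
        X[:, dim_a : dim_a + dim_b] = radius_b[:, None] * _sphere(rng, n, dim_b)
        X[:, :n_informative] += rng.normal(scale=noise_sd, size=(n, n_informative))

    noise_start = n_informative + n_decoys
    X[:, noise_start:] = rng.normal(size=(n, n_noise))

    # subject-level random effects over the metabolite/element block
    sd_subject = subject_sd * (15.0 if nonlinearity == "subject_clusters" else 1.0)
    offsets = rng.normal(scale=sd_subject, size=(n_subjects, p))
    X += offsets[subjects]

    # decoys: correlated copies of informative variables, built from the final
    # informative columns so the measured correlation meets its target
    decoy_map: dict[str, str] = {}
    for i in range(n_decoys):
        target = i % n_informative
        col = X[:, target]
        z = (col - col.mean()) / col.std()
        X[:, n_informative + i] = decoy_rho * z + np.sqrt(
            1 - decoy_rho**2
        ) * rng.normal(size=n)
        decoy_map[dec_names[i]] = inf_names[target]

    # standardize every column, then apply a single global scale chosen so
    # that the informative kernel bandwidth falls inside the published sigma
    # window (0.05-0.30); apply `autoscale` only when merging external blocks,
    # as it would undo this bandwidth convention
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd * kernel_scale

    features = FeatureMatrix(X, names, modalities, sample_ids, subject_ids)

    # nutrient table with planted co-occurrences on informative metabolites
    nutr_names = [f"nutr_planted{i + 1:02d}" for i in range(n_planted)] + [
        f"nutr{i + 1:02d}" for i in range(n_nutrients - n_planted)
    ]
    if n_nutrients < n_planted:
        raise SyntheticError("n_nutrients must cover the planted pairs")
    N = rng.normal(size=(n, n_nutrients))
    planted_pairs: list[tuple[str, str]] = []
    for i in range(n_planted):
        met = X[:, i]
        z = (met - met.mean()) / met.std()
        N[:, i] = nutrient_rho * z + np.sqrt(1 - nutrient_rho**2) * rng.normal(size=n)
        planted_pairs.append((inf_names[i], nutr_names[i]))
    nutrients = FeatureMatrix(
        N, nutr_names, ["nutrient"] * n_nutrients, sample_ids, subject_ids
    )

    # generation self-check: decoys must really be tightly correlated
    for dec, target in decoy_map.items():
        r = np.corrcoef(
            features.values[:, names.index(dec)],
            features.values[:, names.index(target)],
        )[0, 1]
        if abs(r) < 0.8:
            raise SyntheticError(
                f"decoy {dec} reached |r|={abs(r):.2f} < 0.8 against {target}"
            )

    return SyntheticStudy(
        features=features,
        nutrients=nutrients,
        true_classes=classes,
        informative=inf_names,
        decoy_map=decoy_map,
        planted_pairs=planted_pairs,
        seed=seed,
        config={
            "n": n,
            "n_subjects": n_subjects,
            "p": p,
            "n_informative": n_informative,
            "noise_sd": noise_sd,
            "nonlinearity": nonlinearity,
            "kernel_scale": kernel_scale,
            "n_nutrients": n_nutrients,
            "n_planted": n_planted,
            "n_decoys": n_decoys,
            "decoy_rho": decoy_rho,
            "nutrient_rho": nutrient_rho,
            "subject_sd": subject_sd,
            "class_proportions": list(class_proportions),
        },
    )


def truth_report(study: SyntheticStudy) -> pd.DataFrame:
    """Machine-readable ground truth: informative variables, decoy targets,
    planted metabolite-nutrient pairs and true classes."""
    rows = [{"kind": "informative", "name": v, "target": ""} for v in study.informative]
    rows += [
        {"kind": "decoy", "name": d, "target": t} for d, t in study.decoy_map.items()
    ]
    rows += [
        {"kind": "planted_pair", "name": m, "target": u}
        for m, u in study.planted_pairs
    ]
    rows += [
        {"kind": "class", "name": sid, "target": str(c)}
        for sid, c in zip(study.features.sample_ids, study.true_classes)
    ]
    return pd.DataFrame(rows, columns=["kind", "name", "target"])


def write_study(study: SyntheticStudy, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": out / "features.tsv",
        "nutrients": out / "nutrients.tsv",
        "truth": out / "truth.tsv",
    }
    study.features.write_tsv(paths["features"])
    study.nutrients.write_tsv(paths["nutrients"])
    truth_report(study).to_csv(paths["truth"], sep="\t", index=False)
    return paths
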