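"""End-to-end pipeline: preprocess -> KPCA -> quadrant labels -> forest
importance (+ LOOCV) -> Kruskal-Wallis on top variables -> association rules
-> network export.

Every stage writes its artifact into the run directory before the next stage
starts, so a failed run keeps the completed intermediates.  Reruns with the
same config and seed reproduce all files.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .assoc import (
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_CONFIDENCE,
    DEFAULT_MIN_LIFT,
    DEFAULT_MIN_SUPPORT,
    discretize,
    export_network,
    mine_rules,
)
from .importance import ForestConfig, conditional_importance, fit_forest, loocv, rank_report
from .kernels import KernelSpec
from .kpca import (
    DEFAULT_QUADRANT_MAP,
    default_sigma_grid,
    kpca_fit,
    pick_sigma,
    quadrant_labels,
    scan_sigma,
)
from .preprocess import FeatureMatrix, autoscale, merge_blocks
from .stats import kw_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    features: Optional[str] = None  # path to the feature table TSV
    nutrients: Optional[str] = None  # optional nutrient table TSV
    out_dir: str = "run"
    autoscale: bool = True
    kernel_family: str = "anova"
    sigma: float = 0.135  # published preset; ignored when scan_sigma is true
    degree: int = 1
    scan_sigma: bool = False
    sigma_min: float = 0.05
    sigma_max: float = 0.30
    sigma_steps: int = 11
    n_components: int = 2
    quadrant_map: Optional[dict] = None
    labels_file: Optional[str] = None  # hand-made labels override
    ntree: int = 80
    mtry: Optional[int] = None
    min_node_size: int = 2
    corr_threshold: float = 0.2
    seed: int = 0
    run_loocv: bool = True
    top: int = 100
    min_support: float = DEFAULT_MIN_SUPPORT
    min_confidence: float = DEFAULT_MIN_CONFIDENCE
    min_lift: float = DEFAULT_MIN_LIFT
    max_itemset: int = DEFAULT_MAX_LEN
    discretize_scheme: str = "median"

    def validate(self) -> None:
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must be in (0, 1]")
        if not 0 < self.min_confidence <= 1:
            raise ValueError("min_confidence must be in (0, 1]")
        if self.min_lift <= 0:
            raise ValueError("min_lift must be positive")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2 for quadrant labels")
        if self.sigma <= 0 or self.sigma_min <= 0 or self.sigma_max < self.sigma_min:
            raise ValueError("sigma values must be positive with max >= min")
        if self.ntree < 1 or self.top < 1:
            raise ValueError("ntree and top must be >= 1")
        KernelSpec(self.kernel_family, self.sigma, self.degree)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.quadrant_map is not None:
            cfg.quadrant_map = {
                tuple(int(v) for v in k.split(",")): int(c)
                for k, c in cfg.quadrant_map.items()
            }
        return cfg

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        if raw["quadrant_map"] is not None:
            raw["quadrant_map"] = {
                ",".join(str(v) for v in k): c for k, c in raw["quadrant_map"].items()
            }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def config_hash(self) -> str:
        raw = asdict(self)
        if raw["quadrant_map"] is not None:
            raw["quadrant_map"] = sorted(
                (list(k), v) for k, v in raw["quadrant_map"].items()
            )
        return hashlib.sha256(
            yaml.safe_dump(raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    features: Optional[FeatureMatrix] = None,
    nutrients: Optional[FeatureMatrix] = None,
) -> Path:
    """Execute all stages; returns the run directory.

    ``features``/``nutrients`` may be passed in memory; otherwise they are
    read from the paths in the config.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("kpcforest")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info(
            "kpcforest %s | seed=%d | config_hash=%s",
            __version__, config.seed, config.config_hash(),
        )
        config.to_yaml(out / "config.yaml")

        stage = "load"
        try:
            if features is None:
                features = FeatureMatrix.read_tsv(config.features)
            if nutrients is None and config.nutrients:
                nutrients = FeatureMatrix.read_tsv(
                    config.nutrients, default_modality="nutrient"
                )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "preprocess"
        try:
            matrix = autoscale(features) if config.autoscale else features
            matrix.write_tsv(out / "matrix.tsv")
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "kpca"
        try:
            sigma = config.sigma
            if config.scan_sigma:
                grid = default_sigma_grid(
                    config.sigma_min, config.sigma_max, config.sigma_steps
                )
                scan = scan_sigma(matrix, grid, config.degree, config.n_components,
                                  family=config.kernel_family)
                scan.to_csv(out / "sigma_scan.tsv", sep="\t", index=False)
                sigma = pick_sigma(scan)
                logger.info("sigma scan selected sigma=%g", sigma)
            spec = KernelSpec(config.kernel_family, sigma, config.degree)
            model = kpca_fit(matrix, spec, config.n_components)
            model.scores_frame().to_csv(out / "scores.tsv", sep="\t", index=False)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "labels"
        try:
            if config.labels_file:
                import pandas as pd

                df = pd.read_csv(config.labels_file, sep="\t")
                from .kpca import QuadrantLabeling

                df = df.set_index("sample_id").loc[matrix.sample_ids]
                labels = QuadrantLabeling(
                    classes=df["class"].to_numpy(int),
                    mapping=dict(DEFAULT_QUADRANT_MAP),
                    sample_ids=list(matrix.sample_ids),
                )
            else:
                labels = quadrant_labels(model, mapping=config.quadrant_map)
            labels.to_frame(model).to_csv(out / "labels.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        forest_config = ForestConfig(
            ntree=config.ntree,
            mtry=config.mtry,
            min_node_size=config.min_node_size,
            corr_threshold=config.corr_threshold,
            seed=config.seed,
        )

        stage = "importance"
        try:
            model_forest = fit_forest(matrix, labels, forest_config)
            imp = conditional_importance(model_forest)
            imp.to_csv(out / "importance.tsv", sep="\t", index=False)
            top = rank_report(imp, config.top)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        if config.run_loocv:
            stage = "loocv"
            try:
                report = loocv(matrix, labels, forest_config)
                with open(out / "loocv.tsv", "w") as fh:
                    fh.write(f"accuracy\t{report.accuracy:.6f}\n")
                report.to_frame().to_csv(
                    out / "confusion.tsv", sep="\t"
                )
            except Exception as exc:
                raise PipelineError(stage, exc) from exc

        stage = "kruskal_wallis"
        try:
            kw = kw_table(matrix, labels, variables=list(top["variable"]))
            kw.to_csv(out / "kw.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "mba"
        try:
            mba_matrix = matrix.select(list(top["variable"]))
            if nutrients is not None:
                mba_matrix = merge_blocks([mba_matrix, nutrients])
            transactions = discretize(mba_matrix, scheme=config.discretize_scheme)
            rules = mine_rules(
                transactions,
                min_support=config.min_support,
                min_confidence=config.min_confidence,
                min_lift=config.min_lift,
                max_len=config.max_itemset,
            )
            transactions.write_baskets(out / "baskets.tsv")
            rules.write_tsv(out / "rules.tsv")
            if len(rules):
                export_network(rules, out / "network")
            else:
                logger.warning("no rules passed the thresholds; network not written")
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        logger.info("pipeline complete: %s", out)
        return out
    finally:
        root.removeHandler(handler)
        handler.close()
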