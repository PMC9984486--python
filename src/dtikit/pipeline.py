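"""One-command orchestration: build -> select -> train -> evaluate.

The pipeline reads the four standard inputs (FASTA, PSSM directory,
fingerprint table, interaction list), assembles the labeled pair
matrix for the chosen combination mode, optionally runs IWSSR feature
selection, trains the rotation forest and evaluates with either a
stratified train/independent split (default) or k-fold cross-validation
with selection nested inside each fold.  Every stage writes its
artifact into the output directory and logs its shapes and timing.
"""

from __future__ import annotations

import json
import logging
import pickle
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from dtikit.evaluation import (
    EvaluationReport,
    evaluate_split,
    independent_split,
    kfold_cv,
)
from dtikit.feature_selection import iwssr_select, rank_features
from dtikit.io_formats import (
    read_fasta,
    read_fingerprints,
    read_interactions,
    read_pssm,
    write_feature_matrix,
)
from dtikit.pair_assembly import CombinationMode, LabeledPairSet, build_pairs
from dtikit.protein_encoders import EncoderConfig
from dtikit.pssm_features import PsePSSMConfig
from dtikit.rotation_forest import RotationForest, RotationForestConfig
from dtikit.synthetic_data import SyntheticDataset

logger = logging.getLogger(__name__)

VALID_MODES = ("A", "B", "C", "MODE_A", "MODE_B", "MODE_C")
VALID_PROTOCOLS = ("split", "kfold")


@dataclass
class PipelineConfig:
    """Flat key-value pipeline configuration; every key mirrors a CLI flag."""

    fasta: str | None = None
    pssm_dir: str | None = None
    fingerprints: str | None = None
    interactions: str | None = None
    mode: str = "A"
    neg_ratio: float = 1.0
    fixed_length: int = 100
    select: bool = True
    bins: int = 5
    max_rank: int | None = None
    trees: int = 35
    subset_size: int = 3
    protocol: str = "split"
    k: int = 10
    train_fraction: float = 0.9
    seed: int = 0
    out_dir: str = "dti_out"
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.mode.upper() not in VALID_MODES:
            raise ValueError(f"unknown combination mode {self.mode!r}; choose A, B or C")
        if self.protocol not in VALID_PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}; choose split or kfold")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(fixed_length=self.fixed_length)

    def rf_config(self) -> RotationForestConfig:
        return RotationForestConfig(
            n_trees=self.trees, subset_size=self.subset_size, seed=self.seed
        )


def load_inputs(config: PipelineConfig):
    """Read the four standard inputs named by the configuration."""
    for key in ("fasta", "fingerprints", "interactions"):
        if getattr(config, key) is None:
            raise ValueError(f"pipeline config is missing the {key!r} input path")
    proteins = read_fasta(config.fasta)
    drugs = read_fingerprints(config.fingerprints)
    interactions = read_interactions(config.interactions)
    pssms = {}
    if config.pssm_dir:
        for path in sorted(Path(config.pssm_dir).glob("*.pssm")):
            pssm = read_pssm(path)
            pssms[pssm.protein_id] = pssm
    return proteins, drugs, pssms, interactions


def build_stage(config: PipelineConfig, dataset: SyntheticDataset | None = None) -> LabeledPairSet:
    """Assemble the labeled pair matrix (from files or an in-memory dataset)."""
    if dataset is not None:
        proteins, drugs, pssms, interactions = (
            dataset.proteins,
            dataset.drugs,
            dataset.pssms,
            dataset.interactions,
        )
    else:
        proteins, drugs, pssms, interactions = load_inputs(config)
    return build_pairs(
        proteins,
        drugs,
        interactions,
        pssms=pssms,
        mode=CombinationMode.from_name(config.mode),
        neg_ratio=config.neg_ratio,
        seed=config.seed,
        config=config.encoder_config(),
        psepssm_config=PsePSSMConfig(),
    )


def run_pipeline(
    config: PipelineConfig, dataset: SyntheticDataset | None = None
) -> EvaluationReport:
    """Execute build -> select -> train -> evaluate and write all artifacts.

    With the default "split" protocol, features are selected on the 90%
    train part and metrics are reported on the 10% independent part;
    with "kfold", selection and fitting are nested inside each of the k
    training folds and pooled out-of-fold metrics are reported.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    pairset = build_stage(config, dataset)
    logger.info(
        "build: %d pairs x %d features (%d positives) in %.1fs",
        len(pairset), pairset.X.shape[1], int(pairset.y.sum()), time.time() - t0,
    )
    write_feature_matrix(
        pairset.X,
        pairset.feature_names,
        [f"{d}|{p}" for d, p in pairset.pair_ids],
        pairset.y,
        out / "matrix.csv",
    )

    rf_config = config.rf_config()
    if config.protocol == "kfold":
        report = kfold_cv(
            pairset,
            k=config.k,
            seed=config.seed,
            rf_config=rf_config,
            select=config.select,
            bins=config.bins,
            max_rank=config.max_rank,
        )
        selection_artifact = {"nested": True, "n_selected": report.n_selected}
    else:
        train, indep = independent_split(pairset, config.train_fraction, config.seed)
        cols = np.arange(pairset.X.shape[1])
        selection_artifact: dict[str, Any] = {"nested": False}
        if config.select:
            t1 = time.time()
            weights = rank_features(train.X, train.y, config.bins)
            result = iwssr_select(
                train.X, train.y, seed=config.seed,
                bins=config.bins, max_rank=config.max_rank,
            )
            cols = np.array(sorted(result.selected))
            selection_artifact.update(
                selected_indices=[int(i) for i in cols],
                selected_names=[pairset.feature_names[i] for i in cols],
                su_weights={
                    pairset.feature_names[int(j)]: float(weights.values[int(j)])
                    for j in weights.ranking[:50]
                },
                best_score=result.best_score,
                trace=[(int(f), a, float(s)) for f, a, s in result.trace if a != "reject"],
            )
            logger.info(
                "select: %d features, inner accuracy %.3f in %.1fs",
                len(cols), result.best_score, time.time() - t1,
            )
            if config.verbose:
                head = [pairset.feature_names[int(j)] for j in weights.ranking[:10]]
                logger.info("select: top-ranked features %s", head)
        train_sel = train.select_columns(cols)
        indep_sel = indep.select_columns(cols)
        t2 = time.time()
        forest = RotationForest(rf_config).fit(train_sel.X, train_sel.y)
        with open(out / "model.pkl", "wb") as fh:
            pickle.dump(forest.model_, fh)
        logger.info("train: %d trees in %.1fs", rf_config.n_trees, time.time() - t2)
        report = evaluate_split(train_sel, indep_sel, seed=config.seed, rf_config=rf_config)
        report.n_selected = len(cols)

    with open(out / "selected.json", "w") as fh:
        json.dump(selection_artifact, fh, indent=2)
    report_dict = report.as_dict()
    report_dict["config"] = asdict(config)
    with open(out / "report.json", "w") as fh:
        json.dump(report_dict, fh, indent=2)
    with open(out / "roc.csv", "w") as fh:
        fh.write("fpr,tpr\n")
        for fpr, tpr in report.roc_points:
            fh.write(f"{fpr:.6g},{tpr:.6g}\n")
    logger.info(
        "eval(%s): Acc=%.3f Sen=%.3f Sp=%.3f Pre=%.3f MCC=%.3f AUC=%.3f",
        config.protocol, report.Acc, report.Sen, report.Sp, report.Pre,
        report.MCC, report.AUC,
    )
    return report
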