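"""End-to-end analysis driver: slide -> GPA -> PCA -> predictors -> ANN.

`run_pipeline` executes the full study protocol on a cohort (synthetic by
default): per tooth, sliding-semilandmark relaxation against the sample
Procrustes mean, generalized Procrustes superimposition, shape PCA fitted on
the training partition, assembly of the predictor table (30 PC scores + log
centroid size per tooth), a set-aside split with exact per-class counts,
k-fold cross-validated hyperparameter selection, final training, and the
confusion-matrix panel on the held-out test partition.  A manifest records
seeds, sizes and stage hashes so runs are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as cm_io
from .ann import (
    AnnModel,
    CvResult,
    SplitPlan,
    cross_validate,
    predict_sex,
    predictor_importance,
    set_aside_split,
    train_ann,
)
from .errors import CurveClampWarning, InvalidInputError
from .evaluation import (
    ClassificationReport,
    ConfusionMatrix,
    RepeatabilityReport,
    RocCurve,
    centroid_size_dimorphism_test,
    classification_report,
    repeatability,
    roc_auc,
)
from .procrustes import AlignedSample, generalized_procrustes
from .shape_space import PredictorTable, ShapePca, assemble_predictors, shape_pca
from .simulate import Cohort, DimorphismSpec, generate_cohort, generate_repeat_round
from .sliding import slide_semilandmarks
from .tps import bending_energy_matrix
from .types import LandmarkConfiguration, Tooth


@dataclass
class RunConfig:
    """Configuration of one pipeline run (all randomness is explicit)."""

    synthetic: DimorphismSpec = field(default_factory=DimorphismSpec)
    slide_cycles: int = 6
    slide_reference: str = "mean_refresh"  # "mean", "mean_refresh" or "none"
    n_components: int = 30
    grid: Sequence[Tuple[int, float]] = ((3, 0.05), (3, 0.1))
    cv_k: int = 10
    epochs: int = 500
    tune_epochs: int = 200
    learning_rate: float = 0.05
    batch_size: int = 8
    train_counts: Dict[str, int] = field(default_factory=lambda: {"F": 84, "M": 90})
    standardize: bool = True
    pca_train_only: bool = True
    repeat_round_size: int = 30
    seed: int = 0
    outdir: Optional[str] = None

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        doc["synthetic"]["teeth"] = [t.value for t in self.synthetic.teeth]
        doc["grid"] = [list(g) for g in self.grid]
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)
        syn = doc.pop("synthetic", {})
        cfg = cls(synthetic=DimorphismSpec(**syn), **doc)
        cfg.grid = [tuple(g) for g in cfg.grid]
        return cfg


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: Cohort
    aligned: Dict[Tooth, AlignedSample]
    pcas: Dict[Tooth, ShapePca]
    predictors: PredictorTable
    split: SplitPlan
    cv: CvResult
    model: AnnModel
    train_report: ClassificationReport
    test_report: ClassificationReport
    roc: RocCurve
    importance: pd.Series
    size_tests: Dict[Tooth, Tuple[float, float]]
    repeatability: Dict[Tooth, RepeatabilityReport]
    manifest: Dict
    warnings: List[str]


def _subset(sample: AlignedSample, ids: Sequence[str]) -> AlignedSample:
    index = {s: i for i, s in enumerate(sample.specimen_ids)}
    rows = [index[s] for s in ids]
    return replace(
        sample,
        specimen_ids=list(ids),
        aligned=sample.aligned[rows],
        centroid_sizes=sample.centroid_sizes[rows],
    )


def _mean_config(sample: AlignedSample, tooth: Tooth, proto: LandmarkConfiguration):
    return proto.with_points(sample.mean_shape)


def _slide_tooth(
    configs: List[LandmarkConfiguration],
    geometries: Dict[str, object],
    n_cycles: int,
    refresh: bool,
) -> List[LandmarkConfiguration]:
    """Slide every specimen against the sample Procrustes mean; optionally
    refresh the mean once from the slid sample and slide again."""
    mean_cfg = _mean_config(generalized_procrustes(configs), configs[0].tooth, configs[0])
    passes = 2 if refresh else 1
    out = configs
    for _ in range(passes):
        lmat = bending_energy_matrix(mean_cfg.points)
        out = [
            slide_semilandmarks(
                cfg, mean_cfg, geometries[cfg.specimen_id], n_cycles=n_cycles,
                l_matrix=lmat,
            )
            for cfg in out
        ]
        mean_cfg = _mean_config(generalized_procrustes(out), configs[0].tooth, configs[0])
    return out


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.round(np.asarray(arr, dtype=float), 10).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, cohort: Optional[Cohort] = None) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the stages."""
    seed = int(config.seed)
    if cohort is None:
        cohort = generate_cohort(config.synthetic)
    labels = cohort.labels()
    teeth = list(cohort.spec.teeth)
    collected: List[str] = []

    # --- sliding + superimposition per tooth -------------------------------
    aligned: Dict[Tooth, AlignedSample] = {}
    for tooth in teeth:
        configs = cohort.configs_for(tooth)
        if config.slide_cycles > 0 and config.slide_reference != "none":
            geoms = {sp.specimen_id: sp.geometries.get(tooth) for sp in cohort.specimens}
            if any(g is None for g in geoms.values()):
                raise InvalidInputError(
                    f"sliding requested but tooth {tooth} lacks specimen geometry"
                )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", CurveClampWarning)
                configs = _slide_tooth(
                    configs, geoms, config.slide_cycles,
                    refresh=config.slide_reference == "mean_refresh",
                )
            collected.extend(str(w.message) for w in caught)
        aligned[tooth] = generalized_procrustes(configs)

    # --- centroid-size dimorphism tests ------------------------------------
    size_tests = {
        tooth: centroid_size_dimorphism_test(
            aligned[tooth].centroid_sizes,
            [labels[s] for s in aligned[tooth].specimen_ids],
        )
        for tooth in teeth
    }

    # --- split, PCA (training only), predictors ----------------------------
    split = set_aside_split(labels, config.train_counts, seed=(seed * 9176 + 11) % 2**31)
    pcas = {
        tooth: shape_pca(
            _subset(aligned[tooth], split.train_ids) if config.pca_train_only else aligned[tooth],
            n_components=config.n_components,
        )
        for tooth in teeth
    }
    predictors = assemble_predictors(pcas, aligned, labels=labels)
    train_table = PredictorTable(
        predictors.table.loc[split.train_ids], predictors.labels.loc[split.train_ids]
    )
    test_table = PredictorTable(
        predictors.table.loc[split.test_ids], predictors.labels.loc[split.test_ids]
    )
    if config.standardize:
        mu, sd = train_table.table.mean(), train_table.table.std(ddof=1)
        train_table = train_table.standardized(mu, sd)
        test_table = test_table.standardized(mu, sd)

    # --- tune, train, evaluate ---------------------------------------------
    cv = cross_validate(
        train_table,
        train_table.labels.to_numpy(),
        grid=config.grid,
        k=config.cv_k,
        seed=(seed * 7351 + 29) % 2**31,
        epochs=config.tune_epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
    )
    model = train_ann(
        train_table,
        train_table.labels.to_numpy(),
        hidden=cv.selected["hidden"],
        decay=cv.selected["decay"],
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        seed=(seed * 4799 + 97) % 2**31,
    )
    proba_tr, pred_tr = predict_sex(model, train_table)
    proba_te, pred_te = predict_sex(model, test_table)
    train_report = classification_report(
        ConfusionMatrix.from_predictions(train_table.labels.to_numpy(), pred_tr)
    )
    test_report = classification_report(
        ConfusionMatrix.from_predictions(test_table.labels.to_numpy(), pred_te)
    )
    roc = roc_auc(proba_te, test_table.labels.to_numpy())
    importance = predictor_importance(model)

    # --- repeatability on a second digitization round ----------------------
    rep: Dict[Tooth, RepeatabilityReport] = {}
    if config.repeat_round_size > 0 and all(sp.geometries for sp in cohort.specimens):
        rng = np.random.default_rng((seed * 6007 + 3) % 2**31)
        k = min(config.repeat_round_size, len(cohort.specimens))
        chosen = [cohort.specimen_ids[i] for i in sorted(rng.choice(len(cohort.specimens), k, replace=False))]
        round2 = generate_repeat_round(
            cohort, cohort.spec.digitization_sd, seed=(seed * 2713 + 5) % 2**31,
            specimen_ids=chosen,
        )
        for tooth in teeth:
            r1 = generalized_procrustes(
                [sp.configs[tooth] for sp in cohort.specimens if sp.specimen_id in set(chosen)]
            )
            r2 = generalized_procrustes([round2[s][tooth] for s in chosen])
            rep[tooth] = repeatability(r1, r2)

    manifest = {
        "seed": seed,
        "teeth": [t.value for t in teeth],
        "n_specimens": len(cohort.specimens),
        "shape_effect": cohort.shape_effect,
        "n_predictors": predictors.n_predictors,
        "train_counts": split.train_counts,
        "test_counts": split.test_counts,
        "selected_hidden": cv.selected["hidden"],
        "selected_decay": cv.selected["decay"],
        "cv_accuracy": float(cv.mean_accuracy[cv.selected_index]),
        "train_accuracy": train_report.accuracy,
        "test_accuracy": test_report.accuracy,
        "test_auc": roc.auc,
        "p_acc_gt_nir": test_report.p_acc_gt_nir,
        "significant_above_nir": bool(test_report.p_acc_gt_nir < 0.05),
        "size_test_p": {t.value: p for t, (_, p) in size_tests.items()},
        "stage_hashes": {
            f"aligned_{t.value}": _hash(aligned[t].aligned) for t in teeth
        } | {"predictors": _hash(predictors.matrix()), "weights": _hash(model.w1)},
        "n_warnings": len(collected),
    }
    if rep:
        manifest["repeatability_error_fraction"] = {
            t.value: r.error_variance_fraction for t, r in rep.items()
        }

    result = PipelineResult(
        config=config,
        cohort=cohort,
        aligned=aligned,
        pcas=pcas,
        predictors=predictors,
        split=split,
        cv=cv,
        model=model,
        train_report=train_report,
        test_report=test_report,
        roc=roc,
        importance=importance,
        size_tests=size_tests,
        repeatability=rep,
        manifest=manifest,
        warnings=collected,
    )
    if config.outdir:
        _persist(result, Path(config.outdir))
    return result


def _persist(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for tooth, sample in result.aligned.items():
        cm_io.write_aligned_csv(sample, outdir / f"aligned_{tooth.value}.csv")
        (outdir / f"pca_{tooth.value}.json").write_text(result.pcas[tooth].to_json())
    result.predictors.table.to_csv(outdir / "predictors.csv")
    cm_io.write_roc_csv(result.roc, outdir / "roc.csv")
    (outdir / "test_report.json").write_text(result.test_report.to_json())
    (outdir / "train_report.json").write_text(result.train_report.to_json())
    result.importance.to_csv(outdir / "predictor_importance.csv", header=["importance"])
    cm_io.write_json(result.manifest, outdir / "manifest.json")
    (outdir / "config.json").write_text(result.config.to_json())
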