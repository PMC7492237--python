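"""End-to-end orchestration: pre-train, adapt, fine-tune, evaluate, rank.

``TransferPipeline`` wires the three training stages together for one of the
transfer modes:

* ``multi_stage`` — source pre-training, autoencoder adaptation, fine-tuning
  (the proposed framework);
* ``single_stage`` — source pre-training transferred directly to fine-tuning;
* ``no_transfer`` — fine-tuning from random initialization only.

Stages 1-2 never see target data, so they are trained once; inside
cross-validation only stage 3 (and every target-side preprocessing
transform) is refitted per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import CVSummary, cross_validate
from .features import ClinicalTransform, SubjectRecord, site_normalize
from .network import WeightSet, default_architectures, forward
from .saliency import SaliencyRanking, saliency_map
from .training import (
    STAGE2_DEFAULTS,
    STAGE3_DEFAULTS,
    TaskWeights,
    TrainingConfig,
    TrainingTrace,
    stacked_inputs,
    train_stage1,
    train_stage2,
    train_stage3,
)

__all__ = ["PipelineConfig", "TransferPipeline", "FittedStage3"]

MODES = ("multi_stage", "single_stage", "no_transfer")


@dataclass
class PipelineConfig:
    """Architecture widths, transfer mode, and per-stage training settings."""

    n_input: int
    task_count: int = 3
    mode: str = "multi_stage"
    widths: tuple[int, int, int, int] = (1024, 256, 64, 32)
    head_hidden_per_task: int = 16
    use_clinical: bool = False
    clinical_width: int = 0
    use_beta: bool = True
    alpha: np.ndarray | None = None
    seed: int = 0
    # exclude transferred layers from stage-3 gradient updates (feature-
    # extraction transfer); the fully fine-tuned default trains all layers
    freeze_transferred: bool = False
    stage1: TrainingConfig = field(default_factory=TrainingConfig)
    stage2: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(**STAGE2_DEFAULTS)
    )
    stage3: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(**STAGE3_DEFAULTS)
    )
    normalize_source_sites: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class FittedStage3:
    """A fine-tuned model bundle: weights plus the fold-fitted transforms."""

    weights: WeightSet
    arch: object
    clinical_transform: ClinicalTransform | None
    task_names: list[str]
    trace: TrainingTrace


class TransferPipeline:
    """Train the staged networks and evaluate them on the target cohort."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        cw = config.clinical_width if config.use_clinical else 0
        self.archs = default_architectures(
            config.n_input,
            widths=config.widths,
            task_count=config.task_count,
            clinical_width=cw,
            head_hidden_per_task=config.head_hidden_per_task,
        )
        if config.freeze_transferred:
            from .network import TransferMap

            for key in ("map_s2_to_s3", "map_s1_to_s3"):
                m = self.archs[key]
                self.archs[key] = TransferMap(
                    m.pairs, frozenset(d for _, d in m.pairs)
                )
        self.w_s1: WeightSet | None = None
        self.w_s2: WeightSet | None = None
        self.traces: dict[str, TrainingTrace] = {}

    # -- stages 1-2 (non-target data; trained once) -------------------------

    def pretrain(
        self,
        source: list[SubjectRecord] | None,
        intermediate: list[SubjectRecord] | None,
    ) -> None:
        cfg = self.config
        if cfg.mode == "no_transfer":
            return
        if source is None:
            raise ValueError("transfer modes require a source cohort")
        if cfg.normalize_source_sites:
            source = site_normalize(source)
        s1_cfg = replace(cfg.stage1, seed=cfg.seed * 4 + 1)
        self.w_s1, self.traces["stage1"] = train_stage1(
            source, self.archs["stage1"], s1_cfg
        )
        if cfg.mode == "multi_stage":
            if intermediate is None:
                raise ValueError("multi_stage requires an intermediate cohort")
            s2_cfg = replace(cfg.stage2, seed=cfg.seed * 4 + 2)
            self.w_s2, self.traces["stage2"] = train_stage2(
                intermediate, self.w_s1, self.archs["stage2"],
                self.archs["map_s1_to_s2"], s2_cfg,
            )

    # -- stage 3 (target data; refit per CV fold) ---------------------------

    def _stage3_init(self):
        cfg = self.config
        if cfg.mode == "multi_stage":
            return self.w_s2, self.archs["map_s2_to_s3"]
        if cfg.mode == "single_stage":
            return self.w_s1, self.archs["map_s1_to_s3"]
        return None, None

    def fit_stage3(
        self, train_records: list[SubjectRecord], seed: int,
        clinical_table=None, clinical_dictionary=None,
    ) -> FittedStage3:
        cfg = self.config
        w_init, tmap = self._stage3_init()
        if cfg.mode != "no_transfer" and w_init is None:
            raise ValueError("pretrain() must run before fine-tuning")
        tf = None
        records = train_records
        if cfg.use_clinical:
            if clinical_table is None or clinical_dictionary is None:
                raise ValueError("clinical fusion needs the table and dictionary")
            ids = [r.subject_id for r in train_records]
            tf = ClinicalTransform(clinical_dictionary).fit(clinical_table.loc[ids])
            enc = tf.transform(clinical_table.loc[ids])
            records = [
                replace_clinical(r, enc[i]) for i, r in enumerate(train_records)
            ]
        task_names = sorted(train_records[0].labels.keys())
        s3_cfg = replace(cfg.stage3, seed=seed)
        tw = TaskWeights(alpha=cfg.alpha, use_beta=cfg.use_beta)
        w, trace = train_stage3(
            records, w_init, self.archs["stage3"], tmap, s3_cfg, tw, task_names
        )
        return FittedStage3(w, self.archs["stage3"], tf, task_names, trace)

    def predict(
        self, model: FittedStage3, records: list[SubjectRecord], clinical_table=None
    ) -> np.ndarray:
        X = stacked_inputs(records)
        clin = None
        if self.config.use_clinical:
            ids = [r.subject_id for r in records]
            clin = model.clinical_transform.transform(clinical_table.loc[ids])
        return np.atleast_2d(
            forward(model.weights, model.arch, X, clin, mode="eval")
        )

    # -- evaluation ---------------------------------------------------------

    def cross_validate_target(
        self,
        target: list[SubjectRecord],
        k: int = 5,
        iterations: int = 50,
        seed: int = 0,
        clinical_table=None,
        clinical_dictionary=None,
        permute_labels: bool = False,
        **cv_kwargs,
    ) -> CVSummary:
        records = target
        if permute_labels:
            rng = np.random.default_rng(seed)
            task_names = sorted(target[0].labels.keys())
            perm = {t: rng.permutation(len(target)) for t in task_names}
            records = [
                SubjectRecord(
                    r.subject_id, r.site, r.cohort, r.connectome, r.clinical,
                    {t: target[perm[t][i]].labels[t] for t in task_names},
                )
                for i, r in enumerate(target)
            ]
        task_names = sorted(records[0].labels.keys())

        def fit_fn(train_records, fold_seed):
            return self.fit_stage3(
                train_records, fold_seed, clinical_table, clinical_dictionary
            )

        def predict_fn(model, test_records):
            return self.predict(model, test_records, clinical_table)

        return cross_validate(
            records, fit_fn, predict_fn, task_names,
            k=k, iterations=iterations, seed=seed, **cv_kwargs,
        )

    def saliency(
        self, model: FittedStage3, records: list[SubjectRecord],
        clinical_table=None, roi_names=None,
    ) -> dict[str, SaliencyRanking]:
        X = np.vstack([r.connectome for r in records])
        clin = None
        if self.config.use_clinical:
            ids = [r.subject_id for r in records]
            clin = model.clinical_transform.transform(clinical_table.loc[ids])
        return {
            name: saliency_map(
                model.weights, model.arch, X, clin, c,
                task_name=name, roi_names=roi_names,
            )
            for c, name in enumerate(model.task_names)
        }


def replace_clinical(r: SubjectRecord, clinical: np.ndarray) -> SubjectRecord:
    return SubjectRecord(
        r.subject_id, r.site, r.cohort, r.connectome, clinical, r.labels
    )
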