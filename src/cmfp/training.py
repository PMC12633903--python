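"""The repeated-resplit training protocol and the best-model archive.

Training runs a fixed number of *epochs* (default 120). Each epoch:

1. re-partitions the non-test patients into training and validation rows
   (train:val = 2:1, mirroring the 60/30 of the 60/30/10 protocol);
2. runs lasso feature selection per modality on the training rows only;
3. fits one boosted-stump classifier per modality;
4. predicts the validation rows to get each modality's (rho, eta, phi)
   triplet and fuses the pair through the CMF rule;
5. records the per-modality validation accuracies and the fused accuracy.

After the loop the archive keeps, per modality, the model with the highest
validation accuracy (``Ms``, earliest epoch on ties) and the fusion
configuration from the epoch with the highest fused validation accuracy
(``Mc``). At test time each ``Ms`` predicts the held-out test rows, its
*archived* validation accuracy stands in for phi (test accuracy is unknown
at prediction time), and the triplets flow through ``Mc``.

The 10% test set is carved out once, before the loop, and never enters
any epoch's training or validation rows (``fixed_test=True``, the
default). The literal fully-repartitioning variant — where all three sets
are redrawn every epoch — is available with ``fixed_test=False`` for
fidelity experiments, at the cost of test information leaking into model
selection.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cohort import MultimodalCohort, split_cohort
from .fusion import FusionParams, FusedPrediction, fuse_batch
from .learners import ModalModel, SingleModalPrediction, predict_modal, train_modal_learner
from .metrics import MetricsReport, evaluate_predictions
from .selection import SelectedFeatures, select_with_fallback

__all__ = [
    "TrainConfig",
    "EpochResult",
    "ModelArchive",
    "epoch_seed",
    "run_epoch",
    "fit_cmfp",
    "test_cmfp",
]

_DEFAULT_MAX_K = {"clinical": 4, "dti": 7, "dat": 4}


@dataclass(frozen=True)
class TrainConfig:
    """Everything the epoch loop needs; fully determines a run with a cohort."""

    pair: tuple[str, str] = ("clinical", "dti")
    epochs: int = 120
    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    master_seed: int = 0
    n_estimators: int = 50
    fusion: FusionParams = field(default_factory=FusionParams)
    max_k: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_MAX_K))
    max_k_default: int = 4
    fixed_test: bool = True
    base_learner: str = "adaboost"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if len(self.pair) != 2 or self.pair[0] == self.pair[1]:
            raise ValueError("pair must name two distinct modalities")

    def max_k_for(self, modality: str) -> int:
        return self.max_k.get(modality, self.max_k_default)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pair"] = list(self.pair)
        d["fractions"] = list(self.fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["pair"] = tuple(d["pair"])
        d["fractions"] = tuple(d["fractions"])
        d["fusion"] = FusionParams(**d["fusion"])
        return cls(**d)


@dataclass
class EpochResult:
    """One epoch's models, validation triplets and accuracies."""

    epoch: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    selections: dict[str, SelectedFeatures]
    models: dict[str, ModalModel]
    val_predictions: dict[str, SingleModalPrediction]
    fused_val_accuracy: float
    fused: list[FusedPrediction]


@dataclass
class ModelArchive:
    """Best single-modal models Ms and the fusion model Mc."""

    config: TrainConfig
    ms: dict[str, ModalModel]
    ms_phi: dict[str, float]
    ms_epoch: dict[str, int]
    mc_epoch: int
    mc_fused_val_accuracy: float
    test_ids: tuple[str, ...]
    audit: list[dict]

    # -- persistence (portable JSON + CSV audit log) --------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {
            "config": self.config.to_dict(),
            "ms": {tag: m.to_dict() for tag, m in self.ms.items()},
            "ms_phi": self.ms_phi,
            "ms_epoch": self.ms_epoch,
            "mc_epoch": self.mc_epoch,
            "mc_fused_val_accuracy": self.mc_fused_val_accuracy,
            "test_ids": list(self.test_ids),
        }
        (directory / "archive.json").write_text(
            json.dumps(payload, sort_keys=True, indent=2) + "\n"
        )
        with open(directory / "audit.csv", "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["epoch", *self.config.pair, "fused"]
            )
            writer.writeheader()
            writer.writerows(self.audit)

    @classmethod
    def load(cls, directory: str | Path) -> "ModelArchive":
        directory = Path(directory)
        payload = json.loads((directory / "archive.json").read_text())
        config = TrainConfig.from_dict(payload["config"])
        with open(directory / "audit.csv", newline="") as fh:
            audit = [
                {k: (int(v) if k == "epoch" else float(v)) for k, v in row.items()}
                for row in csv.DictReader(fh)
            ]
        return cls(
            config=config,
            ms={tag: ModalModel.from_dict(d) for tag, d in payload["ms"].items()},
            ms_phi={k: float(v) for k, v in payload["ms_phi"].items()},
            ms_epoch={k: int(v) for k, v in payload["ms_epoch"].items()},
            mc_epoch=int(payload["mc_epoch"]),
            mc_fused_val_accuracy=float(payload["mc_fused_val_accuracy"]),
            test_ids=tuple(payload["test_ids"]),
            audit=audit,
        )


def epoch_seed(master_seed: int, epoch_index: int, stream: int = 0) -> int:
    """Deterministic per-epoch seed, a pure function of its arguments."""
    ss = np.random.SeedSequence((master_seed, epoch_index, stream))
    return int(ss.generate_state(1)[0] % (2**31))


def fixed_test_ids(cohort: MultimodalCohort, config: TrainConfig) -> tuple[str, ...]:
    """The once-carved held-out test ids (empty when test fraction is 0)."""
    n_test = int(cohort.n_patients * config.fractions[2])
    if n_test == 0:
        return ()
    rng = np.random.default_rng(np.random.SeedSequence((config.master_seed, 0, 1)))
    perm = rng.permutation(cohort.n_patients)
    ids = cohort.patient_ids
    return tuple(ids[i] for i in perm[:n_test])


def _epoch_split(
    cohort: MultimodalCohort, config: TrainConfig, seed: int
) -> tuple[list[str], list[str], tuple[str, ...]]:
    """Train/val/test ids for one epoch draw, honouring fixed_test."""
    if config.fixed_test:
        test = fixed_test_ids(cohort, config)
        pool = [p for p in cohort.patient_ids if p not in set(test)]
        f_train = config.fractions[0] / (config.fractions[0] + config.fractions[1])
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(pool))
        n_train = int(len(pool) * f_train)
        train = [pool[i] for i in perm[:n_train]]
        val = [pool[i] for i in perm[n_train:]]
        if not train or not val:
            raise ValueError("epoch split leaves an empty train or validation set")
        return train, val, test
    split = split_cohort(cohort, config.fractions, seed=seed)
    return list(split.train_ids), list(split.val_ids), split.test_ids


def run_epoch(
    cohort: MultimodalCohort, config: TrainConfig, epoch_index: int
) -> EpochResult:
    """One resplit-select-train-fuse cycle.

    If the training split comes out single-class it is redrawn once with a
    derived alternate seed; a second single-class draw is an error.
    """
    for attempt in (0, 1):
        draw_seed = epoch_seed(config.master_seed, epoch_index, stream=2 * attempt)
        train_ids, val_ids, _ = _epoch_split(cohort, config, draw_seed)
        train = cohort.subset(train_ids)
        if len(np.unique(train.labels)) == 2:
            break
    else:
        raise ValueError(f"epoch {epoch_index}: training split single-class after redraw")
    val = cohort.subset(val_ids)
    seed = epoch_seed(config.master_seed, epoch_index)

    selections: dict[str, SelectedFeatures] = {}
    models: dict[str, ModalModel] = {}
    val_preds: dict[str, SingleModalPrediction] = {}
    for tag in config.pair:
        if tag not in cohort.tables:
            raise KeyError(f"cohort has no modality {tag!r}")
        sel = select_with_fallback(
            train.tables[tag], train.labels, max_k=config.max_k_for(tag), seed=seed
        )
        selections[tag] = sel
        model = train_modal_learner(
            train.tables[tag], train.labels, sel.feature_names,
            n_estimators=config.n_estimators, seed=seed,
            threshold=config.fusion.threshold,
            base_learner=config.base_learner,
        )
        models[tag] = model
        val_preds[tag] = predict_modal(model, val.tables[tag], val.labels)

    a, b = config.pair
    fused, fused_acc = fuse_batch(
        val_preds[a], val_preds[b], config.fusion, eval_labels=val.labels
    )
    return EpochResult(
        epoch=epoch_index,
        train_ids=tuple(train_ids),
        val_ids=tuple(val_ids),
        selections=selections,
        models=models,
        val_predictions=val_preds,
        fused_val_accuracy=float(fused_acc),
        fused=fused,
    )


def fit_cmfp(cohort: MultimodalCohort, config: TrainConfig) -> ModelArchive:
    """Run the full epoch loop and keep the best models (Ms, Mc)."""
    if len(np.unique(cohort.labels)) < 2:
        raise ValueError("cohort labels contain a single class")
    test = fixed_test_ids(cohort, config) if config.fixed_test else ()
    best_phi: dict[str, float] = {tag: -1.0 for tag in config.pair}
    best_model: dict[str, ModalModel] = {}
    best_epoch: dict[str, int] = {}
    mc_best = -1.0
    mc_epoch = 0
    audit: list[dict] = []
    for e in range(1, config.epochs + 1):
        result = run_epoch(cohort, config, e)
        row = {"epoch": e, "fused": result.fused_val_accuracy}
        for tag in config.pair:
            phi = result.val_predictions[tag].phi
            row[tag] = phi
            if phi > best_phi[tag]:  # strict: earliest epoch wins ties
                best_phi[tag] = phi
                best_model[tag] = result.models[tag]
                best_epoch[tag] = e
        if result.fused_val_accuracy > mc_best:
            mc_best = result.fused_val_accuracy
            mc_epoch = e
        audit.append(row)
    return ModelArchive(
        config=config,
        ms=best_model,
        ms_phi=best_phi,
        ms_epoch=best_epoch,
        mc_epoch=mc_epoch,
        mc_fused_val_accuracy=mc_best,
        test_ids=test,
        audit=audit,
    )


def test_cmfp(
    archive: ModelArchive,
    test_cohort: MultimodalCohort,
    test_labels: np.ndarray | None = None,
) -> tuple[list[FusedPrediction], MetricsReport]:
    """Apply Ms then Mc to held-out rows and score the fused output.

    Each modality's phi entering the fusion rule is the *archived*
    validation accuracy of that Ms, not an accuracy measured on the test
    rows.
    """
    labels = np.asarray(
        test_cohort.labels if test_labels is None else test_labels, dtype=int
    )
    a, b = archive.config.pair
    preds = {}
    for tag in (a, b):
        p = predict_modal(archive.ms[tag], test_cohort.tables[tag])
        preds[tag] = SingleModalPrediction(
            p.modality, p.patient_ids, p.rho, p.eta, phi=archive.ms_phi[tag]
        )
    fused, _ = fuse_batch(preds[a], preds[b], archive.config.fusion)
    eta = np.array([f.eta for f in fused])
    rho = np.array([f.rho for f in fused])
    report = evaluate_predictions(rho, eta, labels)
    return fused, report
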