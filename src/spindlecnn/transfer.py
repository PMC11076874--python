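"""Transfer learning between spindle populations by conv-layer transfer.

Two modes, mirroring the two experiments on the healthy → insomnia shift:

``all_conv``
    all five conv blocks carry the source parameters; only the
    fully-connected head is (re-initialized and) retrained.
``first_four``
    conv blocks 1–4 carry the source parameters; block 5 and the head are
    re-initialized and retrained. The early blocks are presumed to encode
    population-independent sigma-burst features, the last block
    population-specific ones.

Transferred blocks travel with their BatchNorm scale/shift *and* running
statistics, and are frozen by default: they receive no gradient updates and
their running statistics stop adapting, so "transferred" is a bitwise
invariant through any amount of finetuning. ``freeze_transferred=False``
instead finetunes everything from the transferred initialization. The head
is never copied — both modes retrain it from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import CNNSpec, TrainedModel, build_model
from .train_eval import (
    EvalReport, TrainConfig, compute_metrics, make_folds, predict, train,
)
from .windowing import WindowSet

__all__ = ["TransferConfig", "transfer_model", "finetune",
           "transfer_experiment", "MODE_BLOCKS"]

#: conv blocks copied from the source model, per mode
MODE_BLOCKS = {"all_conv": (1, 2, 3, 4, 5), "first_four": (1, 2, 3, 4)}


@dataclass(frozen=True)
class TransferConfig:
    """Transfer mode plus the finetuning schedule.

    ``finetune_lr0`` replaces the source-training ``lr0`` during finetuning
    (the stepped decay and all other settings are inherited from ``train``).
    Retraining re-initialized blocks on a small target cohort at the source
    rate of 0.1 is unstable; 0.01 finetunes reliably. Set it to
    ``train.lr0`` to reproduce the inherit-everything behaviour.
    """

    mode: str = "first_four"
    freeze_transferred: bool = True
    finetune_lr0: float = 0.01
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.mode not in MODE_BLOCKS:
            raise ValueError(
                f"mode must be one of {sorted(MODE_BLOCKS)}, got {self.mode!r}"
            )
        if self.finetune_lr0 <= 0:
            raise ValueError("finetune_lr0 must be positive")

    def finetune_train_config(self) -> TrainConfig:
        return replace(self.train, lr0=self.finetune_lr0)


def transfer_model(
    source: TrainedModel, config: TransferConfig, seed: int
) -> TrainedModel:
    """A fresh model carrying the source's transferred conv blocks.

    Non-transferred parts (block 5 in ``first_four`` mode, the head in both)
    are re-initialized from ``seed``. Freeze flags are set per
    ``config.freeze_transferred``.
    """
    target = build_model(source.spec, seed=seed)
    src_state = source.net.state()
    transferred_layers: list[str] = []
    for block in MODE_BLOCKS[config.mode]:
        transferred_layers.extend(target.conv_block_layers(block))
    for lname in transferred_layers:
        layer = target.net[lname]
        layer.load_state(
            {
                k.split(".", 1)[1]: v
                for k, v in src_state.items()
                if k.startswith(lname + ".")
            }
        )
        layer.frozen = config.freeze_transferred
    target.provenance = {
        "transfer_mode": config.mode,
        "frozen": config.freeze_transferred,
        "source_provenance": source.provenance,
        "reinit_seed": int(seed),
    }
    return target


def trainable_param_names(model: TrainedModel) -> set[str]:
    return {qname for qname, _, _ in model.net.trainable_params()}


def finetune(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray,
    config: TransferConfig,
    log: list | None = None,
) -> TrainedModel:
    """Retrain the trainable part on target-domain windows.

    Frozen layers are bitwise unchanged afterwards (no gradient steps, no
    BatchNorm statistic updates).
    """
    return train(model, X, y, config.finetune_train_config(), log=log)


def _eval_on(model: TrainedModel, ws: WindowSet, idx: np.ndarray) -> dict:
    scores = predict(model, ws.X[idx])
    return compute_metrics(ws.y[idx], (scores >= 0.5).astype(int), scores)


def transfer_experiment(
    source_windows: WindowSet,
    target_windows: WindowSet,
    cnn_spec: CNNSpec = CNNSpec(),
    train_config: TrainConfig = TrainConfig(),
    modes: tuple[str, ...] = ("all_conv", "first_four"),
    k: int = 5,
) -> dict[str, EvalReport]:
    """Source training + per-mode transfer evaluation on the target cohort.

    Trains one source model on all source windows, then for each requested
    mode runs k-fold cross-validation on the target set: each fold transfers
    from the same source model, finetunes on the fold's training windows and
    is scored on the held-out windows. A ``no_transfer`` entry evaluates the
    unadapted source model on the same held-out folds, so the value of
    finetuning can be read off directly.
    """
    source_model = build_model(cnn_spec, seed=train_config.seed)
    train(source_model, source_windows.X, source_windows.y, train_config)

    folds = make_folds(
        target_windows, k=k, grouping=train_config.fold_grouping,
        seed=train_config.seed,
    )
    results: dict[str, EvalReport] = {}
    baseline = EvalReport()
    for _, test_idx in folds:
        baseline.per_fold.append(_eval_on(source_model, target_windows, test_idx))
    results["no_transfer"] = baseline

    for mode in modes:
        cfg = TransferConfig(mode=mode, train=train_config)
        report = EvalReport()
        for fold_i, (train_idx, test_idx) in enumerate(folds):
            seed = train_config.seed + 1000 * (fold_i + 1)
            mdl = transfer_model(source_model, cfg, seed=seed)
            finetune(
                mdl, target_windows.X[train_idx], target_windows.y[train_idx],
                replace(cfg, train=replace(train_config, seed=seed)),
            )
            scores = predict(mdl, target_windows.X[test_idx])
            y_test = target_windows.y[test_idx]
            report.per_fold.append(
                compute_metrics(y_test, (scores >= 0.5).astype(int), scores)
            )
            report.predictions.append(
                {"fold": fold_i, "test_idx": test_idx, "y": y_test, "scores": scores}
            )
        results[mode] = report
    return results
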