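"""Joint segmentation+classification training loop.

Orchestrates the full procedure: SGD with momentum under the step-decay
learning-rate schedule, the two-headed loss (per-pixel cross-entropy +
per-image cross-entropy + L2 auxiliary), dispersion-adaptive early
stopping, and periodic magnitude pruning.  An optional outer firefly
search tunes the stopping sensitivity and pruning strength with short
inner trainings.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import fss, losses, mwr
from .network import _softmax
from .phantoms import CLASSES, LabeledSample

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "RunReport",
    "lr_schedule",
    "sgd_momentum_step",
    "stratified_split",
    "samples_to_arrays",
    "train",
    "evaluate",
    "tune_hyperparameters",
]


@dataclass
class TrainConfig:
    """Training protocol defaults.

    Batch size 32, 50 epochs, initial learning rate 1e-3 multiplied by
    0.9 every 10 epochs, SGD momentum 0.9, early stopping when the
    validation loss fails to improve by 0.01 for 10 epochs.  ``alpha`` is
    the pruning strength; pruning runs every ``prune_every`` epochs after
    a ``prune_warmup`` burn-in.
    """

    batch_size: int = 32
    epochs: int = 50
    lr0: float = 0.001
    lr_decay: float = 0.9
    lr_step: int = 10
    momentum: float = 0.9
    use_momentum: bool = True
    l2_coeff: float = 1e-4
    alpha: float = 0.5
    sigma_mult: float = 1.0
    patience: int = 10
    min_delta: float = 0.01
    eta_theta: float = 0.1
    prune_every: int = 5
    prune_warmup: int = 5
    fd_val_cap: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must lie in (0, 1]")

    def early_stop_state(self) -> fss.EarlyStopState:
        return fss.EarlyStopState(
            sigma_mult=self.sigma_mult,
            patience=self.patience,
            min_delta=self.min_delta,
            eta_theta=self.eta_theta,
        )


@dataclass
class EpochRecord:
    epoch: int
    train_seg_loss: float
    train_class_loss: float
    train_aux_loss: float
    train_total_loss: float
    val_seg_loss: float
    val_class_loss: float
    val_total_loss: float
    theta: float
    sigma_loss: float
    lr: float
    sparsity: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    mse: float
    pixel_accuracy: float


@dataclass
class RunReport:
    records: list = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = "completed"
    final_metrics: losses.MetricsReport | None = None
    wall_time: float = 0.0
    config: TrainConfig | None = None
    seed: int = 0
    prune_events: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "records": [asdict(r) for r in self.records],
            "stop_epoch": self.stop_epoch,
            "stop_reason": self.stop_reason,
            "final_metrics": asdict(self.final_metrics) if self.final_metrics else None,
            "wall_time": self.wall_time,
            "config": asdict(self.config) if self.config else None,
            "seed": self.seed,
            "prune_events": self.prune_events,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def epoch_csv(self, path: str | Path) -> None:
        if not self.records:
            return
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(asdict(self.records[0])))
            w.writeheader()
            for r in self.records:
                w.writerow(asdict(r))


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """lr0 * decay^floor(epoch / step); epoch is 0-based."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.lr0 * config.lr_decay ** (epoch // config.lr_step)


def sgd_momentum_step(
    weights: np.ndarray,
    gradients: np.ndarray,
    velocity: np.ndarray,
    lr: float,
    momentum: float = 0.9,
    l2_coeff: float = 0.0,
    mask: np.ndarray | None = None,
) -> bool:
    """In-place update v <- mu*v - lr*(g + l2*w); w <- w + v.

    Pruned positions (mask False) receive no update and stay zero.  A
    non-finite gradient rejects the whole step; returns whether the step
    was applied.
    """
    if weights.shape != gradients.shape or weights.shape != velocity.shape:
        raise ValueError(
            f"shape mismatch: w{weights.shape} g{gradients.shape} v{velocity.shape}"
        )
    if not np.all(np.isfinite(gradients)):
        return False
    velocity *= momentum
    velocity -= lr * (gradients + l2_coeff * weights)
    if mask is not None:
        velocity *= mask
    weights += velocity
    if mask is not None:
        weights *= mask
    return True


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------


def samples_to_arrays(samples: list[LabeledSample]):
    """Stack samples into (N,1,H,W) images, (N,H,W) masks, (N,) labels."""
    X = np.stack([s.image for s in samples])[:, None, :, :]
    y_seg = np.stack([s.mask for s in samples]).astype(np.int64)
    y_cls = np.array([CLASSES.index(s.label) for s in samples], dtype=np.int64)
    return X, y_seg, y_cls


def stratified_split(
    samples: list[LabeledSample],
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
):
    """Label-stratified train/validation/test split."""
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        by_label.setdefault(s.label, []).append(i)
    parts: tuple[list, list, list] = ([], [], [])
    for label in sorted(by_label):
        idx = np.array(by_label[label])
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        cuts = [n_tr, n_tr + n_va]
        for part, chunk in zip(parts, np.split(idx, cuts)):
            part.extend(int(i) for i in chunk)
    return tuple([samples[i] for i in part] for part in parts)


# ---------------------------------------------------------------------------
# forward/backward bookkeeping shared by train and evaluate
# ---------------------------------------------------------------------------


def _one_hot(y: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(y), n))
    out[np.arange(len(y)), y] = 1.0
    return out


def _batch_losses(model, class_logits, seg_logits, y_cls, y_seg, l2_coeff):
    n, c_seg = seg_logits.shape[:2]
    p_cls = _softmax(class_logits, axis=1)
    p_seg = _softmax(seg_logits, axis=1)
    y_cls_oh = _one_hot(y_cls, class_logits.shape[1])
    class_loss = float(
        -(y_cls_oh * np.log(np.clip(p_cls, losses.EPS, 1.0))).sum() / n
    )
    pix_true = np.eye(c_seg)[y_seg].transpose(0, 3, 1, 2)  # (N,Cs,H,W)
    n_pix = n * y_seg.shape[1] * y_seg.shape[2]
    seg_l = float(
        -(pix_true * np.log(np.clip(p_seg, losses.EPS, 1.0))).sum() / n_pix
    )
    aux = 0.0
    if l2_coeff > 0:
        aux = 0.5 * l2_coeff * sum(
            float((layer.W**2).sum()) for _, layer in model.prunable_layers(True)
        )
    d_class = (p_cls - y_cls_oh) / n
    d_seg = (p_seg - pix_true) / n_pix
    return seg_l, class_loss, aux, d_class, d_seg


def _forward_losses(model, X, y_seg, y_cls, l2_coeff, chunk=64):
    """Average losses and predictions over a split, dropout off."""
    seg_l = class_l = 0.0
    preds, pix_correct, pix_total = [], 0, 0
    for i in range(0, len(X), chunk):
        xs, ys, yc = X[i:i + chunk], y_seg[i:i + chunk], y_cls[i:i + chunk]
        class_logits, seg_logits = model.forward(xs, train=False)
        s, c, aux, _, _ = _batch_losses(model, class_logits, seg_logits, yc, ys, 0.0)
        w = len(xs) / len(X)
        seg_l += s * w
        class_l += c * w
        preds.append(class_logits.argmax(axis=1))
        seg_pred = seg_logits.argmax(axis=1)
        pix_correct += int((seg_pred == ys).sum())
        pix_total += ys.size
    aux = 0.0
    if l2_coeff > 0:
        aux = 0.5 * l2_coeff * sum(
            float((layer.W**2).sum()) for _, layer in model.prunable_layers(True)
        )
    return seg_l, class_l, aux, np.concatenate(preds), pix_correct / pix_total


def evaluate(model, split: list[LabeledSample], l2_coeff: float = 0.0) -> losses.MetricsReport:
    """Deterministic evaluation pass (dropout off) over one split."""
    if not split:
        raise ValueError("cannot evaluate an empty split")
    X, y_seg, y_cls = samples_to_arrays(split)
    seg_l, class_l, aux, y_pred, pix_acc = _forward_losses(
        model, X, y_seg, y_cls, l2_coeff
    )
    report = losses.macro_metrics(y_cls, y_pred, len(CLASSES))
    report.seg_loss = seg_l
    report.class_loss = class_l
    report.aux_loss = aux
    report.total_loss = losses.total_loss(seg_l, class_l, aux)
    report.pixel_accuracy = pix_acc
    return report


# ---------------------------------------------------------------------------
# pruning-threshold surrogate gradient (central finite difference)
# ---------------------------------------------------------------------------


def _val_loss_at_threshold(model, X, y_seg, y_cls, thr: float) -> float:
    """Validation total loss with extra masks keeping only |w| >= thr.

    Weights are temporarily zeroed and restored; an approximation used
    only to steer the threshold update.
    """
    saved = []
    for _, layer in model.prunable_layers():
        saved.append((layer, layer.W.copy()))
        layer.W *= np.abs(layer.W) >= thr
    try:
        seg_l, class_l, _, _, _ = _forward_losses(model, X, y_seg, y_cls, 0.0)
    finally:
        for layer, w in saved:
            layer.W[...] = w
    return seg_l + class_l


def threshold_surrogate_gradient(model, X, y_seg, y_cls, theta: float) -> float:
    """d(val loss)/d(theta) by central finite difference at theta +/- delta."""
    if theta <= 0:
        return 0.0
    delta = 0.1 * theta
    lo = _val_loss_at_threshold(model, X, y_seg, y_cls, theta - delta)
    hi = _val_loss_at_threshold(model, X, y_seg, y_cls, theta + delta)
    return (hi - lo) / (2 * delta)


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def train(model, splits, config: TrainConfig) -> RunReport:
    """Run the full training procedure and return the epoch-by-epoch report.

    ``splits`` is ``(train, val)`` or ``(train, val, test)`` lists of
    labeled samples.  Per epoch: mini-batch SGD over the two-headed loss;
    then validation, the dispersion statistic and adaptive threshold, the
    stopping decision, scheduled pruning, and the surrogate-gradient
    threshold refinement.  Reproducible bit-exactly for a fixed seed.
    """
    train_split, val_split = splits[0], splits[1]
    if not train_split or not val_split:
        raise ValueError("train and validation splits must be non-empty")
    Xtr, ytr_seg, ytr_cls = samples_to_arrays(train_split)
    Xva, yva_seg, yva_cls = samples_to_arrays(val_split)
    cap = min(config.fd_val_cap, len(Xva))
    state = config.early_stop_state()
    rng = np.random.default_rng(config.seed)
    velocity: dict[int, np.ndarray] = {}
    report = RunReport(config=config, seed=config.seed)
    history: list[float] = []
    t0 = time.perf_counter()

    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        order = rng.permutation(len(Xtr))
        mu = config.momentum if config.use_momentum else 0.0
        ep_seg = ep_cls = ep_aux = 0.0
        n_batches = 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            class_logits, seg_logits = model.forward(Xtr[idx], train=True)
            seg_l, class_l, aux, d_class, d_seg = _batch_losses(
                model, class_logits, seg_logits, ytr_cls[idx], ytr_seg[idx],
                config.l2_coeff,
            )
            model.backward(d_class, d_seg)
            for name, layer in model.prunable_layers(include_heads=True):
                for key, grad in (("W", layer.dW), ("b", layer.db)):
                    arr = getattr(layer, key)
                    vid = id(arr)
                    if vid not in velocity:
                        velocity[vid] = np.zeros_like(arr)
                    sgd_momentum_step(
                        arr, grad, velocity[vid], lr, mu,
                        config.l2_coeff if key == "W" else 0.0,
                        mask=layer.mask if key == "W" else None,
                    )
            ep_seg += seg_l
            ep_cls += class_l
            ep_aux += aux
            n_batches += 1

        val = evaluate(model, val_split, config.l2_coeff)
        if not np.isfinite(val.total_loss):
            raise FloatingPointError(
                f"validation loss became non-finite at epoch {epoch}"
            )
        history.append(val.total_loss)
        w = min(state.window, len(history))
        sigma = fss.loss_stddev(history, w)
        state.theta = fss.compute_threshold(state, sigma)
        stop, reason = fss.should_stop(state, history)

        sparsity = 1.0 - model.n_nonzero() / model.n_parameters()
        report.records.append(EpochRecord(
            epoch=epoch,
            train_seg_loss=ep_seg / n_batches,
            train_class_loss=ep_cls / n_batches,
            train_aux_loss=ep_aux / n_batches,
            train_total_loss=(ep_seg + ep_cls + ep_aux) / n_batches,
            val_seg_loss=val.seg_loss,
            val_class_loss=val.class_loss,
            val_total_loss=val.total_loss,
            theta=state.theta,
            sigma_loss=sigma,
            lr=lr,
            sparsity=sparsity,
            accuracy=val.accuracy,
            precision=val.precision,
            recall=val.recall,
            f1=val.f1,
            mse=val.mse,
            pixel_accuracy=val.pixel_accuracy,
        ))

        if stop:
            report.stop_epoch = epoch
            report.stop_reason = reason
            break

        # scheduled magnitude pruning + threshold refinement
        t = epoch + 1
        if (
            config.alpha > 0
            and t >= config.prune_warmup
            and (t - config.prune_warmup) % config.prune_every == 0
        ):
            prune_rep = mwr.apply_pruning(model, config.alpha)
            report.prune_events.append(
                {"epoch": epoch, **prune_rep.as_dict()}
            )
            g = threshold_surrogate_gradient(
                model, Xva[:cap], yva_seg[:cap], yva_cls[:cap], state.theta
            )
            fss.update_threshold(state, g)
    else:
        report.stop_epoch = config.epochs - 1
        report.stop_reason = "completed"

    report.wall_time = time.perf_counter() - t0
    report.final_metrics = evaluate(model, val_split, config.l2_coeff)
    return report


def tune_hyperparameters(
    model_factory,
    splits,
    config: TrainConfig,
    swarm: fss.SwarmConfig | None = None,
    inner_epochs: int = 5,
) -> dict:
    """Firefly search over (sigma_mult, alpha) with short inner trainings.

    Each firefly evaluation trains a fresh model for ``inner_epochs`` and
    returns the final validation total loss as brightness.  The outer
    loop is deliberately separate from the inner SGD loop.
    """
    swarm = swarm or fss.SwarmConfig(
        bounds=((0.1, 5.0), (0.0, 2.0)), population=6, iterations=5,
        seed=config.seed,
    )

    def objective(x):
        sigma_mult, alpha = float(x[0]), float(x[1])
        cfg = TrainConfig(**{**asdict(config), "sigma_mult": sigma_mult,
                             "alpha": alpha, "epochs": inner_epochs})
        rep = train(model_factory(), splits, cfg)
        return rep.records[-1].val_total_loss

    result = fss.optimize(objective, swarm)
    return {
        "sigma_mult": float(result["best_position"][0]),
        "alpha": float(result["best_position"][1]),
        "best_val_loss": result["best_value"],
        "trace": result["trace"],
    }
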