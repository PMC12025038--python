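"""MagWeight Rank: magnitude-threshold pruning of network weights.

For every prunable layer the pruning threshold is alpha times the mean
absolute value of the currently active (not yet pruned) weights; weights
whose magnitude falls below the threshold are zeroed and their mask bits
cleared, so masks only ever grow sparser.  Exact equality with the
threshold keeps the weight (the conservative reading of "exceeding ...
kept, falling below ... pruned").  Biases are never pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LayerPruneRecord",
    "PruneReport",
    "layer_mean_abs",
    "pruning_threshold",
    "build_mask",
    "apply_pruning",
    "rank_weights",
]


@dataclass
class LayerPruneRecord:
    name: str
    mean_abs: float
    alpha: float
    threshold: float
    n_total: int
    n_pruned: int
    kept_last_weight: bool = False  # threshold would have emptied the layer

    @property
    def sparsity(self) -> float:
        return self.n_pruned / self.n_total

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "mean_abs": self.mean_abs,
            "alpha": self.alpha,
            "threshold": self.threshold,
            "n_total": self.n_total,
            "n_pruned": self.n_pruned,
            "sparsity": self.sparsity,
            "kept_last_weight": self.kept_last_weight,
        }


@dataclass
class PruneReport:
    layers: list = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return sum(r.n_total for r in self.layers)

    @property
    def n_pruned(self) -> int:
        return sum(r.n_pruned for r in self.layers)

    @property
    def sparsity(self) -> float:
        return self.n_pruned / self.n_total if self.n_total else 0.0

    def as_dict(self) -> dict:
        return {
            "layers": [r.as_dict() for r in self.layers],
            "n_total": self.n_total,
            "n_pruned": self.n_pruned,
            "sparsity": self.sparsity,
        }


def layer_mean_abs(weights: np.ndarray, active_mask: np.ndarray | None = None) -> float:
    """Mean absolute value (1/n) sum |w_i| over the active weights only."""
    weights = np.asarray(weights)
    if active_mask is None:
        active_mask = np.ones(weights.shape, dtype=bool)
    active = weights[active_mask]
    if active.size == 0:
        raise ValueError("all weights in the layer are masked; mean undefined")
    return float(np.abs(active).mean())


def pruning_threshold(mean_abs: float, alpha: float) -> float:
    """alpha * mean|W|; linear in alpha."""
    if mean_abs < 0:
        raise ValueError(f"mean_abs must be >= 0, got {mean_abs}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    return alpha * mean_abs


def build_mask(
    weights: np.ndarray, threshold: float, existing: np.ndarray | None = None
) -> np.ndarray:
    """Keep iff |w| >= threshold AND previously kept.

    Masks only grow sparser; a weight exactly at the threshold is kept.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    weights = np.asarray(weights)
    keep = np.abs(weights) >= threshold
    if existing is not None:
        keep &= np.asarray(existing, dtype=bool)
    return keep


def apply_pruning(model, alpha: float, include_heads: bool = False) -> "PruneReport":
    """Prune every prunable layer of ``model`` in place and report.

    Per layer: mean|W| over active weights, threshold = alpha * mean|W|,
    mask update, masked weights zeroed.  If the threshold would empty a
    layer, its single largest-magnitude active weight is kept and the
    record is flagged.  Heads are skipped unless ``include_heads``.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    report = PruneReport()
    for name, layer in model.prunable_layers(include_heads=include_heads):
        mean = layer_mean_abs(layer.W, layer.mask)
        thr = pruning_threshold(mean, alpha)
        new_mask = build_mask(layer.W, thr, existing=layer.mask)
        kept_last = False
        if not new_mask.any():
            absw = np.where(layer.mask, np.abs(layer.W), -np.inf)
            flat = int(np.argmax(absw))
            new_mask.flat[flat] = True
            kept_last = True
        n_total = layer.W.size
        n_pruned = n_total - int(new_mask.sum())
        layer.mask = new_mask
        layer.W *= new_mask
        report.layers.append(
            LayerPruneRecord(
                name=name, mean_abs=mean, alpha=alpha, threshold=thr,
                n_total=n_total, n_pruned=n_pruned, kept_last_weight=kept_last,
            )
        )
    if not report.layers:
        raise ValueError("model has no prunable layers")
    return report


def rank_weights(weights: np.ndarray) -> np.ndarray:
    """Flat indices ordered by descending |w|; ties by ascending index.

    The first entry (rank 1) is the largest-magnitude weight.  Exposed as
    a diagnostic of which connections the pruning considers important.
    """
    w = np.abs(np.asarray(weights)).ravel()
    # stable sort on -|w| keeps ascending index order within ties
    return np.argsort(-w, kind="stable")
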