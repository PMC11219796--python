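"""Losses, augmentation, the training schedule, metrics and the prediction
pipeline.

Training minimizes a masked MSE (RMSF regression) or a class-weighted
cross-entropy (occupancy classification) with Adam at learning rate 0.004,
batch 32: the learning rate is halved after 10 consecutive epochs without a
strictly lower validation loss (and again after 20), training stops after 30,
and the parameters with the minimum validation loss are kept.  Mirror
augmentation over the three axes expands the training set eightfold.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn as _nn
from .boxing import BoxSpec, SampleBox, merge_subboxes, segment_boxes
from .density import (binarize_simulated_map, occupancy_annotation,
                      one_hot_encode, simulate_density)
from .nn import Adam, Tensor, no_grad
from .rmsf import RMSFMap, aggregate_to_residues
from .structure import AtomicModel
from .voxel import VoxelGrid, resample_to_voxel_size, world_to_voxel

__all__ = [
    "TrainConfig", "TrainResult", "PredictionResult",
    "masked_mse", "weighted_cross_entropy", "augment_box",
    "RMSFObjective", "OccupancyObjective", "train",
    "pearson_cc", "evaluate_entry", "kfold_split", "occ_metrics",
    "predict_rmsf_map", "summarize_correlations",
]

#: Class weights (unoccupied, occupied) for occupancy training.
OCC_CLASS_WEIGHTS = (0.05, 0.95)

#: Thresholds at which occupancy precision/recall/F1 are reported.
OCC_THRESHOLDS = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


@dataclass
class TrainConfig:
    """Optimization schedule defaults."""

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.004
    lr_patience: int = 10      # halve lr after this many stagnant epochs
    stop_patience: int = 30    # stop after this many stagnant epochs
    train_val_ratio: tuple[int, int] = (3, 1)
    seed: int = 0
    micro_batch: int = 2       # gradient-accumulation chunk (cache-friendly)
    augment: bool = True

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.lr_patience,
               self.stop_patience, self.micro_batch) < 1:
            raise ValueError("schedule parameters must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    lr_halvings: list[int] = field(default_factory=list)


# --------------------------------------------------------------------------
# losses (array-level contracts; Tensor-aware for training)
# --------------------------------------------------------------------------

def masked_mse(pred, target, mask):
    """MSE over masked voxels only; a Tensor input returns a Tensor."""
    if isinstance(pred, Tensor):
        return _nn.masked_mse(pred, target, mask)
    return _nn.masked_mse(Tensor(pred), target, mask).item()


def weighted_cross_entropy(probs, truth, weights=OCC_CLASS_WEIGHTS):
    """Class-weighted cross-entropy on two-channel probabilities."""
    if isinstance(probs, Tensor):
        return _nn.weighted_cross_entropy(probs, truth, weights)
    return _nn.weighted_cross_entropy(Tensor(probs), truth, weights).item()


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def augment_box(sample: SampleBox, seed: int | None = None) -> list[SampleBox]:
    """The 8 axis-mirroring images of a sample (identity included).

    Every channel, the label, the mask and the occupancy field are flipped
    jointly, so labels stay registered with densities.  Each transform is an
    involution; ``seed`` is accepted for interface stability but the group
    (and its order) is fixed.
    """
    out = []
    for flips in itertools.product((False, True), repeat=3):
        axes = tuple(i for i, f in enumerate(flips) if f)
        ch_axes = tuple(a + 1 for a in axes)

        def t(arr, ch=False):
            if arr is None or not axes:
                return None if arr is None else arr.copy()
            return np.flip(arr, axis=ch_axes if ch else axes).copy()

        out.append(SampleBox(t(sample.channels, ch=True), sample.grid_index,
                             t(sample.label), t(sample.mask),
                             t(sample.occupancy)))
    return out


# --------------------------------------------------------------------------
# training objectives
# --------------------------------------------------------------------------

class RMSFObjective:
    """Masked-MSE regression objective over sample boxes."""

    def __init__(self, network):
        self.network = network

    def parameters(self):
        return self.network.parameters()

    def batch_loss(self, samples: list[SampleBox]) -> Tensor:
        x = np.stack([s.channels for s in samples])
        y = np.stack([s.label for s in samples])[:, None]
        m = np.stack([s.mask for s in samples])[:, None]
        return _nn.masked_mse(self.network(x), y, m)

    def train(self):
        self.network.train()

    def eval(self):
        self.network.eval()

    def state(self):
        return copy.deepcopy(self.network.named_state())

    def load(self, state):
        self.network.load_state(state)


class OccupancyObjective:
    """Class-weighted cross-entropy objective for the occupancy classifier."""

    def __init__(self, network, weights=OCC_CLASS_WEIGHTS):
        self.network = network
        self.weights = weights

    def parameters(self):
        return self.network.parameters()

    def batch_loss(self, samples: list[SampleBox]) -> Tensor:
        x = np.stack([s.channels for s in samples])
        truth = np.stack([s.occupancy for s in samples])
        return _nn.weighted_cross_entropy(self.network(x), truth, self.weights)

    def train(self):
        self.network.train()

    def eval(self):
        self.network.eval()

    def state(self):
        return copy.deepcopy(self.network.named_state())

    def load(self, state):
        self.network.load_state(state)


# --------------------------------------------------------------------------
# the schedule
# --------------------------------------------------------------------------

def _chunks(seq, size):
    for i in range(0, len(seq), size):
        yield seq[i:i + size]


def train(objective, train_samples: list, val_samples: list,
          config: TrainConfig = TrainConfig()) -> TrainResult:
    """Run the optimization schedule; restores the best-validation weights.

    ``objective`` exposes ``parameters()``, ``batch_loss(samples) -> Tensor``
    and optionally train/eval mode toggles and state snapshots, so both real
    networks and schedule-test stubs fit.
    """
    if not train_samples or not val_samples:
        raise ValueError("need non-empty training and validation sets")
    rng = np.random.default_rng(config.seed)
    data = list(train_samples)
    if config.augment:
        data = [a for s in data for a in augment_box(s)]
    opt = Adam(objective.parameters(), lr=config.learning_rate)
    best_val = np.inf
    best_epoch = 0
    best_state = None
    stagnant = 0
    halvings: list[int] = []
    rows = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(data))
        if hasattr(objective, "train"):
            objective.train()
        train_loss = 0.0
        n_seen = 0
        for batch_idx in _chunks(order, config.batch_size):
            batch = [data[i] for i in batch_idx]
            opt.zero_grad()
            for chunk in _chunks(batch, config.micro_batch):
                loss = objective.batch_loss(chunk) * (len(chunk) / len(batch))
                loss.backward()
                train_loss += loss.item() * len(batch)
            n_seen += len(batch)
            opt.step()
        train_loss /= max(n_seen, 1)
        if hasattr(objective, "eval"):
            objective.eval()
        with no_grad():
            val_loss = 0.0
            for chunk in _chunks(val_samples, config.micro_batch):
                val_loss += objective.batch_loss(chunk).item() * len(chunk)
            val_loss /= len(val_samples)
        if val_loss < best_val:  # strict improvement
            best_val = val_loss
            best_epoch = epoch
            stagnant = 0
            if hasattr(objective, "state"):
                best_state = objective.state()
        else:
            stagnant += 1
            if stagnant % config.lr_patience == 0 and stagnant < config.stop_patience:
                opt.lr *= 0.5
                halvings.append(stagnant)
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss, "lr": opt.lr, "stagnant": stagnant})
        if stagnant >= config.stop_patience:
            break
    if best_state is not None and hasattr(objective, "load"):
        objective.load(best_state)
    return TrainResult(pd.DataFrame(rows), best_epoch, float(best_val), halvings)


# --------------------------------------------------------------------------
# metrics and splits
# --------------------------------------------------------------------------

def pearson_cc(a, b) -> float:
    """Pearson correlation; errors on constant or too-short input."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if a.size < 2:
        raise ValueError("correlation needs at least 2 values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_entry(pred: RMSFMap, truth: RMSFMap,
                   pred_residues=None, truth_residues=None) -> dict:
    """Voxel-level (and optionally residue-level) Pearson correlations.

    Voxel level compares RMSF on the intersection of the two label masks;
    residue level compares per-residue vectors.
    """
    inter = pred.mask & truth.mask
    if not inter.any():
        raise ValueError("empty mask intersection: nothing to evaluate")
    out = {"voxel_cc": pearson_cc(pred.values.values[inter],
                                  truth.values.values[inter]),
           "n_voxels": int(inter.sum())}
    if pred_residues is not None and truth_residues is not None:
        out["residue_cc"] = pearson_cc(pred_residues, truth_residues)
    return out


def kfold_split(entries: list, k: int = 5, ratio: tuple[int, int] = (3, 1),
                seed: int = 0) -> list[dict]:
    """Entry-level k-fold split with a train:val split of the remainder.

    Every entry appears in exactly one test fold; within each fold the
    remaining entries are split ``ratio`` (train:val) in whole entries.
    """
    n = len(entries)
    if n < k:
        raise ValueError(f"need at least k={k} entries, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    out = []
    for i, test_idx in enumerate(folds):
        rest = np.concatenate([f for j, f in enumerate(folds) if j != i])
        n_val = max(1, (len(rest) * ratio[1]) // (ratio[0] + ratio[1]))
        out.append({
            "test": [entries[j] for j in test_idx],
            "val": [entries[j] for j in rest[:n_val]],
            "train": [entries[j] for j in rest[n_val:]],
        })
    return out


def occ_metrics(probs: np.ndarray, truth: np.ndarray,
                thresholds=OCC_THRESHOLDS) -> pd.DataFrame:
    """Precision/recall/F1 of the occupied class at several thresholds.

    ``probs`` is (..., 2, D, H, W); a voxel is predicted occupied when
    P(occupied) >= threshold.  Zero denominators yield 0 with the
    ``degenerate`` flag set.
    """
    probs = np.asarray(probs)
    ch_axis = probs.ndim - 4
    p_occ = np.take(probs, 1, axis=ch_axis).ravel()
    t = np.asarray(truth).ravel() > 0.5
    rows = []
    for thr in thresholds:
        pred = p_occ >= thr
        tp = int(np.sum(pred & t))
        fp = int(np.sum(pred & ~t))
        fn = int(np.sum(~pred & t))
        degenerate = (tp + fp == 0) or (tp + fn == 0)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        rows.append({"threshold": thr, "precision": precision,
                     "recall": recall, "f1": f1, "tp": tp, "fp": fp,
                     "fn": fn, "degenerate": degenerate})
    return pd.DataFrame(rows)


def summarize_correlations(values) -> dict:
    """Dataset-level mean/median/std of per-entry correlations."""
    v = np.asarray(values, dtype=np.float64)
    return {"mean": float(v.mean()), "median": float(np.median(v)),
            "std": float(v.std()), "n": int(v.size)}


# --------------------------------------------------------------------------
# end-to-end prediction
# --------------------------------------------------------------------------

@dataclass
class PredictionResult:
    rmsf_map: RMSFMap
    per_atom: np.ndarray
    residue_keys: list[tuple[str, int]]
    per_residue: np.ndarray


def build_variant_channels(variant: str, cryo: VoxelGrid, simulated: VoxelGrid
                           ) -> list[VoxelGrid]:
    """Input channel grids for each model variant."""
    if variant in ("cryo", "occ", "occ2rmsf"):
        return [cryo]  # single experimental-density channel
    if variant == "pdb":
        return [simulated]
    if variant == "dual":
        return [cryo, simulated]
    if variant == "pdb01":
        binary, _ = binarize_simulated_map(simulated)
        chans = one_hot_encode(binary)
        return [VoxelGrid(chans[0], cryo.voxel_size, cryo.origin.copy()),
                VoxelGrid(chans[1], cryo.voxel_size, cryo.origin.copy())]
    raise ValueError(f"unknown variant {variant!r}")


def predict_rmsf_map(network, cryo_map: VoxelGrid, atomic_model: AtomicModel,
                     variant: str = "dual", resolution: float = 5.0,
                     spec: BoxSpec = BoxSpec(), voxel_size: float = 1.5,
                     batch: int = 8) -> PredictionResult:
    """Full inference pipeline: map + model -> RMSF map, atoms and residues.

    Resamples the map to 1.5 Å, simulates the model density on the same
    frame, builds the variant's channels, segments/screens/normalizes boxes
    using the model-derived occupancy, runs the network, merges the subboxes
    and reads out per-atom and per-residue values at nearest voxels.
    """
    from .nn import VARIANT_CHANNELS
    if variant not in VARIANT_CHANNELS or variant == "occ":
        raise ValueError(f"unknown prediction variant {variant!r}")
    expected = VARIANT_CHANNELS[variant]
    net_in = getattr(network, "config").in_channels
    if net_in != expected:
        raise ValueError(f"network takes {net_in} input channels but variant "
                         f"{variant!r} provides {expected}")
    grid = resample_to_voxel_size(cryo_map, voxel_size)
    simulated = simulate_density(atomic_model, grid, resolution)
    channels = build_variant_channels(variant, grid, simulated)
    occ = occupancy_annotation(atomic_model, grid)
    occ_mask = occ.values > 0
    boxes = segment_boxes(channels, labels=None, screen_mask=occ_mask, spec=spec)
    preds = []
    for chunk in _chunks(boxes, batch):
        x = np.stack([b.channels for b in chunk])
        out = network.predict(x)
        preds.extend((b.grid_index, out[i]) for i, b in enumerate(chunk))
    merged = merge_subboxes(preds, grid.shape, spec, grid.voxel_size, grid.origin)
    merged.mask &= occ_mask
    per_atom = np.zeros(atomic_model.n_atoms)
    for i, xyz in enumerate(atomic_model.coords):
        idx = world_to_voxel(grid, xyz)
        if idx is not None:
            per_atom[i] = merged.values.values[idx]
    keys, per_res = aggregate_to_residues(per_atom, atomic_model)
    return PredictionResult(merged, per_atom, keys, per_res)
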