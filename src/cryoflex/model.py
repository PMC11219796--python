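"""Model/Results facade over the full pipeline.

`FlexibilityModel` is built from a set of data entries (map + atomic model +
voxelized RMSF truth); ``fit`` trains the selected network variant and
returns a `FlexibilityResults` carrying the trained network, the training
history and evaluation utilities, with a ``summary()`` in the spirit of
statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boxing import BoxSpec, SampleBox, segment_boxes
from .density import occupancy_annotation, simulate_density
from .nn import (NetworkConfig, build_occ_network, build_rmsf_network,
                 compose_occ2rmsf, save_checkpoint)
from .synthetic import SyntheticEntry
from .train import (OccupancyObjective, RMSFObjective, TrainConfig,
                    TrainResult, build_variant_channels, evaluate_entry,
                    occ_metrics, predict_rmsf_map, summarize_correlations,
                    train)
from .voxel import resample_to_voxel_size

__all__ = ["FlexibilityModel", "FlexibilityResults", "entry_sample_boxes"]


def entry_sample_boxes(entry: SyntheticEntry, variant: str = "dual",
                       resolution: float = 5.0, spec: BoxSpec = BoxSpec(),
                       with_labels: bool = True) -> list[SampleBox]:
    """Segment one entry into screened, normalized training boxes."""
    grid = resample_to_voxel_size(entry.cryo_map, 1.5)
    simulated = simulate_density(entry.model, grid, resolution)
    channels = build_variant_channels(variant, grid, simulated)
    occ = occupancy_annotation(entry.model, grid)
    labels = entry.truth_map if with_labels else None
    screen = None if with_labels else occ.values > 0
    return segment_boxes(channels, labels=labels, screen_mask=screen,
                         spec=spec, occupancy=occ)


@dataclass
class FlexibilityModel:
    """Voxel flexibility model over a set of (map, model, truth) entries.

    Parameters
    ----------
    entries : list of SyntheticEntry
        The data the model is fitted on (and, by default, validated on).
    variant : str
        Input recipe: 'cryo' (map only), 'pdb' (simulated model map),
        'pdb01' (one-hot thresholded model map), 'dual' (map + model map),
        'occ' (occupancy classifier) or 'occ2rmsf' (two-stage).
    """

    entries: list
    variant: str = "dual"
    base_channels: int = 16
    resolution: float = 5.0
    box_spec: BoxSpec = field(default_factory=BoxSpec)
    seed: int = 0
    occ_stage: object = None  # trained OccClassifier for variant='occ2rmsf'

    def _network(self):
        config = NetworkConfig(variant=self.variant,
                               base_channels=self.base_channels, seed=self.seed)
        if self.variant == "occ":
            return build_occ_network(config)
        if self.variant == "occ2rmsf":
            if self.occ_stage is None:
                raise ValueError("variant 'occ2rmsf' needs a trained occ_stage")
            return compose_occ2rmsf(self.occ_stage, config)
        return build_rmsf_network(config)

    def _boxes(self, entries) -> list[SampleBox]:
        out = []
        for e in entries:
            out.extend(entry_sample_boxes(e, self.variant, self.resolution,
                                          self.box_spec))
        return out

    def fit(self, config: TrainConfig | None = None,
            train_entries: list | None = None,
            val_entries: list | None = None) -> "FlexibilityResults":
        """Train the network; defaults to a 3:1 entry-level train/val split."""
        config = config or TrainConfig(seed=self.seed)
        if train_entries is None or val_entries is None:
            rng = np.random.default_rng(config.seed)
            order = rng.permutation(len(self.entries))
            r = config.train_val_ratio
            n_val = max(1, (len(self.entries) * r[1]) // (r[0] + r[1]))
            val_entries = [self.entries[i] for i in order[:n_val]]
            train_entries = [self.entries[i] for i in order[n_val:]]
        network = self._network()
        if self.variant == "occ":
            objective = OccupancyObjective(network)
        else:
            objective = RMSFObjective(network)
        result = train(objective, self._boxes(train_entries),
                       self._boxes(val_entries), config)
        if self.variant == "occ":
            network.trained = True
        return FlexibilityResults(self, network, result, config,
                                  train_entries, val_entries)


@dataclass
class FlexibilityResults:
    """Fitted model: trained network + history + evaluation helpers."""

    model: FlexibilityModel
    network: object
    train_result: TrainResult
    config: TrainConfig
    train_entries: list
    val_entries: list
    _eval_table: pd.DataFrame | None = None

    def predict_entry(self, entry):
        """Full-pipeline RMSF prediction for one entry."""
        return predict_rmsf_map(self.network, entry.cryo_map, entry.model,
                                self.model.variant, self.model.resolution,
                                self.model.box_spec)

    def evaluate(self, entries) -> pd.DataFrame:
        """Per-entry voxel- and residue-level correlations against truth."""
        rows = []
        for e in entries:
            pred = self.predict_entry(e)
            scores = evaluate_entry(pred.rmsf_map, e.truth_map,
                                    pred.per_residue, e.residue_truth)
            rows.append({"entry": e.name, **scores})
        self._eval_table = pd.DataFrame(rows)
        return self._eval_table

    def evaluate_occupancy(self, entries) -> pd.DataFrame:
        """Precision/recall/F1 of the occupancy classifier on entries."""
        probs, truths = [], []
        for e in entries:
            boxes = entry_sample_boxes(e, "occ", self.model.resolution,
                                       self.model.box_spec)
            for b in boxes:
                probs.append(self.network.predict_proba(b.channels[None])[0])
                truths.append(b.occupancy)
        return occ_metrics(np.stack(probs), np.stack(truths))

    def save(self, path) -> None:
        save_checkpoint(self.network, path)

    def summary(self) -> str:
        h = self.train_result
        lines = [
            "Flexibility model fit",
            "=" * 44,
            f"variant:          {self.model.variant}",
            f"base channels:    {self.model.base_channels}",
            f"train entries:    {len(self.train_entries)}",
            f"val entries:      {len(self.val_entries)}",
            f"epochs run:       {len(h.history)}",
            f"best epoch:       {h.best_epoch}",
            f"best val loss:    {h.best_val_loss:.6f}",
            f"lr halvings at stagnant epochs: {h.lr_halvings or 'none'}",
        ]
        if self._eval_table is not None and len(self._eval_table):
            s = summarize_correlations(self._eval_table["voxel_cc"])
            lines += ["-" * 44,
                      f"voxel-level CC:   {s['mean']:.3f} "
                      f"(median {s['median']:.3f}, std {s['std']:.3f}, "
                      f"n={s['n']})"]
            if "residue_cc" in self._eval_table:
                s = summarize_correlations(self._eval_table["residue_cc"])
                lines.append(f"residue-level CC: {s['mean']:.3f} "
                             f"(median {s['median']:.3f}, std {s['std']:.3f})")
        return "\n".join(lines)

    def plot_profile(self, entry, ax=None):
        """Plot predicted vs true per-residue RMSF for one entry."""
        import matplotlib.pyplot as plt
        pred = self.predict_entry(entry)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(pred.per_residue, label="predicted")
        if entry.residue_truth is not None:
            ax.plot(entry.residue_truth, label="ensemble truth")
        ax.set_xlabel("residue")
        ax.set_ylabel("RMSF (Å)")
        ax.legend()
        return ax
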