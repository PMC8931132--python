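"""Net crop-area change between two epochs and its classification.

Epoch surfaces are 3-year means to damp short-term fluctuation from prices
or unusual weather.  Cell-level classification and buffer-level significance
both use strict inequalities: a change exactly equal to a threshold counts
as "none".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .buffers import BufferZone
from .synthetic import CropAreaGrid

__all__ = [
    "ChangeGrid",
    "epoch_mean",
    "net_change",
    "classify_change",
    "buffer_net_balance",
    "flag_significant",
    "SIGNIFICANCE_THRESHOLD_HA",
    "DISPLAY_MIN_HA",
    "CELL_CHANGE_THRESHOLD_HA",
]

DISPLAY_MIN_HA = 50.0  # minimum cropland per cell to display/classify
CELL_CHANGE_THRESHOLD_HA = 250.0  # |delta| beyond which a cell is classified
SIGNIFICANCE_THRESHOLD_HA = {"rice": 15_000.0, "maize": 10_000.0}  # buffer net balance

CONTRACTING, EXPANDING, NONE = "contracting", "expanding", "none"


@dataclass(frozen=True)
class ChangeGrid:
    """Cell-wise net area change with display mask and 3-way classification."""

    delta: np.ndarray  # ha per cell, positive = expansion
    display_mask: np.ndarray  # cells with enough cropland to classify
    change_class: np.ndarray  # object array of {contracting, expanding, none}

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.change_class, return_counts=True)
        return {str(l): int(c) for l, c in zip(labels, counts)}


def epoch_mean(yearly_grids: np.ndarray | CropAreaGrid) -> np.ndarray:
    """Cell-wise arithmetic mean over a (n_years, rows, cols) stack."""
    if isinstance(yearly_grids, CropAreaGrid):
        return yearly_grids.epoch_mean()
    stack = np.asarray(yearly_grids, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (n_years, rows, cols) stack")
    return stack.mean(axis=0)


def net_change(epoch2_mean: np.ndarray, epoch1_mean: np.ndarray) -> np.ndarray:
    """Cell-wise epoch2 - epoch1 (ha); positive means expansion."""
    a = np.asarray(epoch2_mean, dtype=float)
    b = np.asarray(epoch1_mean, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a - b


def classify_change(
    delta: np.ndarray,
    epoch_area: np.ndarray,
    display_min: float = DISPLAY_MIN_HA,
    change_threshold: float = CELL_CHANGE_THRESHOLD_HA,
) -> ChangeGrid:
    """Classify displayed cells as contracting / expanding / none.

    ``epoch_area`` (the epoch-1 mean, i.e. the pre-conversion surface)
    gates the display mask at ``display_min``; classification then applies
    strict |delta| > ``change_threshold``.
    """
    if display_min < 0 or change_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    delta = np.asarray(delta, dtype=float)
    epoch_area = np.asarray(epoch_area, dtype=float)
    if delta.shape != epoch_area.shape:
        raise ValueError("delta and epoch_area shapes differ")
    mask = epoch_area >= display_min
    cls = np.full(delta.shape, NONE, dtype=object)
    cls[mask & (delta > change_threshold)] = EXPANDING
    cls[mask & (delta < -change_threshold)] = CONTRACTING
    return ChangeGrid(delta=delta, display_mask=mask, change_class=cls)


def buffer_net_balance(delta: np.ndarray, buffer: BufferZone) -> float:
    """Net area balance of a buffer: sum of delta over its member cells (ha)."""
    delta = np.asarray(delta, dtype=float)
    nr, nc = delta.shape
    for r, c in buffer.member_cells:
        if not (0 <= r < nr and 0 <= c < nc):
            raise ValueError(f"buffer cell {(r, c)} outside grid {delta.shape}")
    return float(sum(delta[r, c] for r, c in buffer.member_cells))


def flag_significant(balance_ha: float, crop: str) -> str:
    """Flag a buffer's net balance against the crop-specific significance
    threshold (15 000 ha rice, 10 000 ha maize), strict inequalities."""
    try:
        threshold = SIGNIFICANCE_THRESHOLD_HA[crop]
    except KeyError:
        raise ValueError(f"unknown crop: {crop!r}") from None
    if balance_ha > threshold:
        return EXPANDING
    if balance_ha < -threshold:
        return CONTRACTING
    return NONE
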