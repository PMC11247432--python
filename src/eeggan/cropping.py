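"""Sliding-window (cropped) expansion of trials and crop-prediction pooling.

Cropped training turns each (C, T) trial into k overlapping (C, window)
segments that inherit the trial's label, multiplying the effective training
set size; at evaluation time the classifier's per-crop class probabilities
are averaged back into a single per-trial distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_pipeline import EEGEpochs

__all__ = ["CropSpec", "CroppedBatch", "crop_epochs", "aggregate_crop_predictions"]


@dataclass
class CropSpec:
    window: int = 500
    step: int = 125

    def validate(self, n_times: int) -> None:
        if not 1 <= self.window <= n_times:
            raise ValueError(f"window {self.window} outside [1, {n_times}]")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    def n_crops(self, n_times: int) -> int:
        return (n_times - self.window) // self.step + 1

    def starts(self, n_times: int) -> np.ndarray:
        return np.arange(self.n_crops(n_times)) * self.step


@dataclass
class CroppedBatch:
    """Crops (n_trials, k, C, window); every crop shares its trial's label.

    `crops` is a strided view into the source trials (no 6x copy); consumers
    must treat it as read-only.
    """

    crops: np.ndarray
    labels: np.ndarray
    crop_starts: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.crops.shape[0]

    @property
    def k(self) -> int:
        return self.crops.shape[1]


def crop_epochs(epochs: EEGEpochs, spec: CropSpec) -> CroppedBatch:
    """Expand trials into sliding windows at starts 0, step, 2*step, ...

    Trailing samples that do not fill a whole window are dropped, so all
    crops are uniform; with T=1125, window=500, step=125 each trial yields
    exactly 6 crops.
    """
    spec.validate(epochs.n_times)
    starts = spec.starts(epochs.n_times)
    # one strided view over all windows, subsampled to the stepped starts
    windows = np.lib.stride_tricks.sliding_window_view(
        epochs.data, spec.window, axis=-1
    )  # (n, C, T-window+1, window)
    crops = windows[:, :, starts, :].transpose(0, 2, 1, 3)
    return CroppedBatch(crops, epochs.labels.copy(), starts)


def aggregate_crop_predictions(per_crop_probs: np.ndarray) -> np.ndarray:
    """Average class probabilities over the crop axis (rows of shape (k, n_c))."""
    per_crop_probs = np.asarray(per_crop_probs, dtype=np.float64)
    if per_crop_probs.ndim != 2 or per_crop_probs.shape[0] == 0:
        raise ValueError("need a non-empty (k, n_c) array of crop probabilities")
    return per_crop_probs.mean(axis=0)
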