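"""Loading, filtering, epoching and normalization of motor-imagery EEG.

Every downstream stage consumes :class:`EEGEpochs`: a stack of fixed-length
(channels x time) trials with integer class labels.  The preprocessing chain
is the conventional one for motor-imagery decoding: an FIR bandpass focused
on the mu/beta rhythms, cue-locked epoching, and a normalization whose
statistics are fitted on training data only and reused on held-out data.

Because the downstream generator ends in a Tanh, the default normalization
("tanh") maps each channel's training-set range onto [-1, 1]; a per-channel
z-score is available as the alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import firwin, filtfilt

logger = logging.getLogger("eeggan")

__all__ = [
    "EEGEpochs",
    "PreprocessSpec",
    "NormStats",
    "bandpass_blackman",
    "extract_epochs",
    "normalize",
    "denormalize",
    "save_bundle",
    "load_bundle",
    "load_gdf",
]


@dataclass
class EEGEpochs:
    """Labeled multichannel EEG trials: data (n_trials, C, T)."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    n_c: int
    generated_mask: np.ndarray | None = None  # True where a trial is synthetic

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"data must be (n_trials, C, T), got shape {self.data.shape}")
        n, c, _ = self.data.shape
        if self.labels.shape != (n,):
            raise ValueError("labels must be one integer per trial")
        if c != len(self.channel_names):
            raise ValueError(
                f"{c} data channels but {len(self.channel_names)} channel names"
            )
        if n and (self.labels.min() < 0 or self.labels.max() >= self.n_c):
            raise ValueError(f"labels must lie in [0, {self.n_c})")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def subset(self, idx: np.ndarray) -> "EEGEpochs":
        mask = None if self.generated_mask is None else self.generated_mask[idx]
        return replace(
            self, data=self.data[idx], labels=self.labels[idx], generated_mask=mask
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_c)


@dataclass
class PreprocessSpec:
    """FIR bandpass + epoching + normalization parameters.

    filter_order is the FIR order (taps = order + 1).  Band corners default
    to 4-38 Hz, covering the mu (8-13 Hz) and beta (18-26 Hz) rhythms that
    carry motor-imagery information while rejecting drift and line noise.
    """

    filter_order: int = 200
    band_lo: float = 4.0
    band_hi: float = 38.0
    window_kind: str = field(default="blackman")  # fixed; kept for the record
    epoch_start_offset: float = 0.5
    epoch_duration: float = 4.5
    normalization: str = "tanh"  # "tanh" or "zscore"

    def validate(self, fs: float) -> None:
        if not 0 < self.band_lo < self.band_hi < fs / 2:
            raise ValueError(
                f"band [{self.band_lo}, {self.band_hi}] Hz invalid for fs={fs} Hz"
            )
        if self.normalization not in ("tanh", "zscore"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        n = self.epoch_duration * fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_duration x fs must be an integer sample count")

    def n_epoch_samples(self, fs: float) -> int:
        return int(round(self.epoch_duration * fs))


def design_bandpass(fs: float, spec: PreprocessSpec) -> np.ndarray:
    """Blackman-window FIR bandpass taps (order + 1 of them)."""
    spec.validate(fs)
    return firwin(
        spec.filter_order + 1,
        [spec.band_lo, spec.band_hi],
        pass_zero=False,
        window="blackman",
        fs=fs,
    )


def bandpass_blackman(
    signal: np.ndarray, fs: float, spec: PreprocessSpec | None = None
) -> np.ndarray:
    """Zero-phase Blackman-window FIR bandpass of a (C, T) continuous record.

    Applied forward-backward so cue-locked epoch timing is not shifted; the
    effective magnitude response is the square of the designed FIR response.
    """
    spec = spec or PreprocessSpec()
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    if signal.shape[-1] <= spec.filter_order:
        raise ValueError(
            f"signal length {signal.shape[-1]} must exceed filter order "
            f"{spec.filter_order}"
        )
    taps = design_bandpass(fs, spec)
    padlen = min(3 * spec.filter_order, signal.shape[-1] - 1)
    return filtfilt(taps, [1.0], signal, axis=-1, padlen=padlen)


def extract_epochs(
    continuous: np.ndarray,
    events: list[tuple[int, int]],
    spec: PreprocessSpec,
    fs: float,
    channel_names: list[str] | None = None,
    n_c: int | None = None,
) -> EEGEpochs:
    """Cut cue-locked trials out of a (C, T_raw) record.

    Each event is (cue_sample, label); the trial covers
    [cue + offset, cue + offset + duration).  Events whose window exceeds the
    record are rejected with a warning rather than raising.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=np.float64))
    c, t_raw = continuous.shape
    offset = int(round(spec.epoch_start_offset * fs))
    n_samp = spec.n_epoch_samples(fs)
    trials, labels = [], []
    for sample, label in events:
        start = int(sample) + offset
        stop = start + n_samp
        if start < 0 or stop > t_raw:
            logger.warning(
                "event at sample %d: window [%d, %d) outside record of %d samples; skipped",
                sample, start, stop, t_raw,
            )
            continue
        trials.append(continuous[:, start:stop])
        labels.append(int(label))
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(c)]
    if n_c is None:
        n_c = (max(labels) + 1) if labels else 1
    data = np.stack(trials) if trials else np.empty((0, c, n_samp))
    return EEGEpochs(data, np.array(labels, dtype=np.int64), fs, list(channel_names), n_c)


@dataclass
class NormStats:
    """Fitted normalization statistics; enough to invert the transform."""

    mode: str
    offset: np.ndarray  # per-channel, shape (C,)
    scale: np.ndarray  # per-channel, shape (C,)

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (data - self.offset[:, None]) / self.scale[:, None]

    def inverse(self, data: np.ndarray) -> np.ndarray:
        return data * self.scale[:, None] + self.offset[:, None]


_EPS_SCALE = 1e-12


def fit_norm_stats(epochs: EEGEpochs, mode: str) -> NormStats:
    flat = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    if mode == "zscore":
        offset = flat.mean(axis=1)
        scale = flat.std(axis=1)
    elif mode == "tanh":
        lo, hi = flat.min(axis=1), flat.max(axis=1)
        offset = (hi + lo) / 2.0  # midpoint -> 0, extremes -> +/-1
        scale = (hi - lo) / 2.0
    else:
        raise ValueError(f"unknown normalization {mode!r}")
    degenerate = scale < _EPS_SCALE
    if degenerate.any():
        logger.warning(
            "normalization: %d zero-variance channel(s); scale floored", degenerate.sum()
        )
        scale = np.where(degenerate, _EPS_SCALE, scale)
    return NormStats(mode, offset, scale)


def normalize(
    epochs: EEGEpochs,
    spec: PreprocessSpec | None = None,
    stats_from: EEGEpochs | NormStats | None = None,
) -> tuple[EEGEpochs, NormStats]:
    """Normalize trials; fit statistics on `stats_from` (or on `epochs` itself).

    Fitting on the training split and passing the returned stats for the test
    split avoids information leakage across the split.
    """
    spec = spec or PreprocessSpec()
    if isinstance(stats_from, NormStats):
        stats = stats_from
    else:
        ref = stats_from if stats_from is not None else epochs
        if ref.n_channels != epochs.n_channels:
            raise ValueError("stats_from channel count does not match")
        stats = fit_norm_stats(ref, spec.normalization)
    out = replace(epochs, data=stats.transform(epochs.data))
    return out, stats


def denormalize(epochs: EEGEpochs, stats: NormStats) -> EEGEpochs:
    return replace(epochs, data=stats.inverse(epochs.data))


# ---------------------------------------------------------------------------
# Fixture bundle I/O (NPZ with named arrays)
# ---------------------------------------------------------------------------


def save_bundle(path, epochs: EEGEpochs) -> None:
    np.savez(
        path,
        data=epochs.data,
        labels=epochs.labels,
        fs=np.float64(epochs.fs),
        channel_names=np.array(epochs.channel_names),
        n_c=np.int64(epochs.n_c),
    )


def load_bundle(path) -> EEGEpochs:
    with np.load(path, allow_pickle=False) as z:
        return EEGEpochs(
            z["data"],
            z["labels"],
            float(z["fs"]),
            [str(s) for s in z["channel_names"]],
            int(z["n_c"]),
        )


def load_gdf(path, stim_prefix: str = "769"):
    """Optional adapter for GDF/EDF recordings (BCI Competition IV distribution).

    Returns (continuous (C, T) array, events [(sample, label)], fs,
    channel_names).  Labels are assigned by order of appearance of the
    annotation descriptions starting at `stim_prefix` codes; callers needing a
    specific mapping should remap.  Requires the optional mne dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - exercised only with extras
        raise ImportError("reading GDF files requires the 'gdf' extra (mne)") from exc

    reader = mne.io.read_raw_edf if str(path).lower().endswith(".edf") else mne.io.read_raw_gdf
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data()
    fs = float(raw.info["sfreq"])
    onsets = (raw.annotations.onset * fs).round().astype(int)
    descs = list(raw.annotations.description)
    codes = sorted({d for d in descs if d.startswith(stim_prefix[0]) and d >= stim_prefix})
    code_to_label = {c: i for i, c in enumerate(codes)}
    events = [
        (int(s), code_to_label[d]) for s, d in zip(onsets, descs) if d in code_to_label
    ]
    return data, events, fs, list(raw.info["ch_names"])
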