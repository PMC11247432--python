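"""Surrogate motor-imagery EEG sessions with known class structure.

Each class is given a signature: a narrow-band oscillation (mu/beta range)
with a fixed channel topography, mimicking the lateralized sensorimotor
rhythm modulations that real motor-imagery decoders exploit.  Trials are the
class oscillation (random phase per trial) added to 1/f Gaussian background
noise, at a configurable oscillation-to-noise power ratio (snr).

The signature constants are fixture choices, not physiological claims; they
make every downstream stage of the pipeline testable without recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_pipeline import EEGEpochs

__all__ = [
    "ClassSignature",
    "SyntheticSessionSpec",
    "session_spec_2a",
    "session_spec_2b",
    "generate_session",
    "separability_check",
    "calibrate_snr",
]


@dataclass
class ClassSignature:
    """One class's oscillatory fingerprint."""

    freq: float  # center frequency, Hz
    topography: np.ndarray  # per-channel weights, length n_channels
    amplitude: float = 1.0

    def __post_init__(self):
        self.topography = np.asarray(self.topography, dtype=np.float64)


@dataclass
class SyntheticSessionSpec:
    n_channels: int
    n_classes: int
    class_signatures: list[ClassSignature]
    trials_per_class: int = 72
    fs: float = 250.0
    duration: float = 4.5
    noise_exponent: float = 1.0
    snr: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        if len(self.class_signatures) != self.n_classes:
            raise ValueError("need one signature per class")
        for sig in self.class_signatures:
            if sig.topography.shape != (self.n_channels,):
                raise ValueError("topography length must equal n_channels")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs x duration must be an integer sample count")

    @property
    def n_times(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def n_trials(self) -> int:
        return self.n_classes * self.trials_per_class


def _bump(n_channels: int, center: float, width: float) -> np.ndarray:
    """Smooth topography bump over the channel index axis."""
    x = np.linspace(0.0, 1.0, n_channels)
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def session_spec_2a(**overrides) -> SyntheticSessionSpec:
    """22-channel, 4-class session (left hand / right hand / foot / tongue like).

    Hand classes are mu-band with opposite lateralization; foot and tongue
    classes use midline/frontal bumps at beta-band frequencies.
    """
    sigs = [
        ClassSignature(10.0, _bump(22, 0.72, 0.14)),  # left hand -> right hemisphere
        ClassSignature(12.0, _bump(22, 0.28, 0.14)),  # right hand -> left hemisphere
        ClassSignature(20.0, _bump(22, 0.50, 0.12)),  # foot -> midline
        ClassSignature(24.0, _bump(22, 0.10, 0.18)),  # tongue -> frontal
    ]
    kw = dict(n_channels=22, n_classes=4, class_signatures=sigs)
    kw.update(overrides)
    return SyntheticSessionSpec(**kw)


def session_spec_2b(**overrides) -> SyntheticSessionSpec:
    """3-channel (C3, Cz, C4), 2-class session (left vs right hand like)."""
    sigs = [
        ClassSignature(10.0, np.array([0.2, 0.35, 1.0])),  # left hand -> C4
        ClassSignature(12.0, np.array([1.0, 0.35, 0.2])),  # right hand -> C3
    ]
    kw = dict(n_channels=3, n_classes=2, class_signatures=sigs)
    kw.update(overrides)
    return SyntheticSessionSpec(**kw)


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_times: int, exponent: float
) -> np.ndarray:
    """Unit-power Gaussian noise with power spectrum proportional to 1/f^exponent."""
    n_freq = n_times // 2 + 1
    shaping = np.zeros(n_freq)
    shaping[1:] = np.arange(1, n_freq, dtype=np.float64) ** (-exponent / 2.0)
    spectrum = (
        rng.normal(size=(n_channels, n_freq)) + 1j * rng.normal(size=(n_channels, n_freq))
    ) * shaping
    noise = np.fft.irfft(spectrum, n=n_times, axis=-1)
    power = (noise**2).mean()
    return noise / np.sqrt(power) if power > 0 else noise


def generate_session(spec: SyntheticSessionSpec) -> EEGEpochs:
    """Draw one session: n_classes x trials_per_class labeled trials.

    Deterministic in spec.seed; per-trial generators are spawned from a
    single root SeedSequence so trial draws are independent but reproducible.
    """
    n_t = spec.n_times
    t = np.arange(n_t) / spec.fs
    labels = np.repeat(np.arange(spec.n_classes), spec.trials_per_class)
    root = np.random.SeedSequence(spec.seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    order = order_rng.permutation(spec.n_trials)
    labels = labels[order]
    trial_seeds = root.spawn(spec.n_trials)

    # mean oscillatory power per channel for a unit-amplitude class, used to
    # place the oscillation at the requested power ratio against unit noise
    data = np.empty((spec.n_trials, spec.n_channels, n_t))
    for i, (label, seed) in enumerate(zip(labels, trial_seeds)):
        rng = np.random.default_rng(seed)
        sig = spec.class_signatures[label]
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * sig.freq * t + phase)
        trial = (sig.amplitude * sig.topography)[:, None] * osc[None, :]
        if np.isinf(spec.snr):
            data[i] = trial
            continue
        osc_power = (trial**2).mean()
        noise = _one_over_f_noise(rng, spec.n_channels, n_t, spec.noise_exponent)
        if spec.snr <= 0:
            data[i] = noise
        else:
            data[i] = trial * np.sqrt(spec.snr / osc_power) + noise
    names = (
        ["C3", "Cz", "C4"]
        if spec.n_channels == 3
        else [f"ch{i}" for i in range(spec.n_channels)]
    )
    return EEGEpochs(data, labels, spec.fs, names, spec.n_classes)


def _band_power_features(
    epochs: EEGEpochs, spec: SyntheticSessionSpec, half_width: float = 2.0
) -> np.ndarray:
    """Per-trial feature vector: topography-projected band power per class signature."""
    n_t = epochs.n_times
    freqs = np.fft.rfftfreq(n_t, d=1.0 / epochs.fs)
    power = np.abs(np.fft.rfft(epochs.data, axis=-1)) ** 2
    feats = np.empty((epochs.n_trials, spec.n_classes))
    for k, sig in enumerate(spec.class_signatures):
        band = (freqs >= sig.freq - half_width) & (freqs <= sig.freq + half_width)
        band_power = power[:, :, band].sum(axis=-1)  # (n_trials, C)
        feats[:, k] = band_power @ sig.topography
    return np.log1p(feats)


def separability_check(epochs: EEGEpochs, spec: SyntheticSessionSpec) -> float:
    """Accuracy of a trivial band-power nearest-centroid rule on a half split.

    Deliberately weak: used to calibrate snr so the classes are learnable
    without being trivially separable for the actual models.
    """
    feats = _band_power_features(epochs, spec)
    train = np.arange(epochs.n_trials) % 2 == 0
    centroids = np.stack(
        [feats[train & (epochs.labels == k)].mean(axis=0) for k in range(spec.n_classes)]
    )
    d = ((feats[~train, None, :] - centroids[None, :, :]) ** 2).sum(axis=-1)
    pred = d.argmin(axis=1)
    return float((pred == epochs.labels[~train]).mean())


def calibrate_snr(
    make_spec,
    target: float = 0.8,
    seeds: tuple[int, ...] = (0, 1, 2),
    lo: float = 1e-3,
    hi: float = 10.0,
    iters: int = 12,
) -> float:
    """Bisect snr until the band-power rule hits `target` mean accuracy.

    `make_spec(snr, seed)` must return a SyntheticSessionSpec.  Accuracy is
    averaged over `seeds`; monotonicity of accuracy in snr (up to sampling
    noise) makes bisection appropriate.
    """

    def acc(snr: float) -> float:
        vals = []
        for s in seeds:
            spec = make_spec(snr, s)
            vals.append(separability_check(generate_session(spec), spec))
        return float(np.mean(vals))

    for _ in range(iters):
        mid = np.sqrt(lo * hi)  # snr acts multiplicatively; bisect in log space
        if acc(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
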