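"""Classification metrics, generation-quality scores, and run statistics.

Generation quality is scored by comparing amplitude distributions of real
and generated trials: an inverted two-sample Kolmogorov-Smirnov statistic
(1 - D, so 1 means indistinguishable CDFs) and a histogram-based KL
divergence (0 means identical binned distributions).  Distributions are
compared per class and channel on samples pooled across trials, then
averaged.  Classifier performance is accuracy and Cohen's kappa; repeated
runs are compared with Wilcoxon signed-rank tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from .data_pipeline import EEGEpochs

logger = logging.getLogger("eeggan")

__all__ = [
    "SimilarityReport",
    "RunSummary",
    "accuracy_and_kappa",
    "ks_similarity",
    "kl_divergence",
    "similarity_report",
    "wilcoxon_signed_rank",
    "repeated_runs",
]


@dataclass
class SimilarityReport:
    """Real-vs-generated distribution scores (averages over class x channel)."""

    ks_score: float  # 1 - KS D statistic; 1 = identical CDFs
    ks_d: float  # the raw D statistic, co-reported
    kl_divergence: float  # >= 0; 0 = identical on the binning
    n_real: int
    n_gen: int
    n_bins: int


@dataclass
class RunSummary:
    accuracies: np.ndarray
    kappas: np.ndarray
    seeds: list[int]
    failed_seeds: list[int]

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracies.max())

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def best_kappa(self) -> float:
        return float(self.kappas.max())

    @property
    def mean_kappa(self) -> float:
        return float(self.kappas.mean())


def accuracy_and_kappa(predicted, true, n_c: int) -> tuple[float, float]:
    """Fraction correct and Cohen's kappa (chance-corrected agreement)."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape or predicted.size == 0:
        raise ValueError("predicted and true labels must be equal-length, non-empty")
    acc = float((predicted == true).mean())
    labels = np.arange(n_c)
    # degenerate case: both sides constant and equal -> p_e = 1
    if len(np.unique(true)) == 1 and np.array_equal(np.unique(predicted), np.unique(true)):
        logger.warning("kappa undefined (expected agreement 1); reporting 0")
        return acc, 0.0
    kappa = float(cohen_kappa_score(true, predicted, labels=labels))
    return acc, kappa


def ks_similarity(real_samples, gen_samples) -> float:
    """1 - D, D the two-sample KS statistic on the flattened amplitude samples."""
    real = np.asarray(real_samples).ravel()
    gen = np.asarray(gen_samples).ravel()
    if real.size == 0 or gen.size == 0:
        raise ValueError("both sample sets must be non-empty")
    d = sps.ks_2samp(real, gen).statistic
    return float(1.0 - d)


def kl_divergence(real_samples, gen_samples, n_bins: int = 100,
                  eps: float = 1e-10) -> float:
    """sum_b p_real ln(p_real / p_gen) on a shared equal-width binning.

    Bins cover the pooled range of both sample sets; empty bins are smoothed
    with ``eps`` before renormalization.
    """
    real = np.asarray(real_samples).ravel()
    gen = np.asarray(gen_samples).ravel()
    lo = min(real.min(), gen.min())
    hi = max(real.max(), gen.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p = np.histogram(real, bins=edges)[0].astype(float) + eps
    q = np.histogram(gen, bins=edges)[0].astype(float) + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def similarity_report(real: EEGEpochs, gen: EEGEpochs, n_bins: int = 100) -> SimilarityReport:
    """Average KS/KL scores over (class, channel) amplitude distributions.

    For each class and channel, samples are pooled across that class's
    trials; classes present in only one of the two sets are skipped.
    """
    ks_vals, kl_vals = [], []
    for k in range(real.n_c):
        r_k = real.data[real.labels == k]
        g_k = gen.data[gen.labels == k]
        if len(r_k) == 0 or len(g_k) == 0:
            continue
        for c in range(real.n_channels):
            r = r_k[:, c, :].ravel()
            g = g_k[:, c, :].ravel()
            ks_vals.append(1.0 - sps.ks_2samp(r, g).statistic)
            kl_vals.append(kl_divergence(r, g, n_bins))
    if not ks_vals:
        raise ValueError("no class is present in both sets")
    ks = float(np.mean(ks_vals))
    return SimilarityReport(
        ks_score=ks,
        ks_d=1.0 - ks,
        kl_divergence=float(np.mean(kl_vals)),
        n_real=real.n_trials,
        n_gen=gen.n_trials,
        n_bins=n_bins,
    )


def wilcoxon_signed_rank(paired_a, paired_b, alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank p-value on paired performance values.

    Exact null distribution for small samples without ties, normal
    approximation otherwise (scipy's default policy).  ``alternative`` may be
    "two-sided", "greater" (a > b) or "less".
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired samples must be equal-length and non-empty")
    if np.allclose(a, b):
        logger.warning("all paired differences are zero; p = 1")
        return 1.0
    res = sps.wilcoxon(a, b, alternative=alternative, zero_method="wilcox")
    return float(res.pvalue)


def repeated_runs(run_fn, seeds) -> RunSummary:
    """Run `run_fn(seed) -> {"accuracy": .., "kappa": ..}` over seeds.

    Crashing runs are logged, excluded from the summary and reported in
    ``failed_seeds``.
    """
    accs, kappas, ok, failed = [], [], [], []
    for seed in seeds:
        try:
            out = run_fn(seed)
        except Exception:
            logger.exception("run with seed %d failed; excluded", seed)
            failed.append(seed)
            continue
        accs.append(out["accuracy"])
        kappas.append(out["kappa"])
        ok.append(seed)
    if not accs:
        raise RuntimeError("all runs failed")
    return RunSummary(np.array(accs), np.array(kappas), ok, failed)
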