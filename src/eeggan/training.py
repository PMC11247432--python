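"""GAN training, class-balanced augmentation, and cropped classifier training.

The end-to-end flow: preprocess real (or surrogate) trials into the tanh
range, train the conditional GAN (alternating least-squares discriminator and
feature-matching generator steps), synthesize a class-balanced set of extra
trials (half the original count by default), and train the classifier — the
discriminator architecture with a softmax head, freshly initialized by
default (optionally fine-tuning the trained discriminator body) — on the
augmented set with cropped sliding windows, scoring held-out trials by
crop-averaged probabilities.

Three ablation switches mirror the framework's components: ``use_cgan``
(augmentation), ``use_cropping`` (sliding windows vs full trials) and
``use_se`` (the SE block in a freshly built classifier).  With all three off
the pipeline reduces to plain EEGNet-style training.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .architecture import (
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    encode_label,
    condition_input,
    sample_latent,
    save_checkpoint,
    to_classifier,
)
from .cropping import CropSpec, crop_epochs
from .data_pipeline import EEGEpochs, PreprocessSpec, normalize
from .losses import (
    GanLossTerms,
    basic_generator_loss,
    cropped_loss_batch,
    discriminator_loss,
    feature_matching_loss,
    generator_loss,
)

logger = logging.getLogger("eeggan")


def _run_in_float32(fn):
    """Run a training/inference loop under float32 (halves memory traffic)."""

    @functools.wraps(fn)
    def wrapper(*args, **kwargs):
        with nn.use_dtype(np.float32):
            return fn(*args, **kwargs)

    return wrapper

__all__ = [
    "TrainConfig",
    "TrainState",
    "train_gan",
    "augment_dataset",
    "train_classifier",
    "predict_proba",
    "predict_labels",
    "run_pipeline",
]


@dataclass
class TrainConfig:
    gan_epochs: int = 25
    clf_epochs: int = 12
    batch_size: int = 64
    lr_gan: float = 2e-4
    betas_gan: tuple[float, float] = (0.5, 0.999)
    lr_clf: float = 1e-3
    betas_clf: tuple[float, float] = (0.9, 0.999)
    seed: int = 0
    augmentation_ratio: float = 0.5
    lam: float = 0.5
    disc_steps: int = 1  # discriminator updates per generator update
    focal: bool = False
    device: str = "cpu"  # descriptor only; execution is numpy on CPU
    # ablation switches
    use_cgan: bool = True
    use_cropping: bool = True
    use_se: bool = True
    crop_discriminator: bool = False  # crop windows also during GAN training
    # classifier body: fresh by default; True fine-tunes the trained
    # discriminator instead (supported, but transfers poorly at small scale)
    share_gan_body: bool = False

    def validate(self) -> None:
        if self.augmentation_ratio < 0:
            raise ValueError("augmentation_ratio must be >= 0")
        if self.gan_epochs < 1 or self.clf_epochs < 1:
            raise ValueError("epoch counts must be >= 1")


@dataclass
class TrainState:
    """Per-step loss history and bookkeeping of one training run."""

    seed: int
    gan_losses: list[GanLossTerms] = field(default_factory=list)
    clf_losses: list[float] = field(default_factory=list)
    gan_epochs_done: int = 0
    clf_epochs_done: int = 0
    checkpoints: dict[str, str] = field(default_factory=dict)

    def gan_loss_array(self) -> np.ndarray:
        """(n_steps, 4) array of [L_M, L_F, L_G, L_D]."""
        return np.array(
            [[t.L_M, t.L_F, t.L_G, t.L_D] for t in self.gan_losses]
        ).reshape(-1, 4)

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step,L_M,L_F,L_G,L_D\n")
            for i, t in enumerate(self.gan_losses):
                fh.write(f"{i},{t.L_M:.6g},{t.L_F:.6g},{t.L_G:.6g},{t.L_D:.6g}\n")


def _condition_tensor(x: nn.Tensor, labels: np.ndarray, n_c: int) -> nn.Tensor:
    """Tensor version of label conditioning: append the encoded-label column."""
    n, c, _ = x.shape
    code = encode_label(labels, n_c)
    col = nn.Tensor(np.broadcast_to(code[:, None, None], (n, c, 1)).copy())
    return nn.concat([x, col], axis=-1)


def _check_finite(value: float, name: str, state: TrainState) -> None:
    if not np.isfinite(value):
        logger.error("divergence: %s is %r; %d GAN steps recorded",
                     name, value, len(state.gan_losses))
        raise FloatingPointError(
            f"{name} became non-finite after {len(state.gan_losses)} steps"
        )


@_run_in_float32
def train_gan(
    epochs: EEGEpochs,
    gcfg: GeneratorConfig | None = None,
    dcfg: DiscriminatorConfig | None = None,
    tcfg: TrainConfig | None = None,
    crop: CropSpec | None = None,
    run_dir=None,
) -> tuple[Generator, Discriminator, TrainState]:
    """Alternate least-squares discriminator and feature-matching generator steps.

    Expects trials already in the tanh range.  Latent noise statistics
    (mu, sigma) are estimated from the training data.  Deterministic given
    tcfg.seed.
    """
    tcfg = tcfg or TrainConfig()
    tcfg.validate()
    epochs.validate()
    if np.bincount(epochs.labels, minlength=epochs.n_c).min() == 0:
        raise ValueError("every class must be present in the GAN training set")

    data, labels = epochs.data, epochs.labels
    n_c, c = epochs.n_c, epochs.n_channels
    if tcfg.crop_discriminator:
        crop = crop or CropSpec()
        d_time = crop.window + 1
    else:
        d_time = epochs.n_times + 1

    gcfg = gcfg or GeneratorConfig(out_channels=c, n_c=n_c)
    dcfg = dcfg or DiscriminatorConfig(in_channels=c, input_time=d_time,
                                       n_c=n_c, use_se=tcfg.use_se)
    root = np.random.SeedSequence(tcfg.seed)
    seeds = root.generate_state(4) % (2**31)
    G = Generator(gcfg, np.random.default_rng(int(seeds[0])))
    D = Discriminator(dcfg, np.random.default_rng(int(seeds[1])))
    rng = np.random.default_rng(int(seeds[2]))
    mu, sigma = float(data.mean()), float(data.std())

    opt_d = nn.Adam(D.parameters(), lr=tcfg.lr_gan, betas=tcfg.betas_gan)
    opt_g = nn.Adam(G.parameters(), lr=tcfg.lr_gan, betas=tcfg.betas_gan)
    state = TrainState(seed=tcfg.seed)
    n = len(labels)
    bs = min(tcfg.batch_size, n)

    for epoch in range(tcfg.gan_epochs):
        order = rng.permutation(n)
        for start in range(0, n - 1, bs):  # drop size-1 remainders (batchnorm)
            idx = order[start : start + bs]
            if len(idx) < 2:
                continue
            x_real = data[idx]
            l_real = labels[idx]
            if tcfg.crop_discriminator:
                starts = rng.choice(crop.starts(epochs.n_times), size=len(idx))
                x_real = np.stack(
                    [x_real[i, :, s : s + crop.window] for i, s in enumerate(starts)]
                )
            cond_real = nn.Tensor(condition_input(x_real, l_real, n_c))

            # --- discriminator step(s): push real -> 1, generated -> 0 ----
            for _ in range(tcfg.disc_steps):
                latent = sample_latent(len(idx), (mu, sigma), n_c, rng,
                                       gcfg.latent_dim)
                fake = G.generate(latent)
                if tcfg.crop_discriminator:
                    s = int(rng.choice(crop.starts(gcfg.out_length)))
                    fake = fake.narrow(-1, s, crop.window)
                cond_fake = _condition_tensor(fake.detach(), latent.labels, n_c)
                D.zero_grad()
                l_d = discriminator_loss(D(cond_real), D(cond_fake))
                l_d.backward()
                opt_d.step()

            # --- generator step: fool D and match its features ------------
            latent = sample_latent(len(idx), (mu, sigma), n_c, rng, gcfg.latent_dim)
            fake = G.generate(latent)
            if tcfg.crop_discriminator:
                s = int(rng.choice(crop.starts(gcfg.out_length)))
                fake = fake.narrow(-1, s, crop.window)
            cond_fake = _condition_tensor(fake, latent.labels, n_c)
            G.zero_grad()
            D.zero_grad()  # gradients flow through D but are not applied
            scores, feats_fake = D(cond_fake, return_features=True)
            feats_real = D.features(cond_real).detach()
            l_m = basic_generator_loss(scores)
            l_f = feature_matching_loss(feats_real, feats_fake)
            l_g = generator_loss(l_m, l_f, tcfg.lam)
            l_g.backward()
            opt_g.step()

            terms = GanLossTerms(l_m.item(), l_f.item(), l_g.item(), l_d.item())
            state.gan_losses.append(terms)
            _check_finite(terms.L_D, "L_D", state)
            _check_finite(terms.L_G, "L_G", state)
        state.gan_epochs_done = epoch + 1

    G.eval()
    D.eval()
    if run_dir is not None:
        import os

        g_path = os.path.join(str(run_dir), "generator.npz")
        d_path = os.path.join(str(run_dir), "discriminator.npz")
        save_checkpoint(g_path, G)
        save_checkpoint(d_path, D)
        state.write_csv(os.path.join(str(run_dir), "gan_losses.csv"))
        state.checkpoints.update(generator=g_path, discriminator=d_path)
    return G, D, state


@_run_in_float32
def augment_dataset(
    G: Generator, epochs: EEGEpochs, tcfg: TrainConfig | None = None,
    seed: int | None = None,
) -> EEGEpochs:
    """Append generated trials: ratio x n_trials total, equal per class.

    The per-class remainder is assigned to the lowest class indices, so the
    split is deterministic.  Generated trials keep the labels they were
    conditioned on and are flagged in ``generated_mask``.
    """
    tcfg = tcfg or TrainConfig()
    n_gen = int(round(tcfg.augmentation_ratio * epochs.n_trials))
    n_c = epochs.n_c
    per_class = np.full(n_c, n_gen // n_c)
    per_class[: n_gen % n_c] += 1
    if per_class.max() == 0:
        logger.warning("augmentation ratio %.3g yields no trials per class; skipping",
                       tcfg.augmentation_ratio)
        return epochs
    labels = np.repeat(np.arange(n_c), per_class)
    rng = np.random.default_rng(tcfg.seed + 7919 if seed is None else seed)
    mu, sigma = float(epochs.data.mean()), float(epochs.data.std())
    G.eval()
    chunks = []
    for start in range(0, len(labels), 128):
        lab = labels[start : start + 128]
        latent = sample_latent(len(lab), (mu, sigma), n_c, rng, G.cfg.latent_dim)
        latent.labels = lab
        chunks.append(G.generate(latent).data)
    gen_data = np.concatenate(chunks)
    mask = np.concatenate(
        [np.zeros(epochs.n_trials, bool), np.ones(len(labels), bool)]
    )
    return replace(
        epochs,
        data=np.concatenate([epochs.data, gen_data]),
        labels=np.concatenate([epochs.labels, labels]),
        generated_mask=mask,
    )


@_run_in_float32
def train_classifier(
    data: EEGEpochs,
    disc: Discriminator | None = None,
    crop: CropSpec | None = None,
    tcfg: TrainConfig | None = None,
) -> tuple[Discriminator, TrainState]:
    """Minimize the cropped loss (crop-averaged probabilities, then NLL).

    ``disc`` — a trained GAN discriminator whose body is reused (head
    swapped); ``None`` builds a fresh body.  ``use_cropping`` off trains on
    one full-length "crop" per trial.
    """
    tcfg = tcfg or TrainConfig()
    tcfg.validate()
    data.validate()
    if data.class_counts().min() == 0:
        raise ValueError("every class must be present in the classifier training set")
    crop_spec = crop or CropSpec()
    if not tcfg.use_cropping:
        crop_spec = CropSpec(window=data.n_times, step=data.n_times)

    root = np.random.SeedSequence(tcfg.seed + 104729)
    seeds = root.generate_state(2) % (2**31)
    if disc is not None:
        clf = to_classifier(disc, data.n_c, input_time=crop_spec.window,
                            seed=int(seeds[0]))
    else:
        cfg = DiscriminatorConfig(
            in_channels=data.n_channels, input_time=crop_spec.window,
            head="classifier", n_c=data.n_c, use_se=tcfg.use_se,
        )
        clf = Discriminator(cfg, np.random.default_rng(int(seeds[0])))
    rng = np.random.default_rng(int(seeds[1]))

    batch = crop_epochs(data, crop_spec)
    k = batch.k
    opt = nn.Adam(clf.parameters(), lr=tcfg.lr_clf, betas=tcfg.betas_clf)
    state = TrainState(seed=tcfg.seed)
    n = batch.n_trials
    bs = max(2, min(tcfg.batch_size // max(k, 1), n))

    clf.train()
    for epoch in range(tcfg.clf_epochs):
        order = rng.permutation(n)
        for start in range(0, n - 1, bs):
            idx = order[start : start + bs]
            if len(idx) < 2:
                continue
            crops = batch.crops[idx].reshape(-1, data.n_channels, crop_spec.window)
            clf.zero_grad()
            logp = clf.predict_log_proba(nn.Tensor(np.ascontiguousarray(crops)))
            probs = logp.exp().reshape(len(idx), k, data.n_c)
            loss = cropped_loss_batch(probs, batch.labels[idx], focal=tcfg.focal)
            loss.backward()
            opt.step()
            state.clf_losses.append(loss.item())
            _check_finite(state.clf_losses[-1], "L_C", state)
        state.clf_epochs_done = epoch + 1
    clf.eval()
    return clf, state


@_run_in_float32
def predict_proba(
    clf: Discriminator, epochs: EEGEpochs, crop: CropSpec | None = None,
    batch_size: int = 32,
) -> np.ndarray:
    """Per-trial class probabilities, averaged over the trial's crops."""
    crop_spec = crop or CropSpec()
    if clf.cfg.input_time == epochs.n_times:
        crop_spec = CropSpec(window=epochs.n_times, step=epochs.n_times)
    elif crop_spec.window != clf.cfg.input_time:
        raise ValueError(
            f"classifier expects windows of {clf.cfg.input_time} samples, "
            f"crop spec provides {crop_spec.window}"
        )
    batch = crop_epochs(epochs, crop_spec)
    clf.eval()
    out = np.empty((epochs.n_trials, clf.cfg.n_c))
    for start in range(0, epochs.n_trials, batch_size):
        idx = np.arange(start, min(start + batch_size, epochs.n_trials))
        crops = batch.crops[idx].reshape(-1, epochs.n_channels, crop_spec.window)
        logp = clf.predict_log_proba(nn.Tensor(np.ascontiguousarray(crops)))
        probs = np.exp(logp.data).reshape(len(idx), batch.k, clf.cfg.n_c)
        out[idx] = probs.mean(axis=1)  # crop-averaged trial probabilities
    return out


def predict_labels(clf, epochs, crop: CropSpec | None = None) -> np.ndarray:
    return predict_proba(clf, epochs, crop).argmax(axis=1)


def run_pipeline(
    train_epochs: EEGEpochs,
    test_epochs: EEGEpochs,
    tcfg: TrainConfig | None = None,
    gcfg: GeneratorConfig | None = None,
    dcfg: DiscriminatorConfig | None = None,
    crop: CropSpec | None = None,
    preprocess: PreprocessSpec | None = None,
    shuffle_labels: bool = False,
    run_dir=None,
):
    """Normalize -> (GAN -> augment) -> cropped classifier -> held-out metrics.

    Normalization statistics are fitted on the training split only.
    ``shuffle_labels`` permutes training labels (a null control: held-out
    accuracy should drop to chance).  Returns a dict with the classifier,
    generator (or None), per-stage states and held-out accuracy.
    """
    from .evaluation import accuracy_and_kappa  # local import; no cycle at module load

    tcfg = tcfg or TrainConfig()
    pre = preprocess or PreprocessSpec()
    train_n, stats = normalize(train_epochs, pre)
    test_n, _ = normalize(test_epochs, pre, stats_from=stats)

    if shuffle_labels:
        rng = np.random.default_rng(tcfg.seed + 65537)
        train_n = replace(train_n, labels=rng.permutation(train_n.labels))

    G = disc = None
    gan_state = None
    if tcfg.use_cgan:
        G, disc, gan_state = train_gan(train_n, gcfg, dcfg, tcfg, crop, run_dir)
        train_n = augment_dataset(G, train_n, tcfg)
    body = disc if tcfg.share_gan_body else None
    clf, clf_state = train_classifier(train_n, body, crop, tcfg)
    proba = predict_proba(clf, test_n, crop or CropSpec())
    pred = proba.argmax(axis=1)
    acc, kappa = accuracy_and_kappa(pred, test_n.labels, test_n.n_c)
    return {
        "classifier": clf,
        "generator": G,
        "gan_state": gan_state,
        "clf_state": clf_state,
        "accuracy": acc,
        "kappa": kappa,
        "predictions": pred,
        "probabilities": proba,
        "norm_stats": stats,
    }
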