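"""ConvBiGRU lung-slice localizer.

A short window of consecutive normalized slices is classified as
centred on the first lung slice (FIRST), the last lung slice (LAST) or
neither (OTHER).  The recurrence is a gated recurrent unit whose gate
transforms are same-padded convolutions over the concatenation of the
previous hidden state and the current slice:

    z_t = sigmoid(W_z * [h_{t-1}, x_t])          update gate
    r_t = sigmoid(W_r * [h_{t-1}, x_t])          reset gate
    h~_t = tanh(W_h * [r_t . h_{t-1}, x_t])      candidate
    h_t = (1 - z_t) . h_{t-1} + z_t . h~_t

run in both sequence directions from zero initial states; the two
final hidden states are concatenated channel-wise, globally average
pooled and passed through a small two-layer 3-way softmax head (one
hidden layer is required: the OTHER class is the exclusive-or of the
two directions' lung evidence and is not linearly separable from the
pooled features).  A config flag
``literal_candidate`` replaces the candidate by tanh(sigmoid(.)), a
variant that bounds it to (0, tanh 1).

Class imbalance (OTHER windows dominate) is handled by a logarithmic
weight per class,

    w_i = counts_i / sum(counts);  W_i = 1 / ln(alpha + w_i),

alpha = 1.1, so every W_i lies strictly inside (1/ln 2.1, 1/ln 1.1).

Localization error is reported as the mean distance (MD) in mm: per
volume, the predicted FIRST (resp. LAST) slice is the one whose window
scores that class highest, and MD = mean(|pred - true| * spacing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .imaging_io import NORMALIZATIONS, LocalizationLabel, SliceWindow


@dataclass
class LocalizerConfig:
    window_length: int = 5
    hidden_channels: int = 8
    kernel_size: int = 3
    normalization: str = "MaxMinNorm"
    n_classes: int = 3
    literal_candidate: bool = False
    alpha: float = 1.1
    weight_mode: str = "additive"  # additive | multiplicative | none
    seed: int = 0
    epochs: int = 30
    lr: float = 1.0
    momentum: float = 0.9
    batch_size: int = 32

    def __post_init__(self):
        if self.window_length not in (3, 5, 7):
            raise ValueError(f"window_length must be 3, 5 or 7, got {self.window_length}")
        if self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.weight_mode not in ("additive", "multiplicative", "none"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


# -- class weights ------------------------------------------------------


@dataclass
class ClassWeights:
    counts: np.ndarray
    normalized: np.ndarray
    W: np.ndarray
    alpha: float = 1.1


def compute_class_weights(counts, alpha=1.1) -> ClassWeights:
    """Logarithmic inverse-frequency penalty per class.

    W_i = 1/ln(alpha + counts_i/sum(counts)); with alpha = 1.1 each W_i
    falls strictly inside (1/ln 2.1, 1/ln 1.1) ~ (1.348, 10.49).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError(f"all class counts must be positive, got {counts}")
    if alpha <= 1:
        raise ValueError(f"alpha must exceed 1, got {alpha}")
    normalized = counts / counts.sum()
    W = 1.0 / np.log(alpha + normalized)
    return ClassWeights(counts=counts, normalized=normalized, W=W, alpha=alpha)


# -- ConvGRU ------------------------------------------------------------


class ConvGRUParams(ad.Module):
    """The three gate convolutions of one ConvGRU direction."""

    def __init__(self, rng, in_channels, hidden_channels, kernel_size):
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        c = in_channels + hidden_channels
        k = kernel_size
        self.in_channels = in_channels
        self.hidden_channels = hidden_channels
        self.kernel_size = kernel_size
        self.W_z = ad.Parameter(ad.he_init(rng, (hidden_channels, c, k, k), c * k * k))
        self.b_z = ad.Parameter(np.zeros(hidden_channels))
        self.W_r = ad.Parameter(ad.he_init(rng, (hidden_channels, c, k, k), c * k * k))
        self.b_r = ad.Parameter(np.zeros(hidden_channels))
        self.W_h = ad.Parameter(ad.he_init(rng, (hidden_channels, c, k, k), c * k * k))
        self.b_h = ad.Parameter(np.zeros(hidden_channels))


def gru_cell_step(x_t, h_prev, params: ConvGRUParams, literal_candidate=False):
    """One recurrence step; returns h_t with the input spatial dims."""
    x_t = ad._wrap(x_t)
    h_prev = ad._wrap(h_prev)
    if x_t.shape[2:] != h_prev.shape[2:]:
        raise ValueError(
            f"spatial dims differ: input {x_t.shape} vs hidden {h_prev.shape}"
        )
    cat = ad.concat([h_prev, x_t], axis=1)
    z = ad.sigmoid(ad.conv2d(cat, params.W_z, params.b_z))
    r = ad.sigmoid(ad.conv2d(cat, params.W_r, params.b_r))
    cand_in = ad.concat([ad.mul(r, h_prev), x_t], axis=1)
    pre = ad.conv2d(cand_in, params.W_h, params.b_h)
    h_tilde = ad.tanh(ad.sigmoid(pre)) if literal_candidate else ad.tanh(pre)
    one_minus_z = ad.add(ad.mul(z, -1.0), 1.0)
    return ad.add(ad.mul(one_minus_z, h_prev), ad.mul(z, h_tilde))


def bigru_forward(xs, fwd: ConvGRUParams, bwd: ConvGRUParams,
                  literal_candidate=False):
    """Run the recurrence in both directions over a slice sequence.

    xs: list of (N, C, H, W) tensors/arrays, ordered along the body
    axis.  Returns the channel-wise concatenation of the two final
    hidden states, shape (N, 2*hidden, H, W).
    """
    if len(xs) == 0:
        raise ValueError("empty slice sequence")
    xs = [ad._wrap(x) for x in xs]
    n, _, h, w = xs[0].shape

    def run(sequence, params):
        hidden = ad.Tensor(np.zeros((n, params.hidden_channels, h, w)))
        for x in sequence:
            hidden = gru_cell_step(x, hidden, params, literal_candidate)
        return hidden

    h_fwd = run(xs, fwd)
    h_bwd = run(xs[::-1], bwd)
    return ad.concat([h_fwd, h_bwd], axis=1)


class ConvBiGRUClassifier(ad.Module):
    """BiGRU over a slice window + global average pool + two-layer head.

    The head mixes the two directions' pooled evidence nonlinearly
    before the 3-way softmax: the OTHER class is the exclusive-or of
    forward and backward lung evidence (lungs on both sides or on
    neither), so a single linear layer cannot separate it.
    """

    def __init__(self, config: LocalizerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.fwd = ConvGRUParams(rng, 1, config.hidden_channels, config.kernel_size)
        self.bwd = ConvGRUParams(rng, 1, config.hidden_channels, config.kernel_size)
        self.hid = ad.LinearLayer(rng, 2 * config.hidden_channels, 16)
        self.head = ad.LinearLayer(rng, 16, config.n_classes)

    def logits(self, batch):
        """batch: (N, L, H, W) normalized window stack -> (N, 3) logits."""
        batch = np.asarray(batch, dtype=float)
        n, L, h, w = batch.shape
        if L != self.config.window_length:
            raise ValueError(
                f"model configured for window length {self.config.window_length}, "
                f"got {L}"
            )
        xs = [ad.Tensor(batch[:, t][:, None]) for t in range(L)]
        feat = bigru_forward(xs, self.fwd, self.bwd, self.config.literal_candidate)
        pooled = ad.global_avg_pool(feat)
        return self.head(ad.relu(self.hid(pooled)))

    def predict_proba(self, batch, chunk=32):
        """Class probabilities per window; inference runs graph-free in
        chunks to bound memory."""
        batch = np.asarray(batch, dtype=float)
        outs = []
        with ad.no_grad():
            for start in range(0, len(batch), chunk):
                z = self.logits(batch[start : start + chunk]).data
                z = z - z.max(axis=1, keepdims=True)
                e = np.exp(z)
                outs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(outs, axis=0)


def window_to_array(window: SliceWindow, normalization="MaxMinNorm"):
    norm = NORMALIZATIONS[normalization]
    return np.stack([norm(s) for s in window.slices])


def classify_window(window: SliceWindow, model: ConvBiGRUClassifier):
    """Probability vector (FIRST, OTHER, LAST) for one window."""
    batch = window_to_array(window, model.config.normalization)[None]
    return model.predict_proba(batch)[0]


# -- training -----------------------------------------------------------


def train_localizer(model: ConvBiGRUClassifier, windows, seed=None,
                    epochs=None, lr=None, verbose=False, log_fn=None,
                    dtype="float32"):
    """SGD-momentum training on labelled windows; returns loss history.

    The per-class logarithmic weight W enters each sample's
    cross-entropy term according to ``config.weight_mode``: "additive"
    adds W of the true class as a constant penalty (the printed form;
    gradients are those of plain cross-entropy), "multiplicative"
    scales the term by W, "none" disables it.
    """
    cfg = model.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    epochs = cfg.epochs if epochs is None else epochs
    lr = cfg.lr if lr is None else lr

    X = np.stack([window_to_array(w, cfg.normalization) for w in windows])
    labels = np.array([int(w.label) for w in windows])
    Y = np.eye(cfg.n_classes)[labels]
    counts = np.bincount(labels, minlength=cfg.n_classes).astype(float)
    cw = compute_class_weights(np.maximum(counts, 1.0), cfg.alpha)

    history = []
    n = len(windows)
    with ad.precision(dtype):
        params = model.parameters()
        for p in params:
            p.data = p.data.astype(ad.DTYPE)
        opt = ad.SGDMomentum(params, lr=lr, beta=cfg.momentum)
        for epoch in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = model.logits(X[idx])
                if cfg.weight_mode == "multiplicative":
                    loss = ad.softmax_cross_entropy(logits, Y[idx], cw.W[labels[idx]])
                    penalty = 0.0
                else:
                    loss = ad.softmax_cross_entropy(logits, Y[idx])
                    penalty = (
                        float(cw.W[labels[idx]].mean())
                        if cfg.weight_mode == "additive"
                        else 0.0
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += (loss.item() + penalty) * len(idx)
            history.append(total / n)
            if log_fn is not None:
                log_fn(epoch, history[-1])
            if verbose:
                print(f"epoch {epoch:3d}  loss {history[-1]:.4f}")
    for p in model.parameters():
        p.data = p.data.astype(ad.DTYPE)
    return history


def training_accuracy(model, windows):
    X = np.stack(
        [window_to_array(w, model.config.normalization) for w in windows]
    )
    pred = model.predict_proba(X).argmax(axis=1)
    truth = np.array([int(w.label) for w in windows])
    return float((pred == truth).mean())


# -- evaluation ---------------------------------------------------------


def predict_volume_extents(model, volume, labels=None):
    """Predicted (first, last) lung-slice indices for one volume.

    Every valid window of the volume is scored; the centre index whose
    window maximises the FIRST (resp. LAST) probability is returned,
    ties going to the smaller index (argmax is first-occurrence).
    """
    from .imaging_io import make_windows

    L = model.config.window_length
    dummy = [LocalizationLabel.OTHER] * len(volume)
    windows = make_windows(volume, labels if labels is not None else dummy, L)
    X = np.stack(
        [window_to_array(w, model.config.normalization) for w in windows]
    )
    probs = model.predict_proba(X)
    centers = np.array([w.center_index for w in windows])
    fl = int(centers[np.argmax(probs[:, int(LocalizationLabel.FIRST)])])
    ll = int(centers[np.argmax(probs[:, int(LocalizationLabel.LAST)])])
    return fl, ll


def mean_distance(pred_indices, true_indices, spacing_mm):
    """MD = mean(|pred - true| * spacing) in millimetres."""
    pred = np.asarray(pred_indices, dtype=float)
    true = np.asarray(true_indices, dtype=float)
    sp = np.asarray(spacing_mm, dtype=float)
    if not (len(pred) == len(true) == len(sp)):
        raise ValueError(
            f"length mismatch: {len(pred)} preds, {len(true)} truths, {len(sp)} spacings"
        )
    if len(pred) == 0:
        raise ValueError("empty prediction list")
    return float((np.abs(pred - true) * sp).mean())


# -- subset balancing ---------------------------------------------------


def balance_subsets(dataset, n_subsets, target_positive, tolerance=0, seed=0):
    """Split windows into disjoint subsets with balanced positives.

    Positive windows are those labelled FIRST or LAST.  Each subset
    receives ``target_positive`` (+/- tolerance) positives; negatives
    are spread evenly.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    pos = [w for w in dataset if w.label != LocalizationLabel.OTHER]
    neg = [w for w in dataset if w.label == LocalizationLabel.OTHER]
    need_min = n_subsets * max(target_positive - tolerance, 0)
    if len(pos) < need_min:
        raise ValueError(
            f"infeasible balance: {len(pos)} positive windows available, "
            f"need at least {need_min} ({n_subsets} subsets x "
            f">={target_positive - tolerance})"
        )
    pos_idx = rng.permutation(len(pos))
    neg_idx = rng.permutation(len(neg))
    per = min(target_positive + tolerance, len(pos) // n_subsets)
    per = max(per, target_positive - tolerance)
    subsets = []
    p = 0
    for k in range(n_subsets):
        take = [pos[i] for i in pos_idx[p : p + per]]
        p += per
        subsets.append(take)
    for k, i in enumerate(neg_idx):
        subsets[k % n_subsets].append(neg[i])
    return subsets
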