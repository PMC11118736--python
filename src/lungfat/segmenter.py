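"""Multi-module UNet for binary adipose-tissue segmentation.

The backbone is a standard 2-D encoder-decoder with skip connections
(two 3x3 convolutions per level, 2x2 max-pooling, nearest-neighbour
upsampling with a 1x1 projection) ending in a single-channel logistic
output, so every pixel carries a probability in (0, 1).  Three optional
blocks modify the skip pathway and can be enabled in any of the eight
combinations for ablation studies:

* multi-resolution (MR) — features from the next deeper encoder level
  are upsampled, projected to the skip's channel count by a 1x1
  convolution and added to the skip, enriching it across scales;
* competitive (CP) — a Maxout over two candidates: the (possibly
  MR/ATTN-modified) skip pathway versus the 1x1-projected upsampled
  decoder features of the peer level; the elementwise maximum wins;
* attention gate (ATTN) — an additive attention coefficient
  alpha = sigmoid(psi * relu(W_s * skip + W_g * gating)) computed from
  the skip and the upsampled decoder features gates the skip
  (output = alpha . skip), suppressing irrelevant regions.

When several blocks are active they compose MR -> ATTN -> CP, so the
Maxout always arbitrates the final candidates.  The gated/fused
pathway is then concatenated with the upsampled decoder features
exactly as in a plain UNet.

Training minimizes the smoothed Dice complement (see
``losses_metrics``) with SGD-momentum (beta = 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .losses_metrics import (
    LossConfig,
    average_reports,
    confusion_metrics,
    dice_coefficient,
    dice_loss_tensor,
)


@dataclass
class ModuleConfig:
    use_mr: bool = False
    use_cp: bool = False
    use_attn: bool = False
    depth: int = 4
    base_channels: int = 16

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")

    @property
    def name(self):
        parts = [n for n, f in (("MR", self.use_mr), ("ATTN", self.use_attn),
                                ("CP", self.use_cp)) if f]
        return "UNet" + ("+" + "+".join(parts) if parts else "")


def all_module_configs(depth=4, base_channels=16):
    """The eight {MR, CP, ATTN} combinations of the ablation design."""
    configs = []
    for mr in (False, True):
        for attn in (False, True):
            for cp in (False, True):
                configs.append(
                    ModuleConfig(use_mr=mr, use_cp=cp, use_attn=attn,
                                 depth=depth, base_channels=base_channels)
                )
    return configs


@dataclass
class ProbabilityMap:
    values: np.ndarray
    threshold: float = 0.5

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.size and not ((v > 0) & (v < 1)).all():
            raise ValueError("probability map values must lie in (0, 1)")

    def binary(self):
        return (np.asarray(self.values) >= self.threshold).astype(np.uint8)


# -- blocks -------------------------------------------------------------


def multi_resolution_block(shallow, deep, projection):
    """Upsample `deep` to `shallow`'s grid, 1x1-project, add.

    `deep` must sit a power of two below `shallow` in resolution;
    `projection` is the 1x1 conv layer mapping deep channels to
    shallow channels.
    """
    shallow = ad._wrap(shallow)
    deep = ad._wrap(deep)
    sh, sw = shallow.shape[2:]
    dh, dw = deep.shape[2:]
    if sh % dh or sw % dw or (sh // dh) & (sh // dh - 1) or sh // dh != sw // dw:
        raise ValueError(
            f"deep {dh}x{dw} must be a power-of-two downscale of shallow {sh}x{sw}"
        )
    up = deep
    steps = (sh // dh).bit_length() - 1
    for _ in range(steps):
        up = ad.upsample2(up)
    return ad.add(shallow, projection(up))


def competitive_block(candidate_a, candidate_b):
    """Maxout over two candidate feature maps (elementwise maximum)."""
    candidate_a = ad._wrap(candidate_a)
    candidate_b = ad._wrap(candidate_b)
    if candidate_a.shape != candidate_b.shape:
        raise ValueError(
            f"competitive candidates differ in shape: "
            f"{candidate_a.shape} vs {candidate_b.shape}"
        )
    return ad.maximum(candidate_a, candidate_b)


class AttentionGateParams(ad.Module):
    """1x1 convolutions of one additive attention gate."""

    def __init__(self, rng, skip_ch, gate_ch, inter_ch):
        self.W_s = ad.Conv2dLayer(rng, skip_ch, inter_ch, 1)
        self.W_g = ad.Conv2dLayer(rng, gate_ch, inter_ch, 1)
        self.psi = ad.Conv2dLayer(rng, inter_ch, 1, 1)


def attention_gate(skip, gating, params: AttentionGateParams):
    """alpha = sigmoid(psi(relu(W_s*skip + W_g*gating))); out = alpha.skip."""
    skip = ad._wrap(skip)
    gating = ad._wrap(gating)
    if skip.shape[0] != gating.shape[0] or skip.shape[2:] != gating.shape[2:]:
        raise ValueError(
            f"skip {skip.shape} and gating {gating.shape} spatial dims differ"
        )
    alpha = ad.sigmoid(
        params.psi(ad.relu(ad.add(params.W_s(skip), params.W_g(gating))))
    )
    return ad.mul(alpha, skip)  # alpha broadcasts over channels


# -- network ------------------------------------------------------------


class _EncoderLevel(ad.Module):
    def __init__(self, rng, in_ch, out_ch):
        self.c1 = ad.Conv2dLayer(rng, in_ch, out_ch, 3)
        self.c2 = ad.Conv2dLayer(rng, out_ch, out_ch, 3)

    def __call__(self, x):
        return ad.relu(self.c2(ad.relu(self.c1(x))))


class _SkipModules(ad.Module):
    """Per-level learned parameters of the optional skip blocks."""

    def __init__(self, rng, config, ch, deeper_ch):
        if config.use_mr:
            self.mr_proj = ad.Conv2dLayer(rng, deeper_ch, ch, 1)
        if config.use_attn:
            self.attn = AttentionGateParams(rng, ch, ch, max(ch // 2, 1))
        if config.use_cp:
            self.cp_proj = ad.Conv2dLayer(rng, ch, ch, 1)


class MultiModuleUNet(ad.Module):
    """UNet with optional MR / ATTN / CP skip-pathway blocks."""

    def __init__(self, config: ModuleConfig, seed=0, in_channels=1):
        self.config = config
        rng = np.random.default_rng(seed)
        d, base = config.depth, config.base_channels
        self.enc_channels = [base * 2**i for i in range(d)]
        bott_ch = base * 2**d
        self.encoders = []
        ch_in = in_channels
        for ch in self.enc_channels:
            self.encoders.append(_EncoderLevel(rng, ch_in, ch))
            ch_in = ch
        self.bottleneck = _EncoderLevel(rng, ch_in, bott_ch)
        self.up_projs = []   # 1x1 conv after nearest upsample, deep->level ch
        self.decoders = []
        self.skip_mods = []
        deeper = bott_ch
        for i in reversed(range(d)):
            ch = self.enc_channels[i]
            self.up_projs.append(ad.Conv2dLayer(rng, deeper, ch, 1))
            self.decoders.append(_EncoderLevel(rng, 2 * ch, ch))
            deeper_enc_ch = bott_ch if i == d - 1 else self.enc_channels[i + 1]
            self.skip_mods.append(_SkipModules(rng, config, ch, deeper_enc_ch))
            deeper = ch
        self.head = ad.Conv2dLayer(rng, base, 1, 1)

    # -- wiring --------------------------------------------------------

    def assemble_skip_pathway(self, skip, decoder_up, deeper_enc, mods):
        """Compose the enabled blocks (MR -> ATTN -> CP) on one skip."""
        cfg = self.config
        pathway = skip
        if cfg.use_mr:
            pathway = multi_resolution_block(pathway, deeper_enc, mods.mr_proj)
        if cfg.use_attn:
            pathway = attention_gate(pathway, decoder_up, mods.attn)
        if cfg.use_cp:
            pathway = competitive_block(pathway, mods.cp_proj(decoder_up))
        return pathway

    def forward_tensor(self, x):
        x = ad._wrap(x)
        d = self.config.depth
        h, w = x.shape[2:]
        if h % 2**d or w % 2**d:
            raise ValueError(
                f"input {h}x{w} must be divisible by 2^depth = {2**d}"
            )
        skips = []
        cur = x
        for enc in self.encoders:
            cur = enc(cur)
            skips.append(cur)
            cur = ad.maxpool2d(cur)
        cur = self.bottleneck(cur)
        deeper_feats = skips[1:] + [cur]  # encoder features one level down
        for j, i in enumerate(reversed(range(d))):
            decoder_up = self.up_projs[j](ad.upsample2(cur))
            pathway = self.assemble_skip_pathway(
                skips[i], decoder_up, deeper_feats[i], self.skip_mods[j]
            )
            cur = self.decoders[j](ad.concat([pathway, decoder_up], axis=1))
        return ad.sigmoid(self.head(cur))

    def predict(self, image):
        """Normalized (H, W) image -> ProbabilityMap."""
        arr = np.asarray(image, dtype=float)
        with ad.no_grad():
            out = self.forward_tensor(arr[None, None]).data[0, 0]
        # keep the open-interval contract even when the logistic saturates
        out = np.clip(out, 1e-12, 1.0 - 1e-12)
        return ProbabilityMap(values=out)


def unet_forward(image, config: ModuleConfig, model: MultiModuleUNet = None,
                 seed=0):
    """One forward pass; builds a freshly initialized model if none given."""
    if model is None:
        model = MultiModuleUNet(config, seed=seed)
    return model.predict(image)


# -- training -----------------------------------------------------------


def train_segmenter(model: MultiModuleUNet, images, masks, epochs=100,
                    lr=0.01, momentum=0.9, batch_size=10, seed=0,
                    loss_config: LossConfig = None, class_weight=0.0,
                    log_fn=None, dtype="float32"):
    """Dice-loss SGD-momentum training; returns per-epoch loss history.

    images: list of normalized (H, W) arrays; masks: matching binary
    arrays.  ``class_weight`` is the additive W of the weighted loss
    (constant per sample; shifts the reported loss, not its gradient)
    and is used when ``loss_config.use_weight_penalty`` is on.
    Training runs at ``dtype`` working precision (float32 by default).
    """
    loss_config = loss_config or LossConfig()
    X = np.stack([np.asarray(im, dtype=float) for im in images])[:, None]
    Y = np.stack([np.asarray(m, dtype=float) for m in masks])[:, None]
    rng = np.random.default_rng(seed)
    history = []
    n = len(X)
    with ad.precision(dtype):
        params = model.parameters()
        for p in params:
            p.data = p.data.astype(ad.DTYPE)
        opt = ad.SGDMomentum(params, lr=lr, beta=momentum)
        W = class_weight if loss_config.use_weight_penalty else 0.0
        for epoch in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                pred = model.forward_tensor(X[idx])
                loss = dice_loss_tensor(Y[idx], pred, kappa=loss_config.kappa, W=W)
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += loss.item() * len(idx)
            history.append(total / n)
            if log_fn is not None:
                log_fn(epoch, history[-1])
    for p in model.parameters():
        p.data = p.data.astype(ad.DTYPE)
    return history


def evaluate_segmenter(model, images, masks, kappa=1.0, threshold=0.5):
    """Per-image confusion metrics averaged over the set.

    Also returns the soft (probability-map) smoothed Dice alongside the
    binarized metrics, since it is ambiguous which of the two a given
    evaluation protocol reports.
    """
    reports, soft_dice = [], []
    for im, msk in zip(images, masks):
        pm = model.predict(im)
        soft_dice.append(dice_coefficient(np.asarray(msk, float), pm.values, kappa))
        pm.threshold = threshold
        reports.append(confusion_metrics(np.asarray(msk, float), pm.binary(), kappa))
    summary = average_reports(reports)
    return summary, float(np.mean(soft_dice))
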