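"""End-to-end orchestration: phantoms -> localize -> range-select -> segment.

The two models are trained on independently managed datasets and meet
only at inference: the localizer proposes the first/last lung slice of
each volume and the segmenter runs on the slices inside that inclusive
range.  Every random operation derives from the single pipeline seed;
a JSON manifest records the configuration, the derived seeds, the
audit-relevant defaults actually used (normalization, natural log in
the class weights, 0.5 binarization threshold) and every metric, so a
run is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .imaging_io import LocalizationLabel, make_windows, max_min_norm, NORMALIZATIONS
from .localizer import (
    ConvBiGRUClassifier,
    LocalizerConfig,
    mean_distance,
    predict_volume_extents,
    train_localizer,
)
from .losses_metrics import LossConfig, aggregate_folds
from .phantom import generate_cohort
from .segmenter import (
    ModuleConfig,
    MultiModuleUNet,
    all_module_configs,
    evaluate_segmenter,
    train_segmenter,
)

log = logging.getLogger(__name__)


@dataclass
class PhantomSettings:
    n_volumes: int = 5
    n_slices: int = 12
    image_size: int = 64
    spacing_mm: float = 2.5
    noise_sd: float = 50.0


@dataclass
class SegTrainSettings:
    epochs: int = 60
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 10


@dataclass
class PipelineConfig:
    out_dir: str = "runs/latest"
    data_dir: str = None  # directory of exported volumes, used when phantoms are off
    generate_phantoms: bool = True
    seed: int = 0
    train_ratio: float = 0.8
    val_ratio: float = 0.2
    folds: int = 4
    phantoms: PhantomSettings = field(default_factory=PhantomSettings)
    localizer: LocalizerConfig = field(default_factory=LocalizerConfig)
    segmenter: ModuleConfig = field(
        default_factory=lambda: ModuleConfig(use_mr=True, use_attn=True)
    )
    loss: LossConfig = field(default_factory=LossConfig)
    seg_train: SegTrainSettings = field(default_factory=SegTrainSettings)

    def __post_init__(self):
        if abs(self.train_ratio + self.val_ratio - 1.0) > 1e-9:
            raise ValueError("train_ratio + val_ratio must sum to 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @staticmethod
    def from_dict(doc):
        doc = dict(doc)
        for key, cls in (
            ("phantoms", PhantomSettings),
            ("localizer", LocalizerConfig),
            ("segmenter", ModuleConfig),
            ("loss", LossConfig),
            ("seg_train", SegTrainSettings),
        ):
            if key in doc and isinstance(doc[key], dict):
                doc[key] = cls(**doc[key])
        return PipelineConfig(**doc)


def select_lung_range(volume_predictions):
    """(first, last) slice indices from per-slice class probabilities.

    ``volume_predictions``: (n_slices, 3) array of (FIRST, OTHER, LAST)
    probabilities.  The argmax rows for FIRST and LAST define the
    inclusive range; an inverted pair is swapped with a warning so the
    returned range always satisfies first <= last.
    """
    probs = np.asarray(volume_predictions, dtype=float)
    if probs.ndim != 2 or probs.shape[0] < 1 or probs.shape[1] != 3:
        raise ValueError(f"expected a (n_slices, 3) array, got shape {probs.shape}")
    fl = int(np.argmax(probs[:, int(LocalizationLabel.FIRST)]))
    ll = int(np.argmax(probs[:, int(LocalizationLabel.LAST)]))
    if fl > ll:
        log.warning("inverted lung range (%d > %d); swapping", fl, ll)
        fl, ll = ll, fl
    return fl, ll


def split_volumes(volumes, train_ratio, seed):
    """Disjoint seeded train/validation split of whole volumes."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(volumes))
    n_train = max(1, int(round(train_ratio * len(volumes))))
    n_train = min(n_train, len(volumes) - 1) if len(volumes) > 1 else 1
    train = [volumes[i] for i in order[:n_train]]
    val = [volumes[i] for i in order[n_train:]]
    return train, val


def kfold_indices(n, k, seed):
    """Seeded exact partition of range(n) into k folds."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[i::k] for i in range(k)]


def _volume_windows(volumes, L):
    windows = []
    for vol in volumes:
        windows.extend(
            make_windows(vol.slices, vol.loc_labels, L, volume_id=vol.volume_id)
        )
    return windows


def true_extents(volume):
    """Ground-truth (first, last) lung indices of a volume."""
    if volume.spec is not None:
        return volume.spec.lung_first, volume.spec.lung_last
    labels = [int(lab) for lab in volume.loc_labels]
    return (
        labels.index(int(LocalizationLabel.FIRST)),
        labels.index(int(LocalizationLabel.LAST)),
    )


def _segmentation_samples(volumes, tissue, ranges=None):
    """Normalized images and masks from the lung range of each volume."""
    images, masks = [], []
    for vi, vol in enumerate(volumes):
        if ranges is not None:
            fl, ll = ranges[vi]
        else:
            fl, ll = true_extents(vol)
        for i in range(fl, ll + 1):
            images.append(max_min_norm(vol.slices[i]))
            mask = vol.sat_masks[i] if tissue == "SAT" else vol.vat_masks[i]
            masks.append(mask)
    return images, masks


def run_pipeline(config: PipelineConfig, localizer_epochs=None):
    """Execute localize -> range-select -> segment on phantom data.

    Returns the manifest dict; everything is also written under
    ``config.out_dir`` (manifest.json, per-volume localization CSV,
    per-epoch logs).
    """
    if not config.generate_phantoms:
        if config.data_dir is None or not Path(config.data_dir).is_dir():
            raise ValueError(
                "phantom generation is disabled and data_dir "
                f"{config.data_dir!r} does not exist"
            )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seed = config.seed
    manifest = {
        "config": _config_dict(config),
        "config_hash": _config_hash(config),
        "seeds": {},
        "stages": {},
        "audited_defaults": {
            "normalization": config.localizer.normalization,
            "class_weight_log_base": "natural",
            "binarization_threshold": 0.5,
            "dice_kappa": config.loss.kappa,
            "weight_alpha": config.loss.alpha,
            "sgd_momentum_beta": config.seg_train.momentum,
        },
    }

    def fail(stage, err):
        manifest["stages"][stage] = {"status": "failed", "error": str(err)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # -- stage 1: phantom data -----------------------------------------
    stage = "phantom"
    try:
        ph = config.phantoms
        manifest["seeds"]["phantom"] = seed + 1
        if config.generate_phantoms:
            volumes = generate_cohort(
                ph.n_volumes, n_slices=ph.n_slices, image_size=ph.image_size,
                spacing_mm=ph.spacing_mm, noise_sd=ph.noise_sd, seed=seed + 1,
            )
        else:
            from .phantom import import_dataset

            subdirs = sorted(
                p for p in Path(config.data_dir).iterdir() if p.is_dir()
            )
            volumes = [import_dataset(p) for p in subdirs]
            if not volumes:
                raise ValueError(f"no volume directories under {config.data_dir}")
        train_vols, val_vols = split_volumes(volumes, config.train_ratio, seed + 2)
        manifest["stages"][stage] = {
            "status": "ok",
            "n_volumes": ph.n_volumes,
            "n_train": len(train_vols),
            "n_val": len(val_vols),
        }
    except Exception as e:  # pragma: no cover - defensive
        fail(stage, e)

    # -- stage 2: localization -----------------------------------------
    stage = "localize"
    try:
        loc_cfg = config.localizer
        manifest["seeds"]["localizer"] = seed + 3
        loc_cfg.seed = seed + 3
        model = ConvBiGRUClassifier(loc_cfg)
        windows = _volume_windows(train_vols, loc_cfg.window_length)
        epoch_log = []
        history = train_localizer(
            model, windows,
            epochs=localizer_epochs,
            log_fn=lambda ep, ls: epoch_log.append(
                {"stage": "localize", "epoch": ep, "loss": ls}
            ),
        )
        eval_vols = val_vols if val_vols else train_vols
        rows, preds_fl, preds_ll, true_fl, true_ll, spacings = [], [], [], [], [], []
        ranges = []
        for vol in eval_vols:
            fl, ll = predict_volume_extents(model, vol.slices)
            if fl > ll:
                log.warning("volume %s: inverted range; swapping", vol.volume_id)
                fl, ll = ll, fl
            tfl, tll = true_extents(vol)
            ranges.append((fl, ll))
            preds_fl.append(fl)
            preds_ll.append(ll)
            true_fl.append(tfl)
            true_ll.append(tll)
            spacings.append(vol.slices[0].spacing_mm)
            d = (abs(fl - tfl) + abs(ll - tll)) / 2 * vol.slices[0].spacing_mm
            rows.append(f"{vol.volume_id},{fl},{tfl},{ll},{tll},{d}")
        md = 0.5 * (
            mean_distance(preds_fl, true_fl, spacings)
            + mean_distance(preds_ll, true_ll, spacings)
        )
        (out / "localization.csv").write_text(
            "volume_id,pred_fl,true_fl,pred_ll,true_ll,distance_mm\n"
            + "\n".join(rows) + "\n"
        )
        manifest["stages"][stage] = {
            "status": "ok",
            "n_windows": len(windows),
            "final_loss": history[-1],
            "mean_distance_mm": md,
            "epochs": len(history),
        }
    except Exception as e:
        fail(stage, e)

    # -- stage 3: segmentation on the selected ranges ------------------
    stage = "segment"
    try:
        manifest["seeds"]["segmenter"] = seed + 4
        st = config.seg_train
        seg_results = {}
        for tissue in ("SAT", "VAT"):
            tr_im, tr_mk = _segmentation_samples(train_vols, tissue)
            model_s = MultiModuleUNet(config.segmenter, seed=seed + 4)
            train_segmenter(
                model_s, tr_im, tr_mk, epochs=st.epochs, lr=st.lr,
                momentum=st.momentum, batch_size=st.batch_size, seed=seed + 5,
                loss_config=config.loss,
                log_fn=lambda ep, ls: epoch_log.append(
                    {"stage": f"segment-{tissue}", "epoch": ep, "loss": ls}
                ),
            )
            ev_im, ev_mk = _segmentation_samples(eval_vols, tissue, ranges=ranges)
            if ev_im:
                report, soft = evaluate_segmenter(model_s, ev_im, ev_mk,
                                                  kappa=config.loss.kappa)
                seg_results[tissue] = {
                    "dice": report.dice, "f1": report.f1,
                    "precision": report.precision, "recall": report.recall,
                    "soft_dice": soft, "n_eval_images": len(ev_im),
                }
        manifest["stages"][stage] = {"status": "ok", **seg_results}
    except Exception as e:
        fail(stage, e)

    (out / "epochs.jsonl").write_text(
        "\n".join(json.dumps(r) for r in epoch_log) + "\n"
    )
    manifest["runtime_s"] = time.time() - t0
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_ablation(volumes, tissue="SAT", depth=4, base_channels=16, folds=4,
                 epochs=40, lr=0.05, seed=0, configs=None):
    """Cross-validated sweep over the eight module combinations.

    Returns rows shaped like the ablation tables: one dict per config
    with "mean ± sd" strings per metric over the folds.
    """
    images, masks = _segmentation_samples(volumes, tissue)
    images, masks = list(images), list(masks)
    fold_idx = kfold_indices(len(images), folds, seed)
    rows = []
    for cfg in configs or all_module_configs(depth, base_channels):
        fold_reports = []
        for f, test_ids in enumerate(fold_idx):
            test_ids = set(int(i) for i in test_ids)
            tr_im = [im for i, im in enumerate(images) if i not in test_ids]
            tr_mk = [mk for i, mk in enumerate(masks) if i not in test_ids]
            te_im = [im for i, im in enumerate(images) if i in test_ids]
            te_mk = [mk for i, mk in enumerate(masks) if i in test_ids]
            model = MultiModuleUNet(cfg, seed=seed + 10 + f)
            train_segmenter(model, tr_im, tr_mk, epochs=epochs, lr=lr,
                            seed=seed + 20 + f)
            report, _ = evaluate_segmenter(model, te_im, te_mk)
            fold_reports.append(report)
        summary = aggregate_folds(fold_reports)
        rows.append({
            "model": cfg.name,
            "tissue": tissue,
            "dice": summary["dice"][2],
            "f1": summary["f1"][2],
            "precision": summary["precision"][2],
            "recall": summary["recall"][2],
        })
    return rows


def ablation_csv(rows, path):
    lines = ["Model,Adipose Type,Dice Score,F1 Score,Precision,Recall"]
    for r in rows:
        lines.append(
            f"{r['model']},{r['tissue']},{r['dice']},{r['f1']},"
            f"{r['precision']},{r['recall']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def _config_dict(config):
    return asdict(config)


def _config_hash(config):
    blob = json.dumps(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
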