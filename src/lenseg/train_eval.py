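"""Training loop, evaluation, and the ablation harness.

Optimisation follows the reference recipe: SGD with momentum 0.99 and
weight decay 5e-4, initial learning rate 1e-3 with a descending (default
polynomial, power 0.9) schedule.  Deep supervision adds the per-stage
auxiliary cross-entropies, weighted (0.2, 0.3) shallow-to-deep, on top of
the main loss; auxiliary heads are ignored at evaluation time.

Training is deterministic for a fixed seed: weight initialisation and epoch
shuffling each draw from generators derived from ``TrainConfig.seed``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .imaging_io import WINDOW_TOOTH, WindowSetting, read_mask, read_slice, read_split_list, mask_path, slice_path
from .le_net import Network, NetworkConfig, build_network
from .losses import LossConfig, PredictionTarget, downsample_gt, iou_loss, one_hot, pixel_ce, total_loss
from .metrics import ConfusionMatrix, accumulate_confusion, iou_per_class, mean_iou, report_table
from .nn.optim import SGD, cosine_lr, poly_lr, step_lr

SCHEDULES = {"poly": poly_lr, "step": step_lr, "cosine": cosine_lr}

__all__ = [
    "TrainConfig",
    "load_split",
    "train",
    "evaluate",
    "run_ablation",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    momentum: float = 0.99
    weight_decay: float = 0.0005
    batch_size: int = 8
    epochs: int = 30  # desk-scale default; the full-scale recipe runs 500
    seed: int = 0
    lr_schedule: str = "poly"
    loss_mode: str = "hard_onehot"  # conventional CE reading for training
    use_aux: bool = True
    eval_every: int = 0  # epochs between validation passes; 0 = never
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr must be > 0, batch_size and epochs >= 1")
        if self.lr_schedule not in SCHEDULES:
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")

    def loss_config(self) -> LossConfig:
        mode = self.loss_mode if self.loss_mode != "iou" else "iou_loss"
        return LossConfig(mode=mode, aux_weights=self.network.aux_weights,
                          num_classes=self.network.num_classes)


# ---------------------------------------------------------------------------
# data
# ---------------------------------------------------------------------------

def load_split(root: str, split: str, window: WindowSetting = WINDOW_TOOTH):
    """Load a dataset split as (images, labels).

    Images are window-normalised to [0, 1] with shape (N, 1, H, W); labels
    are integer (N, H, W).  The tooth window is the training default (the
    dual-window merge utility handles metal annotation upstream).
    """
    from .imaging_io import apply_window

    stems = read_split_list(root, split)
    if not stems:
        raise ValueError(f"split {split!r} in {root!r} is empty")
    images, labels = [], []
    for stem in stems:
        ct = read_slice(slice_path(root, stem))
        mask = read_mask(mask_path(root, stem))
        if mask.classes.shape != ct.pixels.shape:
            raise ValueError(f"slice/mask shape mismatch for {stem!r}")
        images.append(apply_window(ct, window)[None])
        labels.append(mask.classes.astype(np.int64))
    return np.stack(images), np.stack(labels)


def _batch_one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], k) + labels.shape[1:])
    for c in range(k):
        out[:, c] = labels == c
    return out


def _batch_losses(net: Network, images, targets_full, cfg: TrainConfig, loss_cfg: LossConfig):
    """Forward a batch and assemble (total, main, aux-values)."""
    main_logits, aux_logits = net(images)
    mode = loss_cfg.mode

    def head_loss(logits, target):
        pt = PredictionTarget(logits, target)
        if mode == "iou_loss":
            return iou_loss(pt)
        return pixel_ce(pt, mode)

    main = head_loss(main_logits, targets_full)
    aux_terms = []
    if cfg.use_aux:
        ds_mode = mode if mode != "iou_loss" else "hard_onehot"
        for logits in aux_logits:
            th, tw = logits.shape[-2:]
            target = np.stack([
                downsample_gt(targets_full[i], th, tw, mode=ds_mode)
                for i in range(targets_full.shape[0])
            ])
            aux_terms.append(head_loss(logits, target))
        total = total_loss(main, aux_terms, loss_cfg)
    else:
        total = main
    return total, main, aux_terms


def train(cfg: TrainConfig, data, log_path: str | None = None) -> dict:
    """Train a network on ``data`` and return the result bundle.

    ``data`` is either ``(images, labels)`` arrays, a manifest dict from
    :func:`lenseg.phantom.generate_phantom_dataset`, or a dataset directory.
    Returns ``{"network", "log", "best_state", "last_state", "config"}``
    where best is by validation mIoU when ``eval_every`` is set (else by
    training loss).
    """
    if isinstance(data, (str, os.PathLike)):
        data = {"root": os.fspath(data)}
    if isinstance(data, dict):
        images, labels = load_split(data["root"], "train")
        val = None
        if cfg.eval_every:
            try:
                val = load_split(data["root"], "test")
            except (FileNotFoundError, ValueError):
                val = None
    else:
        images, labels = data
        val = None
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels)
    if images.shape[0] == 0:
        raise ValueError("empty training set")

    k = cfg.network.num_classes
    net = build_network(cfg.network, seed=cfg.seed)
    net.train()
    opt = SGD(net.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    schedule = SCHEDULES[cfg.lr_schedule]
    loss_cfg = cfg.loss_config()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x5EED)))

    n = images.shape[0]
    batches_per_epoch = max(1, n // cfg.batch_size)
    total_steps = cfg.epochs * batches_per_epoch
    log, best = [], {"miou": -1.0, "loss": np.inf, "state": None}
    targets_all = _batch_one_hot(labels, k)
    step = 0
    log_fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for b in range(batches_per_epoch):
                idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
                opt.lr = schedule(cfg.lr, step, total_steps)
                total, main, aux_terms = _batch_losses(
                    net, images[idx], targets_all[idx], cfg, loss_cfg
                )
                if not np.isfinite(total.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} step {step} "
                        f"(main={float(main.data)!r})"
                    )
                opt.zero_grad()
                total.backward()
                opt.step()
                step += 1
                epoch_losses.append(
                    (total.item(), main.item(), [a.item() for a in aux_terms])
                )
            mean_total = float(np.mean([e[0] for e in epoch_losses]))
            entry = {
                "epoch": epoch,
                "lr": opt.lr,
                "loss_total": mean_total,
                "loss_main": float(np.mean([e[1] for e in epoch_losses])),
                "loss_aux": [float(v) for v in np.mean(
                    [e[2] for e in epoch_losses], axis=0)] if cfg.use_aux and epoch_losses[0][2] else [],
            }
            if cfg.eval_every and val is not None and (epoch + 1) % cfg.eval_every == 0:
                entry["val_miou"] = evaluate(net, val[0], val[1])["miou"]
            log.append(entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
            score = entry.get("val_miou")
            if score is not None:
                if score > best["miou"]:
                    best.update(miou=score, state=net.state_dict())
            elif mean_total < best["loss"]:
                best.update(loss=mean_total, state=net.state_dict())
    finally:
        if log_fh:
            log_fh.close()
    net.eval()
    return {
        "network": net,
        "log": log,
        "best_state": best["state"],
        "last_state": net.state_dict(),
        "config": cfg,
    }


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(model, images, labels, batch_size: int = 8, empty_class: str = "one") -> dict:
    """Accumulate a confusion matrix over a split and report IoU / mIoU.

    ``model`` is a :class:`Network` (main head only, eval mode) or any
    callable mapping an image batch to integer label maps — handy for
    oracle hooks like a constant or identity predictor.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    k = model.cfg.num_classes if isinstance(model, Network) else int(labels.max()) + 1
    k = max(k, 3)
    cm = ConfusionMatrix(k)
    predict = model.predict if isinstance(model, Network) else model
    for lo in range(0, images.shape[0], batch_size):
        pred = predict(images[lo : lo + batch_size])
        accumulate_confusion(cm, pred, labels[lo : lo + batch_size])
    ious = iou_per_class(cm, empty_class=empty_class)
    return {
        "confusion": cm,
        "iou_per_class": ious,
        "miou": mean_iou(cm, empty_class=empty_class),
    }


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, net: Network, state: dict | None = None) -> None:
    """Serialise weights + the NetworkConfig that built them (single .npz)."""
    state = state or net.state_dict()
    cfg_json = json.dumps(asdict(net.cfg))
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **{k: v for k, v in state.items()})


def load_checkpoint(path: str, expect: NetworkConfig | None = None) -> Network:
    """Rebuild the network from a checkpoint; refuse a mismatched config."""
    with np.load(path) as npz:
        cfg_dict = json.loads(bytes(npz["__config__"]).decode())
        for key in ("aux_weights", "dilation_rates"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = NetworkConfig(**cfg_dict)
        if expect is not None and cfg != expect:
            raise ValueError(f"checkpoint config {cfg} does not match expected {expect}")
        state = {k: npz[k] for k in npz.files if k != "__config__"}
    net = build_network(cfg)
    net.load_state_dict(state)
    net.eval()
    return net


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

def run_ablation(
    grid,
    train_data,
    test_data,
    base_cfg: TrainConfig,
    seeds=(0,),
) -> dict:
    """Train every (variant, loss_mode, use_aux) cell under identical conditions.

    Each cell is trained once per seed on the same data with the same
    schedule; reported per-class IoU / mIoU values are medians across seeds.
    Returns ``{"rows": {name: ious}, "miou": {name: value}, "table": str,
    "csv": str, "provenance": [...]}``.
    """
    test_images, test_labels = test_data
    rows, mious, provenance = {}, {}, []
    for cell in grid:
        if len(cell) == 2:
            variant, loss_mode = cell
            use_aux = base_cfg.use_aux
        else:
            variant, loss_mode, use_aux = cell
        name = variant + ("" if loss_mode == base_cfg.loss_mode else f"+{loss_mode}")
        if not use_aux:
            name += "-noaux"
        per_seed = []
        for seed in seeds:
            cfg = replace(
                base_cfg,
                seed=seed,
                loss_mode=loss_mode,
                use_aux=use_aux,
                network=replace(base_cfg.network, variant=variant),
            )
            result = train(cfg, train_data)
            report = evaluate(result["network"], test_images, test_labels)
            per_seed.append(list(report["iou_per_class"]) + [report["miou"]])
            provenance.append({
                "cell": name, "seed": seed, "variant": variant,
                "loss_mode": loss_mode, "use_aux": use_aux,
                "epochs": cfg.epochs, "lr": cfg.lr, "miou": report["miou"],
            })
        med = np.median(np.array(per_seed), axis=0)
        rows[name] = list(med[:-1])
        mious[name] = float(med[-1])
    text, csv = report_table(rows)
    return {"rows": rows, "miou": mious, "table": text, "csv": csv,
            "provenance": provenance}
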