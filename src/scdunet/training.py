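"""Training and evaluation orchestration.

Five-fold protocol: train on the tumor-containing slices of the training
cases with the combined focal/Dice loss, monitor the validation mean
foreground aggregated DSC on full volumes every epoch, keep the best
checkpoint, and stop early after a fixed patience without improvement.
Optimisation is Adam with a cosine-annealed learning rate bounded below
by a floor.  Every source of randomness (weight init, batch shuffling)
derives from the config seeds, so a run is reproducible bit-for-bit on a
fixed platform.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .losses import LossConfig, combined_loss
from .metrics import MetricReport, STRUCTURES, dsc_agg, evaluate_volume
from .model import NetworkConfig, SCDUNet, build_scdunet
from .nn import Adam, Tensor, cosine_annealing_lr
from .phantom import MriCase
from .preprocess import normalize_intensity, read_case, resample_slice, screen_slices

__all__ = ["TrainConfig", "TrainHistory", "TrainResult", "toy_preset",
           "build_training_slices", "train_fold", "cross_validate",
           "predict_volume", "evaluate_cases", "early_stop_epoch",
           "make_toy_train_fn"]


@dataclass
class TrainConfig:
    """Optimiser/schedule/stopping configuration.

    Full-scale defaults follow the study protocol (Adam at 1e-4, batch 16,
    up to 1000 epochs, cosine annealing to a 1e-5 floor over 10 000 steps,
    20-epoch patience, 448x448 inputs).  ``toy_preset`` scales everything
    to the 64x64 phantom grid.
    """

    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 1000
    lr_floor: float = 1e-5
    schedule_period: int = 10_000      # steps over which the cosine decays
    early_stop_patience: int = 20
    seed: int = 0
    side: int = 448
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("learning_rate, batch_size and max_epochs must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.lr_floor < 0 or self.lr_floor > self.learning_rate:
            raise ValueError("lr_floor must lie in [0, learning_rate]")


def toy_preset(**overrides) -> TrainConfig:
    """Toy-scale configuration: 64x64 inputs, 8 base channels, batch 4.

    The learning rate is raised to 2e-3, proportionate to the much smaller
    network and problem, and the cosine period matches the planned step
    budget of a short run.
    """
    params = dict(learning_rate=2e-3, batch_size=4, max_epochs=30,
                  schedule_period=1200, early_stop_patience=10, side=64,
                  network=NetworkConfig(base_channels=8, reduction_ratio=4),
                  loss=LossConfig())
    params.update(overrides)
    return TrainConfig(**params)


@dataclass
class TrainHistory:
    rows: list = field(default_factory=list)   # epoch, train_loss, val_dsc, lr
    stop_reason: str = ""

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows, columns=["epoch", "train_loss", "val_dsc", "lr"])


@dataclass
class TrainResult:
    model: SCDUNet
    history: TrainHistory
    best_epoch: int
    best_val_dsc: float


def early_stop_epoch(monitor_values, patience: int):
    """Epoch (1-based) at which training stops under patience-based early
    stopping, or None if the sequence never triggers it.

    Stops at exactly best_epoch + patience when `patience` consecutive
    epochs fail to improve on the running best.
    """
    best = -np.inf
    best_epoch = 0
    for epoch, value in enumerate(monitor_values, start=1):
        if value > best:
            best = value
            best_epoch = epoch
        elif epoch - best_epoch >= patience:
            return epoch
    return None


def _resolve_cases(data, ids):
    """Accept a mapping id -> MriCase or a directory of NIfTI pairs."""
    if isinstance(data, (str, Path)):
        root = Path(data)
        missing = [i for i in ids if not (root / f"{i}_T2.nii.gz").exists()]
        if missing:
            raise FileNotFoundError(f"missing case files for ids: {missing}")
        return {i: read_case(root / f"{i}_T2.nii.gz", root / f"{i}_mask.nii.gz",
                             case_id=i) for i in ids}
    missing = [i for i in ids if i not in data]
    if missing:
        raise KeyError(f"missing cases for ids: {missing}")
    return {i: data[i] for i in ids}


def build_training_slices(cases, side: int):
    """Screened, normalised, resized training slices.

    Returns (images (N, side, side) float32, masks (N, side, side) int).
    Only slices containing tumor are retained (training-time screening).
    """
    images, masks = [], []
    for case in cases:
        vol = normalize_intensity(case.volume)
        for idx in screen_slices(case):
            img, msk = resample_slice(vol[:, :, idx], case.mask[:, :, idx], side)
            images.append(img.astype(np.float32))
            masks.append(msk.astype(np.int64))
    if not images:
        raise ValueError("no tumor-containing slices in the training cases")
    return np.stack(images), np.stack(masks)


def predict_volume(model: SCDUNet, case: MriCase, side: int | None = None,
                   batch_size: int = 8) -> np.ndarray:
    """Segment a full volume slice by slice (no screening).

    Each axial slice is normalised with the volume statistics, resized to
    the network side, classified by argmax over the logits, and the label
    slice is resized back to the native in-plane shape with
    nearest-neighbour interpolation.
    """
    if side is None:
        side = 448
    vol = normalize_intensity(case.volume).astype(np.float32)
    n_slices = vol.shape[2]
    from skimage.transform import resize as _resize
    slices = []
    for k in range(n_slices):
        img = vol[:, :, k]
        if img.shape != (side, side):
            img = _resize(img.astype(np.float64), (side, side), order=1,
                          preserve_range=True, anti_aliasing=False).astype(np.float32)
        slices.append(img)
    labels_small = model.predict_slices(np.stack(slices), batch_size=batch_size)
    native = case.mask.shape[:2]
    out = np.zeros(case.mask.shape, dtype=np.int16)
    for k in range(n_slices):
        lab = labels_small[k]
        if lab.shape != native:
            lab = _resize(lab, native, order=0, preserve_range=True,
                          anti_aliasing=False)
        out[:, :, k] = lab.astype(np.int16)
    return out


def _validation_monitor(model, cases, side, batch_size=8):
    """Mean over structures of the aggregated DSC on the validation set."""
    pairs = {name: [] for name in STRUCTURES}
    preds = []
    for case in cases:
        pred = predict_volume(model, case, side, batch_size=batch_size)
        preds.append(pred)
        for name, label in STRUCTURES.items():
            pairs[name].append((case.mask == label, pred == label))
    aggs = [dsc_agg(pairs[name]) for name in STRUCTURES]
    defined = [a for a in aggs if a is not None]
    return (float(np.mean(defined)) if defined else 0.0), preds


def train_fold(fold: dict, cfg: TrainConfig, data) -> TrainResult:
    """Train one fold and return the best-validation model plus history.

    `fold` holds "train" and "val" id lists; `data` is a case mapping or a
    directory of NIfTI pairs.
    """
    train_cases = list(_resolve_cases(data, fold["train"]).values())
    val_cases = list(_resolve_cases(data, fold["val"]).values())
    images, masks = build_training_slices(train_cases, cfg.side)

    model = build_scdunet(cfg.network)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    best_state, best_val, best_epoch = None, -np.inf, 0
    step = 0
    lr = cfg.learning_rate

    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(len(images))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            batch = Tensor(images[sel][:, None, :, :])
            lr = cosine_annealing_lr(step, lr_max=cfg.learning_rate,
                                     lr_min=cfg.lr_floor, period=cfg.schedule_period)
            optimizer.lr = lr
            loss = combined_loss(model(batch), masks[sel], cfg.loss)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
            step += 1
        val_dsc, _ = _validation_monitor(model, val_cases, cfg.side,
                                         batch_size=cfg.batch_size)
        history.rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                             "val_dsc": val_dsc, "lr": float(lr)})
        if val_dsc > best_val:
            best_val, best_epoch = val_dsc, epoch
            best_state = copy.deepcopy(model.state_dict())
        elif epoch - best_epoch >= cfg.early_stop_patience:
            history.stop_reason = f"no improvement for {cfg.early_stop_patience} epochs"
            break
    else:
        history.stop_reason = "max_epochs reached"

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       best_val_dsc=float(best_val))


def evaluate_cases(model: SCDUNet, cases, side: int) -> tuple:
    """MetricReport rows plus (gt, pred, spacing) triples for aggregation."""
    rows, triples = [], []
    for case in cases:
        pred = predict_volume(model, case, side)
        rows.extend(evaluate_volume(case.mask, pred, case.spacing_mm,
                                    case_id=case.case_id))
        triples.append((case.mask, pred, case.spacing_mm))
    return MetricReport(rows=rows), triples


def cross_validate(plan, cfg: TrainConfig, data) -> "pandas.DataFrame":
    """Run every fold; report per-fold and averaged validation metrics.

    Returns a table with one row per metric (mean foreground DSC, mean
    HD95) and columns Fold0..Fold{k-1} plus Average (arithmetic mean of
    the fold columns).
    """
    import pandas as pd

    dsc_cols, hd_cols = [], []
    for fold in plan.folds:
        result = train_fold(fold, cfg, data)
        val_cases = list(_resolve_cases(data, fold["val"]).values())
        report, triples = evaluate_cases(result.model, val_cases, cfg.side)
        summary = report.summary(triples)
        aggs = [summary[name]["dsc_agg"] for name in STRUCTURES
                if summary[name]["dsc_agg"] is not None]
        dsc_cols.append(float(np.mean(aggs)) if aggs else np.nan)
        hd = report.mean_hd95()
        hd_cols.append(np.nan if hd is None else hd)
    cols = {f"Fold{i}": [dsc_cols[i], hd_cols[i]] for i in range(len(dsc_cols))}
    frame = pd.DataFrame(cols, index=["dsc", "hd95_mm"])
    frame["Average"] = frame.mean(axis=1)
    return frame


def make_toy_train_fn(data, cfg: TrainConfig):
    """A `train_fn(fold, alpha)` for the mixing-weight grid search:
    trains with the fold's data at the given alpha and returns
    (mean foreground DSC, mean HD95) on the fold's validation cases."""
    def train_fn(fold, alpha):
        fold_cfg = copy.deepcopy(cfg)
        fold_cfg.loss.alpha = alpha
        result = train_fold(fold, fold_cfg, data)
        val_cases = list(_resolve_cases(data, fold["val"]).values())
        report, triples = evaluate_cases(result.model, val_cases, fold_cfg.side)
        summary = report.summary(triples)
        aggs = [summary[name]["dsc_agg"] for name in STRUCTURES
                if summary[name]["dsc_agg"] is not None]
        dsc = float(np.mean(aggs)) if aggs else float("nan")
        hd = report.mean_hd95()
        return dsc, float("nan") if hd is None else hd
    return train_fn
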