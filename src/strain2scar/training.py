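"""Training orchestration: single-fidelity, multi-fidelity, cross-validation
and the scaled-down multi-fidelity benefit benchmark.

Single-fidelity training fits a UNet to phantom images with an Adam
optimizer, early stopping on validation loss, and rotation augmentation
applied to training folds only (validation and test always see original
orientations, so no rotated copy of a subject ever leaks across the
split).  Multi-fidelity training minimizes the composite objective
MSE_L + MSE_H + lambda * sum(beta^2) jointly over the trunk and the two
correction heads, alternating low- and high-fidelity mini-batches within
each step and accumulating both gradients before the update.

All randomness (splits, shuffling, weight initialization) is routed
through seeds derived from the config seed, so identical seeds reproduce
identical histories.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import losses
from .bullseye import BullseyeLayout, augment_rotations, circular_roi
from .datasets import PhantomDataset, build_dataset, to_nchw
from .nn import (Adam, CompositeConfig, CompositeModel, UNet, UNetConfig,
                 build_composite, build_unet)
from .phantoms import DEFAULT_HF_SHIFT, FidelityShift, sample_phantom_specs


@dataclass
class TrainConfig:
    """Hyperparameters shared by the training entry points.

    Defaults follow the reference protocol: 100 epochs with early-stop
    patience 5, batch size 128, Adam at learning rate 1e-3, 128 x 128
    images.  ``loss`` picks the single-fidelity objective (bce/dsc/iou);
    the multi-fidelity objective is always the composite MSE.
    """

    epochs: int = 100
    patience: int = 5
    batch_size: int = 128
    learning_rate: float = 1e-3
    loss: str = "bce"
    l2_rate: float = 1e-5
    seed: int = 0
    image_size: int = 128
    channels: tuple = (16, 32, 64, 128, 256)
    val_fraction: float = 0.2
    augment: bool = True
    loss_domain: str = "roi"

    def __post_init__(self):
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.loss not in ("bce", "dsc", "iou", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.loss_domain not in ("roi", "full"):
            raise ValueError("loss_domain must be 'roi' or 'full'")


@dataclass
class FoldPlan:
    """Cross-validation folds: list of (train ids, test ids) with a tag."""

    folds: list
    scheme: str

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_fold_plan(subjects, scheme: str, k: int | None = None) -> FoldPlan:
    """Build a cross-validation plan over subject identifiers.

    ``loocv`` holds out each subject once; ``k_train_rest_test`` rotates a
    k-subject training window so every subject is tested at least once.
    Train and test sets are disjoint in every fold.
    """
    subjects = list(subjects)
    n = len(subjects)
    if n < 2:
        raise ValueError("at least two subjects are required")
    if scheme == "loocv":
        folds = [([s for j, s in enumerate(subjects) if j != i], [subjects[i]])
                 for i in range(n)]
        return FoldPlan(folds=folds, scheme="loocv")
    if scheme == "k_train_rest_test":
        if k is None or not (1 <= k < n):
            raise ValueError("k must satisfy 1 <= k < number of subjects")
        folds = []
        for i in range(n):
            train = [subjects[(i + j) % n] for j in range(k)]
            test = [s for s in subjects if s not in train]
            folds.append((train, test))
        return FoldPlan(folds=folds, scheme=f"k_train_rest_test(k={k})")
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# split and batching helpers

def _stratified_split(fractions, val_fraction, rng):
    """80/20-style split stratified on infarct-fraction quartile."""
    n = len(fractions)
    idx = np.arange(n)
    if fractions is None or val_fraction <= 0 or n < 5:
        rng.shuffle(idx)
        n_val = max(1, int(round(n * val_fraction))) if val_fraction > 0 else 0
        return idx[n_val:], idx[:n_val]
    qs = np.quantile(fractions, [0.25, 0.5, 0.75])
    strata = np.digitize(fractions, qs)
    train_idx, val_idx = [], []
    for s in np.unique(strata):
        members = idx[strata == s]
        rng.shuffle(members)
        n_val = max(1, int(round(len(members) * val_fraction)))
        val_idx.extend(members[:n_val])
        train_idx.extend(members[n_val:])
    return np.asarray(train_idx), np.asarray(val_idx)


def _batches(n, batch_size, rng=None):
    order = np.arange(n)
    if rng is not None:
        rng.shuffle(order)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _predict_batched(model, images_nchw, batch_size=32):
    out = []
    for start in range(0, len(images_nchw), batch_size):
        out.append(model.forward(images_nchw[start:start + batch_size]))
    return np.concatenate(out, axis=0)


def _epoch_loss(model, images, masks, loss_fn, roi):
    p = _predict_batched(model, images)
    return loss_fn(p[:, 0], masks[:, 0], roi)


# ---------------------------------------------------------------------------
# single fidelity

def train_single_fidelity(dataset: PhantomDataset, config: TrainConfig,
                          model: UNet | None = None):
    """Train a UNet on one fidelity; returns (best model, history frame).

    The dataset is split by phantom into train/validation (stratified on
    infarct-fraction quartile), rotation augmentation is applied to the
    training fold only, and the weights with the lowest validation loss
    are restored at the end.  Early stopping triggers after ``patience``
    consecutive epochs without improvement.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _stratified_split(dataset.fractions,
                                           config.val_fraction, rng)
    if len(train_idx) == 0:
        train_idx, val_idx = val_idx, train_idx
    train_pairs = dataset.subset(train_idx).pairs()
    if config.augment:
        train_pairs = augment_rotations(train_pairs)
    x_train, y_train = to_nchw(train_pairs)
    have_val = len(val_idx) > 0
    if have_val:
        x_val, y_val = to_nchw(dataset.subset(val_idx).pairs())

    res = dataset.resolution
    if model is None:
        model = build_unet(UNetConfig(input_resolution=res,
                                      channels=config.channels),
                           seed=config.seed)
    loss_fn, grad_fn = losses.LOSSES[config.loss]
    roi = (circular_roi(BullseyeLayout(resolution=res)).astype(bool)
           if config.loss_domain == "roi" else None)
    opt = Adam(model.parameters(), lr=config.learning_rate)

    history = []
    best_val = np.inf
    best_state = model.state_dict()
    bad_epochs = 0
    for epoch in range(1, config.epochs + 1):
        train_losses = []
        for batch in _batches(len(x_train), config.batch_size, rng):
            xb, yb = x_train[batch], y_train[batch]
            p = model.forward(xb)
            train_losses.append(loss_fn(p[:, 0], yb[:, 0], roi))
            g = grad_fn(p[:, 0], yb[:, 0], roi)[:, None]
            model.zero_grad()
            model.backward(g)
            if config.l2_rate > 0:
                for prm in model.parameters():
                    prm.grad += 2.0 * config.l2_rate * prm.data
            opt.step()
        val_loss = (_epoch_loss(model, x_val, y_val, loss_fn, roi)
                    if have_val else float(np.mean(train_losses)))
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(train_losses)),
                        "val_loss": float(val_loss)})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    model.load_state_dict(best_state)
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# multi fidelity

def train_multi_fidelity(lf_dataset: PhantomDataset,
                         hf_dataset: PhantomDataset | None,
                         config: TrainConfig,
                         lf_model: UNet | None = None,
                         composite_config: CompositeConfig | None = None,
                         epochs: int | None = None):
    """Jointly train the composite model on the multi-fidelity MSE objective.

    Returns (CompositeModel, history frame with per-epoch loss terms).
    ``lf_model`` may carry pre-trained trunk weights; otherwise the trunk
    is initialized fresh.  The high-fidelity set may be empty or None, in
    which case only MSE_L and the weight penalty are minimized.
    """
    if lf_dataset is None or len(lf_dataset) == 0:
        raise ValueError("low-fidelity dataset must be nonempty")
    rng = np.random.default_rng(config.seed + 1)
    res = lf_dataset.resolution
    if lf_model is None:
        lf_model = build_unet(UNetConfig(input_resolution=res,
                                         channels=config.channels),
                              seed=config.seed)
    composite_config = composite_config or CompositeConfig(l2_rate=config.l2_rate)
    model = build_composite(lf_model, composite_config, seed=config.seed + 2)

    lf_pairs = lf_dataset.pairs()
    if config.augment:
        lf_pairs = augment_rotations(lf_pairs)
    x_l, y_l = to_nchw(lf_pairs)
    have_hf = hf_dataset is not None and len(hf_dataset) > 0
    if have_hf:
        hf_pairs = hf_dataset.pairs()
        if config.augment:
            hf_pairs = augment_rotations(hf_pairs)
        x_h, y_h = to_nchw(hf_pairs)

    roi = (circular_roi(BullseyeLayout(resolution=res)).astype(bool)
           if config.loss_domain == "roi" else None)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    lam = composite_config.l2_rate
    n_epochs = epochs if epochs is not None else config.epochs

    history = []
    hf_bs = min(config.batch_size, len(x_h)) if have_hf else 0
    for epoch in range(1, n_epochs + 1):
        lf_batches = list(_batches(len(x_l), config.batch_size, rng))
        if have_hf:
            hf_order = rng.permutation(len(x_h))
        ep_mse_l, ep_mse_h = [], []
        for step, lb in enumerate(lf_batches):
            model.zero_grad()
            # low-fidelity pass through the trunk alone (MSE_L)
            p_l = model.lf.forward(x_l[lb])
            ep_mse_l.append(losses.mse_loss(p_l[:, 0], y_l[lb][:, 0], roi))
            model.lf.backward(
                losses.mse_grad(p_l[:, 0], y_l[lb][:, 0], roi)[:, None])
            # alternate with a high-fidelity pass through the composite (MSE_H)
            if have_hf:
                hb = hf_order[(step * hf_bs) % len(x_h):][:hf_bs]
                if len(hb) < hf_bs:
                    hb = np.concatenate([hb, hf_order[:hf_bs - len(hb)]])
                p_h = model.forward(x_h[hb])
                ep_mse_h.append(losses.mse_loss(p_h[:, 0], y_h[hb][:, 0], roi))
                model.backward(
                    losses.mse_grad(p_h[:, 0], y_h[hb][:, 0], roi)[:, None])
            if lam > 0:
                for prm in model.parameters():
                    if prm.name.endswith(".W"):
                        prm.grad += 2.0 * lam * prm.data
            opt.step()
        l2 = float(lam * sum(np.sum(p.data.astype(np.float64) ** 2)
                             for p in model.parameters()
                             if p.name.endswith(".W")))
        mse_l = float(np.mean(ep_mse_l))
        mse_h = float(np.mean(ep_mse_h)) if ep_mse_h else 0.0
        history.append({"epoch": epoch, "mse_l": mse_l, "mse_h": mse_h,
                        "l2_penalty": l2, "total": mse_l + mse_h + l2})
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# evaluation helper

def mean_dsc(model, dataset: PhantomDataset, threshold: float = 0.5) -> float:
    """Mean per-sample DSC of thresholded predictions over a dataset."""
    roi = circular_roi(BullseyeLayout(resolution=dataset.resolution))
    x, y = to_nchw(dataset.pairs())
    p = _predict_batched(model, x)
    scores = []
    for i in range(len(x)):
        pred = losses.binarize(p[i, 0], threshold, roi)
        scores.append(losses.evaluate(pred, y[i, 0].astype(np.uint8), roi).dsc)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# benchmark

@dataclass
class BenchmarkConfig:
    """Desk-scale multi-fidelity benefit experiment.

    Sizes are deliberately compact — 64 x 64 images, ~200 low-fidelity
    phantoms, a light (8, 16, 32) UNet ladder — so the full sweep runs on
    a single CPU in minutes while preserving the structure of the
    experiment: a trunk trained on abundant shifted-free data, correction
    heads trained on a handful of fidelity-shifted subjects, both
    evaluated on held-out shifted subjects.
    """

    n_low: int = 200
    hf_settings: tuple = (0, 2, 4)
    n_hf_test: int = 20
    resolution: int = 64
    channels: tuple = (8, 16, 32)
    lf_epochs: int = 8
    mf_epochs: int = 6
    batch_size: int = 16
    lf_learning_rate: float = 1e-3
    mf_learning_rate: float = 5e-4
    shift: FidelityShift = field(default_factory=lambda: DEFAULT_HF_SHIFT)


def run_benchmark(seeds=(0, 1, 2, 3, 4), bench: BenchmarkConfig | None = None,
                  out_dir=None):
    """Quantify the multi-fidelity benefit across high-fidelity counts.

    For each seed: sample and render a low-fidelity phantom library and a
    fidelity-shifted high-fidelity pool, train the trunk on the former,
    then for each setting train the composite correction heads on that
    many high-fidelity subjects (with rotation augmentation) and score the
    held-out shifted test subjects.  Setting 0 is the single-fidelity
    baseline (trunk alone on shifted data).

    Returns (per-run frame, aggregate frame); optionally writes CSVs and a
    summary plot under ``out_dir``.
    """
    bench = bench or BenchmarkConfig()
    layout = BullseyeLayout(resolution=bench.resolution)
    rows = []
    for seed in seeds:
        lf_specs = sample_phantom_specs(bench.n_low, seed=seed)
        lf_ds = build_dataset(lf_specs, layout)
        n_hf_pool = max(bench.hf_settings) + bench.n_hf_test
        hf_specs = sample_phantom_specs(n_hf_pool, seed=seed + 100_003,
                                        fidelity="high")
        hf_ds = build_dataset(hf_specs, layout, shift=bench.shift)
        hf_train_pool = hf_ds.subset(np.arange(max(bench.hf_settings)))
        hf_test = hf_ds.subset(np.arange(max(bench.hf_settings), n_hf_pool))

        # trunk pre-trained with the composite objective's own data term
        # (MSE_L), so joint fine-tuning continues the same objective
        cfg = TrainConfig(epochs=bench.lf_epochs, patience=bench.lf_epochs,
                          batch_size=bench.batch_size,
                          learning_rate=bench.lf_learning_rate,
                          channels=bench.channels, seed=seed,
                          image_size=bench.resolution, loss="mse",
                          augment=False)
        trunk, _ = train_single_fidelity(lf_ds, cfg)
        trunk_state = trunk.state_dict()

        for n_hf in bench.hf_settings:
            if n_hf == 0:
                dsc = mean_dsc(trunk, hf_test)
            else:
                trunk_i = build_unet(
                    UNetConfig(input_resolution=bench.resolution,
                               channels=bench.channels), seed=seed)
                trunk_i.load_state_dict(trunk_state)
                # rotation augmentation of the scarce high-fidelity subjects
                pairs = augment_rotations(
                    hf_train_pool.subset(np.arange(n_hf)).pairs())
                hf_aug = PhantomDataset(
                    images=np.stack([p[0] for p in pairs]),
                    masks=np.stack([p[1] for p in pairs]), fidelity="high")
                mf_cfg = replace(cfg, epochs=bench.mf_epochs,
                                 patience=bench.mf_epochs,
                                 learning_rate=bench.mf_learning_rate)
                composite, _ = train_multi_fidelity(
                    lf_ds, hf_aug, mf_cfg,
                    lf_model=trunk_i, epochs=bench.mf_epochs)
                dsc = mean_dsc(composite, hf_test)
            rows.append({"n_high_fidelity": n_hf, "seed": seed, "dsc": dsc})

    report = pd.DataFrame(rows)
    agg = (report.groupby("n_high_fidelity")["dsc"]
           .agg(["mean", "std"]).reset_index())
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "benchmark_runs.csv", index=False)
        agg.to_csv(out_dir / "benchmark_summary.csv", index=False)
        _plot_benchmark(agg, out_dir / "benchmark.png")
    return report, agg


def _plot_benchmark(agg: pd.DataFrame, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(agg["n_high_fidelity"], agg["mean"], yerr=agg["std"],
                marker="o", capsize=3)
    ax.set_xlabel("high-fidelity subjects in training")
    ax.set_ylabel("held-out DSC")
    ax.set_title("Multi-fidelity benefit")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
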