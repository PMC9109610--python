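"""U-net phase-stack-to-ventilation regressor.

The learned estimator maps an axial stack of co-registered breathing-phase
slices directly to the reference ventilation slice, bypassing deformable
registration entirely.  Input modes:

* ``phases10``  — all ten phases T00..T90 as 10 channels;
* ``phases2``   — peak inhale and peak exhale only, 2 channels;
* ``phases10_adjacent`` — 2.5D variant: each phase contributes the slice and
  its two axial neighbors (clamped at the edges), 30 channels.

Training follows an image-regression recipe: he-normal init, RMSprop at
1e-4 on mean squared error with mini-batches of 4, an 80/20 subject-level
train/validation split, learning-rate drop x0.2 after 10 stagnant validation
epochs, early stopping after 15, and restoration of the best-validation
weights.  Augmentation (flip/rotate/scale/shift) is applied identically to
all input channels and the label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from ._seeds import derive_seed
from .errors import ConfigError, DataError, SplitError
from .imagecore import crop_center, crop_center_mask
from .nnet import Conv2D, Dropout, MaxPool2, ReLU, RMSprop, Upsample2, mse_loss
from .ventilation import VentilationImage, postprocess

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SliceSample",
    "FoldSplit",
    "UNet",
    "make_samples",
    "augment",
    "build_unet",
    "train",
    "predict_volume",
    "crossvalidate",
]

INPUT_MODES = ("phases10", "phases2", "phases10_adjacent")


@dataclass
class ModelConfig:
    """U-net sizing; the clinical-scale default is 192 in-plane with depth 4
    and 64 base filters, the desk-scale test default 64/depth 3/base 8."""

    input_mode: str = "phases10"
    in_plane_size: int = 192
    depth: int = 4
    base_filters: int = 64
    dropout_rate: float = 0.2
    output_nonneg: bool = True

    def __post_init__(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ConfigError(f"input_mode must be one of {INPUT_MODES}")
        if self.in_plane_size % (2**self.depth) != 0:
            raise ConfigError(
                f"in_plane_size {self.in_plane_size} not divisible by 2^depth={2**self.depth}"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")

    @property
    def n_channels(self) -> int:
        return {"phases10": 10, "phases2": 2, "phases10_adjacent": 30}[self.input_mode]


@dataclass
class TrainConfig:
    """Optimization schedule (RMSprop / MSE)."""

    initial_lr: float = 1e-4
    batch_size: int = 4
    plateau_factor: float = 0.2
    plateau_patience: int = 10
    early_stop_patience: int = 15
    max_epochs: int = 300
    validation_fraction: float = 0.2
    augment_flip: bool = True
    augment_rotate_deg: float = 10.0
    augment_scale: float = 0.10
    augment_shift_px: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.plateau_factor < 1:
            raise ConfigError("plateau_factor must be in (0, 1)")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ConfigError("patiences must be positive")


@dataclass
class SliceSample:
    """One training sample: a (C, H, W) phase stack and its (H, W) label."""

    input: np.ndarray
    label: np.ndarray
    subject_id: str
    slice_index: int


@dataclass
class FoldSplit:
    """Partition of subject ids into k folds (by subject, never by slice)."""

    folds: list[list[str]]

    def __post_init__(self) -> None:
        flat = [s for f in self.folds for s in f]
        if len(flat) != len(set(flat)):
            raise SplitError("fold assignment is not a partition (duplicate subject)")

    @property
    def k(self) -> int:
        return len(self.folds)


# ---------------------------------------------------------------------------
# Sample extraction
# ---------------------------------------------------------------------------

def _scale_hu(values: np.ndarray) -> np.ndarray:
    """HU -> network input scale: (HU + 1000)/1000 clipped to [0, 2]."""
    return np.clip((values + 1000.0) / 1000.0, 0.0, 2.0)


def _label_volume(subject) -> np.ndarray:
    """Reference ventilation normalized by the in-mask 90th percentile and
    zeroed outside the exhale lung mask."""
    m = subject.exhale_mask.values
    ref = subject.spect_like.values
    norm = float(np.percentile(ref[m], 90.0))
    if norm <= 0:
        raise DataError("reference ventilation has nonpositive 90th percentile")
    return np.where(m, ref / norm, 0.0)


def _phase_indices(mode: str) -> list[int]:
    return [0, 5] if mode == "phases2" else list(range(10))


def make_samples(subjects, config: ModelConfig) -> list[SliceSample]:
    """One sample per axial slice intersecting the exhale lung mask.

    Channels are ordered T00..T90 (``phases10``), [T00, T50] (``phases2``),
    or per phase the slice below, the slice, and the slice above
    (``phases10_adjacent``, edge slices clamped).  Inputs are scaled HU,
    labels per-subject-normalized reference ventilation.
    """
    size = (config.in_plane_size, config.in_plane_size)
    samples: list[SliceSample] = []
    for subject in subjects:
        phases = [
            _scale_hu(crop_center(subject.series.phases[p], size).values)
            for p in _phase_indices(config.input_mode)
        ]
        mask_c = crop_center_mask(subject.exhale_mask, size).values
        lbl = crop_center(
            subject.series.exhale.with_values(_label_volume(subject), "dimensionless"), size
        ).values
        nz = subject.series.grid.shape[2]
        z_any = np.where(mask_c.any(axis=(0, 1)))[0]
        if z_any.size == 0:
            raise DataError(f"subject {subject.subject_id}: no lung-intersecting slices")
        for z in z_any:
            chans = []
            for ph in phases:
                if config.input_mode == "phases10_adjacent":
                    for dz in (-1, 0, 1):
                        chans.append(ph[:, :, int(np.clip(z + dz, 0, nz - 1))])
                else:
                    chans.append(ph[:, :, z])
            samples.append(
                SliceSample(
                    input=np.stack(chans).astype(np.float32),
                    label=lbl[:, :, z].astype(np.float32),
                    subject_id=subject.subject_id,
                    slice_index=int(z),
                )
            )
    return samples


def augment(sample: SliceSample, config: TrainConfig, rng: np.random.Generator) -> SliceSample:
    """Random flip/rotate/scale/shift, identical for all channels and label."""
    do_flip = config.augment_flip and rng.random() < 0.5
    angle = rng.uniform(-config.augment_rotate_deg, config.augment_rotate_deg) \
        if config.augment_rotate_deg > 0 and rng.random() < 0.5 else 0.0
    scale = 1.0 + rng.uniform(-config.augment_scale, config.augment_scale) \
        if config.augment_scale > 0 and rng.random() < 0.5 else 1.0
    shift = rng.uniform(-config.augment_shift_px, config.augment_shift_px, size=2) \
        if config.augment_shift_px > 0 and rng.random() < 0.5 else np.zeros(2)

    if not do_flip and angle == 0.0 and scale == 1.0 and not shift.any():
        return sample

    h, w = sample.label.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    theta = np.deg2rad(angle)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    mat = rot / scale
    offset = center - mat @ (center + shift)

    def apply(img: np.ndarray) -> np.ndarray:
        out = ndimage.affine_transform(img, mat, offset=offset, order=1, cval=0.0)
        return out[::-1, :] if do_flip else out

    chans = np.stack([apply(c) for c in sample.input]).astype(np.float32)
    label = apply(sample.label).astype(np.float32)
    return SliceSample(chans, label, sample.subject_id, sample.slice_index)


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------

class UNet:
    """Encoder-decoder with skip connections.

    Each encoder block: two 3x3 conv + ReLU, dropout, then 2x2 max pool
    (filters doubling per level).  Each decoder block: 2x2 nearest upsample,
    one 3x3 conv + ReLU, concatenation with the matching encoder output, two
    3x3 conv + ReLU.  Head: one 3x3 conv + ReLU, then a 1x1 conv (+ ReLU if
    the output is constrained nonnegative).
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = config.base_filters
        c_in = config.n_channels
        self.enc = []
        for d in range(config.depth):
            c_out = f * 2**d
            self.enc.append(
                {
                    "conv1": Conv2D(c_in, c_out, 3, rng),
                    "relu1": ReLU(),
                    "conv2": Conv2D(c_out, c_out, 3, rng),
                    "relu2": ReLU(),
                    "drop": Dropout(config.dropout_rate),
                    "pool": MaxPool2(),
                }
            )
            c_in = c_out
        c_bot = f * 2**config.depth
        self.bottom = {
            "conv1": Conv2D(c_in, c_bot, 3, rng),
            "relu1": ReLU(),
            "conv2": Conv2D(c_bot, c_bot, 3, rng),
            "relu2": ReLU(),
        }
        self.dec = []
        c_in = c_bot
        for d in reversed(range(config.depth)):
            c_out = f * 2**d
            self.dec.append(
                {
                    "up": Upsample2(),
                    "upconv": Conv2D(c_in, c_out, 3, rng),
                    "uprelu": ReLU(),
                    "conv1": Conv2D(2 * c_out, c_out, 3, rng),
                    "relu1": ReLU(),
                    "conv2": Conv2D(c_out, c_out, 3, rng),
                    "relu2": ReLU(),
                }
            )
            c_in = c_out
        self.head = {
            "conv3": Conv2D(c_in, f, 3, rng),
            "relu3": ReLU(),
            "conv1": Conv2D(f, 1, 1, rng),
        }
        self.head_relu = ReLU() if config.output_nonneg else None
        for i, d in enumerate(self._dropouts()):
            d.reseed(derive_seed(seed, f"dropout{i}"))

    def _dropouts(self):
        return [blk["drop"] for blk in self.enc]

    def layers(self) -> list:
        out = []
        for blk in self.enc:
            out += [blk["conv1"], blk["conv2"]]
        out += [self.bottom["conv1"], self.bottom["conv2"]]
        for blk in self.dec:
            out += [blk["upconv"], blk["conv1"], blk["conv2"]]
        out += [self.head["conv3"], self.head["conv1"]]
        return out

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        for blk in self.enc:
            x = blk["relu1"].forward(blk["conv1"].forward(x, train), train)
            x = blk["relu2"].forward(blk["conv2"].forward(x, train), train)
            x = blk["drop"].forward(x, train)
            skips.append(x)
            x = blk["pool"].forward(x, train)
        x = self.bottom["relu1"].forward(self.bottom["conv1"].forward(x, train), train)
        x = self.bottom["relu2"].forward(self.bottom["conv2"].forward(x, train), train)
        self._skip_channels = []
        for blk, skip in zip(self.dec, reversed(skips)):
            x = blk["up"].forward(x, train)
            x = blk["uprelu"].forward(blk["upconv"].forward(x, train), train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = blk["relu1"].forward(blk["conv1"].forward(x, train), train)
            x = blk["relu2"].forward(blk["conv2"].forward(x, train), train)
        x = self.head["relu3"].forward(self.head["conv3"].forward(x, train), train)
        x = self.head["conv1"].forward(x, train)
        if self.head_relu is not None:
            x = self.head_relu.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        if self.head_relu is not None:
            dy = self.head_relu.backward(dy)
        dy = self.head["conv1"].backward(dy)
        dy = self.head["conv3"].backward(self.head["relu3"].backward(dy))
        dskips = []
        for blk, c_skip in zip(reversed(self.dec), reversed(self._skip_channels)):
            dy = blk["conv2"].backward(blk["relu2"].backward(dy))
            dy = blk["conv1"].backward(blk["relu1"].backward(dy))
            dskips.append(dy[:, :c_skip])
            dy = dy[:, c_skip:]
            dy = blk["upconv"].backward(blk["uprelu"].backward(dy))
            dy = blk["up"].backward(dy)
        dy = self.bottom["conv2"].backward(self.bottom["relu2"].backward(dy))
        dy = self.bottom["conv1"].backward(self.bottom["relu1"].backward(dy))
        for blk, dskip in zip(reversed(self.enc), reversed(dskips)):
            dy = blk["pool"].backward(dy)
            dy = blk["drop"].backward(dy + dskip)
            dy = blk["conv2"].backward(blk["relu2"].backward(dy))
            dy = blk["conv1"].backward(blk["relu1"].backward(dy))

    def get_weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(l.W.copy(), l.b.copy()) for l in self.layers()]

    def set_weights(self, weights) -> None:
        for layer, (W, b) in zip(self.layers(), weights):
            layer.W = W.copy()
            layer.b = b.copy()

    def predict(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        out = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)


def build_unet(config: ModelConfig, seed: int = 0) -> UNet:
    """Construct a U-net with he-normal initial weights (seeded)."""
    return UNet(config, seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _split_by_subject(samples, fraction: float, rng: np.random.Generator):
    ids = sorted({s.subject_id for s in samples})
    if len(ids) < 2:
        raise SplitError("need at least 2 subjects for a subject-level train/val split")
    ids = list(rng.permutation(ids))
    n_val = max(1, int(round(fraction * len(ids))))
    if n_val >= len(ids):
        n_val = len(ids) - 1
    val_ids = set(ids[:n_val])
    train_s = [s for s in samples if s.subject_id not in val_ids]
    val_s = [s for s in samples if s.subject_id in val_ids]
    return train_s, val_s


def _eval_loss(model: UNet, samples, batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(samples), batch_size):
        batch = samples[i : i + batch_size]
        x = np.stack([s.input for s in batch])
        y = np.stack([s.label for s in batch])[:, None]
        pred = model.forward(x, train=False)
        total += float(np.sum((pred - y) ** 2))
        n += pred.size
    return total / n


def train(
    samples: list[SliceSample],
    model: UNet,
    config: TrainConfig,
    val_samples: list[SliceSample] | None = None,
) -> tuple[UNet, pd.DataFrame]:
    """Train with the RMSprop/plateau/early-stop schedule.

    Splits 80/20 by subject unless an explicit validation set is given.
    Returns the model carrying the weights of the epoch with minimum
    validation loss, plus the per-epoch history (train loss, val loss, lr).
    """
    rng = np.random.default_rng(derive_seed(config.seed, "train"))
    if val_samples is None:
        train_s, val_s = _split_by_subject(samples, config.validation_fraction, rng)
    else:
        train_s, val_s = list(samples), list(val_samples)
    if not train_s or not val_s:
        raise SplitError("empty training or validation set")

    opt = RMSprop(model.layers(), lr=config.initial_lr)
    aug_rng = np.random.default_rng(derive_seed(config.seed, "augment"))
    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    plateau_wait = 0
    stop_wait = 0
    history = []
    augmenting = config.augment_flip or config.augment_rotate_deg > 0 \
        or config.augment_scale > 0 or config.augment_shift_px > 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_s))
        run_loss, run_n = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            batch = [train_s[j] for j in order[i : i + config.batch_size]]
            if augmenting:
                batch = [augment(s, config, aug_rng) for s in batch]
            x = np.stack([s.input for s in batch])
            y = np.stack([s.label for s in batch])[:, None]
            pred = model.forward(x, train=True)
            loss, dloss = mse_loss(pred, y)
            model.backward(dloss.astype(np.float32))
            opt.step()
            run_loss += loss * pred.size
            run_n += pred.size
        val_loss = _eval_loss(model, val_s, config.batch_size)
        history.append(
            {"epoch": epoch, "train_loss": run_loss / run_n, "val_loss": val_loss, "lr": opt.lr}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            plateau_wait = 0
            stop_wait = 0
        else:
            plateau_wait += 1
            stop_wait += 1
            if plateau_wait >= config.plateau_patience:
                opt.lr *= config.plateau_factor
                plateau_wait = 0
            if stop_wait >= config.early_stop_patience:
                break

    model.set_weights(best_weights)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return model, hist


# ---------------------------------------------------------------------------
# Prediction and cross-validation
# ---------------------------------------------------------------------------

def predict_volume(
    model: UNet, subject, config: ModelConfig, filter_size: int = 9
) -> VentilationImage:
    """Slice-wise inference reassembled on the exhale grid, post-processed.

    ``filter_size`` is the median-filter box of the post-processing chain;
    pass 1 to skip smoothing (appropriate when the grid is coarse enough
    that a 9-voxel box spans a large fraction of the lung).
    """
    samples = make_samples([subject], config)
    x = np.stack([s.input for s in samples])
    pred = model.predict(x)[:, 0]
    grid = subject.series.grid
    full = np.zeros(grid.shape)
    nx, ny, _ = grid.shape
    size = config.in_plane_size
    ox, oy = (nx - size) // 2, (ny - size) // 2
    for s, sl in zip(samples, pred):
        full[ox : ox + size, oy : oy + size, s.slice_index] = sl
    vi = VentilationImage(full, subject.exhale_mask, "DL")
    return postprocess(vi, subject.exhale_mask, filter_size=filter_size)


def save_model(model: UNet, directory) -> None:
    """Serialize weights (npz) plus a schema-versioned JSON config."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, (w, b) in enumerate(model.get_weights()):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(directory / "weights.npz", **arrays)
    meta = {"schema": 1, "model_config": asdict(model.config)}
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(directory) -> UNet:
    """Inverse of save_model."""
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    if meta.get("schema") != 1:
        raise ConfigError(f"unsupported model schema {meta.get('schema')}")
    config = ModelConfig(**meta["model_config"])
    model = UNet(config, seed=0)
    with np.load(directory / "weights.npz") as data:
        n = len(model.layers())
        model.set_weights([(data[f"W{i}"], data[f"b{i}"]) for i in range(n)])
    return model


def make_folds(subject_ids: list[str], k: int, seed: int) -> FoldSplit:
    """Seeded random partition of subjects into k near-equal folds."""
    if k > len(subject_ids):
        raise SplitError(f"k={k} folds but only {len(subject_ids)} subjects")
    rng = np.random.default_rng(derive_seed(seed, "folds"))
    order = list(rng.permutation(sorted(subject_ids)))
    folds = [sorted(order[i::k]) for i in range(k)]
    return FoldSplit(folds)


def crossvalidate(
    subjects,
    k: int = 7,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    reference_getter=None,
    train_fn=None,
    predict_fn=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sevenfold-style patient-level cross-validation.

    For each fold: train on the remaining subjects (with an internal 80/20
    subject-level validation split), predict the held-out subjects, and
    evaluate each prediction against its reference with masked Spearman and
    tertile DSC.  A subject-id audit guarantees zero test leakage.  Returns
    (per-subject report, per-fold summary).

    ``train_fn(samples, model, config) -> model`` and
    ``predict_fn(model, subject, config) -> VentilationImage`` default to the
    real implementations; they are injectable so the harness can be
    exercised with cheap stand-ins.
    """
    from .evaluation import evaluate_subject

    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    if train_fn is None:
        def train_fn(samples, model, config):
            return train(samples, model, config)[0]
    if predict_fn is None:
        predict_fn = predict_volume
    if reference_getter is None:
        def reference_getter(s):
            return VentilationImage(s.spect_like.values, s.exhale_mask, "REF")

    by_id = {s.subject_id: s for s in subjects}
    split = make_folds(sorted(by_id), k, seed)
    rows = []
    for fold_i, test_ids in enumerate(split.folds):
        test_set = set(test_ids)
        train_subjects = [s for s in subjects if s.subject_id not in test_set]
        assert not ({s.subject_id for s in train_subjects} & test_set), "subject leakage"
        samples = make_samples(train_subjects, model_config)
        assert not ({s.subject_id for s in samples} & test_set), "slice leakage"
        model = build_unet(model_config, seed=derive_seed(seed, f"fold{fold_i}-init"))
        fold_tc = replace(train_config, seed=derive_seed(seed, f"fold{fold_i}-train"))
        model = train_fn(samples, model, fold_tc)
        for sid in test_ids:
            subject = by_id[sid]
            vi = predict_fn(model, subject, model_config)
            report = evaluate_subject({"DL": vi}, reference_getter(subject), subject.exhale_mask)
            row = report.iloc[0].to_dict()
            row.update({"subject_id": sid, "fold": fold_i})
            rows.append(row)
    per_subject = pd.DataFrame(rows)
    tested = sorted(per_subject["subject_id"])
    assert tested == sorted(by_id), "each subject must be tested exactly once"
    per_fold = (
        per_subject.groupby("fold")[["spearman", "dsc_hfl", "dsc_mfl", "dsc_lfl", "dsc_avg"]]
        .mean()
        .reset_index()
    )
    return per_subject, per_fold
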