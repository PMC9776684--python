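"""Per-spectrum ADC/SqCC classification and evaluation-dataset assembly.

The classifier is a 1-D residual convnet over the preprocessed spectrum:
the first convolution spans 5 channels (≈ 5 Da at the peptide-resampled
resolution, the width of an isotope envelope), followed by two residual
blocks, global average pooling and a 2-class softmax head.  Training uses
the repeated-training / best-epoch protocol with balanced accuracy as the
selection metric.

This module also builds the four mask-defined evaluation spot subsets per
section: D1 (pathologist annotations), D2 (segmented tumor), D3 = D2 \\ D1
(segmented but unannotated) and D4 (everything outside the segmentation).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigError, ValidationError
from .register import AffineTransform2D, transfer_mask_to_spots
from .types import ADC, SQCC, BinaryMask, MsiDataset, SpectrumPrediction

log = logging.getLogger(__name__)

LABEL_TO_INDEX = {ADC: 0, SQCC: 1}
INDEX_TO_LABEL = {v: k for k, v in LABEL_TO_INDEX.items()}


@dataclass
class SpecTrainConfig:
    """Training protocol for the spectrum classifier."""

    epochs: int = 15
    repetitions: int = 5
    learning_rate: float = 3e-3
    batch_size: int = 64
    seed: int = 0
    selection_metric: str = "balanced_accuracy"
    channels: int = 16
    pool: int = 4

    def validate(self) -> "SpecTrainConfig":
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        if self.selection_metric != "balanced_accuracy":
            raise ConfigError(f"unknown selection metric {self.selection_metric!r}")
        return self


class IsotopeNet1d:
    """1-D residual convnet over a fixed-length spectrum.

    conv(k=5) -> ReLU -> avgpool -> 2 residual blocks -> avgpool ->
    flatten -> dense softmax head.  The convolutional part extracts local
    isotope-envelope features; the head is position-aware (dense over
    pooled positions) because the subtype signal lies in *which* masses
    carry peaks — a translation-invariant pooling head cannot represent
    that.
    """

    KERNEL = 5

    def __init__(self, n_channels: int, channels: int = 16, pool: int = 4, seed: int = 0):
        if n_channels < self.KERNEL:
            raise ConfigError(
                f"spectrum length {n_channels} shorter than the kernel width {self.KERNEL}"
            )
        rng = np.random.default_rng(seed)
        self.n_channels = n_channels
        # per-channel input standardization (training-set statistics):
        # preprocessed spectra are dominated by a flat shared level, and the
        # class signal lives in a few marker channels; z-scoring makes those
        # O(1) for the convolutions
        self.input_mean = np.zeros(n_channels)
        self.input_sd = np.ones(n_channels)
        self.stem = [nn.Conv1d(1, channels, self.KERNEL, rng), nn.ReLU(), nn.AvgPool1d(pool)]
        self.blocks = []
        for _ in range(2):
            self.blocks.append([
                nn.Conv1d(channels, channels, self.KERNEL, rng),
                nn.ReLU(),
                nn.Conv1d(channels, channels, self.KERNEL, rng),
            ])
        self.post = [nn.ReLU(), nn.ReLU()]
        self.pool2 = nn.AvgPool1d(pool)
        self.flatten = nn.Flatten()
        l1 = -(-n_channels // pool)  # ceil division: length after each pool
        l2 = -(-l1 // pool)
        self.head = nn.Dense(channels * l2, 2, rng)

    def _all_layers(self):
        out = list(self.stem)
        for blk in self.blocks:
            out.extend(blk)
        out.extend(self.post)
        out.extend([self.pool2, self.flatten, self.head])
        return out

    @property
    def n_params(self) -> int:
        return nn.count_params(self._all_layers())

    def params(self):
        return [p for layer in self._all_layers() for p in layer.params()]

    def get_state(self):
        return nn.get_state(self._all_layers())

    def set_state(self, state):
        nn.set_state(self._all_layers(), state)

    def set_input_stats(self, train_x: np.ndarray) -> None:
        self.input_mean = train_x.mean(axis=0)
        self.input_sd = np.maximum(train_x.std(axis=0), 1e-8)

    def forward(self, x, train=False):
        """x: (B, L) spectra -> (B, 2) logits."""
        if x.shape[1] != self.n_channels:
            raise ValidationError(
                f"spectrum length {x.shape[1]} does not match model input {self.n_channels}"
            )
        h = ((x - self.input_mean) / self.input_sd)[:, None, :]
        for layer in self.stem:
            h = layer.forward(h, train=train)
        for blk, post in zip(self.blocks, self.post):
            r = h
            for layer in blk:
                r = layer.forward(r, train=train)
            h = post.forward(h + r, train=train)
        h = self.pool2.forward(h, train=train)
        h = self.flatten.forward(h, train=train)
        return self.head.forward(h, train=train)

    def backward(self, dlogits):
        d = self.head.backward(dlogits)
        d = self.flatten.backward(d)
        d = self.pool2.backward(d)
        for blk, post in zip(reversed(self.blocks), reversed(self.post)):
            d = post.backward(d)
            dr = d
            for layer in reversed(blk):
                dr = layer.backward(dr)
            d = d + dr
        for layer in reversed(self.stem):
            d = layer.backward(d)
        return d[:, 0, :]

    def predict_proba(self, x):
        return nn.softmax(self.forward(x, train=False), axis=1)


class StubSpecModel:
    """Constant-probability spectrum model for dry runs and wiring tests."""

    def __init__(self, p_adc=0.9, n_channels=None):
        self.p_adc = float(p_adc)
        self.n_channels = n_channels
        self.n_params = 0

    def predict_proba(self, x):
        out = np.empty((x.shape[0], 2))
        out[:, 0] = self.p_adc
        out[:, 1] = 1.0 - self.p_adc
        return out


def build_isotopenet(n_channels: int, config: SpecTrainConfig) -> IsotopeNet1d:
    cfg = config.validate()
    model = IsotopeNet1d(n_channels, channels=cfg.channels, pool=cfg.pool, seed=cfg.seed)
    log.info("IsotopeNet-style model: %d input channels, %d parameters",
             n_channels, model.n_params)
    return model


def _balanced_accuracy_idx(pred_idx, true_idx):
    accs = []
    for c in (0, 1):
        sel = true_idx == c
        if sel.any():
            accs.append(float((pred_idx[sel] == c).mean()))
    return float(np.mean(accs))


def train_spectrum_classifier(train_x, train_y, val_x, val_y, config: SpecTrainConfig):
    """Repeated training with best-epoch selection on validation balanced accuracy.

    ``*_y`` are label strings (ADC/SqCC); both classes must be present in
    both splits.  Returns (model, history) where the history records the
    per-epoch validation balanced accuracy of every repetition and the
    selected checkpoint.
    """
    cfg = config.validate()
    ytr = np.array([LABEL_TO_INDEX[y] for y in train_y])
    yva = np.array([LABEL_TO_INDEX[y] for y in val_y])
    for name, y in (("training", ytr), ("validation", yva)):
        if len(np.unique(y)) < 2:
            raise ValidationError(f"{name} split contains only one class")
    train_x = np.asarray(train_x, dtype=np.float64)
    val_x = np.asarray(val_x, dtype=np.float64)
    n_channels = train_x.shape[1]

    history = {"repetitions": [], "param_count": None}
    best = {"val_bacc": -1.0, "repetition": None, "epoch": None, "state": None}
    n_aborted = 0
    for rep in range(cfg.repetitions):
        rng = np.random.default_rng([cfg.seed, rep])
        model = IsotopeNet1d(n_channels, channels=cfg.channels, pool=cfg.pool,
                             seed=int(rng.integers(2**31 - 1)))
        model.set_input_stats(train_x)
        history["param_count"] = model.n_params
        opt = nn.Adam(model.params(), lr=cfg.learning_rate)
        rep_hist = []
        aborted = False
        for epoch in range(cfg.epochs):
            order = rng.permutation(train_x.shape[0])
            for i in range(0, order.size, cfg.batch_size):
                sel = order[i : i + cfg.batch_size]
                logits = model.forward(train_x[sel], train=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, ytr[sel], axis=1)
                if not np.isfinite(loss):
                    aborted = True
                    break
                opt.zero_grad()
                model.backward(dlogits)
                opt.step()
            if aborted:
                log.warning("classifier repetition %d aborted on NaN loss", rep)
                break
            pred = np.argmax(model.predict_proba(val_x), axis=1)
            bacc = _balanced_accuracy_idx(pred, yva)
            rep_hist.append(bacc)
            if bacc > best["val_bacc"]:
                best.update(val_bacc=bacc, repetition=rep, epoch=epoch,
                            state=model.get_state())
        history["repetitions"].append(rep_hist)
        if aborted:
            n_aborted += 1
    if n_aborted == cfg.repetitions:
        raise ValidationError("all classifier repetitions aborted with NaN loss")

    model = IsotopeNet1d(n_channels, channels=cfg.channels, pool=cfg.pool, seed=cfg.seed)
    model.set_input_stats(train_x)
    model.set_state(best["state"])
    history["best"] = {k: best[k] for k in ("val_bacc", "repetition", "epoch")}
    return model, history


def predict_spectra(model, ds: MsiDataset):
    """One prediction per spot; exact probability ties resolve to ADC.

    Ties are measure-zero in practice but must be deterministic; the tie
    count is logged.
    """
    if getattr(model, "n_channels", None) not in (None, ds.n_channels):
        raise ValidationError(
            f"dataset has {ds.n_channels} channels, model expects {model.n_channels}"
        )
    probs = model.predict_proba(np.asarray(ds.intensities, dtype=np.float64))
    n_ties = int(np.sum(probs[:, 0] == probs[:, 1]))
    if n_ties:
        log.info("predict_spectra: %d exact probability ties resolved to ADC", n_ties)
    out = []
    for i in range(ds.n_spots):
        p_adc, p_sqcc = float(probs[i, 0]), float(probs[i, 1])
        label = ADC if p_adc >= p_sqcc else SQCC
        out.append(SpectrumPrediction(
            section_id=ds.section_id, x=int(ds.coords[i, 0]), y=int(ds.coords[i, 1]),
            p_adc=p_adc, p_sqcc=p_sqcc, label=label,
        ))
    return out


def build_eval_datasets(ds: MsiDataset, annotation_mask: BinaryMask,
                        segmentation_mask: BinaryMask, transform: AffineTransform2D):
    """The four mask-defined evaluation spot subsets of one section.

    D1 = spots inside the (incomplete) annotations; D2 = spots inside the
    segmented tumor regions; D3 = D2 \\ D1; D4 = complement of D2.  Spots
    mapping outside a mask raster count as outside that mask.

    Returns a dict with boolean membership arrays ``D1``..``D4`` over the
    dataset's spots plus a ``counts`` entry.
    """
    d1, _ = transfer_mask_to_spots(annotation_mask, transform, ds)
    d2, _ = transfer_mask_to_spots(segmentation_mask, transform, ds)
    d3 = d2 & ~d1
    d4 = ~d2
    out = {"D1": d1, "D2": d2, "D3": d3, "D4": d4}
    out["counts"] = {k: int(v.sum()) for k, v in out.items()}
    for name in ("D1", "D2", "D3", "D4"):
        if out["counts"][name] == 0:
            log.info("section %s: dataset %s is empty", ds.section_id, name)
    return out


def assemble_training_variants(tma_spots: dict, section_spots: dict, group_map: dict):
    """Build the MALDI1/2/3 training and validation spot-index specs.

    Parameters
    ----------
    tma_spots : {sample_id: {"group": g, "annotation": bool array,
                 "seg": {model_name: bool array}}}
    section_spots : {section_id: {"annotation": bool array,
                     "seg1": bool array}}  (validation sections only)
    group_map : {model_name: validated group id}

    Returns
    -------
    {"MALDI1" | "MALDI2" | "MALDI3": {"train": {sid: bool array},
                                      "val": {sid: bool array}}}

    MALDI1 and MALDI2 share the identical annotation-based training set and
    differ only in validation (annotations vs Seg1 tumor regions);
    MALDI3 trains on segmentation-derived spots, where each TMA group
    contributes the regions found by the network that was *validated* on
    that group (and therefore never trained on it).
    """
    if not group_map:
        raise ValidationError("missing segmentation group map")
    model_for_group = {g: m for m, g in group_map.items()}
    ann_train = {sid: rec["annotation"] for sid, rec in tma_spots.items()}
    seg_train = {}
    for sid, rec in tma_spots.items():
        model = model_for_group.get(rec["group"])
        if model is None:
            raise ValidationError(f"no segmentation model validated on group {rec['group']!r}")
        seg_train[sid] = rec["seg"][model]
    ann_val = {sid: rec["annotation"] for sid, rec in section_spots.items()}
    seg1_val = {sid: rec["seg1"] for sid, rec in section_spots.items()}
    return {
        "MALDI1": {"train": ann_train, "val": ann_val},
        "MALDI2": {"train": ann_train, "val": seg1_val},
        "MALDI3": {"train": seg_train, "val": seg1_val},
    }
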