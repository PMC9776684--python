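"""Tumor/non-tumor segmentation of tiled WSIs with a small U-Net.

Images are tiled with overlap, each tile is classified per-pixel by an
encoder–decoder network with skip connections, and tile predictions are
stitched back into a probability heatmap (overlaps averaged).  Training
follows a repeated-training / best-epoch selection protocol with
three-fold cross-validation over TMA groups.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from skimage.measure import block_reduce

from . import nn
from .errors import ConfigError, ValidationError
from .types import BinaryMask, Heatmap, WsiImage

log = logging.getLogger(__name__)


@dataclass
class SegTrainConfig:
    """Training protocol for the segmentation network."""

    tile_size: int = 64
    stride: int = 32
    epochs: int = 8
    repetitions: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 8
    loss: str = "cross_entropy"
    seed: int = 0
    downsample: int = 4
    depth: int = 4
    base_width: int = 32
    tiles_per_epoch: int = 24
    min_tumor_tile_fraction: float = 0.25

    def validate(self) -> "SegTrainConfig":
        if self.stride > self.tile_size:
            raise ConfigError("stride must be <= tile_size")
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        return self


class Tile(NamedTuple):
    image: np.ndarray  # (tile, tile, 3) float, zero-padded at edges
    mask: np.ndarray | None  # (tile, tile) bool or None
    origin: tuple  # (y, x) in the source raster
    padding: tuple  # (pad_y, pad_x) zero-padding applied at the far edges


def tile_image(image: np.ndarray, mask: np.ndarray | None, tile_size: int, stride: int):
    """Cover a raster with overlapping tiles.

    Tile origins advance by ``stride``; when the raster size minus the tile
    is not a stride multiple, one extra tile is anchored at the far edge so
    the whole raster is covered.  Rasters smaller than the tile yield a
    single zero-padded tile with the padding recorded.
    """
    arr = np.asarray(image)
    h, w = arr.shape[:2]

    def _origins(dim):
        if dim <= tile_size:
            return [0]
        out = list(range(0, dim - tile_size + 1, stride))
        if out[-1] != dim - tile_size:
            out.append(dim - tile_size)
        return out

    tiles = []
    for oy in _origins(h):
        for ox in _origins(w):
            sub = arr[oy : oy + tile_size, ox : ox + tile_size]
            pad_y = tile_size - sub.shape[0]
            pad_x = tile_size - sub.shape[1]
            if pad_y or pad_x:
                pad = [(0, pad_y), (0, pad_x)] + [(0, 0)] * (arr.ndim - 2)
                sub = np.pad(sub, pad)
            msub = None
            if mask is not None:
                msub = np.asarray(mask)[oy : oy + tile_size, ox : ox + tile_size]
                if pad_y or pad_x:
                    msub = np.pad(msub, [(0, pad_y), (0, pad_x)])
            tiles.append(Tile(sub, msub, (oy, ox), (pad_y, pad_x)))
    return tiles


def downsample_image(image: WsiImage, factor: int) -> np.ndarray:
    """Block-mean downsample of the RGB raster, returned as float in [0, 1]."""
    if factor == 1:
        return image.pixels.astype(np.float64) / 255.0
    return block_reduce(image.pixels.astype(np.float64), (factor, factor, 1), np.mean) / 255.0


def downsample_mask(values: np.ndarray, factor: int) -> np.ndarray:
    """Majority block downsample of a boolean mask."""
    if factor == 1:
        return values.astype(bool)
    return block_reduce(values.astype(np.float64), (factor, factor), np.mean) >= 0.5


class UNet:
    """Encoder–decoder with skip connections; per-pixel 2-class softmax."""

    def __init__(self, depth=4, base_width=32, in_channels=3, n_classes=2, seed=0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.enc = []
        cin = in_channels
        widths = [base_width * 2**i for i in range(depth)]
        for wdt in widths:
            self.enc.append(self._block(cin, wdt, rng))
            cin = wdt
        self.bottleneck = self._block(cin, base_width * 2**depth, rng)
        self.dec = []
        up_in = base_width * 2**depth
        for wdt in reversed(widths):
            self.dec.append(self._block(up_in + wdt, wdt, rng))
            up_in = wdt
        self.head = nn.Conv2d(widths[0], n_classes, 1, rng)
        self.pool = [nn.MaxPool2d() for _ in range(depth)]
        self.up = [nn.Upsample2d() for _ in range(depth)]

    @staticmethod
    def _block(cin, cout, rng):
        return [nn.Conv2d(cin, cout, 3, rng), nn.ReLU(), nn.Conv2d(cout, cout, 3, rng), nn.ReLU()]

    def _all_layers(self):
        out = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            out.extend(blk)
        out.append(self.head)
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

    @staticmethod
    def _run_block(blk, x, train):
        for layer in blk:
            x = layer.forward(x, train=train)
        return x

    @staticmethod
    def _back_block(blk, d):
        for layer in reversed(blk):
            d = layer.backward(d)
        return d

    def forward(self, x, train=False):
        """x: (B, tile, tile, 3) float -> (B, tile, tile, 2) probabilities."""
        h = np.ascontiguousarray(np.transpose(x, (0, 3, 1, 2)))
        if h.shape[2] % 2**self.depth or h.shape[3] % 2**self.depth:
            raise ConfigError(
                f"tile size {h.shape[2:]} must be divisible by 2^depth = {2 ** self.depth}"
            )
        skips = []
        for i in range(self.depth):
            h = self._run_block(self.enc[i], h, train)
            skips.append(h)
            h = self.pool[i].forward(h, train)
        h = self._run_block(self.bottleneck, h, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for i in range(self.depth):
            h = self.up[i].forward(h, train)
            h = np.concatenate([skips[self.depth - 1 - i], h], axis=1)
            h = self._run_block(self.dec[i], h, train)
        logits = self.head.forward(h, train)
        return np.transpose(logits, (0, 2, 3, 1))

    def backward(self, dlogits):
        d = np.ascontiguousarray(np.transpose(dlogits, (0, 3, 1, 2)))
        d = self.head.backward(d)
        dskips = [None] * self.depth
        for i in reversed(range(self.depth)):
            d = self._back_block(self.dec[i], d)
            cs = self._skip_channels[self.depth - 1 - i]
            dskips[self.depth - 1 - i] = d[:, :cs]
            d = self.up[i].backward(d[:, cs:])
        d = self._back_block(self.bottleneck, d)
        for i in reversed(range(self.depth)):
            d = self.pool[i].backward(d)
            d = d + dskips[i]
            d = self._back_block(self.enc[i], d)
        return np.transpose(d, (0, 2, 3, 1))

    def predict_proba(self, x):
        return nn.softmax(self.forward(x, train=False), axis=3)


class StubSegModel:
    """Constant-probability segmentation model for dry runs and wiring tests."""

    def __init__(self, p_tumor=0.7):
        self.p = float(p_tumor)
        self.n_params = 0

    def predict_proba(self, x):
        b, h, w, _ = x.shape
        out = np.empty((b, h, w, 2))
        out[..., 1] = self.p
        out[..., 0] = 1.0 - self.p
        return out


def build_unet(config: SegTrainConfig) -> UNet:
    """Instantiate the segmentation network for a config (untrained)."""
    cfg = config.validate()
    if cfg.tile_size % 2**cfg.depth:
        raise ConfigError(
            f"tile_size {cfg.tile_size} must be divisible by 2^depth = {2 ** cfg.depth}"
        )
    model = UNet(depth=cfg.depth, base_width=cfg.base_width, seed=cfg.seed)
    log.info("U-Net depth=%d base=%d parameters=%d", cfg.depth, cfg.base_width, model.n_params)
    return model


def predict_heatmap(model, image: WsiImage, tile_size: int = 64, stride: int = 32,
                    downsample: int = 4) -> Heatmap:
    """Stitch tile-wise tumor probabilities into a section heatmap.

    Overlapping pixels are averaged; zero-padded margins are cropped away.
    """
    arr = downsample_image(image, downsample) - 0.5
    h, w = arr.shape[:2]
    acc = np.zeros((h, w))
    wgt = np.zeros((h, w))
    for tile in tile_image(arr, None, tile_size, stride):
        p = model.predict_proba(tile.image[None])[0, :, :, 1]
        oy, ox = tile.origin
        vy = tile_size - tile.padding[0]
        vx = tile_size - tile.padding[1]
        acc[oy : oy + vy, ox : ox + vx] += p[:vy, :vx]
        wgt[oy : oy + vy, ox : ox + vx] += 1.0
    values = acc / np.maximum(wgt, 1.0)
    return Heatmap(values=np.clip(values, 0.0, 1.0),
                   reference_section=image.section_id, downsample=downsample).validate()


def binarize(heatmap: Heatmap, threshold: float = 0.5) -> BinaryMask:
    """Threshold a heatmap; ties at the threshold count as tumor."""
    return BinaryMask(values=heatmap.values >= threshold,
                      reference_section=heatmap.reference_section,
                      downsample=heatmap.downsample)


def compute_iou(pred: BinaryMask, truth: BinaryMask) -> float:
    """Tumor-class intersection over union; 1.0 when both masks are empty."""
    a, b = pred.values, truth.values
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def compute_iou_averaged(pred: BinaryMask, truth: BinaryMask) -> float:
    """Class-averaged IoU (tumor and non-tumor), for comparison."""
    inv_p = BinaryMask(~pred.values, pred.reference_section, pred.downsample)
    inv_t = BinaryMask(~truth.values, truth.reference_section, truth.downsample)
    return 0.5 * (compute_iou(pred, truth) + compute_iou(inv_p, inv_t))


def _tile_pool(sections, cfg: SegTrainConfig):
    pool = []
    for image, mask in sections:
        arr = downsample_image(image, cfg.downsample) - 0.5
        msk = downsample_mask(mask.values, cfg.downsample)
        pool.extend(tile_image(arr, msk, cfg.tile_size, cfg.stride))
    return pool


def train_segmentation(train_sections, val_sections, config: SegTrainConfig):
    """Repeated training with best-epoch selection on validation IoU.

    ``train_sections`` and ``val_sections`` are lists of (WsiImage,
    BinaryMask) pairs at full resolution; tiling and downsampling happen
    here.  Each of ``config.repetitions`` independent trainings records the
    validation IoU after every epoch; the checkpoint with the global
    maximum is returned.  A repetition whose loss turns NaN is aborted;
    training fails only if all repetitions abort.

    Training tiles are sampled so that at least
    ``min_tumor_tile_fraction`` of each epoch's tiles contain tumor pixels
    (the tumor class is heavily outnumbered on tissue rasters).
    """
    cfg = config.validate()
    if not train_sections or not val_sections:
        raise ValidationError("both training and validation splits must be non-empty")
    pool = _tile_pool(train_sections, cfg)
    tumor_tiles = [t for t in pool if t.mask is not None and t.mask.any()]
    other_tiles = [t for t in pool if t.mask is None or not t.mask.any()]

    val_ds = [
        (img, BinaryMask(downsample_mask(msk.values, cfg.downsample), msk.reference_section,
                         cfg.downsample))
        for img, msk in val_sections
    ]

    history = {"repetitions": [], "param_count": None}
    best = {"val_iou": -1.0, "repetition": None, "epoch": None, "state": None}

    n_aborted = 0
    for rep in range(cfg.repetitions):
        rng = np.random.default_rng([cfg.seed, rep])
        model = UNet(depth=cfg.depth, base_width=cfg.base_width,
                     seed=int(rng.integers(2**31 - 1)))
        history["param_count"] = model.n_params
        opt = nn.Adam(model.params(), lr=cfg.learning_rate)
        rep_hist = []
        aborted = False
        for epoch in range(cfg.epochs):
            n_tiles = min(cfg.tiles_per_epoch, max(len(pool), 1))
            n_tum = max(1, int(round(cfg.min_tumor_tile_fraction * n_tiles)))
            chosen = []
            if tumor_tiles:
                chosen += [tumor_tiles[i] for i in rng.integers(0, len(tumor_tiles), n_tum)]
            if other_tiles:
                chosen += [other_tiles[i] for i in
                           rng.integers(0, len(other_tiles), n_tiles - len(chosen))]
            rng.shuffle(chosen)
            for i in range(0, len(chosen), cfg.batch_size):
                batch = chosen[i : i + cfg.batch_size]
                x = np.stack([t.image for t in batch])
                y = np.stack([t.mask for t in batch]).astype(np.int64)
                # inverse-frequency class weights: tumor pixels are rare and
                # an unweighted loss collapses to all-background
                frac = max(y.mean(), 1e-3)
                w = np.where(y == 1, 0.5 / frac, 0.5 / max(1 - frac, 1e-3))
                logits = model.forward(x, train=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, y, axis=3, weights=w)
                if not np.isfinite(loss):
                    aborted = True
                    break
                opt.zero_grad()
                model.backward(dlogits)
                opt.step()
            if aborted:
                log.warning("segmentation repetition %d aborted on NaN loss", rep)
                break
            iou = float(np.mean([
                compute_iou(
                    binarize(predict_heatmap(model, img, cfg.tile_size, cfg.stride,
                                             cfg.downsample)),
                    msk,
                )
                for img, msk in val_ds
            ]))
            rep_hist.append(iou)
            if iou > best["val_iou"]:
                best.update(val_iou=iou, repetition=rep, epoch=epoch, state=model.get_state())
        history["repetitions"].append(rep_hist)
        if aborted:
            n_aborted += 1
    if n_aborted == cfg.repetitions:
        raise ValidationError("all segmentation repetitions aborted with NaN loss")

    model = UNet(depth=cfg.depth, base_width=cfg.base_width, seed=cfg.seed)
    model.set_state(best["state"])
    history["best"] = {k: best[k] for k in ("val_iou", "repetition", "epoch")}
    return model, history


def crossvalidate_segmentation(tma_groups: dict, config: SegTrainConfig):
    """Three-fold cross-validation over TMA groups.

    ``tma_groups`` maps group id -> list of (WsiImage, BinaryMask).  Model
    ``Seg{i}`` is trained on the other two groups and validated on group i.

    Returns (models, group_map, histories) with ``group_map`` mapping model
    name -> the group it was validated on.
    """
    groups = sorted(tma_groups)
    if len(groups) != 3:
        raise ValidationError(f"expected exactly 3 groups, got {len(groups)}")
    seen = []
    for g in groups:
        ids = {id(s[0]) for s in tma_groups[g]}
        for prev in seen:
            if ids & prev:
                raise ValidationError("groups must be disjoint")
        seen.append(ids)
    models, group_map, histories = {}, {}, {}
    for i, g in enumerate(groups, start=1):
        name = f"Seg{i}"
        train = [s for gg in groups if gg != g for s in tma_groups[gg]]
        cfg = replace(config, seed=config.seed + i)
        model, hist = train_segmentation(train, tma_groups[g], cfg)
        models[name] = model
        group_map[name] = g
        histories[name] = hist
    return models, group_map, histories
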