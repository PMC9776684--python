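"""Landmark-based affine co-registration of MSI spot grids onto WSI pixels.

The MALDI raster and the slide scan live in different coordinate systems;
a handful of manually placed anchor pairs determines a planar affine map
``(x, y) -> (x', y')`` fitted by least squares.  Mask membership is then
transferred to spots by sampling the mask at each transformed spot center.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .errors import MisregistrationError, SingularConfigurationError
from .types import AnchorPairs, BinaryMask, MsiDataset

log = logging.getLogger(__name__)


@dataclass
class AffineTransform2D:
    """Invertible planar affine map given by a 2x3 matrix.

    ``apply`` computes ``A @ (x, y).T + t`` where ``A`` is the 2x2 linear
    part and ``t`` the translation column.
    """

    matrix: np.ndarray  # (2, 3)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 3)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def validate(self) -> "AffineTransform2D":
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise SingularConfigurationError("affine linear part is singular")
        return self

    def apply(self, coords) -> np.ndarray:
        """Map (n, 2) or (2,) coordinates; returns float array of same shape."""
        pts = np.atleast_2d(np.asarray(coords, dtype=np.float64))
        out = pts @ self.linear.T + self.translation
        return out[0] if np.asarray(coords).ndim == 1 else out

    def invert(self) -> "AffineTransform2D":
        self.validate()
        inv = np.linalg.inv(self.linear)
        t = -inv @ self.translation
        return AffineTransform2D(np.column_stack([inv, t]))

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return self ∘ other (apply ``other`` first)."""
        lin = self.linear @ other.linear
        t = self.linear @ other.translation + self.translation
        return AffineTransform2D(np.column_stack([lin, t]))

    # serialization: 6 numbers, row-major
    def to_json(self) -> str:
        return json.dumps([float(v) for v in self.matrix.ravel()])

    @classmethod
    def from_json(cls, text: str) -> "AffineTransform2D":
        vals = json.loads(text)
        if len(vals) != 6:
            raise ValueError("affine JSON must contain exactly 6 numbers")
        return cls(np.asarray(vals, dtype=np.float64).reshape(2, 3))

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_params(cls, scale=1.0, rotation_deg=0.0, offset=(0.0, 0.0)) -> "AffineTransform2D":
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lin = scale * rot
        return cls(np.column_stack([lin, np.asarray(offset, dtype=np.float64)]))


def _check_not_collinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    # rank < 2 means all source points lie on one line (or coincide)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    if s[-1] / scale < 1e-9:
        raise SingularConfigurationError("MSI anchor points are collinear")


def fit_affine(anchors: AnchorPairs) -> AffineTransform2D:
    """Least-squares affine fit from anchor pairs.

    With exactly 3 non-collinear pairs the result interpolates the anchors
    exactly; with more pairs it minimizes the summed squared residual.
    """
    anchors.validate()
    _check_not_collinear(anchors.msi)
    n = len(anchors)
    design = np.column_stack([anchors.msi, np.ones(n)])
    sol, *_ = np.linalg.lstsq(design, anchors.wsi, rcond=None)  # (3, 2)
    return AffineTransform2D(sol.T).validate()


def anchor_rmse(anchors: AnchorPairs, transform: AffineTransform2D) -> float:
    """Root-mean-square anchor residual in pixels."""
    res = transform.apply(anchors.msi) - anchors.wsi
    return float(np.sqrt(np.mean(np.sum(res**2, axis=1))))


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (symmetric)."""
    x = np.asarray(x, dtype=np.float64)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def transfer_mask_to_spots(
    mask: BinaryMask,
    transform: AffineTransform2D,
    ds: MsiDataset,
    footprint_majority: bool = False,
    rmse_warn_px: float = 2.0,
    anchors: AnchorPairs | None = None,
):
    """Boolean mask membership per spot, by center-pixel sampling.

    A spot is a member iff the mask is true at its transformed, rounded
    center (divided by the mask's downsample).  Spots landing outside the
    raster are non-members; their count is returned so gross misregistration
    is visible.  ``footprint_majority=True`` instead samples the full spot
    footprint (pitch-sized square) and takes the majority, for sensitivity
    checks.

    Returns
    -------
    membership : (n_spots,) bool
    n_out_of_bounds : int
    """
    if anchors is not None:
        rmse = anchor_rmse(anchors, transform)
        if rmse > rmse_warn_px:
            log.warning("anchor RMSE %.2f px exceeds %.2f px", rmse, rmse_warn_px)

    h, w = mask.values.shape
    px = transform.apply(ds.coords.astype(np.float64))

    if not footprint_majority:
        pix = round_half_away(px)
        col = pix[:, 0] // mask.downsample
        row = pix[:, 1] // mask.downsample
        inb = (col >= 0) & (col < w) & (row >= 0) & (row < h)
        member = np.zeros(ds.n_spots, dtype=bool)
        member[inb] = mask.values[row[inb], col[inb]]
    else:
        # sample a pitch-sized square footprint on a 3x3 subgrid
        half = _footprint_half_px(transform, ds)
        offs = np.linspace(-half, half, 3)
        votes = np.zeros(ds.n_spots, dtype=np.int64)
        valid = np.zeros(ds.n_spots, dtype=np.int64)
        for dx in offs:
            for dy in offs:
                pix = round_half_away(px + np.array([dx, dy]))
                col = pix[:, 0] // mask.downsample
                row = pix[:, 1] // mask.downsample
                inb = (col >= 0) & (col < w) & (row >= 0) & (row < h)
                valid += inb
                votes[inb] += mask.values[row[inb], col[inb]]
        member = votes * 2 > valid
        pix = round_half_away(px)
        col = pix[:, 0] // mask.downsample
        row = pix[:, 1] // mask.downsample
        inb = (col >= 0) & (col < w) & (row >= 0) & (row < h)

    n_oob = int(ds.n_spots - inb.sum())
    if ds.n_spots > 0 and n_oob == ds.n_spots:
        raise MisregistrationError(
            f"all {ds.n_spots} spots map outside the {h}x{w} mask raster"
        )
    return member, n_oob


def _footprint_half_px(transform: AffineTransform2D, ds: MsiDataset) -> float:
    # half the spot pitch expressed in WSI pixels through the fitted scale
    scale = float(np.sqrt(abs(np.linalg.det(transform.linear))))
    return 0.5 * scale
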