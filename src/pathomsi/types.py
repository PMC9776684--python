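"""Core in-memory containers shared by all pipeline stages.

Coordinate convention used throughout the package: 0-based integer grids,
x increasing rightward and y increasing downward.  imzML files store 1-based
coordinates; the shift happens in :mod:`pathomsi.io` on read/write.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Canonical class names for the two non-small cell lung cancer subtypes.
ADC = "ADC"
SQCC = "SqCC"
CLASS_NAMES = (ADC, SQCC)

#: Integer codes for the ground-truth label field of synthetic scenes.
BG, NORMAL, TUMOR, CONFOUNDER, NECROSIS = 0, 1, 2, 3, 4
SCENE_LABELS = {
    "background": BG,
    "normal": NORMAL,
    "tumor": TUMOR,
    "confounder": CONFOUNDER,
    "necrosis": NECROSIS,
}


@dataclass
class MsiDataset:
    """A MALDI mass spectrometry imaging dataset with a shared m/z axis.

    Parameters
    ----------
    mz_axis : (C,) float array, strictly increasing m/z values in Da.
    intensities : (N, C) float array, one intensity vector per spot.
    coords : (N, 2) int array of 0-based (x, y) grid positions, unique rows.
    spot_pitch_um : center-to-center spot distance in microns.
    section_id : free-text label of the tissue section.
    """

    mz_axis: np.ndarray
    intensities: np.ndarray
    coords: np.ndarray
    spot_pitch_um: float = 100.0
    section_id: str = ""

    def __post_init__(self):
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        self.intensities = np.asarray(self.intensities)
        self.coords = np.asarray(self.coords, dtype=np.int64)

    @property
    def n_spots(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.mz_axis.shape[0]

    def validate(self, require_nonnegative: bool = True) -> "MsiDataset":
        if self.mz_axis.ndim != 1:
            raise ValidationError("mz_axis must be 1-D")
        if np.any(np.diff(self.mz_axis) <= 0):
            raise ValidationError("mz_axis must be strictly increasing")
        if self.intensities.ndim != 2 or self.intensities.shape[1] != self.n_channels:
            raise ValidationError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{self.n_channels} m/z channels"
            )
        if self.coords.shape != (self.intensities.shape[0], 2):
            raise ValidationError("coords must be (n_spots, 2)")
        if len({tuple(c) for c in self.coords.tolist()}) != self.n_spots:
            raise ValidationError("spot coordinates must be unique")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")
        if require_nonnegative and np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")
        return self

    def replace(self, **kw) -> "MsiDataset":
        """Copy with some fields replaced (arrays are not copied)."""
        args = dict(
            mz_axis=self.mz_axis,
            intensities=self.intensities,
            coords=self.coords,
            spot_pitch_um=self.spot_pitch_um,
            section_id=self.section_id,
        )
        args.update(kw)
        return MsiDataset(**args)


@dataclass
class WsiImage:
    """An RGB raster of an H&E-stained slide scan."""

    pixels: np.ndarray  # (H, W, 3) uint8
    microns_per_pixel: float = 0.25
    section_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)

    def validate(self) -> "WsiImage":
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError("WSI pixels must be (H, W, 3)")
        if self.microns_per_pixel <= 0:
            raise ValidationError("microns_per_pixel must be > 0")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValidationError("pixel values must lie in [0, 255]")
        return self

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """A boolean tumor mask aligned to a WSI at an integer downsample."""

    values: np.ndarray  # (h, w) bool
    reference_section: str = ""
    downsample: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)

    def validate(self, image_shape=None) -> "BinaryMask":
        if self.values.ndim != 2:
            raise ValidationError("mask must be 2-D")
        if self.downsample < 1 or int(self.downsample) != self.downsample:
            raise ValidationError("downsample must be an integer >= 1")
        if image_shape is not None:
            expect = tuple(-(-s // self.downsample) for s in image_shape)
            if self.values.shape != expect:
                raise ValidationError(
                    f"mask shape {self.values.shape} != ceil(image/downsample) {expect}"
                )
        return self


@dataclass
class Heatmap:
    """Per-pixel tumor probability raster in [0, 1]."""

    values: np.ndarray  # (h, w) float
    reference_section: str = ""
    downsample: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)

    def validate(self) -> "Heatmap":
        if self.values.ndim != 2:
            raise ValidationError("heatmap must be 2-D")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValidationError("heatmap values must lie in [0, 1]")
        return self


@dataclass
class AnchorPairs:
    """Manually placed landmark pairs linking MSI spots to WSI pixels."""

    msi: np.ndarray  # (n, 2) float, MSI grid coordinates
    wsi: np.ndarray  # (n, 2) float, WSI pixel coordinates

    def __post_init__(self):
        self.msi = np.asarray(self.msi, dtype=np.float64)
        self.wsi = np.asarray(self.wsi, dtype=np.float64)

    def __len__(self) -> int:
        return self.msi.shape[0]

    def validate(self) -> "AnchorPairs":
        from .errors import TooFewAnchorsError

        if self.msi.shape != self.wsi.shape or self.msi.ndim != 2 or self.msi.shape[1] != 2:
            raise ValidationError("anchor arrays must both be (n, 2)")
        if len(self) < 3:
            raise TooFewAnchorsError(f"need >= 3 anchor pairs, got {len(self)}")
        return self


@dataclass
class SpectrumPrediction:
    """Per-spot subtype call with class probabilities."""

    section_id: str
    x: int
    y: int
    p_adc: float
    p_sqcc: float
    label: str

    def validate(self) -> "SpectrumPrediction":
        if not (self.p_adc >= 0 and self.p_sqcc >= 0):
            raise ValidationError("probabilities must be >= 0")
        if abs(self.p_adc + self.p_sqcc - 1.0) > 1e-6:
            raise ValidationError("probabilities must sum to 1")
        expect = ADC if self.p_adc >= self.p_sqcc else SQCC
        if self.label != expect:
            raise ValidationError("hard label must be the argmax class")
        return self


@dataclass
class SectionVerdict:
    """Section-level majority-vote verdict with quality control."""

    section_id: str
    n_spectra: int
    counts: dict
    p_majority: float
    label: str  # ADC | SqCC | inconclusive
    qc_threshold: float = 0.9
    qc_pass: bool = False


@dataclass
class TissueScene:
    """Synthetic ground truth for one paired WSI/MSI sample."""

    label_field: np.ndarray  # (H, W) uint8 with SCENE_LABELS codes
    diagnosis: str  # ADC | SqCC
    region_geometry: list = field(default_factory=list)
    true_transform: object = None  # AffineTransform2D
    seed: int = 0
    section_id: str = ""
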