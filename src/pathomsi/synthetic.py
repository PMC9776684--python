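"""Synthetic paired-modality cohort with known ground truth.

Real paired H&E / MALDI MSI cohorts with spot-level truth are not openly
deposited, so this module fabricates them: a labeled tissue scene is
rendered twice, once as an H&E-like RGB raster (nucleus-dot texture,
darker/denser in tumor) and once as a grid of mass spectra (peptide-like
isotope envelopes, subtype marker peaks only under tumor).  The two
renderings are linked by a known affine transform, so every downstream
stage — segmentation, registration, preprocessing, classification,
aggregation — can be scored against exact truth.

Confounder structures (bronchus-like rings) and necrosis patches with
attenuated marker signal emulate the hard negatives that drive
misclassification on real lung sections.  Whole-section samples carry
deliberately incomplete annotation masks covering only a fraction of the
true tumor area, mirroring exemplary-only pathologist annotations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import poisson

from . import io as pio
from .errors import ConfigError, ValidationError
from .register import AffineTransform2D, round_half_away
from .types import (
    ADC, SQCC, BG, NORMAL, TUMOR, CONFOUNDER, NECROSIS,
    AnchorPairs, BinaryMask, MsiDataset, TissueScene, WsiImage,
)

ISOTOPE_SPACING = 1.00335  # Da, 13C-12C mass difference


@dataclass
class PeakModel:
    """Spectral content of the synthetic tissue classes.

    Shared peaks appear wherever there is tissue; the subtype marker peaks
    appear only under tumor of the matching subtype (attenuated under
    necrosis).  Each peak is an isotope envelope: Gaussians spaced by the
    13C-12C mass difference with Poisson(mass/1800) relative intensities.
    """

    shared_peaks: list = field(default_factory=lambda: [
        (842.51, 0.9), (944.53, 0.7), (1105.58, 0.8), (1305.72, 0.6),
        (1478.79, 0.7), (1707.80, 0.5), (2115.07, 0.45), (2465.20, 0.4),
    ])
    adc_peaks: list = field(default_factory=lambda: [
        (911.46, 1.0), (1198.70, 0.9), (1570.68, 0.8), (2211.10, 0.7),
    ])
    sqcc_peaks: list = field(default_factory=lambda: [
        (976.45, 1.0), (1325.75, 0.9), (1790.89, 0.8), (2383.95, 0.7),
    ])
    isotope_spacing: float = ISOTOPE_SPACING
    peak_sigma: float = 0.10          # Da
    baseline_amplitude: float = 0.8   # intensity units at the low-mass end
    baseline_decay: float = 600.0     # Da
    noise_sd: float = 0.1
    mass_shift_range: float = 0.2     # Da, per-spot rigid shift ~ U(+/- range)
    intensity_cv: float = 0.15
    necrosis_attenuation: float = 0.2

    def validate(self, mz_range) -> "PeakModel":
        lo, hi = mz_range
        for name in ("shared_peaks", "adc_peaks", "sqcc_peaks"):
            for mass, _ in getattr(self, name):
                if not (lo <= mass <= hi):
                    raise ConfigError(
                        f"{name} mass {mass} Da outside generated range [{lo}, {hi}]"
                    )
        if self.noise_sd < 0 or self.mass_shift_range < 0:
            raise ConfigError("noise_sd and mass_shift_range must be >= 0")
        return self


def _ellipse_mask(shape, center, radii, angle_rad):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - center[0]
    dy = yy - center[1]
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    u = (c * dx + s * dy) / radii[0]
    v = (-s * dx + c * dy) / radii[1]
    return u**2 + v**2 <= 1.0


def generate_scene(
    shape=(256, 256),
    n_tumor_regions: int = 3,
    confounder_rate: float = 0.5,
    diagnosis: str = ADC,
    seed: int = 0,
    necrosis_prob: float = 0.5,
    section_id: str = "",
    true_transform: AffineTransform2D | None = None,
) -> TissueScene:
    """Lay out a labeled tissue scene: tissue disk, tumor blobs, confounders.

    Deterministic for fixed arguments.  Tumor regions are disjoint ellipses
    (connected components); confounders are bronchus-like rings; necrosis
    patches sit at tumor boundaries, claiming only non-tumor pixels, and are
    labeled non-tumor in the ground truth.
    """
    if diagnosis not in (ADC, SQCC):
        raise ValidationError(f"diagnosis must be ADC or SqCC, got {diagnosis!r}")
    h, w = shape
    if h < 64 or w < 64:
        raise ConfigError("scene must be at least 64x64 pixels")
    rng = np.random.default_rng(seed)
    field_ = np.zeros(shape, dtype=np.uint8)
    geometry = []

    # tissue body
    tc = (w / 2 + rng.uniform(-w * 0.03, w * 0.03), h / 2 + rng.uniform(-h * 0.03, h * 0.03))
    tr = (w * rng.uniform(0.40, 0.46), h * rng.uniform(0.40, 0.46))
    tissue = _ellipse_mask(shape, tc, tr, rng.uniform(0, np.pi))
    field_[tissue] = NORMAL
    geometry.append(dict(label="normal", center=tc, radii=tr, angle=0.0))

    # tumor regions: disjoint ellipses inside the tissue
    rmin, rmax = 0.07 * min(shape), 0.13 * min(shape)
    placed = []
    for i in range(n_tumor_regions):
        ok = False
        for _attempt in range(500):
            r = (rng.uniform(rmin, rmax), rng.uniform(rmin, rmax))
            c = (
                tc[0] + rng.uniform(-0.6, 0.6) * tr[0],
                tc[1] + rng.uniform(-0.6, 0.6) * tr[1],
            )
            ang = rng.uniform(0, np.pi)
            if all(
                np.hypot(c[0] - pc[0], c[1] - pc[1]) > max(r) + max(pr) + 4
                for pc, pr in placed
            ):
                ok = True
                break
        if not ok:
            raise ConfigError(
                f"could not place {n_tumor_regions} disjoint tumor regions in {shape}"
            )
        m = _ellipse_mask(shape, c, r, ang) & tissue
        field_[m] = TUMOR
        placed.append((c, r))
        geometry.append(dict(label="tumor", subtype=diagnosis, center=c, radii=r, angle=ang))

        if rng.uniform() < necrosis_prob:
            # necrosis bite at the tumor boundary; claims only non-tumor pixels
            th = rng.uniform(0, 2 * np.pi)
            nc = (c[0] + max(r) * 1.05 * np.cos(th), c[1] + max(r) * 1.05 * np.sin(th))
            nr = (max(r) * 0.45, max(r) * 0.45)
            nm = _ellipse_mask(shape, nc, nr, 0.0) & tissue & (field_ != TUMOR)
            field_[nm] = NECROSIS
            geometry.append(dict(label="necrosis", center=nc, radii=nr, angle=0.0))

    # bronchus-like rings as confounders
    n_conf = int(rng.poisson(confounder_rate * max(1, n_tumor_regions)))
    for _ in range(n_conf):
        r_out = rng.uniform(0.04, 0.07) * min(shape)
        c = (
            tc[0] + rng.uniform(-0.7, 0.7) * tr[0],
            tc[1] + rng.uniform(-0.7, 0.7) * tr[1],
        )
        outer = _ellipse_mask(shape, c, (r_out, r_out), 0.0)
        inner = _ellipse_mask(shape, c, (r_out * 0.55, r_out * 0.55), 0.0)
        ring = outer & ~inner & tissue & (field_ == NORMAL)
        field_[ring] = CONFOUNDER
        geometry.append(dict(label="confounder", center=c, radii=(r_out, r_out), angle=0.0))

    transform = true_transform or AffineTransform2D.from_params(
        scale=12.0, rotation_deg=2.0, offset=(8.0, 6.0)
    )
    return TissueScene(
        label_field=field_,
        diagnosis=diagnosis,
        region_geometry=geometry,
        true_transform=transform,
        seed=seed,
        section_id=section_id,
    )


# H&E-like style: base color and nucleus-dot density per scene label
DEFAULT_STYLE = {
    BG: dict(color=(246, 244, 246), dots=0.0),
    NORMAL: dict(color=(231, 170, 196), dots=0.02),
    TUMOR: dict(color=(148, 96, 168), dots=0.12),
    CONFOUNDER: dict(color=(196, 128, 178), dots=0.06),
    NECROSIS: dict(color=(214, 182, 160), dots=0.01),
}


def render_he(scene: TissueScene, style_params=None, seed: int = 0):
    """Render the scene as an H&E-like RGB raster plus the exact tumor mask.

    Tumor renders darker and with denser nucleus dots than normal tissue;
    confounders sit in between (hard negatives for the segmenter).
    """
    style = dict(DEFAULT_STYLE)
    if style_params:
        style.update(style_params)
    rng = np.random.default_rng(seed)
    h, w = scene.label_field.shape
    img = np.zeros((h, w, 3), dtype=np.float64)
    for code, st in style.items():
        img[scene.label_field == code] = st["color"]

    # hematoxylin nucleus dots, 2x2 px
    dot_color = np.array([72.0, 40.0, 112.0])
    for code, st in style.items():
        if st["dots"] <= 0:
            continue
        ys, xs = np.nonzero(scene.label_field == code)
        if ys.size == 0:
            continue
        n_dots = rng.binomial(ys.size, st["dots"])
        pick = rng.choice(ys.size, size=n_dots, replace=False)
        for py, px in zip(ys[pick], xs[pick]):
            img[py : py + 2, px : px + 2] = dot_color

    img += rng.normal(0, 5.0, size=img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    image = WsiImage(pixels=pixels, section_id=scene.section_id)
    mask = BinaryMask(
        values=scene.label_field == TUMOR,
        reference_section=scene.section_id,
        downsample=1,
    )
    return image, mask


def _envelope(mass, amp, spacing):
    """Isotope envelope (mass_k, amp_k) with Poisson(mass/1800) intensities."""
    lam = mass / 1800.0
    ks = np.arange(5)
    rel = poisson.pmf(ks, lam)
    rel = rel / rel.max()
    return [(mass + k * spacing, amp * r) for k, r in zip(ks, rel)]


def render_msi(
    scene: TissueScene,
    peak_model: PeakModel | None = None,
    mz_range=(690.0, 2710.0),
    sampling_step: float = 0.1,
    seed: int = 0,
):
    """Render the scene as a continuous-mode MSI dataset on an integer grid.

    Every grid spot whose transformed center lands inside the scene raster
    gets a spectrum: exponential-decay baseline + shared tissue peaks +
    subtype marker peaks (tumor only; attenuated under necrosis) with a
    per-spot rigid mass shift, a multiplicative intensity factor, and
    truncated additive Gaussian noise.

    Returns
    -------
    (MsiDataset, truth) where ``truth`` is a DataFrame with per-spot columns
    x, y, scene_label, subtype, mass_shift.
    """
    pm = (peak_model or PeakModel()).validate(mz_range)
    lo, hi = mz_range
    if not (lo <= 700.0 and hi >= 2700.0):
        raise ConfigError("mz_range must cover [700, 2700] Da")
    rng = np.random.default_rng(seed)
    h, w = scene.label_field.shape
    T = scene.true_transform
    Tinv = T.invert()

    # bounding box of the spot grid that covers the raster
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
    gc = Tinv.apply(corners)
    # grid coordinates stay non-negative so imzML round-trips losslessly and
    # the stored true_transform applies to the written coordinates as-is
    gx0, gy0 = np.maximum(np.floor(gc.min(axis=0)).astype(int), 0)
    gx1, gy1 = np.ceil(gc.max(axis=0)).astype(int)
    gxx, gyy = np.meshgrid(np.arange(gx0, gx1 + 1), np.arange(gy0, gy1 + 1))
    grid = np.column_stack([gxx.ravel(), gyy.ravel()])
    centers = T.apply(grid.astype(float))
    pix = round_half_away(centers)
    inb = (pix[:, 0] >= 0) & (pix[:, 0] < w) & (pix[:, 1] >= 0) & (pix[:, 1] < h)
    grid = grid[inb]
    pix = pix[inb]
    if grid.shape[0] < 64:
        raise ConfigError("transform maps fewer than an 8x8 grid of spots onto the scene")

    labels = scene.label_field[pix[:, 1], pix[:, 0]]
    mz = np.arange(lo, hi + sampling_step / 2, sampling_step)
    base = pm.baseline_amplitude * np.exp(-(mz - lo) / pm.baseline_decay)

    shared = [p for m, a in pm.shared_peaks for p in _envelope(m, a, pm.isotope_spacing)]
    markers = {
        ADC: [p for m, a in pm.adc_peaks for p in _envelope(m, a, pm.isotope_spacing)],
        SQCC: [p for m, a in pm.sqcc_peaks for p in _envelope(m, a, pm.isotope_spacing)],
    }
    marker = markers[scene.diagnosis]

    n = grid.shape[0]
    shifts = rng.uniform(-pm.mass_shift_range, pm.mass_shift_range, size=n)
    scales = rng.lognormal(-pm.intensity_cv**2 / 2, pm.intensity_cv, size=n)
    inten = np.empty((n, mz.size), dtype=np.float32)
    sig = pm.peak_sigma
    halfwin = 5 * sig

    for i in range(n):
        spec = base.copy()
        lab = labels[i]
        peaks = []
        if lab in (NORMAL, TUMOR, CONFOUNDER, NECROSIS):
            peaks += [(m, a) for m, a in shared]
        if lab == TUMOR:
            peaks += [(m, a) for m, a in marker]
        elif lab == NECROSIS:
            peaks += [(m, a * pm.necrosis_attenuation) for m, a in marker]
        d = shifts[i]
        s = scales[i]
        for m, a in peaks:
            mc = m + d
            i0, i1 = np.searchsorted(mz, [mc - halfwin, mc + halfwin])
            seg = mz[i0:i1]
            spec[i0:i1] += s * a * np.exp(-((seg - mc) ** 2) / (2 * sig**2))
        spec += rng.normal(0, pm.noise_sd, size=mz.size)
        inten[i] = np.clip(spec, 0.0, None)

    ds = MsiDataset(
        mz_axis=mz,
        intensities=inten,
        coords=grid,
        spot_pitch_um=100.0,
        section_id=scene.section_id,
    ).validate()
    label_names = {BG: "background", NORMAL: "normal", TUMOR: "tumor",
                   CONFOUNDER: "confounder", NECROSIS: "necrosis"}
    truth = pd.DataFrame({
        "x": grid[:, 0],
        "y": grid[:, 1],
        "scene_label": [label_names[int(v)] for v in labels],
        "subtype": [scene.diagnosis if v == TUMOR else "" for v in labels],
        "mass_shift": shifts,
    })
    return ds, truth


def sample_anchors(
    true_transform: AffineTransform2D, n: int = 8, jitter_px: float = 0.0, seed: int = 0
) -> AnchorPairs:
    """Draw non-collinear MSI anchor points and their (jittered) WSI images."""
    if n < 3:
        raise ValidationError(f"need at least 3 anchors, got {n}")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        msi = rng.uniform(0, 20, size=(n, 2))
        s = np.linalg.svd(msi - msi.mean(axis=0), compute_uv=False)
        if s[-1] / max(s[0], 1.0) > 1e-3:
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise ValidationError("failed to draw non-collinear anchor points")
    wsi = true_transform.apply(msi) + rng.normal(0, jitter_px, size=(n, 2))
    return AnchorPairs(msi=msi, wsi=wsi).validate()


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Composition of the synthetic cohort.

    The paper-scale layout is 6 TMA-like samples (both subtypes),
    14 validation and 16 test whole sections; the desk-scale default used
    throughout the tests is 6 TMAs, 6 validation and 8 test sections.
    """

    n_tma_adc: int = 3
    n_tma_sqcc: int = 3
    n_val_adc: int = 3
    n_val_sqcc: int = 3
    n_test_adc: int = 4
    n_test_sqcc: int = 4
    scene_shape: tuple = (256, 256)
    n_tumor_regions: int = 3
    confounder_rate: float = 0.5
    necrosis_prob: float = 0.5
    annotation_fraction: float = 0.3
    sampling_step: float = 0.1
    mz_range: tuple = (690.0, 2710.0)
    anchor_jitter_px: float = 0.3
    n_anchors: int = 8

    @classmethod
    def paper_scale(cls) -> "CohortConfig":
        return cls(n_val_adc=7, n_val_sqcc=7, n_test_adc=8, n_test_sqcc=8)

    def validate(self) -> "CohortConfig":
        counts = [self.n_tma_adc + self.n_tma_sqcc,
                  self.n_val_adc + self.n_val_sqcc,
                  self.n_test_adc + self.n_test_sqcc]
        if any(c == 0 for c in counts):
            raise ConfigError("every split (tma/val/test) needs at least one sample")
        if (self.n_tma_adc + self.n_tma_sqcc) % 3 == 0:
            pass  # 3 cross-validation groups of equal size
        return self


def _annotation_mask(scene: TissueScene, fraction: float, rng) -> np.ndarray:
    """Incomplete annotation: shrunken, jittered ellipse per tumor region."""
    out = np.zeros_like(scene.label_field, dtype=bool)
    tumor = scene.label_field == TUMOR
    shrink = np.sqrt(fraction)
    for geo in scene.region_geometry:
        if geo["label"] != "tumor":
            continue
        c = geo["center"]
        r = geo["radii"]
        jitter = (rng.uniform(-0.2, 0.2) * r[0], rng.uniform(-0.2, 0.2) * r[1])
        m = _ellipse_mask(
            scene.label_field.shape,
            (c[0] + jitter[0], c[1] + jitter[1]),
            (r[0] * shrink, r[1] * shrink),
            geo["angle"],
        )
        out |= m
    return out & tumor


MANIFEST_COLUMNS = [
    "sample_id", "split", "kind", "diagnosis", "tma_group",
    "image_path", "imzml_path", "gt_mask_path", "ann_mask_path",
    "anchors_path", "spots_path", "transform_path",
]


def generate_cohort(config: CohortConfig, seed: int, outdir) -> pd.DataFrame:
    """Write a full synthetic cohort to ``outdir`` and return its manifest.

    Per sample: H&E-like PNG, continuous imzML, full ground-truth tumor mask,
    annotation mask (complete for TMAs, ~``annotation_fraction`` of tumor
    area for whole sections), anchor CSV, per-spot truth CSV, and the true
    transform JSON.  TMAs are partitioned into 3 cross-validation groups.
    """
    cfg = config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(seed)

    plan = []
    for i in range(cfg.n_tma_adc):
        plan.append((f"tma{i + 1:02d}", "train", "tma", ADC))
    for i in range(cfg.n_tma_sqcc):
        plan.append((f"tma{cfg.n_tma_adc + i + 1:02d}", "train", "tma", SQCC))
    for i in range(cfg.n_val_adc):
        plan.append((f"val{i + 1:02d}", "val", "section", ADC))
    for i in range(cfg.n_val_sqcc):
        plan.append((f"val{cfg.n_val_adc + i + 1:02d}", "val", "section", SQCC))
    for i in range(cfg.n_test_adc):
        plan.append((f"test{i + 1:02d}", "test", "section", ADC))
    for i in range(cfg.n_test_sqcc):
        plan.append((f"test{cfg.n_test_adc + i + 1:02d}", "test", "section", SQCC))

    # random partition of TMAs into 3 groups (groups of two at paper scale)
    n_tma = cfg.n_tma_adc + cfg.n_tma_sqcc
    order = root_rng.permutation(n_tma)
    groups = {}
    for pos, idx in enumerate(order):
        groups[plan[idx][0]] = pos % 3 + 1

    rows = []
    for k, (sid, split, kind, diagnosis) in enumerate(plan):
        srng = np.random.default_rng([seed, k])
        s_seed = int(srng.integers(0, 2**31 - 1))
        scene = generate_scene(
            shape=cfg.scene_shape,
            n_tumor_regions=cfg.n_tumor_regions,
            confounder_rate=cfg.confounder_rate if kind == "section" else 0.25,
            diagnosis=diagnosis,
            seed=s_seed,
            necrosis_prob=cfg.necrosis_prob if kind == "section" else 0.0,
            section_id=sid,
        )
        image, gt_mask = render_he(scene, seed=s_seed + 1)
        ds, truth = render_msi(
            scene, mz_range=cfg.mz_range, sampling_step=cfg.sampling_step,
            seed=s_seed + 2,
        )
        anchors = sample_anchors(
            scene.true_transform, n=cfg.n_anchors, jitter_px=cfg.anchor_jitter_px,
            seed=s_seed + 3,
        )
        if kind == "tma":
            ann = gt_mask.values.copy()
        else:
            ann = _annotation_mask(scene, cfg.annotation_fraction, np.random.default_rng(s_seed + 4))

        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)
        paths = dict(
            image_path=pio.write_image(image, sdir / "image.png"),
            imzml_path=pio.write_imzml(ds, sdir / "spectra.imzML"),
            gt_mask_path=pio.write_mask(gt_mask, sdir / "gt_mask.png"),
            ann_mask_path=pio.write_mask(
                BinaryMask(ann, reference_section=sid, downsample=1), sdir / "ann_mask.png"
            ),
            anchors_path=pio.write_anchors(anchors, sdir / "anchors.csv"),
        )
        truth.to_csv(sdir / "spots.csv", index=False)
        (sdir / "true_transform.json").write_text(scene.true_transform.to_json())
        rows.append(dict(
            sample_id=sid, split=split, kind=kind, diagnosis=diagnosis,
            tma_group=groups.get(sid, 0),
            spots_path=sdir / "spots.csv",
            transform_path=sdir / "true_transform.json",
            **paths,
        ))

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest = manifest.assign(
        **{c: manifest[c].map(lambda p: str(Path(p).relative_to(outdir)) if isinstance(p, Path) else p)
           for c in MANIFEST_COLUMNS if c.endswith("_path")}
    )
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
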