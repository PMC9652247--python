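"""Synthetic paired B-mode / shear-wave-elastography lesion phantoms.

The clinical data this package targets — compound ultrasound screenshots
containing a grayscale B-mode panel and an equal-sized SWE panel in which
a color stiffness map is superimposed inside a radiologist-chosen
rectangle — is private, so this module generates statistically analogous
phantoms with full ground truth:

* a speckled B-mode image with a hypoechoic lesion whose boundary is an
  ellipse with class-dependent radial irregularity (malignant lesions are
  more irregular) and a class-dependent posterior acoustic shadow
  (malignant lesions attenuate more strongly distal to the mass);
* an SWE image equal to the B-mode outside the elastogram rectangle and,
  inside it, a rendered per-pixel stiffness field with higher mean and
  higher spatial heterogeneity for malignant lesions;
* compound screenshots that place the two panels on a cluttered bezel the
  way an acquisition workstation would, with every panel/ROI rectangle
  recorded so cropping can be verified pixel-exactly.

No acoustic wave physics is simulated; the generator only has to carry
class-separable morphology and stiffness contrasts through the pipeline.
All rectangles are 0-based half-open ``(row_start, col_start, row_stop,
col_stop)`` tuples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib import colormaps
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomParams",
    "PairedSample",
    "CompoundScreenshot",
    "generate_phantom_pair",
    "generate_dataset",
    "compose_screenshot",
    "save_dataset",
    "load_dataset",
    "crop_box",
]

Box = tuple[int, int, int, int]

MANIFEST_COLUMNS = [
    "sample_id", "patient_id", "label", "us_path", "swe_path", "compound_path",
    "roi_row_start", "roi_col_start", "roi_row_stop", "roi_col_stop",
]


def crop_box(img: np.ndarray, box: Box) -> np.ndarray:
    r0, c0, r1, c1 = box
    return img[r0:r1, c0:c1]


@dataclass(frozen=True)
class PhantomParams:
    """Generator configuration; defaults mirror the clinical contrasts.

    Stiffness is in arbitrary kilopascal-like units mapped onto
    ``colormap_name`` after division by ``stiffness_scale_max``.  The
    class balance defaults to the 486-malignant / 260-benign imbalance of
    the clinical cohort, grouped into 207 patients.
    """

    image_height: int = 112
    image_width: int = 144
    lesion_radius_range: tuple[float, float] = (14.0, 26.0)
    malignant_irregularity: float = 0.18
    benign_irregularity: float = 0.10
    stiffness_benign_mean: float = 30.0
    stiffness_malignant_mean: float = 45.0
    stiffness_heterogeneity_malignant: float = 18.0
    stiffness_heterogeneity_benign: float = 8.0
    stiffness_between_lesion_sd: float = 10.0
    stiffness_background: float = 12.0
    stiffness_scale_max: float = 100.0
    speckle_scale: float = 0.25
    colormap_name: str = "jet"
    swe_alpha: float = 0.5
    lesion_echogenicity: float = 0.45
    background_level: float = 0.55
    shadow_strength_malignant: float = 0.35   # attenuation (shadowing)
    shadow_strength_benign: float = -0.15     # negative = posterior enhancement
    shadow_strength_sd: float = 0.10
    shadow_ramp_px: int = 30
    class_balance: float = 486 / 746
    n_patients: int = 207
    images_per_patient_range: tuple[int, int] = (2, 6)

    def __post_init__(self):
        if self.stiffness_malignant_mean <= self.stiffness_benign_mean:
            raise ValueError("malignant stiffness mean must exceed benign")
        if self.malignant_irregularity < self.benign_irregularity:
            raise ValueError("malignant irregularity must be >= benign")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError("class_balance must be in [0, 1]")
        if self.lesion_radius_range[0] > self.lesion_radius_range[1]:
            raise ValueError("lesion_radius_range must be (lo, hi) with lo <= hi")
        if not 0.0 <= self.swe_alpha <= 1.0:
            raise ValueError("swe_alpha must be in [0, 1]")

    def with_(self, **kw) -> "PhantomParams":
        return replace(self, **kw)


@dataclass
class PairedSample:
    """One lesion's aligned B-mode and SWE images with ground truth.

    ``lesion_mask`` and ``stiffness_field`` exist only for synthetic
    samples; loaded real-style data carries ``None`` there.
    """

    sample_id: str
    patient_id: str
    us_image: np.ndarray          # (H, W) grayscale in [0, 1]
    swe_image: np.ndarray         # (H, W, 3) color in [0, 1]
    roi_box: Box
    label: int                    # 1 = malignant, 0 = benign
    lesion_mask: np.ndarray | None = None
    stiffness_field: np.ndarray | None = None


@dataclass
class CompoundScreenshot:
    raster: np.ndarray            # (H, W, 3) in [0, 1]
    us_panel_box: Box
    swe_panel_box: Box
    roi_box_in_us_panel: Box
    label: int
    margin_content: list[Box] = field(default_factory=list)


def _boundary_perturbation(theta: np.ndarray, irregularity: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Random low-order Fourier perturbation with RMS amplitude = irregularity."""
    modes = np.arange(2, 7)
    coef_c = rng.standard_normal(len(modes)) / modes
    coef_s = rng.standard_normal(len(modes)) / modes
    raw = sum(c * np.cos(k * theta) + s * np.sin(k * theta)
              for k, c, s in zip(modes, coef_c, coef_s))
    rms = np.sqrt(0.5 * np.sum((coef_c ** 2 + coef_s ** 2)))
    if rms == 0.0:
        return np.zeros_like(theta)
    return irregularity * raw / rms


def _lesion_mask(params: PhantomParams, label: int, rng: np.random.Generator,
                 geometry: dict | None) -> tuple[np.ndarray, dict]:
    h, w = params.image_height, params.image_width
    irregularity = (params.malignant_irregularity if label == 1
                    else params.benign_irregularity)
    if geometry is None:
        geometry = {
            "radius": float(rng.uniform(*params.lesion_radius_range)),
            "aspect": float(rng.uniform(0.6, 1.0)),
            "angle": float(rng.uniform(0.0, np.pi)),
        }
    radius, aspect, angle = geometry["radius"], geometry["aspect"], geometry["angle"]
    a = radius / np.sqrt(aspect)   # long semi-axis
    b = radius * np.sqrt(aspect)
    edge = 6
    reach = a * (1.0 + irregularity)
    if 2 * reach + 2 * edge >= min(h, w):
        raise ValueError(
            f"lesion with semi-axis {a:.1f} (irregularity {irregularity}) cannot "
            f"fit inside a {h}x{w} image"
        )
    cy = float(rng.uniform(reach + edge, h - reach - edge))
    cx = float(rng.uniform(reach + edge, w - reach - edge))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / a
    v = (-sa * dx + ca * dy) / b
    rho = np.sqrt(u * u + v * v)
    theta = np.arctan2(v, u)
    pert = _boundary_perturbation(theta, irregularity, rng)
    mask = rho <= 1.0 + pert
    return mask, geometry


def _posterior_shadow(mask: np.ndarray, strength: float, ramp_px: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Multiplicative posterior-attenuation map below the lesion.

    Positive strength darkens (acoustic shadowing, typical of malignant
    masses); negative strength brightens (posterior enhancement, typical
    of benign ones).  The effect ramps up with depth over ``ramp_px``
    rows below the lesion, so the contrast develops distally — mostly
    outside the elastogram rectangle, which hugs the lesion.
    """
    h, w = mask.shape
    attn = np.ones((h, w), dtype=np.float64)
    if strength == 0.0 or not mask.any():
        return attn
    cols = np.where(mask.any(axis=0))[0]
    bottoms = np.array([np.max(np.where(mask[:, j])[0]) for j in cols])
    shade = np.zeros((h, w), dtype=np.float64)
    depth = np.arange(h)
    for j, bot in zip(cols, bottoms):
        below = depth > bot
        shade[below, j] = np.clip((depth[below] - bot) / max(ramp_px, 1), 0.0, 1.0)
    shade = gaussian_filter(shade, sigma=2.0)
    return np.clip(attn - strength * np.clip(shade, 0.0, 1.0), 0.0, None)


def _stiffness_field(params: PhantomParams, label: int, mask: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    h, w = mask.shape
    bg_noise = gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
    sd = bg_noise.std()
    bg_noise = bg_noise / sd if sd > 0 else bg_noise
    fieldv = params.stiffness_background * (1.0 + 0.2 * bg_noise)
    if mask.any():
        mean = (params.stiffness_malignant_mean if label == 1
                else params.stiffness_benign_mean)
        # between-lesion random effect: lesions of one class overlap the other
        mean = mean + params.stiffness_between_lesion_sd * rng.standard_normal()
        het = (params.stiffness_heterogeneity_malignant if label == 1
               else params.stiffness_heterogeneity_benign)
        vals = mean + het * rng.standard_normal((h, w))
        # normalized (masked) smoothing: no background bleed into the lesion,
        # so the lesion-interior expectation stays exactly `mean`
        mf = mask.astype(np.float64)
        num = gaussian_filter(vals * mf, sigma=1.5)
        den = gaussian_filter(mf, sigma=1.5)
        smoothed = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-8)
        fieldv = np.where(mask, smoothed, fieldv)
    return np.clip(fieldv, 0.0, None)


def _render_swe(us: np.ndarray, stiffness: np.ndarray, roi: Box,
                params: PhantomParams) -> np.ndarray:
    swe = np.repeat(us[:, :, None], 3, axis=2).astype(np.float32)
    cmap = colormaps[params.colormap_name]
    norm = np.clip(stiffness / params.stiffness_scale_max, 0.0, 1.0)
    rgb = cmap(norm)[:, :, :3].astype(np.float32)
    r0, c0, r1, c1 = roi
    a = params.swe_alpha
    swe[r0:r1, c0:c1] = ((1.0 - a) * swe[r0:r1, c0:c1] + a * rgb[r0:r1, c0:c1])
    return np.clip(swe, 0.0, 1.0).astype(np.float32)


def generate_phantom_pair(params: PhantomParams, label: int, seed: int,
                          geometry: dict | None = None,
                          sample_id: str = "S0000",
                          patient_id: str = "P000") -> PairedSample:
    """Generate one aligned B-mode/SWE phantom pair, deterministically.

    Raises ``ValueError`` if the requested lesion radius (inflated by the
    class irregularity) cannot fit inside the image.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 (benign) or 1 (malignant)")
    rng = np.random.default_rng(seed)
    h, w = params.image_height, params.image_width

    mask, geometry = _lesion_mask(params, label, rng, geometry)

    smooth = gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
    sd = smooth.std()
    smooth = smooth / sd if sd > 0 else smooth
    base = params.background_level * (1.0 + 0.12 * smooth)
    soft = gaussian_filter(mask.astype(np.float64), sigma=1.0)
    echo = base * (1.0 - (1.0 - params.lesion_echogenicity) * np.clip(soft, 0, 1))

    strength = (params.shadow_strength_malignant if label == 1
                else params.shadow_strength_benign)
    # per-lesion jitter: posterior effects of the two classes overlap
    strength = strength + params.shadow_strength_sd * rng.standard_normal()
    attn = _posterior_shadow(mask, strength, params.shadow_ramp_px, rng)

    if params.speckle_scale > 0:
        k = 1.0 / params.speckle_scale ** 2
        speckle = rng.gamma(k, 1.0 / k, (h, w))
    else:
        speckle = np.ones((h, w))
    us = np.clip(echo * attn * speckle, 0.0, 1.0).astype(np.float32)

    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    m = rng.integers(4, 13, size=3)
    # the distal (bottom) margin stays tight, as radiologists draw it,
    # so the developing posterior shadow lies outside the elastogram box
    m_bottom = rng.integers(2, 7)
    roi = (int(max(rows[0] - m[0], 0)), int(max(cols[0] - m[1], 0)),
           int(min(rows[-1] + 1 + m_bottom, h)), int(min(cols[-1] + 1 + m[2], w)))

    stiffness = _stiffness_field(params, label, mask, rng)
    swe = _render_swe(us, stiffness, roi, params)

    return PairedSample(sample_id=sample_id, patient_id=patient_id,
                        us_image=us, swe_image=swe, roi_box=roi, label=label,
                        lesion_mask=mask, stiffness_field=stiffness)


def _allocate_counts(total: int, n_groups: int, lo: int, hi: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Split `total` images over `n_groups` patients, targets drawn in [lo, hi]."""
    if n_groups == 0:
        return np.zeros(0, dtype=int)
    weights = rng.integers(lo, hi + 1, size=n_groups).astype(np.float64)
    raw = total * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    # every patient contributes at least one image
    while (counts == 0).any() and counts.max() > 1:
        counts[np.argmin(counts)] += 1
        counts[np.argmax(counts)] -= 1
    return counts


def generate_dataset(params: PhantomParams, n_samples: int, seed: int
                     ) -> tuple[list[PairedSample], pd.DataFrame]:
    """Generate a patient-grouped phantom cohort plus its manifest table.

    Class counts are exactly ``round(n * class_balance)`` malignant and the
    remainder benign; each patient's images share one label and correlated
    lesion geometry.  The manifest's path columns are filled in by
    :func:`save_dataset`.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if params.n_patients > n_samples:
        raise ValueError("n_patients cannot exceed n_samples")
    rng = np.random.default_rng(seed)
    n_mal = int(round(n_samples * params.class_balance))
    n_ben = n_samples - n_mal
    n_pat = params.n_patients
    n_pat_mal = int(round(n_pat * n_mal / n_samples))
    if n_mal > 0:
        n_pat_mal = max(n_pat_mal, 1)
    if n_ben > 0:
        n_pat_mal = min(n_pat_mal, n_pat - 1)
    n_pat_mal = 0 if n_mal == 0 else n_pat_mal
    n_pat_ben = n_pat - n_pat_mal

    lo, hi = params.images_per_patient_range
    counts_mal = _allocate_counts(n_mal, n_pat_mal, lo, hi, rng)
    counts_ben = _allocate_counts(n_ben, n_pat_ben, lo, hi, rng)

    jobs: list[tuple[str, int, dict]] = []   # (patient_id, label, base geometry)
    pid = 0
    for label, counts in ((1, counts_mal), (0, counts_ben)):
        for c in counts:
            patient_id = f"P{pid:04d}"
            pid += 1
            base = {
                "radius": float(rng.uniform(*params.lesion_radius_range)),
                "aspect": float(rng.uniform(0.6, 1.0)),
                "angle": float(rng.uniform(0.0, np.pi)),
            }
            for _ in range(int(c)):
                jobs.append((patient_id, label, base))
    rng.shuffle(jobs)

    samples: list[PairedSample] = []
    rows = []
    lo_r, hi_r = params.lesion_radius_range
    for i, (patient_id, label, base) in enumerate(jobs):
        geometry = {
            "radius": float(np.clip(base["radius"] * rng.uniform(0.9, 1.1), lo_r, hi_r)),
            "aspect": float(np.clip(base["aspect"] * rng.uniform(0.9, 1.1), 0.5, 1.0)),
            "angle": float(base["angle"] + rng.uniform(-0.2, 0.2)),
        }
        sample_seed = int(rng.integers(2 ** 31))
        sample_id = f"S{i:05d}"
        pair = generate_phantom_pair(params, label, sample_seed, geometry=geometry,
                                     sample_id=sample_id, patient_id=patient_id)
        samples.append(pair)
        r0, c0, r1, c1 = pair.roi_box
        rows.append({"sample_id": sample_id, "patient_id": patient_id,
                     "label": label, "us_path": "", "swe_path": "",
                     "compound_path": "", "roi_row_start": r0, "roi_col_start": c0,
                     "roi_row_stop": r1, "roi_col_stop": c1})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return samples, manifest


# ---------------------------------------------------------------------------
# compound screenshots


def _draw_clutter(canvas: np.ndarray, forbidden: list[Box],
                  rng: np.random.Generator) -> list[Box]:
    """Scatter bright label-like dashes over the bezel; panels overwrite later."""
    h, w = canvas.shape[:2]
    boxes = []
    for _ in range(int(rng.integers(8, 16))):
        bh = int(rng.integers(2, 5))
        bw = int(rng.integers(6, 24))
        r = int(rng.integers(0, max(h - bh, 1)))
        c = int(rng.integers(0, max(w - bw, 1)))
        val = float(rng.uniform(0.6, 0.95))
        canvas[r:r + bh, c:c + bw] = val
        boxes.append((r, c, r + bh, c + bw))
    return boxes


def compose_screenshot(pair: PairedSample, layout_seed: int) -> CompoundScreenshot:
    """Place the US and SWE panels on a cluttered bezel, boxes recorded.

    Panel pixels are copied verbatim, so extracting the recorded boxes
    reproduces the source images bitwise.  Only the margins, offsets and
    clutter depend on ``layout_seed``.
    """
    rng = np.random.default_rng(layout_seed)
    h, w = pair.us_image.shape
    horizontal = bool(rng.integers(0, 2))
    top = int(rng.integers(12, 28))
    left = int(rng.integers(8, 24))
    gap = int(rng.integers(4, 14))
    bottom = int(rng.integers(10, 22))
    right = int(rng.integers(8, 24))

    if horizontal:
        ch, cw = top + h + bottom, left + w + gap + w + right
        us_box = (top, left, top + h, left + w)
        swe_box = (top, left + w + gap, top + h, left + w + gap + w)
    else:
        ch, cw = top + h + gap + h + bottom, left + w + right
        us_box = (top, left, top + h, left + w)
        swe_box = (top + h + gap, left, top + h + gap + h, left + w)

    canvas = np.full((ch, cw, 3), 0.08, dtype=np.float32)
    clutter = _draw_clutter(canvas, [us_box, swe_box], rng)

    r0, c0, r1, c1 = us_box
    canvas[r0:r1, c0:c1] = pair.us_image[:, :, None]
    r0, c0, r1, c1 = swe_box
    canvas[r0:r1, c0:c1] = pair.swe_image

    return CompoundScreenshot(raster=canvas, us_panel_box=us_box,
                              swe_panel_box=swe_box,
                              roi_box_in_us_panel=pair.roi_box,
                              label=pair.label, margin_content=clutter)


# ---------------------------------------------------------------------------
# disk round-trip (8-bit PNG + CSV manifest)


def _save_png(path: Path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    arr = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(path, arr)


def _load_png(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return (iio.imread(path).astype(np.float32) / 255.0)


def save_dataset(samples: list[PairedSample], manifest: pd.DataFrame,
                 out_dir: str | Path, compose_seed: int | None = None
                 ) -> pd.DataFrame:
    """Write 8-bit PNGs (and optionally compound screenshots) plus manifest.csv.

    Returns the manifest with path (and, for compounds, panel-box) columns
    filled in.  Images survive the round trip to within 8-bit quantization.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    extra_cols: dict[str, list] = {}
    for i, pair in enumerate(samples):
        us_path = out_dir / "images" / f"{pair.sample_id}_us.png"
        swe_path = out_dir / "images" / f"{pair.sample_id}_swe.png"
        _save_png(us_path, pair.us_image)
        _save_png(swe_path, pair.swe_image)
        manifest.loc[i, "us_path"] = str(us_path)
        manifest.loc[i, "swe_path"] = str(swe_path)
        if compose_seed is not None:
            shot = compose_screenshot(pair, layout_seed=compose_seed + i)
            cpath = out_dir / "images" / f"{pair.sample_id}_compound.png"
            _save_png(cpath, shot.raster)
            manifest.loc[i, "compound_path"] = str(cpath)
            for prefix, box in (("us_panel", shot.us_panel_box),
                                ("swe_panel", shot.swe_panel_box)):
                for suffix, v in zip(("row_start", "col_start", "row_stop", "col_stop"), box):
                    extra_cols.setdefault(f"{prefix}_{suffix}", []).append(v)
    for col, vals in extra_cols.items():
        manifest[col] = vals
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> tuple[list[PairedSample], pd.DataFrame]:
    """Reload a saved dataset; masks/stiffness ground truth is not persisted."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    samples = []
    for _, row in manifest.iterrows():
        us = _load_png(Path(row["us_path"]))
        if us.ndim == 3:
            us = us[:, :, 0]
        swe = _load_png(Path(row["swe_path"]))[:, :, :3]
        roi = (int(row["roi_row_start"]), int(row["roi_col_start"]),
               int(row["roi_row_stop"]), int(row["roi_col_stop"]))
        samples.append(PairedSample(sample_id=str(row["sample_id"]),
                                    patient_id=str(row["patient_id"]),
                                    us_image=us, swe_image=swe, roi_box=roi,
                                    label=int(row["label"])))
    return samples, manifest
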