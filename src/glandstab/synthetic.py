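"""Synthetic H&E-like ROIs and multi-site feature tables with ground truth.

The image generator renders lumen-bearing glands — a near-white lumen
ellipse inside a dark epithelial/nuclear ring — on textured pinkish
stroma, which is exactly the structure the lumen-based segmentation keys
on. Gleason-4-like regions are emulated by giving a fraction of glands no
visible lumen (fused, lumenless glands contribute only through lumen
absence). Site effects model preparation/scanner variation as a stain
rotation in optical-density space plus RGB shift, contrast scaling, blur
and gland dropout; the identity effect is bit-exact.

The table generator produces the statistical structure the stability
analysis assumes: features are i.i.d. across sites at baseline,
designated unstable features receive per-site location shifts (applied to
every region of a site, non-cancerous ones included), and designated
discriminative features receive a class effect in units of within-class
standard deviation. Site-varying class balance lets unstable features
carry spurious pooled separation — the confound the stability gate
exists to reject.

All generators are pure functions of their spec and seed.
"""
from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .types import Gland, GlandSet, Roi

CLASS_LABELS = ("noncancer", "cancer", "gleason3", "gleason4")

# rendering palette (RGB)
_STROMA = np.array([226.0, 170.0, 196.0])
_RING = np.array([118.0, 84.0, 148.0])
_LUMEN = np.array([246.0, 243.0, 248.0])
_FUSED = np.array([178.0, 138.0, 168.0])

# canonical stain directions in OD space (Ruifrok–Johnston H&E)
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
EOSIN_OD = np.array([0.072, 0.990, 0.105])


@dataclass
class RoiSpec:
    """Parameters of one synthetic region of interest."""

    seed: int
    class_label: str = "noncancer"
    n_glands: int = 40
    image_size_px: tuple[int, int] = (512, 512)  # (height, width)
    microns_per_pixel: float = 2.0
    gland_radius_mean_um: float = 32.0
    gland_radius_cv: float = 0.25
    crowding: float = 1.0
    lumen_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.n_glands < 1:
            raise ValueError("n_glands must be positive")
        if not 0.0 < self.lumen_fraction <= 1.0:
            raise ValueError("lumen_fraction must be in (0, 1]")
        if self.crowding < 0:
            raise ValueError("crowding must be >= 0")
        if self.microns_per_pixel <= 0 or self.gland_radius_mean_um <= 0:
            raise ValueError("scales must be positive")


_CLASS_PRESETS: dict[str, dict] = {
    "noncancer": dict(n_glands=40, gland_radius_mean_um=32.0, crowding=1.0,
                      lumen_fraction=1.0),
    "cancer": dict(n_glands=55, gland_radius_mean_um=22.0, crowding=1.8,
                   lumen_fraction=1.0),
    "gleason3": dict(n_glands=50, gland_radius_mean_um=26.0, crowding=1.5,
                     lumen_fraction=1.0),
    "gleason4": dict(n_glands=55, gland_radius_mean_um=24.0, crowding=1.8,
                     lumen_fraction=0.5),
}


def roi_spec_for_class(class_label: str, seed: int, **overrides) -> RoiSpec:
    """Class-typical spec: cancerous classes are smaller-gland and more
    crowded; Gleason-4-like regions have lumenless glands."""
    params = dict(_CLASS_PRESETS[class_label])
    params.update(overrides)
    return RoiSpec(seed=seed, class_label=class_label, **params)


def _ellipse_vertices(center, a, b, phi, n=64) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    ca, sa = np.cos(phi), np.sin(phi)
    x = center[0] + a * np.cos(t) * ca - b * np.sin(t) * sa
    y = center[1] + a * np.cos(t) * sa + b * np.sin(t) * ca
    return np.column_stack([x, y])


def _fill(image: np.ndarray, verts: np.ndarray, color: np.ndarray) -> np.ndarray:
    rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=image.shape[:2])
    image[rr, cc] = color
    return np.column_stack([cc, rr])  # (x, y) of filled pixels


def simulate_roi(spec: RoiSpec) -> tuple[Roi, GlandSet]:
    """Render one ROI; returns the image plus ground-truth glands."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    r_px = spec.gland_radius_mean_um / spec.microns_per_pixel

    radii = rng.normal(r_px, spec.gland_radius_cv * r_px, spec.n_glands)
    radii = np.clip(radii, 0.35 * r_px, 2.0 * r_px)
    eccs = rng.uniform(0.05, 0.35, spec.n_glands)
    phis = rng.uniform(0.0, np.pi, spec.n_glands)
    a_axes = radii * (1 + eccs)
    b_axes = radii * (1 - eccs)

    margin = 1.1 * a_axes.max() + 2.0
    cx0, cy0 = w / 2.0, h / 2.0
    hx, hy = cx0 - margin, cy0 - margin
    if hx <= 0 or hy <= 0:
        raise ValueError(
            f"image {spec.image_size_px} too small for glands of radius "
            f"{spec.gland_radius_mean_um} um at {spec.microns_per_pixel} um/px"
        )
    shrink = 1.0 / np.sqrt(max(spec.crowding, 1.0))
    hx, hy = hx * shrink, hy * shrink

    centers: list[np.ndarray] = []
    max_attempts = 400 * spec.n_glands
    attempts = 0
    for i in range(spec.n_glands):
        placed = False
        while attempts < max_attempts:
            attempts += 1
            c = np.array([
                cx0 + rng.uniform(-hx, hx), cy0 + rng.uniform(-hy, hy)
            ])
            ok = all(
                np.linalg.norm(c - cj) >= 1.02 * (a_axes[i] + a_axes[j])
                for j, cj in enumerate(centers)
            )
            if ok:
                centers.append(c)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {spec.n_glands} glands of mean radius "
                f"{spec.gland_radius_mean_um} um at crowding {spec.crowding} "
                f"in a {h}x{w} px image"
            )

    image = _STROMA + rng.normal(0.0, 8.0, (h, w, 3))
    image = gaussian_filter(image, sigma=(1.0, 1.0, 0.0))

    n_lumen = int(round(spec.lumen_fraction * spec.n_glands))
    lumen_idx = set(rng.choice(spec.n_glands, size=n_lumen, replace=False))

    glands: list[Gland] = []
    from shapely.geometry import Polygon as _Poly

    for i, c in enumerate(centers):
        outer = _ellipse_vertices(c, a_axes[i], b_axes[i], phis[i])
        if i in lumen_idx:
            _fill(image, outer, _RING + rng.normal(0.0, 4.0, 3))
            inner = _ellipse_vertices(
                c, 0.6 * a_axes[i], 0.6 * b_axes[i], phis[i]
            )
            lumen_px = _fill(image, inner, _LUMEN + rng.normal(0.0, 2.0, 3))
        else:
            _fill(image, outer, _FUSED + rng.normal(0.0, 4.0, 3))
            lumen_px = np.empty((0, 2), dtype=int)
        glands.append(
            Gland(
                boundary=outer,
                centroid=c,
                area_px=float(_Poly(outer).area),
                lumen_pixels=lumen_px,
            )
        )

    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    roi = Roi(
        image=image,
        microns_per_pixel=spec.microns_per_pixel,
        roi_id=f"sim_{spec.class_label}_{spec.seed}",
        label=spec.class_label,
    )
    return roi, GlandSet(glands, roi_id=roi.roi_id,
                         microns_per_pixel=spec.microns_per_pixel)


@dataclass
class SiteEffect:
    """Preparation/scanner appearance effect applied to an ROI.

    The identity effect (zero shift, unit contrast, zero blur/rotation/
    dropout) leaves the image bit-identical. Order of application:
    stain rotation (OD plane) -> contrast -> RGB shift -> blur -> dropout.
    """

    site_id: str
    rgb_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    contrast_scale: float = 1.0
    blur_sigma_px: float = 0.0
    stain_rotation_deg: float = 0.0
    gland_dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.contrast_scale <= 0:
            raise ValueError("contrast_scale must be positive")
        if self.blur_sigma_px < 0:
            raise ValueError("blur_sigma_px must be >= 0")
        if not 0.0 <= self.gland_dropout_rate < 1.0:
            raise ValueError("gland_dropout_rate must be in [0, 1)")

    @property
    def is_identity(self) -> bool:
        return (
            tuple(self.rgb_shift) == (0.0, 0.0, 0.0)
            and self.contrast_scale == 1.0
            and self.blur_sigma_px == 0.0
            and self.stain_rotation_deg == 0.0
            and self.gland_dropout_rate == 0.0
        )


def _stain_plane_basis() -> tuple[np.ndarray, np.ndarray]:
    e1 = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)
    e2 = EOSIN_OD - (EOSIN_OD @ e1) * e1
    return e1, e2 / np.linalg.norm(e2)


def rotate_stains(image_float: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate each pixel's OD vector within the canonical H&E stain plane."""
    od = -np.log10((image_float + 1.0) / 256.0)
    e1, e2 = _stain_plane_basis()
    a = od @ e1
    b = od @ e2
    residual = od - a[..., None] * e1 - b[..., None] * e2
    th = np.radians(angle_deg)
    a2 = a * np.cos(th) - b * np.sin(th)
    b2 = a * np.sin(th) + b * np.cos(th)
    od2 = residual + a2[..., None] * e1 + b2[..., None] * e2
    return 256.0 * np.power(10.0, -od2) - 1.0


def apply_site_effect(
    roi: Roi,
    effect: SiteEffect,
    seed: int = 0,
    glands: GlandSet | None = None,
) -> Roi:
    """Apply a site effect; gland dropout repaints dropped glands with the
    stroma color and therefore needs the ground-truth ``glands``."""
    if effect.is_identity:
        return Roi(
            image=roi.image.copy(),
            microns_per_pixel=roi.microns_per_pixel,
            roi_id=roi.roi_id, site=effect.site_id,
            patient=roi.patient, label=roi.label,
        )
    img = roi.image.astype(float)
    if effect.stain_rotation_deg != 0.0:
        img = np.clip(rotate_stains(img, effect.stain_rotation_deg), 0.0, 255.0)
    if effect.contrast_scale != 1.0:
        img = 127.5 + effect.contrast_scale * (img - 127.5)
    if tuple(effect.rgb_shift) != (0.0, 0.0, 0.0):
        img = img + np.asarray(effect.rgb_shift, dtype=float)
    if effect.blur_sigma_px > 0:
        img = gaussian_filter(
            img, sigma=(effect.blur_sigma_px, effect.blur_sigma_px, 0.0)
        )
    if effect.gland_dropout_rate > 0:
        if glands is None:
            raise ValueError(
                "gland_dropout_rate > 0 requires the ground-truth GlandSet"
            )
        rng = np.random.default_rng(seed)
        n_drop = int(round(effect.gland_dropout_rate * len(glands)))
        drop = rng.choice(len(glands), size=n_drop, replace=False)
        for i in drop:
            _fill(img, glands.glands[i].boundary, _STROMA)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return Roi(
        image=img, microns_per_pixel=roi.microns_per_pixel,
        roi_id=roi.roi_id, site=effect.site_id,
        patient=roi.patient, label=roi.label,
    )


@dataclass
class TableSpec:
    """Parameters of a synthetic multi-site feature table.

    ``unstable_features`` maps feature index to either a per-site shift
    sequence (length ``n_sites``, in units of the within-class standard
    deviation) or a scalar, meaning the shift applies to the first site
    only. ``discriminative_features`` maps feature index to a class
    effect size in the same units, applied to the positive task class
    (cancer, or gleason4). The two sets may overlap: a feature can be
    both discriminative and site-shifted, which is exactly what the
    stability gate must reject.
    """

    seed: int
    n_sites: int = 4
    n_regions_per_site: int = 40
    n_features: int = 20
    class_balance: float | Sequence[float] = 0.5
    task: str = "cancer"  # "cancer" (vs noncancer) or "gleason" (g3 vs g4)
    n_noncancer_per_site: int | None = None  # gleason task only
    discriminative_features: Mapping[int, float] = field(default_factory=dict)
    unstable_features: Mapping[int, float | Sequence[float]] = field(
        default_factory=dict
    )
    noise_family: str = "gaussian"
    regions_per_patient: int = 1

    def __post_init__(self) -> None:
        if self.task not in ("cancer", "gleason"):
            raise ValueError("task must be 'cancer' or 'gleason'")
        if self.noise_family not in ("gaussian", "lognormal"):
            raise ValueError("noise_family must be gaussian or lognormal")
        if min(self.n_sites, self.n_regions_per_site, self.n_features) < 1:
            raise ValueError("sizes must be positive")
        for idx in list(self.discriminative_features) + list(
            self.unstable_features
        ):
            if not 0 <= idx < self.n_features:
                raise ValueError(f"feature index {idx} out of range")
        for idx, shifts in self.unstable_features.items():
            if not np.isscalar(shifts) and len(shifts) != self.n_sites:
                raise ValueError(
                    f"per-site shifts for feature {idx} must have length "
                    f"{self.n_sites}"
                )

    def balances(self) -> np.ndarray:
        if np.isscalar(self.class_balance):
            return np.full(self.n_sites, float(self.class_balance))
        b = np.asarray(self.class_balance, dtype=float)
        if len(b) != self.n_sites:
            raise ValueError("class_balance sequence must match n_sites")
        return b

    def site_shifts(self, idx: int) -> np.ndarray:
        shifts = self.unstable_features[idx]
        if np.isscalar(shifts):
            out = np.zeros(self.n_sites)
            out[0] = float(shifts)
            return out
        return np.asarray(shifts, dtype=float)


def feature_columns(n_features: int) -> list[str]:
    return [f"f{i:03d}" for i in range(n_features)]


def simulate_feature_table(spec: TableSpec) -> tuple[pd.DataFrame, dict]:
    """Multi-site feature table plus ground-truth annotation.

    Returns ``(table, truth)`` where ``truth`` records which feature
    columns are discriminative and which are site-shifted.
    """
    rng = np.random.default_rng(spec.seed)
    cols = feature_columns(spec.n_features)
    balances = spec.balances()
    pos_class = "cancer" if spec.task == "cancer" else "gleason4"
    neg_class = "noncancer" if spec.task == "cancer" else "gleason3"

    frames = []
    patient_counter = 0
    for s in range(spec.n_sites):
        site = f"site{s + 1}"
        n_task = spec.n_regions_per_site
        n_pos = int(round(balances[s] * n_task))
        labels = [neg_class] * (n_task - n_pos) + [pos_class] * n_pos
        if spec.task == "gleason":
            n_nc = (
                spec.n_noncancer_per_site
                if spec.n_noncancer_per_site is not None
                else spec.n_regions_per_site // 2
            )
            labels = ["noncancer"] * n_nc + labels
        n_rows = len(labels)
        z = rng.standard_normal((n_rows, spec.n_features))
        y = np.array([lab == pos_class for lab in labels], dtype=float)
        for idx, effect in spec.discriminative_features.items():
            z[:, idx] += effect * y
        for idx in spec.unstable_features:
            z[:, idx] += spec.site_shifts(idx)[s]
        if spec.noise_family == "lognormal":
            z = np.exp(z)
        df = pd.DataFrame(z, columns=cols)
        df.insert(0, "class", labels)
        region_ids, patient_ids = [], []
        for r in range(n_rows):
            if r % spec.regions_per_patient == 0:
                patient_counter += 1
            region_ids.append(f"{site}_r{r:03d}")
            patient_ids.append(f"p{patient_counter:04d}")
        df.insert(0, "site", site)
        df.insert(0, "patient_id", patient_ids)
        df.insert(0, "region_id", region_ids)
        frames.append(df)

    table = pd.concat(frames, ignore_index=True)
    truth = {
        "discriminative": {
            cols[i]: float(v) for i, v in spec.discriminative_features.items()
        },
        "unstable": {
            cols[i]: spec.site_shifts(i).tolist()
            for i in spec.unstable_features
        },
    }
    return table, truth


def confounded_table_spec(
    seed: int,
    n_sites: int = 4,
    n_regions_per_site: int = 40,
    n_features: int = 20,
    task: str = "cancer",
    n_unstable: int = 5,
    n_stable: int = 5,
    unstable_shift: float = 3.0,
    stable_effect: float = 0.7,
) -> TableSpec:
    """Study-condition table where the apparently strongest features are
    site-confounded: unstable features carry a per-site location gradient
    (up to ``unstable_shift`` sigma) and no true class effect, while class
    balance varies across sites, so pooled training separation on them is
    spurious. Moderate genuinely discriminative features (``stable_effect``
    sigma) are stable across sites.
    """
    balances = np.linspace(0.1, 0.9, n_sites)
    gradient = np.linspace(0.0, 1.0, n_sites)
    unstable = {
        i: (unstable_shift * gradient).tolist() for i in range(n_unstable)
    }
    discriminative = {
        n_unstable + i: stable_effect for i in range(n_stable)
    }
    return TableSpec(
        seed=seed,
        n_sites=n_sites,
        n_regions_per_site=n_regions_per_site,
        n_features=n_features,
        class_balance=balances.tolist(),
        task=task,
        n_noncancer_per_site=n_regions_per_site // 2 if task == "gleason"
        else None,
        discriminative_features=discriminative,
        unstable_features=unstable,
    )


def make_demo_table(seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """The bundled Gleason-grading analogue: 4 sites x 40 task regions
    (plus 20 non-cancerous regions per site for the instability step)."""
    spec = confounded_table_spec(
        seed, task="gleason", n_features=25, n_regions_per_site=40
    )
    return simulate_feature_table(spec)
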