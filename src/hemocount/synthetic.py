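"""Synthetic HE-like micrograph generator with ground truth.

No micrograph data accompany the counting protocol, so testability rests on
synthetic fields that emulate the appearance the method exploits:

* an eosin-pink tissue background with low-amplitude smooth texture;
* bright, near-white hemolymph lacunae (empty slide-like regions, removed
  by the green/blue background threshold);
* granular hemocytes: purple disks carrying a dense speckle of darker
  granules — the color *and* texture signature the PCA model learns.
  Hemocytes are planted inside bright lacunae, where these cells reside in
  tissue sections;
* confounders: small smooth dark-blue nuclei (share the hue, lack the size)
  and elongated pink-red muscle fibers (share smoothness, fail the shape
  criteria).

Everything is deterministic for a fixed (spec, seed).  Four independent
random streams (background, hemocytes, confounders, pixel noise) are
spawned from the seed in that documented order, so switching confounders
on or off never perturbs hemocyte placement or the noise field.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from .errors import EmptyTrainingError, PlacementError, ValidationError
from .imaging import RGBImage, write_image
from .training import Annotation

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "TruthRecord",
    "generate_field",
    "generate_study",
    "generate_training_set",
    "auto_annotate",
    "match_to_truth",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic HE field.

    Geometry defaults to a 256 x 256 px field at 0.8559 um/px, i.e. the
    0.048 mm^2 field of a 40x brightfield objective.  Hemocyte radii
    7-10 px correspond to 12-17 um Group II granular hemocytes; nucleus
    radii 2-3 px to 3.4-5 um tissue nuclei.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.8559

    background_rgb: tuple[int, int, int] = (236, 182, 193)
    texture_amplitude: float = 5.0
    texture_scale: float = 8.0
    bright_fraction: float = 0.08
    bright_rgb: tuple[int, int, int] = (250, 248, 250)

    hemocyte_lambda: float = 5.0
    hemocyte_count: int | None = None  # fixed count overriding the Poisson draw
    hemocyte_radius: tuple[int, int] = (7, 10)
    body_rgb: tuple[int, int, int] = (158, 100, 168)
    granule_rgb: tuple[int, int, int] = (96, 52, 120)
    granule_density: float = 0.45
    granule_jitter: float = 12.0
    halo_margin: int = 6  # lacuna extends this many px beyond the cell body

    nucleus_count: int = 30
    nucleus_radius: tuple[int, int] = (2, 3)
    nucleus_rgb: tuple[int, int, int] = (64, 62, 138)

    fiber_count: int = 5
    fiber_width: tuple[int, int] = (3, 5)
    fiber_length: tuple[int, int] = (40, 80)
    fiber_rgb: tuple[int, int, int] = (196, 100, 122)

    min_separation: float = 16.0
    noise_sigma: float = 2.0
    blur_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hemocyte_lambda < 0:
            raise ValidationError("hemocyte_lambda must be >= 0")
        for name in ("hemocyte_radius", "nucleus_radius"):
            lo, hi = getattr(self, name)
            if lo < 2 or hi < lo:
                raise ValidationError(f"{name}={lo, hi}: radii must be >= 2 and ordered")
        for name in ("background_rgb", "bright_rgb", "body_rgb", "granule_rgb",
                     "nucleus_rgb", "fiber_rgb"):
            if any(not (0 <= v <= 255) for v in getattr(self, name)):
                raise ValidationError(f"{name} has channels outside [0, 255]")
        if not (0.0 <= self.granule_density <= 1.0):
            raise ValidationError("granule_density must be in [0, 1]")
        if not (0.0 <= self.bright_fraction < 1.0):
            raise ValidationError("bright_fraction must be in [0, 1)")

    def replace(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            doc = json.load(fh)
        for k, v in doc.items():
            if isinstance(v, list):
                doc[k] = tuple(v)
        return cls(**doc)


@dataclass(frozen=True)
class TruthRecord:
    kind: str  # "hemocyte" | "nucleus" | "fiber"
    center: tuple[float, float]  # (row, col)
    radius: float
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1) half-open


@dataclass
class GroundTruth:
    records: list[TruthRecord] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == kind]

    @property
    def n_hemocytes(self) -> int:
        return len(self.of_kind("hemocyte"))


_RETRIES = 300


def _place(
    rng: np.random.Generator,
    existing: list[tuple[float, float, float]],
    radius: float,
    border: float,
    shape: tuple[int, int],
    min_separation: float,
    kind: str,
    requested: int,
    achieved: int,
    forbidden: np.ndarray | None = None,
) -> tuple[float, float]:
    """One rejection-sampled center.

    Pairwise distance must exceed max(min_separation, r_i + r_j + 4) so
    planted objects never overlap; ``forbidden`` (e.g. bright lacunae, for
    nuclei) excludes centers falling on True pixels.
    """
    h, w = shape
    lo = border
    for _ in range(_RETRIES):
        r = lo + rng.random() * (h - 2 * lo)
        c = lo + rng.random() * (w - 2 * lo)
        if forbidden is not None and forbidden[int(r), int(c)]:
            continue
        ok = True
        for (er, ec, erad) in existing:
            need = max(min_separation, radius + erad + 4.0)
            if (er - r) ** 2 + (ec - c) ** 2 < need**2:
                ok = False
                break
        if ok:
            return r, c
    raise PlacementError(requested=requested, achieved=achieved, kind=kind)


def _point_segment_dist(pr: float, pc: float, p0: np.ndarray, p1: np.ndarray) -> float:
    d = p1 - p0
    t = float(np.clip(np.dot([pr, pc] - p0, d) / max(np.dot(d, d), 1e-12), 0.0, 1.0))
    proj = p0 + t * d
    return float(np.hypot(pr - proj[0], pc - proj[1]))


def _disk_bbox(r: float, c: float, rad: float, shape: tuple[int, int]):
    h, w = shape
    return (
        max(int(np.floor(r - rad)), 0),
        max(int(np.floor(c - rad)), 0),
        min(int(np.ceil(r + rad)) + 1, h),
        min(int(np.ceil(c + rad)) + 1, w),
    )


def generate_field(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[RGBImage, GroundTruth]:
    """Render one synthetic HE field; deterministic for fixed (spec, seed)."""
    if seed is None:
        seed = spec.seed
    ss = np.random.SeedSequence(seed)
    bg_rng, hemo_rng, conf_rng, noise_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    h, w = spec.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_rgb

    # smooth eosin texture, shared across channels (illumination-like)
    tex = ndimage.gaussian_filter(bg_rng.standard_normal((h, w)), spec.texture_scale)
    sd = tex.std()
    if sd > 0:
        img += (spec.texture_amplitude * tex / sd)[:, :, None]

    # bright lacunae as thresholded smooth noise (organic shapes)
    bright = np.zeros((h, w), dtype=bool)
    if spec.bright_fraction > 0:
        blob = ndimage.gaussian_filter(bg_rng.standard_normal((h, w)), 12.0)
        bright = blob >= np.quantile(blob, 1.0 - spec.bright_fraction)
        soft = ndimage.gaussian_filter(bright.astype(np.float64), 1.5)
        soft = np.clip(soft, 0.0, 1.0)[:, :, None]
        img = img * (1.0 - soft) + np.asarray(spec.bright_rgb, dtype=np.float64) * soft

    truth = GroundTruth()
    placed: list[tuple[float, float, float]] = []

    # --- hemocyte placement (own stream: confounders never shift them) ---
    if spec.hemocyte_count is not None:
        n_h = int(spec.hemocyte_count)
    else:
        n_h = int(hemo_rng.poisson(spec.hemocyte_lambda))
    r_lo, r_hi = spec.hemocyte_radius
    body = np.asarray(spec.body_rgb, dtype=np.float64)
    gran = np.asarray(spec.granule_rgb, dtype=np.float64)
    brightc = np.asarray(spec.bright_rgb, dtype=np.float64)
    cells = []  # (row, col, radius, granule mask draws deferred to render)
    for i in range(n_h):
        rad = float(hemo_rng.integers(r_lo, r_hi + 1))
        border = rad + spec.halo_margin + 2
        rr0, cc0 = _place(
            hemo_rng, placed, rad, border, spec.shape, spec.min_separation,
            "hemocyte", n_h, i,
        )
        placed.append((rr0, cc0, rad))
        cells.append((rr0, cc0, rad))
        truth.records.append(
            TruthRecord(
                kind="hemocyte",
                center=(rr0, cc0),
                radius=rad,
                bbox=_disk_bbox(rr0, cc0, rad, spec.shape),
            )
        )

    # --- fibers: elongated smooth pink-red ribbons, drawn under the cells.
    # Fibers are segments: they may cross each other (merged ribbons stay
    # elongated) but must keep clear of every hemocyte's lacuna.
    fiberc = np.asarray(spec.fiber_rgb, dtype=np.float64)
    for i in range(spec.fiber_count):
        length = float(conf_rng.uniform(*spec.fiber_length))
        width = float(conf_rng.uniform(*spec.fiber_width))
        half_l, half_w = length / 2.0, width / 2.0
        seg = None
        for _ in range(_RETRIES):
            rr0 = half_w + 2 + conf_rng.random() * (h - 2 * (half_w + 2))
            cc0 = half_w + 2 + conf_rng.random() * (w - 2 * (half_w + 2))
            ang = conf_rng.uniform(0, np.pi)
            dr, dc = np.sin(ang), np.cos(ang)
            p0 = np.array([rr0 - half_l * dr, cc0 - half_l * dc])
            p1 = np.array([rr0 + half_l * dr, cc0 + half_l * dc])
            ok = True
            for (er, ec, erad) in placed:
                if _point_segment_dist(er, ec, p0, p1) < (
                    erad + spec.halo_margin + half_w + 3
                ):
                    ok = False
                    break
            if ok:
                seg = (rr0, cc0, ang, dr, dc)
                break
        if seg is None:
            raise PlacementError(requested=spec.fiber_count, achieved=i, kind="fiber")
        rr0, cc0, ang, dr, dc = seg
        nr, nc = -dc, dr  # unit normal
        corners_r = [rr0 + s * half_l * dr + t * half_w * nr
                     for s, t in ((1, 1), (1, -1), (-1, -1), (-1, 1))]
        corners_c = [cc0 + s * half_l * dc + t * half_w * nc
                     for s, t in ((1, 1), (1, -1), (-1, -1), (-1, 1))]
        prr, pcc = draw.polygon(corners_r, corners_c, shape=spec.shape)
        img[prr, pcc] = fiberc
        if prr.size:
            bbox = (int(prr.min()), int(pcc.min()), int(prr.max()) + 1, int(pcc.max()) + 1)
        else:
            bbox = (0, 0, 0, 0)
        truth.records.append(
            TruthRecord(kind="fiber", center=(rr0, cc0), radius=length / 2.0, bbox=bbox)
        )

    # --- render hemocytes over the fibers: lacuna halo, body, granules ---
    for (rr0, cc0, rad) in cells:
        hrr, hcc = draw.disk((rr0, cc0), rad + spec.halo_margin, shape=spec.shape)
        img[hrr, hcc] = brightc
        bright[hrr, hcc] = True
        drr, dcc = draw.disk((rr0, cc0), rad, shape=spec.shape)
        img[drr, dcc] = body
        gm = hemo_rng.random(drr.size) < spec.granule_density
        jit = hemo_rng.uniform(-spec.granule_jitter, spec.granule_jitter, (int(gm.sum()), 3))
        img[drr[gm], dcc[gm]] = np.clip(gran + jit, 0, 255)

    # --- nuclei: small smooth dark-blue ellipses, in tissue only ---
    n_lo, n_hi = spec.nucleus_radius
    nucc = np.asarray(spec.nucleus_rgb, dtype=np.float64)
    for i in range(spec.nucleus_count):
        rad = float(conf_rng.uniform(n_lo, n_hi))
        rr0, cc0 = _place(
            conf_rng, placed, rad, rad + 2, spec.shape, spec.min_separation,
            "nucleus", spec.nucleus_count, i, forbidden=bright,
        )
        placed.append((rr0, cc0, rad))
        ecc = conf_rng.uniform(0.8, 1.2)
        ang = conf_rng.uniform(0, np.pi)
        err, ecc_ = draw.ellipse(rr0, cc0, rad, rad * ecc, shape=spec.shape, rotation=ang)
        img[err, ecc_] = nucc
        truth.records.append(
            TruthRecord(
                kind="nucleus",
                center=(rr0, cc0),
                radius=rad,
                bbox=_disk_bbox(rr0, cc0, rad * max(1.0, ecc), spec.shape),
            )
        )

    # optics blur + sensor noise
    if spec.blur_sigma > 0:
        for c in range(3):
            img[:, :, c] = ndimage.gaussian_filter(img[:, :, c], spec.blur_sigma)
    if spec.noise_sigma > 0:
        img += noise_rng.normal(0.0, spec.noise_sigma, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return (
        RGBImage(pixels=pixels, pixel_size_um=spec.pixel_size_um, id=f"field_{seed}"),
        truth,
    )


def auto_annotate(
    truth: GroundTruth,
    image_id: str,
    image_shape: tuple[int, int],
    margin: int = 2,
) -> list[Annotation]:
    """Training annotations from planted hemocyte bounding rects.

    Stands in, on synthetic data, for the manual singling-out an operator
    performs once during calibration.
    """
    cells = truth.of_kind("hemocyte")
    if not cells:
        raise EmptyTrainingError(f"{image_id}: ground truth contains no hemocytes")
    h, w = image_shape
    out = []
    for rec in cells:
        r0, c0, r1, c1 = rec.bbox
        r0, c0 = max(r0 - margin, 0), max(c0 - margin, 0)
        r1, c1 = min(r1 + margin, h), min(c1 + margin, w)
        out.append(Annotation(image_id=image_id, rect=(r0, c0, r1 - r0, c1 - c0)))
    return out


def generate_training_set(
    spec: SyntheticSpec,
    n_images: int = 10,
    cells_per_image: int = 5,
    seed: int = 0,
) -> tuple[list[RGBImage], list[Annotation], list[GroundTruth]]:
    """Fields with a fixed number of clear hemocytes, plus auto-annotations."""
    tspec = spec.replace(hemocyte_count=cells_per_image)
    rng = np.random.default_rng(seed)
    images, annots, truths = [], [], []
    for i in range(n_images):
        img, truth = generate_field(tspec, seed=int(rng.integers(2**31)))
        img.id = f"train_{i:02d}"
        images.append(img)
        annots.extend(auto_annotate(truth, img.id, tspec.shape))
        truths.append(truth)
    return images, annots, truths


def generate_study(
    control_lambda: float,
    regen_lambda: float,
    n_per_group: int,
    out_dir: str | Path,
    groups: Sequence[str] = ("control", "regen"),
    spec: SyntheticSpec | None = None,
    seed: int = 0,
):
    """Write a grouped study to disk and return its true-count table.

    The first group label is the control (Poisson mean ``control_lambda``);
    every other group draws hemocyte counts from ``regen_lambda``.  Creates
    ``images/*.png``, ``groups.csv``, ``truth.csv`` and ``spec.json``.
    """
    from .stats import CountTable

    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if len(groups) < 1:
        raise ValidationError("at least one group label required")
    if spec is None:
        spec = SyntheticSpec()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    records, truth_rows = [], []
    for gi, group in enumerate(groups):
        lam = control_lambda if gi == 0 else regen_lambda
        gspec = spec.replace(hemocyte_lambda=lam, hemocyte_count=None)
        for i in range(n_per_group):
            img, truth = generate_field(gspec, seed=int(rng.integers(2**31)))
            image_id = f"{group}_{i:03d}"
            img.id = image_id
            write_image(img, out_dir / "images" / f"{image_id}.png")
            area = img.field_area_mm2
            records.append((image_id, group, truth.n_hemocytes, area))
            for rec in truth.records:
                truth_rows.append(
                    {
                        "image_id": image_id,
                        "kind": rec.kind,
                        "row": rec.center[0],
                        "col": rec.center[1],
                        "radius": rec.radius,
                        "r0": rec.bbox[0],
                        "c0": rec.bbox[1],
                        "r1": rec.bbox[2],
                        "c1": rec.bbox[3],
                    }
                )
    table = CountTable.from_records(records)
    table.to_csv(out_dir / "groups.csv")
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    spec.to_json(out_dir / "spec.json")
    return table


def match_to_truth(
    kept_centroids: Sequence[tuple[float, float]],
    truth: GroundTruth,
    slack: float = 5.0,
) -> dict:
    """Greedy nearest-first matching of detections to planted hemocytes.

    A detection matches a planted cell if their centers are within
    ``cell radius + slack`` pixels; each cell and each detection is used at
    most once.  Returns true/false positive and false negative tallies.
    """
    cells = truth.of_kind("hemocyte")
    pairs = []
    for di, (dr, dc) in enumerate(kept_centroids):
        for ci, rec in enumerate(cells):
            d = float(np.hypot(dr - rec.center[0], dc - rec.center[1]))
            if d <= rec.radius + slack:
                pairs.append((d, di, ci))
    pairs.sort()
    used_d, used_c = set(), set()
    matches = []
    for d, di, ci in pairs:
        if di in used_d or ci in used_c:
            continue
        used_d.add(di)
        used_c.add(ci)
        matches.append((di, ci, d))
    tp = len(matches)
    return {
        "tp": tp,
        "fp": len(kept_centroids) - tp,
        "fn": len(cells) - tp,
        "matches": matches,
    }
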