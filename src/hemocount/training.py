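"""Training-image assembly from manual hemocyte annotations.

Calibration needs a reference image made of nothing but granular
hemocytes: rectangles singled out on a handful of micrographs are cropped,
stripped of background pixels, and packed onto a single mosaic.  The
assembly happens once; afterwards any image can be scored against the model
without manual work.

Pixel masks throughout the package are plain (H, W) boolean arrays,
True = retained/selected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EmptyTrainingError, ValidationError
from .imaging import BackgroundConfig, RGBImage, background_mask

__all__ = [
    "Annotation",
    "TrainingImage",
    "load_annotations",
    "save_annotations",
    "assemble_training_image",
]

logger = logging.getLogger(__name__)

#: RGB value used to pad the mosaic between tiles; never part of the model
#: because padded/invalid pixels are excluded from every unfolded row.
SENTINEL_RGB = (255, 255, 255)

GRANULAR_LABEL = "group2_granular"


@dataclass(frozen=True)
class Annotation:
    """Axis-aligned rectangle marking one hemocyte on a source image.

    ``rect = (row0, col0, n_rows, n_cols)`` in 0-based, half-open pixel
    coordinates.
    """

    image_id: str
    rect: tuple[int, int, int, int]
    label: str = GRANULAR_LABEL

    def __post_init__(self) -> None:
        r0, c0, nr, nc = self.rect
        if nr < 3 or nc < 3:
            raise ValidationError(
                f"annotation on {self.image_id!r}: rectangle {self.rect} "
                f"smaller than 3x3"
            )
        if r0 < 0 or c0 < 0:
            raise ValidationError(
                f"annotation on {self.image_id!r}: negative origin in {self.rect}"
            )

    def validate_against(self, img: RGBImage) -> None:
        r0, c0, nr, nc = self.rect
        h, w = img.shape
        if r0 + nr > h or c0 + nc > w:
            raise ValidationError(
                f"annotation rect {self.rect} exceeds the {h}x{w} bounds of "
                f"image {self.image_id!r}"
            )

    def crop(self, img: RGBImage) -> np.ndarray:
        r0, c0, nr, nc = self.rect
        return img.pixels[r0 : r0 + nr, c0 : c0 + nc]


@dataclass
class TrainingImage:
    """Mosaic of annotated hemocyte crops with a validity mask.

    ``valid`` is True exactly on pixels that belong to an annotated
    hemocyte and were not removed as background; sentinel padding and
    background pixels are False.  ``provenance`` records, per tile,
    the source image, rectangle and placement offset.
    """

    mosaic: RGBImage
    valid: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def load_annotations(path: str | Path) -> list[Annotation]:
    """Read annotations from a JSON list of ``{"image": ..., "rect": [...]}``."""
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, list):
        raise ValidationError(f"{path}: annotation file must be a JSON list")
    out = []
    for i, entry in enumerate(doc):
        try:
            rect = tuple(int(v) for v in entry["rect"])
            if len(rect) != 4:
                raise ValueError
            out.append(
                Annotation(
                    image_id=str(entry["image"]),
                    rect=rect,  # type: ignore[arg-type]
                    label=str(entry.get("label", GRANULAR_LABEL)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: malformed annotation #{i}: {entry!r}") from exc
    return out


def save_annotations(annots: Sequence[Annotation], path: str | Path) -> None:
    doc = [
        {"image": a.image_id, "rect": list(a.rect), "label": a.label}
        for a in annots
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def assemble_training_image(
    images: Sequence[RGBImage],
    annots: Sequence[Annotation],
    cfg: BackgroundConfig | None = None,
    pad: int = 6,
) -> TrainingImage:
    """Pack annotated crops row-wise onto a hemocyte-only mosaic.

    Each rectangle is cropped from its source image; pixels classified as
    background under ``cfg`` are marked invalid.  Tiles are shelf-packed
    row-wise with at least ``pad`` pixels of white sentinel between and
    around them so that no unfolding window ever spans two hemocytes
    (``pad`` should be >= 2 * window_radius of the downstream model).

    Raises
    ------
    EmptyTrainingError
        If no annotations are given.
    ValidationError
        If an annotation references a missing image or exceeds its bounds.
    """
    if cfg is None:
        cfg = BackgroundConfig()
    if len(annots) == 0:
        raise EmptyTrainingError("no annotations supplied")
    by_id = {img.id: img for img in images}

    tiles: list[tuple[Annotation, np.ndarray, np.ndarray]] = []
    for a in annots:
        if a.image_id not in by_id:
            raise ValidationError(f"annotation references unknown image {a.image_id!r}")
        src = by_id[a.image_id]
        a.validate_against(src)
        crop = a.crop(src)
        r0, c0, nr, nc = a.rect
        tile_valid = background_mask(src, cfg)[r0 : r0 + nr, c0 : c0 + nc].copy()
        if not tile_valid.any():
            logger.warning(
                "annotation %s on %s is entirely background; contributes no pixels",
                a.rect,
                a.image_id,
            )
        tiles.append((a, crop, tile_valid))

    # Row-wise shelf packing into a roughly square mosaic.
    total_area = sum((c.shape[0] + pad) * (c.shape[1] + pad) for _, c, _ in tiles)
    target_w = max(
        int(np.ceil(np.sqrt(total_area))),
        max(c.shape[1] for _, c, _ in tiles) + 2 * pad,
    )
    placements: list[tuple[int, int]] = []
    row_r, row_c, row_h = pad, pad, 0
    for _, crop, _ in tiles:
        nr, nc = crop.shape[:2]
        if row_c + nc + pad > target_w and row_c > pad:
            row_r += row_h + pad
            row_c, row_h = pad, 0
        placements.append((row_r, row_c))
        row_c += nc + pad
        row_h = max(row_h, nr)
    total_h = row_r + row_h + pad

    mosaic = np.empty((total_h, target_w, 3), dtype=np.uint8)
    mosaic[:] = SENTINEL_RGB
    valid = np.zeros((total_h, target_w), dtype=bool)
    provenance = []
    for (a, crop, tile_valid), (pr, pc) in zip(tiles, placements):
        nr, nc = crop.shape[:2]
        mosaic[pr : pr + nr, pc : pc + nc] = crop
        valid[pr : pr + nr, pc : pc + nc] = tile_valid
        provenance.append(
            {
                "image": a.image_id,
                "rect": list(a.rect),
                "offset": [int(pr), int(pc)],
                "valid_pixels": int(tile_valid.sum()),
            }
        )
    logger.info(
        "assembled training mosaic %dx%d from %d tiles, %d valid pixels",
        total_h, target_w, len(tiles), int(valid.sum()),
    )
    return TrainingImage(
        mosaic=RGBImage(pixels=mosaic, id="training_mosaic"),
        valid=valid,
        provenance=provenance,
    )
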