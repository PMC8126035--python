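"""The trained counting protocol as a scikit-learn-style estimator.

``HemocyteCounter.fit`` performs the one-off calibration: assemble the
hemocyte-only training mosaic from annotated micrographs, fit the
pixel-neighborhood PCA, choose/orient the segmentation component, set the
score threshold, and calibrate the shape filter from the detected training
cells.  ``predict`` then counts hemocytes on any number of images with no
manual assessment.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .detection import (
    DetectionResult,
    ShapeFilter,
    calibrate_filter,
    clean_mask,
    count_hemocytes,
    filter_objects,
    label_objects,
    shape_descriptors,
)
from .errors import ValidationError
from .imaging import BackgroundConfig, RGBImage, background_mask
from .mia import (
    PCAModel,
    calibrate_threshold,
    component_separability,
    fit_pca,
    score_image,
    threshold_scores,
)
from .training import Annotation, assemble_training_image

__all__ = ["HemocyteCounter"]


class HemocyteCounter(BaseEstimator):
    """Marker-free granular-hemocyte counter for HE brightfield micrographs.

    Parameters
    ----------
    green_threshold, blue_threshold : int
        Brightness above which a pixel counts as empty-slide background.
    window_radius : int
        Half-width of the pixel neighborhood (2 -> 5x5 window, 75 features).
    n_components : int
        Principal components retained in the model.
    selected_pc : int or "auto"
        1-based component used for segmentation.  "auto" ranks components
        by the standardized separation between annotated hemocyte pixels
        and other tissue pixels on the training micrographs; an explicit
        index is still orientation-checked against the same diagnostic.
    threshold_quantile : float
        Training-score quantile used as the segmentation threshold.
    closing_radius, fill_holes, connectivity
        Mask consolidation and labeling parameters.
    shape_filter : ShapeFilter or None
        Explicit exclusion bounds; None calibrates them from the training
        cells with ``filter_margin`` relative widening.

    Attributes (after fit)
    ----------------------
    model_ : PCAModel
        The persisted trained protocol (mean, loadings, eigenvalues,
        selected component, score threshold).
    shape_filter_ : ShapeFilter
    separability_ : ndarray
        Per-component hemocyte-vs-tissue standardized separation.
    training_image_ : TrainingImage
    """

    def __init__(
        self,
        green_threshold: int = 200,
        blue_threshold: int = 200,
        window_radius: int = 2,
        n_components: int = 10,
        selected_pc: int | str = 4,
        threshold_quantile: float = 0.05,
        closing_radius: int = 1,
        fill_holes: bool = True,
        connectivity: int = 8,
        shape_filter: ShapeFilter | None = None,
        filter_margin: float = 0.5,
    ):
        self.green_threshold = green_threshold
        self.blue_threshold = blue_threshold
        self.window_radius = window_radius
        self.n_components = n_components
        self.selected_pc = selected_pc
        self.threshold_quantile = threshold_quantile
        self.closing_radius = closing_radius
        self.fill_holes = fill_holes
        self.connectivity = connectivity
        self.shape_filter = shape_filter
        self.filter_margin = filter_margin

    # -- calibration --------------------------------------------------

    def fit(self, X: list[RGBImage], y: list[Annotation]):
        """Calibrate on annotated training micrographs.

        X is the list of training images, y the hemocyte annotations
        referencing them by id.
        """
        images, annots = list(X), list(y)
        bg = BackgroundConfig(self.green_threshold, self.blue_threshold)
        train = assemble_training_image(images, annots, bg, pad=2 * self.window_radius + 2)
        model = fit_pca(
            train,
            window_radius=self.window_radius,
            n_components=self.n_components,
            background=bg,
        )

        # component choice + orientation against annotated vs other pixels
        hemo_masks, valid_masks = [], []
        for img in images:
            hmask = np.zeros(img.shape, dtype=bool)
            for a in annots:
                if a.image_id == img.id:
                    r0, c0, nr, nc = a.rect
                    hmask[r0 : r0 + nr, c0 : c0 + nc] = True
            hemo_masks.append(hmask)
            valid_masks.append(background_mask(img, bg))
        sep = component_separability(model, images, hemo_masks, valid_masks)
        if self.selected_pc == "auto":
            pc = int(np.argmax(np.abs(sep))) + 1
        else:
            pc = int(self.selected_pc)
            if not (1 <= pc <= model.n_components):
                raise ValidationError(
                    f"selected_pc={pc} outside 1..{model.n_components}"
                )
        if sep[pc - 1] < 0:  # make hemocytes the >=-threshold side
            model.loadings[:, pc - 1] = -model.loadings[:, pc - 1]
            model.sign_convention = "hemocyte-high (flipped by separability)"
        else:
            model.sign_convention = "hemocyte-high"
        model.selected_pc = pc
        calibrate_threshold(model, train, quantile=self.threshold_quantile)
        model.metadata["component_separability"] = [float(v) for v in sep]

        # shape filter from the training cells as the pipeline detects them
        if self.shape_filter is not None:
            sf = self.shape_filter
        else:
            descriptors = []
            for img, hmask in zip(images, hemo_masks):
                valid = background_mask(img, bg)
                scores = score_image(img, valid, model)
                mask = threshold_scores(scores, model.score_threshold)
                mask = clean_mask(mask, self.closing_radius, self.fill_holes)
                labels = label_objects(mask, self.connectivity)
                for obj in shape_descriptors(labels):
                    r, c = int(round(obj.centroid[0])), int(round(obj.centroid[1]))
                    if hmask[r, c]:
                        descriptors.append(obj)
            if not descriptors:
                raise ValidationError(
                    "no training hemocytes detected; cannot calibrate the "
                    "shape filter (check thresholds and annotations)"
                )
            sf = calibrate_filter(descriptors, margin=self.filter_margin)

        self.model_ = model
        self.shape_filter_ = sf
        self.separability_ = sep
        self.training_image_ = train
        return self

    # -- inference ----------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise ValidationError("HemocyteCounter is not fitted")

    def detect(self, img: RGBImage) -> DetectionResult:
        """Full detection report (kept/rejected objects) for one image."""
        self._check_fitted()
        return count_hemocytes(
            img,
            self.model_,
            self.shape_filter_,
            closing_radius=self.closing_radius,
            fill_holes=self.fill_holes,
            connectivity=self.connectivity,
        )

    def predict(self, X: list[RGBImage]) -> np.ndarray:
        """Hemocyte count per image."""
        return np.array([self.detect(img).count for img in X], dtype=int)

    @classmethod
    def from_model(
        cls, model: PCAModel, shape_filter: ShapeFilter, **params
    ) -> "HemocyteCounter":
        """Rebuild a fitted counter from a persisted model + filter."""
        est = cls(
            green_threshold=model.background.green_threshold,
            blue_threshold=model.background.blue_threshold,
            window_radius=model.window_radius,
            n_components=model.n_components,
            selected_pc=model.selected_pc,
            **params,
        )
        est.model_ = model
        est.shape_filter_ = shape_filter
        return est
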