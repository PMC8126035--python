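"""Multivariate image analysis: pixel-neighborhood unfolding and PCA score
images.

Each retained pixel is represented by the RGB intensities of its whole
(2r+1) x (2r+1) spatial neighborhood, giving 3*(2r+1)^2 features per pixel.
A PCA model fitted on the unfolded training mosaic (hemocyte pixels only)
captures the joint color/texture signature of granular hemocytes; projecting
any image onto one principal component and refolding the scores to image
geometry yields a *score image*, which is thresholded to isolate
hemocyte-like pixels.

The eigendecomposition is done with a deterministic LAPACK SVD on the
mean-centered matrix — no variance scaling, since all channels share the
0-255 intensity scale.  Eigenvalues use the sample (n-1) normalization and
the full spectrum is kept, so the trace identity
``sum(eigenvalues) == total variance`` holds exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .errors import EmptyTrainingError, ValidationError
from .imaging import BackgroundConfig, RGBImage
from .training import TrainingImage

__all__ = [
    "UnfoldedMatrix",
    "PCAModel",
    "ScoreImage",
    "unfold",
    "refold_center",
    "fit_pca",
    "score_image",
    "project_scores",
    "calibrate_threshold",
    "threshold_scores",
    "component_separability",
]


@dataclass
class UnfoldedMatrix:
    """Pixelwise-unfolded feature matrix.

    ``rows`` has one row per retained pixel; each row is the concatenation,
    channel-major then window row-major, of the neighborhood intensities of
    the red, green and blue channels.  ``pixel_index`` holds the (row, col)
    of each center pixel in the source image.
    """

    rows: np.ndarray
    pixel_index: np.ndarray
    window_radius: int
    image_shape: tuple[int, int]

    @property
    def n_features(self) -> int:
        return self.rows.shape[1]


@dataclass
class PCAModel:
    """The persisted trained protocol.

    Attributes
    ----------
    window_radius : neighborhood half-width in pixels (window is 2r+1 wide)
    mean : (n_features,) column mean of the unfolded training matrix
    loadings : (n_features, n_components) orthonormal columns
    eigenvalues : full spectrum of the sample covariance, non-increasing
    selected_pc : 1-based index of the component used for segmentation
    score_threshold : scalar on the selected component (hemocytes score >= it)
    sign_convention : description of the orientation rule applied
    background : green/blue thresholds the model was calibrated with
    """

    window_radius: int
    mean: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    selected_pc: int = 4
    score_threshold: float | None = None
    sign_convention: str = "max-abs-loading-positive"
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.loadings = np.asarray(self.loadings, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        k = 2 * self.window_radius + 1
        if self.mean.shape[0] != 3 * k * k:
            raise ValidationError(
                f"mean has {self.mean.shape[0]} features; window radius "
                f"{self.window_radius} implies {3 * k * k}"
            )
        if not (1 <= self.selected_pc <= self.n_components):
            raise ValidationError(
                f"selected_pc={self.selected_pc} outside 1..{self.n_components}"
            )

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        """Persist as JSON.  Floats are serialized via ``repr`` so reload is
        bit-exact."""
        doc = {
            "format": "hemocount-pca-model",
            "version": 1,
            "window_radius": self.window_radius,
            "mean": self.mean.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "selected_pc": self.selected_pc,
            "score_threshold": self.score_threshold,
            "sign_convention": self.sign_convention,
            "background": {
                "green_threshold": self.background.green_threshold,
                "blue_threshold": self.background.blue_threshold,
            },
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "hemocount-pca-model":
            raise ValidationError(f"{path}: not a hemocount PCA model file")
        return cls(
            window_radius=int(doc["window_radius"]),
            mean=np.array(doc["mean"], dtype=np.float64),
            loadings=np.array(doc["loadings"], dtype=np.float64),
            eigenvalues=np.array(doc["eigenvalues"], dtype=np.float64),
            selected_pc=int(doc["selected_pc"]),
            score_threshold=doc["score_threshold"],
            sign_convention=doc["sign_convention"],
            background=BackgroundConfig(**doc["background"]),
            metadata=doc.get("metadata", {}),
        )


@dataclass
class ScoreImage:
    """Per-pixel projection onto one principal component, in image geometry.

    Scores are defined only where ``valid``; other entries are 0 and must
    not be interpreted.
    """

    values: np.ndarray
    valid: np.ndarray
    component: int


def _neighborhood_features(pixels: np.ndarray, radius: int) -> np.ndarray:
    """(H, W, 3*(2r+1)^2) feature volume; borders replicate-padded."""
    r = int(radius)
    k = 2 * r + 1
    h, w = pixels.shape[:2]
    padded = np.pad(
        pixels.astype(np.float64), ((r, r), (r, r), (0, 0)), mode="edge"
    )
    chans = []
    for c in range(3):
        win = sliding_window_view(padded[:, :, c], (k, k))  # (H, W, k, k)
        chans.append(win.reshape(h, w, k * k))
    return np.concatenate(chans, axis=2)


def unfold(
    img: RGBImage,
    valid: np.ndarray | None = None,
    window_radius: int = 2,
) -> UnfoldedMatrix:
    """Unfold an image into one feature row per retained pixel.

    Validity governs only which rows exist: invalid *neighbor* pixels
    contribute their raster values (e.g. sentinel white) to neighboring
    rows.  Image borders are handled by edge replication.
    """
    if window_radius < 0:
        raise ValidationError("window_radius must be >= 0")
    h, w = img.shape
    if valid is None:
        valid = np.ones((h, w), dtype=bool)
    if valid.shape != (h, w):
        raise ValidationError("valid mask geometry does not match image")
    feats = _neighborhood_features(img.pixels, window_radius)
    return UnfoldedMatrix(
        rows=feats[valid],
        pixel_index=np.argwhere(valid),
        window_radius=window_radius,
        image_shape=(h, w),
    )


def refold_center(mat: UnfoldedMatrix) -> np.ndarray:
    """Rebuild the (H, W, 3) center-pixel channels from an unfolded matrix.

    Entries outside ``pixel_index`` are 0.  The center pixel of channel c
    sits at column c*(2r+1)^2 + (center offset of the window).
    """
    k = 2 * mat.window_radius + 1
    center = (k * k) // 2
    out = np.zeros((*mat.image_shape, 3), dtype=np.float64)
    rr, cc = mat.pixel_index[:, 0], mat.pixel_index[:, 1]
    for c in range(3):
        out[rr, cc, c] = mat.rows[:, c * k * k + center]
    return out


def _orient_loadings(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign fix: largest-|value| element of each column > 0.

    The natural convention (mean training score >= 0) is vacuous after
    centering — every component's mean training score is exactly 0 — so the
    orientation is fixed by the dominant loading element instead; pipeline
    calibration may still flip the selected component so hemocytes fall on
    the >= threshold side.
    """
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def training_rows(train: TrainingImage, window_radius: int) -> UnfoldedMatrix:
    """Unfold the mosaic keeping only rows with fully valid windows.

    Rows whose window overlaps any invalid pixel (sentinel padding or
    background-removed pixels) are dropped, so white never leaks into the
    hemocyte color/texture model or the threshold calibration.
    """
    k = 2 * window_radius + 1
    invalid_near = ndimage.binary_dilation(
        ~train.valid, structure=np.ones((k, k), dtype=bool)
    )
    clean = train.valid & ~invalid_near
    if not clean.any():
        # fall back to all valid rows rather than failing outright
        clean = train.valid
    return unfold(train.mosaic, clean, window_radius)


def fit_pca(
    train: TrainingImage,
    window_radius: int = 2,
    n_components: int = 10,
    background: BackgroundConfig | None = None,
) -> PCAModel:
    """Fit the hemocyte PCA model on the unfolded training mosaic.

    Uses a full SVD of the centered matrix (deterministic); keeps
    ``n_components`` loading vectors and the complete eigenvalue spectrum.
    """
    if train.n_valid == 0:
        raise EmptyTrainingError("training image has no valid pixels")
    mat = training_rows(train, window_radius)
    X = mat.rows
    n, p = X.shape
    if n < p:
        import warnings

        warnings.warn(
            f"training matrix has fewer rows ({n}) than features ({p}); "
            f"the model will be rank-deficient",
            stacklevel=2,
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    denom = max(n - 1, 1)
    eigenvalues = (s**2) / denom
    n_components = min(n_components, vt.shape[0])
    loadings = _orient_loadings(vt[:n_components].T)
    return PCAModel(
        window_radius=window_radius,
        mean=mean,
        loadings=loadings,
        eigenvalues=eigenvalues,
        selected_pc=min(4, n_components),
        background=background if background is not None else BackgroundConfig(),
        metadata={"n_training_rows": int(n)},
    )


def project_scores(
    mat: UnfoldedMatrix, model: PCAModel, component: int | None = None
) -> np.ndarray:
    """Scores of unfolded rows on one (1-based) component."""
    comp = model.selected_pc if component is None else component
    if not (1 <= comp <= model.n_components):
        raise IndexError(
            f"component {comp} out of range 1..{model.n_components}"
        )
    return (mat.rows - model.mean) @ model.loadings[:, comp - 1]


def score_image(
    img: RGBImage,
    valid: np.ndarray,
    model: PCAModel,
    component: int | None = None,
) -> ScoreImage:
    """Project every valid pixel onto one component and refold to geometry."""
    comp = model.selected_pc if component is None else component
    mat = unfold(img, valid, model.window_radius)
    scores = project_scores(mat, model, comp)
    values = np.zeros(img.shape, dtype=np.float64)
    values[valid] = scores
    return ScoreImage(values=values, valid=valid, component=comp)


def calibrate_threshold(
    model: PCAModel, train: TrainingImage, quantile: float = 0.05
) -> float:
    """Set the score threshold to a low quantile of training hemocyte scores.

    With the default 5% quantile, thresholding the training image itself
    retains ~95% of hemocyte pixels.  Stored into ``model.score_threshold``.
    """
    if not (0.0 < quantile < 1.0):
        raise ValidationError(f"quantile={quantile} outside (0, 1)")
    mat = training_rows(train, model.window_radius)
    scores = project_scores(mat, model)
    tau = float(np.quantile(scores, quantile))
    model.score_threshold = tau
    return tau


def threshold_scores(scores: ScoreImage, tau: float) -> np.ndarray:
    """Mask of pixels that are valid AND score >= tau."""
    return scores.valid & (scores.values >= tau)


def component_separability(
    model: PCAModel,
    images: Sequence[RGBImage],
    hemocyte_masks: Sequence[np.ndarray],
    valid_masks: Sequence[np.ndarray],
) -> np.ndarray:
    """Standardized separation of hemocyte vs other tissue, per component.

    For each component c returns
    ``(mean score of hemocyte pixels - mean score of other valid pixels) /
    pooled standard deviation``.  Positive values mean hemocytes fall on the
    high-score side; the magnitude ranks how well a component isolates them.
    Used to suggest (and orient) the segmentation component for a microscope
    configuration where the canonical index is unknown.
    """
    hemo_rows, other_rows = [], []
    for img, hmask, vmask in zip(images, hemocyte_masks, valid_masks):
        feats = _neighborhood_features(img.pixels, model.window_radius)
        hemo_rows.append(feats[hmask & vmask])
        other_rows.append(feats[vmask & ~hmask])
    H = np.concatenate(hemo_rows) - model.mean
    O = np.concatenate(other_rows) - model.mean
    if H.shape[0] == 0 or O.shape[0] == 0:
        raise ValidationError("separability needs both hemocyte and other pixels")
    sh = H @ model.loadings
    so = O @ model.loadings
    pooled = np.sqrt((sh.var(axis=0) + so.var(axis=0)) / 2.0)
    pooled[pooled == 0] = np.inf
    return (sh.mean(axis=0) - so.mean(axis=0)) / pooled
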