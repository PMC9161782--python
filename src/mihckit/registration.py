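"""Co-registration of per-round mIHC scans into one aligned stack.

Sequential chromogenic mIHC re-scans the same tissue section once per staining
round, so each region of interest (ROI) yields one RGB raster per round that
is shifted, rotated and slightly rescaled relative to the others.  This module
aligns all rounds to a chosen reference round by detecting gradient-based
feature descriptors (ORB), matching them between rounds, and fitting a
similarity transform (scale + rotation + translation) with random-sample
consensus to reject bad matches.  The aligned rounds are cropped to the
largest rectangle valid in every warped round.

Coordinate convention: 0-based pixel indices, ``x`` = column, ``y`` = row,
origin at the top-left; physical coordinates in µm are ``pixel *
pixel_size_um`` (0.22 µm/px for the default 20x brightfield scans).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import transform as sktransform
from skimage.color import rgb2gray
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac


class InsufficientFeaturesError(RuntimeError):
    """Raised when an image pair does not yield enough feature matches."""


@dataclass(frozen=True)
class RoundImage:
    """One staining round of one ROI: an RGB raster plus its pixel size."""

    roi_id: str
    round_index: int
    rgb: np.ndarray  # H x W x 3, uint8 or float
    pixel_size_um: float = 0.22

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be an H x W x 3 raster")
        if self.rgb.shape[0] < 1 or self.rgb.shape[1] < 1:
            raise ValueError("empty raster")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class SimilarityTransform:
    """Similarity map ``p_fixed = scale * R(angle) @ p_moving + t`` in pixels."""

    scale: float = 1.0
    angle: float = 0.0  # radians, counter-clockwise
    translation: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def to_skimage(self) -> sktransform.SimilarityTransform:
        return sktransform.SimilarityTransform(
            scale=self.scale, rotation=self.angle, translation=self.translation
        )

    @classmethod
    def from_skimage(cls, t: sktransform.SimilarityTransform) -> "SimilarityTransform":
        return cls(
            scale=float(t.scale),
            angle=float(t.rotation),
            translation=(float(t.translation[0]), float(t.translation[1])),
        )

    @property
    def matrix(self) -> np.ndarray:
        return self.to_skimage().params

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) moving-frame points into the fixed frame."""
        return self.to_skimage()(np.asarray(xy, dtype=float))

    def inverse(self) -> "SimilarityTransform":
        inv = sktransform.SimilarityTransform(matrix=np.linalg.inv(self.matrix))
        return SimilarityTransform.from_skimage(inv)

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "angle_deg": float(np.degrees(self.angle)),
            "dx": self.translation[0],
            "dy": self.translation[1],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(
            scale=float(d["scale"]),
            angle=float(np.radians(d["angle_deg"])),
            translation=(float(d["dx"]), float(d["dy"])),
        )


@dataclass
class RegisteredStack:
    """All rounds of one ROI warped into the reference frame and cropped.

    ``rounds`` hold the aligned RGB rasters (reference frame, common crop);
    ``nuclear`` and ``marker_rasters`` are filled by the stain-separation step
    (:func:`mihckit.stain_quant.deconvolve_stack`).
    """

    roi_id: str
    rounds: list[np.ndarray]
    transforms: dict[int, SimilarityTransform]
    crop_box: tuple[int, int, int, int]  # (row0, row1, col0, col1) exclusive
    reference_round: int
    pixel_size_um: float
    nuclear: np.ndarray | None = None
    marker_rasters: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rounds[0].shape[:2]

    def save_transforms(self, path: str | Path) -> None:
        payload = {
            "roi_id": self.roi_id,
            "reference_round": self.reference_round,
            "crop_box": [int(v) for v in self.crop_box],
            "transforms": {str(k): t.to_dict() for k, t in self.transforms.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = rgb2gray(img)
    img = img.astype(float)
    if img.max() > 1.5:
        img = img / 255.0
    return img


def detect_and_match_features(
    fixed: RoundImage | np.ndarray,
    moving: RoundImage | np.ndarray,
    n_keypoints: int = 1500,
    min_matches: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect ORB descriptors in both images and match them.

    Returns ``(correspondences, scores)`` where ``correspondences`` is an
    (N, 4) array of ``(x_fixed, y_fixed, x_moving, y_moving)`` and ``scores``
    the Hamming distance of each descriptor match (smaller is better).
    Matches may contain outliers; robust estimation happens downstream.

    Raises
    ------
    InsufficientFeaturesError
        If either image is featureless or fewer than ``min_matches``
        cross-checked matches survive.
    """
    if isinstance(fixed, RoundImage) and isinstance(moving, RoundImage):
        if not np.isclose(fixed.pixel_size_um, moving.pixel_size_um):
            raise ValueError("fixed and moving images must share a pixel size")
    gray_f = _to_gray(fixed.rgb if isinstance(fixed, RoundImage) else fixed)
    gray_m = _to_gray(moving.rgb if isinstance(moving, RoundImage) else moving)

    kp = []
    for name, gray in (("fixed", gray_f), ("moving", gray_m)):
        orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
        try:
            orb.detect_and_extract(gray)
        except RuntimeError as exc:  # skimage raises when no keypoints found
            raise InsufficientFeaturesError(
                f"insufficient features in {name} image"
            ) from exc
        if len(orb.keypoints) < 3:
            raise InsufficientFeaturesError(f"insufficient features in {name} image")
        kp.append((orb.keypoints, orb.descriptors))

    (kp_f, desc_f), (kp_m, desc_m) = kp
    matches = match_descriptors(desc_f, desc_m, cross_check=True)
    if len(matches) < min_matches:
        raise InsufficientFeaturesError(
            f"insufficient features: only {len(matches)} matches "
            f"(minimum {min_matches})"
        )
    # keypoints are (row, col); emit (x, y) = (col, row)
    pf = kp_f[matches[:, 0]][:, ::-1]
    pm = kp_m[matches[:, 1]][:, ::-1]
    scores = np.array(
        [np.count_nonzero(desc_f[i] != desc_m[j]) for i, j in matches], dtype=float
    )
    return np.hstack([pf, pm]), scores


def _lsq_similarity(src: np.ndarray, dst: np.ndarray) -> sktransform.SimilarityTransform:
    """Least-squares (Umeyama) similarity fit src -> dst."""
    if hasattr(sktransform.SimilarityTransform, "from_estimate"):
        model = sktransform.SimilarityTransform.from_estimate(src, dst)
        if model is None or not np.all(np.isfinite(model.params)):
            raise ValueError("least-squares similarity fit failed")
        return model
    model = sktransform.SimilarityTransform()
    if not model.estimate(src, dst):
        raise ValueError("least-squares similarity fit failed")
    return model


def estimate_similarity(
    correspondences: np.ndarray,
    residual_threshold: float = 2.0,
    seed: int = 0,
    max_trials: int = 1000,
) -> tuple[SimilarityTransform, dict]:
    """Robustly fit a similarity transform mapping moving points onto fixed.

    Random-sample consensus selects an inlier set at ``residual_threshold``
    pixels, then the transform is re-estimated on all inliers by least squares
    (Umeyama).  Returns the transform and a diagnostics dict with the inlier
    count, inlier mask and the inlier residual RMS in pixels.
    """
    corr = np.asarray(correspondences, dtype=float)
    if corr.ndim != 2 or corr.shape[1] != 4:
        raise ValueError("correspondences must be an (N, 4) array")
    if len(corr) < 3:
        raise ValueError("need at least 3 correspondences")
    fixed = corr[:, :2]
    moving = corr[:, 2:]

    # degenerate geometry: all moving points collinear (rank < 2 after centering)
    centered = moving - moving.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("degenerate correspondence geometry (collinear points)")

    model, inliers = ransac(
        (moving, fixed),
        sktransform.SimilarityTransform,
        min_samples=3,
        residual_threshold=residual_threshold,
        max_trials=max_trials,
        rng=seed,
    )
    if model is None or inliers is None or inliers.sum() < 3:
        raise ValueError("robust consensus failed: fewer than 3 usable inliers")

    # iterative trimmed least squares: refit on the consensus set, then
    # re-select inliers at the (tightening) threshold and refit again, which
    # sharpens the estimate when keypoint localization noise is ~1 px
    refined = _lsq_similarity(moving[inliers], fixed[inliers])
    for thresh in (residual_threshold, 0.75 * residual_threshold):
        resid = np.linalg.norm(refined(moving) - fixed, axis=1)
        new_inliers = resid <= thresh
        if new_inliers.sum() >= 3:
            inliers = new_inliers
            refined = _lsq_similarity(moving[inliers], fixed[inliers])
    residuals = np.linalg.norm(refined(moving[inliers]) - fixed[inliers], axis=1)
    info = {
        "n_inliers": int(inliers.sum()),
        "inlier_mask": inliers,
        "residual_rms": float(np.sqrt(np.mean(residuals**2))),
    }
    return SimilarityTransform.from_skimage(refined), info


def _warp_to_reference(
    image: np.ndarray, t: SimilarityTransform, output_shape: tuple[int, int]
) -> np.ndarray:
    """Resample ``image`` (moving frame) on the reference grid.

    ``t`` maps moving → fixed, so the warp's output→input map is its inverse.
    Bilinear interpolation; out-of-bounds pixels filled with 0.
    """
    img = np.asarray(image, dtype=float)
    inv = t.to_skimage().inverse
    if img.ndim == 3:
        out = np.stack(
            [
                sktransform.warp(
                    img[..., c], inv, output_shape=output_shape, order=1, cval=0.0
                )
                for c in range(img.shape[2])
            ],
            axis=-1,
        )
    else:
        out = sktransform.warp(img, inv, output_shape=output_shape, order=1, cval=0.0)
    return out


def _largest_rectangle(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Largest axis-aligned all-True rectangle, as (row0, row1, col0, col1)."""
    h, w = mask.shape
    heights = np.zeros(w, dtype=int)
    best = (0, 0, 0, 0)
    best_area = 0
    for r in range(h):
        heights = np.where(mask[r], heights + 1, 0)
        # histogram largest-rectangle with a stack
        stack: list[int] = []
        for c in range(w + 1):
            cur = heights[c] if c < w else 0
            while stack and heights[stack[-1]] >= cur:
                top = stack.pop()
                height = heights[top]
                left = stack[-1] + 1 if stack else 0
                area = height * (c - left)
                if area > best_area:
                    best_area = area
                    best = (r - height + 1, r + 1, left, c)
            stack.append(c)
    if best_area == 0:
        raise ValueError("no common valid region across rounds")
    return best


def register_stack(
    rounds: list[RoundImage],
    reference_round: int = 0,
    residual_threshold: float = 2.0,
    seed: int = 0,
    n_keypoints: int = 1500,
) -> RegisteredStack:
    """Warp every round of one ROI into the reference round's frame.

    Each non-reference round is feature-matched against the reference and a
    robust similarity transform estimated; all rounds are then resampled on
    the reference grid and cropped to the largest rectangle contained in every
    warped round's valid region.  A round that fails feature matching aborts
    the ROI with a diagnostic naming the round.
    """
    if not rounds:
        raise ValueError("no rounds given")
    roi_ids = {r.roi_id for r in rounds}
    if len(roi_ids) != 1:
        raise ValueError(f"rounds span multiple ROIs: {sorted(roi_ids)}")
    sizes = {round(r.pixel_size_um, 9) for r in rounds}
    if len(sizes) != 1:
        raise ValueError(f"rounds have mismatched pixel sizes: {sorted(sizes)}")
    if not 0 <= reference_round < len(rounds):
        raise ValueError("reference_round out of range")

    ref = rounds[reference_round]
    out_shape = ref.rgb.shape[:2]
    transforms: dict[int, SimilarityTransform] = {}
    aligned: list[np.ndarray] = []
    valid = np.ones(out_shape, dtype=bool)

    for r in rounds:
        if r.round_index == ref.round_index:
            transforms[r.round_index] = SimilarityTransform()
            aligned.append(np.asarray(r.rgb, dtype=float))
            continue
        try:
            corr, _ = detect_and_match_features(ref, r, n_keypoints=n_keypoints)
            t, _info = estimate_similarity(
                corr, residual_threshold=residual_threshold, seed=seed
            )
        except (InsufficientFeaturesError, ValueError) as exc:
            raise RuntimeError(
                f"registration failed for ROI {r.roi_id} round {r.round_index}: {exc}"
            ) from exc
        transforms[r.round_index] = t
        aligned.append(_warp_to_reference(r.rgb, t, out_shape))
        ones = np.ones(r.rgb.shape[:2], dtype=float)
        valid &= _warp_to_reference(ones, t, out_shape) > 0.999

    r0, r1, c0, c1 = _largest_rectangle(valid)
    cropped = [a[r0:r1, c0:c1] for a in aligned]
    return RegisteredStack(
        roi_id=ref.roi_id,
        rounds=cropped,
        transforms=transforms,
        crop_box=(r0, r1, c0, c1),
        reference_round=reference_round,
        pixel_size_um=ref.pixel_size_um,
    )
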