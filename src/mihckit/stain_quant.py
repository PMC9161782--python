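"""Chromogen deconvolution, nuclear segmentation and single-cell quantification.

Brightfield mIHC encodes each marker as the red chromogen AEC
(3-amino-9-ethylcarbazole) with a hematoxylin nuclear counterstain.  Under the
Beer–Lambert model a pixel's RGB transmittance is ``rgb = background *
exp(-(c_aec * v_aec + c_hem * v_hem))`` where ``v`` are unit optical-density
(OD) stain vectors.  Deconvolution inverts this: convert to OD, project onto
the stain basis, clip negative projections and rescale to [0, 1] by a fixed
reference OD.  Nuclei are segmented from the hematoxylin channel by
distance-transform-seeded watershed, and each cell's marker expressions are
the mean deconvolved AEC intensities over its nucleus pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import relabel_sequential, watershed

from mihckit.registration import RegisteredStack

# Default OD stain vectors (RGB order).  Hematoxylin is the standard
# Ruifrok–Johnston vector; AEC is the ImageJ colour-deconvolution AEC vector.
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
AEC_OD = (0.2743, 0.6796, 0.6803)
DEFAULT_BACKGROUND = 255.0


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero stain vector")
    return v / n


@dataclass(frozen=True)
class StainVectors:
    """AEC / hematoxylin optical-density basis and the background white level."""

    aec_rgb: tuple[float, float, float] = AEC_OD
    hematoxylin_rgb: tuple[float, float, float] = HEMATOXYLIN_OD
    background_rgb: tuple[float, float, float] = (
        DEFAULT_BACKGROUND,
        DEFAULT_BACKGROUND,
        DEFAULT_BACKGROUND,
    )

    def matrix(self) -> np.ndarray:
        """3x3 stain matrix, rows = (aec, hematoxylin, residual) unit OD vectors."""
        a = _unit(self.aec_rgb)
        h = _unit(self.hematoxylin_rgb)
        r = np.cross(a, h)
        if np.linalg.norm(r) < 1e-8:
            raise ValueError("singular stain basis: AEC and hematoxylin parallel")
        m = np.stack([a, h, r / np.linalg.norm(r)])
        if abs(np.linalg.det(m)) < 1e-8:
            raise ValueError("singular stain basis")
        return m


@dataclass
class NucleusMask:
    """Labelled nucleus raster: 0 = background, positive integers = cells."""

    labels: np.ndarray
    cell_ids: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cell_ids:
            self.cell_ids = {int(v): int(v) for v in np.unique(self.labels) if v != 0}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def deconvolve_stains(
    rgb: np.ndarray,
    vectors: StainVectors | None = None,
    od_reference: float = 1.0,
    method: str = "od",
    eps: float = 1.0,
) -> dict[str, np.ndarray]:
    """Separate an RGB raster into AEC and hematoxylin intensity rasters.

    ``method="od"`` (default) performs optical-density unmixing against the
    configurable stain basis; negative projections are clipped to zero and the
    result is rescaled to [0, 1] by ``od_reference``.  ``method="cmyk"``
    instead uses the simple CMYK heuristic (AEC ≈ magenta, hematoxylin ≈ cyan
    of the naive CMYK conversion), provided for fidelity with legacy ImageJ
    macro pipelines; it is less well conditioned than OD unmixing.
    """
    img = np.asarray(rgb, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("rgb must be H x W x 3")
    if method == "cmyk":
        rgbn = np.clip(img / 255.0, 0.0, 1.0)
        k = 1.0 - rgbn.max(axis=2)
        denom = np.maximum(1.0 - k, 1e-9)
        cyan = (1.0 - rgbn[..., 0] - k) / denom
        magenta = (1.0 - rgbn[..., 1] - k) / denom
        return {"aec": np.clip(magenta, 0, 1), "hematoxylin": np.clip(cyan, 0, 1)}
    if method != "od":
        raise ValueError(f"unknown deconvolution method {method!r}")

    vectors = vectors or StainVectors()
    bg = np.asarray(vectors.background_rgb, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background level must be positive")
    od = -np.log((img + eps) / (bg + eps))
    m = vectors.matrix()
    conc = od.reshape(-1, 3) @ np.linalg.inv(m)
    conc = np.clip(conc, 0.0, None).reshape(img.shape)
    aec = np.clip(conc[..., 0] / od_reference, 0.0, 1.0)
    hem = np.clip(conc[..., 1] / od_reference, 0.0, 1.0)
    return {"aec": aec, "hematoxylin": hem}


def deconvolve_stack(
    stack: RegisteredStack,
    marker_names: list[str],
    vectors: StainVectors | None = None,
    hematoxylin_round: int | None = None,
    od_reference: float = 1.0,
    method: str = "od",
) -> RegisteredStack:
    """Fill a registered stack's nuclear and per-marker rasters in place.

    The nuclear raster is the hematoxylin channel of ``hematoxylin_round``
    (default: the reference round); each marker raster is the AEC channel of
    its round.  Rounds are assumed ordered hematoxylin first, then one round
    per marker in panel order.
    """
    if hematoxylin_round is None:
        hematoxylin_round = stack.reference_round
    if len(stack.rounds) != len(marker_names) + 1:
        raise ValueError(
            f"expected {len(marker_names) + 1} rounds "
            f"(hematoxylin + markers), got {len(stack.rounds)}"
        )
    nuc = deconvolve_stains(
        stack.rounds[hematoxylin_round], vectors, od_reference, method
    )
    stack.nuclear = nuc["hematoxylin"]
    marker_rounds = [i for i in range(len(stack.rounds)) if i != hematoxylin_round]
    for name, idx in zip(marker_names, marker_rounds):
        sep = deconvolve_stains(stack.rounds[idx], vectors, od_reference, method)
        stack.marker_rasters[name] = sep["aec"]
    return stack


def segment_nuclei(
    nuclear: np.ndarray,
    pixel_size_um: float = 0.22,
    min_area_um2: float = 8.0,
    threshold: float | None = None,
    smooth_sigma_um: float = 0.7,
    min_distance_um: float = 2.5,
) -> NucleusMask:
    """Watershed segmentation of nuclei from a hematoxylin intensity raster.

    The raster is Gaussian-smoothed, thresholded (Otsu unless ``threshold`` is
    given), and foreground components are split by a watershed seeded at
    distance-transform maxima at least ``min_distance_um`` apart, which
    separates touching nuclei with distinct cores.  Components smaller than
    ``min_area_um2`` are removed and labels relabelled sequentially; a blank
    raster yields an empty mask, not an error.
    """
    img = np.asarray(nuclear, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclear raster must be 2-D")
    if np.any(img < 0):
        raise ValueError("nuclear raster must be non-negative")
    smoothed = gaussian(img, sigma=smooth_sigma_um / pixel_size_um, preserve_range=True)
    if threshold is None:
        if np.ptp(smoothed) < 1e-9:
            return NucleusMask(np.zeros(img.shape, dtype=np.int32))
        threshold = threshold_otsu(smoothed)
    fg = smoothed > threshold
    min_px = max(1, int(round(min_area_um2 / pixel_size_um**2)))
    try:
        fg = remove_small_objects(fg, max_size=min_px - 1)
    except TypeError:  # skimage < 0.26
        fg = remove_small_objects(fg, min_size=min_px)
    if not fg.any():
        return NucleusMask(np.zeros(img.shape, dtype=np.int32))

    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist,
        min_distance=max(1, int(round(min_distance_um / pixel_size_um))),
        labels=fg,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    # deterministic seed ordering: peak_local_max returns peaks sorted by
    # intensity; re-sort by (row, col) so labels follow raster order
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    for i, (r, c) in enumerate(peaks[order], start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=fg)

    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_px)
    labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return NucleusMask(labels.astype(np.int32))


def quantify_cells(
    mask: NucleusMask,
    stack: RegisteredStack | dict[str, np.ndarray],
    pixel_size_um: float | None = None,
    roi_id: str | None = None,
) -> pd.DataFrame:
    """Build the single-cell table from a nucleus mask and marker rasters.

    Each row is one segmented cell: ``cell_id``, ``roi_id``, the unweighted
    centroid in µm (``x_um``, ``y_um``), the nucleus area in µm², and the mean
    deconvolved intensity of every panel marker over the nucleus pixels.  An
    empty mask yields an empty table with the full header.
    """
    if isinstance(stack, RegisteredStack):
        rasters = stack.marker_rasters
        pixel_size_um = pixel_size_um or stack.pixel_size_um
        roi_id = roi_id or stack.roi_id
    else:
        rasters = stack
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required with a raster dict")
        roi_id = roi_id or "ROI"
    markers = list(rasters)
    labels = mask.labels
    for name, raster in rasters.items():
        if raster.shape != labels.shape:
            raise ValueError(f"marker raster {name!r} shape mismatch with mask")

    columns = ["cell_id", "roi_id", "x_um", "y_um", "area_um2", *markers]
    ids = sorted(mask.cell_ids)
    if not ids:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in columns}).astype(
            {"roi_id": str}
        )

    index = np.array(ids)
    counts = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, index)
    com = np.array(ndi.center_of_mass(np.ones_like(labels, float), labels, index))
    data = {
        "cell_id": [mask.cell_ids[i] for i in ids],
        "roi_id": roi_id,
        "x_um": com[:, 1] * pixel_size_um,
        "y_um": com[:, 0] * pixel_size_um,
        "area_um2": counts * pixel_size_um**2,
    }
    for name in markers:
        data[name] = ndi.mean(np.asarray(rasters[name], float), labels, index)
    return pd.DataFrame(data, columns=columns)
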