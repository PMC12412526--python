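"""OCTA–fluorescence fusion: co-registration, red–green merge, and SSIM.

The OCTA (flow) and GFP (structure) en-face maps image the same vasculature
through different contrasts; after a similarity-transform co-registration
they are merged into a red (flow) / green (structure) composite in which
perfused vessels appear yellow, and compared with the structural similarity
index (SSIM), whose global score summarizes how well blood flow matches
vessel structure — high for a healthy, fully perfused network, low when
many structural vessels carry no flow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity
from skimage.registration import phase_cross_correlation
from skimage.transform import SimilarityTransform, warp

from .io import ROI, EnFaceMap

__all__ = ["RegistrationResult", "SSIMResult", "coregister", "merge_red_green", "ssim"]

log = logging.getLogger(__name__)


@dataclass
class RegistrationResult:
    """Similarity transform mapping the moving map onto the fixed map."""

    rotation_deg: float
    scale: float
    shift_rowcol: tuple[float, float]
    correlation: float
    resampled: EnFaceMap
    identity: bool = False


@dataclass
class SSIMResult:
    """Global and local structural similarity between two maps over an ROI."""

    global_score: float
    local_map: np.ndarray
    window_size: int
    k1: float
    k2: float
    roi: ROI
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.global_score <= 1.0 + 1e-9:
            raise ValueError("global SSIM must lie in [-1, 1]")

    def display_map(self) -> np.ndarray:
        """The reporting convention for local SSIM maps: values mapped for an
        inverted hot colormap where black corresponds to a score of 1 and
        white to −1 (render with ``matplotlib`` cmap ``hot_r``)."""
        return (1.0 - self.local_map) / 2.0


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _apply(moving: np.ndarray, rot_deg: float, scale: float,
           shift: tuple[float, float]) -> np.ndarray:
    """Rotate (counter-clockwise positive, as in ``skimage.transform.rotate``)
    and scale about the image center, then translate by (drow, dcol)."""
    h, w = moving.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    t = (
        SimilarityTransform(translation=-center)
        + SimilarityTransform(rotation=np.radians(-rot_deg), scale=scale)
        + SimilarityTransform(translation=center)
        + SimilarityTransform(translation=(shift[1], shift[0]))
    )
    return warp(moving, t.inverse, order=1, mode="constant", cval=0.0,
                preserve_range=True)


def coregister(
    moving: EnFaceMap,
    fixed: EnFaceMap,
    rotation_range_deg: float = 5.0,
    rotation_step_deg: float = 1.0,
    scale_range: float = 0.0,
    refine_step_deg: float = 0.1,
    correlation_floor: float = 0.1,
    translation_only: bool = False,
) -> RegistrationResult:
    """Recover the similarity transform aligning ``moving`` to ``fixed``.

    Coarse-to-fine grid search over rotation (and optionally isotropic
    scale); at each candidate the translation comes from sub-pixel phase
    cross-correlation and the candidate is scored by normalized
    cross-correlation.  Ties break toward the smaller transform.  If the
    best correlation is below ``correlation_floor`` a warning is issued and
    the identity transform returned.
    """
    if moving.shape != fixed.shape:
        raise ValueError("coregister expects equally shaped maps")
    mov, fix = moving.pixels, fixed.pixels

    def evaluate(rot: float, scale: float):
        cand = _apply(mov, rot, scale, (0.0, 0.0))
        shift, _, _ = phase_cross_correlation(fix, cand, upsample_factor=10,
                                              normalization=None)
        shifted = _apply(mov, rot, scale, (float(shift[0]), float(shift[1])))
        return _ncc(fix, shifted), (float(shift[0]), float(shift[1])), shifted

    candidates: list[tuple[float, float]] = []
    if translation_only:
        candidates = [(0.0, 1.0)]
    else:
        rots = np.arange(-rotation_range_deg, rotation_range_deg + 1e-9,
                         rotation_step_deg)
        scales = ([1.0] if scale_range == 0 else
                  np.linspace(1 - scale_range, 1 + scale_range, 5))
        candidates = [(float(r), float(s)) for r in rots for s in scales]

    def magnitude(rot, scale, shift):
        return abs(rot) + 10 * abs(scale - 1) + 0.01 * (abs(shift[0]) + abs(shift[1]))

    best = None
    for rot, scale in candidates:
        score, shift, img = evaluate(rot, scale)
        key = (-score, magnitude(rot, scale, shift))
        if best is None or key < best[0]:
            best = (key, rot, scale, shift, score, img)

    if not translation_only:
        # local refinement around the coarse optimum
        _, rot0, scale0, _, _, _ = best
        for rot in np.arange(rot0 - rotation_step_deg, rot0 + rotation_step_deg + 1e-9,
                             refine_step_deg):
            for scale in ([scale0] if scale_range == 0
                          else np.linspace(scale0 * 0.98, scale0 * 1.02, 5)):
                score, shift, img = evaluate(float(rot), float(scale))
                key = (-score, magnitude(rot, scale, shift))
                if key < best[0]:
                    best = (key, float(rot), float(scale), shift, score, img)

    _, rot, scale, shift, score, img = best
    if score < correlation_floor:
        msg = (f"registration correlation {score:.3f} below floor "
               f"{correlation_floor}; returning identity transform")
        warnings.warn(msg, stacklevel=2)
        log.warning(msg)
        return RegistrationResult(0.0, 1.0, (0.0, 0.0), _ncc(fix, mov),
                                  EnFaceMap(np.clip(mov, 0, None),
                                            moving.pixel_size_um,
                                            moving.channel, moving.roi),
                                  identity=True)
    res = EnFaceMap(np.clip(img, 0.0, None), moving.pixel_size_um,
                    moving.channel, moving.roi)
    return RegistrationResult(rot, scale, shift, score, res)


def merge_red_green(octa: EnFaceMap, gfp: EnFaceMap) -> np.ndarray:
    """Red–green composite: red = normalized flow, green = normalized
    structure, blue = 0.  Perfused vessels (both channels) appear yellow."""
    if octa.shape != gfp.shape:
        raise ValueError("maps must be co-registered to the same shape")
    r = octa.normalized().pixels
    g = gfp.normalized().pixels
    return np.stack([r, g, np.zeros_like(r)], axis=-1)


def ssim(
    a: EnFaceMap,
    b: EnFaceMap,
    window_size: int = 11,
    gaussian_sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
    roi: ROI | None = None,
) -> SSIMResult:
    """Structural similarity between two equally shaped maps over an ROI.

    Standard luminance/contrast/structure SSIM with a Gaussian window; the
    global score is the mean of the local map over the ROI.  The dynamic
    range is taken from the data (max over both maps), matching common
    built-in implementations.
    """
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    roi = roi or a.roi or a.full_roi()
    if not roi.fits(a.shape):
        raise ValueError("ROI exceeds map bounds")
    pa = a.pixels[roi.slices]
    pb = b.pixels[roi.slices]
    if min(pa.shape) < window_size:
        raise ValueError("SSIM window larger than ROI")
    data_range = float(max(pa.max(), pb.max()) - min(pa.min(), pb.min()))
    if data_range == 0:
        # identical constant images: similarity is exact by definition
        local = np.ones_like(pa) if np.array_equal(pa, pb) else np.zeros_like(pa)
        return SSIMResult(float(local.mean()), local, window_size, k1, k2, roi)
    score, local = structural_similarity(
        pa, pb, win_size=window_size, gaussian_weights=True,
        sigma=gaussian_sigma, K1=k1, K2=k2, data_range=data_range,
        use_sample_covariance=False, full=True,
    )
    return SSIMResult(float(score), local, window_size, k1, k2, roi)
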