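"""Vessel segmentation: maximum-entropy thresholding combined with white top-hat.

The vascular mask is extracted in two complementary passes and united:

* a Kapur maximum-entropy threshold ``t*`` on the gray-level histogram picks
  up the main, high-attenuation vessels — ``t*`` maximizes the sum of the
  Shannon entropies of the below- and above-threshold gray-level
  distributions, ``H_b(t) + H_w(t)``;
* a white top-hat (image minus its grayscale opening) responds to bright
  structures smaller than the structuring element — the minor vessels missed
  by the global threshold — and is binarized with its own max-entropy
  threshold by default.

Histograms use 256 equal-width bins over the observed intensity range (8-bit
semantics, also for 16-bit data, matching the common ImageJ/Fiji behaviour).
Entropies use the natural logarithm; the argmax is base-invariant but the
criterion-curve values are reported in nats.  Ties are broken toward the
smallest threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume import Volume3D

__all__ = [
    "Histogram",
    "ThresholdResult",
    "StructuringElement",
    "SegmentationResult",
    "remove_background",
    "volume_histogram",
    "max_entropy_threshold",
    "white_top_hat",
    "segment_vessels",
]

logger = logging.getLogger(__name__)

N_BINS = 256


@dataclass
class Histogram:
    """Gray-level counts over equal-width bins spanning [lo, hi]."""

    counts: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")
        self.bin_edges = np.asarray(self.bin_edges, float)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have len(counts)+1 entries")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ThresholdResult:
    """Kapur threshold: chosen bin index, gray-level value, criterion curve."""

    t_star: int               # bin index: foreground is bins > t_star
    threshold_value: float    # gray level (upper edge of bin t_star)
    criterion_curve: np.ndarray  # H_b(t)+H_w(t) per candidate t; NaN where invalid


@dataclass
class StructuringElement:
    """Ellipsoidal (ball) structuring element with per-axis radii in voxels."""

    radius_vx: tuple[int, int, int] = (2, 2, 2)
    shape: str = "ball"

    def __post_init__(self) -> None:
        r = np.atleast_1d(np.asarray(self.radius_vx, int))
        if r.size == 1:
            r = np.repeat(r, 3)
        if r.size != 3 or np.any(r < 1):
            raise ValueError("structuring element radius must be >= 1 voxel per axis")
        self.radius_vx = tuple(int(v) for v in r)
        if self.shape not in ("ball", "ellipsoid"):
            raise ValueError(f"unknown structuring element shape {self.shape!r}")

    def footprint(self) -> np.ndarray:
        rz, ry, rx = self.radius_vx
        zz, yy, xx = np.mgrid[-rz:rz + 1, -ry:ry + 1, -rx:rx + 1]
        return (zz / rz) ** 2 + (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0

    @classmethod
    def isotropic_for(cls, radius_um: float, voxel_size_um) -> "StructuringElement":
        """Ball of a physical radius expressed in (possibly anisotropic) voxels."""
        r = tuple(max(1, int(round(radius_um / v))) for v in voxel_size_um)
        return cls(radius_vx=r)


@dataclass
class SegmentationResult:
    entropy_mask: np.ndarray
    tophat_mask: np.ndarray
    combined_mask: np.ndarray
    t_star: float
    tophat_threshold: float
    entropy_result: ThresholdResult | None = None
    tophat_result: ThresholdResult | None = None


# ---------------------------------------------------------------------------
# operations


def remove_background(volume: Volume3D, tissue_mask: np.ndarray | None = None) -> Volume3D:
    """Set everything outside the tissue mask to the volume minimum.

    With no mask the volume is returned unchanged (a notice is logged):
    background removal is then assumed to have happened upstream.
    """
    if tissue_mask is None:
        logger.info("remove_background: no tissue mask given; volume left unchanged")
        return volume.copy()
    tissue_mask = np.asarray(tissue_mask, bool)
    if not volume.same_lattice(tissue_mask):
        raise ValueError(
            f"tissue mask shape {tissue_mask.shape} does not match volume {volume.shape}"
        )
    out = volume.data.astype(np.float64, copy=True)
    out[~tissue_mask] = volume.data.min()
    return Volume3D(out, volume.voxel_size_um)


def volume_histogram(volume: Volume3D, mask: np.ndarray | None = None,
                     n_bins: int = N_BINS) -> Histogram:
    """256-bin histogram over the observed min-max range, optionally within a mask."""
    data = volume.data[mask] if mask is not None else volume.data.ravel()
    if data.size == 0:
        raise ValueError("no voxels to histogram")
    lo, hi = float(np.min(data)), float(np.max(data))
    if hi == lo:
        hi = lo + 1.0  # single-valued volume: everything lands in bin 0
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    return Histogram(counts, edges)


def max_entropy_threshold(hist: Histogram) -> ThresholdResult:
    """Kapur's maximum-entropy threshold.

    For each candidate bin ``t`` the gray levels are split into a background
    class (bins ``<= t``) and a foreground class (bins ``> t``); the class
    entropies are

        H_b(t) = -sum_{i<=t} (p_i/P_b) ln(p_i/P_b),
        H_w(t) = -sum_{i>t}  (p_i/P_w) ln(p_i/P_w),

    with ``P_b = sum_{i<=t} p_i`` and ``P_w = 1 - P_b`` (empty bins contribute
    zero).  The returned threshold maximizes ``H_b + H_w`` over candidates
    where both classes are non-empty; ties go to the smallest ``t``.
    """
    counts = hist.counts
    total = hist.total
    if total <= 0:
        raise ValueError("empty histogram")
    if np.count_nonzero(counts) < 2:
        raise ValueError("no threshold separates one gray level")

    p = counts / total
    plogp = np.where(p > 0, p * np.log(p, where=p > 0, out=np.zeros_like(p)), 0.0)
    P_b = np.cumsum(p)
    S_b = np.cumsum(plogp)                      # sum_{i<=t} p ln p
    # tail sums by reversed cumulation: subtracting from the grand total
    # cancels catastrophically when the tail class is nearly empty
    P_w = np.cumsum(p[::-1])[::-1]              # sum_{i>=t}
    S_w = np.cumsum(plogp[::-1])[::-1]

    n = len(counts)
    crit = np.full(n - 1, np.nan)    # candidates t = 0 .. n-2
    pb = P_b[:-1]
    pw = P_w[1:]                     # class probability of bins > t
    sw = S_w[1:]
    valid = (pb > 0) & (pw > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_b = np.log(pb) - S_b[:-1] / pb
        h_w = np.log(pw) - sw / pw
    crit[valid] = (h_b + h_w)[valid]

    if not valid.any():
        raise ValueError("no threshold separates one gray level")
    best = float(np.nanmax(crit))
    # ties (within float jitter of the analytically equal criterion) -> smallest t
    with np.errstate(invalid="ignore"):
        t_star = int(np.flatnonzero(crit >= best - 1e-10)[0])
    return ThresholdResult(
        t_star=t_star,
        threshold_value=float(hist.bin_edges[t_star + 1]),
        criterion_curve=crit,
    )


def white_top_hat(volume: Volume3D, se: StructuringElement) -> Volume3D:
    """White top-hat: f minus its grayscale opening with the given element.

    Non-negative everywhere; large structures (bigger than the element) are
    suppressed while small bright details are kept.
    """
    fp = se.footprint()
    if any(f > s for f, s in zip(fp.shape, volume.shape)):
        raise ValueError(
            f"structuring element {fp.shape} larger than volume {volume.shape}"
        )
    data = volume.data.astype(np.float64)
    out = ndi.white_tophat(data, footprint=fp)
    return Volume3D(out, volume.voxel_size_um)


def segment_vessels(
    volume: Volume3D,
    se: StructuringElement | None = None,
    tophat_threshold_rule: str | float = "max_entropy",
    tissue_mask: np.ndarray | None = None,
) -> SegmentationResult:
    """Two-pass vessel segmentation: max-entropy threshold OR'd with top-hat.

    The volume is expected to be background-removed.  If ``tissue_mask`` is
    given, both histograms are computed over tissue voxels only, so that the
    flattened exterior does not dominate the gray-level statistics; the
    resulting masks are also clipped to the tissue.

    ``tophat_threshold_rule`` is either ``"max_entropy"`` (threshold the
    top-hat response with its own Kapur threshold) or a fixed numeric value.
    """
    if se is None:
        se = StructuringElement()

    hist = volume_histogram(volume, mask=tissue_mask)
    entropy_res = max_entropy_threshold(hist)
    entropy_mask = volume.data > entropy_res.threshold_value

    tophat = white_top_hat(volume, se)
    if isinstance(tophat_threshold_rule, str):
        if tophat_threshold_rule != "max_entropy":
            raise ValueError(f"unknown top-hat threshold rule {tophat_threshold_rule!r}")
        th_hist = volume_histogram(tophat, mask=tissue_mask)
        th_res = max_entropy_threshold(th_hist)
        th_value = th_res.threshold_value
    else:
        th_res = None
        th_value = float(tophat_threshold_rule)
    tophat_mask = tophat.data > th_value

    if tissue_mask is not None:
        tissue_mask = np.asarray(tissue_mask, bool)
        entropy_mask &= tissue_mask
        tophat_mask &= tissue_mask

    return SegmentationResult(
        entropy_mask=entropy_mask,
        tophat_mask=tophat_mask,
        combined_mask=entropy_mask | tophat_mask,
        t_star=entropy_res.threshold_value,
        tophat_threshold=th_value,
        entropy_result=entropy_res,
        tophat_result=th_res,
    )
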