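"""Otsu segmentation of Young's-modulus maps into glial and axon classes.

The modulus image of the optic-nerve-head glial plate is bimodal: a stiffer
glial (astrocytic) matrix and softer axon bundles. Segmentation quantizes the
valid pixels into a fixed number of levels between robust percentiles,
computes the histogram, and applies Otsu's criterion — the threshold
maximizing the between-class variance

    sigma_b^2(t) = omega_0(t) * omega_1(t) * (mu_0(t) - mu_1(t))^2

by exhaustive search over all levels (ties resolved toward the lowest level;
the argmax comparison is carried out in exact integer arithmetic on the
histogram counts, so the result never depends on floating-point rounding).
Pixels above the threshold are labeled glial, pixels at or below it axon;
because quantization is monotone in modulus, the glial class is always the
stiffer phase, matching its anatomical definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curve_processing import ModulusMap

__all__ = [
    "ModulusHistogram",
    "SegmentationResult",
    "DegenerateMapError",
    "LABEL_AXON",
    "LABEL_GLIAL",
    "LABEL_INVALID",
    "quantize_map",
    "otsu_threshold",
    "segment_map",
    "extract_class_values",
]

LABEL_AXON = 0
LABEL_GLIAL = 1
LABEL_INVALID = -1


class DegenerateMapError(RuntimeError):
    pass


@dataclass
class ModulusHistogram:
    """Histogram of quantized modulus levels plus the level -> Pa mapping."""

    counts: np.ndarray  # integer counts per level
    lo_pa: float  # lower edge of level 0
    hi_pa: float  # upper edge of the last level
    log_scale: bool = False

    @property
    def n_levels(self) -> int:
        return int(self.counts.size)

    def level_upper_edge_pa(self, level: int) -> float:
        """Physical value of the upper edge of ``level``."""
        frac = (level + 1) / self.n_levels
        if self.log_scale:
            return float(np.exp(np.log(self.lo_pa) + frac * (np.log(self.hi_pa) - np.log(self.lo_pa))))
        return float(self.lo_pa + frac * (self.hi_pa - self.lo_pa))


def quantize_map(
    mmap: ModulusMap,
    n_levels: int = 256,
    lo_percentile: float = 1.0,
    hi_percentile: float = 99.0,
    log_scale: bool = False,
) -> ModulusHistogram:
    """Linearly bin the valid pixels into ``n_levels`` quantization levels.

    Bin edges span the lo/hi percentiles of the valid pixels (outliers are
    clipped into the end bins); with ``log_scale`` binning is uniform in
    log-modulus instead. The returned counts sum to the number of valid
    pixels.
    """
    vals = mmap.values_pa[mmap.valid_mask]
    if np.unique(vals).size < 2:
        raise DegenerateMapError("degenerate_map: fewer than 2 distinct valid values")
    x = np.log(vals) if log_scale else vals
    lo, hi = np.percentile(x, [lo_percentile, hi_percentile])
    if not hi > lo:
        raise DegenerateMapError("degenerate_map: percentile range collapsed")
    levels = _levels_of(x, lo, hi, n_levels)
    counts = np.bincount(levels, minlength=n_levels)
    return ModulusHistogram(
        counts=counts,
        lo_pa=float(np.exp(lo)) if log_scale else float(lo),
        hi_pa=float(np.exp(hi)) if log_scale else float(hi),
        log_scale=log_scale,
    )


def _levels_of(x: np.ndarray, lo: float, hi: float, n_levels: int) -> np.ndarray:
    idx = np.floor((x - lo) / (hi - lo) * n_levels).astype(int)
    return np.clip(idx, 0, n_levels - 1)


def otsu_threshold(counts: np.ndarray) -> tuple[int, float]:
    """Otsu's threshold over a level histogram.

    Returns ``(level, between_class_variance)`` where levels ``<= level``
    form the lower class. The scan is exhaustive; the maximizer comparison
    uses exact integer arithmetic (sigma_b^2 = (m0*N - mT*w0)^2 / (N^2*w0*w1)
    with integer numerators), and ties pick the lowest level.
    """
    counts = np.asarray(counts)
    if np.count_nonzero(counts) < 2:
        raise DegenerateMapError("degenerate_histogram: fewer than 2 occupied bins")
    c = [int(v) for v in counts]
    n_levels = len(c)
    total = sum(c)
    m_total = sum(i * v for i, v in enumerate(c))

    best_t = -1
    best_num = -1  # (m0*N - mT*w0)^2, exact int
    best_den = 1  # w0*w1, exact int
    w0 = 0
    m0 = 0
    for t in range(n_levels - 1):
        w0 += c[t]
        m0 += t * c[t]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (m0 * total - m_total * w0) ** 2
        den = w0 * w1
        # strict > keeps the lowest maximizing level
        if num * best_den > best_num * den:
            best_num, best_den, best_t = num, den, t
    if best_t < 0:
        raise DegenerateMapError("degenerate_histogram: no admissible split")
    sigma_b2 = best_num / (best_den * total * total)
    return best_t, float(sigma_b2)


@dataclass
class SegmentationResult:
    """Two-class segmentation of a modulus map."""

    threshold_pa: float
    class_mask: np.ndarray  # LABEL_AXON / LABEL_GLIAL / LABEL_INVALID
    between_class_variance: float  # in quantized-level units
    quantization: tuple[int, float, float]  # (n_levels, lo_pa, hi_pa)

    def class_pixels(self, label: int) -> np.ndarray:
        return self.class_mask == label


def segment_map(
    mmap: ModulusMap,
    n_levels: int = 256,
    lo_percentile: float = 1.0,
    hi_percentile: float = 99.0,
    log_scale: bool = False,
) -> SegmentationResult:
    """Otsu-segment a modulus map into glial (stiff) and axon (soft) classes.

    Valid pixels with quantization level above the Otsu level become glial,
    the rest axon; invalid pixels stay invalid. Because quantization is
    monotone in value, the glial class always has the higher mean modulus.
    """
    hist = quantize_map(mmap, n_levels, lo_percentile, hi_percentile, log_scale)
    level, sigma_b2 = otsu_threshold(hist.counts)
    threshold_pa = hist.level_upper_edge_pa(level)

    x = np.log(mmap.values_pa, out=np.full(mmap.shape, np.nan), where=mmap.valid_mask) if log_scale else mmap.values_pa
    lo = np.log(hist.lo_pa) if log_scale else hist.lo_pa
    hi = np.log(hist.hi_pa) if log_scale else hist.hi_pa
    mask = np.full(mmap.shape, LABEL_INVALID, dtype=np.int8)
    valid = mmap.valid_mask
    levels = _levels_of(np.where(valid, x, lo), lo, hi, hist.n_levels)
    mask[valid] = np.where(levels[valid] > level, LABEL_GLIAL, LABEL_AXON)

    return SegmentationResult(
        threshold_pa=threshold_pa,
        class_mask=mask,
        between_class_variance=sigma_b2,
        quantization=(hist.n_levels, hist.lo_pa, hist.hi_pa),
    )


def extract_class_values(
    mmap: ModulusMap, seg: SegmentationResult, tissue_class: str
) -> np.ndarray:
    """All valid moduli (Pa) of one class, in row-major pixel order."""
    if tissue_class not in {"glial", "axon"}:
        raise ValueError("tissue_class must be 'glial' or 'axon'")
    label = LABEL_GLIAL if tissue_class == "glial" else LABEL_AXON
    sel = (seg.class_mask == label) & mmap.valid_mask
    vals = mmap.values_pa[sel]
    if vals.size == 0:
        raise DegenerateMapError(f"empty_class: no valid {tissue_class} pixels")
    return vals
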