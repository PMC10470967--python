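"""Edge-preserving denoising and contrast enhancement operators.

These four operators build the enhanced training detail image of the
super-resolution pipeline: a bilateral filter (denoise while keeping edges),
brightness-preserving dynamic histogram equalization (restore contrast lost
to smoothing), singular value equalization (global contrast normalization
toward a uniform-histogram reference) and a guided filter (transfer structure
from an unfiltered guide while suppressing its noise).

All operators work on 2-D float images of arbitrary intensity scale and use
reflect padding at the borders.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import find_peaks

__all__ = ["bilateral_filter", "bpdhe", "sve", "guided_filter"]


def bilateral_filter(
    image: np.ndarray,
    sigma_spatial: float = 3.0,
    sigma_range: float | None = None,
) -> np.ndarray:
    """Bilateral filter: Gaussian weights in both space and intensity.

    ``w(q) = exp(-d(p,q)^2 / 2 s_s^2) * exp(-(I(p) - I(q))^2 / 2 s_r^2)``
    over a square window of radius ``ceil(3 s_s)``; the output is the
    weight-normalized mean, so it always stays inside the local intensity
    range and commutes exactly with adding a constant.  ``sigma_range``
    defaults to 10% of the image's intensity span.
    """
    image = np.asarray(image, dtype=float)
    if sigma_spatial <= 0:
        raise ValueError("sigma_spatial must be positive")
    if sigma_range is None:
        span = float(image.max() - image.min())
        sigma_range = 0.1 * span if span > 0 else 1.0
    if sigma_range <= 0:
        raise ValueError("sigma_range must be positive")
    radius = int(np.ceil(3.0 * sigma_spatial))
    # "symmetric" matches scipy.ndimage's reflect convention used elsewhere
    padded = np.pad(image, radius, mode="symmetric")
    num = np.zeros_like(image)
    den = np.zeros_like(image)
    h, w = image.shape
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            ws = np.exp(-(dx * dx + dy * dy) / (2.0 * sigma_spatial**2))
            shifted = padded[radius + dy : radius + dy + h, radius + dx : radius + dx + w]
            wr = np.exp(-((shifted - image) ** 2) / (2.0 * sigma_range**2))
            weight = ws * wr
            num += weight * shifted
            den += weight
    return num / den


def _histogram_partitions(smoothed: np.ndarray) -> list[tuple[int, int]]:
    """Split gray levels at the local minima between local maxima."""
    peaks, _ = find_peaks(smoothed)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(smoothed))])
    boundaries = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        boundaries.append(int(a + np.argmin(smoothed[a : b + 1])))
    boundaries.append(smoothed.size - 1)
    parts = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        if hi > lo or (lo, hi) == (0, smoothed.size - 1):
            parts.append((lo, hi))
    return parts


def bpdhe(image: np.ndarray, smoothing_window: int = 3) -> np.ndarray:
    """Brightness-preserving dynamic histogram equalization.

    The 256-level histogram is smoothed with a small Gaussian kernel
    (``smoothing_window`` bins wide, default 3), partitioned at the local
    minima between its peaks, and each partition is equalized into an output
    sub-range proportional to the partition's dynamic range.  The result is
    rescaled so the mean brightness matches the input exactly (up to range
    clipping).  A constant image is returned unchanged.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return image.copy()
    levels = np.rint((image - lo) / (hi - lo) * 255.0).astype(int)
    hist = np.bincount(levels.ravel(), minlength=256).astype(float)
    radius = max(smoothing_window // 2, 1)
    taps = np.exp(-0.5 * (np.arange(-radius, radius + 1) / (radius / 2.0)) ** 2)
    smoothed = np.convolve(hist, taps / taps.sum(), mode="same")

    parts = _histogram_partitions(smoothed)
    spans = np.array([p[1] - p[0] for p in parts], dtype=float)
    if spans.sum() <= 0:
        return image.copy()
    out_spans = spans / spans.sum() * 255.0

    lut = np.zeros(256)
    start = 0.0
    for (plo, phi), out_span in zip(parts, out_spans):
        seg = hist[plo : phi + 1]
        total = seg.sum()
        if total > 0:
            cdf = np.cumsum(seg) / total
        else:
            cdf = np.linspace(0.0, 1.0, seg.size)
        lut[plo : phi + 1] = start + out_span * cdf
        start += out_span
    # keep the mapping monotone across partition boundaries
    lut = np.maximum.accumulate(lut)

    out = lut[levels] / 255.0 * (hi - lo) + lo
    # mean-brightness restoration; iterate because range clipping after a
    # rescale can itself move the mean
    mean_in = image.mean()
    for _ in range(8):
        mean_out = out.mean()
        if mean_out == 0 or abs(mean_out - mean_in) < 1e-3:
            break
        out = np.clip(out * (mean_in / mean_out), lo, hi)
    return out


def sve(
    image: np.ndarray,
    intensity_range: tuple[float, float] = (0.0, 255.0),
    clip: bool = True,
) -> np.ndarray:
    """Singular value equalization.

    With ``U S V^T`` the SVD of the input and ``S_ref`` the singular values of
    a same-shape reference whose entries follow a uniform histogram over
    ``intensity_range``, the output is ``U (xi S) V^T`` with
    ``xi = max(S_ref) / max(S)``.  Because ``xi`` is a scalar this equals
    ``xi * image``; the reference is deterministic (inverse uniform CDF in
    raster order).  An all-zero image is returned unchanged.
    """
    image = np.asarray(image, dtype=float)
    smax = float(np.linalg.norm(image, ord=2)) if image.any() else 0.0
    if smax == 0.0:
        return image.copy()
    lo, hi = intensity_range
    ref = np.linspace(lo, hi, image.size).reshape(image.shape)
    ref_smax = float(np.linalg.norm(ref, ord=2))
    out = (ref_smax / smax) * image
    if clip:
        out = np.clip(out, lo, hi)
    return out


def guided_filter(
    guide: np.ndarray, image: np.ndarray, radius: int = 8, eps: float = 1e-4
) -> np.ndarray:
    """Guided filter: output is a local linear function of the guide.

    Per window w: ``a_w = cov(guide, image) / (var(guide) + eps)`` and
    ``b_w = mean(image) - a_w mean(guide)``; the output averages
    ``a_w guide + b_w`` over all windows containing each pixel.  ``eps`` is an
    absolute regularizer in squared guide-intensity units; windows are squares
    of side ``2 radius + 1`` with reflect padding.  Linear in ``image`` for a
    fixed guide.
    """
    guide = np.asarray(guide, dtype=float)
    image = np.asarray(image, dtype=float)
    if guide.shape != image.shape:
        raise ValueError("guide and input must have the same shape")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if eps < 0:
        raise ValueError("eps must be non-negative")
    size = 2 * radius + 1

    def box(x: np.ndarray) -> np.ndarray:
        return uniform_filter(x, size=size, mode="reflect")

    mean_i = box(guide)
    mean_p = box(image)
    cov_ip = box(guide * image) - mean_i * mean_p
    var_i = box(guide * guide) - mean_i * mean_i
    a = cov_ip / (var_i + eps) if eps > 0 else np.where(
        var_i > 0, cov_ip / np.where(var_i > 0, var_i, 1.0), 0.0
    )
    b = mean_p - a * mean_i
    return box(a) * guide + box(b)
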