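"""Image-quality measures: PSNR/MSE, Shannon entropy, average gradient.

Fidelity metrics (MSE, PSNR) compare a reconstruction with a reference on a
common intensity scale; the scale-free sharpness/information measures
(entropy, average gradient) are computed on a single image.  For float images
the 8-bit convention is recovered by affinely mapping the *reference's*
min/max to [0, 255] and applying the same affine to the test image, so
``MaxValue = 255`` retains its usual meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import to_display_range

__all__ = [
    "MetricsReport",
    "mse",
    "psnr",
    "image_entropy",
    "average_gradient",
    "metrics_report",
]


@dataclass
class MetricsReport:
    """PSNR/MSE of an image against its reference plus entropy and AG."""

    psnr: float
    mse: float
    entropy: float
    avg_gradient: float
    max_value: float = 255.0

    def as_dict(self) -> dict[str, float]:
        return {
            "psnr": self.psnr,
            "mse": self.mse,
            "entropy": self.entropy,
            "avg_gradient": self.avg_gradient,
            "max_value": self.max_value,
        }


def _check_same_shape(reference: np.ndarray, image: np.ndarray) -> None:
    if reference.shape != image.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs image {image.shape}"
        )


def mse(reference: np.ndarray, image: np.ndarray) -> float:
    """Mean squared pixel difference."""
    reference = np.asarray(reference, dtype=float)
    image = np.asarray(image, dtype=float)
    _check_same_shape(reference, image)
    return float(np.mean((reference - image) ** 2))


def psnr(reference: np.ndarray, image: np.ndarray, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(max_value^2 / MSE)`` in dB.

    Identical images give ``+inf``.
    """
    err = mse(reference, image)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_value**2 / err))


def image_entropy(image: np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy (bits) of the ``n_bins``-level gray histogram.

    The image is expected on the [0, 255] scale; values are clipped into
    range and ``0 * log 0`` is taken as 0.  Maximum is ``log2(n_bins)``.
    """
    image = np.clip(np.asarray(image, dtype=float), 0.0, 255.0)
    hist, _ = np.histogram(image, bins=n_bins, range=(0.0, 255.0))
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def average_gradient(image: np.ndarray) -> float:
    """Mean local gradient magnitude ``sqrt((dx^2 + dy^2) / 2)``.

    Forward differences on the interior (the last row/column, which have no
    forward neighbor, are excluded); scales linearly with image intensity.
    """
    image = np.asarray(image, dtype=float)
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("image side must be >= 2")
    dx = image[:-1, 1:] - image[:-1, :-1]
    dy = image[1:, :-1] - image[:-1, :-1]
    return float(np.mean(np.sqrt((dx**2 + dy**2) / 2.0)))


def metrics_report(
    reference: np.ndarray, image: np.ndarray, max_value: float = 255.0
) -> MetricsReport:
    """Full quality report for ``image`` against ``reference``.

    PSNR/MSE are computed after mapping both images to [0, 255] with the
    reference's min/max (so the reference spans the full scale); entropy and
    average gradient are single-image measures computed on the test image's
    own [0, 255] mapping, matching how they are reported for reconstructions
    without a reference.
    """
    reference = np.asarray(reference, dtype=float)
    image = np.asarray(image, dtype=float)
    _check_same_shape(reference, image)
    lo, hi = float(reference.min()), float(reference.max())
    ref8 = to_display_range(reference, lo, hi)
    img8 = to_display_range(image, lo, hi)
    own8 = to_display_range(image)
    return MetricsReport(
        psnr=psnr(ref8, img8, max_value=max_value),
        mse=mse(ref8, img8),
        entropy=image_entropy(own8),
        avg_gradient=average_gradient(own8),
        max_value=max_value,
    )
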