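"""Parallel-beam tomography: forward projection, FBP, SART, ring rebinning.

All operators share one discretization: the image lives on the ``[-1, 1]^2``
phantom frame and a projection value is the exact line integral of the
pixel-constant image along a ray, computed from Siddon-style ray/pixel
intersection lengths.  Because the forward projector and the SART system
matrix are the same object, algebraic consistency properties (fixed points,
residual decrease) hold exactly rather than only approximately.

Angles are in degrees with the convention ``r = x cos(theta) + y sin(theta)``;
radial samples are equispaced and symmetric about ``r = 0``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import interp1d
from scipy.ndimage import map_coordinates

from .phantoms import PhantomImage, phantom_grid

logger = logging.getLogger(__name__)

__all__ = [
    "Sinogram",
    "SartConfig",
    "RingAcquisition",
    "default_radial_offsets",
    "radon_forward",
    "ramp_filter_projections",
    "fbp_reconstruct",
    "sart_reconstruct",
    "add_projection_noise",
    "simulate_ring_acquisition",
    "amplitude_to_attenuation",
    "rearrange_ring_data",
    "ParallelGeometry",
]


@dataclass
class Sinogram:
    """Line-integral projection data ``g(theta, r)``.

    ``values`` has one row per projection angle; ``radial_offsets`` are the
    (equispaced, zero-symmetric) sample positions in phantom-frame units.
    """

    values: np.ndarray
    angles_deg: np.ndarray
    radial_offsets: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles_deg = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        self.radial_offsets = np.asarray(self.radial_offsets, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be a 2-D matrix")
        if self.values.shape[0] != self.angles_deg.size:
            raise ValueError("one row of values per angle is required")
        if self.values.shape[1] != self.radial_offsets.size:
            raise ValueError("one column of values per radial sample is required")

    @property
    def n_angles(self) -> int:
        return self.angles_deg.size

    @property
    def radial_spacing(self) -> float:
        if self.radial_offsets.size < 2:
            return 0.0
        return float(self.radial_offsets[1] - self.radial_offsets[0])


@dataclass
class SartConfig:
    """SART settings: relaxation ``0 < lam < 2`` and full-sweep count."""

    relaxation: float = 1.0
    iterations: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.relaxation < 2.0):
            raise ValueError("relaxation factor must lie in (0, 2)")
        if self.iterations < 1:
            raise ValueError("at least one iteration is required")


def default_radial_offsets(size: int, n_radial: int | None = None) -> np.ndarray:
    """Radial sample positions covering the grid diagonal.

    The default count is ``ceil(sqrt(2) * size)`` rounded up to odd so that a
    sample sits exactly at ``r = 0`` and the frame corners are covered; the
    spacing equals one pixel width.
    """
    if n_radial is None:
        n_radial = math.ceil(math.sqrt(2.0) * size)
        if n_radial % 2 == 0:
            n_radial += 1
    if n_radial < 2:
        raise ValueError("need at least two radial samples")
    dr = 2.0 / size
    return (np.arange(n_radial) - (n_radial - 1) / 2.0) * dr


def _siddon_matrix(size: int, theta_deg: float, offsets: np.ndarray) -> sp.csr_matrix:
    """Exact ray/pixel intersection lengths for one parallel view.

    Rays are ``p(t) = r * n + t * d`` with normal ``n = (cos, sin)`` and
    direction ``d = (-sin, cos)``.  Segment lengths come from sorting the ray's
    crossings with all grid lines (clipped to the frame box), the midpoint of
    each segment identifying its pixel.
    """
    h = 2.0 / size
    th = math.radians(theta_deg)
    ct, st = math.cos(th), math.sin(th)
    r = np.asarray(offsets, dtype=float)
    nrays = r.size
    x0, y0 = r * ct, r * st
    dx, dy = -st, ct

    def slab(p0: np.ndarray, d: float) -> tuple[np.ndarray, np.ndarray]:
        if abs(d) > 1e-12:
            ta = (-1.0 - p0) / d
            tb = (1.0 - p0) / d
            return np.minimum(ta, tb), np.maximum(ta, tb)
        inside = np.abs(p0) <= 1.0
        lo = np.where(inside, -np.inf, np.inf)
        hi = np.where(inside, np.inf, -np.inf)
        return lo, hi

    lox, hix = slab(x0, dx)
    loy, hiy = slab(y0, dy)
    t_in = np.maximum(lox, loy)
    t_out = np.minimum(hix, hiy)
    hit = t_out > t_in
    t_in = np.where(hit, t_in, 0.0)
    t_out = np.where(hit, t_out, 0.0)

    lines = -1.0 + h * np.arange(size + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tx = (
            (lines[None, :] - x0[:, None]) / dx
            if abs(dx) > 1e-12
            else np.full((nrays, size + 1), np.inf)
        )
        ty = (
            (lines[None, :] - y0[:, None]) / dy
            if abs(dy) > 1e-12
            else np.full((nrays, size + 1), np.inf)
        )
    ts = np.concatenate([tx, ty, t_in[:, None], t_out[:, None]], axis=1)
    ts = np.clip(ts, t_in[:, None], t_out[:, None])
    ts.sort(axis=1)

    lengths = np.diff(ts, axis=1)
    tm = 0.5 * (ts[:, :-1] + ts[:, 1:])
    xm = x0[:, None] + tm * dx
    ym = y0[:, None] + tm * dy
    ix = np.clip(np.floor((xm + 1.0) / h).astype(np.int64), 0, size - 1)
    iy = np.clip(np.floor((1.0 - ym) / h).astype(np.int64), 0, size - 1)

    valid = lengths > 1e-12
    rows = np.repeat(np.arange(nrays), valid.sum(axis=1))
    cols = (iy * size + ix)[valid]
    data = lengths[valid]
    return sp.csr_matrix((data, (rows, cols)), shape=(nrays, size * size))


class ParallelGeometry:
    """Per-angle Siddon system matrices for a fixed grid/angle/offset layout."""

    def __init__(self, size: int, angles_deg: Sequence[float], offsets: np.ndarray):
        self.size = int(size)
        self.angles_deg = np.atleast_1d(np.asarray(angles_deg, dtype=float))
        self.offsets = np.asarray(offsets, dtype=float)
        if self.angles_deg.size == 0:
            raise ValueError("at least one projection angle is required")
        self.matrices = [
            _siddon_matrix(self.size, th, self.offsets) for th in self.angles_deg
        ]
        # Cached per-pixel view weights used by the SART update.
        self.col_sum = [np.asarray(A.sum(axis=0)).ravel() for A in self.matrices]

    def forward(self, pixels: np.ndarray) -> np.ndarray:
        f = pixels.ravel()
        return np.stack([A @ f for A in self.matrices])


_GEOMETRY_CACHE: dict[tuple, ParallelGeometry] = {}


def _geometry(size: int, angles_deg: np.ndarray, offsets: np.ndarray) -> ParallelGeometry:
    key = (int(size), angles_deg.tobytes(), offsets.tobytes())
    geo = _GEOMETRY_CACHE.get(key)
    if geo is None:
        geo = ParallelGeometry(size, angles_deg, offsets)
        if len(_GEOMETRY_CACHE) >= 8:  # keep the cache small; matrices are large
            _GEOMETRY_CACHE.pop(next(iter(_GEOMETRY_CACHE)))
        _GEOMETRY_CACHE[key] = geo
    return geo


def radon_forward(
    image: PhantomImage | np.ndarray,
    angles_deg: Sequence[float],
    n_radial: int | None = None,
    oversample: int = 4,
) -> Sinogram:
    """Discrete Radon transform: exact line integrals of the pixel raster.

    Linear in the image and mass-preserving: ``sum_r g(theta, r) * dr``
    approximates the image integral identically for every angle.

    ``oversample`` models a finite detector: each radial sample averages that
    many equispaced sub-rays across the detector width, which suppresses the
    stair-step aliasing a single exact ray picks up from pixelized edges
    (set 1 for pure single-ray integrals, e.g. to match the SART system
    model exactly).
    """
    pixels = image.pixels if isinstance(image, PhantomImage) else np.asarray(image, float)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError("image must be a square 2-D array")
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if angles.size == 0:
        raise ValueError("at least one projection angle is required")
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    size = pixels.shape[0]
    offsets = default_radial_offsets(size, n_radial)
    if oversample == 1:
        geo = _geometry(size, angles, offsets)
        return Sinogram(geo.forward(pixels), angles, offsets)
    dr = offsets[1] - offsets[0]
    shifts = ((np.arange(oversample) + 0.5) / oversample - 0.5) * dr
    sub = (offsets[:, None] + shifts[None, :]).ravel()
    f = pixels.ravel()
    rows = []
    for th in angles:  # per-angle build; sub-ray matrices are too big to cache
        A = _siddon_matrix(size, th, sub)
        rows.append((A @ f).reshape(-1, oversample).mean(axis=1))
    return Sinogram(np.stack(rows), angles, offsets)


def add_projection_noise(
    sino: Sinogram, noise_frac: float, rng: np.random.Generator | int | None = None
) -> Sinogram:
    """Additive Gaussian noise with sigma = ``noise_frac`` * max projection."""
    rng = np.random.default_rng(rng)
    sigma = noise_frac * float(np.abs(sino.values).max())
    noisy = sino.values + rng.normal(0.0, sigma, sino.values.shape) if sigma > 0 else sino.values.copy()
    return Sinogram(noisy, sino.angles_deg.copy(), sino.radial_offsets.copy())


_WINDOWS = ("ramp", "hann")


def ramp_filter_projections(sino: Sinogram, window: str = "ramp") -> Sinogram:
    """Filter each projection row with the |omega| ramp in the frequency domain.

    Rows are zero-padded to a power of two >= 2N before the FFT so the circular
    product approximates linear convolution; ``window='hann'`` apodizes the
    ramp to trade resolution for noise.  The DC component is annihilated by
    |omega| itself.
    """
    if window not in _WINDOWS:
        raise ValueError(f"unknown filter window {window!r}; choose from {_WINDOWS}")
    if sino.values.size == 0:
        raise ValueError("empty sinogram")
    n = sino.values.shape[1]
    dr = sino.radial_spacing if sino.radial_spacing > 0 else 1.0
    pad = 1 << max(6, int(math.ceil(math.log2(2 * n))))
    freqs = np.fft.fftfreq(pad, d=dr)
    filt = np.abs(freqs)
    if window == "hann":
        fmax = np.abs(freqs).max()
        filt = filt * 0.5 * (1.0 + np.cos(np.pi * freqs / fmax))
    spec = np.fft.fft(sino.values, n=pad, axis=1)
    filtered = np.real(np.fft.ifft(spec * filt[None, :], axis=1))[:, :n]
    return Sinogram(filtered, sino.angles_deg.copy(), sino.radial_offsets.copy())


def fbp_reconstruct(sino: Sinogram, size: int, window: str = "ramp") -> PhantomImage:
    """Filtered back projection onto a ``size x size`` grid.

    Back-projects the ramp-filtered rows with linear interpolation at
    ``r = x cos(theta) + y sin(theta)`` and scales by ``pi / n_angles`` (the
    Riemann weight of the angular integral over ``[0, pi)``).
    """
    if sino.n_angles < 2:
        raise ValueError("FBP needs at least two projection angles")
    if size < 2:
        raise ValueError("image size must be >= 2")
    span = float(np.abs(sino.radial_offsets).max())
    if span < 0.5:
        raise ValueError(
            "sinogram radial extent does not cover the image frame"
        )
    filtered = ramp_filter_projections(sino, window=window)
    X, Y = phantom_grid(size)
    recon = np.zeros(size * size)
    xf, yf = X.ravel(), Y.ravel()
    for row, th in zip(filtered.values, np.deg2rad(filtered.angles_deg)):
        t = xf * math.cos(th) + yf * math.sin(th)
        recon += np.interp(t, filtered.radial_offsets, row, left=0.0, right=0.0)
    recon *= math.pi / sino.n_angles
    return PhantomImage(recon.reshape(size, size))


def sart_reconstruct(
    sino: Sinogram,
    cfg: SartConfig,
    size: int,
    system: ParallelGeometry | None = None,
    initial: np.ndarray | None = None,
    return_info: bool = False,
):
    """Simultaneous algebraic reconstruction technique (Andersen-Kak form).

    One update processes all rays of a single projection angle: for pixel j,
    ``f_j += lam * sum_i [a_ij (p_i - (A f)_i) / sum_j a_ij] / sum_i a_ij``
    where ``a_ij`` are exact ray/pixel intersection lengths, the inner
    normalizer is the ray's total intersection length and the outer one the
    pixel's total weight in the view.  Angles are swept sequentially; one
    iteration is a full sweep.  Rays whose row of ``a`` is identically zero
    are skipped.
    """
    geo = system if system is not None else _geometry(
        size, sino.angles_deg, sino.radial_offsets
    )
    if geo.size != size:
        raise ValueError("system geometry does not match the requested size")
    f = (
        np.zeros(size * size)
        if initial is None
        else np.asarray(initial, dtype=float).ravel().copy()
    )
    lam = cfg.relaxation
    residuals = []
    warned = False
    row_sums = [np.asarray(A.sum(axis=1)).ravel() for A in geo.matrices]
    for _ in range(cfg.iterations):
        for A, p, rsum, csum in zip(
            geo.matrices, sino.values, row_sums, geo.col_sum
        ):
            good = rsum > 0
            if not good.all() and not warned:
                logger.warning("skipping %d rays that miss the grid", (~good).sum())
                warned = True
            if not good.any():
                continue
            resid = p - A @ f
            w = np.where(good, resid / np.where(good, rsum, 1.0), 0.0)
            numer = A.T @ w
            cmask = csum > 0
            f[cmask] += lam * numer[cmask] / csum[cmask]
        if return_info:
            residuals.append(
                float(np.linalg.norm(geo.forward(f.reshape(size, size)) - sino.values))
            )
    img = PhantomImage(f.reshape(size, size))
    if return_info:
        return img, {"residual_norms": residuals}
    return img


# ---------------------------------------------------------------------------
# Ring-array acquisition and common-midpoint rebinning
# ---------------------------------------------------------------------------


@dataclass
class RingAcquisition:
    """Pairwise ring-array data: entry (i, j) is transmitter i / receiver j.

    ``amplitudes`` holds peak received pressure amplitudes (or, after
    log-conversion, path-integrated attenuation).  The diagonal (self pairs)
    carries no information; with N transducers there are N(N-1)/2 independent
    pairs.  Transducer k sits at angle ``2 pi k / N`` on a circle of
    ``ring_radius`` in the phantom frame.
    """

    amplitudes: np.ndarray
    ring_radius: float = 0.95

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 2 or self.amplitudes.shape[0] != self.amplitudes.shape[1]:
            raise ValueError("acquisition matrix must be square (N x N)")
        if self.amplitudes.shape[0] % 2 != 0:
            raise ValueError("the number of transducers must be even")

    @property
    def n_transducers(self) -> int:
        return self.amplitudes.shape[0]

    def transducer_positions(self) -> np.ndarray:
        ang = 2.0 * np.pi * np.arange(self.n_transducers) / self.n_transducers
        return self.ring_radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def simulate_ring_acquisition(
    phantom: PhantomImage,
    n_transducers: int = 256,
    ring_radius: float = 0.95,
    source_amplitude: float = 1.0,
    n_samples: int = 512,
    noise_frac: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> RingAcquisition:
    """Synthesize peak-amplitude ring data with a Beer-Lambert chord model.

    The received amplitude for pair (i, j) is
    ``A0 / max(len, h) * exp(-integral of attenuation along the chord)``:
    cylindrical geometric spreading times exponential attenuation.  Path
    integrals use dense bilinear sampling of the phantom raster (``n_samples``
    points per chord), an integrator deliberately different from the Siddon
    projector so the two can cross-validate.  Optional multiplicative Gaussian
    noise models amplitude measurement error.
    """
    if n_transducers % 2 != 0:
        raise ValueError("the number of transducers must be even")
    pos = ring_radius * np.stack(
        [
            np.cos(2 * np.pi * np.arange(n_transducers) / n_transducers),
            np.sin(2 * np.pi * np.arange(n_transducers) / n_transducers),
        ],
        axis=1,
    )
    size = phantom.size
    h = 2.0 / size
    ii, jj = np.triu_indices(n_transducers, k=1)
    p0, p1 = pos[ii], pos[jj]
    lengths = np.linalg.norm(p1 - p0, axis=1)
    ts = (np.arange(n_samples) + 0.5) / n_samples
    # (n_pairs, n_samples, 2) sample points along every chord
    pts = p0[:, None, :] + ts[None, :, None] * (p1 - p0)[:, None, :]
    rows = (1.0 - pts[..., 1]) / h - 0.5
    cols = (pts[..., 0] + 1.0) / h - 0.5
    vals = map_coordinates(
        phantom.pixels, [rows.ravel(), cols.ravel()], order=1, mode="constant"
    ).reshape(rows.shape)
    integrals = vals.mean(axis=1) * lengths
    amp = source_amplitude / np.maximum(lengths, h) * np.exp(-integrals)
    if noise_frac > 0:
        rng = np.random.default_rng(rng)
        amp = amp * (1.0 + noise_frac * rng.standard_normal(amp.shape))
    A = np.zeros((n_transducers, n_transducers))
    A[ii, jj] = amp
    A[jj, ii] = amp
    return RingAcquisition(A, ring_radius=ring_radius)


def amplitude_to_attenuation(
    acq: RingAcquisition, reference: RingAcquisition
) -> RingAcquisition:
    """Log-ratio conversion ``-log(A / A_ref)`` to path-integrated attenuation.

    ``reference`` must be a water-only acquisition with identical geometry;
    the ratio cancels geometric spreading, leaving the line integral of the
    attenuation difference along each chord.  The (uninformative) diagonal is
    set to zero.
    """
    if acq.amplitudes.shape != reference.amplitudes.shape:
        raise ValueError("acquisition and reference must have the same shape")
    if acq.ring_radius != reference.ring_radius:
        raise ValueError("acquisition and reference geometries differ")
    off = ~np.eye(acq.n_transducers, dtype=bool)
    if np.any(reference.amplitudes[off] <= 0):
        raise ValueError("reference acquisition contains non-positive amplitudes")
    out = np.zeros_like(acq.amplitudes)
    with np.errstate(divide="ignore"):
        out[off] = -np.log(acq.amplitudes[off] / reference.amplitudes[off])
    return RingAcquisition(out, ring_radius=acq.ring_radius)


def rearrange_ring_data(
    acq: RingAcquisition, return_intermediate: bool = False
):
    """Rebin pairwise ring data into an (N/2) x (N/2) parallel-beam sinogram.

    Ordered pair (i, j) belongs to the common-midpoint view
    ``v = floor(((i + j) mod N) / 2)`` (the chord's perpendicular direction is
    ``pi (i + j) / N``), giving N/2 views of 2N samples each — for N = 256 an
    intermediate 128 x 512 matrix.  The signed ray offset is
    ``R cos(pi (i - j) / N)``, sign-flipped when the midpoint direction
    exceeds pi (i.e. when ``i + j >= N``), so that it equals the projection
    of either endpoint onto the view's normal direction.  Each view's
    irregular offsets are resampled with cubic interpolation onto N/2
    equispaced positions, yielding the final square sinogram (128 x 128 for
    N = 256).
    """
    n = acq.n_transducers
    m = n // 2
    R = acq.ring_radius
    i_idx, j_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    s = (i_idx + j_idx) % n
    view = s // 2
    parity = s % 2
    col = parity * n + i_idx  # 2N columns per view
    offset = R * np.cos(np.pi * (i_idx - j_idx) / n)
    flip = (i_idx + j_idx) >= n
    offset = np.where(flip, -offset, offset)

    intermediate = np.zeros((m, 2 * n))
    inter_offsets = np.zeros((m, 2 * n))
    inter_valid = np.zeros((m, 2 * n), dtype=bool)
    diag = i_idx == j_idx
    intermediate[view[~diag], col[~diag]] = acq.amplitudes[~diag]
    inter_offsets[view, col] = offset
    inter_valid[view[~diag], col[~diag]] = True

    targets = np.linspace(-R, R, m)
    values = np.zeros((m, m))
    for v in range(m):
        mask = inter_valid[v]
        x = inter_offsets[v][mask]
        y = intermediate[v][mask]
        order = np.argsort(x)
        x, y = x[order], y[order]
        # average duplicate offsets (reciprocal pairs measure the same chord)
        xq = np.round(x / (1e-9 * max(R, 1.0))).astype(np.int64)
        uniq, inv = np.unique(xq, return_inverse=True)
        xs = np.bincount(inv, weights=x) / np.bincount(inv)
        ys = np.bincount(inv, weights=y) / np.bincount(inv)
        if xs.size >= 4:
            f = interp1d(
                xs, ys, kind="cubic", bounds_error=False, fill_value=0.0, assume_sorted=True
            )
            values[v] = f(targets)
        else:
            values[v] = np.interp(targets, xs, ys, left=0.0, right=0.0)
    angles = 180.0 * (2.0 * np.arange(m) + 0.5) / n
    sino = Sinogram(values, angles, targets)
    if return_intermediate:
        return sino, intermediate
    return sino
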