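"""Sparse-coding super-resolution core.

The method learns a coupled pair of dictionaries from a single tomographic
training image: a low-resolution dictionary ``A_l`` over PCA-reduced
high-pass patch features of the interpolated LR image, and a high-resolution
dictionary ``A_h`` over patches of a *detail image* (HR minus interpolated
LR).  At test time an LR image is interpolated, its patch features are
sparse-coded on ``A_l`` with orthogonal matching pursuit, and ``A_h`` applied
to the codes synthesizes the missing detail, which is aggregated by overlap
averaging and added back.

The distinguishing step of this variant is the construction of the training
detail image: the (noisy) HR training image is bilateral-filtered and
contrast-restored with BPDHE before the detail subtraction, the detail is
singular-value equalized, and finally guided-filtered using the raw detail as
guide — so the HR dictionary learns denoised but structure-faithful detail.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.ndimage import correlate, gaussian_filter
from skimage.transform import resize
from sklearn.decomposition import PCA

from .enhancement import bilateral_filter, bpdhe, guided_filter, sve

logger = logging.getLogger(__name__)

__all__ = [
    "DegradationSpec",
    "PatchConfig",
    "EnhanceConfig",
    "DetailImages",
    "DictionaryPair",
    "SparseCode",
    "degrade",
    "upscale",
    "high_pass_filters",
    "extract_lr_features",
    "extract_patches",
    "extract_feature_patches",
    "aggregate_patches",
    "fit_pca_projection",
    "PcaProjection",
    "omp_batch",
    "omp_code",
    "ksvd_train",
    "solve_hr_dictionary",
    "build_mesr_detail_image",
    "mesr_train",
    "train_dictionary_variants",
    "sr_reconstruct",
]


# ---------------------------------------------------------------------------
# Degradation model: z_l = D V y_h + v, y_l = upscale(z_l)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegradationSpec:
    """Blur + integer decimation + additive Gaussian noise, and its inverse-scale
    interpolation rule.

    ``blur_sigma`` is the Gaussian low-pass width in pixels (0 disables),
    ``scale`` the integer decimation/upscaling factor, ``noise_sigma`` the
    standard deviation of the additive noise on the decimated image, and
    ``upscaler`` the interpolation order used to return to the original grid
    (``'bicubic'`` or ``'nearest'``/``'spline'`` aliases of orders 0/3).
    """

    scale: int = 2
    blur_sigma: float = 1.0
    noise_sigma: float = 0.0
    upscaler: str = "bicubic"

    def __post_init__(self) -> None:
        if self.scale < 1 or int(self.scale) != self.scale:
            raise ValueError("scale must be a positive integer")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


_UPSCALE_ORDERS = {"nearest": 0, "bilinear": 1, "bicubic": 3, "spline": 3}


def degrade(
    y_h: np.ndarray,
    spec: DegradationSpec = DegradationSpec(),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Apply the forward degradation: blur, downsample by ``scale``, add noise.

    Downsampling averages ``scale x scale`` blocks, which places the LR
    samples at half-integer HR positions — exactly the grid convention of the
    interpolating :func:`upscale`, so the degrade/upscale pair is free of the
    half-pixel shift plain decimation would introduce.  The image sides must
    be divisible by ``scale``; odd-sized images should be edge-padded by the
    caller first.
    """
    y_h = np.asarray(y_h, dtype=float)
    s = spec.scale
    if y_h.shape[0] % s or y_h.shape[1] % s:
        raise ValueError(f"image sides {y_h.shape} not divisible by scale {s}")
    blurred = gaussian_filter(y_h, spec.blur_sigma, mode="reflect") if spec.blur_sigma > 0 else y_h
    h, w = blurred.shape
    z = blurred.reshape(h // s, s, w // s, s).mean(axis=(1, 3))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(rng)
        z = z + rng.normal(0.0, spec.noise_sigma, z.shape)
    return z


def upscale(z_l: np.ndarray, spec: DegradationSpec = DegradationSpec()) -> np.ndarray:
    """Interpolate the decimated image back to the original grid size."""
    z_l = np.asarray(z_l, dtype=float)
    order = _UPSCALE_ORDERS.get(spec.upscaler)
    if order is None:
        raise ValueError(f"unknown upscaler {spec.upscaler!r}")
    shape = (z_l.shape[0] * spec.scale, z_l.shape[1] * spec.scale)
    return resize(
        z_l, shape, order=order, mode="edge", anti_aliasing=False, preserve_range=True
    )


# ---------------------------------------------------------------------------
# Patches and features
# ---------------------------------------------------------------------------


def high_pass_filters() -> list[np.ndarray]:
    """The four high-pass feature kernels: first derivatives and second
    derivatives (1-D Laplacians) along x and y."""
    d1 = np.array([[1.0, 0.0, -1.0]])
    d2 = np.array([[1.0, 0.0, -2.0, 0.0, 1.0]])
    return [d1, d1.T, d2, d2.T]


@dataclass(frozen=True)
class PatchConfig:
    """Patch geometry and training-sample policy.

    ``block_size`` is the square patch side on the HR grid, ``stride`` the
    sampling step, ``max_train_patches`` the cap on the (seeded, uniform)
    training subsample, and ``min_feature_variance`` the threshold below which
    a flat feature patch is excluded from training.
    """

    block_size: int = 9
    stride: int = 1
    max_train_patches: int = 30_000
    min_feature_variance: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_size < 3:
            raise ValueError("block_size must be >= 3")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def extract_lr_features(y_l: np.ndarray, filters: list[np.ndarray] | None = None) -> np.ndarray:
    """High-pass responses of the interpolated LR image, stacked as (4, H, W)."""
    y_l = np.asarray(y_l, dtype=float)
    filters = high_pass_filters() if filters is None else filters
    return np.stack([correlate(y_l, k, mode="reflect") for k in filters])


def _patch_grid(shape: tuple[int, int], block: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    if block > h or block > w:
        raise ValueError(f"block size {block} exceeds image shape {shape}")
    rows = np.arange(0, h - block + 1, stride)
    cols = np.arange(0, w - block + 1, stride)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return rr.ravel(), cc.ravel()


def extract_patches(
    image: np.ndarray, block_size: int = 9, stride: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized stride-spaced patches and their top-left locations.

    Returns ``(patches, locations)`` with ``patches`` of shape
    ``(n, block_size^2)`` and ``locations`` of shape ``(n, 2)`` (row, col).
    """
    image = np.asarray(image, dtype=float)
    rr, cc = _patch_grid(image.shape, block_size, stride)
    view = np.lib.stride_tricks.sliding_window_view(image, (block_size, block_size))
    patches = view[rr, cc].reshape(rr.size, -1)
    return patches, np.stack([rr, cc], axis=1)


def extract_feature_patches(
    feature_stack: np.ndarray, block_size: int = 9, stride: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Per-location concatenation of the 4 filtered-image patches -> (n, 4 b^2)."""
    parts = [extract_patches(f, block_size, stride) for f in feature_stack]
    patches = np.concatenate([p for p, _ in parts], axis=1)
    return patches, parts[0][1]


def aggregate_patches(
    patches: np.ndarray, locations: np.ndarray, shape: tuple[int, int], block_size: int
) -> np.ndarray:
    """Uniform overlap-averaging of patches back onto an image grid."""
    npix = shape[0] * shape[1]
    db, dc = np.meshgrid(np.arange(block_size), np.arange(block_size), indexing="ij")
    flat_off = (db * shape[1] + dc).ravel()
    base = locations[:, 0] * shape[1] + locations[:, 1]
    idx = (base[:, None] + flat_off[None, :]).ravel()
    acc = np.bincount(idx, weights=patches.ravel(), minlength=npix)
    cnt = np.bincount(idx, minlength=npix)
    out = np.zeros(npix)
    nz = cnt > 0
    out[nz] = acc[nz] / cnt[nz]
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# PCA projection
# ---------------------------------------------------------------------------


@dataclass
class PcaProjection:
    """Orthonormal linear projection fitted on training feature patches."""

    components: np.ndarray  # (d_reduced, D)
    mean: np.ndarray  # (D,)
    explained_variance_ratio: np.ndarray

    @property
    def dim(self) -> int:
        return self.components.shape[0]

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components.T

    def backproject(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, float) @ self.components + self.mean


def fit_pca_projection(
    feature_patches: np.ndarray, retained_variance: float = 0.999
) -> PcaProjection:
    """PCA keeping the smallest dimension reaching ``retained_variance``.

    ``retained_variance = 1.0`` keeps the full numerical rank.  Zero-variance
    input degenerates to the identity projection (with a warning).
    """
    X = np.asarray(feature_patches, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two feature patches")
    if not (0.0 < retained_variance <= 1.0):
        raise ValueError("retained_variance must lie in (0, 1]")
    if np.allclose(X.var(axis=0).sum(), 0.0):
        warnings.warn("zero-variance features: PCA degenerates to identity")
        d = X.shape[1]
        return PcaProjection(np.eye(d), np.zeros(d), np.ones(d) / d)
    n_comp = retained_variance if retained_variance < 1.0 else None
    pca = PCA(n_components=n_comp, svd_solver="full").fit(X)
    comps, evr = pca.components_, pca.explained_variance_ratio_
    if retained_variance >= 1.0:
        # full rank: drop numerically-null directions
        keep = pca.explained_variance_ > pca.explained_variance_[0] * 1e-12
        comps, evr = comps[keep], evr[keep]
    return PcaProjection(comps, pca.mean_, evr)


# ---------------------------------------------------------------------------
# Orthogonal matching pursuit (batch, fixed sparsity or residual tolerance)
# ---------------------------------------------------------------------------


@dataclass
class SparseCode:
    """One OMP coding result: coefficient vector, support and residual."""

    coefficients: np.ndarray
    support: np.ndarray
    residual_norm: float
    epsilon: float | None = None


def _omp_chunk(
    D: np.ndarray,
    G: np.ndarray,
    X: np.ndarray,
    sparsity: int,
    eps: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = X.shape[1]
    hT = X.T @ D  # (n, m); row-major layout keeps the per-step gathers cheap
    xx = np.einsum("ij,ij->j", X, X)
    S = np.full((n, sparsity), -1, dtype=np.int64)
    C = np.zeros((n, sparsity), dtype=hT.dtype)
    resid_sq = xx.copy()
    ai = np.arange(n)
    if eps is not None:
        ai = ai[resid_sq > eps**2]
    for t in range(sparsity):
        if ai.size == 0:
            break
        if t == 0:
            c = hT
        else:
            # residual correlations of the active signals: h - G_supp coef
            # (G is symmetric, so its rows serve as columns)
            c = hT[ai].copy()
            for s_slot in range(t):
                c -= G[S[ai, s_slot], :] * C[ai, s_slot][:, None]
            c[np.arange(ai.size)[:, None], S[ai, :t]] = 0.0
        cact = c[ai] if t == 0 else c
        pick = np.argmax(np.abs(cact), axis=1)
        mag = np.abs(cact[np.arange(ai.size), pick])
        # signals whose residual correlation vanished are done (e.g. zero vectors)
        alive = mag > 1e-13
        ai = ai[alive]
        if ai.size == 0:
            break
        S[ai, t] = pick[alive]
        k = t + 1
        sub = S[ai, :k]
        Gs = G[sub[:, :, None], sub[:, None, :]]  # (n_a, k, k)
        hs = hT[ai[:, None], sub]  # (n_a, k)
        try:
            coef = np.linalg.solve(Gs, hs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            coef = np.stack(
                [np.linalg.lstsq(g, r, rcond=None)[0] for g, r in zip(Gs, hs)]
            )
        C[ai, :k] = coef
        resid_sq[ai] = np.maximum(xx[ai] - np.einsum("ij,ij->i", coef, hs), 0.0)
        if eps is not None:
            ai = ai[resid_sq[ai] > eps**2]
    return S, C, np.sqrt(resid_sq)


def omp_batch(
    D: np.ndarray,
    X: np.ndarray,
    sparsity: int = 3,
    eps: float | None = None,
    chunk: int = 20_000,
    dtype: type = np.float64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy OMP coding of many signals at once.

    ``D`` is (d, m) with unit-norm atoms, ``X`` is (d, n) signals as columns.
    Atoms are selected by maximal absolute residual correlation and the
    coefficients are re-fit by least squares at every step; coding stops at
    ``sparsity`` atoms or when the residual norm drops to ``eps``.  Returns
    ``(supports, coefficients, residual_norms)`` with supports padded by -1.

    ``dtype=np.float32`` halves the memory traffic of the (memory-bound)
    correlation updates; the large-batch internal callers use it, while the
    default keeps full double precision.
    """
    D = np.asarray(D, dtype=dtype)
    X = np.asarray(X, dtype=dtype)
    if D.ndim != 2 or X.ndim != 2 or D.shape[0] != X.shape[0]:
        raise ValueError("dictionary and signals must share the feature dimension")
    sparsity = int(min(sparsity, D.shape[1]))
    G = D.T @ D
    outs = [
        _omp_chunk(D, G, X[:, i : i + chunk], sparsity, eps)
        for i in range(0, X.shape[1], chunk)
    ]
    S = np.concatenate([o[0] for o in outs])
    C = np.concatenate([o[1] for o in outs]).astype(np.float64, copy=False)
    R = np.concatenate([o[2] for o in outs]).astype(np.float64, copy=False)
    return S, C, R


def omp_code(
    vector: np.ndarray,
    dictionary: np.ndarray,
    sparsity: int = 3,
    epsilon: float | None = None,
) -> SparseCode:
    """OMP coding of a single feature vector; see :func:`omp_batch`."""
    x = np.asarray(vector, dtype=float).reshape(-1, 1)
    S, C, _R = omp_batch(dictionary, x, sparsity=sparsity, eps=epsilon)
    support = S[0][S[0] >= 0]
    q = np.zeros(dictionary.shape[1])
    q[support] = C[0][: support.size]
    # recompute the residual directly: the Gram-matrix shortcut used in the
    # batch path loses half the significant digits to cancellation
    resid = float(np.linalg.norm(x[:, 0] - dictionary @ q))
    return SparseCode(q, support, resid, epsilon)


def codes_to_sparse(S: np.ndarray, C: np.ndarray, m: int) -> sp.csc_matrix:
    """Assemble OMP outputs into the (m, n) sparse code matrix Q."""
    n, k = S.shape
    mask = S >= 0
    rows = S[mask]
    cols = np.repeat(np.arange(n), mask.sum(axis=1))
    # mask flattens row-major, matching the repeat order above
    data = C[mask]
    return sp.csc_matrix((data, (rows, cols)), shape=(m, n))


# ---------------------------------------------------------------------------
# K-SVD dictionary learning
# ---------------------------------------------------------------------------


def _normalize_columns(A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    norms = np.linalg.norm(A, axis=0)
    dead = norms < 1e-12
    if dead.any():
        A = A.copy()
        A[:, dead] = rng.standard_normal((A.shape[0], dead.sum()))
        norms = np.linalg.norm(A, axis=0)
    return A / norms


def ksvd_train(
    X: np.ndarray,
    m: int,
    sparsity: int = 3,
    iterations: int = 15,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, sp.csc_matrix, dict]:
    """K-SVD: alternate OMP sparse coding with per-atom rank-1 SVD updates.

    ``X`` is (d, n) training vectors as columns with ``n >= m``.  The
    dictionary is initialized from a seeded random subset of the data
    (normalized); each sweep recodes all signals at the given ``sparsity``
    and then updates every atom (and its active coefficients) as the best
    rank-1 approximation of the residual restricted to the signals using it.
    Unused atoms are replaced by the currently worst-represented signal.

    Returns ``(A, Q, info)`` with unit-norm atoms, the final sparse codes and
    a log of the per-iteration training error ``sum ||x - A q||^2`` (non-
    increasing in practice).
    """
    X = np.asarray(X, dtype=float)
    d, n = X.shape
    if m > n:
        raise ValueError(f"dictionary size {m} exceeds sample count {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = _normalize_columns(X[:, rng.choice(n, size=m, replace=False)], rng)

    def _synth(S: np.ndarray, C: np.ndarray, cols=None) -> np.ndarray:
        idx = slice(None) if cols is None else cols
        Sv, Cv = S[idx], C[idx]
        out = np.zeros((d, Sv.shape[0]))
        for slot in range(Sv.shape[1]):
            use = Sv[:, slot] >= 0
            if use.any():
                out[:, use] += A[:, Sv[use, slot]] * Cv[use, slot][None, :]
        return out

    errors: list[float] = []
    S = C = None
    prev_res_sq = None
    for _ in range(max(iterations, 0)):
        # float32 coding: the correlation sweeps are memory-bound and the
        # safeguard below re-evaluates every accepted code in full precision
        S_new, C_new, _res = omp_batch(A, X, sparsity=sparsity, dtype=np.float32)
        Xhat = _synth(S_new, C_new)
        if prev_res_sq is not None:
            # monotonicity safeguard: keep a signal's previous code when the
            # greedy recode is worse (the dictionary is unchanged here)
            new_res_sq = np.einsum("ij,ij->j", X - Xhat, X - Xhat)
            worse = np.flatnonzero(new_res_sq > prev_res_sq * (1 + 1e-12))
            if worse.size:
                S_new[worse], C_new[worse] = S[worse], C[worse]
                Xhat[:, worse] = _synth(S_new, C_new, cols=worse)
        S, C = S_new, C_new
        R = X - Xhat

        # per-atom usage index built once per sweep
        flat = S.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_atoms = flat[order]
        starts = np.searchsorted(sorted_atoms, np.arange(m))
        stops = np.searchsorted(sorted_atoms, np.arange(m), side="right")
        sig_of = order // S.shape[1]
        slot_of = order % S.shape[1]

        col_err = None
        for j in range(m):
            lo, hi = starts[j], stops[j]
            if lo == hi:
                if col_err is None:
                    col_err = np.einsum("ij,ij->j", R, R)
                worst = int(np.argmax(col_err))
                col_err[worst] = 0.0
                v = X[:, worst]
                A[:, j] = v / np.linalg.norm(v) if np.linalg.norm(v) > 1e-12 else A[:, j]
                continue
            sigs = sig_of[lo:hi]
            slots = slot_of[lo:hi]
            coefs = C[sigs, slots]
            E = R[:, sigs] + np.outer(A[:, j], coefs)
            U, svals, Vt = np.linalg.svd(E, full_matrices=False)
            a_new = U[:, 0]
            c_new = svals[0] * Vt[0]
            R[:, sigs] = E - np.outer(a_new, c_new)
            A[:, j] = a_new
            C[sigs, slots] = c_new
        prev_res_sq = np.einsum("ij,ij->j", R, R)
        errors.append(float(prev_res_sq.sum()))

    if S is None:  # iterations == 0: code once with the initial dictionary
        S, C, _res = omp_batch(A, X, sparsity=sparsity)
    Q = codes_to_sparse(S, C, m)
    return A, Q, {"errors": errors}


def solve_hr_dictionary(P_h: np.ndarray, Q: np.ndarray | sp.spmatrix) -> np.ndarray:
    """Least-squares HR dictionary ``A_h = P_h Q^T (Q Q^T)^(-1)``.

    ``P_h`` is (patch_dim, n) HR patches as columns, ``Q`` the (m, n) code
    matrix.  A rank-deficient ``Q Q^T`` is ridge-regularized by
    ``1e-8 * trace / m`` with a warning.
    """
    P_h = np.asarray(P_h, dtype=float)
    Qs = sp.csr_matrix(Q) if not sp.issparse(Q) else Q.tocsr()
    if P_h.shape[1] != Qs.shape[1]:
        raise ValueError("patch matrix and code matrix must share sample count")
    G = np.asarray((Qs @ Qs.T).toarray())
    B = np.asarray(Qs @ P_h.T)  # (m, patch_dim)
    try:
        cf = cho_factor(G)
        return cho_solve(cf, B).T
    except np.linalg.LinAlgError:
        pass
    ridge = 1e-8 * np.trace(G) / G.shape[0]
    logger.warning("rank-deficient Q Q^T; adding ridge %.3e", ridge)
    cf = cho_factor(G + ridge * np.eye(G.shape[0]))
    return cho_solve(cf, B).T


# ---------------------------------------------------------------------------
# Detail-image construction and the training / testing pipelines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnhanceConfig:
    """Parameters of the detail-enhancement chain.

    Bilateral sigmas follow the operator defaults (spatial 3 px, range 10% of
    the image span); the guided filter uses ``radius`` 8 and a relative
    ``eps`` of 1e-4 of the squared guide span; SVE normalizes on the 8-bit
    scale of the affinely mapped detail image.
    """

    bilateral_sigma_spatial: float = 3.0
    bilateral_sigma_range_frac: float = 0.1
    bpdhe_smoothing_window: int = 3
    guided_radius: int = 8
    guided_eps: float = 1e-4


@dataclass
class DetailImages:
    """All intermediates of the training-detail construction."""

    y_h: np.ndarray  # HR training image (e.g. a SART reconstruction)
    y_l: np.ndarray  # interpolated LR image on the HR grid
    y_h_enhanced: np.ndarray  # bilateral + BPDHE result
    raw_detail: np.ndarray  # y_h - y_l
    enhanced_detail: np.ndarray  # y_h_enhanced - y_l
    equalized_detail: np.ndarray  # SVE of the enhanced detail
    guided_detail: np.ndarray  # guided filter (guide = raw detail)


def build_mesr_detail_image(
    y_h: np.ndarray, y_l: np.ndarray, cfg: EnhanceConfig = EnhanceConfig()
) -> DetailImages:
    """Construct the enhanced training detail image.

    Chain: denoise + re-contrast the HR image (bilateral, then BPDHE);
    subtract the interpolated LR image to form the enhanced detail; equalize
    its singular-value scale (computed on the detail's own [0, 255] affine
    mapping, then mapped back, since detail images are signed); finally
    guided-filter it using the raw detail ``y_h - y_l`` as the guide so true
    structure lost by the filters is re-imposed without its noise.
    """
    y_h = np.asarray(y_h, dtype=float)
    y_l = np.asarray(y_l, dtype=float)
    if y_h.shape != y_l.shape:
        raise ValueError("y_h and y_l must have the same shape")
    span = float(y_h.max() - y_h.min())
    y_he = bpdhe(
        bilateral_filter(
            y_h,
            sigma_spatial=cfg.bilateral_sigma_spatial,
            sigma_range=cfg.bilateral_sigma_range_frac * span if span > 0 else None,
        ),
        smoothing_window=cfg.bpdhe_smoothing_window,
    )
    raw = y_h - y_l
    enh = y_he - y_l
    lo, hi = float(enh.min()), float(enh.max())
    if hi > lo:
        mapped = (enh - lo) * (255.0 / (hi - lo))
        eq_mapped = sve(mapped, intensity_range=(0.0, 255.0), clip=False)
        eq = eq_mapped * ((hi - lo) / 255.0) + lo
    else:
        eq = enh.copy()
    g_span = float(raw.max() - raw.min())
    eps_abs = cfg.guided_eps * (g_span**2 if g_span > 0 else 1.0)
    guided = guided_filter(raw, eq, radius=cfg.guided_radius, eps=eps_abs)
    return DetailImages(y_h, y_l, y_he, raw, enh, eq, guided)


@dataclass
class DictionaryPair:
    """Coupled LR/HR dictionaries with the PCA projector and patch geometry."""

    A_l: np.ndarray  # (d_reduced, m), unit-norm atoms
    A_h: np.ndarray  # (block^2, m)
    pca: PcaProjection
    patch_cfg: PatchConfig
    scale: int
    sparsity: int = 3

    def __post_init__(self) -> None:
        if self.A_l.shape[1] != self.A_h.shape[1]:
            raise ValueError("LR and HR dictionaries must have equal atom counts")

    @property
    def n_atoms(self) -> int:
        return self.A_l.shape[1]

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            A_l=self.A_l,
            A_h=self.A_h,
            pca_components=self.pca.components,
            pca_mean=self.pca.mean,
            pca_evr=self.pca.explained_variance_ratio,
            block_size=self.patch_cfg.block_size,
            stride=self.patch_cfg.stride,
            scale=self.scale,
            sparsity=self.sparsity,
        )

    @classmethod
    def load_npz(cls, path) -> "DictionaryPair":
        z = np.load(path)
        return cls(
            A_l=z["A_l"],
            A_h=z["A_h"],
            pca=PcaProjection(z["pca_components"], z["pca_mean"], z["pca_evr"]),
            patch_cfg=PatchConfig(
                block_size=int(z["block_size"]), stride=int(z["stride"])
            ),
            scale=int(z["scale"]),
            sparsity=int(z["sparsity"]),
        )


def _training_features(
    y_l: np.ndarray, detail_images: list[np.ndarray], cfg: PatchConfig
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Paired LR feature patches and HR detail patches at common locations."""
    feats = extract_lr_features(y_l)
    fp, locs = extract_feature_patches(feats, cfg.block_size, cfg.stride)
    hps = [extract_patches(E, cfg.block_size, cfg.stride)[0] for E in detail_images]

    keep = fp.var(axis=1) > cfg.min_feature_variance
    fp = fp[keep]
    hps = [hp[keep] for hp in hps]
    if fp.shape[0] > cfg.max_train_patches:
        rng = np.random.default_rng(cfg.seed)
        sel = rng.choice(fp.shape[0], size=cfg.max_train_patches, replace=False)
        sel.sort()
        fp = fp[sel]
        hps = [hp[sel] for hp in hps]
    return fp, hps


def train_dictionary_variants(
    y_h: np.ndarray,
    z_l: np.ndarray,
    patch_cfg: PatchConfig = PatchConfig(),
    m: int = 1000,
    sparsity: int = 3,
    ksvd_iterations: int = 15,
    seed: int = 0,
    degradation: DegradationSpec = DegradationSpec(),
    enhance: EnhanceConfig = EnhanceConfig(),
    retained_variance: float = 0.999,
) -> tuple[DictionaryPair, DictionaryPair]:
    """Train the plain and the detail-enhanced dictionary pair together.

    The LR side (features, PCA, K-SVD dictionary and codes) depends only on
    the interpolated LR image and is therefore shared; the two variants
    differ solely in which detail image supplies the HR patches: the raw
    ``y_h - y_l`` (plain sparse-coding baseline) or the enhanced/guided
    detail (the full method).  Returns ``(pair_raw, pair_enhanced)``.
    """
    y_h = np.asarray(y_h, dtype=float)
    y_l = upscale(z_l, degradation)
    if y_l.shape != y_h.shape:
        if y_l.shape[0] < y_h.shape[0] or y_l.shape[1] < y_h.shape[1]:
            raise ValueError("upscaled z_l is smaller than y_h")
        y_l = y_l[: y_h.shape[0], : y_h.shape[1]]
    details = build_mesr_detail_image(y_h, y_l, enhance)
    fp, (hp_raw, hp_enh) = _training_features(
        y_l, [details.raw_detail, details.guided_detail], patch_cfg
    )
    if fp.shape[0] < m:
        raise ValueError(
            f"only {fp.shape[0]} usable training patches for {m} atoms"
        )
    pca = fit_pca_projection(fp, retained_variance)
    Xl = pca.project(fp).T
    A_l, Q, _info = ksvd_train(Xl, m, sparsity=sparsity, iterations=ksvd_iterations, seed=seed)
    pair_raw = DictionaryPair(
        A_l, solve_hr_dictionary(hp_raw.T, Q), pca, patch_cfg, degradation.scale, sparsity
    )
    pair_enh = DictionaryPair(
        A_l.copy(),
        solve_hr_dictionary(hp_enh.T, Q),
        pca,
        patch_cfg,
        degradation.scale,
        sparsity,
    )
    return pair_raw, pair_enh


def mesr_train(
    y_h: np.ndarray,
    z_l: np.ndarray,
    patch_cfg: PatchConfig = PatchConfig(),
    m: int = 1000,
    sparsity: int = 3,
    ksvd_iterations: int = 15,
    seed: int = 0,
    degradation: DegradationSpec = DegradationSpec(),
    enhance: EnhanceConfig = EnhanceConfig(),
    retained_variance: float = 0.999,
    use_detail_chain: bool = True,
) -> DictionaryPair:
    """Full training stage: returns the coupled dictionary pair.

    With ``use_detail_chain=False`` the HR patches come from the raw detail
    image (the plain sparse-coding baseline); otherwise from the
    bilateral/BPDHE/SVE/guided-filter enhanced detail.
    """
    pair_raw, pair_enh = train_dictionary_variants(
        y_h,
        z_l,
        patch_cfg=patch_cfg,
        m=m,
        sparsity=sparsity,
        ksvd_iterations=ksvd_iterations,
        seed=seed,
        degradation=degradation,
        enhance=enhance,
        retained_variance=retained_variance,
    )
    return pair_enh if use_detail_chain else pair_raw


def sr_reconstruct(
    test_lr: np.ndarray,
    pair: DictionaryPair,
    degradation: DegradationSpec | None = None,
    chunk: int = 50_000,
    return_detail: bool = False,
):
    """Test stage: super-resolve an LR image with a trained dictionary pair.

    The LR image is interpolated up by ``pair.scale``; stride-spaced patch
    features are PCA-projected and OMP-coded on ``A_l``; ``A_h`` times the
    codes synthesizes HR detail patches, which are overlap-averaged and added
    to the interpolated image.  The output is clipped to the interpolated
    image's intensity range.
    """
    spec = degradation if degradation is not None else DegradationSpec(scale=pair.scale)
    spec = replace(spec, scale=pair.scale)
    y_up = upscale(np.asarray(test_lr, float), spec)
    cfg = pair.patch_cfg
    feats = extract_lr_features(y_up)
    fp, locs = extract_feature_patches(feats, cfg.block_size, cfg.stride)

    b2 = cfg.block_size**2
    detail_patches = np.zeros((fp.shape[0], b2))
    for i in range(0, fp.shape[0], chunk):
        Z = pair.pca.project(fp[i : i + chunk]).T
        S, C, _ = omp_batch(pair.A_l, Z, sparsity=pair.sparsity, dtype=np.float32)
        for slot in range(S.shape[1]):
            use = S[:, slot] >= 0
            if use.any():
                detail_patches[i : i + chunk][use] += (
                    pair.A_h[:, S[use, slot]] * C[use, slot][None, :]
                ).T
    detail = aggregate_patches(detail_patches, locs, y_up.shape, cfg.block_size)
    out = np.clip(y_up + detail, y_up.min(), y_up.max())
    if return_detail:
        return out, detail
    return out
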