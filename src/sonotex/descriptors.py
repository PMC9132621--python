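"""Per-patch texture (LPQ) and shape (HOG) descriptors.

Each 16 x 16 patch yields a 256-bin local phase quantization histogram
followed by a 36-value histogram of oriented gradients, concatenated
into a frozen-order 292-vector; the 341 patch vectors of one image
concatenate into a 99,572-long feature vector.

LPQ quantizes the signs of short-term Fourier transform coefficients at
four low frequencies inside a small sliding window into 8-bit codes and
histograms the codes — a blur-insensitive texture signature.  HOG bins
Sobel gradient orientations weighted by magnitude over 8 x 8 cells and
block-normalizes, capturing the dominant local directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .imaging import PATCH_SIDE, PatchSet

__all__ = [
    "LPQ_LENGTH",
    "HOG_LENGTH",
    "PATCH_FEATURE_LENGTH",
    "IMAGE_FEATURE_LENGTH",
    "N_PATCHES",
    "LPQParams",
    "HOGParams",
    "GradientField",
    "compute_gradients",
    "lpq_descriptor",
    "hog_descriptor",
    "patch_features",
    "image_feature_vector",
    "feature_provenance",
]

LPQ_LENGTH = 256
HOG_LENGTH = 36
PATCH_FEATURE_LENGTH = LPQ_LENGTH + HOG_LENGTH  # 292
N_PATCHES = 341
IMAGE_FEATURE_LENGTH = N_PATCHES * PATCH_FEATURE_LENGTH  # 99,572

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


@dataclass(frozen=True)
class LPQParams:
    """Local phase quantization parameters.

    window_side: side of the square STFT window (odd, >= 3).
    decorrelation_rho: exponential correlation coefficient used to whiten
        the 8 coefficient channels before sign quantization; ``None``
        disables whitening.
    histogram_mode: "normalized" (sums to 1) or "counts".
    """

    window_side: int = 3
    decorrelation_rho: float | None = 0.9
    histogram_mode: str = "normalized"

    def __post_init__(self) -> None:
        if self.window_side < 3 or self.window_side % 2 == 0:
            raise ValueError("window_side must be odd and >= 3")
        if self.histogram_mode not in ("normalized", "counts"):
            raise ValueError(f"unknown histogram_mode {self.histogram_mode!r}")


@dataclass(frozen=True)
class HOGParams:
    """Histogram-of-oriented-gradients parameters.

    Defaults (8-px cells, one 2x2-cell block, 9 unsigned bins, L2-Hys)
    are the unique common parameterization giving 36 values on a 16x16
    patch.
    """

    cell_side: int = 8
    block_cells: int = 2
    n_bins: int = 9
    block_norm: str = "L2-Hys"


@dataclass(frozen=True)
class GradientField:
    """Sobel gradients with magnitude and unsigned orientation (degrees)."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    angle: np.ndarray  # in [0, 180)


def _reflect_pad(batch: np.ndarray, pad: int) -> np.ndarray:
    return np.pad(batch, ((0, 0), (pad, pad), (pad, pad)), mode="reflect")


def _sobel_batch(batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sobel gx/gy for a (n, h, w) batch with reflective borders.

    Correlation (not flipped-kernel convolution); the unsigned-orientation
    HOG downstream is insensitive to the global sign either way.
    """
    win = sliding_window_view(_reflect_pad(batch, 1), (3, 3), axis=(1, 2))
    gx = np.einsum("nhwij,ij->nhw", win, _SOBEL_X)
    gy = np.einsum("nhwij,ij->nhw", win, _SOBEL_Y)
    return gx, gy


def compute_gradients(patch: np.ndarray) -> GradientField:
    """Sobel gradient field of a single patch.

    The orientation is the standard gradient angle ``atan2(gy, gx)``
    reduced to the unsigned range ``[0, 180)`` degrees.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or min(patch.shape) < 3:
        raise ValueError(f"patch must be 2-D and at least 3x3, got {patch.shape}")
    gx, gy = _sobel_batch(patch[None])
    gx, gy = gx[0], gy[0]
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0
    return GradientField(gx=gx, gy=gy, magnitude=mag, angle=ang)


# ---------------------------------------------------------------------------
# LPQ


@lru_cache(maxsize=8)
def _lpq_operators(window_side: int, rho: float | None):
    """STFT filter bank (4 complex filters over the window) and the
    whitening transform implied by an exponential pixel-correlation model."""
    r = window_side // 2
    offs = np.arange(-r, r + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    pos = np.column_stack([dy.ravel(), dx.ravel()])  # (p, 2) row-major
    a = 1.0 / window_side
    freqs = [(a, 0.0), (0.0, a), (a, a), (a, -a)]  # (u along x, v along y)
    filt = np.stack([
        np.exp(-2j * np.pi * (u * pos[:, 1] + v * pos[:, 0])) for u, v in freqs
    ])  # (4, p)
    # real-valued channel matrix: [Re f1, Im f1, Re f2, Im f2, ...]
    m = np.empty((8, pos.shape[0]))
    m[0::2] = filt.real
    m[1::2] = filt.imag
    if rho is None or rho == 0:
        white = np.eye(8)
    else:
        dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        cov_pos = rho ** dist
        cov = m @ cov_pos @ m.T
        _, _, vt = np.linalg.svd(cov)
        white = vt
    return filt, white


def _lpq_batch(batch: np.ndarray, params: LPQParams) -> np.ndarray:
    n, h, w = batch.shape
    ws = params.window_side
    if h < ws or w < ws:
        raise ValueError(f"patch side {min(h, w)} smaller than LPQ window {ws}")
    filt, white = _lpq_operators(ws, params.decorrelation_rho)
    # valid-region windows only: border codes are not computed
    win = sliding_window_view(batch, (ws, ws), axis=(1, 2))
    nv = win.shape[1] * win.shape[2]
    flat = win.reshape(n, nv, ws * ws)
    resp = np.einsum("npw,fw->npf", flat, filt)
    # snap numerically-zero coefficients (filter sums are zero in exact
    # arithmetic on constant windows) so the >=0 sign convention is stable
    tol = 1e-12 * np.abs(flat).sum(axis=2)[:, :, None]
    resp.real[np.abs(resp.real) < tol] = 0.0
    resp.imag[np.abs(resp.imag) < tol] = 0.0
    chan = np.empty((n, nv, 8))
    chan[:, :, 0::2] = resp.real
    chan[:, :, 1::2] = resp.imag
    q = chan @ white.T
    codes = ((q >= 0) * (1 << np.arange(8))).sum(axis=2)
    offsets = (np.arange(n) * LPQ_LENGTH)[:, None]
    hist = np.bincount((codes + offsets).ravel(),
                       minlength=n * LPQ_LENGTH).reshape(n, LPQ_LENGTH)
    hist = hist.astype(np.float64)
    if params.histogram_mode == "normalized":
        hist /= hist.sum(axis=1, keepdims=True)
    return hist


def lpq_descriptor(patch: np.ndarray, params: LPQParams | None = None) -> np.ndarray:
    """256-bin LPQ code histogram of one patch."""
    params = params or LPQParams()
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2:
        raise ValueError("patch must be 2-D")
    return _lpq_batch(patch[None], params)[0]


# ---------------------------------------------------------------------------
# HOG


def _hog_batch(batch: np.ndarray, params: HOGParams) -> np.ndarray:
    n, h, w = batch.shape
    cs, bc, nb = params.cell_side, params.block_cells, params.n_bins
    ncy, ncx = h // cs, w // cs
    if ncy < bc or ncx < bc or h % cs or w % cs:
        raise ValueError(
            f"patch {h}x{w} incompatible with cell {cs} / block {bc} geometry")
    gx, gy = _sobel_batch(batch)
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0
    # magnitude split linearly between the two bins bracketing the angle;
    # bin centres at 0, 20, ..., 160 degrees with wrap-around at 180
    t = ang * nb / 180.0
    lo = np.floor(t).astype(np.int64)
    frac = t - lo
    b0 = lo % nb
    b1 = (lo + 1) % nb
    cell_row = (np.arange(h) // cs)[None, :, None]
    cell_col = (np.arange(w) // cs)[None, None, :]
    img_idx = np.arange(n)[:, None, None]
    base = ((img_idx * ncy + cell_row) * ncx + cell_col) * nb
    size = n * ncy * ncx * nb
    hist = (np.bincount((base + b0).ravel(), weights=(mag * (1 - frac)).ravel(),
                        minlength=size)
            + np.bincount((base + b1).ravel(), weights=(mag * frac).ravel(),
                          minlength=size)).reshape(n, ncy, ncx, nb)
    # blocks of bc x bc cells, stride one cell; 16x16 defaults give one block
    eps = 1e-12
    rows = []
    for by in range(ncy - bc + 1):
        for bx in range(ncx - bc + 1):
            blk = hist[:, by:by + bc, bx:bx + bc, :].reshape(n, -1)
            v = blk / np.sqrt((blk ** 2).sum(axis=1, keepdims=True) + eps ** 2)
            if params.block_norm == "L2-Hys":
                v = np.minimum(v, 0.2)
                v = v / np.sqrt((v ** 2).sum(axis=1, keepdims=True) + eps ** 2)
            rows.append(v)
    return np.concatenate(rows, axis=1)


def hog_descriptor(patch: np.ndarray, params: HOGParams | None = None) -> np.ndarray:
    """36-value HOG descriptor of one 16 x 16 patch (defaults)."""
    params = params or HOGParams()
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2:
        raise ValueError("patch must be 2-D")
    return _hog_batch(patch[None], params)[0]


# ---------------------------------------------------------------------------
# Concatenation


@dataclass(frozen=True)
class PatchFeatures:
    values: np.ndarray  # length 292: LPQ (256) then HOG (36)
    patch_index: int    # 1-based position within the patch ordering


def patch_features(patch: np.ndarray, lpq: LPQParams | None = None,
                   hog: HOGParams | None = None, patch_index: int = 1) -> PatchFeatures:
    """LPQ-then-HOG concatenation for one patch (length 292)."""
    v = np.concatenate([lpq_descriptor(patch, lpq), hog_descriptor(patch, hog)])
    return PatchFeatures(values=v, patch_index=patch_index)


def patchset_feature_matrix(ps: PatchSet, lpq: LPQParams | None = None,
                            hog: HOGParams | None = None) -> np.ndarray:
    """(n_patches, 292) matrix for a whole patch set in one vectorized pass."""
    lpq = lpq or LPQParams()
    hog = hog or HOGParams()
    return np.concatenate([_lpq_batch(ps.patches, lpq),
                           _hog_batch(ps.patches, hog)], axis=1)


def image_feature_vector(ps: PatchSet, lpq: LPQParams | None = None,
                         hog: HOGParams | None = None) -> np.ndarray:
    """Concatenate the 341 per-patch 292-vectors into one 99,572-vector.

    Segment ``j`` (1-based) occupies ``[(j-1)*292, j*292)`` and equals the
    per-patch descriptor of patch ``j`` under the frozen patch ordering.
    """
    if len(ps) != N_PATCHES:
        raise ValueError(f"expected {N_PATCHES} patches, got {len(ps)}")
    return patchset_feature_matrix(ps, lpq, hog).ravel()


def feature_provenance(ps: PatchSet | None = None):
    """Column provenance of the image feature vector.

    Returns a DataFrame with one row per column: 1-based patch index,
    pyramid level (if a patch set is supplied), descriptor family and the
    index within the descriptor.
    """
    import pandas as pd

    patch_idx = np.repeat(np.arange(1, N_PATCHES + 1), PATCH_FEATURE_LENGTH)
    family = np.tile(np.array(["lpq"] * LPQ_LENGTH + ["hog"] * HOG_LENGTH), N_PATCHES)
    local = np.tile(np.concatenate([np.arange(LPQ_LENGTH), np.arange(HOG_LENGTH)]),
                    N_PATCHES)
    out = pd.DataFrame({"patch_index": patch_idx, "family": family,
                        "local_index": local})
    if ps is not None:
        out["level"] = np.repeat(ps.provenance[:, 0], PATCH_FEATURE_LENGTH)
    return out
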