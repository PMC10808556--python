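"""2D linear registration by block matching.

The engine follows the classical scheme: small high-variance blocks of the
reference image are matched exhaustively in the test image by Pearson
cross-correlation, a global rigid or affine transform is fitted to the
matched point pairs by least-trimmed-squares, and the whole loop runs
coarse-to-fine over a Gaussian pyramid, composing incremental transforms
onto the initialisation.  Everything is deterministic: CC-peak ties break by
smallest displacement magnitude then lexicographic order, and the trimmed
fit uses stable sorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from numpy.lib.stride_tricks import sliding_window_view

from .imaging import (ContractError, PlaneImage, SliceMapperError,
                      Transform2D, apply_transform, compose)

__all__ = [
    "BlockMatchConfig",
    "BlockPairSet",
    "InsufficientMatchesError",
    "SingularFitError",
    "RegistrationFailureError",
    "block_correlation",
    "match_blocks",
    "estimate_transform",
    "register",
]

log = logging.getLogger(__name__)


class InsufficientMatchesError(SliceMapperError):
    """Too few valid block pairs to fit a transform."""


class SingularFitError(SliceMapperError):
    """Degenerate (collinear) point configuration."""


class RegistrationFailureError(SliceMapperError):
    """Registration produced a non-finite transform."""


@dataclass(frozen=True)
class BlockMatchConfig:
    """Block-matching parameters.

    block_size: pixels per block side.
    block_spacing: pixels between block origins.
    search_radius: exhaustive displacement search extent (pixels, per level).
    variance_keep_fraction: fraction of highest-variance blocks retained.
    trim_fraction: fraction of point pairs kept by least-trimmed-squares.
    pyramid_levels: coarse-to-fine levels (finest at working resolution).
    iterations_per_level: match/fit rounds per level.
    background_overlap_limit: blocks with more than this fraction of exactly
        background (0) pixels are excluded before variance ranking —
        histology slices have large empty fields.
    """

    block_size: int = 4
    block_spacing: int = 4
    search_radius: int = 5
    variance_keep_fraction: float = 0.5
    trim_fraction: float = 0.6
    pyramid_levels: int = 3
    iterations_per_level: int = 2
    background_overlap_limit: float = 0.75

    def __post_init__(self):
        if self.block_size < 4:
            raise ContractError("block_size must be >= 4")
        if not 0 < self.variance_keep_fraction <= 1:
            raise ContractError("variance_keep_fraction must be in (0, 1]")
        if not 0.5 <= self.trim_fraction <= 1:
            raise ContractError("trim_fraction must be in [0.5, 1]")
        if self.pyramid_levels < 1:
            raise ContractError("pyramid_levels must be >= 1")
        if self.block_spacing < 1 or self.search_radius < 1:
            raise ContractError("block_spacing and search_radius must be >= 1")
        if self.iterations_per_level < 1:
            raise ContractError("iterations_per_level must be >= 1")


DEFAULT_BLOCKMATCH = BlockMatchConfig()


@dataclass
class BlockPairSet:
    """Matched point pairs from one block-matching pass.

    ``ref_points`` and ``test_points`` are (n, 2) arrays of physical µm
    coordinates on the common grid; ``cc`` holds the peak Pearson
    cross-correlation of each pair, every value in [-1, 1].
    """

    ref_points: np.ndarray
    test_points: np.ndarray
    cc: np.ndarray
    level: int = 0

    def __post_init__(self):
        self.ref_points = np.asarray(self.ref_points, float).reshape(-1, 2)
        self.test_points = np.asarray(self.test_points, float).reshape(-1, 2)
        self.cc = np.asarray(self.cc, float).reshape(-1)
        if not (len(self.ref_points) == len(self.test_points) == len(self.cc)):
            raise ContractError("BlockPairSet arrays must have equal length")
        if len(self.cc) and (self.cc.min() < -1 - 1e-9 or self.cc.max() > 1 + 1e-9):
            raise ContractError("cross-correlation values must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.cc)


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------

def block_correlation(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """Pearson cross-correlation of two flattened patches.

    Returns NaN (the "undefined" sentinel excluding the block from matching)
    when either patch has zero variance.
    """
    a = np.asarray(block_a, float).ravel()
    b = np.asarray(block_b, float).ravel()
    if a.shape != b.shape:
        raise ContractError("block_correlation: patch shapes differ")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# block matching
# ---------------------------------------------------------------------------

def _displacement_order(radius: int) -> np.ndarray:
    """All integer displacements in [-r, r]^2, sorted by magnitude then lexicographic.

    Feeding candidates in this order makes ``argmax`` (first maximum) break
    CC ties toward the smallest displacement, deterministically.
    """
    rng = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(rng, rng, indexing="ij")
    disp = np.stack([dy.ravel(), dx.ravel()], axis=1)
    order = np.lexsort((disp[:, 1], disp[:, 0], (disp ** 2).sum(axis=1)))
    return disp[order]


def match_blocks(ref: PlaneImage, test: PlaneImage, cfg: BlockMatchConfig,
                 init: Transform2D | None = None, level: int = 0) -> BlockPairSet:
    """Match high-variance reference blocks into the test image.

    If ``init`` is given the test image is first warped onto the reference
    grid through it, so matching happens on a common grid; the returned test
    points live in that warped frame.  For each retained block the integer
    displacement in [-search_radius, +search_radius]^2 maximising Pearson CC
    is recorded; blocks with undefined or non-positive peak CC are dropped.
    """
    if init is not None:
        test = apply_transform(test, init, "linear", reference=ref)
    elif ref.shape != test.shape:
        raise ContractError("match_blocks: images must share a grid (or pass init)")

    bs, sp, r = cfg.block_size, cfg.block_spacing, cfg.search_radius
    h, w = ref.shape
    if h < bs + 2 * r + 1 or w < bs + 2 * r + 1:
        raise InsufficientMatchesError(
            f"image {ref.shape} too small for block size {bs} and radius {r}")

    # block origins kept clear of the border so every displacement is in-domain
    ii = np.arange(r, h - bs - r + 1, sp)
    jj = np.arange(r, w - bs - r + 1, sp)
    oi, oj = np.meshgrid(ii, jj, indexing="ij")
    oi, oj = oi.ravel(), oj.ravel()

    ref_win = sliding_window_view(ref.pixels, (bs, bs))
    blocks = ref_win[oi, oj].reshape(len(oi), -1)  # (nb, bs*bs)

    # exclude blocks dominated by exact background, then rank by variance
    bg_frac = (blocks == 0.0).mean(axis=1)
    keep = bg_frac <= cfg.background_overlap_limit
    if not keep.any():
        raise InsufficientMatchesError("all blocks lie in the background")
    oi, oj, blocks = oi[keep], oj[keep], blocks[keep]
    var = blocks.var(axis=1)
    n_keep = max(1, int(np.ceil(cfg.variance_keep_fraction * len(var))))
    order = np.lexsort((np.arange(len(var)), -var))[:n_keep]  # stable ties
    order = np.sort(order)  # keep raster order for determinism of output
    oi, oj, blocks = oi[order], oj[order], blocks[order]

    nb = len(blocks)
    n = bs * bs
    bmean = blocks.mean(axis=1, keepdims=True)
    bzero = blocks - bmean
    bnorm = np.sqrt((bzero * bzero).sum(axis=1))
    valid_ref = bnorm > 0

    # box sums of the test image for O(1) per-window mean/variance
    tw = sliding_window_view(test.pixels, (bs, bs))
    pad = np.zeros((h + 1, w + 1))
    np.cumsum(np.cumsum(test.pixels, axis=0), axis=1, out=pad[1:, 1:])
    s1 = pad[bs:, bs:] - pad[:-bs, bs:] - pad[bs:, :-bs] + pad[:-bs, :-bs]
    pad2 = np.zeros((h + 1, w + 1))
    np.cumsum(np.cumsum(test.pixels ** 2, axis=0), axis=1, out=pad2[1:, 1:])
    s2 = pad2[bs:, bs:] - pad2[:-bs, bs:] - pad2[bs:, :-bs] + pad2[:-bs, :-bs]

    disps = _displacement_order(r)
    ti = oi[None, :] + disps[:, 0:1]  # (nd, nb)
    tj = oj[None, :] + disps[:, 1:2]
    tb = tw[ti, tj].reshape(len(disps), nb, -1)   # (nd, nb, bs*bs)
    t1 = s1[ti, tj]
    tss = s2[ti, tj] - t1 * t1 / n
    cross = np.einsum("bk,dbk->db", bzero, tb)
    denom = bnorm[None, :] * np.sqrt(np.maximum(tss, 1e-300))
    ok = valid_ref[None, :] & (tss > 1e-12)
    with np.errstate(over="ignore", invalid="ignore"):
        cc_all = np.where(ok, cross / denom, -np.inf)
    np.clip(cc_all, -1.0, 1.0, out=cc_all)

    best = np.argmax(cc_all, axis=0)  # first maximum = smallest displacement
    peak = cc_all[best, np.arange(nb)]
    good = np.isfinite(peak) & (peak > 0.0)
    if good.sum() < 6:
        raise InsufficientMatchesError(
            f"only {int(good.sum())} valid block pairs (need >= 6)")

    centre = (bs - 1) / 2.0
    ps = np.asarray(ref.pixel_size)
    origin = np.asarray(ref.origin)
    ref_idx = np.stack([oi[good] + centre, oj[good] + centre], axis=1)
    test_idx = ref_idx + disps[best[good]]
    return BlockPairSet(ref_points=origin + ref_idx * ps,
                        test_points=origin + test_idx * ps,
                        cc=peak[good], level=level)


# ---------------------------------------------------------------------------
# transform estimation
# ---------------------------------------------------------------------------

def _fit_affine(P: np.ndarray, Q: np.ndarray) -> Transform2D:
    A = np.hstack([P, np.ones((len(P), 1))])
    sol, _, rank, _ = np.linalg.lstsq(A, Q, rcond=None)
    if rank < 3:
        raise SingularFitError("collinear point configuration for affine fit")
    return Transform2D(kind="affine", linear=sol[:2].T, offset=sol[2])


def _fit_rigid(P: np.ndarray, Q: np.ndarray) -> Transform2D:
    pbar, qbar = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pbar).T @ (Q - qbar)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        raise SingularFitError("degenerate point configuration for rigid fit")
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    return Transform2D(kind="rigid", linear=R, offset=qbar - R @ pbar)


def estimate_transform(pairs: BlockPairSet, model: str,
                       trim_fraction: float = 0.6,
                       max_iter: int = 8) -> Transform2D:
    """Least-trimmed-squares fit of a rigid or affine map to matched pairs.

    The model is fitted by least squares, residuals are computed for every
    pair, the fit is repeated on the ``trim_fraction`` of pairs with the
    smallest residuals, and this iterates until the inlier set stabilises.
    The rigid solution uses the orthogonal Procrustes construction (rotation
    + translation, no scaling).
    """
    if model not in ("rigid", "affine"):
        raise ContractError(f"unknown model {model!r}")
    P, Q = pairs.ref_points, pairs.test_points
    min_pairs = 3 if model == "affine" else 2
    if len(P) < min_pairs:
        raise InsufficientMatchesError(
            f"{len(P)} pairs, {model} needs >= {min_pairs}")
    fit = _fit_affine if model == "affine" else _fit_rigid
    n_keep = max(min_pairs, int(round(trim_fraction * len(P))))
    inliers = np.arange(len(P))
    for _ in range(max_iter):
        T = fit(P[inliers], Q[inliers])
        resid = np.linalg.norm(T(P) - Q, axis=1)
        new = np.lexsort((np.arange(len(P)), resid))[:n_keep]
        new = np.sort(new)
        if len(new) == len(inliers) and np.array_equal(new, inliers):
            break
        inliers = new
    return fit(P[inliers], Q[inliers])


# ---------------------------------------------------------------------------
# multiresolution registration
# ---------------------------------------------------------------------------

def _downsample(img: PlaneImage, factor: int) -> PlaneImage:
    """Gaussian-smoothed decimation by an integer factor (anti-aliased)."""
    if factor == 1:
        return img
    sm = ndi.gaussian_filter(img.pixels, sigma=factor / 2.0)
    sub = sm[::factor, ::factor]
    ps = (img.pixel_size[0] * factor, img.pixel_size[1] * factor)
    origin = (img.origin[0] + (factor - 1) / 2.0 * img.pixel_size[0],
              img.origin[1] + (factor - 1) / 2.0 * img.pixel_size[1])
    return PlaneImage(sub, ps, origin=origin, name=img.name)


def register(ref: PlaneImage, test: PlaneImage, model: str,
             init: Transform2D | None = None,
             cfg: BlockMatchConfig = DEFAULT_BLOCKMATCH,
             return_diagnostics: bool = False):
    """Coarse-to-fine block-matching registration of ``test`` onto ``ref``.

    Returns the pull-back transform (kind = ``model``) mapping reference
    points to test sampling points, obtained by composing incremental
    match/fit transforms onto ``init`` (the centering translation for rigid,
    the rigid result for affine).  Deterministic given inputs and config.
    """
    if model not in ("rigid", "affine"):
        raise ContractError(f"unknown model {model!r}")
    if not np.allclose(ref.pixel_size, test.pixel_size):
        raise ContractError("register: pixel sizes differ, resample first")
    T = init if init is not None else Transform2D.identity()
    diag = []
    levels = list(range(cfg.pyramid_levels - 1, -1, -1))  # coarse -> fine
    for level in levels:
        factor = 2 ** level
        ref_l = _try_downsample(ref, factor, cfg)
        test_l = _try_downsample(test, factor, cfg)
        if ref_l is None or test_l is None:
            continue  # level too coarse for this image size
        level_cc = []
        for _ in range(cfg.iterations_per_level):
            try:
                pairs = match_blocks(ref_l, test_l, cfg, init=T, level=level)
                D = estimate_transform(pairs, model, cfg.trim_fraction)
            except (InsufficientMatchesError, SingularFitError):
                if level == 0 and not diag:
                    raise
                log.debug("level %d: matching failed, keeping current transform",
                          level)
                break
            T = compose(T, D)
            if not (np.all(np.isfinite(T.linear)) and np.all(np.isfinite(T.offset))):
                raise RegistrationFailureError(
                    f"non-finite transform at pyramid level {level}")
            resid = np.linalg.norm(D(pairs.ref_points) - pairs.test_points, axis=1)
            n_keep = max(2, int(round(cfg.trim_fraction * len(pairs))))
            inl = np.argsort(resid, kind="stable")[:n_keep]
            level_cc.append(float(pairs.cc[inl].mean()))
        if level_cc:
            diag.append({"level": level, "mean_inlier_cc": level_cc[-1]})
    if model == "rigid":
        # re-orthogonalise: composition of rigid increments is rigid up to
        # floating-point drift
        U, _, Vt = np.linalg.svd(T.linear)
        lin = U @ Vt
        if np.linalg.det(lin) < 0:
            U = U.copy()
            U[:, -1] *= -1
            lin = U @ Vt
        T = Transform2D(kind="rigid", linear=lin, offset=T.offset)
    else:
        T = T.as_kind("affine")
    if return_diagnostics:
        return T, diag
    return T


def _try_downsample(img: PlaneImage, factor: int, cfg: BlockMatchConfig):
    need = cfg.block_size + 2 * cfg.search_radius + 1
    if min(img.shape) // factor < need:
        return None
    return _downsample(img, factor)
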