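"""Normalized mutual information, the registration-external similarity score.

NMI(A, B) = (H(A) + H(B)) / H(A, B) computed from a joint intensity
histogram: 2 for identical images, 1 in the independence limit.  In the
localization pipeline it is never used to drive registration (block matching
optimises cross-correlation internally); it only scores the correspondence
between the experimental slice and each registered template candidate, which
keeps the similarity criterion independent of the registration engine and
robust across imaging modalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import ContractError, PlaneImage, SliceMapperError

__all__ = ["HistogramSpec", "SimilarityUndefinedError", "nmi"]


class SimilarityUndefinedError(SliceMapperError):
    """The joint histogram carries no information (empty mask or constant pair)."""


@dataclass(frozen=True)
class HistogramSpec:
    """Joint-histogram layout for NMI.

    bins: histogram bins per axis (default 64).
    range_policy: 'joint-min-max' spans each image's own masked min-max;
        'fixed-unit' uses [0, 1] on both axes (images are normalised at load).
    foreground_only: exclude pixels where both images are exactly background
        (0) — registered template slices carry large zero-filled borders that
        would otherwise inflate similarity.
    """

    bins: int = 64
    range_policy: str = "joint-min-max"
    foreground_only: bool = True

    def __post_init__(self):
        if self.bins < 8:
            raise ContractError("HistogramSpec.bins must be >= 8")
        if self.range_policy not in ("joint-min-max", "fixed-unit"):
            raise ContractError(f"unknown range_policy {self.range_policy!r}")


DEFAULT_HISTOGRAM = HistogramSpec()


def _entropy(p: np.ndarray) -> float:
    # natural log; the NMI ratio is log-base invariant
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(a: PlaneImage, b: PlaneImage, spec: HistogramSpec = DEFAULT_HISTOGRAM) -> float:
    """Normalized mutual information (H(A)+H(B))/H(A,B) of two images.

    Symmetric in its arguments; value in (0, 2].  Raises
    :class:`SimilarityUndefinedError` when the evaluation mask is empty or
    the joint entropy vanishes (constant images).
    """
    if a.shape != b.shape:
        raise ContractError(f"nmi: grids differ, {a.shape} vs {b.shape}")
    # canonical argument order: the measure is symmetric, but float summation
    # over a transposed joint histogram is not bit-exact — evaluate both
    # orders through the same path so nmi(a, b) == nmi(b, a) exactly
    if a.pixels.tobytes() > b.pixels.tobytes():
        a, b = b, a
    av, bv = a.pixels.ravel(), b.pixels.ravel()
    if spec.foreground_only:
        mask = ~((av == 0.0) & (bv == 0.0))
        if not mask.any():
            raise SimilarityUndefinedError("empty evaluation mask")
        av, bv = av[mask], bv[mask]
    if spec.range_policy == "fixed-unit":
        ra, rb = (0.0, 1.0), (0.0, 1.0)
    else:
        ra, rb = (av.min(), av.max()), (bv.min(), bv.max())
        if ra[0] == ra[1]:
            ra = (ra[0] - 0.5, ra[1] + 0.5)
        if rb[0] == rb[1]:
            rb = (rb[0] - 0.5, rb[1] + 0.5)
    joint, _, _ = np.histogram2d(av, bv, bins=spec.bins, range=[ra, rb])
    total = joint.sum()
    p = joint / total
    h_a = _entropy(p.sum(axis=1))
    h_b = _entropy(p.sum(axis=0))
    h_ab = _entropy(p.ravel())
    if h_ab == 0.0:
        raise SimilarityUndefinedError("zero joint entropy (constant images)")
    return (h_a + h_b) / h_ab
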