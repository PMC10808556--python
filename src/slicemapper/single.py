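"""Single-slice localization: exhaustive candidate scoring, argmax z, label mapping.

For an experimental slice I_r and every candidate template slice T_a the
pipeline (i) registers T_a rigidly onto I_r (initialised by automated
centering) and scores the result with NMI, (ii) refines with an affine
registration initialised by the rigid result and scores again, and (iii)
blends the two scores as s_w = (1-w)*s_rig + w*s_aff with the rigid-affine
weighting w.  The selected position z is the argmax of s_w over candidates;
the winning transforms push the label slice L_z onto the experimental slice
with nearest-neighbour interpolation, producing its atlas segmentation.

Registration optimises block cross-correlation internally; NMI is evaluated
only afterwards, as an independent similarity criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .blockmatch import BlockMatchConfig, DEFAULT_BLOCKMATCH, register
from .imaging import (AtlasStack, ContractError, LabelImage, PlaneImage,
                      SliceMapperError, Transform2D, apply_transform,
                      center_images, compose, resample_to)
from .parallel import parallel_map
from .similarity import DEFAULT_HISTOGRAM, HistogramSpec, nmi

__all__ = [
    "CandidateRecord",
    "SimilarityProfile",
    "LocalizationResult",
    "LocalizationFailureError",
    "weighted_similarity",
    "score_candidate",
    "locate_single",
    "map_labels",
]

log = logging.getLogger(__name__)

WORKING_PIXEL_SIZE = 25.0  # µm, the standard working resolution for registration


class LocalizationFailureError(SliceMapperError):
    """Every candidate registration failed."""


def weighted_similarity(s_rig: float, s_aff: float, w: float) -> float:
    """Rigid-affine blend (1-w)*s_rig + w*s_aff, with w in [0, 1].

    w = 0 falls back to the rigid score alone, w = 1 to the affine score.
    """
    if not 0.0 <= w <= 1.0:
        raise ContractError(f"w must be in [0, 1], got {w}")
    if not (np.isfinite(s_rig) and np.isfinite(s_aff)):
        raise ContractError("similarity inputs must be finite")
    return (1.0 - w) * s_rig + w * s_aff


@dataclass
class CandidateRecord:
    """Evidence collected for one candidate template slice."""

    a: int
    s_rig: float = float("nan")
    s_aff: float = float("nan")
    s_w: float = float("nan")
    theta_rig: Transform2D | None = None
    theta_aff: Transform2D | None = None
    status: str = "ok"  # ok | failed
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class SimilarityProfile:
    """Per-candidate similarity records, sorted by slice number.

    Failed registrations are flagged, never silently dropped; for every
    successful record s_w equals the stored weighted blend exactly.
    """

    records: list[CandidateRecord]
    w: float

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ContractError(f"w must be in [0, 1], got {self.w}")
        self.records = sorted(self.records, key=lambda r: r.a)

    def record(self, a: int) -> CandidateRecord:
        for rec in self.records:
            if rec.a == a:
                return rec
        raise ContractError(f"no record for candidate {a}")

    def candidates(self) -> list[int]:
        return [r.a for r in self.records]

    def successful(self) -> list[CandidateRecord]:
        return [r for r in self.records if r.ok]

    def argmax(self) -> int:
        """Candidate with maximal s_w; exact ties go to the smallest a."""
        ok = self.successful()
        if not ok:
            raise LocalizationFailureError(
                "all candidates failed: "
                + "; ".join(f"a={r.a}: {r.message}" for r in self.records))
        best = max(ok, key=lambda r: (r.s_w, -r.a))
        return best.a

    def reweighted(self, w: float) -> "SimilarityProfile":
        """Re-blend the cached rigid/affine scores at a new w, no re-registration."""
        if not 0.0 <= w <= 1.0:
            raise ContractError(f"w must be in [0, 1], got {w}")
        recs = []
        for r in self.records:
            if r.ok:
                recs.append(CandidateRecord(
                    a=r.a, s_rig=r.s_rig, s_aff=r.s_aff,
                    s_w=weighted_similarity(r.s_rig, r.s_aff, w),
                    theta_rig=r.theta_rig, theta_aff=r.theta_aff,
                    status=r.status, message=r.message))
            else:
                recs.append(r)
        return SimilarityProfile(records=recs, w=w)

    # -- serialisation -----------------------------------------------------
    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("a,s_rig,s_aff,s_w,status\n")
            for r in self.records:
                fh.write(f"{r.a},{r.s_rig:.17g},{r.s_aff:.17g},"
                         f"{r.s_w:.17g},{r.status}\n")

    @staticmethod
    def from_csv(path, w: float) -> "SimilarityProfile":
        recs = []
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                a, s_rig, s_aff, s_w, status = line.rstrip("\n").split(",")
                recs.append(CandidateRecord(
                    a=int(a), s_rig=float(s_rig), s_aff=float(s_aff),
                    s_w=float(s_w), status=status))
        return SimilarityProfile(records=recs, w=w)


@dataclass
class LocalizationResult:
    """Outcome of single-slice localization."""

    z: int
    theta_rig: Transform2D
    theta_aff: Transform2D
    profile: SimilarityProfile
    mapped_labels: LabelImage | None = None

    @property
    def theta_full(self) -> Transform2D:
        """Complete template -> slice sampling map (rigid then affine refinement)."""
        return compose(self.theta_rig, self.theta_aff)


# ---------------------------------------------------------------------------
# candidate scoring
# ---------------------------------------------------------------------------

def score_candidate(I_r: PlaneImage, T_a: PlaneImage, a: int, w: float,
                    bm_cfg: BlockMatchConfig = DEFAULT_BLOCKMATCH,
                    hist_spec: HistogramSpec = DEFAULT_HISTOGRAM
                    ) -> CandidateRecord:
    """Score one candidate template slice against the experimental slice.

    Both images must already be at the working pixel size.  Runs rigid
    registration (initialised by foreground centering) then affine
    registration (initialised by the rigid result), evaluating NMI after
    each.  A registration failure yields a flagged record, never an
    exception — the candidate sweep must survive bad candidates.
    """
    try:
        init = center_images(T_a, I_r)
        theta_rig = register(I_r, T_a, "rigid", init=init, cfg=bm_cfg)
        warped_rig = apply_transform(T_a, theta_rig, "linear", reference=I_r)
        s_rig = nmi(I_r, warped_rig, hist_spec)
        theta_full = register(I_r, T_a, "affine", init=theta_rig, cfg=bm_cfg)
        theta_aff = compose(theta_rig.inverse(), theta_full).as_kind("affine")
        warped_aff = apply_transform(T_a, theta_full, "linear", reference=I_r)
        s_aff = nmi(I_r, warped_aff, hist_spec)
        return CandidateRecord(a=a, s_rig=s_rig, s_aff=s_aff,
                               s_w=weighted_similarity(s_rig, s_aff, w),
                               theta_rig=theta_rig, theta_aff=theta_aff)
    except SliceMapperError as exc:
        return CandidateRecord(a=a, status="failed", message=str(exc))


# ---------------------------------------------------------------------------
# the candidate sweep
# ---------------------------------------------------------------------------

def _prepare_working(img, working_pixel_size: float):
    return resample_to(img, (working_pixel_size, working_pixel_size))


def sweep_candidates(I_r: PlaneImage, atlas: AtlasStack,
                     candidates: list[int], w: float,
                     bm_cfg: BlockMatchConfig = DEFAULT_BLOCKMATCH,
                     hist_spec: HistogramSpec = DEFAULT_HISTOGRAM,
                     working_pixel_size: float = WORKING_PIXEL_SIZE,
                     n_workers: int = 1) -> SimilarityProfile:
    """Evaluate score_candidate for an explicit candidate list.

    Candidates are independent, so evaluation order cannot change the
    result; the profile is assembled in slice-number order regardless of the
    worker count.
    """
    I_w = _prepare_working(I_r, working_pixel_size)
    tasks = [(a, _prepare_working(atlas.template(a), working_pixel_size))
             for a in candidates]

    def _score(task):
        a, T_w = task
        return score_candidate(I_w, T_w, a, w, bm_cfg, hist_spec)

    records = parallel_map(_score, tasks, n_workers=n_workers)
    profile = SimilarityProfile(records=records, w=w)
    n_failed = sum(not r.ok for r in profile.records)
    if n_failed > 0.5 * len(profile.records):
        log.warning("%d of %d candidate registrations failed",
                    n_failed, len(profile.records))
    return profile


def locate_single(I_r: PlaneImage, atlas: AtlasStack, w: float = 0.5,
                  search_range: tuple[int, int] | None = None,
                  bm_cfg: BlockMatchConfig = DEFAULT_BLOCKMATCH,
                  hist_spec: HistogramSpec = DEFAULT_HISTOGRAM,
                  working_pixel_size: float = WORKING_PIXEL_SIZE,
                  n_workers: int = 1,
                  with_labels: bool = True) -> LocalizationResult:
    """Localize one experimental slice in the template stack.

    ``search_range`` is an inclusive 1-based interval of template slice
    numbers (defaults to the full stack); restricting it to a known region
    gives the same argmax whenever the similarity peak is interior, at a
    fraction of the registrations.
    """
    N = atlas.n_slices
    lo, hi = search_range if search_range is not None else (1, N)
    if not (1 <= lo <= hi <= N):
        raise ContractError(f"search_range {search_range} outside [1, {N}]")
    profile = sweep_candidates(I_r, atlas, list(range(lo, hi + 1)), w,
                               bm_cfg, hist_spec, working_pixel_size,
                               n_workers)
    z = profile.argmax()
    best = profile.record(z)
    mapped = None
    if with_labels:
        mapped = map_labels(atlas, z, best.theta_rig, best.theta_aff, I_r,
                            working_pixel_size=working_pixel_size)
    return LocalizationResult(z=z, theta_rig=best.theta_rig,
                              theta_aff=best.theta_aff, profile=profile,
                              mapped_labels=mapped)


def map_labels(atlas: AtlasStack, z: int, theta_rig: Transform2D,
               theta_aff: Transform2D, target: PlaneImage,
               working_pixel_size: float = WORKING_PIXEL_SIZE) -> LabelImage:
    """Push the label slice L_z onto the target slice's native grid.

    L_z is resampled to the working resolution, then sampled through the
    composed rigid-affine map with nearest-neighbour interpolation so the
    integer region identifiers are preserved (the mapped value set is a
    subset of L_z's values plus background).
    """
    atlas._check_index(z)
    L = resample_to(atlas.label(z), (working_pixel_size, working_pixel_size))
    full = compose(theta_rig, theta_aff)
    return apply_transform(L, full, "nearest", reference=target)
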