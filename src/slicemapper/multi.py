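"""Joint localization of an ordered multi-slice set.

A region-driven histological protocol yields n ordered slices from one
brain at known physical spacing d_r (µm).  Because an experimental brain and
the template rarely have the same size along the cutting axis, a relative
scaling factor γ converts experimental distances into template distances:
d_t = d_r / γ (γ < 1 shrinkage, γ = 1 same size, γ > 1 enlargement), and the
corresponding whole-slice offset is step = round(d_t / e_t), half away from
zero.

Joint localization then restricts each slice s to the candidate window
[u_s, v_s] with u_s = 1 + step*(s-1) and v_s = N - step*(n-s), pools the
offset-aligned weighted similarity curves with per-slice contribution
weights π_s, takes the pooled argmax as the first-slice position z_m, and
propagates z_s = z_m + step*(s-1).  Setting π_s = 0 excludes an
artifact-laden slice from the pooled estimate while still giving it a
mapped segmentation at its propagated position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .blockmatch import BlockMatchConfig, DEFAULT_BLOCKMATCH
from .imaging import AtlasStack, ContractError, PlaneImage, SliceMapperError
from .phantom import round_half_away
from .similarity import DEFAULT_HISTOGRAM, HistogramSpec
from .single import (LocalizationResult, SimilarityProfile, WORKING_PIXEL_SIZE,
                     locate_single, map_labels, score_candidate,
                     sweep_candidates, _prepare_working)

__all__ = [
    "MultiSliceSpec",
    "MultiSliceResult",
    "ProtocolInfeasibleError",
    "GammaEstimationError",
    "PoolingFailureError",
    "template_distance",
    "slice_range_series",
    "pooled_position",
    "propagate_positions",
    "estimate_gamma",
    "locate_multi",
    "locate_slices",
]

log = logging.getLogger(__name__)


class ProtocolInfeasibleError(SliceMapperError):
    """Too many slices (or too large a spacing) for the template span."""


class GammaEstimationError(SliceMapperError):
    """The scaling-factor regression is unusable (non-positive slope)."""


class PoolingFailureError(SliceMapperError):
    """Every candidate first-slice position is excluded."""


@dataclass
class MultiSliceSpec:
    """An ordered multi-slice study.

    slices: ordered experimental slices I_1..I_n; e_r: experimental slice
    thickness µm; d_r: inter-slice distance(s) µm — a scalar for constant
    spacing or a per-gap list of length n-1; gamma: relative scaling factor
    (> 0) or "auto" to estimate it from a preliminary independent pass;
    pi: per-slice contribution weights (default uniform 1/n).
    """

    slices: list[PlaneImage]
    e_r: float
    d_r: float | list[float]
    gamma: float | str = 1.0
    pi: list[float] | None = None

    def __post_init__(self):
        n = len(self.slices)
        if n < 2:
            raise ContractError("a multi-slice study needs n >= 2")
        if self.e_r <= 0:
            raise ContractError("e_r must be positive")
        gaps = self.gaps()
        if len(gaps) != n - 1:
            raise ContractError(
                f"d_r list has {len(gaps)} entries, expected n-1 = {n - 1}")
        if any(g <= 0 for g in gaps):
            raise ContractError("d_r entries must be positive")
        if isinstance(self.gamma, str):
            if self.gamma != "auto":
                raise ContractError(f"gamma must be positive or 'auto'")
        elif self.gamma <= 0:
            raise ContractError("gamma must be positive")
        if self.pi is None:
            self.pi = [1.0 / n] * n
        if len(self.pi) != n:
            raise ContractError(f"pi has {len(self.pi)} entries, expected {n}")
        if any(p < 0 for p in self.pi) or not any(p > 0 for p in self.pi):
            raise ContractError("pi entries must be >= 0 with at least one > 0")

    @property
    def n(self) -> int:
        return len(self.slices)

    def gaps(self) -> list[float]:
        if np.isscalar(self.d_r):
            return [float(self.d_r)] * (len(self.slices) - 1)
        return [float(g) for g in self.d_r]


@dataclass
class MultiSliceResult:
    """Joint localization outcome."""

    z_m: int
    z_s: list[int]
    per_slice: list[LocalizationResult]
    gamma_used: float
    gamma_r2: float | None
    pooled_curve: dict[int, float]
    clamped: list[bool] = field(default_factory=list)
    ranges: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# the series arithmetic
# ---------------------------------------------------------------------------

def template_distance(d_r: float, gamma: float, e_t: float
                      ) -> tuple[float, int]:
    """Template-space distance and whole-slice step for an experimental gap.

    d_t = d_r / γ converts the physical inter-slice distance into the
    template's metric; step = round_half_away(d_t / e_t) is the matching
    whole number of template slices.  A zero step means the experimental
    slices sit closer than one template slice — the protocol is degenerate.
    """
    if d_r <= 0 or gamma <= 0 or e_t <= 0:
        raise ContractError("d_r, gamma and e_t must all be positive")
    d_t = d_r / gamma
    step = round_half_away(d_t / e_t)
    if step == 0:
        raise ContractError(
            f"degenerate spacing: d_t = {d_t:.1f} µm is below one template "
            f"slice ({e_t} µm)")
    return d_t, step


def _cumulative_offsets(gaps: list[float], gamma: float, e_t: float) -> list[int]:
    """Whole-slice offsets of each slice relative to the first.

    Constant spacing uses the per-gap step times the index (the series
    convention); heterogeneous spacing rounds the cumulative template
    distance at each slice.
    """
    if len(set(gaps)) <= 1:
        if gaps:
            _, step = template_distance(gaps[0], gamma, e_t)
        else:
            step = 0
        return [step * s for s in range(len(gaps) + 1)]
    offsets = [0]
    cum = 0.0
    for g in gaps:
        if g <= 0:
            raise ContractError("d_r entries must be positive")
        cum += g / gamma
        off = int(round_half_away(cum / e_t))
        if off <= offsets[-1]:
            raise ContractError(
                "degenerate spacing: consecutive slices collapse onto the "
                "same template slice")
        offsets.append(off)
    return offsets


def slice_range_series(s: int, n: int, N: int, step: int) -> tuple[int, int]:
    """Candidate window [u_s, v_s] for slice s of n under constant step.

    u_s = 1 + step*(s-1) (the first slice starts at template slice 1) and
    v_s = N - step*(n-s); every slice's window has the same length, so the
    per-slice similarity curves align after shifting by the offsets.
    """
    if not 1 <= s <= n:
        raise ContractError(f"slice index {s} outside [1, {n}]")
    if step < 1:
        raise ContractError("step must be >= 1")
    u_s = 1 + step * (s - 1)
    v_s = N - step * (n - s)
    if u_s > v_s:
        raise ProtocolInfeasibleError(
            f"slice {s}/{n}: window [{u_s}, {v_s}] is empty — the protocol "
            f"spans more than the {N} template slices")
    return u_s, v_s


def _ranges_from_offsets(offsets: list[int], N: int) -> list[tuple[int, int]]:
    total = offsets[-1]
    ranges = []
    for off in offsets:
        u, v = 1 + off, N - (total - off)
        if u > v:
            raise ProtocolInfeasibleError(
                f"candidate window [{u}, {v}] is empty — the protocol spans "
                f"more than the {N} template slices")
        ranges.append((u, v))
    return ranges


# ---------------------------------------------------------------------------
# pooling and propagation
# ---------------------------------------------------------------------------

def pooled_position(profiles: list[SimilarityProfile], pi: list[float],
                    step: int | None = None,
                    offsets: list[int] | None = None
                    ) -> tuple[int, dict[int, float]]:
    """Pooled first-slice position from offset-aligned similarity curves.

    For each candidate first-slice position c, the pooled score is
    (1/n) * Σ_s π_s * s_w^(s)(c + offset_s); failed records contribute
    nothing and their π mass is renormalised at that candidate.  Candidates
    where every slice failed are excluded.  Returns the argmax (smallest c
    on exact ties) and the whole pooled curve.
    """
    n = len(profiles)
    if n == 0:
        raise ContractError("pooled_position needs at least one profile")
    if len(pi) != n:
        raise ContractError("pi length must match the number of profiles")
    if offsets is None:
        if step is None:
            raise ContractError("pass either step or offsets")
        offsets = [step * s for s in range(n)]
    lengths = {len(p.records) for p in profiles}
    if len(lengths) != 1:
        raise ContractError("all restricted profiles must cover equal-length "
                            "candidate windows")
    total_pi = sum(pi)
    first = profiles[0].candidates()
    curve: dict[int, float] = {}
    for c in first:
        num = 0.0
        active = 0.0
        for s, prof in enumerate(profiles):
            try:
                rec = prof.record(c + offsets[s])
            except ContractError:
                raise ContractError(
                    f"profile {s + 1} does not cover candidate "
                    f"{c + offsets[s]}")
            if rec.ok:
                num += pi[s] * rec.s_w
                active += pi[s]
        if active > 0:
            # renormalise the π mass of failed slices onto the active ones
            curve[c] = (num / active) * (total_pi / n)
    if not curve:
        raise PoolingFailureError("every candidate position is excluded")
    z_m = min(curve, key=lambda c: (-curve[c], c))
    return z_m, curve


def propagate_positions(z_m: int, n: int, step: int | None = None,
                        N: int | None = None,
                        offsets: list[int] | None = None
                        ) -> tuple[list[int], list[bool]]:
    """Propagate the pooled first-slice position to the whole series.

    z_s = z_m + offset_s with z_1 = z_m; positions outside [1, N] are
    clamped and flagged rather than fatal.
    """
    if offsets is None:
        if step is None:
            raise ContractError("pass either step or offsets")
        offsets = [step * s for s in range(n)]
    z_s, clamped = [], []
    for off in offsets[:n]:
        z = z_m + off
        flag = False
        if N is not None:
            if z < 1:
                z, flag = 1, True
            elif z > N:
                z, flag = N, True
        z_s.append(int(z))
        clamped.append(flag)
    if any(clamped):
        log.warning("propagated positions clamped to [1, %s]: %s", N, z_s)
    return z_s, clamped


# ---------------------------------------------------------------------------
# scaling-factor estimation
# ---------------------------------------------------------------------------

def estimate_gamma(independent_z: list[float], d_r: float, e_t: float
                   ) -> tuple[float, float]:
    """Estimate γ from independent per-slice position estimates.

    Fits the line t = m*(r-1) + t_1 over the slice index r by ordinary
    least squares; the slope m is the template-slice spacing of the series,
    so γ = d_r / (m * e_t).  Returns (γ, R²); an R² below 0.97 is logged as
    a warning — a sound series regression is typically above that.
    """
    t = np.asarray(independent_z, dtype=float)
    if len(t) < 3 or not np.all(np.isfinite(t)):
        raise ContractError("estimate_gamma needs >= 3 finite estimates")
    if d_r <= 0 or e_t <= 0:
        raise ContractError("d_r and e_t must be positive")
    r = np.arange(len(t), dtype=float)
    slope, intercept = np.polyfit(r, t, 1)
    if slope <= 0:
        raise GammaEstimationError(
            f"non-positive slope {slope:.3f}: slices are not ordered along "
            "the cutting axis")
    fitted = slope * r + intercept
    ss_res = float(((t - fitted) ** 2).sum())
    ss_tot = float(((t - t.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < 0.97:
        log.warning("gamma regression R² = %.3f is below 0.97; the estimate "
                    "may be unreliable", r2)
    gamma = d_r / (slope * e_t)
    return float(gamma), r2


# ---------------------------------------------------------------------------
# joint localization
# ---------------------------------------------------------------------------

def locate_multi(spec: MultiSliceSpec, atlas: AtlasStack, w: float = 0.5,
                 bm_cfg: BlockMatchConfig = DEFAULT_BLOCKMATCH,
                 hist_spec: HistogramSpec = DEFAULT_HISTOGRAM,
                 working_pixel_size: float = WORKING_PIXEL_SIZE,
                 n_workers: int = 1,
                 with_labels: bool = True) -> MultiSliceResult:
    """Jointly localize an ordered multi-slice set in the template stack.

    With gamma="auto" a preliminary full-range single-slice pass per slice
    feeds :func:`estimate_gamma`.  Each slice is then scored only over its
    restricted window, the offset-aligned curves are pooled with the π
    weights, and positions propagate from the pooled argmax.  Final
    transforms come from each slice's cached record at its propagated
    position (re-registered only if that record failed), and labels are
    mapped per slice.
    """
    N = atlas.n_slices
    gamma_r2 = None
    if spec.gamma == "auto":
        if spec.n < 3:
            raise ContractError("gamma='auto' needs n >= 3 slices")
        gaps = spec.gaps()
        if len(set(gaps)) != 1:
            raise ContractError("gamma='auto' requires constant d_r")
        prelim = [locate_single(img, atlas, w, bm_cfg=bm_cfg,
                                hist_spec=hist_spec,
                                working_pixel_size=working_pixel_size,
                                n_workers=n_workers, with_labels=False).z
                  for img in spec.slices]
        gamma, gamma_r2 = estimate_gamma(prelim, gaps[0], atlas.e_t)
    else:
        gamma = float(spec.gamma)

    offsets = _cumulative_offsets(spec.gaps(), gamma, atlas.e_t)
    ranges = _ranges_from_offsets(offsets, N)

    profiles = []
    for img, (u, v) in zip(spec.slices, ranges):
        profiles.append(sweep_candidates(img, atlas, list(range(u, v + 1)), w,
                                         bm_cfg, hist_spec,
                                         working_pixel_size, n_workers))
    z_m, curve = pooled_position(profiles, spec.pi, offsets=offsets)
    z_s, clamped = propagate_positions(z_m, spec.n, N=N, offsets=offsets)

    per_slice = []
    for s, (img, prof, z) in enumerate(zip(spec.slices, profiles, z_s)):
        rec = None
        if z in prof.candidates():
            rec = prof.record(z)
        if rec is None or not rec.ok:
            # the cached record is missing (clamped position) or failed:
            # re-register this single candidate
            I_w = _prepare_working(img, working_pixel_size)
            T_w = _prepare_working(atlas.template(z), working_pixel_size)
            rec = score_candidate(I_w, T_w, z, w, bm_cfg, hist_spec)
        mapped = None
        if rec.ok and with_labels:
            mapped = map_labels(atlas, z, rec.theta_rig, rec.theta_aff, img,
                                working_pixel_size=working_pixel_size)
        elif not rec.ok:
            log.warning("slice %d: mapping failed at z=%d: %s",
                        s + 1, z, rec.message)
        per_slice.append(LocalizationResult(
            z=z, theta_rig=rec.theta_rig, theta_aff=rec.theta_aff,
            profile=prof, mapped_labels=mapped))
    return MultiSliceResult(z_m=z_m, z_s=z_s, per_slice=per_slice,
                            gamma_used=gamma, gamma_r2=gamma_r2,
                            pooled_curve=curve, clamped=clamped,
                            ranges=ranges)


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def locate_slices(slices: list[PlaneImage], atlas: AtlasStack,
                  spec: MultiSliceSpec | None = None, w: float = 0.5,
                  s_star: int | None = None,
                  **kwargs) -> LocalizationResult | MultiSliceResult:
    """Generic dispatcher over the number of slices.

    n = 1 runs single-slice localization; n >= 2 runs the joint multi-slice
    method (which requires ``spec``).  When n reaches the 3D-reconstruction
    threshold ``s_star`` a notice is logged — full 3D reconstruction is not
    part of this tool.
    """
    n = len(slices)
    if n == 0:
        raise ContractError("no slices given")
    if n == 1:
        return locate_single(slices[0], atlas, w, **kwargs)
    if spec is None:
        raise ContractError("multi-slice localization needs a MultiSliceSpec")
    if list(spec.slices) != list(slices):
        raise ContractError("spec.slices must match the given slice list")
    if s_star is not None and n >= s_star:
        log.info("n = %d >= S* = %d slices: enough for 3D reconstruction, "
                 "which is outside this tool's scope; running joint "
                 "localization", n, s_star)
    return locate_multi(spec, atlas, w, **kwargs)
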