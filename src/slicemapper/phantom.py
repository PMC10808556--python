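"""Synthetic atlas and experimental-slice generator with known ground truth.

The phantom emulates the structure the pipeline relies on in a real
template: a smooth brain-like outline whose size and internal region
geometry vary smoothly and monotonically along the slice axis (so the
similarity profile has a unique peak), an ordered integer label volume
aligned with the template, and experimental slices derived from a known
template position through a known linear transform, a monotone intensity
remap (emulating a different imaging modality), Gaussian noise and optional
histological artifacts (tissue folding, missing tissue, external noise).

Every dataset carries its generating parameters back out as a
:class:`GroundTruth`, which plays the role an expert rating plays for real
data: the reference z-position, transform and scaling factor against which
the method is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .imaging import (AtlasStack, ContractError, LabelImage, PlaneImage,
                      Transform2D, apply_transform)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "REGION_LEGEND",
    "make_phantom_atlas",
    "make_experimental_slice",
    "make_multislice_set",
    "sample_transform",
    "round_half_away",
]

REGION_LEGEND = {
    1: "parenchyma",
    2: "cortical shell",
    3: "deep nucleus",
    4: "small nucleus",
}


def round_half_away(x) -> np.ndarray | int:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1)."""
    arr = np.sign(x) * np.floor(np.abs(x) + 0.5)
    if np.isscalar(x):
        return int(arr)
    return arr.astype(int)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic atlas.

    N: template slice count; shape: (rows, cols) pixels; pixel_size µm
    (in-plane); e_t µm (slice thickness); n_regions: labelled regions
    (4 = parenchyma, cortex-like shell, deep nucleus, small nucleus at
    <1% of tissue pixels); texture_amplitude: amplitude of the smooth 3D
    texture field riding on the per-region base intensities; seed: RNG seed
    for the (deterministic) texture.
    """

    N: int = 60
    shape: tuple[int, int] = (96, 96)
    pixel_size: float = 25.0
    e_t: float = 100.0
    n_regions: int = 4
    texture_amplitude: float = 0.16
    seed: int = 0

    def __post_init__(self):
        if self.N < 2 or min(self.shape) < 16:
            raise ContractError("phantom needs N >= 2 and shape >= 16 px")
        if not 1 <= self.n_regions <= 4:
            raise ContractError("n_regions must be in [1, 4]")
        if self.pixel_size <= 0 or self.e_t <= 0:
            raise ContractError("pixel_size and e_t must be positive")


@dataclass
class GroundTruth:
    """Generating parameters of a phantom dataset (the evaluation reference)."""

    z_star: list[int]
    theta_star: list[Transform2D]
    gamma_star: float = 1.0
    region_masks: list[LabelImage] = field(default_factory=list)
    seed: int | None = None


# ---------------------------------------------------------------------------
# atlas generation
# ---------------------------------------------------------------------------

def _slice_geometry(t: float, shape: tuple[int, int]):
    """Normalised coordinate grids and outline parameters at axis position t."""
    h, w = shape
    y = (np.arange(h) - (h - 1) / 2.0) / ((h - 1) / 2.0)
    x = (np.arange(w) - (w - 1) / 2.0) / ((w - 1) / 2.0)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    growth = 0.70 + 0.30 * t           # monotone size growth along the axis
    ay, ax = 0.58 * growth, 0.72 * growth
    p = 2.5                            # super-ellipse exponent
    rho = (np.abs(yy / ay) ** p + np.abs(xx / ax) ** p) ** (1.0 / p)
    return yy / ay, xx / ax, rho       # outline-relative coordinates


def _slice_labels(t: float, shape: tuple[int, int], n_regions: int) -> np.ndarray:
    Y, X, rho = _slice_geometry(t, shape)
    labels = np.zeros(shape, dtype=np.int32)
    tissue = rho <= 1.0
    labels[tissue] = 1
    if n_regions >= 2:                 # cortex-like shell
        labels[tissue & (rho >= 0.72)] = 2
    if n_regions >= 3:                 # deep nucleus, drifting with t
        cy, cx = -0.12 + 0.24 * t, -0.28 + 0.10 * t
        ry, rx = 0.45 + 0.06 * t, 0.52 + 0.05 * t
        blob = ((Y - cy) / ry) ** 2 + ((X - cx) / rx) ** 2 <= 1.0
        labels[tissue & blob & (rho < 0.72)] = 3
    if n_regions >= 4:                 # small nucleus, < 1% of tissue pixels
        cy, cx = 0.30 - 0.12 * t, 0.34
        r = 0.085
        small = ((Y - cy) / r) ** 2 + ((X - cx) / r) ** 2 <= 1.0
        labels[tissue & small & (rho < 0.72)] = 4
    return labels


_BASE_INTENSITY = {0: 0.0, 1: 0.40, 2: 0.62, 3: 0.80, 4: 0.95}


def make_phantom_atlas(spec: PhantomSpec = PhantomSpec()) -> AtlasStack:
    """Generate a synthetic template + label stack, deterministic per seed.

    Intensities combine per-region base levels, a smooth in-plane modulation
    drifting with the slice position, and a smooth seeded 3D texture field,
    so blocks carry variance for cross-correlation matching and adjacent
    slices differ (z is identifiable) while neighbours stay similar.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    texture = ndi.gaussian_filter(
        rng.standard_normal((spec.N, h, w)), sigma=(1.0, 1.8, 1.8))
    texture *= spec.texture_amplitude / max(np.abs(texture).max(), 1e-12)

    templates, labels = [], []
    ps = (spec.pixel_size, spec.pixel_size)
    for a in range(1, spec.N + 1):
        t = (a - 0.5) / spec.N
        lab = _slice_labels(t, spec.shape, spec.n_regions)
        Y, X, rho = _slice_geometry(t, spec.shape)
        base = np.vectorize(_BASE_INTENSITY.get, otypes=[float])(lab)
        mod = (0.12 * np.sin((2.4 + 1.5 * t) * X + 4.0 * t)
               * np.cos((2.1 + 1.2 * t) * Y - 3.0 * t))
        tissue = lab > 0
        pix = np.where(tissue,
                       np.clip(base + mod + texture[a - 1], 0.05, 1.0), 0.0)
        templates.append(PlaneImage(pix, ps, name=f"phantom_T_{a}"))
        labels.append(LabelImage(lab, ps, legend=dict(REGION_LEGEND),
                                 name=f"phantom_L_{a}"))
    return AtlasStack(templates=templates, labels=labels,
                      e_t=spec.e_t, axis="coronal")


# ---------------------------------------------------------------------------
# experimental slices
# ---------------------------------------------------------------------------

_MODALITY_MAPS = {
    "identity": lambda v: v,
    "gamma": lambda v: v ** 0.6,
    "sqrt": lambda v: np.sqrt(v),
    "inverted": None,  # handled specially: monotone decreasing on tissue
}


def _remap_modality(pixels: np.ndarray, modality_map: str) -> np.ndarray:
    """Monotone intensity remap on the tissue, background stays 0."""
    if modality_map not in _MODALITY_MAPS:
        raise ContractError(f"unknown modality_map {modality_map!r}")
    tissue = pixels > 0
    out = np.zeros_like(pixels)
    if modality_map == "inverted":
        if tissue.any():
            lo, hi = pixels[tissue].min(), pixels[tissue].max()
            out[tissue] = lo + hi - pixels[tissue]
    else:
        out[tissue] = _MODALITY_MAPS[modality_map](pixels[tissue])
    return out


def sample_transform(rng: np.random.Generator, rotation_deg=(2.0, 5.0),
                     translation_um: float = 450.0,
                     scale_range: tuple[float, float] | None = None,
                     shear: float = 0.0) -> Transform2D:
    """Draw a random perturbation transform (pull-back convention).

    Rotation magnitude uniform in ``rotation_deg`` with random sign;
    translation direction uniform, magnitude uniform in
    [0.2, 1] x ``translation_um``; optional anisotropic scales and shear
    promote the result to an affine map.
    """
    angle = rng.uniform(*rotation_deg) * rng.choice([-1.0, 1.0])
    direction = rng.uniform(0, 2 * np.pi)
    mag = rng.uniform(0.2, 1.0) * translation_um
    offset = mag * np.array([np.sin(direction), np.cos(direction)])
    T = Transform2D.rigid(angle, offset)
    if scale_range is None and shear == 0.0:
        return T
    sy = rng.uniform(*scale_range) if scale_range else 1.0
    sx = rng.uniform(*scale_range) if scale_range else 1.0
    sh = rng.uniform(-shear, shear) if shear else 0.0
    lin = T.linear @ np.array([[sy, sh], [0.0, sx]])
    return Transform2D(kind="affine", linear=lin, offset=offset)


def _apply_artifact(pixels: np.ndarray, artifact: str,
                    rng: np.random.Generator) -> np.ndarray:
    out = pixels.copy()
    tissue = out > 0
    if not tissue.any():
        return out
    rows = np.where(tissue.any(axis=1))[0]
    cols = np.where(tissue.any(axis=0))[0]
    if artifact == "fold":
        # locally mirrored band: a strip of tissue is replaced by the mirror
        # image of the strip just above it
        height = max(4, (rows[-1] - rows[0]) // 6)
        r0 = int(rng.integers(rows[0] + height, rows[-1] - height))
        out[r0:r0 + height] = out[r0 - height:r0][::-1]
    elif artifact == "missing":
        # zeroed wedge from the foreground centroid, 5-25% of the tissue
        cy, cx = np.argwhere(tissue).mean(axis=0)
        yy, xx = np.mgrid[0:out.shape[0], 0:out.shape[1]]
        angle = np.arctan2(yy - cy, xx - cx)
        start = rng.uniform(-np.pi, np.pi)
        for width in np.deg2rad([50, 70, 90, 110]):
            diff = np.angle(np.exp(1j * (angle - start)))
            wedge = (diff >= 0) & (diff < width)
            frac = (wedge & tissue).sum() / tissue.sum()
            if 0.05 <= frac <= 0.25:
                break
        out[wedge & tissue] = 0.0
    elif artifact == "noise":
        # salt-speckle patch over part of the tissue
        h = max(8, (rows[-1] - rows[0]) // 3)
        w = max(8, (cols[-1] - cols[0]) // 3)
        r0 = int(rng.integers(rows[0], max(rows[0] + 1, rows[-1] - h)))
        c0 = int(rng.integers(cols[0], max(cols[0] + 1, cols[-1] - w)))
        salt = rng.random((h, w)) < 0.5
        patch = out[r0:r0 + h, c0:c0 + w]
        patch[salt[:patch.shape[0], :patch.shape[1]]] = 1.0
    else:
        raise ContractError(f"unknown artifact {artifact!r}")
    return out


def make_experimental_slice(atlas: AtlasStack, z_star: int,
                            theta_star: Transform2D | None = None,
                            noise_sigma: float = 0.0,
                            modality_map: str = "identity",
                            artifact: str | None = None,
                            rng: np.random.Generator | int | None = None
                            ) -> tuple[PlaneImage, GroundTruth]:
    """Derive an experimental slice from template position ``z_star``.

    Chain: template slice -> monotone intensity remap (multimodality) ->
    ``theta_star`` warp (pull-back: the transform registration should
    recover) -> Gaussian noise at ``noise_sigma`` x dynamic range ->
    optional artifact.  The ground-truth region masks are the label slice
    warped through the same transform.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if theta_star is None:
        theta_star = Transform2D.identity()
    atlas._check_index(z_star)
    template = atlas.template(z_star)
    if not (np.all(theta_star.scales() >= 0.8)
            and np.all(theta_star.scales() <= 1.25)
            and abs(theta_star.rotation_deg()) <= 10.0):
        raise ContractError(
            "theta_star outside the realistic range (rotation <= 10 deg, "
            "scales in [0.8, 1.25])")

    pixels = _remap_modality(template.pixels, modality_map)
    remapped = PlaneImage(pixels, template.pixel_size, origin=template.origin)
    # sample the remapped template through theta_star: the experimental slice
    # equals the template seen through the inverse motion, so registering the
    # template onto it recovers theta_star
    warped = apply_transform(remapped, theta_star, "linear", reference=template)
    out = warped.pixels
    if noise_sigma > 0:
        rng_noise = rng.normal(0.0, noise_sigma * max(out.max(), 1e-12),
                               size=out.shape)
        out = np.clip(out + rng_noise, 0.0, 1.0)
    if artifact is not None:
        out = _apply_artifact(out, artifact, rng)
    image = PlaneImage(out, template.pixel_size, origin=template.origin,
                       name=f"phantom_slice_z{z_star}")
    masks = apply_transform(atlas.label(z_star), theta_star, "nearest",
                            reference=template)
    truth = GroundTruth(z_star=[z_star], theta_star=[theta_star],
                        region_masks=[masks])
    return image, truth


# ---------------------------------------------------------------------------
# multi-slice protocols
# ---------------------------------------------------------------------------

def make_multislice_set(atlas: AtlasStack, z_start: int, d_r: float,
                        gamma_star: float = 1.0, n: int = 5,
                        e_r: float = 20.0,
                        perturbations: list[Transform2D] | None = None,
                        noise_sigma: float = 0.0,
                        modality_map: str = "identity",
                        artifacts: dict[int, str] | None = None,
                        rotation_deg=(2.0, 5.0), translation_um: float = 400.0,
                        scale_range: tuple[float, float] | None = None,
                        rng: np.random.Generator | int | None = None):
    """Generate an ordered multi-slice protocol with known ground truth.

    True positions follow the series convention
    ``z*_s = z_start + round((s-1) * d_r / (gamma_star * e_t))``; each slice
    is produced by :func:`make_experimental_slice` with an independent
    perturbation.  ``artifacts`` maps 1-based slice indices to artifact
    names.  Returns ``(slices, ground_truth)`` where ``slices`` is the
    ordered list of :class:`PlaneImage`; wrap it in a
    :class:`slicemapper.multi.MultiSliceSpec` to run joint localization.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if n < 1:
        raise ContractError("n must be >= 1")
    if d_r <= 0 or gamma_star <= 0:
        raise ContractError("d_r and gamma_star must be positive")
    z_true = [z_start + round_half_away((s - 1) * d_r / (gamma_star * atlas.e_t))
              for s in range(1, n + 1)]
    if z_true[0] < 1 or z_true[-1] > atlas.n_slices:
        raise ContractError(
            f"protocol positions {z_true} exceed template range "
            f"[1, {atlas.n_slices}]")
    artifacts = artifacts or {}
    slices, thetas, masks = [], [], []
    for s, z in enumerate(z_true, start=1):
        theta = (perturbations[s - 1] if perturbations is not None
                 else sample_transform(rng, rotation_deg, translation_um,
                                       scale_range))
        img, gt = make_experimental_slice(
            atlas, z, theta, noise_sigma=noise_sigma,
            modality_map=modality_map, artifact=artifacts.get(s), rng=rng)
        img.name = f"phantom_slice_s{s}_z{z}"
        slices.append(img)
        thetas.append(theta)
        masks.append(gt.region_masks[0])
    truth = GroundTruth(z_star=z_true, theta_star=thetas,
                        gamma_star=gamma_star, region_masks=masks)
    return slices, truth
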