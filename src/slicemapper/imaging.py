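"""Image and atlas data model, file I/O, resampling and transform application.

All geometry is expressed in physical micrometres with a pixel-centre
convention: the centre of pixel ``(i, j)`` sits at
``origin + (i, j) * pixel_size`` (row = first axis).  Slice numbers are
1-based externally, matching the convention ``a = 1..N`` for an atlas of N
coronal template slices; arrays are of course indexed 0-based internally.

Transforms follow the pull-back (resampling) convention: a
:class:`Transform2D` maps a point of the *reference* space to the sampling
point in the *test* image, so warping a test image through a transform
produces an image laid out on the reference grid.  This matches the pipeline
choice of registering template slices (test) onto the experimental slice
(reference) so that propagated labels land in the slice's native geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "SliceMapperError",
    "AlignmentError",
    "FormatError",
    "DegenerateImageError",
    "CenteringError",
    "ContractError",
    "PlaneImage",
    "LabelImage",
    "AtlasStack",
    "Transform2D",
    "compose",
    "load_atlas",
    "save_atlas",
    "load_plane_image",
    "load_label_image",
    "save_plane_image",
    "save_label_image",
    "resample_to",
    "center_images",
    "apply_transform",
    "save_transform",
    "load_transform",
    "save_legend",
    "load_legend",
]


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class SliceMapperError(Exception):
    """Base class for all package errors."""


class AlignmentError(SliceMapperError):
    """Template and label volumes do not share a voxel grid."""


class FormatError(SliceMapperError):
    """A file's content violates the expected format."""


class DegenerateImageError(SliceMapperError):
    """An operation would produce or received a degenerate image."""


class CenteringError(SliceMapperError):
    """Foreground extraction failed during automated centering."""


class ContractError(SliceMapperError):
    """An argument violates an operation's contract."""


MIN_DIM = 8  # smallest admissible image side, in pixels


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _as_pixel_size(value) -> tuple[float, float]:
    if np.isscalar(value):
        value = (float(value), float(value))
    h, w = float(value[0]), float(value[1])
    if h <= 0 or w <= 0:
        raise ContractError(f"pixel_size must be positive, got {(h, w)}")
    return (h, w)


@dataclass
class PlaneImage:
    """A 2D scalar image with a physical pixel size.

    ``pixels`` holds finite real intensities; ``pixel_size`` is
    ``(row µm, col µm)``; ``origin`` is the physical coordinate of the centre
    of pixel ``(0, 0)`` in µm.
    """

    pixels: np.ndarray
    pixel_size: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    name: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ContractError(f"{self.name or 'image'}: expected 2D pixels")
        if min(self.pixels.shape) < MIN_DIM:
            raise DegenerateImageError(
                f"{self.name or 'image'}: both dimensions must be >= {MIN_DIM}, "
                f"got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError(f"{self.name or 'image'}: non-finite intensities")
        self.pixel_size = _as_pixel_size(self.pixel_size)
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def physical_extent(self) -> tuple[float, float]:
        """Physical size (row µm, col µm) covered by the pixel grid."""
        return (self.shape[0] * self.pixel_size[0],
                self.shape[1] * self.pixel_size[1])

    def center(self) -> np.ndarray:
        """Physical coordinate of the grid centre in µm."""
        return (np.asarray(self.origin)
                + (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
                * np.asarray(self.pixel_size))

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.pixel_size, other.pixel_size)
                and np.allclose(self.origin, other.origin))


@dataclass
class LabelImage:
    """A 2D grid of non-negative integer region identifiers (0 = background)."""

    labels: np.ndarray
    pixel_size: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    legend: dict[int, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise FormatError(f"{self.name or 'labels'}: non-integer labels")
            arr = arr.astype(np.int32)
        if arr.ndim != 2:
            raise ContractError(f"{self.name or 'labels'}: expected 2D labels")
        if arr.min(initial=0) < 0:
            raise FormatError(f"{self.name or 'labels'}: negative labels")
        self.labels = arr.astype(np.int32)
        self.pixel_size = _as_pixel_size(self.pixel_size)
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if self.legend:
            extra = set(np.unique(self.labels)) - set(self.legend) - {0}
            if extra:
                raise FormatError(
                    f"{self.name or 'labels'}: ids {sorted(extra)} missing from legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def value_set(self) -> set[int]:
        return set(int(v) for v in np.unique(self.labels))

    def physical_extent(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_size[0],
                self.shape[1] * self.pixel_size[1])

    def center(self) -> np.ndarray:
        return (np.asarray(self.origin)
                + (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
                * np.asarray(self.pixel_size))

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.pixel_size, other.pixel_size)
                and np.allclose(self.origin, other.origin))


@dataclass
class AtlasStack:
    """Ordered template slices with voxel-aligned label slices.

    ``templates[a-1]`` and ``labels[a-1]`` are the template and label slice
    at position ``a`` (1-based); ``e_t`` is the slice thickness in µm.
    """

    templates: list[PlaneImage]
    labels: list[LabelImage]
    e_t: float
    axis: str = "coronal"

    def __post_init__(self):
        if len(self.templates) != len(self.labels):
            raise AlignmentError(
                f"{len(self.templates)} template slices vs "
                f"{len(self.labels)} label slices")
        if len(self.templates) < 2:
            raise ContractError("an atlas needs at least 2 slices")
        if self.e_t <= 0:
            raise ContractError("slice thickness e_t must be positive")
        for a, (t, l) in enumerate(zip(self.templates, self.labels), start=1):
            if t.shape != l.shape or not np.allclose(t.pixel_size, l.pixel_size):
                raise AlignmentError(f"slice {a}: template/label geometry mismatch")

    @property
    def n_slices(self) -> int:
        return len(self.templates)

    def template(self, a: int) -> PlaneImage:
        """Template slice at 1-based position ``a``."""
        self._check_index(a)
        return self.templates[a - 1]

    def label(self, a: int) -> LabelImage:
        """Label slice at 1-based position ``a``."""
        self._check_index(a)
        return self.labels[a - 1]

    def _check_index(self, a: int):
        if not (1 <= a <= self.n_slices):
            raise ContractError(
                f"slice number {a} outside [1, {self.n_slices}]")


@dataclass(frozen=True)
class Transform2D:
    """A 2D linear map in physical µm coordinates (pull-back convention).

    ``p_test = linear @ p_ref + offset`` gives, for each reference-space
    point, the test-space point to sample when warping the test image onto
    the reference grid.
    """

    kind: str  # translation | rigid | affine
    linear: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        lin = np.asarray(self.linear, dtype=np.float64).reshape(2, 2)
        off = np.asarray(self.offset, dtype=np.float64).reshape(2)
        if not (np.all(np.isfinite(lin)) and np.all(np.isfinite(off))):
            raise ContractError("non-finite transform parameters")
        if self.kind not in ("translation", "rigid", "affine"):
            raise ContractError(f"unknown transform kind {self.kind!r}")
        if self.kind == "translation" and not np.allclose(lin, np.eye(2), atol=1e-9):
            raise ContractError("translation transform must have identity linear part")
        if self.kind == "rigid":
            if (not np.allclose(lin.T @ lin, np.eye(2), atol=1e-6)
                    or abs(np.linalg.det(lin) - 1.0) > 1e-6):
                raise ContractError("rigid linear part must be a proper rotation")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "offset", off)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity(kind: str = "translation") -> "Transform2D":
        return Transform2D(kind=kind)

    @staticmethod
    def translation(offset_um) -> "Transform2D":
        return Transform2D(kind="translation", offset=np.asarray(offset_um, float))

    @staticmethod
    def rigid(angle_deg: float, offset_um=(0.0, 0.0)) -> "Transform2D":
        th = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return Transform2D(kind="rigid", linear=rot, offset=np.asarray(offset_um, float))

    @staticmethod
    def affine(linear, offset_um=(0.0, 0.0)) -> "Transform2D":
        return Transform2D(kind="affine", linear=np.asarray(linear, float),
                           offset=np.asarray(offset_um, float))

    # -- algebra -----------------------------------------------------------
    def __call__(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.linear.T + self.offset

    def inverse(self) -> "Transform2D":
        inv = np.linalg.inv(self.linear)
        return Transform2D(kind=self.kind, linear=inv, offset=-inv @ self.offset)

    def rotation_deg(self) -> float:
        """Rotation angle of the linear part (polar decomposition), degrees."""
        u, _, vt = np.linalg.svd(self.linear)
        rot = u @ vt
        if np.linalg.det(rot) < 0:  # reflective part, report the closest rotation
            u = u.copy()
            u[:, -1] *= -1
            rot = u @ vt
        return float(np.rad2deg(np.arctan2(rot[1, 0], rot[0, 0])))

    def scales(self) -> np.ndarray:
        """Singular values of the linear part (anisotropic scale factors)."""
        return np.linalg.svd(self.linear, compute_uv=False)

    def as_kind(self, kind: str) -> "Transform2D":
        return Transform2D(kind=kind, linear=self.linear, offset=self.offset)


def compose(outer: Transform2D, inner: Transform2D) -> Transform2D:
    """Function composition ``p -> outer(inner(p))``.

    ``compose(theta_rig, theta_aff)`` is the full sampling map of a template
    slice registered rigidly then refined affinely: the reference point is
    first sent through the affine increment, then through the rigid map.
    """
    kinds = {outer.kind, inner.kind}
    if "affine" in kinds:
        kind = "affine"
    elif "rigid" in kinds:
        kind = "rigid"
    else:
        kind = "translation"
    return Transform2D(kind=kind,
                       linear=outer.linear @ inner.linear,
                       offset=outer.linear @ inner.offset + outer.offset)


# ---------------------------------------------------------------------------
# intensity normalisation
# ---------------------------------------------------------------------------

def normalize_intensities(pixels: np.ndarray) -> np.ndarray:
    """Min-max normalise to [0, 1]; a constant image maps to all zeros."""
    pixels = np.asarray(pixels, dtype=np.float64)
    lo, hi = pixels.min(), pixels.max()
    if hi <= lo:
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# atlas I/O (NIfTI volumes)
# ---------------------------------------------------------------------------

def _load_nifti(path):
    import nibabel as nib
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return data, zooms


_AXIS_INDEX = {"coronal": 0, "axial": 0, "sagittal": 0}
# Volumes are decomposed along their first array axis; the ``axis`` argument
# records the anatomical incidence of that axis.  Reordering volumes so the
# cutting axis comes first is the caller's responsibility (nibabel's
# as_closest_canonical plus a transpose covers the standard cases).


def load_atlas(template_path, labels_path, axis: str = "coronal") -> AtlasStack:
    """Load a template volume and its aligned integer label volume.

    Both files must be 3D volumes on an identical voxel grid.  The volume is
    decomposed along the first array axis into an ordered slice sequence with
    1-based numbering ``a = 1..N``; the voxel size along that axis becomes
    the slice thickness ``e_t`` and the in-plane voxel sizes become the
    per-slice ``pixel_size``.  Template intensities are min-max normalised to
    [0, 1] over the whole volume.
    """
    tdata, tzooms = _load_nifti(template_path)
    ldata, lzooms = _load_nifti(labels_path)
    if tdata.ndim != 3 or ldata.ndim != 3:
        raise FormatError("atlas volumes must be 3D")
    if tdata.shape != ldata.shape:
        raise AlignmentError(
            f"template shape {tdata.shape} != labels shape {ldata.shape}")
    if not np.allclose(tzooms, lzooms, rtol=1e-4):
        raise AlignmentError(
            f"template zooms {tzooms} != labels zooms {lzooms}")
    if not np.issubdtype(ldata.dtype, np.integer):
        if not np.all(ldata == np.round(ldata)):
            raise FormatError(f"labels volume {labels_path} is not integer-valued")
        ldata = ldata.astype(np.int32)
    tdata = normalize_intensities(tdata.astype(np.float64))
    e_t = float(tzooms[0])
    pixel_size = (float(tzooms[1]), float(tzooms[2]))
    templates = [PlaneImage(tdata[a], pixel_size, name=f"T_{a + 1}")
                 for a in range(tdata.shape[0])]
    labels = [LabelImage(ldata[a], pixel_size, name=f"L_{a + 1}")
              for a in range(ldata.shape[0])]
    return AtlasStack(templates=templates, labels=labels, e_t=e_t, axis=axis)


def save_atlas(stack: AtlasStack, template_path, labels_path) -> None:
    """Write an atlas back to a NIfTI template/labels volume pair."""
    import nibabel as nib
    tvol = np.stack([t.pixels for t in stack.templates])
    lvol = np.stack([l.labels for l in stack.labels]).astype(np.int32)
    ps = stack.templates[0].pixel_size
    affine = np.diag([stack.e_t, ps[0], ps[1], 1.0])
    nib.save(nib.Nifti1Image(tvol, affine), str(template_path))
    nib.save(nib.Nifti1Image(lvol, affine), str(labels_path))


# ---------------------------------------------------------------------------
# 2D slice I/O
# ---------------------------------------------------------------------------

def _read_2d(path):
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        data, zooms = _load_nifti_2d(path)
        return data, zooms
    if path.endswith((".tif", ".tiff")):
        import tifffile
        return tifffile.imread(path), None
    import imageio.v3 as iio
    return iio.imread(path), None


def _load_nifti_2d(path):
    import nibabel as nib
    img = nib.load(path)
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 2:
        raise FormatError(f"{path}: expected a single 2D slice")
    zooms = img.header.get_zooms()[:2]
    return data, (float(zooms[0]), float(zooms[1]))


def _to_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # RGB(A) -> single channel
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise FormatError(f"cannot interpret array of shape {arr.shape} as 2D")
    return arr.astype(np.float64)


def load_plane_image(path, pixel_size=None, name: str = "") -> PlaneImage:
    """Load a grayscale 2D slice (PNG, TIFF or single-slice NIfTI).

    ``pixel_size`` (µm) is required for raster formats that carry no physical
    metadata; for NIfTI it defaults to the header zooms.  Intensities are
    min-max normalised to [0, 1].
    """
    data, zooms = _read_2d(path)
    if pixel_size is None:
        if zooms is None:
            raise ContractError(f"{path}: pixel_size required for this format")
        pixel_size = zooms
    return PlaneImage(normalize_intensities(_to_gray(data)), pixel_size,
                      name=name or str(path))


def load_label_image(path, pixel_size=None, legend=None, name: str = "") -> LabelImage:
    """Load a 2D label map (integer-valued PNG/TIFF/NIfTI)."""
    data, zooms = _read_2d(path)
    if pixel_size is None:
        if zooms is None:
            raise ContractError(f"{path}: pixel_size required for this format")
        pixel_size = zooms
    if data.ndim != 2:
        raise FormatError(f"{path}: label maps must be single-channel")
    return LabelImage(data, pixel_size, legend=legend or {}, name=name or str(path))


def save_plane_image(img: PlaneImage, path) -> None:
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        affine = np.diag([img.pixel_size[0], img.pixel_size[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(img.pixels[..., None], affine), path)
    elif path.endswith((".tif", ".tiff")):
        import tifffile
        tifffile.imwrite(path, img.pixels.astype(np.float32))
    else:
        import imageio.v3 as iio
        lo, hi = img.pixels.min(), img.pixels.max()
        scaled = (img.pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(img.pixels)
        iio.imwrite(path, (scaled * 65535).astype(np.uint16))


def save_label_image(img: LabelImage, path) -> None:
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        affine = np.diag([img.pixel_size[0], img.pixel_size[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(img.labels.astype(np.int32)[..., None], affine), path)
    elif path.endswith((".tif", ".tiff")):
        import tifffile
        tifffile.imwrite(path, img.labels.astype(np.uint16))
    else:
        import imageio.v3 as iio
        iio.imwrite(path, img.labels.astype(np.uint16))


def save_legend(legend: dict[int, str], path) -> None:
    with open(path, "w") as fh:
        for key in sorted(legend):
            fh.write(f"{key}\t{legend[key]}\n")


def load_legend(path) -> dict[int, str]:
    legend = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, _, name = line.partition("\t")
            legend[int(key)] = name
    return legend


# ---------------------------------------------------------------------------
# transform (de)serialisation
# ---------------------------------------------------------------------------

_CONVENTION = "physical-um pull-back (reference point -> test sampling point)"


def save_transform(T: Transform2D, path) -> None:
    payload = {
        "kind": T.kind,
        "linear": [[float(v) for v in row] for row in T.linear],
        "offset_um": [float(v) for v in T.offset],
        "convention": _CONVENTION,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_transform(path) -> Transform2D:
    with open(path) as fh:
        payload = json.load(fh)
    return Transform2D(kind=payload["kind"],
                       linear=np.asarray(payload["linear"], float),
                       offset=np.asarray(payload["offset_um"], float))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_to(img, target_pixel_size):
    """Resample an image to a new pixel size, preserving physical extent.

    :class:`PlaneImage` uses linear interpolation, :class:`LabelImage`
    nearest-neighbour (the label value set never grows).  The grid centre is
    preserved, so the physical extent matches within one target pixel.
    """
    target = _as_pixel_size(target_pixel_size)
    current = img.pixel_size
    if np.allclose(current, target):
        return img
    shape = img.shape
    new_shape = tuple(
        int(round(shape[k] * current[k] / target[k])) for k in range(2))
    if min(new_shape) < MIN_DIM:
        raise DegenerateImageError(
            f"resampling {img.name or 'image'} to {target} µm would leave "
            f"{new_shape} pixels")
    centre = img.center()
    new_origin = tuple(
        centre[k] - (new_shape[k] - 1) / 2.0 * target[k] for k in range(2))
    geom = _Geometry(new_shape, target, new_origin)
    if isinstance(img, LabelImage):
        out = _warp(img.labels.astype(np.float64), img, Transform2D.identity(),
                    geom, order=0)
        return LabelImage(out.astype(np.int32), target, origin=new_origin,
                          legend=dict(img.legend), name=img.name)
    out = _warp(img.pixels, img, Transform2D.identity(), geom, order=1)
    return PlaneImage(out, target, origin=new_origin, name=img.name)


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Geometry:
    shape: tuple[int, int]
    pixel_size: tuple[float, float]
    origin: tuple[float, float]


def _geometry_of(ref) -> _Geometry:
    if isinstance(ref, _Geometry):
        return ref
    return _Geometry(tuple(ref.shape), tuple(ref.pixel_size), tuple(ref.origin))


def _warp(data: np.ndarray, img, T: Transform2D, geom: _Geometry, order: int):
    """Sample ``data`` (laid out on ``img``'s grid) through ``T`` onto ``geom``."""
    s_ref = np.diag(geom.pixel_size)
    s_in = np.diag(img.pixel_size)
    s_in_inv = np.linalg.inv(s_in)
    matrix = s_in_inv @ T.linear @ s_ref
    offset = s_in_inv @ (T.linear @ np.asarray(geom.origin) + T.offset
                         - np.asarray(img.origin))
    return ndi.affine_transform(data, matrix, offset=offset,
                                output_shape=geom.shape, order=order,
                                mode="constant", cval=0.0, prefilter=False)


def apply_transform(img, T: Transform2D, interpolation: str = "linear",
                    reference=None):
    """Warp an image through a transform onto the reference grid.

    ``reference`` supplies the output geometry (defaults to the input's own
    grid).  Out-of-domain samples are filled with background 0.  Label images
    must use nearest-neighbour interpolation so region identifiers are
    preserved.
    """
    if interpolation not in ("linear", "nearest"):
        raise ContractError(f"unknown interpolation {interpolation!r}")
    is_labels = isinstance(img, LabelImage)
    if is_labels and interpolation != "nearest":
        raise ContractError("label images require nearest-neighbour interpolation")
    geom = _geometry_of(reference if reference is not None else img)
    order = 0 if interpolation == "nearest" else 1
    if is_labels:
        out = _warp(img.labels.astype(np.float64), img, T, geom, order=0)
        return LabelImage(out.astype(np.int32), geom.pixel_size,
                          origin=geom.origin, legend=dict(img.legend),
                          name=img.name)
    out = _warp(img.pixels, img, T, geom, order=order)
    return PlaneImage(out, geom.pixel_size, origin=geom.origin, name=img.name)


# ---------------------------------------------------------------------------
# automated centering
# ---------------------------------------------------------------------------

def foreground_mask(img: PlaneImage, sigma: float = 1.0) -> np.ndarray:
    """Binarise tissue foreground: Otsu threshold on a Gaussian-smoothed image."""
    from skimage.filters import threshold_otsu
    smoothed = ndi.gaussian_filter(img.pixels, sigma)
    if smoothed.max() <= smoothed.min():
        raise CenteringError(f"{img.name or 'image'}: constant image, no foreground")
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    if not mask.any():
        raise CenteringError(f"{img.name or 'image'}: empty foreground after Otsu")
    return mask


def _centroid_um(img: PlaneImage, mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask).mean(axis=0)
    return np.asarray(img.origin) + idx * np.asarray(img.pixel_size)


def center_images(test: PlaneImage, ref: PlaneImage) -> Transform2D:
    """Translation aligning the foreground centroid of ``test`` to ``ref``.

    Returned in pull-back form: sampling ``test`` at ``p + (c_test - c_ref)``
    puts the test tissue on top of the reference tissue.  Used as the
    registration initialisation, minimising the displacement amplitude the
    block matcher has to recover.
    """
    c_test = _centroid_um(test, foreground_mask(test))
    c_ref = _centroid_um(ref, foreground_mask(ref))
    return Transform2D.translation(c_test - c_ref)
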