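"""Rigid / affine / deformable registration on top of SimpleITK.

The package keeps geometry in nibabel's RAS convention; ITK works in LPS.
All conversions happen at this module's boundary: :func:`to_sitk` /
:func:`from_sitk` translate images, and :class:`SpatialTransform` exposes
point mapping and serialization in RAS mm while wrapping the native ITK
transform.

Registration models:

* ``rigid`` / ``affine`` — multi-resolution ITK registration with a
  correlation metric, full (non-random) sampling and a regular-step
  gradient-descent optimizer, so results are deterministic for fixed
  inputs and settings.
* ``deformable`` — affine pre-alignment followed by multi-resolution fast
  symmetric-forces demons on histogram-matched images. Demons assumes
  matched intensity profiles, which the pipeline's histogram specification
  provides.

A transform maps points of the *fixed* image domain into the *moving*
image domain (the resampling convention): ``apply_transform`` evaluates
``moving(T(x))`` on a target grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .imgio import Geometry, LabelVolume, Volume, spacing_from_affine

# single-threaded ITK: bitwise-reproducible metrics and demons updates
sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)

_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


class RegistrationError(RuntimeError):
    """Registration failed or was given incompatible inputs."""


def to_sitk(volume: Volume | LabelVolume) -> sitk.Image:
    """Convert to a SimpleITK image (LPS geometry)."""
    data = volume.codes if isinstance(volume, LabelVolume) else volume.voxels
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(np.asarray(data, np.float64 if not isinstance(volume, LabelVolume) else np.int32), (2, 1, 0)))
    )
    lps = _RAS2LPS @ volume.affine
    spacing = spacing_from_affine(lps)
    direction = lps[:3, :3] / spacing[None, :]
    img.SetSpacing(tuple(spacing))
    img.SetOrigin(tuple(lps[:3, 3]))
    img.SetDirection(tuple(direction.ravel()))
    return img


def _affine_from_sitk_image(img: sitk.Image) -> np.ndarray:
    direction = np.array(img.GetDirection()).reshape(3, 3)
    spacing = np.array(img.GetSpacing())
    lps = np.eye(4)
    lps[:3, :3] = direction * spacing[None, :]
    lps[:3, 3] = img.GetOrigin()
    return _RAS2LPS @ lps  # back to RAS


def from_sitk(img: sitk.Image, as_labels: bool = False, legend: dict | None = None):
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    affine = _affine_from_sitk_image(img)
    if as_labels:
        return LabelVolume(np.rint(data).astype(np.int32), affine, legend or {})
    return Volume(np.ascontiguousarray(data), affine)


def _reference_image(geometry: Geometry) -> sitk.Image:
    dummy = Volume(np.zeros(geometry.shape, dtype=np.float32), geometry.affine)
    return to_sitk(dummy)


@dataclass
class SpatialTransform:
    """A fixed-domain -> moving-domain spatial map.

    ``kind`` is one of ``identity``, ``rigid``, ``affine``, ``dense`` (any
    transform containing a displacement field, including affine+demons
    composites). ``domain`` records the fixed-image geometry the transform
    was estimated on (needed to rasterize dense fields).
    """

    kind: str
    transform: sitk.Transform
    domain: Geometry | None = None

    def transform_points(self, points_ras: np.ndarray) -> np.ndarray:
        """Map RAS-mm points through the transform (vectorized)."""
        pts = np.atleast_2d(np.asarray(points_ras, dtype=float))
        flip = np.array([-1.0, -1.0, 1.0])
        out = np.array([self.transform.TransformPoint(tuple(p * flip)) for p in pts])
        return out * flip

    def displacement(self, points_ras: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_ras, dtype=float))
        return self.transform_points(pts) - pts

    def matrix_ras(self) -> np.ndarray:
        """Homogeneous 4x4 point-map matrix in RAS (affine kinds only)."""
        if self.kind not in ("identity", "rigid", "affine"):
            raise ValueError("matrix only defined for affine-kind transforms")
        t = self.transform
        if isinstance(t, sitk.CompositeTransform):
            raise ValueError("composite transform has no single matrix")
        hom = np.eye(4)
        if self.kind != "identity":
            # Euler3D and Affine both expose matrix + center + translation
            hom_lps = np.eye(4)
            m = np.array(t.GetMatrix()).reshape(3, 3)
            c = np.array(t.GetCenter())
            tr = np.array(t.GetTranslation())
            hom_lps[:3, :3] = m
            hom_lps[:3, 3] = tr + c - m @ c
            hom = _RAS2LPS @ hom_lps @ _RAS2LPS
        return hom


def identity_transform() -> SpatialTransform:
    return SpatialTransform("identity", sitk.Transform(3, sitk.sitkIdentity))


@dataclass
class RegistrationSettings:
    """Deterministic defaults sized for desk-scale phantom grids."""

    shrink_factors: tuple[int, ...] = (4, 2)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0)  # voxels per level
    iterations: int = 60
    learning_rate: float = 1.0
    min_step: float = 1e-4
    metric: str = "correlation"  # or "mean_squares", "mutual_information"
    # demons (deformable) settings: (shrink factor, iterations) per level
    demons_levels: tuple[tuple[int, int], ...] = ((4, 40), (2, 20), (1, 6))
    demons_field_sigma_vox: float = 1.2
    demons_intensity_match: bool = True


def _linear_registration(
    moving: sitk.Image, fixed: sitk.Image, model: str, s: RegistrationSettings
) -> sitk.Transform:
    if model == "rigid":
        init_tx = sitk.Euler3DTransform()
    else:
        init_tx = sitk.AffineTransform(3)
    initial = sitk.CenteredTransformInitializer(
        fixed, moving, init_tx, sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    if s.metric == "mean_squares":
        reg.SetMetricAsMeanSquares()
    elif s.metric == "mutual_information":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    else:
        reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=s.learning_rate,
        minStep=s.min_step,
        numberOfIterations=s.iterations,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(s.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(s.smoothing_sigmas))
    reg.SetInitialTransform(initial, inPlace=False)
    try:
        result = reg.Execute(fixed, moving)
    except RuntimeError as exc:  # non-overlapping FOV etc.
        raise RegistrationError(f"{model} registration failed: {exc}") from exc
    result = result.Downcast() if hasattr(result, "Downcast") else result
    if isinstance(result, sitk.CompositeTransform) and result.GetNumberOfTransforms() == 1:
        result = result.GetNthTransform(0)
    return result


def _shrink_image(img: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        return img
    smoothed = sitk.DiscreteGaussian(img, [(factor / 2.0 * sp) ** 2 for sp in img.GetSpacing()])
    return sitk.BinShrink(smoothed, [factor] * 3)


def _demons_multires(
    fixed: sitk.Image, moving: sitk.Image, s: RegistrationSettings
) -> sitk.Image:
    """Multi-resolution fast symmetric-forces demons; returns the field (LPS mm)."""
    if s.demons_intensity_match:
        moving = sitk.HistogramMatching(
            moving, fixed, numberOfHistogramLevels=128, numberOfMatchPoints=15,
            thresholdAtMeanIntensity=True,
        )
    field = None
    for factor, iters in s.demons_levels:
        f_small = _shrink_image(fixed, factor)
        m_small = _shrink_image(moving, factor)
        if field is None:
            field = sitk.Image(f_small.GetSize(), sitk.sitkVectorFloat64, 3)
            field.CopyInformation(f_small)
        else:
            field = sitk.Resample(field, f_small, sitk.Transform(3, sitk.sitkIdentity),
                                  sitk.sitkLinear)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(iters)
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(s.demons_field_sigma_vox * min(f_small.GetSpacing()))
        demons.SetSmoothUpdateField(True)
        demons.SetUpdateFieldStandardDeviations(s.demons_field_sigma_vox * min(f_small.GetSpacing()))
        field = demons.Execute(f_small, m_small, field)
    return field


def register(
    moving: Volume,
    fixed: Volume,
    model: str = "deformable",
    settings: RegistrationSettings | None = None,
) -> SpatialTransform:
    """Estimate a transform mapping the fixed domain into the moving domain.

    ``model``: ``rigid`` | ``affine`` | ``deformable``. Deformable runs an
    affine pre-alignment internally and composes it with a demons
    displacement field estimated on the fixed grid.
    """
    if model not in ("rigid", "affine", "deformable"):
        raise ValueError(f"unknown registration model {model!r}")
    s = settings or RegistrationSettings()
    f_img = to_sitk(fixed)
    m_img = to_sitk(moving)
    if model in ("rigid", "affine"):
        tx = _linear_registration(m_img, f_img, model, s)
        return SpatialTransform(model, tx, fixed.geometry)
    affine_tx = _linear_registration(m_img, f_img, "affine", s)
    if not s.demons_levels:
        return SpatialTransform("affine", affine_tx, fixed.geometry)
    moving_aff = sitk.Resample(m_img, f_img, affine_tx, sitk.sitkLinear, 0.0)
    field = _demons_multires(f_img, moving_aff, s)
    field = sitk.Cast(field, sitk.sitkVectorFloat64)
    disp_tx = sitk.DisplacementFieldTransform(field)
    total = sitk.CompositeTransform(3)
    total.AddTransform(affine_tx)
    total.AddTransform(disp_tx)  # applied first: x -> x+u(x) -> affine
    return SpatialTransform("dense", total, fixed.geometry)


def apply_transform(
    transform: SpatialTransform,
    image: Volume | LabelVolume,
    target_geometry: Geometry,
    interpolation: str | None = None,
):
    """Resample ``image`` through the transform onto ``target_geometry``.

    Labels are forced to nearest-neighbour interpolation and never gain
    codes not present in the input.
    """
    is_labels = isinstance(image, LabelVolume)
    if interpolation is None:
        interpolation = "nearest" if is_labels else "linear"
    if is_labels and interpolation == "linear":
        raise ValueError("linear interpolation is invalid for label volumes")
    interp = sitk.sitkNearestNeighbor if interpolation == "nearest" else sitk.sitkLinear
    ref = _reference_image(target_geometry)
    out = sitk.Resample(to_sitk(image), ref, transform.transform, interp, 0.0)
    if is_labels:
        return from_sitk(out, as_labels=True, legend=dict(image.legend))
    return from_sitk(out)


def compose(outer: SpatialTransform, inner: SpatialTransform) -> SpatialTransform:
    """Transform for 'apply inner, then outer' image warps.

    ``apply(compose(outer, inner), img) == apply(outer, apply(inner, img))``
    up to one interpolation step.
    """
    affine_kinds = ("identity", "rigid", "affine")
    if outer.kind in affine_kinds and inner.kind in affine_kinds:
        m = inner.matrix_ras() @ outer.matrix_ras()  # point map: inner after outer
        kind = "rigid" if outer.kind == inner.kind == "rigid" else "affine"
        if outer.kind == inner.kind == "identity":
            kind = "identity"
        lps = _RAS2LPS @ m @ _RAS2LPS
        tx = sitk.AffineTransform(3)
        tx.SetMatrix(tuple(lps[:3, :3].ravel()))
        tx.SetTranslation(tuple(lps[:3, 3]))
        return SpatialTransform(kind, tx, outer.domain or inner.domain)
    c = sitk.CompositeTransform(3)
    c.AddTransform(sitk.Transform(inner.transform))
    c.AddTransform(sitk.Transform(outer.transform))  # applied first
    return SpatialTransform("dense", c, outer.domain or inner.domain)


def invert(transform: SpatialTransform, domain: Geometry | None = None) -> SpatialTransform:
    """Invert a transform.

    Affine kinds invert exactly; dense transforms are rasterized on their
    domain and inverted by ITK's iterative fixed-point displacement-field
    inversion.
    """
    if transform.kind in ("identity", "rigid", "affine"):
        inv = transform.transform.GetInverse()
        return SpatialTransform(transform.kind, inv, transform.domain)
    dom = domain or transform.domain
    if dom is None:
        raise ValueError("dense inversion requires a domain geometry")
    ref = _reference_image(dom)
    filt = sitk.TransformToDisplacementFieldFilter()
    filt.SetReferenceImage(ref)
    field = filt.Execute(transform.transform)
    inv_field = sitk.InvertDisplacementField(
        field,
        maximumNumberOfIterations=50,
        maxErrorToleranceThreshold=0.05,
        meanErrorToleranceThreshold=0.0005,
        enforceBoundaryCondition=True,
    )
    inv_tx = sitk.DisplacementFieldTransform(sitk.Cast(inv_field, sitk.sitkVectorFloat64))
    return SpatialTransform("dense", inv_tx, dom)


def save_transform(transform: SpatialTransform, path) -> None:
    """Serialize: affine kinds as a 4x4 RAS text matrix, dense as an ITK file."""
    path = Path(path)
    if transform.kind in ("identity", "rigid", "affine"):
        header = f"# striatseg {transform.kind} transform (RAS point map)\n"
        np.savetxt(path, transform.matrix_ras(), header=header.strip("#\n "))
    else:
        sitk.WriteTransform(transform.transform, str(path))


def load_transform(path, kind: str = "affine") -> SpatialTransform:
    path = Path(path)
    if path.suffix in (".txt", ".mat") and kind in ("identity", "rigid", "affine"):
        m = np.loadtxt(path)
        lps = _RAS2LPS @ m @ _RAS2LPS
        tx = sitk.AffineTransform(3)
        tx.SetMatrix(tuple(lps[:3, :3].ravel()))
        tx.SetTranslation(tuple(lps[:3, 3]))
        return SpatialTransform(kind, tx)
    return SpatialTransform("dense", sitk.ReadTransform(str(path)))
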