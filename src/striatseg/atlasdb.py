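"""PET template construction and the atlas database.

The database is the segmentation engine's reference material: a groupwise
PET template (built by iterative registration and voxelwise averaging of
the atlas-cohort scans), a template-space label image (majority vote of the
warped per-subject labels), and one :class:`Atlas` per cohort subject. Each
atlas stores its preprocessed template-space PET together with the global
and local (striatal) histogram-specified variants the two-step atlas
selection compares against, plus its warped label image for fusion.

Directory layout on disk::

    atlasdb/
      template.nii.gz
      template_labels.nii.gz (+ .labels.json legend)
      atlases/<id>/{pet,labels,global_spec,local_spec}.nii.gz
      params.json            # provenance: settings, ids, reference quantiles
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import __version__
from .imgio import Geometry, LabelVolume, Volume, read_volume, resample, write_volume
from .phantom import STRIATUM_CODES
from .preprocess import (
    DEFAULT_PVC_ALPHA,
    DEFAULT_PVC_MAX_ITER,
    DEFAULT_PVC_PSF_FWHM_MM,
    DEFAULT_PVC_TOL,
    DEFAULT_SMOOTH_FWHM_MM,
    apply_histogram_map,
    fit_histogram_map,
    pvc_van_cittert,
    skull_strip,
    smooth_fwhm,
)
from .registration import RegistrationSettings, SpatialTransform, apply_transform, register


@dataclass
class AtlasBuildSettings:
    """Preprocessing and registration parameters for atlas creation."""

    template_iterations: int = 3
    smooth_fwhm_mm: tuple[float, float, float] = DEFAULT_SMOOTH_FWHM_MM
    pvc_psf_fwhm_mm: float = DEFAULT_PVC_PSF_FWHM_MM
    pvc_alpha: float = DEFAULT_PVC_ALPHA
    pvc_max_iter: int = DEFAULT_PVC_MAX_ITER
    pvc_tol: float = DEFAULT_PVC_TOL
    n_quantiles: int = 256
    registration: RegistrationSettings = field(default_factory=RegistrationSettings)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["registration"]["demons_levels"] = [list(x) for x in d["registration"]["demons_levels"]]
        return d


@dataclass
class Atlas:
    """One cohort subject in template space."""

    atlas_id: str
    group: str
    pet: Volume  # preprocessed (stripped, PVC'd, smoothed) template-space PET
    labels: LabelVolume
    global_spec: Volume
    local_spec: Volume


@dataclass
class AtlasDatabase:
    template: Volume  # preprocessed template (registration target + histogram reference)
    template_labels: LabelVolume
    atlases: list[Atlas]
    params: dict

    def __post_init__(self) -> None:
        if not self.atlases:
            raise ValueError("atlas database needs at least one atlas")
        if not self.template_labels.same_geometry(self.template):
            raise ValueError("template labels geometry differs from template")

    @property
    def geometry(self) -> Geometry:
        return self.template.geometry

    def brain_mask(self) -> np.ndarray:
        return self.template_labels.codes > 0

    def striatum_mask(self, dilate: int = 0) -> np.ndarray:
        m = np.isin(self.template_labels.codes, STRIATUM_CODES)
        if dilate > 0:
            m = ndimage.binary_dilation(m, iterations=dilate)
        return m

    def global_reference_quantiles(self) -> np.ndarray:
        return np.asarray(self.params["global_reference_quantiles"], float)

    def local_reference_quantiles(self) -> np.ndarray:
        return np.asarray(self.params["local_reference_quantiles"], float)


def build_template(
    pets: list[Volume],
    iterations: int = 3,
    settings: RegistrationSettings | None = None,
) -> Volume:
    """Groupwise template by iterative registration to the running average.

    The first pass aligns affinely, later passes deformably; after each pass
    the warped images are voxelwise-averaged into the next template.
    Deterministic for fixed inputs and settings.
    """
    if len(pets) < 2:
        raise ValueError("template construction needs at least 2 images")
    geometry = pets[0].geometry
    aligned = [resample(p, geometry, "linear") for p in pets]
    template = Volume(np.mean([a.voxels for a in aligned], axis=0), geometry.affine)
    for it in range(iterations):
        model = "affine" if it == 0 else "deformable"
        warped = []
        for pet in pets:
            tx = register(pet, template, model, settings)
            warped.append(apply_transform(tx, pet, geometry).voxels)
        template = Volume(np.mean(warped, axis=0), geometry.affine)
    return template


def _majority_vote(label_stacks: list[np.ndarray], affine, legend) -> LabelVolume:
    """Voxelwise plurality label; ties go to the smallest code."""
    codes = sorted({int(c) for arr in label_stacks for c in np.unique(arr)})
    counts = np.zeros((len(codes), *label_stacks[0].shape), dtype=np.uint16)
    for arr in label_stacks:
        for i, c in enumerate(codes):
            counts[i] += arr == c
    winner = np.argmax(counts, axis=0)  # argmax takes first (smallest code) on ties
    out = np.array(codes, dtype=np.int32)[winner]
    return LabelVolume(out, affine, legend)


def _preprocess_template_space(
    pet_t: Volume,
    brain_mask: np.ndarray,
    settings: AtlasBuildSettings,
    with_pvc: bool,
) -> Volume:
    stripped = skull_strip(pet_t, brain_mask)
    if with_pvc:
        stripped = pvc_van_cittert(
            stripped,
            psf_fwhm_mm=settings.pvc_psf_fwhm_mm,
            alpha=settings.pvc_alpha,
            max_iter=settings.pvc_max_iter,
            tol=settings.pvc_tol,
            mask=brain_mask,
        )
    return smooth_fwhm(stripped, settings.smooth_fwhm_mm, mask=brain_mask)


def create_atlas(
    pet: Volume,
    labels_native: LabelVolume,
    template: Volume,
    template_labels: LabelVolume,
    settings: AtlasBuildSettings | None = None,
    atlas_id: str = "atlas",
    group: str = "",
    reference_quantiles: tuple[np.ndarray, np.ndarray] | None = None,
    transform: SpatialTransform | None = None,
) -> Atlas:
    """Warp one subject into template space and preprocess it into an atlas.

    ``labels_native`` must be co-registered with ``pet`` (they share
    geometry). The non-linear PET -> template transform is estimated here
    unless a precomputed one is passed. Histogram specification uses the
    template's own intensity quantiles (or precomputed reference knots).
    """
    settings = settings or AtlasBuildSettings()
    if not labels_native.same_geometry(pet):
        raise ValueError("native labels must share the PET geometry")
    if not np.any(np.isin(labels_native.codes, STRIATUM_CODES)):
        raise ValueError("striatum absent from native labels")
    tx = transform or register(pet, template, "deformable", settings.registration)
    geometry = template.geometry
    pet_t = apply_transform(tx, pet, geometry)
    labels_t = apply_transform(tx, labels_native, geometry)
    if not np.any(np.isin(labels_t.codes, STRIATUM_CODES)):
        raise ValueError("striatum empty after warping to template space")
    brain = template_labels.codes > 0
    striatum = np.isin(template_labels.codes, STRIATUM_CODES)
    processed = _preprocess_template_space(pet_t, brain, settings, with_pvc=True)
    if reference_quantiles is None:
        template_brain_q = np.quantile(
            template.voxels[brain], np.linspace(0, 1, settings.n_quantiles)
        )
        template_str_q = np.quantile(
            template.voxels[striatum], np.linspace(0, 1, settings.n_quantiles)
        )
    else:
        template_brain_q, template_str_q = reference_quantiles
    gmap = fit_histogram_map(processed, template_brain_q, brain, n_quantiles=settings.n_quantiles)
    global_spec = apply_histogram_map(gmap, processed, brain)
    lmap = fit_histogram_map(global_spec, template_str_q, striatum, n_quantiles=settings.n_quantiles)
    local_spec = apply_histogram_map(lmap, global_spec, striatum)
    return Atlas(atlas_id, group, processed, labels_t, global_spec, local_spec)


def build_database(
    subjects: list[tuple[Volume, LabelVolume, str]],
    settings: AtlasBuildSettings | None = None,
    ids: list[str] | None = None,
) -> AtlasDatabase:
    """Build template, template labels, and one atlas per subject.

    ``subjects`` is a list of (native PET, native labels, group tag). The
    template labels are the majority vote of all warped subject labels; the
    stored template is the preprocessed average (stripped, PVC'd, smoothed),
    whose brain/striatum quantiles become the histogram-specification
    reference for atlases and targets alike.
    """
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to build a database")
    settings = settings or AtlasBuildSettings()
    ids = ids or [f"a{i:02d}" for i in range(len(subjects))]
    pets = [s[0] for s in subjects]
    template_raw = build_template(pets, settings.template_iterations, settings.registration)
    geometry = template_raw.geometry

    transforms, warped_labels = [], []
    for pet, labels, _ in subjects:
        tx = register(pet, template_raw, "deformable", settings.registration)
        transforms.append(tx)
        warped_labels.append(apply_transform(tx, labels, geometry).codes)
    legend = dict(subjects[0][1].legend)
    template_labels = _majority_vote(warped_labels, geometry.affine, legend)

    brain = template_labels.codes > 0
    striatum = np.isin(template_labels.codes, STRIATUM_CODES)
    template = _preprocess_template_space(template_raw, brain, settings, with_pvc=True)
    levels = np.linspace(0, 1, settings.n_quantiles)
    ref_global = np.quantile(template.voxels[brain], levels)
    ref_local = np.quantile(template.voxels[striatum], levels)

    atlases = []
    for (pet, labels, group), tx, aid in zip(subjects, transforms, ids):
        atlases.append(
            create_atlas(
                pet, labels, template, template_labels, settings,
                atlas_id=aid, group=group,
                reference_quantiles=(ref_global, ref_local), transform=tx,
            )
        )
    params = {
        "version": __version__,
        "settings": settings.to_jsonable(),
        "atlas_ids": ids,
        "groups": [s[2] for s in subjects],
        "global_reference_quantiles": ref_global.tolist(),
        "local_reference_quantiles": ref_local.tolist(),
    }
    return AtlasDatabase(template, template_labels, atlases, params)


_ATLAS_FILES = ("pet", "labels", "global_spec", "local_spec")


def save(db: AtlasDatabase, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(db.template, directory / "template.nii.gz")
    write_volume(db.template_labels, directory / "template_labels.nii.gz")
    for atlas in db.atlases:
        adir = directory / "atlases" / atlas.atlas_id
        adir.mkdir(parents=True, exist_ok=True)
        write_volume(atlas.pet, adir / "pet.nii.gz")
        write_volume(atlas.labels, adir / "labels.nii.gz")
        write_volume(atlas.global_spec, adir / "global_spec.nii.gz")
        write_volume(atlas.local_spec, adir / "local_spec.nii.gz")
    (directory / "params.json").write_text(json.dumps(db.params, indent=1))


def load(directory) -> AtlasDatabase:
    directory = Path(directory)
    params_path = directory / "params.json"
    if not params_path.exists():
        raise FileNotFoundError(f"missing atlas database file: {params_path}")
    params = json.loads(params_path.read_text())
    for fname in ("template.nii.gz", "template_labels.nii.gz"):
        if not (directory / fname).exists():
            raise FileNotFoundError(f"missing atlas database file: {directory / fname}")
    template = read_volume(directory / "template.nii.gz")
    template_labels = read_volume(directory / "template_labels.nii.gz", as_labels=True)
    atlases = []
    for aid, group in zip(params["atlas_ids"], params["groups"]):
        adir = directory / "atlases" / aid
        images = {}
        for key in _ATLAS_FILES:
            path = adir / f"{key}.nii.gz"
            if not path.exists():
                raise FileNotFoundError(f"missing atlas database file: {path}")
            images[key] = read_volume(path, as_labels=(key == "labels"))
        atlases.append(
            Atlas(aid, group, images["pet"], images["labels"],
                  images["global_spec"], images["local_spec"])
        )
    return AtlasDatabase(template, template_labels, atlases, params)
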