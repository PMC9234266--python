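"""Synthetic striatal VMAT2 PET phantoms with ground-truth labels.

The generator emulates the features of striatal vesicular-monoamine-
transporter PET that drive atlas-based segmentation: a bright striatum
(caudate, putamen, nucleus accumbens) over a dim brain background, a
cerebellum of unit relative activity serving as the reference region,
finite scanner resolution (Gaussian point-spread blur), post-reconstruction
Gaussian noise, and smooth inter-subject anatomical deformation.

Two uptake profiles are built in. The healthy-control profile has uniform
striatal uptake 2.5-3.6x cerebellum. The parkinsonian profile loses signal
with an anterior -> posterior gradient in the putamen and caudate, the
posterior putamen being most affected — the hallmark of nigrostriatal
dopaminergic degeneration.

Anatomy is rasterized from per-structure ellipsoids on a canonical RAS grid
(origin at the grid center), mirror-symmetric about the mid-sagittal plane,
then warped per subject by a band-limited random displacement field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imgio import LabelVolume, Volume

# anatomy codes (shared by the whole pipeline)
BRAIN = 1
CEREBELLUM = 2
CAUDATE = 3
PUTAMEN = 4
ACCUMBENS = 5

ANATOMY_LEGEND = {
    BRAIN: "brain",
    CEREBELLUM: "cerebellum",
    CAUDATE: "caudate",
    PUTAMEN: "putamen",
    ACCUMBENS: "nucleus_accumbens",
}

STRIATUM_CODES = (CAUDATE, PUTAMEN, ACCUMBENS)

# rasterization precedence, most specific structure wins
_PRECEDENCE = [BRAIN, CEREBELLUM, CAUDATE, PUTAMEN, ACCUMBENS]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in world mm: center and semi-axes."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    bilateral: bool = False  # mirror about x=0 in addition to the stated center


@dataclass(frozen=True)
class UptakeProfile:
    """Activity ratios vs cerebellum (== 1) for one diagnostic group.

    ``putamen`` / ``caudate`` are (anterior, posterior) endpoint ratios;
    uptake varies linearly along each structure's own anterior-posterior
    extent. Uniform uptake is expressed as equal endpoints.
    """

    putamen: tuple[float, float]
    caudate: tuple[float, float]
    accumbens: float
    brain: float = 0.4


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the synthetic cohort's imaging conditions."""

    shape: tuple[int, int, int] = (64, 80, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    structures: dict[int, Ellipsoid] = field(default_factory=lambda: dict(_DEFAULT_STRUCTURES))
    uptake: dict[str, UptakeProfile] = field(default_factory=lambda: dict(_DEFAULT_UPTAKE))
    psf_fwhm: float = 6.0  # mm, scanner resolution
    noise_sd: float = 0.08  # fraction of cerebellar activity
    uptake_jitter_sd: float = 0.10  # per-subject fractional spread of ratios
    # disease severity continuum: each PD subject's profile is the HC profile
    # moved toward the PD profile by s/mean(range), s ~ U(range), so the
    # group mean stays at the stated PD profile while severity varies the
    # way clinical stage does in real cohorts
    pd_severity_range: tuple[float, float] = (0.5, 0.95)
    deform_amplitude: float = 10.0  # mm, max |u| of the random warp
    seed: int = 0

    def validate(self) -> None:
        if not self.structures:
            raise ValueError("structure list is empty")
        if BRAIN not in self.structures:
            raise ValueError("a brain envelope structure is required")
        if self.deform_amplitude < 0:
            raise ValueError("deform_amplitude must be >= 0")
        if self.psf_fwhm < 0 or self.noise_sd < 0 or self.uptake_jitter_sd < 0:
            raise ValueError("psf_fwhm, noise_sd and uptake_jitter_sd must be >= 0")
        lo, hi = self.pd_severity_range
        if not (0 < lo <= hi):
            raise ValueError("pd_severity_range must satisfy 0 < low <= high")
        for profile in self.uptake.values():
            ratios = (*profile.putamen, *profile.caudate, profile.accumbens, profile.brain)
            if any(r <= 0 for r in ratios):
                raise ValueError("uptake ratios must be > 0")


_DEFAULT_STRUCTURES: dict[int, Ellipsoid] = {
    BRAIN: Ellipsoid((0.0, 0.0, 0.0), (54.0, 72.0, 54.0)),
    CEREBELLUM: Ellipsoid((0.0, -42.0, -26.0), (26.0, 16.0, 14.0)),
    CAUDATE: Ellipsoid((13.0, 10.0, 10.0), (6.5, 17.0, 9.0), bilateral=True),
    PUTAMEN: Ellipsoid((24.0, 2.0, 2.0), (9.0, 19.0, 11.0), bilateral=True),
    ACCUMBENS: Ellipsoid((16.0, 16.0, -8.0), (6.0, 7.0, 6.0), bilateral=True),
}

# group profiles: healthy uptake uniform; parkinsonian uptake falls
# anterior -> posterior, posterior putamen most affected
_DEFAULT_UPTAKE: dict[str, UptakeProfile] = {
    "HC": UptakeProfile(putamen=(3.6, 3.6), caudate=(3.0, 3.0), accumbens=2.5),
    "PD": UptakeProfile(putamen=(2.0, 1.5), caudate=(2.1, 1.45), accumbens=2.1),
}


@dataclass
class PhantomSubject:
    """One synthetic scan: ground-truth labels, noise-free activity, PET."""

    subject_id: str
    group: str
    seed: int
    truth: LabelVolume
    activity: Volume
    pet: Volume
    applied_uptake: dict[str, float]  # per-structure ratio endpoints actually used


def _grid_affine(spec: PhantomSpec) -> np.ndarray:
    affine = np.diag([*spec.spacing, 1.0])
    affine[:3, 3] = -(np.array(spec.shape) - 1) * np.array(spec.spacing) / 2.0
    return affine


def _ellipsoid_mask(coords: tuple[np.ndarray, ...], e: Ellipsoid, mirror: bool) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = e.center
    if mirror:
        cx = -cx
    ax, ay, az = e.semi_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def build_anatomy(spec: PhantomSpec) -> LabelVolume:
    """Rasterize the ellipsoid anatomy into a label volume.

    Overlaps resolve by precedence (accumbens > putamen > caudate >
    cerebellum > brain); bilateral structures are mirrored about x=0 so the
    anatomy is exactly mirror-symmetric on a symmetric grid. Every structure
    must lie inside the brain envelope.
    """
    spec.validate()
    affine = _grid_affine(spec)
    idx = np.indices(spec.shape, dtype=float)
    coords = tuple(
        idx[d] * spec.spacing[d] + affine[d, 3] for d in range(3)
    )  # world mm, diagonal affine
    envelope = _ellipsoid_mask(coords, spec.structures[BRAIN], mirror=False)
    codes = np.zeros(spec.shape, dtype=np.int16)
    for code in _PRECEDENCE:
        if code not in spec.structures:
            continue
        e = spec.structures[code]
        m = _ellipsoid_mask(coords, e, mirror=False)
        if e.bilateral:
            m |= _ellipsoid_mask(coords, e, mirror=True)
        if code != BRAIN and np.any(m & ~envelope):
            raise ValueError(f"structure {ANATOMY_LEGEND.get(code, code)} exits the brain envelope")
        codes[m] = code
    return LabelVolume(codes, affine, dict(ANATOMY_LEGEND))


def _displacement_field(
    spec: PhantomSpec, rng: np.random.Generator, n_bumps: int = 20
) -> np.ndarray:
    """Smooth random displacement (mm), shape (3, *grid), max |u| == amplitude."""
    if spec.deform_amplitude == 0:
        return np.zeros((3, *spec.shape))
    affine = _grid_affine(spec)
    idx = np.indices(spec.shape, dtype=float)
    coords = [idx[d] * spec.spacing[d] + affine[d, 3] for d in range(3)]
    brain = spec.structures[BRAIN]
    field_mm = np.zeros((3, *spec.shape))
    for _ in range(n_bumps):
        center = rng.uniform(-0.7, 0.7, size=3) * np.array(brain.semi_axes)
        sigma = rng.uniform(5.0, 12.0)  # mm: includes shape detail finer than the PSF
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r2 = sum((coords[d] - center[d]) ** 2 for d in range(3))
        bump = np.exp(-r2 / (2.0 * sigma**2))
        for d in range(3):
            field_mm[d] += direction[d] * bump
    mag = np.sqrt((field_mm**2).sum(axis=0))
    peak = mag.max()
    if peak > 0:
        field_mm *= spec.deform_amplitude / peak
    return field_mm


def _warp_labels_nearest(labels: np.ndarray, field_mm: np.ndarray, spacing) -> np.ndarray:
    """Pull-back warp L'(x) = L(x + u(x)) with nearest interpolation."""
    idx = np.indices(labels.shape, dtype=float)
    sample = [idx[d] + field_mm[d] / spacing[d] for d in range(3)]
    return ndimage.map_coordinates(labels, sample, order=0, mode="nearest")


def _uptake_for_voxels(
    truth: LabelVolume, profile: UptakeProfile, jitter: dict[str, float]
) -> tuple[np.ndarray, dict[str, float]]:
    """Piecewise activity: constant per structure, linear A->P gradient where
    the profile's endpoints differ. Cerebellum is pinned at 1."""
    act = np.zeros(truth.shape, dtype=np.float64)
    applied: dict[str, float] = {"cerebellum": 1.0}
    act[truth.codes == CEREBELLUM] = 1.0
    act[truth.codes == BRAIN] = profile.brain * jitter.get("brain", 1.0)
    applied["brain"] = profile.brain * jitter.get("brain", 1.0)
    y_world = None
    for code, name, endpoints in (
        (PUTAMEN, "putamen", profile.putamen),
        (CAUDATE, "caudate", profile.caudate),
        (ACCUMBENS, "nucleus_accumbens", (profile.accumbens, profile.accumbens)),
    ):
        m = truth.codes == code
        if not np.any(m):
            continue
        j = jitter.get(name, 1.0)
        ant, post = endpoints[0] * j, endpoints[1] * j
        applied[f"{name}_anterior"] = ant
        applied[f"{name}_posterior"] = post
        if ant == post:
            act[m] = ant
        else:
            if y_world is None:
                y_world = truth.world_coords()[:, 1].reshape(truth.shape)
            y = y_world[m]
            span = y.max() - y.min()
            t = (y - y.min()) / span if span > 0 else np.full(y.shape, 0.5)
            act[m] = post + (ant - post) * t  # t=1 at the anterior end
    return act, applied


def synthesize_subject(
    spec: PhantomSpec, group: str, seed: int, subject_id: str | None = None
) -> PhantomSubject:
    """Deterministically simulate one subject of the given group.

    Pipeline: seeded random warp of the template anatomy (nearest, so the
    ground-truth labels are exact) -> per-subject uptake assignment (group
    profile x seeded per-structure jitter) -> Gaussian PSF blur -> additive
    Gaussian noise scaled to cerebellar activity.
    """
    spec.validate()
    if group not in spec.uptake:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(spec.uptake)}")
    rng = np.random.default_rng(seed)
    anatomy = build_anatomy(spec)
    field_mm = _displacement_field(spec, rng)
    warped = _warp_labels_nearest(anatomy.codes, field_mm, spec.spacing)
    truth = LabelVolume(warped, anatomy.affine, dict(ANATOMY_LEGEND))

    jitter = {
        name: float(np.exp(rng.normal(0.0, spec.uptake_jitter_sd)))
        for name in ("putamen", "caudate", "nucleus_accumbens", "brain")
    }
    profile = spec.uptake[group]
    severity = None
    if group == "PD" and "HC" in spec.uptake:
        lo, hi = spec.pd_severity_range
        s = float(rng.uniform(lo, hi))
        c = s / ((lo + hi) / 2.0)  # E[c] = 1: group mean stays at the PD profile
        hc = spec.uptake["HC"]

        def _lerp(a: float, b: float) -> float:
            return a + c * (b - a)

        profile = UptakeProfile(
            putamen=(_lerp(hc.putamen[0], profile.putamen[0]),
                     _lerp(hc.putamen[1], profile.putamen[1])),
            caudate=(_lerp(hc.caudate[0], profile.caudate[0]),
                     _lerp(hc.caudate[1], profile.caudate[1])),
            accumbens=_lerp(hc.accumbens, profile.accumbens),
            brain=profile.brain,
        )
        severity = s
    act, applied = _uptake_for_voxels(truth, profile, jitter)
    if severity is not None:
        applied["severity"] = severity
    activity = Volume(act, anatomy.affine)

    pet_data = act
    if spec.psf_fwhm > 0:
        sigma_vox = spec.psf_fwhm / np.sqrt(8.0 * np.log(2.0)) / np.array(spec.spacing)
        pet_data = ndimage.gaussian_filter(act, sigma=sigma_vox)
    if spec.noise_sd > 0:
        pet_data = pet_data + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    pet = Volume(pet_data.astype(np.float32), anatomy.affine)
    sid = subject_id or f"{group.lower()}_{seed}"
    return PhantomSubject(sid, group, seed, truth, activity, pet, applied)


def generate_cohort(
    spec: PhantomSpec, n_hc: int, n_pd: int, seed: int
) -> list[PhantomSubject]:
    """Simulate ``n_hc`` healthy and ``n_pd`` parkinsonian subjects.

    Subject seeds are spawned from the master seed, so cohorts are
    reproducible and per-subject independent.
    """
    if n_hc < 0 or n_pd < 0:
        raise ValueError("subject counts must be >= 0")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_hc + n_pd)]
    subjects = []
    for i in range(n_hc):
        subjects.append(
            synthesize_subject(spec, "HC", child_seeds[i], subject_id=f"hc{i:02d}")
        )
    for i in range(n_pd):
        subjects.append(
            synthesize_subject(spec, "PD", child_seeds[n_hc + i], subject_id=f"pd{i:02d}")
        )
    return subjects


def default_spec(**overrides) -> PhantomSpec:
    """The default imaging conditions, optionally overridden field-wise."""
    return replace(PhantomSpec(), **overrides)
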