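"""Multi-atlas segmentation: two-step MSE atlas selection and joint label fusion.

For a target PET the method (i) warps the target into template space and
histogram-specifies it, (ii) ranks all atlases by mean-squared error of the
globally specified images over the brain and keeps the best ``k1`` (default
10), (iii) re-ranks those by MSE of the locally specified images over the
striatum and keeps the best ``k2`` (default 5), (iv) registers each chosen
atlas to the target, warps its labels to native target space, and (v) fuses
the candidate labels with joint label fusion (JLF): per voxel, each atlas
contributes its intensity patch at the best-matching offset within a search
window; a patch-error dependency matrix is inverted to obtain voting weights
that down-weight atlases making *correlated* errors, and the fused label is
the weighted plurality vote.

A single-registration template-based baseline is included for comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .atlasdb import AtlasDatabase
from .imgio import LabelVolume, Volume
from .preprocess import apply_histogram_map, fit_histogram_map, skull_strip, smooth_fwhm
from .registration import apply_transform, invert, register


class SegmentationError(RuntimeError):
    pass


def mse(a: Volume, b: Volume, mask) -> float:
    """Mean squared voxelwise difference over the mask."""
    if not a.same_geometry(b):
        raise ValueError("images must share geometry")
    m = np.asarray(mask) > 0
    if m.shape != a.shape:
        raise ValueError("mask shape mismatch")
    if not np.any(m):
        raise ValueError("empty mask")
    diff = np.asarray(a.voxels, float)[m] - np.asarray(b.voxels, float)[m]
    return float(np.mean(diff**2))


@dataclass
class SelectionResult:
    """Ordered outcome of the two-step atlas search."""

    step1: list[tuple[str, float]]  # (atlas id, global MSE), ascending
    step2: list[tuple[str, float]]  # (atlas id, local MSE), ascending

    @property
    def step1_ids(self) -> list[str]:
        return [i for i, _ in self.step1]

    @property
    def step2_ids(self) -> list[str]:
        return [i for i, _ in self.step2]

    def to_jsonable(self) -> dict:
        return {
            "step1": [{"id": i, "global_mse": v} for i, v in self.step1],
            "step2": [{"id": i, "local_mse": v} for i, v in self.step2],
        }


def select_atlases(
    target_global_spec: Volume,
    target_local_spec: Volume,
    db: AtlasDatabase,
    k1: int = 10,
    k2: int = 5,
) -> SelectionResult:
    """Two-step best-matched atlas search.

    Step 1 ranks the whole database by global-specified MSE over the brain
    mask and keeps the ``k1`` most similar; step 2 re-ranks the candidates
    by local-specified MSE over the (1-voxel-dilated) striatum mask and
    keeps the ``k2`` best. Ties break by atlas id.
    """
    if k2 > k1:
        raise ValueError(f"k2 ({k2}) must not exceed k1 ({k1})")
    brain = db.brain_mask()
    striatum = db.striatum_mask(dilate=1)
    step1_all = sorted(
        ((a.atlas_id, mse(target_global_spec, a.global_spec, brain)) for a in db.atlases),
        key=lambda t: (t[1], t[0]),
    )
    step1 = step1_all[: min(k1, len(step1_all))]
    kept = {i for i, _ in step1}
    step2_all = sorted(
        (
            (a.atlas_id, mse(target_local_spec, a.local_spec, striatum))
            for a in db.atlases
            if a.atlas_id in kept
        ),
        key=lambda t: (t[1], t[0]),
    )
    step2 = step2_all[: min(k2, len(step2_all))]
    return SelectionResult(step1, step2)


@dataclass
class FusionParams:
    """Joint-label-fusion hyperparameters (voxel units)."""

    patch_radius: int = 2
    search_radius: int = 2
    beta: float = 2.0
    lam: float = 0.1  # ridge, scaled by the mean diagonal of the dependency matrix

    def __post_init__(self) -> None:
        if self.patch_radius < 0 or self.search_radius < 0:
            raise ValueError("radii must be >= 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


def _search_offsets(sr: int) -> list[tuple[int, int, int]]:
    """Lexicographic offset enumeration; argmin keeps the first minimum."""
    return list(itertools.product(range(-sr, sr + 1), repeat=3))


def _shift_zero(a: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """out[x] = a[x+d] with zero padding outside the grid."""
    out = np.zeros_like(a)
    src, dst = [], []
    for axis, dd in enumerate(d):
        n = a.shape[axis]
        if dd >= 0:
            src.append(slice(dd, n))
            dst.append(slice(0, n - dd))
        else:
            src.append(slice(0, n + dd))
            dst.append(slice(-dd, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


def solve_fusion_weights(M: np.ndarray, lam: float) -> np.ndarray:
    """Voting weights from dependency matrices, batched over voxels.

    Solves ``(M + ridge*I) w = 1`` with ridge ``lam * mean(diag(M))`` plus a
    tiny jitter keeping near-singular systems solvable, then clips negative
    weights to zero and renormalizes to a convex combination. All-zero
    matrices (every atlas patch identical to the target) fall back to equal
    weights.
    """
    M = np.asarray(M, dtype=np.float64)
    single = M.ndim == 2
    if single:
        M = M[None]
    nvox, n, _ = M.shape
    diag_mean = np.einsum("vii->v", M) / n
    ridge = lam * diag_mean + 1e-9 * np.maximum(diag_mean, 1.0)
    Mreg = M + ridge[:, None, None] * np.eye(n)
    ones = np.ones((nvox, n, 1))
    try:
        w = np.linalg.solve(Mreg, ones)[..., 0]
    except np.linalg.LinAlgError:
        w = np.stack(
            [np.linalg.lstsq(m, o[..., 0], rcond=None)[0] for m, o in zip(Mreg, ones)]
        )
    w = np.clip(w, 0.0, None)
    total = w.sum(axis=1)
    bad = total <= 0
    w[bad] = 1.0
    total[bad] = n
    w /= total[:, None]
    w[diag_mean == 0] = 1.0 / n
    return w[0] if single else w


def joint_label_fusion(
    target: Volume,
    atlas_pets: list[Volume],
    atlas_labels: list[LabelVolume],
    params: FusionParams | None = None,
) -> LabelVolume:
    """Fuse candidate label maps by locally weighted voting.

    Per voxel x: each atlas i contributes the absolute intensity
    difference patch ``y_i(p) = |A_i(x+d_i+p) - T(x+p)|^beta`` at its
    best-matching offset ``d_i`` (smallest patch SSD within the search
    window); the dependency matrix ``M_ij = sum_p y_i(p) y_j(p)`` is solved
    for weights ``w = (M + ridge I)^-1 1`` (clipped, renormalized) and the
    fused label is ``argmax_l sum_i w_i [L_i(x) = l]``, smallest code on
    ties. Voxels where all atlases agree take that label directly (any
    convex weighting gives the same vote). Out-of-grid intensities read as
    zero everywhere.
    """
    params = params or FusionParams()
    if len(atlas_pets) == 0:
        raise ValueError("at least one atlas is required")
    if len(atlas_pets) != len(atlas_labels):
        raise ValueError("atlas pets and labels must pair up")
    for img in (*atlas_pets, *atlas_labels):
        if not img.same_geometry(target):
            raise ValueError("all atlas images must share the target geometry")
    legend: dict[int, str] = {}
    for lab in atlas_labels:
        legend.update(lab.legend)
    L = np.stack([lab.codes for lab in atlas_labels])
    out = L[0].copy()
    n = len(atlas_pets)
    if n == 1:
        return LabelVolume(out, target.affine, legend)
    agree = np.all(L == L[0][None], axis=0)
    if bool(agree.all()):
        return LabelVolume(out, target.affine, legend)
    vox = np.argwhere(~agree)
    T = np.asarray(target.voxels, dtype=np.float32)
    A = [np.asarray(p.voxels, dtype=np.float32) for p in atlas_pets]
    pr, sr = params.patch_radius, params.search_radius
    psize = 2 * pr + 1
    offsets = _search_offsets(sr)

    # crop to the disagreement bounding box (plus patch+search margin) so the
    # per-offset error maps are computed on as little of the grid as possible
    lo = np.maximum(vox.min(axis=0) - (pr + sr), 0)
    hi = np.minimum(vox.max(axis=0) + (pr + sr) + 1, T.shape)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    Tb = T[box].copy()
    Ab = [a[box].copy() for a in A]
    vox_b = vox - lo[None, :]

    # off-grid intensity reads are zero (for each image independently), so
    # pad by the patch radius before differencing and box-filtering
    Tb_pad = np.pad(Tb, pr)
    Ab_pad = [np.pad(a, pr) for a in Ab]
    center = tuple(v + pr for v in np.asarray(vox_b).T)
    best_err = np.full((n, len(vox)), np.inf, dtype=np.float32)
    best_off = np.zeros((n, len(vox)), dtype=np.int32)
    for oi, d in enumerate(offsets):
        for i in range(n):
            sq = (_shift_zero(Ab_pad[i], d) - Tb_pad) ** 2
            errs = ndimage.uniform_filter(sq, size=psize, mode="constant", cval=0.0)
            e = errs[center]
            upd = e < best_err[i]
            best_err[i][upd] = e[upd]
            best_off[i][upd] = oi

    # gather best-offset patches and build the dependency matrices
    patch_offsets = np.array(list(itertools.product(range(-pr, pr + 1), repeat=3)))
    pad_t = pr
    pad_a = pr + sr
    Tp = np.pad(Tb, pad_t)
    Ap = [np.pad(a, pad_a) for a in Ab]
    t_idx = vox_b[:, None, :] + patch_offsets[None, :, :] + pad_t  # (nvox, P, 3)
    t_shape = Tp.shape
    t_flat = np.ravel_multi_index(
        (t_idx[..., 0], t_idx[..., 1], t_idx[..., 2]), t_shape
    )
    T_patches = Tp.ravel()[t_flat]  # (nvox, P)
    off_arr = np.array(offsets)
    Y = np.empty((n, len(vox), patch_offsets.shape[0]), dtype=np.float64)
    a_shape = Ap[0].shape
    for i in range(n):
        d_i = off_arr[best_off[i]]  # (nvox, 3)
        a_idx = vox_b[:, None, :] + patch_offsets[None, :, :] + d_i[:, None, :] + pad_a
        a_flat = np.ravel_multi_index(
            (a_idx[..., 0], a_idx[..., 1], a_idx[..., 2]), a_shape
        )
        Y[i] = np.abs(Ap[i].ravel()[a_flat] - T_patches) ** params.beta
    M = np.einsum("ivp,jvp->vij", Y, Y, optimize=True)
    w = solve_fusion_weights(M, params.lam)  # (nvox, n)

    # weighted plurality vote, ties -> smallest code
    labels_at = L[(slice(None),) + tuple(vox.T)]  # (n, nvox)
    codes = np.unique(labels_at)
    scores = np.zeros((len(codes), len(vox)))
    for ci, c in enumerate(codes):
        scores[ci] = np.sum(w.T * (labels_at == c), axis=0)
    fused = codes[np.argmax(scores, axis=0)]
    out[tuple(vox.T)] = fused
    return LabelVolume(out, target.affine, legend)


def _specify_target_native(target: Volume, brain_mask, db: AtlasDatabase):
    """Strip + smooth + globally specify the target in its native space."""
    smooth = db.params["settings"]["smooth_fwhm_mm"]
    nq = db.params["settings"]["n_quantiles"]
    stripped = skull_strip(target, brain_mask)
    smoothed = smooth_fwhm(stripped, smooth, mask=brain_mask)
    gmap = fit_histogram_map(
        smoothed, db.global_reference_quantiles(), brain_mask, n_quantiles=nq
    )
    return apply_histogram_map(gmap, smoothed, brain_mask)


def preprocess_target_template_space(target_tpl: Volume, db: AtlasDatabase):
    """Target preprocessing in template space: strip, smooth, global + local
    histogram specification (no partial-volume correction for targets)."""
    brain = db.brain_mask()
    striatum = db.striatum_mask()
    nq = db.params["settings"]["n_quantiles"]
    stripped = skull_strip(target_tpl, brain)
    smoothed = smooth_fwhm(stripped, db.params["settings"]["smooth_fwhm_mm"], mask=brain)
    gmap = fit_histogram_map(smoothed, db.global_reference_quantiles(), brain, n_quantiles=nq)
    global_spec = apply_histogram_map(gmap, smoothed, brain)
    lmap = fit_histogram_map(
        global_spec, db.local_reference_quantiles(), striatum, n_quantiles=nq
    )
    local_spec = apply_histogram_map(lmap, global_spec, striatum)
    return global_spec, local_spec


def segment_multiatlas(
    target_pet: Volume,
    db: AtlasDatabase,
    params: FusionParams | None = None,
    k1: int = 10,
    k2: int = 5,
    transform=None,
) -> tuple[LabelVolume, SelectionResult]:
    """Full multi-atlas chain for one native-space target PET.

    Warp target to template space and preprocess it; select atlases by the
    two-step MSE search; register each chosen atlas to the target; warp the
    chosen labels into native target space; fuse with JLF. The output label
    volume lives on the target's native grid.
    """
    params = params or FusionParams()
    reg_settings = None  # database defaults are baked into RegistrationSettings()
    try:
        tx = transform or register(target_pet, db.template, "deformable", reg_settings)
    except Exception as exc:
        raise SegmentationError(f"target-to-template registration failed: {exc}") from exc
    target_tpl = apply_transform(tx, target_pet, db.geometry)
    global_spec, local_spec = preprocess_target_template_space(target_tpl, db)
    selection = select_atlases(global_spec, local_spec, db, k1=k1, k2=k2)

    # native-space brain mask via the inverse warp of the template labels
    inv_tx = invert(tx)
    labels_native_tpl = apply_transform(inv_tx, db.template_labels, target_pet.geometry)
    brain_native = labels_native_tpl.codes > 0
    target_spec_native = _specify_target_native(target_pet, brain_native, db)

    chosen = {a.atlas_id: a for a in db.atlases}
    warped_pets, warped_labels = [], []
    for aid in selection.step2_ids:
        atlas = chosen[aid]
        try:
            tx_a = register(atlas.global_spec, target_spec_native, "deformable", reg_settings)
        except Exception as exc:
            raise SegmentationError(f"atlas {aid} registration to target failed: {exc}") from exc
        warped_pets.append(apply_transform(tx_a, atlas.global_spec, target_pet.geometry))
        warped_labels.append(apply_transform(tx_a, atlas.labels, target_pet.geometry))
    fused = joint_label_fusion(target_spec_native, warped_pets, warped_labels, params)
    return fused, selection


def segment_template_based(
    target_pet: Volume, db: AtlasDatabase, transform=None
) -> LabelVolume:
    """Single-template baseline: one deformable registration to the template,
    inverse warp of the template labels back to native space."""
    try:
        tx = transform or register(target_pet, db.template, "deformable")
    except Exception as exc:
        raise SegmentationError(f"target-to-template registration failed: {exc}") from exc
    inv_tx = invert(tx)
    return apply_transform(inv_tx, db.template_labels, target_pet.geometry)
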