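"""Geometric subdivision of the striatum into 7 bilateral subregions.

The striatum is split into hemispheres by a sagittal plane through the
median left-right (world-x) coordinate of all putamen voxels. Within each
hemisphere the putamen and caudate are then cut into anterior / median /
posterior thirds of equal length along the oblique 3D line joining each
structure's anterior-most and posterior-most voxel centers; the nucleus
accumbens passes through undivided. The result is 14 codes: {anterior,
median, posterior} x {putamen, caudate} plus accumbens, per side, with the
cerebellum kept under its own code as the SUVR reference region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imgio import LabelVolume
from .phantom import ACCUMBENS, CAUDATE, CEREBELLUM, PUTAMEN

SUBREGION_NAMES = ("APu", "MPu", "PPu", "ACa", "MCa", "PCa", "NAc")

# default code table: left 11..17, right 21..27, cerebellum 30
_DEFAULT_CODES = {
    **{f"{name}_L": 11 + i for i, name in enumerate(SUBREGION_NAMES)},
    **{f"{name}_R": 21 + i for i, name in enumerate(SUBREGION_NAMES)},
}
CEREBELLUM_CODE = 30


@dataclass(frozen=True)
class SubregionScheme:
    """Code table for the 14 striatal subregions plus the reference region."""

    codes: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_CODES))
    cerebellum_code: int = CEREBELLUM_CODE

    def __post_init__(self) -> None:
        expected = {f"{n}_{h}" for n in SUBREGION_NAMES for h in "LR"}
        if set(self.codes) != expected:
            raise ValueError(f"scheme must define exactly the codes {sorted(expected)}")
        values = list(self.codes.values()) + [self.cerebellum_code]
        if len(set(values)) != len(values):
            raise ValueError("subregion codes must be distinct")

    def code(self, name: str, hemisphere: str) -> int:
        return self.codes[f"{name}_{hemisphere}"]

    def legend(self) -> dict[int, str]:
        leg = {v: k for k, v in self.codes.items()}
        leg[self.cerebellum_code] = "cerebellum"
        return leg


def hemisphere_plane(labels: LabelVolume, putamen_code: int = PUTAMEN) -> float:
    """Sagittal splitting plane through the putamen's left-right midpoint.

    The putamen's world-x coordinates form two lateral clusters, so the
    plain median of all voxels is unstable: with any count imbalance it
    jumps to the inner edge of the larger cluster instead of the midline.
    The plane is therefore placed midway between the median x of each side
    (sides split at the centroid), which equals the plain median for
    balanced sets and stays at the inter-cluster midline otherwise.

    Voxels strictly below the plane belong to the right hemisphere, strictly
    above to the left; voxels exactly on the plane go left (fixed rule).
    """
    m = labels.codes == putamen_code
    if not np.any(m):
        raise ValueError("no putamen voxels present")
    xs = labels.world_coords(m)[:, 0]
    c = xs.mean()
    lower, upper = xs[xs <= c], xs[xs > c]
    if lower.size == 0 or upper.size == 0:
        return float(np.median(xs))
    return float((np.median(lower) + np.median(upper)) / 2.0)


def divide_thirds(
    structure_mask: np.ndarray, labels: LabelVolume
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a structure into (anterior, median, posterior) masks.

    F and B are the anterior-most and posterior-most voxel centers (max /
    min world-y, ties resolved by smallest x then smallest z). Every voxel
    center projects onto the line FB as ``t`` in [0, 1] (t=0 at B); the
    thirds are the half-open bands t < 1/3, 1/3 <= t < 2/3, t >= 2/3, so
    boundary voxels join the more anterior segment. A single-point axis
    (F == B) puts the whole structure in the median band.
    """
    m = np.asarray(structure_mask) > 0
    if not np.any(m):
        raise ValueError("empty structure mask")
    coords = labels.world_coords(m)  # (n, 3) world mm

    def _endpoint(maximize: bool) -> np.ndarray:
        y = coords[:, 1]
        sel = coords[y == (y.max() if maximize else y.min())]
        order = np.lexsort((sel[:, 2], sel[:, 0]))  # smallest x, then z
        return sel[order[0]]

    F = _endpoint(True)
    B = _endpoint(False)
    axis = F - B
    norm2 = float(axis @ axis)
    anterior = np.zeros(m.shape, bool)
    median = np.zeros(m.shape, bool)
    posterior = np.zeros(m.shape, bool)
    idx = np.argwhere(m)
    if norm2 == 0.0:
        median[m] = True
        return anterior, median, posterior
    t = (coords - B) @ axis / norm2
    post_sel = t < 1.0 / 3.0
    ant_sel = t >= 2.0 / 3.0
    med_sel = ~(post_sel | ant_sel)
    for sel, dest in ((ant_sel, anterior), (med_sel, median), (post_sel, posterior)):
        ii = idx[sel]
        dest[ii[:, 0], ii[:, 1], ii[:, 2]] = True
    return anterior, median, posterior


def build_subregions(
    labels: LabelVolume, scheme: SubregionScheme | None = None
) -> LabelVolume:
    """Produce the 14-code subregion label volume from anatomy labels.

    Requires caudate, putamen and accumbens codes in the input. All
    non-striatal voxels map to 0 except the cerebellum, which keeps its own
    reference code.
    """
    scheme = scheme or SubregionScheme()
    for code, name in ((CAUDATE, "caudate"), (PUTAMEN, "putamen"), (ACCUMBENS, "accumbens")):
        if not np.any(labels.codes == code):
            raise ValueError(f"missing structure in labels: {name}")
    x0 = hemisphere_plane(labels)
    x_world = labels.world_coords().reshape(*labels.shape, 3)[..., 0]
    left = x_world >= x0  # ties (x == x0) go left
    out = np.zeros(labels.shape, dtype=np.int16)
    out[labels.codes == CEREBELLUM] = scheme.cerebellum_code
    for hemi, hemi_mask in (("L", left), ("R", ~left)):
        for code, prefix in ((PUTAMEN, "Pu"), (CAUDATE, "Ca")):
            m = (labels.codes == code) & hemi_mask
            if not np.any(m):
                continue
            ant, med, post = divide_thirds(m, labels)
            out[ant] = scheme.code(f"A{prefix}", hemi)
            out[med] = scheme.code(f"M{prefix}", hemi)
            out[post] = scheme.code(f"P{prefix}", hemi)
        acc = (labels.codes == ACCUMBENS) & hemi_mask
        out[acc] = scheme.code("NAc", hemi)
    return LabelVolume(out, labels.affine, scheme.legend())
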