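"""SUVR quantification over striatal subregions.

SUVR = (mean activity in the target region) / (mean activity in the
reference region). The reference is the whole cerebellum taken from the
same label volume that produced the subregions, so target and reference
live in a single space. Bilateral mode (the default) pools left and right
voxels of each subregion before averaging, yielding 7 rows per subject;
per-hemisphere mode yields 14.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imgio import LabelVolume, Volume
from .subregions import SUBREGION_NAMES, SubregionScheme

SUVR_COLUMNS = ["subject", "method", "region", "hemisphere", "suvr"]


def suvr(pet: Volume, target_mask, reference_mask) -> float:
    """Mean-target over mean-reference uptake ratio."""
    t = np.asarray(target_mask) > 0
    r = np.asarray(reference_mask) > 0
    if t.shape != pet.shape or r.shape != pet.shape:
        raise ValueError("mask geometry mismatch")
    if not np.any(t):
        raise ValueError("empty target mask")
    if not np.any(r):
        raise ValueError("empty reference mask")
    ref_mean = float(np.mean(np.asarray(pet.voxels, float)[r]))
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference mean ({ref_mean:g})")
    return float(np.mean(np.asarray(pet.voxels, float)[t])) / ref_mean


def suvr_table(
    pet: Volume,
    subregion_labels: LabelVolume,
    scheme: SubregionScheme | None = None,
    bilateral: bool = True,
    subject: str = "",
    method: str = "",
) -> pd.DataFrame:
    """SUVR of every striatal subregion against the cerebellar reference.

    Raises if any subregion (or the reference) has no voxels — a silent
    zero-voxel region would poison downstream group statistics.
    """
    scheme = scheme or SubregionScheme()
    if not subregion_labels.same_geometry(pet):
        raise ValueError("labels must share the PET geometry")
    ref = subregion_labels.codes == scheme.cerebellum_code
    rows = []
    for name in SUBREGION_NAMES:
        masks = {h: subregion_labels.codes == scheme.code(name, h) for h in "LR"}
        for h, m in masks.items():
            if not np.any(m):
                raise ValueError(f"subregion {name}_{h} has zero voxels")
        if bilateral:
            rows.append((subject, method, name, "bilateral",
                         suvr(pet, masks["L"] | masks["R"], ref)))
        else:
            for h, m in masks.items():
                rows.append((subject, method, name, h, suvr(pet, m, ref)))
    return pd.DataFrame(rows, columns=SUVR_COLUMNS)
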