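"""Evaluation statistics: Dice overlap, consistency ICC, group t-tests.

* Dice = 2|A n B| / (|A| + |B|) between two binary segmentations.
* ICC(3,1) — the two-way mixed-effects single-measure *consistency*
  intraclass correlation between two measurement methods, from the two-way
  ANOVA decomposition. Consistency ICC ignores a constant additive offset
  between the methods, which is the right notion when comparing a pipeline's
  SUVRs against reference-mask SUVRs.
* Two-sample t (pooled variance by default, Welch optional) with Cohen's d,
  computable from summary statistics so published group means/SDs can be
  re-analyzed directly. No multiplicity adjustment is applied to the
  per-subregion group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def dice(a_mask, b_mask) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a_mask) > 0
    b = np.asarray(b_mask) > 0
    if a.shape != b.shape:
        raise ValueError("masks must share geometry")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int(np.logical_and(a, b).sum()) / (sa + sb)


def icc_consistency(pairs) -> float:
    """ICC(3,1): (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error).

    ``pairs`` is a sequence of (x, y) measurements of the same subjects by
    two methods (k = 2 raters). The value is returned as computed — it may
    be negative; no silent clipping.
    """
    data = np.asarray(list(pairs), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (x, y) tuples")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    if not np.all(np.isfinite(data)):
        raise ValueError("pairs contain non-finite values")
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    if np.allclose(data, grand):
        raise ValueError("zero total variance")
    ms_subj = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    resid = data - subj_means[:, None] - rater_means[None, :] + grand
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = ms_subj + (k - 1) * ms_err
    if denom == 0:
        raise ValueError("degenerate ANOVA decomposition")
    return float((ms_subj - ms_err) / denom)


def two_sample_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variance: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t from summary statistics: (t, df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    v1, v2 = sd1**2, sd2**2
    if variance == "pooled":
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    elif variance == "welch":
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        ) if se > 0 else float(n1 + n2 - 2)
    else:
        raise ValueError(f"unknown variance model {variance!r}")
    if se == 0:
        if mean1 == mean2:
            raise ValueError("degenerate test: zero variance and equal means")
        raise ValueError("degenerate test: zero variance with unequal means")
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def two_sample_t_from_samples(x, y, variance: str = "pooled"):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return two_sample_t(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), variance
    )


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Effect size: mean difference in pooled-SD units."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    s2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if s2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((mean1 - mean2) / np.sqrt(s2))


@dataclass
class GroupStats:
    """Per-subregion group comparison table."""

    table: pd.DataFrame  # region, mean/sd/n per group, t, df, p, d

    def region(self, name: str) -> pd.Series:
        return self.table.set_index("region").loc[name]


def compare_groups(
    suvr_table: pd.DataFrame,
    group_map: dict[str, str],
    variance: str = "pooled",
    group_a: str = "HC",
    group_b: str = "PD",
) -> GroupStats:
    """Group statistics (t, p, Cohen's d) per subregion from a SUVR table.

    ``suvr_table`` has columns subject/region/suvr (one value per subject
    and region); ``group_map`` assigns each subject to a group.
    """
    df = suvr_table.copy()
    df["group"] = df["subject"].map(group_map)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "subject"].unique())
        raise ValueError(f"subjects missing from group map: {missing}")
    rows = []
    for region, sub in df.groupby("region", sort=False):
        a = sub.loc[sub["group"] == group_a, "suvr"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "suvr"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"group with <2 subjects for region {region}")
        t, dfree, p = two_sample_t(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b), variance
        )
        d = cohens_d(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
        rows.append(
            dict(region=region,
                 mean_a=a.mean(), sd_a=a.std(ddof=1), n_a=len(a),
                 mean_b=b.mean(), sd_b=b.std(ddof=1), n_b=len(b),
                 t=t, df=dfree, p=p, cohens_d=d)
        )
    return GroupStats(pd.DataFrame(rows))


def dice_table(
    predicted: "np.ndarray | object", truth: "np.ndarray | object", regions: dict[str, tuple[int, ...]]
) -> pd.DataFrame:
    """Per-region Dice between two label volumes.

    ``regions`` maps a region name to the label codes it comprises (e.g.
    striatum = caudate + putamen + accumbens codes).
    """
    pred_codes = predicted.codes if hasattr(predicted, "codes") else np.asarray(predicted)
    true_codes = truth.codes if hasattr(truth, "codes") else np.asarray(truth)
    rows = []
    for name, codes in regions.items():
        rows.append(
            dict(region=name,
                 dice=dice(np.isin(pred_codes, codes), np.isin(true_codes, codes)))
        )
    return pd.DataFrame(rows)
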