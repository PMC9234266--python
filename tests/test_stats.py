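"""Dice, consistency ICC, two-sample t and effect size, group tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from striatseg.stats import (
    cohens_d,
    compare_groups,
    dice,
    dice_table,
    icc_consistency,
    two_sample_t,
    two_sample_t_from_samples,
)

# published reference-cohort SUVR summaries (mean, SD) for the seven
# striatal subregions, healthy (n=20) vs parkinsonian (n=28)
REFERENCE_GROUPS = {
    "APu": ((3.34, 0.29), (1.99, 0.46)),
    "MPu": ((3.57, 0.41), (1.67, 0.40)),
    "PPu": ((3.67, 0.47), (1.52, 0.40)),
    "ACa": ((3.04, 0.31), (2.14, 0.53)),
    "MCa": ((2.97, 0.43), (2.07, 0.53)),
    "PCa": ((2.03, 0.39), (1.45, 0.36)),
    "NAc": ((2.46, 0.18), (2.14, 0.31)),
}


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool); a[0] = True
        b = np.zeros((4, 4, 4), bool); b[3] = True
        assert dice(a, b) == 0.0

    def test_hand_case(self):
        # |A| = 4, |B| = 6, |A n B| = 3 -> 2*3 / 10 = 0.6
        a = np.zeros(10, bool); a[:4] = True
        b = np.zeros(10, bool); b[1:7] = True
        assert dice(a, b) == pytest.approx(0.6)

    def test_symmetric(self, rng):
        a = rng.random((5, 5, 5)) > 0.5
        b = rng.random((5, 5, 5)) > 0.5
        assert dice(a, b) == dice(b, a)

    def test_both_empty_rejected(self):
        z = np.zeros((3, 3, 3), bool)
        with pytest.raises(ValueError):
            dice(z, z)

    def test_dice_table_regions(self):
        pred = np.zeros((4, 4, 4), int); pred[1:3] = 3
        true = np.zeros((4, 4, 4), int); true[1:3] = 3
        out = dice_table(pred, true, {"caudate": (3,), "striatum": (3, 4, 5)})
        assert dict(zip(out.region, out.dice)) == {"caudate": 1.0, "striatum": 1.0}


class TestICC:
    def test_perfect_agreement(self):
        pairs = [(1.0, 1.0), (2.0, 2.0), (3.5, 3.5), (4.0, 4.0)]
        assert icc_consistency(pairs) == pytest.approx(1.0)

    def test_additive_offset_ignored(self):
        pairs = [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6)]
        assert icc_consistency(pairs) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(77)
        pairs = list(zip(rng.normal(size=1000), rng.normal(size=1000)))
        assert abs(icc_consistency(pairs)) < 0.1

    def test_affine_transform_invariance(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.2, size=30)
        base = icc_consistency(zip(x, y))
        scaled = icc_consistency(zip(3.0 * x + 7.0, 3.0 * y + 7.0))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_matches_pingouin_icc3(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(5, 1, size=25)
        y = x + rng.normal(0, 0.5, size=25)
        ours = icc_consistency(zip(x, y))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(25), 2),
            "rater": np.tile(["a", "b"], 25),
            "score": np.column_stack([x, y]).ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        icc3 = float(ref["ICC"].iloc[2])  # two-way mixed, single, consistency
        assert ours == pytest.approx(icc3, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_consistency([(1, 1), (2, 2)])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_consistency([(1.0, 1.0)] * 5)


class TestTwoSampleT:
    def test_equal_means_give_zero(self):
        t, df, p = two_sample_t(2.0, 0.5, 10, 2.0, 0.7, 12)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("region,printed_t", [
        ("APu", 11.52), ("MPu", 15.94), ("PPu", 17.09), ("ACa", 6.75),
        ("MCa", 6.21), ("PCa", 5.36), ("NAc", 4.18),
    ])
    def test_reference_cohort_t_values(self, region, printed_t):
        (m1, s1), (m2, s2) = REFERENCE_GROUPS[region]
        t, df, p = two_sample_t(m1, s1, 20, m2, s2, 28, "pooled")
        assert df == 46
        assert t == pytest.approx(printed_t, rel=0.02)
        assert p < 0.001

    def test_matches_scipy_from_stats(self, rng):
        m1, s1, n1, m2, s2, n2 = 3.1, 0.4, 14, 2.2, 0.6, 19
        t, df, p = two_sample_t(m1, s1, n1, m2, s2, n2, "pooled")
        ref = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)
        tw, dfw, pw = two_sample_t(m1, s1, n1, m2, s2, n2, "welch")
        refw = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
        assert tw == pytest.approx(refw.statistic, rel=1e-12)
        assert pw == pytest.approx(refw.pvalue, rel=1e-12)

    def test_pooled_equals_welch_for_balanced_equal_sd(self):
        tp = two_sample_t(1.0, 0.5, 10, 0.4, 0.5, 10, "pooled")
        tw = two_sample_t(1.0, 0.5, 10, 0.4, 0.5, 10, "welch")
        assert tp[0] == pytest.approx(tw[0], rel=1e-12)

    def test_summary_equals_raw(self, rng):
        x = rng.normal(3, 1, 17)
        y = rng.normal(2, 1.5, 23)
        t_raw = two_sample_t_from_samples(x, y)
        t_sum = two_sample_t(x.mean(), x.std(ddof=1), len(x),
                             y.mean(), y.std(ddof=1), len(y))
        assert t_raw[0] == pytest.approx(t_sum[0], abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_sample_t(1.0, 0.0, 5, 1.0, 0.0, 5)


class TestCohensD:
    def test_equal_means(self):
        assert cohens_d(2.0, 1.0, 10, 2.0, 1.0, 10) == 0.0

    def test_unit_case(self):
        assert cohens_d(1.0, 1.0, 10, 0.0, 1.0, 10) == pytest.approx(1.0)

    def test_reference_cohort_effect_size(self):
        # hand evaluation: pooled SD = sqrt((19*0.29^2 + 27*0.46^2)/46)
        (m1, s1), (m2, s2) = REFERENCE_GROUPS["APu"]
        expected = (m1 - m2) / np.sqrt((19 * s1**2 + 27 * s2**2) / 46)
        assert cohens_d(m1, s1, 20, m2, s2, 28) == pytest.approx(expected, rel=1e-12)
        assert cohens_d(m1, s1, 20, m2, s2, 28) == pytest.approx(3.39, abs=0.05)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0, 5, 2.0, 0.0, 5)


def _toy_suvr_table(rng, n_per_group=10, gap=0.5):
    rows = []
    for g, base in (("HC", 3.0), ("PD", 3.0 - gap)):
        for i in range(n_per_group):
            sid = f"{g.lower()}{i}"
            for region in ("APu", "MPu", "PPu"):
                rows.append((sid, "multiatlas", region, "bilateral",
                             base + rng.normal(0, 0.25)))
    return pd.DataFrame(rows, columns=["subject", "method", "region",
                                       "hemisphere", "suvr"])


class TestCompareGroups:
    def test_identical_groups_give_zero_t(self, rng):
        table = _toy_suvr_table(rng, gap=0.0)
        # duplicate HC values into PD rows so groups are literally identical
        wide = table.pivot_table(index="subject", columns="region", values="suvr")
        hc = wide.loc[[s for s in wide.index if s.startswith("hc")]]
        rows = []
        for g in ("HC", "PD"):
            for i, (_, vals) in enumerate(hc.iterrows()):
                for region, v in vals.items():
                    rows.append((f"{g.lower()}{i}", "m", region, "bilateral", v))
        table = pd.DataFrame(rows, columns=["subject", "method", "region",
                                            "hemisphere", "suvr"])
        group_map = {s: ("HC" if s.startswith("hc") else "PD")
                     for s in table["subject"].unique()}
        out = compare_groups(table, group_map).table
        np.testing.assert_allclose(out["t"], 0.0, atol=1e-12)

    def test_separated_groups_significant(self, rng):
        table = _toy_suvr_table(rng, gap=0.6)
        group_map = {s: ("HC" if s.startswith("hc") else "PD")
                     for s in table["subject"].unique()}
        out = compare_groups(table, group_map).table
        assert (out["p"] < 0.05).all()
        assert (out["t"] > 0).all()  # healthy uptake higher

    def test_shuffled_labels_calibrated(self, rng):
        # permutation calibration: false-positive rate ~ alpha under the null
        n_perm, alpha = 200, 0.05
        hits = 0
        table = _toy_suvr_table(rng, n_per_group=10, gap=0.0)
        subjects = list(table["subject"].unique())
        for _ in range(n_perm):
            perm = rng.permutation(len(subjects))
            group_map = {s: ("HC" if perm[i] < 10 else "PD")
                         for i, s in enumerate(subjects)}
            out = compare_groups(table, group_map).table
            hits += int((out["p"] < alpha).sum())
        rate = hits / (n_perm * 3)
        assert abs(rate - alpha) < 0.04

    def test_small_group_rejected(self, rng):
        table = _toy_suvr_table(rng)
        group_map = {s: ("HC" if s == "hc0" else "PD")
                     for s in table["subject"].unique()}
        with pytest.raises(ValueError, match="<2"):
            compare_groups(table, group_map)

    def test_unmapped_subject_rejected(self, rng):
        table = _toy_suvr_table(rng)
        with pytest.raises(ValueError, match="missing from group map"):
            compare_groups(table, {"hc0": "HC"})
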