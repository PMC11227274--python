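"""Footfall-pattern classification, support timelines and aerial detection."""

import numpy as np
import pytest

from hippogait import (
    CLASS4_LABELS,
    CLASS8_LABELS,
    LimbId,
    StrideParams,
    bipedal_support_profile,
    classify,
    detect_aerial,
    forelimb_lag,
    support_timeline,
)
from hippogait.gaits import _circular_bin

from conftest import make_trial  # noqa: F401


def params(phase_lf, phase_rh, phase_rf, df=0.5, dfs=None, duration=1.0):
    """Directly assemble StrideParams for classification tests."""
    phases = {
        LimbId.LH: 0.0,
        LimbId.LF: phase_lf,
        LimbId.RH: phase_rh,
        LimbId.RF: phase_rf,
    }
    dfs = dfs or {limb: df for limb in LimbId}
    return StrideParams(
        duration=duration,
        phases=phases,
        duty_factors=dfs,
        stance={l: dfs[l] * duration for l in LimbId},
        swing={l: (1 - dfs[l]) * duration for l in LimbId},
    )


def sampled_supports(p, resolution=1e-4):
    """Brute-force support counts on a phase grid — independent oracle."""
    grid = np.arange(0.0, 1.0, resolution)
    counts = np.zeros_like(grid, dtype=int)
    for limb in LimbId:
        on = p.phases[limb] % 1.0
        df = p.duty_factors[limb]
        counts += ((grid - on) % 1.0 < df).astype(int) | (df >= 1.0)
    return grid, counts


class TestForelimbLag:
    def test_hippo_mean_phases(self):
        # circular mean of LF offset 0.46 and RF-RH offset 0.43
        lag = forelimb_lag(params(0.46, 0.51, 0.94))
        assert lag == pytest.approx(0.445, abs=1e-12)

    @pytest.mark.parametrize(
        "phases,expected",
        [
            ((0.5, 0.5, 0.0), 0.5),  # ideal trot
            ((0.0, 0.5, 0.5), 0.0),  # ideal pace
            ((0.25, 0.5, 0.75), 0.25),  # LS singlefoot
            ((0.75, 0.5, 0.25), 0.75),  # DS singlefoot
        ],
    )
    def test_ideal_templates(self, phases, expected):
        assert forelimb_lag(params(*phases)) == pytest.approx(expected, abs=1e-12)


class TestClassify:
    def test_hippo_mean_stride_is_a_walking_trot(self):
        g = classify(params(0.46, 0.51, 0.94, df=0.76))
        assert g.class8 == "trot"
        assert g.class4 == "trot"
        assert g.locomotion == "walking"
        assert g.symmetry == "symmetrical"

    def test_running_below_duty_factor_half_walking_at_exactly_half(self):
        assert classify(params(0.5, 0.5, 0.0, df=0.49)).locomotion == "running"
        assert classify(params(0.5, 0.5, 0.0, df=0.5)).locomotion == "walking"

    def test_ls_singlefoot_labels(self):
        g = classify(params(0.25, 0.50, 0.75))
        assert g.class8 == "LS-singlefoot"
        assert g.class4 == "lateral-sequence"

    def test_hind_lag_outside_window_flags_asymmetrical(self):
        g = classify(params(0.50, 0.20, 0.00))
        assert g.symmetry == "asymmetrical"
        assert g.class8 in CLASS8_LABELS  # labels still reported

    def test_bin_partition_covers_the_circle_once(self):
        """Every lag on a fine grid falls in exactly one 8-bin and one 4-bin,
        each bin is hit, bins are half-open with boundaries going up, and the
        4-way label's center is within 0.125 of the 8-way label's center."""
        grid = np.arange(0.0, 1.0, 1e-3)
        hits8 = np.zeros(8, dtype=int)
        hits4 = np.zeros(4, dtype=int)
        for lag in grid:
            k8 = _circular_bin(lag, 8)
            k4 = _circular_bin(lag, 4)
            hits8[k8] += 1
            hits4[k4] += 1
            d = abs(k8 / 8.0 - k4 / 4.0)
            assert min(d, 1 - d) <= 0.125 + 1e-12
        assert (hits8 == 125).all()  # 0.125-wide bins on a 1e-3 grid
        assert (hits4 == 250).all()
        # boundary values go to the higher bin
        assert CLASS8_LABELS[_circular_bin(0.4375, 8)] == "trot"
        assert CLASS8_LABELS[_circular_bin(0.5625, 8)] == "DS-diagonal-couplets"

    def test_cardinal_class8_labels_match_class4(self):
        pairs = {
            "trot": "trot",
            "pace": "pace",
            "LS-singlefoot": "lateral-sequence",
            "DS-singlefoot": "diagonal-sequence",
        }
        for lag, label8 in [(0.5, "trot"), (0.0, "pace"),
                            (0.25, "LS-singlefoot"), (0.75, "DS-singlefoot")]:
            g = classify(params((lag) % 1.0, 0.5, (0.5 + lag) % 1.0))
            assert g.class8 == label8
            assert g.class4 == pairs[label8]


class TestSupportTimeline:
    def test_ideal_trot_alternates_diagonal_pairs_and_aerial_gaps(self):
        tl = support_timeline(params(0.5, 0.5, 0.0, df=0.45))
        counts = [len(limbs) for _, _, limbs in tl.intervals]
        assert sorted(counts) == [0, 0, 2, 2]

    def test_continuous_contact_is_a_single_interval(self):
        tl = support_timeline(params(0.0, 0.0, 0.0, df=1.0))
        assert len(tl.intervals) == 1
        assert tl.intervals[0][2] == frozenset(LimbId)

    def test_hippo_phases_low_df_aerial_windows(self):
        p = params(0.46, 0.51, 0.94, df=0.40)
        tl = support_timeline(p)
        report = detect_aerial(tl, p)
        assert report.has_aerial
        windows = [
            (round(a, 6), round(b, 6)) for a, b in report.aerial_windows
        ]
        assert windows == [(0.40, 0.46), (0.91, 0.94)]
        assert report.aerial_fraction == pytest.approx(0.09)

    def test_interval_lengths_sum_to_one_and_match_duty_factors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = params(*rng.uniform(0, 1, 3),
                       dfs={l: float(rng.uniform(0.2, 0.95)) for l in LimbId})
            tl = support_timeline(p)
            assert sum(e - s for s, e, _ in tl.intervals) == pytest.approx(1.0)
            for limb in LimbId:
                frac = sum(
                    e - s for s, e, limbs in tl.intervals if limb in limbs
                )
                assert frac == pytest.approx(p.duty_factors[limb], abs=1e-9)


class TestDetectAerial:
    def test_mean_phase_gaps_match_published_arithmetic(self):
        p = params(0.46, 0.51, 0.94, df=0.36)
        report = detect_aerial(support_timeline(p), p)
        assert report.max_ipsilateral_gap == pytest.approx(0.54)
        assert report.predicted_simplified  # DF 0.36 < 0.54

    def test_ideal_trot_df_above_half_has_no_aerial(self):
        p = params(0.5, 0.5, 0.0, df=0.55)
        report = detect_aerial(support_timeline(p), p)
        assert not report.has_aerial
        assert not report.predicted_simplified
        assert report.aerial_fraction == 0.0

    def test_ideal_trot_df_045_aerial_fraction(self):
        p = params(0.5, 0.5, 0.0, df=0.45)
        report = detect_aerial(support_timeline(p), p)
        assert report.has_aerial
        assert report.aerial_fraction == pytest.approx(0.10)

    def test_exact_detection_agrees_with_sampled_timeline(self):
        """Interval arithmetic vs 1e-4-resolution brute force on random
        phase/DF configurations."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = params(
                *rng.uniform(0, 1, 3),
                dfs={l: float(rng.uniform(0.05, 1.0)) for l in LimbId},
            )
            report = detect_aerial(support_timeline(p), p)
            grid, counts = sampled_supports(p)
            sampled_fraction = float(np.mean(counts == 0))
            assert report.aerial_fraction == pytest.approx(
                sampled_fraction, abs=5e-4
            )
            if report.aerial_fraction > 1e-3:
                assert (counts == 0).any()


class TestBipedalSupportProfile:
    def test_ideal_trot_is_fully_diagonal(self):
        profile = bipedal_support_profile(
            support_timeline(params(0.5, 0.5, 0.0, df=0.5))
        )
        assert profile["2-diagonal"] == pytest.approx(1.0)
        assert profile["2-lateral"] == 0.0

    def test_ideal_pace_is_fully_lateral(self):
        profile = bipedal_support_profile(
            support_timeline(params(0.0, 0.5, 0.5, df=0.5))
        )
        assert profile["2-lateral"] == pytest.approx(1.0)

    def test_ls_singlefoot_walk_alternates_triple_and_double_support(self):
        # DF 0.625: mean support 2.5 — equal time on 3 and 2 feet; the
        # two-foot episodes alternate between diagonal and ipsilateral
        # (lateral) pairs, so laterals do occur (unlike in a trot)
        profile = bipedal_support_profile(
            support_timeline(params(0.25, 0.5, 0.75, df=0.625))
        )
        assert profile["3"] == pytest.approx(0.5)
        assert profile["2-lateral"] == pytest.approx(0.25)
        assert profile["2-diagonal"] == pytest.approx(0.25)

    def test_ls_singlefoot_df_075_is_constant_triple_support(self):
        # 4 limbs x DF 0.75 evenly spaced = exactly three feet down always
        profile = bipedal_support_profile(
            support_timeline(params(0.25, 0.5, 0.75, df=0.75))
        )
        assert profile["3"] == pytest.approx(1.0)

    def test_fractions_sum_to_one_on_random_configurations(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = params(
                *rng.uniform(0, 1, 3),
                dfs={l: float(rng.uniform(0.05, 1.0)) for l in LimbId},
            )
            profile = bipedal_support_profile(support_timeline(p))
            assert sum(profile.values()) == pytest.approx(1.0, abs=1e-12)
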