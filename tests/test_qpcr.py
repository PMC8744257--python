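import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proximatome import qpcr
from proximatome.errors import AnchorError, MissingNormalizerError, ValidationError
from proximatome.synthetic import simulate_qpcr_plate


class TestDdct:
    def test_hand_computation(self):
        # test (20,15), calibrator (18,15): ddCT = 2 -> 2^-2
        assert qpcr.ddct(20, 15, 18, 15) == pytest.approx(0.25)

    def test_identity(self):
        assert qpcr.ddct(18, 15, 18, 15) == pytest.approx(1.0)

    @given(shift=st.floats(-10, 10))
    @settings(max_examples=30, deadline=None)
    def test_global_ct_shift_invariance(self, shift):
        base = qpcr.ddct(20, 15, 18, 15)
        shifted = qpcr.ddct(20 + shift, 15 + shift, 18 + shift, 15 + shift)
        assert shifted == pytest.approx(base)

    def test_replicates_averaged_on_ct_scale(self):
        table = pd.DataFrame(
            {
                "target": ["T", "T", "T", "G", "T", "G"],
                "sample": ["test", "test", "test", "test", "calib", "calib"],
                "replicate": [1, 2, 3, 1, 1, 1],
                "ct": [19.0, 20.0, 21.0, 15.0, 18.0, 15.0],
            }
        )
        assert qpcr.ddct_from_table(table, "T", "G", "test", "calib") == \
            pytest.approx(0.25)

    def test_missing_reference_errors(self):
        table = pd.DataFrame(
            {"target": ["T"], "sample": ["test"], "replicate": [1], "ct": [20.0]}
        )
        with pytest.raises(MissingNormalizerError):
            qpcr.ddct_from_table(table, "T", "GAPDH", "test", "calib")


class TestPercentInput:
    def test_hand_computation(self):
        frac = qpcr.percent_input(ct_ip=25, ct_input=20, input_fraction=0.01)
        assert frac.percent_input == pytest.approx(0.03125)

    def test_total_recovery(self):
        frac = qpcr.percent_input(ct_ip=20, ct_input=20, input_fraction=1.0)
        assert frac.percent_input == pytest.approx(100.0)

    def test_reference_normalization_symmetry(self):
        frac = qpcr.percent_input(25, 20, 0.01, reference=(25, 20))
        assert frac.normalized_percent_input == pytest.approx(1.0)

    @pytest.mark.parametrize("f", [0.0, -0.1, 1.5])
    def test_input_fraction_domain(self, f):
        with pytest.raises(ValidationError):
            qpcr.percent_input(25, 20, input_fraction=f)

    def test_monotone_decreasing_in_ct_ip(self):
        values = [qpcr.percent_input(ct, 20).percent_input for ct in (22, 24, 26)]
        assert values == sorted(values, reverse=True)


class TestDecay:
    def test_one_cycle_delta_is_half(self):
        curve = qpcr.decay_curve({0: 20.0, 4: 21.0}, {0: 15.0, 4: 15.0})
        assert curve.set_index("time").loc[4, "remaining"] == pytest.approx(0.5)
        assert curve.set_index("time").loc[0, "remaining"] == pytest.approx(1.0)

    def test_no_decay_flagged(self):
        curve = qpcr.decay_curve({0: 20.0, 4: 20.0, 8: 20.0},
                                 {0: 15.0, 4: 15.0, 8: 15.0})
        fit = qpcr.fit_half_life(curve)
        assert fit.no_decay and fit.half_life_hours == float("inf")

    def test_missing_t0_anchor_errors(self):
        with pytest.raises(AnchorError):
            qpcr.decay_curve({4: 21.0}, {4: 15.0})

    def test_exact_half_life_round_trip(self):
        """CTs back-computed from a 6 h half-life with zero noise refit to
        6 h within 1e-6."""
        rate = np.log(2) / 6.0
        times = [0.0, 2.0, 4.0, 8.0]
        ct_target = {t: 20.0 + rate * t / np.log(2) for t in times}
        ct_ref = {t: 15.0 for t in times}
        curve, = (qpcr.decay_curve(ct_target, ct_ref),)
        fit = qpcr.fit_half_life(curve)
        assert fit.half_life_hours == pytest.approx(6.0, abs=1e-6)

    def test_decay_from_table_parses_timepoints(self):
        rows = []
        for tp, ct in (("0h", 20.0), ("4h", 21.0)):
            rows.append(dict(target="T", sample=f"s{tp}", timepoint=tp,
                             replicate=1, ct=ct))
            rows.append(dict(target="G", sample=f"s{tp}", timepoint=tp,
                             replicate=1, ct=15.0))
        curve, fit = qpcr.decay_from_table(pd.DataFrame(rows), "T", "G", t0="0h")
        assert curve.set_index("time").loc[4.0, "remaining"] == pytest.approx(0.5)
        assert fit.half_life_hours == pytest.approx(4.0)

    @pytest.mark.parametrize(
        "label,hours", [("30min", 0.5), ("16h", 16.0), (4, 4.0), ("2 h", 2.0)]
    )
    def test_timepoint_parsing(self, label, hours):
        assert qpcr.parse_timepoint(label) == pytest.approx(hours)


class TestGeneratorRoundTrips:
    def test_ddct_recovers_planted_fold_change(self):
        table = simulate_qpcr_plate(
            {("T", "test"): 0.25, ("T", "calib"): 1.0,
             ("G", "test"): 1.0, ("G", "calib"): 1.0},
            ct_noise_sd=0.0,
        )
        assert qpcr.ddct_from_table(table, "T", "G", "test", "calib") == \
            pytest.approx(0.25)

    def test_percent_input_recovers_planted_recovery(self):
        # true recovery 1% of total; input is 1% of the lysate, so the
        # input aliquot holds 0.01 of total and the IP holds 0.01 of total
        table = simulate_qpcr_plate(
            {("T", "ip"): 0.01, ("T", "input"): 0.01}, ct_noise_sd=0.0
        )
        frac = qpcr.percent_input(
            qpcr.mean_ct(table, "T", "ip"),
            qpcr.mean_ct(table, "T", "input"),
            input_fraction=0.01,
        )
        assert frac.percent_input == pytest.approx(1.0)

    def test_noisy_ddct_coverage_matches_closed_form(self):
        """CT noise sd 0.2 on each of four wells, 3 replicates: the
        estimate/truth ratio is 2^-x with x ~ N(0, 0.2 * 2/sqrt(3)), so the
        Monte-Carlo fraction inside the +-30% band must match the normal-cdf
        prediction within binomial sampling error."""
        from scipy.stats import norm

        sd_ddct = 0.2 * 2 / np.sqrt(3)
        # 2^-x in [0.7, 1.3] <=> x in [-log2 1.3, -log2 0.7]
        predicted = float(
            norm.cdf(-np.log2(0.7) / sd_ddct) - norm.cdf(-np.log2(1.3) / sd_ddct)
        )
        rng = np.random.default_rng(19)
        ok = 0
        n_sim = 1000
        for _ in range(n_sim):
            table = simulate_qpcr_plate(
                {("T", "test"): 0.25, ("T", "calib"): 1.0,
                 ("G", "test"): 1.0, ("G", "calib"): 1.0},
                ct_noise_sd=0.2, n_replicates=3, seed=rng,
            )
            est = qpcr.ddct_from_table(table, "T", "G", "test", "calib")
            if 0.7 * 0.25 <= est <= 1.3 * 0.25:
                ok += 1
        se = np.sqrt(predicted * (1 - predicted) / n_sim)
        assert abs(ok / n_sim - predicted) < 4 * se
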