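"""Closed-form nucleus checks and the channel-selection oracle."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from schemabg.basal_ganglia import (
    BGWeights,
    ChannelLayerState,
    feature_match,
    reward_prediction_error,
    step_channel_layer,
    step_gpe,
    step_gpi,
    step_stn,
    step_striatum,
    step_thalamus,
    update_beta_str,
)

TOL = 1e-9
W = BGWeights()


def sigma(x, beta, alpha):
    return 1.0 / (1.0 + math.exp(-alpha * (x - beta)))


class TestStriatum:
    def test_hand_value(self):
        s = ChannelLayerState(1)
        step_striatum([0.5], s, delta=0.6, beta_d1=[0.5], beta_d2=[0.5], alpha_str=8.5)
        assert s.a_d1[0] == pytest.approx(0.2, abs=TOL)
        assert s.o_d1[0] == pytest.approx(sigma(0.2, 0.5, 8.5), abs=TOL)

    def test_threshold_at_activation_gives_half(self):
        s = ChannelLayerState(1)
        step_striatum([0.5], s, 0.6, [0.2], [0.2], 8.5)
        assert s.o_d1[0] == pytest.approx(0.5, abs=TOL)

    def test_output_decreasing_in_threshold(self):
        outs = []
        for beta in (0.1, 0.3, 0.5, 0.7):
            s = ChannelLayerState(1)
            step_striatum([0.5], s, 0.6, [beta], [beta], 8.5)
            outs.append(s.o_d1[0])
        assert outs == sorted(outs, reverse=True)


class TestSTN:
    def test_hand_value(self):
        s = ChannelLayerState(1)
        s.o_gpe_prev = [0.3]
        step_stn([0.5], s, W, delta=0.6, beta=0.3, alpha=8.0)
        assert s.a_stn[0] == pytest.approx(0.6 * 0.0 + 0.4 * 0.3, abs=TOL)
        assert s.o_stn[0] == pytest.approx(sigma(0.12, 0.3, 8.0), abs=TOL)

    def test_pure_feedforward_without_gpe(self):
        s = ChannelLayerState(1)
        step_stn([0.5], s, W, 0.6, 0.3, 8.0)
        assert s.a_stn[0] == pytest.approx(0.4 * 0.6, abs=TOL)

    def test_gpe_inhibits(self):
        lo, hi = ChannelLayerState(1), ChannelLayerState(1)
        hi.o_gpe_prev = [0.8]
        step_stn([0.5], lo, W, 0.6, 0.3, 8.0)
        step_stn([0.5], hi, W, 0.6, 0.3, 8.0)
        assert hi.o_stn[0] < lo.o_stn[0]


class TestGPe:
    def test_diffuse_stn_drive(self):
        s = ChannelLayerState(3)
        s.o_stn = [0.2, 0.2, 0.2]
        step_gpe(s, W, 0.6, 0.25, 8.0)
        assert s.a_gpe[0] == pytest.approx(0.4 * 0.54, abs=TOL)

    def test_d2_inhibition(self):
        s = ChannelLayerState(2)
        s.o_d2_prev = [1.0, 0.0]
        step_gpe(s, W, 0.6, 0.25, 8.0)
        assert s.a_gpe[0] == pytest.approx(0.4 * -1.0, abs=TOL)
        assert s.a_gpe[1] == pytest.approx(0.0, abs=TOL)

    def test_identical_across_channels_when_d2_equal(self):
        s = ChannelLayerState(3)
        s.o_stn = [0.1, 0.5, 0.3]
        s.o_d2_prev = [0.4, 0.4, 0.4]
        step_gpe(s, W, 0.6, 0.25, 8.0)
        assert s.o_gpe[0] == s.o_gpe[1] == s.o_gpe[2]


class TestGPi:
    def test_tonic_activity_from_rest(self):
        s = ChannelLayerState(1)
        for _ in range(200):
            step_gpi(s, W, 0.6, 0.25, 8.0)
        assert s.o_gpi[0] == pytest.approx(sigma(0.0, 0.25, 8.0), abs=TOL)

    def test_direct_pathway_silences_gpi(self):
        s = ChannelLayerState(1)
        s.o_d1 = [0.8]
        for _ in range(400):
            s.o_d1 = [0.8]
            step_gpi(s, W, 0.6, 0.25, 8.0)
        assert s.o_gpi[0] == pytest.approx(sigma(-0.8, 0.25, 8.0), abs=1e-8)

    def test_d1_is_channel_specific(self):
        s = ChannelLayerState(2)
        s.o_d1 = [0.8, 0.0]
        step_gpi(s, W, 0.6, 0.25, 8.0)
        assert s.o_gpi[0] < s.o_gpi[1]


class TestThalamus:
    def test_midpoint_gives_minus_half(self):
        s = ChannelLayerState(1)
        for _ in range(200):
            s.o_gpi = [0.45]
            step_thalamus(s, 0.6, 0.45, 8.0)
        assert s.o_thal[0] == pytest.approx(-0.5, abs=TOL)

    def test_quiet_gpi_releases_cortex(self):
        s = ChannelLayerState(1)
        for _ in range(200):
            step_thalamus(s, 0.6, 0.45, 8.0)
        assert s.o_thal[0] == pytest.approx(-sigma(0.0, 0.45, 8.0), abs=TOL)

    def test_strictly_decreasing_in_gpi(self):
        outs = []
        for g in (0.0, 0.3, 0.6, 0.9):
            s = ChannelLayerState(1)
            for _ in range(100):
                s.o_gpi = [g]
                step_thalamus(s, 0.6, 0.45, 8.0)
            outs.append(s.o_thal[0])
        assert outs == sorted(outs, reverse=True)


class TestStriatalLearning:
    @pytest.mark.parametrize(
        "matched,w_neg,m_r,f_prev,r_prev,expected",
        [
            (False, 0.0, 0.0, 0.0, 0.0, -1.0),
            (True, 0.0, 0.0, 0.0, 0.0, 1.0),
            (False, 0.65, 0.0, 0.0, 0.0, 0.30),
            (False, 0.0, 0.6, 1.0, -1.0, -1.0 + 0.6),
        ],
    )
    def test_feature_match(self, matched, w_neg, m_r, f_prev, r_prev, expected):
        assert feature_match(matched, w_neg, m_r, f_prev, r_prev) == pytest.approx(
            expected, abs=TOL
        )

    @pytest.mark.parametrize(
        "r,f,a,expected",
        [(1, 1, 0.9, 0.1), (1, 0.9, 0.9, 0.0), (-1, -1, 0.9, 1.9)],
    )
    def test_reward_prediction_error(self, r, f, a, expected):
        assert reward_prediction_error(r, f, a) == pytest.approx(expected, abs=TOL)

    @pytest.mark.parametrize(
        "beta,eps,rpe,zeta,expected",
        [
            (0.5, 0.4, 0.1, 0.0, 0.46),
            (0.5, 0.4, 0.0, 0.0, 0.5),
            (0.05, 0.4, 1.9, 0.0, 0.0),
            (0.9, 0.4, -1.5, 0.0, 1.0),
        ],
    )
    def test_update_beta_str(self, beta, eps, rpe, zeta, expected):
        assert update_beta_str(beta, eps, rpe, zeta) == pytest.approx(expected, abs=TOL)

    @given(
        beta=st.floats(0, 1),
        rpe=st.floats(-2, 2),
        zeta=st.floats(-0.1, 0.1),
    )
    @settings(max_examples=100, derandomize=True)
    def test_threshold_stays_in_unit_interval(self, beta, rpe, zeta):
        assert 0.0 <= update_beta_str(beta, 0.4, rpe, zeta) <= 1.0


def run_static_loop(o_ctx, beta=0.5, n_cycles=400):
    """Drive one channel complex with fixed cortical input; return GPi outputs."""
    n = len(o_ctx)
    s = ChannelLayerState(n)
    for _ in range(n_cycles):
        step_channel_layer(
            o_ctx, s, W, 0.6,
            [beta] * n, [beta] * n, 8.5,
            0.3, 8.0, 0.25, 8.0, 0.25, 8.0, 0.45, 8.0,
        )
    return list(s.o_gpi)


class TestSelectionOracle:
    def test_max_input_channel_has_lowest_gpi(self):
        gpi = run_static_loop([0.7, 0.4, 0.4])
        assert gpi[0] < gpi[1]
        assert gpi[0] < gpi[2]

    def test_symmetric_inputs_give_symmetric_outputs(self):
        gpi = run_static_loop([0.5, 0.5, 0.5])
        assert gpi[0] == pytest.approx(gpi[1], abs=1e-9)
        assert gpi[1] == pytest.approx(gpi[2], abs=1e-9)

    def test_margin_grows_with_input_difference(self):
        margins = []
        for hi in (0.55, 0.65, 0.75):
            gpi = run_static_loop([hi, 0.5, 0.5])
            margins.append(gpi[1] - gpi[0])
        assert margins[0] < margins[1] < margins[2]

    def test_lower_striatal_threshold_disinhibits_channel(self):
        n = 3
        base, low = ChannelLayerState(n), ChannelLayerState(n)
        for s, b0 in ((base, [0.5] * 3), (low, [0.2, 0.5, 0.5])):
            for _ in range(400):
                step_channel_layer(
                    [0.5] * 3, s, W, 0.6, b0, [0.5] * 3, 8.5,
                    0.3, 8.0, 0.25, 8.0, 0.25, 8.0, 0.45, 8.0,
                )
        assert low.o_d1[0] > base.o_d1[0]
        assert low.o_gpi[0] < base.o_gpi[0]
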