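"""Per-lesion indices: FFR, hAPV, cHSR, TAWSS, OSI, WSS, ROI averaging."""

import math

import numpy as np
import pytest

from coro0d.indices import (
    compute_chsr,
    compute_delta_p,
    compute_ffr,
    compute_hapv,
    compute_lesion_indices,
    compute_osi,
    compute_tawss,
    roi_metrics,
    segment_wss_series,
)
from coro0d.network import Stenosis, VascularNetwork, VesselSegment, WindkesselOutlet
from coro0d.solver import SimulationResult


def fake_result(times, node_pressures, segment_flows, label="hyperemia"):
    return SimulationResult(
        times=np.asarray(times, float),
        node_pressures={k: np.asarray(v, float) for k, v in node_pressures.items()},
        segment_flows={k: np.asarray(v, float) for k, v in segment_flows.items()},
        converged=True,
        cycles_run=1,
        periodicity_error=0.0,
        state_label=label,
    )


def line_network(radius=0.1, n_extra=0, extra_length=1.0, extra_radius=0.1):
    segs = [VesselSegment("prox", "inlet", "n1", 1.0, radius),
            VesselSegment("lesion", "n1", "n2", 1.0, radius)]
    prev = "n2"
    for k in range(n_extra):
        nxt = f"n{3 + k}"
        segs.append(VesselSegment(f"d{k}", prev, nxt, extra_length, extra_radius))
        prev = nxt
    net = VascularNetwork(
        segments=segs,
        stenoses=[Stenosis("lesion", radius, 0.5 * radius, 1.0)],
        outlets={prev: WindkesselOutlet(1, 1, 1)},
        inflow_node="inlet",
    )
    return net


class TestFFR:
    def test_identical_series_give_unity(self):
        t = np.linspace(0, 1, 11)
        p = 80 + 10 * np.sin(2 * np.pi * t)
        net = line_network()
        res = fake_result(t, {"inlet": p, "n1": p, "n2": p}, {"lesion": 0 * t,
                                                              "prox": 0 * t})
        assert compute_ffr(res, net, net.stenoses[0]) == pytest.approx(1.0)

    def test_constant_ratio(self):
        t = np.linspace(0, 1, 11)
        net = line_network()
        res = fake_result(
            t, {"inlet": np.full(11, 80.0), "n1": np.full(11, 80.0),
                "n2": np.full(11, 60.0)}, {"lesion": 0 * t, "prox": 0 * t},
        )
        assert compute_ffr(res, net, net.stenoses[0]) == pytest.approx(0.75)

    def test_pulsatile_equals_quotient_of_trapezoid_means(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 0.8, 101)
        pa = 90 + 15 * np.sin(2 * np.pi * t / 0.8) + rng.normal(0, 1, 101)
        pd_ = pa - 12 - 3 * np.cos(2 * np.pi * t / 0.8)
        net = line_network()
        res = fake_result(t, {"inlet": pa, "n1": pa, "n2": pd_},
                          {"lesion": 0 * t, "prox": 0 * t})
        expected = np.trapezoid(pd_, t) / np.trapezoid(pa, t)
        assert compute_ffr(res, net, net.stenoses[0]) == pytest.approx(
            expected, rel=1e-12
        )

    def test_rest_result_refused_unless_overridden(self):
        t = np.linspace(0, 1, 11)
        net = line_network()
        res = fake_result(t, {"inlet": np.full(11, 80.0), "n1": np.full(11, 80.0),
                              "n2": np.full(11, 60.0)},
                          {"lesion": 0 * t, "prox": 0 * t}, label="rest")
        with pytest.raises(ValueError):
            compute_ffr(res, net, net.stenoses[0])
        with pytest.warns(UserWarning):
            assert compute_ffr(res, net, net.stenoses[0],
                               allow_rest=True) == pytest.approx(0.75)


class TestHAPV:
    def test_steady_flow_arithmetic(self):
        # Q = 3 mL/s through r_min = 0.1 cm: mean 95.49, peak 190.99 cm/s
        t = np.linspace(0, 1, 11)
        net = line_network(radius=0.2)
        net.stenoses = [Stenosis("lesion", 0.2, 0.1, 1.0)]
        res = fake_result(t, {}, {"lesion": np.full(11, 3.0)})
        hapv = compute_hapv(res, net.stenoses[0])
        assert hapv == pytest.approx(190.99, rel=1e-4)

    def test_linearity_and_quadrature(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 0.9, 77)
        q = 2 + np.abs(rng.normal(0, 1, 77))
        sten = Stenosis("lesion", 0.2, 0.1, 1.0)
        res1 = fake_result(t, {}, {"lesion": q})
        res2 = fake_result(t, {}, {"lesion": q / 2})
        a_s = math.pi * 0.1**2
        expected = 2 / a_s * np.trapezoid(q, t) / 0.9
        assert compute_hapv(res1, sten) == pytest.approx(expected, rel=1e-12)
        assert compute_hapv(res2, sten) == pytest.approx(expected / 2, rel=1e-12)


class TestCHSR:
    @pytest.mark.parametrize("dp,hapv,expected",
                             [(20.0, 40.0, 0.5), (0.0, 40.0, 0.0),
                              (30.0, 40.0, 0.75)])
    def test_quotient(self, dp, hapv, expected):
        assert compute_chsr(dp, hapv) == expected

    def test_nonpositive_velocity_rejected(self):
        with pytest.raises(ValueError):
            compute_chsr(10.0, 0.0)


class TestShearMetrics:
    def test_tawss_constant(self):
        assert compute_tawss(np.full(100, 2.0), 1.0) == pytest.approx(2.0)

    def test_tawss_of_sine_is_two_over_pi(self):
        t = np.linspace(0, 1, 2001)
        tau = np.sin(2 * np.pi * t)
        assert compute_tawss(tau, 1.0, t) == pytest.approx(2 / np.pi, rel=1e-5)

    def test_tawss_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_tawss(np.array([]), 1.0)

    def test_osi_nonnegative_signal_is_zero(self):
        t = np.linspace(0, 1, 1000)
        tau = 2 + np.sin(2 * np.pi * t)
        assert compute_osi(tau, 1.0, t) == 0.0

    def test_osi_zero_mean_signal_is_half(self):
        t = np.linspace(0, 1, 1000)
        tau = np.sin(2 * np.pi * t)
        assert compute_osi(tau, 1.0, t) == pytest.approx(0.5, abs=1e-6)

    def test_osi_matches_brute_force_quadrature(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 0.8, 333)
        tau = rng.normal(0.3, 1.0, 333)
        expected = 0.5 * (1 - abs(np.trapezoid(tau, t)) / np.trapezoid(np.abs(tau), t))
        assert compute_osi(tau, 0.8, t) == pytest.approx(expected, rel=1e-12)
        assert 0.0 <= compute_osi(tau, 0.8, t) <= 0.5

    def test_osi_zero_series_warns(self):
        with pytest.warns(UserWarning):
            assert compute_osi(np.zeros(50), 1.0) == 0.0


class TestWallShear:
    def test_unit_conversion_oracle(self):
        # mu=0.04 P, Q=1 mL/s, r=0.15 cm -> 15.09 dyn/cm^2 = 1.509 Pa
        seg = VesselSegment("s", "a", "b", 1.0, 0.15)
        net = VascularNetwork(segments=[seg],
                              outlets={"b": WindkesselOutlet(1, 1, 1)},
                              inflow_node="a")
        t = np.linspace(0, 1, 11)
        res = fake_result(t, {}, {"s": np.full(11, 1.0)})
        tau = segment_wss_series(res, net, seg)
        assert tau[0] == pytest.approx(1.509, rel=1e-3)

    def test_sign_and_radius_laws(self):
        seg1 = VesselSegment("s", "a", "b", 1.0, 0.15)
        seg2 = VesselSegment("s", "a", "b", 1.0, 0.30)
        t = np.linspace(0, 1, 11)
        net = VascularNetwork(segments=[seg1],
                              outlets={"b": WindkesselOutlet(1, 1, 1)},
                              inflow_node="a")
        res_fwd = fake_result(t, {}, {"s": np.full(11, 2.0)})
        res_rev = fake_result(t, {}, {"s": np.full(11, -2.0)})
        tau_f = segment_wss_series(res_fwd, net, seg1)
        tau_r = segment_wss_series(res_rev, net, seg1)
        np.testing.assert_allclose(tau_r, -tau_f)
        tau_wide = segment_wss_series(res_fwd, net, seg2)
        np.testing.assert_allclose(tau_f / tau_wide, 8.0)


class TestROI:
    def test_single_downstream_segment_equals_its_metrics(self):
        net = line_network(n_extra=1, extra_length=2.0)
        t = np.linspace(0, 1, 51)
        q = 1.5 + 0.5 * np.sin(2 * np.pi * t)
        res = fake_result(t, {}, {"prox": q, "lesion": q, "d0": q})
        tawss, osi = roi_metrics(res, net, net.stenoses[0], roi_length=1.5)
        seg = net.segment_by_id("d0")
        tau = segment_wss_series(res, net, seg)
        assert tawss == pytest.approx(compute_tawss(tau, 1.0, t), rel=1e-12)
        assert osi == pytest.approx(compute_osi(tau, 1.0, t), abs=1e-12)

    def test_two_equal_segments_average_by_length(self):
        net = line_network(n_extra=2, extra_length=0.75)
        t = np.linspace(0, 1, 51)
        # flows chosen so the two downstream segments carry TAWSS of 1 and 3 Pa
        q_for = lambda tau_pa, r: tau_pa / 0.1 * math.pi * r**3 / (4 * 0.04)
        res = fake_result(
            t, {},
            {"prox": 0 * t, "lesion": 0 * t,
             "d0": np.full(51, q_for(1.0, 0.1)),
             "d1": np.full(51, q_for(3.0, 0.1))},
        )
        tawss, osi = roi_metrics(res, net, net.stenoses[0], roi_length=1.5)
        assert tawss == pytest.approx(2.0, rel=1e-12)
        assert osi == 0.0

    def test_zero_roi_rejected_and_leaf_lesion_warns(self):
        net = line_network()
        t = np.linspace(0, 1, 51)
        res = fake_result(t, {}, {"prox": np.full(51, 1.0),
                                  "lesion": np.full(51, 1.0)})
        with pytest.raises(ValueError):
            roi_metrics(res, net, net.stenoses[0], roi_length=0.0)
        with pytest.warns(UserWarning):
            roi_metrics(res, net, net.stenoses[0], roi_length=1.5)


class TestEndToEndPanel:
    def test_panel_invariants_on_demo(self, demo_states):
        net_h = demo_states["hyper_network"]
        res_h = demo_states["hyper"]
        idx = compute_lesion_indices(res_h, net_h, net_h.stenoses[0])
        assert 0.0 < idx.ffr_cfd <= 1.0
        assert idx.delta_p > 0
        assert idx.hapv > 0
        assert idx.chsr == pytest.approx(idx.delta_p / idx.hapv, rel=1e-12)
        assert 0.0 <= idx.osi <= 0.5
        assert idx.tawss >= 0
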