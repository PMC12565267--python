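"""Network representation, validation, and lumped-parameter initialization."""

import math

import numpy as np
import pytest

from coro0d.network import (
    CoronaryOutlet,
    NetworkError,
    Stenosis,
    VascularNetwork,
    VesselSegment,
    WindkesselOutlet,
    artery_rest_flow,
    initialize_coronary_outlets,
    initialize_systemic_outlet,
    poiseuille_resistance,
    segment_resistance,
)
from coro0d.waveforms import PatientRecord, Waveform


def flat_pim():
    return Waveform(np.linspace(0, 1, 17), np.zeros(17), 1.0)


def coronary_leaf(artery="LAD"):
    return CoronaryOutlet(Ra=1.0, Ca=5e-4, Ra_micro=1.0, Cim=5e-3, Rv_micro=1.0,
                          Pim=flat_pim(), artery=artery)


class TestSegmentResistance:
    def test_unit_conversion_oracle(self):
        # 8*0.04*1/(pi*0.15^4) = 201.2 dyn*s/cm^5 = 0.1509 mmHg*s/mL
        seg = VesselSegment("s", "a", "b", length=1.0, radius=0.15)
        expected_dyn = 8 * 0.04 * 1.0 / (math.pi * 0.15**4)
        assert expected_dyn == pytest.approx(201.2, rel=1e-3)
        assert segment_resistance(seg, 0.04) == pytest.approx(0.1509, rel=1e-3)
        assert seg.viscous_resistance == pytest.approx(expected_dyn / 1333.22)

    def test_scaling_laws(self):
        r1 = poiseuille_resistance(1.0, 0.15)
        assert poiseuille_resistance(2.0, 0.15) == pytest.approx(2 * r1)
        assert poiseuille_resistance(1.0, 0.30) == pytest.approx(r1 / 16)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            poiseuille_resistance(1.0, 0.0)


class TestTypesInvariants:
    def test_stenosis_geometry(self):
        st = Stenosis("s", reference_radius=0.2, minimal_lumen_radius=0.1,
                      lesion_length=1.0)
        assert st.percent_stenosis == pytest.approx(50.0)
        with pytest.raises(NetworkError):
            Stenosis("s", 0.2, 0.25, 1.0)  # lumen wider than reference
        with pytest.raises(NetworkError):
            Stenosis("s", 0.2, 0.1, -1.0)

    def test_outlet_positivity(self):
        with pytest.raises(NetworkError):
            WindkesselOutlet(Rp=0.0, C=1.0, Rd=1.0)
        with pytest.raises(NetworkError):
            CoronaryOutlet(Ra=1, Ca=-1, Ra_micro=1, Cim=1, Rv_micro=1,
                           Pim=flat_pim())


class TestValidation:
    def test_cycle_rejected(self):
        net = VascularNetwork(
            segments=[
                VesselSegment("a", "inlet", "n1", 1, 0.5),
                VesselSegment("b", "n1", "n2", 1, 0.5),
                VesselSegment("c", "n2", "n1", 1, 0.5),
            ],
            outlets={},
            inflow_node="inlet",
        )
        with pytest.raises(NetworkError):
            net.validate()

    def test_orphan_stenosis_rejected(self):
        net = VascularNetwork(
            segments=[VesselSegment("a", "inlet", "n1", 1, 0.5)],
            stenoses=[Stenosis("ghost", 0.2, 0.1, 1.0)],
            outlets={"n1": WindkesselOutlet(1, 1, 1)},
            inflow_node="inlet",
        )
        with pytest.raises(NetworkError):
            net.validate()

    def test_bare_leaf_rejected(self):
        net = VascularNetwork(
            segments=[VesselSegment("a", "inlet", "n1", 1, 0.5)],
            outlets={},
            inflow_node="inlet",
        )
        with pytest.raises(NetworkError):
            net.validate()


def two_leaf_artery_network(r1=0.2, r2=0.2):
    segs = [
        VesselSegment("ao", "inlet", "sys", 5.0, 1.0),
        VesselSegment("lad", "inlet", "j", 2.0, 0.25),
        VesselSegment("d1", "j", "leaf1", 2.0, r1),
        VesselSegment("d2", "j", "leaf2", 2.0, r2),
    ]
    outlets = {
        "sys": WindkesselOutlet(0.1, 1.0, 1.0),
        "leaf1": coronary_leaf(),
        "leaf2": coronary_leaf(),
    }
    return VascularNetwork(segments=segs, outlets=outlets, inflow_node="inlet")


class TestCoronaryInitialization:
    patient = PatientRecord(
        heart_rate=60.0, systolic_pressure=120.0, diastolic_pressure=80.0,
        stroke_volume=80.0, systolic_ejection_time=0.3, body_surface_area=1.8,
        myocardial_mass=150.0,
        artery_mass_fractions={"LAD": 0.5, "LCx": 0.25, "RCA": 0.25},
    )

    def test_single_outlet_total_resistance(self):
        # MAP = 93.33 mmHg, Pv = 5, q = 0.8*150*0.5/60 = 1 mL/s -> R = 88.33
        net = two_leaf_artery_network()
        net.segments = [s for s in net.segments if s.id != "d2"]
        del net.outlets["leaf2"]
        net.segments[-1] = VesselSegment("d1", "j", "leaf1", 2.0, 0.2)
        out = initialize_coronary_outlets(net, self.patient)
        o = out.outlets["leaf1"]
        assert o.total_resistance == pytest.approx(88.3333, rel=1e-4)

    def test_equal_radii_split_half(self):
        out = initialize_coronary_outlets(two_leaf_artery_network(), self.patient)
        o1, o2 = out.outlets["leaf1"], out.outlets["leaf2"]
        assert o1.total_resistance == pytest.approx(o2.total_resistance)

    def test_murray_cube_law_split(self):
        out = initialize_coronary_outlets(
            two_leaf_artery_network(r1=0.2, r2=0.1), self.patient
        )
        q_total = 0.8 * 150.0 * 0.5 / 60.0
        map_ = self.patient.mean_arterial_pressure
        q1 = (map_ - 5.0) / out.outlets["leaf1"].total_resistance
        q2 = (map_ - 5.0) / out.outlets["leaf2"].total_resistance
        assert q1 / q2 == pytest.approx(8.0, rel=1e-9)
        assert q1 + q2 == pytest.approx(q_total, rel=1e-9)

    def test_splits_sum_exactly(self):
        out = initialize_coronary_outlets(two_leaf_artery_network(), self.patient,
                                          splits=(0.32, 0.52, 0.16))
        o = out.outlets["leaf1"]
        assert o.Ra + o.Ra_micro + o.Rv_micro == pytest.approx(
            o.total_resistance, rel=1e-12
        )

    def test_missing_mass_fraction_rejected(self):
        net = two_leaf_artery_network()
        net.outlets["leaf1"] = coronary_leaf(artery="OM1")
        with pytest.raises(NetworkError):
            initialize_coronary_outlets(net, self.patient)

    def test_rest_flow_conservation_across_arteries(self):
        q_lad = artery_rest_flow(self.patient, "LAD")
        q_lcx = artery_rest_flow(self.patient, "LCx")
        q_rca = artery_rest_flow(self.patient, "RCA")
        total = 0.8 * self.patient.myocardial_mass / 60.0
        assert q_lad + q_lcx + q_rca == pytest.approx(total, rel=1e-12)


class TestSystemicInitialization:
    patient = PatientRecord(
        heart_rate=60.0, systolic_pressure=130.0, diastolic_pressure=85.0,
        stroke_volume=5000.0 / 60.0, systolic_ejection_time=0.3,
        body_surface_area=1.8, myocardial_mass=120.0,
        artery_mass_fractions={"LAD": 1.0},
    )  # CO = 5 L/min = 83.33 mL/s, MAP = 100 mmHg

    def net(self):
        return VascularNetwork(
            segments=[VesselSegment("ao", "inlet", "sys", 5.0, 1.0)],
            outlets={"sys": WindkesselOutlet(1.0, 1.0, 1.0)},
            inflow_node="inlet",
        )

    def test_total_resistance_quotient(self):
        out = initialize_systemic_outlet(self.net(), self.patient,
                                         coronary_flow_fraction=0.04,
                                         rp_fraction=0.06)
        o = out.outlets["sys"]
        assert o.Rp + o.Rd == pytest.approx(1.25, rel=1e-4)
        assert o.Rp == pytest.approx(0.075, rel=1e-4)

    @pytest.mark.parametrize("cf,rp", [(0.03, 0.1), (0.05, 0.06), (0.1, 0.5)])
    def test_resistance_always_pressure_over_flow(self, cf, rp):
        out = initialize_systemic_outlet(self.net(), self.patient,
                                         coronary_flow_fraction=cf,
                                         rp_fraction=rp)
        o = out.outlets["sys"]
        q = self.patient.cardiac_output * (1 - cf)
        assert o.Rp + o.Rd == pytest.approx(
            self.patient.mean_arterial_pressure / q, rel=1e-12
        )

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            initialize_systemic_outlet(self.net(), self.patient,
                                       coronary_flow_fraction=0.5)
        with pytest.raises(ValueError):
            initialize_systemic_outlet(self.net(), self.patient, rp_fraction=1.5)


def test_json_round_trip(tmp_path):
    net = two_leaf_artery_network()
    path = tmp_path / "net.json"
    net.to_json(path)
    net2 = VascularNetwork.from_json(path)
    assert [s.id for s in net2.segments] == [s.id for s in net.segments]
    assert set(net2.outlets) == set(net.outlets)
    assert isinstance(net2.outlets["leaf1"], CoronaryOutlet)
    assert net2.outlets["sys"].Rd == net.outlets["sys"].Rd
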