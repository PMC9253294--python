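"""Exact algebra of the two-state ligand-gating model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gatecycle import (
    DomainError,
    GatingParams,
    ec50_from_kd,
    hill,
    kd_from_ec50,
    l_from_pomax,
    model_response_curve,
    open_probability,
    pomax_from_l,
)
from gatecycle.gating import gating_table, read_gating_table, write_gating_table


def po_boltzmann(c, kd, L):
    """Independent oracle: Boltzmann-weight enumeration over the three
    states {C0: 1, C1: c/Kd, O: (c/Kd) L}."""
    weights = np.array([1.0, c / kd, (c / kd) * L])
    return weights[2] / weights.sum()


log_kd = st.floats(np.log(1e-2), np.log(1e4))
log_l = st.floats(np.log(1e-3), np.log(1e3))


class TestOpenProbability:
    def test_zero_concentration(self):
        assert open_probability(0.0, kd=100.0, L=1.0) == 0.0

    def test_half_maximum_at_ec50(self):
        # c = Kd/(1+L) gives exactly half of Po_max by construction
        assert open_probability(37.5, kd=150.0, L=3.0) == pytest.approx(0.375, abs=1e-12)
        assert open_probability(62.64, kd=125.28, L=1.0) == pytest.approx(0.25, rel=1e-12)

    @pytest.mark.parametrize(
        "c,kd,L",
        [(62.64, 125.28, 1.0), (75.0, 100.0, 1.0), (500.0, 313.2, 4.0), (1.0, 1e3, 1e-2)],
    )
    def test_matches_boltzmann_enumeration(self, c, kd, L):
        assert open_probability(c, kd, L) == pytest.approx(po_boltzmann(c, kd, L), rel=1e-12)

    def test_boltzmann_oracle_over_random_triples(self, rng):
        for _ in range(100):
            kd = float(np.exp(rng.uniform(np.log(1e-2), np.log(1e4))))
            L = float(np.exp(rng.uniform(np.log(1e-3), np.log(1e3))))
            c = float(np.exp(rng.uniform(np.log(1e-2), np.log(1e4))))
            assert open_probability(c, kd, L) == pytest.approx(
                po_boltzmann(c, kd, L), rel=1e-9
            )

    def test_strictly_increasing_in_concentration_and_L(self):
        c = np.logspace(-2, 4, 50)
        po = open_probability(c, kd=150.0, L=3.0)
        assert np.all(np.diff(po) > 0)
        assert open_probability(50.0, 150.0, 4.0) > open_probability(50.0, 150.0, 3.0)

    def test_saturates_at_pomax(self):
        assert open_probability(1e12, kd=150.0, L=3.0) == pytest.approx(0.75, rel=1e-9)

    @pytest.mark.parametrize("kd,L", [(0.0, 1.0), (-5.0, 1.0), (100.0, 0.0), (100.0, -1.0)])
    def test_domain_errors_name_parameter(self, kd, L):
        with pytest.raises(DomainError, match="Kd|L"):
            open_probability(10.0, kd, L)


class TestIdentities:
    @pytest.mark.parametrize("po,expected", [(0.5, 1.0), (0.75, 3.0), (0.9, 9.0)])
    def test_l_from_pomax(self, po, expected):
        assert l_from_pomax(po) == pytest.approx(expected, rel=1e-12)

    def test_l_pomax_round_trip(self):
        assert l_from_pomax(pomax_from_l(9.0)) == pytest.approx(9.0, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_l_from_pomax_domain(self, bad):
        with pytest.raises(DomainError, match="Po_max"):
            l_from_pomax(bad)

    @pytest.mark.parametrize(
        "ec50,L,expected", [(50.0, 1.0, 100.0), (62.64, 3.0, 250.56), (50.0, 1e-12, 50.0)]
    )
    def test_kd_from_ec50(self, ec50, L, expected):
        assert kd_from_ec50(ec50, L) == pytest.approx(expected, rel=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(log_kd, log_l)
    def test_round_trip_identities(self, lkd, ll):
        kd, L = np.exp(lkd), np.exp(ll)
        ec50 = ec50_from_kd(kd, L)
        assert kd_from_ec50(ec50, L) == pytest.approx(kd, rel=1e-9)
        assert l_from_pomax(pomax_from_l(L)) == pytest.approx(L, rel=1e-9)
        assert ec50 <= kd  # gating always sharpens the apparent affinity

    def test_ec50_decreasing_in_L(self):
        ls = np.array([0.5, 1.0, 2.0, 4.0])
        ec = [ec50_from_kd(300.0, l) for l in ls]
        assert np.all(np.diff(ec) < 0)


class TestModelResponseCurve:
    def test_zero_concentration_gives_zero_current(self):
        assert model_response_curve([0.0], kd=100.0, L=1.0, imax_unit=100.0)[0] == 0.0

    def test_hill_equivalence(self):
        # model curve == Hill(h=1, EC50=Kd/(1+L), Imax=imax_unit*L/(1+L))
        c = np.array([10.0, 30.0, 100.0, 300.0, 1000.0])
        curve = model_response_curve(c, kd=125.28, L=1.0, imax_unit=100.0)
        expected = hill(c, imax=50.0, ec50=62.64, h=1.0)
        np.testing.assert_allclose(curve, expected, rtol=1e-9)

    def test_monotone_for_ascending_concentrations(self):
        c = np.logspace(0, 4, 30)
        curve = model_response_curve(c, kd=300.0, L=2.0, imax_unit=200.0)
        assert np.all(np.diff(curve) >= 0)


class TestGatingParams:
    def make(self, **kw):
        base = dict(
            construct="WT", ligand="ligA", voltage_mV=80.0,
            kd=313.2, L=4.0, po_max=0.8, ec50=62.64,
        )
        base.update(kw)
        return GatingParams(**base)

    def test_consistent_set_accepted(self):
        p = self.make()
        assert p.ec50 == pytest.approx(p.kd / (1 + p.L), rel=1e-9)

    @pytest.mark.parametrize("field,value", [("ec50", 70.0), ("po_max", 0.7), ("kd", 100.0)])
    def test_inconsistent_set_rejected(self, field, value):
        with pytest.raises(DomainError, match="inconsistent"):
            self.make(**{field: value})

    def test_from_ec50_pomax_propagates_sems(self):
        p = GatingParams.from_ec50_pomax("WT", "ligA", 80.0, ec50=62.64, po_max=0.8,
                                         sem_ec50=1.2, sem_po_max=0.02)
        # delta method: dL/dp = 1/(1-p)^2; dKd = hypot((1+L) dE, E/(1-p)^2 dp)
        assert p.sem_L == pytest.approx(0.02 / 0.04, rel=1e-9)
        assert p.sem_kd == pytest.approx(np.hypot(5 * 1.2, 62.64 / 0.04 * 0.02), rel=1e-9)

    def test_table_round_trip(self, tmp_path):
        params = [self.make(), GatingParams.from_ec50_pomax("MUT", "ligB", -80.0, 150.0, 0.6)]
        path = tmp_path / "gating.csv"
        write_gating_table(params, path)
        back = read_gating_table(path)
        assert back == params
        assert list(gating_table(params).columns)[:3] == ["construct", "ligand", "voltage_mV"]
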