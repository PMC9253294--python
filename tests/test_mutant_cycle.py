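"""Mutant-cycle algebra: LnOmega, coupling energy, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gatecycle import (
    DomainError,
    GatingParams,
    InputError,
    build_cycle,
    classify,
    coupling_energy,
    cycle_report_table,
    ln_omega,
)
from gatecycle.mutant_cycle import IncompleteCycleError

log_kd = st.floats(np.log(1e-2), np.log(1e4))


class TestLnOmega:
    def test_additive_perturbations_give_zero(self):
        assert ln_omega(50.0, 500.0, 60.0, 600.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_oracle(self):
        assert ln_omega(50.0, 500.0, 60.0, 60.0) == pytest.approx(np.log(0.1), abs=1e-9)
        assert abs(ln_omega(50.0, 500.0, 60.0, 60.0)) == pytest.approx(2.3026, abs=1e-4)

    @settings(derandomize=True, max_examples=150)
    @given(log_kd, log_kd, log_kd, log_kd)
    def test_axis_swap_symmetries(self, a, b, c, d):
        k1, k2, k3, k4 = np.exp([a, b, c, d])
        base = ln_omega(k1, k2, k3, k4)
        # swapping the mutant/WT axis or the ligand axis flips the sign
        assert ln_omega(k2, k1, k4, k3) == pytest.approx(-base, rel=1e-9, abs=1e-12)
        assert ln_omega(k3, k4, k1, k2) == pytest.approx(-base, rel=1e-9, abs=1e-12)
        # swapping both leaves it unchanged
        assert ln_omega(k4, k3, k2, k1) == pytest.approx(base, rel=1e-9, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(log_kd, log_kd, log_kd, log_kd, st.floats(np.log(1e-3), np.log(1e3)))
    def test_scale_invariance(self, a, b, c, d, ls):
        k = np.exp([a, b, c, d])
        s = np.exp(ls)
        assert ln_omega(*(s * k)) == pytest.approx(ln_omega(*k), rel=1e-9, abs=1e-12)

    def test_missing_corner_names_offender(self):
        with pytest.raises(IncompleteCycleError, match="Mut\\+alt"):
            ln_omega(50.0, 500.0, 60.0, None)
        with pytest.raises(IncompleteCycleError, match="WT\\+ref"):
            ln_omega(-5.0, 500.0, 60.0, 60.0)


class TestCouplingEnergy:
    def test_zero_coupling(self):
        e, sem = coupling_energy(0.0, [0.1, 0.1, 0.1, 0.1])
        assert e == 0.0
        assert sem == pytest.approx(0.2)

    def test_magnitude_on_kt_scale(self):
        e, sem = coupling_energy(-2.3026, [0, 0, 0, 0])
        assert e == pytest.approx(2.3026)
        assert sem == 0.0

    def test_delta_method_quadrature(self):
        _, sem = coupling_energy(1.0, [0.03, 0.04, 0.0, 0.12])
        assert sem == pytest.approx(np.sqrt(0.03**2 + 0.04**2 + 0.12**2), rel=1e-9)

    def test_delta_method_matches_parametric_monte_carlo(self, rng):
        # independent log-normal corner errors: the quadrature formula should
        # match the Monte-Carlo spread of LnOmega within a few percent
        kds = np.array([50.0, 500.0, 60.0, 60.0])
        rel = np.array([0.05, 0.08, 0.04, 0.10])
        draws = kds * np.exp(rel * rng.standard_normal((2000, 4)))
        lnom = (
            np.log(draws[:, 0]) + np.log(draws[:, 3])
            - np.log(draws[:, 1]) - np.log(draws[:, 2])
        )
        _, sem = coupling_energy(1.0, rel)
        assert np.std(lnom, ddof=1) == pytest.approx(sem, rel=0.25)


class TestClassify:
    @pytest.mark.parametrize(
        "energy,expected", [(2.30, True), (0.0, False), (1.5, False), (1.5000001, True)]
    )
    def test_strict_threshold(self, energy, expected):
        assert classify(energy) is expected

    def test_configurable_threshold(self):
        assert classify(1.2, threshold=1.0) is True


def corner(construct, ligand, kd, voltage=80.0, sem=None):
    po = 0.5
    return GatingParams.from_ec50_pomax(
        construct, ligand, voltage, ec50=kd / 2.0, po_max=po,
        sem_ec50=None if sem is None else sem / 2.0,
    )


class TestBuildCycle:
    def test_complete_cycle(self):
        params = [
            corner("WT", "ligA", 50.0, sem=5.0),
            corner("MUT", "ligA", 500.0, sem=50.0),
            corner("WT", "ligB", 60.0, sem=6.0),
            corner("MUT", "ligB", 60.0, sem=6.0),
        ]
        res = build_cycle(params, "WT", "MUT", "ligA", "ligB")
        assert res.complete
        assert res.coupling_energy_kT == pytest.approx(2.3026, abs=1e-4)
        assert res.interacting is True
        assert res.sem_kT == pytest.approx(0.2, rel=1e-9)

    def test_null_cycle_with_common_fold_change(self):
        params = [
            corner("WT", "ligA", 50.0),
            corner("MUT", "ligA", 350.0),
            corner("WT", "ligB", 60.0),
            corner("MUT", "ligB", 420.0),
        ]
        res = build_cycle(params, "WT", "MUT", "ligA", "ligB")
        assert res.coupling_energy_kT == pytest.approx(0.0, abs=1e-12)
        assert res.interacting is False

    def test_swapping_axes_preserves_energy_and_flips_sign(self):
        params = [
            corner("WT", "ligA", 50.0),
            corner("MUT", "ligA", 500.0),
            corner("WT", "ligB", 60.0),
            corner("MUT", "ligB", 60.0),
        ]
        fwd = build_cycle(params, "WT", "MUT", "ligA", "ligB")
        swapped = build_cycle(params, "MUT", "WT", "ligA", "ligB")
        assert swapped.ln_omega == pytest.approx(-fwd.ln_omega, rel=1e-12)
        assert swapped.coupling_energy_kT == pytest.approx(fwd.coupling_energy_kT, rel=1e-12)

    def test_missing_corner_gives_incomplete_status(self):
        params = [
            corner("WT", "ligA", 50.0),
            corner("MUT", "ligA", 500.0),
            corner("WT", "ligB", 60.0),
            None,
        ]
        res = build_cycle(params, "WT", "MUT", "ligA", "ligB")
        assert not res.complete
        assert "Mut+alt" in res.status
        assert res.interacting is None and res.coupling_energy_kT is None

    def test_mismatched_voltage_rejected(self):
        params = [
            corner("WT", "ligA", 50.0, voltage=80.0),
            corner("MUT", "ligA", 500.0, voltage=-80.0),
            corner("WT", "ligB", 60.0),
            corner("MUT", "ligB", 60.0),
        ]
        with pytest.raises(InputError, match="voltage"):
            build_cycle(params, "WT", "MUT", "ligA", "ligB")

    def test_duplicated_corner_rejected(self):
        params = [corner("WT", "ligA", 50.0), corner("WT", "ligA", 55.0)]
        with pytest.raises(InputError, match="duplicated"):
            build_cycle(params, "WT", "MUT", "ligA", "ligB")

    def test_report_table_row(self):
        res = build_cycle(
            [
                corner("WT", "ligA", 50.0),
                corner("MUT", "ligA", 500.0),
                corner("WT", "ligB", 60.0),
                corner("MUT", "ligB", 60.0),
            ],
            "WT", "MUT", "ligA", "ligB",
        )
        df = cycle_report_table([res])
        row = df.iloc[0]
        assert row["status"] == "complete"
        assert row["coupling_energy_kcal_mol"] == pytest.approx(row["coupling_energy_kT"] * 0.593)
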