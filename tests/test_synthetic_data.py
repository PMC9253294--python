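"""Statistical and bookkeeping properties of the trace simulator."""

import numpy as np
import pytest

from gatecycle import DomainError, InputError, SimulationCondition
from gatecycle.simulate import (
    child_seed,
    default_study_conditions,
    expected_mean,
    expected_variance,
    generate_tmca_study,
    read_study,
    simulate_dose_response,
    simulate_trace,
)


def make_cond(**kw):
    base = dict(
        construct="WT", ligand="ligA", voltage_mV=80.0,
        n_channels=100, i_single=1.0, kd=100.0, L=1.0,
        baseline_pA=0.0, noise_sd_pA=0.0,
    )
    base.update(kw)
    return SimulationCondition(**base)


class TestSimulateTrace:
    def test_zero_concentration_silent_channels(self):
        tr = simulate_trace(make_cond(), 0.0, n_samples=500, seed=1)
        assert np.all(tr.samples == 0.0)

    def test_binomial_moments(self):
        # c = 75 µM with Kd=100, L=1 gives Po = 0.3 exactly
        cond = make_cond()
        tr = simulate_trace(cond, 75.0, n_samples=20000, seed=3)
        n = tr.samples.size
        se_mean = np.sqrt(21.0 / n)
        se_var = 21.0 * np.sqrt(2.0 / (n - 1))
        assert abs(tr.samples.mean() - 30.0) < 3 * se_mean
        assert abs(tr.samples.var(ddof=1) - 21.0) < 3 * se_var

    def test_against_independent_generator(self):
        # direct Monte-Carlo with the legacy RandomState generator
        cond = make_cond()
        tr = simulate_trace(cond, 75.0, n_samples=20000, seed=3)
        other = np.random.RandomState(99).binomial(100, 0.3, size=20000).astype(float)
        se = np.sqrt(2 * 21.0 / 20000)
        assert abs(tr.samples.mean() - other.mean()) < 4 * se

    def test_determinism_under_fixed_seed(self):
        cond = make_cond(noise_sd_pA=2.0)
        a = simulate_trace(cond, 50.0, 1000, seed=42)
        b = simulate_trace(cond, 50.0, 1000, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_duration_matches_samples(self):
        tr = simulate_trace(make_cond(), 10.0, n_samples=700, seed=0)
        assert tr.duration_ms == pytest.approx(350.0)
        assert tr.samples.size * tr.sample_interval_ms == pytest.approx(tr.duration_ms)

    def test_negative_voltage_sign_convention(self):
        cond = make_cond(voltage_mV=-80.0, i_single=-1.0)
        tr = simulate_trace(cond, 1e6, n_samples=200, seed=5)
        assert tr.samples.mean() < 0

    def test_invalid_condition_rejected_before_sampling(self):
        with pytest.raises(DomainError):
            make_cond(n_channels=0)
        with pytest.raises(DomainError):
            make_cond(i_single=0.0)
        with pytest.raises(DomainError):
            make_cond(kd=-1.0)


class TestDoseResponse:
    def test_empty_ladder(self):
        assert simulate_dose_response(make_cond(), [], 1, 100, seed=0) == []

    def test_default_ladder_concentration_groups(self):
        traces = simulate_dose_response(
            make_cond(), [10, 30, 100, 300, 1000, 2000], 2, 50, seed=0
        )
        concs = sorted({t.concentration_uM for t in traces})
        assert concs == [10, 30, 100, 300, 1000, 2000]
        assert len(traces) == 12

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            simulate_dose_response(make_cond(), [10, 10, 30], 1, 50, seed=0)

    def test_noiseless_means_nondecreasing(self):
        traces = simulate_dose_response(
            make_cond(), [10, 30, 100, 300, 1000], 1, 4000, seed=1
        )
        means = [t.samples.mean() for t in traces]
        assert all(b >= a - 0.5 for a, b in zip(means, means[1:]))


class TestMoments:
    def test_expected_moment_helpers(self):
        cond = make_cond(baseline_pA=5.0, noise_sd_pA=2.0)
        po = cond.open_prob(75.0)
        assert expected_mean(cond, 75.0) == pytest.approx(5.0 + 100 * po)
        assert expected_variance(cond, 75.0) == pytest.approx(100 * po * (1 - po) + 4.0)


class TestTmcaStudy:
    def test_study_layout(self, tiny_coupled_study):
        m = tiny_coupled_study.manifest
        assert len(m["corners"]) == 4
        # 2 ref corners x (1 zero + 6 ladder) + 2 alt corners x (+ ref sweep)
        assert len(tiny_coupled_study.traces) == 3 * (2 * 7 + 2 * 8)

    def test_manifest_round_trip_bit_exact(self, tiny_coupled_study, tmp_path):
        d = tiny_coupled_study.write(tmp_path / "study")
        back = read_study(d)
        assert back.manifest == tiny_coupled_study.manifest
        assert len(back.traces) == len(tiny_coupled_study.traces)

    def test_byte_identical_output_for_same_seed(self, tmp_path):
        corners = default_study_conditions("null")
        for sub in ("a", "b"):
            generate_tmca_study(corners, replicates=3, n_samples=100, seed=5).write(
                tmp_path / sub
            )
        for name in ("traces.csv", "manifest.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_corner_validation(self):
        corners = default_study_conditions("coupled")
        with pytest.raises(InputError, match="4 corners"):
            generate_tmca_study(corners[:3])
        from dataclasses import replace

        bad = [replace(corners[0], voltage_mV=-80.0)] + corners[1:]
        with pytest.raises(InputError, match="voltage"):
            generate_tmca_study(bad)
        dup = [corners[0], corners[0], corners[2], corners[3]]
        with pytest.raises(InputError, match="two constructs x two ligands|duplicated"):
            generate_tmca_study(dup)
        with pytest.raises(InputError, match="replicates"):
            generate_tmca_study(corners, replicates=2)

    def test_cell_channel_counts_jittered(self, tiny_coupled_study):
        ns = [c["n_channels"] for c in tiny_coupled_study.manifest["cells"]]
        assert len(set(ns)) > 1
        assert all(abs(n / 200.0 - 1.0) <= 0.2 + 1e-6 for n in ns)


class TestChildSeed:
    def test_stable_and_distinct(self):
        a = child_seed(1, "ladder", "WT:ligA:r0", 0)
        assert a == child_seed(1, "ladder", "WT:ligA:r0", 0)
        assert a != child_seed(1, "ladder", "WT:ligA:r0", 1)
        assert 0 <= a < 2**31
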