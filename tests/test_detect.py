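"""Rip/zip detection, hopping detection, extension measurement, hysteresis."""

import numpy as np
import pytest

from forcemelt.detect import (classify_hysteresis, detect_hopping,
                              detect_rips, measure_extension)
from forcemelt.equilibrium import BranchFit
from forcemelt.trajectory_io import Trajectory, segment_cycles

META = {"construct": "X", "salt": "HIGH_1M", "temperature_C": 22.8,
        "trap_stiffness_pN_nm": 0.156, "trap_velocity_nm_s": 50.0,
        "sample_rate_hz": 1000.0, "noise_sd_pN": 0.3}


def ramp_with_steps(n=4000, slope=0.0078, noise=0.3, steps=(), seed=0,
                    f0=40.0):
    """Noisy loading ramp with instantaneous force steps at given indices."""
    rng = np.random.default_rng(seed)
    f = f0 + slope * np.arange(n) + rng.normal(0, noise, n)
    for idx, size in steps:
        f[idx:] += size
    t = np.arange(n) * 1e-3
    x = 300.0 + 0.05 * np.arange(n)
    traj = Trajectory(t, x, f, dict(META))
    traj.phase = np.full(n, "PULL")
    return traj


class TestDetectRips:
    def test_pure_elastic_phase_is_empty(self):
        traj = ramp_with_steps()
        assert detect_rips(traj) == []

    def test_single_drop_detected_with_location_and_size(self):
        traj = ramp_with_steps(steps=[(2000, -2.2)], seed=1)
        events = detect_rips(traj)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "RIP"
        assert abs(ev.index - 2000) <= 2
        assert ev.force_drop == pytest.approx(2.2, abs=0.25)
        # event force = force immediately before the jump
        assert ev.force == pytest.approx(40.0 + 0.0078 * 2000, abs=0.3)
        assert ev.extension_change == pytest.approx(2.2 / 0.156, rel=0.15)

    def test_rise_is_classified_zip(self):
        traj = ramp_with_steps(slope=-0.0078, f0=60.0,
                               steps=[(2500, 1.9)], seed=2)
        events = detect_rips(traj)
        assert len(events) == 1
        assert events[0].kind == "ZIP"

    def test_two_events_separated(self):
        traj = ramp_with_steps(steps=[(1200, -2.0), (2600, -2.5)], seed=3)
        events = detect_rips(traj)
        assert [e.kind for e in events] == ["RIP", "RIP"]
        assert abs(events[0].index - 1200) <= 2
        assert abs(events[1].index - 2600) <= 2

    def test_low_threshold_warns_about_noise(self):
        traj = ramp_with_steps(seed=4)
        with pytest.warns(UserWarning, match="false-positive"):
            detect_rips(traj, min_drop=0.5)

    def test_too_short_phase_rejected(self):
        traj = ramp_with_steps(n=40)
        with pytest.raises(ValueError, match="samples"):
            detect_rips(traj, window=30)

    def test_simulated_melt_rip_matches_log(self, five_prime_cycles):
        """5'AT pull: exactly one RIP within 0.5 pN of the logged melt."""
        trajs, log = five_prime_cycles
        for traj, clog in zip(trajs, log.cycles):
            pull, relax = segment_cycles(traj)[0]
            rips = [e for e in detect_rips(pull) if e.kind == "RIP"]
            assert len(rips) == 1
            assert rips[0].force == pytest.approx(
                clog.events_named("melt")[0].force, abs=0.5)

    def test_simulated_rezip_zip_matches_log(self, five_prime_cycles):
        trajs, log = five_prime_cycles
        for traj, clog in zip(trajs, log.cycles):
            pull, relax = segment_cycles(traj)[0]
            zips = [e for e in detect_rips(relax, min_drop=1.2)
                    if e.kind == "ZIP"]
            assert len(zips) == 1
            assert zips[0].force == pytest.approx(
                clog.events_named("rezip")[0].force, abs=0.5)


class TestMeasureExtension:
    def make_branch(self, slope, intercept, window=(40.0, 70.0)):
        return BranchFit(slope, intercept, window, 0.1, 100)

    def test_parallel_branches_give_constant_offset(self):
        low = self.make_branch(0.15, -20.0)
        high = self.make_branch(0.15, -20.0 - 0.15 * 14.7)
        for f in (45.0, 55.0, 65.0):
            assert measure_extension(low, high, f) == pytest.approx(14.7)

    def test_antisymmetric_under_branch_exchange(self):
        low = self.make_branch(0.15, -20.0)
        high = self.make_branch(0.14, -24.0)
        f = 50.0
        assert measure_extension(low, high, f) == pytest.approx(
            -measure_extension(high, low, f))

    def test_swapped_branches_give_negative_value(self):
        low = self.make_branch(0.15, -20.0)
        high = self.make_branch(0.15, -22.0)
        assert measure_extension(high, low, 50.0) < 0

    def test_extrapolation_warns(self):
        low = self.make_branch(0.15, -20.0, window=(40.0, 50.0))
        high = self.make_branch(0.15, -22.0, window=(40.0, 50.0))
        with pytest.warns(UserWarning, match="extrapolating"):
            measure_extension(low, high, 60.0)

    def test_zero_slope_degenerate(self):
        bad = BranchFit(0.0, 5.0, (40.0, 50.0), 0.1, 50)
        with pytest.raises(ValueError, match="degenerate"):
            measure_extension(bad, bad, 45.0)


class TestDetectHopping:
    def two_branches(self):
        low = BranchFit(0.15, -20.0, (40.0, 60.0), 0.3, 500)
        high = BranchFit(0.15, -20.9, (40.0, 60.0), 0.3, 500)  # +6 nm offset
        return low, high

    def test_noise_only_single_branch_is_empty(self):
        low, high = self.two_branches()
        rng = np.random.default_rng(0)
        n = 2000
        f = 50.0 + 0.0078 * np.arange(n) + rng.normal(0, 0.3, n)
        x = (f - low.intercept) / low.slope
        traj = Trajectory(np.arange(n) * 1e-3, x, f, dict(META))
        assert detect_hopping(traj, low, high, min_switches=4) == []

    def test_square_wave_alternation_counted(self):
        low, high = self.two_branches()
        n = 2000
        rng = np.random.default_rng(1)
        f = 50.0 + rng.normal(0, 0.05, n)
        x = (f - low.intercept) / low.slope
        # 10 switches: five 100-sample dwells on the upper branch, the last
        # returning to the lower branch before the end of the phase
        state = np.zeros(n, bool)
        for k in range(5):
            state[1000 + 200 * k:1000 + 200 * k + 100] = True
        x[state] += 6.0
        traj = Trajectory(np.arange(n) * 1e-3, x, f, dict(META))
        segs = detect_hopping(traj, low, high, min_switches=4)
        assert len(segs) == 1
        assert segs[0].n_switches == 10
        assert segs[0].dwell_high == pytest.approx(500, abs=30)
        assert not segs[0].upper_isolated

    def test_overlapping_branches_warn_and_return_empty(self):
        low = BranchFit(0.15, -20.0, (40.0, 60.0), 0.3, 500)
        high = BranchFit(0.15, -20.05, (40.0, 60.0), 0.3, 500)
        rng = np.random.default_rng(2)
        n = 500
        f = 50.0 + rng.normal(0, 0.3, n)
        x = (f - low.intercept) / low.slope
        traj = Trajectory(np.arange(n) * 1e-3, x, f, dict(META))
        with pytest.warns(UserWarning, match="separation"):
            assert detect_hopping(traj, low, high) == []

    def test_simulated_hopping_overlaps_logged_interval(
            self, five_prime_high):
        """Detected hopping segment overlaps the logged hop events."""
        from forcemelt.simulate import simulate_molecule
        from forcemelt.equilibrium import fit_branches
        # find a cycle with enough hops
        for seed in range(60, 80):
            trajs, log = simulate_molecule(five_prime_high, 1, seed=seed)
            clog = log.cycles[0]
            hops = [e for e in clog.events if e.name.startswith("hop")]
            if len(hops) >= 6:
                break
        else:
            pytest.fail("no strongly hopping cycle in 20 seeds: hopping "
                        "kinetics look broken")
        traj = trajs[0]
        pull, _ = segment_cycles(traj)[0]
        xb = five_prime_high.states["B"].extension
        xi = five_prime_high.states["I"].extension
        k = five_prime_high.protocol.trap_stiffness
        # branches built from the known state extensions around the crossing
        f_grid = np.linspace(52.0, 62.0, 30)
        low = fit_branches(np.array([xb(f) + f / k for f in f_grid]), f_grid,
                           [(52.0, 62.0)])[0]
        high = fit_branches(np.array([xi(f) + f / k for f in f_grid]), f_grid,
                            [(52.0, 62.0)])[0]
        segs = detect_hopping(pull, low, high, min_switches=4)
        assert segs, "hopping not detected"
        t0 = pull.time[segs[0].start_index]
        t1 = pull.time[segs[0].stop_index]
        hop_times = [e.time for e in hops]
        assert min(hop_times) - 0.5 <= t1 and t0 <= max(hop_times) + 0.5


class TestClassifyHysteresis:
    def test_identical_pull_relax_is_reversible(self):
        n = 3000
        rng = np.random.default_rng(5)
        x = np.concatenate([300 + 0.05 * np.arange(n),
                            300 + 0.05 * (n - 1 - np.arange(n))])
        f_clean = 2.0 + 0.0156 * np.concatenate(
            [np.arange(n), n - 1 - np.arange(n)]) * 0.5
        f = f_clean + rng.normal(0, 0.3, 2 * n)
        t = np.arange(2 * n) * 1e-3
        pull = Trajectory(t[:n], x[:n], f[:n], dict(META))
        relax = Trajectory(t[n:], x[n:], f[n:], dict(META))
        call = classify_hysteresis(pull, relax)
        assert call.verdict == "REVERSIBLE"
        assert call.max_gap < 1.0

    def test_simulated_five_prime_cycle_is_hysteretic(self,
                                                      five_prime_cycles):
        trajs, log = five_prime_cycles
        for traj, clog in zip(trajs, log.cycles):
            pull, relax = segment_cycles(traj)[0]
            call = classify_hysteresis(pull, relax)
            assert call.verdict == "HYSTERETIC"
            assert call.rezip_force is not None
            assert call.rezip_force < clog.events_named("melt")[0].force
            assert call.rezip_force == pytest.approx(
                clog.events_named("rezip")[0].force, abs=1.0)

    def test_disjoint_position_ranges_rejected(self):
        n = 200
        t = np.arange(n) * 1e-3
        a = Trajectory(t, 100 + 0.05 * np.arange(n), np.full(n, 5.0),
                       dict(META))
        b = Trajectory(t, 500 + 0.05 * np.arange(n), np.full(n, 5.0),
                       dict(META))
        with pytest.raises(ValueError, match="range"):
            classify_hysteresis(a, b)
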