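"""Branch fits, reaction extent, two-state and three-state model fits."""

import numpy as np
import pytest
from scipy.special import expit

from forcemelt.equilibrium import (BranchFit, ThreeStateModel, TwoStateModel,
                                   assign_states, branch_position,
                                   fit_branches, population_curves,
                                   reaction_extent)
from forcemelt.polymer import kbt_at

KBT = kbt_at(22.8)


class TestFitBranches:
    def test_exact_linear_data_recovered(self):
        x = np.linspace(300, 400, 200)
        f = -12.0 + 0.15 * x
        br = fit_branches(x, f, [(f.min(), f.max())])[0]
        assert br.slope == pytest.approx(0.15, abs=1e-12)
        assert br.intercept == pytest.approx(-12.0, abs=1e-9)
        assert br.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_noisy_estimates_within_three_se(self):
        rng = np.random.default_rng(11)
        x = np.linspace(300, 400, 500)
        f = -12.0 + 0.15 * x + rng.normal(0, 0.3, x.size)
        br = fit_branches(x, f, [(f.min(), f.max())])[0]
        se_slope = 0.3 / (x.std() * np.sqrt(x.size))
        assert abs(br.slope - 0.15) < 3 * se_slope

    def test_too_few_samples_rejected(self):
        x = np.linspace(0, 1, 5)
        with pytest.raises(ValueError, match="samples"):
            fit_branches(x, x, [(0.0, 1.0)])

    def test_constant_position_singular(self):
        x = np.full(50, 10.0)
        f = np.linspace(0, 1, 50)
        with pytest.raises(ValueError, match="singular"):
            fit_branches(x, f, [(0.0, 1.0)])

    def test_intermediate_slope_smaller_than_flanks(self, atgc_cycles,
                                                    atgc_high):
        """ATGC: the intermediate branch has a smaller force-position
        gradient than the B-form and stretched branches."""
        from forcemelt.pipeline import three_state_from_cycles
        from forcemelt.trajectory_io import segment_cycles
        trajs, _ = atgc_cycles
        pos = np.concatenate([t.trap_position for t in trajs])
        f = np.concatenate([t.force for t in trajs])
        windows = [(50.0, 59.5), (63.3, 65.3), (69.0, 73.5)]
        b, i, s = fit_branches(pos, f, windows, robust=3)
        # the middle window mixes states; compare with the refined pipeline
        res, _pops = three_state_from_cycles(
            [segment_cycles(t)[0] for t in trajs], windows, atgc_high.kbt)
        assert b.slope > 0 and s.slope > 0
        # simulated intermediate gradient is below both flanking gradients
        x_i = atgc_high.states["I"].extension
        k = atgc_high.protocol.trap_stiffness
        fg = np.linspace(63.3, 65.3, 20)
        slope_i = np.polyfit([x_i(v) + v / k for v in fg], fg, 1)[0]
        assert slope_i < b.slope
        assert slope_i < s.slope


class TestReactionExtent:
    def branches(self):
        low = BranchFit(0.15, -20.0, (40.0, 55.0), 0.1, 100)
        high = BranchFit(0.15, -21.5, (70.0, 80.0), 0.1, 100)  # +10 nm
        return low, high

    def test_point_on_lower_branch_is_zero(self):
        low, high = self.branches()
        f = np.array([60.0])
        x = branch_position(low, f)
        ff, phi = reaction_extent(x, f, low, high, force_range=(55.0, 70.0))
        assert phi[0] == pytest.approx(0.0, abs=1e-12)

    def test_point_on_upper_branch_is_one(self):
        low, high = self.branches()
        f = np.array([60.0])
        x = branch_position(high, f)
        _, phi = reaction_extent(x, f, low, high, force_range=(55.0, 70.0))
        assert phi[0] == pytest.approx(1.0, abs=1e-12)

    def test_midway_point_is_half(self):
        low, high = self.branches()
        f = np.array([60.0])
        x = 0.5 * (branch_position(low, f) + branch_position(high, f))
        _, phi = reaction_extent(x, f, low, high, force_range=(55.0, 70.0))
        assert phi[0] == pytest.approx(0.5, abs=1e-12)

    def test_clamped_to_unit_interval(self):
        low, high = self.branches()
        f = np.array([60.0, 60.0])
        x = np.array([branch_position(low, 60.0) - 5.0,
                      branch_position(high, 60.0) + 5.0])
        _, phi = reaction_extent(x, f, low, high, force_range=(55.0, 70.0))
        assert phi[0] == 0.0 and phi[1] == 1.0

    def test_narrow_separation_warns(self):
        low = BranchFit(0.15, -20.0, (40.0, 55.0), 0.5, 100)
        high = BranchFit(0.15, -20.05, (70.0, 80.0), 0.5, 100)
        f = np.array([60.0, 61.0])
        x = branch_position(low, f)
        with pytest.warns(UserWarning, match="separation"):
            reaction_extent(x, f, low, high, force_range=(55.0, 70.0))


class TestTwoStateModel:
    def logistic_data(self, f_tr=67.8, delta=2.6, n=200, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        f = np.linspace(f_tr - 8, f_tr + 8, n)
        phi = expit(delta * (f - f_tr) / KBT)
        if noise:
            phi = np.clip(phi + rng.normal(0, noise, n), 0, 1)
        return f, phi

    def test_noise_free_recovery_to_1e6(self):
        f, phi = self.logistic_data()
        res = TwoStateModel(f, phi, KBT).fit()
        assert res.f_tr == pytest.approx(67.8, rel=1e-6)
        assert res.delta == pytest.approx(2.6, rel=1e-6)

    def test_antisymmetric_data_midpoint_exact(self):
        # data exactly antisymmetric about F0: the midpoint estimate is F0
        f0 = 55.0
        f = np.concatenate([f0 - np.linspace(0.5, 6, 40),
                            [f0], f0 + np.linspace(0.5, 6, 40)])
        phi_side = expit(3.0 * (np.linspace(0.5, 6, 40)) / KBT)
        phi = np.concatenate([1 - phi_side, [0.5], phi_side])
        res = TwoStateModel(f, phi, KBT).fit()
        assert res.f_tr == pytest.approx(f0, abs=1e-9)

    def test_transition_width_identity(self):
        """F(phi=0.95) - F(phi=0.05) = 2 ln(19) kBT / delta ~ 9.3 pN at
        delta = 2.6 nm, consistent with a 60-70 pN transition interval."""
        f, phi = self.logistic_data()
        res = TwoStateModel(f, phi, KBT).fit()
        width = res.transition_width()
        assert width == pytest.approx(2 * np.log(19.0) * KBT / 2.6, rel=1e-6)
        assert width == pytest.approx(9.3, abs=0.2)

    def test_poor_span_warns(self):
        f = np.linspace(60, 62, 30)
        phi = expit(2.6 * (f - 67.8) / KBT)
        with pytest.warns(UserWarning, match="span"):
            TwoStateModel(f, phi, KBT)

    def test_summary_contains_parameters(self):
        f, phi = self.logistic_data(noise=0.05, seed=3)
        res = TwoStateModel(f, phi, KBT).fit()
        text = res.summary()
        assert "F_tr" in text and "delta" in text

    def test_matches_grid_search_oracle(self):
        """Within one grid cell of an exhaustive (F_tr, delta) SSE search."""
        rng = np.random.default_rng(21)
        for _ in range(3):
            f_tr = rng.uniform(60, 70)
            delta = rng.uniform(1.5, 4.0)
            f, phi = self.logistic_data(f_tr, delta, noise=0.05,
                                        seed=rng.integers(1 << 30))
            res = TwoStateModel(f, phi, KBT).fit()
            fg = np.arange(55.0, 75.0, 0.05)
            dg = np.arange(0.5, 6.0, 0.02)
            FF, DD = np.meshgrid(fg, dg, indexing="ij")
            sse = ((phi[None, None, :]
                    - expit(DD[..., None] * (f[None, None, :] - FF[..., None])
                            / KBT)) ** 2).sum(axis=-1)
            i, j = np.unravel_index(np.argmin(sse), sse.shape)
            assert abs(res.f_tr - fg[i]) <= 0.05 + 1e-9
            assert abs(res.delta - dg[j]) <= 0.02 + 1e-9


class TestAssignStates:
    def three_branches(self):
        return [BranchFit(0.15, -12.0, (50.0, 60.0), 0.3, 100),
                BranchFit(0.10, 13.0, (63.0, 65.5), 0.3, 100),
                BranchFit(0.14, -13.0, (69.0, 74.0), 0.3, 100)]

    def test_sample_on_branch_gets_its_label(self):
        brs = self.three_branches()
        f = np.array([64.0, 64.0, 64.0])
        x = np.array([branch_position(b, 64.0) for b in brs])
        labels = assign_states(x, f, brs)
        assert list(labels) == [0, 1, 2]

    def test_tie_breaks_toward_lower_extension(self):
        brs = self.three_branches()
        f = np.array([64.0])
        x0 = branch_position(brs[0], 64.0)
        x1 = branch_position(brs[1], 64.0)
        mid = np.array([(x0 + x1) / 2.0])
        labels = assign_states(mid, f, brs)
        assert labels[0] == 0

    def test_simulated_atgc_agreement_with_ground_truth(self, atgc_cycles):
        """>= 95% per-sample label agreement with the simulator's logged
        state sequence in the transition region."""
        from forcemelt.equilibrium import BranchFit as BF
        trajs, log = atgc_cycles
        pos = np.concatenate([t.trap_position for t in trajs])
        f = np.concatenate([t.force for t in trajs])
        lbl = np.concatenate([c.state_labels for c in log.cycles])
        windows = [(50.0, 59.5), (63.3, 65.3), (69.0, 73.5)]
        branches = list(fit_branches(pos, f, windows, robust=3))
        sel = (f >= 61.5) & (f <= 67.0)
        for _ in range(3):  # refine the intermediate branch on its dwells
            lab = assign_states(pos[sel], f[sel], branches)
            mid = (lab == 1) & (f[sel] >= 63.3) & (f[sel] <= 65.3)
            slope, ic = np.polyfit(pos[sel][mid], f[sel][mid], 1)
            branches[1] = BF(float(slope), float(ic), windows[1], 0.3,
                             int(mid.sum()))
        pred = assign_states(pos[sel], f[sel], branches)
        truth = np.array([{"B": 0, "I": 1, "S": 2}[x] for x in lbl[sel]])
        assert (pred == truth).mean() >= 0.95


class TestPopulationCurves:
    def test_single_state_probability_one(self):
        labels = np.zeros(200, dtype=int)
        forces = np.linspace(60, 64, 200)
        pops, dropped = population_curves(labels, forces, bin_width=0.5)
        assert np.allclose(pops["p_0"], 1.0)
        assert np.allclose(pops["p_1"], 0.0)

    def test_populations_sum_to_one(self):
        rng = np.random.default_rng(31)
        labels = rng.integers(0, 3, 2000)
        forces = rng.uniform(60, 70, 2000)
        pops, _ = population_curves(labels, forces, bin_width=0.5)
        total = pops[["p_0", "p_1", "p_2"]].sum(axis=1)
        assert np.allclose(total, 1.0)

    def test_sparse_bins_dropped_and_reported(self):
        labels = np.zeros(103, dtype=int)
        forces = np.concatenate([np.full(100, 60.2), np.full(3, 65.2)])
        pops, dropped = population_curves(labels, forces, bin_width=0.5)
        assert len(pops) == 1
        assert dropped and abs(dropped[0] - 65.25) < 0.5

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            population_curves(np.zeros(5, int), np.zeros(5), bin_width=0.0)


class TestThreeStateModel:
    TRUE = dict(g_i=496.8, x_i=8.0, g_s=1281.19, x_s=19.9)

    def model_populations(self, f, g_i, x_i, g_s, x_s):
        w = np.stack([np.ones_like(f),
                      np.exp((f * x_i - g_i) / KBT),
                      np.exp((f * x_s - g_s) / KBT)])
        return w / w.sum(axis=0)

    def make_frame(self, noise=0.0, seed=0, n=400):
        import pandas as pd
        rng = np.random.default_rng(seed)
        f = np.arange(58.25, 69.75, 0.5)
        p = self.model_populations(f, **self.TRUE)
        if noise:
            p = np.clip(p + rng.normal(0, noise, p.shape), 0, 1)
            p /= p.sum(axis=0)
        return pd.DataFrame({"force": f, "n": np.full(f.size, n),
                             "p_0": p[0], "p_1": p[1], "p_2": p[2]})

    def test_noise_free_parameters_recovered_to_1e6(self):
        res = ThreeStateModel(self.make_frame(), KBT).fit()
        assert res.g_i == pytest.approx(self.TRUE["g_i"], rel=1e-6)
        assert res.x_i == pytest.approx(self.TRUE["x_i"], rel=1e-6)
        assert res.g_s == pytest.approx(self.TRUE["g_s"], rel=1e-6)
        assert res.x_s == pytest.approx(self.TRUE["x_s"], rel=1e-6)

    def test_crossings_match_closed_forms(self):
        res = ThreeStateModel(self.make_frame(), KBT).fit()
        assert res.crossing_numeric("BI") == pytest.approx(res.f_tr_I,
                                                           abs=1e-6)
        assert res.crossing_numeric("IS") == pytest.approx(res.f_tr_II,
                                                           abs=1e-6)
        assert res.f_tr_numeric() == pytest.approx(res.f_tr, abs=1e-6)
        # and the printed-value anchors used to build the frame
        assert res.f_tr_I == pytest.approx(62.1, abs=1e-3)
        assert res.f_tr == pytest.approx(64.3, abs=1e-3)

    def test_symmetric_configuration_puts_ftr_midway(self):
        # x_I = x_S/2 with symmetric G: F_tr halfway between the crossings
        x_s, x_i = 16.0, 8.0
        f_lo, f_hi = 60.0, 66.0
        g_i = f_lo * x_i
        g_s = g_i + f_hi * (x_s - x_i)
        import pandas as pd
        f = np.arange(55.25, 70.75, 0.5)
        p = self.model_populations(f, g_i, x_i, g_s, x_s)
        frame = pd.DataFrame({"force": f, "n": 400, "p_0": p[0],
                              "p_1": p[1], "p_2": p[2]})
        res = ThreeStateModel(frame, KBT).fit()
        assert res.f_tr == pytest.approx((f_lo + f_hi) / 2.0, abs=1e-6)

    def test_populations_normalised_at_every_force(self):
        res = ThreeStateModel(self.make_frame(noise=0.02, seed=5), KBT).fit()
        fg = np.linspace(55, 72, 300)
        p = res.populations(fg)
        assert np.allclose(p.sum(axis=0), 1.0, atol=1e-12)

    def test_degenerate_intermediate_flagged(self):
        # push the intermediate's free energy up so it never dominates
        import pandas as pd
        g_i = self.TRUE["g_i"] + 40.0
        f = np.arange(58.25, 69.75, 0.5)
        p = self.model_populations(f, g_i, 8.0, self.TRUE["g_s"], 19.9)
        frame = pd.DataFrame({"force": f, "n": 400, "p_0": p[0],
                              "p_1": p[1], "p_2": p[2]})
        with pytest.warns(UserWarning, match="degenerate"):
            res = ThreeStateModel(frame, KBT).fit()
        assert res.degenerate
        # crossings are still reported even though barely identifiable
        assert np.isfinite(res.f_tr_I)
        assert np.isfinite(res.f_tr_II)
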