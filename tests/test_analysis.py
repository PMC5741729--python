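"""Morphometry, SSF/FSF classification and population statistics."""

import numpy as np
import pytest

from fibrilsim import (ModelParams, classify_restretch, population_analysis,
                       relaxed_length, resting_stiffness, summarize,
                       thickness)
from fibrilsim.analysis import (FSF, SSF, RestretchResult,
                                brute_force_enclosing_diameter,
                                population_table)
from fibrilsim.core import axial_to_xy, hex_neighbors
from fibrilsim.errors import FitError, WindowError
from fibrilsim.simulator import Trajectory

from conftest import grow_fibril


def _synthetic(t, f_sub, dL=None, L_r=1.0, n_fn=100):
    t = np.asarray(t, dtype=float)
    f_sub = np.asarray(f_sub, dtype=float)
    dL = np.zeros_like(t) if dL is None else np.asarray(dL, dtype=float)
    return Trajectory(t=t, n_fn=np.full(t.shape, n_fn, dtype=np.int64),
                      L_r=np.full(t.shape, L_r), L_s=L_r + dL,
                      n_integrins=np.zeros(t.shape, dtype=np.int64),
                      f_sub=f_sub)


class TestRelaxedLength:
    def test_single_dimer_is_sum_of_rest_lengths(self, single_dimer):
        p = single_dimer.params
        expected = (30 * p.l_III + 2 * p.l_I_II) / 1000.0  # 0.136 um
        assert relaxed_length(single_dimer) == pytest.approx(expected)
        assert expected == pytest.approx(0.136)

    def test_monotone_under_attachment(self, single_dimer):
        rng = np.random.default_rng(2)
        fib = single_dimer
        prev = relaxed_length(fib)
        for _ in range(20):
            grow_fibril(fib, 1, rng)
            cur = relaxed_length(fib)
            assert cur >= prev - 1e-12
            prev = cur

    def test_equals_stretched_length_without_integrins(self, single_dimer):
        from fibrilsim import solve_equilibrium
        from fibrilsim.analysis import stretched_length
        solve_equilibrium(single_dimer)
        assert stretched_length(single_dimer) == pytest.approx(
            relaxed_length(single_dimer))


class TestThickness:
    def test_single_molecule_is_one_lattice_width(self, single_dimer):
        assert thickness(single_dimer) == pytest.approx(
            single_dimer.params.d_lat)

    def test_hexagonal_flower_is_three_spacings(self, single_dimer):
        fib = single_dimer
        for pos in range(1, 7):
            fib.exposed[fib.node_of(0, pos)] = True
            fib.attach_soluble_fn(0, pos)
        assert thickness(fib) == pytest.approx(3 * fib.params.d_lat)

    def test_matches_bruteforce_enclosing_circle(self, single_dimer):
        rng = np.random.default_rng(9)
        fib = grow_fibril(single_dimer, 60, rng)
        pts = [axial_to_xy(c, fib.params.d_lat) for c in fib.lattice]
        oracle = brute_force_enclosing_diameter(pts) + fib.params.d_lat
        assert thickness(fib) == pytest.approx(oracle, rel=1e-9)


class TestSummarize:
    def test_constant_trajectory_recovers_constants(self, params):
        t = np.arange(0, 1001.0)
        traj = _synthetic(t, f_sub=np.full(t.shape, 50.0),
                          dL=np.full(t.shape, 0.5), L_r=1.0)
        s = summarize(traj, params, window=600.0)
        assert s.f_sub == pytest.approx(50.0)
        assert s.L_s == pytest.approx(1.5)
        assert s.extensibility == pytest.approx(1.5)
        assert np.isnan(s.thickness)

    def test_alternating_samples_average(self, params):
        t = np.arange(0, 701.0)
        ls = np.where(np.arange(t.size) % 2 == 0, 2.0, 3.0)
        traj = _synthetic(t, f_sub=np.zeros(t.size), dL=ls - 1.0, L_r=1.0)
        s = summarize(traj, params, window=600.0)
        assert s.L_s == pytest.approx(2.5, abs=0.01)

    def test_window_longer_than_trajectory_rejected(self, params):
        t = np.arange(0, 100.0)
        traj = _synthetic(t, f_sub=np.zeros(t.size))
        with pytest.raises(WindowError):
            summarize(traj, params, window=600.0)

    def test_sampling_phase_shift_barely_moves_window_means(self, params):
        # shifting sample times by less than the cadence changes the
        # final-window means by < 1 %
        base = np.arange(0, 1201.0)
        f = 100.0 + 10.0 * np.sin(base / 37.0)
        s0 = summarize(_synthetic(base, f_sub=f, dL=f / 1000.0), params)
        s1 = summarize(_synthetic(base + 0.4,
                                  f_sub=100.0 + 10.0 * np.sin((base + 0.4) / 37.0),
                                  dL=None), params)
        assert abs(s1.f_sub - s0.f_sub) / s0.f_sub < 0.01


class TestClassifyRestretch:
    def test_ramp_to_stall_is_ssf(self, params):
        t = np.arange(0, 301.0)
        f = np.minimum(t * 2.0, params.f_stall)
        dL = np.minimum(t * 0.01, 2.0)
        res = classify_restretch(_synthetic(t, f, dL), params)
        assert res.label == SSF
        assert res.window_mean_force == pytest.approx(params.f_stall)

    def test_oscillating_below_stall_is_fsf(self, params):
        t = np.arange(0, 301.0)
        f = 0.6 * params.f_stall * (1.0 + 0.3 * np.sin(t / 5.0))
        dL = np.clip(t * 0.02, 0.0, 1.5) + 0.01 * np.sin(t / 5.0)
        res = classify_restretch(_synthetic(t, f, dL), params)
        assert res.label == FSF

    def test_short_trajectory_rejected(self, params):
        t = np.arange(0, 60.0)
        with pytest.raises(WindowError):
            classify_restretch(_synthetic(t, np.zeros(t.size)), params)

    def test_deterministic_given_trajectory(self, params):
        t = np.arange(0, 301.0)
        f = np.minimum(t * 2.0, params.f_stall)
        traj = _synthetic(t, f, np.minimum(t * 0.01, 2.0))
        a = classify_restretch(traj, params)
        b = classify_restretch(traj, params)
        assert (a.label, a.resting_stiffness) == (b.label, b.resting_stiffness)


class TestRestingStiffness:
    def test_linear_force_stretch_recovers_slope(self):
        t = np.arange(0, 301.0)
        dL = np.minimum(t * 0.004, 1.0)
        traj = _synthetic(t, f_sub=52.5 * dL, dL=dL)
        assert resting_stiffness(traj) == pytest.approx(52.5)

    def test_quadratic_term_bounded_by_taylor_window(self):
        a, b = 40.0, 30.0
        t = np.arange(0, 301.0)
        dL = np.minimum(t * 0.004, 1.0)
        traj = _synthetic(t, f_sub=a * dL + b * dL**2, dL=dL)
        fit = resting_stiffness(traj)
        assert abs(fit - a) <= 2 * b * 0.1  # window is 10% of plateau ~ 1
    def test_too_few_points_raises(self):
        t = np.arange(0, 181.0)
        dL = np.minimum(0.5 + t * 0.004, 1.0)  # starts above the window
        traj = _synthetic(t, f_sub=40 * dL, dL=dL)
        with pytest.raises(FitError):
            resting_stiffness(traj)


def _rr(label, n_fn, stiff, stretch, force, seed=0):
    return RestretchResult(label=label, resting_stiffness=stiff,
                           window_mean_stretch=stretch,
                           window_mean_force=force, n_fn=n_fn, seed=seed)


class TestPopulationAnalysis:
    def test_pearson_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 4.5, 9.0])
        rs = [_rr(FSF, int(n), 10.0 + i, s, f) for i, (n, s, f)
              in enumerate(zip(x * 100, x / 10, y * 20))]
        rs += [_rr(SSF, 500, 15.0, 2.0, 200.0)]
        out = population_analysis([_fake_summary()] * 3, rs)
        r = out["correlations"]["fsf_force_vs_nfn"]
        # direct formula oracle
        xm, ym = x - x.mean(), (y * 20) - (y * 20).mean()
        expected = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_collinear_data_gives_unit_correlation(self):
        n = np.array([100, 200, 300, 400])
        rs = [_rr(FSF, int(v), 10.0, v / 100.0, v / 2.0) for v in n]
        out = population_analysis([_fake_summary()] * 3, rs)
        assert out["correlations"]["fsf_force_vs_nfn"] == pytest.approx(1.0)
        rs = [_rr(FSF, int(v), 10.0, v / 100.0, 300.0 - v / 2.0) for v in n]
        out = population_analysis([_fake_summary()] * 3, rs)
        assert out["correlations"]["fsf_force_vs_nfn"] == pytest.approx(-1.0)

    def test_zero_variance_reported_missing(self):
        rs = [_rr(FSF, 100, 10.0, 1.0, 50.0) for _ in range(4)]
        out = population_analysis([_fake_summary()] * 3, rs)
        assert np.isnan(out["correlations"]["fsf_force_vs_nfn"])

    def test_label_counts_and_fractions(self):
        rs = [_rr(SSF, 480, 16.0, 2.0, 200.0)] * 3 \
            + [_rr(FSF, 320, 22.0, 1.5, 120.0)] * 1
        out = population_analysis([_fake_summary()] * 3, rs)
        assert out["labels"].loc[SSF, "count"] == 3
        assert out["labels"].loc[SSF, "fraction"] == pytest.approx(0.75)

    def test_mean_and_standard_error_convention(self):
        vals = [1.0, 2.0, 3.0]
        table = population_table([_fake_summary(n_fn=v) for v in vals])
        assert table.loc["n_fn", "mean"] == pytest.approx(2.0)
        assert table.loc["n_fn", "se"] == pytest.approx(
            np.std(vals, ddof=1) / np.sqrt(3))

    def test_needs_three_fibrils(self):
        with pytest.raises(ValueError):
            population_analysis([_fake_summary()] * 2)


def _fake_summary(n_fn=100):
    from fibrilsim.analysis import FibrilSummary
    return FibrilSummary(n_fn=int(n_fn), L_r=1.0, L_s=3.0, extensibility=3.0,
                         thickness=50.0, aspect=20.0, n_integrins=30.0,
                         f_sub=150.0)
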