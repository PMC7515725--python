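"""Hopping-trace analysis: decimation, detection, dwells, rates, energetics."""

import numpy as np
import pytest

from nucdyn.hopping import (
    UNWRAPPED,
    WRAPPED,
    DwellSet,
    HoppingTrace,
    NoEquilibriumError,
    RatePoint,
    TransitionSet,
    WLCParams,
    analyze_hopping_experiment,
    decimate_trace,
    detect_transitions,
    estimate_rates,
    extract_dwells,
    fit_force_dependence,
    outer_wrap_free_energy,
    stretch_energy,
    wlc_extension_fraction,
    wlc_force,
)
from nucdyn.simulate import DEFAULT_BELL, analytic_f_eq, gen_hopping_trace


def _trace(ext, rate=250.0, force=3.0):
    ext = np.asarray(ext, dtype=float)
    return HoppingTrace(np.arange(len(ext)) / rate, ext, force, rate)


class TestDecimate:
    def test_factor_one_is_identity(self):
        tr = _trace([1.0, 2.0, 3.0, 4.0])
        assert decimate_trace(tr, 1) is tr

    def test_pair_means(self):
        out = decimate_trace(_trace([1, 3, 5, 7]), 2)
        assert out.ext == pytest.approx([2.0, 6.0])
        assert out.sample_rate == 125.0

    def test_mean_preserved_and_rate_quartered(self):
        rng = np.random.default_rng(0)
        ext = rng.normal(size=4000)
        tr = HoppingTrace(np.arange(4000) / 1000.0, ext, 3.0, 1000.0)
        out = decimate_trace(tr, 4)
        assert out.sample_rate == 250.0
        assert out.ext.mean() == pytest.approx(ext.mean(), abs=1e-12)

    def test_trailing_partial_block_dropped(self):
        out = decimate_trace(_trace([1, 3, 5, 7, 9]), 2)
        assert len(out) == 2

    def test_factor_exceeding_length(self):
        with pytest.raises(ValueError):
            decimate_trace(_trace([1.0, 2.0]), 5)


class TestDetect:
    def test_null_trace_no_change_points(self):
        rng = np.random.default_rng(7)
        ts = detect_transitions(_trace(rng.normal(0, 5, 25000)))
        assert len(ts.change_points) == 0

    def test_noiseless_square_wave_exact(self):
        ext = np.repeat(np.arange(21) % 2, 100) * 25.0
        ts = detect_transitions(_trace(ext), window=25)
        true_cp = np.arange(1, 21) * 100
        assert len(ts.change_points) == 20
        assert np.all(np.abs(ts.change_points - true_cp) <= 1)
        # segments labeled by mean extension
        assert ts.states[0] == WRAPPED and ts.states[1] == UNWRAPPED

    def test_noisy_square_wave_snr5(self):
        rng = np.random.default_rng(11)
        ext = np.repeat(np.arange(21) % 2, 100) * 25.0 + rng.normal(0, 5, 2100)
        ts = detect_transitions(_trace(ext))
        true_cp = np.arange(1, 21) * 100
        hits = sum(np.any(np.abs(ts.change_points - t) <= 5) for t in true_cp)
        spurious = sum(np.all(np.abs(c - true_cp) > 5) for c in ts.change_points)
        assert hits >= 19
        assert spurious == 0

    def test_alternation_and_count_conservation(self):
        trace, _ = gen_hopping_trace(5, 3.0, duration=60.0)
        ts = detect_transitions(decimate_trace(trace, 4))
        for a, b in zip(ts.states, ts.states[1:]):
            assert a != b
        n_uw = sum(s == WRAPPED for s in ts.states[:-1])
        n_wu = sum(s == UNWRAPPED for s in ts.states[:-1])
        assert abs(n_uw - n_wu) <= 1

    def test_too_short_trace(self):
        with pytest.raises(ValueError):
            detect_transitions(_trace(np.zeros(30)), window=25)


class TestDwellsAndRates:
    def test_hand_computed_interior_dwells(self):
        ts = TransitionSet([100, 200, 350], [WRAPPED, UNWRAPPED, WRAPPED, UNWRAPPED],
                           [10.0, 10.0, 10.0], 500)
        ds = extract_dwells(ts, 250.0, drop_boundary=True)
        assert ds.dwells_unwrapped == pytest.approx([0.4])  # samples 100-200
        assert ds.dwells_wrapped == pytest.approx([0.6])  # samples 200-350

    def test_boundary_segments_restored(self):
        ts = TransitionSet([100, 200, 350], [WRAPPED, UNWRAPPED, WRAPPED, UNWRAPPED],
                           [10.0, 10.0, 10.0], 500)
        ds = extract_dwells(ts, 250.0, drop_boundary=False)
        assert len(ds.dwells_wrapped) == 2 and len(ds.dwells_unwrapped) == 2

    def test_single_segment_fully_censored(self):
        ts = TransitionSet([], [WRAPPED], [], 500)
        ds = extract_dwells(ts, 250.0, drop_boundary=True)
        assert len(ds.dwells_wrapped) == 0 and len(ds.dwells_unwrapped) == 0

    def test_reciprocal_mean(self):
        ds = DwellSet([2.0, 2.0, 2.0], [1.0])
        rp = estimate_rates(ds, 3.0)
        assert rp.k_u == pytest.approx(0.5)
        assert rp.k_w == pytest.approx(1.0)
        assert rp.se_kw == pytest.approx(1.0)  # n = 1 edge: se equals the rate

    def test_simulated_exponential_dwells(self):
        rng = np.random.default_rng(123)
        d = rng.exponential(1.0 / 10.0, 1000)
        ds = DwellSet(d, [1.0])
        rp = estimate_rates(ds, 3.0)
        assert abs(rp.k_u - 10.0) < 3 * rp.se_ku

    def test_empty_state_errors(self):
        with pytest.raises(ValueError, match="unwrapped"):
            estimate_rates(DwellSet([1.0], []), 3.0)


class TestBellFit:
    @staticmethod
    def _points(forces, ln_ku, ln_kw):
        return [
            RatePoint(f, np.exp(u), np.exp(w), 0.1, 0.1, 10)
            for f, u, w in zip(forces, ln_ku, ln_kw)
        ]

    def test_analytic_intersection(self):
        f = np.array([2.0, 3.0, 4.0, 5.0])
        pts = self._points(f, -4 + 1.2 * f, 2 - 0.8 * f)
        fit = fit_force_dependence(pts)
        assert fit.f_eq == pytest.approx(3.0, abs=1e-10)
        assert fit.k_eq == pytest.approx(np.exp(-0.4), rel=1e-10)

    def test_swap_symmetry(self):
        f = np.array([2.0, 3.0, 4.0, 5.0])
        pts = self._points(f, -4 + 1.2 * f, 2 - 0.8 * f)
        swapped = [RatePoint(p.force, p.k_w, p.k_u, p.se_kw, p.se_ku, p.n_events) for p in pts]
        with pytest.warns(UserWarning):
            fit2 = fit_force_dependence(swapped)
        assert fit2.f_eq == pytest.approx(fit_force_dependence(pts).f_eq, abs=1e-10)

    def test_noisy_bell_recovery(self):
        rng = np.random.default_rng(21)
        kT = 4.114
        forces = np.linspace(2, 5, 5)
        true_feq = analytic_f_eq(**DEFAULT_BELL, kT=kT)
        pts = []
        for f in forces:
            ku = DEFAULT_BELL["k_u0"] * np.exp(f * DEFAULT_BELL["x_u_dagger"] / kT)
            kw = DEFAULT_BELL["k_w0"] * np.exp(-f * DEFAULT_BELL["x_w_dagger"] / kT)
            pts.append(RatePoint(
                f, ku * np.exp(rng.normal(0, 0.05)), kw * np.exp(rng.normal(0, 0.05)),
                0.1, 0.1, 100,
            ))
        fit = fit_force_dependence(pts)
        assert abs(fit.f_eq - true_feq) < 0.15

    def test_parallel_lines_error(self):
        f = np.array([2.0, 3.0, 4.0])
        pts = self._points(f, -4 + 0.5 * f, 2 + 0.5 * f)
        with pytest.raises(NoEquilibriumError), pytest.warns(UserWarning):
            fit_force_dependence(pts)

    def test_single_force_invalid(self):
        pts = self._points([3.0, 3.0], [1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            fit_force_dependence(pts)


INEXT = WLCParams(stretch_modulus=np.inf)


class TestWLC:
    def test_zero_extension_zero_force(self):
        assert wlc_force(0.0, INEXT) == 0.0

    def test_marko_siggia_midpoint(self):
        # (kT/P)(1/(4*(1/2)^2*4) ...) = 0.08228 * 1.25
        assert wlc_force(0.5, INEXT) == pytest.approx(0.10285, abs=1e-5)

    def test_strictly_monotone(self):
        z = np.linspace(0.0, 0.95, 50)
        f = wlc_force(z, WLCParams())
        assert np.all(np.diff(f) > 0)

    def test_extensible_force_extension_consistency(self):
        params = WLCParams()
        for force in (0.5, 3.0, 10.0, 20.0):
            z = wlc_extension_fraction(force, params)
            assert wlc_force(z, params) == pytest.approx(force, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            wlc_force(1.0, INEXT)


class TestStretchEnergy:
    def test_zero_force_zero_work(self):
        assert stretch_energy(0.0, 25.0, INEXT) == 0.0

    def test_refinement_oracle(self):
        params = WLCParams(persistence_length=50.0, stretch_modulus=np.inf, kT=4.114)
        w = stretch_energy(3.0, 25.0, params)
        # independent fine-grid trapezoid over extension
        z_max = wlc_extension_fraction(3.0, params)
        zs = np.linspace(0, z_max, 20001)
        oracle = 25.0 * np.trapezoid(wlc_force(zs, params), zs)
        assert w == pytest.approx(oracle, rel=1e-3)

    def test_monotone_in_force(self):
        works = [stretch_energy(f, 25.0) for f in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(works) > 0)

    def test_low_force_harmonic_limit(self):
        # F -> 0: x = (2P/3kT) L F, so W = F^2 L P / (3 kT); the expansion
        # needs z = 2PF/3kT << 1 (z ~ 0.016 here)
        params = INEXT
        f, L = 0.001, 100.0
        expected = f**2 * L * params.persistence_length / (3 * params.kT)
        assert stretch_energy(f, L, params) == pytest.approx(expected, rel=0.01)


class TestFreeEnergy:
    def test_exact_cancellation(self):
        res = outer_wrap_free_energy(3.0, 10.0, 30.0, 1.0)
        assert res.dG0_pNnm == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_and_units(self):
        res = outer_wrap_free_energy(3.0, 21.0, 28.0, 1.0)
        assert res.dG0_pNnm == pytest.approx(35.0)
        assert res.dG0_kJmol == pytest.approx(21.077, abs=1e-3)
        assert res.dG0_kJmol / res.dG0_pNnm == pytest.approx(0.6022)

    def test_monotone_in_f_eq(self):
        lo = outer_wrap_free_energy(2.0, 21.0, 5.0, 1.0).dG0_pNnm
        hi = outer_wrap_free_energy(3.0, 21.0, 5.0, 1.0).dG0_pNnm
        assert lo < hi

    def test_invalid_k_eq(self):
        with pytest.raises(ValueError):
            outer_wrap_free_energy(3.0, 21.0, 5.0, 0.0)


class TestPipeline:
    def test_single_force_raises_no_equilibrium(self):
        traces = [gen_hopping_trace(s, 3.0, duration=40.0)[0] for s in (1, 2)]
        with pytest.raises(ValueError):
            analyze_hopping_experiment(traces)

    def test_deterministic_given_fixed_inputs(self):
        traces = [
            gen_hopping_trace(10 + i, f, duration=120.0)[0]
            for i, f in enumerate([2.5, 3.5, 4.5])
        ]
        r1 = analyze_hopping_experiment(traces)
        r2 = analyze_hopping_experiment(traces)
        assert r1.bell.f_eq == r2.bell.f_eq
        assert r1.energy.dG0_pNnm == r2.energy.dG0_pNnm
        assert r1.delta_x == r2.delta_x

    def test_occupancy_consistency(self):
        # wrapped occupancy of the simulated trace matches k_w/(k_u+k_w) and
        # the pipeline's own rate estimates reproduce it
        trace, truth = gen_hopping_trace(42, 3.0, duration=400.0)
        dec = decimate_trace(trace, 4)
        ts = detect_transitions(dec)
        dwells = extract_dwells(ts, dec.sample_rate)
        rp = estimate_rates(dwells, 3.0)
        occ_true = truth["occupancy_wrapped"]
        n_trans = len(truth["transition_times"])
        se = np.sqrt(occ_true * (1 - occ_true) / max(n_trans, 1))
        occ_est = rp.k_w / (rp.k_u + rp.k_w)
        assert abs(occ_est - occ_true) < max(3 * se, 0.03)
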