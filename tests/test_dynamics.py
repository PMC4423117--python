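"""Integrator contracts: conservation, exactness, refinement, topologies."""

import warnings

import numpy as np
import pytest

import dvpattern as dv
from dvpattern.dynamics import (Grid, IntegrationError, NO_CONSTRAINTS,
                                ScenarioConstraints, fourier_upsample_ring,
                                run, step, time_derivative)
from dvpattern.model import FieldState


@pytest.fixture
def p():
    return dv.ModelParameters()


def inert_parameters():
    """All reaction fluxes switched off (basal expression included)."""
    return dv.ModelParameters(eta0=0.0, eta1=1e-30, eta_b=0.0, alpha_s=0.0,
                              alpha_b=0.0, k_plus=0.0, k_minus=0.0, alpha_d=0.0)


class TestGrid:
    def test_cell_centered_coordinates(self):
        g = Grid(nx=64)
        assert g.x[0] == pytest.approx(g.dx / 2)
        assert g.x[-1] == pytest.approx(g.l_x - g.dx / 2)

    def test_minimum_resolution(self):
        with pytest.raises(ValueError):
            Grid(nx=16)

    def test_topology_validation(self):
        with pytest.raises(ValueError):
            Grid(topology="moebius")
        with pytest.raises(ValueError):
            Grid(topology="cylinder", dim=1)
        with pytest.raises(ValueError):
            Grid(topology="cut-ring")  # needs cuts

    def test_fragments_partition_the_ring(self):
        g = Grid(nx=64, topology="cut-ring", cuts=(10, 40))
        a, b = g.fragments()
        assert a.size + b.size == 64
        assert sorted(np.concatenate([a, b])) == list(range(64))

    def test_tiny_fragment_rejected(self):
        g = Grid(nx=64, topology="cut-ring", cuts=(0, 5))
        with pytest.raises(ValueError, match="10 grid cells"):
            g.fragments()


class TestStep:
    @pytest.mark.parametrize("topology", ["ring", "interval"])
    def test_pure_diffusion_conserves_mass(self, topology):
        p = inert_parameters()
        g = Grid(nx=128, topology=topology)
        rng = np.random.default_rng(0)
        fields = [0.1 + 0.05 * rng.random(128) for _ in range(4)]
        state = FieldState(*fields)
        totals0 = [f.sum() for f in (state.s, state.b, state.c, state.d)]
        for _ in range(1000):
            state = step(state, 5.0, g, p)
        totals = [f.sum() for f in (state.s, state.b, state.c, state.d)]
        for t0, t1 in zip(totals0, totals):
            assert abs(t1 - t0) <= 1e-10 * t0

    def test_uniform_fixed_point_is_invariant(self, p):
        g = Grid(nx=64)
        fp = dv.homogeneous_fixed_point(0.0, p)
        state = FieldState(*(np.full(64, v) for v in fp), np.zeros(64))
        for _ in range(200):
            state = step(state, 2.0, g, p)
        for field, v in zip((state.s, state.b, state.c), fp):
            assert np.abs(field - v).max() < 1e-12

    def test_dorsal_decays_exponentially(self, p):
        g = Grid(nx=64)
        state = FieldState(np.full(64, 0.01), np.full(64, 0.32),
                           np.full(64, 0.14), np.full(64, 0.3))
        T, dt = 5e4, 2.0
        for _ in range(int(T / dt)):
            state = step(state, dt, g, p)
        expected = 0.3 * np.exp(-p.alpha_d * T)
        assert state.d == pytest.approx(expected, rel=1e-6)

    def test_dorsal_fixed_mode_holds_the_cue(self, p):
        g = Grid(nx=64)
        cons = ScenarioConstraints(dorsal_mode="fixed")
        state = FieldState(np.full(64, 0.01), np.full(64, 0.32),
                           np.full(64, 0.14), np.full(64, 0.3))
        out = step(state, 2.0, g, p, cons)
        assert (out.d == 0.3).all()

    def test_clamped_species_stay_zero(self, p):
        g = Grid(nx=64)
        cons = ScenarioConstraints(clamps=frozenset({"b"}))
        state = FieldState(np.full(64, 0.01), np.zeros(64),
                           np.full(64, 0.14), np.full(64, 0.3))
        for _ in range(50):
            state = step(state, 2.0, g, p, cons)
        assert (state.b == 0).all()

    def test_nan_aborts_with_field_name(self, p):
        g = Grid(nx=64)
        s = np.full(64, 0.01)
        s[3] = np.nan
        state = FieldState(s, np.full(64, 0.32), np.full(64, 0.14), np.zeros(64))
        with pytest.raises(IntegrationError, match="'s'"):
            step(state, 2.0, g, p)


class TestTimeDerivative:
    def test_vanishes_at_uniform_fixed_point(self, p):
        g = Grid(nx=64)
        fp = dv.homogeneous_fixed_point(0.7, p)
        state = FieldState(*(np.full(64, v) for v in fp), np.full(64, 0.7))
        f_s, f_b, f_c, f_d = time_derivative(
            state, g, p, ScenarioConstraints(dorsal_mode="fixed"))
        assert max(np.abs(f).max() for f in (f_s, f_b, f_c, f_d)) < 1e-12

    def test_dorsal_rate_is_pure_decay(self, p):
        g = Grid(nx=64)
        state = FieldState(np.full(64, 0.01), np.full(64, 0.32),
                           np.full(64, 0.14), np.full(64, 0.3))
        *_, f_d = time_derivative(state, g, p)
        assert f_d == pytest.approx(-p.alpha_d * 0.3)


class TestWildTypeRun:
    def test_single_ventral_stripe(self, wt_run):
        result, summary = wt_run
        assert result.converged
        assert summary.stripe_count == 1
        center, width = summary.stripes[0]
        assert center == pytest.approx(0.5, abs=0.02)  # on the Dorsal maximum
        assert 0.1 < width < 0.6

    def test_bmp_depleted_where_sog_high(self, wt_run):
        result, _ = wt_run
        s, b = result.final.s, result.final.b
        inside = s > (s.max() + s.min()) / 2
        assert b[inside].mean() < 0.05 * b[~inside].mean()

    def test_nonnegative_fields(self, wt_run):
        assert wt_run[0].final.min_concentration() >= -1e-12

    def test_no_undershoot_warning_in_reference_conditions(self, p):
        g = Grid(nx=64)
        state = dv.initial_state(g, dv.ProfileSpec(D0=0.3), p)
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            run(g, state, p, t_end=2e4, polish="never", warn_nonconverged=False)

    def test_snapshots_strictly_increasing(self, p):
        g = Grid(nx=64)
        state = dv.initial_state(g, dv.ProfileSpec(D0=0.3), p)
        res = run(g, state, p, t_end=1e4, polish="never",
                  snapshot_times=[0, 2e3, 5e3], warn_nonconverged=False)
        times = [s.t for s in res.snapshots]
        assert times == sorted(times)
        assert len(times) == 3
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_stripe_persists_without_dorsal(self, wt_run, p):
        # the pattern is self-maintaining once formed: wipe the cue and go on
        result, summary = wt_run
        g = Grid(nx=256)
        state = result.final.copy()
        state.d[...] = 0.0
        cont = run(g, state, p, t_end=state.t + 2e4, polish="never",
                   warn_nonconverged=False)
        after = dv.count_stripes(cont.final.s, "ring")
        assert after.stripe_count == summary.stripe_count == 1
        assert sum(after.widths) == pytest.approx(sum(summary.widths), rel=0.02)

    def test_no_spontaneous_patterning_from_noise(self, p):
        # sub-threshold uniform Dorsal with 1% noise must stay unpatterned
        g = Grid(nx=64)
        cons = ScenarioConstraints(dorsal_mode="fixed")
        for seed in range(10):
            d = dv.perturbed_uniform_profile(g, 0.01, 1e-4, seed=seed)
            state = FieldState(np.full(64, 0.01), np.full(64, 0.32),
                               np.full(64, 0.14), d)
            res = run(g, state, p, cons, t_end=4e4, warn_nonconverged=False)
            assert dv.count_stripes(res.final.s, "ring").stripe_count == 0


class TestTwoDimensional:
    def test_y_uniform_initial_state_stays_y_uniform(self, p):
        g = Grid(nx=64, ny=16, dim=2, topology="cylinder")
        state = dv.initial_state(g, dv.ProfileSpec(D0=0.3), p)
        res = run(g, state, p, t_end=5e3, polish="never", warn_nonconverged=False)
        for field in (res.final.s, res.final.b, res.final.c):
            spread = np.abs(field - field[:, :1]).max()
            assert spread < 1e-10 * max(field.max(), 1e-30)

    def test_run_2d_requires_cylinder(self, p):
        g = Grid(nx=64)
        state = dv.initial_state(g, dv.ProfileSpec(D0=0.3), p)
        with pytest.raises(ValueError):
            dv.run_2d(g, state, p)


class TestCutRing:
    def test_cut_blocks_transport(self, p):
        # diffusion only: mass initially in one fragment must stay there
        pin = inert_parameters()
        g = Grid(nx=64, topology="cut-ring", cuts=(0, 32))
        a, b_idx = g.fragments()
        s = np.zeros(64)
        s[a] = 1.0
        state = FieldState(s, np.zeros(64), np.zeros(64), np.zeros(64))
        for _ in range(500):
            state = step(state, 5.0, g, pin)
        assert state.s[b_idx].max() == 0.0
        assert state.s[a].sum() == pytest.approx(a.size, rel=1e-10)


class TestRefinementHelpers:
    def test_fourier_upsample_exact_on_band_limited_data(self):
        n, nf = 64, 256
        x = (np.arange(n) + 0.5) / n
        xf = (np.arange(nf) + 0.5) / nf
        u = 1.0 + np.sin(2 * np.pi * x) + 0.2 * np.cos(8 * np.pi * x + 0.3)
        uf = 1.0 + np.sin(2 * np.pi * xf) + 0.2 * np.cos(8 * np.pi * xf + 0.3)
        assert np.abs(fourier_upsample_ring(u, nf) - uf).max() < 1e-12

    def test_upsample_requires_multiple(self):
        with pytest.raises(ValueError):
            fourier_upsample_ring(np.zeros(64), 100)
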