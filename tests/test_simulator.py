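import numpy as np
import pytest

from dyadrot import simulator as sim
from dyadrot import trajectory as T


def small_config(**kw):
    defaults = dict(n_steps=20_000, breaking_steps=2_000, record_every=500, seed=1)
    defaults.update(kw)
    return sim.SimConfig(**defaults)


class TestEnergyFunctions:
    @pytest.mark.parametrize("a,b,expected", [(10, 350, 20), (0, 180, 180), (42.5, 42.5, 0)])
    def test_circular_distance(self, a, b, expected):
        assert sim.circular_distance(a, b) == pytest.approx(expected)
        assert sim.circular_distance(b, a) == pytest.approx(expected)

    def test_repulsion_closed_forms(self):
        cfg = small_config()
        assert sim.repulsion_energy(0.0, 180.0, cfg) == pytest.approx(1.0)
        assert sim.repulsion_energy(0.0, 90.0, cfg) == pytest.approx(4096.0)  # 2**12
        assert sim.repulsion_energy(30.0, 80.0, cfg) == sim.repulsion_energy(80.0, 30.0, cfg)

    def test_repulsion_strictly_decreasing(self):
        cfg = small_config()
        d = np.linspace(10, 180, 50)
        u = [sim.repulsion_energy(0.0, x, cfg) for x in d]
        assert np.all(np.diff(u) < 0)

    def test_overlap_is_infinite(self):
        assert sim.repulsion_energy(10.0, 10.0, small_config()) == np.inf

    def test_well_closed_forms(self):
        assert sim.well_energy(90.0, 90.0, 30.0) == pytest.approx(-1.0)
        assert sim.well_energy(120.0, 90.0, 30.0) == pytest.approx(-np.exp(-0.5))
        assert sim.well_energy(90.0 + 300.0, 90.0, 30.0) == pytest.approx(
            sim.well_energy(90.0 - 60.0, 90.0, 30.0)
        )  # circular difference inside the Gaussian
        assert -1e-6 < sim.well_energy(0.0, 180.0, 10.0) < 0.0  # tail limit

    def test_hamiltonian_composition(self):
        cfg = small_config(rho=1.0, omega1=50.0, omega2=20.0, mu1=0.0, mu2=180.0)
        h = sim.hamiltonian(0.0, 180.0, cfg, wells_active=True)
        assert h == pytest.approx(1.0 - 70.0)
        # wells off == zero-depth wells
        cfg0 = small_config(rho=1.0, omega1=0.0, omega2=0.0)
        assert sim.hamiltonian(30.0, 200.0, cfg, wells_active=False) == pytest.approx(
            sim.hamiltonian(30.0, 200.0, cfg0, wells_active=True)
        )


class TestMetropolisStep:
    def test_downhill_always_accepted_uphill_sometimes_rejected(self):
        cfg = small_config(omega1=50.0, omega2=0.0, mu1=0.0, beta=5.0)
        rng = np.random.default_rng(0)
        # start cell 1 on a steep flank of its well: moves toward mu drop energy
        state = sim.SimState(30.0, 210.0, sim.hamiltonian(30.0, 210.0, cfg, True), True)
        accepted_down = rejected_up = 0
        for _ in range(500):
            new = sim.metropolis_step(state, cfg, rng)
            de = new.energy - state.energy
            if new.accepted and de < 0:
                accepted_down += 1
            if not new.accepted:
                rejected_up += 1
                assert (new.theta1, new.theta2) == (state.theta1, state.theta2)
            state = new
        assert accepted_down > 0 and rejected_up > 0

    def test_zero_delta_accepted(self):
        cfg = small_config(omega1=0.0, omega2=0.0, rho=0.0)
        rng = np.random.default_rng(1)
        state = sim.SimState(10.0, 200.0, 0.0, False)
        results = [sim.metropolis_step(state, cfg, rng).accepted for _ in range(50)]
        assert all(results)  # exp(0) = 1

    def test_single_lattice_move_per_step(self):
        cfg = small_config()
        rng = np.random.default_rng(2)
        state = sim.SimState(0.0, 180.0, sim.hamiltonian(0.0, 180.0, cfg, True), True)
        for _ in range(200):
            new = sim.metropolis_step(state, cfg, rng)
            m1 = sim.circular_distance(new.theta1, state.theta1)
            m2 = sim.circular_distance(new.theta2, state.theta2)
            assert {round(m1 / cfg.step_deg), round(m2 / cfg.step_deg)} <= {0, 1}
            assert m1 == 0.0 or m2 == 0.0  # one cell at a time
            state = new


class TestRunSimulation:
    def test_same_seed_bit_identical(self):
        cfg = small_config(omega2=20.0, mu2=180.0)
        a, b = sim.run_simulation(cfg), sim.run_simulation(cfg)
        np.testing.assert_array_equal(a.theta1, b.theta1)
        np.testing.assert_array_equal(a.energy, b.energy)

    def test_lattice_positions_only(self):
        out = sim.run_simulation(small_config())
        frac = (out.theta1 / out.config.step_deg) % 1.0
        np.testing.assert_allclose(np.minimum(frac, 1 - frac), 0.0, atol=1e-9)

    def test_energy_bookkeeping_matches_recomputation(self):
        cfg = small_config(omega2=25.0, mu2=180.0)
        out = sim.run_ensemble(cfg, n_reps=4, seed=9)
        for k, step in enumerate(out["steps"]):
            active = step > cfg.breaking_steps or cfg.breaking_steps == 0
            h = sim.hamiltonian(out["theta1"][:, k], out["theta2"][:, k], cfg, active)
            np.testing.assert_allclose(h, out["energy"][:, k], atol=1e-9)

    def test_free_walk_has_no_net_drift(self):
        # no wells: the pair axis performs a symmetric random walk
        cfg = small_config(omega1=0.0, omega2=0.0, n_steps=20_000, breaking_steps=0)
        drifts = []
        for seed in range(40):
            out = sim.run_ensemble(cfg, n_reps=1, seed=seed)
            rec = sim.SimTrajectory(cfg, out["steps"], out["theta1"][0], out["theta2"][0],
                                    out["energy"][0], 1.0)
            pair = rec.pair_record()
            s = T.angle_series(T.center_pair(pair))
            drifts.append(s.final_cumulative)
        sem = np.std(drifts) / np.sqrt(len(drifts))
        assert abs(np.mean(drifts)) < 2.5 * sem + 1e-9

    def test_deep_well_captures_particle(self):
        cfg = small_config(
            omega1=50.0, omega2=0.0, mu1=90.0, sigma=140.0, beta=0.5,
            n_steps=150_000, breaking_steps=0, record_every=5_000,
        )
        out = sim.run_ensemble(cfg, n_reps=30, seed=4)
        d = sim.circular_distance(out["final_theta1"], cfg.mu1)
        width = cfg.sigma / np.sqrt(cfg.beta * cfg.omega1)
        assert np.mean(d < 2 * width) >= 0.9

    def test_global_rotation_covariance_exact(self):
        # rotating wells and initial condition by a lattice-multiple offset
        # rotates the whole trajectory exactly (matched seeds)
        offset = 45.0
        base = small_config(omega1=50.0, omega2=20.0, mu1=0.0, mu2=180.0, init_mean=180.0)
        rot = small_config(
            omega1=50.0, omega2=20.0, mu1=offset, mu2=180.0 + offset, init_mean=180.0 + offset
        )
        a = sim.run_simulation(base)
        b = sim.run_simulation(rot)
        np.testing.assert_allclose((a.theta1 + offset) % 360.0, b.theta1 % 360.0, atol=1e-9)
        np.testing.assert_allclose((a.theta2 + offset) % 360.0, b.theta2 % 360.0, atol=1e-9)

    def test_swap_symmetry_of_summaries(self):
        # exchanging the two cells' wells AND their initial positions
        # (relabeling 1 <-> 2) leaves the ensemble summaries unchanged
        # up to Monte Carlo error; in axis init mode the positions swap
        # when the initial axis angle is advanced by 180 degrees
        kw = dict(n_steps=120_000, breaking_steps=5_000, record_every=2_000,
                  sigma=140.0, beta=0.2)
        cfg_a = sim.SimConfig(omega1=50.0, omega2=20.0, mu1=180.0, mu2=180.0,
                              init_mean=180.0, **kw)
        cfg_b = sim.SimConfig(omega1=20.0, omega2=50.0, mu1=180.0, mu2=180.0,
                              init_mean=0.0, **kw)
        dev = {}
        for name, cfg in (("a", cfg_a), ("b", cfg_b)):
            out = sim.run_ensemble(cfg, n_reps=60, seed=5)
            dev[name] = np.median(
                sim.final_axis_deviation(out["final_theta1"], out["final_theta2"])
            )
        assert dev["a"] == pytest.approx(dev["b"], abs=12.0)


class TestConfigsAndSweep:
    def test_relative_depth_examples(self):
        assert sim.relative_well_depth(sim.make_asymmetric_config()) == 0.0
        assert sim.relative_well_depth(sim.make_symmetric_config()) == pytest.approx(0.4)
        assert sim.relative_well_depth(
            sim.make_symmetric_config(omega2=25.0)
        ) == pytest.approx(0.5)

    def test_asymmetric_wells_opposed_symmetric_coincide(self):
        a, s = sim.make_asymmetric_config(), sim.make_symmetric_config()
        assert sim.circular_distance(a.mu1, a.mu2) == pytest.approx(180.0)
        assert s.mu1 == s.mu2

    def test_sweep_single_replicate_degenerate(self):
        tmpl = small_config(n_steps=5_000, breaking_steps=500, record_every=100)
        df = sim.sweep_replicates(tmpl, n_reps=1, depth_ratios=(0.4,), seed=3)
        assert len(df) == 2  # both models, one ratio
        assert set(df["model"]) == {"asymmetric", "symmetric"}
        assert df["n_reps"].eq(1).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sim.SimConfig(d_int=200.0)
        with pytest.raises(ValueError):
            sim.SimConfig(n_steps=10, breaking_steps=10)
        with pytest.raises(ValueError):
            sim.SimConfig(omega1=-1.0)
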