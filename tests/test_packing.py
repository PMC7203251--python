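"""Unit and property tests for the packing model (radii, energy, minimizer)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sphepi
from sphepi import (
    DegenerateGeometryError,
    EnergyModel,
    ParticleConfiguration,
    energy_gradient,
    minimize,
    random_configuration,
    random_uniform_sphere,
    sample_radii,
    total_energy,
)


# ---------------------------------------------------------------------------
# Radius sampling
# ---------------------------------------------------------------------------


class TestSampleRadii:
    def test_zero_sigma_gives_unit_radii(self):
        assert np.array_equal(sample_radii(5, 0.0), np.ones(5))

    def test_mean_normalized_exactly(self):
        radii = sample_radii(10000, 0.1, seed=1)
        assert radii.mean() == pytest.approx(1.0, abs=1e-15)
        assert (radii > 0).all()

    def test_sample_std_matches_gaussian_spread(self):
        radii = sample_radii(10000, 0.1, seed=1)
        assert abs(radii.std() - 0.1) < 0.005

    @pytest.mark.parametrize("n", [0, -3])
    def test_invalid_n_raises(self, n):
        with pytest.raises(ValueError):
            sample_radii(n, 0.1)

    def test_negative_sigma_raises(self):
        with pytest.raises(ValueError):
            sample_radii(5, -0.1)


class TestRandomUniformSphere:
    def test_unit_norm(self):
        pos = random_uniform_sphere(2, seed=0)
        assert np.allclose(np.linalg.norm(pos, axis=1), 1.0, atol=1e-12)

    def test_mean_vector_small(self):
        pos = random_uniform_sphere(1000, seed=0)
        assert np.linalg.norm(pos.mean(axis=0)) < 0.1

    def test_distinct_points(self):
        pos = random_uniform_sphere(4, seed=7)
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        assert (d[np.triu_indices(4, 1)] > 0).all()

    def test_too_few_raises(self):
        with pytest.raises(ValueError):
            random_uniform_sphere(1, seed=0)


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------


def antipodal_pair() -> ParticleConfiguration:
    return ParticleConfiguration(
        positions=np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]),
        radii=np.ones(2))


class TestTotalEnergy:
    @pytest.mark.parametrize("alpha", [1.0, 2.0, 12.0, 300.0])
    def test_antipodal_unit_pair_is_one(self, alpha):
        # chord distance 2, s_i + s_j = 2 -> (2/2)^alpha = 1
        assert total_energy(antipodal_pair(), EnergyModel(alpha=alpha)) == pytest.approx(1.0)

    def test_doubling_radii_scales_by_2_to_alpha(self):
        cfg = random_configuration(30, 0.1, seed=2)
        scaled = ParticleConfiguration(cfg.positions, cfg.radii * 2)
        model = EnergyModel(alpha=12.0)
        u = total_energy(cfg, model)
        assert total_energy(scaled, model) == pytest.approx(4096 * u, rel=1e-10)

    def test_equilateral_triangle_on_great_circle(self):
        # inscribed equilateral triangle, side sqrt(3), alpha=1: 3 * (2/sqrt(3))
        ang = 2 * np.pi * np.arange(3) / 3
        pos = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(3)])
        cfg = ParticleConfiguration(pos, np.ones(3))
        u = total_energy(cfg, EnergyModel(alpha=1.0))
        assert u == pytest.approx(3 * 2 / np.sqrt(3), rel=1e-12)

    def test_lennard_jones_pair_minimum(self):
        # two particles at r = rho sit at the pair minimum, energy -1
        cfg = ParticleConfiguration(
            positions=np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]),
            radii=np.ones(2))
        assert total_energy(cfg, EnergyModel(variant="lennard_jones", rho=2.0)) == \
            pytest.approx(-1.0)

    def test_coincident_particles_raise(self):
        pos = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        cfg = ParticleConfiguration.__new__(ParticleConfiguration)
        cfg.positions, cfg.radii = pos, np.ones(3)
        with pytest.raises(DegenerateGeometryError):
            total_energy(cfg, EnergyModel(alpha=12.0))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_permutation_and_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        cfg = random_configuration(12, 0.1, seed=seed)
        model = EnergyModel(alpha=6.0)
        u = total_energy(cfg, model)
        perm = rng.permutation(12)
        u_perm = total_energy(ParticleConfiguration(cfg.positions[perm], cfg.radii[perm]), model)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rot = cfg.positions @ q.T
        rot /= np.linalg.norm(rot, axis=1)[:, None]
        u_rot = total_energy(ParticleConfiguration(rot, cfg.radii), model)
        assert u_perm == pytest.approx(u, rel=1e-10)
        assert u_rot == pytest.approx(u, rel=1e-8)

    @given(beta=st.floats(0.25, 4.0), alpha=st.floats(1.0, 40.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_energy_scaling_law(self, beta, alpha):
        cfg = random_configuration(15, 0.1, seed=3)
        model = EnergyModel(alpha=alpha)
        u = total_energy(cfg, model)
        scaled = ParticleConfiguration(cfg.positions, cfg.radii * beta)
        assert total_energy(scaled, model) == pytest.approx(beta**alpha * u, rel=1e-10)


# ---------------------------------------------------------------------------
# Gradient
# ---------------------------------------------------------------------------


class TestEnergyGradient:
    def test_antipodal_pair_is_stationary(self):
        g = energy_gradient(antipodal_pair(), EnergyModel(alpha=12.0))
        assert np.linalg.norm(g, axis=1).max() < 1e-12

    def test_tangency(self):
        cfg = random_configuration(20, 0.1, seed=4)
        g = energy_gradient(cfg, EnergyModel(alpha=12.0))
        radial = np.abs(np.einsum("ik,ik->i", g, cfg.positions))
        assert (radial <= 1e-10 * np.linalg.norm(g, axis=1).max()).all()

    @pytest.mark.parametrize("variant,alpha", [("generalized_repulsive", 12.0),
                                               ("generalized_repulsive", 1.0),
                                               ("lennard_jones", 12.0)])
    def test_matches_central_differences(self, variant, alpha):
        cfg = random_configuration(10, 0.1, seed=5)
        model = EnergyModel(alpha=alpha, variant=variant, rho=0.8)
        g = energy_gradient(cfg, model)
        eps = 1e-6
        fd = np.zeros_like(g)
        for i in range(10):
            for k in range(3):
                for sgn, tgt in ((1, 0), (-1, 1)):
                    p = cfg.positions.copy()
                    p[i, k] += sgn * eps
                    p[i] /= np.linalg.norm(p[i])
                    c = ParticleConfiguration(p, cfg.radii)
                    if tgt == 0:
                        up = total_energy(c, model)
                    else:
                        um = total_energy(c, model)
                fd[i, k] = (up - um) / (2 * eps)
        scale = np.abs(g).max()
        assert np.abs(fd - g).max() < 1e-6 * scale

    def test_rotational_equivariance(self):
        cfg = random_configuration(15, 0.1, seed=6)
        model = EnergyModel(alpha=12.0)
        g = energy_gradient(cfg, model)
        q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((3, 3)))
        rot_pos = cfg.positions @ q.T
        rot_pos /= np.linalg.norm(rot_pos, axis=1)[:, None]
        g_rot = energy_gradient(ParticleConfiguration(rot_pos, cfg.radii), model)
        assert np.allclose(g_rot, g @ q.T, rtol=1e-6, atol=1e-9 * np.abs(g).max())


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------


class TestMinimize:
    def test_two_particles_become_antipodal(self):
        cfg = random_configuration(2, 0.0, seed=1)
        res = minimize(cfg, EnergyModel(alpha=3.0))
        chord = np.linalg.norm(res.config.positions[0] - res.config.positions[1])
        assert res.converged
        assert chord == pytest.approx(2.0, abs=1e-6)

    def test_four_identical_particles_form_tetrahedron(self):
        # Thomson optimum at N=4: regular tetrahedron, chord sqrt(8/3)
        cfg = random_configuration(4, 0.0, seed=0)
        res = minimize(cfg, EnergyModel(alpha=1.0))
        d = np.linalg.norm(res.config.positions[:, None] - res.config.positions[None, :], axis=-1)
        chords = d[np.triu_indices(4, 1)]
        assert np.allclose(chords, np.sqrt(8 / 3), atol=1e-4)

    def test_twelve_identical_particles_form_icosahedron(self):
        cfg = random_configuration(12, 0.0, seed=0)
        res = minimize(cfg, EnergyModel(alpha=1.0))
        tri = sphepi.delaunay_on_sphere(res.config.positions)
        assert sphepi.valence_histogram(sphepi.valences(tri)) == {5: 12}

    # Optima of U = sum 2/r_ij at sigma=0 (twice the classic Coulomb Thomson
    # energies), frozen from an independent multi-start L-BFGS oracle on
    # embedded coordinates.
    @pytest.mark.parametrize("n,u_opt", [(4, 7.348469228),
                                         (6, 19.970562748),
                                         (12, 98.330506115)])
    def test_thomson_optima_energy(self, n, u_opt):
        """alpha=1, sigma=0 minimized energies reach the known Thomson optima."""
        model = EnergyModel(alpha=1.0)
        energies = [minimize(random_configuration(n, 0.0, seed=s), model).energy
                    for s in range(5)]
        assert min(energies) == pytest.approx(u_opt, rel=1e-4)

    def test_energy_trace_monotone_non_increasing(self):
        cfg = random_configuration(40, 0.1, seed=2)
        res = minimize(cfg, EnergyModel(alpha=12.0), keep_trace=True)
        assert (np.diff(res.energy_trace) <= 0).all()

    def test_output_positions_unit_norm_and_radii_unchanged(self, minimized_small):
        res = minimized_small
        assert np.allclose(np.linalg.norm(res.config.positions, axis=1), 1.0, atol=1e-12)
        assert res.config.radii.mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonconvergence_flagged_not_raised(self):
        cfg = random_configuration(30, 0.1, seed=3)
        res = minimize(cfg, EnergyModel(alpha=12.0), max_iter=3, flow_steps=2)
        assert res.converged is False


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------


def test_configuration_csv_round_trip(tmp_path, minimized_small):
    path = tmp_path / "config.csv"
    sphepi.write_configuration_csv(minimized_small.config, path)
    back = sphepi.read_configuration_csv(path)
    assert np.allclose(back.positions, minimized_small.config.positions, atol=1e-12)
    assert np.allclose(back.radii, minimized_small.config.radii, atol=1e-15)


def test_run_config_yaml_and_json(tmp_path):
    (tmp_path / "run.yaml").write_text("n: 50\nsigma: 0.1\nalpha: 12\nseed: 3\n")
    cfg = sphepi.load_run_config(tmp_path / "run.yaml")
    assert cfg == {"n": 50, "sigma": 0.1, "alpha": 12, "seed": 3}
    (tmp_path / "run.json").write_text('{"n": 5, "bogus": 1}')
    with pytest.raises(ValueError):
        sphepi.load_run_config(tmp_path / "run.json")
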