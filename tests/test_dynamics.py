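"""Unwrapping, MSD/diffusion, conductivity, viscosity, residence, dielectric."""

import numpy as np
import pytest

import liqprop.constants as c
from liqprop import dynamics, synthetic
from liqprop.errors import UnsupportedSystemError
from liqprop.trajio import Trajectory

from conftest import make_frame


# ---------------------------------------------------------------------------
# unwrap
# ---------------------------------------------------------------------------


class TestUnwrap:
    def test_boundary_crossing_becomes_continuous(self):
        frames = []
        for t, (x, ix) in enumerate([(18.0, 0), (19.5, 0), (1.0, 1), (2.5, 1)]):
            frames.append(
                make_frame([[x, 5.0, 5.0]], step=t,
                           images=np.array([[ix, 0, 0]]))
            )
        traj = dynamics.unwrap(Trajectory(frames))
        x = traj.positions_array()[:, 0, 0]
        np.testing.assert_allclose(x, [18.0, 19.5, 21.0, 22.5])
        assert np.max(np.abs(np.diff(x))) < 10.0

    def test_static_atoms_unchanged(self, static_trajectory):
        out = dynamics.unwrap(static_trajectory)
        np.testing.assert_array_equal(
            out.positions_array(), static_trajectory.positions_array()
        )

    def test_jump_heuristic_matches_flags_on_brownian_path(self):
        fx = synthetic.gen_brownian(n_atoms=20, n_frames=200, D=1e-9,
                                    dt=1e-12, seed=5, box_edge=1e-8)
        by_flags = dynamics.unwrap(fx.trajectory)
        by_jumps = dynamics.unwrap(fx.trajectory_no_flags)
        np.testing.assert_allclose(
            by_jumps.positions_array(), by_flags.positions_array(), atol=1e-20
        )
        np.testing.assert_allclose(
            by_flags.positions_array(), fx.unwrapped_positions, atol=1e-20
        )


# ---------------------------------------------------------------------------
# MSD + diffusion
# ---------------------------------------------------------------------------


class TestMSD:
    def test_ballistic_motion_is_exactly_quadratic(self):
        v = np.array([0.03, 0.0, 0.04])  # |v| = 0.05 per frame
        frames = [make_frame([[1.0, 1.0, 1.0] + t * v], step=t) for t in range(40)]
        traj = Trajectory(frames, dt_sample=1.0)
        res = dynamics.compute_msd(traj, max_lag_fraction=1.0)
        np.testing.assert_allclose(res.msd, (0.05 * res.lag) ** 2, atol=1e-12)

    def test_fft_equals_direct_on_brownian_fixture(self):
        fx = synthetic.gen_brownian(n_atoms=30, n_frames=100, D=1e-9,
                                    dt=1e-12, seed=8, box_edge=1e-8)
        traj = dynamics.unwrap(fx.trajectory)
        fft = dynamics.compute_msd(traj, method="fft")
        direct = dynamics.compute_msd(traj, method="direct")
        np.testing.assert_allclose(fft.msd[1:], direct.msd[1:], rtol=1e-8)
        assert fft.msd[0] == direct.msd[0] == 0.0

    def test_static_atoms_have_zero_msd(self, static_trajectory):
        res = dynamics.compute_msd(static_trajectory)
        np.testing.assert_allclose(res.msd, 0.0, atol=1e-10)
        direct = dynamics.compute_msd(static_trajectory, method="direct")
        np.testing.assert_array_equal(direct.msd, 0.0)

    def test_wrapped_input_detected(self):
        fx = synthetic.gen_brownian(n_atoms=10, n_frames=50, D=1e-7,
                                    dt=1e-12, seed=1, box_edge=1e-9)
        with pytest.raises(ValueError, match="unwrap"):
            dynamics.compute_msd(fx.trajectory)


class TestFitDiffusion:
    def test_exact_linear_msd_recovers_d(self):
        lag = np.linspace(0, 1e-9, 200)
        msd = dynamics.MSDResult(lag=lag, msd=6 * 1e-9 * lag, method="fft",
                                 n_origins=200, unit_style="si")
        fit = dynamics.fit_diffusion(msd)
        assert fit.D == pytest.approx(1e-9, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.linear

    @pytest.mark.parametrize("d_true", [1e-10, 1e-9, 1e-8])
    def test_brownian_parameter_recovery(self, d_true):
        fx = synthetic.gen_brownian(n_atoms=200, n_frames=2000, D=d_true,
                                    dt=1e-12, seed=0, box_edge=1e-8)
        traj = dynamics.unwrap(fx.trajectory)
        fit = dynamics.fit_diffusion(dynamics.compute_msd(traj))
        assert fit.D_si == pytest.approx(d_true, rel=0.05)

    def test_ballistic_msd_flags_nonlinearity(self):
        lag = np.linspace(0, 10, 100)
        msd = dynamics.MSDResult(lag=lag, msd=lag**2, method="fft", n_origins=100)
        fit = dynamics.fit_diffusion(msd, window=(0.05, 1.0))
        assert not fit.linear
        assert fit.r_squared < 0.98

    def test_too_few_points_in_window(self):
        lag = np.linspace(0, 1.0, 6)
        msd = dynamics.MSDResult(lag=lag, msd=lag, method="fft", n_origins=6)
        with pytest.raises(ValueError, match="window"):
            dynamics.fit_diffusion(msd, window=(0.5, 0.6))


# ---------------------------------------------------------------------------
# Nernst-Einstein conductivity
# ---------------------------------------------------------------------------


class TestNernstEinstein:
    V = (10e-9) ** 3
    T = 298.15

    def test_hand_evaluated_closed_form(self):
        sigma = dynamics.nernst_einstein(
            [1e-9, 1e-9], [1, -1], [10, 10], self.V, self.T
        )
        expected = (
            c.E_CHARGE**2 / (self.V * c.KB * self.T) * (10 * 1e-9 + 10 * 1e-9)
        )
        assert sigma == pytest.approx(expected, rel=1e-12)
        assert sigma == pytest.approx(0.1247, rel=1e-3)

    def test_neutral_species_contribute_nothing(self):
        assert dynamics.nernst_einstein([1e-9], [0], [100], self.V, self.T) == 0.0

    def test_linearity_in_counts_and_inverse_volume(self):
        base = dynamics.nernst_einstein([1e-9], [2], [10], self.V, self.T)
        assert dynamics.nernst_einstein(
            [1e-9], [2], [20], self.V, self.T
        ) == pytest.approx(2 * base)
        assert dynamics.nernst_einstein(
            [1e-9], [2], [10], 2 * self.V, self.T
        ) == pytest.approx(base / 2)

    def test_species_order_irrelevant(self):
        a = dynamics.nernst_einstein([1e-9, 2e-9], [1, -2], [5, 3], self.V, self.T)
        b = dynamics.nernst_einstein([2e-9, 1e-9], [-2, 1], [3, 5], self.V, self.T)
        assert a == pytest.approx(b, rel=1e-14)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dynamics.nernst_einstein([1e-9], [1, -1], [10], self.V, self.T)


# ---------------------------------------------------------------------------
# Green-Kubo viscosity
# ---------------------------------------------------------------------------


class TestGKViscosity:
    def test_zero_stress_gives_zero_eta(self):
        import pandas as pd

        from liqprop.trajio import ThermoTable

        table = ThermoTable(pd.DataFrame({
            "Step": np.arange(1000.0), "Pxy": np.zeros(1000)
        }))
        res = dynamics.gk_viscosity(table, 1e-26, 300.0, t_cut=50.0, dt=1.0)
        assert res.eta == 0.0

    def test_ou_series_matches_analytic_integral(self):
        fx = synthetic.gen_ou_stress(n_samples=100000, dt=1.0, variance=2.5,
                                     tau_c=10.0, seed=3)
        V, T = 1e-26, 300.0
        res = dynamics.gk_viscosity(fx.thermo, V, T, t_cut=50.0, dt=1.0)
        expected = V * fx.manifest["truth"]["acf_integral"] / (c.KB * T)
        assert res.eta == pytest.approx(expected, rel=0.10)

    def test_single_component_equals_three_identical(self):
        import pandas as pd

        from liqprop.trajio import ThermoTable

        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        one = ThermoTable(pd.DataFrame({"Step": np.arange(2000.0), "Pxy": x}))
        three = ThermoTable(pd.DataFrame({
            "Step": np.arange(2000.0), "Pxy": x, "Pxz": x, "Pyz": x
        }))
        r1 = dynamics.gk_viscosity(one, 1e-26, 300.0, t_cut=20.0, dt=1.0)
        r3 = dynamics.gk_viscosity(three, 1e-26, 300.0, t_cut=20.0, dt=1.0)
        assert r1.eta == pytest.approx(r3.eta, rel=1e-12)

    def test_non_uniform_steps_rejected(self):
        import pandas as pd

        from liqprop.trajio import ThermoTable

        table = ThermoTable(pd.DataFrame({
            "Step": [0.0, 1.0, 3.0], "Pxy": [0.0, 1.0, 0.0]
        }))
        with pytest.raises(ValueError, match="uniform"):
            dynamics.gk_viscosity(table, 1e-26, 300.0, t_cut=2.0, dt=1.0)


# ---------------------------------------------------------------------------
# residence time
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def markov():
    return synthetic.gen_markov_binding(p_leave=0.05, seed=4)


class TestResidenceTime:

    def test_markov_leave_process_fit(self, markov):
        res = dynamics.residence_time(
            markov.trajectory, {"species": "center"}, {"species": "ligand"},
            cutoff=markov.manifest["cutoff"], definition="continuous",
            system_map=markov.system_map,
        )
        assert res.tau_fit == pytest.approx(markov.manifest["truth"]["tau"], rel=0.05)
        assert res.converged

    def test_c_zero_is_one_and_continuous_below_intermittent(self, markov):
        kwargs = dict(
            center_sel={"species": "center"}, ligand_sel={"species": "ligand"},
            cutoff=markov.manifest["cutoff"], system_map=markov.system_map,
        )
        cont = dynamics.residence_time(markov.trajectory, definition="continuous",
                                       **kwargs)
        inter = dynamics.residence_time(markov.trajectory, definition="intermittent",
                                        **kwargs)
        assert cont.C[0] == 1.0 and inter.C[0] == 1.0
        assert np.all(cont.C <= inter.C + 1e-12)

    def test_permanently_bound_pair_unconverged(self, neutral_ion_template,
                                                diatomic_template):
        from liqprop.sysmodel import build_system_map

        smap = build_system_map([neutral_ion_template, diatomic_template], [1, 1])
        pos = np.array([[5.0, 5, 5], [6.0, 5, 5], [6.5, 5, 5]])
        frames = [make_frame(pos, step=t) for t in range(20)]
        traj = Trajectory(frames)
        res = dynamics.residence_time(traj, {"species": "probe"},
                                      {"species": "solv"}, cutoff=2.0,
                                      system_map=smap)
        assert np.all(res.C == 1.0)
        assert not res.converged

    def test_never_bound_is_an_error(self, neutral_ion_template,
                                     diatomic_template):
        from liqprop.sysmodel import build_system_map

        smap = build_system_map([neutral_ion_template, diatomic_template], [1, 1])
        pos = np.array([[1.0, 1, 1], [10.0, 10, 10], [10.5, 10, 10]])
        traj = Trajectory([make_frame(pos, step=t) for t in range(5)])
        with pytest.raises(ValueError, match="cutoff"):
            dynamics.residence_time(traj, {"species": "probe"},
                                    {"species": "solv"}, cutoff=1.0,
                                    system_map=smap)


# ---------------------------------------------------------------------------
# dielectric constant
# ---------------------------------------------------------------------------


class TestDielectric:
    def test_zero_charges_give_unity(self):
        from liqprop.sysmodel import SpeciesTemplate, build_system_map

        tmpl = SpeciesTemplate("apolar", ["Ar"], [39.9], [0.0])
        smap = build_system_map([tmpl], [10])
        rng = np.random.default_rng(2)
        frames = [
            make_frame(rng.uniform(0, 20, (10, 3)), step=t) for t in range(50)
        ]
        traj = Trajectory(frames)
        res = dynamics.dielectric_constant(traj, smap, 298.15)
        assert res.epsilon == pytest.approx(1.0)

    def test_random_dipole_gas_closed_form(self):
        fx = synthetic.gen_dipole_gas(n_dipoles=100, box_edge=50.0,
                                      n_frames=10000, seed=5)
        res = dynamics.dielectric_constant(fx.trajectory, fx.system_map, 298.15)
        mu = fx.manifest["truth"]["mu"] * c.E_CHARGE * 1e-10
        V = (fx.manifest["box_edge"] * 1e-10) ** 3
        expected = 1.0 + fx.manifest["n_dipoles"] * mu**2 / (
            3 * c.EPS0 * V * c.KB * 298.15
        )
        assert res.epsilon - 1 == pytest.approx(expected - 1, rel=0.05)

    def test_frozen_parallel_dipoles_have_no_fluctuation(self):
        from liqprop.sysmodel import SpeciesTemplate, build_system_map

        tmpl = SpeciesTemplate("dip", ["He", "He"], [1.0, 1.0], [0.5, -0.5])
        smap = build_system_map([tmpl], [4])
        base = np.array(
            [[2, 2, 2], [2, 2, 3], [6, 6, 6], [6, 6, 7],
             [12, 2, 2], [12, 2, 3], [2, 12, 2], [2, 12, 3]], dtype=float
        )
        traj = Trajectory([make_frame(base, step=t) for t in range(30)])
        res = dynamics.dielectric_constant(traj, smap, 298.15)
        assert res.epsilon == pytest.approx(1.0)

    def test_ionic_species_rejected_with_explanation(self, ion_template):
        from liqprop.sysmodel import build_system_map

        smap = build_system_map([ion_template], [2])
        traj = Trajectory([make_frame([[1.0, 1, 1], [5.0, 5, 5]])])
        with pytest.raises(UnsupportedSystemError, match="ionic"):
            dynamics.dielectric_constant(traj, smap, 298.15)
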