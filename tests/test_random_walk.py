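"""Random-walk engine: diffusion statistics, membranes, exchange calibration."""

import math

import numpy as np
import pytest

from tddscope import random_walk as rw
from tddscope.substrate import Compartment, lattice_from_vin


class TestInitialization:
    def test_intracellular_fraction_matches_vin(self):
        lat = lattice_from_vin(6.0, 0.30, 0.0)
        ens = rw.initialize_walkers(lat, 100_000, seed=3)
        sigma = math.sqrt(0.3 * 0.7 / 100_000)
        assert abs(ens.intracellular_fraction() - 0.30) < 3 * sigma

    def test_same_seed_reproduces_ensemble(self):
        lat = lattice_from_vin(6.0, 0.52, 0.0)
        a = rw.initialize_walkers(lat, 5000, seed=9)
        b = rw.initialize_walkers(lat, 5000, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.compartment, b.compartment)

    def test_tiny_sphere_leaves_walkers_extracellular(self):
        lat = lattice_from_vin(0.05, 1e-6, 0.0)
        ens = rw.initialize_walkers(lat, 2000, seed=1)
        assert ens.intracellular_fraction() < 0.01

    def test_compartment_restricted_start(self):
        lat = lattice_from_vin(6.0, 0.30, 0.0)
        ens = rw.initialize_walkers(
            lat, 2000, seed=4, compartment=Compartment.INTRA
        )
        assert ens.intracellular_fraction() == 1.0


class TestFreeDiffusion:
    def test_einstein_relation(self):
        # MSD/(6t) recovers D0 within MC error in a free medium
        ens = rw.run_trajectories(None, 20_000, 2e-3, 50.0, seed=5)
        d = ens.displacements()
        d_est = np.mean(np.sum(d * d, axis=1)) / (6 * 50.0)
        # relative MC error of the MSD mean is ~0.6% at n=2e4; allow 3 sigma
        assert d_est == pytest.approx(2.0, rel=0.02)

    def test_step_size_invariance_of_msd_slope(self):
        # Gaussian diffusion: the MSD slope is independent of dt
        slopes = []
        for dt in (5e-3, 1e-3):
            ens = rw.run_trajectories(None, 10_000, dt, 40.0, seed=6)
            d = ens.displacements()
            slopes.append(np.mean(np.sum(d * d, axis=1)) / 40.0)
        assert slopes[0] == pytest.approx(slopes[1], rel=0.03)

    def test_deterministic_given_seed(self):
        a = rw.run_trajectories(None, 500, 2e-3, 1.0, seed=8)
        b = rw.run_trajectories(None, 500, 2e-3, 1.0, seed=8)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestRestrictedDiffusion:
    def test_impermeable_sphere_long_time_variance(self):
        # stationary uniform density in a sphere: Var(dx) -> 2 r^2 / 5
        lat = lattice_from_vin(10.0, 0.52, 0.0)
        ens = rw.run_trajectories(
            lat, 8000, 2e-3, 80.0, seed=11, start_compartment=Compartment.INTRA
        )
        var = np.var(ens.displacements()[:, 0])
        assert var == pytest.approx(2 * 10.0**2 / 5, rel=0.05)

    def test_impermeable_labels_never_change(self):
        lat = lattice_from_vin(8.0, 0.30, 0.0)
        ens = rw.initialize_walkers(lat, 4000, seed=12)
        labels0 = ens.compartment.copy()
        for _ in range(5):
            rw.step_walkers(ens, lat)
        np.testing.assert_array_equal(ens.compartment, labels0)
        assert not ens.ever_crossed.any()

    def test_walker_count_conserved(self):
        lat = lattice_from_vin(4.0, 0.52, 20.0)
        ens = rw.run_trajectories(lat, 3000, 2e-3, 5.0, seed=13)
        assert ens.n_walkers == 3000
        assert np.isfinite(ens.positions).all()
        # wrapped positions stay in the primary cell
        assert np.max(np.abs(ens.positions)) <= lat.pitch_um / 2 + 1e-9

    def test_trajectory_record_memory_guard(self):
        # full traces at production scale must stream, not materialize
        with pytest.raises(MemoryError, match="record_stride"):
            rw.run_trajectories(None, 20_000, 1e-3, 100.0, seed=1, record_stride=1)

    def test_step_length_warning_for_coarse_raster(self):
        lat = lattice_from_vin(2.0, 0.30, 0.0)
        ens = rw.initialize_walkers(lat, 10, seed=1, dt_ms=0.05)
        with pytest.warns(UserWarning, match="step length"):
            rw.step_walkers(ens, lat)


class TestExchange:
    def test_survival_rate_recovers_k(self):
        # first-passage survival of initially-INTRA walkers decays at rate k
        lat = lattice_from_vin(5.0, 0.30, 8.0)
        t, s = rw.intracellular_survival(lat, 20_000, 2e-3, 100.0, seed=123)
        k_emp = rw.empirical_escape_rate(t, s)
        assert k_emp == pytest.approx(8.0, rel=0.10)

    def test_equilibrium_occupancy_is_vin(self):
        # detailed balance: long-time intracellular occupancy returns to vin
        lat = lattice_from_vin(5.0, 0.30, 20.0)
        ens = rw.run_trajectories(lat, 20_000, 2e-3, 100.0, seed=14)
        sigma = math.sqrt(0.3 * 0.7 / 20_000)
        assert abs(ens.intracellular_fraction() - 0.30) < 4 * sigma

    def test_transmission_probability_formula(self):
        lat = lattice_from_vin(6.0, 0.30, 20.0)
        l = rw.step_length(2.0, 2e-3)
        expected = rw.PT_COEFF * lat.kappa_um_per_ms * l / 2.0
        assert rw.transmission_probability(lat, 2e-3) == pytest.approx(expected)
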