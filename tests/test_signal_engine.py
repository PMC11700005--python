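"""Phase accumulation, signal statistics, Karger and GPD oracles."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from tddscope import random_walk as rw
from tddscope import signal_engine as se
from tddscope.pgse_waveforms import (
    CONVENTIONAL_1P5T,
    MRI_LINAC_1P5T,
    PgseWaveform,
    waveform_for_b,
)
from tddscope.substrate import Compartment, lattice_from_vin


class TestPhaseAccumulation:
    def test_static_walkers_rephase_exactly(self):
        # balanced lobes: zero phase for stationary spins
        wf = waveform_for_b(1000.0, 10.0, 20.0)
        ens = rw.run_trajectories(None, 50, 2e-3, 0.0, seed=1)
        # freeze walkers by simulating a zero-diffusivity medium: emulate by
        # accumulating the phase of the *initial* positions under the raster
        signs = wf.sign_raster(2e-3)
        phases = (
            se._GAMMA_SIM * wf.G_mT_per_m * 2e-3 * signs.sum() * ens.positions[:, 0]
        )
        np.testing.assert_allclose(phases, 0.0, atol=1e-12)

    def test_zero_amplitude_waveform_gives_zero_phase(self):
        wf = PgseWaveform(0.0, 10.0, 20.0)
        ens = rw.run_trajectories(None, 200, 2e-3, 0.0, seed=2)
        phi = se.accumulate_phase(ens, wf)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_free_diffusion_phase_variance_is_2bD(self):
        # Gaussian phase: Var(phi) = 2 b D
        wf = waveform_for_b(1000.0, 20.0, 40.0)
        ens = rw.run_trajectories(None, 20_000, 2e-3, 0.0, seed=3)
        phi = se.accumulate_phase(ens, wf)
        assert np.var(phi) == pytest.approx(2 * 1.0 * 2.0, rel=0.05)

    def test_misaligned_raster_rejected(self):
        wf = PgseWaveform(10.0, 10.001, 20.0)
        ens = rw.run_trajectories(None, 10, 2e-3, 0.0, seed=4)
        with pytest.raises(ValueError, match="align"):
            se.accumulate_phase(ens, wf)


class TestSignalFromPhases:
    def test_zero_phases_give_unit_signal(self):
        s, serr = se.signal_from_phases(np.zeros(100))
        assert s == 1.0 and serr == 0.0

    def test_free_diffusion_signal_all_protocol_waveforms(self):
        # engine reproduces exp(-b D0) for every protocol timing; this also
        # verifies the b bookkeeping end to end
        wfs = [
            w
            for proto, b in ((CONVENTIONAL_1P5T, 1250.0), (MRI_LINAC_1P5T, 1000.0))
            for w in proto.waveforms(b)
        ]
        names = [f"wf{i}" for i in range(len(wfs))]
        import dataclasses

        wfs = [dataclasses.replace(w, name=n) for w, n in zip(wfs, names)]
        tab = se.simulate_signals(None, wfs, n_walkers=20_000, dt_ms=2e-3, seed=5)
        for row in tab.itertuples():
            expected = math.exp(-row.b * 1e-3 * 2.0)
            assert abs(row.signal - expected) < 3 * row.se + 0.003

    def test_minimum_two_walkers(self):
        with pytest.raises(ValueError):
            se.signal_from_phases(np.array([0.1]))


class TestKargerOracle:
    def test_no_exchange_is_biexponential(self):
        s = se.karger_signal(0.4, 0.6, 2.0, 0.0, 1500.0, 60.0)
        expected = 0.4 * math.exp(-1.5 * 0.6) + 0.6 * math.exp(-1.5 * 2.0)
        assert s == pytest.approx(expected, rel=1e-12)

    def test_fast_exchange_is_monoexponential(self):
        s = se.karger_signal(0.4, 0.6, 2.0, 1e7, 1500.0, 60.0)
        expected = math.exp(-1.5 * (0.4 * 0.6 + 0.6 * 2.0))
        assert s == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("k", [1.0, 8.0, 20.0, 100.0])
    def test_matches_matrix_exponential(self, k):
        # brute-force two-site master equation via scipy expm
        f, din, dex, b, td = 0.3, 0.5, 1.8, 2000.0, 50.0
        q2 = b * 1e-3 / td
        kie = k * 1e-3
        kei = kie * f / (1 - f)
        A = np.array([[-q2 * din - kie, kei], [kie, -q2 * dex - kei]])
        expected = float(expm(A * td) @ np.array([f, 1 - f]) @ np.ones(2))
        assert se.karger_signal(f, din, dex, k, b, td) == pytest.approx(
            expected, rel=1e-10
        )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            se.karger_signal(1.2, 1.0, 2.0, 0.0, 1000.0, 50.0)


class TestGpdSphereOracle:
    def test_free_limit_large_radius(self):
        # the series approaches exp(-b D) as r -> inf (O(1/r) convergence)
        wf = waveform_for_b(1000.0, 10.0, 30.0)
        free = math.exp(-1.0 * 2.0)
        errs = [
            se.gpd_sphere_signal(r, 2.0, wf.G_mT_per_m, 10.0, 30.0, n_terms=40) - free
            for r in (100.0, 200.0, 500.0)
        ]
        assert errs[0] > errs[1] > errs[2] > 0
        assert errs[2] < 0.03 * free + 0.003

    def test_long_time_restricted_plateau(self):
        # SGP-like regime, q r small: -ln S ~ q^2 r^2 / 5 (variance r^2/5)
        r, d0 = 5.0, 2.0
        delta, Delta = 0.1, 200.0
        G = 10.0
        q = se._GAMMA_SIM * G * delta  # 1/um
        s = se.gpd_sphere_signal(r, d0, G, delta, Delta, n_terms=40)
        assert -math.log(s) == pytest.approx(q**2 * r**2 / 5.0, rel=0.05)

    def test_monotone_decreasing_in_gradient(self):
        vals = [se.gpd_sphere_signal(8.0, 2.0, g, 20.0, 40.0) for g in (5, 15, 30)]
        assert vals[0] > vals[1] > vals[2] > 0

    def test_engine_matches_gpd_for_intracellular_spins(self):
        # impermeable r=10 um sphere, conventional WF1 at b = 1000 s/mm^2
        lat = lattice_from_vin(10.0, 0.52, 0.0)
        wf = waveform_for_b(1000.0, 27.0, 35.0, name="WF1")
        tab = se.simulate_signals(
            lat,
            [wf],
            n_walkers=10_000,
            dt_ms=2e-3,
            seed=6,
            start_compartment=Compartment.INTRA,
        )
        s_mc, serr = float(tab.signal.iloc[0]), float(tab.se.iloc[0])
        s_gpd = se.gpd_sphere_signal(10.0, 2.0, wf.G_mT_per_m, 27.0, 35.0)
        assert abs(s_mc - s_gpd) < 0.03 + 3 * serr


class TestComEffect:
    def test_longer_delta_raises_small_sphere_signal(self):
        # at fixed b and t_d, lengthening delta pushes the probed restriction
        # size toward zero (center-of-mass effect): intracellular signal rises
        td, b, r = 40.0, 1000.0, 3.0
        lat = lattice_from_vin(r, 0.52, 0.0)
        sigs, ses = [], []
        for delta in (6.0, 30.0):
            Delta = td + delta / 3.0
            wf = waveform_for_b(b, delta, Delta, name=f"d{delta}")
            tab = se.simulate_signals(
                lat,
                [wf],
                n_walkers=8000,
                dt_ms=2e-3,
                seed=7,
                start_compartment=Compartment.INTRA,
            )
            sigs.append(float(tab.signal.iloc[0]))
            ses.append(float(tab.se.iloc[0]))
        assert sigs[1] > sigs[0] + 5 * max(ses)

    def test_com_effect_in_gpd_oracle(self):
        td, b, r = 40.0, 1000.0, 3.0
        out = []
        for delta in (2.0, 30.0):
            Delta = td + delta / 3.0
            wf = waveform_for_b(b, delta, Delta)
            out.append(se.gpd_sphere_signal(r, 2.0, wf.G_mT_per_m, delta, Delta))
        assert out[1] > out[0]


class TestExchangeRecovery:
    def test_karger_fit_recovers_exchange_rate(self):
        # fit the Karger model to engine signals on an exchange-dominated
        # substrate (r = 2 um, k = 20 1/s); k recovered within 25%
        from scipy.optimize import curve_fit

        lat = lattice_from_vin(2.0, 0.52, 20.0)
        delta = 3.0  # Delta = td + 1 ms keeps lobe edges on the raster
        tds = (20.0, 40.0, 70.0)
        bs = (800.0, 1600.0, 2500.0)
        wfs = [
            waveform_for_b(b, delta, td + delta / 3.0, name=f"td{td}_b{b}")
            for td in tds
            for b in bs
        ]
        tab = se.simulate_signals(lat, wfs, n_walkers=20_000, dt_ms=2e-3, seed=8)

        def model(X, din, dex, k):
            b, td = X
            return np.array(
                [
                    se.karger_signal(lat.vin, din, dex, k, bi, tdi)
                    for bi, tdi in zip(b, td)
                ]
            )

        X = (tab.b.to_numpy(), tab.td_ms.to_numpy())
        popt, _ = curve_fit(
            model,
            X,
            tab.signal.to_numpy(),
            p0=(0.3, 1.5, 5.0),
            bounds=([0.0, 0.1, 0.0], [2.0, 3.0, 100.0]),
            maxfev=5000,
        )
        assert popt[2] == pytest.approx(20.0, rel=0.25)


class TestSignalTableIO:
    def test_csv_and_hdf5_roundtrip(self, tmp_path):
        wf = waveform_for_b(500.0, 10.0, 20.0, name="WF1")
        tab = se.simulate_signals(None, [wf], n_walkers=500, dt_ms=5e-3, seed=9)
        for name in ("t.csv", "t.h5"):
            p = tmp_path / name
            se.save_signal_table(tab, p)
            back = se.load_signal_table(p)
            assert back.waveform_id.iloc[0] == "WF1"
            assert back.signal.iloc[0] == pytest.approx(tab.signal.iloc[0])
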