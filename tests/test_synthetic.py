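"""Synthetic-data generator: determinism, noise calibration, presets."""

import numpy as np
import pytest

from pr10flex.constants import ARAH8_HELIX_RESIDUES, ARAH8_SHEET_RESIDUES
from pr10flex.dispersion import compute_r2eff, model_r2eff_limits
from pr10flex.synthetic import (
    TwoSiteTruth,
    backbone_schedule,
    simulate_dispersion_dataset,
    simulate_ligand_dispersion,
    simulate_titration_series,
    truth_presets,
)


class TestPresets:
    def test_helix_preset_parameters(self):
        t = truth_presets("arah8_helix")
        assert t.kex == 1060.0
        assert t.p_b == 0.079
        assert len(t.residues) == 20
        assert set(t.residues) == set(ARAH8_HELIX_RESIDUES)

    def test_sheet_preset_parameters(self):
        t = truth_presets("arah8_sheet")
        assert t.kex == 810.0
        assert t.p_b == 0.013
        assert len(t.residues) == 26
        assert set(t.residues) == set(ARAH8_SHEET_RESIDUES)

    def test_clusters_disjoint(self):
        assert not set(ARAH8_HELIX_RESIDUES) & set(ARAH8_SHEET_RESIDUES)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            truth_presets("betv1_helix")

    def test_delta_range_and_override(self):
        t = truth_presets("arah8_helix", seed=5)
        assert all(0.3 <= d <= 3.5 for d in t.delta_ppm.values())
        t2 = truth_presets("arah8_helix", delta_ppm={r: 1.0 for r in ARAH8_HELIX_RESIDUES})
        assert set(t2.delta_ppm.values()) == {1.0}


class TestDispersionSimulation:
    def test_same_seed_bit_identical(self, helix_truth, sched):
        a = simulate_dispersion_dataset(helix_truth, sched, 0.3, seed=9)
        b = simulate_dispersion_dataset(helix_truth, sched, 0.3, seed=9)
        assert a.equals(b)

    def test_different_seed_differs(self, helix_truth, sched):
        a = simulate_dispersion_dataset(helix_truth, sched, 0.3, seed=9)
        b = simulate_dispersion_dataset(helix_truth, sched, 0.3, seed=10)
        assert not a.intensity.equals(b.intensity)

    def test_no_minor_state_gives_flat_recomputed_rates(self, sched):
        truth = TwoSiteTruth(kex=1000.0, p_b=0.0, delta_ppm={5: 2.0},
                             r2_0={(5, 600.0): 14.0, (5, 700.0): 14.0})
        tab = simulate_dispersion_dataset(truth, sched, noise_sigma=0.0)
        r2 = compute_r2eff(tab.intensity.to_numpy(), tab.i0.to_numpy(),
                           sched.relax_time)
        assert np.allclose(r2, 14.0)

    def test_zero_shift_residue_flat(self, sched):
        truth = TwoSiteTruth(kex=1000.0, p_b=0.08, delta_ppm={5: 0.0},
                             r2_0={(5, 600.0): 14.0, (5, 700.0): 14.0})
        tab = simulate_dispersion_dataset(truth, sched, noise_sigma=0.0)
        r2 = compute_r2eff(tab.intensity.to_numpy(), tab.i0.to_numpy(),
                           sched.relax_time)
        assert np.allclose(r2, 14.0)

    def test_negative_noise_rejected(self, helix_truth, sched):
        with pytest.raises(ValueError):
            simulate_dispersion_dataset(helix_truth, sched, noise_sigma=-0.1)

    def test_repeat_points_present_twice(self, helix_truth, sched):
        tab = simulate_dispersion_dataset(helix_truth, sched, 0.0, seed=1)
        counts = tab.groupby(["residue", "field_mhz", "n_cycles"]).size()
        for n in sched.repeats:
            assert (counts.xs(n, level="n_cycles") == 2).all()

    def test_rate_noise_calibration(self, sched):
        """sd of recomputed rates matches noise_sigma within 10%."""
        truth = TwoSiteTruth(kex=1000.0, p_b=0.0, delta_ppm={5: 0.0},
                             r2_0={(5, 600.0): 14.0, (5, 700.0): 14.0})
        draws = []
        for s in range(60):  # 60 datasets x 28 points = 1680 draws
            tab = simulate_dispersion_dataset(truth, sched, noise_sigma=0.3, seed=s)
            r2 = compute_r2eff(tab.intensity.to_numpy(), tab.i0.to_numpy(),
                               sched.relax_time)
            draws.extend(r2 - 14.0)
        assert len(draws) >= 1000
        assert np.std(draws) == pytest.approx(0.3, rel=0.10)

    def test_amplitude_grows_with_field(self, helix_truth, sched):
        """ddelta_omega scales with B0, so 700 MHz amplitudes >= 600 MHz."""
        for res in helix_truth.residues[:5]:
            amps = {}
            for f in (600.0, 700.0):
                z, inf = model_r2eff_limits(
                    helix_truth.kex, helix_truth.p_b, helix_truth.delta_ppm[res],
                    helix_truth.r2_0[(res, f)], f, "15N")
                amps[f] = z - inf
            assert amps[700.0] >= amps[600.0]


class TestTitrationSimulation:
    def test_no_binding_limit(self):
        s = simulate_titration_series(kd=1e6, noise_ppm=0.0, seed=1)
        assert np.abs(s.table.delta_h_ppm).max() < 1e-3

    def test_saturation_limit_reaches_endpoint(self):
        endpoint = {1: (0.3, 1.0)}
        s = simulate_titration_series(kd=1e-5, protein_conc=0.2,
                                      ratios=(30.0,), endpoint_shifts=endpoint,
                                      noise_ppm=0.0, seed=1)
        assert s.table.delta_h_ppm.iloc[0] == pytest.approx(0.3, rel=1e-3)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_titration_series(kd=-1.0)
        with pytest.raises(ValueError):
            simulate_titration_series(kd=0.76, ratios=(-2.0,))

    def test_determinism(self):
        a = simulate_titration_series(kd=0.76, seed=4).table
        b = simulate_titration_series(kd=0.76, seed=4).table
        assert a.equals(b)


class TestLigandSimulation:
    def test_zero_saturation_profile_flat(self):
        s = simulate_ligand_dispersion(1600.0, [0.0, 0.06], noise_sigma=0.0, seed=1)
        flat = s.table[s.table.saturation == 0.0]
        assert np.allclose(flat.r2_eff, flat.r2_eff.iloc[0])

    def test_amplitude_increases_with_saturation(self):
        s = simulate_ligand_dispersion(1600.0, [0.02, 0.06, 0.12],
                                       noise_sigma=0.0, seed=1)
        amps = [np.ptp(g.groupby("nu_cpmg_hz").r2_eff.mean().to_numpy())
                for _, g in s.table.groupby("saturation")]
        assert amps[0] < amps[1] < amps[2]

    def test_saturation_bounds_enforced(self):
        with pytest.raises(ValueError):
            simulate_ligand_dispersion(1600.0, [0.6])
        with pytest.raises(ValueError):
            simulate_ligand_dispersion(-5.0, [0.1])
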