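"""Subglobal exchange fits, Monte Carlo errors, model comparison."""

import numpy as np
import pytest

from pr10flex.dispersion import DispersionCurve, model_r2eff_closed
from pr10flex.exchange import (
    ClusterSpec,
    compare_models,
    compare_to_unfolding_shifts,
    exchange_timescale,
    fit_subglobal,
    monte_carlo_uncertainty,
)
from pr10flex.synthetic import backbone_schedule

SCHED = backbone_schedule()


def make_curves(kex, p_b, deltas, r2_0=15.0, sigma=0.3, noise=0.0, seed=0):
    """Noisy model curves at both fields for residues in ``deltas``."""
    rng = np.random.default_rng(seed)
    curves = []
    for res, d in deltas.items():
        for f in (600.0, 700.0):
            model = model_r2eff_closed(kex, p_b, d, r2_0, f, "15N",
                                       SCHED.nu_cpmg, relax_time=SCHED.relax_time)
            r2 = np.atleast_1d(model) + rng.normal(0.0, noise, len(SCHED.n_cycles))
            curves.append(DispersionCurve(
                residue_id=res, field=f, nu_cpmg=SCHED.nu_cpmg, r2_eff=r2,
                sigma=np.full(len(r2), sigma), relax_time=SCHED.relax_time))
    return curves


class TestFitSubglobal:
    def test_noiseless_roundtrip_recovers_truth(self, helix_truth,
                                                helix_curves_noiseless):
        spec = ClusterSpec("helix", helix_truth.residues)
        fit = fit_subglobal(helix_curves_noiseless, spec, max_starts=2)
        assert fit.kex == pytest.approx(helix_truth.kex, rel=0.01)
        assert fit.p_b == pytest.approx(helix_truth.p_b, rel=0.01)
        for r in helix_truth.residues:
            assert fit.delta_ppm[r] == pytest.approx(helix_truth.delta_ppm[r], rel=0.01)

    def test_shallow_valley_still_identified_noiselessly(self):
        """p_B and ddelta trade off at low p_B; exact recovery must still hold."""
        deltas = {1: 0.8, 2: 1.6, 3: 2.8, 4: 3.3}
        curves = make_curves(810.0, 0.013, deltas, sigma=0.05)
        fit = fit_subglobal(curves, ClusterSpec("sheet-like", tuple(deltas)),
                            max_starts=3)
        assert fit.kex == pytest.approx(810.0, rel=0.01)
        assert fit.p_b == pytest.approx(0.013, rel=0.02)

    def test_deterministic_between_calls(self, helix_truth, helix_curves_noisy):
        spec = ClusterSpec("helix", helix_truth.residues)
        f1 = fit_subglobal(helix_curves_noisy, spec, max_starts=2)
        f2 = fit_subglobal(helix_curves_noisy, spec, max_starts=2)
        assert f1.chi2 == f2.chi2 and f1.kex == f2.kex

    def test_more_starts_never_worse(self, helix_truth, helix_curves_noisy):
        spec = ClusterSpec("helix", helix_truth.residues)
        chi1 = fit_subglobal(helix_curves_noisy, spec, max_starts=1).chi2
        chi3 = fit_subglobal(helix_curves_noisy, spec, max_starts=3).chi2
        assert chi3 <= chi1 + 1e-9

    def test_conflicting_curves_yield_large_reduced_chi2(self):
        a = make_curves(300.0, 0.05, {1: 2.0}, sigma=0.05)
        b = make_curves(4000.0, 0.15, {2: 2.5}, sigma=0.05)
        fit = fit_subglobal(a + b, ClusterSpec("conflict", (1, 2)), max_starts=4)
        assert fit.reduced_chi2 > 10

    def test_missing_residue_data_rejected(self, helix_curves_noiseless):
        spec = ClusterSpec("bad", (16, 17, 999))
        with pytest.raises(ValueError):
            fit_subglobal(helix_curves_noiseless, spec)

    def test_single_field_warns(self):
        deltas = {1: 1.0, 2: 2.0}
        curves = [c for c in make_curves(1000.0, 0.05, deltas) if c.field == 700.0]
        with pytest.warns(UserWarning):
            fit_subglobal(curves, ClusterSpec("one-field", (1, 2)), max_starts=2)


class TestMonteCarlo:
    def test_sigma_vanishes_with_noise(self):
        deltas = {1: 1.0, 2: 2.0, 3: 3.0}
        curves = make_curves(1000.0, 0.05, deltas, sigma=0.01)
        spec = ClusterSpec("tiny", tuple(deltas))
        fit = fit_subglobal(curves, spec, max_starts=2)
        fit = monte_carlo_uncertainty(fit, curves, spec, n_datasets=10, seed=1)
        assert fit.kex_sigma < 2.0
        assert fit.p_b_sigma < 1e-3

    def test_sigma_scales_with_noise(self):
        deltas = {1: 1.0, 2: 2.0, 3: 3.0}
        curves = make_curves(1000.0, 0.05, deltas, sigma=0.3, noise=0.3, seed=5)
        spec = ClusterSpec("tiny", tuple(deltas))
        fit = fit_subglobal(curves, spec, max_starts=2)
        fit = monte_carlo_uncertainty(fit, curves, spec, n_datasets=20, seed=1)
        assert fit.kex_sigma > 2.0

    def test_one_sigma_interval_covers_truth_two_thirds_of_time(self):
        """Parametric bootstrap calibration on a small cluster."""
        deltas = {1: 0.8, 2: 1.6, 3: 2.6}
        spec = ClusterSpec("cov", tuple(deltas))
        hits = 0
        n_rep = 30
        for i in range(n_rep):
            curves = make_curves(1060.0, 0.079, deltas, sigma=0.3, noise=0.3,
                                 seed=100 + i)
            fit = fit_subglobal(curves, spec, max_starts=2)
            fit = monte_carlo_uncertainty(fit, curves, spec, n_datasets=25,
                                          seed=i)
            if abs(fit.kex - 1060.0) <= fit.kex_sigma:
                hits += 1
        assert 0.53 <= hits / n_rep <= 0.83

    def test_too_few_datasets_rejected(self, helix_truth, helix_curves_noisy):
        spec = ClusterSpec("helix", helix_truth.residues)
        fit = fit_subglobal(helix_curves_noisy, spec, max_starts=1)
        with pytest.raises(ValueError):
            monte_carlo_uncertainty(fit, helix_curves_noisy, spec, n_datasets=1)


class TestCompareModels:
    def test_two_distinct_processes_preferred(self):
        helix = make_curves(1060.0, 0.079, {1: 1.0, 2: 1.8, 3: 2.6, 4: 1.4},
                            noise=0.3, sigma=0.3, seed=1)
        sheet = make_curves(810.0, 0.013, {11: 1.5, 12: 2.5, 13: 3.2, 14: 2.0},
                            noise=0.3, sigma=0.3, seed=2)
        out = compare_models(
            helix + sheet,
            ClusterSpec("all", (1, 2, 3, 4, 11, 12, 13, 14)),
            (ClusterSpec("helix", (1, 2, 3, 4)), ClusterSpec("sheet", (11, 12, 13, 14))),
            max_starts=2)
        assert out["two_process_preferred"]

    def test_single_process_not_rejected_on_homogeneous_data(self):
        data = make_curves(1000.0, 0.05, {1: 1.0, 2: 1.8, 3: 2.6, 4: 1.4,
                                          5: 2.0, 6: 1.2}, noise=0.3,
                           sigma=0.3, seed=3)
        out = compare_models(
            data,
            ClusterSpec("all", (1, 2, 3, 4, 5, 6)),
            (ClusterSpec("a", (1, 2, 3)), ClusterSpec("b", (4, 5, 6))),
            max_starts=2)
        assert not out["two_process_preferred"]


class TestTimescale:
    @pytest.mark.parametrize("kex,ms", [(810.0, 1.2), (1060.0, 0.9), (1000.0, 1.0)])
    def test_reciprocal_in_milliseconds(self, kex, ms):
        assert exchange_timescale(kex) == ms

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            exchange_timescale(0.0)


class TestUnfoldingComparison:
    def test_identical_vectors(self):
        v = {1: 1.0, 2: 2.0, 3: 3.0}
        out = compare_to_unfolding_shifts(v, dict(v))
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["fraction_smaller_than_unfolding"] == 0.0

    def test_reference_twice_as_large_flags_smaller(self):
        v = {r: 0.5 + 0.1 * r for r in range(1, 11)}
        ref = {r: 2 * x for r, x in v.items()}
        out = compare_to_unfolding_shifts(v, ref)
        assert out["fraction_smaller_than_unfolding"] == 1.0
        assert out["smaller_than_unfolding"]

    def test_independent_vectors_uncorrelated_on_average(self):
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(100):
            x = {r: float(v) for r, v in enumerate(rng.uniform(0, 3, 26))}
            y = {r: float(v) for r, v in enumerate(rng.uniform(0, 3, 26))}
            rs.append(abs(compare_to_unfolding_shifts(x, y)["pearson_r"]))
        assert np.mean(rs) < 0.2

    def test_too_few_shared_residues(self):
        with pytest.raises(ValueError):
            compare_to_unfolding_shifts({1: 1.0, 2: 2.0}, {1: 1.0, 2: 2.0})
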