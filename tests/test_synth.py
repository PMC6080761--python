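"""Synthetic generators: parameter recovery against their own ground truth."""

import numpy as np
import pytest
from scipy import stats

from protonpmf import BiasWindow, EnergeticsTarget, Surface1D, calibrate_surface
from protonpmf.constants import KB, TEMPERATURE
from protonpmf.synth import (
    EventChainParams,
    OUParams,
    event_chain_rates,
    gen_boltzmann_window_samples,
    gen_correlated_pair,
    gen_event_chain,
    gen_ou_series,
    gen_structure_models,
)
from protonpmf.trajectory import pearson

KT = KB * TEMPERATURE


class TestOUSeries:
    def test_stationary_mean_and_sd(self):
        # average the estimates over 10 seeds so the check sits well inside
        # the generator's single-run band (mean 5.1 +/- 0.01 at n = 10^4)
        means, sds = [], []
        for seed in range(10):
            x = gen_ou_series(OUParams(mean=5.1, sd=0.2, length=10_000, seed=seed))
            means.append(x.mean())
            sds.append(x.std(ddof=1))
        assert np.mean(means) == pytest.approx(5.1, abs=0.01)
        assert np.mean(sds) == pytest.approx(0.2, abs=0.01)

    def test_lag1_autocorrelation(self):
        tau = 2.0
        x = gen_ou_series(OUParams(mean=0.0, sd=1.0, relaxation_frames=tau,
                                   length=200_000, seed=3))
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(np.exp(-1.0 / tau), abs=0.01)

    def test_zero_sd_is_constant(self):
        x = gen_ou_series(OUParams(mean=4.2, sd=0.0, length=100, seed=0))
        assert np.all(x == 4.2)

    def test_determinism(self):
        p = OUParams(mean=1.0, sd=0.5, length=500, seed=11)
        assert np.array_equal(gen_ou_series(p), gen_ou_series(p))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            OUParams(mean=0.0, sd=-0.1)
        with pytest.raises(ValueError):
            OUParams(mean=0.0, sd=1.0, relaxation_frames=0.5)


class TestEventChain:
    def test_rates_realize_occupancy_and_dwell(self):
        q_off, q_on = event_chain_rates(EventChainParams(occupancy=0.5, mean_dwell_frames=20))
        assert q_off == pytest.approx(1.0 / 20.0)
        assert q_on == pytest.approx(1.0 / 20.0)  # symmetric at 50%

    def test_occupancy_recovered(self):
        x = gen_event_chain(
            EventChainParams(occupancy=0.7, mean_dwell_frames=10, length=100_000, seed=4)
        )
        assert x.mean() == pytest.approx(0.7, abs=0.02)

    def test_mean_dwell_recovered(self):
        x = gen_event_chain(
            EventChainParams(occupancy=0.5, mean_dwell_frames=25, length=200_000, seed=5)
        )
        # bonded-run lengths from the transition structure
        changes = np.flatnonzero(np.diff(x.astype(int)))
        runs = np.diff(np.concatenate([[-1], changes, [len(x) - 1]]))
        on_runs = runs[0 if x[0] else 1 :: 2]
        assert on_runs.mean() == pytest.approx(25.0, rel=0.05)

    def test_degenerate_occupancies(self):
        assert gen_event_chain(EventChainParams(occupancy=1.0, length=50)).all()
        assert not gen_event_chain(EventChainParams(occupancy=0.0, length=50)).any()

    def test_infeasible_dwell_rejected(self):
        with pytest.raises(ValueError):
            event_chain_rates(EventChainParams(occupancy=0.99, mean_dwell_frames=20))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EventChainParams(occupancy=1.2)
        with pytest.raises(ValueError):
            EventChainParams(occupancy=0.5, mean_dwell_frames=0.5)


class TestCorrelatedPair:
    def test_target_correlation_recovered(self):
        rs = []
        for seed in range(10):
            d, c = gen_correlated_pair(
                0.63, OUParams(mean=5.1, sd=0.2, length=5_000, seed=seed),
                count_mean=6.0, count_sd=1.0, seed=seed,
            )
            rs.append(pearson(d, c.astype(float)))
        assert np.mean(rs) == pytest.approx(0.63, abs=0.03)

    def test_null_correlation(self):
        d, c = gen_correlated_pair(
            0.0, OUParams(mean=5.1, sd=0.2, length=20_000, seed=8),
            count_mean=6.0, count_sd=1.0, seed=8,
        )
        assert abs(pearson(d, c.astype(float))) < 0.03

    def test_count_moments_recovered(self):
        _, c = gen_correlated_pair(
            0.3, OUParams(mean=5.0, sd=0.3, length=50_000, seed=9),
            count_mean=6.0, count_sd=1.0, seed=9,
        )
        assert c.mean() == pytest.approx(6.0, abs=0.05)
        # rounding to integers adds ~1/12 of variance on top of count_sd^2
        assert c.std(ddof=1) == pytest.approx(np.sqrt(1.0 + 1.0 / 12.0), abs=0.03)
        assert np.issubdtype(c.dtype, np.integer)
        assert (c >= 0).all()

    def test_zero_count_sd_with_nonzero_target_rejected(self):
        with pytest.raises(ValueError):
            gen_correlated_pair(0.5, OUParams(mean=5.0, sd=0.2), 6.0, 0.0)

    def test_target_magnitude_one_rejected(self):
        with pytest.raises(ValueError):
            gen_correlated_pair(1.0, OUParams(mean=5.0, sd=0.2), 6.0, 1.0)


class TestBoltzmannOracle:
    def test_gaussian_closed_form_on_flat_surface(self):
        flat = Surface1D(well_positions=(-1.0, 1.0), well_depths=(0.0, 0.0))
        w = BiasWindow(d_ref=-0.3, k=150.0)
        ts = gen_boltzmann_window_samples(flat, w, 200_000, seed=10)
        assert ts.samples.mean() == pytest.approx(-0.3, abs=0.002)
        assert ts.samples.var() == pytest.approx(KT / 150.0, rel=0.02)

    def test_chi_square_against_analytic_density(self):
        surface = calibrate_surface(EnergeticsTarget(3.0, 6.0))
        w = BiasWindow(d_ref=-0.6, k=150.0)
        ts = gen_boltzmann_window_samples(surface, w, 100_000, seed=12)
        edges = np.linspace(-1.0, -0.2, 33)
        obs, _ = np.histogram(ts.samples, bins=edges)
        grid = np.linspace(-1.0, -0.2, 3201)
        u = surface.energy(grid) + 0.5 * w.k * (grid - w.d_ref) ** 2
        p = np.exp(-(u - u.min()) / KT)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(grid))])
        cdf /= cdf[-1]
        probs = np.diff(np.interp(edges, grid, cdf))
        probs /= probs.sum()
        keep = probs * len(ts.samples) >= 5
        chi2 = np.sum(
            (obs[keep] - probs[keep] * obs.sum()) ** 2 / (probs[keep] * obs.sum())
        )
        pval = stats.chi2.sf(chi2, df=int(keep.sum()) - 1)
        assert pval > 0.01

    def test_determinism(self):
        surface = calibrate_surface(EnergeticsTarget(3.0, 6.0))
        w = BiasWindow(d_ref=0.0)
        a = gen_boltzmann_window_samples(surface, w, 1_000, seed=1)
        b = gen_boltzmann_window_samples(surface, w, 1_000, seed=1)
        assert np.array_equal(a.samples, b.samples)


class TestStructureFixtures:
    def test_model_zero_is_reference(self):
        models, _ = gen_structure_models(3, jitter_spec={"helix": 1.0}, seed=0)
        ref, _ = gen_structure_models(1, seed=99)
        assert np.array_equal(models[0].coords, ref[0].coords)

    def test_masks_partition_residues(self):
        models, masks = gen_structure_models(1, seed=0)
        total = np.zeros(len(models[0].atom_names), dtype=int)
        for mask in masks.values():
            total += mask.astype(int)
        assert np.all(total == 1)

    def test_fixture_round_trip_through_pdb(self, tmp_path):
        from protonpmf.io import read_structure
        from protonpmf.synth import gen_structure_fixture

        path = tmp_path / "fixture.pdb"
        gen_structure_fixture(path, n_models=3, jitter_spec={"loop": 0.8}, seed=5)
        models, _ = gen_structure_models(3, jitter_spec={"loop": 0.8}, seed=5)
        back = read_structure(path)
        assert len(back) == 3
        for orig, rt in zip(models, back):
            assert np.max(np.abs(orig.coords - rt.coords)) < 1e-3 + 1e-9
            assert rt.atom_names == orig.atom_names

    def test_determinism(self):
        a, _ = gen_structure_models(4, jitter_spec={"helix": 0.5}, seed=7)
        b, _ = gen_structure_models(4, jitter_spec={"helix": 0.5}, seed=7)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.coords, mb.coords)
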