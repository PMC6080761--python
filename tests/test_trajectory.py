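"""Trajectory statistics and structure-model operations."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from protonpmf.synth import gen_structure_models
from protonpmf.trajectory import (
    DegenerateSuperpositionError,
    HBondCriteria,
    TrajectoryTable,
    distance_histogram,
    hbond_occupancy,
    kabsch_rmsd,
    measure_distance,
    occupancy_report,
    pearson,
    percentiles,
    rmsd_profile,
    smooth,
    water_count_series,
)


class TestHBond:
    def test_geometric_criteria(self):
        crit = HBondCriteria(distance_cutoff=3.5, angle_cutoff=140.0)
        d = np.array([3.4, 3.6, 3.5, 3.0])
        a = np.array([150.0, 150.0, 139.0, 140.0])
        assert list(crit.evaluate(d, a)) == [True, False, False, True]

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            HBondCriteria(distance_cutoff=0.0)
        with pytest.raises(ValueError):
            HBondCriteria(angle_cutoff=-10.0)

    def test_mismatched_series_rejected(self):
        with pytest.raises(ValueError):
            HBondCriteria().evaluate(np.zeros(3), np.zeros(4))

    def test_occupancy_from_events_and_geometry_agree(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(2.5, 4.5, 1000)
        a = rng.uniform(100.0, 180.0, 1000)
        events = HBondCriteria().evaluate(d, a)
        assert hbond_occupancy(events) == hbond_occupancy(
            distances=d, angles=a, criteria=HBondCriteria()
        )

    def test_occupancy_and_complement_sum_to_100(self):
        events = np.array([True] * 75 + [False] * 25)
        assert hbond_occupancy(events) == 75
        assert hbond_occupancy(~events) == 25

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            hbond_occupancy(np.array([], dtype=bool))

    def test_report_suppresses_sub_3pct_partners(self):
        n = 1000
        chans = {
            "major": np.arange(n) < 990,   # 99%
            "rare": np.arange(n) < 20,     # 2%
            "edge": np.arange(n) < 30,     # exactly 3% -> suppressed (strict >)
        }
        report = occupancy_report(chans)
        assert report == {"major": 99}


class TestSeriesStatistics:
    def test_water_count_series_last_half(self):
        frames = pd.DataFrame({"waters": [0] * 50 + [6] * 25 + [8] * 25})
        mean, sd = water_count_series(TrajectoryTable(frames), "waters")
        tail = np.array([6] * 25 + [8] * 25, dtype=float)
        assert mean == pytest.approx(tail.mean())
        assert sd == pytest.approx(tail.std(ddof=1))

    def test_water_count_missing_channel(self):
        with pytest.raises(KeyError):
            water_count_series(TrajectoryTable(pd.DataFrame({"a": [1]})), "waters")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryTable(pd.DataFrame({"waters": [1, -2, 3]}))

    def test_pearson_exact_cases(self):
        x = np.arange(100, dtype=float)
        assert pearson(x, 2.0 * x + 1.0) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_pearson_degenerate_input(self):
        with pytest.raises(ValueError):
            pearson(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            pearson(np.arange(2.0), np.arange(2.0))

    def test_percentiles_match_numpy(self):
        x = np.arange(1.0, 101.0)
        p = percentiles(x)
        assert p[50] == pytest.approx(50.5)
        for q in (5, 25, 75, 95):
            assert p[q] == pytest.approx(np.percentile(x, q))
        with pytest.raises(ValueError):
            percentiles([])


class TestSmooth:
    def test_identity_cases(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert np.array_equal(smooth(x, 1), x)
        assert np.allclose(smooth(np.full(20, 2.5), 7), 2.5)

    def test_linear_series_preserved(self):
        x = np.linspace(0.0, 10.0, 50)
        assert np.allclose(smooth(x, 9), x)  # symmetric window, linear trend

    def test_interior_is_moving_average(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        s = smooth(x, 5)
        assert s[10] == pytest.approx(x[8:13].mean())

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.zeros(10), 4)
        with pytest.raises(ValueError):
            smooth(np.zeros(3), 5)


class TestDistanceHistogram:
    def test_bimodal_modes_recovered(self):
        rng = np.random.default_rng(2)
        x = np.concatenate(
            [rng.normal(4.4, 0.1, 20_000), rng.normal(5.3, 0.1, 10_000)]
        )
        density, edges, modes = distance_histogram(x, bin_width=0.05)
        widths = np.diff(edges)
        assert np.sum(density * widths) == pytest.approx(1.0)
        assert abs(modes[0] - 4.4) < 0.08          # primary mode first
        assert any(abs(m - 5.3) < 0.08 for m in modes)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distance_histogram([])


class TestKabsch:
    def test_identical_clouds_zero(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((30, 3))
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((30, 3)) * 5.0
        rot = Rotation.random(random_state=5).as_matrix()
        b = a @ rot.T + np.array([10.0, -3.0, 7.0])
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((50, 3)) * 4.0
        b = a + rng.standard_normal((50, 3)) * 0.8
        got = kabsch_rmsd(a, b)
        # independent oracle: scipy's least-squares rotation alignment
        rot, rssd = Rotation.align_vectors(
            a - a.mean(axis=0), b - b.mean(axis=0)
        )
        expected = rssd / np.sqrt(len(a))
        assert got == pytest.approx(expected, rel=1e-8)

    def test_selection_mask(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((20, 3)) * 3.0
        b = a.copy()
        b[10:] += 100.0  # gross mismatch outside the selection
        mask = np.arange(20) < 10
        assert kabsch_rmsd(a, b, selection_mask=mask) == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_selections_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(DegenerateSuperpositionError):
            kabsch_rmsd(line, line + 1.0)
        with pytest.raises(DegenerateSuperpositionError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((5, 3)), np.zeros((6, 3)))


class TestRmsdProfile:
    def test_zero_jitter_all_zero(self):
        models, masks = gen_structure_models(4, jitter_spec={}, seed=0)
        df = rmsd_profile(models, models[0], masks)
        assert np.allclose(df.to_numpy(), 0.0, atol=1e-12)

    def test_jitter_scaling_by_region(self):
        # isotropic per-atom jitter sigma gives E[RMSD^2] ~ 3 sigma^2 before
        # the (small) superposition absorption; check the region ordering and
        # magnitude over many models
        sig_h, sig_l = 0.4, 1.5
        models, masks = gen_structure_models(
            60, jitter_spec={"helix": sig_h, "loop": sig_l}, seed=1
        )
        df = rmsd_profile(models[1:], models[0], masks, span_fraction=1.0)
        mean = df.attrs["mean"]
        assert mean["helix"] == pytest.approx(sig_h * np.sqrt(3.0), rel=0.12)
        assert mean["loop"] == pytest.approx(sig_l * np.sqrt(3.0), rel=0.12)
        assert mean["loop"] > mean["helix"]

    def test_mismatched_atom_count_rejected(self):
        models, masks = gen_structure_models(2, seed=2)
        small, _ = gen_structure_models(1, region_spec=[("helix", 5)], seed=2)
        with pytest.raises(ValueError):
            rmsd_profile(small, models[0], masks)


class TestMeasureDistance:
    def test_known_distance(self):
        models, _ = gen_structure_models(1, seed=0)
        m = models[0]
        i, j = 0, 7
        expected = float(np.linalg.norm(m.coords[i] - m.coords[j]))
        got = measure_distance(
            m,
            ("A", int(m.residue_ids[i]), "CA"),
            ("A", int(m.residue_ids[j]), "CA"),
        )
        assert got == pytest.approx(expected)

    def test_missing_atom_reports_neighbours(self):
        models, _ = gen_structure_models(1, seed=0)
        with pytest.raises(KeyError, match="CA"):
            measure_distance(models[0], ("A", 1, "OW"), ("A", 2, "CA"))
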